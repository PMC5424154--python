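"""Probe panels for single-molecule molecular inversion probe (smMIP) capture.

A smMIP is a single-stranded oligo whose two terminal targeting sequences
(the *extension arm* and the *ligation arm*) hybridize to the sequences
flanking a target region.  Gap-filling polymerization and ligation
circularize the probe, capturing a copy of the target together with a
random unique molecular identifier (UMI) carried by the probe.  A *panel*
is the ordered set of probes used in one capture reaction.

Assembled oligo convention (5'->3'):

    ligation_arm + backbone + N*umi_length + extension_arm

i.e. the UMI sits between the extension arm and the universal
amplification primer contained in the backbone.  For expression panels
the two arms are each 16-24 nt and sum to 40 nt; with the standard 9-nt
UMI and 30-nt backbone this yields a 79-nt oligo.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "STANDARD_BACKBONE",
    "Probe",
    "Panel",
    "ProtocolParams",
    "PanelFormatError",
    "SequenceError",
    "load_panel",
    "write_panel",
    "assemble_oligo",
    "pool_concentration",
    "smmip_molecules_for_input",
    "phosphorylation_volume",
]

#: Common backbone carrying the universal primer binding sites.
STANDARD_BACKBONE = "CTTCAGCTTCCCGATATCCGACGGTAGTGT"

_VALID_BASES = frozenset("ACGT")

PANEL_COLUMNS = [
    "name",
    "gene",
    "target_id",
    "target_start",
    "target_end",
    "extension_arm",
    "ligation_arm",
    "umi_length",
    "junction_crossing",
    "oligo",
]


class PanelFormatError(ValueError):
    """Malformed panel table (missing columns, duplicate names, bad fields)."""


class SequenceError(ValueError):
    """A nucleotide sequence contains characters outside A/C/G/T."""


def _check_sequence(seq: str, what: str) -> str:
    seq = seq.upper()
    bad = set(seq) - _VALID_BASES
    if bad:
        raise SequenceError(f"{what} contains non-ACGT characters: {sorted(bad)}")
    return seq


@dataclass(frozen=True)
class Probe:
    """One smMIP: targeting arms, UMI/backbone layout and target coordinates.

    ``target_start``/``target_end`` are 0-based half-open transcript
    coordinates of the gap-fill region (the sequence copied into the
    captured circle).
    """

    name: str
    extension_arm: str
    ligation_arm: str
    target_id: str
    target_start: int
    target_end: int
    umi_length: int = 9
    backbone: str = STANDARD_BACKBONE
    junction_crossing: bool = False
    gene: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "extension_arm", _check_sequence(self.extension_arm, f"extension arm of {self.name}"))
        object.__setattr__(self, "ligation_arm", _check_sequence(self.ligation_arm, f"ligation arm of {self.name}"))
        if len(self.extension_arm) < 1 or len(self.ligation_arm) < 1:
            raise PanelFormatError(f"probe {self.name}: arms must be non-empty")
        if self.umi_length < 0:
            raise PanelFormatError(f"probe {self.name}: negative umi_length")
        if not (0 <= self.target_start <= self.target_end):
            raise PanelFormatError(
                f"probe {self.name}: invalid target coordinates [{self.target_start}, {self.target_end})"
            )

    @property
    def arm_total(self) -> int:
        return len(self.extension_arm) + len(self.ligation_arm)

    @property
    def gap_fill_length(self) -> int:
        return self.target_end - self.target_start


@dataclass
class Panel:
    """Ordered probe collection sharing one UMI length."""

    probes: list[Probe] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [p.name for p in self.probes]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise PanelFormatError(f"duplicate probe names: {sorted(dupes)}")
        umis = {p.umi_length for p in self.probes}
        if len(umis) > 1:
            raise PanelFormatError(f"probes disagree on umi_length: {sorted(umis)}")

    def __len__(self) -> int:
        return len(self.probes)

    def __iter__(self):
        return iter(self.probes)

    def __getitem__(self, name: str) -> Probe:
        for p in self.probes:
            if p.name == name:
                return p
        raise KeyError(name)

    @property
    def umi_length(self) -> int:
        if not self.probes:
            return 9
        return self.probes[0].umi_length

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.probes]

    @property
    def gene_map(self) -> dict[str, str]:
        """target_id -> gene (falls back to the target id itself)."""
        return {p.target_id: (p.gene or p.target_id) for p in self.probes}


@dataclass(frozen=True)
class ProtocolParams:
    """Reagent arithmetic constants for the capture protocol.

    ``gdna_molecules_per_ng`` is the probe-to-template molar ratio expressed
    as probe molecules per ng of genomic DNA; cDNA captures use
    ``cdna_multiplier`` times more probe to compensate for the larger number
    of template molecules per nanogram.
    """

    gdna_molecules_per_ng: float = 264_000.0
    cdna_multiplier: float = 10.0
    aliquot_ul_per_probe: float = 0.5

    def __post_init__(self) -> None:
        if min(self.gdna_molecules_per_ng, self.cdna_multiplier, self.aliquot_ul_per_probe) <= 0:
            raise ValueError("protocol parameters must be strictly positive")


# ---------------------------------------------------------------------------
# Panel I/O (tab-separated, '#' comments, one probe per row)
# ---------------------------------------------------------------------------

_REQUIRED = ["name", "extension_arm", "ligation_arm", "target_id", "target_start", "target_end"]


def load_panel(path: str | os.PathLike | io.TextIOBase) -> Panel:
    """Read a probe panel from a tab-separated table.

    Required columns: name, extension_arm, ligation_arm, target_id,
    target_start, target_end.  Optional: gene, umi_length,
    junction_crossing, oligo (ignored on input).  Lines starting with '#'
    are comments.  Sequences are upper-cased.
    """
    close = False
    if isinstance(path, io.TextIOBase):
        fh = path
    else:
        fh = open(path)
        close = True
    try:
        header: list[str] | None = None
        probes: list[Probe] = []
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                missing = [c for c in _REQUIRED if c not in header]
                if missing:
                    raise PanelFormatError(f"panel table missing columns: {missing}")
                continue
            row = dict(zip(header, fields))
            probes.append(
                Probe(
                    name=row["name"],
                    extension_arm=row["extension_arm"],
                    ligation_arm=row["ligation_arm"],
                    target_id=row["target_id"],
                    target_start=int(row["target_start"]),
                    target_end=int(row["target_end"]),
                    umi_length=int(row.get("umi_length", 9) or 9),
                    junction_crossing=str(row.get("junction_crossing", "0")).strip().lower() in ("1", "true", "yes"),
                    gene=row.get("gene", "") or "",
                )
            )
        if header is None:
            raise PanelFormatError("empty panel file (no header)")
    finally:
        if close:
            fh.close()
    return Panel(probes)


def write_panel(panel: Panel, path: str | os.PathLike | io.TextIOBase) -> None:
    """Write a panel in the dialect read by :func:`load_panel` (byte-stable)."""
    close = False
    if isinstance(path, io.TextIOBase):
        fh = path
    else:
        fh = open(path, "w")
        close = True
    try:
        fh.write("# smMIP panel; oligo = ligation_arm + backbone + N*umi_length + extension_arm (5'->3')\n")
        fh.write("\t".join(PANEL_COLUMNS) + "\n")
        for p in panel:
            fh.write(
                "\t".join(
                    [
                        p.name,
                        p.gene,
                        p.target_id,
                        str(p.target_start),
                        str(p.target_end),
                        p.extension_arm,
                        p.ligation_arm,
                        str(p.umi_length),
                        "1" if p.junction_crossing else "0",
                        assemble_oligo(p),
                    ]
                )
                + "\n"
            )
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------------------
# Oligo assembly and protocol arithmetic
# ---------------------------------------------------------------------------


def assemble_oligo(probe: Probe) -> str:
    """Assemble the single-stranded oligo sequence for ordering.

    Layout (5'->3'): ligation arm, common backbone, UMI placeholder
    ('N' * umi_length), extension arm — the UMI is adjacent to the
    extension arm.  Length is exactly
    ``len(arms) + len(backbone) + umi_length``.
    """
    if not probe.backbone:
        raise ValueError("probe has an empty backbone; configure a backbone sequence")
    return probe.ligation_arm + probe.backbone + "N" * probe.umi_length + probe.extension_arm


def pool_concentration(
    volumes: Sequence[float], concentrations: Sequence[float]
) -> tuple[float, float, list[float]]:
    """Pool individual probe stocks and report the resulting concentrations.

    Conservation of moles: ``v_i * c_i = V_pool * c_i,pool`` for each
    species.  Returns ``(pool_volume, total_concentration,
    per_species_concentrations)``; volumes in ul, concentrations in uM.
    """
    if len(volumes) != len(concentrations):
        raise ValueError("volumes and concentrations must have equal length")
    if len(volumes) == 0:
        raise ValueError("empty pool")
    if min(volumes) <= 0 or min(concentrations) <= 0:
        raise ValueError("volumes and concentrations must be positive")
    v_pool = float(sum(volumes))
    per_species = [v * c / v_pool for v, c in zip(volumes, concentrations)]
    return v_pool, sum(per_species), per_species


def smmip_molecules_for_input(
    input_ng: float, template_kind: str, params: ProtocolParams = ProtocolParams()
) -> float:
    """Number of probe molecules to add for a given template mass (ng)."""
    if input_ng <= 0:
        raise ValueError("input mass must be positive")
    kind = template_kind.lower()
    if kind == "gdna":
        return input_ng * params.gdna_molecules_per_ng
    if kind == "cdna":
        return input_ng * params.gdna_molecules_per_ng * params.cdna_multiplier
    raise ValueError(f"unknown template kind {template_kind!r}; expected 'gdna' or 'cdna'")


def phosphorylation_volume(n_probes: int, params: ProtocolParams = ProtocolParams()) -> float:
    """Volume (ul) of pooled probe aliquoted into the phosphorylation reaction."""
    if n_probes < 1:
        raise ValueError("need at least one probe")
    return n_probes * params.aliquot_ul_per_probe
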