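"""Paired-end reads to error-corrected unique-molecule counts.

Reads are assigned to probes by arm matching alone — no reference
alignment — so counting is free of mapping bias.  The workflow per
sample is:

1. match each read pair to a probe by Hamming distance on the two arm
   sequences (at most ``max_arm_mismatches`` per arm, default 2);
2. remove likely extension-ligation dimers (no genuine gap-fill);
3. group retained reads by UMI within each probe;
4. apply the read-coverage threshold *R*: keep the UMIs that jointly
   account for at least 95% of the probe's reads, discarding the
   low-coverage tail of UMIs created by sequencing errors.

Read layout convention (configurable via :class:`ReadLayout`): mate 1
begins with the ligation arm followed by the gap-fill; mate 2 begins
with the UMI followed by the reverse complement of the extension arm.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .design import revcomp
from .panel import Panel, Probe

__all__ = [
    "ReadLayout",
    "ProbeAssignment",
    "UmiTable",
    "MoleculeCounts",
    "assign_probe",
    "detect_dimer",
    "tally_umis",
    "error_corrected_count",
    "count_sample",
    "count_samples",
    "read_sample_sheet",
]


@dataclass(frozen=True)
class ReadLayout:
    """Where the UMI and the arm sequences sit on the two mates."""

    umi_length: int = 9
    umi_read: int = 2  # mate carrying the UMI prefix
    max_arm_mismatches: int = 2
    dimer_min_insert: int = 20

    def __post_init__(self) -> None:
        if self.umi_length < 0 or self.max_arm_mismatches < 0:
            raise ValueError("umi_length and max_arm_mismatches must be >= 0")
        if self.umi_read not in (1, 2):
            raise ValueError("umi_read must be 1 or 2")


@dataclass
class ProbeAssignment:
    """Outcome of matching one read pair against the panel."""

    read_id: str
    probe_name: str | None
    mismatches_lig: int = 0
    mismatches_ext: int = 0
    umi: str = ""
    dimer: bool = False
    reason: str = ""  # 'ambiguous' / 'short' / 'unmatched' when unassigned

    @property
    def assigned(self) -> bool:
        return self.probe_name is not None


class _PanelIndex:
    """Precomputed arm matrices and exact-match dictionaries for a panel."""

    def __init__(self, panel: Panel, layout: ReadLayout):
        self.panel = panel
        self.layout = layout
        self.probes = list(panel)
        self.names = [p.name for p in self.probes]
        self.lig = [p.ligation_arm for p in self.probes]
        self.ext_rc = [revcomp(p.extension_arm) for p in self.probes]
        self.lig_lens = np.array([len(a) for a in self.lig])
        self.ext_lens = np.array([len(a) for a in self.ext_rc])
        self.max_lig = int(self.lig_lens.max()) if self.probes else 0
        self.max_ext = int(self.ext_lens.max()) if self.probes else 0
        P = len(self.probes)
        self.lig_mat = np.zeros((P, self.max_lig), dtype=np.uint8)
        self.ext_mat = np.zeros((P, self.max_ext), dtype=np.uint8)
        self.lig_mask = np.zeros((P, self.max_lig), dtype=bool)
        self.ext_mask = np.zeros((P, self.max_ext), dtype=bool)
        for i, (l, e) in enumerate(zip(self.lig, self.ext_rc)):
            self.lig_mat[i, : len(l)] = np.frombuffer(l.encode(), dtype=np.uint8)
            self.lig_mask[i, : len(l)] = True
            self.ext_mat[i, : len(e)] = np.frombuffer(e.encode(), dtype=np.uint8)
            self.ext_mask[i, : len(e)] = True
        # exact joint lookup: (lig, ext_rc) -> probe index, unique pairs only
        pair_counts = Counter(zip(self.lig, self.ext_rc))
        self.exact: dict[tuple[str, str], int] = {}
        self.dup_pairs = {k for k, v in pair_counts.items() if v > 1}
        self.lig_by_len: dict[int, dict[str, list[int]]] = {}
        for i, l in enumerate(self.lig):
            self.lig_by_len.setdefault(len(l), {}).setdefault(l, []).append(i)
            key = (l, self.ext_rc[i])
            if key not in self.dup_pairs:
                self.exact[key] = i
        self.distinct_lig_lens = sorted(self.lig_by_len, reverse=True)
        # dimer search patterns per probe (either orientation of the extension arm)
        self.dimer_pats = []
        for p in self.probes:
            k = min(12, len(p.extension_arm))
            self.dimer_pats.append((p.extension_arm[:k], revcomp(p.extension_arm)[:k]))

    def min_read1(self) -> int:
        return self.max_lig

    def min_read2(self) -> int:
        return self.layout.umi_length + self.max_ext

    def full_assign(self, seq1: str, seq2: str) -> tuple[int, int, int, str]:
        """Exhaustive Hamming comparison against every probe.

        Returns (probe_index, lig_mm, ext_mm, reason); index -1 when
        unassigned.
        """
        u = self.layout.umi_length
        r1 = np.frombuffer(seq1[: self.max_lig].encode(), dtype=np.uint8)
        r2 = np.frombuffer(seq2[u : u + self.max_ext].encode(), dtype=np.uint8)
        mm_l = ((self.lig_mat != r1) & self.lig_mask).sum(axis=1)
        mm_e = ((self.ext_mat != r2) & self.ext_mask).sum(axis=1)
        k = self.layout.max_arm_mismatches
        valid = (mm_l <= k) & (mm_e <= k)
        if not valid.any():
            return -1, 0, 0, "unmatched"
        total = np.where(valid, mm_l + mm_e, np.iinfo(np.int64).max)
        best = int(total.min())
        winners = np.flatnonzero(total == best)
        if len(winners) > 1:
            return -1, 0, 0, "ambiguous"
        i = int(winners[0])
        return i, int(mm_l[i]), int(mm_e[i]), ""


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def assign_probe(
    read_pair: tuple[str, str] | tuple[str, str, str],
    panel: Panel | _PanelIndex,
    layout: ReadLayout = ReadLayout(),
) -> ProbeAssignment:
    """Assign one read pair to a probe by arm Hamming distance.

    ``read_pair`` is ``(seq1, seq2)`` or ``(read_id, seq1, seq2)``.  The
    unique probe with both arm distances within the mismatch budget and
    minimal total distance wins; exact ties are left unassigned as
    ambiguous.
    """
    if len(read_pair) == 3:
        read_id, seq1, seq2 = read_pair
    else:
        read_id, (seq1, seq2) = "", read_pair
    index = panel if isinstance(panel, _PanelIndex) else _PanelIndex(panel, layout)
    layout = index.layout
    if len(seq1) < index.min_read1() or len(seq2) < index.min_read2():
        return ProbeAssignment(read_id, None, reason="short")
    i, mm_l, mm_e, reason = index.full_assign(seq1, seq2)
    if i < 0:
        return ProbeAssignment(read_id, None, reason=reason)
    umi = seq2[: layout.umi_length] if layout.umi_read == 2 else seq1[: layout.umi_length]
    return ProbeAssignment(read_id, index.names[i], mm_l, mm_e, umi=umi)


def detect_dimer(
    assignment: ProbeAssignment,
    read_pair: tuple[str, str],
    panel: Panel | _PanelIndex,
    min_insert: int | None = None,
) -> bool:
    """Flag extension-ligation dimers: the other arm follows the ligation
    arm after fewer than ``min_insert`` bases of genuine gap-fill."""
    if not assignment.assigned:
        return False
    index = panel if isinstance(panel, _PanelIndex) else _PanelIndex(panel, ReadLayout())
    if min_insert is None:
        min_insert = index.layout.dimer_min_insert
    i = index.names.index(assignment.probe_name)
    seq1 = read_pair[0] if len(read_pair) == 2 else read_pair[1]
    lig_len = len(index.lig[i])
    pat_f, pat_r = index.dimer_pats[i]
    region = seq1[lig_len : lig_len + min_insert + len(pat_f) - 1]
    for pat in (pat_f, pat_r):
        pos = region.find(pat)
        if 0 <= pos < min_insert:
            return True
    return False


@dataclass
class UmiTable:
    """Per-probe UMI read-coverage tallies for one sample."""

    counts: dict[str, Counter] = field(default_factory=dict)

    def add(self, probe: str, umi: str, n: int = 1) -> None:
        self.counts.setdefault(probe, Counter())[umi] += n

    def coverages(self, probe: str) -> list[int]:
        return sorted(self.counts.get(probe, Counter()).values(), reverse=True)

    def total_reads(self, probe: str) -> int:
        return sum(self.counts.get(probe, Counter()).values())


def tally_umis(
    assignments: Iterable[ProbeAssignment],
    *,
    umi_n_policy: str = "drop",
) -> UmiTable:
    """Group retained (assigned, non-dimer) reads by exact UMI sequence.

    UMIs containing N are dropped by default (``umi_n_policy='keep'``
    retains them as distinct UMIs).
    """
    if umi_n_policy not in ("drop", "keep"):
        raise ValueError("umi_n_policy must be 'drop' or 'keep'")
    table = UmiTable()
    for a in assignments:
        if not a.assigned or a.dimer:
            continue
        if umi_n_policy == "drop" and "N" in a.umi:
            continue
        table.add(a.probe_name, a.umi)
    return table


def error_corrected_count(
    umi_coverages: Sequence[int],
    fraction: float = 0.95,
    *,
    strict: bool = False,
) -> tuple[int | None, int]:
    """Sequencing-error correction of UMI counts by coverage thresholding.

    ``R`` is the largest read count such that the UMIs with coverage at
    least ``R`` still account for at least ``fraction`` of the probe's
    reads; the corrected molecule count is the number of such UMIs.
    Error-generated UMIs sit in the low-coverage tail and are removed,
    while the retained-read fraction stays >= ``fraction`` by
    construction.  ``strict=True`` uses a strictly-greater comparison
    instead (an alternative reading of the rule; not the default).
    Returns ``(None, 0)`` on empty input.
    """
    covs = sorted(umi_coverages, reverse=True)
    if not covs:
        return None, 0
    if covs[-1] < 1:
        raise ValueError("UMI coverages must all be >= 1")
    total = sum(covs)
    need = fraction * total
    if strict:
        candidates = sorted({c - 1 for c in covs} | {0}, reverse=True)
        for r in candidates:
            kept = [c for c in covs if c > r]
            if sum(kept) >= need:
                return r, len(kept)
        return 0, len(covs)
    running = 0
    kept_n = 0
    for cov, group in itertools.groupby(covs):
        g = list(group)
        running += cov * len(g)
        kept_n += len(g)
        if running >= need:
            return cov, kept_n
    return 1, len(covs)


@dataclass
class MoleculeCounts:
    """Tidy per-(sample, probe) molecule counts with QC columns.

    Columns: sample, probe, total_reads, raw_umis, threshold_R, molecules.
    """

    table: pd.DataFrame

    def matrix(self, value: str = "molecules") -> pd.DataFrame:
        """Probes x samples matrix of the requested value."""
        return self.table.pivot(index="probe", columns="sample", values=value).fillna(0)


def _fastq_pairs(fastq1, fastq2):
    import pysam

    with pysam.FastxFile(str(fastq1)) as fh1, pysam.FastxFile(str(fastq2)) as fh2:
        for r1, r2 in itertools.zip_longest(fh1, fh2):
            if r1 is None or r2 is None:
                raise ValueError(f"mate-count mismatch between {fastq1} and {fastq2}")
            yield r1, r2


def count_sample(
    fastq1,
    fastq2,
    panel: Panel,
    layout: ReadLayout = ReadLayout(),
    *,
    fraction: float = 0.95,
    sample: str = "sample",
    umi_n_policy: str = "drop",
) -> tuple[pd.DataFrame, dict]:
    """Count error-corrected molecules per probe for one FASTQ pair.

    Composes probe assignment, dimer removal, UMI tallying and the
    coverage threshold.  Returns a per-probe table (probe, total_reads,
    raw_umis, threshold_R, molecules) and a QC summary with read-fate
    fractions.
    """
    index = _PanelIndex(panel, layout)
    u = layout.umi_length
    min1, min2 = index.min_read1(), index.min_read2()
    table = UmiTable()
    reads_per_probe: Counter = Counter()
    qc = Counter(total=0, assigned=0, ambiguous=0, short=0, unmatched=0, dimer=0, umi_dropped=0)
    lens = index.distinct_lig_lens
    drop_n = umi_n_policy == "drop"

    for r1, r2 in _fastq_pairs(fastq1, fastq2):
        qc["total"] += 1
        seq1, seq2 = r1.sequence, r2.sequence
        if len(seq1) < min1 or len(seq2) < min2:
            qc["short"] += 1
            continue
        # fast path: an exact hit on both arms is always the unique winner
        # unless a second probe also matches exactly (then: ambiguous tie at 0)
        i = -1
        for L in lens:
            probes_at = index.lig_by_len[L].get(seq1[:L])
            if not probes_at:
                continue
            for cand in probes_at:
                e = index.ext_rc[cand]
                if seq2[u : u + len(e)] == e and (index.lig[cand], e) not in index.dup_pairs:
                    if i >= 0 and i != cand:
                        i = -2  # two distinct exact matches -> ambiguous
                        break
                    i = cand
            if i == -2:
                break
        if i == -2:
            qc["ambiguous"] += 1
            continue
        if i < 0:
            i, _, _, reason = index.full_assign(seq1, seq2)
            if i < 0:
                qc[reason] += 1
                continue
        qc["assigned"] += 1
        # dimer check
        lig_len = len(index.lig[i])
        pat_f, pat_r = index.dimer_pats[i]
        region = seq1[lig_len : lig_len + layout.dimer_min_insert + len(pat_f) - 1]
        pos = region.find(pat_f)
        if not 0 <= pos < layout.dimer_min_insert:
            pos = region.find(pat_r)
        if 0 <= pos < layout.dimer_min_insert:
            qc["dimer"] += 1
            qc["assigned"] -= 1
            continue
        umi = seq2[:u] if layout.umi_read == 2 else seq1[:u]
        if drop_n and "N" in umi:
            qc["umi_dropped"] += 1
            continue
        table.add(index.names[i], umi)
        reads_per_probe[index.names[i]] += 1

    rows = []
    for name in index.names:
        covs = table.coverages(name)
        R, molecules = error_corrected_count(covs, fraction)
        rows.append(
            {
                "sample": sample,
                "probe": name,
                "total_reads": reads_per_probe.get(name, 0),
                "raw_umis": len(covs),
                "threshold_R": R if R is not None else 0,
                "molecules": molecules,
            }
        )
    df = pd.DataFrame(rows)
    total = max(qc["total"], 1)
    qc_out = {k: qc[k] for k in ("total", "assigned", "ambiguous", "short", "unmatched", "dimer", "umi_dropped")}
    qc_out.update({f"frac_{k}": qc[k] / total for k in ("assigned", "ambiguous", "short", "unmatched", "dimer")})
    tot_mol = int(df["molecules"].sum())
    qc_out["molecules"] = tot_mol
    qc_out["molecules_per_read"] = tot_mol / max(int(df["total_reads"].sum()), 1)
    qc_out["sample"] = sample
    return df, qc_out


def read_sample_sheet(path) -> pd.DataFrame:
    """Read a sample sheet TSV with columns sample, fastq1, fastq2,
    condition, replicate_class, experiment (the last three optional)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"sample", "fastq1", "fastq2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    for col, default in (("condition", "cond"), ("replicate_class", "A"), ("experiment", "exp")):
        if col not in df.columns:
            df[col] = default
    return df


def count_samples(
    samples: pd.DataFrame,
    panel: Panel,
    layout: ReadLayout = ReadLayout(),
    *,
    fraction: float = 0.95,
) -> tuple[MoleculeCounts, pd.DataFrame]:
    """Run :func:`count_sample` for every row of a sample sheet.

    Returns the combined tidy molecule-count table and a per-sample QC
    table.
    """
    tables, qcs = [], []
    for _, row in samples.iterrows():
        df, qc = count_sample(
            row["fastq1"], row["fastq2"], panel, layout, fraction=fraction, sample=row["sample"]
        )
        tables.append(df)
        qcs.append(qc)
    return MoleculeCounts(pd.concat(tables, ignore_index=True)), pd.DataFrame(qcs)
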