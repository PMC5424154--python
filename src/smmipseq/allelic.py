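"""Allele-specific expression from smMIP capture by per-molecule majority vote.

Each captured molecule is identified by its (probe, UMI) pair; all reads
sharing that pair vote on the base observed at the targeted SNP, and the
strictly winning allele contributes one molecule.  Reads with the same
UMI but assigned to different probes are independent molecules — two
probes covering the same SNP therefore give independent allelic-ratio
estimates.  Exact vote ties discard the molecule by default.

Two counting backends share the vote logic: alignment-free (the SNP base
is located by offset arithmetic inside the designed gap-fill; default)
and SAM input with the UMI carried in the read identifier, mirroring a
mapper-based route.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import beta

from .design import revcomp
from .panel import Panel, Probe
from .readproc import ReadLayout, _PanelIndex

__all__ = [
    "SnpTarget",
    "AlleleCounts",
    "DilutionSeries",
    "rewrite_umi_to_header",
    "allele_of_read",
    "majority_vote_counts",
    "allelic_ratio",
    "dilution_ratio_of_ratios",
    "read_snp_table",
]


@dataclass(frozen=True)
class SnpTarget:
    """A targeted SNP located on a transcript, with its covering probes."""

    snp_id: str
    target_id: str
    offset: int  # 0-based transcript offset
    ref_allele: str
    alt_allele: str
    probes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.ref_allele) != 1 or len(self.alt_allele) != 1 or self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.snp_id}: alleles must be two distinct single bases")


@dataclass
class AlleleCounts:
    """Tidy molecule counts per (snp, probe, sample) and allele class."""

    table: pd.DataFrame  # columns: snp, probe, sample, ref, alt, other, tied

    def totals(self, snp: str, sample: str) -> tuple[int, int]:
        sub = self.table[(self.table["snp"] == snp) & (self.table["sample"] == sample)]
        return int(sub["ref"].sum()), int(sub["alt"].sum())


def rewrite_umi_to_header(
    fastq_in: tuple, fastq_out: tuple, layout: ReadLayout = ReadLayout(), *, delimiter: str = ":"
) -> int:
    """Move the UMI from the read sequence into the read identifier.

    Mapping-based workflows need UMI-free sequences (the random tag hurts
    mapability) but must keep the tag for molecule grouping; the UMI is
    excised from the sequence and quality strings of the UMI mate and
    appended to both identifiers after ``delimiter``.  Returns the number
    of pairs written; with ``umi_length == 0`` the records pass through
    unchanged.
    """
    import pysam

    u = layout.umi_length
    n = 0
    out1 = open(str(fastq_out[0]), "w")
    out2 = open(str(fastq_out[1]), "w")
    try:
        with pysam.FastxFile(str(fastq_in[0])) as fh1, pysam.FastxFile(str(fastq_in[1])) as fh2:
            for r1, r2 in zip(fh1, fh2):
                if u > 0:
                    if layout.umi_read == 2:
                        umi = r2.sequence[:u]
                        seq2, qual2 = r2.sequence[u:], (r2.quality or "I" * len(r2.sequence))[u:]
                        seq1, qual1 = r1.sequence, r1.quality or "I" * len(r1.sequence)
                    else:
                        umi = r1.sequence[:u]
                        seq1, qual1 = r1.sequence[u:], (r1.quality or "I" * len(r1.sequence))[u:]
                        seq2, qual2 = r2.sequence, r2.quality or "I" * len(r2.sequence)
                    if len(umi) < u:
                        raise ValueError(f"record {n + 1}: UMI mate shorter than umi_length")
                    name1 = f"{r1.name}{delimiter}{umi}"
                    name2 = f"{r2.name}{delimiter}{umi}"
                else:
                    seq1, qual1 = r1.sequence, r1.quality or "I" * len(r1.sequence)
                    seq2, qual2 = r2.sequence, r2.quality or "I" * len(r2.sequence)
                    name1, name2 = r1.name, r2.name
                out1.write(f"@{name1}\n{seq1}\n+\n{qual1}\n")
                out2.write(f"@{name2}\n{seq2}\n+\n{qual2}\n")
                n += 1
    finally:
        out1.close()
        out2.close()
    return n


def allele_of_read(
    read_pair: tuple[str, str],
    snp: SnpTarget,
    probe: Probe,
    layout: ReadLayout = ReadLayout(),
) -> str:
    """Classify the base a read pair carries at the SNP position.

    Alignment-free: the SNP's transcript offset is converted to a
    position within the gap-fill, read primarily off mate 1 (ligation arm
    + gap-fill) and off mate 2 (UMI + extension arm rc + gap-fill rc)
    when mate 1 is too short.  Returns 'ref', 'alt' or 'other'.
    """
    if not (probe.target_start <= snp.offset < probe.target_end):
        raise ValueError(f"SNP {snp.snp_id} outside gap-fill of probe {probe.name}")
    j = snp.offset - probe.target_start
    seq1, seq2 = read_pair
    pos1 = len(probe.ligation_arm) + j
    if pos1 < len(seq1):
        base = seq1[pos1]
    else:
        pos2 = layout.umi_length + len(probe.extension_arm) + (probe.gap_fill_length - 1 - j)
        if pos2 >= len(seq2):
            return "other"
        base = revcomp(seq2[pos2])
    if base == snp.ref_allele:
        return "ref"
    if base == snp.alt_allele:
        return "alt"
    return "other"


def majority_vote_counts(
    reads: Iterable[tuple],
    panel: Panel,
    snps: Sequence[SnpTarget],
    layout: ReadLayout = ReadLayout(),
    *,
    sample: str = "sample",
    tie_policy: str = "discard",
    rng: np.random.Generator | None = None,
) -> AlleleCounts:
    """Count molecules per allele by per-(probe, UMI) majority vote.

    ``reads`` are ``(seq1, seq2)`` or ``(read_id, seq1, seq2)`` pairs;
    assignment to probes uses the same arm matching as expression
    counting.  Each (probe, UMI) group contributes one molecule to the
    allele winning a strict majority of its reads; ties are discarded
    (``tie_policy='random'`` resolves them with the supplied RNG and is
    intended for sensitivity checks).
    """
    if tie_policy not in ("discard", "random"):
        raise ValueError("tie_policy must be 'discard' or 'random'")
    if tie_policy == "random" and rng is None:
        rng = np.random.default_rng(0)
    index = _PanelIndex(panel, layout)
    by_probe: dict[str, list[SnpTarget]] = defaultdict(list)
    for s in snps:
        probes = s.probes or tuple(
            p.name for p in panel if p.target_id == s.target_id and p.target_start <= s.offset < p.target_end
        )
        for pn in probes:
            by_probe[pn].append(s)
    # votes[(snp, probe)][umi] = Counter of allele classes
    votes: dict[tuple[str, str], dict[str, Counter]] = defaultdict(lambda: defaultdict(Counter))
    u = layout.umi_length
    for rp in reads:
        if len(rp) == 3:
            _, seq1, seq2 = rp
        else:
            seq1, seq2 = rp
        if len(seq1) < index.min_read1() or len(seq2) < index.min_read2():
            continue
        i, _, _, _ = index.full_assign(seq1, seq2)
        if i < 0:
            continue
        pname = index.names[i]
        targets = by_probe.get(pname)
        if not targets:
            continue
        umi = seq2[:u] if layout.umi_read == 2 else seq1[:u]
        if "N" in umi:
            continue
        probe = index.probes[i]
        for s in targets:
            call = allele_of_read((seq1, seq2), s, probe, layout)
            votes[(s.snp_id, pname)][umi][call] += 1

    rows = []
    seen = {(s.snp_id, pn) for s in snps for pn in (s.probes or [p.name for p in panel if p.target_id == s.target_id and p.target_start <= s.offset < p.target_end])}
    for key in sorted(seen):
        snp_id, pname = key
        tallies = Counter(ref=0, alt=0, other=0, tied=0)
        for umi, counts in votes.get(key, {}).items():
            top = counts.most_common()
            if len(top) > 1 and top[0][1] == top[1][1]:
                if tie_policy == "discard":
                    tallies["tied"] += 1
                    continue
                tied_calls = sorted(c for c, n in top if n == top[0][1])
                tallies[tied_calls[int(rng.integers(len(tied_calls)))]] += 1
            else:
                tallies[top[0][0]] += 1
        rows.append({"snp": snp_id, "probe": pname, "sample": sample, **tallies})
    return AlleleCounts(pd.DataFrame(rows, columns=["snp", "probe", "sample", "ref", "alt", "other", "tied"]))


def majority_vote_counts_sam(
    sam_path,
    panel: Panel,
    snps: Sequence[SnpTarget],
    layout: ReadLayout = ReadLayout(),
    *,
    sample: str = "sample",
    tie_policy: str = "discard",
    umi_delimiter: str = ":",
    rng: np.random.Generator | None = None,
) -> AlleleCounts:
    """SAM-backed allele counting; vote logic identical to the
    alignment-free route.

    Expects reads mapped to the transcript sequences (reference name ==
    ``target_id``) with the UMI as the last ``umi_delimiter``-separated
    field of the read identifier (see :func:`rewrite_umi_to_header`).
    Probe assignment matches the ligation arm at the start of the
    forward mate against the panel (within the mismatch budget).
    """
    import pysam

    if tie_policy == "random" and rng is None:
        rng = np.random.default_rng(0)
    index = _PanelIndex(panel, layout)
    k = layout.max_arm_mismatches
    by_ref: dict[str, list[SnpTarget]] = defaultdict(list)
    for s in snps:
        by_ref[s.target_id].append(s)
    votes: dict[tuple[str, str], dict[str, Counter]] = defaultdict(lambda: defaultdict(Counter))
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary or rec.is_reverse:
                continue
            targets = by_ref.get(rec.reference_name)
            if not targets:
                continue
            seq = rec.query_sequence
            if seq is None:
                continue
            # assign by ligation-arm match at the read start
            best, best_mm, tie = -1, k + 1, False
            for i, arm in enumerate(index.lig):
                if index.probes[i].target_id != rec.reference_name:
                    continue
                if len(seq) < len(arm):
                    continue
                mm = sum(a != b for a, b in zip(arm, seq))
                if mm < best_mm:
                    best, best_mm, tie = i, mm, False
                elif mm == best_mm:
                    tie = True
            if best < 0 or tie or best_mm > k:
                continue
            pname = index.names[best]
            umi = rec.query_name.rsplit(umi_delimiter, 1)[-1]
            pairs = dict(
                (ref, q) for q, ref in rec.get_aligned_pairs(matches_only=True)
            )
            for s in targets:
                q = pairs.get(s.offset)
                if q is None:
                    continue
                base = seq[q]
                call = "ref" if base == s.ref_allele else "alt" if base == s.alt_allele else "other"
                votes[(s.snp_id, pname)][umi][call] += 1
    rows = []
    for key in sorted(votes):
        snp_id, pname = key
        tallies = Counter(ref=0, alt=0, other=0, tied=0)
        for umi, counts in votes[key].items():
            top = counts.most_common()
            if len(top) > 1 and top[0][1] == top[1][1]:
                if tie_policy == "discard":
                    tallies["tied"] += 1
                    continue
                tied_calls = sorted(c for c, n in top if n == top[0][1])
                tallies[tied_calls[int(rng.integers(len(tied_calls)))]] += 1
            else:
                tallies[top[0][0]] += 1
        rows.append({"snp": snp_id, "probe": pname, "sample": sample, **tallies})
    return AlleleCounts(pd.DataFrame(rows, columns=["snp", "probe", "sample", "ref", "alt", "other", "tied"]))


def allelic_ratio(
    counts: AlleleCounts,
    snp: str,
    sample: str,
    *,
    probe: str | None = None,
    conf: float = 0.95,
) -> tuple[float, tuple[float, float]] | None:
    """Reference-allele molecule fraction with a Clopper-Pearson interval.

    Counts are summed over the SNP's probes unless ``probe`` is given.
    Returns None when no informative (ref or alt) molecules exist.
    """
    sub = counts.table[(counts.table["snp"] == snp) & (counts.table["sample"] == sample)]
    if probe is not None:
        sub = sub[sub["probe"] == probe]
    r, a = int(sub["ref"].sum()), int(sub["alt"].sum())
    n = r + a
    if n == 0:
        return None
    alpha = 1.0 - conf
    lo = 0.0 if r == 0 else float(beta.ppf(alpha / 2, r, n - r + 1))
    hi = 1.0 if r == n else float(beta.ppf(1 - alpha / 2, r + 1, n - r))
    return r / n, (lo, hi)


@dataclass
class DilutionSeries:
    """Ordered dilution steps with nominal pool-A fractions.

    ``ratios`` maps (snp or probe unit) -> ordered per-step allelic
    ratio estimates (NaN for missing steps).
    """

    fractions: list[float]
    ratios: pd.DataFrame  # rows: unit, columns: step index

    def __post_init__(self) -> None:
        if any(not (0 < f <= 1) for f in self.fractions):
            raise ValueError("nominal fractions must be in (0, 1]")
        if any(b >= a for a, b in zip(self.fractions, self.fractions[1:])):
            raise ValueError("nominal fractions must decrease along the series")


def dilution_ratio_of_ratios(series: DilutionSeries) -> tuple[pd.DataFrame, float]:
    """Consecutive-step ratios of allelic ratios and their geometric mean.

    In an exponential dilution at rate q of pool A into pool B (with the
    targeted genes expressed equally in the two pools) the allelic ratio
    itself scales by q between steps, so every consecutive-step ratio
    estimates q.  The absolute ratio of the first step depends on the
    unknown pool expression levels and is not predictable a priori; only
    step-to-step ratios are reported.  Missing steps produce gaps: the
    affected pairs are skipped.
    """
    if series.ratios.shape[1] < 2:
        raise ValueError("need at least two dilution steps")
    rows = []
    logs = []
    for unit, row in series.ratios.iterrows():
        vals = row.values.astype(float)
        for k in range(len(vals) - 1):
            r0, r1 = vals[k], vals[k + 1]
            if not (np.isfinite(r0) and np.isfinite(r1)) or r0 <= 0 or r1 <= 0:
                rows.append({"unit": unit, "step": k + 1, "ratio": np.nan, "note": "missing"})
                continue
            ratio = r1 / r0
            rows.append({"unit": unit, "step": k + 1, "ratio": ratio, "note": ""})
            logs.append(math.log(ratio))
    if not logs:
        raise ValueError("no computable step ratios")
    geo_mean = float(math.exp(np.mean(logs)))
    return pd.DataFrame(rows), geo_mean


def read_snp_table(path) -> list[SnpTarget]:
    """Read SNP targets from a TSV with columns snp_id, target_id, offset,
    ref, alt[, probes (comma-separated)]."""
    out = []
    with open(path) as fh:
        header = None
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if header is None:
                header = f
                continue
            row = dict(zip(header, f))
            probes = tuple(p for p in row.get("probes", "").split(",") if p)
            out.append(
                SnpTarget(
                    snp_id=row["snp_id"],
                    target_id=row["target_id"],
                    offset=int(row["offset"]),
                    ref_allele=row["ref"],
                    alt_allele=row["alt"],
                    probes=probes,
                )
            )
    return out
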