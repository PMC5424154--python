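"""Design of smMIP panels against spliced transcript sequences.

Probes are designed against transcript (cDNA) sequence rather than the
genome, so candidate probes may legitimately span exon-exon junctions;
such candidates are flagged rather than rejected.  The design procedure
is: splice transcripts from exon structures, segment each target (or
anchor on a variant position), exhaustively enumerate candidate probes
satisfying the arm-length and target-length constraints, discard
candidates whose arms are not unique in the reference, and — for variant
panels — select pairs of probes with non-overlapping arms so that the two
probes give independent molecule counts for the same site.

Coordinates are 0-based half-open internally; VCF positions are 1-based
and converted at the boundary.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .panel import Panel, Probe

__all__ = [
    "TranscriptModel",
    "DesignConstraints",
    "CandidateProbe",
    "VariantTarget",
    "Segment",
    "CoordinateError",
    "DesignInfeasibleError",
    "splice_transcript",
    "genomic_to_transcript",
    "segment_targets",
    "enumerate_candidates",
    "arm_copy_number",
    "filter_by_copy_number",
    "filter_by_variants",
    "design_snp_pair",
    "design_expression_panel",
    "revcomp",
]

_RC = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide sequence."""
    return seq.translate(_RC)[::-1]


class CoordinateError(ValueError):
    """Exon coordinates outside the reference, or inconsistent structures."""


class DesignInfeasibleError(RuntimeError):
    """No candidate set satisfies the design constraints."""


@dataclass
class TranscriptModel:
    """A spliced transcript: exon structure plus spliced sequence.

    ``exons`` are genomic 0-based half-open intervals, sorted and
    non-overlapping.  For '-' strand transcripts the spliced sequence is
    the reverse complement of the concatenated exon sequence, and
    transcript coordinate 0 corresponds to the genomically rightmost base.
    """

    id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    sequence: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise CoordinateError(f"strand must be '+' or '-', got {self.strand!r}")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise CoordinateError(f"{self.id}: exons overlap or are unsorted")
        if len(self.sequence) != sum(e - s for s, e in self.exons):
            raise CoordinateError(f"{self.id}: sequence length != summed exon length")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def junction_offsets(self) -> list[int]:
        """Transcript offsets at which a new exon begins (internal junctions)."""
        lens = [e - s for s, e in self.exons]
        if self.strand == "-":
            lens = lens[::-1]
        offs = list(itertools.accumulate(lens))[:-1]
        return offs

    def genomic_to_transcript(self, pos: int) -> int | None:
        """Map a genomic position to a transcript offset; None if intronic/outside."""
        off = 0
        if self.strand == "+":
            for s, e in self.exons:
                if s <= pos < e:
                    return off + (pos - s)
                off += e - s
            return None
        for s, e in reversed(self.exons):
            if s <= pos < e:
                return off + (e - 1 - pos)
            off += e - s
        return None

    def transcript_to_genomic(self, off: int) -> int:
        """Inverse of :meth:`genomic_to_transcript` on exonic bases."""
        if not 0 <= off < len(self):
            raise CoordinateError(f"offset {off} outside transcript {self.id}")
        if self.strand == "+":
            for s, e in self.exons:
                if off < e - s:
                    return s + off
                off -= e - s
        else:
            for s, e in reversed(self.exons):
                if off < e - s:
                    return e - 1 - off
                off -= e - s
        raise AssertionError("unreachable")


def splice_transcript(
    exons: Sequence[tuple[int, int]],
    genome_sequence: str,
    strand: str,
    *,
    id: str = "tx",
    chrom: str = "ref",
) -> TranscriptModel:
    """Build a :class:`TranscriptModel` by splicing exons out of a reference.

    For '-' strand the spliced sequence is the reverse complement of the
    exon concatenation, so transcript coordinates always run 5'->3' in
    mRNA orientation.
    """
    exons = sorted((int(s), int(e)) for s, e in exons)
    for s, e in exons:
        if not (0 <= s < e <= len(genome_sequence)):
            raise CoordinateError(f"exon [{s},{e}) outside reference of length {len(genome_sequence)}")
    seq = "".join(genome_sequence[s:e] for s, e in exons).upper()
    if strand == "-":
        seq = revcomp(seq)
    return TranscriptModel(id=id, chrom=chrom, strand=strand, exons=list(exons), sequence=seq)


def genomic_to_transcript(pos: int, transcript: TranscriptModel) -> int | None:
    """Module-level convenience wrapper; see :meth:`TranscriptModel.genomic_to_transcript`."""
    return transcript.genomic_to_transcript(pos)


@dataclass(frozen=True)
class DesignConstraints:
    """Arm- and target-length constraints for candidate enumeration.

    Defaults correspond to expression panels (112-nt gap-fill); variant
    panels conventionally use ``target_length=100``.
    """

    arm_min: int = 16
    arm_max: int = 24
    arm_total: int = 40
    target_length: int = 112
    max_copy_number: int = 1
    segment_length: int = 200

    def __post_init__(self) -> None:
        if self.arm_min > self.arm_max:
            raise ValueError("arm_min > arm_max")
        if not (2 * self.arm_min <= self.arm_total <= 2 * self.arm_max):
            raise ValueError("arm_total not achievable with arm_min/arm_max")

    @property
    def footprint(self) -> int:
        return self.arm_total + self.target_length

    def arm_splits(self) -> list[tuple[int, int]]:
        """All (extension, ligation) arm-length splits summing to arm_total."""
        return [
            (e, self.arm_total - e)
            for e in range(self.arm_min, self.arm_max + 1)
            if self.arm_min <= self.arm_total - e <= self.arm_max
        ]

    @classmethod
    def snp_panel(cls) -> "DesignConstraints":
        return cls(target_length=100)


@dataclass(frozen=True)
class CandidateProbe(Probe):
    """A designed probe candidate with provenance and filter metadata."""

    copy_number_extension: int | None = None
    copy_number_ligation: int | None = None
    score: float | None = None
    n_transcripts: int = 1

    @property
    def extension_interval(self) -> tuple[int, int]:
        """Transcript interval occupied by the extension arm (gap-fill-adjacent)."""
        return (self.target_start - len(self.extension_arm), self.target_start)

    @property
    def ligation_interval(self) -> tuple[int, int]:
        return (self.target_end, self.target_end + len(self.ligation_arm))


@dataclass(frozen=True)
class VariantTarget:
    """A single-nucleotide variant to target, in genomic and transcript space."""

    snp_id: str
    chrom: str
    genomic_pos: int  # 1-based, VCF convention
    ref_allele: str
    alt_allele: str
    transcript_positions: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
            raise ValueError(f"{self.snp_id}: alleles must be single bases")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.snp_id}: ref and alt alleles are identical")


@dataclass(frozen=True)
class Segment:
    """A design window on a transcript; trailing remainders are flagged partial."""

    start: int
    end: int
    partial: bool = False


def segment_targets(transcript: TranscriptModel | int, segment_length: int = 200) -> list[Segment]:
    """Divide a transcript into consecutive non-overlapping windows.

    Accepts a transcript model or a bare length.  A trailing window
    shorter than ``segment_length`` is emitted with ``partial=True``.
    """
    if segment_length < 1:
        raise ValueError("segment_length must be >= 1")
    length = transcript if isinstance(transcript, int) else len(transcript)
    segments = []
    for start in range(0, length, segment_length):
        end = min(start + segment_length, length)
        segments.append(Segment(start, end, partial=(end - start) < segment_length))
    return segments


def _junction_crossing(tx: TranscriptModel, start: int, end: int) -> bool:
    return any(start < j < end for j in tx.junction_offsets)


def enumerate_candidates(
    transcript: TranscriptModel,
    anchor: Segment | tuple[int, int] | int,
    constraints: DesignConstraints = DesignConstraints(),
    *,
    umi_length: int = 9,
    gene: str = "",
) -> list[CandidateProbe]:
    """Exhaustively enumerate candidate probes covering an anchor.

    The anchor is either a segment (the gap-fill must overlap it) or a
    variant transcript offset (the variant base must lie strictly inside
    the gap-fill, not at its first or last base).  Every candidate has arm
    lengths within ``[arm_min, arm_max]`` summing to ``arm_total`` and a
    gap-fill of exactly ``target_length``; candidates whose arms or
    gap-fill span an exon-exon junction are flagged ``junction_crossing``.
    Returns an empty list when the transcript is too short.
    """
    L = len(transcript)
    tlen = constraints.target_length
    if isinstance(anchor, Segment):
        seg: tuple[int, int] | None = (anchor.start, anchor.end)
        snp_off = None
    elif isinstance(anchor, tuple):
        seg = (int(anchor[0]), int(anchor[1]))
        snp_off = None
    else:
        seg = None
        snp_off = int(anchor)

    out: list[CandidateProbe] = []
    for ext_len, lig_len in constraints.arm_splits():
        # gap-fill [g, g+tlen); extension arm immediately 5', ligation arm 3'
        g_lo = ext_len
        g_hi = L - tlen - lig_len  # inclusive
        if seg is not None:
            g_lo = max(g_lo, seg[0] - tlen + 1)
            g_hi = min(g_hi, seg[1] - 1)
        else:
            g_lo = max(g_lo, snp_off - tlen + 2)
            g_hi = min(g_hi, snp_off - 1)
        for g in range(g_lo, g_hi + 1):
            ext = transcript.sequence[g - ext_len : g]
            lig = transcript.sequence[g + tlen : g + tlen + lig_len]
            crossing = _junction_crossing(transcript, g - ext_len, g + tlen + lig_len)
            out.append(
                CandidateProbe(
                    name=f"{transcript.id}:{g}-{g + tlen}:e{ext_len}",
                    extension_arm=ext,
                    ligation_arm=lig,
                    target_id=transcript.id,
                    target_start=g,
                    target_end=g + tlen,
                    umi_length=umi_length,
                    junction_crossing=crossing,
                    gene=gene,
                )
            )
    out.sort(key=lambda c: (c.target_start, len(c.extension_arm)))
    return out


def arm_copy_number(arm: str, references: Iterable[str]) -> int:
    """Occurrences of an arm (either strand, overlapping) in a reference set.

    Exact string matching stands in for read-mapper copy-number
    estimation; for arms of >=16 nt the two agree at panel-design scale.
    """
    if not arm:
        raise ValueError("empty arm sequence")
    refs = list(references)
    if not refs:
        raise ValueError("empty reference set")
    arm = arm.upper()
    rc = revcomp(arm)
    patterns = [arm] if rc == arm else [arm, rc]
    count = 0
    for ref in refs:
        ref = ref.upper()
        for pat in patterns:
            start = 0
            while True:
                i = ref.find(pat, start)
                if i == -1:
                    break
                count += 1
                start = i + 1
    return count


def filter_by_copy_number(
    candidates: Iterable[CandidateProbe],
    references: Sequence[str],
    max_copy_number: int = 1,
    *,
    precomputed: Mapping[str, tuple[int, int]] | None = None,
) -> list[CandidateProbe]:
    """Keep candidates whose two arms each occur at most ``max_copy_number`` times.

    ``precomputed`` maps candidate name -> (extension, ligation) copy
    numbers computed externally (e.g. by a read mapper), bypassing the
    built-in exact matcher.
    """
    kept = []
    for c in candidates:
        if precomputed is not None and c.name in precomputed:
            ce, cl = precomputed[c.name]
        else:
            ce = arm_copy_number(c.extension_arm, references)
            cl = arm_copy_number(c.ligation_arm, references)
        c = replace(c, copy_number_extension=ce, copy_number_ligation=cl)
        if 1 <= ce <= max_copy_number and 1 <= cl <= max_copy_number:
            kept.append(c)
    return kept


def filter_by_variants(
    candidates: Iterable[CandidateProbe],
    variant_offsets: Mapping[str, Sequence[int]],
) -> list[CandidateProbe]:
    """Reject candidates whose arms overlap known variant positions.

    Variants under an arm compromise hybridization and bias capture of
    one allele; ``variant_offsets`` maps transcript id -> transcript
    offsets of known variants.
    """
    kept = []
    for c in candidates:
        offs = variant_offsets.get(c.target_id, ())
        es, ee = c.extension_interval
        ls, le = c.ligation_interval
        if any(es <= o < ee or ls <= o < le for o in offs):
            continue
        kept.append(c)
    return kept


def _intervals_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def design_snp_pair(
    snp: VariantTarget,
    candidates: Sequence[CandidateProbe],
) -> tuple[CandidateProbe, CandidateProbe]:
    """Choose two probes for one SNP with mutually non-overlapping arms.

    Two probes whose extension arms do not overlap and whose ligation
    arms do not overlap capture physically independent molecules and so
    give independent allelic-ratio estimates.  Among feasible pairs the
    summed performance score is maximized (unscored candidates count 0);
    ties prefer the pair valid in more transcripts, then lexicographic
    probe names.
    """
    if len(candidates) < 2:
        raise DesignInfeasibleError(f"{snp.snp_id}: fewer than two candidate probes")
    best: tuple | None = None
    for a, b in itertools.combinations(candidates, 2):
        if _intervals_overlap(a.extension_interval, b.extension_interval):
            continue
        if _intervals_overlap(a.ligation_interval, b.ligation_interval):
            continue
        key = (
            -((a.score or 0.0) + (b.score or 0.0)),
            -(a.n_transcripts + b.n_transcripts),
            tuple(sorted([a.name, b.name])),
        )
        if best is None or key < best[0]:
            best = (key, (a, b) if a.name <= b.name else (b, a))
    if best is None:
        raise DesignInfeasibleError(f"{snp.snp_id}: no candidate pair with non-overlapping arms")
    return best[1]


def design_expression_panel(
    transcripts: Sequence[TranscriptModel],
    constraints: DesignConstraints = DesignConstraints(),
    *,
    references: Sequence[str] | None = None,
    min_score: float | None = None,
    scores: Mapping[str, float] | None = None,
    umi_length: int = 9,
) -> tuple[Panel, list[dict]]:
    """Segment each transcript and pick one probe per designable segment.

    For every non-partial segment the candidate with the fewest junction
    crossings and the highest score (externally supplied, optional) is
    chosen.  Returns the panel and a per-segment design report.
    """
    chosen: list[Probe] = []
    report: list[dict] = []
    refs = references if references is not None else [t.sequence for t in transcripts]
    for tx in transcripts:
        for k, seg in enumerate(segment_targets(tx, constraints.segment_length)):
            rec = {"transcript": tx.id, "segment": k, "start": seg.start, "end": seg.end, "partial": seg.partial}
            cands = enumerate_candidates(tx, seg, constraints, umi_length=umi_length, gene=tx.id)
            rec["n_candidates"] = len(cands)
            if scores:
                cands = [replace(c, score=scores.get(c.name)) for c in cands]
            cands = filter_by_copy_number(cands, refs, constraints.max_copy_number)
            rec["n_unique_arms"] = len(cands)
            if min_score is not None:
                cands = [c for c in cands if c.score is not None and c.score >= min_score]
            if not cands:
                rec["chosen"] = None
                rec["reason"] = "no candidate passed filters"
                report.append(rec)
                continue
            pick = max(cands, key=lambda c: (c.score or 0.0, -c.target_start, c.name))
            chosen.append(
                replace(pick, name=f"{tx.id}_seg{k}", gene=tx.id)
            )
            rec["chosen"] = chosen[-1].name
            rec["reason"] = ""
            report.append(rec)
    return Panel([Probe(
        name=c.name,
        extension_arm=c.extension_arm,
        ligation_arm=c.ligation_arm,
        target_id=c.target_id,
        target_start=c.target_start,
        target_end=c.target_end,
        umi_length=c.umi_length,
        junction_crossing=c.junction_crossing,
        gene=c.gene,
    ) for c in chosen]), report


# ---------------------------------------------------------------------------
# File input helpers
# ---------------------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into a name -> sequence mapping."""
    import pysam

    seqs: dict[str, str] = {}
    with pysam.FastxFile(str(path)) as fh:
        for rec in fh:
            seqs[rec.name] = rec.sequence.upper()
    return seqs


def read_exon_table(path) -> dict[str, list[dict]]:
    """Read exon structures from GFF3 (via gffutils) or a BED-like TSV.

    The TSV dialect has four or five columns: transcript_id, chrom,
    start, end[, strand] with one exon per row (0-based half-open).
    Returns transcript id -> {"chrom", "strand", "exons"}.
    """
    path = str(path)
    out: dict[str, dict] = {}
    if path.endswith((".gff", ".gff3")):
        import gffutils

        db = gffutils.create_db(path, ":memory:", merge_strategy="create_unique", keep_order=True)
        for exon in db.features_of_type("exon"):
            parents = exon.attributes.get("Parent", [exon.attributes.get("transcript_id", ["?"])[0]])
            for tid in parents:
                rec = out.setdefault(tid, {"chrom": exon.seqid, "strand": exon.strand, "exons": []})
                rec["exons"].append((exon.start - 1, exon.end))  # GFF is 1-based closed
    else:
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                tid, chrom, start, end = f[0], f[1], int(f[2]), int(f[3])
                strand = f[4] if len(f) > 4 else "+"
                rec = out.setdefault(tid, {"chrom": chrom, "strand": strand, "exons": []})
                rec["exons"].append((start, end))
    for rec in out.values():
        rec["exons"] = sorted(rec["exons"])
    return out


def read_variants(path) -> list[VariantTarget]:
    """Read variant targets from a VCF (CHROM/POS/REF/ALT only) or TSV.

    The TSV dialect has columns snp_id, chrom, pos (1-based), ref, alt.
    """
    path = str(path)
    out: list[VariantTarget] = []
    if path.endswith((".vcf", ".vcf.gz")):
        import pysam

        with pysam.VariantFile(path) as vcf:
            for rec in vcf:
                if rec.alts is None:
                    continue
                out.append(
                    VariantTarget(
                        snp_id=rec.id or f"{rec.chrom}:{rec.pos}",
                        chrom=rec.chrom,
                        genomic_pos=rec.pos,
                        ref_allele=rec.ref,
                        alt_allele=rec.alts[0],
                    )
                )
    else:
        with open(path) as fh:
            header = None
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                if header is None and f[0] == "snp_id":
                    header = f
                    continue
                out.append(VariantTarget(snp_id=f[0], chrom=f[1], genomic_pos=int(f[2]), ref_allele=f[3], alt_allele=f[4]))
    return out
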