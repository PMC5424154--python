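"""Ground-truth simulator for smMIP capture experiments.

Generates everything the analysis modules consume — transcriptome FASTA,
probe panel, paired FASTQ with UMI/PCR-duplicate/sequencing-error
structure, sample sheets — together with the underlying truth, so the
whole pipeline is testable without external sequencing data.

What is emulated: transcript abundances spanning several orders of
magnitude; two-mix designs with fixed fold-change groups (0.5/0.67/1.0/4.0
by default, the standard spike-in layout); per-probe capture-efficiency
variation (log-normal); a condition-independent per-probe bias affecting
one replicate class, shared across conditions; PCR duplication with a
heavy-tailed reads-per-molecule distribution; uniform-random UMIs
(collisions possible, as in real tags); i.i.d. substitution sequencing
errors; and a two-genotype exponential dilution series for
allele-specific expression.

Read layout matches :mod:`smmipseq.readproc`: mate 1 = ligation arm +
gap-fill; mate 2 = UMI + reverse-complemented extension arm + gap-fill.
All outputs are byte-reproducible for a fixed seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .allelic import SnpTarget
from .design import revcomp
from .panel import Panel, Probe, write_panel

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SimOutput",
    "DilutionOutput",
    "make_transcriptome",
    "make_panel",
    "simulate_capture",
    "simulate_reads",
    "simulate_expression_experiment",
    "simulate_dilution",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the simulator.

    Defaults reproduce a spike-in style two-mix experiment: four equal
    fold-change groups at 0.5/0.67/1.0/4.0, abundances log-uniform over
    four orders of magnitude, 5-9 probes per transcript, two replicate
    classes (e.g. two cDNA input amounts), 0.2% per-base sequencing
    error and a 9-nt UMI.
    """

    seed: int = 1
    n_transcripts: int = 40
    transcript_length: tuple[int, int] = (1500, 2000)
    abundance_span_log10: float = 4.0
    fold_change_groups: tuple[float, ...] = (0.5, 0.67, 1.0, 4.0)
    probes_per_transcript: tuple[int, int] = (5, 9)
    capture_efficiency_sd: float = 0.5
    class_bias_sd: float = 0.25
    n_molecules: int = 50_000
    pcr_mean_reads: float = 10.0
    pcr_dispersion: float = 5.0
    seq_error_rate: float = 0.002
    umi_length: int = 9
    read_length: int = 76
    target_length: int = 112
    arm_min: int = 16
    arm_max: int = 24
    arm_total: int = 40
    replicates_per_condition: int = 4
    conditions: tuple[str, ...] = ("mix1", "mix2")
    replicate_classes: tuple[str, ...] = ("A", "B")

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.fold_change_groups):
            raise ValueError("fold-change ratios must be positive")
        if not (0 <= self.seq_error_rate <= 1):
            raise ValueError("seq_error_rate must be a probability")


@dataclass
class GroundTruth:
    """Everything needed to check pipeline output against the simulation."""

    abundances: pd.DataFrame  # transcript x condition relative abundance
    groups: pd.Series  # transcript -> fold-change ratio (cond1 / cond2)
    efficiencies: pd.Series  # probe -> capture efficiency multiplier
    class_bias: pd.Series  # probe -> multiplier applied to the first replicate class
    molecule_counts: pd.DataFrame  # tidy: sample, probe, molecules
    umis: dict = field(default_factory=dict)  # sample -> probe -> array of UMI strings


@dataclass
class SimOutput:
    sample_sheet: pd.DataFrame
    panel: Panel
    truth: GroundTruth
    transcriptome: dict
    outdir: Path


@dataclass
class DilutionOutput:
    sample_sheet: pd.DataFrame
    panel: Panel
    snps: list
    fractions: list  # nominal pool-A fraction per step (controls excluded)
    truth: pd.DataFrame  # tidy: sample, snp, probe, ref_molecules, alt_molecules
    outdir: Path


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def _random_umis(rng: np.random.Generator, n: int, u: int) -> np.ndarray:
    arr = _BASES[rng.integers(0, 4, (n, u))]
    return arr.view(f"S{u}").ravel().astype(str)


def make_transcriptome(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], pd.DataFrame, pd.Series]:
    """Random transcript sequences plus two-condition abundance vectors.

    Transcripts are split into equal groups, one per fold-change ratio;
    the ratio multiplies condition-1 abundance relative to condition-2.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    names = [f"TX{i:03d}" for i in range(config.n_transcripts)]
    lo, hi = config.transcript_length
    seqs = {n: _random_seq(rng, int(rng.integers(lo, hi + 1))) for n in names}
    base = 10 ** rng.uniform(0, config.abundance_span_log10, config.n_transcripts)
    # stratified group assignment: deal abundance-ranked transcripts around
    # the groups so every group spans the dynamic range, as two-mix
    # spike-in panels are laid out
    ngroups = len(config.fold_change_groups)
    ratios = np.empty(config.n_transcripts)
    for j, i in enumerate(np.argsort(-base)):
        ratios[i] = config.fold_change_groups[j % ngroups]
    cond1, cond2 = config.conditions[:2]
    ab = pd.DataFrame({cond1: base * ratios, cond2: base}, index=names)
    groups = pd.Series(ratios, index=names, name="ratio")
    return seqs, ab, groups


def make_panel(
    transcriptome: dict[str, str], config: SimConfig, rng: np.random.Generator | None = None
) -> Panel:
    """Place 5-9 evenly spaced probes per transcript with random arm splits."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    probes = []
    lo, hi = config.probes_per_transcript
    tlen = config.target_length
    for tx, seq in transcriptome.items():
        footprint = config.arm_total + tlen
        max_fit = max((len(seq)) // (footprint + 8), 1)
        n = min(int(rng.integers(lo, hi + 1)), max_fit)
        pitch = len(seq) // n
        for j in range(n):
            ext_len = int(rng.integers(config.arm_min, config.arm_max + 1))
            ext_len = min(max(ext_len, config.arm_total - config.arm_max), config.arm_total - config.arm_min)
            lig_len = config.arm_total - ext_len
            g0 = j * pitch + ext_len
            g1 = g0 + tlen
            if g1 + lig_len > len(seq):
                continue
            probes.append(
                Probe(
                    name=f"{tx}_p{j}",
                    extension_arm=seq[g0 - ext_len : g0],
                    ligation_arm=seq[g1 : g1 + lig_len],
                    target_id=tx,
                    target_start=g0,
                    target_end=g1,
                    umi_length=config.umi_length,
                    gene=tx,
                )
            )
    return Panel(probes)


def simulate_capture(
    abundances: pd.Series,
    panel: Panel,
    config: SimConfig,
    rng: np.random.Generator,
    *,
    efficiencies: pd.Series,
    class_bias: pd.Series,
    biased_class: bool,
    n_molecules: int | None = None,
) -> tuple[pd.Series, dict[str, np.ndarray]]:
    """Draw per-probe molecule counts and UMIs for one replicate.

    Counts are multinomial over probes with weights abundance x
    efficiency x (class bias when the replicate belongs to the biased
    class); every molecule receives an independent uniform UMI.
    """
    names = [p.name for p in panel]
    w = np.array(
        [
            abundances[p.target_id] * efficiencies[p.name] * (class_bias[p.name] if biased_class else 1.0)
            for p in panel
        ]
    )
    n = config.n_molecules if n_molecules is None else n_molecules
    counts = rng.multinomial(n, w / w.sum()) if n > 0 else np.zeros(len(w), dtype=int)
    umis = {name: _random_umis(rng, int(c), config.umi_length) for name, c in zip(names, counts)}
    return pd.Series(counts, index=names, name="molecules"), umis


def _mutate(seqs: list[str], rng: np.random.Generator, rate: float) -> list[str]:
    """Apply i.i.d. substitution errors to a list of equal-rate sequences."""
    if rate <= 0 or not seqs:
        return seqs
    lens = np.array([len(s) for s in seqs])
    n_err = rng.binomial(lens, rate)
    for i in np.nonzero(n_err)[0]:
        s = np.frombuffer(seqs[i].encode(), dtype=np.uint8).copy()
        pos = rng.choice(len(s), size=n_err[i], replace=False)
        for p in pos:
            choices = _BASES[_BASES != s[p]]
            s[p] = choices[rng.integers(0, len(choices))]
        seqs[i] = s.tobytes().decode()
    return seqs


def simulate_reads(
    umis_by_probe: dict[str, np.ndarray],
    panel: Panel,
    transcriptome: dict[str, str],
    config: SimConfig,
    rng: np.random.Generator,
    fastq1,
    fastq2,
    *,
    sample: str = "sample",
    allele_by_probe: dict[str, np.ndarray] | None = None,
    snp_by_probe: dict[str, tuple[int, str]] | None = None,
) -> int:
    """Write paired FASTQ for the molecules of one replicate.

    Reads per molecule follow a shifted negative binomial (always >= 1),
    giving the heavy-tailed UMI read-coverage distribution that the
    error-correction threshold is designed for.  When ``allele_by_probe``
    marks molecules as carrying the alternative allele,
    ``snp_by_probe[probe] = (gap_fill_offset, alt_base)`` is substituted
    into the gap-fill.  Returns the number of read pairs written.
    """
    L = config.read_length
    u = config.umi_length
    mean_extra = max(config.pcr_mean_reads - 1.0, 0.0)
    size = config.pcr_dispersion
    total = 0
    qual1 = "I" * L
    out1, out2 = [], []
    for probe in panel:
        umis = umis_by_probe.get(probe.name)
        if umis is None or len(umis) == 0:
            continue
        tx = transcriptome[probe.target_id]
        gap = tx[probe.target_start : probe.target_end]
        t1 = (probe.ligation_arm + gap)[:L]
        t2 = (revcomp(probe.extension_arm) + revcomp(gap))[: L - u]
        variants = {False: (t1, t2)}
        if snp_by_probe and probe.name in snp_by_probe:
            off, alt = snp_by_probe[probe.name]
            gap_alt = gap[:off] + alt + gap[off + 1 :]
            variants[True] = ((probe.ligation_arm + gap_alt)[:L], (revcomp(probe.extension_arm) + revcomp(gap_alt))[: L - u])
        alleles = (
            allele_by_probe.get(probe.name) if allele_by_probe is not None else None
        )
        n_mol = len(umis)
        if mean_extra > 0:
            extra = rng.negative_binomial(size, size / (size + mean_extra), n_mol)
        else:
            extra = np.zeros(n_mol, dtype=int)
        reads_per_mol = 1 + extra
        rep = np.repeat(np.arange(n_mol), reads_per_mol)
        seq1 = []
        seq2 = []
        names = []
        for ridx, mi in enumerate(rep):
            is_alt = bool(alleles[mi]) if alleles is not None else False
            a1, a2 = variants[is_alt]
            seq1.append(a1)
            seq2.append(umis[mi] + a2)
            names.append(f"{sample}:{probe.name}:m{mi}:r{ridx}")
        seq1 = _mutate(seq1, rng, config.seq_error_rate)
        seq2 = _mutate(seq2, rng, config.seq_error_rate)
        for nm, s1, s2 in zip(names, seq1, seq2):
            out1.append(f"@{nm}\n{s1}\n+\n{qual1[: len(s1)]}\n")
            out2.append(f"@{nm}\n{s2}\n+\n{qual1[: len(s2)]}\n")
        total += len(rep)
    with open(str(fastq1), "w") as fh:
        fh.write("".join(out1))
    with open(str(fastq2), "w") as fh:
        fh.write("".join(out2))
    return total


def simulate_expression_experiment(
    config: SimConfig, outdir, *, keep_umis: bool = False
) -> SimOutput:
    """End-to-end two-condition experiment: FASTA, panel, FASTQ, truth.

    Per condition, ``replicates_per_condition`` replicates alternate
    between the two replicate classes; the per-probe class-bias factor
    multiplies capture weights in the first class only, identically in
    both conditions (the systematic bias the expression model corrects).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    transcriptome, abundances, groups = make_transcriptome(config, rng)
    panel = make_panel(transcriptome, config, rng)
    names = [p.name for p in panel]
    efficiencies = pd.Series(np.exp(rng.normal(0, config.capture_efficiency_sd, len(names))), index=names)
    class_bias = pd.Series(np.exp(rng.normal(0, config.class_bias_sd, len(names))), index=names)

    # calibrate the mixes to equal total capture propensity: scale the
    # up-regulated groups (both conditions, ratios preserved) so that
    # sum_p w1 = sum_p w2.  Matched-total mixes are the regime in which a
    # depth-normalized model reports the nominal fold changes directly.
    per_tx_w = pd.Series(0.0, index=abundances.index)
    for p in panel:
        per_tx_w[p.target_id] += efficiencies[p.name]
    w_base = abundances[config.conditions[1]] * per_tx_w
    pos = (w_base * (groups - 1.0)).clip(lower=0).sum()
    neg = -(w_base * (groups - 1.0)).clip(upper=0).sum()
    if pos > 0 and neg > 0:
        d = neg / pos
        scale = pd.Series(np.where(groups > 1.0, d, 1.0), index=abundances.index)
        abundances = abundances.mul(scale, axis=0)

    with open(outdir / "transcriptome.fasta", "w") as fh:
        for name, seq in transcriptome.items():
            fh.write(f">{name}\n{seq}\n")
    write_panel(panel, outdir / "panel.tsv")

    rows = []
    count_rows = []
    umis_all: dict = {}
    half = (config.replicates_per_condition + 1) // 2
    for cond in config.conditions[:2]:
        for r in range(config.replicates_per_condition):
            klass = config.replicate_classes[0] if r < half else config.replicate_classes[1]
            sample = f"{cond}_rep{r + 1}"
            counts, umis = simulate_capture(
                abundances[cond],
                panel,
                config,
                rng,
                efficiencies=efficiencies,
                class_bias=class_bias,
                biased_class=(klass == config.replicate_classes[0]),
            )
            fq1 = outdir / f"{sample}_R1.fastq"
            fq2 = outdir / f"{sample}_R2.fastq"
            simulate_reads(umis, panel, transcriptome, config, rng, fq1, fq2, sample=sample)
            rows.append(
                {
                    "sample": sample,
                    "fastq1": str(fq1),
                    "fastq2": str(fq2),
                    "condition": cond,
                    "replicate_class": klass,
                    "experiment": "sim",
                }
            )
            for probe, c in counts.items():
                count_rows.append({"sample": sample, "probe": probe, "molecules": int(c)})
            if keep_umis:
                umis_all[sample] = umis
    sheet = pd.DataFrame(rows)
    sheet.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    truth = GroundTruth(
        abundances=abundances,
        groups=groups,
        efficiencies=efficiencies,
        class_bias=class_bias,
        molecule_counts=pd.DataFrame(count_rows),
        umis=umis_all,
    )
    truth.molecule_counts.to_csv(outdir / "truth_molecules.tsv", sep="\t", index=False)
    return SimOutput(sheet, panel, truth, transcriptome, outdir)


def _snp_panel(
    n_snps: int, config: SimConfig, rng: np.random.Generator
) -> tuple[dict[str, str], Panel, list[SnpTarget]]:
    """One transcript per SNP, two probes with non-overlapping arms each."""
    tlen = 100
    transcriptome: dict[str, str] = {}
    probes: list[Probe] = []
    snps: list[SnpTarget] = []
    for i in range(n_snps):
        tx = f"SNPTX{i:03d}"
        seq = _random_seq(rng, 320)
        transcriptome[tx] = seq
        off = 150  # SNP transcript offset, strictly inside both gap-fills
        ref = seq[off]
        alt_choices = [b for b in "ACGT" if b != ref]
        alt = alt_choices[int(rng.integers(0, 3))]
        placements = [(100, f"{tx}_pA"), (70, f"{tx}_pB")]  # gap starts; arms disjoint
        pnames = []
        for g0, name in placements:
            probes.append(
                Probe(
                    name=name,
                    extension_arm=seq[g0 - 20 : g0],
                    ligation_arm=seq[g0 + tlen : g0 + tlen + 20],
                    target_id=tx,
                    target_start=g0,
                    target_end=g0 + tlen,
                    umi_length=config.umi_length,
                    gene=tx,
                )
            )
            pnames.append(name)
        snps.append(SnpTarget(f"snp{i:03d}", tx, off, ref, alt, tuple(pnames)))
    return transcriptome, Panel(probes), snps


def simulate_dilution(
    outdir,
    *,
    n_steps: int = 8,
    rate: float = 0.75,
    start: float = 0.75,
    n_snps: int = 32,
    molecules_per_snp: int = 2000,
    config: SimConfig | None = None,
    include_controls: bool = True,
) -> DilutionOutput:
    """Two-genotype serial dilution for allelic-ratio analysis.

    Pool A is homozygous for the transcript (reference) base at every
    SNP, pool B for the alternative base; the targeted genes are
    expressed equally in both pools.  The pool-A cDNA fraction at step k
    is ``start * rate**(k-1)``, so between consecutive steps the allelic
    (reference) ratio contracts by exactly ``rate``.  Pure-A and pure-B
    control samples are appended when ``include_controls``.
    """
    if config is None:
        # allelic votes need only a few reads per molecule; lighter
        # sequencing than the expression default is the realistic regime
        config = SimConfig(pcr_mean_reads=3.0, pcr_dispersion=2.0)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed + 17)
    transcriptome, panel, snps = _snp_panel(n_snps, config, rng)
    with open(outdir / "snp_transcriptome.fasta", "w") as fh:
        for name, seq in transcriptome.items():
            fh.write(f">{name}\n{seq}\n")
    write_panel(panel, outdir / "snp_panel.tsv")
    with open(outdir / "snps.tsv", "w") as fh:
        fh.write("snp_id\ttarget_id\toffset\tref\talt\tprobes\n")
        for s in snps:
            fh.write(f"{s.snp_id}\t{s.target_id}\t{s.offset}\t{s.ref_allele}\t{s.alt_allele}\t{','.join(s.probes)}\n")

    snp_by_probe = {}
    for s in snps:
        for pn in s.probes:
            probe = panel[pn]
            snp_by_probe[pn] = (s.offset - probe.target_start, s.alt_allele)

    fractions = [start * rate ** k for k in range(n_steps)]
    steps: list[tuple[str, float]] = [(f"step{k + 1}", f) for k, f in enumerate(fractions)]
    if include_controls:
        steps += [("pureA", 1.0), ("pureB", 0.0)]
    rows, truth_rows = [], []
    per_probe = molecules_per_snp // 2
    for sample, frac in steps:
        umis_by_probe: dict[str, np.ndarray] = {}
        allele_by_probe: dict[str, np.ndarray] = {}
        for s in snps:
            for pn in s.probes:
                n_mol = int(rng.poisson(per_probe))
                umis_by_probe[pn] = _random_umis(rng, n_mol, config.umi_length)
                # alt allele comes from pool B (fraction 1 - frac)
                allele_by_probe[pn] = rng.random(n_mol) >= frac
                truth_rows.append(
                    {
                        "sample": sample,
                        "snp": s.snp_id,
                        "probe": pn,
                        "ref_molecules": int(n_mol - allele_by_probe[pn].sum()),
                        "alt_molecules": int(allele_by_probe[pn].sum()),
                    }
                )
        fq1 = outdir / f"{sample}_R1.fastq"
        fq2 = outdir / f"{sample}_R2.fastq"
        simulate_reads(
            umis_by_probe,
            panel,
            transcriptome,
            config,
            rng,
            fq1,
            fq2,
            sample=sample,
            allele_by_probe=allele_by_probe,
            snp_by_probe=snp_by_probe,
        )
        rows.append(
            {
                "sample": sample,
                "fastq1": str(fq1),
                "fastq2": str(fq2),
                "condition": sample,
                "replicate_class": "A",
                "experiment": "dilution",
                "nominal_fraction": frac,
            }
        )
    sheet = pd.DataFrame(rows)
    sheet.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    truth = pd.DataFrame(truth_rows)
    truth.to_csv(outdir / "truth_alleles.tsv", sep="\t", index=False)
    return DilutionOutput(sheet, panel, snps, fractions, truth, outdir)
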