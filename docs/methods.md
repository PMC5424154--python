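# Methods

`smmipseq` implements targeted expression quantification with
single-molecule molecular inversion probes (cDNA smMIPs): probe-panel
design against spliced transcripts, alignment-free conversion of
paired-end capture reads into error-corrected unique-molecule counts, a
Bayesian hierarchical negative-binomial model for normalized and
differential expression, and allele-specific expression by per-molecule
majority vote. A ground-truth simulator covers the whole pipeline so
every claim made by the test suite is checked against known truth.

## The assay in brief

A smMIP is a 79-nt single-stranded oligo: two targeting arms (extension
and ligation, each 16–24 nt, 40 nt in total), a 30-nt backbone carrying
the universal amplification primers, and a random 9-nt unique molecular
identifier (UMI) between the extension arm and the backbone. The arms
hybridize to the sequences flanking a 112-nt (expression panels) or
100-nt (variant panels) target on the cDNA; gap-fill polymerization and
ligation circularize the probe, capturing a copy of the target together
with the UMI. After amplification and sequencing, the number of distinct
UMIs per probe — not the number of reads — estimates the number of
captured cDNA molecules, which is the quantification unit throughout.

## Panel design

Probes are designed against spliced transcript sequence, so candidates
may span exon–exon junctions; such candidates are flagged, not rejected
(on cDNA a junction is ordinary sequence, and junction probes add
specificity against genomic DNA). The procedure: splice transcripts from
exon structures (genomic↔transcript coordinate maps are exact inverses on
every exonic base; minus-strand transcripts are reverse-complemented),
divide each target into non-overlapping 200-nt segments (trailing
partial segments are flagged), exhaustively enumerate candidates over
all arm-length splits and placements, and filter on arm uniqueness in
the reference. Copy number uses exact string matching of each arm and
its reverse complement against the supplied reference set — for ≥16-nt
arms this is equivalent to read-mapper copy estimation at panel scale
and is deterministic and dependency-free; a hook accepts externally
computed copy numbers, and an optional externally supplied performance
score can be used as a filter (score computation itself is out of
scope). For variant panels, candidates must hold the variant strictly
inside the gap-fill, and each variant receives a *pair* of probes whose
extension arms do not overlap and whose ligation arms do not overlap:
the two probes then capture physically independent molecules and give
independent allelic-ratio estimates.

## From reads to molecules

Reads are never aligned to a reference for expression counting — probe
assignment is by arm matching alone, which avoids mapping bias:

1. **Assignment.** Mate 1 begins with the ligation arm, mate 2 with the
   UMI followed by the reverse-complemented extension arm (the layout is
   configurable). Each mate's expected arm region is compared to every
   panel probe by Hamming distance; a read pair is assigned to the
   unique probe with both arm distances ≤ 2 and minimal total distance.
   Exact ties are discarded as ambiguous. The implementation uses an
   exact-match dictionary fast path with a vectorized full comparison as
   fallback; the test suite proves it identical to a plain brute-force
   search.
2. **Dimer removal.** Pairs in which the partner arm (either
   orientation) begins fewer than 20 nt after the ligation arm have no
   genuine gap-fill — extension–ligation dimers — and are excluded. The
   20-nt minimum insert sits far below the 100–112-nt designed gap-fills
   and far above read-start noise.
3. **UMI tallying.** Retained reads are grouped per probe by exact UMI
   sequence (UMIs containing N are dropped by default). No 1-mismatch
   merging is applied; the coverage threshold below is the sole
   error-correction device.
4. **Coverage threshold R.** Sequencing errors inside the UMI create
   phantom UMIs: at 0.2% per-base error a 9-nt UMI is corrupted with
   probability 1 − 0.998⁹ ≈ 1.8% per read, so observed UMI counts keep
   growing with depth. Per probe, R is the largest read count such that
   UMIs with coverage ≥ R still account for ≥ 95% of the probe's reads;
   the corrected molecule count is the number of such UMIs. Phantom UMIs
   concentrate in the 1-read tail and are removed, while the retained
   fraction ≥ 95% holds by construction. The implementation is tested
   against a brute-force search over every integer threshold. The
   wording "above a threshold" admits a strict-inequality reading; the
   ≥ form is the default (it is the only one that always retains ≥ 95%)
   and a `strict=True` mode exposes the alternative.

## The expression model

For one condition with probes *p* and replicates *r*:

    y[p,r] ~ NegBin(mean = m[p,r], dispersion = phi[e(r)])
    log m[p,r] = log N[r] + mu[p] + alpha[k(r)] + lambda[k(r)] · x[p]

with Var = m + m²/phi. N[r] is the replicate's total molecule count
(depth), mu[p] the probe's log mean normalized expression (exp(mu) is a
proportion of the panel total), phi[e] a per-experiment overdispersion
shared across probes, and k(r) the replicate class (e.g. cDNA input
amount).

**Probe-bias covariate.** Replicate-class-dependent deviations of a
probe's normalized counts are systematic — they correlate across
unrelated conditions — so they are estimated once, as x[p] = the
cross-condition average of ½·(mean log(1+mpm) in class A − mean
log(1+mpm) in class B), centered to zero mean, and entered as a
covariate with a per-class loading lambda[k]. mpm is molecules per
million (1e6·y/N).

**Class intercept.** alpha[k] (reference class pinned at 0) absorbs the
probe-independent depth offset that any multiplicative per-probe class
bias necessarily induces (the class's total capture shifts by a Jensen
term that a centered slope cannot represent). Without it, unbalanced
class designs leak class bias into fold changes.

**Priors.** mu[p] ~ Normal(log(1/P), 5²) with P the probe count —
weakly informative and scale-free on the composition simplex; alpha,
lambda ~ Normal(0, 1); 1/phi ~ Half-Cauchy(0, 5). All exposed in
`MCMCConfig`.

**Sampling.** Given (alpha, lambda, phi) the likelihood factorizes over
probes, so an adaptive Metropolis-within-Gibbs sampler mixes well:
element-wise random-walk updates for all mu simultaneously, scalar
updates for alpha, lambda and log phi, and a likelihood-invariant
"ridge" move that shifts every lambda[k] by δ while moving each mu[p] by
−δ·x[p] (this direction is identified only by the priors; without the
move, tight mu conditionals freeze the lambda level and split-R̂ exceeds
2). Proposal scales adapt toward 44% acceptance during warmup
(Robbins–Monro, clipped) and are frozen afterwards; alpha and lambda are
initialized at least-squares estimates because their conditionals can be
orders of magnitude narrower than their priors. Defaults: 4 chains,
1,000 warmup iterations, 250 draws kept per chain at thinning 4 → 1,000
posterior draws; split-chain R̂ is reported for every parameter and a
warning is raised above 1.05. The sampler was validated against 2-D grid
quadrature on single-probe posteriors (agreement < 1%) and recovers
known parameters from model-simulated data.

**Estimates.** Condition fits are independent; differential expression
pairs the s-th draw of each fit, Δ = (mu_A − mu_B)/ln 2, summarized by
the posterior mean and central 95% interval. Gene-level estimates
average the *draws* of a gene's probes (not the point estimates), so
uncertainty propagates; single-probe genes pass through. Relative
expression reports gene-level log2(1 + mpm) and is comparable to
external measures only up to an affine transform. Zero counts are
retained (they are in the NB support); log(1+·) appears only in the bias
covariate and in expression reporting.

A caveat on the contrast scale: with depth normalization, a global
composition shift between conditions is indistinguishable from uniform
differential expression. The two-mix evaluation below therefore anchors
fold changes on the no-change control group, exactly as spike-in
controls are used to calibrate scale in practice.

## Allele-specific expression

Reads are assigned to probes by the same arm matching; per (probe, UMI)
group, all reads vote on the base observed at the SNP and the strictly
winning allele contributes one molecule. Exact ties discard the molecule
(a seeded random-resolution mode exists for sensitivity checks); base
qualities are ignored — the vote is the error-correction device. Groups
with the same UMI under different probes are independent molecules. The
allelic ratio is ref/(ref+alt) molecules with a Clopper–Pearson 95%
interval. Two backends share the vote logic: alignment-free (the SNP
position is located by offset arithmetic inside the designed gap-fill,
from either mate) and SAM input with the UMI carried in the read
identifier (`rewrite_umi_to_header` prepares FASTQ for mapping); they
agree exactly on error-free reads.

In an exponential dilution of genotype pool A into pool B (each step
keeps fraction ρ of the previous step and adds 1−ρ of pool B), the
A-allele molecule count scales by exactly ρ per step, so the ratio of
allelic ratios between consecutive steps equals ρ *provided the targeted
genes are expressed equally in the two pools* — the criterion on which
dilution SNPs are selected, and an assumption the simulator makes
exactly. The absolute ratio of the first step depends on the unknown
pool expression levels and is not predicted; only step-to-step ratios
are evaluated, summarized by their geometric mean over steps and SNPs.

## The simulator

The simulator defines the study conditions under which the pipeline is
validated; its defaults are fixed and the tests run against them.

* **Transcriptome and mixes.** Random transcripts (40 by default,
  1.5–2 kb) with abundances log-uniform over 4 orders of magnitude. The
  two-mix design assigns fold-change groups 0.5/0.67/1.0/4.0 by dealing
  abundance-ranked transcripts around the groups (each group spans the
  dynamic range, as real spike-in subpools are laid out) and rescales
  the up-regulated groups so both mixes have equal total capture
  propensity. Matched totals are the regime in which a depth-normalized
  model can report nominal fold changes; the residual global shift in
  any one realization is handled by anchoring (above).
* **Capture.** Per replicate, molecule counts are multinomial over
  probes with weights abundance × per-probe efficiency (log-normal,
  sd 0.5 — substantial between-probe variation within a transcript) ×
  per-probe class bias (log-normal, sd 0.25, applied to one replicate
  class identically in both conditions — the systematic bias the model
  corrects). Each molecule draws an independent uniform 9-nt UMI;
  collisions are allowed and produce the same small downward bias real
  tags have, which is why "exact" round-trip checks count distinct UMIs.
* **Reads.** Reads per molecule are 1 + NegBin (default mean 10,
  dispersion 5 — deep sequencing): the heavy-tailed coverage the
  threshold rule is designed for, with phantom UMIs in the 1-read tail
  and real molecules at ~10 reads. (At shallow duplication ~3× the
  singleton-read fraction sits exactly at the 95% knife edge and R flips
  stochastically per probe; dilution simulations default to 3× because
  majority votes need few reads and no threshold is involved.)
  Substitution errors are i.i.d. at 0.2% per base; no indels, since arm
  matching and UMI thresholding — the components under test — are
  substitution-driven. Qualities are constant. Everything is
  byte-reproducible under a fixed seed.
* **Dilution.** One transcript per SNP, two arm-disjoint probes per SNP,
  pool A homozygous for the transcript base and pool B for the
  alternative, equal expression in both pools; pool-A fraction
  0.75·0.75^(k−1) over 8 steps plus pure-pool controls, ~2,000 molecules
  per SNP per step.

What the simulator does *not* emulate: indels and quality-dependent
errors, sequence-dependent (GC) capture efficiency, rRNA or off-target
background, mapping ambiguity between homologous targets, and library-
dependent UMI base composition. Passing tests therefore demonstrate the
correctness and calibration of the algorithms under the stated
generative assumptions, not performance on any particular real library.

## Evaluation designs used by the test suite

* **Two-mix recovery.** Full pipeline (simulate → count → fit → contrast
  → gene aggregation) at 5×10⁴ molecules per replicate, 4 replicates per
  condition split over two replicate classes. Group summaries include
  transcripts whose true mix proportion is ≥ 5×10⁻⁴ in both conditions
  (a truth-based inclusion rule: filtering on *estimated* expression
  preferentially keeps upward-fluctuating genes near the detection
  boundary and tilts the extreme groups), weight gene estimates by
  inverse posterior variance, and report fold changes relative to the
  1.0× group. This design was validated on the simulator's truth layer
  across 24 seeds (worst group-mean error 0.032 log2 units) before being
  frozen.
* **Dilution.** 32 SNPs × 2 probes × 8 steps; geometric-mean
  consecutive-step ratio compared to the dilution rate 0.75; per-SNP
  concordance of the two independent probe series by squared Pearson
  correlation.
* **Calibration.** On data simulated from the model itself (200 probes,
  4 replicates, 2 classes, 3 independent datasets), 95% credible
  intervals cover true probe expression for 95% ± 3% of probes;
  self-vs-self contrasts are centered at zero; with an injected class
  bias under unbalanced class designs, the covariate+intercept reduce
  the mean absolute fold-change error below 0.1 log2 (≥ 0.3 without).

## Numerical and edge-case conventions

* Coordinates 0-based half-open internally; VCF positions converted at
  the boundary. Volumes µl, concentrations µM, masses ng; no automatic
  unit conversion.
* `error_corrected_count([])` → no threshold, zero molecules; empty
  FASTQ → all-zero count row; zero-depth replicates are excluded with a
  warning; a transcript shorter than arms+target yields an empty
  candidate list, not an error.
* Probe-assignment ties and vote ties are discarded, never guessed.
* Threshold search scans the distinct coverage values in descending
  order (f(r) is a step function constant between them), which is exact
  and O(n log n).
* Reproducibility: one `numpy` Generator per run seeds every stochastic
  step; the workflow manifest records seeds and input checksums, and
  re-running with unchanged inputs reproduces count tables byte-for-byte
  and posterior summaries under a fixed MCMC seed.

## Known limitations

* Composition normalization: only relative statements are possible;
  global shifts between conditions are not identifiable without anchor
  genes or matched-total designs.
* The NB model shares one dispersion per experiment across probes; truly
  probe-specific overdispersion would be absorbed partly into wider
  intervals, partly into the shared phi.
* Arm-based assignment assumes arms are unique within the panel at the
  mismatch budget; the design module's copy-number and pairwise-distance
  properties make this true for designed panels, but degenerate custom
  panels fall back to ambiguous-read discarding.
* UMI collisions bias molecule counts downward by ~n²/(2·4⁹) per probe;
  negligible below ~10³ molecules per probe, and shared across
  conditions.
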