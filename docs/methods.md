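# Methods

## The problem

Formalin fixation fragments DNA and introduces chemical lesions
(cross-links, adducts and cytosine deamination). A spectrophotometer or
dye assay reports the *bulk* mass of an FFPE extract, but only a small —
often single-digit-percent — fraction of those molecules can actually
serve as templates in a PCR. Targeted NGS panels enrich their loci by
multiplex PCR, so the effective library complexity is set by the
*amplifiable* copy number, not the loaded nanograms. When that number is
small, two failure modes follow: real mutations drift away from their true
allele fraction or vanish entirely (false negatives), and single lesioned
templates become a large enough fraction of the library to cross variant-
calling thresholds (false positives, dominated by C>T/G>A).

`qfikit` quantifies the amplifiable fraction from qPCR data, converts it
into input-mass requirements, simulates the stochastic consequences of
violating them, and audits variant calls against an orthogonal
confirmation assay.

## Quantification model

A calibration curve is fitted by ordinary least squares of Cq on
log10(copies), using a titration of high-quality genomic DNA
(canonically 5-fold from 15,150 down to ~5 copies; replicates enter as
individual points, not level means — the simplest defensible estimator).
Amplification efficiency is `E = 10^(-1/slope) - 1`; a slope of
−3.3219 cycles/log10 is one doubling per cycle (100%).

A sample Cq inverts through the curve to absolute amplifiable copies
`10^((Cq - b)/m)`. The Quantitative Functional Index is

    QFI (%) = 100 * amplifiable_copies / (input_ng * 303)

with 303 haploid copies per nanogram of human DNA held as an exact,
named convention (`COPIES_PER_NG`) so that the standard worked numbers
(3,030 copies in 10 ng, 1,515 in 5 ng) are reproduced without rounding
drift. An undetected Cq (no signal within 50 cycles) is a first-class
value mapping to 0 copies / QFI 0 / `detected=False`; it is never an
exception or missing datum. Estimates outside the fitted titration are
returned but flagged as extrapolated. When both reference assays (TBP
and FTH1) are measured, the TBP value is reported by default with an
averaging option; the two assays agree to a mean fold change of ~1 in
practice and no canonical combination rule exists, so the choice is
exposed rather than hidden.

Detection and quantification limits default to 5 and 10 copies. The LOQ
criterion is replicate Cq standard deviation < 0.5 cycles with all
replicates detected, taken as the smallest level such that it and every
larger level qualify (variability must grow monotonically as template
runs out; a noisy intermediate level is not skipped). Ten quantifiable
copies against a 5 ng input is 100·10/1,515 = 0.66% — the smallest QFI
the assay can report as a number rather than a flag.

Inhibition is checked with an exogenous spike (the SPUD potato amplicon,
no human homology): a Cq delay of ≥ 1 cycle versus a clean control flags
inhibition; an undetected spike flags total inhibition.

## Input planning

With QFI and mutant fraction %M as fractions, the mass of bulk DNA that
delivers the mutant-template floor k (default 10 copies, a chosen
stochastic-safety value, exposed as a parameter) is

    bulk_ng = k / (303 * QFI * %M)

Halving QFI exactly doubles the requirement — an identity the test suite
holds to float precision. The planner classifies samples into QFI tiers
(low < 3%, borderline 3–6%, acceptable > 6%; both thresholds
configurable, since the accuracy break point is a band, not a line) and
issues `pass` when the assay's default input (10 ng) already carries the
required copies, `rescue_increase_input` when the required mass is within
the DNA available, `fail` otherwise or when the sample is undetected or
inhibited. Degenerate inputs produce fail decisions with reasons, never
exceptions, because QC pipelines must keep running past bad samples.

## Sampling simulator

Per replicate: templates delivered `n* ~ Poisson(n)` (pipetting a dilute
solution physically Poisson-distributes molecules; a fixed-count mode
exists for exact oracle comparisons), mutant templates
`m ~ Binomial(n*, p)`, and observed reads `Binomial(depth, m/n*)`.
`depth=None` is the infinite-depth sentinel where the observed fraction
is the template fraction itself. Enrichment PCR is treated as unbiased —
every functional template amplifies equally — because no amplification-
bias data exist to parameterize a branching model; consequently the
infinite-depth CV has the closed form `100·sqrt((1-p)/(np))`, which
serves as the analytic oracle. Replicates with `n* = 0` have no defined
fraction; they are recorded as dropouts and counted as false negatives.
False-negative probabilities for fixed n ≤ 30 at infinite depth are
computed by exhaustive enumeration over the binomial support instead of
sampling.

The model intentionally excludes read-level error (base quality,
homopolymer artifacts) and wet-lab dilution noise, so empirically
observed CVs in titration experiments sit above the simulated ones; the
simulator bounds qualitative behavior (CV and FN rate fall with n, the
variance knee near a few hundred copies) rather than reproducing
instrument-specific numbers.

## Artifact (false-positive) model

Each template independently carries a lesion at each base with
probability r (`lesion_rate_per_base`, default 1e-4 — a free parameter;
no published per-base rate pins it). At a site, the lesioned-template
count is `X ~ Binomial(n, r)` and a variant is called when the
read-sampled allele fraction reaches the calling threshold (default 5%):
`P(call | X=x) = P(Binomial(d, x/n) >= ceil(d·t))` at read depth d
(default 900, matching typical per-variant coverage of a clinical
amplicon panel). Germline heterozygosity adds
`Binomial(region_bp, 1/1,000)` true calls. Sites are i.i.d. — damage
clustering is not modeled for lack of data — so the per-replicate
artifact count is drawn as `Binomial(region_bp, p_site)` with `p_site`
computed by exact marginalization; this is distributionally identical to
placing lesions base by base and much cheaper.

The read-depth layer is part of the model, not a convenience: with calls
made directly on the template lesion fraction, the integer threshold
`ceil(0.05·n)` stays at 2 lesioned templates for both n = 24 and n = 36,
so the expected artifact-call count would *rise* between those copy
numbers even though more templates means more dilution of damage. Read
sampling smooths the threshold and restores the physically expected
monotone decline of artifact calls with library complexity. The germline
random stream is drawn from its own spawned generator before the
artifact stream, so runs sharing a seed share germline noise across copy
numbers and differ only in the artifact component — the monotonicity
property is then testable without germline sampling noise masking it.

## Confirmation audit

Primary-panel calls pass through a fixed cascade: restriction to the
regions shared with the confirmation panel (BED semantics, 0-based
half-open; variant positions 1-based; indels excluded by default because
no indel loci overlap the confirmation content), an allele-aware
blacklist of known systematic loci, a strict >5% allele-fraction filter,
and exact `(chrom, pos, ref, alt)` matching against the confirmation
calls. Calls below the confirmation assay's 4% analytical sensitivity
are tallied as unconfirmable rather than false. Input allele fractions
are treated as already aggregated (how a "mean AF" was averaged upstream
is not modeled). Tier summaries report mean ± SD of variant counts per
QFI tier, the pooled confirmation rate, and Welch's unequal-variance
t-test for the low-vs-acceptable contrast — one contrast, no
multiple-testing adjustment. Two zero-variance groups with equal means
return t = 0, p = 1 by convention.

The packaged 19-sample reference audit (`qfikit.datasets`) stores the
published per-row cascade counts; the per-variant loci behind them were
never published, so the fixture builder engineers synthetic loci and
allele fractions that reproduce every row's counts exactly. The counts
are the contract; the loci are labelled synthetic.

## Synthetic cohort generator

Defaults encode the study conditions: standard curve at 92.6%
efficiency (slope −3.512, intercept 40 cycles at 1 copy), 5 ng qPCR
inputs, cohort size 165, and a log-normal QFI distribution
parameterized to median 3.96% with interquartile range 1.22–8.55%
(log-sigma = (ln 8.55 − ln 1.22)/(2·0.6745) ≈ 1.444, capped at 100%).
The log-normal family is an assumption — only summary statistics were
reported. Cq noise defaults to the value implying the assay's 26%
copy-number repeatability CV through the curve slope:
`sigma_Cq = 0.26·|slope|/ln 10 ≈ 0.40` cycles (the per-level noise
magnitude was not published, so it is back-solved from the repeatability
figure). Samples whose true copies fall below the 5-copy detection limit
emit UNDETECTED. Germline SNP allele fractions are drawn near 0.5 (het)
or 1.0 (hom) at a 2:1 ratio — unreported upstream, chosen as typical.
Calibrator titration noise defaults to 0.15 cycles, a clean
high-quality-DNA run.

What the generator does *not* emulate: PCR amplification bias,
sequencing error, inter-operator effects, tissue heterogeneity and
extraction chemistry. Passing recovery tests therefore demonstrate that
the estimators invert the stated model, not that the model captures
every property of real FFPE extracts.

## Numerical and testing choices

Problem sizes were chosen to make Monte Carlo checks decisive at
interactive runtimes: 10,000 replicates for simulator-vs-oracle
comparisons (agreement asserted within 3 delta-method standard errors of
the CV estimator, with exact binomial moments enumerated for the SE),
1,000-sample cohorts for QFI recovery, 1,000 replicates for artifact-
count curves. The recovered-median QFI of a single 1,000-sample cohort
carries ~2.6% relative noise from rank reshuffling at the prescribed
26% repeatability CV, so the recovery check takes the median error over
five independent cohorts. All randomness flows through explicit integer
seeds (numpy `Generator`/`SeedSequence`; no global state); identical
seed and model give bit-identical replicate arrays.

Display rounding is nearest-integer for copies and one decimal for
percentages, matching the conventions of the worked examples (370, 289,
36, 27.8%); all internal values stay real-valued. QFI and %M enter every
formula as fractions; user-facing I/O uses percentages — one internal
convention to prevent 100× errors.

## Known limitations

* The lesion rate per base is a free parameter; observed variant-count
  inflation at low QFI constrains but does not uniquely identify it.
* The simulator's unbiased-PCR assumption understates variance relative
  to titration experiments that include wet-lab noise.
* The planner flags but does not cap very large rescue inputs; an upper
  bound on enrichment-PCR input mass is assay-specific.
* Empirical cohort-level quantities (median QFI of a given tissue bank,
  dye-vs-qPCR correlation) are properties of particular datasets and are
  out of scope.
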