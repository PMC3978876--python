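"""Monte Carlo simulation of template sampling and FFPE artifact calls.

Two stochastic phenomena dominate targeted NGS of low-quality FFPE DNA:

* **Mutant-fraction variance / false negatives.** When only n functional
  templates enter the enrichment PCR, the number of mutant templates is
  Binomial(n, p). Reads then sample that template pool, so at low n the
  observed allele fraction is wildly variable regardless of read depth,
  and a real mutation can fall below the calling threshold.

* **False positives.** Deamination lesions (chiefly C>T/G>A) sit on
  individual templates. With few templates, one lesioned molecule is a
  large fraction of the library and its reads can cross the allele-
  fraction calling threshold, inflating variant counts at low QFI.

The sampling model deliberately treats enrichment PCR as unbiased: every
functional template amplifies equally, so read sampling is binomial around
the template fraction. Amplification-efficiency branching processes are
out of scope. Template delivery is Poisson around the pipetted mean by
default (physically forced at low dilution); a fixed-count mode exists for
exact oracle comparisons.

All randomness flows through explicit integer seeds; there is no global
random state, and identical seed + model give bit-identical replicate
values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

#: Maximum exact-enumeration template count for false_negative_rate.
ENUMERATION_MAX_N = 30


@dataclass(frozen=True)
class SamplingModel:
    """Template-sampling experiment: n templates, mutant fraction p, reads.

    ``read_depth=None`` is the infinite-depth sentinel: the observed
    fraction is the template fraction itself (no read-sampling layer).
    """

    functional_copies: float
    mutant_fraction: float
    read_depth: int | None = None
    replicates: int = 1000
    poisson_delivery: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.functional_copies < 0:
            raise ValueError("functional_copies must be non-negative")
        if not 0 <= self.mutant_fraction <= 1:
            raise ValueError("mutant_fraction must be in [0, 1]")
        if self.read_depth is not None and self.read_depth < 1:
            raise ValueError("read_depth must be >= 1 (or None for infinite)")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass(frozen=True)
class ArtifactModel:
    """Per-template lesion model for FFPE deamination false positives.

    Each template carries an independent lesion at each base with
    probability ``lesion_rate_per_base``. At a given site the lesioned
    template fraction is Binomial(n, rate)/n; reads sampled at
    ``read_depth`` around that fraction produce a variant call when the
    observed allele fraction reaches ``af_call_threshold``. Germline
    heterozygosity contributes Binomial(region_bp, germline_snp_rate)
    true calls per sample; ``transition_bias`` is the fraction of
    artifact calls that are C>T or G>A.
    """

    lesion_rate_per_base: float = 1e-4
    region_bp: int = 13000
    af_call_threshold: float = 0.05
    germline_snp_rate: float = 1e-3
    transition_bias: float = 0.75
    read_depth: int | None = 900

    def __post_init__(self):
        for name in ("lesion_rate_per_base", "af_call_threshold",
                     "germline_snp_rate", "transition_bias"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.region_bp < 0:
            raise ValueError("region_bp must be non-negative")


@dataclass
class SimOutcome:
    """Distributional summary of a simulation run.

    ``per_replicate_values`` holds the observed mutant fraction (sampling
    simulations; NaN marks a zero-template dropout) or the total variant
    calls (false-positive simulations) for each replicate.
    """

    mean_observed_fraction: float
    cv_percent: float
    false_negative_rate: float
    expected_variant_calls: float
    per_replicate_values: np.ndarray
    n_dropout: int = 0


def simulate_mutant_fraction(model: SamplingModel) -> SimOutcome:
    """Simulate the observed mutant allele fraction over replicates.

    Per replicate: templates n* (Poisson around the mean, or fixed), mutant
    templates Binomial(n*, p), then—at finite depth—reads Binomial(depth,
    m/n*). A replicate with n* = 0 has no defined fraction; it is recorded
    as NaN and counted as a dropout (and toward false negatives).
    """
    rng = np.random.default_rng(model.seed)
    reps = model.replicates
    if model.poisson_delivery:
        n = rng.poisson(model.functional_copies, size=reps)
    else:
        n = np.full(reps, int(round(model.functional_copies)))
    m = rng.binomial(n, model.mutant_fraction)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n > 0, m / np.maximum(n, 1), np.nan)
    if model.read_depth is not None:
        safe = np.nan_to_num(frac)
        reads = rng.binomial(model.read_depth, safe)
        observed = np.where(np.isnan(frac), np.nan, reads / model.read_depth)
    else:
        observed = frac
    valid = observed[~np.isnan(observed)]
    n_dropout = int(np.isnan(observed).sum())
    if valid.size:
        mean = float(valid.mean())
        sd = float(valid.std(ddof=1)) if valid.size > 1 else 0.0
        cv = 100.0 * sd / mean if mean > 0 else 0.0
    else:
        mean, cv = math.nan, math.nan
    fn = float((np.isnan(observed) | (observed == 0)).sum() / reps)
    return SimOutcome(
        mean_observed_fraction=mean,
        cv_percent=cv,
        false_negative_rate=fn,
        expected_variant_calls=math.nan,
        per_replicate_values=observed,
        n_dropout=n_dropout,
    )


def analytic_cv(functional_copies: float, mutant_fraction: float) -> float:
    """Closed-form CV (%) of the template mutant fraction at infinite depth.

    For fixed n templates the observed fraction is Binomial(n, p)/n, so
    CV = 100 * sqrt((1-p)/(n*p)). The degenerate fractions 0 and 1 have no
    sampling variance and return 0.
    """
    if functional_copies <= 0:
        raise ValueError("functional_copies must be positive")
    p = mutant_fraction
    if not 0 <= p <= 1:
        raise ValueError("mutant_fraction must be in [0, 1]")
    if p in (0.0, 1.0):
        return 0.0
    return 100.0 * math.sqrt((1.0 - p) / (functional_copies * p))


def enumerate_fn_rate(n: int, p: float, call_threshold: float) -> float:
    """Exact P[observed fraction < threshold] for fixed n at infinite depth.

    Exhaustive enumeration over Binomial(n, p): sums the pmf over all
    mutant counts m with m/n < threshold. Serves as the independent oracle
    for the sampling simulator.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    pmf = stats.binom.pmf(np.arange(n + 1), n, p)
    ms = np.arange(n + 1)
    return float(pmf[ms / n < call_threshold].sum())


def false_negative_rate(model: SamplingModel, call_threshold: float) -> float:
    """Probability the observed mutant fraction falls below a call threshold.

    Uses exact enumeration (no sampling) for fixed delivery of at most 30
    templates at infinite depth; otherwise Monte Carlo via
    :func:`simulate_mutant_fraction`, with zero-template dropouts counted
    as false negatives.
    """
    if not 0 <= call_threshold < 1:
        raise ValueError("call_threshold must be in [0, 1)")
    if call_threshold == 0:
        return 0.0
    n = model.functional_copies
    exact_ok = (
        not model.poisson_delivery
        and model.read_depth is None
        and n <= ENUMERATION_MAX_N
        and float(n).is_integer()
    )
    if exact_ok:
        return enumerate_fn_rate(int(n), model.mutant_fraction, call_threshold)
    out = simulate_mutant_fraction(model)
    obs = out.per_replicate_values
    return float((np.isnan(obs) | (obs < call_threshold)).sum() / obs.size)


def artifact_site_call_probability(
    n_functional: int, artifact: ArtifactModel
) -> float:
    """Probability a single site produces an artifact variant call.

    Marginalizes over the lesioned-template count X ~ Binomial(n, rate):
    at finite read depth d the call probability given X=x is
    P[Binomial(d, x/n) >= ceil(d * threshold)]; at infinite depth it is the
    indicator x/n >= threshold. X = 0 can never be called.
    """
    n = int(n_functional)
    if n <= 0:
        return 0.0
    r = artifact.lesion_rate_per_base
    if r == 0:
        return 0.0
    t = artifact.af_call_threshold
    xs = np.arange(1, n + 1)
    weights = stats.binom.pmf(xs, n, r)
    # trim the negligible upper tail for large n
    keep = weights > 1e-18
    if keep.any():
        xs, weights = xs[keep], weights[keep]
    frac = xs / n
    if artifact.read_depth is None:
        called = (frac >= t).astype(float)
    else:
        d = artifact.read_depth
        kmin = math.ceil(d * t)
        called = stats.binom.sf(kmin - 1, d, frac)
    return float(np.sum(weights * called))


def expected_calls(n_functional: int, artifact: ArtifactModel) -> float:
    """Analytic expected variant calls per sample: germline SNPs + artifacts.

    region_bp * (snp_rate + per-site artifact call probability). With a
    lesion rate of 0 this is exactly region_bp * snp_rate (13 for a 13 kb
    panel at 1 SNP per 1,000 bases).
    """
    p_art = artifact_site_call_probability(n_functional, artifact)
    return artifact.region_bp * (artifact.germline_snp_rate + p_art)


def simulate_false_positives(
    n_functional: int,
    artifact: ArtifactModel,
    replicates: int = 1000,
    seed: int = 0,
) -> SimOutcome:
    """Monte Carlo total variant calls per sample at a functional copy number.

    Per replicate the germline SNP count is Binomial(region_bp, snp_rate)
    and the artifact call count is Binomial(region_bp, p_site) where p_site
    marginalizes the per-template lesion process (sites are i.i.d.). The
    germline stream is drawn first from its own spawned generator, so runs
    sharing a seed share germline noise across different copy numbers and
    differ only in the artifact component.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    snp_rng, art_rng = np.random.default_rng(seed).spawn(2)
    region = artifact.region_bp
    if region == 0:
        calls = np.zeros(replicates)
    else:
        snps = snp_rng.binomial(region, artifact.germline_snp_rate, size=replicates)
        p_site = artifact_site_call_probability(n_functional, artifact)
        artifacts = art_rng.binomial(region, p_site, size=replicates)
        calls = (snps + artifacts).astype(float)
    mean = float(calls.mean())
    sd = float(calls.std(ddof=1)) if replicates > 1 else 0.0
    return SimOutcome(
        mean_observed_fraction=math.nan,
        cv_percent=100.0 * sd / mean if mean > 0 else 0.0,
        false_negative_rate=math.nan,
        expected_variant_calls=mean,
        per_replicate_values=calls,
    )


def dilution_series(start_copies: float, fold: float, steps: int) -> list[int]:
    """Geometric dilution series rounded to integer copies.

    3,030 copies diluted 2-fold over 8 levels ends at 24 (3,030/2^7 = 23.7).
    """
    if fold <= 1:
        raise ValueError("fold must be > 1")
    if steps < 1:
        raise ValueError("steps must be >= 1")
    return [int(round(start_copies / fold**i)) for i in range(steps)]
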