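"""Seeded synthetic-data generators with known ground truth.

Every input the pipeline consumes can be generated here with its truth
recorded, enabling closed-loop recovery tests: calibrator titration Cq
series from a known standard curve, FFPE cohort Cq tables at known QFI,
mutant/total read-count tables from the template-sampling model, and
paired primary/confirmation variant tables with germline SNPs plus
QFI-dependent artifact calls.

Default study conditions: a standard curve at ~92.6% amplification
efficiency (slope -3.512, intercept 40 cycles at 1 copy); a log-normal
QFI distribution with median 3.96% and interquartile range 1.22-8.55%;
5 ng qPCR inputs; Cq noise back-solved from a 26% copy-number
repeatability CV (sigma_Cq = 0.26 * |slope| / ln 10 ~ 0.40 cycles);
a 13 kb panel with 1 germline SNP per 1,000 bases and 75% C>T/G>A
artifact transitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import COPIES_PER_NG
from .confirmation import Region, VariantCall
from .qpcr import UNDETECTED, CalibrationCurve, CqMeasurement, efficiency_from_slope
from .simulate import ArtifactModel, SamplingModel, simulate_mutant_fraction, \
    artifact_site_call_probability

#: log-space sigma matching the default QFI interquartile range 1.22-8.55%
#: around a median of 3.96%: (ln 8.55 - ln 1.22) / (2 * 0.6745).
_DEFAULT_QFI_SIGMA = (math.log(8.55) - math.log(1.22)) / (2 * stats.norm.ppf(0.75))


@dataclass(frozen=True)
class GeneratorConfig:
    """Ground-truth parameters for all generators; the seed is mandatory."""

    seed: int
    slope: float = -3.512
    intercept: float = 40.0
    cq_noise_sd: float | None = None  # None: back-solve from repeatability_cv
    repeatability_cv: float = 0.26    # relative SD of repeated copy estimates
    qfi_median_percent: float = 3.96
    qfi_log_sigma: float = _DEFAULT_QFI_SIGMA
    n_samples: int = 165
    input_mass_ng: float = 5.0
    lod_copies: float = 5.0
    max_cycles: float = 50.0
    replicates: int = 3

    def __post_init__(self):
        if self.slope >= 0:
            raise ValueError("slope must be negative")
        if self.cq_noise_sd is not None and self.cq_noise_sd < 0:
            raise ValueError("cq_noise_sd must be non-negative")

    @property
    def noise_sd(self) -> float:
        """Cq noise SD; by default the value implying the repeatability CV.

        A Cq perturbation dq moves log10(copies) by dq/slope, so the
        relative SD of copies is approximately sigma_Cq * ln(10)/|slope|.
        """
        if self.cq_noise_sd is not None:
            return self.cq_noise_sd
        return self.repeatability_cv * abs(self.slope) / math.log(10.0)

    @property
    def curve(self) -> CalibrationCurve:
        return CalibrationCurve(
            slope=self.slope,
            intercept=self.intercept,
            r_squared=1.0,
            efficiency_percent=efficiency_from_slope(self.slope),
        )


def gen_calibrator_titration(
    config: GeneratorConfig,
    *,
    top_copies: float = 15150.0,
    fold: float = 5.0,
    n_levels: int = 6,
    replicates: int | None = None,
    noise_sd: float | None = None,
) -> tuple[pd.DataFrame, CalibrationCurve]:
    """Calibrator titration Cq table plus the generating curve.

    Levels descend ``fold``-fold from ``top_copies`` (default 15,150 down
    to ~5 copies over 6 levels); each level gets ``replicates`` wells with
    Gaussian Cq noise (default 0.15 cycles, a clean calibrator run).
    """
    reps = replicates if replicates is not None else config.replicates
    sd = 0.15 if noise_sd is None else noise_sd
    rng = np.random.default_rng(config.seed)
    rows = []
    for i in range(n_levels):
        copies = top_copies / fold**i
        for rep in range(1, reps + 1):
            cq = config.curve.cq_at(copies) + rng.normal(0.0, sd)
            rows.append({"copies": copies, "replicate": rep, "cq": cq})
    return pd.DataFrame(rows), config.curve


def gen_ffpe_cohort(
    config: GeneratorConfig,
    *,
    qfi_percent: Sequence[float] | None = None,
) -> tuple[list[CqMeasurement], pd.DataFrame]:
    """FFPE cohort Cq measurements at known QFI plus the truth table.

    True QFI is drawn log-normal (median/sigma from the config, capped at
    100%) unless ``qfi_percent`` pins it per sample. True amplifiable
    copies are mass x 303 x QFI; the emitted Cq is the curve value plus
    noise. Samples whose true copies fall below the detection limit, or
    whose noisy Cq exceeds the cycle ceiling, are emitted UNDETECTED.
    """
    rng = np.random.default_rng(config.seed)
    if qfi_percent is None:
        qfi = np.minimum(
            rng.lognormal(math.log(config.qfi_median_percent),
                          config.qfi_log_sigma, size=config.n_samples),
            100.0,
        )
    else:
        qfi = np.asarray(qfi_percent, dtype=float)
    measurements, truth_rows = [], []
    for i, q in enumerate(qfi):
        sid = f"SYN{i:04d}"
        copies = config.input_mass_ng * COPIES_PER_NG * q / 100.0
        cq: float | None
        if copies < config.lod_copies:
            cq = UNDETECTED
        else:
            cq = config.curve.cq_at(copies) + rng.normal(0.0, config.noise_sd)
            if cq > config.max_cycles:
                cq = UNDETECTED
        measurements.append(
            CqMeasurement(
                sample_id=sid, target="TBP",
                input_mass_ng=config.input_mass_ng, replicate=1, cq=cq,
                max_cycles=config.max_cycles,
            )
        )
        truth_rows.append(
            {"sample_id": sid, "true_qfi_percent": float(q),
             "true_copies": float(copies)}
        )
    return measurements, pd.DataFrame(truth_rows)


def gen_dilution_readcounts(
    true_fraction: float,
    copy_levels: Sequence[float],
    depth: int | None,
    seed: int,
    *,
    replicates: int = 3,
    poisson_delivery: bool = True,
) -> pd.DataFrame:
    """Mutant read-count table across a template dilution series.

    Each copy level is simulated with the template-sampling model
    (independent sub-seeds per level); rows carry the observed mutant
    fraction per replicate and the generating truth. At infinite depth
    (``depth=None``) the observed fraction is the template fraction.
    """
    level_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1,
                                                       size=len(copy_levels))
    rows = []
    for copies, sub_seed in zip(copy_levels, level_seeds):
        out = simulate_mutant_fraction(
            SamplingModel(
                functional_copies=copies,
                mutant_fraction=true_fraction,
                read_depth=depth,
                replicates=replicates,
                poisson_delivery=poisson_delivery,
                seed=int(sub_seed),
            )
        )
        for rep, frac in enumerate(out.per_replicate_values, start=1):
            rows.append(
                {
                    "copies": copies,
                    "replicate": rep,
                    "observed_fraction": float(frac),
                    "mutant_reads": (
                        int(round(frac * depth))
                        if depth is not None and not math.isnan(frac) else None
                    ),
                    "total_reads": depth,
                    "true_fraction": true_fraction,
                    "dropout": math.isnan(frac),
                }
            )
    return pd.DataFrame(rows)


_BASES = ("A", "C", "G", "T")


def _positions_in_regions(
    regions: Sequence[Region], count: int, rng: np.random.Generator
) -> list[tuple[str, int]]:
    """Distinct (chrom, 1-based pos) sites drawn uniformly over regions."""
    lengths = [end - start for _, start, end in regions]
    total = sum(lengths)
    if count > total:
        raise ValueError("more sites requested than bases in the regions")
    flat = rng.choice(total, size=count, replace=False)
    offsets = np.cumsum([0] + lengths)
    sites = []
    for idx in flat:
        ri = int(np.searchsorted(offsets, idx, side="right")) - 1
        chrom, start, _ = regions[ri]
        sites.append((chrom, start + int(idx - offsets[ri]) + 1))
    return sites


def _artifact_af(
    n_functional: int, artifact: ArtifactModel, rng: np.random.Generator
) -> float:
    """Allele fraction of one *called* artifact site.

    Samples the lesioned-template count conditioned on the site being
    called, then the read fraction conditioned on crossing the threshold.
    """
    n = n_functional
    xs = np.arange(1, n + 1)
    weights = stats.binom.pmf(xs, n, artifact.lesion_rate_per_base)
    if artifact.read_depth is None:
        called = (xs / n >= artifact.af_call_threshold).astype(float)
    else:
        kmin = math.ceil(artifact.read_depth * artifact.af_call_threshold)
        called = stats.binom.sf(kmin - 1, artifact.read_depth, xs / n)
    w = weights * called
    if w.sum() <= 0:
        return artifact.af_call_threshold
    x = int(rng.choice(xs, p=w / w.sum()))
    if artifact.read_depth is None:
        return x / n
    d = artifact.read_depth
    kmin = math.ceil(d * artifact.af_call_threshold)
    ks = np.arange(kmin, d + 1)
    pk = stats.binom.pmf(ks, d, x / n)
    if pk.sum() <= 0:
        return kmin / d
    return int(rng.choice(ks, p=pk / pk.sum())) / d


def gen_variant_tables(
    truth: pd.DataFrame,
    regions: Sequence[Region],
    artifact: ArtifactModel,
    seed: int,
    *,
    input_mass_ng: float = 10.0,
    het_hom_ratio: float = 2.0,
) -> tuple[dict[str, list[VariantCall]], dict[str, list[VariantCall]],
           pd.DataFrame]:
    """Paired primary/confirmation variant tables with truth labels.

    ``truth`` needs columns ``sample_id`` and ``true_qfi_percent``. Per
    sample: germline SNPs (1 per 1,000 bases by default) appear in *both*
    panels with allele fractions near 0.5 (het) or 1.0 (hom) at a 2:1
    ratio; artifact calls appear only in the primary panel, with count and
    allele fraction driven by the sample's functional copy number through
    the lesion model, and 75% C>T/G>A by default. The returned label
    table marks every primary call TP (germline) or FP (artifact).
    """
    rng = np.random.default_rng(seed)
    primary: dict[str, list[VariantCall]] = {}
    confirmation: dict[str, list[VariantCall]] = {}
    labels = []
    p_het = het_hom_ratio / (het_hom_ratio + 1.0)
    for rec in truth.itertuples(index=False):
        sid = rec.sample_id
        qfi_frac = rec.true_qfi_percent / 100.0
        n_func = int(round(input_mass_ng * COPIES_PER_NG * qfi_frac))
        p_calls: list[VariantCall] = []
        c_calls: list[VariantCall] = []

        n_snp = rng.binomial(artifact.region_bp, artifact.germline_snp_rate)
        n_art = (
            rng.binomial(
                artifact.region_bp,
                artifact_site_call_probability(n_func, artifact),
            )
            if n_func > 0 else 0
        )
        sites = _positions_in_regions(regions, n_snp + n_art, rng)

        for chrom, pos in sites[:n_snp]:
            if rng.random() < p_het:
                af = float(np.clip(rng.normal(0.5, 0.03), 0.05, 0.95))
            else:
                af = float(np.clip(rng.normal(0.98, 0.01), 0.9, 1.0))
            ref = _BASES[rng.integers(4)]
            alt = rng.choice([b for b in _BASES if b != ref])
            p_calls.append(VariantCall(sid, chrom, pos, ref, alt, af))
            c_calls.append(
                VariantCall(sid, chrom, pos, ref, alt, af, panel="confirmation")
            )
            labels.append({"sample_id": sid, "chrom": chrom, "pos": pos,
                           "alt": alt, "label": "TP"})

        for chrom, pos in sites[n_snp:]:
            if rng.random() < artifact.transition_bias:
                ref, alt = ("C", "T") if rng.random() < 0.5 else ("G", "A")
            else:
                ref = _BASES[rng.integers(4)]
                alt = rng.choice(
                    [b for b in _BASES
                     if b != ref and (ref, b) not in {("C", "T"), ("G", "A")}]
                )
            af = _artifact_af(n_func, artifact, rng)
            p_calls.append(VariantCall(sid, chrom, pos, ref, alt, af))
            labels.append({"sample_id": sid, "chrom": chrom, "pos": pos,
                           "alt": alt, "label": "FP"})

        primary[sid] = p_calls
        confirmation[sid] = c_calls
    return primary, confirmation, pd.DataFrame(
        labels, columns=["sample_id", "chrom", "pos", "alt", "label"]
    )
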