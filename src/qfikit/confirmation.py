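"""Variant-confirmation audit: filter cascade, matching, tier statistics.

Primary-panel variant calls are pushed through a fixed cascade —

1. restrict to the genomic regions shared with the confirmation panel
   (indels excluded by default, since indel loci did not overlap),
2. remove known systematic artifact loci (a blacklist, e.g. recurrent
   PIK3CA positives seen in both high- and low-quality samples),
3. keep calls with allele fraction strictly above the reporting threshold
   (default >5%),
4. confirm each surviving call against an orthogonal panel by exact
   (chrom, pos, ref, alt) match —

yielding a per-sample ConfirmationRecord whose counts are monotone
non-increasing along the cascade. Tier summaries compare variant-count
burden between QFI tiers with Welch's unequal-variance t-test.

Coordinate conventions: variant positions are 1-based (VCF); regions are
half-open 0-based (BED). A variant at 1-based position p overlaps region
[start, end) iff start <= p-1 < end.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .planning import Tier, classify_tier

Region = tuple[str, int, int]  # (chrom, start, end), 0-based half-open
BlacklistEntry = tuple[str, int, str]  # (chrom, pos 1-based, alt)


@dataclass(frozen=True)
class VariantCall:
    """A single variant call with its allele fraction and source panel."""

    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    allele_fraction: float
    panel: str = "primary"  # "primary" or "confirmation"
    annotation: str = ""    # optional free text carried through

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError("pos must be >= 1 (1-based)")
        if not 0 <= self.allele_fraction <= 1:
            raise ValueError("allele_fraction must be in [0, 1]")
        if self.panel not in ("primary", "confirmation"):
            raise ValueError("panel must be 'primary' or 'confirmation'")

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class ConfirmationRecord:
    """Per-sample audit row: counts through each filter stage.

    ``true_positive_percent`` is 100 * confirmed / post-AF-filter calls
    (NaN when nothing survives the filters). ``n_unconfirmable`` counts
    post-filter calls whose allele fraction sits below the confirmation
    assay's analytical sensitivity — they can be neither confirmed nor
    refuted.
    """

    sample_id: str
    qfi_percent: float
    tier: Tier
    n_total: int
    n_overlap: int
    n_after_blacklist: int
    n_after_af_filter: int
    n_confirmed: int
    n_unconfirmable: int = 0

    def __post_init__(self):
        counts = (self.n_total, self.n_overlap, self.n_after_blacklist,
                  self.n_after_af_filter, self.n_confirmed)
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        if any(a < b for a, b in zip(counts, counts[1:])):
            raise ValueError(f"filter cascade counts must be non-increasing: {counts}")

    @property
    def true_positive_percent(self) -> float:
        if self.n_after_af_filter == 0:
            return math.nan
        return 100.0 * self.n_confirmed / self.n_after_af_filter


def _region_trees(regions: Iterable[Region]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in regions:
        if end <= start or start < 0:
            raise ValueError(f"malformed region {chrom}:{start}-{end}")
        trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def restrict_to_overlap(
    calls: Sequence[VariantCall],
    regions: Iterable[Region],
    *,
    include_indels: bool = False,
) -> list[VariantCall]:
    """Keep calls whose position falls inside the shared panel regions.

    Regions are 0-based half-open; a call exactly at a region end is
    excluded. Indels are dropped unless ``include_indels`` (the default
    mirrors a confirmation panel whose content shares no indel loci with
    the primary assay).
    """
    trees = _region_trees(regions)
    out = []
    for call in calls:
        if call.is_indel and not include_indels:
            continue
        tree = trees.get(call.chrom)
        if tree is not None and tree.overlaps_point(call.pos - 1):
            out.append(call)
    return out


def remove_systematic(
    calls: Sequence[VariantCall],
    blacklist: Iterable[BlacklistEntry],
) -> list[VariantCall]:
    """Drop calls at known systematic-artifact loci.

    Matching is allele-aware: a blacklist entry (chrom, pos, alt) removes
    only calls with that alternate allele at that position.
    """
    bl = set(blacklist)
    return [c for c in calls if (c.chrom, c.pos, c.alt) not in bl]


def filter_af(
    calls: Sequence[VariantCall],
    threshold: float = 0.05,
    *,
    strict: bool = True,
) -> list[VariantCall]:
    """Keep calls with allele fraction above the reporting threshold.

    Strict ``>`` by default (a call at exactly 5% is removed); set
    ``strict=False`` for ``>=``.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    if strict:
        return [c for c in calls if c.allele_fraction > threshold]
    return [c for c in calls if c.allele_fraction >= threshold]


def _dedup(calls: Sequence[VariantCall], label: str) -> list[VariantCall]:
    seen: dict[tuple, VariantCall] = {}
    dups = 0
    for c in calls:
        if c.key in seen:
            dups += 1
        else:
            seen[c.key] = c
    if dups:
        warnings.warn(f"{label}: removed {dups} duplicate call(s) at the same locus")
    return list(seen.values())


def confirm(
    primary_calls: Sequence[VariantCall],
    confirmation_calls: Sequence[VariantCall],
    confirmation_sensitivity: float = 0.04,
    *,
    sample_id: str | None = None,
    qfi_percent: float = math.nan,
    regions: Iterable[Region] | None = None,
    blacklist: Iterable[BlacklistEntry] = (),
    af_threshold: float = 0.05,
    include_indels: bool = False,
    tier_low_max: float = 3.0,
    tier_acceptable_min: float = 6.0,
) -> ConfirmationRecord:
    """Run the audit cascade for one sample and match against confirmation.

    A primary call is confirmed when the confirmation set contains an
    exact (chrom, pos, ref, alt) match. Post-filter calls whose allele
    fraction is below ``confirmation_sensitivity`` are tallied as
    unconfirmable. When ``regions`` is None the overlap stage is the
    identity (calls are assumed pre-restricted).
    """
    if sample_id is None:
        sample_id = primary_calls[0].sample_id if primary_calls else ""
    primary = _dedup(primary_calls, f"{sample_id} primary")
    confirmation = _dedup(confirmation_calls, f"{sample_id} confirmation")

    n_total = len(primary)
    overlap = (
        restrict_to_overlap(primary, regions, include_indels=include_indels)
        if regions is not None
        else list(primary)
    )
    after_bl = remove_systematic(overlap, blacklist)
    after_af = filter_af(after_bl, af_threshold)
    conf_keys = {c.key for c in confirmation}
    confirmed = [c for c in after_af if c.key in conf_keys]
    unconfirmable = [
        c for c in after_af if c.allele_fraction < confirmation_sensitivity
    ]
    tier = (
        classify_tier(qfi_percent, low_max=tier_low_max,
                      acceptable_min=tier_acceptable_min)
        if not math.isnan(qfi_percent)
        else Tier.LOW
    )
    return ConfirmationRecord(
        sample_id=sample_id,
        qfi_percent=qfi_percent,
        tier=tier,
        n_total=n_total,
        n_overlap=len(overlap),
        n_after_blacklist=len(after_bl),
        n_after_af_filter=len(after_af),
        n_confirmed=len(confirmed),
        n_unconfirmable=len(unconfirmable),
    )


@dataclass
class TierStats:
    tier: Tier
    n_samples: int
    mean_variants: float
    sd_variants: float
    pooled_confirmed: int
    pooled_overlap: int

    @property
    def pooled_confirmation_percent(self) -> float:
        if self.pooled_overlap == 0:
            return math.nan
        return 100.0 * self.pooled_confirmed / self.pooled_overlap


@dataclass
class TierSummary:
    per_tier: dict[Tier, TierStats]
    welch_t: float | None
    welch_p: float | None
    tested: bool
    note: str = ""


def tier_summary(
    records: Sequence[ConfirmationRecord],
    variant_counts: Mapping[str, int] | None = None,
) -> TierSummary:
    """Summarize variant burden and confirmation by QFI tier.

    ``variant_counts`` maps sample id to its total (unfiltered) variant
    count; defaults to each record's ``n_total``. Reports per-tier
    mean +/- SD of the counts and the pooled unfiltered confirmation rate
    (confirmed / overlapping calls), plus Welch's unequal-variance t-test
    between the low and acceptable tiers when both have at least two
    samples. A single contrast only; no multiplicity adjustment.
    """
    if not records:
        raise ValueError("no records to summarize")
    counts = {
        r.sample_id: (variant_counts[r.sample_id]
                      if variant_counts is not None else r.n_total)
        for r in records
    }
    per_tier: dict[Tier, TierStats] = {}
    for tier in Tier:
        rs = [r for r in records if r.tier == tier]
        if not rs:
            continue
        vals = np.array([counts[r.sample_id] for r in rs], dtype=float)
        per_tier[tier] = TierStats(
            tier=tier,
            n_samples=len(rs),
            mean_variants=float(vals.mean()),
            sd_variants=float(vals.std(ddof=1)) if len(rs) > 1 else 0.0,
            pooled_confirmed=sum(r.n_confirmed for r in rs),
            pooled_overlap=sum(r.n_overlap for r in rs),
        )
    low = per_tier.get(Tier.LOW)
    acc = per_tier.get(Tier.ACCEPTABLE)
    if low and acc and low.n_samples >= 2 and acc.n_samples >= 2:
        low_vals = [counts[r.sample_id] for r in records if r.tier == Tier.LOW]
        acc_vals = [counts[r.sample_id] for r in records if r.tier == Tier.ACCEPTABLE]
        if np.var(low_vals) == 0 and np.var(acc_vals) == 0:
            # degenerate zero-variance groups: no evidence either way
            equal = float(np.mean(low_vals)) == float(np.mean(acc_vals))
            t, p = (0.0, 1.0) if equal else (math.inf, 0.0)
        else:
            t, p = stats.ttest_ind(low_vals, acc_vals, equal_var=False)
        return TierSummary(per_tier=per_tier, welch_t=float(t), welch_p=float(p),
                           tested=True)
    return TierSummary(
        per_tier=per_tier, welch_t=None, welch_p=None, tested=False,
        note="low/acceptable contrast skipped: fewer than 2 samples in a tier",
    )


def expected_snp_count(region_bp: int, snp_rate: float = 1e-3) -> float:
    """Expected germline SNPs in a panel footprint (1 per 1,000 bases).

    A 13 kb panel is expected to show ~13 SNPs per sample; a large excess
    of calls over this baseline indicates artifact inflation.
    """
    if region_bp < 0:
        raise ValueError("region_bp must be non-negative")
    if not 0 <= snp_rate <= 1:
        raise ValueError("snp_rate must be in [0, 1]")
    return region_bp * snp_rate


def transition_fraction(calls: Sequence[VariantCall]) -> float:
    """Fraction of SNV calls that are C>T or G>A transitions.

    Cytosine-deamination artifacts are overwhelmingly C>T (G>A on the
    opposite strand), so this fraction fingerprints FFPE damage. Indels
    are skipped; an input with no SNVs returns NaN with a warning.
    """
    snvs = [c for c in calls if not c.is_indel]
    if not snvs:
        warnings.warn("transition_fraction: no SNV calls; returning NaN")
        return math.nan
    hits = sum(
        1 for c in snvs
        if (c.ref.upper(), c.alt.upper()) in {("C", "T"), ("G", "A")}
    )
    return hits / len(snvs)
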