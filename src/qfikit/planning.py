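"""Library-complexity input planning from QFI and assay sensitivity.

Accurate NGS quantification of a mutation present in a fraction %M of
templates needs a minimum number of *mutant* template molecules in the
enrichment reaction (default 10, to tame stochastic sampling). Working
backwards: 10/%M functional templates are needed in total, and since only
a QFI fraction of an FFPE sample's nominal copies are functional, the bulk
DNA mass to load is

    bulk_ng = min_mutant_copies / (303 * QFI * %M)

with QFI and %M as fractions and 303 haploid copies per ng. Halving the
QFI exactly doubles the required input. This module exposes each step of
that calculation plus a tiered pass / rescue / fail decision for a sample
with a known amount of DNA available.

All functions take QFI and mutant fraction as *fractions* (0-1); only the
``qfi_percent``/tier surfaces use percent. This single internal convention
prevents 100x unit errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

from .config import COPIES_PER_NG
from .qpcr import QfiResult


class Tier(str, Enum):
    """QFI quality band around the 3-6% accuracy threshold."""

    LOW = "low"
    BORDERLINE = "borderline"
    ACCEPTABLE = "acceptable"


class Decision(str, Enum):
    PASS = "pass"
    RESCUE = "rescue_increase_input"
    FAIL = "fail"


class UnplannableError(ValueError):
    """Raised when a plan is requested for a sample with no functional DNA."""


@dataclass(frozen=True)
class AssayRequirement:
    """Sensitivity requirement of a downstream targeted assay.

    ``target_mutant_fraction`` is the lowest mutant allele fraction the
    assay must quantify reliably; ``min_mutant_copies`` is the mutant
    template floor deemed necessary for that (a chosen value, not a law).
    """

    target_mutant_fraction: float
    min_mutant_copies: float = 10.0
    default_bulk_input_ng: float = 10.0

    def __post_init__(self):
        if not 0 < self.target_mutant_fraction <= 1:
            raise ValueError("target_mutant_fraction must be in (0, 1]")
        if self.min_mutant_copies < 1:
            raise ValueError("min_mutant_copies must be >= 1")
        if self.default_bulk_input_ng <= 0:
            raise ValueError("default_bulk_input_ng must be positive")


@dataclass
class InputPlan:
    """Copy and mass requirements plus the pass/rescue/fail decision."""

    sample_id: str
    qfi_percent: float
    tier: Tier
    required_functional_copies_unadjusted: float
    required_functional_copies: float  # nominal copies after QFI adjustment
    required_bulk_ng: float
    functional_copies_at_default_input: float
    min_detectable_fraction_at_default: float
    decision: Decision
    reason: str = ""


def required_copies(req: AssayRequirement) -> float:
    """Functional templates needed: min_mutant_copies / target fraction.

    E.g. 10 mutant copies at a 30% mutation demand 33.3 functional copies.
    """
    return req.min_mutant_copies / req.target_mutant_fraction


def adjust_for_qfi(copies: float, qfi_fraction: float) -> float:
    """Scale a functional-copy requirement up to nominal copies at a QFI.

    33.3 functional copies at QFI 9% require 33.3/0.09 = 370 nominal
    copies of the sample. Identity at QFI 1.0.
    """
    if not 0 < qfi_fraction <= 1:
        raise UnplannableError(f"qfi_fraction must be in (0, 1], got {qfi_fraction}")
    return copies / qfi_fraction


def bulk_input_ng(
    qfi_fraction: float,
    req: AssayRequirement,
    copies_per_ng: float = COPIES_PER_NG,
) -> float:
    """Bulk DNA mass delivering enough mutant templates at a given QFI.

    bulk_ng = min_mutant_copies / (303 * QFI * %M). At QFI 6.6% a 5%
    mutation needs 10 ng; at QFI 3.3% it needs 20 ng.
    """
    if not 0 < qfi_fraction <= 1:
        raise UnplannableError(f"qfi_fraction must be in (0, 1], got {qfi_fraction}")
    return req.min_mutant_copies / (
        copies_per_ng * qfi_fraction * req.target_mutant_fraction
    )


def functional_copies_at_input(
    mass_ng: float,
    qfi_fraction: float,
    copies_per_ng: float = COPIES_PER_NG,
) -> float:
    """Amplifiable templates delivered by a bulk mass: mass * 303 * QFI.

    10 ng at QFI 1.2% carries only 0.012 * 3,030 = 36 functional copies.
    """
    if mass_ng < 0:
        raise ValueError("mass_ng must be non-negative")
    if not 0 <= qfi_fraction <= 1:
        raise ValueError("qfi_fraction must be in [0, 1]")
    return mass_ng * copies_per_ng * qfi_fraction


def min_detectable_fraction(
    functional_copies: float, min_mutant_copies: float = 10.0
) -> float:
    """Smallest reliably quantifiable mutant fraction given the templates.

    min_mutant_copies / functional_copies, capped at 1.0 (a sample with 36
    functional copies cannot reliably quantify anything below 27.8%).
    """
    if functional_copies <= 0:
        raise UnplannableError("no functional copies: nothing is detectable")
    return min(1.0, min_mutant_copies / functional_copies)


def classify_tier(
    qfi_percent: float,
    *,
    low_max: float = 3.0,
    acceptable_min: float = 6.0,
) -> Tier:
    """QFI tier: low below 3%, borderline in [3%, 6%], acceptable above 6%.

    The 3-6% band is where false-positive inflation sets in; both
    thresholds are overridable.
    """
    if qfi_percent < 0:
        raise ValueError("qfi_percent must be non-negative")
    if low_max > acceptable_min:
        raise ValueError("tier thresholds out of order")
    if qfi_percent < low_max:
        return Tier.LOW
    if qfi_percent <= acceptable_min:
        return Tier.BORDERLINE
    return Tier.ACCEPTABLE


def plan(
    qfi: QfiResult,
    req: AssayRequirement,
    available_ng: float,
    *,
    copies_per_ng: float = COPIES_PER_NG,
    tier_low_max: float = 3.0,
    tier_acceptable_min: float = 6.0,
) -> InputPlan:
    """Full input plan for one sample: requirements, tier and decision.

    ``pass`` when the assay's default input already supplies the required
    mutant templates; ``rescue_increase_input`` when a larger input within
    ``available_ng`` would; ``fail`` otherwise, or when the sample is
    undetected or inhibited. Degenerate inputs produce fail decisions with
    a reason, never exceptions.
    """
    tier = classify_tier(
        max(qfi.qfi_percent, 0.0),
        low_max=tier_low_max,
        acceptable_min=tier_acceptable_min,
    )
    unadjusted = required_copies(req)
    qfi_fraction = qfi.qfi_percent / 100.0

    def failed(reason: str) -> InputPlan:
        return InputPlan(
            sample_id=qfi.sample_id,
            qfi_percent=qfi.qfi_percent,
            tier=tier,
            required_functional_copies_unadjusted=unadjusted,
            required_functional_copies=math.inf,
            required_bulk_ng=math.inf,
            functional_copies_at_default_input=0.0,
            min_detectable_fraction_at_default=1.0,
            decision=Decision.FAIL,
            reason=reason,
        )

    if not qfi.detected or qfi_fraction <= 0:
        return failed("no amplifiable template detected")
    if qfi.inhibited:
        return failed("PCR inhibition detected; QFI unreliable")

    qfi_fraction = min(qfi_fraction, 1.0)
    adjusted = adjust_for_qfi(unadjusted, qfi_fraction)
    bulk = bulk_input_ng(qfi_fraction, req, copies_per_ng)
    at_default = functional_copies_at_input(
        req.default_bulk_input_ng, qfi_fraction, copies_per_ng
    )
    if bulk <= req.default_bulk_input_ng:
        decision, reason = Decision.PASS, "default input is sufficient"
    elif bulk <= available_ng:
        decision, reason = Decision.RESCUE, (
            f"increase input to {bulk:.1f} ng to restore library complexity"
        )
    else:
        decision, reason = Decision.FAIL, (
            f"requires {bulk:.1f} ng but only {available_ng:.1f} ng available"
        )
    return InputPlan(
        sample_id=qfi.sample_id,
        qfi_percent=qfi.qfi_percent,
        tier=tier,
        required_functional_copies_unadjusted=unadjusted,
        required_functional_copies=adjusted,
        required_bulk_ng=bulk,
        functional_copies_at_default_input=at_default,
        min_detectable_fraction_at_default=min_detectable_fraction(
            at_default, req.min_mutant_copies
        ),
        decision=decision,
        reason=reason,
    )
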