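"""qPCR standard-curve calibration and amplifiable-copy quantification.

Formalin fixation fragments and chemically modifies DNA, so only a fraction
of the genome copies in an FFPE extract can actually serve as PCR templates.
This module quantifies that *functional* fraction: a calibration curve is
fitted to a titration of high-quality genomic DNA (Cq against log10 copies),
sample Cq values are inverted through the curve to absolute amplifiable copy
numbers, and the Quantitative Functional Index (QFI) expresses those copies
as a percentage of the nominal haploid copies loaded (303 copies per ng).

An undetected Cq (no amplification within the cycle ceiling, default 50) is
a first-class value, represented as ``None``: it maps to 0 copies, QFI 0%,
``detected=False`` — never an exception.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .config import COPIES_PER_NG

#: Sentinel for a Cq that never crossed threshold within ``max_cycles``.
UNDETECTED = None

#: Slope (cycles per log10 copies) of a perfectly efficient PCR:
#: a doubling per cycle means -1/log10(2).
PERFECT_SLOPE = -1.0 / math.log10(2.0)


class InsufficientDataError(ValueError):
    """Raised when a calibration has fewer than three distinct copy levels."""


class DegenerateCurveError(ValueError):
    """Raised when the fitted slope is non-negative (miscalibrated input)."""


@dataclass(frozen=True)
class CqMeasurement:
    """One qPCR well: a sample, a target assay and a quantification cycle.

    ``cq`` is ``None`` when the well never crossed threshold (UNDETECTED).
    """

    sample_id: str
    target: str  # "TBP", "FTH1", "SPUD", or another assay name
    input_mass_ng: float
    replicate: int = 1
    cq: float | None = None
    max_cycles: float = 50.0

    def __post_init__(self):
        if self.input_mass_ng <= 0:
            raise ValueError("input_mass_ng must be positive")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")
        if self.cq is not None and not (0 < self.cq <= self.max_cycles):
            raise ValueError(
                f"cq {self.cq} outside (0, {self.max_cycles}]; "
                "use cq=None for an undetected well"
            )

    @property
    def detected(self) -> bool:
        return self.cq is not None


@dataclass
class CalibrationCurve:
    """Least-squares line Cq = intercept + slope * log10(copies).

    ``efficiency_percent`` is the per-cycle amplification gain derived from
    the slope, E = (10^(-1/slope) - 1) * 100; a slope of -3.3219 (one
    doubling per cycle) is 100%. ``lod_copies``/``loq_copies`` are the
    limits of detection and quantification in template copies.
    """

    slope: float
    intercept: float
    r_squared: float
    efficiency_percent: float
    copy_range: tuple[float, float] = (5.0, 15150.0)
    lod_copies: float = 5.0
    loq_copies: float = 10.0

    def __post_init__(self):
        if self.slope >= 0:
            raise DegenerateCurveError(f"slope must be negative, got {self.slope}")
        if self.lod_copies > self.loq_copies:
            raise ValueError("lod_copies must not exceed loq_copies")

    def in_range(self, copies: float) -> bool:
        lo, hi = self.copy_range
        return lo <= copies <= hi

    def cq_at(self, copies: float) -> float:
        """Predicted Cq at a given copy number (inverse of estimate_copies)."""
        if copies <= 0:
            raise ValueError("copies must be positive")
        return self.intercept + self.slope * math.log10(copies)


@dataclass
class QfiResult:
    """Per-sample amplifiable-copy estimate and Quantitative Functional Index.

    ``qfi_percent`` is 100 x estimated amplifiable copies over the nominal
    haploid copies loaded (input mass x 303/ng). A fully functional,
    high-quality DNA therefore scores ~100%.
    """

    sample_id: str
    estimated_copies: float
    nominal_copies: float
    qfi_percent: float
    detected: bool
    below_loq: bool
    inhibited: bool | None = None  # None = inhibition status unknown
    extrapolated: bool = False     # copy estimate outside the fitted titration


def efficiency_from_slope(slope: float) -> float:
    """Amplification efficiency (%) from a standard-curve slope.

    E = (10^(-1/slope) - 1) * 100. A slope of -3.3219 gives 100%; the
    efficiency tends to 0% as the slope steepens toward -infinity.
    """
    if slope >= 0:
        raise DegenerateCurveError("efficiency undefined for non-negative slope")
    return (10.0 ** (-1.0 / slope) - 1.0) * 100.0


def fit_calibration(
    points: Iterable[tuple[float, float]],
    *,
    lod_copies: float = 5.0,
    loq_copies: float = 10.0,
) -> CalibrationCurve:
    """Fit the calibrator standard curve by OLS of Cq on log10(copies).

    Replicates enter as individual points, not level means. Requires at
    least three distinct copy levels; a non-negative fitted slope (more
    template amplifying *later*) signals miscalibrated input and raises
    :class:`DegenerateCurveError`.

    Parameters
    ----------
    points
        Iterable of ``(copies, cq)`` pairs from the calibrator titration
        (canonically a 5-fold series from 15,150 down to 5 copies).
    lod_copies, loq_copies
        Detection/quantification limits to record on the curve; override
        with :func:`determine_loq` output when replicate data are available.
    """
    pts = [(float(c), float(q)) for c, q in points]
    if any(c <= 0 for c, _ in pts):
        raise ValueError("all copy levels must be positive")
    if any(q is None or not math.isfinite(q) for _, q in pts):
        raise ValueError("all calibration Cq values must be present and finite")
    levels = {c for c, _ in pts}
    if len(levels) < 3:
        raise InsufficientDataError(
            f"need >= 3 distinct copy levels, got {len(levels)}"
        )
    log_copies = np.log10([c for c, _ in pts])
    cqs = np.array([q for _, q in pts])
    fit = stats.linregress(log_copies, cqs)
    if fit.slope >= 0:
        raise DegenerateCurveError(
            f"fitted slope {fit.slope:.4g} is non-negative; "
            "check the titration orientation"
        )
    return CalibrationCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        efficiency_percent=efficiency_from_slope(float(fit.slope)),
        copy_range=(min(levels), max(levels)),
        lod_copies=lod_copies,
        loq_copies=loq_copies,
    )


def estimate_copies(curve: CalibrationCurve, cq: float | None) -> float:
    """Invert the standard curve: absolute amplifiable copies from a Cq.

    Returns ``10^((cq - intercept)/slope)``; strictly decreasing in Cq.
    An UNDETECTED Cq (``None``) returns 0.0 — the sample simply has no
    amplifiable template at the assay's sensitivity. Values outside the
    fitted titration range are still returned; use ``curve.in_range`` (or
    the ``extrapolated`` flag set by :func:`compute_qfi`) to detect them.
    """
    if cq is UNDETECTED:
        return 0.0
    return 10.0 ** ((float(cq) - curve.intercept) / curve.slope)


def mass_to_copies(mass_ng: float, copies_per_ng: float = COPIES_PER_NG) -> float:
    """Nominal haploid genome copies in a DNA mass (303 copies per ng).

    Real-valued; rounding for display is the caller's decision.
    """
    if mass_ng < 0:
        raise ValueError("mass_ng must be non-negative")
    return mass_ng * copies_per_ng


def compute_qfi(
    estimated_copies: float,
    input_mass_ng: float,
    *,
    sample_id: str = "",
    curve: CalibrationCurve | None = None,
    inhibited: bool | None = None,
    copies_per_ng: float = COPIES_PER_NG,
) -> QfiResult:
    """Quantitative Functional Index from an amplifiable-copy estimate.

    QFI (%) = 100 x estimated_copies / (input_mass_ng x 303). An estimate
    of 0 copies means the sample was undetected (QFI 0, detected=False).
    """
    if input_mass_ng <= 0:
        raise ValueError("input_mass_ng must be positive")
    if estimated_copies < 0:
        raise ValueError("estimated_copies must be non-negative")
    nominal = mass_to_copies(input_mass_ng, copies_per_ng)
    detected = estimated_copies > 0
    qfi = 100.0 * estimated_copies / nominal if detected else 0.0
    loq = curve.loq_copies if curve is not None else 10.0
    return QfiResult(
        sample_id=sample_id,
        estimated_copies=float(estimated_copies),
        nominal_copies=nominal,
        qfi_percent=qfi,
        detected=detected,
        below_loq=detected and estimated_copies < loq,
        inhibited=inhibited,
        extrapolated=(
            detected and curve is not None and not curve.in_range(estimated_copies)
        ),
    )


def determine_loq(
    replicate_cq_by_level: Mapping[float, Sequence[float | None]],
    *,
    sd_threshold: float = 0.5,
) -> float | None:
    """Limit of quantification from replicate Cq variability.

    The LOQ is the smallest copy level that is quantifiable — replicate Cq
    standard deviation below ``sd_threshold`` cycles with every replicate
    detected — such that all larger levels are quantifiable too (variability
    is expected to grow as template runs out, but a noisy intermediate level
    must not be skipped over). Returns ``None`` when no level qualifies
    ("not quantifiable").
    """
    loq: float | None = None
    for level in sorted(replicate_cq_by_level, reverse=True):
        cqs = replicate_cq_by_level[level]
        if len(cqs) < 2:
            raise ValueError(f"level {level}: need >= 2 replicates")
        if any(c is UNDETECTED for c in cqs):
            break
        sd = float(np.std(np.asarray(cqs, dtype=float), ddof=1))
        if sd < sd_threshold:
            loq = float(level)
        else:
            break
    return loq


@dataclass(frozen=True)
class InhibitionCheck:
    """Outcome of a SPUD exogenous-spike inhibition check; truthy if inhibited."""

    inhibited: bool
    total_inhibition: bool
    delta_cq: float | None

    def __bool__(self) -> bool:
        return self.inhibited


def check_inhibition(
    sample_spud_cq: float | None,
    control_spud_cq: float,
    threshold_cycles: float = 1.0,
) -> InhibitionCheck:
    """Flag PCR inhibition from a SPUD assay Cq shift.

    The SPUD amplicon (a potato sequence with no human homology) is spiked
    into the sample; inhibitors delay its Cq relative to a clean control.
    A shift >= ``threshold_cycles`` (default 1 cycle) is flagged; an
    undetected SPUD Cq means total inhibition.
    """
    if sample_spud_cq is UNDETECTED:
        return InhibitionCheck(inhibited=True, total_inhibition=True, delta_cq=None)
    delta = float(sample_spud_cq) - float(control_spud_cq)
    return InhibitionCheck(
        inhibited=delta >= threshold_cycles, total_inhibition=False, delta_cq=delta
    )


def relative_dye_quant(
    measured_ng: float,
    nominal_ng: float,
    *,
    floor_ng: float = 0.1,
) -> float | None:
    """Dye-based (fluorometric) quantification relative to the nominal mass.

    Returns 100 x measured/nominal, or ``None`` ("undetected") when the
    measurement sits below the instrument floor (default 0.1 ng/ul
    equivalent). Used only to compare an orthogonal quantification method
    against nominal spectrophotometric mass.
    """
    if nominal_ng <= 0:
        raise ValueError("nominal_ng must be positive")
    if measured_ng < 0:
        raise ValueError("measured_ng must be non-negative")
    if measured_ng < floor_ng:
        return None
    return 100.0 * measured_ng / nominal_ng


def quantify_samples(
    measurements: Iterable[CqMeasurement],
    curve: CalibrationCurve,
    *,
    target_priority: Sequence[str] = ("TBP", "FTH1"),
    combine: str = "priority",
    spud_control_cq: float | None = None,
    inhibition_threshold: float = 1.0,
) -> list[QfiResult]:
    """Convert a table of sample Cq measurements into per-sample QFI results.

    Per sample and target, replicate Cq values are inverted through the
    curve individually and the copy estimates averaged (undetected
    replicates contribute 0 copies). When multiple reference targets are
    present the first in ``target_priority`` is reported
    (``combine="priority"``, the default) or their copy estimates averaged
    (``combine="average"``). SPUD wells are consumed for inhibition
    checking when ``spud_control_cq`` is given, never for quantification.
    """
    if combine not in ("priority", "average"):
        raise ValueError("combine must be 'priority' or 'average'")
    by_sample: dict[str, dict[str, list[CqMeasurement]]] = {}
    for m in measurements:
        by_sample.setdefault(m.sample_id, {}).setdefault(m.target, []).append(m)

    results = []
    for sample_id, by_target in by_sample.items():
        inhibited: bool | None = None
        spud = by_target.pop("SPUD", [])
        if spud and spud_control_cq is not None:
            checks = [
                check_inhibition(m.cq, spud_control_cq, inhibition_threshold)
                for m in spud
            ]
            inhibited = any(c.inhibited for c in checks)

        usable = [t for t in target_priority if t in by_target]
        if not usable:
            usable = sorted(by_target)
        if not usable:
            continue
        if combine == "priority":
            usable = usable[:1]

        per_target_copies, masses = [], []
        for target in usable:
            wells = by_target[target]
            copies = [estimate_copies(curve, m.cq) for m in wells]
            per_target_copies.append(float(np.mean(copies)))
            masses.extend(m.input_mass_ng for m in wells)
        if len(set(masses)) > 1:
            warnings.warn(
                f"{sample_id}: mixed input masses across wells; using the mean"
            )
        results.append(
            compute_qfi(
                float(np.mean(per_target_copies)),
                float(np.mean(masses)),
                sample_id=sample_id,
                curve=curve,
                inhibited=inhibited,
            )
        )
    return results
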