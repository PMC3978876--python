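"""Aggregate run report: per-sample QC verdicts plus summary statistics.

Combines QFI results, input plans, confirmation records and simulation
outcomes into one JSON-serializable document (schema version 1) and a
human-readable text rendering. Sample ids must reconcile across sections;
orphans raise :class:`ReportError` listing them.
"""

from __future__ import annotations

import json
import math
from typing import Mapping, Sequence

from .config import RunConfig
from .confirmation import ConfirmationRecord, TierSummary
from .planning import Decision, InputPlan
from .qpcr import QfiResult
from .simulate import SimOutcome

SCHEMA_VERSION = 1


class ReportError(ValueError):
    """Raised for empty reports or irreconcilable sample ids."""


def _check_ids(base: set[str], other: Sequence[str], section: str) -> None:
    orphans = sorted(set(other) - base)
    if orphans:
        raise ReportError(
            f"{section} contains sample ids absent from the QFI results: {orphans}"
        )


def run_report(
    qfi_results: Sequence[QfiResult] | None = None,
    plans: Sequence[InputPlan] | None = None,
    confirmation_records: Sequence[ConfirmationRecord] | None = None,
    tier_stats: TierSummary | None = None,
    sim_outcomes: Mapping[str, SimOutcome] | None = None,
    config: RunConfig | None = None,
) -> dict:
    """Build the report document; at least one input section is required."""
    if not any([qfi_results, plans, confirmation_records, sim_outcomes]):
        raise ReportError("nothing to report: all input sections are empty")
    config = config or RunConfig()

    samples: dict[str, dict] = {}
    if qfi_results:
        for r in qfi_results:
            samples[r.sample_id] = {
                "qfi_percent": r.qfi_percent,
                "estimated_copies": r.estimated_copies,
                "detected": r.detected,
                "below_loq": r.below_loq,
                "inhibited": r.inhibited,
            }
    base_ids = set(samples)
    if plans:
        if base_ids:
            _check_ids(base_ids, [p.sample_id for p in plans], "plans")
        for p in plans:
            samples.setdefault(p.sample_id, {}).update(
                {
                    "tier": p.tier.value,
                    "decision": p.decision.value,
                    "required_bulk_ng": (
                        None if math.isinf(p.required_bulk_ng)
                        else p.required_bulk_ng
                    ),
                    "reason": p.reason,
                }
            )
    if confirmation_records:
        if base_ids:
            _check_ids(
                base_ids, [r.sample_id for r in confirmation_records], "confirmation"
            )
        for r in confirmation_records:
            tp = r.true_positive_percent
            samples.setdefault(r.sample_id, {}).update(
                {
                    "tier": r.tier.value,
                    "confirmation": {
                        "n_total": r.n_total,
                        "n_overlap": r.n_overlap,
                        "n_after_blacklist": r.n_after_blacklist,
                        "n_after_af_filter": r.n_after_af_filter,
                        "n_confirmed": r.n_confirmed,
                        "true_positive_percent": None if math.isnan(tp) else tp,
                    },
                }
            )

    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "constants": config.to_dict(),
        "samples": samples,
    }
    if tier_stats is not None:
        report["tier_summary"] = {
            "per_tier": {
                tier.value: {
                    "n_samples": s.n_samples,
                    "mean_variants": s.mean_variants,
                    "sd_variants": s.sd_variants,
                    "pooled_confirmation_percent": (
                        None if math.isnan(s.pooled_confirmation_percent)
                        else s.pooled_confirmation_percent
                    ),
                }
                for tier, s in tier_stats.per_tier.items()
            },
            "welch_t": tier_stats.welch_t,
            "welch_p": tier_stats.welch_p,
        }
    if sim_outcomes:
        report["simulations"] = {
            name: {
                "mean_observed_fraction": _nan_none(o.mean_observed_fraction),
                "cv_percent": _nan_none(o.cv_percent),
                "false_negative_rate": _nan_none(o.false_negative_rate),
                "expected_variant_calls": _nan_none(o.expected_variant_calls),
            }
            for name, o in sim_outcomes.items()
        }
    report["any_fail"] = any(
        s.get("decision") == Decision.FAIL.value
        or (s.get("detected") is False)
        for s in samples.values()
    )
    return report


def _nan_none(x: float) -> float | None:
    return None if x is None or math.isnan(x) else x


def render_report(report: dict) -> str:
    """Human-readable text rendering of the report document."""
    lines = [f"qfikit report (schema v{report['schema_version']})", ""]
    samples = report.get("samples", {})
    if samples:
        lines.append(f"{'sample':<12} {'QFI%':>7} {'tier':>11} {'decision':>22}")
        for sid in sorted(samples):
            s = samples[sid]
            qfi = s.get("qfi_percent")
            qfi_txt = f"{qfi:.2f}" if qfi is not None else "-"
            lines.append(
                f"{sid:<12} {qfi_txt:>7} {s.get('tier', '-'):>11} "
                f"{s.get('decision', '-'):>22}"
            )
    ts = report.get("tier_summary")
    if ts:
        lines.append("")
        lines.append("tier summary:")
        for tier, s in ts["per_tier"].items():
            pooled = s["pooled_confirmation_percent"]
            pooled_txt = f"{pooled:.1f}%" if pooled is not None else "n/a"
            lines.append(
                f"  {tier:<11} n={s['n_samples']:<3} "
                f"variants {s['mean_variants']:.1f} ± {s['sd_variants']:.1f}  "
                f"pooled confirmation {pooled_txt}"
            )
        if ts.get("welch_p") is not None:
            lines.append(
                f"  low vs acceptable (Welch): t={ts['welch_t']:.3f}, "
                f"p={ts['welch_p']:.4g}"
            )
    lines.append("")
    lines.append("QC status: " + ("FAIL" if report.get("any_fail") else "PASS"))
    return "\n".join(lines) + "\n"


def write_report(report: dict, path) -> None:
    from pathlib import Path

    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
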