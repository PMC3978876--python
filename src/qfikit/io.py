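"""Readers and writers for the pipeline's tabular and genomic formats.

Cq tables, QFI results and variant tables travel as delimited text
(CSV/TSV); calibration curves as JSON; panel regions as BED (0-based
half-open); variant calls additionally as minimal VCF with the allele
fraction in INFO/AF (read through cyvcf2). Instrument-export quirks are
handled with explicit dialect options (e.g. comma decimals, off by
default); the strings ``Undetermined``, ``undetected`` and an empty cell
all denote an undetected Cq.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .confirmation import BlacklistEntry, ConfirmationRecord, Region, VariantCall
from .qpcr import UNDETECTED, CalibrationCurve, CqMeasurement, QfiResult

_UNDETECTED_TOKENS = {"", "undetermined", "undetected", "na", "nan", "n/a"}


# ---------------------------------------------------------------- Cq tables

def read_cq_csv(
    path: str | Path,
    *,
    sep: str = ",",
    decimal: str = ".",
    max_cycles: float = 50.0,
) -> list[CqMeasurement]:
    """Load Cq measurements from a delimited table.

    Required columns: sample_id, target, input_mass_ng, replicate, cq.
    Set ``decimal=","`` for instrument exports using comma decimals.
    """
    df = pd.read_csv(path, sep=sep, decimal=decimal, dtype={"cq": str})
    required = {"sample_id", "target", "input_mass_ng", "replicate", "cq"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        raw = "" if row.cq is None or (isinstance(row.cq, float) and
                                       math.isnan(row.cq)) else str(row.cq).strip()
        if raw.lower() in _UNDETECTED_TOKENS:
            cq = UNDETECTED
        else:
            cq = float(raw.replace(",", ".") if decimal == "," else raw)
        out.append(
            CqMeasurement(
                sample_id=str(row.sample_id),
                target=str(row.target),
                input_mass_ng=float(row.input_mass_ng),
                replicate=int(row.replicate),
                cq=cq,
                max_cycles=max_cycles,
            )
        )
    return out


def write_cq_csv(measurements: Iterable[CqMeasurement], path: str | Path) -> None:
    rows = [
        {
            "sample_id": m.sample_id,
            "target": m.target,
            "input_mass_ng": m.input_mass_ng,
            "replicate": m.replicate,
            "cq": "Undetermined" if m.cq is UNDETECTED else m.cq,
        }
        for m in measurements
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# --------------------------------------------------------- calibration JSON

def write_curve_json(curve: CalibrationCurve, path: str | Path) -> None:
    doc = {
        "slope": curve.slope,
        "intercept": curve.intercept,
        "r_squared": curve.r_squared,
        "efficiency_percent": curve.efficiency_percent,
        "copy_range": list(curve.copy_range),
        "lod_copies": curve.lod_copies,
        "loq_copies": curve.loq_copies,
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_curve_json(path: str | Path) -> CalibrationCurve:
    doc = json.loads(Path(path).read_text())
    return CalibrationCurve(
        slope=doc["slope"],
        intercept=doc["intercept"],
        r_squared=doc["r_squared"],
        efficiency_percent=doc["efficiency_percent"],
        copy_range=tuple(doc.get("copy_range", (5.0, 15150.0))),
        lod_copies=doc.get("lod_copies", 5.0),
        loq_copies=doc.get("loq_copies", 10.0),
    )


# -------------------------------------------------------------- QFI tables

def write_qfi_csv(results: Iterable[QfiResult], path: str | Path) -> None:
    rows = [
        {
            "sample_id": r.sample_id,
            "estimated_copies": r.estimated_copies,
            "nominal_copies": r.nominal_copies,
            "qfi_percent": r.qfi_percent,
            "detected": r.detected,
            "below_loq": r.below_loq,
            "inhibited": "" if r.inhibited is None else r.inhibited,
            "extrapolated": r.extrapolated,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_qfi_csv(path: str | Path) -> list[QfiResult]:
    df = pd.read_csv(path)
    out = []
    for row in df.itertuples(index=False):
        inhibited = getattr(row, "inhibited", None)
        if inhibited is None or (isinstance(inhibited, float) and math.isnan(inhibited)):
            inhibited = None
        elif isinstance(inhibited, str):
            inhibited = inhibited.strip().lower() == "true"
        else:
            inhibited = bool(inhibited)
        out.append(
            QfiResult(
                sample_id=str(row.sample_id),
                estimated_copies=float(row.estimated_copies),
                nominal_copies=float(row.nominal_copies),
                qfi_percent=float(row.qfi_percent),
                detected=bool(row.detected),
                below_loq=bool(row.below_loq),
                inhibited=inhibited,
                extrapolated=bool(getattr(row, "extrapolated", False)),
            )
        )
    return out


# ---------------------------------------------------------- variant tables

def read_variant_table(
    path: str | Path, *, panel: str = "primary", sep: str = "\t"
) -> list[VariantCall]:
    """TSV dialect: columns sample_id, chrom, pos, ref, alt, af."""
    df = pd.read_csv(path, sep=sep)
    required = {"sample_id", "chrom", "pos", "ref", "alt", "af"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        VariantCall(
            sample_id=str(r.sample_id),
            chrom=str(r.chrom),
            pos=int(r.pos),
            ref=str(r.ref),
            alt=str(r.alt),
            allele_fraction=float(r.af),
            panel=panel,
        )
        for r in df.itertuples(index=False)
    ]


def write_variant_table(
    calls: Iterable[VariantCall], path: str | Path, *, sep: str = "\t"
) -> None:
    rows = [
        {
            "sample_id": c.sample_id,
            "chrom": c.chrom,
            "pos": c.pos,
            "ref": c.ref,
            "alt": c.alt,
            "af": c.allele_fraction,
        }
        for c in calls
    ]
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def read_vcf(
    path: str | Path, *, sample_id: str | None = None, panel: str = "primary"
) -> list[VariantCall]:
    """Minimal VCF reader: CHROM/POS/REF/ALT with allele fraction in INFO/AF.

    Multi-allelic records are split, pairing each ALT with the matching
    entry of a vector AF. ``sample_id`` defaults to the VCF's single
    sample name, or the file stem for a site-only VCF.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if sample_id is None:
        sample_id = vcf.samples[0] if vcf.samples else Path(path).stem
    calls = []
    for variant in vcf:
        af = variant.INFO.get("AF")
        if af is None:
            raise ValueError(f"{path}: record at {variant.CHROM}:{variant.POS} "
                             "has no INFO/AF")
        afs = list(af) if isinstance(af, (tuple, list)) else [af] * len(variant.ALT)
        for alt, alt_af in zip(variant.ALT, afs):
            calls.append(
                VariantCall(
                    sample_id=sample_id,
                    chrom=variant.CHROM,
                    pos=variant.POS,
                    ref=variant.REF,
                    alt=alt,
                    allele_fraction=float(alt_af),
                    panel=panel,
                )
            )
    return calls


def write_vcf(calls: Sequence[VariantCall], path: str | Path) -> None:
    """Write calls as a minimal uncompressed VCF with AF in INFO."""
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Allele fraction">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for c in sorted(calls, key=lambda c: (c.chrom, c.pos, c.alt)):
        lines.append(
            f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t.\t.\tAF={c.allele_fraction:.6g}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ------------------------------------------------------- regions, blacklist

def read_bed(path: str | Path) -> list[Region]:
    """BED3+: chrom, start, end (0-based half-open); '#' lines skipped."""
    regions: list[Region] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: malformed BED line: {line!r}")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
        if end <= start or start < 0:
            raise ValueError(f"{path}:{lineno}: invalid interval {start}-{end}")
        regions.append((parts[0], start, end))
    if not regions:
        raise ValueError(f"{path}: no regions found")
    return regions


def write_bed(regions: Iterable[Region], path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{c}\t{s}\t{e}\n" for c, s, e in regions)
    )


def read_blacklist(path: str | Path) -> list[BlacklistEntry]:
    """Blacklist of systematic loci: tab-separated chrom, pos (1-based), alt."""
    entries: list[BlacklistEntry] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: expected chrom<TAB>pos<TAB>alt")
        entries.append((parts[0], int(parts[1]), parts[2]))
    return entries


# -------------------------------------------------------------- audit table

def write_confirmation_csv(
    records: Iterable[ConfirmationRecord], path: str | Path
) -> None:
    """Per-sample audit rows in the published column order."""
    rows = [
        {
            "sample_id": r.sample_id,
            "tier": r.tier.value,
            "qfi_percent": r.qfi_percent,
            "n_total": r.n_total,
            "n_overlap": r.n_overlap,
            "n_after_blacklist": r.n_after_blacklist,
            "n_after_af_filter": r.n_after_af_filter,
            "n_confirmed": r.n_confirmed,
            "true_positive_percent": (
                "" if math.isnan(r.true_positive_percent)
                else round(r.true_positive_percent, 1)
            ),
            "n_unconfirmable": r.n_unconfirmable,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
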