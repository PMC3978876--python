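"""Packaged reference audit dataset (19 FFPE samples) and fixture builder.

``REFERENCE_AUDIT`` transcribes a published 19-sample FFPE targeted-NGS
confirmation audit: per sample, the QFI, the variant counts surviving each
stage of the filter cascade (total calls -> confirmation-panel overlap ->
systematic-locus blacklist -> >5% allele-fraction filter -> orthogonally
confirmed), and the resulting true-positive percentage.

The underlying per-variant loci were not published, so
:func:`build_reference_audit_calls` constructs *synthetic* primary and
confirmation call tables engineered so that running the audit cascade
reproduces every row's printed counts exactly. The loci, alleles and
allele fractions are a modeling choice, not measured ground truth; the
counts are the fixture's contract.
"""

from __future__ import annotations

from dataclasses import dataclass

from .confirmation import BlacklistEntry, Region, VariantCall


@dataclass(frozen=True)
class AuditRow:
    sample_id: str
    quality_label: str  # published Low/Medium/High banding
    qfi_percent: float
    qubit_percent: float
    n_total: int
    n_overlap: int
    n_after_blacklist: int
    n_after_af_filter: int
    n_confirmed: int
    tp_percent: float
    n_dbsnp: int


REFERENCE_AUDIT: tuple[AuditRow, ...] = (
    AuditRow("RS00863", "Low", 0.5, 4, 451, 48, 44, 28, 3, 10.7, 2),
    AuditRow("RS00856", "Low", 0.7, 5, 352, 42, 36, 26, 3, 11.5, 2),
    AuditRow("RS01279", "Low", 1.1, 4, 123, 23, 19, 8, 3, 37.5, 3),
    AuditRow("RS00865", "Low", 2.2, 4, 222, 33, 30, 21, 3, 14.3, 2),
    AuditRow("RS01283", "Low", 2.3, 0, 31, 9, 6, 3, 3, 100.0, 3),
    AuditRow("RS01282", "Low", 2.4, 5, 98, 21, 17, 10, 3, 30.0, 3),
    AuditRow("RS01289", "Low", 2.7, 2, 35, 11, 8, 5, 4, 80.0, 3),
    AuditRow("RS01274", "Low", 2.9, 3, 22, 12, 9, 6, 4, 66.7, 3),
    AuditRow("RS00866", "Medium", 6.3, 7, 24, 11, 8, 5, 5, 100.0, 3),
    AuditRow("RS00860", "Medium", 6.5, 7, 19, 7, 4, 3, 3, 100.0, 3),
    AuditRow("RS01294", "Medium", 6.6, 8, 8, 3, 3, 3, 3, 100.0, 3),
    AuditRow("RS00875", "Medium", 6.7, 5, 17, 6, 3, 2, 1, 50.0, 1),
    AuditRow("RS00855", "Medium", 6.8, 11, 16, 8, 5, 3, 3, 100.0, 2),
    AuditRow("RS00876", "High", 16.5, 12, 15, 6, 4, 4, 3, 75.0, 2),
    AuditRow("RS01291", "High", 16.9, 13, 18, 9, 6, 3, 3, 100.0, 3),
    AuditRow("RS00871", "High", 17.8, 16, 9, 4, 2, 2, 2, 100.0, 2),
    AuditRow("RS00873", "High", 19.5, 10, 14, 6, 3, 3, 3, 100.0, 3),
    AuditRow("RS00857", "High", 20.5, 13, 15, 5, 4, 4, 4, 100.0, 3),
    AuditRow("RS00877", "High", 23.9, 20, 12, 7, 4, 4, 4, 100.0, 3),
)

#: Shared panel footprint for the fixture (0-based half-open; ~13.1 kb).
AUDIT_REGIONS: tuple[Region, ...] = (
    ("chr7", 1000, 14000),            # generic panel content
    ("chr3", 178936000, 178936100),   # recurrent-artifact locus region
)

#: Synthetic systematic-artifact loci inside the chr3 region (allele-aware).
AUDIT_BLACKLIST: tuple[BlacklistEntry, ...] = tuple(
    ("chr3", 178936001 + j, "T") for j in range(8)
)


def build_reference_audit_calls(
    rows: tuple[AuditRow, ...] = REFERENCE_AUDIT,
) -> tuple[dict[str, list[VariantCall]], dict[str, list[VariantCall]]]:
    """Synthetic per-sample call tables reproducing the audit cascade counts.

    Returns ``(primary, confirmation)`` dicts keyed by sample id. Call
    placement per sample: out-of-panel calls on chr9; blacklisted calls at
    the synthetic chr3 loci; sub-threshold calls at 3% allele fraction;
    confirmed calls (mirrored in the confirmation table) at 25%;
    unconfirmed survivors at 8% with a C>T-dominated spectrum.
    """
    primary: dict[str, list[VariantCall]] = {}
    confirmation: dict[str, list[VariantCall]] = {}
    for row in rows:
        calls: list[VariantCall] = []
        conf: list[VariantCall] = []
        sid = row.sample_id

        n_out = row.n_total - row.n_overlap
        for i in range(n_out):  # outside the shared panel footprint
            calls.append(VariantCall(sid, "chr9", 1 + i, "G", "C", 0.10))

        n_black = row.n_overlap - row.n_after_blacklist
        if n_black > len(AUDIT_BLACKLIST):
            raise ValueError(f"{sid}: more blacklisted calls than loci")
        for chrom, pos, alt in AUDIT_BLACKLIST[:n_black]:
            calls.append(VariantCall(sid, chrom, pos, "C", alt, 0.40))

        n_low_af = row.n_after_blacklist - row.n_after_af_filter
        pos = 1001  # walk along the chr7 panel region
        for i in range(n_low_af):
            calls.append(VariantCall(sid, "chr7", pos, "C", "T", 0.03))
            pos += 1

        for i in range(row.n_confirmed):
            call = VariantCall(sid, "chr7", pos, "A", "G", 0.25)
            calls.append(call)
            conf.append(
                VariantCall(sid, call.chrom, call.pos, call.ref, call.alt,
                            0.25, panel="confirmation")
            )
            pos += 1

        n_unconfirmed = row.n_after_af_filter - row.n_confirmed
        for i in range(n_unconfirmed):  # false positives: 3 in 4 are C>T
            ref, alt = ("C", "T") if i % 4 != 3 else ("A", "C")
            calls.append(VariantCall(sid, "chr7", pos, ref, alt, 0.08))
            pos += 1

        primary[sid] = calls
        confirmation[sid] = conf
    return primary, confirmation
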