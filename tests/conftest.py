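import pytest

from qfikit.datasets import (
    AUDIT_BLACKLIST,
    AUDIT_REGIONS,
    REFERENCE_AUDIT,
    build_reference_audit_calls,
)


@pytest.fixture(scope="session")
def audit_calls():
    """Synthetic per-sample call tables reproducing the reference audit."""
    return build_reference_audit_calls()


@pytest.fixture(scope="session")
def audit_setup(audit_calls):
    primary, confirmation = audit_calls
    return {
        "primary": primary,
        "confirmation": confirmation,
        "regions": AUDIT_REGIONS,
        "blacklist": AUDIT_BLACKLIST,
        "rows": REFERENCE_AUDIT,
    }
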