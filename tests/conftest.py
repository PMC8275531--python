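import numpy as np
import pytest

from mrtwosample import HarmonizedInstrument, harmonize, load_fixture


def make_instruments(bx, sx, by, sy, rsids=None):
    """Build included harmonized instruments from plain arrays."""
    n = len(bx)
    rsids = rsids or [f"rs{i}" for i in range(n)]
    return [
        HarmonizedInstrument(
            rsid=rsids[i], beta_exposure=float(bx[i]), se_exposure=float(sx[i]),
            beta_outcome=float(by[i]), se_outcome=float(sy[i]),
            effect_allele="A", status="included",
        )
        for i in range(n)
    ]


@pytest.fixture(scope="session")
def forward():
    instruments, outcome, meta = load_fixture("vitd_to_adhd")
    return harmonize(instruments, outcome), meta


@pytest.fixture(scope="session")
def forward_included(forward):
    harmonized, _ = forward
    return [h for h in harmonized if h.included]


@pytest.fixture(scope="session")
def reverse():
    instruments, outcome, meta = load_fixture("adhd_to_vitd")
    return harmonize(instruments, outcome), meta


@pytest.fixture(scope="session")
def reverse_included(reverse):
    harmonized, _ = reverse
    return [h for h in harmonized if h.included]
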