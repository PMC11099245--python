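import logging

import numpy as np
import pytest

from mrscreen.harmonization import HarmonizedInstrument, HarmonizedSet

logging.getLogger("mrscreen").setLevel(logging.ERROR)


def make_set(bx, by, sy, sx=None, exposure_id="exp", outcome_id="out"):
    """Build a HarmonizedSet directly from effect arrays."""
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    sy = np.broadcast_to(np.asarray(sy, dtype=float), bx.shape)
    sx = (
        np.broadcast_to(np.asarray(sx, dtype=float), bx.shape)
        if sx is not None
        else np.full_like(bx, 1e-6)
    )
    instruments = [
        HarmonizedInstrument(
            variant_id=f"rs{i:03d}",
            effect_allele="A",
            beta_exp=float(bx[i]),
            se_exp=float(sx[i]),
            beta_out=float(by[i]),
            se_out=float(sy[i]),
        )
        for i in range(len(bx))
    ]
    return HarmonizedSet(exposure_id=exposure_id, outcome_id=outcome_id, instruments=instruments)


@pytest.fixture
def ivw_fixture_set():
    """Three instruments whose per-SNP ratios are all exactly 0.2."""
    return make_set([0.5, 0.4, 0.25], [0.10, 0.08, 0.05], 0.02)


@pytest.fixture
def ratio_set():
    """Equal-weight instruments with ratios 0.1, 0.2, 0.9."""
    return make_set([1.0, 1.0, 1.0], [0.1, 0.2, 0.9], 1.0)
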