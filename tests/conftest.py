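from __future__ import annotations

from typing import Optional

import numpy as np
import pytest

from nmoh.autonomic import OrthostaticPanel, Vitals


def make_panel(
    supine: tuple[float, float, float],
    m1: Optional[tuple[float, float, float]] = None,
    m3: Optional[tuple[float, float, float]] = None,
    m5: Optional[tuple[float, float, float]] = None,
) -> OrthostaticPanel:
    """Shorthand constructor for vitals vignettes: (sbp, dbp, hr) tuples."""
    return OrthostaticPanel(
        supine=Vitals(*supine),
        standing={
            1: Vitals(*m1) if m1 else None,
            3: Vitals(*m3) if m3 else None,
            5: Vitals(*m5) if m5 else None,
        },
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
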