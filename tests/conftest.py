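"""Shared fixtures: the two simulation studies used across test modules.

Both are desk-scale versions of the benchmark's study conditions (see
``ampbench.studies``) and are computed once per session with fixed seeds.
"""

from __future__ import annotations

import pytest

from ampbench.studies import (
    dilution_trend_study,
    parameter_recovery_study,
    q30_error_model,  # noqa: F401  (re-exported for test modules)
)


@pytest.fixture(scope="session")
def recovery_study():
    """High-biomass parameter recovery: 8 uniform strains >= 20 nt apart,
    50 000 reads at Q30, no contamination, no chimeras."""
    return parameter_recovery_study(seed=7)


@pytest.fixture(scope="session")
def dilution_study():
    """The 9-sample 3-fold dilution series with a 30-member fixed-mass
    contaminant pool, 5000 reads per sample, per-sample processing."""
    return dilution_trend_study(seed=19)
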