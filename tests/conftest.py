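"""Shared fixtures: measured phantom cases reused across test modules.

The full pipeline takes seconds per case, so every end-to-end run lives in a
session-scoped fixture and the assertions are spread over the test modules.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from aortascreen.morphometry import PipelineConfig, measure_case
from aortascreen.phantoms import generate_phantom, standard_spec


@pytest.fixture(scope="session")
def aaa_case():
    """A 50 mm aneurysmal phantom (lumen + thrombus) and its measurement."""
    spec = standard_spec(50.0, with_thrombus=True, seed=3)
    lumen, thrombus, truth = generate_phantom(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = measure_case(lumen, thrombus, PipelineConfig(keep_intermediates=True),
                              case_id="aaa50")
    return {"spec": spec, "lumen": lumen, "thrombus": thrombus,
            "truth": truth, "result": result}


@pytest.fixture(scope="session")
def control_case():
    """A 24 mm non-aneurysmal phantom (lumen only) and its measurement."""
    spec = standard_spec(24.0, with_thrombus=False, seed=11)
    lumen, thrombus, truth = generate_phantom(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = measure_case(lumen, thrombus, PipelineConfig(keep_intermediates=True),
                              case_id="ctl24")
    return {"spec": spec, "lumen": lumen, "thrombus": thrombus,
            "truth": truth, "result": result}


@pytest.fixture(scope="session")
def phantom_suite():
    """20 measured phantoms spanning 18-90 mm at 0.75 mm isotropic spacing."""
    diameters = np.linspace(18.0, 90.0, 20)
    rows = []
    for i, d in enumerate(diameters):
        spec = standard_spec(float(d), with_thrombus=d > 30.0, seed=100 + i)
        lumen, thrombus, truth = generate_phantom(spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = measure_case(lumen, thrombus, PipelineConfig(), case_id=f"suite_{i:02d}")
        rows.append({"target": float(d), "truth": truth, "result": result})
    return rows
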