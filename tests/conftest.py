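import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from rplca import CoverageMatrix, SmMipRecord, gen_panel

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture
def small_panel() -> list[SmMipRecord]:
    """Synthetic 40-probe panel over the built-in gene table."""
    return gen_panel(40)


@pytest.fixture
def flat_matrix(small_panel) -> CoverageMatrix:
    """10 samples x 40 probes, constant counts, one NTC."""
    samples = [f"P{i:02d}" for i in range(9)] + ["NTC01"]
    roles = {s: "proband" for s in samples[:-1]}
    roles["NTC01"] = "NTC"
    counts = pd.DataFrame(
        np.full((10, 40), 100, dtype=np.int64),
        index=samples, columns=[p.probe_id for p in small_panel])
    counts.loc["NTC01"] = 0
    return CoverageMatrix(counts, roles)
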