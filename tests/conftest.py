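import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20131)


def normal_equations(x, y):
    """Independent OLS oracle: naive summation normal equations.

    Returns (slope, intercept, r_squared, sd_slope, sd_intercept) computed
    from raw sums only, as a cross-check for the regression core.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    sx, sy = x.sum(), y.sum()
    sxx, sxy, syy = (x * x).sum(), (x * y).sum(), (y * y).sum()
    denom = n * sxx - sx * sx
    slope = (n * sxy - sx * sy) / denom
    intercept = (sy - slope * sx) / n
    ss_res = ((y - slope * x - intercept) ** 2).sum()
    ss_tot = syy - sy * sy / n
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    if n > 2:
        s2 = ss_res / (n - 2)
        sd_slope = np.sqrt(n * s2 / denom)
        sd_intercept = np.sqrt(s2 * sxx / denom)
    else:
        sd_slope = sd_intercept = float("nan")
    return slope, intercept, r2, sd_slope, sd_intercept
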