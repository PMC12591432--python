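"""Shared test helpers: independent oracles and series constructors.

These deliberately avoid the package's own code paths: the OLS oracle
solves the normal equations directly from an explicitly constructed design,
and the piecewise constructor builds series by evaluating the two line
segments, so engine tests compare two independent routes.
"""

import numpy as np

from comorbits.trajectory import PrevalenceSeries


def ols_oracle(offsets, y):
    """Closed-form normal-equations solution of the segmented regression."""
    t = np.asarray(offsets, dtype=float)
    d = (t >= 0).astype(float)
    p = t * d
    X = np.column_stack([np.ones_like(t), t, d, p])
    return np.linalg.solve(X.T @ X, X.T @ np.asarray(y, dtype=float))


def piecewise_values(offsets, pre_intercept, pre_slope, post_intercept, post_slope):
    """y = pre_intercept + pre_slope*T before 0; post segment from T >= 0."""
    t = np.asarray(offsets, dtype=float)
    pre = pre_intercept + pre_slope * t
    post = post_intercept + post_slope * t
    return np.where(t < 0, pre, post)


def make_series(values, condition_id="c", group="all_tbi", window=None,
                group_size=1000):
    values = np.asarray(values, dtype=float)
    if window is None:
        window = (len(values) - 1) // 2
    offsets = np.arange(-window, -window + len(values))
    return PrevalenceSeries(condition_id, group, offsets, values, group_size)


def table2_style_series(condition_id, group, prev_at_minus1, jump,
                        pre_annual, post_annual, window=72, group_size=100000):
    """Piecewise-linear prevalence series parameterized the way the headline
    metrics read it: level just before index, index-month jump, and annual
    pre/post slopes (percent per year)."""
    s_pre = pre_annual / 12.0
    s_post = post_annual / 12.0
    offsets = np.arange(-window, window + 1)
    values = np.where(
        offsets < 0,
        prev_at_minus1 + s_pre * (offsets + 1),
        prev_at_minus1 + jump + s_post * offsets,
    )
    return PrevalenceSeries(condition_id, group, offsets, values, group_size)
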