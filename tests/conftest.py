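"""Shared fixtures and independent oracle helpers.

Oracles here are deliberately naive re-implementations (scalar loops,
closed forms) kept independent of the library code paths they check.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from hystfit import ObservedProfile, ReuseModelParams


def tanh_oracle(range_, slope, x_offset, y_offset, drawer):
    """Scalar closed-form sigmoid, independent of hystfit.optimal_angle."""
    if range_ == 0:
        return y_offset
    return y_offset + (range_ / 2.0) * math.tanh(
        (2.0 * slope / range_) * (drawer - x_offset)
    )


def recursion_oracle(range_, slope, x_offset, y_offset, reuse, drawers):
    """Step-by-step reuse recursion as a plain Python loop."""
    angles = []
    for i, d in enumerate(drawers):
        opt = tanh_oracle(range_, slope, x_offset, y_offset, d)
        if i == 0:
            angles.append(opt)
        else:
            angles.append(reuse * angles[-1] + (1.0 - reuse) * opt)
    return angles


def make_directional_profile(params: ReuseModelParams, drawers=range(1, 10),
                             task: str = "ordered") -> ObservedProfile:
    """Noiseless ascending+descending profile generated by the oracle recursion."""
    s = params.sigmoid
    drawers = sorted(drawers)
    asc = recursion_oracle(s.range, s.slope, s.x_offset, s.y_offset,
                           params.reuse, drawers)
    desc = recursion_oracle(s.range, s.slope, s.x_offset, s.y_offset,
                            params.reuse, drawers[::-1])
    cells = {("ascending", d): a for d, a in zip(drawers, asc)}
    cells.update({("descending", d): a for d, a in zip(drawers[::-1], desc)})
    series = pd.Series(cells)
    series.index = pd.MultiIndex.from_tuples(series.index)
    return ObservedProfile(task, series)


def make_randomized_profile(params, drawers=range(1, 10)) -> ObservedProfile:
    s = params.sigmoid if isinstance(params, ReuseModelParams) else params
    cells = {
        ("none", d): tanh_oracle(s.range, s.slope, s.x_offset, s.y_offset, d)
        for d in drawers
    }
    series = pd.Series(cells)
    series.index = pd.MultiIndex.from_tuples(series.index)
    return ObservedProfile("randomized", series)


@pytest.fixture
def paper_ordered_params() -> ReuseModelParams:
    """Cohort-mean parameters of the ordered task."""
    return ReuseModelParams.from_values(131.9, 41.2, 4.4, 16.5, 0.156)


@pytest.fixture
def paper_randomized_params() -> ReuseModelParams:
    """Cohort-mean parameters of the randomized task (no reuse)."""
    return ReuseModelParams.from_values(133.3, 39.4, 4.4, 17.2, 0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20261002)
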