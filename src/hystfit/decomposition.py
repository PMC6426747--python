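"""Factorial variance decomposition of direction-by-drawer profiles.

A balanced 2 x D cell-mean table (ascending/descending x drawers) is
partitioned into sequence, drawer and sequence-x-drawer components.  The
sequence main effect and the interaction are the two components affected by
motor hysteresis; how much of their combined variance a model captures, and
how participants split into "hysteresis" and "noise" groups by their
sequence/interaction variance ratio, is computed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import (
    HystfitWarning,
    IncompleteDesignError,
    UndefinedVarianceError,
)

__all__ = [
    "FactorialSS",
    "HysteresisSummary",
    "factorial_ss",
    "hysteresis_effect",
    "captured_hysteresis_variance",
    "classify_participants",
]


def _as_matrix(profile) -> np.ndarray:
    """Coerce a 2 x D profile (array, DataFrame or ObservedProfile) to ndarray."""
    if hasattr(profile, "matrix"):  # ObservedProfile
        profile = profile.matrix()
    m = np.asarray(profile, dtype=float)
    if m.ndim != 2 or m.shape[0] != 2 or m.shape[1] < 2:
        raise IncompleteDesignError(
            f"need a 2 x D matrix with D >= 2, got shape {m.shape}"
        )
    if not np.all(np.isfinite(m)):
        raise IncompleteDesignError("profile has missing or non-finite cells")
    return m


@dataclass(frozen=True)
class FactorialSS:
    """Sum-of-squares partition of a balanced 2 x D cell-mean design.

    All components are in squared degrees and satisfy
    ``ss_total = ss_sequence + ss_drawer + ss_interaction`` (additivity of a
    balanced two-way decomposition).
    """

    ss_total: float
    ss_sequence: float
    ss_drawer: float
    ss_interaction: float


@dataclass(frozen=True)
class HysteresisSummary:
    """Per-drawer and mean hysteresis effect (descending minus ascending).

    Positive values mean the descending pass is more pronated.  The optional
    ``combined_captured_pct`` and ``group_label`` fields are filled by the
    pipeline when a fitted model / cohort context is available.
    """

    drawers: tuple[int, ...]
    per_drawer_effect: np.ndarray
    mean_effect: float
    combined_captured_pct: float = float("nan")
    group_label: str = ""


def factorial_ss(profile) -> FactorialSS:
    """Decompose a 2 x D cell-mean matrix into factorial sums of squares.

    ``ss_sequence = D * sum_s (row mean - grand)^2``,
    ``ss_drawer = 2 * sum_d (col mean - grand)^2``, and the interaction is
    the remainder of the total about the grand mean.
    """

    m = _as_matrix(profile)
    n_dir, n_drawer = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_total = float(np.sum((m - grand) ** 2))
    ss_sequence = float(n_drawer * np.sum((row_means - grand) ** 2))
    ss_drawer = float(n_dir * np.sum((col_means - grand) ** 2))
    ss_interaction = float(
        np.sum((m - row_means[:, None] - col_means[None, :] + grand) ** 2)
    )
    return FactorialSS(ss_total, ss_sequence, ss_drawer, ss_interaction)


def hysteresis_effect(profile, drawers=None) -> HysteresisSummary:
    """Per-drawer and mean (descending - ascending) hysteresis effect.

    Row 0 of the matrix is the ascending, row 1 the descending profile
    (:meth:`ObservedProfile.matrix` ordering).
    """

    if hasattr(profile, "matrix"):
        wide = profile.matrix()
        drawers = tuple(int(d) for d in wide.columns)
        m = wide.to_numpy(dtype=float)
    else:
        m = _as_matrix(profile)
        drawers = tuple(drawers) if drawers is not None else tuple(
            range(1, m.shape[1] + 1)
        )
    per_drawer = m[1] - m[0]
    return HysteresisSummary(
        drawers=drawers,
        per_drawer_effect=per_drawer,
        mean_effect=float(np.mean(per_drawer)),
    )


def captured_hysteresis_variance(observed, predicted) -> float:
    """Percent of the hysteresis-related variance captured by a model.

    The hysteresis-related variance of a profile is the sum of its sequence
    and sequence-x-drawer components.  The captured fraction is defined by
    residual projection: decompose ``observed - predicted`` and return
    ``100 * (1 - (ss_seq_res + ss_int_res) / (ss_seq_obs + ss_int_obs))``.
    This is 100 for a perfect fit, ~0 for a direction-symmetric model, and
    may be negative when the model *adds* spurious direction structure
    (reported as-is).
    """

    obs = _as_matrix(observed)
    pred = _as_matrix(predicted)
    if obs.shape != pred.shape:
        raise IncompleteDesignError("observed and predicted designs must match")
    ss_obs = factorial_ss(obs)
    denom = ss_obs.ss_sequence + ss_obs.ss_interaction
    if denom == 0.0:
        raise UndefinedVarianceError(
            "observed profile has zero hysteresis variance; nothing to capture"
        )
    ss_res = factorial_ss(obs - pred)
    pct = 100.0 * (1.0 - (ss_res.ss_sequence + ss_res.ss_interaction) / denom)
    if pct < 0:
        warnings.warn(
            f"model increases hysteresis-component residual variance "
            f"(captured = {pct:.1f}%)",
            HystfitWarning,
            stacklevel=2,
        )
    return pct


def classify_participants(
    ss_sequence, ss_interaction, participant_ids=None
) -> pd.Series:
    """Split participants into 'hysteresis' and 'noise' halves.

    Participants are ranked by the ratio ``ss_sequence / ss_interaction``
    (infinite when the interaction SS is 0 but the sequence SS is not); the
    top half is labelled ``'hysteresis'``, the bottom half ``'noise'``.  For
    odd N the median participant is labelled ``'excluded'``, as is any
    participant whose both components are zero (undefined ratio).
    """

    seq = np.asarray(ss_sequence, dtype=float)
    inter = np.asarray(ss_interaction, dtype=float)
    if seq.shape != inter.shape or seq.ndim != 1:
        raise ValueError("ss_sequence and ss_interaction must be matching 1-D arrays")
    n = seq.size
    if n < 2:
        raise ValueError("need >= 2 participants to classify")
    if participant_ids is None:
        participant_ids = np.arange(n)

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = seq / inter
    ratio = np.where((inter == 0) & (seq > 0), np.inf, ratio)
    undefined = (inter == 0) & (seq == 0)
    if undefined.any():
        warnings.warn(
            f"{int(undefined.sum())} participant(s) with zero sequence and "
            "interaction SS; ratio undefined, labelled 'excluded'",
            HystfitWarning,
            stacklevel=2,
        )

    labels = np.full(n, "excluded", dtype=object)
    defined_idx = np.flatnonzero(~undefined)
    # stable sort: ties and equal ratios keep input order, high ratio first
    order = defined_idx[np.argsort(-ratio[defined_idx], kind="stable")]
    m = order.size
    half = m // 2
    labels[order[:half]] = "hysteresis"
    labels[order[m - half:]] = "noise"  # middle one stays 'excluded' for odd m
    return pd.Series(labels, index=participant_ids, name="group")
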