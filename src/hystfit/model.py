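"""Core five-parameter model of sequential posture selection.

The optimal pro/supination grasp angle is a sigmoid (hyperbolic tangent)
function of drawer number, described by four parameters: the asymptotic
*range* of the curve, its steepest *slope*, and the *x-* and *y-offset* of
the inflection point.  A fifth parameter, the *reuse* fraction, blends the
previous trial's grasp posture into the plan for the next drawer, producing
motor hysteresis: in a descending sequence the hand stays more pronated, in
an ascending sequence more supinated, than the optimum.

All angles are in degrees, drawers are 1-based apparatus coordinates
(1 = lowest, 9 = highest), and reuse is stored as a fraction in [0, 1]
(human-facing reports multiply by 100).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import InvalidInputError, UnsupportedTaskError

__all__ = [
    "SigmoidParams",
    "ReuseModelParams",
    "SequenceSpec",
    "TaskSpec",
    "TaskPrediction",
    "CostCurves",
    "optimal_angle",
    "blend",
    "simulate_sequence",
    "predict_task",
    "cost_curves",
    "ORDERED_DRAWERS",
    "SKIPPED_DRAWERS",
]

ORDERED_DRAWERS: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8, 9)
SKIPPED_DRAWERS: tuple[int, ...] = (1, 3, 5, 7, 9)


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise InvalidInputError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class SigmoidParams:
    """Parameters of the sigmoid optimal grasp-angle curve.

    Attributes
    ----------
    range : float
        Asymptotic span of the curve from the lowest to the highest drawer,
        in degrees.  Must be >= 0; 0 denotes a flat curve.
    slope : float
        Steepest derivative of the curve (at the inflection point), in
        degrees per drawer.  Must be >= 0.
    x_offset : float
        Drawer coordinate of the inflection point, in drawer units;
        constrained to [0, 10] (one drawer-unit margin beyond 1..9).
    y_offset : float
        Grasp angle at the inflection point, in degrees, in [-180, 180].
    """

    range: float
    slope: float
    x_offset: float
    y_offset: float

    def __post_init__(self) -> None:
        for name in ("range", "slope", "x_offset", "y_offset"):
            _require_finite(name, getattr(self, name))
        if self.range < 0:
            raise InvalidInputError(f"range must be >= 0, got {self.range}")
        if self.slope < 0:
            raise InvalidInputError(f"slope must be >= 0, got {self.slope}")
        if not 0.0 <= self.x_offset <= 10.0:
            raise InvalidInputError(
                f"x_offset must be in [0, 10], got {self.x_offset}"
            )
        if not -180.0 <= self.y_offset <= 180.0:
            raise InvalidInputError(
                f"y_offset must be in [-180, 180], got {self.y_offset}"
            )


@dataclass(frozen=True)
class ReuseModelParams:
    """The full five-parameter model: sigmoid optimum plus reuse fraction.

    ``reuse`` is the fraction (in [0, 1]) of the previous motor plan carried
    over to the next trial; it is reported externally as a percentage.
    """

    sigmoid: SigmoidParams
    reuse: float

    def __post_init__(self) -> None:
        _require_finite("reuse", self.reuse)
        if not 0.0 <= self.reuse <= 1.0:
            raise InvalidInputError(f"reuse must be in [0, 1], got {self.reuse}")

    @classmethod
    def from_values(
        cls,
        range: float,
        slope: float,
        x_offset: float,
        y_offset: float,
        reuse: float = 0.0,
    ) -> "ReuseModelParams":
        return cls(SigmoidParams(range, slope, x_offset, y_offset), reuse)

    def as_array(self) -> np.ndarray:
        """Parameter vector [range, slope, x_offset, y_offset, reuse]."""
        s = self.sigmoid
        return np.array([s.range, s.slope, s.x_offset, s.y_offset, self.reuse])


@dataclass(frozen=True)
class SequenceSpec:
    """An ordered list of drawers visited in a single pass.

    ``direction`` is 'ascending', 'descending', or 'custom'; ascending
    sequences must be strictly increasing, descending strictly decreasing.
    """

    direction: str
    drawers: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.direction not in ("ascending", "descending", "custom"):
            raise InvalidInputError(f"unknown direction {self.direction!r}")
        drawers = tuple(int(d) for d in self.drawers)
        object.__setattr__(self, "drawers", drawers)
        if not drawers:
            raise InvalidInputError("drawers must be non-empty")
        if any(not 1 <= d <= 9 for d in drawers):
            raise InvalidInputError(f"drawers must be in 1..9, got {drawers}")
        diffs = np.diff(drawers)
        if self.direction == "ascending" and not np.all(diffs > 0):
            raise InvalidInputError("ascending sequence must be strictly increasing")
        if self.direction == "descending" and not np.all(diffs < 0):
            raise InvalidInputError("descending sequence must be strictly decreasing")

    @classmethod
    def ascending(cls, drawers: Sequence[int] = ORDERED_DRAWERS) -> "SequenceSpec":
        return cls("ascending", tuple(sorted(drawers)))

    @classmethod
    def descending(cls, drawers: Sequence[int] = ORDERED_DRAWERS) -> "SequenceSpec":
        return cls("descending", tuple(sorted(drawers, reverse=True)))


@dataclass(frozen=True)
class TaskSpec:
    """One of the three drawer-opening tasks of the experimental design.

    'randomized' visits the nine drawers in pseudo-random order, 'ordered'
    runs full ascending/descending passes over drawers 1..9, and 'skipped'
    does the same over drawers {1, 3, 5, 7, 9} only.
    """

    name: str
    drawer_set: tuple[int, ...] = ORDERED_DRAWERS
    n_repetitions: int = 4

    def __post_init__(self) -> None:
        if self.name not in ("randomized", "ordered", "skipped"):
            raise InvalidInputError(f"unknown task {self.name!r}")
        drawer_set = tuple(int(d) for d in self.drawer_set)
        object.__setattr__(self, "drawer_set", drawer_set)
        if self.name == "ordered" and drawer_set != ORDERED_DRAWERS:
            raise InvalidInputError("ordered task uses drawers 1..9")
        if self.name == "skipped" and drawer_set != SKIPPED_DRAWERS:
            raise InvalidInputError("skipped task uses drawers {1,3,5,7,9}")
        if self.n_repetitions < 1:
            raise InvalidInputError("n_repetitions must be >= 1")

    @classmethod
    def randomized(cls, n_repetitions: int = 4) -> "TaskSpec":
        return cls("randomized", ORDERED_DRAWERS, n_repetitions)

    @classmethod
    def ordered(cls, n_repetitions: int = 4) -> "TaskSpec":
        return cls("ordered", ORDERED_DRAWERS, n_repetitions)

    @classmethod
    def skipped(cls, n_repetitions: int = 4) -> "TaskSpec":
        return cls("skipped", SKIPPED_DRAWERS, n_repetitions)


def optimal_angle(params: SigmoidParams, drawer) -> float | np.ndarray:
    """Optimal grasp angle at a (possibly fractional) drawer coordinate.

    Evaluates ``y_offset + (range/2) * tanh((2*slope/range) * (d - x_offset))``,
    parameterized so that ``range`` is the full asymptotic span and ``slope``
    the literal steepest derivative in degrees/drawer.  For ``range == 0``
    the flat limit ``y_offset`` is returned.
    """

    drawer = np.asarray(drawer, dtype=float)
    if not np.all(np.isfinite(drawer)):
        raise InvalidInputError("drawer coordinate must be finite")
    if params.range == 0.0:
        out = np.full_like(drawer, params.y_offset)
    else:
        gain = 2.0 * params.slope / params.range
        with np.errstate(over="ignore", invalid="ignore"):
            arg = gain * (drawer - params.x_offset)
        # inf * 0 at the inflection of a near-degenerate (step-like) curve
        arg = np.where(drawer == params.x_offset, 0.0, arg)
        out = params.y_offset + (params.range / 2.0) * np.tanh(arg)
    return out.item() if out.ndim == 0 else out


def blend(previous_angle: float, optimal: float, reuse: float) -> float:
    """Blend the previous grasp posture with the current optimum.

    Returns ``reuse * previous_angle + (1 - reuse) * optimal``; the weighted
    average always lies between the two input angles.
    """

    previous_angle = _require_finite("previous_angle", previous_angle)
    optimal = _require_finite("optimal", optimal)
    reuse = _require_finite("reuse", reuse)
    if not 0.0 <= reuse <= 1.0:
        raise InvalidInputError(f"reuse must be in [0, 1], got {reuse}")
    return reuse * previous_angle + (1.0 - reuse) * optimal


def simulate_sequence(
    params: ReuseModelParams,
    seq: SequenceSpec,
    first_trial: str = "optimal",
) -> np.ndarray:
    """Simulate the grasp angles of one pass over a drawer sequence.

    Trial 1 adopts the optimal angle for its drawer (``first_trial='optimal'``,
    the default: reuse acts only *between* subsequent drawers, and each pass
    starts from a resting posture).  With ``first_trial='blend'`` an explicit
    starting angle can instead be threaded in via ``simulate_sequence_from``.
    Every later trial blends the previous angle with the current optimum.
    """

    if first_trial != "optimal":
        raise InvalidInputError(
            "only first_trial='optimal' is supported here; "
            "use simulate_sequence_from for an explicit start"
        )
    start = optimal_angle(params.sigmoid, seq.drawers[0])
    return simulate_sequence_from(params, seq, start)


def simulate_sequence_from(
    params: ReuseModelParams, seq: SequenceSpec, first_angle: float
) -> np.ndarray:
    """Simulate a pass whose first trial uses ``first_angle`` directly."""

    angles = np.empty(len(seq.drawers))
    angles[0] = _require_finite("first_angle", first_angle)
    for i, d in enumerate(seq.drawers[1:], start=1):
        angles[i] = blend(angles[i - 1], optimal_angle(params.sigmoid, d), params.reuse)
    return angles


@dataclass(frozen=True)
class TaskPrediction:
    """Predicted direction-by-drawer profile and its hysteresis effect.

    ``ascending``/``descending`` hold one predicted angle per drawer in
    ``drawers`` (ascending order); ``per_drawer_effect`` is descending minus
    ascending and ``mean_effect`` its mean, restricted to ``effect_drawers``.
    """

    drawers: tuple[int, ...]
    ascending: np.ndarray
    descending: np.ndarray
    effect_drawers: tuple[int, ...]
    per_drawer_effect: np.ndarray
    mean_effect: float


def predict_task(
    params: ReuseModelParams,
    task: TaskSpec,
    effect_drawers: Sequence[int] | None = None,
) -> TaskPrediction:
    """Predict the mean ascending/descending profile of an ordered-style task.

    One ascending and one descending pass over ``task.drawer_set`` are
    simulated (repetitions are averaged in the experiment and each pass
    restarts from rest, so a single pass per direction suffices).  The
    hysteresis effect is the mean of (descending - ascending) over
    ``effect_drawers`` (default: all drawers of the task), positive when the
    descending pass is more pronated.
    """

    if task.name == "randomized":
        raise UnsupportedTaskError(
            "randomized task has no direction structure; cannot predict hysteresis"
        )
    drawers = tuple(sorted(task.drawer_set))
    asc = simulate_sequence(params, SequenceSpec.ascending(drawers))
    desc = simulate_sequence(params, SequenceSpec.descending(drawers))[::-1]
    if effect_drawers is None:
        effect_drawers = drawers
    effect_drawers = tuple(sorted(int(d) for d in effect_drawers))
    missing = set(effect_drawers) - set(drawers)
    if missing:
        raise InvalidInputError(f"effect drawers {sorted(missing)} not in task")
    idx = [drawers.index(d) for d in effect_drawers]
    per_drawer = desc[idx] - asc[idx]
    return TaskPrediction(
        drawers=drawers,
        ascending=asc,
        descending=desc,
        effect_drawers=effect_drawers,
        per_drawer_effect=per_drawer,
        mean_effect=float(np.mean(per_drawer)),
    )


@dataclass(frozen=True)
class CostCurves:
    """Cognitive, mechanical and total cost as functions of the reuse fraction."""

    reuse_grid: np.ndarray
    cognitive: np.ndarray
    mechanical: np.ndarray
    total: np.ndarray
    argmin_reuse: float


def cost_curves(
    reuse_grid: Sequence[float],
    cognitive_weight: float,
    mechanical_weight: float,
    exponent: float,
) -> CostCurves:
    """Illustrative cost-optimization curves over a reuse grid.

    Cognitive planning cost decreases with reuse, mechanical execution cost
    increases; both are modelled as power functions:
    ``w_c * (1 - u)**p`` and ``w_m * u**p`` with ``p > 1`` (convexity).
    The returned ``argmin_reuse`` is the grid point minimizing the total.
    """

    exponent = _require_finite("exponent", exponent)
    if exponent <= 1.0:
        raise InvalidInputError(f"exponent must be > 1, got {exponent}")
    w_c = _require_finite("cognitive_weight", cognitive_weight)
    w_m = _require_finite("mechanical_weight", mechanical_weight)
    if w_c < 0 or w_m < 0 or (w_c == 0 and w_m == 0):
        raise InvalidInputError("weights must be >= 0 and not both zero")
    u = np.asarray(reuse_grid, dtype=float)
    if u.size == 0 or np.any((u < 0) | (u > 1)):
        raise InvalidInputError("reuse grid must be non-empty and within [0, 1]")
    cognitive = w_c * (1.0 - u) ** exponent
    mechanical = w_m * u ** exponent
    total = cognitive + mechanical
    return CostCurves(
        reuse_grid=u,
        cognitive=cognitive,
        mechanical=mechanical,
        total=total,
        argmin_reuse=float(u[int(np.argmin(total))]),
    )
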