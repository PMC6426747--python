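"""Repetition-averaged direction-by-drawer grasp-angle profiles.

An :class:`ObservedProfile` is the fitting target of the toolkit: one mean
grasp angle per (direction, drawer) cell, obtained by averaging the
repetitions of a trial table.  Randomized tasks carry a single
pseudo-direction ``'none'``; ordered and skipped tasks carry ``'ascending'``
and ``'descending'`` cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import IncompleteDesignError, InsufficientDataError, InvalidInputError

__all__ = ["ObservedProfile", "DIRECTIONS"]

DIRECTIONS = ("none", "ascending", "descending")


@dataclass(frozen=True)
class ObservedProfile:
    """Per-cell mean grasp angles keyed by (direction, drawer).

    Parameters
    ----------
    task : str
        'randomized', 'ordered' or 'skipped'.
    cells : pandas.Series
        Mean angle in degrees, MultiIndex (direction, drawer); each cell is
        the mean of its repetitions.
    """

    task: str
    cells: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        cells = self.cells
        if not isinstance(cells.index, pd.MultiIndex) or cells.index.nlevels != 2:
            raise InvalidInputError("cells must have a (direction, drawer) MultiIndex")
        cells = cells.copy()
        cells.index = cells.index.set_names(["direction", "drawer"])
        cells = cells.sort_index()
        if not np.all(np.isfinite(cells.to_numpy(dtype=float))):
            raise InvalidInputError("profile contains non-finite angles")
        bad = set(cells.index.get_level_values("direction")) - set(DIRECTIONS)
        if bad:
            raise InvalidInputError(f"unknown direction(s) {sorted(bad)}")
        if cells.index.has_duplicates:
            raise InvalidInputError("duplicate (direction, drawer) cells")
        object.__setattr__(self, "cells", cells)

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_trials(cls, trials: pd.DataFrame, task: str) -> "ObservedProfile":
        """Average the repetitions of one participant's trials for ``task``.

        ``trials`` is a trial table slice (columns ``task``, ``direction``,
        ``drawer``, ``angle_deg``) for a single participant.
        """

        sub = trials[trials["task"] == task]
        if sub.empty:
            raise InsufficientDataError(f"no trials for task {task!r}")
        cells = sub.groupby(["direction", "drawer"], observed=True)["angle_deg"].mean()
        return cls(task=task, cells=cells)

    # -- views ------------------------------------------------------------

    @property
    def directions(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.cells.index.get_level_values("direction"))))

    @property
    def drawers(self) -> tuple[int, ...]:
        return tuple(sorted(set(self.cells.index.get_level_values("drawer"))))

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def values(self) -> np.ndarray:
        return self.cells.to_numpy(dtype=float)

    def collapsed(self) -> pd.Series:
        """Mean over directions, one value per drawer (sorted)."""
        return self.cells.groupby(level="drawer").mean().sort_index()

    def matrix(self) -> pd.DataFrame:
        """The balanced 2 x D cell-mean matrix of a directional profile.

        Rows are 'ascending' and 'descending', columns the sorted drawers.
        Raises if either direction or any cell is missing.
        """

        dirs = self.directions
        if set(dirs) != {"ascending", "descending"}:
            raise IncompleteDesignError(
                f"2 x D matrix needs ascending and descending cells, have {dirs}"
            )
        wide = self.cells.unstack(level="drawer").loc[["ascending", "descending"]]
        if wide.isna().any().any():
            missing = [
                (r, c) for r in wide.index for c in wide.columns
                if pd.isna(wide.loc[r, c])
            ]
            raise IncompleteDesignError(f"missing cells: {missing}")
        return wide
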