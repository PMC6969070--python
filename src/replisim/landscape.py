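"""Ground-truth effect landscapes.

The community searches a grid of candidate phenomena: each cell is a unique
combination of an experimental intervention and an outcome measure, and its
ground truth is 1 (a real effect of unit size) or 0 (no effect).  Two search
modes are modelled:

* **discovery** — effects are scattered independently over the grid with
  probability ``p_h1`` and experiments target cells uniformly at random;
* **theory** — all effects cluster inside a square window placed uniformly
  at random, and experiments target cells inside a *predicted* window whose
  distance from the true cluster is governed by the theory-quality parameter
  ``rho`` (1 = perfect overlap, near 0 = searching where nothing is).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np

logger = logging.getLogger("replisim")

DISCOVERY = "discovery"
THEORY = "theory"

Anchor = Tuple[int, int]


@dataclass(frozen=True)
class GridSpec:
    """Dimensions and effect prevalence of the ground-truth grid.

    Defaults are the scenario constants: a 10x10 grid, a 4x4 theory window,
    and a base rate P(H1) = .09 of true effects.
    """

    n_rows: int = 10
    n_cols: int = 10
    window_size: int = 4
    p_h1: float = 0.09

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be positive")
        if not (1 <= self.window_size <= min(self.n_rows, self.n_cols)):
            raise ValueError("window_size must fit inside the grid")
        if not 0.0 <= self.p_h1 <= 1.0:
            raise ValueError("p_h1 must be a probability")

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def max_anchor(self) -> Anchor:
        """Largest feasible (row, col) for a window's top-left corner."""
        return (self.n_rows - self.window_size, self.n_cols - self.window_size)


@dataclass(frozen=True)
class TheoryQuality:
    """Overlap between the theory's predicted window and the true cluster.

    ``rho`` = 1 means the predicted and true centroids coincide; for
    rho < 1 the predicted centroid is displaced (1 - rho) * (grid size - 1)
    rows and columns, clipped so the window still fits the grid.
    """

    rho: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")


@dataclass(frozen=True)
class Landscape:
    """A drawn ground truth: the grid plus (in theory mode) window anchors.

    Anchors are 0-based (row, col) of a window's top-left cell, row-major.
    """

    truth: np.ndarray
    mode: str
    spec: GridSpec = field(default_factory=GridSpec)
    true_anchor: Optional[Anchor] = None
    predicted_anchor: Optional[Anchor] = None

    def __post_init__(self) -> None:
        truth = np.asarray(self.truth, dtype=np.int8)
        object.__setattr__(self, "truth", truth)
        if truth.shape != (self.spec.n_rows, self.spec.n_cols):
            raise ValueError("truth grid does not match spec dimensions")
        if not np.isin(truth, (0, 1)).all():
            raise ValueError("truth cells must be 0 or 1")
        if self.mode not in (DISCOVERY, THEORY):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == DISCOVERY:
            if self.true_anchor is not None or self.predicted_anchor is not None:
                raise ValueError("discovery landscapes carry no window anchors")
        else:
            if self.true_anchor is None:
                raise ValueError("theory landscapes need a true_anchor")
            for anchor in (self.true_anchor, self.predicted_anchor):
                if anchor is not None:
                    self._check_window_fits(anchor)
            self._check_containment()

    def _check_window_fits(self, anchor: Anchor) -> None:
        mr, mc = self.spec.max_anchor
        if not (0 <= anchor[0] <= mr and 0 <= anchor[1] <= mc):
            raise ValueError(f"window at {anchor} does not fit the grid")

    def _check_containment(self) -> None:
        ws = self.spec.window_size
        r0, c0 = self.true_anchor
        inside = self.truth[r0 : r0 + ws, c0 : c0 + ws].sum()
        if inside != self.truth.sum():
            raise ValueError("theory-mode effects must all lie in the true window")

    @property
    def n_effects(self) -> int:
        return int(self.truth.sum())

    def window_cells(self, anchor: Anchor) -> np.ndarray:
        """Flat row-major cell indices of the window at ``anchor``."""
        ws = self.spec.window_size
        rows = np.arange(anchor[0], anchor[0] + ws)
        cols = np.arange(anchor[1], anchor[1] + ws)
        return (rows[:, None] * self.spec.n_cols + cols[None, :]).ravel()

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "truth": self.truth.tolist(),
            "mode": self.mode,
            "spec": {
                "n_rows": self.spec.n_rows,
                "n_cols": self.spec.n_cols,
                "window_size": self.spec.window_size,
                "p_h1": self.spec.p_h1,
            },
            "true_anchor": list(self.true_anchor) if self.true_anchor else None,
            "predicted_anchor": (
                list(self.predicted_anchor) if self.predicted_anchor else None
            ),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, doc: dict) -> "Landscape":
        spec = GridSpec(**doc["spec"])
        anchors = {
            key: tuple(doc[key]) if doc.get(key) is not None else None
            for key in ("true_anchor", "predicted_anchor")
        }
        return cls(
            truth=np.array(doc["truth"], dtype=np.int8),
            mode=doc["mode"],
            spec=spec,
            **anchors,
        )

    @classmethod
    def from_json(cls, text: str) -> "Landscape":
        return cls.from_dict(json.loads(text))


def generate_discovery_landscape(
    spec: GridSpec, rng: np.random.Generator
) -> Landscape:
    """Draw a discovery-mode grid: each cell 1 independently with p_h1."""
    truth = (rng.random((spec.n_rows, spec.n_cols)) < spec.p_h1).astype(np.int8)
    return Landscape(truth=truth, mode=DISCOVERY, spec=spec)


def generate_theory_landscape(spec: GridSpec, rng: np.random.Generator) -> Landscape:
    """Draw a theory-mode grid with all effects clustered in one window.

    The window anchor is uniform over all positions where it fits.  The
    effect count is Binomial(n_cells, p_h1) — the same marginal prevalence
    as discovery mode — capped at the window capacity; the drawn cells are
    distinct and uniform inside the window.  The predicted window is placed
    separately by :func:`place_theory_window`.
    """
    mr, mc = spec.max_anchor
    anchor = (int(rng.integers(0, mr + 1)), int(rng.integers(0, mc + 1)))
    capacity = spec.window_size**2
    count = int(rng.binomial(spec.n_cells, spec.p_h1))
    if count > capacity:
        logger.info(
            "effect count %d exceeds window capacity %d; capping", count, capacity
        )
        count = capacity
    truth = np.zeros((spec.n_rows, spec.n_cols), dtype=np.int8)
    if count:
        flat = rng.choice(capacity, size=count, replace=False)
        rows = anchor[0] + flat // spec.window_size
        cols = anchor[1] + flat % spec.window_size
        truth[rows, cols] = 1
    return Landscape(truth=truth, mode=THEORY, spec=spec, true_anchor=anchor)


def _round_half_away_from_zero(x: float) -> int:
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def place_theory_window(
    landscape: Landscape, quality: TheoryQuality, rng: np.random.Generator
) -> Landscape:
    """Place the theory's predicted window at distance (1 - rho)*(size - 1).

    The displacement magnitude applies per dimension; the sign is chosen
    uniformly among directions in which any displacement is feasible, and
    the anchor is clipped so the predicted window fits the grid.  rho = 1
    reproduces the true anchor exactly.
    """
    if landscape.mode != THEORY or landscape.true_anchor is None:
        raise ValueError("predicted window requires a theory-mode landscape")
    spec = landscape.spec
    anchor = []
    for dim, extent in enumerate((spec.n_rows, spec.n_cols)):
        delta = _round_half_away_from_zero((1.0 - quality.rho) * (extent - 1))
        a = landscape.true_anchor[dim]
        hi = spec.max_anchor[dim]
        if delta == 0:
            anchor.append(a)
            continue
        feasible = [s for s in (-1, 1) if int(np.clip(a + s * delta, 0, hi)) != a]
        if not feasible:  # window fills the grid dimension; nowhere to go
            anchor.append(a)
            continue
        sign = feasible[rng.integers(0, len(feasible))]
        anchor.append(int(np.clip(a + sign * delta, 0, hi)))
    return replace(landscape, predicted_anchor=tuple(anchor))


def sample_target_cell(
    landscape: Landscape, rng: np.random.Generator
) -> Tuple[int, int]:
    """Pick one cell to experiment on (with replacement across calls)."""
    row, col = sample_target_cells(landscape, 1, rng)
    return int(row[0]), int(col[0])


def sample_target_cells(
    landscape: Landscape, size: int, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorized target sampling: ``size`` iid cells as (rows, cols)."""
    spec = landscape.spec
    if landscape.mode == DISCOVERY:
        rows = rng.integers(0, spec.n_rows, size=size)
        cols = rng.integers(0, spec.n_cols, size=size)
        return rows, cols
    if landscape.predicted_anchor is None:
        raise ValueError("theory-mode targeting requires predicted_anchor")
    ws = spec.window_size
    r0, c0 = landscape.predicted_anchor
    rows = r0 + rng.integers(0, ws, size=size)
    cols = c0 + rng.integers(0, ws, size=size)
    return rows, cols
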