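"""Fit-percentage grid over component combinations and model selection.

A higher fit percentage can always be achieved by adding components, so
the number of components per mode is chosen by scanning a grid of
(P, Q, R) combinations and weighing fit against the number of free
parameters.

Only *feasible* combinations are scanned: a Tucker3 core with P > Q*R
(or any permutation thereof) is algebraically equivalent to the model
with P = Q*R -- the surplus components cannot change the fit -- so
combinations violating the min-product condition P <= QR, Q <= PR,
R <= PQ are redundant and omitted.  Every fitted model warm starts from
the orthonormally padded solutions of all maximal dominated grid
entries, which guarantees fit percentages are non-decreasing along
every coordinate of the (feasible) grid.

The selection rule is an elbow on component additions: pick the
smallest model (by total component count) for which no minimal
strictly-larger grid entry improves fit by at least
``min_gain_percent`` points.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .tucker import Tucker3, Tucker3Results, hosvd_init

__all__ = [
    "FitGrid",
    "SelectionResult",
    "free_parameters",
    "feasible",
    "grid_search",
    "select_model",
]


def free_parameters(n: int, m: int, T: int, P: int, Q: int, R: int) -> int:
    """Free parameters of a Tucker3 model after the rotational correction.

    Loadings contribute nP + mQ + TR and the core PQR; orthonormality
    plus within-mode rotational indeterminacy remove P^2 + Q^2 + R^2.
    """
    return n * P + m * Q + T * R + P * Q * R - P * P - Q * Q - R * R


def feasible(P: int, Q: int, R: int) -> bool:
    """Min-product condition: each mode's count at most the others' product."""
    return P <= Q * R and Q <= P * R and R <= P * Q


def _pad_orthonormal(M: np.ndarray, k: int, basis: np.ndarray) -> np.ndarray:
    """Extend orthonormal columns of M to k columns using a full basis."""
    if M.shape[1] >= k:
        return M[:, :k]
    Qm, _ = np.linalg.qr(np.hstack([M, basis]))
    return np.hstack([M, Qm[:, M.shape[1]:k]])


def _dominates(a: tuple, b: tuple) -> bool:
    """a strictly dominates b: componentwise >= with at least one >."""
    return a != b and all(x >= y for x, y in zip(a, b))


@dataclass
class FitGrid:
    """Fit percentage and parameter count per feasible (P, Q, R)."""

    table: pd.DataFrame          # columns P, Q, R, fit_percent, free_params
    shape: tuple[int, int, int]  # (n, m, T) of the fitted cube
    models: dict = field(default_factory=dict, repr=False)

    def fits(self) -> dict[tuple[int, int, int], float]:
        return {
            (int(r.P), int(r.Q), int(r.R)): float(r.fit_percent)
            for r in self.table.itertuples()
        }

    def fit_at(self, P: int, Q: int, R: int) -> float:
        try:
            return self.fits()[(P, Q, R)]
        except KeyError:
            raise KeyError(f"combination ({P},{Q},{R}) not in grid") from None

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path: str | Path, shape=(0, 0, 0)) -> "FitGrid":
        return cls(table=pd.read_csv(path), shape=tuple(shape))


def grid_search(
    pre,
    max_P: int,
    max_Q: int,
    max_R: int,
    tol: float = 1e-6,
    max_iter: int = 200,
    n_starts: int = 1,
    seed: int = 0,
    keep_models: bool = False,
) -> FitGrid:
    """Fit every feasible (P, Q, R) within the given bounds.

    Combinations are visited in ascending lexicographic order so each
    fit can warm start from its already-fitted dominated entries; the
    scanning tolerance is looser than a final fit's because only fit
    differences of the order of tenths of a point matter for selection.
    """
    model0 = Tucker3(pre, (1, 1, 1))
    n, m, T = model0.X.shape
    if not (1 <= max_P <= n and 1 <= max_Q <= m and 1 <= max_R <= T):
        raise ValueError(
            f"grid bounds ({max_P},{max_Q},{max_R}) exceed mode sizes ({n},{m},{T})"
        )
    # full-mode HOSVD bases used to pad warm starts deterministically
    fullA, fullB, fullC = hosvd_init(
        model0.X, min(n, m * T), min(m, n * T), min(T, n * m)
    )
    solutions: dict[tuple[int, int, int], Tucker3Results] = {}
    rows = []
    combos = [
        (P, Q, R)
        for P in range(1, max_P + 1)
        for Q in range(1, max_Q + 1)
        for R in range(1, max_R + 1)
        if feasible(P, Q, R)
    ]
    for P, Q, R in combos:
        dominated = [c for c in solutions if _dominates((P, Q, R), c)]
        maximal = [
            c for c in dominated
            if not any(_dominates(d, c) for d in dominated)
        ]
        inits = [
            (
                _pad_orthonormal(solutions[c].A, P, fullA),
                _pad_orthonormal(solutions[c].B, Q, fullB),
                _pad_orthonormal(solutions[c].C, R, fullC),
            )
            for c in maximal
        ]
        res = Tucker3(pre, (P, Q, R)).fit(
            tol=tol, max_iter=max_iter, n_starts=n_starts, seed=seed, inits=inits
        )
        solutions[(P, Q, R)] = res
        rows.append(
            {
                "P": P, "Q": Q, "R": R,
                "fit_percent": res.fit_percent,
                "free_params": free_parameters(n, m, T, P, Q, R),
            }
        )
    table = pd.DataFrame(rows)
    return FitGrid(
        table=table, shape=(n, m, T), models=solutions if keep_models else {}
    )


@dataclass
class SelectionResult:
    selected: tuple[int, int, int]
    fit_percent: float
    candidates: list[tuple[int, int, int]]  # other elbow-stable combinations

    def __iter__(self):
        return iter(self.selected)


def select_model(grid: FitGrid, min_gain_percent: float = 1.0) -> SelectionResult:
    """Pick the smallest model whose upward fit gains all fall short.

    A grid entry is *stable* when every minimal strictly-dominating
    entry present in the grid improves fit by less than
    ``min_gain_percent`` points.  Among stable entries the one with the
    smallest total component count wins (ties broken lexicographically
    by (P, Q, R)), so the rule is deterministic and monotone: raising
    the threshold never selects a larger model.
    """
    if grid.table.empty:
        raise ValueError("empty fit grid")
    fits = grid.fits()
    stable = []
    for c, f in fits.items():
        larger = [d for d in fits if _dominates(d, c)]
        minimal = [d for d in larger if not any(_dominates(d, e) for e in larger if e != d)]
        if all(fits[d] - f < min_gain_percent for d in minimal):
            stable.append(c)
    stable.sort(key=lambda c: (sum(c), c))
    sel = stable[0]
    return SelectionResult(
        selected=sel, fit_percent=fits[sel], candidates=stable[1:]
    )
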