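"""Tucker3 three-mode principal component analysis.

The model decomposes a three-mode array X (persons x symptoms x times)
as

    X[i,j,k] = sum_{p,q,r} A[i,p] B[j,q] C[k,r] G[p,q,r] + E[i,j,k]

with column-orthonormal loading matrices A (n x P), B (m x Q),
C (T x R) and a free core array G (P x Q x R) whose entries quantify
how person, symptom and time components interact.  Fitting is by
alternating least squares (higher-order orthogonal iteration): each
mode's loadings are updated to the leading singular vectors of the
cube projected onto the other two modes' current loadings, which never
decreases the explained sum of squares.  Fit is reported as the
percentage of the preprocessed cube's total sum of squares captured by
the reconstruction.

Identification conventions: within each mode, columns are ordered by
descending explained sum of squares (the squared norm of the matching
core slice) and signed so the largest-magnitude entry of each column
is positive, with compensating flips absorbed into the core.  The
solution remains rotation-indeterminate within each mode, as in any
Tucker model; the conventions merely make output reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .cube import DataCube
from .preprocess import PreprocessedCube

__all__ = [
    "Tucker3",
    "Tucker3Results",
    "ResidualSummary",
    "unfold",
    "refold",
    "reconstruct",
    "compute_core",
    "hosvd_init",
    "fit_als",
    "fit_percentage",
]

MODE_NAMES = {"person": 0, "symptom": 1, "time": 2}


def _mode_index(mode) -> int:
    if isinstance(mode, str):
        try:
            return MODE_NAMES[mode]
        except KeyError:
            raise ValueError(f"unknown mode {mode!r}; expected person/symptom/time")
    mode = int(mode)
    if mode not in (0, 1, 2):
        raise ValueError(f"mode index must be 0, 1 or 2, got {mode}")
    return mode


def _as_array(data) -> np.ndarray:
    if isinstance(data, (DataCube, PreprocessedCube)):
        return np.asarray(data.values, dtype=float)
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 3:
        raise ValueError("expected a three-mode array")
    return arr


def unfold(cube, mode) -> np.ndarray:
    """Mode-n matricization.

    The mode-0 (person) unfolding is n x (m*T) with column j + (t-1)*m
    (1-based): the symptom index varies fastest.  Other modes are
    analogous, with the remaining modes kept in original order and the
    first of them fastest.
    """
    X = _as_array(cube)
    k = _mode_index(mode)
    return np.reshape(np.moveaxis(X, k, 0), (X.shape[k], -1), order="F")


def refold(mat: np.ndarray, mode, shape: tuple[int, int, int]) -> np.ndarray:
    """Inverse of :func:`unfold` for the given cube shape."""
    k = _mode_index(mode)
    rest = [s for i, s in enumerate(shape) if i != k]
    X = np.reshape(np.asarray(mat), (shape[k], *rest), order="F")
    return np.moveaxis(X, 0, k)


def reconstruct(A: np.ndarray, B: np.ndarray, C: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Evaluate the trilinear model sum_{pqr} a_ip b_jq c_kr g_pqr."""
    A, B, C, G = (np.asarray(x, dtype=float) for x in (A, B, C, G))
    if G.shape != (A.shape[1], B.shape[1], C.shape[1]):
        raise ValueError(
            f"core shape {G.shape} does not match loading columns "
            f"({A.shape[1]}, {B.shape[1]}, {C.shape[1]})"
        )
    return np.einsum("ip,jq,kr,pqr->ijk", A, B, C, G, optimize=True)


def _check_orthonormal(M: np.ndarray, name: str, tol: float = 1e-8) -> None:
    gram = M.T @ M
    if not np.allclose(gram, np.eye(M.shape[1]), atol=tol):
        raise ValueError(f"{name} does not have orthonormal columns")


def compute_core(cube, A: np.ndarray, B: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Least-squares core for orthonormal loadings: G = X x_1 A' x_2 B' x_3 C'."""
    X = _as_array(cube)
    for M, name in ((A, "A"), (B, "B"), (C, "C")):
        _check_orthonormal(np.asarray(M), name)
    return np.einsum("ijk,ip,jq,kr->pqr", X, A, B, C, optimize=True)


def _leading_left_singular(mat: np.ndarray, k: int) -> np.ndarray:
    U, _, _ = scipy.linalg.svd(mat, full_matrices=False, lapack_driver="gesdd")
    if U.shape[1] >= k:
        return U[:, :k]
    # fewer singular vectors than components requested (the projected
    # subproblem can have lower rank than k, e.g. P*R < Q); extend with a
    # deterministic orthonormal complement -- the extra columns carry zero
    # explained SS and are free to rotate in later sweeps
    Qm, _ = np.linalg.qr(np.hstack([U, np.eye(U.shape[0])]))
    return np.hstack([U, Qm[:, U.shape[1]:k]])


def hosvd_init(cube, P: int, Q: int, R: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Truncated higher-order SVD: leading singular vectors per unfolding."""
    X = _as_array(cube)
    n, m, T = X.shape
    _validate_components(n, m, T, P, Q, R)
    A = _leading_left_singular(unfold(X, 0), P)
    B = _leading_left_singular(unfold(X, 1), Q)
    C = _leading_left_singular(unfold(X, 2), R)
    return _fix_signs_loadings(A), _fix_signs_loadings(B), _fix_signs_loadings(C)


def _validate_components(n, m, T, P, Q, R) -> None:
    if not (1 <= P <= n and 1 <= Q <= m and 1 <= R <= T):
        raise ValueError(
            f"component numbers (P,Q,R)=({P},{Q},{R}) must lie in "
            f"[1,n]x[1,m]x[1,T] = [1,{n}]x[1,{m}]x[1,{T}]"
        )


def _fix_signs_loadings(M: np.ndarray) -> np.ndarray:
    """Flip columns so the largest-|entry| of each is positive (no core)."""
    M = M.copy()
    for c in range(M.shape[1]):
        i = int(np.argmax(np.abs(M[:, c])))
        if M[i, c] < 0:
            M[:, c] = -M[:, c]
    return M


def _random_orthonormal(rng: np.random.Generator, rows: int, cols: int) -> np.ndarray:
    Qm, _ = np.linalg.qr(rng.standard_normal((rows, cols)))
    return Qm[:, :cols]


def _canonicalize(A, B, C, G):
    """Apply the column-ordering and sign conventions, compensating in G."""
    mats = [A.copy(), B.copy(), C.copy()]
    G = G.copy()
    for mode in range(3):
        ss = np.sum(np.moveaxis(G, mode, 0).reshape(G.shape[mode], -1) ** 2, axis=1)
        order = np.argsort(-ss, kind="stable")
        mats[mode] = mats[mode][:, order]
        G = np.take(G, order, axis=mode)
        for c in range(mats[mode].shape[1]):
            i = int(np.argmax(np.abs(mats[mode][:, c])))
            if mats[mode][i, c] < 0:
                mats[mode][:, c] = -mats[mode][:, c]
                sl = [slice(None)] * 3
                sl[mode] = c
                G[tuple(sl)] = -G[tuple(sl)]
    return mats[0], mats[1], mats[2], G


@dataclass
class ResidualSummary:
    """Sums of squares of a fitted model on the preprocessed cube."""

    sse: float
    sst: float

    @property
    def fit_percent(self) -> float:
        return 100.0 * (1.0 - self.sse / self.sst)


@dataclass
class Tucker3Results:
    """Fitted Tucker3 decomposition.

    Attributes
    ----------
    A, B, C : person-, symptom- and time-mode loadings, column-orthonormal.
    core : P x Q x R core array of mode-component interactions.
    fit_percent : percentage of the (preprocessed) total sum of squares
        explained by the reconstruction.
    fit_trace : per-iteration fit values of the winning start (non-decreasing).
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    core: np.ndarray
    fit_percent: float
    iterations: int
    converged: bool
    fit_trace: np.ndarray
    sst: float
    n_starts: int = 1
    persons: list[str] | None = None
    items: list[str] | None = None
    times: list[int] | None = None

    @property
    def n_components(self) -> tuple[int, int, int]:
        return (self.A.shape[1], self.B.shape[1], self.C.shape[1])

    @property
    def sse(self) -> float:
        return self.sst * (1.0 - self.fit_percent / 100.0)

    def reconstruct(self) -> np.ndarray:
        return reconstruct(self.A, self.B, self.C, self.core)

    def residual_summary(self) -> ResidualSummary:
        return ResidualSummary(sse=self.sse, sst=self.sst)

    def loadings_frame(self, mode) -> pd.DataFrame:
        k = _mode_index(mode)
        M = (self.A, self.B, self.C)[k]
        labels = (self.persons, self.items, self.times)[k]
        if labels is None:
            labels = list(range(1, M.shape[0] + 1))
        cols = [f"comp_{c + 1}" for c in range(M.shape[1])]
        return pd.DataFrame(M, index=labels, columns=cols)

    def core_frame(self) -> pd.DataFrame:
        P, Q, R = self.core.shape
        rows = [
            {"person_component": p + 1, "symptom_component": q + 1,
             "time_component": r + 1, "value": self.core[p, q, r]}
            for p in range(P) for q in range(Q) for r in range(R)
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        P, Q, R = self.n_components
        n, m, T = self.A.shape[0], self.B.shape[0], self.C.shape[0]
        lines = [
            "Tucker3 (three-mode PCA) results",
            "=" * 40,
            f"cube shape (n, m, T):      ({n}, {m}, {T})",
            f"components (P, Q, R):      ({P}, {Q}, {R})",
            f"fit percentage:            {self.fit_percent:.2f}",
            f"iterations:                {self.iterations}"
            f" ({'converged' if self.converged else 'not converged'})",
            f"starts:                    {self.n_starts}",
            "",
            "core array (explained SS per person-component slice):",
        ]
        for p in range(P):
            ss = float(np.sum(self.core[p] ** 2))
            lines.append(f"  person component {p + 1}: {100 * ss / self.sst:.2f}%")
        return "\n".join(lines)


class Tucker3:
    """Tucker3 model of a (preprocessed) three-mode data cube.

    Parameters
    ----------
    data : PreprocessedCube, DataCube or 3-d array
        The array to decompose.  For the heterogeneity analysis this is
        the fiber-centered, slab-normalized cube.
    n_components : (P, Q, R)
        Number of person-, symptom- and time-mode components.
    """

    def __init__(self, data, n_components: tuple[int, int, int]):
        self.data = data
        self.X = _as_array(data)
        if not np.isfinite(self.X).all():
            raise ValueError("data cube contains non-finite values")
        P, Q, R = (int(c) for c in n_components)
        n, m, T = self.X.shape
        _validate_components(n, m, T, P, Q, R)
        self.n_components = (P, Q, R)
        self.sst = float(np.sum(self.X**2))
        if self.sst == 0:
            raise ValueError("all-zero cube: total sum of squares is zero")
        if isinstance(data, (DataCube, PreprocessedCube)):
            self.persons, self.items, self.times = (
                list(data.persons), list(data.items), list(data.times),
            )
        else:
            self.persons = self.items = self.times = None

    # -- single ALS run -----------------------------------------------------
    def _als(self, A, B, C, tol, max_iter):
        X, sst = self.X, self.sst
        P, Q, R = self.n_components
        G = np.einsum("ijk,ip,jq,kr->pqr", X, A, B, C, optimize=True)
        fit = 100.0 * float(np.sum(G**2)) / sst
        trace = [fit]
        converged = False
        for _ in range(max_iter):
            Y = np.einsum("ijk,jq,kr->iqr", X, B, C, optimize=True)
            A = _leading_left_singular(Y.reshape(X.shape[0], Q * R), P)
            Y = np.einsum("ijk,ip,kr->jpr", X, A, C, optimize=True)
            B = _leading_left_singular(Y.reshape(X.shape[1], P * R), Q)
            Y = np.einsum("ijk,ip,jq->kpq", X, A, B, optimize=True)
            C = _leading_left_singular(Y.reshape(X.shape[2], P * Q), R)
            G = np.einsum("ijk,ip,jq,kr->pqr", X, A, B, C, optimize=True)
            new_fit = 100.0 * float(np.sum(G**2)) / sst
            trace.append(new_fit)
            if abs(new_fit - fit) < tol * max(fit, 1e-12):
                fit = new_fit
                converged = True
                break
            fit = new_fit
        return A, B, C, G, fit, np.asarray(trace), converged

    def fit(
        self,
        tol: float = 1e-8,
        max_iter: int = 500,
        n_starts: int = 5,
        seed: int = 0,
        inits: Sequence[tuple[np.ndarray, np.ndarray, np.ndarray]] | None = None,
    ) -> Tucker3Results:
        """Fit by ALS over multiple starts and return the best solution.

        The truncated HOSVD start is always included; the remaining
        ``n_starts - 1`` starts use seeded random orthonormal loadings.
        Extra warm starts (e.g. padded solutions of smaller models) can
        be supplied via ``inits``.  Convergence: relative fit change
        below ``tol``.
        """
        n, m, T = self.X.shape
        P, Q, R = self.n_components
        starts: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = [
            hosvd_init(self.X, P, Q, R)
        ]
        if inits:
            starts.extend((np.asarray(a), np.asarray(b), np.asarray(c)) for a, b, c in inits)
        for k in range(max(0, int(n_starts) - 1)):
            rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, k])
            starts.append(
                (
                    _random_orthonormal(rng, n, P),
                    _random_orthonormal(rng, m, Q),
                    _random_orthonormal(rng, T, R),
                )
            )
        best = None
        for A0, B0, C0 in starts:
            res = self._als(A0, B0, C0, tol, max_iter)
            if best is None or res[4] > best[4] + 1e-12:
                best = res
        A, B, C, G, fit, trace, converged = best
        A, B, C, G = _canonicalize(A, B, C, G)
        return Tucker3Results(
            A=A, B=B, C=C, core=G, fit_percent=fit,
            iterations=len(trace) - 1, converged=converged, fit_trace=trace,
            sst=self.sst, n_starts=len(starts),
            persons=self.persons, items=self.items, times=self.times,
        )


def fit_als(
    pre,
    P: int,
    Q: int,
    R: int,
    tol: float = 1e-8,
    max_iter: int = 500,
    n_starts: int = 5,
    seed: int = 0,
    inits=None,
) -> Tucker3Results:
    """Functional wrapper: ``Tucker3(pre, (P, Q, R)).fit(...)``."""
    return Tucker3(pre, (P, Q, R)).fit(
        tol=tol, max_iter=max_iter, n_starts=n_starts, seed=seed, inits=inits
    )


def fit_percentage(pre, model: Tucker3Results) -> ResidualSummary:
    """Recompute SSE/SST of a fitted model against a (preprocessed) cube."""
    X = _as_array(pre)
    sst = float(np.sum(X**2))
    if sst == 0:
        raise ValueError("total sum of squares is zero; fit percentage undefined")
    if model.reconstruct().shape != X.shape:
        raise ValueError("model shapes do not match the cube")
    sse = float(np.sum((X - model.reconstruct()) ** 2))
    return ResidualSummary(sse=sse, sst=sst)
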