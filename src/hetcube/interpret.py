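"""Interpretation tables for a fitted decomposition.

Component loadings become assignment tables (each item or time point is
allocated to the component on which it has the highest absolute score,
the "boldface" rule), the core array becomes a long-format labelled
interaction table, and Tucker congruence matching aligns estimated with
reference components for recovery studies.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .tucker import Tucker3Results

__all__ = [
    "assign_components",
    "core_table",
    "congruence",
    "match_components",
    "MatchResult",
]


def assign_components(
    loadings: np.ndarray,
    labels: Sequence,
    component_names: Sequence[str] | None = None,
    tie_tol: float = 0.05,
) -> pd.DataFrame:
    """Allocate each row entity to the component with the largest |score|.

    Ties (within exact equality) go to the lowest component index; rows
    whose top two absolute scores differ by less than ``tie_tol`` are
    flagged as borderline.  Assignments ignore sign; the sign of the
    assigned score is reported separately.
    """
    L = np.asarray(loadings, dtype=float)
    if L.ndim != 2 or L.size == 0:
        raise ValueError("loadings must be a non-empty 2-d matrix")
    if not np.isfinite(L).all():
        raise ValueError("loadings contain non-finite values")
    if len(labels) != L.shape[0]:
        raise ValueError("label count does not match loading rows")
    ncomp = L.shape[1]
    if component_names is None:
        component_names = [f"comp_{c + 1}" for c in range(ncomp)]
    absL = np.abs(L)
    assigned = absL.argmax(axis=1)  # argmax takes the first (lowest) index on ties
    rows = []
    for i, label in enumerate(labels):
        top = np.sort(absL[i])[::-1]
        borderline = ncomp > 1 and (top[0] - top[1]) < tie_tol
        rows.append(
            {
                "label": label,
                **{component_names[c]: L[i, c] for c in range(ncomp)},
                "assigned": int(assigned[i]) + 1,
                "assigned_sign": int(np.sign(L[i, assigned[i]])) or 1,
                "borderline": bool(borderline),
            }
        )
    return pd.DataFrame(rows)


def core_table(
    model: Tucker3Results | np.ndarray,
    person_labels: Sequence[str] | None = None,
    symptom_labels: Sequence[str] | None = None,
    time_labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Long-format labelled core array, person-component major.

    One row per (person, symptom, time) component triple; ``value`` is
    the corresponding core entry, exactly as stored.
    """
    G = model.core if isinstance(model, Tucker3Results) else np.asarray(model)
    P, Q, R = G.shape
    def _names(labels, k, default):
        if labels is None:
            return [f"{default} {i + 1}" for i in range(k)]
        return list(labels)
    pl = _names(person_labels, P, "person component")
    ql = _names(symptom_labels, Q, "symptom component")
    rl = _names(time_labels, R, "time component")
    rows = [
        {"person_component": pl[p], "symptom_component": ql[q],
         "time_component": rl[r], "value": G[p, q, r]}
        for p in range(P) for q in range(Q) for r in range(R)
    ]
    return pd.DataFrame(rows)


def congruence(x: np.ndarray, y: np.ndarray) -> float:
    """Tucker congruence phi = sum(xy) / sqrt(sum(x^2) sum(y^2))."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    nx, ny = np.sqrt(np.sum(x**2)), np.sqrt(np.sum(y**2))
    if nx == 0 or ny == 0:
        raise ValueError("congruence undefined for a zero-norm column")
    return float(np.dot(x, y) / (nx * ny))


@dataclass
class MatchResult:
    """Greedy congruence matching of estimated to reference components."""

    permutation: tuple[int, ...]   # permutation[j] = estimated column for ref column j
    phis: np.ndarray               # signed congruence per reference column
    mean_abs_phi: float


def match_components(estimated: np.ndarray, reference: np.ndarray) -> MatchResult:
    """Match estimated columns to reference columns by maximum |congruence|.

    Components are sign- and order-indeterminate, so matching is greedy
    on absolute congruence; the signed values are reported so a flipped
    component shows phi close to -1.
    """
    E = np.asarray(estimated, dtype=float)
    F = np.asarray(reference, dtype=float)
    if E.shape != F.shape:
        raise ValueError(f"shape mismatch: {E.shape} vs {F.shape}")
    k = E.shape[1]
    phi = np.empty((k, k))
    for a in range(k):
        for b in range(k):
            phi[a, b] = congruence(F[:, a], E[:, b])
    perm = [-1] * k
    phis = np.zeros(k)
    absphi = np.abs(phi).copy()
    for _ in range(k):
        a, b = np.unravel_index(np.argmax(absphi), absphi.shape)
        perm[a] = int(b)
        phis[a] = phi[a, b]
        absphi[a, :] = -np.inf
        absphi[:, b] = -np.inf
    return MatchResult(
        permutation=tuple(perm), phis=phis, mean_abs_phi=float(np.mean(np.abs(phis)))
    )
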