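"""Synthetic data generators for the full analysis pipeline.

The original clinic data behind this kind of analysis are rarely
deposited, so every input is emulated here: continuous cubes with a
planted Tucker3 structure (for recovery and model-selection studies),
QIDS-like ordinal symptom cubes whose heterogeneity pattern mirrors a
depression cohort -- a shared downward severity trend plus a planted
3 (person) x 2 (symptom-domain) x 2 (time-phase) interaction -- and
categorical/trajectory datasets for the latent-class and
growth-mixture baselines.  All generators are pure functions of their
spec including the seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cube import DataCube, QIDS_RECODED_ITEMS
from .tucker import compute_core, hosvd_init, reconstruct

__all__ = [
    "PlantedCubeSpec",
    "QidsLikeSpec",
    "generate_planted_cube",
    "generate_qids_like",
    "generate_lca_data",
    "generate_growth_data",
    "noise_sd_for_expected_fit",
]


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *stream])


def _random_orthonormal(rng, rows, cols):
    Q, _ = np.linalg.qr(rng.standard_normal((rows, cols)))
    return Q[:, :cols]


def noise_sd_for_expected_fit(signal_ss: float, size: int, fit_percent: float) -> float:
    """White-noise SD at which the expected fit is ``fit_percent``.

    Expected fit of the true-size model is approximately
    100 * signal_ss / (signal_ss + size * sd^2) for large arrays.
    """
    if not 0 < fit_percent < 100:
        raise ValueError("target fit must lie strictly between 0 and 100")
    return float(np.sqrt(signal_ss * (100.0 - fit_percent) / (fit_percent * size)))


@dataclass
class PlantedCubeSpec:
    """Continuous cube with exact low-multilinear-rank structure plus noise.

    With ``noise_sd=None`` the noise level is derived from the realised
    signal so the construction-expected fit equals ``target_fit``
    (default 80, the explained-variance regime typical of questionnaire
    cubes of this size).
    """

    n: int = 82
    m: int = 12
    T: int = 9
    P: int = 3
    Q: int = 2
    R: int = 2
    core_scale: float = 1.0
    noise_sd: float | None = None
    target_fit: float = 80.0
    seed: int = 0

    def __post_init__(self):
        if not (1 <= self.P <= self.n and 1 <= self.Q <= self.m and 1 <= self.R <= self.T):
            raise ValueError("component counts must lie within mode sizes")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def generate_planted_cube(spec: PlantedCubeSpec) -> tuple[DataCube, dict]:
    """Draw a planted Tucker3 cube and its canonical ground truth.

    Loadings are random orthonormal bases and the core is Gaussian.  The
    returned ground-truth loadings/core are the exact truncated HOSVD of
    the noise-free signal -- the canonical representative of the
    (rotation-indeterminate) planted solution -- so estimated components
    can be compared column-wise after sign/permutation matching.
    """
    rng = _rng(spec.seed, 11)
    A = _random_orthonormal(rng, spec.n, spec.P)
    B = _random_orthonormal(rng, spec.m, spec.Q)
    C = _random_orthonormal(rng, spec.T, spec.R)
    G = spec.core_scale * rng.standard_normal((spec.P, spec.Q, spec.R))
    signal = reconstruct(A, B, C, G)
    signal_ss = float(np.sum(signal**2))
    size = spec.n * spec.m * spec.T
    if spec.noise_sd is None:
        sd = noise_sd_for_expected_fit(signal_ss, size, spec.target_fit)
    else:
        sd = float(spec.noise_sd)
    noise = sd * rng.standard_normal(signal.shape)
    values = signal + noise
    # canonical ground truth: exact HOSVD of the noise-free signal
    Ac, Bc, Cc = hosvd_init(signal, spec.P, spec.Q, spec.R)
    Gc = compute_core(signal, Ac, Bc, Cc)
    expected_fit = 100.0 * signal_ss / (signal_ss + size * sd**2)
    cube = DataCube(
        values,
        persons=[f"P{i + 1:03d}" for i in range(spec.n)],
        items=[f"item_{j + 1}" for j in range(spec.m)],
        times=list(range(1, spec.T + 1)),
    )
    truth = {
        "A": Ac, "B": Bc, "C": Cc, "G": Gc, "signal": signal,
        "noise_sd": sd, "signal_ss": signal_ss, "expected_fit": expected_fit,
    }
    return cube, truth


# ---------------------------------------------------------------------------
# QIDS-like ordinal cubes

# 3 person archetypes x 2 symptom domains x 2 time phases, on the latent
# severity scale.  Rows: archetype; inner rows: domain (somatic/affective,
# cognitive/appetitive); columns: phase (weeks 1-5, weeks 6-9).
DEFAULT_EFFECTS = np.array(
    [
        # quick recovery: elevated everywhere early, clearly below trend late
        [[0.50, -0.40], [0.30, -0.35]],
        # persistent somatic/affective: somatic stays high, cognitive stays low
        [[0.45, 0.45], [-0.35, -0.30]],
        # increasing symptomatology: near trend early, both domains rise late
        [[-0.10, 0.55], [0.00, 0.50]],
    ]
)

#: Somatic/affective items of the recoded QIDS (the rest are
#: cognitive/appetitive): hyposomnia, sadness, concentration, interest,
#: energy, retardation, agitation.
QIDS_SOMATIC_ITEMS = ("1-3", "5", "10", "13", "14", "15", "16")


@dataclass
class QidsLikeSpec:
    """Ordinal symptom cohort with planted three-way heterogeneity.

    Defaults reflect the reference cohort layout: 82 persons, 12 recoded
    items on a 0-2 scale, 9 weekly measurements, an overall downward
    severity trend, two symptom domains, a time-phase split after week
    5, and three person archetypes.  ``raw_scale=True`` instead emits
    the 16 raw 0-3 items (hyposomnia triple, mutually exclusive
    appetite/weight pairs) to exercise the recoding path.
    """

    n: int = 82
    m: int = 12
    T: int = 9
    archetype_weights: tuple[float, ...] = (0.45, 0.30, 0.25)
    effects: np.ndarray = field(default_factory=lambda: DEFAULT_EFFECTS.copy())
    interaction_scale: float = 1.0
    baseline: float = 1.15
    trend_slope: float = -0.09      # latent units per week, shared by everyone
    person_sd: float = 0.20         # stable person severity offset
    noise_sd: float = 0.32          # occasion-level latent noise
    cutpoints: tuple[float, ...] = (0.55, 1.15)
    phase_split: int = 5            # last week of the first phase
    raw_scale: bool = False
    seed: int = 0

    def __post_init__(self):
        w = np.asarray(self.archetype_weights, dtype=float)
        if w.min() < 0 or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("archetype weights must lie on the simplex")
        if list(self.cutpoints) != sorted(self.cutpoints):
            raise ValueError("cutpoints must be strictly increasing")
        eff = np.asarray(self.effects, dtype=float)
        if eff.shape != (len(w), 2, 2):
            raise ValueError("effects must be n_archetypes x 2 domains x 2 phases")
        if self.raw_scale and self.m != 12:
            raise ValueError("raw 16-item generation requires the m=12 QIDS preset")
        if not (1 <= self.phase_split < self.T):
            raise ValueError("phase split must fall inside the follow-up window")


def _qids_domains(spec: QidsLikeSpec) -> np.ndarray:
    """0 = somatic/affective, 1 = cognitive/appetitive per item."""
    if spec.m == 12:
        return np.array([0 if it in QIDS_SOMATIC_ITEMS else 1 for it in QIDS_RECODED_ITEMS])
    n_somatic = int(round(spec.m * 7 / 12))
    return np.array([0] * n_somatic + [1] * (spec.m - n_somatic))


def generate_qids_like(spec: QidsLikeSpec) -> tuple[pd.DataFrame, dict]:
    """Long-format ordinal records with planted archetype structure.

    Latent severity is ``baseline + trend*(t-1) + person offset +
    interaction_scale * effects[archetype, domain, phase] + noise``,
    thresholded at the cutpoints into ordinal categories.
    """
    rng = _rng(spec.seed, 22)
    weights = np.asarray(spec.archetype_weights, dtype=float)
    z = rng.choice(len(weights), size=spec.n, p=weights)
    domains = _qids_domains(spec)
    phases = (np.arange(1, spec.T + 1) > spec.phase_split).astype(int)
    person_offset = spec.person_sd * rng.standard_normal(spec.n)
    trend = spec.baseline + spec.trend_slope * np.arange(spec.T)

    latent = (
        trend[None, None, :]
        + person_offset[:, None, None]
        + spec.interaction_scale * spec.effects[z][:, domains, :][:, :, phases]
        + spec.noise_sd * rng.standard_normal((spec.n, spec.m, spec.T))
    )
    if spec.raw_scale:
        # extra cutpoint yields the scarce top category of the raw scale
        cuts = np.array([*spec.cutpoints, spec.cutpoints[-1] + 0.6])
    else:
        cuts = np.asarray(spec.cutpoints)
    scores = np.searchsorted(cuts, latent, side="right")

    persons = [f"P{i + 1:03d}" for i in range(spec.n)]
    items = (
        list(QIDS_RECODED_ITEMS) if spec.m == 12
        else [f"item_{j + 1}" for j in range(spec.m)]
    )
    truth = {
        "archetypes": z,
        "domains": domains,
        "phases": phases,
        "effects": spec.interaction_scale * spec.effects,
        "latent": latent,
        "persons": persons,
        "items": items,
    }

    if not spec.raw_scale:
        cube = DataCube(scores.astype(float), persons, items, list(range(1, spec.T + 1)))
        return cube.to_long_frame().astype({"score": int}), truth

    # expand the 12 recoded items into the 16 raw QIDS items
    rows = []
    # stable per-person direction of the mutually exclusive pairs
    appetite_dir = rng.integers(0, 2, size=spec.n)   # 0 -> item 6, 1 -> item 7
    weight_dir = rng.integers(0, 2, size=spec.n)     # 0 -> item 8, 1 -> item 9
    sleep_item = rng.integers(0, 3, size=(spec.n, spec.T))  # which of items 1..3 peaks
    item_index = {it: j for j, it in enumerate(items)}
    for i, pid in enumerate(persons):
        for t in range(spec.T):
            raw = {str(k): 0 for k in range(1, 17)}
            for it in items:
                s = int(scores[i, item_index[it], t])
                if it == "1-3":
                    raw[str(1 + sleep_item[i, t])] = s
                elif it == "6/7":
                    raw["7" if appetite_dir[i] else "6"] = s
                elif it == "8/9":
                    raw["9" if weight_dir[i] else "8"] = s
                else:
                    raw[it] = s
            rows.extend(
                {"person_id": pid, "time": t + 1, "item": k, "score": v}
                for k, v in raw.items()
            )
    return pd.DataFrame(rows), truth


def generate_lca_data(
    weights: Sequence[float],
    item_probs: np.ndarray,
    n: int,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample an n x m ordinal matrix from a latent class mixture.

    Classes are drawn from ``weights``; items are conditionally
    independent given class with category distributions
    ``item_probs[k, j, :]``.  Returns the data matrix and class labels.
    """
    w = np.asarray(weights, dtype=float)
    probs = np.asarray(item_probs, dtype=float)
    if abs(w.sum() - 1.0) > 1e-9 or w.min() < 0:
        raise ValueError("class weights must lie on the simplex")
    if probs.ndim != 3 or probs.shape[0] != len(w):
        raise ValueError("item_probs must be K x m x C")
    if np.any(probs < 0) or not np.allclose(probs.sum(axis=2), 1.0, atol=1e-9):
        raise ValueError("category probabilities must sum to 1 per class and item")
    rng = _rng(seed, 33)
    K, m, C = probs.shape
    z = rng.choice(K, size=n, p=w)
    u = rng.random((n, m))
    cum = np.cumsum(probs, axis=2)[z]          # n x m x C
    X = (u[:, :, None] > cum).sum(axis=2)
    return X.astype(int), z


def generate_growth_data(
    class_specs: Sequence[tuple[float, tuple[float, float, float]]],
    n: int,
    T: int,
    kind: str = "gmm_ri",
    sigma2: float = 4.0,
    tau2: float = 2.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample n x T trajectories from a quadratic growth mixture.

    ``class_specs`` is a sequence of (weight, (b0, b1, b2)) pairs; time
    is coded 1..T.  ``kind='gmm_ri'`` adds a person-level random
    intercept with variance ``tau2``; ``kind='lcgm'`` omits it.
    Returns the trajectory matrix and class labels.
    """
    if T < 3:
        raise ValueError("need T >= 3")
    if sigma2 < 0 or tau2 < 0:
        raise ValueError("variances must be non-negative")
    if kind not in ("lcgm", "gmm_ri"):
        raise ValueError(f"unknown kind {kind!r}")
    w = np.array([s[0] for s in class_specs], dtype=float)
    betas = np.array([s[1] for s in class_specs], dtype=float)
    if abs(w.sum() - 1.0) > 1e-9 or w.min() < 0:
        raise ValueError("class weights must lie on the simplex")
    rng = _rng(seed, 44)
    t = np.arange(1, T + 1, dtype=float)
    design = np.column_stack([np.ones(T), t, t * t])
    z = rng.choice(len(w), size=n, p=w)
    Y = betas[z] @ design.T
    if kind == "gmm_ri" and tau2 > 0:
        Y = Y + np.sqrt(tau2) * rng.standard_normal(n)[:, None]
    if sigma2 > 0:
        Y = Y + np.sqrt(sigma2) * rng.standard_normal((n, T))
    return Y, z
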