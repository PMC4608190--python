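"""Centering and normalization of the data cube before decomposition.

The decomposition is meant to describe heterogeneity *around* the mean
course shared by all persons, so each (item, time) fiber is centered
across persons, removing every item's average trajectory.  Item slabs
are then rescaled to unit mean square so that high-variance items do
not dominate the least-squares fit -- the standard multiway convention
for questionnaire items.  After both steps the total sum of squares of
the cube equals n*m*T, the denominator base for fit percentages.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .cube import DataCube

__all__ = [
    "PreprocessedCube",
    "DegenerateItemError",
    "center_fibers",
    "normalize_slabs",
    "preprocess",
    "inverse_transform",
    "write_preprocessed",
    "read_preprocessed",
]


class DegenerateItemError(ValueError):
    """An item slab is constant after centering and cannot be normalized."""


@dataclass
class PreprocessedCube:
    """A centered/scaled cube plus the affine transform that produced it.

    ``values = (source - offsets) / scales`` with offsets broadcast over
    persons and scales over person-time; the inverse transform restores
    the original units exactly.
    """

    values: np.ndarray          # n x m x T
    offsets: np.ndarray         # m x T fiber means removed
    scales: np.ndarray          # m per-item scale factors
    persons: list[str]
    items: list[str]
    times: list[int]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.scales = np.asarray(self.scales, dtype=float)
        n, m, T = self.values.shape
        if self.offsets.shape != (m, T) or self.scales.shape != (m,):
            raise ValueError("offsets/scales do not match cube shape")
        if np.any(self.scales <= 0):
            raise ValueError("scales must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def total_ss(self) -> float:
        return float(np.sum(self.values**2))


def center_fibers(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Remove, per (item, time) fiber, the mean across persons.

    Returns the centered array and the m x T array of removed means.
    This is what subtracts the general mean trend of every symptom from
    each person's trajectory.
    """
    values = np.asarray(values, dtype=float)
    offsets = values.mean(axis=0)
    return values - offsets[None, :, :], offsets


def normalize_slabs(
    centered: np.ndarray, items: list[str] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Rescale each item slab to mean square one.

    Slab j is divided by sqrt(sum_it x[i,j,t]^2 / (n*T)) so that every
    item contributes equal total variance to the fit.
    """
    centered = np.asarray(centered, dtype=float)
    n, m, T = centered.shape
    ms = np.sum(centered**2, axis=(0, 2)) / (n * T)
    if np.any(ms <= 0):
        j = int(np.argmax(ms <= 0))
        label = items[j] if items is not None else str(j)
        raise DegenerateItemError(
            f"item {label!r} is constant across persons and times after "
            "centering; a zero-variance symptom cannot be normalized"
        )
    scales = np.sqrt(ms)
    return centered / scales[None, :, None], scales


def preprocess(
    cube: DataCube,
    center: bool = True,
    normalize: Literal["item_slab", "none"] = "item_slab",
) -> PreprocessedCube:
    """Center fibers across persons and scale item slabs to mean square 1."""
    values = np.asarray(cube.values, dtype=float)
    n, m, T = values.shape
    if center:
        values, offsets = center_fibers(values)
    else:
        offsets = np.zeros((m, T))
    if normalize == "item_slab":
        values, scales = normalize_slabs(values, cube.items)
    elif normalize == "none":
        scales = np.ones(m)
    else:
        raise ValueError(f"unknown normalization {normalize!r}")
    return PreprocessedCube(
        values, offsets, scales, list(cube.persons), list(cube.items), list(cube.times)
    )


def inverse_transform(pre: PreprocessedCube, approx: np.ndarray) -> np.ndarray:
    """Map an array on the preprocessed scale back to original units."""
    approx = np.asarray(approx, dtype=float)
    if approx.shape != pre.values.shape:
        raise ValueError(
            f"shape mismatch: {approx.shape} vs cube {pre.values.shape}"
        )
    return approx * pre.scales[None, :, None] + pre.offsets[None, :, :]


def write_preprocessed(pre: PreprocessedCube, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n, m, T = pre.shape
    idx = pd.MultiIndex.from_product(
        [pre.persons, pre.times, pre.items], names=["person_id", "time", "item"]
    )
    df = pd.DataFrame(idx.to_frame(index=False))
    df["value"] = pre.values.transpose(0, 2, 1).reshape(-1)
    df.to_csv(outdir / "values.csv", index=False, float_format="%.17g")
    pd.DataFrame(pre.offsets, index=pre.items, columns=pre.times).to_csv(
        outdir / "offsets.csv", index_label="item", float_format="%.17g"
    )
    pd.Series(pre.scales, index=pre.items, name="scale").to_csv(
        outdir / "scales.csv", index_label="item", float_format="%.17g"
    )
    axes = {"persons": pre.persons, "items": pre.items, "times": pre.times}
    (outdir / "axes.json").write_text(json.dumps(axes, indent=1) + "\n")


def read_preprocessed(indir: str | Path) -> PreprocessedCube:
    indir = Path(indir)
    axes = json.loads((indir / "axes.json").read_text())
    persons = [str(p) for p in axes["persons"]]
    items = [str(j) for j in axes["items"]]
    times = [int(t) for t in axes["times"]]
    n, m, T = len(persons), len(items), len(times)
    df = pd.read_csv(indir / "values.csv", dtype={"person_id": str, "item": str})
    pi = pd.Categorical(df["person_id"], categories=persons).codes
    ji = pd.Categorical(df["item"], categories=items).codes
    ti = pd.Categorical(df["time"], categories=times).codes
    values = np.full((n, m, T), np.nan)
    values[pi, ji, ti] = df["value"].to_numpy()
    offsets = pd.read_csv(indir / "offsets.csv", index_col=0).to_numpy()
    scales = pd.read_csv(indir / "scales.csv", index_col=0)["scale"].to_numpy()
    return PreprocessedCube(values, offsets, scales, persons, items, times)
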