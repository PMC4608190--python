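"""Long-format symptom records and the person x item x time data cube.

Longitudinal questionnaire data arrive as long-format records
``(person_id, time, item, score)`` with one ordinal score per person,
item and measurement occasion.  This module validates those records,
applies the QIDS recoding rules (top-category merging and collapsing of
composite/mutually-exclusive items), and assembles the complete
three-mode array -- the "data cube" -- that the decomposition operates
on.  Completeness is a hard requirement: three-mode PCA cannot handle
missing data, so persons or cells with gaps are rejected, never imputed.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LongRecord",
    "DataCube",
    "SumScoreMatrix",
    "InvalidScoreError",
    "IncompleteDataError",
    "QIDS_RAW_ITEMS",
    "QIDS_RECODED_ITEMS",
    "QIDS_ITEM_LABELS",
    "QIDS_MERGE_GROUPS",
    "merge_top_category",
    "recode_items",
    "build_cube",
    "sum_scores",
    "read_records",
    "write_records",
    "read_cube",
    "write_cube",
    "write_sum_scores",
]

MISSING_DATA_MSG = (
    "incomplete data cube: three-mode PCA cannot handle missing data; "
    "every (person, item, time) cell must be present exactly once"
)

#: The 16 raw QIDS-SR items, by questionnaire number.
QIDS_RAW_ITEMS: tuple[str, ...] = tuple(str(i) for i in range(1, 17))

#: The 12 recoded items, in the fixed presentation order used for all outputs.
QIDS_RECODED_ITEMS: tuple[str, ...] = (
    "1-3", "4", "5", "6/7", "8/9", "10", "11", "12", "13", "14", "15", "16",
)

QIDS_ITEM_LABELS: dict[str, str] = {
    "1-3": "Hyposomnia",
    "4": "Hypersomnia",
    "5": "Feeling sad",
    "6/7": "Changed appetite",
    "8/9": "Changed weight",
    "10": "Concentration",
    "11": "View of myself",
    "12": "Thoughts of death/suicide",
    "13": "General interest",
    "14": "Energy level",
    "15": "Psychomotor retardation",
    "16": "Psychomotor agitation",
}

#: Composite items: the recoded item takes the maximum of its constituents.
#: Items 1-3 probe the same sleep-onset/maintenance domain; 6 vs 7 (appetite
#: decrease/increase) and 8 vs 9 (weight decrease/increase) are mutually
#: exclusive by design, so the maximum picks the endorsed direction.
QIDS_MERGE_GROUPS: dict[str, tuple[str, ...]] = {
    "1-3": ("1", "2", "3"),
    "6/7": ("6", "7"),
    "8/9": ("8", "9"),
}

REQUIRED_COLUMNS = ("person_id", "time", "item", "score")


class InvalidScoreError(ValueError):
    """An ordinal score lies outside the allowed category set."""


class IncompleteDataError(ValueError):
    """A (person, item, time) cell is missing or duplicated."""


class LongRecord(NamedTuple):
    """One observation: a person's score on one item at one week."""

    person_id: str
    time: int
    item: str
    score: int


def _item_sort_key(item: str):
    # numeric-first ordering so "2" < "10"; composite labels sort by first number
    head = item.split("-")[0].split("/")[0]
    try:
        return (0, int(head), item)
    except ValueError:
        return (1, 0, item)


def _canonical_item_order(items: Iterable[str]) -> list[str]:
    items = list(dict.fromkeys(items))
    if set(items) == set(QIDS_RECODED_ITEMS):
        return list(QIDS_RECODED_ITEMS)
    if set(items) == set(QIDS_RAW_ITEMS):
        return list(QIDS_RAW_ITEMS)
    return sorted(items, key=_item_sort_key)


def as_records_frame(records) -> pd.DataFrame:
    """Coerce a record sequence or DataFrame to the canonical long frame."""
    if isinstance(records, pd.DataFrame):
        missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
        if missing:
            raise ValueError(f"records frame is missing columns {missing}")
        df = records.loc[:, list(REQUIRED_COLUMNS)].copy()
    else:
        df = pd.DataFrame(list(records), columns=list(REQUIRED_COLUMNS))
    if df.empty:
        raise ValueError("no records supplied")
    df["person_id"] = df["person_id"].astype(str)
    df["time"] = df["time"].astype(int)
    df["item"] = df["item"].astype(str)
    df["score"] = df["score"].astype(int)
    if (df["time"] < 1).any():
        raise ValueError("time indices must be 1-based positive integers")
    dup = df.duplicated(subset=["person_id", "time", "item"])
    if dup.any():
        first = df.loc[dup.idxmax()]
        raise IncompleteDataError(
            "duplicate record for person "
            f"{first.person_id!r}, time {first.time}, item {first.item!r}"
        )
    return df


def _canonical_sort(df: pd.DataFrame) -> pd.DataFrame:
    order = {it: k for k, it in enumerate(_canonical_item_order(df["item"]))}
    key = df["item"].map(order)
    return (
        df.assign(_k=key)
        .sort_values(["person_id", "time", "_k"], kind="stable")
        .drop(columns="_k")
        .reset_index(drop=True)
    )


def merge_top_category(records) -> pd.DataFrame:
    """Merge ordinal category 3 into category 2 (4-point -> 3-point scale).

    The highest QIDS category is endorsed too scarcely to support
    categorical modelling, so scores of 3 are recoded to 2; all other
    scores pass through unchanged.
    """
    df = as_records_frame(records)
    bad = ~df["score"].isin((0, 1, 2, 3))
    if bad.any():
        rec = df.loc[bad.idxmax()]
        raise InvalidScoreError(
            f"score {rec['score']} outside {{0,1,2,3}} for person "
            f"{rec['person_id']!r}, time {rec['time']}, item {rec['item']!r}"
        )
    out = df.copy()
    out["score"] = np.minimum(out["score"].to_numpy(), 2)
    return out


def recode_items(
    records,
    merge_groups: dict[str, tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Collapse composite item groups to single items by the maximum score.

    With the QIDS preset, the three hyposomnia items become item "1-3",
    appetite change items 6 and 7 become "6/7", and weight change items
    8 and 9 become "8/9", leaving 12 items per person-time.  Idempotent:
    already-recoded records are returned unchanged (canonically sorted).
    """
    df = as_records_frame(records)
    if (df["score"] > 2).any() or (df["score"] < 0).any():
        raise InvalidScoreError(
            "recode_items expects 3-point scores; run merge_top_category first"
        )
    groups = QIDS_MERGE_GROUPS if merge_groups is None else merge_groups
    constituents = {c: tgt for tgt, cs in groups.items() for c in cs}
    present = set(df["item"])
    if not present & set(constituents):
        # nothing to collapse -> idempotent pass-through
        return _canonical_sort(df)

    wide = df.pivot(index=["person_id", "time"], columns="item", values="score")
    for tgt, cs in groups.items():
        missing = [c for c in cs if c not in wide.columns]
        if missing:
            raise IncompleteDataError(
                f"constituent item(s) {missing} of group {tgt!r} absent from records"
            )
        block = wide[list(cs)]
        if block.isna().any().any():
            pid, t = block.isna().any(axis=1).idxmax()
            raise IncompleteDataError(
                f"constituent of item group {tgt!r} missing for person "
                f"{pid!r} at time {t}"
            )
        if len(cs) > 1:
            both = (block > 0).sum(axis=1) > 1
            if both.any():
                n_both = int(both.sum())
                logger.warning(
                    "items %s are nominally mutually exclusive but both nonzero "
                    "for %d person-time(s); taking the maximum", cs, n_both,
                )
        wide[tgt] = block.max(axis=1)
        wide = wide.drop(columns=list(cs))
    out = (
        wide.stack()
        .rename("score")
        .reset_index()
        .astype({"score": int})
        .loc[:, list(REQUIRED_COLUMNS)]
    )
    return _canonical_sort(out)


@dataclass
class DataCube:
    """Complete n x m x T array of scores with axis labels.

    ``values[i, j, t]`` is person i's score on item j at occasion t.
    All cells must be present and finite; modes must each have length
    at least 2 for a decomposition to be meaningful.
    """

    values: np.ndarray
    persons: list[str]
    items: list[str]
    times: list[int]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.persons = [str(p) for p in self.persons]
        self.items = [str(j) for j in self.items]
        self.times = [int(t) for t in self.times]
        n, m, T = self.values.shape
        if (n, m, T) != (len(self.persons), len(self.items), len(self.times)):
            raise ValueError("axis labels do not match value array shape")
        if min(n, m, T) < 2:
            raise ValueError("each mode needs length >= 2")
        if not np.isfinite(self.values).all():
            raise IncompleteDataError(MISSING_DATA_MSG)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def to_long_frame(self) -> pd.DataFrame:
        n, m, T = self.shape
        idx = pd.MultiIndex.from_product(
            [self.persons, self.times, self.items], names=["person_id", "time", "item"]
        )
        scores = self.values.transpose(0, 2, 1).reshape(-1)
        df = pd.DataFrame(idx.to_frame(index=False))
        df["score"] = scores
        return df

    def is_integer(self) -> bool:
        return bool(np.all(self.values == np.round(self.values)))


@dataclass
class SumScoreMatrix:
    """n x T matrix of per-person total severity scores."""

    values: np.ndarray
    persons: list[str]
    times: list[int]

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.persons), len(self.times)):
            raise ValueError("axis labels do not match value array shape")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.persons, columns=self.times)


def build_cube(records) -> DataCube:
    """Assemble the complete data cube from (recoded) long records.

    Persons are sorted by id, items follow the QIDS presentation order
    (natural order otherwise) and times ascend.  Any absent
    (person, item, time) cell is an error.
    """
    df = as_records_frame(records)
    persons = sorted(df["person_id"].unique())
    items = _canonical_item_order(df["item"])
    times = sorted(df["time"].unique())
    n, m, T = len(persons), len(items), len(times)
    if len(df) != n * m * T:
        raise IncompleteDataError(MISSING_DATA_MSG)
    pi = pd.Categorical(df["person_id"], categories=persons).codes
    ji = pd.Categorical(df["item"], categories=items).codes
    ti = pd.Categorical(df["time"], categories=times).codes
    values = np.full((n, m, T), np.nan)
    values[pi, ji, ti] = df["score"].to_numpy()
    if np.isnan(values).any():
        raise IncompleteDataError(MISSING_DATA_MSG)
    return DataCube(values, persons, items, times)


def sum_scores(cube: DataCube) -> SumScoreMatrix:
    """Total score per person-time: entry (i, t) = sum_j cube[i, j, t]."""
    if not cube.is_integer():
        raise ValueError("sum scores are defined only on integer ordinal cubes")
    totals = cube.values.sum(axis=1).astype(int)
    return SumScoreMatrix(totals, list(cube.persons), list(cube.times))


# ---------------------------------------------------------------------------
# plain-text IO

def read_records(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"person_id": str, "item": str})
    return as_records_frame(df)


def write_records(records, path: str | Path) -> None:
    df = _canonical_sort(as_records_frame(records))
    df.to_csv(path, index=False)


def write_cube(cube: DataCube, outdir: str | Path) -> None:
    """Serialise a cube as a long CSV plus a JSON axis-label sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = cube.to_long_frame()
    df.to_csv(outdir / "cube.csv", index=False, float_format="%.12g")
    axes = {"persons": cube.persons, "items": cube.items, "times": cube.times}
    (outdir / "axes.json").write_text(json.dumps(axes, indent=1) + "\n")


def read_cube(indir: str | Path) -> DataCube:
    indir = Path(indir)
    axes = json.loads((indir / "axes.json").read_text())
    df = pd.read_csv(indir / "cube.csv", dtype={"person_id": str, "item": str})
    n, m, T = len(axes["persons"]), len(axes["items"]), len(axes["times"])
    pi = pd.Categorical(df["person_id"], categories=[str(p) for p in axes["persons"]]).codes
    ji = pd.Categorical(df["item"], categories=[str(j) for j in axes["items"]]).codes
    ti = pd.Categorical(df["time"], categories=[int(t) for t in axes["times"]]).codes
    values = np.full((n, m, T), np.nan)
    values[pi, ji, ti] = df["score"].to_numpy(dtype=float)
    return DataCube(values, axes["persons"], axes["items"], axes["times"])


def write_sum_scores(sums: SumScoreMatrix, path: str | Path) -> None:
    sums.to_frame().to_csv(path, index_label="person_id")
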