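"""Diallel cross-compatibility classification and summaries.

A complete p x p diallel (all ordered female x male pairs including
selfs) is classified by fruit-set rate: a cross is *compatible* when more
than 50% of the pollinated flowers set fruit, *incompatible* when none do,
and *partially compatible* otherwise (0 < rate <= 50%, the 50% boundary
included).  Selfs are reported separately, so the off-diagonal summary is
over p(p-1) reciprocal cells.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CompletenessError, DomainError

__all__ = [
    "CrossRecord",
    "DiallelTable",
    "DiallelSummary",
    "classify_cross",
    "summarize_diallel",
    "reciprocal_asymmetry",
    "read_diallel",
    "write_diallel",
]

CLASSES = ("compatible", "partial", "incompatible")


@dataclass(frozen=True)
class CrossRecord:
    """Fruit-set outcome of one ordered (female, male) pollination."""

    female: str
    male: str
    n_pollinated: int
    n_set: int

    def __post_init__(self):
        if self.n_pollinated < 0 or self.n_set < 0:
            raise DomainError("counts must be non-negative")
        if self.n_set > self.n_pollinated:
            raise DomainError(
                f"n_set ({self.n_set}) exceeds n_pollinated ({self.n_pollinated})"
            )

    @property
    def rate(self) -> float:
        if self.n_pollinated == 0:
            raise DomainError("fruit-set rate undefined with 0 pollinations")
        return self.n_set / self.n_pollinated

    @property
    def is_self(self) -> bool:
        return self.female == self.male


def classify_cross(c: CrossRecord) -> str:
    """Compatibility class from the fruit-set rate (selfs use the same rule)."""
    r = c.rate
    if r > 0.5:
        return "compatible"
    if r == 0.0:
        return "incompatible"
    return "partial"


@dataclass
class DiallelTable:
    """Complete grid of :class:`CrossRecord` over an ordered parent list."""

    parents: list
    records: dict = field(default_factory=dict)  # (female, male) -> CrossRecord

    def __post_init__(self):
        self.parents = [str(p) for p in self.parents]

    def check_complete(self) -> None:
        missing = [(f, m) for f in self.parents for m in self.parents
                   if (f, m) not in self.records]
        if missing:
            raise CompletenessError(f"diallel grid incomplete: missing {missing[:5]}"
                                    f"{'...' if len(missing) > 5 else ''}")

    def rate_matrix(self) -> pd.DataFrame:
        self.check_complete()
        p = self.parents
        vals = [[self.records[(f, m)].rate for m in p] for f in p]
        return pd.DataFrame(vals, index=pd.Index(p, name="female"),
                            columns=pd.Index(p, name="male"))

    def class_matrix(self) -> pd.DataFrame:
        """Class per cell; the diagonal is labelled 'self'."""
        self.check_complete()
        p = self.parents
        vals = [
            ["self" if f == m else classify_cross(self.records[(f, m)])
             for m in p]
            for f in p
        ]
        return pd.DataFrame(vals, index=pd.Index(p, name="female"),
                            columns=pd.Index(p, name="male"))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"female": r.female, "male": r.male,
             "n_pollinated": r.n_pollinated, "n_set": r.n_set}
            for r in (self.records[(f, m)] for f in self.parents
                      for m in self.parents if (f, m) in self.records)
        ]
        return pd.DataFrame(rows)


@dataclass
class DiallelSummary:
    counts: dict            # class -> number of off-diagonal cells
    percentages: dict       # class -> percent of off-diagonal cells
    n_reciprocal_cells: int
    female_fertility: dict  # female -> sets fruit with at least one male
    self_classes: dict      # parent -> class of its self-pollination


def summarize_diallel(t: DiallelTable) -> DiallelSummary:
    """Off-diagonal class counts/percentages plus per-female fertility."""
    t.check_complete()
    p = t.parents
    counts = {c: 0 for c in CLASSES}
    fertility = {f: False for f in p}
    for f in p:
        for m in p:
            if f == m:
                continue
            rec = t.records[(f, m)]
            counts[classify_cross(rec)] += 1
            if rec.n_set > 0:
                fertility[f] = True
    n_off = len(p) * (len(p) - 1)
    pct = {c: 100.0 * counts[c] / n_off for c in CLASSES}
    selfs = {f: classify_cross(t.records[(f, f)]) for f in p}
    return DiallelSummary(counts, pct, n_off, fertility, selfs)


def reciprocal_asymmetry(t: DiallelTable) -> list:
    """Unordered parent pairs whose two cross directions classify differently.

    Each entry reports both directions: ``{"pair": (a, b), "class_ab": ...,
    "class_ba": ...}`` where class_ab is for female a x male b.  Invariant
    under transposing the female/male axes since pairs are unordered.
    """
    t.check_complete()
    p = t.parents
    out = []
    for i, a in enumerate(p):
        for b in p[i + 1:]:
            cab = classify_cross(t.records[(a, b)])
            cba = classify_cross(t.records[(b, a)])
            if cab != cba:
                out.append({"pair": (a, b), "class_ab": cab, "class_ba": cba})
    return out


def read_diallel(path) -> DiallelTable:
    """Read a diallel CSV with columns female, male, n_pollinated, n_set."""
    df = pd.read_csv(Path(path), comment="#")
    need = {"female", "male", "n_pollinated", "n_set"}
    if not need <= set(df.columns):
        raise CompletenessError(f"diallel CSV needs columns {sorted(need)}")
    parents: list = []
    records = {}
    for _, row in df.iterrows():
        f, m = str(row["female"]), str(row["male"])
        for x in (f, m):
            if x not in parents:
                parents.append(x)
        records[(f, m)] = CrossRecord(f, m, int(row["n_pollinated"]),
                                      int(row["n_set"]))
    return DiallelTable(parents, records)


def write_diallel(t: DiallelTable, path) -> None:
    t.to_frame().to_csv(Path(path), index=False)


def summary_payload(t: DiallelTable) -> dict:
    """JSON-ready summary: class matrix, counts, percentages, asymmetries."""
    s = summarize_diallel(t)
    return {
        "parents": t.parents,
        "class_matrix": {f: dict(row) for f, row in t.class_matrix().iterrows()},
        "counts": s.counts,
        "percentages": s.percentages,
        "n_reciprocal_cells": s.n_reciprocal_cells,
        "female_fertility": s.female_fertility,
        "self_classes": s.self_classes,
        "asymmetric_pairs": [
            {"pair": list(e["pair"]), "class_ab": e["class_ab"],
             "class_ba": e["class_ba"]}
            for e in reciprocal_asymmetry(t)
        ],
    }
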