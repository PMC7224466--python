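"""Plot-level phenotype data model for multi-environment trials.

The central container is :class:`METDataset`: a long-format table of plot
records (one row per genotype x environment x block plot, with one column
per trait) plus the design metadata needed downstream -- canonical genotype
and environment orderings, blocks per environment and plant/row spacing.

Trait columns follow the fruit-trait vocabulary of sweet passion fruit
breeding trials: WF (fruit weight, g), DF (fruit diameter, mm), LF (fruit
length, mm), TS (skin thickness, mm), WS (skin weight, g), SS (soluble
solids, degrees Brix), fruit_count (fruits per plant) and the derived
WP (pulp weight, g), YP (pulp yield, %), production_kg (kg per plant) and
yield_t_ha (t/ha).  Units are metadata only; no conversion is performed.
"""
from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field, asdict, is_dataclass
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DuplicateKeyError, SchemaError

__all__ = [
    "KEY_COLUMNS",
    "METDataset",
    "ValidationReport",
    "read_phenotypes",
    "write_dataset",
    "validate_dataset",
    "derive_traits",
    "write_table",
]

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("genotype", "environment", "block")
KEY_COLUMNS = ("genotype", "environment", "block", "plot")

#: hectare in square metres, used for the per-hectare yield extrapolation
_HA_M2 = 10_000.0


def _ordered_unique(values: Sequence) -> list:
    """Unique values in order of first appearance."""
    seen: dict = {}
    for v in values:
        if v not in seen:
            seen[v] = None
    return list(seen)


@dataclass
class METDataset:
    """Long-format multi-environment trial dataset.

    Parameters
    ----------
    records
        One row per plot; columns ``genotype, environment, block, plot``
        followed by trait columns (float; NaN = missing).
    genotypes, environments
        Canonical orderings (first appearance in the input) used for every
        matrix built downstream.
    design
        Environment -> number of blocks.
    spacing
        Environment -> plant/row spacing in metres (square planting grid).
    parents
        Genotype labels that are parents rather than full-sib progeny.
    """

    records: pd.DataFrame
    genotypes: list = field(default_factory=list)
    environments: list = field(default_factory=list)
    design: dict = field(default_factory=dict)
    spacing: dict = field(default_factory=dict)
    parents: list = field(default_factory=list)

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        *,
        spacing: Mapping | None = None,
        parents: Sequence | None = None,
    ) -> "METDataset":
        df = df.copy()
        for col in REQUIRED_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"required column {col!r} is missing")
        if "plot" not in df.columns:
            df["plot"] = df.groupby(list(REQUIRED_COLUMNS), sort=False).cumcount() + 1
        for col in ("genotype", "environment", "block", "plot"):
            df[col] = df[col].astype(str)
        dup = df.duplicated(list(KEY_COLUMNS))
        if dup.any():
            keys = df.loc[dup, list(KEY_COLUMNS)].iloc[0].tolist()
            raise DuplicateKeyError(f"duplicate plot key {tuple(keys)}")
        genotypes = _ordered_unique(df["genotype"])
        environments = _ordered_unique(df["environment"])
        design = {
            env: int(df.loc[df["environment"] == env, "block"].nunique())
            for env in environments
        }
        parents = [str(p) for p in (parents or []) if str(p) in set(genotypes)]
        spacing = {str(k): float(v) for k, v in (spacing or {}).items()}
        trait_cols = [c for c in df.columns if c not in KEY_COLUMNS]
        for c in trait_cols:
            df[c] = pd.to_numeric(df[c], errors="coerce")
        ordered = list(KEY_COLUMNS) + trait_cols
        return cls(df[ordered].reset_index(drop=True), genotypes, environments,
                   design, spacing, parents)

    # -- views -----------------------------------------------------------
    @property
    def traits(self) -> list:
        return [c for c in self.records.columns if c not in KEY_COLUMNS]

    @property
    def full_sibs(self) -> list:
        return [g for g in self.genotypes if g not in self.parents]

    @property
    def n_environments(self) -> int:
        return len(self.environments)

    def subset_env(self, env: str) -> "METDataset":
        sub = self.records[self.records["environment"] == env]
        return METDataset.from_frame(sub, spacing=self.spacing, parents=self.parents)

    def cell_means(self, trait: str, genotypes: Sequence | None = None) -> pd.DataFrame:
        """Genotype x environment table of plot means for one trait."""
        piv = self.records.pivot_table(
            index="genotype", columns="environment", values=trait, aggfunc="mean"
        )
        rows = list(genotypes) if genotypes is not None else self.genotypes
        return piv.reindex(index=rows, columns=self.environments)

    def copy(self) -> "METDataset":
        return METDataset(self.records.copy(), list(self.genotypes),
                          list(self.environments), dict(self.design),
                          dict(self.spacing), list(self.parents))


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_dataset`; violations are data, not errors."""

    n_records: int
    n_missing: dict
    unbalance: dict
    violations: list

    @property
    def ok(self) -> bool:
        return not self.violations


def read_phenotypes(
    path,
    schema: Mapping[str, str] | None = None,
    *,
    spacing: Mapping | None = None,
    parents: Sequence | None = None,
) -> METDataset:
    """Read a long-format phenotype CSV into a :class:`METDataset`.

    ``schema`` maps file column names to canonical names, e.g.
    ``{"geno": "genotype"}``.  Lines starting with ``#`` are metadata
    comments; a ``# meta: {...}`` line written by :func:`write_dataset`
    restores spacing and parent labels on round trip.  Empty cells and
    ``NA`` are recorded as missing, never dropped.
    """
    path = Path(path)
    meta: dict = {}
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    body = []
    for line in lines:
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if stripped.startswith("meta:"):
                meta = json.loads(stripped[len("meta:"):])
        else:
            body.append(line)
    df = pd.read_csv(io.StringIO("".join(body)), na_values=["NA", ""])
    if schema:
        df = df.rename(columns=dict(schema))
    return METDataset.from_frame(
        df,
        spacing=spacing if spacing is not None else meta.get("spacing"),
        parents=parents if parents is not None else meta.get("parents"),
    )


def write_dataset(d: METDataset, path, *, float_format: str = "%.10g") -> None:
    """Write a dataset as CSV with a metadata comment line for round trips."""
    path = Path(path)
    meta = {"spacing": d.spacing, "parents": d.parents}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# meta: {json.dumps(meta)}\n")
        d.records.to_csv(fh, index=False, float_format=float_format)


def validate_dataset(d: METDataset) -> ValidationReport:
    """Check every plot-record invariant and report violations.

    Checked: trait values finite-or-missing, WF >= WS >= 0 where both are
    present, block labels nested within a single environment, and the
    record-level membership of genotype/environment in the canonical
    orderings.  Pure function; violations never raise.
    """
    df = d.records
    violations: list[dict] = []
    for trait in d.traits:
        col = df[trait]
        bad = np.isinf(col.to_numpy(dtype=float))
        for i in np.nonzero(bad)[0]:
            violations.append({"rule": "finite", "trait": trait, "row": int(i),
                               "message": f"{trait} is not finite"})
    if "WF" in d.traits and "WS" in d.traits:
        wf = df["WF"].to_numpy(dtype=float)
        ws = df["WS"].to_numpy(dtype=float)
        both = ~np.isnan(wf) & ~np.isnan(ws)
        for i in np.nonzero(both & (wf < ws))[0]:
            violations.append({"rule": "WF>=WS", "row": int(i),
                               "message": f"WF={wf[i]:g} < WS={ws[i]:g}"})
        for i in np.nonzero(both & (ws < 0))[0]:
            violations.append({"rule": "WS>=0", "row": int(i),
                               "message": f"WS={ws[i]:g} negative"})
    known_g = set(d.genotypes)
    known_e = set(d.environments)
    for i, (g, e) in enumerate(zip(df["genotype"], df["environment"])):
        if g not in known_g:
            violations.append({"rule": "genotype-membership", "row": i,
                               "message": f"unknown genotype {g}"})
        if e not in known_e:
            violations.append({"rule": "environment-membership", "row": i,
                               "message": f"unknown environment {e}"})

    n_missing = {t: int(df[t].isna().sum()) for t in d.traits}
    # unbalance: genotypes observed in fewer blocks than the environment has
    unbalance = {}
    for env in d.environments:
        sub = df[df["environment"] == env]
        per_geno = sub.groupby("genotype")["block"].nunique()
        expected = d.design.get(env, per_geno.max())
        short = per_geno[per_geno < expected]
        missing_geno = [g for g in d.genotypes if g not in set(sub["genotype"])]
        if len(short) or missing_geno:
            unbalance[env] = {"incomplete_genotypes": sorted(short.index.tolist()
                                                            + missing_geno)}
    return ValidationReport(len(df), n_missing, unbalance, violations)


def derive_traits(d: METDataset, *, spacing: Mapping | None = None) -> METDataset:
    """Compute derived fruit traits per plot and return a new dataset.

    WP = WF - WS (g); YP = 100 * WP / WF (%); production_kg = fruit_count *
    WF / 1000 (kg/plant); yield_t_ha = production_kg * plants_per_ha / 1000
    with plants_per_ha = 10000 / spacing^2 (square planting grid, spacing in
    metres per environment).  Existing derived columns are overwritten, so
    the operation is idempotent.  Missing inputs propagate to missing
    outputs; WF = 0 makes YP undefined for that plot (set missing, logged).
    """
    out = d.copy()
    df = out.records
    spacing = {**d.spacing, **(dict(spacing) if spacing else {})}
    if "WF" in df.columns and "WS" in df.columns:
        df["WP"] = df["WF"] - df["WS"]
        wf = df["WF"].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            yp = 100.0 * df["WP"].to_numpy(dtype=float) / wf
        zero = wf == 0
        if zero.any():
            log.warning("YP undefined for %d plot(s) with WF=0; set missing",
                        int(zero.sum()))
            yp[zero] = np.nan
        df["YP"] = yp
    if "fruit_count" in df.columns and "WF" in df.columns:
        df["production_kg"] = df["fruit_count"] * df["WF"] / 1000.0
        dens = df["environment"].map(
            {e: _HA_M2 / (s * s) for e, s in spacing.items()}
        ).astype(float)
        df["yield_t_ha"] = df["production_kg"] * dens / 1000.0
    return out


def _to_frame(obj: Any) -> pd.DataFrame:
    if isinstance(obj, pd.DataFrame):
        return obj
    if isinstance(obj, pd.Series):
        return obj.to_frame()
    if is_dataclass(obj) and not isinstance(obj, type):
        return pd.json_normalize(asdict(obj))
    if isinstance(obj, Mapping):
        return pd.json_normalize(dict(obj))
    raise SchemaError(f"cannot serialise object of type {type(obj).__name__}")


def write_table(
    obj: Any,
    path,
    format: str = "csv",
    *,
    float_precision: int = 6,
    meta: Mapping | None = None,
) -> None:
    """Write a result table (DataFrame / Series / dataclass / mapping).

    CSV output carries provenance header comments and a deterministic
    column order; floats are printed at a fixed precision.  JSON output
    nests the metadata under ``"meta"``.
    """
    from . import __version__

    path = Path(path)
    header = {"package": f"metqg {__version__}", **(dict(meta) if meta else {})}
    if format == "csv":
        df = _to_frame(obj)
        with open(path, "w", encoding="utf-8") as fh:
            for k, v in header.items():
                fh.write(f"# {k}: {v}\n")
            df.to_csv(fh, float_format=f"%.{float_precision}g",
                      index=not isinstance(df.index, pd.RangeIndex))
    elif format == "json":
        if is_dataclass(obj) and not isinstance(obj, type):
            payload = asdict(obj)
        elif isinstance(obj, pd.DataFrame):
            payload = json.loads(obj.to_json(orient="split"))
        elif isinstance(obj, pd.Series):
            payload = obj.to_dict()
        else:
            payload = obj

        def _default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(f"not JSON serialisable: {type(o)}")

        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"meta": header, "data": payload}, fh, indent=1,
                      default=_default)
            fh.write("\n")
    else:
        raise SchemaError(f"unknown format {format!r}")
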