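"""Truncation selection, the multiplicative selection index (MSI) and
response-to-selection reporting.

The MSI for genotype i over index traits t is ``MI_i = prod_t (yhat_it -
lambda_t)`` for traits selected upward and ``(lambda_t - yhat_it)`` for
traits selected downward, where ``yhat_it`` is the adjusted genotypic value
and ``lambda_t`` the acceptance limit; with this orientation MI increases
monotonically in merit for every trait.  Genotypes with any non-positive
factor are non-admissible and excluded before truncation (configurable to
strict rank-by-product).

Response to selection for trait t is the mean BLUP of the selected set,
``RS_t = mean(BLUP_t | selected)``, and ``RS% = 100 RS / xbar_0`` with
``xbar_0`` the base-population phenotypic mean -- computed for all traits so
correlated responses are visible.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = [
    "SelectionConfig",
    "SelectionResult",
    "multiplicative_index",
    "select",
    "response_to_selection",
    "run_scenarios",
]

#: default acceptance limits sit 5% of the observed range beyond the worst
#: adjusted value, so every genotype is admissible and the index weighs the
#: full population (limits are agronomic choices; override via lambdas)
DEFAULT_LAMBDA_MARGIN = 0.05

#: the four standard scenarios: three single-trait truncations and the MSI
STANDARD_SCENARIOS = (
    ("against_TS", "single", "TS", "decrease"),
    ("against_WS", "single", "WS", "decrease"),
    ("for_WP", "single", "WP", "increase"),
    ("msi", "msi", None, None),
)


@dataclass
class SelectionConfig:
    """Index traits with limits/directions and the selection intensity."""

    traits: tuple = ("WP", "TS", "WS")
    directions: dict = field(default_factory=lambda: {
        "WP": "increase", "TS": "decrease", "WS": "decrease"})
    lambdas: dict = field(default_factory=dict)  # trait -> acceptance limit
    intensity: float = 0.20
    admissibility: str = "exclude"  # or "literal": rank raw products

    def __post_init__(self):
        if not (0.0 < self.intensity <= 1.0):
            raise ConfigError("selection intensity must be in (0, 1]")
        for t in self.traits:
            if self.directions.get(t) not in ("increase", "decrease"):
                raise ConfigError(f"trait {t!r} needs a direction "
                                  "('increase' or 'decrease')")


@dataclass
class SelectionResult:
    scenario: str
    index: pd.Series              # score per genotype (MI or trait value)
    selected: list                # ordered best-first
    response: pd.DataFrame        # per trait: RS, RS_pct
    non_admissible: list = field(default_factory=list)


def n_selected(intensity: float, n_genotypes: int) -> int:
    """Selected-set size: round-half-up of intensity * n."""
    return int(np.floor(intensity * n_genotypes + 0.5))


def multiplicative_index(values: pd.DataFrame, cfg: SelectionConfig
                         ) -> tuple[pd.Series, pd.Series]:
    """MSI scores and an admissibility mask over a genotype x trait table.

    Returns ``(mi, admissible)``; under the default policy non-admissible
    genotypes (some factor <= 0, i.e. the adjusted value on the wrong side
    of its limit) keep their raw product but are excluded downstream.
    """
    missing = [t for t in cfg.traits if t not in values.columns]
    if missing:
        raise ConfigError(f"index traits absent from table: {missing}")
    missing_l = [t for t in cfg.traits if t not in cfg.lambdas]
    if missing_l:
        raise ConfigError(f"no lambda limit for index traits: {missing_l}")
    factors = pd.DataFrame(index=values.index)
    for t in cfg.traits:
        lam = float(cfg.lambdas[t])
        y = values[t].astype(float)
        factors[t] = (y - lam) if cfg.directions[t] == "increase" else (lam - y)
    mi = factors.prod(axis=1)
    admissible = (factors > 0).all(axis=1)
    return mi, admissible


def select(scores: pd.Series, intensity: float, direction: str = "max") -> list:
    """Truncation selection: the best ``round(intensity * n)`` genotypes.

    ``direction='min'`` selects the smallest scores ("selection against").
    Ties break on the genotype label, so the outcome is deterministic.
    """
    if len(scores) == 0:
        raise ConfigError("empty score table")
    k = n_selected(intensity, len(scores))
    asc = direction == "min"
    ordered = sorted(
        scores.items(),
        key=lambda kv: ((kv[1] if asc else -kv[1]), str(kv[0])),
    )
    return [g for g, _ in ordered[:k]]


def response_to_selection(blups: pd.DataFrame, selected, base_means: pd.Series
                          ) -> pd.DataFrame:
    """Per-trait RS (mean BLUP of the selected set) and RS% for ALL traits."""
    selected = list(selected)
    unknown = [g for g in selected if g not in blups.index]
    if unknown:
        raise ConfigError(f"selected genotypes not in BLUP table: {unknown}")
    rs = blups.loc[selected].mean(axis=0)
    rs_pct = pd.Series(np.nan, index=rs.index)
    for t in rs.index:
        base = float(base_means.get(t, np.nan))
        if base != 0 and np.isfinite(base):
            rs_pct[t] = 100.0 * rs[t] / base
    return pd.DataFrame({"RS": rs, "RS_pct": rs_pct})


def run_scenarios(blups: pd.DataFrame, base_means: pd.Series,
                  cfg: SelectionConfig | None = None) -> dict:
    """Run the four standard selection scenarios at the same intensity.

    Scenario 1 selects against TS, 2 against WS, 3 for WP, 4 by the MSI
    over (WP up, TS down, WS down).  Adjusted genotypic values are
    ``base mean + BLUP``; MSI limits default to amplitude-based bounds
    (5% of the observed range beyond the worst value), keeping every
    genotype admissible unless explicit agronomic limits are supplied.
    """
    cfg = cfg or SelectionConfig()
    for t in ("TS", "WS", "WP"):
        if t not in blups.columns:
            raise ConfigError(f"scenario trait {t!r} missing from BLUP table")
    adjusted = blups.add(base_means, axis=1)
    lambdas = dict(cfg.lambdas)
    for t in cfg.traits:
        if t not in lambdas:
            lo, hi = float(adjusted[t].min()), float(adjusted[t].max())
            margin = DEFAULT_LAMBDA_MARGIN * (hi - lo)
            lambdas[t] = (lo - margin if cfg.directions[t] == "increase"
                          else hi + margin)
    msi_cfg = SelectionConfig(traits=cfg.traits, directions=cfg.directions,
                              lambdas=lambdas, intensity=cfg.intensity,
                              admissibility=cfg.admissibility)
    results = {}
    for name, kind, trait, direction in STANDARD_SCENARIOS:
        if kind == "single":
            scores = adjusted[trait]
            order = "min" if direction == "decrease" else "max"
            chosen = select(scores, cfg.intensity, order)
            index = scores
            bad: list = []
        else:
            mi, admissible = multiplicative_index(adjusted, msi_cfg)
            bad = list(mi.index[~admissible])
            pool = mi[admissible] if msi_cfg.admissibility == "exclude" else mi
            # the intensity refers to the whole population, not the pool
            k = n_selected(cfg.intensity, len(mi))
            ordered = sorted(pool.items(), key=lambda kv: (-kv[1], str(kv[0])))
            chosen = [g for g, _ in ordered[:k]]
            index = mi
        resp = response_to_selection(blups, chosen, base_means)
        results[name] = SelectionResult(name, index, chosen, resp, bad)
    return results
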