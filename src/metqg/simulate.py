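"""Synthetic MET phenotypes and diallel outcomes with the statistical
structure the analysis pipeline assumes.

The default configuration emulates a sweet passion fruit trial design:
30 full-sib genotypes plus their 2 parents, three environments (A with 6
randomised complete blocks, B and C with 3), plot means for the measured
fruit traits (WF, DF, LF, TS, WS, SS and fruits per plant), heterogeneous
residual variances per environment, fixed block shifts, and ~5% of plots
missing at random.  Genetic cell effects follow the interaction
decomposition: a genotype main effect (correlated across traits through a
two-factor loading model that reproduces the strong fruit-size correlation
block and the negative pulp-yield/soluble-solids relations) plus
independent genotype-by-environment deviations; the same trait correlation
matrix is applied to the GEI deviations and plot residuals so that jointly
measured traits stay physically consistent (in particular WF >= WS).
Magnitudes of means and variance components follow the published ranges
for this crop, so simulated heritabilities land in the 0.7-0.9 band.

A trait may instead carry an explicit across-environment genetic
covariance matrix (any structure from :mod:`metqg.vcov`); such traits are
drawn independently of the others and are the backbone of the
covariance-recovery simulation studies.

The diallel simulator draws fruit set from an S-locus self-incompatibility
model: selfs never set fruit; under gametophytic control the expected rate
is the base rate times the fraction of pollen S-alleles absent from the
pistil genotype; under sporophytic control any shared allele blocks the
cross entirely.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import vcov
from .data_model import METDataset, derive_traits
from .diallel import CrossRecord, DiallelTable
from .errors import ConfigError

__all__ = [
    "TraitSim",
    "SimConfig",
    "SimTruth",
    "paper_like_config",
    "simulate_met",
    "expected_fruit_set",
    "simulate_diallel",
    "default_s_genotypes",
    "make_fixture_table4",
]


@dataclass(frozen=True)
class TraitSim:
    """Generative parameters for one trait.

    Either (sigma_g2, sigma_ge2) for the interaction decomposition, or an
    explicit q x q ``g_cov`` across-environment genetic covariance.
    ``sigma2_by_env`` holds the residual plot variance per environment.
    """

    name: str
    env_means: tuple
    sigma_g2: float = 0.0
    sigma_ge2: float = 0.0
    sigma2_by_env: tuple = ()
    parent_offset: float = 0.0
    g_cov: np.ndarray | None = None
    nonnegative: bool = False


@dataclass
class SimConfig:
    """Study design and generative truth for :func:`simulate_met`."""

    seed: int
    traits: tuple
    n_full_sibs: int = 30
    n_parents: int = 2
    blocks: Mapping[str, int] = field(
        default_factory=lambda: {"A": 6, "B": 3, "C": 3})
    spacing: Mapping[str, float] = field(
        default_factory=lambda: {"A": 5.0, "B": 3.0, "C": 3.0})
    trait_correlation: np.ndarray | None = None  # aligned with traits order
    block_var_frac: float = 0.1   # block-effect variance as fraction of sigma2
    missing_rate: float = 0.05
    derive: bool = True           # append WP/YP/yield via derive_traits

    def __post_init__(self):
        if self.seed is None:
            raise ConfigError("a seed is mandatory")
        q = len(self.blocks)
        for t in self.traits:
            if len(t.env_means) != q or (t.sigma2_by_env and
                                         len(t.sigma2_by_env) != q):
                raise ConfigError(f"trait {t.name}: per-environment fields "
                                  f"must have length {q}")
            if t.g_cov is not None and np.asarray(t.g_cov).shape != (q, q):
                raise ConfigError(f"trait {t.name}: g_cov must be {q}x{q}")
        if self.trait_correlation is not None:
            R = np.asarray(self.trait_correlation)
            if R.shape != (len(self.traits),) * 2:
                raise ConfigError("trait_correlation shape mismatch")
            np.linalg.cholesky(R)  # raises if not PD


@dataclass
class SimTruth:
    """Everything the generator drew, for parameter-recovery ledgers."""

    config: SimConfig
    genotype_main: pd.DataFrame          # genotype x trait main effects
    cell_effects: dict                   # trait -> genotype x env DataFrame
    block_effects: dict                  # (env, block, trait) -> shift
    sigma_env: dict                      # trait -> implied q x q genetic cov
    deleted_plots: list
    n_ws_clipped: int = 0


# ---------------------------------------------------------------------------
# the paper-like preset: the study conditions used throughout the tests
# ---------------------------------------------------------------------------

_PRESET = [
    # name, env means (A,B,C), sigma_g2, sigma_ge2, sigma2 (A,B,C), parent off
    ("WF", (156.41, 157.38, 194.53), 839.15, 593.32,
     (940.07, 837.20, 1016.99), -22.2),
    ("DF", (67.74, 66.95, 72.77), 8.53, 11.77, (19.90, 16.71, 15.89), -1.4),
    ("LF", (111.93, 109.43, 116.77), 33.90, 22.68, (56.20, 50.14, 46.23), -6.0),
    ("TS", (8.89, 8.15, 9.54), 0.78, 0.15, (1.05, 0.86, 0.57), -0.1),
    ("WS", (110.34, 105.10, 143.04), 636.45, 408.48,
     (599.11, 483.55, 620.11), -11.0),
    ("SS", (15.67, 15.81, 16.62), 0.83, 0.10, (1.29, 1.22, 0.78), 0.9),
    ("fruit_count", (30.0, 12.0, 18.0), 9.0, 4.0, (9.0, 4.0, 9.0), -2.0),
]

# two-factor loading model: factor 1 = fruit size/architecture, factor 2 =
# sweetness; reproduces the strong WF-WS block and the negative SS relations
_LOADINGS = {
    "WF": (0.97, 0.0),
    "DF": (0.85, 0.0),
    "LF": (0.70, 0.0),
    "TS": (0.80, 0.0),
    "WS": (0.99, 0.0),
    "SS": (-0.35, 0.80),
    "fruit_count": (0.40, 0.10),
}


def _loading_correlation(names: Sequence[str]) -> np.ndarray:
    lam = np.array([_LOADINGS[n] for n in names])
    R = lam @ lam.T
    np.fill_diagonal(R, 1.0)
    return R


def paper_like_config(seed: int, **overrides) -> SimConfig:
    """The default study conditions: full design, seven measured traits."""
    traits = tuple(
        TraitSim(name=n, env_means=em, sigma_g2=sg, sigma_ge2=sge,
                 sigma2_by_env=s2, parent_offset=off,
                 nonnegative=(n == "fruit_count"))
        for n, em, sg, sge, s2, off in _PRESET
    )
    cfg = SimConfig(seed=seed, traits=traits,
                    trait_correlation=_loading_correlation(
                        [t[0] for t in _PRESET]))
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# MET simulation
# ---------------------------------------------------------------------------

def _corr_chol(cfg: SimConfig) -> np.ndarray:
    if cfg.trait_correlation is None:
        return np.eye(len(cfg.traits))
    return np.linalg.cholesky(np.asarray(cfg.trait_correlation, dtype=float))


def simulate_met(cfg: SimConfig) -> tuple[METDataset, SimTruth]:
    """Draw one MET dataset plus the generative truth, reproducibly.

    Genetic cell effects per trait are ``main + GEI`` (or a draw from the
    explicit ``g_cov``); fixed block shifts are drawn once per
    (environment, block); residuals are heterogeneous per environment;
    whole plots are deleted at ``missing_rate``.
    """
    rng = np.random.default_rng(cfg.seed)
    envs = list(cfg.blocks)
    q = len(envs)
    names = [t.name for t in cfg.traits]
    T = len(names)
    full_sibs = [f"G{i:02d}" for i in range(1, cfg.n_full_sibs + 1)]
    parents = [f"P{i}" for i in range(1, cfg.n_parents + 1)]
    genotypes = full_sibs + parents
    m = len(genotypes)
    Lr = _corr_chol(cfg)

    sg = np.array([t.sigma_g2 for t in cfg.traits])
    sge = np.array([t.sigma_ge2 for t in cfg.traits])
    main = (rng.standard_normal((m, T)) @ Lr.T) * np.sqrt(sg)
    cell = np.empty((m, q, T))
    for e in range(q):
        dev = (rng.standard_normal((m, T)) @ Lr.T) * np.sqrt(sge)
        cell[:, e, :] = main + dev
    sigma_env = {}
    for t_i, t in enumerate(cfg.traits):
        if t.g_cov is not None:
            G = np.asarray(t.g_cov, dtype=float)
            Lg = np.linalg.cholesky(G + 1e-12 * np.trace(G) / q * np.eye(q))
            cell[:, :, t_i] = rng.standard_normal((m, q)) @ Lg.T
            main[:, t_i] = cell[:, :, t_i].mean(axis=1)
            sigma_env[t.name] = G
        else:
            sigma_env[t.name] = (np.full((q, q), t.sigma_g2)
                                 + t.sigma_ge2 * np.eye(q))

    s2 = np.array([t.sigma2_by_env if t.sigma2_by_env else (0.0,) * q
                   for t in cfg.traits])  # T x q
    block_effects = {}
    for e, env in enumerate(envs):
        for b in range(1, cfg.blocks[env] + 1):
            drawn = rng.standard_normal(T) * np.sqrt(cfg.block_var_frac * s2[:, e])
            for t_i, tn in enumerate(names):
                block_effects[(env, str(b), tn)] = float(drawn[t_i])

    rows = []
    for g_i, g in enumerate(genotypes):
        is_parent = g in parents
        for e, env in enumerate(envs):
            for b in range(1, cfg.blocks[env] + 1):
                resid = (rng.standard_normal(T) @ Lr.T) * np.sqrt(s2[:, e])
                vals = {}
                for t_i, t in enumerate(cfg.traits):
                    v = (t.env_means[e]
                         + (t.parent_offset if is_parent else 0.0)
                         + block_effects[(env, str(b), t.name)]
                         + cell[g_i, e, t_i] + resid[t_i])
                    if t.nonnegative:
                        v = max(v, 0.0)
                    vals[t.name] = v
                rows.append({"genotype": g, "environment": env,
                             "block": str(b), "plot": f"{env}{b}", **vals})
    df = pd.DataFrame(rows)

    n_clipped = 0
    if "WF" in df.columns and "WS" in df.columns:
        bad = df["WS"] > df["WF"]
        n_clipped = int(bad.sum())
        df.loc[bad, "WS"] = df.loc[bad, "WF"] * 0.98

    deleted = []
    if cfg.missing_rate > 0:
        n_drop = int(round(cfg.missing_rate * len(df)))
        drop_idx = rng.choice(len(df), size=n_drop, replace=False)
        deleted = df.iloc[sorted(drop_idx)][
            ["genotype", "environment", "block"]].to_dict("records")
        df = df.drop(df.index[sorted(drop_idx)]).reset_index(drop=True)

    d = METDataset.from_frame(df, spacing=cfg.spacing, parents=parents)
    if cfg.derive:
        d = derive_traits(d)
    truth = SimTruth(
        config=cfg,
        genotype_main=pd.DataFrame(main, index=genotypes, columns=names),
        cell_effects={
            t.name: pd.DataFrame(cell[:, :, t_i], index=genotypes, columns=envs)
            for t_i, t in enumerate(cfg.traits)
        },
        block_effects=block_effects,
        sigma_env=sigma_env,
        deleted_plots=deleted,
        n_ws_clipped=n_clipped,
    )
    return d, truth


# ---------------------------------------------------------------------------
# diallel simulation
# ---------------------------------------------------------------------------

def expected_fruit_set(female: tuple, male: tuple, mode: str,
                       base_rate: float) -> float:
    """Expected fruit-set probability of a cross under S-locus control."""
    fset, mset = set(female), set(male)
    if len(female) != 2 or len(male) != 2:
        raise ConfigError("each parent needs exactly two S-alleles")
    if mode == "gametophytic":
        ok = sum(1 for a in male if a not in fset) / 2.0
        return base_rate * ok
    if mode == "sporophytic":
        return 0.0 if fset & mset else base_rate
    raise ConfigError(f"unknown incompatibility mode {mode!r}")


def default_s_genotypes(parents: Sequence[str], seed: int) -> dict:
    """Assign full-sib S-genotypes segregating from an S1S2 x S3S4 cross."""
    rng = np.random.default_rng(seed)
    pool = [("S1", "S3"), ("S1", "S4"), ("S2", "S3"), ("S2", "S4")]
    return {p: pool[rng.integers(len(pool))] for p in parents}


def simulate_diallel(
    s_genotypes: Mapping[str, tuple],
    mode: str = "gametophytic",
    n_pollinated: int = 10,
    base_rate: float = 0.9,
    seed: int = 0,
) -> DiallelTable:
    """Simulate a complete diallel: binomial fruit set at the S-locus rate.

    Selfs never set fruit.  ``n_pollinated`` flowers per cross (>= 1).
    """
    if n_pollinated < 1:
        raise ConfigError("need at least one pollination per cross")
    rng = np.random.default_rng(seed)
    parents = list(s_genotypes)
    records = {}
    for f in parents:
        for m_ in parents:
            if f == m_:
                p = 0.0
            else:
                p = expected_fruit_set(tuple(s_genotypes[f]),
                                       tuple(s_genotypes[m_]), mode, base_rate)
            n_set = int(rng.binomial(n_pollinated, p))
            records[(f, m_)] = CrossRecord(f, m_, n_pollinated, n_set)
    return DiallelTable(parents, records)


# ---------------------------------------------------------------------------
# the published 6 x 6 compatibility grid
# ---------------------------------------------------------------------------

# classes as printed: '+' compatible, '-' incompatible, percentages partial.
_TABLE4 = {
    "21":  ("self", "+", "-", "+", "+", "+"),
    "49":  ("+", "self", "+", "40%", "+", "+"),
    "107": ("26.7%", "+", "self", "+", "+", "+"),
    "122": ("+", "+", "+", "self", "25%", "11.1%"),
    "125": ("+", "+", "25%", "25%", "self", "-"),
    "140": ("+", "+", "+", "-", "7.7%", "self"),
}

# synthetic count encodings: the published grid reports only classes and
# partial percentages, so denominators here are invented at the >= 10
# pollinations scale such that n_set / n_pollinated reproduces each printed
# percentage exactly; only the classes are meaningful.
_PCT_COUNTS = {"40%": (10, 4), "26.7%": (15, 4), "25%": (12, 3),
               "11.1%": (18, 2), "7.7%": (13, 1)}


def make_fixture_table4() -> DiallelTable:
    """The packaged 6-genotype compatibility grid (synthetic raw counts).

    Cell classes match the published diallel exactly; raw counts behind
    '+' (10/10) and partial-percentage cells are synthetic stand-ins chosen
    to reproduce the printed rates.
    """
    parents = list(_TABLE4)
    records = {}
    for f, row in _TABLE4.items():
        for m, code in zip(parents, row):
            if code in ("self", "-"):
                n, k = 10, 0
            elif code == "+":
                n, k = 10, 10
            else:
                n, k = _PCT_COUNTS[code]
            records[(f, m)] = CrossRecord(f, m, n, k)
    return DiallelTable(parents, records)
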