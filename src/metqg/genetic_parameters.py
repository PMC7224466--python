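"""Heritability, coefficients of variation and genetic correlations.

Heritability uses the generalised (Cullis) form valid for unbalanced data,

    Hc^2 = 1 - vbar_Delta / (2 sigma_g^2),

where ``vbar_Delta`` is the mean prediction-error variance of a difference
of two genotype BLUPs.  On a balanced single-environment trial with ``r``
replicates this approaches the classical plot-mean heritability
``sigma_g^2 / (sigma_g^2 + sigma^2 / r)``.

Correlation magnitudes are classed as weak (|r| <= 0.45), moderate
(0.45 < |r| < 0.76) and strong (|r| >= 0.76).
"""
from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .data_model import METDataset
from .errors import DegenerateError, DomainError
from .mixed_models import FitResult

__all__ = [
    "cullis_heritability",
    "coefficient_of_variation",
    "phenotypic_variance",
    "GeneticSummary",
    "variance_summary",
    "CorrelationSet",
    "env_correlations",
    "trait_correlations",
    "classify_correlation",
    "correlation_network",
]


def mean_pairwise_pev(pev: np.ndarray) -> float:
    """Average prediction-error variance of a BLUP difference.

    vbar_Delta = 2/(m(m-1)) * sum_{i<j} (pev_ii + pev_jj - 2 pev_ij).
    """
    pev = np.asarray(pev, dtype=float)
    m = pev.shape[0]
    if m < 2 or pev.shape != (m, m):
        raise DegenerateError("PEV matrix must be square with m >= 2")
    d = np.diag(pev)
    # sum over ordered pairs i != j of (pev_ii + pev_jj - 2 pev_ij)
    total = 2.0 * m * d.sum() - 2.0 * pev.sum()
    return float(total / (m * (m - 1)))


def cullis_heritability(sigma_g2: float, pev: np.ndarray, *,
                        printed_form: bool = False) -> float:
    """Generalised heritability from the genetic variance and the BLUP PEV.

    ``printed_form=True`` drops the factor 2 in the denominator (a variant
    that appears in some published write-ups); the default divides
    ``vbar_Delta`` by ``2 sigma_g^2``, which recovers the classical balanced
    closed form.  The value is reported raw and may leave [0, 1] numerically.
    """
    if sigma_g2 <= 0:
        raise DomainError("sigma_g2 must be positive")
    v = mean_pairwise_pev(pev)
    denom = sigma_g2 if printed_form else 2.0 * sigma_g2
    return float(1.0 - v / denom)


def coefficient_of_variation(sigma2: float, mean: float) -> float:
    """CV in percent: 100 * sqrt(sigma2) / mean."""
    if mean == 0:
        raise DomainError("CV undefined for zero mean")
    if sigma2 < 0:
        raise DomainError("variance must be non-negative")
    return float(100.0 * np.sqrt(sigma2) / mean)


def phenotypic_variance(*components: float) -> float:
    """Phenotypic variance as the sum of estimated variance components."""
    comps = np.asarray(components, dtype=float)
    if np.any(comps < 0):
        raise DomainError("variance components must be non-negative")
    return float(comps.sum())


# ---------------------------------------------------------------------------
# summary table
# ---------------------------------------------------------------------------

@dataclass
class GeneticSummary:
    """Per-trait variance components and genetic parameters, one row per
    (trait, scope) where scope is 'MET' or a single environment label."""

    table: pd.DataFrame

    def row(self, trait: str, scope: str) -> pd.Series:
        t = self.table
        return t[(t["trait"] == trait) & (t["scope"] == scope)].iloc[0]


def _summary_row(trait: str, scope: str, d: METDataset, f: FitResult) -> dict:
    df = d.records
    if scope != "MET":
        df = df[df["environment"] == scope]
    vals = df[df["genotype"].isin(d.full_sibs)][trait].dropna()
    pvals = df[df["genotype"].isin(d.parents)][trait].dropna()
    est = f.estimates
    sigma_g2 = f.genotype_sigma_g2()
    sigma_ge2 = float(est.get("sigma_ge2", np.nan))
    sigma2 = float(est["sigma2"])
    comps = [sigma_g2, sigma2] + ([sigma_ge2] if np.isfinite(sigma_ge2) else [])
    mean_fs = float(vals.mean())
    hc2 = np.nan
    if sigma_g2 > 0:
        hc2 = cullis_heritability(sigma_g2, f.genotype_pev())
    return {
        "trait": trait,
        "scope": scope,
        "mean_full_sibs": mean_fs,
        "mean_parents": float(pvals.mean()) if len(pvals) else np.nan,
        "min": float(vals.min()),
        "max": float(vals.max()),
        "sigma_g2": sigma_g2,
        "sigma_ge2": sigma_ge2,
        "sigma2": sigma2,
        "sigma_f2": phenotypic_variance(*[c for c in comps if c >= 0]),
        "CVg_pct": coefficient_of_variation(max(sigma_g2, 0.0), mean_fs),
        "CVe_pct": coefficient_of_variation(sigma2, mean_fs),
        "Hc2": hc2,
    }


def variance_summary(d: METDataset, fits: dict) -> GeneticSummary:
    """Assemble the per-trait parameter table from fitted models.

    ``fits`` maps ``(trait, scope)`` to a :class:`FitResult`, where scope is
    ``'MET'`` (interaction-model fit) or an environment label (single-trial
    fit).  Means and amplitudes come from the raw full-sib plot data;
    parents are summarised separately and never enter the genetic variance.
    """
    rows = []
    for (trait, scope), f in fits.items():
        if trait not in d.traits:
            raise KeyError(f"trait {trait!r} not in dataset")
        rows.append(_summary_row(trait, scope, d, f))
    tab = pd.DataFrame(rows)
    return GeneticSummary(tab.sort_values(["trait", "scope"]).reset_index(drop=True))


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

@dataclass
class CorrelationSet:
    """A labelled correlation matrix with magnitude classes."""

    labels: list
    matrix: pd.DataFrame
    classes: pd.DataFrame
    method: str


def classify_correlation(r: float) -> str:
    """Magnitude class: weak (|r| <= 0.45), moderate (< 0.76), strong (>= 0.76).

    The half-open gap between the published class bounds is closed by
    assigning 0.45 < |r| < 0.76 to 'moderate'.  NaN maps to 'undefined'.
    """
    if np.isnan(r):
        return "undefined"
    a = abs(r)
    if a > 1.0 + 1e-12:
        raise DomainError(f"correlation {r} outside [-1, 1]")
    if a <= 0.45:
        return "weak"
    if a < 0.76:
        return "moderate"
    return "strong"


def _class_frame(mat: pd.DataFrame) -> pd.DataFrame:
    return mat.map(lambda r: classify_correlation(r) if np.isfinite(r) or
                   np.isnan(r) else "undefined")


def env_correlations(Sigma_env: np.ndarray, labels) -> CorrelationSet:
    """Between-environment genetic correlations from a fitted q x q
    genetic covariance: r_kk' = sigma_kk' / sqrt(sigma_k^2 sigma_k'^2)."""
    S = np.asarray(Sigma_env, dtype=float)
    d = np.diag(S)
    if np.any(d <= 0):
        raise DegenerateError("zero or negative genetic variance on the diagonal")
    sd = np.sqrt(d)
    R = S / np.outer(sd, sd)
    np.fill_diagonal(R, 1.0)
    R = np.clip(R, -1.0, 1.0)
    labels = list(labels)
    mat = pd.DataFrame(R, index=labels, columns=labels)
    return CorrelationSet(labels, mat, _class_frame(mat), "env-from-Sigma_env")


def trait_correlations(blup_table: pd.DataFrame) -> CorrelationSet:
    """Pairwise Pearson correlations of genotype BLUPs across traits.

    Missing values are handled pairwise (complete pairs); a constant column
    yields NaN, flagged 'undefined' in the class matrix.
    """
    if blup_table.shape[0] < 3 or blup_table.shape[1] < 2:
        raise DegenerateError("need >= 3 genotypes and >= 2 traits")
    mat = blup_table.corr(method="pearson", min_periods=3)
    labels = list(blup_table.columns)
    return CorrelationSet(labels, mat, _class_frame(mat), "trait-from-BLUP-Pearson")


def correlation_network(c: CorrelationSet, min_abs: float = 0.0) -> pd.DataFrame:
    """Edge list (source, target, r, sign, magnitude class) for |r| >= min_abs.

    Deterministic ordering: edges follow the label order of the set.
    """
    g = nx.Graph()
    labels = c.labels
    g.add_nodes_from(labels)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            r = float(c.matrix.loc[a, b])
            if np.isfinite(r) and abs(r) >= min_abs and a != b:
                g.add_edge(a, b, r=r)
    rows = [
        {"source": a, "target": b, "r": data["r"],
         "sign": "positive" if data["r"] >= 0 else "negative",
         "magnitude": classify_correlation(data["r"])}
        for a, b, data in g.edges(data=True)
    ]
    cols = ["source", "target", "r", "sign", "magnitude"]
    return pd.DataFrame(rows, columns=cols)
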