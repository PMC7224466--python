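"""Replicated simulation experiments validating the estimation machinery.

Each experiment regenerates data under known truth with the study design
(30 full-sib genotypes plus 2 parents; environments with 6/3/3 blocks;
~5% missing plots) and measures how well the REML machinery recovers it:

* agreement of the balanced-trial REML genetic variance with the
  expected-mean-squares (ANOVA) estimator, and of the interaction-model
  restricted likelihood with the nested compound-symmetry fit;
* entrywise recovery of an unstructured across-environment genetic
  covariance over replicate simulations (relative error of the mean
  estimate, i.e. bias plus Monte-Carlo error of the mean);
* how often BIC chooses the generating structure (or one nesting it) when
  the truth is a diagonal structure with strongly unequal variances;
* exactness of which-won-where winners against the per-column argmax on
  random rank-2 tables;
* agreement of the generalised heritability with the balanced closed form.

All randomness flows from one integer seed through a SeedSequence.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .gge import decompose, which_won_where
from .genetic_parameters import cullis_heritability
from .mixed_models import ModelSpec, fit, interaction_fit, select_model
from .simulate import SimConfig, TraitSim, simulate_met

__all__ = [
    "balanced_reml_vs_anova",
    "interaction_equivalence_gap",
    "unst_recovery",
    "bic_selection_rate",
    "gge_argmax_agreement",
    "cullis_vs_balanced_closed_form",
]

#: truth for the unstructured-recovery study: heterogeneous genetic
#: variances with intermediate positive correlations across environments
UNST_TRUTH = np.array([[4.0, 2.4, 1.2],
                       [2.4, 3.0, 1.5],
                       [1.2, 1.5, 2.0]])

#: truth for the selection-consistency study: strongly unequal variances
DIAG_TRUTH = np.diag([4.0, 1.0, 0.25])

#: structures whose parameter space contains a diagonal matrix
NESTING_DIAG = frozenset({"DIAG", "CSHet", "AR1H", "UNST", "FA1"})


def _subseeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2 ** 31 - 1, size=n)


def _study_config(seed: int, *, g_cov=None, sigma_g2=0.0, sigma_ge2=0.0,
                  sigma2=(1.0, 1.0, 1.0), blocks=None, n_full_sibs=30,
                  n_parents=2, missing_rate=0.05) -> SimConfig:
    blocks = blocks or {"A": 6, "B": 3, "C": 3}
    q = len(blocks)
    trait = TraitSim("y", env_means=(10.0,) * q, sigma_g2=sigma_g2,
                     sigma_ge2=sigma_ge2, sigma2_by_env=tuple(sigma2)[:q],
                     g_cov=g_cov)
    return SimConfig(seed=int(seed), traits=(trait,), blocks=blocks,
                     spacing={e: 3.0 for e in blocks}, derive=False,
                     missing_rate=missing_rate, n_full_sibs=n_full_sibs,
                     n_parents=n_parents)


def anova_sigma_g2(d, trait="y"):
    """Expected-mean-squares moment estimator on a balanced RCB trial."""
    ge = d.records.pivot_table(index="genotype", columns="block", values=trait)
    m, r = ge.shape
    arr = ge.to_numpy()
    mu = arr.mean()
    ss_g = r * ((ge.mean(1) - mu) ** 2).sum()
    ss_b = m * ((ge.mean(0) - mu) ** 2).sum()
    ss_e = ((arr - mu) ** 2).sum() - ss_g - ss_b
    ms_g = ss_g / (m - 1)
    ms_e = ss_e / ((m - 1) * (r - 1))
    return (ms_g - ms_e) / r


def balanced_reml_vs_anova(seed: int, n_reps: int = 5) -> float:
    """Max relative error of REML sigma_g2 against the ANOVA estimator over
    balanced single-environment replicates (interior solutions only)."""
    errs = []
    for s in _subseeds(seed, n_reps):
        cfg = _study_config(s, sigma_g2=4.0, sigma2=(4.0,), blocks={"A": 6},
                            n_parents=0, missing_rate=0.0)
        d, _ = simulate_met(cfg)
        target = anova_sigma_g2(d)
        if target <= 0:
            continue
        f = fit(ModelSpec(trait="y", layout="single", environment="A"),
                d, seed=0)
        errs.append(abs(f.estimates["sigma_g2"] - target) / target)
    if not errs:
        raise RuntimeError("no interior replicate produced")
    return float(max(errs))


def interaction_equivalence_gap(seed: int) -> float:
    """|lR(interaction) - lR(nested CShom)| on one study-design dataset."""
    cfg = _study_config(seed, sigma_g2=4.0, sigma_ge2=1.0)
    d, _ = simulate_met(cfg)
    fi = interaction_fit(d, "y", seed=0)
    fc = fit(ModelSpec(trait="y", layout="nested", g_structure="CShom"),
             d, seed=0)
    return float(abs(fi.loglik - fc.loglik))


def unst_recovery(seed: int, n_reps: int = 100) -> float:
    """Mean absolute relative error (percent) of the mean UNST estimate of
    the across-environment genetic covariance over replicates."""
    ests = []
    for s in _subseeds(seed, n_reps):
        d, _ = simulate_met(_study_config(s, g_cov=UNST_TRUTH))
        f = fit(ModelSpec(trait="y", layout="nested", g_structure="UNST"),
                d, seed=0, n_starts=2)
        ests.append(f.estimates["Sigma_env"])
    mean_est = np.mean(ests, axis=0)
    rel = np.abs((mean_est - UNST_TRUTH) / UNST_TRUTH)
    return float(100.0 * rel.mean())


def bic_selection_rate(seed: int, n_reps: int = 50,
                       candidates=("ID", "DIAG", "CShom", "CSHet", "UNST")
                       ) -> float:
    """Percent of DIAG-truth replicates where BIC selects the generating
    structure or one whose parameter space nests it."""
    hits = 0
    for s in _subseeds(seed, n_reps):
        d, _ = simulate_met(_study_config(s, g_cov=DIAG_TRUTH))
        tab = select_model(d, "y", candidates, ["ID"], seed=0, n_starts=2)
        g, _ = tab.best_bic
        hits += g in NESTING_DIAG
    return float(100.0 * hits / n_reps)


def gge_argmax_agreement(seed: int, n_tables: int = 200, m: int = 6,
                         q: int = 3) -> tuple[float, float]:
    """(percent of winners equal to the per-column argmax, max deviation of
    the PC variance-fraction sum from 100) over random rank-2 tables."""
    rng = np.random.default_rng(seed)
    agree = total = 0
    worst_sum = 0.0
    for _ in range(n_tables):
        M = rng.normal(size=(m, q))
        C = M - M.mean(axis=0)
        U, dvals, Vt = np.linalg.svd(C, full_matrices=False)
        dvals[2:] = 0.0
        t = pd.DataFrame(U @ np.diag(dvals) @ Vt,
                         index=[f"g{i}" for i in range(m)],
                         columns=[f"e{j}" for j in range(q)])
        b = decompose(t)
        worst_sum = max(worst_sum, abs(float(b.var_fraction.sum()) - 100.0))
        www = which_won_where(b)
        for cond in t.columns:
            total += 1
            agree += www.winners[cond] == t[cond].idxmax()
    return float(100.0 * agree / total), float(worst_sum)


def cullis_vs_balanced_closed_form(seed: int, m: int = 50, r: int = 6
                                   ) -> float:
    """|Hc2 - sigma_g2/(sigma_g2 + sigma2/r)| on one balanced trial."""
    cfg = _study_config(seed, sigma_g2=4.0, sigma2=(4.0,), blocks={"A": r},
                        n_full_sibs=m, n_parents=0, missing_rate=0.0)
    d, _ = simulate_met(cfg)
    f = fit(ModelSpec(trait="y", layout="single", environment="A"), d, seed=0)
    sg2, s2 = f.estimates["sigma_g2"], f.estimates["sigma2"]
    h = cullis_heritability(sg2, f.genotype_pev())
    return float(abs(h - sg2 / (sg2 + s2 / r)))
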