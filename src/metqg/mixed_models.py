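"""REML linear mixed models for single- and multi-environment trials.

Three model layouts are supported, all with fixed block (within environment)
and environment effects and random genetic effects:

``single``
    One environment: ``y = mu + block + g + e`` with ``g ~ N(0, sigma_g^2 I_m)``.
``nested``
    Genotype-within-environment effects ``u`` of length ``m*q`` with
    ``cov(u_i.) = Sigma_env`` per genotype, where ``Sigma_env`` is any of the
    eight structures in :mod:`metqg.vcov`; residuals homogeneous (ID) or
    heterogeneous per environment (DIAG).
``interaction``
    ``y = mu + block(env) + env + g + ge + e`` with two scalar variances.
    Marginally equivalent to the nested layout under a homogeneous
    compound-symmetry (CShom) structure with ``c = sigma_g^2`` and
    ``v = sigma_g^2 + sigma_ge^2``.

Variance parameters are estimated by maximising the restricted
log-likelihood

    lR = -1/2 [ (n - p) log 2 pi + log|V| + log|X' V^-1 X| + y' P y ]

over a transformed (unconstrained) parameter scale, with fixed effects
profiled out.  BLUPs are ``G Z' V^-1 (y - X beta)`` and their
prediction-error variance is ``G - G Z' P Z G``.

The nested layout uses a structure-exploiting evaluator (per-genotype q x q
blocks) so that model-selection sweeps and simulation studies run in
milliseconds per likelihood evaluation; a dense generic evaluator backs the
interaction layout and all BLUP/PEV computations.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from . import vcov
from .data_model import METDataset
from .errors import ConfigError, DegenerateError, DomainError, SelectionError

__all__ = [
    "ModelSpec",
    "FitResult",
    "ModelSelectionTable",
    "restricted_loglik",
    "evaluate",
    "fit",
    "interaction_fit",
    "cshom_to_interaction",
    "interaction_to_cshom",
    "lrt",
    "information_criteria",
    "select_model",
]

log = logging.getLogger(__name__)
_LOG2PI = np.log(2.0 * np.pi)

LAYOUTS = ("single", "nested", "interaction", "fixed")


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: response trait, layout and covariance structures."""

    trait: str
    layout: str = "nested"
    g_structure: str = "ID"
    r_structure: str = "ID"
    environment: str | None = None  # single layout only
    random_terms: tuple = ("g", "ge")  # interaction layout only
    covariates: tuple = ()

    def __post_init__(self):
        if self.layout not in LAYOUTS:
            raise ConfigError(f"unknown layout {self.layout!r}")
        if self.layout == "single" and self.g_structure != "ID":
            raise ConfigError("single-environment layout forces g_structure='ID'")
        if self.r_structure not in vcov.R_STRUCTURES:
            raise ConfigError(f"unknown residual structure {self.r_structure!r}")
        if self.layout == "interaction" and not set(self.random_terms) <= {"g", "ge"}:
            raise ConfigError(f"unknown random terms {self.random_terms}")


@dataclass
class FitResult:
    """A fitted mixed model: estimates, REML log-likelihood, BLUPs, PEV."""

    spec: ModelSpec
    estimates: dict
    beta: pd.Series
    loglik: float
    n: int
    p: int
    k: int
    blups: pd.Series
    pev: np.ndarray
    converged: bool
    message: str = ""
    n_evals: int = 0
    genotypes: list = field(default_factory=list)
    environments: list = field(default_factory=list)

    # -- genotype main effects ------------------------------------------
    def genotype_blups(self) -> pd.Series:
        """BLUPs of genotype main effects (averaged over environments for
        the nested layout; the ``g`` block for the interaction layout)."""
        m = len(self.genotypes)
        if self.spec.layout in ("single",):
            return self.blups
        if self.spec.layout == "interaction":
            if "g" not in self.spec.random_terms:
                raise ConfigError("model has no genotype main effect")
            return self.blups.iloc[:m].set_axis(self.genotypes)
        # nested, genotype-major: average the q within-genotype effects
        q = len(self.environments)
        u = self.blups.to_numpy().reshape(m, q)
        return pd.Series(u.mean(axis=1), index=self.genotypes)

    def genotype_pev(self) -> np.ndarray:
        """PEV matrix (m x m) matching :meth:`genotype_blups`."""
        m = len(self.genotypes)
        if self.spec.layout == "single":
            return self.pev
        if self.spec.layout == "interaction":
            return self.pev[:m, :m]
        q = len(self.environments)
        K = np.kron(np.eye(m), np.full((q, 1), 1.0 / q))
        return K.T @ self.pev @ K

    def genotype_sigma_g2(self) -> float:
        """Genetic variance attached to the genotype main effect."""
        est = self.estimates
        if "sigma_g2" in est:
            return float(est["sigma_g2"])
        # nested layout: average covariance between environments plays the
        # role of the main-effect variance (CShom equivalence)
        S = np.asarray(est["Sigma_env"])
        q = S.shape[0]
        if q == 1:
            return float(S[0, 0])
        off = S[~np.eye(q, dtype=bool)]
        return float(off.mean())

    def cell_predictions(self) -> pd.DataFrame:
        """Adjusted genotype x environment means: fixed environment mean
        (block effects averaged) plus the genetic cell effect."""
        m, envs = len(self.genotypes), self.environments
        q = len(envs)
        fixed = self.estimates["env_adjusted_means"]
        if self.spec.layout == "single":
            vals = fixed[0] + self.blups.to_numpy()[:, None]
        elif self.spec.layout == "interaction":
            u = self.blups.to_numpy()
            g = u[:m] if "g" in self.spec.random_terms else np.zeros(m)
            if "ge" in self.spec.random_terms:
                ge = u[-m * q:].reshape(m, q)
            else:
                ge = np.zeros((m, q))
            vals = fixed[None, :] + g[:, None] + ge
        else:
            vals = fixed[None, :] + self.blups.to_numpy().reshape(m, q)
        return pd.DataFrame(vals, index=self.genotypes, columns=envs)


# ---------------------------------------------------------------------------
# problem setup
# ---------------------------------------------------------------------------

class _Problem:
    """Design matrices and fast REML evaluation for one model/dataset pair."""

    def __init__(self, spec: ModelSpec, d: METDataset):
        self.spec = spec
        df = d.records
        if spec.trait not in df.columns:
            raise ConfigError(f"trait {spec.trait!r} not in dataset")
        if spec.layout == "single":
            env = spec.environment or d.environments[0]
            if env not in d.environments:
                raise ConfigError(f"unknown environment {env!r}")
            df = df[df["environment"] == env]
            self.environments = [env]
        else:
            self.environments = list(d.environments)
        df = df[df[spec.trait].notna()]
        if len(df) == 0:
            raise DegenerateError(f"no observations for trait {spec.trait!r}")
        self.genotypes = list(d.genotypes)
        if len(self.genotypes) < 2:
            raise DegenerateError("need at least 2 genotypes")
        self.df = df
        m, q = len(self.genotypes), len(self.environments)
        self.m, self.q = m, q

        y = df[spec.trait].to_numpy(dtype=float)
        self.scale = float(np.std(y)) or 1.0
        self.y = y / self.scale
        self.n = len(y)

        gmap = {g: i for i, g in enumerate(self.genotypes)}
        emap = {e: i for i, e in enumerate(self.environments)}
        self.g_idx = df["genotype"].map(gmap).to_numpy()
        self.e_idx = df["environment"].map(emap).to_numpy()
        self.cell_idx = self.g_idx * q + self.e_idx  # genotype-major

        self.X, self.beta_names = self._fixed_design(df)
        self.p = self.X.shape[1]
        if self.n <= self.p:
            raise DegenerateError("no residual degrees of freedom")

        # per-environment sufficient statistics for the fast path
        X, yv = self.X, self.y
        self.counts = np.bincount(self.cell_idx, minlength=m * q).reshape(m, q)
        self.cell_sum_y = np.bincount(
            self.cell_idx, weights=yv, minlength=m * q
        ).reshape(m, q)
        csx = np.zeros((m * q, self.p))
        np.add.at(csx, self.cell_idx, X)
        self.cell_sum_X = csx.reshape(m, q, self.p)
        self.n_env = np.bincount(self.e_idx, minlength=q).astype(float)
        self.XtX_env = np.stack(
            [X[self.e_idx == e].T @ X[self.e_idx == e] for e in range(q)]
        )
        self.Xty_env = np.stack(
            [X[self.e_idx == e].T @ yv[self.e_idx == e] for e in range(q)]
        )
        self.yty_env = np.array(
            [float(yv[self.e_idx == e] @ yv[self.e_idx == e]) for e in range(q)]
        )

        # parameter packing
        self.kg = self._kg()
        self.kr = 1 if spec.r_structure == "ID" else q
        self.k = self.kg + self.kr
        self._Z = None  # dense random design, built lazily

    def _kg(self) -> int:
        s = self.spec
        if s.layout == "fixed":
            return 0
        if s.layout == "single":
            return 1
        if s.layout == "interaction":
            return len(s.random_terms)
        return vcov.n_params(s.g_structure, self.q)

    def _fixed_design(self, df):
        cols = [np.ones(self.n)]
        names = ["(intercept)"]
        q = self.q
        if q > 1:
            for e in range(1, q):
                cols.append((self.e_idx == e).astype(float))
                names.append(f"env[{self.environments[e]}]")
        for e, env in enumerate(self.environments):
            blocks = sorted(df.loc[df["environment"] == env, "block"].unique())
            in_env = self.e_idx == e
            brow = df["block"].to_numpy()
            for b in blocks[1:]:
                cols.append((in_env & (brow == b)).astype(float))
                names.append(f"block[{env}:{b}]")
        for cov in self.spec.covariates:
            cols.append(df[cov].to_numpy(dtype=float))
            names.append(cov)
        X = np.column_stack(cols)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise DegenerateError("fixed-effect design is rank deficient")
        return X, names

    # -- parameter handling ---------------------------------------------
    def split(self, theta):
        return np.asarray(theta[: self.kg]), np.asarray(theta[self.kg:])

    def g_natural(self, theta_g):
        s = self.spec
        if s.layout == "fixed":
            return np.array([])
        if s.layout in ("single",):
            return vcov.theta_to_natural("ID", 1, theta_g)
        if s.layout == "interaction":
            return np.exp(np.clip(theta_g, -40, 40))
        return vcov.theta_to_natural(s.g_structure, self.q, theta_g)

    def r_natural(self, theta_r):
        return np.exp(np.clip(theta_r, -40, 40))

    def r_pervar(self, theta_r):
        """Residual variance per environment (length q)."""
        nat = self.r_natural(theta_r)
        if self.spec.r_structure == "ID":
            return np.full(self.q, nat[0])
        return nat

    def sigma_env(self, theta_g) -> np.ndarray:
        """q x q genetic covariance implied by the g parameters."""
        s = self.spec
        nat = self.g_natural(theta_g)
        if s.layout == "single":
            return np.array([[nat[0]]])
        if s.layout == "interaction":
            terms = dict(zip(s.random_terms, nat))
            sg = terms.get("g", 0.0)
            sge = terms.get("ge", 0.0)
            return np.full((self.q, self.q), sg) + sge * np.eye(self.q)
        return vcov.build(vcov.VcovSpec(s.g_structure, self.q, nat))

    # -- REML log-likelihood --------------------------------------------
    def loglik(self, theta) -> float:
        tg, tr = self.split(theta)
        rvar = self.r_pervar(tr)
        try:
            if self.spec.layout in ("single", "nested"):
                Sigma = self.sigma_env(tg)
                return self._nested_ll(Sigma, rvar)
            return self._dense_ll(tg, rvar)
        except (np.linalg.LinAlgError, DomainError):
            return -np.inf

    def _nested_ll(self, Sigma, rvar) -> float:
        q, p, n = self.q, self.p, self.n
        rinv = 1.0 / rvar
        D = self.counts * rinv
        C_y = self.cell_sum_y * rinv
        C_X = self.cell_sum_X * rinv[None, :, None]
        XtRiX = np.einsum("e,epq->pq", rinv, self.XtX_env)
        XtRiy = rinv @ self.Xty_env
        ytRiy = float(rinv @ self.yty_env)
        logdetR = float(self.n_env @ np.log(rvar))

        L = np.linalg.cholesky(Sigma + 1e-12 * np.trace(Sigma) / q * np.eye(q))
        B = np.einsum("ba,gb,bc->gac", L, D, L) + np.eye(q)[None]
        cB = np.linalg.cholesky(B)
        logdetB = 2.0 * float(np.log(np.diagonal(cB, axis1=1, axis2=2)).sum())
        T_y = np.einsum("ba,gb->ga", L, C_y)
        T_X = np.einsum("ba,gbp->gap", L, C_X)
        W_y = np.linalg.solve(B, T_y[..., None])[..., 0]
        W_X = np.linalg.solve(B, T_X)
        ytViy = ytRiy - float((T_y * W_y).sum())
        XtViy = XtRiy - np.einsum("gap,ga->p", T_X, W_y)
        XtViX = XtRiX - np.einsum("gap,gaq->pq", T_X, W_X)
        cA = cho_factor(XtViX)
        logdetA = 2.0 * float(np.log(np.diag(cA[0])).sum())
        beta = cho_solve(cA, XtViy)
        ytPy = ytViy - float(XtViy @ beta)
        return -0.5 * ((n - p) * _LOG2PI + logdetR + logdetB + logdetA + ytPy)

    # -- dense generic path ---------------------------------------------
    def Z_dense(self) -> np.ndarray:
        if self._Z is None:
            n, m, q = self.n, self.m, self.q
            if self.spec.layout == "fixed":
                self._Z = np.zeros((n, 0))
            elif self.spec.layout == "interaction":
                blocks = []
                if "g" in self.spec.random_terms:
                    Zg = np.zeros((n, m))
                    Zg[np.arange(n), self.g_idx] = 1.0
                    blocks.append(Zg)
                if "ge" in self.spec.random_terms:
                    Zge = np.zeros((n, m * q))
                    Zge[np.arange(n), self.cell_idx] = 1.0
                    blocks.append(Zge)
                self._Z = np.hstack(blocks)
            else:
                Z = np.zeros((n, m * q))
                Z[np.arange(n), self.cell_idx] = 1.0
                self._Z = Z
        return self._Z

    def G_dense(self, theta_g) -> np.ndarray:
        s, m, q = self.spec, self.m, self.q
        if s.layout == "fixed":
            return np.zeros((0, 0))
        if s.layout == "interaction":
            nat = self.g_natural(theta_g)
            terms = dict(zip(s.random_terms, nat))
            parts = []
            if "g" in s.random_terms:
                parts.append(np.full(m, terms["g"]))
            if "ge" in s.random_terms:
                parts.append(np.full(m * q, terms["ge"]))
            return np.diag(np.concatenate(parts))
        return np.kron(np.eye(m), self.sigma_env(theta_g))

    def _dense_ll(self, theta_g, rvar) -> float:
        out = _dense_reml(self.y, self.X, self.Z_dense(), self.G_dense(theta_g),
                          rvar[self.e_idx])
        return out["loglik"]

    # -- final quantities at the optimum --------------------------------
    def solution(self, theta) -> dict:
        tg, tr = self.split(theta)
        rvar = self.r_pervar(tr)
        out = _dense_reml(self.y, self.X, self.Z_dense(), self.G_dense(tg),
                          rvar[self.e_idx], want_blups=True)
        return out

    # -- starting values -------------------------------------------------
    def moment_start(self) -> np.ndarray:
        df, q = self.df, self.q
        piv = pd.DataFrame({
            "g": self.g_idx, "e": self.e_idx, "y": self.y
        }).pivot_table(index="g", columns="e", values="y", aggfunc="mean")
        piv = piv.reindex(index=range(self.m), columns=range(q))
        vary = float(np.var(self.y)) or 1.0
        # pooled within-cell residual variance, per environment
        res = pd.DataFrame({"c": self.cell_idx, "e": self.e_idx, "y": self.y})
        within = res.groupby("c")["y"].var(ddof=1)
        cell_env = res.groupby("c")["e"].first()
        r0 = np.empty(q)
        for e in range(q):
            vals = within[cell_env == e].dropna()
            r0[e] = float(vals.mean()) if len(vals) else 0.5 * vary
        r0 = np.clip(r0, 0.05 * vary, None)

        S = piv.cov(min_periods=2).to_numpy()
        bad = ~np.isfinite(S)
        if bad.any():
            S[bad] = 0.0
        if not np.all(np.isfinite(np.diag(S))) or np.any(np.diag(S) <= 0):
            S = 0.5 * vary * np.eye(q)
        tr_q = float(np.trace(S)) / q
        S = 0.8 * S + 0.2 * tr_q * np.eye(q)  # shrink toward sphericity

        s = self.spec
        if s.layout == "fixed":
            tg = np.array([])
        elif s.layout == "single":
            nb = max(self.n / self.m, 1.0)
            sg0 = max(float(S[0, 0]) - r0[0] / nb, 0.1 * vary)
            tg = np.log([sg0])
        elif s.layout == "interaction":
            off = S[~np.eye(q, dtype=bool)]
            sg0 = float(np.clip(off.mean() if off.size else 0.3 * tr_q,
                                0.05 * vary, None))
            sge0 = max(tr_q - sg0, 0.05 * vary)
            vals = {"g": sg0, "ge": sge0}
            tg = np.log([vals[t] for t in s.random_terms])
        else:
            tg = vcov.natural_to_theta(s.g_structure, q,
                                       _moment_params(s.g_structure, S))
        if s.r_structure == "ID":
            tr = np.log([float(np.average(r0, weights=self.n_env))])
        else:
            tr = np.log(r0)
        return np.concatenate([tg, tr])

    def bounds(self):
        vary = 1.0  # data standardised to unit variance
        lo, hi = np.log(1e-10 * vary), np.log(1e5 * vary)
        s = self.spec
        if s.layout == "fixed":
            gb = []
        elif s.layout == "single":
            gb = [(lo, hi)]
        elif s.layout == "interaction":
            gb = [(lo, hi)] * len(s.random_terms)
        else:
            gb = vcov.theta_bounds(s.g_structure, self.q, lo, hi)
        rb = [(lo, hi)] * self.kr
        return gb + rb

    def jitter(self, theta, rng) -> np.ndarray:
        t = np.array(theta, dtype=float)
        gb = self.bounds()
        for i, (lo, hi) in enumerate(gb):
            if hi - lo > 50:  # a log-variance coordinate
                t[i] += rng.normal(0, 0.5)
            else:
                t[i] = t[i] * rng.uniform(0.3, 1.0) + rng.normal(0, 0.3)
            t[i] = np.clip(t[i], lo + 1e-6, hi - 1e-6)
        return t


def _moment_params(name: str, S: np.ndarray) -> np.ndarray:
    """Natural-scale starting parameters derived from a cell-means covariance."""
    q = S.shape[0]
    d = np.clip(np.diag(S), 1e-8, None)
    sd = np.sqrt(d)
    R = S / np.outer(sd, sd)
    off = R[~np.eye(q, dtype=bool)]
    rbar = float(np.clip(off.mean() if off.size else 0.0, -0.8 / max(q - 1, 1), 0.9))
    if name == "ID":
        return np.array([d.mean()])
    if name == "DIAG":
        return d
    if name == "CShom":
        return np.array([d.mean(), rbar * d.mean()])
    if name == "CSHet":
        return np.concatenate([d, [rbar]])
    if name in ("AR1", "AR1H"):
        if q > 1:
            lag1 = np.array([R[i, i + 1] for i in range(q - 1)])
            rho = float(np.clip(lag1.mean(), -0.9, 0.9))
        else:
            rho = 0.0
        if name == "AR1":
            return np.array([d.mean(), rho])
        return np.concatenate([d, [rho]])
    if name == "UNST":
        return S[np.tril_indices(q)]
    if name == "FA1":
        w, V = np.linalg.eigh(S)
        lam = V[:, -1] * np.sqrt(max(w[-1], 1e-8))
        psi = np.clip(np.diag(S) - lam ** 2, 0.05 * d.mean(), None)
        return np.concatenate([lam, psi])
    raise DomainError(name)


# ---------------------------------------------------------------------------
# dense REML (generic; also the BLUP/PEV backend)
# ---------------------------------------------------------------------------

def _dense_reml(y, X, Z, G, rdiag, want_blups: bool = False) -> dict:
    """Evaluate the REML log-likelihood for V = Z G Z' + diag(rdiag).

    Uses the Woodbury identity through a Cholesky factor of ``G`` so that
    only c x c systems are solved (c = number of random effects).  With
    ``want_blups`` also returns fixed-effect solutions, BLUPs and their
    prediction-error variance matrix ``G - G Z' P Z G``.
    """
    n, p = X.shape
    c = Z.shape[1]
    rinv = 1.0 / rdiag
    logdetR = float(np.sum(np.log(rdiag)))

    if c > 0:
        LG = np.linalg.cholesky(G + 1e-12 * (np.trace(G) / c + 1e-300) * np.eye(c))
        U = (rinv[:, None] * Z) @ LG  # R^-1 Z LG
        B = LG.T @ (Z.T @ U) + np.eye(c)
        cB = cho_factor(B)
        logdetB = 2.0 * float(np.log(np.diag(cB[0])).sum())

        def vinv(M):
            return rinv[:, None] * M - U @ cho_solve(cB, U.T @ M)
    else:
        logdetB = 0.0

        def vinv(M):
            return rinv[:, None] * M

    ViX = vinv(X)
    Viy = vinv(y[:, None])[:, 0]
    A = X.T @ ViX
    cA = cho_factor(A)
    logdetA = 2.0 * float(np.log(np.diag(cA[0])).sum())
    XtViy = X.T @ Viy
    beta = cho_solve(cA, XtViy)
    ytPy = float(y @ Viy) - float(XtViy @ beta)
    ll = -0.5 * ((n - p) * _LOG2PI + logdetR + logdetB + logdetA + ytPy)
    out = {"loglik": ll, "beta": beta}
    if want_blups and c > 0:
        Vir = Viy - ViX @ beta
        u = G @ (Z.T @ Vir)
        ZtViZ = Z.T @ vinv(Z)
        ZtViX = Z.T @ ViX
        ZtPZ = ZtViZ - ZtViX @ cho_solve(cA, ZtViX.T)
        pev = G - G @ ZtPZ @ G
        pev = 0.5 * (pev + pev.T)
        out.update(u=u, pev=pev)
    elif want_blups:
        out.update(u=np.zeros(0), pev=np.zeros((0, 0)))
    return out


def reml_loglik_dense(y, X, V) -> float:
    """Direct REML log-likelihood for an explicit covariance matrix V.

    Reference implementation used for verification; O(n^3).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    n, p = X.shape
    cV = cho_factor(np.asarray(V, dtype=float))
    logdetV = 2.0 * float(np.log(np.diag(cV[0])).sum())
    ViX = cho_solve(cV, X)
    Viy = cho_solve(cV, y)
    A = X.T @ ViX
    cA = cho_factor(A)
    logdetA = 2.0 * float(np.log(np.diag(cA[0])).sum())
    XtViy = X.T @ Viy
    beta = cho_solve(cA, XtViy)
    ytPy = float(y @ Viy) - float(XtViy @ beta)
    return -0.5 * ((n - p) * _LOG2PI + logdetV + logdetA + ytPy)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def _theta_from_natural(prob: _Problem, g_params, r_params) -> np.ndarray:
    s = prob.spec
    inv = 1.0 / prob.scale ** 2
    r_params = np.atleast_1d(np.asarray(r_params, dtype=float)) * inv
    if s.layout == "fixed":
        tg = np.array([])
    elif s.layout in ("single", "interaction"):
        tg = np.log(np.atleast_1d(np.asarray(g_params, dtype=float)) * inv)
    else:
        nat = vcov.scale_params(s.g_structure, prob.q,
                                np.atleast_1d(np.asarray(g_params, float)), inv)
        tg = vcov.natural_to_theta(s.g_structure, prob.q, nat)
    return np.concatenate([tg, np.log(r_params)])


def restricted_loglik(spec: ModelSpec, d: METDataset, g_params, r_params) -> float:
    """REML log-likelihood at the given natural-scale variance parameters.

    ``g_params``: structure parameters for the genetic side (variance for
    ``single``; ``(sigma_g2, sigma_ge2)`` for ``interaction``; the
    :mod:`metqg.vcov` parameter vector for ``nested``).  ``r_params``:
    residual variance(s).
    """
    prob = _Problem(spec, d)
    theta = _theta_from_natural(prob, g_params, r_params)
    ll = prob.loglik(theta)
    return ll - (prob.n - prob.p) * np.log(prob.scale)


def _finish(prob: _Problem, theta, converged, message, n_evals) -> FitResult:
    s, m, q = prob.spec, prob.m, prob.q
    sol = prob.solution(theta)
    sc = prob.scale
    tg, tr = prob.split(theta)
    rnat = prob.r_natural(tr) * sc ** 2

    estimates: dict = {}
    if s.r_structure == "ID":
        estimates["sigma2"] = float(rnat[0])
    else:
        estimates["sigma2_by_env"] = dict(zip(prob.environments, rnat.tolist()))
        estimates["sigma2"] = float(np.average(rnat, weights=prob.n_env))
    if s.layout == "single":
        estimates["sigma_g2"] = float(prob.g_natural(tg)[0] * sc ** 2)
    elif s.layout == "interaction":
        nat = prob.g_natural(tg) * sc ** 2
        for term, v in zip(s.random_terms, nat):
            estimates["sigma_g2" if term == "g" else "sigma_ge2"] = float(v)
    elif s.layout == "nested":
        Sigma = prob.sigma_env(tg) * sc ** 2
        estimates["Sigma_env"] = Sigma
        estimates["g_spec"] = vcov.VcovSpec(
            s.g_structure, q,
            vcov.scale_params(s.g_structure, q, prob.g_natural(tg), sc ** 2))

    beta = pd.Series(sol["beta"] * sc, index=prob.beta_names)
    # fixed adjusted mean per environment (block effects averaged)
    env_means = np.empty(q)
    for e, env in enumerate(prob.environments):
        mask = prob.e_idx == e
        env_means[e] = float(prob.X[mask].mean(axis=0) @ sol["beta"]) * sc
    estimates["env_adjusted_means"] = env_means

    if s.layout == "single":
        index = pd.Index(prob.genotypes, name="genotype")
    elif s.layout == "interaction":
        parts = []
        if "g" in s.random_terms:
            parts.extend([("g", g, "") for g in prob.genotypes])
        if "ge" in s.random_terms:
            parts.extend([("ge", g, e) for g in prob.genotypes
                          for e in prob.environments])
        index = pd.MultiIndex.from_tuples(parts, names=["term", "genotype",
                                                        "environment"])
    elif s.layout == "fixed":
        index = pd.Index([])
    else:
        index = pd.MultiIndex.from_product(
            [prob.genotypes, prob.environments], names=["genotype", "environment"])
    blups = pd.Series(sol["u"] * sc, index=index)
    pev = sol["pev"] * sc ** 2
    ll = sol["loglik"] - (prob.n - prob.p) * np.log(sc)
    return FitResult(
        spec=s, estimates=estimates, beta=beta, loglik=float(ll),
        n=prob.n, p=prob.p, k=prob.k, blups=blups, pev=pev,
        converged=converged, message=message, n_evals=n_evals,
        genotypes=prob.genotypes, environments=prob.environments,
    )


def evaluate(spec: ModelSpec, d: METDataset, g_params, r_params) -> FitResult:
    """Build the full fit summary (BLUPs, PEV, ...) at fixed parameters."""
    prob = _Problem(spec, d)
    theta = _theta_from_natural(prob, g_params, r_params)
    return _finish(prob, theta, converged=True, message="evaluated at fixed "
                   "parameters", n_evals=1)


def fit(
    spec: ModelSpec,
    d: METDataset,
    *,
    n_starts: int = 3,
    seed: int = 0,
    polish: bool = True,
    maxiter: int = 500,
) -> FitResult:
    """Fit the model by REML with multi-start quasi-Newton optimisation.

    Deterministic given dataset and ``seed`` (used only to jitter the
    additional starting points).  Non-convergence is flagged on the result,
    not raised, so that model-selection sweeps can skip the structure.
    """
    prob = _Problem(spec, d)
    rng = np.random.default_rng(seed)
    t0 = prob.moment_start()
    starts = [t0] + [prob.jitter(t0, rng) for _ in range(max(n_starts - 1, 0))]
    bounds = prob.bounds()

    def neg(theta):
        ll = prob.loglik(theta)
        # large finite penalty keeps finite-difference gradients well defined
        return 1e10 if not np.isfinite(ll) else -ll

    best = None
    n_evals = 0
    any_success = False
    for t in starts:
        try:
            res = optimize.minimize(
                neg, t, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-7},
            )
        except (np.linalg.LinAlgError, DomainError):
            continue
        n_evals += res.nfev
        if not np.isfinite(res.fun):
            continue
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise DegenerateError(
            f"REML optimisation failed for every start ({spec.g_structure}/"
            f"{spec.r_structure}, trait {spec.trait!r})")
    theta, fun = best.x, best.fun
    polished = False
    if polish:
        nm = optimize.minimize(
            neg, theta, method="Nelder-Mead",
            options={"maxiter": 3000, "maxfev": 3000,
                     "fatol": 1e-10, "xatol": 1e-7},
        )
        n_evals += nm.nfev
        polished = bool(nm.success)
        if np.isfinite(nm.fun) and nm.fun < fun:
            theta, fun = nm.x, nm.fun
    converged = bool(any_success or polished)
    message = best.message if isinstance(best.message, str) else str(best.message)
    out = _finish(prob, theta, converged, message, n_evals)
    return out


def interaction_fit(d: METDataset, trait: str, *, r_structure: str = "ID",
                    **fit_kw) -> FitResult:
    """Fit the MET interaction model ``mu + block(env) + env + g + ge + e``."""
    if d.n_environments < 2:
        raise ConfigError("interaction layout needs at least 2 environments")
    spec = ModelSpec(trait=trait, layout="interaction", r_structure=r_structure)
    return fit(spec, d, **fit_kw)


def cshom_to_interaction(v: float, c: float) -> tuple[float, float]:
    """Map CShom (diagonal v, off-diagonal c) to (sigma_g2, sigma_ge2)."""
    return float(c), float(v - c)


def interaction_to_cshom(sigma_g2: float, sigma_ge2: float) -> tuple[float, float]:
    return float(sigma_g2 + sigma_ge2), float(sigma_g2)


def lrt(full: FitResult, reduced: FitResult, *,
        boundary_mixture: bool = False) -> tuple[float, int, float]:
    """Likelihood-ratio test of a reduced model nested in a full model.

    Statistic ``2 (lR_full - lR_reduced)`` clipped at zero and referred to a
    chi-square with ``k_full - k_reduced`` degrees of freedom (plain
    chi-square by default; 50:50 boundary mixture for a single variance
    behind ``boundary_mixture``).
    """
    if full.spec.trait != reduced.spec.trait or full.n != reduced.n:
        raise ConfigError("LRT requires the same trait and data in both models")
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    df = full.k - reduced.k
    if df < 0:
        raise ConfigError("reduced model has more parameters than the full model")
    if df == 0:
        return stat, 0, 1.0
    if boundary_mixture and df == 1:
        p = 0.5 * stats.chi2.sf(stat, 1) + 0.5 * float(stat <= 0.0)
    else:
        p = float(stats.chi2.sf(stat, df))
    if stat == 0.0:
        p = 1.0
    return stat, df, p


def information_criteria(f: FitResult, *, n_basis: str = "residual"
                         ) -> tuple[float, float]:
    """AIC and BIC from the REML log-likelihood and variance-parameter count.

    ``n_basis='residual'`` uses n - p in the BIC sample size (the convention
    of common MET software); ``'n'`` uses n.
    """
    nn = f.n - f.p if n_basis == "residual" else f.n
    aic = -2.0 * f.loglik + 2.0 * f.k
    bic = -2.0 * f.loglik + f.k * np.log(nn)
    return float(aic), float(bic)


@dataclass
class ModelSelectionTable:
    """Ranked covariance-structure candidates for one trait."""

    trait: str
    table: pd.DataFrame
    fits: dict

    @property
    def best_aic(self) -> tuple[str, str]:
        row = self.table[self.table["best_aic"]].iloc[0]
        return row["g_structure"], row["r_structure"]

    @property
    def best_bic(self) -> tuple[str, str]:
        row = self.table[self.table["best_bic"]].iloc[0]
        return row["g_structure"], row["r_structure"]

    def best_fit(self, criterion: str = "bic") -> FitResult:
        key = self.best_bic if criterion == "bic" else self.best_aic
        return self.fits[key]


def select_model(
    d: METDataset,
    trait: str,
    g_candidates: Sequence[str] = vcov.G_STRUCTURES,
    r_candidates: Sequence[str] = vcov.R_STRUCTURES,
    **fit_kw,
) -> ModelSelectionTable:
    """Fit every (G, R) structure pair by REML and rank by AIC and BIC.

    Only converged fits are eligible; ties break on fewer parameters then
    on structure-name order.  Raises :class:`SelectionError` if every
    candidate fails.
    """
    if not len(g_candidates) or not len(r_candidates):
        raise SelectionError("no candidate structures given")
    rows = []
    fits = {}
    failures = []
    for g, r in itertools.product(g_candidates, r_candidates):
        spec = ModelSpec(trait=trait, layout="nested", g_structure=g,
                         r_structure=r)
        try:
            f = fit(spec, d, **fit_kw)
        except Exception as exc:  # noqa: BLE001 - diagnostics, not control flow
            failures.append(f"{g}/{r}: {exc}")
            continue
        aic, bic = information_criteria(f)
        fits[(g, r)] = f
        rows.append({"g_structure": g, "r_structure": r, "n_params": f.k,
                     "loglik": f.loglik, "AIC": aic, "BIC": bic,
                     "converged": f.converged})
    if not rows:
        raise SelectionError("all candidates failed: " + "; ".join(failures))
    tab = pd.DataFrame(rows)
    order_g = {g: i for i, g in enumerate(vcov.G_STRUCTURES)}
    order_r = {r: i for i, r in enumerate(vcov.R_STRUCTURES)}
    tab["_og"] = tab["g_structure"].map(order_g)
    tab["_or"] = tab["r_structure"].map(order_r)
    eligible = tab["converged"]
    for crit, flag in (("AIC", "best_aic"), ("BIC", "best_bic")):
        ranked = tab[eligible].sort_values([crit, "n_params", "_og", "_or"])
        tab[flag] = False
        if len(ranked):
            tab.loc[ranked.index[0], flag] = True
    tab = tab.sort_values(["BIC"]).drop(columns=["_og", "_or"]).reset_index(drop=True)
    return ModelSelectionTable(trait, tab, fits)
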