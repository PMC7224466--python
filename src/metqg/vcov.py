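"""Parameterised variance-covariance structures for genetic and residual effects.

Eight structures are available for the across-environment genetic covariance
matrix of a MET mixed model, and two for the residual side:

========  ====================================  ==========
name      matrix                                parameters
========  ====================================  ==========
ID        v * I                                 1
DIAG      diag(v_1..v_q)                        q
CShom     v on diagonal, c off-diagonal         2
CSHet     sqrt(v_i v_j) * rho off-diagonal      q + 1
AR1       v * rho^|i-j|                         2
AR1H      sqrt(v_i v_j) * rho^|i-j|             q + 1
UNST      any symmetric positive definite       q(q+1)/2
FA1       lambda lambda' + diag(psi)            2q
========  ====================================  ==========

Natural-scale parameter vectors are stored in :class:`VcovSpec`; the
``*_theta`` helpers map them to and from an unconstrained scale
(log variances, logit/atanh correlations, log-Cholesky for UNST) used by
the REML optimiser.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError

__all__ = [
    "G_STRUCTURES",
    "R_STRUCTURES",
    "VcovSpec",
    "n_params",
    "build",
    "natural_to_theta",
    "theta_to_natural",
]

G_STRUCTURES = ("ID", "DIAG", "CShom", "CSHet", "AR1", "AR1H", "UNST", "FA1")
R_STRUCTURES = ("ID", "DIAG")

_EPS = 1e-6


@dataclass(frozen=True)
class VcovSpec:
    """A named covariance structure of dimension ``dim`` with natural params."""

    name: str
    dim: int
    params: np.ndarray

    def __post_init__(self):
        if self.name not in G_STRUCTURES:
            raise DomainError(f"unknown structure {self.name!r}")
        object.__setattr__(self, "params", np.asarray(self.params, dtype=float))
        k = n_params(self.name, self.dim)
        if self.params.shape != (k,):
            raise DomainError(
                f"{self.name} (q={self.dim}) needs {k} parameters, "
                f"got {self.params.shape}"
            )

    def matrix(self) -> np.ndarray:
        return build(self)


def n_params(name: str, q: int) -> int:
    """Number of free parameters of structure ``name`` at dimension ``q``."""
    table = {
        "ID": 1,
        "DIAG": q,
        "CShom": 2,
        "CSHet": q + 1,
        "AR1": 2,
        "AR1H": q + 1,
        "UNST": q * (q + 1) // 2,
        "FA1": 2 * q,
    }
    try:
        return table[name]
    except KeyError:
        raise DomainError(f"unknown structure {name!r}") from None


def _check_var(v, what="variance"):
    v = np.asarray(v, dtype=float)
    if np.any(v <= 0) or not np.all(np.isfinite(v)):
        raise DomainError(f"{what} must be positive and finite, got {v}")
    return v


def build(spec: VcovSpec) -> np.ndarray:
    """Build the q x q covariance matrix for a spec with in-domain params."""
    q, p = spec.dim, spec.params
    name = spec.name
    if name == "ID":
        return _check_var(p[0]) * np.eye(q)
    if name == "DIAG":
        return np.diag(_check_var(p))
    if name == "CShom":
        v, c = float(p[0]), float(p[1])
        _check_var(v)
        if not (-v / max(q - 1, 1) < c < v):
            raise DomainError(f"CShom covariance {c} outside (-v/(q-1), v)")
        return np.full((q, q), c) + (v - c) * np.eye(q)
    if name == "CSHet":
        v = _check_var(p[:q])
        rho = float(p[q])
        if not (-1.0 / max(q - 1, 1) < rho < 1.0):
            raise DomainError(f"CSHet correlation {rho} out of domain")
        s = np.sqrt(v)
        m = rho * np.outer(s, s)
        np.fill_diagonal(m, v)
        return m
    if name in ("AR1", "AR1H"):
        if name == "AR1":
            v = _check_var(p[0]) * np.ones(q)
            rho = float(p[1])
        else:
            v = _check_var(p[:q])
            rho = float(p[q])
        if not (-1.0 < rho < 1.0):
            raise DomainError(f"{name} correlation {rho} out of (-1, 1)")
        lag = np.abs(np.subtract.outer(np.arange(q), np.arange(q)))
        s = np.sqrt(v)
        return np.outer(s, s) * rho ** lag
    if name == "UNST":
        m = np.zeros((q, q))
        idx = np.tril_indices(q)
        m[idx] = p
        m = m + np.tril(m, -1).T
        try:
            np.linalg.cholesky(m + 1e-12 * np.trace(m) / q * np.eye(q))
        except np.linalg.LinAlgError:
            raise DomainError("UNST parameters are not positive definite") from None
        return m
    if name == "FA1":
        lam = np.asarray(p[:q], dtype=float)
        psi = np.asarray(p[q:], dtype=float)
        if np.any(psi < 0):
            raise DomainError("FA1 specific variances must be >= 0")
        return np.outer(lam, lam) + np.diag(psi)
    raise DomainError(f"unknown structure {name!r}")


# ---------------------------------------------------------------------------
# unconstrained transforms (optimiser scale)
# ---------------------------------------------------------------------------

def _cs_lo(q: int) -> float:
    return -1.0 / max(q - 1, 1) + _EPS


def _z_to_interval(z, lo, hi):
    return lo + (hi - lo) / (1.0 + np.exp(-np.clip(z, -40, 40)))


def _interval_to_z(x, lo, hi):
    x = np.clip(x, lo + 1e-12, hi - 1e-12)
    frac = (x - lo) / (hi - lo)
    return np.log(frac / (1.0 - frac))


def _safe_exp(z):
    return np.exp(np.clip(z, -40.0, 40.0))


def theta_to_natural(name: str, q: int, theta: np.ndarray) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    if name == "ID":
        return _safe_exp(theta)
    if name == "DIAG":
        return _safe_exp(theta)
    if name == "CShom":
        v = _safe_exp(theta[0])
        rho = _z_to_interval(theta[1], _cs_lo(q), 1.0 - _EPS)
        return np.array([v, rho * v])
    if name == "CSHet":
        v = _safe_exp(theta[:q])
        rho = _z_to_interval(theta[q], _cs_lo(q), 1.0 - _EPS)
        return np.concatenate([v, [rho]])
    if name == "AR1":
        return np.array([_safe_exp(theta[0]), np.tanh(theta[1]) * (1 - _EPS)])
    if name == "AR1H":
        v = _safe_exp(theta[:q])
        return np.concatenate([v, [np.tanh(theta[q]) * (1 - _EPS)]])
    if name == "UNST":
        L = np.zeros((q, q))
        k = 0
        for i in range(q):
            for j in range(i + 1):
                L[i, j] = _safe_exp(theta[k]) if i == j else theta[k]
                k += 1
        m = L @ L.T
        return m[np.tril_indices(q)]
    if name == "FA1":
        lam = theta[:q].copy()
        if lam[0] < 0:  # sign indeterminacy: first loading >= 0
            lam = -lam
        return np.concatenate([lam, _safe_exp(theta[q:])])
    raise DomainError(f"unknown structure {name!r}")


def natural_to_theta(name: str, q: int, params: np.ndarray) -> np.ndarray:
    params = np.asarray(params, dtype=float)
    if name in ("ID", "DIAG"):
        return np.log(_check_var(params))
    if name == "CShom":
        v, c = params
        return np.array([np.log(v),
                         _interval_to_z(c / v, _cs_lo(q), 1.0 - _EPS)])
    if name == "CSHet":
        return np.concatenate([np.log(_check_var(params[:q])),
                               [_interval_to_z(params[q], _cs_lo(q), 1.0 - _EPS)]])
    if name == "AR1":
        return np.array([np.log(params[0]),
                         np.arctanh(np.clip(params[1] / (1 - _EPS), -1 + 1e-12,
                                            1 - 1e-12))])
    if name == "AR1H":
        return np.concatenate([np.log(_check_var(params[:q])),
                               [np.arctanh(np.clip(params[q] / (1 - _EPS),
                                                   -1 + 1e-12, 1 - 1e-12))]])
    if name == "UNST":
        m = np.zeros((q, q))
        m[np.tril_indices(q)] = params
        m = m + np.tril(m, -1).T
        L = np.linalg.cholesky(m + 1e-10 * np.trace(m) / q * np.eye(q))
        out = []
        for i in range(q):
            for j in range(i + 1):
                out.append(np.log(max(L[i, j], 1e-12)) if i == j else L[i, j])
        return np.array(out)
    if name == "FA1":
        lam = params[:q]
        psi = np.maximum(params[q:], 1e-12)
        return np.concatenate([lam, np.log(psi)])
    raise DomainError(f"unknown structure {name!r}")


def scale_params(name: str, q: int, params: np.ndarray, factor: float) -> np.ndarray:
    """Rescale natural parameters when the response is scaled by sqrt(factor).

    Variance-like parameters multiply by ``factor``; correlations are scale
    free; FA1 loadings multiply by sqrt(factor).
    """
    p = np.asarray(params, dtype=float).copy()
    if name in ("ID", "DIAG", "CShom", "UNST"):
        return p * factor
    if name in ("CSHet", "AR1H"):
        p[:q] *= factor
        return p
    if name == "AR1":
        p[0] *= factor
        return p
    if name == "FA1":
        p[:q] *= np.sqrt(factor)
        p[q:] *= factor
        return p
    raise DomainError(f"unknown structure {name!r}")


def theta_bounds(name: str, q: int, log_var_lo: float, log_var_hi: float):
    """L-BFGS-B bounds on the unconstrained scale (standardised data)."""
    vb = (log_var_lo, log_var_hi)
    zb = (-15.0, 15.0)
    if name == "ID":
        return [vb]
    if name == "DIAG":
        return [vb] * q
    if name == "CShom":
        return [vb, zb]
    if name == "CSHet":
        return [vb] * q + [zb]
    if name == "AR1":
        return [vb, (-7.0, 7.0)]
    if name == "AR1H":
        return [vb] * q + [(-7.0, 7.0)]
    if name == "UNST":
        out = []
        for i in range(q):
            for j in range(i + 1):
                out.append((log_var_lo / 2, log_var_hi / 2) if i == j
                           else (-30.0, 30.0))
        return out
    if name == "FA1":
        return [(-30.0, 30.0)] * q + [vb] * q
    raise DomainError(f"unknown structure {name!r}")
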