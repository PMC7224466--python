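"""REML engine checks against closed forms and independent implementations."""
import numpy as np
import pandas as pd
import pytest

from metqg.mixed_models import (ModelSpec, evaluate, fit, reml_loglik_dense,
                                restricted_loglik)
from metqg.simulate import simulate_met

from conftest import anova_sigma_g2, single_trait_config


def test_closed_form_identity_covariance():
    """For y=(1,2,3), intercept-only fixed part and V=I the restricted
    likelihood has the closed form -(log 3 + 2 + 2 log 2pi)/2."""
    expected = -0.5 * (np.log(3.0) + 2.0 + 2.0 * np.log(2 * np.pi))
    ll = reml_loglik_dense([1.0, 2.0, 3.0], np.ones((3, 1)), np.eye(3))
    assert ll == pytest.approx(expected, abs=1e-10)
    assert ll == pytest.approx(-3.3872, abs=1e-4)


def test_scaling_change_of_variables():
    """lR(c*y, c^2*V) = lR(y, V) - (n - p) log c."""
    rng = np.random.default_rng(1)
    y = rng.normal(size=8)
    X = np.column_stack([np.ones(8), rng.normal(size=8)])
    A = rng.normal(size=(8, 8))
    V = A @ A.T + 8 * np.eye(8)
    c = 3.7
    lhs = reml_loglik_dense(c * y, X, c * c * V)
    rhs = reml_loglik_dense(y, X, V) - (8 - 2) * np.log(c)
    assert lhs == pytest.approx(rhs, abs=1e-8)


def _manual_V_and_X(d, trait, Sigma, rvar_by_env):
    """Marginal covariance and fixed design built directly from the records,
    independently of the engine's internals."""
    df = d.records[d.records[trait].notna()].reset_index(drop=True)
    envs = list(d.environments)
    e_idx = df["environment"].map({e: i for i, e in enumerate(envs)}).to_numpy()
    g = df["genotype"].to_numpy()
    n = len(df)
    V = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if g[i] == g[j]:
                V[i, j] = Sigma[e_idx[i], e_idx[j]]
    V += np.diag(np.asarray(rvar_by_env)[e_idx])
    cols = [np.ones(n)]
    for e in envs[1:]:
        cols.append((df["environment"] == e).to_numpy(float))
    for e in envs:
        blocks = sorted(df.loc[df["environment"] == e, "block"].unique())
        for b in blocks[1:]:
            cols.append(((df["environment"] == e) & (df["block"] == b))
                        .to_numpy(float))
    return df[trait].to_numpy(float), V, np.column_stack(cols)


@pytest.mark.parametrize("structure,params", [
    ("CSHet", [2.0, 1.0, 0.5, 0.4]),
    ("AR1", [1.5, -0.3]),
    ("UNST", [2.0, 0.7, 1.5, 0.2, 0.3, 1.0]),
])
def test_fast_path_matches_dense_oracle(small_met, structure, params):
    """The structured evaluator agrees with a brute-force dense likelihood."""
    d, _ = small_met
    from metqg.vcov import VcovSpec, build
    Sigma = build(VcovSpec(structure, 3, params))
    rvar = [0.8, 1.2, 1.0]
    spec = ModelSpec(trait="y", layout="nested", g_structure=structure,
                     r_structure="DIAG")
    ll = restricted_loglik(spec, d, params, rvar)
    y, V, X = _manual_V_and_X(d, "y", Sigma, rvar)
    assert ll == pytest.approx(reml_loglik_dense(y, V=V, X=X), abs=1e-7)


def test_balanced_reml_equals_anova_moment_estimator(balanced_single):
    """On a balanced RCB trial the REML genetic variance coincides with the
    expected-mean-squares estimator (MS_G - MS_E)/r when interior."""
    d, _ = balanced_single
    f = fit(ModelSpec(trait="y", layout="single", environment="A"), d, seed=0)
    sg2_anova, ms_e = anova_sigma_g2(d)
    assert sg2_anova > 0
    assert f.estimates["sigma_g2"] == pytest.approx(sg2_anova, rel=1e-4)
    assert f.estimates["sigma2"] == pytest.approx(ms_e, rel=1e-4)


def test_reference_fitter_agrees(balanced_single):
    """statsmodels MixedLM (an independent REML implementation) reproduces
    the restricted log-likelihood and the variance components."""
    smf = pytest.importorskip("statsmodels.formula.api")
    d, _ = balanced_single
    f = fit(ModelSpec(trait="y", layout="single", environment="A"), d, seed=0)
    res = smf.mixedlm("y ~ C(block)", d.records,
                      groups=d.records["genotype"]).fit(reml=True)
    assert f.loglik == pytest.approx(res.llf, abs=1e-6)
    assert f.estimates["sigma_g2"] == pytest.approx(
        float(res.cov_re.iloc[0, 0]), rel=1e-3)
    assert f.estimates["sigma2"] == pytest.approx(res.scale, rel=1e-3)


def test_null_signal_boundary(balanced_single):
    """Data simulated without genetic signal drives sigma_g2 to the boundary
    and every genotype BLUP to ~0."""
    cfg = single_trait_config(7, sigma_g2=0.0, sigma_ge2=0.0, sigma2=(1.0,),
                              blocks={"A": 6}, missing_rate=0.0, n_parents=0)
    d, _ = simulate_met(cfg)
    f = fit(ModelSpec(trait="y", layout="single", environment="A"), d, seed=0)
    assert f.estimates["sigma_g2"] < 0.05
    assert np.abs(f.blups.to_numpy()).max() < 0.2


class TestShrinkage:
    def _centered_adjusted_means(self, d):
        # block-adjusted genotype means, centered (balanced: plain means)
        g = d.records.groupby("genotype")["y"].mean()
        return (g - g.mean()).reindex(d.genotypes)

    def test_no_shrinkage_limit(self, balanced_single):
        d, _ = balanced_single
        var = float(d.records["y"].var())
        f = evaluate(ModelSpec(trait="y", layout="single", environment="A"),
                     d, [1e4 * var], [var * 1e0 / 1e0])
        target = self._centered_adjusted_means(d)
        assert np.allclose(f.blups.to_numpy(), target.to_numpy(), atol=1e-2)

    def test_full_shrinkage_limit(self, balanced_single):
        d, _ = balanced_single
        var = float(d.records["y"].var())
        f = evaluate(ModelSpec(trait="y", layout="single", environment="A"),
                     d, [1e-4 * var], [var])
        # shrinkage factor is ~6e-4 at this variance ratio with 6 blocks
        target = self._centered_adjusted_means(d)
        assert np.abs(f.blups.to_numpy()).max() < \
            0.01 * np.abs(target.to_numpy()).max()


def test_permutation_equivariance(small_met):
    """Relabelling genotypes permutes the BLUPs and leaves lR unchanged."""
    d, _ = small_met
    spec = ModelSpec(trait="y", layout="nested", g_structure="CShom")
    params = ([3.0, 1.5], [1.0])
    base = evaluate(spec, d, *params)

    perm = d.copy()
    mapping = {g: f"Z{i:02d}" for i, g in enumerate(reversed(d.genotypes))}
    perm.records["genotype"] = perm.records["genotype"].map(mapping)
    perm.genotypes = [mapping[g] for g in d.genotypes][::-1]
    permuted = evaluate(spec, perm, *params)
    assert permuted.loglik == pytest.approx(base.loglik, abs=1e-8)
    b0 = base.genotype_blups()
    b1 = permuted.genotype_blups()
    for g in d.genotypes:
        assert b1[mapping[g]] == pytest.approx(b0[g], abs=1e-8)


@pytest.mark.parametrize("structure", ["ID", "DIAG", "CShom", "CSHet",
                                       "AR1", "AR1H", "UNST", "FA1"])
def test_parameter_recovery_shrinks_with_replication(structure):
    """Total genetic variance is recovered increasingly well as the block
    count grows (smoke grid, single replicate per size)."""
    errs = []
    for blocks in (3, 30):
        cfg = single_trait_config(17, sigma_g2=3.0, sigma_ge2=1.0,
                                  blocks={"A": blocks, "B": blocks, "C": blocks},
                                  missing_rate=0.0, n_full_sibs=40, n_parents=0)
        d, truth = simulate_met(cfg)
        f = fit(ModelSpec(trait="y", layout="nested", g_structure=structure),
                d, seed=0, n_starts=2)
        S = f.estimates["Sigma_env"]
        true_S = truth.sigma_env["y"]
        errs.append(np.abs(np.diag(S) - np.diag(true_S)).mean())
    assert np.isfinite(errs).all()
    # with 10x replication the diagonal error should not blow up
    assert errs[1] < max(errs[0] * 2.0, 1.5)
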