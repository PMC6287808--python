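"""Henderson MME solutions against brute-force GLS, and A-matrix recursion."""

import numpy as np
import pandas as pd
import pytest

from conifergs.blup import (
    MixedModelSpec,
    build_A,
    build_A_from_arrays,
    ebv_accuracy_summary,
    solve_collapsed_clone_model,
    solve_mme,
)


def _gls_oracle(spec: MixedModelSpec):
    """Direct GLS: invert the full phenotypic covariance V."""
    D = spec.D if spec.D is not None else np.eye(spec.Z_d.shape[1])
    V = (
        spec.Z_a @ spec.A @ spec.Z_a.T * spec.sigma2_a
        + spec.Z_d @ D @ spec.Z_d.T * spec.sigma2_d
        + np.eye(len(spec.y)) * spec.sigma2_e
    )
    Vi = np.linalg.inv(V)
    ones = np.ones(len(spec.y))
    mu = (ones @ Vi @ spec.y) / (ones @ Vi @ ones)
    a_hat = spec.sigma2_a * spec.A @ spec.Z_a.T @ Vi @ (spec.y - mu)
    return mu, a_hat


def _random_instance(rng, n_clones, n_ramets):
    """A small clonal pedigree: founders plus a few offspring."""
    n_founders = max(2, n_clones // 2)
    sire = np.full(n_clones, -1, dtype=np.int64)
    dam = np.full(n_clones, -1, dtype=np.int64)
    for i in range(n_founders, n_clones):
        s, d = rng.choice(i, size=2, replace=False)
        sire[i], dam[i] = s, d
    A = build_A_from_arrays(sire, dam)
    Z = np.repeat(np.eye(n_clones), n_ramets, axis=0)
    y = rng.normal(10.0, 4.0, size=n_clones * n_ramets)
    return MixedModelSpec(
        y=y, Z_a=Z, Z_d=Z, A=A,
        sigma2_a=rng.uniform(1.0, 5.0),
        sigma2_d=rng.uniform(0.5, 2.0),
        sigma2_e=rng.uniform(0.5, 3.0),
    )


# --- A-matrix -------------------------------------------------------------


def test_A_unrelated_founders_is_identity():
    ped = pd.DataFrame({"id": [1, 2], "sire": [0, 0], "dam": [0, 0]})
    assert np.allclose(build_A(ped), np.eye(2))


def test_A_parent_offspring_full_and_half_sibs():
    ped = pd.DataFrame(
        {
            "id": [1, 2, 6, 3, 4, 5],
            "sire": [0, 0, 0, 1, 1, 1],
            "dam": [0, 0, 0, 2, 2, 6],
        }
    )
    A = build_A(ped)
    i = {v: k for k, v in enumerate(ped["id"])}
    assert A[i[1], i[3]] == pytest.approx(0.5)  # parent-offspring
    assert A[i[3], i[4]] == pytest.approx(0.5)  # full sibs
    assert A[i[3], i[5]] == pytest.approx(0.25)  # half sibs (shared sire)
    assert np.allclose(np.diag(A)[:2], 1.0)


def test_A_inbred_offspring_diagonal():
    # offspring of full sibs: F = 0.25, diagonal 1.25
    ped = pd.DataFrame(
        {
            "id": [1, 2, 3, 4, 5],
            "sire": [0, 0, 1, 1, 3],
            "dam": [0, 0, 2, 2, 4],
        }
    )
    A = build_A(ped)
    assert A[4, 4] == pytest.approx(1.25)


def test_A_rejects_unordered_pedigree():
    ped = pd.DataFrame({"id": [1, 2], "sire": [2, 0], "dam": [0, 0]})
    with pytest.raises(ValueError):
        build_A(ped)


# --- MME vs GLS -----------------------------------------------------------


@pytest.mark.parametrize("seed", range(8))
def test_mme_equals_brute_force_gls(seed):
    """MME solution matches direct V-inversion GLS on <= 12-record instances."""
    rng = np.random.default_rng(seed)
    n_clones = int(rng.integers(3, 7))
    n_ramets = int(rng.integers(1, 3))
    spec = _random_instance(rng, n_clones, n_ramets)
    res = solve_mme(spec)
    mu, a_hat = _gls_oracle(spec)
    assert np.allclose(res.ebv, a_hat, atol=1e-8)


@pytest.mark.parametrize("seed", range(4))
def test_collapsed_clone_model_equals_full_mme(seed):
    """The clone-mean reduction reproduces ramet-level EBVs and accuracies."""
    rng = np.random.default_rng(100 + seed)
    n_clones, n_ramets = 5, 3
    spec = _random_instance(rng, n_clones, n_ramets)
    full = solve_mme(spec, with_accuracy=True)
    y_mean = spec.y.reshape(n_clones, n_ramets).mean(axis=1)
    ebv, acc = solve_collapsed_clone_model(
        y_mean, np.full(n_clones, n_ramets), spec.A,
        spec.sigma2_a, spec.sigma2_d, spec.sigma2_e, with_accuracy=True,
    )
    assert np.allclose(ebv, full.ebv, atol=1e-8)
    assert np.allclose(acc, full.accuracy_r, atol=1e-8)


def test_equal_phenotypes_give_zero_ebvs():
    rng = np.random.default_rng(1)
    spec = _random_instance(rng, 4, 2)
    spec.y = np.full_like(spec.y, 7.0)
    res = solve_mme(spec)
    assert np.allclose(res.ebv, 0.0, atol=1e-10)


def test_more_ramets_never_reduce_accuracy():
    """Adding a ramet record to a clone never decreases PEV-based accuracy."""
    rng = np.random.default_rng(2)
    A = build_A_from_arrays(np.array([-1, -1, 0]), np.array([-1, -1, 1]))
    accs = []
    for extra in range(1, 5):
        _, acc = solve_collapsed_clone_model(
            np.array([1.0, 2.0, 3.0]), np.array([2, 2, extra]), A,
            sigma2_a=2.0, sigma2_d=1.0, sigma2_e=3.0, with_accuracy=True,
        )
        accs.append(acc[2])
    assert np.all(np.diff(accs) >= -1e-12)


def test_shrinkage_var_ebv_below_var_tbv():
    """BLUP shrinks: E[Var(EBV)] <= E[Var(a)] at matched variance components.

    Breeding values are drawn from their assumed distribution a ~ N(0, A
    sigma2_a), so the model variances match the data-generating process;
    averaged over replicates the predictor has less variance than the truth.
    """
    rng = np.random.default_rng(9)
    sire = np.array([-1, -1, -1, -1, 0, 0, 2])
    dam = np.array([-1, -1, -1, -1, 1, 3, 3])
    A = build_A_from_arrays(sire, dam)
    L = np.linalg.cholesky(A)
    s2a, s2d, s2e = 4.0, 1.0, 3.0
    n = len(sire)
    var_ebv, var_a = [], []
    for _ in range(200):
        a = L @ rng.normal(0, np.sqrt(s2a), n)
        d = rng.normal(0, np.sqrt(s2d), n)
        y = a + d + rng.normal(0, np.sqrt(s2e), n)
        ebv, _ = solve_collapsed_clone_model(y, np.ones(n), A, s2a, s2d, s2e)
        var_ebv.append(ebv.var())
        var_a.append(a.var())
    assert np.mean(var_ebv) < np.mean(var_a)


def test_realized_accuracy_trivials():
    tbv = np.arange(10.0)
    assert ebv_accuracy_summary(tbv, tbv) == pytest.approx(1.0)
    rng = np.random.default_rng(3)
    noise = rng.normal(size=5000)
    tbv = rng.normal(size=5000)
    assert abs(ebv_accuracy_summary(noise, tbv)) < 0.05
    with pytest.raises(ValueError):
        ebv_accuracy_summary(np.zeros(10), tbv[:10])


def test_singular_mme_raises_named_error():
    # sigma2 ratios fine but duplicated confounded structure via zero Z
    y = np.array([1.0, 2.0])
    Z = np.zeros((2, 2))
    spec = MixedModelSpec(
        y=y, Z_a=Z, Z_d=np.zeros((2, 2)), A=np.eye(2),
        sigma2_a=1.0, sigma2_d=1.0, sigma2_e=0.0,
    )
    with pytest.raises(Exception):
        solve_mme(spec)
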