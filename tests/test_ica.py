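import numpy as np
import pytest

from ifcpipe import (
    ComponentSet,
    IcaConfig,
    TemplateSet,
    back_reconstruct,
    concat_reduce,
    icasso_stability,
    infomax_ica,
    match_templates,
)
from ifcpipe.ica import _zscore_rows


def planted_mixture(rng, n_sources=3, n_vox=5000, n_mix=None, noise=0.0):
    """Sparse, disjoint spatial sources mixed by a random full-rank matrix."""
    n_mix = n_mix or n_sources
    S = np.zeros((n_sources, n_vox))
    block = n_vox // n_sources
    for k in range(n_sources):
        sl = slice(k * block, k * block + block // 4)
        S[k, sl] = rng.gamma(2.0, 1.0, size=block // 4)
    A = rng.standard_normal((n_mix, n_sources))
    X = A @ S
    if noise:
        X = X + noise * rng.standard_normal(X.shape)
    return X, S, A


def best_abs_corr(est, truth):
    """For each true source, the best |r| over estimated components."""
    E = _zscore_rows(est)
    T = _zscore_rows(truth)
    C = np.abs(T @ E.T) / E.shape[1]
    return C.max(axis=1)


def principal_angles(A, B):
    qa, _ = np.linalg.qr(A.T)
    qb, _ = np.linalg.qr(B.T)
    s = np.linalg.svd(qa.T @ qb, compute_uv=False)
    return np.arccos(np.clip(s, -1, 1))


# -- two-step PCA reduction -------------------------------------------------

def test_lossless_when_data_lies_in_k_dim_subspace(rng):
    k, T, V = 4, 60, 800
    tc = rng.standard_normal((T, k))
    maps = rng.standard_normal((k, V))
    X = (tc @ maps).T  # voxel x time, temporal rank k
    cfg = IcaConfig(n_group_components=k, n_subject_pcs=k)
    reduced, ops = concat_reduce([X], cfg)
    # reconstruct from the reduction operators
    U = ops["subject_bases"][0]
    P = ops["group_projector"]
    Xc = X - X.mean(axis=1, keepdims=True)
    stack = U.T @ Xc.T
    recon = U @ (P @ (P.T @ stack))
    rel = np.linalg.norm(recon - Xc.T) / np.linalg.norm(Xc)
    assert rel < 1e-8


def test_single_subject_equals_direct_pca(rng):
    T, V, m = 50, 600, 5
    X = rng.standard_normal((V, T))
    cfg = IcaConfig(n_group_components=m, n_subject_pcs=T)
    reduced, _ = concat_reduce([X], cfg)
    # direct PCA oracle: top-m eigenvectors of the time x time covariance
    Xc = X - X.mean(axis=1, keepdims=True)
    evals, evecs = np.linalg.eigh(Xc.T @ Xc)
    top = evecs[:, np.argsort(evals)[::-1][:m]]
    direct = top.T @ Xc.T  # (m, V)
    assert principal_angles(reduced, direct).max() < 1e-6


def test_subject_permutation_leaves_group_subspace(rng):
    subs = [rng.standard_normal((500, 40)) for _ in range(4)]
    cfg = IcaConfig(n_group_components=4, n_subject_pcs=6)
    r1, _ = concat_reduce(subs, cfg)
    r2, _ = concat_reduce(subs[::-1], cfg)
    assert principal_angles(r1, r2).max() < 1e-6


def test_rank_overflow_raises(rng):
    X = rng.standard_normal((100, 10))
    with pytest.raises(ValueError):
        concat_reduce([X], IcaConfig(n_group_components=20, n_subject_pcs=10))


# -- infomax ----------------------------------------------------------------

def test_recovers_planted_sparse_sources(rng):
    X, S, _ = planted_mixture(rng, n_sources=3, n_vox=5000)
    res = infomax_ica(X, IcaConfig(n_group_components=3), seed=0)
    assert res["converged"]
    assert best_abs_corr(res["sources"], S).min() >= 0.95


def test_independent_input_recovered_up_to_signed_permutation(rng):
    # sparse sources fed in unmixed: output is a signed permutation
    _, S, _ = planted_mixture(rng, n_sources=4, n_vox=4000)
    res = infomax_ica(S.copy(), IcaConfig(n_group_components=4), seed=1)
    C = _zscore_rows(res["sources"]) @ _zscore_rows(S).T / S.shape[1]
    C = np.abs(C)
    # one dominant entry per row/column
    assert np.allclose(np.sort(C.max(axis=0)), 1.0, atol=1e-2)
    assert (C > 0.5).sum() == 4


def test_same_seed_identical_output(rng):
    X, _, _ = planted_mixture(rng, n_sources=3, n_vox=2000)
    r1 = infomax_ica(X, IcaConfig(), seed=42)
    r2 = infomax_ica(X, IcaConfig(), seed=42)
    assert np.array_equal(r1["sources"], r2["sources"])
    assert np.array_equal(r1["unmixing"], r2["unmixing"])


# -- ICASSO -----------------------------------------------------------------

def test_noiseless_planted_sources_are_stable(rng):
    X, S, _ = planted_mixture(rng, n_sources=3, n_vox=4000)
    cs = icasso_stability(X, IcaConfig(n_group_components=3, n_icasso_runs=6, seed=3))
    assert cs.n_components == 3
    assert cs.stability_index.min() >= 0.95
    assert best_abs_corr(cs.spatial_maps, S).min() >= 0.95
    # ordered by stability
    assert np.all(np.diff(cs.stability_index) <= 1e-12)


def test_noise_input_less_stable_than_planted(rng):
    Xs, _, _ = planted_mixture(rng, n_sources=4, n_vox=3000)
    Xn = rng.standard_normal((8, 3000))  # 8 mixtures, 4 requested comps
    cfg = IcaConfig(n_group_components=4, n_icasso_runs=5, seed=5, max_iter=80)
    planted = icasso_stability(Xs, cfg)
    noise = icasso_stability(Xn[:4], cfg)
    assert noise.stability_index.mean() < planted.stability_index.mean()


def test_single_run_stability_is_nan_with_warning(rng):
    X, _, _ = planted_mixture(rng, n_sources=3, n_vox=2000)
    with pytest.warns(RuntimeWarning, match="stability undefined"):
        cs = icasso_stability(X, IcaConfig(n_group_components=3, n_icasso_runs=1))
    assert np.all(np.isnan(cs.stability_index))


# -- dual regression --------------------------------------------------------

def test_noiseless_dual_regression_exact(rng):
    C, V, T = 4, 3000, 100
    maps = _zscore_rows(rng.standard_normal((C, V)))
    tc = rng.standard_normal((T, C))
    Y = (tc @ maps).T
    subj = back_reconstruct(ComponentSet(spatial_maps=maps), Y)
    for k in range(C):
        r = abs(np.corrcoef(subj.timecourses[:, k], tc[:, k])[0, 1])
        assert r > 0.999
        rm = abs(np.corrcoef(subj.spatial_maps[k], maps[k])[0, 1])
        assert rm > 0.999


def test_zero_data_gives_zero_outputs(rng):
    maps = _zscore_rows(rng.standard_normal((3, 500)))
    subj = back_reconstruct(ComponentSet(spatial_maps=maps), np.zeros((500, 40)))
    assert np.all(subj.timecourses == 0)
    assert np.all(subj.spatial_maps == 0)


def test_noisy_recovery_degrades_gracefully(rng):
    C, V, T = 4, 3000, 100
    maps = _zscore_rows(rng.standard_normal((C, V)))
    tc = rng.standard_normal((T, C))
    Y = (tc @ maps).T
    Y = Y + np.sqrt(np.var(Y)) * rng.standard_normal(Y.shape)  # SNR 1
    subj = back_reconstruct(ComponentSet(spatial_maps=maps), Y)
    rs = [
        abs(np.corrcoef(subj.timecourses[:, k], tc[:, k])[0, 1]) for k in range(C)
    ]
    assert min(rs) > 0.8


# -- template matching ------------------------------------------------------

def test_identity_assignment(rng):
    maps = _zscore_rows(rng.standard_normal((5, 1000)))
    comp = ComponentSet(spatial_maps=maps)
    templ = TemplateSet(maps=maps.copy())
    out = match_templates(comp, templ)
    assert [a["component"] for a in out] == list(range(5))
    assert all(a["goodness"] == pytest.approx(1.0, abs=1e-6) for a in out)


def test_permutation_recovered(rng):
    maps = _zscore_rows(rng.standard_normal((6, 800)))
    perm = rng.permutation(6)
    comp = ComponentSet(spatial_maps=maps[perm])
    templ = TemplateSet(maps=maps)
    out = match_templates(comp, templ)
    inverse = np.argsort(perm)
    # template t corresponds to original map t, found at position inverse[t]
    assert [a["component"] for a in out] == [int(np.where(perm == t)[0][0]) for t in range(6)]


def test_contested_component_goes_to_higher_goodness(rng):
    base = _zscore_rows(rng.standard_normal((2, 2000)))
    compA, compB = base
    # template 1 is nearly compA; template 2 is a weaker blend favouring compA too
    t1 = _zscore_rows((0.95 * compA + 0.05 * rng.standard_normal(2000))[None])[0]
    t2 = _zscore_rows((0.60 * compA + 0.40 * compB)[None])[0]
    comp = ComponentSet(spatial_maps=np.vstack([compA, compB]))
    out = match_templates(comp, TemplateSet(maps=np.vstack([t1, t2]), names=["t1", "t2"]),
                          method="correlation")
    assert out[0]["component"] == 0  # t1 wins the contested component
    assert out[1]["component"] == 1  # t2 falls back to its next best
    assert out[0]["goodness"] > out[1]["goodness"]


def test_more_templates_than_components_raises(rng):
    comp = ComponentSet(spatial_maps=rng.standard_normal((2, 100)))
    with pytest.raises(ValueError):
        match_templates(comp, TemplateSet(maps=rng.standard_normal((3, 100))))
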