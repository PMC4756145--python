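"""Group spatial ICA with ICASSO stability and dual-regression back-projection.

The group decomposition follows the standard temporal-concatenation
recipe: each subject's series is reduced along time by PCA, subjects are
stacked, a second PCA brings the stack to the requested number of group
dimensions, and an infomax ICA (natural-gradient, logistic nonlinearity)
unmixes spatially independent component maps. Running the ICA many times
from different starts and clustering the resulting components ("ICASSO")
yields a stability index per component. Subject-specific maps and time
courses are recovered by dual regression, and components of interest are
selected by spatial multiple regression against template maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform


@dataclass
class IcaConfig:
    """Controls for the group decomposition.

    ``n_group_components=75`` and ``n_icasso_runs=40`` reproduce the
    full-scale analysis; the desk-scale defaults (8 components, 10 runs)
    keep simulation studies fast while exercising every code path.
    ``n_subject_pcs=None`` keeps 1.5x the group dimension (rounded up,
    capped by rank).
    """

    n_group_components: int = 8
    n_subject_pcs: int | None = None
    n_icasso_runs: int = 10
    learning_rate: float = 0.01
    max_iter: int = 200
    tol: float = 1e-6
    bootstrap: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_group_components < 1:
            raise ValueError("n_group_components must be >= 1")
        if self.n_icasso_runs < 1:
            raise ValueError("n_icasso_runs must be >= 1")

    def subject_pcs(self, rank: int) -> int:
        k = self.n_subject_pcs
        if k is None:
            k = int(np.ceil(1.5 * self.n_group_components))
        return min(k, rank)


@dataclass
class ComponentSet:
    """Spatial maps plus (optionally) their time courses.

    Maps are z-scaled across voxels. At group level ``timecourses`` is
    None; back-reconstruction fills it per subject. Components are ordered
    by stability index, ties broken by explained variance.
    """

    spatial_maps: np.ndarray  # (n_components, n_voxels), z-scaled
    timecourses: np.ndarray | None = None  # (n_volumes, n_components)
    stability_index: np.ndarray | None = None
    provenance: str = "group"
    converged: bool = True

    @property
    def n_components(self) -> int:
        return self.spatial_maps.shape[0]


@dataclass
class TemplateSet:
    """Reference spatial maps used to pick components of interest."""

    maps: np.ndarray  # (n_templates, n_voxels)
    names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.maps = np.atleast_2d(np.asarray(self.maps, float))
        if not self.names:
            self.names = [f"template{i:02d}" for i in range(self.maps.shape[0])]


def _zscore_rows(m: np.ndarray) -> np.ndarray:
    m = m - m.mean(axis=1, keepdims=True)
    sd = m.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return m / sd


def concat_reduce(
    subject_data: list[np.ndarray], cfg: IcaConfig
) -> tuple[np.ndarray, dict]:
    """Two-step PCA reduction of temporally concatenated subjects.

    Each voxel x time matrix is centred over time and reduced to
    ``cfg.subject_pcs`` temporal dimensions (eigenvectors of the small
    time x time covariance); the per-subject reductions are stacked and a
    second PCA brings the stack to ``n_group_components`` rows.

    Returns the reduced group matrix (components x voxels) and the
    reduction operators (per-subject temporal bases and the group
    projector), retained for provenance and reconstruction checks.
    """
    if not subject_data:
        raise ValueError("no subjects")
    n_vox = subject_data[0].shape[0]
    reduced = []
    bases = []
    for s, X in enumerate(subject_data):
        X = np.asarray(X)
        if X.shape[0] != n_vox:
            raise ValueError(f"subject {s} is on a different voxel grid")
        T = X.shape[1]
        k = cfg.subject_pcs(rank=T)
        if k > T:
            raise ValueError(
                f"subject {s}: requested {k} PCs exceed {T} time points"
            )
        Xc = X - X.mean(axis=1, keepdims=True)
        # time x time covariance keeps the eigenproblem small; single
        # precision is ample for a variance-ranked subspace cut
        C = (Xc.T @ Xc).astype(np.float64)
        evals, evecs = np.linalg.eigh(C)
        order = np.argsort(evals)[::-1][:k]
        U = evecs[:, order]  # (T, k) temporal basis
        reduced.append(U.T.astype(Xc.dtype) @ Xc.T)  # (k, n_vox)
        bases.append(U)
    stack = np.vstack(reduced)  # (sum k, n_vox)
    m = cfg.n_group_components
    if m > stack.shape[0]:
        raise ValueError(
            f"requested {m} group components but stacked rank is {stack.shape[0]}"
        )
    # rows are linear images of temporally centred data; no further centring,
    # so one subject's two-step reduction equals its direct PCA exactly
    C2 = (stack @ stack.T).astype(np.float64)
    evals2, evecs2 = np.linalg.eigh(C2)
    order2 = np.argsort(evals2)[::-1][:m]
    P = evecs2[:, order2]  # (sum k, m)
    group = (P.T.astype(stack.dtype) @ stack).astype(np.float64)  # (m, n_vox)
    operators = {"subject_bases": bases, "group_projector": P}
    return group, operators


def _whiten(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    Xc = X - X.mean(axis=1, keepdims=True)
    cov = Xc @ Xc.T / Xc.shape[1]
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals, 1e-12, None)
    K = (evecs / np.sqrt(evals)) @ evecs.T  # symmetric whitening
    return K @ Xc, K


def infomax_ica(X: np.ndarray, cfg: IcaConfig, seed: int | None = None) -> dict:
    """Natural-gradient infomax with a logistic nonlinearity.

    ``X`` has one mixed signal per row and one sample (voxel) per column;
    it is whitened internally. Minibatch updates with a random sample
    permutation per pass; the learning rate is annealed when the weight
    update blows up or the update direction oscillates, the usual runica
    schedule. Deterministic given the seed.

    Returns a dict with ``sources`` (components x samples), ``mixing``,
    ``unmixing`` (including the whitening), ``converged`` and ``n_iter``.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    X = np.asarray(X, np.float64)
    n_comp, n_samp = X.shape
    Xw, K = _whiten(X)

    W = np.linalg.qr(rng.standard_normal((n_comp, n_comp)))[0]
    bias = np.zeros((n_comp, 1))
    lrate = cfg.learning_rate
    block = max(32, n_samp // 32)
    ident = np.eye(n_comp)
    max_weight = 1e8
    anneal = 0.9
    old_delta = None
    converged = False
    it = 0
    W_good, bias_good = W.copy(), bias.copy()
    while it < cfg.max_iter:
        it += 1
        perm = rng.permutation(n_samp)
        W_prev = W.copy()
        blowup = False
        for start in range(0, n_samp - block + 1, block):
            idx = perm[start : start + block]
            u = W @ Xw[:, idx] + bias
            y = 1.0 / (1.0 + np.exp(-u))
            W = W + (lrate / block) * ((block * ident + (1.0 - 2.0 * y) @ u.T) @ W)
            bias = bias + (lrate / block) * (1.0 - 2.0 * y).sum(axis=1, keepdims=True)
            if np.max(np.abs(W)) > max_weight or not np.all(np.isfinite(W)):
                blowup = True
                break
        if blowup:
            lrate *= 0.5
            W, bias = W_good.copy(), bias_good.copy()
            old_delta = None
            continue
        W_good, bias_good = W.copy(), bias.copy()
        delta = (W - W_prev).ravel()
        change = float(delta @ delta)
        if old_delta is not None:
            denom = np.sqrt((old_delta @ old_delta) * change)
            if denom > 0 and (old_delta @ delta) / denom < 0:
                lrate *= anneal  # direction oscillates: cool down
        old_delta = delta
        if change < cfg.tol * n_comp:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"infomax did not reach tol={cfg.tol} in {cfg.max_iter} passes",
            RuntimeWarning,
            stacklevel=2,
        )
    unmixing = W @ K
    sources = W @ Xw
    return {
        "sources": sources,
        "unmixing": unmixing,
        "mixing": np.linalg.pinv(unmixing),
        "converged": converged,
        "n_iter": it,
    }


def icasso_stability(X: np.ndarray, cfg: IcaConfig) -> ComponentSet:
    """Multi-run ICA with agglomerative component clustering.

    The decomposition is repeated ``cfg.n_icasso_runs`` times from
    different seeds (optionally on bootstrap-resampled samples), all
    resulting components are clustered by average linkage on
    ``1 - |spatial correlation|`` into ``n_group_components`` clusters,
    and each cluster is represented by its centrotype (the member most
    similar to the rest of its cluster). The stability index of a cluster
    is the mean within-cluster |r| minus the mean |r| to all other
    components.

    With a single run the stability index is undefined (NaN, with a
    warning).
    """
    n_comp = cfg.n_group_components
    ss = np.random.SeedSequence(cfg.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(cfg.n_icasso_runs)]
    boot_rng = np.random.default_rng(seeds[0] ^ 0x5EED)
    runs = []
    conv = True
    for r, sd in enumerate(seeds):
        Xr = X
        if cfg.bootstrap and r > 0:
            idx = boot_rng.integers(0, X.shape[1], size=X.shape[1])
            Xr = X[:, idx]
        res = infomax_ica(Xr, cfg, seed=sd)
        conv &= res["converged"]
        src = res["unmixing"] @ (X - X.mean(axis=1, keepdims=True))
        runs.append(_zscore_rows(src))
    allc = np.vstack(runs)  # (runs*n_comp, n_samples)

    if cfg.n_icasso_runs == 1:
        warnings.warn("stability undefined for a single ICASSO run", RuntimeWarning)
        return ComponentSet(
            spatial_maps=_zscore_rows(allc),
            stability_index=np.full(n_comp, np.nan),
            provenance="group",
            converged=conv,
        )

    V = allc.shape[1]
    sim = np.abs(allc @ allc.T) / V  # rows are z-scored: this is |corr|
    np.clip(sim, 0.0, 1.0, out=sim)
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=n_comp, criterion="maxclust")
    uniq = np.unique(labels)
    if uniq.size < n_comp:
        warnings.warn(
            f"only {uniq.size} component clusters found for {n_comp} requested",
            RuntimeWarning,
        )
    centrotypes = []
    stability = []
    for lab in uniq:
        members = np.flatnonzero(labels == lab)
        others = np.flatnonzero(labels != lab)
        sub = sim[np.ix_(members, members)]
        centro = members[np.argmax(sub.sum(axis=1))]
        if members.size > 1:
            within = (sub.sum() - members.size) / (members.size * (members.size - 1))
        else:
            within = 1.0
        between = sim[members][:, others].mean() if others.size else 0.0
        centrotypes.append(centro)
        stability.append(within - between)
    maps = allc[centrotypes]
    stability = np.asarray(stability)
    # explained variance of each centrotype w.r.t. the group matrix
    Xc = _zscore_rows(np.asarray(X, float))
    ev = ((maps @ Xc.T) ** 2).sum(axis=1)
    order = np.lexsort((-ev, -stability))
    return ComponentSet(
        spatial_maps=_zscore_rows(maps[order]),
        stability_index=stability[order],
        provenance="group",
        converged=conv,
    )


def back_reconstruct(group: ComponentSet, subject_data: np.ndarray) -> ComponentSet:
    """Dual regression of one subject's data on the group maps.

    First regression: subject time courses are the least-squares loadings
    of the subject's voxel x time data on the group spatial maps. Second
    regression: subject maps are the loadings of the data on those time
    courses, z-scaled.
    """
    M = np.asarray(group.spatial_maps, float)  # (C, V)
    Y = np.asarray(subject_data)  # (V, T)
    if Y.shape[0] != M.shape[1]:
        raise ValueError("subject not on the group voxel grid")
    G = M @ M.T
    if np.linalg.cond(G) > 1e10:
        raise ValueError("rank-deficient group map matrix")
    Yc = Y - Y.mean(axis=1, keepdims=True)
    # normal equations: C is tiny, the V-sized work is one gemm each way
    MY = M.astype(Yc.dtype) @ Yc  # (C, T)
    tc = np.linalg.solve(G, MY.astype(np.float64)).T  # (T, C)
    if not np.any(tc):
        maps = np.zeros_like(M)
    else:
        YT = (Yc @ tc.astype(Yc.dtype)).astype(np.float64).T  # (C, V)
        maps = np.linalg.solve(tc.T @ tc, YT)
        maps = _zscore_rows(maps) if np.any(maps) else maps
    return ComponentSet(
        spatial_maps=maps,
        timecourses=tc,
        stability_index=group.stability_index,
        provenance="subject",
        converged=group.converged,
    )


def match_templates(
    components: ComponentSet,
    templates: TemplateSet,
    method: str = "regression",
) -> list[dict]:
    """Assign one component to each template by spatial multiple regression.

    Each template map is regressed on all component maps simultaneously;
    the standardized coefficients score the components. Assignment is
    greedy in descending |score| without replacement, so a component
    contested by two templates goes to the one scoring it higher and the
    loser falls back to its next-best component. ``method="correlation"``
    scores by plain spatial correlation instead.

    Returns a list of ``{"template", "component", "goodness"}`` dicts in
    template order.
    """
    D = _zscore_rows(np.asarray(components.spatial_maps, float))
    Tm = _zscore_rows(np.asarray(templates.maps, float))
    n_templ, n_comp = Tm.shape[0], D.shape[0]
    if n_templ > n_comp:
        raise ValueError(f"{n_templ} templates but only {n_comp} components")
    if method == "regression":
        beta, *_ = np.linalg.lstsq(D.T, Tm.T, rcond=None)  # (C, n_templ)
        score = beta.T  # standardized: maps are all z-scored
    elif method == "correlation":
        score = Tm @ D.T / D.shape[1]
    else:
        raise ValueError(f"unknown method {method!r}")
    order = np.argsort(-np.abs(score), axis=None, kind="stable")
    assigned_t: dict[int, tuple[int, float]] = {}
    used_c: set[int] = set()
    for flat in order:
        t, c = divmod(int(flat), n_comp)
        if t in assigned_t or c in used_c:
            continue
        assigned_t[t] = (c, float(score[t, c]))
        used_c.add(c)
        if len(assigned_t) == n_templ:
            break
    return [
        {
            "template": templates.names[t],
            "component": assigned_t[t][0],
            "goodness": assigned_t[t][1],
        }
        for t in range(n_templ)
    ]
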