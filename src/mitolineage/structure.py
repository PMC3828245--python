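"""Population structure: distance matrices, AMOVA / Phi statistics, MDS.

AMOVA follows the distance-based decomposition of molecular variance: sums
of squared deviations are computed from the matrix of pairwise difference
counts (used directly as squared Euclidean distances, the convention for
haplotype data), variance components come from the method-of-moments
equations for the 2-level (populations in total) or 3-level (populations in
groups in total) designs, and Phi statistics are ratios of components.
Significance is by permutation: samples among populations for Phi_ST,
samples among populations within groups for Phi_SC, whole populations among
groups for Phi_CT, with the (b+1)/(m+1) p-value estimator.  Negative
components are reported as computed; percentages are renormalized for
display only.

The MDS embedding is Kruskal's nonmetric scaling (stress-1) driven by
iterative majorization with a monotone regression step, started from the
classical (Torgerson) solution plus seeded random restarts.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .refio import VariantProfile


class StructureError(ValueError):
    pass


# ---------------------------------------------------------------------------
# distances


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.ids), len(self.ids)):
            raise StructureError("distance matrix shape mismatch")
        if not np.allclose(d, d.T) or np.any(np.diag(d) != 0) or np.any(d < 0):
            raise StructureError("distances must be symmetric, nonnegative, "
                                 "zero-diagonal")
        self.d = d


def distance_matrix(profiles: Sequence[VariantProfile],
                    include_indels: bool = False,
                    complete_deletion: bool = True) -> DistanceMatrix:
    """Pairwise difference counts between samples at mutually compared sites."""
    if not profiles:
        raise StructureError("no profiles")
    n = len(profiles)
    if complete_deletion:
        excluded: set[int] = set()
        for p in profiles:
            excluded |= set(p.uncompared)
    slots = []
    for p in profiles:
        dd = {}
        for v in p.variants:
            if v.is_indel and not include_indels:
                continue
            if complete_deletion and v.position in excluded:
                continue
            dd[(v.position, v.insert_index)] = v.label
        slots.append(dd)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if complete_deletion:
                keys = set(slots[i]) | set(slots[j])
                diff = sum(1 for s in keys
                           if slots[i].get(s) != slots[j].get(s))
            else:
                shared_excl = set(profiles[i].uncompared) | set(profiles[j].uncompared)
                keys = {s for s in set(slots[i]) | set(slots[j])
                        if s[0] not in shared_excl}
                diff = sum(1 for s in keys
                           if slots[i].get(s) != slots[j].get(s))
            d[i, j] = d[j, i] = diff
    return DistanceMatrix(ids=[p.sample_id for p in profiles], d=d)


# ---------------------------------------------------------------------------
# AMOVA


@dataclass
class AmovaResult:
    levels: list[str]
    variance_components: dict[str, float]
    percent_variation: dict[str, float]
    phi_statistics: dict[str, float]
    p_values: dict[str, float]
    n_permutations: int
    seed: int
    df: dict[str, int] = field(default_factory=dict)
    ssd: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for lvl in self.levels:
            rows.append({
                "source": lvl, "df": self.df.get(lvl),
                "SSD": self.ssd.get(lvl),
                "variance_component": self.variance_components.get(lvl),
                "percent_variation": self.percent_variation.get(lvl),
            })
        return pd.DataFrame(rows)


def _ssd_within(d2: np.ndarray, idx: np.ndarray) -> float:
    sub = d2[np.ix_(idx, idx)]
    return float(sub.sum() / (2.0 * len(idx)))


def _amova_components(d2: np.ndarray, pops: np.ndarray,
                      groups: np.ndarray | None):
    """Variance components from squared distances (method of moments)."""
    N = len(pops)
    pop_ids = sorted(set(pops))
    P = len(pop_ids)
    all_idx = np.arange(N)
    ssd_total = _ssd_within(d2, all_idx)
    pop_idx = {p: np.where(pops == p)[0] for p in pop_ids}
    ssd_wp = sum(_ssd_within(d2, pop_idx[p]) for p in pop_ids)
    n_p = {p: len(pop_idx[p]) for p in pop_ids}
    if groups is None:
        df_a, df_w = P - 1, N - P
        ssd_ap = ssd_total - ssd_wp
        sigma_c = ssd_wp / df_w
        n_prime = (N - sum(v ** 2 for v in n_p.values()) / N) / (P - 1)
        sigma_b = (ssd_ap / df_a - sigma_c) / n_prime
        comps = {"among_populations": sigma_b, "within_populations": sigma_c}
        total = sigma_b + sigma_c
        phi = {"Phi_ST": sigma_b / total if total != 0 else 0.0}
        dfs = {"among_populations": df_a, "within_populations": df_w}
        ssds = {"among_populations": ssd_ap, "within_populations": ssd_wp}
        return comps, phi, dfs, ssds
    group_ids = sorted(set(groups))
    G = len(group_ids)
    if G < 2:
        raise StructureError("grouped AMOVA needs >= 2 groups")
    grp_idx = {g: np.where(groups == g)[0] for g in group_ids}
    pop_group = {}
    for p in pop_ids:
        gset = set(groups[pop_idx[p]])
        if len(gset) != 1:
            raise StructureError(f"population {p!r} spans multiple groups")
        pop_group[p] = gset.pop()
    ssd_wg = sum(_ssd_within(d2, grp_idx[g]) for g in group_ids)
    ssd_ag = ssd_total - ssd_wg
    ssd_ap_wg = ssd_wg - ssd_wp
    df_ag, df_ap, df_wp = G - 1, P - G, N - P
    N_g = {g: len(grp_idx[g]) for g in group_ids}
    sum_np2_over_Ng = sum(
        sum(n_p[p] ** 2 for p in pop_ids if pop_group[p] == g) / N_g[g]
        for g in group_ids)
    sum_np2_over_N = sum(v ** 2 for v in n_p.values()) / N
    sum_Ng2_over_N = sum(v ** 2 for v in N_g.values()) / N
    n1 = (N - sum_np2_over_Ng) / df_ap
    n2 = (sum_np2_over_Ng - sum_np2_over_N) / df_ag
    n3 = (N - sum_Ng2_over_N) / df_ag
    sigma_c = ssd_wp / df_wp
    sigma_b = (ssd_ap_wg / df_ap - sigma_c) / n1
    sigma_a = (ssd_ag / df_ag - sigma_c - n2 * sigma_b) / n3
    comps = {"among_groups": sigma_a, "among_populations": sigma_b,
             "within_populations": sigma_c}
    total = sigma_a + sigma_b + sigma_c
    phi = {
        "Phi_CT": sigma_a / total if total != 0 else 0.0,
        "Phi_SC": sigma_b / (sigma_b + sigma_c) if (sigma_b + sigma_c) != 0 else 0.0,
        "Phi_ST": (sigma_a + sigma_b) / total if total != 0 else 0.0,
    }
    dfs = {"among_groups": df_ag, "among_populations": df_ap,
           "within_populations": df_wp}
    ssds = {"among_groups": ssd_ag, "among_populations": ssd_ap_wg,
            "within_populations": ssd_wp}
    return comps, phi, dfs, ssds


def amova(d: DistanceMatrix, populations: Sequence[str],
          groups: Sequence[str] | None = None,
          n_perm: int = 10000, seed: int = 0) -> AmovaResult:
    """Hierarchical AMOVA with permutation p-values.

    Permutations shuffle sample indices, not labels, so results are
    invariant to the row order of the distance matrix under a fixed seed.
    """
    if n_perm < 0:
        raise StructureError("negative permutation count")
    pops = np.asarray(list(populations))
    if len(pops) != len(d.ids):
        raise StructureError("population labels do not match matrix")
    counts = pd.Series(pops).value_counts()
    if len(counts) < 2:
        raise StructureError("need >= 2 populations")
    if (counts < 2).any():
        raise StructureError(
            f"singleton population(s): {list(counts[counts < 2].index)}")
    grp = None if groups is None else np.asarray(list(groups))
    # order-canonical view: sort samples by (population, id) before analysis
    order = np.lexsort((np.asarray(d.ids), pops))
    d2 = d.d[np.ix_(order, order)]
    pops_o = pops[order]
    grp_o = None if grp is None else grp[order]
    comps, phi, dfs, ssds = _amova_components(d2, pops_o, grp_o)

    rng = np.random.default_rng(seed)
    exceed = {k: 0 for k in phi}
    for _ in range(n_perm):
        # Phi_ST (and 2-level): samples among populations
        perm = rng.permutation(len(pops_o))
        try:
            _, phi_p, _, _ = _amova_components(
                d2[np.ix_(perm, perm)], pops_o, grp_o)
        except StructureError:
            continue
        if phi_p.get("Phi_ST", -np.inf) >= phi["Phi_ST"]:
            exceed["Phi_ST"] += 1
        if grp_o is not None:
            # Phi_SC: permute samples among populations within each group
            perm_wg = np.arange(len(pops_o))
            for g in sorted(set(grp_o)):
                gi = np.where(grp_o == g)[0]
                perm_wg[gi] = gi[rng.permutation(len(gi))]
            try:
                _, phi_s, _, _ = _amova_components(
                    d2[np.ix_(perm_wg, perm_wg)], pops_o, grp_o)
            except StructureError:
                continue
            if phi_s["Phi_SC"] >= phi["Phi_SC"]:
                exceed["Phi_SC"] += 1
        if grp_o is not None:
            # Phi_CT: permute whole populations among groups
            pop_ids = sorted(set(pops_o))
            pop_groups = np.asarray(
                [grp_o[np.where(pops_o == p)[0][0]] for p in pop_ids])
            shuffled = pop_groups[rng.permutation(len(pop_ids))]
            gmap = dict(zip(pop_ids, shuffled))
            grp_perm = np.asarray([gmap[p] for p in pops_o])
            try:
                _, phi_c, _, _ = _amova_components(d2, pops_o, grp_perm)
            except StructureError:
                continue
            if phi_c["Phi_CT"] >= phi["Phi_CT"]:
                exceed["Phi_CT"] += 1
    p_values = {k: (exceed[k] + 1) / (n_perm + 1) if n_perm > 0 else float("nan")
                for k in phi}
    total = sum(comps.values())
    if total != 0:
        pct = {k: 100.0 * v / total for k, v in comps.items()}
        norm = sum(pct.values())
        pct = {k: 100.0 * v / norm for k, v in pct.items()}
    else:
        pct = {k: float("nan") for k in comps}
    return AmovaResult(levels=list(comps), variance_components=comps,
                       percent_variation=pct, phi_statistics=phi,
                       p_values=p_values, n_permutations=n_perm, seed=seed,
                       df=dfs, ssd=ssds)


def pairwise_phist(d: DistanceMatrix, populations: Sequence[str],
                   n_perm: int = 10000, seed: int = 0
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Phi_ST matrix and permutation p-values (2-population AMOVAs)."""
    pops = np.asarray(list(populations))
    pop_ids = sorted(set(pops))
    K = len(pop_ids)
    phist = pd.DataFrame(np.zeros((K, K)), index=pop_ids, columns=pop_ids)
    pvals = pd.DataFrame(np.ones((K, K)), index=pop_ids, columns=pop_ids)
    for a, b in itertools.combinations(pop_ids, 2):
        idx = np.where((pops == a) | (pops == b))[0]
        sub = DistanceMatrix(ids=[d.ids[i] for i in idx],
                             d=d.d[np.ix_(idx, idx)])
        res = amova(sub, pops[idx], n_perm=n_perm, seed=seed)
        phist.loc[a, b] = phist.loc[b, a] = res.phi_statistics["Phi_ST"]
        pvals.loc[a, b] = pvals.loc[b, a] = res.p_values["Phi_ST"]
    return phist, pvals


# ---------------------------------------------------------------------------
# multidimensional scaling


@dataclass
class MdsEmbedding:
    labels: list[str]
    coords: np.ndarray
    stress: float
    seed: int
    restarts: int


def _pava(y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted pool-adjacent-violators: isotonic (nondecreasing) fit."""
    n = len(y)
    level_y = list(y.astype(float))
    level_w = list(w.astype(float))
    sizes = [1] * n
    i = 0
    out_y, out_w, out_s = [], [], []
    for i in range(n):
        cy, cw, cs = level_y[i], level_w[i], 1
        while out_y and out_y[-1] > cy:
            py, pw, ps = out_y.pop(), out_w.pop(), out_s.pop()
            cy = (py * pw + cy * cw) / (pw + cw)
            cw += pw
            cs += ps
        out_y.append(cy)
        out_w.append(cw)
        out_s.append(cs)
    fit = np.empty(n)
    pos = 0
    for cy, cs in zip(out_y, out_s):
        fit[pos:pos + cs] = cy
        pos += cs
    return fit


def _classical_scaling(D: np.ndarray, dim: int) -> np.ndarray:
    n = len(D)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:dim]
    lam = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(lam)


def _stress1(dhat: np.ndarray, dist: np.ndarray) -> float:
    denom = np.sum(dist ** 2)
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((dhat - dist) ** 2) / denom))


def _smacof_nonmetric(D: np.ndarray, X0: np.ndarray, metric: bool,
                      max_iter: int = 300, tol: float = 1e-10):
    n = len(D)
    iu = np.triu_indices(n, k=1)
    delta = D[iu]
    order = np.argsort(delta, kind="stable")
    X = X0.copy()
    last = np.inf
    w = np.ones_like(delta)
    for _ in range(max_iter):
        diff = X[:, None, :] - X[None, :, :]
        dist_full = np.sqrt((diff ** 2).sum(axis=2))
        dist = dist_full[iu]
        if metric:
            # optimal scaling is a single multiplicative factor
            denom = np.sum(delta ** 2)
            b = np.sum(delta * dist) / denom if denom > 0 else 1.0
            dhat = delta * b
        else:
            dhat = np.empty_like(dist)
            dhat[order] = _pava(dist[order], w[order])
        stress = _stress1(dhat, dist)
        if abs(last - stress) < tol:
            last = stress
            break
        last = stress
        # Guttman transform with target disparities
        Dhat = np.zeros((n, n))
        Dhat[iu] = dhat
        Dhat += Dhat.T
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist_full > 0, Dhat / dist_full, 0.0)
        B = -ratio
        np.fill_diagonal(B, ratio.sum(axis=1))
        X = B @ X / n
    return X - X.mean(axis=0), last


def mds(fst: np.ndarray | pd.DataFrame, dim: int = 2, seed: int = 0,
        restarts: int = 8, metric: bool = False) -> MdsEmbedding:
    """Kruskal nonmetric (default) MDS of a Phi_ST-type matrix.

    Slightly negative input entries (possible for Phi_ST) are clamped to 0
    with a warning.  Deterministic under a fixed seed; the best of the
    classical-scaling start and ``restarts`` random starts is returned.
    """
    labels = list(fst.index) if isinstance(fst, pd.DataFrame) else \
        [str(i) for i in range(len(fst))]
    D = np.asarray(fst, dtype=float).copy()
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-12):
        raise StructureError("MDS needs a square symmetric matrix")
    if (D < 0).any():
        warnings.warn("negative dissimilarities clamped to 0")
        D = np.clip(D, 0.0, None)
    np.fill_diagonal(D, 0.0)
    n = len(D)
    if n <= dim + 1 or D[np.triu_indices(n, 1)].max(initial=0.0) == 0:
        X = _classical_scaling(D, dim)
        X, stress = _smacof_nonmetric(D, X, metric)
        return MdsEmbedding(labels=labels, coords=X, stress=stress,
                            seed=seed, restarts=0)
    rng = np.random.default_rng(seed)
    best = None
    starts = [_classical_scaling(D, dim)]
    scale = D.max() or 1.0
    for _ in range(restarts):
        starts.append(rng.normal(scale=scale, size=(n, dim)))
    for X0 in starts:
        X, stress = _smacof_nonmetric(D, X0, metric)
        if best is None or stress < best[1] - 1e-15:
            best = (X, stress)
    return MdsEmbedding(labels=labels, coords=best[0], stress=best[1],
                        seed=seed, restarts=restarts)
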