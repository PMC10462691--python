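"""Spatially regularized admixture estimation.

Individual ancestry proportions Q (n x K, rows on the simplex) and cluster
allele frequencies G (K x L, in [0,1]) are fitted by minimising

    sum_observed (X - 2 Q G)^2  +  alpha * trace(Q' L Q)

where X is the alternate-allele dosage matrix and L the graph Laplacian of a
k-nearest-neighbour graph on sampling coordinates with heat-kernel edge
weights. The spatial term pulls geographically close individuals towards
similar ancestry; alpha -> 0 recovers plain (non-spatial) constrained NMF.

Optimisation alternates projected-gradient steps on Q and G with steps set
from Lipschitz bounds, so the objective is non-increasing by construction.
The number of source populations K is chosen by a masked cross-entropy
criterion: hide a fraction of observed genotypes, fit on the rest, and score
the hidden entries under Binomial(2, [QG]) genotype probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, LocationTable, KM_PER_DEG

#: genotype-probability floor inside the cross-entropy criterion
PROB_FLOOR = 1e-9


def project_rows_to_simplex(Q: np.ndarray) -> np.ndarray:
    """Euclidean projection of each row onto the probability simplex."""
    n, k = Q.shape
    u = np.sort(Q, axis=1)[:, ::-1]
    css = np.cumsum(u, axis=1) - 1.0
    ind = np.arange(1, k + 1)
    cond = u - css / ind > 0
    rho = k - np.argmax(cond[:, ::-1], axis=1) - 1  # last True index
    theta = css[np.arange(n), rho] / (rho + 1.0)
    return np.maximum(Q - theta[:, None], 0.0)


def spatial_laplacian(coords_lonlat: np.ndarray, k: int = 10) -> np.ndarray:
    """Graph Laplacian of a kNN heat-kernel graph on sample coordinates.

    Distances are km on a local equirectangular projection; the kernel
    bandwidth is the median nonzero neighbour distance. Co-located samples
    (same site) get full weight 1.
    """
    lon, lat = coords_lonlat[:, 0], coords_lonlat[:, 1]
    lat0 = float(np.mean(lat))
    x = lon * KM_PER_DEG * np.cos(np.radians(lat0))
    y = lat * KM_PER_DEG
    P = np.column_stack([x, y])
    n = len(P)
    D = np.sqrt(((P[:, None, :] - P[None, :, :]) ** 2).sum(-1))
    k = min(k, n - 1)
    W = np.zeros((n, n))
    order = np.argsort(D, axis=1, kind="stable")
    neigh = order[:, 1: k + 1]
    nd = np.take_along_axis(D, neigh, axis=1)
    h = np.median(nd[nd > 0]) if (nd > 0).any() else 1.0
    w = np.exp(-(nd**2) / (2.0 * h * h))
    rows = np.repeat(np.arange(n), k)
    W[rows, neigh.ravel()] = w.ravel()
    W = np.maximum(W, W.T)  # symmetric kNN graph
    return np.diag(W.sum(axis=1)) - W


@dataclass
class AdmixtureSolution:
    K: int
    Q: np.ndarray
    G: np.ndarray
    alpha: float
    objective: float
    replicate_objectives: list = field(default_factory=list)
    n_iter: int = 0
    cross_entropy: float | None = None

    def q_frame(self, gm: GenotypeMatrix) -> pd.DataFrame:
        cols = [f"cluster_{i + 1}" for i in range(self.K)]
        return pd.DataFrame(self.Q, index=gm.sample_ids, columns=cols)


def _objective(X, M, Q, G, alpha, L) -> float:
    R = np.where(M, X - 2.0 * Q @ G, 0.0)
    obj = float((R**2).sum())
    if alpha > 0:
        obj += alpha * float(np.trace(Q.T @ L @ Q))
    return obj


def _fit_single(X, M, coords, K, alpha, L_sp, lam_L, max_iter, tol, rng):
    n, Lc = X.shape
    Q = rng.dirichlet(np.ones(K), size=n)
    p_obs = np.where(M, X, np.nan)
    base = np.nanmean(p_obs, axis=0) / 2.0
    base = np.nan_to_num(base, nan=0.5)
    G = np.clip(base[None, :] + 0.05 * rng.standard_normal((K, Lc)), 0.0, 1.0)
    Xz = np.where(M, X, 0.0)
    prev = _objective(X, M, Q, G, alpha, L_sp)
    it = 0
    for it in range(1, max_iter + 1):
        # --- Q step (projected gradient, monotone step from Lipschitz bound)
        GG = G @ G.T
        lip_q = 8.0 * max(np.linalg.eigvalsh(GG)[-1], 1e-12) + 2.0 * alpha * lam_L
        R = Xz - np.where(M, 2.0 * Q @ G, 0.0)
        grad_q = -4.0 * R @ G.T
        if alpha > 0:
            grad_q += 2.0 * alpha * L_sp @ Q
        Q = project_rows_to_simplex(Q - grad_q / lip_q)
        # --- G step
        QQ = Q.T @ Q
        lip_g = 8.0 * max(np.linalg.eigvalsh(QQ)[-1], 1e-12)
        R = Xz - np.where(M, 2.0 * Q @ G, 0.0)
        grad_g = -4.0 * Q.T @ R
        G = np.clip(G - grad_g / lip_g, 0.0, 1.0)
        obj = _objective(X, M, Q, G, alpha, L_sp)
        if prev - obj <= tol * max(prev, 1.0):
            prev = obj
            break
        prev = obj
    return Q, G, prev, it


def fit_admixture(
    gm: GenotypeMatrix,
    loc: LocationTable,
    K: int,
    alpha: float = 0.01,
    replicates: int = 10,
    max_iter: int = 10000,
    tol: float = 1e-6,
    seed: int = 0,
    mask: np.ndarray | None = None,
) -> AdmixtureSolution:
    """Fit ancestry proportions for K source populations.

    ``mask`` optionally marks genotype entries to *exclude* from fitting
    (used by cross-validation); missing calls are always excluded. The best
    of ``replicates`` random restarts (lowest final objective) is returned.
    """
    if K < 1 or K > gm.n_samples:
        raise ValueError("K must lie in [1, n_samples]")
    X = np.nan_to_num(gm.calls, nan=0.0)
    M = ~np.isnan(gm.calls)
    if mask is not None:
        M = M & ~mask
    coords = loc.coords_of_samples(gm)
    if K == 1:
        # forced by the simplex: Q = 1, G = observed mean frequency
        Q = np.ones((gm.n_samples, 1))
        denom = 2.0 * np.maximum(M.sum(axis=0), 1)
        G = ((X * M).sum(axis=0) / denom)[None, :]
        L_sp = np.zeros((gm.n_samples, gm.n_samples))
        obj = _objective(X, M, Q, G, alpha, L_sp)
        return AdmixtureSolution(1, Q, G, alpha, obj, [obj], 0)
    L_sp = spatial_laplacian(coords) if alpha > 0 else np.zeros((gm.n_samples,) * 2)
    lam_L = float(np.linalg.eigvalsh(L_sp)[-1]) if alpha > 0 else 0.0
    rng = np.random.default_rng(seed)
    best = None
    objs = []
    for _ in range(replicates):
        Q, G, obj, it = _fit_single(
            X, M, coords, K, alpha, L_sp, lam_L, max_iter, tol, rng
        )
        objs.append(obj)
        if best is None or obj < best.objective:
            best = AdmixtureSolution(K, Q, G, alpha, obj, [], it)
    best.replicate_objectives = objs
    return best


def genotype_log_prob(dosage: np.ndarray, p: np.ndarray) -> np.ndarray:
    """log P(dosage | Binomial(2, p)) with a probability floor."""
    p = np.clip(p, PROB_FLOOR, 1.0 - PROB_FLOOR)
    prob = np.where(
        dosage == 0,
        (1 - p) ** 2,
        np.where(dosage == 1, 2 * p * (1 - p), p**2),
    )
    return np.log(np.maximum(prob, PROB_FLOOR))


def cross_entropy_select(
    gm: GenotypeMatrix,
    loc: LocationTable,
    K_range=range(1, 9),
    mask_fraction: float = 0.10,
    replicates: int = 10,
    alpha: float = 0.01,
    max_iter: int = 10000,
    tol: float = 1e-6,
    seed: int = 0,
) -> tuple[pd.DataFrame, int]:
    """Choose K by masked-genotype cross-entropy.

    Per replicate and per K: mask a uniform random ``mask_fraction`` of the
    observed entries, fit on the rest, and score the masked entries by mean
    negative log predicted genotype probability. Returns the per-K table
    (mean and sd over replicates) and the arg-min K. A flat profile (min at
    K = 1) is a legitimate outcome and is reported as such.
    """
    if not 0.0 < mask_fraction < 0.5:
        raise ValueError("mask_fraction must lie in (0, 0.5)")
    rng = np.random.default_rng(seed)
    obs = ~np.isnan(gm.calls)
    obs_idx = np.flatnonzero(obs.ravel())
    n_mask = int(round(mask_fraction * obs_idx.size))
    if n_mask == 0:
        raise ValueError("mask_fraction leaves zero masked entries")
    rows = []
    for rep in range(replicates):
        chosen = rng.choice(obs_idx, size=n_mask, replace=False)
        mask = np.zeros(gm.calls.size, dtype=bool)
        mask[chosen] = True
        mask = mask.reshape(gm.calls.shape)
        fit_seed = int(rng.integers(0, 2**31 - 1))
        for K in K_range:
            sol = fit_admixture(
                gm, loc, K, alpha=alpha, replicates=1, max_iter=max_iter,
                tol=tol, seed=fit_seed, mask=mask,
            )
            P = sol.Q @ sol.G
            ll = genotype_log_prob(gm.calls[mask], P[mask])
            rows.append({"K": K, "replicate": rep, "cross_entropy": float(-ll.mean())})
    table = pd.DataFrame(rows)
    summary = (
        table.groupby("K")["cross_entropy"].agg(["mean", "std", "min"]).reset_index()
    )
    chosen_k = int(summary.loc[summary["mean"].idxmin(), "K"])
    return summary, chosen_k


def ancestry_by_location(
    solution: AdmixtureSolution, gm: GenotypeMatrix, loc: LocationTable
) -> pd.DataFrame:
    """Mean ancestry proportion per sampling location (rows sum to 1)."""
    labels = loc.location_of(gm)
    q = pd.DataFrame(solution.Q, columns=[f"cluster_{i+1}" for i in range(solution.K)])
    q["location_id"] = labels
    return q.groupby("location_id", sort=False).mean()


def align_clusters(Q_ref: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Greedy correlation matching of cluster columns to a reference.

    Returns a column order for ``Q`` so its clusters line up with
    ``Q_ref``'s (for plotting across K); extra columns keep relative order.
    """
    k_ref, k = Q_ref.shape[1], Q.shape[1]
    C = np.zeros((k_ref, k))
    for a in range(k_ref):
        for b in range(k):
            x, y = Q_ref[:, a], Q[:, b]
            sx, sy = x.std(), y.std()
            C[a, b] = ((x - x.mean()) @ (y - y.mean())) / (len(x) * sx * sy) \
                if sx > 0 and sy > 0 else 0.0
    order: list[int] = []
    used: set = set()
    for _ in range(min(k_ref, k)):
        masked = np.where(
            np.isin(np.arange(k), list(used))[None, :], -np.inf, C
        )
        a, b = np.unravel_index(np.argmax(masked), C.shape)
        order.append(int(b))
        used.add(int(b))
        C[a, :] = -np.inf
    order += [b for b in range(k) if b not in used]
    return np.array(order)
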