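"""Seascape connectivity models: over-water distance, circuit-theory
resistance on bathymetry, surface optimization, Mantel tests, and causal
model comparison.

Three candidate models of genetic connectivity are compared:

* IBD — shortest over-water distance between sampling locations;
* contemporary IBR — effective (circuit-theory) resistance on a resistance
  surface derived from present-day depth;
* paleo IBR — the same on a bathymetry where every cell that was shallow at
  glacial-maximum sea levels (0 to -210 m) is clamped to 1 m depth,
  re-opening historical dispersal corridors.

Depth is mapped to resistance by a (reverse) monomolecular transformation,
whose shape and magnitude parameters can be optimized against genetic
distances by differential evolution with a Mantel r^2 objective.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import differential_evolution
from scipy.sparse.csgraph import dijkstra
from scipy.sparse.linalg import splu

from .containers import BathymetryGrid, PairwiseMatrix

log = logging.getLogger(__name__)

SQRT2 = np.sqrt(2.0)
#: 8-neighbour moves: (drow, dcol, length factor)
_MOVES = [
    (0, 1, 1.0), (1, 0, 1.0), (1, 1, SQRT2), (1, -1, SQRT2),
]


# ---------------------------------------------------------------------------
# focal points

def snap_to_water(
    bathy: BathymetryGrid, lonlat: np.ndarray, max_radius_cells: int = 3
) -> list[tuple[int, int]]:
    """Map coordinates to water cells, snapping to the nearest within radius."""
    water = bathy.is_water()
    wr, wc = np.where(water)
    out = []
    for lon, lat in np.atleast_2d(lonlat):
        r, c = bathy.lonlat_to_rowcol(lon, lat)
        r = int(np.clip(r, 0, bathy.n_rows - 1))
        c = int(np.clip(c, 0, bathy.n_cols - 1))
        if water[r, c]:
            out.append((r, c))
            continue
        d2 = (wr - r) ** 2 + (wc - c) ** 2
        j = int(np.argmin(d2))
        dist = np.sqrt(d2[j])
        if dist > max_radius_cells:
            raise ValueError(
                f"point ({lon}, {lat}) is {dist:.1f} cells from water "
                f"(max {max_radius_cells})"
            )
        log.info("snapped (%s, %s) %.1f cells to water", lon, lat, dist)
        out.append((int(wr[j]), int(wc[j])))
    return out


def _cell_index_map(mask: np.ndarray) -> np.ndarray:
    idx = np.full(mask.shape, -1, dtype=int)
    idx[mask] = np.arange(mask.sum())
    return idx


def _grid_edges(mask: np.ndarray):
    """(i, j, diag) arrays for 8-neighbour edges among True cells."""
    idx = _cell_index_map(mask)
    nrows, ncols = mask.shape
    ii, jj, diag = [], [], []
    for dr, dc, fac in _MOVES:
        r0s, r0e = max(0, -dr), min(nrows, nrows - dr)
        c0s, c0e = max(0, -dc), min(ncols, ncols - dc)
        a = mask[r0s:r0e, c0s:c0e]
        b = mask[r0s + dr:r0e + dr, c0s + dc:c0e + dc]
        both = a & b
        src = idx[r0s:r0e, c0s:c0e][both]
        dst = idx[r0s + dr:r0e + dr, c0s + dc:c0e + dc][both]
        ii.append(src)
        jj.append(dst)
        diag.append(np.full(src.size, fac == SQRT2))
    return np.concatenate(ii), np.concatenate(jj), np.concatenate(diag), idx


# ---------------------------------------------------------------------------
# over-water least-cost distance (IBD null model)

def overwater_distance(
    bathy: BathymetryGrid, points_lonlat: np.ndarray, location_ids=None
) -> PairwiseMatrix:
    """Shortest path through water only, 8-neighbour moves, in km.

    Orthogonal steps cost one cell size, diagonal steps sqrt(2) of it.
    Unreachable pairs (disconnected water bodies) get ``inf`` with a warning.
    """
    water = bathy.is_water()
    cells = snap_to_water(bathy, points_lonlat)
    ii, jj, diag, idx = _grid_edges(water)
    step = bathy.cell_size_km
    w = np.where(diag, SQRT2 * step, step)
    n = int(water.sum())
    A = sparse.coo_matrix((w, (ii, jj)), shape=(n, n)).tocsr()
    A = A + A.T
    focal = np.array([idx[r, c] for r, c in cells])
    D = dijkstra(A, directed=False, indices=focal)
    M = D[:, focal]
    M = 0.5 * (M + M.T)  # guard fp asymmetry
    np.fill_diagonal(M, 0.0)
    if np.isinf(M).any():
        warnings.warn("overwater_distance: some location pairs are disconnected")
    if location_ids is None:
        location_ids = [f"loc_{i}" for i in range(len(cells))]
    return PairwiseMatrix(list(location_ids), M, "overwater_km", True)


# ---------------------------------------------------------------------------
# paleo clamping and depth -> resistance transformation

def make_paleo(
    bathy: BathymetryGrid, clamp_floor: float = -210.0, assigned_depth: float = 1.0
) -> BathymetryGrid:
    """Clamp glacial-maximum shallows to a nominal shallow depth.

    Water cells with elevation in [clamp_floor, 0) — shallow at least once
    during late-Quaternary sea-level low stands — are set to
    ``-assigned_depth``; deeper water, land, and NoData are unchanged.
    """
    if clamp_floor >= 0:
        raise ValueError("clamp_floor must be negative")
    elev = bathy.elevation.copy()
    shallow = bathy.is_water() & (elev >= clamp_floor)
    elev[shallow] = -abs(assigned_depth)
    return BathymetryGrid(elev, bathy.origin, bathy.cellsize_deg, bathy.nodata)


@dataclass
class ResistanceSurface:
    """Per-cell resistance on the water mask of a bathymetry grid."""

    bathy: BathymetryGrid
    resistance: np.ndarray  # nan on land/NoData, >= 1 on water
    family: str = ""
    shape: float = np.nan
    magnitude: float = np.nan
    meta: dict = field(default_factory=dict)

    def conductance(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return 1.0 / self.resistance


def transform_surface(
    bathy: BathymetryGrid,
    family: str,
    shape: float,
    magnitude: float,
    depth_range: tuple | None = None,
) -> ResistanceSurface:
    """Monomolecular depth-to-resistance transformation.

    Depth (positive metres) is min-max rescaled to x in [0, 1] over water;
    pass ``depth_range=(dmin, dmax)`` to pin the rescaling (e.g. to put a
    contemporary and a paleo surface on one common depth scale — only then
    is clamping shallows guaranteed to lower every cell's resistance).
    The monomolecular curve f(x) = 1 + (m-1)(1 - e^{-s x})/(1 - e^{-s})
    rises concavely from 1 to m (resistance saturates quickly with depth).
    The reverse family applies the curve to 1 - x and re-anchors it
    vertically (r = 1 + m - f(1 - x)), giving a convex rise: shallows stay
    conductive and resistance climbs steeply only at depth. Both map the
    shallowest water to resistance 1 and the deepest to m.
    """
    if shape <= 0:
        raise ValueError("shape s must be > 0")
    if magnitude <= 1:
        raise ValueError("magnitude m must be > 1")
    if family not in ("monomolecular", "reverse_monomolecular"):
        raise ValueError(f"unknown transformation family {family!r}")
    water = bathy.is_water()
    depth = -bathy.elevation[water]
    dmin, dmax = (
        (depth.min(), depth.max()) if depth_range is None else depth_range
    )
    rng = dmax - dmin
    if rng == 0:
        warnings.warn("transform_surface: constant depth; flat surface returned")
        x = np.zeros_like(depth)
    else:
        x = np.clip((depth - dmin) / rng, 0.0, 1.0)
    def f(u):
        return 1.0 + (magnitude - 1.0) * (1.0 - np.exp(-shape * u)) / (
            1.0 - np.exp(-shape)
        )

    if family == "monomolecular":
        r = f(x)
    else:
        r = 1.0 + magnitude - f(1.0 - x)
    res = np.full(bathy.elevation.shape, np.nan)
    res[water] = r
    return ResistanceSurface(bathy, res, family, shape, magnitude)


# ---------------------------------------------------------------------------
# effective resistance (circuit theory)

def _surface_laplacian(surface: ResistanceSurface):
    water = surface.bathy.is_water()
    cond = surface.conductance()[water]
    ii, jj, diag, idx = _grid_edges(water)
    # edge conductance = mean of end-cell conductances; diagonal edges are
    # longer by sqrt(2), so their conductance is scaled by 1/sqrt(2)
    g = 0.5 * (cond[ii] + cond[jj])
    g = np.where(diag, g / SQRT2, g)
    n = cond.size
    A = sparse.coo_matrix((g, (ii, jj)), shape=(n, n)).tocsr()
    A = A + A.T
    lap = sparse.diags(np.asarray(A.sum(axis=1)).ravel()) - A
    return lap.tocsc(), idx


def effective_resistance_graph(lap, focal: np.ndarray) -> np.ndarray:
    """Pairwise effective resistance between focal nodes of a graph Laplacian.

    One grounded sparse-LU solve per focal node: with node g grounded,
    solving L_red v_i = e_i for each focal i gives
    R(i, j) = v_i[i] + v_j[j] - 2 v_i[j] (and R(i, g) = v_i[i]).
    Pairs in different connected components get ``inf``.
    """
    lap = sparse.csc_matrix(lap)
    focal = np.asarray(focal, dtype=int)
    k = len(focal)
    # self-loops on the Laplacian diagonal do not affect connectivity
    n_comp, comp = sparse.csgraph.connected_components(lap, directed=False)
    R = np.full((k, k), np.inf)
    np.fill_diagonal(R, 0.0)
    for comp_id in np.unique(comp[focal]):
        in_comp = np.flatnonzero(comp == comp_id)
        sub_focal = [i for i in range(k) if comp[focal[i]] == comp_id]
        if len(sub_focal) < 2:
            continue
        pos = {node: i for i, node in enumerate(in_comp)}
        sub_lap = lap[np.ix_(in_comp, in_comp)].tocsc()
        g_local = pos[focal[sub_focal[0]]]
        keep = np.ones(len(in_comp), dtype=bool)
        keep[g_local] = False
        red = sub_lap[np.ix_(np.flatnonzero(keep), np.flatnonzero(keep))]
        lu = splu(red.tocsc())
        # map local index -> reduced index
        red_pos = np.cumsum(keep) - 1
        V = {}
        for fi in sub_focal:
            node = pos[focal[fi]]
            if node == g_local:
                V[fi] = None
                continue
            e = np.zeros(red.shape[0])
            e[red_pos[node]] = 1.0
            V[fi] = lu.solve(e)
        for ai in range(len(sub_focal)):
            for bi in range(ai + 1, len(sub_focal)):
                fa, fb = sub_focal[ai], sub_focal[bi]
                na, nb = pos[focal[fa]], pos[focal[fb]]
                if na == g_local:
                    val = V[fb][red_pos[nb]]
                elif nb == g_local:
                    val = V[fa][red_pos[na]]
                else:
                    val = (
                        V[fa][red_pos[na]] + V[fb][red_pos[nb]]
                        - 2.0 * V[fa][red_pos[nb]]
                    )
                R[fa, fb] = R[fb, fa] = val
    return R


def effective_resistance(
    surface: ResistanceSurface, points_lonlat: np.ndarray, location_ids=None
) -> PairwiseMatrix:
    """Pairwise effective resistance between focal points on the water graph.

    Builds the conductance-weighted 8-neighbour graph over water cells and
    delegates to :func:`effective_resistance_graph`. Effective resistance is
    a metric; disconnected pairs get ``inf`` with a warning.
    """
    cells = snap_to_water(surface.bathy, points_lonlat)
    lap, idx = _surface_laplacian(surface)
    focal = np.array([idx[r, c] for r, c in cells])
    R = effective_resistance_graph(lap, focal)
    if np.isinf(R).any():
        warnings.warn("effective_resistance: some focal pairs are disconnected")
    if location_ids is None:
        location_ids = [f"loc_{i}" for i in range(len(cells))]
    return PairwiseMatrix(list(location_ids), R, "effective_resistance", True)


# ---------------------------------------------------------------------------
# Mantel machinery

def _check_pair(A: PairwiseMatrix, B: PairwiseMatrix):
    if list(A.location_ids) != list(B.location_ids):
        raise ValueError("matrices have different location sets/orders")


def _mantel_r(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise ValueError("Mantel r undefined for a constant matrix")
    return float(((a - a.mean()) @ (b - b.mean())) / (len(a) * sa * sb))


def mantel(
    A: PairwiseMatrix,
    B: PairwiseMatrix,
    n_perm: int = 1000,
    seed: int = 0,
    alternative: str = "two-sided",
    exact: bool = False,
) -> dict:
    """Mantel test between two distance matrices.

    r is the Pearson correlation over lower-triangle entries; the p-value
    permutes rows/columns of A simultaneously with the +1 correction.
    ``alternative`` is 'two-sided' (|r| comparison) or 'greater'.
    ``exact=True`` enumerates all n! permutations (identity included, no +1
    correction) — feasible only for a handful of locations.
    """
    _check_pair(A, B)
    n = A.n
    i, j = np.tril_indices(n, k=-1)
    a, b = A.values[i, j], B.values[i, j]
    r_obs = _mantel_r(a, b)

    def _exceeds(rp):
        if alternative == "greater":
            return rp >= r_obs - 1e-12
        return abs(rp) >= abs(r_obs) - 1e-12

    if exact:
        if n > 8:
            raise ValueError("exact enumeration is limited to n <= 8")
        import itertools
        import math

        count = sum(
            _exceeds(_mantel_r(A.values[np.ix_(perm, perm)][i, j], b))
            for perm in itertools.permutations(range(n))
        )
        p = count / math.factorial(n)
        return {"r": r_obs, "r2": r_obs**2, "p": p, "n_perm": math.factorial(n)}
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        ap = A.values[np.ix_(perm, perm)][i, j]
        count += _exceeds(_mantel_r(ap, b))
    p = (1.0 + count) / (n_perm + 1.0)
    return {"r": r_obs, "r2": r_obs**2, "p": p, "n_perm": n_perm}


def _partial_r(rab: float, rac: float, rbc: float) -> float:
    num = rab - rac * rbc
    denom = np.sqrt(max((1 - rac**2) * (1 - rbc**2), 0.0))
    if denom < 1e-12:
        if abs(num) < 1e-12:
            # controlling a matrix for itself: nothing left to correlate
            return 0.0
        raise ValueError("partial correlation undefined (perfect control)")
    return num / denom


def partial_mantel(
    A: PairwiseMatrix,
    B: PairwiseMatrix,
    C: PairwiseMatrix,
    n_perm: int = 1000,
    seed: int = 0,
    alternative: str = "two-sided",
) -> dict:
    """Partial Mantel: correlation of A and B controlling C (residual method).

    Permutes A's rows/columns and recomputes the partial correlation.
    """
    _check_pair(A, B)
    _check_pair(A, C)
    n = A.n
    i, j = np.tril_indices(n, k=-1)
    a, b, c = A.values[i, j], B.values[i, j], C.values[i, j]
    rbc = _mantel_r(b, c)
    r_obs = _partial_r(_mantel_r(a, b), _mantel_r(a, c), rbc)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        ap = A.values[np.ix_(perm, perm)][i, j]
        rp = _partial_r(_mantel_r(ap, b), _mantel_r(ap, c), rbc)
        if alternative == "greater":
            count += rp >= r_obs
        else:
            count += abs(rp) >= abs(r_obs)
    p = (1.0 + count) / (n_perm + 1.0)
    return {"r": r_obs, "p": p, "n_perm": n_perm}


# ---------------------------------------------------------------------------
# surface optimization

@dataclass
class ModelFit:
    model: str
    distances: PairwiseMatrix
    r: float
    r2: float
    p: float
    params: dict = field(default_factory=dict)
    supported: bool | None = None

    def summary(self) -> dict:
        return {"model": self.model, "r": self.r, "r2": self.r2, "p": self.p,
                **{f"param_{k}": v for k, v in self.params.items()},
                "supported": self.supported}


def optimize_surface(
    bathy: BathymetryGrid,
    genetic_dist: PairwiseMatrix,
    points_lonlat: np.ndarray,
    families=("monomolecular", "reverse_monomolecular"),
    s_bounds: tuple = (0.1, 10.0),
    m_bounds: tuple = (1.5, 1000.0),
    seed: int = 0,
    maxiter: int = 15,
    popsize: int = 8,
    n_perm: int = 1000,
    model_name: str = "IBR",
) -> tuple[ResistanceSurface, ModelFit]:
    """Fit the depth-to-resistance transformation to genetic distances.

    Differential evolution searches (s, m) within bounds for each family,
    maximising Mantel r^2 between effective resistance and the genetic
    distance matrix; the best family wins. Deterministic for a fixed seed.
    """
    if not families:
        raise ValueError("families must be non-empty")
    if genetic_dist.n < 4:
        raise ValueError("need >= 4 locations to optimize a surface")
    n_eval = 0

    def make_obj(family):
        def obj(theta):
            nonlocal n_eval
            n_eval += 1
            s, m = theta
            surf = transform_surface(bathy, family, s, m)
            eff = effective_resistance(surf, points_lonlat, genetic_dist.location_ids)
            i, j = np.tril_indices(eff.n, k=-1)
            a, b = eff.values[i, j], genetic_dist.values[i, j]
            if not np.isfinite(a).all() or a.std() == 0:
                return 1.0
            return 1.0 - _mantel_r(a, b) ** 2
        return obj

    best = None
    for fi, family in enumerate(families):
        res = differential_evolution(
            make_obj(family),
            bounds=[s_bounds, m_bounds],
            seed=seed + fi,
            maxiter=maxiter,
            popsize=popsize,
            tol=1e-6,
            polish=False,
        )
        if best is None or res.fun < best[1].fun:
            best = (family, res)
    family, res = best
    s, m = res.x
    surf = transform_surface(bathy, family, float(s), float(m))
    eff = effective_resistance(surf, points_lonlat, genetic_dist.location_ids)
    mt = mantel(eff, genetic_dist, n_perm=n_perm, seed=seed, alternative="greater")
    log.info("optimize_surface: %d objective evaluations", n_eval)
    fit = ModelFit(
        model=model_name, distances=eff, r=mt["r"], r2=mt["r2"], p=mt["p"],
        params={"family": family, "shape": float(s), "magnitude": float(m),
                "n_evaluations": n_eval},
    )
    return surf, fit


def causal_compare(
    genetic_dist: PairwiseMatrix,
    candidates: dict,
    n_perm: int = 1000,
    seed: int = 0,
    level: float = 0.05,
) -> dict:
    """Causal-modeling comparison of candidate distance models.

    A candidate is *supported* iff (i) the partial Mantel of genetic vs
    candidate controlling each alternative is significant, and (ii) genetic
    vs each alternative controlling the candidate is non-significant, at
    the given level (one-sided tests of positive association). Returns the
    full test matrix, simple-Mantel r^2 ranking, and per-candidate verdict.
    """
    names = list(candidates)
    tests = {}
    simple = {}
    for k, name in enumerate(names):
        simple[name] = mantel(
            genetic_dist, candidates[name].align(genetic_dist.location_ids),
            n_perm=n_perm, seed=seed + k, alternative="greater",
        )
    verdict = {}
    for k, name in enumerate(names):
        cand = candidates[name].align(genetic_dist.location_ids)
        support = True
        for k2, other in enumerate(names):
            if other == name:
                continue
            oth = candidates[other].align(genetic_dist.location_ids)
            fwd = partial_mantel(
                genetic_dist, cand, oth, n_perm=n_perm,
                seed=seed + 101 * k + k2, alternative="greater",
            )
            rev = partial_mantel(
                genetic_dist, oth, cand, n_perm=n_perm,
                seed=seed + 211 * k + k2, alternative="greater",
            )
            tests[(name, other)] = {"candidate_given_other": fwd,
                                    "other_given_candidate": rev}
            if fwd["p"] > level or rev["p"] <= level:
                support = False
        verdict[name] = support
    ranking = sorted(names, key=lambda n: -simple[n]["r2"])
    return {"simple": simple, "partial": tests, "supported": verdict,
            "ranking_by_r2": ranking, "level": level}
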