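"""Synthetic archipelagos, genotypes, and Wright–Fisher samples.

The generator produces the three inputs the analysis consumes, with the
statistical structure the method assumes, so every stage can be tested in a
closed loop:

* :func:`make_archipelago` — a bathymetry grid of Gaussian-cone volcanic
  islands on a deep channel baseline, with optional shallow sills between
  chosen island pairs (the glacial-sea-level corridors);
* :func:`simulate_genotypes` — deme allele frequencies whose logit-scale
  divergence grows with a supplied resistance matrix (covariance
  sigma^2 * exp(-R/rho)), then binomial genotypes per individual;
* :func:`simulate_wright_fisher` — an individual-based constant-size
  diploid Wright–Fisher population with unlinked loci, the test harness for
  the LD-Ne estimator.

The logit-normal frequency model is used instead of a coalescent because it
gives direct, tunable control over the divergence–resistance relationship
the isolation-by-resistance tests assume, at trivial compute cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import BathymetryGrid, GenotypeMatrix, LocationTable, PairwiseMatrix


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic generator.

    Defaults emulate a multi-island archipelago survey: ~10^2 diploids in a
    handful of demes, ~10^3 biallelic loci, weak-to-moderate divergence.
    """

    seed: int = 0
    # --- archipelago raster
    n_rows: int = 100
    n_cols: int = 100
    origin: tuple = (-91.8, -1.5)
    cellsize_deg: float = 0.02
    channel_depth: float = -900.0
    plateau_depth: float = -120.0
    island_centers: list = field(default_factory=list)  # (row, col) per island
    island_radii: list = field(default_factory=list)  # cells
    island_peak: float = 400.0  # metres above sea level at the cone centre
    sills: list = field(default_factory=list)  # (island_a, island_b, depth_m)
    sill_width: float = 4.0  # cells, Gaussian half-width of the ridge
    # --- genotypes
    samples_per_deme: int = 25
    n_loci: int = 2000
    sigma2: float = 0.09  # logit-scale divergence variance at R = 0 distance
    rho: float = 1.0  # resistance decay scale (units of the R matrix)
    # --- Wright–Fisher block
    wf_ne: int = 200
    wf_generations: int = 50
    wf_sample: int = 50
    wf_loci: int = 500


def default_archipelago_config(seed: int = 0) -> SimConfig:
    """A five-island layout exercising all three connectivity regimes.

    Islands 0-1 share a shallow plateau (connected now and in the past),
    islands 1-2 are close but cut by a deep channel (isolated in both), and
    islands 2-3 and 3-4 are linked by -150 m sills — dry or shallow at
    glacial-maximum sea level, so the paleo clamp re-opens them.
    """
    return SimConfig(
        seed=seed,
        island_centers=[(20, 15), (20, 45), (20, 80), (55, 80), (85, 50)],
        island_radii=[7, 7, 7, 7, 7],
        sills=[(0, 1, -60.0), (2, 3, -150.0), (3, 4, -150.0)],
    )


def make_archipelago(cfg: SimConfig) -> BathymetryGrid:
    """Deterministic bathymetry grid of Gaussian-cone islands and sills."""
    if not cfg.island_centers:
        raise ValueError("config has no islands")
    rows, cols = np.mgrid[0: cfg.n_rows, 0: cfg.n_cols]
    elev = np.full((cfg.n_rows, cfg.n_cols), float(cfg.channel_depth))
    for (r0, c0), rad in zip(cfg.island_centers, cfg.island_radii):
        if not (0 <= r0 < cfg.n_rows and 0 <= c0 < cfg.n_cols):
            raise ValueError(f"island centre {(r0, c0)} outside grid")
        d2 = (rows - r0) ** 2 + (cols - c0) ** 2
        cone = (cfg.island_peak - cfg.channel_depth) * np.exp(
            -d2 / (2.0 * rad**2)
        ) + cfg.channel_depth
        elev = np.maximum(elev, cone)
    for a, b, depth in cfg.sills:
        ra, ca = cfg.island_centers[a]
        rb, cb = cfg.island_centers[b]
        # raise the seafloor to the sill depth within a Gaussian ridge
        # around the segment between the two island centres
        pa = np.array([ra, ca], float)
        pb = np.array([rb, cb], float)
        ab = pb - pa
        t = np.clip(
            ((rows - pa[0]) * ab[0] + (cols - pa[1]) * ab[1]) / (ab @ ab), 0, 1
        )
        px = pa[0] + t * ab[0]
        py = pa[1] + t * ab[1]
        dist2 = (rows - px) ** 2 + (cols - py) ** 2
        # quadratic falloff from sill depth on the ridge line down to the
        # channel baseline at 2 * sill_width cells laterally
        w2 = (2.0 * cfg.sill_width) ** 2
        ridge = depth + (cfg.channel_depth - depth) * np.minimum(dist2 / w2, 1.0)
        near = dist2 <= w2
        elev = np.where(near, np.maximum(elev, ridge), elev)
    return BathymetryGrid(elev, cfg.origin, cfg.cellsize_deg)


def deme_coordinates(cfg: SimConfig, bathy: BathymetryGrid) -> pd.DataFrame:
    """One coastal sampling site per island: nearest water cell seaward of
    the island centre, offset by one radius toward the grid centre."""
    water = bathy.is_water()
    wr, wc = np.where(water)
    rows = []
    centre = np.array([cfg.n_rows / 2.0, cfg.n_cols / 2.0])
    for i, ((r0, c0), rad) in enumerate(zip(cfg.island_centers, cfg.island_radii)):
        p = np.array([r0, c0], float)
        v = centre - p
        nv = np.linalg.norm(v)
        tgt = p + (v / nv * (rad + 2.0) if nv > 0 else np.array([rad + 2.0, 0.0]))
        d2 = (wr - tgt[0]) ** 2 + (wc - tgt[1]) ** 2
        j = int(np.argmin(d2))
        lon, lat = bathy.rowcol_to_lonlat(int(wr[j]), int(wc[j]))
        rows.append({"location_id": f"deme_{i}", "longitude": lon, "latitude": lat})
    return pd.DataFrame(rows).set_index("location_id")


def simulate_genotypes(
    resist: PairwiseMatrix, cfg: SimConfig, coords: pd.DataFrame | None = None
) -> tuple[GenotypeMatrix, LocationTable]:
    """Genotypes whose between-deme divergence tracks resistance distance.

    Per locus: ancestral frequency p0 ~ U(0.1, 0.9); deme logit frequencies
    are multivariate normal with mean logit(p0) and covariance
    sigma^2 exp(-R/rho); individual genotypes are Binomial(2, p_deme).
    Byte-for-byte reproducible for a fixed config.
    """
    R = np.asarray(resist.values, float)
    if not np.isfinite(R).all():
        raise ValueError("resistance matrix must be finite")
    if not np.allclose(R, R.T):
        raise ValueError("resistance matrix must be symmetric")
    rng = np.random.default_rng(cfg.seed)
    k = resist.n
    cov = cfg.sigma2 * np.exp(-R / cfg.rho)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        import warnings

        warnings.warn("covariance not positive definite; jitter applied")
        chol = np.linalg.cholesky(cov + 1e-8 * np.eye(k))
    L = cfg.n_loci
    p0 = rng.uniform(0.1, 0.9, size=L)
    z = rng.standard_normal(size=(L, k)) @ chol.T
    logits = np.log(p0 / (1 - p0))[:, None] + z
    freqs = 1.0 / (1.0 + np.exp(-logits))  # (L, k)
    n = cfg.samples_per_deme
    calls = np.empty((n * k, L))
    sample_ids, rows_meta = [], []
    if coords is None:
        coords = pd.DataFrame(
            {
                "longitude": cfg.origin[0] + 0.1 + 0.05 * np.arange(k),
                "latitude": cfg.origin[1] + 0.1 + 0.05 * np.arange(k),
            },
            index=resist.location_ids,
        )
    for d, lid in enumerate(resist.location_ids):
        g = rng.binomial(2, freqs[:, d], size=(n, L)).astype(float)
        calls[d * n:(d + 1) * n] = g
        for i in range(n):
            sid = f"{lid}_s{i}"
            sample_ids.append(sid)
            rows_meta.append(
                {
                    "sample_id": sid,
                    "location_id": lid,
                    "longitude": float(coords.loc[lid, "longitude"]),
                    "latitude": float(coords.loc[lid, "latitude"]),
                }
            )
    gm = GenotypeMatrix(sample_ids, [f"L{j}" for j in range(L)], calls)
    return gm, LocationTable(pd.DataFrame(rows_meta))


def simulate_wright_fisher(cfg: SimConfig) -> GenotypeMatrix:
    """Individual-based diploid Wright–Fisher sample with unlinked loci.

    Constant population of ``wf_ne`` diploids; each generation every
    offspring draws two random parents and inherits, at every locus
    independently, one allele from each (free recombination). Initial
    frequencies are U(0.2, 0.8); loci fixed by the end of the run are
    re-run down the same pedigree so the output stays polymorphic. The
    returned sample is a cohort of ``wf_sample`` offspring bred from the
    final population — the LD method's model of a sample whose parents are
    the Ne breeders (sampling adults of a small population instead would
    add a finite-pool correction the method does not assume).

    LD among unlinked loci equilibrates within tens of generations (it is
    regenerated each generation by drift and halved by recombination), so
    the default run length targets that quasi-equilibrium rather than full
    coalescent equilibrium of allele frequencies.
    """
    if cfg.wf_ne < 10:
        raise ValueError("wf_ne must be >= 10")
    if cfg.wf_sample > cfg.wf_ne:
        raise ValueError("sample size exceeds population size")
    rng = np.random.default_rng(cfg.seed)
    N, L = cfg.wf_ne, cfg.wf_loci
    # one shared pedigree for every locus: the identity disequilibrium that
    # carries the Ne signal comes from loci travelling the same genealogy
    pedigree = [rng.integers(0, N, size=(N, 2)) for _ in range(cfg.wf_generations)]

    def transmit(loci: int) -> np.ndarray:
        p0 = rng.uniform(0.2, 0.8, size=loci)
        pop = rng.binomial(2, p0, size=(N, loci)).astype(np.int8)
        for parents in pedigree:
            ha = rng.binomial(1, pop[parents[:, 0]] / 2.0)
            hb = rng.binomial(1, pop[parents[:, 1]] / 2.0)
            pop = (ha + hb).astype(np.int8)
        return pop

    pop = transmit(L)
    for _ in range(50):  # re-run fixed loci down the same pedigree
        freq = pop.mean(axis=0) / 2.0
        fixed = np.flatnonzero((freq == 0.0) | (freq == 1.0))
        if fixed.size == 0:
            break
        pop[:, fixed] = transmit(fixed.size)
    parents = rng.integers(0, N, size=(cfg.wf_sample, 2))
    ha = rng.binomial(1, pop[parents[:, 0]] / 2.0)
    hb = rng.binomial(1, pop[parents[:, 1]] / 2.0)
    calls = (ha + hb).astype(float)
    return GenotypeMatrix(
        [f"ind_{i}" for i in range(cfg.wf_sample)],
        [f"L{j}" for j in range(L)],
        calls,
    )
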