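"""Closed-loop study-level experiments on synthetic data.

These functions wire the synthetic generator to the analysis stages and
measure how well the pipeline recovers known truth:

* :func:`model_ranking_replicates` — genotypes generated from the paleo
  resistance surface of a sill-bearing archipelago; checks that Mantel r^2
  ranks paleo IBR > contemporary IBR > IBD and that causal modeling singles
  out the paleo model (the qualitative structure of a paleo-connectivity
  verdict);
* :func:`ld_ne_recovery` — Wright–Fisher cohorts of known Ne through the
  LD estimator; checks point recovery and jackknife-CI coverage of truth;
* :func:`drift_free_r2` — very large population, so mean Burrows r^2 should
  match the pure-sampling expectation;
* :func:`type_one_error_rates` — exchangeable (no-signal) data through the
  pairwise tests and outlier scans; flag rates should not exceed nominal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import resistance as res
from . import simulate as sim
from .containers import GenotypeMatrix, LocationTable
from .ne import burrows_r2, expected_sampling_r2, jackknife_ci, ne_from_r2
from .outliers import fst_outlier_scan, pca_outlier_scan
from .popgen import linearize_matrix, pairwise_with_bootstrap


@dataclass
class RankingResult:
    r2: dict  # model -> Mantel r^2 per replicate (list)
    rank_ok: list  # paleo > contemporary > IBD per replicate
    paleo_only_supported: list  # causal verdict per replicate

    @property
    def rank_fraction(self) -> float:
        return float(np.mean(self.rank_ok))

    @property
    def paleo_support_fraction(self) -> float:
        return float(np.mean(self.paleo_only_supported))


def archipelago_distance_models(
    cfg: sim.SimConfig | None = None,
    transform=("reverse_monomolecular", 2.0, 100.0),
):
    """Build the three candidate distance matrices for one archipelago.

    Returns (bathy, coords, dict of PairwiseMatrix: IBD / IBR_contemporary /
    IBR_paleo) at the given depth-to-resistance transform.
    """
    if cfg is None:
        cfg = sim.default_archipelago_config()
    family, s, m = transform
    bathy = sim.make_archipelago(cfg)
    coords = sim.deme_coordinates(cfg, bathy)
    pts = coords[["longitude", "latitude"]].to_numpy()
    ids = list(coords.index)
    paleo = res.make_paleo(bathy)
    surf_c = res.transform_surface(bathy, family, s, m)
    surf_p = res.transform_surface(paleo, family, s, m)
    models = {
        "IBD": res.overwater_distance(bathy, pts, ids),
        "IBR_contemporary": res.effective_resistance(surf_c, pts, ids),
        "IBR_paleo": res.effective_resistance(surf_p, pts, ids),
    }
    return bathy, coords, models


def model_ranking_replicates(
    n_replicates: int = 20,
    seed: int = 0,
    n_perm: int = 199,
    cfg: sim.SimConfig | None = None,
) -> RankingResult:
    """Simulate genotypes from the paleo surface and rank the three models.

    The archipelago (hence the three distance matrices) is fixed; each
    replicate draws new genotypes whose divergence follows the paleo
    resistance matrix, computes pairwise linearized FST, and evaluates the
    three models by Mantel r^2 plus reciprocal partial-Mantel support.
    """
    base = sim.default_archipelago_config(seed) if cfg is None else cfg
    _, coords, models = archipelago_distance_models(base)
    rho = float(np.median(models["IBR_paleo"].lower_triangle()))
    r2 = {name: [] for name in models}
    rank_ok, paleo_only = [], []
    for rep in range(n_replicates):
        rep_cfg = sim.SimConfig(**{**base.__dict__, "seed": seed + rep, "rho": rho})
        gm, loc = sim.simulate_genotypes(models["IBR_paleo"], rep_cfg, coords)
        fst = pairwise_with_bootstrap(gm, loc, "fst", n_boot=1, seed=seed + rep)
        gen = linearize_matrix(fst)
        vals = {}
        for name, M in models.items():
            mt = res.mantel(
                M.align(gen.location_ids), gen, n_perm=n_perm,
                seed=seed + rep, alternative="greater",
            )
            vals[name] = mt["r2"]
            r2[name].append(mt["r2"])
        rank_ok.append(
            vals["IBR_paleo"] > vals["IBR_contemporary"] > vals["IBD"]
        )
        cc = res.causal_compare(
            gen,
            {k: v.align(gen.location_ids) for k, v in models.items()},
            n_perm=n_perm, seed=seed + rep,
        )
        sup = cc["supported"]
        paleo_only.append(
            sup["IBR_paleo"] and not sup["IBD"] and not sup["IBR_contemporary"]
        )
    return RankingResult(r2, rank_ok, paleo_only)


def ld_ne_recovery(
    n_replicates: int = 100,
    seed: int = 0,
    true_ne: int = 200,
    sample: int = 50,
    loci: int = 500,
    generations: int = 50,
    pcrit: float = 0.02,
) -> pd.DataFrame:
    """Wright–Fisher cohorts of known Ne through the full LD pipeline.

    Returns one row per replicate: point estimate, jackknife CI, and
    whether the CI covers the simulated truth.
    """
    rows = []
    for rep in range(n_replicates):
        cfg = sim.SimConfig(
            seed=seed + rep, wf_ne=true_ne, wf_generations=generations,
            wf_sample=sample, wf_loci=loci,
        )
        gm = sim.simulate_wright_fisher(cfg)
        mean_r2, n_pairs, S = burrows_r2(gm, pcrit)
        point = ne_from_r2(mean_r2, S)
        lo, hi = jackknife_ci(gm, pcrit)
        rows.append(
            {
                "replicate": rep,
                "mean_r2": mean_r2,
                "Ne": point,
                "CI_low": lo,
                "CI_high": hi,
                "covers_truth": bool(lo <= true_ne <= hi),
            }
        )
    return pd.DataFrame(rows)


def drift_free_r2(
    n_replicates: int = 3, seed: int = 0, sample: int = 50, loci: int = 150
) -> tuple[float, float]:
    """Mean Burrows r^2 with (effectively) no drift vs the sampling formula.

    Simulates cohorts from a very large population so the drift component
    1/(3Ne) is negligible; returns (observed mean r^2, expected 1/S +
    3.19/S^2).
    """
    vals = []
    for rep in range(n_replicates):
        cfg = sim.SimConfig(
            seed=seed + rep, wf_ne=10**5, wf_generations=0,
            wf_sample=sample, wf_loci=loci,
        )
        gm = sim.simulate_wright_fisher(cfg)
        vals.append(burrows_r2(gm, 0.02)[0])
    return float(np.mean(vals)), expected_sampling_r2(sample)


def _exchangeable_panel(rng, n_per, n_demes, n_loci, fst_null=0.0):
    """Genotypes with exchangeable loci: panmictic or Balding–Nichols drift."""
    p = rng.uniform(0.1, 0.9, n_loci)
    blocks = []
    for _ in range(n_demes):
        if fst_null > 0:
            a = p * (1 - fst_null) / fst_null
            b = (1 - p) * (1 - fst_null) / fst_null
            pd_ = rng.beta(a, b)
        else:
            pd_ = p
        blocks.append(rng.binomial(2, pd_, (n_per, n_loci)))
    calls = np.vstack(blocks).astype(float)
    gm = GenotypeMatrix(
        [f"s{i}" for i in range(n_per * n_demes)],
        [f"L{j}" for j in range(n_loci)],
        calls,
    )
    labels = np.repeat([f"d{k}" for k in range(n_demes)], n_per)
    loc = LocationTable(
        pd.DataFrame(
            {
                "sample_id": gm.sample_ids,
                "location_id": labels,
                "longitude": 0.0,
                "latitude": 0.0,
            }
        )
    )
    return gm, loc


def type_one_error_rates(
    n_pairwise: int = 500,
    n_outlier: int = 200,
    seed: int = 0,
    q_level: float = 0.05,
) -> dict:
    """False-positive rates of the FDR-adjusted tests on no-signal data.

    Pairwise FST tests run on panmictic 3-deme data (any flag is a false
    positive); the outlier scans run on panmictic (PCA scan) and
    drift-exchangeable (FST scan) panels where no locus is an outlier.
    """
    rng = np.random.default_rng(seed)
    flags = total = 0
    for rep in range(n_pairwise):
        gm, loc = _exchangeable_panel(rng, 10, 3, 100)
        pm = pairwise_with_bootstrap(gm, loc, "fst", n_boot=100, seed=seed + rep)
        iu = np.triu_indices(3, 1)
        flags += int((pm.p_adjusted[iu] <= q_level).sum())
        total += len(iu[0])
    pairwise_rate = flags / total

    pca_rates, fst_rates = [], []
    for rep in range(n_outlier):
        gm, _ = _exchangeable_panel(rng, 20, 2, 200)
        rep_pca = pca_outlier_scan(gm, K=2, q_threshold=q_level)
        pca_rates.append(rep_pca.flagged.mean())
        gm2, loc2 = _exchangeable_panel(rng, 15, 2, 200, fst_null=0.05)
        rep_fst = fst_outlier_scan(gm2, loc2, q_level, 0.05)
        fst_rates.append(rep_fst.flagged.mean())
    return {
        "pairwise_fdr_rate": pairwise_rate,
        "pca_outlier_rate": float(np.mean(pca_rates)),
        "fst_outlier_rate": float(np.mean(fst_rates)),
        "nominal": q_level,
    }
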