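"""Relative directional migration between population pairs.

For each ordered pair (a, b) a hypothetical pool population is built whose
allele frequencies are the (by default unweighted) mean of a's and b's.
Nei's G_ST is computed between each member and the pool; a population that
receives many migrants resembles the joint migrant pool, so LOW
differentiation from the pool marks the SINK of gene flow. The directional
migration entry m(a -> b) therefore uses the pool distance of the sink:

    m(a -> b)  proportional to  (1 / D_b - 1) / 4,   D_b = G_ST(b, pool)

(the standard Nm transform of G_ST). The matrix is divided by its maximum,
so entries are relative rates in [0, 1] with max exactly 1. Bootstrapping
over loci yields percentile CIs per direction; a pair is flagged
directionally asymmetric when the two 95% CIs do not overlap.
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import GenotypeMatrix, LocationTable, PairwiseMatrix

log = logging.getLogger(__name__)


def _freq_and_n(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = np.sum(~np.isnan(calls), axis=0).astype(float)
    with np.errstate(invalid="ignore"):
        p = np.nansum(calls, axis=0) / (2.0 * n)
    return p, n


def nei_gst_per_locus(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Per-locus Nei G_ST between two frequency arrays (equal weight)."""
    hs = 0.5 * (2 * p1 * (1 - p1) + 2 * p2 * (1 - p2))
    pbar = 0.5 * (p1 + p2)
    ht = 2 * pbar * (1 - pbar)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(ht > 0, (ht - hs) / ht, np.nan)


def _gst_multi(p1, p2, idx=None) -> float:
    """Multi-locus G_ST as ratio of locus sums (optionally on a resample)."""
    hs = 0.5 * (2 * p1 * (1 - p1) + 2 * p2 * (1 - p2))
    pbar = 0.5 * (p1 + p2)
    ht = 2 * pbar * (1 - pbar)
    if idx is not None:
        hs, ht = hs[idx], ht[idx]
    denom = np.nansum(ht)
    if denom == 0:
        return np.nan
    return float((np.nansum(ht) - np.nansum(hs)) / denom)


def _nm_from_gst(gst: float) -> float:
    """Wright's island-model transform Nm = (1/G_ST - 1)/4."""
    if not np.isfinite(gst):
        return np.nan
    if gst <= 0:
        return np.inf
    return (1.0 / gst - 1.0) / 4.0


def relative_migration(
    gm: GenotypeMatrix,
    loc: LocationTable,
    n_boot: int = 1000,
    seed: int = 0,
    min_samples: int = 8,
    weighted_pool: bool = False,
    ci_level: float = 0.95,
) -> PairwiseMatrix:
    """Relative directional migration matrix (row = source, column = sink).

    Entries are normalized to a maximum of exactly 1. ``meta`` carries the
    per-direction bootstrap CIs and the per-pair asymmetry verdicts.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    labels = loc.location_of(gm)
    groups = {}
    for lid in dict.fromkeys(labels):
        calls = gm.calls[np.flatnonzero(labels == lid)]
        if len(calls) >= min_samples:
            groups[lid] = _freq_and_n(calls)
    ids = list(groups)
    if len(ids) < 2:
        raise ValueError("fewer than 2 locations pass the inclusion rule")
    k = len(ids)
    raw = np.full((k, k), np.nan)
    ci = {}
    L = gm.n_loci
    boot_idx = rng.integers(0, L, size=(n_boot, L))
    for ai in range(k):
        for bi in range(ai + 1, k):
            (pa, na), (pb, nb) = groups[ids[ai]], groups[ids[bi]]
            if weighted_pool:
                with np.errstate(invalid="ignore"):
                    pool = (na * pa + nb * pb) / (na + nb)
            else:
                pool = 0.5 * (pa + pb)
            d_a = _gst_multi(pa, pool)
            d_b = _gst_multi(pb, pool)
            m_into_b = _nm_from_gst(d_b)  # a -> b: sink is b
            m_into_a = _nm_from_gst(d_a)  # b -> a: sink is a
            raw[ai, bi] = m_into_b
            raw[bi, ai] = m_into_a
            boots_ab = np.array(
                [_nm_from_gst(_gst_multi(pb, pool, idx)) for idx in boot_idx]
            )
            boots_ba = np.array(
                [_nm_from_gst(_gst_multi(pa, pool, idx)) for idx in boot_idx]
            )
            lo = 100 * (1 - ci_level) / 2
            ci[(ids[ai], ids[bi])] = {
                "a_to_b": tuple(np.nanpercentile(boots_ab, [lo, 100 - lo])),
                "b_to_a": tuple(np.nanpercentile(boots_ba, [lo, 100 - lo])),
            }
    if np.isinf(raw).any():
        # zero differentiation from the pool: cap at the largest finite
        # entry (or 1 if none) so normalization stays defined
        log.warning("relative_migration: zero differentiation; entries set to max")
        finite_vals = raw[np.isfinite(raw)]
        cap = finite_vals.max() if finite_vals.size else 1.0
        raw[np.isinf(raw)] = cap
    mmax = np.nanmax(raw)
    m_rel = raw / mmax if mmax > 0 else raw
    scale = mmax if mmax > 0 else 1.0
    asym = {}
    for (a, b), c in ci.items():
        lo1, hi1 = c["a_to_b"]
        lo2, hi2 = c["b_to_a"]
        asym[(a, b)] = bool(hi1 < lo2 or hi2 < lo1)
        ci[(a, b)] = {
            "a_to_b": (lo1 / scale, hi1 / scale),
            "b_to_a": (lo2 / scale, hi2 / scale),
        }
    return PairwiseMatrix(
        ids, m_rel, "relative_migration", symmetric=False,
        meta={"ci": ci, "asymmetric": asym, "n_boot": n_boot, "seed": seed,
              "ci_level": ci_level},
    )


def to_dot(pm: PairwiseMatrix, threshold: float = 0.0) -> str:
    """DOT-format digraph of the migration matrix (edges above threshold)."""
    lines = ["digraph migration {"]
    for i, a in enumerate(pm.location_ids):
        for j, b in enumerate(pm.location_ids):
            v = pm.values[i, j]
            if i != j and np.isfinite(v) and v > threshold:
                lines.append(f'  "{a}" -> "{b}" [label="{v:.3f}"];')
    lines.append("}")
    return "\n".join(lines)
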