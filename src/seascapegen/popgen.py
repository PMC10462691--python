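"""Diversity and differentiation statistics with resampling significance.

Per-location diversity: rarefied allelic richness (A_R), observed and
unbiased expected heterozygosity (H_O, H_E), and the inbreeding coefficient
F_IS = 1 - H_O/H_E. Differentiation: Weir & Cockerham's theta (variance
components a, b, c; multi-locus value is the ratio of sums) and Jost's D
with Nei–Chesser sample-size-corrected heterozygosities. Pairwise matrices
get one-sided locus-bootstrap p-values and Benjamini–Hochberg adjustment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .containers import GenotypeMatrix, LocationTable, PairwiseMatrix

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# helpers

def _pop_calls(gm: GenotypeMatrix, loc: LocationTable) -> dict:
    """Mapping location_id -> genotype sub-array (rows of that location)."""
    labels = loc.location_of(gm)
    return {
        lid: gm.calls[np.flatnonzero(labels == lid)]
        for lid in dict.fromkeys(labels)
    }


def _allele_counts(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(alt-allele count, total gene copies) per locus for one population."""
    alt = np.nansum(calls, axis=0)
    copies = 2.0 * np.sum(~np.isnan(calls), axis=0)
    return alt, copies


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, in [p, 1])."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# diversity

def _log_comb(n: np.ndarray, k: float) -> np.ndarray:
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def _rarefied_richness(alt: np.ndarray, copies: np.ndarray, g: int) -> np.ndarray:
    """Expected allele count per locus in a hypergeometric draw of g copies."""
    a = np.stack([alt, copies - alt])  # counts of the two alleles
    with np.errstate(invalid="ignore"):
        # P(allele absent from the draw) = C(copies - count, g) / C(copies, g)
        log_p_absent = _log_comb(copies - a, g) - _log_comb(copies, g)
        p_absent = np.where(copies - a >= g, np.exp(log_p_absent), 0.0)
        present = np.where(a > 0, 1.0 - p_absent, 0.0)
    return present.sum(axis=0)


@dataclass
class DiversityTable:
    table: pd.DataFrame  # index location_id; columns n, A_R, H_O, H_E, F_IS

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="location_id")


def diversity(
    gm: GenotypeMatrix,
    loc: LocationTable,
    rarefaction_g: int | None = None,
) -> DiversityTable:
    """Per-location diversity indices over all loci.

    ``rarefaction_g`` is the number of gene copies drawn for allelic
    richness; default is twice the smallest per-location sample count (the
    smallest complete-data standard draw).
    """
    pops = _pop_calls(gm, loc)
    pops = {k: v for k, v in pops.items() if len(v) > 0}
    if rarefaction_g is None:
        rarefaction_g = 2 * min(len(v) for v in pops.values())
    rows = []
    for lid, calls in pops.items():
        alt, copies = _allele_counts(calls)
        usable = copies >= rarefaction_g
        if not usable.all():
            log.warning(
                "diversity: %d loci at %s have < g copies; excluded from A_R",
                int((~usable).sum()), lid,
            )
        ar = _rarefied_richness(alt[usable], copies[usable], rarefaction_g).mean()
        with np.errstate(invalid="ignore"):
            ho_locus = np.nanmean(calls == 1.0, axis=0)
            p = np.divide(alt, copies, out=np.full_like(alt, np.nan), where=copies > 0)
            n2 = copies
            he_locus = 2.0 * p * (1.0 - p) * np.divide(
                n2, n2 - 1.0, out=np.full_like(n2, np.nan), where=n2 > 1
            )
        ho = float(np.nanmean(ho_locus))
        he = float(np.nanmean(he_locus))
        fis = 0.0 if he == 0 else 1.0 - ho / he
        rows.append((lid, len(calls), ar, ho, he, fis))
    table = pd.DataFrame(
        rows, columns=["location_id", "n", "A_R", "H_O", "H_E", "F_IS"]
    ).set_index("location_id")
    return DiversityTable(table)


# ---------------------------------------------------------------------------
# Weir & Cockerham theta

def wc_components(
    gm: GenotypeMatrix, loc: LocationTable, pops: list | None = None
) -> np.ndarray:
    """Per-locus WC (1984) variance components; shape (n_loci, 3) = (a, b, c).

    Loci where no population has data get nan components.
    """
    groups = _pop_calls(gm, loc)
    if pops is not None:
        groups = {k: groups[k] for k in pops}
    if len(groups) < 2:
        raise ValueError("need >= 2 populations")
    # per-pop per-locus: sample size n_i, alt frequency p_i, het fraction h_i
    ns, ps, hs = [], [], []
    for calls in groups.values():
        n_i = np.sum(~np.isnan(calls), axis=0).astype(float)
        with np.errstate(invalid="ignore"):
            p_i = np.nansum(calls, axis=0) / (2.0 * n_i)
            h_i = np.nansum(calls == 1.0, axis=0) / n_i
        ns.append(n_i)
        ps.append(p_i)
        hs.append(h_i)
    n = np.stack(ns)  # (r, L)
    p = np.stack(ps)
    h = np.stack(hs)
    valid = n >= 1
    r = valid.sum(axis=0).astype(float)  # populations with data per locus
    n = np.where(valid, n, 0.0)
    p = np.where(valid, np.nan_to_num(p), 0.0)
    h = np.where(valid, np.nan_to_num(h), 0.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = n.sum(axis=0) / r
        nc = (n.sum(axis=0) - (n**2).sum(axis=0) / n.sum(axis=0)) / (r - 1.0)
        pbar = (n * p).sum(axis=0) / (r * nbar)
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1.0) * nbar)
        hbar = (n * h).sum(axis=0) / (r * nbar)
        inner = pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0
        a = nbar / nc * (s2 - inner / (nbar - 1.0))
        b = nbar / (nbar - 1.0) * (
            pbar * (1 - pbar)
            - (r - 1.0) / r * s2
            - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
    comps = np.stack([a, b, c], axis=1)
    comps[(r < 2) | ~np.isfinite(nbar) | (nbar <= 1)] = np.nan
    return comps


def wc_fst(
    gm: GenotypeMatrix, loc: LocationTable, pops: list | None = None
) -> float:
    """Multi-locus Weir–Cockerham theta: sum(a) / sum(a + b + c)."""
    comps = wc_components(gm, loc, pops)
    ok = np.isfinite(comps).all(axis=1)
    denom = comps[ok].sum(axis=1)
    usable = ok.copy()
    usable[ok] = denom != 0
    if not usable.any():
        raise ValueError("theta undefined: no locus with nonzero denominator")
    comps = comps[usable]
    return float(comps[:, 0].sum() / comps.sum())


# ---------------------------------------------------------------------------
# Jost's D (Nei–Chesser corrected)

def jost_d_components(
    gm: GenotypeMatrix, loc: LocationTable, pops: list | None = None
) -> np.ndarray:
    """Per-locus Jost's D using Nei–Chesser estimators of H_S and H_T.

    Loci with undefined or degenerate (H_S = 1) estimators get nan.
    """
    groups = _pop_calls(gm, loc)
    if pops is not None:
        groups = {k: groups[k] for k in pops}
    k = len(groups)
    if k < 2:
        raise ValueError("need >= 2 populations")
    ns, ps, hos = [], [], []
    for calls in groups.values():
        n_i = np.sum(~np.isnan(calls), axis=0).astype(float)
        with np.errstate(invalid="ignore"):
            p_i = np.nansum(calls, axis=0) / (2.0 * n_i)
            ho_i = np.nansum(calls == 1.0, axis=0) / n_i
        ns.append(n_i)
        ps.append(p_i)
        hos.append(ho_i)
    n = np.stack(ns)
    p = np.stack(ps)
    ho = np.stack(hos)
    with np.errstate(invalid="ignore", divide="ignore"):
        ntilde = k / (1.0 / n).sum(axis=0)  # harmonic mean sample size
        sum_p2 = (p**2 + (1 - p) ** 2).mean(axis=0)
        ho_bar = ho.mean(axis=0)
        hs = ntilde / (ntilde - 1.0) * (1.0 - sum_p2 - ho_bar / (2.0 * ntilde))
        pbar = p.mean(axis=0)
        ht = (
            1.0
            - (pbar**2 + (1 - pbar) ** 2)
            + hs / (ntilde * k)
            - ho_bar / (2.0 * ntilde * k)
        )
        d = (k / (k - 1.0)) * (ht - hs) / (1.0 - hs)
    bad = ~np.isfinite(d)
    if bad.any():
        log.warning("jost_d: %d loci skipped (degenerate H_S)", int(bad.sum()))
    return d


def jost_d(
    gm: GenotypeMatrix,
    loc: LocationTable,
    pops: list | None = None,
    aggregate: str = "arithmetic",
) -> float:
    """Multi-locus Jost's D; arithmetic mean over loci by default.

    ``aggregate='harmonic'`` gives the harmonic-mean variant (positive loci
    only), provided because usage differs between packages.
    """
    d = jost_d_components(gm, loc, pops)
    d = d[np.isfinite(d)]
    if d.size == 0:
        raise ValueError("Jost's D undefined: no usable locus")
    if aggregate == "arithmetic":
        return float(d.mean())
    if aggregate == "harmonic":
        pos = d[d > 0]
        if pos.size == 0:
            return 0.0
        return float(pos.size / (1.0 / pos).sum())
    raise ValueError(f"unknown aggregate {aggregate!r}")


# ---------------------------------------------------------------------------
# pairwise matrices with bootstrap significance

def pairwise_with_bootstrap(
    gm: GenotypeMatrix,
    loc: LocationTable,
    statistic: str = "fst",
    n_boot: int = 1000,
    seed: int = 0,
    min_samples: int = 8,
    alternative: str = "greater",
) -> PairwiseMatrix:
    """Pairwise FST or Jost's D with locus-bootstrap p-values and BH FDR.

    Only locations with >= ``min_samples`` genotyped individuals enter. The
    p-value per pair is the +1-corrected fraction of locus-bootstrap
    replicates whose multi-locus statistic is <= 0 (one-sided test of
    differentiation > 0); ``alternative='two-sided'`` doubles it (capped at
    1). Adjustment is Benjamini–Hochberg over all pairs.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if statistic not in ("fst", "jost_d"):
        raise ValueError("statistic must be 'fst' or 'jost_d'")
    rng = np.random.default_rng(seed)
    labels = loc.location_of(gm)
    counts = pd.Series(labels).value_counts()
    keep = [l for l in dict.fromkeys(labels) if counts[l] >= min_samples]
    if len(keep) < 2:
        raise ValueError("fewer than 2 locations pass the inclusion rule")
    k = len(keep)
    values = np.zeros((k, k))
    p_values = np.full((k, k), np.nan)
    for ai in range(k):
        for bi in range(ai + 1, k):
            pair = [keep[ai], keep[bi]]
            if statistic == "fst":
                comps = wc_components(gm, loc, pair)
                ok = np.isfinite(comps).all(axis=1) & (comps.sum(axis=1) != 0)
                comps = comps[ok]
                point = comps[:, 0].sum() / comps.sum()
                idx = rng.integers(0, len(comps), size=(n_boot, len(comps)))
                a_sum = comps[:, 0][idx].sum(axis=1)
                tot = comps.sum(axis=1)[idx].sum(axis=1)
                boots = np.divide(a_sum, tot, out=np.zeros(n_boot), where=tot != 0)
            else:
                d = jost_d_components(gm, loc, pair)
                d = d[np.isfinite(d)]
                point = d.mean()
                idx = rng.integers(0, d.size, size=(n_boot, d.size))
                boots = d[idx].mean(axis=1)
            p = (1.0 + np.sum(boots <= 0.0)) / (n_boot + 1.0)
            if alternative == "two-sided":
                p = min(1.0, 2.0 * p)
            values[ai, bi] = values[bi, ai] = point
            p_values[ai, bi] = p_values[bi, ai] = p
    iu = np.triu_indices(k, 1)
    p_adj_flat = bh_adjust(p_values[iu])
    p_adjusted = np.full((k, k), np.nan)
    p_adjusted[iu] = p_adj_flat
    p_adjusted.T[iu] = p_adj_flat
    name = "F_ST" if statistic == "fst" else "D_ST"
    return PairwiseMatrix(
        keep, values, name, True, p_values, p_adjusted,
        meta={"n_boot": n_boot, "seed": seed, "alternative": alternative},
    )


def linearize(fst_value: float) -> float:
    """Rousset's linearized genetic distance FST / (1 - FST).

    Negative estimates are clamped to 0 first; FST = 1 returns inf with a
    warning (a fixed pair has no finite linearized distance).
    """
    if fst_value >= 1.0:
        warnings.warn("linearize: FST >= 1, returning inf")
        return np.inf
    f = max(0.0, float(fst_value))
    return f / (1.0 - f)


def linearize_matrix(pm: PairwiseMatrix) -> PairwiseMatrix:
    vals = np.vectorize(linearize)(pm.values).astype(float)
    np.fill_diagonal(vals, 0.0)
    return PairwiseMatrix(
        list(pm.location_ids), vals, f"{pm.statistic_name}/(1-{pm.statistic_name})",
        True, meta=dict(pm.meta),
    )
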