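"""Outlier-locus scans and construction of the neutral SNP set.

Two independent scans flag loci putatively under selection:

* a PCA scan — Mahalanobis distance of per-locus z-scores on the top-K
  principal axes, rescaled by a genomic inflation factor, chi-squared(K)
  tail probabilities, BH q-values;
* an FST scan — per-locus Weir–Cockerham FST against a central
  chi-square-shaped null fitted to the trimmed FST distribution.

Loci flagged by BOTH scans form the consensus outlier set; removing them
yields the neutral SNP panel used by every downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix, LocationTable
from .popgen import bh_adjust, wc_components


@dataclass
class OutlierReport:
    locus_ids: list
    scores: np.ndarray
    q_values: np.ndarray
    method: str
    q_threshold: float

    @property
    def flagged(self) -> np.ndarray:
        """Boolean mask of loci at q <= threshold."""
        return np.nan_to_num(self.q_values, nan=1.0) <= self.q_threshold

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus_id": self.locus_ids,
                f"score_{self.method}": self.scores,
                f"q_{self.method}": self.q_values,
                "flagged": self.flagged,
            }
        )


def _standardized_dosage(gm: GenotypeMatrix) -> np.ndarray:
    """Mean-imputed, centred, frequency-scaled dosage matrix."""
    X = gm.calls.copy()
    p = gm.allele_freq()
    mu = 2.0 * p
    inds, locs = np.where(np.isnan(X))
    X[inds, locs] = mu[locs]
    sd = np.sqrt(np.maximum(2.0 * p * (1.0 - p), 1e-12))
    return (X - mu) / sd


def pca_outlier_scan(
    gm: GenotypeMatrix, K: int, q_threshold: float = 0.05
) -> OutlierReport:
    """Flag loci whose loadings on the top-K axes are outlying.

    Each locus is regressed on the K leading sample-space principal
    components; the squared norm of the resulting z-score vector is a
    Mahalanobis distance, rescaled by the genomic inflation factor
    (median distance / chi-squared(K) median) so the bulk matches the null.
    """
    if not 1 <= K < min(gm.n_samples, gm.n_loci):
        raise ValueError("K must satisfy 1 <= K < min(n_samples, n_loci)")
    Z = _standardized_dosage(gm)
    # polymorphic loci only; monomorphic ones carry no signal
    poly = Z.std(axis=0) > 0
    U, s, _ = np.linalg.svd(Z[:, poly], full_matrices=False)
    PCs = U[:, :K]  # orthonormal sample scores
    n = gm.n_samples
    scores = np.full(gm.n_loci, np.nan)
    # regression of each (unit-variance) locus on orthonormal PCs:
    # beta_k = PC_k . locus ; residual variance per locus
    B = PCs.T @ Z  # (K, n_loci)
    resid = Z - PCs @ B
    dof = max(n - K - 1, 1)
    sigma2 = (resid**2).sum(axis=0) / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        z2 = (B**2) / sigma2
    d = z2.sum(axis=0)
    d[~poly] = np.nan
    med = np.nanmedian(d)
    gif = med / stats.chi2.median(K) if med > 0 else 1.0
    d_scaled = d / gif
    p = stats.chi2.sf(d_scaled, K)
    q = np.full(gm.n_loci, np.nan)
    ok = np.isfinite(p)
    q[ok] = bh_adjust(p[ok])
    return OutlierReport(list(gm.locus_ids), d_scaled, q, "pca", q_threshold)


def _trimmed_mean_chi2_unit(df: float, trim: float) -> float:
    """Trimmed mean of chi2(df)/df between its trim and 1-trim quantiles."""
    lo, hi = stats.chi2.ppf([trim, 1.0 - trim], df)
    # E[X | lo < X < hi] for X ~ chi2(df): integrate via the df+2 identity
    mass = stats.chi2.cdf(hi, df) - stats.chi2.cdf(lo, df)
    part = df * (stats.chi2.cdf(hi, df + 2) - stats.chi2.cdf(lo, df + 2))
    return (part / mass) / df


def fst_outlier_scan(
    gm: GenotypeMatrix,
    loc: LocationTable,
    q_threshold: float = 0.05,
    trim_fraction: float = 0.05,
) -> OutlierReport:
    """Flag high-FST loci against a trimmed central chi-square null.

    The null models locus FST as mu * chi2(df)/df with df = (#demes - 1);
    mu is fitted by matching the trimmed mean of the observed FST
    distribution (``trim_fraction`` clipped from each tail), so selected
    outliers do not inflate the null.
    """
    labels = loc.location_of(gm)
    n_demes = len(dict.fromkeys(labels))
    if n_demes < 2:
        raise ValueError("need >= 2 demes")
    comps = wc_components(gm, loc)
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = comps.sum(axis=1)
        fst = np.where(denom != 0, comps[:, 0] / denom, np.nan)
    usable = np.isfinite(fst)
    if usable.sum() < 20:
        raise ValueError("fewer than 20 usable loci: null unestimable")
    vals = np.sort(fst[usable])
    k = int(np.floor(trim_fraction * vals.size))
    trimmed = vals[k: vals.size - k] if k > 0 else vals
    df = float(n_demes - 1)
    mu = trimmed.mean() / _trimmed_mean_chi2_unit(df, trim_fraction)
    if mu <= 0 or np.ptp(vals) == 0:
        # all-equal or non-positive bulk: degenerate null, nothing flagged
        q = np.where(usable, 1.0, np.nan)
        return OutlierReport(list(gm.locus_ids), fst, q, "fst", q_threshold)
    p = stats.chi2.sf(fst * df / mu, df)
    q = np.full(gm.n_loci, np.nan)
    q[usable] = bh_adjust(p[usable])
    return OutlierReport(list(gm.locus_ids), fst, q, "fst", q_threshold)


def consensus_neutral_set(
    gm: GenotypeMatrix, report_a: OutlierReport, report_b: OutlierReport
) -> tuple[GenotypeMatrix, list]:
    """Remove loci flagged by BOTH scans; returns (neutral panel, removed ids)."""
    if report_a.locus_ids != list(gm.locus_ids) or report_b.locus_ids != list(
        gm.locus_ids
    ):
        raise ValueError("outlier reports were not computed on this locus set")
    both = report_a.flagged & report_b.flagged
    removed = [gm.locus_ids[j] for j in np.flatnonzero(both)]
    neutral = gm.take_loci(np.flatnonzero(~both))
    return neutral, removed


def choose_k_broken_stick(gm: GenotypeMatrix, k_max: int = 20) -> int:
    """Scree choice of K: largest K whose axis variance beats broken-stick."""
    Z = _standardized_dosage(gm)
    poly = Z.std(axis=0) > 0
    s = np.linalg.svd(Z[:, poly], compute_uv=False)
    var = s**2 / (s**2).sum()
    m = min(len(var), k_max)
    bstick = np.array([np.sum(1.0 / np.arange(i + 1, m + 1)) / m for i in range(m)])
    above = var[:m] > bstick
    k = 0
    for a in above:
        if a:
            k += 1
        else:
            break
    return max(k, 1)
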