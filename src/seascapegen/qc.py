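"""Quality control of SNP genotype matrices.

Filter steps run in a fixed order so QC reports are comparable across runs:
sample call rate -> locus call rate -> minor allele frequency -> one SNP per
sequence tag -> monomorphic removal. Duplicate-sample detection and
sex-linked-locus detection are separate screens whose removal decisions are
left to the caller.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .containers import GenotypeMatrix, LocationTable
from .io import EmptyInputError

log = logging.getLogger(__name__)


@dataclass
class QCReport:
    """Counts removed at each filter step, in execution order."""

    steps: list = field(default_factory=list)  # (step name, n removed)
    n_samples_in: int = 0
    n_loci_in: int = 0
    n_samples_out: int = 0
    n_loci_out: int = 0

    def to_dict(self) -> dict:
        return {
            "n_samples_in": self.n_samples_in,
            "n_loci_in": self.n_loci_in,
            "n_samples_out": self.n_samples_out,
            "n_loci_out": self.n_loci_out,
            "steps": [{"step": s, "removed": n} for s, n in self.steps],
        }


def minor_allele_freq(gm: GenotypeMatrix) -> np.ndarray:
    p = gm.allele_freq()
    return np.minimum(p, 1.0 - p)


def qc_filter(
    gm: GenotypeMatrix,
    min_locus_call_rate: float = 0.9,
    min_sample_call_rate: float = 0.8,
    min_maf: float = 0.01,
    one_per_tag: bool = True,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the standard genotype QC cascade; returns (filtered, report).

    ``one_per_tag`` keeps, for each sequence tag, the locus with the highest
    call rate (ties broken by file order); loci that end up monomorphic are
    dropped last. Raises :class:`EmptyInputError` (report attached as
    ``.report``) if nothing survives.
    """
    for thr in (min_locus_call_rate, min_sample_call_rate, min_maf):
        if not 0.0 <= thr <= 1.0:
            raise ValueError("QC thresholds must lie in [0, 1]")
    rep = QCReport(n_samples_in=gm.n_samples, n_loci_in=gm.n_loci)

    keep_s = gm.sample_call_rate >= min_sample_call_rate
    rep.steps.append(("sample_call_rate", int((~keep_s).sum())))
    gm = gm.take_samples(np.flatnonzero(keep_s))

    keep_l = gm.locus_call_rate >= min_locus_call_rate
    rep.steps.append(("locus_call_rate", int((~keep_l).sum())))
    gm = gm.take_loci(np.flatnonzero(keep_l))

    maf = minor_allele_freq(gm)
    keep_l = np.nan_to_num(maf, nan=0.0) >= min_maf
    rep.steps.append(("maf", int((~keep_l).sum())))
    gm = gm.take_loci(np.flatnonzero(keep_l))

    if one_per_tag and gm.tag_ids is not None:
        cr = gm.locus_call_rate
        best: dict = {}
        for j, tag in enumerate(gm.tag_ids):
            if tag not in best or cr[j] > cr[best[tag]]:
                best.setdefault(tag, j)
                if cr[j] > cr[best[tag]]:
                    best[tag] = j
        keep = sorted(best.values())
        rep.steps.append(("one_per_tag", gm.n_loci - len(keep)))
        gm = gm.take_loci(keep)
    else:
        rep.steps.append(("one_per_tag", 0))

    maf = minor_allele_freq(gm)
    keep_l = np.nan_to_num(maf, nan=0.0) > 0.0
    rep.steps.append(("monomorphic", int((~keep_l).sum())))
    gm = gm.take_loci(np.flatnonzero(keep_l))

    rep.n_samples_out, rep.n_loci_out = gm.n_samples, gm.n_loci
    if gm.n_loci == 0 or gm.n_samples == 0:
        err = EmptyInputError("qc_filter removed all loci or samples")
        err.report = rep
        raise err
    return gm, rep


def find_duplicates(
    gm: GenotypeMatrix, identity_threshold: float = 0.95
) -> list[dict]:
    """Pairs of samples whose non-missing calls agree at >= threshold.

    For each flagged pair the member with the lower call rate is marked for
    removal (``remove`` key); on a tie the first sample in matrix order is
    retained. Recaptured/replicated individuals surface here.
    """
    if not 0.5 < identity_threshold <= 1.0:
        raise ValueError("identity_threshold must lie in (0.5, 1]")
    X = gm.calls
    cr = gm.sample_call_rate
    out = []
    for i in range(gm.n_samples):
        for j in range(i + 1, gm.n_samples):
            both = ~np.isnan(X[i]) & ~np.isnan(X[j])
            n = int(both.sum())
            if n == 0:
                continue
            ident = float((X[i, both] == X[j, both]).mean())
            if ident >= identity_threshold:
                keep, drop = (i, j) if cr[i] >= cr[j] else (j, i)
                out.append(
                    {
                        "pair": (gm.sample_ids[i], gm.sample_ids[j]),
                        "identity": ident,
                        "n_compared": n,
                        "retain": gm.sample_ids[keep],
                        "remove": gm.sample_ids[drop],
                    }
                )
    return out


def detect_sex_linked(
    gm: GenotypeMatrix,
    loc: LocationTable,
    het_margin: float = 0.2,
    presence_window: float = 0.15,
) -> list:
    """Flag putatively female-linked loci (male-heterogametic pattern).

    A locus is flagged when female heterozygosity exceeds male heterozygosity
    by more than ``het_margin`` AND the male non-missing call fraction is
    within ``presence_window`` of 50% of the female fraction — the signature
    of a locus on the female-specific chromosome region. Returns locus ids;
    removal is left to the caller.
    """
    sex = (
        loc.table.set_index("sample_id")
        .loc[gm.sample_ids, "sex"]
        .astype(str)
        .str.upper()
        .to_numpy()
    )
    fem, mal = sex == "F", sex == "M"
    if not fem.any() or not mal.any():
        log.warning("detect_sex_linked: need both sexes; rule skipped")
        return []

    def _het(rows: np.ndarray) -> np.ndarray:
        sub = gm.calls[rows]
        with np.errstate(invalid="ignore"):
            return np.nanmean(sub == 1.0, axis=0)

    def _presence(rows: np.ndarray) -> np.ndarray:
        return 1.0 - np.isnan(gm.calls[rows]).mean(axis=0)

    het_f, het_m = _het(fem), _het(mal)
    pres_f, pres_m = _presence(fem), _presence(mal)
    with np.errstate(invalid="ignore"):
        het_gap = np.nan_to_num(het_f, nan=0.0) - np.nan_to_num(het_m, nan=0.0)
        ratio = np.divide(pres_m, pres_f, out=np.ones_like(pres_m), where=pres_f > 0)
    flagged = (het_gap > het_margin) & (np.abs(ratio - 0.5) <= presence_window)
    return [gm.locus_ids[j] for j in np.flatnonzero(flagged)]


def balanced_subsample(
    gm: GenotypeMatrix, loc: LocationTable, cap: int, seed: int
) -> tuple[GenotypeMatrix, LocationTable]:
    """Cap per-location sample counts by uniform draws without replacement.

    Locations at or below ``cap`` are kept whole; reproducible for a fixed
    seed. Used to counter sample-size bias in clustering.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    rng = np.random.default_rng(seed)
    labels = loc.location_of(gm)
    keep: list[int] = []
    for lid in dict.fromkeys(labels):
        idx = np.flatnonzero(labels == lid)
        if len(idx) > cap:
            idx = np.sort(rng.choice(idx, size=cap, replace=False))
        keep.extend(idx.tolist())
    keep = sorted(keep)
    sub = gm.take_samples(keep)
    return sub, loc.subset(sub.sample_ids)
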