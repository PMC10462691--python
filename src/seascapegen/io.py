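"""Readers and writers for genotypes, sample metadata, and bathymetry rasters.

Supported dialects
------------------
* Genotype CSV: samples as rows, loci as columns, header row of locus ids,
  first column ``sample_id``, missing coded ``NA``. An optional second header
  line starting with ``#tag`` gives a sequence-tag id per locus.
* VCF: biallelic SNP records only; anything multi-allelic, non-SNP, or
  symbolic is skipped and counted.
* Raster: ESRI ASCII grid (``ncols/nrows/xllcorner/yllcorner/cellsize``
  header, optional ``NODATA_value``).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import BathymetryGrid, GenotypeMatrix, LocationTable

log = logging.getLogger(__name__)


class EmptyInputError(ValueError):
    """No usable loci or samples after reading/filtering."""


def read_genotypes(path) -> GenotypeMatrix:
    """Read a genotype matrix from CSV or VCF (chosen by file extension)."""
    path = Path(path)
    if path.suffix.lower() in (".vcf", ".gz", ".bcf"):
        return read_genotypes_vcf(path)
    return read_genotypes_csv(path)


def read_genotypes_csv(path) -> GenotypeMatrix:
    path = Path(path)
    tag_ids = None
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")
        second = fh.tell()
        line2 = fh.readline()
    locus_ids = header[1:]
    skiprows = [0]
    if line2.startswith("#tag"):
        tag_ids = line2.rstrip("\n").split(",")[1:]
        if len(tag_ids) != len(locus_ids):
            raise ValueError(f"{path}: #tag line length mismatch")
        skiprows = [0, 1]
    df = pd.read_csv(
        path, skiprows=skiprows, header=None, na_values=["NA"], dtype=str
    )
    sample_ids = df.iloc[:, 0].tolist()
    try:
        calls = df.iloc[:, 1:].to_numpy(dtype=float)
    except ValueError as e:
        raise ValueError(f"{path}: non-numeric genotype entry ({e})") from e
    if calls.shape[1] != len(locus_ids):
        raise ValueError(f"{path}: row width does not match header")
    if calls.size == 0:
        raise EmptyInputError(f"{path}: zero usable loci")
    return GenotypeMatrix(sample_ids, locus_ids, calls, tag_ids)


def read_genotypes_vcf(path) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF; other records are skipped and logged."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    sample_ids = list(vcf.samples)
    locus_ids, rows, n_skipped = [], [], 0
    for var in vcf:
        alts = var.ALT
        if (
            len(alts) != 1
            or len(var.REF) != 1
            or len(alts[0]) != 1
            or alts[0] not in "ACGT"
            or var.REF not in "ACGT"
        ):
            n_skipped += 1
            continue
        gt = np.asarray(var.gt_types, dtype=float)  # 0/1/2, 3 = missing
        gt[gt == 3] = np.nan
        rows.append(gt)
        lid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        locus_ids.append(lid)
    if n_skipped:
        log.info("read_genotypes_vcf: skipped %d non-biallelic-SNP records", n_skipped)
    if not rows:
        raise EmptyInputError(f"{path}: zero usable biallelic SNP records")
    calls = np.column_stack(rows) if rows else np.empty((len(sample_ids), 0))
    gm = GenotypeMatrix(sample_ids, locus_ids, calls)
    gm_meta_skipped = n_skipped  # kept for callers via attribute below
    gm.n_skipped_records = gm_meta_skipped
    return gm


def write_genotypes_csv(gm: GenotypeMatrix, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("sample_id," + ",".join(map(str, gm.locus_ids)) + "\n")
        if gm.tag_ids is not None:
            fh.write("#tag," + ",".join(map(str, gm.tag_ids)) + "\n")
        for sid, row in zip(gm.sample_ids, gm.calls):
            vals = ["NA" if np.isnan(v) else str(int(v)) for v in row]
            fh.write(f"{sid}," + ",".join(vals) + "\n")


def read_metadata(path) -> LocationTable:
    """Read the sample metadata CSV (sample_id, location_id, lon, lat[, sex])."""
    return LocationTable(pd.read_csv(path))


def write_metadata(loc: LocationTable, path) -> None:
    loc.table.to_csv(path, index=False)


_HEADER_KEYS = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize"}


def read_raster(path) -> BathymetryGrid:
    """Read an ESRI ASCII elevation grid (metres, negative below sea level)."""
    path = Path(path)
    header: dict = {}
    data_start = 0
    with open(path) as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS | {"nodata_value"}:
            header[parts[0].lower()] = float(parts[1])
            data_start = i + 1
        else:
            break
    missing = _HEADER_KEYS - set(header)
    if missing:
        raise ValueError(f"{path}: raster header missing fields {sorted(missing)}")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    grid = np.loadtxt(lines[data_start:], dtype=float)
    grid = np.atleast_2d(grid)
    if grid.shape != (nrows, ncols):
        raise ValueError(
            f"{path}: grid shape {grid.shape} does not match header "
            f"({nrows} x {ncols})"
        )
    return BathymetryGrid(
        elevation=grid,
        origin=(header["xllcorner"], header["yllcorner"]),
        cellsize_deg=header["cellsize"],
        nodata=header.get("nodata_value", -9999.0),
    )


def write_raster(bathy: BathymetryGrid, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"ncols {bathy.n_cols}\n")
        fh.write(f"nrows {bathy.n_rows}\n")
        fh.write(f"xllcorner {float(bathy.origin[0]):.17g}\n")
        fh.write(f"yllcorner {float(bathy.origin[1]):.17g}\n")
        fh.write(f"cellsize {float(bathy.cellsize_deg):.17g}\n")
        fh.write(f"NODATA_value {float(bathy.nodata):.17g}\n")
        elev = np.where(np.isnan(bathy.elevation), bathy.nodata, bathy.elevation)
        for row in elev:
            fh.write(" ".join(f"{float(v):.17g}" for v in row) + "\n")
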