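"""Core data containers shared by every analysis stage.

The package works on four in-memory objects: a :class:`GenotypeMatrix` of
alternate-allele dosages, a :class:`LocationTable` mapping samples to sampling
locations with geographic coordinates, a :class:`BathymetryGrid` of elevations
(metres, negative below sea level), and a :class:`PairwiseMatrix` holding a
location-by-location distance or statistic, optionally with p-values.

Genotypes are stored as ``float`` arrays with ``nan`` for missing calls so that
vectorised allele-frequency arithmetic works without masked arrays; every
non-missing entry is an integer dosage in {0, 1, 2}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: kilometres per degree of latitude (spherical earth, mean radius)
KM_PER_DEG = 111.195


@dataclass
class GenotypeMatrix:
    """Diploid biallelic genotypes as alternate-allele dosage counts.

    Parameters
    ----------
    sample_ids : list of str
        Row labels, unique, order preserved from the source file.
    locus_ids : list of str
        Column labels, unique, order preserved.
    calls : ndarray of shape (n_samples, n_loci)
        Dosages in {0, 1, 2}; missing calls are ``nan``.
    tag_ids : list of str, optional
        Sequence-tag label per locus (several SNPs can share one sequenced
        tag; QC can then keep one SNP per tag).
    """

    sample_ids: list
    locus_ids: list
    calls: np.ndarray
    tag_ids: list | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.sample_ids), len(self.locus_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.locus_ids)} loci"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids are not unique")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise ValueError("locus_ids are not unique")
        if self.tag_ids is not None and len(self.tag_ids) != len(self.locus_ids):
            raise ValueError("tag_ids length does not match locus count")
        ok = np.isnan(self.calls) | np.isin(self.calls, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = np.unique(self.calls[~ok])
            raise ValueError(f"calls contain values outside {{0,1,2,missing}}: {bad}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def sample_call_rate(self) -> np.ndarray:
        """Fraction of non-missing calls per sample."""
        return 1.0 - np.isnan(self.calls).mean(axis=1)

    @property
    def locus_call_rate(self) -> np.ndarray:
        """Fraction of non-missing calls per locus."""
        return 1.0 - np.isnan(self.calls).mean(axis=0)

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per locus over non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.calls, axis=0) / 2.0

    def take_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            [self.sample_ids[i] for i in idx],
            list(self.locus_ids),
            self.calls[idx, :],
            None if self.tag_ids is None else list(self.tag_ids),
        )

    def take_loci(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            list(self.sample_ids),
            [self.locus_ids[j] for j in idx],
            self.calls[:, idx],
            None if self.tag_ids is None else [self.tag_ids[j] for j in idx],
        )


@dataclass
class LocationTable:
    """Sample metadata: location assignment, coordinates, optional sex."""

    table: pd.DataFrame

    REQUIRED = ("sample_id", "location_id", "longitude", "latitude")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"metadata table missing columns: {missing}")
        if "sex" not in self.table.columns:
            self.table = self.table.assign(sex="unknown")
        self.table = self.table.reset_index(drop=True)
        if self.table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in metadata")
        lon = self.table["longitude"].to_numpy(float)
        lat = self.table["latitude"].to_numpy(float)
        if (np.abs(lon) > 180).any() or (np.abs(lat) > 90).any():
            raise ValueError("coordinates outside geographic bounds")

    @property
    def location_ids(self) -> list:
        """Locations in order of first appearance."""
        return list(dict.fromkeys(self.table["location_id"]))

    def samples_at(self, location_id) -> list:
        t = self.table
        return list(t.loc[t["location_id"] == location_id, "sample_id"])

    def subset(self, sample_ids) -> "LocationTable":
        keep = self.table["sample_id"].isin(set(sample_ids))
        return LocationTable(self.table.loc[keep].copy())

    def location_of(self, gm: GenotypeMatrix) -> np.ndarray:
        """Location id per row of ``gm``, aligned to ``gm.sample_ids``."""
        m = dict(zip(self.table["sample_id"], self.table["location_id"]))
        try:
            return np.array([m[s] for s in gm.sample_ids], dtype=object)
        except KeyError as e:  # pragma: no cover
            raise KeyError(f"sample {e} absent from metadata") from e

    def coords_of_samples(self, gm: GenotypeMatrix) -> np.ndarray:
        """(lon, lat) per row of ``gm``."""
        t = self.table.set_index("sample_id")
        return t.loc[gm.sample_ids, ["longitude", "latitude"]].to_numpy(float)

    def location_coords(self) -> pd.DataFrame:
        """Mean coordinate per location (index = location_id)."""
        return (
            self.table.groupby("location_id", sort=False)[["longitude", "latitude"]]
            .mean()
        )


@dataclass
class BathymetryGrid:
    """Single-band elevation grid with an ESRI-ASCII-style georeference.

    ``elevation[0, 0]`` is the north-west (top-left) cell, matching raster
    file order. ``origin`` is the (longitude, latitude) of the lower-left
    corner; ``cellsize_deg`` is the cell edge in degrees. Distances are
    computed on a local equirectangular projection centred on the grid,
    adequate at archipelago scale.
    """

    elevation: np.ndarray
    origin: tuple
    cellsize_deg: float
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.elevation = np.asarray(self.elevation, dtype=float)
        if self.elevation.ndim != 2:
            raise ValueError("elevation must be 2-D")
        if self.cellsize_deg <= 0:
            raise ValueError("cellsize must be positive")

    @property
    def n_rows(self) -> int:
        return self.elevation.shape[0]

    @property
    def n_cols(self) -> int:
        return self.elevation.shape[1]

    @property
    def center_lat(self) -> float:
        return self.origin[1] + 0.5 * self.n_rows * self.cellsize_deg

    @property
    def cell_size_km(self) -> float:
        """Cell edge in km on the local equirectangular projection.

        A single isotropic value (geometric mean of the N-S and E-W cell
        edges) keeps grid moves isotropic; at |lat| < 5 deg the two differ
        by < 0.5%.
        """
        klat = KM_PER_DEG
        klon = KM_PER_DEG * np.cos(np.radians(self.center_lat))
        return float(self.cellsize_deg * np.sqrt(klat * klon))

    def is_nodata(self) -> np.ndarray:
        return np.isnan(self.elevation) | (self.elevation == self.nodata)

    def is_water(self) -> np.ndarray:
        return (~self.is_nodata()) & (self.elevation < 0)

    def lonlat_to_rowcol(self, lon: float, lat: float) -> tuple:
        """Map a coordinate to the (row, col) of the containing cell."""
        col = int(np.floor((lon - self.origin[0]) / self.cellsize_deg))
        row_from_bottom = int(np.floor((lat - self.origin[1]) / self.cellsize_deg))
        row = self.n_rows - 1 - row_from_bottom
        return row, col

    def rowcol_to_lonlat(self, row: int, col: int) -> tuple:
        """Centre coordinate of cell (row, col); inverse of the above."""
        lon = self.origin[0] + (col + 0.5) * self.cellsize_deg
        lat = self.origin[1] + (self.n_rows - row - 0.5) * self.cellsize_deg
        return lon, lat


@dataclass
class PairwiseMatrix:
    """Location x location matrix of a named statistic.

    Symmetric matrices carry a zero diagonal; directional matrices (row =
    source, column = sink) set ``symmetric=False`` and leave the diagonal
    ``nan``. Optional p-value matrices ride along.
    """

    location_ids: list
    values: np.ndarray
    statistic_name: str = ""
    symmetric: bool = True
    p_values: np.ndarray | None = None
    p_adjusted: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.location_ids)
        if self.values.shape != (k, k):
            raise ValueError("values must be square and match location_ids")
        if self.symmetric:
            finite = np.isfinite(self.values)
            both = finite & finite.T
            if not np.allclose(
                self.values[both].reshape(-1), self.values.T[both].reshape(-1)
            ):
                raise ValueError("declared symmetric but values are not")
        for p in (self.p_values, self.p_adjusted):
            if p is not None:
                p = np.asarray(p, float)
                inb = np.isfinite(p)
                if ((p[inb] < 0) | (p[inb] > 1)).any():
                    raise ValueError("p-values outside [0, 1]")

    @property
    def n(self) -> int:
        return len(self.location_ids)

    def lower_triangle(self) -> np.ndarray:
        """Vector of values below the diagonal (row-major order)."""
        i, j = np.tril_indices(self.n, k=-1)
        return self.values[i, j]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.location_ids, columns=self.location_ids
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    def align(self, location_ids) -> "PairwiseMatrix":
        """Reorder/subset to the given location list."""
        pos = {l: i for i, l in enumerate(self.location_ids)}
        idx = np.array([pos[l] for l in location_ids])
        sub = self.values[np.ix_(idx, idx)]
        return PairwiseMatrix(
            list(location_ids), sub, self.statistic_name, self.symmetric,
            None if self.p_values is None else self.p_values[np.ix_(idx, idx)],
            None if self.p_adjusted is None else self.p_adjusted[np.ix_(idx, idx)],
            dict(self.meta),
        )
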