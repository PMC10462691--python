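#!/usr/bin/env python
"""Generate the synthetic archipelago study used by the downstream scripts.

Builds a five-island bathymetry with three kinds of inter-island channels
(shallow plateau, deep trench, glacial-sea-level sills), derives the paleo
resistance matrix between one coastal sampling site per island, and draws
genotypes whose between-deme divergence follows that matrix. Everything is
written through the package's own file formats so later stages exercise the
real I/O path.
"""

import sys
from pathlib import Path

import numpy as np

from seascapegen import io
from seascapegen import resistance as res
from seascapegen import simulate as sim

OUT = Path("results/synthetic")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 7


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = sim.default_archipelago_config(seed=SEED)
    bathy = sim.make_archipelago(cfg)
    io.write_raster(bathy, OUT / "bathymetry.asc")

    coords = sim.deme_coordinates(cfg, bathy)
    paleo = res.make_paleo(bathy)
    surf = res.transform_surface(paleo, "reverse_monomolecular", 2.0, 100.0)
    pts = coords[["longitude", "latitude"]].to_numpy()
    eff = res.effective_resistance(surf, pts, list(coords.index))
    cfg.rho = float(np.median(eff.lower_triangle()))
    gm, loc = sim.simulate_genotypes(eff, cfg, coords)
    io.write_genotypes_csv(gm, OUT / "genotypes.csv")
    io.write_metadata(loc, OUT / "metadata.csv")
    eff.to_csv(OUT / "generating_paleo_resistance.csv")

    n_water = int(bathy.is_water().sum())
    n_shallow = int(((paleo.elevation == -1.0) & paleo.is_water()).sum())
    print(f"wrote {OUT}/: {bathy.n_rows}x{bathy.n_cols} grid "
          f"({n_water} water cells, {n_shallow} paleo-shallow), "
          f"{gm.n_samples} samples x {gm.n_loci} loci in "
          f"{len(coords)} demes (seed {SEED})")
    print("generating resistance matrix (paleo surface):")
    print(np.round(eff.values, 2))


if __name__ == "__main__":
    main()
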