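# seascapegen

Seascape genomics for archipelago populations of shallow-water marine
species with limited dispersal. Starting from biallelic SNP genotypes,
sampling coordinates, and a bathymetry raster, the package answers three
linked questions:

1. **How is genetic variation structured?** Pairwise Weir–Cockerham
   F<sub>ST</sub> and Jost's D with locus-bootstrap significance and FDR
   correction, spatially regularized admixture proportions with a
   cross-entropy choice of the number of source populations *K*, and
   relative directional migration between sites.
2. **What shapes connectivity — distance or depth?** Isolation-by-distance
   (shortest over-water paths) is compared against two
   isolation-by-resistance models in which ocean depth is mapped to
   dispersal resistance: one on the contemporary bathymetry, one on a
   *paleo* bathymetry in which every cell between 0 and −210 m — shallow at
   least once during late-Quaternary sea-level low stands — is clamped to
   1 m depth, re-opening historical dispersal corridors. Effective
   resistance between sites is computed by circuit theory on the water
   grid, the depth-to-resistance transformation is optimized against
   genetic distances, and the candidate models are ranked by Mantel r² and
   judged by reciprocal partial-Mantel causal modeling.
3. **How large are the isolated populations?** Contemporary effective
   population size N<sub>e</sub> by the bias-corrected linkage-
   disequilibrium method (Burrows composite r̂² with *Pcrit*
   allele-frequency screening), delete-one-individual jackknife confidence
   intervals, and a chromosome-number correction
   N<sub>e,cor</sub> = N<sub>e</sub> / (0.098 + 0.219 ln Chr).

A synthetic-data module generates archipelago rasters, genotypes whose
between-deme divergence follows a supplied resistance matrix, and
Wright–Fisher cohorts of known N<sub>e</sub>, so every stage is tested in a
closed loop without any external data.

## The models in brief

**Isolation by resistance.** The water mask of the bathymetry grid becomes
an electrical network: each water cell is a node, 8-neighbour edges carry
the mean conductance of their end cells (diagonals scaled by 1/√2), and the
distance between two sampling sites is the effective resistance between
their nodes — computed exactly from grounded sparse solves of the graph
Laplacian. Depth *d* maps to per-cell resistance through a bounded
monomolecular curve on min–max-scaled depth *x*:

    r(x) = 1 + (m − 1) · (1 − e^(−s·x)) / (1 − e^(−s))        (monomolecular)
    r(x) = 1 + m − r_mono(1 − x)                              (reverse variant)

Both anchor the shallowest water at resistance 1 and the deepest at *m*;
they differ in curvature. The shape *s* and magnitude *m* are fitted by
differential evolution, maximising Mantel r² against linearized genetic
distances F<sub>ST</sub>/(1 − F<sub>ST</sub>).

**LD effective population size.** For unlinked locus pairs the Burrows
composite disequilibrium gives r̂², whose expectation is the sampling term
E[r̂²] = 1/S + 3.19/S² plus a drift term ≈ 1/(3N<sub>e</sub>); subtracting
the former and inverting the latter (with the standard bias-corrected
quadratic) yields N<sub>e</sub>. Loci with minor allele frequency below
*Pcrit* ∈ (1/(2S), 1/S] are screened out first.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (about three minutes in total):

```
python analysis/01_simulate_study.py      # archipelago + genotypes
python analysis/02_quality_control.py     # QC cascade + neutral panel
python analysis/03_population_structure.py
python analysis/04_isolation_by_depth.py  # the model comparison
python analysis/05_effective_population_size.py
```

`04_isolation_by_depth.py` prints, for a study whose genotypes were
generated from the paleo resistance surface:

```
           model        r       r2     p  supported
       IBR_paleo 0.986815 0.973803 0.009       True
IBR_contemporary 0.950341 0.903147 0.017      False
             IBD 0.574797 0.330391 0.048      False
ranking by Mantel r^2: IBR_paleo > IBR_contemporary > IBD
causal modeling supports: ['IBR_paleo']
```

i.e. all three models correlate with genetic distance, but accounting for
depth improves the fit and accounting for historical sea level recovers the
generating model — the ranking the method is designed to detect, and only
the paleo model survives the reciprocal partial-Mantel tests.
`05_effective_population_size.py` ends with the reference chromosome-
corrected estimates:

```
  espanola: raw 342.9 -> corrected 358
  floreana: raw 1641.0 -> corrected 1711
  west: raw 7415.3 -> corrected 7732
```

A `seascapegen` command-line interface (subcommands `simulate`, `qc`,
`structure`, `resistance`, `ne`, `run`) drives the same pipeline from a
YAML config; `seascapegen ne --r2 0.0213 -S 107 --chromosomes 51` computes
an estimate directly from a precomputed mean r̂².

## Layout

```
src/seascapegen/     the library: io, qc, popgen, outliers, admixture,
                     migration, resistance, ne, simulate, study, pipeline, cli
analysis/            numbered narrative drivers over the library
scripts/acceptance.py
tests/               pytest suite (unit, property, and acceptance tests)
docs/methods.md      modelling assumptions, parameter choices, limitations
```
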