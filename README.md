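# clawmorph

Avian claw-shape analysis as a tested, reusable pipeline: the traditional
inscribed-circle arc protocol, geometric morphometrics of an 83-point
bony-core/keratinous-sheath landmark scheme (GPA with bending-energy
sliding of semilandmarks), and the phylogenetic comparative statistics used
to test ecology, allometry, phylogenetic signal, modularity, and
integration — exercised end to end on synthetic claw data with known
ground truth.

## Modules

| module | contents |
| --- | --- |
| `clawmorph.data` | domain types (`ClawConfiguration`, `LandmarkPartition`, `Phylogeny`, `MetadataTable`), TPS/Newick/CSV I/O, tree pruning, species means |
| `clawmorph.arcs` | seven-point protocol: circle fitting, subtended arcs, arc-length ratio |
| `clawmorph.superimpose` | centroid size, Generalized Procrustes Analysis, TPS bending-energy matrix, semilandmark sliding |
| `clawmorph.shapestats` | shape PCA, common allometric component, Procrustes-variance disparity |
| `clawmorph.phylo` | phylogenetic covariance & Pagel's λ, PGLS with ML λ, simulation-based phylogenetic ANOVA, K_mult, GLS Procrustes ANOVA (RRPP), evolutionary covariance, covariance-ratio modularity, phylogenetic two-block PLS + effect-size comparison, phylogenetic paired t |
| `clawmorph.synth` | parametric claw outlines with exact ground truth, pure-birth trees, Brownian-motion trait simulation, full study scenarios |
| `clawmorph.pipeline` / `clawmorph.cli` | end-to-end workflow and the `clawmorph` command |

## CLI

```sh
# synthetic dataset (TPS + metadata CSV + Newick + truth JSON)
clawmorph simulate --seed 1 --out out/sim --n-species 30

# traditional arc measurements for every TPS record
clawmorph measure out/sim/claws.tps --out out/metrics.csv

# GPA with semilandmark sliding
clawmorph gpa out/sim/claws.tps --out out/aligned.csv --slide --outer-iters 3

# statistics on real or simulated data
clawmorph analyze --tps out/sim/claws.tps --tree out/sim/tree.nwk \
    --metadata out/sim/metadata.csv --out out/analysis --n-perm 999 --seed 1

# full simulate -> measure -> GPA -> analyze workflow
clawmorph report --seed 1 --out out/run
```

`analyze`/`report` accept `--config config.json` mirroring
`clawmorph.pipeline.RunConfig` (scenario parameters, permutation counts,
test selection, sliding options). All randomness flows from `--seed`; the
JSON report records every stage seed and is byte-identical for a fixed
config + seed.

## Data formats

- **TPS** — both flat `LM=83` records and `LM=6` + `CURVES=4`/`POINTS=`
  records (curves in SL1..SL4 order); `SCALE=` applied multiplicatively,
  `ID=`/`IMAGE=` used as the specimen id. Canonical point order: LM1–LM6,
  then SL1 (13, dorsal bony core), SL2 (18, ventral bony core), SL3 (28,
  dorsal keratinous sheath), SL4 (18, ventral keratinous sheath).
- **Newick** — rooted trees with branch lengths (dendropy-backed);
  polytomies allowed, duplicate tips rejected.
- **Metadata CSV** — columns `specimen_id, species, ecology` with ecology
  in `{predatory, ground, flying, unknown}`.
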