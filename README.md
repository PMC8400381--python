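# ralogic

Integrative signed-network construction and executable Boolean modelling of
the transcription-factor regulators of anti-TNF treatment response in
rheumatoid arthritis.

The package builds a global regulatory network by fusing a TF co-regulatory
network with a mechanistic signalling network, projects differential
expression and disease-variant evidence onto it, extracts an executable
subnetwork, and analyses its Boolean dynamics: exhaustive fixed-point
enumeration, asynchronous attractor classification, virtual knock-outs,
stochastic dose–response / sensitivity simulation, fixed-point-preserving
model reduction, and reconstruction of monotone logical rules from
stable-state constraint tables.

## Layout

| module | contents |
| --- | --- |
| `ralogic.netio` | SIF / bnet / TSV-overlay / JSON-graph readers and writers; `SignedNetwork`, `LogicalModel` |
| `ralogic.expr` | Boolean expression trees, `&`/`|`/`!` parser, numpy-compilable evaluation |
| `ralogic.integrate` | symbol normalisation, complex expansion, entity deduplication, TF matching, network merging, seeded subnetwork extraction, DEG/variant overlay projection |
| `ralogic.logic` | rule inference from signed topology, clamping perturbations, exhaustive stable-state enumeration (≤ 24 free variables), asynchronous attractors (≤ 16), model reduction, constraint-based rule reconstruction |
| `ralogic.simulate` | stochastic activity simulation with per-step input dosing, dose–response curves, two-input sensitivity grids |
| `ralogic.ra_fixture` | packaged 13-variable subnetwork (`TNF`, `IL6`, `TGFB1`, `JUN`, `FOS`, `JUND`, `NFKBIA`, `DAXX`, `ILK`, `NFKB1`, `MAP2K1`, `MAPK1`, `MAPK14`), its four stable-state constraint tables (wild type + three knock-out contexts with TNF blocked), and the reconstructed model satisfying all of them |
| `ralogic.synthetic_data` | seeded generators for co-regulatory / signalling networks, DEG and variant tables, and random Boolean models used as engine oracles |
| `ralogic.pipeline` / `ralogic.cli` | end-to-end orchestration with deterministic artifacts and the `ralogic` command line |

The constraint tables are shipped as plain text under `src/ralogic/data/`
(`ra_subnetwork.sif`, `ra_model.bnet`, `ra_tables.tsv`). The packaged rule
set was reconstructed from the tables with
`ralogic.logic.solve_rules_from_constraints` and can be regenerated with
`ralogic.ra_fixture.solve_ra_model()`; `verify_fixture()` re-checks every
table row by exhaustive enumeration.

Not reproducible at desk scale (documented, untested): the original
614-node/1736-edge global network, the 244-node upstream network, the
38-node/59-edge and 23-node model variants, and the numeric dose–response
curves — these depend on external expression/variant datasets or exist only
as figures. The packaged fixture covers the 13 species whose stable states
are machine-verifiable.

## CLI

```sh
ralogic synth --preset paperlike --seed 7 -o data/        # synthetic inputs
ralogic merge --coreg data/coreg.sif --map data/map.sif -o global.sif
ralogic overlay --net global.sif --deg data/deg.tsv --fdr 0.1 \
    --variants data/variants.tsv --vda 0.7 --ei 0.7 -o overlay.json
ralogic extract --net global.sif --mode downstream-to-tf \
    --seeds TNF,IL6,TGFB1 --tfs tfs.txt -o sub.sif
ralogic rules --sif sub.sif -o model.bnet
ralogic stablestates --model model.bnet --ko MAPK14,MAPK1 --clamp TNF=0
ralogic reduce --model model.bnet --drop MAP2K1,MAPK1
ralogic simulate --model model.bnet --dose IL6=1.0 --ko ILK,MAP2K1,DAXX \
    --steps 2000 --runs 50 --seed 17 -o activity.tsv
ralogic doseresponse --model model.bnet --vary TGFB1 --base TNF=0,IL6=0 \
    --grid 0:1:0.1 -o curve.tsv
ralogic fixture --verify                                   # check packaged model
ralogic run --fixture -o out/                              # end-to-end, fixture mode
ralogic run --config config.yaml -o out/                   # end-to-end, synthetic
```

`ralogic run` writes `global.sif`, `overlay.json`, `subnetwork.sif`,
`model.bnet`, `states.tsv`, `activity.tsv` and a `manifest.json` with all
counts, seeds and thresholds; re-running with the same config and seed
produces byte-identical artifacts.

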