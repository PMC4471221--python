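# External inputs (not redistributed)

The paper-reproduction targets (acceptance criterion 8 / targets t1–t7)
need two third-party files that cannot ship with this repository. Place
them here to enable `scripts/acceptance.py` and
`tests/test_acceptance.py::test_c8_paper_reproduction`:

## `specimens.csv`

Per-specimen trait table (transcribed from the study's supplementary
specimen table), one row per specimen:

| column         | meaning                                               |
|----------------|-------------------------------------------------------|
| `specimen_id`  | unique specimen label                                 |
| `species`      | binomial, matching the tree tip labels exactly        |
| `group`        | `hominoid`, `cercopithecoid`, or `fossil`             |
| `ECL`          | external cochlear length, mm (may be empty)           |
| `TUR`          | number of turns (may be empty)                        |
| `CUR`          | curvature gradient (may be empty)                     |
| `RECL`         | relative cochlear length, mm (may be empty)           |
| `OWA`          | oval window area, mm² (may be empty)                  |
| `body_mass_kg` | species-level sex-averaged adult body mass, repeated  |

## `catarrhine_consensus.nwk`

The 50% majority-rule catarrhine consensus phylogram (10kTrees for
Primates, v2; "molecular-calibrated" branch lengths), Newick with branch
lengths, tip labels matching `species` for the 22 living study species.
Extra tips are pruned automatically.
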