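# stanalyzer

A simulation-trajectory analysis suite: a Python library plus a
project-configured, subcommand-per-analysis command-line tool covering
membrane, protein, geometry, contact and non-bonded-interaction
observables, with reproducibility logging and seeded synthetic fixtures
that make every analysis testable without external data.

## Features

24 built-in analyses, grouped as in the registry:

| Category | Analyses |
|---|---|
| Membrane | sterol-tilt, zdensity, msd-membrane, scd, thickness, apl (Voronoi), shell-composition (Voronoi), ka, position |
| System Dimensions | system-size |
| Proteins and Nucleic Acids | secondary-structure (`dssp` alias), pore-radius, rmsd, rmsf |
| Geometry | bond-stats (distance/angle/dihedral) |
| Contacts | residence-time, residue-contacts (`contacts` alias), rdf |
| Non-bond Interactions | hbond, pi-stacking, salt-bridge, water-bridge |
| Others | covariance, msd-solution |

Supporting machinery:

- **Inputs**: PDB structures, CHARMM-style DCD trajectories (multi-model
  PDB also readable), orthorhombic boxes. Outputs are TSV files with a
  `#`-prefixed header line.
- **Project config**: a flat JSON file (`project.json`) stores defaults
  (structure, trajectory glob, output directory, frame window); explicit
  command-line options always win over file values.
- **Reproducibility log**: every analysis appends the exact replayable
  command line to `commands.log` in the output directory; replaying a
  recorded line reproduces deterministic outputs bit-exactly.
- **Synthetic fixtures** (`stanalyzer make-fixture`): seeded, byte-
  reproducible generators for flat bilayers with prescribed chain
  orientations, ideal-gas boxes, random walks with known diffusion, ideal
  helices/strands, hydrogen-bond/salt-bridge/π-stacking/water-bridge
  motifs and pore geometries — each with machine-readable ground truth.

## CLI usage

```sh
# create a project file interactively
stanalyzer config

# run analyses (defaults from ./project.json; options override)
stanalyzer system-size --output-dir results
stanalyzer apl --sel 'name P' --out apl.tsv
stanalyzer rmsd --sel 'protein and name CA' --frame-start 100 --frame-stride 5
stanalyzer hbond --donor-sel protein --acceptor-sel protein

# utilities
stanalyzer ci --values 41.2,40.8,41.9 --level 0.90
stanalyzer make-fixture --kind bilayer --seed 1 --n-frames 10 --out-dir demo
```

Every analysis accepts `--structure-path`, `--trajectory-pattern`,
`--output-dir`, `--frame-start/--frame-stop/--frame-stride` (0-based,
stop-exclusive), `--time-step` and analysis-specific options
(`stanalyzer <name> --help`).

Selections use a small grammar: `name X`, `resname X`, `resid N[:M]`,
`segid X`, `element X`, `protein`, `water`, combined with `and`, `or`,
`not` and parentheses.

## Library usage

```python
from stanalyzer import load_structure, iterate_frames, ProjectSettings
from stanalyzer.membrane import area_per_lipid

project = ProjectSettings(structure_path="s.pdb", trajectory_pattern="t*.dcd")
atoms = load_structure(project.structure_path)
table = area_per_lipid(iterate_frames(project, atoms), "name P", atoms)
print(table.to_tsv())
```

## Tests and acceptance report

```sh
python -m pytest -q tests/          # full suite (unit + property + acceptance)
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` holds one test per acceptance criterion
(analytic limits, rigid-motion invariance, stochastic recovery, oracle
equivalence, detector gates, reproducibility, registry completeness).
All test data is generated at test time by the fixture module.

## Conventions

Units are Å, degrees, ps, K and amu throughout; K_A is reported in mN/m
and diffusion coefficients in both Ų/ps and cm²/s. Frame indices are
0-based and global across trajectory files (naturally sorted, so `run2`
precedes `run10`). Only orthorhombic boxes are supported for
PBC-dependent analyses.
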