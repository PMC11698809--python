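# gliosim

Hybrid multiscale simulator of avascular glioblastoma growth in which the
hypoxia-inducible factor (HIF) couples cell metabolism to extracellular
matrix remodelling and collagen-dependent migration.

## Who this is for

Computational/systems biologists studying how hypoxia shapes tumour
metabolism (the Warburg effect) and invasion. The package provides a
tested, scriptable 2D agent-based model: a reaction-diffusion
microenvironment (oxygen, glucose, protons, collagen), per-cell gene
regulation, demand-driven metabolism, ATP/pH fate rules, PhysiCell-style
mechanics, and the analysis metrics used in comparative growth studies —
plus the parameter-calibration recipe for estimating gene-regulation
constants from expression tables.

## The model in brief

Seven per-cell protein activities — HIF *h*, LDH *l*, PDK *k*, PDH *q*,
P4HA1 *p*, MT1-MMP *m*, LOX *r* — obey ODEs built from the Shifted-Hill
function

    S(Y, s, γ) = sⁿ/(sⁿ+Yⁿ) + γ·Yⁿ/(sⁿ+Yⁿ),  n = 4,

with HIF stabilised by hypoxia (oxygen gates its degradation) and driving
the rest. Metabolism follows

    f_O = Ψ_O(q)·V_O·O/(K_O+O)
    f_G = max(0, Ψ_G(l)·A_0/2 − 29f_O/10)·G/(K_G+G)
    f_A = 2f_G + (29/5)f_O,     f_H = 2f_G·k_H

so glycolysis tops ATP up toward the demand A_0, overshooting in
high-LDH (Warburg) cells. Cells remodel the collagen of their own voxel
(P4HA1 secretes, MT1-MMP degrades, LOX cross-links into a
degradation-resistant pool), and migrate with the biphasic speed law

    v(C_t) = v0·(−0.23C_t² + 0.971C_t − 0.048) on C_t ∈ [0.5, 4.0] mg/mL,
    v = 0 outside,

where C_t is total collagen density. Fate rules: necrosis on ATP
shortage or acidosis, quiescence at intermediate ATP, division (no
crowding condition) on a completed 18-h cycle. See `docs/methods.md` for
the full account, parameter tables and numerical scheme.

## Worked example

Run a half-day of the reference scenario on a small domain:

```
gliosim run --scenario reference --seed 3 --days 0.5 \
    --config examples/small.yaml --out /tmp/demo
```

with `examples/small.yaml` containing

```yaml
nx: 20
ny: 20
voxel_size: 30.0
n_initial_cells: 40
seeding_radius: 70.0
dt_diffusion: 1.0
dt_mechanics: 1.0
snapshot_interval: 180.0
```

prints

```
reference: day 0.5  living=71 dead=0 radius=125 um
```

— after 12 hours the 40-cell inoculum has grown to 71 living cells (cell
cycle phases are randomised at seeding, so within 12 h about two thirds of
the cells complete their 18-h cycle and divide) and the proliferative
radius is 125 µm: still fully oxygenated, pre-hypoxic growth. The run directory contains
`timeseries.csv` (counts and layer radii per snapshot), per-snapshot cell
tables `cells_t*.csv` (position, state, the seven gene levels, speed,
proton export, local oxygen), the final fields as CSV with text headers,
and a `manifest.json` recording the full configuration and seed.

Library use mirrors the CLI:

```python
import gliosim as g

report = g.run_simulation(g.scaled_config("restricted_oxygen", seed=1))
print(report.counts_frame().tail(1))
flagged = g.warburg_cells(report.final_cells)   # Warburg-phenotype cells
```

For calibration, `gliosim calibrate table.tsv --regulator HIF1A
--target LDHA --direction up` fits the Shifted-Hill threshold and
fold-change for one regulatory edge from a genes-by-samples count table.

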