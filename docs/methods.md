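# Methods

`gliosim` is a hybrid discrete-continuum simulator of avascular tumour
growth in which the hypoxia-inducible factor (HIF) couples three layers of
biology: a per-cell gene regulatory network, cell metabolism with a
Warburg-capable glycolytic switch, and remodelling of extracellular
collagen that in turn sets the cell migration speed.

## Model

### Gene regulation (module `grn`)

Each cell carries seven dimensionless protein activities: HIF (h), LDH
(l), PDK (k), PDH (q), P4HA1 (p), MT1-MMP (m) and LOX (r).  Regulation
uses the Shifted-Hill function

    S(Y, s, γ) = s^n/(s^n + Y^n) + γ·Y^n/(s^n + Y^n),   n = 4,

which interpolates monotonically between 1 (no regulator) and γ
(saturating regulator); γ > 1 is an up-regulation, γ < 1 a
down-regulation.  HIF is produced constitutively (α_h·β_h) and degraded
oxygen-dependently (d_h·S(O)·h), so hypoxia stabilises it; HIF then drives
l, k, p, m, r, and PDK represses PDH (γ_{k→q} = 0.78 < 1).  All rates and
regulation constants default to the published calibration (α = d =
0.005 min⁻¹ for all seven species, so every fixed point is simply the
incoming S value, and the common relaxation time is 1/d = 200 min).
MT1-MMP is up-regulated by HIF, like the other remodelling genes, with
threshold 13.25 and strength 20.43.

Integration is classical fixed-step RK4 with the local voxel oxygen
frozen over each step (operator splitting).  With a 200-min relaxation
time, any step up to a few minutes is far below the accuracy floor of the
other couplings; the dt-halving test bounds the 14-day trajectory change
at < 0.1 %.  Closed-form fixed points (cascaded down the network) serve
as test oracles.

### Metabolism (module `metabolism`)

Oxygen uptake is Michaelis-Menten in O gated by a logistic function of
PDH; glucose uptake is demand-driven: glycolysis makes up whatever
respiration does not supply toward the ATP target A_0, scaled by a
logistic function of LDH (Ψ_G ∈ [1, 50]) that encodes glycolytic
overflow:

    f_O = Ψ_O(q)·V_O·O/(K_O+O)
    f_G = max(0, Ψ_G(l)·A_0/2 − 29·f_O/10)·G/(K_G+G)
    f_A = 2·f_G + 29/5·f_O
    f_H = 2·f_G·k_H

Two structural consequences matter for the dynamics: (1) with glucose
available, f_A ≈ Ψ_G(l)·A_0 ≥ A_0, so cells die of ATP shortage only when
glucose locally collapses; (2) a glycolytic cell (l ≈ 16, Ψ_G ≈ 50) draws
~50× the baseline glucose, so a hypoxic tumour core digs its own glucose
crater — that crash, together with acidification, is what produces the
necrotic core.  The published constants make A_0/2 = 2.9·V_O exactly, so
full respiration sits precisely on the uptake clamp boundary (cells never
excrete glucose).

### Microenvironment (module `microenv`)

A 2D square-voxel lattice carries O, G, H⁺ (diffusible, Dirichlet
boundaries at normoxia 0.056 mmol/L, serum glucose 5.0 mmol/L, pH 7.4 =
3.98×10⁻⁵ mmol/L) and the two collagen pools C and C_r (no diffusion, no
decay).  Uptake and secretion act on the concentration of the whole voxel
a cell occupies, so the effective sink per cell scales with voxel volume
— this is the convention the per-voxel source summation implies, and it
is worth keeping in mind when changing `voxel_size`.

Numerics.  Diffusion uses backward Euler with a cached sparse LU of the
full 2D 5-point operator; Dirichlet voxels are identity rows, so a
time-varying boundary (the oscillating-oxygen driver) is a pure RHS
update.  The matrix is an M-matrix, hence unconditional stability and
exact non-negativity.  At the coarse steps used for study runs a naive
split (subtract uptake, then diffuse) is inconsistent: one implicit step
equilibrates the field over √(D·dt) ≈ 400 μm, so cells would never sample
the hypoxic quasi-steady profile, and crowded voxels would see transient
undiluted proton spikes.  The engine therefore solves O and G with the
cell uptake folded into the implicit matrix as a linearised first-order
sink (refreshed every fourth step; the sink map evolves on the slow cell
timescale), and H⁺ with its secretion in the RHS of the implicit solve.
The fixed point of these maps is exactly the discrete reaction-diffusion
balance, independent of dt.  Collagen changes are applied explicitly;
when degradation plus cross-linking would overdraw a voxel, both are
scaled down proportionally, so C ≥ 0 holds and C + C_r changes exactly by
secretion − degradation (cross-linking conserves the total; the grid
keeps a cumulative ledger that the conservation test checks to 10⁻⁶).

The oscillating boundary is a continuous triangular wave: 5 % O₂ (0.056
mmol/L) down to 1 % O₂ (0.0112 mmol/L, by linear scaling of the 5 % ↔
0.056 mapping) over 360 min and back, period 720 min.  In the
restricted-oxygen protocol only the top and bottom edges carry the oxygen
Dirichlet condition (left/right become zero-flux for O); glucose and
protons stay pinned on all four sides.

### Cell agents (module `agents`)

Off-lattice circular agents (radius 8.4 μm) with PhysiCell-style pairwise
mechanics: quadratic repulsion inside contact, quadratic adhesion up to
1.5× the radii sum (adhesion 0.4, repulsion 10 μm/min; adhesion 0
reproduces the no-adhesion study).  Motility is a persistent random walk:
uniform direction re-drawn every 5 min, speed from the biphasic collagen
law

    v = 0                          if C_t = C + C_r outside [0.5, 4.0] mg/mL
    v = v0·(−0.23·C_t² + 0.971·C_t − 0.048)  otherwise, clamped to [0, v0]

with v0 = 0.8 μm/min; the quadratic peaks near 2.11 mg/mL.  The 5-min
persistence (PhysiCell's default is 1 min) keeps simulated tumours
near-compact, matching the reported morphology in which detaching cells
move only slightly away from the main body, while still letting matrix
stiffness shape growth.  Longer persistence (≥ 15 min) disperses pioneer
cells hundreds of μm and erases the reported bi-gel asymmetry at
test-scale domains.

Fate is evaluated every 6 min from the ATP generated over the interval
and the local pH: necrosis below 0.3·A_0·dt or pH < 5.6, division above
0.8·A_0·dt once the fixed 18-h cycle completes (daughter placed at one
radius, no crowding condition), quiescence in between (cycle clock
paused, reversible).  The pH threshold is the one fate constant without a
published value; 5.6 is chosen so that the glycolytic living population
the study reports can exist — at 6.0, acidosis kills cells at exactly the
LDH level where they become glycolytic and the tumour never shows the
glycolytic state.  Necrotic cells persist (counted as dead), never
consume, remodel, divide or move actively, but are displaced passively by
mechanical forces; rigid corpses would otherwise jam the tissue at
several times contact density and distort every nutrient field.

Collagen remodelling is strictly local to the occupied voxel: secretion
β_p·p, Michaelis-Menten degradation β_m·m·C/(K_m+C) and cross-linking
β_r·r·C/(K_r+C), the latter converting C into degradation-resistant C_r.

### Calibration (module `calibration`)

The regulation parameters (s, γ) of a network edge are estimated from a
gene-by-sample expression table by: log₂(count+1) normalisation, min-max
interpolation of each gene to [0, 1], least-squares fit of the single
Hill branch matching the regulation direction (n fixed at 4), rescaling
of s to the original scale, and γ as the target's fold-change (max/min
up, min/max down; pseudo-count 1 when the minimum is 0).  Because the
Shifted-Hill response is affine in the fitted branch, min-max
normalisation makes the single-branch fit exact for noise-free data.  The
1-D fit uses a coarse geometric grid followed by bounded scalar
minimisation — derivative-free and robust to the flat tails of the
objective.

The synthetic generator draws the regulator's log-expression uniformly
(default 0–16, a typical RNA-Seq dynamic range), places the target on the
Shifted-Hill response, and multiplies the stored counts by log-normal
measurement noise (noise is multiplicative on the count scale, as in
sequencing data).  Parameter recovery on this generator: noise-free
(s, γ) to < 1 %; at σ = 0.1 with 100 samples the median error of s is
≈ 3 %.  The fold-change estimator for γ is inflated by noise extremes
(median ≈ 10 % under the same conditions) — an inherent property of a
max/min statistic, not of the fit.

What the generator does not emulate: library-size variation, gene-gene
correlation, zero inflation, or any confounding between regulator and
target.  Passing recovery tests therefore demonstrate correctness of the
recipe, not robustness to real bulk RNA-Seq artefacts.

### Scenarios and metrics (module `scenarios`)

Named scenarios reproduce the study conditions: uniform reference gel
(2.5 mg/mL), bi-gel (soft 2.5 lower half / stiff 5.0 upper half),
restricted oxygen (top/bottom supply only), their combination,
heterogeneous matrix (i.i.d. uniform 0.5–4.0 mg/mL), no cell-cell
adhesion, reduced HIF degradation (γ_{O→h} = 17.5), stronger PDH
inhibition (γ_{k→q} = 0.14), oscillating oxygen, and the combination of
the last two (the Warburg-rescue study).  Metrics: counts by state,
tumour radius (max distance from the seeding centre, per layer, NaN for
an empty layer), metabolic-state classification of (l, q) with thresholds
at the midpoint of each gene's attainable fixed-point range, and Warburg
detection — a living cell is flagged when its local oxygen exceeds the
2 % hypoxia threshold (0.02085 mmol/L) while its proton export exceeds a
bound defaulting to half the theoretical maximal glycolytic rate
(2·k_H·Φ_G·A_0/2); both bounds are config-exposed.

Engine loop per diffusion step (default 0.01 min; study runs 3 min):
boundary driver → implicit O/G solves with uptake → per-cell rates and
ATP accrual → implicit H solve with secretion → gene RK4 at local O →
collagen source application; mechanics every dt_mechanics (per-step
displacement capped at 6 μm for stability of coarse steps; forces
computed by a numba kernel over voxel-binned neighbours); fate every
dt_phenotype = 6 min.  A single seeded PRNG drives seeding, motility and
division placement, making runs bit-reproducible.

## Scaled study conditions

Full-scale runs (1500×1500 μm, 20-μm voxels, 14 days, millisecond-scale
steps) are supported by the same code path but are not what the test
suite executes.  The comparative claims are evaluated on a reduced
protocol chosen so the governing length scales still fit the domain:
1980×1980 μm of 30-μm voxels, 100-cell inoculum (radius 80 μm), 7 days,
dt = 3 min, three seeds, medians.  The inoculum is larger than the
full-scale default because in 2D the oxygen drawdown needed for a hypoxic
core requires a tumour radius of roughly 450 μm — smaller tumours remain
permanently normoxic no matter how long they grow — and the domain must
still hold the final population at physical packing.  The
oscillating-oxygen metabolic studies use a 500-cell inoculum and 120-min
snapshots: the window in which a formerly-hypoxic cell surfaces above the
hypoxia threshold with its glycolytic program still active is only about
two hours around each normoxic peak, and it requires the deeper drawdown
that a 14-day full-scale tumour mass would provide.

Known limitation of the scaled setting: with oxygen supplied at the top
and bottom edges, living cells inside the oxygen penetration depth
(~150–250 μm) of those edges are well-fed and classify as
oxidative/intermediate, so the strict claim that a restricted-oxygen
end state contains *only* glycolytic living cells does not hold at
simulable domain sizes; the glycolytic state does dominate the interior.

## Other limitations

2D only; no explicit collagen fibres or orientation; no pH feedback on
ECM or MMP activation; no MMP2/MMP9/TIMP autoregulation; no angiogenesis;
no cell volume dynamics (necrotic cells neither swell nor lyse); no
stochastic gene expression.  Default full-scale time steps follow the
PhysiCell triple (0.01 / 0.1 / 6 min); the implicit field solves make the
coarser study steps stable, with the operator-splitting error absorbed
into the quasi-steady field approximation.
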