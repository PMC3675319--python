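# Methods

## The model

`tim2iron` models the handling of radiolabelled iron (⁵⁵Fe) by mouse kidney
TCMK-1 cells expressing the H-ferritin receptor TIM-2. Every labelled pool
is expressed in pmol of ⁵⁵Fe-equivalents per 10⁶ cells, resting on the
specific-activity assumption: scintillation counts are proportional to
tracer amount, with a fixed ratio per iron-carrying species, so tracer
bookkeeping in pmol is exact.

The state has three parts.

**Homeostasis core** — the labile iron pool x₁ (LIP), labelled iron in
endogenous H-ferritin x₄, and three regulatory levels: transferrin
receptor 1 (x₂), ferroportin (x₃) and active iron-regulatory proteins
(x₅). Regulation enters through saturating Hill-type factors: promotion
`α·x/(k+x)` and inhibition `α·k/(k+x)`. LIP iron is stored into endogenous
ferritin at an IRP-gated first-order rate and released back at rate γ₄;
it leaves the cell through ferroportin.

**TIM-2 receptor cycle** — free membrane receptor capacity x₆ binds
Fe-HFt from the media at the lumped rate `alpha7_Ftex·x₆` (label moves
media → x₇); membrane-bound complexes x₇ are endocytosed at the
ferritin-suppressed rate `γ₇·K₄₇/(K₄₇+x₄+x₉)`; endosomal receptor x₈
recycles back to the membrane at γ₆. At endocytosis the complex's iron is
routed immediately: a fraction α₉ stays in surviving exogenous HFt (x₉,
degrading slowly at γ₉) and α₁₀ is released to the LIP. There is no
separate endosomal-iron pool; the endosome lifetime appears only through
the capacity recycling rate γ₆.

**Media bookkeeping** — `media_unbound` (label in the media not yet
cell-associated) and `media_exported` (cumulative ferroportin export).
These two pools are plumbing the measurements require: the export
experiment counts ⁵⁵Fe in collected media.

### Conservation by construction

With the defaults α₁₀ = 1 − α₉ and α₁₁ = 1 (all iron from degraded HFt
reaches the LIP), the labelled-pool derivatives sum to zero identically,
so total label x₁+x₄+x₇+x₉+media is constant along any trajectory, and
x₆+x₇+x₈ (total receptor capacity) is conserved exactly. Both are
asserted as property tests.

The published x₉/LIP source terms use the unsuppressed flux γ₇x₇ while
the x₇/x₈ exchange carries the K₄₇ suppression; applied literally the
four terms do not balance and tracer would be created. We apply the
suppressed flux uniformly in all four terms (outflow of x₇ equals the sum
of its destinations); the literal form remains available behind
`ModelParameters.literal_processing` for comparison.

### Linear regime (`frozen_core`)

The study's working assumption is that the cells sit at homeostatic
equilibrium and the tracer perturbation is below every nonlinear
threshold of the core. With `frozen_core=True` (default) x₂/x₃/x₅ are
held at their label-free resting values and their Hill factors fold into
effective constants; the full regulatory ODEs integrate when the flag is
off. Three kinetic products are stored as single lumped coefficients
because only the products are identifiable from these data:
`alpha7_Ftex` (= α₇·Ft_ex), `alpha1_Feex_x2` (direct, TIM-2-independent
uptake, first order on unbound media label) and `alpha6_x3_eff`
(ferroportin export of the LIP).

## Parameters

Reference values (packaged `data/table1.json`), per minute unless noted:

| name | value | meaning |
|---|---|---|
| `alpha7_Ftex` | 0.166 | TIM-2/Fe-HFt combination (binding probability) |
| `gamma7` | 0.118 | endocytosis rate at low ferritin |
| `gamma6` | 0.0142 | endosome → membrane receptor recycling |
| `alpha9` | 0.283 | fraction of HFt surviving endocytosis (unitless) |
| `gamma9` | 0.00031 | slow degradation of surviving HFt |
| `K47` | 0.11 | ferritin level halving endocytosis (pmol/10⁶ cells) |
| `alpha1_Feex_x2` | 0.00015 | direct uptake coefficient |
| `alpha6_x3_eff` | 0.0019 | LIP export coefficient (0.2 %/min) |

Core constants are not part of the extracted set and mostly drop out
under `frozen_core`; the pair that matters is the storage/release balance.
We use `alpha4_storage = 0.0008` (effective gated rate 0.0004/min) and
`gamma4 = 0.0001/min`, fixed by two observations: the transferrin-preload
partition of cell iron is 80% ferritin / 20% LIP (ratio 4:1), and the
late storage phase must lose biotinylated signal at 1–2 %/h, i.e. remain
γ₉-dominated (a faster ferritin-iron turnover re-suppresses endocytosis
late in the chase and contaminates the slow phase). The implied
endogenous-ferritin iron residence time (~days) is at the slow end of the
plausible range for non-erythroid cells.

## Protocols

* **uptake** — one 120-min exposure to Fe-HFt, sampled at 0/5/15/30/60/
  90/120 min; observable: whole-lysate label (x₁+x₄+x₇+x₉).
* **storage** — 120-min biotin-Fe-HFt exposure, PBS wash (zeroes
  `media_unbound`; surface-bound complexes stay with the cells), 48-h
  chase sampled 0/2/4/8/24/48 h post-wash; observables: biotinylated
  (x₇+x₉) and non-biotinylated (x₁+x₄) label.
* **export** — cells preloaded with 10.8 pmol/10⁶ cells of label (split
  80/20 at the storage balance) in media carrying 2.4 pmol/10⁶ cells of
  transferrin-bound residue; media sampled 0/2/4/24/48 h; observable:
  cumulative exported label. Because the media label is not Fe-HFt, TIM-2
  binding is disabled in this protocol, which makes the exported
  timecourse exactly identical between TIM-2 and vector cells — the
  model-level statement that TIM-2 is not involved in export. The
  biotinylated apo-HFt treatment carries no label and is modelled as
  having no effect on labelled-iron flux.

Vector (empty-vector control) cells are modelled by zero membrane TIM-2
capacity with the receptor equations inert.

Two study conditions are not printed anywhere and were fixed once by
calibration against printed behaviours (scan in the development notes):
the exposure media label, 25 pmol/10⁶ cells (large enough to sustain the
slow late-uptake phase while keeping depletion moderate — the binding
coefficient is scaled by the remaining unbound-media fraction so label
cannot be created), and the initial membrane capacity x₆(0) = 8.4
pmol-equivalents/10⁶ cells, the ratio of the initial uptake rate
(1.4 pmol/min/10⁶ cells) to the combination rate (0.166/min). Two printed
behaviours are *not* reproduced at any scanned condition and are left as
known model tensions rather than tuned: the first-phase storage loss
(~11 %/h simulated vs ~20 %/h described; the pooled biotinylated
observable mixes the fast-draining x₇ with the slow x₉) and the late
uptake rate (~0.035 vs 0.07 pmol/min; suppressed endocytosis throttles
receptor recycling).

## Numerics

LSODA with relative tolerance 1e-8 and absolute tolerance 1e-10, hard
restart at phase boundaries; media events are applied between phases.
During fitting the tolerances are relaxed to 1e-7/1e-9 for speed.
Equilibration is closed-form under the frozen core and a fixed-point
iteration otherwise (tolerance 1e-9, capped iterations). Snapshots are
taken exactly at the sampling grids; the storage clock starts at the
wash.

## Fitting

The objective is the sum of squares due to normalized error,
SSNE = Σⱼ (mⱼ−yⱼ)²/σⱼ², pooled across experiments. Points with zero or
unreported SD use the floor σ = 0.001·maxⱼ|yⱼ| so the objective stays
finite (triplicate SDs can be zero at t = 0). Free parameters are
searched in log10 space within positive bounds (default: a factor of 10
either side of the reference value, fractions capped at 1), from 16
Latin-hypercube starting points, each refined by a bounded trust-region
least-squares solve on the normalized residuals — chosen over a
derivative-free search because SSNE is an exact sum of squares and the
residual solver needs far fewer model evaluations per start. Fits are
deterministic given the seed. A flat-objective probe (doubling/halving
each estimate) flags unidentifiable parameters in `FitResult.warnings`.

### Identifiability

K₄₇ is structurally unidentifiable from these sampling grids: once
intracellular ferritin S = x₄+x₉ exceeds K₄₇ (within minutes of
exposure), the data constrain only γ₇·K₄₇/(K₄₇+S), and fits with K₄₇
free run the γ₇/K₄₇ pair to opposite bounds along this ridge. The
recovery study therefore frees the five rate constants
(`alpha7_Ftex`, `gamma7`, `gamma6`, `alpha9`, `gamma9`) and holds K₄₇
fixed. An asymptotic (Cramér–Rao) analysis of the design — 7 uptake + 12
storage points, 10% CV, triplicates — puts the per-seed relative
standard errors of γ₇ and γ₆ at roughly 30–40%; per-seed estimates
scatter accordingly, while the median estimate across 20 seeds is nearly
unbiased (within ~2% of the generating values). Recovery is therefore
summarized by the median estimate over seeds.

## Synthetic data

The generator emulates triplicate ⁵⁵Fe measurements: Gaussian scatter on
replicate values (SD = cv·mean with an optional absolute floor, draws
clipped at zero counts), then per-point mean/SD/n — so reported SDs are
themselves realistic random variables. The default cv = 0.10 matches the
order of magnitude of the published error bars; the true replicate
variance is not recoverable from the published summaries. The generator does not model
Poisson counting statistics, pull-down efficiency, batch effects, or any
systematic error, so passing recovery tests demonstrate statistical
self-consistency of the pipeline under the assumed noise — not accuracy
against the original laboratory measurements, whose raw values are not
tabulated.

## Known limitations

* The source study's quoted initial uptake of 2.17 pmol per million cells
  lacks a per-time unit and is not reconciled with the 1.4 pmol/min
  figure used to set x₆(0).
* The ~2 h endosome lifetime quoted in the source study is not identical
  to 1/γ₆ ≈ 70 min; no reconciliation is attempted.
* Hepcidin enters only as a lumped decay term on ferroportin; there are
  no explicit hepcidin dynamics, no stochastic simulation, and no claim
  beyond the TCMK-1 system.
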