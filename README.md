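# tim2iron

Kinetic modelling of TIM-2 mediated ferritin-iron uptake, storage and
export in mouse kidney cells.

TIM-2 (T cell immunoglobulin and mucin domain-2) is a mouse receptor that
binds H-chain ferritin (HFt) and internalizes it by endocytosis,
delivering the iron the ferritin carries. `tim2iron` is for modellers and
experimentalists who want to simulate ⁵⁵Fe radiotracer experiments on
TCMK-1 kidney cells (TIM-2 transfectants vs empty-vector controls),
extract the receptor pathway's rate constants from timecourse data by
weighted least squares, and test whether those constants are recoverable
at realistic noise.

## The model

A classical iron-homeostasis core (labile iron pool x₁, TfR1 x₂,
ferroportin x₃, endogenous HFt iron x₄, active IRPs x₅) is extended with
a TIM-2 receptor cycle — free membrane receptor x₆, membrane-bound
TIM-2·Fe-HFt complex x₇, endosomal receptor x₈ and surviving exogenous
HFt x₉:

    dx6/dt = γ₆x₈ − α₇Ft_ex·x₆
    dx7/dt = α₇Ft_ex·x₆ − γ₇x₇·K₄₇/(K₄₇ + x₄ + x₉)
    dx8/dt = γ₇x₇·K₄₇/(K₄₇ + x₄ + x₉) − γ₆x₈
    dx9/dt = α₉·F − γ₉x₉
    dx1/dt = (core terms) + α₁₀·F + α₁₁γ₉x₉

with F the (ferritin-suppressed) endocytosis flux, α₉ the fraction of
internalized HFt surviving endocytosis and α₁₀ = 1 − α₉ the iron released
to the LIP, so the tracer budget closes exactly. All labelled pools are
in pmol ⁵⁵Fe-equivalents per 10⁶ cells. Fitting minimizes the sum of
squares due to normalized error over all experiments jointly,

    SSNE = Σⱼ (mⱼ − yⱼ)² / σⱼ²,

with point means/SDs from triplicates. The original work solved these
ODEs by mapping them to an equivalent electrical circuit in a circuit
simulator (states as capacitor charges, fluxes as currents, optimization
over the component values); this package integrates the same equations
directly with a stiff ODE solver and fits with bounded multi-start
least squares. See `docs/methods.md` for assumptions, units and
identifiability analysis.

## Worked example

The packaged reference parameter set (`tim2iron.load_table1()`) carries
the extracted pathway constants. The headline kinetic quantities they
imply:

```sh
$ tim2iron report
TIM-2 / Fe-HFt binding probability: 16.6% per min
Mean endosome formation time: 8.5 min
Surviving HFt at end of endocytosis: 28%
LIP export rate through ferroportin: 0.2% per min
Phase-two HFt degradation: 1.8% per h
```

Read: each minute, 16.6% of free membrane TIM-2 binds Fe-HFt; a bound
complex needs 8.5 min on average to form an endosome; 28% of the
internalized ferritin survives endocytosis and then degrades slowly
(≈1.8%/h, the slow second phase of biotinylated-HFt loss); the LIP loses
0.2% of its iron per minute through ferroportin, identically in TIM-2 and
vector cells — TIM-2 plays no role in export.

Simulating the pulse-chase storage experiment (2 h biotin-Fe-HFt loading,
wash, 48 h chase) and the other protocols:

```sh
$ tim2iron simulate --protocol storage --cell-line tim2 --out storage.csv
$ head -4 storage.csv
experiment,observable,time_min,value
storage_tim2,biotinylated_55fe,0.0,7.195508897989191
storage_tim2,biotinylated_55fe,120.0,5.417670147865191
storage_tim2,biotinylated_55fe,240.0,4.522210898104988
```

— the biotinylated (exogenous-HFt) label falls from 7.2 pmol/10⁶ cells at
the wash in two phases: fast while bound complexes are still being
processed, then at γ₉ once only surviving HFt remains.

Synthetic triplicates and parameter recovery:

```sh
tim2iron generate --seed 1 --cv 0.10 --out data/       # three experiments
tim2iron fit --data data/uptake.csv --data data/storage.csv \
             --seed 1 --out fit.json                   # SSNE co-fit
tim2iron recover --seed 1 --n-seeds 20 --out recovery.csv
```

`recover` regenerates noisy datasets for 20 seeds, co-fits the five
identifiable TIM-2 rate constants each time, and prints the median
recovered value and per-seed scatter for each.

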