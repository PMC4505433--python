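# rmekit

Quantification pipeline for rapid, tonicity-induced translocation of a
membrane protein (the motivating case is the water channel aquaporin-4
carrying a GFP tag) between intracellular vesicles and the plasma membrane.
It is written for cell biologists who quantify confocal micrographs and
biotinylation-ELISA plates, and for anyone who wants a fully verifiable,
simulation-backed implementation of the underlying statistics.

## What it computes

**Relative membrane expression (RME).** For a line profile crossing a cell,
let *M* be the average membrane fluorescence (the two plasma-membrane
crossing peaks), *C* the average intracellular fluorescence, and
*I*<sub>max</sub> the maximum fluorescence intensity of the profile within
the cell. Then

&nbsp;&nbsp;&nbsp;&nbsp;RME = 100 · (M − C) / I<sub>max</sub>

so a cell with protein evenly distributed between membrane and intracellular
compartments scores 0 and a cell with 100% of the protein at the membrane
scores 100. Profiles are placed deterministically (three per cell, avoiding
the nucleus and perinuclear region), sampled bilinearly, and aggregated
hierarchically: profiles → cell → experimental repeat → condition mean ± SEM.

**Cell swelling.** Cross-sectional areas from particle detection (Otsu
threshold, hole filling, connected components), pre/post-challenge cell
matching, and post-challenge area as a percentage of the pre-challenge area,
reported separately for transfected and non-transfected cells.

**Translocation kinetics.** Per-frame RME of a time-lapse stack and the
response time constant τ from exponential kinetics of the latent membrane
fraction, fitted through the hyperbolic saturation of the RME statistic
(plus the plain single-exponential τ and the model-free time to 90% for
comparison).

**Surface expression by biotinylation ELISA.** Triplicate-well aggregation,
blank subtraction, per-repeat fold changes versus a control condition, and
constitutive surface expression as percent of a reference construct.

**Decision rule.** Repeated-measures ANOVA gate, paired (or Welch) t tests,
Bonferroni correction over the planned comparisons, p values displayed
rounded up to one significant figure, significance at p < 0.05, and a
translocation "Yes/No" call per condition (Yes requires a significant RME
*increase*).

Because real micrographs of this kind are not redistributable, the package
includes a first-class synthetic-data generator (`rmekit.scenes`) that
renders two-channel micrographs — membrane ring, diffuse cytoplasm, dim
nucleus, optional ER puncta, membrane-dye channel — and ELISA plates with
exact, seeded ground truth for every quantity the pipeline estimates.

## Worked example

```python
from rmekit.scenes import SceneSpec, CellSpec, render_scene
from rmekit.profiles import measure_scene_rme, aggregate_rme

spec = SceneSpec(
    image_shape=(128, 128),
    cells=(CellSpec(center=(64.0, 64.0), membrane_fraction=0.33),),
    noise_gaussian_sd=1.5,
    seed=42,
)
scene = render_scene(spec)
per_profile = measure_scene_rme(scene)
print(per_profile.round(2).to_string(index=False))
agg = aggregate_rme(per_profile)
print(f"cell mean RME = {agg['mean']:.2f}")
```

prints

```
 cell_id  profile_id      M     C  I_max   rme flags
       0           0 113.66 37.22 115.58 66.14
       0           1 111.59 37.03 111.95 66.60
       0           2 113.52 36.87 113.96 67.26
cell mean RME = 66.66
```

One third of the cell's tagged protein sits in the membrane ring
(`membrane_fraction=0.33`); the three line scans each find membrane peaks
(*M* ≈ 113 a.u.) about three times brighter than the cytoplasm
(*C* ≈ 37 a.u.), giving an RME near 67 — a strongly membrane-shifted cell,
comparable to a hypotonically stimulated one.

The end-to-end demonstration (three tonicities, three repeats, full report):

```bash
rmekit run --seed 1 --out report/
```

writes `table1.csv`/`table1.txt` with isotonic/hypotonic RME ± SEM, percent
area change, the corrected p value and the Yes/No translocation call per
condition. `rmekit --help` lists the other subcommands (`simulate`,
`simulate-plate`, `rme`, `area`, `elisa`, `show-config`).

## Documentation

`docs/methods.md` describes the rendering model, the membrane-detection
rule, the kinetics estimator, all tunable parameters with units and
defaults, and known limitations.
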