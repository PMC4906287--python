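# isrscape

Binding-energy-landscape topography for enzyme–substrate panels: compute the
**intrinsic specificity ratio (ISR)** from docking decoy ensembles, relate it
to enzyme activity, and flag low-specificity hot spots.

## The problem

Measuring or computing the catalytic efficiency `kcat/Km` for every point
mutant of an enzyme is slow: each variant needs kinetics experiments or
MD + QM/MM simulation. The topography of the enzyme–substrate *binding*
energy landscape offers a fast proxy. Docking one substrate into each
variant yields an ensemble of poses; the lowest-energy pose is the native
complex and the rest are decoys. A funneled landscape — a native state well
separated from a narrow decoy band — discriminates the productive complex
from non-productive ones and tracks catalytic activity.

For a decoy ensemble with native energy `E_n`, decoy mean `⟨E_D⟩` and decoy
spread `ΔE` (all kcal/mol):

    δE  = ⟨E_D⟩ − E_n          (energy gap, the funnel slope)
    ISR = δE / ΔE              (unit-less, affine-invariant)

Across a panel of variants, ISR correlates with `ln(kcat/Km)`; the
correlation with binding affinity `ΔG_bind` alone (or barrier `ΔG‡` alone)
is weaker, but sharpens when the other quantity is held near the wild-type
value (± 1.5 kcal/mol by default). Variants whose ISR drops below a
threshold (presets 4.0 / 4.5) are "hot spots" — residues whose substitution
destroys intrinsic specificity and activity. Activity and the two free
energies are linked by transition-state theory:
`ln(kcat/Km) = −(ΔG_bind + ΔG‡)/(R·T)` up to a constant.

The package is for computational enzymologists and method developers: it
consumes docking *energies* (flat CSV tables or AutoDock4 DLG logs) — it
never runs docking, MD or QM/MM itself — and ships a synthetic panel
generator with known ground truth so every stage is testable from scratch.

## Worked example

```python
import isrscape as isr

# landscape statistics of one 5-pose ensemble
s = isr.landscape_stats(isr.DecoyEnsemble("WT", [-10.0, -5.0, -4.0, -6.0, -5.0]))
print(f"En={s.e_native}  <E_D>={s.mean_decoy}  dE={s.delta_gap}  "
      f"DE={s.roughness:.4f}  ISR={s.isr:.3f}")

# a synthetic 12-variant panel with known truth
panel = isr.simulate_panel(isr.PanelConfig(seed=42))
head = isr.correlate_panel(panel.records, "isr", "ln_activity")
direct = isr.correlate_panel(panel.records, "isr", "affinity")
cond = isr.correlate_panel(panel.records, "isr", "affinity", subset=("barrier", 1.5))
hot = [c.variant_id for c in isr.classify_hot_spots(panel.records, threshold=4.0)
       if c.is_hot_spot]
print(f"ISR vs activity: R = {head.pearson_r:.3f} (n = {head.n_used})")
print(f"ISR vs affinity: R = {direct.pearson_r:.3f} -> "
      f"{cond.pearson_r:.3f} within 1.5 kcal/mol of the WT barrier (n = {cond.n_used})")
print("hot spots below ISR 4.0:", hot)
```

prints

```
En=-10.0  <E_D>=-5.0  dE=5.0  DE=0.8165  ISR=6.124
ISR vs activity: R = 0.915 (n = 12)
ISR vs affinity: R = -0.731 -> -0.854 within 1.5 kcal/mol of the WT barrier (n = 5)
hot spots below ISR 4.0: ['M03', 'M05', 'M07', 'M08', 'M11']
```

Reading the numbers: the toy ensemble has a 5 kcal/mol gap over a 0.82
kcal/mol-rough decoy band, i.e. a sharply funneled landscape (ISR ≈ 6.1).
In the simulated panel, ISR explains most of the activity variation
(R = 0.92 for this seed; the distribution over seeds is centered near
0.77). Its correlation with binding affinity is negative — stronger
(more negative) binding means higher ISR — and strengthens in magnitude
once variants with perturbed barriers are excluded. Five mutants lose
enough intrinsic specificity to be called hot spots.

The same pipeline from the shell:

```bash
isr simulate --seed 42 --out-dir runs/panel        # energies.csv, records.csv, truth.csv
isr compute  --energies runs/panel/energies.csv \
             --bootstrap 1000 --seed 1 --out-dir runs/stats
isr analyze  --records runs/panel/records.csv --x isr --y ln_activity \
             --hotspot-threshold 4.0 --out-dir runs/analysis
isr report   --records runs/panel/records.csv --out-dir runs/report
```

Each run directory gains a `manifest.json` (command, seeds, input digests,
version) and reruns with the same seed are byte-identical. Real docking
output plugs in the same way: `isr compute --dlg variant.dlg ...` extracts
the per-run binding energies from AutoDock4 DLG logs.

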