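# Methods

## The statistic

For one enzyme–substrate system, molecular docking yields an ensemble of
poses with binding energies `E_1 … E_N` (kcal/mol, more negative =
more favorable). The pose with the lowest energy is taken as the native
enzyme–substrate complex; the remaining poses are decoys. The landscape
topography is summarized by

- the native energy `E_n = min_i E_i`,
- the decoy mean `⟨E_D⟩` (average over the non-native poses),
- the energy gap `δE = ⟨E_D⟩ − E_n` (the funnel's slope),
- the roughness `ΔE` (spread of the non-native energies), and
- the intrinsic specificity ratio `ISR = δE / ΔE`.

ISR is unit-less and invariant under any affine rescaling `E → aE + b`
(`a > 0`) of the energy function, which makes it comparable across scoring
functions and across variants. A large ISR means a landscape strongly
funneled toward the native complex — high intrinsic specificity — and is
used here as a fast proxy for enzyme activity `ln(kcat/Km)`.

Conventions and their rationale:

- **Decoy mean vs all-states mean.** `⟨E⟩` can be read as the average over
  all poses or over the non-native poses only. The default excludes the
  native so that δE and ΔE are estimated on the same population;
  `include_native_in_mean=True` gives the all-states reading. With 1000
  poses the two differ by less than δE/1000.
- **Roughness estimator.** ΔE is the sample standard deviation (n−1
  denominator) of the non-native energies — the conventional roughness
  estimator for an approximately Gaussian decoy cloud; a population-sd
  option exists. Width measures such as the range were rejected because they
  do not converge as N grows.
- **Native tie-break.** If several poses share the minimum energy, the first
  in file order is native and the rest remain decoys: deterministic and
  order-stable.
- **Entropy term.** The generalized ratio `δE/(ΔE·sqrt(2S))` is available
  via `isr_value(..., entropy_term=S)` for users who can estimate a
  configurational-entropy term S elsewhere. It is off by default: when one
  ligand is docked against a series of variants of the same receptor, the
  ligand entropy change is effectively constant and cancels out of
  comparisons.
- **Degenerate input.** Fewer than 3 poses (no spread defined) and
  zero-roughness ensembles are errors, not NaNs; a negative gap
  (anti-funneled landscape) is legal and logged.

## Activity model

Activity is linked to the energetics through transition-state theory:

    ln(kcat/Km) = offset − (ΔG_bind + ΔG‡) / (R·T)

with `ΔG_bind ≤ 0` the binding free energy, `ΔG‡ ≥ 0` the catalytic
barrier, `R = 1.9872×10⁻³ kcal/(mol·K)` and `T = 298.15 K` by default.
Under this sign convention tighter binding and a lower barrier both raise
the activity, and along any iso-activity line a change in binding is
exactly offset by the opposite change in barrier. With the default
`offset = 0` activities are relative; an offset can absorb the reference
state when absolute values are needed.

## Panel analyses

- **Correlations** are Pearson product-moment coefficients with a
  least-squares line for reporting (Spearman available as an option, never
  the default). Records missing a field are dropped pairwise per analysis
  and logged; at least 3 usable records are required. No multiple-testing
  correction is applied — analyses report raw R values.
- **Conditional subsets.** The correlation between ISR and one energy term
  is confounded by variation in the other. `filter_by_reference` keeps the
  wild type plus every variant whose barrier (or affinity) lies within a
  tolerance — default 1.5 kcal/mol, inclusive — of the wild-type value,
  which isolates the ISR–affinity (or ISR–barrier) relation.
- **Hot spots.** A variant is called a hot spot when its ISR falls strictly
  below a threshold. The threshold is a free parameter with presets 4.0
  (serine-protease-like panels) and 4.5 (hydroxylase-like panels); the
  presets reflect observed gaps in real ISR distributions, not a derived
  rule, so they should be re-examined per system.

## Uncertainty

`bootstrap_isr` resamples the full ensemble with replacement, re-identifies
each resample's native pose, recomputes the ISR under the default
convention, and reports a percentile interval. Degenerate resamples are
skipped and counted; more than 50% of them aborts the estimate. All
resampling flows from one integer seed. Note that resamples that omit the
original native pose produce lower ISR values, so the bootstrap
distribution is left-skewed and empirical coverage of a 95% interval runs
slightly below nominal (≈ 93–96% in the acceptance checks) — adequate for
error bars, not for sharp hypothesis tests.

## The synthetic generator

`simulate_panel` emulates the data a docking + MM/GBSA + QM/MM campaign
would produce for an alanine-scanning panel, so the entire pipeline is
testable without structures. Per variant:

1. a latent environment quality `q ~ U(0,1)` is drawn (the wild type takes
   the panel maximum — an idealization; real wild types are merely among
   the best);
2. `ΔG_bind = affinity_base + coupling·(1−q) + ε_aff` and
   `ΔG‡ = barrier_base + coupling·(1−q) + ε_bar` with independent Gaussian
   noises — one scalar quality coupling both energies is the simplest
   structure that reproduces the observed correlation patterns, a modelling
   choice, not a claim about enzymes;
3. activity is the TST transform of the two energies plus
   `N(0, noise_sd_activity²)`;
4. the landscape follows the *realized* energetics: the effective quality
   `q_eff = 1 − (ΔG_bind,dev + ΔG‡,dev)/(2·coupling)` (clipped to [0,1])
   sets the true roughness σ linearly over `roughness_range` and the true
   ISR linearly between `gap_lo/σ_lo` and `gap_hi/σ_hi`, with the true gap
   `g = ISR_true·σ`. Interpolating the ISR (rather than the gap) keeps the
   true ratio affine in `q_eff`, so in the noise-free limit the
   ISR–activity correlation is exactly 1 — a useful analytic anchor for
   tests. Tying the landscape to the realized energies rather than the
   latent q is what makes conditioning work: within a subset of
   near-wild-type barriers, `q_eff` becomes an affine function of the
   affinity alone, so the ISR–affinity correlation rises, mirroring the
   conditional behavior seen in real panels;
5. the decoy ensemble is `native + N(native + g, σ²)` draws with rejection
   below the native energy (the native stays the minimum by construction;
   for `g/σ ≥ 2.5`, the panel minimum, the truncation bias on the ISR is
   under ~2%).

Defaults and why (energies kcal/mol):

| parameter          | default     | rationale |
|--------------------|-------------|-----------|
| n_variants         | 12          | wild type + 11 alanine mutants, a typical scanning panel |
| n_decoys           | 1000        | standard docking-ensemble size for topography statistics |
| gap_range          | (2, 6)      | with roughness below, true ISR spans ≈ 2.5–5.0, the range real panels show |
| roughness_range    | (0.8, 1.2)  | ~1 kcal/mol decoy spread typical of MM/GBSA rescoring noise |
| affinity_base      | −8          | mid-range small-molecule/peptide binding free energy |
| barrier_base       | 18          | typical enzymatic barrier for s⁻¹–ms⁻¹ chemistry |
| coupling           | 2           | mutations span ~2 kcal/mol in each energy — alanine-scan scale |
| noise_sd_affinity  | 0.3         | affinity is the better-determined quantity |
| noise_sd_barrier   | 1.5         | barrier estimates are the noisier quantity; dominance over the affinity noise produces the low direct ISR–affinity correlation and the strong conditional one |
| noise_sd_activity  | 2.5 (preset "paper-like") | calibrated once (500 panels) so the ISR vs ln(kcat/Km) Pearson R distribution over default panels has median ≈ 0.77 and central 80% ≈ [0.60, 0.89], inside [0.55, 0.92] |
| temperature        | 298.15 K    | standard state |

Randomness: one root `seed` feeds a `numpy.random.SeedSequence`; child 0
drives panel-level draws, children 1..n the per-variant ensembles, so
streams are independent and any subset is reproducible.

What the generator does **not** emulate: pose geometries, docking scoring
physics, correlated (non-Gaussian) decoy energies, multi-substrate panels,
mechanism changes upon mutation (it assumes every variant shares the
wild-type mechanism), or entropy differences between variants. Passing
tests on synthetic panels therefore validate the statistical machinery —
estimator correctness, calibration, conditioning logic — not the physical
claim that ISR predicts activity for any particular enzyme.

## Problem sizes used in the checks

The test suite and the acceptance script use: 100 default panels (12 × 1000
poses) for parameter recovery; 200 panels for the ISR–activity correlation
distribution and for the paired conditional-filter comparison (sign test);
200 ensembles × 1000 bootstrap resamples for coverage; 100,000 decoys for
the large-N consistency check; 1000 random affine transforms for the
invariance check. These sizes give Monte-Carlo error well below each
check's tolerance while keeping a full run in seconds.

## Known limitations

- The ISR point estimate is biased upward by the native-floor truncation
  when the true gap/roughness ratio is small (~9% at g/σ = 2 if the decoy
  cloud is generated with rejection); real funnels with ISR ≳ 3 are barely
  affected.
- Percentile-bootstrap intervals undercover slightly (see above).
- `filter_by_reference` requires the filter field on every record — panels
  with missing barriers must be subset beforehand.
- Hot-spot thresholds are system-specific free parameters, not derived
  quantities.
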