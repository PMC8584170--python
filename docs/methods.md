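# Methods

## Assay model

The pipeline models an ATP-depletion readout: a nucleoside kinase transfers
the γ-phosphate of a donor NTP to a nucleoside, and the luciferase signal of
a well is taken to be linear in the residual donor concentration over the
calibrated range (0–500 µM). Activity is therefore inferred from signal
*loss* relative to a same-plate negative control. Three control types anchor
the quantification:

* **negative control** (substrate + donor, no enzyme): the full-donor signal
  *N*, which also absorbs nonenzymatic donor degradation, since that occurs
  with or without enzyme;
* **substrate control** (substrate only, no donor): the background signal
  *S* of the substrate itself (autoluminescence); normally ≈ 0;
* **basal-activity control** (enzyme + donor, no substrate): substrate-
  independent donor consumption by the enzyme; its difference from the
  negative control is the correction *B* = *N* − basal, floored at 0.

Consumed donor is `100 − 100·(R + B + S)/(N + S)` and product formation is
that value times the donor:substrate molar ratio; both are clamped to
0–100 % after each step. Two modelling choices deserve note:

* *S enters the numerator with a positive sign*, exactly as the assay
  formula is conventionally written. For a luminescent substrate this makes
  apparent consumption drop asymmetrically — arguably an anomaly, but we
  implement the formula as used rather than a reinterpretation, and the
  interference checks exist to catch luminescent substrates before
  quantification is trusted.
* *B = N − basal with that operand order*: this makes B a positive
  correction exactly when the enzyme consumes donor without substrate, the
  only physically sensible direction.

Clamping is applied to both the consumed and the product percentage, and the
replicate spread (`sd_pct`) pushes each replicate through both equations
before a single final clamp; the group mean clamps after each equation.
Controls are averaged before any reaction math.

### Stoichiometric multiplier

With 400 µM donor and 330–333 µM substrate the donor:substrate ratio rounds
to 1.2 at two significant figures, the conventional product multiplier;
`stoichiometric_ratio()` computes it for arbitrary setups. `quantify_plate`
takes the ratio as an explicit argument rather than silently rounding,
because the rounded value carries a ~0.1 % bias relative to the exact
400/333 stoichiometry — negligible on real plates, but the exact value is
what makes noiseless simulated luminescence and HPLC results agree to
machine precision, which is how the two estimator paths are verified against
each other.

### Verification flag

Product values strictly between 0 and 10 % set `flag_verify`. The flag means
"confirm by HPLC or repeat at higher enzyme load", never automatic zeroing:
at low conversions the depletion readout's relative error is largest and
false positives concentrate there. Exactly 0 % is not flagged (nothing to
verify).

## Quality control

Z′ is computed per plate from the negative controls (top of the assay
window) and the substrate controls (bottom), with sample standard deviations
(n − 1). The pipeline's default pass threshold is Z′ ≥ 0.5, the common
screening convention; the statistic itself is reported so other cutoffs can
be applied downstream. Interference checks operationalize "does compound X
shift the luminescence at fixed ATP" as: relative mean shift above 10 %, or
a Welch two-sample rejection at α = 0.05 combined with a shift above 5 %
(significance alone is not interference if the effect is negligible). The
AMP titration check compares mixed AMP/ATP standards against the signal
predicted for their ATP content, from a fitted ATP curve or from AMP-free
levels.

## HPLC quantification

Peaks are labeled by nearest expected retention time within a tolerance
(default 0.3 min). The retention library refuses methods whose expected
times are within 2× tolerance of each other, which is also what makes a peak
equidistant between two analytes impossible for a valid library. Missing
ADP/AMP peaks count as zero area (low-conversion samples often show none);
a zero total pool is a hard error. Quantification is ratio-based within the
adenosine pool (consumed ATP) and within the substrate/product pool
(product), so it is invariant to the detector's absolute response.

## The synthetic-data generator

`simulate_plate` emulates, per well and before noise:

| quantity | default | meaning |
|---|---|---|
| `donor_conc` | 400 µM | donor concentration of reactions and negative/basal controls |
| `substrate_conc` | 333 µM | nucleoside concentration |
| `true_conversion` | per-pair map | fraction of substrate converted (ground truth) |
| `basal_consumption` | 0.02 | donor fraction consumed by enzyme without substrate |
| `atp_degradation` | 0.01 | donor fraction degraded nonenzymatically to AMP |
| `noise_cv` | 0.03 | multiplicative Gaussian well noise (plate-reader repeatability) |
| `n_replicates` / `n_standard_replicates` | 3 / 2 | reaction and standard replication |

Donor response slopes are set so the 500 µM signals reproduce the
luciferase's donor preference (ATP 57 892 RLU ≫ dATP 1128 > GTP 504 >
UTP 220 > CTP 161 > dGTP/dCTP/TTP ≈ 20, i.e. below the 30 RLU acceptance
floor). The default conversion map emulates a human deoxycytidine kinase
natural-substrate panel: high turnover of dCyd/dAdo/dGuo/Cyd, a ~13 %
thymidine side activity, none on Ado/Guo/Urd. Measurement noise is not a
published instrument property; 3 % CV is typical plate-reader repeatability
and is a config field. Consumed donor is routed to ADP in the simulated
chromatogram (single phosphoryl transfer), degradation to AMP, converted
substrate to its monophosphate. Standard levels {0, 50, 100, 200, 300, 400,
500} µM span the calibrated range; placement is column-major with controls
following their reaction block. Controls are shared where chemistry allows
(negative per substrate × donor, substrate control per substrate, basal per
enzyme × donor), as on a bench plate.

Closed-form expectations (`expected_lum_quantification`,
`expected_hplc_quantification`) give what each estimator returns on a
noiseless plate; with basal consumption *b* and degradation *d* the
luminescence route returns the enzymatic consumed fraction rescaled by
1/(1 − d) while HPLC counts all ATP loss (enzymatic + basal + degraded), so
the two methods genuinely differ by a few points under the default
conditions — matching the single-digit method deviations the assay is
expected to show — and coincide exactly only for ideal chemistry
(b = d = 0). The adenosine-substrate case is special: its product *is* AMP,
so the degradation AMP peak contaminates the product pool (~1 % apparent
product at zero conversion). The generator refuses to emit chromatograms for
adenosine substrates with nonzero conversion (the pools are not separable),
and the closed form exposes the contamination via `amp_is_product`.

### What the generator does not emulate

No kinetics (end-point conversions only), no spatial plate effects (edge
evaporation, drift), no carry-over, no nonlinearity or saturation of the
luciferase response, and no chromatographic peak shape — peak tables are
consumed as already integrated. Passing tests therefore demonstrate that the
estimators are correct for the assay's statistical model, not that a
particular instrument satisfies that model.

## Numerical choices

Standard curves are ordinary least squares on all replicate points (not
level means), intercept free, so r² reflects replicate scatter; a constant
response reports r² = 0. Curve inversion clips to [0, calibrated max] and
flags extrapolation. Donor ranking breaks ties alphabetically. The Z′
denominator is a hard error when the control means coincide. Problem sizes
in tests (one 89-well plate per seed, 200 seeds for recovery and specificity
studies) keep the whole suite in seconds while giving ≈ 1600 pair estimates
for the recovery rate; measured at the default conditions, ~97.5 % of
estimates land within 5 points of the closed-form truth.

## Known limitations

The layout reader accepts comma-thousands numbers ("57,892") but does not
auto-detect dot-thousands ("57.892"), which is ambiguous with decimals; a
`--decimal-style de` override handles exports from German-locale software.
Whether clamping should precede or follow replicate averaging is not
standardized; we clamp the group mean after each equation and clamp
per-replicate values only once, after both equations. Basal controls are
optional: without them B = 0 and apparent consumption is biased upward by
the enzyme's substrate-free donor turnover.
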