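# Methods

## Response models

Inhibition of viability is the fraction `I = 1 − V`, where relative
viability `V` is the background-corrected absorbance (A490 − A750) of a
treated well over the mean corrected absorbance of same-plate vehicle
controls (for raw-intensity tables, raw intensity over mean control
intensity). All concentrations are handled internally in nanomolar and all
responses as fractions; percent appears only in report columns.

Two models of `I(D)` are fit jointly to every curve:

* **Hill**: `I = I_max · Dⁿ / (IC₅₀*ⁿ + Dⁿ)` — `I_max` the asymptotic
  inhibition, `IC₅₀*` the half-effect dose of the drug-sensitive fraction,
  `n` the slope. `I_max` is bounded at 1 (100 %).
* **Biphasic (two-site)**: `I = F₁·D/(D+K_d1) + F₂·D/(D+K_d2)` with
  `F₂ = 1 − F₁` derived, never free, and `K_d2 ≥ K_d1` by construction —
  phase 1 is always the high-affinity, target-specific phase, phase 2 the
  off-target phase. This removes label switching.

The mechanistic distinction the two models encode: the Hill model explains
a shallow curve as single-site binding with negative cooperativity
(n < 1), the biphasic model as the blend of a partial target-specific
inhibition and a weaker off-target one. A pure single-site response is the
common special case of both (n = 1, F₂ = 0).

## Fitting

The objective is the unweighted RMSE between model and the
per-concentration *mean* inhibition (replicate-level fitting is available
via `use_replicates=True`; the default mirrors the one-curve-per-drug
convention of screening analyses). Replicate values are never clamped
before fitting — sub-zero and supra-one excursions are informative noise;
clamping to [0, 1] happens only at the IC_x-interpolation/plotting
boundary, where a fraction is semantically required.

Optimization is deterministic multi-start L-BFGS-B:

* Hill: 15 starts (5 log-spaced IC₅₀* values × n ∈ {0.5, 1, 2}), bounds
  I_max ∈ [0, 1], IC₅₀* ∈ [0.1 nM, 100 µM] (log10 scale), n ∈ [0.1, 5].
* Biphasic: 32 starts over F₁ ∈ {0.3, 0.6, 0.9, 1.0}, log10 K_d1 ∈
  {0.5, 1.5, 2.5, 3.5}, log10(K_d2/K_d1) ∈ {1.5, 3.5}; the free
  parameters are (F₁, log10 K_d1, log10 K_d2/K_d1 ≥ 0).

The dissociation-constant box [0.1 nM, 100 µM] reflects the assay window
(0.6 nM – ~20 µM): affinities well outside it are unidentifiable. A K_d2
pinned at the upper bound is flagged *censored* and printed ">100" (µM);
forward evaluation uses the bound value, so censored rows round-trip
through fit tables.

### Second-phase detectability

Two post-processing rules make the two-phase fit well behaved on
single-phase data, where the parametrization is degenerate:

1. **Canonical relabeling.** If the fitted F₁ ≤ 0.005, all amplitude sits
   in phase 2 — the identical single-phase model with swapped labels — and
   the fit is relabeled so the surviving phase is phase 1 (mirror of the
   F₁ ≥ 0.995 rule below).
2. **Extra-sum-of-squares F-test** (default, `phase_test="ftest"`). The
   two-phase optimum (3 parameters) is kept only if it fits significantly
   better than the nested one-phase fit `I = a·D/(D+K)` (2 parameters).
   Otherwise the one-phase fit is returned with the second phase flagged
   absent. Without this, RMSE minimization rewards any sub-noise second
   phase (a median RMSE gain of ~3 × 10⁻⁴ at σ = 0.02) and scatters F₁
   essentially uniformly on monophasic data. The test level defaults to
   α = 0.01 rather than the nominal 0.05 because the two-phase optimum is
   selected across a multi-start search with boundary parameters, which
   makes the nominal F-test anti-conservative. `phase_test=None` restores
   the raw RMSE minimizer (the spreadsheet-Solver-style procedure), which
   is also what the optimizer-vs-grid-oracle tests exercise.

When the two-phase model is kept, F₁ ≥ 0.995 still flags the second phase
absent (printed "None"). Phases whose K_d's lie within about 10-fold of
each other are not separately identifiable — parameter-recovery guarantees
are only claimed for K_d2/K_d1 ≥ 10.

Model comparison reports both RMSEs and their ratio; ratios within 10 % of
unity are called "comparable" (the data cannot statistically distinguish
the models, and mechanism must be argued on other grounds).

## Driver classification

Three criteria are evaluated per (cell line, drug), each against
configurable thresholds, as mono-like / multi-like / intermediate:

| criterion | mono-like | multi-like | default cuts |
| --- | --- | --- | --- |
| F₁ | > f1_hi | ≤ f1_lo | f1_hi = 0.85, f1_lo = 0.80 |
| Hill n | ≥ n_hi | ≤ n_lo | n_hi = 0.90, n_lo = 0.85 |
| IC₅₀*/K_d1 | ≤ r_lo | ≥ r_hi | r_lo = 3, r_hi = 1.1 |

The verdict is *mono* only when all three are mono-like, *multi* only when
all three are multi-like, *indeterminate* otherwise. The defaults were
calibrated on the bundled 25-row reference panel of published joint fits
(three colorectal, two TNBC, one lung, one leukemia cell line, plus the
seven DU-4475 responses) so that every row reproduces its known verdict;
the bands deliberately leave an indeterminate gap rather than forcing a
binary cut. Notes on individual cuts: the mono slope band starts at 0.90,
not 1.0, because a noiseless single-site response has n exactly 1 and a
cut at 1.0 would misclassify half of all noisy mono responses; the
multi-side potency band (r_hi = 1.1) is permissive because the published
multi-driver rows include potency ratios as low as 1.14 — the ratio
criterion mostly vetoes, while F₁ and n carry the separation.

Cell-line aggregation: *mono* if ≥ 1 drug gives a mono verdict with
near-full inhibition (I_max ≥ 0.85); *multi* if ≥ 2 drugs with distinct
declared targets give multi verdicts; else indeterminate. Drug→target
labels are explicit inputs (they come from external binding panels, never
from the fits).

## Synergy quantification

Empirical IC_x is the dose at which the clamped mean-inhibition curve
crosses level x, by linear interpolation on log10(dose) between the first
bracketing grid pair — a reproducible stand-in for reading values off a
graph; model-based inversion (`ic_x_model`) is provided as a cross-check.
If the curve never reaches the level, the IC_x is flagged unattainable.

For a 1:1 equal-molar mixture dosed at D *per drug* (totals are never
summed), the combination index at level x is `CI = D/IC_x1 + D/IC_x2` and
the pooled dose-reduction index is its reciprocal,
`DRI = IC_x1·IC_x2/(IC_x_combo·(IC_x1 + IC_x2))`; per-drug reductions
`IC_xi/IC_x_combo` are reported alongside, since the pooled formula and
the per-drug reading are both in circulation. DRI/CI are reported only
when all three IC_x values are attainable; otherwise the report carries an
explicit "not calculable" note naming the offending curve. Isobologram
records contain the single-agent intercepts, the additivity line, the
combination point, and the interaction index `d₁/IC_x1 + d₂/IC_x2`
(< 1 synergy, = 1 additive, > 1 antagonism).

Combination ranking scores drug pairs with distinct target labels by
combined target-specific coverage `min(F₁ₐ + F₁ᵦ, 1)` (descending), then
by the larger K_d1 (the potency bottleneck, ascending); same-target pairs
are excluded.

## Synthetic data generator

The generator emulates the screening design the analysis assumes:

* dose grid: 16 two-fold dilutions from 0.6 nM (top 0.6 × 2¹⁵ ≈ 19.66 µM)
  — the unique standard series with 16 points spanning ~0.6 nM–20 µM;
* 3 replicates per concentration;
* additive i.i.d. Gaussian noise on the inhibition scale, σ = 0.02 by
  default, bracketing the residual RMSEs (0.018–0.11) of well-fit
  published curves;
* deterministic under a fixed seed; `simulate_plate` emits raw A490/A750
  wells (clean baseline controls) that normalize back to exactly the same
  inhibition draws as the direct curve simulation under the same seed.

Combination ground truths come in two forms. *Independent action*
multiplies survival terms, one per driver-specific phase and one per
off-target phase: `V(D) = Π (1 − f_k·D/(D+K_k))`. This is a simulation
assumption of this package — a plausible generative model for drivers
acting through distinct pathways — not an estimate of any published
combination curve, and it is never used as an oracle against published
numbers. Note its semantics: phases *within* one drug combine additively
in the biphasic monotherapy model but multiplicatively across the product,
so a combination containing one biphasic drug and a null partner differs
from that drug's monotherapy curve by the cross-term (they coincide
exactly for single-phase drugs). *Loewe additivity* constructs the
zero-interaction null by dose equivalence (solving
`D/D_A(I) + D/D_B(I) = 1` for I at each mixture dose); its isobologram
interaction index is 1 by construction, up to interpolation error, which
is what the additivity tests check.

What passing tests on these simulations do **not** show about real data:
real replicate noise is neither homoscedastic nor independent across a
plate (edge effects, batch drift); real off-target phases need not be
single-site; and real combination responses have no reason to follow
independent action exactly. Recovery tolerances (median F₁ within ±5
percentage points, median K_d1 within ±20 % over 20 seeds) are claims
about this noise model at these sample sizes.

## Numerical choices and degenerate inputs

* Biphasic inversion uses bracketed Brent root-finding at 10⁻¹² relative
  tolerance; targets at or above the model asymptote raise an
  "unreachable inhibition level" error.
* IC_x interpolation warns and uses the first crossing when noise makes
  the mean curve cross a level more than once, and warns when the lowest
  dose is already above the level (the lowest dose is then an upper-bound
  estimate).
* Negative corrected absorbances warn but are retained (they normalize to
  I > 1, which the fit treats as noise).
* Specificity folds propagate censoring: if the less sensitive cell line
  never reaches the level, the fold is reported as a lower bound from its
  top dose; the level being unattainable on the *sensitive* line is an
  error.
* Fit tables print ≥ 6 significant digits; JSON reports embed the package
  version, seed, and a content-based config hash, and identical
  config + seed reruns are byte-identical.

## Problem sizes

The test suite and the acceptance script use the study's own scale: 16
concentrations × 3 replicates per curve, 20 seeds per recovery experiment,
30 seeds per classification-robustness experiment, and a 40×40×40 grid for
the independent grid-search oracle. These sizes are the package's
reference protocol; everything completes in well under a minute per
experiment on one CPU.

## Known limitations

* No confidence intervals or bootstrap on fitted parameters (point
  estimates only, as in the source procedure) and no AIC/BIC model
  selection; the only inferential step is the phase-detectability F-test.
* No three-or-more-phase models; responses with ≥ 3 separable phases are
  outside scope.
* No plate-layout effects, growth kinetics, or mechanistic signaling
  simulation.
* Classification thresholds are calibrated on a 25-row panel; they are
  exposed in full and echoed in every report precisely because other
  panels may need different cuts.
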