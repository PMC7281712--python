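# biphasic

Biphasic dose–response analysis and synergistic combination design for
multi-driver cancer cells.

## The problem

Targeted therapy works when a cancer depends on one dominant driver; most
cancers — triple negative breast cancer prominently among them — depend on
several. When a kinase inhibitor is screened against such a *multi-driver*
cell line, the viability curve is characteristically shallow and often
visibly two-phased: a partial, potent inhibition at low nanomolar doses
(the drug's actual target supports only part of viability) followed by a
second rise at micromolar doses (off-target toxicity). The classical Hill
analysis absorbs this structure into an apparent negative cooperativity
(Hill coefficient n < 1) and an inflated IC₅₀, and so both mis-describes
the mechanism and overstates the useful potency of single agents.

This package implements the alternative two-site analysis and everything
around it:

* **Models** — the Hill equation `I = I_max·Dⁿ/(IC₅₀*ⁿ + Dⁿ)` and the
  biphasic model `I = F₁·D/(D+K_d1) + F₂·D/(D+K_d2)` with `F₂ = 1 − F₁`,
  where F₁/K_d1 quantify the target-specific phase and F₂/K_d2 the
  off-target phase; closed-form/rootfinding inverses for model-based IC_x.
* **Fitting** — RMSE-minimizing multi-start bounded optimization on
  log-scaled dissociation constants (0.1 nM – 100 µM, the upper bound
  realizing the ">100 µM" censoring convention), K_d2 ≥ K_d1 by
  construction, and an extra-sum-of-squares F-test that keeps the second
  phase only when the data can actually detect it.
* **Driver classification** — mono- vs multi-driver verdicts from the
  joint fits: mono-driver responses show F₁ ≈ 100 %, n ≥ 1, and
  IC₅₀* ≈ K_d1; multi-driver responses show partial F₁, n < 1, and a
  low-nM K_d1 far below the IC₅₀*.
* **Synergy** — empirical IC_x by log-linear interpolation, the
  Chou–Talalay dose-reduction index `DRI = IC_x1·IC_x2 / (IC_x1+2·(IC_x1+IC_x2))`
  and combination index `CI = 1/DRI` for 1:1 (equal-molar) mixtures,
  isobologram coordinates, cell-specificity fold-differences, and ranking
  of candidate combinations by combined target coverage
  `min(F₁ₐ+F₁ᵦ, 1)`.
* **Synthetic plates** — a generator reproducing the screening design the
  analysis assumes (16 two-fold dilutions from 0.6 nM to ~20 µM,
  triplicates, Gaussian replicate noise σ = 0.02) under mono-driver,
  multi-driver, and combination ground truths, down to raw A490/A750
  wells and control-based normalization (`I = 1 − V`,
  `V = (A490−A750)_treated / mean(A490−A750)_control`).

It is intended for cell-biology and drug-discovery groups analyzing
viability screens (plate reader or GDSC-style tables) who want a
reproducible, scriptable version of this analysis.

## Worked example

Simulate a multi-driver cell line carrying two partial drivers — a
Src-family driver (F₁ = 49 %, K_d1 = 29.9 nM, off-target K_d2 = 9.3 µM)
and a Mek driver (F₁ = 36 %, K_d1 = 91 nM, no off-target phase within the
assay window) — then fit, classify, and design the combination:

```python
from biphasic import (
    BiphasicParams, simulate_monotherapy, simulate_combination,
    fit_hill, fit_biphasic, classify_response, rank_combinations, ic_x,
)

das = BiphasicParams(f1=0.49, kd1_nm=29.9, kd2_nm=9300.0)
azd = BiphasicParams(f1=0.36, kd1_nm=91.0, kd2_nm=1e5, kd2_censored=True)

curves = {
    "dasatinib": simulate_monotherapy(das, treatment="dasatinib", seed=1),
    "AZD-6244": simulate_monotherapy(azd, treatment="AZD-6244", seed=2),
}
for name, curve in curves.items():
    h, b = fit_hill(curve), fit_biphasic(curve)
    cl = classify_response(h, b)
    print(name, h.params, b.params, cl.verdict)
```

which prints (reformatted):

```
dasatinib   Hill: I_max=90% IC50*=357 nM n=0.46 | biphasic: F1=48% Kd1=28.4 nM Kd2=8.6 uM -> multi-driver pattern
AZD-6244    Hill: I_max=44% IC50*=161 nM n=0.73 | biphasic: F1=35% Kd1=79.4 nM Kd2=>100 uM -> multi-driver pattern
```

Both fits recover the generating truth: partial F₁, shallow Hill slopes
(n ≪ 1), and IC₅₀* values roughly 2–13× above the true K_d1 — the
multi-driver signature. Ranking combinations by combined target coverage,

```python
pairs = rank_combinations(
    {n: fit_biphasic(c).params for n, c in curves.items()},
    {"dasatinib": "Src", "AZD-6244": "Mek"})
print(pairs[0])
```

```
top combination: AZD-6244 + dasatinib (coverage 82%, bottleneck Kd1 79 nM)
```

i.e. hitting both drivers at once should remove ~82 % of viability at
low-nM doses. Simulating that 1:1 combination under independent action
across drivers and reading empirical IC values off the curves:

```
IC50%: dasatinib alone 647 nM, combination 113 nM/drug (6-fold dose reduction)
IC70%: dasatinib alone 6334 nM, combination 2439 nM/drug (3-fold dose reduction)
IC50% DRI: not calculable — level unattainable for AZD-6244 alone
```

The pooled Chou–Talalay DRI is reported absent here because the Mek
inhibitor alone never reaches 50 % inhibition (its F₁ is 36 %) — exactly
the situation in which single-agent IC₅₀ comparisons are the honest
fallback.

The same workflow is available from the shell — `biphasic simulate / fit /
classify / synergy / report` — reading long-format curve CSVs and writing
tidy fit tables (Hill RMSE, I_max %, IC₅₀*, n, biphasic RMSE, F₁/F₂,
K_d1, K_d2 with ">100" and "None" conventions), classification CSVs, and
synergy/isobologram JSON+CSV; see `biphasic --help`.

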