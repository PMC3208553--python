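# phagofit

Model-based separation of **phagocytosis** from **adsorption** in two-channel
flow-cytometric uptake assays.

## The problem

In ex vivo phagocytosis assays, macrophages are exposed to fluorescently
labeled targets (e.g. DIO-labeled platelets) and stained with an antibody
against a target surface marker (e.g. PE-anti-CD61). Gating the two-channel
plot splits the cells into quadrant 1 (marker-negative cells with uptake
fluorescence above the negative-control mean: phagocytosis without surface
targets) and quadrants 2+3 (all marker-positive cells: at least one adsorbed
target, with or without uptake). Simply discarding the marker-positive cells
is biased — how many cells adsorb targets and how many internalize them are
coupled quantities — and quenching of internalized-target fluorescence makes
the uptake-positive population overlap the negative control.

`phagofit` fits a three-parameter generative model to the two observed
quadrant fractions:

- **m** — functional target:macrophage ratio; a macrophage receives
  `n ~ Poisson(m)` adsorption hits, `P(n) = e^{-m} m^n / n!`;
- **p** — probability that any single adsorbed target is internalized,
  independent across hits, so a cell shows *only* phagocytosis with
  probability `p^n`;
- **α** — mean log-fluorescence shift per internalized target, in units of
  the negative-control log SD.

Predicted fractions (hit classes truncated at n_max = 12, valid for m < 6.5):

```
Q(2+3) = Σ_{n=1}^{12} P(n) (1 − p^n)          →  1 − e^{−m(1−p)}  as n_max → ∞
Q1     = Σ_{n=0}^{12} P(n) p^n Φ(n·α)
```

where Φ is the standard normal CDF and the uptake gate sits at the
negative-control log mean (so the n = 0 term contributes `e^{−m}/2`).

The inverse problem is solved by an exhaustive scan: a 20×20×20 grid of
(p, α, m) — 8000 points at the standard resolutions p = 0.04, α = 0.15,
m = 0.0625 — scored by the relative residual sum
`Rt = |Q1−Q1̂|/Q1 + |Q23−Q23̂|/Q23`. Because two observables constrain three
parameters, solutions lie on a ridge; the deliverable is the set of **local
Rt minima** along m, and experimental conditions are compared by
nearest-neighbor matching of those minima (changes in labeling intensity,
target ratio, and opsonization map onto α, m, and p respectively).

A per-cell Monte Carlo simulator generates synthetic event tables under the
same assumptions, closing the loop: simulate → gate → scan → recover.

## Worked example

```
$ python examples/simulate_and_fit.py
simulated truth: m=1.5, p=0.48, alpha=1.6
observed fractions: Q1=0.3395, Q2+3=0.5428
scan: 8000 grid points, 5 local Rt minima

label        m      p   alpha        Rt
LM1     1.3750   0.44    3.25    0.0196
LM2     1.5000   0.48    1.75    0.0049  <- truth
LM3     1.6250   0.52    1.15    0.0055
LM4     1.7500   0.56    0.85    0.0134
LM5     1.9375   0.60    0.70    0.0068
```

100,000 cells were simulated at a known truth, gated against a simulated
negative control, and scanned. Five local minima trace the model's ridge;
the one at the simulated truth fits the data to ~0.5% — the level of
counting noise — and the others show how m can trade off against p and α.
`examples/forward_model.py` prints the forward predictions at the reference
fit (Q2+3 = 0.4324, Q1 = 0.5094), and `examples/compare_conditions.py`
attributes a simulated opsonization effect (p 0.48 → 0.68) to p by
nearest-neighbor minima matching.

The same pipeline is scriptable from a shell:

```
phagofit simulate --m 1.5 --p 0.48 --alpha 1.6 --seed 11 --out run/
phagofit fit --events run/events.csv --control run/control.csv --out fit/
phagofit compare --minima-a fit/minima.json --minima-b fit2/minima.json --out cmp/
```

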