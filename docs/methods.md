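# Methods

## Generative model

A macrophage exposed to fluorescent targets receives `n` adsorption "hits"
with `n ~ Poisson(m)`. The functional ratio `m` is proportional to — not
equal to — the input target:macrophage ratio, since not every target
contacts a macrophage. Each hit is internalized independently with
probability `p` (no cooperative or saturating uptake), so the number
internalized is `k | n ~ Binomial(n, p)` and a cell retains a surface target
(is adsorption-marker positive, quadrants 2+3) iff `k < n`. Marginally the
retained hits are Poisson with mean `m(1−p)`, giving the closed form
`Q(2+3) = 1 − e^{−m(1−p)}`.

Uptake fluorescence is treated in the log domain. The negative control
(macrophages without targets) is lognormal with log-mean `FI_neg` and log-SD
`σ`; each internalized target shifts a cell's log fluorescence by `α·σ`
while leaving the spread unchanged, so the marker-negative population is a
mixture of normals at `FI_neg + n·α·σ`, weighted `P(n)·p^n`. With the uptake
gate at `FI_neg`, the fraction of the `n`-hit fully-internalized class above
the gate is `Φ(n·α)`, whence
`Q1 = Σ_{n≥0} P(n) p^n Φ(n·α)` (the n = 0 term is `e^{−m}/2`). All internal
logs are natural; because `α` and the gate are defined in SD-normalized log
units, every fitted quantity is invariant to the log base used for display
(log10 values convert by ×ln 10).

An alternative convention reads the marker-negative above-gate fraction at
these parameters as ≈0.405 rather than the 0.509 this rule yields; the exact
rule behind that figure is not recoverable from its source, so this package
adopts the gate-crossing formula above, which follows directly from the
mixture assumption, and treats 0.405 as a documented discrepancy rather than
a target.

## Truncation and parameter bounds

The hit-class sums are truncated at `n_max = 12` (configurable). At the scan
bound `m < 6.5` the cumulative Poisson mass of twelve or fewer hits exceeds
0.98, and the truncated `Q(2+3)` lies within 0.02 of the closed form over
the whole working range (it converges from below). Grids refusing `m ≥ 6.5`
protect this guarantee. `p` is a probability; `α` is capped at 4.5 because
larger shifts imply visibly multimodal marker-negative histograms that
typical assays do not show. The forward model itself accepts any `m > 0`,
`α ≥ 0`, including the degenerate `p ∈ {0, 1}`.

## Inverse problem

The fit objective is `Rt = R1 + R2` with relative residuals
`R1 = |Q1 − Q1̂|/Q1`, `R2 = |Q23 − Q23̂|/Q23`. An exhaustive rectangular scan
(default 20 points per axis, 8000 evaluations, vectorized) records residuals
at every point in m-major/α/p order. Per (m, α) line the minimum of `Rt`
over p is kept (`Rtmin(j,k)` at `Ptmin(j,k)`; the marginal `R1min`/`R2min`
and their p's are reported too, but the objective is always minimized at a
single point); per m-plane the minimum over (p, α) gives the `Rtmin(k)`
curve. Ties break toward the smallest p, then the smallest α —
deterministic everywhere.

Two observables cannot pin three parameters: exact solutions form a
one-dimensional ridge, which the finite grid cuts into several **local
minima** of `Rtmin(k)` (interior planes strictly below both m-neighbors;
plateaus are reported once at their lowest m and flagged). No global
optimum is declared and no continuous optimizer is used; the coarse p-grid
actually aids identifiability, because neighboring m-planes cannot re-tune
p finely enough to hide the truth plane. Default resolutions are p = 0.04
and α = 0.15, below which scans develop narrowly spaced ripple minima;
m = 0.0625 with optional 0.01 refinement windows. Refinement of the α range
to follow minima found at coarse resolution is left to the user, as no
automatic schedule is well defined.

## Condition comparison

Replicate conditions are compared through their local minima, not through
single best fits, because minima wander along the ridge. Pairing is greedy
nearest-neighbor on a chosen axis with surplus minima reported. Attribution
of a between-condition change is two-stage:

1. `Q(2+3)` is independent of α, so a material change in the fitted
   adsorption-positive fraction (|Δ| ≥ 0.02, well above the ~0.005 counting
   noise plus gate leakage at 10⁵ events and below the effect of any
   meaningful m or p change) implicates m or p; an unchanged `Q(2+3)`
   implicates α.
2. m and p are separated by ridge-controlled comparisons: nearest-m pairs
   read Δp (a constant-ratio comparison), nearest-α pairs read Δm (a
   constant-labeling comparison); the larger median delta in grid-step units
   wins. A plain nearest-m pairing cannot attribute an m-shift — it pairs
   minima at similar m by construction — which is why the constant-α
   comparison exists.

## Data handling

Event tables are CSV exports of linear scale values (`uptake_fi`,
`marker_fi`); CSV is the only ingest path, matching how such data is
exported as text in practice. Automated instrument baselining can produce
negative scale values; each channel of each file with a minimum ≤ 0 is
shifted by `|min| + ε` with ε = 1 scale unit — the smallest change that
keeps the established per-file correction rule while leaving the minimum
strictly positive for the log transform. Correction constants and gate
provenance are recorded. The uptake gate is placed at the control's log
mean (geometric-mean position — identical to the median under the
lognormality assumption, and the model's reference point), putting 50% of
the control in Q1; the marker gate is the 0.995 quantile of the control's
marker channel. Where exactly the marker gate falls barely matters because
Q2 and Q3 are always pooled; the quantile is configurable.

## Simulator

The simulator draws `n ~ Poisson(m)` untruncated (truncation is a
fitting-side approximation only), `k ~ Binomial(n, p)`, uptake log-FI
`Normal(FI_neg + k·α·σ, σ)`, and a marker channel from a two-component
lognormal: baseline `Normal(3.0, 0.5)` in natural-log units, shifted by 6
SDs for cells retaining surface targets. The 6-SD separation reflects a
bright adsorption antibody and makes the vertical gate unambiguous; since
marker positivity is treated as binary, nothing downstream depends on the
exact shift. Uptake FI of marker-positive cells uses the same k-shift (their
uptake values never enter the fit). Seeds are mandatory; identical
configurations give bitwise-identical tables.

What the simulator deliberately omits — target aggregation/multimers,
n-dependent p, heterogeneous macrophage capacity, heavy-tailed fluorescence
— are exactly the mechanisms suspected behind the high-FI tails that the
mixture model underestimates in real data. Passing closed-loop tests
therefore demonstrates correctness of the inference machinery under the
model's own assumptions, not robustness to their violation.

## Validation scenarios and problem sizes

Closed-loop experiments use 10⁵ cells per condition (quadrant-fraction
counting SD ≈ 0.0016, well inside one grid step) and a reference control of
log10 mean 4.57, log10 SD 0.29. Ten recovery truths span m ∈ [1, 3],
p ∈ [0.32, 0.72], α ∈ [1.0, 1.9]. The α range is a sensitivity decision
made at design time: above α ≈ 2 the gate-crossing terms `Φ(n·α)` saturate,
one α grid step moves `Q1` by less than counting noise plus the 0.5%
marker-gate leakage, and α is then identified only up to the ridge — the
regime in which only matched-minima comparisons, not point recovery, are
meaningful. Discrimination pairs change one parameter by 4–12 grid steps
(p 0.48→0.68, m 1.5→2.25, α 1.0→1.75), emulating opsonization, a higher
target dose, and brighter labeling.

## Known limitations

- Only two observed quantities enter the fit; the ridge degeneracy is
  intrinsic and all conclusions should be drawn from matched minima across
  controlled conditions, never from a single "best" (m, p, α).
- Relative residuals are undefined for zero observed fractions; such data
  needs re-gating or an absolute-residual variant, which is intentionally
  not silently substituted.
- The marker gate's false-positive rate (1 − quantile) slightly inflates
  observed Q2+3 and deflates Q1; at the defaults this is a ~0.5% relative
  effect, negligible for p and m but visible in α at low sensitivity.
- No compensation, doublet exclusion or scatter gating: input tables are
  assumed to already contain the macrophage population of interest.
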