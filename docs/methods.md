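# Methods

This note documents the models implemented in `spheroquant`, the
parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical choices that a
maintainer would otherwise have to reverse-engineer.

## Thermal dose

Heating protocols are converted to CEM43 (cumulative equivalent minutes
at 43 °C) segment by segment: `duration · R^(43 − T)`, summed over
segments, with the per-degree factor `R` switching at the 43 °C
breakpoint. Defaults are the classic convention `R = 0.5` above and
`0.25` at or below 43 °C; both are exposed (`SapareroBreakpoints`) so a
cell-line-specific conversion can be substituted. Temperatures are
restricted to 20–50 °C — the range over which the thermal-dose concept is
considered valid — and out-of-range segments are rejected rather than
extrapolated. The sum is additive over concatenation by construction,
which the tests exercise as a property.

## Combined survival model

Clonogenic survival under a radiation dose `D` (Gy) plus thermal dose `H`
(CEM43) is

    S(D, H) = exp(−(a·H + b·H²) − α₀·(1 + c·H)·D − β·D²)

This is the minimal parametric family carrying the three phenomena the
pipeline needs: thermal-only kill (`a`, `b`), LQ radiation kill (`α₀`,
`β`) and heat-induced radiosensitization as a linear inflation of α
(`c`). It makes no claim to mechanistic truth — in particular it is *not*
the AlphaR-type cell-line-specific model used in experimental work, whose
functional form is not public — but it is monotone in both doses,
satisfies S(0,0)=1, and is invertible, which is what fitting, BEQD and
isoeffect solving require. No thermotolerance/saturation term is
included; at very high thermal dose the model therefore overstates kill
relative to assays that plateau.

**Presets.** Two parameter sets are shipped:

| parameter | HCT116 | CAL27 | units |
|---|---|---|---|
| α₀ | 0.55 | 0.43 | Gy⁻¹ |
| β | 0.036 | 0.031 | Gy⁻² |
| a | 0.0384 | 0.0212 | CEM43⁻¹ |
| b | 0 | 0 | CEM43⁻² |
| c | 0.022 | 0.0093 | CEM43⁻¹ |

They were calibrated once, forward from the published isoeffective
treatment panels: for HCT116 the set {10 Gy, 2 Gy + 120 CEM43,
5 Gy + 60 CEM43, 240 CEM43} shares a survival level near 1·10⁻⁴, for
CAL27 the set {10 Gy, 2 Gy + 220 CEM43, 5 Gy + 110 CEM43, 350 CEM43} a
level near 6·10⁻⁴. The solved isoeffect tables land within a few CEM43 of
those panels (e.g. HCT116: 2 Gy + 125.5, 5 Gy + 55.1, 237.0 CEM43),
which is as close as a five-parameter family can match four printed
combinations.

**Fitting.** `fit_survival_params` minimises weighted residuals of ln S
over colony-count records, with weights √n from the Poisson/binomial
counting variance Var(ln S) ≈ 1/n. Zero-colony records get a +0.5
continuity correction before the log; this keeps them in the design but
means heavily censored points (expected counts ≪ 1) carry little and
slightly biased information — visible as reduced precision on `c` when
the only informative combinations are censored. Bounds are non-negative;
the trf solver runs at tight (1e−14) tolerances; non-convergence is
flagged in the returned diagnostics, never silent. Standard errors come
from the Gauss–Newton covariance scaled by the residual variance.

**BEQD and isoeffect.** BEQD uses the positive root of
α₀x + βx² = E (linear fallback when β = 0; an error when both are zero,
since no radiation response is defined). Isoeffect solving brackets H in
[0, 10⁵ CEM43] — two orders beyond the experimentally relevant range —
and polishes with bisection until the effect residual is ≤ 1e−9;
monotonicity of S in H guarantees uniqueness. Grid doses whose
radiation-only effect already exceeds the target are omitted.

## Image quantification

Segmentation is classical: Gaussian smooth (σ = 2 px) → Otsu threshold →
morphological closing (radius 2) → hole fill → remove specks
(< 16 px) → largest connected component. This replaces trained-CNN
contouring deliberately: the downstream metrics need a consistent
contour, not a learned one, and the synthetic generator supplies exact
ground truth to validate against (IoU ≥ 0.95 under the generator's noise
settings). Shed-cell debris is excluded by the largest-component rule; a
`fragmented` flag records when the thresholded frame contained several
bodies, and an `include_corona` option dilates/merges nearby debris for
corona studies.

Diameters: 36 lines through the binary-mask centre of mass, every 5° over
180°. Each diameter runs outermost crossing to outermost crossing, which
is robust to interior holes; the crossing is localised to sub-pixel
precision by bisection on the bilinearly interpolated mask. A centroid
that falls outside the mask (ring-like shapes) triggers a warning but is
still measured.

Mean PI defaults to the whole-image mean — the field-of-view-dependent
but acquisition-faithful convention — with a mask-restricted mode
provided; values are comparable only within one imaging geometry.

Radial profiles: the PI channel is Gaussian filtered (σ = 2 px by
default), sampled at unit-radius steps along 72 angles (every 5° over
360°) by bilinear interpolation, aligned at the centroid and averaged up
to the shortest in-bounds profile. Against an annulus-binning oracle the
agreement on smooth fields is within 5% pointwise.

Conventions: arrays are (row, col) with origin top-left; angles
counter-clockwise from the +col axis; pixel size defaults to 1 µm/px.

## Growth curves and statistics

Each repeat experiment (the mean over its 4–6 spheroids per scan) is
linearly interpolated onto integer days 0–21 strictly inside its scan
range — no extrapolation; missing days stay missing for that repeat.
Pooling is per-day mean and SEM (sd/√n) over repeats with data; a
`publication_grade` flag requires n ≥ 3 on every populated day.

Peak PI uses the day 0–7 window by default (configurable), ties breaking
to the earliest day. The peak-vs-effect regression is plain OLS with
R² = 1 − SSres/SStot and the convention R² = 0 for a constant response.
Group comparisons use Welch's unequal-variance two-sided t-test.

Growth delay is the difference in first crossing times of a diameter
threshold (linear between grid days), with `inf` (“not reached”) for
treated curves that never cross — the growth-control case; a control that
never crosses is an error, since the threshold is then meaningless.

Regime classification works on the deepest relative drawdown from the
running maximum of the diameter curve: a drawdown below 15% is
control-like growth (or growth-control if the curve never ends above its
day-0 value); otherwise a pre-drawdown peak above day 0 signals
transient swelling; a sustained post-minimum rise (≥ 3 consecutive days
each ≥ 0.5% up) signals regrowth; the remaining shrinking shapes split
into monotone shrinkage versus growth control. All three thresholds are
config-exposed (`RegimeConfig`) because the regimes are qualitative by
nature.

## Synthetic-data generator

The simulator is a deliberately minimal compartment model — not
agent-based, no oxygen PDE — because its job is controllable ground
truth, not mechanism discovery. Cells sit in proliferating (P), quiescent
(Q), necrotic (C), dead-attached (A, split by death origin) and shed
pools; counts are continuous expected values; the radius follows from
(4/3)πr³·ρ = attached count with packing density ρ = 3.4·10⁻⁴ cells/µm³
(≈ 4800 cells in a 300 µm spheroid). Geometry is by depth: proliferation
within 75 µm of the surface, necrosis beyond 220 µm, with Q→C relaxing at
1/day rather than instantaneously so that a cleared core refills with a
lag. Default growth rate 0.18/day for rim cells takes an untreated 300 µm
spheroid to ≈ 740 µm in 21 days.

Treatment at t = 0: heat kills the fraction 1 − S_HT of P, Q and C alike
(position-independent death) into the attached-dead pool and loosens
packing; radiation marks 1 − S_RT of P as doomed, dying into the
attached pool with an exponential lag of mean 3 days (mitosis-linked
death), leaving Q untouched. Dead cells shed into the corona pool at
0.35/day (heat origin) versus 0.15/day (radiation origin). Loosening
scales with the heat-killed fraction (so a biologically null heat dose
changes nothing), ramps in over 1 day and recovers over 4; its amplitude
(up to 40% of ρ) produces the observed continue-to-grow-then-shrink
transient on a daily grid. Regrowing spheroids whose necrotic count is
below half the geometric target for their size proliferate 30% faster
(reoxygenation boost, switchable) — one of the two candidate explanations
for post-heating acceleration; the generator implements it without
claiming it is the true mechanism.

The four canonical scenarios used in testing are untreated control,
240 CEM43 (high heat, isoeffective with 10 Gy under the HCT116 preset),
10 Gy (high radiation) and 5 Gy (intermediate radiation); their expected
regimes are control-like growth, transient swelling then shrinkage,
monotone shrinkage, and shrinkage then regrowth respectively.

The renderer draws an antialiased textured disc plus a faint corona
annulus whose brightness saturates with the shed pool; PI is composed
from class fractions with a centre-weighted radial ramp for heat-killed
and necrotic cells and an edge-weighted ramp for radiation-killed cells,
plus seeded Gaussian noise. One global seed governs everything; the
renderer uses a sub-stream, so ground-truth dynamics are identical across
seeds while noise realisations differ. Colony counts are binomial
thinnings of the plated cells with probability PE·S — equal in mean to
the Poisson description and indistinguishable from it in the sparse
counting regime, while never exceeding the plated number. Viability
tables are live-cell ratios with unit-mean lognormal noise of configured
CV.

**What passing tests do and do not show.** The generator reproduces the
qualitative treatment-response structure (regimes, death-timing contrast,
staining patterns) and exact bookkeeping, so green tests demonstrate that
the measurement and analysis stack recovers known truth through a
realistic rendering path. They do not validate the biology: real
spheroids are more heat-resistant in 3D than their 2D survival predicts
(the simulator kills at 2D survival levels, so simulated heated spheroids
regrow more slowly than experimental ones), PI intensity in reality
depends on microenvironmental chemistry and focal depth, disintegration
produces fragments the renderer does not draw, and the simulated peak-PI
versus effect relation saturates where experiments report near-linearity.

## Problem sizes

Default canvases are 1024 px at 1 µm/px (a full control trajectory plus
corona fits); test and example runs use 22 daily frames per scenario,
50 seeded frames for segmentation quality, 20 seeds per scenario for
regime checks, and clonogenic designs of 4 × 4 dose combinations × 3
replicates at 10⁵ plated cells. These sizes keep the full suite and the
acceptance script at desk scale while leaving every statistical check
comfortably powered.

## Known limitations

- Single treatment fraction, fixed heating temperature; no sequencing or
  fractionation effects (the RT–HT gap is metadata only).
- No oxygen/pH fields: rim and core are geometric; the reoxygenation
  boost is a switch, not a transport model.
- The survival family is a declared stand-in; its parameters are
  calibrated to printed isoeffect panels, not fitted to raw assay data.
- Whole-image PI means depend on the field of view; compare only within
  one geometry.
- Sub-pixel contouring accuracy is limited to the bilinear mask
  interpolation (~0.3 px); spheroids below ~20 px diameter measure
  noticeably less accurately.
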