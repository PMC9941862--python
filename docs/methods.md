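# Methods

## Model

The package analyses BOLD responses to controlled breathing challenges
with the hyperoxia-calibrated BOLD model and the Davis model under Grubb
flow–volume coupling.  All signal changes are fractions internally
(`0.02` = 2 %); user-facing tables are in percent.

**Oxygen transport.**  Arterial saturation follows the Severinghaus closed
form `SaO₂ = 1/(23400/(PaO₂³ + 150·PaO₂) + 1)`; arterial content is
`CaO₂ = φ·[Hb]·SaO₂ + ε·PaO₂`.  Arterial PaO₂ is taken equal to measured
end-tidal PetO₂.  Under hyperoxia, CBF and CMRO₂ are assumed unchanged, so
the arterio-venous content difference stays at its baseline value
`OEF₀·CaO₂(baseline)`; venous saturation is `SvO₂ = CvO₂/(φ·[Hb])`
(dissolved venous O₂ neglected, SvO₂ capped at 1), and the venous
deoxyhaemoglobin ratio is `r = (1 − SvO₂)/(1 − SvO₂⁰)`.

**Hyperoxia calibration.**  `ΔBOLD/BOLD₀ = M·(1 − r^β)`, inverted for M.

**Hypercapnia forward model and inversion.**  Substituting Grubb's law
`CBV/CBV₀ = (CBF/CBF₀)^α` into the Davis model gives
`ΔBOLD/BOLD₀ = M·(1 − v^(1−β/α)·c^β)` with `v = CBV/CBV₀` and
`c = CMRO₂/CMRO₂|₀`; the exponent `1 − β/α` is the algebraically
self-consistent form.  The inversion
`v = [(1 − ΔBOLD/(M·BOLD₀))/c^β]^(1/(1−β/α))` is exact (round-trip
tested to < 1e-9), and ΔCBV is reported as `(v − 1)·100` %.

## Parameters

| parameter | default | unit | meaning |
|---|---|---|---|
| α | 0.2 | – | venous CBF/CBV coupling exponent |
| β | 1.0 | – | dHb relaxation exponent (7 T) |
| OEF₀ | 0.30 | – | assumed baseline O₂ extraction fraction |
| [Hb] | 15 | g/dL | haemoglobin concentration |
| φ | 1.34 | mL O₂/g | Hb O₂-carrying capacity |
| ε | 0.0031 | mL O₂/dL/mmHg | plasma O₂ solubility |
| CMRO₂/CMRO₂|₀ | 0.97/0.95/0.92/0.90 | – | metabolic scaling at +3/+5/+8/+10 mmHg |

All are configurable (`CalibParams`, serialised as a flat JSON document);
every run record logs them, since M and ΔCBV inherit their assumptions.
CMRO₂ scaling is looked up per condition label, never interpolated.

## Protocol and synthetic data

The default session is 200 s baseline, 120 s hypercapnia at +5 then
+10 mmHg PetCO₂ back to back, a 137 s return to baseline, and a final
120 s hyperoxia block at +350 mmHg PetO₂ — 697 s, 820 volumes at
TR 0.85 s.  The four printed block durations alone sum to 560 s; the
recovery period is the package's reading of the remaining 137 s, placed
so that CO₂ clears before the O₂ challenge and the session ends with
hyperoxia.  An alternative session swaps in +3/+8 mmHg with identical
timing.

Gas traces relax toward the block targets with a first-order time
constant (default τ = 15 s, a smooth ramp as produced by sequential gas
delivery) plus breath-to-breath Gaussian noise (default sd 0.5 mmHg).
Respiration (≈0.28 Hz) and pulse (≈1.1 Hz) traces carry slow rate and
amplitude wander so RVT/BPM extraction sees realistic variation; six
motion traces are smoothed random walks (≈0.05 mm/deg) that enter only as
nuisance regressors.

Ground truth lives on a rectangular slab of 20 equivolumetric layers
(plus one out-of-cortex slice per face) with three ROI stripes and vein
flags at the superficial face.  Depth profiles are linear in normalised
depth and anchored so that the *deep and superficial bin means* equal the
reference group values — M: 9→21 % (GE-like), 9→16 % (SE-like); CVR:
0.39→0.64 and 0.18→0.25 %BOLD/mmHg; ΔCBV at +10 mmHg: 12.5 % and 8.5 %,
depth-constant.  Per-voxel truth is made mutually consistent: M and the
+10 CBV ratio fix the +10 plateau, the CVR line over targeted ΔPetCO₂
places the other plateaus, and inverting the forward model yields every
level's CBV ratio.  Lognormal voxel jitter (sd 0.05 in log space) acts on
M, CVR and the CBV increase; CVR is clipped so each plateau clears the
metabolic floor `m·(1 − CMRO₂ ratio)` with a 20 % margin, keeping all CBV
ratios above 1.  The BOLD series is
`s₀·(1 + f_hc + f_ho) + drift + noise`: hypercapnia responses are binary
plateaus of the forward model, the hyperoxia response follows the PetO₂
trace sample by sample, drift is a one-cycle cosine of fractional
amplitude 0.005 with random voxel phase, and noise is white Gaussian with
sd `s₀/tsnr` (default tsnr 50).  GE-like and SE-like runs share one grid;
sequence differences are encoded purely in ground truth (and optionally
tsnr), not in voxel size.

**What the generator does not emulate:** vascular network anatomy and
partial-volume mixing across the 1.0 vs 1.5 mm acquisitions, T2/T2*
biophysics, motion-induced signal changes, serial autocorrelation of
physiological noise, and BOLD transients of the hypercapnic response
(only the hyperoxia response carries transition dynamics).  Passing
recovery tests therefore demonstrates estimator correctness under the
stated generative model, not robustness to those real-data effects.

## Estimation pipeline

1. **Restricted smoothing** — 3D Gaussian (FWHM 2.35 mm) confined to each
   (depth bin, ROI) cell, kernel renormalised inside the cell; voxels
   outside every cell pass through.  The 20 layers are collapsed to 3
   bins by dropping layers 1 and 20 and mapping 2–7/8–13/14–19 to
   deep/middle/superficial.
2. **Rescaling** — percent signal change about the whole-series temporal
   mean; non-positive-mean voxels are flagged invalid.
3. **GLM** — intercept plus one binary indicator per gas condition
   (fitting the average plateau), estimated by per-voxel OLS.  The 8
   nuisance regressors (6 motion, RVT, BPM) and the sub-0.003 Hz DCT
   drift basis (K = ⌊2·T·f_c⌋ = 4 vectors) enter *orthogonalised against
   the task columns*: the gas blocks are one-off and spectrally adjacent
   to the drift basis, so un-orthogonalised confounds absorb task
   variance — in simulation they shrank the late hyperoxia beta by up to
   ~50 % (drift basis) and shifted betas by several percent (nuisance).
   Orthogonalised confounds only reduce residual variance; condition
   estimates equal raw block contrasts.  A standalone
   mean-preserving, idempotent `dct_highpass` is provided for direct
   filtering use.
4. **Baseline referencing** — condition betas are rescaled by
   `100/(100 + intercept)`, converting plateau-vs-mean PSC estimates into
   plateau-vs-baseline %ΔBOLD; this removes the ≈1.4 % compression
   introduced by normalising with the whole-series mean.
5. **Selection** — per-voxel omnibus F test over the gas columns
   (per-condition t tests optional), Holm–Bonferroni step-down across the
   in-mask voxel family at α = 0.05.
6. **Metrics** — CVR: least-squares line *with intercept* of %ΔBOLD on
   measured ΔPetCO₂ (block mean minus initial-baseline mean of the
   trace), per-voxel over available conditions, NaN if fewer than two.
   M: from the hyperoxia beta with the dHb ratio evaluated as the
   *hyperoxia-block mean of the per-sample ratio* (`ratio_mean`, default)
   — the exactly consistent calibration for a binary-regressor estimate
   of a trace-driven response; the conventional ratio-at-block-mean-PetO₂
   (`block_mean`) is available and differs by ≈ −9 % at τ = 15 s.
   ΔCBV: model inversion per level; voxels with M ≤ 0 or a saturated
   response (ΔBOLD ≥ M) are excluded and counted in the QC log.
7. **Aggregation** — subject bin means first, then across-subject mean
   and SEM (0 by convention for one subject); GE/SE ratios with
   first-order error propagation.

## Numerical choices and degenerate inputs

Non-positive pressures, flows and tsnr are rejected; a fully saturated
baseline (no venous dHb) and a unit dHb ratio raise dedicated errors
(uninformative calibration); model saturation raises rather than
returning complex values.  Rank-deficient designs fail with the offending
column names.  NaN voxels propagate without poisoning neighbours; NaN
p-values are excluded from the Holm family.  Holm uses stable sorting;
the step-down threshold sequence is `α/(m − i)` for 0-based rank i.

## Problem sizes

Recovery studies run on desk-scale grids chosen as the package's default
study sizes: the noiseless identifiability check uses one subject per
sequence on a 10×10×22 slab with smoothing, drift, BOLD noise and gas
noise disabled (smoothing deliberately trades voxelwise accuracy for SNR
by averaging across the depth gradient, so per-voxel identity is assessed
without it); the group study uses 8 subjects × 2 sequences on a 16×16×22
slab at tsnr 50 with all noise sources and smoothing active, scoring
bin-level group means.  `make_slab` defaults to the full 40×40×22 grid.

## Known limitations

Estimates inherit the assumed α, β, OEF₀ and CMRO₂ scalings; no attempt
is made to estimate them from data.  CBF is not measured (no ASL), so M
and ΔCBV rest on the stated coupling assumptions.  The binary-regressor
GLM ignores serial autocorrelation (no prewhitening) and spatial
inference (no cluster correction).  CVR from sessions using the +3/+8
levels is biased by ≈5 % under slow gas transitions because the two
blocks settle from different step sizes; the default ±5/±10 session is
immune (equal settling deficits cancel in the slope).
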