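# Methods

## Signal model

Pump-probe microscopy measures the differential absorption Δα = −ΔT/T of a
probe pulse as a function of its delay τ after a pump pulse.  Three
excited-state processes contribute: excited-state absorption (ESA, positive
Δα), ground-state bleaching (GSB, negative) and stimulated emission (SE,
negative).  With a 1040 nm pump (1.192 eV photons by hc/λ) and an 860 nm
probe (1.442 eV), the probe photon is more energetic than the pump photon
and SE cannot occur; the package checks this ordering explicitly
(`stimulated_emission_absent`) and models only ESA and GSB.

A pigment's transient is a sum of signed exponentials,

    S(τ) = Σ_i A_i · exp(−τ/λ_i),  τ ≥ 0,

convolved with a Gaussian instrument response function (IRF) of standard
deviation σ.  The convolution has the closed exponentially-modified-Gaussian
form per component,

    C_i(τ) = (A_i/2) · exp(σ²/2λ_i² − (τ−t0)/λ_i) · erfc((σ/λ_i − (τ−t0)/σ)/√2),

evaluated in a log-stabilised split (`erfcx` for the growing branch) so it is
finite for all delays.  The IRF width is derived from the pulse durations:
the cross-correlation of 150 fs and 120 fs FWHM Gaussian pulses has FWHM
√(150²+120²) ≈ 192 fs, i.e. σ ≈ 81.6 fs.  Time zero is the cross-correlation
maximum; t0 is an explicit parameter defaulting to 0.  All internal times
are ps; fs appears only at I/O boundaries.

## Default pigment models

- **Pheomelanin**: one ESA component, lifetime 0.15 ps, amplitude +1.  The
  physical constraint is only that the lifetime lies below 0.2 ps; 0.15 ps
  is the package default.
- **Eumelanin**: the same fast ESA component plus a GSB component with
  lifetime 9.4 ps and amplitude −0.35.  The amplitude ratio is a package
  default chosen to reproduce the qualitative signature that identifies
  eumelanin: positive signal at τ = 0, clearly negative signal by 0.5 ps,
  slow recovery.  Both models are overridable and serialize to JSON.

Note on the 500 fs residual: the *unconvolved* pheomelanin decay retains
exp(−0.5/0.15) ≈ 3.6% of its τ=0 value at 500 fs, i.e. effectively zero.
After convolution with the 81.6 fs IRF the residual at the 500 fs frame is
≈ 12% of the τ=0 value (the EMG tail).  This residual is positive, so it
cannot leak into the eumelanin channel (which only responds to negative
signal), but it slightly dilutes the pheomelanin-map contrast.

## Synthetic phantoms

No imaging data accompany the method, so the pipeline is exercised on
ground-truthed phantoms whose statistics mirror the tissue imagery the
method targets:

- `two_region_interface`: eumelanin-dominated melanoma on one side of a wavy
  sinusoidal boundary, pheomelanin-dominated paracancer on the other.
- `choroid_belt`: melanin-free elliptical cores each ringed by a
  pheomelanin-rich belt inside a paracancer field (normal choroid).
- `scattered_cells`: sparse ~10 µm eumelanin-rich disks (single melanoma
  cells, 1 px Gaussian-feathered edges) on a pheomelanin background.
- `uniform`: one label everywhere (controls).

Concentration maps are the label indicator times a unit-mean log-normal
texture (Gaussian-smoothed white noise, default 4 µm correlation length,
log-σ 0.4 — positive by construction).  Melanoma pixels also carry
pheomelanin at 0.3× their eumelanin concentration; paracancer pixels carry
no eumelanin.  With these defaults the tumor mask coincides exactly with
per-pixel eumelanin dominance, which is what the margin finder estimates.

Rendering: AC(x,y,τ) = dc(x,y)·[c_eu·M_eu(τ) + c_ph·M_ph(τ)] with M the
IRF-convolved pigment responses, and dc = exp(−k_abs·(c_eu+c_ph)) — a
Beer-Lambert transmission with one lumped extinction coefficient
(k_abs = 0.5 per unit concentration) standing in for heterogeneous melanin
absorption.  Noise is additive Gaussian on AC (lock-in detection noise,
default σ = 5% of the peak |AC|) and multiplicative Gaussian on DC (1%);
shot noise is deliberately omitted.  Default geometry is 512×512 px over a
212 µm field; the default delay grid {−0.5, −0.25, 0, 0.1, 0.2, 0.3, 0.5,
1, 2, 5, 10, 20, 40} ps is dense near time zero, includes the two frames
unmixing needs and two pre-time-zero baseline frames, and is an emulation —
the actual acquisition grid of such instruments is not standardized.

What the phantoms do **not** emulate: optical point-spread blurring, depth
sectioning, scattering, motion, or frozen/paraffin/fresh appearance
differences.  Passing tests therefore demonstrate correctness of the
computational chain under the stated noise model, not robustness to every
real-tissue artifact.

## Decay fitting

Bounded nonlinear least squares (trust-region reflective) on the
IRF-convolved model, restarted from a small lifetime grid — {(0.1), (0.2)}
ps for one component, {(0.1, 5), (0.2, 10), (0.15, 20)} ps for two — with
amplitudes initialised from the trace at τ=0 and the frame nearest 0.5 ps.
The restart with the lowest residual RMS wins; ties go to grid order, so
fits are deterministic.  Lifetime bounds default to (0.02, 100) ps.  The
IRF σ is fixed from the pulse pair by default; fitting it is opt-in because
it is nearly degenerate with a sub-σ fast lifetime.  A trace where no
restart converges is flagged, not raised.

Classification of a fitted trace: *unpigmented* if the trace peak is below
the peak floor; *eumelanin* if a component slower than 1 ps has amplitude
below −amp_floor; *pheomelanin* if the dominant component is positive above
amp_floor with lifetime under 0.5 ps; else *ambiguous*.  The 1 ps / 0.5 ps
cutoffs sit between the two melanin lifetimes (0.15 and 9.4 ps).  Floors
default to 3× (amplitude) and 5× (peak) the robust noise estimate
1.4826·MAD of the pre-time-zero baseline frames.

Per-image fitting block-averages traces over binning×binning pixels first;
blocks below the peak floor are labelled unpigmented without fitting.

## Two-delay unmixing

With frames at 0 and 500 fs (matched within 0.05 ps of the nominal stage
positions):

    S_eu = max(−S(500 fs), 0),   S_ph = max(S(0) + S(500 fs), 0).

Both channels are clamped at zero: sign reversal alone would otherwise
produce negative eumelanin under noise, so symmetric clamping is the only
consistent reading of "negative signal rounded to 0".  Frames are
DC-normalized (per-frame division by the DC transmission image, floored at
0.01 with a validity flag) *before* the delay arithmetic; the order is
configurable because the acquisition description does not pin it down.
Because the eumelanin model still has residual positive ESA at the 0 fs
frame, S_eu is proportional to, but not equal to, eumelanin concentration;
recovery is monotone (rank correlation > 0.95 on noiseless phantoms), which
is sufficient for dominance-based margin finding.

## Margin delineation

The margin statistic is the eumelanin fraction F = S_eu/(S_eu+S_ph+ε),
smoothed with a 2 µm Gaussian, thresholded at 0.5 (eumelanin dominance),
cleaned by removing components under 20 µm² and filling holes.  A log-ratio
statistic was rejected for its zero-handling complexity.  Scores: Dice
overlap (defined as 1 for empty-vs-empty, 0 for empty-vs-nonempty) and
boundary distances between border-pixel sets (symmetrised mean
nearest-neighbour and Hausdorff, in µm).

Known limitation: F is undefined where both pigment signals are ≈ 0, so in
melanin-free areas (the cores of the choroid-belt phantom, pigment-free
background) noise can push smoothed F above 0.5 and produce speckle false
positives; the small-object filter removes most but not all of them.  A
pigment-signal floor (larger ε, or masking by total signal) suppresses
these at the cost of sensitivity to weakly pigmented single cells.  The
shipped default keeps ε as a pure stabilizer (1e-6).

## Problem sizes and numerical choices

The shipped analyses use 256² px phantoms (the end-to-end acceptance check
uses the full 512² default geometry); per-pixel fitting examples use 8×-
or 16×-binned traces.  All randomness flows from explicit integer seeds
(separate phantom and noise seeds); repeated runs are byte-identical.
Convolution accuracy is verified against discrete convolution of the
sampled decay with a sampled Gaussian kernel to 1e-3 relative error.
Degenerate inputs (all-zero traces, empty masks, pigment-free phantoms)
resolve to the neutral outputs (zero amplitudes, empty masks, Dice 1 for
vacuous agreement) rather than errors.
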