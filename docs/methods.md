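# Methods

This note documents the models behind `mbovs`, the defaults and why they
were chosen, and what the simulations do and do not capture.

## Pulse model

A single saturation band is a sampled sinc envelope
`b1(t) ∝ sinc(TBW · (t − T/2) / T)` on a 10 µs raster, optionally
multiplied by a Hamming window (`0.54 − 0.46 cos(2πt/T)`). The
"amplitude-optimized" (AM) family is implemented as the Hamming-apodized
sinc: apodization removes the truncation sidelobes that plain sinc pulses
ring into the pass-band, at the cost of a wider transition and a slightly
higher peak B1+ for the same flip. The exact analytic form of
amplitude-optimized pulses varies between implementations; the window is
therefore a configuration option (`PulseShapeSpec.apodization`), and
Hamming is the default because it reproduces the observed smooth profiles
and moderate peak-B1+ penalty.

Amplitude is calibrated so the on-resonance rotation angle
`2π γ̄ ∫ B1 dt` equals the nominal flip. For an amplitude-modulated pulse
all on-resonance rotations share one axis, so this calibration is exact —
the Bloch-simulated `|Mz|` at slab center after a 90° band is < 10⁻⁶.
`flip = 0` is accepted and produces an all-zero waveform (useful for
controls).

The two-band waveform is

    mb(t) = Σ_k b1(t − τ_k) · exp(i (2π f_k (t − τ_k) + φ_k)),

with `f_k = γ̄ · Gr · z_k` for slab centers `z_k` and time shifts
`τ_k = ± (s/2) · T` for a total *peak shift* `s` (default 0.15). The shift
desynchronizes the two envelope peaks: the summed peak B1+ drops below
twice the single-band peak while the waveform buffer grows by `s · T`
(never truncated). The shift is implemented in the time domain and applied
symmetrically, i.e. the quoted 15% is the *total* relative offset between
the bands. RF energy `∫|B1|² dt` is reported relative to the SINC TBW-40
module (= 1.0); an absolute SAR in W/kg would require a scanner-specific
body model and is out of scope.

## Pulse catalog

Two design philosophies are compared:

* AM-sinc TBW 5/8/11 at a **fixed 3.84 ms duration** — bandwidth and hence
  gradient grow with TBW (204/326/448 µT/m for a 150 mm slab), sharpening
  the transition but raising peak B1+ (7.6/12.3/16.8 µT single-band).
* Plain sinc TBW 5/10/20/30/40 at a **fixed bandwidth** (2604 Hz, the TBW-5
  pulse at 1.92 ms) — all play at 407 µT/m with identical off-resonance
  behavior, while the duration grows proportionally to TBW
  (1.92 … 15.36 ms).

## Geometry

Slab centers are not uniquely determined by the application; the default
places two 150 mm slabs at ±110 mm, leaving a 70 mm pass-band around the
isocenter inside a 320 mm field of view (chest and back bands around the
heart). All geometry is configurable through `SlabGeometry`.

## Bloch engine

Magnetization is propagated with the hard-pulse approximation: per 10 µs
raster step a Rodrigues rotation about the effective field
(`γ̄ B1 · b1_scale` transverse, `γ̄ Gr z + Δf` longitudinal), optionally
interleaved with per-step exponential T1/T2 decay. Key numerical
properties (all under test): rotations conserve `|m|` to 10⁻⁹ per event;
halving the raster changes a 90° profile by < 10⁻³ RMS; at 5° flip the
profile matches the Fourier transform of the envelope within 2% RMS; and
the two-band profile is the superposition of the single-band profiles in
the small-tip regime.

Spoiling is ideal (transverse magnetization zeroed, Mz kept). The
residual-signal metric is a ratio between two simulations that share the
spoiling model, so spoiling fidelity largely cancels; intra-voxel
dephasing is deliberately not modeled.

## Sequence models

The interleaved CINE loop repeats

    module → spoiler → N × [excite(α), record |Mxy|, spoil, relax TR]

continuously for 6 heartbeats at 60 bpm (the spoiled-GRE transient decays
within ~1 s for all tissues considered; the last R-R interval is analyzed,
binned into 25 uniform cardiac phases). Recorded signal is `|Mxy|`
immediately after excitation, `∝ sin α · Mz`; echo-time decay cancels in
the residual ratio and is omitted. The module occupies its own time slot
(waveform + 200 µs spoiler ≈ 4.6 ms for the default AM-sinc TBW-8 module
with 15% peak shift), displacing readout time.

**Module relaxation treatment.** Inside sequence loops the module is
applied as an instantaneous rotation in the relaxation bookkeeping: its
slot still displaces sequence time and the spoiler interval relaxes, but
no T1 recovery is accumulated *during* the RF play
(`MbOvsModule.relax_during_rf = False` by default). The module is short
(3.8–15.7 ms) compared with the T1 values it suppresses, and this choice
makes the residual-vs-T1 curve a pure measure of inter-module recovery;
enabling per-step relaxation raises the curve by roughly 1.7 percentage
points at T1 = 200 ms. The engine supports both treatments.

The perfusion shot model plays a composite non-selective saturation
(4 × 90° hard pulses, each followed by a 200 µs spoiled gap — repetition
makes the preparation robust to transmit-scale errors: the longitudinal
remainder at scale `s` is ~`cos(90° s)⁴`), relaxes for the saturation
delay (150 ms default), then runs the readout train with the module
interleaved before every 9th imaging pulse. The composite's individual
flip angles and spacing are an implementation default (4 × 90°), not a
measured reference.

## Residual-signal metric

    residual % = 100 · mean(stop-band signal with module)
                      / mean(stop-band signal without module),

phase-averaged. Two region conventions are used:

* `metrics.residual_signal` defaults to the central 80% of each nominal
  slab — a conservative mask that includes part of the profile transition.
* `sequences.residual_vs_t1` measures over the 8 cm stop-band compartments
  of the suppression phantom (|z| ∈ [60, 140] mm). Like manually drawn
  ROIs in a phantom image, this samples tissue well inside the slabs, away
  from the ~30 mm transition of the 150 mm Hamming-sinc slab, so the T1
  curve characterizes recovery dynamics rather than profile sharpness.

The metric is scale-invariant and, because both arms share the spoiling
and echo-time model, insensitive to those choices; tests verify
< 0.5 percentage-point change under grid-density doubling and T2 changes.

## Profile metrics

Pass-band deviation is `max |1 − Mz|` in the central 80% of the pass-band;
transition width is the distance between the Mz = 0.1 and 0.9 crossings at
each nominal slab edge (0.9/0.1 is the standard convention; thresholds are
configurable), averaged over the four edges; the sidelobe level is
`max |1 − Mz|` between the inner-edge 0.9 crossings. Crossings are chosen
*nearest the nominal edge* among all sign changes, which keeps the metric
stable when unapodized pulses ring across the thresholds — even so,
threshold metrics on strongly ringing 90° sinc profiles remain noisier
than on apodized ones.

## Digital phantom

The 1D phantom projects the suppression experiment onto the phase-encode
axis: 12 cm water between two 8 cm fat compartments, 1 mm isochromat
spacing. A 1D model is sufficient because with Cartesian readouts slice
leakage acts only along the phase encode. Presets: fat T1/T2 =
300/80 ms (mid-range for subcutaneous fat at 3T), water 2900/200 ms
(undoped water; the physical phantom's doping is unknown, so these are
explicit configuration, and the residual metric is shown insensitive to
the T2 choices). The phantom omits 2D/3D geometry, coil sensitivities,
flow, motion, and intra-voxel dephasing — passing tests therefore validate
the pulse/sequence physics, not image-domain artifact levels; measured
phantom residuals (which fold in ROI placement, readout, and
reconstruction) are expected to sit above the simulated curve.

## Problem sizes and determinism

Default grids are 1 mm isochromat spacing over ±160 mm (321 points;
profile metrics use ±225 mm to cover the outer slab edges), 10 µs RF
raster, 6 simulated heartbeats. The sequence loops exploit that one module
acting on a fixed grid is an affine map `m → A m + b` per isochromat
(`affine_propagator`), so repeated modules cost a 3×3 multiply; the full
residual-vs-T1 characterization runs in seconds. All simulations are
deterministic; a seed is accepted wherever randomized field maps could be
configured.

## Known limitations

* Plain-threshold transition metrics are sensitive to ringing of
  unapodized pulses (see above).
* The RF-0 control and the module share one timing model; vendor-specific
  gradient ramps are not modeled (the 200 µs spoiler is a flat interval
  followed by ideal spoiling).
* bSSFP sequences, SLR/adiabatic pulse families, 2D spatially selective
  pulses, k-space encoding and reconstruction are out of scope.
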