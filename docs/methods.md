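# Methods

## Scope and intent

`stenovoice` studies one mechanism: a subglottic constriction in series
with the glottis consumes part of a fixed transglottal pressure budget,
and the impact on phonation is governed by the ratio of the (cycle-
averaged) glottal area to the stenosis area.  The pipeline is deliberately
desk-scale — a lumped-element fold model and an algebraic flow law in
place of a 3D fluid–structure–acoustic solver — so severity/location
sweeps run in seconds.  Quantities that require resolved flow or tissue
fields (formant levels, viscous losses inside the stenosis, 3D mode
shapes) are outside what this surrogate can predict; the analyses that
only need waveforms (quotients, MFDR, resistances, POD of lumped
kinematics, monopole far field) are first-class.

## Stenosis geometry

The constriction is a cosine-modulated radial scaling of a circular tube
over an axial window of length `L = 1.0 cm` (a common clinical extent).
With `a` the fractional reduction of the transverse dimensions at the
narrowest section, severity (fractional area reduction) is
`1 − (1 − a)²`; `a = 0.9` therefore removes 99% of the lumen.  The law is
verified in the tests by meshing the constricted section densely and
integrating its polygon area (agreement required within 0.5%).  Severity
maps to the four-grade clinical scale; the printed grade ranges leave
gaps ("below 50", "51–70"), which we close by making each grade's upper
boundary inclusive: I = [0, 0.50], II = (0.50, 0.70], III = (0.70, 1),
IV = 1.

The stenosis location (distance between narrowest section and the
superior fold surface; 2.1 cm and 3.13 cm in the sweeps, the minimum and
mean of reported patient anatomies) is carried through the pipeline but
deliberately does not enter the flow law — a quasi-steady series of
orifices has no notion of spacing.  Location insensitivity is therefore
exact in this model, which is consistent with (but stronger than) the
within-2% insensitivity the full 3D physics produces.

## Fold model and flow law

Tissue: a symmetric two-mass model per fold (one side simulated and
mirrored) in the Ishizaka–Flanagan/Steinecke–Herzel tradition, in SI
units.  The lower (inferior) mass `m1 = 0.125 g` and upper mass
`m2 = 0.025 g` carry linear springs `k1 = 150 N/m`, `k2 = 15 N/m`, a
coupling spring `kc = 85 N/m` and dampers `r1 = 0.04`, `r2 = 0.008 N·s/m`.
Glottal section areas are `a_i = a_i0 + 2 l x_i` with fold length
`l = 1.4 cm` and rest areas `3.0` and `2.0 mm²` (slightly convergent at
rest).  Contact is a penalty spring (3× the element stiffness) engaging
when a section falls below the floor area `min_gap × l`, with the
artificial minimum gap of 0.2 mm; the glottal area is clipped at that
floor, so flow never stops during the closed phase.

Aerodynamics: the driving pressure `P = 0.8 kPa` is split across the
stenosis (area `A_s = A_sub (1 − severity)`, with `A_sub = 2.5 cm²` a
realistic subglottal tube) and the glottis (instantaneous minimum section
`A_g`) by the quasi-steady Bernoulli series law

    Q = √(2P/ρ) / √(1/(C_s A_s)² + 1/(C_g A_g)²),
    ΔP_i = ρ Q²/(2 C_i² A_i²),

with discharge coefficients 1.0 and full pressure-recovery loss at each
constriction (no inertance).  The glottal share of the drop loads the
lower mass through the standard jet-separation pressure
`p1 = ΔP_g (1 − (A_g/a_1)²)`; the upper mass is unloaded.  The partition
is computed so `ΔP_g + ΔP_s = P` holds to machine precision at every
sample — this conservation is asserted across the test suite.

Integration: classical fixed-step RK4 at `dt = 10 µs`.  Halving the step
changes the cycle-averaged flow by well under 0.5% (tested).  The default
run length of 0.08 s yields 11–13 cycles at the calibrated f0; the first
two cycles hold the start-up transient and are discarded everywhere, in
line with the convention that self-sustained vibration is established
after the second cycle.  Runs are deterministic; a seed only randomizes a
small initial-displacement perturbation for robustness studies.

### Calibration

The tissue parameters were calibrated once, at baseline (no stenosis),
against the typical physiological ranges of human phonation — f0 65–260
Hz, skewness quotient 1.1–3.4, open quotient 0.4–0.7, peak flow 200–580
mL/s, mean flow 110–220 mL/s — with the additional qualitative
requirements that the oscillation (i) keeps the same limit-cycle branch
from 0 to 96% severity so that threshold estimates reflect the series-
resistance mechanism rather than a regime jump, and (ii) still oscillates
at 99% severity.  The shipped defaults (also in `configs/baseline.yaml`)
give f0 = 167 Hz, τs = 2.27, τo = 0.69, q_peak = 234 mL/s, q_mean = 143
mL/s.  No exact reproduction of any particular 3D solver's numbers is
promised or attempted; the surrogate is judged on ranges and trends.

Two empirical observations from the calibration study are worth
recording.  First, parameter sets near a bifurcation of the two-mass
model can flip attractors under sub-percent changes in available driving
pressure, which masquerades as a spurious low severity threshold; the
default set was chosen well inside a monostable region.  Second, at 99%
severity some otherwise acceptable calibrations reach phonation arrest
(the folds settle onto the minimum-gap floor); the default set keeps a
reduced oscillation there, but arrest is a physically meaningful outcome
and is reported through the `oscillating` flag rather than an exception.

## Waveform analysis

Cycle boundaries are upward crossings of the steady-state mean level
(mean over the second half of the record), linearly interpolated between
samples.  Each steady cycle is resampled onto 1000 uniform phases and
averaged phase-by-phase; averaging is exact for strictly periodic input
and shrinks additive noise by 1/√n_cycles (verified by Monte Carlo).

The closed phase of the area waveform is defined by the 2%-slope rule —
|dA/dt| below 2% of its cycle maximum — ANDed with proximity to the
waveform floor (within 5% of the cycle's range), because the slope rule
alone also fires at the waveform peak.  Two numerical refinements matter
at the one-phase-bin level: the slope at each phase is taken as the
smaller of the two one-sided differences (a central difference at an
open/closed junction mixes in the steep open-side slope and biases the
open duration by one bin per edge), and closed runs shorter than 1% of
the cycle are discarded so a tangent minimum of an always-open waveform
does not count as closure.  With these choices the open quotient of
fixtures with planted values is recovered within one phase bin.

τs is measured between flow landmarks: opening instant (end of the
closed phase, or the waveform minimum when no closed phase exists) to
the flow peak, versus peak to closure instant, on the circular phase
grid.  Whether the acceleration duration should instead start at the
*area* opening is not settled; flow landmarks are used because τs is a
flow-waveform quantity.  MFDR is the maximum of −dQ/dt by central
differences on the phase grid.  Resistances are ratios of cycle means,
`|mean ΔP| / mean Q`, not means of instantaneous ratios, so the identity
`R_total = R_glottis + R_stenosis` holds exactly under a shared pressure
partition.

## Acoustics

The far field is the compact-monopole estimate `p_s = ρ/(4πr)·dQ/dt` at
r = 5 cm, driven directly by the glottal flow (no tract filter — wave
propagation in the tract is out of scope, so radiated spectra lack
formant structure and the absolute SPL of the surrogate is not
comparable to a resolved acoustic field).  Spectra use the full record
(resolution = 1/record length); the SNR estimator Hann-windows the
signal and splits energy into harmonic bins (±1 bin around each multiple
of f0 up to Nyquist) versus the rest — an estimator choice, since "SNR"
is not otherwise pinned down.  Sound intensity uses the amplitude of the
phase-averaged pressure waveform, read as half the peak-to-trough
excursion, in `I = Δp² /(2ρc)` with `I0 = 10⁻¹² W/m²`.  Tract resonances
come from the closed–open quarter-wave formula `F_n = (2n−1)c/4L` with
c = 351.88 m/s and L = 17.4 cm (506, 1517, 2528 Hz).

A note on vocal efficiency: the conventional formula
`4πr²·10^((SPL−120)/10)/(P_pul·U_g)` evaluated at SPL = 89.31 dB,
r = 5 cm, P_pul = 0.8 kPa, U_g = 113 mL/s gives ≈ 3.0×10⁻⁴; published
efficiency figures computed from nominally the same inputs sometimes
differ by an order of magnitude (different reference distance or flow
conventions), so no literature efficiency value is used as a test oracle
— only the formula's self-consistency and scaling laws are asserted.

## POD

Snapshots (rows = steady-cycle time samples, columns = displacement
DOFs) are mean-removed and factorized by SVD; mode energies are
σ²-fractions, coefficients are snapshot projections.  Weighting is
uniform — appropriate for the surrogate's few equivalent DOFs.  Mode
sign is arbitrary, hence the absolute cosine in the modal-similarity
measure.  The surrogate's medial surface is a linear blend of two mass
displacements, so its fluctuation rank is exactly 2 and the two leading
modes (lateral and convergent–divergent) carry all vibration energy;
richer mode structure is exercised through the synthetic kinematics
fixtures instead.

## Synthetic fixtures

The flow/area fixture is a pulse train — closed phase at a floor value,
then a rise of duration `τo T τs/(1+τs)` and a fall of `τo T/(1+τs)` —
whose segments are quarter-sine ramps by default: steepest exactly at
the open/closed junctions and flat at the peak, so the 2%-slope closure
rule triggers at an analytically known instant and every planted
parameter (f0, τs, τo, peak flow, MFDR = (π/2)·Δq/t_fall) is recovered
within discretization error.  A raised-cosine segment shape (C¹
everywhere, but with a soft trigger that smears the detected closure by
a few phase bins) and a linear shape are available as options.

The kinematic fixture plants orthonormal mode shapes with prescribed
energies; the two leading modes share the fundamental frequency with a
prescribed coefficient lag (default 0.38 T).  Two same-frequency cosines
with a non-quadrature lag are correlated, and POD cannot separate
correlated coefficients, so the shared coefficient waveform carries one
higher harmonic `m` with weight `γ² = −cos(2πδ)/cos(2πmδ)` (smallest
`m ≥ 2` making `γ² ≥ 0`), which zeroes the empirical cross-correlation
at the planted lag exactly on the discrete grid.  Remaining modes use
distinct higher harmonics.  Energy fractions are then recovered to 1e-6
and the lag to within one sample.

What the fixtures do *not* emulate: cycle-to-cycle jitter and shimmer,
turbulence noise, asymmetric left/right folds, and measurement noise
beyond optional additive Gaussian noise — so passing round-trip tests
demonstrates correctness of the estimators on clean periodic signals,
not robustness to clinical recordings.

## Sweeps and thresholds

The default experiment is the full severity × location grid
({0, 25, 50, 75, 90, 96, 99}% × {2.1, 3.13 cm}), one simulation plus the
full analysis chain per cell, collected in a tidy table with
baseline-relative deltas per location.  "Noticeable" is operationalized
as a configurable relative tolerance (default 1%); the per-metric
threshold is the smallest severity whose |delta| exceeds it, with a
`none` sentinel.  With the shipped calibration the peak-flow threshold
is 90% (changes ≤ 0.7% through 75%), the total resistance at 99%
severity is ≈ 2.1× baseline, and the glottis/stenosis area ratio rises
from ≈ 0.02 at baseline through ≈ 0.1 at 90% to ≈ 1.2 at 99%.  Problem
sizes throughout (0.08 s runs, 10 µs steps, 1000 phases, 14-cell sweep)
are the package defaults chosen for desk-scale iteration.

## Known limitations

* No air inertance or tract loading: flow is slaved to the glottal area,
  so flow-skewing comes entirely from the fold kinematics, and acoustic
  source–filter interaction is absent.
* The trans-glottis resistance's slight *decrease* beyond 75% severity
  seen in resolved 3D flow is reproduced only weakly and is not asserted
  as an invariant of the surrogate.
* Severity thresholds quoted here are properties of this calibration of
  this surrogate; they land in the clinically expected range (no effect
  through Grade I–II, rapid degradation deep in Grade III) but are not
  patient predictions.
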