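# Methods

`phaseloop` simulates closed-loop optogenetic control of gamma oscillations:
a data-constrained channelrhodopsin-2 (ChR2) photocurrent model drives
partially transduced spiking networks whose collective rhythm is analyzed,
perturbed and predicted in real time. This note records the models, the
parameter choices, the numerical decisions, and what the desk-scale study
conditions do and do not show.

## ChR2 photoconductance model

The light-evoked conductance factor is a product of a single-exponential
activation and a biphasic inactivation envelope,

    F(t) = A_act (1 - e^-(t')/tau_act) ·
           (A_persist + A1 e^-t'/tau1 + A2 e^-t'/tau2),   t' = t - t_ON - d,

valid while light is on; after light-off F relaxes with tau_off = 10 ms.
A_persist = 1 - A1 - A2 keeps the envelope non-negative. The latency d,
activation time constant tau_act, amplitude A_act and inactivating fractions
A1, A2 depend on the relative light intensity W ∈ (0, 1] through fitted
laws (a rational latency law d = d_A + d_B·W + d_C/W, exponential
tau_act(W), sigmoidal A_act(W), Lorentzian A1(W), exponential A2(W)); the
two inactivation time constants (9.06 ms, 59.6 ms) are global. All default
constants are the published least-squares values. The interplay of slower
activation and stronger inactivation at both ends of the intensity range
produces a non-monotonic peak current with an interior optimum; for a 3 ms
pulse the scan-plus-interpolation optimizer finds W* ≈ 0.182 (18% of the
maximal intensity).

Two conventions needed fixing:

* **Latency law reading.** d = d_A + d_B·W + d_C/W is the only reading
  consistent with d_C carrying units of ms·[W]. Negative values (possible at
  high W) are clipped to zero.
* **Conductance prefactor.** The printed 0.007 uS with a peak-normalized F
  and a ~64 mV driving force yields ≈0.3 nA, inconsistent with the stated
  calibration that an optimal 3 ms pulse evokes a 2 nA peak photocurrent at
  rest. The default prefactor is therefore re-derived from that calibration
  rule (≈43.5 nS at V_rest = -64 mV); the printed value remains selectable
  (`ChR2GlobalParams(g_chr2=PRINTED_G_CHR2_NS)`).

Arbitrary light waveforms (ramps) are piecewise-constant segments (default
1 ms resolution). Between events the state is advanced with exact
exponentials, so rectangular pulses reproduce the closed form to machine
precision. Across contiguous segment boundaries the conductance is kept
continuous by re-solving the activation level for the new intensity's
parameters; the latency and the inactivation envelope restart only at
dark-to-light transitions. The model has no inactivation-recovery dynamics
in darkness (none is defined by the functional form), so closely spaced
pulse pairs slightly overestimate the second response.

`fit_model` reproduces the two-stage fitting procedure on synthetic
voltage-clamp traces: a joint bounded least-squares fit with the two
inactivation time constants shared across intensities, followed by fits of
the intensity laws (k_inact held fixed by default, as in the original
procedure). Multi-start with seeded perturbed initializations guards
against local minima. With noiseless synthetic traces the generating
parameters are recovered to better than 0.1%; with 1% additive noise the
shared tau_inact_1 is recovered within 5%.

## Spiking network

Each area is a random network of N_E excitatory and N_I = N_E/4 inhibitory
Wang-Buzsaki neurons (C = 100 pF, g_L = 10 nS, E_L = -65 mV, g_Na = 3.5 uS,
g_K = 0.9 uS, instantaneous Na activation, gating temperature factor 5).
Synapses are peak-normalized differences of exponentials (AMPA 1/3 ms rise/
decay, reversal 0 mV; GABA 1/4 ms, reversal -80 mV) with conduction delays
of 1.5 ms locally and 1.0 ms for long-range projections. Connection
probabilities are P_E = 0.12, P_I = 0.3 within an area; only excitatory
neurons project across areas (P_E_lr = 0.06); inhibition never crosses
areas. Each neuron receives an independent 3 kHz Poisson excitatory
background train. A fraction P_chr2 of neurons (drawn i.i.d. over both
classes) carries the ChR2 conductance; light schedules are per-area scalar
waveforms.

**Unit reading of synaptic conductances.** The tabulated values
(g_E = 0.5, g_I = 18, g_noise = 0.5, printed as uS) would exceed the leak
conductance by three to four orders of magnitude per synapse; they are read
as nanosiemens, preserving the printed ratios (g_I/g_E = 36,
g_noise = g_E). This reading reproduces an interneuron-generated gamma
rhythm at 40-70 Hz with low, irregular single-neuron firing. The literal
microsiemens reading stays available (`literal_microsiemens=True`). Note
that single-neuron rates in the scaled model (~6-10 Hz) remain above the
1-3 Hz reported for the full-size reference; the model's E and I
populations receive statistically identical input, so the published E/I
rate asymmetry cannot emerge from the printed parameters alone.

**Down-scaling.** The desk-scale default is N_E = 400, N_I = 100 with the
recurrent peak conductances multiplied by N_E_ref/N_E = 10, preserving the
product (in-degree × peak conductance) per synapse class. Background noise
and the photoconductance are per-neuron quantities and are not rescaled.
Scaling preserves the mean synaptic drive but increases input shot noise
(sqrt(10) larger per-volley fluctuation), which weakens collective
synchrony (chi ≈ 0.2 at N_E = 400 vs ≈ 0.65 at N_E = 4000) and — important
for perturbation experiments — shortens the time over which frozen-noise
twin runs stay coherent (see below).

**Integration.** Exponential Euler for the gating variables and for the
membrane potential, fixed dt = 0.05 ms. The membrane update uses the
conductance form V ← V_eq + (V - V_eq)·exp(-dt·g_tot/C); a forward-Euler
voltage update is unstable at this dt whenever a synchronized inhibitory
volley pushes the total conductance past C/dt, which happens routinely in
the synchronous regime. Spikes are upward crossings of -20 mV. Synaptic
state is two exponential filters per kernel class driven by delayed spike
deltas (mathematically identical to summing the kernels); delays are
realized in a ring buffer at spike-scheduling time, so local and long-range
excitatory inputs share one filter pair.

**Reproducibility and frozen noise.** Topology, transduction mask, initial
conditions and the noise stream are pure functions of four named seeds.
Noise is generated in fixed 1 s chunks keyed by (noise seed, chunk index)
and addressed by absolute step index, so a run continued from a checkpoint
consumes bit-identical noise: a perturbed run differs from its unperturbed
twin only through the photocurrent. Checkpoints carry the complete state
(membrane, gates, synaptic filters, in-flight delayed spikes).

## Phase analysis

Phases live on the cyclic unit interval. The origin convention is fixed at
upward zero crossings of the demeaned, band-passed LFP (zero-phase
Butterworth, ±20 Hz around the spectral peak) — a pure sinusoid has its
maximum at phase 0.25. Under this convention the network LFP waveform
attains its maximum near phase 0.35 and its minimum near 0.65; their
convention-free separation is 0.30 cycles (fast fall, slow rise, as
expected for inhibition-dominated gamma).

The phase-response protocol simulates frozen-noise run pairs: one long
unperturbed reference run with checkpoints at candidate onset times, and
one perturbed continuation per onset (single rectangular pulse, default
3 ms at the optimal intensity W = 0.18). Onset phases are attributed from
the unperturbed twin; induced shifts are circular means of the
instantaneous Hilbert-phase difference over a post-onset cycle window, and
are binned into 30 onset-phase bins (circular mean ± circular std).

**Desk-scale measurement window.** The published protocol discards 10
cycles and averages cycles 11-60 after the pulse. That window presupposes
that twin runs remain phase-coherent for ~60 cycles, which holds only for
large, strongly synchronous networks. At the desk-scale size the collective
dynamics are chaotic enough that twin pairs decorrelate within ~3 cycles;
a 1500-onset control run confirmed that the cycle-11-60 window yields
near-uniform circular noise (resultant length < 0.25 in every bin) with no
resolvable phase dependence, while averaging cycles 2-5 resolves a smooth,
highly significant PRC (per-bin standard error ≈ 0.04 at 50 onsets/bin).
`measure_phase_shift` keeps the published window as its default; the
desk-scale analyses in `scripts/acceptance.py` pass `discard_cycles=1,
average_cycles=4` explicitly. Consequences of the small scale, measured
with that window: the peak advance (~0.35-0.4 cycles at 25% transduction)
is larger than the quarter cycle reported for the full-size model, and a
weak phase-delay region appears near phase 0.85-0.9 even for 3 ms pulses.

**PRC peak location vs the printed value.** Empirically the advance region
is a plateau spanning onset phases ≈ 0.78-0.05 whose maximum (argmax bin at
240-300 onsets: 0.82-0.95 across seeds; at 1500 onsets: ≈ 0.98) sits
half-way between the waveform trough (0.65) and the next maximum (1.35),
matching the verbal description of the optimal stimulation phase. The printed numeric peak location (phi = 0.17)
is not consistent with the same publication's own waveform-phase
convention (max at 0.3, min at 0.6, reproduced here), and cannot be mapped
onto it without knowing an undocumented phase origin. The package reports
the empirical location under its documented convention and does not force
agreement.

## Two-area phase locking

Two mutually coupled areas lock out of phase, with inter-areal phase
difference bistable between Delta-phi_locked and 1 - Delta-phi_locked
(leader/laggard). Modes are detected by circular kernel density (bandwidth
0.03 cycles), not a fixed threshold. Mode membership of a window is the
sign of the circularly smoothed, wrapped difference; spontaneous switching
statistics use a 50-cycle smoothing window and ±0.05 hysteresis. The pulse
protocol verifies a locked pre-state (20 pre-pulse cycles, circular std
≤ 0.05, transduced area leading), measures shifting over post-pulse cycles
1-5 (relative change of the phase difference > 10% by default; an absolute
threshold mode is provided) and switching over cycles 11-60 (50-cycle mean
within ±0.05 of the opposite mode), each against matched unperturbed
windows of the same network as the spontaneous baseline. Unlike the
single-area PRC, these measures are computed within each run (the
inter-areal difference is an attractor of the coupled system), so they are
robust to twin decoherence.

At the desk scale the motif does not develop tight out-of-phase
bistability: the phase-difference distribution is broad and centered near
in-phase, 20-cycle windows have circular std ≈ 0.2-0.3 (so the default
pre-pulse gate of 0.05 rejects everything and the desk-scale analyses
relax it to 0.35), and the detected "modes" are nearly degenerate. The
shifting and switching probabilities are still computed exactly per
protocol, but their headline numbers at this scale mostly reflect the
large spontaneous variability rather than controlled mode switching; the
mean spontaneous waiting time between smoothed sign changes of the phase
difference (> 100 periods) remains well-defined.

## Online phase prediction

The testing stage applies windowed FFTs (256 samples at 1 kHz) to both
areas' demeaned LFPs and requires a gamma-band (30-100 Hz) peak exceeding
5× the median broadband power in both areas, with peak frequencies
agreeing within 5 Hz (the publication leaves both thresholds unspecified;
these defaults are configurable). The monitoring stage filters the target
LFP with a causal two-pole resonator V_f(t) = V(t) + a1 V_f(t-1) +
a2 V_f(t-2), a2 = -0.99. The printed a1 formula places the resonance at the
mirrored frequency under this recursion; its magnitude 4|a2|/(1-a2) =
1.98995 equals 2·sqrt(0.99), so the standard resonator coefficient
a1 = 2 sqrt(-a2) cos(2π f_peak/f_s) is used (the literal printed form is
selectable). Cycle boundaries are upward zero crossings with linear
sub-sample interpolation over ~20 monitored cycles.

Two desk-scale refinements keep the pipeline self-consistent. First, the
testing-stage FFT resolves the peak only to a few Hz while the resonator's
bandwidth is ~1.6 Hz, so a detuned resonator would ring at its own pole
frequency; the pass frequency is therefore refined from the monitoring
window itself (crossing count of the zero-phase wide-band signal) before
tuning the resonator — all computations use only recorded past data.
Second, the realized onset phase is evaluated with the same linear
(crossing-based) phase used for prediction, i.e., the phi_H ≈ phi_L
approximation adopted throughout the online pipeline; evaluating against
the zero-phase Hilbert convention instead would add the resonator's phase
lag (~0.2-0.3 cycles at the pass frequency) and a clock-rate mismatch
between crossing counts and unwrapped Hilbert phase that grows with the
prediction horizon.

The AR(1) coefficient estimator is the lag-1 autocovariance ratio with its
k/(k-1) prefactor, verified against a brute-force oracle. The s-cycle
forecast adds the geometric correction ((a^(s+1) - a)/(a - 1)) to the
linear extrapolation t_k + s·T̄. The printed correction multiplies the full
last period T_k, which is dimensionally a period rather than a deviation
and does not vanish for T_k = T̄; the default applies it to (T_k - T̄), the
statistically standard AR(1) forecast, for which the one-step error ratio
to linear extrapolation converges to sqrt(1 - a²) on Gaussian surrogates
(verified). The literal form is selectable. Stimulus onset is
t_pred + phi_target·T̄, with phi_target = 0.18 by default and s = 3 cycles
(a realistic prediction-stage length of ~50 ms for a 40-70 Hz rhythm).
When the period variance vanishes or |a| ≥ 1, prediction falls back to
linear extrapolation. The closed-loop driver additionally applies the
rule of thumb that the AR(1) correction only pays off for period
correlations above ~0.3: the coefficient entering this decision is
estimated from the wide-band period series, because the resonator's own
two-sample memory inflates the lag-1 correlation of its output (≈0.8)
regardless of the rhythm. The desk-scale rhythm's intrinsic coefficient is
≈0.24, so closed-loop trials at this scale use linear extrapolation; the
AR(1) forecast itself is exercised and validated on surrogates.

## Surrogate oscillations

Cycle periods follow a stationary AR(1) process (defaults: mean 18 ms ≈
55 Hz gamma, a = 0.3, residual sd 1 ms, matching the weak-to-intermediate
period correlations of the simulated rhythm); each cycle renders a
waveform template time-warped to its period, plus additive white noise
(sd 0.05 of unit amplitude). The default asymmetric template warps a sine
so the maximum falls at phase 0.3 and the minimum at 0.6, emulating the
network waveform's fast-fall/slow-rise asymmetry; a pure sine is available.
Ground-truth phase grows linearly within each cycle. The surrogate
reproduces period statistics and waveform shape but none of the network's
amplitude fluctuations, chaos or perturbation response — tests that pass
on surrogates validate the analysis chain, not the network dynamics.

## Desk-scale study conditions

All simulation-based analyses default to the scaled network (N_E = 400,
N_I = 100, conductance-compensated, dt = 0.05 ms, 1 kHz LFP sampling):

| analysis | size used |
| --- | --- |
| reference run (spectrum, waveform phases, chi) | 13.5 s (>= 500 cycles), one area |
| PRC | 240-300 onsets over 50 cycles, early window (cycles 2-5) |
| two-area pulse protocol | ~120 onsets, pulses W = 0.20, 3 ms |
| spontaneous switching | 55 s (>= 2000 cycles), two areas |
| closed loop | >= 25 delivered pulses, s = 3 |

Waveform-extremum locations are read from the 50-bin phase-binned average
waveform after a 3-bin circular moving average (stabilizes the argmax /
argmin against bin noise without shifting a symmetric extremum). At this
scale the maximum is stable at phase 0.33-0.35 while the broad minimum
lands at 0.63-0.69 across seeds, slightly later than the full-size
reference value of 0.6. The spontaneous-switching waiting time stabilizes
near 65 periods once >= 2000 cycles are analyzed.

Known limitations: single-neuron rates above the full-size reference
values; weaker synchrony and faster twin decoherence than at full size
(hence the early PRC window); the PRC peak location is reported under this
package's phase convention and is not comparable to the printed numeric
location (see above); no spatial structure, plasticity, multi-compartment
neurons, or extracellular forward model (the LFP is the mean membrane
potential by definition).
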