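# Methods

This note documents the models, estimators and numerical choices behind
`hairbundle`, in the order a record flows through the pipeline.

## Scientific setting

Free-standing hair bundles of the bullfrog sacculus oscillate
spontaneously at 5–100 Hz with amplitudes of tens of nm; their position
histograms are bimodal because the bundle dwells alternately on the
channel-closed and channel-open side of an unstable midpoint. An overlying
rigid plate (a mica flake standing in for the otolithic membrane)
mechanically couples several bundles; electrical activation of the
efferent nerve modulates the oscillations. The package quantifies that
modulation: synchronization (zero-lag cross-correlation), oscillation
profile (amplitude, open probability, instantaneous frequency), and
dynamical irregularity (truncated Kolmogorov entropy), on either recorded
traces or the built-in synthetic generator.

## Synthetic generator

Each cell is a two-variable relaxation oscillator,

    tau_m dx/dt = -x^3 + a x - f + k (X_m - x) + g_x s(t) + sigma xi(t)
         df/dt = eps (1 + g_f s(t)) (x - c - g_s s(t))

with x the dimensionless bundle position (scaled to nm by
`position_scale`, default 35 nm so the histogram modes sit near ±35 nm),
f a slow adaptation force, and X_m the position of a massless rigid plate,
the spring-weighted mean of all attached cells. The bistable fast equation
produces the bimodal histograms and spike-shaped excursions the estimators
require; the slow variable sets the cycle rate.

Parameters and defaults:

| parameter | default | meaning |
|---|---|---|
| `stiffness_scale` a | 1 | bistability; wells near ±sqrt(a) |
| `fast_timescale_s` tau_m | 2 ms | branch-jump time; shapes the spikes |
| `adaptation_rate` eps | from target f | cycle rate (1/s) |
| `natural_frequency_target` | 10–30 Hz drawn per cell | typical saccular range |
| `noise_intensity` | 250 nm/sqrt(s) | gives dip ≈ 0.07 and null cc sigma ≈ 0.03 |
| plate spring k | 0.35 (well-coupled), 0.02 (partial contact) | baseline membrane cc ≈ 0.8 / ≈ 0.05 |
| `gain_setpoint` g_s | −0.0015 /µA | closes channels (open probability falls) |
| `gain_frequency` g_f | +0.003 /µA | raises cycle rate |
| `gain_force` g_x | +0.008 /µA | fast forcing; entrains pulse trains |

The cycle rate of this oscillator is sublinear in eps (the branch jumps
cost a finite fraction of each cycle), so the frequency target is mapped
to eps through a measured table (noiseless 20 s runs over eps = 5–2600,
log-log interpolated) rather than a single constant.

**Efferent mapping.** The drive waveform s(t) (µA) is a square pulse
train or a constant step confined to the 10 s "during" window of the
10/10/10 s protocol. Three instantaneous gains convert it into parameter
shifts. The set-point gain is negative — efferent activation
hyperpolarizes the soma and biases the bundle toward the channel-closed
state — which reproduces the open-probability and amplitude reductions.
The rate gain raises the frequency. The force gain acts on the fast
equation; because the adaptation variable absorbs any constant force, it
has no steady-state effect under a step, but it passes periodic forcing
and is what lets a 40 Hz pulse train entrain 10–30 Hz oscillators 1:1
(the set-point pathway alone is low-pass filtered by eps and measurably
cannot entrain — this is why the mapping has three gains rather than
two). The mapping is instantaneous: no efferent latency or synaptic
filtering is modelled, and the gains are phenomenological, not a claim
about ACh/SK2 biophysics.

**Simulated study conditions.** The default battery uses ensembles of
10 cells — 5 well-coupled, 3 partial-contact (under the membrane but
below the coupling threshold at rest, as uneven membranes produce), and
2 controls — at 500 frames/s for the 30 s protocol, with pulse trains of
5–100 Hz at 100 µA (50% duty) and steps of 25–200 µA, mirroring the
stimulus schedule of the targeted experiments. Integration is
Euler–Maruyama at 10 kHz (an integer multiple of the frame rate; the step
is config-exposed), decimated by striding; a fixed seed is bit-identical
across runs. What the generator does NOT emulate: efferent latency,
elastic (non-rigid) membranes, amplitude non-stationarity, tracking
artifacts, inter-epithelium variability, and the empirically observed
asymmetry in which control cells respond *more* strongly than coupled
ones — coupled and control percent changes are statistically
indistinguishable here, so tests of the group t-test use constructed
groups instead. Passing tests therefore validate the estimators and the
qualitative efferent patterns, not quantitative agreement with any
recorded cell.

## Tracking

Per frame, the intensity-weighted centroid of the ROI seeds an elliptic
2-D Gaussian fit with offset, refined by Levenberg–Marquardt (at most 100
iterations); a diverged fit (or one with widths outside [0.5, ROI/2] px
or a center outside the ROI) falls back to the centroid and is flagged,
never raised. Width is refit per frame. The 2-D track is projected onto
the leading eigenvector of its centered covariance; the sign follows the
supplied kinocilium bearing, or, for synthetic data, positive skewness
(spike-up). The default scale is 108.3 nm/px. Accuracy on rendered spots:
< 0.01 px noiseless, < 0.1 px RMS at peak SNR ≈ 10.

## Detrending and segmentation

Default chain: order-2 polynomial fit, then subtraction of a 1 s
centered moving average ("both", applied in series); both parameters are
config-exposed since only the procedure, not its orders, is standard.
The moving average uses shrinking windows at the record edges so stimulus
transitions are kept. A 20 Hz tone loses < 1% amplitude through the 1 s
window (the running mean of an integer number of cycles vanishes). The
polynomial step is an exact projection (idempotent to machine precision);
the truncated moving average is not, so the full chain is idempotent only
to ~1% RMS — the second application changes an already-detrended trace by
less than 1% and the property test asserts exactly that. Segmentation
places the stimulus-onset sample in the "during" window; the three
windows tile the record exactly.

## Oscillation profile

The position density is a Gaussian KDE (Silverman bandwidth, 512-point
grid spanning the data ± 3 bandwidths). Modes are sign changes of the
discrete derivative; when more than two maxima exist the two with the
greatest density are kept (deterministic tie-break) and the antimode is
the lowest minimum between them.

A trace is oscillatory iff the dip statistic exceeds 0.01, its bootstrap
p-value is below 0.001, and the density has two modes and an antimode
(thresholds config-exposed). The dip is computed exactly: the minimax
sup-distance between the empirical CDF and the nearest unimodal CDF,
minimized over every candidate modal position by greatest-convex-minorant
/ least-concave-majorant feasibility plus an exact monotone-connection
correction, located by bisection to 1e-13. The test suite checks it
against an independent linear-programming oracle on every small input.
P-values bootstrap the uniform(0,1) null (the dip is invariant under
monotone transformations), 1000 draws by default, cached per sample size.

Amplitude is half the distance between the modes. Open probability is the
KDE mass above the antimode (recentring at the antimode reconciles
"positive position area" with the marked extrema; a "zero" boundary
variant is available). Mean frequency is the average of the positive
instantaneous-frequency samples of the Hilbert analytic phase, excluding
5% edges; negative samples (phase slips of noisy relaxation oscillations)
are excluded and reported as a slip fraction. Whether the original
analysis averaged over samples or cycles is not documented; per-sample
averaging was chosen and agrees with cycle counting to ~5% on relaxation
traces.

## Synchronization

cc(x, y) = cov(x, y) / (sigma_x sigma_y), zero-lag, population (1/n)
normalization (the factors cancel; documented for bit-reproducibility).
Matrices are computed per stimulus segment, never across boundaries. The
coupling threshold comes from the null spread of uncoupled cells: a
kernel-smoothed sigma of ≈ 0.046 puts [4σ, 5σ] = [0.184, 0.230], whose
only one-decimal value is 0.2 (when several qualify the smallest is used;
when none, 4.5σ). A cell is coupled when it lies under the membrane AND
its correlation with the membrane trace exceeds the threshold;
under-membrane cells below threshold have uncertain contact and are
excluded from coupled-group statistics. Chimera-style views sort the
matrix by descending row mean (diagonal excluded, ties by cell id).

## Kolmogorov entropy

Delay embedding with tau = first zero-crossing of the biased
autocorrelation (interpolated, rounded, ≥ 1 sample) and D = 5; each
coordinate is cut once — at the KDE antimode when the trace is bimodal,
else at the median (the cut value is not standardized anywhere; the
antimode separates the two dwelling states) — giving 2^5 = 32 hypercubes.
Plug-in block entropies S_n (natural log, blocks spaced tau, stride 1,
no bias correction, coverage warning below 10 symbols per cell) give the
truncated rate K = S1 − S0 in nats per tau, an intrinsic-time unit that
makes cells of different frequency comparable; a per-second variant
(K·fs/tau) is an auxiliary field. With overlapping binary delay blocks
K ≤ ln 2 per tau: white noise attains the ceiling, the r = 4 logistic map
gives its exact KS entropy ln 2 per iterate, and a periodic signal gives
0 — provided its sampling is commensurate with tau (a tone whose quarter
period is not an integer number of samples picks up a small positive
discretization bias; the oracle uses 25 Hz at 500 fps, where tau = 5
exactly). K is clamped at 0 against-floating point residue.

## Pipeline aggregation

Groups are fixed from the PRE-segment classification. Percent changes are
per cell (pre → during); amplitude and open probability require the cell
to be oscillatory in both segments (dropped otherwise, with counts
reported); frequency and K are defined for every trace. Group means carry
across-cell SDs. Coupled-vs-control contrasts use Welch's t-test
(pooled-variance optional), raw p-values with star annotations at
0.05/0.01/0.001 and no multiple-testing correction (documented
limitation). Cells are the statistical unit (epithelium-level nesting is
not modelled). Errors in any stage are logged with cell/segment context
and collected in a failure manifest; the pipeline continues.

## Problem sizes

The test suite and the acceptance script run simulated batteries at
500 fps with 30 s protocols, 5–10 cells, and 4–20 seeds per check, and
entropy oracles at 1e5 samples — sizes at which every qualitative pattern
above is stable while a full run stays in the minutes range on one CPU.

## Known limitations

* The dip p-value is bootstrap-based (n_boot = 1000 default); p < 0.001
  therefore means "no null exceedance observed", not a continuous tail
  estimate.
* The generator's efferent gains are tuned to the qualitative
  phenomenology; absolute percent changes are not calibrated to any
  recording.
* The spurious-correlation tail probability of a Gaussian null with
  σ = 0.046 at 0.2 is ~1e-5; no attempt is made to reproduce any
  particular printed tail figure.
* Kolmogorov-entropy values depend on the partition boundary rule; the
  antimode/median rule is declared in the output rather than inferred.
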