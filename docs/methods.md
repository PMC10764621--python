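# Methods

## Scope and design

`sanpace` implements the quantitative chain used in cellular
electrophysiology studies of sinoatrial pacemaker automaticity: extraction
of action-potential (AP) parameters from spontaneous recordings,
drug-response statistics across concentrations, telemetry heart-rhythm
metrics on RR-interval series, and FDR-based classification of a receptor
expression catalog. Because raw patch-clamp and telemetry recordings are
rarely redistributable, every stage is paired with a synthetic generator
whose outputs carry exact ground truth for the quantities the stage
measures; the test suite and the acceptance script validate the chain
end-to-end against that truth.

## Synthetic AP trains

Each cycle is a piecewise-analytic waveform running MDP-to-MDP:

1. a **linear diastolic ramp** from MDP to the nominal take-off voltage at
   the early diastolic slope *s* (duration `T_dia = (TOP − MDP)/s`);
2. a **logistic upstroke** to the peak, truncated to its central
   `1 − 2δ` portion (δ = 10⁻³) and rescaled to pass exactly through the
   segment endpoints, with steepness set so the maximum dV/dt equals the
   requested `upstroke_vmax`;
3. a **monotone cosine repolarization** back to MDP whose half-amplitude
   crossing falls exactly `apd50_ms` after the upstroke's half-amplitude
   crossing.

The AP-complex duration `T_ap = CL − T_dia` is derived, so slope, cycle
length, and landmark voltages are mutually consistent; infeasible
combinations (ordering violations, APD₅₀ that leaves no room for
repolarization, repolarization steeper than twice the upstroke — which
would be unphysiological and would alias into upstroke detection) are
rejected with the violated constraint named.

Because the waveform is analytic, the generator emits per cycle the values
that the *operational* definitions yield on it: in particular the
"take-off potential" reported as truth is the closed-form point on the
logistic where dV/dt = 10% of its maximum (about 1.5 mV above the nominal
ramp-end voltage for a 60 mV upstroke), which is what a correct extractor
must measure. EDDR ground truth equals *s* exactly because the 10–50%
MDP-to-TOP window always lies on the linear ramp (checked at
construction).

A drug is modeled as a multiplicative scale on the diastolic slope,
`s → s · (1 − f·a(t))`, with exponential onset
`a(t) = 1 − e^{−(t−t₀)/τ}` and optional exponential washout, plus an
optional proportional APD₅₀ stretch — matching the observation that
CCK-type agonists reduce EDDR and prolong APD₅₀ without moving MDP, TOP
or amplitude. The activation is frozen at each cycle start (quasi-static
approximation), which keeps the per-cycle truth in closed form:
`CL' = T_dia/(1 − f·a) + T_ap`. White noise (default SD 0.2 mV, a typical
patch-clamp digitization figure) and linear drift are added last; default
sampling 10 kHz.

## AP feature extraction

The derivative is a Savitzky–Golay differentiator (1 ms window, order 3 —
the window-mean of this estimator telescopes, so EDDR is nearly
noise-free even at 0.5 mV sample noise). Upstroke detection runs on a
second, 3 ms differentiator: peaks above a threshold equal to 25% of a
*robust* global maximum (the median of candidate peak heights, so one
outsized AP cannot mask the others), separated by a 40 ms refractory, and
with a 1 mV/ms absolute floor so a flat or empty trace yields zero
detections rather than noise anchors. Landmark measurements that involve
per-cycle dV/dt extrema (anchor, max dV/dt, TOP crossing) also use the
3 ms derivative: the "last upward crossing before the maximum" rule is
otherwise dragged toward the maximum by noise re-crossings.

MDP is located on a 5 ms moving-average copy of the trace (so white noise
does not bias the minimum search by ~3σ) and its voltage is read from the
raw sample at the located index; the peak is read raw because smoothing
would clip it. All threshold crossings (TOP at 10% of the cycle's dV/dt
maximum, APD₅₀ at half amplitude) use linear interpolation between
samples; upstroke crossings take the earliest hit and the TOP search takes
the last crossing before the dV/dt maximum. EDDR averages dV/dt over
`[MDP + 0.1Δ, MDP + 0.5Δ]` with `Δ = t_TOP − t_MDP` interpreted as a
**time** interval (a voltage-interval interpretation is available via
`APConfig(eddr_interval="voltage")` for sensitivity analysis; the two
coincide on a linear diastole). Cycles run MDP-to-MDP; first/last
partials are discarded; a cycle that violates `MDP ≤ TOP ≤ peak` or lacks
a required crossing is flagged invalid with a reason and excluded from
window summaries, which require ≥ 3 valid cycles and report the mean of
each parameter plus firing rate = 60000 / mean cycle length.

Measured on noiseless synthetic trains, all seven parameters agree with
ground truth to interpolation precision (rate ~10⁻¹⁴ relative, potentials
≤ 0.12 mV, APD₅₀ ≤ 0.01 ms); at 0.5 mV noise the firing-rate error stays
below 0.1% and the EDDR error below 1%.

## Dose-response

Percent change is `100 · (R_BL − R_drug)/R_BL`, positive for slowing.
Default windows: baseline = 60 s immediately before the perfusion
annotation; drug = 60 s starting 60 s after perfusion (measurement
latencies of 1–3 min are typical in perfusion experiments and the window
is configurable); washout = 60 s starting 120 s after washout. Washout is
classified complete when the post-washout rate returns within 5% of
baseline (inclusive), partial when more than half the deficit is
recovered, none otherwise; the 5% tolerance is a package convention since
published descriptions are qualitative.

The Hill fit constrains E(0) = 0, leaves the slope free, and optimizes in
log₁₀-concentration space so EC₅₀ (molar), slope and E_max are comparably
scaled; starting values come from the observed maximum and the
half-maximum interpolation. Fits are refused (flagged, not forced) for
all-zero or grossly non-monotone responses, and at least four distinct
concentrations are required. On noise-free curves the fit recovers
EC₅₀/E_max/slope to < 0.01%.

## RR series and HRV

The generator draws a stationary AR(1) process (variance equal to the
requested SDRR², 200-sample burn-in), adds sinusoidal modulation evaluated
at first-pass beat times (one-pass approximation: beat times are then
re-accumulated from the modulated intervals; the timing perturbation is of
order SDRR/mean and leaves modulation frequencies recoverable), plants
pauses only among beats that survive the duration trim, and refuses
parameter sets that would drive more than 1% of draws non-positive.

Time-domain metrics follow the standard definitions — RMSSD on successive
differences, SDRR with the n−1 denominator, pNNx with an *inclusive*
threshold (|ΔRR| ≥ x, murine default x = 6 ms) — and equal explicit-loop
oracles to machine precision. Spectral band powers use the Lomb–Scargle
periodogram of the mean-subtracted tachogram on a 4× oversampled grid up
to the HF band edge, scaled by 2/f̄ (f̄ = mean beat rate) so band
integrals approximate the tachogram variance (verified within 10% on
tone-modulated series); cubic-interpolation + Welch is available as an
alternative. Murine band defaults are LF 0.15–1.5 Hz and HF 1.5–5 Hz —
the common telemetry convention — and the band edges are echoed in every
result. Total power integrates the full estimated spectrum, so
LF + HF ≤ total by construction.

Rate histograms bin instantaneous HR (60000/RR) into half-open 10-bpm
bins normalized per activity period. Sinus pauses are intervals exceeding
2× the 50-beat centered rolling median (robust to slow rate drift);
bradycardia episodes are ≥ 10 consecutive beats below 400 bpm (half the
normal murine rate is well below, normal beats well above); runs closer
than 5 beats merge. All thresholds are carried in the report. AV block is
not detectable from RR intervals alone and is deliberately not attempted.

## Expression analysis

`bh_adjust` implements the Benjamini–Hochberg step-up exactly
(`q_(k) = min_{i≥k} min(m·p_(i)/i, 1)`, stable ties) and is tested for
equivalence against both a brute-force double loop and statsmodels.
`differential_stats` uses a pooled-variance two-sample t on log₂ values —
with the 2–3 replicates per group typical of sorted-cell designs, pooling
keeps the degrees of freedom stable where per-gene Welch corrections
become erratic — and reports the log₂ fold change as the difference of
group means. Externally computed (lfc, p) tables can be supplied directly
to the classifier, so published differential-expression outputs slot in
unchanged.

`classify_receptors` intersects the statistics table with the receptor
annotation list, applies a log₂ expression floor (default 1.0, in at
least one group), and labels each surviving receptor enriched-A
(q < FDR, lfc > 0), enriched-B (q < FDR, lfc < 0), or shared; counts
always partition the intersection. The default generator plants the
13/18/40 structure over 71 receptors among 2000 genes at log₂FC 4 with
dispersion 0.2 (log₂ SD) and 3 replicates per group; at these settings the
classifier recovers the planted partition exactly in ≈ 50/50 seeds
(Monte-Carlo), and with no planted effects the enriched fraction at
q < 0.05 stays far below 5%.

ΔΔCT: per sample ΔCT = CT_target − CT_control; per group
ΔΔCT = mean ΔCT(group) − mean ΔCT(calibrator); fold = 2^(−ΔΔCT). An
undetected target CT is censored at 40 cycles and the group's fold change
flagged as a bound, mirroring the handling needed when a transcript is
absent from one tissue. CT values must lie in (0, 45); missing control
CTs are an error.

## Pipeline, configuration, I/O

All on-disk formats are plain CSV/JSON (vendor binary electrophysiology
formats are out of scope; an import point is `sanpace.io.read_trace`,
which validates uniform sampling to 1 ppm jitter — tolerating the
integer-multiple gaps left by dropped non-finite rows — and normalizes
units to s/mV). The run configuration is a strictly validated nested
mapping: unknown keys anywhere abort before any computation, and the full
effective configuration (every threshold) is echoed into the output
MANIFEST. All randomness flows from config seeds; reruns of the same
configuration produce byte-identical bundles (timings go to the log, not
to outputs). A failed stage leaves partial outputs in place with the
MANIFEST naming the failure.

## What the synthetic data does and does not show

The generators reproduce the *structure* of the real inputs — landmark
geometry, drug kinetics acting on the diastolic slope, RR variance and
band-limited modulation, planted enrichment — but not biophysical detail:
no ionic-current model underlies the AP waveform, RR dynamics are linear
Gaussian rather than autonomically driven, and expression replicates are
log-normal rather than count-based. Passing tests therefore demonstrate
that the *measurement chain* is correct and faithful (monotone in applied
effects, exact on known inputs), not that any biological effect size is
reproduced; headline experimental numbers (e.g. maximal percent slowing
at nanomolar agonist, cohort heart rates) depend on live recordings and
are outside what desk-scale synthesis can establish.

## Problem sizes

Defaults keep everything fast on one CPU: 10 s traces at 10 kHz for
recovery checks (~50 cycles), 2–5 min RR series (~1200–3000 beats),
2000-gene tables with 6 samples, 200-replicate null simulations at 300
genes, and a 20 s end-to-end pipeline run. The full test suite runs in
about 15 s and the acceptance script in about 5 s.
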