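# Methods

`redoxtf` couples a mechanistic single-cell simulator of the
H₂O₂ → peroxiredoxin-hyperoxidation → {FOXO1, p53} switch to the analysis
pipeline used on single-cell TF-reporter movies: activation-event
detection, event-aligned aggregation, windowed autocorrelation of p53
dynamics, and fixed-timepoint quadrant classification. This note records
the model, its assumptions, the calibration of the shipped defaults, and
what the synthetic data do and do not capture.

## The model

Each cell carries seven states, integrated by fixed-step RK4 at
dt = 1 min over a 24-h movie sampled every 20 min (73 frames).

**Intracellular H₂O₂ (H).** Linear clearance at `k_clear` = 2.3 /h, so a
bolus decays below 5% of its peak in ~1.3 h, matching the known fast
depletion of an acute addition. A bolus sets H(0) = dose (µM-equivalent
labels); continuous enzymatic production adds H at rate
v = `gox_rate`·dose^`gox_exponent` per hour, reaching the steady state
v/`k_clear` with a ~30-min rise. The sublinear exponent (≈0.5) encodes
transport/O₂ limitation of the enzyme; a linear mapping cannot reconcile
the shallow death–dose curve under continuous production with the steep
bolus curve (see Calibration). An optional production dip after the first
hour (`gox_dip`) and a cell-density dose attenuation (`density_coupling`)
are provided but off by default.

**Hyperoxidized PRDX fraction (P).** Mass-action hyperoxidation with
first-order sulfiredoxin repair,

    dP/dt = k_hyp·H·(1 − P) − k_srx·m_srx·P,    P(0) = 0, P ∈ [0, 1],

where `m_srx` is the SRXN1 activity multiplier (0 for the inhibitor,
4 for overexpression). P is the switch variable of the whole model.

**The two-threshold switch.** While P exceeds `theta_F` (default 0.40),
the FOXO1 nuclear fraction relaxes toward `f_max` = 0.9 with time
constant `tau_f` = 9 min, and the p53 subsystem is frozen (production,
feedback, and upstream drive all halted). When P falls back below
`theta_F`, FOXO1 relaxes toward its cytoplasmic resting point and p53 is
released. Because P integrates H, an acute bolus crosses both the p53
and FOXO1 thresholds nearly at once (FOXO1 first, p53 blocked), whereas
slow accumulation under continuous production crosses the lower p53
threshold hours before P reaches `theta_F` — reproducing the reversal of
activation order between the two exposure modes, and the p53 plateau
once FOXO1 enters the nucleus under continuous production.

Below the threshold, the resting FOXO1 nuclear fraction is
`f_min`/(1 + `k_retention`·P): the still-active PRDX relay tethers FOXO
in the cytoplasm (disulfide retention), so sub-threshold-stressed cells
sit slightly *below* the untreated baseline. This matters for snapshot
classification: without it, a control-quantile threshold fixes the FOXO1
false-positive rate at exactly 1 − quantile in every treated condition,
and the both-active fraction is pinned to the mutual-exclusivity bound
by construction. The measured p53 channel is symmetrically scaled by
1 − `p53_suppression`·P (default 0.12): severe hyperoxidation mildly
suppresses the basal p53 pool, so cells frozen in the blockade sit at or
just below the untreated baseline — consistent with high-dose p53 levels
reading comparable to untreated controls — rather than exactly on the
control distribution where the quantile cut would misclassify 5% of
them.

**Damage (D) and death.** Damage integrates the H₂O₂ burden plus a
contribution from hyperoxidized PRDX that is suppressed by the SRXN1
cycling flux:

    dD/dt = k_dmg·H + k_pdmg·P/(1 + m_srx·k_srx/k_srx_half) − k_rep·D.

The flux-suppression term is the package's resolution of an otherwise
contradictory pair of observations: sustained continuous production
holds P high for a day at modest lethality, while blocking SRXN1 at a
mildly lethal bolus dose is strongly lethal. The discriminating variable
cannot be P itself; it is whether the repair cycle is running. Death is
a hazard process on excess damage,

    λ(t) = lambda_d · min(max(D − D_c, 0), hazard_cap),

with a per-cell unit-exponential threshold on the cumulative hazard and
a 3-h commitment-to-execution latency (`death_latency`). The cap makes
survival possible even at extreme doses (a few percent survive the
highest bolus) and spreads deaths over hours rather than minutes, which
is what makes nuclear-residence durations measurable in doomed cells.

**p53 (x above baseline) and MDM2 (M).** A delayed negative feedback
with cooperative repressor production:

    dx/dt = beta_p·s − (alpha_p·M + alpha_x)·x
    dM/dt = gamma_m/(1 + (D/d_m)²) · x(t−τ)⁴/(K_m⁴ + x(t−τ)⁴) − delta_m·M

with transcriptional delay τ = 1.5 h (sample-and-hold at the integration
step). A purely linear delayed pair cannot oscillate here — its loop gain
stays below the Hopf threshold for any rate choice — so the repressor arm
uses a fourth-order Hill term, the standard relaxation form for this
feedback. The limit cycle has a ~5.5–6 h period and 30–60 AU pulses on a
100 AU baseline. Damage weakens the feedback (`d_m`), so heavily damaged
(dying) cells show a sustained, higher rise instead of pulsing; this is
what the fate-stratified autocorrelation comparison detects.

**Upstream drive (s).** The p53-activating signal follows
u = (D + `w_relay`·P)·[P ≤ `theta_F`] through a first-order filter:
rise time `tau_act` = 1.5 h when u > `theta_p`, decay `tau_deact` = 24 h
once activated (the stress-kinase signal effectively latches for the
movie, which keeps pulsing alive through the 10-h analysis window), and
fast shut-off during the freeze. A short transduction latency
`tau_sig` = 12 min precedes the filter. Together these set the ~1 h
median lag between detected FOXO1 exit and detected p53 onset and keep
FOXO1-first ordering above 95% of activating cells under acute exposure.
The `w_relay`·P term lets hyperoxidation itself contribute drive at low
doses, which is why SRXN1 overexpression *reduces* p53 activation below
~60 µM while increasing it at high doses.

**Heterogeneity and measurement.** Each cell draws lognormal multipliers
(CV = `cv_cell` ≈ 0.20) on `k_hyp`, `k_clear`, `theta_F` and `D_c` from a
counter-based (Philox) stream keyed on (seed, cell index) — populations
are bit-reproducible and independent of batch size. Both channels carry
5% multiplicative measurement noise; samples at or after the death time
are missing. PRDX-loss perturbations scale `k_clear` and `theta_F` down
by `prdx_capacity_multiplier` (0.70 knockout, 0.85 knockdown): a smaller
pool scavenges less and needs less oxidation to be inactivated.

## Calibration of the shipped defaults

The death model — `lambda_d`, `D_c`, `k_dmg`, `cv_cell`, plus the
continuous-production mapping (`gox_rate`, `gox_exponent`), `k_pdmg`,
`k_rep` and `hazard_cap` — was fit once by Nelder–Mead
(`redoxtf.calibrate.fit_death_model`, arcsine-square-root scale) to seven
24-h death fractions: 1/11/34/97% at the four bolus settings, 27/97% at
the two extreme continuous settings, and 70% for SRXN1 inhibition at the
~14%-lethality bolus dose; a final polish used 800 cells per condition.
Achieved rates: 0.5/12.0/33.8/97.0%, 27.1/97.0% under continuous production, and 70.0% under SRXN1 inhibition. The timing
constants (`tau_act`, `tau_sig`, `tau_f`) were set so the pooled median
exit→onset lag is 1.0 h (one 20-min frame lattice cell) and entry occurs
within 1 h in activating cells. `theta_F` and `k_hyp` were chosen so the
bimodal activation split and the duration–dose slope across 50–300 µM
match the observed pattern. All other constants are order-of-magnitude
physiological choices fixed before any fitting.

## Event detection

FOXO1 episodes use hysteresis on the 3-frame running median of the
nuclear fraction: entry at the first of ≥2 consecutive frames ≥ 0.55,
exit at the first of ≥2 consecutive frames ≤ 0.45; episodes open at death
or movie end count to the last observed frame; the longest episode is the
cell's primary anchor. p53 onset is the first run of 3 consecutive frames
above baseline + 3·scale, with the baseline the median of the first three
frames and the scale a Gaussian-consistent MAD (×1.4826) floored at 5% of
baseline. The floor is essential: the MAD of three points is the smaller
of two deviations and collapses toward zero often enough that, without
it, onset calls during the p53 blockade are noise artifacts and the
lag/ordering statistics are meaningless. The p53 rate series uses central
differences (one-sided at the ends, NaN-propagating).

## Alignment and autocorrelation

Event-aligned ensembles re-index each anchored cell to lag = t − t_event
and summarize lags by median and MAD where ≥5 cells contribute. Heat-map
orders sort by descending nuclear duration (acute) or ascending entry
time (continuous), anchor-less cells last, ties by cell id.

The p53 autocorrelation window follows the FOXO1-conditioned rule: first
10 h for cells that never accumulate FOXO1; the 10 h after exit for cells
with a completed episode (truncated, and flagged, at the last observed
frame); cells whose episode never closes are excluded. Windows are
linearly detrended by default — not part of the original procedure, but
without it a monotone post-exit rise masquerades as long-lag structure —
and require ≥8 valid frames. The oscillation score is the maximum sample
ACF over 3–8 h lags; the binary call compares it with
max(0.2, 2/√n). Note that a 31-frame window puts that floor at 0.36,
which even a pure sinusoid only just exceeds, so realistic noisy traces
are mostly called non-oscillatory; fate comparisons therefore rest on the
continuous score (surviving-cell median > dying-cell median), not the
binary fractions.

## Snapshot classification

Activation cuts are the 95th percentile of the untreated control for
each channel (log nuclear p53; FOXO1 nuclear fraction); a cell strictly
above both cuts is "both", etc. By construction the control
false-positive rate per channel is 1 − quantile. The classifier is
channel-agnostic, so any level-TF/shuttling-TF pair can be gated the
same way. Fixed cuts can be supplied for cross-condition comparability.

## What the generator does and does not emulate

Emulated: 20-min sampling over 24 h; dose-dependent bimodal activation;
acute-vs-continuous ordering reversal; dose-dependent entry times and
nuclear residence; the p53 blockade and plateau; pulsing vs sustained
p53 by fate; dose-dependent death with the published fractions; the four
perturbation phenotypes (SRXN1-OE, SRXN1 inhibition, PRDX1-KO,
PRDX2-KD); lognormal cell-to-cell spread and multiplicative shot noise.

Not emulated: cell division and lineage effects; tracking errors,
focus drift and segmentation noise (noise here is i.i.d. lognormal);
spatial H₂O₂ gradients and explicit thioredoxin/NADPH pools (lumped into
`k_srx` and the relay terms); p53 activation at the very lowest doses is
weaker than observed (~6% active at 20 µM versus a substantial
fraction), a consequence of the single drive threshold `theta_p`;
absolute fluorescence scales are arbitrary. Passing tests therefore
validate the pipeline's logic and the model's coherence with the
reported population statistics, not photometric realism.

## Numerical choices and degenerate inputs

Fixed-step RK4 at 1 min (stiffness-free system; bitwise reproducibility
preferred over adaptive steppers); delay terms held constant across the
four RK4 stages; states clipped to their physical ranges after each
step; non-finite states raise an error naming the cell. The H and P
subsystems agree with their closed forms to relative error < 1e-6 on
constant inputs. Zero-variance ACF windows are flagged and excluded, not
scored. Grid uniformity on read is checked to 1e-3 h, the tolerance
implied by 6-significant-digit CSV printing of the time column;
simulator output in memory is uniform to 1e-9 h. Empty dose groups are
dropped from dose-response tables with a warning. Problem sizes in the
test suite and acceptance script (150–2000 cells per condition) were
chosen to keep binomial noise well inside the quantities' tolerances.
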