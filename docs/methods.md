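# Methods

## The task and the quantity of interest

In the bimanual finger-oscillation paradigm both index fingers oscillate
laterally to an accelerating metronome (ten plateaus, 1.4–3.4 Hz, five
beats each, one full movement cycle per beat, ~22 s per trial). The core
performance variable is the **relative phase** between the two fingers'
lateral-position oscillations, expressed in external space: 180° is
perfect mirror symmetry (one finger leftmost when the other is rightmost),
0° is perfect parallel movement. Accuracy is the probability that a cycle's
phase falls within a tolerance window (±50° by default, ±20° as a stricter
variant) around the instructed target.

## Kinematic pipeline

Per trial and hand: missing samples are linearly interpolated (edge runs
held at the nearest observed value; trials with more than 20% missing are
excluded), the trajectory is low-pass filtered with a first-order
Butterworth at 7.5 Hz applied forward and backward (zero phase — a causal
pass would bias phase differentially across movement speeds), and
demeaned.

Movement cycles are the intervals between consecutive maxima and minima of
the **right** finger's trajectory, located with a prominence threshold of
10% of the trial position s.d. and a minimum spacing of half the fastest
metronome period; cycles whose peak-to-peak excursion falls below 20% of
the trial median are dropped as unidentifiably small. Each cycle is
assigned the metronome plateau (1–10) containing its temporal midpoint.

Per cycle, a sine `offset + A·sin(2πft + φ)` is fitted to each finger.
The frequency is shared by the two fingers (they track the same beat): it
is refined by bounded scalar minimization of the residual on a window of
up to 1.5 periods of the right finger, clipped to the cycle's own
metronome plateau so tempo changes cannot leak in. Amplitude, phase and
offset then come from a Hann-weighted linear least-squares fit at that
frequency on a 0.7-period window centered on the cycle; because the fit
is model-based it is unbiased under any weighting, and the taper
suppresses the influence of neighbouring cycles that the zero-phase
filter smears across window edges. Both fits share the window's time
origin, so the relative phase is simply φ_left − φ_right, wrapped to
[−90°, 270°) — an interval chosen so that both attractors (0° and 180°)
lie in its interior. Cycles whose windows would cross the trial edges
fall back to a plain fit on the max→min interval (trimmed by 2 samples
against filter transients).

An optional cross-check (`continuous_phase_diff`) computes the
analytic-signal (Hilbert) instantaneous phase difference averaged
circularly per cycle; it agrees with the sine-fit route on clean data.

## Accuracy scoring

A cycle is correct when the **circular** distance between its relative
phase and the instructed target (180° symmetrical, 0° parallel) is at most
the tolerance; a distance exactly equal to the tolerance counts as
correct. Circular distance makes scoring consistent near the wrap
boundary. Histograms use 18 half-open 20° bins over [−90°, 270°),
normalized per participant to percentages.

Speeds pool into slow (plateaus 1–5) and fast (6–10); the four raw palm
configurations pool into same (both up / both down) vs different
orientation. Conditions 1–8 number the instruction × pooled-posture cells,
odd without mirror, even with; in mirrored blocks the mirror always shows
two same-oriented hands moving symmetrically, so congruence of visual
movement direction holds for symmetrical instructions, congruence of seen
posture for same orientations, and congruence of apparent muscles exactly
when the true movement requires homologous muscles (conditions 2 and 8;
4 and 6 are incongruent).

## Hierarchical Bayesian logistic regression

Cycle correctness is modelled as Bernoulli with

    logit P(correct) = β₀ + Σₖ βₖ xₖ + u_j

where x are the ±1 sum-to-zero codes of the four main effects
(instruction: symmetrical = +1; mirror: non-mirrored = +1; posture:
same = +1; speed: fast = +1) and of all 11 interactions (products of main
codes), and u_j are zero-centered participant intercepts. All 16 group
weights get normal priors centered on zero whose **precision** is drawn,
per weight, from an inverse-gamma(shape 1, scale 0.01) hyperprior — the
literal reading of the precision hyperprior; an option flag provides the
conventional variance-inverse-gamma reading (precision ~ gamma), and an
alternative hyperparameterization (0.01, 0.01) supports prior-robustness
checks. The participant intercepts share one precision with the same
hyperprior family.

Sampling is by Metropolis-within-Gibbs, all chains advanced as vectorized
state: each group weight is updated by an adaptive random-walk step
(target acceptance ≈ 0.44, adaptation frozen after burn-in); participant
intercepts update in one parallel block since the likelihood factorizes
across participants; a recentering move shifts β₀ and all u_j in opposite
directions along the likelihood-invariant ridge, which is what makes the
intercept mix; precisions are drawn exactly from their conditional
generalized-inverse-Gaussian (a Wald draw in the shape-1 special case, or
a gamma under the variance parameterization). The likelihood is evaluated
on sufficient statistics — per participant × design-cell success counts —
so a fit on 62k cycles costs the same as one on its ~320 cells.

The default schedule mirrors the standard reporting setup (4 chains,
1,500 burn-in, 60,000 post-burn-in iterations thinned by 20 → 12,000
recorded draws); the `scaled` profile (4 × 2,000 unthinned draws after
1,000 burn-in) is the routine/testing default and completes a full-size
fit in seconds. Convergence is monitored by effective sample size and the
potential-scale-reduction (shrink) factor, computed with ArviZ; shrink
factors above 1.1 raise a warning.

Inference follows the HDI-exclusion rule: the 95% highest-density interval
is the shortest contiguous interval containing ⌈0.95·n⌉ sorted draws; a
weight contributes when this interval excludes zero (a boundary exactly at
zero counts as spanning).

## Contrasts

Cell predictions evaluate the group-level linear predictor at a cell's ±1
codes per posterior draw, with the participant effect at its population
center; leaving a factor out zeroes its codes, which equals averaging its
two levels on the logit scale. Credible differences are formed per MCMC
draw (paired, preserving posterior correlation) and summarized by mean,
95% HDI and the fractions of draws below/above zero. The named suite
contains twelve comparisons: homologous minus non-homologous posture per
instruction × speed (four), mirrored minus non-mirrored per instruction ×
speed (four), muscle-congruent minus incongruent within mirrored blocks
per instruction (two), and congruent-mirrored vs congruent-non-mirrored
per instruction (two). Differences are reported on the logit scale;
`logit_to_percent` and `percent_point_change` convert to percent correct.

## Synthetic-data generator

The generator emulates the experiment's structure, not its biomechanics.
Defaults: 20 participants, 2 sessions, 4 repetitions of each of the 16
block conditions, 100 Hz sampling, ten speeds 1.4–3.4 Hz × 5 beats,
amplitude 20 mm, additive Gaussian position noise 0.5 mm, 2% per-sample
marker dropout, a 25 ms dominant-(right-)hand lead, and ~2.5% of cycles
lost to pauses/off-beat movement — which yields ≈39 analyzable cycles per
condition (instruction × posture-pooled × mirror cell × speed plateau) and
participant and ≈62k cycles in total. Group-level effects default to
logit-scale magnitudes representative of adult performance in this task
(strong symmetry advantage 0.82, speed cost −0.62, homologous-muscle
advantage 0.48 on instruction × posture, small mirror × instruction
modulation); participant intercepts are Normal(0, 0.5 logits) — the 0.5 is
a free choice producing between-subject spread comparable to published
group data, as no population value is available.

Correctness is drawn **first** (Bernoulli at the cell's model probability)
and the cycle's phase error second — truncated von Mises(0, κ = 8) within
the ±50° window when correct, uniform over the complement when not — so
that scoring the generated phases recovers the generating probabilities
exactly, making parameter recovery a clean end-to-end test. Waveforms are
phase-continuous piecewise sinusoids: the right hand leads the metronome
by the configured lead; the left hand carries a constant per-beat phase
offset equal to the drawn relative phase, with offset transitions blended
over ±0.03 beat centered in the unfitted min→max half-cycle, where they
cannot contaminate the fitted windows. Seeding is hierarchical: one master
seed, per-trial counter-derived substreams, so any trial regenerates
independently. A cycle-level fast path (`simulate_cycle_outcomes`) emits
the outcome table directly without waveform synthesis and is used for
large parameter-recovery runs; the trajectory path exercises the kinematic
stages.

What the generator does **not** emulate: coupled-oscillator dynamics
(no phase attraction, transition hysteresis or phase wandering within a
cycle), marker-cluster geometry (one position stream per hand; the
secondary dimension is noise only), serial correlation of errors across
cycles, and participant-specific speed–accuracy trade-offs beyond the
global intercept. Passing tests therefore demonstrate that the pipeline
measures what the generative model encodes — not that the model captures
every property of real kinematic data.

## Numerical choices and edge cases

- Frequency refinement uses bounded Brent minimization (tolerance 1e-9
  relative) within [0.5, 2] × the initial guess.
- The phase-estimation cross-check oracle is a Hann-tapered circular
  cross-correlation over one exact period with the peak read from the
  fundamental harmonic of the correlation curve; a plain truncated-window
  correlation is biased toward zero lag, and 3-point peak interpolation
  amplifies correlated noise.
- Degenerate inputs: all-missing trajectories and empty outcome tables are
  rejected with named errors; a flat trajectory yields no cycles; all-equal
  outcomes warn and return a prior-dominated posterior; a single chain
  reports its shrink factor as missing.
- On noise-free generator output the measured relative phase matches the
  drawn phase to well under a degree for ~99% of cycles; a small tail
  (max ≈ 1.4°) remains at the fastest tempo when both neighbouring cycles
  carry near-opposite phases, via the smoothing filter's exponential tail.
- HDI on multimodal draw sets still returns the shortest contiguous
  window; the posteriors here are unimodal in practice.

## Limitations

- The sampler is tuned for this model family (logistic, ≤ a few dozen
  parameters, cell-aggregable likelihood); it is not a general-purpose
  MCMC engine.
- With weakly informative data (hundreds of cycles) the heavy-tailed
  hyperprior leaves beta posteriors diffuse; posterior means then carry
  large Monte-Carlo error in any finite chain, and bounded summaries
  (cell probabilities) are the stable quantities.
- Printed credible-difference magnitudes from the original dataset are
  not reproducible from synthetic data; only sign and ordering patterns
  are checked.
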