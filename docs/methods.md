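# Methods

## The measurement chain

All trials — synthetic or imported — pass through the same preparation:

1. **Filtering.** Every channel is low-pass filtered with a zero-phase
   (forward–backward) 4th-order Butterworth filter, cutoff 8 Hz. The two
   passes square the magnitude response, so the effective gain at
   frequency f is 1 / (1 + (f/8)⁸). CoM velocity is obtained by central
   differences *after* filtering (filter-then-differentiate), which is the
   noise-robust ordering.
2. **Gait events.** Heel strike is an upward crossing of 20 N on the
   vertical GRF sustained ≥ 50 ms; toe-off is the following downward
   crossing. Events are detected on the **raw** force signal: the 8 Hz
   zero-phase filter smears the contact transient over tens of
   milliseconds and, because the post-contact force slope scales with body
   weight, filtering first introduced a body-mass-dependent heel-strike
   bias of up to one marker sample (≈ 1 cm of MoS) — detectable only
   because the generator knows the true contact times.
3. **Per-step outcomes.** MoS and step length are evaluated at the marker
   sample nearest the detected heel strike; 1D channels are linearly
   interpolated onto 101 nodes spanning [heel strike, toe-off], inclusive.
   ω₀ uses g = 9.81 m/s² and leg length 0.53 × body height (anthropometric
   proxy; the factor is configurable).
4. **Baseline.** Each participant's unperturbed baseline is the mean and
   sample SD of the MoS over five consecutive gait cycles of the side that
   is later perturbed, skipping two warm-up steps. The per-participant SD
   (not a group SD) defines the ±1 SD band of the n_steps criterion, with
   inclusive band edges; ties at the boundary count as "within".
5. **n_steps.** First index k (1-based) with steps k, k+1, k+2 all in the
   band; 16 (capped) otherwise. Values 14–15 are unreachable under the
   three-step rule, which is consistent with the cap convention.

## The synthetic cohort

The generator emulates a two-group study (17 young adults, 25.2 ± 3.7 y,
176.1 ± 8.1 cm, 71.8 ± 10.1 kg; 17 older adults, 62.4 ± 6.6 y,
161.8 ± 7.2 cm, 66.5 ± 11.3 kg) walking at 1.2 m/s with step time 0.55 s
and stance 0.70 s (0.65 s on the perturbed step — stance quickens under
the slip). The belt under the perturbed foot follows a triangular speed
bump: +5 m/s² from 20 % to 70 % of commanded stance, peak speed
1.2 + 5 × (episode/2) m/s. Perturbed side is a seeded coin flip per
participant, fixed across slips.

### Balance model

For recovery step k of slip s:

    MoS(s, k) = baseline + anticipation(s)
                − A1 · ρ^(s−1) · exp(−(k−1)/τ) + ε,   ε ~ N(0, σ²)

    anticipation(s) = γ · (1 − exp(−(s−1)/3))

The exponential form is the simplest able to reproduce the printed
per-step means and the adaptation across slips. Pre-slip and perturbed
steps carry `baseline + anticipation(s) + ε` (the slip strikes mid-stance,
after the perturbed step's heel strike).

A single latent proficiency factor z ~ N(0,1) per participant carries all
between-participant couplings: A1 = 6.0428 − 1.5 z (cm, clipped ≥ 0.5),
τ = N(4 − 0.8 z, 0.4) steps (clipped to [1, 12]), step-length and
joint-moment deviations scale with A1/Ā, and the GRF-angle shifts scale
with (1 + 0.2 z). Less proficient walkers therefore suffer a larger and
slower-recovering disturbance, shorten their first recovery step more,
produce larger knee-extensor and smaller plantarflexor compensations, and
need more recovery steps — the sign structure the correlation analysis
measures.

### Calibration

Three printed cohort anchors identify the three free dynamics parameters
(baseline 4.6 cm is drawn directly; γ keeps its 1.0 cm default):

- Slip01 Rec6 = 2.8 cm  ⇒  E[A1 · e^(−5/τ)] = 1.8 cm
- Slip03 Rec1 = 2.0 cm  ⇒  E[A1] · ρ² = 4.6 + γ(1 − e^(−2/3)) − 2.0

With the proficiency loadings above, the expectations were evaluated by
Monte-Carlo quadrature (2 × 10⁶ draws, fixed seed), giving A1 mean 6.0428
cm and adaptation rate ρ = 0.7147. These ship as the defaults and are not
tuning knobs. Ten-replicate verification through the full pipeline gives
cohort means 4.51 / 2.81 / 1.85 cm against 4.6 / 2.8 / 2.0, the residual
deviations being cohort-sampling scatter (≈ 0.2–0.3 cm SE per study).
Within-participant step-to-step SD is drawn from N(1.3, 0.5²) truncated to
[0.4, 3.1] cm; between-participant SD of the baseline mean is 1.0 cm.

The same calibration reproduces the recovery-outcome pattern without
targeting it: mean n_steps falls from ≈ 12 (first slip, ~14/34 capped)
towards ≈ 8 by the fourth slip.

### Waveforms

Continuous channels are synthesised per step from parametric templates:
vertical GRF as a double hump (peaks ≈ 1.1 BW near 25/75 % stance, valley
0.75 BW) over a 30 N contact pedestal; GRF angle as −8°·sin(2πu) (posterior
braking, anterior propulsion) with the slip adding a −4° mid-stance and
+3° push-off shift on the perturbed step of every slip; ankle moment
rising monotonically to a push-off peak (1.4 N·m/kg, −0.15 for older
adults) at 75 % stance; knee and hip as biphasic bump mixtures. First-
recovery-step deviations — step length −21 %, knee extensor peak +200 %,
plantarflexor peak −25 % — decay with ρ^(s−1) (normalised by the last
slip), while the +8 % perturbed-step lengthening and the GRF-angle shifts
are maintained across slips, matching the observed retention pattern.
Each step also receives 6 % multiplicative template-amplitude noise and a
smooth additive disturbance (offset plus two broad lobes; 0.05 N·m/kg for
moments, 0.8° for GRF angle). Without that variability the cohort's
stance curves were near-identical and the node-wise t statistics
degenerate.

### Kinematic reconstruction

Foot placements follow the step-length recursion on the moving belts
(normal step length = belt speed × step time, which keeps treadmill-frame
positions stationary); stance feet translate with their belt, swings are
polynomials matched to stance kinematics up to the 4th derivative so the
8 Hz filter leaves heel-strike positions essentially untouched. The CoM is
reconstructed from the *target* XCoM trajectory (a cubic spline through
the per-heel-strike constraints implied by the imposed MoS) by integrating
x′ = ω₀(XCoM − x), exact for piecewise-linear targets; by construction
x + x′/ω₀ reproduces the target identically, so the pipeline's
filter-differentiate-evaluate chain recovers imposed MoS values to
< 0.03 cm (test bound 0.05 cm).

## Statistics

1D inference is nonparametric: the threshold is the (1−α) quantile of the
permutation distribution of the maximum |t| over the 101 nodes (sign-flip
permutations for paired contrasts, label permutations otherwise,
exhaustive enumeration when ≤ n_perm). This controls the family-wise error
across nodes without random-field assumptions; the type-I error of the
whole procedure is verified by simulation (any-cluster rate 3–7 % at
α = 0.05). Zero-variance nodes receive a large sentinel statistic and are
flagged. Condition contrasts vs baseline use α = 0.0056 (nine-contrast
Bonferroni family); the other documented families map 5→0.01, 7→0.007,
8→0.0063, 10→0.005, 45→0.0011.

Scalar comparisons: Friedman + Wilcoxon signed-rank post-hocs (zero
differences dropped, the standard convention) for n_steps and pre-slip
MoS; Mann–Whitney for age; mixed-design ANOVA (via pingouin, no sphericity
correction — a documented limitation) for recovery-step MoS, repeated per
slip at α = 0.005. Correlations use Pearson only when both variables pass
Shapiro–Wilk at 0.05, otherwise Spearman; correlations involving n_steps
exclude capped participants and report the excluded count; correlation
p-values carry no further multiplicity correction.

## What a green test does and does not establish

The generator reproduces the *statistical skeleton* of a real perturbed-
gait study: cohort-level MoS means and variability, recovery and
adaptation dynamics, retention/discarding of mechanical adjustments, and
a consistent single-factor correlation structure. It does not emulate:
marker soft-tissue artefact or measurement noise (channels are smooth,
targets are imposed exactly); timing adjustments of heel strikes under
perturbation (step timing is fixed); mediolateral dynamics, trunk
kinematics, or muscle-level mechanics; age effects beyond a fixed
plantarflexor-peak deficit (the real age contrast is null on balance
outcomes, which the generator matches trivially). Passing calibration
therefore validates the pipeline's arithmetic and the model's cohort
means, not the biomechanical fidelity of individual waveforms.

Known limitations: the exponential adaptation model cannot hold the
first-recovery-step MoS depressed at late slips (the emulated study shows
a plateau: its Slip06 Rec1 ≈ 1.9 cm), so only the two calibrated recovery
anchors are matched; SPM clusters at the extreme stance edges (< 3 % or
> 95 %) can reflect filter edge effects on the synthetic templates;
stance-phase percentages refer to commanded belt timing, whereas a
physical treadmill adds mechanical latency (the real protocol measured
onset near 25 % and return near 86.5 % of stance).
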