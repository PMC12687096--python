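# Methods

This note documents the models behind `prehabsim`, the defaults and why
they were chosen, the numerical conventions, and what the synthetic data
can and cannot show.

## 1. Synthetic cohort model

The generator emulates a two-arm feasibility trial (default n = 71,
allocated 1:1 with the odd participant to the intervention arm) of an
intensive preoperative weight-loss program before colorectal cancer
resection.

**Baseline covariates.** Age ~ N(64, 8.7²) years; BMI ~ N(35.4, 5.4²)
kg/m² (floored at 15); sex Bernoulli(0.61 male); WHO performance status
restricted (1–2) with probability 0.30. Height is drawn by sex
(N(1.75, 0.07²) m for males, N(1.62, 0.07²) for females — UK adult
anthropometry) and baseline weight is BMI × height², giving a mean of
about 102 kg. Height is not a reported trial quantity; it exists only to
give weight a realistic scale and dispersion.

**Pathway times.** Both intervals (MDT meeting → randomization,
randomization → surgery) are lognormal, the natural right-skewed family
for waiting times; nothing beyond median and IQR is available, and the
lognormal fit to (median m, IQR q) is closed-form:
μ = log m, σ = asinh(q / 2m) / z₀.₇₅. The surgery interval is truncated
below at the 20-day minimum window (an eligibility requirement), by
inverse-CDF sampling on the conditional distribution. Defaults: 17 (27.5)
and 33 (17.5) days.

**Intervention weight loss.** The percentage of baseline weight lost by
surgery is

  pct(D) = R · T_med · (D / T_med)^γ,  T_med = 33 d,

where D is the participant's window, R a participant-specific rate
(% of baseline weight per day at the median window) drawn from a normal
truncated at zero, and γ the time exponent. Kilogram change is
−pct·weight/100 plus N(0, 0.5²) measurement noise.

Two calibration steps fix the free parameters, both performed analytically
at design time (they are *derivations from the stated study conditions*,
not tuning knobs):

1. *(R mean, R sd)* solve the two-quantile system
   P(33R ≥ 5) = 0.61, P(33R < 2) = 0.08 under the zero-truncated normal
   (numeric root find; `calibrate_loss_rate`). This encodes the adherence
   mixture — 61 % adherent, 8 % nonadherent — at the median window.
2. *γ = 0.5.* A linear-in-time accumulation (γ = 1) is inconsistent with
   the remaining study conditions: with the mixture fixed at 33 days it
   implies a mean between-group difference near −4.9 kg and a
   loss-versus-days correlation near 0.55, overshooting both the −4.3 kg
   effect and the r ≈ 0.38 association. Very-low-energy-diet weight loss
   is front-loaded (glycogen/water early, adaptive slowing later), so a
   concave square-root-time curve is the physiologically sensible family;
   γ = 0.5 jointly lands the mean difference near −4.3 kg and the
   correlation near 0.3, within the trial's plausible range. γ = 1
   recovers the plain per-day-rate model.

**Usual care.** Weight change ~ N(−2.0, 2.5²) kg, independent of the
window (no information suggests a time association in the control arm,
so none is modeled). Both arms share a common postoperative drift
N(−2.0, 1.0²) kg so the 30-day change preserves the between-group
difference. Fat-free-mass change is a per-arm fraction of the weight
change (0 for the intervention — FFM preserved; 0.05 for usual care,
centering the between-group FFM difference near +0.1 kg) plus
N(0, 2²) kg noise matching the reported interval widths.

**Complications.** Presence ~ Bernoulli with per-arm probabilities 0.39 /
0.40 on the logit scale plus an optional weight-loss effect (log-odds per
percentage point lost; default 0, because the observed loss–morbidity
association is exploratory and its causal magnitude unknown — the lever
is exposed, not asserted). Affected participants draw a zero-truncated
Poisson event count with mean 51/28 ≈ 1.82 (pooled events per affected
participant; no count distribution is reported, and the ZTP is the
minimal choice consistent with "at least one event"). Grades are i.i.d.
categorical over {I: 0.35, II: 0.45, IIIa: 0.15, IIIb: 0.05} — mostly
minor, no grade IV/V by default. Retention is Bernoulli(1.0).

**Allocation.** Arms come from the minimization module (below) with
q = 0.2, plus per-arm quotas from the allocation ratio so the final split
is exactly 36/35; once an arm fills, the remainder goes to the other arm
(the trial's fixed final split cannot otherwise be guaranteed by a
stochastic rule).

**Determinism.** One `numpy` Generator seeded per cohort drives every
draw in a fixed order; equal (config, seed) pairs give byte-identical
CSVs.

## 2. Minimization

Pocock–Simon with the range (absolute-difference) imbalance metric,
equal factor weights, two factors (performance status 0 vs 1–2, age <70
vs ≥70). The "random element" q defaults to the coin-flip reading: with
probability q the minimization rule is ignored and a fair coin decides;
ties always fall to a fair coin. A biased-coin variant (minimizing arm
with probability 1 − q) is available, since the phrase admits both
readings. No explicit total-count factor is included; overall 1:1
pressure enters through the factor margins.

## 3. Complication scoring

CCI = min(100, √(Σ wᵢ)/2) with the published severity weights
w = {I: 300, II: 1750, IIIa: 2750, IIIb: 4550, IVa: 7200, IVb: 8550,
V: 39940}; any grade V (death) maps directly to the scale maximum 100.
Single-event values reproduce the public calculator (I → 8.7, II → 20.9,
IIIa → 26.2, IIIb → 33.7, IVa → 42.4, IVb → 46.2). Events are pooled
across discharge and 30-day time points into one index per participant.
Adjudication of two coders' grades: agreement passes through;
disagreements resolve by `take_higher` (conservative pipeline default —
"discussion" cannot be automated), `take_lower`, or `consensus_flag`
(emit unresolved for human review).

## 4. Trial analysis

- **Adherence:** loss ≥5 % adherent; loss <2 % nonadherent; otherwise
  intermediate. Exactly 2 % loss is intermediate, exactly 5 % adherent.
- **Odds ratio:** (ad)/(bc) with Woolf log-scale 95 % CI
  (z = 1.96); Haldane–Anscombe +0.5 on all cells only when requested and
  a cell is zero.
- **Between-group differences:** ANCOVA — OLS of the outcome on an arm
  indicator plus the baseline covariate, normal-approximation 95 % CI.
  Each outcome is analyzed at a single time point, so the ANCOVA form
  stands in for repeated-measures mixed models without loss. A constant
  baseline column is dropped (the estimate then equals the raw
  difference). Missing outcomes are dropped, never imputed.
- **Progression criteria:** green iff observed ≥ green limit; red iff
  observed ≤ red limit (boundary counts as red — conservative, since the
  published zone conventions are not available); else amber. Proportion
  criteria get an exact one-sided binomial tail p-value against the red
  limit. Default green limits (adherence 0.60, engagement 0.75, retention
  0.875) are chosen so the exact test at the planned n has ≈90 % power;
  they are user-supplied settings, not reported trial values.
- **Median-split CCI:** split the whole cohort at the median percentage
  loss; ratio of mean CCI (high-loss / low-loss) with a percentile
  bootstrap CI, B = 2000, resampling within groups, seed-controlled. The
  interval is forced to cover the point estimate (percentile intervals
  on small, zero-inflated samples can otherwise exclude it). A zero-mean
  reference group raises an undefined-ratio error.
- **Analysis sets:** ITT = all randomized with observed outcome;
  per-protocol = full usual-care arm plus adherent (≥5 % loss)
  intervention participants.

## 5. Feasibility design

Non-randomized exact one-sided binomial test: k* = min{k : P(X ≥ k |
p_red) ≤ α}; power = P(X ≥ k* | p_alt); attained size ≤ α always.
Collective power across criteria defaults to the product rule under an
independence assumption, exposed as a strategy parameter. Note the
arithmetic consequence: three criteria at 90 % each give 0.9³ ≈ 0.73
collective, so a "90 % per criterion / 85 % collective" pairing cannot
arise from the product rule — the package reports whatever the chosen
rule yields rather than reconciling the two numbers. Sample-size search
scans n upward (exact power saw-tooths, so the defining property is
power(n) ≥ target and power(n−1) < target).

## 6. Cost-utility model

Decision tree (first 30 postoperative days): morbidity vs no-morbidity
branches; intervention morbidity = usual-care morbidity × (1 − RRR),
default RRR = 0.20 (a deliberately conservative effect assumption);
branch costs/QALYs are expectations; the intervention arm adds the
program cost; each branch maps to a Markov entry state. Tree values are
treated as cycle-0 quantities and not discounted.

Markov component: row-stochastic transition matrix (optionally
cycle-indexed), exactly one absorbing death state (identity row enforced
to 1e-9), yearly cycles, default horizon 30. Cycle t accrues rewards on
the start-of-cycle occupancy (so a two-state model with per-cycle death
probability p and utility 1 yields the geometric sum (1 − (1−p)^H)/p),
discounted at (1 + r)^−t with t starting at 0; r defaults to 3.5 %/year
for both costs and outcomes (UK reference-case convention). Half-cycle
correction (averaging start and end occupancy) is off by default and
available as a flag.

ICER = ΔC/ΔQ with `dominant` / `dominated` / `undefined` labels for the
off-quadrant and ΔQ = 0 cases. PSA draws each uncertain parameter from
its declared family — beta for probabilities/utilities, gamma for costs,
normal or moment-matched lognormal for effects — with one joint draw
applied to both arms per sample; CEAC(λ) is the fraction of samples with
λ·ΔQ − ΔC > 0 on a 0–50 000 grid in steps of 500 (20 000 always on the
grid). One-way sensitivity re-evaluates the ICER at each parameter's
bounds, others at base.

The bundled `default_econ_model.yaml` is a **synthetic illustrative
parameterization**: the published evaluation's state structure,
transition probabilities, costs and utilities live in supplementary
material that is not reproducible from summary data, so the bundled
values are order-of-magnitude placeholders for exercising the machinery.
Its ICER (~£75 000/QALY) is not an economic estimate of anything; real
analyses must supply their own YAML.

## 7. Pipeline

A single global seed feeds `numpy.random.SeedSequence`, which derives
independent substreams for cohort generation, bootstrap, and PSA; stages
are therefore individually reproducible and the whole run is
byte-identical under a fixed (config, seed). Outputs embed the seed and
a config hash. Stage failures surface as `PipelineError` labeled with
the stage name.

## 8. Problem sizes used in validation

The test suite and acceptance script use desk-scale Monte Carlo sizes
chosen to keep sampling error well inside the asserted tolerances:
500 simulated trials for estimator-recovery checks (Monte-Carlo SE of
the mean difference ≈ 0.03 kg), cohorts of 2 000–4 000 for single-cohort
calibration checks (±3-point tolerance on proportions), 10 000 draws for
fair-coin allocation checks (±2 points), 1 000 replicates for the
minimization-vs-simple-randomization comparison, and B = 200–2 000
bootstrap/PSA samples.

## 9. Limitations

- The generator reproduces first- and second-moment structure and the
  stated mixtures; it does not emulate recruitment dynamics, site
  effects, missing-data mechanisms (retention is a simple Bernoulli), or
  the joint distribution of quality-of-life instruments. Passing
  calibration tests shows the *machinery* recovers the encoded truth,
  not that the trial's real data-generating process is captured.
- The loss–morbidity relationship is generated as null by default; the
  exploratory median-split analysis applied to synthetic cohorts will
  often show spurious ratios at n = 71 (as the real exploratory analysis
  might).
- Collective power assumes independent criteria; engagement and
  adherence are measured on the same participants and are likely
  positively dependent, making the product rule conservative.
- The economic model's parameterization is illustrative; only its
  structural behavior (conservation, discounting, dominance handling,
  CEAC limits) is validated.
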