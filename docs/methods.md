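# Methods

## Design overview

The package implements a two-stage continual reassessment method for a
six-dose phase I trial (dose levels −1, 0, 1, 2a, 2b, 3) in which levels 2a
and 2b — same total dose delivered over a longer schedule vs a higher daily
dose — cannot be ranked in toxicity a priori.  Two candidate orderings are
carried: (−1, 0, 1, 2a, 2b, 3) and (−1, 0, 1, 2b, 2a, 3), each with prior
weight 0.5.  The target dose is the TD25, the dose with DLT probability
closest to θ = 0.25.

### Working model and skeleton

The dose-toxicity curve is the one-parameter power model
ψ_m(d_i, β) = α_mi^exp(β).  The skeleton α is calibrated from the
indifference interval [θ−δ, θ+δ] with δ = 0.05: seed position ν (the prior
guess of the target dose, here ν = 5 of 6) at θ, then recurse

    α_{i+1} = (θ+δ)^{ln α_i / ln(θ−δ)}   upward,
    α_{i−1} = (θ−δ)^{ln α_i / ln(θ+δ)}   downward.

For (θ, δ, ν, k) = (0.25, 0.05, 5, 6) this yields
(0.0120, 0.0365, 0.0840, 0.1567, 0.25, 0.3545), i.e. (0.01, 0.04, 0.08,
0.16, 0.25, 0.35) at two decimals.  By default the design uses the rounded
two-decimal values, since those are the values the trial was parameterised
with; `build_adept_design(rounded=False)` switches to full precision.  The
choice is visible but inconsequential at the operating-characteristic level.

### Time-to-event weights

Each patient is observed for 49 days of treatment plus 364 days (52 weeks)
of follow-up.  A patient without an observed DLT enters the likelihood with
weight

* 0.60 up to 56 days (8 weeks) of post-treatment follow-up — the minimum
  before a cohort's escalation decision, and the floor for patients still
  on treatment;
* rising linearly to 0.80 at 84 days (+5 percentage points/week);
* rising linearly to 1.00 at 364 days (+0.5 points/week);
* a patient with an observed DLT always contributes with weight 1.

The two linear segments reflect an acute-toxicity window (most radiotherapy
DLTs) and a long late-onset tail.  The follow-up clock starts at the end of
treatment; weight does not accrue during the 7-week treatment course, whose
elapsed time is instead covered by the floor.

### Inference

A normal prior g(β) with mean 0 and variance 1.34 is assumed.  The design
description leaves g(β) open; 1.34 is the long-standing default of the
empiric-CRM software lineage and is configurable via `PriorBeta`.  Checks
with variances 5 and 20 moved the simulated selection probabilities by less
than 0.03, so the default is not a sensitive choice here.

All β-integrals (per-ordering evidence, posterior mean) are evaluated on a
fixed 2001-point trapezoid grid on [−10, 10].  ψ saturates outside this
range and the integrand decays below 1e−16 of its peak at the endpoints, so
the composite trapezoid rule converges spectrally (no boundary terms in the
Euler–Maclaurin expansion); the grid agrees with a 20,001-point reference
to better than 1e−6 relative on randomised datasets (tested), and one fixed
vectorised grid keeps a 10,000-replicate simulation cheap.  Likelihood
evaluation is clipped at 1 − 1e−12 to guard the w·ψ → 1 corner.

Exact ties are resolved deterministically given the seed: the most probable
ordering by a seeded uniform draw among the tied set (mirroring the random
choice prescribed at the equal-prior start of a trial), and the recommended
dose toward the lower toxicity rank (the safer dose; the design text does
not specify this case).

### Stopping rules

*Success*: once 15 patients (five cohorts) have been treated at one dose
and the next allocation is that dose again, recruitment stops.  The count
is cumulative, not consecutive, and includes stage-1 allocations.

*Safety*: after each model-based decision the probability that the lowest
dose's DLT rate exceeds 0.35 is estimated by sampling β* from
Normal(β̂_ML, v), where β̂_ML maximises the weighted likelihood and
v = [−d² log L̃/dβ²]^{−1} is the observed-information variance at β̂_ML
(central differences, step 1e−4; prior variance with a flag when the data
carry no curvature).  If that probability exceeds 0.80 and at least 3
patients have been treated at the lowest dose, the trial stops without a
dose.  The likelihood framework (ML estimate + observed information) is
used here because that is the framework the variance construction comes
from; allocation remains fully Bayesian.  With the posterior mean in its
place the rule is materially less sensitive (prior shrinkage toward β = 0
masks over-toxicity early on) and simulated all-toxic scenarios stop far
too rarely.

*Cap*: 60 patients.

*Final analysis*: whenever recruitment ends without a safety stop, the
model is refit on the fully observed data — every patient followed to the
end of the window, late-onset DLTs included, all weights 1 — and the target
dose is that fit's recommendation, with the safety rule applied once more.
This follows the design's definition of the TD ("once all patients have
been recruited and observed") rather than freezing the recommendation made
at the moment the success rule fired; the distinction matters because at
any interim decision roughly a quarter to half of eventually occurring DLTs
are still latent under uniform onset times, so interim fits are
systematically optimistic.

Checks run in the order safety → success → cap, so an all-toxic trial
cannot end by "success" on a technicality.

## Simulator

The simulator emulates the stated trial protocol: one patient per month
(inter-arrival 365.25/12 days; "month" vs 28 or 30.44 days is not resolved
by the protocol but is immaterial at the reported precision), cohorts of
three, each decision gated on the cohort's last patient reaching 56 days of
post-treatment follow-up, and the next cohort starting at the later of the
accrual clock and the decision.  Each patient's DLT indicator is Bernoulli
with the scenario's true rate for the assigned dose; an event's onset day
is uniform on (0, 413) from treatment start, drawn at enrollment and
revealed to the model only once the patient's follow-up passes it.  Sixteen
built-in scenarios set each dose in turn as the true TD25 under both
orderings, plus equal-step and all-toxic curves.

The published-style tables use 10,000 replicates per scenario; the
package's own verification suite and the reproduction script run 3000 and
2500 replicates respectively, which puts the Monte-Carlo standard error of
an estimated probability near 0.009 — small against the ±0.05 comparison
bands — while keeping a full verification run in the minutes range.

Per-replicate randomness is split into an outcome stream and a decision
stream derived from the replicate seed, so replaying a logged trial from
its patient file reproduces every decision bit for bit, and aggregated
results are independent of execution order.  Monte-Carlo standard errors
√(p(1−p)/n) are reported alongside every probability.

### What the generator does and does not capture

Uniform DLT onsets imply a constant hazard across the whole observation
window; real late-onset radiotherapy toxicity is likely lumpier.  Accrual
is perfectly regular, decisions are instantaneous, and no patient drops
out, replaces, or is re-evaluated.  Passing simulation checks therefore
demonstrates that the decision machinery behaves as designed under the
stated generative assumptions, not that the trial will enjoy these
operating characteristics under real accrual and toxicity kinetics.

### Known limitations

* In heavily toxic scenarios the simulated mean sample size runs roughly
  one cohort (~2 patients) above the published value for this design even
  though stop probabilities and patient allocation match; the in-trial
  safety evidence accumulates slightly more slowly under the floored
  weight function than in the original (unpublished) simulation code.
  Replacing the floored weights with the classical elapsed-time fraction
  u/413 closes that gap but contradicts the stated weight function and
  degrades the benign-scenario stop rates, so it was not adopted.
* The safety stop is automatic in simulation; in the live trial the rule
  only alerts a safety committee, which may decide otherwise.
* Dose level 3 is modelled as a single dose; the choice between its two
  candidate regimens is outside the dose-finding model.
* Replicates run serially; at ~20–40 ms per simulated trial a 10,000-
  replicate scenario takes a few minutes on one CPU.
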