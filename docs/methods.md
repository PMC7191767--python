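# Methods

## Anchored survival laws

Survival times follow either a Weibull law S(t) = exp(−(t/λ)^k) or a
log-logistic law S(t) = 1/(1 + (t/α)^β). The scale parameter is never set
directly: each subgroup's curve is pinned to an anchor (t, S(t)) with
t > 0 and S(t) strictly inside (0, 1), and the scale is solved in closed
form (see README). The closed forms are implemented exactly in their
mixed base-10/natural-logarithm shape, and the test suite asserts their
algebraic identity with the direct solves λ = t(−ln S)^(−1/k) and
α = t(1/S − 1)^(−1/β) to machine precision; round-trip inversion is
checked to 1e−10 relative, the tolerance a single log/exp pair warrants
in double precision.

There is deliberately **no default shape parameter**: the shape controls
the entire character of the hazard and no single value is a safe
default, so the configuration requires it explicitly for every subgroup.
Shape k > 1 gives an increasing Weibull hazard (aging), k = 1 the
exponential special case, k < 1 a decreasing hazard; β acts analogously
for the log-logistic family. Times are unit-agnostic; months are the
documented convention throughout.

Sampling is by inverse CDF — Weibull: λ(−ln U)^(1/k); log-logistic:
α(1/U − 1)^(−1/β), U uniform on (0, 1) — which is exact, dependency-free
and reproducible. The measure-zero draw U = 0 is clamped to the smallest
positive double so no infinite time can ever be produced.

## Cohort organization

`n_total` must be even and is split into two exactly equal arms. Within
an arm, the LTS/STS split and the survivor/non-survivor split are
*deterministic*: expected leaf counts are rounded by largest-remainder
(Hamilton) apportionment, with ties to the earlier leaf. Subgroup sizes
are design quantities of the simulated study, so making them exact (at
most one unit from expectation, arms always balanced) was preferred over
multinomial noise; the realized counts are also what the biomarker
feasibility checks use.

The superiority correction adds δ/2 to arm B's anchor survival and
subtracts δ/2 from arm A's, applied to the LTS and STS anchors
separately with the same δ/2. Because the anchors are per subgroup, the
arm-level difference depends on subgroup sizes; rather than silently
rescaling, `validate_config` (and the `validate` subcommand) recomputes
the cohort-weighted difference from the deterministic leaf counts and
reports it. Corrected survivals must stay inside (0, 1) or the
configuration is rejected naming the offending arm and subgroup.

**Censoring.** The mechanism is a package design choice: survivors draw
their observation time from the *same* anchored law as their leaf and are
flagged event = 0. This keeps the observation-period histogram bimodal
regardless of status and is simple to reason about, but it means
censoring is non-informative only in the trivial sense — the censoring
time distribution equals the event-time distribution. An optional
administrative `followup_horizon` additionally truncates every time
beyond it to the horizon with event = 0. No accrual or calendar-time
process is modelled.

**Random streams.** One master seed; each stage (times, censoring,
nominal biomarker, numeric biomarker, each named attribute) consumes its
own child stream keyed by a CRC-32 of the stage name. Consequences
guaranteed by tests: adding or reordering random attributes never changes
survival times, and reordering the attribute list permutes columns
without changing any attribute's values.

## Biomarkers

"Overall equally distributed" is implemented as an exact count property:
K = round-half-up(n_arm · prevalence) subjects are marked in each arm,
never a binomial draw — a detection tool comparing arm-level counts must
see exactly nothing. In the enriched arm (configurable, default A) K is
apportioned across LTS-survivors, LTS-non-survivors and STS by
largest-remainder rounding of n_i·p_i, then carriers are chosen uniformly
within each leaf; the flat arm chooses its K carriers uniformly. The STS
probability p₃ = (prevalence − f₁p₁ − f₂p₂)/f₃ is reconstructed from the
balance requirement (it is the unique value closing the identity);
values outside [0, 1] are rejected with the feasible prevalence interval
[f₁p₁ + f₂p₂, f₁p₁ + f₂p₂ + f₃] in the error, and a rounding-level
excursion (|p₃| within 1e−9 of a bound) is clamped rather than rejected
so boundary-feasible configurations remain usable. Splitting only the
LTS leaf by survival status mirrors the cohort tree: the STS group gets
a single probability.

The numeric biomarker is two-stage: marking identical in mechanism to the
nominal biomarker but with independent probabilities and an independent
stream, then values from N(μ_biomarker, σ²_biomarker) for marked and
N(μ_non-biomarker, σ²_non-biomarker) for unmarked subjects. Equal means
and variances give a planted intensity of exactly zero; the KM-curve
separation recovered by the cutoff search grows with |μ_bm − μ_non|
(checked at three spacings on a fixed seed).

## Nominalization

The product-limit (Kaplan–Meier) estimator uses the standard tie rule:
subjects censored at t remain in the risk set for events at t. Curves
are right-continuous step functions equal to 1 before the first event
time.

The cutoff search evaluates every midpoint between consecutive distinct
sorted attribute values — midpoints make "A ≤ c" unambiguous under
floating-point noise — and maximizes the *absolute* area between the two
KM curves, integrated exactly over the union of their step grids up to
`t_max` (default: the largest observed time in the pooled sample, since
the curves are undefined beyond follow-up; configurable). Ties in the
objective resolve to the smallest cutoff. Observations are sorted by time
once; each candidate then costs one linear pass, so the whole search is
O(N²). `min_group_size` defaults to 1: the degenerate-split hazard (a
lone extreme subject can dominate the area) is deliberately exposed
rather than hidden, and the CLI flag lets users raise it.

## Configuration and I/O

The JSON configuration is validated strictly (unknown keys rejected, all
violations reported with JSON-pointer-style paths) by pydantic models,
followed by cross-field feasibility checks — corrected anchors inside
(0, 1), p₃ inside [0, 1] for the deterministic leaf sizes — before any
generation. Output is plain CSV (comma, dot decimal, UTF-8, header);
`include_truth` adds the generating ground truth (group, survivor flag,
numeric-marking flag) for scoring detection software. Plot export renders
one KM step curve per stratum of a nominal column and is purely
presentational.

## What the generator does and does not emulate

Generated cohorts have exactly balanced arms, deterministic subgroup
sizes, independent attributes, a single event type, and censoring drawn
from the event law. Real trials add what is deliberately out of scope
here: correlated covariates, informative censoring, accrual patterns,
competing or recurrent events, and covariate-driven hazards. Passing
tests therefore demonstrate that analysis software recovers *planted*
effects under clean conditions, not that it is robust to those
real-world complications.

## Problem sizes and checks

The test suite works at the smallest sizes that make each statistical
check sharp: 10⁵ draws for closed-form sampling checks (±0.01),
10,000–20,000 subjects for KM anchor recovery (±0.02) and censoring
proportions, 40,000 for arm-level superiority recovery (±0.03 on
δ = 0.2), 200 random feasible configurations for exact biomarker
balance, and 50 random instances (N ≤ 40) for exact agreement of the
cutoff search with a brute-force oracle built on an independent KM
implementation (lifelines). Bimodality is verified by refitting a
two-component Weibull mixture by EM on 10,000 event times from the
equal-mix scenario anchored at (36, 0.5) and (12, 0.2) — shapes k = 2
chosen for both subgroups as the example scenario's shapes — recovering
the 0.5 mixture weight to ±0.03.
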