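# Methods

## Model

Each agent holds, for every cultural worldview `k` in a fixed ordered set
(default `M`, `C`, `A`), an acceptance segment `b_k ≤ a_k ≤ B_k` on the
position axis `[−1, 1]`, with `a_k` its most acceptable position. The
agent's group is the worldview with the highest `a_k` (ties broken by the
fixed worldview order — documented, never silent). Population agents must
hold a positive `a_k` on at least one worldview; the terrorist agent is
exempt from this check and from all group statistics.

The attitude kernel has three levels:

1. *Position.* `ω(p) = 1` strictly inside `(b, B)`, exactly `0` at either
   bound, and `tanh(y/2)` outside with `y` the signed distance past the
   bound in units of the margin on that side. The function is
   intentionally discontinuous at the bounds (a jump from 1 to 0); see
   *Numerical behavior* below. The branch above the upper bound mirrors
   the lower one, `y = 1 + (a − p)/(B − a)`, so that a narrower margin
   gives a faster fall toward the asymptote −1.
2. *Segment.* The attitude of an observer about another segment is the
   mean of the observer's kernel over the grid positions strictly inside
   the target segment. This equals the ratio form
   `Σ ω_obs(p_d)·max(ω_tgt(p_d), 0) / Σ max(ω_tgt(p_d), 0)` because the
   clipped target kernel is exactly the indicator of its open interior.
   The normalization is over the *target's* interior: when a target
   segment shrinks, the average re-weights over the surviving positions.
   This choice is load-bearing; it produces the de-escalation effect and
   also the caveats below.
3. *Identity.* The mean of the K per-worldview segment attitudes.
   Self-attitude is 1, and attitude matrices force the diagonal to exactly
   1.

## Threat dynamics

A terrorist agent `q` has minimal-width margins (`ε` on each side) around
`a = 0.95` on the targeted worldview and around `−0.95` on the others; all
segment values are configurable. The reaction trigger is the *terrorist's
attitude about the agent*, `ω^{qi}` (not the reverse; both are computable,
only this one gates the update). A non-negative `ω^{qi}` means no
reaction. Otherwise the intensity is `μ = α·tanh(ω^{qi}/2)`, strictly
negative and bounded below by `α·tanh(−1/2)` (≈ −0.231 at the default
`α = 0.5`).

Only the targeted worldview's segment changes, and only the bound closest
to the terrorist's m.a.position (ties, which require the bound midpoint to
hit `a_q` exactly, go to the upper bound — the generic case since `a_q` is
near +1). The bound update contracts the margin width by
`w' = (1 + μ)·w − μ·ε`: widths above `ε` shrink strictly toward `ε`,
width `ε` is an exact fixed point, and a (hand-built) width below `ε`
grows back toward it. When the bound coincides with the m.a.position,
`sign(0)` is defined as +1 for the upper bound and −1 for the lower, which
keeps the growth direction consistent. The update provably preserves
`b ≤ a ≤ B`; a final clamp to `[−1, 1]` guards hand-built inputs whose
sub-`ε` margins would otherwise grow past the axis ends.

Scenario execution is synchronous: every step, all agents react to the
same broadcast identity, and each agent's update depends only on its own
current identity (so synchronous and sequential updates coincide).
`ω^{qi}` is recomputed each step from the agent's current identity. The
exposure schedule defaults to iteration until the largest bound movement
falls below `1e−6`, capped at 50 steps; both are configurable and every
report states the step count actually run. Trajectories record the
attitude matrix and group statistics at `t = 0` and after every step
(optionally endpoints only, for large property sweeps).

## Evolution classification

For each non-terrorist agent, the attitude toward the targeted group is
the agent-weight-weighted mean attitude toward the group's non-terrorist
members (self included for members — self-attitude is part of the model,
and a switch exposes the exclude-self alternative in the group statistics).
A change above `1e−9` between the first and last recorded state counts as
an increase; anything else as decrease-or-unchanged. Because the
aggregation basis is genuinely ambiguous, summaries report both a
weight-based percentage (prototype agents represent population shares) and
a per-agent count percentage.

## Survey statistics and the synthetic survey

Survey records follow the eleven-column attitude-table layout (participant
id, region, age, gender, three 5-point attitude items toward C, M, A,
religion, free-text religion, start/end timestamps); the reader
auto-detects tab/comma/semicolon delimiters and an optional header, skips
malformed rows with a logged count, and refuses files with more than 10%
malformed rows. Religion labels map to groups through an explicit
French/English lookup table; unmappable respondents are excluded and
counted. Responses map linearly onto the model scale, `r → (r − 3)/2`, so
the 5-point scale spans exactly `[−1, 1]`. Group-pair cells use the
population (ddof = 0) standard deviation, matching the weighted population
SD used on the model side.

The synthetic generator emulates this record structure with
group-conditional Gaussian attitudes on the raw 1–5 scale, rounded and
clipped to `{1..5}`. Group sizes follow the requested fractions exactly by
largest-remainder apportionment (at `n = 1000` the default fractions
0.036/0.606/0.358 give exactly 36/606/358 respondents), which removes
sampling noise from the group composition while keeping attitudes
stochastic. Default fractions are the published composition of the French
sample (3.6% Muslim, 60.6% Christian, 35.8% areligious). The default
attitude matrix was chosen once on realism grounds for the 2014 French
context — in-group means of 4.0–4.4, out-group ratings of Muslims lowest
from Christian and areligious respondents (2.6–2.9), SDs of 0.8–1.1 —
since the source survey's cell values are not reproduced here. What the
generator does *not* emulate: item non-response, acquiescence or ordering
effects, demographic correlates of attitudes, and any within-group
heterogeneity beyond a single Gaussian per cell. Tests passing on
synthetic surveys therefore validate the pipeline's statistics and
calibration machinery, not the attitudinal content of any real population.

## Population synthesis

Six prototype identities — an inclusive and an exclusive agent per group —
are sampled from quantitative templates: *exclusive* prototypes keep their
own-group segment inside `[0, 1]` with total width ≤ 0.8 and the other
worldviews' segments at non-positive m.a.positions with at least 60% of
their length below zero; *inclusive* prototypes have a positive own-group
m.a.position, all widths ≥ 0.7, at least 60% of every segment above −0.2,
and the other m.a.positions near zero. The templates quantify an otherwise
qualitative distinction and are configuration-exposed. All sampled margins
respect the floor `ε`.

A population is a 57-vector: 54 segment values plus three per-group
inclusive weight shares (clipped to `[0.01, 0.99]` so no prototype gets
zero weight); group fractions come from the calibration target, so an
agent's weight is `fraction × share`. The repair operator — clip, sort
each `(b, a, B)` triple, clamp m.a.positions so `ε`-margins fit, restore
strict own-group argmax by minimal shift with a `1e−6` tie-break offset,
widen margins to `ε` — is idempotent and applied at every optimizer
evaluation, so every evaluated vector decodes to a valid population.

The calibration error sums the absolute differences of the 9 group-pair
means and 9 SDs (18 terms). Relative errors divide each term by
`max(|target|, 0.05)`; the floor prevents blow-up for near-zero target
statistics and 0.05 is small on the `[−1, 1]` scale. Optimization is
standard global-best PSO (`v ← w·v + c1·r1·(pbest − x) + c2·r2·(gbest −
x)`), inertia 0.72 and `c1 = c2 = 1.49` (common constriction-equivalent
values), swarm 40, 500 iterations by default, velocities clamped at 0.25
per coordinate, particles initialized by template sampling. An optional
prescreen evaluates a larger template-sampled set first and keeps the best
as the initial swarm — a reproducible stand-in for manual seed screening.
The result is the requested number of distinct personal-best populations
ranked by absolute error; the global-best error trace is returned and, by
construction, non-increasing. Everything is deterministic given the seed.

## Determinism

A single master seed drives the pipeline through named substreams (CRC-32
of the stage name as a spawn key, children reduced below 2^31), so the
survey, calibration, and fixture stages can be re-run independently with
identical results. Reports with the same configuration and seed are
byte-identical.

## Numerical behavior and known limitations

- *Bound discontinuity.* The position kernel jumps from 1 (inside) to 0
  (at the bound). Grid averages therefore converge at rate
  `O(spacing / target width)` where an observer bound cuts a target
  interior, not uniformly: between `D = 400` and `D = 4000` the typical
  segment-attitude difference over random pairs with margins ≥ ε is about
  0.002, but roughly 1% of pairs differ by more than 0.01 (worst observed
  ≈ 0.03 at narrow target widths). Per-pair agreement within 0.01 should
  only be expected for wide targets; exact bound hits are measure-zero
  under the default grid and handled deterministically (value 0).
- *Degenerate margins.* A zero-width margin yields the limit value −1
  beyond it. Synthesis never generates margins below `ε`; the case exists
  for hand-built inputs.
- *Re-normalization can raise attitudes.* Because segment attitudes
  average over the target's current interior, an M agent whose upper bound
  contracts from beyond an observer's segment back inside it *gains*
  standing with that observer — the negatively valued top positions leave
  the average. Consequently the intuitive monotonicity claim "an observer
  with the higher m.a.position never comes to value the lower agent more
  after a threat" does not hold uniformly: it fails in roughly 5–10% of
  random two-agent configurations (e.g. observer M segment
  `(−0.5, 0.5, 0.6)` vs target `(−0.2, 0.0, 0.9)`, whose attitude rises
  from 0.57 to 1.0 under the default scenario). The same mechanism,
  deliberately combined — minimal observer upper margin, persistent
  overlap, strongly contracting M agent — produces the de-escalation
  effect, whose direction and monotonicity in the M agent's initial upper
  margin (and in the m.a.position gap) the test suite verifies.
- *Unresolvable segments.* A target segment containing no grid point
  raises a dedicated error naming the resolution, rather than returning a
  silent value; callers may raise `D`.

## Problem sizes used by the test suite

Property sweeps use 200–1000 randomized instances; scenario propositions
run 10 synchronous steps per instance; parameter recovery and
survey-calibration checks run PSO with swarm 30 for 300 iterations against
a six-agent target at `D = 400`, and the pooled evolution split is
computed over the 20 best calibrated populations under the default
scenario. These sizes were chosen so the entire suite completes in well
under a minute of optimizer time while leaving the conclusions unchanged
at larger settings.
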