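# Methods

## The scheduler

The scheduler is a deterministic state machine over eight variables: the
1-based index of the next trial; the Bias+ reward-cycle counter; the
unrewarded-click streak; the count of consecutive Bias+ choices; the two
per-side reward budgets (25 each); and two flags, `reset_mode` and
`awaiting_recommit`. Each trial proceeds allocate → choose → reveal →
agent update → state advance, so the trial's allocation is committed
before the choice and is a pure function of the history.

A **Bias+ reward** is allocated when the cycle counter has reached the
effective interval *X* (the stage table's value, or 1 in `reset_mode`),
the pattern is not suspended, and budget remains — or when the forcing
rule fires. A **Bias− reward** is allocated when it can ride along with a
Bias+ reward while the agent is highly committed (co-allocation), or by
forcing. The **forcing rule** fires per side, independently, when the
remaining trials equal the remaining budget of that side; by induction the
remaining budget never exceeds the remaining trials, which makes the
25-per-side budget an invariant of every complete session rather than a
hope.

Budgets are spent on allocation, not on collection: a reward placed on the
unchosen side is gone. This is the accounting that lets the scheduler
"hide" Bias− rewards behind Bias+ commitment.

### Choices that the published description leaves open

The prose description of the algorithm leaves several constants and edge
cases to its reference implementation. This package fixes them as its own
canonical definition, all configurable where noted:

* **Recommitment threshold R = 2** consecutive Bias+ choices after a
  defection before the pattern resumes (keyword `recommit_threshold`).
  This is the smallest number of choices that demonstrates recommitment
  rather than a single exploratory click. The cycle counter restarts at 0
  on recommitment.
* **Commitment threshold C = 5** consecutive Bias+ choices before a Bias−
  reward may be co-allocated (keyword `commitment_threshold`). Five
  consecutive choices of one side is well past the point where the agent
  is plausibly "locked in" (a fair coin produces it 3% of the time).
* **Reset semantics**: ten consecutive unrewarded clicks (on either side)
  set `reset_mode`, which forces the effective interval to X = 1 until the
  next obtained reward; the stage-appropriate X then resumes with a fresh
  cycle. The streak counter zeroes when the reset fires, so a persistently
  unlucky agent is re-simplified every ten clicks rather than once.
* **Cycle carry-over**: the cycle counter is not reset at stage
  boundaries; the X in force at the moment of a click is the one that
  matters. When X shrinks across a boundary (stages 3→4 and 4→5) a carried
  cycle can arm a reward immediately, which shows up as a shorter
  inter-reward gap at those boundaries.
* **Same-trial double allocation** is permitted (and necessary): it is how
  co-allocation works and how both forcing rules can fire at once in the
  endgame.

The scheduler itself uses no randomness; all stochasticity lives in the
agents.

## Agents

Agents see only their own choices and the reward on the chosen side, as in
the task. Each agent owns one `numpy` Generator seeded from its spec;
batches derive per-session seeds with `SeedSequence(base, spawn_key=(spec,
replicate))`, so experiments are reproducible and extensible without
reusing streams.

* `always_plus` / `always_minus` — deterministic probes for the budget,
  forcing and oracle tests.
* `bernoulli(p_plus)` — memoryless choice. Because its choice on a trial is
  independent of that trial's pre-committed allocation, its expected total
  is exactly `p·25 + (1−p)·25 = 25` regardless of `p` — the anchor for the
  chance-level checks.
* `wsls(stay_after_reward, shift_after_no_reward)` — probabilistic
  win-stay/lose-shift; first trial is a fair coin.
* `qlearn(alpha, epsilon, q0_plus, q0_minus)` — delta rule
  `V ← V + α(r − V)` on the chosen side, epsilon-greedy choice, fair-coin
  tie-break. With α = 1 and ε = 0 it degenerates to deterministic
  win-stay/lose-shift except at value ties, which the tests exploit as a
  cross-check between the two implementations. Defaults α = 0.1, ε = 0.1,
  initial values 0.5 — conventional mid-scale settings for a Bernoulli
  reward in [0, 1].
* `regularity_seeker(commitment_gain, exploration_floor)` — a
  demonstration heuristic, not a fitted cognitive model. It tracks the
  interval in Bias+ clicks between consecutive Bias+ rewards. A reward
  arriving within ±1 click of the last interval confirms the pattern
  hypothesis and raises the probability of choosing Bias+ by
  `commitment_gain`; a wait exceeding the expected interval by more than
  one click counts as a single violation, lowering it by the same amount
  and dropping the hypothesis until the next reward re-anchors it (without
  penalty — the overdue wait, not the reward, is the punishment; an early
  version penalised the late reward as well and every defection then cost
  two decrements, which drove even committed agents to the floor).
  Commitment starts at 0.6 (a mild initial pull toward the target, needed
  for the pattern to be discovered at all) and is clipped to
  `[exploration_floor, 1 − exploration_floor]`.

The shipped fixture archetypes — strong (gain 0.3, floor 0.02), medium
(gain 0.12, floor 0.15) and weak (gain 0.04, floor 0.35) — produce mean
biases of roughly 0.89, 0.74 and 0.63 over 100 seeds, bracketing the
strongly/moderately/weakly biased participant archetypes.

## Metrics and statistics

Per-session measures: bias fraction (Bias+ choices over all 100 trials),
the normalized obtained-reward difference `(R⁺ − R⁻)/(R⁺ + R⁻)`, observed
expectancy (rewards won per choice of an option) and exploitation (rewards
won per 25 allocated). Ratios with zero denominators are reported as
`None`, never coerced to 0: simulations do reach them (a side never
chosen; a session with no obtained reward), even though human data rarely
would.

Rolling means use a trailing window (default 10) with the warm-up trimmed,
so position *i* averages trials *i*..*i+9*; alignment is a convention and
this one keeps every reported value a mean of fully observed trials.

The *t*-test layer is classical Student machinery via `scipy.stats`:
two-sample tests use pooled variance (matching df = n₁ + n₂ − 2), CIs are
95% two-sided on the mean difference, one-sample Cohen's *d* uses the n−1
sample SD and two-sample *d* the pooled SD. Spearman correlation comes
from `scipy.stats.spearmanr`. Degenerate inputs (zero variance, zero
pooled variance) raise rather than returning infinities. The test suite
cross-checks this layer against `pingouin` as an independent
implementation.

## What the simulations do and do not show

The synthetic agents exercise every structural property of the scheduler:
budget conservation under arbitrary policies, the stage table, the reset
and recommitment rules, forcing correctness, and the metric identities
`obtained⁺ = expectancy⁺ × choices⁺ = exploitation⁺ × 25`. They also
reproduce the mechanism of biased reward discovery: a committed seeker
discovers most Bias+ rewards and almost none of the Bias− budget, so its
experienced reward history is lopsided even though the objective
allocation is 50/50.

They do **not** reproduce population-level findings about human
participants (mean bias near 0.70, the large effect size of the bias, or
the negative rank correlation between absolute bias and earnings). Those
are properties of human decision-making, measurable only on the
participant dataset via the export adapter. Notably, for the simple
simulated agents here, total earnings cluster tightly around 25 at every
bias level — the endgame forcing compensates almost any policy — so the
human "cost of bias" pattern does not emerge from these policies; the
package computes the statistic but the simulation makes no claim about its
sign in people.

## Problem sizes and numerics

The conservation sweep uses 10,000 sessions spread over eight agent
configurations; the chance-level check uses 10,000 fair-coin sessions and
accepts a deviation of up to three Monte-Carlo standard errors of the
simulated mean (≈ 0.1 rewards). Property-based tests run 50–200 examples
each, derandomized for reproducibility. All counts are exact integer
bookkeeping; the only floating-point tolerances in the suite are those of
the statistics layer (absolute 1e-9 against the reference implementation,
plus the reference's own 2-decimal rounding of CIs).

## Known limitations

* The scheduler follows the published stage table and allocation
  principles with the thresholds above; it is a canonical reconstruction,
  not a bit-for-bit copy of the authors' submitted code, and the two
  submitted variants are represented by a single scheduler with
  configurable R and C.
* The regularity seeker is a deliberately simple commitment heuristic;
  it is not calibrated to human data and its parameters are chosen to
  span bias levels, not to fit anything.
* The export adapter validates structure but cannot guess an export's
  column coding; the mapping must be supplied by the user.
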