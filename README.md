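# racas

A simulator and analysis toolkit for **RaCaS** ("Regularity as Carrot and
Stick"), a dynamic reward-allocation algorithm that biases choices in a
100-trial two-alternative task by exploiting people's attraction to
regularity rather than by paying them more.

## The task and the algorithm

In the choice-engineering setting, a decision-maker makes 100 choices
between two options, trying to collect as many rewards as possible. The
experimenter must allocate exactly 25 rewards to each option (50 total) but
is free to choose *when* — and, in the dynamic track, may react to the
ongoing choices. The goal is to covertly attract choices toward a target
option, **Bias+**, and away from the other, **Bias−**.

RaCaS allocates the Bias+ rewards in a trackable pattern: after *X*
non-rewarded clicks on Bias+, the next Bias+ click is rewarded, with *X*
stepping through six stages over the session,

| stage | trials  | X |
|------:|---------|---|
| 0     | 1–11    | 1 |
| 1     | 12–25   | 2 |
| 2     | 26–40   | 3 |
| 3     | 41–60   | 4 |
| 4     | 61–80   | 3 |
| 5     | 81–100  | 2 |

so a committed agent sees rewards at predictable, slowly growing intervals
(the *carrot*). Choosing Bias− suspends the pattern until the agent
recommits to Bias+ (the *stick*). Ten consecutive unrewarded clicks switch
on a simplified schedule (effective X = 1) until the next reward
re-engages the agent. Bias− rewards are hidden: they are co-allocated with
Bias+ rewards only while the agent is highly committed to Bias+ (so they
are rarely discovered), and whatever remains is forced into the final
trials, where a per-side forcing rule guarantees the 25/25 budget in every
session. The scheduler is a pure, deterministic state machine: each trial's
allocation is fixed **before** the choice and is a function of the history
only.

The package provides:

* `racas.schedule` — the scheduler state machine (`allocate_trial`,
  `advance_state`, `stage_for_trial`);
* `racas.agents` — simulated decision-makers: `always_plus`,
  `always_minus`, `bernoulli(p_plus)`, win-stay/lose-shift, an
  epsilon-greedy delta-rule Q-learner, and a `regularity_seeker` heuristic
  that tracks the inter-reward interval;
* `racas.session` — one-agent-vs-scheduler sessions and reproducible
  batched experiments;
* `racas.metrics` — per-session bias fraction, normalized reward difference
  Δrewards(norm.) = (R⁺ − R⁻)/(R⁺ + R⁻), observed expectancy
  (#rewards won / #choices), exploitation (#rewards won / #rewards
  allocated), window-10 rolling means, Cohen's *d*, one/two-sample Student
  *t*-tests and Spearman rank correlation;
* `racas.io` + a `racas` CLI — a canonical session CSV, a mapping-driven
  adapter for external dataset exports, fixture scenarios, and
  `simulate` / `analyze` / `fixtures` / `check` commands.

## Worked example

A strongly pattern-seeking agent against the scheduler:

```python
from racas import AgentSpec, run_session, summarize_session

spec = AgentSpec("regularity_seeker",
                 {"commitment_gain": 0.3, "exploration_floor": 0.02}, seed=6)
summary = summarize_session(run_session(spec))
```

prints (via `summary.as_dict()`):

```
bias_plus            0.91
delta_rewards_norm   0.68
expectancy_plus      0.231
expectancy_minus     0.444
exploitation_plus    0.84
exploitation_minus   0.16
obtained_plus        21
obtained_minus       4
total_obtained       25
```

The agent made 91% of its choices on Bias+ and discovered 84% of the
Bias+ rewards but only 16% of the Bias− rewards — the hidden Bias− budget
did its job — yet earned exactly the chance-level 25 rewards in total.
Note `expectancy_minus` (0.444) exceeds `expectancy_plus` (0.231): the few
Bias− choices landed disproportionately on the forced endgame rewards, and
the pull of the pattern kept the agent on Bias+ anyway.

A fully committed agent is rewarded on trials

```python
>>> from racas import always_plus_reward_trials
>>> always_plus_reward_trials()
[2, 4, 6, 8, 10, 13, 16, 19, 22, 25, 29, 33, 37, 42, 47, 52, 57, 61, 65, 69, 73, 77, 81, 84, 87]
```

— every 2nd click in stage 0, every 3rd in stage 1, and so on, until the
25-reward budget runs out at trial 87.

The same analysis from the shell:

```sh
racas simulate --agent regularity_seeker \
      --params commitment_gain=0.3,exploration_floor=0.02 \
      --n 50 --seed 0 --out sessions.csv
racas analyze sessions.csv --out summary.json --group-by agent
racas check sessions.csv
```

The 50-session group summary reports a mean bias of 0.89 toward Bias+
(Cohen's *d* = 4.87 against indifference) with a mean of 24.1 rewards
obtained — a large choice bias at no gain in earnings.

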