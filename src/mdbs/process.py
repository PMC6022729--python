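"""From accumulation rates to choices.

Evidence accumulation is a random walk over per-alternative evidence counts:
on each comparison step alternative *j* gains one unit with probability
rate(j), and with probability 1 - sum(rates) the step yields no evidence.
The walk stops when the leading count exceeds the mean count by the
threshold theta (relative stopping rule).

For theta <= 1 - 1/n the very first evidence unit decides, and the choice
probabilities are exactly the normalized rates.  For larger theta the walk is
solved as an absorbing chain over evidence-count states: null steps are
self-loops that stretch time without moving the walk, so they are conditioned
out of the absorption computation and folded back into the expected number of
comparison steps.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import accumulation_rates
from .types import (
    DecisionProblem,
    ModelParams,
    NoDecisionError,
    RateVector,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ChoiceDistribution",
    "SimulationResult",
    "is_stopped",
    "choice_probabilities",
    "expected_comparisons",
    "predict_choice",
    "simulate",
    "fixed_horizon_choice",
    "comparison_frequency_prediction",
]

_TIE_EPS = 1e-12

STOPPING_RULES = ("max_minus_mean", "max_minus_next")


def _stop_margin(c: np.ndarray, rule: str) -> float:
    if rule == "max_minus_mean":
        return float(c.max() - c.mean())
    if rule == "max_minus_next":
        if c.size == 1:
            return float(c[0])
        top = np.partition(c, -2)
        return float(top[-1] - top[-2])
    raise ValueError(f"unknown stopping rule {rule!r}; one of {STOPPING_RULES}")


@dataclass
class ChoiceDistribution:
    """Choice probabilities plus the expected number of comparison steps."""

    probabilities: dict[str, float]
    expected_comparisons: float
    method: str  # closed_form | simulation | fixed_horizon

    def __getitem__(self, alt_id: str) -> float:
        return self.probabilities[alt_id]

    @property
    def ids(self) -> list[str]:
        return list(self.probabilities)


@dataclass
class SimulationResult:
    n_trials: int
    wins: dict[str, int]
    comparisons: np.ndarray  # per-trial comparison-step counts
    seed: int

    def choice_distribution(self) -> ChoiceDistribution:
        return ChoiceDistribution(
            {k: v / self.n_trials for k, v in self.wins.items()},
            float(self.comparisons.mean()),
            "simulation",
        )


def is_stopped(counts, theta: float, rule: str = "max_minus_mean") -> bool:
    """Relative stopping rule: the leader's margin reaches theta.

    The default margin is max(counts) - mean(counts); ``max_minus_next``
    swaps in the lead over the runner-up (a config hook, kept untested
    against the documented phenomena).
    """
    c = np.asarray(counts, dtype=float)
    return bool(_stop_margin(c, rule) >= theta - _TIE_EPS)


def _as_rates(rates) -> RateVector:
    if isinstance(rates, RateVector):
        return rates
    return RateVector(dict(rates))


def choice_probabilities(
    rates: RateVector | dict[str, float],
    theta: float = 0.1,
    t_max: int = 200,
    rule: str = "max_minus_mean",
) -> ChoiceDistribution:
    """Absorption probabilities of the evidence random walk.

    When theta <= 1 - 1/n this reduces exactly to rate(A) / sum(rates).  The
    general solver propagates probability mass through evidence-count states
    (total evidence capped at ``t_max``); residual transient mass below 1e-12
    is renormalized away, larger residuals raise ``NoDecisionError``.
    """
    rv = _as_rates(rates)
    ids = rv.ids
    n = len(ids)
    r = np.array([rv[i] for i in ids], dtype=float)
    total = r.sum()
    if total <= 0:
        raise NoDecisionError(
            "all accumulation rates are zero; no decision can be reached"
        )
    if n == 1:
        # degenerate: a lone alternative wins with its first evidence unit
        # (the relative rule never separates a single accumulator from its
        # own mean, so the walk is read as an immediate win)
        return ChoiceDistribution({ids[0]: 1.0}, 1.0 / total, "closed_form")
    first_unit_decides = (
        theta <= 1 - 1 / n + _TIE_EPS
        if rule == "max_minus_mean"
        else theta <= 1 + _TIE_EPS
    )
    if first_unit_decides:
        p = r / total
        return ChoiceDistribution(
            {k: float(v) for k, v in zip(ids, p)}, 1.0 / total, "closed_form"
        )

    # embedded chain: condition out null steps
    step = r / total
    absorbed = np.zeros(n)
    frontier: dict[tuple[int, ...], float] = {(0,) * n: 1.0}
    embedded_steps = 0.0
    residual = 0.0
    while frontier:
        # process states in increasing total-evidence order (the walk is a
        # DAG in total evidence): pop the whole minimum level at once
        level = min(sum(s) for s in frontier)
        current = {s: m for s, m in frontier.items() if sum(s) == level}
        for s in current:
            del frontier[s]
        if level >= t_max:
            residual += sum(current.values())
            continue
        for state, mass in current.items():
            if mass == 0.0:
                continue
            embedded_steps += mass
            for j in range(n):
                if step[j] == 0.0:
                    continue
                child = list(state)
                child[j] += 1
                m = mass * step[j]
                c = np.array(child, dtype=float)
                if _stop_margin(c, rule) >= theta - _TIE_EPS:
                    # the incremented accumulator is the unique maximum
                    absorbed[j] += m
                else:
                    key = tuple(child)
                    frontier[key] = frontier.get(key, 0.0) + m
    if residual > 1e-3:
        raise NoDecisionError(
            f"transient mass {residual:.3g} remains at total evidence "
            f"{t_max}; increase t_max or lower theta"
        )
    if residual > 1e-12:
        warnings.warn(
            f"renormalizing residual transient mass {residual:.3g} at "
            f"t_max={t_max}",
            RuntimeWarning,
            stacklevel=2,
        )
    absorbed = absorbed / absorbed.sum()
    return ChoiceDistribution(
        {k: float(v) for k, v in zip(ids, absorbed)},
        embedded_steps / total,
        "closed_form",
    )


def expected_comparisons(
    rates: RateVector | dict[str, float], theta: float = 0.1, t_max: int = 200
) -> float:
    """Expected comparison steps until stopping, counting null steps.

    Equals 1 / sum(rates) whenever theta <= 1 - 1/n (a single geometric wait
    for the first evidence unit)."""
    return choice_probabilities(rates, theta, t_max).expected_comparisons


def predict_choice(
    problem: DecisionProblem,
    params: ModelParams | None = None,
    collapse: bool = False,
    t_max: int = 200,
    partner_alpha: float | None = None,
) -> ChoiceDistribution:
    """Closed-form choice distribution for a decision problem."""
    params = params or ModelParams()
    return choice_probabilities(
        accumulation_rates(problem, params, collapse, partner_alpha),
        params.theta,
        t_max,
    )


def simulate(
    problem: DecisionProblem,
    params: ModelParams | None = None,
    n_trials: int = 10_000,
    seed: int = 0,
    max_steps: int = 100_000,
    collapse: bool = False,
) -> SimulationResult:
    """Monte Carlo accumulation trials.

    Each comparison step draws an evaluation target (similarity-weighted), a
    comparison partner, and a win outcome; marginally, alternative *j* gains
    one unit with probability rate(j) and the step is null otherwise, which
    is how the draw is implemented.  Stops per the relative stopping rule.
    Fully reproducible from ``seed``.
    """
    params = params or ModelParams()
    rv = accumulation_rates(problem, params, collapse)
    ids = rv.ids
    n = len(ids)
    r = np.array([rv[i] for i in ids])
    total = r.sum()
    if total <= 0:
        raise NoDecisionError(
            "all accumulation rates are zero (e.g. identical alternatives); "
            "simulation would never terminate"
        )
    rng = np.random.default_rng(seed)
    step = r / total  # embedded (non-null) step distribution
    counts = np.zeros((n_trials, n), dtype=np.int64)
    comparisons = np.zeros(n_trials, dtype=np.int64)
    winner = np.full(n_trials, -1, dtype=np.int64)
    active = np.arange(n_trials)
    theta = params.theta
    # walk the embedded chain; each evidence unit costs Geometric(total) steps
    for _ in range(max_steps):
        if active.size == 0:
            break
        gained = rng.choice(n, size=active.size, p=step)
        comparisons[active] += rng.geometric(total, size=active.size)
        counts[active, gained] += 1
        c = counts[active]
        stopped = c.max(axis=1) - c.mean(axis=1) >= theta - _TIE_EPS
        winner[active[stopped]] = gained[stopped]
        active = active[~stopped]
    if active.size:
        raise NoDecisionError(
            f"{active.size} of {n_trials} trials undecided after "
            f"{max_steps} evidence units (rates {dict(zip(ids, r))}, "
            f"theta={theta})"
        )
    if int(comparisons.max()) > max_steps:
        raise NoDecisionError(
            f"a trial needed {int(comparisons.max())} comparison steps, "
            f"above the max_steps={max_steps} guard"
        )
    wins = {ids[j]: int((winner == j).sum()) for j in range(n)}
    return SimulationResult(n_trials, wins, comparisons, seed)


def fixed_horizon_choice(
    problem: DecisionProblem,
    params: ModelParams | None = None,
    n_comparisons: int = 10,
    dp_cap: int = 25,
    seed: int = 0,
    n_trials: int = 100_000,
    collapse: bool = False,
) -> ChoiceDistribution:
    """Choice distribution after a fixed number of comparison steps.

    Models time pressure: the walk runs for ``n_comparisons`` steps (null
    steps included), stopping early if the relative criterion is met; any
    trial still undecided at the horizon picks uniformly among the evidence
    maxima.  Exact dynamic programming up to ``dp_cap`` steps; beyond that a
    seeded simulation is used (logged).
    """
    params = params or ModelParams()
    rv = accumulation_rates(problem, params, collapse)
    ids = rv.ids
    n = len(ids)
    r = np.array([rv[i] for i in ids])
    total = r.sum()
    null = 1.0 - total
    theta = params.theta

    if n_comparisons > dp_cap:
        logger.info(
            "horizon %d above exact-DP cap %d; falling back to simulation",
            n_comparisons,
            dp_cap,
        )
        return _fixed_horizon_simulated(
            ids, r, theta, n_comparisons, seed, n_trials
        )

    absorbed = np.zeros(n)
    states: dict[tuple[int, ...], float] = {(0,) * n: 1.0}
    steps_used = 0.0
    for step_idx in range(n_comparisons):
        nxt: dict[tuple[int, ...], float] = {}
        for state, mass in states.items():
            steps_used += mass
            if null > 0:
                nxt[state] = nxt.get(state, 0.0) + mass * null
            for j in range(n):
                if r[j] == 0.0:
                    continue
                child = list(state)
                child[j] += 1
                m = mass * r[j]
                c = np.array(child, dtype=float)
                if c.max() - c.mean() >= theta - _TIE_EPS:
                    absorbed[j] += m
                else:
                    key = tuple(child)
                    nxt[key] = nxt.get(key, 0.0) + m
        states = nxt
        if not states:
            break
    # undecided at the horizon: uniform among evidence maxima
    for state, mass in states.items():
        c = np.array(state)
        top = np.flatnonzero(c == c.max())
        for j in top:
            absorbed[j] += mass / top.size
    p = absorbed / absorbed.sum()
    return ChoiceDistribution(
        {k: float(v) for k, v in zip(ids, p)}, steps_used, "fixed_horizon"
    )


def _fixed_horizon_simulated(ids, r, theta, horizon, seed, n_trials):
    n = len(ids)
    rng = np.random.default_rng(seed)
    probs = np.append(r, 1.0 - r.sum())
    counts = np.zeros((n_trials, n), dtype=np.int64)
    decided = np.full(n_trials, -1, dtype=np.int64)
    active = np.arange(n_trials)
    used = 0.0
    for _ in range(horizon):
        if active.size == 0:
            break
        used += active.size
        draw = rng.choice(n + 1, size=active.size, p=probs)
        gained = draw < n
        rows = active[gained]
        counts[rows, draw[gained]] += 1
        c = counts[rows]
        stopped = c.max(axis=1) - c.mean(axis=1) >= theta - _TIE_EPS
        decided[rows[stopped]] = draw[gained][stopped]
        keep = np.ones(active.size, dtype=bool)
        keep[np.isin(active, rows[stopped])] = False
        active = active[keep]
    undecided = decided < 0
    if undecided.any():
        c = counts[undecided]
        maxed = c == c.max(axis=1, keepdims=True)
        pick = [
            rng.choice(np.flatnonzero(row)) for row in maxed
        ]  # uniform among maxima
        decided[undecided] = pick
    p = np.bincount(decided, minlength=n) / n_trials
    return ChoiceDistribution(
        {k: float(v) for k, v in zip(ids, p)}, used / n_trials, "fixed_horizon"
    )


def comparison_frequency_prediction(
    problem: DecisionProblem,
    params: ModelParams | None = None,
    theta: float | None = None,
) -> dict[frozenset, float]:
    """Expected number of evaluations per unordered alternative pair.

    Multiplies the expected comparison count by the probability that a step
    evaluates a member of the pair against the other member, averaging over
    the direction of comparison.  Partners drawn from the context pool are
    reported under the pair (alternative, "context").  Pair counts sum to the
    expected number of comparisons.
    """
    from .core import cell_table, partner_distribution  # local import: cycle

    params = params or ModelParams()
    theta = params.theta if theta is None else theta
    rv = accumulation_rates(problem, params)
    expected = choice_probabilities(rv, theta).expected_comparisons

    table = cell_table(problem, params)
    # rebuild partner pools with owners
    from .core import _build_space, _comparators, _similarity_weights

    cells, _attention, comparison = _build_space(problem, collapse=False)
    by_key = {(c.alt_id, c.dim): c for c in cells}
    pair_prob: dict[frozenset, float] = {}
    for rec in table:
        cell = by_key[(rec["alternative"], rec["dimension"])]
        comps = _comparators(comparison[cell.dim], cell)
        if not comps:
            continue
        w = _similarity_weights(cell, comps, params.alpha)
        p = w / w.sum()
        for e, pi in zip(comps, p):
            other = e.owner if e.owner is not None else "context"
            key = frozenset((cell.alt_id, other))
            pair_prob[key] = pair_prob.get(key, 0.0) + rec["p_evaluate"] * float(pi)
    return {k: v * expected for k, v in pair_prob.items()}
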