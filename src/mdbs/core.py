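"""Evidence-unit mechanics: distances, soft ordinal comparisons, and
similarity-weighted attention.

The model evaluates one (alternative, dimension) cell at a time.  Attention
is drawn toward cells whose values are similar to the rest of the
working-memory pool; the attended value is then compared against one pool
member (again selected by similarity), and the alternative gains one evidence
unit when its value wins the soft ordinal comparison.  All distances are
fractional (Weber-like), so every quantity here is invariant to rescaling the
units of a dimension.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .types import (
    Alternative,
    DecisionProblem,
    DegenerateProblemError,
    DimensionSpec,
    EvaluationDistribution,
    HIGHER_BETTER,
    InvalidValueError,
    ModelParams,
    RateVector,
)

__all__ = [
    "advantage_distance",
    "win_probability",
    "evaluation_distribution",
    "partner_distribution",
    "accumulation_rates",
    "relative_rank",
    "subjective_value",
    "enumerate_comparisons",
    "cell_table",
]


def advantage_distance(target_value: float, comparator_value: float) -> float:
    """Fractional distance |target - comparator| / comparator.

    Asymmetric in its arguments: the comparator sets the Weber denominator.
    """
    if not comparator_value > 0:
        raise InvalidValueError(
            f"comparator value must be > 0, got {comparator_value!r}"
        )
    if not target_value > 0:
        raise InvalidValueError(f"target value must be > 0, got {target_value!r}")
    return abs(target_value - comparator_value) / comparator_value


def _prefers(target: float, comparator: float, polarity: str) -> bool:
    """True iff the target magnitude is strictly preferable under polarity.
    Exact ties are never preferable."""
    if polarity == HIGHER_BETTER:
        return target > comparator
    return target < comparator


def win_probability(
    target_value: float,
    comparator_value: float,
    polarity: str = HIGHER_BETTER,
    params: ModelParams | None = None,
) -> float:
    """Probability that the target wins a soft ordinal comparison.

    Zero whenever the target is not strictly preferable under the dimension's
    polarity; otherwise a logistic in the fractional advantage, centred at
    beta0 with slope beta1.  At a 10% advantage (defaults) the comparison is
    won with probability exactly one half.
    """
    params = params or ModelParams()
    d = advantage_distance(target_value, comparator_value)
    if not _prefers(target_value, comparator_value, polarity):
        return 0.0
    x = params.beta1 * (d - params.beta0)
    # logistic, numerically safe for large |x|
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    z = math.exp(x)
    return z / (1.0 + z)


# ---------------------------------------------------------------------------
# cell machinery


@dataclass(frozen=True)
class _Cell:
    alt_id: str
    dim: str
    value: float
    polarity: str
    attention_key: str  # pool driving attention similarity (group when collapsed)


@dataclass(frozen=True)
class _PoolEntry:
    value: float
    owner: str | None  # None for context values
    dim: str


def _build_space(
    problem: DecisionProblem, collapse: bool
) -> tuple[list[_Cell], dict[str, list[_PoolEntry]], dict[str, list[_PoolEntry]]]:
    """Cells plus two pool maps: attention pools (keyed by attention_key) and
    per-dimension comparison pools.

    When ``collapse`` is true, dimensions sharing a ``commensurable_group``
    contribute to one joint attention pool, so attention similarity runs
    across those dimensions; ordinal comparisons remain within-dimension.
    """
    if collapse:
        groups = {d.name: d.commensurable_group for d in problem.dimensions}
        if not any(groups.values()):
            raise InvalidValueError(
                "collapsing requested but no dimension declares a "
                "commensurable_group"
            )
        for g in {v for v in groups.values() if v is not None}:
            pols = {
                d.polarity
                for d in problem.dimensions
                if d.commensurable_group == g
            }
            if len(pols) > 1:
                raise InvalidValueError(
                    f"commensurable group {g!r} mixes polarities {sorted(pols)}"
                )

    def att_key(d: DimensionSpec) -> str:
        if collapse and d.commensurable_group is not None:
            return "group:" + d.commensurable_group
        return "dim:" + d.name

    attention: dict[str, list[_PoolEntry]] = {}
    comparison: dict[str, list[_PoolEntry]] = {}
    for d in problem.dimensions:
        comparison.setdefault(d.name, [])
        attention.setdefault(att_key(d), [])
        for a in problem.alternatives:
            v = a.value(d.name)
            if v is not None:
                e = _PoolEntry(v, a.id, d.name)
                comparison[d.name].append(e)
                attention[att_key(d)].append(e)
        for v in problem.context.get(d.name, ()):
            e = _PoolEntry(v, None, d.name)
            comparison[d.name].append(e)
            attention[att_key(d)].append(e)

    cells = [
        _Cell(a.id, d.name, a.values[d.name], d.polarity, att_key(d))
        for a in problem.alternatives
        for d in problem.dimensions
        if d.name in a.values
    ]
    return cells, attention, comparison


def _comparators(pool: Sequence[_PoolEntry], cell: _Cell) -> list[_PoolEntry]:
    """Pool without the cell's own value instance.

    The entry owned by the cell's alternative on the cell's dimension is
    removed; failing that (context-supplied targets never arise), one entry
    equal in value is removed.  Other entries that merely tie the target in
    value remain: they attract attention maximally but can never be beaten.
    """
    out = list(pool)
    for i, e in enumerate(out):
        if e.owner == cell.alt_id and e.dim == cell.dim:
            del out[i]
            return out
    for i, e in enumerate(out):
        if e.value == cell.value:
            del out[i]
            return out
    return out


def _similarity_weights(
    cell: _Cell, comps: Sequence[_PoolEntry], alpha: float
) -> np.ndarray:
    if not comps:
        return np.zeros(0)
    d = np.array([advantage_distance(cell.value, e.value) for e in comps])
    return np.exp(-alpha * d)


def cell_table(
    problem: DecisionProblem,
    params: ModelParams | None = None,
    collapse: bool = False,
    partner_alpha: float | None = None,
) -> list[dict]:
    """Per-cell breakdown: attention weight, win probability, evidence share.

    Returns one record per (alternative, dimension) cell with the raw
    attention weight, the partner-weighted probability of winning the
    comparison, and the cell's contribution to the alternative's
    accumulation rate.  Useful for tracing which comparisons drive an
    effect.

    ``partner_alpha`` overrides the similarity decay used for *partner*
    selection only (0 makes partner choice uniform over the pool); by
    default partners are selected with the same similarity weighting as
    attention.
    """
    params = params or ModelParams()
    p_alpha = params.alpha if partner_alpha is None else partner_alpha
    cells, attention, comparison = _build_space(problem, collapse)
    out = []
    total = 0.0
    for cell in cells:
        att = _comparators(attention[cell.attention_key], cell)
        w = float(_similarity_weights(cell, att, params.alpha).sum())
        comps = _comparators(comparison[cell.dim], cell)
        pw = _similarity_weights(cell, comps, p_alpha)
        if pw.sum() > 0:
            partner = pw / pw.sum()
            pwin = float(
                sum(
                    p * win_probability(cell.value, e.value, cell.polarity, params)
                    for p, e in zip(partner, comps)
                )
            )
        else:
            pwin = 0.0
        out.append(
            {
                "alternative": cell.alt_id,
                "dimension": cell.dim,
                "value": cell.value,
                "weight": w,
                "p_win": pwin,
            }
        )
        total += w
    if total <= 0:
        raise DegenerateProblemError(
            "no evaluation target has a comparator; the problem is degenerate"
        )
    for rec in out:
        rec["p_evaluate"] = rec["weight"] / total
        rec["rate_contribution"] = rec["p_evaluate"] * rec["p_win"]
    return out


def evaluation_distribution(
    problem: DecisionProblem,
    params: ModelParams | None = None,
    collapse: bool = False,
) -> EvaluationDistribution:
    """Probability that each (alternative, dimension) cell is evaluated next.

    The weight of a cell is the summed similarity of its value to the other
    values in the working-memory pool for that dimension, normalized over all
    cells of choosable alternatives.  Context values are never targets; cells
    whose value is missing, or whose pool holds no comparator, get zero mass.
    """
    table = cell_table(problem, params, collapse)
    return EvaluationDistribution(
        {(r["alternative"], r["dimension"]): r["p_evaluate"] for r in table}
    )


def partner_distribution(
    problem: DecisionProblem,
    target_cell: tuple[str, str],
    params: ModelParams | None = None,
) -> list[tuple[float, float]]:
    """Distribution over comparator values for one target cell.

    Probability of comparator X is proportional to exp(-alpha * D(A_i, X))
    over the dimension's working-memory pool, excluding the target's own
    value instance.  Returns (comparator value, probability) pairs.
    """
    params = params or ModelParams()
    alt_id, dim = target_cell
    alt = problem.alternative(alt_id)
    v = alt.value(dim)
    if v is None:
        raise InvalidValueError(f"alternative {alt_id!r} has no value on {dim!r}")
    cells, _attention, comparison = _build_space(problem, collapse=False)
    cell = next(c for c in cells if c.alt_id == alt_id and c.dim == dim)
    comps = _comparators(comparison[dim], cell)
    if not comps:
        raise DegenerateProblemError(
            f"cell ({alt_id!r}, {dim!r}) has an empty comparator pool"
        )
    w = _similarity_weights(cell, comps, params.alpha)
    p = w / w.sum()
    return [(e.value, float(pi)) for e, pi in zip(comps, p)]


def accumulation_rates(
    problem: DecisionProblem,
    params: ModelParams | None = None,
    collapse: bool = False,
    partner_alpha: float | None = None,
) -> RateVector:
    """Per-step probability that each alternative gains one evidence unit.

    rate(A) = sum over dimensions of p(evaluate A_i) * p(A_i wins its
    comparison), where the win probability marginalizes over the
    similarity-weighted partner choice.  Winning against a context value
    counts as evidence; context values themselves never accrue any.
    """
    table = cell_table(problem, params, collapse, partner_alpha)
    rates = {a.id: 0.0 for a in problem.alternatives}
    for rec in table:
        rates[rec["alternative"]] += rec["rate_contribution"]
    return RateVector(rates)


def relative_rank(
    target_value: float,
    pool_of_values: Sequence[float],
    polarity: str = HIGHER_BETTER,
) -> float:
    """Proportion of pool values the target strictly beats under polarity.

    Ties count as not beaten.  The pool is used exactly as given: callers
    decide whether the target itself is a pool member (the denominator then
    includes it, and it can never be beaten).
    """
    pool = list(pool_of_values)
    if not pool:
        raise InvalidValueError("relative_rank needs a nonempty pool")
    wins = sum(1 for v in pool if _prefers(target_value, v, polarity))
    return wins / len(pool)


def subjective_value(
    target_value: float,
    comparison_pool: Sequence[float],
    polarity: str = HIGHER_BETTER,
    params: ModelParams | None = None,
) -> float:
    """Partner-probability-weighted mean win probability against the pool.

    This is the single-cell accumulation rate for the target value: the soft
    analogue of its relative rank.  The pool is used exactly as given.
    """
    params = params or ModelParams()
    pool = [float(v) for v in comparison_pool]
    if not pool:
        raise InvalidValueError("subjective_value needs a nonempty pool")
    d = np.array([advantage_distance(target_value, v) for v in pool])
    w = np.exp(-params.alpha * d)
    p = w / w.sum()
    return float(
        sum(
            pi * win_probability(target_value, v, polarity, params)
            for pi, v in zip(p, pool)
        )
    )


def enumerate_comparisons(
    problem: DecisionProblem,
) -> list[tuple[str, str, str]]:
    """All (target, comparator, dimension) triples among choosable
    alternatives: ordered pairs of distinct alternatives crossed with the
    dimensions on which both hold a value."""
    out = []
    for a in problem.alternatives:
        for b in problem.alternatives:
            if a.id == b.id:
                continue
            for d in problem.dimensions:
                if d.name in a.values and d.name in b.values:
                    out.append((a.id, b.id, d.name))
    return out
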