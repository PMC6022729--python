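"""Domain types for multiattribute choice problems.

A decision problem couples a set of named attribute dimensions (each with a
preference polarity) with choosable alternatives holding strictly positive
attribute magnitudes, plus optional per-dimension *context pools*: values that
sit in working memory without being choosable (prior-trial alternatives,
announced-unavailable options, long-term-memory samples).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

HIGHER_BETTER = "higher_better"
LOWER_BETTER = "lower_better"
POLARITIES = (HIGHER_BETTER, LOWER_BETTER)


class InvalidValueError(ValueError):
    """An attribute magnitude or parameter violates its domain (e.g. <= 0)."""


class DegenerateProblemError(ValueError):
    """No evaluation target has any comparator: every cell has zero weight."""


class NoDecisionError(RuntimeError):
    """The accumulation process cannot terminate (all rates zero) or exceeded
    its step budget."""


class SchemaError(ValueError):
    """A serialized choice-set description violates the documented schema."""


@dataclass(frozen=True)
class DimensionSpec:
    """One attribute dimension.

    ``polarity`` states whether larger magnitudes are preferred
    (``higher_better``, e.g. fuel efficiency) or smaller ones
    (``lower_better``, e.g. price).  Dimensions sharing a
    ``commensurable_group`` label are on the same scale and unit and may be
    pooled for cross-dimension attention (attribute-balance collapsing).
    """

    name: str
    polarity: str = HIGHER_BETTER
    commensurable_group: str | None = None

    def __post_init__(self) -> None:
        if self.polarity not in POLARITIES:
            raise SchemaError(
                f"polarity for dimension {self.name!r} must be one of "
                f"{POLARITIES}, got {self.polarity!r}"
            )


@dataclass(frozen=True)
class Alternative:
    """A choosable option: id plus a mapping dimension name -> magnitude.

    Entries may be absent (missing attribute value); present entries must be
    strictly positive.
    """

    id: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.values:
            raise InvalidValueError(f"alternative {self.id!r} has no values")
        for dim, v in self.values.items():
            if not v > 0:
                raise InvalidValueError(
                    f"alternative {self.id!r} has nonpositive value {v!r} on "
                    f"dimension {dim!r}; magnitudes must be > 0"
                )

    def value(self, dim: str) -> float | None:
        return self.values.get(dim)


@dataclass(frozen=True)
class ModelParams:
    """Model parameters with their standard defaults.

    alpha : similarity decay for attention weighting (>= 0)
    beta0 : fractional-advantage threshold at which a comparison is won with
            probability one half
    beta1 : sensitivity (slope) of the logistic soft comparison (> 0)
    theta : relative stopping threshold on max-minus-mean evidence (> 0)
    """

    alpha: float = 3.0
    beta0: float = 0.1
    beta1: float = 50.0
    theta: float = 0.1

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise InvalidValueError("alpha must be >= 0")
        if not self.beta1 > 0:
            raise InvalidValueError("beta1 must be > 0")
        if not self.theta > 0:
            raise InvalidValueError("theta must be > 0")

    def replace(self, **kw: float) -> "ModelParams":
        d = {"alpha": self.alpha, "beta0": self.beta0,
             "beta1": self.beta1, "theta": self.theta}
        d.update(kw)
        return ModelParams(**d)


@dataclass
class DecisionProblem:
    """A choice set plus the working-memory context.

    The working-memory pool on dimension *i* is the multiset of all present
    alternative values on *i* plus the context values on *i*.
    """

    dimensions: list[DimensionSpec]
    alternatives: list[Alternative]
    context: dict[str, list[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [d.name for d in self.dimensions]
        if len(set(names)) != len(names):
            raise SchemaError(f"duplicate dimension names in {names}")
        ids = [a.id for a in self.alternatives]
        if len(set(ids)) != len(ids):
            raise SchemaError(f"duplicate alternative ids in {ids}")
        if not self.alternatives:
            raise SchemaError("a decision problem needs at least one alternative")
        declared = set(names)
        for a in self.alternatives:
            unknown = set(a.values) - declared
            if unknown:
                raise SchemaError(
                    f"alternative {a.id!r} has values on undeclared "
                    f"dimensions {sorted(unknown)}"
                )
        for dim, vals in self.context.items():
            if dim not in declared:
                raise SchemaError(f"context pool on undeclared dimension {dim!r}")
            for v in vals:
                if not v > 0:
                    raise InvalidValueError(
                        f"context value {v!r} on dimension {dim!r} must be > 0"
                    )

    # -- convenience -------------------------------------------------------

    @property
    def ids(self) -> list[str]:
        return [a.id for a in self.alternatives]

    def dimension(self, name: str) -> DimensionSpec:
        for d in self.dimensions:
            if d.name == name:
                return d
        raise KeyError(name)

    def alternative(self, alt_id: str) -> Alternative:
        for a in self.alternatives:
            if a.id == alt_id:
                return a
        raise KeyError(alt_id)

    def subset(self, ids: Sequence[str]) -> "DecisionProblem":
        """A new problem restricted to the given alternatives (context kept)."""
        return DecisionProblem(
            dimensions=list(self.dimensions),
            alternatives=[self.alternative(i) for i in ids],
            context={k: list(v) for k, v in self.context.items()},
        )

    def with_context(self, extra: Mapping[str, Sequence[float]]) -> "DecisionProblem":
        """A new problem with additional context values merged in."""
        ctx = {k: list(v) for k, v in self.context.items()}
        for dim, vals in extra.items():
            ctx.setdefault(dim, []).extend(float(v) for v in vals)
        return DecisionProblem(
            dimensions=list(self.dimensions),
            alternatives=list(self.alternatives),
            context=ctx,
        )


@dataclass
class EvaluationDistribution:
    """Probability that each (alternative, dimension) cell is the next
    evaluation target.  Sums to one over all cells of choosable alternatives;
    cells on missing-value or comparator-free dimensions carry zero mass."""

    probabilities: dict[tuple[str, str], float]

    def by_alternative(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for (alt, _dim), p in self.probabilities.items():
            out[alt] = out.get(alt, 0.0) + p
        return out

    def __getitem__(self, cell: tuple[str, str]) -> float:
        return self.probabilities.get(cell, 0.0)


@dataclass
class RateVector:
    """Per-alternative probability of accruing one evidence unit on a single
    comparison step.  Entries lie in [0, 1] and sum to at most one; the
    remainder is the probability that a step yields no evidence."""

    rates: dict[str, float]

    @property
    def ids(self) -> list[str]:
        return list(self.rates)

    @property
    def total(self) -> float:
        return float(sum(self.rates.values()))

    def __getitem__(self, alt_id: str) -> float:
        return self.rates[alt_id]

    def items(self):
        return self.rates.items()
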