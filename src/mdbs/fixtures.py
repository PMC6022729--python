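"""Packaged choice sets, decoy constructors, and synthetic value pools.

The catalog carries the attribute tables the model's qualitative predictions
are evaluated on (intransitive three-option set, normalized car coordinates,
consumer-product pairs, rating cars, money value sets) together with a
hand-built two-attribute car fixture calibrated so that the two core cars are
exactly indifferent in a binary choice under default parameters.

Monetary sets quoted with a zero entry encode it as a small positive
placeholder (``EPSILON_ZERO``): the fractional distance is undefined at zero,
and a vanishing value is beaten by everything, which the placeholder
preserves.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (
    Alternative,
    DecisionProblem,
    DimensionSpec,
    HIGHER_BETTER,
    InvalidValueError,
    LOWER_BETTER,
    ModelParams,
)

__all__ = [
    "EPSILON_ZERO",
    "FIXTURES",
    "VALUE_SETS",
    "LtmSpec",
    "load_fixture",
    "load_value_set",
    "make_attraction_decoy",
    "make_similarity_decoy",
    "make_compromise_decoy",
    "sample_ltm",
    "generate_choice_data",
]

EPSILON_ZERO = 0.01  # stand-in for a quoted value of zero


def _data(name: str) -> pd.DataFrame:
    ref = importlib.resources.files("mdbs.data") / name
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


# ---------------------------------------------------------------------------
# catalog builders


def _synthetic_big_three() -> DecisionProblem:
    """Two-attribute cars (price in USD, fuel efficiency in mpg).

    A and B trade off price against efficiency with equal similarity-weighted
    winning cells, so the binary choice is split .5/.5 exactly.  The decoys:
    D dominated by A (attraction), C extending the B->A line beyond A
    (compromise), S a near-clone of B (similarity), R worsening A's weak
    dimension only (range decoy), F worsening A's strong dimension only
    (frequency decoy).
    """
    dims = [
        DimensionSpec("price", LOWER_BETTER),
        DimensionSpec("mpg", HIGHER_BETTER),
    ]
    alts = [
        Alternative("A", {"price": 24000, "mpg": 32}),
        Alternative("B", {"price": 16000, "mpg": 24}),
        Alternative("C", {"price": 32000, "mpg": 40}),
        Alternative("D", {"price": 28000, "mpg": 29}),
        Alternative("S", {"price": 16500, "mpg": 23}),
        Alternative("R", {"price": 28000, "mpg": 32}),
        Alternative("F", {"price": 24000, "mpg": 29}),
        Alternative("E", {"price": 36000, "mpg": 23}),
    ]
    return DecisionProblem(dims, alts)


def _intransitive() -> DecisionProblem:
    df = _data("table5_intransitive.csv")
    dims = [
        DimensionSpec(r.dimension, r.polarity) for r in df.itertuples()
    ]
    alts = []
    for alt_id in ("V", "Y", "Z"):
        vals = {
            r.dimension: float(getattr(r, alt_id))
            for r in df.itertuples()
            if pd.notna(getattr(r, alt_id))
        }
        alts.append(Alternative(alt_id, vals))
    return DecisionProblem(dims, alts)


def _j1_cars() -> DecisionProblem:
    df = _data("tableJ1_cars.csv")
    dims = [
        DimensionSpec("x", HIGHER_BETTER),
        DimensionSpec("y", HIGHER_BETTER),
    ]
    alts = [
        Alternative(r.alternative, {"x": float(r.x), "y": float(r.y)})
        for r in df.itertuples()
    ]
    return DecisionProblem(dims, alts)


def _balance_ratings() -> DecisionProblem:
    """Rating cars on a shared 0-100 scale: warranty and efficiency ratings
    are commensurable, so cross-dimension attention pooling applies."""
    dims = [
        DimensionSpec("warranty_rating", HIGHER_BETTER, "rating"),
        DimensionSpec("efficiency_rating", HIGHER_BETTER, "rating"),
    ]
    table = {"K": (40, 80), "L": (50, 70), "Q": (60, 60),
             "U": (70, 50), "W": (80, 40)}
    alts = [
        Alternative(k, {"warranty_rating": w, "efficiency_rating": e})
        for k, (w, e) in table.items()
    ]
    return DecisionProblem(dims, alts)


def _products() -> dict[str, DecisionProblem]:
    df = _data("tableF1_products.csv")
    out = {}
    for product, grp in df.groupby("product", sort=False):
        dims = [
            DimensionSpec(r.dimension, r.polarity) for r in grp.itertuples()
        ]
        alts = [
            Alternative(
                alt_id,
                {r.dimension: float(getattr(r, alt_id)) for r in grp.itertuples()},
            )
            for alt_id in ("A", "B")
        ]
        out[product] = DecisionProblem(dims, alts)
    return out


FIXTURES = (
    "synthetic_big_three",
    "intransitive",
    "j1_cars",
    "balance_ratings",
    "products",
)

VALUE_SETS = ("money_skewed", "money_uniform", "gain_loss_ranges")


def load_fixture(name: str):
    """Load a packaged decision problem by name.

    ``products`` returns a dict of two-alternative problems keyed by cover
    story; ``products:<story>`` returns a single one.  Monetary value sets
    live under :func:`load_value_set`.
    """
    if name == "synthetic_big_three":
        return _synthetic_big_three()
    if name == "intransitive":
        return _intransitive()
    if name == "j1_cars":
        return _j1_cars()
    if name == "balance_ratings":
        return _balance_ratings()
    if name == "products":
        return _products()
    if name.startswith("products:"):
        story = name.split(":", 1)[1]
        prods = _products()
        if story not in prods:
            raise KeyError(
                f"unknown product {story!r}; available: {sorted(prods)}"
            )
        return prods[story]
    raise KeyError(
        f"unknown fixture {name!r}; problems: {FIXTURES}, "
        f"value sets (load_value_set): {VALUE_SETS}"
    )


def load_value_set(name: str):
    """Monetary working-memory pools quoted in the literature.

    money_skewed   : positively skewed amounts {0, 10, 20, 50, 100, 200, 500}
    money_uniform  : uniform amounts {0, 100, 200, 300, 400, 500}
    gain_loss_ranges : dict of 1-unit grids, gains 0-40 and losses 0-20
    """
    if name == "money_skewed":
        return [EPSILON_ZERO, 10.0, 20.0, 50.0, 100.0, 200.0, 500.0]
    if name == "money_uniform":
        return [EPSILON_ZERO, 100.0, 200.0, 300.0, 400.0, 500.0]
    if name == "gain_loss_ranges":
        return {
            "gains": [EPSILON_ZERO] + [float(v) for v in range(1, 41)],
            "losses": [EPSILON_ZERO] + [float(v) for v in range(1, 21)],
        }
    raise KeyError(f"unknown value set {name!r}; available: {VALUE_SETS}")


# ---------------------------------------------------------------------------
# decoy constructors


def _utility_worsen(value: float, delta: float, polarity: str) -> float:
    """Move a magnitude by |delta| in the *worse* direction under polarity."""
    return value - delta if polarity == HIGHER_BETTER else value + delta


def make_attraction_decoy(
    A: Alternative,
    B: Alternative,
    dimensions: list[DimensionSpec],
    favored: str,
    fraction: float = 0.25,
    decoy_id: str | None = None,
) -> Alternative:
    """Dominated decoy: the favored alternative worsened, in the utility
    direction, by ``fraction`` of the per-dimension |A - B| difference."""
    if not fraction > 0:
        raise InvalidValueError("fraction must be > 0")
    fav = A if favored == A.id else B
    vals = {}
    for d in dimensions:
        if d.name not in fav.values:
            continue
        delta = fraction * abs(A.values[d.name] - B.values[d.name])
        v = _utility_worsen(fav.values[d.name], delta, d.polarity)
        if not v > 0:
            raise InvalidValueError(
                f"decoy value on {d.name!r} would be nonpositive ({v})"
            )
        vals[d.name] = v
    return Alternative(decoy_id or f"D_{fav.id}", vals)


def make_similarity_decoy(
    A: Alternative,
    B: Alternative,
    dimensions: list[DimensionSpec],
    favored: str,
    fraction: float = 0.02,
    subtract_dimension: str | None = None,
    decoy_id: str | None = None,
) -> Alternative:
    """Near-clone decoy: the *rival* of the favored alternative perturbed by
    -fraction * |A - B| on one dimension and +fraction * |A - B| on the
    other.  Subtraction lands on the first declared dimension unless
    ``subtract_dimension`` overrides it."""
    if len(dimensions) != 2:
        raise InvalidValueError("similarity decoy needs exactly two dimensions")
    rival = B if favored == A.id else A
    sub = subtract_dimension or dimensions[0].name
    vals = {}
    for d in dimensions:
        delta = fraction * abs(A.values[d.name] - B.values[d.name])
        sign = -1.0 if d.name == sub else 1.0
        vals[d.name] = rival.values[d.name] + sign * delta
    return Alternative(decoy_id or f"S_{'A' if favored == A.id else 'B'}", vals)


def make_compromise_decoy(
    A: Alternative,
    B: Alternative,
    dimensions: list[DimensionSpec],
    favored: str,
    extrapolation: float = 1.0,
    decoy_id: str | None = None,
) -> Alternative:
    """Extreme decoy making the favored alternative the compromise: extends
    the rival->favored line past the favored end by ``extrapolation`` times
    the per-dimension difference."""
    if not extrapolation > 0:
        raise InvalidValueError("extrapolation must be > 0")
    fav = A if favored == A.id else B
    rival = B if favored == A.id else A
    vals = {}
    for d in dimensions:
        v = fav.values[d.name] + extrapolation * (
            fav.values[d.name] - rival.values[d.name]
        )
        if not v > 0:
            raise InvalidValueError(
                f"compromise decoy value on {d.name!r} nonpositive ({v})"
            )
        vals[d.name] = v
    return Alternative(decoy_id or f"C_{fav.id}", vals)


# ---------------------------------------------------------------------------
# synthetic long-term-memory pools and choice data


@dataclass
class LtmSpec:
    """Long-term-memory value distribution: per-dimension normal means and
    standard deviations with a shared cross-dimension correlation.  Draws are
    truncated to positive values by resampling."""

    means: dict[str, float]
    sds: dict[str, float]
    correlation: float = -0.2
    n_samples: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1 < self.correlation < 1:
            raise InvalidValueError("correlation must lie in (-1, 1)")
        for d, s in self.sds.items():
            if not s > 0:
                raise InvalidValueError(f"sd on {d!r} must be > 0")


def ltm_spec_from_pair(
    problem: DecisionProblem,
    anchor: str = "A",
    rival: str = "B",
    correlation: float = -0.2,
    n_samples: int = 0,
    seed: int = 0,
) -> LtmSpec:
    """Spec whose means are the anchor's attribute values and whose standard
    deviations are the absolute anchor-rival differences."""
    a = problem.alternative(anchor)
    b = problem.alternative(rival)
    dims = [d.name for d in problem.dimensions if d.name in a.values]
    return LtmSpec(
        means={d: a.values[d] for d in dims},
        sds={d: abs(a.values[d] - b.values[d]) for d in dims},
        correlation=correlation,
        n_samples=n_samples,
        seed=seed,
    )


def sample_ltm(spec: LtmSpec) -> dict[str, list[float]]:
    """Seeded correlated-normal value pool, one list per dimension.

    Nonpositive draws are rejected and resampled; if the nonpositive mass of
    any marginal exceeds 99% the truncation is infeasible and an error is
    raised."""
    from scipy.stats import norm

    dims = list(spec.means)
    mu = np.array([spec.means[d] for d in dims])
    sd = np.array([spec.sds[d] for d in dims])
    for d, m, s in zip(dims, mu, sd):
        if norm.cdf(0.0, loc=m, scale=s) > 0.99:
            raise InvalidValueError(
                f"dimension {d!r}: over 99% of the normal mass is nonpositive"
            )
    if spec.n_samples == 0:
        return {d: [] for d in dims}
    k = len(dims)
    cov = np.full((k, k), spec.correlation) + np.eye(k) * (1 - spec.correlation)
    cov = cov * np.outer(sd, sd)
    rng = np.random.default_rng(spec.seed)
    rows: list[np.ndarray] = []
    while len(rows) < spec.n_samples:
        draw = rng.multivariate_normal(mu, cov, size=spec.n_samples)
        good = draw[(draw > 0).all(axis=1)]
        rows.extend(good)
    draws = np.array(rows[: spec.n_samples])
    return {d: draws[:, j].tolist() for j, d in enumerate(dims)}


def generate_choice_data(
    problem: DecisionProblem,
    params: ModelParams | None = None,
    n_trials: int = 1000,
    seed: int = 0,
) -> dict[str, int]:
    """Multinomial choice counts drawn from the closed-form probabilities."""
    from .process import predict_choice

    params = params or ModelParams()
    dist = predict_choice(problem, params)
    rng = np.random.default_rng(seed)
    ids = dist.ids
    counts = rng.multinomial(n_trials, [dist[i] for i in ids])
    return dict(zip(ids, counts.tolist()))
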