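"""Named context-effect scenarios.

Each scenario builds its choice sets (from packaged fixtures or constructed
context pools), runs the model, and returns a :class:`ScenarioResult` with
per-condition choice tables and named effect sizes.  Everything is
deterministic given (fixture, parameters, seed); stochastic scenarios carry
their seed in the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import accumulation_rates, relative_rank, subjective_value
from .fixtures import (
    EPSILON_ZERO,
    LtmSpec,
    load_fixture,
    load_value_set,
    ltm_spec_from_pair,
    sample_ltm,
)
from .process import (
    ChoiceDistribution,
    fixed_horizon_choice,
    predict_choice,
)
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
    "ScenarioResult",
    "run_big_three",
    "sweep_decoy",
    "compare_decoy_locations",
    "dilute_with_ltm",
    "sweep_horizon",
    "sweep_alpha",
    "attribute_balance",
    "contextual_choice",
    "intransitivity_suite",
    "perceptual_focus",
    "value_curve",
    "SCENARIOS",
    "run_scenario",
]


@dataclass
class ScenarioResult:
    name: str
    tables: dict[str, ChoiceDistribution]
    effects: dict[str, float]
    params: ModelParams
    seed: int | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "scenario": self.name,
            "params": {
                "alpha": self.params.alpha,
                "beta0": self.params.beta0,
                "beta1": self.params.beta1,
                "theta": self.params.theta,
            },
            "seed": self.seed,
            "tables": {
                cond: dist.probabilities for cond, dist in self.tables.items()
            },
            "effects": self.effects,
            "extras": {
                k: v for k, v in self.extras.items() if _jsonable(v)
            },
        }


def _jsonable(v) -> bool:
    return isinstance(v, (int, float, str, bool, list, dict, type(None)))


_TRIADS = {"attraction": "D", "compromise": "C", "similarity": "S"}


def _pab(dist: ChoiceDistribution, a: str = "A", b: str = "B") -> float:
    return dist[a] - dist[b]


def run_big_three(
    fixture: DecisionProblem | None = None,
    params: ModelParams | None = None,
) -> ScenarioResult:
    """Binary baseline plus the attraction, compromise, and similarity
    triads.  Effect sizes are p(A) - p(B) per triad; the attraction triad
    additionally reports the regularity violation p(A|{A,B,D}) - p(A|{A,B}).
    """
    params = params or ModelParams()
    fixture = fixture or load_fixture("synthetic_big_three")
    tables = {"AB": predict_choice(fixture.subset(["A", "B"]), params)}
    effects: dict[str, float] = {}
    for effect, decoy in _TRIADS.items():
        dist = predict_choice(fixture.subset(["A", "B", decoy]), params)
        tables["AB" + decoy] = dist
        effects[effect] = _pab(dist)
    effects["regularity_violation"] = tables["ABD"]["A"] - tables["AB"]["A"]
    return ScenarioResult("big_three", tables, effects, params)


def sweep_decoy(
    fixture: DecisionProblem | None = None,
    start: str = "E",
    end: str = "A",
    n_steps: int = 21,
    params: ModelParams | None = None,
) -> ScenarioResult:
    """Move the dominated decoy along the line from a distant inferior car to
    coincidence with the favored car.  The attraction effect first
    strengthens then fades: very close to the favored car the decoy's
    disadvantages fall below the soft comparison threshold and are mostly
    unrecognized."""
    params = params or ModelParams()
    fixture = fixture or load_fixture("synthetic_big_three")
    a = fixture.alternative(end)
    e = fixture.alternative(start)
    dims = [d.name for d in fixture.dimensions]
    tables = {}
    p_a = []
    for i, t in enumerate(np.linspace(0.0, 1.0, n_steps)):
        vals = {
            d: (1 - t) * e.values[d] + t * a.values[d] for d in dims
        }
        decoy = Alternative("decoy", vals)
        prob = DecisionProblem(
            list(fixture.dimensions),
            [fixture.alternative("A"), fixture.alternative("B"), decoy],
        )
        dist = predict_choice(prob, params)
        tables[f"pos_{i:02d}"] = dist
        p_a.append(dist["A"])
    p_a = np.array(p_a)
    peak = int(p_a.argmax())
    effects = {
        "p_A_at_start": float(p_a[0]),
        "p_A_peak": float(p_a.max()),
        "p_A_at_end": float(p_a[-1]),
        "peak_position": peak / (n_steps - 1),
        "nonmonotone": float(0 < peak < n_steps - 1),
    }
    return ScenarioResult(
        "decoy_distance", tables, effects, params,
        extras={"p_A_path": p_a.tolist()},
    )


def compare_decoy_locations(
    fixture: DecisionProblem | None = None,
    params: ModelParams | None = None,
) -> ScenarioResult:
    """Range decoy R (worsens the favored car's weak dimension, widening that
    range) versus frequency decoy F (worsens its strong dimension).  The
    model predicts a stronger attraction effect with R."""
    params = params or ModelParams()
    fixture = fixture or load_fixture("synthetic_big_three")
    tables = {
        "ABR": predict_choice(fixture.subset(["A", "B", "R"]), params),
        "ABF": predict_choice(fixture.subset(["A", "B", "F"]), params),
    }
    effects = {
        "p_A_with_R": tables["ABR"]["A"],
        "p_A_with_F": tables["ABF"]["A"],
        "location_advantage": tables["ABR"]["A"] - tables["ABF"]["A"],
    }
    return ScenarioResult("decoy_location", tables, effects, params)


def dilute_with_ltm(
    fixture: DecisionProblem | None = None,
    sample_counts: tuple[int, ...] = (0, 4, 16, 64),
    n_reps: int = 500,
    seed: int = 0,
    params: ModelParams | None = None,
    ltm_spec: LtmSpec | None = None,
) -> ScenarioResult:
    """Familiarity: values sampled from long-term memory swamp the immediate
    context and weaken all three effects.

    The memory distribution is normal with mean at car A's attribute values,
    per-dimension sd equal to the |A - B| difference, and cross-dimension
    correlation -0.2.  Effect sizes are replicate means of p(A) - p(B).
    """
    params = params or ModelParams()
    fixture = fixture or load_fixture("synthetic_big_three")
    base_spec = ltm_spec or ltm_spec_from_pair(fixture)
    rng = np.random.default_rng(seed)
    tables: dict[str, ChoiceDistribution] = {}
    effects: dict[str, float] = {}
    curves: dict[str, list[float]] = {}
    for effect, decoy in _TRIADS.items():
        triad = fixture.subset(["A", "B", decoy])
        curve = []
        for count in sample_counts:
            if count == 0:
                mean_eff = _pab(predict_choice(triad, params))
            else:
                vals = []
                for _ in range(n_reps):
                    spec = LtmSpec(
                        base_spec.means,
                        base_spec.sds,
                        base_spec.correlation,
                        n_samples=count,
                        seed=int(rng.integers(2**31 - 1)),
                    )
                    diluted = triad.with_context(sample_ltm(spec))
                    vals.append(_pab(predict_choice(diluted, params)))
                mean_eff = float(np.mean(vals))
            curve.append(mean_eff)
            effects[f"{effect}_at_{count}"] = mean_eff
        curves[effect] = curve
        slope = np.polyfit(sample_counts, curve, 1)[0]
        effects[f"{effect}_weakens"] = float(
            curve[-1] < curve[0] and slope < 0
        )
    return ScenarioResult(
        "ltm_dilution", tables, effects, params, seed=seed,
        extras={"sample_counts": list(sample_counts), "curves": curves,
                "n_reps": n_reps},
    )


def sweep_horizon(
    fixture: DecisionProblem | None = None,
    horizons: tuple[int, ...] = tuple(range(0, 11)),
    params: ModelParams | None = None,
) -> ScenarioResult:
    """Time pressure: choice after a fixed number of comparisons.  With few
    comparisons decisions are nearly random and the effects vanish; they
    strengthen as the horizon grows."""
    params = params or ModelParams()
    fixture = fixture or load_fixture("synthetic_big_three")
    tables = {}
    effects = {}
    curves = {}
    for effect, decoy in _TRIADS.items():
        triad = fixture.subset(["A", "B", decoy])
        curve = []
        for h in horizons:
            dist = fixed_horizon_choice(triad, params, n_comparisons=h)
            tables[f"{effect}_h{h}"] = dist
            curve.append(_pab(dist))
        curves[effect] = curve
        effects[f"{effect}_at_h{horizons[0]}"] = curve[0]
        effects[f"{effect}_at_h{horizons[-1]}"] = curve[-1]
        effects[f"{effect}_strengthens"] = float(
            all(b >= a - 1e-12 for a, b in zip(curve, curve[1:]))
        )
    return ScenarioResult(
        "time_pressure", tables, effects, params,
        extras={"horizons": list(horizons), "curves": curves},
    )


def sweep_alpha(
    fixture: DecisionProblem | None = None,
    alpha_grid: tuple[float, ...] | None = None,
    params: ModelParams | None = None,
) -> ScenarioResult:
    """Individual differences in the similarity parameter: the relative
    choice share of A over B per effect as alpha moves over [0, 5].
    Attraction and compromise strengthen with alpha while similarity
    weakens, mirroring the meta-analytic correlation pattern."""
    params = params or ModelParams()
    fixture = fixture or load_fixture("synthetic_big_three")
    grid = (
        tuple(np.linspace(0.0, 5.0, 11)) if alpha_grid is None
        else tuple(alpha_grid)
    )
    if min(grid) < 0 or max(grid) > 5:
        raise InvalidValueError("alpha grid must lie within [0, 5]")
    tables = {}
    effects = {}
    curves = {}
    for effect, decoy in _TRIADS.items():
        triad = fixture.subset(["A", "B", decoy])
        shares = []
        for a in grid:
            dist = predict_choice(triad, params.replace(alpha=a))
            shares.append(dist["A"] / (dist["A"] + dist["B"]))
        curves[effect] = shares
        effects[f"{effect}_share_low_alpha"] = shares[0]
        effects[f"{effect}_share_high_alpha"] = shares[-1]
        effects[f"{effect}_trend"] = float(np.sign(shares[-1] - shares[0]))
    return ScenarioResult(
        "alpha_sweep", tables, effects, params,
        extras={"alpha_grid": list(grid), "curves": curves},
    )


def attribute_balance(
    fixture: DecisionProblem | None = None,
    params: ModelParams | None = None,
    triads: tuple[tuple[str, ...], ...] = (
        ("K", "L", "Q"), ("L", "Q", "U"), ("Q", "U", "W"),
    ),
) -> ScenarioResult:
    """Commensurable rating dimensions: pooling them for attention makes the
    balanced car the compromise of the collapsed value set, and it draws the
    most evaluations.  Returns collapsed choice distributions per triad."""
    params = params or ModelParams()
    fixture = fixture or load_fixture("balance_ratings")
    tables = {}
    effects = {}
    for ids in triads:
        key = "".join(ids)
        dist = predict_choice(fixture.subset(ids), params, collapse=True)
        tables[key] = dist
        balanced = "Q" if "Q" in ids else ids[len(ids) // 2]
        effects[f"p_{balanced}_{key}"] = dist[balanced]
        effects[f"{balanced}_maximal_{key}"] = float(
            dist[balanced] == max(dist.probabilities.values())
        )
    klq = fixture.subset(triads[0])
    pool = sorted(
        v for a in klq.alternatives for v in a.values.values()
    )
    return ScenarioResult(
        "attribute_balance", tables, effects, params,
        extras={"collapsed_pool_KLQ": pool},
    )


# ---------------------------------------------------------------------------
# contextual presets


def _background_contrast_fixture() -> tuple[DecisionProblem, dict, dict]:
    """Computers traded off between price and RAM.

    The focal pair trades at 2.50 $/KB.  The shallow prior pair (0.22 $/KB,
    RAM above both focal computers) erodes A's RAM rank from 1.0 to 1/3;
    the steep prior pair (17.50 $/KB, prices below both) erodes B's price
    rank instead.
    """
    dims = [
        DimensionSpec("price", LOWER_BETTER),
        DimensionSpec("ram", HIGHER_BETTER),
    ]
    alts = [
        Alternative("A", {"price": 600, "ram": 320}),
        Alternative("B", {"price": 400, "ram": 240}),
    ]
    problem = DecisionProblem(dims, alts)
    shallow = {"price": [450.0, 428.0], "ram": [500.0, 400.0]}
    steep = {"price": [350.0, 280.0], "ram": [310.0, 306.0]}
    return problem, shallow, steep


def _background_contrast(params: ModelParams, **kw) -> ScenarioResult:
    problem, shallow, steep = _background_contrast_fixture()
    tables = {
        "no_prior": predict_choice(problem, params),
        "shallow_prior": predict_choice(problem.with_context(shallow), params),
        "steep_prior": predict_choice(problem.with_context(steep), params),
    }
    effects = {
        "p_A_no_prior": tables["no_prior"]["A"],
        "p_A_shallow_prior": tables["shallow_prior"]["A"],
        "p_A_steep_prior": tables["steep_prior"]["A"],
        "preference_reverses": float(
            tables["shallow_prior"]["A"] < 0.5 < tables["steep_prior"]["A"]
        ),
    }
    rank_ram_before = relative_rank(320, [240], HIGHER_BETTER)
    rank_ram_after = relative_rank(320, [240] + shallow["ram"], HIGHER_BETTER)
    return ScenarioResult(
        "background_contrast", tables, effects, params,
        extras={
            "rank_A_ram_no_prior": rank_ram_before,
            "rank_A_ram_shallow_prior": rank_ram_after,
        },
    )


def _phantom_decoy(params: ModelParams, alpha: float = 10.0, **kw) -> ScenarioResult:
    """An announced-unavailable neighbour dominating A stays in working
    memory as context values.

    Under the standard rule (partner selection similarity-weighted with the
    same decay as attention) the attention boost cancels from the
    accumulation rates exactly, so the phantom can never favour A: the
    ``*_similarity_partner`` conditions report that analytical null.  When
    partner choice is made uniform (``partner_alpha=0``) attention frequency
    matters, and the effect emerges -- weakly at the default similarity
    decay and strongly at the larger ``alpha``, which is why a stronger
    similarity weighting is needed for this phenomenon than for the others.
    """
    cars = load_fixture("j1_cars")
    pair = cars.subset(["A", "B"])
    a = cars.alternative("A")
    r = cars.alternative("R")
    # reflect the range decoy R through A to get its superior twin
    phantom = {
        d: [2 * a.values[d] - r.values[d]] for d in ("x", "y")
    }
    with_phantom = pair.with_context(phantom)
    strong = params.replace(alpha=alpha)
    tables = {
        "default_alpha_similarity_partner": predict_choice(with_phantom, params),
        "large_alpha_similarity_partner": predict_choice(with_phantom, strong),
        "default_alpha_uniform_partner": predict_choice(
            with_phantom, params, partner_alpha=0.0
        ),
        "large_alpha_uniform_partner": predict_choice(
            with_phantom, strong, partner_alpha=0.0
        ),
    }
    effects = {
        "effect_default_alpha": _pab(tables["default_alpha_similarity_partner"]),
        "effect_large_alpha": _pab(tables["large_alpha_similarity_partner"]),
        "effect_default_alpha_uniform_partner": _pab(
            tables["default_alpha_uniform_partner"]
        ),
        "effect_large_alpha_uniform_partner": _pab(
            tables["large_alpha_uniform_partner"]
        ),
        "phantom_alpha": alpha,
    }
    return ScenarioResult(
        "phantom_decoy", tables, effects, params,
        extras={"phantom_values": phantom},
    )


def _less_is_more(params: ModelParams, horizon: int = 10, **kw) -> ScenarioResult:
    """Bundling a low-ranked extra attribute (with unflattering context
    comparators) onto the leading car strictly lowers its accumulation rate;
    under a comparison horizon its choice probability drops too."""
    fixture = load_fixture("synthetic_big_three")
    base = fixture.subset(["A", "B", "D"])
    dims = list(base.dimensions) + [DimensionSpec("umbrella_rating", HIGHER_BETTER)]
    a = base.alternative("A")
    bundled = DecisionProblem(
        dims,
        [
            Alternative("A", {**dict(a.values), "umbrella_rating": 30.0}),
            base.alternative("B"),
            base.alternative("D"),
        ],
        context={"umbrella_rating": [60.0, 80.0]},
    )
    rate_before = accumulation_rates(base, params)["A"]
    rate_after = accumulation_rates(bundled, params)["A"]
    tables = {
        "base": fixed_horizon_choice(base, params, n_comparisons=horizon),
        "bundled": fixed_horizon_choice(bundled, params, n_comparisons=horizon),
    }
    effects = {
        "rate_A_base": rate_before,
        "rate_A_bundled": rate_after,
        "rate_drop": rate_before - rate_after,
        "p_A_base": tables["base"]["A"],
        "p_A_bundled": tables["bundled"]["A"],
        "p_drop": tables["base"]["A"] - tables["bundled"]["A"],
    }
    return ScenarioResult("less_is_more", tables, effects, params,
                          extras={"horizon": horizon})


def _alignability(params: ModelParams, **kw) -> ScenarioResult:
    """Attributes unique to a single alternative have no working-memory
    comparators, so they receive zero evaluation probability and leave the
    decision untouched, however their values are perturbed."""
    dims = [
        DimensionSpec("calories", LOWER_BETTER),
        DimensionSpec("kernel_size", HIGHER_BETTER),
        DimensionSpec("sweetness", HIGHER_BETTER),
    ]

    def popcorns(kernel: float, sweet: float) -> DecisionProblem:
        return DecisionProblem(
            dims,
            [
                Alternative("A", {"calories": 110, "kernel_size": kernel}),
                Alternative("B", {"calories": 130, "sweetness": sweet}),
            ],
        )

    tables = {
        "base": predict_choice(popcorns(7.0, 6.0), params),
        "perturbed": predict_choice(popcorns(9.5, 3.0), params),
    }
    diff = max(
        abs(tables["base"][i] - tables["perturbed"][i]) for i in ("A", "B")
    )
    effects = {
        "p_A": tables["base"]["A"],
        "unique_dimension_influence": diff,
    }
    return ScenarioResult("alignability", tables, effects, params)


_PRESETS = {
    "background_contrast": _background_contrast,
    "phantom_decoy": _phantom_decoy,
    "less_is_more": _less_is_more,
    "alignability": _alignability,
}


def contextual_choice(
    preset: str,
    params: ModelParams | None = None,
    **kwargs,
) -> ScenarioResult:
    """Run one of the context-pool presets: background_contrast,
    phantom_decoy, less_is_more, alignability."""
    params = params or ModelParams()
    if preset not in _PRESETS:
        raise KeyError(
            f"unknown preset {preset!r}; available: {sorted(_PRESETS)}"
        )
    return _PRESETS[preset](params, **kwargs)


def intransitivity_suite(
    fixture: DecisionProblem | None = None,
    params: ModelParams | None = None,
) -> ScenarioResult:
    """Three-attribute alternatives with systematically missing values: each
    pairwise choice is decided by the single shared dimension, producing a
    preference cycle, while the ternary choice is near-indifferent."""
    params = params or ModelParams()
    fixture = fixture or load_fixture("intransitive")
    tables = {
        "VY": predict_choice(fixture.subset(["V", "Y"]), params),
        "YZ": predict_choice(fixture.subset(["Y", "Z"]), params),
        "ZV": predict_choice(fixture.subset(["Z", "V"]), params),
        "VYZ": predict_choice(fixture, params),
    }
    effects = {
        "p_Y_given_VY": tables["VY"]["Y"],
        "p_Z_given_YZ": tables["YZ"]["Z"],
        "p_V_given_ZV": tables["ZV"]["V"],
        "ternary_max": max(tables["VYZ"].probabilities.values()),
        "ternary_min": min(tables["VYZ"].probabilities.values()),
        "cycle": float(
            tables["VY"]["Y"] > 0.5
            and tables["YZ"]["Z"] > 0.5
            and tables["ZV"]["V"] > 0.5
        ),
    }
    return ScenarioResult("intransitivity", tables, effects, params)


def perceptual_focus(
    fixture: DecisionProblem | None = None,
    params: ModelParams | None = None,
) -> ScenarioResult:
    """Five cars where four share the same second-dimension value, leaving A
    distinctive there; A also sits amid similar first-dimension rivals.  A
    wins both on attention and on relative rank."""
    params = params or ModelParams()
    fixture = fixture or load_fixture("j1_cars").subset(
        ["A", "B", "G", "H", "J"]
    )
    dist = predict_choice(fixture, params)
    xs = {a.id: a.values["x"] for a in fixture.alternatives}
    ys = {a.id: a.values["y"] for a in fixture.alternatives}
    rivals_x = [v for k, v in xs.items() if k != "A"]
    rivals_y = [v for k, v in ys.items() if k != "A"]
    effects = {
        "p_A": dist["A"],
        "A_maximal": float(dist["A"] == max(dist.probabilities.values())),
        "rank_A_x": relative_rank(xs["A"], rivals_x, HIGHER_BETTER),
        "rank_B_x": relative_rank(
            xs["B"], [v for k, v in xs.items() if k != "B"], HIGHER_BETTER
        ),
        "rank_A_y": relative_rank(ys["A"], rivals_y, HIGHER_BETTER),
    }
    return ScenarioResult("perceptual_focus", {"ABGHJ": dist}, effects, params)


def value_curve(
    preset: str,
    grid: tuple[float, ...] | None = None,
    params: ModelParams | None = None,
) -> ScenarioResult:
    """Relative-rank and subjective-value curves over monetary pools.

    incidental   : the {1, 2, 7} working-memory pool and a target grid
    distribution : skewed vs uniform money sets (risk-aversion malleability)
    loss_ranges  : asymmetric gain/loss ranges (loss aversion and reversal)
    """
    params = params or ModelParams()
    effects: dict[str, float] = {}
    extras: dict = {}
    if preset == "incidental":
        pool = [1.0, 2.0, 7.0]
        g = grid or tuple(np.arange(0.5, 8.5, 0.5))
        extras["grid"] = list(g)
        extras["rank_curve"] = [
            relative_rank(v, pool, HIGHER_BETTER) for v in g
        ]
        extras["sv_curve"] = [
            subjective_value(v, pool, HIGHER_BETTER, params) for v in g
        ]
        effects["rank_at_5"] = relative_rank(5.0, pool, HIGHER_BETTER)
    elif preset == "distribution":
        skewed = load_value_set("money_skewed")
        uniform = load_value_set("money_uniform")
        g = grid or tuple([EPSILON_ZERO] + list(np.arange(10.0, 501.0, 10.0)))
        extras["grid"] = list(g)
        for label, pool in (("skewed", skewed), ("uniform", uniform)):
            extras[f"rank_curve_{label}"] = [
                relative_rank(v, pool, HIGHER_BETTER) for v in g
            ]
            extras[f"sv_curve_{label}"] = [
                subjective_value(v, pool, HIGHER_BETTER, params) for v in g
            ]
        effects["rank_200_skewed"] = relative_rank(200.0, skewed, HIGHER_BETTER)
        effects["rank_200_uniform"] = relative_rank(200.0, uniform, HIGHER_BETTER)
        effects["sv_200_skewed"] = subjective_value(
            200.0, skewed, HIGHER_BETTER, params
        )
        effects["sv_200_uniform"] = subjective_value(
            200.0, uniform, HIGHER_BETTER, params
        )
        rs = extras["rank_curve_skewed"]
        below = [r for v, r in zip(g, rs) if v <= 100]
        effects["skewed_rise_below_100"] = below[-1] - below[0]
        effects["skewed_rise_above_100"] = rs[-1] - below[-1]
    elif preset == "loss_ranges":
        pools = load_value_set("gain_loss_ranges")
        g = grid or tuple(float(v) for v in range(1, 21))
        extras["grid"] = list(g)
        for direction, pool in (
            ("gain", pools["gains"]),
            ("loss", pools["losses"]),
        ):
            extras[f"sv_curve_{direction}"] = [
                subjective_value(v, pool, HIGHER_BETTER, params) for v in g
            ]
            extras[f"rank_curve_{direction}"] = [
                relative_rank(v, pool, HIGHER_BETTER) for v in g
            ]
        effects["sv_gain_at_10"] = subjective_value(
            10.0, pools["gains"], HIGHER_BETTER, params
        )
        effects["sv_loss_at_10"] = subjective_value(
            10.0, pools["losses"], HIGHER_BETTER, params
        )
        effects["loss_aversion"] = (
            effects["sv_loss_at_10"] - effects["sv_gain_at_10"]
        )
        # reversed ranges: losses wide, gains narrow
        effects["sv_gain_at_10_reversed"] = subjective_value(
            10.0, pools["losses"], HIGHER_BETTER, params
        )
        effects["sv_loss_at_10_reversed"] = subjective_value(
            10.0, pools["gains"], HIGHER_BETTER, params
        )
        effects["loss_aversion_reversed"] = (
            effects["sv_loss_at_10_reversed"] - effects["sv_gain_at_10_reversed"]
        )
    else:
        raise KeyError(
            f"unknown value-curve preset {preset!r}; available: "
            "incidental, distribution, loss_ranges"
        )
    return ScenarioResult(f"value_{preset}", {}, effects, params, extras=extras)


# ---------------------------------------------------------------------------
# registry

SCENARIOS = {
    "big_three": run_big_three,
    "decoy_distance": sweep_decoy,
    "decoy_location": compare_decoy_locations,
    "ltm_dilution": dilute_with_ltm,
    "time_pressure": sweep_horizon,
    "alpha_sweep": sweep_alpha,
    "attribute_balance": attribute_balance,
    "background_contrast": lambda **kw: contextual_choice(
        "background_contrast", **kw
    ),
    "phantom_decoy": lambda **kw: contextual_choice("phantom_decoy", **kw),
    "less_is_more": lambda **kw: contextual_choice("less_is_more", **kw),
    "alignability": lambda **kw: contextual_choice("alignability", **kw),
    "intransitivity": intransitivity_suite,
    "perceptual_focus": perceptual_focus,
    "value_incidental": lambda **kw: value_curve("incidental", **kw),
    "value_distribution": lambda **kw: value_curve("distribution", **kw),
    "value_loss_ranges": lambda **kw: value_curve("loss_ranges", **kw),
}


def run_scenario(name: str, **kwargs) -> ScenarioResult:
    if name not in SCENARIOS:
        raise KeyError(
            f"unknown scenario {name!r}; available: {sorted(SCENARIOS)}"
        )
    return SCENARIOS[name](**kwargs)
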