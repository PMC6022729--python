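"""Serialization: choice-set JSON/CSV schema and tidy result tables.

JSON schema (version 1)::

    {
      "schema": "mdbs-problem/1",
      "dimensions": [{"name": ..., "polarity": ..., "commensurable_group": ...}],
      "alternatives": [{"id": ..., "values": {dim: value, ...}}],
      "context": {dim: [value, ...]}
    }

CSV dialect: one row per dimension with columns ``dimension``, ``polarity``,
optional ``group`` and ``context`` (space-separated values), then one column
per alternative id.  Blank cells are missing attribute values.
"""

from __future__ import annotations

import io as _stdio
import json
from pathlib import Path

import pandas as pd

from .types import (
    Alternative,
    DecisionProblem,
    DimensionSpec,
    POLARITIES,
    SchemaError,
)

__all__ = [
    "parse_problem",
    "problem_to_json",
    "problem_to_csv",
    "write_problem",
    "write_results",
    "results_frame",
]

_RESERVED = ("dimension", "polarity", "group", "context")


def problem_to_json(problem: DecisionProblem) -> str:
    doc = {
        "schema": "mdbs-problem/1",
        "dimensions": [
            {
                "name": d.name,
                "polarity": d.polarity,
                "commensurable_group": d.commensurable_group,
            }
            for d in problem.dimensions
        ],
        "alternatives": [
            {"id": a.id, "values": dict(a.values)} for a in problem.alternatives
        ],
        "context": {k: list(v) for k, v in problem.context.items() if v},
    }
    return json.dumps(doc, indent=2)


def problem_to_csv(problem: DecisionProblem) -> str:
    rows = []
    for d in problem.dimensions:
        row = {
            "dimension": d.name,
            "polarity": d.polarity,
            "group": d.commensurable_group or "",
            "context": " ".join(
                repr(v) for v in problem.context.get(d.name, [])
            ),
        }
        for a in problem.alternatives:
            v = a.value(d.name)
            row[a.id] = "" if v is None else repr(v)
        rows.append(row)
    buf = _stdio.StringIO()
    pd.DataFrame(rows).to_csv(buf, index=False)
    return buf.getvalue()


def _problem_from_dict(doc: dict) -> DecisionProblem:
    try:
        dims = [
            DimensionSpec(
                d["name"], d["polarity"], d.get("commensurable_group")
            )
            for d in doc["dimensions"]
        ]
        alts = [
            Alternative(a["id"], {k: float(v) for k, v in a["values"].items()})
            for a in doc["alternatives"]
        ]
    except KeyError as e:
        raise SchemaError(f"missing required field {e.args[0]!r}") from e
    ctx = {
        k: [float(v) for v in vs] for k, vs in doc.get("context", {}).items()
    }
    return DecisionProblem(dims, alts, ctx)


def _problem_from_csv(text: str) -> DecisionProblem:
    df = pd.read_csv(_stdio.StringIO(text), dtype=str).fillna("")
    if "dimension" not in df.columns or "polarity" not in df.columns:
        raise SchemaError("CSV needs 'dimension' and 'polarity' columns")
    alt_cols = [c for c in df.columns if c not in _RESERVED]
    if not alt_cols:
        raise SchemaError("CSV declares no alternative columns")
    dims, ctx = [], {}
    for r in df.itertuples():
        pol = r.polarity.strip()
        if pol not in POLARITIES:
            raise SchemaError(
                f"dimension {r.dimension!r}: polarity must be one of "
                f"{POLARITIES}, got {pol!r}"
            )
        group = getattr(r, "group", "").strip() or None
        dims.append(DimensionSpec(r.dimension.strip(), pol, group))
        raw_ctx = getattr(r, "context", "").strip()
        if raw_ctx:
            ctx[r.dimension.strip()] = [float(v) for v in raw_ctx.split()]
    alts = []
    for col in alt_cols:
        vals = {}
        for r in df.itertuples():
            cell = str(getattr(r, col)).strip()
            if cell:
                vals[r.dimension.strip()] = float(cell)
        alts.append(Alternative(col, vals))
    return DecisionProblem(dims, alts, ctx)


def parse_problem(source: str | Path) -> DecisionProblem:
    """Parse a choice-set description from a path or literal text.

    JSON (object with a ``dimensions`` key) and the CSV dialect above are
    both accepted; validation errors name the offending field.
    """
    text = None
    if isinstance(source, Path):
        text = source.read_text()
    else:
        p = Path(source)
        try:
            if p.exists():
                text = p.read_text()
        except OSError:
            pass
        if text is None:
            text = source
    stripped = text.lstrip()
    if stripped.startswith("{"):
        return _problem_from_dict(json.loads(text))
    return _problem_from_csv(text)


def write_problem(problem: DecisionProblem, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".csv":
        path.write_text(problem_to_csv(problem))
    else:
        path.write_text(problem_to_json(problem))


# ---------------------------------------------------------------------------
# results


def results_frame(result) -> pd.DataFrame:
    """Tidy table (scenario, condition, alternative, probability,
    effect_size) for a ScenarioResult, or (alternative, probability) for a
    bare ChoiceDistribution."""
    from .process import ChoiceDistribution
    from .scenarios import ScenarioResult

    if isinstance(result, ChoiceDistribution):
        return pd.DataFrame(
            [
                {"alternative": a, "probability": p}
                for a, p in result.probabilities.items()
            ]
        )
    if isinstance(result, ScenarioResult):
        rows = []
        for condition, dist in result.tables.items():
            for a, p in dist.probabilities.items():
                rows.append(
                    {
                        "scenario": result.name,
                        "condition": condition,
                        "alternative": a,
                        "probability": p,
                        "effect_size": "",
                    }
                )
        for name, value in result.effects.items():
            rows.append(
                {
                    "scenario": result.name,
                    "condition": name,
                    "alternative": "",
                    "probability": "",
                    "effect_size": value,
                }
            )
        return pd.DataFrame(rows)
    raise TypeError(f"cannot tabulate {type(result).__name__}")


def write_results(result, path: str | Path, format: str = "csv") -> None:
    """Write a result as tidy CSV or JSON (6 significant digits; JSON keeps
    parameters and seed for provenance)."""
    from .scenarios import ScenarioResult

    path = Path(path)
    if format == "csv":
        df = results_frame(result)
        num = df.select_dtypes("number").columns
        df[num] = df[num].map(lambda v: float(f"{v:.6g}"))
        df.to_csv(path, index=False)
        return
    if format == "json":
        if isinstance(result, ScenarioResult):
            doc = result.to_dict()
        else:
            doc = {
                "probabilities": result.probabilities,
                "expected_comparisons": result.expected_comparisons,
                "method": result.method,
            }
        path.write_text(json.dumps(doc, indent=2, default=float))
        return
    raise ValueError(f"format must be 'csv' or 'json', got {format!r}")
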