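"""Batch scoring of product tables and category-level summaries.

Reads CSV/TSV product tables into :class:`~fvnlpoints.scorer.ProductRecord`
objects (collecting row-level validation problems instead of silently
dropping rows), scores them under one or more nutrient-profile models, and
summarises the point distribution per TRA category the way food-supply
audits report it (n, mean, SD, min, quartiles, max, plus a TOTAL row).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .categories import CategoryError
from .lexicon import Lexicon
from .models import Model
from .scorer import FvnlScorer, ProductRecord, ScoringConfig

__all__ = [
    "SchemaError",
    "ReadReport",
    "CategorySummary",
    "read_products",
    "score_database",
    "summarize_by_category",
    "summaries_to_frame",
]

# default column names; remap with column_map={"id": "product_code", ...}
DEFAULT_COLUMNS = {
    "id": "id",
    "name": "name",
    "category": "category",
    "ingredients": "ingredients",
    "nutriscore_beverage": "nutriscore_beverage",
    "exclude": "exclude",
}
_MANDATORY = ("id", "category", "ingredients")
_TRUTHY = {"1", "true", "yes", "y", "t"}

# separator between the component ingredient lists of a multi-part product
COMPONENT_SEP = "|"


class SchemaError(ValueError):
    """Raised when a mandatory column is missing from the input table."""


@dataclass
class ReadReport:
    """Row-level outcome of an ingest: errors and exclusions are reported,
    never silently dropped."""

    n_rows: int = 0
    n_valid: int = 0
    errors: list[dict] = None
    excluded: list[str] = None

    def __post_init__(self):
        self.errors = self.errors if self.errors is not None else []
        self.excluded = self.excluded if self.excluded is not None else []

    @property
    def ok(self) -> bool:
        return not self.errors


def _as_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return False
    return str(value).strip().lower() in _TRUTHY


def read_products(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    delimiter: str | None = None,
) -> tuple[list[ProductRecord], ReadReport]:
    """Read a product table into validated records plus a row-level report.

    The delimiter is sniffed between comma and tab unless given explicitly.
    Component lists of multi-part products are separated by ``|`` inside the
    ingredients column.  Rows with the exclusion flag set are counted in the
    report and left out of the scoring set (sample filters such as foods for
    children under 4, meal replacements, drink mixers).
    """
    path = Path(path)
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    if delimiter is None:
        with open(path, "r", encoding="utf-8") as fh:
            head = fh.readline()
        delimiter = "\t" if head.count("\t") >= head.count(",") and "\t" in head else ","
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    missing = [cols[k] for k in _MANDATORY if cols[k] not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")

    report = ReadReport(n_rows=len(df))
    records: list[ProductRecord] = []
    for idx, row in df.iterrows():
        rid = str(row[cols["id"]]).strip()
        if cols["exclude"] in df.columns and _as_bool(row[cols["exclude"]]):
            report.excluded.append(rid)
            continue
        texts = [
            t.strip()
            for t in str(row[cols["ingredients"]]).split(COMPONENT_SEP)
            if t.strip()
        ]
        try:
            rec = ProductRecord(
                id=rid,
                name=str(row.get(cols["name"], "")).strip(),
                tra_category=row[cols["category"]],
                ingredient_texts=texts,
                nutriscore_beverage=(
                    _as_bool(row[cols["nutriscore_beverage"]])
                    if cols["nutriscore_beverage"] in df.columns
                    else False
                ),
            )
        except (CategoryError, ValueError) as exc:
            report.errors.append({"row": int(idx), "id": rid, "error": str(exc)})
            continue
        records.append(rec)
    report.n_valid = len(records)
    return records, report


def score_database(
    records: list[ProductRecord],
    models: list[Model | str],
    lexicon: Lexicon | None = None,
    config: ScoringConfig | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Score every record under every model.

    Returns one output row per record x model, in input order, plus a list of
    JSON-serialisable trace dicts keyed by product id and model.  Per-row
    scoring errors are reported in the trace list with ``"error"`` set, and
    the row carries points ``-1`` so failures are visible, not silent.
    """
    scorer = FvnlScorer(lexicon=lexicon, config=config)
    model_objs = [Model.parse(m) if isinstance(m, str) else Model(m) for m in models]
    rows = []
    traces: list[dict] = []
    for rec in records:
        for model in model_objs:
            trace_id = f"{rec.id}:{model.value}"
            try:
                res = scorer.score_product(rec, model)
            except Exception as exc:  # propagate into the report, keep going
                rows.append(
                    {
                        "product_id": rec.id,
                        "product_name": rec.name,
                        "category": rec.tra_category,
                        "model": model.value,
                        "option_used": "error",
                        "level": "",
                        "points": -1,
                        "trace_id": trace_id,
                    }
                )
                traces.append({"trace_id": trace_id, "error": str(exc)})
                continue
            rows.append(
                {
                    "product_id": rec.id,
                    "product_name": rec.name,
                    "category": rec.tra_category,
                    "model": model.value,
                    "option_used": res.option_used,
                    "level": res.level.value if res.level is not None else "",
                    "points": res.points,
                    "trace_id": trace_id,
                }
            )
            traces.append(
                {
                    "trace_id": trace_id,
                    "product_id": rec.id,
                    "model": model.value,
                    "points": res.points,
                    "trace": res.trace,
                }
            )
    return pd.DataFrame(rows), traces


@dataclass
class CategorySummary:
    """Distribution of points within one TRA category (or TOTAL)."""

    category: str
    n: int
    mean: float
    sd: float
    min: float
    q25: float
    median: float
    q75: float
    max: float


def _summary(points: pd.Series, label: str) -> CategorySummary:
    n = int(points.size)
    sd = float(points.std(ddof=1)) if n > 1 else 0.0
    # quartiles: inclusive linear-interpolation convention
    q25, med, q75 = (float(points.quantile(q)) for q in (0.25, 0.5, 0.75))
    return CategorySummary(
        category=label,
        n=n,
        mean=float(points.mean()),
        sd=sd,
        min=float(points.min()),
        q25=q25,
        median=med,
        q75=q75,
        max=float(points.max()),
    )


def summarize_by_category(
    scored: pd.DataFrame, model: Model | str
) -> list[CategorySummary]:
    """Per-category distribution of points for one model, plus a TOTAL row.

    The sample standard deviation (ddof=1) is reported, 0 for singleton
    categories; quartiles use linear interpolation between order statistics.
    Returns an empty list (with no TOTAL) for empty input.
    """
    model = Model.parse(model) if isinstance(model, str) else Model(model)
    sub = scored[(scored["model"] == model.value) & (scored["points"] >= 0)]
    if sub.empty:
        import warnings

        warnings.warn(f"no scored rows for model {model.value}", stacklevel=2)
        return []
    out = [_summary(sub["points"].astype(float), "TOTAL")]
    for cat in sorted(sub["category"].unique()):
        pts = sub.loc[sub["category"] == cat, "points"].astype(float)
        out.append(_summary(pts, cat))
    return out


def summaries_to_frame(summaries: list[CategorySummary]) -> pd.DataFrame:
    return pd.DataFrame([asdict(s) for s in summaries])


def write_traces(traces: list[dict], path: str | Path) -> None:
    """Write rationale traces as JSON lines keyed by product id and model."""
    with open(path, "w", encoding="utf-8") as fh:
        for t in traces:
            fh.write(json.dumps(t, ensure_ascii=False) + "\n")
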