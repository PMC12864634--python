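"""Study-level data types, log odds ratio effect sizes, and CSV/JSON ingestion.

The whole pipeline runs on per-study log odds ratios ``y`` with standard
errors ``se``.  A study may be supplied either as a 2x2 table of event counts
(events/total per arm) or as a precomputed ``(y, se)`` pair; when counts are
present the effect size is (re)computed with the Woolf formula,

    y  = ln(a d / (b c)),        se = sqrt(1/a + 1/b + 1/c + 1/d),

where ``a = events_treat``, ``b = n_treat - events_treat``,
``c = events_ctrl``, ``d = n_ctrl - events_ctrl``.  A zero cell triggers the
Haldane–Anscombe correction (0.5 added to all four cells) when enabled,
otherwise a :class:`ZeroCellError` is raised.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import pandas as pd

__all__ = [
    "StudyRecord",
    "MetaDataset",
    "MetaInputError",
    "ZeroCellError",
    "DegenerateTableError",
    "SchemaError",
    "log_odds_ratio",
    "back_transform",
    "se_from_ci",
    "read_studies",
    "write_studies",
    "dataset_to_json",
    "dataset_from_json",
]

_WALD_Z = 1.96  # fixed quantile used throughout; matches published-CI extraction
_SCHEMA_VERSION = 1


class MetaInputError(ValueError):
    """Base class for invalid study-level input."""


class ZeroCellError(MetaInputError):
    """A 2x2 cell is zero and the continuity correction is disabled."""


class DegenerateTableError(MetaInputError):
    """An arm has no events and no non-events (n = 0 or double-zero arm)."""


class SchemaError(MetaInputError):
    """A CSV/JSON input does not match the declared schema."""


def log_odds_ratio(
    events_treat: int,
    n_treat: int,
    events_ctrl: int,
    n_ctrl: int,
    correction: bool = True,
) -> tuple[float, float]:
    """Woolf log odds ratio and standard error from a 2x2 table.

    Parameters
    ----------
    events_treat, n_treat, events_ctrl, n_ctrl
        Event and total counts for the treatment and control arms.
    correction
        If true, add 0.5 to all four cells whenever at least one cell is
        zero (Haldane–Anscombe).  If false, a zero cell raises
        :class:`ZeroCellError`.

    Returns
    -------
    (y, se)
        Log odds ratio (treatment vs control) and its standard error.
    """
    for name, ev, n in (
        ("treatment", events_treat, n_treat),
        ("control", events_ctrl, n_ctrl),
    ):
        if n < 1:
            raise DegenerateTableError(f"{name} arm has n = {n} < 1")
        if not 0 <= ev <= n:
            raise MetaInputError(f"{name} arm events {ev} outside [0, {n}]")

    a = float(events_treat)
    b = float(n_treat - events_treat)
    c = float(events_ctrl)
    d = float(n_ctrl - events_ctrl)
    if (a == 0.0 and b == 0.0) or (c == 0.0 and d == 0.0):
        raise DegenerateTableError("an arm has neither events nor non-events")
    if min(a, b, c, d) == 0.0:
        if not correction:
            raise ZeroCellError(
                "2x2 table contains a zero cell; enable the continuity correction"
            )
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    y = math.log(a * d / (b * c))
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    return y, se


def back_transform(y, interval=None):
    """Map log odds ratio values back to the odds ratio scale.

    ``back_transform(-0.40)`` → 0.670 — the componentwise exponential.  When
    ``interval`` (a pair of log-scale bounds) is given, returns
    ``(exp(y), (exp(low), exp(high)))``; the bound ordering is preserved.
    """
    if not math.isfinite(y):
        raise MetaInputError(f"non-finite log odds ratio {y!r}")
    if interval is None:
        return math.exp(y)
    low, high = interval
    if not (math.isfinite(low) and math.isfinite(high)):
        raise MetaInputError("non-finite interval bound")
    return math.exp(y), (math.exp(low), math.exp(high))


def se_from_ci(ci_low: float, ci_high: float) -> float:
    """Standard error recovered from a published 95% CI on the log OR scale.

    se = (upper − lower) / (2 · 1.96), the standard route when only
    confidence intervals are reported alongside the estimate.
    """
    if not (math.isfinite(ci_low) and math.isfinite(ci_high)):
        raise MetaInputError("non-finite CI bound")
    if ci_high <= ci_low:
        raise MetaInputError(f"CI bounds out of order: [{ci_low}, {ci_high}]")
    return (ci_high - ci_low) / (2.0 * _WALD_Z)


@dataclass(frozen=True)
class StudyRecord:
    """One randomized trial: label, publication order, counts and/or (y, se)."""

    label: str
    order_key: int | float | None = None
    events_treat: int | None = None
    n_treat: int | None = None
    events_ctrl: int | None = None
    n_ctrl: int | None = None
    y: float | None = None
    se: float | None = None

    def __post_init__(self):
        counts = (self.events_treat, self.n_treat, self.events_ctrl, self.n_ctrl)
        has_counts = any(v is not None for v in counts)
        if has_counts and any(v is None for v in counts):
            raise MetaInputError(
                f"study {self.label!r}: counts must be given for both arms or not at all"
            )
        if has_counts:
            y_c, se_c = log_odds_ratio(*[int(v) for v in counts], correction=True)
            if self.y is None:
                object.__setattr__(self, "y", y_c)
                object.__setattr__(self, "se", se_c)
            else:
                if abs(self.y - y_c) > 1e-9 or abs((self.se or 0.0) - se_c) > 1e-9:
                    raise MetaInputError(
                        f"study {self.label!r}: supplied (y, se) = "
                        f"({self.y}, {self.se}) disagrees with counts "
                        f"({y_c:.6f}, {se_c:.6f})"
                    )
        if self.y is None or self.se is None:
            raise MetaInputError(
                f"study {self.label!r}: needs 2x2 counts or a (y, se) pair"
            )
        if not (math.isfinite(self.y) and math.isfinite(self.se)):
            raise MetaInputError(f"study {self.label!r}: non-finite effect size")
        if self.se <= 0:
            raise MetaInputError(f"study {self.label!r}: se must be > 0, got {self.se}")

    @property
    def has_counts(self) -> bool:
        return self.events_treat is not None


@dataclass(frozen=True)
class MetaDataset:
    """An ordered collection of studies sharing one binary outcome."""

    studies: tuple[StudyRecord, ...]
    outcome_label: str = "outcome"

    def __post_init__(self):
        object.__setattr__(self, "studies", tuple(self.studies))
        if len(self.studies) < 1:
            raise MetaInputError("a dataset needs at least one study")
        labels = [s.label for s in self.studies]
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise MetaInputError(f"duplicate study labels: {dup}")

    def __len__(self) -> int:
        return len(self.studies)

    def __iter__(self):
        return iter(self.studies)

    @property
    def y(self):
        return [s.y for s in self.studies]

    @property
    def se(self):
        return [s.se for s in self.studies]

    def sorted_by_order_key(self) -> "MetaDataset":
        """Chronological ordering: ascending order_key, ties by input order."""
        missing = [s.label for s in self.studies if s.order_key is None]
        if missing:
            raise MetaInputError(
                f"order_key (year) missing for studies: {missing}"
            )
        idx = sorted(range(len(self.studies)),
                     key=lambda i: (self.studies[i].order_key, i))
        return replace(self, studies=tuple(self.studies[i] for i in idx))

    def prefix(self, k: int) -> "MetaDataset":
        if not 1 <= k <= len(self.studies):
            raise MetaInputError(f"prefix length {k} outside [1, {len(self.studies)}]")
        return replace(self, studies=self.studies[:k])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.studies:
            rows.append({
                "label": s.label, "year": s.order_key,
                "events_treat": s.events_treat, "n_treat": s.n_treat,
                "events_ctrl": s.events_ctrl, "n_ctrl": s.n_ctrl,
                "log_or": s.y, "se": s.se,
            })
        return pd.DataFrame(rows)


_COUNT_COLS = ["label", "year", "events_treat", "n_treat", "events_ctrl", "n_ctrl"]
_EFFECT_COLS = ["label", "year", "log_or"]


def read_studies(path, schema: str, outcome_label: str = "outcome",
                 correction: bool = True) -> MetaDataset:
    """Read a counts or effects CSV into a validated :class:`MetaDataset`.

    ``schema="counts"`` expects columns
    ``label, year, events_treat, n_treat, events_ctrl, n_ctrl``;
    ``schema="effects"`` expects ``label, year, log_or`` plus either ``se`` or
    ``ci_low, ci_high`` (bounds on the log OR scale).  Row order is preserved.
    """
    if schema not in ("counts", "effects"):
        raise SchemaError(f"unknown schema {schema!r}; use 'counts' or 'effects'")
    df = pd.read_csv(path)
    required = list(_COUNT_COLS) if schema == "counts" else list(_EFFECT_COLS)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    use_ci = False
    if schema == "effects":
        if "se" in df.columns:
            required.append("se")
        elif {"ci_low", "ci_high"} <= set(df.columns):
            required += ["ci_low", "ci_high"]
            use_ci = True
        else:
            raise SchemaError(f"{path}: effects schema needs 'se' or 'ci_low'/'ci_high'")
    extra = [c for c in df.columns if c not in required]
    if extra:
        raise SchemaError(f"{path}: unexpected columns {extra}")

    studies = []
    for i, row in df.iterrows():
        try:
            numeric = {c: row[c] for c in required if c not in ("label", "year")}
            for c, v in numeric.items():
                if pd.isna(v) or not math.isfinite(float(v)):
                    raise MetaInputError(f"non-numeric value in column {c!r}")
            year = None if pd.isna(row["year"]) else float(row["year"])
            if year is not None and year == int(year):
                year = int(year)
            if schema == "counts":
                counts = [int(row[c]) for c in _COUNT_COLS[2:]]
                for c, v in zip(_COUNT_COLS[2:], counts):
                    if float(row[c]) != v:
                        raise MetaInputError(f"column {c!r} is not an integer count")
                y, se = log_odds_ratio(*counts, correction=correction)
                studies.append(StudyRecord(str(row["label"]), year, *counts,
                                           y=y, se=se))
            else:
                se = (se_from_ci(float(row["ci_low"]), float(row["ci_high"]))
                      if use_ci else float(row["se"]))
                studies.append(StudyRecord(str(row["label"]), year,
                                           y=float(row["log_or"]), se=se))
        except (MetaInputError, ValueError, TypeError) as exc:
            raise SchemaError(f"{path}, row {i}: {exc}") from exc
    try:
        return MetaDataset(tuple(studies), outcome_label=outcome_label)
    except MetaInputError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def write_studies(dataset: MetaDataset, path, schema: str = "effects") -> None:
    """Write a dataset back to CSV in a schema ``read_studies`` accepts."""
    if schema == "counts":
        if not all(s.has_counts for s in dataset):
            raise SchemaError("counts schema requested but some studies lack counts")
        df = dataset.to_frame()[_COUNT_COLS]
    elif schema == "effects":
        df = dataset.to_frame()[["label", "year", "log_or", "se"]]
    else:
        raise SchemaError(f"unknown schema {schema!r}")
    df.to_csv(path, index=False)


def dataset_to_json(dataset: MetaDataset) -> str:
    """Serialize a dataset to versioned JSON."""
    payload = {
        "schema_version": _SCHEMA_VERSION,
        "outcome_label": dataset.outcome_label,
        "studies": [
            {
                "label": s.label, "order_key": s.order_key,
                "events_treat": s.events_treat, "n_treat": s.n_treat,
                "events_ctrl": s.events_ctrl, "n_ctrl": s.n_ctrl,
                "y": s.y, "se": s.se,
            }
            for s in dataset
        ],
    }
    return json.dumps(payload, sort_keys=True)


def dataset_from_json(text: str) -> MetaDataset:
    payload = json.loads(text)
    if payload.get("schema_version") != _SCHEMA_VERSION:
        raise SchemaError(
            f"unsupported dataset schema version {payload.get('schema_version')!r}"
        )
    studies = tuple(StudyRecord(**rec) for rec in payload["studies"])
    return MetaDataset(studies, outcome_label=payload["outcome_label"])
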