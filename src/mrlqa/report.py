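"""Longitudinal QA bookkeeping: tolerance evaluation, drift estimation,
change-point flagging, and deterministic report serialization.

Tolerance strictness follows the printed operator: ``"> 59"`` and ``"< 47"``
are strict, ``">="``/``"<="`` include the boundary, and intervals like
``"4.65-5.15"`` are closed.  Trends are ordinary least-squares fits of the
(optionally baseline-normalized) metric on the session date, annualized by
365.25 days/year.  Sustained shifts are flagged with a tabular CUSUM against
the baseline of the first 30 sessions.
"""

from __future__ import annotations

import datetime as _dt
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ToleranceSpec",
    "QARecord",
    "TrendResult",
    "ConfigError",
    "evaluate_tolerance",
    "fit_trend",
    "render_report",
    "records_to_csv",
    "records_from_csv",
]


class ConfigError(ValueError):
    """Malformed tolerance specification or record log."""


_INTERVAL_RE = re.compile(
    r"^\s*([-+]?\d*\.?\d+)\s*[-–—]\s*([-+]?\d*\.?\d+)\s*$"
)
_BOUND_RE = re.compile(r"^\s*(>=|<=|>|<)\s*([-+]?\d*\.?\d+)\s*$")


@dataclass(frozen=True)
class ToleranceSpec:
    """One-sided bound or closed interval on a QA metric."""

    op: str  # "gt" | "ge" | "lt" | "le" | "interval"
    low: float = None
    high: float = None

    @classmethod
    def parse(cls, spec) -> "ToleranceSpec":
        if isinstance(spec, ToleranceSpec):
            return spec
        if isinstance(spec, (tuple, list)) and len(spec) == 2:
            lo, hi = float(spec[0]), float(spec[1])
            if not lo <= hi:
                raise ConfigError("interval bounds out of order")
            return cls("interval", lo, hi)
        if isinstance(spec, dict):
            return cls(spec["op"], spec.get("low"), spec.get("high"))
        if isinstance(spec, str):
            m = _BOUND_RE.match(spec)
            if m:
                op = {">": "gt", ">=": "ge", "<": "lt", "<=": "le"}[m.group(1)]
                v = float(m.group(2))
                return cls(op, low=v if op in ("gt", "ge") else None,
                           high=v if op in ("lt", "le") else None)
            m = _INTERVAL_RE.match(spec)
            if m:
                lo, hi = float(m.group(1)), float(m.group(2))
                if not lo <= hi:
                    raise ConfigError("interval bounds out of order")
                return cls("interval", lo, hi)
        raise ConfigError(f"cannot parse tolerance spec {spec!r}")

    def check(self, value: float) -> bool:
        if self.op == "gt":
            return value > self.low
        if self.op == "ge":
            return value >= self.low
        if self.op == "lt":
            return value < self.high
        if self.op == "le":
            return value <= self.high
        if self.op == "interval":
            return self.low <= value <= self.high
        raise ConfigError(f"unknown tolerance operator {self.op!r}")

    def as_text(self) -> str:
        sym = {"gt": ">", "ge": ">=", "lt": "<", "le": "<="}
        if self.op == "interval":
            return f"{self.low}-{self.high}"
        bound = self.low if self.op in ("gt", "ge") else self.high
        return f"{sym[self.op]} {bound}"


@dataclass
class QARecord:
    """One dated QA measurement with its tolerance verdict."""

    date: _dt.date
    metric: str
    value: float
    units: str = ""
    tolerance: ToleranceSpec = None
    passed: bool = None
    context: dict = field(default_factory=dict)

    def __post_init__(self):
        if isinstance(self.date, str):
            self.date = _dt.date.fromisoformat(self.date)
        if self.tolerance is not None:
            ok = self.tolerance.check(self.value)
            if self.passed is not None and self.passed != ok:
                raise ConfigError("stored pass flag contradicts the tolerance")
            self.passed = ok


@dataclass
class TrendResult:
    slope_per_day: float
    slope_per_year: float
    intercept: float
    cov_percent: float
    changepoints: list
    normalized: bool


def evaluate_tolerance(
    value: float, tolerance_spec, metric: str = "", date=None, units: str = "", context=None
) -> QARecord:
    """Evaluate a value against its tolerance and return the QA record.

    Boundary handling is exactly as printed: strict for ``>``/``<``,
    inclusive for ``>=``/``<=`` and for interval specs.
    """
    tol = ToleranceSpec.parse(tolerance_spec)
    return QARecord(
        date=date or _dt.date.today(),
        metric=metric,
        value=float(value),
        units=units,
        tolerance=tol,
        context=context or {},
    )


def _cusum_changepoints(values: np.ndarray, dates, baseline_n: int = 30, h_sigma: float = 4.0,
                        k_sigma: float = 0.5) -> list:
    n = len(values)
    nb = min(baseline_n, max(3, n // 2))
    mu = values[:nb].mean()
    sd = values[:nb].std(ddof=1)
    if sd == 0:
        sd = np.finfo(float).eps
    sp = sn = 0.0
    flagged = []
    armed = True
    for i in range(n):
        z = values[i] - mu
        sp = max(0.0, sp + z - k_sigma * sd)
        sn = max(0.0, sn - z - k_sigma * sd)
        if armed and (sp > h_sigma * sd or sn > h_sigma * sd):
            flagged.append(dates[i])
            armed = False  # one flag per sustained shift
        elif sp == 0.0 and sn == 0.0:
            armed = True
    return flagged


def fit_trend(series: list, normalize: bool = False, baseline_n: int = 30) -> TrendResult:
    """Linear drift of a dated QA series.

    With ``normalize`` the series is expressed as percent of its first
    (baseline) value, so the annualized slope reads directly as %/year.
    Change-points are sustained shifts exceeding 4 sigma of the baseline
    (first ``baseline_n`` sessions) under a tabular CUSUM.
    """
    if len(series) < 3:
        raise ConfigError("trend fitting needs at least three dated records")
    recs = sorted(series, key=lambda r: r.date)
    dates = [r.date for r in recs]
    t_days = np.array([(d - dates[0]).days for d in dates], dtype=float)
    if np.all(t_days == t_days[0]):
        raise ConfigError("all records share one date; trend undefined")
    y = np.array([r.value for r in recs], dtype=float)
    if normalize:
        if y[0] == 0:
            raise ConfigError("cannot normalize to a zero baseline value")
        y = y / y[0] * 100.0
    slope, intercept = np.polyfit(t_days, y, 1)
    mu = y.mean()
    cov = float(y.std(ddof=1) / abs(mu) * 100.0) if mu != 0 else float("inf")
    cps = _cusum_changepoints(y, dates, baseline_n=baseline_n)
    return TrendResult(
        slope_per_day=float(slope),
        slope_per_year=float(slope * 365.25),
        intercept=float(intercept),
        cov_percent=cov,
        changepoints=cps,
        normalized=normalize,
    )


# -- serialization -----------------------------------------------------------

_CSV_COLUMNS = ["date", "metric", "value", "units", "tolerance", "passed", "context"]


def records_to_csv(records: list, path: str | Path) -> Path:
    rows = [
        {
            "date": r.date.isoformat(),
            "metric": r.metric,
            "value": repr(float(r.value)),
            "units": r.units,
            "tolerance": r.tolerance.as_text() if r.tolerance else "",
            "passed": "" if r.passed is None else str(bool(r.passed)),
            "context": json.dumps(r.context, sort_keys=True),
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=_CSV_COLUMNS)
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def records_from_csv(path: str | Path) -> list:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    records = []
    for _, row in df.iterrows():
        tol = ToleranceSpec.parse(row["tolerance"]) if row["tolerance"] else None
        records.append(
            QARecord(
                date=row["date"],
                metric=row["metric"],
                value=float(row["value"]),
                units=row["units"],
                tolerance=tol,
                context=json.loads(row["context"]) if row["context"] else {},
            )
        )
    return records


def render_report(records: list, trends: dict | None = None, path: str | Path | None = None) -> dict:
    """Assemble (and optionally write) the QA report.

    The JSON serialization is canonical — sorted keys, repr floats — so the
    same inputs always produce byte-identical output.
    """
    trends = trends or {}
    failures = [
        {"date": r.date.isoformat(), "metric": r.metric, "value": r.value,
         "tolerance": r.tolerance.as_text() if r.tolerance else ""}
        for r in records
        if r.passed is False
    ]
    report = {
        "n_records": len(records),
        "n_failures": len(failures),
        "failures": failures,
        "records": [
            {
                "date": r.date.isoformat(),
                "metric": r.metric,
                "value": r.value,
                "units": r.units,
                "tolerance": r.tolerance.as_text() if r.tolerance else "",
                "passed": r.passed,
                "context": r.context,
            }
            for r in records
        ],
        "trends": {
            name: {
                "slope_per_day": t.slope_per_day,
                "slope_per_year": t.slope_per_year,
                "intercept": t.intercept,
                "cov_percent": t.cov_percent,
                "changepoints": [d.isoformat() for d in t.changepoints],
                "normalized": t.normalized,
            }
            for name, t in trends.items()
        },
    }
    if path is not None:
        Path(path).write_text(json.dumps(report, sort_keys=True, indent=1))
    return report
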