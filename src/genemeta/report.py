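"""Pipeline orchestration and machine-readable reporting.

:func:`run_pipeline` takes a validated study table through every stage - HWE
per study, per-study effects, total pooling under the heterogeneity-threshold
rule, each requested stratification, both publication-bias tests and
leave-one-out sensitivity - for each requested genetic model, and returns an
:class:`AnalysisReport` that serializes to deterministic JSON (no timestamps).

Display rounding is half-up at 2 decimals for ORs/CIs and 3 for P-values;
full-precision values always travel alongside the display strings, so
rounding never destroys information.  No multiple-testing adjustment is
applied; all P-values are raw.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .bias import begg_test, egger_test, leave_one_out, study_tables, subgroup_analysis
from .contrasts import allele_frequency, hwe_test
from .errors import GenemetaError
from .models import (
    BiasMethod,
    BiasTestResult,
    EffectEstimate,
    GeneticModel,
    HeterogeneityResult,
    HWETestResult,
    LeaveOneOutResult,
    ModelChoice,
    PooledResult,
    PoolMethod,
    StudyTable,
)
from .pooling import pool_auto, q_test, select_model, study_effect

__all__ = [
    "AnalysisReport",
    "run_pipeline",
    "render_tables",
    "report_to_json",
    "report_from_json",
    "validate_report_dict",
    "forest_frame",
    "funnel_frame",
    "fmt_or_ci",
    "fmt_p",
]

logger = logging.getLogger("genemeta")

DEFAULT_SUBGROUP_KEYS = ("design", "country", "size_class", "gc_type")
ALL_MODELS = tuple(GeneticModel)


def _round_half_up(x: float, places: int) -> str:
    q = Decimal(1).scaleb(-places)
    return str(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def fmt_or_ci(or_: float, lo: float, hi: float) -> str:
    """Render ``OR(low-high)`` at 2 decimals, half-up - the table style."""
    return f"{_round_half_up(or_, 2)}({_round_half_up(lo, 2)}-{_round_half_up(hi, 2)})"


def fmt_p(p: float) -> str:
    """Render a P-value at 3 decimals, half-up (0.0004 prints as 0.000)."""
    return _round_half_up(p, 3)


@dataclass(frozen=True)
class AnalysisReport:
    """Machine twin of the result tables of a full meta-analysis run."""

    metadata: dict
    subjects: dict
    maf: dict
    hwe: dict  # study_id -> HWETestResult
    effects: dict  # model name -> tuple[EffectEstimate, ...]
    results: dict  # model name -> {"total": PooledResult, "subgroups": {key: {stratum: PooledResult}}}
    bias: dict  # model name -> {"egger": BiasTestResult | error dict, "begg": ...}
    sensitivity: dict  # model name -> tuple[LeaveOneOutResult, ...] | error dict


def run_pipeline(
    table: StudyTable,
    models: Sequence[GeneticModel] = ALL_MODELS,
    subgroup_keys: Sequence[str] = DEFAULT_SUBGROUP_KEYS,
    het_threshold: float = 0.10,
    cc_increment: float = 0.5,
) -> AnalysisReport:
    """Run the complete analysis; deterministic for fixed input and settings."""
    if len(table) == 0:
        raise GenemetaError("cannot analyse an empty study table")

    case_pool = table.pooled_case_counts()
    ctrl_rows = table.pooled_control_counts(deduplicate_shared=False)
    ctrl_uni = table.pooled_control_counts(deduplicate_shared=True)
    subjects = {
        "cases": table.case_total(),
        "controls_rows": table.control_total(deduplicate_shared=False),
        "controls_unique": table.control_total(deduplicate_shared=True),
    }
    maf = {
        "case_t": allele_frequency(case_pool, "T"),
        "control_t_rows": allele_frequency(ctrl_rows, "T"),
        "control_t_unique": allele_frequency(ctrl_uni, "T"),
    }
    hwe = {r.study_id: hwe_test(r.control) for r in table.records}

    effects_by_model: dict[str, tuple] = {}
    results: dict[str, dict] = {}
    bias: dict[str, dict] = {}
    sensitivity: dict[str, object] = {}

    for model in models:
        tabs = study_tables(table, model)
        effects = tuple(study_effect(t, cc_increment) for t in tabs)
        effects_by_model[model.name] = effects
        het = q_test(effects)
        choice = select_model(het, het_threshold)
        logger.info(
            "model %s, stratum total: P_h = %.4g -> %s effects",
            model.name,
            het.p_h,
            choice.value,
        )
        total = pool_auto(tabs, het_threshold, cc_increment, stratum="total")
        subgroups: dict[str, dict] = {}
        for key in subgroup_keys:
            per_key = subgroup_analysis(table, key, model, het_threshold, cc_increment)
            for stratum, pooled in per_key.items():
                logger.info(
                    "model %s, %s = %s: k = %d, P_h = %.4g -> %s",
                    model.name,
                    key,
                    stratum,
                    pooled.k,
                    pooled.het.p_h,
                    pooled.method.name,
                )
            subgroups[key] = per_key
        results[model.name] = {"total": total, "subgroups": subgroups}

        bias[model.name] = {}
        for name, test in (("egger", egger_test), ("begg", begg_test)):
            try:
                bias[model.name][name] = test(effects)
            except GenemetaError as exc:
                bias[model.name][name] = {"error": str(exc)}
        try:
            sensitivity[model.name] = tuple(
                leave_one_out(table, model, het_threshold, cc_increment)
            )
        except GenemetaError as exc:
            sensitivity[model.name] = {"error": str(exc)}

    metadata = {
        "provenance": table.provenance,
        "package_version": __version__,
        "settings": {
            "models": [m.name for m in models],
            "subgroup_keys": list(subgroup_keys),
            "het_threshold": het_threshold,
            "cc_increment": cc_increment,
        },
        "notes": "P-values are raw; no multiple-testing adjustment applied.",
    }
    return AnalysisReport(
        metadata=metadata,
        subjects=subjects,
        maf=maf,
        hwe=hwe,
        effects=effects_by_model,
        results=results,
        bias=bias,
        sensitivity=sensitivity,
    )


# ---------------------------------------------------------------------------
# serialization

def _enc(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        d = {f.name: _enc(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        d["__type__"] = type(obj).__name__
        return d
    if isinstance(obj, (GeneticModel, PoolMethod, ModelChoice, BiasMethod)):
        return {"__enum__": type(obj).__name__, "name": obj.name}
    if isinstance(obj, dict):
        return {k: _enc(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_enc(v) for v in obj]
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


_TYPES = {
    "HWETestResult": HWETestResult,
    "EffectEstimate": EffectEstimate,
    "HeterogeneityResult": HeterogeneityResult,
    "PooledResult": PooledResult,
    "BiasTestResult": BiasTestResult,
    "LeaveOneOutResult": LeaveOneOutResult,
}
_ENUMS = {
    "GeneticModel": GeneticModel,
    "PoolMethod": PoolMethod,
    "ModelChoice": ModelChoice,
    "BiasMethod": BiasMethod,
}


def _dec(obj):
    if isinstance(obj, dict):
        if "__enum__" in obj:
            return _ENUMS[obj["__enum__"]][obj["name"]]
        if "__type__" in obj:
            cls = _TYPES[obj["__type__"]]
            kwargs = {k: _dec(v) for k, v in obj.items() if k != "__type__"}
            return cls(**kwargs)
        return {k: _dec(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_dec(v) for v in obj]
    return obj


def report_to_dict(report: AnalysisReport) -> dict:
    return _enc(report) | {"__type__": "AnalysisReport"}


def report_to_json(report: AnalysisReport, validate: bool = True) -> str:
    """Serialize to deterministic JSON (sorted keys, no timestamps)."""
    d = report_to_dict(report)
    if validate:
        validate_report_dict(d)
    return json.dumps(d, indent=2, sort_keys=True)


def _retuple(x):
    """Effects/sensitivity sequences are tuples on the dataclass."""
    return {k: tuple(v) if isinstance(v, list) else v for k, v in x.items()}


def report_from_json(text: str) -> AnalysisReport:
    d = json.loads(text)
    if d.get("__type__") != "AnalysisReport":
        raise GenemetaError("not an AnalysisReport JSON document")
    body = {k: _dec(v) for k, v in d.items() if k != "__type__"}
    body["effects"] = _retuple(body["effects"])
    body["sensitivity"] = _retuple(body["sensitivity"])
    return AnalysisReport(**body)


def _schema() -> dict:
    ref = resources.files("genemeta.data").joinpath("report_schema.json")
    return json.loads(ref.read_text(encoding="utf-8"))


def _check(node, schema, path):
    types = {
        "object": dict,
        "array": list,
        "string": str,
        "number": (int, float),
        "integer": int,
        "boolean": bool,
    }
    t = schema.get("type")
    if t is not None:
        allowed = tuple(
            c for name in ([t] if isinstance(t, str) else t) for c in (
                types[name] if isinstance(types[name], tuple) else (types[name],)
            )
        )
        if node is None:
            if "null" not in ([t] if isinstance(t, str) else t):
                raise GenemetaError(f"report schema: {path} must not be null")
        elif not isinstance(node, allowed) or isinstance(node, bool) and bool not in allowed:
            raise GenemetaError(f"report schema: {path} has wrong type {type(node).__name__}")
    if isinstance(node, dict):
        for req in schema.get("required", []):
            if req not in node:
                raise GenemetaError(f"report schema: {path} missing required key {req!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in node:
                _check(node[key], sub, f"{path}.{key}")
    if isinstance(node, list) and "items" in schema:
        for i, item in enumerate(node):
            _check(item, schema["items"], f"{path}[{i}]")


def validate_report_dict(d: dict) -> None:
    """Structural validation of a serialized report against the shipped schema.

    Checks the subset of JSON-schema this package uses (type/required/
    properties/items); raises :class:`GenemetaError` on the first violation.
    """
    _check(d, _schema(), "$")


# ---------------------------------------------------------------------------
# table / export rendering

def render_tables(report: AnalysisReport) -> str:
    """Delimited text, one row per (stratum, model): OR(CI), P_h, P.

    Mirrors the layout of a stratified meta-analysis results table: the total
    row first, then each stratification key's strata in first-seen order.
    """
    cols = ["stratum_key", "stratum", "model", "k", "method", "or_ci", "p_h", "p"]
    lines = ["\t".join(cols)]

    def row(stratum_key: str, stratum: str, model_name: str, pooled: PooledResult):
        p_h = "-" if pooled.k == 1 else fmt_p(pooled.het.p_h)
        lines.append(
            "\t".join(
                [
                    stratum_key,
                    stratum,
                    model_name,
                    str(pooled.k),
                    pooled.method.name,
                    fmt_or_ci(pooled.or_, pooled.ci_low, pooled.ci_high),
                    p_h,
                    fmt_p(pooled.p),
                ]
            )
        )

    for model_name, res in report.results.items():
        row("total", "total", model_name, res["total"])
    for model_name, res in report.results.items():
        for key, strata in res["subgroups"].items():
            for stratum, pooled in strata.items():
                row(key, stratum, model_name, pooled)
    return "\n".join(lines) + "\n"


def forest_frame(report: AnalysisReport, model: GeneticModel) -> pd.DataFrame:
    """Forest-plot data: per-study rows then the pooled row, input order.

    ``weight_pct`` is the percentage weight under the method the selection
    rule chose (DL weights for random effects, inverse-variance weights
    otherwise).
    """
    effects = report.effects[model.name]
    total: PooledResult = report.results[model.name]["total"]
    tau2 = total.het.tau2 if total.method is PoolMethod.DL_RANDOM else 0.0
    w = np.array([1.0 / (e.se**2 + tau2) for e in effects])
    weight_pct = 100.0 * w / w.sum()
    rows = [
        {
            "stratum": total.stratum,
            "study_id": e.study_id,
            "model": model.name,
            "or": e.or_,
            "ci_low": e.ci_low,
            "ci_high": e.ci_high,
            "weight_pct": float(wp),
            "pooled": False,
        }
        for e, wp in zip(effects, weight_pct)
    ]
    rows.append(
        {
            "stratum": total.stratum,
            "study_id": "POOLED",
            "model": model.name,
            "or": total.or_,
            "ci_low": total.ci_low,
            "ci_high": total.ci_high,
            "weight_pct": 100.0,
            "pooled": True,
        }
    )
    return pd.DataFrame(rows)


def funnel_frame(report: AnalysisReport, model: GeneticModel) -> pd.DataFrame:
    """Funnel-plot data (study_id, log_or, se, precision) for a model."""
    effects = report.effects[model.name]
    return pd.DataFrame(
        {
            "study_id": [e.study_id for e in effects],
            "log_or": [e.log_or for e in effects],
            "se": [e.se for e in effects],
            "precision": [1.0 / e.se for e in effects],
        }
    )
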