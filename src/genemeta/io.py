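"""Reading, writing and validating study tables.

The canonical interchange format is a delimited text table with one row per
case-control study and a header naming at least the :data:`REQUIRED_COLUMNS`.
Commas are canonical; a tab-delimited dialect is auto-detected by sniffing the
header line.  Unknown extra columns survive a read/write round trip as opaque
per-study metadata.

A 14-study gastric-cancer dataset for PRKAA1 rs13361707 (C/T) ships with the
package and is returned by :func:`bundled_fixture`; two of its rows reuse one
control series of 3,227 subjects and are marked with a common
``shared_control_key`` so subject-level summaries can count them once.
"""

from __future__ import annotations

import io as _io
from importlib import resources
from pathlib import Path
from typing import IO, Sequence, Union

import pandas as pd

from .contrasts import hwe_test
from .errors import DegenerateHWEError, SchemaError, ValidationError
from .models import GenotypeCounts, StudyRecord, StudyTable, ValidationIssue

__all__ = [
    "REQUIRED_COLUMNS",
    "CANONICAL_COLUMNS",
    "read_study_table",
    "write_study_table",
    "bundled_fixture",
    "validate_table",
]

COUNT_COLUMNS = (
    "case_tt",
    "case_tc",
    "case_cc",
    "control_tt",
    "control_tc",
    "control_cc",
)

REQUIRED_COLUMNS = (
    "study_id",
    "author",
    "year",
    "country",
    "design",
    "size_class",
) + COUNT_COLUMNS

#: Full column set emitted by :func:`write_study_table`, in order.
CANONICAL_COLUMNS = (
    "study_id",
    "author",
    "year",
    "country",
    "design",
    "size_class",
    "gc_type",
    "genotyping_method",
    "nos",
    "case_tt",
    "case_tc",
    "case_cc",
    "control_tt",
    "control_tc",
    "control_cc",
    "shared_control_key",
)

Source = Union[str, Path, IO[str]]


def _sniff_sep(source: Source) -> tuple[str, str]:
    """Return (text, separator); separator is tab iff the header contains one."""
    if hasattr(source, "read"):
        text = source.read()  # type: ignore[union-attr]
    else:
        text = Path(source).read_text(encoding="utf-8")
    header = text.splitlines()[0] if text else ""
    return text, ("\t" if "\t" in header else ",")


def _parse_count(value: str, row: str, column: str) -> int:
    try:
        n = int(str(value).strip())
    except (TypeError, ValueError):
        raise ValidationError(
            f"row {row!r}, column {column!r}: expected a nonnegative integer, got {value!r}"
        ) from None
    if n < 0:
        raise ValidationError(
            f"row {row!r}, column {column!r}: count must be >= 0, got {n}"
        )
    return n


def _opt(value) -> str:
    """Normalise a possibly-missing cell to a string ('' = missing)."""
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return ""
    return str(value).strip()


def read_study_table(source: Source) -> StudyTable:
    """Parse a delimited study table into a :class:`StudyTable`.

    Raises
    ------
    SchemaError
        If a required column is absent from the header.
    ValidationError
        For non-integer or negative counts, or duplicate study ids.
    """
    text, sep = _sniff_sep(source)
    provenance = str(source) if not hasattr(source, "read") else "stream"
    df = pd.read_csv(_io.StringIO(text), sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    extras = [c for c in df.columns if c not in CANONICAL_COLUMNS]
    records = []
    for _, row in df.iterrows():
        sid = str(row["study_id"]).strip()
        counts = {c: _parse_count(row[c], sid, c) for c in COUNT_COLUMNS}
        try:
            year = int(str(row["year"]).strip())
        except ValueError:
            raise ValidationError(f"row {sid!r}: year must be an integer, got {row['year']!r}") from None
        nos_raw = _opt(row["nos"]) if "nos" in df.columns else ""
        records.append(
            StudyRecord(
                study_id=sid,
                author=str(row["author"]).strip(),
                year=year,
                country=str(row["country"]).strip(),
                design=str(row["design"]).strip(),
                size_class=str(row["size_class"]).strip(),
                gc_type=_opt(row["gc_type"]) if "gc_type" in df.columns else "NA",
                genotyping_method=(_opt(row["genotyping_method"]) or None)
                if "genotyping_method" in df.columns
                else None,
                nos=int(nos_raw) if nos_raw else None,
                case=GenotypeCounts(counts["case_tt"], counts["case_tc"], counts["case_cc"]),
                control=GenotypeCounts(
                    counts["control_tt"], counts["control_tc"], counts["control_cc"]
                ),
                shared_control_key=(_opt(row["shared_control_key"]) or None)
                if "shared_control_key" in df.columns
                else None,
                extra={c: _opt(row[c]) for c in extras},
            )
        )
    return StudyTable(records=tuple(records), provenance=provenance)


def write_study_table(table: StudyTable, sink: Source, sep: str = ",") -> None:
    """Write a study table with the canonical column set in canonical order.

    Extra metadata columns, if any, are appended after the canonical ones so
    the write/read cycle is lossless.
    """
    extra_cols: list[str] = []
    for rec in table.records:
        for c in rec.extra:
            if c not in extra_cols:
                extra_cols.append(c)
    rows = []
    for rec in table.records:
        row = {
            "study_id": rec.study_id,
            "author": rec.author,
            "year": rec.year,
            "country": rec.country,
            "design": rec.design,
            "size_class": rec.size_class,
            "gc_type": rec.gc_type,
            "genotyping_method": rec.genotyping_method or "",
            "nos": "" if rec.nos is None else rec.nos,
            "case_tt": rec.case.tt,
            "case_tc": rec.case.tc,
            "case_cc": rec.case.cc,
            "control_tt": rec.control.tt,
            "control_tc": rec.control.tc,
            "control_cc": rec.control.cc,
            "shared_control_key": rec.shared_control_key or "",
        }
        for c in extra_cols:
            row[c] = rec.extra.get(c, "")
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS) + extra_cols)
    if hasattr(sink, "write"):
        df.to_csv(sink, sep=sep, index=False)
    else:
        df.to_csv(Path(sink), sep=sep, index=False, encoding="utf-8")


def bundled_fixture() -> StudyTable:
    """The bundled 14-study PRKAA1 rs13361707 gastric-cancer dataset.

    14,485 cases; 18,019 control rows of which 14,792 are unique subjects
    (the two Shi sub-studies share one 3,227-control series).
    """
    ref = resources.files("genemeta.data").joinpath("table1.csv")
    with ref.open("r", encoding="utf-8") as fh:
        table = read_study_table(fh)
    return StudyTable(records=table.records, provenance="fixture")


def validate_table(
    table: StudyTable, hwe_alpha: float = 0.05
) -> list[ValidationIssue]:
    """Structural and genetic sanity checks, returned as a report.

    Errors: empty case or control groups.  Warnings: control genotype
    distributions departing from Hardy-Weinberg equilibrium at ``hwe_alpha``
    (a conventional genotyping-quality flag), and rows that reuse a shared
    control series (those subjects are double-counted in naive row sums).
    Duplicate study ids are rejected earlier, at :class:`StudyTable`
    construction.
    """
    issues: list[ValidationIssue] = []
    for rec in table.records:
        if rec.case.n == 0:
            issues.append(ValidationIssue("error", rec.study_id, "empty case group"))
        if rec.control.n == 0:
            issues.append(ValidationIssue("error", rec.study_id, "empty control group"))
            continue
        try:
            hwe = hwe_test(rec.control)
        except DegenerateHWEError:
            issues.append(
                ValidationIssue(
                    "warning", rec.study_id, "monomorphic control group; HWE untestable"
                )
            )
        else:
            if hwe.p < hwe_alpha:
                issues.append(
                    ValidationIssue(
                        "warning",
                        rec.study_id,
                        f"controls depart from HWE (P = {hwe.p:.3g} < {hwe_alpha})",
                    )
                )
        if rec.shared_control_key:
            issues.append(
                ValidationIssue(
                    "warning",
                    rec.study_id,
                    f"reuses control series {rec.shared_control_key!r}; "
                    "subjects are double-counted in row sums",
                )
            )
    # shared keys must point at identical control series
    by_key: dict[str, GenotypeCounts] = {}
    for rec in table.records:
        if not rec.shared_control_key:
            continue
        prev = by_key.setdefault(rec.shared_control_key, rec.control)
        if prev != rec.control:
            issues.append(
                ValidationIssue(
                    "error",
                    rec.study_id,
                    f"control counts differ from other rows sharing key {rec.shared_control_key!r}",
                )
            )
    return issues
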