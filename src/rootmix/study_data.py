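"""Data model, validation and CSV I/O for root-sample isotope studies.

The study design follows a long-term field trial in which maize root samples
were cored from 12 plots (3 management treatments x 4 field blocks) at three
soil depths with two coring methods that define distinct sample streams:

* Humax cores: taken within and between maize rows, roots pooled over size
  (>0.5 mm), extraneous organic matter (EOM) removed by hand.
* Puerckhauer cores: taken within rows only, roots split into coarse (>2 mm)
  and fine (0.5-2 mm) classes, no EOM exclusion.

Every measured record carries a calibrated delta13C value (per mil vs V-PDB)
that the mixing stage partitions into recent-crop root C versus EOM C.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

log = logging.getLogger("rootmix")

# ---------------------------------------------------------------------------
# Factor levels
# ---------------------------------------------------------------------------

TREATMENTS = ("BIOORG1", "BIOORG2", "CONFYM2")
BLOCKS = (1, 2, 3, 4)
#: Depth labels and the meter ranges they denote; depth is analyzed as a
#: factor, never as a numeric midpoint.
DEPTHS = ("D1", "D2", "D3")
DEPTH_RANGES_M = {"D1": (0.0, 0.25), "D2": (0.25, 0.5), "D3": (0.5, 0.75)}
POSITIONS = ("row", "inter_row")
METHODS = ("humax", "puerckhauer")
SIZE_CLASSES = ("pooled", "coarse", "fine")

#: Hard validity window for calibrated delta13C (per mil vs V-PDB); terrestrial
#: plant material lies well inside it, values outside indicate data corruption.
DELTA13C_WINDOW = (-40.0, 0.0)

#: Columns of the samples CSV, in order.
SAMPLE_COLUMNS = (
    "sample_id", "plot_id", "treatment", "block", "depth", "position",
    "method", "size_class", "eom_excluded", "delta13c", "dry_mass",
    "c_concentration",
)
REFERENCE_COLUMNS = ("sample_id", "plot_id", "treatment", "delta13c")

SCHEMA_VERSION = "1"

# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------


class RootmixError(Exception):
    """Base class for all package errors."""


class SchemaError(RootmixError):
    """Input file does not match the documented schema."""


class RowParseError(RootmixError):
    """A data row could not be parsed into a valid record."""


class IntegrityError(RootmixError):
    """Table-level integrity violation (e.g. duplicate design key)."""


class InsufficientDataError(RootmixError):
    """Too few values for the requested estimate."""


class DegenerateSelectionError(RootmixError):
    """A selection rule returned an empty or degenerate subset."""


class DegenerateEndmemberError(RootmixError):
    """Endmember separation too small for a stable mixing fraction."""


class GroupingError(RootmixError):
    """Invalid grouping for a between-group test."""


class WeightingError(RootmixError):
    """Invalid weights for a weighted average."""


class DesignError(RootmixError):
    """Factorial design requirement violated (empty cell, single level)."""


class SpecificationError(RootmixError):
    """Unknown factor or malformed analysis request."""


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IsotopeSample:
    """One measured (or derived) root-sample record.

    ``derived`` marks records synthesized downstream (e.g. mass-weighted
    pooled Puerckhauer records); method/size-class coupling rules apply to
    measured records only.
    """

    sample_id: str
    plot_id: str
    treatment: str
    block: int
    depth: str
    position: str
    method: str
    size_class: str
    eom_excluded: bool
    delta13c: float
    dry_mass: float | None = None
    c_concentration: float | None = None
    derived: bool = False

    def design_key(self) -> tuple:
        return (self.plot_id, self.depth, self.method, self.position,
                self.size_class)


@dataclass
class SampleTable:
    """A validated collection of :class:`IsotopeSample` records."""

    records: list[IsotopeSample]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        """Design factors and measurements as a pandas DataFrame."""
        return pd.DataFrame([vars(r) for r in self.records],
                            columns=list(SAMPLE_COLUMNS) + ["derived"])

    def subset(self, keep, provenance: str | None = None) -> "SampleTable":
        recs = [r for r in self.records if keep(r)]
        return SampleTable(recs, provenance or self.provenance)


@dataclass(frozen=True)
class Violation:
    """One invariant violation found by :func:`validate_table`."""

    sample_id: str
    code: str
    message: str


# ---------------------------------------------------------------------------
# Parsing helpers
# ---------------------------------------------------------------------------

_BOOL = {"true": True, "false": False, "1": True, "0": False,
         "yes": True, "no": False}


def _parse_bool(text: str, line: int) -> bool:
    try:
        return _BOOL[text.strip().lower()]
    except KeyError:
        raise RowParseError(f"line {line}: cannot parse boolean {text!r}")


def _parse_float(text: str, line: int, name: str) -> float:
    # tolerate the unicode minus that spreadsheet exports sometimes emit
    try:
        return float(text.replace("−", "-"))
    except ValueError:
        raise RowParseError(f"line {line}: unparseable {name} {text!r}")


def _parse_row(row: Mapping[str, str], line: int) -> IsotopeSample:
    delta = _parse_float(row["delta13c"], line, "delta13c")
    lo, hi = DELTA13C_WINDOW
    if not (lo <= delta <= hi):
        raise RowParseError(
            f"line {line}: delta13c {delta} outside validity window "
            f"[{lo}, {hi}] per mil")
    block = row["block"].strip()
    if block not in {"1", "2", "3", "4"}:
        raise RowParseError(f"line {line}: block {block!r} not in 1-4")

    def _cat(name: str, levels: Sequence[str]) -> str:
        val = row[name].strip()
        if val not in levels:
            raise RowParseError(
                f"line {line}: {name} {val!r} not one of {levels}")
        return val

    def _optional(name: str) -> float | None:
        raw = (row.get(name) or "").strip()
        return None if raw == "" else _parse_float(raw, line, name)

    return IsotopeSample(
        sample_id=row["sample_id"].strip(),
        plot_id=row["plot_id"].strip(),
        treatment=_cat("treatment", TREATMENTS),
        block=int(block),
        depth=_cat("depth", DEPTHS),
        position=_cat("position", POSITIONS),
        method=_cat("method", METHODS),
        size_class=_cat("size_class", SIZE_CLASSES),
        eom_excluded=_parse_bool(row["eom_excluded"], line),
        delta13c=delta,
        dry_mass=_optional("dry_mass"),
        c_concentration=_optional("c_concentration"),
    )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def read_samples(path: str | Path, schema_version: str = SCHEMA_VERSION
                 ) -> SampleTable:
    """Read a samples CSV into a validated :class:`SampleTable`.

    Rows with an empty ``delta13c`` cell are treated as recorded-but-missing
    observations and dropped (complete-case handling); their count is logged.

    Raises
    ------
    SchemaError
        If a mandatory column is missing or the schema version is unknown.
    RowParseError
        On the first unparseable row (with its line number).
    IntegrityError
        If two rows share a (plot, depth, method, position, size_class) key.
    """
    if schema_version != SCHEMA_VERSION:
        raise SchemaError(f"unknown schema version {schema_version!r}")
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(
            f"missing mandatory column(s): {', '.join(missing_cols)}")
    records: list[IsotopeSample] = []
    n_missing = 0
    for i, row in enumerate(df.to_dict("records")):
        line = i + 2  # header is line 1
        if (row["delta13c"] or "").strip() == "":
            n_missing += 1
            continue
        records.append(_parse_row(row, line))
    if n_missing:
        log.info("%s: %d row(s) with missing delta13c dropped", path.name,
                 n_missing)
    if not records:
        log.warning("%s: no measured records after parsing", path.name)
    seen: dict[tuple, str] = {}
    for rec in records:
        key = rec.design_key()
        if key in seen:
            raise IntegrityError(
                f"duplicate design key {key} (samples {seen[key]!r} and "
                f"{rec.sample_id!r})")
        seen[key] = rec.sample_id
    return SampleTable(records, provenance=str(path))


def read_reference(path: str | Path) -> pd.DataFrame:
    """Read the prior-year ley fine-root reference CSV."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    df = pd.read_csv(path)
    missing = [c for c in REFERENCE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"missing mandatory column(s): {', '.join(missing)}")
    return df


def validate_table(table: SampleTable, pair=None) -> list[Violation]:
    """Report all invariant violations in *table* (does not raise).

    With an endmember *pair* supplied, additionally flags samples whose
    delta13C lies outside ``[eom.mean - 3 sd, root.mean + 3 sd]`` — i.e.
    outside any plausible two-source mixture given endmember spread.
    Flagged samples are reported, never deleted.
    """
    out: list[Violation] = []
    plot_attrs: dict[str, tuple] = {}
    for r in table.records:
        if not r.derived:
            if r.method == "humax":
                if r.size_class != "pooled":
                    out.append(Violation(r.sample_id, "humax_size",
                                         "humax implies pooled size class"))
                if not r.eom_excluded:
                    out.append(Violation(r.sample_id, "humax_exclusion",
                                         "humax implies EOM excluded"))
            elif r.method == "puerckhauer":
                if r.position != "row":
                    out.append(Violation(r.sample_id, "puerckhauer_position",
                                         "puerckhauer implies row position"))
                if r.size_class not in ("coarse", "fine"):
                    out.append(Violation(
                        r.sample_id, "puerckhauer_size",
                        "puerckhauer implies coarse or fine size class"))
                if r.eom_excluded:
                    out.append(Violation(r.sample_id, "puerckhauer_exclusion",
                                         "puerckhauer implies no exclusion"))
        lo, hi = DELTA13C_WINDOW
        if not (lo <= r.delta13c <= hi):
            out.append(Violation(r.sample_id, "delta_window",
                                 f"delta13c {r.delta13c} outside [{lo}, {hi}]"))
        prev = plot_attrs.setdefault(r.plot_id, (r.treatment, r.block))
        if prev != (r.treatment, r.block):
            out.append(Violation(
                r.sample_id, "plot_consistency",
                f"plot {r.plot_id}: treatment/block differ across records"))
        if pair is not None:
            low = pair.eom.mean - 3.0 * pair.eom.sd
            high = pair.root.mean + 3.0 * pair.root.sd
            if not (low <= r.delta13c <= high):
                out.append(Violation(
                    r.sample_id, "mixture_range",
                    f"delta13c {r.delta13c} outside plausible mixture range "
                    f"[{low:.2f}, {high:.2f}]"))
    return out


def build_subsets(table: SampleTable) -> dict[str, SampleTable]:
    """Split *table* into the analysis subsets.

    ``full``
        every record (measured records only);
    ``positions``
        all Humax records (row vs inter-row contrast);
    ``size_classes``
        all measured Puerckhauer records (coarse vs fine contrast);
    ``exclusion``
        records sharing position ``row`` and size class ``pooled`` across
        both methods — Humax row records versus Puerckhauer pooled records
        synthesized by the size-class pooling step (include them in *table*
        before building subsets).
    """
    subsets = {
        "full": table.subset(lambda r: not r.derived, "full"),
        "positions": table.subset(
            lambda r: r.method == "humax" and not r.derived, "positions"),
        "size_classes": table.subset(
            lambda r: r.method == "puerckhauer"
            and r.size_class in ("coarse", "fine") and not r.derived,
            "size_classes"),
        "exclusion": table.subset(
            lambda r: r.position == "row" and r.size_class == "pooled",
            "exclusion"),
    }
    for name, sub in subsets.items():
        if len(sub) == 0:
            log.warning("subset %r is empty", name)
    return subsets


def write_fractions(results, path: str | Path, table: SampleTable | None = None
                    ) -> None:
    """Write mixing results to CSV (4-decimal fractions).

    If *table* is given, design keys are joined in by sample_id so the file
    is directly usable by the summaries stage.
    """
    results = list(results)
    if not results:
        raise RootmixError("no results to write")
    rows = []
    by_id = {r.sample_id: r for r in table.records} if table else {}
    for res in results:
        row: dict = {"sample_id": res.sample_id}
        rec = by_id.get(res.sample_id)
        if table is not None and rec is not None:
            for f in ("plot_id", "treatment", "block", "depth", "position",
                      "method", "size_class", "eom_excluded", "derived"):
                row[f] = getattr(rec, f)
        row.update(
            raw_fraction=f"{res.raw_fraction:.4f}",
            fraction=f"{res.fraction:.4f}",
            se_analytic=f"{res.se_analytic:.4f}",
            ci_low="" if math.isnan(res.ci_low) else f"{res.ci_low:.4f}",
            ci_high="" if math.isnan(res.ci_high) else f"{res.ci_high:.4f}",
            flag=res.flag,
        )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_fractions(path: str | Path) -> pd.DataFrame:
    """Read a fractions CSV written by :func:`write_fractions`."""
    df = pd.read_csv(path)
    if "fraction" not in df.columns:
        raise SchemaError("missing mandatory column(s): fraction")
    return df
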