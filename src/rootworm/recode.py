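"""Disambiguation of blanks from zeros in raw weekly trap records.

Field sheets recorded blanks and zeroes interchangeably, so a blank cell
may be a true zero count or a missing observation.  Traps with no positive
count over the 19-week season are excluded; for the rest, each blank-or-
zero slot is classified by a four-rule scheme, applied in order with
first-match precedence:

1. slots before the first strictly positive count -> zero (early season);
2. slots between two positive neighbours -> missing if either neighbour is
   >= 10, else zero;
3. slots with no positive neighbour -> zero (sequential zeroes are real);
4. blank slots adjacent to exactly one positive neighbour -> missing;
   a recorded zero in that position is a legitimate observation and kept.

Rules 1-3 cover "blank or zero" records; rule 4 covers blanks only.
"Neighbour" means the immediately adjacent weeks (t-1, t+1) in the raw
sheet; at the season edges the single existing neighbour decides between
rules 3 and 4.  MISSING slots carry no likelihood downstream — the model
treats them as nuisance parameters.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BLANK",
    "MISSING",
    "N_WEEKS",
    "MIDSEASON_WEEKS",
    "RULE_LABELS",
    "TrapSeries",
    "RecodedSeries",
    "RecodingReport",
    "retain_trap",
    "recode_records",
    "recode_series",
    "recoding_report",
    "recode_confusion",
    "read_raw_counts",
    "recoded_to_frame",
]

#: sentinel for an empty cell in the raw sheet
BLANK = None
#: sentinel for a cell the rules classify as missing
MISSING = None

N_WEEKS = 19
#: mid-season block: weeks 4-16, excluding the first three and last three weeks
MIDSEASON_WEEKS = range(4, 17)

RULE_LABELS = (
    "observed",
    "rule1_zero",
    "rule2_missing",
    "rule2_zero",
    "rule3_zero",
    "rule4_missing",
)


@dataclass(frozen=True)
class TrapSeries:
    """One trap-year of raw records: 19 slots, each BLANK (None) or an int >= 0."""

    trap_id: object
    year: int
    records: tuple

    def __post_init__(self) -> None:
        if len(self.records) != N_WEEKS:
            raise ValueError(f"expected {N_WEEKS} weekly records, got {len(self.records)}")
        for r in self.records:
            if r is not BLANK and (not isinstance(r, (int, np.integer)) or r < 0):
                raise ValueError(f"records must be BLANK or non-negative integers, got {r!r}")


@dataclass(frozen=True)
class RecodedSeries:
    """A cleaned trap-year: 19 slots each MISSING (None) or an int >= 0, plus rule labels."""

    trap_id: object
    year: int
    records: tuple
    rule_applied: tuple

    def __post_init__(self) -> None:
        if len(self.records) != N_WEEKS or len(self.rule_applied) != N_WEEKS:
            raise ValueError("records and rule labels must both have 19 slots")
        for lab in self.rule_applied:
            if lab not in RULE_LABELS:
                raise ValueError(f"unknown rule label {lab!r}")


def retain_trap(series: TrapSeries) -> bool:
    """True iff the trap caught at least one beetle (some strictly positive count)."""
    return any(r is not BLANK and r > 0 for r in series.records)


def _is_positive(value) -> bool:
    return value is not BLANK and value > 0


def recode_records(rec: Sequence) -> tuple[tuple, tuple]:
    """Rule engine on a bare record sequence of any length.

    Returns (records, labels); used by :func:`recode_series` and directly
    by exhaustive small-pattern checks.
    """
    if not any(_is_positive(r) for r in rec):
        raise ValueError("recoding requires at least one positive count")
    first_pos = next(i for i, r in enumerate(rec) if _is_positive(r))

    out: list = []
    labels: list[str] = []
    for i, r in enumerate(rec):
        if _is_positive(r):
            out.append(int(r))
            labels.append("observed")
            continue
        # r is BLANK or a recorded zero: interchangeable, classified by the rules
        if i < first_pos:
            out.append(0)
            labels.append("rule1_zero")
            continue
        left = rec[i - 1] if i > 0 else BLANK
        right = rec[i + 1] if i < len(rec) - 1 else BLANK
        left_pos, right_pos = _is_positive(left), _is_positive(right)
        if left_pos and right_pos:
            if max(left, right) >= 10:
                out.append(MISSING)
                labels.append("rule2_missing")
            else:
                out.append(0)
                labels.append("rule2_zero")
        elif not left_pos and not right_pos:
            out.append(0)
            labels.append("rule3_zero")
        elif r is BLANK:
            # rule 4 covers blank records only; a recorded zero next to a
            # positive is a legitimate observation and is kept as observed
            out.append(MISSING)
            labels.append("rule4_missing")
        else:
            out.append(0)
            labels.append("observed")
    return tuple(out), tuple(labels)


def recode_series(series: TrapSeries) -> RecodedSeries:
    """Apply the four-rule scheme to one retained trap-year."""
    if not retain_trap(series):
        raise ValueError("recode_series requires a retained trap (some positive count)")
    records, labels = recode_records(series.records)
    return RecodedSeries(series.trap_id, series.year, records, labels)


@dataclass(frozen=True)
class RecodingReport:
    """Record accounting for a recoded dataset.

    Counts are stored; percentages are recomputed exactly from them.  Rule
    percentages use the denominator n_traps_retained * 19; the mid-season
    block is weeks 4-16 (13 weeks per retained trap).
    """

    n_traps_total: int
    n_traps_retained: int
    rule_counts: dict = field(default_factory=dict)
    n_midseason_blank_or_zero: int = 0

    @property
    def percent_retained(self) -> float:
        return 100.0 * self.n_traps_retained / self.n_traps_total

    @property
    def n_slots(self) -> int:
        return self.n_traps_retained * N_WEEKS

    @property
    def n_midseason_records(self) -> int:
        return self.n_traps_retained * len(MIDSEASON_WEEKS)

    @property
    def percent_midseason_blank_or_zero(self) -> float:
        return 100.0 * self.n_midseason_blank_or_zero / self.n_midseason_records

    def rule_percent(self, label: str) -> float:
        return 100.0 * self.rule_counts.get(label, 0) / self.n_slots

    def to_dict(self) -> dict:
        return {
            "n_traps_total": self.n_traps_total,
            "n_traps_retained": self.n_traps_retained,
            "percent_retained": self.percent_retained,
            "n_slots": self.n_slots,
            "rule_counts": dict(self.rule_counts),
            "rule_percents": {lab: self.rule_percent(lab) for lab in RULE_LABELS},
            "n_midseason_records": self.n_midseason_records,
            "n_midseason_blank_or_zero": self.n_midseason_blank_or_zero,
            "percent_midseason_blank_or_zero": self.percent_midseason_blank_or_zero,
        }


def recoding_report(dataset: Iterable[TrapSeries]) -> RecodingReport:
    """Recode every retained trap in ``dataset`` and tally the accounting."""
    dataset = list(dataset)
    retained = [s for s in dataset if retain_trap(s)]
    counts: Counter = Counter()
    n_mid_boz = 0
    for s in retained:
        rec = recode_series(s)
        counts.update(rec.rule_applied)
        for w in MIDSEASON_WEEKS:
            r = s.records[w - 1]
            if r is BLANK or r == 0:
                n_mid_boz += 1
    return RecodingReport(
        n_traps_total=len(dataset),
        n_traps_retained=len(retained),
        rule_counts=dict(counts),
        n_midseason_blank_or_zero=n_mid_boz,
    )


def recode_confusion(
    recoded: Sequence[RecodedSeries], truth: Sequence[Sequence[int]]
) -> pd.DataFrame:
    """Cross-tabulate recoding outcomes against synthetic ground truth.

    Rows: recoded_zero, recoded_missing, observed.  Columns: true_zero,
    true_positive.  Entries sum to 19 * len(recoded).
    """
    if len(recoded) != len(truth):
        raise ValueError("recoded and truth tables differ in length")
    table = pd.DataFrame(
        0,
        index=["recoded_zero", "recoded_missing", "observed"],
        columns=["true_zero", "true_positive"],
    )
    for series, true_row in zip(recoded, truth):
        if len(true_row) != N_WEEKS:
            raise ValueError("truth rows must have 19 slots")
        for value, label, true_value in zip(series.records, series.rule_applied, true_row):
            col = "true_positive" if true_value > 0 else "true_zero"
            if label == "observed":
                row = "observed"
            elif value is MISSING:
                row = "recoded_missing"
            else:
                row = "recoded_zero"
            table.loc[row, col] += 1
    return table


def read_raw_counts(path) -> list[TrapSeries]:
    """Read a long-format raw count CSV (trap_id, year, week, count; empty cell = BLANK)."""
    df = pd.read_csv(path, keep_default_na=False, dtype={"count": str})
    out = []
    for (trap_id, year), grp in df.groupby(["trap_id", "year"], sort=True):
        grp = grp.sort_values("week")
        if list(grp["week"]) != list(range(1, N_WEEKS + 1)):
            raise ValueError(f"trap {trap_id} year {year}: weeks must be 1..{N_WEEKS}")
        records = tuple(
            BLANK if c.strip() == "" else int(c) for c in grp["count"]
        )
        out.append(TrapSeries(trap_id, int(year), records))
    return out


def recoded_to_frame(recoded: Sequence[RecodedSeries]) -> pd.DataFrame:
    """Long-format frame of recoded records; MISSING rendered as the string 'NA'."""
    rows = []
    for s in recoded:
        for w, (value, label) in enumerate(zip(s.records, s.rule_applied), start=1):
            rows.append(
                {
                    "trap_id": s.trap_id,
                    "year": s.year,
                    "week": w,
                    "count": "NA" if value is MISSING else int(value),
                    "rule": label,
                }
            )
    return pd.DataFrame(rows)
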