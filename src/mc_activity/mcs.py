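"""The Microscopic Colitis Score (MCS): a composite 0-15 disease-severity
score summing item-specific points awarded from MCSQ weekly summaries.

Five diary items carry points: mean loose stools/day, mean nocturnal
stools/day, urgency days/week, leakage days/week, and mean abdominal pain.
Mean solid stools and mean total stools are deliberately excluded (solid
stools do not contribute to a diarrhea score; total stools are derivable and
less predictive of quality of life than loose stools).  Each item awards 0-3
points through strictly increasing cut-offs, so the maximum score is 15.

Severity classes partition the score: remission 0-3, mild 4-6, moderate 7-9,
severe 10-15.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .instruments import WeeklySymptomSummary

__all__ = [
    "INCLUDED_ITEMS",
    "EXCLUDED_ITEMS",
    "MCS_MAX",
    "SEVERITY_BANDS",
    "ScoreTableEntry",
    "ScoreTable",
    "MCSResult",
    "ScoreTableError",
    "award_item_points",
    "compute_mcs",
    "classify_severity",
    "load_score_table",
    "dump_score_table",
    "default_score_table",
]

INCLUDED_ITEMS = ("mean_loose", "mean_nocturnal", "urgency_days", "leakage_days", "mean_pain")
EXCLUDED_ITEMS = ("mean_solid", "mean_total")
MCS_MAX = 15

# severity: [low, high] inclusive integer bands
SEVERITY_BANDS = {
    "remission": (0, 3),
    "mild": (4, 6),
    "moderate": (7, 9),
    "severe": (10, 15),
}


class ScoreTableError(ValueError):
    """Raised when a score table violates the MCS construction constraints."""


@dataclass(frozen=True)
class ScoreTableEntry:
    """Cut-offs and points for one MCS item.

    ``thresholds`` are strictly increasing; a value in the half-open interval
    [thresholds[i-1], thresholds[i]) earns ``points[i]``, values below the
    first threshold earn ``points[0]`` and values at or above the last earn
    ``points[-1]``.  Points start at 0 and increase strictly.
    """

    item: str
    thresholds: tuple[float, ...]
    points: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.item in EXCLUDED_ITEMS:
            raise ScoreTableError(f"item {self.item!r} is excluded from the MCS")
        if self.item not in INCLUDED_ITEMS:
            raise ScoreTableError(f"unknown MCS item {self.item!r}")
        if len(self.points) != len(self.thresholds) + 1:
            raise ScoreTableError(
                f"{self.item}: need len(points) == len(thresholds) + 1, "
                f"got {len(self.points)} vs {len(self.thresholds)}"
            )
        if any(b <= a for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ScoreTableError(f"{self.item}: thresholds must be strictly increasing")
        if self.points[0] != 0:
            raise ScoreTableError(f"{self.item}: points must start at 0")
        if any(b <= a for a, b in zip(self.points, self.points[1:])):
            raise ScoreTableError(f"{self.item}: points must be strictly increasing")

    @property
    def max_points(self) -> int:
        return int(self.points[-1])


@dataclass(frozen=True)
class ScoreTable:
    """The item -> points mapping that defines the MCS."""

    entries: tuple[ScoreTableEntry, ...]

    def __post_init__(self) -> None:
        items = [e.item for e in self.entries]
        if sorted(items) != sorted(INCLUDED_ITEMS):
            raise ScoreTableError(
                f"score table must contain exactly the items {INCLUDED_ITEMS}, got {items}"
            )
        total = sum(e.max_points for e in self.entries)
        if total != MCS_MAX:
            raise ScoreTableError(f"item maximum points sum to {total}, must be {MCS_MAX}")

    def entry(self, item: str) -> ScoreTableEntry:
        for e in self.entries:
            if e.item == item:
                return e
        raise ScoreTableError(f"score table has no entry for {item!r}")


@dataclass(frozen=True)
class MCSResult:
    item_points: dict[str, int]
    mcs: int
    severity: str


def award_item_points(value: float, entry: ScoreTableEntry) -> int:
    """Points for one item value under a half-open interval convention.

    The interval index is found with a right-open search: a value exactly at
    a threshold falls into the higher interval (thresholds behave like the
    >=-style cut-offs used for disease activity).
    """
    if value < 0:
        raise ValueError(f"{entry.item}: negative value {value}")
    idx = int(np.searchsorted(entry.thresholds, value, side="right"))
    return int(entry.points[idx])


def compute_mcs(summary: WeeklySymptomSummary, table: ScoreTable) -> MCSResult:
    """Sum item-specific points over the five included items and classify."""
    values = summary.as_dict()
    item_points = {
        item: award_item_points(values[item], table.entry(item)) for item in INCLUDED_ITEMS
    }
    total = int(sum(item_points.values()))
    return MCSResult(item_points=item_points, mcs=total, severity=classify_severity(total))


def classify_severity(mcs: int) -> str:
    """Map an integer MCS to its severity class (remission/mild/moderate/severe)."""
    if not 0 <= mcs <= MCS_MAX or int(mcs) != mcs:
        raise ValueError(f"MCS {mcs} outside 0-{MCS_MAX}")
    for name, (lo, hi) in SEVERITY_BANDS.items():
        if lo <= mcs <= hi:
            return name
    raise AssertionError("severity bands do not cover 0-15")  # pragma: no cover


# ---------------------------------------------------------------------------
# Score-table serialization: one block per item, human-readable
# ---------------------------------------------------------------------------

def dump_score_table(table: ScoreTable, path=None) -> str:
    """Serialize a score table to its text config format.

    Format, one block per item::

        [mean_loose]
        thresholds = 0.8, 2.75, 5.5
        points = 0, 1, 2, 3
    """
    lines = []
    for e in table.entries:
        lines.append(f"[{e.item}]")
        lines.append("thresholds = " + ", ".join(repr(float(t)) for t in e.thresholds))
        lines.append("points = " + ", ".join(str(int(p)) for p in e.points))
        lines.append("")
    text = "\n".join(lines)
    if path is not None:
        Path(path).write_text(text)
    return text


def load_score_table(source) -> ScoreTable:
    """Parse a score-table config (path or raw text); validates all invariants."""
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                    and Path(source).is_file()):
        text = Path(source).read_text()
    else:
        text = str(source)
    entries = []
    item = None
    thresholds: tuple[float, ...] | None = None
    points: tuple[int, ...] | None = None

    def flush():
        nonlocal item, thresholds, points
        if item is not None:
            if thresholds is None or points is None:
                raise ScoreTableError(f"incomplete block for {item!r}")
            entries.append(ScoreTableEntry(item=item, thresholds=thresholds, points=points))
        item, thresholds, points = None, None, None

    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("[") and line.endswith("]"):
            flush()
            item = line[1:-1].strip()
        elif "=" in line:
            key, _, val = line.partition("=")
            vals = [v.strip() for v in val.split(",") if v.strip()]
            if key.strip() == "thresholds":
                thresholds = tuple(float(v) for v in vals)
            elif key.strip() == "points":
                points = tuple(int(v) for v in vals)
            else:
                raise ScoreTableError(f"unknown key {key.strip()!r} in score table")
        else:
            raise ScoreTableError(f"unparsable line in score table: {raw!r}")
    flush()
    return ScoreTable(entries=tuple(entries))


def default_score_table() -> ScoreTable:
    """The packaged default score table.

    The clinically validated item cut-offs for the MCS are not freely
    redistributable; this default was derived by running the IBDQ-anchored
    calibration on the packaged synthetic reference cohort and is shipped as
    a version-pinned config.  Replace it with a published or site-specific
    table via :func:`load_score_table`.
    """
    text = resources.files("mc_activity").joinpath("data/mcs_table.cfg").read_text()
    return load_score_table(text)
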