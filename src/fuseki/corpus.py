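"""Game records, corpus cleaning filters, and historical segmentation.

A corpus is a list of :class:`GameRecord`. Cleaning removes handicap games,
games without a usable date, games played before 1600, and games involving
AI players, attributing each removed game to exactly one reason in that
priority order. Retained games are segmented two ways: into six named
historical eras, and into variable-width time bins (25-year bins before
1850, 5-year bins 1850–1949, annual bins from 1950) that compensate for the
sparseness of the early record.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .board import BoardPoint, is_on_board

MIN_YEAR = 1600
MAX_YEAR = 2024


@dataclass(frozen=True, order=True)
class GameDate:
    """A possibly partial calendar date; many historical games are year-only."""

    year: int
    month: Optional[int] = None
    day: Optional[int] = None

    def __str__(self) -> str:
        parts = [f"{self.year:04d}"]
        if self.month is not None:
            parts.append(f"{self.month:02d}")
            if self.day is not None:
                parts.append(f"{self.day:02d}")
        return "-".join(parts)


_DATE_RE = re.compile(r"(\d{3,4})(?:-(\d{1,2}))?(?:-(\d{1,2}))?")


def parse_date(text: str) -> Optional[GameDate]:
    """Extract a :class:`GameDate` from an SGF ``DT`` value.

    The first date-like token wins (a game spanning two dates uses its start
    date). Returns ``None`` if no year can be found.
    """
    m = _DATE_RE.search(text)
    if m is None:
        return None
    year = int(m.group(1))
    month = int(m.group(2)) if m.group(2) else None
    day = int(m.group(3)) if m.group(3) else None
    if month is not None and not 1 <= month <= 12:
        month, day = None, None
    if day is not None and not 1 <= day <= 31:
        day = None
    return GameDate(year, month, day)


@dataclass
class GameRecord:
    """One game: its move sequence plus the metadata carried by the archive."""

    moves: list[BoardPoint] = field(default_factory=list)
    date: Optional[GameDate] = None
    black_player: Optional[str] = None
    white_player: Optional[str] = None
    nationality_black: Optional[str] = None
    nationality_white: Optional[str] = None
    handicap: int = 0
    komi: Optional[float] = None
    result: Optional[str] = None
    is_ai_black: bool = False
    is_ai_white: bool = False
    game_id: Optional[str] = None
    #: unparsed SGF properties, preserved verbatim for round-tripping
    extras: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.handicap < 0:
            raise ValueError("handicap must be non-negative")
        for p in self.moves:
            if not is_on_board(p):
                raise ValueError(f"move {p!r} is off the board")

    @property
    def year(self) -> Optional[int]:
        return self.date.year if self.date is not None else None


@dataclass(frozen=True)
class FilterReport:
    """Bookkeeping for corpus cleaning; each removal counted under one reason."""

    n_input: int
    n_handicap_removed: int
    n_undated_removed: int
    n_pre1600_removed: int
    n_ai_removed: int
    n_retained: int

    def __post_init__(self) -> None:
        removed = (
            self.n_handicap_removed
            + self.n_undated_removed
            + self.n_pre1600_removed
            + self.n_ai_removed
        )
        if self.n_retained != self.n_input - removed:
            raise ValueError("filter report counts are inconsistent")


def filter_corpus(
    games: Sequence[GameRecord],
    min_year: int = MIN_YEAR,
    drop_handicap: bool = True,
    drop_undated: bool = True,
    drop_ai: bool = True,
) -> tuple[list[GameRecord], FilterReport]:
    """Apply the cleaning rules, returning retained games and a report.

    Removal reasons are evaluated in priority order handicap > undated >
    pre-``min_year`` > AI, so a game that is both handicapped and undated
    counts only as a handicap removal.
    """
    kept: list[GameRecord] = []
    n_handicap = n_undated = n_old = n_ai = 0
    for g in games:
        if drop_handicap and g.handicap > 0:
            n_handicap += 1
        elif drop_undated and g.year is None:
            n_undated += 1
        elif g.year is not None and g.year < min_year:
            n_old += 1
        elif drop_ai and (g.is_ai_black or g.is_ai_white):
            n_ai += 1
        else:
            kept.append(g)
    report = FilterReport(
        n_input=len(games),
        n_handicap_removed=n_handicap,
        n_undated_removed=n_undated,
        n_pre1600_removed=n_old,
        n_ai_removed=n_ai,
        n_retained=len(kept),
    )
    return kept, report


@dataclass(frozen=True)
class EraLabel:
    name: str
    start_year: int
    end_year: int

    def __str__(self) -> str:
        return self.name


#: The six eras, demarcated by major historical events; they partition
#: 1600-2024.
ERAS: tuple[EraLabel, ...] = (
    EraLabel("EarlyModern", 1600, 1867),
    EraLabel("Imperial", 1868, 1945),
    EraLabel("ColdWar", 1946, 1972),
    EraLabel("International", 1973, 1991),
    EraLabel("Internet", 1992, 2015),
    EraLabel("SAI", 2016, 2024),
)

_ERA_BY_NAME = {e.name: e for e in ERAS}


def era_by_name(name: str) -> EraLabel:
    return _ERA_BY_NAME[name]


def assign_era(year: int) -> EraLabel:
    """The unique era whose [start_year, end_year] interval contains ``year``."""
    for era in ERAS:
        if era.start_year <= year <= era.end_year:
            return era
    raise ValueError(f"year {year} is outside the covered range "
                     f"{MIN_YEAR}-{MAX_YEAR}")


@dataclass(frozen=True, order=True)
class TimeBin:
    start_year: int
    end_year: int

    @property
    def width(self) -> int:
        return self.end_year - self.start_year + 1

    def __str__(self) -> str:
        if self.width == 1:
            return str(self.start_year)
        return f"{self.start_year}-{self.end_year}"


def assign_time_bin(year: int) -> TimeBin:
    """Variable-width time bin for ``year``.

    Annual bins from 1950 on; 5-year bins anchored at 1850 for 1850-1949;
    25-year bins anchored at 1600 before 1850.
    """
    if year < MIN_YEAR:
        raise ValueError(f"year {year} precedes the corpus range ({MIN_YEAR})")
    if year >= 1950:
        return TimeBin(year, year)
    if year >= 1850:
        start = 1850 + 5 * ((year - 1850) // 5)
        return TimeBin(start, start + 4)
    start = MIN_YEAR + 25 * ((year - MIN_YEAR) // 25)
    return TimeBin(start, start + 24)


def group_by_bin(games: Iterable[GameRecord]) -> dict[TimeBin, list[GameRecord]]:
    """Dated games keyed by time bin, in chronological bin order."""
    out: dict[TimeBin, list[GameRecord]] = {}
    for g in games:
        if g.year is None:
            continue
        out.setdefault(assign_time_bin(g.year), []).append(g)
    return dict(sorted(out.items()))


def group_by_era(games: Iterable[GameRecord]) -> dict[EraLabel, list[GameRecord]]:
    """Dated games keyed by era, in chronological era order."""
    out: dict[EraLabel, list[GameRecord]] = {e: [] for e in ERAS}
    for g in games:
        if g.year is None:
            continue
        out[assign_era(g.year)].append(g)
    return {e: gs for e, gs in out.items() if gs}


def corpus_summary(games: Sequence[GameRecord]) -> pd.DataFrame:
    """Per-game summary table (one row per dated game)."""
    rows = []
    for i, g in enumerate(games):
        if g.year is None:
            era = bin_ = None
        else:
            era = assign_era(g.year).name if MIN_YEAR <= g.year <= MAX_YEAR else None
            bin_ = assign_time_bin(g.year)
        rows.append(
            {
                "game_id": g.game_id if g.game_id is not None else f"game{i:06d}",
                "year": g.year,
                "era": era,
                "bin_start": bin_.start_year if bin_ else None,
                "bin_width": bin_.width if bin_ else None,
                "black": g.black_player,
                "white": g.white_player,
                "handicap": g.handicap,
                "komi": g.komi,
                "n_moves": len(g.moves),
            }
        )
    return pd.DataFrame(rows)
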