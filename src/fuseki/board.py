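"""Board coordinates for the 19×19 Go grid.

Three coordinate conventions appear in game records and reports:

* :class:`BoardPoint` — the package's internal form, 1-based ``(col, row)``
  with rows counted from the *bottom* of the board.
* SGF letter pairs (``"qc"``) — column then row, ``a``–``s``, rows counted
  from the *top*; the on-disk form.
* Korschelt strings (``"Q16"``) — the human-readable notation used in Go
  literature: column letters A–T skipping I, row numbers 1–19 from the
  bottom.
"""

from __future__ import annotations

from typing import NamedTuple

BOARD_SIZE = 19

#: Column letters in Korschelt notation; the letter "I" is omitted.
KORSCHELT_COLS = "ABCDEFGHJKLMNOPQRST"

_SGF_LETTERS = "abcdefghijklmnopqrs"


class BoardPoint(NamedTuple):
    """A grid intersection, ``1 <= col, row <= 19``, row 1 at the bottom."""

    col: int
    row: int


def is_on_board(p: BoardPoint) -> bool:
    return 1 <= p.col <= BOARD_SIZE and 1 <= p.row <= BOARD_SIZE


def _check(p: BoardPoint) -> None:
    if not is_on_board(p):
        raise ValueError(f"point {p!r} is outside the 19x19 board")


def point_to_korschelt(p: BoardPoint) -> str:
    """Render a point as a Korschelt coordinate, e.g. ``(16, 16) -> "Q16"``."""
    _check(p)
    return f"{KORSCHELT_COLS[p.col - 1]}{p.row}"


def korschelt_to_point(s: str) -> BoardPoint:
    """Inverse of :func:`point_to_korschelt`."""
    if len(s) < 2:
        raise ValueError(f"not a Korschelt coordinate: {s!r}")
    letter, digits = s[0].upper(), s[1:]
    col = KORSCHELT_COLS.find(letter) + 1
    if col == 0:
        raise ValueError(f"bad column letter in Korschelt coordinate {s!r}")
    try:
        row = int(digits)
    except ValueError:
        raise ValueError(f"bad row in Korschelt coordinate {s!r}") from None
    p = BoardPoint(col, row)
    _check(p)
    return p


def sgf_to_point(s: str) -> BoardPoint:
    """Convert an SGF letter pair (column, row-from-top) to a BoardPoint."""
    if len(s) != 2 or s[0] not in _SGF_LETTERS or s[1] not in _SGF_LETTERS:
        raise ValueError(f"bad SGF coordinate {s!r}")
    col = _SGF_LETTERS.index(s[0]) + 1
    row_from_top = _SGF_LETTERS.index(s[1]) + 1
    return BoardPoint(col, BOARD_SIZE + 1 - row_from_top)


def point_to_sgf(p: BoardPoint) -> str:
    """Inverse of :func:`sgf_to_point`."""
    _check(p)
    return _SGF_LETTERS[p.col - 1] + _SGF_LETTERS[BOARD_SIZE - p.row]


def all_points() -> list[BoardPoint]:
    """All 361 intersections, in (col, row) lexicographic order."""
    return [
        BoardPoint(c, r)
        for c in range(1, BOARD_SIZE + 1)
        for r in range(1, BOARD_SIZE + 1)
    ]
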