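"""Reading and writing SGF (Smart Game Format) game records.

Supports the FF[4] conventions used by curated Go archives: a file is a
collection of game trees ``(;PROP[value]...;B[pd];W[dp]...)``. Only 19×19 Go
(``GM[1]``, ``SZ[19]``) is accepted. Where a file branches into variations,
the main line (first branch) is followed. Pass moves (``B[]`` or the ``tt``
convention) are dropped from the move list.

Recognised metadata properties: ``DT`` (date), ``PB``/``PW`` (players),
``BC``/``WC`` (nationalities, GoGoD style), ``HA`` (handicap), ``KM``
(komi), ``RE`` (result), ``GN`` (game id), and the extension flags
``AIB[1]``/``AIW[1]`` marking an AI player. Unrecognised properties are
preserved verbatim and re-emitted on writing.
"""

from __future__ import annotations

from typing import Iterator

from .board import BoardPoint, point_to_sgf, sgf_to_point
from .corpus import GameDate, GameRecord, parse_date


class SgfParseError(ValueError):
    """Malformed SGF input; ``offset`` is the character position at fault."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at offset {offset})")
        self.offset = offset


class UnsupportedBoardError(ValueError):
    """The record is not a 19×19 Go game."""


# ---------------------------------------------------------------------------
# low-level parsing

Node = dict[str, list[str]]


class _Scanner:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def skip_ws(self) -> None:
        while self.pos < len(self.text) and self.text[self.pos].isspace():
            self.pos += 1

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def expect(self, ch: str) -> None:
        if self.peek() != ch:
            raise SgfParseError(f"expected {ch!r}", self.pos)
        self.pos += 1

    def read_prop_ident(self) -> str:
        start = self.pos
        while self.pos < len(self.text) and self.text[self.pos].isalpha():
            self.pos += 1
        if self.pos == start:
            raise SgfParseError("expected property identifier", self.pos)
        return self.text[start : self.pos].upper()

    def read_prop_value(self) -> str:
        self.expect("[")
        out = []
        while True:
            if self.pos >= len(self.text):
                raise SgfParseError("unterminated property value", self.pos)
            ch = self.text[self.pos]
            if ch == "\\":
                if self.pos + 1 >= len(self.text):
                    raise SgfParseError("dangling escape", self.pos)
                out.append(self.text[self.pos + 1])
                self.pos += 2
            elif ch == "]":
                self.pos += 1
                return "".join(out)
            else:
                out.append(ch)
                self.pos += 1


def _parse_game_tree(sc: _Scanner) -> list[Node]:
    """Parse one game tree, returning the main-line node sequence."""
    sc.expect("(")
    nodes: list[Node] = []
    sc.skip_ws()
    while sc.peek() == ";":
        sc.pos += 1
        node: Node = {}
        sc.skip_ws()
        while sc.peek().isalpha():
            ident = sc.read_prop_ident()
            sc.skip_ws()
            values = []
            while sc.peek() == "[":
                values.append(sc.read_prop_value())
                sc.skip_ws()
            if not values:
                raise SgfParseError(f"property {ident} has no value", sc.pos)
            node.setdefault(ident, []).extend(values)
        nodes.append(node)
        sc.skip_ws()
    # variations: follow the first, skip the rest
    first = True
    while sc.peek() == "(":
        if first:
            nodes.extend(_parse_game_tree(sc))
            first = False
        else:
            _skip_game_tree(sc)
        sc.skip_ws()
    sc.expect(")")
    return nodes


def _skip_game_tree(sc: _Scanner) -> None:
    depth = 0
    while sc.pos < len(sc.text):
        ch = sc.text[sc.pos]
        if ch == "[":
            sc.read_prop_value()
            continue
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth == 0:
                sc.pos += 1
                return
        sc.pos += 1
    raise SgfParseError("unterminated game tree", sc.pos)


# ---------------------------------------------------------------------------
# record assembly

_KNOWN = {"GM", "FF", "SZ", "DT", "PB", "PW", "BC", "WC",
          "HA", "KM", "RE", "GN", "AIB", "AIW", "B", "W"}

_PASS_VALUES = {"", "tt"}


def _record_from_nodes(nodes: list[Node]) -> GameRecord:
    root = nodes[0] if nodes else {}
    gm = root.get("GM", ["1"])[0]
    if gm.strip() not in ("", "1"):
        raise UnsupportedBoardError(f"not a Go record (GM[{gm}])")
    sz = root.get("SZ", ["19"])[0]
    if sz.strip() != "19":
        raise UnsupportedBoardError(f"only 19x19 boards are supported (SZ[{sz}])")

    moves: list[BoardPoint] = []
    for node in nodes:
        for key in ("B", "W"):
            for value in node.get(key, []):
                if value in _PASS_VALUES:
                    continue
                moves.append(sgf_to_point(value))

    def first(key: str) -> str | None:
        vals = root.get(key)
        return vals[0] if vals else None

    komi_raw = first("KM")
    try:
        komi = float(komi_raw) if komi_raw not in (None, "") else None
    except ValueError:
        komi = None
    ha_raw = first("HA")
    try:
        handicap = int(ha_raw) if ha_raw not in (None, "") else 0
    except ValueError:
        handicap = 0

    extras = {k: list(v) for k, v in root.items() if k not in _KNOWN}
    dt = first("DT")
    return GameRecord(
        moves=moves,
        date=parse_date(dt) if dt else None,
        black_player=first("PB"),
        white_player=first("PW"),
        nationality_black=first("BC"),
        nationality_white=first("WC"),
        handicap=max(handicap, 0),
        komi=komi,
        result=first("RE"),
        is_ai_black=first("AIB") == "1",
        is_ai_white=first("AIW") == "1",
        game_id=first("GN"),
        extras=extras,
    )


def parse_sgf(text: str) -> list[GameRecord]:
    """Parse an SGF collection into one :class:`GameRecord` per game tree."""
    sc = _Scanner(text)
    records = []
    sc.skip_ws()
    if sc.peek() != "(":
        raise SgfParseError("expected start of game tree '('", sc.pos)
    while sc.peek() == "(":
        records.append(_record_from_nodes(_parse_game_tree(sc)))
        sc.skip_ws()
    if sc.pos != len(sc.text):
        raise SgfParseError("trailing content after game collection", sc.pos)
    return records


def iter_sgf_games(text: str) -> Iterator[GameRecord]:
    yield from parse_sgf(text)


# ---------------------------------------------------------------------------
# writing


def _escape(value: str) -> str:
    return value.replace("\\", "\\\\").replace("]", "\\]")


def write_sgf(record: GameRecord) -> str:
    """Serialize a record as a single-game SGF document (round-trips)."""
    props: list[tuple[str, list[str]]] = [("GM", ["1"]), ("FF", ["4"]), ("SZ", ["19"])]
    if record.game_id is not None:
        props.append(("GN", [record.game_id]))
    if record.date is not None:
        props.append(("DT", [str(record.date)]))
    if record.black_player is not None:
        props.append(("PB", [record.black_player]))
    if record.white_player is not None:
        props.append(("PW", [record.white_player]))
    if record.nationality_black is not None:
        props.append(("BC", [record.nationality_black]))
    if record.nationality_white is not None:
        props.append(("WC", [record.nationality_white]))
    if record.handicap:
        props.append(("HA", [str(record.handicap)]))
    if record.komi is not None:
        komi = record.komi
        props.append(("KM", [f"{komi:g}"]))
    if record.result is not None:
        props.append(("RE", [record.result]))
    if record.is_ai_black:
        props.append(("AIB", ["1"]))
    if record.is_ai_white:
        props.append(("AIW", ["1"]))
    props.extend(sorted(record.extras.items()))

    parts = ["(;"]
    for ident, values in props:
        parts.append(ident + "".join(f"[{_escape(v)}]" for v in values))
    for i, move in enumerate(record.moves):
        color = "B" if i % 2 == 0 else "W"
        parts.append(f";{color}[{point_to_sgf(move)}]")
    parts.append(")")
    return "".join(parts)


def write_sgf_collection(records: list[GameRecord]) -> str:
    """Serialize several records as an SGF collection, one tree per game."""
    return "\n".join(write_sgf(r) for r in records) + "\n"
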