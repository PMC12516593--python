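"""Dihedral-symmetry canonicalization of move sequences.

A Go board has the symmetry group of the square (D4, order 8): four
rotations and four reflections. Two games whose move sequences differ only
by one of these transforms are strategically identical, so before any
frequency analysis every game is mapped to a canonical representative of
its symmetry orbit: the first move is brought into the closed top-right
quadrant (col ≥ 10 and row ≥ 10), and among the transforms achieving this
the one producing the lexicographically smallest full sequence (points
ordered by ``(col, row)``) is chosen. This makes the canonical form unique
and the operation idempotent.

The module also counts symmetry orbits of opening sequences via Burnside's
lemma, which is how the size of the opening search space (nearly 10^17
distinct seven-move openings) is computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

from .board import BOARD_SIZE, BoardPoint

_C = BOARD_SIZE + 1  # col + reflected col = 20; board center at (10, 10)


@dataclass(frozen=True)
class SymmetryTransform:
    """One element of the board's D4 symmetry group."""

    name: str
    _map: Callable[[int, int], tuple[int, int]]

    def __call__(self, p: BoardPoint) -> BoardPoint:
        return BoardPoint(*self._map(p.col, p.row))

    def apply_sequence(self, moves: Sequence[BoardPoint]) -> list[BoardPoint]:
        return [self(p) for p in moves]

    def __repr__(self) -> str:
        return f"SymmetryTransform({self.name!r})"


#: The 8 board symmetries. Rotations are counter-clockwise; ``flip_v``
#: reflects across the vertical axis, ``flip_h`` across the horizontal one,
#: ``flip_diag``/``flip_anti`` across the two diagonals.
TRANSFORMS: tuple[SymmetryTransform, ...] = (
    SymmetryTransform("identity", lambda c, r: (c, r)),
    SymmetryTransform("rot90", lambda c, r: (_C - r, c)),
    SymmetryTransform("rot180", lambda c, r: (_C - c, _C - r)),
    SymmetryTransform("rot270", lambda c, r: (r, _C - c)),
    SymmetryTransform("flip_v", lambda c, r: (_C - c, r)),
    SymmetryTransform("flip_h", lambda c, r: (c, _C - r)),
    SymmetryTransform("flip_diag", lambda c, r: (r, c)),
    SymmetryTransform("flip_anti", lambda c, r: (_C - r, _C - c)),
)

_BY_NAME = {t.name: t for t in TRANSFORMS}

IDENTITY = _BY_NAME["identity"]


def transform_by_name(name: str) -> SymmetryTransform:
    return _BY_NAME[name]


def apply_transform(p: BoardPoint, t: SymmetryTransform) -> BoardPoint:
    return t(p)


def inverse(t: SymmetryTransform) -> SymmetryTransform:
    """The group inverse (rotations invert to the opposite rotation,
    reflections are involutions)."""
    probe = BoardPoint(2, 5)  # a point with trivial stabilizer
    image = t(probe)
    for cand in TRANSFORMS:
        if cand(image) == probe and cand(t(BoardPoint(3, 7))) == BoardPoint(3, 7):
            return cand
    raise AssertionError("group inverse not found")  # pragma: no cover


def _in_top_right(p: BoardPoint) -> bool:
    half = (BOARD_SIZE + 1) // 2  # 10; center lines included
    return p.col >= half and p.row >= half


def canonicalize_game(
    moves: Sequence[BoardPoint],
) -> tuple[list[BoardPoint], SymmetryTransform]:
    """Map a move sequence to the canonical representative of its D4 orbit.

    Returns the transformed sequence and the transform applied. The first
    canonical move lies in the closed top-right quadrant; ties between
    qualifying transforms are broken by full-sequence lexicographic order,
    then by transform declaration order, so the result is deterministic and
    idempotent.
    """
    if not moves:
        raise ValueError("cannot canonicalize an empty move sequence")
    best: tuple[list[BoardPoint], SymmetryTransform] | None = None
    for t in TRANSFORMS:
        first = t(moves[0])
        if not _in_top_right(first):
            continue
        candidate = t.apply_sequence(moves)
        if best is None or candidate < best[0]:
            best = (candidate, t)
    assert best is not None  # every orbit meets the closed quadrant
    return best


def count_symmetry_orbits(depth: int) -> int:
    """Number of D4-equivalence classes of ordered sequences of ``depth``
    distinct board points, by Burnside's lemma.

    A sequence is fixed by a symmetry iff every one of its points is, so the
    fixed-sequence count for a group element with ``f`` fixed board points
    is the falling factorial P(f, depth). The identity fixes all 361 points,
    each rotation only the center, each reflection the 19 points of its
    axis.
    """
    if not 1 <= depth <= BOARD_SIZE * BOARD_SIZE:
        raise ValueError(f"depth must be in [1, 361], got {depth}")
    fixed_points = (361, 1, 1, 1, 19, 19, 19, 19)
    total = sum(math.perm(f, depth) for f in fixed_points)
    assert total % len(TRANSFORMS) == 0
    return total // len(TRANSFORMS)
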