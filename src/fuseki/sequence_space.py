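"""Edit-distance geometry of opening sequences and its low-dimensional map.

Games are compared as *token* sequences — each move (a Korschelt
coordinate) is one symbol — truncated to the first ``max_depth`` moves
(50 by default). Three edit distances are available:

* ``lv``  — Levenshtein: insertions, deletions, substitutions;
* ``osa`` — optimal string alignment: adds adjacent transposition, but a
  transposed pair cannot be edited again (may violate the triangle
  inequality);
* ``dl``  — full Damerau–Levenshtein.

The N×N distance matrix is embedded by classical (Torgerson) MDS: double-
center −½·d², eigendecompose, and keep the top-k non-negative eigenvalues;
coordinates are eigenvectors scaled by the square roots of their
eigenvalues. Negative eigenvalues (non-Euclidean input) are truncated to
zero and reported. Axis signs are fixed so each coordinate's largest-
magnitude loading is positive, making the embedding deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .board import point_to_korschelt
from .corpus import GameRecord

METHODS = ("lv", "osa", "dl")

MoveTokenSequence = Sequence[str]


def game_tokens(game: GameRecord, max_depth: int = 50) -> list[str]:
    """Korschelt tokens of a (canonicalized) game, truncated to max_depth."""
    return [point_to_korschelt(p) for p in game.moves[:max_depth]]


def _encode_pair(a: MoveTokenSequence, b: MoveTokenSequence
                 ) -> tuple[list[int], list[int]]:
    symbols = {tok: i for i, tok in enumerate(dict.fromkeys([*a, *b]))}
    return [symbols[t] for t in a], [symbols[t] for t in b]


def _lv(a: list[int], b: list[int]) -> int:
    m, n = len(a), len(b)
    prev = list(range(n + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        ai = a[i - 1]
        for j in range(1, n + 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1,
                         prev[j - 1] + (ai != b[j - 1]))
        prev = cur
    return prev[n]


def _osa(a: list[int], b: list[int]) -> int:
    m, n = len(a), len(b)
    rows = [list(range(n + 1))]
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cost = min(rows[i - 1][j] + 1, cur[j - 1] + 1,
                       rows[i - 1][j - 1] + (a[i - 1] != b[j - 1]))
            if i > 1 and j > 1 and a[i - 1] == b[j - 2] and a[i - 2] == b[j - 1]:
                cost = min(cost, rows[i - 2][j - 2] + 1)
            cur[j] = cost
        rows.append(cur)
    return rows[m][n]


def _dl(a: list[int], b: list[int]) -> int:
    # Lowrance-Wagner: unrestricted transpositions via last-occurrence table
    m, n = len(a), len(b)
    maxdist = m + n
    alphabet = set(a) | set(b)
    da = {s: 0 for s in alphabet}
    d = np.zeros((m + 2, n + 2), dtype=int)
    d[0, :] = maxdist
    d[:, 0] = maxdist
    d[1, 1:] = np.arange(n + 1)
    d[1:, 1] = np.arange(m + 1)
    for i in range(1, m + 1):
        db = 0
        for j in range(1, n + 1):
            k = da[b[j - 1]]
            l = db
            if a[i - 1] == b[j - 1]:
                cost = 0
                db = j
            else:
                cost = 1
            d[i + 1, j + 1] = min(
                d[i, j] + cost,              # substitute / match
                d[i + 1, j] + 1,             # insert
                d[i, j + 1] + 1,             # delete
                d[k, l] + (i - k - 1) + 1 + (j - l - 1),  # transpose
            )
        da[a[i - 1]] = i
    return int(d[m + 1, n + 1])


def edit_distance(a: MoveTokenSequence, b: MoveTokenSequence,
                  method: str = "lv") -> int:
    """Token-level edit distance between two move sequences."""
    if method not in METHODS:
        raise ValueError(f"unknown edit-distance method {method!r}; "
                         f"choose from {METHODS}")
    ea, eb = _encode_pair(a, b)
    if method == "lv":
        return _lv(ea, eb)
    if method == "osa":
        return _osa(ea, eb)
    return _dl(ea, eb)


@dataclass
class DistanceMatrix:
    d: np.ndarray
    method: str

    @property
    def n(self) -> int:
        return self.d.shape[0]


def _lv_matrix(encoded: list[np.ndarray]) -> np.ndarray:
    """All-pairs Levenshtein via a vectorized row-DP.

    The inner minimum over deletions (a same-row prefix dependency) is
    rewritten as min_k (cur[k] - k) + j, a cumulative minimum.
    """
    n = len(encoded)
    out = np.zeros((n, n), dtype=int)
    for i in range(n):
        a = encoded[i]
        for j in range(i + 1, n):
            b = encoded[j]
            if len(a) == 0 or len(b) == 0:
                out[i, j] = out[j, i] = max(len(a), len(b))
                continue
            prev = np.arange(len(b) + 1)
            jj = np.arange(len(b) + 1)
            for r, sym in enumerate(a, start=1):
                sub = prev[:-1] + (b != sym)
                cur = np.empty_like(prev)
                cur[0] = r
                cur[1:] = np.minimum(prev[1:] + 1, sub)
                cur = np.minimum.accumulate(cur - jj) + jj
                prev = cur
            out[i, j] = out[j, i] = prev[-1]
    return out


def distance_matrix(sequences: Sequence[MoveTokenSequence],
                    method: str = "lv") -> DistanceMatrix:
    """Symmetric matrix of pairwise edit distances."""
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences")
    if method not in METHODS:
        raise ValueError(f"unknown edit-distance method {method!r}")
    if method == "lv":
        vocab: dict[str, int] = {}
        encoded = []
        for s in sequences:
            for tok in s:
                vocab.setdefault(tok, len(vocab))
            encoded.append(np.array([vocab[t] for t in s], dtype=np.int32))
        return DistanceMatrix(_lv_matrix(encoded), method)
    n = len(sequences)
    d = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = edit_distance(sequences[i], sequences[j], method)
    return DistanceMatrix(d, method)


@dataclass
class MdsEmbedding:
    coords: np.ndarray          # n x k, columns ordered by decreasing eigenvalue
    eigenvalues: np.ndarray     # all n scaling eigenvalues, descending
    n_negative: int             # count of negative eigenvalues truncated

    @property
    def k(self) -> int:
        return self.coords.shape[1]


def classical_mds(dist: DistanceMatrix | np.ndarray, k: int = 2) -> MdsEmbedding:
    """Torgerson classical scaling of a distance matrix.

    Coordinates are centered at the origin; columns are ordered by
    decreasing eigenvalue and sign-fixed (largest-magnitude loading
    positive) for determinism.
    """
    d = dist.d if isinstance(dist, DistanceMatrix) else np.asarray(dist, float)
    n = d.shape[0]
    if k >= n:
        raise ValueError(f"k must be < n (got k={k}, n={n})")
    d = np.asarray(d, dtype=float)
    j_mat = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j_mat @ (d**2) @ j_mat
    # symmetrize against rounding before eigh
    b = 0.5 * (b + b.T)
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    lam = np.clip(evals[:k], 0.0, None)
    coords = evecs[:, :k] * np.sqrt(lam)
    for col in range(coords.shape[1]):
        c = coords[:, col]
        if c.size and c[np.argmax(np.abs(c))] < 0:
            coords[:, col] = -c
    return MdsEmbedding(coords=coords, eigenvalues=evals,
                        n_negative=int((evals < -1e-9).sum()))


@dataclass
class EraOccupancy:
    """Embedded point indices per era, with the cumulative prior-era
    background (the grey underlay of era-wise occupancy maps)."""

    era_order: list
    points: dict                # era -> array of row indices
    background: dict            # era -> array of indices from earlier eras


def era_occupancy(embedding: MdsEmbedding, eras: Sequence) -> EraOccupancy:
    """Partition embedded games by era, attaching cumulative backgrounds."""
    if len(eras) != embedding.coords.shape[0]:
        raise ValueError("era labels and embedding rows differ in length")
    order = sorted(set(eras), key=lambda e: getattr(e, "start_year", e))
    points: dict = {}
    background: dict = {}
    seen: list[int] = []
    for era in order:
        idx = np.array([i for i, e in enumerate(eras) if e == era], dtype=int)
        points[era] = idx
        background[era] = np.array(seen, dtype=int)
        seen.extend(idx.tolist())
    return EraOccupancy(era_order=order, points=points, background=background)
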