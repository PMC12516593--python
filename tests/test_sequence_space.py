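"""Edit distances against independent oracles; classical-MDS exactness."""

from functools import lru_cache

import edlib
import numpy as np
import pytest

from fuseki.sequence_space import (classical_mds, distance_matrix,
                                   edit_distance, era_occupancy)

# ---------------------------------------------------------------------------
# independent oracles (recursive definitions, memoized)


def oracle_lv(a, b):
    a, b = tuple(a), tuple(b)

    @lru_cache(maxsize=None)
    def d(i, j):
        if i == 0:
            return j
        if j == 0:
            return i
        return min(d(i - 1, j) + 1, d(i, j - 1) + 1,
                   d(i - 1, j - 1) + (a[i - 1] != b[j - 1]))

    return d(len(a), len(b))


def oracle_osa(a, b):
    a, b = tuple(a), tuple(b)

    @lru_cache(maxsize=None)
    def d(i, j):
        if min(i, j) == 0:
            return max(i, j)
        best = min(d(i - 1, j) + 1, d(i, j - 1) + 1,
                   d(i - 1, j - 1) + (a[i - 1] != b[j - 1]))
        if i > 1 and j > 1 and a[i - 1] == b[j - 2] and a[i - 2] == b[j - 1]:
            best = min(best, d(i - 2, j - 2) + 1)
        return best

    return d(len(a), len(b))


def oracle_dl(a, b):
    """Unrestricted Damerau-Levenshtein by brute-force search over edit
    scripts, implemented as BFS over sequence states (small inputs only)."""
    from collections import deque

    a, b = tuple(a), tuple(b)
    limit = len(a) + len(b)
    seen = {a: 0}
    queue = deque([a])
    alphabet = set(a) | set(b)
    while queue:
        s = queue.popleft()
        cost = seen[s]
        if s == b:
            return cost
        if cost >= limit:
            continue
        neighbours = set()
        for i in range(len(s) + 1):
            for sym in alphabet:                       # insertion
                neighbours.add(s[:i] + (sym,) + s[i:])
        for i in range(len(s)):
            neighbours.add(s[:i] + s[i + 1:])          # deletion
            for sym in alphabet:                       # substitution
                neighbours.add(s[:i] + (sym,) + s[i + 1:])
        for i in range(len(s) - 1):                    # adjacent transposition
            neighbours.add(s[:i] + (s[i + 1], s[i]) + s[i + 2:])
        for t in neighbours:
            if len(t) <= limit and t not in seen:
                seen[t] = cost + 1
                queue.append(t)
    raise AssertionError("unreachable")


def edlib_lv(a, b):
    symbols = {tok: chr(33 + i) for i, tok in enumerate({*a, *b})}
    return edlib.align("".join(symbols[t] for t in a),
                       "".join(symbols[t] for t in b))["editDistance"]


def random_tokens(rng, max_len=10, vocab=8):
    return [f"T{int(v)}" for v in
            rng.integers(0, vocab, size=int(rng.integers(0, max_len + 1)))]


# ---------------------------------------------------------------------------
# edit distance


GAME_1 = "R16,D17,Q3,O16,Q14,D4,D15,C15,C14,C16,D14,E16,C10,K3,N3,R6,F3,R3,R4"
GAME_2 = "R16,D17,Q3,C3,D15,P16,P17,O17,Q17,C15,C14,C16,D14,E16,D10,D8,O16,Q5"


def test_identical_sequences_have_zero_distance():
    seq = GAME_1.split(",")
    for method in ("lv", "osa", "dl"):
        assert edit_distance(seq, seq, method) == 0


def test_empty_versus_sequence_costs_its_length():
    seq = ["Q16", "D16", "R4"]
    for method in ("lv", "osa", "dl"):
        assert edit_distance([], seq, method) == 3
        assert edit_distance(seq, [], method) == 3


def test_printed_game_pair_regression_fixture():
    """The two similar published openings (19 and 18 moves): distance was
    pre-registered with an independent DP oracle before implementation."""
    a, b = GAME_1.split(","), GAME_2.split(",")
    assert edit_distance(a, b, "lv") == 13
    assert edit_distance(a, b, "osa") == 13
    assert oracle_lv(a, b) == 13
    # similar games are far closer than the all-different ceiling
    assert 13 < max(len(a), len(b))


def test_transposition_methods_differ_from_levenshtein():
    a, b = ["C", "A"], ["A", "B", "C"]
    assert edit_distance(a, b, "lv") == 3
    assert edit_distance(a, b, "osa") == 3     # osa cannot reuse transposed pair
    assert edit_distance(a, b, "dl") == 2      # transpose then insert


def test_unknown_method_rejected():
    with pytest.raises(ValueError):
        edit_distance(["A"], ["B"], "hamming")


def test_all_methods_match_oracles_on_random_pairs(rng):
    for _ in range(60):
        a, b = random_tokens(rng), random_tokens(rng)
        assert edit_distance(a, b, "lv") == oracle_lv(a, b) == edlib_lv(a, b)
        assert edit_distance(a, b, "osa") == oracle_osa(a, b)


def test_dl_matches_bfs_oracle_on_small_pairs(rng):
    for _ in range(25):
        a, b = random_tokens(rng, max_len=4, vocab=3), random_tokens(
            rng, max_len=4, vocab=3)
        assert edit_distance(a, b, "dl") == oracle_dl(a, b)


def test_levenshtein_metric_axioms(rng):
    seqs = [random_tokens(rng, max_len=6) for _ in range(12)]
    for a in seqs:
        for b in seqs:
            dab = edit_distance(a, b, "lv")
            assert dab == edit_distance(b, a, "lv")
            assert (dab == 0) == (a == b)
            for c in seqs:
                assert dab <= (edit_distance(a, c, "lv")
                               + edit_distance(c, b, "lv"))


def test_distance_matrix_matches_pairwise_calls(rng):
    seqs = [random_tokens(rng) for _ in range(15)]
    for method in ("lv", "osa"):
        mat = distance_matrix(seqs, method).d
        assert np.array_equal(mat, mat.T)
        assert np.all(np.diag(mat) == 0)
        for i in range(len(seqs)):
            for j in range(len(seqs)):
                assert mat[i, j] == edit_distance(seqs[i], seqs[j], method)


def test_distance_matrix_of_identical_games_is_zero():
    seqs = [GAME_1.split(",")] * 3
    assert not distance_matrix(seqs, "lv").d.any()


def test_distance_matrix_needs_two_sequences():
    with pytest.raises(ValueError):
        distance_matrix([["Q16"]], "lv")


# ---------------------------------------------------------------------------
# classical MDS


def pairwise(x):
    return np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))


def test_mds_equilateral_triangle():
    c = 4.0
    d = np.full((3, 3), c) - c * np.eye(3)
    emb = classical_mds(d, k=2)
    np.testing.assert_allclose(pairwise(emb.coords), d, atol=1e-9)


def test_mds_collinear_points_recover_positions():
    n = 7
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n))).astype(float)
    emb = classical_mds(d, k=2)
    # one dominant axis; pairwise distances reproduced exactly
    assert emb.eigenvalues[0] > 1e-9 and abs(emb.eigenvalues[1]) < 1e-9
    np.testing.assert_allclose(pairwise(emb.coords), d, atol=1e-9)


def test_mds_reproduces_euclidean_distances(rng):
    for _ in range(10):
        x = rng.normal(size=(12, 2))
        emb = classical_mds(pairwise(x), k=2)
        np.testing.assert_allclose(pairwise(emb.coords), pairwise(x),
                                   atol=1e-9)
        np.testing.assert_allclose(emb.coords.mean(axis=0), 0, atol=1e-9)


def test_mds_duplicate_points_coincide(rng):
    x = rng.normal(size=(6, 2))
    x[3] = x[0]
    emb = classical_mds(pairwise(x), k=2)
    np.testing.assert_allclose(emb.coords[3], emb.coords[0], atol=1e-9)


def test_mds_negative_eigenvalues_reported():
    # a non-Euclidean dissimilarity (violates triangle inequality)
    d = np.array([[0, 1, 1, 1], [1, 0, 1, 1], [1, 1, 0, 10],
                  [1, 1, 10, 0]], dtype=float)
    emb = classical_mds(d, k=2)
    assert emb.n_negative > 0


def test_mds_deterministic_sign_convention(rng):
    x = rng.normal(size=(9, 2))
    a = classical_mds(pairwise(x), k=2)
    b = classical_mds(pairwise(x), k=2)
    np.testing.assert_array_equal(a.coords, b.coords)
    for col in range(2):
        c = a.coords[:, col]
        assert c[np.argmax(np.abs(c))] >= 0


def test_mds_k_must_be_less_than_n():
    with pytest.raises(ValueError):
        classical_mds(np.zeros((3, 3)), k=3)


def test_era_occupancy_backgrounds_are_cumulative(rng):
    x = rng.normal(size=(12, 2))
    emb = classical_mds(pairwise(x), k=2)
    eras = [1600, 1900, 1900, 2000] * 3
    occ = era_occupancy(emb, eras)
    assert occ.era_order == [1600, 1900, 2000]
    assert occ.background[1600].size == 0
    assert set(occ.background[1900]) == set(occ.points[1600])
    assert set(occ.background[2000]) == (set(occ.points[1600])
                                         | set(occ.points[1900]))
    with pytest.raises(ValueError):
        era_occupancy(emb, eras[:-1])
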