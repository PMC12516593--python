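"""Variant frequencies, Hill-number diversity, Jensen–Shannon divergence,
and bootstrapped time series.

An opening *variant* is the comma-joined Korschelt label of a game's first
``depth`` canonical moves (depth 2 by default: Black's first move and
White's response, e.g. ``"Q16,D16"``). Diversity of a variant assemblage is
summarized by Hill numbers

    qD = (Σ p_i^q)^(1/(1-q)),   1D = exp(H'),  H' = -Σ p_i ln p_i,

the "effective number" of equally common variants: q = 0 gives richness,
q = 1 the exponential of Shannon entropy, q = 2 the inverse Simpson index.
Change between two assemblages is the Jensen–Shannon divergence, the mean
Kullback–Leibler divergence of each distribution from their average.

Because sample sizes differ enormously across time periods, per-bin
statistics are rarefied by a bootstrap: ``n_draw`` games are resampled per
bin, the statistic computed, and the result averaged over ``n_iter``
iterations. For the divergence-versus-previous-bin series, draws are paired
across adjacent bins within an iteration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .board import point_to_korschelt
from .corpus import GameRecord, TimeBin
from .canonical import canonicalize_game

INCOMPLETE_PAD = "-"

_FLOAT_TOL = 1e-12


def variant_label(game: GameRecord, depth: int = 2, canonicalized: bool = True) -> str:
    """Comma-joined Korschelt label of the first ``depth`` canonical moves.

    Games shorter than ``depth`` are padded with ``"-"`` (and thereby marked
    incomplete; see :func:`label_is_complete`).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not game.moves:
        raise ValueError("cannot label a game with no moves")
    moves = game.moves if canonicalized else canonicalize_game(game.moves)[0]
    tokens = [point_to_korschelt(p) for p in moves[:depth]]
    tokens += [INCOMPLETE_PAD] * (depth - len(tokens))
    return ",".join(tokens)


def label_is_complete(label: str) -> bool:
    return INCOMPLETE_PAD not in label.split(",")


@dataclass
class VariantDistribution:
    """Relative frequencies of opening variants in a set of games."""

    labels: list[str]
    freqs: np.ndarray
    n_games: int
    n_incomplete: int = 0

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if len(self.labels) != len(self.freqs):
            raise ValueError("labels and freqs differ in length")
        if len(self.freqs) and (self.freqs <= 0).any():
            raise ValueError("listed variants must have positive frequency")
        if len(self.freqs) and abs(self.freqs.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must sum to 1")

    @classmethod
    def from_counts(cls, counts: Mapping[str, int],
                    n_incomplete: int = 0) -> "VariantDistribution":
        items = sorted((k, v) for k, v in counts.items() if v > 0)
        total = sum(v for _, v in items)
        if total == 0:
            raise ValueError("empty distribution: no games with complete labels")
        labels = [k for k, _ in items]
        freqs = np.array([v / total for _, v in items])
        return cls(labels, freqs, n_games=total, n_incomplete=n_incomplete)

    @property
    def richness(self) -> int:
        return len(self.labels)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.labels, self.freqs))


def tally_variants(games: Sequence[GameRecord], depth: int = 2,
                   canonicalized: bool = True) -> VariantDistribution:
    """Variant frequency distribution over games with complete labels.

    Games with fewer than ``depth`` moves are excluded from the frequencies
    and reported in ``n_incomplete``.
    """
    counts: dict[str, int] = {}
    n_incomplete = 0
    for g in games:
        lab = variant_label(g, depth, canonicalized=canonicalized)
        if label_is_complete(lab):
            counts[lab] = counts.get(lab, 0) + 1
        else:
            n_incomplete += 1
    return VariantDistribution.from_counts(counts, n_incomplete=n_incomplete)


@dataclass(frozen=True)
class DiversityValue:
    q: float
    value: float


def hill_from_freqs(freqs: np.ndarray, q: float) -> float:
    """Hill number of order ``q`` for a frequency vector (zeros ignored)."""
    p = np.asarray(freqs, dtype=float)
    p = p[p > 0]
    if p.size == 0:
        raise ValueError("empty distribution")
    if q < 0:
        raise ValueError("order q must be non-negative")
    if q == 0:
        return float(p.size)
    if abs(q - 1.0) < _FLOAT_TOL:
        return float(np.exp(-(p * np.log(p)).sum()))
    return float((p**q).sum() ** (1.0 / (1.0 - q)))


def hill_diversity(dist: VariantDistribution, q: float = 1.0) -> DiversityValue:
    """Hill diversity ``qD`` of a variant distribution."""
    return DiversityValue(q=q, value=hill_from_freqs(dist.freqs, q))


def shannon_diversity(dist: VariantDistribution) -> float:
    """``1D = exp(H')``, the effective number of variants."""
    return hill_from_freqs(dist.freqs, 1.0)


def _align(P: VariantDistribution, Q: VariantDistribution
           ) -> tuple[list[str], np.ndarray, np.ndarray]:
    labels = sorted(set(P.labels) | set(Q.labels))
    pd_, qd_ = P.as_dict(), Q.as_dict()
    p = np.array([pd_.get(l, 0.0) for l in labels])
    q = np.array([qd_.get(l, 0.0) for l in labels])
    return labels, p, q


def _kl(p: np.ndarray, m: np.ndarray, log) -> float:
    mask = p > 0
    return float((p[mask] * log(p[mask] / m[mask])).sum())


@dataclass
class DivergencePair:
    labels: list[str]
    p: np.ndarray
    q: np.ndarray
    m: np.ndarray
    jsd: float
    log_base: float


def jsd(P: VariantDistribution, Q: VariantDistribution,
        log_base: float = 2.0) -> DivergencePair:
    """Jensen–Shannon divergence between two variant distributions.

    Distributions are zero-padded to the union of their labels;
    ``JSD = ½ KL(P‖M) + ½ KL(Q‖M)`` with ``M = (P+Q)/2`` and the convention
    ``0·log(0/m) = 0``. With base-2 logarithms the result lies in [0, 1].
    """
    labels, p, q = _align(P, Q)
    return DivergencePair(labels, p, q, *(_jsd_arrays(p, q, log_base)),
                          log_base=log_base)


def _jsd_arrays(p: np.ndarray, q: np.ndarray,
                log_base: float = 2.0) -> tuple[np.ndarray, float]:
    if log_base == 2.0:
        log = np.log2
    elif log_base == np.e:
        log = np.log
    else:
        def log(x, b=log_base):
            return np.log(x) / np.log(b)
    m = 0.5 * (p + q)
    value = 0.5 * _kl(p, m, log) + 0.5 * _kl(q, m, log)
    # clip tiny negative rounding
    return m, max(value, 0.0)


def jsd_value(P: VariantDistribution, Q: VariantDistribution,
              log_base: float = 2.0) -> float:
    return jsd(P, Q, log_base).jsd


# ---------------------------------------------------------------------------
# bootstrap time series

STATISTICS = ("shannon_diversity", "jsd_vs_previous")


@dataclass
class BootstrapSeries:
    """Per-bin bootstrap-averaged statistic with its Monte-Carlo spread."""

    bins: list[TimeBin]
    stat_mean: np.ndarray          # NaN where undefined (empty bin / first bin)
    mc_se: np.ndarray              # bootstrap SE of the mean across iterations
    n_games: list[int]
    statistic: str
    n_draw: int
    n_iter: int
    seed: int
    depth: int = 2
    warnings_: list[str] = field(default_factory=list)


def _bin_label_indices(games: Sequence[GameRecord], depth: int
                       ) -> tuple[np.ndarray, list[str]]:
    """Integer-coded complete variant labels for one bin's games."""
    labels = []
    for g in games:
        if len(g.moves) >= depth:
            labels.append(variant_label(g, depth))
    uniq = sorted(set(labels))
    index = {l: i for i, l in enumerate(uniq)}
    return np.array([index[l] for l in labels], dtype=np.intp), uniq


def bootstrap_series(
    games_by_bin: Mapping[TimeBin, Sequence[GameRecord]],
    statistic: str = "shannon_diversity",
    depth: int = 2,
    n_draw: int = 100,
    n_iter: int = 100,
    seed: int = 0,
    log_base: float = 2.0,
    replace: bool = True,
) -> BootstrapSeries:
    """Bootstrap-rarefied per-bin statistic series.

    For each bin and iteration, ``n_draw`` games are drawn (with
    replacement by default) and the statistic evaluated on the draw's
    variant tally; ``jsd_vs_previous`` compares against the same-iteration
    draw of the preceding non-empty bin. Per-bin values are the mean over
    iterations; fully reproducible from ``seed``.
    """
    if statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; choose from {STATISTICS}")
    rng = np.random.default_rng(seed)
    bins = sorted(games_by_bin)
    means = np.full(len(bins), np.nan)
    ses = np.full(len(bins), np.nan)
    n_games = []
    notes: list[str] = []

    # per-bin, per-iteration variant count matrices (n_iter x n_variants)
    draw_counts: list[np.ndarray | None] = []
    global_codes: list[np.ndarray | None] = []
    for b in bins:
        games = games_by_bin[b]
        codes, uniq = _bin_label_indices(games, depth)
        n_games.append(len(codes))
        if len(codes) == 0:
            msg = f"bin {b}: no games with complete labels; statistic undefined"
            warnings.warn(msg)
            notes.append(msg)
            draw_counts.append(None)
            global_codes.append(None)
            continue
        if replace:
            draws = rng.integers(0, len(codes), size=(n_iter, n_draw))
        else:
            k = min(n_draw, len(codes))
            draws = np.stack([
                rng.permutation(len(codes))[:k] for _ in range(n_iter)
            ])
        sampled = codes[draws]  # n_iter x n_draw of local variant ids
        counts = np.stack([np.bincount(row, minlength=len(uniq)) for row in sampled])
        draw_counts.append(counts)
        global_codes.append(uniq)

    for i, b in enumerate(bins):
        counts = draw_counts[i]
        if counts is None:
            continue
        if statistic == "shannon_diversity":
            freqs = counts / counts.sum(axis=1, keepdims=True)
            with np.errstate(divide="ignore", invalid="ignore"):
                logs = np.where(freqs > 0, np.log(np.where(freqs > 0, freqs, 1.0)), 0.0)
            vals = np.exp(-(freqs * logs).sum(axis=1))
        else:  # jsd_vs_previous
            j = i - 1
            while j >= 0 and draw_counts[j] is None:
                j -= 1
            if j < 0:
                continue  # no previous bin: undefined
            prev_counts, prev_labels = draw_counts[j], global_codes[j]
            labels_i = global_codes[i]
            union = sorted(set(labels_i) | set(prev_labels))
            pos = {l: k for k, l in enumerate(union)}
            p = np.zeros((counts.shape[0], len(union)))
            q = np.zeros_like(p)
            p[:, [pos[l] for l in labels_i]] = counts / counts.sum(axis=1, keepdims=True)
            q[:, [pos[l] for l in prev_labels]] = (
                prev_counts / prev_counts.sum(axis=1, keepdims=True))
            vals = np.array([
                _jsd_arrays(p[r], q[r], log_base)[1] for r in range(p.shape[0])
            ])
        means[i] = vals.mean()
        ses[i] = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0

    return BootstrapSeries(
        bins=bins, stat_mean=means, mc_se=ses, n_games=n_games,
        statistic=statistic, n_draw=n_draw, n_iter=n_iter, seed=seed,
        depth=depth, warnings_=notes,
    )
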