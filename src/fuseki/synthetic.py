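"""Synthetic GoGoD-like corpora with known ground truth.

The commercial archive the pipeline is designed for cannot be
redistributed, so every stage is exercised on generated corpora that
emulate its structure: six historical eras with exponentially growing game
counts, skewed (Zipf-like) era-specific opening-variant distributions with
turnover between eras and a pronounced repertoire shift at the start of
the superhuman-AI era, players organized into latent communities who
preferentially play within their community, per-game random board-symmetry
scrambling (so canonicalization is exercised), and the archive's data
blemishes — handicap games, missing dates, and AI-flagged players.

Every quantity the pipeline estimates is recorded in a
:class:`GroundTruth` object at generation time, enabling end-to-end
parameter-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .board import BoardPoint, all_points, korschelt_to_point, point_to_korschelt
from .canonical import TRANSFORMS, canonicalize_game
from .corpus import ERAS, GameDate, GameRecord, era_by_name
from .diversity import VariantDistribution, hill_from_freqs, _jsd_arrays

#: Two-move opening labels drawn from well-known corner openings (4-4, 3-4
#: and 3-3 first moves with standard responses). Stored pre-canonicalization;
#: the generator canonicalizes them once so planted labels match pipeline
#: labels exactly.
VARIANT_POOL: tuple[str, ...] = (
    "Q16,D16", "Q16,D4", "Q16,D17", "Q16,C4", "Q16,C15", "Q16,C16",
    "Q16,D15", "Q16,E16", "Q17,D17", "Q17,D3", "Q17,Q3", "Q17,C16",
    "Q17,D16", "Q17,R4", "Q17,C3", "Q17,D4", "R17,D17", "R17,C3",
    "R17,D16", "R17,C10", "R17,C4", "R17,E16", "R17,D15", "R17,C16",
)


def _canonical_label(label: str) -> str:
    pts = [korschelt_to_point(tok) for tok in label.split(",")]
    canon, _ = canonicalize_game(pts)
    return ",".join(point_to_korschelt(p) for p in canon)


@dataclass
class EraSpec:
    """Generation parameters for one era."""

    name: str                              # must match an era label name
    n_games: int
    n_players: int
    n_communities: int
    within_community_match_prob: float = 0.9
    pool_offset: int = 0                   # rotation into the variant pool
    n_variants: int = 12
    zipf_exponent: float = 1.2
    opening_weights: dict[str, float] | None = None   # overrides the Zipf pool
    continuation_depth: int = 12
    continuation_branching: int = 3

    def distribution(self) -> tuple[list[str], np.ndarray]:
        """Planted (canonical-label, probability) pairs for this era."""
        if self.opening_weights is not None:
            labels = [_canonical_label(l) for l in self.opening_weights]
            w = np.array(list(self.opening_weights.values()), dtype=float)
        else:
            pool = [_canonical_label(l) for l in VARIANT_POOL]
            idx = [(self.pool_offset + i) % len(pool) for i in range(self.n_variants)]
            labels = [pool[i] for i in idx]
            w = 1.0 / np.arange(1, len(labels) + 1) ** self.zipf_exponent
        if len(set(labels)) != len(labels):
            raise ValueError("variant pool collapses under canonicalization")
        return labels, w / w.sum()


@dataclass
class GeneratorConfig:
    eras: list[EraSpec]
    seed: int
    handicap_fraction: float = 0.04
    missing_date_fraction: float = 0.006
    ai_player_fraction: float = 0.05       # of games in eras starting >= 2016
    komi: float = 6.5

    def __post_init__(self) -> None:
        for f in (self.handicap_fraction, self.missing_date_fraction,
                  self.ai_player_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        for spec in self.eras:
            if spec.n_communities > spec.n_players:
                raise ValueError(
                    f"era {spec.name}: more communities than players")
            if spec.n_players < 2:
                raise ValueError(f"era {spec.name}: need at least 2 players")


def default_config(seed: int, total_games: int = 20_000) -> GeneratorConfig:
    """The standard study-shaped corpus: six eras, exponential growth of
    games and players, moderate variant turnover between eras and a large
    repertoire shift at 2016."""
    weights = {"EarlyModern": 0.03, "Imperial": 0.09, "ColdWar": 0.12,
               "International": 0.16, "Internet": 0.275, "SAI": 0.325}
    players = {"EarlyModern": 60, "Imperial": 200, "ColdWar": 400,
               "International": 700, "Internet": 1200, "SAI": 1500}
    communities = {"EarlyModern": 3, "Imperial": 5, "ColdWar": 8,
                   "International": 10, "Internet": 12, "SAI": 12}
    offsets = {"EarlyModern": 0, "Imperial": 2, "ColdWar": 4,
               "International": 6, "Internet": 8, "SAI": 16}
    # era-specific skew: a diversity rise into the mid-20th century, a dip
    # in the internet years, partial recovery after 2016
    zipf = {"EarlyModern": 1.6, "Imperial": 1.15, "ColdWar": 0.85,
            "International": 0.95, "Internet": 1.3, "SAI": 1.1}
    eras = [
        EraSpec(
            name=e.name,
            n_games=round(total_games * weights[e.name]),
            n_players=players[e.name],
            n_communities=communities[e.name],
            pool_offset=offsets[e.name],
            zipf_exponent=zipf[e.name],
        )
        for e in ERAS
    ]
    return GeneratorConfig(eras=eras, seed=seed)


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    era_distributions: dict[str, dict[str, float]]
    era_hill1: dict[str, float]
    communities: dict[str, dict[str, int]]       # era -> player -> community
    games: pd.DataFrame                          # per-game flags and labels
    step_change_year: int | None                 # None for single-era configs
    seed: int


def _true_step_change_year(config: GeneratorConfig) -> int | None:
    """The era boundary with the largest jump between planted
    distributions; ``None`` when there is only one era."""
    best_year, best_jsd = None, -1.0
    for prev, curr in zip(config.eras, config.eras[1:]):
        lp, wp = prev.distribution()
        lc, wc = curr.distribution()
        union = sorted(set(lp) | set(lc))
        p = np.array([dict(zip(lp, wp)).get(l, 0.0) for l in union])
        q = np.array([dict(zip(lc, wc)).get(l, 0.0) for l in union])
        val = _jsd_arrays(q, p)[1]
        year = era_by_name(curr.name).start_year
        if val > best_jsd:
            best_year, best_jsd = year, val
    return best_year


def _continuation(prefix: tuple[BoardPoint, ...], depth: int, branching: int,
                  cache: dict, rng: np.random.Generator,
                  points: list[BoardPoint]) -> list[BoardPoint]:
    """Extend a two-move prefix by a conditional branching process.

    Each prefix has a cached set of ``branching`` candidate next moves with
    geometric popularity weights, so games sharing a prefix share likely
    continuations — enough structure for edit-distance clustering and tree
    pruning to have something to find.
    """
    moves = list(prefix)
    while len(moves) < depth:
        key = tuple(moves)
        if key not in cache:
            used = set(moves)
            candidates = []
            while len(candidates) < branching:
                p = points[rng.integers(0, len(points))]
                if p not in used and p not in candidates:
                    candidates.append(p)
            w = 0.55 ** np.arange(branching)
            cache[key] = (candidates, w / w.sum())
        candidates, w = cache[key]
        nxt = candidates[rng.choice(len(candidates), p=w)]
        if nxt in moves:       # candidate clashes with a later duplicate path
            nxt = next(p for p in points if p not in moves)
        moves.append(nxt)
    return moves


def generate_corpus(config: GeneratorConfig
                    ) -> tuple[list[GameRecord], GroundTruth]:
    """Generate a corpus of game records plus its ground truth.

    Fully deterministic given ``config.seed``; two identical-seed calls
    produce identical records (and hence byte-identical SGF output).
    """
    rng = np.random.default_rng(config.seed)
    points = all_points()
    records: list[GameRecord] = []
    rows: list[dict] = []
    era_distributions: dict[str, dict[str, float]] = {}
    era_hill1: dict[str, float] = {}
    communities: dict[str, dict[str, int]] = {}
    nationalities = ("JP", "CN", "KR", "TW")

    for spec in config.eras:
        era = era_by_name(spec.name)
        labels, probs = spec.distribution()
        era_distributions[spec.name] = dict(zip(labels, probs))
        era_hill1[spec.name] = hill_from_freqs(probs, 1.0)
        label_points = {
            l: tuple(korschelt_to_point(t) for t in l.split(",")) for l in labels}

        players = [f"{spec.name}_p{i:04d}" for i in range(spec.n_players)]
        membership = {
            p: i * spec.n_communities // spec.n_players
            for i, p in enumerate(players)}
        communities[spec.name] = membership
        by_comm: list[list[str]] = [[] for _ in range(spec.n_communities)]
        for p, c in membership.items():
            by_comm[c].append(p)

        cache: dict = {}
        years = rng.integers(era.start_year, era.end_year + 1, size=spec.n_games)
        variant_ids = rng.choice(len(labels), size=spec.n_games, p=probs)
        for i in range(spec.n_games):
            if rng.random() < spec.within_community_match_prob:
                comm = by_comm[rng.integers(0, spec.n_communities)]
                while len(comm) < 2:
                    comm = by_comm[rng.integers(0, spec.n_communities)]
                a, b = rng.choice(len(comm), size=2, replace=False)
                black, white = comm[a], comm[b]
            else:
                c1, c2 = rng.choice(spec.n_communities, size=2, replace=False)
                black = by_comm[c1][rng.integers(0, len(by_comm[c1]))]
                white = by_comm[c2][rng.integers(0, len(by_comm[c2]))]
            label = labels[variant_ids[i]]
            moves = _continuation(label_points[label], spec.continuation_depth,
                                  spec.continuation_branching, cache, rng, points)
            t = TRANSFORMS[rng.integers(0, len(TRANSFORMS))]
            scrambled = t.apply_sequence(moves)
            gid = f"{spec.name}_g{i:05d}"
            records.append(GameRecord(
                moves=scrambled,
                date=GameDate(int(years[i])),
                black_player=black,
                white_player=white,
                nationality_black=nationalities[membership[black] % len(nationalities)],
                nationality_white=nationalities[membership[white] % len(nationalities)],
                komi=config.komi if era.start_year >= 1946 else None,
                result="B+R" if rng.random() < 0.5 else "W+R",
                game_id=gid,
            ))
            rows.append({
                "game_id": gid, "era": spec.name, "year": int(years[i]),
                "variant": label, "handicap": False, "missing_date": False,
                "ai": False, "transform": t.name,
            })

    n = len(records)
    n_handicap = round(config.handicap_fraction * n)
    n_undated = round(config.missing_date_fraction * n)
    for idx in rng.choice(n, size=n_handicap, replace=False):
        records[idx].handicap = 2
        rows[idx]["handicap"] = True
    for idx in rng.choice(n, size=n_undated, replace=False):
        records[idx].date = None
        rows[idx]["missing_date"] = True
    ai_eligible = [i for i, r in enumerate(rows)
                   if era_by_name(r["era"]).start_year >= 2016]
    n_ai = round(config.ai_player_fraction * len(ai_eligible))
    if n_ai:
        for idx in rng.choice(len(ai_eligible), size=n_ai, replace=False):
            i = ai_eligible[idx]
            records[i].is_ai_white = True
            rows[i]["ai"] = True

    for row in rows:     # single-reason removal attribution, priority order
        if row["handicap"]:
            row["removal_reason"] = "handicap"
        elif row["missing_date"]:
            row["removal_reason"] = "undated"
        elif row["ai"]:
            row["removal_reason"] = "ai"
        else:
            row["removal_reason"] = None

    truth = GroundTruth(
        era_distributions=era_distributions,
        era_hill1=era_hill1,
        communities=communities,
        games=pd.DataFrame(rows),
        step_change_year=_true_step_change_year(config),
        seed=config.seed,
    )
    return records, truth


# ---------------------------------------------------------------------------
# recovery reporting


def plugin_hill1(labels: Sequence[str]) -> float:
    """Plug-in ^1D of a label sample with the Miller–Madow entropy
    correction (adds (S−1)/2n to H' before exponentiating), removing the
    small-sample downward bias of the naive estimator."""
    values, counts = np.unique(np.asarray(labels), return_counts=True)
    p = counts / counts.sum()
    h = -(p * np.log(p)).sum() + (len(values) - 1) / (2 * counts.sum())
    return float(np.exp(h))


def hill1_with_se(labels: Sequence[str], n_boot: int = 100,
                  rng: np.random.Generator | None = None
                  ) -> tuple[float, float]:
    """Bias-corrected ^1D of a sample plus its bootstrap standard error."""
    rng = rng or np.random.default_rng(0)
    arr = np.asarray(labels)
    est = plugin_hill1(arr)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        boots[b] = plugin_hill1(arr[rng.integers(0, len(arr), size=len(arr))])
    return est, float(boots.std(ddof=1))


def jsd_noise_floor(dist: VariantDistribution, n_bin_a: int, n_bin_b: int,
                    n_draw: int = 100, n_iter: int = 300,
                    rng: np.random.Generator | None = None) -> float:
    """Sampling noise floor for the bootstrapped divergence between two
    time bins drawn from the *same* stationary distribution.

    Mimics the estimator's full sampling chain: a bin of ``n_bin`` games is
    itself a finite sample from the true distribution, and the bootstrap
    then redraws ``n_draw`` games from that bin. Returns the Monte-Carlo
    mean + 3 SD of the resulting JSD; observed within-era divergences
    above this are evidence of real change, not sample-size noise.
    """
    rng = rng or np.random.default_rng(0)
    p = dist.freqs
    vals = np.empty(n_iter)
    emp_a = rng.multinomial(n_bin_a, p, size=n_iter) / n_bin_a
    emp_b = rng.multinomial(n_bin_b, p, size=n_iter) / n_bin_b
    for i in range(n_iter):
        qa = rng.multinomial(n_draw, emp_a[i]) / n_draw
        qb = rng.multinomial(n_draw, emp_b[i]) / n_draw
        vals[i] = _jsd_arrays(qa, qb)[1]
    return float(vals.mean() + 3 * vals.std(ddof=1))


def recovery_report(
    truth: GroundTruth,
    era_hill1_est: Mapping[str, tuple[float, float]] | None = None,
    community_counts: Mapping[str, int] | None = None,
    tempo_argmax_year: int | None = None,
    stationary_jsd: Mapping[str, tuple[float, float]] | None = None,
    community_tolerance: int = 2,
) -> pd.DataFrame:
    """Tabulate true vs. pipeline-estimated quantities.

    ``era_hill1_est`` maps era name to (estimate, SE); tolerance is 3 SE.
    ``community_counts`` maps era name to the detected community count;
    tolerance ±``community_tolerance``. ``tempo_argmax_year`` is compared
    exactly against the planted step-change year. ``stationary_jsd`` maps
    era name to (max observed within-era divergence, noise floor).
    """
    rows = []
    if era_hill1_est:
        for era, (est, se) in era_hill1_est.items():
            true = truth.era_hill1[era]
            tol = 3 * se
            rows.append({"quantity": f"hill1[{era}]", "true": true,
                         "estimated": est, "tolerance": tol,
                         "passed": abs(est - true) <= tol})
    if community_counts:
        for era, est in community_counts.items():
            true = len(set(truth.communities[era].values()))
            rows.append({"quantity": f"n_communities[{era}]", "true": true,
                         "estimated": est, "tolerance": community_tolerance,
                         "passed": abs(est - true) <= community_tolerance})
    if tempo_argmax_year is not None:
        rows.append({"quantity": "step_change_year",
                     "true": truth.step_change_year,
                     "estimated": tempo_argmax_year, "tolerance": 0,
                     "passed": tempo_argmax_year == truth.step_change_year})
    if stationary_jsd:
        for era, (observed, floor) in stationary_jsd.items():
            rows.append({"quantity": f"stationary_jsd[{era}]", "true": 0.0,
                         "estimated": observed, "tolerance": floor,
                         "passed": observed <= floor})
    return pd.DataFrame(rows,
                        columns=["quantity", "true", "estimated",
                                 "tolerance", "passed"])
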