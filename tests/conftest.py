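import numpy as np
import pytest
from hypothesis import settings

from fuseki.board import BoardPoint
from fuseki.corpus import GameDate, GameRecord

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_game(moves, year=2000, black="b01", white="w01", handicap=0,
              date=True, ai=False, **kw):
    """Terse GameRecord builder for tests."""
    return GameRecord(
        moves=[BoardPoint(*m) for m in moves],
        date=GameDate(year) if date else None,
        black_player=black,
        white_player=white,
        handicap=handicap,
        is_ai_black=ai,
        **kw,
    )


def random_games(rng, n, n_moves=8):
    """Random move sequences of distinct points (not canonicalized)."""
    games = []
    for _ in range(n):
        k = int(rng.integers(1, n_moves + 1))
        flat = rng.choice(361, size=k, replace=False)
        games.append([BoardPoint(int(i) // 19 + 1, int(i) % 19 + 1)
                      for i in flat])
    return games


@pytest.fixture(scope="session")
def synthetic_small():
    """A small six-era corpus with ground truth, shared across tests."""
    from fuseki.synthetic import default_config, generate_corpus

    return generate_corpus(default_config(seed=11, total_games=2500))
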