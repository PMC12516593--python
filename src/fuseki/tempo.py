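"""The tempo of opening evolution: annual frequency changes and a
Gaussian-process smoother.

For every year t, the frequencies of first-move and first-two-move variants
are compared with the previous year's, giving a change vector
Δp_i(t) = p_i(t) − p_i(t−1) over the union of variants observed in either
year (depth-1 and depth-2 changes pooled). The raw tempo statistic for the
year is the population standard deviation of that vector — large when many
variants move at once, zero for a stationary repertoire.

The raw series is smoothed by Gaussian-process regression with a
squared-exponential kernel plus observation noise,

    k(t, t') = a² exp(−(t−t')² / (2ℓ²)) + s² δ(t,t'),

with hyperparameters (a, ℓ, s) either supplied or fitted by maximizing the
log marginal likelihood. The reported band is the central 89% interval of
the Gaussian posterior for the latent function.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .corpus import GameRecord
from .diversity import VariantDistribution, tally_variants

INTERVAL_MASS = 0.89


# ---------------------------------------------------------------------------
# frequency changes


@dataclass
class AnnualChanges:
    """Per-year pooled change vectors Δp, with gap-year bookkeeping."""

    years: list[int]
    changes: dict[int, np.ndarray]
    gap_years: list[int]                  # years compared against a non-adjacent year
    per_depth: dict[int, dict[int, np.ndarray]]


def _delta(curr: VariantDistribution, prev: VariantDistribution) -> np.ndarray:
    labels = sorted(set(curr.labels) | set(prev.labels))
    c, p = curr.as_dict(), prev.as_dict()
    return np.array([c.get(l, 0.0) - p.get(l, 0.0) for l in labels])


def annual_frequency_changes(
    dists_by_year: Mapping[int, Sequence[VariantDistribution]],
) -> AnnualChanges:
    """Year-over-year frequency change vectors.

    ``dists_by_year`` maps a year to its variant distributions, one per
    depth (typically depth 1 and depth 2); per-depth change vectors are
    concatenated. A year following a gap is compared against the most
    recent prior year and flagged in ``gap_years``.
    """
    years = sorted(dists_by_year)
    changes: dict[int, np.ndarray] = {}
    per_depth: dict[int, dict[int, np.ndarray]] = {}
    gaps: list[int] = []
    for prev_year, year in zip(years, years[1:]):
        if year - prev_year > 1:
            gaps.append(year)
        prev_d = dists_by_year[prev_year]
        curr_d = dists_by_year[year]
        if len(prev_d) != len(curr_d):
            raise ValueError("inconsistent number of depths across years")
        deltas = [_delta(c, p) for c, p in zip(curr_d, prev_d)]
        changes[year] = np.concatenate(deltas)
        per_depth[year] = {i: d for i, d in enumerate(deltas)}
    return AnnualChanges(years=list(changes), changes=changes,
                         gap_years=gaps, per_depth=per_depth)


def tempo_statistic(change_vector: np.ndarray) -> float:
    """Population SD, across variants, of one year's frequency changes."""
    v = np.asarray(change_vector, dtype=float)
    if v.size == 0:
        raise ValueError("empty change vector")
    if v.size == 1:
        return 0.0
    return float(v.std(ddof=0))


def yearly_distributions(
    games: Sequence[GameRecord],
    depths: Sequence[int] = (1, 2),
    from_year: int | None = None,
    min_games: int = 1,
) -> dict[int, list[VariantDistribution]]:
    """Per-year variant distributions at the requested depths."""
    by_year: dict[int, list[GameRecord]] = {}
    for g in games:
        if g.year is None or (from_year is not None and g.year < from_year):
            continue
        by_year.setdefault(g.year, []).append(g)
    out: dict[int, list[VariantDistribution]] = {}
    for year in sorted(by_year):
        if len(by_year[year]) < min_games:
            continue
        try:
            out[year] = [tally_variants(by_year[year], depth=d) for d in depths]
        except ValueError:
            continue  # no complete labels that year
    return out


def raw_tempo_series(
    games: Sequence[GameRecord],
    depths: Sequence[int] = (1, 2),
    from_year: int | None = 1945,
    min_games: int = 1,
) -> pd.DataFrame:
    """Observed per-year tempo values (columns year, raw, n_variants, gap)."""
    dists = yearly_distributions(games, depths=depths, from_year=from_year,
                                 min_games=min_games)
    ch = annual_frequency_changes(dists)
    rows = [{"year": y, "raw": tempo_statistic(ch.changes[y]),
             "n_variants": ch.changes[y].size, "gap": y in ch.gap_years}
            for y in ch.years]
    return pd.DataFrame(rows, columns=["year", "raw", "n_variants", "gap"])


def standardized_tempo_series(
    games: Sequence[GameRecord],
    depths: Sequence[int] = (1, 2),
    from_year: int | None = 1945,
    min_games: int = 1,
) -> pd.DataFrame:
    """Alternative tempo reading: mean |Δp_i| in units of each variant's
    historical SD of annual changes (a haldane-like standardization).

    Variants whose change SD is zero across the whole series are skipped.
    """
    dists = yearly_distributions(games, depths=depths, from_year=from_year,
                                 min_games=min_games)
    years = sorted(dists)
    if len(years) < 2:
        return pd.DataFrame(columns=["year", "standardized"])
    # align every depth's variants on the global union across years
    aligned: list[np.ndarray] = []
    for d_idx in range(len(depths)):
        union = sorted({l for y in years for l in dists[y][d_idx].labels})
        mat = np.zeros((len(years), len(union)))
        for r, y in enumerate(years):
            dd = dists[y][d_idx].as_dict()
            mat[r] = [dd.get(l, 0.0) for l in union]
        aligned.append(np.diff(mat, axis=0))
    deltas = np.hstack(aligned)                  # (n_years-1) x n_variants
    sds = deltas.std(axis=0, ddof=0)
    usable = sds > 0
    rows = []
    for r, year in enumerate(years[1:]):
        vals = np.abs(deltas[r, usable]) / sds[usable]
        rows.append({"year": year,
                     "standardized": float(vals.mean()) if vals.size else 0.0})
    return pd.DataFrame(rows, columns=["year", "standardized"])


# ---------------------------------------------------------------------------
# Gaussian-process smoother


@dataclass(frozen=True)
class KernelParams:
    amplitude: float
    length_scale: float
    noise_sd: float


@dataclass
class TempoSeries:
    years: np.ndarray
    raw: np.ndarray
    smooth_mean: np.ndarray
    interval_lo: np.ndarray
    interval_hi: np.ndarray
    kernel_params: KernelParams


def _sq_exp(x1: np.ndarray, x2: np.ndarray, amp: float, ls: float) -> np.ndarray:
    d = x1[:, None] - x2[None, :]
    return amp**2 * np.exp(-0.5 * (d / ls) ** 2)


def _neg_log_marginal(theta: np.ndarray, x: np.ndarray, y: np.ndarray) -> float:
    amp, ls, noise = np.exp(theta)
    k = _sq_exp(x, x, amp, ls) + (noise**2 + 1e-10) * np.eye(len(x))
    try:
        chol = np.linalg.cholesky(k)
    except np.linalg.LinAlgError:
        return 1e10
    alpha = np.linalg.solve(chol.T, np.linalg.solve(chol, y))
    return float(0.5 * y @ alpha + np.log(np.diag(chol)).sum()
                 + 0.5 * len(x) * np.log(2 * np.pi))


def fit_kernel_params(x: np.ndarray, y: np.ndarray) -> KernelParams:
    """Maximize the log marginal likelihood over (amplitude, length-scale,
    noise SD); deterministic multi-start L-BFGS on log-parameters."""
    sd = y.std() if y.std() > 0 else 1.0
    span = max(x.max() - x.min(), 1.0)
    best = None
    for ls0 in (span / 20, span / 5, span / 2):
        theta0 = np.log([sd, ls0, sd / 2])
        res = optimize.minimize(_neg_log_marginal, theta0, args=(x, y),
                                method="L-BFGS-B")
        if best is None or res.fun < best.fun:
            best = res
    amp, ls, noise = np.exp(best.x)
    return KernelParams(float(amp), float(ls), float(noise))


def gp_smooth(
    years: Sequence[int],
    values: Sequence[float],
    kernel_params: KernelParams | str = "fit",
    interval_mass: float = INTERVAL_MASS,
) -> TempoSeries:
    """GP posterior mean and central credible band at the observed years.

    Hyperparameters are fitted by marginal-likelihood maximization unless
    supplied. A constant series is returned as-is with a near-zero band.
    """
    x = np.asarray(years, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points to smooth")
    if np.ptp(y) == 0.0:
        flat = np.full_like(y, y[0])
        return TempoSeries(x.astype(int), y, flat, flat.copy(), flat.copy(),
                           KernelParams(0.0, 1.0, 0.0))
    mean_y = y.mean()
    yc = y - mean_y
    params = fit_kernel_params(x, yc) if kernel_params == "fit" else kernel_params
    k = _sq_exp(x, x, params.amplitude, params.length_scale)
    ky = k + (params.noise_sd**2 + 1e-10) * np.eye(len(x))
    chol = np.linalg.cholesky(ky)
    alpha = np.linalg.solve(chol.T, np.linalg.solve(chol, yc))
    mu = k @ alpha + mean_y
    v = np.linalg.solve(chol, k)
    var = np.clip(np.diag(k) - np.einsum("ij,ij->j", v, v), 0.0, None)
    z = stats.norm.ppf(0.5 + interval_mass / 2)
    sd_post = np.sqrt(var)
    return TempoSeries(
        years=x.astype(int), raw=y, smooth_mean=mu,
        interval_lo=mu - z * sd_post, interval_hi=mu + z * sd_post,
        kernel_params=params,
    )


def tempo_table(series: TempoSeries) -> pd.DataFrame:
    return pd.DataFrame({
        "year": series.years,
        "raw": series.raw,
        "smooth_mean": series.smooth_mean,
        "lo89": series.interval_lo,
        "hi89": series.interval_hi,
    })
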