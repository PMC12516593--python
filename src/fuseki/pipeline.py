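"""End-to-end pipeline: simulate → ingest → canonicalize → analyses.

A single :class:`RunConfig` drives every stage. Each stochastic stage
derives its own sub-seed deterministically from the global seed and the
stage name, so re-running with the same configuration reproduces every
output byte-for-byte; the run manifest records a SHA-256 hash per artifact
to make this checkable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import canonical as canon_mod
from . import diversity as div_mod
from . import match_network as net_mod
from . import opening_tree as tree_mod
from . import sequence_space as seq_mod
from . import synthetic as syn_mod
from . import tempo as tempo_mod
from .corpus import (GameRecord, corpus_summary, era_by_name, group_by_bin,
                     group_by_era)
from .sgf import parse_sgf, write_sgf_collection

log = logging.getLogger("fuseki.pipeline")

ALL_STAGES = ("simulate", "ingest", "canonicalize", "diversity", "divergence",
              "mds", "tree", "network", "tempo", "recovery")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed (< 2^31)."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    input_sgf: str | None = None       # omit to run on a simulated corpus
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    total_games: int = 20_000
    depth: int = 2
    q: float = 1.0
    n_draw: int = 100
    n_iter: int = 100
    edit_method: str = "lv"
    mds_k: int = 2
    mds_sample: int = 300
    mds_depth: int = 50
    tree_depth: int = 7
    tempo_from: int = 1945
    tempo_min_games: int = 30     # skip years too sparse to estimate Δp

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        unknown = set(payload) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Execute the enabled stages in dependency order.

    Returns the manifest (artifact name → SHA-256), also written to
    ``manifest.json`` in the output directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    enabled = set(config.stages)
    truth: syn_mod.GroundTruth | None = None
    records: list[GameRecord] | None = None
    canonical_records: list[GameRecord] | None = None
    community_counts: dict[str, int] = {}
    divergence_series = None
    tempo_raw = None

    def emit(name: str, text: str) -> Path:
        p = out / name
        p.write_text(text)
        written.append(p)
        return p

    def emit_df(name: str, df: pd.DataFrame) -> Path:
        p = out / name
        df.to_csv(p, index=False)
        written.append(p)
        return p

    def stage(name: str) -> bool:
        return name in enabled

    try:
        name = "simulate"
        if stage(name) and config.input_sgf is None:
            t0 = time.perf_counter()
            cfg = syn_mod.default_config(stage_seed(config.seed, name),
                                         total_games=config.total_games)
            records, truth = syn_mod.generate_corpus(cfg)
            emit("corpus.sgf", write_sgf_collection(records))
            emit("truth.json", json.dumps({
                "seed": truth.seed,
                "step_change_year": truth.step_change_year,
                "era_hill1": truth.era_hill1,
                "era_distributions": truth.era_distributions,
                "n_communities": {e: len(set(m.values()))
                                  for e, m in truth.communities.items()},
            }, indent=1, sort_keys=True))
            emit_df("truth_games.csv", truth.games)
            log.info("simulate: %d games in %.1fs", len(records),
                     time.perf_counter() - t0)

        name = "ingest"
        if stage(name):
            t0 = time.perf_counter()
            if records is None:
                if config.input_sgf is None:
                    raise ValueError("no input: enable 'simulate' or set input_sgf")
                records = parse_sgf(Path(config.input_sgf).read_text())
            from .corpus import filter_corpus
            records, report = filter_corpus(records)
            emit("filter_report.json", json.dumps(asdict(report), indent=1))
            emit_df("summary.csv", corpus_summary(records))
            log.info("ingest: retained %d games in %.1fs", len(records),
                     time.perf_counter() - t0)

        name = "canonicalize"
        if stage(name):
            if records is None:
                raise ValueError("canonicalize requires ingest")
            t0 = time.perf_counter()
            canonical_records = []
            rows = []
            for g in records:
                moves, t = canon_mod.canonicalize_game(g.moves)
                c = GameRecord(**{**g.__dict__, "moves": moves})
                canonical_records.append(c)
                rows.append({"game_id": g.game_id, "transform": t.name})
            emit("canonical.sgf", write_sgf_collection(canonical_records))
            emit_df("transforms.csv", pd.DataFrame(rows))
            log.info("canonicalize: %d games in %.1fs", len(canonical_records),
                     time.perf_counter() - t0)

        by_bin = (group_by_bin(canonical_records)
                  if canonical_records is not None else None)
        by_era = (group_by_era(canonical_records)
                  if canonical_records is not None else None)

        name = "diversity"
        if stage(name) and by_bin is not None:
            t0 = time.perf_counter()
            series = div_mod.bootstrap_series(
                by_bin, "shannon_diversity", depth=config.depth,
                n_draw=config.n_draw, n_iter=config.n_iter,
                seed=stage_seed(config.seed, name))
            emit_df("diversity.csv", _series_table(series))
            log.info("diversity: %d bins in %.1fs", len(series.bins),
                     time.perf_counter() - t0)

        name = "divergence"
        if stage(name) and by_bin is not None:
            t0 = time.perf_counter()
            divergence_series = div_mod.bootstrap_series(
                by_bin, "jsd_vs_previous", depth=config.depth,
                n_draw=config.n_draw, n_iter=config.n_iter,
                seed=stage_seed(config.seed, name))
            emit_df("divergence.csv", _series_table(divergence_series))
            log.info("divergence: %d bins in %.1fs", len(divergence_series.bins),
                     time.perf_counter() - t0)

        name = "mds"
        if stage(name) and canonical_records is not None:
            t0 = time.perf_counter()
            rng = np.random.default_rng(stage_seed(config.seed, name))
            dated = [g for g in canonical_records
                     if g.year is not None and g.moves]
            take = min(config.mds_sample, len(dated))
            idx = sorted(rng.choice(len(dated), size=take, replace=False))
            sample = [dated[i] for i in idx]
            seqs = [seq_mod.game_tokens(g, config.mds_depth) for g in sample]
            dmat = seq_mod.distance_matrix(seqs, method=config.edit_method)
            emb = seq_mod.classical_mds(dmat, k=config.mds_k)
            df = pd.DataFrame({
                "game_id": [g.game_id for g in sample],
                **{f"mds{i+1}": emb.coords[:, i] for i in range(emb.k)},
                "era": [era_by_name_safe(g.year) for g in sample],
                "first3_label": [div_mod.variant_label(g, 3) for g in sample],
            })
            emit_df("embedding.csv", df)
            log.info("mds: %d games in %.1fs", take, time.perf_counter() - t0)

        name = "tree"
        if stage(name) and by_era is not None:
            t0 = time.perf_counter()
            payload = {}
            flat = []
            for era, games in by_era.items():
                tree = tree_mod.build_tree(games, depth=config.tree_depth,
                                           era=era)
                pruned = tree_mod.prune_tree(tree)
                payload[era.name] = tree_mod.tree_to_dict(pruned)
                t = tree_mod.tree_to_table(tree)
                t.insert(0, "era", era.name)
                flat.append(t)
            emit("tree.json", json.dumps(payload, indent=1))
            emit_df("tree.csv", pd.concat(flat, ignore_index=True))
            log.info("tree: %d eras in %.1fs", len(payload),
                     time.perf_counter() - t0)

        name = "network"
        if stage(name) and by_era is not None:
            t0 = time.perf_counter()
            edge_tables, comm_tables = [], []
            for era, games in by_era.items():
                net = net_mod.build_network(games, period=era)
                part = net_mod.detect_communities(net)
                community_counts[era.name] = part.n_communities
                e = net_mod.edges_table(net)
                e.insert(0, "era", era.name)
                edge_tables.append(e)
                comm_tables.append(net_mod.communities_table(part, period=era))
            emit_df("network_edges.csv", pd.concat(edge_tables, ignore_index=True))
            emit_df("communities.csv", pd.concat(comm_tables, ignore_index=True))
            emit_df("network_summary.csv",
                    net_mod.community_series(by_era, depth=config.depth))
            log.info("network: %d eras in %.1fs", len(by_era),
                     time.perf_counter() - t0)

        name = "tempo"
        if stage(name) and canonical_records is not None:
            t0 = time.perf_counter()
            tempo_raw = tempo_mod.raw_tempo_series(
                canonical_records, from_year=config.tempo_from,
                min_games=config.tempo_min_games)
            if len(tempo_raw) >= 3:
                smooth = tempo_mod.gp_smooth(tempo_raw["year"], tempo_raw["raw"])
                emit_df("tempo.csv", tempo_mod.tempo_table(smooth))
            else:
                emit_df("tempo.csv", tempo_raw)
            log.info("tempo: %d years in %.1fs", len(tempo_raw),
                     time.perf_counter() - t0)

        name = "recovery"
        if stage(name) and truth is not None and canonical_records is not None:
            t0 = time.perf_counter()
            rng = np.random.default_rng(stage_seed(config.seed, name))
            report = recovery_from_outputs(
                truth, canonical_records, community_counts,
                tempo_raw, divergence_series, rng,
                depth=config.depth, n_draw=config.n_draw)
            emit_df("recovery.csv", report)
            log.info("recovery: %d checks in %.1fs", len(report),
                     time.perf_counter() - t0)
    except Exception as exc:
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(name, exc) from exc

    manifest = {p.name: _sha256(p) for p in sorted(written)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    return manifest


def era_by_name_safe(year: int) -> str:
    from .corpus import assign_era
    try:
        return assign_era(year).name
    except ValueError:
        return ""


def _series_table(series: div_mod.BootstrapSeries) -> pd.DataFrame:
    return pd.DataFrame({
        "bin_start": [b.start_year for b in series.bins],
        "bin_width": [b.width for b in series.bins],
        "n_games": series.n_games,
        "stat": series.stat_mean,
        "mc_se": series.mc_se,
    })


def recovery_from_outputs(
    truth: syn_mod.GroundTruth,
    canonical_records: Sequence[GameRecord],
    community_counts: dict[str, int],
    tempo_raw: pd.DataFrame | None,
    divergence_series: div_mod.BootstrapSeries | None,
    rng: np.random.Generator,
    depth: int = 2,
    n_draw: int = 100,
) -> pd.DataFrame:
    """Assemble the ground-truth recovery table from pipeline outputs."""
    by_era = group_by_era(canonical_records)
    hill_est = {}
    for era, games in by_era.items():
        labels = [div_mod.variant_label(g, depth) for g in games
                  if len(g.moves) >= depth]
        hill_est[era.name] = syn_mod.hill1_with_se(labels, rng=rng)
    argmax_year = None
    if tempo_raw is not None and len(tempo_raw):
        argmax_year = int(tempo_raw.loc[tempo_raw["raw"].idxmax(), "year"])
    stationary = None
    if divergence_series is not None:
        stationary = {}
        bins = divergence_series.bins
        # index of the preceding non-empty bin each divergence was paired with
        prev_of: dict[int, int] = {}
        last = None
        for i, n in enumerate(divergence_series.n_games):
            if last is not None:
                prev_of[i] = last
            if n > 0:
                last = i
        for era_name, dist in truth.era_distributions.items():
            era = era_by_name(era_name)

            def inside(b) -> bool:
                return era.start_year <= b.start_year and b.end_year <= era.end_year

            vd = div_mod.VariantDistribution(
                list(dist), np.array(list(dist.values())), n_games=1)
            worst: tuple[float, float] | None = None
            for i, v in enumerate(divergence_series.stat_mean):
                if (np.isnan(v) or i not in prev_of
                        or not inside(bins[i]) or not inside(bins[prev_of[i]])):
                    continue
                floor = syn_mod.jsd_noise_floor(
                    vd, divergence_series.n_games[i],
                    divergence_series.n_games[prev_of[i]],
                    n_draw=n_draw, rng=rng)
                if worst is None or v - floor > worst[0] - worst[1]:
                    worst = (float(v), floor)
            if worst is not None:
                stationary[era_name] = worst
    return syn_mod.recovery_report(
        truth,
        era_hill1_est=hill_est,
        community_counts=community_counts,
        tempo_argmax_year=argmax_year,
        stationary_jsd=stationary,
    )
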