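"""Pipeline orchestration: clean -> DTWA consensus -> vote -> evaluate.

:func:`run_pipeline` executes the full flow for one ensemble and a set of
averaging algorithms, persisting every intermediate under ``outdir`` and
re-using any artifact whose content-hashed cache key is unchanged, so
re-running with the same configuration is a no-op.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import average, clean, metrics, vote
from .squiggle_io import Ensemble, GoldModel, Squiggle, read_squiggles, write_squiggles

log = logging.getLogger("squigglevote")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    ``n_start``/``group_size`` select the consensus-building slice of the
    cleaned ensemble; ``voter_size`` may be larger, letting reads not used
    for averaging still vote.
    """

    ensemble_path: str
    outdir: str
    gold_path: str | None = None
    n_start: int = 0
    group_size: int | None = None     # None: all cleaned reads
    voter_size: int | None = None     # None: same as group_size
    algorithms: tuple[str, ...] = ("dba", "mm", "ssg")
    cleaning: clean.CleaningConfig = field(default_factory=clean.CleaningConfig)
    thresholds: list[float] | None = None
    max_iter: int = 10
    tol: float = 1e-4
    passes: int = 1
    epochs: int = 3
    step0: float = 0.25
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "cleaning" in raw:
            raw["cleaning"] = clean.CleaningConfig(**raw["cleaning"])
        if "algorithms" in raw:
            raw["algorithms"] = tuple(raw["algorithms"])
        return cls(**raw)

    def cache_key(self, section: str) -> str:
        payload = dataclasses.asdict(self)
        payload["__section__"] = section
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


def _consensus_fn(name: str, cfg: RunConfig):
    if name == "dba":
        return lambda ens: average.dba(ens, max_iter=cfg.max_iter, tol=cfg.tol)
    if name == "mm":
        return lambda ens: average.mm_mean(ens, passes=cfg.passes)
    if name == "ssg":
        return lambda ens: average.ssg_mean(
            ens, epochs=cfg.epochs, step0=cfg.step0, seed=cfg.seed
        )
    raise ValueError(f"unknown algorithm {name!r}")


def run_pipeline(cfg: RunConfig) -> dict[str, dict]:
    """Run clean -> consensus -> vote sweep -> select -> evaluate.

    Returns per-algorithm summary dicts (also written as JSON files).
    Stage errors abort with the stage named.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gold = None
    if cfg.gold_path:
        gold_ens = read_squiggles(cfg.gold_path)
        gold = GoldModel(gold_ens[0].levels, source_sequence_id=gold_ens[0].read_id)

    # stage 1: cleaning (cached)
    key = cfg.cache_key("clean")
    cleaned_path = outdir / f"cleaned-{key}.tsv"
    if cleaned_path.exists():
        log.info("clean: cache hit (%s)", cleaned_path.name)
        cleaned = read_squiggles(cleaned_path)
    else:
        ensemble = read_squiggles(cfg.ensemble_path)
        try:
            cleaned, report = clean.clean_pipeline(ensemble, cfg.cleaning, gold)
        except Exception as exc:
            raise RuntimeError(f"stage 'clean' failed: {exc}") from exc
        write_squiggles(cleaned, cleaned_path)
        with open(outdir / f"cleaning-report-{key}.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2)
        log.info("clean: %d -> %d reads", len(ensemble), len(cleaned))

    group_size = cfg.group_size or len(cleaned)
    voter_size = cfg.voter_size or group_size
    if not group_size <= voter_size <= len(cleaned):
        raise ValueError(
            f"need group_size ({group_size}) <= voter_size ({voter_size})"
            f" <= cleaned reads ({len(cleaned)})"
        )
    group = Ensemble(cleaned.squiggles[cfg.n_start : cfg.n_start + group_size], label="group")
    voters = Ensemble(cleaned.squiggles[cfg.n_start : cfg.n_start + voter_size], label="voters")

    summaries: dict[str, dict] = {}
    for name in cfg.algorithms:
        key = cfg.cache_key(f"consensus-{name}")
        summary_path = outdir / f"summary-{name}-{key}.json"
        if summary_path.exists():
            log.info("%s: cache hit (%s)", name, summary_path.name)
            summaries[name] = json.loads(summary_path.read_text())
            continue
        try:
            cons = _consensus_fn(name, cfg)(group)
        except Exception as exc:
            raise RuntimeError(f"stage 'consensus:{name}' failed: {exc}") from exc
        write_squiggles(
            Ensemble([Squiggle(f"{name}-consensus", cons.levels)]),
            outdir / f"consensus-{name}-{key}.tsv",
        )
        try:
            sweep = vote.vote_sweep(cons, voters, cfg.thresholds, gold=gold)
            threshold, final = vote.select_final(sweep, source=cons)
        except Exception as exc:
            raise RuntimeError(f"stage 'vote:{name}' failed: {exc}") from exc
        write_squiggles(
            Ensemble([Squiggle(f"{name}-final", final.levels)]),
            outdir / f"final-{name}-{key}.tsv",
        )
        _write_sweep_csv(sweep, outdir / f"sweep-{name}-{key}.csv")
        summary = {
            "algorithm": name,
            "seed": cfg.seed,
            "initial_length": int(len(cons)),
            "selected_threshold": threshold,
            "final_length": int(len(final)),
            "frechet_history": cons.frechet_history,
        }
        if gold is not None:
            rep = metrics.evaluate(final, voters, gold)
            summary["metrics"] = rep.to_row()
        with open(summary_path, "w") as fh:
            json.dump(summary, fh, indent=2)
        log.info(
            "%s: length %d -> %d at %.0f%% agreement",
            name, len(cons), len(final), 100 * threshold,
        )
        summaries[name] = summary
    return summaries


def _write_sweep_csv(sweep: vote.VotingSweep, path: Path) -> None:
    import pandas as pd

    pd.DataFrame(sweep.to_records()).to_csv(path, index=False)
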