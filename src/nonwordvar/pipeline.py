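"""End-to-end orchestration: gpc -> score -> stats -> fit, with a manifest.

Every stage writes tidy CSV/JSON into the output directory; the manifest
records the package version, seed, configuration hash and any random-effect
fallbacks, so a run is reproducible and auditable.  Reruns with identical
inputs produce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analyses import (
    composite_literacy,
    fit_distance_lmm,
    fit_diversity_lmm,
    fit_novelty_glmm,
    fit_trajectories,
    ttest_vs_one,
)
from .consistency import GPCEntropyModel
from .lexicon import GPCTable, read_lexicon_tsv, read_rules_csv
from .responses import (
    diversity_table,
    gower_distances,
    novelty_table,
    pronunciation_frequencies,
    read_responses_csv,
)

log = logging.getLogger("nonwordvar")


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {detail}")


@dataclass
class PipelineConfig:
    """Paths and options for one pipeline run; round-trips through YAML."""

    lexicon: str | None = None
    rules: str | None = None
    gpc: str | None = None               # precomputed GPC table CSV (alternative to lexicon)
    nonwords: str | None = None          # plain text, one nonword per line
    overrides: str | None = None         # CSV nonword,syllabification
    responses: str | None = None
    literacy: str | None = None          # CSV participant,spelling,vocabulary
    out_dir: str = "out"
    weighting: str = "types"
    eps: float = 0.01
    transform_variant: str = "neg_log"
    drop_last_session_freqs: bool = True
    analyses: tuple[str, ...] = ("1", "2", "3", "4", "5")
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        if "analyses" in raw:
            raw["analyses"] = tuple(str(a) for a in raw["analyses"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({**dataclasses.asdict(self),
                            "analyses": list(self.analyses)}, fh)


def read_overrides_csv(path) -> dict[str, list[str]]:
    df = pd.read_csv(path, dtype=str)
    return {row.iloc[0].upper(): row.iloc[1].upper().split("-") for _, row in df.iterrows()}


def _write_float_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.6g")


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run every requested stage, returning the output directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "seed": cfg.seed,
                "config_hash": _config_hash(cfg), "stages": {}, "fallbacks": {}}

    def stage(name):
        t0 = time.perf_counter()

        def done():
            dt = time.perf_counter() - t0
            manifest["stages"][name] = round(dt, 3)
            log.info("stage %s: %.2fs", name, dt)
        return done

    # --- consistency scores -------------------------------------------------
    scores = None
    if cfg.nonwords is not None:
        done = stage("score")
        try:
            if cfg.gpc is not None:
                table = GPCTable.from_csv(cfg.gpc)
                model = GPCEntropyModel(eps=cfg.eps, transform_variant=cfg.transform_variant)
                model.fit(table)
            elif cfg.lexicon is not None:
                rules = read_rules_csv(cfg.rules) if cfg.rules else None
                model = GPCEntropyModel(rules=rules, weighting=cfg.weighting, eps=cfg.eps,
                                        transform_variant=cfg.transform_variant)
                model.fit(read_lexicon_tsv(cfg.lexicon))
                model.table_.to_csv(out / "gpc.csv")
            else:
                raise StageError("score", "need either a lexicon or a GPC table")
            if cfg.overrides:
                model.set_params(syllable_overrides=read_overrides_csv(cfg.overrides))
            items = [ln.strip() for ln in Path(cfg.nonwords).read_text().splitlines() if ln.strip()]
            scores = model.transform(items)
            _write_float_csv(scores, out / "consistency.csv")
        except StageError:
            raise
        except Exception as err:
            raise StageError("score", str(err)) from err
        done()

    if cfg.responses is None:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return out

    # --- response statistics ------------------------------------------------
    done = stage("stats")
    try:
        resp = read_responses_csv(cfg.responses)
        div = diversity_table(resp)
        nov = novelty_table(resp)
        dist = gower_distances(resp)
        freq = pronunciation_frequencies(resp, drop_last_session=cfg.drop_last_session_freqs)
        _write_float_csv(div, out / "diversity.csv")
        _write_float_csv(nov, out / "novelty.csv")
        _write_float_csv(dist, out / "distances.csv")
        _write_float_csv(freq, out / "frequencies.csv")
    except Exception as err:
        raise StageError("stats", str(err)) from err
    done()

    # --- models --------------------------------------------------------------
    lit = None
    if cfg.literacy is not None:
        lit = composite_literacy(pd.read_csv(cfg.literacy))
        _write_float_csv(lit, out / "literacy_composite.csv")

    results = {}
    if "1" in cfg.analyses:
        done = stage("fit1")
        part_means = div.groupby("participant")["n_distinct"].mean()
        item_means = div.groupby("item")["n_distinct"].mean()
        tp = ttest_vs_one(part_means)
        ti = ttest_vs_one(item_means)
        results["analysis1"] = {
            "participants": {"mean": float(part_means.mean()), "t": tp[0], "df": tp[1], "p": tp[2]},
            "items": {"mean": float(item_means.mean()), "t": ti[0], "df": ti[1], "p": ti[2]},
        }
        done()

    def _joined_covariates(base: pd.DataFrame) -> pd.DataFrame:
        if scores is None:
            raise StageError("fit", "analyses 2/3 need consistency scores (nonwords+lexicon/gpc)")
        if lit is None:
            raise StageError("fit", "analyses 2/3 need a literacy file")
        j = base.merge(scores[["nonword", "covariate"]].rename(
            columns={"nonword": "item", "covariate": "consistency"}), on="item")
        return j.merge(lit[["participant", "literacy"]], on="participant")

    if "2" in cfg.analyses:
        done = stage("fit2")
        r2 = fit_diversity_lmm(_joined_covariates(div))
        results["analysis2"] = r2.to_dict()
        manifest["fallbacks"]["analysis2"] = r2.fallback_applied
        done()
    if "3" in cfg.analyses:
        done = stage("fit3")
        r3 = fit_novelty_glmm(_joined_covariates(nov))
        results["analysis3"] = r3.to_dict()
        manifest["fallbacks"]["analysis3"] = r3.fallback_applied
        done()
    if "4" in cfg.analyses:
        done = stage("fit4")
        r4 = fit_distance_lmm(dist)
        results["analysis4"] = r4.to_dict()
        manifest["fallbacks"]["analysis4"] = r4.fallback_applied
        done()
    if "5" in cfg.analyses:
        done = stage("fit5")
        traj = fit_trajectories(freq)
        _write_float_csv(traj.table, out / "trajectories.csv")
        results["analysis5"] = {"r_intercept_slope": traj.r, "p": traj.p,
                                "n_pronunciations": traj.n, "degenerate": traj.degenerate,
                                **{"model": traj.result.to_dict()}}
        manifest["fallbacks"]["analysis5"] = traj.result.fallback_applied
        done()

    (out / "models.json").write_text(json.dumps(results, indent=2, default=float))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def setup_logging(verbose: bool = True) -> None:
    logging.basicConfig(stream=sys.stderr,
                        level=logging.INFO if verbose else logging.WARNING,
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")
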