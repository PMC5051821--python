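"""End-to-end orchestration: tree + richness in, result tables out.

``run_full_analysis`` chains richness estimation, clade enumeration, rate
tables and summaries, the windowed age–richness regressions, the
rate–richness regression with its permutation null, and the stepwise
shift search, writing one CSV per stage plus a JSON run manifest (seed,
config, versions, per-stage timings).  Any stage failure aborts with the
stage name; outputs written so far are kept next to a ``FAILED`` marker.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import pandas as pd

from . import __version__
from .rate_richness import randomization_null, rate_richness_fit
from .rates import rate_table, summarize_rates, top_rank_overlap, write_rate_csv
from .richness import read_counts_csv, read_richness_csv, richness_series
from .shifts import stepwise_shift_search
from .tree_model import enumerate_clades, read_newick_file, write_clade_csv
from .windows import window_analysis, window_table

log = logging.getLogger("cladediv")

__all__ = ["AnalysisConfig", "PipelineError", "run_full_analysis"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class AnalysisConfig:
    tree_path: str
    richness_path: str              # counts CSV (family,S_A,S_R,S_U) or direct family,richness
    out_dir: str
    overrides_path: Optional[str] = None
    epsilons: Tuple[float, ...] = (0.0, 0.9)
    window_width: float = 10.0
    min_age: float = 20.0
    max_age: float = 100.0
    n_reps: int = 1000
    seed: int = 0
    top_k: int = 10
    do_shifts: bool = True
    model_kinds: Tuple[str, ...] = ("yule", "bd")
    max_models: int = 25

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _load_richness(config: AnalysisConfig) -> pd.Series:
    head = pd.read_csv(config.richness_path, nrows=0)
    overrides = None
    if config.overrides_path:
        overrides = read_richness_csv(config.overrides_path).to_dict()
    if {"S_A", "S_R", "S_U"}.issubset(head.columns):
        return richness_series(read_counts_csv(config.richness_path), overrides)
    series = read_richness_csv(config.richness_path)
    if overrides:
        series.update(pd.Series(overrides))
    return series


def run_full_analysis(config: AnalysisConfig) -> Dict[str, str]:
    """Run every stage; returns a mapping stage → output path."""
    for path in (config.tree_path, config.richness_path, config.overrides_path):
        if path and not Path(path).exists():
            raise FileNotFoundError(f"input does not exist: {path}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: Dict[str, str] = {}
    timings: Dict[str, float] = {}
    state: dict = {}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                fn()
            except Exception as exc:
                (out / "FAILED").write_text(
                    json.dumps({"stage": name, "error": repr(exc)}) + "\n"
                )
                raise PipelineError(name, exc) from exc
            timings[name] = round(time.perf_counter() - t0, 4)
            log.info("stage %s: done in %.2fs", name, timings[name])

        return deco

    @stage("richness")
    def _richness():
        series = _load_richness(config)
        path = out / "richness.csv"
        series.rename_axis("family").to_frame().to_csv(path)
        outputs["richness"] = str(path)
        state["richness"] = series

    @stage("clades")
    def _clades():
        tree = read_newick_file(config.tree_path)
        records = enumerate_clades(tree, state["richness"].to_dict())
        path = out / "clades.csv"
        write_clade_csv(records, path)
        outputs["clades"] = str(path)
        state["tree"], state["records"] = tree, records

    @stage("rates")
    def _rates():
        table = rate_table(state["records"], config.epsilons)
        write_rate_csv(table, out / "rates.csv")
        summarize_rates(table).to_csv(out / "rate_summary.csv", index=False)
        state["overlap"] = (
            top_rank_overlap(table, config.top_k) if len(config.epsilons) == 2 else None
        )
        outputs["rates"] = str(out / "rates.csv")
        outputs["rate_summary"] = str(out / "rate_summary.csv")

    @stage("windows")
    def _windows():
        fits = window_analysis(
            state["records"], config.window_width, config.min_age, config.max_age
        )
        path = out / "windows.csv"
        window_table(fits).to_csv(path, index=False)
        outputs["windows"] = str(path)

    @stage("rate_richness")
    def _rate_richness():
        eps = config.epsilons[0]
        fit = rate_richness_fit(state["records"], eps)
        null = randomization_null(
            state["records"], eps, n_reps=config.n_reps, seed=config.seed
        )
        pd.DataFrame({"permuted_r2": null.permuted_r2}).to_csv(
            out / "permuted_r2.csv", index=False
        )
        report = {
            "epsilon": eps,
            "slope": fit.slope,
            "p": fit.p,
            "observed_r2": fit.r_squared,
            "mean_permuted_r2": null.mean_permuted_r2,
            "n_reps": null.n_reps,
            "seed": null.seed,
            "top_rank_overlap": state["overlap"],
        }
        (out / "rate_richness.json").write_text(json.dumps(report, indent=2) + "\n")
        outputs["rate_richness"] = str(out / "rate_richness.json")
        outputs["permuted_r2"] = str(out / "permuted_r2.csv")

    if config.do_shifts:

        @stage("shifts")
        def _shifts():
            cfg = stepwise_shift_search(
                state["tree"],
                state["richness"].to_dict(),
                model_kinds=config.model_kinds,
                max_models=config.max_models,
            )
            models = pd.DataFrame(
                {
                    "model": range(1, cfg.n_models + 1),
                    "kind": [m.kind for m in cfg.models],
                    "r": [m.r for m in cfg.models],
                    "epsilon": [m.epsilon for m in cfg.models],
                    "break_node": [None] + cfg.break_nodes,
                }
            )
            models.to_csv(out / "shift_models.csv", index=False)
            pd.Series(cfg.partition_of, name="model").rename_axis("clade_id").add(
                1
            ).to_frame().to_csv(out / "shift_branches.csv")
            outputs["shift_models"] = str(out / "shift_models.csv")
            outputs["shift_branches"] = str(out / "shift_branches.csv")
            state["shift_aicc_trace"] = cfg.aicc_trace

    manifest = {
        "package": "cladediv",
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_digest": config.digest(),
        "outputs": outputs,
        "timings_s": timings,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    outputs["manifest"] = str(out / "manifest.json")
    failed = out / "FAILED"
    if failed.exists():
        failed.unlink()
    return outputs
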