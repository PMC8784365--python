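"""End-to-end analysis orchestration.

``run_full_analysis`` executes the whole pipeline — read (or generate)
annotations, merge sub-threshold activities, build activity vectors, score
similarity, compute efficiency, fit the group-comparison models, and
optionally run the noise sweep — writing every result as delimited text plus
a JSON manifest with content checksums, so a run is fully reproducible from
its config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .annotation_model import preprocess_dataset, read_annotations, write_annotations
from .efficiency import efficiency_table
from .noise import DEFAULT_P_GRID, SWEEP_ANALYSES, noise_sweep
from .similarity import similarity_table
from .stats import segment_level_anova, suture_level_lmm, StatsError
from .synthetic import SyntheticConfig, generate_dataset
from .vectorization import get_vocabulary

__all__ = ["RunConfig", "PipelineError", "run_full_analysis"]

logger = logging.getLogger("suturespm")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """What to analyse and where to put the results."""

    output_dir: Path
    input_path: Optional[Path] = None
    synthetic: Optional[SyntheticConfig] = None
    levels: Sequence[str] = ("suture", "segment")
    hands: Sequence[str] = ("left", "right")
    vocabularies: Sequence[str] = ("full18",)
    min_duration_s: float = 0.5
    noise_enabled: bool = False
    noise_grid: Sequence[float] = DEFAULT_P_GRID
    noise_replicates: int = 20
    noise_analyses: Sequence[str] = SWEEP_ANALYSES
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.synthetic is None):
            raise PipelineError("exactly one of input_path or synthetic must be given")
        if self.synthetic is None and self.noise_enabled and self.seed is None:
            raise PipelineError("a seed is required when the noise sweep is enabled")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_analysis(config: RunConfig) -> dict:
    """Run every enabled stage; returns the manifest (also written to disk)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "suturespm",
        "version": __version__,
        "seed": config.seed if config.seed is not None else (
            config.synthetic.seed if config.synthetic else None
        ),
        "input": str(config.input_path) if config.input_path else "synthetic",
        "stages": {},
        "outputs": {},
        "complete": False,
    }
    outputs: list[Path] = []

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            logger.info("stage %s: starting", name)
            try:
                fn()
            except Exception as exc:
                manifest["stages"][name] = {"status": "failed", "error": str(exc)}
                _write_manifest(out, manifest, outputs)
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            manifest["stages"][name] = {
                "status": "ok",
                "seconds": round(time.perf_counter() - t0, 3),
            }
            logger.info("stage %s: done", name)
        return wrap

    state: dict = {}

    @stage("load")
    def _load():
        if config.input_path is not None:
            state["dataset"] = read_annotations(config.input_path)
        else:
            state["dataset"] = generate_dataset(config.synthetic)
            path = out / "synthetic_annotations.csv"
            write_annotations(state["dataset"], path)
            outputs.append(path)

    @stage("preprocess")
    def _preprocess():
        state["dataset"] = preprocess_dataset(state["dataset"], config.min_duration_s)

    @stage("similarity")
    def _similarity():
        for level in config.levels:
            for hand in config.hands:
                for variant in config.vocabularies:
                    table = similarity_table(
                        state["dataset"], level, hand, get_vocabulary(variant)
                    )
                    path = out / f"similarity_{level}_{hand}_{variant}.csv"
                    table.to_csv(path, index=False)
                    outputs.append(path)
                    state[f"similarity_{level}_{hand}_{variant}"] = table

    @stage("efficiency")
    def _efficiency():
        for level in config.levels:
            table = efficiency_table(state["dataset"], level)
            path = out / f"efficiency_{level}.csv"
            table.to_csv(path, index=False)
            outputs.append(path)
            state[f"efficiency_{level}"] = table

    @stage("stats")
    def _stats():
        rows = []
        report_lines = ["Group comparison (novice minus expert contrasts)", ""]
        if "suture" in config.levels:
            eff = state.get("efficiency_suture")
            jobs = []
            if eff is not None:
                jobs += [
                    (eff, "s_eff_left", "suturing efficiency, left hand (microforceps)"),
                    (eff, "s_eff_right", "suturing efficiency, right hand (needleholder)"),
                    (eff, "b_eff", "bimanual efficiency"),
                ]
            for hand in config.hands:
                for variant in config.vocabularies:
                    table = state.get(f"similarity_suture_{hand}_{variant}")
                    if table is not None:
                        jobs.append(
                            (table, "difference", f"similarity difference, {hand} hand ({variant})")
                        )
            for table, outcome, label in jobs:
                try:
                    res = suture_level_lmm(table, outcome)
                except StatsError as exc:
                    report_lines.append(f"{label}: not fitted ({exc})")
                    continue
                rows.append(
                    dict(level="suture", model="lmm", outcome=label, term="skill",
                         estimate=res.fixed_effect_estimate, ci_low=res.ci_low,
                         ci_high=res.ci_high, statistic=float("nan"), p_value=res.p_value,
                         random_intercept_sd=res.random_intercept_sd, df=res.df,
                         singular=res.singular)
                )
                report_lines.append(
                    f"{label}: beta = {res.fixed_effect_estimate:+.3f} "
                    f"(95% CI [{res.ci_low:.3f}, {res.ci_high:.3f}]), "
                    f"p = {res.p_value:.4g}, participant SD = {res.random_intercept_sd:.3f}"
                    + (" [singular fit]" if res.singular else "")
                )
        if "segment" in config.levels:
            report_lines += ["", "Segment-level type III tests", ""]
            eff = state.get("efficiency_segment")
            jobs = []
            if eff is not None:
                jobs += [
                    (eff, "s_eff_left", "suturing efficiency, left hand"),
                    (eff, "s_eff_right", "suturing efficiency, right hand"),
                    (eff, "b_eff", "bimanual efficiency"),
                ]
            for hand in config.hands:
                for variant in config.vocabularies:
                    table = state.get(f"similarity_segment_{hand}_{variant}")
                    if table is not None:
                        jobs.append(
                            (table, "difference", f"similarity difference, {hand} hand ({variant})")
                        )
            for table, outcome, label in jobs:
                try:
                    res = segment_level_anova(table, outcome)
                except StatsError as exc:
                    report_lines.append(f"{label}: not fitted ({exc})")
                    continue
                for term in res.terms:
                    rows.append(
                        dict(level="segment", model="anova3", outcome=label, term=term.term,
                             estimate=float("nan"), ci_low=float("nan"), ci_high=float("nan"),
                             statistic=term.F, p_value=term.p,
                             random_intercept_sd=res.random_intercept_variance ** 0.5,
                             df=term.df_den, singular=res.singular)
                    )
                report_lines.append(
                    f"{label}: "
                    + "; ".join(
                        f"{t.term} F = {t.F:.3f} (p = {t.p:.4g})" for t in res.terms
                    )
                )
        stats_path = out / "stats_results.csv"
        pd.DataFrame(rows).to_csv(stats_path, index=False)
        outputs.append(stats_path)
        report_path = out / "stats_report.txt"
        report_path.write_text("\n".join(report_lines) + "\n", encoding="utf-8")
        outputs.append(report_path)

    if config.noise_enabled:
        @stage("noise_sweep")
        def _noise():
            result = noise_sweep(
                state["dataset"],
                p_grid=config.noise_grid,
                replicates=config.noise_replicates,
                analyses=config.noise_analyses,
                seed=config.seed if config.seed is not None else 0,
            )
            path = out / "noise_sweep.csv"
            result.table.to_csv(path, index=False)
            outputs.append(path)
    else:
        manifest["stages"]["noise_sweep"] = {"status": "skipped"}

    manifest["complete"] = True
    _write_manifest(out, manifest, outputs)
    return manifest


def _write_manifest(out: Path, manifest: dict, outputs: Sequence[Path]) -> None:
    manifest["outputs"] = {p.name: _sha256(p) for p in outputs if p.exists()}
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
    )
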