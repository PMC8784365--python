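"""Label-noise robustness analysis.

Annotating targets of interest leaves room for interpretation, so the
pipeline's conclusions are stress-tested by corrupting the target labels:
each productive interval independently, with probability p, has its target
replaced by one drawn uniformly from the three *other* targets (so p = 1
means every target changed).  Action labels, idle and not-visible intervals
are never touched — whether a tool is moving, holding, grasping or out of
view is considered objectively visible.

Because the efficiency metrics depend only on the idle/not-visible labels,
they are exactly invariant under this corruption.  An optional mode
(``mode="to_idle"``) instead relabels a productive interval as idle with
probability p, which does perturb the efficiency metrics; it exists to
emulate annotation disagreement about whether an activity had any target at
all (see docs/methods.md for why these two readings differ).

:func:`noise_sweep` re-runs the similarity and efficiency analyses over a
grid of corruption probabilities with replication and reports, per headline
contrast, the largest noise level at which it remains significant.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotation_model import (
    TARGETS,
    AnnotatedInterval,
    AnnotationDataset,
    SegmentAnnotation,
    SutureAnnotation,
    ActivityLabel,
)
from .efficiency import efficiency_table
from .similarity import similarity_table
from .stats import segment_level_anova, suture_level_lmm, StatsError
from .vectorization import get_vocabulary

__all__ = [
    "NoiseError",
    "inject_target_noise",
    "NoiseSweepResult",
    "noise_sweep",
    "reduced_vocabulary_analysis",
    "ReducedVocabularyResult",
    "DEFAULT_P_GRID",
    "SWEEP_ANALYSES",
]

DEFAULT_P_GRID = tuple(round(0.1 * i, 1) for i in range(0, 11))
SWEEP_ANALYSES = ("similarity_suture", "similarity_segment", "s_eff", "b_eff")


class NoiseError(ValueError):
    """Raised for invalid corruption parameters."""


def inject_target_noise(
    dataset: AnnotationDataset, p: float, seed: int, mode: str = "switch"
) -> AnnotationDataset:
    """Corrupt target labels with probability p per productive interval.

    ``mode="switch"`` (default) resamples the target uniformly among the
    three other targets; ``mode="to_idle"`` relabels the interval idle
    instead.  Deterministic given the seed.
    """
    if not 0 <= p <= 1:
        raise NoiseError(f"noise probability must be in [0, 1], got {p}")
    if mode not in ("switch", "to_idle"):
        raise NoiseError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)

    def corrupt(iv: AnnotatedInterval) -> AnnotatedInterval:
        if not iv.label.is_productive:
            return iv
        if rng.random() >= p:
            return iv
        if mode == "to_idle":
            return replace(iv, label=ActivityLabel.idle())
        others = [t for t in TARGETS if t != iv.label.target]
        new_target = others[int(rng.integers(len(others)))]
        return replace(iv, label=ActivityLabel(iv.label.action, new_target))

    annotations = {}
    for pid, sutures in dataset.annotations.items():
        rebuilt = []
        for suture in sutures:
            segs = tuple(
                SegmentAnnotation(
                    segment_type=seg.segment_type,
                    intervals_left=tuple(corrupt(iv) for iv in seg.intervals_left),
                    intervals_right=tuple(corrupt(iv) for iv in seg.intervals_right),
                )
                for seg in suture.segments
            )
            rebuilt.append(SutureAnnotation(suture_index=suture.suture_index, segments=segs))
        annotations[pid] = tuple(rebuilt)
    return AnnotationDataset(participants=dataset.participants, annotations=annotations)


def _cell_seed(seed: int, p_index: int, replicate: int) -> int:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(p_index, replicate))
    return int(ss.generate_state(1)[0] % (2**31))


def _analyse(dataset: AnnotationDataset, analyses: Sequence[str]) -> list[dict]:
    """Run the requested analyses on one (possibly corrupted) dataset."""
    rows: list[dict] = []
    vocab = get_vocabulary("full18")
    if "similarity_suture" in analyses or "similarity_segment" in analyses:
        for hand in ("left", "right"):
            if "similarity_suture" in analyses:
                table = similarity_table(dataset, "suture", hand, vocab)
                res = suture_level_lmm(table, "difference")
                rows.append(
                    dict(
                        analysis="similarity_suture", hand=hand, term="skill",
                        estimate=res.fixed_effect_estimate, statistic=np.nan,
                        p_value=res.p_value,
                        expert_mean=float(
                            table.loc[table["group"] == "expert", "difference"].mean()
                        ),
                        novice_mean=float(
                            table.loc[table["group"] == "novice", "difference"].mean()
                        ),
                    )
                )
            if "similarity_segment" in analyses:
                table = similarity_table(dataset, "segment", hand, vocab)
                res = segment_level_anova(table, "difference")
                for term in res.terms:
                    rows.append(
                        dict(
                            analysis="similarity_segment", hand=hand, term=term.term,
                            estimate=np.nan, statistic=term.F, p_value=term.p,
                            expert_mean=np.nan, novice_mean=np.nan,
                        )
                    )
    if "s_eff" in analyses or "b_eff" in analyses:
        eff = efficiency_table(dataset, "suture")
        if "s_eff" in analyses:
            for hand, col in (("left", "s_eff_left"), ("right", "s_eff_right")):
                res = suture_level_lmm(eff, col)
                rows.append(
                    dict(
                        analysis="s_eff", hand=hand, term="skill",
                        estimate=res.fixed_effect_estimate, statistic=np.nan,
                        p_value=res.p_value,
                        expert_mean=float(eff.loc[eff["group"] == "expert", col].mean()),
                        novice_mean=float(eff.loc[eff["group"] == "novice", col].mean()),
                    )
                )
        if "b_eff" in analyses:
            res = suture_level_lmm(eff, "b_eff")
            rows.append(
                dict(
                    analysis="b_eff", hand="both", term="skill",
                    estimate=res.fixed_effect_estimate, statistic=np.nan,
                    p_value=res.p_value,
                    expert_mean=float(eff.loc[eff["group"] == "expert", "b_eff"].mean()),
                    novice_mean=float(eff.loc[eff["group"] == "novice", "b_eff"].mean()),
                )
            )
    return rows


@dataclass
class NoiseSweepResult:
    """Long-format sweep statistics plus survival summaries."""

    table: pd.DataFrame
    alpha: float = 0.05

    def surviving_noise_level(
        self, analysis: str, term: str = "skill", hand: Optional[str] = None
    ) -> float:
        """Largest noise p at which >= 50% of replicates are significant at alpha.

        Returns -1.0 if the contrast is not significant even at p = 0 (or the
        analysis produced no rows).
        """
        sub = self.table[(self.table["analysis"] == analysis) & (self.table["term"] == term)]
        if hand is not None:
            sub = sub[sub["hand"] == hand]
        best = -1.0
        for p_val, grp in sub.groupby("noise_p"):
            ok = grp["p_value"].dropna()
            if len(ok) and (ok < self.alpha).mean() >= 0.5:
                best = max(best, float(p_val))
        return best


def noise_sweep(
    dataset: AnnotationDataset,
    p_grid: Sequence[float] = DEFAULT_P_GRID,
    replicates: int = 20,
    analyses: Sequence[str] = SWEEP_ANALYSES,
    seed: int = 0,
    alpha: float = 0.05,
    mode: str = "switch",
) -> NoiseSweepResult:
    """Corrupt-and-reanalyse over a grid of noise probabilities.

    One corrupted dataset is drawn per (p, replicate) cell from a seed
    derived deterministically from ``seed``; analysis failures in a cell are
    recorded (``error`` column) without aborting the sweep.  At p = 0 a
    single replicate is run (the corruption is the identity).
    """
    unknown = set(analyses) - set(SWEEP_ANALYSES)
    if unknown:
        raise NoiseError(f"unknown analyses {sorted(unknown)}; choose from {SWEEP_ANALYSES}")
    if replicates < 1:
        raise NoiseError("replicates must be >= 1")
    records: list[dict] = []
    for p_index, p in enumerate(p_grid):
        n_rep = 1 if p == 0 else replicates
        for rep in range(n_rep):
            cell_seed = _cell_seed(seed, p_index, rep)
            corrupted = inject_target_noise(dataset, p, seed=cell_seed, mode=mode)
            try:
                rows = _analyse(corrupted, analyses)
                for row in rows:
                    records.append(
                        dict(noise_p=p, replicate=rep, seed=cell_seed, error="", **row)
                    )
            except (StatsError, ValueError) as exc:
                records.append(
                    dict(
                        noise_p=p, replicate=rep, seed=cell_seed, error=str(exc),
                        analysis="", hand="", term="", estimate=np.nan,
                        statistic=np.nan, p_value=np.nan,
                        expert_mean=np.nan, novice_mean=np.nan,
                    )
                )
    return NoiseSweepResult(table=pd.DataFrame(records), alpha=alpha)


@dataclass
class ReducedVocabularyResult:
    """Similarity tables and suture-level skill tests under a reduced vocabulary."""

    variant: str
    similarity_tables: dict  # hand -> DataFrame
    lmm_results: dict  # hand -> MixedModelResult
    n_skipped: int
    n_items: int


def reduced_vocabulary_analysis(
    dataset: AnnotationDataset, variant: str
) -> ReducedVocabularyResult:
    """Re-run the suture-level similarity pipeline under a collapsed vocabulary.

    Items with no in-vocabulary activity time (possible under
    ``actions_only4``) are skipped and counted; more than 50% skipped items
    aborts with a diagnostic.
    """
    if variant not in ("actions_special6", "actions_only4"):
        raise NoiseError(
            f"variant must be 'actions_special6' or 'actions_only4', got {variant!r}"
        )
    vocab = get_vocabulary(variant)
    tables = {}
    results = {}
    n_skipped = 0
    n_items = 0
    for hand in ("left", "right"):
        table = similarity_table(dataset, "suture", hand, vocab)
        skipped = table.attrs.get("skipped", [])
        n_skipped += len(skipped)
        n_items += len(table) + len(skipped)
        tables[hand] = table
    if n_items and n_skipped / n_items > 0.5:
        raise NoiseError(
            f"{n_skipped}/{n_items} items had no in-vocabulary activity time under "
            f"{variant!r}; the reduced-vocabulary analysis is not meaningful"
        )
    for hand in ("left", "right"):
        results[hand] = suture_level_lmm(tables[hand], "difference")
    return ReducedVocabularyResult(
        variant=variant,
        similarity_tables=tables,
        lmm_results=results,
        n_skipped=n_skipped,
        n_items=n_items,
    )
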