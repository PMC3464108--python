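"""End-to-end convenience: normalize → score → linkage-filter → call."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .linkage import LinkageFlagger, LinkageWindow
from .normalize import PlateNormalizer
from .scoring import InteractionScorer, ScoringConfig, call_hits


@dataclass
class ScreenResult:
    normalized: pd.DataFrame
    normalization_report: pd.DataFrame
    results: pd.DataFrame
    per_experiment: pd.DataFrame


def score_screen(
    colonies: pd.DataFrame,
    annotations: pd.DataFrame | None = None,
    windows: Sequence[LinkageWindow] = (),
    config: ScoringConfig = ScoringConfig(),
    middle_stat: str = "mean",
    per_ring: bool = False,
) -> ScreenResult:
    """Run the full per-screen analysis on a raw colony table.

    Normalizes all plates together, scores every gene, flags linkage when
    annotations and windows are given, and adjusts/calls over the resulting
    universe.
    """
    normalizer = PlateNormalizer(middle_stat=middle_stat, per_ring=per_ring)
    normalized = normalizer.fit(colonies).transform(colonies)
    scorer = InteractionScorer(
        alpha=config.alpha, diff_threshold=config.diff_threshold,
        adjust_method=config.adjust_method, combine=config.combine,
        sided=config.sided,
    ).fit(normalized)
    stats = scorer.stats_
    if annotations is not None and len(windows):
        stats = LinkageFlagger(windows).fit(annotations).transform(stats)
    results = call_hits(stats, config)
    return ScreenResult(
        normalized=normalized,
        normalization_report=normalizer.report_,
        results=results,
        per_experiment=scorer.per_experiment_,
    )
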