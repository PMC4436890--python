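"""Agreement statistics between delineations.

The per-area overlap score between two labelings of the same surface is
100 * |A_i intersect B_i| / |A_i union B_i| — an intersection-over-
union (Jaccard) percentage on the vertex sets of area i.  The V4
overlap fraction of an activation pattern is
100 * |active in V4| / |active in ventral stream|, the percentage of
ventral-stream activation that falls inside retinotopically defined V4.
Group summaries report per-area mean and sample SD across cases, with
areas missing from both labelings of a case excluded as missing rather
than imputed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import (
    AREA_CODES,
    BAND_ORDER,
    ActivationMask,
    AreaLabeling,
    OverlapReport,
    ParameterError,
)

__all__ = [
    "overlap_score",
    "v4_overlap_fraction",
    "compare_labelings",
    "method_agreement",
    "report_to_frames",
]

DEFAULT_VENTRAL = ("V2v", "V3v", "V4")


def overlap_score(a: AreaLabeling, b: AreaLabeling, area: str | int) -> float:
    """Percent intersection-over-union of one area across two labelings.

    Returns NaN (missing) when the area is absent from both labelings;
    0 when it is present in exactly one (total disagreement).
    """
    if a.labels.shape != b.labels.shape:
        raise ParameterError("labelings must live on the same vertex set")
    code = AREA_CODES[area] if isinstance(area, str) else int(area)
    in_a = a.labels == code
    in_b = b.labels == code
    union = int(np.count_nonzero(in_a | in_b))
    if union == 0:
        return float("nan")
    inter = int(np.count_nonzero(in_a & in_b))
    return 100.0 * inter / union


def v4_overlap_fraction(
    activation: ActivationMask,
    labeling: AreaLabeling,
    ventral_areas: tuple[str, ...] = DEFAULT_VENTRAL,
) -> float:
    """Percent of ventral-stream activation falling inside V4.

    ``activation`` and ``labeling`` must index the same space.  Returns
    NaN when no active member lies in the ventral union (denominator
    zero, reported as missing).
    """
    codes = [AREA_CODES[a] for a in ventral_areas]
    active_labels = labeling.labels[activation.member_ids]
    n_ventral = int(np.count_nonzero(np.isin(active_labels, codes)))
    if n_ventral == 0:
        return float("nan")
    n_v4 = int(np.count_nonzero(active_labels == AREA_CODES["V4"]))
    return 100.0 * n_v4 / n_ventral


def compare_labelings(
    cases: list[tuple[AreaLabeling, AreaLabeling]],
    areas: tuple[str, ...] | None = None,
    space: str = "surface",
) -> OverlapReport:
    """Per-area overlap scores across cases with summary moments.

    One score per (case, area); missing cells (area absent from both
    labelings of a case) stay NaN and are excluded from the moments.
    """
    if not cases:
        raise ParameterError("need at least one case")
    areas = areas or BAND_ORDER
    scores = {
        a: np.array([overlap_score(x, y, a) for x, y in cases]) for a in areas
    }
    return OverlapReport(scores=scores, space=space)  # type: ignore[arg-type]


def method_agreement(scores_a: np.ndarray, scores_b: np.ndarray) -> float:
    """Pearson correlation between two per-case score vectors.

    Cases with either value missing are dropped pairwise; at least
    three complete pairs are required.  Zero variance in either vector
    yields NaN (undefined).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ParameterError("score vectors must have equal length")
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    if a.size < 3:
        raise ParameterError("need at least three complete pairs")
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def report_to_frames(report: OverlapReport) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long (area, case, score) and summary (area, n, mean, sd) tables."""
    rows = [
        {"area": a, "case": i, "score": s}
        for a, vec in report.scores.items()
        for i, s in enumerate(vec)
    ]
    long = pd.DataFrame(rows)
    mean = report.mean_per_area()
    sd = report.sd_per_area()
    summary = pd.DataFrame(
        [
            {
                "area": a,
                "n": int(np.count_nonzero(np.isfinite(report.scores[a]))),
                "mean": mean[a],
                "sd": sd[a],
            }
            for a in report.scores
        ]
    )
    return long, summary
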