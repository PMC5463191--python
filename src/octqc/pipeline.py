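"""Study orchestration: per-scan quality reports, mean curves relative to
the 2-frame baseline, the per-eye frame-matching analysis, and design
bookkeeping.

The matching analysis asks, per eye and per measure, for the smallest
preoperative averaging setting whose raw image-level value reaches the same
eye's postoperative 16-frame value; ties count as achieved ("equal or
more"), and NONE records that no setting up to the maximum sufficed.  Raw
(not baseline-normalized) values are compared: the comparison is within one
eye, where baseline normalization would cancel for d and Dice but silently
change the SNR comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotations import LABEL_NAMES, LAYER_LABELS, rasterize
from .errors import ConfigurationError
from .metrics import QualityReport, image_quality, relative_to_baseline
from .segmentation import image_dice
from .synthetic import StudyDataset, StudyDesign

logger = logging.getLogger(__name__)

__all__ = [
    "StudySeries", "MatchingResult", "DesignCounts",
    "run_study", "series_to_frame", "summarize_curves",
    "matching_analysis", "design_counts",
]

MEASURES = ("snr", "d", "dice")
#: Measures whose summary curves are shown relative to the 2-frame baseline.
RELATIVE_MEASURES = ("snr", "d")


@dataclass
class StudySeries:
    """All quality reports of one eye over the (condition, M) grid."""

    eye_id: str
    reports: dict[tuple[str, int], QualityReport]
    gaps: list[tuple[str, int]]

    def values(self, condition: str, measure: str) -> dict[int, float]:
        """Image-level values of one measure for one condition, by M."""
        return {
            m: rep.value(measure)
            for (cond, m), rep in sorted(self.reports.items())
            if cond == condition
        }


@dataclass
class MatchingResult:
    """Min preoperative M reaching the postoperative target, or None."""

    eye_id: str
    measure: str
    matched_m: int | None


@dataclass(frozen=True)
class DesignCounts:
    """Bookkeeping totals implied by a study design."""

    scans_per_patient: int
    layers_per_patient: int
    boundaries_per_patient: int
    total_annotations: int


def _scan_seed(seed: int, eye_index: int, condition: str, m: int) -> int:
    cond_code = 0 if condition == "pre" else 1
    return int(
        np.random.SeedSequence(
            [int(seed), int(eye_index), cond_code, int(m)]
        ).generate_state(1)[0]
    )


def run_study(
    dataset: StudyDataset, seed: int, compute_dice: bool = True
) -> list[StudySeries]:
    """Compute a QualityReport for every scan of every eye.

    Deterministic given ``seed``; unreadable or missing scans are recorded
    as gaps and the run continues.
    """
    series: list[StudySeries] = []
    recorded_gaps = {
        (g["eye"], g["condition"], int(g["n_averaged"])) for g in dataset.gaps
    }
    for eye_index, eye in enumerate(dataset.eyes):
        reports: dict[tuple[str, int], QualityReport] = {}
        gaps: list[tuple[str, int]] = []
        mask = None
        for cond in dataset.design.conditions:
            for m in dataset.design.settings:
                scan = eye.scans.get((cond, m))
                if scan is None:
                    if (eye.eye_id, cond, m) not in recorded_gaps:
                        logger.warning("missing scan %s %s M=%d",
                                       eye.eye_id, cond, m)
                    gaps.append((cond, m))
                    continue
                if mask is None or mask.labels.shape != scan.image.shape:
                    mask = rasterize(
                        eye.boundaries, depth=scan.depth, band=dataset.band
                    )
                report = image_quality(scan, mask)
                if compute_dice:
                    report.dice, _ = image_dice(
                        scan, mask,
                        seed=_scan_seed(seed, eye_index, cond, m),
                    )
                reports[(cond, m)] = report
        series.append(StudySeries(eye_id=eye.eye_id, reports=reports, gaps=gaps))
        logger.info("analyzed %s: %d reports, %d gaps",
                    eye.eye_id, len(reports), len(gaps))
    return series


def series_to_frame(series: list[StudySeries]) -> pd.DataFrame:
    """Tidy long table: eye, condition, n_averaged, layer, metric, value."""
    rows = []
    for s in series:
        for (cond, m), rep in sorted(s.reports.items()):
            for measure in MEASURES:
                arr = {"snr": rep.snr, "d": rep.d, "dice": rep.dice}[measure]
                for k, label in enumerate(LAYER_LABELS):
                    rows.append(
                        (s.eye_id, cond, m, LABEL_NAMES[label], measure,
                         float(arr[k]))
                    )
                rows.append((s.eye_id, cond, m, "image", measure,
                             rep.value(measure)))
    return pd.DataFrame(
        rows, columns=["eye", "condition", "n_averaged", "layer", "metric",
                       "value"]
    )


def summarize_curves(
    series: list[StudySeries],
    measure: str,
    baseline_m: int = 2,
) -> pd.DataFrame:
    """Mean image-level curve per condition over eyes.

    SNR and d are normalized per eye to the 2-frame baseline before
    averaging; Dice (already on [0, 1]) is averaged raw.  Eyes with gaps at
    a setting are excluded there, with counts reported.
    """
    if not series:
        raise ConfigurationError("summarize_curves needs at least one series")
    rows = []
    conditions = sorted({cond for s in series for (cond, _) in s.reports})
    for cond in conditions:
        per_m: dict[int, list[float]] = {}
        for s in series:
            vals = {
                m: v for m, v in s.values(cond, measure).items()
                if np.isfinite(v)
            }
            if not vals:
                continue
            if measure in RELATIVE_MEASURES:
                try:
                    vals = relative_to_baseline(vals, baseline_m=baseline_m)
                except ConfigurationError:
                    logger.warning("eye %s %s: no %d-frame baseline, excluded",
                                   s.eye_id, cond, baseline_m)
                    continue
            for m, v in vals.items():
                per_m.setdefault(m, []).append(v)
        for m in sorted(per_m):
            rows.append((measure, cond, m, float(np.mean(per_m[m])),
                         len(per_m[m])))
    return pd.DataFrame(
        rows, columns=["measure", "condition", "n_averaged", "mean_value",
                       "n_eyes"]
    )


def matching_analysis(
    series: StudySeries, measure: str, target_m: int = 16
) -> MatchingResult:
    """Smallest preoperative M whose raw value reaches the postoperative
    value at ``target_m`` frames (ties achieve it); None if no setting does.
    """
    post = series.values("post", measure)
    if target_m not in post or not np.isfinite(post[target_m]):
        raise ConfigurationError(
            f"eye {series.eye_id}: postoperative M={target_m} value missing"
        )
    target = post[target_m]
    pre = series.values("pre", measure)
    for m in sorted(pre):
        if np.isfinite(pre[m]) and pre[m] >= target:
            return MatchingResult(series.eye_id, measure, m)
    return MatchingResult(series.eye_id, measure, None)


def design_counts(design: StudyDesign) -> DesignCounts:
    """Scan/layer/boundary bookkeeping implied by the design grid."""
    scans = len(design.conditions) * len(design.settings)
    layers = scans * design.n_layers
    boundaries = scans * design.n_boundaries
    return DesignCounts(
        scans_per_patient=scans,
        layers_per_patient=layers,
        boundaries_per_patient=boundaries,
        total_annotations=boundaries * design.n_eyes,
    )
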