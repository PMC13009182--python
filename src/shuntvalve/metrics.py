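"""Evaluation statistics for the setting-detection pipeline.

Covers per-label segmentation overlap (Dice / IoU), the determinability
rate, the 8x8 setting confusion matrix with exact and adjacent-setting
accuracy, per-setting angle summaries, and Clopper-Pearson exact
binomial confidence intervals.  Accuracies use ALL cases in the
denominator: a case whose angle could not be determined counts as
incorrect, since a clinician gets no usable prediction for it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .settings import N_SETTINGS, setting_to_expected_angle, settings_adjacent
from .volumes_io import LABEL_NAMES, LabelMap


def _overlap_counts(map_a: LabelMap, map_b: LabelMap, label: int) -> tuple[int, int, int]:
    if not map_a.same_geometry(map_b):
        raise ValueError("label maps have mismatched geometry (shape or affine)")
    a = map_a.labels == label
    b = map_b.labels == label
    return int(np.count_nonzero(a & b)), int(np.count_nonzero(a)), int(np.count_nonzero(b))


def dice(map_a: LabelMap, map_b: LabelMap, label: int) -> float:
    """Dice similarity 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    inter, na, nb = _overlap_counts(map_a, map_b, label)
    if na + nb == 0:
        return 1.0
    return 2.0 * inter / (na + nb)


def iou(map_a: LabelMap, map_b: LabelMap, label: int) -> float:
    """Jaccard index |A∩B| / |A∪B|; 1.0 when both masks are empty."""
    inter, na, nb = _overlap_counts(map_a, map_b, label)
    union = na + nb - inter
    if union == 0:
        return 1.0
    return inter / union


@dataclass
class OverlapScores:
    """Per-label Dice/IoU between a reference and a predicted label map."""

    dsc: dict[str, float]
    iou: dict[str, float]
    voxels_ref: dict[str, int]
    voxels_pred: dict[str, int]


def overlap_scores(reference: LabelMap, predicted: LabelMap) -> OverlapScores:
    dsc, jac, nref, npred = {}, {}, {}, {}
    for label, name in LABEL_NAMES.items():
        inter, na, nb = _overlap_counts(reference, predicted, label)
        dsc[name] = 1.0 if na + nb == 0 else 2.0 * inter / (na + nb)
        union = na + nb - inter
        jac[name] = 1.0 if union == 0 else inter / union
        nref[name], npred[name] = na, nb
    return OverlapScores(dsc=dsc, iou=jac, voxels_ref=nref, voxels_pred=npred)


def clopper_pearson(
    successes: int, trials: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Exact binomial confidence interval from beta-distribution quantiles.

    Lower bound is the alpha/2 quantile of Beta(k, n-k+1) (0 when k=0);
    upper is the 1-alpha/2 quantile of Beta(k+1, n-k) (1 when k=n).
    """
    k, n = int(successes), int(trials)
    if n < 1 or not 0 <= k <= n:
        raise ValueError(f"need 0 <= successes <= trials with trials >= 1, got {k}/{n}")
    if not 0.0 < confidence < 1.0:
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")
    alpha = 1.0 - confidence
    lower = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2.0, k, n - k + 1))
    upper = 1.0 if k == n else float(stats.beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return lower, upper


def percent(successes: int, trials: int, decimals: int = 1) -> float:
    """A proportion as a percentage rounded for reporting (96.0, 97.3, ...)."""
    if trials < 1:
        raise ValueError("trials must be >= 1")
    return round(100.0 * successes / trials, decimals)


@dataclass
class ConfusionMatrix:
    """8x8 counts, rows = true setting, cols = predicted setting.

    Undeterminable cases are tallied separately and never enter the
    matrix; matrix total therefore equals the number of determinable
    cases.
    """

    counts: np.ndarray
    n_undeterminable: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (N_SETTINGS, N_SETTINGS):
            raise ValueError("confusion matrix must be 8x8")
        if np.any(self.counts < 0) or self.n_undeterminable < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def n_determinable(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        idx = pd.Index(range(1, N_SETTINGS + 1), name="true_setting")
        cols = [f"pred_{s}" for s in range(1, N_SETTINGS + 1)]
        return pd.DataFrame(self.counts, index=idx, columns=cols)


@dataclass
class AccuracyEstimate:
    successes: int
    trials: int
    confidence: float = 0.95
    value: float = field(init=False)
    ci_lower: float = field(init=False)
    ci_upper: float = field(init=False)

    def __post_init__(self) -> None:
        self.value = self.successes / self.trials
        self.ci_lower, self.ci_upper = clopper_pearson(
            self.successes, self.trials, self.confidence
        )

    def as_dict(self) -> dict:
        return {
            "successes": self.successes,
            "trials": self.trials,
            "value": self.value,
            "percent": percent(self.successes, self.trials),
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "confidence": self.confidence,
        }


def confusion_and_accuracies(
    truths,
    preds,
    *,
    circular_adjacency: bool = False,
    confidence: float = 0.95,
) -> tuple[ConfusionMatrix, AccuracyEstimate, AccuracyEstimate, AccuracyEstimate]:
    """Confusion matrix plus exact / adjacent accuracy and determinability.

    ``preds`` entries are settings 1..8 or None for undeterminable
    cases.  All three rates use the full case count as denominator and
    carry Clopper-Pearson intervals at ``confidence``.
    """
    truths = list(truths)
    preds = list(preds)
    if len(truths) != len(preds):
        raise ValueError(f"length mismatch: {len(truths)} truths vs {len(preds)} predictions")
    counts = np.zeros((N_SETTINGS, N_SETTINGS), dtype=int)
    n_undet = exact = adjacent = 0
    for t, p in zip(truths, preds):
        t = int(t)
        if not 1 <= t <= N_SETTINGS:
            raise ValueError(f"invalid true setting {t}")
        if p is None:
            n_undet += 1
            continue
        p = int(p)
        if not 1 <= p <= N_SETTINGS:
            raise ValueError(f"invalid predicted setting {p}")
        counts[t - 1, p - 1] += 1
        exact += int(t == p)
        adjacent += int(settings_adjacent(t, p, circular=circular_adjacency))
    n = len(truths)
    matrix = ConfusionMatrix(counts=counts, n_undeterminable=n_undet)
    return (
        matrix,
        AccuracyEstimate(exact, n, confidence),
        AccuracyEstimate(adjacent, n, confidence),
        AccuracyEstimate(n - n_undet, n, confidence),
    )


@dataclass
class EvalReport:
    """Bundle of cohort-level evaluation results, serialisable to JSON."""

    confusion: ConfusionMatrix
    exact_accuracy: AccuracyEstimate
    adjacent_accuracy: AccuracyEstimate
    determinable_rate: AccuracyEstimate
    angle_table: pd.DataFrame
    overlap_summary: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        out = {
            "confusion_matrix": self.confusion.counts.tolist(),
            "n_undeterminable": self.confusion.n_undeterminable,
            "exact_accuracy": self.exact_accuracy.as_dict(),
            "adjacent_accuracy": self.adjacent_accuracy.as_dict(),
            "determinable_rate": self.determinable_rate.as_dict(),
            "angle_summary": self.angle_table.to_dict(orient="records"),
        }
        if self.overlap_summary is not None:
            out["overlap_summary"] = self.overlap_summary.to_dict(orient="records")
        return out


def evaluate_predictions(
    truths,
    preds,
    angle_records=None,
    overlaps: list[OverlapScores] | None = None,
    *,
    circular_adjacency: bool = False,
    confidence: float = 0.95,
) -> EvalReport:
    """Assemble the full evaluation report for one cohort.

    ``angle_records`` is the (true_setting, measured_angle) list for the
    determinable cases; ``overlaps`` optionally carries per-case
    segmentation scores, summarised as per-label mean and SD.
    """
    matrix, exact, adjacent, determinable = confusion_and_accuracies(
        truths, preds, circular_adjacency=circular_adjacency, confidence=confidence
    )
    table = angle_summary(angle_records if angle_records is not None else [])
    overlap_frame = None
    if overlaps:
        rows = []
        for name in LABEL_NAMES.values():
            dscs = np.array([o.dsc[name] for o in overlaps])
            ious = np.array([o.iou[name] for o in overlaps])
            rows.append(
                {
                    "label": name,
                    "mean_dsc": float(dscs.mean()),
                    "sd_dsc": float(dscs.std(ddof=1)) if len(dscs) > 1 else float("nan"),
                    "mean_iou": float(ious.mean()),
                    "sd_iou": float(ious.std(ddof=1)) if len(ious) > 1 else float("nan"),
                }
            )
        overlap_frame = pd.DataFrame(rows)
    return EvalReport(
        confusion=matrix,
        exact_accuracy=exact,
        adjacent_accuracy=adjacent,
        determinable_rate=determinable,
        angle_table=table,
        overlap_summary=overlap_frame,
    )


def angle_summary(records) -> pd.DataFrame:
    """Per-setting mean/SD of measured angles next to the expected angle.

    ``records`` is an iterable of (true_setting, measured_angle_deg).
    SD uses the n-1 denominator and is reported as NaN for singleton
    settings; settings with no samples are omitted.  ``expected_outside_2sd``
    flags settings whose nominal zone-centre angle falls outside
    mean +/- 2 SD.
    """
    frame = pd.DataFrame(records, columns=["setting", "angle_deg"])
    rows = []
    for s in range(1, N_SETTINGS + 1):
        angles = frame.loc[frame["setting"] == s, "angle_deg"].to_numpy(dtype=float)
        if angles.size == 0:
            continue
        mean = float(angles.mean())
        sd = float(angles.std(ddof=1)) if angles.size > 1 else float("nan")
        expected = setting_to_expected_angle(s)
        outside = bool(abs(expected - mean) > 2 * sd) if angles.size > 1 else False
        rows.append(
            {
                "setting": s,
                "n": int(angles.size),
                "mean_deg": mean,
                "sd_deg": sd,
                "expected_deg": expected,
                "expected_outside_2sd": outside,
            }
        )
    return pd.DataFrame(rows)


def plot_angle_by_setting(records, path, *, show_zones: bool = True) -> None:
    """Scatter of measured angle vs setting with mean +/- SD error bars.

    Optional reporting hook; imports matplotlib lazily.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = pd.DataFrame(records, columns=["setting", "angle_deg"])
    summary = angle_summary(records)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(frame["setting"], frame["angle_deg"], s=10, c="0.6", zorder=2)
    ax.errorbar(
        summary["setting"], summary["mean_deg"], yerr=summary["sd_deg"].fillna(0.0),
        fmt="o", mfc="white", mec="black", ecolor="black", zorder=3,
    )
    if show_zones:
        for cut in np.arange(-90.0, 271.0, 45.0):
            ax.axhline(cut, ls=":", c="0.8", zorder=1)
    ax.set_xlabel("valve setting")
    ax.set_ylabel("indicator angle (deg)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
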