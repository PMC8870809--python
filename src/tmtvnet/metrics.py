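"""Validation statistics for automated vs. manual TMTV segmentations.

Voxel-level agreement (dice, Jaccard, sensitivity/specificity/predictive
values) plus cohort-level agreement between two TMTV measurement arms:
distribution statistics, paired Student's t-test, Spearman rank
correlation and Bland-Altman limits of agreement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "OverlapMetrics",
    "dice",
    "jaccard",
    "confusion_metrics",
    "bland_altman",
    "spearman",
    "paired_t",
    "distribution_stats",
    "CaseRecord",
    "AgreementReport",
    "cohort_report",
]


def _as_masks(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a, b = np.asarray(a, dtype=bool), np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return a, b


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice score 2|A∩B| / (|A|+|B|); two empty masks agree perfectly (1)."""
    a, b = _as_masks(a, b)
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard coefficient |A∩B| / |A∪B| (= dice / (2 - dice))."""
    a, b = _as_masks(a, b)
    union = int((a | b).sum())
    if union == 0:
        return 1.0
    return int((a & b).sum()) / union


@dataclass
class OverlapMetrics:
    """Voxel-level agreement between a predicted and a truth mask.

    Ratios with a zero denominator are reported as ``nan`` (missing),
    never silently as 0.
    """

    dice: float
    jaccard: float
    se: float
    sp: float
    ppv: float
    npv: float


def confusion_metrics(pred: np.ndarray, truth: np.ndarray) -> OverlapMetrics:
    """Se = TP/(TP+FN), Sp = TN/(TN+FP), PPV = TP/(TP+FP), NPV = TN/(TN+FN)
    computed over voxels, alongside dice and Jaccard."""
    pred, truth = _as_masks(pred, truth)
    tp = int((pred & truth).sum())
    tn = int((~pred & ~truth).sum())
    fp = int((pred & ~truth).sum())
    fn = int((~pred & truth).sum())

    def ratio(num: int, den: int) -> float:
        return num / den if den else float("nan")

    return OverlapMetrics(
        dice=dice(pred, truth),
        jaccard=jaccard(pred, truth),
        se=ratio(tp, tp + fn),
        sp=ratio(tn, tn + fp),
        ppv=ratio(tp, tp + fp),
        npv=ratio(tn, tn + fn),
    )


def bland_altman(x: Sequence[float], y: Sequence[float]) -> dict[str, float]:
    """Bland-Altman agreement of two paired measurements.

    Differences d = x - y; bias = mean(d); limits of agreement
    bias ± 1.96 * sd(d) with the sample (n-1) standard deviation.
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return {"bias": bias, "loa_low": bias - 1.96 * sd, "loa_high": bias + 1.96 * sd}


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (average ranks on ties) with two-sided p.

    Constant input has no defined rank correlation: returns (nan, nan).
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    r, p = stats.spearmanr(x, y)
    return float(r), float(p)


def paired_t(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided paired Student's t-test p-value on the per-case pairs.

    Identical arms (all differences zero) give p = 1 by convention.
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need equal-length inputs with n >= 2")
    d = x - y
    if np.all(d == 0):
        return 1.0
    return float(stats.ttest_rel(x, y).pvalue)


def distribution_stats(values: Sequence[float]) -> dict[str, float]:
    """max / min / mean / median / sd summary of one measurement arm."""
    v = np.asarray(values, dtype=float)
    return {
        "max": float(v.max()),
        "min": float(v.min()),
        "mean": float(v.mean()),
        "median": float(np.median(v)),
        "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
    }


# ---------------------------------------------------------------------------
# cohort-level report

@dataclass
class CaseRecord:
    """Manual and predicted results for one case.

    ``manual_masks`` / ``pred_masks`` map methodology name (e.g. "41pc",
    "suv2.5", "suv4") to the final binary mask; the TMTV dictionaries map
    the same keys to volumes in mL.  ``subtype`` is the lymphoma subtype
    label (HL / DLBCL / FL) used for stratification.
    """

    case_id: str
    subtype: str
    manual_masks: Mapping[str, np.ndarray]
    pred_masks: Mapping[str, np.ndarray]
    manual_tmtv_ml: Mapping[str, float]
    pred_tmtv_ml: Mapping[str, float]


@dataclass
class AgreementReport:
    """Per-case table plus cohort summaries, per methodology (and subtype)."""

    per_case: pd.DataFrame
    summary: pd.DataFrame
    by_subtype: pd.DataFrame

    def to_csv(self, prefix: str) -> list[str]:
        paths = []
        for name, frame in (
            ("per_case", self.per_case),
            ("summary", self.summary),
            ("by_subtype", self.by_subtype),
        ):
            path = f"{prefix}_{name}.csv"
            frame.to_csv(path, index=False)
            paths.append(path)
        return paths


def cohort_report(cases: Sequence[CaseRecord], methods: Sequence[str]) -> AgreementReport:
    """Aggregate agreement between manual and predicted TMTV over a cohort.

    Per case and methodology: dice between final masks and both TMTV
    values.  Per methodology (overall and per subtype): median and
    mean±SD dice, TMTV distribution statistics for both arms, Spearman
    correlation, Bland-Altman bias and limits of agreement, and the
    paired t-test p-value.  Cases missing a methodology are excluded from
    that methodology's rows.
    """
    rows = []
    for case in cases:
        for m in methods:
            if m not in case.manual_masks or m not in case.pred_masks:
                continue
            rows.append(
                {
                    "case_id": case.case_id,
                    "subtype": case.subtype,
                    "method": m,
                    "dice": dice(case.pred_masks[m], case.manual_masks[m]),
                    "manual_tmtv_ml": float(case.manual_tmtv_ml[m]),
                    "pred_tmtv_ml": float(case.pred_tmtv_ml[m]),
                }
            )
    per_case = pd.DataFrame(rows)
    if per_case.empty:
        raise ValueError("no (case, method) pairs to report on")

    def summarize(frame: pd.DataFrame, keys: dict) -> dict:
        out = dict(keys)
        out["n"] = len(frame)
        out["dice_median"] = float(frame["dice"].median())
        out["dice_mean"] = float(frame["dice"].mean())
        out["dice_sd"] = float(frame["dice"].std(ddof=1)) if len(frame) > 1 else 0.0
        for arm in ("manual", "pred"):
            for k, v in distribution_stats(frame[f"{arm}_tmtv_ml"]).items():
                out[f"{arm}_tmtv_{k}"] = v
        man, prd = frame["manual_tmtv_ml"].to_numpy(), frame["pred_tmtv_ml"].to_numpy()
        if len(frame) >= 3:
            r, p = spearman(man, prd)
            out["spearman_r"], out["spearman_p"] = r, p
        if len(frame) >= 2:
            ba = bland_altman(man, prd)
            out.update({f"ba_{k}": v for k, v in ba.items()})
            out["paired_t_p"] = paired_t(man, prd)
        return out

    summary = pd.DataFrame(
        [summarize(g, {"method": m}) for m, g in per_case.groupby("method", sort=False)]
    )
    by_subtype = pd.DataFrame(
        [
            summarize(g, {"subtype": s, "method": m})
            for (s, m), g in per_case.groupby(["subtype", "method"], sort=False)
        ]
    )
    return AgreementReport(per_case=per_case, summary=summary, by_subtype=by_subtype)


# ---------------------------------------------------------------------------
# optional plots (Bland-Altman / correlation / distribution)

def plot_agreement(report: AgreementReport, method: str, out_path: str) -> None:
    """Three-panel agreement figure for one methodology."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = report.per_case[report.per_case["method"] == method]
    man, prd = frame["manual_tmtv_ml"], frame["pred_tmtv_ml"]
    fig, axes = plt.subplots(1, 3, figsize=(12, 4))
    axes[0].boxplot([man, prd], tick_labels=["manual", "predicted"])
    axes[0].set_ylabel("TMTV (mL)")
    axes[0].set_title(f"{method}: distribution")
    mean, diff = (man + prd) / 2, man - prd
    ba = bland_altman(man, prd)
    axes[1].scatter(mean, diff, s=12)
    for key, style in (("bias", "-"), ("loa_low", "--"), ("loa_high", "--")):
        axes[1].axhline(ba[key], linestyle=style, color="k")
    axes[1].set_xlabel("mean TMTV (mL)")
    axes[1].set_ylabel("manual - predicted (mL)")
    axes[1].set_title("Bland-Altman")
    axes[2].scatter(man, prd, s=12)
    lim = max(float(man.max()), float(prd.max())) or 1.0
    axes[2].plot([0, lim], [0, lim], "k--", linewidth=0.8)
    axes[2].set_xlabel("manual TMTV (mL)")
    axes[2].set_ylabel("predicted TMTV (mL)")
    axes[2].set_title("correlation")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
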