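"""Per-marker discrimination of induction-chemotherapy response.

Patients are dichotomized into responders (complete or partial response,
CR/PR) and non-responders (stable or progressive disease, SD/PD). The
*positive class* throughout this module is the non-responder (SD/PD) group:
sensitivity is the fraction of SD/PD patients called SD/PD, and
1 - specificity is the fraction of CR/PR patients called SD/PD. The ROC
curve is plotted in exactly those coordinates and its area (AUC) equals
the Mann-Whitney concordant-pair fraction with ties counted 1/2.

Orientation is per marker: ``"high"`` means high scores indicate SD/PD
(e.g. high XPF expression tracking worse response), ``"low"`` the reverse,
and ``"auto"`` picks whichever direction yields AUC >= 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "RESPONSE_CATEGORIES",
    "RocSummary",
    "ThresholdMetrics",
    "dichotomize_response",
    "roc_curve",
    "pct_correct_at_full_capture",
    "response_rank_test",
    "threshold_metrics",
    "optimal_response_threshold",
]

RESPONSE_CATEGORIES = ("CR", "PR", "SD", "PD")
_RESPONDER = {"CR", "PR"}


@dataclass
class RocSummary:
    """ROC curve, AUC and the 100%-SD/PD-capture statistic for one marker."""

    points: list[tuple[float, float]]  # (1 - specificity, sensitivity)
    auc: float
    pct_correct_at_full_capture: float | None
    orientation: str  # resolved direction, "high" or "low"


@dataclass
class ThresholdMetrics:
    """Classification statistics of a single score threshold.

    The 2x2 table is predicted vs actual class with SD/PD positive.
    ``relative_risk`` is the risk of actual SD/PD among predicted SD/PD
    relative to predicted CR/PR. When the table contains a zero cell,
    RR and OR use the Haldane-Anscombe +0.5 correction and
    ``haldane_corrected`` is set.
    """

    threshold: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    relative_risk: float
    odds_ratio: float
    apparent_error_rate: float
    table: tuple[int, int, int, int] = (0, 0, 0, 0)  # TP, FN, FP, TN
    haldane_corrected: bool = False
    youden: float = field(init=False)

    def __post_init__(self) -> None:
        self.youden = self.sensitivity + self.specificity - 1.0


def dichotomize_response(category: str) -> bool:
    """True for responders (CR/PR), False for non-responders (SD/PD)."""
    if category not in RESPONSE_CATEGORIES:
        raise ValueError(f"unknown response category {category!r}")
    return category in _RESPONDER


def _as_arrays(scores, responder):
    s = np.asarray(scores, dtype=float)
    r = np.asarray(responder, dtype=bool)
    if s.shape != r.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D and of equal length")
    if r.all() or (~r).all():
        raise ValueError("need at least one patient in each response class")
    return s, r


def _oriented(scores, orientation):
    """Return scores transformed so that *larger means SD/PD*."""
    if orientation == "high":
        return scores
    if orientation == "low":
        return -scores
    raise ValueError(f"orientation must be 'high' or 'low', got {orientation!r}")


def roc_curve(scores, responder, orientation: str = "high") -> RocSummary:
    """ROC sweep over all unique score thresholds.

    Points run from (0, 0) to (1, 1) in (1 - specificity, sensitivity)
    coordinates; AUC is the trapezoidal area, which equals the fraction of
    (SD/PD, CR/PR) pairs ranked concordantly with ties counted half.

    With ``orientation="auto"`` both directions are evaluated and the one
    with AUC >= 0.5 is reported (``RocSummary.orientation`` says which).
    """
    s, r = _as_arrays(scores, responder)
    if orientation == "auto":
        high = roc_curve(s, r, "high")
        return high if high.auc >= 0.5 else roc_curve(s, r, "low")

    x = _oriented(s, orientation)
    pos = ~r  # SD/PD
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())

    # Sweep thresholds downward through the unique scores; at threshold t the
    # prediction is SD/PD iff oriented score >= t.
    thresholds = np.unique(x)[::-1]
    pts = [(0.0, 0.0)]
    for t in thresholds:
        called = x >= t
        sens = float((called & pos).sum()) / n_pos
        fpr = float((called & ~pos).sum()) / n_neg
        pts.append((fpr, sens))
    if pts[-1] != (1.0, 1.0):
        pts.append((1.0, 1.0))

    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    auc = float(np.trapezoid(ys, xs))
    pct = pct_correct_at_full_capture(s, r, orientation)
    return RocSummary(points=pts, auc=auc, pct_correct_at_full_capture=pct,
                      orientation=orientation)


def pct_correct_at_full_capture(scores, responder, orientation: str = "high") -> float:
    """Percent of CR/PR patients correctly classified when every SD/PD is.

    The threshold is placed at the extreme score of the SD/PD class (its
    minimum under ``"high"`` orientation) so that every SD/PD patient is
    called SD/PD; the statistic is 100 x the fraction of CR/PR patients
    strictly on the responder side of that threshold.
    """
    s, r = _as_arrays(scores, responder)
    if orientation == "auto":
        orientation = roc_curve(s, r, "auto").orientation
    x = _oriented(s, orientation)
    capture = x[~r].min()  # all SD/PD have oriented score >= capture
    correct = (x[r] < capture).sum()
    return float(100.0 * correct / r.sum())


def response_rank_test(scores, responder) -> float:
    """Two-sided Wilcoxon rank-sum p for responder vs non-responder scores.

    Exact enumeration for combined n <= 20 without ties; otherwise the
    normal approximation with tie correction.
    """
    s, r = _as_arrays(scores, responder)
    if np.unique(s).size == 1:
        return 1.0  # constant scores carry no discrimination
    has_ties = np.unique(s).size < s.size
    method = "exact" if (s.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(s[r], s[~r], alternative="two-sided",
                             method=method, use_continuity=False)
    return float(min(res.pvalue, 1.0))


def threshold_metrics(scores, responder, threshold: float,
                      orientation: str = "high") -> ThresholdMetrics:
    """2x2-table statistics for calling SD/PD past ``threshold``.

    Under ``"high"`` orientation a patient is called SD/PD when their score
    exceeds the threshold. Margins that are empty leave the corresponding
    statistics NaN; zero cells trigger the Haldane-Anscombe correction for
    RR/OR only.
    """
    s, r = _as_arrays(scores, responder)
    x = _oriented(s, orientation)
    t = threshold if orientation == "high" else -threshold
    called = x > t
    pos = ~r
    tp = int((called & pos).sum())
    fn = int((~called & pos).sum())
    fp = int((called & ~pos).sum())
    tn = int((~called & ~pos).sum())

    def _ratio(num, den):
        return num / den if den > 0 else float("nan")

    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    ppv = _ratio(tp, tp + fp)
    npv = _ratio(tn, tn + fn)
    aer = (fp + fn) / (tp + fn + fp + tn)

    corrected = 0 in (tp, fn, fp, tn)
    a, b, c, d = (v + 0.5 for v in (tp, fp, fn, tn)) if corrected else (tp, fp, fn, tn)
    rr = (a / (a + b)) / (c / (c + d))
    odds = (a * d) / (b * c)

    return ThresholdMetrics(threshold=float(threshold), sensitivity=sens,
                            specificity=spec, ppv=ppv, npv=npv,
                            relative_risk=rr, odds_ratio=odds,
                            apparent_error_rate=aer, table=(tp, fn, fp, tn),
                            haldane_corrected=corrected)


def optimal_response_threshold(scores, responder,
                               orientation: str = "high"
                               ) -> tuple[float, ThresholdMetrics]:
    """Threshold minimizing the apparent error rate (AER).

    Candidates are midpoints of consecutive unique scores. Ties on AER are
    broken by maximal Youden index, then by the lower threshold, so the
    output is deterministic.
    """
    s, r = _as_arrays(scores, responder)
    if orientation == "auto":
        orientation = roc_curve(s, r, "auto").orientation
    uniq = np.unique(s)
    if uniq.size < 2:
        raise ValueError("need at least two unique scores to form a threshold")
    # midpoints plus the two degenerate thresholds (call everyone one
    # class), so the optimum never loses to the majority rule
    candidates = np.concatenate([[uniq[0] - (uniq[1] - uniq[0]) / 2.0],
                                 (uniq[:-1] + uniq[1:]) / 2.0,
                                 [uniq[-1] + (uniq[-1] - uniq[-2]) / 2.0]])

    best = None
    for t in candidates:
        m = threshold_metrics(s, r, t, orientation)
        key = (m.apparent_error_rate, -m.youden, t)
        if best is None or key < best[0]:
            best = (key, t, m)
    _, t, m = best
    return float(t), m
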