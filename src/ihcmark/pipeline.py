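"""End-to-end cohort analysis: response table, survival table, concordance.

Given a cohort table (one row per patient; response category, survival
time, event flag, and per-marker score columns), produce the three
study-style output tables:

* a per-marker **response table** — ROC AUC for discriminating
  non-responders (SD/PD) from responders (CR/PR), the percent of
  responders correctly classified when every SD/PD patient is captured,
  the rank-sum p-value, and the AER-optimal threshold with its metrics;
* a per-marker **survival table** — the minimum-p-value cutpoint under
  the 10% group-size rule, the log-rank statistic, and the univariate Cox
  hazard ratio per standard deviation of score;
* a **concordance table** — Pearson r / r^2 between pathologist (IxQ)
  and machine (H-score) scoring per marker.

Markers measured in fewer than half the patients produce rows with
undefined (NaN) statistics rather than errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import response as resp
from . import survival as surv
from .scoring import concordance

__all__ = [
    "MarkerAnalysis",
    "AnalysisConfig",
    "CohortSummary",
    "summarize_cohort",
    "run_response_table",
    "run_survival_table",
    "run_concordance_table",
    "km_group_coordinates",
    "run_all",
    "read_analysis_config",
    "write_analysis_config",
]

log = logging.getLogger("ihcmark")


@dataclass
class MarkerAnalysis:
    """One marker column to analyze and its ROC orientation."""

    column: str  # column prefix, e.g. "XPF" or "pMK2_cyt"
    orientation: str = "auto"  # "high", "low" or "auto"


@dataclass
class AnalysisConfig:
    markers: list[MarkerAnalysis]
    score_field: str = "hscore"  # suffix of the score column analyzed
    min_group_frac: float = 0.10
    n_perm: int = 0  # permutation adjustment of the min-p; 0 = off
    seed: int = 0
    max_missing_frac: float = 0.5

    def __post_init__(self) -> None:
        if not self.markers:
            raise ValueError("marker list must be non-empty")
        if not 0 < self.min_group_frac < 0.5:
            raise ValueError("min_group_frac must lie in (0, 0.5)")


@dataclass
class CohortSummary:
    n: int
    counts: dict[str, int]
    percentages: dict[str, float]  # one decimal place
    n_events: int
    median_followup: float

    def as_frame(self) -> pd.DataFrame:
        rows = [{"category": c, "count": k, "percent": self.percentages[c]}
                for c, k in self.counts.items()]
        return pd.DataFrame(rows)


def summarize_cohort(cohort: pd.DataFrame) -> CohortSummary:
    """Tally response categories (percentages to one decimal) and follow-up."""
    if cohort.empty:
        raise ValueError("empty cohort")
    cats = cohort["response"]
    unknown = set(cats) - set(resp.RESPONSE_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown response categories: {sorted(unknown)}")
    n = len(cohort)
    counts = {c: int((cats == c).sum()) for c in resp.RESPONSE_CATEGORIES
              if (cats == c).any()}
    pct = {c: round(100.0 * k / n, 1) for c, k in counts.items()}
    n_events = int(cohort["event"].sum()) if "event" in cohort else 0
    median_fu = float(cohort["time_months"].median()) if "time_months" in cohort else np.nan
    return CohortSummary(n=n, counts=counts, percentages=pct,
                         n_events=n_events, median_followup=median_fu)


def _score_column(cohort, marker: MarkerAnalysis, score_field: str):
    col = f"{marker.column}_{score_field}"
    if col not in cohort:
        raise KeyError(f"cohort table has no column {col!r}")
    return cohort[col].to_numpy(dtype=float)


def _undefined_row(marker: str, fields: list[str]) -> dict:
    row: dict = {"marker": marker}
    row.update({f: np.nan for f in fields})
    return row


_RESPONSE_FIELDS = ["auc", "pct_correct_at_full_capture", "rank_p",
                    "threshold", "aer", "sensitivity", "specificity",
                    "odds_ratio"]


def run_response_table(cohort: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    """One row per marker: AUC, full-capture percent, rank-sum p, optimal
    threshold metrics. Deterministic given the input."""
    if "response" not in cohort:
        raise ValueError("cohort table lacks a 'response' column")
    responder = cohort["response"].map(resp.dichotomize_response).to_numpy(dtype=bool)
    rows = []
    for marker in config.markers:
        scores = _score_column(cohort, marker, config.score_field)
        ok = np.isfinite(scores)
        if ok.mean() < 1.0 - config.max_missing_frac:
            log.warning("response: %s missing for >%.0f%% of patients; undefined",
                        marker.column, 100 * config.max_missing_frac)
            rows.append(_undefined_row(marker.column, _RESPONSE_FIELDS + ["orientation"]))
            continue
        s, r = scores[ok], responder[ok]
        roc = resp.roc_curve(s, r, marker.orientation)
        thr, m = resp.optimal_response_threshold(s, r, roc.orientation)
        rows.append({
            "marker": marker.column,
            "auc": roc.auc,
            "pct_correct_at_full_capture": roc.pct_correct_at_full_capture,
            "rank_p": resp.response_rank_test(s, r),
            "threshold": thr,
            "aer": m.apparent_error_rate,
            "sensitivity": m.sensitivity,
            "specificity": m.specificity,
            "odds_ratio": m.odds_ratio,
            "orientation": roc.orientation,
        })
        log.info("response: %s AUC=%.3f", marker.column, roc.auc)
    return pd.DataFrame(rows)


_SURVIVAL_FIELDS = ["threshold", "n_low", "n_high", "chi_square", "logrank_p",
                    "cox_beta", "cox_hr", "cox_p"]


def run_survival_table(cohort: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    """One row per marker: min-p cutpoint (10% rule), log-rank p, and the
    univariate Cox hazard ratio per sample standard deviation of score.

    Rows with missing survival time are excluded from this analysis only.
    With ``config.n_perm > 0`` a permutation-adjusted p accompanies the raw
    minimum p.
    """
    for col in ("time_months", "event"):
        if col not in cohort:
            raise ValueError(f"cohort table lacks a {col!r} column")
    keep = cohort["time_months"].notna().to_numpy()
    if not keep.all():
        log.warning("survival: dropping %d rows with missing survival time",
                    (~keep).sum())
    sub = cohort.loc[keep]
    times = sub["time_months"].to_numpy(dtype=float)
    events = sub["event"].to_numpy(dtype=bool)

    rows = []
    for marker in config.markers:
        scores = _score_column(sub, marker, config.score_field)
        ok = np.isfinite(scores)
        fields = _SURVIVAL_FIELDS + (["adjusted_p"] if config.n_perm else [])
        if ok.mean() < 1.0 - config.max_missing_frac or events[ok].sum() < 2:
            log.warning("survival: %s undefined (missing scores or <2 events)",
                        marker.column)
            rows.append(_undefined_row(marker.column, fields))
            continue
        s, t, e = scores[ok], times[ok], events[ok]
        cut = surv.optimal_survival_cutpoint(s, t, e, config.min_group_frac)
        z = (s - s.mean()) / s.std()
        cox = surv.cox_univariate(t, e, z)
        row = {"marker": marker.column}
        if cut is None:
            log.warning("survival: %s has no admissible cutpoint", marker.column)
            row.update({f: np.nan for f in
                        ("threshold", "n_low", "n_high", "chi_square", "logrank_p")})
        else:
            row.update({"threshold": cut.threshold, "n_low": cut.n_low,
                        "n_high": cut.n_high, "chi_square": cut.chi_square,
                        "logrank_p": cut.p_value})
        row.update({"cox_beta": cox.beta if cox.converged else np.nan,
                    "cox_hr": cox.hazard_ratio if cox.converged else np.nan,
                    "cox_p": cox.wald_p})
        if config.n_perm:
            row["adjusted_p"] = (
                surv.minp_permutation_adjust(s, t, e, config.n_perm,
                                             config.seed, config.min_group_frac)
                if cut is not None else np.nan)
        rows.append(row)
        log.info("survival: %s logrank_p=%s", marker.column,
                 None if cut is None else f"{cut.p_value:.4g}")
    return pd.DataFrame(rows)


def run_concordance_table(cohort: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    """Pearson concordance of pathologist (IxQ) vs machine (H-score) scores."""
    rows = []
    for marker in config.markers:
        try:
            a = _score_column(cohort, marker, "IxQ")
            b = _score_column(cohort, marker, "hscore")
        except KeyError:
            rows.append(_undefined_row(marker.column, ["r", "r_squared"]))
            continue
        ok = np.isfinite(a) & np.isfinite(b)
        try:
            c = concordance(a[ok], b[ok])
        except ValueError:
            rows.append(_undefined_row(marker.column, ["r", "r_squared"]))
            continue
        rows.append({"marker": marker.column, **c})
    return pd.DataFrame(rows)


def km_group_coordinates(cohort: pd.DataFrame, marker: MarkerAnalysis,
                         threshold: float, score_field: str = "hscore"
                         ) -> pd.DataFrame:
    """KM step-function coordinates for the low/high groups at a cutpoint,
    in long format (group, time, survival, at_risk) for plotting."""
    scores = _score_column(cohort, marker, score_field)
    frames = []
    for name, mask in (("low", scores <= threshold), ("high", scores > threshold)):
        km = surv.km_estimate(cohort.loc[mask, "time_months"],
                              cohort.loc[mask, "event"])
        frames.append(pd.DataFrame({
            "group": name, "time": km.event_times,
            "survival": km.survival_probs, "at_risk": km.at_risk}))
    return pd.concat(frames, ignore_index=True)


def _format_pvalues(df: pd.DataFrame) -> pd.DataFrame:
    """Render p-value columns to 4 significant figures for the text tables."""
    out = df.copy()
    for col in out.columns:
        if col.endswith("_p") or col in ("logrank_p", "adjusted_p"):
            out[col] = out[col].map(
                lambda v: f"{v:.4g}" if isinstance(v, float) and np.isfinite(v) else "")
    return out


def run_all(cohort: pd.DataFrame, config: AnalysisConfig, outdir) -> dict[str, pd.DataFrame]:
    """Run every stage and write the delimited output tables to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = {
        "cohort_summary": summarize_cohort(cohort).as_frame(),
        "response_table": run_response_table(cohort, config),
        "survival_table": run_survival_table(cohort, config),
        "concordance_table": run_concordance_table(cohort, config),
    }
    for name, df in tables.items():
        _format_pvalues(df).to_csv(outdir / f"{name}.csv", index=False)
        log.info("wrote %s", outdir / f"{name}.csv")
    return tables


# ---------------------------------------------------------------------------
# Config I/O (flat key-value text)

def write_analysis_config(config: AnalysisConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)


def read_analysis_config(path) -> AnalysisConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    markers = [MarkerAnalysis(**m) if isinstance(m, dict) else MarkerAnalysis(m)
               for m in raw.pop("markers")]
    return AnalysisConfig(markers=markers, **raw)
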