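"""Quantitative immunohistochemistry (IHC) scoring.

Two scoring conventions coexist in quantitative IHC of tumor sections:

* **Pathologist scoring** — an ordinal quantity grade Q (0-4, from the
  percentage of positively stained tumor cells) and an intensity grade I
  (0-3, negative/weak/intermediate/strong), combined multiplicatively into
  a composite score IxQ on 0-12.
* **Machine scoring** — a digital image-analysis platform reports, for each
  specimen, the fraction of tumor nuclei falling in the 0, 1+, 2+ and 3+
  intensity bins; the weighted sum ``100*(f1 + 2*f2 + 3*f3)`` is the
  H-score on 0-300.

This module implements both conventions plus the Pearson concordance used
to compare them across a cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "MarkerMeasurement",
    "quantity_bin",
    "composite_score",
    "h_score",
    "concordance",
]

#: Lower edges of the quantity bins (percent positive cells -> Q grade).
#: Intervals are half-open, [0,1) -> 0, [1,10) -> 1, [10,40) -> 2,
#: [40,70) -> 3, [70,100] -> 4, preserving the integer anchors of the
#: conventional rule.
_Q_EDGES = np.array([1.0, 10.0, 40.0, 70.0])

#: Tolerance on the bin-fraction sum; inputs within it are renormalized.
FRACTION_TOL = 1e-6


@dataclass
class MarkerMeasurement:
    """One marker x compartment x patient measurement.

    Pathologist fields (Q, I, IxQ) and machine fields (bin fractions,
    H-score) may both be present; either side may be missing (None).
    """

    marker_name: str
    compartment: str  # "nuclear" or "cytoplasmic"
    pct_positive: float | None = None
    quantity_Q: int | None = None
    intensity_I: int | None = None
    composite_IxQ: int | None = None
    bin_fractions: tuple[float, float, float, float] | None = None
    h_score: float | None = None

    def __post_init__(self) -> None:
        if self.compartment not in ("nuclear", "cytoplasmic"):
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if self.quantity_Q is not None and self.intensity_I is not None:
            if self.composite_IxQ is None:
                self.composite_IxQ = composite_score(self.quantity_Q, self.intensity_I)
        if self.bin_fractions is not None and self.h_score is None:
            self.h_score = h_score(self.bin_fractions)


def quantity_bin(pct_positive: float) -> int:
    """Ordinal quantity grade Q (0-4) from the percent of positive cells.

    0% of cells stained -> 0; 1-9% -> 1; 10-39% -> 2; 40-69% -> 3;
    70-100% -> 4. Fractional percentages fall into the half-open interval
    containing them.

    Parameters
    ----------
    pct_positive : float
        Percentage of tumor cells with positive staining, in [0, 100].

    Returns
    -------
    int
        The quantity grade, 0-4.
    """
    pct = float(pct_positive)
    if not np.isfinite(pct) or pct < 0.0 or pct > 100.0:
        raise ValueError(f"pct_positive must be in [0, 100], got {pct_positive!r}")
    return int(np.searchsorted(_Q_EDGES, pct, side="right"))


def composite_score(quantity_Q: int, intensity_I: int) -> int:
    """Pathologist composite score IxQ = Q * I, on 0-12."""
    q = int(quantity_Q)
    i = int(intensity_I)
    if q != quantity_Q or not 0 <= q <= 4:
        raise ValueError(f"quantity grade must be an integer in 0-4, got {quantity_Q!r}")
    if i != intensity_I or not 0 <= i <= 3:
        raise ValueError(f"intensity grade must be an integer in 0-3, got {intensity_I!r}")
    return q * i


def h_score(bin_fractions) -> float:
    """H-score on 0-300 from (0, 1+, 2+, 3+) intensity-bin fractions.

    ``H = 100 * (1*f1 + 2*f2 + 3*f3)``: 0 when every nucleus is negative,
    300 when every nucleus stains 3+.

    Parameters
    ----------
    bin_fractions : sequence of 4 floats
        Fractions of tumor nuclei in the 0, 1+, 2+ and 3+ bins. Must be
        non-negative and sum to 1 within ``FRACTION_TOL`` (renormalized).
    """
    f = np.asarray(bin_fractions, dtype=float)
    if f.shape != (4,):
        raise ValueError(f"expected 4 bin fractions, got shape {f.shape}")
    if np.any(f < 0) or not np.all(np.isfinite(f)):
        raise ValueError("bin fractions must be finite and non-negative")
    total = f.sum()
    if abs(total - 1.0) > FRACTION_TOL:
        raise ValueError(f"bin fractions sum to {total:.6g}, not 1")
    f = f / total
    return float(100.0 * (f[1] + 2.0 * f[2] + 3.0 * f[3]))


def concordance(scores_a, scores_b) -> dict[str, float]:
    """Pearson concordance between two scoring strategies on one cohort.

    Returns both the correlation ``r`` and ``r_squared`` — reports in this
    area quote either interchangeably, so both are exposed.

    Raises
    ------
    ValueError
        If the vectors differ in length, have fewer than 3 entries, or
        either has zero variance.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("score vectors must be 1-D and of equal length")
    if a.size < 3:
        raise ValueError("need at least 3 paired scores")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in one of the score vectors")
    r = float(stats.pearsonr(a, b).statistic)
    return {"r": r, "r_squared": r * r}
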