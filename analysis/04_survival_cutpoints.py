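"""Per-marker overall-survival analysis via minimum-p cutpoints.

For each marker: the dichotomizing threshold minimizing the log-rank
p-value under the 10% minimum-group-size rule, the resulting group sizes
and p, and the univariate Cox hazard ratio per standard deviation of
score. KM step coordinates for the marker with the smallest p are exported
for plotting. The min-p search is multiplicity-inflating by construction;
the permutation-adjusted p for the top marker is reported alongside.
"""

from pathlib import Path

from ihcmark.pipeline import (
    AnalysisConfig,
    MarkerAnalysis,
    km_group_coordinates,
    run_survival_table,
)
from ihcmark.survival import minp_permutation_adjust
from ihcmark.synthetic import read_cohort

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 20240704

MARKERS = ["XPF", "ERCC1", "pMK2", "pMK2_cyt", "MLH1", "PARP1", "PAR",
           "FANCD2", "gH2AX"]


def main() -> None:
    cohort = read_cohort(OUT / "cohort.csv")
    cfg = AnalysisConfig(markers=[MarkerAnalysis(m) for m in MARKERS])
    table = run_survival_table(cohort, cfg).sort_values("logrank_p")
    table.to_csv(OUT / "survival_table.csv", index=False)
    cols = ["marker", "threshold", "n_low", "n_high", "logrank_p", "cox_hr",
            "cox_p"]
    print(table[cols].to_string(index=False, float_format=lambda v: f"{v:.4g}"))

    best = table.iloc[0]
    marker = str(best["marker"])
    coords = km_group_coordinates(cohort, MarkerAnalysis(marker),
                                  float(best["threshold"]))
    coords.to_csv(OUT / f"km_{marker}.csv", index=False)

    adj = minp_permutation_adjust(
        cohort[f"{marker}_hscore"].to_numpy(),
        cohort["time_months"].to_numpy(),
        cohort["event"].to_numpy(), n_perm=999, seed=SEED)
    print(f"\nsmallest survival p: {marker} at threshold "
          f"{best['threshold']:.1f} (raw log-rank p {best['logrank_p']:.4g}, "
          f"permutation-adjusted p {adj:.4g})")
    print("the adjusted p accounts for the threshold search; the raw "
          "minimum p does not")


if __name__ == "__main__":
    main()
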