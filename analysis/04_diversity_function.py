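"""Diversity-multifunctionality associations.

OLS regressions of EMF on multidiversity and the above-/below-ground
aggregates, single-group correlations, leave-one-group-out sensitivity of
the multidiversity-EMF relationship, and the per-threshold regressions of
the multithreshold function counts on multidiversity.
"""

from pathlib import Path

import pandas as pd

from grazemulti.association import (correlation_screen, leave_one_group_out,
                                    ols_fit)
from grazemulti.multithreshold import threshold_regressions
from grazemulti.standardization import minmax_standardize
from grazemulti.tables_io import RichnessTable, read_results, write_results

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    idx = read_results(ROOT / "analysis" / "indices.csv").set_index("plot_id")
    rich = RichnessTable(read_results(ROOT / "data" / "richness.csv"))
    std_r = minmax_standardize(rich)
    out = ROOT / "analysis"

    screen = correlation_screen(
        idx[["multidiversity", "above_diversity", "below_diversity"]],
        idx[["EMF_avg", "EMF_weighted"]])
    write_results(screen, out / "associations.csv")
    headline = screen[(screen.predictor == "multidiversity")
                      & (screen.response == "EMF_avg")].iloc[0]
    print(f"multidiversity ~ EMF: R = {headline['R']:.3f}, "
          f"p = {headline['p']:.4f}, n = {int(headline['n'])}")

    # single-group richness correlations with EMF
    single = correlation_screen(std_r.data.set_index("plot_id"),
                                idx[["EMF_avg"]])
    write_results(single, out / "single_group_correlations.csv")

    loo_rows = [leave_one_group_out(std_r, std_r.variables,
                                    idx["EMF_avg"], g).as_dict()
                for g in std_r.variables]
    write_results(pd.DataFrame(loo_rows), out / "leave_one_group_out.csv")
    worst = min(loo_rows, key=lambda r: abs(r["R"]))
    print(f"leave-one-out R range: {min(r['R'] for r in loo_rows):.3f} to "
          f"{max(r['R'] for r in loo_rows):.3f} "
          f"(weakest without {worst['excluded_group']})")

    profile = read_results(ROOT / "analysis" / "multithreshold_counts.csv")
    fits = threshold_regressions(profile, idx["multidiversity"])
    write_results(fits, out / "multithreshold_regressions.csv")
    for row in fits.itertuples():
        print(f"  threshold {row.threshold:.2f}: slope = {row.slope:5.2f}, "
              f"R = {row.R:.3f}, p = {row.p:.4f}")


if __name__ == "__main__":
    main()
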