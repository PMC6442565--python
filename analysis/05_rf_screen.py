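"""Random-forest screen of multifunctionality predictors.

Ranks livestock diversification, multidiversity and the soil covariates
(pH, electrical conductivity, bulk density) as predictors of EMF by
permutation importance, with response-permutation significance.
"""

from pathlib import Path

from grazemulti.path_model import dummy_code
from grazemulti.rf_importance import rf_screen
from grazemulti.tables_io import DesignTable, read_results, write_results

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 20260927


def main() -> None:
    design = DesignTable(read_results(ROOT / "data" / "design.csv"))
    idx = read_results(ROOT / "analysis" / "indices.csv").set_index("plot_id")
    cov = read_results(ROOT / "data" / "covariates.csv").set_index("plot_id")

    X = idx[["multidiversity"]].join(cov)
    X["livestock"] = dummy_code(design, "MG").reindex(X.index)
    res = rf_screen(X, idx["EMF_avg"], n_trees=500, n_permutations=199,
                    seed=SEED)
    write_results(res.table, ROOT / "analysis" / "rf_importance.csv", seed=SEED)
    print(res.table.sort_values("importance", ascending=False)
          .to_string(index=False))
    print(f"top predictor of EMF: {res.top_predictor()}")


if __name__ == "__main__":
    main()
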