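"""End-to-end pipeline: simulate/load -> standardize -> indices ->
multithreshold -> ANOVA -> associations -> RF screen -> path model.

Every stage writes a plain CSV under the output directory and registers
itself in a YAML manifest carrying the config hash, the per-stage seeds and
a SHA-256 digest of every output file, so a rerun with the same config can
be verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import pandas as pd
import yaml

from grazemulti import __version__
from grazemulti.association import correlation_screen, leave_one_group_out
from grazemulti.group_comparison import block_anova, tukey_hsd
from grazemulti.indices import average_index, derive_weights, weighted_index
from grazemulti.multithreshold import (DEFAULT_THRESHOLDS,
                                       functions_beyond_threshold,
                                       threshold_regressions)
from grazemulti.path_model import (PathModelSpec, default_model, dummy_code,
                                   fit_path_model, total_effects_table)
from grazemulti.rf_importance import rf_screen
from grazemulti.standardization import minmax_standardize
from grazemulti.synthetic import (RICHNESS_GROUPS, SyntheticScenario, generate)
from grazemulti.tables_io import (DEFAULT_PARTITION, config_hash, read_tables,
                                  write_results)

logger = logging.getLogger("grazemulti")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Run every stage from one config; returns the manifest dict.

    Config keys (all optional, with defaults): ``seed``, ``scenario`` (kwargs
    for :class:`SyntheticScenario`) or ``inputs`` (design/functions/richness
    paths), ``above_groups``/``below_groups``, ``thresholds``, ``alpha``,
    ``rf`` (trees/permutations), ``path_bootstrap``, ``dummy_level``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    alpha = float(config.get("alpha", 0.1))
    thresholds = config.get("thresholds", list(DEFAULT_THRESHOLDS))
    outputs: list[str] = []

    def emit(obj, name: str, stage_seed: int | None = None):
        path = out / name
        write_results(obj, path, seed=stage_seed, meta=config)
        outputs.append(name)
        return path

    try:
        # -- stage 1: data --------------------------------------------------
        if "inputs" in config:
            paths = config["inputs"]
            design, raw, rich = read_tables(paths["design"], paths["functions"],
                                            paths["richness"])
            covariates = (pd.read_csv(paths["covariates"], comment="#",
                                      dtype={"plot_id": str})
                          if "covariates" in paths else None)
        else:
            scenario = SyntheticScenario(**{**config.get("scenario", {}),
                                            "seed": seed})
            design, raw, rich, covariates = generate(scenario)
        emit(design, "design.csv", seed)
        emit(raw, "functions_raw.csv", seed)
        emit(rich, "richness.csv", seed)
        if covariates is not None:
            emit(covariates, "covariates.csv", seed)

        above = config.get("above_groups", DEFAULT_PARTITION.above_groups)
        below = config.get("below_groups", DEFAULT_PARTITION.below_groups)
        groups = [g for g in rich.groups if g in set(above) | set(below)] \
            or list(rich.groups)

        # -- stage 2: standardization ---------------------------------------
        std_fun = minmax_standardize(raw)
        std_rich = minmax_standardize(rich)
        emit(std_fun.data, "functions_standardized.csv")
        prov = pd.DataFrame([{"variable": v, "min": lo, "max": hi}
                             for v, (lo, hi) in std_fun.provenance.items()])
        emit(prov, "standardization_provenance.csv")

        # -- stage 3: indices ------------------------------------------------
        emf = average_index(std_fun, std_fun.variables, "EMF_avg")
        scheme = derive_weights(std_fun, std_fun.variables)
        emf_w = weighted_index(std_fun, scheme, "EMF_weighted")
        multidiv = average_index(std_rich, groups, "multidiversity")
        above_div = average_index(std_rich, [g for g in groups if g in above],
                                  "above_diversity")
        below_div = average_index(std_rich, [g for g in groups if g in below],
                                  "below_diversity")
        idx_frame = emf.to_frame()
        for res in (emf_w, multidiv, above_div, below_div):
            idx_frame = idx_frame.merge(res.to_frame(), on="plot_id")
        emit(idx_frame, "indices.csv")
        emit(pd.DataFrame([{"variable": v, "weight": w}
                           for v, w in sorted(scheme.weights.items())]),
             "emf_weights.csv")

        # -- stage 4: multithreshold ------------------------------------------
        profile = functions_beyond_threshold(raw, thresholds)
        emit(profile, "multithreshold_counts.csv")

        # -- stage 5: blocked ANOVA + Tukey -----------------------------------
        anova_rows, letter_rows = [], []
        for col in ["EMF_avg", "EMF_weighted", "multidiversity",
                    "above_diversity", "below_diversity"]:
            y = idx_frame.set_index("plot_id")[col]
            res = block_anova(y, design, response=col)
            anova_rows.append(res.summary())
            _, letters = tukey_hsd(y, design, alpha=alpha, response=col)
            for trt, letter in letters.items():
                letter_rows.append({"response": col, "treatment": trt,
                                    "mean": res.treatment_means[trt],
                                    "letters": letter})
        emit(pd.DataFrame(anova_rows), "anova.csv")
        emit(pd.DataFrame(letter_rows), "tukey_letters.csv")

        # -- stage 6: associations --------------------------------------------
        pred = idx_frame.set_index("plot_id")[
            ["multidiversity", "above_diversity", "below_diversity"]]
        resp = idx_frame.set_index("plot_id")[["EMF_avg", "EMF_weighted"]]
        assoc = correlation_screen(pred, resp)
        loo_rows = []
        emf_series = idx_frame.set_index("plot_id")["EMF_avg"]
        if len(groups) > 2:
            for g in groups:
                fit = leave_one_group_out(std_rich, groups, emf_series, g)
                loo_rows.append(fit.as_dict())
        emit(assoc, "associations.csv")
        if loo_rows:
            emit(pd.DataFrame(loo_rows), "leave_one_group_out.csv")

        # -- stage 7: random-forest screen ------------------------------------
        rf_cfg = config.get("rf", {})
        rf_seed = int(rf_cfg.get("seed", seed + 1))
        X = pred.copy()
        X["livestock"] = dummy_code(design, config.get("dummy_level", "MG")
                                    ).reindex(X.index)
        if covariates is not None:
            X = X.join(covariates.set_index("plot_id"))
        X = X.drop(columns=["above_diversity", "below_diversity"])
        rf_res = rf_screen(X, emf_series.reindex(X.index),
                           n_trees=int(rf_cfg.get("trees", 200)),
                           n_permutations=int(rf_cfg.get("permutations", 99)),
                           seed=rf_seed)
        emit(rf_res.table, "rf_importance.csv", rf_seed)

        # -- stage 8: path model ----------------------------------------------
        path_seed = int(config.get("path_seed", seed + 2))
        model = (PathModelSpec.from_dict(config["path_model"])
                 if "path_model" in config else default_model())
        data = idx_frame.set_index("plot_id")[
            ["above_diversity", "below_diversity", "EMF_avg"]].rename(
                columns={"EMF_avg": "EMF"})
        data["livestock"] = dummy_code(design, config.get("dummy_level", "MG")
                                       ).reindex(data.index)
        fit = fit_path_model(data, model,
                             bootstrap=int(config.get("path_bootstrap", 500)),
                             seed=path_seed)
        emit(fit.summary(), "path_fit.csv", path_seed)
        ste = total_effects_table(fit, "EMF")
        emit(pd.DataFrame({"predictor": ste.index, "STE": ste.to_numpy()}),
             "path_total_effects.csv")
    except Exception:
        (out / "FAILED").write_text("pipeline failed; partial outputs retained\n")
        raise

    manifest = {
        "version": __version__,
        "config_hash": config_hash(config),
        "seeds": {"data": seed, "rf": rf_seed, "path": path_seed},
        "stages": sorted(outputs),
        "sha256": {name: _sha256(out / name) for name in sorted(outputs)},
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    logger.info("pipeline complete: %d outputs in %s", len(outputs), out)
    return manifest
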