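"""Synthetic grazing experiments with a known causal structure.

The generator emulates the reference design — a randomized complete block
layout of 6 blocks x 4 grazing treatments (no grazing NG, sheep SG, cattle
CG, mixed MG) — with 6 organism-group richness counts, 12 partially
correlated ecosystem functions and 3 soil covariates, wired through an
explicit causal chain:

    livestock diversification (x, standardized MG indicator)
        --a-->  latent diversity signals (above-ground M_A, below-ground M_B)
        --b-->  latent function signal F  (plus the direct path  x --c'--> F)

The above- and below-ground diversity latents are distinct but correlated
(``above_below_latent_correlation``), and the livestock effect on the
below-ground latent is attenuated (``below_livestock_effect_scale``),
mirroring grazing systems where soil communities respond more weakly to
livestock diversification than plants and insects. Group richness counts
are affine images of their latent (plus per-treatment shifts, block effects
and noise, rounded to nonnegative integers); each ecosystem function is an
affine image of F — driven by the pooled diversity signal — plus a
cluster-shared latent factor (four clusters of three functions, inducing
the correlation structure that the weighted-EMF down-weighting needs) plus
independent noise. Soil covariates are independent of treatment by default.
Everything is determined by the scenario seed.

Because block effects enter only the observed tables (never the latent
chain), the standardized path coefficients among (x, M, F) are exactly
(a, b, c'), and block-residualization removes the block nuisance without
touching the causal structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from grazemulti.tables_io import (DesignTable, RawFunctionTable, RichnessTable,
                                  TREATMENTS)

#: Richness groups: above-ground (plants, insects) then below-ground.
RICHNESS_GROUPS = ("plants", "herbivores", "predators",
                   "bacteria", "fungi", "nematodes")

#: The 12 ecosystem functions of the reference experiment.
FUNCTIONS = ("herbivore_abundance", "predator_abundance",
             "aboveground_biomass", "belowground_biomass",
             "leaf_N", "leaf_P",
             "soil_N_availability", "soil_total_N", "soil_total_P",
             "soil_organic_C", "soil_moisture", "ecm_abundance")

#: Default cluster structure: four clusters of three correlated functions.
DEFAULT_CLUSTER_MAP = {
    "herbivore_abundance": 1, "predator_abundance": 1, "aboveground_biomass": 1,
    "belowground_biomass": 2, "leaf_N": 2, "leaf_P": 2,
    "soil_N_availability": 3, "soil_total_N": 3, "soil_total_P": 3,
    "soil_organic_C": 4, "soil_moisture": 4, "ecm_abundance": 4,
}

# (base, scale) per richness group: counts ~ base + scale * latent
_RICHNESS_SCALES = {"plants": (22.0, 4.0), "herbivores": (15.0, 3.0),
                    "predators": (9.0, 2.0), "bacteria": (1200.0, 150.0),
                    "fungi": (320.0, 45.0), "nematodes": (26.0, 5.0)}

# (base, scale) per function column (arbitrary positive measurement scales)
_FUNCTION_SCALES = {f: (10.0 * (i + 2), 1.5 * (i + 2))
                    for i, f in enumerate(FUNCTIONS)}


@dataclass
class SyntheticScenario:
    """Full parameterization of one simulated experiment.

    ``path_coefficients`` are the standardized (a, b, c') of the causal
    chain; ``treatment_effects_on_diversity`` are additive shifts of the
    per-group richness latent, in latent-SD units, applied on top of the
    chain. Defaults give the 6x4 design moderate (roughly 50-80%) power for
    the treatment F-test at alpha = 0.1, so both significant and null
    outcomes are exercisable.
    """

    n_blocks: int = 6
    treatments: tuple[str, ...] = TREATMENTS
    treatment_effects_on_diversity: dict[str, np.ndarray] = field(
        default_factory=lambda: {
            "NG": np.zeros(6),
            "SG": np.array([0.25, 0.25, 0.25, 0.1, 0.1, 0.1]),
            "CG": np.array([0.25, 0.25, 0.25, 0.1, 0.1, 0.1]),
            "MG": np.array([0.6, 0.6, 0.6, 0.2, 0.2, 0.2]),
        })
    path_coefficients: tuple[float, float, float] = (0.5, 0.45, 0.15)
    #: correlation between the above- and below-ground latent disturbances;
    #: 1.0 collapses them to a single shared multidiversity latent.
    above_below_latent_correlation: float = 0.3
    #: attenuation of the livestock effect on the below-ground latent,
    #: emulating the weaker below-ground response to grazing diversification.
    below_livestock_effect_scale: float = 0.4
    block_sd: float = 0.4
    noise_sd: float = 0.4
    function_cluster_sd: float = 0.4
    function_noise_sd: float = 0.3
    function_cluster_map: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLUSTER_MAP))
    seed: int = 0

    def __post_init__(self) -> None:
        a, b, c = self.path_coefficients
        for name, v in (("a", a), ("b", b), ("c'", c)):
            if not -1 < v < 1:
                raise ValueError(f"standardized path coefficient {name}={v} "
                                 "must lie in (-1, 1)")
        if not 0 <= self.above_below_latent_correlation <= 1:
            raise ValueError("above/below latent correlation must be in [0, 1]")
        if not 0 <= self.below_livestock_effect_scale <= 1:
            raise ValueError("below-ground effect scale must be in [0, 1]")
        resid = 1.0 - b * b - c * c - 2 * self._a_combined() * b * c
        if resid <= 0:
            raise ValueError("implied function-signal variance non-positive; "
                             "reduce |b|, |c'| or their product with a")
        if self.block_sd < 0 or self.noise_sd < 0:
            raise ValueError("scenario error: negative noise scale")

    def _a_combined(self) -> float:
        """Standardized livestock effect on the pooled diversity latent."""
        a, _, _ = self.path_coefficients
        s = self.below_livestock_effect_scale
        rho = self.above_below_latent_correlation
        cov_ab = (s * a * a
                  + np.sqrt(1 - a * a) * np.sqrt(1 - (s * a) ** 2) * rho)
        return a * (1 + s) / np.sqrt(2 + 2 * cov_ab)


def null_scenario(seed: int = 0) -> SyntheticScenario:
    """All treatment effects and path coefficients zero.

    Used to calibrate type-I error rates and permutation nulls: every
    significant result on a null scenario is a false positive.
    """
    return SyntheticScenario(
        treatment_effects_on_diversity={t: np.zeros(6) for t in TREATMENTS},
        path_coefficients=(0.0, 0.0, 0.0),
        seed=seed,
    )


def chain_scenario(a: float = 0.6, b: float = 0.5, c_prime: float = 0.2,
                   n_blocks: int = 6, seed: int = 0) -> SyntheticScenario:
    """A clean mediation chain for parameter-recovery studies.

    Per-treatment richness shifts are zero and nuisance noise is kept small
    so the observed multidiversity and EMF are tight proxies of the latent M
    and F, and the fitted standardized coefficients converge to (a, b, c')
    as the number of blocks grows.
    """
    return SyntheticScenario(
        n_blocks=n_blocks,
        treatment_effects_on_diversity={t: np.zeros(6) for t in TREATMENTS},
        path_coefficients=(a, b, c_prime),
        above_below_latent_correlation=1.0,
        below_livestock_effect_scale=1.0,
        block_sd=0.0,
        noise_sd=0.25,
        function_cluster_sd=0.35,
        function_noise_sd=0.3,
        seed=seed,
    )


def _round_half_even_clamp(x: np.ndarray) -> np.ndarray:
    return np.maximum(np.rint(x), 0.0).astype(int)


def generate(scenario: SyntheticScenario
             ) -> tuple[DesignTable, RawFunctionTable, RichnessTable, pd.DataFrame]:
    """Simulate one experiment: design, functions, richness and covariates."""
    rng = np.random.default_rng(scenario.seed)
    a, b, c = scenario.path_coefficients

    treatments = list(scenario.treatments)
    n = scenario.n_blocks * len(treatments)
    width = max(2, len(str(n)))
    rows = []
    k = 0
    for blk in range(1, scenario.n_blocks + 1):
        order = rng.permutation(treatments)  # randomize within block
        for trt in order:
            k += 1
            rows.append({"plot_id": f"p{k:0{width}d}",
                         "block": f"block{blk:03d}", "treatment": trt})
    design_df = pd.DataFrame(rows)
    design = DesignTable(design_df)

    trt = design_df["treatment"].to_numpy()
    is_mg = (trt == "MG").astype(float)
    x = (is_mg - is_mg.mean()) / is_mg.std(ddof=1) if is_mg.std() > 0 else is_mg

    # latent causal chain; coefficients are exact standardized effects.
    # block_sd == noise_sd == 0 is the fully deterministic limit: every
    # stochastic disturbance (including the latent ones) is switched off.
    latent = 0.0 if (scenario.block_sd == 0 and scenario.noise_sd == 0) else 1.0
    rho = scenario.above_below_latent_correlation
    s = scenario.below_livestock_effect_scale
    e_shared = rng.standard_normal(n)
    u_above = (np.sqrt(rho) * e_shared
               + np.sqrt(1 - rho) * rng.standard_normal(n))
    u_below = (np.sqrt(rho) * e_shared
               + np.sqrt(1 - rho) * rng.standard_normal(n))
    M_above = a * x + latent * np.sqrt(1 - a * a) * u_above
    M_below = (s * a * x
               + latent * np.sqrt(1 - (s * a) ** 2) * u_below)
    cov_ab = s * a * a + np.sqrt(1 - a * a) * np.sqrt(1 - (s * a) ** 2) * rho
    M = (M_above + M_below) / np.sqrt(2 + 2 * cov_ab) if latent else M_above
    a_eff = scenario._a_combined() if latent else a
    resid_f = np.sqrt(max(1 - b * b - c * c - 2 * a_eff * b * c, 0.0))
    F = b * M + c * x + latent * resid_f * rng.standard_normal(n)

    block_idx = design_df["block"].astype("category").cat.codes.to_numpy()

    # block effects are drawn per organism group / per function: different
    # taxa and processes respond to different site characteristics
    rich = {"plot_id": design_df["plot_id"]}
    for gi, g in enumerate(RICHNESS_GROUPS):
        shift = np.array([scenario.treatment_effects_on_diversity[t][gi]
                          for t in trt])
        block_eff = scenario.block_sd * rng.standard_normal(scenario.n_blocks)
        group_latent = M_above if gi < 3 else M_below
        signal = (group_latent + shift + block_eff[block_idx]
                  + scenario.noise_sd * rng.standard_normal(n))
        base, scale = _RICHNESS_SCALES[g]
        rich[g] = _round_half_even_clamp(base + scale * signal)
    richness = RichnessTable(pd.DataFrame(rich))

    clusters = sorted(set(scenario.function_cluster_map.values()))
    cluster_factor = {cl: latent * rng.standard_normal(n) for cl in clusters}
    funcs = {"plot_id": design_df["plot_id"]}
    for f in FUNCTIONS:
        cl = scenario.function_cluster_map.get(f)
        fblock_eff = scenario.block_sd * rng.standard_normal(scenario.n_blocks)
        shared = (scenario.function_cluster_sd * cluster_factor[cl]
                  if cl is not None else 0.0)
        signal = (F + shared + fblock_eff[block_idx]
                  + scenario.function_noise_sd * rng.standard_normal(n))
        base, scale = _FUNCTION_SCALES[f]
        funcs[f] = np.maximum(base + scale * signal, 0.0)
    raw = RawFunctionTable(pd.DataFrame(funcs))

    covariates = pd.DataFrame({
        "plot_id": design_df["plot_id"],
        "soil_pH": 7.8 + 0.3 * rng.standard_normal(n),
        "electrical_conductivity": np.maximum(
            0.40 + 0.10 * rng.standard_normal(n), 0.01),
        "bulk_density": np.maximum(1.25 + 0.08 * rng.standard_normal(n), 0.5),
    })
    return design, raw, richness, covariates


def with_seed(scenario: SyntheticScenario, seed: int) -> SyntheticScenario:
    """Copy of a scenario with a different seed."""
    return replace(scenario, seed=seed)
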