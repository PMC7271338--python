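"""Bundled reference tables for the neo-tetraploid rice knockout trial.

``KNOCKOUT_TRIAL`` holds the published phenotype means ± sd for the
wild-type neo-tetraploid line Huaduo1 and nine CRISPR/Cas9 knockout
mutants of candidate non-parental fertility genes, for three traits:
pollen fertility (%), seed setting (%) and yield per plant (g). These
printed group summaries are the input for the contrast arithmetic — the
underlying replicate data are not public.

``SANGER_VALIDATION`` holds the Sanger-resequencing validation counts
(variants compared and in accordance) used for the concordance-rate
computation.
"""

from __future__ import annotations

from tetramosaic.traits import TraitTable
from tetramosaic.sim import simulate_traits

__all__ = [
    "WILD_TYPE",
    "KNOCKOUT_MUTANTS",
    "TRAITS",
    "KNOCKOUT_TRIAL",
    "SANGER_VALIDATION",
    "knockout_trial_table",
]

WILD_TYPE = "Huaduo1"

#: mutant line order as published
KNOCKOUT_MUTANTS = (
    "BZR3", "NRFG2", "NRFG3", "NRFG4", "CLPC3",
    "KIN7L", "KIN14M", "NRFG5", "NRFG6",
)

TRAITS = ("pollen_fertility_pct", "seed_setting_pct", "yield_per_plant_g")

#: line -> {trait: (mean, sd)}
KNOCKOUT_TRIAL: dict[str, dict[str, tuple[float, float]]] = {
    "Huaduo1": {"pollen_fertility_pct": (94.45, 1.67),
                "seed_setting_pct": (80.21, 1.28),
                "yield_per_plant_g": (14.19, 0.78)},
    "BZR3":    {"pollen_fertility_pct": (64.33, 7.33),
                "seed_setting_pct": (55.79, 4.11),
                "yield_per_plant_g": (8.29, 1.28)},
    "NRFG2":   {"pollen_fertility_pct": (72.04, 12.75),
                "seed_setting_pct": (60.87, 2.42),
                "yield_per_plant_g": (10.77, 1.22)},
    "NRFG3":   {"pollen_fertility_pct": (77.97, 5.95),
                "seed_setting_pct": (52.09, 4.43),
                "yield_per_plant_g": (6.66, 0.92)},
    "NRFG4":   {"pollen_fertility_pct": (84.93, 1.66),
                "seed_setting_pct": (51.88, 3.42),
                "yield_per_plant_g": (7.97, 1.09)},
    "CLPC3":   {"pollen_fertility_pct": (68.15, 11.31),
                "seed_setting_pct": (57.43, 4.19),
                "yield_per_plant_g": (11.74, 1.22)},
    "KIN7L":   {"pollen_fertility_pct": (37.49, 9.59),
                "seed_setting_pct": (35.56, 4.45),
                "yield_per_plant_g": (5.38, 0.86)},
    "KIN14M":  {"pollen_fertility_pct": (77.81, 3.27),
                "seed_setting_pct": (55.91, 3.88),
                "yield_per_plant_g": (9.48, 1.65)},
    "NRFG5":   {"pollen_fertility_pct": (54.05, 3.65),
                "seed_setting_pct": (67.13, 2.80),
                "yield_per_plant_g": (11.99, 1.40)},
    "NRFG6":   {"pollen_fertility_pct": (72.92, 6.32),
                "seed_setting_pct": (54.58, 3.89),
                "yield_per_plant_g": (11.59, 1.24)},
}

#: Sanger validation: (n_compared, n_in_accordance)
SANGER_VALIDATION = (255, 245)


def knockout_trial_table(
    n_replicates: int = 3, sd: float | None = None, seed: int = 0
) -> TraitTable:
    """Build a replicate-level trait table from the published group means.

    With ``sd=0`` (the default for exact arithmetic checks is to pass 0)
    every replicate equals the group mean, so contrasts reproduce the
    published mean differences exactly; with ``sd=None`` the published
    group sds are used to draw noisy replicates.
    """
    specs = []
    for line, traits in KNOCKOUT_TRIAL.items():
        means = {t: mv[0] for t, mv in traits.items()}
        sds = {t: (sd if sd is not None else mv[1]) for t, mv in traits.items()}
        specs.append((line, means, sds, n_replicates))
    return simulate_traits(specs, seed=seed)
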