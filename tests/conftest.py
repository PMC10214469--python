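"""Shared fixtures: handcrafted miniature trials and the default
study-shaped simulation."""

from __future__ import annotations

import itertools

import pandas as pd
import pytest

from metstress import make_dataset, simulate_met
from metstress.core_data import TRAITS


def trial_frame(rows: list[dict]) -> pd.DataFrame:
    """Build a records frame from partial row dicts, filling key defaults."""
    defaults = {"location": "L1", "year": "Y1", "environment": "OE",
                "replicate": 1, "block": 1}
    return pd.DataFrame([{**defaults, **r} for r in rows])


def single_factor_dataset(values_by_genotype: dict[str, list[float]],
                          trait: str = "SY"):
    """One location/year/environment; genotypes x replicates with the given
    trait values (replicate index = position in the list)."""
    rows = []
    for geno, vals in values_by_genotype.items():
        for rep, v in enumerate(vals, start=1):
            rows.append({"genotype": geno, "replicate": rep, trait: v})
    return make_dataset(trial_frame(rows), traits=(trait,))


def two_env_dataset(per_env: dict[str, dict[str, list[float]]],
                    trait: str = "SY"):
    """Genotype x environment x replicate layout for contrast tests.

    ``per_env`` maps environment -> genotype -> replicate values.
    """
    rows = []
    for env, by_geno in per_env.items():
        for geno, vals in by_geno.items():
            for rep, v in enumerate(vals, start=1):
                rows.append({"genotype": geno, "environment": env,
                             "replicate": rep, trait: v})
    return make_dataset(trial_frame(rows), traits=(trait,))


def crafted_trait_dataset(trait_values: dict[str, list[float]]):
    """One plot per genotype; each trait column set to the given vector
    (for correlation/regression hand examples)."""
    n = len(next(iter(trait_values.values())))
    rows = []
    for i in range(n):
        row = {"genotype": f"G{i + 1}"}
        for t, vals in trait_values.items():
            row[t] = vals[i]
        rows.append(row)
    traits = tuple(t for t in TRAITS if t in trait_values)
    return make_dataset(trial_frame(rows), traits=traits)


def full_factorial_dataset(genotypes, locations, years, environments,
                           replicates, value_fn, trait: str = "SY"):
    """Complete balanced factorial with values from ``value_fn(g, l, y, e,
    r)``."""
    rows = []
    for g, l, y, e, r in itertools.product(genotypes, locations, years,
                                           environments, replicates):
        rows.append({"genotype": g, "location": l, "year": y,
                     "environment": e, "replicate": r,
                     trait: value_fn(g, l, y, e, r)})
    return make_dataset(trial_frame(rows), traits=(trait,))


@pytest.fixture(scope="session")
def study_sim():
    """Default study-shaped simulation (34 x 2 x 2 x 3 x 2 = 816 plots)."""
    return simulate_met(seed=7)


@pytest.fixture(scope="session")
def study_dataset(study_sim):
    return study_sim[0]


@pytest.fixture(scope="session")
def study_truth(study_sim):
    return study_sim[1]
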