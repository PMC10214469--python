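"""Seeded generator of trial datasets shaped like the study design, with
known ground truth for recovery testing.

The default configuration emulates the study layout: 34 genotypes, two
locations (Banda, Jhansi), two seasons, three environments (OE optimum,
HSE heat stress, HDSE combined heat-drought), two replicates with two
incomplete blocks nested in each replicate (816 plots).  Stress acts
multiplicatively on yield-type traits (SY, BY, TKW, NGS and other
magnitude traits) and as an additive shift on phenology (DFF, and the
DFF-to-maturity gap that defines DM), so large relative yield losses
coexist with modest phenology shifts.  Plot values follow

    value = multiplier[genotype, env] * (mu_loc + year + g + gl + gy + ge
                                         + block + eps)

for multiplicative traits (additive shift replaces the multiplier for
phenology), with Gaussian effects and noise throughout and truncation at
zero for physical traits.  A configurable subset of "true tolerant"
genotypes receives a reduced stress penalty; the remaining genotypes'
penalty is scaled up so that the population-mean multiplier equals the
configured environment multiplier (hence the realised stress intensity
matches 1 - multiplier in expectation).

One seed governs all draws: a master seed sequence spawns one stream for
genotype-level effects shared across locations and one sub-stream per
location for field-level draws, so a location can be regenerated without
disturbing the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .anova import balanced_decompose
from .core_data import TRAITS, TrialDataset, make_dataset
from .exceptions import ConfigError

#: traits drawn from their own Gaussian model ("DM_GAP" is the
#: DFF-to-maturity interval; DM = DFF + gap and HI = 100*SY/BY are derived)
MODELLED_TRAITS: tuple[str, ...] = (
    "DFF", "DM_GAP", "PH", "NT", "SL", "NSS", "NGS", "TKW", "BY", "SY",
)


@dataclass
class TraitModel:
    """Generative model of one trait.

    ``means`` is the optimum-environment trait mean per location;
    ``multipliers`` (for multiplicative traits) or ``shifts`` (additive, for
    phenology) give the stress response per environment.  ``yield_like``
    traits receive the per-genotype tolerance adjustment.
    """

    means: dict[str, float]
    sigma_g: float
    sigma_gl: float
    sigma_gy: float
    sigma_ge: float
    sigma_e: float
    sigma_year: float
    sigma_block: float
    response: str = "multiplicative"  # or "shift"
    multipliers: dict[str, float] | None = None
    shifts: dict[str, float] | None = None
    yield_like: bool = False

    def sds(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in
                ("sigma_g", "sigma_gl", "sigma_gy", "sigma_ge",
                 "sigma_e", "sigma_year", "sigma_block")}


@dataclass
class SimulationConfig:
    """Design and variance parameters of a simulated trial."""

    n_genotypes: int = 34
    locations: tuple[str, ...] = ("Banda", "Jhansi")
    years: tuple[str, ...] = ("2020-21", "2021-22")
    #: population-mean seed-yield multiplier per environment
    environments: dict[str, float] = field(
        default_factory=lambda: {"OE": 1.0, "HSE": 0.80, "HDSE": 0.64}
    )
    replicates: int = 2
    blocks_per_replicate: int = 2
    trait_models: dict[str, TraitModel] = field(default_factory=dict)
    #: genotype-effect factor loadings coupling traits (row trait = sum of
    #: loading * standardised latent of source trait); defaults to identity
    genotype_loadings: dict[str, dict[str, float]] = field(
        default_factory=dict
    )
    n_true_tolerant: int = 5
    #: fraction of the stress penalty removed for true tolerant genotypes
    tolerance: float = 0.8

    def validate(self) -> None:
        if self.environments.get("OE") != 1.0:
            raise ConfigError("OE multiplier must be exactly 1")
        for env, m in self.environments.items():
            if not (0 < m <= 1):
                raise ConfigError(f"multiplier for {env} must be in (0, 1]")
        if not (0 <= self.tolerance <= 1):
            raise ConfigError("tolerance must be in [0, 1]")
        if not (0 <= self.n_true_tolerant <= self.n_genotypes):
            raise ConfigError("n_true_tolerant out of range")
        for trait, tm in self.trait_models.items():
            for name, sd in tm.sds().items():
                if sd < 0:
                    raise ConfigError(f"{trait}.{name} is negative")
            for loc in self.locations:
                if loc not in tm.means:
                    raise ConfigError(f"{trait} has no mean for {loc}")

    @property
    def env_names(self) -> tuple[str, ...]:
        return tuple(self.environments)

    @property
    def n_plots(self) -> int:
        return (self.n_genotypes * len(self.locations) * len(self.years)
                * len(self.environments) * self.replicates)


def default_study_config() -> SimulationConfig:
    """Defaults emulating the study conditions.

    Optimum-environment means come from the published per-location
    descriptive statistics; the stress multipliers reproduce the published
    mean percent reductions (seed yield approx. 20% under heat and 36% under
    combined heat-drought at the reference location); phenology shifts
    shorten flowering and maturity under late sowing.  Variance components
    are sized so that the tolerance signal of the planted tolerant genotypes
    is detectable at the trial's replication level (see the methods note).
    """
    mult = {
        # per-environment multiplier by trait, from the published mean
        # percent reductions (OE always 1)
        "PH": {"OE": 1.0, "HSE": 0.96, "HDSE": 0.90},
        "NT": {"OE": 1.0, "HSE": 0.76, "HDSE": 0.73},
        "SL": {"OE": 1.0, "HSE": 0.93, "HDSE": 0.82},
        "NSS": {"OE": 1.0, "HSE": 0.96, "HDSE": 0.92},
        "NGS": {"OE": 1.0, "HSE": 0.93, "HDSE": 0.79},
        "TKW": {"OE": 1.0, "HSE": 0.92, "HDSE": 0.87},
        "BY": {"OE": 1.0, "HSE": 0.84, "HDSE": 0.63},
    }
    tm = {
        "DFF": TraitModel(
            means={"Banda": 88, "Jhansi": 85}, response="shift",
            shifts={"OE": 0.0, "HSE": -9.0, "HDSE": -14.0},
            sigma_g=3, sigma_gl=1, sigma_gy=1, sigma_ge=1.2,
            sigma_e=2, sigma_year=2, sigma_block=0.5,
        ),
        # interval from 50% flowering to maturity; shortened under stress
        "DM_GAP": TraitModel(
            means={"Banda": 49, "Jhansi": 49}, response="shift",
            shifts={"OE": 0.0, "HSE": -16.0, "HDSE": -17.0},
            sigma_g=1.5, sigma_gl=0.5, sigma_gy=0.5, sigma_ge=0.8,
            sigma_e=1.5, sigma_year=1, sigma_block=0.3,
        ),
        "PH": TraitModel(
            means={"Banda": 112, "Jhansi": 103}, multipliers=mult["PH"],
            sigma_g=16, sigma_gl=2, sigma_gy=2, sigma_ge=2,
            sigma_e=4, sigma_year=3, sigma_block=1,
        ),
        "NT": TraitModel(
            means={"Banda": 11, "Jhansi": 8}, multipliers=mult["NT"],
            sigma_g=1.2, sigma_gl=0.4, sigma_gy=0.4, sigma_ge=0.5,
            sigma_e=1.8, sigma_year=0.8, sigma_block=0.3,
        ),
        "SL": TraitModel(
            means={"Banda": 9, "Jhansi": 8}, multipliers=mult["SL"],
            sigma_g=1.0, sigma_gl=0.2, sigma_gy=0.2, sigma_ge=0.3,
            sigma_e=0.7, sigma_year=0.3, sigma_block=0.1,
        ),
        "NSS": TraitModel(
            means={"Banda": 19, "Jhansi": 18}, multipliers=mult["NSS"],
            sigma_g=0.6, sigma_gl=0.3, sigma_gy=0.3, sigma_ge=0.4,
            sigma_e=1.2, sigma_year=0.5, sigma_block=0.2,
        ),
        "NGS": TraitModel(
            means={"Banda": 45, "Jhansi": 46}, multipliers=mult["NGS"],
            sigma_g=7, sigma_gl=1.5, sigma_gy=1.5, sigma_ge=2.5,
            sigma_e=6, sigma_year=2, sigma_block=1, yield_like=True,
        ),
        "TKW": TraitModel(
            means={"Banda": 4.2, "Jhansi": 3.2}, multipliers=mult["TKW"],
            sigma_g=0.5, sigma_gl=0.1, sigma_gy=0.1, sigma_ge=0.15,
            sigma_e=0.3, sigma_year=0.15, sigma_block=0.05, yield_like=True,
        ),
        "BY": TraitModel(
            means={"Banda": 2277, "Jhansi": 2193}, multipliers=mult["BY"],
            sigma_g=250, sigma_gl=60, sigma_gy=60, sigma_ge=80,
            sigma_e=220, sigma_year=80, sigma_block=40, yield_like=True,
        ),
        "SY": TraitModel(
            means={"Banda": 790, "Jhansi": 598}, multipliers=None,
            sigma_g=30, sigma_gl=15, sigma_gy=15, sigma_ge=25,
            sigma_e=60, sigma_year=25, sigma_block=15, yield_like=True,
        ),
    }
    loadings = {
        # seed yield is driven mainly by grains per spike, secondarily by
        # kernel weight; biomass shares part of the yield latent
        "SY": {"NGS": 0.75, "TKW": 0.25, "SY": float(np.sqrt(0.375))},
        "BY": {"NGS": 0.25, "SY": 0.35, "BY": float(np.sqrt(0.815))},
    }
    cfg = SimulationConfig(trait_models=tm, genotype_loadings=loadings)
    cfg.validate()
    return cfg


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated trial."""

    config: SimulationConfig
    genotype_names: tuple[str, ...]
    tolerant: tuple[str, ...]
    genotype_effects: dict[str, np.ndarray]          # trait -> (g,)
    gl_effects: dict[str, np.ndarray]                # trait -> (g, l)
    gy_effects: dict[str, np.ndarray]                # trait -> (g, y)
    ge_effects: dict[str, np.ndarray]                # trait -> (g, e)
    year_effects: dict[str, np.ndarray]              # trait -> (y,)
    multipliers: dict[str, np.ndarray]               # trait -> (g, e)
    shifts: dict[str, np.ndarray]                    # trait -> (e,)

    def expected_surface(self, trait: str) -> pd.DataFrame:
        """Noise-free expected plot values on the full (genotype, location,
        year, environment) grid."""
        cfg = self.config
        if trait not in MODELLED_TRAITS:
            raise ConfigError(
                f"no generative model for derived trait {trait!r}"
            )
        tm = cfg.trait_models[trait]
        rows = []
        for j, loc in enumerate(cfg.locations):
            for k, year in enumerate(cfg.years):
                for m, env in enumerate(cfg.env_names):
                    base = (tm.means[loc]
                            + self.year_effects[trait][k]
                            + self.genotype_effects[trait]
                            + self.gl_effects[trait][:, j]
                            + self.gy_effects[trait][:, k]
                            + self.ge_effects[trait][:, m])
                    if tm.response == "multiplicative":
                        vals = self.multipliers[trait][:, m] * base
                    else:
                        vals = base + self.shifts[trait][m]
                    for i, g in enumerate(self.genotype_names):
                        rows.append((g, loc, year, env, vals[i]))
        return pd.DataFrame(
            rows,
            columns=["genotype", "location", "year", "environment", "value"],
        )

    def effective_components(self, trait: str) -> dict[str, float]:
        """Realised variance components the pooled ANOVA estimator targets.

        Multiplicative stress makes the nominal sigma^2 parameters not the
        estimand, so the truth is computed from the noise-free expected
        surface: its balanced decomposition gives surface mean squares
        MS~_T = SS_T/df_T and, with l, y, e the factor sizes,

            sigma2_ge = MS~_GE / (l*y)      (and analogously GL, GY)
            sigma2_g  = (MS~_G - MS~_GL - MS~_GY - MS~_GE) / (l*y*e)
        """
        cfg = self.config
        surf = self.expected_surface(trait)
        terms = [("genotype",), ("location",), ("year",), ("environment",),
                 ("genotype", "location"), ("genotype", "year"),
                 ("genotype", "environment")]
        ss = balanced_decompose(surf, "value", terms)
        g = cfg.n_genotypes
        l, y, e = len(cfg.locations), len(cfg.years), len(cfg.env_names)
        ms_g = ss["genotype"] / (g - 1)
        ms_gl = ss["genotype:location"] / ((g - 1) * (l - 1)) if l > 1 else 0.0
        ms_gy = ss["genotype:year"] / ((g - 1) * (y - 1)) if y > 1 else 0.0
        ms_ge = ss["genotype:environment"] / ((g - 1) * (e - 1))
        return {
            "sigma2_g": (ms_g - ms_gl - ms_gy - ms_ge) / (l * y * e),
            "sigma2_gl": ms_gl / (y * e),
            "sigma2_gy": ms_gy / (l * e),
            "sigma2_ge": ms_ge / (l * y),
        }

    def as_json_dict(self) -> dict:
        """JSON-serialisable view (config + effects as lists)."""
        def arr(d):
            return {k: np.asarray(v).tolist() for k, v in d.items()}
        cfg = asdict(self.config)
        return {
            "config": cfg,
            "genotype_names": list(self.genotype_names),
            "tolerant": list(self.tolerant),
            "genotype_effects": arr(self.genotype_effects),
            "gl_effects": arr(self.gl_effects),
            "gy_effects": arr(self.gy_effects),
            "ge_effects": arr(self.ge_effects),
            "year_effects": arr(self.year_effects),
            "multipliers": arr(self.multipliers),
            "shifts": arr(self.shifts),
        }


def _genotype_multipliers(cfg: SimulationConfig, env_mult: dict[str, float],
                          tolerant_idx: np.ndarray) -> np.ndarray:
    """Per-genotype multipliers with mean penalty preserved.

    Tolerant genotypes keep only ``1 - tolerance`` of each stress penalty;
    the others are scaled up so the population mean equals the configured
    multiplier.
    """
    n, n_tol = cfg.n_genotypes, len(tolerant_idx)
    out = np.ones((n, len(env_mult)))
    for m, (env, mult) in enumerate(env_mult.items()):
        penalty = 1.0 - mult
        if penalty == 0 or n_tol == 0:
            out[:, m] = mult
            continue
        if n_tol == n:
            out[:, m] = 1.0 - penalty * (1 - cfg.tolerance)
            continue
        scale_up = (n - n_tol * (1 - cfg.tolerance)) / (n - n_tol)
        out[:, m] = 1.0 - penalty * scale_up
        out[tolerant_idx, m] = 1.0 - penalty * (1 - cfg.tolerance)
    return out


def simulate_met(config: SimulationConfig | None = None,
                 seed: int = 0) -> tuple[TrialDataset, SyntheticTruth]:
    """Simulate one multi-environment trial; identical (config, seed) pairs
    yield bit-identical datasets."""
    cfg = config or default_study_config()
    cfg.validate()
    master = np.random.SeedSequence(seed)
    eff_ss, *loc_ss = master.spawn(1 + len(cfg.locations))
    rng = np.random.default_rng(eff_ss)

    g = cfg.n_genotypes
    names = tuple(f"G{i + 1:02d}" for i in range(g))
    n_y, n_e = len(cfg.years), len(cfg.env_names)
    traits = [t for t in MODELLED_TRAITS if t in cfg.trait_models]

    # shared genotype-level draws (fixed trait order for reproducibility)
    latent = {t: rng.standard_normal(g) for t in traits}
    geno, gy_eff, ge_eff, year_eff, mults, shifts = {}, {}, {}, {}, {}, {}
    tol_idx = np.sort(rng.choice(g, size=cfg.n_true_tolerant, replace=False))
    for t in traits:
        tm = cfg.trait_models[t]
        loadings = cfg.genotype_loadings.get(t, {t: 1.0})
        z = sum(w * latent[src] for src, w in loadings.items())
        geno[t] = tm.sigma_g * z
        gy_eff[t] = rng.normal(0, tm.sigma_gy, (g, n_y))
        ge_eff[t] = rng.normal(0, tm.sigma_ge, (g, n_e))
        year_eff[t] = rng.normal(0, tm.sigma_year, n_y)
        if tm.response == "multiplicative":
            env_mult = tm.multipliers or cfg.environments
            if tm.yield_like:
                mults[t] = _genotype_multipliers(cfg, env_mult, tol_idx)
            else:
                mults[t] = np.tile(list(env_mult.values()), (g, 1))
            shifts[t] = np.zeros(n_e)
        else:
            mults[t] = np.ones((g, n_e))
            shifts[t] = np.array([tm.shifts[e] for e in cfg.env_names])

    gl_eff = {t: np.zeros((g, len(cfg.locations))) for t in traits}
    frames = []
    truncated = 0
    total_vals = 0
    for j, loc in enumerate(cfg.locations):
        rng_loc = np.random.default_rng(loc_ss[j])
        for t in traits:
            gl_eff[t][:, j] = rng_loc.normal(
                0, cfg.trait_models[t].sigma_gl, g
            )
        for k, year in enumerate(cfg.years):
            for m, env in enumerate(cfg.env_names):
                for rep in range(1, cfg.replicates + 1):
                    # alpha-lattice style: genotypes re-randomised into
                    # incomplete blocks within every replicate
                    perm = rng_loc.permutation(g)
                    blocks = np.empty(g, dtype=int)
                    for b, part in enumerate(
                        np.array_split(perm, cfg.blocks_per_replicate)
                    ):
                        blocks[part] = b + 1
                    cell = {
                        "genotype": names,
                        "location": loc,
                        "year": year,
                        "environment": env,
                        "replicate": rep,
                        "block": blocks,
                    }
                    values = {}
                    for t in traits:
                        tm = cfg.trait_models[t]
                        block_eff = rng_loc.normal(
                            0, tm.sigma_block, cfg.blocks_per_replicate
                        )[blocks - 1]
                        eps = rng_loc.normal(0, tm.sigma_e, g)
                        base = (tm.means[loc] + year_eff[t][k] + geno[t]
                                + gl_eff[t][:, j] + gy_eff[t][:, k]
                                + ge_eff[t][:, m] + block_eff + eps)
                        if tm.response == "multiplicative":
                            vals = mults[t][:, m] * base
                        else:
                            vals = base + shifts[t][m]
                        truncated += int((vals < 0).sum())
                        total_vals += g
                        values[t] = np.maximum(vals, 0.0)
                    row = dict(cell)
                    row["DFF"] = values["DFF"]
                    row["DM"] = values["DFF"] + values["DM_GAP"]
                    for t in ("PH", "NT", "SL", "NSS", "NGS", "TKW", "BY",
                              "SY"):
                        row[t] = values[t]
                    # grain is part of biomass: cap SY at BY so the derived
                    # harvest index stays within [0, 100]
                    row["SY"] = np.minimum(row["SY"], row["BY"])
                    with np.errstate(divide="ignore", invalid="ignore"):
                        hi = np.where(
                            row["BY"] > 0, 100.0 * row["SY"] / row["BY"],
                            np.nan,
                        )
                    # guard the SY == BY case against float round-up
                    row["HI"] = np.clip(hi, 0.0, 100.0)
                    frames.append(pd.DataFrame(row))
    records = pd.concat(frames, ignore_index=True)
    if truncated / max(total_vals, 1) > 0.01:
        import warnings
        warnings.warn(
            f"{100 * truncated / total_vals:.1f}% of generated values were "
            "truncated at zero; consider revising the trait models",
            stacklevel=2,
        )
    dataset = make_dataset(records, traits=TRAITS)
    truth = SyntheticTruth(
        config=cfg, genotype_names=names,
        tolerant=tuple(names[i] for i in tol_idx),
        genotype_effects=geno, gl_effects=gl_eff, gy_effects=gy_eff,
        ge_effects=ge_eff, year_effects=year_eff,
        multipliers=mults, shifts=shifts,
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# YAML round-trip for configs

def config_to_yaml(cfg: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(asdict(cfg)), fh, sort_keys=False)


def config_from_yaml(path) -> SimulationConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    raw["locations"] = tuple(raw.get("locations", ()))
    raw["years"] = tuple(raw.get("years", ()))
    raw["trait_models"] = {
        t: TraitModel(**tm) for t, tm in raw.get("trait_models", {}).items()
    }
    cfg = SimulationConfig(**raw)
    cfg.validate()
    return cfg


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
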