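"""Percent reduction of each trait from the optimum to a stress environment.

Reductions are computed on genotype x environment pooled means (never by
pairing individual plots across environments) and summarised across
genotypes as the unweighted mean of per-genotype percent reductions
(mean-of-ratios, not ratio-of-means; on heterogeneous data the two differ
and the former is the documented contract).
"""

from __future__ import annotations

import pandas as pd

from .core_data import TrialDataset, genotype_env_means
from .exceptions import UndefinedRatioError, ValidationError
from ._round import round_half_away

CONTRASTS = {"OE-HSE": "HSE", "OE-HDSE": "HDSE"}


def percent_reduction(x_oe: float, x_stress: float) -> float:
    """100*(X_OE - X_S)/X_OE; signed, negative means gain under stress."""
    if x_oe == 0:
        raise UndefinedRatioError("optimum-environment value is zero")
    return 100.0 * (x_oe - x_stress) / x_oe


def genotype_reductions(dataset: TrialDataset, location: str,
                        contrast: str, trait: str) -> pd.DataFrame:
    """Per-genotype percent reduction of one trait for one contrast.

    Genotypes missing either arm (or with a zero optimum mean) are excluded.
    """
    if contrast not in CONTRASTS:
        raise ValidationError(
            f"contrast must be one of {sorted(CONTRASTS)}, got {contrast!r}"
        )
    stress_env = CONTRASTS[contrast]
    means = genotype_env_means(dataset, trait)
    at_loc = means[means["location"] == location]
    if at_loc.empty:
        raise ValidationError(f"location {location!r} not present in dataset")
    wide = at_loc.pivot(index="genotype", columns="environment",
                        values="mean")
    for env in ("OE", stress_env):
        if env not in wide.columns:
            raise ValidationError(
                f"environment {env} not present at location {location}"
            )
    wide = wide[["OE", stress_env]].dropna()
    wide = wide[wide["OE"] > 0]
    if wide.empty:
        raise ValidationError(
            f"no genotype has both arms of {contrast} at {location}"
        )
    out = pd.DataFrame({
        "genotype": wide.index,
        "location": location,
        "trait": trait,
        "contrast": contrast,
        "reduction": (100.0 * (wide["OE"] - wide[stress_env])
                      / wide["OE"]).to_numpy(),
    })
    return out.reset_index(drop=True)


def reduction_summary(dataset: TrialDataset, location: str, contrast: str,
                      traits: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Per-trait min/max/mean of per-genotype percent reductions."""
    traits = traits or dataset.traits
    rows = []
    for trait in traits:
        red = genotype_reductions(dataset, location, contrast, trait)
        rows.append({
            "trait": trait, "location": location, "contrast": contrast,
            "min": red["reduction"].min(),
            "max": red["reduction"].max(),
            "mean": red["reduction"].mean(),
            "n_genotypes": len(red),
        })
    return pd.DataFrame(rows)


def render_reduction_report(summary: pd.DataFrame) -> pd.DataFrame:
    """Printed-precision view: min/max at 1 dp, mean as an integer."""
    out = summary[["trait", "location", "contrast"]].copy()
    out["Min"] = [round_half_away(v, 1) for v in summary["min"]]
    out["Max"] = [round_half_away(v, 1) for v in summary["max"]]
    out["Mean"] = [int(round_half_away(v, 0)) for v in summary["mean"]]
    return out
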