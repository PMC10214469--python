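"""Descriptive statistics per trait x environment x location.

Summaries are computed at plot level (not on genotype means) with the
sample (n-1) standard deviation, matching conventional field-trial
reporting.  Years are pooled by default; pass ``year=`` to restrict.
"""

from __future__ import annotations

import warnings

import pandas as pd

from .core_data import TrialDataset
from .exceptions import ValidationError


def describe_traits(dataset: TrialDataset,
                    group_by: tuple[str, ...] = ("location", "environment"),
                    year: str | None = None) -> pd.DataFrame:
    """One row per trait x group with min, max, mean, sample sd and n.

    Groups in which a trait has no non-missing value are omitted with a
    warning.
    """
    if len(dataset) == 0:
        raise ValidationError("cannot describe an empty dataset")
    records = dataset.records
    if year is not None:
        records = records[records["year"] == year]
    long = records.melt(
        id_vars=list(group_by), value_vars=list(dataset.traits),
        var_name="trait", value_name="value",
    ).dropna(subset=["value"])
    grouped = long.groupby(["trait", *group_by], observed=True)["value"]
    out = grouped.agg(min="min", max="max", mean="mean", sd="std", n="count")
    out = out.reset_index()
    # a single observation has undefined sample sd; report 0 spread? no --
    # keep NaN sd but flag groups that vanished entirely
    n_expected = len(dataset.traits) * (
        records.groupby(list(group_by), observed=True).ngroups
    )
    if len(out) < n_expected:
        warnings.warn(
            f"{n_expected - len(out)} trait/group combination(s) had no "
            "observations and were omitted",
            stacklevel=2,
        )
    # canonical ordering: traits in catalogue order, then group levels
    out["trait"] = pd.Categorical(out["trait"], categories=dataset.traits,
                                  ordered=True)
    out = out.sort_values(["trait", *group_by]).reset_index(drop=True)
    out["trait"] = out["trait"].astype(str)
    return out


def export_distribution_data(dataset: TrialDataset, trait: str) -> pd.DataFrame:
    """Tidy per-plot export of one trait for external distribution plotting.

    One row per plot-level observation (missing values dropped), columns
    ``value, genotype, location, environment``; row order follows the
    dataset, so re-running on the same dataset is byte-stable.
    """
    if trait not in dataset.traits:
        raise ValidationError(f"trait {trait!r} not present in dataset")
    out = dataset.records[["genotype", "location", "environment", trait]]
    out = out.rename(columns={trait: "value"}).dropna(subset=["value"])
    return out[["value", "genotype", "location", "environment"]].reset_index(
        drop=True
    )


def summary_table(summaries: pd.DataFrame) -> pd.DataFrame:
    """Pivot :func:`describe_traits` output into a report layout: one block
    per location, rows = traits, columns = (min, max, mean, sd) per
    environment."""
    wide = summaries.pivot_table(
        index=["location", "trait"], columns="environment",
        values=["min", "max", "mean", "sd"], sort=False, observed=True,
    )
    wide.columns = [f"{env}_{stat}" for stat, env in wide.columns]
    return wide.reset_index()
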