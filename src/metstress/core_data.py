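"""Data model, validation and I/O for plot-level multi-environment trial phenotypes.

The canonical exchange format is a long ("tidy") CSV with one row per
genotype x location x year x environment x replicate plot and one column per
trait.  Eleven agronomic traits are recognised: phenology (DFF, DM), plant
architecture (PH, NT, SL), spike components (NSS, NGS, TKW), and yield
(BY, HI, SY).  Years are opaque season labels such as "2020-21" and are never
parsed as integers.  Missing trait values are permitted and propagate as
missing; they are never imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import SchemaError, UndefinedRatioError, ValidationError

#: the 11 recognised trait codes, in canonical column order
TRAITS: tuple[str, ...] = (
    "DFF", "DM", "PH", "NT", "SL", "NSS", "NGS", "TKW", "BY", "HI", "SY",
)

#: stress-environment labels: optimum, heat stress, combined heat-drought
ENVIRONMENTS: tuple[str, ...] = ("OE", "HSE", "HDSE")

#: identifying (key) columns of a plot record; (genotype, location, year,
#: environment, replicate) must be unique, block is design metadata
KEY_COLUMNS: tuple[str, ...] = (
    "genotype", "location", "year", "environment", "replicate", "block",
)

UNIQUE_KEY: tuple[str, ...] = (
    "genotype", "location", "year", "environment", "replicate",
)

#: tolerated disagreement (percentage points) between a stored HI value and
#: the value recomputed from SY and BY before a validation warning is issued
HI_CONSISTENCY_TOL = 0.5


@dataclass(frozen=True)
class TrialDesign:
    """Shape of a multi-environment trial.

    ``balanced`` is true iff every genotype appears exactly once in every
    (location, year, environment, replicate) cell.
    """

    n_genotypes: int
    n_locations: int
    n_years: int
    n_environments: int
    n_replicates: int
    blocks_per_replicate: int
    balanced: bool

    @property
    def n_plots(self) -> int:
        return (self.n_genotypes * self.n_locations * self.n_years
                * self.n_environments * self.n_replicates)


@dataclass
class TrialDataset:
    """Validated plot-level records plus design metadata.

    ``records`` is a long-format DataFrame with the key columns followed by
    the trait columns listed in ``traits``.
    """

    records: pd.DataFrame
    design: TrialDesign
    traits: tuple[str, ...]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TrialDataset):
            return NotImplemented
        if self.design != other.design or self.traits != other.traits:
            return False
        try:
            pd.testing.assert_frame_equal(
                self.records.reset_index(drop=True),
                other.records.reset_index(drop=True),
                check_dtype=False,
            )
        except AssertionError:
            return False
        return True

    def __len__(self) -> int:
        return len(self.records)


def infer_design(records: pd.DataFrame) -> TrialDesign:
    """Infer the trial design from the distinct factor levels present."""
    counts = {c: records[c].nunique() for c in KEY_COLUMNS}
    cell = ["location", "year", "environment", "replicate"]
    balanced = False
    if len(records) > 0:
        per_cell = records.groupby(cell, observed=True)["genotype"]
        sizes = per_cell.nunique()
        occurs = records.groupby(cell + ["genotype"], observed=True).size()
        n_cells = (counts["location"] * counts["year"]
                   * counts["environment"] * counts["replicate"])
        balanced = bool(
            len(sizes) == n_cells
            and (sizes == counts["genotype"]).all()
            and (occurs == 1).all()
        )
    return TrialDesign(
        n_genotypes=counts["genotype"],
        n_locations=counts["location"],
        n_years=counts["year"],
        n_environments=counts["environment"],
        n_replicates=counts["replicate"],
        blocks_per_replicate=counts["block"],
        balanced=balanced,
    )


def _validate(records: pd.DataFrame, traits: tuple[str, ...]) -> None:
    bad_env = ~records["environment"].isin(ENVIRONMENTS)
    if bad_env.any():
        row = int(np.flatnonzero(bad_env.to_numpy())[0])
        raise ValidationError(
            f"unknown environment label {records['environment'].iloc[row]!r} "
            f"at row {row} (expected one of {ENVIRONMENTS})"
        )
    dup = records.duplicated(subset=list(UNIQUE_KEY))
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        key = records.loc[records.index[row], list(UNIQUE_KEY)].to_dict()
        raise ValidationError(f"duplicate plot key at row {row}: {key}")
    for t in traits:
        vals = records[t]
        if (vals.dropna() < 0).any():
            raise ValidationError(f"trait {t} contains negative values")
    if "HI" in traits:
        hi = records["HI"].dropna()
        if ((hi < 0) | (hi > 100)).any():
            raise ValidationError("HI outside [0, 100]")
    if "DFF" in traits and "DM" in traits:
        both = records[["DFF", "DM"]].dropna()
        if (both["DM"] < both["DFF"]).any():
            raise ValidationError("DM < DFF for at least one plot")
    if {"HI", "SY", "BY"} <= set(traits):
        sub = records[["HI", "SY", "BY"]].dropna()
        sub = sub[sub["BY"] > 0]
        if len(sub):
            recomputed = 100.0 * sub["SY"] / sub["BY"]
            off = (recomputed - sub["HI"]).abs() > HI_CONSISTENCY_TOL
            if off.any():
                warnings.warn(
                    f"{int(off.sum())} plot(s) have stored HI deviating from "
                    f"100*SY/BY by more than {HI_CONSISTENCY_TOL} percentage "
                    "points; stored values kept",
                    stacklevel=3,
                )


def make_dataset(records: pd.DataFrame,
                 traits: tuple[str, ...] | None = None) -> TrialDataset:
    """Validate a long-format frame and wrap it as a :class:`TrialDataset`."""
    if traits is None:
        traits = tuple(t for t in TRAITS if t in records.columns)
    missing = [c for c in KEY_COLUMNS if c not in records.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    if not traits:
        raise SchemaError("no trait columns present")
    records = records[list(KEY_COLUMNS) + list(traits)].copy()
    records["replicate"] = records["replicate"].astype(int)
    records["block"] = records["block"].astype(int)
    for t in traits:
        records[t] = pd.to_numeric(records[t], errors="raise").astype(float)
    _validate(records, traits)
    return TrialDataset(records=records, design=infer_design(records),
                        traits=traits)


def _read_schema(schema: dict | str | Path | None) -> dict:
    if schema is None:
        return {}
    if isinstance(schema, (str, Path)):
        with open(schema) as fh:
            loaded = yaml.safe_load(fh) or {}
        return loaded.get("columns", loaded)
    return dict(schema)


def load_trials(path: str | Path,
                schema: dict | str | Path | None = None) -> TrialDataset:
    """Read a long-format trial CSV and return a validated dataset.

    Parameters
    ----------
    path:
        CSV file with one header row and one row per plot.
    schema:
        Optional mapping of file column names to canonical names (or a YAML
        file with a ``columns:`` mapping).
    """
    mapping = _read_schema(schema)
    df = pd.read_csv(path)
    if mapping:
        df = df.rename(columns=mapping)
    missing = [c for c in KEY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"missing mandatory column(s) after mapping: {', '.join(missing)}"
        )
    for c in ("genotype", "location", "year", "environment"):
        df[c] = df[c].astype(str)
    return make_dataset(df)


def write_trials(dataset: TrialDataset, path: str | Path) -> None:
    """Write the canonical long CSV (UTF-8, header row, stable column order)."""
    cols = list(KEY_COLUMNS) + list(dataset.traits)
    dataset.records[cols].to_csv(path, index=False, encoding="utf-8")


def derive_harvest_index(sy, by):
    """Harvest index HI = 100 * SY / BY (percent).

    Accepts scalars or arrays.  A zero biological yield raises
    :class:`UndefinedRatioError`; grain yield exceeding biological yield is
    physiologically implausible and triggers a warning, but the value is
    returned unchanged.
    """
    sy_a = np.asarray(sy, dtype=float)
    by_a = np.asarray(by, dtype=float)
    if np.any(by_a == 0):
        raise UndefinedRatioError("BY = 0: harvest index undefined")
    if np.any(sy_a > by_a):
        warnings.warn("SY > BY: harvest index exceeds 100%", stacklevel=2)
    out = 100.0 * sy_a / by_a
    return float(out) if np.isscalar(sy) or out.ndim == 0 else out


def genotype_env_means(dataset: TrialDataset, trait: str,
                       pooling: tuple[str, ...] = ("year", "replicate"),
                       ) -> pd.DataFrame:
    """Per-genotype means for each (location, environment), pooling years
    and replicates.

    Returns a frame with columns ``location, environment, genotype, mean, n``
    covering the full cross of observed levels; cells with no non-missing
    observation carry ``mean = NaN`` and ``n = 0``.
    """
    if trait not in dataset.traits:
        raise ValidationError(f"trait {trait!r} not present in dataset")
    keep = [c for c in ("location", "environment", "genotype")
            if c not in pooling]
    grp = dataset.records.groupby(keep, observed=True)[trait]
    out = grp.agg(mean="mean", n="count").reset_index()
    full = pd.MultiIndex.from_product(
        [sorted(dataset.records[c].unique()) for c in keep], names=keep
    )
    out = (out.set_index(keep).reindex(full).reset_index())
    out["n"] = out["n"].fillna(0).astype(int)
    return out
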