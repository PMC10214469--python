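"""Stress-tolerance indices, genotype ranking and tolerant/susceptible
selection.

Given per-genotype mean seed yields under the optimum environment (Yp) and a
stress environment (Ys), with population means over all entries Ȳp and Ȳs,
the six indices are

    STI  = Yp*Ys / Ȳp²                 (potential + tolerance, higher = better)
    SSI  = (1 - Ys/Yp) / SI            where SI = 1 - Ȳs/Ȳp (stress intensity)
    MP   = (Yp + Ys) / 2               (mean productivity, g/plot)
    TOL  = Yp - Ys                     (yield loss, g/plot; smaller = tolerant)
    MSTI = (Ys/Ȳs)² * STI              (STI reweighted towards stress yield)
    GMP  = sqrt(Yp*Ys)                 (geometric mean productivity, g/plot)

GMP's formula is a field convention (its definition is not printed in the
source tables); it is marked "convention" in output metadata.  STI, SSI and
MSTI are dimensionless and scale-invariant; MP, TOL and GMP carry the yield
unit.  Yp/Ys are computed per location with years and replicates pooled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import TrialDataset, genotype_env_means
from .exceptions import NoStressError, UndefinedRatioError, ValidationError
from ._round import round_half_away

#: printed precision of report tables: SY/MP/TOL integer, STI/SSI 2 dp,
#: MSTI 1 dp, GMP integer (same unit as MP)
REPORT_ROUNDING: dict[str, int] = {
    "SY": 0, "Yp": 0, "Ys": 0, "STI": 2, "SSI": 2, "MP": 0, "TOL": 0,
    "MSTI": 1, "GMP": 0,
}


# ---------------------------------------------------------------------------
# scalar index formulas

def sti(yp: float, ys: float, yp_bar: float) -> float:
    """Stress tolerance index Yp*Ys/Ȳp²."""
    if yp_bar == 0:
        raise UndefinedRatioError("population optimum yield is zero")
    return yp * ys / yp_bar**2


def ssi(yp: float, ys: float, yp_bar: float, ys_bar: float) -> float:
    """Stress susceptibility index (1 - Ys/Yp)/SI; 1 = population-average
    loss, > 1 = more susceptible than average."""
    if yp == 0:
        raise UndefinedRatioError("genotype optimum yield is zero")
    if yp_bar == 0:
        raise UndefinedRatioError("population optimum yield is zero")
    si = 1.0 - ys_bar / yp_bar
    if si <= 0:
        raise NoStressError(
            f"stress intensity {si:.4g} is not positive; SSI undefined"
        )
    return (1.0 - ys / yp) / si


def mp(yp: float, ys: float) -> float:
    """Mean productivity (Yp + Ys)/2."""
    return (yp + ys) / 2.0


def tol(yp: float, ys: float) -> float:
    """Tolerance Yp - Ys (signed; negative means yield gain under stress)."""
    return yp - ys


def msti(yp: float, ys: float, yp_bar: float, ys_bar: float) -> float:
    """Modified stress tolerance index (Ys/Ȳs)² * STI."""
    if ys_bar == 0:
        raise UndefinedRatioError("population stress yield is zero")
    return (ys / ys_bar) ** 2 * sti(yp, ys, yp_bar)


def gmp(yp: float, ys: float) -> float:
    """Geometric mean productivity sqrt(Yp*Ys) (convention)."""
    return float(np.sqrt(yp * ys))


# ---------------------------------------------------------------------------
# yield summaries and index tables

@dataclass
class YieldSummary:
    """Per-genotype Yp/Ys at one location for one stress contrast, plus the
    population means and stress intensity SI = 1 - Ȳs/Ȳp."""

    location: str
    stress_env: str
    yields: pd.DataFrame  # columns: genotype, Yp, Ys
    yp_bar: float
    ys_bar: float
    trait: str = "SY"

    @property
    def si(self) -> float:
        return 1.0 - self.ys_bar / self.yp_bar


def build_yield_summary(dataset: TrialDataset, location: str,
                        stress_env: str, trait: str = "SY") -> YieldSummary:
    """Genotype means (years and replicates pooled) under OE and one stress
    environment at one location.

    Genotypes missing either arm are excluded with a warning; population
    means are unweighted over the genotypes with both arms.  A non-positive
    stress intensity raises :class:`NoStressError`.
    """
    if stress_env not in ("HSE", "HDSE"):
        raise ValidationError(
            f"stress environment must be HSE or HDSE, got {stress_env!r}"
        )
    means = genotype_env_means(dataset, trait)
    at_loc = means[means["location"] == location]
    if at_loc.empty:
        raise ValidationError(f"location {location!r} not present in dataset")
    have = set(at_loc["environment"])
    for env in ("OE", stress_env):
        if env not in have:
            raise ValidationError(
                f"environment {env} not present at location {location}"
            )
    wide = at_loc.pivot(index="genotype", columns="environment",
                        values="mean")[["OE", stress_env]]
    wide.columns = ["Yp", "Ys"]
    incomplete = wide.isna().any(axis=1)
    if incomplete.any():
        warnings.warn(
            f"{int(incomplete.sum())} genotype(s) lack one arm of the "
            f"OE-{stress_env} contrast and were excluded",
            stacklevel=2,
        )
        wide = wide[~incomplete]
    if wide.empty:
        raise ValidationError("no genotype has both contrast arms")
    yp_bar = float(wide["Yp"].mean())
    ys_bar = float(wide["Ys"].mean())
    if yp_bar <= 0:
        raise UndefinedRatioError("population optimum yield is not positive")
    if 1.0 - ys_bar / yp_bar <= 0:
        raise NoStressError(
            f"{stress_env} does not yield below OE at {location} "
            "(stress intensity <= 0)"
        )
    return YieldSummary(
        location=location, stress_env=stress_env,
        yields=wide.reset_index(), yp_bar=yp_bar, ys_bar=ys_bar, trait=trait,
    )


@dataclass
class IndexTable:
    """Per-genotype index records with ranks and selection labels."""

    summary: YieldSummary
    records: pd.DataFrame  # genotype, Yp, Ys, STI, SSI, MP, TOL, MSTI, GMP...
    k: int | None = None
    metadata: dict = field(default_factory=dict)


def compute_index_table(summary: YieldSummary) -> IndexTable:
    """All six indices for every genotype of a yield summary.

    A genotype with Yp = 0 gets a missing SSI (its relative loss is
    undefined); the other indices are still computed.  Negative TOL values
    (yield gain under stress) are flagged, not clamped.
    """
    yp = summary.yields["Yp"].to_numpy(float)
    ys = summary.yields["Ys"].to_numpy(float)
    yp_bar, ys_bar = summary.yp_bar, summary.ys_bar
    si = summary.si
    with np.errstate(divide="ignore", invalid="ignore"):
        ssi_vals = np.where(yp > 0, (1.0 - ys / yp) / si, np.nan)
    records = pd.DataFrame({
        "genotype": summary.yields["genotype"],
        "Yp": yp,
        "Ys": ys,
        "STI": yp * ys / yp_bar**2,
        "SSI": ssi_vals,
        "MP": (yp + ys) / 2.0,
        "TOL": yp - ys,
        "MSTI": (ys / ys_bar) ** 2 * (yp * ys / yp_bar**2),
        "GMP": np.sqrt(yp * ys),
        "stress_gain": yp - ys < 0,
    })
    return IndexTable(
        summary=summary, records=records,
        metadata={"location": summary.location,
                  "stress_env": summary.stress_env,
                  "trait": summary.trait,
                  "SI": si,
                  "GMP": "convention"},
    )


def _ordering(records: pd.DataFrame, key: str, descending: bool) -> pd.Index:
    # ties broken by higher Ys, then lexicographic genotype id
    col = records[key]
    sort_key = -col if descending else col
    order = records.assign(_k=sort_key).sort_values(
        ["_k", "Ys", "genotype"], ascending=[True, False, True],
        kind="mergesort",
    )
    return order.index


def rank_and_select(table: IndexTable, k: int = 5,
                    tolerant_key: str = "STI",
                    susceptible_key: str = "SSI") -> IndexTable:
    """Rank genotypes and label the top-k tolerant (by STI, descending) and
    top-k susceptible (by SSI, descending) sets."""
    if k <= 0:
        raise ValidationError("k must be a positive integer")
    records = table.records.copy()
    if k > len(records):
        raise ValidationError(
            f"k = {k} exceeds the {len(records)} available genotypes"
        )
    tol_order = _ordering(records, tolerant_key, descending=True)
    sus_order = _ordering(records, susceptible_key, descending=True)
    records["rank"] = 0
    records.loc[tol_order, "rank"] = np.arange(1, len(records) + 1)
    records["tolerant"] = False
    records.loc[tol_order[:k], "tolerant"] = True
    records["susceptible"] = False
    records.loc[sus_order[:k], "susceptible"] = True
    return IndexTable(summary=table.summary, records=records, k=k,
                      metadata={**table.metadata,
                                "tolerant_key": tolerant_key,
                                "susceptible_key": susceptible_key})


def top_k_summary(selected, k: int | None = None,
                  round_spec: dict[str, int] = REPORT_ROUNDING) -> pd.Series:
    """Unweighted column means over the selected top-k records, rounded
    half-away-from-zero at the printed precisions.

    ``selected`` may be a labelled :class:`IndexTable` (its tolerant set is
    used) or a plain DataFrame of the k records.
    """
    if isinstance(selected, IndexTable):
        recs = selected.records
        if "tolerant" in recs.columns:
            recs = recs[recs["tolerant"]]
        df = recs
    else:
        df = selected
    if k is not None:
        if k > len(df):
            raise ValidationError(f"k = {k} exceeds {len(df)} selected rows")
        df = df.iloc[:k]
    if df.empty:
        raise ValidationError("no selected records to summarise")
    numeric = df.select_dtypes(include=[np.number])
    means = numeric.mean()
    return pd.Series({
        col: round_half_away(val, round_spec.get(col, 2))
        for col, val in means.items()
    })


def render_index_report(table: IndexTable, include_gmp: bool = True,
                        round_spec: dict[str, int] = REPORT_ROUNDING,
                        ) -> pd.DataFrame:
    """Report table mirroring the published layout: Cultivar, SY(g) (= Yp,
    the optimum-environment plot yield), STI, SSI, MP, TOL, MSTI (+ GMP),
    restricted to the tolerant selection with an appended Mean row."""
    recs = table.records
    if "tolerant" in recs.columns:
        recs = recs[recs["tolerant"]].sort_values("rank")
    cols = ["STI", "SSI", "MP", "TOL", "MSTI"] + (
        ["GMP"] if include_gmp else []
    )
    out = pd.DataFrame({"Cultivar": recs["genotype"],
                        "SY(g)": recs["Yp"]})
    for c in cols:
        out[c] = recs[c].to_numpy()
    def fmt(value: float, digits: int):
        r = round_half_away(value, digits)
        return int(r) if digits == 0 else r

    rounded = out.copy()
    rounded["SY(g)"] = [fmt(v, round_spec["Yp"]) for v in out["SY(g)"]]
    for c in cols:
        rounded[c] = [fmt(v, round_spec.get(c, 2)) for v in out[c]]
    mean_row = {"Cultivar": "Mean",
                "SY(g)": fmt(out["SY(g)"].mean(), round_spec["Yp"])}
    for c in cols:
        mean_row[c] = fmt(out[c].mean(), round_spec.get(c, 2))
    return pd.concat([rounded, pd.DataFrame([mean_row])], ignore_index=True)
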