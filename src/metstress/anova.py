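"""Fixed-effects factorial ANOVA for multi-environment trials.

The pooled model decomposes each trait over location, year, environment,
genotype, their interactions, and the replicate / incomplete-block terms of
the alpha-lattice layout (intra-block analysis: blocks are fixed and nested
in replicates, no inter-block information recovery).  Estimation is OLS with
sequential (Type-I) sums of squares in the printed term order; with balanced
data main-effect SS are order-invariant.  F statistics test every term
against the residual mean square.

The "random factor" role of locations, years and environments is honoured
through the expected-mean-square step: method-of-moments variance components
(sigma^2_G, sigma^2_GL, sigma^2_GY, sigma^2_GE, sigma^2_e) and entry-mean
broad-sense heritability

    H^2 = sigma^2_G / (sigma^2_G + sigma^2_GL/l + sigma^2_GY/y
                       + sigma^2_GE/e + sigma^2_e/(l*y*e*r)) * 100

where l, y, e, r are the numbers of locations, years, environments and
replicates.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

from .core_data import TrialDataset, make_dataset
from .exceptions import UnbalancedDesignError, ValidationError

#: term order of the pooled (across-location) model
POOLED_TERMS: tuple[str, ...] = (
    "Location", "Year", "Env", "Gen",
    "Location:Gen", "Year:Gen", "Env:Gen",
    "Location:Env", "Location:Year", "Year:Env",
    "Location:Year:Gen", "Location:Env:Gen", "Location:Year:Env:Gen",
    "Rep", "Block(Rep)",
)

#: term order of the single-location model
PER_LOCATION_TERMS: tuple[str, ...] = (
    "Year", "Env", "Gen", "Year:Gen", "Env:Gen", "Year:Env:Gen",
    "Rep", "Block(Rep)",
)

_FACTOR_COLUMNS = {
    "Location": "location",
    "Year": "year",
    "Env": "environment",
    "Gen": "genotype",
    "Rep": "replicate",
}


def _term_to_patsy(term: str) -> str:
    if term == "Block(Rep)":
        return "C(replicate):C(block)"
    parts = term.split(":")
    unknown = [p for p in parts if p not in _FACTOR_COLUMNS]
    if unknown:
        raise ValidationError(f"unknown model term component(s): {unknown}")
    return ":".join(f"C({_FACTOR_COLUMNS[p]})" for p in parts)


def significance_code(p: float) -> str:
    """Star convention: *** < 0.001, ** < 0.01, * < 0.05, . < 0.1."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "."
    return ""


@dataclass
class AnovaTable:
    """Ordered ANOVA terms with df, SS, MS, F, p and significance codes."""

    trait: str
    table: pd.DataFrame  # columns: term, df, sum_sq, mean_sq, F, p, signif
    n_obs: int

    def _row(self, term: str) -> pd.Series:
        hit = self.table[self.table["term"] == term]
        if hit.empty:
            raise ValidationError(f"term {term!r} missing from ANOVA table")
        return hit.iloc[0]

    def df(self, term: str) -> int:
        return int(self._row(term)["df"])

    def ms(self, term: str) -> float:
        return float(self._row(term)["mean_sq"])

    @property
    def residual_df(self) -> int:
        return self.df("Residuals")

    @property
    def residual_ms(self) -> float:
        return self.ms("Residuals")

    @property
    def total_ss(self) -> float:
        return float(self.table["sum_sq"].sum())


def fit_factorial_anova(dataset: TrialDataset, trait: str,
                        terms: tuple[str, ...] = POOLED_TERMS) -> AnovaTable:
    """Sequential-SS factorial ANOVA of one trait on a balanced dataset.

    Raises :class:`UnbalancedDesignError` for unbalanced data (including
    missing values in the response) rather than silently switching SS type.
    """
    if trait not in dataset.traits:
        raise ValidationError(f"trait {trait!r} not present in dataset")
    if not dataset.design.balanced:
        raise UnbalancedDesignError(
            "sequential-SS ANOVA requires a balanced design"
        )
    data = dataset.records
    if data[trait].isna().any():
        raise UnbalancedDesignError(
            f"trait {trait} has missing plot values; the design is "
            "effectively unbalanced"
        )
    patsy_terms = [_term_to_patsy(t) for t in terms]
    formula = f"Q('{trait}') ~ " + " + ".join(patsy_terms)
    with warnings.catch_warnings():
        # constant responses emit harmless divide-by-zero warnings
        warnings.simplefilter("ignore", RuntimeWarning)
        fit = ols(formula, data=data).fit()
        raw = anova_lm(fit, typ=1)
    if int(raw.loc["Residual", "df"]) == 0:
        raise UnbalancedDesignError("residual degrees of freedom are zero")
    name_map = dict(zip(patsy_terms, terms))
    name_map["Residual"] = "Residuals"
    out = raw.rename(index=name_map).reset_index(names="term")
    # patsy orders terms by interaction degree; restore the requested order
    # (balanced data makes the sequential SS order-invariant)
    order = {t: i for i, t in enumerate((*terms, "Residuals"))}
    out = out.sort_values("term", key=lambda s: s.map(order),
                          kind="mergesort").reset_index(drop=True)
    out["df"] = out["df"].astype(int)
    out["mean_sq"] = out["sum_sq"] / out["df"]
    ms_res = out.loc[out["term"] == "Residuals", "mean_sq"].iloc[0]
    if ms_res == 0 or float(np.var(data[trait].to_numpy())) == 0.0:
        out["F"] = np.nan
        out["p"] = np.nan
    else:
        out["F"] = out["mean_sq"] / ms_res
        df_res = int(out.loc[out["term"] == "Residuals", "df"].iloc[0])
        out["p"] = stats.f.sf(out["F"], out["df"], df_res)
    out.loc[out["term"] == "Residuals", ["F", "p"]] = np.nan
    out["signif"] = [significance_code(p) if t != "Residuals" else ""
                     for t, p in zip(out["term"], out["p"])]
    out = out[["term", "df", "sum_sq", "mean_sq", "F", "p", "signif"]]
    return AnovaTable(trait=trait, table=out, n_obs=len(data))


def per_location_anova(dataset: TrialDataset, trait: str,
                       location: str,
                       terms: tuple[str, ...] = PER_LOCATION_TERMS,
                       ) -> AnovaTable:
    """Single-location ANOVA across environments (Year, Env, Gen and their
    interactions plus Rep and Block(Rep))."""
    recs = dataset.records
    if location not in set(recs["location"]):
        raise ValidationError(f"location {location!r} not present in dataset")
    sub = make_dataset(recs[recs["location"] == location].copy(),
                       traits=dataset.traits)
    return fit_factorial_anova(sub, trait, terms=terms)


@dataclass
class VarianceComponents:
    """Method-of-moments variance components; negative solutions are
    truncated to zero and recorded in ``truncated``."""

    sigma2_g: float
    sigma2_gl: float
    sigma2_gy: float
    sigma2_ge: float
    sigma2_e: float
    truncated: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {"sigma2_g": self.sigma2_g, "sigma2_gl": self.sigma2_gl,
                "sigma2_gy": self.sigma2_gy, "sigma2_ge": self.sigma2_ge,
                "sigma2_e": self.sigma2_e}


def estimate_variance_components(table: AnovaTable,
                                 design) -> VarianceComponents:
    """Solve the balanced-factorial EMS equations for the pooled model.

    With l locations, y years, e environments and r replicates:

        E[MS_Gen]  = s2_e + y*e*r*s2_GL + l*e*r*s2_GY + l*y*r*s2_GE
                     + l*y*e*r*s2_G
        E[MS_GL]   = s2_e + y*e*r*s2_GL      (and analogously GY, GE)
        E[MS_res]  = s2_e
    """
    l, y = design.n_locations, design.n_years
    e, r = design.n_environments, design.n_replicates
    for needed in ("Gen", "Location:Gen", "Year:Gen", "Env:Gen", "Residuals"):
        table._row(needed)  # raises naming the missing term
    ms_g = table.ms("Gen")
    ms_gl = table.ms("Location:Gen")
    ms_gy = table.ms("Year:Gen")
    ms_ge = table.ms("Env:Gen")
    ms_res = table.residual_ms
    raw = {
        "sigma2_gl": (ms_gl - ms_res) / (y * e * r),
        "sigma2_gy": (ms_gy - ms_res) / (l * e * r),
        "sigma2_ge": (ms_ge - ms_res) / (l * y * r),
        "sigma2_g": (ms_g - ms_gl - ms_gy - ms_ge + 2 * ms_res)
        / (l * y * e * r),
    }
    truncated = tuple(k for k, v in raw.items() if v < 0)
    clipped = {k: max(v, 0.0) for k, v in raw.items()}
    return VarianceComponents(sigma2_e=ms_res, truncated=truncated, **clipped)


@dataclass
class HeritabilityResult:
    """Entry-mean broad-sense heritability (percent) with provenance."""

    h2: float
    components: VarianceComponents
    divisors: dict[str, int] = field(default_factory=dict)


def broad_sense_heritability(vc: VarianceComponents,
                             design) -> HeritabilityResult:
    """Entry-mean H^2 on the 0-100 percent scale, clamped to [0, 100]."""
    l, y = design.n_locations, design.n_years
    e, r = design.n_environments, design.n_replicates
    denom = (vc.sigma2_g + vc.sigma2_gl / l + vc.sigma2_gy / y
             + vc.sigma2_ge / e + vc.sigma2_e / (l * y * e * r))
    if denom == 0:
        warnings.warn("all variance components are zero; H^2 reported as 0",
                      stacklevel=2)
        h2 = 0.0
    else:
        h2 = float(np.clip(100.0 * vc.sigma2_g / denom, 0.0, 100.0))
    return HeritabilityResult(
        h2=h2, components=vc, divisors={"l": l, "y": y, "e": e, "r": r}
    )


# ---------------------------------------------------------------------------
# post-hoc mean separation

@dataclass
class PostHocResult:
    method: str
    alpha: float
    critical_value: float
    pairs: pd.DataFrame  # group_1, group_2, difference, significant
    letters: dict[str, str]
    means: pd.Series


def _compact_letter_display(groups: list[str],
                            means: dict[str, float],
                            significant: set[frozenset]) -> dict[str, str]:
    # insert-and-absorb: start with one set holding everything, split on each
    # significant pair, drop subsets, then letter the sets by best mean
    sets: list[set[str]] = [set(groups)]
    for pair in significant:
        a, b = tuple(pair)
        for s in list(sets):
            if a in s and b in s:
                sets.remove(s)
                for cand in (s - {a}, s - {b}):
                    if cand and not any(cand <= other for other in sets):
                        sets.append(cand)
        sets = [s for s in sets if not any(s < other for other in sets)]
    sets.sort(key=lambda s: -max(means[g] for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for letter, s in zip(alphabet, sets):
        for g in s:
            out[g] += letter
    return {g: "".join(sorted(out[g])) for g in groups}


def post_hoc(dataset: TrialDataset, trait: str, factor: str,
             method: str = "LSD", alpha: float = 0.05,
             anova: AnovaTable | None = None) -> PostHocResult:
    """Pairwise mean separation by LSD or Tukey HSD with a compact letter
    display.

    The error term is the residual mean square of ``anova`` when given,
    otherwise of a one-way fit on ``factor``.  A pair is significant when
    its absolute mean difference strictly exceeds the critical value:

        LSD   = t(1 - alpha/2, df_res) * sqrt(2 * MS_res / n)
        Tukey = q(alpha, k, df_res) * sqrt(MS_res / n)
    """
    col = _FACTOR_COLUMNS.get(factor, factor)
    if col not in dataset.records.columns:
        raise ValidationError(f"factor {factor!r} not present in dataset")
    data = dataset.records.dropna(subset=[trait])
    means = data.groupby(col, observed=True)[trait].mean()
    counts = data.groupby(col, observed=True)[trait].count()
    k = len(means)
    if k < 2:
        raise ValidationError("post-hoc comparison requires >= 2 groups")
    if counts.nunique() != 1:
        raise UnbalancedDesignError("post-hoc requires balanced group sizes")
    n = int(counts.iloc[0])
    if anova is None:
        one_way = pd.DataFrame({col: data[col], trait: data[trait]})
        grand = one_way[trait].mean()
        group_mean = one_way.groupby(col, observed=True)[trait].transform("mean")
        ss_res = float(((one_way[trait] - group_mean) ** 2).sum())
        df_res = len(one_way) - k
        if df_res == 0:
            raise UnbalancedDesignError("residual degrees of freedom are zero")
        ms_res = ss_res / df_res
        del grand
    else:
        ms_res = anova.residual_ms
        df_res = anova.residual_df
    if method.upper() == "LSD":
        crit = stats.t.ppf(1 - alpha / 2, df_res) * np.sqrt(2 * ms_res / n)
    elif method.upper() in ("TUKEY", "TUKEYHSD", "HSD"):
        crit = stats.studentized_range.ppf(1 - alpha, k, df_res) * np.sqrt(
            ms_res / n
        )
    else:
        raise ValidationError(f"unknown post-hoc method {method!r}")
    mean_by = {str(g): float(v) for g, v in means.items()}
    rows = []
    sig_pairs: set[frozenset] = set()
    for g1, g2 in itertools.combinations(sorted(mean_by), 2):
        diff = mean_by[g1] - mean_by[g2]
        sig = bool(abs(diff) > crit)
        if sig:
            sig_pairs.add(frozenset((g1, g2)))
        rows.append({"group_1": g1, "group_2": g2, "difference": diff,
                     "critical_value": float(crit), "significant": sig})
    letters = _compact_letter_display(sorted(mean_by), mean_by, sig_pairs)
    return PostHocResult(
        method=method, alpha=alpha, critical_value=float(crit),
        pairs=pd.DataFrame(rows), letters=letters,
        means=means.rename("mean"),
    )


# ---------------------------------------------------------------------------
# direct balanced decomposition (group-mean algebra, no regression)

def balanced_decompose(df: pd.DataFrame, response: str,
                       terms: list[tuple[str, ...]]) -> dict[str, float]:
    """Sums of squares of a complete balanced factorial from cell means.

    Each term is a tuple of factor columns; the effect of a term at a cell
    is its cell mean minus the effects of every proper sub-term minus the
    grand mean, and its SS is the sum of squared per-record effects.  Also
    returns ``Residuals`` and ``Total`` (corrected).  Valid only for
    complete balanced layouts.
    """
    y = df[response].to_numpy(float)
    grand = y.mean()
    cache: dict[frozenset, np.ndarray] = {}

    def effect(cols: frozenset) -> np.ndarray:
        if cols in cache:
            return cache[cols]
        cell = df.groupby(list(cols), observed=True)[response].transform(
            "mean"
        ).to_numpy()
        e = cell - grand
        for size in range(1, len(cols)):
            for sub in itertools.combinations(sorted(cols), size):
                e = e - effect(frozenset(sub))
        cache[cols] = e
        return e

    out: dict[str, float] = {}
    for term in terms:
        out[":".join(term)] = float((effect(frozenset(term)) ** 2).sum())
    total = float(((y - grand) ** 2).sum())
    out["Residuals"] = total - sum(out[":".join(t)] for t in terms)
    out["Total"] = total
    return out


def render_anova_report(tables: dict[str, AnovaTable]) -> pd.DataFrame:
    """Wide report mirroring the classic layout: one row per term with df and
    the MS of every trait side by side."""
    first = next(iter(tables.values()))
    out = first.table[["term", "df"]].copy()
    for trait, tab in tables.items():
        out[f"MS_{trait}"] = tab.table["mean_sq"].to_numpy()
        out[f"sig_{trait}"] = tab.table["signif"].to_numpy()
    return out
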