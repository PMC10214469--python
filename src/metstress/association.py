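"""Per-environment trait associations: Pearson correlation matrices with
significance stars and single-predictor regressions of seed yield.

The unit of analysis is the genotype mean within an environment, pooled over
locations and years (n = number of genotypes); plot-level analysis is
available behind ``unit="plot"``.  Pairwise-complete deletion is used for
missing values and no multiple-testing correction is applied across pairs,
mirroring the usual star convention (* at 0.05, ** at 0.01).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import TrialDataset
from .exceptions import ValidationError


def _analysis_frame(dataset: TrialDataset, environment: str,
                    unit: str) -> pd.DataFrame:
    recs = dataset.records
    if environment not in set(recs["environment"]):
        raise ValidationError(
            f"environment {environment!r} not present in dataset"
        )
    sub = recs[recs["environment"] == environment]
    if unit == "genotype":
        return sub.groupby("genotype", observed=True)[
            list(dataset.traits)
        ].mean().reset_index()
    if unit == "plot":
        return sub[["genotype", *dataset.traits]].reset_index(drop=True)
    raise ValidationError(f"unknown analysis unit {unit!r}")


def star_code(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class CorrelationMatrix:
    environment: str
    r: pd.DataFrame
    p: pd.DataFrame
    codes: pd.DataFrame
    n: pd.DataFrame


def pearson_matrix(dataset: TrialDataset, environment: str,
                   unit: str = "genotype") -> CorrelationMatrix:
    """Pairwise-complete Pearson correlations among all traits within one
    environment, with two-sided t-test p-values (df = n - 2) and stars.

    A trait with zero variance has its pairs reported missing with a
    warning.
    """
    frame = _analysis_frame(dataset, environment, unit)
    traits = list(dataset.traits)
    k = len(traits)
    r = np.eye(k)
    p = np.full((k, k), np.nan)
    n_mat = np.zeros((k, k), dtype=int)
    degenerate = set()
    for i, j in itertools.combinations(range(k), 2):
        pair = frame[[traits[i], traits[j]]].dropna()
        n = len(pair)
        n_mat[i, j] = n_mat[j, i] = n
        if n < 3:
            r[i, j] = r[j, i] = np.nan
            continue
        x = pair.iloc[:, 0].to_numpy(float)
        y = pair.iloc[:, 1].to_numpy(float)
        if np.std(x) == 0 or np.std(y) == 0:
            degenerate.add(traits[i] if np.std(x) == 0 else traits[j])
            r[i, j] = r[j, i] = np.nan
            continue
        res = stats.pearsonr(x, y)
        r[i, j] = r[j, i] = res.statistic
        p[i, j] = p[j, i] = res.pvalue
    np.fill_diagonal(n_mat, [int(frame[t].notna().sum()) for t in traits])
    if degenerate:
        warnings.warn(
            f"zero-variance trait(s) {sorted(degenerate)}: their "
            "correlations are reported missing",
            stacklevel=2,
        )
    codes = np.empty((k, k), dtype=object)
    for i in range(k):
        for j in range(k):
            codes[i, j] = "" if i == j else star_code(p[i, j])
    idx = pd.Index(traits, name="trait")
    return CorrelationMatrix(
        environment=environment,
        r=pd.DataFrame(r, index=idx, columns=traits),
        p=pd.DataFrame(p, index=idx, columns=traits),
        codes=pd.DataFrame(codes, index=idx, columns=traits),
        n=pd.DataFrame(n_mat, index=idx, columns=traits),
    )


@dataclass
class RegressionResult:
    environment: str
    predictor: str
    slope: float
    intercept: float
    r_squared: float
    n: int


def regress_yield_on_trait(dataset: TrialDataset, environment: str,
                           predictor: str, response: str = "SY",
                           unit: str = "genotype") -> RegressionResult:
    """OLS of seed yield on one predictor trait at the correlation unit of
    analysis; R² equals the squared Pearson r of the pair."""
    if predictor not in dataset.traits:
        raise ValidationError(f"trait {predictor!r} not present in dataset")
    frame = _analysis_frame(dataset, environment, unit)
    pair = frame[[predictor, response]].dropna()
    x = pair[predictor].to_numpy(float)
    y = pair[response].to_numpy(float)
    if len(pair) < 3:
        raise ValidationError("need >= 3 observations for regression")
    if np.std(x) == 0:
        raise ValidationError(f"predictor {predictor} has zero variance")
    res = stats.linregress(x, y)
    return RegressionResult(
        environment=environment, predictor=predictor,
        slope=float(res.slope), intercept=float(res.intercept),
        r_squared=float(res.rvalue**2), n=len(pair),
    )


def rank_predictors(dataset: TrialDataset, environment: str,
                    response: str = "SY",
                    unit: str = "genotype") -> list[RegressionResult]:
    """All single-trait regressions of seed yield, ordered by R² descending
    (ties by trait code)."""
    predictors = [t for t in dataset.traits if t != response]
    if not predictors:
        raise ValidationError("no predictor traits available")
    results = [
        regress_yield_on_trait(dataset, environment, t, response, unit)
        for t in predictors
    ]
    return sorted(results, key=lambda r: (-r.r_squared, r.predictor))


def render_dual_triangle(upper: CorrelationMatrix,
                         lower: CorrelationMatrix) -> pd.DataFrame:
    """Two environments in one matrix: ``upper`` above the diagonal,
    ``lower`` below, each cell "r<stars>" (the published dual layout)."""
    traits = list(upper.r.columns)
    out = pd.DataFrame("", index=traits, columns=traits)
    for i, a in enumerate(traits):
        for j, b in enumerate(traits):
            if i == j:
                continue
            src = upper if i < j else lower
            r = src.r.loc[a, b]
            if np.isfinite(r):
                out.loc[a, b] = f"{r:.2f}{src.codes.loc[a, b]}"
    return out


def tidy_correlations(matrix: CorrelationMatrix) -> pd.DataFrame:
    """Long-format export: one row per unordered trait pair."""
    traits = list(matrix.r.columns)
    rows = []
    for a, b in itertools.combinations(traits, 2):
        rows.append({
            "environment": matrix.environment, "trait_1": a, "trait_2": b,
            "r": matrix.r.loc[a, b], "p": matrix.p.loc[a, b],
            "code": matrix.codes.loc[a, b], "n": matrix.n.loc[a, b],
        })
    return pd.DataFrame(rows)
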