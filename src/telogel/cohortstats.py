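"""Cohort-level statistics for telomere-length summaries.

Predictors enter models as *blocks*: a categorical block (island of
origin, Symbiodiniaceae community profile, bacterial community profile)
contributes all of its dummy columns together, a numeric block (colony
diameter) contributes one column.  On top of ordinary least squares this
module provides

* the log(TL) ~ colony-diameter model family (linear, quadratic,
  logarithmic) with lowest-AIC selection,
* an all-subsets R-squared map and its commonality decomposition into
  unique and common (shared) variance contributions per predictor subset
  (negative commonality coefficients indicate suppression), and
* pairwise Spearman/Pearson correlation matrices with Benjamini-Hochberg
  adjusted p-values.

AIC follows the R ``lm`` convention: the full Gaussian log-likelihood,
with the error variance counted as a parameter, so only differences are
meaningful but values line up with common statistical software.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ModelFit",
    "CommonalityResult",
    "CorrelationMatrix",
    "COHORT_COLUMNS",
    "validate_cohort",
    "ols_fit",
    "fit_tl_size_models",
    "aic_select",
    "all_subsets_r2",
    "commonality",
    "correlation_matrix",
    "bh_adjust",
]

AIC_PERFECT_FIT = -1.0e12  # sentinel replacing -inf when RSS == 0

COHORT_COLUMNS = [
    "colony_id", "island", "genus", "species",
    "symbiodiniaceae_profile", "bacteria_profile", "diameter_cm",
    "htl_mean_kb", "htl_med_kb", "htl_q1_kb", "htl_q3_kb", "htl_iq_kb",
    "stl_mean_kb", "stl_med_kb", "stl_q1_kb", "stl_q3_kb", "stl_iq_kb",
]


def validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Check the cohort CSV schema; returns the table unchanged."""
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    if table["colony_id"].duplicated().any():
        dup = table.loc[table["colony_id"].duplicated(), "colony_id"].iloc[0]
        raise ValueError(f"duplicated colony id: {dup!r}")
    tl_cols = [c for c in COHORT_COLUMNS if c.endswith("_kb") and not c.endswith("iq_kb")]
    for c in tl_cols:
        vals = pd.to_numeric(table[c], errors="coerce")
        if (vals.dropna() <= 0).any():
            raise ValueError(f"non-positive TL value in column {c}")
    return table


# ---------------------------------------------------------------------------
# design-matrix blocks
# ---------------------------------------------------------------------------

def _encode_block(name: str, values: pd.Series | np.ndarray) -> tuple[np.ndarray, list[str]]:
    """One predictor block -> design columns (dummies for categoricals)."""
    s = pd.Series(values).reset_index(drop=True)
    if s.dtype.kind in "biufc":
        return s.to_numpy(dtype=float).reshape(-1, 1), [name]
    levels = pd.unique(s.astype(str))
    if len(levels) < 2:
        raise ValueError(f"categorical block {name!r} has < 2 levels")
    dummies = pd.get_dummies(s.astype(str), prefix=name, drop_first=True)
    return dummies.to_numpy(dtype=float), list(dummies.columns)


def _design(blocks: Mapping[str, pd.Series | np.ndarray]) -> tuple[np.ndarray, list[str]]:
    cols, names = [], ["(intercept)"]
    n = None
    for name, values in blocks.items():
        X, colnames = _encode_block(name, values)
        if n is None:
            n = X.shape[0]
        elif X.shape[0] != n:
            raise ValueError("predictor blocks have unequal lengths")
        cols.append(X)
        names.extend(colnames)
    if n is None:
        raise ValueError("at least one predictor block required")
    X = np.column_stack([np.ones(n)] + cols)
    return X, names


@dataclass
class ModelFit:
    """An OLS fit: coefficients, fit statistics and an R-style Gaussian AIC."""

    formula: str
    coef: dict[str, float]
    r2: float
    adj_r2: float
    aic: float
    n: int
    df_resid: int
    k_params: int            # regression coefficients + 1 for the error variance
    rss: float
    pvalues: dict[str, float] = field(default_factory=dict)
    slope: Optional[float] = None
    slope_p: Optional[float] = None
    dropped_aliased: list[str] = field(default_factory=list)
    response_tag: int = 0    # fingerprint of the response vector for comparability

    def __post_init__(self) -> None:
        if not (-1e-10 <= self.r2 <= 1 + 1e-10):
            raise ValueError(f"R^2 out of range: {self.r2}")


def _response_tag(y: np.ndarray) -> int:
    return hash((y.size, float(np.round(y.sum(), 9)), float(np.round((y ** 2).sum(), 9))))


def ols_fit(
    response: np.ndarray | pd.Series,
    blocks: Mapping[str, pd.Series | np.ndarray],
    formula: str = "",
) -> ModelFit:
    """OLS of ``response`` on the concatenated predictor blocks plus intercept.

    Rank-deficient designs are handled by dropping aliased columns (pivoted
    QR) with a warning.  A constant response gets R^2 = 0 by convention; a
    perfect fit gets the sentinel AIC so it always wins model selection.
    """
    y = np.asarray(response, dtype=float)
    X, names = _design(blocks)
    n = y.size
    if X.shape[0] != n:
        raise ValueError("response and design lengths differ")

    # pivoted QR to detect and drop aliased columns
    from scipy.linalg import qr
    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    keep = np.sort(piv[:rank])
    dropped = [names[j] for j in piv[rank:]]
    if dropped:
        warnings.warn(f"dropping aliased design columns: {dropped}", stacklevel=2)
    Xk = X[:, keep]
    kept_names = [names[j] for j in keep]

    p = Xk.shape[1]
    if n <= p:
        raise ValueError(f"n={n} must exceed the {p} model parameters")
    beta, *_ = np.linalg.lstsq(Xk, y, rcond=None)
    resid = y - Xk @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 0.0 if tss == 0 else max(0.0, 1.0 - rss / tss)
    df_resid = n - p
    adj_r2 = r2 if tss == 0 else 1.0 - (1.0 - r2) * (n - 1) / df_resid

    k = p + 1  # + error variance
    if rss <= 1e-20 * max(tss, np.finfo(float).tiny):
        aic = AIC_PERFECT_FIT
    else:
        aic = n * np.log(2 * np.pi) + n * np.log(rss / n) + n + 2 * k

    pvalues: dict[str, float] = {}
    if df_resid > 0 and rss > 0:
        sigma2 = rss / df_resid
        xtx_inv = np.linalg.pinv(Xk.T @ Xk)
        se = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 0))
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = np.where(se > 0, beta / se, np.inf)
        pvalues = {
            name: float(2 * stats.t.sf(abs(t), df_resid))
            for name, t in zip(kept_names, tvals)
        }

    return ModelFit(
        formula=formula or " + ".join(blocks),
        coef=dict(zip(kept_names, map(float, beta))),
        r2=r2,
        adj_r2=min(adj_r2, r2),
        aic=float(aic),
        n=n,
        df_resid=df_resid,
        k_params=k,
        rss=rss,
        pvalues=pvalues,
        dropped_aliased=dropped,
        response_tag=_response_tag(y),
    )


# ---------------------------------------------------------------------------
# TL ~ colony size model family
# ---------------------------------------------------------------------------

def fit_tl_size_models(
    table: pd.DataFrame,
    response: str = "htl_mean_kb",
    genus: Optional[str] = None,
) -> list[ModelFit]:
    """Fit ln(TL) on diameter: linear, quadratic and logarithmic models.

    Rows with missing or non-positive diameter are dropped listwise for all
    three models so the AICs stay comparable; the number of dropped rows is
    recorded on each fit.
    """
    df = table
    if genus is not None:
        df = df[df["genus"] == genus]
    df = df[[response, "diameter_cm"]].apply(pd.to_numeric, errors="coerce").dropna()
    n_raw = len(df)
    df = df[(df["diameter_cm"] > 0) & (df[response] > 0)]
    n_dropped = n_raw - len(df)
    if len(df) < 10:
        raise ValueError(f"need >= 10 colonies with TL and diameter, got {len(df)}")
    y = np.log(df[response].to_numpy())
    d = df["diameter_cm"].to_numpy()

    fits = []
    linear = ols_fit(y, {"diameter": d}, formula=f"ln({response}) ~ diameter")
    linear.slope = linear.coef.get("diameter")
    linear.slope_p = linear.pvalues.get("diameter")
    fits.append(linear)

    quadratic = ols_fit(
        y, {"diameter": d, "diameter^2": d ** 2},
        formula=f"ln({response}) ~ diameter + diameter^2",
    )
    quadratic.slope = quadratic.coef.get("diameter")
    quadratic.slope_p = quadratic.pvalues.get("diameter")
    fits.append(quadratic)

    logarithmic = ols_fit(
        y, {"ln_diameter": np.log(d)}, formula=f"ln({response}) ~ ln(diameter)"
    )
    logarithmic.slope = logarithmic.coef.get("ln_diameter")
    logarithmic.slope_p = logarithmic.pvalues.get("ln_diameter")
    fits.append(logarithmic)

    for f in fits:
        f.dropped_aliased = f.dropped_aliased  # unchanged
        f.n_dropped_rows = n_dropped  # type: ignore[attr-defined]
    return fits


def aic_select(fits: Sequence[ModelFit]) -> ModelFit:
    """Lowest-AIC fit; ties break toward fewer parameters.

    Fits computed on different data subsets (different n or response
    values) are not comparable and are refused.
    """
    if not fits:
        raise ValueError("no fits to select from")
    tags = {(f.n, f.response_tag) for f in fits}
    if len(tags) > 1:
        raise ValueError("AIC values computed on different data subsets are not comparable")
    return min(fits, key=lambda f: (f.aic, f.k_params))


# ---------------------------------------------------------------------------
# commonality analysis
# ---------------------------------------------------------------------------

def all_subsets_r2(
    response: np.ndarray | pd.Series,
    blocks: Mapping[str, pd.Series | np.ndarray],
) -> dict[frozenset, float]:
    """R^2 of the OLS fit on every non-empty subset of predictor blocks."""
    names = list(blocks)
    if len(names) > 10:
        raise ValueError("more than 10 predictor blocks (2^p - 1 fits) not supported")
    out: dict[frozenset, float] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            sub = {k: blocks[k] for k in combo}
            out[frozenset(combo)] = ols_fit(response, sub).r2
    return out


@dataclass
class CommonalityResult:
    """Unique/common R^2 decomposition over all non-empty predictor subsets."""

    coefficients: dict[frozenset, float]
    total_r2: float
    predictors: tuple[str, ...]

    @property
    def percentages(self) -> dict[frozenset, float]:
        if self.total_r2 == 0:
            return {s: float("nan") for s in self.coefficients}
        return {s: 100.0 * c / self.total_r2 for s, c in self.coefficients.items()}

    def unique(self, predictor: str) -> float:
        return self.coefficients[frozenset([predictor])]

    def label(self, subset: frozenset) -> str:
        ordered = [p for p in self.predictors if p in subset]
        if len(ordered) == 1:
            return f"Unique to {ordered[0]}"
        return "Common to " + ", and ".join([", ".join(ordered[:-1]), ordered[-1]])

    def to_frame(self) -> pd.DataFrame:
        """Table mirroring the classic commonality layout plus a Total row."""
        rows = []
        pct = self.percentages
        subsets = sorted(self.coefficients, key=lambda s: (len(s), self.label(s)))
        for s in subsets:
            rows.append({
                "subset": self.label(s),
                "coefficient": self.coefficients[s],
                "percent_of_total": pct[s],
            })
        rows.append({
            "subset": "Total",
            "coefficient": self.total_r2,
            "percent_of_total": 100.0 if self.total_r2 else float("nan"),
        })
        return pd.DataFrame(rows, columns=["subset", "coefficient", "percent_of_total"])


def commonality(r2map: Mapping[frozenset, float]) -> CommonalityResult:
    """Solve for commonality coefficients from the all-subsets R^2 map.

    For every non-empty model M, ``R^2(M) = sum of C(S) over subsets S that
    intersect M``.  The 2^p - 1 equations have a unique solution; unique
    contributions satisfy ``unique(X) = R^2(full) - R^2(full minus X)``.
    """
    predictors = sorted({p for s in r2map for p in s})
    full = frozenset(predictors)
    subsets = [
        frozenset(c)
        for r in range(1, len(predictors) + 1)
        for c in itertools.combinations(predictors, r)
    ]
    missing = [s for s in subsets if s not in r2map]
    if missing:
        raise ValueError(f"r2map incomplete; missing subsets: {missing}")
    m = len(subsets)
    A = np.zeros((m, m))
    b = np.zeros(m)
    for i, M in enumerate(subsets):
        b[i] = r2map[M]
        for j, S in enumerate(subsets):
            if S & M:
                A[i, j] = 1.0
    coef = np.linalg.solve(A, b)
    resid = float(np.max(np.abs(A @ coef - b)))
    if resid > 1e-8:
        raise ValueError(f"inconsistent r2map: system residual {resid:.2e}")
    return CommonalityResult(
        coefficients={s: float(c) for s, c in zip(subsets, coef)},
        total_r2=float(r2map[full]),
        predictors=tuple(predictors),
    )


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (NaNs passed through)."""
    p = np.asarray(pvals, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


@dataclass
class CorrelationMatrix:
    method: str
    variables: tuple[str, ...]
    coef: pd.DataFrame
    pvalue: pd.DataFrame
    pvalue_adjusted: pd.DataFrame


def correlation_matrix(
    columns: pd.DataFrame,
    method: str = "spearman",
    min_pairs: int = 3,
) -> CorrelationMatrix:
    """Pairwise correlation matrix with BH-adjusted p-values.

    Pairs are complete-observation; cells with fewer than ``min_pairs``
    complete pairs or a constant column are recorded as missing (NaN),
    never as 0.  Adjustment pools the upper-triangle raw p-values.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown method {method!r}")
    cols = list(columns.columns)
    k = len(cols)
    coef = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    pval = pd.DataFrame(np.nan, index=cols, columns=cols)
    corr_fn = stats.spearmanr if method == "spearman" else stats.pearsonr
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            x = pd.to_numeric(columns[cols[i]], errors="coerce")
            y = pd.to_numeric(columns[cols[j]], errors="coerce")
            ok = x.notna() & y.notna()
            r, p = np.nan, np.nan
            if ok.sum() >= min_pairs:
                xv, yv = x[ok].to_numpy(), y[ok].to_numpy()
                if np.ptp(xv) > 0 and np.ptp(yv) > 0:
                    res = corr_fn(xv, yv)
                    r, p = float(res.statistic), float(res.pvalue)
            coef.iloc[i, j] = coef.iloc[j, i] = r
            pval.iloc[i, j] = pval.iloc[j, i] = p
            pairs.append((i, j, p))
    adj = pd.DataFrame(np.nan, index=cols, columns=cols)
    adj_vals = bh_adjust([p for _, _, p in pairs])
    for (i, j, _), a in zip(pairs, adj_vals):
        adj.iloc[i, j] = adj.iloc[j, i] = a
    return CorrelationMatrix(
        method=method,
        variables=tuple(cols),
        coef=coef,
        pvalue=pval,
        pvalue_adjusted=adj,
    )
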