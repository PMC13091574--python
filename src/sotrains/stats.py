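"""Statistical comparisons of ISOI distributions and density relationships.

Three in-scope procedures:

* a two-sample Kolmogorov–Smirnov test between ISOI distributions (D is the
  supremum ECDF distance, p from the asymptotic two-sample distribution);
* a log-normal shape fit of ISOI samples — maximum likelihood, i.e.
  μ = mean(log x) and σ = population SD(log x) — with a seeded nonparametric
  bootstrap percentile CI for the between-group shape difference Δσ; and
* ordinary least squares with interaction terms (e.g. mean-centered density ×
  group × dataset) on tidy per-subject tables, dummy-coding categorical terms
  against a configurable reference level.

Mixed beta/Dirichlet regressions of composite proportions are intentionally
not implemented here; :func:`export_for_stats` writes the tidy tables those
models consume in an external statistics environment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sample KS statistic and asymptotic p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class LognormalFit:
    mu: float
    sigma: float
    n: int


def lognormal_shape(intervals) -> LognormalFit:
    """ML log-normal fit: μ = mean of logs, σ = population SD of logs."""
    x = np.asarray(intervals, dtype=float)
    if x.size == 0:
        raise ValueError("empty interval sample")
    if np.any(x <= 0):
        raise ValueError("intervals must be strictly positive")
    logs = np.log(x)
    return LognormalFit(mu=float(logs.mean()), sigma=float(logs.std(ddof=0)),
                        n=int(x.size))


def delta_sigma_ci(
    intervals_a,
    intervals_b,
    B: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Δσ = σ_a − σ_b with a bootstrap percentile CI and two-sided p.

    Intervals are resampled with replacement within each group; p is the
    doubled bootstrap tail proportion of Δσ* crossing 0, floored at 1/B.
    """
    if B < 100:
        warnings.warn("fewer than 100 bootstrap repetitions gives a crude CI")
    a = np.asarray(intervals_a, dtype=float)
    b = np.asarray(intervals_b, dtype=float)
    d_obs = lognormal_shape(a).sigma - lognormal_shape(b).sigma
    rng = np.random.default_rng(seed)
    la, lb = np.log(a), np.log(b)
    boots = np.empty(B)
    for i in range(B):
        boots[i] = (la[rng.integers(0, la.size, la.size)].std(ddof=0)
                    - lb[rng.integers(0, lb.size, lb.size)].std(ddof=0))
    lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
    tail = min((boots <= 0).mean(), (boots >= 0).mean())
    p = max(2 * tail, 1.0 / B)
    return {"delta_sigma": float(d_obs), "ci": (float(lo), float(hi)),
            "p": float(min(p, 1.0)), "B": B}


@dataclass
class OlsResult:
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    r_squared: float
    df_resid: int

    def as_dict(self) -> dict:
        return {
            "coef": self.params.to_dict(),
            "se": self.bse.to_dict(),
            "t": self.tvalues.to_dict(),
            "p": self.pvalues.to_dict(),
            "r_squared": self.r_squared,
            "df_resid": self.df_resid,
        }


def _encode_column(col: pd.Series, reference: str | None) -> pd.Series:
    """Dummy-code a 2-level categorical column against a reference level."""
    levels = sorted(col.astype(str).unique())
    if len(levels) > 2:
        raise ValueError(f"column {col.name!r} has >2 levels; encode it upstream")
    ref = str(reference) if reference is not None else levels[0]
    return (col.astype(str) != ref).astype(float)


def ols_fit(
    table: pd.DataFrame,
    response: str,
    terms: list[str],
    center: list[str] | None = None,
    references: dict[str, str] | None = None,
) -> OlsResult:
    """Closed-form OLS with interaction terms written as ``a:b`` / ``a:b:c``.

    ``center`` columns are mean-centered before products are formed;
    ``references`` gives the reference level per categorical column (e.g.
    ``{"group": "elderly", "source": "observed"}``).
    """
    df = table.copy()
    references = references or {}
    for c in center or []:
        df[c] = df[c] - df[c].mean()

    def base(name: str) -> pd.Series:
        col = df[name]
        if col.dtype == object or str(col.dtype) == "category" or col.dtype == bool:
            return _encode_column(col, references.get(name))
        return col.astype(float)

    X = pd.DataFrame(index=df.index)
    for term in terms:
        parts = term.split(":")
        v = base(parts[0]).copy()
        for p in parts[1:]:
            v = v * base(p)
        X[term] = v
    X = sm.add_constant(X, prepend=True)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError("singular design matrix (rank-deficient after coding)")
    fit = sm.OLS(df[response].astype(float), X).fit()
    return OlsResult(params=fit.params, bse=fit.bse, tvalues=fit.tvalues,
                     pvalues=fit.pvalues, r_squared=float(fit.rsquared),
                     df_resid=int(fit.df_resid))


def export_for_stats(df: pd.DataFrame, path) -> None:
    """Write a tidy table for external mixed-model machinery (CSV)."""
    df.to_csv(path, index=False)
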