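"""Cohort-level statistics: paired and subgroup comparisons, progression
regressions, and logistic outcome models.

Conventions
-----------
* Wilcoxon signed-rank: zero differences are dropped (Wilcoxon's original
  rule) and their count reported; the exact null distribution (midranks,
  tie-tolerant, computed by characteristic-polynomial convolution) is used for
  up to 25 nonzero pairs, a tie-corrected normal approximation beyond.
* Mann-Whitney U: exact for min group size <= 8 without ties, tie-corrected
  normal approximation otherwise.
* All p-values are two-sided: 2 x min(lower tail, upper tail), capped at 1.
* Odds-ratio confidence intervals are Wald intervals on the log-odds scale.
* Favorable outcome = 90-day modified Rankin Scale 0-2; successful
  recanalization = mAOL score 3.  Complete-case analysis per model: rows
  missing any variable entering a given analysis are excluded and the
  resulting n is reported.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import DegenerateInputError, SeparationError

log = logging.getLogger(__name__)

FAVORABLE_MRS_MAX = 2
RECANALIZED_MAOL = 3
#: Table-4-style confounder set for the outcome models
DEFAULT_CONFOUNDERS = ["tilv_24h_per10", "age", "coumarins", "systolic_bp",
                       "baseline_nihss", "proximal_occlusion", "collaterals",
                       "evt_allocated"]


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n: tuple[int, ...]
    method: Literal["wilcoxon_signed_rank", "mann_whitney_u"]
    exact: bool = False
    n_zeros_dropped: int = 0


@dataclass
class RegressionResult:
    beta: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int


@dataclass
class OutcomeModel:
    """A fitted logistic model of favorable outcome.

    ``terms`` lists (name, odds ratio, 95% CI bounds, p) per predictor;
    ``params`` are the raw log-odds coefficients (incl. intercept).
    """

    terms: list[tuple[str, float, float, float, float]]
    aic: float
    n: int
    loglik: float = float("nan")
    params: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        df = pd.DataFrame(self.terms, columns=["term", "odds_ratio", "ci_low",
                                               "ci_high", "p_value"])
        df.attrs["aic"] = self.aic
        df.attrs["n"] = self.n
        return df


# ---------------------------------------------------------------------------
# Rank tests
# ---------------------------------------------------------------------------

def _exact_signed_rank_p(w_plus: float, ranks: np.ndarray) -> float:
    """Two-sided exact p for the signed-rank statistic given midranks.

    The null distribution of W+ = sum of ranks of positive differences under
    random signs is built by convolving (1 + z^{2r}) over the (doubled, hence
    integer) midranks.
    """
    r2 = np.rint(2.0 * ranks).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        nxt = dist.copy()
        nxt[r:] += dist[: total + 1 - r]
        dist = nxt
    dist /= dist.sum()
    w2 = int(np.rint(2.0 * w_plus))
    p_le = dist[: w2 + 1].sum()
    p_ge = dist[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def paired_wilcoxon(x_24h: Sequence[float], x_1week: Sequence[float],
                    exact_max_n: int = 25) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired per-patient values."""
    x = np.asarray(x_24h, dtype=float)
    y = np.asarray(x_1week, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"paired samples differ in length: {len(x)} vs {len(y)}")
    d = y - x
    nz = d[d != 0]
    n_zero = int(len(d) - len(nz))
    if n_zero:
        log.info("wilcoxon: dropped %d zero differences", n_zero)
    if len(nz) == 0:
        raise DegenerateInputError("all paired differences are zero")
    ranks = sps.rankdata(np.abs(nz))
    w_plus = float(ranks[nz > 0].sum())
    if len(nz) <= exact_max_n:
        p = _exact_signed_rank_p(w_plus, ranks)
        exact = True
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, p = sps.wilcoxon(nz, zero_method="wilcox", correction=False,
                                alternative="two-sided", method="approx")
        p = float(p)
        exact = False
    return TestResult(w_plus, p, (len(nz),), "wilcoxon_signed_rank",
                      exact=exact, n_zeros_dropped=n_zero)


def mann_whitney(a: Sequence[float], b: Sequence[float],
                 exact_max_n: int = 8) -> TestResult:
    """Two-sided Mann-Whitney U test between two independent groups."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise DegenerateInputError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    use_exact = min(len(a), len(b)) <= exact_max_n and not has_ties
    res = sps.mannwhitneyu(a, b, alternative="two-sided",
                           method="exact" if use_exact else "asymptotic")
    return TestResult(float(res.statistic), float(res.pvalue),
                      (len(a), len(b)), "mann_whitney_u", exact=use_exact)


# ---------------------------------------------------------------------------
# Regressions
# ---------------------------------------------------------------------------

def univariable_linear(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """OLS slope of y on x with a t-based 95% CI (n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    lo, hi = fit.conf_int(alpha=0.05)[1]
    return RegressionResult(float(fit.params[1]), float(lo), float(hi),
                            float(fit.pvalues[1]), int(fit.nobs))


def _prepare_outcome_frame(records: pd.DataFrame) -> pd.DataFrame:
    df = records.copy()
    if "favorable" not in df and "mrs_90d" in df:
        df["favorable"] = (df["mrs_90d"] <= FAVORABLE_MRS_MAX).where(
            df["mrs_90d"].notna()).astype(float)
    if "tilv_24h_per10" not in df and "tilv_24h" in df:
        df["tilv_24h_per10"] = df["tilv_24h"] / 10.0
    return df


def fit_outcome_model(records: pd.DataFrame,
                      progression_term: Literal["d_ev", "d_eciv"] = "d_ev",
                      confounders: Sequence[str] = (),
                      per_ml: float = 10.0) -> OutcomeModel:
    """Logistic regression of favorable 90-day outcome on lesion progression.

    The progression term is rescaled to ``per_ml`` millilitres before fitting,
    so its odds ratio reads "per ``per_ml`` ml of progression".  Confounders
    enter untransformed (collaterals as a single ordinal term).  Complete
    cases only.
    """
    if per_ml <= 0:
        raise ValueError("per_ml must be positive")
    df = _prepare_outcome_frame(records)
    if "favorable" not in df:
        raise ValueError("no outcome available: records lack an mrs_90d "
                         "(or favorable) column")
    term_col = f"{progression_term}_per{per_ml:g}ml"
    df[term_col] = df[progression_term] / per_ml
    cols = [term_col, *confounders, "favorable"]
    data = df[cols].dropna()
    n = len(data)
    yv = data["favorable"].to_numpy()
    if yv.min() == yv.max():
        raise DegenerateInputError("outcome is degenerate (single class)")
    X = data[[term_col, *confounders]].astype(float)
    for c in X.columns:
        if np.ptp(X[c].to_numpy()) == 0:
            raise ValueError(f"constant predictor: {c}")
    Xc = sm.add_constant(X)
    cond = np.linalg.cond(np.asarray(Xc, dtype=float))
    if cond > 1e6:
        warnings.warn(f"ill-conditioned design (condition number {cond:.2g}); "
                      "collinear confounders?", stacklevel=2)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(yv, Xc).fit(method="newton", maxiter=200,
                                       tol=1e-10, disp=0)
    except Exception as exc:  # statsmodels raises on perfect separation
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    fitted = fit.predict(Xc)
    if (np.any((fitted < 1e-8) | (fitted > 1 - 1e-8))
            and np.max(np.abs(fit.params)) > 50):
        raise SeparationError("separation detected: fitted probabilities at "
                              "0/1 with diverging coefficients")
    ci = fit.conf_int(alpha=0.05)
    terms = []
    for name in Xc.columns:
        if name == "const":
            continue
        terms.append((name, float(np.exp(fit.params[name])),
                      float(np.exp(ci.loc[name, 0])),
                      float(np.exp(ci.loc[name, 1])),
                      float(fit.pvalues[name])))
    return OutcomeModel(terms=terms, aic=float(fit.aic), n=n,
                        loglik=float(fit.llf),
                        params={k: float(v) for k, v in fit.params.items()})


def compare_models_aic(m1: OutcomeModel, m2: OutcomeModel) -> dict:
    """AICs of two outcome models fitted on the same records, and their difference."""
    if m1.n != m2.n:
        raise ValueError(f"models fitted on different n: {m1.n} vs {m2.n}")
    return {"aic_1": m1.aic, "aic_2": m2.aic, "delta_aic": m1.aic - m2.aic,
            "n": m1.n}


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def summarize_cohort(records: pd.DataFrame,
                     continuous: Sequence[str] = (),
                     categorical: Sequence[str] = ()) -> pd.DataFrame:
    """Median (IQR) for continuous variables, count (%) for categorical ones,
    with per-variable missing counts."""
    if len(records) == 0:
        raise ValueError("empty cohort")
    rows = []
    for v in continuous:
        x = records[v].astype(float)
        ok = x.dropna()
        q1, med, q3 = (np.percentile(ok, [25, 50, 75]) if len(ok)
                       else (np.nan,) * 3)
        rows.append({"variable": v, "kind": "continuous", "median": med,
                     "q1": q1, "q3": q3, "n_missing": int(x.isna().sum()),
                     "summary": f"{med:.3g} ({q1:.3g}-{q3:.3g})" if len(ok) else "NA"})
    for v in categorical:
        x = records[v]
        nmiss = int(x.isna().sum())
        counts = x.dropna().value_counts().sort_index()
        total = counts.sum()
        desc = "; ".join(f"{lvl}: {c} ({100 * c / total:.0f}%)"
                         for lvl, c in counts.items())
        rows.append({"variable": v, "kind": "categorical", "median": np.nan,
                     "q1": np.nan, "q3": np.nan, "n_missing": nmiss,
                     "summary": desc})
    return pd.DataFrame(rows)


def add_derived_columns(records: pd.DataFrame) -> pd.DataFrame:
    """Attach favorable-outcome and recanalization indicators (NaN-preserving)."""
    df = _prepare_outcome_frame(records)
    if "successful_recanalization" not in df and "maol" in df:
        df["successful_recanalization"] = (
            (df["maol"] == RECANALIZED_MAOL).where(df["maol"].notna())
        ).astype(float)
    return df
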