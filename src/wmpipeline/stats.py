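"""Statistical layer: paired comparisons, ROC discrimination, trend ANCOVA.

Conventions chosen to mirror a pROC/car-style workflow: empirical ROC with
midpoint thresholds and a Youden-optimal operating point (ties broken toward
the lower threshold), DeLong confidence intervals for the AUC, Type II sums
of squares for the categorical trend factor, and Pearson chi-square without
continuity correction for incidence tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "DegenerateInputError",
    "EmptyMaskError",
    "TissueSummary",
    "RocResult",
    "AncovaResult",
    "masked_mean",
    "paired_t",
    "cohen_d_pooled",
    "roc_discrimination",
    "logistic_univariate",
    "ancova_trend",
    "nested_f",
    "chi_square_incidence",
    "flag_outliers",
]


class DegenerateInputError(ValueError):
    """Input has no variability where the method requires some."""


class EmptyMaskError(ValueError):
    """An aggregation mask contains no voxels."""


@dataclass
class TissueSummary:
    """Per-subject, per-ROI aggregate of one biomarker."""

    subject: str
    label: str
    biomarker: str
    mean: float
    voxel_count: int

    def __post_init__(self) -> None:
        if self.voxel_count < 1:
            raise EmptyMaskError("a reported mean requires at least one voxel")


def masked_mean(volume, mask: np.ndarray, subject: str = "", label: str = "",
                biomarker: str = "") -> TissueSummary:
    """Arithmetic mean of map values over a binary mask."""
    data = volume.data if hasattr(volume, "data") else np.asarray(volume)
    mask = np.asarray(mask, dtype=bool)
    if data.shape != mask.shape:
        raise ValueError(f"map shape {data.shape} != mask shape {mask.shape}")
    count = int(mask.sum())
    if count == 0:
        raise EmptyMaskError(f"empty mask for ({subject}, {label}, {biomarker})")
    return TissueSummary(subject, label, biomarker, float(data[mask].mean()), count)


def paired_t(x, y) -> tuple[float, int, float]:
    """Classic two-sided paired t-test on the differences.  Returns (t, df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing pairs are not allowed")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        if np.allclose(d, 0):
            return 0.0, int(d.size - 1), 1.0
        raise DegenerateInputError("differences have zero variance")
    t = d.mean() / (sd / np.sqrt(d.size))
    df = d.size - 1
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), int(df), float(p)


def cohen_d_pooled(mean_x: float, sd_x: float, mean_y: float, sd_y: float) -> float:
    """Pooled-SD effect size d = (mean_x - mean_y) / sqrt((sd_x^2 + sd_y^2) / 2)."""
    if sd_x < 0 or sd_y < 0:
        raise ValueError("SDs must be non-negative")
    if sd_x == 0 and sd_y == 0:
        raise DegenerateInputError("both SDs are zero")
    return float((mean_x - mean_y) / np.sqrt((sd_x**2 + sd_y**2) / 2.0))


@dataclass
class RocResult:
    auc: float
    auc_ci: tuple[float, float]
    ci_level: float
    threshold: float
    sensitivity: float
    specificity: float
    accuracy: float
    direction: str  # "high": positive class takes larger values

    def __post_init__(self) -> None:
        lo, hi = self.auc_ci
        if not (0.0 <= self.auc <= 1.0 and lo <= self.auc <= hi):
            raise ValueError("inconsistent AUC / CI")


def _delong_ci(pos: np.ndarray, neg: np.ndarray, auc: float, level: float):
    """DeLong variance of the AUC from placement values."""
    # V10_i: fraction of negatives below positive i (ties count half)
    v10 = np.array([(np.sum(neg < p) + 0.5 * np.sum(neg == p)) / neg.size for p in pos])
    v01 = np.array([(np.sum(pos > n) + 0.5 * np.sum(pos == n)) / pos.size for n in neg])
    var = 0.0
    if pos.size > 1:
        var += v10.var(ddof=1) / pos.size
    if neg.size > 1:
        var += v01.var(ddof=1) / neg.size
    z = sps.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return max(0.0, auc - half), min(1.0, auc + half)


def roc_discrimination(values, labels, ci_level: float = 0.95) -> RocResult:
    """Empirical ROC analysis of a scalar marker against binary class labels.

    The AUC is the trapezoid-rule area, identical to the rank-sum
    (concordant + half-tied pair) statistic.  Candidate thresholds are the
    midpoints of consecutive sorted unique pooled values; the operating
    point maximises Youden's J with ties broken toward the lower threshold.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(int)
    if values.shape != labels.shape or values.ndim != 1:
        raise ValueError("values and labels must be 1-D and of equal length")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    pos = values[labels == 1]
    neg = values[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")

    def _rank_auc(p, n):
        # rank-sum AUC (== trapezoid area under the empirical ROC)
        ranks = sps.rankdata(np.concatenate([p, n]))
        return (ranks[: p.size].sum() - p.size * (p.size + 1) / 2.0) / (p.size * n.size)

    # direction "auto": orient so the AUC is >= 0.5
    direction = "high" if _rank_auc(pos, neg) >= 0.5 else "low"
    v = values if direction == "high" else -values
    p, n = (v[labels == 1], v[labels == 0])
    auc = _rank_auc(p, n)
    ci = _delong_ci(p, n, auc, ci_level)

    uniq = np.unique(v)
    if uniq.size < 2:
        raise DegenerateInputError("all observations share one value")
    cuts = 0.5 * (uniq[:-1] + uniq[1:])
    # vectorized sens/spec at every cut: predict positive when value > cut
    sens = 1.0 - np.searchsorted(np.sort(p), cuts, side="right") / p.size
    spec = np.searchsorted(np.sort(n), cuts, side="right") / n.size
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # first (lowest threshold) among ties
    thr = cuts[best]
    acc = (sens[best] * p.size + spec[best] * n.size) / (p.size + n.size)

    return RocResult(
        auc=float(auc),
        auc_ci=(float(ci[0]), float(ci[1])),
        ci_level=ci_level,
        threshold=float(thr if direction == "high" else -thr),
        sensitivity=float(sens[best]),
        specificity=float(spec[best]),
        accuracy=float(acc),
        direction=direction,
    )


def logistic_univariate(values, labels, tol: float = 1e-8, max_iter: int = 100):
    """Univariate logistic regression by iteratively reweighted least squares.

    Returns ``(intercept, slope, deviance, separated)`` where ``separated``
    flags complete separation (coefficients diverge; the ROC operating point
    remains valid).
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("labels must contain both classes")
    if np.unique(x).size < 2:
        raise DegenerateInputError("values are constant")

    separated = bool(x[y == 1].min() > x[y == 0].max() or x[y == 1].max() < x[y == 0].min())

    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    ll_old = -np.inf
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        wx = X * w[:, None]
        beta = np.linalg.solve(X.T @ wx, wx.T @ z)
        ll = float(np.sum(y * np.log(np.clip(mu, 1e-12, 1)) +
                          (1 - y) * np.log(np.clip(1 - mu, 1e-12, 1))))
        if abs(ll - ll_old) < tol:
            break
        ll_old = ll
    if abs(beta[1]) > 1e3:
        separated = True
    deviance = -2.0 * ll
    return float(beta[0]), float(beta[1]), float(deviance), separated


@dataclass
class AncovaResult:
    terms: dict[str, tuple[float, float]]  # term -> (F, p)
    r_squared: float
    df_resid: int
    model: object = field(repr=False, default=None)

    def __post_init__(self) -> None:
        for term, (f, _) in self.terms.items():
            if f < 0:
                raise ValueError(f"negative F for {term}")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("R^2 outside [0, 1]")


def ancova_trend(
    outcome,
    score,
    age=None,
    gender=None,
    vrf_block: pd.DataFrame | None = None,
) -> AncovaResult:
    """Linear model of an outcome on the ordinal severity score as a factor.

    Covariates (age, gender, optional risk-factor block) enter additively;
    the factor's F uses Type II sums of squares.  Constant covariates are
    dropped (they are collinear with the intercept), which makes the
    no-covariate case collapse exactly to one-way ANOVA.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    data = pd.DataFrame({"outcome": np.asarray(outcome, dtype=float),
                         "score": np.asarray(score)})
    groups = data.groupby("score").size()
    if (groups > 0).sum() < 2:
        raise ValueError("need at least two non-empty score groups")

    terms = ["C(score)"]
    if age is not None:
        data["age"] = np.asarray(age, dtype=float)
        if data["age"].nunique() > 1:
            terms.append("age")
        else:
            warnings.warn("age is constant; dropped from the model")
    if gender is not None:
        data["gender"] = np.asarray(gender)
        if data["gender"].nunique() > 1:
            terms.append("C(gender)")
        else:
            warnings.warn("gender is constant; dropped from the model")
    if vrf_block is not None:
        for col in vrf_block.columns:
            vals = np.asarray(vrf_block[col], dtype=float)
            name = f"vrf_{col}"
            data[name] = vals
            if data[name].nunique() > 1:
                terms.append(name)

    formula = "outcome ~ " + " + ".join(terms)
    fit = smf.ols(formula, data=data).fit()
    table = anova_lm(fit, typ=2)
    out_terms = {}
    for term in terms:
        key = "score" if term == "C(score)" else ("gender" if term == "C(gender)" else term)
        out_terms[key] = (float(table.loc[term, "F"]), float(table.loc[term, "PR(>F)"]))
    return AncovaResult(terms=out_terms, r_squared=float(fit.rsquared),
                        df_resid=int(fit.df_resid), model=fit)


def nested_f(model_small, model_big) -> tuple[float, int, int, float]:
    """F-test comparing two nested least-squares fits.

    Accepts fitted OLS results; verifies the small model's design space is a
    subspace of the big one.  Returns ``(F, df1, df2, p)``.
    """
    if model_small.nobs != model_big.nobs:
        raise ValueError("models were fit on different observation counts")
    Xs = np.asarray(model_small.model.exog)
    Xb = np.asarray(model_big.model.exog)
    proj, *_ = np.linalg.lstsq(Xb, Xs, rcond=None)
    if not np.allclose(Xb @ proj, Xs, atol=1e-6):
        raise ValueError("models are not nested")
    df1 = int(round(model_small.df_resid - model_big.df_resid))
    df2 = int(round(model_big.df_resid))
    rss_small = float(model_small.ssr)
    rss_big = float(model_big.ssr)
    if df1 == 0:
        return 0.0, 0, df2, 1.0
    f = ((rss_small - rss_big) / df1) / (rss_big / df2)
    f = max(f, 0.0)
    p = float(sps.f.sf(f, df1, df2))
    return float(f), df1, df2, p


def chi_square_incidence(table) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) on a contingency table."""
    table = np.asarray(table, dtype=float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal in contingency table")
    chi2, p, df, expected = sps.chi2_contingency(table, correction=False)
    if np.any(expected <= 0):
        raise ValueError("expected counts must be positive")
    return float(chi2), int(df), float(p)


def flag_outliers(summaries: pd.DataFrame, z_cut: float = 3.5) -> pd.DataFrame:
    """Flag per-biomarker robust outliers (median/MAD z-score) for review.

    Flagged rows are not dropped automatically; downstream callers decide.
    Falls back to a mean/SD z-score with a warning when the MAD is zero.
    """
    out = summaries.copy()
    out["robust_z"] = 0.0
    out["flagged"] = False
    for biomarker, group in out.groupby("biomarker"):
        x = group["mean"].to_numpy(dtype=float)
        if x.size < 10:
            raise ValueError(f"need >= 10 subjects per biomarker, got {x.size} for {biomarker}")
        med = np.median(x)
        mad = np.median(np.abs(x - med))
        if mad == 0:
            warnings.warn(f"MAD is zero for {biomarker}; falling back to SD z-score")
            sd = x.std(ddof=1)
            z = np.zeros_like(x) if sd == 0 else (x - x.mean()) / sd
        else:
            z = 0.6744897501960817 * (x - med) / mad
        out.loc[group.index, "robust_z"] = z
        out.loc[group.index, "flagged"] = np.abs(z) > z_cut
    return out
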