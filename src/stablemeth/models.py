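"""Per-probe differential methylation models.

The workhorse is :class:`ModeratedLinearModel`: ordinary least squares on
M values per probe with a shared design matrix, followed by
empirical-Bayes variance moderation. Probe variances s^2 are shrunk toward
a common prior fitted by moments on log s^2 (scaled inverse-chi-square
prior with d0 degrees of freedom and scale s0^2):

    s~^2 = (d0 * s0^2 + d * s^2) / (d0 + d)

and the moderated t statistic effect / (se * s~/s) is referred to a t
distribution with d + d0 degrees of freedom. The CD133-fraction contrast
uses :class:`BlockedAnovaModel`: a full model (class + block) against a
reduced model (block only), tested by the exact F statistic, which under
Gaussian errors is a monotone transform of the likelihood-ratio statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma

from .normalize import beta_to_m


# ---------------------------------------------------------------------------
# empirical-Bayes variance shrinkage

def trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1 - tri / x) / polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def _running_mean_trend(x: np.ndarray, y: np.ndarray,
                        frac: float = 0.3) -> np.ndarray:
    """Smooth y as a function of x with a centred running mean over the
    sorted x (deterministic lowess stand-in)."""
    order = np.argsort(x, kind="stable")
    n = len(x)
    w = max(int(frac * n), 5)
    cums = np.concatenate([[0.0], np.cumsum(y[order])])
    lo = np.maximum(np.arange(n) - w // 2, 0)
    hi = np.minimum(np.arange(n) + w // 2 + 1, n)
    smoothed = (cums[hi] - cums[lo]) / (hi - lo)
    out = np.empty(n)
    out[order] = smoothed
    return out


def fit_variance_prior(s2: np.ndarray, df: float,
                       covariate: np.ndarray | None = None
                       ) -> tuple[float, np.ndarray | float]:
    """Moment-match log s^2 against its scaled-F sampling distribution.

    Returns ``(d0, s0^2)``; ``d0`` is ``inf`` when the observed spread of
    log s^2 is no larger than the pure chi-square sampling spread (e.g. all
    variances equal). With ``covariate`` (typically the probe's mean M
    value) the prior scale follows a smooth trend in the covariate and only
    the spread around the trend is attributed to true variance
    heterogeneity.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.median(s2[ok])) if ok.any() else np.nan
    z = np.log(np.where(ok, s2, np.nan))
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    if covariate is not None:
        etrend = np.full(len(s2), np.nan)
        etrend[ok] = _running_mean_trend(np.asarray(covariate, float)[ok], e[ok])
        resid = e[ok] - etrend[ok]
    else:
        etrend = float(np.nanmean(e))
        resid = e[ok] - etrend
    evar = float(np.var(resid, ddof=1)) - float(polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_sq = np.exp(etrend + digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0_sq = np.exp(etrend)
    if covariate is not None:
        s0_sq = np.where(np.isfinite(s0_sq), s0_sq, np.nanmedian(s0_sq))
        return d0, s0_sq
    return d0, float(s0_sq)


def squeeze_variances(s2: np.ndarray, df: float,
                      prior_df: float | None = None,
                      covariate: np.ndarray | None = None
                      ) -> tuple[np.ndarray, float, np.ndarray | float]:
    """Shrink per-probe variances toward the fitted prior.

    ``prior_df`` overrides the fitted d0 (0 disables moderation). Returns
    ``(s2_post, d0, s0_sq)``.
    """
    s2 = np.asarray(s2, dtype=float)
    d0, s0_sq = fit_variance_prior(s2, df, covariate=covariate)
    if prior_df is not None:
        d0 = float(prior_df)
    if np.any(~np.isfinite(np.atleast_1d(s0_sq))) or np.any(np.atleast_1d(s0_sq) <= 0):
        warnings.warn("variance prior could not be estimated; "
                      "falling back to unmoderated variances")
        return s2.copy(), 0.0, np.nan
    if d0 == 0:
        return s2.copy(), 0.0, s0_sq
    if np.isinf(d0):
        return np.broadcast_to(np.asarray(s0_sq, float), s2.shape).copy(), d0, s0_sq
    post = (d0 * s0_sq + df * s2) / (d0 + df)
    return post, d0, s0_sq


# ---------------------------------------------------------------------------
# multiple testing

def bh_adjust(p) -> np.ndarray | pd.Series:
    """Benjamini–Hochberg step-up FDR adjustment, order-preserving."""
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1:
        raise ValueError("bh_adjust expects a 1-D vector")
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    n = len(arr)
    order = np.argsort(arr, kind="stable")
    ranked = arr[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    if isinstance(p, pd.Series):
        return pd.Series(q, index=p.index)
    return q


# ---------------------------------------------------------------------------
# design construction

TREATMENT_EFFECT = "treatment_effect"


@dataclass
class DesignSpec:
    """A contrast on the sample sheet: test level vs reference level of one
    factor, adjusting for covariates (e.g. cell line) and surrogates.

    With ``per_timepoint_effects`` the model spans every timepoint in one
    design — a timepoint main effect plus one treatment-effect column per
    timepoint (named ``treatment_effect_<tp>``) — so the residual variance
    is pooled across all samples while each timepoint keeps its own
    contrast. With ``timepoint`` set, the model is fitted on that
    timepoint's samples only and the single effect column is named
    ``treatment_effect``.
    """
    factor: str = "treatment"
    contrast: tuple[str, str] = ("TGFB", "control")   # (test, reference)
    covariates: tuple[str, ...] = ("cell_line",)
    timepoint: str | None = None
    per_timepoint_effects: bool = False

    def select_samples(self, sheet: pd.DataFrame) -> pd.DataFrame:
        sub = sheet
        if self.factor != "fraction" and "fraction" in sub.columns:
            sub = sub[sub["fraction"].fillna("") == ""]
        if self.timepoint is not None:
            sub = sub[sub["timepoint"] == self.timepoint]
        sub = sub[sub[self.factor].isin(self.contrast)]
        return sub

    def effect_name(self, timepoint: str | None = None) -> str:
        """Name of the design column holding the tested effect."""
        if self.per_timepoint_effects:
            if timepoint is None:
                raise ValueError("per-timepoint design needs a timepoint")
            return f"{TREATMENT_EFFECT}_{timepoint}"
        return TREATMENT_EFFECT

    def build(self, sheet: pd.DataFrame,
              surrogates: pd.DataFrame | None = None) -> pd.DataFrame:
        if self.per_timepoint_effects and self.timepoint is not None:
            raise ValueError("per_timepoint_effects is incompatible with "
                             "restricting the design to one timepoint")
        sub = self.select_samples(sheet)
        test, ref = self.contrast
        for level in (test, ref):
            if (sub[self.factor] == level).sum() < 2:
                raise ValueError(f"contrast level {level!r} has fewer than 2 samples")
        X = pd.DataFrame(index=sub.index)
        X["intercept"] = 1.0
        is_test = (sub[self.factor] == test).astype(float)
        if self.per_timepoint_effects:
            tps = sorted(sub["timepoint"].unique())
            for tp in tps[1:]:                       # timepoint main effects
                X[f"timepoint_{tp}"] = (sub["timepoint"] == tp).astype(float)
            for tp in tps:                           # one contrast per timepoint
                X[self.effect_name(tp)] = \
                    is_test * (sub["timepoint"] == tp).astype(float)
        else:
            X[TREATMENT_EFFECT] = is_test
        for cov in self.covariates:
            dummies = pd.get_dummies(sub[cov], prefix=cov, drop_first=True)
            for c in dummies.columns:
                X[c] = dummies[c].astype(float)
        if surrogates is not None and surrogates.shape[1] > 0:
            for c in surrogates.columns:
                X[c] = surrogates.loc[sub.index, c].astype(float)
        if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
            raise ValueError("design matrix is rank deficient")
        return X


def _ols_stats(Y: np.ndarray, X: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray, float]:
    """Vectorized OLS of each row of Y on X: (coefs, residual SS, resid df)."""
    n, p = X.shape
    Q, R = np.linalg.qr(X)
    coefs = np.linalg.solve(R, Q.T @ Y.T)          # p x probes
    fitted = X @ coefs
    resid = Y.T - fitted
    rss = np.sum(resid ** 2, axis=0)
    return coefs, rss, float(n - p)


# ---------------------------------------------------------------------------
# moderated linear model (Model / Results pair)

class ModeratedLinearModel:
    """Probe-wise linear model on M values with empirical-Bayes moderation.

    Parameters
    ----------
    m_values : DataFrame, probes x samples
    design : DataFrame, samples x terms (numeric, includes intercept)
    coef : name of the design column whose effect is tested
    """

    def __init__(self, m_values: pd.DataFrame, design: pd.DataFrame,
                 coef: str = TREATMENT_EFFECT):
        if not design.index.isin(m_values.columns).all():
            missing = design.index.difference(m_values.columns)
            raise ValueError(f"design rows absent from matrix: {list(missing[:5])}")
        if coef not in design.columns:
            raise ValueError(f"coefficient {coef!r} not in design")
        self.m = m_values[design.index]
        self.design = design
        self.coef = coef

    @classmethod
    def from_sample_sheet(cls, m_values: pd.DataFrame, sheet: pd.DataFrame,
                          spec: DesignSpec | None = None,
                          surrogates: pd.DataFrame | None = None,
                          timepoint: str | None = None
                          ) -> "ModeratedLinearModel":
        spec = spec or DesignSpec()
        X = spec.build(sheet.loc[sheet.index.intersection(m_values.columns)],
                       surrogates=surrogates)
        return cls(m_values, X, coef=spec.effect_name(timepoint)
                   if spec.per_timepoint_effects else TREATMENT_EFFECT)

    def fit(self, prior_df: float | None = None,
            trend: bool = False) -> "ModeratedLMResults":
        """Fit per-probe OLS and moderate the variances.

        With ``trend=True`` the prior scale s0^2 follows a smooth trend in
        each probe's mean M value instead of being a single constant, so
        probes in the low-variance middle of the mean-variance relationship
        are not penalized by the genome-wide average variance.
        """
        X = self.design.to_numpy(dtype=float)
        Y = self.m.to_numpy(dtype=float)
        coefs, rss, df_resid = self._check_df(X, Y)
        j = list(self.design.columns).index(self.coef)
        xtx_inv = np.linalg.inv(X.T @ X)
        cjj = xtx_inv[j, j]
        effect = coefs[j]
        s2 = rss / df_resid
        covariate = Y.mean(axis=1) if trend else None
        s2_post, d0, s0_sq = squeeze_variances(s2, df_resid, prior_df=prior_df,
                                               covariate=covariate)
        se = np.sqrt(cjj * s2_post)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, effect / se, 0.0)
        df_total = df_resid + (d0 if np.isfinite(d0) else 1e12)
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
        return ModeratedLMResults(
            model=self, probe_ids=self.m.index,
            effect=effect, stderr=se, s2=s2, s2_post=s2_post,
            t=t, p=p, q=bh_adjust(p),
            df_resid=df_resid, df_prior=d0, s2_prior=s0_sq)

    def _check_df(self, X, Y):
        n, p = X.shape
        if n - p < 1:
            raise ValueError(f"no residual degrees of freedom (n={n}, p={p})")
        return _ols_stats(Y, X)


@dataclass
class ModeratedLMResults:
    """Per-probe estimates from :class:`ModeratedLinearModel.fit`."""
    model: ModeratedLinearModel
    probe_ids: pd.Index
    effect: np.ndarray          # M-scale effect of the tested coefficient
    stderr: np.ndarray
    s2: np.ndarray              # residual variance
    s2_post: np.ndarray         # moderated variance
    t: np.ndarray
    p: np.ndarray
    q: np.ndarray
    df_resid: float
    df_prior: float
    s2_prior: float | np.ndarray       # scalar, or per-probe when trended
    delta_beta: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        """The DMP table: fixed column order, optionally with per-stratum deltas."""
        df = pd.DataFrame({
            "effect": self.effect, "stderr": self.stderr,
            "s2": self.s2, "s2_post": self.s2_post,
            "t": self.t, "p": self.p, "q": self.q,
        }, index=self.probe_ids)
        if self.delta_beta is not None:
            df = df.join(self.delta_beta)
        return df

    def significant(self, q_max: float = 0.05) -> pd.Index:
        return self.probe_ids[self.q < q_max]

    def summary(self, n_top: int = 10) -> str:
        lines = [
            "Moderated linear model results",
            "==============================",
            f"probes:            {len(self.probe_ids)}",
            f"residual df:       {self.df_resid:g}",
            f"prior df (d0):     {self.df_prior:g}",
            f"prior scale s0^2:  {float(np.mean(self.s2_prior)):.4g}"
            + (" (trended mean)" if np.ndim(self.s2_prior) else ""),
            f"probes q < 0.05:   {int((self.q < 0.05).sum())}",
            "",
            f"top {n_top} probes by q:",
        ]
        top = self.to_frame().nsmallest(n_top, "q")
        lines.append(top[["effect", "t", "p", "q"]].to_string(float_format="%.3g"))
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# blocked ANOVA (randomized-block class comparison)

class BlockedAnovaModel:
    """Class comparison with a blocking factor absorbed by both models.

    Full model: class + block. Reduced model: block only. The per-probe F
    statistic [(SSE_r - SSE_f)/q_diff] / [SSE_f/(n - p_f)] is referred to
    the exact F distribution; under Gaussian errors this is equivalent to
    the likelihood-ratio test of the class term.
    """

    def __init__(self, m_values: pd.DataFrame, classes: pd.Series,
                 blocks: pd.Series):
        classes = classes.loc[m_values.columns]
        blocks = blocks.loc[m_values.columns]
        for blk, grp in classes.groupby(blocks):
            if grp.nunique() < 2:
                raise ValueError(f"block {blk!r} does not contain both classes")
        self.m = m_values
        self.classes = classes
        self.blocks = blocks

    def _design(self, with_class: bool) -> np.ndarray:
        parts = [np.ones((len(self.classes), 1))]
        bd = pd.get_dummies(self.blocks, drop_first=True).to_numpy(dtype=float)
        parts.append(bd)
        if with_class:
            cd = pd.get_dummies(self.classes, drop_first=True).to_numpy(dtype=float)
            parts.append(cd)
        return np.hstack(parts)

    def fit(self) -> "BlockedAnovaResults":
        Y = self.m.to_numpy(dtype=float)
        X_full = self._design(with_class=True)
        X_red = self._design(with_class=False)
        _, rss_full, df_full = _ols_stats(Y, X_full)
        _, rss_red, _ = _ols_stats(Y, X_red)
        q_diff = X_full.shape[1] - X_red.shape[1]
        if df_full < 1:
            raise ValueError("no residual degrees of freedom in the full model")
        with np.errstate(divide="ignore", invalid="ignore"):
            F = ((rss_red - rss_full) / q_diff) / (rss_full / df_full)
        F = np.where(np.isfinite(F), np.maximum(F, 0.0), 0.0)
        p = stats.f.sf(F, q_diff, df_full)
        n = Y.shape[1]
        with np.errstate(divide="ignore", invalid="ignore"):
            lrt = n * np.log(np.where(rss_full > 0, rss_red / rss_full, 1.0))
        return BlockedAnovaResults(probe_ids=self.m.index, F=F, p=p, lrt=lrt,
                                   df_num=q_diff, df_den=df_full)


@dataclass
class BlockedAnovaResults:
    probe_ids: pd.Index
    F: np.ndarray
    p: np.ndarray
    lrt: np.ndarray            # Gaussian LRT statistic n*log(SSE_r/SSE_f)
    df_num: int
    df_den: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"F": self.F, "p": self.p, "lrt": self.lrt},
                            index=self.probe_ids)

    def summary(self) -> str:
        return "\n".join([
            "Randomized-block class comparison",
            "=================================",
            f"probes:        {len(self.probe_ids)}",
            f"F df:          ({self.df_num}, {self.df_den:g})",
            f"probes p<1e-3: {int((self.p < 1e-3).sum())}",
        ])


# ---------------------------------------------------------------------------
# surrogate variables

def estimate_surrogates(m_values: pd.DataFrame, design: pd.DataFrame,
                        max_k: int = 5, seed: int = 0, n_perm: int = 20,
                        quantile: float = 0.95) -> pd.DataFrame:
    """Data-driven covariates for unmodeled structure (batch effects).

    M values are residualized on the design; the top principal components
    of the residual matrix are retained while their eigenvalues exceed the
    ``quantile`` of the corresponding eigenvalues from residuals whose rows
    are independently permuted (parallel analysis, ``n_perm`` permutations).
    """
    if max_k <= 0:
        return pd.DataFrame(index=design.index)
    X = design.to_numpy(dtype=float)
    Y = m_values[design.index].to_numpy(dtype=float)
    Q, _ = np.linalg.qr(X)
    resid = Y - (Y @ Q) @ Q.T                     # probes x samples, row-wise residuals
    if float(np.abs(resid).max(initial=0.0)) < 1e-12:
        warnings.warn("residuals are numerically zero; returning no surrogates")
        return pd.DataFrame(index=design.index)

    def eigvals(mat: np.ndarray) -> np.ndarray:
        s = np.linalg.svd(mat, compute_uv=False)
        return s ** 2

    obs = eigvals(resid)
    rng = np.random.default_rng(seed)
    perm_eigs = np.empty((n_perm, len(obs)))
    row_norm = np.linalg.norm(resid, axis=1, keepdims=True)
    for b in range(n_perm):
        idx = np.argsort(rng.random(resid.shape), axis=1)
        shuffled = np.take_along_axis(resid, idx, axis=1)
        # permuted rows leave the residual subspace; re-project and restore
        # each row's norm so the null spectrum carries the same energy
        shuffled = shuffled - (shuffled @ Q) @ Q.T
        norms = np.linalg.norm(shuffled, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        shuffled *= row_norm / norms
        perm_eigs[b] = eigvals(shuffled)
    thresh = np.quantile(perm_eigs, quantile, axis=0)
    k = 0
    for j in range(min(max_k, len(obs))):
        if obs[j] > thresh[j]:
            k += 1
        else:
            break
    if k == 0:
        return pd.DataFrame(index=design.index)
    _, _, vt = np.linalg.svd(resid, full_matrices=False)
    sv = pd.DataFrame(vt[:k].T, index=design.index,
                      columns=[f"sv{i + 1}" for i in range(k)])
    return sv


# ---------------------------------------------------------------------------
# group delta-beta

def group_delta_beta(beta: pd.DataFrame, sheet: pd.DataFrame,
                     factor: str = "treatment",
                     contrast: tuple[str, str] = ("TGFB", "control"),
                     stratify_by: tuple[str, ...] = ("cell_line", "timepoint")
                     ) -> pd.DataFrame:
    """Per-probe mean(beta | test) - mean(beta | reference), per stratum.

    Computed on normalized betas (not M values). Returns one column per
    stratum (named by the joined stratum levels) plus ``overall``.
    """
    test, ref = contrast
    sheet = sheet.loc[beta.columns]
    if factor != "fraction" and "fraction" in sheet.columns:
        keep = sheet["fraction"].fillna("") == ""
        sheet = sheet[keep]
        beta = beta[sheet.index]
    out = {}
    strata = sheet.groupby(list(stratify_by), sort=True) if stratify_by \
        else [((), sheet)]
    for key, grp in strata:
        if not isinstance(key, tuple):
            key = (key,)
        name = "_".join(str(k) for k in key) if key else "all"
        t_ids = grp.index[grp[factor] == test]
        r_ids = grp.index[grp[factor] == ref]
        if len(t_ids) == 0 or len(r_ids) == 0:
            raise ValueError(f"stratum {name!r} lacks samples for one contrast group")
        out[name] = beta[t_ids].mean(axis=1) - beta[r_ids].mean(axis=1)
    table = pd.DataFrame(out, index=beta.index)
    t_ids = sheet.index[sheet[factor] == test]
    r_ids = sheet.index[sheet[factor] == ref]
    table["overall"] = beta[t_ids].mean(axis=1) - beta[r_ids].mean(axis=1)
    return table


def m_matrix(beta: pd.DataFrame, eps: float = 0.001) -> pd.DataFrame:
    """Convenience: the M-value matrix for modeling."""
    return beta_to_m(beta, eps=eps)
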