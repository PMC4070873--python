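"""Probe-chemistry bias correction by beta-mixture quantile matching.

Infinium arrays mix two probe chemistries whose beta-value distributions
differ: type II values are compressed toward 0.5. Per sample, a
three-component beta mixture (unmethylated / hemimethylated / methylated
states) is fitted by EM to the type I and to the type II probes
separately; type II values are then remapped onto the type I reference by
state-wise beta-mixture quantile matching — parametric CDF transforms for
the unmethylated and methylated states and an endpoint-anchored dilation
for the hemimethylated state — leaving type I values untouched. The
composed map is continuous and monotone in the input, so probes near a
state boundary are not torn apart across samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import betaln, digamma, polygamma

_EPS = 1e-6


@dataclass
class BetaMixtureFit:
    """Three-state beta mixture: shapes[k] = (a_k, b_k), ordered by mean."""
    shapes: np.ndarray                      # (3, 2)
    weights: np.ndarray                     # (3,)
    loglik_trace: list = field(default_factory=list)
    converged: bool = False

    def log_density(self, x: np.ndarray) -> np.ndarray:
        """(n, 3) log of weight_k * f_k(x)."""
        x = np.clip(x, _EPS, 1 - _EPS)
        out = np.empty((len(x), 3))
        for k in range(3):
            a, b = self.shapes[k]
            out[:, k] = (np.log(self.weights[k])
                         + (a - 1) * np.log(x) + (b - 1) * np.log1p(-x)
                         - betaln(a, b))
        return out

    def loglik(self, x: np.ndarray) -> float:
        ld = self.log_density(x)
        mx = ld.max(axis=1)
        return float(np.sum(mx + np.log(np.exp(ld - mx[:, None]).sum(axis=1))))

    def state_thresholds(self, grid_size: int = 2001) -> tuple[float, float]:
        """Beta-value cutpoints between states, from the maximum-posterior
        assignment on a grid; forces the three states onto ordered intervals."""
        u = np.linspace(_EPS, 1 - _EPS, grid_size)
        state = self.log_density(u).argmax(axis=1)
        i1 = int(np.argmax(state >= 1)) if (state >= 1).any() else grid_size
        i2 = int(np.argmax(state == 2)) if (state == 2).any() else grid_size
        t1 = u[i1 - 1] if 0 < i1 < grid_size else (0.25 if i1 == 0 else 1.0)
        t2 = u[i2 - 1] if 0 < i2 < grid_size else (0.75 if i2 == 0 else 1.0)
        return min(t1, t2), max(t1, t2)


def _beta_obj(a: float, b: float, s1: float, s2: float, n: float) -> float:
    return n * (-betaln(a, b)) + (a - 1) * s1 + (b - 1) * s2


# semantic mean ranges of the three methylation states; constraining each
# component to its range keeps the state segmentation comparable across
# samples even when a sample has extra local structure (e.g. a treated
# sample's shifted probes forming a bump near one mode)
_STATE_MEAN_RANGE = ((0.0, 0.4), (0.3, 0.7), (0.6, 1.0))
_STATE_SHAPE_MIN = (1e-2, 1.0, 1e-2)     # hemi stays interior-unimodal


def _project_state(a: float, b: float, state: int) -> tuple[float, float]:
    """Project shapes onto the state's admissible region (mean range and
    minimum shape), preserving the concentration a+b."""
    smin = _STATE_SHAPE_MIN[state]
    lo, hi = _STATE_MEAN_RANGE[state]
    a = min(max(a, smin), 1e4)
    b = min(max(b, smin), 1e4)
    mean = a / (a + b)
    if not lo <= mean <= hi:
        m = min(max(mean, lo), hi)
        s = a + b
        a = max(m * s, smin)
        b = max((1 - m) * s, smin)
    return a, b


def _weighted_beta_mle(s_logx: float, s_log1mx: float, n: float,
                       start: np.ndarray, state: int = 1
                       ) -> tuple[np.ndarray, float]:
    """Maximize the weighted beta log-likelihood given sufficient statistics.

    Damped projected Newton on the two shape parameters; every accepted
    step increases the objective, so using this as the M step keeps EM
    monotone, and every iterate respects the state's mean-range constraint.
    """
    a, b = _project_state(float(start[0]), float(start[1]), state)
    best = _beta_obj(a, b, s_logx, s_log1mx, n)
    for _ in range(40):
        psi_ab = digamma(a + b)
        ga = n * (psi_ab - digamma(a)) + s_logx
        gb = n * (psi_ab - digamma(b)) + s_log1mx
        tri_ab = polygamma(1, a + b)
        haa = n * (tri_ab - polygamma(1, a))
        hbb = n * (tri_ab - polygamma(1, b))
        hab = n * tri_ab
        det = haa * hbb - hab * hab
        if not np.isfinite(det) or abs(det) < 1e-300:
            break
        da = -(hbb * ga - hab * gb) / det
        db = -(haa * gb - hab * ga) / det
        step = 1.0
        improved = False
        for _ in range(20):
            na, nb = _project_state(a + step * da, b + step * db, state)
            obj = _beta_obj(na, nb, s_logx, s_log1mx, n)
            if obj > best:
                a, b, best = na, nb, obj
                improved = True
                break
            step *= 0.5
        if not improved or max(abs(da), abs(db)) < 1e-8 * (1 + max(a, b)):
            break
    return np.array([a, b]), best


def _moment_shapes(x: np.ndarray) -> np.ndarray:
    m, v = float(np.mean(x)), float(np.var(x))
    v = max(v, 1e-6)
    common = max(m * (1 - m) / v - 1, 0.1)
    return np.array([max(m * common, 1e-2), max((1 - m) * common, 1e-2)])


def fit_beta_mixture(x: np.ndarray, tol: float = 1e-6, max_iter: int = 500
                     ) -> BetaMixtureFit:
    """Generalized EM for a three-component beta mixture.

    Initialization thresholds the data at 0.25/0.75 into the three
    methylation states (deterministic). The M step maximizes the weighted
    beta likelihood per component from its sufficient statistics; a step
    that would lower the component objective is rejected, so the observed
    log-likelihood is non-decreasing.
    """
    x = np.clip(np.asarray(x, dtype=float), _EPS, 1 - _EPS)
    if len(x) < 30:
        raise ValueError("need at least 30 values to fit the beta mixture")
    groups = [x[x <= 0.25], x[(x > 0.25) & (x <= 0.75)], x[x > 0.75]]
    shapes = np.empty((3, 2))
    weights = np.empty(3)
    for k, g in enumerate(groups):
        if len(g) < 5:        # degenerate state: seed a broad prior-like component
            centers = (0.1, 0.5, 0.9)
            shapes[k] = _moment_shapes(np.array([centers[k] - 0.05, centers[k] + 0.05]))
            weights[k] = 1.0 / len(x)
        else:
            shapes[k] = _moment_shapes(g)
            weights[k] = len(g) / len(x)
        shapes[k] = _project_state(shapes[k][0], shapes[k][1], k)
    weights /= weights.sum()
    fit = BetaMixtureFit(shapes=shapes, weights=weights)

    logx, log1mx = np.log(x), np.log1p(-x)
    prev = -np.inf
    for _ in range(max_iter):
        ld = fit.log_density(x)
        mx = ld.max(axis=1)
        lse = mx + np.log(np.exp(ld - mx[:, None]).sum(axis=1))
        ll = float(lse.sum())
        fit.loglik_trace.append(ll)
        if ll - prev < tol * abs(prev) and np.isfinite(prev):
            fit.converged = True
            break
        prev = ll
        resp = np.exp(ld - lse[:, None])                      # E step
        nk = resp.sum(axis=0)
        fit.weights = np.maximum(nk, 1e-10) / len(x)
        fit.weights /= fit.weights.sum()
        for k in range(3):                                    # M step (ascent or keep)
            s1 = float(resp[:, k] @ logx)
            s2 = float(resp[:, k] @ log1mx)
            old = fit.shapes[k].copy()
            old_obj = (nk[k] * (-betaln(*old)) + (old[0] - 1) * s1 + (old[1] - 1) * s2)
            new, new_obj = _weighted_beta_mle(s1, s2, nk[k], old, state=k)
            if new_obj >= old_obj:
                fit.shapes[k] = new
    # keep components ordered by mean so state 0/1/2 = un/hemi/methylated
    means = fit.shapes[:, 0] / fit.shapes.sum(axis=1)
    order = np.argsort(means)
    fit.shapes = fit.shapes[order]
    fit.weights = fit.weights[order]
    return fit


def _state_split(values: np.ndarray, thresholds: tuple[float, float]) -> np.ndarray:
    t1, t2 = thresholds
    return np.where(values <= t1, 0, np.where(values <= t2, 1, 2))


def _map_type2_states(src: np.ndarray, ref: np.ndarray,
                      th2: tuple[float, float], th1: tuple[float, float]
                      ) -> np.ndarray:
    """State-wise beta-mixture quantile map of type II values onto type I.

    Each state interval of the type II scale is mapped onto the matching
    type I state interval by empirical quantile matching (linear
    interpolation between empirical quantiles), with the interpolation
    knots anchored at the state-interval endpoints. Every piece is
    monotone and pinned to the shared thresholds, so the composed map is
    continuous and monotone in x — a probe near a state boundary maps to
    nearly the same value whichever side it falls on, instead of jumping
    across the type I state gap. An empty reference state falls back to
    the linear interval map.
    """
    t1_2, t2_2 = th2
    t1_1, t2_1 = th1
    # state intervals on each scale, [lo, hi] per state
    iv2 = ((0.0, t1_2), (t1_2, t2_2), (t2_2, 1.0))
    iv1 = ((0.0, t1_1), (t1_1, t2_1), (t2_1, 1.0))
    states = _state_split(src, (t1_2, t2_2))
    ref_states = _state_split(ref, (t1_1, t2_1))
    mapped = np.empty_like(src)
    for k in range(3):
        mask = states == k
        if not mask.any():
            continue
        lo2, hi2 = iv2[k]
        lo1, hi1 = iv1[k]
        s = src[mask]
        t = np.sort(ref[ref_states == k])
        if len(t) < 2 or hi2 <= lo2 or hi1 <= lo1:
            # no usable reference: linear dilation between the thresholds
            mapped[mask] = lo1 + (s - lo2) * (hi1 - lo1) / max(hi2 - lo2, _EPS)
            continue
        # empirical quantile of each source value within its state ...
        order = np.argsort(s, kind="stable")
        ranks = np.empty(len(s))
        ranks[order] = np.arange(1, len(s) + 1)
        p = ranks / (len(s) + 1)
        # ... matched to the reference state's quantile function, whose
        # knots are the reference values at plotting positions r/(n+1)
        # plus the interval endpoints at p = 0 and p = 1
        tp = np.concatenate([[0.0], np.arange(1, len(t) + 1) / (len(t) + 1), [1.0]])
        tv = np.concatenate([[lo1], np.clip(t, lo1, hi1), [hi1]])
        mapped[mask] = np.interp(p, tp, tv)
    return np.clip(mapped, _EPS, 1 - _EPS)


def probe_type_correct(beta: pd.DataFrame, manifest: pd.DataFrame,
                       tol: float = 1e-6, max_iter: int = 500
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample correction of type II probe betas onto the type I reference.

    Returns the corrected matrix and a per-sample diagnostics table
    (converged flags, iteration counts, state thresholds). A sample whose
    EM fails to converge is left uncorrected (identity transform) and
    flagged.
    """
    ptype = manifest.reindex(beta.index)["probe_type"]
    is1 = (ptype == "I").to_numpy()
    is2 = (ptype == "II").to_numpy()
    if not is1.any() or not is2.any():
        raise ValueError("probe_type_correct requires both probe chemistries")

    out = beta.copy()
    diag = []
    for col in beta.columns:
        v = beta[col].to_numpy(dtype=float)
        fit1 = fit_beta_mixture(v[is1], tol=tol, max_iter=max_iter)
        fit2 = fit_beta_mixture(v[is2], tol=tol, max_iter=max_iter)
        row = {"sample_id": col,
               "converged_I": fit1.converged, "converged_II": fit2.converged,
               "iters_I": len(fit1.loglik_trace), "iters_II": len(fit2.loglik_trace)}
        if not (fit1.converged and fit2.converged):
            warnings.warn(f"EM did not converge for sample {col!r}; "
                          f"leaving its type II probes uncorrected")
            row.update(t1_I=np.nan, t2_I=np.nan, t1_II=np.nan, t2_II=np.nan)
            diag.append(row)
            continue
        th1 = fit1.state_thresholds()
        th2 = fit2.state_thresholds()
        row.update(t1_I=th1[0], t2_I=th1[1], t1_II=th2[0], t2_II=th2[1])
        diag.append(row)

        full = v.copy()
        full[is2] = _map_type2_states(v[is2], v[is1], th2, th1)
        out[col] = full
    return out, pd.DataFrame(diag).set_index("sample_id")
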