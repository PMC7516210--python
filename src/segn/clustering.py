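"""Functional clustering of transcriptional-plasticity curves.

Genes are grouped into modules by a finite mixture over whole time courses.
The default emission treats the rounded plasticity value at each time as a
Skellam variable — the difference of two Poisson counts with time-varying
intensities mu1(t), mu2(t) — so the module mean curve is mu1(t) - mu2(t).
Each intensity curve is a Legendre polynomial in mapped time passed through
a softplus link to stay positive.  A Gaussian emission is available for
plasticity values that are not count-like.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .lop import LopCurve, fit_lop_curve, legendre_basis, AffineMap
from .plasticity import PlasticitySeries

__all__ = ["skellam_logpmf", "SkellamParams", "ModulePartition", "em_cluster", "select_module_count"]

_MU_FLOOR = 1e-8


def skellam_logpmf(k, mu1, mu2):
    """log P(N1 - N2 = k) for independent N1~Poisson(mu1), N2~Poisson(mu2).

    Evaluated through the exponentially scaled modified Bessel function,
    log pmf = -(mu1+mu2) + (k/2) log(mu1/mu2) + 2 sqrt(mu1 mu2)
              + log ive(|k|, 2 sqrt(mu1 mu2)),
    which is stable across the intensity range.  Intensities must be
    positive.
    """
    k = np.asarray(k)
    mu1 = np.asarray(mu1, dtype=float)
    mu2 = np.asarray(mu2, dtype=float)
    if np.any(mu1 <= 0) or np.any(mu2 <= 0):
        raise ValueError("Skellam intensities must be positive")
    root = 2.0 * np.sqrt(mu1 * mu2)
    with np.errstate(divide="ignore"):
        out = (-(mu1 + mu2) + (k / 2.0) * (np.log(mu1) - np.log(mu2))
               + root + np.log(special.ive(np.abs(k), root)))
    return out


def _softplus(x):
    return np.logaddexp(0.0, x)


def _softplus_inv(y):
    y = np.maximum(y, 1e-10)
    return y + np.log1p(-np.exp(-y))


@dataclass
class SkellamParams:
    """One module's intensity curves: mu_c(t) = softplus(LOP_c(t)) + floor."""

    beta1: np.ndarray
    beta2: np.ndarray
    domain: tuple[float, float]

    def intensities(self, times):
        m = AffineMap(*self.domain)
        B = legendre_basis(m(times), len(self.beta1) - 1)
        return (_softplus(B @ self.beta1) + _MU_FLOOR,
                _softplus(B @ self.beta2) + _MU_FLOOR)

    def mean_curve(self, times):
        mu1, mu2 = self.intensities(times)
        return mu1 - mu2


@dataclass
class ModulePartition:
    """Result of mixture clustering: weights, module parameters, posteriors."""

    n_modules: int
    weights: np.ndarray
    params: list          # SkellamParams, or (LopCurve, sigma2) for gaussian
    posterior: np.ndarray
    labels: np.ndarray
    log_likelihood: float
    aic: float
    gene_ids: list[str]
    emission: str = "skellam"
    loglik_trace: list[float] | None = None   # winning restart's EM path

    def module_mean_curve(self, module: int, times):
        if self.emission == "skellam":
            return self.params[module].mean_curve(times)
        return self.params[module][0](times)

    def assignments(self) -> dict[str, int]:
        return dict(zip(self.gene_ids, (int(l) for l in self.labels)))


def _n_free_params(L: int, lop_order: int, emission: str) -> int:
    if emission == "skellam":
        return (L - 1) + L * 2 * (lop_order + 1)
    return (L - 1) + L * ((lop_order + 1) + 1)


def _stack(series: list[PlasticitySeries]):
    times = series[0].times
    for s in series:
        if not np.array_equal(s.times, times):
            raise ValueError("all series must share the design time grid")
    Y = np.stack([s.values for s in series])
    return times, Y


def _component_loglik_matrix(Yint, B, params_list, emission):
    """(genes x L) per-module log-likelihood of each gene's whole series."""
    cols = []
    for p in params_list:
        if emission == "skellam":
            mu1 = _softplus(B @ p.beta1) + _MU_FLOOR
            mu2 = _softplus(B @ p.beta2) + _MU_FLOOR
            cols.append(skellam_logpmf(Yint, mu1, mu2).sum(axis=1))
        else:
            curve, s2 = p
            mean = B @ curve.coefficients
            cols.append(stats.norm.logpdf(Yint, mean, np.sqrt(s2)).sum(axis=1))
    return np.column_stack(cols)


def _mstep_skellam(Yint, B, resp_l, init: SkellamParams, domain) -> SkellamParams:
    q = B.shape[1]

    def nll(theta):
        mu1 = _softplus(B @ theta[:q]) + _MU_FLOOR
        mu2 = _softplus(B @ theta[q:]) + _MU_FLOOR
        ll = skellam_logpmf(Yint, mu1, mu2).sum(axis=1)
        return -float(resp_l @ ll)

    x0 = np.concatenate([init.beta1, init.beta2])
    res = optimize.minimize(nll, x0, method="L-BFGS-B", options={"maxiter": 60})
    theta = res.x if np.isfinite(res.fun) and res.fun <= nll(x0) else x0
    return SkellamParams(theta[:q], theta[q:], domain)


def _init_params(times, Y, labels, L, lop_order, domain, emission, rng):
    """Seed module parameters from per-label mean curves."""
    params = []
    m = AffineMap(*domain)
    B = legendre_basis(m(times), lop_order)
    for l in range(L):
        members = Y[labels == l]
        mean_t = members.mean(axis=0) if len(members) else Y[rng.integers(len(Y))]
        if emission == "skellam":
            spread = max(float(np.var(members, axis=0).mean()) if len(members) > 1 else 1.0, 1.0)
            s = np.maximum(np.abs(mean_t) + 0.5, spread)
            mu1 = (s + mean_t) / 2.0
            mu2 = (s - mean_t) / 2.0
            b1, *_ = np.linalg.lstsq(B, _softplus_inv(mu1), rcond=None)
            b2, *_ = np.linalg.lstsq(B, _softplus_inv(mu2), rcond=None)
            params.append(SkellamParams(b1, b2, domain))
        else:
            curve = fit_lop_curve(times, mean_t, min(lop_order, len(times) - 1), domain)
            resid = members - curve(times) if len(members) else np.ones((1, len(times)))
            s2 = max(float(np.mean(resid**2)), 1e-4)
            params.append((curve, s2))
    return params


def em_cluster(
    series: list[PlasticitySeries],
    n_modules: int,
    lop_order: int = 4,
    emission: str = "skellam",
    max_iter: int = 500,
    tol: float = 1e-6,
    n_restarts: int = 5,
    seed: int = 1,
) -> ModulePartition:
    """EM fit of the L-module functional mixture.

    Plasticity values are rounded to integers for the Skellam emission.
    Initialization is k-means on per-gene LOP coefficients; the best of
    ``n_restarts`` seeded runs (by final log-likelihood) is returned.
    Raises if every restart collapses a module to emptiness.
    """
    L = int(n_modules)
    if L < 1:
        raise ValueError("n_modules must be >= 1")
    if len(series) < L:
        raise ValueError(f"need >= {L} genes to fit {L} modules")
    if emission not in ("skellam", "gaussian"):
        raise ValueError(f"unknown emission {emission!r}")

    times, Y = _stack(series)
    domain = (float(times.min()), float(times.max()))
    Yfit = np.rint(Y) if emission == "skellam" else Y
    m = AffineMap(*domain)
    B = legendre_basis(m(times), lop_order)

    coefs = np.stack([
        fit_lop_curve(times, y, min(lop_order, len(times) - 1), domain).coefficients
        for y in Y
    ])
    rng = np.random.default_rng(seed)

    best = None
    for restart in range(n_restarts):
        if restart == 0 and L <= len(series):
            km = KMeans(n_clusters=L, n_init=5, random_state=int(rng.integers(2**31 - 1)))
            labels0 = km.fit_predict(coefs)
        else:
            labels0 = rng.integers(L, size=len(series))
        if len(np.unique(labels0)) < L:  # force occupancy
            labels0[rng.choice(len(series), L, replace=False)] = np.arange(L)
        params = _init_params(times, Yfit, labels0, L, lop_order, domain, emission, rng)
        weights = np.bincount(labels0, minlength=L).astype(float)
        weights = np.maximum(weights, 1.0)
        weights /= weights.sum()

        prev_ll = -np.inf
        ok = True
        trace = []
        for _ in range(max_iter):
            logl = _component_loglik_matrix(Yfit, B, params, emission) + np.log(weights)
            norm = logsumexp(logl, axis=1)
            ll = float(norm.sum())
            resp = np.exp(logl - norm[:, None])
            trace.append(ll)

            nk = resp.sum(axis=0)
            if np.any(nk < 1e-8):
                ok = False
                break
            weights = nk / nk.sum()
            new_params = []
            for l in range(L):
                if emission == "skellam":
                    new_params.append(_mstep_skellam(Yfit, B, resp[:, l], params[l], domain))
                else:
                    w = resp[:, l]
                    # shared design matrix: WLS reduces to fitting the
                    # responsibility-weighted mean series
                    num = (w[:, None] * Yfit).sum(axis=0) / w.sum()
                    coef, *_ = np.linalg.lstsq(B, num, rcond=None)
                    curve = LopCurve(coef, domain)
                    resid2 = (Yfit - curve(times)) ** 2
                    s2 = max(float((w[:, None] * resid2).sum() / (w.sum() * len(times))), 1e-6)
                    new_params.append((curve, s2))
            params = new_params

            if ll - prev_ll < tol * max(abs(ll), 1.0) and np.isfinite(prev_ll):
                prev_ll = ll
                break
            prev_ll = ll
        if not ok:
            continue

        logl = _component_loglik_matrix(Yfit, B, params, emission) + np.log(weights)
        norm = logsumexp(logl, axis=1)
        ll = float(norm.sum())
        if best is None or ll > best[0]:
            resp = np.exp(logl - norm[:, None])
            trace.append(ll)
            best = (ll, weights.copy(), params, resp, trace)

    if best is None:
        raise RuntimeError("EM failed: every restart produced an empty module")

    ll, weights, params, resp, trace = best
    labels = resp.argmax(axis=1)
    aic = -2.0 * ll + 2.0 * _n_free_params(L, lop_order, emission)
    return ModulePartition(
        n_modules=L,
        weights=weights,
        params=params,
        posterior=resp,
        labels=labels,
        log_likelihood=ll,
        aic=aic,
        gene_ids=[s.entity_id for s in series],
        emission=emission,
        loglik_trace=trace,
    )


def select_module_count(
    series: list[PlasticitySeries],
    l_range=range(1, 7),
    lop_order: int = 4,
    emission: str = "skellam",
    seed: int = 1,
    **em_kwargs,
) -> ModulePartition:
    """Fit each candidate module count and return the AIC-minimizing partition."""
    l_range = list(l_range)
    if not l_range:
        raise ValueError("l_range must be non-empty")
    best, errors = None, []
    for L in l_range:
        try:
            part = em_cluster(series, L, lop_order=lop_order, emission=emission,
                              seed=seed, **em_kwargs)
        except (ValueError, RuntimeError) as exc:
            errors.append((L, exc))
            continue
        if best is None or part.aic < best.aic:
            best = part
    if best is None:
        raise RuntimeError(f"all module-count fits failed: {errors}")
    return best
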