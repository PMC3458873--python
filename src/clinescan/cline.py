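"""Likelihood fits of allele-frequency clines along a latitudinal transect.

Three nested models of focal-allele frequency p(lat):

* horizontal — a single constant frequency (1 parameter);
* twice-broken-stick — two flat plateaus joined by one linear segment
  (4 parameters: the two break coordinates (lat_south_break, p_south) and
  (lat_north_break, p_north));
* logistic — a four-parameter sigmoid, used only to cross-validate
  broken-stick fits on well-behaved clines.

Two objectives are supported.  ``objective="binomial"`` maximises the exact
binomial log-likelihood of the allele counts — appropriate when sampling
noise dominates.  ``objective="gaussian"`` maximises the variance-profiled
normal likelihood of the observed frequencies (equivalently, minimises
residual sum of squares) — appropriate when among-site overdispersion from
genetic drift would otherwise swamp the binomial model.  Likelihood-ratio
tests of broken-stick vs horizontal use 2*delta-loglik against chi-square
with 3 degrees of freedom.

From the broken-stick parameters the cline midpoint
(lat_south_break + lat_north_break)/2 and signed slope
(p_north - p_south)/(lat_north_break - lat_south_break) are derived.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, gammaln, logit, xlogy
from scipy.stats import chi2, f as f_dist
from sklearn.base import BaseEstimator

_P_EPS = 1e-6  # frequency clamp for the binomial log-likelihood
MIN_BREAK_SEPARATION = 0.01  # degrees; fits at this bound are "step-like"
_TIE_TOL = 1e-8


class ClineFitError(RuntimeError):
    """Raised when a fit cannot be attempted on the given data."""


@dataclass(frozen=True)
class BrokenStickParams:
    """Break coordinates of the twice-broken-stick model."""

    lat_south_break: float
    p_south: float
    lat_north_break: float
    p_north: float

    def __post_init__(self):
        if not self.lat_south_break < self.lat_north_break:
            raise ValueError("lat_south_break must be < lat_north_break")
        for p in (self.p_south, self.p_north):
            if not 0.0 <= p <= 1.0:
                raise ValueError("plateau frequencies must lie in [0, 1]")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lat_south_break + self.lat_north_break)

    @property
    def slope(self) -> float:
        return (self.p_north - self.p_south) / (self.lat_north_break - self.lat_south_break)


@dataclass
class ClineFit:
    """Result of one model fit to one locus."""

    model: str  # horizontal | broken_stick | logistic
    params: object
    loglik: float
    midpoint: float | None = None
    slope: float | None = None
    converged: bool = True
    flags: tuple[str, ...] = ()
    objective: str = "binomial"
    n_sites: int = 0


def broken_stick_predict(params: BrokenStickParams, lat) -> np.ndarray:
    """Predicted frequency: plateaus outside the breaks, linear between."""
    lat = np.asarray(lat, dtype=float)
    return np.interp(
        lat,
        [params.lat_south_break, params.lat_north_break],
        [params.p_south, params.p_north],
    )


# ---------------------------------------------------------------------------
# objectives
# ---------------------------------------------------------------------------


def binomial_loglik(x, n, p) -> float:
    """Sum of binomial log-pmf terms with p clamped to [1e-6, 1-1e-6]."""
    x = np.asarray(x, float)
    n = np.asarray(n, float)
    p = np.clip(np.asarray(p, float), _P_EPS, 1 - _P_EPS)
    const = gammaln(n + 1) - gammaln(x + 1) - gammaln(n - x + 1)
    return float(np.sum(const + xlogy(x, p) + xlogy(n - x, 1 - p)))


def gaussian_profile_loglik(y, pred) -> float:
    """Normal log-likelihood with the residual variance profiled out."""
    y = np.asarray(y, float)
    resid = y - np.asarray(pred, float)
    m = len(y)
    rss = max(float(np.sum(resid**2)), 1e-12)
    return -0.5 * m * (np.log(2 * np.pi * rss / m) + 1.0)


def _loglik(objective, x, n, pred):
    if objective == "binomial":
        return binomial_loglik(x, n, pred)
    if objective == "gaussian":
        return gaussian_profile_loglik(x / n, pred)
    raise ValueError(f"unknown objective {objective!r}")


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


class HorizontalCline(BaseEstimator):
    """Constant-frequency (intercept-only) fit.

    The MLE under both objectives is the pooled frequency sum(x)/sum(n)
    for binomial, or the mean observed frequency for gaussian.
    """

    def __init__(self, objective: str = "binomial"):
        self.objective = objective

    def fit(self, latitudes, counts, trials):
        lat, x, n = _validate_series(latitudes, counts, trials, min_sites=2)
        # canonical orientation keeps the fit bit-identical under x -> n - x
        flip = BrokenStickCline._must_flip(x, n)
        xf = n - x if flip else x
        if self.objective == "binomial":
            pf = float(xf.sum() / n.sum())
        else:
            pf = float(np.mean(xf / n))
        self.p_ = 1.0 - pf if flip else pf
        self.loglik_ = _loglik(self.objective, xf, n, np.full(len(xf), pf))
        self.fit_ = ClineFit(
            "horizontal", (self.p_,), self.loglik_, objective=self.objective, n_sites=len(x)
        )
        return self

    def predict(self, latitudes):
        return np.full(np.asarray(latitudes, float).shape, self.p_)


class BrokenStickCline(BaseEstimator):
    """Maximum-likelihood twice-broken-stick cline fit.

    Optimisation is multi-start: all ordered pairs of ``n_quantiles``
    latitude quantiles seed the break positions with plateau frequencies
    from the data means on either side; the best ``n_refine`` starts are
    refined by Nelder-Mead in a transformed parameter space that enforces
    break ordering, the window [min lat - pad, max lat + pad], and
    frequencies in (0, 1).  Ties (delta loglik < 1e-8) are broken in favour
    of the smaller absolute slope.  Fits driven to the minimum break
    separation are flagged "step_like".

    Fitting is exactly symmetric under reflection of the focal allele
    (x -> n - x): the data are canonically oriented before optimisation and
    the result is mirrored back, so loglik, midpoint and |slope| are
    preserved exactly and the slope changes sign.
    """

    def __init__(
        self,
        objective: str = "binomial",
        n_quantiles: int = 9,
        n_refine: int = 3,
        min_separation: float = MIN_BREAK_SEPARATION,
        pad: float = 1.0,
        maxiter: int = 400,
    ):
        self.objective = objective
        self.n_quantiles = n_quantiles
        self.n_refine = n_refine
        self.min_separation = min_separation
        self.pad = pad
        self.maxiter = maxiter

    # -- parameter transform ------------------------------------------------

    def _unpack(self, t, lo, hi):
        a = lo + (hi - lo) * expit(np.clip(t[0], -35, 35))
        b = a + self.min_separation + (hi - a - self.min_separation) * expit(
            np.clip(t[1], -35, 35)
        )
        ps = expit(np.clip(t[2], -35, 35))
        pn = expit(np.clip(t[3], -35, 35))
        return a, ps, b, pn

    def _pack(self, a, ps, b, pn, lo, hi):
        eps = 1e-9
        fa = np.clip((a - lo) / (hi - lo), eps, 1 - eps)
        fb = np.clip(
            (b - a - self.min_separation) / max(hi - a - self.min_separation, eps),
            eps,
            1 - eps,
        )
        ps = np.clip(ps, 1e-4, 1 - 1e-4)
        pn = np.clip(pn, 1e-4, 1 - 1e-4)
        return [logit(fa), logit(fb), logit(ps), logit(pn)]

    # -- fitting ------------------------------------------------------------

    def fit(self, latitudes, counts, trials):
        lat, x, n = _validate_series(latitudes, counts, trials, min_sites=5)
        if len(np.unique(lat)) < 3:
            raise ClineFitError("need >= 3 distinct latitudes")
        # canonical orientation so reflection symmetry is exact
        flip = self._must_flip(x, n)
        xf = n - x if flip else x
        a, ps, b, pn, ll, converged = self._optimise(lat, xf, n)
        # slope from the canonical orientation, negated on flip-back, so the
        # reflection property x -> n - x holds bit-for-bit
        slope = (pn - ps) / (b - a)
        if flip:
            ps, pn, slope = 1 - ps, 1 - pn, -slope
        params = BrokenStickParams(a, ps, b, pn)
        flags = []
        if b - a <= self.min_separation * 1.1:
            flags.append("step_like")
        if not converged:
            flags.append("not_converged")
        self.params_ = params
        self.loglik_ = ll
        self.midpoint_ = params.midpoint
        self.slope_ = float(slope)
        self.converged_ = converged
        self.flags_ = tuple(flags)
        self.fit_ = ClineFit(
            "broken_stick",
            params,
            ll,
            midpoint=params.midpoint,
            slope=float(slope),
            converged=converged,
            flags=tuple(flags),
            objective=self.objective,
            n_sites=len(x),
        )
        return self

    @staticmethod
    def _must_flip(x, n) -> bool:
        s, t = float(np.sum(x)), float(np.sum(n - x))
        if s != t:
            return s > t
        # tie on totals: lexicographic tiebreak; palindromic data are
        # self-symmetric, orientation then irrelevant
        for xi, ci in zip(x, n - x):
            if xi != ci:
                return xi > ci
        return False

    def _optimise(self, lat, x, n):
        lo, hi = lat.min() - self.pad, lat.max() + self.pad
        qs = np.quantile(lat, np.linspace(0.1, 0.9, self.n_quantiles))
        cands = []
        for i in range(self.n_quantiles):
            for j in range(i, self.n_quantiles):
                a = float(qs[i])
                b = max(float(qs[j]), a + self.min_separation)
                if b > hi - 1e-9:
                    b = hi - 1e-9
                    if b <= a:
                        continue
                mid = 0.5 * (a + b)
                sel = lat <= mid
                ps = _plateau_mean(x, n, sel, self.objective)
                pn = _plateau_mean(x, n, ~sel, self.objective)
                pred = np.interp(lat, [a, b], [ps, pn])
                cands.append((_loglik(self.objective, x, n, pred), (a, ps, b, pn)))
        cands.sort(key=lambda t: -t[0])

        def nll(t):
            a, ps, b, pn = self._unpack(t, lo, hi)
            return -_loglik(self.objective, x, n, np.interp(lat, [a, b], [ps, pn]))

        results = []
        any_converged = False
        for ll0, par in cands[: self.n_refine]:
            res = minimize(
                nll,
                self._pack(*par, lo, hi),
                method="Nelder-Mead",
                options=dict(maxiter=self.maxiter, xatol=1e-4, fatol=1e-7),
            )
            any_converged = any_converged or bool(res.success)
            a, ps, b, pn = self._unpack(res.x, lo, hi)
            results.append((-res.fun, (a, ps, b, pn)))
        # keep grid candidates as fallback so loglik never falls below them
        results.extend(cands[:1])
        best_ll = max(r[0] for r in results)
        tied = [r for r in results if r[0] >= best_ll - _TIE_TOL]
        tied.sort(key=lambda r: abs((r[1][3] - r[1][1]) / (r[1][2] - r[1][0])))
        ll, (a, ps, b, pn) = tied[0]
        return a, ps, b, pn, ll, any_converged

    def predict(self, latitudes):
        return broken_stick_predict(self.params_, latitudes)


class LogisticCline(BaseEstimator):
    """Four-parameter logistic cline p(lat) = pS + (pN - pS) * sigmoid(s (lat - c)).

    Used only to cross-check broken-stick fits; convergence failures and
    boundary fits are flagged rather than raised.  A constant-frequency
    start is always included so the logistic log-likelihood never falls
    below the horizontal fit.
    """

    def __init__(self, objective: str = "binomial", maxiter: int = 600):
        self.objective = objective
        self.maxiter = maxiter

    def fit(self, latitudes, counts, trials):
        lat, x, n = _validate_series(latitudes, counts, trials, min_sites=5)
        y = x / n
        lo, hi = lat.min(), lat.max()

        def pred(c, s, pS, pN):
            return pS + (pN - pS) * expit(np.clip(s * (lat - c), -500, 500))

        def nll(t):
            c, s = t[0], t[1]
            pS, pN = expit(np.clip(t[2], -35, 35)), expit(np.clip(t[3], -35, 35))
            return -_loglik(self.objective, x, n, pred(c, s, pS, pN))

        phat = float(np.clip(x.sum() / n.sum(), 1e-4, 1 - 1e-4))
        starts = [
            [0.5 * (lo + hi), 1.0, logit(np.clip(y[lat <= np.median(lat)].mean(), 1e-4, 1 - 1e-4)),
             logit(np.clip(y[lat > np.median(lat)].mean(), 1e-4, 1 - 1e-4))],
            [0.5 * (lo + hi), -1.0, logit(phat), logit(phat)],
            [0.5 * (lo + hi), 0.0, logit(phat), logit(phat)],
        ]
        best = (-np.inf, None, False)
        for t0 in starts:
            res = minimize(
                nll, t0, method="Nelder-Mead",
                options=dict(maxiter=self.maxiter, xatol=1e-5, fatol=1e-8),
            )
            if -res.fun > best[0]:
                best = (-res.fun, res.x, bool(res.success))
        ll, t, ok = best
        c, s = float(t[0]), float(t[1])
        pS, pN = float(expit(np.clip(t[2], -35, 35))), float(expit(np.clip(t[3], -35, 35)))
        flags = []
        if not ok:
            flags.append("not_converged")
        if abs(s) > 50 or abs(pN - pS) < 1e-4 or not lo - 1 <= c <= hi + 1:
            flags.append("boundary")
        slope = s * (pN - pS) / 4.0  # max derivative of the sigmoid
        self.params_ = (c, s, pS, pN)
        self.loglik_ = ll
        self.midpoint_ = c
        self.slope_ = slope
        self.converged_ = ok and "boundary" not in flags
        self.flags_ = tuple(flags)
        self.fit_ = ClineFit(
            "logistic", self.params_, ll, midpoint=c, slope=slope,
            converged=self.converged_, flags=tuple(flags),
            objective=self.objective, n_sites=len(x),
        )
        return self

    def predict(self, latitudes):
        c, s, pS, pN = self.params_
        lat = np.asarray(latitudes, float)
        return pS + (pN - pS) * expit(np.clip(s * (lat - c), -500, 500))


# ---------------------------------------------------------------------------
# functional wrappers and the LRT
# ---------------------------------------------------------------------------


def fit_horizontal(lats, counts, n, objective: str = "binomial") -> ClineFit:
    return HorizontalCline(objective=objective).fit(lats, counts, n).fit_


def fit_broken_stick(lats, counts, n, objective: str = "binomial", **kwargs) -> ClineFit:
    return BrokenStickCline(objective=objective, **kwargs).fit(lats, counts, n).fit_


def fit_logistic(lats, counts, n, objective: str = "binomial") -> ClineFit:
    return LogisticCline(objective=objective).fit(lats, counts, n).fit_


def lrt_clinal(
    fit_bs: ClineFit, fit_h: ClineFit, reference: str = "auto"
) -> tuple[float, int, float]:
    """Test of broken-stick vs horizontal (3 extra parameters).

    Returns (statistic, df, p); df is the numerator degrees of freedom, 3.
    A log-likelihood difference more negative than the optimiser tolerance
    indicates a failed optimisation and raises.

    ``reference`` picks the null distribution of the statistic:

    * ``"chi2"`` — statistic 2*delta-loglik against chi-square(3); exact
      asymptotics for the binomial likelihood.
    * ``"f"`` — the equivalent exact F-test for least-squares fits with the
      variance profiled out: F = (RSS_h/RSS_bs - 1)(m - 4)/3 against
      F(3, m - 4).  The chi-square reference is anticonservative at modest
      site counts when the residual variance is estimated.
    * ``"auto"`` (default) — chi2 for the binomial objective, f for the
      gaussian objective.
    """
    if fit_bs.objective != fit_h.objective:
        raise ValueError("fits use different objectives")
    dll = fit_bs.loglik - fit_h.loglik
    if dll < -5e-7:
        raise ClineFitError(
            f"broken-stick loglik below horizontal by {-dll:.3g}: optimiser failure"
        )
    dll = max(dll, 0.0)
    df = 3
    if reference == "auto":
        reference = "f" if fit_bs.objective == "gaussian" else "chi2"
    if reference == "chi2":
        stat = 2.0 * dll
        return stat, df, float(chi2.sf(stat, df))
    if reference == "f":
        m = fit_bs.n_sites
        if m <= 4:
            raise ClineFitError("F reference needs more sites than parameters")
        ratio = float(np.exp(2.0 * dll / m))  # RSS_h / RSS_bs
        stat = max(ratio - 1.0, 0.0) * (m - 4) / df
        return stat, df, float(f_dist.sf(stat, df, m - 4))
    raise ValueError(f"unknown reference {reference!r}")


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _validate_series(latitudes, counts, trials, min_sites):
    lat = np.asarray(latitudes, dtype=float).ravel()
    x = np.asarray(counts, dtype=float).ravel()
    n = np.asarray(trials, dtype=float).ravel()
    if not (len(lat) == len(x) == len(n)):
        raise ValueError("latitudes, counts and trials must have equal length")
    mask = n > 0
    lat, x, n = lat[mask], x[mask], n[mask]
    if len(lat) < min_sites:
        raise ClineFitError(f"need >= {min_sites} assayed sites, got {len(lat)}")
    if np.any(x < 0) or np.any(x > n):
        raise ValueError("counts must satisfy 0 <= x <= n")
    order = np.argsort(lat, kind="stable")
    return lat[order], x[order], n[order]


def _plateau_mean(x, n, sel, objective):
    if not sel.any():
        sel = np.ones(len(x), bool)
    if objective == "binomial":
        return float((x[sel].sum() + 0.5) / (n[sel].sum() + 1.0))
    return float(np.clip(np.mean(x[sel] / n[sel]), 1e-4, 1 - 1e-4))
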