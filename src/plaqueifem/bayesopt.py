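"""Gaussian-process Bayesian optimization of the Yeoh constants, plus the
GP-inversion uniqueness assessment.

The six-parameter search (intima c1-c3, wall c1-c3) is a black-box global
minimization where every cost evaluation is a full FE inflation analysis.
A GP surrogate (Matern 5/2 with automatic relevance determination, inputs
normalized to the unit box, log-transformed standardized outputs) is refit
after every evaluation; the next point maximizes expected improvement over a
randomized candidate pool that mixes global exploration with perturbations
of the incumbent.  Failed FE evaluations enter as a large finite penalty so
the surrogate stays informative.

Uniqueness: after the search, the GP posterior mean is "inverted" — a
coordinate-wise slice sampler with step-out draws uniformly from the
sub-level set of parameter vectors whose predicted cost lies within a
similarity threshold (achieved NMSE + 5 percentage points by default) — and
the medians of the drawn set are compared with the optimizer's best values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize as opt_minimize
from scipy.stats import norm, qmc
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

from .errors import ConfigurationError, PlaqueIfemError
from .materials import check_yeoh_stability

__all__ = ["SearchSpace", "OptimizationRecord", "UniquenessReport", "Surrogate",
           "minimize", "fit_gp", "invert_gp", "default_search_space"]


@dataclass(frozen=True)
class SearchSpace:
    """Box bounds per parameter (kPa) with optional Yeoh-triplet stability
    screening.  ``log_scale`` flags parameters searched on a log axis —
    essential for c1 and c3, whose physiological values span orders of
    magnitude and would otherwise collapse into a corner of the normalized
    box.  ``yeoh_groups`` lists index triplets (c1, c2, c3) that must
    satisfy the stability criteria when ``stability_mode='reject'``."""

    lower: tuple
    upper: tuple
    names: tuple = ()
    log_scale: tuple = ()            # bool per parameter; default all linear
    yeoh_groups: tuple = ()
    stability_mode: str = "reject"   # or "penalize" / "none"

    def __post_init__(self):
        lo, up = np.asarray(self.lower, float), np.asarray(self.upper, float)
        if lo.shape != up.shape or np.any(lo >= up):
            raise ConfigurationError("need lower < upper per parameter")
        if self.stability_mode not in ("reject", "penalize", "none"):
            raise ConfigurationError("unknown stability mode")
        if not self.log_scale:
            object.__setattr__(self, "log_scale", (False,) * len(self.lower))
        if any(f and l <= 0 for f, l in zip(self.log_scale, self.lower)):
            raise ConfigurationError("log-scaled parameters need lower > 0")

    @property
    def dim(self):
        return len(self.lower)

    def _axes(self):
        lo = np.asarray(self.lower, float).copy()
        up = np.asarray(self.upper, float).copy()
        logf = np.asarray(self.log_scale, bool)
        lo[logf] = np.log10(lo[logf])
        up[logf] = np.log10(up[logf])
        return lo, up, logf

    def to_unit(self, x):
        lo, up, logf = self._axes()
        x = np.asarray(x, float).copy()
        x[..., logf] = np.log10(x[..., logf])
        return (x - lo) / (up - lo)

    def from_unit(self, z):
        lo, up, logf = self._axes()
        x = lo + np.asarray(z, float) * (up - lo)
        x[..., logf] = 10.0 ** x[..., logf]
        return x

    def is_admissible(self, x) -> bool:
        x = np.asarray(x, dtype=float)
        if np.any(x < self.lower) or np.any(x > self.upper):
            return False
        if self.stability_mode == "reject":
            for i, j, k in self.yeoh_groups:
                if not check_yeoh_stability(x[i], x[j], x[k]).stable:
                    return False
        return True


def default_search_space() -> SearchSpace:
    """Bounds for the six Yeoh constants, sized to cover reported fits."""
    layer = ([0.1, -150.0, 0.1], [50.0, 150.0, 700.0])
    return SearchSpace(lower=tuple(layer[0] * 2), upper=tuple(layer[1] * 2),
                       names=("intima_c1", "intima_c2", "intima_c3",
                              "wall_c1", "wall_c2", "wall_c3"),
                       log_scale=(True, False, True) * 2,
                       yeoh_groups=((0, 1, 2), (3, 4, 5)))


@dataclass
class OptimizationRecord:
    x: np.ndarray                   # (n, d) evaluated parameter vectors
    y: np.ndarray                   # (n,) NMSE fractions (penalties included)
    failed: np.ndarray              # (n,) bool, FE failures
    n_init: int
    seed: int
    termination: str
    space: SearchSpace

    @property
    def best_index(self) -> int:
        return int(np.argmin(self.y))

    @property
    def best_x(self) -> np.ndarray:
        return self.x[self.best_index]

    @property
    def best_y(self) -> float:
        return float(self.y[self.best_index])

    def best_trace(self) -> np.ndarray:
        return np.minimum.accumulate(self.y)


@dataclass
class UniquenessReport:
    achieved_nmse: float
    threshold: float                # on the same (fraction) scale
    samples: np.ndarray             # (m, d) inverted parameter set
    medians: np.ndarray             # (d,)
    best_parameters: np.ndarray
    agreement: np.ndarray           # (d,) best value within the IQR of samples

    def summary(self) -> dict:
        return {"achieved_nmse": self.achieved_nmse, "threshold": self.threshold,
                "medians": self.medians.tolist(),
                "best_parameters": self.best_parameters.tolist(),
                "agreement": self.agreement.tolist()}


class Surrogate:
    """GP posterior over the cost, trained in the normalized unit box.

    Outputs are modeled on a log scale (costs span orders of magnitude near
    and far from the optimum); ``mean`` returns the posterior median on the
    original NMSE-fraction scale, ``std`` the matching lognormal spread.
    """

    _FLOOR = 1e-12

    def __init__(self, space: SearchSpace, x, y, seed=0, n_restarts=2):
        self.space = space
        x = np.atleast_2d(np.asarray(x, float))
        y = np.asarray(y, float)
        if len(np.unique(x, axis=0)) < 2:
            raise ConfigurationError("need >= 2 distinct evaluations to fit a GP")
        z = space.to_unit(x)
        t = np.log(np.maximum(y, self._FLOOR))
        self._t_mean, self._t_std = float(t.mean()), float(t.std() or 1.0)
        kernel = (ConstantKernel(1.0, (1e-3, 1e3))
                  * Matern(length_scale=np.full(space.dim, 0.3),
                           length_scale_bounds=(1e-2, 1e2), nu=2.5)
                  + WhiteKernel(1e-6, (1e-9, 1e1)))
        self.gp = GaussianProcessRegressor(
            kernel=kernel, normalize_y=False, alpha=1e-10,
            n_restarts_optimizer=n_restarts,
            random_state=np.random.RandomState(seed % (2**31 - 1)))
        import warnings as _warnings

        from sklearn.exceptions import ConvergenceWarning
        with _warnings.catch_warnings():
            # hyperparameters pinned at their bounds are routine here
            _warnings.simplefilter("ignore", ConvergenceWarning)
            self.gp.fit(z, (t - self._t_mean) / self._t_std)

    def _posterior_log(self, x):
        z = self.space.to_unit(np.atleast_2d(x))
        m, s = self.gp.predict(z, return_std=True)
        return m * self._t_std + self._t_mean, s * self._t_std

    def mean(self, x):
        """Point prediction of the cost (fraction scale): the posterior
        median exp(E[log cost]), which is robust to the large log-scale
        variances far from the data."""
        m, _ = self._posterior_log(x)
        return np.exp(m)

    def std(self, x):
        m, s = self._posterior_log(x)
        return np.exp(m) * np.sqrt(np.maximum(np.expm1(s**2), 0.0))

    def expected_improvement(self, x, best_y):
        """EI on the log-cost scale (monotone-equivalent to the original)."""
        m, s = self._posterior_log(x)
        tb = np.log(max(best_y, self._FLOOR))
        s = np.maximum(s, 1e-12)
        u = (tb - m) / s
        return s * (u * norm.cdf(u) + norm.pdf(u))


def fit_gp(record: OptimizationRecord, seed: int | None = None) -> Surrogate:
    """Refit the surrogate on every recorded evaluation."""
    return Surrogate(record.space, record.x, record.y,
                     seed=record.seed if seed is None else seed, n_restarts=3)


def _admissible_lhs(space: SearchSpace, n, rng):
    """Latin hypercube start, resampling inadmissible rows."""
    sampler = qmc.LatinHypercube(d=space.dim, seed=rng)
    pts = space.from_unit(sampler.random(n))
    for i in range(n):
        tries = 0
        while not space.is_admissible(pts[i]):
            pts[i] = space.from_unit(rng.uniform(size=space.dim))
            tries += 1
            if tries > 10000:
                raise ConfigurationError("cannot sample admissible start points")
    return pts


def minimize(cost, space: SearchSpace, n_init: int = 50, budget: int = 400,
             seed: int = 0, improvement_tol: float = 1e-4,
             patience: int = 50, penalty_factor: float = 10.0,
             n_candidates: int = 2048) -> OptimizationRecord:
    """GP-guided global minimization of a black-box cost over a box.

    The cost may raise :class:`PlaqueIfemError` (e.g. FE divergence); such
    evaluations receive a penalty of ``penalty_factor`` x the worst valid
    value observed so far.  The search stops at ``budget`` evaluations or
    when the incumbent improves by less than ``improvement_tol`` over
    ``patience`` consecutive evaluations (after the initial design).
    """
    if budget < 1:
        raise ConfigurationError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    n_init = min(n_init, budget)
    xs, ys, failed = [], [], []

    def evaluate(x):
        try:
            val = float(cost(np.asarray(x, dtype=float)))
            ok = np.isfinite(val)
        except PlaqueIfemError:
            val, ok = np.nan, False
        xs.append(np.asarray(x, dtype=float))
        ys.append(val)
        failed.append(not ok)

    for x in _admissible_lhs(space, n_init, rng):
        evaluate(x)

    def with_penalties():
        y = np.asarray(ys, dtype=float)
        bad = np.asarray(failed) | ~np.isfinite(y)
        if bad.all():
            raise PlaqueIfemError("all cost evaluations failed")
        worst = np.max(y[~bad])
        y[bad] = penalty_factor * max(worst, 1.0)
        return y

    termination = "budget"
    stall, last_best = 0, np.inf
    while len(xs) < budget:
        y = with_penalties()
        best = float(np.min(y))
        if best < last_best - improvement_tol:
            stall, last_best = 0, best
        else:
            stall += 1
            if stall >= patience:
                termination = "converged"
                break
        try:
            sur = Surrogate(space, np.array(xs), y,
                            seed=int(rng.integers(2**31 - 1)), n_restarts=1)
        except ConfigurationError:
            termination = "degenerate"
            break
        # candidate pool: global uniform + multi-scale perturbations of the
        # incumbent
        n_loc = n_candidates // 2
        cand = rng.uniform(size=(n_candidates - n_loc, space.dim))
        inc = space.to_unit(np.array(xs)[int(np.argmin(y))])
        scales = np.repeat([0.02, 0.05, 0.15], n_loc // 3 + 1)[:n_loc, None]
        loc = np.clip(inc + scales * rng.standard_normal((n_loc, space.dim)),
                      0.0, 1.0)
        cand = space.from_unit(np.vstack([cand, loc]))
        ok = np.array([space.is_admissible(c) for c in cand])
        cand = cand[ok]
        if len(cand) == 0:
            cand = _admissible_lhs(space, 32, rng)
        exploit = len(xs) % 5 == 4

        def neg_score(z):
            z = np.clip(z, 0.0, 1.0)
            p = space.from_unit(z)
            if not space.is_admissible(p):
                return np.inf
            if exploit:
                return float(sur.mean(p[None])[0])
            return -float(sur.expected_improvement(p[None], best)[0])

        score = (-sur.mean(cand) if exploit
                 else sur.expected_improvement(cand, best))
        z_best = space.to_unit(cand[int(np.argmax(score))])
        polish = opt_minimize(neg_score, z_best, method="Nelder-Mead",
                              options={"maxfev": 120, "xatol": 1e-4,
                                       "fatol": 1e-12})
        z_next = np.clip(polish.x, 0.0, 1.0) \
            if np.isfinite(polish.fun) and polish.fun <= neg_score(z_best) \
            else z_best
        x_next = space.from_unit(z_next)
        if not space.is_admissible(x_next):
            x_next = space.from_unit(z_best)
        if any(np.allclose(x_next, px, rtol=0, atol=1e-10) for px in xs):
            x_next = space.from_unit(np.clip(space.to_unit(x_next)
                                             + 1e-3 * rng.standard_normal(space.dim),
                                             0, 1))
        evaluate(x_next)

    y = with_penalties()
    return OptimizationRecord(x=np.array(xs), y=y, failed=np.array(failed),
                              n_init=n_init, seed=seed, termination=termination,
                              space=space)


# ---------------------------------------------------------------------------
# GP inversion by slice sampling

def _slice_sample_indicator(inside, z0, dim, n_samples, rng,
                            burn_in=200, thin=5, width=0.1):
    """Coordinate-wise slice sampler with step-out for the uniform
    distribution over ``{z in [0, 1]^d : inside(z)}`` (normalized space)."""
    z = np.asarray(z0, dtype=float).copy()
    out = []
    total = burn_in + n_samples * thin
    for it in range(total):
        for k in rng.permutation(dim):
            lo = z[k] - width * rng.uniform()
            hi = lo + width
            zk = z[k]

            def ok(v):
                if v < 0.0 or v > 1.0:
                    return False
                z[k] = v
                res = inside(z)
                z[k] = zk
                return res

            while lo > 0.0 and ok(lo):
                lo -= width
            while hi < 1.0 and ok(hi):
                hi += width
            lo, hi = max(lo, 0.0), min(hi, 1.0)
            while True:
                v = rng.uniform(lo, hi)
                if ok(v):
                    z[k] = v
                    break
                if v < zk:
                    lo = v
                else:
                    hi = v
                if hi - lo < 1e-14:
                    break   # degenerate slice; keep current value
        if it >= burn_in and (it - burn_in) % thin == 0:
            out.append(z.copy())
    return np.array(out)


def invert_gp(surrogate: Surrogate, achieved_nmse: float, space: SearchSpace,
              n_samples: int = 400, seed: int = 0,
              threshold: float | None = None, threshold_offset: float = 0.05,
              burn_in: int = 200, thin: int = 5,
              best_parameters=None) -> UniquenessReport:
    """Sample parameter sets whose GP-predicted cost is 'similar' to the
    achieved optimum (within ``achieved + threshold_offset`` by default,
    i.e. +5 percentage points of NMSE) and compare their medians with the
    optimizer's best values."""
    thr = achieved_nmse + threshold_offset if threshold is None else threshold
    rng = np.random.default_rng(seed)

    def inside(z):
        return float(surrogate.mean(space.from_unit(z))[0]) <= thr

    # find a starting point inside the sub-level set
    z0 = None
    if best_parameters is not None:
        zb = np.clip(space.to_unit(np.asarray(best_parameters, float)), 0, 1)
        if inside(zb):
            z0 = zb
    if z0 is None:
        probe = rng.uniform(size=(4096, space.dim))
        vals = surrogate.mean(space.from_unit(probe))
        if float(np.min(vals)) <= thr:
            z0 = probe[int(np.argmin(vals))]
    if z0 is None:
        raise ConfigurationError(
            f"threshold {thr:.4g} lies below the GP minimum; increase the "
            "similarity threshold")

    zsamples = _slice_sample_indicator(inside, z0, space.dim, n_samples, rng,
                                       burn_in=burn_in, thin=thin)
    samples = space.from_unit(zsamples)
    med = np.median(samples, axis=0)
    best = np.asarray(best_parameters, dtype=float) if best_parameters is not None \
        else x0
    q25, q75 = np.percentile(samples, [25, 75], axis=0)
    agreement = (best >= q25) & (best <= q75)
    return UniquenessReport(achieved_nmse=achieved_nmse, threshold=thr,
                            samples=samples, medians=med, best_parameters=best,
                            agreement=agreement)
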