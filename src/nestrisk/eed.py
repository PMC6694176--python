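"""Environmental exposure distributions (EEDs) from censored residue data.

An EED is a parametric distribution fitted to the measured environmental
concentrations of a chemical; the probability that the environment exceeds a
benchmark concentration is 1 - CDF(benchmark).  Residue datasets are heavily
censored — non-detects are left-censored at the LOD, detections below the
LOQ are interval-censored on [LOD, LOQ] — so the fit maximises the censored
log-likelihood

    l(theta) = sum_exact log f(x_i; theta)
             + sum_left  log F(b_i; theta)
             + sum_interval log [F(hi_i; theta) - F(lo_i; theta)]

over four candidate families (log-normal, gamma, Weibull, exponential), with
the family chosen by AIC.  Parameter uncertainty comes from a nonparametric
bootstrap that resamples the censored observation records with replacement
and refits; exceedance confidence intervals are percentile bounds of
1 - CDF(benchmark) across the replicates.

A translocation fraction T in (0, 1] models partial transfer of soil residue
to the bee: if only a fraction T of the contacted residue reaches the bee,
the soil concentration needed to deliver the benchmark dose rises by 1/T, so
exceedance is evaluated at benchmark / T.  This is applied on the benchmark
side, which is mathematically identical to scaling the concentrations by T
and avoids refitting per scenario.

Fitting refuses datasets with no fully quantified observation: with only
censoring bounds the likelihood is weakly identified at these sample sizes,
and monitoring studies treat such compounds as "not quantifiable".
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .exposure import ExposureProfile
from .hazard import (
    ENDPOINT_KINDS,
    KIND_HB_GEOMEAN,
    KIND_SURROGATE,
    ROUTE_CONTACT,
    EndpointSet,
    benchmark_concentration,
)
from .residues import (
    STATUS_BELOW_LOQ,
    STATUS_NONDETECT,
    STATUS_QUANTIFIED,
    ResidueDataset,
)

FAMILIES = ("lognormal", "gamma", "weibull", "exponential")
N_PARAMS = {"lognormal": 2, "gamma": 2, "weibull": 2, "exponential": 1}
PARAM_NAMES = {
    "lognormal": ("mu", "sigma"),
    "gamma": ("shape", "rate"),
    "weibull": ("shape", "scale"),
    "exponential": ("rate",),
}

DEFAULT_RISK_THRESHOLD = 0.05
_LL_SENTINEL = -1e300  # stands in for -inf so optimizers keep moving


class CannotFitEED(ValueError):
    """Raised when a dataset has no quantifiable observations to anchor a fit."""


class FitConvergenceError(RuntimeError):
    """Raised when the likelihood optimizer fails to converge; never silent."""


@dataclass(frozen=True)
class CensoredSample:
    """One observation: exact value, left-censored bound, or interval.

    kind='exact'    -> value > 0 known exactly (quantified residue)
    kind='left'     -> value in (0, bound]     (non-detect at LOD=bound)
    kind='interval' -> value in [lo, hi]       (detected between LOD and LOQ)
    """

    kind: str
    value: float | None = None
    bound: float | None = None
    lo: float | None = None
    hi: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "exact":
            if self.value is None or not self.value > 0:
                raise ValueError("exact sample requires value > 0")
        elif self.kind == "left":
            if self.bound is None or not self.bound > 0:
                raise ValueError("left-censored sample requires bound > 0")
        elif self.kind == "interval":
            if self.lo is None or self.hi is None or not 0 < self.lo < self.hi:
                raise ValueError("interval sample requires 0 < lo < hi")
        else:
            raise ValueError(f"unknown censoring kind {self.kind!r}")

    @property
    def midpoint(self) -> float:
        """Ranking value for plotting: exact value, or the censoring-interval midpoint."""
        if self.kind == "exact":
            return float(self.value)  # type: ignore[arg-type]
        if self.kind == "left":
            return float(self.bound) / 2.0  # type: ignore[arg-type]
        return (float(self.lo) + float(self.hi)) / 2.0  # type: ignore[arg-type]


def censored_from_residues(ds: ResidueDataset, analyte: str | None = None,
                           matrix: str | None = None) -> list[CensoredSample]:
    """Map residue observations to censored samples (ND -> left at LOD,
    below-LOQ -> interval [LOD, LOQ], quantified -> exact)."""
    out: list[CensoredSample] = []
    for o in ds.subset(analyte=analyte, matrix=matrix):
        if o.status == STATUS_QUANTIFIED:
            out.append(CensoredSample(kind="exact", value=o.value))
        elif o.status == STATUS_NONDETECT:
            out.append(CensoredSample(kind="left", bound=o.lod))
        elif o.status == STATUS_BELOW_LOQ:
            out.append(CensoredSample(kind="interval", lo=o.lod, hi=o.loq))
    return out


class _Compiled:
    """Array representation of a censored dataset for fast likelihoods.

    Every record is an interval [lo, hi]: exact -> [v, v], left -> [0, b],
    interval -> [lo, hi].  Resampling indexes these arrays directly; the
    exact/censored split is precomputed once per dataset.
    """

    __slots__ = ("lo", "hi", "n", "n_exact", "n_left", "n_interval",
                 "exact_vals", "cens_lo", "cens_hi")

    def __init__(self, lo: np.ndarray, hi: np.ndarray):
        self.lo = lo
        self.hi = hi
        exact = lo == hi
        self.n = lo.size
        self.n_exact = int(exact.sum())
        self.n_left = int((lo == 0).sum())
        self.n_interval = self.n - self.n_exact - self.n_left
        self.exact_vals = lo[exact]
        self.cens_lo = lo[~exact]
        self.cens_hi = hi[~exact]

    @classmethod
    def from_samples(cls, data: Sequence[CensoredSample]) -> "_Compiled":
        lo = np.empty(len(data))
        hi = np.empty(len(data))
        for i, s in enumerate(data):
            if s.kind == "exact":
                lo[i] = hi[i] = s.value
            elif s.kind == "left":
                lo[i], hi[i] = 0.0, s.bound
            else:
                lo[i], hi[i] = s.lo, s.hi
        return cls(lo, hi)

    def take(self, idx: np.ndarray) -> "_Compiled":
        return _Compiled(self.lo[idx], self.hi[idx])

    def imputed(self) -> np.ndarray:
        """Censoring-midpoint-imputed values, for moment-based starts."""
        return (self.lo + self.hi) / 2.0


@dataclass
class EEDFit:
    """A fitted EED: family, parameters, fit quality, and bootstrap replicates."""

    family: str
    params: tuple[float, ...]
    loglik: float
    aic: float
    n_exact: int
    n_left: int
    n_interval: int
    seed: int | None = None
    bootstrap_reps: np.ndarray | None = None
    n_boot_failed: int = 0
    warning: str | None = None

    @property
    def n(self) -> int:
        return self.n_exact + self.n_left + self.n_interval

    @property
    def dist(self):
        return _dist(self.family, self.params)

    def cdf(self, x):
        return self.dist.cdf(x)

    def sf(self, x):
        return self.dist.sf(x)

    def median(self) -> float:
        return float(self.dist.median())

    def param_names(self) -> tuple[str, ...]:
        return PARAM_NAMES[self.family]

    def param_ci(self, level: float = 0.95) -> np.ndarray | None:
        """Percentile bootstrap CI per parameter, shape (k, 2)."""
        if self.bootstrap_reps is None or len(self.bootstrap_reps) == 0:
            return None
        a = (1 - level) / 2 * 100
        return np.percentile(self.bootstrap_reps, [a, 100 - a], axis=0).T


def _dist(family: str, params: Sequence[float]):
    if family == "lognormal":
        mu, sigma = params
        return stats.lognorm(sigma, scale=math.exp(mu))
    if family == "gamma":
        shape, rate = params
        return stats.gamma(shape, scale=1.0 / rate)
    if family == "weibull":
        shape, scale = params
        return stats.weibull_min(shape, scale=scale)
    if family == "exponential":
        (rate,) = params
        return stats.expon(scale=1.0 / rate)
    raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")


def _to_theta(family: str, params: Sequence[float]) -> np.ndarray:
    # Log-transform positive parameters for unconstrained optimization;
    # the lognormal location mu is already unconstrained.
    if family == "lognormal":
        return np.array([params[0], math.log(params[1])])
    return np.log(np.asarray(params, dtype=float))


def _from_theta(family: str, theta: np.ndarray) -> tuple[float, ...]:
    if family == "lognormal":
        return (float(theta[0]), float(math.exp(theta[1])))
    return tuple(float(x) for x in np.exp(theta))


_LOG_SQRT_2PI = 0.5 * math.log(2 * math.pi)


def _logpdf_cdf(family: str, params: Sequence[float],
                x: np.ndarray, lo: np.ndarray, hi: np.ndarray):
    """(sum log pdf at x, CDF mass on each [lo, hi]) without frozen-dist overhead."""
    if family == "lognormal":
        mu, sigma = params
        z = (np.log(x) - mu) / sigma
        lp = -np.log(x) - math.log(sigma) - _LOG_SQRT_2PI - 0.5 * z * z
        with np.errstate(divide="ignore"):
            zlo = np.where(lo > 0, (np.log(np.where(lo > 0, lo, 1.0)) - mu) / sigma, -np.inf)
        mass = special.ndtr((np.log(hi) - mu) / sigma) - np.where(
            lo > 0, special.ndtr(zlo), 0.0
        )
    elif family == "gamma":
        shape, rate = params
        lp = (shape * math.log(rate) - special.gammaln(shape)
              + (shape - 1) * np.log(x) - rate * x)
        mass = special.gammainc(shape, rate * hi) - special.gammainc(shape, rate * lo)
    elif family == "weibull":
        k, lam = params
        t = x / lam
        lp = math.log(k / lam) + (k - 1) * np.log(t) - t**k
        mass = np.exp(-((lo / lam) ** k)) - np.exp(-((hi / lam) ** k))
    elif family == "exponential":
        (rate,) = params
        lp = math.log(rate) - rate * x
        mass = np.exp(-rate * lo) - np.exp(-rate * hi)
    else:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
    return lp, mass


def _sf_replicates(family: str, params: np.ndarray, x: float) -> np.ndarray:
    """Survival probability at x for each parameter row (vectorized)."""
    p = np.asarray(params, dtype=float)
    if family == "lognormal":
        return special.ndtr(-(math.log(x) - p[:, 0]) / p[:, 1])
    if family == "gamma":
        return special.gammaincc(p[:, 0], p[:, 1] * x)
    if family == "weibull":
        return np.exp(-((x / p[:, 1]) ** p[:, 0]))
    if family == "exponential":
        return np.exp(-p[:, 0] * x)
    raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")


def _loglik_compiled(family: str, params: Sequence[float], comp: _Compiled) -> float:
    for i, p in enumerate(params):
        if not math.isfinite(p):
            return _LL_SENTINEL
        if (family != "lognormal" or i != 0) and not p > 0:
            return _LL_SENTINEL
    with np.errstate(divide="ignore", invalid="ignore", over="ignore", under="ignore"):
        lp, mass = _logpdf_cdf(family, params, comp.exact_vals, comp.cens_lo, comp.cens_hi)
        ll = 0.0
        if comp.exact_vals.size:
            if not np.all(np.isfinite(lp)):
                return _LL_SENTINEL
            ll += float(lp.sum())
        if comp.cens_lo.size:
            if np.any(mass <= 0) or not np.all(np.isfinite(mass)):
                return _LL_SENTINEL
            ll += float(np.log(mass).sum())
    return ll


def censored_loglik(params: Sequence[float], family: str,
                    data: Sequence[CensoredSample]) -> float:
    """Censored log-likelihood of `params` under `family` for `data`.

    Returns a large negative sentinel when any observation has zero
    probability mass at the given parameters.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
    if len(data) == 0:
        raise ValueError("data must be nonempty")
    return _loglik_compiled(family, params, _Compiled.from_samples(data))


def _start_params(family: str, comp: _Compiled) -> tuple[float, ...]:
    x = np.clip(comp.imputed(), 1e-12, None)
    m = float(np.mean(x))
    v = float(np.var(x))
    if family == "lognormal":
        logs = np.log(x)
        return (float(np.mean(logs)), max(float(np.std(logs)), 0.1))
    if family == "gamma":
        v = max(v, 1e-12)
        shape = max(m * m / v, 1e-3)
        return (shape, shape / m)
    if family == "weibull":
        cv = math.sqrt(max(v, 1e-12)) / m
        shape = max(cv, 1e-3) ** -1.086  # standard moment approximation
        scale = m / math.gamma(1 + 1 / shape)
        return (shape, scale)
    return (1.0 / m,)


def _closed_form_uncensored(family: str, comp: _Compiled) -> tuple[float, ...] | None:
    """Exact MLE where available and no censoring is present."""
    if comp.n_exact != comp.n:
        return None
    x = comp.lo
    if family == "lognormal":
        logs = np.log(x)
        sigma = float(np.sqrt(np.mean((logs - logs.mean()) ** 2)))
        if sigma <= 0:
            return None  # degenerate sample, fall through to optimizer guards
        return (float(logs.mean()), sigma)
    if family == "exponential":
        return (1.0 / float(np.mean(x)),)
    return None


def _fit_compiled(family: str, comp: _Compiled, x0: Sequence[float] | None = None,
                  method: str = "auto") -> tuple[tuple[float, ...], float]:
    if method == "auto":
        cf = _closed_form_uncensored(family, comp)
        if cf is not None:
            return cf, _loglik_compiled(family, cf, comp)

    start = tuple(x0) if x0 is not None else _start_params(family, comp)
    theta0 = _to_theta(family, start)

    def neg(theta: np.ndarray) -> float:
        return -_loglik_compiled(family, _from_theta(family, theta), comp)

    best = None
    for attempt, t0 in enumerate([theta0, theta0 + 0.5, theta0 - 0.5]):
        res = optimize.minimize(
            neg, t0, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000, "maxfev": 8000},
        )
        if res.success and res.fun < 1e299:
            best = res
            break
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not math.isfinite(best.fun) or best.fun >= 1e299:
        raise FitConvergenceError(f"{family} fit failed to converge")
    if not best.success:
        raise FitConvergenceError(
            f"{family} fit did not converge: {best.message}"
        )
    params = _from_theta(family, best.x)
    return params, -float(best.fun)


def fit_censored(
    data: Sequence[CensoredSample],
    family: str,
    seed: int | None = None,
    x0: Sequence[float] | None = None,
    method: str = "auto",
) -> EEDFit:
    """Maximum-likelihood fit of one family to censored data.

    method='auto' uses exact closed-form MLEs where they exist (log-normal and
    exponential on fully uncensored data) and numerical optimization otherwise;
    method='numeric' always optimizes.  Refuses datasets with no exact
    (quantified) observation, and warns when fewer than 5 observations carry
    concentration information beyond a non-detect bound.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
    if len(data) < 2:
        raise CannotFitEED("cannot fit EED: need at least 2 observations")
    comp = _Compiled.from_samples(data)
    if comp.n_exact == 0:
        raise CannotFitEED(
            "cannot fit EED: no quantifiable (exact) residue observations"
        )
    if comp.n_exact + comp.n_interval < 5:
        warnings.warn(
            f"only {comp.n_exact + comp.n_interval} quantified/interval observations; "
            "fit will be weakly determined",
            stacklevel=2,
        )
    params, ll = _fit_compiled(family, comp, x0=x0, method=method)
    k = N_PARAMS[family]
    return EEDFit(
        family=family,
        params=params,
        loglik=ll,
        aic=2 * k - 2 * ll,
        n_exact=comp.n_exact,
        n_left=comp.n_left,
        n_interval=comp.n_interval,
        seed=seed,
    )


def select_family(
    data: Sequence[CensoredSample],
    families: Sequence[str] = FAMILIES,
    seed: int | None = None,
    method: str = "auto",
) -> EEDFit:
    """Fit every candidate family and return the minimum-AIC fit.

    Ties (within 1e-9 AIC) break toward fewer parameters, then the fixed
    family order log-normal, gamma, Weibull, exponential.  Families that fail
    to fit are skipped; if all fail, the errors are reported together.
    """
    fits: list[tuple[float, int, int, EEDFit]] = []
    failures: list[str] = []
    for fam in families:
        try:
            fit = fit_censored(data, fam, seed=seed, method=method)
        except (CannotFitEED, FitConvergenceError) as exc:
            if isinstance(exc, CannotFitEED):
                raise
            failures.append(f"{fam}: {exc}")
            continue
        fits.append((fit.aic, N_PARAMS[fam], FAMILIES.index(fam), fit))
    if not fits:
        raise FitConvergenceError(
            "no candidate family could be fitted: " + "; ".join(failures)
        )
    fits.sort(key=lambda t: (round(t[0] / 1e-9) * 1e-9, t[1], t[2]))
    return fits[0][3]


@dataclass(frozen=True)
class BootstrapReplicates:
    """Parameter replicates from the nonparametric bootstrap."""

    family: str
    params: np.ndarray  # shape (n_ok, k)
    n_iter: int
    n_failed: int
    seed: int | None


def bootstrap_params(
    data: Sequence[CensoredSample],
    family: str,
    n_iter: int = 1000,
    seed: int | None = None,
    x0: Sequence[float] | None = None,
) -> BootstrapReplicates:
    """Nonparametric bootstrap: resample censored records with replacement, refit.

    Replicates whose resample has no exact observation, or whose fit fails,
    are dropped and counted in ``n_failed``.  Reproducible for a given seed.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    comp = _Compiled.from_samples(data)
    if comp.n_exact == 0:
        raise CannotFitEED("cannot bootstrap: no quantifiable observations")
    if x0 is None:
        x0, _ = _fit_compiled(family, comp)
    rng = np.random.default_rng(seed)
    reps: list[tuple[float, ...]] = []
    n_failed = 0
    for _ in range(n_iter):
        idx = rng.integers(0, comp.n, comp.n)
        sub = comp.take(idx)
        if sub.n_exact == 0:
            n_failed += 1
            continue
        try:
            params, _ = _fit_compiled(family, sub, x0=x0)
        except FitConvergenceError:
            n_failed += 1
            continue
        reps.append(params)
    return BootstrapReplicates(
        family=family,
        params=np.array(reps) if reps else np.empty((0, N_PARAMS[family])),
        n_iter=n_iter,
        n_failed=n_failed,
        seed=seed,
    )


def with_bootstrap(
    fit: EEDFit,
    data: Sequence[CensoredSample],
    n_iter: int = 1000,
    seed: int | None = None,
) -> EEDFit:
    """Attach bootstrap replicates to a fit; warn if over half the replicates failed."""
    boot = bootstrap_params(data, fit.family, n_iter=n_iter, seed=seed, x0=fit.params)
    warning = fit.warning
    if boot.n_failed > boot.n_iter / 2:
        warning = f"{boot.n_failed}/{boot.n_iter} bootstrap replicates failed"
        warnings.warn(warning, stacklevel=2)
    return replace(
        fit,
        bootstrap_reps=boot.params,
        n_boot_failed=boot.n_failed,
        seed=seed if seed is not None else fit.seed,
        warning=warning,
    )


@dataclass(frozen=True)
class ExceedanceResult:
    """Probability that the environmental concentration exceeds a benchmark."""

    benchmark_ng_g: float
    endpoint_kind: str
    scenario: str
    translocation: float
    probability: float
    ci_lo: float
    ci_hi: float
    acceptable: bool


def exceedance(
    fit: EEDFit,
    benchmark_ng_g: float,
    translocation: float = 1.0,
    scenario: str = "chronic",
    endpoint_kind: str = "",
    risk_threshold: float = DEFAULT_RISK_THRESHOLD,
) -> ExceedanceResult:
    """Exceedance = 1 - CDF(benchmark / translocation).

    A translocation fraction T < 1 means only part of the contacted residue
    reaches the bee, so a higher environmental concentration (benchmark / T)
    is needed to deliver the benchmark dose.  ``acceptable`` is True when the
    exceedance probability is below the risk threshold (default 5%, i.e. 95%
    population protection).  Confidence bounds evaluate the same survival
    probability at every bootstrap parameter replicate (2.5/97.5 percentiles).
    """
    if not benchmark_ng_g > 0:
        raise ValueError("benchmark must be > 0")
    if not 0 < translocation <= 1:
        raise ValueError(f"translocation must be in (0, 1], got {translocation}")
    effective = benchmark_ng_g / translocation
    prob = float(fit.sf(effective))
    ci_lo = ci_hi = float("nan")
    if fit.bootstrap_reps is not None and len(fit.bootstrap_reps) > 0:
        probs = _sf_replicates(fit.family, fit.bootstrap_reps, effective)
        ci_lo, ci_hi = (float(v) for v in np.percentile(probs, [2.5, 97.5]))
    return ExceedanceResult(
        benchmark_ng_g=benchmark_ng_g,
        endpoint_kind=endpoint_kind,
        scenario=scenario,
        translocation=translocation,
        probability=prob,
        ci_lo=ci_lo,
        ci_hi=ci_hi,
        acceptable=prob < risk_threshold,
    )


def hazen_positions(n: int) -> np.ndarray:
    """Hazen plotting positions (i - 0.5)/n for i = 1..n."""
    if n < 0:
        raise ValueError("n must be >= 0")
    return (np.arange(1, n + 1) - 0.5) / n if n else np.array([])


def empirical_points(data: Sequence[CensoredSample]) -> pd.DataFrame:
    """Ranked empirical CDF points for plotting.

    Observations are ranked by their censoring-interval midpoint (exact values
    by the value itself) and assigned Hazen probabilities.
    """
    rows = sorted(data, key=lambda s: s.midpoint)
    pos = hazen_positions(len(rows))
    return pd.DataFrame(
        {
            "midpoint": [s.midpoint for s in rows],
            "kind": [s.kind for s in rows],
            "lo": [0.0 if s.kind == "left" else (s.value if s.kind == "exact" else s.lo)
                   for s in rows],
            "hi": [s.bound if s.kind == "left" else (s.value if s.kind == "exact" else s.hi)
                   for s in rows],
            "prob": pos,
        }
    )


_RESULT_COLUMNS = [
    "analyte", "scenario", "endpoint_kind", "translocation", "benchmark_ng_g",
    "exceedance", "ci_lo", "ci_hi", "acceptable", "family", "params", "aic",
    "n", "n_exact", "n_left", "n_interval", "n_boot_failed", "status",
]


def run_risk_assessment(
    ds: ResidueDataset,
    profile: ExposureProfile,
    endpoints: EndpointSet,
    scenarios: Sequence[str] = ("chronic", "acute"),
    translocations: Sequence[float] = (0.10, 0.25, 0.50, 0.75, 1.00),
    families: Sequence[str] = FAMILIES,
    n_boot: int = 1000,
    seed: int = 0,
    risk_threshold: float = DEFAULT_RISK_THRESHOLD,
    matrix: str = "soil",
) -> pd.DataFrame:
    """Full probabilistic assessment over every analyte x scenario x endpoint
    kind x translocation combination.

    For each analyte with residue data in `matrix`, fits the AIC-best family,
    bootstraps it, converts each available endpoint kind (honey-bee geometric
    mean, honey-bee lowest when supplied, solitary surrogate = geomean/10) to
    a concentration benchmark with the scenario's soil amount, and evaluates
    exceedance.  Analytes that cannot be fitted appear as 'not assessed'
    rows rather than being dropped.  Per-analyte bootstrap seeds derive
    deterministically from the pipeline seed.
    """
    analytes = sorted({a for a, m in ds.groups() if m == matrix})
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(max(len(analytes), 1))
    rows: list[dict] = []
    for i, analyte in enumerate(analytes):
        samples = censored_from_residues(ds, analyte=analyte, matrix=matrix)
        boot_seed = int(children[i].generate_state(1)[0] % (2**31))
        try:
            fit = select_family(samples, families=families)
            fit = with_bootstrap(fit, samples, n_iter=n_boot, seed=boot_seed)
        except (CannotFitEED, FitConvergenceError) as exc:
            rows.append(
                {c: float("nan") for c in _RESULT_COLUMNS}
                | {
                    "analyte": analyte,
                    "status": f"not assessed: {exc}",
                    "n": len(samples),
                    "family": "",
                    "params": "",
                    "endpoint_kind": "",
                    "scenario": "",
                    "acceptable": "",
                }
            )
            continue
        param_str = ";".join(
            f"{name}={v:.6g}" for name, v in zip(fit.param_names(), fit.params)
        )
        kinds = endpoints.kinds_for(analyte, ROUTE_CONTACT)
        for scenario in scenarios:
            soil_g = profile.soil_for(scenario)
            for kind in kinds:
                ep = endpoints.get(analyte, ROUTE_CONTACT, kind)
                if ep is None:
                    continue
                benchmark = benchmark_concentration(ep.value, soil_g)
                for t in translocations:
                    res = exceedance(
                        fit, benchmark, translocation=t, scenario=scenario,
                        endpoint_kind=kind, risk_threshold=risk_threshold,
                    )
                    rows.append(
                        {
                            "analyte": analyte,
                            "scenario": scenario,
                            "endpoint_kind": kind,
                            "translocation": t,
                            "benchmark_ng_g": res.benchmark_ng_g,
                            "exceedance": res.probability,
                            "ci_lo": res.ci_lo,
                            "ci_hi": res.ci_hi,
                            "acceptable": res.acceptable,
                            "family": fit.family,
                            "params": param_str,
                            "aic": fit.aic,
                            "n": fit.n,
                            "n_exact": fit.n_exact,
                            "n_left": fit.n_left,
                            "n_interval": fit.n_interval,
                            "n_boot_failed": fit.n_boot_failed,
                            "status": "ok" if fit.warning is None else fit.warning,
                        }
                    )
    return pd.DataFrame(rows, columns=_RESULT_COLUMNS)
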