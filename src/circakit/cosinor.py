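"""Damped-cosinor regression with a fixed circadian period.

The model fitted throughout this package is

    y(t) = B + A * exp(-k * t) * sin(2 * pi * t / T + P)

where ``B`` is the baseline (same units as the data), ``A`` the amplitude,
``k`` a damping rate in 1/h, ``T`` the oscillation period (held fixed,
24 h by default, never estimated) and ``P`` the phase in radians.

A series is called rhythmic when two independent gates both pass:

1. goodness of fit: R^2 of the cosinor regression exceeds a threshold
   (0.55 by default), and
2. zero-amplitude test: the 95% confidence region of the fitted
   oscillatory component excludes a flat (zero-amplitude) signal.

The zero-amplitude test is carried out on the linear sinusoid
coefficients ``(b1, b2) = (A cos P, A sin P)`` via their joint confidence
ellipse, which is exactly calibrated in the undamped (linear) case; the
reported amplitude confidence interval is the range of sqrt(b1^2 + b2^2)
over that ellipse.  A Wald interval (``A +/- t * SE(A)``), the convention
of common curve-fitting software, is available as an alternative but is
anti-conservative under the null because the phase is chosen to maximise
the apparent amplitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "TimeSeries",
    "CosinorFit",
    "AmplitudeTest",
    "RhythmConfig",
    "RhythmicityCall",
    "damped_cosinor",
    "fit_damped_cosinor",
    "zero_amplitude_test",
    "classify_rhythmic",
    "normalize_amplitude_phase",
]

TWO_PI = 2.0 * math.pi


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TimeSeries:
    """A sampled measurement over hours with replicate structure.

    Times are hours since synchronization (medium change / lights-on);
    values are in arbitrary units (protein ratio, relative RNA quantity,
    percent of initial value, fluorescence).
    """

    times: np.ndarray
    values: np.ndarray
    replicates: np.ndarray
    series_id: str = "series"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float).ravel()
        v = np.asarray(self.values, dtype=float).ravel()
        r = np.asarray(self.replicates).ravel()
        if not (t.size == v.size == r.size):
            raise ValueError("times, values and replicates must have equal length")
        if t.size == 0:
            raise ValueError("empty time series")
        if not np.all(np.isfinite(t)):
            raise ValueError(f"{self.series_id}: non-finite times")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"{self.series_id}: non-finite values")
        if np.any(t < 0):
            raise ValueError(f"{self.series_id}: negative times")
        if np.unique(t).size < 4:
            raise ValueError(
                f"{self.series_id}: need at least 4 distinct time points, "
                f"got {np.unique(t).size}"
            )
        order = np.lexsort((t, r.astype(str)))
        t, v, r = t[order], v[order], r[order]
        for rep in np.unique(r):
            tr = t[r == rep]
            if np.any(np.diff(tr) <= 0):
                raise ValueError(
                    f"{self.series_id}: times not strictly increasing within "
                    f"replicate {rep!r}"
                )
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "replicates", r)

    @classmethod
    def build(
        cls,
        times: Sequence[float],
        values: Sequence[float],
        replicates: Sequence | None = None,
        series_id: str = "series",
    ) -> "TimeSeries":
        times = np.asarray(times, dtype=float)
        if replicates is None:
            replicates = np.repeat("r1", times.size)
        return cls(times=times, values=np.asarray(values, dtype=float),
                   replicates=np.asarray(replicates), series_id=series_id)

    @property
    def n_replicates(self) -> int:
        return int(np.unique(self.replicates).size)

    def replicate_means(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-time means over replicates (times sorted ascending)."""
        ut = np.unique(self.times)
        means = np.array([self.values[self.times == t].mean() for t in ut])
        return ut, means


@dataclass(frozen=True)
class CosinorFit:
    """Least-squares damped-cosinor parameters and fit diagnostics.

    ``beta`` holds the linear sinusoid coefficients (b1, b2) with
    ``b1 = A cos P`` and ``b2 = A sin P``; ``beta_cov`` their asymptotic
    2x2 covariance, used by the zero-amplitude test.
    """

    baseline: float
    amplitude: float
    damping_rate: float
    phase: float
    period: float
    r_squared: float
    ss_residual: float
    ss_total: float
    param_se: dict[str, float]
    dof: int
    n_points: int
    converged: bool
    beta: np.ndarray = field(repr=False)
    beta_cov: np.ndarray = field(repr=False)
    cov_singular: bool = False
    residual_variance: float = float("nan")

    def predict(self, t: np.ndarray | float) -> np.ndarray | float:
        return damped_cosinor(t, self.baseline, self.amplitude,
                              self.damping_rate, self.period, self.phase)


@dataclass(frozen=True)
class AmplitudeTest:
    """Outcome of the zero-amplitude test."""

    ci_low: float
    ci_high: float
    significant: bool
    statistic: float
    dof: int
    alpha: float
    method: str
    reason: str | None = None


@dataclass(frozen=True)
class RhythmConfig:
    """Tunable parameters for rhythmicity calls."""

    period_h: float = 24.0
    r2_threshold: float = 0.55
    alpha: float = 0.05
    fit_damping: bool = True
    k_fixed: float | None = None
    k_max: float = 0.2
    n_starts: int = 8
    fit_replicate_means: bool = True
    amplitude_test_method: str = "ellipse"


@dataclass(frozen=True)
class RhythmicityCall:
    """Rhythmic / non-rhythmic decision with both gates reported."""

    series_id: str
    rhythmic: bool
    fit: CosinorFit | None
    amplitude_test: AmplitudeTest | None
    r2_pass: bool
    amplitude_pass: bool
    r2_threshold: float
    alpha: float
    reason: str | None
    detail: str = ""


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

def damped_cosinor(t, B: float, A: float, k: float, T: float, P: float):
    """Evaluate ``B + A * exp(-k*t) * sin(2*pi*t/T + P)``.

    With ``k = 1`` this is the literal exponentially damped sine in units
    of 1/h; ``k = 0`` gives the plain (undamped) cosinor.
    """
    for name, val in (("B", B), ("A", A), ("k", k), ("T", T), ("P", P)):
        if not np.isfinite(val):
            raise ValueError(f"non-finite parameter {name}={val}")
    if T <= 0:
        raise ValueError(f"period must be positive, got {T}")
    if k < 0:
        raise ValueError(f"damping rate must be non-negative, got {k}")
    t = np.asarray(t, dtype=float)
    out = B + A * np.exp(-k * t) * np.sin(TWO_PI * t / T + P)
    return float(out) if out.ndim == 0 else out


def normalize_amplitude_phase(A: float, P: float) -> tuple[float, float]:
    """Map (A, P) to the canonical representative with A >= 0, P in [0, 2pi)."""
    if A < 0:
        A, P = -A, P + math.pi
    return A, P % TWO_PI


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _linear_start(t, y, omega, k):
    """Exact least-squares solution for (B, b1, b2) at a fixed damping rate."""
    env = np.exp(-k * t)
    X = np.column_stack([np.ones_like(t), env * np.sin(omega * t),
                         env * np.cos(omega * t)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    B, b1, b2 = coef
    return B, math.hypot(b1, b2), math.atan2(b2, b1)


def fit_damped_cosinor(
    series: TimeSeries,
    period: float = 24.0,
    fit_damping: bool = True,
    k_fixed: float | None = None,
    k_max: float = 0.2,
    fit_replicate_means: bool = True,
    n_starts: int = 8,
) -> CosinorFit:
    """Fit the damped cosinor by nonlinear least squares with T fixed.

    Parameters
    ----------
    series:
        Input time series.  By default the per-time replicate means are
        fitted; set ``fit_replicate_means=False`` to fit all points.
    period:
        Fixed oscillation period in hours (never estimated).
    fit_damping:
        Estimate the damping rate ``k`` within ``[0, k_max]``.  When
        False, ``k`` is held at ``k_fixed`` (or 0 when unset).
    k_fixed:
        Freeze the damping rate at this value; ``k_fixed=1.0`` reproduces
        the literal ``exp(-t)`` damping term.
    n_starts:
        Number of equally spaced phase starts in [0, 2pi).  An exact
        variable-projection start (linear solve at fixed k) is always
        added, so the global optimum is found reliably.

    Raises
    ------
    ValueError
        Too few points for the number of free parameters, or zero
        variance in the fitted values.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    if n_starts < 1:
        raise ValueError("need at least one start")
    if fit_replicate_means:
        t, y = series.replicate_means()
    else:
        t, y = series.times, series.values

    fit_k = fit_damping and k_fixed is None
    n_free = 4 if fit_k else 3
    n = t.size
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError(f"{series.series_id}: zero-variance values cannot be fitted")
    if n <= n_free:
        raise ValueError(
            f"{series.series_id}: {n} fitted points cannot constrain "
            f"{n_free} free parameters"
        )

    omega = TWO_PI / period
    kfix = float(k_fixed) if k_fixed is not None else 0.0

    def resid(x):
        B, A, P = x[0], x[1], x[2]
        k = x[3] if fit_k else kfix
        return B + A * np.exp(-k * t) * np.sin(omega * t + P) - y

    def jac(x):
        B, A, P = x[0], x[1], x[2]
        k = x[3] if fit_k else kfix
        env = np.exp(-k * t)
        s = np.sin(omega * t + P)
        c = np.cos(omega * t + P)
        cols = [np.ones_like(t), env * s, A * env * c]
        if fit_k:
            cols.append(-t * A * env * s)
        return np.column_stack(cols)

    # multi-start over a phase grid, plus exact linear-solve starts
    A0 = 0.5 * float(np.ptp(y))
    B0 = float(y.mean())
    starts: list[np.ndarray] = []
    for P0 in np.linspace(0.0, TWO_PI, n_starts, endpoint=False):
        x0 = [B0, A0, P0] + ([0.0] if fit_k else [])
        starts.append(np.array(x0))
    k_seeds = [0.0, 0.5 * k_max, k_max] if fit_k else [kfix]
    for kc in k_seeds:
        Bl, Al, Pl = _linear_start(t, y, omega, kc)
        x0 = [Bl, Al, Pl] + ([kc] if fit_k else [])
        starts.append(np.array(x0))

    if fit_k:
        lb = np.array([-np.inf, -np.inf, -np.inf, 0.0])
        ub = np.array([np.inf, np.inf, np.inf, k_max])
    else:
        lb, ub = -np.inf, np.inf

    best = None
    any_success = False
    for x0 in starts:
        if fit_k:
            x0 = np.clip(x0, lb + 0, ub - 0)
        try:
            res = optimize.least_squares(
                resid, x0, jac=jac, bounds=(lb, ub),
                method="trf" if fit_k else "lm", xtol=1e-12, ftol=1e-12,
                gtol=1e-12, max_nfev=2000,
            )
        except Exception:
            continue
        any_success = any_success or bool(res.success)
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError(f"{series.series_id}: optimizer failed from every start")

    B, A, P = best.x[0], best.x[1], best.x[2]
    k = float(best.x[3]) if fit_k else kfix
    A, P = normalize_amplitude_phase(float(A), float(P))
    b1, b2 = A * math.cos(P), A * math.sin(P)

    ss_res = float(2.0 * best.cost)
    dof = n - n_free
    sigma2 = ss_res / dof
    r_squared = 1.0 - ss_res / ss_tot

    # covariance in the linear parametrization (B, b1, b2[, k]); exact
    # reparametrization of the asymptotic covariance, well-behaved as A -> 0
    env = np.exp(-k * t)
    s, c = np.sin(omega * t), np.cos(omega * t)
    cols = [np.ones_like(t), env * s, env * c]
    if fit_k:
        cols.append(-t * env * (b1 * s + b2 * c))
    J = np.column_stack(cols)
    JTJ = J.T @ J
    cov_singular = False
    try:
        cov = sigma2 * np.linalg.inv(JTJ)
        if not np.all(np.isfinite(cov)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        cov = sigma2 * np.linalg.pinv(JTJ)
        cov_singular = True
    if np.linalg.cond(JTJ) > 1e12:
        cov_singular = True

    beta = np.array([b1, b2])
    beta_cov = cov[1:3, 1:3]

    param_se: dict[str, float] = {"baseline": float(math.sqrt(max(cov[0, 0], 0.0)))}
    if A > 0:
        v = beta / A
        w = np.array([-b2, b1]) / A**2
        param_se["amplitude"] = float(math.sqrt(max(v @ beta_cov @ v, 0.0)))
        param_se["phase"] = float(math.sqrt(max(w @ beta_cov @ w, 0.0)))
    else:
        param_se["amplitude"] = float(math.sqrt(max(beta_cov[0, 0], 0.0)))
        param_se["phase"] = float("nan")
    if fit_k:
        param_se["damping_rate"] = float(math.sqrt(max(cov[3, 3], 0.0)))

    return CosinorFit(
        baseline=float(B), amplitude=A, damping_rate=k, phase=P,
        period=float(period), r_squared=float(r_squared),
        ss_residual=ss_res, ss_total=ss_tot, param_se=param_se,
        dof=int(dof), n_points=int(n), converged=bool(any_success),
        beta=beta, beta_cov=beta_cov, cov_singular=cov_singular,
        residual_variance=float(sigma2),
    )


# ---------------------------------------------------------------------------
# zero-amplitude test
# ---------------------------------------------------------------------------

def _ellipse_amplitude_range(beta, beta_cov, radius, n_angles=1440):
    """Min/max of ||b|| over the confidence ellipse {beta + r L u, |u|<=1}."""
    L = np.linalg.cholesky(beta_cov)
    theta = np.linspace(0.0, TWO_PI, n_angles, endpoint=False)
    ring = beta[:, None] + radius * (L @ np.vstack([np.cos(theta), np.sin(theta)]))
    norms = np.hypot(ring[0], ring[1])
    return float(norms.min()), float(norms.max())


def zero_amplitude_test(
    fit: CosinorFit,
    alpha: float = 0.05,
    method: str = "ellipse",
) -> AmplitudeTest:
    """Decide whether the fitted amplitude is significantly non-zero.

    ``method="ellipse"`` (default): joint confidence ellipse for the
    sinusoid coefficients (b1, b2); the amplitude CI is the range of
    amplitudes over the ellipse and excludes zero exactly when the
    2-degree-of-freedom F test on (b1, b2) rejects.  Exactly calibrated
    for the undamped model under Gaussian noise.

    ``method="wald"``: ``A +/- t(1-alpha/2, dof) * SE(A)``, the output of
    common curve-fitting software; anti-conservative under the null.
    """
    if not fit.converged:
        raise ValueError("zero-amplitude test requires a converged fit")
    if fit.dof < 1:
        raise ValueError("zero-amplitude test requires dof >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")

    # perfect (noiseless) fit: the confidence region collapses onto the
    # point estimate, so any positive amplitude is trivially significant
    perfect = fit.ss_total > 0 and fit.ss_residual <= 1e-12 * fit.ss_total
    if perfect:
        return AmplitudeTest(
            ci_low=fit.amplitude, ci_high=fit.amplitude,
            significant=fit.amplitude > 0, statistic=float("inf"),
            dof=fit.dof, alpha=alpha, method=method, reason="noiseless_fit",
        )

    bad_cov = (
        fit.cov_singular
        or not np.all(np.isfinite(fit.beta_cov))
        or np.linalg.det(fit.beta_cov) <= 0
    )
    if bad_cov:
        return AmplitudeTest(
            ci_low=0.0, ci_high=float("nan"), significant=False,
            statistic=float("nan"), dof=fit.dof, alpha=alpha, method=method,
            reason="singular_covariance",
        )

    if method == "ellipse":
        f_stat = float(fit.beta @ np.linalg.solve(fit.beta_cov, fit.beta) / 2.0)
        crit = float(stats.f.ppf(1.0 - alpha, 2, fit.dof))
        significant = f_stat > crit
        radius = math.sqrt(2.0 * crit)
        lo, hi = _ellipse_amplitude_range(fit.beta, fit.beta_cov, radius)
        if not significant:
            lo = 0.0
        return AmplitudeTest(ci_low=lo, ci_high=hi, significant=significant,
                             statistic=f_stat, dof=fit.dof, alpha=alpha,
                             method=method)
    if method == "wald":
        se = fit.param_se.get("amplitude", float("nan"))
        if not np.isfinite(se) or se < 0:
            return AmplitudeTest(ci_low=0.0, ci_high=float("nan"),
                                 significant=False, statistic=float("nan"),
                                 dof=fit.dof, alpha=alpha, method=method,
                                 reason="singular_covariance")
        tcrit = float(stats.t.ppf(1.0 - alpha / 2.0, fit.dof))
        lo, hi = fit.amplitude - tcrit * se, fit.amplitude + tcrit * se
        t_stat = fit.amplitude / se if se > 0 else float("inf")
        return AmplitudeTest(ci_low=lo, ci_high=hi, significant=lo > 0,
                             statistic=t_stat, dof=fit.dof, alpha=alpha,
                             method=method)
    raise ValueError(f"unknown amplitude test method {method!r}")


# ---------------------------------------------------------------------------
# rhythmicity call
# ---------------------------------------------------------------------------

def classify_rhythmic(series: TimeSeries, config: RhythmConfig | None = None,
                      ) -> RhythmicityCall:
    """Run both rhythmicity gates and return a combined call.

    A series is rhythmic iff the cosinor R^2 exceeds
    ``config.r2_threshold`` AND the zero-amplitude test is significant at
    ``config.alpha``.  Fit failures propagate as non-rhythmic calls with
    a reason rather than exceptions.
    """
    cfg = config or RhythmConfig()
    try:
        fit = fit_damped_cosinor(
            series, period=cfg.period_h, fit_damping=cfg.fit_damping,
            k_fixed=cfg.k_fixed, k_max=cfg.k_max,
            fit_replicate_means=cfg.fit_replicate_means, n_starts=cfg.n_starts,
        )
    except (ValueError, RuntimeError) as exc:
        return RhythmicityCall(
            series_id=series.series_id, rhythmic=False, fit=None,
            amplitude_test=None, r2_pass=False, amplitude_pass=False,
            r2_threshold=cfg.r2_threshold, alpha=cfg.alpha,
            reason="fit_error", detail=str(exc),
        )
    if not fit.converged:
        return RhythmicityCall(
            series_id=series.series_id, rhythmic=False, fit=fit,
            amplitude_test=None, r2_pass=False, amplitude_pass=False,
            r2_threshold=cfg.r2_threshold, alpha=cfg.alpha,
            reason="fit_error", detail="no start converged",
        )
    amp = zero_amplitude_test(fit, alpha=cfg.alpha,
                              method=cfg.amplitude_test_method)
    r2_pass = fit.r_squared > cfg.r2_threshold
    amp_pass = amp.significant
    rhythmic = r2_pass and amp_pass
    if rhythmic:
        reason = None
    elif not r2_pass and not amp_pass:
        reason = "r2_gate+zero_amplitude"
    elif not r2_pass:
        reason = "r2_gate"
    else:
        reason = "zero_amplitude"
    return RhythmicityCall(
        series_id=series.series_id, rhythmic=rhythmic, fit=fit,
        amplitude_test=amp, r2_pass=r2_pass, amplitude_pass=amp_pass,
        r2_threshold=cfg.r2_threshold, alpha=cfg.alpha,
        reason=reason,
        detail=amp.reason or "",
    )
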