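"""Power-law (Korsmeyer-Peppas) release kinetics.

The semi-empirical power law

    M_t / M_inf = k * t^n

describes the early fraction of an encapsulated compound released by
time t: k (min^-n) bundles structural and geometric effects of the
carrier, while the exponent n diagnoses the transport mechanism. For
spherical particles, pure Fickian diffusion gives n = 0.43 and Case II
(relaxation-controlled) transport gives n = 0.85; intermediate values
indicate anomalous transport, a superposition of diffusion and polymer
relaxation or erosion.

Fitting minimizes the linear-space sum of squared errors over (k, n)
with the Nelder-Mead simplex, initialized from the log-log OLS line
(ln f = ln k + n ln t). Positivity of both parameters is enforced by
optimizing (ln k, ln n). On noiseless power-law data the simplex
solution coincides with the log-log closed form, which doubles as an
independent oracle in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .errors import CannotNormalizeError, FitFailureError, InsufficientDataError
from .headspace import ConcentrationMeasurement

logger = logging.getLogger(__name__)

#: Slack above 1 tolerated in observed fractions (measurement noise).
FRACTION_SLACK = 0.05

#: Mechanism reference exponents (Fickian, Case II) per particle geometry.
GEOMETRY_EXPONENTS: dict[str, tuple[float, float]] = {
    "sphere": (0.43, 0.85),
    "cylinder": (0.45, 0.89),
    "slab": (0.50, 1.00),
}

LABEL_QUASI_FICKIAN = "quasi-Fickian/combined"
LABEL_FICKIAN = "Fickian"
LABEL_ANOMALOUS = "anomalous (non-Fickian)"
LABEL_CASE_II = "Case II"
LABEL_SUPER_CASE_II = "super Case II"


@dataclass
class ReleaseCurve:
    """Fractional release versus time.

    ``m_infinity`` records the normalizing asymptote and where it came
    from (``"supplied"`` or ``"plateau-estimated"``).
    """

    times: np.ndarray  # min, strictly increasing
    fractions: np.ndarray  # M_t / M_inf
    m_infinity: float | None = None
    m_infinity_source: str | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.times.shape != self.fractions.shape or self.times.ndim != 1:
            raise ValueError("times and fractions must be 1-D arrays of equal length")
        if (np.diff(self.times) <= 0).any():
            raise ValueError("times must be strictly increasing")
        if (self.times < 0).any():
            raise ValueError("times must be >= 0")
        if (self.fractions < 0).any() or (self.fractions > 1 + FRACTION_SLACK).any():
            raise ValueError(f"fractions must lie in [0, 1 + {FRACTION_SLACK}]")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class FitOptions:
    """Tunables of the power-law fit; defaults are the package defaults."""

    max_iterations: int = 2000
    sse_tolerance: float = 1e-10  # absolute Nelder-Mead ftol on the SSE
    exclude_saturated: bool = True  # drop points with fraction >= 1 (model validity)
    early_window_cap: float | None = None  # e.g. 0.6 for the classical validity window
    rmse_divisor: str = "n"  # "n" or "n_minus_p"


@dataclass(frozen=True)
class GoodnessOfFit:
    r_squared: float
    r_squared_adj: float
    sse: float
    rmse: float


@dataclass(frozen=True)
class PeppasFit:
    """Fitted power-law parameters with goodness-of-fit statistics."""

    k: float  # min^-n
    n: float  # dimensionless kinetic order
    r_squared: float
    r_squared_adj: float
    sse: float
    rmse: float
    converged: bool
    n_points_used: int
    n_iterations: int = 0

    def __post_init__(self) -> None:
        if self.k <= 0 or self.n <= 0:
            raise ValueError("k and n must be > 0")
        if self.sse < 0:
            raise ValueError("sse must be >= 0")

    def predict(self, t) -> np.ndarray:
        return peppas_predict(self.k, self.n, t)


@dataclass(frozen=True)
class MechanismCall:
    """Transport-mechanism label determined solely by (n, geometry, tolerance)."""

    label: str
    geometry: str
    n: float
    tolerance: float


def peppas_predict(k: float, n: float, t) -> np.ndarray | float:
    """Evaluate k * t^n. May exceed 1; callers clip only for simulation."""
    if k <= 0 or n <= 0:
        raise ValueError("k and n must be > 0")
    t_arr = np.asarray(t, dtype=float)
    if (t_arr < 0).any():
        raise ValueError("time must be >= 0")
    out = k * t_arr**n
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def normalize_release(
    series: list[ConcentrationMeasurement] | np.ndarray,
    m_infinity: float | None = None,
    times: np.ndarray | None = None,
    plateau_rel_spread: float = 0.02,
    min_plateau_points: int = 3,
) -> ReleaseCurve:
    """Convert a measured release series to fractional form.

    When ``m_infinity`` is not supplied it is plateau-estimated: the
    longest trailing window (>= ``min_plateau_points`` points) whose
    relative spread (max-min over mean) stays below
    ``plateau_rel_spread`` is averaged. A series that never flattens
    and has no supplied asymptote cannot be normalized.
    """
    if times is None:
        t = np.array([m.time for m in series], dtype=float)
        v = np.array([m.concentration for m in series], dtype=float)
    else:
        t = np.asarray(times, dtype=float)
        v = np.asarray(series, dtype=float)
    if len(t) < 3:
        raise InsufficientDataError("need >= 3 points to normalize a release series")
    if (v < 0).any():
        raise ValueError("release values must be >= 0")
    order = np.argsort(t)
    t, v = t[order], v[order]

    if m_infinity is not None:
        if m_infinity <= 0:
            raise ValueError("m_infinity must be > 0")
        source = "supplied"
        m_inf = float(m_infinity)
    else:
        m_inf = _estimate_plateau(v, plateau_rel_spread, min_plateau_points)
        if m_inf is None:
            raise CannotNormalizeError(
                "series has no stationary plateau and no m_infinity was supplied"
            )
        source = "plateau-estimated"

    fractions = np.minimum(v / m_inf, 1 + FRACTION_SLACK)
    return ReleaseCurve(t, fractions, m_infinity=m_inf, m_infinity_source=source)


def _estimate_plateau(values: np.ndarray, rel_spread: float, min_points: int) -> float | None:
    """Mean of the longest stationary trailing window, or None."""
    best = None
    for start in range(len(values) - min_points + 1):
        window = values[start:]
        mean = window.mean()
        if mean <= 0:
            continue
        if (window.max() - window.min()) / mean < rel_spread:
            best = float(mean)
            break  # longest qualifying suffix wins
    return best


def goodness_of_fit(observed, predicted, n_params: int = 2,
                    rmse_divisor: str = "n") -> GoodnessOfFit:
    """R^2, adjusted R^2, SSE and RMSE of a fitted curve.

    r2_adj = 1 - (1 - r2)(N - 1)/(N - p - 1); RMSE uses divisor N by
    default (``"n_minus_p"`` switches to N - p).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predicted must be 1-D arrays of equal length")
    n = len(obs)
    if n < 3:
        raise InsufficientDataError("need >= 3 points for goodness of fit")
    if n_params >= n - 1:
        raise ValueError("n_params must be < N - 1")
    sse = float(((obs - pred) ** 2).sum())
    sst = float(((obs - obs.mean()) ** 2).sum())
    if sst == 0:
        raise ZeroDivisionError("R^2 undefined: observed values have zero variance")
    r2 = 1.0 - sse / sst
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)
    divisor = n if rmse_divisor == "n" else n - n_params
    rmse = float(np.sqrt(sse / divisor))
    return GoodnessOfFit(r_squared=r2, r_squared_adj=r2_adj, sse=sse, rmse=rmse)


def loglog_ols_estimate(times: np.ndarray, fractions: np.ndarray) -> tuple[float, float]:
    """Closed-form (k, n) from OLS on (ln t, ln f); exact on noiseless data."""
    lt = np.log(times)
    lf = np.log(fractions)
    n_hat, lnk_hat = np.polyfit(lt, lf, 1)
    return float(np.exp(lnk_hat)), float(n_hat)


def fit_peppas(curve: ReleaseCurve, options: FitOptions | None = None) -> PeppasFit:
    """Fit (k, n) by Nelder-Mead least squares in linear space.

    Points with t = 0 or fraction <= 0 are unusable (the log-log
    initializer needs positive values and t=0 carries no information
    about n); saturated points (fraction >= 1) are excluded by default.
    Deterministic for fixed input and options.
    """
    opts = options or FitOptions()
    t = curve.times
    f = curve.fractions
    mask = (t > 0) & (f > 0)
    if opts.exclude_saturated:
        mask &= f < 1
    if opts.early_window_cap is not None:
        mask &= f <= opts.early_window_cap
    t, f = t[mask], f[mask]
    if len(t) < 3:
        raise InsufficientDataError(
            f"need >= 3 usable points (t > 0, 0 < fraction < 1), got {len(t)}"
        )
    if np.allclose(f, f[0]):
        raise FitFailureError("degenerate data: all fractions equal")

    k0, n0 = loglog_ols_estimate(t, f)
    if k0 <= 0 or n0 <= 0:
        # fall back to a neutral start inside the admissible region
        k0, n0 = max(k0, 1e-6), 0.5

    def sse_of(theta: np.ndarray) -> float:
        k, n = np.exp(theta)
        with np.errstate(over="ignore"):
            resid = f - k * t**n
        return float(np.dot(resid, resid))

    result = optimize.minimize(
        sse_of,
        x0=np.log([k0, n0]),
        method="Nelder-Mead",
        options={
            "maxiter": opts.max_iterations,
            "fatol": opts.sse_tolerance,
            "xatol": 1e-10,
        },
    )
    k_hat, n_hat = (float(v) for v in np.exp(result.x))
    gof = goodness_of_fit(f, k_hat * t**n_hat, n_params=2, rmse_divisor=opts.rmse_divisor)
    fit = PeppasFit(
        k=k_hat,
        n=n_hat,
        r_squared=gof.r_squared,
        r_squared_adj=gof.r_squared_adj,
        sse=gof.sse,
        rmse=gof.rmse,
        converged=bool(result.success),
        n_points_used=len(t),
        n_iterations=int(result.nit),
    )
    if not result.success:
        raise FitFailureError(
            f"Nelder-Mead did not converge within {opts.max_iterations} iterations",
            best=fit,
        )
    return fit


def classify_mechanism(
    n: float, geometry: str = "sphere", tolerance: float = 0.02
) -> MechanismCall:
    """Label the transport mechanism from the fitted exponent.

    For spheres the reference exponents are 0.43 (Fickian) and 0.85
    (Case II). Exponents strictly within ``tolerance`` of a reference
    get that label; band edges fall in the neighbouring non-Fickian
    class, so a fitted n of reference + tolerance reads as anomalous
    transport rather than pure diffusion.
    """
    if n <= 0:
        raise ValueError("exponent n must be > 0")
    try:
        n_fickian, n_case2 = GEOMETRY_EXPONENTS[geometry]
    except KeyError:
        raise ValueError(
            f"unsupported geometry {geometry!r}; supported: {sorted(GEOMETRY_EXPONENTS)}"
        ) from None
    if abs(n - n_fickian) < tolerance:
        label = LABEL_FICKIAN
    elif abs(n - n_case2) < tolerance:
        label = LABEL_CASE_II
    elif n < n_fickian:
        label = LABEL_QUASI_FICKIAN
    elif n < n_case2:
        label = LABEL_ANOMALOUS
    else:
        label = LABEL_SUPER_CASE_II
    return MechanismCall(label=label, geometry=geometry, n=n, tolerance=tolerance)
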