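"""Per-profile polynomial regression and the fit/performance metrics.

Every profile is fit by ordinary least squares across polynomial degrees,
with time affinely scaled to [-1, 1] over the 24 h window before building
the Vandermonde system (raw-minute powers up to degree 6 are catastrophically
ill-conditioned).  Coefficients are reported in the scaled basis with the
scale parameters stored; predictions are basis-independent.

Three evaluation surfaces are supported:

* self fit - R2 and RMSE of a fit against its own training data;
* alternative-model performance - a sparse-scheme fit evaluated against the
  dense ground-truth data (:func:`metrics_against`);
* interpolation error - handled in :mod:`cortinterp.interpolation`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import polynomial as npoly

from .profiles import Profile, WINDOW_MAX, WINDOW_MIN
from .schemes import SamplingScheme

#: affine time scaling: u = (t - TIME_CENTER) / TIME_HALF_RANGE
TIME_CENTER = 720.0
TIME_HALF_RANGE = 720.0

MAX_DEGREE = 6


def scale_time(times) -> np.ndarray:
    """Map minutes in [0, 1440] onto the fitting basis [-1, 1]."""
    return (np.asarray(times, dtype=float) - TIME_CENTER) / TIME_HALF_RANGE


@dataclass(frozen=True)
class FitMetrics:
    """Coefficient of determination and root mean squared error."""

    r2: float
    rmse: float


@dataclass(frozen=True)
class PolyFit:
    """A fitted polynomial with residuals and self-fit metrics."""

    degree: int
    coefficients: np.ndarray  #: ascending powers, scaled-time basis
    scale_params: tuple[float, float]
    training_times: np.ndarray = field(repr=False)
    training_values: np.ndarray = field(repr=False)
    fitted_values: np.ndarray = field(repr=False)
    residuals: np.ndarray = field(repr=False)
    r2_self: float = 0.0
    rmse_self: float = 0.0
    source_scheme: str | None = None

    @property
    def n_obs(self) -> int:
        return len(self.training_times)

    @property
    def n_params(self) -> int:
        return self.degree + 1

    def residual_scale(self, mode: str = "rse") -> float:
        """Spread of the residuals used for stochastic error injection.

        ``"rse"`` (default) is the residual standard error
        ``sqrt(SSres / (n - p))``, the standard unbiased estimate of the
        residual sigma; ``"sample"`` is the plain sample sd (ddof=1), which
        shrinks mechanically as parameters are added.
        """
        ss = float(np.sum(self.residuals**2))
        if mode == "rse":
            dof = max(self.n_obs - self.n_params, 1)
        elif mode == "sample":
            dof = max(self.n_obs - 1, 1)
        else:
            raise ValueError(f"unknown residual scale mode {mode!r}")
        return float(np.sqrt(ss / dof))

    def to_dict(self) -> dict:
        return {
            "degree": self.degree,
            "coefficients": list(map(float, self.coefficients)),
            "scale_params": list(self.scale_params),
            "training_times": list(map(float, self.training_times)),
            "training_values": list(map(float, self.training_values)),
            "r2_self": self.r2_self,
            "rmse_self": self.rmse_self,
            "source_scheme": self.source_scheme,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PolyFit":
        times = np.asarray(d["training_times"], dtype=float)
        values = np.asarray(d["training_values"], dtype=float)
        coeffs = np.asarray(d["coefficients"], dtype=float)
        fitted = npoly.polyval(scale_time(times), coeffs)
        return cls(
            degree=int(d["degree"]),
            coefficients=coeffs,
            scale_params=tuple(d["scale_params"]),
            training_times=times,
            training_values=values,
            fitted_values=fitted,
            residuals=values - fitted,
            r2_self=float(d["r2_self"]),
            rmse_self=float(d["rmse_self"]),
            source_scheme=d.get("source_scheme"),
        )


def r_squared(observed: np.ndarray, predicted: np.ndarray) -> float:
    """1 - SSres/SStot; defined as 0 for zero-variance reference data."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn(
            "zero-variance reference data: R2 defined as 0", stacklevel=2
        )
        return 0.0
    ss_res = float(np.sum((observed - predicted) ** 2))
    return 1.0 - ss_res / ss_tot


def rmse(observed: np.ndarray, predicted: np.ndarray) -> float:
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    return float(np.sqrt(np.mean((observed - predicted) ** 2)))


def fit_polynomial(
    profile: Profile, degree: int, source_scheme: str | None = None
) -> PolyFit:
    """Ordinary least-squares polynomial fit of ``profile`` at ``degree``.

    Requires ``degree + 2`` or more points so at least one residual degree
    of freedom remains beyond an interpolating fit.
    """
    if not 1 <= degree <= MAX_DEGREE:
        raise ValueError(f"degree must be between 1 and {MAX_DEGREE}")
    if degree > len(profile) - 2:
        raise ValueError(
            f"degree {degree} too high for {len(profile)} points; "
            f"need at least degree + 2 points"
        )
    u = scale_time(profile.times)
    coeffs = npoly.polyfit(u, profile.values, degree)
    fitted = npoly.polyval(u, coeffs)
    residuals = profile.values - fitted
    return PolyFit(
        degree=degree,
        coefficients=coeffs,
        scale_params=(TIME_CENTER, TIME_HALF_RANGE),
        training_times=profile.times.copy(),
        training_values=profile.values.copy(),
        fitted_values=fitted,
        residuals=residuals,
        r2_self=r_squared(profile.values, fitted),
        rmse_self=rmse(profile.values, fitted),
        source_scheme=source_scheme,
    )


def predict(fit: PolyFit, times) -> np.ndarray:
    """Evaluate the fitted polynomial at ``times`` (minutes in [0, 1440])."""
    times = np.asarray(times, dtype=float)
    if np.any(times < WINDOW_MIN) or np.any(times > WINDOW_MAX):
        raise ValueError(
            f"prediction times must lie within [{WINDOW_MIN}, {WINDOW_MAX}]"
        )
    return npoly.polyval(scale_time(times), fit.coefficients)


def metrics_against(fit: PolyFit, reference: Profile) -> FitMetrics:
    """R2 and RMSE of ``fit`` evaluated against a reference profile.

    This is the alternative-model-vs-ground-truth-data surface: a fit from
    a sparse scheme is judged by how well it reproduces the full data.
    """
    if len(reference) < 2:
        raise ValueError("reference profile needs at least 2 points")
    pred = predict(fit, reference.times)
    return FitMetrics(
        r2=r_squared(reference.values, pred), rmse=rmse(reference.values, pred)
    )


def polynomial_validation(profile: Profile, scheme: SamplingScheme) -> list[PolyFit]:
    """Fits of degree 1 ... ``scheme.max_degree``, ascending.

    The profile must lie exactly on the scheme grid.
    """
    if len(profile) != scheme.n_points or not np.array_equal(
        profile.times, scheme.grid_minutes
    ):
        raise ValueError(
            f"profile does not lie on scheme {scheme.name} grid"
        )
    return [
        fit_polynomial(profile, d, source_scheme=scheme.name)
        for d in range(1, scheme.max_degree + 1)
    ]
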