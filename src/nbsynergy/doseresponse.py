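"""Viability-plate normalisation and log-logistic dose-response fitting.

The response model is the two-parameter "log(inhibitor) vs normalized
response" curve

    Y = 100 / (1 + 10**((X - logIC50) * HillSlope)),   X = log10(dose)

with the top plateau fixed at 100% (vehicle) and the bottom at 0%, so that
the predicted response at the IC50 is exactly 50%.  The model is fitted by
least squares with a deterministic multi-start policy; IC50 uncertainty
comes from a residual bootstrap.

The public surface follows the Model/Results pattern:
``LogLogisticModel(dose, response).fit()`` returns a
:class:`DoseResponseResults` carrying the parameter estimates, fit
diagnostics and ``bootstrap_ic50``.  ``fit_normalized_logistic`` and
``estimate_ic50`` are thin functional wrappers over the same machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "Well",
    "ViabilityPlate",
    "NormalizedResponse",
    "LogisticFit",
    "IC50Estimate",
    "PlateError",
    "normalize_plate",
    "LogLogisticModel",
    "DoseResponseResults",
    "fit_normalized_logistic",
    "estimate_ic50",
]

Role = Literal["treated", "vehicle", "blank"]


class PlateError(ValueError):
    """A plate violates its invariants (no vehicle wells, degenerate ODs...)."""


@dataclass(frozen=True)
class Well:
    """One microtiter well: a dose, an optical density and a role."""

    dose: float
    od: float
    replicate: int
    role: Role


@dataclass
class ViabilityPlate:
    """Raw per-well 490-nm optical densities with dose and control annotation.

    All wells share one concentration unit.  Treated wells at dose 0 are
    folded into the vehicle pool during normalisation.
    """

    wells: list[Well]
    drug_label: str = ""
    unit: str = "uM"

    def validate(self) -> None:
        if not self.wells:
            raise PlateError("empty plate")
        for w in self.wells:
            if w.dose < 0:
                raise PlateError(f"negative dose {w.dose}")
            if w.role not in ("treated", "vehicle", "blank"):
                raise PlateError(f"unknown well role {w.role!r}")
        if not self._vehicle_ods():
            raise PlateError("no vehicle wells on plate")

    def _vehicle_ods(self) -> list[float]:
        # dose-0 treated wells are vehicle-equivalent
        return [
            w.od
            for w in self.wells
            if w.role == "vehicle" or (w.role == "treated" and w.dose == 0)
        ]

    def _blank_ods(self) -> list[float]:
        return [w.od for w in self.wells if w.role == "blank"]


@dataclass(frozen=True)
class NormalizedResponse:
    """Percent viability relative to vehicle at one dose (vehicle = 100)."""

    dose: float
    response: float
    n_replicates: int
    sem: float


def normalize_plate(plate: ViabilityPlate) -> list[NormalizedResponse]:
    """Convert raw ODs to percent-of-vehicle viability.

    response(d) = 100 * (mean OD_treated(d) - mean OD_blank)
                       / (mean OD_vehicle - mean OD_blank)

    The blank term is 0 when the plate has no blank wells.  The per-dose SEM
    is computed over the per-well normalised responses.  The dose-0 point
    (the vehicle condition) is included with response exactly 100.
    """
    plate.validate()
    blank = float(np.mean(plate._blank_ods())) if plate._blank_ods() else 0.0
    vehicle = float(np.mean(plate._vehicle_ods()))
    denom = vehicle - blank
    if denom <= 0:
        raise PlateError(
            f"degenerate plate: vehicle mean {vehicle:g} <= blank mean {blank:g}"
        )

    by_dose: dict[float, list[float]] = {}
    for w in plate.wells:
        if w.role == "treated" and w.dose > 0:
            by_dose.setdefault(w.dose, []).append(w.od)

    out = []
    # vehicle anchor at dose 0, response 100 by construction
    veh = np.asarray(plate._vehicle_ods(), dtype=float)
    veh_resp = 100.0 * (veh - blank) / denom
    out.append(
        NormalizedResponse(
            dose=0.0,
            response=100.0,
            n_replicates=len(veh),
            sem=_sem(veh_resp),
        )
    )
    for dose in sorted(by_dose):
        ods = np.asarray(by_dose[dose], dtype=float)
        resp = 100.0 * (ods - blank) / denom
        out.append(
            NormalizedResponse(
                dose=dose,
                response=float(np.mean(resp)),
                n_replicates=len(ods),
                sem=_sem(resp),
            )
        )
    return out


def _sem(x: np.ndarray) -> float:
    if len(x) < 2:
        return 0.0
    return float(np.std(x, ddof=1) / np.sqrt(len(x)))


# ---------------------------------------------------------------------------
# model fitting


@dataclass(frozen=True)
class LogisticFit:
    """Fitted normalized log-logistic parameters.

    ``top``/``bottom`` are fixed at 100/0 in normalized mode; ``sse`` is the
    residual sum of squares at the optimum; ``bounds`` records the box the
    optimiser searched, in (logIC50, Hill) order.
    """

    log_ic50: float
    hill_slope: float
    sse: float
    converged: bool
    top: float = 100.0
    bottom: float = 0.0
    bounds: tuple[tuple[float, float], tuple[float, float]] = field(
        default=((-np.inf, np.inf), (0.05, 10.0))
    )

    @property
    def ic50(self) -> float:
        return 10.0 ** self.log_ic50

    def predict(self, dose):
        """Predicted percent viability at the given dose(s)."""
        x = np.log10(np.asarray(dose, dtype=float))
        return _model(x, self.log_ic50, self.hill_slope)


@dataclass(frozen=True)
class IC50Estimate:
    """IC50 with percentile-bootstrap bounds (plate units)."""

    ic50: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int
    n_failed: int = 0


def _model(logdose: np.ndarray, log_ic50: float, hill: float) -> np.ndarray:
    return 100.0 / (1.0 + 10.0 ** ((logdose - log_ic50) * hill))


_LN10 = np.log(10.0)


def _model_jac(logdose: np.ndarray, log_ic50: float, hill: float) -> np.ndarray:
    """Analytic Jacobian of the model wrt (logIC50, Hill)."""
    u = 10.0 ** ((logdose - log_ic50) * hill)
    common = 100.0 * _LN10 * u / (1.0 + u) ** 2
    return np.column_stack([common * hill, -common * (logdose - log_ic50)])


_HILL_BOUNDS = (0.05, 10.0)
_HILL_STARTS = (1.0, 0.5, 2.0)


class LogLogisticModel:
    """Normalized log-logistic dose-response model.

    Parameters
    ----------
    dose, response
        Paired arrays; dose in plate units, response in percent of vehicle.
        Zero doses are the normalisation anchor and are excluded from the
        fit (the model lives on log10 dose).
    variable_slope
        Fit the Hill slope (default) or fix it at 1.
    anchor_sem
        SEM (in percent points) of the vehicle condition that anchored the
        normalisation.  When given, the bootstrap propagates it as a common
        scale error across the plate; ``from_points`` picks it up from the
        dose-0 point automatically.
    """

    def __init__(
        self,
        dose,
        response,
        variable_slope: bool = True,
        anchor_sem: float | None = None,
        anchor_n: int | None = None,
    ):
        self.anchor_sem = anchor_sem
        self.anchor_n = anchor_n
        dose = np.asarray(dose, dtype=float)
        response = np.asarray(response, dtype=float)
        if dose.shape != response.shape:
            raise ValueError("dose and response must have equal length")
        keep = dose > 0
        self.dose = dose[keep]
        self.response = response[keep]
        self.variable_slope = bool(variable_slope)
        n_param = 2 if variable_slope else 1
        n_distinct = len(np.unique(self.dose))
        min_doses = 4 if variable_slope else 3
        if n_distinct < min_doses:
            raise ValueError(
                f"need >= {min_doses} distinct nonzero doses for "
                f"{n_param}-parameter fit, got {n_distinct}"
            )
        self.logdose = np.log10(self.dose)
        pad = 3.0
        self._log_ic50_bounds = (self.logdose.min() - pad, self.logdose.max() + pad)

    @classmethod
    def from_points(
        cls, points: Sequence[NormalizedResponse], variable_slope: bool = True
    ) -> "LogLogisticModel":
        anchor = next((p for p in points if p.dose == 0), None)
        return cls(
            [p.dose for p in points],
            [p.response for p in points],
            variable_slope=variable_slope,
            anchor_sem=anchor.sem if anchor else None,
            anchor_n=anchor.n_replicates if anchor else None,
        )

    @classmethod
    def from_plate(
        cls, plate: ViabilityPlate, variable_slope: bool = True
    ) -> "LogLogisticModel":
        return cls.from_points(normalize_plate(plate), variable_slope)

    # -- fitting -----------------------------------------------------------

    def _start_log_ic50(self) -> float:
        # dose whose response is nearest 50 seeds logIC50
        i = int(np.argmin(np.abs(self.response - 50.0)))
        return float(self.logdose[i])

    def fit(self) -> "DoseResponseResults":
        """Least-squares fit with deterministic multi-start initialisation.

        LogIC50 starts at the dose whose response is nearest 50; Hill starts
        at 1, 0.5 and 2 (variable-slope mode); the lowest-SSE solution wins,
        ties broken toward |Hill - 1|.  Optimiser failure is reported via
        ``converged=False``, never an exception.
        """
        if np.allclose(self.response, self.response[0]):
            fit = LogisticFit(
                log_ic50=np.nan,
                hill_slope=np.nan,
                sse=np.nan,
                converged=False,
                bounds=(self._log_ic50_bounds, _HILL_BOUNDS),
            )
            return DoseResponseResults(self, fit)
        x0_log = self._start_log_ic50()
        hill_starts = _HILL_STARTS if self.variable_slope else (1.0,)
        best: tuple[float, float, LogisticFit] | None = None
        for h0 in hill_starts:
            fit = self._fit_once(x0_log, h0)
            if fit is None:
                continue
            key = (fit.sse, abs(fit.hill_slope - 1.0))
            if best is None or key < (best[0], best[1]):
                best = (fit.sse, abs(fit.hill_slope - 1.0), fit)
        if best is None:
            fit = LogisticFit(
                log_ic50=np.nan,
                hill_slope=np.nan,
                sse=np.nan,
                converged=False,
                bounds=(self._log_ic50_bounds, _HILL_BOUNDS),
            )
            return DoseResponseResults(self, fit)
        return DoseResponseResults(self, best[2])

    def _fit_once(
        self, log_ic50_0: float, hill_0: float, y: np.ndarray | None = None
    ) -> LogisticFit | None:
        if y is None:
            y = self.response
        lb, ub = self._log_ic50_bounds

        if self.variable_slope:

            def resid(theta):
                return _model(self.logdose, theta[0], theta[1]) - y

            def jac(theta):
                return _model_jac(self.logdose, theta[0], theta[1])

            x0 = [np.clip(log_ic50_0, lb, ub), hill_0]
            bounds = ([lb, _HILL_BOUNDS[0]], [ub, _HILL_BOUNDS[1]])
        else:

            def resid(theta):
                return _model(self.logdose, theta[0], 1.0) - y

            def jac(theta):
                return _model_jac(self.logdose, theta[0], 1.0)[:, :1]

            x0 = [np.clip(log_ic50_0, lb, ub)]
            bounds = ([lb], [ub])

        try:
            sol = least_squares(resid, x0=x0, bounds=bounds, method="trf", jac=jac)
        except Exception:
            return None
        if not sol.success or not np.all(np.isfinite(sol.x)):
            return None
        hill = float(sol.x[1]) if self.variable_slope else 1.0
        return LogisticFit(
            log_ic50=float(sol.x[0]),
            hill_slope=hill,
            sse=float(2.0 * sol.cost),
            converged=True,
            bounds=(self._log_ic50_bounds, _HILL_BOUNDS),
        )


class DoseResponseResults:
    """Results of a :class:`LogLogisticModel` fit."""

    def __init__(self, model: LogLogisticModel, fit: LogisticFit):
        self.model = model
        self.params = fit

    @property
    def converged(self) -> bool:
        return self.params.converged

    @property
    def ic50(self) -> float:
        return self.params.ic50

    @property
    def sse(self) -> float:
        return self.params.sse

    def predict(self, dose):
        return self.params.predict(dose)

    @property
    def fittedvalues(self) -> np.ndarray:
        return _model(self.model.logdose, self.params.log_ic50, self.params.hill_slope)

    @property
    def resid(self) -> np.ndarray:
        return self.model.response - self.fittedvalues

    def bootstrap_ic50(self, n_boot: int = 1000, seed: int = 0) -> IC50Estimate:
        """Residual-bootstrap percentile interval for the IC50.

        Residuals of the full-data fit are resampled with replacement,
        inflated by sqrt(n/(n - p)) to undo the least-squares shrinkage, and
        added back to the fitted curve; when the model knows the vehicle
        anchor's SEM, each replicate additionally draws a common scale
        factor for the whole plate, since normalising to a noisy vehicle
        mean perturbs every response coherently.  Each replicate is
        refitted starting from the full-data parameters.  Replicates whose
        refit fails are dropped and counted (a warning is raised when more
        than 10% fail).  The percentile interval is widened, if needed, to
        include the point estimate.  Fully reproducible given ``seed``.
        """
        if n_boot < 0:
            raise ValueError("n_boot must be >= 0")
        if not self.converged:
            raise ValueError("cannot bootstrap an unconverged fit")
        ic50 = self.ic50
        if n_boot == 0:
            return IC50Estimate(ic50, ic50, ic50, 0, seed)
        rng = np.random.default_rng(seed)
        fitted = self.fittedvalues
        n = len(fitted)
        n_param = 2 if self.model.variable_slope else 1
        inflate = np.sqrt(n / (n - n_param)) if n > n_param else 1.0
        resid = self.resid * inflate
        anchor_rel = (
            self.model.anchor_sem / 100.0 if self.model.anchor_sem else 0.0
        )
        # the anchor error relative to its estimated SEM is t-distributed
        anchor_df = (self.model.anchor_n or 2) - 1
        boot = []
        n_failed = 0
        for _ in range(n_boot):
            y_star = fitted + rng.choice(resid, size=n, replace=True)
            if anchor_rel > 0:
                scale = 1.0 + anchor_rel * rng.standard_t(max(anchor_df, 1))
                y_star = y_star * scale
            refit = self.model._fit_once(
                self.params.log_ic50, self.params.hill_slope, y=y_star
            )
            if refit is None or not refit.converged:
                n_failed += 1
                continue
            boot.append(refit.ic50)
        if n_failed > 0.1 * n_boot:
            warnings.warn(
                f"{n_failed}/{n_boot} bootstrap refits failed", stacklevel=2
            )
        if not boot:
            return IC50Estimate(ic50, ic50, ic50, n_boot, seed, n_failed)
        lo, hi = np.percentile(boot, [2.5, 97.5])
        return IC50Estimate(
            ic50=ic50,
            ci_low=float(min(lo, ic50)),
            ci_high=float(max(hi, ic50)),
            n_boot=n_boot,
            seed=seed,
            n_failed=n_failed,
        )

    def summary(self) -> str:
        p = self.params
        lines = [
            "Normalized log-logistic dose-response fit",
            "-----------------------------------------",
            f"n points (dose > 0):  {len(self.model.dose)}",
            f"variable slope:       {self.model.variable_slope}",
            f"converged:            {p.converged}",
        ]
        if p.converged:
            lines += [
                f"LogIC50:              {p.log_ic50:.4f}",
                f"IC50:                 {p.ic50:.4g}",
                f"Hill slope:           {p.hill_slope:.4f}",
                f"SSE:                  {p.sse:.4g}",
            ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# functional wrappers


def fit_normalized_logistic(
    points: Sequence[NormalizedResponse], variable_slope: bool = True
) -> LogisticFit:
    """Fit the normalized log-logistic model to dose-response points."""
    return LogLogisticModel.from_points(points, variable_slope).fit().params


def estimate_ic50(
    points: Sequence[NormalizedResponse],
    n_boot: int = 1000,
    seed: int = 0,
    variable_slope: bool = True,
) -> IC50Estimate:
    """Full-data IC50 with a residual-bootstrap percentile interval."""
    res = LogLogisticModel.from_points(points, variable_slope).fit()
    if not res.converged:
        raise ValueError("dose-response fit did not converge")
    return res.bootstrap_ic50(n_boot=n_boot, seed=seed)
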