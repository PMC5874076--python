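"""Global kinetic fitting and 4PL calibration.

Two estimation problems live here:

* **Global tight-binding fits.** All initial-rate series of one
  experiment are fitted jointly by nonlinear least squares with shared
  parameters — (Ki, kcat) for the inhibition design (no decoy present),
  or (Kd, kcat) for the decoy-titration design with Km and Ki held at
  pre-determined values. Parameters are optimized on a log scale to
  enforce positivity; residuals are unweighted in velocity units.
* **Four-parameter logistic (4PL) calibration** for the plasma anti-FXa
  assay, with analytic inversion to quantify unknowns in
  drug-equivalent ng/mL.

Residuals are scaled to nM/s internally for optimizer conditioning;
reported RSS is in (M/s)^2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import kendalltau

from .equilibrium import NO_BINDING, EquilibriumSystem, solve_species_equilibrium
from .rates import RateMeasurement

__all__ = [
    "IdentifiabilityError",
    "FitError",
    "KineticDataset",
    "FitResult",
    "StandardCurve",
    "Quantification",
    "fit_ki_global",
    "fit_kd_global",
    "fit_4pl",
    "quantify_anti_fxa",
]

_VSCALE = 1e9  # residuals optimized in nM/s


class IdentifiabilityError(ValueError):
    """The experimental design cannot constrain the requested parameter."""


class FitError(RuntimeError):
    """A least-squares fit failed outright (degenerate data)."""


@dataclass
class KineticDataset:
    """Initial-rate measurements grouped for one global fit.

    ``design_kind`` is ``"ki_design"`` (inhibitor titration, no decoy,
    ≥2 enzyme levels) or ``"kd_design"`` (decoy titration at fixed
    enzyme, ≥2 inhibitor levels). ``Km`` (μM) is always fixed; ``Ki``
    (nM) must be supplied for the kd design.
    """

    measurements: list[RateMeasurement]
    design_kind: str
    Km: float = 82.2
    Ki: float | None = None

    def __post_init__(self) -> None:
        if self.design_kind not in ("ki_design", "kd_design"):
            raise ValueError(f"unknown design_kind {self.design_kind!r}")
        if self.Km <= 0:
            raise ValueError("Km must be > 0")
        if not self.measurements:
            raise ValueError("dataset has no measurements")
        if self.design_kind == "ki_design":
            if any(m.A_total != 0 for m in self.measurements):
                raise ValueError("ki_design requires A_total = 0 in every well")
            if len({m.E_total for m in self.measurements}) < 2:
                raise ValueError("ki_design requires >= 2 distinct enzyme levels")
        else:
            if len({m.E_total for m in self.measurements}) != 1:
                raise ValueError("kd_design requires a single fixed enzyme level")
            if len({m.I_total for m in self.measurements}) < 2:
                raise ValueError("kd_design requires >= 2 distinct inhibitor levels")

    def velocities(self) -> np.ndarray:
        v = [m.velocity for m in self.measurements]
        if any(x is None for x in v):
            raise ValueError("all measurements must carry velocities before fitting")
        return np.asarray(v, dtype=float)


@dataclass
class FitResult:
    """Outcome of one global fit.

    ``estimates``/``standard_errors`` are keyed by parameter name
    ("Ki_nM" or "Kd_nM", and "kcat_per_s"). SEs are Jacobian-based
    linear approximations at the optimum. ``rss`` is in (M/s)^2.
    """

    estimates: dict[str, float]
    standard_errors: dict[str, float]
    residuals: np.ndarray
    rss: float
    converged: bool
    n_iterations: int
    seed_or_start: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "estimates": self.estimates,
            "standard_errors": self.standard_errors,
            "rss_M2_per_s2": self.rss,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "start": self.seed_or_start,
        }


def _predicted_velocities(
    conditions: np.ndarray, Km: float, Ki: float, Kd: float, kcat: float
) -> np.ndarray:
    """kcat·[ES] (M/s) for an array of (E, I, A, S) well conditions."""
    out = np.empty(len(conditions))
    for j, (e, i, a, s) in enumerate(conditions):
        state = solve_species_equilibrium(
            EquilibriumSystem(E_total=e, I_total=i, A_total=a, S_total=s, Km=Km, Ki=Ki, Kd=Kd)
        )
        out[j] = kcat * state.ES * 1e-9
    return out


def _kcat_start(dataset: KineticDataset) -> float:
    """Closed-form Michaelis inversion of the uninhibited/undecoyed wells."""
    vals = []
    for m in dataset.measurements:
        if m.I_total == 0 and m.velocity:
            sat = m.S_total / (m.S_total + dataset.Km)
            if m.E_total > 0 and sat > 0:
                vals.append(m.velocity / (m.E_total * 1e-9 * sat))
    return float(np.mean(vals)) if vals else 100.0


def _half_effect_start(levels: np.ndarray, activities: np.ndarray) -> float:
    """Concentration nearest 50% residual activity; 1 nM fallback."""
    mask = levels > 0
    if not mask.any() or activities.size == 0:
        return 1.0
    idx = int(np.argmin(np.abs(activities[mask] - 0.5)))
    guess = float(levels[mask][idx])
    return guess if guess > 0 else 1.0


def _run_global_fit(
    dataset: KineticDataset,
    param_name: str,
    model: "callable",
    k0: float,
    kcat0: float,
) -> FitResult:
    v_obs = dataset.velocities()

    def residual(theta: np.ndarray) -> np.ndarray:
        k, kcat = np.exp(theta)
        return (v_obs - model(k, kcat)) * _VSCALE

    theta0 = np.log([k0, kcat0])
    sol = least_squares(residual, theta0, method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14)
    k_hat, kcat_hat = np.exp(sol.x)
    res_ms = sol.fun / _VSCALE
    rss = float(res_ms @ res_ms)

    n, p = v_obs.size, 2
    se = {param_name: math.nan, "kcat_per_s": math.nan}
    if n > p:
        jtj = sol.jac.T @ sol.jac
        try:
            cov_log = np.linalg.inv(jtj) * (sol.fun @ sol.fun) / (n - p)
            sd_log = np.sqrt(np.clip(np.diag(cov_log), 0, None))
            se = {param_name: k_hat * sd_log[0], "kcat_per_s": kcat_hat * sd_log[1]}
        except np.linalg.LinAlgError:
            pass

    return FitResult(
        estimates={param_name: float(k_hat), "kcat_per_s": float(kcat_hat)},
        standard_errors=se,
        residuals=res_ms,
        rss=rss,
        converged=bool(sol.success),
        n_iterations=int(sol.nfev),
        seed_or_start={param_name: k0, "kcat_per_s": kcat0},
    )


def fit_ki_global(dataset: KineticDataset) -> FitResult:
    """Jointly fit shared Ki (nM) and kcat (1/s) across all series.

    Km is fixed at ``dataset.Km``. Requires at least one well with
    inhibitor present, otherwise Ki is unidentifiable.
    """
    if dataset.design_kind != "ki_design":
        raise ValueError("fit_ki_global requires a ki_design dataset")
    levels = np.array([m.I_total for m in dataset.measurements])
    if not (levels > 0).any():
        raise IdentifiabilityError("Ki is unconstrained: no wells with inhibitor present")

    conditions = np.array(
        [[m.E_total, m.I_total, m.A_total, m.S_total] for m in dataset.measurements]
    )
    v_obs = dataset.velocities()
    v0 = v_obs[levels == 0].mean() if (levels == 0).any() else v_obs.max()
    ki0 = _half_effect_start(levels, v_obs / v0 if v0 > 0 else v_obs)
    kcat0 = _kcat_start(dataset)

    def model(ki: float, kcat: float) -> np.ndarray:
        return _predicted_velocities(conditions, dataset.Km, ki, NO_BINDING, kcat)

    return _run_global_fit(dataset, "Ki_nM", model, ki0, kcat0)


def fit_kd_global(dataset: KineticDataset) -> FitResult:
    """Jointly fit shared Kd (nM) and kcat (1/s) across inhibitor series.

    Km and Ki are fixed (``dataset.Km``, ``dataset.Ki``). Requires wells
    with both inhibitor and decoy present, otherwise Kd is
    unidentifiable.
    """
    if dataset.design_kind != "kd_design":
        raise ValueError("fit_kd_global requires a kd_design dataset")
    if dataset.Ki is None or dataset.Ki <= 0:
        raise ValueError("kd_design fitting requires the fixed Ki in the dataset")
    informative = [m for m in dataset.measurements if m.A_total > 0 and m.I_total > 0]
    if not informative:
        raise IdentifiabilityError(
            "Kd is unconstrained: no wells with both decoy and inhibitor present"
        )

    conditions = np.array(
        [[m.E_total, m.I_total, m.A_total, m.S_total] for m in dataset.measurements]
    )
    a_levels = np.array([m.A_total for m in dataset.measurements])
    v_obs = dataset.velocities()
    # Half-effect heuristic on the decoy axis within the inhibited wells.
    inh = conditions[:, 1] > 0
    v_ref = v_obs[~inh].mean() if (~inh).any() else v_obs.max()
    kd0 = _half_effect_start(a_levels[inh], v_obs[inh] / v_ref if v_ref > 0 else v_obs[inh])
    kcat0 = _kcat_start(dataset)

    def model(kd: float, kcat: float) -> np.ndarray:
        return _predicted_velocities(conditions, dataset.Km, dataset.Ki, kd, kcat)

    return _run_global_fit(dataset, "Kd_nM", model, kd0, kcat0)


# ---------------------------------------------------------------------------
# 4PL calibration
# ---------------------------------------------------------------------------


def _four_pl(c: np.ndarray, bottom: float, top: float, ec50: float, hill: float) -> np.ndarray:
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(c > 0, (c / ec50) ** hill, 0.0 if hill > 0 else np.inf)
    return bottom + (top - bottom) / (1.0 + ratio)


@dataclass
class StandardCurve:
    """Fitted 4PL calibration: OD = bottom + (top−bottom)/(1+(c/ec50)^hill).

    ``top`` is the OD of the zero-drug standard (uninhibited signal);
    ``ec50`` is in ng/mL. ``conc_min``/``conc_max`` record the standard
    range used to censor out-of-range unknowns.
    """

    bottom: float
    top: float
    ec50: float
    hill: float
    rss: float = 0.0
    converged: bool = True
    n_points: int = 0
    conc_min: float = 0.0
    conc_max: float = math.inf

    def __post_init__(self) -> None:
        if not self.top > self.bottom:
            raise ValueError("StandardCurve requires top > bottom")
        if self.ec50 <= 0:
            raise ValueError("StandardCurve requires ec50 > 0")

    def predict(self, conc: float | np.ndarray) -> float | np.ndarray:
        out = _four_pl(conc, self.bottom, self.top, self.ec50, self.hill)
        return float(out) if np.isscalar(conc) else out

    def inverse(self, od: float) -> float:
        """Analytic inversion; defined for od strictly inside (bottom, top)."""
        if not (self.bottom < od < self.top):
            raise ValueError("od outside the open interval (bottom, top)")
        ratio = (self.top - od) / (od - self.bottom)
        return self.ec50 * ratio ** (1.0 / self.hill)

    def __call__(self, conc: float | np.ndarray) -> float | np.ndarray:
        return self.predict(conc)


class Quantification(NamedTuple):
    """An inverted unknown: ng/mL value plus an out-of-range flag."""

    value: float
    out_of_range: bool


def fit_4pl(standards: Sequence[tuple[float, float]]) -> StandardCurve:
    """Least-squares 4PL fit to (concentration ng/mL, OD) standards.

    Requires ≥5 distinct concentration levels including 0. Warns (does
    not fail) if the standards are not monotone beyond noise; raises
    :class:`FitError` when the response is flat.
    """
    conc = np.array([c for c, _ in standards], dtype=float)
    od = np.array([o for _, o in standards], dtype=float)
    levels = np.unique(conc)
    if levels.size < 5:
        raise ValueError("fit_4pl requires >= 5 distinct concentration levels")
    if 0.0 not in levels:
        raise ValueError("fit_4pl requires a zero-concentration standard")
    if (conc < 0).any():
        raise ValueError("concentrations must be >= 0")
    if np.ptp(od) == 0:
        raise FitError("all ODs identical: 4PL fit is degenerate")

    tau = kendalltau(conc, od).statistic
    if tau is not None and not math.isnan(tau) and abs(tau) < 0.5:
        warnings.warn(
            "standards are not monotone beyond noise; 4PL calibration may be unreliable",
            stacklevel=2,
        )

    # Decreasing response (inhibition assay) => hill > 0; increasing => hill < 0.
    hill0 = 1.0 if (tau is None or math.isnan(tau) or tau <= 0) else -1.0
    bottom0, top0 = float(od.min()), float(od.max())
    span = top0 - bottom0
    mid_od = bottom0 + span / 2.0
    pos = levels[levels > 0]
    level_means = np.array([od[conc == lv].mean() for lv in pos])
    ec50_0 = float(pos[np.argmin(np.abs(level_means - mid_od))]) if pos.size else 1.0

    def residual(theta: np.ndarray) -> np.ndarray:
        bottom, top, log_ec50, hill = theta
        return od - _four_pl(conc, bottom, top, math.exp(log_ec50), hill)

    sol = least_squares(
        residual,
        np.array([bottom0 - 0.05 * span, top0 + 0.05 * span, math.log(ec50_0), hill0]),
        method="lm",
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
    )
    bottom, top, log_ec50, hill = sol.x
    if not top > bottom:
        raise FitError("4PL fit collapsed (top <= bottom)")
    return StandardCurve(
        bottom=float(bottom),
        top=float(top),
        ec50=float(math.exp(log_ec50)),
        hill=float(hill),
        rss=float(sol.fun @ sol.fun),
        converged=bool(sol.success),
        n_points=int(conc.size),
        conc_min=float(levels.min()),
        conc_max=float(levels.max()),
    )


def quantify_anti_fxa(od: float, curve: StandardCurve) -> Quantification:
    """Invert an unknown OD to drug-equivalent anti-FXa activity (ng/mL).

    ODs outside the invertible span (beyond ±5% of the curve amplitude)
    or mapping beyond the standard range are flagged and censored at the
    nearest curve limit: ODs at/above ``top`` read as the minimum
    standard concentration, ODs at/below ``bottom`` (or inverting past
    ``conc_max``) are censored at ``conc_max``.
    """
    if curve.hill <= 0:
        raise ValueError("quantification assumes a decreasing calibration (hill > 0)")
    span = curve.top - curve.bottom
    tol = 0.05 * span
    if od >= curve.top:
        return Quantification(curve.conc_min, od > curve.top + tol)
    if od <= curve.bottom:
        return Quantification(curve.conc_max, True)
    value = curve.inverse(od)
    if value > curve.conc_max:
        return Quantification(curve.conc_max, True)
    if value < curve.conc_min:
        return Quantification(curve.conc_min, True)
    return Quantification(value, False)
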