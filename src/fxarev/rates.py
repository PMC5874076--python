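"""Plate-reader slope ⇄ molar velocity conversion and the velocity model.

Kinetic plate readers report initial rates as mOD405/min. Beer–Lambert
with the chromophore extinction coefficient (ε405 = 9887 M⁻¹cm⁻¹ for the
p-nitroaniline leaving group) and the effective optical path of the well
(0.59 cm for a 200 μL reaction) converts those slopes to molar product
formation rates, which is what the kinetic model predicts:

    v = kcat · [ES]

with [ES] from the coupled-equilibrium solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .equilibrium import ConvergenceError, EquilibriumSystem, solve_species_equilibrium

__all__ = [
    "EXTINCTION_405",
    "PATH_LENGTH_CM",
    "PLATE_COLUMNS",
    "RateMeasurement",
    "slope_to_velocity",
    "velocity_to_slope",
    "model_velocity",
    "read_plate_csv",
    "write_plate_csv",
]

#: Molar extinction coefficient at 405 nm, M^-1 cm^-1.
EXTINCTION_405 = 9887.0
#: Effective optical path length of a 200 μL well, cm.
PATH_LENGTH_CM = 0.59

#: Required columns of the plate CSV schema.
PLATE_COLUMNS = [
    "series_id",
    "E_total_nM",
    "I_total_nM",
    "A_total_nM",
    "S_uM",
    "slope_mOD_min",
    "replicate",
]


@dataclass
class RateMeasurement:
    """One well's condition and measured initial rate.

    ``slope`` is the blank-subtracted rate in mOD405/min (blank
    subtraction is the caller's responsibility); ``velocity`` in M/s is
    populated once :func:`slope_to_velocity` has been applied.
    """

    series_id: str
    E_total: float  # nM
    I_total: float  # nM
    A_total: float  # nM
    S_total: float  # μM
    slope: float  # mOD405/min
    replicate: int = 0
    velocity: float | None = field(default=None)

    def __post_init__(self) -> None:
        if self.slope < 0:
            raise ValueError(f"slope must be >= 0 after blank subtraction, got {self.slope}")


def slope_to_velocity(
    slope: float, epsilon: float = EXTINCTION_405, path_cm: float = PATH_LENGTH_CM
) -> float:
    """Convert an initial rate in mOD405/min to M/s.

    velocity = (slope/1000 OD/min) / (ε · l) / 60; strictly linear.
    """
    if epsilon <= 0 or path_cm <= 0:
        raise ValueError("epsilon and path_cm must be > 0")
    if slope < 0:
        raise ValueError("slope must be >= 0")
    return (slope / 1000.0) / (epsilon * path_cm) / 60.0


def velocity_to_slope(
    velocity: float, epsilon: float = EXTINCTION_405, path_cm: float = PATH_LENGTH_CM
) -> float:
    """Exact inverse of :func:`slope_to_velocity` (used by the simulator)."""
    if epsilon <= 0 or path_cm <= 0:
        raise ValueError("epsilon and path_cm must be > 0")
    return velocity * 60.0 * epsilon * path_cm * 1000.0


def model_velocity(system: EquilibriumSystem, kcat: float) -> float:
    """Predicted molar velocity (M/s) for one well: kcat·[ES].

    [ES] comes from the coupled tight-binding equilibrium solver (nM,
    converted to M here). Raises :class:`ConvergenceError` if the solver
    did not close its mass balances.
    """
    if kcat <= 0:
        raise ValueError("kcat must be > 0")
    state = solve_species_equilibrium(system)
    if not state.converged:
        raise ConvergenceError(
            f"equilibrium solve did not converge (residual {state.residual_norm:.3e})"
        )
    return kcat * state.ES * 1e-9


def measurements_to_frame(measurements: list[RateMeasurement]) -> pd.DataFrame:
    rows = [
        {
            "series_id": m.series_id,
            "E_total_nM": m.E_total,
            "I_total_nM": m.I_total,
            "A_total_nM": m.A_total,
            "S_uM": m.S_total,
            "slope_mOD_min": m.slope,
            "replicate": m.replicate,
        }
        for m in measurements
    ]
    return pd.DataFrame(rows, columns=PLATE_COLUMNS)


def write_plate_csv(measurements: list[RateMeasurement], path: str | Path) -> None:
    """Write measurements in the documented plate CSV schema (UTF-8)."""
    measurements_to_frame(measurements).to_csv(path, index=False)


def read_plate_csv(path: str | Path) -> list[RateMeasurement]:
    """Read a plate CSV, validating the schema with row/column context."""
    df = pd.read_csv(path)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"plate CSV {path}: missing required columns {missing}")
    measurements: list[RateMeasurement] = []
    for i, row in df.iterrows():
        try:
            measurements.append(
                RateMeasurement(
                    series_id=str(row["series_id"]),
                    E_total=float(row["E_total_nM"]),
                    I_total=float(row["I_total_nM"]),
                    A_total=float(row["A_total_nM"]),
                    S_total=float(row["S_uM"]),
                    slope=float(row["slope_mOD_min"]),
                    replicate=int(row["replicate"]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"plate CSV {path}: invalid value in row {i}: {exc}") from exc
    return measurements
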