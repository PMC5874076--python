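"""Plasma reversal dose–response: normalization, prediction, molar arithmetic.

A decoy protein titrated into inhibitor-spiked plasma lowers the residual
anti-FXa activity. Measured curves are reported as percent of the mean
zero-decoy activity; predicted curves identify percent residual activity
with the percent of inhibitor left unbound by the decoy (activity is
assumed linear in free inhibitor over the assay range — the minimal
assay-transfer assumption, stated here explicitly).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._report import DerivedValue, round_half_up
from .equilibrium import unbound_inhibitor_fraction

__all__ = [
    "EDOXABAN_MW",
    "ANDEXANET_MW",
    "ReversalCurvePoint",
    "normalize_to_zero_decoy",
    "level_summary",
    "predict_reversal_curve",
    "molar_ratio",
    "mass_to_molar",
]

#: Molecular mass of edoxaban free base, g/mol.
EDOXABAN_MW = 548.06
#: Effective molecular mass of the decoy protein andexanet alfa, g/mol
#: (consistent with reported μg/mL ↔ μM pairings for the glycoprotein).
ANDEXANET_MW = 41_000.0


@dataclass(frozen=True)
class ReversalCurvePoint:
    """One plasma well on the reversal dose–response curve."""

    A_total: float  # decoy concentration, μM
    raw_activity: float  # anti-FXa activity, ng/mL
    percent_activity: float  # % of the zero-decoy mean

    def __post_init__(self) -> None:
        if self.percent_activity < 0:
            raise ValueError("percent_activity must be >= 0")


def normalize_to_zero_decoy(
    points: Iterable[tuple[float, float]],
) -> list[ReversalCurvePoint]:
    """Express raw activities as percent of the mean zero-decoy activity.

    ``points`` are (A_total μM, raw anti-FXa ng/mL) pairs with at least
    one replicate at A_total = 0 whose mean is positive.
    """
    pts = [(float(a), float(raw)) for a, raw in points]
    zero = [raw for a, raw in pts if a == 0.0]
    if not zero:
        raise ValueError("normalization requires at least one zero-decoy replicate")
    baseline = float(np.mean(zero))
    if baseline <= 0:
        raise ValueError(f"zero-decoy mean must be positive, got {baseline}")
    return [
        ReversalCurvePoint(A_total=a, raw_activity=raw, percent_activity=100.0 * raw / baseline)
        for a, raw in pts
    ]


def level_summary(points: Sequence[ReversalCurvePoint]) -> pd.DataFrame:
    """Replicate mean ± SD of percent activity per decoy level."""
    df = pd.DataFrame(
        {
            "A_total_uM": [p.A_total for p in points],
            "percent_activity": [p.percent_activity for p in points],
        }
    )
    out = (
        df.groupby("A_total_uM")["percent_activity"]
        .agg(mean_percent="mean", sd_percent="std", n="count")
        .reset_index()
    )
    return out


def predict_reversal_curve(
    I_total: float, A_grid: Sequence[float], Kd: float
) -> np.ndarray:
    """Predicted percent residual activity over a decoy grid.

    ``I_total`` and ``A_grid`` in μM, ``Kd`` in nM. Returns percent
    unbound inhibitor at each decoy level: 100 at A = 0, monotone
    nonincreasing in A.
    """
    if I_total <= 0:
        raise ValueError("I_total must be > 0")
    if Kd <= 0:
        raise ValueError("Kd must be > 0")
    kd_um = Kd * 1e-3
    return np.array(
        [100.0 * unbound_inhibitor_fraction(I_total, float(a), kd_um) for a in A_grid]
    )


def molar_ratio(decoy_conc: float, inhibitor_conc: float) -> DerivedValue:
    """Decoy:inhibitor molar ratio (both μM), reported to 1 decimal."""
    if inhibitor_conc <= 0:
        raise ValueError("inhibitor_conc must be > 0")
    exact = decoy_conc / inhibitor_conc
    return DerivedValue(round_half_up(exact, 1), exact)


def mass_to_molar(conc_ng_ml: float, molecular_mass: float) -> DerivedValue:
    """Convert ng/mL to μM; reported to 2 decimals, exact value alongside."""
    if molecular_mass <= 0:
        raise ValueError("molecular_mass must be > 0")
    exact = conc_ng_ml / molecular_mass  # (ng/mL)/(g/mol) = μM
    return DerivedValue(round_half_up(exact, 2), exact)
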