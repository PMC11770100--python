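"""Droplet dosing and concentration-verification math.

A larva is encapsulated in a small medium droplet (≈5.56 µL in the reference
chip design); dosing injects stock drug solution into that droplet. Assuming
the droplet starts drug-free and mixing is complete, the final concentration
after injecting volume V_inj of stock S into droplet volume V is

    C_final = S · V_inj / (V + V_inj)

which inverts to V_inj = C_target · V / (S − C_target). In-droplet
concentrations are verified photometrically through a Beer–Lambert line
A = ε·C + b fitted to standard solutions; the molar-absorptivity slope ε
then converts measured absorbance back to concentration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DropletSpec",
    "Calibration",
    "injection_volume",
    "gradient_plan",
    "fit_calibration",
    "absorbance_to_concentration",
]


@dataclass(frozen=True)
class DropletSpec:
    """A medium droplet holding one larva."""

    volume: float = 5.56  # µL
    concentration: float = 0.0  # µM, drug already in the droplet

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError("droplet volume must be positive")
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")


@dataclass(frozen=True)
class Calibration:
    """Beer–Lambert concentration–absorbance line."""

    slope: float  # absorbance/µM (molar absorptivity × path length)
    intercept: float  # absorbance
    r_squared: float
    concentration_range: tuple[float, float]  # µM, fitted support

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")


def injection_volume(droplet: DropletSpec, stock: float, target: float) -> float:
    """Stock volume (µL) to inject for a target in-droplet concentration.

    Solves target = stock·V_inj/(V + V_inj) for V_inj; requires a drug-free
    droplet and 0 ≤ target < stock (the stock concentration is the ceiling
    of any achievable mixture).
    """
    if droplet.concentration != 0:
        raise ValueError("droplet must be drug-free before injection")
    if stock <= 0:
        raise ValueError("stock concentration must be positive")
    if not 0 <= target < stock:
        raise ValueError(
            f"target {target} µM is unreachable from a {stock} µM stock (need 0 <= target < stock)"
        )
    v_inj = target * droplet.volume / (stock - target)
    # forward-mixing sanity check; exact by algebra, cheap to assert
    mixed = stock * v_inj / (droplet.volume + v_inj) if v_inj > 0 else 0.0
    assert abs(mixed - target) <= 1e-9 * max(target, 1.0)
    return v_inj


def gradient_plan(
    droplet: DropletSpec, stock: float, targets: "list[float] | np.ndarray"
) -> list[tuple[float, float]]:
    """Injection volumes for a series of target concentrations.

    Returns (target, V_inj) pairs in the given order; any target at or above
    the stock concentration raises.
    """
    return [(float(t), injection_volume(droplet, stock, float(t))) for t in targets]


def fit_calibration(table: pd.DataFrame, through_origin: bool = False) -> Calibration:
    """Fit the Beer–Lambert line A = slope·C + intercept by least squares.

    ``table`` needs columns ``concentration_uM`` and ``absorbance`` with at
    least 3 distinct concentrations. ``through_origin`` constrains the
    intercept to zero (the strict Beer–Lambert form). R² is 1 − SS_res/SS_tot.
    """
    conc = np.asarray(table["concentration_uM"], dtype=float)
    ab = np.asarray(table["absorbance"], dtype=float)
    if np.unique(conc).size < 3:
        raise ValueError("need at least 3 distinct concentrations to calibrate")
    if through_origin:
        slope = float(np.dot(conc, ab) / np.dot(conc, conc))
        intercept = 0.0
    else:
        slope, intercept = (float(v) for v in np.polyfit(conc, ab, 1))
    residuals = ab - (slope * conc + intercept)
    ss_res = float(np.dot(residuals, residuals))
    ss_tot = float(np.sum((ab - ab.mean()) ** 2))
    r_squared = 1.0 if ss_tot == 0 else max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    return Calibration(
        slope=slope,
        intercept=intercept,
        r_squared=r_squared,
        concentration_range=(float(conc.min()), float(conc.max())),
    )


def absorbance_to_concentration(absorbance: float, cal: Calibration) -> float:
    """Invert the calibration line: C = (A − intercept)/slope, in µM.

    Warns when the result falls outside the fitted concentration range,
    where the linear law is extrapolated.
    """
    conc = (absorbance - cal.intercept) / cal.slope
    lo, hi = cal.concentration_range
    if not lo <= conc <= hi:
        warnings.warn(
            f"concentration {conc:.4g} µM is outside the calibrated range [{lo:g}, {hi:g}] µM",
            stacklevel=2,
        )
    return conc
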