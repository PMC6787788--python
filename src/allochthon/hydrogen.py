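"""Nonexchangeable δ2H determination.

Tissue hydrogen partly exchanges with ambient moisture, so a measured δ2H
mixes an exchangeable fraction *f_ex* (which takes the isotope value of the
equilibration water) with the ecologically meaningful nonexchangeable value
δ2H_n:

    δ2H_total = f_ex · δ2H_water + (1 − f_ex) · δ2H_n

Two treatments are provided, matching laboratory practice:

* two-water solve — the sample is equilibrated separately with two waters of
  strongly contrasting composition (here −435.5‰ and +945‰), giving two
  measured totals and a closed-form solve for (f_ex, δ2H_n); used for
  materials of unknown exchangeability (invertebrates, plants);
* comparative equilibration — keratin reference materials of matched
  exchangeability (CBS, −157.0‰; KHS, −35.3‰) are equilibrated alongside the
  samples and a two-point linear calibration maps measured to known values;
  used for fish muscle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence
import warnings

#: equilibration waters used for the two-water treatment (per-mil vs VSMOW)
DEFAULT_WATERS = (-435.5, 945.0)

#: keratin reference materials: name -> accepted nonexchangeable δ2H
DEFAULT_REFERENCES = {"CBS": -157.0, "KHS": -35.3}

#: laboratory fish-muscle replicate SD used by the QA/QC report (per-mil)
QAQC_REPLICATE_SD = 1.0

#: analytical-noise tolerance on f_ex outside [0, 1] before it is an error
F_EX_TOLERANCE = 0.02


class InfeasibleExchangeError(ValueError):
    """Measured totals imply an exchangeable fraction outside [0, 1]."""


class DegenerateCalibrationError(ValueError):
    """Calibration anchors coincide; no two-point line exists."""


@dataclass(frozen=True)
class EquilibrationRun:
    """Measured δ2H totals of one sample under known equilibration waters."""

    sample_id: str
    d2H_total_A: float
    water_A: float
    d2H_total_B: float | None = None
    water_B: float | None = None

    def __post_init__(self) -> None:
        if self.water_B is not None and self.water_A == self.water_B:
            raise ValueError("equilibration waters A and B must differ")
        for v in (self.d2H_total_A, self.d2H_total_B):
            if v is not None and not math.isfinite(v):
                raise ValueError("measured totals must be finite")


@dataclass(frozen=True)
class ReferencePair:
    """Two reference materials anchoring a comparative-equilibration batch."""

    names: tuple[str, str] = ("CBS", "KHS")
    known_values: tuple[float, float] = (DEFAULT_REFERENCES["CBS"], DEFAULT_REFERENCES["KHS"])
    measured_values: tuple[float, float] = (DEFAULT_REFERENCES["CBS"], DEFAULT_REFERENCES["KHS"])

    def __post_init__(self) -> None:
        if self.known_values[0] == self.known_values[1]:
            raise DegenerateCalibrationError("known reference values must differ")
        if self.measured_values[0] == self.measured_values[1]:
            raise DegenerateCalibrationError("measured reference values must differ")


def forward_two_water(f_ex: float, d2H_n: float, water: float) -> float:
    """Forward mixing model: measured total from (f_ex, δ2H_n, water)."""
    return f_ex * water + (1.0 - f_ex) * d2H_n


def solve_two_water(run: EquilibrationRun) -> tuple[float, float]:
    """Solve the two-water equilibration for (f_ex, δ2H_n).

    Subtracting the mixing equation under the two waters cancels δ2H_n:

        f_ex = (δ_total_A − δ_total_B) / (water_A − water_B)
        δ2H_n = (δ_total_A − f_ex · water_A) / (1 − f_ex)

    f_ex slightly outside [0, 1] (within ±0.02, analytical noise) is clipped
    with a warning; beyond that the measurements are inconsistent and an
    :class:`InfeasibleExchangeError` is raised.
    """
    if run.d2H_total_B is None or run.water_B is None:
        raise ValueError("two-water solve requires both waters and both measured totals")
    f_ex = (run.d2H_total_A - run.d2H_total_B) / (run.water_A - run.water_B)
    if not (-F_EX_TOLERANCE <= f_ex <= 1.0 + F_EX_TOLERANCE):
        raise InfeasibleExchangeError(
            f"{run.sample_id}: f_ex={f_ex:.4f} outside [0, 1] beyond tolerance "
            f"{F_EX_TOLERANCE}; measured totals inconsistent with waters"
        )
    if f_ex != min(max(f_ex, 0.0), 1.0):
        warnings.warn(f"{run.sample_id}: f_ex={f_ex:.4f} clipped into [0, 1]", stacklevel=2)
        f_ex = min(max(f_ex, 0.0), 1.0)
    if f_ex > 0.99:
        raise InfeasibleExchangeError(
            f"{run.sample_id}: f_ex≈1, nonexchangeable δ2H undetermined (division guard)"
        )
    d2H_n = (run.d2H_total_A - f_ex * run.water_A) / (1.0 - f_ex)
    return f_ex, d2H_n


def calibrate_comparative(refs: ReferencePair, measured_samples: Sequence[float]
                          ) -> list[float]:
    """Two-point comparative-equilibration calibration.

    Fits the affine map through the two (measured, known) reference points and
    applies it to every sample; by construction the map returns the accepted
    reference values exactly at the reference measurements.
    """
    (m1, m2) = refs.measured_values
    (k1, k2) = refs.known_values
    slope = (k2 - k1) / (m2 - m1)
    intercept = k1 - slope * m1
    return [slope * x + intercept for x in measured_samples]


def qaqc_report(replicates: Sequence[float], expected_sd: float = QAQC_REPLICATE_SD) -> dict:
    """Batch QA/QC: replicate SD of the laboratory standard vs the expected ±1.0‰.

    Reported only; never blocks processing.
    """
    n = len(replicates)
    if n < 2:
        return {"n": n, "sd": float("nan"), "expected_sd": expected_sd, "within_spec": None}
    mean = sum(replicates) / n
    sd = math.sqrt(sum((x - mean) ** 2 for x in replicates) / (n - 1))
    return {"n": n, "sd": sd, "expected_sd": expected_sd, "within_spec": sd <= 2 * expected_sd}
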