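"""Reflectometer calibration: incident-intensity ratio and RPF estimation.

Two procedures.  First, the incident-intensity voltage ratio
V0(590)/V0(780): the high-gain measurement channel cannot view the LED
outputs directly, so a low-gain twin system measures the probe against
the filter (V0') and against a Delrin reflection standard (VR'), and the
high-gain system measures the same Delrin reflection (VR); then
V0 = VR * V0' / VR' per wavelength, and only ratios enter the estimator.

Second, the differential pathlength factor RPF = PF(780)/PF(590): during
a venous occlusion the attenuation change at each wavelength is
proportional to PF(lambda) * mueff(lambda), so the slope of
delta-ln Ve(780) against delta-ln Ve(590), multiplied by the ratio
mueff(590)/mueff(780) = 14.87, is RPF.  The regression runs over a
window 10-70 s after cuff inflation (the first 10 s excludes the
inflation transient), with each channel referenced to its mean
pre-inflation baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .lrbc_core import DEFAULT_MUEFF_RATIO

#: Occlusion regression window, seconds after the start of cuff inflation.
DEFAULT_OCCLUSION_WINDOW = (10.0, 70.0)


@dataclass(frozen=True)
class CalibrationReadings:
    """The six lock-in voltages of the incident-intensity calibration.

    ``v0p_*``: low-gain probe-to-filter readings (V0'); ``vrp_*``:
    low-gain Delrin-reflection readings (VR'); ``vr_*``: high-gain
    Delrin-reflection readings (VR).  Arbitrary units; all ratios.
    """

    v0p_590: float
    vrp_590: float
    v0p_780: float
    vrp_780: float
    vr_590: float
    vr_780: float

    def __post_init__(self) -> None:
        for nm in ("v0p_590", "vrp_590", "v0p_780", "vrp_780", "vr_590", "vr_780"):
            if not getattr(self, nm) > 0:
                raise ValueError(f"{nm} must be strictly positive")


def v0_ratio(readings: CalibrationReadings) -> float:
    """Incident-intensity voltage ratio V0(590)/V0(780).

    With V0(lambda) = VR(lambda) * V0'(lambda) / VR'(lambda), the ratio is
    (VR(590)/VR(780)) * (V0'(590)/VR'(590)) / (V0'(780)/VR'(780));
    invariant to any common rescaling of the readings.
    """
    return ((readings.vr_590 / readings.vr_780)
            * (readings.v0p_590 / readings.vrp_590)
            / (readings.v0p_780 / readings.vrp_780))


def v0_ratio_from_ratios(v0p_over_vrp_590: float, v0p_over_vrp_780: float,
                         vr_ratio: float) -> float:
    """V0(590)/V0(780) from pre-averaged calibration ratios.

    Convenience form taking V0'/VR' per wavelength and VR(590)/VR(780)
    directly, e.g. bench averages over repeated readings.
    """
    if min(v0p_over_vrp_590, v0p_over_vrp_780, vr_ratio) <= 0:
        raise ValueError("calibration ratios must be strictly positive")
    return vr_ratio * v0p_over_vrp_590 / v0p_over_vrp_780


def estimate_rpf(demod, inflation_time: float,
                 baseline_window: tuple[float, float] | None = None,
                 occlusion_window: tuple[float, float] = DEFAULT_OCCLUSION_WINDOW,
                 mueff_ratio: float = DEFAULT_MUEFF_RATIO) -> float:
    """Differential pathlength factor from an occlusion recording.

    Parameters
    ----------
    demod : DemodulatedSeries
        Demodulated two-channel envelope series (shared time base).
    inflation_time : float
        Absolute time of the start of cuff inflation, s (t = 0 of the
        occlusion clock).
    baseline_window : (float, float), optional
        Absolute time window over which the per-channel baseline mean is
        taken; defaults to everything before ``inflation_time``.
    occlusion_window : (float, float)
        Regression window in seconds after inflation; default 10-70 s.
    mueff_ratio : float
        mueff(590)/mueff(780) of red blood cells; default 14.87.

    Returns the OLS slope (with intercept) of delta-ln Ve(780) against
    delta-ln Ve(590) over the occlusion window, multiplied by
    ``mueff_ratio``.  Per-channel gains cancel in delta-ln, so the
    estimate is gain-invariant.
    """
    time = np.asarray(demod.time, float)
    v590 = np.asarray(demod.ve_590, float)
    v780 = np.asarray(demod.ve_780, float)
    if np.any(v590 <= 0) or np.any(v780 <= 0):
        raise ValueError("all demodulated voltages must be strictly positive")
    if baseline_window is None:
        baseline_window = (time[0], inflation_time)
    base = (time >= baseline_window[0]) & (time < baseline_window[1])
    occ = ((time >= inflation_time + occlusion_window[0])
           & (time <= inflation_time + occlusion_window[1]))
    if base.sum() < 2 or occ.sum() < 2:
        raise ValueError("baseline and occlusion windows each need >= 2 samples")
    dln590 = np.log(v590[occ]) - np.log(np.mean(v590[base]))
    dln780 = np.log(v780[occ]) - np.log(np.mean(v780[base]))
    if np.ptp(dln590) == 0:
        raise ValueError("degenerate regression: delta-ln Ve(590) has zero variance")
    slope = stats.linregress(dln590, dln780).slope
    return slope * mueff_ratio
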