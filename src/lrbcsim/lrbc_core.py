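"""Two-wavelength estimation of the red-blood-cell pathlength index LRBC.

The model is a modified Beer-Lambert decomposition of diffuse-reflectance
attenuation: at wavelengths where bloodless-tissue attenuation and
geometric losses are nearly wavelength-independent, the attenuation
difference between two wavelengths isolates the red-blood-cell term,

    A(l1) - A(l2) = LRBC * [PF(l1) * mueff(l1) - PF(l2) * mueff(l2)],

where ``mueff`` is the effective attenuation coefficient of red blood
cells at each wavelength and ``PF`` a wavelength-dependent pathlength
factor.  Working near hemoglobin isosbestic points (590 and 780 nm here)
removes the oxygen-saturation dependence.  With PF(590) fixed at 1 and
PF(780) equal to the differential pathlength factor RPF, LRBC is obtained
directly from measured (or simulated) emerging intensities:

    LRBC = [ln(I0(590)/I0(780)) + ln(Ie(780)/Ie(590))]
           / [mueff(590) - RPF * mueff(780)].

Natural logarithms throughout; a base-10 convention would rescale LRBC by
ln 10.  LRBC is carried in mm internally and reported in micrometers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

#: Ratio mueff(590 nm) / mueff(780 nm) for red blood cells, from published
#: whole-blood optical constants.
DEFAULT_MUEFF_RATIO = 14.87

#: Effective attenuation coefficient of red blood cells at 590 nm, mm^-1.
#: Only the 590/780 ratio is tightly constrained by published blood optics;
#: the absolute scale is calibrated so the canonical baseline skin model
#: yields LRBC of ~16 um at the 0.5-1.2 mm detection window, and is
#: configuration-exposed (see docs/methods.md for the calibration).
DEFAULT_MUEFF_590 = 41.0

#: Differential pathlength factor PF(780)/PF(590) (occlusion-calibrated).
DEFAULT_RPF = 2.20

#: Incident-intensity voltage ratio V0(590)/V0(780) of the reference
#: reflectometer calibration.
DEFAULT_V0_RATIO = 1.21


@dataclass(frozen=True)
class LrbcConstants:
    """Constants parameterizing the LRBC estimator.

    ``mueff_590`` and ``mueff_780`` are the effective attenuation
    coefficients of red blood cells (mm^-1) at the two working
    wavelengths; their ratio is pinned to ``mueff_ratio``.  ``PF_590`` is
    the 590 nm pathlength factor (fixed at 1 by convention, so LRBC is
    proportional to the true geometric pathlength), ``RPF`` the
    differential pathlength factor PF(780)/PF(590), and ``v0_ratio`` the
    incident-intensity (voltage) ratio V0(590)/V0(780) used with
    voltage-mode inputs.
    """

    mueff_590: float = DEFAULT_MUEFF_590
    mueff_ratio: float = DEFAULT_MUEFF_RATIO
    mueff_780: float = field(default=DEFAULT_MUEFF_590 / DEFAULT_MUEFF_RATIO)
    PF_590: float = 1.0
    RPF: float = DEFAULT_RPF
    v0_ratio: float = DEFAULT_V0_RATIO

    def __post_init__(self) -> None:
        for name in ("mueff_590", "mueff_ratio", "mueff_780", "PF_590", "RPF", "v0_ratio"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not math.isclose(self.mueff_590, self.mueff_ratio * self.mueff_780,
                            rel_tol=1e-9, abs_tol=1e-9):
            raise ValueError(
                "inconsistent constants: mueff_590 must equal mueff_ratio * mueff_780"
            )
        if not self.denominator > 0:
            raise ValueError(
                "PF_590*mueff_590 - RPF*mueff_780 must be positive; "
                "the estimator is undefined otherwise"
            )

    @classmethod
    def from_ratio(cls, mueff_590: float = DEFAULT_MUEFF_590,
                   mueff_ratio: float = DEFAULT_MUEFF_RATIO, **kwargs) -> "LrbcConstants":
        """Build constants from the 590 nm value and the 590/780 ratio."""
        return cls(mueff_590=mueff_590, mueff_ratio=mueff_ratio,
                   mueff_780=mueff_590 / mueff_ratio, **kwargs)

    @property
    def denominator(self) -> float:
        """PF(590)*mueff(590) - RPF*mueff(780), mm^-1."""
        return self.PF_590 * self.mueff_590 - self.RPF * self.mueff_780


@dataclass
class LrbcSeries:
    """A time series of LRBC values (micrometers) with phase annotations."""

    time: np.ndarray
    lrbc: np.ndarray
    annotations: np.ndarray | None = None
    constants: LrbcConstants | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.lrbc = np.asarray(self.lrbc, dtype=float)
        if self.time.shape != self.lrbc.shape:
            raise ValueError("time and lrbc must have the same shape")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")


def attenuation(i0: float, ie: float) -> float:
    """Attenuation ln(I0/Ie) of light emerging from a medium (natural log)."""
    if i0 <= 0 or ie <= 0:
        raise ValueError("intensities must be strictly positive")
    return math.log(i0 / ie)


def lrbc_from_intensities(i0_ratio_590_over_780: float, ie_590: float, ie_780: float,
                          constants: LrbcConstants | None = None) -> float:
    """LRBC (micrometers) from emerging intensities at 590 and 780 nm.

    ``i0_ratio_590_over_780`` is I0(590)/I0(780); in simulations where both
    wavelengths launch equal photon numbers it is exactly 1 and the term
    vanishes.  A negative result (physically impossible, but produced by
    e.g. instrument drift) is returned with a warning rather than clipped.
    """
    if constants is None:
        constants = LrbcConstants()
    if i0_ratio_590_over_780 <= 0 or ie_590 <= 0 or ie_780 <= 0:
        raise ValueError("intensities and intensity ratio must be strictly positive")
    numerator = math.log(i0_ratio_590_over_780) + math.log(ie_780 / ie_590)
    lrbc_mm = numerator / constants.denominator
    if lrbc_mm < 0:
        warnings.warn(f"negative LRBC ({lrbc_mm * 1e3:.3g} um): check inputs for drift",
                      stacklevel=2)
    return lrbc_mm * 1e3  # mm -> um


def lrbc_from_voltages(demod, constants: LrbcConstants | None = None,
                       annotations: np.ndarray | None = None) -> LrbcSeries:
    """Per-sample LRBC series from demodulated two-wavelength voltages.

    ``demod`` is a :class:`~lrbcsim.occlusion_synthesis.DemodulatedSeries`
    (or anything with ``time``, ``ve_590`` and ``ve_780`` arrays on a
    shared time base).  Nonpositive voltage samples are flagged invalid
    (NaN in the output) rather than silently dropped, so gaps remain
    visible in the series.
    """
    if constants is None:
        constants = LrbcConstants()
    v590 = np.asarray(demod.ve_590, dtype=float)
    v780 = np.asarray(demod.ve_780, dtype=float)
    time = np.asarray(demod.time, dtype=float)
    if v590.shape != v780.shape or v590.shape != time.shape:
        raise ValueError("demodulated channels must share one time base")
    valid = (v590 > 0) & (v780 > 0)
    if not np.all(valid):
        warnings.warn(f"{int(np.sum(~valid))} nonpositive voltage sample(s) flagged invalid",
                      stacklevel=2)
    lrbc = np.full(v590.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        num = math.log(constants.v0_ratio) + np.log(v780[valid] / v590[valid])
    lrbc[valid] = num / constants.denominator * 1e3
    if np.any(lrbc[valid] < 0):
        warnings.warn("negative LRBC samples present: check inputs for drift", stacklevel=2)
    return LrbcSeries(time=time, lrbc=lrbc, annotations=annotations, constants=constants)
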