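"""Layered skin optical models for dual-wavelength reflectance simulation.

The canonical model is a semi-infinite stack of seven layers (stratum
corneum, vital epidermis, upper vascular plexus, reticular dermis, deep
vascular plexus, subcutaneous fat, muscle), each carrying an absorption
coefficient ``mua``, a scattering coefficient ``mus``, a Henyey-Greenstein
anisotropy ``g`` and a refractive index ``n``.  Vascularized layers hold a
volume fraction of blood ``Cb``; rescaling the skin blood content rescales
``Cb`` (and with it ``mua``) in every layer except the basal muscle layer,
whose optical properties are held fixed.

Units are fixed package-wide: lengths in mm, coefficients in mm^-1.
"""

from __future__ import annotations

import importlib.resources
import logging
import math
from dataclasses import dataclass

import yaml

logger = logging.getLogger(__name__)

WAVELENGTHS = (590, 780)

#: Blood scales for which the canonical model carries tabulated absorption
#: coefficients (0.1x hypoperfusion, 1.0x baseline, 3.0x hyperemia).
TABULATED_SCALES = (0.1, 1.0, 3.0)


@dataclass(frozen=True)
class OpticalLayer:
    """One homogeneous tissue layer.

    Parameters
    ----------
    name : str
        Layer label.
    d : float
        Thickness in mm; ``math.inf`` for a semi-infinite basal layer.
    Cb : float
        Blood volume fraction in [0, 1].
    mua : float
        Absorption coefficient, mm^-1, at the model's wavelength.
    mus : float
        Scattering coefficient, mm^-1.
    g : float
        Scattering anisotropy in [-1, 1].
    n : float
        Refractive index (>= 1).
    """

    name: str
    d: float
    Cb: float
    mua: float
    mus: float
    g: float
    n: float

    def __post_init__(self) -> None:
        if not self.d > 0:
            raise ValueError(f"layer {self.name!r}: thickness must be > 0, got {self.d}")
        if not 0.0 <= self.Cb <= 1.0:
            raise ValueError(f"layer {self.name!r}: Cb must be in [0, 1], got {self.Cb}")
        if self.mua < 0 or self.mus < 0:
            raise ValueError(f"layer {self.name!r}: coefficients must be >= 0")
        if not -1.0 <= self.g <= 1.0:
            raise ValueError(f"layer {self.name!r}: g must be in [-1, 1], got {self.g}")
        if self.n < 1.0:
            raise ValueError(f"layer {self.name!r}: refractive index must be >= 1, got {self.n}")


@dataclass(frozen=True)
class SkinModel:
    """An ordered stack of :class:`OpticalLayer`, surface downward."""

    layers: tuple[OpticalLayer, ...]
    n_above: float = 1.0
    wavelength_tag: int | None = None

    def __post_init__(self) -> None:
        if len(self.layers) == 0:
            raise ValueError("a SkinModel needs at least one layer")
        object.__setattr__(self, "layers", tuple(self.layers))
        for lay in self.layers[:-1]:
            if math.isinf(lay.d):
                raise ValueError("only the last layer may be semi-infinite")

    @property
    def semi_infinite(self) -> bool:
        return math.isinf(self.layers[-1].d)

    def layer(self, name: str) -> OpticalLayer:
        for lay in self.layers:
            if lay.name == name:
                return lay
        raise KeyError(name)


def mix_absorption(Cb: float, mua_blood: float, mua_tissue: float) -> float:
    """Volume-fraction mixing of blood and bloodless-tissue absorption.

    Returns ``Cb * mua_blood + (1 - Cb) * mua_tissue`` (mm^-1): the layer
    absorption is the blood and bloodless-tissue coefficients weighted by
    their volume fractions.
    """
    if not 0.0 <= Cb <= 1.0:
        raise ValueError(f"Cb must be in [0, 1], got {Cb}")
    if mua_blood < 0 or mua_tissue < 0:
        raise ValueError("absorption coefficients must be >= 0")
    return Cb * mua_blood + (1.0 - Cb) * mua_tissue


def _load_canonical() -> dict:
    path = importlib.resources.files("lrbcsim.data") / "seven_layer_skin.yaml"
    with path.open("r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


_CANONICAL_CACHE: dict | None = None


def _canonical_table() -> dict:
    global _CANONICAL_CACHE
    if _CANONICAL_CACHE is None:
        _CANONICAL_CACHE = _load_canonical()
    return _CANONICAL_CACHE


def _blood_tissue_coefficients(entry: dict, wavelength: int) -> tuple[float, float]:
    """Per-layer blood and bloodless-tissue absorption coefficients.

    Solved from the tabulated (Cb, mua) pairs of the 0.1x and 1.0x columns,
    i.e. the 2x2 linear system ``mua = Cb*B + (1-Cb)*T``.  For bloodless
    layers (Cb == 0) the system is degenerate and the baseline-column value
    is returned as the tissue coefficient with B = 0.
    """
    cb1 = 0.1 * entry["Cb"]
    cb2 = entry["Cb"]
    mua = entry["mua"][wavelength]
    a1, a2 = mua[0.1], mua[1.0]
    if cb2 == 0.0:
        return 0.0, a2
    # [cb1, 1-cb1; cb2, 1-cb2] @ [B, T] = [a1, a2]
    det = cb1 * (1.0 - cb2) - cb2 * (1.0 - cb1)
    B = ((1.0 - cb2) * a1 - (1.0 - cb1) * a2) / det
    T = (cb1 * a2 - cb2 * a1) / det
    return B, T


def canonical_skin_model(blood_scale: float, wavelength: int) -> SkinModel:
    """Build the canonical seven-layer model at a given blood content.

    Parameters
    ----------
    blood_scale : float
        Skin blood content relative to baseline, in [0.1, 3.0].  At the
        tabulated scales 0.1, 1.0 and 3.0 the absorption coefficients are
        taken verbatim from the model table; at intermediate scales they
        are computed with :func:`mix_absorption` from per-layer blood and
        bloodless-tissue coefficients fitted to the 0.1x and 1.0x columns.
    wavelength : int
        590 or 780 (nm).

    Notes
    -----
    The tabulated columns are not exactly linear in ``Cb``: the linear
    fit to the 0.1x/1.0x columns overpredicts some 3.0x entries (most
    visibly the upper vascular plexus at 590 nm).  Tabulated values take
    precedence at the tabulated scales; for intermediate scales a warning
    is logged for layers where the linear extrapolation to 3.0x disagrees
    with the table, so the interpolation's limits are visible.
    """
    if wavelength not in WAVELENGTHS:
        raise ValueError(f"wavelength must be one of {WAVELENGTHS}, got {wavelength}")
    if not 0.1 <= blood_scale <= 3.0:
        raise ValueError(f"blood_scale must be in [0.1, 3.0], got {blood_scale}")
    table = _canonical_table()
    tab_scale = next((s for s in TABULATED_SCALES if math.isclose(blood_scale, s)), None)

    layers = []
    for entry in table["layers"]:
        name = entry["name"]
        fixed = name == "muscle"  # basal layer held at baseline properties
        cb_base = entry["Cb"]
        if fixed:
            cb = cb_base
            mua = entry["mua"][wavelength][1.0]
        elif tab_scale is not None:
            cb = blood_scale * cb_base if cb_base > 0 else 0.0
            mua = entry["mua"][wavelength][tab_scale]
        else:
            cb = blood_scale * cb_base if cb_base > 0 else 0.0
            B, T = _blood_tissue_coefficients(entry, wavelength)
            mua = mix_absorption(cb, B, T) if cb_base > 0 else entry["mua"][wavelength][1.0]
            extrap3 = mix_absorption(min(3.0 * cb_base, 1.0), B, T) if cb_base > 0 else None
            tab3 = entry["mua"][wavelength][3.0]
            if extrap3 is not None and tab3 > 0 and abs(extrap3 - tab3) / tab3 > 0.02:
                logger.warning(
                    "layer %s at %d nm: linear blood-fraction extrapolation to 3.0x "
                    "(%.3f mm^-1) disagrees with the tabulated value (%.3f mm^-1); "
                    "intermediate-scale mua interpolates the 0.1x/1.0x columns",
                    name, wavelength, extrap3, tab3,
                )
        d = float(entry["d"])
        layers.append(
            OpticalLayer(
                name=name, d=d, Cb=cb, mua=float(mua),
                mus=float(entry["mus"]), g=float(entry["g"]), n=float(entry["n"]),
            )
        )
    return SkinModel(layers=tuple(layers), n_above=float(table["n_above"]),
                     wavelength_tag=wavelength)


# ---------------------------------------------------------------------------
# Config round-trip (YAML, one block per layer)

def model_to_dict(model: SkinModel) -> dict:
    return {
        "n_above": model.n_above,
        "wavelength_tag": model.wavelength_tag,
        "layers": [
            {"name": l.name, "d": l.d, "Cb": l.Cb, "mua": l.mua,
             "mus": l.mus, "g": l.g, "n": l.n}
            for l in model.layers
        ],
    }


def model_from_dict(data: dict) -> SkinModel:
    layers = tuple(OpticalLayer(**entry) for entry in data["layers"])
    return SkinModel(layers=layers, n_above=data.get("n_above", 1.0),
                     wavelength_tag=data.get("wavelength_tag"))


def save_model(model: SkinModel, path) -> None:
    """Serialize a model to a YAML config; floats round-trip bit-exactly."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(model_to_dict(model), fh, sort_keys=False)


def load_model(path) -> SkinModel:
    with open(path, "r", encoding="utf-8") as fh:
        return model_from_dict(yaml.safe_load(fh))
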