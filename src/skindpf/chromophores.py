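"""Chromophore absorption spectra and layer absorption mixtures.

Layer absorption coefficients are built as volume-fraction-weighted blends of
water, hemoglobin (oxy/deoxy at a blood oxygen saturation ``S``), melanin and a
small residual "baseline" spectrum representing everything else (cell dry
matter, collagen, trace pigments).  All coefficients are in mm⁻¹ and all
spectra live on the 7-point diagnostic-window grid 450–1050 nm (100 nm step);
lookups are nearest-grid only (no interpolation).

The default compilation below is a literature-standard one:

* water — Hale–Querry / Segelstein-style pure-water absorption;
* Hb / HbO₂ — Prahl-style molar extinction coefficients converted to whole
  blood at 150 g Hb / L (2.33 mM), μa = ln(10)·ε·C; the 1050 nm entries are a
  flat extrapolation of the 1000 nm end of the standard tabulation;
* melanin — the power law μa = C_mel · λ^(−3.33) with λ in nm and
  C_mel = 6.6×10¹⁰ giving mm⁻¹ directly (equivalent to the familiar
  6.6×10¹¹ λ^(−3.33) cm⁻¹ form);
* baseline — a flat 0.0025 mm⁻¹.

Every value is overridable: :class:`ChromophoreLibrary` is a plain container
and the YAML model schema accepts a replacement table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WAVELENGTH_GRID",
    "MELANIN_SCALE",
    "MELANIN_EXPONENT",
    "ChromophoreLibrary",
    "melanin_mua",
    "epidermis_mua",
    "layer_mua",
]

#: Diagnostic-window wavelength grid, nm.
WAVELENGTH_GRID = np.array([450.0, 550.0, 650.0, 750.0, 850.0, 950.0, 1050.0])

#: Melanin power-law scale (mm⁻¹ · nm^3.33).  Exposed as a module constant
#: because published variants of this law differ in units by powers of ten.
MELANIN_SCALE = 6.6e10
#: Melanin power-law exponent (dimensionless).
MELANIN_EXPONENT = -3.33

# Pure-water absorption, mm⁻¹ (cm⁻¹ values / 10).
_MUA_WATER = np.array([9.2e-6, 4.5e-5, 3.2e-4, 2.8e-3, 4.3e-3, 3.0e-2, 1.6e-2])

# Whole-blood absorption at 150 g Hb / L, mm⁻¹:
# μa[mm⁻¹] = ln(10) × ε[M⁻¹cm⁻¹] × 2.326e-3 M / 10.
_MUA_HB = np.array([55.3, 28.6, 2.01, 0.753, 0.370, 0.371, 0.482])
_MUA_HBO2 = np.array([33.7, 23.0, 0.197, 0.301, 0.567, 0.645, 0.616])

# Residual background absorption of bloodless, dry tissue, mm⁻¹.
_MUA_OTHER = np.full(7, 2.5e-3)


def _grid_index(wavelengths: np.ndarray, wavelength: float) -> int:
    """Index of ``wavelength`` on the grid; raise if off-grid.

    Nearest-grid lookup with a 0.5 nm snap tolerance: the model is defined
    only at the tabulated wavelengths, so anything else is a caller error
    rather than something to interpolate silently.
    """
    idx = int(np.argmin(np.abs(wavelengths - wavelength)))
    if abs(wavelengths[idx] - wavelength) > 0.5:
        raise ValueError(
            f"wavelength {wavelength} nm is not on the supported grid "
            f"{wavelengths.tolist()} nm"
        )
    return idx


@dataclass(frozen=True)
class ChromophoreLibrary:
    """Absorption spectra (mm⁻¹) of the model chromophores on a common grid.

    Parameters
    ----------
    wavelengths
        Wavelength grid in nm, strictly increasing, covering 450–1050 nm.
    mua_water, mua_Hb, mua_HbO2, mua_other
        Absorption coefficient per wavelength in mm⁻¹ for pure water,
        deoxyhemoglobin and oxyhemoglobin (both at whole-blood reference
        concentration), and the residual baseline.
    """

    wavelengths: np.ndarray = field(default_factory=lambda: WAVELENGTH_GRID.copy())
    mua_water: np.ndarray = field(default_factory=lambda: _MUA_WATER.copy())
    mua_Hb: np.ndarray = field(default_factory=lambda: _MUA_HB.copy())
    mua_HbO2: np.ndarray = field(default_factory=lambda: _MUA_HBO2.copy())
    mua_other: np.ndarray = field(default_factory=lambda: _MUA_OTHER.copy())
    melanin_scale: float = MELANIN_SCALE
    melanin_exponent: float = MELANIN_EXPONENT

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.ndim != 1 or len(wl) < 2 or np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be a strictly increasing 1-D grid")
        if wl[0] > 450.0 or wl[-1] < 1050.0:
            raise ValueError("wavelength grid must cover 450–1050 nm inclusive")
        for name in ("mua_water", "mua_Hb", "mua_HbO2", "mua_other"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != wl.shape:
                raise ValueError(f"{name} must have one value per grid wavelength")
            if np.any(arr < 0) or not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} must be finite and non-negative")
            object.__setattr__(self, name, arr)
        object.__setattr__(self, "wavelengths", wl)

    def index(self, wavelength: float) -> int:
        return _grid_index(self.wavelengths, wavelength)

    def mua_blood(self, wavelength: float, oxygen_saturation: float) -> float:
        """Whole-blood absorption at the given oxygen saturation, mm⁻¹."""
        if not 0.0 <= oxygen_saturation <= 1.0:
            raise ValueError("oxygen_saturation must be in [0, 1]")
        i = self.index(wavelength)
        s = oxygen_saturation
        return s * self.mua_HbO2[i] + (1.0 - s) * self.mua_Hb[i]


def melanin_mua(wavelength: float, lib: ChromophoreLibrary | None = None) -> float:
    """Melanin absorption coefficient (mm⁻¹) from the λ^(−3.33) power law.

    Parameters
    ----------
    wavelength
        Wavelength in nm; must lie within 450–1050 nm.
    lib
        Optional library carrying a non-default power-law scale/exponent.
    """
    if not 450.0 <= wavelength <= 1050.0:
        raise ValueError(f"wavelength {wavelength} nm outside supported 450–1050 nm")
    scale = lib.melanin_scale if lib is not None else MELANIN_SCALE
    exponent = lib.melanin_exponent if lib is not None else MELANIN_EXPONENT
    return scale * wavelength**exponent


def epidermis_mua(
    wavelength: float,
    v_mel: float,
    v_water: float,
    lib: ChromophoreLibrary | None = None,
    middle_term: str = "water",
) -> float:
    """Epidermis absorption (mm⁻¹) as a melanin/water/baseline mixture.

    μa = v_mel·μa_mel + v_water·μa_mid + (1 − v_mel − v_water)·μa_other,
    where μa_mid is the water spectrum by default.  ``middle_term="hbo2"``
    instead multiplies the water volume fraction by the oxyhemoglobin
    spectrum — a printed variant of this mixture that is almost certainly a
    typo, kept selectable so both behaviors can be compared explicitly.
    """
    if v_mel < 0 or v_water < 0:
        raise ValueError("volume fractions must be non-negative")
    if v_mel + v_water > 1.0 + 1e-12:
        raise ValueError("v_mel + v_water must not exceed 1")
    if middle_term not in ("water", "hbo2"):
        raise ValueError("middle_term must be 'water' or 'hbo2'")
    lib = lib if lib is not None else ChromophoreLibrary()
    i = lib.index(wavelength)
    mua_mid = lib.mua_water[i] if middle_term == "water" else lib.mua_HbO2[i]
    return (
        v_mel * melanin_mua(wavelength, lib)
        + v_water * mua_mid
        + (1.0 - (v_mel + v_water)) * lib.mua_other[i]
    )


def layer_mua(layer, wavelength: float, lib: ChromophoreLibrary | None = None) -> float:
    """Absorption coefficient (mm⁻¹) of a skin layer at one wavelength.

    Non-melanotic layers use the standard blend

    μa = v_blood·(S·μa_HbO2 + (1−S)·μa_Hb) + v_water·μa_H2O
         + (1 − v_blood − v_water)·μa_other,

    with S the blood oxygen saturation carried by the layer.  Layers with
    ``v_mel > 0`` (the epidermis) dispatch to :func:`epidermis_mua`.
    """
    lib = lib if lib is not None else ChromophoreLibrary()
    if layer.v_mel > 0:
        return epidermis_mua(
            wavelength,
            layer.v_mel,
            layer.v_water,
            lib,
            middle_term=getattr(layer, "epidermis_middle_term", "water"),
        )
    i = lib.index(wavelength)
    blood = lib.mua_blood(wavelength, layer.oxygen_saturation)
    remainder = 1.0 - (layer.v_blood + layer.v_water)
    mua = (
        layer.v_blood * blood
        + layer.v_water * lib.mua_water[i]
        + remainder * lib.mua_other[i]
    )
    # floating-point guard; the mixture itself cannot go negative
    return max(mua, 0.0)
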