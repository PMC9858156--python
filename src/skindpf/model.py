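"""Layered skin model: geometry, optical properties, YAML (de)serialisation.

The default model is a seven-layer slab (stratum corneum → subcutaneous
tissue, 2.95 mm total) with one scattering spectrum shared by all layers,
per-layer blood/water/melanin volume fractions, anisotropy g = 0.9 and
refractive index n = 1.37 throughout, under air (n = 1.0).  Two packaged
fixtures, ``skin_2pct.yaml`` and ``skin_20pct.yaml``, hold the light- and
dark-skin variants (2 % vs 20 % epidermal melanin).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .chromophores import WAVELENGTH_GRID, ChromophoreLibrary, layer_mua

__all__ = [
    "LayerSpec",
    "SkinModel",
    "build_default_model",
    "load_model",
    "dump_model",
    "packaged_model",
    "DEFAULT_MUS_SPECTRUM",
    "DEFAULT_G",
    "DEFAULT_N",
    "DEFAULT_OXYGEN_SATURATION",
]

#: Scattering coefficient spectrum (mm⁻¹) on the 450–1050 nm grid, applied to
#: every layer unless a per-layer spectrum is supplied.
DEFAULT_MUS_SPECTRUM = np.array([60.61, 41.74, 22.33, 15.05, 13.32, 9.5, 7.52])
DEFAULT_G = 0.9
DEFAULT_N = 1.37
DEFAULT_OXYGEN_SATURATION = 0.75

# (name, thickness mm, v_blood, v_water)
_DEFAULT_STACK = [
    ("stratum_corneum", 0.02, 0.0, 0.05),
    ("epidermis", 0.25, 0.0, 0.20),
    ("papillary_dermis", 0.10, 0.04, 0.50),
    ("upper_blood_net_dermis", 0.08, 0.30, 0.60),
    ("reticular_dermis", 0.20, 0.04, 0.70),
    ("deep_blood_net_dermis", 0.30, 0.10, 0.70),
    ("subcutaneous_tissue", 2.00, 0.05, 0.70),
]


@dataclass(frozen=True)
class LayerSpec:
    """One tissue layer: geometry, scattering and composition."""

    name: str
    thickness: float  # mm
    mus: np.ndarray  # mm⁻¹ per grid wavelength
    g: float = DEFAULT_G
    n: float = DEFAULT_N
    v_blood: float = 0.0
    v_water: float = 0.0
    v_mel: float = 0.0
    oxygen_saturation: float = DEFAULT_OXYGEN_SATURATION
    epidermis_middle_term: str = "water"

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValueError(f"layer '{self.name}': thickness must be > 0")
        mus = np.asarray(self.mus, dtype=float)
        if np.any(mus <= 0) or not np.all(np.isfinite(mus)):
            raise ValueError(f"layer '{self.name}': mus must be finite and > 0")
        object.__setattr__(self, "mus", mus)
        if not -1.0 <= self.g <= 1.0:
            raise ValueError(f"layer '{self.name}': anisotropy g must be in [-1, 1]")
        if self.n < 1.0:
            raise ValueError(f"layer '{self.name}': refractive index must be >= 1")
        for fname in ("v_blood", "v_water", "v_mel"):
            v = getattr(self, fname)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"layer '{self.name}': {fname} must be in [0, 1]")
        if self.v_blood + self.v_water + self.v_mel > 1.0 + 1e-12:
            raise ValueError(
                f"layer '{self.name}': v_blood + v_water + v_mel must not exceed 1"
            )
        if not 0.0 <= self.oxygen_saturation <= 1.0:
            raise ValueError(f"layer '{self.name}': oxygen_saturation must be in [0, 1]")


@dataclass(frozen=True)
class SkinModel:
    """Ordered layer stack (top first) under an ambient medium.

    ``boundaries()`` returns the interface depths 0 = z₀ < z₁ < … < z_L (mm);
    per-wavelength optical-property vectors come from :meth:`optical_arrays`.
    """

    layers: tuple[LayerSpec, ...]
    n_ambient: float = 1.0
    library: ChromophoreLibrary = field(default_factory=ChromophoreLibrary)

    def __post_init__(self) -> None:
        if len(self.layers) == 0:
            raise ValueError("model must have at least one layer")
        object.__setattr__(self, "layers", tuple(self.layers))
        if self.n_ambient < 1.0:
            raise ValueError("ambient refractive index must be >= 1")
        shapes = {tuple(np.shape(l.mus)) for l in self.layers}
        if len(shapes) != 1 or shapes.pop() != self.library.wavelengths.shape:
            raise ValueError("every layer needs one mus value per grid wavelength")

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def wavelengths(self) -> np.ndarray:
        return self.library.wavelengths

    def boundaries(self) -> np.ndarray:
        """Interface depths in mm, starting at the surface z = 0."""
        return np.concatenate([[0.0], np.cumsum([l.thickness for l in self.layers])])

    @property
    def total_thickness(self) -> float:
        return float(sum(l.thickness for l in self.layers))

    def mua(self, wavelength: float) -> np.ndarray:
        """Per-layer absorption coefficients (mm⁻¹) at one wavelength."""
        return np.array([layer_mua(l, wavelength, self.library) for l in self.layers])

    def mus(self, wavelength: float) -> np.ndarray:
        """Per-layer scattering coefficients (mm⁻¹) at one wavelength."""
        i = self.library.index(wavelength)
        return np.array([l.mus[i] for l in self.layers])

    def optical_arrays(self, wavelength: float):
        """(z_top, z_bot, mua, mus, g, n) arrays for the transport kernel."""
        b = self.boundaries()
        return (
            b[:-1].copy(),
            b[1:].copy(),
            self.mua(wavelength),
            self.mus(wavelength),
            np.array([l.g for l in self.layers]),
            np.array([l.n for l in self.layers]),
        )

    def with_melanin(self, melanin_fraction: float) -> "SkinModel":
        """Copy of the model with the epidermal melanin fraction replaced."""
        layers = tuple(
            replace(l, v_mel=melanin_fraction) if l.name == "epidermis" else l
            for l in self.layers
        )
        return replace(self, layers=layers)


def build_default_model(
    melanin_fraction: float = 0.02,
    *,
    g: float = DEFAULT_G,
    n: float = DEFAULT_N,
    oxygen_saturation: float = DEFAULT_OXYGEN_SATURATION,
    library: ChromophoreLibrary | None = None,
    epidermis_middle_term: str = "water",
) -> SkinModel:
    """The seven-layer default skin model.

    Parameters
    ----------
    melanin_fraction
        Epidermal melanin volume fraction; 0.02 and 0.20 are the light- and
        dark-skin study values (any value in [0, 1] is accepted).
    """
    if not 0.0 <= melanin_fraction <= 0.8:
        raise ValueError("melanin_fraction must be in [0, 0.8]")
    library = library if library is not None else ChromophoreLibrary()
    layers = []
    for name, thickness, v_blood, v_water in _DEFAULT_STACK:
        layers.append(
            LayerSpec(
                name=name,
                thickness=thickness,
                mus=DEFAULT_MUS_SPECTRUM.copy(),
                g=g,
                n=n,
                v_blood=v_blood,
                v_water=v_water,
                v_mel=melanin_fraction if name == "epidermis" else 0.0,
                oxygen_saturation=oxygen_saturation,
                epidermis_middle_term=epidermis_middle_term,
            )
        )
    return SkinModel(layers=tuple(layers), n_ambient=1.0, library=library)


# ---------------------------------------------------------------------------
# YAML schema
# ---------------------------------------------------------------------------

_LAYER_KEYS = {
    "name", "thickness", "mus", "g", "n",
    "v_blood", "v_water", "v_mel", "oxygen_saturation", "epidermis_middle_term",
}


def _model_to_dict(model: SkinModel) -> dict:
    lib = model.library
    return {
        "n_ambient": model.n_ambient,
        "chromophores": {
            "wavelengths": lib.wavelengths.tolist(),
            "mua_water": lib.mua_water.tolist(),
            "mua_Hb": lib.mua_Hb.tolist(),
            "mua_HbO2": lib.mua_HbO2.tolist(),
            "mua_other": lib.mua_other.tolist(),
            "melanin_scale": lib.melanin_scale,
            "melanin_exponent": lib.melanin_exponent,
        },
        "layers": [
            {
                "name": l.name,
                "thickness": l.thickness,
                "mus": np.asarray(l.mus).tolist(),
                "g": l.g,
                "n": l.n,
                "v_blood": l.v_blood,
                "v_water": l.v_water,
                "v_mel": l.v_mel,
                "oxygen_saturation": l.oxygen_saturation,
                "epidermis_middle_term": l.epidermis_middle_term,
            }
            for l in model.layers
        ],
    }


def _model_from_dict(doc: dict) -> SkinModel:
    if not isinstance(doc, dict):
        raise ValueError("model config must be a mapping")
    unknown = set(doc) - {"n_ambient", "chromophores", "layers"}
    if unknown:
        raise ValueError(f"unknown top-level model keys: {sorted(unknown)}")
    if "layers" not in doc or not isinstance(doc["layers"], list) or not doc["layers"]:
        raise ValueError("model config must contain a non-empty 'layers' list")
    chrom = doc.get("chromophores")
    if chrom is None:
        library = ChromophoreLibrary()
    else:
        try:
            library = ChromophoreLibrary(
                wavelengths=np.asarray(chrom["wavelengths"], dtype=float),
                mua_water=np.asarray(chrom["mua_water"], dtype=float),
                mua_Hb=np.asarray(chrom["mua_Hb"], dtype=float),
                mua_HbO2=np.asarray(chrom["mua_HbO2"], dtype=float),
                mua_other=np.asarray(chrom["mua_other"], dtype=float),
                melanin_scale=float(chrom.get("melanin_scale", 6.6e10)),
                melanin_exponent=float(chrom.get("melanin_exponent", -3.33)),
            )
        except KeyError as exc:
            raise ValueError(f"chromophores table missing column {exc}") from None
    layers = []
    for k, entry in enumerate(doc["layers"]):
        if not isinstance(entry, dict):
            raise ValueError(f"layer #{k} must be a mapping")
        unknown = set(entry) - _LAYER_KEYS
        if unknown:
            raise ValueError(f"layer #{k}: unknown keys {sorted(unknown)}")
        for required in ("name", "thickness", "mus"):
            if required not in entry:
                raise ValueError(f"layer #{k}: missing required field '{required}'")
        mus = entry["mus"]
        if np.isscalar(mus):
            mus = np.full(library.wavelengths.shape, float(mus))
        layers.append(LayerSpec(**{**entry, "mus": np.asarray(mus, dtype=float)}))
    return SkinModel(
        layers=tuple(layers),
        n_ambient=float(doc.get("n_ambient", 1.0)),
        library=library,
    )


def dump_model(model: SkinModel, path) -> None:
    """Write a model to a YAML file (round-trips through :func:`load_model`)."""
    with open(path, "w") as fh:
        yaml.safe_dump(_model_to_dict(model), fh, sort_keys=False)


def load_model(path) -> SkinModel:
    """Read and validate a YAML model config."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return _model_from_dict(doc)


def packaged_model(name: str) -> SkinModel:
    """Load one of the packaged fixtures: 'skin_2pct' or 'skin_20pct'."""
    ref = importlib.resources.files("skindpf").joinpath(f"data/{name}.yaml")
    with importlib.resources.as_file(ref) as path:
        return load_model(path)
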