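import numpy as np
import pytest

from skindpf import (
    ChromophoreLibrary,
    LayerSpec,
    SkinModel,
    build_default_model,
)


@pytest.fixture(scope="session")
def lib():
    return ChromophoreLibrary()


@pytest.fixture(scope="session")
def model_2pct():
    return build_default_model(0.02)


@pytest.fixture(scope="session")
def model_20pct():
    return build_default_model(0.20)


def make_homogeneous(mua, mus, g=0.9, n=1.0, thickness=100.0):
    """Single-layer model with constant optical properties at every wavelength."""
    library = ChromophoreLibrary(
        mua_water=np.full(7, float(mua)),
        mua_Hb=np.zeros(7),
        mua_HbO2=np.zeros(7),
        mua_other=np.zeros(7),
    )
    return SkinModel(
        layers=(
            LayerSpec(
                name="bulk", thickness=thickness, mus=np.full(7, float(mus)),
                g=g, n=n, v_water=1.0,
            ),
        ),
        n_ambient=1.0,
        library=library,
    )


def make_two_layer(mua1=0.05, mus1=8.0, mua2=0.02, mus2=4.0, g=0.8, n=1.37):
    """Small two-layer toy model used for engine/oracle equivalence checks."""
    library = ChromophoreLibrary(
        mua_water=np.ones(7),
        mua_Hb=np.zeros(7),
        mua_HbO2=np.zeros(7),
        mua_other=np.zeros(7),
    )
    return SkinModel(
        layers=(
            LayerSpec(name="top", thickness=0.5, mus=np.full(7, mus1), g=g, n=n,
                      v_water=mua1),
            LayerSpec(name="bottom", thickness=3.0, mus=np.full(7, mus2), g=g, n=n,
                      v_water=mua2),
        ),
        n_ambient=1.0,
        library=library,
    )
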