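import numpy as np
import pytest

from psexcite import (
    ExcitationConfig,
    OpticalSystem,
    VesselSpec,
    build_psf_kernel,
    generate_phantom,
    simulate_image,
)


@pytest.fixture(scope="session")
def optics():
    return OpticalSystem(wavelength_nm=532.0, numerical_aperture=1.4)


@pytest.fixture(scope="session")
def gaussian_kernel(optics):
    return build_psf_kernel(optics, "gaussian", pixel_size_nm=10.0)


@pytest.fixture(scope="session")
def phase_shifted_kernel(optics):
    cfg = ExcitationConfig(gamma=1.16, waist=optics.waist_nm)
    return build_psf_kernel(optics, "phase_shifted", cfg, pixel_size_nm=10.0)


@pytest.fixture(scope="session")
def phantom():
    """Default 512x512, 10 nm/px phantom with the 120 nm calibrated junction."""
    return generate_phantom(VesselSpec(), field_nm=5120.0, pixel_size_nm=10.0, seed=0)


@pytest.fixture(scope="session")
def simulated_pair(phantom, gaussian_kernel, phase_shifted_kernel):
    return (
        simulate_image(phantom, gaussian_kernel, "gaussian"),
        simulate_image(phantom, phase_shifted_kernel, "phase_shifted"),
    )
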