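import numpy as np
import pytest

from mirdose import LU177, SphereGeometry


def sphere_phi_quadrature(radius_mm: float, track_length_mm: float, n: int = 800) -> float:
    """Independent deterministic oracle for the sphere absorbed fraction.

    Gauss-Legendre quadrature of E[min(d_exit, L)]/L over the emission
    radius s (density 3 s^2 / R^3 on [0, R], uniform-in-volume source) and
    the direction cosine c (uniform on [-1, 1], isotropic emission), with
    d_exit = -s c + sqrt(R^2 - s^2 (1 - c^2)) the distance to the sphere
    surface. No Monte Carlo, no shared code with the estimator under test.
    """
    if track_length_mm == 0:
        return 1.0
    xs, ws = np.polynomial.legendre.leggauss(n)
    s = 0.5 * radius_mm * (xs + 1.0)
    w_s = ws * 0.5 * radius_mm * 3.0 * s**2 / radius_mm**3
    c = xs
    w_c = ws * 0.5
    S, C = np.meshgrid(s, c, indexing="ij")
    d_exit = -S * C + np.sqrt(radius_mm**2 - S**2 * (1.0 - C**2))
    val = np.minimum(d_exit, track_length_mm) / track_length_mm
    return float((w_s[:, None] * w_c[None, :] * val).sum())


@pytest.fixture(scope="session")
def tumor_sphere() -> SphereGeometry:
    """The study tumor: 3 mm diameter sphere weighing 0.016 g."""
    return SphereGeometry(radius_mm=1.5, mass_g=0.016)


@pytest.fixture(scope="session")
def lu177():
    return LU177
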