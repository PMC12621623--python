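"""Isotropic linear elasticity parameters for the continuum seta shaft.

The shaft material is beta-keratin treated as an isotropic linear-elastic
solid.  Each run samples Young's modulus E and Poisson's ratio nu from
independent normal distributions (default means/sds from mesoscale keratin
calibrations: E = 4.518 +/- 0.036 GPa, nu = 0.401 +/- 0.002) and converts
them to the Lame parameters used in the stress assembly

    sigma = lambda tr(eps) I + 2 mu eps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

E_GPA_MEAN_DEFAULT = 4.518
E_GPA_SD_DEFAULT = 0.036
NU_MEAN_DEFAULT = 0.401
NU_SD_DEFAULT = 0.002


def lame_from_E_nu(E: float, nu: float) -> tuple[float, float]:
    """Lame parameters (lambda, mu) from Young's modulus and Poisson's ratio.

    ``E`` must be positive and ``nu`` in [0, 0.5); the incompressible limit
    nu = 0.5 makes lambda diverge and is rejected.
    """
    if E <= 0:
        raise ValueError(f"Young's modulus must be positive, got {E}")
    if not (0 <= nu < 0.5):
        raise ValueError(f"Poisson's ratio must lie in [0, 0.5), got {nu}")
    lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    mu = E / (2.0 * (1.0 + nu))
    return lam, mu


def E_nu_from_lame(lam: float, mu: float) -> tuple[float, float]:
    """Inverse of :func:`lame_from_E_nu`."""
    if mu <= 0:
        raise ValueError(f"shear modulus must be positive, got {mu}")
    E = mu * (3.0 * lam + 2.0 * mu) / (lam + mu)
    nu = lam / (2.0 * (lam + mu))
    return E, nu


@dataclass(frozen=True)
class ElasticParams:
    """Isotropic elastic constants of the seta shaft (moduli in GPa)."""

    E: float
    nu: float
    lam: float = field(init=False)
    mu: float = field(init=False)

    def __post_init__(self) -> None:
        lam, mu = lame_from_E_nu(self.E, self.nu)
        object.__setattr__(self, "lam", lam)
        object.__setattr__(self, "mu", mu)


def sample_material(
    E_mean: float = E_GPA_MEAN_DEFAULT,
    E_sd: float = E_GPA_SD_DEFAULT,
    nu_mean: float = NU_MEAN_DEFAULT,
    nu_sd: float = NU_SD_DEFAULT,
    rng: np.random.Generator | int | None = None,
) -> ElasticParams:
    """Draw one (E, nu) realisation for a run.

    E and nu are sampled independently; draws violating E > 0 or
    0 < nu < 0.5 are rejected and redrawn (vanishingly rare at the default
    standard deviations).  ``sd = 0`` returns the means exactly.
    """
    if E_sd < 0 or nu_sd < 0:
        raise ValueError("standard deviations must be non-negative")
    rng = np.random.default_rng(rng)
    for _ in range(1000):
        E = float(rng.normal(E_mean, E_sd)) if E_sd > 0 else E_mean
        nu = float(rng.normal(nu_mean, nu_sd)) if nu_sd > 0 else nu_mean
        if E > 0 and 0 < nu < 0.5:
            return ElasticParams(E=E, nu=nu)
    raise RuntimeError("material sampling failed to produce valid parameters")
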