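"""Steady-state diffusion-approximation reflectance for a semi-infinite medium.

Closed-form spatially resolved reflectance of a point source on a
semi-infinite homogeneous medium with an extrapolated boundary (dipole
image-source construction).  Valid in the high-albedo regime at separations
of a few transport mean free paths; used as an independent physics check on
the Monte Carlo transport, never as the forward model.
"""

from __future__ import annotations

import numpy as np

__all__ = ["diffusion_rd", "internal_reflection_parameter"]


def internal_reflection_parameter(n_rel: float) -> float:
    """Boundary mismatch parameter A for the extrapolated-boundary condition.

    Uses the Groenhuis-style polynomial fit of the effective internal
    reflection coefficient: A = (1 + r_eff) / (1 - r_eff) with
    r_eff = -1.440 n^-2 + 0.710 n^-1 + 0.668 + 0.0636 n.
    """
    if n_rel == 1.0:
        return 1.0
    r_eff = -1.440 / n_rel**2 + 0.710 / n_rel + 0.668 + 0.0636 * n_rel
    return (1.0 + r_eff) / (1.0 - r_eff)


def diffusion_rd(rho_mm, mua: float, musp: float, n_rel: float = 1.435):
    """Diffuse reflectance per unit area (mm^-2) at radius rho from the source.

    Dipole solution: an isotropic source at depth z0 = 1/(mua + musp) and an
    image sink mirrored about the extrapolated boundary at z = -2*zb,
    zb = 2*A*D, D = 1/(3*(mua + musp)).

    Rd(rho) = (1/4pi) * [ z0 (mueff + 1/r1) e^{-mueff r1} / r1^2
                        + (z0 + 2 zb)(mueff + 1/r2) e^{-mueff r2} / r2^2 ]
    with mueff = sqrt(3 mua (mua + musp)).
    """
    rho = np.asarray(rho_mm, dtype=float)
    mut = mua + musp
    z0 = 1.0 / mut
    d_coef = 1.0 / (3.0 * mut)
    zb = 2.0 * internal_reflection_parameter(n_rel) * d_coef
    mueff = np.sqrt(3.0 * mua * mut)
    r1 = np.sqrt(rho**2 + z0**2)
    r2 = np.sqrt(rho**2 + (z0 + 2.0 * zb) ** 2)
    term1 = z0 * (mueff + 1.0 / r1) * np.exp(-mueff * r1) / r1**2
    term2 = (z0 + 2.0 * zb) * (mueff + 1.0 / r2) * np.exp(-mueff * r2) / r2**2
    return (term1 + term2) / (4.0 * np.pi)
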