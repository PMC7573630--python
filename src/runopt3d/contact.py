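"""Penetration-based ground contact, smooth enough for gradient-based NLP.

The ground is the plane y = 0 with y up.  Each contact point generates a
normal force from a cubic penetration law with velocity-dependent damping and
a smoothed Coulomb friction force.  Every branch point (contact on/off,
stick/slip) is replaced by a C1 smooth approximation so that the force and
its partial derivatives stay finite and continuous everywhere -- a
requirement for use inside interior-point / Gauss-Newton optimization.

All functions accept real or complex arrays (complex-step differentiable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ContactParameters", "contact_force"]

# half-width of the soft clamp applied to the damping factor (dimensionless)
_EPS_CLAMP = 0.01


@dataclass(frozen=True)
class ContactParameters:
    """Ground contact law parameters.

    k_n    cubic normal stiffness, N/m^3
    c_n    normal damping coefficient, s/m
    mu     friction coefficient
    v_c    friction velocity smoothing, m/s
    eps_p  penetration smoothing half-width, m
    """

    k_n: float = 2.5e8
    c_n: float = 1.0
    mu: float = 1.0
    v_c: float = 0.01
    eps_p: float = 1e-3

    def validate(self) -> list[str]:
        bad = []
        for attr in ("k_n", "c_n", "mu", "v_c", "eps_p"):
            if not getattr(self, attr) > 0:
                bad.append(f"contact parameter {attr} must be > 0")
        if self.mu > 2.0:
            bad.append("friction coefficient mu must be <= 2")
        return bad


def contact_force(pos, vel, cp: ContactParameters):
    """Ground force (N) on a point at ``pos`` (m) moving at ``vel`` (m/s).

    ``pos``/``vel`` have shape (..., 3) with components (x, y, z), y up.
    The smoothed penetration is ``p = 0.5*(sqrt(y^2 + eps_p^2) - y)`` (zero
    far above the ground, -y deep below); the normal force is
    ``k_n * p^3 * clamp(1 - c_n * ydot)`` with a soft positive clamp, and the
    tangential force is Coulomb friction regularized around zero slip speed.
    """
    pos = np.asarray(pos)
    vel = np.asarray(vel)
    y = pos[..., 1]
    ydot = vel[..., 1]
    p = 0.5 * (np.sqrt(y * y + cp.eps_p**2) - y)
    damp = 1.0 - cp.c_n * ydot
    damp = 0.5 * (damp + np.sqrt(damp * damp + _EPS_CLAMP**2))
    f_y = cp.k_n * p**3 * damp
    vx = vel[..., 0]
    vz = vel[..., 2]
    slip = np.sqrt(vx * vx + vz * vz + cp.v_c**2)
    f_x = -cp.mu * f_y * vx / slip
    f_z = -cp.mu * f_y * vz / slip
    return np.stack([f_x, f_y, f_z], axis=-1)
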