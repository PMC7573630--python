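"""Hill-type muscle-tendon units in implicit form.

Each muscle-tendon unit (MTU) is a three-element Hill model: a contractile
element (CE) with activation and contraction dynamics, a parallel elastic
element (PEE) across the CE, and a series elastic element (SEE, the tendon).
The contraction state is ``s``, the projection of the CE length onto the
muscle line of action, which keeps the dynamics free of singularities as the
pennation angle approaches pi/2: with the constant-height pennation model

    l_CE = sqrt(s**2 + h**2),   h = l_CE_opt * sin(phi_opt),

``cos(phi) = s / l_CE`` is smooth and positive for every ``s > 0``.

Muscle-tendon path geometry is represented by multivariate polynomials in the
joint angles; moment arms follow from the virtual-work convention
``arm_j = -d l_MTU / d q_j``.

All force computations are written to accept real or complex arrays so that
derivatives can be obtained by complex-step differentiation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "MuscleParameters",
    "PathPolynomial",
    "mtu_geometry",
    "fit_path_polynomial",
    "contraction_residual",
    "activation_residual",
    "force_length",
    "force_velocity",
    "tendon_force",
]

# smoothing half-widths for the soft positive-part used in SEE/PEE engagement
_EPS_STRAIN = 1e-4


def _smooth_pos(x, eps):
    """C-infinity positive part 0.5*(x + sqrt(x^2 + eps^2)); complex-safe."""
    return 0.5 * (x + np.sqrt(x * x + eps * eps))


@dataclass(frozen=True)
class MuscleParameters:
    """Parameters of one Hill-type MTU (SI units).

    ``v_max`` is expressed in optimal CE lengths per second, ``k_PEE`` is the
    dimensionless quadratic PEE stiffness (force ``k_PEE*F_ISO*strain^2``) and
    ``d_CE`` the small CE damping in units of F_ISO per (l_CE_opt/s).
    """

    name: str
    F_ISO: float
    l_CE_opt: float
    l_slack: float
    W: float = 0.56
    v_max: float = 10.0
    A_hill: float = 0.25
    phi_opt: float = 0.0
    T_act: float = 0.01
    T_deact: float = 0.04
    eps0_SEE: float = 0.04
    k_PEE: float = 1.0 / 0.56**2
    d_CE: float = 0.01
    f_ecc_max: float = 1.5

    def validate(self) -> list[str]:
        bad = []
        for attr in ("F_ISO", "l_CE_opt", "l_slack", "W", "v_max", "A_hill",
                     "T_act", "T_deact", "eps0_SEE", "k_PEE"):
            if not getattr(self, attr) > 0:
                bad.append(f"muscle '{self.name}': {attr} must be > 0")
        if self.phi_opt < 0:
            bad.append(f"muscle '{self.name}': phi_opt must be >= 0")
        if self.d_CE < 0:
            bad.append(f"muscle '{self.name}': d_CE must be >= 0")
        if self.T_act > self.T_deact:
            bad.append(f"muscle '{self.name}': T_act must be <= T_deact")
        return bad

    @property
    def height(self) -> float:
        return self.l_CE_opt * np.sin(self.phi_opt)


@dataclass(frozen=True)
class PathPolynomial:
    """Muscle-tendon length as a polynomial of joint angles.

    ``terms`` is a sequence of ``(exponents, coefficient)`` where
    ``exponents`` has one entry per name in ``dof_names``.  The length is
    ``l_MTU(q) = sum_t c_t * prod_j q_j**e_tj`` in metres.
    """

    dof_names: tuple[str, ...]
    terms: tuple[tuple[tuple[int, ...], float], ...]

    def __post_init__(self):
        object.__setattr__(self, "dof_names", tuple(self.dof_names))
        object.__setattr__(
            self, "terms",
            tuple((tuple(int(e) for e in exps), float(c)) for exps, c in self.terms))

    def validate(self) -> list[str]:
        bad = []
        const = 0.0
        for exps, c in self.terms:
            if len(exps) != len(self.dof_names):
                bad.append("path term exponent tuple length mismatch")
                continue
            if not np.isfinite(c):
                bad.append("path coefficient not finite")
            if sum(exps) > 4:
                bad.append("path term total degree exceeds 4")
            if all(e == 0 for e in exps):
                const += c
        if not const > 0:
            bad.append("path constant term must be > 0")
        return bad

    def length(self, q_path):
        """Evaluate l_MTU for stacked coordinates ``q_path`` of shape (..., n_dof)."""
        q_path = np.asarray(q_path)
        l = np.zeros(q_path.shape[:-1], dtype=q_path.dtype)
        for exps, c in self.terms:
            term = np.full(q_path.shape[:-1], c, dtype=q_path.dtype)
            for j, e in enumerate(exps):
                if e:
                    term = term * q_path[..., j] ** e
            l = l + term
        return l

    def dlength(self, q_path):
        """Gradient of l_MTU w.r.t. the path coordinates, shape (..., n_dof)."""
        q_path = np.asarray(q_path)
        g = np.zeros(q_path.shape, dtype=q_path.dtype)
        for exps, c in self.terms:
            for j, e in enumerate(exps):
                if e == 0:
                    continue
                term = np.full(q_path.shape[:-1], c * e, dtype=q_path.dtype)
                for k, ek in enumerate(exps):
                    p = ek - 1 if k == j else ek
                    if p:
                        term = term * q_path[..., k] ** p
                g[..., j] += term
        return g


def mtu_geometry(path: PathPolynomial, q_path):
    """Muscle-tendon length and moment arms at coordinates ``q_path``.

    Moment arms use the virtual-work sign convention ``arm_j = -dl/dq_j`` so a
    positive arm produces a positive generalized force on DOF j when the
    tendon force is positive (pulling).
    """
    return path.length(q_path), -path.dlength(q_path)


def _monomials(n_dof: int, max_degree: int) -> list[tuple[int, ...]]:
    out: list[tuple[int, ...]] = []

    def rec(prefix, remaining):
        if len(prefix) == n_dof:
            out.append(tuple(prefix))
            return
        for e in range(remaining + 1):
            rec(prefix + [e], remaining - e)

    rec([], max_degree)
    out.sort(key=lambda t: (sum(t), t))
    return out


def fit_path_polynomial(dof_names: Sequence[str], samples, max_degree: int) -> tuple["PathPolynomial", float]:
    """Least-squares fit of a PathPolynomial to ``(q, l_MTU)`` samples.

    Returns the fitted path and the RMS length residual.  Raises
    ``ValueError`` when the monomial design matrix is rank deficient (too few
    or degenerate samples for the requested degree).
    """
    dof_names = tuple(dof_names)
    Q = np.asarray([np.atleast_1d(q) for q, _ in samples], dtype=float)
    L = np.asarray([l for _, l in samples], dtype=float)
    monos = _monomials(len(dof_names), max_degree)
    A = np.empty((len(samples), len(monos)))
    for j, exps in enumerate(monos):
        col = np.ones(len(samples))
        for k, e in enumerate(exps):
            if e:
                col = col * Q[:, k] ** e
        A[:, j] = col
    if len(samples) < len(monos) or np.linalg.matrix_rank(A) < len(monos):
        raise ValueError(
            f"rank-deficient path fit: {len(samples)} samples for {len(monos)} "
            f"monomials; sample more poses or lower max_degree")
    coef, *_ = np.linalg.lstsq(A, L, rcond=None)
    rms = float(np.sqrt(np.mean((A @ coef - L) ** 2)))
    terms = tuple((exps, c) for exps, c in zip(monos, coef))
    return PathPolynomial(dof_names, terms), rms


# ---------------------------------------------------------------------------
# force curves
# ---------------------------------------------------------------------------

def force_length(p: MuscleParameters, l_CE):
    """Gaussian active force-length curve, 1 at the optimal CE length."""
    x = (l_CE / p.l_CE_opt - 1.0) / p.W
    return np.exp(-x * x)


def force_velocity(p: MuscleParameters, v_norm):
    """Hill force-velocity factor as a function of v_CE in l_CE_opt/s.

    Concentric branch is the Hill hyperbola (0 at -v_max, 1 at 0); the
    eccentric branch is a saturating hyperbola reaching ``f_ecc_max`` with a
    slope-continuous (C1) joint at zero velocity.
    """
    w = v_norm / p.v_max
    conc = (1.0 + w) / (1.0 - w / p.A_hill)
    g = p.f_ecc_max
    # match concentric slope (1 + 1/A) at w = 0
    c = (g - 1.0) / (1.0 + 1.0 / p.A_hill)
    ecc = (g * w + c) / (w + c)
    wr = np.real(np.asarray(w))
    return np.where(wr < 0.0, conc, ecc)


def tendon_force(p: MuscleParameters, l_MTU, s):
    """SEE force: quadratic in strain above slack, smoothly zero below."""
    eps = (l_MTU - s - p.l_slack) / p.l_slack
    e = _smooth_pos(eps, _EPS_STRAIN)
    return p.F_ISO * (e / p.eps0_SEE) ** 2


def tendon_force_ds(p: MuscleParameters, l_MTU, s):
    """Analytic d F_SEE / d s (used when assembling sparse Jacobians)."""
    eps = (l_MTU - s - p.l_slack) / p.l_slack
    e = _smooth_pos(eps, _EPS_STRAIN)
    de = 0.5 * (1.0 + eps / np.sqrt(eps * eps + _EPS_STRAIN**2))
    return p.F_ISO * 2.0 * e / p.eps0_SEE**2 * de * (-1.0 / p.l_slack)


def _pee_force(p: MuscleParameters, l_CE):
    stretch = _smooth_pos(l_CE / p.l_CE_opt - 1.0, _EPS_STRAIN)
    return p.k_PEE * p.F_ISO * stretch * stretch


def contraction_residual(p: MuscleParameters, a, s, sdot, l_MTU):
    """Implicit contraction dynamics residual (N) and the SEE force (N).

    With the constant-height pennation model the CE force projected on the
    line of action must balance the tendon force:

        F_SEE(l_MTU, s) - (a F_ISO f_L f_V + F_PEE + F_damp) cos(phi) = 0

    where ``v_CE = sdot * cos(phi)`` and the residual is zero iff ``sdot``
    satisfies the contraction dynamics.  Strictly monotone (decreasing) in
    ``sdot``, hence the implicit ODE is well posed.
    """
    s = np.asarray(s)
    if np.any(np.real(s) <= 0):
        raise ValueError("contraction state s must be > 0")
    h = p.height
    l_CE = np.sqrt(s * s + h * h)
    cos_phi = s / l_CE
    v_CE = sdot * cos_phi
    F_SEE = tendon_force(p, l_MTU, s)
    fL = force_length(p, l_CE)
    fV = force_velocity(p, v_CE / p.l_CE_opt)
    F_damp = p.d_CE * p.F_ISO * (v_CE / p.l_CE_opt)
    F_CE = a * p.F_ISO * fL * fV + _pee_force(p, l_CE) + F_damp
    return F_SEE - F_CE * cos_phi, F_SEE


def activation_residual(p: MuscleParameters, a, adot, n_e):
    """Implicit first-order activation dynamics residual (1/s).

    The rate constant blends smoothly between 1/T_act (full excitation) and
    1/T_deact (no excitation), so the residual is differentiable everywhere:

        adot - (n_e - a) * (n_e/T_act + (1 - n_e)/T_deact) = 0
    """
    rate = n_e / p.T_act + (1.0 - n_e) / p.T_deact
    return adot - (n_e - a) * rate
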