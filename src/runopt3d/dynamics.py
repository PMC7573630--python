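"""Implicit full-body dynamics: f(x, xdot, u) = 0 and its sparse Jacobians.

The skeletal equations of motion are evaluated in inverse-dynamics form by a
recursive Newton-Euler pass over the kinematic tree: every multi-DOF joint is
decomposed into a chain of elementary one-DOF prismatic/revolute joints, so a
single algorithm covers free, ball and revolute joints.  The multibody rows
of the residual are

    tau_ID(q, qdot, qddot) - tau_muscles - tau_actuators - tau_contact = 0

without ever forming the mass matrix explicitly.  The full residual stacks

    (a) kinematic identity   xdot_q - x_qdot
    (b) multibody rows       (above)
    (c) muscle contraction   implicit Hill dynamics per MTU
    (d) muscle activation    implicit first-order dynamics per MTU

Everything is vectorized over a leading batch axis and written to be
dtype-agnostic so that derivatives are obtained by batched complex-step
differentiation (exact to machine precision, satisfying the finite-difference
agreement contract by a wide margin).

Row scaling: ``full_dynamics_residual`` nondimensionalizes multibody rows by
subject weight, contraction rows by each muscle's F_ISO and activation rows
by T_act, so a single defect tolerance is meaningful across units.
``multibody_residual`` itself is raw SI (N / N m).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .contact import contact_force
from .model import _AXES, ModelDefinition
from .muscles import activation_residual, contraction_residual

__all__ = [
    "KinematicsResult",
    "ResidualJacobians",
    "forward_kinematics",
    "multibody_residual",
    "full_dynamics_residual",
    "residual_jacobians",
    "residual_batched",
    "grf_batched",
    "forward_dynamics",
    "energy",
]

_CS_H = 1e-30  # complex-step size


def _skew(a):
    return np.array([[0.0, -a[2], a[1]], [a[2], 0.0, -a[0]], [-a[1], a[0], 0.0]])


def _mm(A, B):
    return np.einsum("...ij,...jk->...ik", A, B)


def _mv(A, b):
    return np.einsum("...ij,...j->...i", A, b)


def _cross(a, b):
    # explicit cross product; np.cross upcasts oddly for complex in some versions
    return np.stack([
        a[..., 1] * b[..., 2] - a[..., 2] * b[..., 1],
        a[..., 2] * b[..., 0] - a[..., 0] * b[..., 2],
        a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0],
    ], axis=-1)


@dataclass
class _Body:
    mass: float
    com: np.ndarray
    inertia: np.ndarray
    contact_points: tuple
    segment: str


@dataclass
class _Elem:
    parent: int  # elementary parent index, -1 = ground
    kind: str  # 'rev' | 'pris'
    axis: np.ndarray  # unit axis in parent-of-this-elementary frame
    offset: np.ndarray  # fixed translation from parent frame origin
    dof: int  # index into q
    body: _Body | None = None


class KinematicChain:
    """Elementary-joint decomposition of a ModelDefinition's joint tree."""

    def __init__(self, model: ModelDefinition):
        elems: list[_Elem] = []
        seg_elem: dict[str, int] = {}
        dof_idx = model.dof_index
        # topological order over joints (parents before children)
        joints = list(model.joints)
        placed = {"ground": -1}
        ordered = []
        while joints:
            progressed = False
            for j in joints:
                if j.parent in placed:
                    ordered.append(j)
                    joints.remove(j)
                    placed[j.child] = None
                    progressed = True
                    break
            if not progressed:
                raise ValueError("joint graph is not a tree rooted at 'ground'")
        for j in ordered:
            parent_elem = seg_elem.get(j.parent, -1)
            names = list(j.dof_names)
            sub = []
            if j.type == "free6":
                for ax, nm in zip(("x", "y", "z"), names[:3]):
                    sub.append(("pris", _AXES[ax], nm))
                for ax, nm in zip(j.rotation_order, names[3:]):
                    sub.append(("rev", _AXES[ax], nm))
            elif j.type == "ball3":
                for ax, nm in zip(j.rotation_order, names):
                    sub.append(("rev", _AXES[ax], nm))
            elif j.type == "revolute1":
                sub.append(("rev", np.asarray(j.axis, dtype=float), names[0]))
            else:
                raise ValueError(f"unknown joint type {j.type}")
            prev = parent_elem
            for i, (kind, axis, nm) in enumerate(sub):
                off = np.asarray(j.translation, dtype=float) if i == 0 else np.zeros(3)
                elems.append(_Elem(prev, kind, np.asarray(axis, float), off, dof_idx[nm]))
                prev = len(elems) - 1
            seg = model.segment(j.child)
            elems[prev].body = _Body(
                seg.mass,
                np.asarray(seg.com_offset, float),
                np.asarray(seg.inertia, float),
                tuple(np.asarray(p, float) for p in seg.contact_points),
                seg.name,
            )
            seg_elem[j.child] = prev
        self.elems = elems
        self.seg_elem = seg_elem
        self.n_dof = len(model.dof_names)
        # ancestor chains for applied point forces
        self.ancestors = []
        for i in range(len(elems)):
            path = []
            k = i
            while k >= 0:
                path.append(k)
                k = elems[k].parent
            self.ancestors.append(path)
        # contact registry: (elem index, local point)
        self.contacts = []
        for i, e in enumerate(elems):
            if e.body is not None:
                for p in e.body.contact_points:
                    self.contacts.append((i, p, e.body.segment))


def get_chain(model: ModelDefinition) -> KinematicChain:
    chain = getattr(model, "_chain", None)
    if chain is None:
        chain = KinematicChain(model)
        model._chain = chain
    return chain


def _rodrigues(axis, th):
    K = _skew(axis)
    K2 = K @ K
    I = np.eye(3)
    s = np.sin(th)[..., None, None]
    c = (1.0 - np.cos(th))[..., None, None]
    return I + s * K + c * K2


class _FramePass:
    """World-frame kinematic/acceleration pass over the elementary chain."""

    __slots__ = ("R", "o", "w", "v", "wd", "ao")

    def __init__(self, chain: KinematicChain, q, qd=None, qdd=None):
        B = q.shape[:-1]
        dt = q.dtype
        for arr in (qd, qdd):
            if arr is not None:
                dt = np.result_type(dt, arr.dtype)
        n = len(chain.elems)
        self.R = [None] * n
        self.o = [None] * n
        self.w = [None] * n
        self.v = [None] * n
        self.wd = [None] * n
        self.ao = [None] * n
        I3 = np.broadcast_to(np.eye(3, dtype=dt), B + (3, 3))
        zero3 = np.zeros(B + (3,), dtype=dt)
        for i, e in enumerate(chain.elems):
            p = e.parent
            Rp = I3 if p < 0 else self.R[p]
            op = zero3 if p < 0 else self.o[p]
            wp = zero3 if p < 0 else self.w[p]
            vp = zero3 if p < 0 else self.v[p]
            wdp = zero3 if p < 0 else self.wd[p]
            aop = zero3 if p < 0 else self.ao[p]
            qi = q[..., e.dof]
            qdi = None if qd is None else qd[..., e.dof]
            qddi = None if qdd is None else qdd[..., e.dof]
            u = _mv(Rp, np.broadcast_to(e.axis.astype(dt), B + (3,)))
            if e.kind == "rev":
                Rrel = _rodrigues(e.axis, qi)
                self.R[i] = _mm(Rp, Rrel)
                d_w = _mv(Rp, np.broadcast_to(e.offset.astype(dt), B + (3,)))
                self.o[i] = op + d_w
                if qd is not None:
                    self.w[i] = wp + qdi[..., None] * u
                    self.v[i] = vp + _cross(wp, d_w)
                if qdd is not None:
                    self.wd[i] = wdp + qddi[..., None] * u + qdi[..., None] * _cross(wp, u)
                    self.ao[i] = aop + _cross(wdp, d_w) + _cross(wp, _cross(wp, d_w))
            else:  # prismatic
                self.R[i] = Rp
                d = e.offset.astype(dt) + qi[..., None] * e.axis.astype(dt)
                d_w = _mv(Rp, d)
                self.o[i] = op + d_w
                if qd is not None:
                    self.w[i] = wp
                    self.v[i] = vp + _cross(wp, d_w) + qdi[..., None] * u
                if qdd is not None:
                    self.wd[i] = wdp
                    self.ao[i] = (aop + _cross(wdp, d_w) + _cross(wp, _cross(wp, d_w))
                                  + 2.0 * qdi[..., None] * _cross(wp, u) + qddi[..., None] * u)

    def point(self, chain, elem, local):
        r_w = _mv(self.R[elem], np.broadcast_to(np.asarray(local, float), self.o[elem].shape))
        pos = self.o[elem] + r_w
        vel = None
        if self.v[elem] is not None:
            vel = self.v[elem] + _cross(self.w[elem], r_w)
        return pos, vel


def _inverse_dynamics(chain: KinematicChain, fp: _FramePass, gravity) -> np.ndarray:
    """Generalized forces tau_ID = M qdd + bias (gravity included)."""
    n = len(chain.elems)
    g = np.asarray(gravity, float)
    F = [None] * n
    M = [None] * n
    for i, e in enumerate(chain.elems):
        if e.body is None:
            continue
        b = e.body
        r_c = _mv(fp.R[i], np.broadcast_to(b.com, fp.o[i].shape))
        c = fp.o[i] + r_c
        a_c = fp.ao[i] + _cross(fp.wd[i], r_c) + _cross(fp.w[i], _cross(fp.w[i], r_c))
        Fi = b.mass * (a_c - g)
        Iw = _mm(_mm(fp.R[i], np.broadcast_to(b.inertia, fp.R[i].shape)),
                 np.swapaxes(fp.R[i], -1, -2))
        Ni = _mv(Iw, fp.wd[i]) + _cross(fp.w[i], _mv(Iw, fp.w[i]))
        F[i] = Fi
        M[i] = Ni + _cross(c, Fi)
    # subtree accumulation (children have larger indices)
    SF = [None] * n
    SM = [None] * n
    for i in range(n - 1, -1, -1):
        sf, sm = SF[i], SM[i]
        if F[i] is not None:
            sf = F[i] if sf is None else sf + F[i]
            sm = M[i] if sm is None else sm + M[i]
        SF[i], SM[i] = sf, sm
        p = chain.elems[i].parent
        if p >= 0 and sf is not None:
            SF[p] = sf if SF[p] is None else SF[p] + sf
            SM[p] = sm if SM[p] is None else SM[p] + sm
    batch = fp.o[0].shape[:-1]
    dt = fp.o[0].dtype
    tau = np.zeros(batch + (chain.n_dof,), dtype=dt)
    for i, e in enumerate(chain.elems):
        if SF[i] is None:
            continue
        p = e.parent
        if p < 0:
            u = np.broadcast_to(e.axis.astype(dt), batch + (3,))
        else:
            u = _mv(fp.R[p], np.broadcast_to(e.axis.astype(dt), batch + (3,)))
        if e.kind == "rev":
            mom = SM[i] - _cross(fp.o[i], SF[i])
            tau[..., e.dof] += np.sum(u * mom, axis=-1)
        else:
            tau[..., e.dof] += np.sum(u * SF[i], axis=-1)
    return tau


def _point_force_tau(chain: KinematicChain, fp: _FramePass, elem: int, P, Fc, tau):
    """Accumulate generalized forces of a point force via virtual work."""
    dt = tau.dtype
    batch = tau.shape[:-1]
    for j in chain.ancestors[elem]:
        e = chain.elems[j]
        p = e.parent
        if p < 0:
            u = np.broadcast_to(e.axis.astype(dt), batch + (3,))
        else:
            u = _mv(fp.R[p], np.broadcast_to(e.axis.astype(dt), batch + (3,)))
        if e.kind == "rev":
            tau[..., e.dof] += np.sum(u * _cross(P - fp.o[j], Fc), axis=-1)
        else:
            tau[..., e.dof] += np.sum(u * Fc, axis=-1)


# ---------------------------------------------------------------------------
# public kinematics API
# ---------------------------------------------------------------------------

@dataclass
class KinematicsResult:
    segment_poses: dict  # name -> (R 3x3, origin 3)
    contact_positions: dict  # segment -> list of 3-vectors
    contact_velocities: dict


def forward_kinematics(model: ModelDefinition, q, qd) -> KinematicsResult:
    q = np.asarray(q, dtype=float)
    qd = np.asarray(qd, dtype=float)
    if q.shape != (len(model.dof_names),) or qd.shape != q.shape:
        raise ValueError("q and qd must both have length n_dof")
    if np.any(~np.isfinite(q)):
        bad = model.dof_names[int(np.flatnonzero(~np.isfinite(q))[0])]
        raise ValueError(f"non-finite value in q at DOF '{bad}'")
    chain = get_chain(model)
    fp = _FramePass(chain, q[None, :], qd[None, :])
    poses = {}
    for seg, i in chain.seg_elem.items():
        poses[seg] = (fp.R[i][0], fp.o[i][0])
    cpos: dict[str, list] = {}
    cvel: dict[str, list] = {}
    for elem, local, seg in chain.contacts:
        pos, vel = fp.point(chain, elem, local)
        cpos.setdefault(seg, []).append(pos[0])
        cvel.setdefault(seg, []).append(vel[0])
    return KinematicsResult(poses, cpos, cvel)


def multibody_residual(model: ModelDefinition, q, qd, qdd, tau_gen) -> np.ndarray:
    """Raw-unit skeletal residual M(q) qdd + bias(q, qd) - tau_gen."""
    arrs = [np.atleast_2d(np.asarray(v)) for v in (q, qd, qdd, tau_gen)]
    q2, qd2, qdd2, tau2 = arrs
    chain = get_chain(model)
    fp = _FramePass(chain, q2, qd2, qdd2)
    res = _inverse_dynamics(chain, fp, model.gravity) - tau2
    return res[0] if np.asarray(q).ndim == 1 else res


# ---------------------------------------------------------------------------
# full residual
# ---------------------------------------------------------------------------

def _muscle_meta(model: ModelDefinition):
    meta = getattr(model, "_muscle_meta", None)
    if meta is None:
        dof_idx = model.dof_index
        meta = []
        for m in model.muscles:
            meta.append((m, np.asarray([dof_idx[d] for d in m.path.dof_names], dtype=int)))
        model._muscle_meta = meta
    return meta


def _scale_vector(model: ModelDefinition) -> np.ndarray:
    lay = model.layout
    scale = np.ones(lay.n_x)
    scale[lay.qdot] = 1.0 / model.weight()
    for i, m in enumerate(model.muscles):
        scale[lay.s.start + i] = 1.0 / m.params.F_ISO
        scale[lay.a.start + i] = m.params.T_act
    return scale


def residual_batched(model: ModelDefinition, X, Xd, U, scaled: bool = True) -> np.ndarray:
    """Vectorized full dynamics residual; X/Xd (B, n_x), U (B, n_u) -> (B, n_x).

    Accepts complex input for algorithmic differentiation.
    """
    lay = model.layout
    X = np.asarray(X)
    Xd = np.asarray(Xd)
    U = np.asarray(U)
    q, qd_state, s, a = lay.unpack_state(X)
    qdot_kin, qdd, sdot, adot = lay.unpack_state(Xd)
    n_e, m_ctrl = lay.unpack_control(U)

    rows_kin = qdot_kin - qd_state

    chain = get_chain(model)
    fp = _FramePass(chain, q, qd_state, qdd)
    tau_id = _inverse_dynamics(chain, fp, model.gravity)

    dt_all = np.result_type(X.dtype, Xd.dtype, U.dtype, float)
    tau_app = np.zeros(q.shape[:-1] + (lay.n_dof,), dtype=dt_all)
    rows_con = np.empty(q.shape[:-1] + (lay.n_mus,), dtype=dt_all)
    for i, (mrec, dofs) in enumerate(_muscle_meta(model)):
        qp = q[..., dofs]
        l_mtu = mrec.path.length(qp)
        arms = -mrec.path.dlength(qp)
        res_i, F_see = contraction_residual(mrec.params, a[..., i], s[..., i], sdot[..., i], l_mtu)
        rows_con[..., i] = res_i
        for j, dof in enumerate(dofs):
            tau_app[..., dof] += arms[..., j] * F_see
    dof_idx = model.dof_index
    for i, (dof, norm) in enumerate(model.torque_actuators):
        tau_app[..., dof_idx[dof]] += norm * m_ctrl[..., i]
    for elem, local, _seg in chain.contacts:
        P, V = fp.point(chain, elem, local)
        Fc = contact_force(P, V, model.contact)
        _point_force_tau(chain, fp, elem, P, Fc, tau_app)

    rows_mb = tau_id - tau_app
    rows_act = np.empty_like(rows_con)
    for i, (mrec, _d) in enumerate(_muscle_meta(model)):
        rows_act[..., i] = activation_residual(mrec.params, a[..., i], adot[..., i], n_e[..., i])

    res = np.concatenate([rows_kin, rows_mb, rows_con, rows_act], axis=-1)
    if scaled:
        res = res * _scale_vector(model)
    return res


def full_dynamics_residual(model: ModelDefinition, x, xd, u, scaled: bool = True) -> np.ndarray:
    """Residual f(x, xdot, u) at a single point, rows nondimensionalized."""
    lay = model.layout
    x = np.asarray(x, dtype=np.result_type(x, float))
    xd = np.asarray(xd, dtype=np.result_type(xd, float))
    u = np.asarray(u, dtype=np.result_type(u, float))
    if x.shape != (lay.n_x,) or xd.shape != (lay.n_x,) or u.shape != (lay.n_u,):
        raise ValueError(
            f"layout mismatch: expected n_x={lay.n_x}, n_u={lay.n_u}, got "
            f"{x.shape}, {xd.shape}, {u.shape}")
    return residual_batched(model, x[None], xd[None], u[None], scaled=scaled)[0]


def grf_batched(model: ModelDefinition, Q, Qd) -> np.ndarray:
    """Per-group ground reaction forces, shape (B, n_groups*3).

    Groups follow ``model.grf_groups`` order; components are (x, y, z) in the
    ground frame.  Complex-safe.
    """
    chain = get_chain(model)
    fp = _FramePass(chain, np.asarray(Q), np.asarray(Qd))
    by_seg: dict[str, np.ndarray] = {}
    for elem, local, seg in chain.contacts:
        P, V = fp.point(chain, elem, local)
        Fc = contact_force(P, V, model.contact)
        by_seg[seg] = Fc if seg not in by_seg else by_seg[seg] + Fc
    outs = []
    B = np.asarray(Q).shape[:-1]
    dt = next(iter(by_seg.values())).dtype if by_seg else np.asarray(Q).dtype
    for side, segs in model.grf_groups.items():
        tot = np.zeros(B + (3,), dtype=dt)
        for seg in segs:
            if seg in by_seg:
                tot = tot + by_seg[seg]
        outs.append(tot)
    return np.concatenate(outs, axis=-1)


def contact_heights(model: ModelDefinition, Q) -> dict:
    """Per-GRF-group minimum contact-point height (B,) at configurations Q."""
    chain = get_chain(model)
    Q = np.asarray(Q, float)
    fp = _FramePass(chain, Q, np.zeros_like(Q))
    by_seg: dict[str, np.ndarray] = {}
    for elem, local, seg in chain.contacts:
        P, _ = fp.point(chain, elem, local)
        y = P[..., 1]
        by_seg[seg] = y if seg not in by_seg else np.minimum(by_seg[seg], y)
    out = {}
    for side, segs in model.grf_groups.items():
        out[side] = np.min([by_seg[s] for s in segs if s in by_seg], axis=0)
    return out


def contact_generalized_forces(model: ModelDefinition, q, qd):
    """Generalized contact forces and per-group GRFs at one configuration."""
    chain = get_chain(model)
    q2 = np.asarray(q, float)[None]
    qd2 = np.asarray(qd, float)[None]
    fp = _FramePass(chain, q2, qd2, np.zeros_like(q2))
    tau = np.zeros((1, chain.n_dof))
    by_seg: dict[str, np.ndarray] = {}
    for elem, local, seg in chain.contacts:
        P, V = fp.point(chain, elem, local)
        Fc = contact_force(P, V, model.contact)
        _point_force_tau(chain, fp, elem, P, Fc, tau)
        by_seg[seg] = Fc if seg not in by_seg else by_seg[seg] + Fc
    grfs = {}
    for side, segs in model.grf_groups.items():
        grfs[side] = np.sum([by_seg.get(s, np.zeros((1, 3))) for s in segs], axis=0)[0]
    return tau[0], grfs


# ---------------------------------------------------------------------------
# Jacobians
# ---------------------------------------------------------------------------

@dataclass
class ResidualJacobians:
    dfdx: sp.csr_matrix
    dfdxd: sp.csr_matrix
    dfdu: sp.csr_matrix


def residual_jacobians_dense(model: ModelDefinition, x, xd, u, scaled: bool = True):
    """Dense (n_x, n_x|n_u) Jacobians of the residual by batched complex step."""
    lay = model.layout
    n_x, n_u = lay.n_x, lay.n_u
    nd = 2 * n_x + n_u
    X = np.tile(np.asarray(x, complex), (nd, 1))
    Xd = np.tile(np.asarray(xd, complex), (nd, 1))
    U = np.tile(np.asarray(u, complex), (nd, 1))
    ih = 1j * _CS_H
    for d in range(n_x):
        X[d, d] += ih
        Xd[n_x + d, d] += ih
    for d in range(n_u):
        U[2 * n_x + d, d] += ih
    res = residual_batched(model, X, Xd, U, scaled=scaled)
    J = res.imag / _CS_H  # (nd, n_x): row d = df/d(dir d)
    return J[:n_x].T.copy(), J[n_x:2 * n_x].T.copy(), J[2 * n_x:].T.copy()


def residual_jacobians(model: ModelDefinition, x, xd, u, scaled: bool = True) -> ResidualJacobians:
    """Sparse residual Jacobians with a fixed, model-cached sparsity pattern."""
    pattern = getattr(model, "_jac_pattern", None)
    if pattern is None:
        rng = np.random.default_rng(7)
        lay = model.layout
        masks = [np.zeros((lay.n_x, n), dtype=bool) for n in (lay.n_x, lay.n_x, lay.n_u)]
        lb, ub = model.state_bounds().T
        for _ in range(3):
            xs = lb + (ub - lb) * rng.uniform(0.2, 0.8, lay.n_x)
            xds = rng.normal(0, 1.0, lay.n_x)
            us = rng.uniform(0.05, 0.9, lay.n_u)
            Js = residual_jacobians_dense(model, xs, xds, us, scaled=scaled)
            for mask, Jm in zip(masks, Js):
                mask |= Jm != 0.0
        pattern = [np.nonzero(mk) for mk in masks]
        model._jac_pattern = pattern
    Jx, Jxd, Ju = residual_jacobians_dense(model, x, xd, u, scaled=scaled)
    lay = model.layout
    out = []
    for Jm, (rows, cols), ncol in zip((Jx, Jxd, Ju), pattern, (lay.n_x, lay.n_x, lay.n_u)):
        out.append(sp.csr_matrix((Jm[rows, cols], (rows, cols)), shape=(lay.n_x, ncol)))
    return ResidualJacobians(*out)


def residual_block_jacobians(model: ModelDefinition, Xk, Xd, Uk):
    """Per-node dense Jacobians (B, n_x, n_x|n_u) of the scaled residual.

    Exploits the residual's block structure to keep the complex-step batch
    small: q/qdot/qddot columns are stepped individually, while the muscle
    contraction and activation rows are diagonal in (s, a, sdot, n_e) and are
    recovered from one simultaneous step per group; the multibody rows'
    dependence on s (tendon force times moment arm) and on the actuator
    controls is filled in analytically.  Agrees with the full complex-step
    Jacobian to machine precision (unit-tested).
    """
    from .muscles import tendon_force_ds

    lay = model.layout
    n_x, n_u, nd_dof, n_mus = lay.n_x, lay.n_u, lay.n_dof, lay.n_mus
    B = np.asarray(Xk).shape[0]
    dirs_q = np.arange(nd_dof)
    dirs_qd = nd_dof + np.arange(nd_dof)
    dir_s, dir_a = 2 * nd_dof, 2 * nd_dof + 1
    dirs_qdd = 2 * nd_dof + 2 + np.arange(nd_dof)
    dir_sdot = 3 * nd_dof + 2
    dir_ne = 3 * nd_dof + 3
    n_dirs = 3 * nd_dof + 4

    ih = 1j * _CS_H
    Xc = np.repeat(np.asarray(Xk, complex)[:, None, :], n_dirs, axis=1)
    Xdc = np.repeat(np.asarray(Xd, complex)[:, None, :], n_dirs, axis=1)
    Uc = np.repeat(np.asarray(Uk, complex)[:, None, :], n_dirs, axis=1)
    Xc[:, dirs_q, dirs_q] += ih
    Xc[:, dirs_qd, nd_dof + dirs_q] += ih
    Xc[:, dir_s, lay.s] += ih
    Xc[:, dir_a, lay.a] += ih
    Xdc[:, dirs_qdd, nd_dof + dirs_q] += ih
    Xdc[:, dir_sdot, lay.s] += ih
    Uc[:, dir_ne, lay.n_e] += ih
    res = residual_batched(model, Xc.reshape(-1, n_x), Xdc.reshape(-1, n_x),
                           Uc.reshape(-1, n_u))
    J = res.reshape(B, n_dirs, n_x).imag / _CS_H  # (B, dir, row)

    r_kin = np.arange(nd_dof)
    r_mb = nd_dof + np.arange(nd_dof)
    r_con = 2 * nd_dof + np.arange(n_mus)
    r_act = 2 * nd_dof + n_mus + np.arange(n_mus)

    dfdx = np.zeros((B, n_x, n_x))
    dfdxd = np.zeros((B, n_x, n_x))
    dfdu = np.zeros((B, n_x, n_u))
    # q and qdot columns: all rows at once
    dfdx[:, :, :nd_dof] = np.swapaxes(J[:, dirs_q], 1, 2)
    dfdx[:, :, nd_dof:2 * nd_dof] = np.swapaxes(J[:, dirs_qd], 1, 2)
    # diagonal muscle blocks
    s_cols = np.arange(lay.s.start, lay.s.stop)
    a_cols = np.arange(lay.a.start, lay.a.stop)
    dfdx[:, r_con, s_cols] = J[:, dir_s][:, r_con]
    dfdx[:, r_con, a_cols] = J[:, dir_a][:, r_con]
    dfdx[:, r_act, a_cols] = J[:, dir_a][:, r_act]
    dfdxd[:, r_con, s_cols] = J[:, dir_sdot][:, r_con]
    dfdu[:, r_act, np.arange(n_mus)] = J[:, dir_ne][:, r_act]
    # qddot columns (multibody mass-matrix action)
    dfdxd[:, :, nd_dof:2 * nd_dof] = np.swapaxes(J[:, dirs_qdd], 1, 2)
    # kinematic identity rows: xdot_q - x_qdot
    dfdxd[:, r_kin, r_kin] = 1.0
    # activation rows: d/d adot = T_act (the row scaling)
    for i, mrec in enumerate(model.muscles):
        dfdxd[:, r_act[i], a_cols[i]] = mrec.params.T_act
    # multibody rows: s columns via tendon force and moment arms (analytic)
    q = np.asarray(Xk)[:, lay.q].real
    s = np.asarray(Xk)[:, lay.s].real
    w_inv = 1.0 / model.weight()
    for i, (mrec, dofs) in enumerate(_muscle_meta(model)):
        qp = q[:, dofs]
        l_mtu = mrec.path.length(qp)
        arms = -mrec.path.dlength(qp)  # (B, n_path_dofs)
        dF = tendon_force_ds(mrec.params, l_mtu, s[:, i])  # (B,)
        for j, dof in enumerate(dofs):
            dfdx[:, nd_dof + dof, s_cols[i]] -= arms[:, j] * dF * w_inv
    # multibody rows: actuator columns (constant)
    di = model.dof_index
    for j, (dof, norm) in enumerate(model.torque_actuators):
        dfdu[:, nd_dof + di[dof], n_mus + j] = -norm * w_inv
    return dfdx, dfdxd, dfdu


# ---------------------------------------------------------------------------
# helpers for oracles/tests
# ---------------------------------------------------------------------------

def forward_dynamics(model: ModelDefinition, q, qd, tau_gen) -> np.ndarray:
    """Solve the (raw) multibody rows for qdd; exploits affinity in qdd."""
    n = len(model.dof_names)
    q = np.asarray(q, float)
    qd = np.asarray(qd, float)
    bias = multibody_residual(model, q, qd, np.zeros(n), np.zeros(n))
    Mcols = np.empty((n, n))
    for i in range(n):
        e = np.zeros(n)
        e[i] = 1.0
        Mcols[:, i] = multibody_residual(model, q, qd, e, np.zeros(n)) - bias
    return np.linalg.solve(Mcols, np.asarray(tau_gen, float) - bias)


def energy(model: ModelDefinition, q, qd) -> float:
    """Total mechanical energy T + V of the passive skeleton."""
    chain = get_chain(model)
    fp = _FramePass(chain, np.asarray(q, float)[None], np.asarray(qd, float)[None])
    g = np.asarray(model.gravity, float)
    E = 0.0
    for i, e in enumerate(chain.elems):
        if e.body is None:
            continue
        b = e.body
        r_c = _mv(fp.R[i], np.broadcast_to(b.com, (1, 3)))
        c = (fp.o[i] + r_c)[0]
        v_c = (fp.v[i] + _cross(fp.w[i], r_c))[0]
        w = fp.w[i][0]
        Iw = fp.R[i][0] @ b.inertia @ fp.R[i][0].T
        E += 0.5 * b.mass * float(v_c @ v_c) + 0.5 * float(w @ Iw @ w) - b.mass * float(g @ c)
    return E
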