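"""Backward-Euler direct collocation: OCP -> sparse NLP -> solution.

The optimal control problem (implicit dynamics, bounds, periodicity, free
cycle duration) is transcribed on N nodes t_k = k h, h = T_sim / N.  The
state at T_sim is not a decision variable: it is the periodicity image of
the first node, so the cycle closes with exactly N defect blocks

    f(x_k, (x_k - x_{k-1}) / h, u_k) = 0,   k = 1..N-1
    f(x_per, (x_per - x_{N-1}) / h, u_0) = 0,   x_per = R_per x_0 + t_per

and controls are identified across the wrap (u(T_sim) = u(0)).

The resulting NLP is solved with scipy.optimize: the single-node standing
problem by SLSQP, the running problems by an augmented-Lagrangian
Gauss-Newton continuation (scipy.optimize.least_squares with sparse
Jacobians and the LSMR trust-region solver) -- every objective term is an
exact sum of squares, so Gauss-Newton curvature is the natural quasi-Newton
model here.  Derivatives of the defects are exact (batched complex step).

First-node anchors (pelvis tx/tz) are imposed by pinning the corresponding
decision variables, which is equivalent to the anchor equality rows.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import least_squares

from .dynamics import grf_batched, residual_batched, residual_block_jacobians
from .model import ModelDefinition
from .objective import (ObjectiveConfig, TrackingReference, adjust_variance,
                        muscle_volume_fractions, signal_weights, total_objective)

__all__ = [
    "central_angle",
    "PeriodicityMap",
    "periodicity_residual",
    "backward_euler_defects",
    "NLPProblem",
    "assemble_nlp",
    "solve",
    "check_derivatives",
    "SolverSettings",
    "Solution",
]

_CS_H = 1e-30


def central_angle(v_norm: float, T_sim, r: float):
    """Central angle of one cycle on a circle: theta = 2 asin(v T / 2r).

    Returns ``(theta, dtheta/dT)``; complex-safe in ``T_sim``.  Raises when
    the chord v*T exceeds the diameter.
    """
    arg = v_norm * T_sim / (2.0 * r)
    if np.any(np.real(arg) > 1.0):
        raise ValueError(
            f"infeasible circle geometry: chord v*T = {np.max(np.real(arg)) * 2 * r:.3f} m "
            f"exceeds diameter {2 * r:.3f} m")
    theta = 2.0 * np.arcsin(arg)
    with np.errstate(divide="ignore"):
        dtheta = v_norm / r / np.sqrt(np.maximum(1e-300, 1.0 - np.real(arg) ** 2))
    return theta, dtheta


@dataclass
class PeriodicityMap:
    """State map across one cycle: x(T) = R_per x(0) + t_per.

    ``kind='straight'`` translates the pelvis position by (v_x T, 0, v_z T);
    ``kind='curved'`` rotates pelvis horizontal position and velocity about
    the vertical axis by the central angle theta(T) and adds theta to the
    heading.  All other entries map identically.
    """

    kind: str = "identity"
    v: tuple = (0.0, 0.0)
    v_norm: float = 0.0
    radius: float = 1.0
    idx_tx: int = 0
    idx_ty: int = 1
    idx_tz: int = 2
    idx_rot: int = 3
    idx_vx: int = 0
    idx_vz: int = 2

    @classmethod
    def straight(cls, model: ModelDefinition, v_x: float, v_z: float) -> "PeriodicityMap":
        return cls(kind="straight", v=(v_x, v_z), **_pelvis_indices(model))

    @classmethod
    def curved(cls, model: ModelDefinition, v_norm: float, radius: float) -> "PeriodicityMap":
        return cls(kind="curved", v_norm=v_norm, radius=radius, **_pelvis_indices(model))

    def theta(self, T):
        if self.kind == "curved":
            return central_angle(self.v_norm, T, self.radius)[0]
        return np.zeros_like(np.asarray(T, dtype=np.result_type(T, float)))

    def t_per(self, T):
        t = np.zeros(3, dtype=np.result_type(T, float))
        if self.kind == "straight":
            t[0] = self.v[0] * T
            t[2] = self.v[1] * T
        return t

    def apply(self, x0, T):
        """Map first-node state(s) to the cycle end; broadcasts and is complex-safe."""
        x0 = np.asarray(x0)
        dt = np.result_type(x0.dtype, np.asarray(T).dtype, float)
        out = x0.astype(dt).copy()
        T = np.asarray(T, dtype=dt)
        if self.kind == "identity":
            return out
        if self.kind == "straight":
            out[..., self.idx_tx] += self.v[0] * T
            out[..., self.idx_tz] += self.v[1] * T
            return out
        th, _ = central_angle(self.v_norm, T, self.radius)
        c, s = np.cos(th), np.sin(th)
        for ix, iz in ((self.idx_tx, self.idx_tz), (self.idx_vx, self.idx_vz)):
            px, pz = x0[..., ix].astype(dt), x0[..., iz].astype(dt)
            out[..., ix] = c * px + s * pz
            out[..., iz] = -s * px + c * pz
        out[..., self.idx_rot] += th
        return out

    def jacobian(self, x0, T):
        """Analytic (dP/dx0, dP/dT) of ``apply`` at a single state."""
        n = len(x0)
        DP = np.eye(n)
        dPdT = np.zeros(n)
        if self.kind == "identity":
            return DP, dPdT
        if self.kind == "straight":
            dPdT[self.idx_tx] = self.v[0]
            dPdT[self.idx_tz] = self.v[1]
            return DP, dPdT
        th, dth = central_angle(self.v_norm, T, self.radius)
        c, s = np.cos(th), np.sin(th)
        for ix, iz in ((self.idx_tx, self.idx_tz), (self.idx_vx, self.idx_vz)):
            DP[ix, ix], DP[ix, iz] = c, s
            DP[iz, ix], DP[iz, iz] = -s, c
            px, pz = x0[ix], x0[iz]
            dPdT[ix] = dth * (-s * px + c * pz)
            dPdT[iz] = dth * (-c * px - s * pz)
        dPdT[self.idx_rot] = dth
        return DP, dPdT


def _pelvis_indices(model: ModelDefinition) -> dict:
    di = model.dof_index
    n = len(model.dof_names)
    return dict(
        idx_tx=di["pelvis_tx"], idx_ty=di["pelvis_ty"], idx_tz=di["pelvis_tz"],
        idx_rot=di["pelvis_rot"],
        idx_vx=n + di["pelvis_tx"], idx_vz=n + di["pelvis_tz"],
    )


def periodicity_residual(x0, x_end, u0, u_end, pmap: PeriodicityMap, T_sim) -> np.ndarray:
    """Residual of Eq. x(T)=R x(0)+t and u(T)=u(0); zero at a periodic solution."""
    rx = np.asarray(x_end) - pmap.apply(x0, T_sim)
    ru = np.asarray(u_end) - np.asarray(u0)
    return np.concatenate([rx, ru])


def backward_euler_defects(residual_fn, X, U, T_sim, pmap: PeriodicityMap | None = None):
    """Backward-Euler collocation defects for a generic implicit residual.

    ``residual_fn(Xk, Xdot, Uk)`` is evaluated at nodes 1..N-1 plus the
    periodic wrap node (the mapped image of node 0 with the first control).
    """
    X = np.asarray(X)
    U = np.asarray(U)
    N = X.shape[0]
    h = T_sim / N
    x_end = pmap.apply(X[0], T_sim) if pmap is not None else X[0]
    Xk = np.vstack([X[1:], x_end[None]])
    Xd = (Xk - X) / h
    Uk = np.vstack([U[1:], U[:1]])
    return residual_fn(Xk, Xd, Uk)


# ---------------------------------------------------------------------------
# NLP assembly
# ---------------------------------------------------------------------------

@dataclass
class SolverSettings:
    ctol: float = 1e-3          # max scaled defect at success
    opt_tol: float = 1e-5       # optimizer relative cost-decrease tolerance
    max_iter: int = 10000
    penalty_stages: tuple = (100.0, 1000.0, 10000.0)
    al_updates: int = 6
    max_nfev_stage: int = 80
    polish_rounds: int = 1
    lsmr_maxiter: int = 150
    abort_defect: float = np.inf  # give up early when still above this after 2 chunks
    contact_relax: tuple = ()   # contact-stiffness factors solved before the true k_n
    relax_updates: int = 2      # Gauss-Newton chunks per relaxation stage
    feas_rounds: int = 2        # defect-only restoration rounds after the stages
    use_lm: bool = True         # exact-solve Levenberg-Marquardt inner iterations
    lm_iters: int = 40          # LM iterations per chunk
    verbose: int = 0


@dataclass
class Solution:
    X: np.ndarray
    U: np.ndarray
    T_sim: float
    x_virtual: np.ndarray
    objective: float
    terms: dict
    max_defect: float
    converged: bool
    log: list
    task_kind: str = ""
    extras: dict = field(default_factory=dict)


class NLPProblem:
    """Sparse NLP: min J(z) s.t. defects(z)=0, lb <= z <= ub.

    Decision vector z = [x_0..x_{N-1}, u_0..u_{N-1}, (T_sim)].  Exposes
    value/gradient and value/sparse-Jacobian callbacks plus the least-squares
    form of the objective used by the Gauss-Newton path.
    """

    def __init__(self, model: ModelDefinition, kind: str, N: int,
                 config: ObjectiveConfig, ref: TrackingReference | None,
                 tracked: list | None, pmap: PeriodicityMap | None,
                 anchors: dict | None = None, T_bounds=(0.3, 1.5)):
        self.model = model
        self.kind = kind
        self.N = int(N)
        self.config = config
        self.pmap = pmap
        lay = model.layout
        self.lay = lay
        self.n_x, self.n_u = lay.n_x, lay.n_u
        self.has_T = kind != "standing"
        self.n_var = self.N * (self.n_x + self.n_u) + (1 if self.has_T else 0)
        self.iT = self.n_var - 1 if self.has_T else None
        self.T_bounds = T_bounds

        xb = model.state_bounds()
        ub_ = model.control_bounds()
        lb = np.concatenate([np.tile(xb[:, 0], self.N), np.tile(ub_[:, 0], self.N)])
        ub = np.concatenate([np.tile(xb[:, 1], self.N), np.tile(ub_[:, 1], self.N)])
        if self.has_T:
            lb = np.append(lb, T_bounds[0])
            ub = np.append(ub, T_bounds[1])
        if anchors:
            di = model.dof_index
            for dof, val in anchors.items():
                j = di[dof]  # anchor applies to node 0
                lb[j] = ub[j] = float(val)
        if kind == "standing":
            # xdot = 0 implies qdot = 0 through the kinematic identity rows;
            # pinning removes those trivially-degenerate directions
            lb[lay.qdot] = ub[lay.qdot] = 0.0
        self.lb, self.ub = lb, ub
        self.n_con = self.N * self.n_x

        # tracked signals
        self.ref = None
        if tracked:
            if ref is None:
                raise ValueError("tracking task requires a reference")
            names = [t[0] for t in tracked]
            self.ref = ref.subset(names)
            if self.ref.n_samples != self.N:
                raise ValueError(
                    f"reference sampled at {self.ref.n_samples} != N={self.N} nodes")
            di = model.dof_index
            self.ang_idx = np.asarray([di[n] for n, k in tracked if k == "angle"], int)
            grf_names = [n for n, k in tracked if k == "grf"]
            self.grf_cols = np.asarray([self._grf_col(n) for n in grf_names], int)
            w = signal_weights(self.ref.kinds, config.W_ang, config.W_GRF)
            var = np.atleast_2d(adjust_variance(self.ref.sd, config.var_floor_frac))
            # per-signal-per-node LS coefficient sqrt(W_Track * w_i / (N var))
            self.track_coef = np.sqrt(config.W_Track * w[:, None] / (self.N * var))  # (S, N)
        self.vol = muscle_volume_fractions(model.muscles)
        self._defect_ix = None

    # -- variable layout ---------------------------------------------------
    def _grf_col(self, name: str) -> int:
        # names like 'grf_r_y'
        _, side, comp = name.split("_")
        sides = list(self.model.grf_groups.keys())
        return sides.index(side) * 3 + "xyz".index(comp)

    def x_slice(self, k: int) -> slice:
        return slice(k * self.n_x, (k + 1) * self.n_x)

    def u_slice(self, k: int) -> slice:
        off = self.N * self.n_x
        return slice(off + k * self.n_u, off + (k + 1) * self.n_u)

    def split(self, z):
        z = np.asarray(z)
        X = z[: self.N * self.n_x].reshape(self.N, self.n_x)
        U = z[self.N * self.n_x: self.N * (self.n_x + self.n_u)].reshape(self.N, self.n_u)
        T = z[self.iT] if self.has_T else None
        return X, U, T

    def pack(self, X, U, T=None):
        parts = [np.asarray(X).ravel(), np.asarray(U).ravel()]
        if self.has_T:
            parts.append(np.atleast_1d(float(T)))
        return np.concatenate(parts)

    # -- constraints -------------------------------------------------------
    def constraints(self, z) -> np.ndarray:
        X, U, T = self.split(z)
        if self.kind == "standing":
            return residual_batched(self.model, X, np.zeros_like(X), U).ravel()
        fn = lambda Xk, Xd, Uk: residual_batched(self.model, Xk, Xd, Uk)
        return backward_euler_defects(fn, X, U, T, self.pmap).ravel()

    def _defect_indices(self):
        """COO (rows, cols) for the block Jacobian; built once."""
        if self._defect_ix is not None:
            return self._defect_ix
        n_x, n_u, N = self.n_x, self.n_u, self.N
        if self.kind == "standing":
            nd = n_x + n_u
            cols = np.concatenate([np.arange(n_x), self.N * n_x + np.arange(n_u)])
            rows = np.repeat(np.arange(n_x), nd)
            cols = np.tile(cols, n_x)
            self._defect_ix = (rows, cols, nd)
            return self._defect_ix
        nd = 2 * n_x + n_u + 1
        rows = []
        cols = []
        for k in range(N):
            ka = k + 1 if k < N - 1 else 0  # node whose state is 'x_k' (wrap -> x_0)
            col_block = np.concatenate([
                np.arange(self.x_slice(ka).start, self.x_slice(ka).stop),
                np.arange(self.x_slice(k).start, self.x_slice(k).stop),
                np.arange(self.u_slice(ka).start, self.u_slice(ka).stop),
                [self.iT],
            ])
            rows.append(np.repeat(k * n_x + np.arange(n_x), nd))
            cols.append(np.tile(col_block, n_x))
        self._defect_ix = (np.concatenate(rows), np.concatenate(cols), nd)
        return self._defect_ix

    def constraints_jac(self, z) -> sp.csr_matrix:
        X, U, T = self.split(z)
        n_x, n_u, N = self.n_x, self.n_u, self.N
        ih = 1j * _CS_H
        if self.kind == "standing":
            nd = n_x + n_u
            Xc = np.tile(X[0].astype(complex), (nd + 1, 1))
            Uc = np.tile(U[0].astype(complex), (nd + 1, 1))
            for d in range(n_x):
                Xc[d, d] += ih
            for d in range(n_u):
                Uc[n_x + d, d] += ih
            res = residual_batched(self.model, Xc, np.zeros_like(Xc), Uc)
            J = res[:nd].imag / _CS_H  # (nd, n_x)
            rows, cols, _ = self._defect_indices()
            data = J.T.ravel()
            return sp.csr_matrix((data, (rows, cols)), shape=(self.n_con, self.n_var))
        nd = 2 * n_x + n_u + 1
        x_end = self.pmap.apply(X[0], T) if self.pmap is not None else X[0]
        Xk = np.vstack([X[1:], x_end[None]])
        Xd = (Xk - X) * (N / T)
        Uk = np.vstack([U[1:], U[:1]])
        dfdx, dfdxd, dfdu = residual_block_jacobians(self.model, Xk, Xd, Uk)
        A = dfdx + (N / T) * dfdxd              # w.r.t. the interval-end state
        Bm = -(N / T) * dfdxd                   # w.r.t. the interval-start state
        Tcol = -np.einsum("bij,bj->bi", dfdxd, Xd) / T
        if self.pmap is not None:
            DP, dPdT = self.pmap.jacobian(X[0], T)
            Tcol[N - 1] += A[N - 1] @ dPdT
            A[N - 1] = A[N - 1] @ DP
        Jblocks = np.concatenate(
            [A, Bm, dfdu, Tcol[:, :, None]], axis=2)  # (N, n_x, nd)
        rows, cols, _ = self._defect_indices()
        return sp.csr_matrix((Jblocks.ravel(), (rows, cols)), shape=(self.n_con, self.n_var))

    def constraints_jac_reference(self, z) -> sp.csr_matrix:
        """Full complex-step defect Jacobian (every direction); test oracle
        for the structured fast path in :meth:`constraints_jac`."""
        X, U, T = self.split(z)
        n_x, n_u, N = self.n_x, self.n_u, self.N
        ih = 1j * _CS_H
        if self.kind == "standing":
            return self.constraints_jac(z)
        nd = 2 * n_x + n_u + 1
        B = nd + 1
        XA = np.empty((N, B, n_x), dtype=complex)
        XB = np.empty((N, B, n_x), dtype=complex)
        UU = np.empty((N, B, n_u), dtype=complex)
        TT = np.full((N, B), complex(T))
        for k in range(N):
            ka = k + 1 if k < N - 1 else 0
            XA[k] = X[ka]
            XB[k] = X[k]
            UU[k] = U[ka if k < N - 1 else 0]
        d = np.arange(n_x)
        XA[:, d, d] += ih
        XB[:, n_x + d, d] += ih
        du = np.arange(n_u)
        UU[:, 2 * n_x + du, du] += ih
        TT[:, 2 * n_x + n_u] += ih
        # wrap block maps through the periodicity image
        Xk = XA.copy()
        if self.pmap is not None:
            Xk[N - 1] = self.pmap.apply(XA[N - 1], TT[N - 1])
        h = TT[..., None] / N
        Xd = (Xk - XB) / h
        res = residual_batched(
            self.model, Xk.reshape(-1, n_x), Xd.reshape(-1, n_x), UU.reshape(-1, n_u))
        res = res.reshape(N, B, n_x)
        Jblocks = np.swapaxes(res[:, :nd].imag / _CS_H, 1, 2)  # (N, n_x, nd)
        rows, cols, _ = self._defect_indices()
        return sp.csr_matrix((Jblocks.ravel(), (rows, cols)), shape=(self.n_con, self.n_var))

    # -- objective in least-squares form ----------------------------------
    def _signals(self, X):
        """Simulated tracked signals (N, S); complex-safe."""
        Q = X[:, self.lay.q]
        Qd = X[:, self.lay.qdot]
        parts = []
        if len(self.ang_idx):
            parts.append(X[:, self.ang_idx])
        if len(self.grf_cols):
            grf = grf_batched(self.model, Q, Qd)
            parts.append(grf[:, self.grf_cols])
        return np.concatenate(parts, axis=1)

    def ls_residuals(self, z) -> np.ndarray:
        X, U, T = self.split(z)
        cfg = self.config
        out = []
        if self.ref is not None and cfg.W_Track > 0:
            Y = self._signals(X)  # (N, S)
            out.append((self.track_coef.T * (Y - self.ref.mean.T)).ravel())
        ne = U[:, self.lay.n_e]
        ce = np.sqrt(cfg.W_mus * self.vol / (self.N * self.lay.n_mus * cfg.speed_norm))
        out.append((ce * np.maximum(ne, 0.0)**1.5).ravel())
        if self.lay.n_tor:
            m = U[:, self.lay.m]
            ct = np.sqrt(cfg.W_tor / (self.N * self.lay.n_tor))
            out.append((ct * m).ravel())
        if cfg.W_reg > 0 and self.has_T:
            h = T / self.N
            x_end = self.pmap.apply(X[0], T) if self.pmap is not None else X[0]
            dX = np.diff(np.vstack([X, x_end[None]]), axis=0) / h
            dU = np.diff(np.vstack([U, U[:1]]), axis=0) / h
            cr = np.sqrt(cfg.W_reg / (self.N * (self.n_x + self.n_u)))
            out.append((cr * dX).ravel())
            out.append((cr * dU).ravel())
        return np.concatenate(out)

    def ls_jac(self, z) -> sp.csr_matrix:
        X, U, T = self.split(z)
        cfg = self.config
        blocks = []
        n_x, n_u, N = self.n_x, self.n_u, self.N
        if self.ref is not None and cfg.W_Track > 0:
            S = len(self.ref.names)
            n_ang = len(self.ang_idx)
            rows, cols, data = [], [], []
            coefT = self.track_coef.T  # (N, S)
            for k in range(N):
                base = k * S
                for i, dof in enumerate(self.ang_idx):
                    rows.append(base + i)
                    cols.append(self.x_slice(k).start + dof)
                    data.append(coefT[k, i])
            rows, cols, data = [list(rows)], [list(cols)], [list(data)]
            if len(self.grf_cols):
                # complex-step GRF rows w.r.t. (q, qdot)
                ndof = self.lay.n_dof
                nd = 2 * ndof
                Q = np.empty((N, nd + 1, ndof), dtype=complex)
                Qd = np.empty((N, nd + 1, ndof), dtype=complex)
                Q[:] = X[:, None, self.lay.q]
                Qd[:] = X[:, None, self.lay.qdot]
                dg = np.arange(ndof)
                Q[:, dg, dg] += 1j * _CS_H
                Qd[:, ndof + dg, dg] += 1j * _CS_H
                grf = grf_batched(self.model, Q.reshape(-1, ndof), Qd.reshape(-1, ndof))
                grf = grf.reshape(N, nd + 1, -1)[:, :, self.grf_cols]
                Jg = grf[:, :nd].imag / _CS_H  # (N, nd, n_grf)
                for k in range(N):
                    for gi in range(len(self.grf_cols)):
                        sig = n_ang + gi
                        coef = coefT[k, sig]
                        r = k * S + sig
                        for d in range(nd):
                            v = Jg[k, d, gi]
                            if v != 0.0:
                                rows[0].append(r)
                                cols[0].append(self.x_slice(k).start + d)
                                data[0].append(coef * v)
            Jtrack = sp.csr_matrix(
                (np.asarray(data[0]), (np.asarray(rows[0]), np.asarray(cols[0]))),
                shape=(N * S, self.n_var))
            blocks.append(Jtrack)
        ne = U[:, self.lay.n_e]
        ce = np.sqrt(cfg.W_mus * self.vol / (self.N * self.lay.n_mus * cfg.speed_norm))
        vals = (1.5 * ce * np.sqrt(np.maximum(ne, 0.0))).ravel()
        rows = np.arange(N * self.lay.n_mus)
        cols = np.concatenate([np.arange(self.u_slice(k).start,
                                         self.u_slice(k).start + self.lay.n_mus)
                               for k in range(N)])
        blocks.append(sp.csr_matrix((vals, (rows, cols)), shape=(N * self.lay.n_mus, self.n_var)))
        if self.lay.n_tor:
            ct = np.sqrt(cfg.W_tor / (self.N * self.lay.n_tor))
            rows = np.arange(N * self.lay.n_tor)
            cols = np.concatenate([np.arange(self.u_slice(k).start + self.lay.n_mus,
                                             self.u_slice(k).stop) for k in range(N)])
            blocks.append(sp.csr_matrix((np.full(N * self.lay.n_tor, ct), (rows, cols)),
                                        shape=(N * self.lay.n_tor, self.n_var)))
        if cfg.W_reg > 0 and self.has_T:
            blocks.append(self._reg_jac(X, U, T))
        return sp.vstack(blocks, format="csr")

    def _reg_jac(self, X, U, T) -> sp.csr_matrix:
        N, n_x, n_u = self.N, self.n_x, self.n_u
        cr = np.sqrt(self.config.W_reg / (N * (n_x + n_u)))
        h = T / N
        rows, cols, data = [], [], []
        x_end = self.pmap.apply(X[0], T) if self.pmap is not None else X[0]
        dX = np.diff(np.vstack([X, x_end[None]]), axis=0) / h
        dU = np.diff(np.vstack([U, U[:1]]), axis=0) / h
        # state intervals k=0..N-2: r = cr (X[k+1]-X[k])/h
        for k in range(N - 1):
            r0 = k * n_x
            rows += list(r0 + np.arange(n_x)) * 2 + list(r0 + np.arange(n_x))
            cols += list(range(self.x_slice(k + 1).start, self.x_slice(k + 1).stop))
            cols += list(range(self.x_slice(k).start, self.x_slice(k).stop))
            cols += [self.iT] * n_x
            data += [cr / h] * n_x + [-cr / h] * n_x + list(-cr * dX[k] / T)
        # wrap state interval: complex-step over (x0, x_{N-1}, T)
        ih = 1j * _CS_H
        ndir = 2 * n_x + 1
        x0c = np.tile(X[0].astype(complex), (ndir, 1))
        xm = np.tile(X[N - 1].astype(complex), (ndir, 1))
        Tc = np.full(ndir, complex(T))
        d = np.arange(n_x)
        x0c[d, d] += ih
        xm[n_x + d, d] += ih
        Tc[2 * n_x] += ih
        x_endc = self.pmap.apply(x0c, Tc) if self.pmap is not None else x0c
        rw = cr * (x_endc - xm) / (Tc[:, None] / N)
        Jw = rw.imag / _CS_H  # (ndir, n_x)
        r0 = (N - 1) * n_x
        for dcol, colbase in ((0, self.x_slice(0).start), (n_x, self.x_slice(N - 1).start)):
            nz = np.nonzero(Jw[dcol:dcol + n_x])
            rows += list(r0 + nz[1])
            cols += list(colbase + nz[0])
            data += list(Jw[dcol:dcol + n_x][nz])
        rows += list(r0 + np.arange(n_x))
        cols += [self.iT] * n_x
        data += list(Jw[2 * n_x])
        nrow_x = N * n_x
        # control intervals (wrap is plain u0 - u_{N-1})
        for k in range(N):
            kn = k + 1 if k < N - 1 else 0
            r0 = nrow_x + k * n_u
            rows += list(r0 + np.arange(n_u)) * 2 + list(r0 + np.arange(n_u))
            cols += list(range(self.u_slice(kn).start, self.u_slice(kn).stop))
            cols += list(range(self.u_slice(k).start, self.u_slice(k).stop))
            cols += [self.iT] * n_u
            data += [cr / h] * n_u + [-cr / h] * n_u + list(-cr * dU[k] / T)
        return sp.csr_matrix((data, (rows, cols)), shape=(N * (n_x + n_u), self.n_var))

    # -- scalar objective --------------------------------------------------
    def objective(self, z):
        r = self.ls_residuals(z)
        J = self.ls_jac(z)
        return float(r @ r), 2.0 * (J.T @ r)

    def objective_value(self, z) -> float:
        r = self.ls_residuals(z)
        return float(r @ r)

    def breakdown(self, z):
        X, U, T = self.split(z)
        T_eff = T if self.has_T else 1.0
        y = self._signals(X) if self.ref is not None else None
        return total_objective(
            y, X, U, U[:, self.lay.n_e], U[:, self.lay.m], T_eff, self.config,
            self.ref, self.model.muscles,
            self.pmap if self.has_T else None)


def assemble_nlp(model: ModelDefinition, task, config: ObjectiveConfig,
                 ref: TrackingReference | None) -> NLPProblem:
    """Build the collocation NLP for a TaskSpec-like object."""
    kind = task.kind
    if kind == "standing":
        pmap = None
        tracked = None
    elif kind == "straight":
        pmap = PeriodicityMap.straight(model, task.v_x, task.v_z)
        tracked = task.tracked
    elif kind == "curved":
        pmap = PeriodicityMap.curved(model, task.v_norm, task.radius)
        tracked = task.tracked
    else:
        raise ValueError(f"unknown task kind '{kind}'")
    if kind != "standing" and not tracked:
        raise ValueError("running tasks must track at least one signal")
    N = 1 if kind == "standing" else task.N
    return NLPProblem(model, kind, N, config, ref, tracked, pmap,
                      anchors=getattr(task, "anchors", None),
                      T_bounds=getattr(task, "T_bounds", (0.3, 1.5)))


# ---------------------------------------------------------------------------
# solve
# ---------------------------------------------------------------------------

def _clip_guess(nlp: NLPProblem, z0, log):
    z = np.clip(np.asarray(z0, float), nlp.lb, nlp.ub)
    n_clip = int(np.sum(z != np.asarray(z0, float)))
    if n_clip:
        log.append(f"initial guess: clipped {n_clip} variables into bounds")
    return z


def solve(nlp: NLPProblem, z0, settings: SolverSettings | None = None) -> Solution:
    """Solve the NLP; never silently accepts an unconverged point."""
    settings = settings or SolverSettings()
    if np.any(nlp.lb > nlp.ub):
        raise ValueError("infeasible bounds: lower > upper")
    log: list[str] = []
    z0 = _clip_guess(nlp, z0, log)
    t0 = time.time()
    n_iter = 0
    # Contact-stiffness continuation: with the full cubic stiffness the
    # Gauss-Newton linear model badly overpredicts force changes near
    # touchdown, shrinking the trust region.  Solving first with a softer
    # ground (scaled-down k_n) and annealing to the model's stiffness keeps
    # the subproblems well behaved.
    import dataclasses as _dc
    base_contact = nlp.model.contact
    try:
        for i, fac in enumerate(settings.contact_relax):
            if not fac < 1.0:
                continue
            nlp.model.contact = _dc.replace(
                base_contact, k_n=fac * base_contact.k_n,
                v_c=base_contact.v_c * fac ** (-2.0 / 3.0))
            # first stage ramps the penalty from scratch; later stages keep
            # the high penalty so the near-feasible iterate is not destroyed
            stages = settings.penalty_stages[:2] if i == 0 else settings.penalty_stages[1:2]
            relax = _dc.replace(settings, al_updates=settings.relax_updates,
                                penalty_stages=stages, feas_rounds=1,
                                contact_relax=())
            log.append(f"-- contact relaxation stage k_n factor {fac:g} --")
            z0, it, _ = _solve_al_gn(nlp, z0, relax, log)
            n_iter += it
    finally:
        nlp.model.contact = base_contact
    # The AL Gauss-Newton path also serves the standing problem: at qdot = 0
    # the pelvis horizontal-force/heading rows are consistent linear
    # combinations of the kinematic-identity rows (friction vanishes with
    # slip speed), which active-set QP solvers reject as singular but a
    # least-squares trust region handles naturally.
    log.append("-- main AL-GN --")
    main = settings
    if settings.contact_relax:
        import dataclasses as _dc2
        main = _dc2.replace(settings, penalty_stages=settings.penalty_stages[1:] or
                            settings.penalty_stages)
    z, it, status = _solve_al_gn(nlp, z0, main, log)
    n_iter += it
    c = nlp.constraints(z)
    max_defect = float(np.max(np.abs(c)))
    converged = max_defect <= settings.ctol and status >= 0
    X, U, T = nlp.split(z)
    x_virt = nlp.pmap.apply(X[0], T) if nlp.pmap is not None else X[0].copy()
    J, terms = nlp.breakdown(z)
    log.append(f"solve: {n_iter} iterations, {time.time() - t0:.1f} s, "
               f"max defect {max_defect:.2e}, J = {J:.6g}, converged={converged}")
    return Solution(X=X, U=U, T_sim=float(T) if nlp.has_T else 0.0, x_virtual=x_virt,
                    objective=J, terms=terms, max_defect=max_defect, converged=converged,
                    log=log, task_kind=nlp.kind)


def _free_mask(nlp: NLPProblem):
    return nlp.lb < nlp.ub


def _lm_bounded(fun, jac, z0, lb, ub, max_iter=80, lam0=1e-3, cost_tol=1e-10):
    """Projected Levenberg-Marquardt with exact sparse normal-equation solves.

    The collocation Jacobians are narrow-banded, so a direct LU of
    J^T J + lam D is cheap and yields far better steps than Krylov
    approximations on these ill-conditioned systems.  Bounds are handled by
    projection (iterates stay feasible; active bounds damp themselves).
    Returns (z, n_iter, converged_flag).
    """
    import scipy.sparse.linalg as spla
    z = np.clip(np.asarray(z0, float), lb, ub)
    r = fun(z)
    cost = 0.5 * float(r @ r)
    lam = lam0
    n_eval = 1
    for it in range(max_iter):
        J = jac(z)
        g = J.T @ r
        d = np.asarray(J.multiply(J).sum(axis=0)).ravel()
        d = np.maximum(d, 1e-10 * (d.max() or 1.0))
        accepted = False
        for _trial in range(14):
            H = (J.T @ J).tocsc() + sp.diags(lam * d)
            try:
                dz = spla.splu(H).solve(-g)
            except RuntimeError:
                lam *= 10.0
                continue
            z_new = np.clip(z + dz, lb, ub)
            r_new = fun(z_new)
            n_eval += 1
            c_new = 0.5 * float(r_new @ r_new)
            if c_new < cost:
                rel = (cost - c_new) / max(cost, 1e-300)
                z, r, cost = z_new, r_new, c_new
                lam = max(lam / 3.0, 1e-12)
                accepted = True
                break
            lam *= 5.0
        if not accepted:
            return z, n_eval, False
        if rel < cost_tol:
            return z, n_eval, True
    return z, n_eval, True


def _solve_al_gn(nlp: NLPProblem, z0, settings: SolverSettings, log):
    """Augmented-Lagrangian Gauss-Newton with penalty continuation."""
    free = _free_mask(nlp)
    zfix = np.where(free, 0.0, nlp.lb)

    def expand(zf):
        z = zfix.copy()
        z[free] = zf
        return z

    shift = np.zeros(nlp.n_con)
    zf = z0[free]
    total_nfev = 0
    status = 0
    polish_left = settings.polish_rounds
    for stage, w in enumerate(settings.penalty_stages):
        prev_viol = np.inf
        for it in range(settings.al_updates):
            def fun(zf_):
                z = expand(zf_)
                return np.concatenate([nlp.ls_residuals(z), w * (nlp.constraints(z) + shift)])

            def jac(zf_):
                z = expand(zf_)
                J = sp.vstack([nlp.ls_jac(z), w * nlp.constraints_jac(z)], format="csr")
                return J[:, free]

            if settings.use_lm:
                zf, nev, _ok = _lm_bounded(fun, jac, zf, nlp.lb[free], nlp.ub[free],
                                           max_iter=settings.lm_iters,
                                           cost_tol=settings.opt_tol * 1e-3)
                total_nfev += nev
            else:
                res = least_squares(
                    fun, zf, jac=jac, method="trf", tr_solver="lsmr",
                    tr_options={"maxiter": settings.lsmr_maxiter},
                    x_scale="jac",
                    bounds=(nlp.lb[free], nlp.ub[free]),
                    xtol=1e-12, ftol=settings.opt_tol * 1e-3, gtol=1e-12,
                    max_nfev=settings.max_nfev_stage, verbose=0)
                zf = res.x
                total_nfev += res.nfev
            c = nlp.constraints(expand(zf))
            viol = float(np.max(np.abs(c)))
            cost_now = 0.5 * float(np.sum(fun(zf) ** 2))
            log.append(f"AL-GN stage w={w:g} update {it}: "
                       f"cost {cost_now:.6g}, max defect {viol:.2e}")
            if viol <= settings.ctol:
                # feasible: let Gauss-Newton polish the objective, then stop
                early = (not settings.use_lm and res.status in (2, 3)
                         and res.nfev < settings.max_nfev_stage // 2)
                if polish_left <= 0 or early:
                    return expand(zf), total_nfev, status
                polish_left -= 1
                continue
            if stage == 0 and it >= 1 and viol > settings.abort_defect:
                log.append(f"AL-GN: aborting start, defect {viol:.2e} > {settings.abort_defect:g}")
                return expand(zf), total_nfev, -1
            final = stage == len(settings.penalty_stages) - 1
            if viol <= 10.0 * settings.ctol:
                shift = shift + c  # multiplier update only once near-feasible
            elif viol > (0.98 if final else 0.85) * prev_viol:
                break  # stalled at this penalty: escalate
            prev_viol = viol
        if stage + 1 < len(settings.penalty_stages):
            shift *= (w / settings.penalty_stages[stage + 1]) ** 2
    # feasibility restoration: Gauss-Newton on the defects alone takes
    # minimum-norm steps and polishes the dynamics without a penalty trade-off
    for it in range(settings.feas_rounds):
        if float(np.max(np.abs(nlp.constraints(expand(zf))))) <= settings.ctol:
            break
        zf, nev, _ok = _lm_bounded(
            lambda zf_: nlp.constraints(expand(zf_)),
            lambda zf_: nlp.constraints_jac(expand(zf_))[:, free].tocsr(),
            zf, nlp.lb[free], nlp.ub[free], max_iter=settings.lm_iters)
        total_nfev += nev
        viol = float(np.max(np.abs(nlp.constraints(expand(zf)))))
        log.append(f"feasibility round {it}: nfev {nev}, max defect {viol:.2e}")
        if viol <= settings.ctol:
            break
    return expand(zf), total_nfev, status


# ---------------------------------------------------------------------------
# derivative check
# ---------------------------------------------------------------------------

def check_derivatives(nlp: NLPProblem, z, seed: int = 0, n_dirs: int | None = None,
                      step: float = 1e-6) -> dict:
    """Central-difference audit of the objective gradient and constraint Jacobian.

    Returns the worst relative errors and the offending (row, col) indices.
    Checks all coordinate directions unless ``n_dirs`` limits to a random
    subset (useful for large problems).
    """
    rng = np.random.default_rng(seed)
    z = np.asarray(z, float)
    dirs = np.arange(nlp.n_var)
    if n_dirs is not None and n_dirs < nlp.n_var:
        dirs = rng.choice(nlp.n_var, size=n_dirs, replace=False)
    _, g = nlp.objective(z)
    Jc = nlp.constraints_jac(z).toarray()
    worst_g, worst_g_i = 0.0, -1
    worst_c, worst_c_ij = 0.0, (-1, -1)
    scale_g = max(1.0, float(np.max(np.abs(g))))
    scale_c = max(1.0, float(np.max(np.abs(Jc))))
    for d in dirs:
        e = np.zeros(nlp.n_var)
        e[d] = step
        fp = nlp.objective_value(z + e)
        fm = nlp.objective_value(z - e)
        gd = (fp - fm) / (2 * step)
        err = abs(gd - g[d]) / scale_g
        if err > worst_g:
            worst_g, worst_g_i = err, int(d)
        cp = nlp.constraints(z + e)
        cm = nlp.constraints(z - e)
        cd = (cp - cm) / (2 * step)
        errs = np.abs(cd - Jc[:, d]) / scale_c
        i = int(np.argmax(errs))
        if errs[i] > worst_c:
            worst_c, worst_c_ij = float(errs[i]), (i, int(d))
    return {
        "grad_max_rel_error": worst_g,
        "grad_worst_index": worst_g_i,
        "jac_max_rel_error": worst_c,
        "jac_worst_index": worst_c_ij,
    }
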