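"""Task drivers: standing prediction, straight-running tracking, curved-running prediction.

The three simulations form a warm-start chain.  Standing is a single-node
problem (xdot = 0, no periodicity) solved from many random initial guesses
with effort-only objective.  Straight running tracks all joint angles, the
pelvis global orientation and both feet's 3D ground reaction forces with
W_Track=1, W_mus=1e3, W_tor=1, starting from the standing solution.  Curved
running is predicted by tracking the *straight* running data (joint angles
and vertical GRFs only), with effort and torque weights increased tenfold,
running counterclockwise on a circle of radius r centred at the origin with
the left leg inside, starting from the straight-running solution bent onto
the arc.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .collocation import (NLPProblem, PeriodicityMap, Solution, SolverSettings,
                          assemble_nlp, central_angle, solve)
from .dynamics import grf_batched
from .model import ModelDefinition
from .objective import ObjectiveConfig, TrackingReference, adjust_variance

__all__ = [
    "TaskSpec",
    "standing_task",
    "straight_running_task",
    "curved_running_task",
    "tracked_signals",
    "forward_speed",
    "start_radius",
    "chord_speed",
    "heading_change",
    "foot_grf",
    "tracking_rms_sd_units",
]


@dataclass
class TaskSpec:
    kind: str
    v_x: float = 0.0
    v_z: float = 0.0
    v_norm: float = 0.0
    radius: float = 0.0
    N: int = 50
    config: ObjectiveConfig = field(default_factory=ObjectiveConfig)
    tracked: list = field(default_factory=list)
    anchors: dict = field(default_factory=dict)
    n_starts: int = 50
    seed: int = 0
    T_bounds: tuple = (0.3, 1.5)

    def validate(self) -> list[str]:
        bad = []
        if self.kind == "curved" and not (self.radius > 0 and self.v_norm > 0):
            bad.append("curved task requires radius > 0 and v_norm > 0")
        if self.kind in ("straight", "curved") and not self.tracked:
            bad.append("running task requires a nonempty tracked-signal set")
        return bad


def tracked_signals(model: ModelDefinition, kind: str) -> list:
    """Tracked-signal sets per task.

    Straight running tracks every non-root joint angle plus the three pelvis
    orientation DOFs and both feet's GRFs in all directions; curved running
    tracks the joint angles and vertical GRFs only, freeing the horizontal
    plane for the circular motion.
    """
    angles = [d for d in model.dof_names if not d.startswith("pelvis_")]
    if kind == "straight":
        sigs = [(d, "angle") for d in ("pelvis_rot", "pelvis_list", "pelvis_tilt")]
        sigs += [(d, "angle") for d in angles]
        sigs += [(f"grf_{side}_{c}", "grf") for side in model.grf_groups for c in "xyz"]
        return sigs
    if kind == "curved":
        sigs = [(d, "angle") for d in angles]
        sigs += [(f"grf_{side}_y", "grf") for side in model.grf_groups]
        return sigs
    return []


# ---------------------------------------------------------------------------
# standing
# ---------------------------------------------------------------------------

def standing_task(model: ModelDefinition, n_starts: int = 50, seed: int = 0,
                  settings: SolverSettings | None = None) -> Solution:
    """Predict a static pose: single node, xdot = 0, effort-only objective.

    Solved ``n_starts`` times from random initial guesses drawn uniformly
    within the variable bounds (pelvis translations within a box around
    upright); returns the converged solution with the lowest objective, with
    the per-start objective list in ``extras``.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    config = ObjectiveConfig(W_Track=0.0, W_mus=1.0, W_tor=1.0, W_reg=0.0, v_ref=(0.0, 0.0))
    task = TaskSpec(kind="standing", config=config, n_starts=n_starts, seed=seed)
    nlp = assemble_nlp(model, task, config, None)
    if settings is None:
        # abandon starts that are still far from equilibrium after two
        # Gauss-Newton rounds; the multistart covers for them
        settings = SolverSettings(al_updates=3, abort_defect=3e-2, use_lm=False)
    rng = np.random.default_rng(seed)
    di = model.dof_index
    lb, ub = nlp.lb.copy(), nlp.ub.copy()
    box = {di["pelvis_tx"]: (-0.5, 0.5), di["pelvis_ty"]: (0.8, 1.2), di["pelvis_tz"]: (-0.5, 0.5)}
    for j, (lo, hi) in box.items():
        lb[j], ub[j] = lo, hi
    best: Solution | None = None
    objs = []
    for k in range(n_starts):
        z0 = lb + (ub - lb) * rng.random(nlp.n_var)
        sol = solve(nlp, z0, settings)
        objs.append(sol.objective if sol.converged else np.nan)
        if sol.converged and (best is None or sol.objective < best.objective):
            best = sol
    if best is None:
        raise RuntimeError(f"standing: none of {n_starts} starts converged")
    best.extras["start_objectives"] = objs
    best.extras["n_converged"] = int(np.sum(np.isfinite(objs)))
    best.extras["seed"] = seed
    return best


# ---------------------------------------------------------------------------
# running
# ---------------------------------------------------------------------------

def _seed_kinematics(model: ModelDefinition, X0: np.ndarray, U0: np.ndarray,
                     ref: TrackingReference, T0: float):
    """Overwrite joint-angle trajectories of a warm start with the tracked means.

    The standing solution supplies pose height, muscle states and controls;
    the reference means supply the periodic joint-angle pattern and its rates
    (backward differences), which conditions the first Gauss-Newton steps.
    """
    N = X0.shape[0]
    di = model.dof_index
    ndof = len(model.dof_names)
    ph = np.arange(N) / N
    for i, name in enumerate(ref.names):
        if ref.kinds[i] != "angle" or name not in di:
            continue
        y = np.interp(ph, np.arange(ref.n_samples) / ref.n_samples, ref.mean[i],
                      period=1.0)
        X0[:, di[name]] = y
        # rates from a low-passed copy: differencing the raw noisy mean
        # amplifies sample noise into m/s-scale foot-speed jitter
        F = np.fft.rfft(y)
        F[9:] = 0.0
        y_s = np.fft.irfft(F, N)
        X0[:, ndof + di[name]] = (y_s - np.roll(y_s, 1)) / (T0 / N)
    _seed_pelvis_height(model, X0, ref, T0)
    _seed_muscles(model, X0, U0, T0)


def _seed_muscles(model: ModelDefinition, X0: np.ndarray, U0: np.ndarray, T0: float):
    """Torque-matched muscle seed (computed-muscle-control style).

    For every node the inverse-dynamics joint torques of the seeded motion
    (minus the contact contribution) are distributed over the muscles by a
    small nonnegative least-squares in tendon force, bounded by each
    muscle's strength; the contraction state then inverts the tendon
    force-strain relation and the activation inverts the static CE balance.
    An all-slack muscle seed leaves the Gauss-Newton model nearly blind to
    the excitation-force chain, so load-bearing muscles from the first
    iterate matter more than the exact distribution.
    """
    from scipy.optimize import lsq_linear
    from .dynamics import _muscle_meta, multibody_residual, contact_generalized_forces
    from .muscles import force_length, tendon_force, _pee_force
    lay = model.layout
    lb, ub = model.state_bounds().T
    N = X0.shape[0]
    h = T0 / N
    ndof = lay.n_dof
    q = X0[:, lay.q]
    qd = X0[:, lay.qdot]
    qdd = (qd - np.roll(qd, 1, axis=0)) / h
    tau_id = multibody_residual(model, q, qd, qdd, np.zeros_like(q))
    di = model.dof_index
    meta = _muscle_meta(model)
    arms = np.zeros((N, ndof, lay.n_mus))
    l_mtus = np.zeros((N, lay.n_mus))
    for i, (mrec, dofs) in enumerate(meta):
        qp = q[:, dofs]
        l_mtus[:, i] = mrec.path.length(qp)
        a_i = -mrec.path.dlength(qp)
        for j, dof in enumerate(dofs):
            arms[:, dof, i] = a_i[:, j]
    mus_dofs = sorted({dof for _, dofs in meta for dof in dofs})
    act_idx = {dof: j for j, (dof, _n) in enumerate(model.torque_actuators)}
    F_max = np.asarray([0.85 * mrec.params.F_ISO for mrec, _ in meta])
    F_seed = np.zeros((N, lay.n_mus))
    for k in range(N):
        tau_c, _ = contact_generalized_forces(model, q[k], qd[k])
        tau_req = tau_id[k] - tau_c
        for dof, j in act_idx.items():
            nrm = model.torque_actuators[j][1]
            U0[k, lay.n_mus + j] = np.clip(tau_req[di[dof]] / nrm, -0.9 * model.m_bound,
                                           0.9 * model.m_bound)
        A = arms[k][mus_dofs, :]
        b = tau_req[mus_dofs]
        # mild Tikhonov spreads the redundancy without affecting the fit much
        A_aug = np.vstack([A, 1e-3 * np.eye(lay.n_mus)])
        b_aug = np.concatenate([b, np.zeros(lay.n_mus)])
        res = lsq_linear(A_aug, b_aug, bounds=(np.zeros(lay.n_mus), F_max),
                         method="bvls", max_iter=100)
        F_seed[k] = res.x
    for i, (mrec, dofs) in enumerate(meta):
        p = mrec.params
        F = F_seed[:, i]
        eps = p.eps0_SEE * np.sqrt(np.maximum(F, 1.0) / p.F_ISO)
        s = l_mtus[:, i] - p.l_slack * (1.0 + eps)
        j = lay.s.start + i
        s = np.clip(s, lb[j] + 1e-6, ub[j] - 1e-6)
        X0[:, j] = s
        F_see = tendon_force(p, l_mtus[:, i], s)
        l_ce = np.sqrt(s**2 + p.height**2)
        cos_phi = s / l_ce
        a = (F_see / cos_phi - _pee_force(p, l_ce)) / (p.F_ISO * force_length(p, l_ce))
        a = np.clip(a, 0.02, 0.95)
        X0[:, lay.a.start + i] = a
        U0[:, i] = a


def _seed_pelvis_height(model: ModelDefinition, X0: np.ndarray, ref: TrackingReference,
                        T0: float, penetration: float = 0.012):
    """Seed the pelvis root trajectory from the reference GRFs.

    Double-integrating the reference total GRF (backward-Euler convention)
    yields pelvis height and fore-aft speed ripples that are dynamically
    consistent with the tracked forces: ballistic in flight, compressed in
    stance.  The height offset is chosen geometrically so the stance foot's
    lowest contact point carries the tracked force at a small penetration.
    """
    from .dynamics import contact_heights
    N = X0.shape[0]
    di = model.dof_index
    ndof = len(model.dof_names)
    h = T0 / N
    ph = np.arange(N) / N
    M = model.subject_mass
    weight = model.weight()

    def ref_interp(name):
        return np.interp(ph, np.arange(ref.n_samples) / ref.n_samples,
                         ref.mean[ref.names.index(name)], period=1.0)

    # stance: pelvis height such that the loaded foot sits just below ground
    # at the seeded leg posture; flight: ballistic parabolas (ydd = -g)
    heights = contact_heights(model, X0[:, :ndof])
    stance_min = np.full(N, np.nan)
    thr = 0.2 * weight
    for side in model.grf_groups:
        name = f"grf_{side}_y"
        if name not in ref.names:
            continue
        g = ref_interp(name)
        mask = g > thr
        rel_h = heights[side] - X0[:, di["pelvis_ty"]]  # foot height for ty = 0
        stance_min[mask] = np.fmin(stance_min[mask], rel_h[mask])
    in_stance = np.isfinite(stance_min)
    # penetration from the tracked force: p = (F / (n_points k_n))^(1/3)
    F_stance = np.zeros(N)
    for side in model.grf_groups:
        name = f"grf_{side}_y"
        if name in ref.names:
            F_stance = np.maximum(F_stance, ref_interp(name))
    pen = np.maximum(penetration,
                     (F_stance / (2.0 * model.contact.k_n)) ** (1.0 / 3.0))
    ty = np.where(in_stance, -pen - stance_min, np.nan)
    # one refinement: account for the normal damping factor (1 - c_n ydot)
    # of the settling/rising foot, which doubles the force at touchdown and
    # cuts it during late-stance rise
    foot_y = np.where(in_stance, ty + stance_min, np.nan)
    vy = np.zeros(N)
    for k in range(N):
        km = (k - 1) % N
        if np.isfinite(foot_y[k]) and np.isfinite(foot_y[km]):
            vy[k] = (foot_y[k] - foot_y[km]) / h
    damp = np.clip(1.0 - model.contact.c_n * vy, 0.3, 3.0)
    pen = np.maximum(penetration,
                     (F_stance / (2.0 * model.contact.k_n * damp)) ** (1.0 / 3.0))
    ty = np.where(in_stance, -pen - stance_min, np.nan)
    if not np.any(in_stance):
        ty[:] = X0[0, di["pelvis_ty"]]
        in_stance[:] = True
    g_mag = weight / M
    # fill each (periodic) flight gap with the unique parabola of curvature -g
    k = 0
    while k < N:
        if in_stance[k]:
            k += 1
            continue
        a = (k - 1) % N  # last stance node before the gap
        b = k
        while not in_stance[b % N]:
            b += 1
        n_gap = b - k
        dt_tot = (n_gap + 1) * h
        ya, yb = ty[a], ty[b % N]
        v0 = (yb - ya + 0.5 * g_mag * dt_tot**2) / dt_tot
        for j in range(n_gap):
            t = (j + 1) * h
            ty[(k + j) % N] = ya + v0 * t - 0.5 * g_mag * t * t
        k = b
    # never let an unloaded foot spike through the stiff contact at the seed
    for side in model.grf_groups:
        rel_h = heights[side] - X0[:, di["pelvis_ty"]]
        name = f"grf_{side}_y"
        loaded = (ref_interp(name) > thr) if name in ref.names else np.zeros(N, bool)
        need = -rel_h + 0.003
        ty = np.where(~loaded & (ty < need), need, ty)
    X0[:, di["pelvis_ty"]] = ty
    X0[:, ndof + di["pelvis_ty"]] = (ty - np.roll(ty, 1)) / h
    # fore-aft speed ripple from the braking/propulsion GRF
    names = [f"grf_{s}_x" for s in model.grf_groups]
    if all(n in ref.names for n in names):
        a_x = sum(ref_interp(n) for n in names) / M
        a_x -= a_x.mean()
        v_r = h * np.cumsum(a_x)
        v_r -= v_r.mean()
        v_mean = X0[0, ndof + di["pelvis_tx"]]
        X0[:, ndof + di["pelvis_tx"]] = v_mean + v_r
        tx = np.concatenate([[0.0], np.cumsum(h * (v_mean + v_r[1:]))])
        X0[:, di["pelvis_tx"]] = X0[0, di["pelvis_tx"]] + tx


def _resample_nodes(A: np.ndarray, N: int) -> np.ndarray:
    """Resample node trajectories (N0, d) -> (N, d), periodic in node phase."""
    N0 = A.shape[0]
    if N0 == N:
        return A.copy()
    ph0 = np.arange(N0) / N0
    ph = np.arange(N) / N
    out = np.empty((N, A.shape[1]))
    for j in range(A.shape[1]):
        out[:, j] = np.interp(ph, np.concatenate([ph0, [1.0]]),
                              np.concatenate([A[:, j], [A[0, j]]]))
    return out


def straight_running_task(model: ModelDefinition, ref: TrackingReference,
                          v_x: float, v_z: float = 0.0, init: Solution | None = None,
                          N: int = 50, settings: SolverSettings | None = None,
                          config: ObjectiveConfig | None = None,
                          warm: Solution | None = None) -> Solution:
    """Track straight-running data at prescribed speed from the standing pose."""
    if init is None:
        raise ValueError("straight running requires the standing solution as initial guess")
    config = config or ObjectiveConfig(W_Track=1.0, W_mus=1e3, W_tor=1.0, W_reg=1e-3,
                                       W_ang=1.0, W_GRF=5.0, v_ref=(v_x, v_z))
    # cycle duration is only weakly identified early in the solve; bound it
    # around the measured cadence
    T_bounds = (0.75 * ref.cadence, 1.3 * ref.cadence)
    task = TaskSpec(kind="straight", v_x=v_x, v_z=v_z, N=N, config=config,
                    tracked=tracked_signals(model, "straight"),
                    anchors={"pelvis_tx": 0.0, "pelvis_tz": 0.0},
                    T_bounds=T_bounds)
    nlp = assemble_nlp(model, task, config, ref)
    di = model.dof_index
    T0 = float(np.clip(ref.cadence, *task.T_bounds))
    X0 = np.tile(init.X[0], (N, 1))
    t_nodes = np.arange(N) * T0 / N
    X0[:, di["pelvis_tx"]] = v_x * t_nodes
    X0[:, di["pelvis_tz"]] = v_z * t_nodes
    X0[:, len(model.dof_names) + di["pelvis_tx"]] = v_x
    X0[:, len(model.dof_names) + di["pelvis_tz"]] = v_z
    U0 = np.tile(init.U[0], (N, 1))
    _seed_kinematics(model, X0, U0, ref, T0)
    if warm is not None and warm.task_kind == "straight":
        # refine a previous solution of the same task (e.g. other node count):
        # detrend the secular pelvis translation, resample periodically, retrend
        Xw = warm.X.copy()
        Nw = Xw.shape[0]
        for dof, v in ((di["pelvis_tx"], v_x), (di["pelvis_tz"], v_z)):
            Xw[:, dof] -= v * warm.T_sim * np.arange(Nw) / Nw
        X0 = _resample_nodes(Xw, N)
        U0 = _resample_nodes(warm.U, N)
        T0 = float(np.clip(warm.T_sim, *task.T_bounds))
        for dof, v in ((di["pelvis_tx"], v_x), (di["pelvis_tz"], v_z)):
            X0[:, dof] += v * T0 * np.arange(N) / N
    z0 = nlp.pack(X0, U0, T0)
    sol = solve(nlp, z0, settings)
    sol.extras.update({"v_x": v_x, "v_z": v_z, "ref": ref, "tracked": task.tracked,
                       "config": config, "nlp": nlp})
    return sol


def curved_running_task(model: ModelDefinition, straight_ref: TrackingReference,
                        v_norm: float, radius: float, init: Solution | None = None,
                        N: int = 50, settings: SolverSettings | None = None,
                        config: ObjectiveConfig | None = None) -> Solution:
    """Predict curved running by tracking straight-running data on a circle.

    Counterclockwise about +y with the left leg inside: the first node is
    anchored at (-r, 0) and the periodicity map rotates the pelvis state by
    the central angle theta(T_sim).
    """
    if init is None:
        raise ValueError("curved running requires the straight solution as initial guess")
    config = config or ObjectiveConfig(W_Track=1.0, W_mus=1e4, W_tor=10.0, W_reg=1e-3,
                                       W_ang=1.0, W_GRF=5.0, v_ref=(v_norm, 0.0))
    T_guess = (0.5 * v_norm + 0.8) / v_norm
    task = TaskSpec(kind="curved", v_norm=v_norm, radius=radius, N=N, config=config,
                    tracked=tracked_signals(model, "curved"),
                    anchors={"pelvis_tx": -radius, "pelvis_tz": 0.0},
                    T_bounds=(0.75 * T_guess, 1.3 * T_guess))
    bad = task.validate()
    if bad:
        raise ValueError("; ".join(bad))
    nlp = assemble_nlp(model, task, config, straight_ref)
    di = model.dof_index
    ndof = len(model.dof_names)
    # cycle duration guess from a stride-length rule consistent with the generator
    T0 = float(np.clip((0.5 * v_norm + 0.8) / v_norm, *task.T_bounds))
    theta0, _ = central_angle(v_norm, T0, radius)
    X0 = _resample_nodes(init.X, N)
    U0 = _resample_nodes(init.U, N)
    psi = theta0 * np.arange(N) / N
    X0[:, di["pelvis_tx"]] = -radius * np.cos(psi)
    X0[:, di["pelvis_tz"]] = radius * np.sin(psi)
    X0[:, di["pelvis_rot"]] = init.X[0, di["pelvis_rot"]] + psi - np.pi / 2
    X0[:, ndof + di["pelvis_tx"]] = v_norm * np.sin(psi)
    X0[:, ndof + di["pelvis_tz"]] = v_norm * np.cos(psi)
    z0 = nlp.pack(X0, U0, T0)
    sol = solve(nlp, z0, settings)
    sol.extras.update({"v_norm": v_norm, "radius": radius, "ref": straight_ref,
                       "tracked": task.tracked, "config": config, "nlp": nlp})
    return sol


# ---------------------------------------------------------------------------
# solution measurements
# ---------------------------------------------------------------------------

def forward_speed(sol: Solution, model: ModelDefinition) -> float:
    """Net forward pelvis displacement over the cycle divided by T_sim."""
    j = model.dof_index["pelvis_tx"]
    return float((sol.x_virtual[j] - sol.X[0, j]) / sol.T_sim)


def start_radius(sol: Solution, model: ModelDefinition) -> float:
    """Horizontal distance from the circle centre to the first-node pelvis."""
    di = model.dof_index
    return float(np.hypot(sol.X[0, di["pelvis_tx"]], sol.X[0, di["pelvis_tz"]]))


def chord_speed(sol: Solution, model: ModelDefinition) -> float:
    """Horizontal chord between first node and its periodicity image over T_sim."""
    di = model.dof_index
    dx = sol.x_virtual[di["pelvis_tx"]] - sol.X[0, di["pelvis_tx"]]
    dz = sol.x_virtual[di["pelvis_tz"]] - sol.X[0, di["pelvis_tz"]]
    return float(np.hypot(dx, dz) / sol.T_sim)


def heading_change(sol: Solution, model: ModelDefinition) -> float:
    j = model.dof_index["pelvis_rot"]
    return float(sol.x_virtual[j] - sol.X[0, j])


def foot_grf(sol: Solution, model: ModelDefinition) -> dict:
    """Per-side GRF trajectories (N, 3) of the solution."""
    lay = model.layout
    grf = grf_batched(model, sol.X[:, lay.q], sol.X[:, lay.qdot])
    out = {}
    for i, side in enumerate(model.grf_groups):
        out[side] = grf[:, 3 * i: 3 * i + 3]
    return out


def tracking_rms_sd_units(model: ModelDefinition, sol: Solution,
                          ref: TrackingReference, tracked: list,
                          floor_frac: float = 0.1) -> np.ndarray:
    """Per-signal RMS deviation from the reference in (floored) SD units."""
    sub = ref.subset([t[0] for t in tracked])
    di = model.dof_index
    lay = model.layout
    grf = grf_batched(model, sol.X[:, lay.q], sol.X[:, lay.qdot])
    sides = list(model.grf_groups)
    cols = []
    for name, kind in tracked:
        if kind == "angle":
            cols.append(sol.X[:, di[name]])
        else:
            _, side, comp = name.split("_")
            cols.append(grf[:, sides.index(side) * 3 + "xyz".index(comp)])
    Y = np.stack(cols, axis=1)  # (N, S)
    var = np.atleast_2d(adjust_variance(sub.sd, floor_frac))
    dev2 = (Y.T - sub.mean) ** 2 / var
    return np.sqrt(dev2.mean(axis=1))
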