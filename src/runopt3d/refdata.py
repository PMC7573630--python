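"""Synthetic tracking references, cycle averaging, and motion-file I/O.

The generator emulates the structure of treadmill-style reference data: a
set of noisy realizations of one periodic gait cycle (right heel strike to
right heel strike), per-signal, which are then linearly resampled to the
collocation grid and averaged into mean and SD trajectories.

Joint-angle templates are periodic splines with running-like stance/swing
asymmetry; the left leg is the right leg phase-shifted by half a cycle
(mirrored DOF sign conventions are built into the model's joint axes, so the
same template serves both sides).  Vertical GRF is a single smooth hump per
stance (duty factor ~0.35) scaled so the two feet's cycle-average vertical
force equals body weight exactly; fore-aft GRF is a braking/propulsion
biphasic shape with zero net impulse; mediolateral GRF is a small hump with
opposite sign per side.  Cycle-to-cycle variation comes from seeded noise:
additive smooth noise with constant pointwise SD for angles, and a
multiplicative (mean-centred) factor on the GRFs, which leaves swing-phase
GRF variance at zero and so exercises the tracking variance floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ModelDefinition
from .objective import TrackingReference

__all__ = [
    "GaitCycleSet",
    "synth_reference",
    "cycles_to_reference",
    "write_sto",
    "read_sto",
]


@dataclass
class GaitCycleSet:
    names: list
    kinds: list
    cycles: list  # list of dict name -> 1D array (variable lengths)
    durations: list  # per-cycle duration, s

    def __post_init__(self):
        if len(self.cycles) < 1:
            raise ValueError("need at least one gait cycle")
        for c in self.cycles:
            missing = [n for n in self.names if n not in c]
            if missing:
                raise ValueError(f"cycle missing signals: {missing}")

    @property
    def cadence(self) -> float:
        return float(np.mean(self.durations))


# non-sagittal periodic templates in degrees (small, sinusoidal)
_DEG_FUNCS = {
    "pelvis_rot": lambda p: 6 * np.sin(2 * np.pi * p),
    "pelvis_list": lambda p: 3 * np.cos(2 * np.pi * p),
    "pelvis_tilt": lambda p: 2 + 1.5 * np.sin(4 * np.pi * p),
    "torso_tilt": lambda p: 5 + 1.5 * np.sin(4 * np.pi * p),
    "torso_list": lambda p: 3 * np.sin(2 * np.pi * p),
    "torso_rot": lambda p: -7 * np.sin(2 * np.pi * p),
    "hip_adduction": lambda p: 4 * np.cos(2 * np.pi * p),
    "hip_rotation": lambda p: -3 * np.sin(2 * np.pi * p),
    "subtalar_angle": lambda p: 3 * np.cos(2 * np.pi * p) + 1,
}


def _smoothstep(u):
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _leg_geometry(model: ModelDefinition) -> dict:
    j = {jt.name: jt for jt in model.joints}
    foot = model.segment("foot_r")
    pts = np.asarray(foot.contact_points)
    heel = pts[np.argmin(pts[:, 0])]
    toe = pts[np.argmax(pts[:, 0])]
    return {
        "hip_drop": -j["hip_r"].translation[1],
        "thigh": -j["knee_r"].translation[1],
        "shank": -j["ankle_r"].translation[1],
        "sub_drop": -j["subtalar_r"].translation[1],
        "heel": heel[:2],
        "toe": toe[:2],
    }


def _sagittal_templates(model: ModelDefinition, speed: float, T_cyc: float,
                        duty: float, n_samp: int = 240):
    """Hip-flexion/knee/ankle templates from a rolling-contact leg plan.

    The stance foot is planned flat and stationary on the ground (heel lift
    about the toe in late stance), the swing foot follows a smooth clearance
    path, and the pelvis bounces vertically at twice the stride frequency.
    Sagittal joint angles then follow from planar two-link inverse
    kinematics, which makes the synthetic angle data dynamically plausible:
    near-zero stance-foot slip and no ground interpenetration.  Returns
    (phase grid, hip, knee, ankle [rad], pelvis height profile [m]).
    """
    g = _leg_geometry(model)
    Lt, Ls = g["thigh"], g["shank"]
    heel_l, toe_l = g["heel"], g["toe"]
    foot_len = toe_l[0] - heel_l[0]
    sole = -heel_l[1] + g["sub_drop"]  # ankle height above ground, foot flat
    stride = speed * T_cyc
    ph = np.arange(n_samp) / n_samp
    y_flat = g["hip_drop"] + Lt + Ls + sole  # pelvis height, straight leg, foot flat
    # pelvis height from double integration of the planned vertical GRF:
    # ballistic in flight, compressed during stance -- dynamically consistent
    # with the GRF templates by construction
    weight = model.weight()
    F_tot = (weight / duty) * (
        np.where(ph < duty, np.sin(np.pi * ph / duty) ** 2, 0.0)
        + np.where(np.mod(ph + 0.5, 1.0) < duty,
                   np.sin(np.pi * np.mod(ph + 0.5, 1.0) / duty) ** 2, 0.0))
    dt = T_cyc / n_samp
    acc = (F_tot - weight) / model.subject_mass
    acc -= acc.mean()
    vel = dt * np.cumsum(acc)
    vel -= vel.mean()
    y_rel = dt * np.cumsum(vel)
    crouch = 0.055
    i_mid = int(round(0.5 * duty * n_samp))
    y_p = y_rel + (y_flat - crouch) - y_rel[i_mid]
    x_p = stride * ph
    # stance plan (right foot): heel lands ahead of the hip, foot flat, then
    # heel lift rotating about the toe over the last 40 % of stance
    x_heel_td = 0.20
    lift_start, lam_max = 0.60 * duty, 0.55
    x_toe = x_heel_td + foot_len
    heel_x = np.empty(n_samp)
    heel_y = np.empty(n_samp)
    pitch = np.empty(n_samp)  # world foot pitch, negative = heel up
    st = ph < duty
    lam = lam_max * _smoothstep((ph - lift_start) / (duty - lift_start))
    heel_x[st] = x_toe - foot_len * np.cos(lam[st])
    heel_y[st] = foot_len * np.sin(lam[st])
    pitch[st] = -lam[st]
    # swing: smooth blend from toe-off to the next touchdown (one stride on)
    sw = ~st
    u = (ph[sw] - duty) / (1.0 - duty)
    x_off = x_toe - foot_len * np.cos(lam_max)
    y_off = foot_len * np.sin(lam_max)
    s_u = _smoothstep(u)
    heel_x[sw] = x_off + (x_heel_td + stride - x_off) * s_u
    heel_y[sw] = (y_off * (1 - s_u) + 0.12 * np.sin(np.pi * u) ** 2
                  + 0.025 * _smoothstep(u / 0.25) * _smoothstep((1.0 - u) / 0.12))
    pitch[sw] = -lam_max * (1 - s_u**2)
    hip_x = x_p
    hip_y = y_p - g["hip_drop"]

    def fk(th, xh, yh):
        t1, k, a = th
        s1 = t1 - k
        f1 = s1 + a
        ank = np.array([xh + Lt * np.sin(t1) + Ls * np.sin(s1),
                        yh - Lt * np.cos(t1) - Ls * np.cos(s1)])
        sub = ank + g["sub_drop"] * np.array([np.sin(f1), -np.cos(f1)])
        R = np.array([[np.cos(f1), -np.sin(f1)], [np.sin(f1), np.cos(f1)]])
        return sub + R @ heel_l, sub + R @ toe_l

    hip_t = np.empty(n_samp)
    knee_t = np.empty(n_samp)
    ankle_t = np.empty(n_samp)
    th = np.array([0.4, 0.3, 0.0])
    reach = 0.995 * (Lt + Ls)
    for i in range(n_samp):
        target = np.array([heel_x[i], heel_y[i],
                           heel_y[i] + foot_len * np.sin(pitch[i])])
        # keep the heel target within leg reach
        dx, dy = target[0] - hip_x[i], (target[1] + sole) - hip_y[i]
        D = np.hypot(dx, dy)
        if D > reach:
            target[0] = hip_x[i] + dx * reach / D
            target[1] = hip_y[i] + dy * reach / D - sole
            target[2] = target[1] + foot_len * np.sin(pitch[i])
        for _ in range(25):
            heel, toe = fk(th, hip_x[i], hip_y[i])
            r = np.array([heel[0] - target[0], heel[1] - target[1],
                          toe[1] - target[2]])
            if np.max(np.abs(r)) < 1e-10:
                break
            J = np.empty((3, 3))
            for d in range(3):
                e = th.copy()
                e[d] += 1e-7
                hp, tp = fk(e, hip_x[i], hip_y[i])
                J[:, d] = (np.array([hp[0], hp[1], tp[1]])
                           - np.array([heel[0], heel[1], toe[1]])) / 1e-7
            try:
                step = np.linalg.solve(J, r)
            except np.linalg.LinAlgError:
                break
            th = th - np.clip(step, -0.5, 0.5)
        th[1] = max(th[1], 0.0)  # no hyperextension
        hip_t[i], knee_t[i], ankle_t[i] = th

    def lowpass(arr, n_harm=12):
        F = np.fft.rfft(arr)
        F[n_harm + 1:] = 0.0
        return np.fft.irfft(F, n_samp)

    # periodic low-pass: removes IK jitter near the reach boundary and makes
    # the wrap smooth, as measured gait data would be after filtering
    return ph, lowpass(hip_t), lowpass(knee_t), lowpass(ankle_t), y_p


def _angle_template(name: str, sag=None):
    """Periodic template in radians as a function of cycle phase in [0, 1)."""
    base, _, side = name.rpartition("_")
    shift = 0.5 if side == "l" else 0.0
    deg2rad = np.pi / 180.0
    if name.startswith("pelvis") or name.startswith("torso"):
        f = _DEG_FUNCS[name]
        return lambda p: deg2rad * f(np.mod(p, 1.0))
    if base in ("hip_adduction", "hip_rotation", "subtalar_angle"):
        f = _DEG_FUNCS[base]
        return lambda p: deg2rad * f(np.mod(p + shift, 1.0))
    ph, hip_t, knee_t, ankle_t, _ = sag
    arr = {"hip_flexion": hip_t, "knee_angle": knee_t,
           "ankle_angle": ankle_t}[base]
    tilt = _DEG_FUNCS["pelvis_tilt"]
    if base == "hip_flexion":
        # hip flexion is measured in the pelvis frame; subtract pelvis tilt
        return lambda p: (np.interp(np.mod(p + shift, 1.0), ph, arr, period=1.0)
                          - deg2rad * tilt(np.mod(p, 1.0)))
    return lambda p: np.interp(np.mod(p + shift, 1.0), ph, arr, period=1.0)


def _grf_templates(weight: float, duty: float):
    """Per-side GRF templates (N) as functions of cycle phase."""
    A = weight / duty  # two-feet cycle-average vertical force = weight

    def stance(p, shift):
        ph = np.mod(p + shift, 1.0)
        in_st = ph < duty
        return ph, in_st

    def fy(p, shift):
        ph, in_st = stance(p, shift)
        return np.where(in_st, A * np.sin(np.pi * ph / duty) ** 2, 0.0)

    def fx(p, shift):
        ph, in_st = stance(p, shift)
        return np.where(in_st, -0.35 * weight * np.sin(2 * np.pi * ph / duty), 0.0)

    def fz(p, shift, sign):
        ph, in_st = stance(p, shift)
        return np.where(in_st, sign * 0.06 * weight * np.sin(np.pi * ph / duty) ** 2, 0.0)

    return {
        "grf_r_x": lambda p: fx(p, 0.0),
        "grf_r_y": lambda p: fy(p, 0.0),
        "grf_r_z": lambda p: fz(p, 0.0, -1.0),
        "grf_l_x": lambda p: fx(p, 0.5),
        "grf_l_y": lambda p: fy(p, 0.5),
        "grf_l_z": lambda p: fz(p, 0.5, +1.0),
    }


def synth_reference(model: ModelDefinition, speed: float = 4.0, n_cycles: int = 12,
                    seed: int = 0, duty: float = 0.35, angle_noise_deg: float = 2.0,
                    grf_noise: float = 0.05, sample_rate: float = 200.0) -> GaitCycleSet:
    """Generate noisy periodic gait cycles for a straight run at ``speed``.

    Cadence follows a stride-length rule L = 0.5 v + 0.8 m, so the cycle
    duration is L / v.  With ``n_cycles`` >= 2 the sample SD across cycles is
    well defined; the GRF noise factors are mean-centred so the across-cycle
    mean vertical impulse of both feet equals body weight times the cycle
    duration exactly.
    """
    if n_cycles < 2:
        raise ValueError("need at least 2 cycles for a sample SD")
    rng = np.random.default_rng(seed)
    T_cyc = (0.5 * speed + 0.8) / speed
    weight = model.weight()
    angle_names = [d for d in model.dof_names if d not in ("pelvis_tx", "pelvis_ty", "pelvis_tz")]
    grf_names = [f"grf_{s}_{c}" for s in model.grf_groups for c in "xyz"]
    names = angle_names + grf_names
    kinds = ["angle"] * len(angle_names) + ["grf"] * len(grf_names)
    sag = _sagittal_templates(model, speed, T_cyc, duty)
    templates = {n: _angle_template(n, sag) for n in angle_names}
    templates.update(_grf_templates(weight, duty))

    sig_a = angle_noise_deg * np.pi / 180.0
    grf_factors = 1.0 + grf_noise * rng.standard_normal(n_cycles)
    grf_factors += 1.0 - grf_factors.mean()  # centre: mean impulse preserved

    cycles = []
    durations = []
    base_len = int(round(T_cyc * sample_rate))
    for c in range(n_cycles):
        n = base_len + int(rng.integers(-4, 5))
        ph = np.arange(n) / n
        cyc = {}
        for nm in angle_names:
            z = rng.standard_normal(3)
            noise = sig_a * (z[0] * np.cos(2 * np.pi * ph) + z[1] * np.sin(2 * np.pi * ph) + z[2]) / np.sqrt(2.0)
            cyc[nm] = templates[nm](ph) + noise
        for nm in grf_names:
            cyc[nm] = templates[nm](ph) * grf_factors[c]
        cycles.append(cyc)
        durations.append(n / sample_rate)
    return GaitCycleSet(names, kinds, cycles, durations)


def cycles_to_reference(cycles: GaitCycleSet, N: int) -> TrackingReference:
    """Resample every cycle to N samples, then average: mean and sample SD.

    Mirrors the usual experimental preparation where single extracted cycles
    of different lengths are linearly interpolated onto a common grid before
    computing mean and SD (here the grid is the collocation grid itself).
    """
    if N < 2:
        raise ValueError("need N >= 2 samples")
    ph = np.arange(N) / N
    n_sig = len(cycles.names)
    stack = np.empty((len(cycles.cycles), n_sig, N))
    for ci, cyc in enumerate(cycles.cycles):
        for si, nm in enumerate(cycles.names):
            y = np.asarray(cyc[nm], float)
            ph0 = np.arange(len(y)) / len(y)
            stack[ci, si] = np.interp(ph, np.concatenate([ph0, [1.0]]),
                                      np.concatenate([y, [y[0]]]))
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if len(cycles.cycles) > 1 else np.zeros_like(mean)
    return TrackingReference(list(cycles.names), list(cycles.kinds), mean, sd,
                             cadence=cycles.cadence)


# ---------------------------------------------------------------------------
# motion storage files (.sto / .mot dialect)
# ---------------------------------------------------------------------------

def write_sto(path, time, columns: dict, in_degrees: bool = False, name: str = "motion"):
    """Write a columnar motion-storage file (tab separated, header + endheader)."""
    time = np.asarray(time, float)
    if np.any(np.diff(time) <= 0):
        raise ValueError("time must be strictly increasing")
    cols = list(columns)
    if len(set(cols)) != len(cols):
        raise ValueError("column names must be unique")
    n_rows = len(time)
    with open(path, "w") as f:
        f.write(f"{name}\n")
        f.write(f"nRows={n_rows}\n")
        f.write(f"nColumns={len(cols) + 1}\n")
        f.write(f"inDegrees={'yes' if in_degrees else 'no'}\n")
        f.write("endheader\n")
        f.write("time\t" + "\t".join(cols) + "\n")
        data = np.column_stack([time] + [np.asarray(columns[c], float) for c in cols])
        for row in data:
            f.write("\t".join(f"{v:.17e}" for v in row) + "\n")


def _is_angle_column(name: str) -> bool:
    if name.startswith("grf") or "force" in name.lower():
        return False
    if name.endswith(("_tx", "_ty", "_tz")):
        return False
    return True


def read_sto(path):
    """Read a motion-storage file; converts angle columns to radians when
    the header declares degrees.  Returns (time, columns dict, in_degrees).
    """
    with open(path) as f:
        lines = f.readlines()
    in_degrees = False
    hdr_end = None
    for i, ln in enumerate(lines):
        s = ln.strip()
        if s.lower().startswith("indegrees"):
            in_degrees = s.split("=", 1)[1].strip().lower() in ("yes", "true", "1")
        if s == "endheader":
            hdr_end = i
            break
    if hdr_end is None:
        raise ValueError(f"{path}: no 'endheader' line found in {len(lines)} lines")
    try:
        names = lines[hdr_end + 1].rstrip("\n").split("\t")
    except IndexError:
        raise ValueError(f"{path}: missing column header at line {hdr_end + 2}")
    if names[0] != "time":
        raise ValueError(f"{path}: first column must be 'time' (line {hdr_end + 2})")
    rows = []
    for ln_no, ln in enumerate(lines[hdr_end + 2:], start=hdr_end + 3):
        s = ln.strip()
        if not s:
            continue
        parts = s.split()
        if len(parts) != len(names):
            raise ValueError(f"{path}: line {ln_no}: expected {len(names)} values, got {len(parts)}")
        try:
            rows.append([float(v) for v in parts])
        except ValueError:
            raise ValueError(f"{path}: line {ln_no}: non-numeric value")
    data = np.asarray(rows)
    time = data[:, 0]
    out = {}
    for j, nm in enumerate(names[1:], start=1):
        col = data[:, j]
        if in_degrees and _is_angle_column(nm):
            col = col * np.pi / 180.0
        out[nm] = col
    return time, out, in_degrees
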