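"""Musculoskeletal model structure: segments, joints, muscles, layout.

Coordinate convention: x forward, y vertical up, z to the subject's right.
The horizontal plane is x-z and heading is a rotation about +y, applied as
the outermost pelvis rotation so that the curved-running periodicity offset
adds to a single coordinate (``pelvis_rot``).  Angles are radians, all
quantities SI.

The state vector is x = (q, qdot, s, a) and the control vector
u = (n_e, m): generalized coordinates and their rates, the projected CE
length and activation of every muscle, neural excitations, and normalized
torques of the residual torque actuators.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import yaml

from .contact import ContactParameters
from .muscles import MuscleParameters, PathPolynomial

__all__ = [
    "SegmentSpec",
    "JointSpec",
    "MuscleRecord",
    "ModelDefinition",
    "StateControlLayout",
    "build_reduced_runner",
    "validate_model",
    "model_to_yaml",
    "model_from_yaml",
]

_AXES = {
    "x": np.array([1.0, 0.0, 0.0]),
    "y": np.array([0.0, 1.0, 0.0]),
    "z": np.array([0.0, 0.0, 1.0]),
    "-x": np.array([-1.0, 0.0, 0.0]),
    "-y": np.array([0.0, -1.0, 0.0]),
    "-z": np.array([0.0, 0.0, -1.0]),
}

_JOINT_NDOF = {"free6": 6, "ball3": 3, "revolute1": 1}


@dataclass(frozen=True)
class SegmentSpec:
    name: str
    mass: float
    inertia: tuple  # 3x3 about COM, segment frame, kg m^2
    com_offset: tuple  # proximal joint -> COM, m
    contact_points: tuple = ()  # list of 3-vectors, segment frame, m

    def __post_init__(self):
        object.__setattr__(self, "inertia", tuple(tuple(float(v) for v in row) for row in self.inertia))
        object.__setattr__(self, "com_offset", tuple(float(v) for v in self.com_offset))
        object.__setattr__(self, "contact_points", tuple(tuple(float(v) for v in p) for p in self.contact_points))


@dataclass(frozen=True)
class JointSpec:
    """One joint of the kinematic tree.

    ``rotation_order`` lists signed axis labels ('y', '-x', ...) outermost
    first for ball3 and for the rotational part of free6; ``axis`` is the
    unit axis of a revolute1 joint.  ``dof_names`` and ``dof_bounds`` are
    ordered translations-then-rotations for free6.
    """

    name: str
    parent: str
    child: str
    type: str
    translation: tuple = (0.0, 0.0, 0.0)
    axis: tuple | None = None
    rotation_order: tuple | None = None
    dof_names: tuple = ()
    dof_bounds: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "translation", tuple(float(v) for v in self.translation))
        if self.axis is not None:
            object.__setattr__(self, "axis", tuple(float(v) for v in self.axis))
        if self.rotation_order is not None:
            object.__setattr__(self, "rotation_order", tuple(self.rotation_order))
        object.__setattr__(self, "dof_names", tuple(self.dof_names))
        object.__setattr__(self, "dof_bounds", tuple(tuple(float(v) for v in b) for b in self.dof_bounds))

    @property
    def ndof(self) -> int:
        return _JOINT_NDOF[self.type]


@dataclass(frozen=True)
class MuscleRecord:
    params: MuscleParameters
    path: PathPolynomial


@dataclass(frozen=True)
class StateControlLayout:
    """Index slices locating (q, qdot, s, a) in x and (n_e, m) in u."""

    n_dof: int
    n_mus: int
    n_tor: int

    @property
    def n_x(self) -> int:
        return 2 * self.n_dof + 2 * self.n_mus

    @property
    def n_u(self) -> int:
        return self.n_mus + self.n_tor

    @property
    def q(self) -> slice:
        return slice(0, self.n_dof)

    @property
    def qdot(self) -> slice:
        return slice(self.n_dof, 2 * self.n_dof)

    @property
    def s(self) -> slice:
        return slice(2 * self.n_dof, 2 * self.n_dof + self.n_mus)

    @property
    def a(self) -> slice:
        return slice(2 * self.n_dof + self.n_mus, self.n_x)

    @property
    def n_e(self) -> slice:
        return slice(0, self.n_mus)

    @property
    def m(self) -> slice:
        return slice(self.n_mus, self.n_u)

    def pack_state(self, q, qdot, s, a):
        return np.concatenate([q, qdot, s, a], axis=-1)

    def unpack_state(self, x):
        x = np.asarray(x)
        return x[..., self.q], x[..., self.qdot], x[..., self.s], x[..., self.a]

    def pack_control(self, n_e, m):
        return np.concatenate([n_e, m], axis=-1)

    def unpack_control(self, u):
        u = np.asarray(u)
        return u[..., self.n_e], u[..., self.m]


@dataclass
class ModelDefinition:
    segments: list
    joints: list
    muscles: list
    torque_actuators: list  # (dof_name, normalization N*m)
    gravity: tuple = (0.0, -9.81, 0.0)
    subject_mass: float = 75.0
    subject_height: float = 1.75
    contact: ContactParameters = field(default_factory=ContactParameters)
    grf_groups: dict = field(default_factory=dict)  # side -> [segment names]
    # default state/control bounds for non-q entries
    qdot_bound: float = 30.0
    s_bounds: tuple = (1e-3, 0.6)
    m_bound: float = 5.0

    def __post_init__(self):
        self._chain = None

    # -- derived layout ----------------------------------------------------
    @property
    def dof_names(self) -> list[str]:
        names = []
        for j in self.joints:
            names.extend(j.dof_names)
        return names

    @property
    def dof_index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.dof_names)}

    @property
    def layout(self) -> StateControlLayout:
        return StateControlLayout(len(self.dof_names), len(self.muscles), len(self.torque_actuators))

    @property
    def segment_index(self) -> dict[str, int]:
        return {s.name: i for i, s in enumerate(self.segments)}

    def segment(self, name: str) -> SegmentSpec:
        return self.segments[self.segment_index[name]]

    # -- bounds ------------------------------------------------------------
    def q_bounds(self) -> np.ndarray:
        out = []
        for j in self.joints:
            out.extend(j.dof_bounds)
        return np.asarray(out, dtype=float)

    def state_bounds(self) -> np.ndarray:
        lay = self.layout
        qb = self.q_bounds()
        qd = np.tile([[-self.qdot_bound, self.qdot_bound]], (lay.n_dof, 1))
        # per-muscle contraction-state box around the optimal CE length,
        # clipped by the global s limits: keeps random/interim iterates at
        # physiological tendon strains
        sb = np.array([
            [max(self.s_bounds[0], 0.3 * m.params.l_CE_opt),
             min(self.s_bounds[1], 2.0 * m.params.l_CE_opt)]
            for m in self.muscles]) if self.muscles else np.zeros((0, 2))
        ab = np.tile([[0.0, 1.0]], (lay.n_mus, 1))
        return np.vstack([qb, qd, sb, ab])

    def control_bounds(self) -> np.ndarray:
        lay = self.layout
        ne = np.tile([[0.0, 1.0]], (lay.n_mus, 1))
        mb = np.tile([[-self.m_bound, self.m_bound]], (lay.n_tor, 1))
        return np.vstack([ne, mb])

    def weight(self) -> float:
        return self.subject_mass * float(-np.asarray(self.gravity)[1])


def validate_model(model: ModelDefinition) -> list[str]:
    """Diagnostics for every structural invariant; empty list iff usable."""
    report: list[str] = []
    seen = set()
    for seg in model.segments:
        if seg.name in seen:
            report.append(f"duplicate segment name '{seg.name}'")
        seen.add(seg.name)
        if not seg.mass > 0:
            report.append(f"segment '{seg.name}': mass must be > 0 (got {seg.mass})")
        I = np.asarray(seg.inertia, dtype=float)
        if I.shape != (3, 3):
            report.append(f"segment '{seg.name}': inertia must be 3x3")
        else:
            if not np.allclose(I, I.T, atol=1e-12):
                report.append(f"segment '{seg.name}': inertia not symmetric")
            elif np.min(np.linalg.eigvalsh(I)) < -1e-12:
                report.append(f"segment '{seg.name}': inertia not positive semi-definite")
    seg_names = {s.name for s in model.segments}
    children = {}
    for j in model.joints:
        if j.type not in _JOINT_NDOF:
            report.append(f"joint '{j.name}': unknown type '{j.type}'")
            continue
        if j.child not in seg_names:
            report.append(f"joint '{j.name}': unknown child segment '{j.child}'")
        if j.parent != "ground" and j.parent not in seg_names:
            report.append(f"joint '{j.name}': unknown parent segment '{j.parent}'")
        if j.child in children:
            report.append(f"segment '{j.child}' has more than one parent joint")
        children[j.child] = j
        if len(j.dof_names) != j.ndof or len(j.dof_bounds) != j.ndof:
            report.append(f"joint '{j.name}': needs {j.ndof} dof names/bounds")
        for n, (lo, hi) in zip(j.dof_names, j.dof_bounds):
            if lo > hi:
                report.append(f"DOF '{n}': lower bound exceeds upper bound")
        if j.type == "revolute1":
            if j.axis is None or abs(np.linalg.norm(j.axis) - 1.0) > 1e-9:
                report.append(f"joint '{j.name}': revolute axis must have unit norm")
        if j.type in ("ball3", "free6"):
            order = j.rotation_order or ()
            if len(order) != 3 or any(a not in _AXES for a in order):
                report.append(f"joint '{j.name}': rotation_order must be 3 signed axis labels")
    if model.joints:
        orphans = [s for s in seg_names if s not in children]
        if orphans:
            report.append(f"segments without a parent joint: {sorted(orphans)}")
        ground_joints = [j.name for j in model.joints if j.parent == "ground"]
        if len(ground_joints) != 1:
            report.append(f"tree must have exactly one root joint from 'ground', found {ground_joints}")
    dof_set = set()
    for j in model.joints:
        dof_set.update(j.dof_names)
    for dof, norm in model.torque_actuators:
        if dof not in dof_set:
            report.append(f"torque actuator references unknown DOF '{dof}'")
    mus_seen = set()
    for m in model.muscles:
        if m.params.name in mus_seen:
            report.append(f"duplicate muscle name '{m.params.name}'")
        mus_seen.add(m.params.name)
        report.extend(m.params.validate())
        report.extend(f"muscle '{m.params.name}': {msg}" for msg in m.path.validate())
        for dof in m.path.dof_names:
            if dof not in dof_set:
                report.append(f"muscle '{m.params.name}' references unknown DOF '{dof}'")
    report.extend(model.contact.validate())
    return report


# ---------------------------------------------------------------------------
# reduced runner
# ---------------------------------------------------------------------------

# body-segment mass fractions (sum exactly 1 with torso as remainder)
_MASS_FRAC = {"pelvis": 0.142, "thigh": 0.100, "shank": 0.0465, "talus": 0.002, "foot": 0.0125}


def _rod_inertia(m, L, r_frac, axial_frac=0.08):
    """Transverse/axial inertia of a y-axis segment from radius of gyration."""
    it = m * (r_frac * L) ** 2
    ia = m * (axial_frac * L) ** 2
    return ((it, 0.0, 0.0), (0.0, ia, 0.0), (0.0, 0.0, it))


def _leg_muscles(side: str) -> list[MuscleRecord]:
    """Nine condensed MTUs per leg (triceps surae merges gastrocnemius+soleus).

    Paths are low-order polynomials of the spanned joint angles; constant
    terms place each muscle at optimal CE length with a just-taut tendon in
    the neutral pose.  Moment arms (m/rad) are in the range of adult lower
    limb values.
    """
    hf, ha, hr = f"hip_flexion_{side}", f"hip_adduction_{side}", f"hip_rotation_{side}"
    kn, an, st = f"knee_angle_{side}", f"ankle_angle_{side}", f"subtalar_angle_{side}"

    def lin(dofs: dict[str, float]) -> list:
        names = tuple(dofs)
        terms = []
        n = len(names)
        for j, c in enumerate(dofs.values()):
            exps = tuple(1 if k == j else 0 for k in range(n))
            terms.append((exps, c))
        return names, terms

    def rec(name, F, lopt, slack, phi, dofs):
        names, terms = lin(dofs)
        const = slack + lopt * float(np.cos(phi))
        terms = [((0,) * len(names), const)] + terms
        return MuscleRecord(
            MuscleParameters(f"{name}_{side}", F_ISO=F, l_CE_opt=lopt, l_slack=slack, phi_opt=phi),
            PathPolynomial(names, terms),
        )

    return [
        rec("iliopsoas", 3000, 0.10, 0.12, 0.15, {hf: -0.040}),
        rec("glutei", 3500, 0.14, 0.12, 0.10, {hf: +0.055, hr: +0.025}),
        rec("hip_abductor", 3500, 0.09, 0.10, 0.10, {ha: +0.045}),
        rec("hip_adductor", 2500, 0.10, 0.11, 0.05, {ha: -0.035, hr: -0.020}),
        rec("hamstrings", 3300, 0.10, 0.32, 0.10, {hf: +0.060, kn: -0.030}),
        rec("rectus_femoris", 1600, 0.11, 0.30, 0.05, {hf: -0.035, kn: +0.042}),
        rec("vasti", 8000, 0.09, 0.22, 0.05, {kn: +0.045}),
        rec("triceps_surae", 9500, 0.07, 0.36, 0.25, {kn: -0.012, an: +0.055, st: +0.030}),
        rec("tibialis_anterior", 2200, 0.08, 0.25, 0.05, {an: -0.040, st: -0.030}),
    ]


def build_reduced_runner(subject_mass: float = 92.0, subject_height: float = 1.95) -> ModelDefinition:
    """Desk-scale 3D runner: 21 DOFs, 18 MTUs, 3 torso torque actuators.

    Pelvis root (3 translations + heading/list/tilt rotations with heading
    about vertical outermost), torso ball joint, and per leg a ball hip, a
    revolute knee, ankle and subtalar joint.  Two contact points (heel, toe)
    under each foot.  Masses, lengths and inertias scale with standard
    anthropometric fractions of the subject's mass and height, so segment
    masses sum exactly to ``subject_mass``.
    """
    if not (subject_mass > 0 and subject_height > 0):
        raise ValueError("subject mass and height must be positive")
    M, H = float(subject_mass), float(subject_height)
    thigh_len = 0.245 * H
    shank_len = 0.246 * H
    foot_len = 0.152 * H
    ankle_h = 0.039 * H
    hip_half = 0.050 * H
    torso_frac = 1.0 - _MASS_FRAC["pelvis"] - 2.0 * (
        _MASS_FRAC["thigh"] + _MASS_FRAC["shank"] + _MASS_FRAC["talus"] + _MASS_FRAC["foot"])

    m_pel = _MASS_FRAC["pelvis"] * M
    m_tor = torso_frac * M
    m_thi = _MASS_FRAC["thigh"] * M
    m_sha = _MASS_FRAC["shank"] * M
    m_tal = _MASS_FRAC["talus"] * M
    m_foo = _MASS_FRAC["foot"] * M

    sole_y = -(ankle_h - 0.02)
    segments = [
        SegmentSpec("pelvis", m_pel, _rod_inertia(m_pel, 0.25 * H, 0.35), (0.0, 0.0, 0.0)),
        SegmentSpec("torso", m_tor, _rod_inertia(m_tor, 0.45 * H, 0.40, 0.25), (0.0, 0.18 * H, 0.0)),
    ]
    joints = [
        JointSpec(
            "ground_pelvis", "ground", "pelvis", "free6",
            rotation_order=("y", "x", "z"),
            dof_names=("pelvis_tx", "pelvis_ty", "pelvis_tz", "pelvis_rot", "pelvis_list", "pelvis_tilt"),
            dof_bounds=((-15, 15), (0.4, 1.5), (-15, 15), (-6.3, 6.3), (-0.6, 0.6), (-0.6, 0.6)),
        ),
        JointSpec(
            "back", "pelvis", "torso", "ball3", translation=(0.0, 0.05 * H, 0.0),
            rotation_order=("z", "x", "y"),
            dof_names=("torso_tilt", "torso_list", "torso_rot"),
            dof_bounds=((-0.6, 0.6), (-0.6, 0.6), (-0.8, 0.8)),
        ),
    ]
    muscles: list[MuscleRecord] = []
    for side, sz in (("r", +1.0), ("l", -1.0)):
        segments += [
            SegmentSpec(f"thigh_{side}", m_thi, _rod_inertia(m_thi, thigh_len, 0.323), (0.0, -0.433 * thigh_len, 0.0)),
            SegmentSpec(f"shank_{side}", m_sha, _rod_inertia(m_sha, shank_len, 0.302), (0.0, -0.433 * shank_len, 0.0)),
            SegmentSpec(f"talus_{side}", m_tal, _rod_inertia(m_tal, 0.05, 0.4), (0.0, -0.01, 0.0)),
            SegmentSpec(
                f"foot_{side}", m_foo, _rod_inertia(m_foo, foot_len, 0.25), (0.25 * foot_len, 0.5 * sole_y, 0.0),
                contact_points=((-0.25 * foot_len, sole_y, 0.0), (0.45 * foot_len, sole_y, 0.0)),
            ),
        ]
        joints += [
            JointSpec(
                f"hip_{side}", "pelvis", f"thigh_{side}", "ball3",
                translation=(0.0, -0.035 * H, sz * hip_half),
                rotation_order=("z", "x" if sz > 0 else "-x", "y" if sz > 0 else "-y"),
                dof_names=(f"hip_flexion_{side}", f"hip_adduction_{side}", f"hip_rotation_{side}"),
                dof_bounds=((-0.7, 2.1), (-0.9, 0.7), (-0.8, 0.8)),
            ),
            JointSpec(
                f"knee_{side}", f"thigh_{side}", f"shank_{side}", "revolute1",
                translation=(0.0, -thigh_len, 0.0), axis=(0.0, 0.0, -1.0),
                dof_names=(f"knee_angle_{side}",), dof_bounds=((-0.05, 2.8),),
            ),
            JointSpec(
                f"ankle_{side}", f"shank_{side}", f"talus_{side}", "revolute1",
                translation=(0.0, -shank_len, 0.0), axis=(0.0, 0.0, 1.0),
                dof_names=(f"ankle_angle_{side}",), dof_bounds=((-1.0, 0.8),),
            ),
            JointSpec(
                f"subtalar_{side}", f"talus_{side}", f"foot_{side}", "revolute1",
                translation=(0.0, -0.02, 0.0), axis=(1.0 * sz, 0.0, 0.0),
                dof_names=(f"subtalar_angle_{side}",), dof_bounds=((-0.7, 0.7),),
            ),
        ]
        muscles += _leg_muscles(side)

    actuators = [("torso_tilt", 10.0), ("torso_list", 10.0), ("torso_rot", 10.0)]
    return ModelDefinition(
        segments=segments,
        joints=joints,
        muscles=muscles,
        torque_actuators=actuators,
        subject_mass=M,
        subject_height=H,
        grf_groups={"r": ["foot_r"], "l": ["foot_l"]},
    )


# ---------------------------------------------------------------------------
# YAML serialization
# ---------------------------------------------------------------------------

def model_to_yaml(model: ModelDefinition) -> str:
    doc = {
        "subject": {"mass": model.subject_mass, "height": model.subject_height},
        "gravity": list(model.gravity),
        "bounds": {
            "qdot": model.qdot_bound,
            "s": list(model.s_bounds),
            "m": model.m_bound,
        },
        "contact": {k: getattr(model.contact, k) for k in ("k_n", "c_n", "mu", "v_c", "eps_p")},
        "grf_groups": {k: list(v) for k, v in model.grf_groups.items()},
        "segments": [
            {
                "name": s.name,
                "mass": s.mass,
                "inertia": [list(r) for r in s.inertia],
                "com_offset": list(s.com_offset),
                "contact_points": [list(p) for p in s.contact_points],
            }
            for s in model.segments
        ],
        "joints": [
            {
                "name": j.name,
                "parent": j.parent,
                "child": j.child,
                "type": j.type,
                "translation": list(j.translation),
                "axis": list(j.axis) if j.axis is not None else None,
                "rotation_order": list(j.rotation_order) if j.rotation_order else None,
                "dof_names": list(j.dof_names),
                "dof_bounds": [list(b) for b in j.dof_bounds],
            }
            for j in model.joints
        ],
        "torque_actuators": [[d, n] for d, n in model.torque_actuators],
        "muscles": [
            {
                "params": {
                    k: getattr(m.params, k)
                    for k in ("name", "F_ISO", "l_CE_opt", "l_slack", "W", "v_max", "A_hill",
                              "phi_opt", "T_act", "T_deact", "eps0_SEE", "k_PEE", "d_CE", "f_ecc_max")
                },
                "path": {
                    "dof_names": list(m.path.dof_names),
                    "terms": [[list(e), c] for e, c in m.path.terms],
                },
            }
            for m in model.muscles
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False)


def model_from_yaml(text: str) -> ModelDefinition:
    doc = yaml.safe_load(text)
    segments = [
        SegmentSpec(s["name"], s["mass"], s["inertia"], s["com_offset"], s.get("contact_points", []))
        for s in doc["segments"]
    ]
    joints = [
        JointSpec(
            j["name"], j["parent"], j["child"], j["type"],
            translation=j.get("translation", (0, 0, 0)),
            axis=j.get("axis"),
            rotation_order=j.get("rotation_order"),
            dof_names=j.get("dof_names", ()),
            dof_bounds=j.get("dof_bounds", ()),
        )
        for j in doc["joints"]
    ]
    muscles = [
        MuscleRecord(
            MuscleParameters(**m["params"]),
            PathPolynomial(m["path"]["dof_names"], [(tuple(e), c) for e, c in m["path"]["terms"]]),
        )
        for m in doc["muscles"]
    ]
    b = doc.get("bounds", {})
    return ModelDefinition(
        segments=segments,
        joints=joints,
        muscles=muscles,
        torque_actuators=[tuple(t) for t in doc.get("torque_actuators", [])],
        gravity=tuple(doc.get("gravity", (0, -9.81, 0))),
        subject_mass=doc["subject"]["mass"],
        subject_height=doc["subject"]["height"],
        contact=ContactParameters(**doc.get("contact", {})),
        grf_groups=doc.get("grf_groups", {}),
        qdot_bound=b.get("qdot", 30.0),
        s_bounds=tuple(b.get("s", (1e-3, 0.6))),
        m_bound=b.get("m", 5.0),
    )
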