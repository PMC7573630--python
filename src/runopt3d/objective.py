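"""Objective terms: tracking, muscular effort, arm torque, regularization.

The total objective is the weighted sum

    J = W_Track J_track + W_mus J_mus + W_tor J_tor + W_reg J_reg

with every term dimensionless and nonnegative.  Integrals are discretized
with the same backward-Euler rectangle rule as the dynamics (uniform
h = T_sim / N), so the 1/T_sim normalization cancels into 1/N; the duration
still enters through the backward-difference rates in the regularization
term.

Tracking divides squared deviations by the measured variance, floored at a
fraction (default 10 %) of the signal's mean variance so that near-zero
variance samples (e.g. swing-phase GRF) cannot dominate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ObjectiveConfig",
    "TrackingReference",
    "adjust_variance",
    "signal_weights",
    "tracking_cost",
    "effort_cost",
    "torque_cost",
    "regularization_cost",
    "total_objective",
]


@dataclass
class ObjectiveConfig:
    W_Track: float = 1.0
    W_mus: float = 1.0
    W_tor: float = 1.0
    W_reg: float = 1e-3
    W_ang: float = 1.0
    W_GRF: float = 5.0
    var_floor_frac: float = 0.1
    v_ref: tuple = (0.0, 0.0)  # (v_x, v_z) m/s; (0, 0) skips the speed normalization

    def validate(self) -> list[str]:
        bad = []
        for w in ("W_Track", "W_mus", "W_tor", "W_reg", "W_ang", "W_GRF"):
            if getattr(self, w) < 0:
                bad.append(f"{w} must be >= 0")
        if not (0.0 < self.var_floor_frac <= 1.0):
            bad.append("var_floor_frac must be in (0, 1]")
        return bad

    @property
    def speed_norm(self) -> float:
        """|v|^3 effort divisor; 1 for the standing task (zero reference speed)."""
        v = float(np.hypot(*self.v_ref))
        return v**3 if v > 0 else 1.0


@dataclass
class TrackingReference:
    """Per-signal mean and SD trajectories over N samples of one gait cycle."""

    names: list
    kinds: list  # 'angle' | 'grf' per signal
    mean: np.ndarray  # (n_signals, N)
    sd: np.ndarray  # (n_signals, N)
    cadence: float = 0.7  # mean measured cycle duration, s

    def __post_init__(self):
        self.mean = np.atleast_2d(np.asarray(self.mean, float))
        self.sd = np.atleast_2d(np.asarray(self.sd, float))
        if self.mean.shape != self.sd.shape:
            raise ValueError("mean and sd must have identical shapes")
        if len(self.names) != self.mean.shape[0] or len(self.kinds) != self.mean.shape[0]:
            raise ValueError("names/kinds must match the number of signals")
        if np.any(self.sd < 0):
            raise ValueError("SD trajectories must be nonnegative")

    @property
    def n_samples(self) -> int:
        return self.mean.shape[1]

    def subset(self, names) -> "TrackingReference":
        idx = [self.names.index(n) for n in names]
        return TrackingReference([self.names[i] for i in idx], [self.kinds[i] for i in idx],
                                 self.mean[idx], self.sd[idx], self.cadence)


def adjust_variance(sd, floor_frac: float = 0.1) -> np.ndarray:
    """Variance trajectory floored at ``floor_frac`` of its own mean.

    var_i(t) = max(sd_i(t)^2, floor_frac * mean_t sd_i(t)^2).  Raises for an
    identically-zero SD, for which tracking normalization is impossible.
    """
    sd_in = np.asarray(sd, float)
    sd2 = np.atleast_2d(sd_in)
    if sd2.size == 0:
        raise ValueError("empty SD trajectory")
    var = sd2**2
    mean_var = var.mean(axis=-1, keepdims=True)
    if np.any(mean_var == 0.0):
        raise ValueError("tracked signal has identically zero SD; cannot normalize")
    out = np.maximum(var, floor_frac * mean_var)
    return out[0] if sd_in.ndim == 1 else out


def signal_weights(kinds, W_ang: float = 1.0, W_GRF: float = 5.0) -> np.ndarray:
    """Per-signal tracking weights from a weighted arithmetic mean.

    W_i = W_ang / (N_ang W_ang + N_grf W_GRF) for angle signals and
    W_GRF / (...) for GRF signals, so the weights sum to one and the balance
    between the two groups is independent of how many signals each has.
    """
    kinds = list(kinds)
    n_ang = sum(1 for k in kinds if k == "angle")
    n_grf = len(kinds) - n_ang
    denom = n_ang * W_ang + n_grf * W_GRF
    if denom <= 0:
        raise ValueError("signal weight denominator is zero")
    return np.asarray([(W_ang if k == "angle" else W_GRF) / denom for k in kinds])


def tracking_cost(y_sim, ref: TrackingReference, weights, T_sim: float,
                  floor_frac: float = 0.1) -> float:
    """Backward-Euler quadrature of the variance-normalized tracking error.

    ``y_sim`` has shape (N, n_signals) on the same node grid as the
    reference.
    """
    y_sim = np.asarray(y_sim)
    if y_sim.shape != (ref.n_samples, len(ref.names)):
        raise ValueError(
            f"grid mismatch: simulated {y_sim.shape}, reference "
            f"{(ref.n_samples, len(ref.names))}")
    var = np.atleast_2d(adjust_variance(ref.sd, floor_frac))  # (S, N)
    dev = (y_sim.T - ref.mean) ** 2 / var
    w = np.asarray(weights)
    return float(np.real(np.sum(w[:, None] * dev) / ref.n_samples))


def muscle_volume_fractions(muscles) -> np.ndarray:
    vols = np.asarray([m.params.F_ISO * m.params.l_CE_opt for m in muscles])
    return vols / vols.sum()


def effort_cost(n_e, muscles, v_ref, T_sim: float) -> float:
    """Volume-weighted cubed neural excitation, speed-normalized.

    J = (1 / (N_mus |v|^3)) * mean_k sum_i volfrac_i n_e_i(k)^3 with the
    divisor |v|^3 = 1 when the reference speed is zero (standing).
    """
    n_e = np.asarray(n_e)
    vol = muscle_volume_fractions(muscles)
    v = float(np.hypot(*v_ref))
    vnorm = v**3 if v > 0 else 1.0
    return float(np.real(np.mean(np.sum(vol * n_e**3, axis=-1)) / (len(muscles) * vnorm)))


def torque_cost(m, T_sim: float) -> float:
    """Mean squared normalized actuator torque; zero when there are none."""
    m = np.asarray(m)
    if m.size == 0:
        return 0.0
    n_tor = m.shape[-1]
    return float(np.real(np.mean(np.sum(m**2, axis=-1)) / n_tor))


def regularization_cost(X, U, T_sim: float, pmap=None) -> float:
    """Mean squared backward-difference rates of states and controls.

    The wrap interval closes the cycle through the periodicity map (identity
    when ``pmap`` is None).
    """
    X = np.asarray(X)
    U = np.asarray(U)
    N = X.shape[0]
    if N < 2 and pmap is None:
        raise ValueError("regularization needs at least 2 nodes")
    h = T_sim / N
    x_end = pmap.apply(X[0], T_sim) if pmap is not None else X[0]
    dX = np.diff(np.vstack([X, x_end[None]]), axis=0) / h
    dU = np.diff(np.vstack([U, U[:1]]), axis=0) / h
    n = X.shape[1] + U.shape[1]
    return float(np.real(np.mean(np.sum(dX**2, axis=1) + np.sum(dU**2, axis=1)) / n))


def total_objective(y_sim, X, U, n_e, m, T_sim, config: ObjectiveConfig,
                    ref: TrackingReference | None, muscles, pmap=None):
    """Weighted objective total and its per-term breakdown."""
    terms = {}
    if config.W_Track > 0 and ref is not None:
        w = signal_weights(ref.kinds, config.W_ang, config.W_GRF)
        terms["track"] = tracking_cost(y_sim, ref, w, T_sim, config.var_floor_frac)
    else:
        terms["track"] = 0.0
    terms["mus"] = effort_cost(n_e, muscles, config.v_ref, T_sim)
    terms["tor"] = torque_cost(m, T_sim)
    terms["reg"] = regularization_cost(X, U, T_sim, pmap) if X.shape[0] >= 2 else 0.0
    J = (config.W_Track * terms["track"] + config.W_mus * terms["mus"]
         + config.W_tor * terms["tor"] + config.W_reg * terms["reg"])
    return float(J), terms
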