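"""Sigmoidal-ODE model of the four-component HPA network.

The hypothalamic-pituitary-adrenal (HPA) axis is modelled as four coupled
activities -- CRH, ACTH, cortisol (COR) and the activated glucocorticoid
receptor (GR) -- each obeying the standard sigmoidal form

    dX_i/dt = ts_i * (F_i - X_i),      F_i = 1 / (1 + exp(-sigma * W_i)),
    W_i     = R_i0 + sum_j R_ij * X_j,

where ``W_i`` is the net regulatory input to component ``i``, ``R_ij`` a
signed regulation weight, ``R_i0`` a background input lumping everything not
modelled explicitly, and ``ts_i`` the component's relaxation rate.  The
exogenous stress signal SS enters CRH only, through the weight ``RCRH_SS``.
The wiring combines the classic negative feedback (GR represses CRH and
ACTH) with two positive feedbacks (CRH and GR self-activation) that make
bistable, disorder-like steady states possible.

All activities live in (0, 1) at steady state, so [0, 1]^4 is forward
invariant and serves as the search box for fixed points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import _kernels

__all__ = [
    "COMPONENTS",
    "REGULATORY_NAMES",
    "BACKGROUND_NAMES",
    "TIMESCALE_NAMES",
    "PARAM_NAMES",
    "NetworkSpec",
    "ParameterSet",
    "SystemState",
    "Trajectory",
    "FixedPoint",
    "StepSignal",
    "ParameterOverlay",
    "IntegrationError",
    "sigmoid_activity",
    "net_input",
    "derivatives",
    "jacobian",
    "integrate",
    "find_fixed_points",
]

COMPONENTS = ("CRH", "ACTH", "COR", "GR")

REGULATORY_NAMES = (
    "RCRH_SS", "RCRH_CRH", "RCRH_GR",
    "RACTH_CRH", "RACTH_GR",
    "RCOR_ACTH",
    "RGR_COR", "RGR_GR",
)
BACKGROUND_NAMES = ("RCRH_0", "RACTH_0", "RCOR_0", "RGR_0")
TIMESCALE_NAMES = ("ts_CRH", "ts_ACTH", "ts_COR", "ts_GR")

#: canonical parameter-vector order used by the integration kernel
PARAM_NAMES = REGULATORY_NAMES + BACKGROUND_NAMES + TIMESCALE_NAMES

_INDEX = {name: i for i, name in enumerate(PARAM_NAMES)}

# (regulator, target) -> weight name; the 8 edges of the network
_EDGES = {
    ("SS", "CRH"): "RCRH_SS",
    ("CRH", "CRH"): "RCRH_CRH",
    ("GR", "CRH"): "RCRH_GR",
    ("CRH", "ACTH"): "RACTH_CRH",
    ("GR", "ACTH"): "RACTH_GR",
    ("ACTH", "COR"): "RCOR_ACTH",
    ("COR", "GR"): "RGR_COR",
    ("GR", "GR"): "RGR_GR",
}

_SIGNS = {name: +1 for name in REGULATORY_NAMES}
_SIGNS["RCRH_GR"] = -1
_SIGNS["RACTH_GR"] = -1


class IntegrationError(RuntimeError):
    """Raised when the adaptive integrator fails; carries the parameters."""

    def __init__(self, message: str, params: "ParameterSet | None" = None):
        super().__init__(message)
        self.params = params


@dataclass(frozen=True)
class NetworkSpec:
    """The fixed HPA wiring plus the sigmoid gain ``sigma``.

    ``edge_roles`` maps (regulator, target) pairs to weight names and
    ``sign_constraints`` records whether each weight is an activation (+1)
    or an inhibition (-1).  Only ``sigma`` is genuinely tunable; the wiring
    is part of the model identity and validated, not configured.
    """

    sigma: float = 10.0
    component_names: tuple[str, ...] = COMPONENTS
    edge_roles: Mapping[tuple[str, str], str] = field(
        default_factory=lambda: dict(_EDGES))
    sign_constraints: Mapping[str, int] = field(
        default_factory=lambda: dict(_SIGNS))

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if dict(self.edge_roles) != _EDGES:
            raise ValueError("edge_roles must be the 8 fixed HPA edges")
        if dict(self.sign_constraints) != _SIGNS:
            raise ValueError(
                "sign_constraints must mark GR->CRH and GR->ACTH as "
                "inhibitions and the other six edges as activations")


@dataclass(frozen=True)
class ParameterSet:
    """One individual's 16 parameter values.

    Split into the 8 regulatory weights, the 4 background inputs and the 4
    relaxation rates; ``as_array`` returns them in the canonical kernel
    order (:data:`PARAM_NAMES`).
    """

    regulatory: Mapping[str, float]
    background: Mapping[str, float]
    timescale: Mapping[str, float]

    def __post_init__(self) -> None:
        for names, group, label in (
            (REGULATORY_NAMES, self.regulatory, "regulatory"),
            (BACKGROUND_NAMES, self.background, "background"),
            (TIMESCALE_NAMES, self.timescale, "timescale"),
        ):
            missing = set(names) - set(group)
            extra = set(group) - set(names)
            if missing or extra:
                raise ValueError(
                    f"{label} parameters: missing {sorted(missing)}, "
                    f"unexpected {sorted(extra)}")
            for k, v in group.items():
                if not math.isfinite(v):
                    raise ValueError(f"parameter {k} is not finite: {v}")
        for name, sign in _SIGNS.items():
            v = self.regulatory[name]
            if v != 0.0 and math.copysign(1.0, v) != sign:
                raise ValueError(
                    f"{name} must have sign {sign:+d} (or be 0), got {v}")
        for name, v in self.timescale.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")

    @classmethod
    def from_dict(cls, values: Mapping[str, float]) -> "ParameterSet":
        return cls(
            regulatory={k: float(values[k]) for k in REGULATORY_NAMES},
            background={k: float(values[k]) for k in BACKGROUND_NAMES},
            timescale={k: float(values[k]) for k in TIMESCALE_NAMES},
        )

    @classmethod
    def from_array(cls, vec: np.ndarray) -> "ParameterSet":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (16,):
            raise ValueError(f"expected 16 values, got shape {vec.shape}")
        return cls.from_dict(dict(zip(PARAM_NAMES, vec)))

    def to_dict(self) -> dict[str, float]:
        return {k: self[k] for k in PARAM_NAMES}

    def as_array(self) -> np.ndarray:
        return np.array([self[k] for k in PARAM_NAMES], dtype=float)

    def __getitem__(self, name: str) -> float:
        if name in REGULATORY_NAMES:
            return float(self.regulatory[name])
        if name in BACKGROUND_NAMES:
            return float(self.background[name])
        if name in TIMESCALE_NAMES:
            return float(self.timescale[name])
        raise KeyError(name)

    def replace(self, **updates: float) -> "ParameterSet":
        d = self.to_dict()
        for k, v in updates.items():
            if k not in d:
                raise KeyError(k)
            d[k] = v
        return ParameterSet.from_dict(d)


@dataclass(frozen=True)
class SystemState:
    """Instantaneous state: 4 component activities plus a time stamp."""

    x: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        if x.shape != (4,):
            raise ValueError(f"state must have 4 components, got {x.shape}")
        if not np.all(np.isfinite(x)):
            raise ValueError(f"state has non-finite entries: {x}")
        object.__setattr__(self, "x", x)


@dataclass(frozen=True)
class Trajectory:
    """Time series of the 4 activities plus the aligned stress input."""

    times: np.ndarray
    states: np.ndarray
    stress: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        x = np.asarray(self.states, dtype=float)
        s = np.asarray(self.stress, dtype=float)
        if x.shape != (t.size, 4) or s.shape != (t.size,):
            raise ValueError("times/states/stress shapes are inconsistent")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(s))):
            raise ValueError("trajectory contains non-finite values")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "states", x)
        object.__setattr__(self, "stress", s)

    def component(self, name: str) -> np.ndarray:
        return self.states[:, COMPONENTS.index(name)]

    def state_at(self, t: float) -> SystemState:
        """State at the output point closest to ``t``."""
        i = int(np.argmin(np.abs(self.times - t)))
        return SystemState(self.states[i], float(self.times[i]))

    def window_mean(self, component: str, t_start: float,
                    t_end: float | None = None) -> float:
        """Time-average of one component over [t_start, t_end]."""
        if t_end is None:
            t_end = float(self.times[-1])
        mask = (self.times >= t_start) & (self.times <= t_end)
        if not mask.any():
            raise ValueError(f"no output points in [{t_start}, {t_end}]")
        return float(np.trapezoid(self.component(component)[mask],
                                  self.times[mask])
                     / (self.times[mask][-1] - self.times[mask][0])) \
            if mask.sum() > 1 else float(self.component(component)[mask][0])

    def peak_to_peak(self, component: str, tail_frac: float = 0.2) -> float:
        """Amplitude of the final ``tail_frac`` of the run."""
        t0 = self.times[-1] - tail_frac * (self.times[-1] - self.times[0])
        y = self.component(component)[self.times >= t0]
        return float(y.max() - y.min())

    def is_oscillatory(self, component: str = "COR",
                       threshold: float = 0.01) -> bool:
        """Non-decaying tail amplitude above ``threshold`` flags a limit cycle."""
        return self.peak_to_peak(component) > threshold

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(COMPONENTS))
        df.insert(0, "time", self.times)
        df["SS"] = self.stress
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        df = pd.read_csv(path)
        return cls(df["time"].to_numpy(),
                   df[list(COMPONENTS)].to_numpy(),
                   df["SS"].to_numpy())


@dataclass(frozen=True)
class FixedPoint:
    """A root of X = F(W(X)) with its linear stability."""

    x: np.ndarray
    stable: bool
    eigenvalues: np.ndarray


class StepSignal:
    """Piecewise-constant exogenous signal defined by breakpoints.

    ``values[i]`` holds on the half-open interval
    [breakpoints[i], breakpoints[i+1]); before the first breakpoint the
    signal is ``values[0]`` extended backwards only if t < breakpoints[0]
    never occurs in practice -- the signal is 0 there.
    """

    def __init__(self, breakpoints: Sequence[float], values: Sequence[float]):
        bp = np.asarray(breakpoints, dtype=float)
        vals = np.asarray(values, dtype=float)
        if bp.size != vals.size:
            raise ValueError("breakpoints and values must align")
        if bp.size and not np.all(np.diff(bp) > 0):
            raise ValueError("breakpoints must be strictly increasing")
        self.breakpoints = bp
        self.values = vals

    @classmethod
    def constant(cls, value: float) -> "StepSignal":
        return cls([], []) if value == 0 else cls([-np.inf], [value])

    def __call__(self, t: float) -> float:
        i = int(np.searchsorted(self.breakpoints, t, side="right")) - 1
        return float(self.values[i]) if i >= 0 else 0.0

    def finite_breakpoints(self) -> np.ndarray:
        return self.breakpoints[np.isfinite(self.breakpoints)]


class ParameterOverlay:
    """Transient additive parameter changes: (name, delta) on [t_on, t_off)."""

    def __init__(self, windows: Iterable[tuple[str, float, float, float]] = ()):
        self.windows = []
        for name, delta, t_on, t_off in windows:
            if name not in _INDEX:
                raise KeyError(f"unknown parameter {name!r}")
            if not t_off > t_on:
                raise ValueError("overlay window must have t_off > t_on")
            self.windows.append((name, float(delta), float(t_on), float(t_off)))

    def breakpoints(self) -> np.ndarray:
        pts = [t for _, _, a, b in self.windows for t in (a, b)]
        return np.array(sorted(set(pts)), dtype=float)

    def apply(self, base: np.ndarray, t: float) -> np.ndarray:
        vec = base.copy()
        for name, delta, a, b in self.windows:
            if a <= t < b:
                vec[_INDEX[name]] += delta
        return vec


def sigmoid_activity(w: float, sigma: float) -> float:
    """Logistic steady-state activity F = 1/(1 + exp(-sigma*w)).

    The exponent is clamped at +/-700 so extreme net inputs saturate to 0 or
    1 instead of overflowing.
    """
    if not sigma > 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    w = np.asarray(w, dtype=float)
    if not np.all(np.isfinite(w)):
        raise ValueError(f"net input must be finite, got {w}")
    z = np.clip(sigma * w, -_kernels._EXP_CLAMP, _kernels._EXP_CLAMP)
    out = 1.0 / (1.0 + np.exp(-z))
    return float(out) if out.ndim == 0 else out


def _regulatory_matrix(params: ParameterSet) -> np.ndarray:
    """4x4 weight matrix R[target, regulator] over the model components."""
    R = np.zeros((4, 4))
    for (reg, tgt), name in _EDGES.items():
        if reg == "SS":
            continue
        R[COMPONENTS.index(tgt), COMPONENTS.index(reg)] = params[name]
    return R


def net_input(state: SystemState, params: ParameterSet,
              ss_value: float) -> np.ndarray:
    """Net regulatory input W_i = R_i0 + sum over wired edges of R_ij X_j."""
    if ss_value < 0:
        raise ValueError(f"stress must be >= 0, got {ss_value}")
    b = np.array([params[k] for k in BACKGROUND_NAMES])
    w = b + _regulatory_matrix(params) @ state.x
    w[0] += params["RCRH_SS"] * ss_value
    return w


def derivatives(state: SystemState, params: ParameterSet,
                ss_value: float, spec: NetworkSpec | None = None) -> np.ndarray:
    """Right-hand side ts_i * (F_i - X_i) at the given state."""
    spec = spec or NetworkSpec()
    w = net_input(state, params, ss_value)
    f = sigmoid_activity(w, spec.sigma)
    ts = np.array([params[k] for k in TIMESCALE_NAMES])
    return ts * (f - state.x)


def jacobian(x: np.ndarray, params: ParameterSet, ss_value: float,
             spec: NetworkSpec | None = None) -> np.ndarray:
    """Analytic Jacobian of the ODE: diag(ts) @ (diag(sigma F(1-F)) R - I)."""
    spec = spec or NetworkSpec()
    w = net_input(SystemState(x), params, ss_value)
    f = sigmoid_activity(w, spec.sigma)
    S = np.diag(spec.sigma * f * (1.0 - f))
    ts = np.array([params[k] for k in TIMESCALE_NAMES])
    return np.diag(ts) @ (S @ _regulatory_matrix(params) - np.eye(4))


def _segments(t0: float, t1: float, base: np.ndarray,
              stress: StepSignal | None,
              overlay: ParameterOverlay | None):
    """Split [t0, t1] at every stress/overlay breakpoint."""
    pts = {t0, t1}
    if stress is not None:
        pts.update(b for b in stress.finite_breakpoints() if t0 < b < t1)
    if overlay is not None:
        pts.update(b for b in overlay.breakpoints() if t0 < b < t1)
    bounds = np.array(sorted(pts))
    n_seg = bounds.size - 1
    seg_params = np.empty((n_seg, 16))
    seg_stress = np.empty(n_seg)
    for s in range(n_seg):
        tm = bounds[s]  # value on [bounds[s], bounds[s+1]) -- left endpoint
        seg_stress[s] = stress(tm) if stress is not None else 0.0
        seg_params[s] = overlay.apply(base, tm) if overlay is not None else base
        # relaxation rates are physically nonnegative; an overlay may not
        # drive them below zero
        seg_params[s, 12:16] = np.maximum(seg_params[s, 12:16], 0.0)
    return bounds, seg_params, seg_stress


def integrate(params: ParameterSet,
              spec: NetworkSpec | None = None,
              *,
              stress: StepSignal | None = None,
              overlay: ParameterOverlay | None = None,
              t_span: tuple[float, float] = (0.0, 100.0),
              x0: np.ndarray | None = None,
              dt_out: float = 0.1,
              atol: float = 1e-9,
              rtol: float = 1e-7) -> Trajectory:
    """Integrate the network ODE and sample it on a uniform grid.

    Stress and treatment overlays are piecewise-constant, so the run is split
    into segments of constant coefficients and each segment is integrated
    with an adaptive embedded Runge-Kutta (Dormand-Prince 4/5) scheme at the
    given tolerances; output points are forced integration stops, so sampled
    values carry full step accuracy.
    """
    spec = spec or NetworkSpec()
    t0, t1 = float(t_span[0]), float(t_span[1])
    if not t1 > t0:
        raise ValueError(f"need t1 > t0, got {t_span}")
    if not dt_out > 0:
        raise ValueError(f"dt_out must be > 0, got {dt_out}")
    if x0 is None:
        x0 = np.full(4, 0.1)
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (4,) or not np.all(np.isfinite(x0)):
        raise ValueError(f"x0 must be a finite 4-vector, got {x0}")

    n_out = int(round((t1 - t0) / dt_out))
    t_out = t0 + dt_out * np.arange(n_out + 1)
    if t_out[-1] > t1 + 1e-12:
        t_out = t_out[:-1]

    base = params.as_array()
    bounds, seg_params, seg_stress = _segments(t0, t1, base, stress, overlay)
    status, states = _kernels.integrate_piecewise(
        x0, bounds, seg_params, seg_stress, spec.sigma, t_out, atol, rtol)
    if status != _kernels.OK:
        reason = {_kernels.STEP_UNDERFLOW: "step-size underflow",
                  _kernels.NONFINITE: "non-finite state"}[status]
        raise IntegrationError(
            f"integration failed ({reason}) for parameters "
            f"{params.to_dict()}", params)
    ss_out = np.array([stress(t) for t in t_out]) if stress is not None \
        else np.zeros_like(t_out)
    return Trajectory(t_out, states, ss_out)


def _fixed_point_map(X: np.ndarray, vec: np.ndarray, ss: float,
                     sigma: float) -> np.ndarray:
    """F(W(X)) for a batch of states X of shape (n, 4)."""
    W = np.empty_like(X)
    W[:, 0] = vec[8] + vec[0] * ss + vec[1] * X[:, 0] + vec[2] * X[:, 3]
    W[:, 1] = vec[9] + vec[3] * X[:, 0] + vec[4] * X[:, 3]
    W[:, 2] = vec[10] + vec[5] * X[:, 1]
    W[:, 3] = vec[11] + vec[6] * X[:, 2] + vec[7] * X[:, 3]
    z = np.clip(sigma * W, -_kernels._EXP_CLAMP, _kernels._EXP_CLAMP)
    return 1.0 / (1.0 + np.exp(-z))


def find_fixed_points(params: ParameterSet,
                      spec: NetworkSpec | None = None,
                      ss_const: float = 0.0,
                      grid_n: int = 5,
                      *,
                      residual_tol: float = 1e-9,
                      dedup_tol: float = 1e-6) -> list[FixedPoint]:
    """Brute-force root search for X = F(W(X)) on [0, 1]^4.

    Newton iterations on G(X) = F(X) - X are seeded from a ``grid_n**4``
    lattice; converged roots are deduplicated within ``dedup_tol`` in the
    infinity norm and returned with stability from the analytic Jacobian of
    the ODE.  Because F maps the unit cube into itself, Brouwer's theorem
    guarantees at least one root -- an empty result indicates a numerical
    failure and raises.
    """
    spec = spec or NetworkSpec()
    if grid_n < 2:
        raise ValueError(f"grid_n must be >= 2, got {grid_n}")
    vec = params.as_array()
    sigma = spec.sigma
    R = _regulatory_matrix(params)

    g = np.linspace(0.0, 1.0, grid_n)
    X = np.stack(np.meshgrid(g, g, g, g, indexing="ij"), axis=-1).reshape(-1, 4)

    # picard pre-pass: plain iteration X <- F(X) pulls lattice points onto
    # the attracting fixed points even when sigma * weights are extreme
    Xp = X.copy()
    for _ in range(60):
        Xp = _fixed_point_map(Xp, vec, ss_const, sigma)
    X = np.vstack([X, Xp])

    eye = np.eye(4)

    def norms(Z):
        return np.abs(_fixed_point_map(Z, vec, ss_const, sigma) - Z).max(
            axis=1)

    done: list[np.ndarray] = []
    for _ in range(120):
        if len(X) == 0:
            break
        F = _fixed_point_map(X, vec, ss_const, sigma)
        G = F - X
        gn = np.abs(G).max(axis=1)
        conv = gn < residual_tol / 10
        if conv.any():
            done.append(X[conv])
            X, F, G, gn = X[~conv], F[~conv], G[~conv], gn[~conv]
            if len(X) == 0:
                break
        # Jacobian of G per seed: diag(sigma F (1-F)) @ R - I
        S = sigma * F * (1.0 - F)                       # (n, 4)
        J = S[:, :, None] * R[None, :, :] - eye[None]   # (n, 4, 4)
        try:
            step = np.linalg.solve(J, G[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            step = np.array([np.linalg.lstsq(Ji, Gi, rcond=None)[0]
                             for Ji, Gi in zip(J, G)])
        # damped update: backtrack seeds whose residual would grow
        lam = np.ones(len(X))
        Xn = np.clip(X - step, -0.2, 1.2)
        for _bt in range(6):
            worse = norms(Xn) > gn * (1.0 - 1e-4)
            if not worse.any():
                break
            lam[worse] *= 0.5
            Xn[worse] = np.clip(X[worse] - lam[worse, None] * step[worse],
                                -0.2, 1.2)
        X = Xn

    X = np.vstack(done + [X]) if done else X
    resid = norms(X)
    roots = X[resid < residual_tol]
    roots = roots[np.all((roots > -1e-9) & (roots < 1 + 1e-9), axis=1)]

    unique: list[np.ndarray] = []
    for r in roots:
        if not any(np.abs(r - u).max() < dedup_tol for u in unique):
            unique.append(r)
    if not unique:
        raise RuntimeError(
            "no fixed point found -- F maps [0,1]^4 into itself, so at least "
            "one must exist; this indicates a numerical bug")

    out = []
    for r in sorted(unique, key=lambda v: tuple(v)):
        lam = np.linalg.eigvals(jacobian(r, params, ss_const, spec))
        out.append(FixedPoint(x=r, stable=bool(np.max(lam.real) < 0),
                              eigenvalues=lam))
    return out
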