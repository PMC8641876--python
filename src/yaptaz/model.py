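"""Core ODE model of the Hippo-YAP/TAZ regulatory circuit.

The model tracks five species: LATS1/2 kinase (``L``), unphosphorylated
(active, nuclear) YAP/TAZ (``YT_up``), phosphorylated (inactive) YAP/TAZ
(``YT_p``), SIRT1 (``S``) and NOTCH (``N``).  Transcriptional regulation is
modelled with Hill functions; YAP/TAZ (de)phosphorylation with
Michaelis-Menten kinetics; basal production is constant and degradation
first-order.  Three feedback loops shape the dynamics:

* a YAP/TAZ -> LATS -| YAP/TAZ negative loop (homeostasis),
* a YAP/TAZ <-> SIRT1 positive loop (lower, degeneration switch),
* a YAP/TAZ <-> NOTCH positive loop (upper, tumorigenesis switch).

Because SIRT1, NOTCH and phosphorylated YAP/TAZ relax quickly to algebraic
steady states, the five-variable system reduces to a two-variable system in
``(L, YT_up)`` that is used for all phase-plane and bifurcation work.

Concentrations and time are in arbitrary units throughout; no unit
conversion layer is provided.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import Iterable, Literal, NamedTuple, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "PARAM_NAMES",
    "ParameterSet",
    "FullState",
    "ReducedState",
    "QssValues",
    "Trajectory",
    "hill_activation",
    "full_rhs",
    "qss_values",
    "reduced_rhs",
    "integrate",
    "state_bounds",
]

#: Canonical parameter order used in files, CSV exports and arrays.
PARAM_NAMES = (
    "kL1", "kL2", "kL3",
    "kYTup0", "kYTup1", "kYTup2", "kYTup3", "kYTup4", "kYTup5",
    "kYTp1",
    "kS1", "kS2", "kS3",
    "kN1", "kN2", "kN3",
    "JL", "JYTup1", "JYTup2", "JYTup3", "JYTup4", "JS", "JN",
    "n",
)


@dataclass(frozen=True)
class ParameterSet:
    """Rate constants, half-saturation constants and the Hill exponent.

    All rates and thresholds must be strictly positive; the Hill exponent
    ``n`` (shared by every Hill term) must be >= 1.
    """

    kL1: float      # basal LATS production
    kL2: float      # YT_up-driven LATS production
    kL3: float      # LATS degradation
    kYTup0: float   # basal YT_up production (the bifurcation parameter)
    kYTup1: float   # SIRT1-driven YT_up production
    kYTup2: float   # NOTCH-driven YT_up production
    kYTup3: float   # LATS-mediated phosphorylation rate
    kYTup4: float   # dephosphorylation rate
    kYTup5: float   # YT_up degradation
    kYTp1: float    # YT_p degradation
    kS1: float      # basal SIRT1 production
    kS2: float      # YT_up-driven SIRT1 production
    kS3: float      # SIRT1 degradation
    kN1: float      # basal NOTCH production
    kN2: float      # YT_up-driven NOTCH production
    kN3: float      # NOTCH degradation
    JL: float       # Hill threshold, YT_up -> LATS
    JYTup1: float   # Hill threshold, SIRT1 -> YT_up
    JYTup2: float   # Hill threshold, NOTCH -> YT_up
    JYTup3: float   # Michaelis constant, phosphorylation
    JYTup4: float   # Michaelis constant, dephosphorylation
    JS: float       # Hill threshold, YT_up -> SIRT1
    JN: float       # Hill threshold, YT_up -> NOTCH
    n: float        # Hill exponent (shared)

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValueError(f"parameter {f.name} is not finite: {v!r}")
            if f.name == "n":
                if v < 1:
                    raise ValueError(f"Hill exponent n must be >= 1, got {v}")
            elif f.name == "kYTup0":
                # the swept parameter may legitimately go negative during
                # continuation (folds can sit at negative basal production)
                pass
            elif v <= 0:
                raise ValueError(f"parameter {f.name} must be > 0, got {v}")

    def replace(self, **kwargs: float) -> "ParameterSet":
        """Return a copy with the given parameters replaced."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in PARAM_NAMES}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "ParameterSet":
        unknown = set(d) - set(PARAM_NAMES)
        if unknown:
            raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
        missing = set(PARAM_NAMES) - set(d)
        if missing:
            raise KeyError(f"missing parameter(s): {sorted(missing)}")
        return cls(**{k: float(v) for k, v in d.items()})


class FullState(NamedTuple):
    """Concentrations of the five model species."""

    L: float
    YT_up: float
    YT_p: float
    S: float
    N: float


class ReducedState(NamedTuple):
    """Concentrations of the two slow species of the reduced system."""

    L: float
    YT_up: float


class QssValues(NamedTuple):
    """Quasi-steady-state concentrations of the three fast species."""

    S_star: float
    N_star: float
    YTp_star: float


def _check_nonneg(y: np.ndarray, label: str) -> None:
    if np.any(np.asarray(y) < 0):
        raise ValueError(f"{label} has negative component(s): {np.asarray(y)}")


def hill_activation(x, J, n):
    """Activating Hill function ``x**n / (x**n + J**n)``.

    Strictly increasing in ``x``, equals 0.5 at ``x == J``.  The repressing
    form is ``1 - hill_activation(x, J, n)``.  Accepts scalars or arrays in
    ``x``.
    """
    x = np.asarray(x, dtype=float)
    if np.any(np.asarray(J) <= 0):
        raise ValueError(f"Hill threshold J must be > 0, got {J}")
    if np.any(np.asarray(n) < 1):
        raise ValueError(f"Hill exponent n must be >= 1, got {n}")
    if np.any(x < 0):
        raise ValueError("Hill input x must be >= 0")
    xn = x ** n
    out = xn / (xn + J ** n)
    return out if out.ndim else float(out)


def _phospho_rate(YT_up, L, p: ParameterSet):
    """Michaelis-Menten phosphorylation flux kYTup3 * YT_up * L / (YT_up + JYTup3)."""
    return p.kYTup3 * YT_up * L / (YT_up + p.JYTup3)


def full_rhs(state, params: ParameterSet) -> np.ndarray:
    """Time derivatives (dL, dYT_up, dYT_p, dS, dN) of the five-species model."""
    y = np.asarray(state, dtype=float)
    if y.shape != (5,):
        raise ValueError(f"full state must have 5 components, got shape {y.shape}")
    _check_nonneg(y, "state")
    L, YT_up, YT_p, S, N = y
    p = params
    phos = _phospho_rate(YT_up, L, p)
    dephos = p.kYTup4 * YT_p / (YT_p + p.JYTup4)
    dL = p.kL1 + p.kL2 * hill_activation(YT_up, p.JL, p.n) - p.kL3 * L
    dYT_up = (
        p.kYTup0
        + p.kYTup1 * hill_activation(S, p.JYTup1, p.n)
        + p.kYTup2 * hill_activation(N, p.JYTup2, p.n)
        - phos
        + dephos
        - p.kYTup5 * YT_up
    )
    dYT_p = phos - dephos - p.kYTp1 * YT_p
    dS = p.kS1 + p.kS2 * hill_activation(YT_up, p.JS, p.n) - p.kS3 * S
    dN = p.kN1 + p.kN2 * hill_activation(YT_up, p.JN, p.n) - p.kN3 * N
    return np.array([dL, dYT_up, dYT_p, dS, dN])


def _ytp_star(phos, p: ParameterSet):
    """Positive root of the YT_p steady-state quadratic, given the phosphorylation flux.

    kYTp1*Yp^2 + (kYTup4 + kYTp1*JYTup4 - phos)*Yp - phos*JYTup4 = 0.
    The closed form is used except when the discriminant underflows toward
    zero, where a bisection fallback avoids catastrophic cancellation.
    """
    b = p.kYTup4 + p.kYTp1 * p.JYTup4 - phos
    disc = b * b + 4.0 * p.kYTp1 * phos * p.JYTup4
    root = (-b + np.sqrt(np.maximum(disc, 0.0))) / (2.0 * p.kYTp1)
    if np.ndim(root) == 0:
        if disc < 1e-12:
            return _ytp_star_bisect(float(phos), p)
        return float(root)
    bad = disc < 1e-12
    if np.any(bad):
        flat = np.atleast_1d(root)
        for i in np.flatnonzero(np.atleast_1d(bad)):
            flat[i] = _ytp_star_bisect(float(np.atleast_1d(phos)[i]), p)
        root = flat.reshape(np.shape(root))
    return root


def _ytp_star_bisect(phos: float, p: ParameterSet) -> float:
    if phos <= 0:
        return 0.0

    def resid(yp: float) -> float:
        return phos - p.kYTup4 * yp / (yp + p.JYTup4) - p.kYTp1 * yp

    hi = phos / p.kYTp1 + 1.0
    while resid(hi) > 0:
        hi *= 2.0
    return brentq(resid, 0.0, hi, xtol=1e-14)


def qss_values(YT_up, L, params: ParameterSet):
    """Quasi-steady-state (S*, N*, YTp*) of the fast species at fixed (YT_up, L).

    Substituting the triple into the full system zeroes the dS, dN and dYT_p
    components exactly.  Vectorised over ``YT_up``/``L``.
    """
    p = params
    YT_up = np.asarray(YT_up, dtype=float)
    L = np.asarray(L, dtype=float)
    if np.any(YT_up < 0) or np.any(L < 0):
        raise ValueError("YT_up and L must be >= 0")
    S_star = (p.kS1 + p.kS2 * hill_activation(YT_up, p.JS, p.n)) / p.kS3
    N_star = (p.kN1 + p.kN2 * hill_activation(YT_up, p.JN, p.n)) / p.kN3
    YTp_star = _ytp_star(_phospho_rate(YT_up, L, p), p)
    if np.ndim(YT_up) == 0 and np.ndim(L) == 0:
        return QssValues(float(S_star), float(N_star), float(YTp_star))
    return S_star, N_star, YTp_star


def reduced_rhs(state, params: ParameterSet) -> np.ndarray:
    """Time derivatives (dL, dYT_up) of the two-variable reduced system."""
    y = np.asarray(state, dtype=float)
    if y.shape != (2,):
        raise ValueError(f"reduced state must have 2 components, got shape {y.shape}")
    _check_nonneg(y, "state")
    L, YT_up = y
    dL, dYT_up = reduced_rhs_components(L, YT_up, params)
    return np.array([float(dL), float(dYT_up)])


def reduced_rhs_components(L, YT_up, params: ParameterSet):
    """Vectorised reduced derivatives; no domain checks (internal fast path)."""
    p = params
    S_star = (p.kS1 + p.kS2 * hill_activation(YT_up, p.JS, p.n)) / p.kS3
    N_star = (p.kN1 + p.kN2 * hill_activation(YT_up, p.JN, p.n)) / p.kN3
    phos = _phospho_rate(YT_up, L, p)
    YTp_star = _ytp_star(phos, p)
    dL = p.kL1 + p.kL2 * hill_activation(YT_up, p.JL, p.n) - p.kL3 * L
    dYT_up = (
        p.kYTup0
        + p.kYTup1 * hill_activation(S_star, p.JYTup1, p.n)
        + p.kYTup2 * hill_activation(N_star, p.JYTup2, p.n)
        - phos
        + p.kYTup4 * YTp_star / (YTp_star + p.JYTup4)
        - p.kYTup5 * YT_up
    )
    return dL, dYT_up


def state_bounds(params: ParameterSet, margin: float = 1.5) -> tuple[float, float]:
    """Upper bounds (B_L, B_YT) on reachable L and YT_up, times ``margin``.

    Every production term is bounded above and degradation is linear, so
    trajectories and equilibria live inside [0, B_L] x [0, B_YT].
    """
    p = params
    B_L = (p.kL1 + p.kL2) / p.kL3 * margin
    prod = max(p.kYTup0, 0.0) + p.kYTup1 + p.kYTup2 + p.kYTup4
    B_YT = prod / p.kYTup5 * margin
    return B_L, B_YT


@dataclass
class Trajectory:
    """A time grid with aligned states (columns ordered as in the header)."""

    times: np.ndarray
    states: np.ndarray  # shape (len(times), n_species)
    columns: tuple[str, ...]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")
        if self.states.shape != (self.times.size, len(self.columns)):
            raise ValueError("states shape does not match times/columns")

    @property
    def terminal(self) -> np.ndarray:
        return self.states[-1]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            np.column_stack([self.times, self.states]),
            columns=("t",) + self.columns,
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


FULL_COLUMNS = ("L", "YT_up", "YT_p", "S", "N")
REDUCED_COLUMNS = ("L", "YT_up")


def integrate(
    state0: Sequence[float],
    params: ParameterSet,
    t_end: float,
    which: Literal["full", "reduced"] = "full",
    t_eval: Iterable[float] | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the full or reduced system from ``state0`` to ``t_end``.

    Uses an adaptive stiff-capable solver (LSODA).  Raises ``RuntimeError``
    with the solver diagnostic on failure.  Negative initial states are
    rejected, never clamped.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    y0 = np.asarray(state0, dtype=float)
    _check_nonneg(y0, "initial state")
    if which == "full":
        if y0.shape != (5,):
            raise ValueError("full initial state needs 5 components")
        fun = lambda t, y: full_rhs(np.maximum(y, 0.0), params)
        columns = FULL_COLUMNS
    elif which == "reduced":
        if y0.shape != (2,):
            raise ValueError("reduced initial state needs 2 components")
        fun = lambda t, y: np.asarray(
            reduced_rhs_components(max(y[0], 0.0), max(y[1], 0.0), params)
        )
        columns = REDUCED_COLUMNS
    else:
        raise ValueError(f"unknown system {which!r}")
    t_eval_arr = None if t_eval is None else np.asarray(list(t_eval), dtype=float)
    sol = solve_ivp(
        fun,
        (0.0, float(t_end)),
        y0,
        method="LSODA",
        rtol=rtol,
        atol=atol,
        t_eval=t_eval_arr,
        dense_output=False,
    )
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    times, states = sol.t, sol.y.T
    if times[0] > 0.0 and t_eval is None:
        pass
    # solver round-off can produce tiny negative excursions; they are within
    # atol of zero and clipped for the stored trajectory
    states = np.maximum(states, 0.0)
    if times.size > 1 and np.any(np.diff(times) <= 0):
        keep = np.concatenate([[True], np.diff(times) > 0])
        times, states = times[keep], states[keep]
    return Trajectory(times=times, states=states, columns=columns)
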