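"""Steady states, stability, and saddle-node bifurcation analysis.

The reduced system has an explicit L-nullcline ``L = (kL1 + kL2*H(Y))/kL3``,
so every equilibrium is a root of the scalar residual

    g(Y) = dYT_up/dt evaluated at (L_null(Y), Y).

``find_steady_states`` exploits this: it scans ``g`` on a dense YT_up grid,
refines each sign change by Brent's method, and classifies stability from
the eigenvalues of the two-variable Jacobian.  ``brute_force_root_census``
is a structurally independent check that works on the full 2-D grid with
Newton refinement and never uses the 1-D reduction.

Bifurcation diagrams are traced by a dense parameter sweep with
nearest-neighbour branch linking; fold (saddle-node) positions are refined
by bisection on the swept parameter.  The four folds of the basal
YAP/TAZ-production diagram are named by the convention

* SN1 — left end of the homeostatic branch (homeostasis lost downward),
* SN2 — right end of the degenerative branch,
* SN3 — right end of the homeostatic branch (jump to tumorigenic),
* SN4 — left end of the tumorigenic branch (recovery threshold).

so SN1 < SN2 bound the lower (degeneration) switch and SN4 < SN3 the upper
(tumorigenesis) switch; tristability occurs when SN4 < SN2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .model import (
    ParameterSet,
    ReducedState,
    hill_activation,
    reduced_rhs,
    reduced_rhs_components,
    state_bounds,
)

logger = logging.getLogger(__name__)

__all__ = [
    "EquilibriumPoint",
    "SaddleNodeSet",
    "Branch",
    "BifurcationDiagram",
    "REGIME_LABELS",
    "find_steady_states",
    "brute_force_root_census",
    "sweep_bifurcation",
    "classify_regime",
    "trace_sn_curves",
]

STABLE_TOL = 1e-8

BRANCH_LABELS = ("degenerative", "homeostatic", "tumorigenic")

REGIME_LABELS = (
    "mono_degenerative",
    "bistable_HD",
    "mono_homeostatic",
    "bistable_HT",
    "mono_tumorigenic",
    "tristable",
)


@dataclass(frozen=True)
class EquilibriumPoint:
    """A root of the reduced vector field with its stability classification."""

    state: ReducedState
    stability: str  # stable | unstable | marginal
    eigenvalues: tuple[complex, complex]
    branch_label: str | None = None

    def with_label(self, label: str) -> "EquilibriumPoint":
        return EquilibriumPoint(self.state, self.stability, self.eigenvalues, label)


@dataclass
class SaddleNodeSet:
    """Swept-parameter values of the four folds; ``None`` when absent."""

    SN1: float | None = None
    SN2: float | None = None
    SN3: float | None = None
    SN4: float | None = None

    def to_dict(self) -> dict[str, float | None]:
        return {k: getattr(self, k) for k in ("SN1", "SN2", "SN3", "SN4")}

    def count(self) -> int:
        return sum(v is not None for v in self.to_dict().values())


@dataclass
class Branch:
    """A continuation branch: aligned parameter values and equilibria."""

    param_values: list[float] = field(default_factory=list)
    points: list[EquilibriumPoint] = field(default_factory=list)
    label: str | None = None

    @property
    def stability(self) -> str:
        # folds aside, stability is constant along a branch
        return self.points[len(self.points) // 2].stability

    @property
    def k_min(self) -> float:
        return self.param_values[0]

    @property
    def k_max(self) -> float:
        return self.param_values[-1]

    def y_at(self, k: float) -> float:
        return float(np.interp(k, self.param_values, [p.state.YT_up for p in self.points]))

    def covers(self, k: float) -> bool:
        return self.k_min - 1e-12 <= k <= self.k_max + 1e-12


@dataclass
class BifurcationDiagram:
    """One-parameter bifurcation diagram of the reduced system."""

    swept_parameter: str
    params: ParameterSet
    branches: list[Branch]
    saddle_nodes: SaddleNodeSet
    param_range: tuple[float, float]

    def stable_branches_at(self, k: float) -> list[Branch]:
        return [
            b
            for b in self.branches
            if b.stability == "stable" and b.covers(k)
        ]

    def unstable_y_at(self, k: float) -> list[float]:
        return sorted(
            b.y_at(k)
            for b in self.branches
            if b.stability == "unstable" and b.covers(k)
        )

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for i, b in enumerate(self.branches):
            for k, pt in zip(b.param_values, b.points):
                rows.append(
                    (k, i, b.label or "", pt.state.L, pt.state.YT_up, pt.stability)
                )
        return pd.DataFrame(
            rows,
            columns=["param_value", "branch_id", "branch_label", "L", "YT_up", "stability"],
        )


# ---------------------------------------------------------------------------
# root finding


def _l_nullcline(Y, p: ParameterSet):
    return (p.kL1 + p.kL2 * hill_activation(Y, p.JL, p.n)) / p.kL3


def _g_residual(Y, p: ParameterSet):
    """dYT_up/dt along the L-nullcline (scalar equilibrium residual)."""
    _, dY = reduced_rhs_components(_l_nullcline(Y, p), Y, p)
    return dY


def reduced_jacobian(state: Sequence[float], p: ParameterSet, eps: float = 1e-6) -> np.ndarray:
    """Central-difference Jacobian of the reduced vector field."""
    x = np.asarray(state, dtype=float)
    J = np.empty((2, 2))
    for j in range(2):
        h = eps * max(1.0, abs(x[j]))
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] = max(xm[j] - h, 0.0)
        fp = np.asarray(reduced_rhs_components(xp[0], xp[1], p))
        fm = np.asarray(reduced_rhs_components(xm[0], xm[1], p))
        J[:, j] = (fp - fm) / (xp[j] - xm[j])
    return J


def _classify(state: Sequence[float], p: ParameterSet) -> EquilibriumPoint:
    eig = np.linalg.eigvals(reduced_jacobian(state, p))
    mx = float(np.max(eig.real))
    if mx < -STABLE_TOL:
        stability = "stable"
    elif mx > STABLE_TOL:
        stability = "unstable"
    else:
        stability = "marginal"
    return EquilibriumPoint(
        state=ReducedState(float(state[0]), float(state[1])),
        stability=stability,
        eigenvalues=(complex(eig[0]), complex(eig[1])),
    )


def _dedupe(ys: list[float], tol: float = 1e-6) -> list[float]:
    out: list[float] = []
    for y in sorted(ys):
        if not out or abs(y - out[-1]) > tol:
            out.append(y)
    return out


def _root_ys(p: ParameterSet, y_max: float, resolution: int) -> list[float]:
    """YT_up coordinates of all equilibria in [0, y_max] via the 1-D residual."""
    grid = np.linspace(0.0, y_max, resolution)
    g = np.asarray(_g_residual(grid, p))
    roots: list[float] = []
    for i in range(resolution - 1):
        a, b = g[i], g[i + 1]
        if a == 0.0:
            roots.append(float(grid[i]))
        elif a * b < 0:
            roots.append(
                float(brentq(lambda y: _g_residual(y, p), grid[i], grid[i + 1], xtol=1e-14))
            )
    if g[-1] == 0.0:
        roots.append(float(grid[-1]))
    return _dedupe(roots)


def find_steady_states(
    params: ParameterSet,
    box: tuple[tuple[float, float], tuple[float, float]] | None = None,
    resolution: int = 2000,
) -> list[EquilibriumPoint]:
    """All equilibria of the reduced system, with stability classification.

    ``box`` is ``((L_min, L_max), (Y_min, Y_max))``; by default the analytic
    production/degradation bounds (x 1.5) guarantee every reachable root is
    inside.  Duplicate roots within state distance 1e-6 are merged.
    """
    if resolution < 50:
        raise ValueError("resolution must be >= 50")
    B_L, B_YT = state_bounds(params)
    if box is None:
        box = ((0.0, B_L), (0.0, B_YT))
    (l_lo, l_hi), (y_lo, y_hi) = box
    if l_hi <= l_lo or y_hi <= y_lo:
        raise ValueError("box must be a non-degenerate rectangle")
    out = []
    for y in _root_ys(params, min(y_hi, B_YT), resolution):
        L = float(_l_nullcline(y, params))
        if l_lo - 1e-12 <= L <= l_hi + 1e-12 and y_lo - 1e-12 <= y <= y_hi + 1e-12:
            out.append(_classify((L, y), params))
    return out


def brute_force_root_census(
    params: ParameterSet,
    box: tuple[tuple[float, float], tuple[float, float]] | None = None,
    fine_resolution: int = 400,
) -> list[ReducedState]:
    """Independent equilibrium census: dense 2-D grid + Newton refinement.

    Enumerates grid cells where both residual components change sign and
    polishes each candidate by damped 2-D Newton iteration.  Slower than
    :func:`find_steady_states` and structurally independent of it (no use of
    the explicit L-nullcline); intended as a verification oracle.
    """
    if fine_resolution < 100:
        raise ValueError("fine_resolution must be >= 100")
    if box is None:
        B_L, B_YT = state_bounds(params)
        box = ((0.0, B_L), (0.0, B_YT))
    (l_lo, l_hi), (y_lo, y_hi) = box
    Ls = np.linspace(l_lo, l_hi, fine_resolution)
    Ys = np.linspace(y_lo, y_hi, fine_resolution)
    Lg, Yg = np.meshgrid(Ls, Ys, indexing="ij")
    dL, dY = reduced_rhs_components(Lg, Yg, params)
    dL, dY = np.asarray(dL), np.asarray(dY)

    def sign_change(f: np.ndarray) -> np.ndarray:
        s = np.sign(f)
        cell = np.zeros((fine_resolution - 1, fine_resolution - 1), dtype=bool)
        for di in (0, 1):
            for dj in (0, 1):
                corner = s[di : di + fine_resolution - 1, dj : dj + fine_resolution - 1]
                cell |= corner != s[:-1, :-1]
        return cell

    candidates = np.argwhere(sign_change(dL) & sign_change(dY))
    roots: list[tuple[float, float]] = []
    for i, j in candidates:
        x = np.array([(Ls[i] + Ls[i + 1]) / 2, (Ys[j] + Ys[j + 1]) / 2])
        ok = False
        for _ in range(60):
            f = np.asarray(reduced_rhs_components(x[0], x[1], params), dtype=float)
            if np.linalg.norm(f) < 1e-12:
                ok = True
                break
            J = reduced_jacobian(x, params)
            try:
                step = np.linalg.solve(J, f)
            except np.linalg.LinAlgError:
                break
            # damp steps so Newton stays in the admissible quadrant
            scale = 1.0
            while np.any(x - scale * step < 0) and scale > 1e-6:
                scale /= 2
            x = x - scale * step
        if ok and l_lo - 1e-9 <= x[0] <= l_hi + 1e-9 and y_lo - 1e-9 <= x[1] <= y_hi + 1e-9:
            roots.append((float(x[0]), float(x[1])))
    merged: list[tuple[float, float]] = []
    for r in sorted(roots, key=lambda t: t[1]):
        if not merged or np.hypot(r[0] - merged[-1][0], r[1] - merged[-1][1]) > 1e-6:
            merged.append(r)
    return [ReducedState(*r) for r in merged]


# ---------------------------------------------------------------------------
# one-parameter sweeps


def _census_ys(p: ParameterSet, base: ParameterSet, resolution: int = 1200) -> list[float]:
    """Root YT_up values using the *baseline* state bounds (sweep-stable box)."""
    _, B_YT = state_bounds(base)
    return _root_ys(p, B_YT, resolution)


def _pair_exists(p: ParameterSet, base: ParameterSet, y_lo: float, y_hi: float) -> bool:
    """True if at least two roots remain inside the merging window [y_lo, y_hi]."""
    ys = _census_ys(p, base)
    return sum(1 for y in ys if y_lo <= y <= y_hi) >= 2


def _refine_fold(
    params: ParameterSet,
    swept: str,
    base: ParameterSet,
    k_exists: float,
    k_gone: float,
    y_window: tuple[float, float],
    tol: float = 1e-9,
) -> float:
    """Bisect the swept parameter between a step where a root pair exists and
    one where it has vanished; returns the fold position."""
    lo, hi = k_exists, k_gone
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if abs(hi - lo) < tol:
            break
        if _pair_exists(params.replace(**{swept: mid}), base, *y_window):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _align_monotone(
    prev_y: list[float],
    prev_stab: list[str],
    new_y: list[float],
    new_stab: list[str],
    span: float,
) -> list[tuple[int, int]]:
    """Order-preserving minimum-cost matching of two sorted root lists.

    Roots of the scalar equilibrium residual cannot cross in YT_up between
    nearby parameter values; folds create or destroy *adjacent* pairs.  The
    alignment therefore only needs monotone matchings: dynamic programme
    with a skip cost, stability-mismatch and large jumps forbidden.
    """
    skip = 0.08 * span
    max_jump = 0.30 * span
    n, m = len(prev_y), len(new_y)
    INF = float("inf")
    cost = np.full((n + 1, m + 1), INF)
    cost[0, 0] = 0.0
    choice = np.zeros((n + 1, m + 1), dtype=np.int8)  # 1: skip prev, 2: skip new, 3: match
    for i in range(n + 1):
        for j in range(m + 1):
            c = cost[i, j]
            if c == INF:
                continue
            if i < n and c + skip < cost[i + 1, j]:
                cost[i + 1, j] = c + skip
                choice[i + 1, j] = 1
            if j < m and c + skip < cost[i, j + 1]:
                cost[i, j + 1] = c + skip
                choice[i, j + 1] = 2
            if i < n and j < m and prev_stab[i] == new_stab[j]:
                d = abs(prev_y[i] - new_y[j])
                if d < max_jump and c + d < cost[i + 1, j + 1]:
                    cost[i + 1, j + 1] = c + d
                    choice[i + 1, j + 1] = 3
    matches = []
    i, j = n, m
    while i > 0 or j > 0:
        ch = choice[i, j]
        if ch == 3:
            matches.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif ch == 1:
            i -= 1
        else:
            j -= 1
    return matches[::-1]


def _link_branches(
    ks: np.ndarray, censuses: list[list[EquilibriumPoint]], y_scale: float
) -> list[Branch]:
    """Continuation of equilibria across sweep steps by monotone alignment."""
    span = max(
        (max((p.state.YT_up for pts in censuses for p in pts), default=1.0)), 1e-6
    )
    branches: list[Branch] = []
    active: list[Branch] = []  # sorted by current YT_up
    for k, pts in zip(ks, censuses):
        pts = sorted(pts, key=lambda p: p.state.YT_up)  # tie-break: smaller YT_up first
        prev_y = [b.points[-1].state.YT_up for b in active]
        prev_s = [b.points[-1].stability for b in active]
        new_y = [p.state.YT_up for p in pts]
        new_s = [p.stability for p in pts]
        matches = _align_monotone(prev_y, prev_s, new_y, new_s, span)
        matched_prev = {i for i, _ in matches}
        matched_new = {j for _, j in matches}
        next_active: list[Branch] = []
        for i, j in matches:
            b = active[i]
            b.param_values.append(float(k))
            b.points.append(pts[j])
            next_active.append(b)
        for i, b in enumerate(active):
            if i not in matched_prev:
                branches.append(b)
        for j, pt in enumerate(pts):
            if j not in matched_new:
                next_active.append(Branch(param_values=[float(k)], points=[pt]))
        active = sorted(next_active, key=lambda b: b.points[-1].state.YT_up)
    branches.extend(active)
    return [b for b in branches if len(b.points) >= 2]


def _label_stable_branches(branches: list[Branch]) -> None:
    """Assign degenerative/homeostatic/tumorigenic by YT_up ordering.

    Stable branches are ranked by their YT_up level wherever they overlap in
    the swept parameter (falling back to overall mean level); lowest ->
    degenerative, highest -> tumorigenic, middle -> homeostatic.  Unstable
    branches get the generic ``unstable_branch`` label.
    """
    stable = [b for b in branches if b.stability == "stable"]
    for b in branches:
        if b.stability != "stable":
            b.label = "unstable_branch"
            for i, pt in enumerate(b.points):
                b.points[i] = pt.with_label("unstable_branch")

    def mean_y(b: Branch) -> float:
        return float(np.mean([p.state.YT_up for p in b.points]))

    stable.sort(key=mean_y)
    if len(stable) == 1:
        labels = ["homeostatic"]
    elif len(stable) == 2:
        # decide whether the pair is (deg, homeo) or (homeo, tumor) by which
        # side of the sweep each branch occupies
        if stable[0].k_min <= stable[1].k_min:
            labels = ["degenerative", "homeostatic"]
        else:
            labels = ["homeostatic", "tumorigenic"]
    else:
        labels = ["degenerative"] + ["homeostatic"] * (len(stable) - 2) + ["tumorigenic"]
    for b, lab in zip(stable, labels):
        b.label = lab
        for i, pt in enumerate(b.points):
            b.points[i] = pt.with_label(lab)


def sweep_bifurcation(
    params: ParameterSet,
    swept: str = "kYTup0",
    sweep_range: tuple[float, float] = (-0.005, 0.03),
    steps: int = 400,
    resolution: int = 1200,
) -> BifurcationDiagram:
    """Trace the one-parameter bifurcation diagram over ``swept``.

    The range may extend to negative values of the basal production rate:
    some perturbations push the tumorigenic recovery fold (SN4) below zero,
    which is exactly the irreversibility signature and must not be lost.
    """
    if steps < 50:
        raise ValueError("steps must be >= 50")
    lo, hi = sweep_range
    ks = np.linspace(lo, hi, steps)
    _, B_YT = state_bounds(params)
    censuses: list[list[EquilibriumPoint]] = []
    for k in ks:
        p_k = params.replace(**{swept: float(k)})
        pts = [
            _classify((_l_nullcline(y, p_k), y), p_k)
            for y in _root_ys(p_k, B_YT, resolution)
        ]
        censuses.append(pts)
    branches = _link_branches(ks, censuses, y_scale=B_YT)

    # refine branch endpoints that terminate inside the sweep range: each is a fold
    step_h = ks[1] - ks[0]
    for b in branches:
        if b.stability != "stable":
            continue
        for side, k_end, y_end in (
            ("left", b.k_min, b.points[0].state.YT_up),
            ("right", b.k_max, b.points[-1].state.YT_up),
        ):
            interior = (side == "left" and k_end > lo + 1.5 * step_h) or (
                side == "right" and k_end < hi - 1.5 * step_h
            )
            if not interior:
                continue
            k_gone = k_end - step_h if side == "left" else k_end + step_h
            window = (max(y_end - 0.2 * B_YT, 0.0), y_end + 0.2 * B_YT)
            p_sweep = params
            fold = _refine_fold(p_sweep, swept, params, k_end, k_gone, window)
            if side == "left":
                b.param_values[0] = fold
            else:
                b.param_values[-1] = fold

    _label_stable_branches(branches)
    sns = SaddleNodeSet()
    for b in branches:
        if b.stability != "stable":
            continue
        left_interior = b.k_min > lo + 1.5 * step_h
        right_interior = b.k_max < hi - 1.5 * step_h
        if b.label == "homeostatic":
            if left_interior:
                sns.SN1 = b.k_min
            if right_interior:
                sns.SN3 = b.k_max
        elif b.label == "degenerative" and right_interior:
            sns.SN2 = b.k_max
        elif b.label == "tumorigenic" and left_interior:
            sns.SN4 = b.k_min
    return BifurcationDiagram(
        swept_parameter=swept,
        params=params,
        branches=branches,
        saddle_nodes=sns,
        param_range=(float(lo), float(hi)),
    )


def detect_folds_1d(
    residual,
    y_range: tuple[float, float],
    a_range: tuple[float, float],
    steps: int = 400,
    resolution: int = 1200,
    tol: float = 1e-7,
) -> list[float]:
    """Fold positions of a scalar family ``residual(y, a) = 0``.

    Generic core of the sweep machinery: scans the parameter ``a``, counts
    roots of the residual in ``y`` on a dense grid, and refines every change
    in the root count by bisection.  Returns the sorted parameter values at
    which roots appear or disappear (saddle-node folds for a smooth family).
    """
    y_lo, y_hi = y_range
    grid = np.linspace(y_lo, y_hi, resolution)

    def count(a: float) -> int:
        g = np.asarray(residual(grid, a))
        s = np.sign(g)
        return int(np.sum(s[:-1] != s[1:]))

    a_vals = np.linspace(*a_range, steps)
    counts = [count(a) for a in a_vals]
    folds = []
    for i in range(steps - 1):
        if counts[i] == counts[i + 1]:
            continue
        lo, hi, c_lo = a_vals[i], a_vals[i + 1], counts[i]
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if count(mid) == c_lo:
                lo = mid
            else:
                hi = mid
        folds.append(0.5 * (lo + hi))
    return sorted(folds)


def classify_regime(diagram: BifurcationDiagram, at_value: float) -> str:
    """Dynamical regime at a swept-parameter value, from the stable branches present."""
    lo, hi = diagram.param_range
    if not (lo <= at_value <= hi):
        raise ValueError(f"{at_value} outside diagram range {diagram.param_range}")
    labels = sorted({b.label for b in diagram.stable_branches_at(at_value)})
    key = frozenset(labels)
    mapping = {
        frozenset({"degenerative"}): "mono_degenerative",
        frozenset({"degenerative", "homeostatic"}): "bistable_HD",
        frozenset({"homeostatic"}): "mono_homeostatic",
        frozenset({"homeostatic", "tumorigenic"}): "bistable_HT",
        frozenset({"tumorigenic"}): "mono_tumorigenic",
        frozenset({"degenerative", "homeostatic", "tumorigenic"}): "tristable",
        frozenset({"degenerative", "tumorigenic"}): "bistable_DT",
    }
    if key not in mapping:
        raise ValueError(f"no stable branch covers {at_value}")
    return mapping[key]


def trace_sn_curves(
    params: ParameterSet,
    second_param: str,
    second_range: tuple[float, float],
    steps: int = 21,
    fold_param: str = "kYTup0",
    fold_range: tuple[float, float] = (-0.01, 0.04),
    fold_steps: int = 300,
) -> "pd.DataFrame":
    """Two-parameter saddle-node curves in the (second_param, fold_param) plane.

    Reruns the one-parameter sweep at each grid value of ``second_param`` and
    records the four fold positions (NaN where a fold is absent).  The output
    supports locating the SN2/SN4 crossing that bounds the tristable region.
    """
    import pandas as pd

    if steps < 2:
        raise ValueError("steps must be >= 2")
    rows = []
    for v in np.linspace(*second_range, steps):
        p = params.replace(**{second_param: float(v)})
        diag = sweep_bifurcation(p, swept=fold_param, sweep_range=fold_range, steps=fold_steps)
        sns = diag.saddle_nodes.to_dict()
        rows.append(
            {second_param: float(v)}
            | {k: (np.nan if x is None else x) for k, x in sns.items()}
        )
    return pd.DataFrame(rows)
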