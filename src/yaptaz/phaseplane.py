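"""Nullclines, vector fields and trajectory sampling in the (L, YT_up) plane.

Equilibria sit at nullcline intersections: the L-nullcline has the explicit
closed form ``L = (kL1 + kL2*H(YT_up)) / kL3`` (independent of the basal
YAP/TAZ production rate), while the YT_up-nullcline is computed implicitly
and may be S-shaped — multivalued in L for a range of YT_up — so it is
returned as one or more continuity-stitched sheets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .model import (
    ParameterSet,
    ReducedState,
    hill_activation,
    reduced_rhs_components,
    state_bounds,
)
from .equilibria import reduced_jacobian

__all__ = [
    "NullclineCurve",
    "VectorFieldGrid",
    "compute_nullcline",
    "intersect_nullclines",
    "compute_vector_field",
]


@dataclass
class NullclineCurve:
    """One nullcline of the reduced system as ordered (L, YT_up) points.

    ``sheets`` holds index ranges delimiting continuity-stitched solution
    sheets (the YT_up-nullcline can be multivalued in L).
    """

    which: str  # "L_nullcline" | "YTup_nullcline"
    points: np.ndarray  # shape (n, 2): columns (L, YT_up)
    sheets: list[tuple[int, int]]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "which": self.which,
                "YT_up": self.points[:, 1],
                "L": self.points[:, 0],
            }
        )


@dataclass
class VectorFieldGrid:
    """Reduced-system derivative vectors on a regular (L, YT_up) grid."""

    L: np.ndarray
    YT_up: np.ndarray
    dL: np.ndarray
    dYT_up: np.ndarray

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.dL, self.dYT_up)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "L": self.L.ravel(),
                "YT_up": self.YT_up.ravel(),
                "dL": self.dL.ravel(),
                "dYT_up": self.dYT_up.ravel(),
                "magnitude": self.magnitude.ravel(),
            }
        )


def compute_nullcline(
    which: str,
    params: ParameterSet,
    y_range: tuple[float, float] | None = None,
    resolution: int = 400,
) -> NullclineCurve:
    """Compute one nullcline over a YT_up range.

    The L-nullcline is evaluated from its closed form.  The YT_up-nullcline
    is found by root-finding ``dYT_up/dt = 0`` in L at each YT_up grid value,
    keeping every root (the curve is S-shaped in bistable regimes) and
    stitching roots into sheets by continuity.
    """
    if resolution < 100:
        raise ValueError("resolution must be >= 100")
    B_L, B_YT = state_bounds(params)
    if y_range is None:
        y_range = (0.0, B_YT / 1.5)
    ys = np.linspace(*y_range, resolution)
    if which == "L_nullcline":
        Ls = (params.kL1 + params.kL2 * hill_activation(ys, params.JL, params.n)) / params.kL3
        pts = np.column_stack([Ls, ys])
        return NullclineCurve(which, pts, sheets=[(0, len(pts))])
    if which != "YTup_nullcline":
        raise ValueError(f"unknown nullcline {which!r}")

    def f(L, y):
        return reduced_rhs_components(L, y, params)[1]

    records: list[tuple[float, float]] = []  # (L, y)
    grid_L = np.linspace(0.0, B_L, 600)
    for y in ys:
        vals = np.asarray(f(grid_L, y))
        for i in range(len(grid_L) - 1):
            if vals[i] == 0.0:
                records.append((float(grid_L[i]), float(y)))
            elif vals[i] * vals[i + 1] < 0:
                root = brentq(f, grid_L[i], grid_L[i + 1], args=(y,), xtol=1e-12)
                records.append((float(root), float(y)))
    if not records:
        return NullclineCurve(which, np.empty((0, 2)), sheets=[])
    pts = np.array(records)
    # stitch into sheets: greedy nearest-continuation in (L, y) scan order
    order = np.lexsort((pts[:, 0], pts[:, 1]))
    pts = pts[order]
    sheets: list[list[int]] = []
    tol_L = 0.08 * B_L
    for idx in range(len(pts)):
        placed = False
        for sheet in sheets:
            last = pts[sheet[-1]]
            if pts[idx, 1] - last[1] <= (ys[1] - ys[0]) * 1.5 + 1e-12 and abs(
                pts[idx, 0] - last[0]
            ) < tol_L:
                sheet.append(idx)
                placed = True
                break
        if not placed:
            sheets.append([idx])
    ordered = np.concatenate([np.array(s) for s in sheets])
    spans = []
    start = 0
    for s in sheets:
        spans.append((start, start + len(s)))
        start += len(s)
    return NullclineCurve(which, pts[ordered], sheets=spans)


def intersect_nullclines(
    curveA: NullclineCurve, curveB: NullclineCurve, params: ParameterSet
) -> list[ReducedState]:
    """Intersection points of two nullclines, refined by 2-D Newton iteration.

    Candidate crossings come from segment-pair proximity; each is polished on
    the reduced vector field and deduplicated at state distance 1e-6.
    """
    if len(curveA.points) == 0 or len(curveB.points) == 0:
        return []
    # orient so A is the single-valued-in-YT_up curve (the L-nullcline)
    if curveA.which != "L_nullcline" and curveB.which == "L_nullcline":
        curveA, curveB = curveB, curveA
    A, B = curveA.points, curveB.points
    cands: list[np.ndarray] = []
    a_order = np.argsort(A[:, 1])
    Ay, AL = A[a_order, 1], A[a_order, 0]
    for lo, hi in curveB.sheets:
        seg = B[lo:hi]
        if len(seg) < 2:
            continue
        interp_L = np.interp(seg[:, 1], Ay, AL)
        resid = seg[:, 0] - interp_L
        inside = (seg[:, 1] >= Ay[0]) & (seg[:, 1] <= Ay[-1])
        for i in range(len(seg) - 1):
            if not (inside[i] and inside[i + 1]):
                continue
            if resid[i] == 0.0 or resid[i] * resid[i + 1] < 0:
                cands.append(0.5 * (seg[i] + seg[i + 1]))
    roots: list[np.ndarray] = []
    for x0 in cands:
        x = x0.copy()
        ok = False
        for _ in range(60):
            fvec = np.asarray(reduced_rhs_components(x[0], x[1], params), dtype=float)
            if np.linalg.norm(fvec) < 1e-12:
                ok = True
                break
            J = reduced_jacobian(x, params)
            try:
                step = np.linalg.solve(J, fvec)
            except np.linalg.LinAlgError:
                break
            scale = 1.0
            while np.any(x - scale * step < 0) and scale > 1e-6:
                scale /= 2
            x = x - scale * step
        if ok:
            roots.append(x)
    merged: list[np.ndarray] = []
    for r in sorted(roots, key=lambda t: t[1]):
        if not merged or np.linalg.norm(r - merged[-1]) > 1e-6:
            merged.append(r)
    return [ReducedState(float(r[0]), float(r[1])) for r in merged]


def compute_vector_field(
    params: ParameterSet,
    box: tuple[tuple[float, float], tuple[float, float]] | None = None,
    grid_n: int = 20,
) -> VectorFieldGrid:
    """Exact reduced derivatives on a ``grid_n`` x ``grid_n`` grid."""
    if grid_n < 10:
        raise ValueError("grid_n must be >= 10")
    if box is None:
        B_L, B_YT = state_bounds(params)
        box = ((0.0, B_L / 1.5), (0.0, B_YT / 1.5))
    (l_lo, l_hi), (y_lo, y_hi) = box
    Lg, Yg = np.meshgrid(
        np.linspace(l_lo, l_hi, grid_n), np.linspace(y_lo, y_hi, grid_n), indexing="ij"
    )
    dL, dY = reduced_rhs_components(Lg, Yg, params)
    return VectorFieldGrid(L=Lg, YT_up=Yg, dL=np.asarray(dL), dYT_up=np.asarray(dY))
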