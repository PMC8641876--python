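"""One-at-a-time +/-15% sensitivity scan of the four saddle-node thresholds.

Each parameter (except the swept basal production rate kYTup0 by default) is
multiplied by 0.85 and 1.15 in turn; the full one-parameter bifurcation
diagram is retraced, the sweep range extended to negative basal production
so folds pushed past zero are not lost, and each fold is reported as a fold
change: perturbed position divided by the baseline position along the
kYTup0 axis.  A fold at or below zero marks the tumorigenic state as
irreversible — once past SN3, no admissible basal production rate can bring
the system back.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .model import PARAM_NAMES, ParameterSet
from .equilibria import SaddleNodeSet, sweep_bifurcation

logger = logging.getLogger(__name__)

__all__ = [
    "SensitivityRecord",
    "scan_all",
    "rank_sensitivities",
    "SIRT1_LOOP",
    "NOTCH_LOOP",
    "LATS_LOOP",
]

SN_KEYS = ("SN1", "SN2", "SN3", "SN4")

#: parameter groups by feedback loop membership
SIRT1_LOOP = ("kS1", "kS2", "kS3", "kYTup1", "JYTup1", "JS")
NOTCH_LOOP = ("kN1", "kN2", "kN3", "kYTup2", "JYTup2", "JN")
LATS_LOOP = ("kL1", "kL2", "kL3", "kYTup3", "kYTup4", "JL", "JYTup3", "JYTup4")


@dataclass
class SensitivityRecord:
    """Fold changes of the four thresholds for one perturbed parameter."""

    parameter: str
    direction: str  # "plus15" | "minus15"
    fold_change: dict[str, float | None] = field(default_factory=dict)
    exists: dict[str, bool] = field(default_factory=dict)
    positions: dict[str, float | None] = field(default_factory=dict)
    irreversible_tumorigenic: bool = False


def _measure(params: ParameterSet, sweep_range, steps) -> SaddleNodeSet:
    return sweep_bifurcation(
        params, swept="kYTup0", sweep_range=sweep_range, steps=steps
    ).saddle_nodes


def scan_all(
    params: ParameterSet,
    fraction: float = 0.15,
    include_swept: bool = False,
    sweep_range: tuple[float, float] = (-0.012, 0.03),
    steps: int = 300,
    baseline: SaddleNodeSet | None = None,
) -> list[SensitivityRecord]:
    """Perturb every parameter by ``+/-fraction`` and re-measure all folds.

    ``include_swept`` adds kYTup0 itself to the scan (off by default: it is
    the bifurcation parameter).  The Hill exponent n is included like any
    other parameter; its perturbation is logged separately since it changes
    the shape, not the scale, of every regulation term.
    """
    if not 0 <= fraction < 0.5:
        raise ValueError("fraction must be in [0, 0.5)")
    base = baseline if baseline is not None else _measure(params, sweep_range, steps)
    names = [p for p in PARAM_NAMES if include_swept or p != "kYTup0"]
    records: list[SensitivityRecord] = []
    for name in names:
        for direction, factor in (("plus15", 1 + fraction), ("minus15", 1 - fraction)):
            if name == "n":
                logger.info("perturbing Hill exponent n by factor %.3f", factor)
            perturbed = params.replace(**{name: getattr(params, name) * factor})
            sns = _measure(perturbed, sweep_range, steps)
            rec = SensitivityRecord(parameter=name, direction=direction)
            for key in SN_KEYS:
                pos = getattr(sns, key)
                ref = getattr(base, key)
                rec.positions[key] = pos
                rec.exists[key] = pos is not None
                rec.fold_change[key] = (
                    pos / ref if (pos is not None and ref not in (None, 0.0)) else None
                )
            sn4 = sns.SN4
            rec.irreversible_tumorigenic = sn4 is not None and sn4 <= 0.0
            records.append(rec)
    return records


def rank_sensitivities(records: list[SensitivityRecord]) -> dict[str, list[str]]:
    """Per-threshold parameter ranking by maximal |log fold change|.

    For each SN, parameters are ordered from most to least influential using
    the larger of the two |log fold changes| (plus15/minus15); absent folds
    rank last.  Ties break alphabetically, so the ordering is deterministic.
    """
    if not records:
        raise ValueError("no sensitivity records given")
    by_param: dict[str, dict[str, float]] = {}
    for rec in records:
        slot = by_param.setdefault(rec.parameter, {k: 0.0 for k in SN_KEYS})
        for key in SN_KEYS:
            fc = rec.fold_change.get(key)
            if fc is not None and fc > 0:
                slot[key] = max(slot[key], abs(np.log(fc)))
    out: dict[str, list[str]] = {}
    for key in SN_KEYS:
        out[key] = sorted(by_param, key=lambda p: (-by_param[p][key], p))
    return out


def records_to_dataframe(records: list[SensitivityRecord]):
    import pandas as pd

    rows = []
    for r in records:
        rows.append(
            {
                "parameter": r.parameter,
                "direction": r.direction,
                **{f"{k}_fold": r.fold_change[k] for k in SN_KEYS},
                **{f"{k}_pos": r.positions[k] for k in SN_KEYS},
                "irreversible": r.irreversible_tumorigenic,
            }
        )
    return pd.DataFrame(rows)
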