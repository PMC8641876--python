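"""Synthetic test inputs with known answers.

Three generators cover the package's verification needs without any
external data:

* an analytic cusp-normal-form toy (``dx/dt = a + b*x - x**3`` embedded in a
  decoupled 2-D system) whose fold positions are known in closed form,
  exercising the continuation machinery end to end;
* random multiplicatively perturbed parameter suites for oracle-equivalence
  regression tests;
* labelled mixture populations for the cell-state classifier.

All generators are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import PARAM_NAMES, ParameterSet

__all__ = [
    "CuspToyModel",
    "LabelledPopulationFixture",
    "make_cusp_toy",
    "make_population_fixture",
    "make_perturbed_parameter_suite",
]


@dataclass(frozen=True)
class CuspToyModel:
    """Decoupled 2-D embedding of the 1-D cusp normal form.

    Dynamics: ``dv/dt = -(v - 1)`` (relaxing carrier variable) and
    ``dx/dt = a + b*x - x**3``.  For ``b > 0`` the saddle-node folds sit at
    ``a = +/- 2*(b/3)**1.5`` exactly.  The state is mapped onto the
    (L, YT_up) slots as (v, x - x_offset) so the same sweep machinery runs
    unchanged; ``x_offset`` shifts the cusp's x-range into positive values.
    """

    a: float
    b: float
    x_offset: float = 3.0

    @property
    def fold_positions(self) -> tuple[float, float]:
        f = 2.0 * (self.b / 3.0) ** 1.5
        return (-f, f)

    def rhs(self, state, a_value: float | None = None) -> np.ndarray:
        a = self.a if a_value is None else a_value
        v = np.asarray(state[0], dtype=float)
        x = np.asarray(state[1], dtype=float) - self.x_offset
        return np.array([-(v - 1.0), a + self.b * x - x**3])

    def residual(self, xs, a_value: float | None = None):
        """x-equation residual in shifted coordinates (vectorised over xs)."""
        a = self.a if a_value is None else a_value
        x = np.asarray(xs, dtype=float) - self.x_offset
        return a + self.b * x - x**3

    def equilibria_x(self, a_value: float | None = None) -> list[float]:
        """Real roots of a + b*x - x^3 = 0 (in shifted coordinates)."""
        a = self.a if a_value is None else a_value
        roots = np.roots([-1.0, 0.0, self.b, a])
        return sorted(float(r.real) + self.x_offset for r in roots if abs(r.imag) < 1e-10)


def make_cusp_toy(b: float = 3.0, a: float = 0.0) -> CuspToyModel:
    """Cusp toy with folds at ``a = +/- 2*(b/3)**1.5``."""
    if b <= 0:
        raise ValueError("b must be > 0 (no folds otherwise)")
    return CuspToyModel(a=a, b=b)


@dataclass(frozen=True)
class LabelledPopulationFixture:
    """Synthetic terminal YT_up values drawn from a labelled mixture."""

    values: np.ndarray
    labels: tuple[str, ...]
    branch_values: tuple[float, ...]


def make_population_fixture(
    branch_values=(0.1, 0.67, 1.8),
    spreads=(0.03, 0.05, 0.1),
    weights=(0.2, 0.6, 0.2),
    n: int = 300,
    seed: int = 0,
) -> LabelledPopulationFixture:
    """Three-component Gaussian mixture around prescribed branch levels.

    Components map onto (degenerative, homeostatic, tumorigenic) in order of
    the strictly increasing ``branch_values``.  Overlapping components
    (spread larger than half the gap to a neighbour) raise a warning since
    classifier accuracy is then not guaranteed.
    """
    import warnings

    branch_values = tuple(float(v) for v in branch_values)
    if any(b2 <= b1 for b1, b2 in zip(branch_values, branch_values[1:])):
        raise ValueError("branch_values must be strictly increasing")
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    gaps = [b2 - b1 for b1, b2 in zip(branch_values, branch_values[1:])]
    for i, s in enumerate(spreads):
        near = [g for j, g in enumerate(gaps) if j in (i - 1, i)]
        if near and s > 0.5 * min(near):
            warnings.warn(f"component {i} spread {s} overlaps a neighbouring branch")
    names = ("degenerative", "homeostatic", "tumorigenic")[: len(branch_values)]
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(branch_values), size=n, p=np.asarray(weights, dtype=float))
    vals = np.array(
        [abs(rng.normal(branch_values[c], spreads[c])) for c in comp]
    )
    return LabelledPopulationFixture(
        values=vals,
        labels=tuple(names[c] for c in comp),
        branch_values=branch_values,
    )


def make_perturbed_parameter_suite(
    params: ParameterSet,
    fraction: float = 0.15,
    n: int = 50,
    seed: int = 0,
) -> list[ParameterSet]:
    """``n`` parameter sets with every entry scaled by an independent uniform
    factor in ``[1 - fraction, 1 + fraction]``; positivity is preserved."""
    if not 0 <= fraction < 0.5:
        raise ValueError("fraction must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        factors = rng.uniform(1 - fraction, 1 + fraction, size=len(PARAM_NAMES))
        out.append(
            ParameterSet(
                **{
                    name: float(getattr(params, name) * f)
                    for name, f in zip(PARAM_NAMES, factors)
                }
            )
        )
    return out
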