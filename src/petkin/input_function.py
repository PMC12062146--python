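"""Arterial input-function construction with metabolite correction.

The measured plasma curve contains both intact tracer and radiolabelled
metabolites; the parent fraction f(t) (fraction of plasma activity that is
intact tracer) is measured on a handful of late samples and applied
multiplicatively. Following the study design, a population-average parent
fraction per cohort group is the default correction; per-individual curves
remain available.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .curves import SampledCurve

__all__ = [
    "ParentFractionCurve",
    "InputFunction",
    "population_parent_fraction",
    "apply_parent_fraction",
]

#: Parent-fraction measurement times used in the study (minutes).
DEFAULT_PF_TIMES = (5.0, 10.0, 15.0, 30.0, 60.0)


@dataclass(frozen=True)
class ParentFractionCurve:
    """Fraction of plasma activity that is intact (parent) tracer.

    Interpolated linearly between measurements, anchored at (0, 1) before the
    first measurement (all activity is parent at injection) and held constant
    beyond the last.
    """

    times: np.ndarray
    fractions: np.ndarray
    scope: str = "individual"
    label: str = ""

    def __post_init__(self) -> None:
        curve = SampledCurve(self.times, self.fractions, self.label, "parent_fraction")
        object.__setattr__(self, "times", curve.times)
        object.__setattr__(self, "fractions", curve.values)
        if self.scope not in {"individual", "population"}:
            raise ValueError("scope must be 'individual' or 'population'")

    def as_curve(self) -> SampledCurve:
        return SampledCurve(self.times, self.fractions, self.label, "parent_fraction")

    def interp(self, t):
        return self.as_curve().interp(t)

    __call__ = interp

    @classmethod
    def from_curve(cls, curve: SampledCurve, scope: str = "individual"):
        return cls(curve.times, curve.values, scope, curve.label)


def population_parent_fraction(
    individuals: list[ParentFractionCurve], grid
) -> ParentFractionCurve:
    """Arithmetic mean of linearly interpolated individual parent fractions
    on a common time grid; used to correct every plasma curve of a group."""
    if not individuals:
        raise ValueError("need at least one individual parent-fraction curve")
    grid = np.asarray(grid, dtype=float)
    stacked = np.vstack([ind.interp(grid) for ind in individuals])
    return ParentFractionCurve(grid, stacked.mean(axis=0), scope="population")


def apply_parent_fraction(
    plasma_total: SampledCurve, pf: ParentFractionCurve
) -> SampledCurve:
    """Metabolite-correct a total plasma curve: pointwise product with f(t)."""
    frac = np.asarray(pf.interp(plasma_total.times), dtype=float)
    if np.any(frac < 0) or np.any(frac > 1):
        raise ValueError("parent fractions must lie in [0, 1]")
    return SampledCurve(
        plasma_total.times,
        plasma_total.values * frac,
        plasma_total.label,
        "plasma_parent",
    )


@dataclass(frozen=True)
class InputFunction:
    """Metabolite-corrected plasma plus whole-blood curves driving the
    tissue models. ``delay`` (minutes) shifts both curves identically:
    the shifted input at t equals the unshifted input at t - delay, and is
    zero before the shifted start."""

    plasma_parent: SampledCurve
    whole_blood: SampledCurve
    delay: float = 0.0

    def __post_init__(self) -> None:
        if self.plasma_parent.kind not in {"plasma_parent", "plasma_total"}:
            raise ValueError("plasma curve must be a plasma kind")
        if self.whole_blood.kind != "whole_blood":
            raise ValueError("whole_blood curve must have kind 'whole_blood'")
        if abs(self.delay) >= 2.0:
            raise ValueError("|delay| must be < 2 min")

    def _shifted(self, curve: SampledCurve, t):
        t_arr = np.asarray(t, dtype=float)
        ts = t_arr - self.delay
        out = np.where(ts <= 0, 0.0, curve.interp(np.maximum(ts, 0.0)))
        return float(out) if t_arr.ndim == 0 else out

    def plasma(self, t):
        """Metabolite-corrected plasma concentration at time(s) t."""
        return self._shifted(self.plasma_parent, t)

    def blood(self, t):
        """Whole-blood concentration at time(s) t."""
        return self._shifted(self.whole_blood, t)

    def shifted(self, delay: float) -> "InputFunction":
        """A copy with the given additional delay applied."""
        return replace(self, delay=self.delay + delay)

    @property
    def end_time(self) -> float:
        return float(min(self.plasma_parent.times[-1], self.whole_blood.times[-1]))


def shift_input(input_function: InputFunction, delay: float) -> InputFunction:
    """Functional form of :meth:`InputFunction.shifted`."""
    return input_function.shifted(delay)
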