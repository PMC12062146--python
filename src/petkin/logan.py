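"""Logan graphical analysis with arterial input.

For a reversible tracer the transformed variables

    y(t) = int_0^t C_T ds / C_T(t),   x(t) = int_0^t C_p ds / C_T(t)

become linear in t beyond an equilibration time t*, with slope V_T. Because
frame values are frame averages, the cumulative tissue integral to a frame
boundary is exactly the running sum of value*duration; evaluation at frame
mid-times adds half the current frame. The plasma integral uses the input
curve's own sampling. Frames are included when their mid-time is >= t*.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .compartment import DEFAULT_VB
from .curves import FrameSchedule
from .input_function import InputFunction

__all__ = ["GraphicalFit", "logan_vt", "cumulative_frame_integral"]


@dataclass(frozen=True)
class GraphicalFit:
    """Late-time linear fit of a graphical analysis. ``slope`` is V_T for the
    plasma-input Logan plot and DVR for the reference-tissue variant (then
    ``bp_nd = DVR - 1`` is populated)."""

    slope: float
    intercept: float
    t_star: float
    n_points: int
    r_squared: float
    method: str = "logan_plasma"
    bp_nd: float | None = None

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError("a graphical fit needs at least 3 points")


def cumulative_frame_integral(values: np.ndarray,
                              schedule: FrameSchedule) -> np.ndarray:
    """Integral of a frame-averaged TAC from 0 to each frame mid-time.

    Frame values are time-averages, so the integral up to a frame start is
    the exact running sum of value*duration; the current frame contributes
    half its own value*duration at the mid-time.
    """
    v = np.asarray(values, dtype=float)
    vd = v * schedule.durations
    to_start = np.concatenate([[0.0], np.cumsum(vd)])[:-1]
    return to_start + 0.5 * vd


def _late_ols(x, y, t_star, mask_extra, method, warn_label):
    usable = mask_extra
    if np.count_nonzero(usable) < 3:
        raise ValueError(f"fewer than 3 usable frames beyond t* for {warn_label}")
    res = stats.linregress(x[usable], y[usable])
    return res, int(np.count_nonzero(usable))


def logan_vt(tac, schedule: FrameSchedule, input_function: InputFunction,
             t_star: float = 20.0, vb: float = DEFAULT_VB,
             blood_correct: bool = True) -> GraphicalFit:
    """Logan plot slope as V_T.

    The measured frame values are first corrected for the fractional blood
    signal, C_T = (C_meas - vb*C_wb)/(1 - vb), then regressed in the Logan
    coordinates over frames with mid-time >= t_star. Frames where the
    corrected tissue activity is not positive are excluded with a warning.
    """
    tac = np.asarray(tac, dtype=float)
    mids = schedule.mids
    if blood_correct and vb > 0:
        ct = (tac - vb * input_function.blood(mids)) / (1.0 - vb)
    else:
        ct = tac.copy()

    int_ct = cumulative_frame_integral(ct, schedule)
    int_cp = np.array([
        input_function.plasma_parent.auc(0.0, float(m)) if m > 0 else 0.0
        for m in mids
    ])

    late = mids >= t_star
    positive = ct > 0
    if np.any(late & ~positive):
        warnings.warn(
            f"excluding {np.count_nonzero(late & ~positive)} frame(s) with "
            "non-positive tissue activity from the Logan fit"
        )
    usable = late & positive
    y = np.where(positive, int_ct, np.nan) / np.where(positive, ct, np.nan)
    x = np.where(positive, int_cp, np.nan) / np.where(positive, ct, np.nan)
    res, n = _late_ols(x, y, t_star, usable, "logan_plasma", "Logan plot")
    return GraphicalFit(
        slope=float(res.slope), intercept=float(res.intercept), t_star=t_star,
        n_points=n, r_squared=float(res.rvalue**2), method="logan_plasma",
    )
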