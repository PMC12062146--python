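"""Closed-form convolution of a piecewise-linear input with exponentials.

Compartmental impulse responses are sums of ``exp(-theta*t)`` terms (plus a
``t*exp(-theta*t)`` term in the confluent, repeated-eigenvalue limit), and the
measured input is piecewise linear between blood samples, so the convolution
integral has an exact per-segment closed form. This module evaluates

    C0(theta, t) = int_0^t exp(-theta*(t-s)) p(s) ds
    C1(theta, t) = int_0^t (t-s) exp(-theta*(t-s)) p(s) ds

exactly (to rounding) for any t >= 0, with p(t) the linearly interpolated
input anchored at (0, 0) before its first sample and held constant after the
last one.
"""

from __future__ import annotations

import numpy as np

from .curves import SampledCurve

__all__ = ["ExpConvolver"]

_SERIES_X = 1e-3


def _phi1(x):
    """(1 - exp(-x)) / x, stable near 0."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < _SERIES_X
    xs = x[small]
    out[small] = 1.0 - xs / 2.0 + xs**2 / 6.0 - xs**3 / 24.0
    xl = x[~small]
    out[~small] = -np.expm1(-xl) / xl
    return out


def _phi2(x):
    """(1 - (1 + x) exp(-x)) / x**2, stable near 0."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < _SERIES_X
    xs = x[small]
    out[small] = 0.5 - xs / 3.0 + xs**2 / 8.0 - xs**3 / 30.0
    xl = x[~small]
    out[~small] = (1.0 - (1.0 + xl) * np.exp(-xl)) / xl**2
    return out


def _phi3(x):
    """(2 - (x**2 + 2x + 2) exp(-x)) / x**3, stable near 0."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < _SERIES_X
    xs = x[small]
    out[small] = 1.0 / 3.0 - xs / 4.0 + xs**2 / 10.0 - xs**3 / 36.0
    xl = x[~small]
    out[~small] = (2.0 - (xl**2 + 2.0 * xl + 2.0) * np.exp(-xl)) / xl**3
    return out


class ExpConvolver:
    """Exact convolution of one piecewise-linear curve with exponentials.

    Built once per input curve; each :meth:`c0` / :meth:`c1` call runs a short
    recursion over the input's segments and then evaluates vectorised over the
    requested times.
    """

    def __init__(self, curve: SampledCurve):
        kt, kv = curve._knots()
        self.t = np.asarray(kt, dtype=float)
        self.v = np.asarray(kv, dtype=float)
        self.dt = np.diff(self.t)
        # slope of each segment; trailing 0 covers constant extrapolation
        self.b = np.diff(self.v) / self.dt if self.dt.size else np.zeros(0)
        self._b_ext = np.concatenate([self.b, [0.0]])

    def _knot_states(self, theta: float) -> tuple[np.ndarray, np.ndarray]:
        """C0 and C1 at every knot: vectorised per-segment quantities, then a
        cheap scalar accumulation of the first-order recurrence."""
        n = self.t.size
        c0 = np.zeros(n)
        c1 = np.zeros(n)
        if n == 1:
            return c0, c1
        d = self.dt
        x = theta * d
        e = np.exp(-x)
        e2 = d * d * _phi2(x)
        pv, b = self.v[1:], self.b
        g0 = pv * (d * _phi1(x)) - b * e2
        g1 = pv * e2 - b * (d * d * d * _phi3(x))
        el, dl = e.tolist(), d.tolist()
        g0l, g1l = g0.tolist(), g1.tolist()
        a0 = a1 = 0.0
        for k in range(n - 1):
            ek = el[k]
            a1 = dl[k] * ek * a0 + ek * a1 + g1l[k]
            a0 = ek * a0 + g0l[k]
            c0[k + 1] = a0
            c1[k + 1] = a1
        return c0, c1

    def _eval(self, theta: float, t, want_c1: bool):
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        out0 = np.zeros_like(t_arr)
        out1 = np.zeros_like(t_arr)
        pos = t_arr > 0
        tp = t_arr[pos]
        k0, k1 = self._knot_states(theta)
        # segment index: knot immediately at/left of each t
        idx = np.searchsorted(self.t, tp, side="right") - 1
        idx = np.clip(idx, 0, self.t.size - 1)
        u = self.t[idx]
        cu0, cu1 = k0[idx], k1[idx]
        d = tp - u
        b = self._b_ext[np.minimum(idx, self.b.size)]
        pv = self.v[idx] + b * d
        x = theta * d
        e = np.exp(-x)
        e1 = d * _phi1(x)
        e2 = d * d * _phi2(x)
        out0[pos] = e * cu0 + pv * e1 - b * e2
        if want_c1:
            e3 = d * d * d * _phi3(x)
            out1[pos] = d * e * cu0 + e * cu1 + pv * e2 - b * e3
        if np.isscalar(t) or np.asarray(t).ndim == 0:
            return (float(out0[0]), float(out1[0])) if want_c1 else float(out0[0])
        return (out0, out1) if want_c1 else out0

    def c0(self, theta: float, t):
        """``int_0^t exp(-theta*(t-s)) p(s) ds`` at time(s) t."""
        return self._eval(theta, t, want_c1=False)

    def c1(self, theta: float, t):
        """``int_0^t (t-s) exp(-theta*(t-s)) p(s) ds`` at time(s) t."""
        return self._eval(theta, t, want_c1=True)[1]

    def both(self, theta: float, t):
        """(c0, c1) in one pass."""
        return self._eval(theta, t, want_c1=True)
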