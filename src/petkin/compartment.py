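"""One- and two-tissue compartment models with blood-based input.

The measured PET concentration is modelled as

    C_model(t) = (1 - V_B) * C_tissue(t) + V_B * C_wb(t)

where C_tissue is the convolution of the metabolite-corrected plasma curve
with the model impulse response: K1*exp(-k2*t) for the one-tissue model, and
for the two-tissue model a sum of two exponentials whose rates are the
eigenvalues of the compartmental system

    theta_{1,2} = ((k2+k3+k4) -/+ sqrt((k2+k3+k4)^2 - 4*k2*k4)) / 2.

Macro parameters: V_ND = K1/k2, BP_ND = k3/k4, V_T = V_ND * (1 + BP_ND).

Fitting is bounded weighted nonlinear least squares from a deterministic
multi-start grid; model comparison uses the least-squares Akaike score
AIC = n*ln(WRSS/n) + 2p.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .convolve import ExpConvolver
from .curves import FrameSchedule, _gauss_nodes
from .input_function import InputFunction

__all__ = [
    "CompartmentParams",
    "MacroParams",
    "ModelConfig",
    "CompartmentFit",
    "MODEL_PRESETS",
    "DEFAULT_VB",
    "TacModel",
    "model_tac",
    "fit_model",
    "macro_params",
    "aic_score",
    "select_model",
]

#: Cerebral blood volume fraction fixed from the literature (3.6%).
DEFAULT_VB = 0.036

#: Eigenvalue separation below which the confluent closed form is used.
_CONFLUENT_TOL = 1e-8

_BOUNDS = {
    "K1": (0.0, 5.0),
    "k2": (1e-6, 5.0),
    "k3": (0.0, 5.0),
    "k4": (1e-6, 5.0),
    "vb": (0.0, 0.2),
    "delay": (-1.0, 1.0),
}


@dataclass(frozen=True)
class CompartmentParams:
    """Micro rate constants. K1 in mL.cm-3.min-1; k2..k4 in min-1; vb is the
    fractional blood volume; delay in minutes (applied to the input)."""

    K1: float
    k2: float
    k3: float = 0.0
    k4: float = 0.0
    vb: float = 0.0
    delay: float = 0.0

    def __post_init__(self) -> None:
        for name in ("K1", "k2", "k3", "k4", "vb", "delay"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.K1 < 0 or self.k2 <= 0 or self.k3 < 0 or self.k4 < 0:
            raise ValueError("rate constants must satisfy K1>=0, k2>0, k3,k4>=0")
        if self.k3 > 0 and self.k4 <= 0:
            raise ValueError("reversible binding requires k4 > 0 when k3 > 0")
        if not 0 <= self.vb < 1:
            raise ValueError("vb must lie in [0, 1)")


@dataclass(frozen=True)
class MacroParams:
    """Derived macro parameters; V_T = V_ND * (1 + BP_ND) by construction."""

    V_ND: float
    V_T: float
    BP_ND: float


def macro_params(params: CompartmentParams) -> MacroParams:
    """V_ND = K1/k2, BP_ND = k3/k4 (0 when k3 = 0), V_T = V_ND*(1+BP_ND)."""
    v_nd = params.K1 / params.k2
    if params.k3 == 0:
        bp = 0.0
    elif params.k4 > 0:
        bp = params.k3 / params.k4
    else:
        raise ValueError("BP_ND undefined: k3 > 0 with k4 = 0")
    return MacroParams(V_ND=v_nd, V_T=v_nd * (1.0 + bp), BP_ND=bp)


def _impulse_terms(K1, k2, k3, k4):
    """Impulse response as [(coef, theta, order)] with order 0 for
    exp(-theta t) and order 1 for t*exp(-theta t) (confluent limit)."""
    if k3 == 0.0 and k4 == 0.0:
        return [(K1, k2, 0)]
    s = k2 + k3 + k4
    disc = s * s - 4.0 * k2 * k4
    d = math.sqrt(max(disc, 0.0))
    if d > _CONFLUENT_TOL:
        th1 = 0.5 * (s - d)
        th2 = 0.5 * (s + d)
        return [
            (K1 * (k3 + k4 - th1) / d, th1, 0),
            (K1 * (th2 - (k3 + k4)) / d, th2, 0),
        ]
    th = 0.5 * s
    return [(K1, th, 0), (K1 * (k3 + k4 - th), th, 1)]


class TacModel:
    """Forward model bound to one input function and frame schedule.

    Caches the input convolver and the frame-averaging quadrature so that
    repeated evaluations during fitting stay cheap.
    """

    def __init__(self, input_function: InputFunction, schedule: FrameSchedule,
                 frame_method: str = "average"):
        self.input = input_function
        self.schedule = schedule
        self.frame_method = frame_method
        self._conv = ExpConvolver(input_function.plasma_parent)
        wb = input_function.whole_blood
        self._wb_knots = wb._knots()
        if frame_method == "average":
            bp = np.unique(
                np.concatenate(
                    [input_function.plasma_parent.times, wb.times]
                )
            )
            # with densely sampled inputs the convolved curve is smooth, so a
            # capped step beats splitting at hundreds of sample knots
            if bp.size > 48:
                bp, max_step = None, 0.125
            else:
                max_step = 0.5
            self._nodes, self._weights, self._fidx = _gauss_nodes(
                schedule.starts, schedule.ends, breakpoints=bp,
                max_step=max_step,
            )
        elif frame_method == "midpoint":
            self._nodes = schedule.mids
        else:
            raise ValueError(f"unknown frame method {frame_method!r}")

    def _wb(self, ts):
        kt, kv = self._wb_knots
        return np.where(ts <= 0, 0.0, np.interp(np.maximum(ts, 0.0), kt, kv))

    def point_values(self, params: CompartmentParams, t):
        """Model concentration at arbitrary time(s) t (minutes)."""
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        ts = t_arr - (self.input.delay + params.delay)
        tissue = np.zeros_like(t_arr)
        pos = ts > 0
        tsp = ts[pos]
        for coef, theta, order in _impulse_terms(
            params.K1, params.k2, params.k3, params.k4
        ):
            if coef == 0.0:
                continue
            basis = self._conv.c1(theta, tsp) if order else self._conv.c0(theta, tsp)
            tissue[pos] += coef * np.asarray(basis)
        out = (1.0 - params.vb) * tissue + params.vb * self._wb(ts)
        if np.asarray(t).ndim == 0:
            return float(out[0])
        return out

    def frame_values(self, params: CompartmentParams) -> np.ndarray:
        """Model concentration mapped onto the acquisition frames."""
        vals = self.point_values(params, self._nodes)
        if self.frame_method == "midpoint":
            return vals
        sums = np.bincount(
            self._fidx, weights=vals * self._weights,
            minlength=self.schedule.n_frames,
        )
        return sums / self.schedule.durations


def model_tac(params: CompartmentParams, input_function: InputFunction,
              schedule: FrameSchedule, frame_method: str = "average") -> np.ndarray:
    """Frame values of the compartment model (convenience wrapper)."""
    return TacModel(input_function, schedule, frame_method).frame_values(params)


# ---------------------------------------------------------------------------
# Model configurations and fitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelConfig:
    name: str
    n_tissues: int
    vb_mode: str = "fixed"          # 'fixed' or 'free'
    vb_value: float = DEFAULT_VB
    fit_delay: bool = False
    weight_scheme: str = "uniform"  # 'uniform' or 'frame_duration'

    def __post_init__(self) -> None:
        if self.n_tissues not in (1, 2):
            raise ValueError("n_tissues must be 1 or 2")
        if self.vb_mode not in ("fixed", "free"):
            raise ValueError("vb_mode must be 'fixed' or 'free'")

    @property
    def free_param_names(self) -> tuple[str, ...]:
        names = ["K1", "k2"]
        if self.n_tissues == 2:
            names += ["k3", "k4"]
        if self.vb_mode == "free":
            names.append("vb")
        if self.fit_delay:
            names.append("delay")
        return tuple(names)

    @property
    def n_free(self) -> int:
        return len(self.free_param_names)


#: The five candidate model variants compared during model selection.
MODEL_PRESETS: dict[str, ModelConfig] = {
    "1tcm_vb_free": ModelConfig("1tcm_vb_free", 1, "free"),
    "1tcm_vb_fixed": ModelConfig("1tcm_vb_fixed", 1, "fixed"),
    "2tcm_vb_free": ModelConfig("2tcm_vb_free", 2, "free"),
    "2tcm_vb_fixed": ModelConfig("2tcm_vb_fixed", 2, "fixed"),
    "2tcm_vb_fixed_delay": ModelConfig("2tcm_vb_fixed_delay", 2, "fixed",
                                       fit_delay=True),
}


@dataclass(frozen=True)
class CompartmentFit:
    config: ModelConfig
    params: CompartmentParams
    macro: MacroParams
    wrss: float
    aic: float
    n_frames: int
    converged: bool
    fitted_tac: np.ndarray
    warnings: tuple[str, ...] = ()


def aic_score(wrss: float, n: int, n_free: int) -> float:
    """Least-squares AIC: n*ln(WRSS/n) + 2p; -inf sentinel on a perfect fit."""
    if wrss <= 0:
        return float("-inf")
    return n * math.log(wrss / n) + 2 * n_free


def select_model(fits: list[CompartmentFit]) -> CompartmentFit:
    """Minimum-AIC converged fit; ties broken toward fewer free parameters."""
    if not fits:
        raise ValueError("no fits to select from")
    pool = [f for f in fits if f.converged] or list(fits)
    return min(pool, key=lambda f: (round(f.aic, 9), f.config.n_free))


def _weights(config: ModelConfig, schedule: FrameSchedule) -> np.ndarray:
    if config.weight_scheme == "uniform":
        return np.ones(schedule.n_frames)
    if config.weight_scheme == "frame_duration":
        d = schedule.durations
        return d / d.mean()
    raise ValueError(f"unknown weight scheme {config.weight_scheme!r}")


def _start_grid(config: ModelConfig) -> list[dict[str, float]]:
    """Deterministic multi-start grid spanning one to two orders of magnitude
    in each rate constant."""
    starts = []
    if config.n_tissues == 1:
        for K1 in (0.05, 0.2, 0.5, 1.0):
            for k2 in (0.05, 0.5):
                starts.append({"K1": K1, "k2": k2})
    else:
        for K1 in (0.1, 0.5):
            for k2 in (0.05, 0.5):
                for k3, k4 in ((0.01, 0.02), (0.2, 0.1)):
                    starts.append({"K1": K1, "k2": k2, "k3": k3, "k4": k4})
    for s in starts:
        if config.vb_mode == "free":
            s["vb"] = DEFAULT_VB
        if config.fit_delay:
            s["delay"] = 0.0
    return starts


def _vector_to_params(x: np.ndarray, config: ModelConfig) -> CompartmentParams:
    d = dict(zip(config.free_param_names, x))
    return CompartmentParams(
        K1=d["K1"],
        k2=max(d["k2"], _BOUNDS["k2"][0]),
        k3=d.get("k3", 0.0),
        k4=max(d.get("k4", 0.0), _BOUNDS["k4"][0]) if config.n_tissues == 2 else 0.0,
        vb=d.get("vb", config.vb_value if config.vb_mode == "fixed" else 0.0),
        delay=d.get("delay", 0.0),
    )


def fit_model(tac, input_function: InputFunction, schedule: FrameSchedule,
              config: ModelConfig | str, init: CompartmentParams | None = None,
              frame_method: str = "average") -> CompartmentFit:
    """Bounded weighted least-squares fit of one model configuration.

    Runs every start of a deterministic grid (plus ``init`` if given) and
    keeps the best weighted residual sum of squares. ``converged`` reflects
    the optimizer's own status of the winning start.
    """
    if isinstance(config, str):
        config = MODEL_PRESETS[config]
    tac = np.asarray(tac, dtype=float)
    if tac.shape != (schedule.n_frames,):
        raise ValueError("tac length does not match the frame schedule")

    model = TacModel(input_function, schedule, frame_method)
    w = _weights(config, schedule)
    sqrt_w = np.sqrt(w)
    names = config.free_param_names
    lo = np.array([_BOUNDS[n][0] for n in names])
    hi = np.array([_BOUNDS[n][1] for n in names])

    if not np.any(tac != 0):
        params = _vector_to_params(lo.copy(), config)
        fitted = model.frame_values(params)
        wrss = float(np.sum(w * (tac - fitted) ** 2))
        return CompartmentFit(
            config, params, macro_params(params), wrss,
            aic_score(wrss, tac.size, config.n_free), tac.size, True, fitted,
            warnings=("degenerate: all-zero tac",),
        )

    def residuals(x):
        return sqrt_w * (tac - model.frame_values(_vector_to_params(x, config)))

    starts = _start_grid(config)
    if init is not None:
        extra = {n: getattr(init, n if n != "vb" else "vb") for n in names}
        starts.insert(0, extra)

    best = None
    diagnostics = []
    for s in starts:
        x0 = np.clip(np.array([s[n] for n in names]), lo + 1e-12, hi - 1e-12)
        try:
            res = least_squares(
                residuals, x0, bounds=(lo, hi), method="trf", x_scale="jac",
                xtol=1e-8, ftol=1e-8, gtol=1e-8, max_nfev=200,
            )
        except Exception as exc:  # pragma: no cover - defensive
            diagnostics.append(f"start {s}: {exc}")
            continue
        wrss = float(np.sum(res.fun**2))
        if best is None or wrss < best[0]:
            best = (wrss, res)
    if best is not None:
        # polish the winning start to tight tolerance
        try:
            res = least_squares(
                residuals, best[1].x, bounds=(lo, hi), method="trf",
                x_scale="jac", xtol=1e-13, ftol=1e-13, gtol=1e-13,
                max_nfev=400,
            )
            wrss = float(np.sum(res.fun**2))
            if wrss <= best[0] + 1e-15:
                best = (wrss, res)
        except Exception as exc:  # pragma: no cover - defensive
            diagnostics.append(f"polish: {exc}")
    if best is None:
        params = _vector_to_params(np.clip(np.array(
            [starts[0][n] for n in names]), lo, hi), config)
        fitted = model.frame_values(params)
        wrss = float(np.sum(w * (tac - fitted) ** 2))
        return CompartmentFit(
            config, params, macro_params(params), wrss, float("nan"),
            tac.size, False, fitted,
            warnings=tuple(["all starts failed"] + diagnostics),
        )

    wrss, res = best
    params = _vector_to_params(res.x, config)
    fitted = model.frame_values(params)
    warns = []
    at_hi = [n for n, x, h in zip(names, res.x, hi) if h - x < 1e-6 * max(h, 1)]
    if at_hi:
        warns.append("at upper bound: " + ",".join(at_hi))
    # a rate pinned at its (positive) lower bound signals an unidentifiable
    # fit (e.g. k4 -> 0 inflating BP_ND), not a converged optimum
    at_lo = [n for n, x, l in zip(names, res.x, lo)
             if l > 0 and x - l < 1e-3 * l]
    if at_lo:
        warns.append("at lower bound: " + ",".join(at_lo))
    converged = bool(res.success) and not at_hi and not at_lo
    return CompartmentFit(
        config, params, macro_params(params), wrss,
        aic_score(wrss, tac.size, config.n_free), tac.size, converged, fitted,
        warnings=tuple(warns),
    )
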