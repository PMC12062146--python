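"""Core curve and frame-schedule types shared by every quantification method.

All times are minutes internally; delimited files carry seconds and are
converted on read. Activity concentration is expressed as %ID/g throughout
(tissue and blood alike), so distribution volumes and binding potentials come
out dimensionless.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "FrameSchedule",
    "SampledCurve",
    "RegionTacSet",
    "CurveParseError",
    "DEFAULT_REGIONS",
    "frame_average",
    "read_tac_table",
    "write_tac_table",
    "read_blood_table",
    "write_blood_table",
    "read_parent_fraction_table",
    "write_parent_fraction_table",
]

#: Brain regions quantified in the study; cerebellar grey serves as the
#: pseudo-reference (no specific binding).
DEFAULT_REGIONS = (
    "cortex",
    "midbrain",
    "brainstem",
    "striatum",
    "hippocampus",
    "cerebellum_grey",
)

CURVE_KINDS = frozenset(
    {"whole_blood", "plasma_total", "plasma_parent", "parent_fraction", "tissue"}
)


class CurveParseError(ValueError):
    """Raised when a delimited curve/TAC file violates the expected layout."""


@dataclass(frozen=True)
class FrameSchedule:
    """Acquisition frame schedule: ordered (start, end) pairs in minutes."""

    frames: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.frames, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] == 0:
            raise ValueError("frames must be a non-empty list of (start, end) pairs")
        starts, ends = arr[:, 0], arr[:, 1]
        if starts[0] < 0:
            raise ValueError("first frame start must be >= 0")
        if np.any(ends <= starts):
            raise ValueError("every frame must satisfy end > start")
        if np.any(np.diff(starts) <= 0):
            raise ValueError("frame starts must be strictly increasing")
        if np.any(starts[1:] < ends[:-1] - 1e-12):
            raise ValueError("frames must not overlap")

    @classmethod
    def default_60min(cls) -> "FrameSchedule":
        """The 22-frame / 60-min schedule: 6x10 s, 4x30 s, 4x60 s, 1x180 s,
        4x300 s, 3x600 s."""
        durations_s = [10] * 6 + [30] * 4 + [60] * 4 + [180] + [300] * 4 + [600] * 3
        edges = np.concatenate([[0.0], np.cumsum(durations_s)]) / 60.0
        return cls(tuple(zip(edges[:-1], edges[1:])))

    @property
    def starts(self) -> np.ndarray:
        return np.asarray([f[0] for f in self.frames], dtype=float)

    @property
    def ends(self) -> np.ndarray:
        return np.asarray([f[1] for f in self.frames], dtype=float)

    @property
    def mids(self) -> np.ndarray:
        return 0.5 * (self.starts + self.ends)

    @property
    def durations(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def __len__(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class SampledCurve:
    """A timed activity (or fraction) curve sampled at discrete times.

    Linear interpolation between samples; before the first sample the curve
    is interpolated linearly from (0, 0) — activity is zero before injection —
    and after the last sample it is held constant.
    """

    times: np.ndarray
    values: np.ndarray
    label: str = ""
    kind: str = "tissue"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or v.ndim != 1 or t.size != v.size or t.size == 0:
            raise ValueError("times and values must be equal-length 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if t[0] < 0:
            raise ValueError("times must be non-negative")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
            raise ValueError("times and values must be finite")
        if self.kind not in CURVE_KINDS:
            raise ValueError(f"unknown curve kind {self.kind!r}")
        if self.kind == "parent_fraction" and (np.any(v < 0) or np.any(v > 1)):
            raise ValueError("parent_fraction values must lie in [0, 1]")

    # -- interpolation contract -------------------------------------------

    def _knots(self) -> tuple[np.ndarray, np.ndarray]:
        """Sample points with the (0, 0) pre-injection anchor prepended."""
        if self.times[0] > 0:
            anchor = 0.0 if self.kind != "parent_fraction" else 1.0
            return (
                np.concatenate([[0.0], self.times]),
                np.concatenate([[anchor], self.values]),
            )
        return self.times, self.values

    def interp(self, t):
        """Linearly interpolated value(s) at time(s) ``t`` (minutes)."""
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise ValueError("cannot evaluate a curve at negative time")
        kt, kv = self._knots()
        out = np.interp(t_arr, kt, kv)
        return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out

    __call__ = interp

    def auc(self, t0: float, t1: float) -> float:
        """Trapezoidal integral of the interpolated curve over [t0, t1]."""
        if not t0 < t1:
            raise ValueError(f"reversed or empty integration bounds [{t0}, {t1}]")
        if t0 < 0 or t1 > self.times[-1] + 1e-12:
            raise ValueError(
                f"bounds [{t0}, {t1}] outside sampled range [0, {self.times[-1]}]"
            )
        kt, kv = self._knots()
        inner = kt[(kt > t0) & (kt < t1)]
        grid = np.concatenate([[t0], inner, [t1]])
        return float(np.trapezoid(np.interp(grid, kt, kv), grid))

    def scaled(self, factor: float) -> "SampledCurve":
        return replace(self, values=self.values * factor)


@dataclass
class RegionTacSet:
    """Regional tissue TACs of one subject on a common frame schedule."""

    schedule: FrameSchedule
    region_tacs: dict[str, np.ndarray]
    subject: str = "subject"
    group: str = "wildtype"

    def __post_init__(self) -> None:
        if self.group not in {"wildtype", "transgenic"}:
            raise ValueError("group must be 'wildtype' or 'transgenic'")
        n = self.schedule.n_frames
        clean: dict[str, np.ndarray] = {}
        for region, vals in self.region_tacs.items():
            arr = np.asarray(vals, dtype=float)
            if arr.shape != (n,):
                raise ValueError(
                    f"region {region!r} has {arr.size} values for {n} frames"
                )
            clean[region] = arr
        self.region_tacs = clean

    @property
    def regions(self) -> list[str]:
        return list(self.region_tacs)

    def __getitem__(self, region: str) -> np.ndarray:
        return self.region_tacs[region]


# ---------------------------------------------------------------------------
# Frame averaging of continuous model curves
# ---------------------------------------------------------------------------


def _gauss_nodes(starts, ends, breakpoints=None, max_step=0.5, order=5):
    """Gauss–Legendre nodes/weights covering each [start, end] interval,
    split at the given breakpoints and capped at ``max_step`` minutes."""
    gx, gw = np.polynomial.legendre.leggauss(order)
    nodes, weights, frame_idx = [], [], []
    bp = np.asarray(breakpoints, dtype=float) if breakpoints is not None else None
    for i, (a, b) in enumerate(zip(starts, ends)):
        edges = [a, b]
        if bp is not None:
            edges.extend(bp[(bp > a) & (bp < b)])
        edges = np.unique(edges)
        refined = [edges[0]]
        for lo, hi in zip(edges[:-1], edges[1:]):
            k = max(1, int(np.ceil((hi - lo) / max_step)))
            refined.extend(np.linspace(lo, hi, k + 1)[1:])
        refined = np.asarray(refined)
        for lo, hi in zip(refined[:-1], refined[1:]):
            half = 0.5 * (hi - lo)
            nodes.append(half * gx + 0.5 * (lo + hi))
            weights.append(half * gw)
            frame_idx.append(np.full(order, i))
    return (
        np.concatenate(nodes),
        np.concatenate(weights),
        np.concatenate(frame_idx),
    )


def frame_average(func, schedule: FrameSchedule, method: str = "average",
                  breakpoints=None) -> np.ndarray:
    """Map a continuous model curve onto acquisition frames.

    ``method='average'`` (default) returns the time-average of ``func`` over
    each frame via composite Gauss–Legendre quadrature, the physically correct
    reading of accumulated counts; ``method='midpoint'`` evaluates at frame
    mid-times.
    """
    if method == "midpoint":
        return np.asarray(func(schedule.mids), dtype=float)
    if method != "average":
        raise ValueError(f"unknown frame method {method!r}")
    nodes, weights, idx = _gauss_nodes(
        schedule.starts, schedule.ends, breakpoints=breakpoints
    )
    vals = np.asarray(func(nodes), dtype=float) * weights
    sums = np.bincount(idx, weights=vals, minlength=schedule.n_frames)
    return sums / schedule.durations


# ---------------------------------------------------------------------------
# Delimited-text I/O (comma or tab, '#' comments, seconds on disk)
# ---------------------------------------------------------------------------

_SEC_PER_MIN = 60.0


def _read_table(path) -> tuple[pd.DataFrame, dict[str, str]]:
    meta: dict[str, str] = {}
    lines = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            stripped = line.strip()
            if stripped.startswith("#"):
                body = stripped.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    meta[key.strip()] = val.strip()
                continue
            if stripped:
                lines.append(line)
    if not lines:
        raise CurveParseError(f"{path}: no data rows")
    sep = "\t" if "\t" in lines[0] else ","
    df = pd.read_csv(io.StringIO("".join(lines)), sep=sep)
    df.columns = [c.strip() for c in df.columns]
    return df, meta


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise CurveParseError(f"{path}: missing column(s) {missing}")


def read_tac_table(path) -> RegionTacSet:
    """Read a regional TAC table: frame_start_s, frame_end_s, one column per
    region. Optional '# subject:' / '# group:' comment headers."""
    df, meta = _read_table(path)
    _require_columns(df, ["frame_start_s", "frame_end_s"], path)
    starts = df["frame_start_s"].to_numpy(float) / _SEC_PER_MIN
    ends = df["frame_end_s"].to_numpy(float) / _SEC_PER_MIN
    for i, (a, b) in enumerate(zip(starts, ends)):
        if b <= a:
            raise CurveParseError(f"{path}: row {i + 1}: frame_end <= frame_start")
        if i and starts[i] < ends[i - 1] - 1e-12:
            raise CurveParseError(f"{path}: row {i + 1}: frames overlap or disorder")
    schedule = FrameSchedule(tuple(zip(starts, ends)))
    regions = [c for c in df.columns if c not in ("frame_start_s", "frame_end_s")]
    if not regions:
        raise CurveParseError(f"{path}: no region columns")
    tacs = {r: df[r].to_numpy(float) for r in regions}
    return RegionTacSet(
        schedule,
        tacs,
        subject=meta.get("subject", "subject"),
        group=meta.get("group", "wildtype"),
    )


def write_tac_table(tacset: RegionTacSet, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# subject: {tacset.subject}\n# group: {tacset.group}\n")
        cols = ["frame_start_s", "frame_end_s"] + tacset.regions
        fh.write(",".join(cols) + "\n")
        starts = tacset.schedule.starts * _SEC_PER_MIN
        ends = tacset.schedule.ends * _SEC_PER_MIN
        for i in range(tacset.schedule.n_frames):
            row = [f"{starts[i]:.6g}", f"{ends[i]:.6g}"]
            row += [f"{tacset.region_tacs[r][i]:.12g}" for r in tacset.regions]
            fh.write(",".join(row) + "\n")


def _monotone_times(times, path):
    if np.any(np.diff(times) <= 0):
        bad = int(np.where(np.diff(times) <= 0)[0][0]) + 2
        raise CurveParseError(f"{path}: row {bad}: times not strictly increasing")


def read_blood_table(path) -> tuple[SampledCurve, SampledCurve]:
    """Read a blood-sample table (time_s, whole_blood, plasma) into
    (whole_blood, plasma_total) curves, times converted to minutes."""
    df, meta = _read_table(path)
    _require_columns(df, ["time_s", "whole_blood", "plasma"], path)
    t = df["time_s"].to_numpy(float) / _SEC_PER_MIN
    _monotone_times(t, path)
    label = meta.get("subject", "")
    wb = SampledCurve(t, df["whole_blood"].to_numpy(float), label, "whole_blood")
    pl = SampledCurve(t, df["plasma"].to_numpy(float), label, "plasma_total")
    return wb, pl


def write_blood_table(whole_blood: SampledCurve, plasma: SampledCurve, path,
                      subject: str = "") -> None:
    if whole_blood.times.shape != plasma.times.shape or np.any(
        whole_blood.times != plasma.times
    ):
        raise ValueError("whole-blood and plasma curves must share sample times")
    with open(path, "w", encoding="utf-8") as fh:
        if subject:
            fh.write(f"# subject: {subject}\n")
        fh.write("time_s,whole_blood,plasma\n")
        for t, w, p in zip(whole_blood.times, whole_blood.values, plasma.values):
            fh.write(f"{t * _SEC_PER_MIN:.6g},{w:.12g},{p:.12g}\n")


def read_parent_fraction_table(path) -> tuple[SampledCurve, dict[str, str]]:
    """Read a parent-fraction table (time_s, parent_fraction); returns the
    curve plus comment metadata (e.g. scope/subject)."""
    df, meta = _read_table(path)
    _require_columns(df, ["time_s", "parent_fraction"], path)
    t = df["time_s"].to_numpy(float) / _SEC_PER_MIN
    _monotone_times(t, path)
    curve = SampledCurve(
        t,
        df["parent_fraction"].to_numpy(float),
        meta.get("subject", ""),
        "parent_fraction",
    )
    return curve, meta


def write_parent_fraction_table(curve: SampledCurve, path, subject: str = "",
                                scope: str = "individual") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if subject:
            fh.write(f"# subject: {subject}\n")
        fh.write(f"# scope: {scope}\n")
        fh.write("time_s,parent_fraction\n")
        for t, v in zip(curve.times, curve.values):
            fh.write(f"{t * _SEC_PER_MIN:.6g},{v:.12g}\n")
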