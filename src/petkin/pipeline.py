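"""End-to-end analysis: input construction, all quantification methods,
cohort tables, outlier handling, cross-validation and group statistics.

The orchestration mirrors the study workflow: group population-average
parent fractions correct individual plasma curves; each subject/region is
quantified with the blood-based two-tissue model, plasma-input Logan, SRTM
and the reference Logan model (k2' handed off from SRTM); cohort-level
tables then feed ratio/AUC comparisons, outlier-filtered cross-validations
and group tests. Every subject is either analysed or excluded with a
recorded reason, and all outputs are reproducible bit-for-bit from
(config, seed).
"""

from __future__ import annotations

import dataclasses
import glob
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort_stats import (
    StatsReport,
    auc_compare,
    compare_groups,
    cross_validate,
    filter_k3k4_outliers,
    make_cohort_table,
    region_ratio,
    tac_auc,
)
from .compartment import DEFAULT_VB, MODEL_PRESETS, fit_model
from .curves import (
    FrameSchedule,
    read_blood_table,
    read_parent_fraction_table,
    read_tac_table,
)
from .input_function import (
    InputFunction,
    ParentFractionCurve,
    apply_parent_fraction,
    population_parent_fraction,
)
from .logan import logan_vt
from .reference import SrtmBasis, fit_srtm, logan_ref_bpnd
from .simulate import CohortSpec, SubjectData, simulate_cohort

__all__ = ["AnalysisConfig", "ResultBundle", "run_analysis", "read_cohort_dir"]

DEFAULT_METHODS = ("2tcm_vb_fixed", "logan_plasma", "srtm", "logan_ref")


@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration of one analysis run (simulated or file-based)."""

    mode: str = "simulate"                 # 'simulate' or 'files'
    cohort_spec: CohortSpec | None = None  # simulate mode
    data_dir: str | None = None            # files mode
    methods: tuple[str, ...] = DEFAULT_METHODS
    reference_region: str = "cerebellum_grey"
    t_star: float = 20.0
    vb: float = DEFAULT_VB
    k3k4_cutoff: float = 1.0
    vt_exclude_above: float | None = 20.0
    k2_prime_mode: str = "per_region"      # or 'subject_median'
    stats_welch: bool = True
    frame_method: str = "average"
    outdir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "files"):
            raise ValueError("mode must be 'simulate' or 'files'")
        if self.mode == "files" and not self.data_dir:
            raise ValueError("files mode requires data_dir")
        if self.k2_prime_mode not in ("per_region", "subject_median"):
            raise ValueError("k2_prime_mode must be per_region or subject_median")
        unknown = [m for m in self.methods
                   if m not in MODEL_PRESETS and m not in
                   ("logan_plasma", "srtm", "logan_ref")]
        if unknown:
            raise ValueError(f"unknown method(s): {unknown}")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "methods" in raw:
            raw["methods"] = tuple(raw["methods"])
        if raw.get("cohort_spec") == "default":
            raw["cohort_spec"] = CohortSpec()
        elif isinstance(raw.get("cohort_spec"), dict):
            raw["cohort_spec"] = CohortSpec(**raw["cohort_spec"])
        return cls(**raw)


@dataclass
class ResultBundle:
    config: AnalysisConfig
    fits: pd.DataFrame            # wide: one row per subject x region x method
    cohort: pd.DataFrame          # long: (subject, group, region, method, parameter, value)
    ratios: pd.DataFrame
    stats: dict[str, StatsReport]
    cross_validations: pd.DataFrame
    exclusions: list[dict]
    log: dict

    def write(self, outdir) -> None:
        os.makedirs(outdir, exist_ok=True)
        fmt = "%.12g"
        self.fits.to_csv(os.path.join(outdir, "fits.csv"), index=False,
                         float_format=fmt)
        self.cohort.to_csv(os.path.join(outdir, "cohort_long.csv"), index=False,
                           float_format=fmt)
        self.ratios.to_csv(os.path.join(outdir, "region_ratios.csv"),
                           index=False, float_format=fmt)
        self.cross_validations.to_csv(
            os.path.join(outdir, "cross_validation.csv"), index=False,
            float_format=fmt)
        for name, report in self.stats.items():
            report.contrasts.to_csv(
                os.path.join(outdir, f"stats_{name}.csv"), index=False,
                float_format=fmt)
            if report.anova is not None:
                report.anova.to_csv(
                    os.path.join(outdir, f"anova_{name}.csv"),
                    float_format=fmt)
        with open(os.path.join(outdir, "run_log.json"), "w",
                  encoding="utf-8") as fh:
            json.dump(self.log, fh, indent=2, sort_keys=True, default=str)
        self._write_summary(outdir)

    def _write_summary(self, outdir) -> None:
        lines = ["# Analysis summary", ""]
        lines.append(f"- subjects analysed: {self.log['n_subjects_analysed']}")
        lines.append(f"- subjects/stages excluded: {len(self.exclusions)}")
        for name, report in self.stats.items():
            sig = report.contrasts[report.contrasts["stars"] != ""]
            regions = ", ".join(
                f"{r.region} ({r.stars}, p_adj={r.p_adj:.3g})"
                for r in sig.itertuples()
            ) or "none"
            lines.append(f"- {name}: significant contrasts: {regions}")
        with open(os.path.join(outdir, "summary.md"), "w",
                  encoding="utf-8") as fh:
            fh.write("\n".join(lines) + "\n")


def read_cohort_dir(directory) -> list[SubjectData]:
    """Read subject observables written in the standard file layout."""
    subjects = []
    for tac_path in sorted(glob.glob(os.path.join(directory, "*_tac.csv"))):
        prefix = tac_path[: -len("_tac.csv")]
        tacs = read_tac_table(tac_path)
        wb, plasma = read_blood_table(prefix + "_blood.csv")
        pf, _ = read_parent_fraction_table(prefix + "_parent_fraction.csv")
        subjects.append(SubjectData(
            subject=tacs.subject, group=tacs.group, plasma_total=plasma,
            whole_blood=wb, parent_fraction=pf, tacs=tacs, n_clipped=0,
        ))
    if not subjects:
        raise FileNotFoundError(f"no *_tac.csv files under {directory}")
    return subjects


def _population_fractions(subjects) -> dict[str, ParentFractionCurve]:
    out = {}
    for group in sorted({s.group for s in subjects}):
        curves = [
            ParentFractionCurve.from_curve(s.parent_fraction)
            for s in subjects if s.group == group
        ]
        grid = np.unique(np.concatenate([c.times for c in curves]))
        out[group] = population_parent_fraction(curves, grid)
    return out


def _subject_rows(config, subject, input_function, exclusions):
    """All per-region fits of one subject, as (wide, long) row lists."""
    wide, long_rows = [], []
    sched = subject.tacs.schedule
    ref_region = config.reference_region
    compartment_methods = [m for m in config.methods if m in MODEL_PRESETS]
    srtm_fits = {}

    basis = None
    if "srtm" in config.methods or "logan_ref" in config.methods:
        basis = SrtmBasis(subject.tacs[ref_region], sched,
                          frame_method=config.frame_method)

    for region in subject.tacs.regions:
        tac = subject.tacs[region]
        for preset in compartment_methods:
            try:
                f = fit_model(tac, input_function, sched, preset,
                              frame_method=config.frame_method)
            except Exception as exc:
                exclusions.append({"subject": subject.subject, "region": region,
                                   "method": preset, "reason": str(exc)})
                continue
            row = {
                "subject": subject.subject, "group": subject.group,
                "region": region, "method": preset,
                "K1": f.params.K1, "k2": f.params.k2, "k3": f.params.k3,
                "k4": f.params.k4, "vb": f.params.vb, "delay": f.params.delay,
                "V_ND": f.macro.V_ND, "V_T": f.macro.V_T,
                "BP_ND": f.macro.BP_ND, "wrss": f.wrss, "aic": f.aic,
                "converged": f.converged,
            }
            wide.append(row)
            for p in ("K1", "k2", "k3", "k4", "V_ND", "V_T", "BP_ND"):
                long_rows.append((subject.subject, subject.group, region,
                                  preset, p, row[p]))
        if "logan_plasma" in config.methods:
            try:
                g = logan_vt(tac, sched, input_function, t_star=config.t_star,
                             vb=config.vb)
                wide.append({
                    "subject": subject.subject, "group": subject.group,
                    "region": region, "method": "logan_plasma",
                    "V_T": g.slope, "intercept": g.intercept,
                    "r_squared": g.r_squared, "n_points": g.n_points,
                    "converged": True,
                })
                long_rows.append((subject.subject, subject.group, region,
                                  "logan_plasma", "V_T", g.slope))
            except Exception as exc:
                exclusions.append({"subject": subject.subject, "region": region,
                                   "method": "logan_plasma", "reason": str(exc)})
        if "srtm" in config.methods and region != ref_region:
            try:
                s = fit_srtm(tac, basis.ref_tac, sched, basis=basis)
                srtm_fits[region] = s
                wide.append({
                    "subject": subject.subject, "group": subject.group,
                    "region": region, "method": "srtm", "R1": s.R1,
                    "k2": s.k2, "BP_ND": s.BP_ND, "k2a": s.k2a,
                    "k2_prime": s.k2_prime, "wrss": s.wrss,
                    "converged": s.converged,
                })
                for p, v in (("BP_ND", s.BP_ND), ("R1", s.R1),
                             ("k2_prime", s.k2_prime)):
                    long_rows.append((subject.subject, subject.group, region,
                                      "srtm", p, v))
            except Exception as exc:
                exclusions.append({"subject": subject.subject, "region": region,
                                   "method": "srtm", "reason": str(exc)})

    if "logan_ref" in config.methods:
        k2p_median = (
            float(np.median([s.k2_prime for s in srtm_fits.values()]))
            if srtm_fits else None
        )
        for region in subject.tacs.regions:
            if region == ref_region:
                continue
            if config.k2_prime_mode == "per_region":
                k2p = srtm_fits[region].k2_prime if region in srtm_fits else None
            else:
                k2p = k2p_median
            if k2p is None or not np.isfinite(k2p) or k2p <= 0:
                exclusions.append({"subject": subject.subject, "region": region,
                                   "method": "logan_ref",
                                   "reason": "no usable k2_prime from SRTM"})
                continue
            try:
                g = logan_ref_bpnd(subject.tacs[region],
                                   subject.tacs[ref_region], sched, k2p,
                                   t_star=config.t_star)
                wide.append({
                    "subject": subject.subject, "group": subject.group,
                    "region": region, "method": "logan_ref", "DVR": g.slope,
                    "BP_ND": g.bp_nd, "r_squared": g.r_squared,
                    "n_points": g.n_points, "k2_prime": k2p, "converged": True,
                })
                long_rows.append((subject.subject, subject.group, region,
                                  "logan_ref", "BP_ND", g.bp_nd))
            except Exception as exc:
                exclusions.append({"subject": subject.subject, "region": region,
                                   "method": "logan_ref", "reason": str(exc)})
    return wide, long_rows


def run_analysis(config: AnalysisConfig) -> ResultBundle:
    """Run the configured study end-to-end and (optionally) write tables."""
    if config.mode == "simulate":
        spec = config.cohort_spec or CohortSpec(seed=config.seed)
        if config.cohort_spec is None:
            spec = CohortSpec(seed=config.seed)
        dataset = simulate_cohort(spec)
        subjects = dataset.subjects
    else:
        subjects = read_cohort_dir(config.data_dir)

    exclusions: list[dict] = []
    pop_pf = _population_fractions(subjects)

    wide_rows, long_rows, ratio_rows = [], [], []
    analysed = []
    for s in subjects:
        try:
            plasma_parent = apply_parent_fraction(
                s.plasma_total, pop_pf[s.group])
            input_function = InputFunction(plasma_parent, s.whole_blood)
        except Exception as exc:
            exclusions.append({"subject": s.subject, "region": "", "method":
                               "input_function", "reason": str(exc)})
            continue
        w, l = _subject_rows(config, s, input_function, exclusions)
        wide_rows.extend(w)
        long_rows.extend(l)
        analysed.append(s.subject)
        for region in s.tacs.regions:
            if region == config.reference_region:
                continue
            try:
                ratio_rows.append({
                    "subject": s.subject, "group": s.group, "region": region,
                    "ratio_50_60": region_ratio(
                        s.tacs, region, config.reference_region),
                    "auc_0_60": tac_auc(s.tacs, region),
                })
            except Exception as exc:
                exclusions.append({"subject": s.subject, "region": region,
                                   "method": "region_ratio", "reason": str(exc)})

    fits = pd.DataFrame(wide_rows)
    cohort = make_cohort_table(long_rows)
    ratios = pd.DataFrame(ratio_rows)

    # ---- cohort statistics ------------------------------------------------
    stats_reports: dict[str, StatsReport] = {}
    welch = config.stats_welch

    def _safe_compare(name, table, parameter, method, design):
        try:
            stats_reports[name] = compare_groups(
                table, parameter, design=design, method=method, welch=welch)
        except ValueError:
            pass

    vt_table = cohort[cohort["parameter"] == "V_T"].copy()
    if config.vt_exclude_above is not None and not vt_table.empty:
        over = vt_table["value"] > config.vt_exclude_above
        for r in vt_table[over].itertuples():
            exclusions.append({"subject": r.subject, "region": r.region,
                               "method": r.method,
                               "reason": f"V_T={r.value:.3g} above "
                                         f"{config.vt_exclude_above}"})
        vt_table = vt_table[~over]

    for preset in [m for m in config.methods if m in MODEL_PRESETS]:
        _safe_compare(f"vt_{preset}", vt_table, "V_T", preset,
                      "two_way_anova_bonferroni")
        _safe_compare(f"bp_{preset}", cohort, "BP_ND", preset,
                      "two_way_anova_bonferroni")
    if "logan_plasma" in config.methods:
        _safe_compare("vt_logan", vt_table, "V_T", "logan_plasma",
                      "two_way_anova_bonferroni")
    for ref_m in ("srtm", "logan_ref"):
        if ref_m in config.methods:
            _safe_compare(f"bp_{ref_m}", cohort, "BP_ND", ref_m,
                          "two_way_anova_bonferroni")
            _safe_compare(f"bp_{ref_m}_ttest", cohort, "BP_ND", ref_m, "ttest")

    if not ratios.empty:
        ratio_long = make_cohort_table([
            (r.subject, r.group, r.region, "tac", "ratio_50_60", r.ratio_50_60)
            for r in ratios.itertuples()
        ])
        _safe_compare("region_ratio", ratio_long, "ratio_50_60", "tac",
                      "two_way_anova_bonferroni")
        tacsets = [s.tacs for s in subjects if s.subject in set(analysed)]
        try:
            stats_reports["auc"] = auc_compare(tacsets, welch=welch)
        except ValueError:
            pass

    # ---- cross-validation (per group, as in the study) --------------------
    cv_rows = []
    pivot = (
        fits.pivot_table(index=["subject", "group", "region"],
                         columns="method", values="V_T", aggfunc="first")
        if not fits.empty and "V_T" in fits.columns else None
    )
    compartment_ref = next(
        (m for m in config.methods if m in MODEL_PRESETS), None)

    def _cv(group, name, x, y, n_excluded=0):
        try:
            cv = cross_validate(x, y)
        except ValueError:
            return
        cv_rows.append({
            "group": group, "comparison": name, "pearson_r": cv.pearson_r,
            "slope": cv.slope, "intercept": cv.intercept,
            "n_points": cv.n_points, "n_excluded": n_excluded,
            "percent_bias_slope": cv.percent_bias_slope,
            "percent_bias_inverse": cv.percent_bias_inverse,
        })

    if pivot is not None and compartment_ref is not None:
        for group in sorted(set(fits["group"])):
            if "logan_plasma" in config.methods:
                sub = pivot.loc[
                    pivot.index.get_level_values("group") == group
                ][[compartment_ref, "logan_plasma"]].dropna()
                if config.vt_exclude_above is not None:
                    sub = sub[sub[compartment_ref] <= config.vt_exclude_above]
                _cv(group, "vt_logan_vs_2tcm",
                    sub["logan_plasma"].to_numpy(),
                    sub[compartment_ref].to_numpy())
            # BP_ND from reference models vs k3/k4 from the compartment fit,
            # outlier-filtered at the k3/k4 cut-off
            comp_bp = fits[fits["method"] == compartment_ref]
            comp_bp = comp_bp[comp_bp["group"] == group]
            comp_bp = comp_bp.set_index(["subject", "region"])["BP_ND"]
            kept_mask = comp_bp <= config.k3k4_cutoff
            n_excl = int((~kept_mask).sum())
            comp_kept = comp_bp[kept_mask]
            for ref_m in ("srtm", "logan_ref"):
                if ref_m not in config.methods:
                    continue
                ref_bp = fits[(fits["method"] == ref_m)
                              & (fits["group"] == group)]
                ref_bp = ref_bp.set_index(["subject", "region"])["BP_ND"]
                joined = pd.concat([comp_kept, ref_bp], axis=1,
                                   join="inner", keys=["comp", "ref"]).dropna()
                _cv(group, f"k3k4_vs_{ref_m}", joined["ref"].to_numpy(),
                    joined["comp"].to_numpy(), n_excluded=n_excl)

    cross_validations = pd.DataFrame(cv_rows)

    log = {
        "package_version": __version__,
        "seed": config.seed,
        # outdir is where the log lands, not part of the analysis identity
        "config": {k: v for k, v in dataclasses.asdict(config).items()
                   if k != "outdir"},
        "n_subjects_input": len(subjects),
        "n_subjects_analysed": len(analysed),
        "subjects_analysed": analysed,
        "exclusions": exclusions,
    }
    bundle = ResultBundle(config, fits, cohort, ratios, stats_reports,
                          cross_validations, exclusions, log)
    if config.outdir:
        bundle.write(config.outdir)
    return bundle
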