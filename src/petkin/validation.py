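"""Validation studies: the package checking itself against independent
oracles and known generative truth.

Each function runs one self-contained study — analytic-vs-ODE agreement,
noise-free parameter recovery, graphical-analysis bias, reference-model
consistency, model-selection behaviour, test calibration, and end-to-end
cohort detection — and returns plain numbers. The studies are seeded and
sized explicitly so they can be reproduced from the command line (see
``scripts/acceptance.py``) or asserted in the test suite.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats
from scipy.integrate import solve_ivp

from .cohort_stats import compare_groups, make_cohort_table
from .compartment import (
    CompartmentParams,
    TacModel,
    fit_model,
)
from .curves import FrameSchedule, SampledCurve
from .input_function import InputFunction, apply_parent_fraction, ParentFractionCurve
from .logan import logan_vt
from .pipeline import AnalysisConfig, run_analysis
from .reference import fit_srtm, logan_ref_bpnd
from .simulate import (
    CohortSpec,
    InputFunctionSpec,
    simulate_input,
    simulate_region_tac,
    true_input_function,
)

__all__ = [
    "observed_input_function",
    "ode_oracle_study",
    "recovery_study",
    "logan_noise_free_study",
    "logan_noise_bias_study",
    "srtm_recovery_study",
    "aic_selection_study",
    "null_type1_study",
    "power_study",
    "cohort_detection_study",
    "cohort_summary",
]


def observed_input_function(spec: InputFunctionSpec | None = None,
                            seed=None, blood_noise_frac: float = 0.0
                            ) -> InputFunction:
    """Input function reconstructed the way the pipeline sees it: the
    standard 16-sample blood schedule, metabolite-corrected with the exact
    parent fraction."""
    spec = spec or InputFunctionSpec.wildtype()
    plasma_total, wb, _ = simulate_input(spec, seed=seed,
                                         blood_noise_frac=blood_noise_frac)
    pf = ParentFractionCurve(
        plasma_total.times, spec.parent_fraction(plasma_total.times))
    return InputFunction(apply_parent_fraction(plasma_total, pf), wb)


# ---------------------------------------------------------------------------
# 1. analytic convolution vs stiff ODE integration
# ---------------------------------------------------------------------------

#: Parameter grid spanning the fit bounds, including a confluent case
#: (k2 = k4, k3 = 0 makes the two eigenvalues coincide).
ODE_GRID = [
    CompartmentParams(K1, k2, k3, k4)
    for K1, k2, (k3, k4) in itertools.product(
        (0.1, 0.5, 2.0),
        (0.05, 0.5, 2.0),
        ((0.0, 0.0), (0.05, 0.03), (0.5, 0.2), (2.0, 1.0)),
    )
] + [
    CompartmentParams(0.5, 0.3, 0.0, 0.3),        # exactly confluent
    CompartmentParams(0.5, 0.3, 1e-9, 0.3),       # nearly confluent
    CompartmentParams(0.4, 0.11, 0.036, 0.15),    # generator regime
]


def ode_oracle_study(params_list=None) -> float:
    """Max relative deviation (to curve peak) between the closed-form
    convolution and a tight-tolerance LSODA integration of the
    two-compartment system, across a parameter grid."""
    inp = observed_input_function()
    schedule = FrameSchedule.default_60min()
    model = TacModel(inp, schedule)
    kt, kv = inp.plasma_parent._knots()
    mids = schedule.mids
    worst = 0.0
    for p in (params_list or ODE_GRID):

        def rhs(t, y, p=p):
            cp = np.interp(t, kt, kv)
            c1, c2 = y
            return [p.K1 * cp - (p.k2 + p.k3) * c1 + p.k4 * c2,
                    p.k3 * c1 - p.k4 * c2]

        sol = solve_ivp(rhs, [0.0, schedule.ends[-1]], [0.0, 0.0],
                        t_eval=mids, method="LSODA", rtol=1e-10, atol=1e-13,
                        max_step=0.25)
        oracle = sol.y.sum(axis=0)
        mine = model.point_values(p, mids)
        worst = max(worst, float(np.max(np.abs(mine - oracle))
                                 / np.max(np.abs(oracle))))
    return worst


# ---------------------------------------------------------------------------
# 2/3. noise-free parameter recovery
# ---------------------------------------------------------------------------

RECOVERY_CASES = [
    CompartmentParams(0.4, 0.3, 0.06, 0.03, vb=0.036),
    CompartmentParams(0.5, 0.4, 0.15, 0.05, vb=0.036),
    CompartmentParams(0.3, 0.15, 0.1, 0.2, vb=0.036),
]


def recovery_study() -> dict[str, float]:
    """Noise-free self-consistency of the two-tissue fit.

    Returns the max relative error on (K1, k2, k3, k4) over identifiable
    cases, and the fitted BP_ND when the generating data carries no
    specific binding (k3 = 0)."""
    inp = observed_input_function()
    schedule = FrameSchedule.default_60min()
    model = TacModel(inp, schedule)
    worst = 0.0
    for p in RECOVERY_CASES:
        tac = model.frame_values(p)
        f = fit_model(tac, inp, schedule, "2tcm_vb_fixed")
        for name in ("K1", "k2", "k3", "k4"):
            worst = max(worst, abs(getattr(f.params, name) - getattr(p, name))
                        / getattr(p, name))
    null_tac = model.frame_values(CompartmentParams(0.4, 0.15, vb=0.036))
    f0 = fit_model(null_tac, inp, schedule, "2tcm_vb_fixed")
    return {"max_rel_error": worst, "bp_nd_on_k3_zero_data": f0.macro.BP_ND}


# ---------------------------------------------------------------------------
# 4. Logan graphical analysis
# ---------------------------------------------------------------------------

LOGAN_GRID = [
    CompartmentParams(0.5, 0.25, 0.0, 0.0),
    CompartmentParams(0.42, 0.11, 0.036, 0.15),
    CompartmentParams(0.42, 0.093, 0.029, 0.12),
    CompartmentParams(0.38, 0.1, 0.018, 0.15),
    CompartmentParams(0.45, 0.12, 0.05, 0.18),
]


def logan_noise_free_study(t_star: float = 20.0) -> dict[str, float]:
    """Signed relative error of the Logan slope on noise-free reversible
    data across generator-range parameters (V_B = 0 so the tissue curve is
    exact). Returns the worst absolute and the largest signed error."""
    inp = observed_input_function()
    schedule = FrameSchedule.default_60min()
    model = TacModel(inp, schedule)
    errors = []
    for p in LOGAN_GRID:
        vt = p.K1 / p.k2 * (1.0 + (p.k3 / p.k4 if p.k3 > 0 else 0.0))
        tac = model.frame_values(p)
        g = logan_vt(tac, schedule, inp, t_star=t_star, vb=0.0,
                     blood_correct=False)
        errors.append((g.slope - vt) / vt)
    errors = np.asarray(errors)
    return {"max_abs_rel_error": float(np.max(np.abs(errors))),
            "max_signed_rel_error": float(np.max(errors))}


def logan_noise_bias_study(seed: int = 0, n_replicates: int = 200,
                           noise_scale: float = 0.3) -> dict[str, float]:
    """Mean Logan slope over seeded noisy replicates minus the noise-free
    slope: the documented negative noise bias of the method.

    The bias is second order in the noise (it comes from the noisy tissue
    value in the denominators of both Logan coordinates), so the replicates
    are drawn as antithetic pairs of zero-mean, unclipped frame-binned
    Gaussian noise: the first-order slope fluctuation cancels within each
    pair and the Monte-Carlo error no longer swamps the effect. The default
    noise level (SD = 0.3*sqrt(value/duration), about 28% on the late
    frames) corresponds to small-VOI or voxel-level statistics; at the
    cohort generator's regional noise level the bias is below Monte-Carlo
    resolution."""
    inp = observed_input_function()
    schedule = FrameSchedule.default_60min()
    model = TacModel(inp, schedule)
    p = CompartmentParams(0.42, 0.11, 0.036, 0.15)
    clean = model.frame_values(p)
    clean_fit = logan_vt(clean, schedule, inp, vb=0.0, blood_correct=False)
    sd = noise_scale * np.sqrt(np.maximum(clean, 0.0) / schedule.durations)
    rng = np.random.default_rng(seed)
    slopes = []
    for _ in range(n_replicates // 2):
        eps = sd * rng.standard_normal(clean.size)
        for tac in (clean + eps, clean - eps):
            slopes.append(logan_vt(tac, schedule, inp, vb=0.0,
                                   blood_correct=False).slope)
    return {"noise_free_slope": clean_fit.slope,
            "mean_noisy_slope": float(np.mean(slopes)),
            "bias": float(np.mean(slopes) - clean_fit.slope)}


# ---------------------------------------------------------------------------
# 5. reference-tissue consistency
# ---------------------------------------------------------------------------


def srtm_recovery_study(bp_true: float = 0.3) -> dict[str, float]:
    """SRTM and reference-Logan on an ideal one-tissue target/reference pair
    sharing V_ND (reference K1 = 0.4, k2 = 0.2; target carries bp_true)."""
    inp = true_input_function(InputFunctionSpec.wildtype())
    schedule = FrameSchedule.default_60min()
    model = TacModel(inp, schedule)
    ref = model.frame_values(CompartmentParams(0.4, 0.2))
    tgt = model.frame_values(CompartmentParams(0.4 * (1 + bp_true), 0.2))
    s = fit_srtm(tgt, ref, schedule)
    g = logan_ref_bpnd(tgt, ref, schedule, s.k2_prime)
    return {
        "srtm_bp": s.BP_ND,
        "srtm_rel_error": abs(s.BP_ND - bp_true) / bp_true,
        "lrtm_bp": g.bp_nd,
        "lrtm_vs_srtm_rel_diff": abs(g.bp_nd - s.BP_ND) / abs(s.BP_ND),
    }


# ---------------------------------------------------------------------------
# 6. AIC model selection
# ---------------------------------------------------------------------------


def aic_selection_study(seed: int = 0, n_replicates: int = 100,
                        noise_scale: float = 0.01) -> dict[str, float]:
    """Fraction of low-noise replicates on which AIC picks the generating
    model family: two-tissue data (well-separated k3, k4) vs one-tissue
    data, each fitted with both fixed-V_B presets."""
    inp = observed_input_function()
    schedule = FrameSchedule.default_60min()
    model = TacModel(inp, schedule)
    two_tissue = CompartmentParams(0.5, 0.4, 0.15, 0.05, vb=0.036)
    one_tissue = CompartmentParams(0.4, 0.15, vb=0.036)
    rng = np.random.default_rng(seed)
    wins = {"2tcm": 0, "1tcm": 0}
    for _ in range(n_replicates):
        for label, truth in (("2tcm", two_tissue), ("1tcm", one_tissue)):
            sim = simulate_region_tac(truth, inp, schedule, noise_scale,
                                      seed=rng.integers(2**31), model=model)
            f1 = fit_model(sim.values, inp, schedule, "1tcm_vb_fixed")
            f2 = fit_model(sim.values, inp, schedule, "2tcm_vb_fixed")
            best = "2tcm" if f2.aic < f1.aic else "1tcm"
            if best == label:
                wins[label] += 1
    return {"rate_2tcm_preferred_on_2tcm_data": wins["2tcm"] / n_replicates,
            "rate_1tcm_preferred_on_1tcm_data": wins["1tcm"] / n_replicates}


# ---------------------------------------------------------------------------
# 7. statistical calibration
# ---------------------------------------------------------------------------

REGIONS_6 = ("cortex", "midbrain", "brainstem", "striatum", "hippocampus",
             "cerebellum_grey")


def null_type1_study(seed: int = 0, n_replicates: int = 1000,
                     n_wt: int = 11, n_tg: int = 8) -> dict[str, float]:
    """Per-region type-I error of the Bonferroni-adjusted regional panel
    under the null: both groups drawn from the same distribution."""
    rng = np.random.default_rng(seed)
    n_sig = 0
    n_contrasts = 0
    for _ in range(n_replicates):
        rows = []
        for g, n in (("wildtype", n_wt), ("transgenic", n_tg)):
            for i in range(n):
                for r in REGIONS_6:
                    rows.append((f"{g[:2]}{i}", g, r, "sim", "value",
                                 rng.normal(0.2, 0.05)))
        rep = compare_groups(make_cohort_table(rows), "value",
                             design="two_way_anova_bonferroni")
        n_sig += int((rep.contrasts["p_adj"] < 0.05).sum())
        n_contrasts += len(rep.contrasts)
    return {"type1_error_rate": n_sig / n_contrasts,
            "n_contrasts": n_contrasts}


def power_study(seed: int = 0, n_replicates: int = 200,
                n_wt: int = 11, n_tg: int = 8) -> float:
    """Fraction of replicates with a significant cortex contrast when groups
    are drawn from the reported cortical SRTM moments
    (0.20 +/- 0.04 wild-type vs 0.28 +/- 0.07 transgenic)."""
    rng = np.random.default_rng(seed)
    n_sig = 0
    for _ in range(n_replicates):
        rows = [(f"wt{i}", "wildtype", "cortex", "sim", "BP_ND",
                 rng.normal(0.20, 0.04)) for i in range(n_wt)]
        rows += [(f"tg{i}", "transgenic", "cortex", "sim", "BP_ND",
                  rng.normal(0.28, 0.07)) for i in range(n_tg)]
        rep = compare_groups(make_cohort_table(rows), "BP_ND", design="ttest")
        if (rep.contrasts["p_adj"] < 0.05).any():
            n_sig += 1
    return n_sig / n_replicates


# ---------------------------------------------------------------------------
# 8. end-to-end cohort studies
# ---------------------------------------------------------------------------


def cohort_detection_study(seed: int = 0, n_cohorts: int = 50
                           ) -> dict[str, float]:
    """Replicate default cohorts through the pipeline's reference-tissue
    quantification; detection means the fitted cortical SRTM BP_ND group
    mean is higher in the transgenic group. The Welch-test significance
    rate at 0.05 is reported alongside."""
    detected = 0
    significant = 0
    for k in range(n_cohorts):
        cohort_seed = (seed + k * 1009) % 2**31
        spec = CohortSpec(seed=cohort_seed)
        bundle = run_analysis(AnalysisConfig(
            cohort_spec=spec, methods=("srtm",), seed=cohort_seed))
        bp = bundle.cohort[(bundle.cohort["parameter"] == "BP_ND")
                           & (bundle.cohort["region"] == "cortex")]
        wt = bp[bp["group"] == "wildtype"]["value"].to_numpy()
        tg = bp[bp["group"] == "transgenic"]["value"].to_numpy()
        if tg.mean() > wt.mean():
            detected += 1
        if stats.ttest_ind(tg, wt, equal_var=False).pvalue < 0.05:
            significant += 1
    return {"detection_rate": detected / n_cohorts,
            "welch_significant_rate": significant / n_cohorts}


def cohort_summary(seed: int = 0) -> dict[str, float]:
    """One default cohort through the full pipeline: the headline group
    means and cross-method agreement the study reports."""
    spec = CohortSpec(seed=seed)
    bundle = run_analysis(AnalysisConfig(cohort_spec=spec, seed=seed))

    def group_mean(parameter, method, region, group):
        c = bundle.cohort
        sel = c[(c["parameter"] == parameter) & (c["method"] == method)
                & (c["region"] == region) & (c["group"] == group)]["value"]
        if parameter == "V_T" and bundle.config.vt_exclude_above is not None:
            sel = sel[sel <= bundle.config.vt_exclude_above]
        return float(sel.mean())

    cv = bundle.cross_validations
    logan_r = cv[cv["comparison"] == "vt_logan_vs_2tcm"]["pearson_r"]
    out = {
        "cortex_vt_2tcm_wildtype": group_mean("V_T", "2tcm_vb_fixed",
                                              "cortex", "wildtype"),
        "cortex_vt_2tcm_transgenic": group_mean("V_T", "2tcm_vb_fixed",
                                                "cortex", "transgenic"),
        "cortex_bp_srtm_wildtype": group_mean("BP_ND", "srtm", "cortex",
                                              "wildtype"),
        "cortex_bp_srtm_transgenic": group_mean("BP_ND", "srtm", "cortex",
                                                "transgenic"),
        "brainstem_bp_srtm_wildtype": group_mean("BP_ND", "srtm", "brainstem",
                                                 "wildtype"),
        "brainstem_bp_srtm_transgenic": group_mean("BP_ND", "srtm",
                                                   "brainstem", "transgenic"),
        "logan_vs_2tcm_vt_pearson_r_min": float(logan_r.min()),
        "n_subjects": len(bundle.log["subjects_analysed"]),
    }
    return out
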