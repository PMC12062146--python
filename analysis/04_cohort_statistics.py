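"""Cohort-level statistics and cross-method validation.

Takes the blood-based and reference-tissue fit tables from the previous
scripts plus the raw study TACs, and reproduces the study's statistical
programme: region-to-cerebellar-grey ratios and TAC areas compared by
two-way ANOVA with Bonferroni-corrected contrasts; per-method group
comparisons of V_T and BP_ND; and the cross-method regressions (Logan V_T
against two-tissue V_T; reference-model BP_ND against k3/k4 with the
k3/k4 > 1 outlier cut-off). Writes tables under results/stats/.
"""

import pathlib

import pandas as pd

from petkin.cohort_stats import (
    auc_compare,
    compare_groups,
    cross_validate,
    filter_k3k4_outliers,
    make_cohort_table,
    region_ratio,
)
from petkin.pipeline import read_cohort_dir

ROOT = pathlib.Path(__file__).resolve().parent.parent
STUDY = ROOT / "results" / "study"
OUT = ROOT / "results" / "stats"
VT_EXCLUDE_ABOVE = 20.0


def _print_contrasts(title, report):
    print(f"{title}:")
    cols = ["region", "mean_wildtype", "mean_transgenic", "p_adj", "stars"]
    print(report.contrasts[cols].round(4).to_string(index=False))
    print()


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    subjects = read_cohort_dir(STUDY)
    blood = pd.read_csv(ROOT / "results" / "blood" / "fits.csv")
    reference = pd.read_csv(ROOT / "results" / "reference" / "fits.csv")

    # ---- uptake measures ------------------------------------------------
    ratio_rows = [
        (s.subject, s.group, r, "tac", "ratio_50_60",
         region_ratio(s.tacs, r))
        for s in subjects for r in s.tacs.regions if r != "cerebellum_grey"
    ]
    ratio_rep = compare_groups(make_cohort_table(ratio_rows), "ratio_50_60",
                               design="two_way_anova_bonferroni")
    _print_contrasts("region / cerebellar-grey ratio (50-60 min)", ratio_rep)
    ratio_rep.contrasts.to_csv(OUT / "ratio_contrasts.csv", index=False,
                               float_format="%.6g")

    auc_rep = auc_compare([s.tacs for s in subjects])
    _print_contrasts("TAC area under the curve (0-60 min)", auc_rep)
    auc_rep.contrasts.to_csv(OUT / "auc_contrasts.csv", index=False,
                             float_format="%.6g")

    # ---- kinetic parameters --------------------------------------------
    comp = blood[blood.method == "2tcm_vb_fixed"].copy()
    n_vt_excluded = int((comp["V_T"] > VT_EXCLUDE_ABOVE).sum())
    comp = comp[comp["V_T"] <= VT_EXCLUDE_ABOVE]
    if n_vt_excluded:
        print(f"excluded {n_vt_excluded} two-tissue fit(s) with V_T > "
              f"{VT_EXCLUDE_ABOVE} as outliers\n")

    for df, method, parameter, label in (
            (comp, "2tcm_vb_fixed", "V_T", "V_T (two-tissue model)"),
            (blood, "logan_plasma", "V_T", "V_T (Logan)"),
            (reference, "srtm", "BP_ND", "BP_ND (SRTM)"),
            (reference, "logan_ref", "BP_ND", "BP_ND (reference Logan)")):
        rows = [(r.subject, r.group, r.region, method, parameter,
                 getattr(r, parameter))
                for r in df[df.method == method].itertuples()]
        rep = compare_groups(make_cohort_table(rows), parameter,
                             design="two_way_anova_bonferroni")
        _print_contrasts(label, rep)
        rep.contrasts.to_csv(
            OUT / f"{method}_{parameter.lower()}_contrasts.csv",
            index=False, float_format="%.6g")

    # ---- cross-method validation ---------------------------------------
    cv_rows = []
    for group in ("wildtype", "transgenic"):
        vt = comp[comp.group == group].set_index(["subject", "region"])["V_T"]
        logan = blood[(blood.method == "logan_plasma")
                      & (blood.group == group)].set_index(
            ["subject", "region"])["V_T"]
        paired = pd.concat([logan, vt], axis=1, join="inner",
                           keys=["logan", "tcm"]).dropna()
        cv = cross_validate(paired["logan"], paired["tcm"])
        cv_rows.append({"group": group, "comparison": "vt_logan_vs_2tcm",
                        **cv.__dict__})
        print(f"{group}: V_T two-tissue on V_T Logan: r={cv.pearson_r:.2f}, "
              f"y={cv.slope:.3f}x{cv.intercept:+.3f} (n={cv.n_points})")

        k3k4 = comp[comp.group == group].set_index(
            ["subject", "region"])["BP_ND"]
        kept, excluded = filter_k3k4_outliers(k3k4.to_numpy())
        k3k4 = k3k4[k3k4 <= 1.0]
        for method in ("srtm", "logan_ref"):
            bp = reference[(reference.method == method)
                           & (reference.group == group)].set_index(
                ["subject", "region"])["BP_ND"]
            paired = pd.concat([bp, k3k4], axis=1, join="inner",
                               keys=["ref", "k3k4"]).dropna()
            cv = cross_validate(paired["ref"], paired["k3k4"])
            cv_rows.append({"group": group,
                            "comparison": f"k3k4_vs_{method}",
                            **cv.__dict__})
            print(f"{group}: k3/k4 on {method} BP_ND "
                  f"({len(excluded)} outliers above 1 dropped): "
                  f"r={cv.pearson_r:.2f}, "
                  f"y={cv.slope:.3f}x{cv.intercept:+.3f}")
    pd.DataFrame(cv_rows).to_csv(OUT / "cross_validation.csv", index=False,
                                 float_format="%.6g")
    print(f"\ntables written to {OUT}")


if __name__ == "__main__":
    main()
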