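"""Cohort-level biomarker statistics.

Covers the density tallies and Pearson chi-squared contrasts over the
four chromatogram categories, the BSP (>= 50% of readable sites showing
any C) and qMSP (any detectable methylation per 150 input copies)
positivity rules, sensitivity/specificity against the pooled non-HCC
groups, empirical ROC curves with AUROC and the DeLong paired comparison,
the combined mAPC + AFP quadrant analysis, and the clinicopathological
group tests (Kruskal-Wallis, Spearman, Student t, Fisher exact).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .msp import QuantResult
from .traces import CallVector, Category, DENSITY_ORDER

NON_HCC_GROUPS = ("adjacent_non_HCC", "normal_liver", "hepatitis", "cirrhosis")

GROUPS = ("HCC",) + NON_HCC_GROUPS + ("nonliver", "fetal_liver", "mouse_liver")

DEFAULT_AFP_CUTOFF = 20.0  # ng/mL

#: categories counted as "methylation detected" for BSP positivity: any visible C
DETECTED_CATEGORIES = frozenset({Category.C_LE_T, Category.C_GT_T, Category.C_ONLY})


# ---------------------------------------------------------------------------
# density tallies and chi-squared

def density_tally(vectors: Sequence[CallVector], groups: Mapping[str, str],
                  site_subset: Sequence[int] | None = None,
                  mode: str = "all_available") -> pd.DataFrame:
    """Per-group counts of sites in each of the four categories.

    ``mode='all_available'`` counts every non-missing site call;
    ``mode='complete_cases'`` first drops any site missing in at least one
    of the vectors, so every group is tallied over the same site set.
    The MISSING column records the excluded calls for bookkeeping.
    """
    if mode not in ("all_available", "complete_cases"):
        raise ValueError(f"unknown tally mode {mode!r}")
    vectors = [v for v in vectors if v.qc_pass]
    sites: set[int] = set()
    for v in vectors:
        sites.update(v.calls)
    if site_subset is not None:
        sites &= set(site_subset)
    sites_order = sorted(sites)
    if mode == "complete_cases":
        sites_order = [s for s in sites_order
                       if all(v.calls.get(s, Category.MISSING) != Category.MISSING
                              for v in vectors)]
    group_names = sorted({groups[v.sample_id] for v in vectors})
    cols = [c.name for c in DENSITY_ORDER] + ["MISSING"]
    tally = pd.DataFrame(0, index=group_names, columns=cols, dtype=int)
    for v in vectors:
        g = groups[v.sample_id]
        for s in sites_order:
            c = v.calls.get(s, Category.MISSING)
            tally.loc[g, "MISSING" if c == Category.MISSING else c.name] += 1
    return tally


def pearson_chi2(table) -> dict:
    """Two-sided Pearson chi-squared on a contingency table, no correction."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (arr < 0).any():
        raise ValueError("counts must be nonnegative")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero-margin contingency table")
    chi2, p, dof, _ = stats.chi2_contingency(arr, correction=False)
    return {"chi2": float(chi2), "df": int(dof), "p": float(p)}


# ---------------------------------------------------------------------------
# positivity rules

def bsp_positive(v: CallVector, threshold_frac: float = 0.5,
                 detected_categories: frozenset = DETECTED_CATEGORIES) -> bool:
    """Methylation detected in >= 50% of readable CpG sites."""
    readable = v.non_missing()
    if not readable:
        raise ValueError(f"sample {v.sample_id}: all sites missing, positivity undefined")
    hits = sum(1 for c in readable.values() if c in detected_categories)
    return hits / len(readable) >= threshold_frac


def msp_positive(q: QuantResult) -> bool:
    """Any detectable methylation per 150 copies of input DNA."""
    return bool(q.detected)


def sensitivity_specificity(calls: Sequence[bool], is_hcc: Sequence[bool]) -> dict:
    calls = np.asarray(calls, dtype=bool)
    is_hcc = np.asarray(is_hcc, dtype=bool)
    if is_hcc.all() or (~is_hcc).all():
        raise ValueError("both HCC and non-HCC samples are required")
    tp = int((calls & is_hcc).sum())
    fn = int((~calls & is_hcc).sum())
    tn = int((~calls & ~is_hcc).sum())
    fp = int((calls & ~is_hcc).sum())
    return {"sensitivity": tp / (tp + fn), "specificity": tn / (tn + fp),
            "tp": tp, "fn": fn, "tn": tn, "fp": fp}


# ---------------------------------------------------------------------------
# ROC / AUROC / DeLong

@dataclass(frozen=True)
class ROCResult:
    thresholds: np.ndarray
    fpr: np.ndarray  # 1 - specificity
    tpr: np.ndarray  # sensitivity
    auroc: float
    n_pos: int
    n_neg: int


def roc(values: Sequence[float], is_hcc: Sequence[bool]) -> ROCResult:
    """Empirical ROC over all distinct thresholds; AUROC by trapezoid.

    Ties take simultaneous steps, so the AUROC equals the Mann-Whitney
    statistic U/(n_pos * n_neg) with ties counted 1/2.
    """
    values = np.asarray(values, dtype=float)
    y = np.asarray(is_hcc, dtype=int)
    if y.all() or (1 - y).all():
        raise ValueError("both classes are required for a ROC curve")
    if np.unique(values).size == 1:
        warnings.warn("constant marker values: AUROC is 0.5 by convention", stacklevel=2)
        return ROCResult(np.array([values[0]]), np.array([0.0, 1.0]),
                         np.array([0.0, 1.0]), 0.5, int(y.sum()), int((1 - y).sum()))
    fpr, tpr, thr = _sk_roc_curve(y, values)
    return ROCResult(thr, fpr, tpr, float(_sk_auc(fpr, tpr)),
                     int(y.sum()), int((1 - y).sum()))


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(values: np.ndarray, y: np.ndarray):
    """Per-subject structural components V10 (positives) and V01 (negatives)."""
    pos = values[y]
    neg = values[~y]
    m, n = len(pos), len(neg)
    tx = _midrank(pos)
    ty = _midrank(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    return auc, v10, v01


def compare_roc(values_a: Sequence[float], values_b: Sequence[float],
                is_hcc: Sequence[bool], paired: bool = True) -> dict:
    """DeLong test for two correlated (paired) ROC curves; two-sided p."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    y = np.asarray(is_hcc, dtype=bool)
    if paired and not (len(a) == len(b) == len(y)):
        raise ValueError("paired comparison requires markers measured on the same samples")
    if y.all() or (~y).all():
        raise ValueError("both classes are required")
    auc_a, v10_a, v01_a = _delong_components(a, y)
    auc_b, v10_b, v01_b = _delong_components(b, y)
    v10 = np.vstack([v10_a, v10_b])
    v01 = np.vstack([v01_a, v01_b])
    s10 = np.cov(v10)
    s01 = np.cov(v01)
    cov = s10 / v10.shape[1] + s01 / v01.shape[1]
    var = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    diff = auc_a - auc_b
    if var <= 0:
        p = 1.0 if abs(diff) < 1e-12 else 0.0
        z = 0.0 if abs(diff) < 1e-12 else np.inf
    else:
        z = diff / np.sqrt(var)
        p = 2.0 * stats.norm.sf(abs(z))
    return {"auc_a": float(auc_a), "auc_b": float(auc_b),
            "z": float(z), "p": float(p)}


# ---------------------------------------------------------------------------
# combined mAPC + AFP analysis

def combined_marker(records: pd.DataFrame,
                    afp_cutoff: float = DEFAULT_AFP_CUTOFF) -> dict:
    """Quadrant analysis of mAPC positivity against AFP >= cutoff in HCC.

    ``records`` needs columns ``mapc_positive`` (bool) and ``afp_ng_ml``;
    rows without an AFP value are rejected.  Percentages are on the 0-100
    scale.
    """
    if "afp_ng_ml" not in records or records["afp_ng_ml"].isna().any():
        raise ValueError("AFP must be available for every included sample")
    mapc = records["mapc_positive"].astype(bool).to_numpy()
    afp = records["afp_ng_ml"].to_numpy(dtype=float) >= afp_cutoff
    n = len(records)
    if n == 0:
        raise ValueError("no samples")
    n_pp = int((mapc & afp).sum())
    n_pn = int((mapc & ~afp).sum())
    n_np = int((~mapc & afp).sum())
    n_nn = int((~mapc & ~afp).sum())
    n_mapc = n_pp + n_pn
    return {
        "n": n,
        "quadrants": {"mapc+afp+": n_pp, "mapc+afp-": n_pn,
                      "mapc-afp+": n_np, "mapc-afp-": n_nn},
        "pct_mapc_pos": 100.0 * n_mapc / n,
        "pct_afp_pos": 100.0 * (n_pp + n_np) / n,
        "pct_union_pos": 100.0 * (n_pp + n_pn + n_np) / n,
        "pct_mapc_pos_afp_neg_of_mapc_pos":
            (100.0 * n_pn / n_mapc) if n_mapc else 0.0,
        "pct_additional_over_afp": 100.0 * n_pn / n,
    }


# ---------------------------------------------------------------------------
# clinicopathological group tests

def _kruskal(groups: list[np.ndarray], label: str) -> dict | None:
    groups = [g for g in groups if len(g) > 0]
    if len(groups) < 2:
        warnings.warn(f"{label}: fewer than two nonempty groups, test skipped",
                      stacklevel=3)
        return None
    stat, p = stats.kruskal(*groups)
    return {"statistic": float(stat), "p": float(p),
            "n": [int(len(g)) for g in groups]}


def group_tests(cohort: pd.DataFrame, afp_cutoff: float = DEFAULT_AFP_CUTOFF) -> dict:
    """Distribution of sense-mAPC values across clinical subgroups of HCC.

    Expects columns: group, age, sex, stage, grade, hbv, hcv, afp_ng_ml and
    sense_msp_value.  Stages 2-4 and grades 2-3 are pooled.  Age (Student t)
    and sex (Fisher exact) compare HCC against all non-HCC subjects.
    """
    hcc = cohort[cohort["group"] == "HCC"]
    non = cohort[cohort["group"] != "HCC"]
    out: dict = {}

    def vals(mask) -> np.ndarray:
        return hcc.loc[mask, "sense_msp_value"].dropna().to_numpy(dtype=float)

    stage = pd.to_numeric(hcc.get("stage"), errors="coerce")
    out["kruskal_stage"] = _kruskal([vals(stage == 1), vals(stage.isin([2, 3, 4]))],
                                    "stage 1 vs 2-4")
    grade = pd.to_numeric(hcc.get("grade"), errors="coerce")
    out["kruskal_grade"] = _kruskal([vals(grade == 1), vals(grade.isin([2, 3]))],
                                    "grade 1 vs 2-3")
    for flag in ("hbv", "hcv"):
        f = hcc[flag].astype(bool)
        out[f"kruskal_{flag}"] = _kruskal([vals(f), vals(~f)], flag)
    afp = hcc["afp_ng_ml"].astype(float)
    out["kruskal_afp_group"] = _kruskal(
        [vals(afp < afp_cutoff), vals(afp >= afp_cutoff)], "AFP group")

    known = hcc.dropna(subset=["afp_ng_ml", "sense_msp_value"])
    if len(known) >= 3:
        rho, p = stats.spearmanr(known["sense_msp_value"], known["afp_ng_ml"])
        out["spearman_mapc_afp"] = {"rho": float(rho), "p": float(p), "n": len(known)}
    else:
        out["spearman_mapc_afp"] = None

    age_h = hcc["age"].dropna().to_numpy(dtype=float)
    age_n = non["age"].dropna().to_numpy(dtype=float)
    if len(age_h) >= 2 and len(age_n) >= 2:
        t, p = stats.ttest_ind(age_h, age_n)
        out["student_t_age"] = {"t": float(t), "p": float(p)}
    else:
        out["student_t_age"] = None

    sex_tab = np.array([
        [(hcc["sex"] == "M").sum(), (hcc["sex"] == "F").sum()],
        [(non["sex"] == "M").sum(), (non["sex"] == "F").sum()],
    ])
    if (sex_tab.sum(axis=1) > 0).all():
        odds, p = stats.fisher_exact(sex_tab)
        out["fisher_sex"] = {"odds_ratio": float(odds), "p": float(p)}
    else:
        out["fisher_sex"] = None
    return out
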