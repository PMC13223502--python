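"""The study-level statistical pipeline.

Implements the analysis plan of a three-group diagnostic imaging study:
Shapiro-Wilk normality screening (which decides mean+/-SD vs median(IQR)
presentation), Mann-Whitney U for two-group ordinal comparisons,
Kruskal-Wallis with Dunn's Bonferroni-adjusted post hoc for three groups
(one-way ANOVA with Bonferroni t-tests on the normal branch),
tie-aware Spearman correlation with Bonferroni adjustment, two-way
random-effects absolute-agreement single-measure ICC(2,1) for inter-reader
agreement, Pearson chi-square for categorical tables, and ROC analysis
with the empirical AUC, DeLong confidence interval/p-value and the
Youden-optimal operating threshold.

Rank-based machinery comes from scipy/scikit-learn; Dunn's z statistics
and the DeLong covariance are computed here (standard formulas).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score, roc_curve

from .cohort import PARAM_NAMES

__all__ = [
    "NormalityResult",
    "MannWhitneyResult",
    "DunnResult",
    "KruskalResult",
    "CorrelationResult",
    "ICCResult",
    "RocResult",
    "StudyResults",
    "normality_screen",
    "mann_whitney",
    "kruskal_wallis_posthoc",
    "anova_posthoc",
    "spearman_bonferroni",
    "icc_two_reader",
    "roc_analysis",
    "chi_square_counts",
    "build_study_report",
    "bonferroni",
]

GROUP_ORDER = ("control", "high_egfr", "low_egfr")
DISPLAY_SCALE = {"adc": 1e3, "adc_slow": 1e3, "adc_fast": 1e3,
                 "f": 1.0, "ddc": 1e3, "alpha": 1.0}


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value, capped at 1 and monotone in ``p``."""
    return float(min(1.0, m * p))


@dataclass(frozen=True)
class NormalityResult:
    classification: str  # "normal" | "non_normal"
    p: float
    flags: tuple[str, ...] = ()


def normality_screen(values, alpha: float = 0.05) -> NormalityResult:
    """Shapiro-Wilk screen at the given alpha.

    A constant vector has no defined W statistic; it is classified
    ``non_normal`` with a ``degenerate`` flag (documented behavior).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("normality screening needs n >= 3")
    if np.ptp(x) == 0:
        return NormalityResult("non_normal", float("nan"), ("degenerate",))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, p = sps.shapiro(x)
    return NormalityResult("normal" if p >= alpha else "non_normal", float(p))


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float  # first-sample-sided U statistic
    p: float  # two-sided
    method: str  # "exact" | "asymptotic"


def mann_whitney(a, b) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test (first-group-sided U).

    Exact null enumeration when n1*n2 <= 400 and there are no ties;
    tie-corrected normal approximation otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size * b.size <= 400 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return MannWhitneyResult(float(res.statistic), float(res.pvalue), method)


@dataclass(frozen=True)
class DunnResult:
    z: float
    p_raw: float
    p_adj: float


@dataclass(frozen=True)
class KruskalResult:
    h: float
    p: float
    pairwise: dict[tuple[int, int], DunnResult]


def kruskal_wallis_posthoc(groups) -> KruskalResult:
    """Kruskal-Wallis omnibus test + Dunn's pairwise post hoc.

    Pairwise z statistics use the tie-corrected rank variance; raw
    two-sided p-values are Bonferroni-multiplied by the number of pairs
    and capped at 1 (so indistinguishable groups print an adjusted 1).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) != 3:
        raise ValueError("expected exactly 3 groups; use mann_whitney for 2")
    if any(g.size == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    h, p = sps.kruskal(*groups)
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    sizes = [g.size for g in groups]
    edges = np.cumsum([0] + sizes)
    mean_ranks = [ranks[edges[i]:edges[i + 1]].mean() for i in range(3)]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    pairwise = {}
    n_pairs = 3
    for i, j in ((0, 1), (0, 2), (1, 2)):
        se = math.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p_raw = 2.0 * sps.norm.sf(abs(z))
        pairwise[(i, j)] = DunnResult(float(z), float(p_raw),
                                      bonferroni(p_raw, n_pairs))
    return KruskalResult(float(h), float(p), pairwise)


def anova_posthoc(groups) -> KruskalResult:
    """One-way ANOVA + pairwise Welch t-tests with Bonferroni (normal branch)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) != 3:
        raise ValueError("expected exactly 3 groups")
    f, p = sps.f_oneway(*groups)
    pairwise = {}
    for i, j in ((0, 1), (0, 2), (1, 2)):
        t, p_raw = sps.ttest_ind(groups[i], groups[j], equal_var=False)
        pairwise[(i, j)] = DunnResult(float(t), float(p_raw), bonferroni(p_raw, 3))
    return KruskalResult(float(f), float(p), pairwise)


@dataclass(frozen=True)
class CorrelationResult:
    parameter: str
    target: str
    rho: float
    p_raw: float
    p_adj: float
    n: int
    family_size: int


def spearman_bonferroni(params, targets, family_size: int | None = None):
    """Spearman rho (average ranks for ties) for every parameter-target pair.

    ``params`` and ``targets`` are mappings from name to equal-length
    vectors.  Raw p-values are Bonferroni-adjusted within a family whose
    size defaults to the number of parameters (one family per target
    column); the family size is recorded in each result so alternative
    conventions are auditable.
    """
    params = {k: np.asarray(v, dtype=float) for k, v in params.items()}
    targets = {k: np.asarray(v, dtype=float) for k, v in targets.items()}
    m = family_size if family_size is not None else len(params)
    out = []
    for tname, tv in targets.items():
        for pname, pv in params.items():
            if pv.shape != tv.shape:
                raise ValueError(
                    f"length mismatch between {pname} and {tname}: "
                    f"{pv.shape} vs {tv.shape}"
                )
            if pv.size < 3:
                raise ValueError("spearman correlation needs n >= 3")
            rho, p = sps.spearmanr(pv, tv)
            out.append(CorrelationResult(pname, tname, float(rho), float(p),
                                         bonferroni(p, m), pv.size, m))
    return out


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float


def icc_two_reader(matrix) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    ``matrix`` is subjects x 2 readers with no missing cells.  The 95%
    confidence interval follows the standard F-based construction
    (as implemented by pingouin).
    """
    import pingouin as pg  # deferred: pingouin import is heavy

    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] != 2:
        raise ValueError("expected a subjects x 2 matrix")
    if m.shape[0] < 5:
        raise ValueError("ICC needs >= 5 subjects")
    if not np.isfinite(m).all():
        raise ValueError("missing or non-finite cells are not allowed")
    n = m.shape[0]
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(n), 2),
        "reader": np.tile(["a", "b"], n),
        "value": m.reshape(-1),
    })
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = pg.intraclass_corr(data=long, targets="subject", raters="reader",
                                 ratings="value")
    # absolute-agreement single-measures row; label varies across versions
    mask = res["Type"].isin(["ICC2", "ICC(A,1)"])
    row = res.loc[mask].iloc[0]
    ci_col = "CI95%" if "CI95%" in res.columns else "CI95"
    lo, hi = row[ci_col]
    return ICCResult(float(row["ICC"]), float(lo), float(hi))


@dataclass(frozen=True)
class RocResult:
    marker: str
    contrast: str
    auc: float
    ci95: tuple[float, float]
    youden: float
    threshold: float
    direction: str  # "<=" (low marker predicts disease) or ">"
    sensitivity: float
    specificity: float
    p_raw: float
    p_adj: float
    auc_se: float


def _delong_auc_variance(pos, neg):
    """Empirical AUC and its DeLong variance from class-wise scores."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    m, n = pos.size, neg.size
    allv = np.concatenate([pos, neg])
    rank_all = sps.rankdata(allv)
    rank_pos = sps.rankdata(pos)
    rank_neg = sps.rankdata(neg)
    v10 = (rank_all[:m] - rank_pos) / n  # placement of each positive
    v01 = 1.0 - (rank_all[m:] - rank_neg) / m  # placement of each negative
    auc = v10.mean()
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def roc_analysis(marker, labels, marker_name: str = "marker",
                 contrast: str = "", direction: str = "auto",
                 family_size: int = 1) -> RocResult:
    """ROC analysis of a continuous marker against binary disease labels.

    The reported AUC is the empirical (trapezoidal/Mann-Whitney) AUC of the
    discriminating direction: for markers lower in disease the decision
    rule is ``marker <= threshold -> disease`` and the threshold is
    reported on the original marker scale.  The operating point maximizes
    the Youden index (sensitivity + specificity - 1); ties go to the first
    (most conservative) threshold encountered.  The 95% CI and the p-value
    against AUC = 0.5 use DeLong's variance estimate.
    """
    marker = np.asarray(marker, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    if direction == "auto":
        direction = "<=" if roc_auc_score(labels, marker) < 0.5 else ">"
    if direction not in ("<=", ">"):
        raise ValueError(f"direction must be '<=' or '>', got {direction!r}")
    score = -marker if direction == "<=" else marker
    auc, var = _delong_auc_variance(score[labels], score[~labels])
    se = math.sqrt(max(var, 0.0))
    ci = (max(0.0, auc - 1.959963984540054 * se),
          min(1.0, auc + 1.959963984540054 * se))
    if se > 0:
        z = (auc - 0.5) / se
        p_raw = 2.0 * sps.norm.sf(abs(z))
    else:
        p_raw = 1.0 if auc == 0.5 else 0.0
    fpr, tpr, thr = roc_curve(labels, score)
    j = tpr - fpr
    k = int(np.argmax(j))
    threshold = float(-thr[k] if direction == "<=" else thr[k])
    return RocResult(
        marker=marker_name, contrast=contrast, auc=auc, ci95=ci,
        youden=float(j[k]), threshold=threshold, direction=direction,
        sensitivity=float(tpr[k]), specificity=float(1.0 - fpr[k]),
        p_raw=float(p_raw), p_adj=bonferroni(p_raw, family_size),
        auc_se=se,
    )


def chi_square_counts(table):
    """Pearson chi-square on an r x k count table (no continuity correction)."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise ValueError("expected a 2-D contingency table")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("table must hold nonnegative integer counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero row or column marginal")
    stat, p, dof, _ = sps.chi2_contingency(t, correction=False)
    return float(stat), float(p), int(dof)


# ---------------------------------------------------------------------------
# Study-level report assembly


@dataclass
class StudyResults:
    """Result tables mirroring the study's published table structure."""

    demographics: pd.DataFrame
    parameters: pd.DataFrame
    pathology: pd.DataFrame
    correlations: pd.DataFrame
    roc: pd.DataFrame
    icc: pd.DataFrame
    roc_points: dict[str, pd.DataFrame] = field(default_factory=dict)


def _summary(values, normal: bool) -> str:
    v = np.asarray(values, dtype=float)
    if normal:
        return f"{v.mean():.3g} ± {v.std(ddof=1):.3g}"
    q25, med, q75 = np.percentile(v, [25, 50, 75])
    return f"{med:.4g} ({q25:.4g}, {q75:.4g})"


def _three_group_row(name, groups, display_scale=1.0):
    scaled = [np.asarray(g, dtype=float) * display_scale for g in groups]
    normal = all(normality_screen(g).classification == "normal" for g in scaled)
    omni = anova_posthoc(scaled) if normal else kruskal_wallis_posthoc(scaled)
    row = {"variable": name,
           "distribution": "normal" if normal else "non_normal",
           "test": "anova" if normal else "kruskal_wallis"}
    for label, g in zip(GROUP_ORDER, scaled):
        row[label] = _summary(g, normal)
    row["p_omnibus"] = omni.p
    row["p_control_vs_high"] = omni.pairwise[(0, 1)].p_adj
    row["p_control_vs_low"] = omni.pairwise[(0, 2)].p_adj
    row["p_high_vs_low"] = omni.pairwise[(1, 2)].p_adj
    return row


def build_study_report(subjects_df: pd.DataFrame,
                       param_values: pd.DataFrame,
                       reader_pairs: pd.DataFrame | None = None,
                       pathology_df: pd.DataFrame | None = None) -> StudyResults:
    """Assemble the full set of study result tables.

    Parameters
    ----------
    subjects_df : one row per subject with ``subject_id, group, age, sex,
        scr_umol_l, egfr``.
    param_values : one row per subject with ``subject_id`` and one column
        per cortical parameter (internal units; the analysis reader).
    reader_pairs : optional; per parameter, columns ``{param}_reader_a``
        and ``{param}_reader_b`` for the inter-reader agreement table.
    pathology_df : optional; per-patient biopsy scores.
    """
    df = subjects_df.merge(param_values, on="subject_id", validate="1:1")
    by_group = {g: df[df["group"] == g] for g in GROUP_ORDER}
    for g, sub in by_group.items():
        if sub.empty:
            raise ValueError(f"group {g!r} is empty")

    # demographics table
    demo_rows = [_three_group_row("age", [by_group[g]["age"] for g in GROUP_ORDER])]
    sex_counts = np.array([
        [(by_group[g]["sex"] == "male").sum() for g in GROUP_ORDER],
        [(by_group[g]["sex"] == "female").sum() for g in GROUP_ORDER],
    ])
    chi, chi_p, _ = chi_square_counts(sex_counts)
    demo_rows.append({
        "variable": "sex_male_female",
        "control": f"{sex_counts[0, 0]}/{sex_counts[1, 0]}",
        "high_egfr": f"{sex_counts[0, 1]}/{sex_counts[1, 1]}",
        "low_egfr": f"{sex_counts[0, 2]}/{sex_counts[1, 2]}",
        "test": "chi_square", "p_omnibus": chi_p,
    })
    for var in ("scr_umol_l", "egfr"):
        demo_rows.append(_three_group_row(var, [by_group[g][var] for g in GROUP_ORDER]))
    demographics = pd.DataFrame(demo_rows)

    # parameter comparison table (display units: 1e-3 mm^2/s for diffusivities)
    param_cols = [p for p in PARAM_NAMES if p in param_values.columns]
    parameters = pd.DataFrame([
        _three_group_row(p, [by_group[g][p] for g in GROUP_ORDER],
                         DISPLAY_SCALE[p])
        for p in param_cols
    ])

    # pathology comparison (high vs low eGFR patients)
    path_rows = []
    if pathology_df is not None and not pathology_df.empty:
        for comp in ("glomerular", "tubulointerstitial", "vasculopathy", "total"):
            hi = pathology_df.loc[pathology_df["group"] == "high_egfr", comp]
            lo = pathology_df.loc[pathology_df["group"] == "low_egfr", comp]
            mw = mann_whitney(hi, lo)
            path_rows.append({
                "score": comp,
                "high_egfr": _summary(hi, normal=False),
                "low_egfr": _summary(lo, normal=False),
                "u": mw.u, "p": mw.p, "method": mw.method,
            })
    pathology = pd.DataFrame(
        path_rows, columns=["score", "high_egfr", "low_egfr", "u", "p", "method"]
    )

    # correlations: parameters vs eGFR (all subjects) and biopsy scores (patients)
    corr_results = list(spearman_bonferroni(
        {p: df[p] for p in param_cols}, {"egfr": df["egfr"]}
    ))
    if pathology_df is not None and not pathology_df.empty:
        pat = df.merge(pathology_df[["subject_id", "glomerular",
                                     "tubulointerstitial", "vasculopathy",
                                     "total"]], on="subject_id")
        corr_results += spearman_bonferroni(
            {p: pat[p] for p in param_cols},
            {t: pat[t] for t in ("glomerular", "tubulointerstitial",
                                 "vasculopathy", "total")},
        )
    correlations = pd.DataFrame([vars(c) for c in corr_results])

    # ROC: control vs all CKD, and control vs preserved-eGFR CKD
    roc_rows, roc_points = [], {}
    contrasts = {
        "control_vs_ckd": df["group"] != "control",
        "control_vs_high": df["group"].isin(["control", "high_egfr"]),
    }
    for cname, mask in contrasts.items():
        sub = df[mask] if cname == "control_vs_high" else df
        labels = (sub["group"] != "control").to_numpy()
        for p in param_cols:
            scale = DISPLAY_SCALE[p]
            res = roc_analysis(sub[p].to_numpy() * scale, labels,
                               marker_name=p, contrast=cname,
                               family_size=len(param_cols))
            row = vars(res).copy()
            row["ci_low"], row["ci_high"] = row.pop("ci95")
            roc_rows.append(row)
            score = -sub[p].to_numpy() * scale if res.direction == "<=" \
                else sub[p].to_numpy() * scale
            fpr, tpr, _ = roc_curve(labels, score)
            roc_points[f"{cname}__{p}"] = pd.DataFrame({"fpr": fpr, "tpr": tpr})
    roc = pd.DataFrame(roc_rows)

    # inter-reader agreement
    icc_rows = []
    if reader_pairs is not None:
        rp = subjects_df[["subject_id"]].merge(reader_pairs, on="subject_id")
        for p in param_cols:
            a, b = f"{p}_reader_a", f"{p}_reader_b"
            if a in rp.columns and b in rp.columns:
                r = icc_two_reader(rp[[a, b]].to_numpy())
                icc_rows.append({"parameter": p, "icc": r.icc,
                                 "ci_low": r.ci_low, "ci_high": r.ci_high})
    icc = pd.DataFrame(icc_rows, columns=["parameter", "icc", "ci_low", "ci_high"])

    return StudyResults(demographics=demographics, parameters=parameters,
                        pathology=pathology, correlations=correlations,
                        roc=roc, icc=icc, roc_points=roc_points)
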