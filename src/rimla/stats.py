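"""Univariate analysis of lesion-class differences.

The main tool is the aligned-rank-transform (ART) ANOVA: a
nonparametric factorial ANOVA obtained by removing the nuisance fixed
effects (patient and disease course) from the response by additive
least squares, ranking the aligned values with mid-ranks, and running a
fixed-effects ANOVA on the ranks. The class effect is reported as an F
ratio with its p value and a partial eta-squared effect size
(SS_class / (SS_class + SS_residual) on the ranked response). Post-hoc
pairwise comparisons use rank-sum tests on the aligned response with
Holm step-down correction; relapsing-remitting vs secondary-progressive
contrasts use the Wilcoxon rank-sum test.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclasses.dataclass
class ArtAnovaResult:
    metric: str
    F: float
    p: float
    eta_sq: float
    df_effect: int
    df_resid: int
    posthoc: dict[tuple[str, str], float]
    group_medians: dict[str, float]
    group_iqrs: dict[str, float]
    p_adj: float = np.nan


def holm_adjust(pvals) -> np.ndarray:
    """Holm step-down multiplicity adjustment.

    Sort ascending, multiply the i-th smallest by (m - i + 1), enforce
    monotonicity with a running maximum, cap at 1, return in the input
    order.
    """
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * (m - np.arange(m))
    adj = np.minimum(np.maximum.accumulate(adj), 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def _dummies(codes: np.ndarray) -> np.ndarray:
    """Treatment-coded dummy columns (first level dropped)."""
    levels = pd.unique(codes)
    if len(levels) < 2:
        return np.empty((codes.size, 0))
    return np.column_stack([(codes == lv).astype(float) for lv in levels[1:]])


def _align(values, patients, phenotypes) -> np.ndarray:
    """Subtract least-squares patient and disease-course effects.

    With a single patient and a single disease course this reduces to
    subtracting the grand mean, leaving ranks unchanged.
    """
    y = np.asarray(values, dtype=float)
    X = np.column_stack(
        [np.ones(y.size), _dummies(np.asarray(patients)), _dummies(np.asarray(phenotypes))]
    )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def _rank_anova_f(ranks, classes, patients, phenotypes):
    """F test for the class effect in a fixed-effects ANOVA on ranks."""
    r = np.asarray(ranks, dtype=float)
    Xn = np.column_stack(
        [np.ones(r.size), _dummies(np.asarray(patients)), _dummies(np.asarray(phenotypes))]
    )
    Xc = _dummies(np.asarray(classes))
    Xf = np.column_stack([Xn, Xc])

    def ssr(X):
        beta, *_ = np.linalg.lstsq(X, r, rcond=None)
        resid = r - X @ beta
        return float(resid @ resid), np.linalg.matrix_rank(X)

    ss_red, rank_red = ssr(Xn)
    ss_full, rank_full = ssr(Xf)
    df_eff = rank_full - rank_red
    df_res = r.size - rank_full
    if df_eff <= 0 or df_res <= 0:
        raise ValueError("insufficient degrees of freedom for the class effect")
    ss_class = ss_red - ss_full
    F = (ss_class / df_eff) / (ss_full / df_res)
    p = float(sps.f.sf(F, df_eff, df_res))
    eta_sq = ss_class / (ss_class + ss_full) if (ss_class + ss_full) > 0 else 0.0
    return float(F), p, float(eta_sq), df_eff, df_res


def art_anova(
    values,
    classes,
    patients=None,
    phenotypes=None,
    metric: str = "",
    posthoc: bool = True,
) -> ArtAnovaResult:
    """Aligned-rank-transform ANOVA for the lesion-class effect.

    ``patients`` and ``phenotypes`` are fixed nuisance effects used both
    in the alignment and in the rank-stage model. Classes with fewer
    than 2 observations are dropped with a warning.
    """
    values = np.asarray(values, dtype=float)
    classes = np.asarray(classes)
    n = values.size
    patients = np.asarray(patients) if patients is not None else np.zeros(n)
    phenotypes = np.asarray(phenotypes) if phenotypes is not None else np.zeros(n)

    ok = np.isfinite(values)
    lv, cnt = np.unique(classes[ok], return_counts=True)
    small = set(lv[cnt < 2])
    if small:
        warnings.warn(f"dropping classes with <2 observations: {sorted(map(str, small))}",
                      stacklevel=2)
        ok &= ~np.isin(classes, list(small))
    if np.unique(classes[ok]).size < 2:
        raise ValueError("art_anova needs >= 2 classes with >= 2 observations each")
    values, classes = values[ok], classes[ok]
    patients, phenotypes = patients[ok], phenotypes[ok]

    aligned = _align(values, patients, phenotypes)
    ranks = sps.rankdata(aligned, method="average")
    F, p, eta, df_e, df_r = _rank_anova_f(ranks, classes, patients, phenotypes)

    ph = (
        posthoc_pairwise(aligned, classes)
        if posthoc
        else {}
    )
    med = {str(c): float(np.median(values[classes == c])) for c in np.unique(classes)}
    iqr = {
        str(c): float(np.subtract(*np.percentile(values[classes == c], [75, 25])))
        for c in np.unique(classes)
    }
    return ArtAnovaResult(metric, F, p, eta, df_e, df_r, ph, med, iqr)


def posthoc_pairwise(aligned_values, classes, adjust: str = "holm"):
    """Pairwise rank-sum tests between classes on the aligned response.

    Returns Holm-adjusted p values keyed by the (sorted) class pair.
    """
    aligned_values = np.asarray(aligned_values, dtype=float)
    classes = np.asarray(classes)
    levels = sorted(map(str, np.unique(classes)))
    pairs, raw = [], []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            a = aligned_values[classes.astype(str) == levels[i]]
            b = aligned_values[classes.astype(str) == levels[j]]
            res = sps.mannwhitneyu(a, b, alternative="two-sided")
            pairs.append((levels[i], levels[j]))
            raw.append(res.pvalue)
    if adjust == "holm":
        adj = holm_adjust(raw)
    elif adjust in (None, "none"):
        adj = np.asarray(raw)
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return {pair: float(p) for pair, p in zip(pairs, adj)}


def subgroup_wilcoxon(values, groups, group_a="RR", group_b="SP"):
    """Two-sided Wilcoxon rank-sum comparison of two patient subgroups.

    Returns (U statistic for ``group_a``, p). Uses the exact null for
    small untied samples and the tie-corrected normal approximation
    otherwise (scipy's automatic policy).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    a = values[groups == group_a]
    b = values[groups == group_b]
    if a.size == 0 or b.size == 0:
        raise ValueError(f"empty subgroup: n({group_a})={a.size}, n({group_b})={b.size}")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def analyze_feature_table(
    table: pd.DataFrame,
    metrics: list[str],
    class_col: str = "rimla_label",
    patient_col: str = "patient_id",
    phenotype_col: str = "phenotype",
) -> pd.DataFrame:
    """Run the ART-ANOVA over a family of metrics with Holm correction.

    Produces a tidy table (metric, F, p, p_adj, eta_sq, per-class median
    and IQR, post-hoc pairwise p values), the layout of the univariate
    results table.
    """
    results = [
        art_anova(
            table[m].to_numpy(),
            table[class_col].to_numpy(),
            table[patient_col].to_numpy(),
            table[phenotype_col].to_numpy(),
            metric=m,
        )
        for m in metrics
    ]
    adj = holm_adjust([r.p for r in results])
    rows = []
    for r, pa in zip(results, adj):
        r.p_adj = float(pa)
        row = {
            "metric": r.metric,
            "F": r.F,
            "p": r.p,
            "p_adj": r.p_adj,
            "eta_sq": r.eta_sq,
        }
        for c, v in r.group_medians.items():
            row[f"median_{c}"] = v
            row[f"iqr_{c}"] = r.group_iqrs[c]
        for (a, b), p in r.posthoc.items():
            row[f"posthoc_{a}_vs_{b}"] = p
        rows.append(row)
    return pd.DataFrame(rows)
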