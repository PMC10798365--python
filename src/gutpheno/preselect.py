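"""Candidate-variable screening.

Taxa are screened by a negative-binomial Wald test on size-factor-normalized
counts (median-of-ratios normalization, method-of-moments dispersion,
delta-method standard error) with Benjamini-Hochberg adjustment across taxa.
Quantitative phenotype variables are screened nonparametrically (Mann-Whitney
for two groups; Kruskal-Wallis gate followed by rank-based many-to-one
comparisons against the control with Holm adjustment when more groups are
present).  Qualitative variables are screened by Pearson's chi-square test of
independence.  Variables passing their test at ``alpha`` form the candidate
set handed to the bootstrap forest engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DATestResult",
    "CandidateSet",
    "size_factors",
    "nb_wald_da",
    "bh_adjust",
    "mann_whitney_u",
    "kruskal_wallis",
    "posthoc_vs_control",
    "chi_square_test",
    "shapiro_normality",
    "select_candidates",
    "split_phenotype_columns",
]

#: sentinel magnitude for log2 fold-changes where one group has zero counts
LFC_SENTINEL = np.inf


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample size factors, normalized to geometric mean 1.

    The geometric-mean reference is built from taxa observed in every sample;
    if no taxon qualifies, falls back to geometric means over positive counts
    only (ratios taken where the sample's count is positive).
    """
    x = counts.to_numpy(dtype=float)
    if x.shape[1] == 0:
        raise ValueError("count table has no taxa")
    all_nonzero = (x > 0).all(axis=0)
    if all_nonzero.any():
        ref = x[:, all_nonzero]
        geo = np.exp(np.mean(np.log(ref), axis=0))
        ratios = ref / geo
        factors = np.median(ratios, axis=1)
    else:
        any_pos = (x > 0).any(axis=0)
        if not any_pos.any():
            raise ValueError("no taxon with positive geometric mean; cannot "
                             "compute size factors")
        with np.errstate(divide="ignore"):
            logx = np.where(x[:, any_pos] > 0, np.log(x[:, any_pos]), np.nan)
        geo = np.full(x.shape[1], np.nan)
        geo[any_pos] = np.exp(np.nanmean(logx, axis=0))
        usable = np.isfinite(geo) & (geo > 0)
        factors = np.empty(x.shape[0])
        for j in range(x.shape[0]):
            r = x[j, usable] / geo[usable]
            r = r[x[j, usable] > 0]
            if r.size == 0:
                raise ValueError(
                    f"sample {counts.index[j]!r} shares no positive taxon with "
                    "the geometric reference"
                )
            factors[j] = np.median(r)
    if (factors <= 0).any():
        bad = counts.index[factors <= 0].tolist()
        raise ValueError(f"non-positive size factor for samples {bad}")
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.index, name="size_factor")


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order.

    q_(i) = min_{j >= i} (m / j) * p_(j), capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


@dataclass
class DATestResult:
    """Per-taxon negative-binomial Wald differential-abundance results."""

    table: pd.DataFrame  # columns: base_mean, log2_fc, se, stat, pvalue, padj

    def significant(self, alpha: float = 0.05) -> list[str]:
        t = self.table
        return sorted(t.index[t["padj"] < alpha])


def nb_wald_da(
    counts: pd.DataFrame,
    labels: pd.Series,
    case: str,
    control: str,
    min_prevalence: float = 0.1,
) -> DATestResult:
    """Negative-binomial Wald test of case vs control abundance per taxon.

    Counts are normalized by median-of-ratios size factors; per-taxon
    dispersion is estimated by a bias-corrected method of moments on
    normalized counts within groups (floored at 1e-8); the Wald statistic is
    log2(case mean / control mean) over its delta-method standard error.
    Two-sided p-values use a t reference with n1 + n2 - 2 degrees of freedom
    (the dispersion is estimated from modest group sizes, so the null
    statistic is t-like rather than normal); BH adjustment across testable
    taxa.

    Taxa observed in fewer than ``min_prevalence`` of the samples are dropped
    before testing.  Taxa with an all-zero group keep a signed infinite
    fold-change and NaN p-value and are excluded from the BH family.
    """
    labels = labels.loc[counts.index]
    mask_case = (labels == case).to_numpy()
    mask_ctrl = (labels == control).to_numpy()
    if mask_case.sum() < 2 or mask_ctrl.sum() < 2:
        raise ValueError("both groups need at least 2 samples")
    sub = counts.loc[mask_case | mask_ctrl]
    labels = labels.loc[sub.index]

    prevalence = (sub > 0).mean(axis=0)
    kept = sub.loc[:, prevalence >= min_prevalence]
    if kept.shape[1] == 0:
        raise ValueError("no taxon passes the prevalence filter")

    sf = size_factors(kept)
    norm = kept.to_numpy(dtype=float) / sf.to_numpy()[:, None]
    is_case = (labels == case).to_numpy()
    n_case, n_ctrl = int(is_case.sum()), int((~is_case).sum())

    mu_case = norm[is_case].mean(axis=0)
    mu_ctrl = norm[~is_case].mean(axis=0)
    base_mean = norm.mean(axis=0)

    # Method-of-moments dispersion from pooled within-group moments:
    # Var(K_norm) ~= mu/s + disp * mu^2; approximate 1/s by its sample mean.
    # The denominator mu^2 - var/n is the bias-corrected moment estimator
    # (plain mu^2 biases the dispersion downward and inflates the Wald tail).
    inv_s = float(np.mean(1.0 / sf.to_numpy()))
    var_case = norm[is_case].var(axis=0, ddof=1)
    var_ctrl = norm[~is_case].var(axis=0, ddof=1)
    n_total = n_case + n_ctrl
    pooled_var = ((n_case - 1) * var_case + (n_ctrl - 1) * var_ctrl) / (
        n_total - 2
    )
    pooled_mu = (n_case * mu_case + n_ctrl * mu_ctrl) / n_total
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = (pooled_var - pooled_mu * inv_s) / (
            pooled_mu**2 - pooled_var / n_total
        )
    disp = np.where(np.isfinite(disp), disp, 0.0)
    disp = np.maximum(disp, 1e-8)

    zero_case = mu_case == 0
    zero_ctrl = mu_ctrl == 0
    pseudo = 0.5  # half a normalized count keeps log2 finite off the sentinel path
    mc = np.maximum(mu_case, pseudo)
    m0 = np.maximum(mu_ctrl, pseudo)
    log2_fc = np.log2(mc / m0)

    # Delta method: Var(mean of K/s in group g) = n_g^-2 * sum_j (mu/s_j + disp*mu^2)
    s = sf.to_numpy()
    sum_inv_s_case = float(np.sum(1.0 / s[is_case]))
    sum_inv_s_ctrl = float(np.sum(1.0 / s[~is_case]))
    var_mean_case = (mc * sum_inv_s_case + disp * mc**2 * n_case) / n_case**2
    var_mean_ctrl = (m0 * sum_inv_s_ctrl + disp * m0**2 * n_ctrl) / n_ctrl**2
    ln2sq = np.log(2.0) ** 2
    se = np.sqrt(var_mean_case / (mc**2 * ln2sq) + var_mean_ctrl / (m0**2 * ln2sq))

    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(se > 0, log2_fc / se, 0.0)
    pvalue = 2.0 * stats.t.sf(np.abs(stat), df=n_total - 2)

    # sentinel handling: one group entirely zero -> direction known, p undefined
    sentinel = zero_case ^ zero_ctrl
    both_zero = zero_case & zero_ctrl
    log2_fc = np.where(sentinel, np.where(zero_ctrl, LFC_SENTINEL, -LFC_SENTINEL),
                       log2_fc)
    log2_fc = np.where(both_zero, 0.0, log2_fc)
    pvalue = np.where(sentinel | both_zero, np.nan, pvalue)
    stat = np.where(sentinel | both_zero, np.nan, stat)
    se = np.where(sentinel | both_zero, np.nan, se)

    padj = np.full_like(pvalue, np.nan)
    testable = np.isfinite(pvalue)
    if testable.any():
        padj[testable] = bh_adjust(pvalue[testable])

    table = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2_fc": log2_fc,
            "se": se,
            "stat": stat,
            "pvalue": pvalue,
            "padj": padj,
        },
        index=kept.columns,
    )
    return DATestResult(table=table)


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Mann-Whitney U (x side) with two-sided p.

    Exact enumeration for small tie-free samples (both n < 8), otherwise the
    normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    if x.size < 8 and y.size < 8 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=False)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Kruskal-Wallis rank test across >= 3 groups (tie-corrected H, chi-square p)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    names = pd.unique(groups)
    if len(names) < 3:
        raise ValueError(
            "kruskal_wallis needs >= 3 groups; use mann_whitney_u for two"
        )
    samples = [values[groups == g] for g in names]
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs at least 2 observations")
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def _holm(pvals: np.ndarray) -> np.ndarray:
    order = np.argsort(pvals, kind="mergesort")
    m = pvals.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(running, 1.0)
    return adj


def posthoc_vs_control(values, groups, control: str, alpha: float = 0.05) -> pd.Series:
    """Each disease group vs control by Mann-Whitney, Holm-adjusted familywise.

    Rank-based many-to-one comparisons standing in for a Dunnett-style
    procedure while staying nonparametric.  Returns adjusted p per disease.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    names = [g for g in pd.unique(groups)]
    if control not in names:
        raise ValueError(f"control group {control!r} not present")
    diseases = [g for g in names if g != control]
    ctrl_vals = values[groups == control]
    raw = np.array(
        [mann_whitney_u(values[groups == g], ctrl_vals)[1] for g in diseases]
    )
    return pd.Series(_holm(raw), index=diseases, name="padj_vs_control")


def chi_square_test(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an r x c contingency table."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("contingency table must hold nonnegative integers")
    total = t.sum()
    if total <= 0:
        raise ValueError("contingency table total must be positive")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / total
    if (expected == 0).any():
        raise ValueError("expected cell count of zero (empty row or column)")
    chi2, p, dof, _ = stats.chi2_contingency(t, correction=False)
    return float(chi2), int(dof), float(p)


def shapiro_normality(x) -> float:
    """Shapiro-Wilk normality p-value (3 <= n <= 5000, non-constant input)."""
    x = np.asarray(x, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk undefined for a constant sample")
    return float(stats.shapiro(x).pvalue)


def split_phenotype_columns(
    phenotypes: pd.DataFrame,
) -> tuple[list[str], list[str]]:
    """Partition phenotype columns into (quantitative, qualitative) by dtype."""
    quant = [c for c in phenotypes.columns
             if pd.api.types.is_numeric_dtype(phenotypes[c])]
    qual = [c for c in phenotypes.columns if c not in quant]
    return quant, qual


@dataclass
class CandidateSet:
    """Variables passing the screening stage for one disease-vs-control contrast."""

    disease: str
    taxa: list[str] = field(default_factory=list)
    quantitative: list[str] = field(default_factory=list)
    qualitative: list[str] = field(default_factory=list)
    alpha: float = 0.05

    def to_dict(self) -> dict:
        return {
            "disease": self.disease,
            "taxa": list(self.taxa),
            "quantitative": list(self.quantitative),
            "qualitative": list(self.qualitative),
            "alpha": self.alpha,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CandidateSet":
        return cls(
            disease=d["disease"],
            taxa=list(d["taxa"]),
            quantitative=list(d["quantitative"]),
            qualitative=list(d["qualitative"]),
            alpha=float(d.get("alpha", 0.05)),
        )

    def block(self, name: str) -> list[str]:
        if name == "taxa":
            return list(self.taxa)
        if name == "quantitative":
            return list(self.quantitative)
        if name == "qualitative":
            return list(self.qualitative)
        if name == "integrated":
            return list(self.taxa) + list(self.quantitative) + list(self.qualitative)
        raise KeyError(name)


def select_candidates(
    counts: pd.DataFrame,
    phenotypes: pd.DataFrame,
    labels: pd.Series,
    disease: str,
    control: str = "CT",
    alpha: float = 0.05,
    min_prevalence: float = 0.1,
) -> CandidateSet:
    """Screen taxa and phenotype variables for one disease-vs-control contrast.

    Taxa: BH-adjusted NB Wald p < alpha.  Quantitative variables: when more
    than two groups exist in the cohort, a Kruskal-Wallis gate at alpha across
    all groups followed by the Holm-adjusted disease-vs-control comparison;
    otherwise a direct Mann-Whitney.  Qualitative variables: chi-square on the
    level x {control, disease} contingency table.  Lists are alphabetical.
    """
    present = set(labels.unique())
    if disease not in present or control not in present:
        raise ValueError(f"labels must contain both {disease!r} and {control!r}")

    da = nb_wald_da(counts, labels, case=disease, control=control,
                    min_prevalence=min_prevalence)
    taxa = da.significant(alpha)

    quant_cols, qual_cols = split_phenotype_columns(phenotypes)
    many_groups = len(present) > 2
    groups_arr = labels.to_numpy()

    quantitative: list[str] = []
    for col in quant_cols:
        vals = phenotypes[col]
        ok = vals.notna().to_numpy()
        v, g = vals.to_numpy(dtype=float)[ok], groups_arr[ok]
        if many_groups:
            try:
                _, p_gate = kruskal_wallis(v, g)
            except ValueError:
                continue
            if p_gate >= alpha:
                continue
            padj = posthoc_vs_control(v, g, control=control, alpha=alpha)
            if disease in padj.index and padj[disease] < alpha:
                quantitative.append(col)
        else:
            _, p = mann_whitney_u(v[g == disease], v[g == control])
            if p < alpha:
                quantitative.append(col)

    qualitative: list[str] = []
    pair = labels.isin([control, disease])
    for col in qual_cols:
        sub = phenotypes.loc[pair, col].dropna()
        ct = pd.crosstab(sub, labels.loc[sub.index])
        ct = ct.loc[(ct.sum(axis=1) > 0), (ct.sum(axis=0) > 0)]
        if ct.shape[0] < 2 or ct.shape[1] < 2:
            continue
        _, _, p = chi_square_test(ct.to_numpy())
        if p < alpha:
            qualitative.append(col)

    return CandidateSet(
        disease=disease,
        taxa=sorted(taxa),
        quantitative=sorted(quantitative),
        qualitative=sorted(qualitative),
        alpha=alpha,
    )
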