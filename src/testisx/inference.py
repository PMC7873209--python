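"""Cell-level permutation inference and bulk per-arm sex-bias statistics.

Single-cell expression is sparse and missingness is not random, so simple
aggregation over cells is avoided: every measure is computed per cell and
compared between cell types with the Mann-Whitney U test, whose null
distribution is then calibrated by shuffling cell-type labels (pairwise
variant) or by repeatedly drawing size-matched random samples of cells
(mean-comparison variant). Bulk per-arm sex differences use per-sample arm
means with bootstrap CIs, Welch t-tests and Benjamini-Hochberg correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix, GeneAnnotation


def mwu(x, y) -> tuple[float, float]:
    """Mann-Whitney U (of ``x`` over ``y``, midrank ties) and two-sided p.

    Exact p for small untied samples, otherwise the normal approximation
    with tie and continuity corrections.
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


@dataclass
class PermutationResult:
    comparison: str
    observed_u: float
    observed_p: float  # two-sided Mann-Whitney p on the real labels
    n_iterations: int
    permutation_p: float | None  # pairwise variant
    significant_fraction: float | None  # mean-comparison variant
    different: bool | None
    seed: int


def _extract_groups(values: pd.Series, labels: pd.Series, *types: str):
    values = pd.Series(values)
    labels = pd.Series(labels).reindex(values.index)
    out = []
    for t in types:
        grp = values[(labels == t) & values.notna()]
        if len(grp) < 2:
            raise ValueError(f"cell type {t!r} has {len(grp)} valid cells (need >= 2)")
        out.append(grp.to_numpy(dtype=float))
    return out


def pairwise_permutation_test(
    values: pd.Series,
    labels: pd.Series,
    a: str,
    b: str,
    n_iter: int = 10000,
    seed: int = 0,
) -> PermutationResult:
    """Label-shuffling calibration of the Mann-Whitney U between two types.

    The pooled a+b labels are permuted ``n_iter`` times; "more extreme" is
    two-sided on |U - E[U]| with E[U] = n_a*n_b/2. The permutation p uses
    the add-one estimator (1 + #extreme) / (n_iter + 1), so it can never
    drop below 1/(n_iter+1).
    """
    if a == b:
        raise ValueError("the two cell types must differ")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    xa, xb = _extract_groups(values, labels, a, b)
    u_obs, p_obs = mwu(xa, xb)

    pooled = np.concatenate([xa, xb])
    ranks = stats.rankdata(pooled)
    n_a, n_b = len(xa), len(xb)
    expected = n_a * n_b / 2.0
    rng = np.random.default_rng([int(seed), 10])

    extreme = 0
    chunk = max(1, min(n_iter, int(2e7 // max(pooled.size, 1))))
    done = 0
    while done < n_iter:
        m = min(chunk, n_iter - done)
        # Random label permutations: the first n_a positions of each argsorted
        # uniform row form a uniform random subset taken as group a.
        perm = np.argsort(rng.random((m, pooled.size)), axis=1)[:, :n_a]
        u_perm = ranks[perm].sum(axis=1) - n_a * (n_a + 1) / 2.0
        extreme += int(
            np.sum(np.abs(u_perm - expected) >= np.abs(u_obs - expected) - 1e-12)
        )
        done += m
    p_perm = (1 + extreme) / (n_iter + 1)
    return PermutationResult(
        comparison=f"{a} vs {b}",
        observed_u=u_obs,
        observed_p=p_obs,
        n_iterations=n_iter,
        permutation_p=p_perm,
        significant_fraction=None,
        different=None,
        seed=seed,
    )


def mean_permutation_test(
    values: pd.Series,
    labels: pd.Series,
    t: str,
    n_iter: int = 10000,
    alpha: float = 0.01,
    decision: float = 0.95,
    seed: int = 0,
) -> PermutationResult:
    """Compare one cell type against size-matched random samples of all cells.

    Each iteration draws a uniform random sample (without replacement) of
    size n_t from all cells and runs the Mann-Whitney U test against the
    type's cells. Reported is the fraction of iterations significant at
    ``alpha``; the type is declared different when that fraction reaches
    ``decision``.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    values = pd.Series(values)
    (vt,) = _extract_groups(values, labels, t)
    all_vals = values.dropna().to_numpy(dtype=float)
    n_t = len(vt)
    if n_t >= all_vals.size:
        raise ValueError("type has as many cells as the whole experiment")
    rng = np.random.default_rng([int(seed), 11])

    n_sig = 0
    p_obs_sum = 0.0
    for _ in range(n_iter):
        sample = all_vals[rng.choice(all_vals.size, size=n_t, replace=False)]
        _, p = stats.mannwhitneyu(
            vt, sample, alternative="two-sided", method="asymptotic"
        )
        n_sig += p <= alpha
        p_obs_sum += p
    frac = n_sig / n_iter
    u_obs, p_obs = mwu(vt, np.concatenate([all_vals]))
    return PermutationResult(
        comparison=f"{t} vs random samples",
        observed_u=u_obs,
        observed_p=p_obs,
        n_iterations=n_iter,
        permutation_p=None,
        significant_fraction=frac,
        different=frac >= decision,
        seed=seed,
    )


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def chi2_independence(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence (no continuity correction)."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    expected = stats.contingency.expected_freq(table)
    if np.any(expected <= 0):
        raise ValueError(
            "zero expected count; merge sparse categories before testing"
        )
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


def bootstrap_ci_mean(
    values, n_boot: int = 1000, level: float = 0.95, seed: int = 0
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval of the mean."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need >= 2 values")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    rng = np.random.default_rng([int(seed), 12])
    means = rng.choice(values, size=(n_boot, values.size), replace=True).mean(axis=1)
    lo, hi = np.percentile(means, [(1 - level) / 2 * 100, (1 + level) / 2 * 100])
    return float(lo), float(hi)


def arm_sex_bias(
    bulk_tpm: CountMatrix,
    annotation: GeneAnnotation,
    sample_meta: pd.DataFrame,
    expressed,
    q_cutoff: float = 0.01,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-element mean TPM by sex, with bootstrap CIs and Welch t-tests.

    For each sample and element the mean TPM over that element's expressed
    genes is computed (summed TPM divided by the number of expressed genes
    on the arm); per element, male and female replicate means are compared
    with a two-sided Welch t-test, BH-corrected across elements. An element
    is flagged ``male_reduced`` when q <= ``q_cutoff`` and the male mean is
    below the female mean. Elements with no expressed genes are omitted.
    """
    meta = sample_meta.reindex(bulk_tpm.obs_names)
    if meta["sex"].isna().any():
        raise ValueError("sex labels missing for some samples")
    for sex in ("male", "female"):
        if (meta["sex"] == sex).sum() < 2:
            raise ValueError(f"need >= 2 replicates of sex {sex!r}")

    expressed = pd.Index(expressed)
    element = annotation.element
    dense = pd.DataFrame(
        bulk_tpm.X.toarray(), index=bulk_tpm.obs_names, columns=bulk_tpm.var_names
    )
    rows = []
    for el in pd.unique(element):
        genes = element.index[(element == el)].intersection(expressed).intersection(
            bulk_tpm.var_names
        )
        if len(genes) == 0:
            continue
        arm_mean = dense[genes].mean(axis=1)  # per-sample mean TPM per gene
        male = arm_mean[(meta["sex"] == "male").to_numpy()]
        female = arm_mean[(meta["sex"] == "female").to_numpy()]
        t_stat, p = stats.ttest_ind(male, female, equal_var=False)
        m_lo, m_hi = bootstrap_ci_mean(male, n_boot=n_boot, seed=seed)
        f_lo, f_hi = bootstrap_ci_mean(female, n_boot=n_boot, seed=seed + 1)
        rows.append(
            {
                "element": el,
                "n_genes": len(genes),
                "male_mean": male.mean(),
                "male_ci_lo": m_lo,
                "male_ci_hi": m_hi,
                "female_mean": female.mean(),
                "female_ci_lo": f_lo,
                "female_ci_hi": f_hi,
                "t_stat": float(t_stat),
                "p": float(p),
            }
        )
    out = pd.DataFrame(rows).set_index("element")
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["male_reduced"] = (out["q"] <= q_cutoff) & (out["male_mean"] < out["female_mean"])
    return out


def sex_bias_classes(
    de_labels: pd.Series, annotation: GeneAnnotation
) -> pd.DataFrame:
    """Element x {male, female, unbiased} contingency table of DE calls."""
    de_labels = pd.Series(de_labels)
    bad = set(de_labels.unique()) - {"male", "female", "unbiased"}
    if bad:
        raise ValueError(f"unknown sex-bias classes: {sorted(bad)}")
    element = annotation.element.reindex(de_labels.index)
    if element.isna().any():
        raise ValueError("some labeled genes are missing from the annotation")
    table = pd.crosstab(element, de_labels)
    table.index.name = "element"
    table.columns.name = "class"
    return table


def welch_sex_de(
    bulk_tpm: CountMatrix,
    sample_meta: pd.DataFrame,
    q_cutoff: float = 0.01,
    min_fold: float = 2.0,
) -> pd.Series:
    """Basic per-gene two-sample sex-bias caller (stand-in labeler).

    Per gene, a Welch t-test of log2(TPM+1) male vs female across samples,
    BH-corrected; genes at q <= cutoff with at least ``min_fold`` linear
    fold change are labeled 'male' or 'female', the rest 'unbiased'. Meant
    to produce labels for :func:`sex_bias_classes` when no external
    differential-expression results are supplied.
    """
    meta = sample_meta.reindex(bulk_tpm.obs_names)
    male = np.log2(bulk_tpm.X.toarray()[(meta["sex"] == "male").to_numpy()] + 1)
    female = np.log2(bulk_tpm.X.toarray()[(meta["sex"] == "female").to_numpy()] + 1)
    t, p = stats.ttest_ind(male, female, axis=0, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    q = bh_fdr(p)
    diff = male.mean(axis=0) - female.mean(axis=0)
    labels = np.where(
        (q <= q_cutoff) & (np.abs(diff) >= np.log2(min_fold)),
        np.where(diff > 0, "male", "female"),
        "unbiased",
    )
    return pd.Series(labels, index=bulk_tpm.var_names, name="sex_bias")
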