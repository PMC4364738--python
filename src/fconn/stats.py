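"""Group inference: permutation tests, FDR, nodal comparison, hub-bin
profiles, module-enrichment resampling, partial correlations and
clinical-table statistics.

Group differences in network metrics are assessed nonparametrically: the
observed difference of group means is compared against an empirical null
built by randomly reallocating subjects into two groups of the original
sizes (default 10,000 permutations); the 95th percentile of the null is the
one-tailed critical value and p-values use the add-one convention
p = (#{null >= observed} + 1) / (n_perm + 1), which can never return 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PermutationResult",
    "EnrichmentResult",
    "BinProfile",
    "permutation_test",
    "fdr_bh",
    "nodal_comparison",
    "hub_bin_profile",
    "compare_bin_profiles",
    "module_enrichment",
    "partial_correlation",
    "payne_corrected_calcium",
    "demographics_tests",
    "dice_coefficient",
]


@dataclass
class PermutationResult:
    observed_diff: float
    null_diffs: np.ndarray
    critical_value: float
    p_one_tailed: float


@dataclass
class EnrichmentResult:
    observed: np.ndarray
    expected: np.ndarray
    p_empirical: np.ndarray
    n_draws: int


@dataclass
class BinProfile:
    percentages: np.ndarray  # length n_bins, sums to 100
    edges: np.ndarray        # length n_bins + 1


def _residualize(y: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    if covariates is None:
        return y
    z = np.column_stack([np.ones(len(y)), np.atleast_2d(covariates.T).T])
    return y - z @ (np.linalg.pinv(z) @ y)


def permutation_test(
    values_a,
    values_b,
    rng: np.random.Generator,
    n_perm: int = 10_000,
    tail: str = "greater",
    covariates: np.ndarray | None = None,
) -> PermutationResult:
    """Two-sample permutation test on the difference of means (A - B).

    `tail="greater"` tests whether mean(A) - mean(B) is larger than chance;
    `tail="less"` the opposite.  Optional `covariates` (rows aligned with
    the concatenation A then B) are regressed out of the pooled values
    before permuting.
    """
    if tail not in ("greater", "less"):
        raise ValueError("tail must be 'greater' or 'less'")
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 observations")
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations gives a coarse p-value",
                      stacklevel=2)
    pooled = _residualize(np.concatenate([a, b]), covariates)
    na = a.size
    observed = float(pooled[:na].mean() - pooled[na:].mean())
    n = pooled.size
    # vectorized label permutations: first na entries of each shuffled order
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    perm_a = np.take(pooled, order[:, :na]).mean(axis=1)
    total_mean = pooled.mean()
    # mean_b = (sum - na*mean_a) / nb
    perm_b = (pooled.sum() - na * perm_a) / (n - na)
    null = perm_a - perm_b
    if tail == "greater":
        p = (np.count_nonzero(null >= observed) + 1) / (n_perm + 1)
        crit = float(np.percentile(null, 95))
    else:
        p = (np.count_nonzero(null <= observed) + 1) / (n_perm + 1)
        crit = float(np.percentile(null, 5))
    return PermutationResult(
        observed_diff=observed, null_diffs=null,
        critical_value=crit, p_one_tailed=float(p),
    )


def fdr_bh(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up rejection mask at level q."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def nodal_comparison(
    nodal_a: np.ndarray,
    nodal_b: np.ndarray,
    rng: np.random.Generator,
    n_perm: int = 10_000,
    q: float = 0.05,
    covariates: np.ndarray | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Node-wise permutation test for *decreased* values in group A.

    `nodal_a`/`nodal_b` are subject-by-node matrices (group A = patients).
    Per-node one-tailed p-values (tail: A < B) are BH-corrected over all
    nodes; returns the flagged node indices and a per-node statistics table.
    """
    a = np.asarray(nodal_a, dtype=float)
    b = np.asarray(nodal_b, dtype=float)
    if a.shape[1] != b.shape[1]:
        raise ValueError("node sets must match")
    pooled = np.vstack([a, b])
    if covariates is not None:
        pooled = _residualize(pooled, covariates)
    na, n = a.shape[0], pooled.shape[0]
    observed = pooled[:na].mean(axis=0) - pooled[na:].mean(axis=0)
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    sel = order[:, :na]
    perm_a = pooled[sel].mean(axis=1)                      # n_perm x n_nodes
    perm_b = (pooled.sum(axis=0)[None, :] - na * perm_a) / (n - na)
    null = perm_a - perm_b
    p = (np.count_nonzero(null <= observed[None, :], axis=0) + 1) / (n_perm + 1)
    reject = fdr_bh(p, q)
    table = pd.DataFrame({
        "observed_diff": observed,
        "p_one_tailed": p,
        "significant": reject,
    })
    return np.flatnonzero(reject), table


def hub_bin_profile(values: np.ndarray, n_bins: int = 8) -> BinProfile:
    """Equal-width binning of nodal values between their min and max.

    Returns the percentage of nodes per bin (top bin right-closed).  A
    constant input degenerates to 100% in bin 1 with a warning.
    """
    v = np.asarray(values, dtype=float)
    lo, hi = v.min(), v.max()
    if lo == hi:
        warnings.warn("constant nodal values; all mass placed in bin 1",
                      stacklevel=2)
        pct = np.zeros(n_bins)
        pct[0] = 100.0
        return BinProfile(percentages=pct, edges=np.linspace(lo, lo + 1, n_bins + 1))
    counts, edges = np.histogram(v, bins=n_bins, range=(lo, hi))
    return BinProfile(percentages=counts / v.size * 100.0, edges=edges)


def compare_bin_profiles(
    profiles_a: list[BinProfile],
    profiles_b: list[BinProfile],
    rng: np.random.Generator,
    n_perm: int = 10_000,
    tail: str = "less",
) -> pd.DataFrame:
    """Per-bin permutation comparison of group bin percentages (A vs B)."""
    pa = np.array([p.percentages for p in profiles_a])
    pb = np.array([p.percentages for p in profiles_b])
    rows = []
    for k in range(pa.shape[1]):
        res = permutation_test(pa[:, k], pb[:, k], rng, n_perm=n_perm, tail=tail)
        rows.append({"bin": k + 1, "observed_diff": res.observed_diff,
                     "p_one_tailed": res.p_one_tailed})
    return pd.DataFrame(rows).set_index("bin")


def module_enrichment(
    flagged: np.ndarray,
    labels: np.ndarray,
    rng: np.random.Generator,
    n_draws: int = 10_000,
) -> EnrichmentResult:
    """Resampling test for over-representation of flagged nodes per module.

    Draws |flagged| nodes uniformly without replacement `n_draws` times and
    computes, per module, the add-one-corrected fraction of draws whose
    count reaches the observed count.  Equivalent in expectation to the
    hypergeometric tail P(X >= observed).
    """
    labels = np.asarray(labels)
    flagged = np.asarray(flagged)
    if flagged.size and (flagged.min() < 0 or flagged.max() >= labels.size):
        raise ValueError("flagged nodes out of range")
    m = labels.max() + 1
    sizes = np.bincount(labels, minlength=m)
    observed = np.bincount(labels[flagged], minlength=m)
    draws = rng.multivariate_hypergeometric(sizes, flagged.size, size=n_draws)
    p = (np.count_nonzero(draws >= observed[None, :], axis=0) + 1) / (n_draws + 1)
    expected = flagged.size * sizes / labels.size
    return EnrichmentResult(observed=observed, expected=expected,
                            p_empirical=p, n_draws=n_draws)


def partial_correlation(
    x,
    y,
    covariates=None,
) -> tuple[float, float]:
    """Pearson correlation of x and y after removing covariates by OLS.

    Complete cases only; p from the t transform with df = n - k - 2 where k
    is the number of covariates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = None if covariates is None else np.atleast_2d(np.asarray(covariates, dtype=float).T).T
    cols = [x, y] + ([z[:, c] for c in range(z.shape[1])] if z is not None else [])
    ok = ~np.any(np.isnan(np.column_stack(cols)), axis=1)
    x, y = x[ok], y[ok]
    k = 0 if z is None else z.shape[1]
    n = x.size
    df = n - k - 2
    if df <= 0:
        raise ValueError("not enough complete cases for the covariate count")
    if z is not None:
        z = z[ok]
        x = _residualize(x, z)
        y = _residualize(y, z)
    if x.std() < 1e-12 or y.std() < 1e-12:
        # no variance left after adjustment: no partial association
        return 0.0, 1.0
    r = float(np.corrcoef(x, y)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    t = r * np.sqrt(df / max(1.0 - r * r, 1e-300))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return r, p


def payne_corrected_calcium(ca_measured_mmol, albumin_g_l):
    """Albumin-adjusted serum calcium: Ca + 0.02 * (40 - albumin) mmol/L."""
    albumin = np.asarray(albumin_g_l, dtype=float)
    if np.any(albumin <= 0):
        raise ValueError("albumin must be positive")
    out = np.asarray(ca_measured_mmol, dtype=float) + 0.02 * (40.0 - albumin)
    return float(out) if out.ndim == 0 else out


def demographics_tests(manifest: pd.DataFrame) -> pd.DataFrame:
    """Table-1-style group comparisons of the subject manifest.

    Categorical variables (sex) use a Pearson chi-square without continuity
    correction; continuous variables use a pooled-variance two-sided
    two-sample t test.  Expects a `group` column with two levels.
    """
    groups = manifest["group"].unique()
    if len(groups) != 2:
        raise ValueError("manifest must contain exactly two groups")
    ga = manifest[manifest["group"] == groups[0]]
    gb = manifest[manifest["group"] == groups[1]]
    rows = []
    for col in manifest.columns:
        if col == "group":
            continue
        if col == "sex" or manifest[col].dropna().nunique() <= 2:
            tab = pd.crosstab(manifest["group"], manifest[col])
            if tab.size < 4 or (sps.contingency.expected_freq(tab.values) == 0).any():
                warnings.warn(f"degenerate count table for {col}; test skipped",
                              stacklevel=2)
                rows.append({"variable": col, "test": "chi2",
                             "statistic": np.nan, "p_value": np.nan})
                continue
            stat, p, _, _ = sps.chi2_contingency(tab.values, correction=False)
            rows.append({"variable": col, "test": "chi2", "statistic": float(stat),
                         "p_value": float(p)})
        else:
            xa = ga[col].dropna().to_numpy(dtype=float)
            xb = gb[col].dropna().to_numpy(dtype=float)
            if xa.size < 2 or xb.size < 2:
                continue
            stat, p = sps.ttest_ind(xa, xb, equal_var=True)
            rows.append({"variable": col, "test": "t", "statistic": float(stat),
                         "p_value": float(p)})
    return pd.DataFrame(rows).set_index("variable")


def chi2_from_counts(counts_a: tuple[int, int], counts_b: tuple[int, int]) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on a 2x2 count table."""
    stat, p, _, _ = sps.chi2_contingency(np.array([counts_a, counts_b]),
                                         correction=False)
    return float(stat), float(p)


def t_from_summaries(mean_a, sd_a, n_a, mean_b, sd_b, n_b) -> tuple[float, float]:
    """Pooled-variance two-sided t test from printed group summaries."""
    stat, p = sps.ttest_ind_from_stats(mean_a, sd_a, n_a, mean_b, sd_b, n_b,
                                       equal_var=True)
    return float(stat), float(p)


def dice_coefficient(set_a, set_b) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|); two empty sets give 1."""
    a, b = set(set_a), set(set_b)
    if not a and not b:
        warnings.warn("both sets empty; Dice defined as 1", stacklevel=2)
        return 1.0
    return 2.0 * len(a & b) / (len(a) + len(b))
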