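"""Low-input proteomics statistics.

The downstream statistical workflow for label-free protein quantification
tables (MaxQuant/DIA-NN-style wide matrices on the log2 scale):

1. stringent valid-value filtering (keep proteins with <= 30% missing,
   after removing decoy / contaminant / site-only entries; zeros are
   treated as missing),
2. left-censored missing-value imputation from a downshifted, narrowed
   normal distribution (width 0.3, downshift 1.8, in units of the
   per-sample sd),
3. an s0-moderated two-sample t statistic (SAM-style: a small constant s0
   added to the standard-error denominator damps large fold changes with
   tiny variance) and one-way ANOVA F for multi-group designs,
4. permutation-based FDR control (group labels permuted, median null
   exceedance count over permutations),
5. Fisher-exact annotation-term enrichment of the significant set against
   the background, Benjamini-Hochberg corrected.

All randomness is seeded; sample standard deviations use the n-1
denominator throughout.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ProteinMatrix",
    "TestResult",
    "EnrichmentResult",
    "filter_matrix",
    "impute_downshift",
    "s0_ttest",
    "anova_F",
    "permutation_fdr",
    "fisher_enrichment",
    "zscore_rows",
    "read_gmt",
]


@dataclass(frozen=True)
class ProteinMatrix:
    """Proteins × samples log2 intensities with per-sample group labels.

    ``values`` is a DataFrame (index: protein ids, columns: sample ids)
    with NaN marking missing; ``groups`` maps every sample id to a group.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if not set(self.values.columns) <= set(self.groups.index):
            missing = set(self.values.columns) - set(self.groups.index)
            raise ValueError(f"samples without group label: {sorted(missing)}")
        groups = self.groups.loc[self.values.columns]
        vals = self.values.to_numpy(float)
        if np.isinf(vals).any():
            raise ValueError("matrix contains non-finite (inf) values")
        object.__setattr__(self, "groups", groups)

    def group_columns(self, group) -> list[str]:
        return list(self.groups.index[self.groups == group])

    @property
    def group_names(self) -> list[str]:
        return list(pd.unique(self.groups))


def filter_matrix(
    m: ProteinMatrix,
    max_missing_frac: float = 0.30,
    flagged: set[str] | pd.Index | None = None,
    zeros_are_missing: bool = True,
) -> ProteinMatrix:
    """Stringent valid-value filter.

    Removes proteins in ``flagged`` (decoys, contaminants, site-only ids),
    converts zero intensities to missing, and keeps only proteins whose
    missing fraction is <= ``max_missing_frac`` (30%-or-less rule: a
    protein missing in exactly 30% of samples is retained).
    """
    if not (0 <= max_missing_frac <= 1):
        raise ValueError("max_missing_frac must be in [0, 1]")
    vals = m.values.copy()
    if flagged:
        vals = vals.loc[~vals.index.isin(set(flagged))]
    if zeros_are_missing:
        vals = vals.where(vals != 0)
    frac = vals.isna().mean(axis=1)
    vals = vals.loc[frac <= max_missing_frac]
    return ProteinMatrix(vals, m.groups)


def impute_downshift(
    m: ProteinMatrix, width: float = 0.3, downshift: float = 1.8, seed: int = 0
) -> ProteinMatrix:
    """Downshifted-normal imputation of missing values, per sample column.

    In each sample column with observed mean μ and sd σ (n−1), every
    missing cell is drawn from Normal(μ − downshift·σ, (width·σ)²) —
    mimicking intensities below the detection limit.  Seeded and
    reproducible.
    """
    rng = np.random.default_rng(seed)
    vals = m.values.copy()
    for col in vals.columns:
        column = vals[col]
        obs = column.dropna()
        n_missing = int(column.isna().sum())
        if n_missing == 0:
            continue
        if len(obs) < 2:
            raise ValueError(f"column {col!r} has fewer than 2 observed values")
        mu = obs.mean()
        sd = obs.std(ddof=1)
        draws = rng.normal(mu - downshift * sd, width * sd, size=n_missing)
        vals.loc[column.isna(), col] = draws
    return ProteinMatrix(vals, m.groups)


def _group_arrays(m: ProteinMatrix, groups: tuple) -> list[np.ndarray]:
    arrays = []
    for g in groups:
        cols = m.group_columns(g)
        if len(cols) < 2:
            raise ValueError(f"group {g!r} needs >= 2 samples")
        arrays.append(m.values[cols].to_numpy(float))
    return arrays


def s0_ttest(
    m: ProteinMatrix, groups: tuple = None, s0: float = 0.1
) -> pd.DataFrame:
    """SAM-style s0-moderated two-sample t statistic per protein.

    d = (mean_a − mean_b) / (s0 + se), with se the pooled-variance
    two-sample standard error; s0 = 0 recovers the classical Student t
    exactly.  Returns a per-protein DataFrame with group means, the log2
    difference and the statistic.  Requires complete (imputed) data.
    """
    if groups is None:
        groups = tuple(m.group_names[:2])
    a, b = _group_arrays(m, groups)
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("impute missing values before testing")
    na, nb = a.shape[1], b.shape[1]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    sp2 = ((na - 1) * var_a + (nb - 1) * var_b) / (na + nb - 2)
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    diff = mean_a - mean_b
    denom = s0 + se
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(denom > 0, diff / denom, 0.0)
    d = np.where((se == 0) & (diff == 0), 0.0, d)
    return pd.DataFrame(
        {
            f"mean_{groups[0]}": mean_a,
            f"mean_{groups[1]}": mean_b,
            "difference": diff,
            "statistic": d,
        },
        index=m.values.index,
    )


_F_VARIANCE_FLOOR = 1e-12


def anova_F(m: ProteinMatrix, groups: tuple = None) -> pd.DataFrame:
    """Classical one-way ANOVA F statistic per protein (>= 2 groups).

    With exactly two groups, F equals the square of the Student t.  A tiny
    variance floor keeps degenerate all-identical proteins finite.
    """
    if groups is None:
        groups = tuple(m.group_names)
    arrays = _group_arrays(m, groups)
    if len(arrays) < 2:
        raise ValueError("ANOVA needs >= 2 groups")
    if any(np.isnan(a).any() for a in arrays):
        raise ValueError("impute missing values before testing")
    ns = np.array([a.shape[1] for a in arrays])
    N = ns.sum()
    k = len(arrays)
    grand = np.hstack(arrays).mean(axis=1)
    means = np.column_stack([a.mean(axis=1) for a in arrays])
    ss_between = (ns[None, :] * (means - grand[:, None]) ** 2).sum(axis=1)
    ss_within = sum(((a - mu[:, None]) ** 2).sum(axis=1) for a, mu in zip(arrays, means.T))
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (N - k)
    F = ms_between / np.maximum(ms_within, _F_VARIANCE_FLOOR)
    return pd.DataFrame({"statistic": F}, index=m.values.index)


@dataclass(frozen=True)
class TestResult:
    """Per-protein permutation-FDR test outcome."""

    table: pd.DataFrame  # statistic, q_value, significant + test columns
    cutoff: float | None  # |statistic| significance cutoff, None if nothing reaches FDR
    target_fdr: float
    n_permutations: int

    @property
    def significant(self) -> pd.Index:
        return self.table.index[self.table["significant"]]


def _label_permutations(labels: np.ndarray, n_perm: int, rng: np.random.Generator):
    """Distinct group-label assignments: exhaustive when few, sampled otherwise."""
    labels = np.asarray(labels)
    n = len(labels)
    counts = pd.Series(labels).value_counts()
    log_total = math.lgamma(n + 1) - sum(math.lgamma(c + 1) for c in counts)
    if log_total <= math.log(max(n_perm, 2)):
        seen = set()
        perms = []
        for p in itertools.permutations(range(n)):
            key = tuple(labels[list(p)])
            if key not in seen:
                seen.add(key)
                perms.append(np.array(key))
        return perms
    return [labels[rng.permutation(n)] for _ in range(n_perm)]


def permutation_fdr(
    m: ProteinMatrix,
    statistic: str = "s0_ttest",
    groups: tuple = None,
    target_fdr: float = 0.05,
    n_perm: int = 250,
    s0: float = 0.1,
    seed: int = 0,
) -> TestResult:
    """Permutation-based FDR control on |statistic| (SAM-style).

    For each candidate cutoff c (the observed |statistic| values), the
    estimated FDR is

        FDR(c) = median over permutations of #{|stat_perm| >= c}
                 / max(1, #{|stat_obs| >= c}),

    where permutations reassign group labels to sample columns (all
    distinct assignments when there are <= ``n_perm``, otherwise
    ``n_perm`` seeded random permutations).  A protein's q-value is the
    running minimum of FDR(c) over cutoffs at or below its own
    |statistic| (monotone non-increasing in |statistic|); proteins with
    q <= ``target_fdr`` are flagged.
    """
    if statistic not in ("s0_ttest", "anova_F"):
        raise ValueError("statistic must be 's0_ttest' or 'anova_F'")
    if groups is None:
        groups = tuple(m.group_names[:2]) if statistic == "s0_ttest" else tuple(m.group_names)

    def stat_for(matrix: ProteinMatrix) -> pd.DataFrame:
        if statistic == "s0_ttest":
            return s0_ttest(matrix, groups, s0=s0)
        return anova_F(matrix, groups)

    obs_table = stat_for(m)
    obs = np.abs(obs_table["statistic"].to_numpy())

    cols = [c for g in groups for c in m.group_columns(g)]
    sub = m.values[cols]
    labels = m.groups.loc[cols].to_numpy()
    rng = np.random.default_rng(seed)
    perms = _label_permutations(labels, n_perm, rng)
    if len(perms) < 2:
        raise ValueError("too few distinct permutations to estimate FDR")

    # sorted descending observed cutoffs; tie-safe #{|obs| >= c} via searchsorted
    order = np.argsort(-obs, kind="stable")
    cutoffs = obs[order]
    sorted_obs_asc = np.sort(obs)
    n_obs_ge = len(obs) - np.searchsorted(sorted_obs_asc, cutoffs, side="left")

    perm_counts = np.empty((len(perms), len(cutoffs)))
    for pi, plabels in enumerate(perms):
        perm_m = ProteinMatrix(sub, pd.Series(plabels, index=cols))
        pstat = np.abs(stat_for(perm_m)["statistic"].to_numpy())
        pstat.sort()
        perm_counts[pi] = len(pstat) - np.searchsorted(pstat, cutoffs, side="left")
    med_null = np.median(perm_counts, axis=0)
    fdr_hat = med_null / np.maximum(1.0, n_obs_ge)
    # q at a protein = min FDR-hat over cutoffs at or below its |stat|
    # (reverse running min over the descending-cutoff axis); monotone in |stat|
    q_sorted = np.minimum.accumulate(fdr_hat[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    significant = q <= target_fdr
    cutoff = float(cutoffs[np.nonzero(q_sorted <= target_fdr)[0].max()]) if significant.any() else None

    table = obs_table.copy()
    table["q_value"] = q
    table["significant"] = significant
    return TestResult(table=table, cutoff=cutoff, target_fdr=target_fdr, n_permutations=len(perms))


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k_sig_in_term: int
    K_in_term: int
    n_significant: int
    N_background: int
    odds_ratio: float
    p_value: float
    q_value: float
    z_score: float
    enriched: bool


def fisher_enrichment(
    significant: set[str],
    background: set[str],
    terms: dict[str, set[str]],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """One-sided Fisher-exact enrichment of annotation terms, BH-corrected.

    Each term's 2×2 table crosses membership with significance within the
    background; the one-sided (greater) p equals the hypergeometric upper
    tail.  Terms with no background overlap are skipped.  The z-score is
    the standardized deviation of the in-term significant count from its
    hypergeometric expectation.
    """
    significant = set(significant)
    background = set(background)
    if not significant <= background:
        raise ValueError("significant set must be a subset of the background")
    N = len(background)
    n = len(significant)
    rows = []
    for term, members in terms.items():
        members_bg = set(members) & background
        K = len(members_bg)
        if K == 0:
            continue
        k = len(members_bg & significant)
        table = [[k, K - k], [n - k, N - K - (n - k)]]
        odds, p = stats.fisher_exact(table, alternative="greater")
        mean = n * K / N
        var = n * (K / N) * (1 - K / N) * (N - n) / (N - 1) if N > 1 else 0.0
        z = (k - mean) / math.sqrt(var) if var > 0 else 0.0
        rows.append((term, k, K, n, N, odds, p, z))
    if not rows:
        return []
    pvals = [r[6] for r in rows]
    _, qvals, *_ = multipletests(pvals, method="fdr_bh")
    return [
        EnrichmentResult(
            term=r[0], k_sig_in_term=r[1], K_in_term=r[2], n_significant=r[3],
            N_background=r[4], odds_ratio=float(r[5]), p_value=float(r[6]),
            q_value=float(qv), z_score=float(r[7]), enriched=bool(qv <= alpha),
        )
        for r, qv in zip(rows, qvals)
    ]


def zscore_rows(values: pd.DataFrame) -> pd.DataFrame:
    """Standardize each row to mean 0 and (sample) sd 1.

    Constant rows cannot be standardized and are rejected.
    """
    arr = values.to_numpy(float)
    mu = np.nanmean(arr, axis=1, keepdims=True)
    sd = np.nanstd(arr, axis=1, ddof=1, keepdims=True)
    bad = ~(sd > 0).ravel()
    if bad.any():
        raise ValueError(f"constant rows cannot be z-scored: {list(values.index[bad])[:5]}")
    return pd.DataFrame((arr - mu) / sd, index=values.index, columns=values.columns)


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT annotation file: term <tab> description <tab> members..."""
    terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            terms[parts[0]] = set(parts[2:])
    return terms
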