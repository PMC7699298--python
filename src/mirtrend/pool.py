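"""Pooled miRNA count tables: TMM normalisation, fold changes, group tests.

The trimmed-mean-of-M-values (TMM) scale factor of a sample is the weighted
mean of per-feature log ratios (M values) against a reference sample, after
trimming the extremes of the M and A (log abundance) distributions; features
with a zero count in either sample are excluded.  Factors are rescaled so
their geometric mean is 1, and normalised values are reported on the
counts-per-million scale ``counts / (library_size * factor) * 1e6``, which
makes them invariant to pure depth differences.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PoolCountTable",
    "NormalizedTable",
    "tmm_factors",
    "normalize",
    "log2_group_fc",
    "per_mirna_ttest",
    "per_mirna_anova",
    "bh_adjust",
    "filter_min_median_reads",
    "compare_groups",
]


@dataclass
class PoolCountTable:
    """miRNA x sample count matrix with a group label per sample.

    ``counts`` may hold non-integer values: pooled sequencing tables are often
    reported as average copy numbers per group replicate, and all downstream
    operations are defined on non-negative reals.
    """

    counts: pd.DataFrame  # features x samples
    groups: pd.Series  # sample_id -> group label

    def __post_init__(self):
        self.groups = pd.Series(self.groups)
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicate feature id {dup!r}")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")
        missing = [s for s in self.counts.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without a group assignment: {missing}")
        self.groups = self.groups.loc[self.counts.columns]
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def mirna_ids(self) -> list:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list:
        return list(self.counts.columns)

    def samples_in(self, group: str) -> list:
        sel = list(self.groups.index[self.groups == group])
        if not sel:
            raise ValueError(f"group {group!r} has no samples")
        return sel

    @property
    def group_labels(self) -> list:
        seen = dict.fromkeys(self.groups.tolist())
        return list(seen)


@dataclass
class NormalizedTable:
    source: PoolCountTable
    scale_factors: pd.Series  # per sample, geometric mean 1
    normalized: pd.DataFrame  # CPM on the effective library size

    def __post_init__(self):
        if (self.scale_factors <= 0).any():
            raise ValueError("scale factors must be strictly positive")


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    mask = (obs > 0) & (ref > 0)
    if not mask.any():
        return 1.0
    po = obs[mask] / lib_obs
    pr = ref[mask] / lib_ref
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    # asymptotic (delta-method) variance of each M value
    v = (lib_obs - obs[mask]) / (lib_obs * obs[mask]) + (lib_ref - ref[mask]) / (lib_ref * ref[mask])
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm = stats.rankdata(m)
    ra = stats.rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_factors(
    table: PoolCountTable,
    reference_sample: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Per-sample TMM scale factors, rescaled to geometric mean 1.

    The reference sample defaults to the one whose upper-quartile
    library-share is closest to the mean upper-quartile; 30% of M values and
    5% of A values are trimmed from both tails and the surviving M values are
    averaged with inverse-variance weights.
    """
    counts = table.counts.to_numpy(dtype=float)
    samples = table.sample_ids
    if len(samples) < 2:
        raise ValueError("TMM requires at least 2 samples")
    lib = counts.sum(axis=0)
    for s, tot in zip(samples, lib):
        if tot <= 0:
            raise ValueError(f"sample {s!r} has zero total count")
    counts = counts[counts.sum(axis=1) > 0]  # all-zero features are uninformative

    f75 = np.quantile(counts / lib, 0.75, axis=0)
    if reference_sample is None:
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        if reference_sample not in samples:
            raise ValueError(f"unknown reference sample {reference_sample!r}")
        ref_idx = samples.index(reference_sample)

    factors = np.array(
        [
            1.0
            if k == ref_idx
            else _tmm_pair(counts[:, k], counts[:, ref_idx], lib[k], lib[ref_idx], trim_m, trim_a)
            for k in range(len(samples))
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=samples, name="tmm_factor")


def normalize(table: PoolCountTable, **tmm_kwargs) -> NormalizedTable:
    """TMM-normalised counts-per-million on the effective library size."""
    factors = tmm_factors(table, **tmm_kwargs)
    lib = table.counts.sum(axis=0)
    eff = lib * factors
    normalized = table.counts.div(eff, axis=1) * 1e6
    return NormalizedTable(source=table, scale_factors=factors, normalized=normalized)


def _values_for(table: PoolCountTable, use_normalized: bool) -> pd.DataFrame:
    return normalize(table).normalized if use_normalized else table.counts


def log2_group_fc(
    table: PoolCountTable,
    mirna_id: str,
    group_a: str,
    group_b: str,
    use_normalized: bool = True,
) -> float:
    """log2 of mean(group_b) / mean(group_a) for one miRNA.

    No pseudocount is applied: a zero mean in either group raises instead of
    silently distorting the ratio.
    """
    values = _values_for(table, use_normalized)
    if mirna_id not in values.index:
        raise KeyError(f"unknown miRNA {mirna_id!r}")
    row = values.loc[mirna_id]
    mean_a = row[table.samples_in(group_a)].mean()
    mean_b = row[table.samples_in(group_b)].mean()
    if mean_a <= 0 or mean_b <= 0:
        raise ValueError(
            f"undefined fold change for {mirna_id!r}: zero mean in "
            f"{'both groups' if mean_a <= 0 and mean_b <= 0 else (group_a if mean_a <= 0 else group_b)}"
        )
    return float(np.log2(mean_b / mean_a))


def _degenerate_p(a: np.ndarray, b: np.ndarray) -> float | None:
    """p-value convention when all within-group variance vanishes."""
    if a.std() == 0 and b.std() == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return None


def per_mirna_ttest(
    table: PoolCountTable,
    group_a: str,
    group_b: str,
    use_normalized: bool = True,
    welch: bool = False,
) -> pd.Series:
    """Two-sided two-sample t-test p-value per miRNA.

    Pooled-variance Student form by default; ``welch=True`` drops the
    equal-variance assumption.  With zero variance in both groups the p-value
    is 1 for equal means and 0 otherwise (degenerate-limit convention).
    """
    values = _values_for(table, use_normalized)
    sa = table.samples_in(group_a)
    sb = table.samples_in(group_b)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("each group needs >= 2 samples for a t-test")
    a = values[sa].to_numpy(dtype=float)
    b = values[sb].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=not welch)
    p = np.asarray(res.pvalue, dtype=float)
    for i in range(p.size):
        if not np.isfinite(p[i]):
            conv = _degenerate_p(a[i], b[i])
            p[i] = conv if conv is not None else 1.0
    return pd.Series(p, index=values.index, name="p_value")


def per_mirna_anova(
    table: PoolCountTable,
    groups: Sequence[str] | None = None,
    use_normalized: bool = True,
) -> pd.Series:
    """One-way ANOVA F-test p-value per miRNA across >= 3 groups.

    In the zero-within-variance limit the F statistic diverges and the
    p-value is reported as 0 when group means differ (1 when all equal).
    """
    groups = list(groups) if groups is not None else table.group_labels
    if len(groups) < 3:
        raise ValueError("ANOVA requires >= 3 groups")
    values = _values_for(table, use_normalized)
    arrays = []
    for g in groups:
        sel = table.samples_in(g)
        if len(sel) < 2:
            raise ValueError(f"group {g!r} needs >= 2 samples")
        arrays.append(values[sel].to_numpy(dtype=float))
    p = np.empty(len(values))
    for i in range(len(values)):
        rows = [a[i] for a in arrays]
        with np.errstate(divide="ignore", invalid="ignore"):
            import warnings as _warnings

            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                res = stats.f_oneway(*rows)
        pv = float(res.pvalue)
        if not np.isfinite(pv):
            means = [r.mean() for r in rows]
            pv = 1.0 if np.ptp(means) == 0 else 0.0
        p[i] = pv
    return pd.Series(p, index=values.index, name="p_value")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def filter_min_median_reads(table: PoolCountTable, threshold: float = 20) -> list:
    """Feature ids whose median count strictly exceeds ``threshold`` in at
    least one sample group (the abundance filter for sparse count data)."""
    keep = []
    medians = {g: table.counts[table.samples_in(g)].median(axis=1) for g in table.group_labels}
    for fid in table.counts.index:
        if any(medians[g].loc[fid] > threshold for g in medians):
            keep.append(fid)
    return keep


def compare_groups(
    table: PoolCountTable,
    group_a: str,
    group_b: str,
    use_normalized: bool = True,
    welch: bool = False,
) -> pd.DataFrame:
    """Per-miRNA log2 fold change (b vs a), t-test p and BH-adjusted p.

    Fold changes with a zero group mean are reported as NaN.
    """
    values = _values_for(table, use_normalized)
    mean_a = values[table.samples_in(group_a)].mean(axis=1)
    mean_b = values[table.samples_in(group_b)].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2_fc = np.where((mean_a > 0) & (mean_b > 0), np.log2(mean_b / mean_a), np.nan)
    p = per_mirna_ttest(table, group_a, group_b, use_normalized=use_normalized, welch=welch)
    out = pd.DataFrame(
        {
            "mirna_id": values.index,
            "group_a": group_a,
            "group_b": group_b,
            "mean_a": mean_a.to_numpy(),
            "mean_b": mean_b.to_numpy(),
            "log2_fc": log2_fc,
            "p_value": p.to_numpy(),
            "fdr_adjusted_p": bh_adjust(p.to_numpy()),
        }
    ).set_index("mirna_id")
    return out
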