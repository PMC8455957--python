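"""Expression profiling: TPM, per-gene z-scores, grouping, up-calls.

Replicate columns are named ``<condition>_<replicate>`` (e.g. ``HTS_2``).
Replicates are collapsed to condition means before z-scoring; z-scores use
the sample standard deviation (ddof=1) by default. Grouping is agglomerative
clustering (average linkage, Euclidean distance on z rows) cut at k
clusters, with clusters renamed I, II, III... by descending size (ties
broken by the lowest gene index) so the largest expression group is always
Group I.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage


def compute_tpm(counts: pd.DataFrame, effective_lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million from read counts and effective lengths."""
    if (counts.values < 0).any():
        raise ValueError("counts must be non-negative")
    lengths = effective_lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every gene needs a positive effective length")
    rate = counts.div(lengths, axis=0)
    totals = rate.sum(axis=0)
    if (totals == 0).any():
        bad = totals.index[totals == 0].tolist()
        raise ValueError(f"zero total rate in sample(s) {bad}")
    return rate.div(totals, axis=1) * 1e6


def condition_means(tpm: pd.DataFrame) -> pd.DataFrame:
    """Collapse replicate columns ``cond_rep`` to per-condition means,
    preserving first-appearance condition order."""
    conds = [c.rsplit("_", 1)[0] for c in tpm.columns]
    order = list(dict.fromkeys(conds))
    grouped = tpm.T.groupby(pd.Categorical(conds, categories=order), observed=True).mean().T
    grouped.columns = order
    return grouped


def zscore_by_gene(tpm: pd.DataFrame, ddof: int = 1) -> tuple[pd.DataFrame, pd.Series]:
    """Per-gene z-scores over condition means.

    Returns (z_matrix, constant_flag); constant genes get an all-zero row.
    """
    means = condition_means(tpm)
    if means.shape[1] < 2:
        raise ValueError("need at least 2 conditions")
    mu = means.mean(axis=1)
    sd = means.std(axis=1, ddof=ddof)
    constant = sd == 0
    sd_safe = sd.replace(0, 1.0)
    z = means.sub(mu, axis=0).div(sd_safe, axis=0)
    z[constant] = 0.0
    return z, constant


@dataclass
class ExpressionGroups:
    labels: pd.Series          # gene -> 'I' / 'II' / 'III' ...
    linkage_matrix: np.ndarray
    hts_up: pd.Series          # per-gene HTS up-regulation flag


ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]


def cluster_expression_groups(
    z: pd.DataFrame,
    k: int = 3,
    method: str = "average",
    metric: str = "euclidean",
    hts_condition: str = "HTS",
    z_threshold: float = 1.0,
) -> ExpressionGroups:
    """Cut an average-linkage tree at k clusters and name groups by size."""
    if len(z) < k:
        raise ValueError(f"need at least k={k} genes, got {len(z)}")
    lm = linkage(z.values, method=method, metric=metric)
    raw = fcluster(lm, t=k, criterion="maxclust")
    # order clusters by (descending size, lowest first gene index)
    order = sorted(
        set(raw),
        key=lambda c: (-int((raw == c).sum()), int(np.argmax(raw == c))),
    )
    rename = {c: ROMAN[i] for i, c in enumerate(order)}
    labels = pd.Series([rename[c] for c in raw], index=z.index, name="group")
    hts = (
        call_upregulated(z, hts_condition, threshold=z_threshold)
        if hts_condition in z.columns
        else pd.Series(False, index=z.index)
    )
    return ExpressionGroups(labels=labels, linkage_matrix=lm, hts_up=hts)


def call_upregulated(
    z: pd.DataFrame, condition: str, threshold: float = 1.0
) -> pd.Series:
    """Flag genes whose z at ``condition`` exceeds the threshold AND is the
    row maximum (so a gene is called for at most one condition)."""
    if condition not in z.columns:
        raise ValueError(f"unknown condition {condition!r}; have {list(z.columns)}")
    flag = (z[condition] > threshold) & (z.T.idxmax() == condition)
    return flag.rename(f"up_{condition}")
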