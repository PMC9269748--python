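"""Count-matrix preprocessing for donor expression data.

Implements the targeted-sequencing processing chain: library-size sample
filter, zero-count gene filter, median-of-ratios size-factor
normalization, log2(count + 1) transform, MDM2 probe collapsing and
hierarchical clustering of donors into low/intermediate/high expression
groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

__all__ = [
    "CountMatrix",
    "filter_samples",
    "filter_genes",
    "size_factors",
    "normalize_counts",
    "log_transform",
    "collapse_probes",
    "cluster_expression_groups",
    "preprocess",
]


@dataclass
class CountMatrix:
    """Probe-by-sample integer counts with probe->gene map and metadata.

    ``counts``: DataFrame, rows are probe ids, columns sample ids.
    ``probe_to_gene``: Series mapping probe id -> gene symbol (MDM2 has
    three probes).  ``metadata``: DataFrame indexed by sample id with at
    least columns ``donor``, ``compound``, ``concentration_uM``,
    ``time_h``, ``replicate``.
    """

    counts: pd.DataFrame
    probe_to_gene: pd.Series
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        arr = self.counts.to_numpy()
        if np.any(arr < 0):
            raise ValueError("counts must be non-negative")
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integers")
        if not self.metadata.empty:
            missing = set(self.counts.columns) - set(self.metadata.index)
            if missing:
                raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_samples(self, samples) -> "CountMatrix":
        meta = self.metadata.loc[samples] if not self.metadata.empty else self.metadata
        return CountMatrix(self.counts[samples], self.probe_to_gene, meta)


def filter_samples(m: CountMatrix, min_library: int = 100_000) -> CountMatrix:
    """Drop samples with library size strictly smaller than ``min_library``."""
    keep = m.library_sizes() >= min_library
    if not keep.any():
        raise ValueError(f"all samples below the library-size threshold {min_library}")
    return m.subset_samples(list(m.counts.columns[keep]))


def filter_genes(m: CountMatrix, max_zero_fraction: float = 0.10) -> CountMatrix:
    """Drop probes with zero counts in strictly more than the given sample fraction."""
    if m.counts.shape[1] < 1:
        raise ValueError("no samples")
    zero_frac = (m.counts == 0).mean(axis=1)
    keep = zero_frac <= max_zero_fraction
    if not keep.any():
        raise ValueError("all probes removed by the zero-count filter")
    return CountMatrix(
        m.counts.loc[keep], m.probe_to_gene.loc[m.counts.index[keep]], m.metadata
    )


def size_factors(m: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    Per probe, the geometric mean across samples; per sample, the median
    over probes (with positive geometric mean) of count / geometric mean.
    """
    arr = m.counts.to_numpy(float)
    with np.errstate(divide="ignore"):
        log_gm = np.mean(np.log(arr), axis=1)  # -inf when any zero
    positive = np.isfinite(log_gm)
    if not positive.any():
        raise ValueError("no probe with all-positive counts; cannot compute size factors")
    ratios = np.log(arr[positive]) - log_gm[positive, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=m.counts.columns, name="size_factor")


def normalize_counts(m: CountMatrix) -> pd.DataFrame:
    """Counts divided by their sample's size factor."""
    return m.counts / size_factors(m)


def log_transform(normalized: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2(x + 1); input must be non-negative."""
    if (normalized.to_numpy() < 0).any():
        raise ValueError("negative values cannot be log-transformed")
    return np.log2(normalized + 1)


def collapse_probes(normalized: pd.DataFrame, probe_to_gene: pd.Series, gene: str) -> pd.Series:
    """Arithmetic mean across the gene's probes per sample."""
    probes = probe_to_gene.index[probe_to_gene == gene]
    probes = [p for p in probes if p in normalized.index]
    if not probes:
        raise ValueError(f"no probes mapped to gene {gene!r}")
    return normalized.loc[probes].mean(axis=0).rename(gene)


def cluster_expression_groups(
    features: pd.DataFrame, k: int = 3
) -> pd.Series:
    """Complete-linkage hierarchical clustering into ordered expression groups.

    ``features``: one row per donor, columns are that donor's expression
    values for the chosen gene across conditions.  The tree over the
    Euclidean distance matrix is cut at ``k`` clusters and labels are
    assigned by ascending cluster mean — ``low``/``intermediate``/``high``
    for k = 3, ``group1..groupk`` otherwise.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(features):
        raise ValueError(f"k={k} exceeds the number of donors ({len(features)})")
    if k == 1:
        labels = np.ones(len(features), int)
    else:
        Z = linkage(pdist(features.to_numpy(float), metric="euclidean"), method="complete")
        labels = fcluster(Z, t=k, criterion="maxclust")
    means = {lab: features.to_numpy(float)[labels == lab].mean() for lab in np.unique(labels)}
    ordered = sorted(means, key=means.get)
    if k == 3:
        names = ["low", "intermediate", "high"]
    else:
        names = [f"group{i + 1}" for i in range(k)]
    rename = {lab: names[i] for i, lab in enumerate(ordered)}
    return pd.Series([rename[lab] for lab in labels], index=features.index, name="cluster")


def preprocess(
    m: CountMatrix,
    min_library: int = 100_000,
    max_zero_fraction: float = 0.10,
) -> pd.DataFrame:
    """Filters, size-factor normalization and log2 transform in order.

    Returns the log2-normalized probe-by-sample matrix; probe collapsing
    and clustering are separate, gene-specific steps.
    """
    filtered = filter_genes(filter_samples(m, min_library), max_zero_fraction)
    return log_transform(normalize_counts(filtered))
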