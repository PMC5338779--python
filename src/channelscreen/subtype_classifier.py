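"""Molecular subtype assignment and hierarchical clustering.

Glioblastoma expression classes (Classical, Mesenchymal, Neural,
Proneural) are assigned by nearest-centroid classification: per-subtype
centroids are the per-gene *median* expression over labelled reference
samples, and a new sample takes the subtype whose centroid maximises the
Spearman rank correlation with it. Replicates are classified separately
and combined by majority consensus. Two agglomerative clustering recipes
(euclidean/average and manhattan/complete) are exposed for the
unsupervised view of the cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
from scipy.stats import spearmanr
from skbio import TreeNode

from .types import ExpressionMatrix, SUBTYPES, ValidationError

logger = logging.getLogger("channelscreen")


@dataclass(frozen=True)
class SubtypeCentroids:
    """subtype -> per-gene median expression over that subtype's references."""

    centroids: pd.DataFrame  # genes x subtypes
    signature_genes: list[str]

    def __post_init__(self) -> None:
        if list(self.centroids.index) != list(self.signature_genes):
            raise ValidationError("centroid gene list must equal the signature gene list")


@dataclass(frozen=True)
class SubtypeCall:
    """One sample's per-subtype correlations and the argmax assignment."""

    sample_id: str
    rho: pd.Series
    subtype: str
    margin: float

    def __post_init__(self) -> None:
        if not np.isclose(self.rho[self.subtype], self.rho.max()):
            raise ValidationError("assigned subtype must attain the maximal correlation")
        if self.margin < -1e-12:
            raise ValidationError("margin must be non-negative")


def compute_centroids(
    reference: ExpressionMatrix,
    labels: pd.Series,
    signature_genes: list[str],
) -> SubtypeCentroids:
    """Per-gene, per-subtype median over labelled reference samples.

    Signature genes absent from the reference are reported and dropped.
    """
    labels = labels.reindex(reference.sample_ids)
    if labels.isna().any():
        missing = [s for s, v in labels.items() if pd.isna(v)]
        raise ValidationError(f"reference samples without a subtype label: {missing}")
    present = [g for g in signature_genes if g in reference.values.index]
    dropped = [g for g in signature_genes if g not in reference.values.index]
    if dropped:
        logger.warning(
            "compute_centroids: %d of %d signature genes absent from reference; dropped",
            len(dropped), len(signature_genes),
        )
    if not present:
        raise ValidationError("no signature genes present in the reference matrix")
    cent = {}
    for subtype in pd.unique(labels):
        cols = [s for s in reference.sample_ids if labels[s] == subtype]
        if not cols:
            raise ValidationError(f"subtype {subtype!r} has no reference samples")
        cent[subtype] = reference.values.loc[present, cols].median(axis=1)
    return SubtypeCentroids(pd.DataFrame(cent, index=present), present)


def classify_by_centroid(
    sample: pd.Series, centroids: SubtypeCentroids, min_shared_genes: int = 10
) -> SubtypeCall:
    """Assign the subtype whose centroid maximises Spearman correlation.

    Ties (average ranks) are handled by scipy's convention; an argmax tie
    is broken by the fixed subtype order with a logged warning. A constant
    sample vector has no defined rank correlation and is an error.
    """
    shared = [g for g in centroids.signature_genes if g in sample.index]
    if len(shared) < min_shared_genes:
        raise ValidationError(
            f"sample shares only {len(shared)} signature genes with the centroids "
            f"(need >= {min_shared_genes})"
        )
    x = sample.reindex(shared).to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValidationError("sample vector contains missing values on signature genes")
    if np.all(x == x[0]):
        raise ValidationError("constant sample vector: rank correlation undefined")
    rho = {}
    for subtype in centroids.centroids.columns:
        c = centroids.centroids.loc[shared, subtype].to_numpy(dtype=float)
        rho[subtype] = float(spearmanr(x, c).statistic)
    rho = pd.Series(rho, name=sample.name)
    best = rho.max()
    tied = [s for s in rho.index if np.isclose(rho[s], best)]
    if len(tied) > 1:
        order = [s for s in SUBTYPES if s in tied] + [s for s in tied if s not in SUBTYPES]
        logger.warning("subtype tie for sample %r among %s; took %r", sample.name, tied, order[0])
        winner = order[0]
    else:
        winner = tied[0]
    runner_up = rho.drop(winner).max() if len(rho) > 1 else rho[winner]
    return SubtypeCall(str(sample.name), rho, winner, float(best - runner_up))


def consensus_call(replicate_calls: list[SubtypeCall]) -> str:
    """Majority subtype over a sample's replicate calls.

    A majority tie goes to the tied label with the highest mean
    correlation; a residual tie falls back to the fixed subtype order with
    a warning.
    """
    if not replicate_calls:
        raise ValidationError("consensus_call needs at least one replicate call")
    votes = pd.Series([c.subtype for c in replicate_calls]).value_counts()
    top = votes.max()
    tied = sorted(votes.index[votes == top])
    if len(tied) == 1:
        return tied[0]
    mean_rho = {
        label: float(np.mean([c.rho[label] for c in replicate_calls])) for label in tied
    }
    best = max(mean_rho.values())
    still = [l for l in tied if np.isclose(mean_rho[l], best)]
    if len(still) > 1:
        order = [s for s in SUBTYPES if s in still] + [s for s in still if s not in SUBTYPES]
        logger.warning("consensus tie among %s; took %r by fixed order", still, order[0])
        return order[0]
    return still[0]


_METRICS = {"euclidean": "euclidean", "manhattan": "cityblock"}
_LINKAGES = ("average", "complete")


@dataclass(frozen=True)
class DendrogramTree:
    """Agglomerative merge tree over samples with merge heights."""

    linkage_matrix: np.ndarray
    leaves: list[str]
    metric: str
    linkage: str

    def __post_init__(self) -> None:
        heights = self.linkage_matrix[:, 2]
        if np.any(np.diff(heights) < -1e-9):
            raise ValidationError("merge heights must be non-decreasing root-ward")

    def to_newick(self) -> str:
        tree = TreeNode.from_linkage_matrix(self.linkage_matrix, self.leaves)
        return str(tree).strip()

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")


def hierarchical_cluster(
    matrix: ExpressionMatrix,
    metric: str = "euclidean",
    linkage: str = "average",
    log_transform: bool = False,
) -> DendrogramTree:
    """Cluster samples (columns) agglomeratively.

    Supported recipes are euclidean distance with unweighted average
    linkage (UPGMA) and manhattan distance with complete linkage; a
    log2(x+1) transform of expression is available but off by default.
    """
    if metric not in _METRICS:
        raise ValidationError(f"unsupported metric {metric!r}; expected {sorted(_METRICS)}")
    if linkage not in _LINKAGES:
        raise ValidationError(f"unsupported linkage {linkage!r}; expected {sorted(_LINKAGES)}")
    x = matrix.values.to_numpy(dtype=float).T  # samples as observations
    if x.shape[0] < 2:
        raise ValidationError("clustering needs at least 2 samples")
    if log_transform:
        x = np.log2(x + 1.0)
    d = ssd.pdist(x, metric=_METRICS[metric])
    z = sch.linkage(d, method=linkage)
    return DendrogramTree(z, matrix.sample_ids, metric, linkage)
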