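"""The enrichment screen: fold-change classification, Signal2Noise ranking,
weighted running-sum enrichment score with a permutation null, candidate
selection, and family-level summaries.

The screen compares tumor stem-cell isolates against normal neural
controls. Genes are first classified by log2 fold change of group-mean
CPM, then ranked by the Signal2Noise statistic
(mu_tumor - mu_control) / (sigma_tumor + sigma_control) with the standard
floor on each class standard deviation, and a gene set's concentration at
the top of the ranking is scored with the weighted Kolmogorov-Smirnov-like
running sum (enrichment score, ES). Candidates are the top-ranked set
members that also clear a minimum mean tumor abundance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .normalization import average_replicates
from .types import (
    ExpressionMatrix,
    FamilyAnnotation,
    SampleMetadata,
    ValidationError,
)

logger = logging.getLogger("channelscreen")

ZERO_POLICIES = ("exclude_zero_denominator", "replace_with_pseudo")

STATUS_TUMOR = "tumor_enriched"
STATUS_CONTROL = "control_enriched"
STATUS_UNCHANGED = "unchanged"
STATUS_EXCLUDED = "excluded_zero_denominator"


def log2fc_screen(
    tumor_means: pd.Series,
    control_means: pd.Series,
    threshold: float = 2.0,
    zero_policy: str = "exclude_zero_denominator",
    pseudo: float = 0.01,
) -> pd.DataFrame:
    """Classify genes by log2 fold change of tumor vs control mean abundance.

    Returns a DataFrame indexed by gene with columns ``log2fc`` and
    ``status``. Under the exclusion policy, genes whose control mean is
    zero are excluded (no fold change); under the pseudo policy, zero
    means on either side are replaced with ``pseudo`` (0.01 by default)
    before taking the ratio.
    """
    if zero_policy not in ZERO_POLICIES:
        raise ValidationError(f"unknown zero_policy {zero_policy!r}; expected {ZERO_POLICIES}")
    if not tumor_means.index.equals(control_means.index):
        control_means = control_means.reindex(tumor_means.index)
        if control_means.isna().any():
            raise ValidationError("tumor and control mean vectors cover different genes")
    t = tumor_means.to_numpy(dtype=float)
    c = control_means.to_numpy(dtype=float)
    if (t < 0).any() or (c < 0).any():
        raise ValidationError("mean abundances must be non-negative")

    log2fc = np.full(t.shape, np.nan)
    status = np.empty(t.shape, dtype=object)
    if zero_policy == "exclude_zero_denominator":
        excl = c == 0
        ok = ~excl
        with np.errstate(divide="ignore"):
            log2fc[ok] = np.log2(t[ok] / c[ok])  # tumor 0 -> -inf, kept as control-enriched
        status[excl] = STATUS_EXCLUDED
    else:
        t = np.where(t == 0, pseudo, t)
        c = np.where(c == 0, pseudo, c)
        ok = np.ones(t.shape, dtype=bool)
        log2fc[ok] = np.log2(t / c)
    status[ok & (log2fc >= threshold)] = STATUS_TUMOR
    status[ok & (log2fc <= -threshold)] = STATUS_CONTROL
    status[ok & (np.abs(log2fc) < threshold)] = STATUS_UNCHANGED
    out = pd.DataFrame({"log2fc": log2fc, "status": status}, index=tumor_means.index)
    out.loc[out["status"] == STATUS_EXCLUDED, "log2fc"] = np.nan
    return out


@dataclass(frozen=True)
class RankedList:
    """Gene scores in strictly-determined descending order."""

    scores: pd.Series
    metric: str = "signal2noise"

    def __post_init__(self) -> None:
        if self.scores.index.duplicated().any():
            raise ValidationError("ranked list contains duplicate genes")

    @property
    def genes(self) -> list[str]:
        return list(self.scores.index)

    def __len__(self) -> int:
        return len(self.scores)


def signal2noise_scores(
    tumor: pd.DataFrame,
    control: pd.DataFrame,
    floor_frac: float = 0.2,
    abs_floor: float | None = None,
) -> pd.Series:
    """Signal2Noise statistic per gene from per-class expression columns.

    Each class standard deviation (sample sd, ddof=1) is floored at
    max(sigma, floor_frac * |mean|, abs_floor); the default absolute floor
    is 0.2 * floor_frac, the convention of the reference enrichment tool.
    """
    if tumor.shape[1] < 2 or control.shape[1] < 2:
        raise ValidationError("signal2noise needs >= 2 columns per class")
    if abs_floor is None:
        abs_floor = 0.2 * floor_frac
    mu_t = tumor.mean(axis=1)
    mu_c = control.mean(axis=1)
    sd_t = tumor.std(axis=1, ddof=1)
    sd_c = control.std(axis=1, ddof=1)
    sd_t = np.maximum(np.maximum(sd_t, floor_frac * mu_t.abs()), abs_floor)
    sd_c = np.maximum(np.maximum(sd_c, floor_frac * mu_c.abs()), abs_floor)
    return ((mu_t - mu_c) / (sd_t + sd_c)).rename("signal2noise")


def _class_columns(
    matrix: ExpressionMatrix, metadata: SampleMetadata, use_isolate_averages: bool
) -> tuple[pd.DataFrame, pd.DataFrame]:
    if use_isolate_averages:
        averaged = average_replicates(matrix, metadata)
        groups = metadata.isolate_groups()
    else:
        averaged = matrix
        groups = metadata.table["group"]
    cols_t = [s for s in averaged.sample_ids if groups.get(s) == "tumor"]
    cols_c = [s for s in averaged.sample_ids if groups.get(s) == "control"]
    return averaged.values[cols_t], averaged.values[cols_c]


def signal2noise_rank(
    matrix: ExpressionMatrix,
    metadata: SampleMetadata,
    floor_frac: float = 0.2,
    abs_floor: float | None = None,
    use_isolate_averages: bool = True,
) -> RankedList:
    """Rank all genes by Signal2Noise, descending; ties broken by gene id."""
    tumor, control = _class_columns(matrix, metadata, use_isolate_averages)
    s = signal2noise_scores(tumor, control, floor_frac, abs_floor)
    order = sorted(s.index, key=lambda g: (-s[g], g))
    return RankedList(s.reindex(order))


@dataclass
class EnrichmentResult:
    """Weighted running-sum enrichment output for one gene set."""

    set_name: str
    es: float
    running_sum: np.ndarray
    leading_edge: list[str]
    nes: float | None = None
    p_value: float | None = None
    n_permutations: int = 0
    n_same_sign_null: int = 0


def _running_sum(scores: np.ndarray, hit: np.ndarray, weight_p: float) -> np.ndarray:
    n = scores.size
    n_hit = int(hit.sum())
    w = np.abs(scores) ** weight_p
    w_hit_total = w[hit].sum()
    if w_hit_total == 0:  # all hit scores zero: fall back to unweighted hits
        w = np.ones(n)
        w_hit_total = float(n_hit)
    step = np.where(hit, w / w_hit_total, -1.0 / (n - n_hit))
    return np.cumsum(step)


def gsea_es(ranked: RankedList, gene_set: list[str], weight_p: float = 1.0,
            set_name: str = "set") -> EnrichmentResult:
    """Enrichment score of a gene set against a ranked list.

    A set member at position i increments the running sum by
    |score_i|^p / sum over members of |score|^p; a non-member decrements
    it by 1/(N - N_members). ES is the signed extremum of the walk; the
    leading edge is the members at or before (after, for negative ES) the
    extremum.
    """
    genes = ranked.genes
    members = set(gene_set)
    hit = np.array([g in members for g in genes])
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise ValidationError(f"gene set {set_name!r} has no genes in the ranked list")
    if n_hit == len(genes):
        raise ValidationError(f"gene set {set_name!r} covers the entire ranked list")
    walk = _running_sum(ranked.scores.to_numpy(dtype=float), hit, weight_p)
    i_ext = int(np.argmax(np.abs(walk)))
    es = float(walk[i_ext])
    if es >= 0:
        leading = [g for k, g in enumerate(genes) if hit[k] and k <= i_ext]
    else:
        leading = [g for k, g in enumerate(genes) if hit[k] and k >= i_ext]
    return EnrichmentResult(set_name, es, walk, leading)


def _es_only(scores: np.ndarray, hit: np.ndarray, weight_p: float) -> float:
    walk = _running_sum(scores, hit, weight_p)
    return float(walk[np.argmax(np.abs(walk))])


def _null_es_gene_set(
    scores: np.ndarray, set_size: int, n_perm: int, weight_p: float, rng: np.random.Generator
) -> np.ndarray:
    """Null ES distribution from random same-size gene sets (vectorised)."""
    n = scores.size
    w = np.abs(scores) ** weight_p
    # random set per row: the first set_size slots of a random permutation
    picks = np.argpartition(rng.random((n_perm, n)), set_size - 1, axis=1)[:, :set_size]
    hits = np.zeros((n_perm, n), dtype=bool)
    np.put_along_axis(hits, picks, True, axis=1)
    w_tot = (w[None, :] * hits).sum(axis=1)
    steps = np.where(hits, w[None, :], 0.0)
    # rows where all member weights are zero fall back to unweighted hits
    degenerate = w_tot == 0
    if degenerate.any():
        steps[degenerate] = hits[degenerate].astype(float)
        w_tot[degenerate] = set_size
    steps = steps / w_tot[:, None]
    steps[~hits] = -1.0 / (n - set_size)
    walks = np.cumsum(steps, axis=1)
    idx = np.argmax(np.abs(walks), axis=1)
    return walks[np.arange(n_perm), idx]


def permutation_pvalue(es: float, null_es: np.ndarray) -> tuple[float, float, int]:
    """One-sided p (same-sign tail, +1 smoothing), NES, same-sign null count.

    p = (1 + #{same-sign null with |null| >= |ES|}) / (1 + #same-sign null);
    NES = ES / mean(|same-sign null ES|). Conditioning on the sign keeps the
    p-value exactly uniform under a random gene set, so its attainable
    minimum is 1/(1 + #same-sign null), not 1/(1 + n_perm).
    """
    if es >= 0:
        same = null_es[null_es >= 0]
        k = int((same >= es).sum())
    else:
        same = null_es[null_es < 0]
        k = int((same <= es).sum())
    p = (1 + k) / (1 + same.size)
    denom = float(np.abs(same).mean()) if same.size else np.nan
    nes = es / denom if denom and np.isfinite(denom) and denom > 0 else np.nan
    return p, nes, int(same.size)


def gsea_permutation_p(
    matrix: ExpressionMatrix,
    metadata: SampleMetadata,
    gene_set: list[str],
    n_perm: int = 1000,
    scheme: str = "gene_set",
    seed: int = 0,
    weight_p: float = 1.0,
    set_name: str = "set",
    use_isolate_averages: bool = True,
) -> EnrichmentResult:
    """ES with permutation p-value and NES.

    ``scheme="gene_set"`` draws random same-size gene sets from the ranked
    universe (robust for small cohorts); ``scheme="phenotype"`` permutes
    the tumor/control labels over columns and re-ranks each time.
    """
    if scheme not in ("phenotype", "gene_set"):
        raise ValidationError(f"unknown permutation scheme {scheme!r}")
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    ranked = signal2noise_rank(matrix, metadata, use_isolate_averages=use_isolate_averages)
    result = gsea_es(ranked, gene_set, weight_p, set_name)
    scores = ranked.scores.to_numpy(dtype=float)
    members = set(gene_set) & set(ranked.genes)

    if scheme == "gene_set":
        null = _null_es_gene_set(scores, len(members), n_perm, weight_p, rng)
    else:
        tumor, control = _class_columns(matrix, metadata, use_isolate_averages)
        n_t = tumor.shape[1]
        pooled = pd.concat([tumor, control], axis=1)
        if pooled.shape[1] < 7:
            logger.warning(
                "phenotype permutation with %d columns has few distinct label "
                "assignments; consider scheme='gene_set'", pooled.shape[1]
            )
        null = np.empty(n_perm)
        cols = np.arange(pooled.shape[1])
        for b in range(n_perm):
            perm = rng.permutation(cols)
            t_b = pooled.iloc[:, perm[:n_t]]
            c_b = pooled.iloc[:, perm[n_t:]]
            s_b = signal2noise_scores(t_b, c_b)
            order = sorted(s_b.index, key=lambda g: (-s_b[g], g))
            s_sorted = s_b.reindex(order)
            hit_b = np.array([g in members for g in order])
            null[b] = _es_only(s_sorted.to_numpy(dtype=float), hit_b, weight_p)

    p, nes, n_same = permutation_pvalue(result.es, null)
    result.p_value = p
    result.nes = nes
    result.n_permutations = n_perm
    result.n_same_sign_null = n_same
    return result


@dataclass
class IGCSelection:
    """Candidate genes surviving rank + abundance filtering, with audit."""

    candidates: list[str]
    top_k: int
    cpm_min: float
    dropped_below_rank: list[str] = field(default_factory=list)
    dropped_low_cpm: list[str] = field(default_factory=list)


def select_candidates(
    ranked: RankedList,
    tumor_mean_cpm: pd.Series,
    top_k: int = 40,
    cpm_min: float = 1.0,
    by_absolute_score: bool = False,
) -> IGCSelection:
    """Top-k ranked genes that also clear a minimum mean tumor CPM.

    The default takes the top of the ranking (the tumor-enriched end);
    ``by_absolute_score=True`` selects by |score| instead.
    """
    if top_k > len(ranked):
        raise ValidationError(f"top_k={top_k} exceeds ranked list length {len(ranked)}")
    genes = ranked.genes
    if by_absolute_score:
        genes = sorted(genes, key=lambda g: (-abs(ranked.scores[g]), g))
    top = genes[:top_k]
    missing = [g for g in top if g not in tumor_mean_cpm.index]
    if missing:
        raise ValidationError(f"no tumor mean CPM for genes {missing}")
    kept = [g for g in top if tumor_mean_cpm[g] >= cpm_min]
    return IGCSelection(
        candidates=kept,
        top_k=top_k,
        cpm_min=cpm_min,
        dropped_below_rank=genes[top_k:],
        dropped_low_cpm=[g for g in top if g not in kept],
    )


def family_enrichment(
    fold_changes: pd.DataFrame,
    families: FamilyAnnotation,
    tumor_mean_cpm: pd.Series,
    fold_cut: float = 2.0,
) -> pd.DataFrame:
    """Per-family summary of fold-change behaviour.

    Uses only genes with a defined fold change (zero-denominator exclusions
    drop out). Reports mean log2 fold change, the proportion of members
    with linear fold change strictly greater than ``fold_cut``, mean tumor
    CPM, and the member count used. Families with <= 1 usable member are
    omitted; genes without a family annotation are skipped with a warning.
    """
    usable = fold_changes[fold_changes["status"] != STATUS_EXCLUDED].dropna(subset=["log2fc"])
    unannotated = [g for g in usable.index if families.family_of(g) is None]
    if unannotated:
        logger.warning("family_enrichment: %d genes lack a family annotation", len(unannotated))
    rows = []
    fams = usable.index.to_series().map(families.mapping)
    for family, idx in usable.groupby(fams).groups.items():
        members = usable.loc[list(idx)]
        if len(members) <= 1:
            continue
        lfc = members["log2fc"]
        rows.append(
            {
                "family": family,
                "mean_log2fc": float(lfc.mean()),
                "proportion_above_fold": float((2.0**lfc > fold_cut).mean()),
                "mean_tumor_cpm": float(tumor_mean_cpm.reindex(members.index).mean()),
                "n_members_used": len(members),
            }
        )
    return pd.DataFrame(rows).set_index("family") if rows else pd.DataFrame(
        columns=["mean_log2fc", "proportion_above_fold", "mean_tumor_cpm", "n_members_used"]
    )
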