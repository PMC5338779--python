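"""Region-resolved expression analysis over the seven anatomic compartments.

Tumor atlas FPKM values are averaged in two levels — replicates to sample,
samples to region — then screened with simple abundance rules: a >= 2-fold
enrichment of the tumor edge (mean of LE and IT) over all other regions,
a high-abundance class at >= 5 FPKM in at least one region, a low class at
< 1 FPKM everywhere, family-by-region expression proportions, and a
cell-type specificity partition for normal neural cell-type panels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .normalization import average_replicates
from .types import (
    ExpressionMatrix,
    FamilyAnnotation,
    REGIONS,
    SampleMetadata,
    ValidationError,
)

logger = logging.getLogger("channelscreen")


@dataclass
class RegionalProfile:
    """Gene x region mean FPKM, plus the per-sample values behind it."""

    region_means: pd.DataFrame          # genes x regions
    sample_values: pd.DataFrame         # genes x (isolate-averaged) samples
    sample_regions: pd.Series           # sample -> region
    n_samples: pd.Series                # region -> sample count

    def __post_init__(self) -> None:
        bad = set(self.region_means.columns) - set(REGIONS)
        if bad:
            raise ValidationError(f"unknown region labels {sorted(bad)}")
        if (self.region_means.to_numpy() < 0).any():
            raise ValidationError("region means must be non-negative")

    @property
    def regions(self) -> list[str]:
        return list(self.region_means.columns)


def aggregate_by_region(
    matrix: ExpressionMatrix, metadata: SampleMetadata
) -> RegionalProfile:
    """Two-level mean: replicates -> sample, then samples -> region.

    Regions with zero samples are omitted with a warning; every sample must
    carry a region label.
    """
    matrix.require_unit("FPKM", "CPM")
    metadata.check_matches(matrix)
    if "region" not in metadata.table:
        raise ValidationError("metadata has no 'region' column")
    averaged = average_replicates(matrix, metadata)
    iso = metadata.isolates()
    region_of: dict[str, str] = {}
    for sample in matrix.sample_ids:
        r = metadata.table.loc[sample, "region"]
        if pd.isna(r):
            raise ValidationError(f"sample {sample!r} has no region label")
        isolate = iso[sample]
        if isolate in region_of and region_of[isolate] != r:
            raise ValidationError(f"isolate {isolate!r} spans multiple regions")
        region_of[isolate] = r
    sample_regions = pd.Series(region_of).reindex(averaged.sample_ids)
    means = {}
    counts = {}
    for region in REGIONS:
        cols = [s for s in averaged.sample_ids if sample_regions[s] == region]
        if not cols:
            logger.warning("region %r has no samples; omitted from profile", region)
            continue
        means[region] = averaged.values[cols].mean(axis=1)
        counts[region] = len(cols)
    return RegionalProfile(
        region_means=pd.DataFrame(means, index=averaged.values.index),
        sample_values=averaged.values,
        sample_regions=sample_regions,
        n_samples=pd.Series(counts, dtype=int),
    )


def edge_enrichment(profile: RegionalProfile, fold: float = 2.0) -> pd.DataFrame:
    """Flag genes enriched at the tumor edge (LE/IT) over all other regions.

    ratio = mean(LE, IT) / mean(other region means); a gene is flagged iff
    ratio >= fold. A zero denominator with positive numerator yields an
    infinite ratio (flagged); 0/0 is defined as 1 (absence of signal is not
    enrichment).
    """
    edge_regions = [r for r in ("LE", "IT") if r in profile.regions]
    if not edge_regions:
        raise ValidationError("profile lacks both LE and IT regions")
    others = [r for r in profile.regions if r not in ("LE", "IT")]
    if not others:
        raise ValidationError("profile has no non-edge regions to compare against")
    num = profile.region_means[edge_regions].mean(axis=1)
    den = profile.region_means[others].mean(axis=1)
    ratio = np.where(
        den > 0, num / den.replace(0, np.nan), np.where(num > 0, np.inf, 1.0)
    )
    ratio = pd.Series(ratio, index=profile.region_means.index, name="edge_ratio")
    return pd.DataFrame({"edge_ratio": ratio, "flagged": ratio >= fold})


def abundance_classes(
    profile: RegionalProfile, high: float = 5.0, low: float = 1.0
) -> pd.Series:
    """Partition genes into high / low / intermediate abundance.

    high: >= ``high`` FPKM in at least one region; low: < ``low`` FPKM
    across all regions; intermediate otherwise. Boundaries are inclusive
    for high (exactly 5 is high) and strict for low (exactly 1 everywhere
    is intermediate).
    """
    if high <= low:
        raise ValidationError(f"high cutoff ({high}) must exceed low cutoff ({low})")
    m = profile.region_means
    is_high = (m >= high).any(axis=1)
    is_low = (m < low).all(axis=1)
    out = pd.Series("intermediate", index=m.index, name="abundance_class")
    out[is_low] = "low"
    out[is_high] = "high"
    return out


def family_region_proportions(
    profile: RegionalProfile,
    families: FamilyAnnotation,
    expr_cut: float = 1.0,
    min_family: int = 3,
) -> pd.DataFrame:
    """Per family and region: proportion of members with mean FPKM > cut.

    Families with fewer than ``min_family`` annotated members in the
    profile are omitted; genes without an annotation are skipped with a
    warning.
    """
    m = profile.region_means
    fams = m.index.to_series().map(families.mapping)
    unannotated = int(fams.isna().sum())
    if unannotated:
        logger.warning("family_region_proportions: %d genes lack a family annotation",
                       unannotated)
    rows = {}
    for family, idx in m.groupby(fams).groups.items():
        members = m.loc[list(idx)]
        if len(members) < min_family:
            continue
        rows[family] = (members > expr_cut).mean(axis=0)
    if not rows:
        return pd.DataFrame(columns=m.columns)
    return pd.DataFrame(rows).T.loc[:, m.columns]


def majority_expressed(
    profile: RegionalProfile, region: str, threshold: float = 1.0
) -> pd.Series:
    """Genes expressed >= threshold in a strict majority of a region's samples."""
    cols = [s for s in profile.sample_values.columns if profile.sample_regions[s] == region]
    if not cols:
        raise ValidationError(f"region {region!r} has no samples")
    frac = (profile.sample_values[cols] >= threshold).mean(axis=1)
    return (frac > 0.5).rename(f"majority_{region}")


def cell_type_specificity(
    celltype_means: pd.DataFrame, low_cut: float = 1.0, ratio_cut: float = 2.0
) -> pd.DataFrame:
    """Classify genes as cell-type specific, multi-type, or low abundance.

    A gene is ``low_abundance`` if no cell-type mean reaches ``low_cut``
    FPKM; otherwise ``specific`` to the top cell type if its mean is at
    least ``ratio_cut`` times the second-highest, else ``multiple``. The
    dominance ratio is a declared convention, exposed as a parameter.
    """
    if celltype_means.shape[1] < 2:
        raise ValidationError("cell_type_specificity needs >= 2 cell types")
    if (celltype_means.to_numpy() < 0).any():
        raise ValidationError("cell-type means must be non-negative")
    classes = []
    for gene, row in celltype_means.iterrows():
        if (row < low_cut).all():
            classes.append({"gene": gene, "class": "low_abundance", "cell_type": None})
            continue
        top = row.idxmax()
        second = row.drop(top).max()
        if row[top] >= ratio_cut * second:
            classes.append({"gene": gene, "class": "specific", "cell_type": top})
        else:
            classes.append({"gene": gene, "class": "multiple", "cell_type": None})
    return pd.DataFrame(classes).set_index("gene")
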