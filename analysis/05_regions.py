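#!/usr/bin/env python
"""Regional expression profiling of the synthetic tumor atlas.

Aggregates FPKM replicates to samples and samples to the seven anatomic
compartments, then applies the regional rules: 2-fold LE/IT edge
enrichment, the >= 5 / < 1 FPKM abundance classes, and family-by-region
expression proportions. Scores edge recovery against the planted truth.
"""

import json
from pathlib import Path

from channelscreen import io_formats as io
from channelscreen import regional_profiles as rp

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    src = ROOT / "synthetic" / "regional"
    if not (src / "fpkm.tsv").exists():
        raise SystemExit("run analysis/01_simulate_cohorts.py first")
    out = ROOT / "regions"
    out.mkdir(parents=True, exist_ok=True)

    fpkm = io.read_expression_table(src / "fpkm.tsv", unit="FPKM")
    meta = io.read_sample_metadata(src / "region_metadata.tsv")
    families = io.read_family_table(ROOT / "synthetic" / "screen" / "families.tsv")
    edge_truth = set(json.loads((src / "truth.json").read_text())["edge_genes"])

    profile = rp.aggregate_by_region(fpkm, meta)
    profile.region_means.to_csv(out / "region_means.tsv", sep="\t",
                                index_label="gene_id")
    print(f"profile: {profile.region_means.shape[0]} genes x "
          f"{len(profile.regions)} regions "
          f"({int(profile.n_samples.sum())} samples)")

    edge = rp.edge_enrichment(profile, fold=2.0)
    edge.to_csv(out / "edge_enrichment.tsv", sep="\t", index_label="gene_id")
    flagged = edge.index[edge["flagged"]]
    recovered = len(set(flagged) & edge_truth)
    print(f"edge enrichment (>= 2-fold LE/IT): {len(flagged)} genes flagged, "
          f"{recovered}/{len(edge_truth)} planted edge genes recovered")

    classes = rp.abundance_classes(profile)
    classes.to_csv(out / "abundance_classes.tsv", sep="\t", index_label="gene_id")
    print("abundance classes:", classes.value_counts().to_dict())

    props = rp.family_region_proportions(profile, families)
    props.to_csv(out / "family_region_proportions.tsv", sep="\t",
                 index_label="family")
    print(f"family-by-region proportions for {len(props)} families "
          f"(>= 3 members) -> {out / 'family_region_proportions.tsv'}")


if __name__ == "__main__":
    main()
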