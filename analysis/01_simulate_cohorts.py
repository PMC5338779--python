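#!/usr/bin/env python
"""Generate the synthetic study inputs used by the downstream analyses.

Writes, under results/synthetic/:
  screen/   counts.tsv, metadata.tsv, channels.gmt, families.tsv, truth.json
  regional/ fpkm.tsv, region_metadata.tsv, true_region_means.tsv
  subtype/  reference.tsv, reference_labels.tsv, signature_genes.txt
  survival/ survival.tsv

The screen cohort mirrors the study design: 20 tumor stem-cell isolates vs
5 normal neural controls, 3 replicates each, 1000 genes with 5% planted
tumor-enriched at log2 effect 3.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from channelscreen import io_formats as io
from channelscreen import synthetic_data as sim
from channelscreen.types import GeneSetCollection, REGIONS

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 2026
ROOT = Path(__file__).resolve().parent.parent / "results" / "synthetic"


def main() -> None:
    # --- screen cohort ---------------------------------------------------
    out = ROOT / "screen"
    out.mkdir(parents=True, exist_ok=True)
    cfg = sim.ScreenSimConfig(seed=SEED)
    matrix, meta, truth = sim.simulate_expression(cfg)
    io.write_expression_table(matrix, out / "counts.tsv")
    io.write_sample_metadata(meta, out / "metadata.tsv")

    # "channel" set: all planted genes plus an equal number of unplanted
    rng = np.random.default_rng(SEED + 1)
    unplanted = [g for g in matrix.gene_ids if g not in set(truth.planted_gene_ids)]
    decoys = sorted(rng.choice(unplanted, len(truth.planted_gene_ids), replace=False))
    channels = sorted(truth.planted_gene_ids) + decoys
    io.write_gene_sets_gmt(
        GeneSetCollection({"channels": channels}, provenance="synthetic"),
        out / "channels.gmt",
    )
    families = pd.DataFrame(
        {"gene_id": channels,
         "family": [f"fam{(i // 5) % 8}" for i in range(len(channels))]}
    )
    families.to_csv(out / "families.tsv", sep="\t", index=False)
    (out / "truth.json").write_text(json.dumps(
        {"planted_gene_ids": truth.planted_gene_ids,
         "planted_log2_effect": cfg.planted_log2_effect, "seed": SEED}, indent=2))
    print(f"screen cohort: {matrix.shape[0]} genes x {matrix.shape[1]} samples, "
          f"{len(truth.planted_gene_ids)} planted -> {out}")

    # --- regional atlas --------------------------------------------------
    out = ROOT / "regional"
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED + 2)
    genes = channels  # profile the screened genes across regions
    means = pd.DataFrame(rng.lognormal(0.5, 1.0, (len(genes), len(REGIONS))),
                         index=genes, columns=list(REGIONS))
    edge = sorted(rng.choice(genes, 20, replace=False))
    other = [r for r in REGIONS if r not in ("LE", "IT")]
    base = means.loc[edge, other].mean(axis=1)
    means.loc[edge, "LE"] = 4.0 * base
    means.loc[edge, "IT"] = 4.0 * base
    fpkm, rmeta, _ = sim.simulate_regional(region_means=means, samples_per_region=3,
                                           noise_sd=0.3, seed=SEED + 3)
    io.write_expression_table(fpkm, out / "fpkm.tsv")
    io.write_sample_metadata(rmeta, out / "region_metadata.tsv")
    means.to_csv(out / "true_region_means.tsv", sep="\t", index_label="gene_id")
    (out / "truth.json").write_text(json.dumps({"edge_genes": edge}, indent=2))
    print(f"regional atlas: {len(genes)} genes x {fpkm.shape[1]} samples, "
          f"{len(edge)} edge-planted -> {out}")

    # --- subtype reference ----------------------------------------------
    out = ROOT / "subtype"
    out.mkdir(parents=True, exist_ok=True)
    ref, labels, _ = sim.simulate_subtype_reference(samples_per_subtype=10,
                                                    seed=SEED + 4)
    io.write_expression_table(ref, out / "reference.tsv")
    labels.to_frame().to_csv(out / "reference_labels.tsv", sep="\t",
                             index_label="sample_id")
    (out / "signature_genes.txt").write_text("\n".join(ref.gene_ids) + "\n")
    print(f"subtype reference: {ref.shape[0]} signature genes x "
          f"{ref.shape[1]} samples -> {out}")

    # --- survival cohort -------------------------------------------------
    out = ROOT / "survival"
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED + 5)
    expr = pd.Series(rng.lognormal(1, 1, 500),
                     index=[f"patient{i:03d}" for i in range(500)])
    table = sim.simulate_survival(expr, beta=1.0, baseline_hazard=1e-3,
                                  censor_rate=0.1, seed=SEED + 6)
    io.write_survival_table(table, out / "survival.tsv")
    print(f"survival cohort: {len(table)} patients, hazard beta = 1 -> {out}")


if __name__ == "__main__":
    main()
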