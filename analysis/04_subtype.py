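#!/usr/bin/env python
"""Molecular subtype assignment and unsupervised clustering.

Builds median centroids from the labelled synthetic reference, assigns
every reference sample by maximal Spearman correlation (out-of-sample via
a train/test split), reports the accuracy, and writes the euclidean/UPGMA
dendrogram of the screen cohort's isolates as newick.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from channelscreen import io_formats as io
from channelscreen import normalization as norm
from channelscreen import subtype_classifier as sc

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    src = ROOT / "synthetic" / "subtype"
    if not (src / "reference.tsv").exists():
        raise SystemExit("run analysis/01_simulate_cohorts.py first")
    out = ROOT / "subtype"
    out.mkdir(parents=True, exist_ok=True)

    ref = io.read_expression_table(src / "reference.tsv", unit="CPM")
    labels = pd.read_csv(src / "reference_labels.tsv", sep="\t", index_col=0).iloc[:, 0]
    signature = [ln.strip() for ln in (src / "signature_genes.txt").read_text().splitlines()
                 if ln.strip()]

    train = [s for s in ref.sample_ids if int(s.rsplit("_", 1)[1]) <= 5]
    test = [s for s in ref.sample_ids if s not in set(train)]
    centroids = sc.compute_centroids(ref.with_values(ref.values[train]),
                                     labels[train], signature)

    rows = []
    for s in test:
        call = sc.classify_by_centroid(ref.values[s], centroids)
        rows.append({"sample_id": s, "true": labels[s], "called": call.subtype,
                     "margin": call.margin})
    calls = pd.DataFrame(rows).set_index("sample_id")
    calls.to_csv(out / "subtype_calls.tsv", sep="\t")
    acc = (calls["true"] == calls["called"]).mean()
    print(f"held-out assignment accuracy: {acc:.3f} over {len(calls)} samples "
          f"(mean margin {calls['margin'].mean():.3f})")

    cpm_path = ROOT / "normalize" / "cpm_by_isolate.tsv"
    if cpm_path.exists():
        cpm = io.read_expression_table(cpm_path, unit="CPM")
        tree = sc.hierarchical_cluster(cpm, metric="euclidean", linkage="average")
        tree.write_newick(out / "isolate_dendrogram.nwk")
        print(f"isolate dendrogram (euclidean/UPGMA) -> {out / 'isolate_dendrogram.nwk'}")
    else:
        print("skipping cohort dendrogram (run 02_normalize.py to produce CPMs)")


if __name__ == "__main__":
    main()
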