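#!/usr/bin/env python
"""The enrichment screen on the synthetic cohort, scored against truth.

Fold-change classification (with the zero-denominator exclusion rule),
Signal2Noise ranking, running-sum enrichment of the "channels" set with a
permutation p-value, top-40 / CPM >= 1 candidate selection, and the
family-level summary. Prints how many planted genes the screen recovered.
"""

import json
from pathlib import Path

from channelscreen import enrichment_screen as es
from channelscreen import io_formats as io
from channelscreen import normalization as norm

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    src = ROOT / "synthetic" / "screen"
    cpm_path = ROOT / "normalize" / "cpm.tsv"
    if not cpm_path.exists():
        raise SystemExit("run analysis/02_normalize.py first")
    out = ROOT / "screen"
    out.mkdir(parents=True, exist_ok=True)

    cpm = io.read_expression_table(cpm_path, unit="CPM")
    meta = io.read_sample_metadata(src / "metadata.tsv")
    sets = io.read_gene_sets_gmt(src / "channels.gmt")
    families = io.read_family_table(src / "families.tsv")
    truth = json.loads((src / "truth.json").read_text())
    planted = set(truth["planted_gene_ids"])

    tumor_means = norm.group_means(cpm, meta, "tumor")
    control_means = norm.group_means(cpm, meta, "control")

    fc = es.log2fc_screen(tumor_means, control_means,
                          zero_policy="exclude_zero_denominator")
    fc.to_csv(out / "fold_changes.tsv", sep="\t", index_label="gene_id")
    counts = fc["status"].value_counts()
    print("fold-change screen (|log2FC| >= 2):", dict(counts))

    ranked = es.signal2noise_rank(cpm, meta)
    ranked.scores.to_csv(out / "ranking.tsv", sep="\t", index_label="gene_id")

    res = es.gsea_permutation_p(cpm, meta, sets["channels"], n_perm=1000,
                                seed=truth["seed"], set_name="channels")
    print(f"channels set: ES = {res.es:.3f}, NES = {res.nes:.2f}, "
          f"p = {res.p_value:.4g}, leading edge = {len(res.leading_edge)} genes")

    in_set = [g for g in ranked.genes if g in set(sets["channels"])]
    set_ranked = es.RankedList(ranked.scores.reindex(in_set))
    sel = es.select_candidates(set_ranked, tumor_means, top_k=40, cpm_min=1.0)
    hits = len(set(sel.candidates) & planted)
    print(f"selection: top 40 by rank, {len(sel.candidates)} pass CPM >= 1; "
          f"{hits} of {len(sel.candidates)} are planted "
          f"({len(planted)} planted in total)")
    with open(out / "candidates.tsv", "w") as fh:
        fh.write("gene_id\tplanted\n")
        for g in sel.candidates:
            fh.write(f"{g}\t{int(g in planted)}\n")

    fam = es.family_enrichment(fc, families, tumor_means)
    fam.to_csv(out / "family_enrichment.tsv", sep="\t")
    top_fam = fam.sort_values("mean_log2fc", ascending=False).head(3)
    print("top families by mean log2FC:")
    for name, row in top_fam.iterrows():
        print(f"  {name}: mean log2FC {row.mean_log2fc:.2f}, "
              f"proportion > 2-fold {row.proportion_above_fold:.2f}, "
              f"n = {int(row.n_members_used)}")


if __name__ == "__main__":
    main()
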