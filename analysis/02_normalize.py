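#!/usr/bin/env python
"""TMM-normalize the screen cohort and write its CPM currency.

Reads results/synthetic/screen/{counts,metadata}.tsv (from 01), computes
TMM scale factors, CPM values, and the replicate-averaged per-isolate
table every later stage consumes. Reports the factor spread as a sanity
check that library composition was handled.
"""

from pathlib import Path

from channelscreen import io_formats as io
from channelscreen import normalization as norm

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    src = ROOT / "synthetic" / "screen"
    if not (src / "counts.tsv").exists():
        raise SystemExit("run analysis/01_simulate_cohorts.py first")
    out = ROOT / "normalize"
    out.mkdir(parents=True, exist_ok=True)

    counts = io.read_expression_table(src / "counts.tsv", unit="counts")
    meta = io.read_sample_metadata(src / "metadata.tsv")
    factors = norm.tmm_factors(counts)
    cpm = norm.cpm(counts, factors)
    averaged = norm.average_replicates(cpm, meta)

    factors.factors.to_csv(out / "tmm_factors.tsv", sep="\t", index_label="sample_id")
    io.write_expression_table(cpm, out / "cpm.tsv")
    io.write_expression_table(averaged, out / "cpm_by_isolate.tsv")

    f = factors.factors
    print(f"TMM reference sample: {factors.reference_sample_id}")
    print(f"factor range: {f.min():.4f} .. {f.max():.4f} "
          f"(geometric mean {f.prod() ** (1 / len(f)):.6f})")
    print(f"CPM tables -> {out} ({cpm.shape[1]} replicate columns, "
          f"{averaged.shape[1]} isolates)")


if __name__ == "__main__":
    main()
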