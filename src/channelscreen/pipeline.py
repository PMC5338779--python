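"""End-to-end orchestration: normalize -> screen -> subtype -> regions ->
survival, from a single declarative configuration, with a run manifest
recording resolved parameters and output digests for provenance.

Stage parameters default to the screen's canonical values: |2| log2
fold-change threshold, top 40 ranked genes, mean tumor CPM >= 1, 2-fold
edge enrichment, 5/1 FPKM abundance cutoffs, 0.10/0.90 survival
quantiles, and a 3-mutant-sample inclusion rule.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import enrichment_screen as screen
from . import io_formats as io
from . import normalization as norm
from . import regional_profiles as regions
from . import subtype_classifier as subtype
from . import survival_assoc as surv
from .types import ValidationError

logger = logging.getLogger("channelscreen")


@dataclass
class RunConfig:
    """Paths and parameters for a pipeline run.

    Stages run when their inputs are provided: normalization needs
    ``counts`` + ``metadata``; the screen additionally needs ``gene_sets``;
    subtyping needs ``reference`` + ``reference_labels`` + ``signature``;
    regions need ``fpkm`` + ``region_metadata``; survival needs
    ``survival`` and ``survival_gene``.
    """

    out_dir: str = "channelscreen_run"
    counts: str | None = None
    metadata: str | None = None
    gene_sets: str | None = None
    families: str | None = None
    reference: str | None = None
    reference_labels: str | None = None
    signature: str | None = None
    fpkm: str | None = None
    region_metadata: str | None = None
    survival: str | None = None
    survival_gene: str | None = None

    use_tmm: bool = True
    fc_threshold: float = 2.0
    zero_policy: str = "exclude_zero_denominator"
    top_k: int = 40
    cpm_min: float = 1.0
    n_perm: int = 1000
    perm_scheme: str = "gene_set"
    edge_fold: float = 2.0
    fpkm_high: float = 5.0
    fpkm_low: float = 1.0
    survival_split: str = "quantile"
    quantile_lo: float = 0.10
    quantile_hi: float = 0.90
    min_mutant: int = 3
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


@dataclass
class RunManifest:
    """Provenance record: resolved config, stage outputs and their digests."""

    config: dict
    version: str = __version__
    stages: list[str] = field(default_factory=list)
    digests: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    failure: str | None = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _record(manifest: RunManifest, path: Path) -> None:
    manifest.digests[path.name] = _digest(path)


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the configured stages in dependency order.

    Missing inputs abort before any stage runs; a stage failure aborts
    with a partial manifest recording the completed stages.
    """
    for name in ("counts", "metadata", "gene_sets", "families", "reference",
                 "reference_labels", "signature", "fpkm", "region_metadata", "survival"):
        p = getattr(config, name)
        if p is not None and not Path(p).exists():
            raise ValidationError(f"input {name!r} does not exist: {p}")
    if config.survival is not None and config.survival_gene is None:
        raise ValidationError("survival stage requested without survival_gene")

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=dataclasses.asdict(config))

    try:
        cpm_matrix = meta = None
        if config.counts is not None:
            if config.metadata is None:
                raise ValidationError("normalization needs both counts and metadata")
            counts = io.read_expression_table(config.counts, unit="counts")
            meta = io.read_sample_metadata(config.metadata)
            factors = norm.tmm_factors(counts) if config.use_tmm else None
            cpm_matrix = norm.cpm(counts, factors)
            path = out / "cpm.tsv"
            io.write_expression_table(cpm_matrix, path)
            _record(manifest, path)
            manifest.stages.append("normalize")

        if config.gene_sets is not None:
            if cpm_matrix is None or meta is None:
                raise ValidationError("screen stage needs normalized counts and metadata")
            sets = io.read_gene_sets_gmt(config.gene_sets)
            io.report_missing_set_genes(sets, cpm_matrix)
            tumor_means = norm.group_means(cpm_matrix, meta, "tumor")
            control_means = norm.group_means(cpm_matrix, meta, "control")
            fc = screen.log2fc_screen(
                tumor_means, control_means, config.fc_threshold, config.zero_policy
            )
            fc.to_csv(out / "fold_changes.tsv", sep="\t", index_label="gene_id")
            _record(manifest, out / "fold_changes.tsv")

            ranked = screen.signal2noise_rank(cpm_matrix, meta)
            ranked.scores.to_csv(out / "ranking.tsv", sep="\t", index_label="gene_id")
            _record(manifest, out / "ranking.tsv")

            results = {}
            for set_name in sets.names():
                members = [g for g in sets[set_name] if g in set(cpm_matrix.gene_ids)]
                if not members:
                    manifest.warnings.append(f"gene set {set_name!r} absent from data")
                    continue
                sub = ranked.scores.reindex([g for g in ranked.genes if g in set(members)])
                res = screen.gsea_permutation_p(
                    cpm_matrix, meta, members, n_perm=config.n_perm,
                    scheme=config.perm_scheme, seed=config.seed, set_name=set_name,
                )
                results[set_name] = res
                set_ranked = screen.RankedList(sub)
                sel = screen.select_candidates(
                    set_ranked, tumor_means,
                    top_k=min(config.top_k, len(set_ranked)), cpm_min=config.cpm_min,
                )
                pd.DataFrame(
                    {"candidate": sel.candidates}
                ).to_csv(out / f"candidates_{set_name}.tsv", sep="\t", index=False)
                _record(manifest, out / f"candidates_{set_name}.tsv")
            pd.DataFrame(
                {
                    name: {"ES": r.es, "NES": r.nes, "p_value": r.p_value,
                           "leading_edge_size": len(r.leading_edge)}
                    for name, r in results.items()
                }
            ).T.to_csv(out / "enrichment.tsv", sep="\t", index_label="set")
            _record(manifest, out / "enrichment.tsv")

            if config.families is not None:
                fams = io.read_family_table(config.families)
                fc_excl = screen.log2fc_screen(
                    tumor_means, control_means, config.fc_threshold,
                    "exclude_zero_denominator",
                )
                fam = screen.family_enrichment(fc_excl, fams, tumor_means)
                fam.to_csv(out / "family_enrichment.tsv", sep="\t")
                _record(manifest, out / "family_enrichment.tsv")
            manifest.stages.append("screen")

        if config.reference is not None:
            if config.reference_labels is None or config.signature is None:
                raise ValidationError("subtype stage needs reference, labels and signature")
            if cpm_matrix is None or meta is None:
                raise ValidationError("subtype stage needs normalized counts and metadata")
            ref = io.read_expression_table(config.reference, unit="CPM")
            labels = pd.read_csv(config.reference_labels, sep="\t", index_col=0).iloc[:, 0]
            signature = [
                ln.strip() for ln in Path(config.signature).read_text().splitlines()
                if ln.strip()
            ]
            centroids = subtype.compute_centroids(ref, labels, signature)
            iso = meta.isolates()
            calls = []
            for isolate in pd.unique(iso):
                reps = [s for s in cpm_matrix.sample_ids if iso[s] == isolate]
                rep_calls = [
                    subtype.classify_by_centroid(cpm_matrix.values[s], centroids)
                    for s in reps
                ]
                calls.append(
                    {"isolate_id": isolate,
                     "subtype": subtype.consensus_call(rep_calls),
                     "n_replicates": len(rep_calls)}
                )
            pd.DataFrame(calls).to_csv(out / "subtype_calls.tsv", sep="\t", index=False)
            _record(manifest, out / "subtype_calls.tsv")

            tree = subtype.hierarchical_cluster(cpm_matrix)
            tree.write_newick(out / "clustering.nwk")
            _record(manifest, out / "clustering.nwk")
            manifest.stages.append("subtype")

        if config.fpkm is not None:
            if config.region_metadata is None:
                raise ValidationError("regions stage needs fpkm and region_metadata")
            fpkm = io.read_expression_table(config.fpkm, unit="FPKM")
            rmeta = io.read_sample_metadata(config.region_metadata)
            profile = regions.aggregate_by_region(fpkm, rmeta)
            profile.region_means.to_csv(out / "region_means.tsv", sep="\t",
                                        index_label="gene_id")
            _record(manifest, out / "region_means.tsv")
            edge = regions.edge_enrichment(profile, config.edge_fold)
            edge.to_csv(out / "edge_enrichment.tsv", sep="\t", index_label="gene_id")
            _record(manifest, out / "edge_enrichment.tsv")
            classes = regions.abundance_classes(profile, config.fpkm_high, config.fpkm_low)
            classes.to_csv(out / "abundance_classes.tsv", sep="\t", index_label="gene_id")
            _record(manifest, out / "abundance_classes.tsv")
            if config.families is not None:
                fams = io.read_family_table(config.families)
                props = regions.family_region_proportions(profile, fams)
                props.to_csv(out / "family_region_proportions.tsv", sep="\t",
                             index_label="family")
                _record(manifest, out / "family_region_proportions.tsv")
            manifest.stages.append("regions")

        if config.survival is not None:
            table = io.read_survival_table(config.survival)
            if "expression" not in table.data:
                raise ValidationError("survival table lacks an expression column")
            expr = table.data["expression"]
            if config.survival_split == "quantile":
                strata = surv.stratify_quantile(expr, config.quantile_lo, config.quantile_hi)
            else:
                strata = surv.stratify_median(expr)
            result = surv.logrank_test(table, strata)
            rows = []
            for label in ("low", "high"):
                sub = table.data[strata == label]
                curve = surv.km_estimate(
                    type(table)(sub, table.dropped_missing_time)
                )
                rows.append({"stratum": label, "n": len(sub),
                             "median_survival": curve.median})
            summary = pd.DataFrame(rows)
            summary["chi2"] = result.chi2
            summary["p_value"] = result.p_value
            summary["gene"] = config.survival_gene
            summary.to_csv(out / "survival.tsv", sep="\t", index=False)
            _record(manifest, out / "survival.tsv")
            manifest.stages.append("survival")
    except Exception as exc:  # record partial progress, then re-raise
        manifest.failure = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(manifest.to_json())
        raise

    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
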