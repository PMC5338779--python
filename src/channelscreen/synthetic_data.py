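"""Synthetic inputs with the statistical structure every stage assumes.

Each generator is a pure function of its configuration (seed included) and
records its ground truth in a :class:`~channelscreen.types.SimTruth`, so
the whole pipeline is testable without downloads:

* ``simulate_expression`` — a negative-binomial count cohort shaped like
  the screen: 20 tumor stem-cell isolates vs 5 normal neural controls,
  2-3 sequencing replicates per isolate, a planted tumor-enriched gene
  subset at a configurable log2 effect, and an isolate-level lognormal
  random effect so replicate averaging is a meaningful stage.
* ``simulate_regional`` — FPKM samples with lognormal noise around
  per-region means over the seven anatomic compartments.
* ``simulate_survival`` — exponential event times whose hazard scales as
  exp(beta x standardized expression), with optional censoring.
* ``simulate_subtype_reference`` — four-class reference cohort whose
  centroids are orthogonal block mean-shifts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (
    ExpressionMatrix,
    REGIONS,
    SampleMetadata,
    SimTruth,
    SUBTYPES,
    SurvivalTable,
    ValidationError,
)


@dataclass
class ScreenSimConfig:
    """Configuration of the negative-binomial screen cohort.

    ``nb_dispersion`` is the quadratic overdispersion of the count model
    (variance = mu + dispersion * mu^2); ``baseline_log_mean``/``log_sd``
    parameterize the lognormal distribution of per-gene baseline mean
    counts (natural-log scale); ``isolate_sd`` is the sd of the
    gene-by-isolate lognormal random effect shared by replicates.
    """

    n_genes: int = 1000
    n_tumor_isolates: int = 20
    n_control_isolates: int = 5
    replicates_per_isolate: int = 3
    fraction_planted: float = 0.05
    planted_log2_effect: float = 3.0
    nb_dispersion: float = 0.1
    baseline_log_mean: float = 4.0
    baseline_log_sd: float = 1.5
    library_size_range: tuple[float, float] = (0.8e6, 1.2e6)
    isolate_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction_planted <= 1.0):
            raise ValidationError("fraction_planted must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValidationError("nb_dispersion must be positive")
        if self.replicates_per_isolate not in (2, 3):
            raise ValidationError("replicates_per_isolate must be 2 or 3")
        n_planted = round(self.n_genes * self.fraction_planted)
        if self.fraction_planted > 0 and n_planted < 1:
            raise ValidationError(
                "n_genes x fraction_planted < 1: nothing to plant "
                "(set fraction_planted = 0 for a null cohort)"
            )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB with variance = mu + dispersion * mu^2 (gamma-Poisson mixture)."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean / shape)
    return rng.poisson(lam)


def simulate_expression(
    config: ScreenSimConfig,
) -> tuple[ExpressionMatrix, SampleMetadata, SimTruth]:
    """Generate the tumor-vs-control count cohort with planted enrichment."""
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    n_planted = round(config.n_genes * config.fraction_planted)
    planted_idx = rng.choice(config.n_genes, size=n_planted, replace=False)
    planted = sorted(genes[i] for i in planted_idx)
    effects = pd.Series(0.0, index=genes, name="true_log2_effect")
    effects.iloc[sorted(planted_idx)] = config.planted_log2_effect

    base = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, config.n_genes)
    rel = base / base.sum()  # relative expression; scaled to library size later

    isolates = [f"T{i:02d}" for i in range(1, config.n_tumor_isolates + 1)] + [
        f"C{i:02d}" for i in range(1, config.n_control_isolates + 1)
    ]
    groups = ["tumor"] * config.n_tumor_isolates + ["control"] * config.n_control_isolates

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    fold = 2.0 ** effects.to_numpy()
    for isolate, group in zip(isolates, groups):
        iso_effect = rng.lognormal(0.0, config.isolate_sd, config.n_genes)
        mu_rel = rel * iso_effect * (fold if group == "tumor" else 1.0)
        for r in range(1, config.replicates_per_isolate + 1):
            lib = rng.uniform(*config.library_size_range)
            mu = mu_rel * lib
            sample = f"{isolate}_r{r}"
            columns[sample] = _nb_draw(rng, mu, config.nb_dispersion)
            meta_rows.append({"sample_id": sample, "group": group, "isolate_id": isolate})

    counts = pd.DataFrame(columns, index=genes, dtype=float)
    matrix = ExpressionMatrix(counts, "counts")
    meta = SampleMetadata(pd.DataFrame(meta_rows).set_index("sample_id"))
    truth = SimTruth(planted_gene_ids=planted, true_log2_effects=effects)
    return matrix, meta, truth


def simulate_regional(
    n_genes: int | None = None,
    samples_per_region: int = 3,
    region_means: pd.DataFrame | None = None,
    noise_sd: float = 0.3,
    replicates_per_sample: int = 2,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SampleMetadata, SimTruth]:
    """Generate region-labelled FPKM samples around given region means.

    ``region_means`` must cover all seven region labels (genes x regions);
    if omitted it is drawn lognormally for ``n_genes`` genes. Each region
    gets ``samples_per_region`` samples of ``replicates_per_sample``
    replicates, each value = region mean x exp(noise_sd x z).
    """
    if samples_per_region < 1:
        raise ValidationError("samples_per_region must be >= 1")
    rng = np.random.default_rng(seed)
    if region_means is None:
        if n_genes is None:
            raise ValidationError("pass region_means or n_genes")
        genes = [f"G{i:05d}" for i in range(n_genes)]
        region_means = pd.DataFrame(
            rng.lognormal(0.5, 1.0, (n_genes, len(REGIONS))), index=genes, columns=REGIONS
        )
    missing = set(REGIONS) - set(region_means.columns)
    if missing:
        raise ValidationError(f"region_means lacks regions {sorted(missing)}")
    region_means = region_means[list(REGIONS)]

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    mu = region_means.to_numpy(dtype=float)
    for j, region in enumerate(REGIONS):
        for s in range(1, samples_per_region + 1):
            isolate = f"{region}_s{s}"
            for r in range(1, replicates_per_sample + 1):
                z = rng.standard_normal(region_means.shape[0])
                sample = f"{isolate}_r{r}"
                columns[sample] = mu[:, j] * np.exp(noise_sd * z)
                meta_rows.append(
                    {"sample_id": sample, "isolate_id": isolate, "region": region}
                )
    matrix = ExpressionMatrix(
        pd.DataFrame(columns, index=region_means.index, dtype=float), "FPKM"
    )
    meta = SampleMetadata(pd.DataFrame(meta_rows).set_index("sample_id"))
    truth = SimTruth(extra={"region_means": region_means})
    return matrix, meta, truth


def simulate_survival(
    expression_row: pd.Series,
    beta: float = 1.0,
    baseline_hazard: float = 1e-3,
    censor_rate: float = 0.0,
    seed: int = 0,
) -> SurvivalTable:
    """Exponential survival times whose hazard depends on expression.

    hazard_i = baseline_hazard x exp(beta x z_i) with z the standardized
    expression. Censoring: each sample is independently censored with
    probability ``censor_rate``; a censored sample's observed time is
    uniform on (0, its event time).
    """
    if baseline_hazard <= 0:
        raise ValidationError("baseline_hazard must be positive")
    if not (0.0 <= censor_rate < 1.0):
        raise ValidationError("censor_rate must lie in [0, 1)")
    x = expression_row.to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise ValidationError("expression values must be finite")
    rng = np.random.default_rng(seed)
    sd = x.std()
    z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
    hazard = baseline_hazard * np.exp(beta * z)
    t_event = rng.exponential(1.0 / hazard)
    censored = rng.random(x.size) < censor_rate
    t_obs = np.where(censored, rng.uniform(0.0, t_event), t_event)
    df = pd.DataFrame(
        {
            "time": t_obs,
            "event": (~censored).astype(int),
            "expression": x,
        },
        index=expression_row.index.astype(str),
    )
    return SurvivalTable(df)


def simulate_subtype_reference(
    n_genes_signature: int = 770,
    n_subtypes: int = 4,
    samples_per_subtype: int = 10,
    centroid_separation: float = 2.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.Series, SimTruth]:
    """Reference cohort with orthogonal block-shift subtype centroids.

    The signature genes are split into ``n_subtypes`` equal blocks; the
    centroid of subtype k adds ``centroid_separation`` to block k on top
    of a shared per-gene baseline. Samples are centroid + gaussian noise,
    clipped at zero.
    """
    if centroid_separation < 0:
        raise ValidationError("centroid_separation must be >= 0")
    if samples_per_subtype < 2:
        raise ValidationError("samples_per_subtype must be >= 2 (median centroid robustness)")
    if not (2 <= n_subtypes <= len(SUBTYPES)):
        raise ValidationError(f"n_subtypes must lie in [2, {len(SUBTYPES)}]")
    rng = np.random.default_rng(seed)
    genes = [f"SIG{i:04d}" for i in range(n_genes_signature)]
    subtypes = list(SUBTYPES[:n_subtypes])
    baseline = rng.uniform(2.0, 10.0, n_genes_signature)
    block = np.arange(n_genes_signature) * n_subtypes // n_genes_signature

    columns: dict[str, np.ndarray] = {}
    labels = {}
    for k, subtype in enumerate(subtypes):
        centroid = baseline + centroid_separation * (block == k)
        for s in range(1, samples_per_subtype + 1):
            sample = f"{subtype[:4]}_{s:02d}"
            noise = rng.standard_normal(n_genes_signature) * noise_sd
            columns[sample] = np.clip(centroid + noise, 0.0, None)
            labels[sample] = subtype
    matrix = ExpressionMatrix(pd.DataFrame(columns, index=genes, dtype=float), "CPM")
    labels = pd.Series(labels, name="subtype")
    truth = SimTruth(true_subtypes=labels, extra={"signature_genes": genes})
    return matrix, labels, truth
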