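"""Core domain containers shared by every pipeline stage.

Expression data travels as a gene x sample :class:`pandas.DataFrame` wrapped
in :class:`ExpressionMatrix`, which carries the abundance unit (raw counts,
CPM, or FPKM) so each operation can declare which currencies it accepts.
Sample annotations (tumor/control group, isolate-of-replicate mapping,
molecular subtype, mutation flags, anatomic region) live in
:class:`SampleMetadata`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("channelscreen")

UNITS = ("counts", "CPM", "FPKM")
GROUPS = ("tumor", "control")
SUBTYPES = ("Classical", "Mesenchymal", "Neural", "Proneural")
REGIONS = ("LE", "IT", "CT", "PZ", "PAN", "HBV", "MVP")
"""Anatomic compartments: leading edge, infiltrating tumor, cellular tumor,
perinecrotic zone, pseudopalisading cells around necrosis, hyperplastic blood
vessels, microvascular proliferation."""


class FormatError(ValueError):
    """Malformed file content (non-numeric cell, bad field count, ...)."""


class ValidationError(ValueError):
    """Structurally parseable input that violates a domain invariant."""


def _check_unique(values: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for v in values:
        if v in seen:
            dups.append(v)
        seen.add(v)
    if dups:
        raise ValidationError(f"duplicate {what}: {sorted(set(dups))}")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene x sample abundance table with a unit tag.

    Parameters
    ----------
    values
        DataFrame with genes as the index and samples as columns. All
        entries must be finite and non-negative; absent genes must be
        explicit zeros, never missing.
    unit
        One of ``counts``, ``CPM``, ``FPKM``.
    """

    values: pd.DataFrame
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValidationError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        _check_unique(self.values.index.astype(str), "gene id")
        _check_unique(self.values.columns.astype(str), "sample id")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("expression values must be numeric")
        if np.isnan(arr).any():
            g, s = np.argwhere(np.isnan(arr))[0]
            raise ValidationError(
                f"missing value at gene {self.values.index[g]!r}, "
                f"sample {self.values.columns[s]!r}"
            )
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative value at gene {self.values.index[g]!r}, "
                f"sample {self.values.columns[s]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def require_unit(self, *accepted: str) -> None:
        if self.unit not in accepted:
            raise ValidationError(
                f"operation requires unit in {accepted}, got {self.unit!r}"
            )

    def with_values(self, values: pd.DataFrame, unit: str | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(values, self.unit if unit is None else unit)


@dataclass
class SampleMetadata:
    """Per-sample annotations.

    ``table`` is indexed by sample id with optional columns ``group``
    (tumor/control), ``isolate_id`` (replicates of one isolate share it),
    ``subtype`` and ``region``. ``mutations`` is an optional isolate x gene
    table with values ``mutant`` / ``wildtype``.
    """

    table: pd.DataFrame
    mutations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        _check_unique(self.table.index.astype(str), "sample id")
        if "group" in self.table:
            bad = set(self.table["group"].dropna()) - set(GROUPS)
            if bad:
                raise ValidationError(f"unknown group labels {sorted(bad)}; expected {GROUPS}")
        if "subtype" in self.table:
            bad = set(self.table["subtype"].dropna()) - set(SUBTYPES)
            if bad:
                raise ValidationError(f"unknown subtype labels {sorted(bad)}")
        if "region" in self.table:
            bad = set(self.table["region"].dropna()) - set(REGIONS)
            if bad:
                raise ValidationError(
                    f"unknown region labels {sorted(bad)}; expected {REGIONS}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def check_matches(self, matrix: ExpressionMatrix) -> None:
        """Every matrix sample must appear exactly once in the metadata."""
        missing = set(matrix.sample_ids) - set(self.table.index)
        if missing:
            raise ValidationError(f"samples without metadata: {sorted(missing)}")

    def isolates(self) -> pd.Series:
        """sample_id -> isolate_id (a sample is its own isolate if unmapped)."""
        if "isolate_id" in self.table:
            iso = self.table["isolate_id"].copy()
            iso = iso.fillna(pd.Series(self.table.index, index=self.table.index))
            return iso.astype(str)
        return pd.Series(self.table.index.astype(str), index=self.table.index)

    def isolate_groups(self) -> pd.Series:
        """isolate_id -> group; errors if replicates of an isolate disagree."""
        if "group" not in self.table:
            raise ValidationError("metadata has no 'group' column")
        iso = self.isolates()
        out: dict[str, str] = {}
        for sample, isolate in iso.items():
            g = self.table.loc[sample, "group"]
            if isolate in out and out[isolate] != g:
                raise ValidationError(f"isolate {isolate!r} has conflicting group labels")
            out[isolate] = g
        return pd.Series(out, name="group")


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style) with a provenance string."""

    sets: dict[str, list[str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")
            _check_unique(members, f"member of set {name!r}")

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class FamilyAnnotation:
    """gene_id -> functional family (one family per gene)."""

    mapping: pd.Series

    def __post_init__(self) -> None:
        _check_unique(self.mapping.index.astype(str), "annotated gene")

    def family_of(self, gene: str) -> str | None:
        return self.mapping.get(gene)

    def members(self, family: str) -> list[str]:
        return list(self.mapping.index[self.mapping == family])


@dataclass
class SurvivalTable:
    """Per-sample time-to-event records.

    ``data`` is indexed by sample id with columns ``time`` (days, >= 0) and
    ``event`` (1 = death observed, 0 = censored), plus an optional
    ``expression`` column and an optional ``stratum`` label.
    ``dropped_missing_time`` counts rows removed for missing time at read.
    """

    data: pd.DataFrame
    dropped_missing_time: int = 0

    def __post_init__(self) -> None:
        for col in ("time", "event"):
            if col not in self.data:
                raise ValidationError(f"survival table lacks {col!r} column")
        t = self.data["time"].to_numpy(dtype=float)
        if np.isnan(t).any() or not np.isfinite(t).all():
            raise ValidationError("survival times must be finite")
        if (t < 0).any():
            raise ValidationError("negative survival time")
        ev = self.data["event"].to_numpy()
        if not np.isin(ev, (0, 1)).all():
            raise ValidationError("event indicator must be 0 or 1")

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class SimTruth:
    """Ground truth recorded by the synthetic generators."""

    planted_gene_ids: list[str] = field(default_factory=list)
    true_log2_effects: pd.Series | None = None
    true_subtypes: pd.Series | None = None
    true_hazard_beta: float | None = None
    extra: dict = field(default_factory=dict)
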