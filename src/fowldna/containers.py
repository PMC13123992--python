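"""Shared tabular containers for the pipeline.

Two structures travel between stages:

* :class:`AsvTable` — an ASV x sample count matrix plus per-sample
  metadata (date, sample type, replicate).  Counts are integer reads until
  depth standardization, fractional afterwards.
* :class:`CommunityMatrix` — a date x taxon abundance matrix, used for
  true abundances, focal survey counts, per-date checklist means, and
  standardized read totals; ``provenance`` records which.

Both round-trip through plain TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["ConfigError", "SAMPLE_TYPES", "CONTROL_TYPES", "AsvTable", "CommunityMatrix"]


class ConfigError(ValueError):
    """Raised when a configuration or input table is invalid."""


SAMPLE_TYPES = ("field", "field_blank", "filtration_blank", "extraction_blank", "pcr_blank")
#: Sample types that drive the contamination-filter threshold (the DNA
#: extraction and PCR negative controls).
CONTROL_TYPES = ("extraction_blank", "pcr_blank")


@dataclass
class AsvTable:
    """ASV x sample count matrix with sample metadata.

    ``counts``: rows are ASV ids, columns sample ids, non-negative values.
    ``meta``: indexed by sample id with columns ``date`` (datetime),
    ``sample_type`` (one of :data:`SAMPLE_TYPES`) and ``replicate``.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.meta.index.is_unique:
            raise ConfigError("duplicate sample ids in metadata")
        missing = set(self.counts.columns) - set(self.meta.index)
        if missing:
            raise ConfigError(f"samples without metadata: {sorted(missing)}")
        bad = set(self.meta["sample_type"]) - set(SAMPLE_TYPES)
        if bad:
            raise ConfigError(f"unknown sample types: {sorted(bad)}")
        if (self.counts.to_numpy() < 0).any():
            raise ConfigError("negative counts")

    def samples_of_type(self, *types: str) -> list[str]:
        wanted = self.meta.index[self.meta["sample_type"].isin(types)]
        return [s for s in self.counts.columns if s in set(wanted)]

    @property
    def field_samples(self) -> list[str]:
        return self.samples_of_type("field")

    @property
    def control_samples(self) -> list[str]:
        """The extraction and PCR blanks (threshold-defining controls)."""
        return self.samples_of_type(*CONTROL_TYPES)

    def field_depths(self) -> pd.Series:
        return self.counts[self.field_samples].sum(axis=0)

    def copy(self) -> "AsvTable":
        return AsvTable(self.counts.copy(), self.meta.copy())

    def write(self, counts_path, meta_path) -> None:
        out = self.counts.copy()
        out.index.name = "asv_id"
        out.to_csv(counts_path, sep="\t")
        meta = self.meta.copy()
        meta.index.name = "sample_id"
        meta = meta.reset_index()[["sample_id", "date", "sample_type", "replicate"]]
        meta["date"] = pd.to_datetime(meta["date"]).dt.strftime("%Y-%m-%d")
        meta.to_csv(meta_path, sep="\t", index=False)

    @classmethod
    def read(cls, counts_path, meta_path) -> "AsvTable":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t")
        meta["date"] = pd.to_datetime(meta["date"])
        meta = meta.set_index("sample_id")
        return cls(counts, meta)


@dataclass
class CommunityMatrix:
    """Date x taxon abundance matrix.

    ``values``: rows indexed by date (strictly increasing), columns are
    taxon names, entries non-negative.  ``provenance`` says what the
    numbers are: ``truth``, ``focal_counts``, ``checklist_mean`` or
    ``standardized_reads``.
    """

    values: pd.DataFrame
    provenance: str = "truth"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = pd.to_datetime(self.values.index)
        if not idx.is_monotonic_increasing or idx.has_duplicates:
            raise ConfigError("dates must be strictly increasing")
        self.values = self.values.copy()
        self.values.index = idx
        self.values.index.name = "date"
        if (self.values.to_numpy() < 0).any():
            raise ConfigError("abundances must be non-negative")

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.values.index

    @property
    def taxa(self) -> list[str]:
        return list(self.values.columns)

    def write(self, path) -> None:
        out = self.values.copy()
        out.index = out.index.strftime("%Y-%m-%d")
        out.index.name = "date"
        out.to_csv(path, sep="\t")

    @classmethod
    def read(cls, path, provenance: str = "truth") -> "CommunityMatrix":
        values = pd.read_csv(path, sep="\t", index_col=0)
        return cls(values, provenance=provenance)
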