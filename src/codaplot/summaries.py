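"""Relative-abundance summaries by taxonomy and GO-slim category."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountTable, CountTableError, MetadataTable

__all__ = [
    "AbundanceSummary",
    "relative_abundance_by_taxon",
    "goslim_stripchart_data",
]


@dataclass
class AbundanceSummary:
    """Per-group relative abundances, groups x samples; columns sum to 1."""

    proportions: pd.DataFrame

    def __post_init__(self) -> None:
        sums = self.proportions.sum(axis=0).to_numpy()
        if np.abs(sums - 1.0).max() > 1e-9:
            raise ValueError("each sample column must sum to 1")

    @property
    def group_ids(self) -> list[str]:
        return list(self.proportions.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.proportions.columns)

    def to_tsv(self, path) -> None:
        self.proportions.to_csv(path, sep="\t", index_label="group")


def relative_abundance_by_taxon(
    table: CountTable,
    level_delimiter: str = ";",
    level: int = 1,
    min_mean_prop: float | None = None,
    sample_order: list[str] | None = None,
) -> AbundanceSummary:
    """Aggregate counts by truncated taxonomic lineage and close per sample.

    Taxonomy strings are split on ``level_delimiter`` and features grouped
    by their first ``level`` fields (missing or empty annotations become
    ``unclassified``).  Groups are ordered by mean abundance, descending.
    ``min_mean_prop`` optionally pools groups below that mean proportion
    into an ``Other`` bin (off by default).  ``sample_order`` reorders the
    columns, e.g. to follow a dendrogram.
    """
    if table.taxonomy is None:
        raise CountTableError("count table carries no taxonomy column")
    if level < 1:
        raise ValueError("level must be >= 1")

    def truncate(t) -> str:
        if t is None or (isinstance(t, float) and np.isnan(t)) or str(t).strip() == "":
            return "unclassified"
        fields = [f.strip() for f in str(t).split(level_delimiter)]
        return level_delimiter.join(fields[:level])

    groups = table.taxonomy.map(truncate)
    agg = table.counts.groupby(groups.to_numpy()).sum()
    props = agg.div(agg.sum(axis=0), axis=1)
    props = props.loc[props.mean(axis=1).sort_values(ascending=False).index]
    if min_mean_prop is not None:
        rare = props.mean(axis=1) < min_mean_prop
        if rare.any():
            other = props.loc[rare].sum(axis=0).rename("Other")
            props = pd.concat([props.loc[~rare], other.to_frame().T])
    if sample_order is not None:
        props = props[list(sample_order)]
    props.index.name = "group"
    return AbundanceSummary(props)


def goslim_stripchart_data(
    table: CountTable,
    metadata: MetadataTable | None = None,
    colour_variable: str | None = None,
) -> pd.DataFrame:
    """Per-(category, GO term, sample) relative-abundance records.

    Each feature contributes one record per sample with its within-sample
    relative abundance, grouped by the GO-slim ``category`` annotation
    (e.g. biological_process).  When ``colour_variable`` is given the
    matching metadata value is attached as a colour key.
    """
    if table.go_annotation is None:
        raise CountTableError("count table carries no GO-slim annotation")
    totals = table.counts.sum(axis=0)
    props = table.counts.div(totals, axis=1)
    long = props.stack().rename("proportion").reset_index()
    long.columns = ["go_id", "sample_id", "proportion"]
    ann = table.go_annotation
    long["category"] = long["go_id"].map(ann["category"]).fillna("unannotated")
    long["description"] = long["go_id"].map(ann["description"]).fillna("")
    cols = ["category", "go_id", "description", "sample_id", "proportion"]
    long = long[cols]
    if colour_variable is not None:
        if metadata is None:
            raise ValueError("colour_variable given without metadata")
        long["colour_key"] = long["sample_id"].map(metadata.column(colour_variable))
    return long.sort_values(["category", "go_id", "sample_id"]).reset_index(drop=True)
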