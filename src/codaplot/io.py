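"""Reading, writing and validation of count, metadata and effect tables.

Count tables follow the sequencing convention: features by rows, samples as
columns, with a header row of sample identifiers and feature identifiers in
the first column.  Three dialects are supported:

``plain``
    feature id column followed by sample columns only.
``taxonomy_last_column``
    as ``plain`` with a trailing per-feature taxonomy column (lineage
    strings such as ``k__Bacteria;p__Firmicutes``).
``go_slim``
    MGnify-style functional tables: the feature id column is a GO term id,
    followed by ``description`` and ``category`` annotation columns, then
    sample columns.

Metadata tables are samples by rows, descriptor variables as columns.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "MetadataTable",
    "CountTableError",
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "write_metadata",
    "align_samples",
    "read_effect_table",
    "EFFECT_TABLE_COLUMNS",
]


class CountTableError(ValueError):
    """Structural or parse error in an input table."""


#: columns every ALDEx2-dialect effect table must carry; ``rab.win.*``
#: columns are located by prefix because the suffix is the group label.
EFFECT_TABLE_COLUMNS = (
    "rab.all",
    "diff.btw",
    "diff.win",
    "effect",
    "overlap",
    "we.ep",
    "we.eBH",
    "wi.ep",
    "wi.eBH",
)


def _sniff_delimiter(path: Path, delimiter: str) -> str:
    if delimiter == "tab":
        return "\t"
    if delimiter == "comma":
        return ","
    if delimiter != "auto":
        raise ValueError(f"unknown delimiter option {delimiter!r}")
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    # tab wins over comma when both occur (MGnify exports are tab-delimited)
    if "\t" in first:
        return "\t"
    if "," in first:
        return ","
    return "\t"


@dataclass
class CountTable:
    """A validated non-negative integer count matrix, features x samples.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers with unique feature ids as the
        index and unique sample ids as columns.
    taxonomy
        Optional per-feature lineage string, aligned to ``counts.index``.
    go_annotation
        Optional per-feature DataFrame with columns ``go_id``,
        ``description`` and ``category``, aligned to ``counts.index``.
    """

    counts: pd.DataFrame
    taxonomy: pd.Series | None = None
    go_annotation: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def validate(self) -> None:
        c = self.counts
        if c.shape[0] == 0 or c.shape[1] == 0:
            raise CountTableError("empty count table")
        dup_f = c.index[c.index.duplicated()].unique().tolist()
        if dup_f:
            raise CountTableError(f"duplicate feature ids: {dup_f}")
        dup_s = c.columns[c.columns.duplicated()].unique().tolist()
        if dup_s:
            raise CountTableError(f"duplicate sample ids: {dup_s}")
        values = c.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise CountTableError("non-numeric count cells present")
        if np.isnan(values.astype(float)).any():
            r, s = np.argwhere(np.isnan(values.astype(float)))[0]
            raise CountTableError(
                f"missing count at feature {c.index[r]!r}, sample {c.columns[s]!r}"
            )
        if (values < 0).any():
            r, s = np.argwhere(values < 0)[0]
            raise CountTableError(
                f"negative count at feature {c.index[r]!r}, sample {c.columns[s]!r}"
            )
        if not np.issubdtype(values.dtype, np.integer):
            frac = values != np.floor(values)
            if frac.any():
                r, s = np.argwhere(frac)[0]
                raise CountTableError(
                    f"non-integer count at feature {c.index[r]!r}, "
                    f"sample {c.columns[s]!r}; pass strict=False to round"
                )
            self.counts = c.astype(np.int64)
        zero = self.counts.sum(axis=0) == 0
        if zero.any():
            raise CountTableError(
                f"samples with zero total counts: {list(c.columns[zero])}"
            )
        if self.taxonomy is not None:
            self.taxonomy = self.taxonomy.reindex(self.counts.index)
        if self.go_annotation is not None:
            self.go_annotation = self.go_annotation.reindex(self.counts.index)

    # -- subsetting --------------------------------------------------
    def select(
        self,
        features: Iterable[str] | None = None,
        samples: Iterable[str] | None = None,
    ) -> "CountTable":
        """Return a new table restricted to the given ids (order preserved)."""
        c = self.counts
        if features is not None:
            c = c.loc[list(features)]
        if samples is not None:
            c = c[list(samples)]
        tax = self.taxonomy.loc[c.index] if self.taxonomy is not None else None
        go = self.go_annotation.loc[c.index] if self.go_annotation is not None else None
        return CountTable(c.copy(), taxonomy=tax, go_annotation=go)


@dataclass
class MetadataTable:
    """Per-sample descriptors: samples by rows, variables as columns.

    Each variable is tagged ``discrete`` or ``continuous``.  Inference is
    deterministic: a variable with any non-numeric value, or with at most
    ``discrete_threshold`` distinct non-missing values, is discrete;
    everything else is continuous.
    """

    data: pd.DataFrame
    kinds: Mapping[str, str] = field(default_factory=dict)
    discrete_threshold: int = 10

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise CountTableError(f"duplicate sample ids in metadata: {dups}")
        if not self.kinds:
            self.kinds = {
                v: _infer_kind(self.data[v], self.discrete_threshold)
                for v in self.data.columns
            }
        else:
            bad = [v for v, k in self.kinds.items() if k not in ("discrete", "continuous")]
            if bad:
                raise ValueError(f"variables with invalid kind tag: {bad}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    def kind(self, variable: str) -> str:
        if variable not in self.kinds:
            raise KeyError(f"unknown metadata variable {variable!r}")
        return self.kinds[variable]

    def column(self, variable: str) -> pd.Series:
        if variable not in self.data.columns:
            raise KeyError(f"unknown metadata variable {variable!r}")
        return self.data[variable]

    def select(self, samples: Iterable[str]) -> "MetadataTable":
        return MetadataTable(
            self.data.loc[list(samples)].copy(),
            kinds=dict(self.kinds),
            discrete_threshold=self.discrete_threshold,
        )


def _infer_kind(col: pd.Series, threshold: int) -> str:
    values = col.dropna()
    if values.empty:
        return "discrete"
    numeric = pd.to_numeric(values, errors="coerce")
    if numeric.isna().any():
        return "discrete"
    return "discrete" if numeric.nunique() <= threshold else "continuous"


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_count_table(
    path: str | Path,
    dialect: str = "plain",
    delimiter: str = "auto",
    strict: bool = True,
    go_annotation_columns: int = 2,
) -> CountTable:
    """Read a features-by-samples count table.

    Parameters
    ----------
    path
        Delimited text file; first row is the sample header, first column
        the feature identifiers.
    dialect
        ``plain``, ``taxonomy_last_column`` or ``go_slim``.
    delimiter
        ``tab``, ``comma`` or ``auto`` (sniffed from the first line, tab
        winning over comma).
    strict
        When False, float-valued count cells are rounded to the nearest
        integer with a warning instead of rejected.
    go_annotation_columns
        Number of annotation columns following the GO id column in the
        ``go_slim`` dialect (MGnify exports carry ``description`` and
        ``category``).
    """
    path = Path(path)
    sep = _sniff_delimiter(path, delimiter)
    try:
        raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, header=0)
    except pd.errors.EmptyDataError as exc:
        raise CountTableError(f"empty table: {path}") from exc
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise CountTableError(f"empty table: {path}")
    raw.index = raw.index.astype(str)

    taxonomy = None
    go_annotation = None
    if dialect == "taxonomy_last_column":
        taxonomy = raw.iloc[:, -1].rename("taxonomy")
        raw = raw.iloc[:, :-1]
    elif dialect == "go_slim":
        if raw.shape[1] <= go_annotation_columns:
            raise CountTableError(
                "go_slim dialect requires annotation columns followed by "
                "at least one sample column"
            )
        ann = raw.iloc[:, :go_annotation_columns]
        names = ["description", "category"][: go_annotation_columns]
        ann.columns = names + list(ann.columns[len(names):])
        go_annotation = ann.copy()
        go_annotation.insert(0, "go_id", raw.index)
        raw = raw.iloc[:, go_annotation_columns:]
    elif dialect != "plain":
        raise ValueError(f"unknown dialect {dialect!r}")

    if raw.shape[1] == 0:
        raise CountTableError(f"no sample columns in {path}")

    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        r, s = np.argwhere(bad.to_numpy())[0]
        raise CountTableError(
            f"non-numeric count {raw.iat[r, s]!r} at feature "
            f"{raw.index[r]!r}, sample {raw.columns[s]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, s = np.argwhere(numeric.isna().to_numpy())[0]
        raise CountTableError(
            f"missing count at feature {raw.index[r]!r}, sample {raw.columns[s]!r}"
        )
    values = numeric.to_numpy(dtype=float)
    if not strict:
        rounded = np.rint(values)
        if (rounded != values).any():
            warnings.warn(
                "non-integer counts rounded to nearest integer (strict=False)",
                UserWarning,
                stacklevel=2,
            )
        values = rounded
    else:
        frac = values != np.floor(values)
        if frac.any():
            r, s = np.argwhere(frac)[0]
            raise CountTableError(
                f"non-integer count {values[r, s]} at feature "
                f"{raw.index[r]!r}, sample {raw.columns[s]!r}; "
                "pass strict=False to round"
            )
    counts = pd.DataFrame(
        values.astype(np.int64), index=raw.index, columns=raw.columns
    )
    return CountTable(counts, taxonomy=taxonomy, go_annotation=go_annotation)


def write_count_table(
    table: CountTable, path: str | Path, delimiter: str = "tab"
) -> None:
    """Write a count table in the dialect implied by its annotations."""
    sep = "\t" if delimiter in ("tab", "auto") else ","
    out = table.counts.copy()
    if table.go_annotation is not None:
        ann = table.go_annotation.drop(columns=["go_id"], errors="ignore")
        out = pd.concat([ann, out], axis=1)
    if table.taxonomy is not None:
        out = pd.concat([out, table.taxonomy.rename("taxonomy")], axis=1)
    out.to_csv(path, sep=sep, index_label=table.counts.index.name or "feature_id")


def read_metadata(
    path: str | Path,
    delimiter: str = "auto",
    discrete_threshold: int = 10,
) -> MetadataTable:
    """Read a samples-by-variables metadata table (first column = sample id)."""
    path = Path(path)
    sep = _sniff_delimiter(path, delimiter)
    try:
        raw = pd.read_csv(path, sep=sep, index_col=0, header=0)
    except pd.errors.EmptyDataError as exc:
        raise CountTableError(f"empty metadata file: {path}") from exc
    if raw.shape[0] == 0:
        raise CountTableError(f"metadata file has no samples: {path}")
    raw.index = raw.index.astype(str)
    return MetadataTable(raw, discrete_threshold=discrete_threshold)


def write_metadata(metadata: MetadataTable, path: str | Path, delimiter: str = "tab") -> None:
    sep = "\t" if delimiter in ("tab", "auto") else ","
    metadata.data.to_csv(path, sep=sep, index_label=metadata.data.index.name or "sample_id")


def align_samples(
    table: CountTable, metadata: MetadataTable
) -> tuple[CountTable, MetadataTable]:
    """Restrict both tables to their shared samples, in count-table order.

    Samples present on only one side are dropped with a warning naming them;
    an empty intersection is an error.  Idempotent.
    """
    shared = [s for s in table.sample_ids if s in set(metadata.sample_ids)]
    if not shared:
        raise CountTableError("no samples shared between counts and metadata")
    dropped_counts = [s for s in table.sample_ids if s not in set(shared)]
    dropped_meta = [s for s in metadata.sample_ids if s not in set(shared)]
    if dropped_counts or dropped_meta:
        warnings.warn(
            f"align_samples dropped {dropped_counts} from counts and "
            f"{dropped_meta} from metadata",
            UserWarning,
            stacklevel=2,
        )
    if not dropped_counts and not dropped_meta and shared == metadata.sample_ids:
        return table, metadata
    return table.select(samples=shared), metadata.select(shared)


def read_effect_table(path: str | Path, delimiter: str = "auto") -> pd.DataFrame:
    """Read a pre-computed ALDEx2-dialect effect table.

    Required columns (case-sensitive): ``rab.all``, ``diff.btw``,
    ``diff.win``, ``effect``, ``overlap``, ``we.ep``, ``we.eBH``,
    ``wi.ep``, ``wi.eBH`` and exactly two ``rab.win.<group>`` columns
    located by prefix.  ``NA`` cells parse as missing values.
    """
    path = Path(path)
    sep = _sniff_delimiter(path, delimiter)
    raw = pd.read_csv(path, sep=sep, index_col=0, header=0, na_values=["NA"])
    raw.index = raw.index.astype(str)
    missing = [c for c in EFFECT_TABLE_COLUMNS if c not in raw.columns]
    if missing:
        raise CountTableError(f"effect table missing required columns: {missing}")
    rab_win = [c for c in raw.columns if c.startswith("rab.win.")]
    if len(rab_win) != 2:
        raise CountTableError(
            f"effect table needs exactly two rab.win.* columns, found {rab_win}"
        )
    numeric_cols = list(EFFECT_TABLE_COLUMNS) + rab_win
    for col in numeric_cols:
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = vals.isna() & raw[col].notna()
        if bad.any():
            feat = raw.index[bad][0]
            raise CountTableError(
                f"non-numeric value in column {col!r} at feature {feat!r}"
            )
        raw[col] = vals
    raw.attrs["group_labels"] = tuple(c.removeprefix("rab.win.") for c in rab_win)
    return raw
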