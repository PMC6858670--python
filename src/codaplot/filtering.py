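"""Low-count filtering of samples and features, with a removal report.

Rules apply in a fixed, documented order: (1) the optional metadata
selector, (2) samples whose column total falls below ``min_sample_total``,
(3) features whose row total over the *retained* samples falls below
``min_feature_total``, (4) features whose maximum per-sample relative
abundance over retained samples falls below ``min_feature_max_prop``.
Thresholds are keep-if-at-least; removal is strict-less-than.  Samples are
filtered before features so that failed samples cannot drag features below
threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd

from .io import CountTable, CountTableError, MetadataTable

__all__ = ["FilterSpec", "FilterReport", "filter_counts", "filter_by_metadata"]


@dataclass(frozen=True)
class FilterSpec:
    """Thresholds for :func:`filter_counts`.

    Defaults perform no filtering; there is no silent default cut-off.
    ``metadata_selector`` is ``(variable, selection)`` where selection is a
    set of levels for a discrete variable or a ``(low, high)`` closed
    interval for a continuous one.
    """

    min_sample_total: int = 0
    min_feature_total: int = 0
    min_feature_max_prop: float = 0.0
    metadata_selector: tuple[str, object] | None = None

    def __post_init__(self) -> None:
        if self.min_sample_total < 0 or self.min_feature_total < 0:
            raise ValueError("count thresholds must be non-negative")
        if not 0.0 <= self.min_feature_max_prop <= 1.0:
            raise ValueError("min_feature_max_prop must lie in [0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["metadata_selector"] is not None:
            var, sel = d["metadata_selector"]
            d["metadata_selector"] = {
                "variable": var,
                "selection": sorted(sel) if isinstance(sel, (set, frozenset)) else list(sel),
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FilterSpec":
        d = dict(d)
        sel = d.get("metadata_selector")
        if isinstance(sel, dict):
            values = sel["selection"]
            d["metadata_selector"] = (sel["variable"], tuple(values))
        return cls(**d)


@dataclass
class FilterReport:
    """What :func:`filter_counts` removed, and why."""

    removed_samples: list[tuple[str, str]] = field(default_factory=list)
    removed_features: list[tuple[str, str]] = field(default_factory=list)
    shape_before: tuple[int, int] = (0, 0)
    shape_after: tuple[int, int] = (0, 0)

    def to_frame(self) -> pd.DataFrame:
        rows = [("sample", i, r) for i, r in self.removed_samples] + [
            ("feature", i, r) for i, r in self.removed_features
        ]
        return pd.DataFrame(rows, columns=["dimension", "id", "reason"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "removed_samples": [{"id": i, "reason": r} for i, r in self.removed_samples],
            "removed_features": [{"id": i, "reason": r} for i, r in self.removed_features],
            "shape_before": list(self.shape_before),
            "shape_after": list(self.shape_after),
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def filter_counts(
    table: CountTable,
    spec: FilterSpec,
    metadata: MetadataTable | None = None,
) -> tuple[CountTable, FilterReport]:
    """Apply the ordered filtering rules; error if nothing survives.

    The error raised on an empty result carries the report in its
    ``report`` attribute so the removals can still be inspected.
    """
    report = FilterReport(shape_before=table.shape)
    counts = table.counts

    keep_samples = list(counts.columns)
    if spec.metadata_selector is not None:
        if metadata is None:
            raise ValueError("spec has a metadata_selector but no metadata was given")
        variable, selection = spec.metadata_selector
        selected = set(
            _select_samples(metadata, variable, selection)
        )
        for s in keep_samples:
            if s not in selected:
                report.removed_samples.append((s, f"metadata_selector[{variable}]"))
        keep_samples = [s for s in keep_samples if s in selected]

    sub = counts[keep_samples]
    totals = sub.sum(axis=0)
    for s in keep_samples:
        if totals[s] < spec.min_sample_total:
            report.removed_samples.append(
                (s, f"sample_total {totals[s]} < {spec.min_sample_total}")
            )
    keep_samples = [s for s in keep_samples if totals[s] >= spec.min_sample_total]
    if not keep_samples:
        err = CountTableError("filtering removed every sample")
        err.report = report
        raise err

    sub = counts[keep_samples]
    ftot = sub.sum(axis=1)
    keep_features = list(counts.index)
    for f in keep_features:
        if ftot[f] < spec.min_feature_total:
            report.removed_features.append(
                (f, f"feature_total {ftot[f]} < {spec.min_feature_total}")
            )
    keep_features = [f for f in keep_features if ftot[f] >= spec.min_feature_total]

    if spec.min_feature_max_prop > 0 and keep_features:
        props = sub.loc[keep_features].div(sub.sum(axis=0), axis=1)
        maxprop = props.max(axis=1)
        for f in list(keep_features):
            if maxprop[f] < spec.min_feature_max_prop:
                report.removed_features.append(
                    (f, f"max_prop {maxprop[f]:.6g} < {spec.min_feature_max_prop}")
                )
        keep_features = [f for f in keep_features if maxprop[f] >= spec.min_feature_max_prop]

    if not keep_features:
        err = CountTableError("filtering removed every feature")
        err.report = report
        raise err

    out = table.select(features=keep_features, samples=keep_samples)
    report.shape_after = out.shape
    return out, report


def _select_samples(metadata: MetadataTable, variable: str, selection) -> list[str]:
    col = metadata.column(variable)
    kind = metadata.kind(variable)
    if kind == "continuous":
        try:
            low, high = selection
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"continuous variable {variable!r} needs a (low, high) interval"
            ) from exc
        numeric = pd.to_numeric(col, errors="coerce")
        mask = (numeric >= low) & (numeric <= high)
    else:
        if isinstance(selection, (str, bytes)):
            selection = {selection}
        allowed = {str(v) for v in selection}
        mask = col.astype("string").isin(allowed).fillna(False)
    return list(col.index[mask.to_numpy(dtype=bool)])


def filter_by_metadata(
    table: CountTable,
    metadata: MetadataTable,
    variable: str,
    selection,
) -> CountTable:
    """Keep samples whose metadata value lies in the selection.

    ``selection`` is a value set for discrete variables or a closed numeric
    interval for continuous ones; missing metadata values never match.
    """
    selected = set(_select_samples(metadata, variable, selection))
    keep = [s for s in table.sample_ids if s in selected]
    if not keep:
        raise CountTableError(
            f"no samples match {variable!r} selection {selection!r}"
        )
    return table.select(samples=keep)
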