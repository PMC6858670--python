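"""Synthetic count tables with known compositional structure.

The generator draws a log-normal base composition, optionally multiplies a
spiked feature subset by a fold change in group B (in proportion space,
before re-closure — deliberately reproducing the compositional confound
whereby an absolute change in some features induces apparent changes in
all others), then simulates biological replicate variation with a
Dirichlet draw around the group composition and sequencing with a
multinomial at a random depth.  Everything is reproducible from a single
seed, and the ground truth (which features were spiked, at what log2 fold
change) is returned alongside the table so recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountTable, MetadataTable

__all__ = ["SynthSpec", "SynthTruth", "RecoveryResult", "generate_counts", "evaluate_recovery"]


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of the synthetic study.

    Defaults describe a modest two-condition sequencing study: 200
    features whose base proportions span roughly two orders of magnitude
    (log2-normal, sd 1.5), ten samples per group, depths uniform on
    5000-20000 reads, and Dirichlet replicate dispersion 500 (per-feature
    replicate CV of roughly 0.2-1.4 across the abundance range).
    """

    n_features: int = 200
    samples_per_group: tuple[int, int] = (10, 10)
    base_log2_mean_sd: tuple[float, float] = (0.0, 1.5)
    spike_ids: tuple[str, ...] = ()
    fold_change: float = 1.0
    depth_range: tuple[int, int] = (5000, 20000)
    dispersion: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features < 2:
            raise ValueError("need at least two features")
        if min(self.samples_per_group) < 1:
            raise ValueError("both groups need at least one sample")
        if self.fold_change <= 0:
            raise ValueError("fold_change must be positive")
        if self.depth_range[0] <= 0 or self.depth_range[1] < self.depth_range[0]:
            raise ValueError("depth_range must be positive and ordered")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.base_log2_mean_sd[1] < 0:
            raise ValueError("base log2 sd must be non-negative")

    def feature_ids(self) -> list[str]:
        width = len(str(self.n_features))
        return [f"F{i + 1:0{width}d}" for i in range(self.n_features)]


@dataclass
class SynthTruth:
    """Ground truth of a generated table."""

    log2_fold_change: pd.Series  # per feature; 0 for non-spiked
    conditions: pd.Series  # per sample, "A"/"B"
    depths: pd.Series  # realized sequencing depth per sample

    @property
    def spiked(self) -> list[str]:
        return list(self.log2_fold_change.index[self.log2_fold_change != 0])

    def to_tsv(self, path) -> None:
        self.log2_fold_change.rename("log2_fold_change").to_csv(
            path, sep="\t", index_label="feature_id"
        )


def generate_counts(spec: SynthSpec) -> tuple[CountTable, MetadataTable, SynthTruth]:
    """Simulate a two-group count table from a :class:`SynthSpec`.

    The base composition is drawn once; group B's target composition
    multiplies the spiked features by ``fold_change`` and re-closes.  Per
    sample, proportions are Dirichlet(dispersion x target) and counts
    multinomial at a depth uniform over ``depth_range``.
    """
    rng = np.random.default_rng(spec.seed)
    features = spec.feature_ids()
    unknown = [f for f in spec.spike_ids if f not in set(features)]
    if unknown:
        raise ValueError(f"spike_ids not among generated features: {unknown}")

    mean, sd = spec.base_log2_mean_sd
    base = np.exp2(rng.normal(mean, sd, size=spec.n_features))
    base /= base.sum()

    spike_mask = np.isin(np.array(features), np.array(spec.spike_ids, dtype=object))
    target_b = base * np.where(spike_mask, spec.fold_change, 1.0)
    target_b /= target_b.sum()

    n_a, n_b = spec.samples_per_group
    sample_ids = [f"A{i + 1:02d}" for i in range(n_a)] + [
        f"B{i + 1:02d}" for i in range(n_b)
    ]
    conditions = ["A"] * n_a + ["B"] * n_b

    counts = np.zeros((spec.n_features, n_a + n_b), dtype=np.int64)
    depths = np.zeros(n_a + n_b, dtype=np.int64)
    lo, hi = spec.depth_range
    for j, cond in enumerate(conditions):
        target = base if cond == "A" else target_b
        p = rng.dirichlet(spec.dispersion * target)
        depth = int(rng.integers(lo, hi + 1))
        counts[:, j] = rng.multinomial(depth, p)
        depths[j] = depth

    table = CountTable(
        pd.DataFrame(counts, index=pd.Index(features, name="feature_id"), columns=sample_ids)
    )
    metadata = MetadataTable(
        pd.DataFrame(
            {"group": conditions},
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    truth = SynthTruth(
        log2_fold_change=pd.Series(
            np.where(spike_mask, np.log2(spec.fold_change), 0.0), index=features
        ),
        conditions=pd.Series(conditions, index=sample_ids),
        depths=pd.Series(depths, index=sample_ids),
    )
    return table, metadata, truth


@dataclass
class RecoveryResult:
    """How well an effect table recovers the spiked features."""

    sensitivity: float
    false_positive_rate: float | None
    rank_agreement: float


def evaluate_recovery(
    effects: pd.DataFrame, truth: SynthTruth, effect_cutoff: float = 1.0
) -> RecoveryResult:
    """Score spiked-feature recovery by |effect| against the ground truth.

    sensitivity — fraction of spiked features with ``|effect| >= cutoff``;
    false_positive_rate — same fraction among non-spiked features (``None``
    when every feature was spiked); rank_agreement — fraction of spiked
    features ranked within the top ``n_spiked`` by ``|effect|``.
    """
    if set(effects.index) != set(truth.log2_fold_change.index):
        raise ValueError("effect table and truth cover different features")
    spiked = set(truth.spiked)
    if not spiked:
        raise ValueError("truth contains no spiked features to recover")
    abs_eff = effects["effect"].abs()
    hit = abs_eff >= effect_cutoff
    sens = float(hit.loc[list(spiked)].mean())
    non = [f for f in effects.index if f not in spiked]
    fpr = float(hit.loc[non].mean()) if non else None
    top = set(abs_eff.sort_values(ascending=False).index[: len(spiked)])
    rank = len(top & spiked) / len(spiked)
    return RecoveryResult(sensitivity=sens, false_positive_rate=fpr, rank_agreement=rank)
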