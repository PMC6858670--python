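"""End-to-end pipeline: read -> align -> filter -> zero-handle -> CLR -> plots.

Every run is a pure function of (inputs, config): all randomness is seeded
from config keys, so the data artifacts of two runs with the same config
and inputs are byte-identical.  Each rendered plot gets a machine-readable
sidecar TSV, and a commented Python script can be exported per plot that
regenerates its sidecar from scratch.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import ConfigError, RunConfig
from .diffabund import (
    GroupDesign,
    aldex_effects,
    effect_plot_data,
    ma_plot_data,
    per_instance_effects,
    sample_mc_instances,
)
from .filtering import FilterSpec, filter_counts
from .io import (
    CountTable,
    align_samples,
    read_count_table,
    read_metadata,
    write_count_table,
)
from .ordination import (
    colour_by_metadata,
    hierarchical_cluster,
    metadata_histogram,
    pca_clr,
    sample_distance_matrix,
)
from .plots import render_plot
from .summaries import goslim_stripchart_data, relative_abundance_by_taxon
from .transform import clr_matrix, impute_zeros_czm, impute_zeros_pseudocount

__all__ = ["run_pipeline", "compute_plot_data", "export_reproduction_script", "PipelineState"]

_EFFECT_QUANTILES = (0.025, 0.25, 0.5, 0.75, 0.975)


class PipelineState(dict):
    """Lazy cache of intermediate pipeline results keyed by stage name."""


def _stage(name):
    def wrap(fn):
        fn._stage = name
        return fn

    return wrap


class _Pipeline:
    def __init__(self, config: RunConfig):
        self.cfg = config
        self.state = PipelineState()

    def get(self, name: str):
        if name not in self.state:
            try:
                self.state[name] = getattr(self, f"_{name}")()
            except (ConfigError, KeyError, ValueError, TypeError, OSError) as exc:
                raise type(exc)(f"[stage {name}] {exc}") from exc
        return self.state[name]

    # -- stages ------------------------------------------------------
    def _table(self) -> CountTable:
        if not self.cfg.counts_path:
            raise ConfigError("counts_path is not set")
        return read_count_table(
            self.cfg.counts_path,
            dialect=self.cfg.counts_dialect,
            delimiter=self.cfg.delimiter,
        )

    def _metadata(self):
        if not self.cfg.metadata_path:
            return None
        return read_metadata(self.cfg.metadata_path, delimiter=self.cfg.delimiter)

    def _aligned(self):
        table = self.get("table")
        metadata = self.get("metadata")
        if metadata is None:
            return table, None
        # fail fast on variables the config references but metadata lacks
        for key in ("design_variable", "colour_variable", "histogram_variable"):
            var = getattr(self.cfg, key)
            if var and var not in metadata.variables:
                raise ConfigError(
                    f"{key}={var!r} not among metadata variables {metadata.variables}"
                )
        return align_samples(table, metadata)

    def _filtered(self):
        table, _ = self.get("aligned")
        spec = FilterSpec(
            min_sample_total=self.cfg.min_sample_total,
            min_feature_total=self.cfg.min_feature_total,
            min_feature_max_prop=self.cfg.min_feature_max_prop,
        )
        return filter_counts(table, spec)

    def _composition(self) -> pd.DataFrame:
        table, _ = self.get("filtered")
        counts = table.counts
        if self.cfg.zero_method == "czm":
            cols = {
                s: impute_zeros_czm(counts[s].to_numpy(), frac=self.cfg.czm_frac)
                for s in counts.columns
            }
            return pd.DataFrame(cols, index=counts.index)
        return pd.DataFrame(
            impute_zeros_pseudocount(counts.to_numpy(), pseudo=self.cfg.pseudocount),
            index=counts.index,
            columns=counts.columns,
        )

    def _clr(self):
        return clr_matrix(self.get("composition"), base=self.cfg.log_base)

    def _pca(self):
        return pca_clr(self.get("clr"), scaling=self.cfg.biplot_scaling)

    def _distance(self) -> pd.DataFrame:
        if self.cfg.distance == "jaccard_presence":
            table, _ = self.get("filtered")
            return sample_distance_matrix(table, metric="jaccard_presence")
        return sample_distance_matrix(self.get("clr"), metric=self.cfg.distance)

    def _dendrogram(self):
        return hierarchical_cluster(
            self.get("distance"),
            linkage=self.cfg.linkage,
            distance_name=self.cfg.distance,
        )

    def _design(self) -> GroupDesign:
        _, metadata = self.get("aligned")
        if metadata is None or not self.cfg.design_variable:
            raise ConfigError("effects need metadata_path and design_variable")
        table, _ = self.get("filtered")
        design = GroupDesign.from_metadata(metadata, self.cfg.design_variable)
        keep = [s for s in design.sample_ids if s in set(table.sample_ids)]
        lab = dict(zip(design.sample_ids, design.conditions))
        return GroupDesign(keep, [lab[s] for s in keep])

    def _ensemble(self):
        table, _ = self.get("filtered")
        return sample_mc_instances(
            table,
            n_instances=self.cfg.mc_instances,
            prior=self.cfg.prior,
            seed=self.cfg.seed,
        )

    def _effects(self) -> pd.DataFrame:
        table, _ = self.get("filtered")
        design = self.get("design")
        sub = table.select(samples=list(design.sample_ids))
        return aldex_effects(
            sub,
            design,
            n_instances=self.cfg.mc_instances,
            prior=self.cfg.prior,
            seed=self.cfg.seed,
            mode=self.cfg.effect_mode,
            max_pairs=self.cfg.max_pairs,
        )

    def _effect_quantiles(self) -> pd.DataFrame:
        table, _ = self.get("filtered")
        design = self.get("design")
        sub = table.select(samples=list(design.sample_ids))
        ens = sample_mc_instances(
            sub,
            n_instances=self.cfg.mc_instances,
            prior=self.cfg.prior,
            seed=self.cfg.seed,
        )
        eff = per_instance_effects(ens, design)
        finite = np.where(np.isfinite(eff), eff, np.nan)
        qs = np.nanquantile(finite, _EFFECT_QUANTILES, axis=0)
        return pd.DataFrame(
            qs.T,
            index=pd.Index(ens.feature_ids, name="feature_id"),
            columns=[f"effect_q{int(q * 1000):03d}" for q in _EFFECT_QUANTILES],
        )

    # -- plot record sets --------------------------------------------
    def plot_records(self, kind: str):
        cfg = self.cfg
        if kind == "effect" or kind == "ma":
            fn = effect_plot_data if kind == "effect" else ma_plot_data
            records = fn(
                self.get("effects"),
                effect_cutoff=cfg.effect_cutoff,
                ebh_cutoff=cfg.ebh_cutoff,
                test=cfg.effect_test,
            )
            return records.join(self.get("effect_quantiles"))
        if kind == "pca_biplot":
            pca = self.get("pca")
            sidecar = pca.scores.copy()
            colours = None
            _, metadata = self.get("aligned")
            if cfg.colour_variable and metadata is not None:
                colours = colour_by_metadata(
                    list(pca.scores.index), metadata, cfg.colour_variable
                )
                sidecar["colour"] = [colours[s] for s in sidecar.index]
                sidecar["colour_value"] = (
                    metadata.column(cfg.colour_variable).reindex(sidecar.index).to_numpy()
                )
            return {"pca": pca, "colours": colours, "sidecar": sidecar}
        if kind == "dendro_abundance":
            dendro = self.get("dendrogram")
            table, _ = self.get("filtered")
            summary = relative_abundance_by_taxon(
                table,
                level_delimiter=cfg.taxonomy_delimiter,
                level=cfg.taxonomy_level,
                sample_order=[
                    s for s in dendro.leaf_order() if s in set(table.sample_ids)
                ],
            )
            return dendro, summary
        if kind == "stripchart":
            table, _ = self.get("filtered")
            _, metadata = self.get("aligned")
            return goslim_stripchart_data(
                table,
                metadata=metadata if cfg.colour_variable else None,
                colour_variable=cfg.colour_variable or None,
            )
        if kind == "histogram":
            _, metadata = self.get("aligned")
            var = cfg.histogram_variable or cfg.colour_variable
            if metadata is None or not var:
                raise ConfigError(
                    "histogram needs metadata and histogram_variable/colour_variable"
                )
            return metadata_histogram(metadata, var, bins=cfg.histogram_bins)
        raise ConfigError(f"unknown plot kind {kind!r}")

    def sidecar_frame(self, kind: str) -> pd.DataFrame:
        records = self.plot_records(kind)
        if kind == "pca_biplot":
            return records["sidecar"]
        if kind == "dendro_abundance":
            _, summary = records
            return summary.proportions
        return records


_SIDECAR_INDEX_LABEL = {
    "effect": "feature_id",
    "ma": "feature_id",
    "pca_biplot": "sample_id",
    "dendro_abundance": "group",
}


def _write_sidecar(frame: pd.DataFrame, path: Path, kind: str) -> None:
    label = _SIDECAR_INDEX_LABEL.get(kind)
    frame.to_csv(path, sep="\t", index=label is not None, index_label=label)


def compute_plot_data(config: RunConfig, kind: str) -> pd.DataFrame:
    """Recompute one plot's sidecar data frame from scratch."""
    return _Pipeline(config).sidecar_frame(kind)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the configured workflow and write all artifacts.

    Returns a mapping from artifact name to path.  Data artifacts (TSV,
    JSON, Newick) are byte-identical across reruns with the same inputs
    and config.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    pipe = _Pipeline(config)
    artifacts: dict[str, Path] = {}

    # fail fast on config/metadata mismatches before heavy computation
    pipe.get("aligned")

    table, report = pipe.get("filtered")
    p = out / "counts_filtered.tsv"
    write_count_table(table, p)
    artifacts["counts_filtered"] = p
    report.to_tsv(out / "filter_report.tsv")
    report.to_json(out / "filter_report.json")
    artifacts["filter_report"] = out / "filter_report.tsv"

    clrm = pipe.get("clr")
    clrm.to_tsv(out / "clr.tsv")
    artifacts["clr"] = out / "clr.tsv"

    pca = pipe.get("pca")
    pca.scores.to_csv(out / "pca_scores.tsv", sep="\t", index_label="sample_id")
    pca.loadings.to_csv(out / "pca_loadings.tsv", sep="\t", index_label="feature_id")
    pd.DataFrame(
        {
            "singular_value": pca.singular_values,
            "variance_explained": pca.variance_explained,
        },
        index=pd.Index(pca.component_names, name="component"),
    ).to_csv(out / "pca_variance.tsv", sep="\t")
    artifacts["pca_scores"] = out / "pca_scores.tsv"

    dist = pipe.get("distance")
    dist.to_csv(out / "distance.tsv", sep="\t", index_label="sample_id")
    dendro = pipe.get("dendrogram")
    (out / "dendrogram.nwk").write_text(dendro.to_newick() + "\n")
    artifacts["dendrogram"] = out / "dendrogram.nwk"

    if config.design_variable and config.metadata_path:
        effects = pipe.get("effects")
        effects.to_csv(out / "effects.tsv", sep="\t", index_label="feature_id")
        artifacts["effects"] = out / "effects.tsv"

    if table.taxonomy is not None:
        summary = relative_abundance_by_taxon(
            table,
            level_delimiter=config.taxonomy_delimiter,
            level=config.taxonomy_level,
        )
        summary.to_tsv(out / "relative_abundance.tsv")
        artifacts["relative_abundance"] = out / "relative_abundance.tsv"
    if table.go_annotation is not None:
        strip = pipe.plot_records("stripchart")
        strip.to_csv(out / "stripchart_records.tsv", sep="\t", index=False)
        artifacts["stripchart_records"] = out / "stripchart_records.tsv"

    for kind in config.plot_kinds():
        records = pipe.plot_records(kind)
        sidecar = pipe.sidecar_frame(kind)
        sidecar_path = out / f"{kind}_data.tsv"
        _write_sidecar(sidecar, sidecar_path, kind)
        artifacts[f"{kind}_data"] = sidecar_path
        if kind == "pca_biplot":
            paths = render_plot(records, kind, out / kind)
        else:
            paths = render_plot(records, kind, out / kind)
        artifacts[f"{kind}_plot"] = paths[0]
        script = export_reproduction_script(config, kind)
        (out / f"reproduce_{kind}.py").write_text(script)
        artifacts[f"{kind}_script"] = out / f"reproduce_{kind}.py"

    manifest = {
        "config": config.to_dict(),
        "codaplot_version": __version__,
        "python_version": sys.version.split()[0],
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "artifacts": {k: str(v) for k, v in artifacts.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    artifacts["manifest"] = out / "manifest.json"
    return artifacts


_SCRIPT_TEMPLATE = '''\
# Reproduction script for the "{kind}" plot sidecar.
#
# Rerunning this file from anywhere regenerates {kind}_data.tsv
# byte-identically from the original inputs, using the exact parameters of
# the original run.  Edit the variables below to adjust the analysis.

from codaplot.config import RunConfig
from codaplot.pipeline import compute_plot_data

# ---- user-chosen parameters of the original run -------------------------
{params}
# -------------------------------------------------------------------------

config = RunConfig(
{kwargs}
)

frame = compute_plot_data(config, "{kind}")
out_path = "{out_path}"
frame.to_csv(
    out_path,
    sep="\\t",
    index={index_flag},
    index_label={index_label!r},
)
print(f"wrote {{out_path}}")
'''

_PARAM_COMMENTS = {
    "counts_path": "input count table (features x samples)",
    "counts_dialect": "plain | taxonomy_last_column | go_slim",
    "metadata_path": "per-sample metadata (empty = none)",
    "min_sample_total": "drop samples with fewer total reads",
    "min_feature_total": "drop features with fewer total reads",
    "min_feature_max_prop": "drop features never reaching this proportion",
    "zero_method": "czm (multiplicative) or pseudocount zero handling",
    "czm_frac": "CZM fraction of the detection limit given to zeros",
    "mc_instances": "Dirichlet Monte-Carlo instances (K)",
    "prior": "Dirichlet prior added to every count",
    "seed": "random seed for all Monte-Carlo draws",
    "design_variable": "two-level metadata variable compared by the effects",
    "effect_cutoff": "|effect| threshold for highlighting features",
    "ebh_cutoff": "expected-BH significance threshold",
    "linkage": "hierarchical clustering linkage",
    "distance": "sample distance metric",
    "biplot_scaling": "form (scores carry singular values) or covariance",
}


def export_reproduction_script(config: RunConfig, target: str) -> str:
    """A standalone, commented script regenerating one plot's sidecar."""
    if target not in config.plot_kinds():
        raise ConfigError(
            f"plot {target!r} is not produced by this config (plots={config.plots!r})"
        )
    d = config.to_dict()
    lines = []
    for key, value in d.items():
        comment = _PARAM_COMMENTS.get(key)
        suffix = f"  # {comment}" if comment else ""
        lines.append(f"{key.upper()} = {value!r}{suffix}")
    kwargs = ",\n".join(f"    {key}={key.upper()}" for key in d)
    out_path = str(Path(config.output_dir) / f"{target}_data.tsv")
    label = _SIDECAR_INDEX_LABEL.get(target)
    return _SCRIPT_TEMPLATE.format(
        kind=target,
        params="\n".join(lines),
        kwargs=kwargs,
        out_path=out_path,
        index_flag=label is not None,
        index_label=label,
    )
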