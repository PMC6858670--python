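"""Flat key-value run configuration.

The config file is a flat YAML mapping (no nesting) so that every
parameter of a run is a single named key; unknown keys are errors rather
than warnings, to protect reproducibility.  All random seeds are explicit
keys.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or unknown configuration key/value."""


@dataclass
class RunConfig:
    """Everything a pipeline run depends on, as flat keys.

    Paths are resolved relative to the config file's directory when loaded
    from disk.  ``plots`` is a comma-separated list of plot kinds to
    render (subset of pca_biplot, effect, ma, dendro_abundance,
    stripchart, histogram).
    """

    counts_path: str = ""
    counts_dialect: str = "plain"  # plain | taxonomy_last_column | go_slim
    delimiter: str = "auto"  # tab | comma | auto
    metadata_path: str = ""  # empty = no metadata

    min_sample_total: int = 0
    min_feature_total: int = 0
    min_feature_max_prop: float = 0.0

    zero_method: str = "czm"  # czm | pseudocount
    czm_frac: float = 0.65
    pseudocount: float = 0.5
    log_base: float = 2.0

    design_variable: str = ""  # two-level metadata variable; empty = no effects
    mc_instances: int = 128
    prior: float = 0.5
    seed: int = 0
    effect_mode: str = "subsample"  # exact | subsample
    max_pairs: int = 10000
    effect_cutoff: float = 1.0
    ebh_cutoff: float = 0.05
    effect_test: str = "wilcoxon"  # wilcoxon | welch

    colour_variable: str = ""
    histogram_variable: str = ""
    histogram_bins: int = 10
    linkage: str = "average"  # single | complete | average | ward
    distance: str = "aitchison"  # aitchison | euclidean_clr | jaccard_presence
    biplot_scaling: str = "form"  # form | covariance
    taxonomy_level: int = 1
    taxonomy_delimiter: str = ";"

    plots: str = "pca_biplot"
    output_dir: str = "codaplot_out"

    def __post_init__(self) -> None:
        checks = {
            "counts_dialect": ("plain", "taxonomy_last_column", "go_slim"),
            "delimiter": ("tab", "comma", "auto"),
            "zero_method": ("czm", "pseudocount"),
            "effect_mode": ("exact", "subsample"),
            "effect_test": ("wilcoxon", "welch"),
            "linkage": ("single", "complete", "average", "ward"),
            "distance": ("aitchison", "euclidean_clr", "jaccard_presence"),
            "biplot_scaling": ("form", "covariance"),
        }
        for key, allowed in checks.items():
            if getattr(self, key) not in allowed:
                raise ConfigError(
                    f"{key} must be one of {allowed}, got {getattr(self, key)!r}"
                )

    # -- serialization -----------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    def plot_kinds(self) -> list[str]:
        return [p.strip() for p in self.plots.split(",") if p.strip()]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True, default_flow_style=False)
        )

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(d) - known)
        if unknown:
            raise ConfigError(f"unknown config keys: {unknown}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} is not a flat mapping")
        for key, value in raw.items():
            if isinstance(value, dict):
                raise ConfigError(f"config must be flat; key {key!r} holds a mapping")
        cfg = cls.from_dict(raw)
        # resolve paths relative to the config file
        for key in ("counts_path", "metadata_path", "output_dir"):
            val = getattr(cfg, key)
            if val and not Path(val).is_absolute():
                setattr(cfg, key, str((path.parent / val).resolve()))
        return cfg
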