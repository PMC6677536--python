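"""Shared analysis parameters.

Every numeric constant and convention used by the pipeline lives in one
validated configuration object, so that the defaults documented below are
asserted in a single place and every stage reads the same values: the 1 rpm
expression threshold, the 4-fold derepression threshold, the ratio-2
Piwi-dependence rule, 10/50 bp coverage bins, the 23-29 nt piRNA window,
the 1000-hit multimapper cap and the seeded random-window protocol.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from typing import Any

import yaml

__all__ = ["AnalysisParameters", "load_parameters"]

_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"


@dataclass(frozen=True)
class AnalysisParameters:
    """Pipeline-wide constants.

    Defaults are the analysis conventions of the study this pipeline
    reimplements; ``metaplot_flank`` and ``fold_change_pseudocount`` have no
    published value and are explicitly configurable choices.
    """

    #: bases removed from each end of every raw sequencing read
    read_end_trim_bases: int = 1
    #: 3' sequencing adapter clipped from small-RNA reads
    srna_adapter: str = _ADAPTER
    #: minimum length of the clipped small-RNA product that is kept
    srna_min_len_after_clip: int = 23
    #: random ligation bases trimmed from each end after adapter clipping
    srna_random_end_trim: int = 4
    #: inclusive piRNA length window (nt)
    pirna_len_min: int = 23
    pirna_len_max: int = 29
    #: reads with more equally-best hits than this are discarded
    multimap_max_hits: int = 1000
    #: genome-space coverage bin (bp)
    coverage_bin_genome: int = 10
    #: TE-consensus-space coverage bin (bp)
    coverage_bin_te: int = 50
    #: k-mer length for mappability
    mappability_kmer: int = 50
    #: mappability track resolution (bp)
    mappability_resolution: int = 50
    #: features below this rpm in both conditions are excluded from fold-change calls
    expression_threshold_rpm: float = 1.0
    #: |fold change| beyond this (strict) flags a feature as changed
    derepression_fold_threshold: float = 4.0
    #: control/knockdown H3K9me3 ratio above which (strict) an insertion is Piwi-dependent
    piwi_dependence_ratio: float = 2.0
    #: random background windows: size, count, RNG seed and retained index slice
    random_window_size: int = 5000
    random_window_count: int = 1000
    random_window_seed: int = 800
    random_window_select: tuple[int, int] = (200, 300)
    #: flank around TE insertions in metaplots (bp); no published value
    metaplot_flank: int = 5000
    #: pseudocount (rpm) added to both conditions in fold changes; no published value
    fold_change_pseudocount: float = 0.01
    #: master seed for every stochastic stage
    global_seed: int = 0

    def __post_init__(self) -> None:
        positive = [
            "read_end_trim_bases",
            "srna_min_len_after_clip",
            "srna_random_end_trim",
            "pirna_len_min",
            "pirna_len_max",
            "multimap_max_hits",
            "coverage_bin_genome",
            "coverage_bin_te",
            "mappability_kmer",
            "mappability_resolution",
            "random_window_size",
            "random_window_count",
            "metaplot_flank",
        ]
        for name in positive:
            value = getattr(self, name)
            if name == "read_end_trim_bases":
                if value < 0:
                    raise ValueError(f"{name} must be >= 0, got {value}")
            elif value <= 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        if self.pirna_len_min > self.pirna_len_max:
            raise ValueError(
                "pirna_len_min must be <= pirna_len_max, got "
                f"{self.pirna_len_min} > {self.pirna_len_max}"
            )
        if set(self.srna_adapter) - set("ACGT"):
            raise ValueError("srna_adapter must contain only ACGT characters")
        if self.derepression_fold_threshold <= 1:
            raise ValueError("derepression_fold_threshold must be > 1")
        if self.piwi_dependence_ratio <= 1:
            raise ValueError("piwi_dependence_ratio must be > 1")
        if self.expression_threshold_rpm < 0:
            raise ValueError("expression_threshold_rpm must be >= 0")
        if self.fold_change_pseudocount <= 0:
            raise ValueError("fold_change_pseudocount must be > 0")
        lo, hi = self.random_window_select
        if not (0 <= lo < hi <= self.random_window_count):
            raise ValueError(
                "random_window_select must satisfy "
                f"0 <= lo < hi <= random_window_count, got {lo}..{hi}"
            )
        # normalize list -> tuple so round-trips compare equal
        object.__setattr__(self, "random_window_select", (int(lo), int(hi)))

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["random_window_select"] = list(self.random_window_select)
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    def replace(self, **overrides: Any) -> "AnalysisParameters":
        return dataclasses.replace(self, **overrides)


def load_parameters(config_source: str | dict[str, Any] | io.TextIOBase | None = None) -> AnalysisParameters:
    """Build :class:`AnalysisParameters` from a YAML document or mapping.

    Unset keys take their defaults; unknown keys are rejected so that a typo
    in a config file cannot silently fall back to a default.
    """
    if config_source is None:
        return AnalysisParameters()
    if isinstance(config_source, dict):
        data = dict(config_source)
    else:
        text = config_source.read() if hasattr(config_source, "read") else config_source
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError("parameter config must be a mapping of key: value pairs")
        data = loaded
    known = {f.name for f in dataclasses.fields(AnalysisParameters)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    if "random_window_select" in data:
        data["random_window_select"] = tuple(data["random_window_select"])
    return AnalysisParameters(**data)
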