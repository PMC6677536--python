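"""Canonical simulated-study configurations.

These are the reference conditions under which the pipeline's recovery
properties are stated and verified: a TE-derepression RNA-seq experiment
(200 kb genome, 10 families of which 4 derepress 8-fold, 3 replicates x 2
conditions x 100k stranded reads), an H3K9me3 knockdown ChIP experiment
(40 insertions, control/knockdown enrichment ratio 4 at half of them, 200k
reads per condition), a 50k-read small-RNA library and a 2x3 qPCR panel.
"""

from __future__ import annotations

from typing import Any

__all__ = [
    "te_derepression_config",
    "piwi_dependence_config",
    "srna_config",
    "qpcr_config",
]


def te_derepression_config(seed: int = 0) -> dict[str, Any]:
    """RNA-seq derepression recovery study: truth folds {8, 1}."""
    return {
        "parameters": {"global_seed": seed},
        "simulation": {
            "n_chrom": 1,
            "chrom_len": 200_000,
            "n_families": 10,
            "copies_per_family": 4,
            "n_genes": 20,
            "divergence": 0.03,
            "n_derepressed": 4,
            "derepression_fold": 8.0,
        },
        "assays": {
            "rnaseq": {
                "conditions": ["control", "knockdown"],
                "replicates": 3,
                "n_reads": 100_000,
            }
        },
    }


def piwi_dependence_config(seed: int = 0) -> dict[str, Any]:
    """H3K9me3 classifier study: 20 insertions at control/knockdown
    enrichment ratio 4, 20 at ratio 1."""
    return {
        "parameters": {"global_seed": seed},
        "simulation": {
            "n_chrom": 1,
            "chrom_len": 200_000,
            "n_families": 10,
            "copies_per_family": 4,
            "n_genes": 20,
            "divergence": 0.03,
            "n_derepressed": 5,
        },
        "assays": {"chipseq": {"mark": "H3K9me3", "n_reads": 200_000}},
    }


def srna_config(seed: int = 0, n_reads: int = 50_000) -> dict[str, Any]:
    """Noise-free small-RNA chain study."""
    return {
        "parameters": {"global_seed": seed},
        "simulation": {
            "n_chrom": 1,
            "chrom_len": 120_000,
            "n_families": 6,
            "copies_per_family": 2,
            "n_genes": 6,
            "divergence": 0.0,
        },
        "assays": {"srna": {"n_reads": n_reads}},
    }


def qpcr_config(seed: int = 0, noise_sd: float = 0.0) -> dict[str, Any]:
    return {
        "parameters": {"global_seed": seed},
        "simulation": {
            "n_chrom": 1,
            "chrom_len": 120_000,
            "n_families": 6,
            "copies_per_family": 2,
            "n_genes": 6,
            "divergence": 0.0,
        },
        "assays": {"qpcr": {"replicates": 3, "noise_sd": noise_sd}},
    }
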