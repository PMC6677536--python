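"""Threshold-based differential expression.

No dispersion model and no p-values: replicate rpm values are averaged per
condition, features whose larger condition mean clears the expression
threshold (default 1 rpm) are *included*, and an included feature is
*changed* when its fold change (with a small pseudocount) exceeds the
derepression threshold (default 4-fold, strict) in either direction.
"""

from __future__ import annotations

import pandas as pd

from .params import AnalysisParameters

__all__ = ["aggregate_replicates", "fold_change_table", "summarize_changes"]


def aggregate_replicates(
    rpm_matrix: pd.DataFrame, sample_conditions: dict[str, str]
) -> pd.DataFrame:
    """Arithmetic mean rpm per condition (features x conditions).

    ``rpm_matrix`` is features x samples; every sample column must be
    mapped to a condition and every condition needs at least one replicate.
    """
    missing = set(rpm_matrix.columns) - set(sample_conditions)
    if missing:
        raise ValueError(f"samples without condition assignment: {sorted(missing)}")
    groups = pd.Series({s: sample_conditions[s] for s in rpm_matrix.columns})
    return rpm_matrix.T.groupby(groups).mean().T


def fold_change_table(
    mean_rpm_a: pd.Series,
    mean_rpm_b: pd.Series,
    params: AnalysisParameters,
    feature_class: str | pd.Series = "te_family",
) -> pd.DataFrame:
    """Fold-change table for condition B over condition A.

    included  <=> max(mean_A, mean_B) > expression_threshold_rpm
    fold      =   (mean_B + c) / (mean_A + c), pseudocount c
    changed   <=> included and (fold > T or fold < 1/T), strict, T the
                  derepression threshold
    """
    a, b = mean_rpm_a.align(mean_rpm_b, fill_value=0.0)
    c = params.fold_change_pseudocount
    t = params.derepression_fold_threshold
    fold = (b + c) / (a + c)
    included = pd.concat([a, b], axis=1).max(axis=1) > params.expression_threshold_rpm
    changed = included & ((fold > t) | (fold < 1.0 / t))
    table = pd.DataFrame(
        {
            "class": feature_class,
            "mean_a": a,
            "mean_b": b,
            "fold_change": fold,
            "included": included,
            "changed": changed,
        }
    )
    table.index.name = "feature"
    return table


def summarize_changes(
    table: pd.DataFrame,
    feature_class: str | None = None,
    direction: str = "up",
) -> tuple[int, int]:
    """(n_changed, n_included) over one feature class.

    ``direction`` restricts the changed count to derepression ("up",
    fold > 1), repression ("down") or both ("both").
    """
    if feature_class is not None:
        table = table[table["class"] == feature_class]
    included = table["included"]
    changed = table["changed"]
    if direction == "up":
        changed = changed & (table["fold_change"] > 1)
    elif direction == "down":
        changed = changed & (table["fold_change"] < 1)
    elif direction != "both":
        raise ValueError(f"unknown direction {direction!r}")
    return int(changed.sum()), int(included.sum())
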