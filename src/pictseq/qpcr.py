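"""Relative qPCR quantification by the ddCT method.

Fold change = 2^-ddCt where dCt = mean Ct(target) - mean Ct(reference gene,
here typically rp49) per condition and ddCt = dCt(condition) -
dCt(control). Statistics are computed on per-replicate dCt values with an
unpaired two-sample t-test (Student by default, Welch by flag).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .model import QPCRMeasurement

__all__ = ["ddct_fold_change", "unpaired_t_test", "significance_label"]


def _cts(
    measurements: list[QPCRMeasurement], target: str, condition: str
) -> list[float]:
    vals = [m.ct for m in measurements if m.target == target and m.condition == condition]
    if not vals:
        raise ValueError(f"no Ct values for target {target!r} in condition {condition!r}")
    return vals


def ddct_fold_change(
    measurements: list[QPCRMeasurement],
    target: str,
    reference_gene: str,
    condition: str,
    control_condition: str,
) -> tuple[float, dict[str, list[float]]]:
    """ddCT fold change of ``condition`` over ``control_condition``.

    Returns (fold_change, per-condition per-replicate dCt lists). dCt per
    replicate is Ct(target) - mean Ct(reference) of the same condition, so
    replicate counts for target and reference may differ.
    """
    delta: dict[str, list[float]] = {}
    for cond in (condition, control_condition):
        ref_mean = float(np.mean(_cts(measurements, reference_gene, cond)))
        delta[cond] = [ct - ref_mean for ct in _cts(measurements, target, cond)]
    ddct = float(np.mean(delta[condition]) - np.mean(delta[control_condition]))
    return 2.0 ** (-ddct), delta


def unpaired_t_test(
    delta_ct_a, delta_ct_b, equal_variance: bool = True
) -> tuple[float, float, float]:
    """Unpaired two-sample t-test on dCt lists: (t, df, two-sided p)."""
    a = np.asarray(delta_ct_a, dtype=float)
    b = np.asarray(delta_ct_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("degenerate (zero) variance in both samples")
    if equal_variance:
        df = na + nb - 2
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    else:
        se2 = va / na + vb / nb
        t = (a.mean() - b.mean()) / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


DEFAULT_STARS = ((0.001, "**"), (0.05, "*"))


def significance_label(p: float, scheme=DEFAULT_STARS) -> str:
    """Star label for a p-value under a configurable threshold scheme.

    ``scheme`` is an ordered sequence of (threshold, label); the label of
    the smallest threshold exceeding p wins, 'ns' otherwise. Published
    figure legends use inconsistent star conventions, so the scheme is
    always explicit configuration, never a fixed rule.
    """
    for threshold, label in sorted(scheme):
        if p < threshold:
            return label
    return "ns"
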