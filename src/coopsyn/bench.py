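"""Bench-side validation metrics: ΔΔCt qPCR quantification, xenograft
tumor volume, and the paired t-test used for group comparisons.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, ValidationError


def ddct_fold_change(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> tuple[float, float]:
    """Relative expression by the ΔΔCt method (efficiency fixed at 2).

    ``ΔΔCt = (Ct_target,treated − Ct_ref,treated) − (Ct_target,control −
    Ct_ref,control)`` and fold-change ``= 2^(−ΔΔCt)``, i.e. expression of
    the target normalized to a reference gene (β-actin in the assays this
    mirrors) and relative to the control condition. Returns
    ``(ddct, fold_change)``.
    """
    cts = (ct_target_treated, ct_ref_treated, ct_target_control, ct_ref_control)
    if any((not math.isfinite(c)) or c <= 0 for c in cts):
        raise ValidationError("all Ct values must be finite and positive")
    ddct = (ct_target_treated - ct_ref_treated) - (ct_target_control - ct_ref_control)
    return ddct, 2.0 ** (-ddct)


def ddct_table(
    ct: pd.DataFrame,
    ref_gene: str = "ACTB",
    control_group: str = "control",
) -> pd.DataFrame:
    """Per-gene fold-changes from a long Ct table.

    ``ct`` needs columns ``sample, group, gene, ct``. Replicate Cts are
    averaged per group × gene before ΔΔCt; each non-control group is
    compared to ``control_group`` with ``ref_gene`` as the normalizer.
    """
    required = {"sample", "group", "gene", "ct"}
    missing = required - set(ct.columns)
    if missing:
        raise ValidationError(f"Ct table missing columns: {sorted(missing)}")
    if (ct["ct"] <= 0).any():
        raise ValidationError("all Ct values must be positive")
    mean_ct = ct.groupby(["group", "gene"], sort=True)["ct"].mean()
    groups = sorted(ct["group"].unique())
    if control_group not in groups:
        raise ValidationError(f"control group {control_group!r} absent from table")
    genes = sorted(g for g in ct["gene"].unique() if g != ref_gene)
    if ref_gene not in set(ct["gene"]):
        raise ValidationError(f"reference gene {ref_gene!r} absent from table")

    rows = []
    for group in groups:
        if group == control_group:
            continue
        for gene in genes:
            ddct, fold = ddct_fold_change(
                mean_ct[(group, gene)],
                mean_ct[(group, ref_gene)],
                mean_ct[(control_group, gene)],
                mean_ct[(control_group, ref_gene)],
            )
            rows.append({"group": group, "gene": gene, "ddct": ddct, "fold_change": fold})
    return pd.DataFrame(rows)


def tumor_volume(length: float, width: float) -> float:
    """Xenograft tumor volume in mm³: ``1/2 · length · width²``.

    Caliper convention places the longer axis in ``length``; a width
    exceeding the length signals swapped measurements and is rejected.
    """
    if not (math.isfinite(length) and math.isfinite(width)) or width <= 0:
        raise ValidationError("length and width must be finite and positive")
    if width > length:
        raise ValidationError("width exceeds length; caliper axes appear swapped")
    return 0.5 * length * width * width


def tumor_volume_table(caliper: pd.DataFrame) -> pd.DataFrame:
    """Append a ``volume`` column (mm³) to a caliper table with length/width in mm."""
    required = {"length", "width"}
    missing = required - set(caliper.columns)
    if missing:
        raise ValidationError(f"caliper table missing columns: {sorted(missing)}")
    out = caliper.copy()
    out["volume"] = [tumor_volume(l, w) for l, w in zip(out["length"], out["width"])]
    return out


def paired_t(x, y) -> tuple[float, float, int]:
    """Paired two-sided t-test; returns ``(t, p, df)``.

    ``t = mean(d) / (sd(d)/√n)`` with ``d = x − y`` and ``df = n − 1``;
    the sample SD uses the ``n − 1`` denominator. Identical series give
    ``t = 0, p = 1``; a nonzero constant difference has no within-pair
    variance and yields ``t = ±inf, p = 0``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D and the same length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("missing or non-finite pairs are not allowed")
    n = x.size
    if n < 2:
        raise InsufficientDataError("paired t-test needs at least 2 pairs")
    d = x - y
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return 0.0, 1.0, n - 1
        return math.copysign(math.inf, d.mean()), 0.0, n - 1
    res = stats.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue), n - 1
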