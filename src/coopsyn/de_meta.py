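"""Cross-cell-line meta-analysis of differential-expression summaries.

Per-line DE results (log2 fold-change, two-sided p) are converted to
signed z-scores, combined across cell lines with Stouffer's method
(``z_meta = Σ z_i / √k``, unweighted), and filtered for homogeneity of
regulation direction. Genes are then assigned Venn labels by which
treatments regulate them, and a cooperative-gene detector flags genes
whose combination fold-change exceeds both single-agent fold-changes in at
least ``min_lines`` cell lines.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

TREATMENTS = ("OPC", "curcumin", "combination")
VENN_LABELS = ("common", "opc_only", "curcumin_only", "combination_only", "unclassified")

_RECORD_COLUMNS = ("gene", "cell_line", "treatment", "log2fc", "p_value")


def signed_z(log2fc: float, p_value: float) -> float:
    """Signed z-score from a two-sided p-value and the fold-change sign.

    ``|z|`` is the upper-tail standard-normal quantile of ``p/2`` and the
    sign is that of the log2 fold-change; ``p = 1`` (or a zero
    fold-change) gives ``z = 0``.
    """
    p = float(p_value)
    if not (0.0 < p <= 1.0):
        raise ValidationError(f"p-value must be in (0, 1], got {p!r}")
    if not math.isfinite(log2fc):
        raise ValidationError("log2fc must be finite")
    magnitude = stats.norm.isf(p / 2.0)
    return float(np.sign(log2fc) * magnitude)


def stouffer_combine(z_by_line: Sequence[float]) -> tuple[float, float]:
    """Unweighted Stouffer combination: ``z_meta = Σ z_i / √k``.

    Returns ``(z_meta, p_meta)`` with the two-sided normal p-value.
    """
    z = np.asarray(list(z_by_line), dtype=float)
    if z.size == 0:
        raise ValidationError("need at least one z-score")
    if not np.all(np.isfinite(z)):
        raise ValidationError("z-scores must be finite")
    z_meta = float(z.sum() / math.sqrt(z.size))
    p_meta = float(min(2.0 * stats.norm.sf(abs(z_meta)), 1.0))
    return z_meta, p_meta


def homogeneity(directions: Iterable[float], rule: str = "all", min_agree_frac: float = 0.5) -> bool:
    """Do the per-line regulation directions agree?

    ``directions`` are per-line signs (+1 up, −1 down, 0 no change); zero
    signs never break agreement. ``rule="all"`` demands unanimity among
    nonzero signs; ``rule="majority"`` accepts when the modal sign holds at
    least ``min_agree_frac`` of the nonzero directions.
    """
    signs = np.sign(np.asarray(list(directions), dtype=float))
    if signs.size == 0:
        raise ValidationError("need at least one direction")
    nonzero = signs[signs != 0]
    if nonzero.size == 0:
        return True
    n_up = int((nonzero > 0).sum())
    n_down = nonzero.size - n_up
    if rule == "all":
        return n_up == 0 or n_down == 0
    if rule == "majority":
        if not (0.0 < min_agree_frac <= 1.0):
            raise ValidationError("min_agree_frac must be in (0, 1]")
        return max(n_up, n_down) / nonzero.size >= min_agree_frac
    raise ValidationError(f"unknown homogeneity rule {rule!r}")


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = set(_RECORD_COLUMNS) - set(records.columns)
    if missing:
        raise ValidationError(f"DE records missing columns: {sorted(missing)}")
    bad = set(records["treatment"].unique()) - set(TREATMENTS)
    if bad:
        raise ValidationError(f"unknown treatments: {sorted(bad)}; expected {TREATMENTS}")
    return records


def meta_analyze(
    records: pd.DataFrame,
    homogeneity_rule: str = "all",
    min_agree_frac: float = 0.5,
    z_column: str | None = None,
) -> pd.DataFrame:
    """Stouffer-combine per-line DE records into one row per gene × treatment.

    Returns columns ``gene, treatment, z_meta, p_meta, direction,
    homogeneous, n_lines``. By default signed z-scores are rebuilt from
    ``(log2fc, p_value)``; pass ``z_column`` to ingest a precomputed
    statistic from the upstream DE tool instead.
    """
    records = _check_records(records)
    df = records.copy()
    if z_column is None:
        p = df["p_value"].to_numpy(dtype=float)
        if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(df["log2fc"])):
            raise ValidationError("p-values must be in (0, 1] and log2fc finite")
        df["z"] = np.sign(df["log2fc"].to_numpy()) * stats.norm.isf(p / 2.0)
    else:
        if z_column not in df.columns:
            raise ValidationError(f"column {z_column!r} not in records")
        df["z"] = df[z_column].astype(float)

    df["_up"] = df["log2fc"] > 0
    df["_down"] = df["log2fc"] < 0
    agg = (
        df.groupby(["gene", "treatment"], sort=True)
        .agg(z_sum=("z", "sum"), n_lines=("z", "size"), n_up=("_up", "sum"), n_down=("_down", "sum"))
        .reset_index()
    )

    z_meta = agg["z_sum"].to_numpy() / np.sqrt(agg["n_lines"].to_numpy())
    p_meta = np.minimum(2.0 * stats.norm.sf(np.abs(z_meta)), 1.0)
    n_up = agg["n_up"].to_numpy()
    n_down = agg["n_down"].to_numpy()
    nonzero = n_up + n_down
    if homogeneity_rule == "all":
        homogeneous = (n_up == 0) | (n_down == 0)
    elif homogeneity_rule == "majority":
        if not (0.0 < min_agree_frac <= 1.0):
            raise ValidationError("min_agree_frac must be in (0, 1]")
        with np.errstate(invalid="ignore"):
            frac = np.where(nonzero > 0, np.maximum(n_up, n_down) / np.maximum(nonzero, 1), 1.0)
        homogeneous = frac >= min_agree_frac
    else:
        raise ValidationError(f"unknown homogeneity rule {homogeneity_rule!r}")

    return pd.DataFrame(
        {
            "gene": agg["gene"],
            "treatment": agg["treatment"],
            "z_meta": z_meta,
            "p_meta": p_meta,
            "direction": np.where(z_meta > 0, "up", np.where(z_meta < 0, "down", "none")),
            "homogeneous": homogeneous,
            "n_lines": agg["n_lines"],
        }
    )


def classify_genes(meta: pd.DataFrame, alpha: float = 0.05, adjust: str | None = "holm") -> pd.DataFrame:
    """Venn classification of genes by which treatments regulate them.

    A gene is *regulated* under a treatment when its (possibly adjusted)
    meta p-value is below ``alpha`` and the per-line directions were
    homogeneous. Labels: regulated by both single agents → ``common``; by
    exactly one single agent → ``opc_only`` / ``curcumin_only``; by the
    combination but neither single → ``combination_only``; otherwise
    ``unclassified``.

    ``adjust`` selects the multiplicity correction applied within each
    treatment before thresholding: ``"holm"`` (default; family-wise
    control), ``"bh"`` (Benjamini–Hochberg) or ``None`` (raw p-values).
    Holm is the default because each false discovery lands in one small
    Venn bucket: with thousands of genes, raw — and even per-treatment
    FDR — thresholding floods the single-agent-unique buckets with null
    genes, since sign unanimity across lines is positively correlated
    with meta significance under the null. Family-wise control keeps
    every bucket trustworthy at no practical power cost when combining
    several cell lines.
    """
    if not (0 < alpha < 1):
        raise ValidationError("alpha must be in (0, 1)")
    required = {"gene", "treatment", "p_meta", "homogeneous"}
    missing = required - set(meta.columns)
    if missing:
        raise ValidationError(f"meta table missing columns: {sorted(missing)}")
    universes = {t: frozenset(sub["gene"]) for t, sub in meta.groupby("treatment")}
    if set(universes) != set(TREATMENTS):
        raise ValidationError(f"meta table must cover treatments {TREATMENTS}")
    if len(set(universes.values())) != 1:
        raise ValidationError("treatments cover different gene universes")

    df = meta.copy()
    if adjust in ("bh", "holm"):
        method = "fdr_bh" if adjust == "bh" else "holm"
        df["p_use"] = np.nan
        for t in TREATMENTS:
            mask = df["treatment"] == t
            df.loc[mask, "p_use"] = multipletests(df.loc[mask, "p_meta"], method=method)[1]
    elif adjust is None:
        df["p_use"] = df["p_meta"]
    else:
        raise ValidationError(f"unknown adjustment {adjust!r}")

    df["regulated"] = (df["p_use"] < alpha) & df["homogeneous"]
    wide = df.pivot(index="gene", columns="treatment", values="regulated").astype(bool)
    opc = wide["OPC"].to_numpy()
    cur = wide["curcumin"].to_numpy()
    combo = wide["combination"].to_numpy()

    label = np.full(len(wide), "unclassified", dtype=object)
    label[combo & ~opc & ~cur] = "combination_only"
    label[opc & ~cur] = "opc_only"
    label[cur & ~opc] = "curcumin_only"
    label[opc & cur] = "common"

    return (
        pd.DataFrame({"gene": wide.index.to_numpy(), "label": label})
        .sort_values("gene", ignore_index=True)
    )


def cooperative_genes(
    records: pd.DataFrame,
    min_lines: int = 3,
    alpha: float = 0.05,
    require_line_significance: bool = True,
) -> list[str]:
    """Genes whose combination response exceeds both single-agent responses.

    A gene qualifies when, in at least ``min_lines`` cell lines,
    ``|log2fc_combination| > max(|log2fc_OPC|, |log2fc_curcumin|)`` and
    (optionally) the combination record is significant at ``alpha`` in that
    line. The returned list is sorted by gene id and invariant to input
    row order.
    """
    records = _check_records(records)
    if not (0 < alpha < 1):
        raise ValidationError("alpha must be in (0, 1)")
    present = set(records["treatment"].unique())
    if present != set(TREATMENTS):
        raise ValidationError(f"records must contain all treatments {TREATMENTS}")
    n_cell_lines = records["cell_line"].nunique()
    if min_lines > n_cell_lines:
        raise ValidationError(
            f"min_lines={min_lines} exceeds the {n_cell_lines} cell lines present"
        )

    fc = records.pivot_table(
        index=["gene", "cell_line"], columns="treatment", values="log2fc", aggfunc="first"
    )
    pv = records.pivot_table(
        index=["gene", "cell_line"], columns="treatment", values="p_value", aggfunc="first"
    )
    if fc[list(TREATMENTS)].isna().any().any():
        raise ValidationError("every gene × cell line needs all three treatments")

    exceeds = np.abs(fc["combination"]) > np.maximum(np.abs(fc["OPC"]), np.abs(fc["curcumin"]))
    if require_line_significance:
        exceeds &= pv["combination"] < alpha
    counts = exceeds.groupby(level="gene").sum()
    return sorted(counts.index[counts >= min_lines])
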