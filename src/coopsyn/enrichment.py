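"""Hypergeometric gene-set enrichment and pathway Venn classification.

Over-representation of a query gene list in each set is scored with the
one-sided hypergeometric upper tail ``P(X ≥ k)`` for ``X ~
Hypergeom(N, K, n)`` — equivalent to the one-sided Fisher exact test on
the 2×2 membership table. Pathways are then Venn-labeled by which
treatments' regulated-gene lists they are enriched in, mirroring the
common / agent-unique / combination-only comparison of the gene level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

logger = logging.getLogger(__name__)

PATHWAY_LABELS = ("common", "opc_only", "curcumin_only", "combination_only", "unclassified")


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (one GMT line)."""

    set_id: str
    name: str
    members: tuple[str, ...]

    def __post_init__(self):
        if not self.set_id:
            raise ValidationError("set_id must be non-empty")
        if len(self.members) == 0:
            raise ValidationError(f"gene set {self.set_id!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise ValidationError(f"gene set {self.set_id!r} has duplicate members")


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """One-sided over-representation p-value ``P(X ≥ k)``, ``X ~ Hypergeom(N, K, n)``.

    ``N`` genes in the universe, ``K`` of them in the set, ``n`` drawn in
    the query, ``k`` of the query inside the set.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValidationError(f"inconsistent 2x2 table: k={k}, N={N}, K={K}, n={n}")
    return float(min(max(stats.hypergeom.sf(k - 1, N, K, n), 0.0), 1.0))


def _dedupe(genes: Sequence[str], what: str) -> list[str]:
    seen: dict[str, None] = {}
    dups = 0
    for g in genes:
        if g in seen:
            dups += 1
        else:
            seen[g] = None
    if dups:
        logger.warning("%d duplicate entries dropped from %s", dups, what)
    return list(seen)


def enrich(
    query: Sequence[str],
    sets: Sequence[GeneSet],
    universe: Sequence[str],
    alpha: float = 0.05,
    adjust: str | None = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    For a universe of ``N`` genes, a set with ``K`` members in the
    universe and a query of ``n`` genes overlapping the set in ``k``,
    the p-value is ``P(X ≥ k)`` with ``X ~ Hypergeom(N, K, n)``. Set
    members absent from the universe are dropped (logged); duplicate query
    entries are dropped with a warning. Results are sorted by p-value,
    ties broken by set id. ``adjust="bh"`` adds a BH-adjusted column and
    thresholds ``enriched`` on it.
    """
    if not (0 < alpha < 1):
        raise ValidationError("alpha must be in (0, 1)")
    universe_list = _dedupe(universe, "universe")
    if len(universe_list) == 0:
        raise ValidationError("empty universe")
    query_list = _dedupe(query, "query")
    if len(query_list) == 0:
        raise ValidationError("empty query gene list")
    uni = set(universe_list)
    outside = [g for g in query_list if g not in uni]
    if outside:
        raise ValidationError(
            f"{len(outside)} query genes not in the universe (e.g. {outside[:3]})"
        )
    qset = set(query_list)

    rows = []
    for gs in sets:
        members_in_uni = [g for g in set(gs.members) if g in uni]
        dropped = len(set(gs.members)) - len(members_in_uni)
        if dropped:
            logger.info("set %s: %d members outside the universe dropped", gs.set_id, dropped)
        K = len(members_in_uni)
        k = len(qset.intersection(members_in_uni))
        N, n = len(uni), len(qset)
        p = hypergeom_upper_tail(k, N, K, n) if K > 0 else 1.0
        rows.append(
            {"set_id": gs.set_id, "name": gs.name, "k_overlap": k, "n_query": n,
             "K_set": K, "N_universe": N, "p_value": p}
        )
    df = pd.DataFrame(rows).sort_values(["p_value", "set_id"], ignore_index=True)
    if adjust == "bh":
        df["p_adjusted"] = multipletests(df["p_value"], method="fdr_bh")[1]
        df["enriched"] = df["p_adjusted"] < alpha
    elif adjust is None:
        df["enriched"] = df["p_value"] < alpha
    else:
        raise ValidationError(f"unknown adjustment {adjust!r}")
    return df


def classify_pathways(
    results_by_treatment: Mapping[str, pd.DataFrame],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Venn-label each pathway by which treatments it is enriched under.

    ``results_by_treatment`` maps the treatments ``OPC, curcumin,
    combination`` to :func:`enrich` outputs over the same set collection.
    Labels follow the gene-level rule: significant under both single
    agents → ``common``; exactly one single agent → ``opc_only`` /
    ``curcumin_only``; combination but neither single →
    ``combination_only``; otherwise ``unclassified``. A per-label count
    summary accompanies the table via the ``attrs['label_counts']`` dict.
    """
    required = {"OPC", "curcumin", "combination"}
    if set(results_by_treatment) != required:
        raise ValidationError(f"need enrichment results for exactly {sorted(required)}")
    sig = {}
    ids_ref = None
    for treatment, df in results_by_treatment.items():
        ids = frozenset(df["set_id"])
        if ids_ref is None:
            ids_ref = ids
        elif ids != ids_ref:
            raise ValidationError("treatments were tested against different set collections")
        sig[treatment] = df.set_index("set_id")["p_value"] < alpha

    set_ids = sorted(ids_ref)
    opc = np.array([bool(sig["OPC"][s]) for s in set_ids])
    cur = np.array([bool(sig["curcumin"][s]) for s in set_ids])
    combo = np.array([bool(sig["combination"][s]) for s in set_ids])

    label = np.full(len(set_ids), "unclassified", dtype=object)
    label[combo & ~opc & ~cur] = "combination_only"
    label[opc & ~cur] = "opc_only"
    label[cur & ~opc] = "curcumin_only"
    label[opc & cur] = "common"

    out = pd.DataFrame(
        {
            "set_id": set_ids,
            "significant_OPC": opc,
            "significant_curcumin": cur,
            "significant_combination": combo,
            "label": label,
        }
    )
    out.attrs["label_counts"] = {
        lab: int((out["label"] == lab).sum()) for lab in PATHWAY_LABELS
    }
    return out


def cooperative_pathways(
    cooperative_gene_list: Sequence[str],
    sets: Sequence[GeneSet],
    universe: Sequence[str],
    alpha: float = 0.05,
    adjust: str | None = None,
) -> pd.DataFrame:
    """Enrichment of the cooperative-gene list (combination beats singles).

    Thin wrapper over :func:`enrich` for the gene list produced by
    :func:`coopsyn.de_meta.cooperative_genes`; an empty list is a
    validation error rather than an empty result.
    """
    if len(cooperative_gene_list) == 0:
        raise ValidationError("cooperative gene list is empty")
    return enrich(cooperative_gene_list, sets, universe, alpha=alpha, adjust=adjust)
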