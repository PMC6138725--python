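"""Recovery metrics against planted synthetic truth."""

from __future__ import annotations

import pandas as pd

from .errors import ValidationError
from .synthetic_data import PlantedTruth


def classification_metrics(labels: pd.DataFrame, truth: PlantedTruth) -> pd.DataFrame:
    """Per-class sensitivity and false-discovery rate of a Venn classification.

    ``labels`` is the output of :func:`coopsyn.de_meta.classify_genes`.
    Each planted class is mapped to the Venn label it should receive
    (e.g. the cooperative class to ``combination_only``); sensitivity is
    the fraction of genes expecting a label that received it, and FDR the
    fraction of genes receiving a label whose expectation differed.
    """
    if not {"gene", "label"} <= set(labels.columns):
        raise ValidationError("labels table needs 'gene' and 'label' columns")
    expected = truth.expected_venn_labels()
    merged = labels.set_index("gene").join(expected.rename("expected"), how="inner")
    if len(merged) != len(truth.table):
        raise ValidationError("classification does not cover the planted gene universe")

    rows = []
    for cls in sorted(expected.unique()):
        is_expected = merged["expected"] == cls
        is_predicted = merged["label"] == cls
        tp = int((is_expected & is_predicted).sum())
        rows.append(
            {
                "label": cls,
                "n_expected": int(is_expected.sum()),
                "n_predicted": int(is_predicted.sum()),
                "sensitivity": tp / max(int(is_expected.sum()), 1),
                "fdr": 1.0 - tp / max(int(is_predicted.sum()), 1) if is_predicted.any() else 0.0,
            }
        )
    return pd.DataFrame(rows)


def cooperative_recall(detected: list[str], truth: PlantedTruth) -> float:
    """Fraction of planted cooperative genes present in the detected list."""
    planted = set(truth.genes_in_class("cooperative"))
    if not planted:
        raise ValidationError("truth contains no cooperative genes")
    return len(planted.intersection(detected)) / len(planted)
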