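"""End-to-end orchestration: simulate → synergy → meta → enrichment → report.

A single :class:`RunConfig` drives every stage; all randomness derives
from one run seed via per-stage child seeds, so identical configs yield
byte-identical result tables. A ``manifest.json`` recording the config,
package version, per-stage row counts and timestamps is written on every
run, including failed ones.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, de_meta, enrichment, io, synergy, synthetic_data
from .errors import ValidationError
from .evaluation import classification_metrics, cooperative_recall

_STAGE_TAGS = {"dose_response": 1, "de_tables": 2, "gene_sets": 3, "bench": 4}


def stage_seed(run_seed: int, stage: str) -> int:
    """Deterministic child seed for a named pipeline stage (< 2**31)."""
    tag = _STAGE_TAGS[stage]
    return int(np.random.SeedSequence([run_seed, tag]).generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Configuration of one full pipeline run.

    Inputs may be paths to existing tables or ``None`` to synthesize them
    with the bundled generators. Analysis knobs mirror the individual
    module defaults: unadjusted α = 0.05 at gene and pathway level,
    unanimous homogeneity, ≥3 cell lines for the cooperative criterion.
    """

    out_dir: str | Path = "coopsyn_run"
    seed: int = 0
    # inputs (None → synthesize)
    dose_response_path: str | None = None
    de_records_path: str | None = None
    gmt_path: str | None = None
    # generator settings
    dose_response: dict = field(default_factory=dict)
    de: dict = field(default_factory=dict)
    synergy_factor: float = 1.3
    n_decoy_sets: int = 20
    set_size: int = 50
    # analysis settings
    alpha: float = 0.05
    gene_p_adjust: str | None = "holm"
    min_lines: int = 3
    homogeneity_rule: str = "all"
    min_agree_frac: float = 0.5
    ci_methods: tuple[str, ...] = ("hsa", "bliss")
    clamp_effects: bool = True
    require_line_significance: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = io.load_config_file(path)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if "ci_methods" in data:
            cfg.ci_methods = tuple(data["ci_methods"])
        return cfg

    def validate(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must be in (0, 1)")
        if self.min_lines < 1:
            raise ValidationError("min_lines must be >= 1")
        for m in self.ci_methods:
            if m not in synergy.CI_METHODS:
                raise ValidationError(f"unknown CI method {m!r}")
        for attr in ("dose_response_path", "de_records_path", "gmt_path"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise ValidationError(f"{attr} does not exist: {p}")
        # constructing the generator configs validates their parameters
        self._dr_config()
        self._de_config()

    def _dr_config(self) -> synthetic_data.DoseResponseConfig:
        kw = dict(self.dose_response)
        kw.setdefault("synergy_factor", self.synergy_factor)
        kw.setdefault("seed", stage_seed(self.seed, "dose_response"))
        return synthetic_data.DoseResponseConfig(**kw)

    def _de_config(self) -> synthetic_data.DEGenConfig:
        kw = dict(self.de)
        kw.setdefault("min_detect_lines", self.min_lines)
        kw.setdefault("seed", stage_seed(self.seed, "de_tables"))
        return synthetic_data.DEGenConfig(**kw)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_full(config: RunConfig) -> dict:
    """Execute every stage in dependency order; return the manifest dict.

    Result tables land in ``config.out_dir``. On a stage failure the
    manifest records the failing stage and the error, earlier outputs are
    left intact, and the exception propagates.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
        "status": "running",
    }

    def _write_manifest():
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=_jsonable)

    current_stage = "validate"
    try:
        config.validate()

        # ------------------------------------------------ simulate / load
        current_stage = "simulate"
        if config.dose_response_path is None:
            dr_obs, dr_truth = synthetic_data.generate_dose_response(config._dr_config())
            io.write_table(dr_obs, out / "dose_response.tsv")
            io.write_table(dr_truth, out / "dose_response_truth.tsv")
        else:
            dr_obs = io.read_table(config.dose_response_path)
        if config.de_records_path is None:
            records, truth = synthetic_data.generate_de_tables(config._de_config())
            io.write_table(records, out / "de_records.tsv")
            io.write_table(truth.table, out / "planted_truth.tsv")
        else:
            records = io.read_table(config.de_records_path)
            truth = None
        if config.gmt_path is None:
            if truth is None:
                raise ValidationError("a GMT path is required when DE records are supplied")
            sets = synthetic_data.generate_gene_sets(
                truth, n_decoy_sets=config.n_decoy_sets, set_size=config.set_size,
                seed=stage_seed(config.seed, "gene_sets"),
            )
            io.write_gmt(sets, out / "gene_sets.gmt")
        else:
            sets = io.read_gmt(config.gmt_path)
        manifest["stages"]["simulate"] = {
            "dose_response_rows": len(dr_obs), "de_rows": len(records), "gene_sets": len(sets),
        }

        # ------------------------------------------------ synergy
        current_stage = "synergy"
        ci_frames = [
            synergy.grid_ci(dr_obs, method=m, clamp=config.clamp_effects)
            for m in config.ci_methods
        ]
        ci_table = pd.concat(ci_frames, ignore_index=True)
        io.write_table(ci_table, out / "ci_results.tsv")
        manifest["stages"]["synergy"] = {
            "ci_rows": len(ci_table),
            "median_ci": {
                m: float(ci_table.loc[ci_table["method"] == m, "ci"].median())
                for m in config.ci_methods
            },
        }

        # ------------------------------------------------ meta-analysis
        current_stage = "meta"
        meta = de_meta.meta_analyze(
            records, homogeneity_rule=config.homogeneity_rule,
            min_agree_frac=config.min_agree_frac,
        )
        io.write_table(meta, out / "meta.tsv")
        labels = de_meta.classify_genes(meta, alpha=config.alpha, adjust=config.gene_p_adjust)
        io.write_table(labels, out / "gene_classification.tsv")
        coop_genes = de_meta.cooperative_genes(
            records, min_lines=config.min_lines, alpha=config.alpha,
            require_line_significance=config.require_line_significance,
        )
        io.write_gene_list(coop_genes, out / "cooperative_genes.txt")
        manifest["stages"]["meta"] = {
            "meta_rows": len(meta),
            "label_counts": labels["label"].value_counts().to_dict(),
            "cooperative_genes": len(coop_genes),
        }

        # ------------------------------------------------ enrichment
        current_stage = "enrichment"
        universe = sorted(records["gene"].unique())
        regulated = labels.set_index("gene")["label"]
        queries = {
            "OPC": sorted(regulated.index[regulated.isin(["common", "opc_only"])]),
            "curcumin": sorted(regulated.index[regulated.isin(["common", "curcumin_only"])]),
            "combination": sorted(
                regulated.index[regulated.isin(["common", "combination_only"])]
            ),
        }
        results_by_treatment = {}
        for treatment, query in queries.items():
            res = enrichment.enrich(query, sets, universe, alpha=config.alpha)
            results_by_treatment[treatment] = res
            io.write_table(res, out / f"enrichment_{treatment}.tsv")
        venn = enrichment.classify_pathways(results_by_treatment, alpha=config.alpha)
        io.write_table(venn, out / "pathway_venn.tsv")
        coop_enrich = (
            enrichment.cooperative_pathways(coop_genes, sets, universe, alpha=config.alpha)
            if coop_genes
            else None
        )
        if coop_enrich is not None:
            io.write_table(coop_enrich, out / "cooperative_pathway_enrichment.tsv")
        manifest["stages"]["enrichment"] = {
            "pathway_label_counts": venn.attrs["label_counts"],
            "cooperative_pathways_tested": 0 if coop_enrich is None else len(coop_enrich),
        }

        # ------------------------------------------------ report
        current_stage = "report"
        summary = {
            "median_ci": manifest["stages"]["synergy"]["median_ci"],
            "gene_label_counts": manifest["stages"]["meta"]["label_counts"],
            "n_cooperative_genes": len(coop_genes),
            "pathway_label_counts": venn.attrs["label_counts"],
        }
        if truth is not None:
            metrics = classification_metrics(labels, truth)
            io.write_table(metrics, out / "classification_metrics.tsv")
            summary["classification"] = {
                row["label"]: {"sensitivity": row["sensitivity"], "fdr": row["fdr"]}
                for _, row in metrics.iterrows()
            }
            summary["cooperative_gene_recall"] = cooperative_recall(coop_genes, truth)
            coop_row = venn.loc[venn["set_id"] == "SET_COOPERATIVE"]
            if len(coop_row):
                summary["cooperative_pathway_label"] = coop_row["label"].iloc[0]
            if coop_enrich is not None:
                hit = coop_enrich.loc[coop_enrich["set_id"] == "SET_COOPERATIVE"]
                if len(hit):
                    summary["cooperative_pathway_p"] = float(hit["p_value"].iloc[0])
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=_jsonable)
        manifest["stages"]["report"] = {"summary": "summary.json"}
        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failed_stage"] = current_stage
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        raise
    finally:
        manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        _write_manifest()
    return manifest
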