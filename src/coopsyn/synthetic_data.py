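"""Synthetic inputs with known ground truth for the cooperativity pipeline.

Every generator is deterministic under a fixed seed and emulates the
statistical structure the downstream analysis assumes:

* dose-response viability surfaces for a two-agent combination experiment,
  built from Hill curves with an optional planted Bliss-synergy multiplier;
* per-cell-line, per-treatment differential-expression summary tables
  (log2 fold-change, p-value) with planted gene classes;
* GMT gene-set collections enriched for the planted classes;
* small qPCR Ct and caliper fixtures for the bench metrics.

Viability is expressed as a fraction of the vehicle control in [0, 1];
inhibition is 1 − viability. Single-agent truth follows the Hill form
``v(d) = 1 / (1 + (d / IC50)^h)`` and combination truth is the Bliss
independence prediction scaled by ``synergy_factor`` and clamped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

TREATMENTS = ("OPC", "curcumin", "combination")

#: Colorectal-cancer cell-line panel emulated by the DE generator.
CELL_LINES = ("SW480", "SW620", "HT29", "HCT116", "RKO", "LoVo")

#: Planted gene classes and the Venn label each is expected to receive.
GENE_CLASSES = ("common", "opc_only", "cur_only", "combo_only", "cooperative", "null")
EXPECTED_VENN_LABEL = {
    "common": "common",
    "opc_only": "opc_only",
    "cur_only": "curcumin_only",
    "combo_only": "combination_only",
    "cooperative": "combination_only",
    "null": "unclassified",
}

#: Cooperative-class combination effect, as a multiple of ``effect_log2fc``.
COOPERATIVE_BOOST = 1.5

# Default dose grids follow the proliferation-assay design: a coarse
# high-range grid for OPCs and a finer low-range grid for curcumin (ng/ul).
DEFAULT_DOSES_CUR = (0.01, 0.05, 0.1, 0.5, 1.0, 2.5, 5.0)
DEFAULT_DOSES_OPC = (10.0, 100.0, 500.0, 1000.0)


def se_for_power(effect: float, power: float = 0.8, alpha: float = 0.05) -> float:
    """Standard error giving the requested two-sided per-line power.

    Solves ``effect / se = z_{1-alpha/2} + z_{power}`` (the usual normal
    approximation, ignoring the negligible lower-tail rejection).
    """
    if not (0 < power < 1 and 0 < alpha < 1 and effect > 0):
        raise ValidationError("need effect > 0 and power, alpha in (0, 1)")
    return effect / (stats.norm.isf(alpha / 2) + stats.norm.ppf(power))


def _check_doses(doses: Sequence[float], label: str) -> tuple[float, ...]:
    arr = tuple(float(d) for d in doses)
    if len(arr) == 0:
        raise ValidationError(f"{label}: at least one dose required")
    if any(d < 0 for d in arr):
        raise ValidationError(f"{label}: doses must be non-negative")
    if any(b <= a for a, b in zip(arr, arr[1:])):
        raise ValidationError(f"{label}: doses must be strictly increasing")
    return arr


@dataclass(frozen=True)
class DoseResponseConfig:
    """Parameters of one synthetic two-agent viability experiment.

    Agent A plays the role of curcumin (low ng/ul range), agent B the role
    of OPCs (high ng/ul range). ``synergy_factor`` multiplies the Bliss
    inhibition prediction: 1 means exact Bliss independence, >1 plants
    cooperativity that the downstream CI should recover.
    """

    ic50_a: float = 0.5
    ic50_b: float = 200.0
    hill_a: float = 1.0
    hill_b: float = 1.0
    synergy_factor: float = 1.0
    noise_sd: float = 0.05
    doses_a: tuple[float, ...] = DEFAULT_DOSES_CUR
    doses_b: tuple[float, ...] = DEFAULT_DOSES_OPC
    n_replicates: int = 3
    seed: int = 0
    cell_line: str = "HCT116"

    def __post_init__(self):
        if self.ic50_a <= 0 or self.ic50_b <= 0:
            raise ValidationError("IC50 values must be positive")
        if self.hill_a <= 0 or self.hill_b <= 0:
            raise ValidationError("Hill slopes must be positive")
        if self.synergy_factor < 0:
            raise ValidationError("synergy_factor must be >= 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        object.__setattr__(self, "doses_a", _check_doses(self.doses_a, "doses_a"))
        object.__setattr__(self, "doses_b", _check_doses(self.doses_b, "doses_b"))


def hill_viability(dose: np.ndarray | float, ic50: float, hill: float) -> np.ndarray | float:
    """Fractional viability of a single agent, ``1 / (1 + (d/IC50)^h)``."""
    d = np.asarray(dose, dtype=float)
    return 1.0 / (1.0 + (d / ic50) ** hill)


def generate_dose_response(config: DoseResponseConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate an observed viability table and its noise-free truth surface.

    Returns ``(observed, truth)``. ``observed`` has one row per replicate
    with columns ``cell_line, dose_cur, dose_opc, replicate, viability``;
    ``truth`` has one row per dose pair with the noise-free viability. The
    grid contains the vehicle control (0, 0), every single-agent dose and
    the full combination product.
    """
    pairs = [(0.0, 0.0)]
    pairs += [(da, 0.0) for da in config.doses_a]
    pairs += [(0.0, db) for db in config.doses_b]
    pairs += [(da, db) for da in config.doses_a for db in config.doses_b]

    da = np.array([p[0] for p in pairs])
    db = np.array([p[1] for p in pairs])
    e_a = 1.0 - hill_viability(da, config.ic50_a, config.hill_a)
    e_b = 1.0 - hill_viability(db, config.ic50_b, config.hill_b)
    e_bliss = e_a + e_b - e_a * e_b
    e_true = np.where(
        (da > 0) & (db > 0),
        np.clip(config.synergy_factor * e_bliss, 0.0, 1.0),
        e_bliss,
    )
    v_true = 1.0 - e_true

    truth = pd.DataFrame(
        {
            "cell_line": config.cell_line,
            "dose_cur": da,
            "dose_opc": db,
            "viability": v_true,
        }
    )

    rng = np.random.default_rng(config.seed)
    rows = []
    for rep in range(1, config.n_replicates + 1):
        noise = rng.normal(0.0, config.noise_sd, size=len(pairs)) if config.noise_sd > 0 else 0.0
        rows.append(
            pd.DataFrame(
                {
                    "cell_line": config.cell_line,
                    "dose_cur": da,
                    "dose_opc": db,
                    "replicate": rep,
                    "viability": np.clip(v_true + noise, 0.0, 1.0),
                }
            )
        )
    observed = pd.concat(rows, ignore_index=True)
    return observed, truth


def generate_dri_pair(
    ic50: float,
    hill: float = 1.0,
    shift: float = 4.0,
    doses: Sequence[float] | None = None,
    noise_sd: float = 0.01,
    n_replicates: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single-agent and in-combination series with an exact potency shift.

    The combination series is the same Hill curve with its midpoint moved
    to ``ic50 / shift``, i.e. the partner lets the agent's dose be reduced
    ``shift``-fold at matched inhibition — the quantity the dose reduction
    index estimates. Returns ``(single, combo)`` tables with columns
    ``dose, replicate, viability``.
    """
    if ic50 <= 0 or hill <= 0 or shift <= 0:
        raise ValidationError("ic50, hill and shift must be positive")
    if doses is None:
        doses = tuple(ic50 * r for r in (0.02, 0.0625, 0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0))
    doses = _check_doses(doses, "doses")
    rng = np.random.default_rng(seed)

    def _series(mid: float) -> pd.DataFrame:
        d = np.array(doses)
        v = hill_viability(d, mid, hill)
        rows = []
        for rep in range(1, n_replicates + 1):
            noise = rng.normal(0.0, noise_sd, size=len(d)) if noise_sd > 0 else 0.0
            rows.append(
                pd.DataFrame({"dose": d, "replicate": rep, "viability": np.clip(v + noise, 0.0, 1.0)})
            )
        return pd.concat(rows, ignore_index=True)

    return _series(ic50), _series(ic50 / shift)


def _default_class_sizes(n_genes: int) -> dict[str, int]:
    sizes = {"common": 300, "opc_only": 150, "cur_only": 150, "combo_only": 150, "cooperative": 150}
    planted = sum(sizes.values())
    if planted > n_genes:
        # scale the planted classes down proportionally for tiny universes
        scale = n_genes / (2 * planted)
        sizes = {k: max(1, int(v * scale)) for k, v in sizes.items()}
        planted = sum(sizes.values())
    sizes["null"] = n_genes - planted
    return sizes


@dataclass(frozen=True)
class DEGenConfig:
    """Parameters of the synthetic differential-expression experiment.

    ``effect_log2fc`` is the planted per-line |log2 fold-change| of
    non-null genes; ``se_log2fc`` its per-line standard error. The default
    standard error is derived so a single cell line detects the planted
    effect with power ≈ 0.8 at α = 0.05.
    """

    n_genes: int = 5000
    n_cell_lines: int = 6
    class_sizes: Mapping[str, int] | None = None
    effect_log2fc: float = 1.5
    se_log2fc: float | None = None
    min_detect_lines: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        if not (1 <= self.n_cell_lines <= len(CELL_LINES)):
            raise ValidationError(f"n_cell_lines must be in [1, {len(CELL_LINES)}]")
        if self.effect_log2fc <= 0:
            raise ValidationError("effect_log2fc must be > 0")
        if self.se_log2fc is None:
            object.__setattr__(self, "se_log2fc", se_for_power(self.effect_log2fc))
        if self.se_log2fc <= 0:
            raise ValidationError("se_log2fc must be > 0")
        sizes = dict(self.class_sizes) if self.class_sizes is not None else _default_class_sizes(self.n_genes)
        unknown = set(sizes) - set(GENE_CLASSES)
        if unknown:
            raise ValidationError(f"unknown gene classes: {sorted(unknown)}")
        for cls in GENE_CLASSES:
            sizes.setdefault(cls, 0)
        if any(v < 0 for v in sizes.values()):
            raise ValidationError("class sizes must be non-negative")
        planted = sum(v for k, v in sizes.items() if k != "null")
        if planted + sizes["null"] > self.n_genes:
            raise ValidationError("class sizes exceed n_genes")
        # remaining genes are null
        sizes["null"] = self.n_genes - planted
        object.__setattr__(self, "class_sizes", sizes)

    @property
    def cell_lines(self) -> tuple[str, ...]:
        return CELL_LINES[: self.n_cell_lines]


@dataclass(frozen=True)
class PlantedTruth:
    """Ground-truth labels of a synthetic DE experiment.

    ``table`` has one row per gene with its class label and the true
    log2 fold-change under each treatment (shared across cell lines).
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        required = {"gene", "class_label", "true_opc", "true_cur", "true_combo"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"truth table missing columns: {sorted(missing)}")
        if self.table["gene"].duplicated().any():
            raise ValidationError("each gene must carry exactly one label")

    @property
    def genes(self) -> list[str]:
        return self.table["gene"].tolist()

    def genes_in_class(self, class_label: str) -> list[str]:
        if class_label not in GENE_CLASSES:
            raise ValidationError(f"unknown class {class_label!r}")
        return self.table.loc[self.table["class_label"] == class_label, "gene"].tolist()

    def expected_venn_labels(self) -> pd.Series:
        """Venn label each planted class should receive downstream."""
        return self.table.set_index("gene")["class_label"].map(EXPECTED_VENN_LABEL)


# true |log2FC| per treatment, as multiples of effect_log2fc
_CLASS_EFFECTS = {
    "common": (1.0, 1.0, 1.0),
    "opc_only": (1.0, 0.0, 0.0),
    "cur_only": (0.0, 1.0, 0.0),
    "combo_only": (0.0, 0.0, 1.0),
    "cooperative": (0.0, 0.0, COOPERATIVE_BOOST),
    "null": (0.0, 0.0, 0.0),
}


def generate_de_tables(config: DEGenConfig) -> tuple[pd.DataFrame, PlantedTruth]:
    """Generate long-format DE summaries with planted gene classes.

    Returns ``(records, truth)``. ``records`` has one row per
    gene × cell line × treatment with columns ``gene, cell_line,
    treatment, log2fc, p_value``; observed log2FC is the true value plus
    N(0, se) noise and the p-value is the two-sided normal test of
    ``log2fc / se``, mimicking the summary output of a count-level DE tool.
    """
    rng = np.random.default_rng(config.seed)
    width = len(str(config.n_genes))
    genes = np.array([f"G{i:0{width}d}" for i in range(1, config.n_genes + 1)])

    labels = np.concatenate(
        [np.repeat(cls, config.class_sizes[cls]) for cls in GENE_CLASSES]
    )
    # random sign per gene, shared across treatments and lines so regulation
    # is homogeneous by construction
    signs = rng.choice([-1.0, 1.0], size=config.n_genes)

    effect_matrix = np.array([_CLASS_EFFECTS[cls] for cls in labels])  # (genes, 3)
    true_fc = effect_matrix * config.effect_log2fc * signs[:, None]

    truth = PlantedTruth(
        pd.DataFrame(
            {
                "gene": genes,
                "class_label": labels,
                "true_opc": true_fc[:, 0],
                "true_cur": true_fc[:, 1],
                "true_combo": true_fc[:, 2],
            }
        )
    )

    se = config.se_log2fc
    frames = []
    for line in config.cell_lines:
        noise = rng.normal(0.0, se, size=(config.n_genes, 3))
        obs = true_fc + noise
        pvals = 2.0 * stats.norm.sf(np.abs(obs) / se)
        for t_idx, treatment in enumerate(TREATMENTS):
            frames.append(
                pd.DataFrame(
                    {
                        "gene": genes,
                        "cell_line": line,
                        "treatment": treatment,
                        "log2fc": obs[:, t_idx],
                        "p_value": np.clip(pvals[:, t_idx], np.nextafter(0, 1), 1.0),
                    }
                )
            )
    records = pd.concat(frames, ignore_index=True)
    return records, truth


def generate_gene_sets(
    truth: PlantedTruth,
    n_decoy_sets: int = 20,
    set_size: int = 50,
    purity: float = 0.9,
    seed: int = 0,
) -> list:
    """Build a gene-set collection enriched for the planted classes.

    One set per non-null planted class drawing ``purity`` of its members
    from that class (the rest at random from the whole universe), plus
    ``n_decoy_sets`` sets of uniformly random genes. Stands in for a
    curated pathway collection such as KEGG.
    """
    from .enrichment import GeneSet

    genes = np.array(truth.genes)
    if len(genes) == 0:
        raise ValidationError("truth must be non-empty")
    if set_size > len(genes):
        raise ValidationError("set_size exceeds the gene universe")
    if not (0 < purity <= 1):
        raise ValidationError("purity must be in (0, 1]")
    rng = np.random.default_rng(seed)

    sets = []
    for cls in GENE_CLASSES:
        if cls == "null":
            continue
        members_pool = np.array(truth.genes_in_class(cls))
        if len(members_pool) == 0:
            continue
        n_class = min(int(round(purity * set_size)), len(members_pool))
        chosen = list(rng.choice(members_pool, size=n_class, replace=False))
        filler_pool = genes[~np.isin(genes, chosen)]
        chosen += list(rng.choice(filler_pool, size=set_size - n_class, replace=False))
        sets.append(
            GeneSet(
                set_id=f"SET_{cls.upper()}",
                name=f"planted {cls} class set",
                members=tuple(sorted(chosen)),
            )
        )
    for i in range(1, n_decoy_sets + 1):
        members = rng.choice(genes, size=set_size, replace=False)
        sets.append(
            GeneSet(
                set_id=f"DECOY_{i:03d}",
                name="random decoy set",
                members=tuple(sorted(members)),
            )
        )
    return sets


def generate_bench_fixtures(seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, float]]:
    """Small qPCR Ct and xenograft caliper fixtures with known truth.

    Returns ``(ct_table, caliper_table, true_fold_changes)``. Ct rows carry
    ``sample, group, gene, ct`` with the reference gene ACTB; per-sample
    loading shifts move target and reference together so the planted
    fold-change is exact under ΔΔCt. Caliper rows carry
    ``animal, group, day, length, width`` in mm with length ≥ width.
    """
    rng = np.random.default_rng(seed)
    true_folds = {"HSPA5": 0.5, "SEC61B": 2.0, "G6PD": 0.25}
    ref_gene = "ACTB"
    base_ref = 18.0
    base_target = {"HSPA5": 24.0, "SEC61B": 26.0, "G6PD": 23.0}

    ct_rows = []
    for group in ("control", "treated"):
        for rep in range(1, 4):
            sample = f"{group}_{rep}"
            shift = rng.uniform(-1.0, 1.0)  # RNA-loading offset, cancels in ΔCt
            ct_rows.append({"sample": sample, "group": group, "gene": ref_gene, "ct": base_ref + shift})
            for gene, fold in true_folds.items():
                ct = base_target[gene] + shift
                if group == "treated":
                    ct -= np.log2(fold)
                ct_rows.append({"sample": sample, "group": group, "gene": gene, "ct": ct})
    ct_table = pd.DataFrame(ct_rows)
    assert ct_table["ct"].between(10, 35).all()

    caliper_rows = []
    growth = {"vehicle": 0.55, "combination": 0.18}  # mm/day in length
    for group, rate in growth.items():
        for animal in range(1, 6):
            start = rng.uniform(4.0, 6.0)
            ratio = rng.uniform(0.6, 0.95)
            for day in range(1, 16, 2):
                length = start + rate * day + rng.normal(0.0, 0.1)
                length = max(length, 1.0)
                width = max(min(length * ratio, length), 0.5)
                caliper_rows.append(
                    {
                        "animal": f"{group}_{animal}",
                        "group": group,
                        "day": day,
                        "length": round(length, 2),
                        "width": round(width, 2),
                    }
                )
    caliper_table = pd.DataFrame(caliper_rows)
    return ct_table, caliper_table, true_folds
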