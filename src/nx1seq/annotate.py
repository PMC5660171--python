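"""Marker-rule cell classification and side-comparison tables.

Cells are typed by positivity for small marker panels (e.g. CD3D for T cells,
CD68 for macrophages); cancer cells are further split by the
epithelial/mesenchymal marker screen into EA (epithelial markers only),
EA_EMT (mesenchymal only) and EA_intEMT (both).  ``side_table`` builds the
per-gene positive-cell comparison between two tissue sides (counts, integer
percentages and one-decimal fold ratios).

"Positive" means normalized tags >= positivity_threshold (default 1 tag);
the threshold is a single global config value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from nx1seq.matrix import DigitalExpressionMatrix

logger = logging.getLogger(__name__)

# EMT trichotomy labels.
EA = "EA"
EA_INT_EMT = "EA_intEMT"
EA_EMT = "EA_EMT"
EMT_NONE = "none"
UNASSIGNED_CLASS = "unassigned"

E_OVER_M = "E-over-M"
M_OVER_E = "M-over-E"

DEFAULT_EPITHELIAL = ("EPCAM", "CDH1")
DEFAULT_MESENCHYMAL = ("ACTA2", "VIM", "FN1", "ZEB1", "THY1", "CD44")


@dataclass(frozen=True)
class MarkerRule:
    """Positivity requirement for one class: any-of or all-of ``genes``."""

    genes: tuple[str, ...]
    mode: str = "any"

    def __post_init__(self) -> None:
        if not self.genes or any(not g for g in self.genes):
            raise ValueError("rule genes must be non-empty strings")
        if self.mode not in ("any", "all"):
            raise ValueError("mode must be 'any' or 'all'")


@dataclass
class MarkerRuleSet:
    """Classification config: threshold, ordered class rules, EMT partition.

    ``class_rules`` insertion order is the priority order; when a cell
    matches several rules the first wins and the conflict is logged.
    """

    class_rules: dict[str, MarkerRule]
    positivity_threshold: float = 1.0
    epithelial_genes: tuple[str, ...] = DEFAULT_EPITHELIAL
    mesenchymal_genes: tuple[str, ...] = DEFAULT_MESENCHYMAL

    def __post_init__(self) -> None:
        if not self.class_rules:
            raise ValueError("class_rules must not be empty")
        if set(self.epithelial_genes) & set(self.mesenchymal_genes):
            raise ValueError("epithelial and mesenchymal gene sets must be disjoint")
        if self.positivity_threshold < 0:
            raise ValueError("positivity_threshold must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MarkerRuleSet":
        cfg = yaml.safe_load(Path(path).read_text())
        rules = {
            name: MarkerRule(tuple(spec["genes"]), spec.get("mode", "any"))
            for name, spec in cfg["class_rules"].items()
        }
        return cls(
            class_rules=rules,
            positivity_threshold=float(cfg.get("positivity_threshold", 1.0)),
            epithelial_genes=tuple(cfg.get("epithelial_genes", DEFAULT_EPITHELIAL)),
            mesenchymal_genes=tuple(cfg.get("mesenchymal_genes", DEFAULT_MESENCHYMAL)),
        )

    def to_yaml(self, path: str | Path) -> None:
        cfg = {
            "positivity_threshold": self.positivity_threshold,
            "class_rules": {
                name: {"genes": list(r.genes), "mode": r.mode}
                for name, r in self.class_rules.items()
            },
            "epithelial_genes": list(self.epithelial_genes),
            "mesenchymal_genes": list(self.mesenchymal_genes),
        }
        Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


@dataclass
class CellAnnotation:
    """Per-barcode classification result."""

    barcode: str
    cell_class: str = UNASSIGNED_CLASS
    emt_class: str | None = None  # set only for cancer cells
    side: str = ""


def is_positive(value: float, threshold: float = 1.0) -> bool:
    """Positivity at a normalized-tag cutoff; the boundary is inclusive."""
    if value < 0:
        raise ValueError("expression value must be >= 0")
    return value >= threshold


def _positive_frame(matrix: DigitalExpressionMatrix, genes, threshold: float) -> pd.DataFrame:
    """Boolean barcode x gene positivity; missing genes warn, all-negative."""
    present = [g for g in genes if g in matrix.data.columns]
    missing = [g for g in genes if g not in matrix.data.columns]
    if missing:
        logger.warning("marker genes absent from matrix (treated as negative): %s", missing)
    pos = pd.DataFrame(False, index=matrix.data.index, columns=list(genes))
    if present:
        pos[present] = matrix.data[present] >= threshold
    return pos


def classify_cells(matrix: DigitalExpressionMatrix, rules: MarkerRuleSet,
                   side: str | None = None) -> list[CellAnnotation]:
    """Assign each barcode the first matching class in rule-priority order."""
    if not rules.class_rules:
        raise ValueError("empty rule set")
    all_genes = sorted({g for r in rules.class_rules.values() for g in r.genes})
    pos = _positive_frame(matrix, all_genes, rules.positivity_threshold)
    side_label = side if side is not None else matrix.sample_label
    annotations = []
    for bc in matrix.barcodes:
        row = pos.loc[bc]
        matches = []
        for name, rule in rules.class_rules.items():
            hit = row[list(rule.genes)]
            if (hit.any() if rule.mode == "any" else hit.all()):
                matches.append(name)
        if len(matches) > 1:
            logger.info("barcode %s matches classes %s; keeping %s",
                        bc, matches, matches[0])
        cls = matches[0] if matches else UNASSIGNED_CLASS
        annotations.append(CellAnnotation(barcode=bc, cell_class=cls, side=side_label))
    return annotations


def classify_emt(annotations: list[CellAnnotation], matrix: DigitalExpressionMatrix,
                 rules: MarkerRuleSet,
                 cancer_classes: tuple[str, ...] = ("cancer",)) -> list[CellAnnotation]:
    """Attach the EMT trichotomy to cancer cells.

    >=1 epithelial & 0 mesenchymal -> EA; >=1 mesenchymal & 0 epithelial ->
    EA_EMT; >=1 of each -> EA_intEMT; neither -> none.  Non-cancer cells keep
    emt_class None; the four labels partition the cancer cells exhaustively.
    """
    if not rules.epithelial_genes or not rules.mesenchymal_genes:
        raise ValueError("epithelial and mesenchymal gene sets must be non-empty")
    epi = _positive_frame(matrix, rules.epithelial_genes, rules.positivity_threshold).any(axis=1)
    mes = _positive_frame(matrix, rules.mesenchymal_genes, rules.positivity_threshold).any(axis=1)
    out = []
    for ann in annotations:
        emt = None
        if ann.cell_class in cancer_classes and ann.barcode in matrix.data.index:
            e, m = bool(epi[ann.barcode]), bool(mes[ann.barcode])
            emt = EA_INT_EMT if (e and m) else EA if e else EA_EMT if m else EMT_NONE
        out.append(CellAnnotation(ann.barcode, ann.cell_class, emt, ann.side))
    return out


def annotations_to_frame(annotations: list[CellAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "barcode": [a.barcode for a in annotations],
            "cell_class": [a.cell_class for a in annotations],
            "emt_class": [a.emt_class for a in annotations],
            "side": [a.side for a in annotations],
        }
    ).set_index("barcode")


# ---------------------------------------------------------------------------
# side-comparison table
# ---------------------------------------------------------------------------


def _round_half_up(x: float, decimals: int = 0) -> float:
    scale = 10 ** decimals
    return math.floor(x * scale + 0.5) / scale


def fold_ratio(count_e: int, total_e: int, count_m: int, total_m: int,
               direction: str = E_OVER_M) -> float:
    """One-decimal fold between side positive-cell proportions.

    NaN when the denominator side has zero positive cells (undefined).
    """
    if total_e <= 0 or total_m <= 0:
        raise ValueError("side totals must be positive")
    pe, pm = count_e / total_e, count_m / total_m
    if direction == E_OVER_M:
        num, den = pe, pm
    elif direction == M_OVER_E:
        num, den = pm, pe
    else:
        raise ValueError(f"unknown direction {direction!r}")
    if den == 0:
        return float("nan")
    return _round_half_up(num / den, 1)


def percent(count: int, total: int) -> int:
    """Integer percent, half rounded up."""
    if total <= 0:
        raise ValueError("total must be positive")
    return int(_round_half_up(100.0 * count / total))


def side_table_from_counts(rows: pd.DataFrame, total_e: int, total_m: int,
                           direction: str = E_OVER_M) -> pd.DataFrame:
    """Build the side table from pre-counted positives.

    ``rows`` is indexed by gene with columns count_E and count_M; direction
    may be a single value or a per-gene column in ``rows``.
    """
    out = rows[["count_E", "count_M"]].copy()
    out["total_E"], out["total_M"] = total_e, total_m
    out["pct_E"] = [percent(c, total_e) for c in out["count_E"]]
    out["pct_M"] = [percent(c, total_m) for c in out["count_M"]]
    directions = rows["direction"] if "direction" in rows.columns else pd.Series(direction, index=rows.index)
    out["direction"] = directions
    out["fold"] = [
        fold_ratio(ce, total_e, cm, total_m, d)
        for ce, cm, d in zip(out["count_E"], out["count_M"], directions)
    ]
    return out


def side_table(matrix_e: DigitalExpressionMatrix, matrix_m: DigitalExpressionMatrix,
               genes, threshold: float = 1.0, direction: str = E_OVER_M) -> pd.DataFrame:
    """Per-gene positive-cell comparison between two comparison populations.

    Both matrices should already be restricted to the population being
    compared (e.g. estimated cancer cells).
    """
    if matrix_e.n_cells == 0 or matrix_m.n_cells == 0:
        raise ValueError("both sides must contain at least one cell")
    pos_e = _positive_frame(matrix_e, genes, threshold).sum(axis=0)
    pos_m = _positive_frame(matrix_m, genes, threshold).sum(axis=0)
    rows = pd.DataFrame({"count_E": pos_e.astype(int), "count_M": pos_m.astype(int)})
    rows.index.name = "gene"
    return side_table_from_counts(rows, matrix_e.n_cells, matrix_m.n_cells, direction)


def chemokine_positive_counts(matrix: DigitalExpressionMatrix, genes,
                              annotations: list[CellAnnotation],
                              threshold: float = 1.0) -> pd.DataFrame:
    """Positive-cell counts per (gene, cell class, side)."""
    ann = annotations_to_frame(annotations)
    common = matrix.data.index.intersection(ann.index)
    pos = _positive_frame(matrix, genes, threshold).loc[common]
    ann = ann.loc[common]
    records = []
    for (cls, side), idx in ann.groupby(["cell_class", "side"], sort=True).groups.items():
        for g in genes:
            records.append(
                {"gene": g, "cell_class": cls, "side": side,
                 "positive_cells": int(pos.loc[idx, g].sum())}
            )
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def cluster_cells(matrix: DigitalExpressionMatrix, metric: str = "euclidean",
                  method: str = "average", n_clusters: int | None = None):
    """Deterministic hierarchical clustering on log-transformed counts.

    Returns ``(linkage, labels, params)``; ``labels`` is None unless
    ``n_clusters`` is given.  Cells are clustered on log2(1 + value).
    """
    if matrix.n_cells < 2:
        raise ValueError("clustering requires at least 2 cells")
    logged = np.log2(1.0 + matrix.data.to_numpy(dtype=float))
    dist = pdist(logged, metric=metric)
    linkage = hierarchy.linkage(dist, method=method)
    labels = None
    if n_clusters is not None:
        labels = hierarchy.fcluster(linkage, t=n_clusters, criterion="maxclust")
    params = {"metric": metric, "method": method, "transform": "log2(1+x)",
              "n_clusters": n_clusters}
    return linkage, labels, params
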