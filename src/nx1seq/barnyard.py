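"""Species-mixing (barnyard) analysis.

Mixing cells of two species and counting, per cell barcode, the transcripts
mapping to each species validates single-cell partitioning: a barcode with
reads from both species indicates a multiplet (or barcode sharing).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from nx1seq.matrix import DigitalExpressionMatrix

CALL_MIXED = "mixed"


@dataclass
class SpeciesCall:
    """Per-barcode species read totals and (optional) species call."""

    barcode: str
    species_a: str
    species_b: str
    reads_a: int
    reads_b: int
    call: str | None = None

    @property
    def total(self) -> int:
        return self.reads_a + self.reads_b

    @property
    def purity(self) -> float | None:
        """max(a, b) / (a + b); None (undefined) for zero-read barcodes."""
        if self.total == 0:
            return None
        return max(self.reads_a, self.reads_b) / self.total


def species_of_gene_by_prefix(genes, sep: str = "_") -> dict[str, str]:
    """Derive a gene->species map from species-prefixed gene ids."""
    return {g: g.split(sep, 1)[0] for g in genes}


def species_counts(
    matrix: DigitalExpressionMatrix,
    species_of_gene: dict[str, str],
    species_pair: tuple[str, str] | None = None,
) -> list[SpeciesCall]:
    """Per-barcode read totals for each of the two species (calls unset)."""
    missing = [g for g in matrix.genes if g not in species_of_gene]
    if missing:
        raise KeyError(f"genes with no species mapping: {missing}")
    if species_pair is None:
        found = sorted(set(species_of_gene[g] for g in matrix.genes))
        if len(found) > 2:
            raise ValueError(f"more than two species present: {found}")
        while len(found) < 2:
            found.append(f"species{len(found)}")
        species_pair = (found[0], found[1])
    sp_a, sp_b = species_pair
    genes_a = [g for g in matrix.genes if species_of_gene[g] == sp_a]
    genes_b = [g for g in matrix.genes if species_of_gene[g] == sp_b]
    tot_a = matrix.data[genes_a].sum(axis=1) if genes_a else pd.Series(0, index=matrix.data.index)
    tot_b = matrix.data[genes_b].sum(axis=1) if genes_b else pd.Series(0, index=matrix.data.index)
    return [
        SpeciesCall(bc, sp_a, sp_b, int(tot_a[bc]), int(tot_b[bc]))
        for bc in matrix.barcodes
    ]


def classify_species(calls: list[SpeciesCall], purity_threshold: float = 0.9) -> list[SpeciesCall]:
    """Call each barcode A, B or mixed at the given purity threshold.

    A barcode is called single-species when that species holds at least
    ``purity_threshold`` of its reads; zero-read barcodes are called mixed
    with undefined purity and should be reported separately.
    """
    if not 0.5 < purity_threshold <= 1.0:
        raise ValueError("purity_threshold must be in (0.5, 1]")
    out = []
    for c in calls:
        if c.total == 0:
            call = CALL_MIXED
        elif c.reads_a / c.total >= purity_threshold:
            call = c.species_a
        elif c.reads_b / c.total >= purity_threshold:
            call = c.species_b
        else:
            call = CALL_MIXED
        out.append(SpeciesCall(c.barcode, c.species_a, c.species_b,
                               c.reads_a, c.reads_b, call=call))
    return out


def calls_to_frame(calls: list[SpeciesCall]) -> pd.DataFrame:
    """Scatter-ready table: per-barcode species reads, purity and call."""
    return pd.DataFrame(
        {
            "barcode": [c.barcode for c in calls],
            "reads_a": [c.reads_a for c in calls],
            "reads_b": [c.reads_b for c in calls],
            "purity": [c.purity for c in calls],
            "call": [c.call for c in calls],
        }
    ).set_index("barcode")


def write_calls_tsv(calls: list[SpeciesCall], path: str | Path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t")
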