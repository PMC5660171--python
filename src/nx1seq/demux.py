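"""Core pipeline: barcode extraction, gene assignment, counting, QC,
normalization.

The chemistry has no UMIs: a count is a read ("tag").  QC keeps barcodes with
*more than* ``min_reads`` reads and *more than* ``min_genes`` detected genes
(strict inequalities), then per-cell totals are rescaled to a fixed tag
count (300,000 by default).
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import pysam

from nx1seq.matrix import DigitalExpressionMatrix, NormalizedMatrixError
from nx1seq.synthetic import ToyTranscriptome

UNASSIGNED = "unassigned"

# Barcode rejection reasons.
REJECT_TOO_SHORT = "too-short"
REJECT_AMBIGUOUS_BASE = "ambiguous-base"
REJECT_NO_MATCH = "no-match"
REJECT_AMBIGUOUS_CORRECTION = "ambiguous-correction"


@dataclass(frozen=True)
class QcThresholds:
    """Cell-calling thresholds; both applied with strict 'more than'."""

    min_reads: int = 20_000
    min_genes: int = 400

    def __post_init__(self) -> None:
        if self.min_reads < 0 or self.min_genes < 0:
            raise ValueError("QC thresholds must be >= 0")


# ---------------------------------------------------------------------------
# barcode extraction
# ---------------------------------------------------------------------------


def extract_barcode(
    read1: str,
    barcode_len: int = 12,
    whitelist: frozenset[str] | set[str] | None = None,
    max_mismatch: int = 0,
) -> tuple[str | None, str | None]:
    """Extract (and optionally error-correct) the cell barcode from read 1.

    Returns ``(barcode, None)`` on success or ``(None, reason)`` on rejection.
    With ``max_mismatch=1`` an observed barcode is rescued iff exactly one
    whitelist entry lies within Hamming distance 1.
    """
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    if len(read1) < barcode_len:
        return None, REJECT_TOO_SHORT
    bc = read1[:barcode_len].upper()
    if not set(bc) <= set("ACGT"):
        return None, REJECT_AMBIGUOUS_BASE
    if whitelist is None:
        return bc, None
    if bc in whitelist:
        return bc, None
    if max_mismatch == 0:
        return None, REJECT_NO_MATCH
    hits = set()
    for i, orig in enumerate(bc):
        for base in "ACGT":
            if base != orig:
                cand = bc[:i] + base + bc[i + 1:]
                if cand in whitelist:
                    hits.add(cand)
    if len(hits) == 1:
        return next(iter(hits)), None
    if not hits:
        return None, REJECT_NO_MATCH
    return None, REJECT_AMBIGUOUS_CORRECTION


# ---------------------------------------------------------------------------
# gene assignment
# ---------------------------------------------------------------------------


class TranscriptIndex:
    """Toy aligner: assign a read to the unique transcript containing it as an
    exact substring; hits in more than one gene are ambiguous."""

    def __init__(self, transcriptome: ToyTranscriptome, k: int = 25) -> None:
        self.k = k
        self._seqs = transcriptome.sequences
        self._kmer_genes: dict[str, set[str]] = {}
        for gene, seq in self._seqs.items():
            for i in range(len(seq) - k + 1):
                self._kmer_genes.setdefault(seq[i:i + k], set()).add(gene)

    def assign(self, read2: str) -> str:
        read2 = read2.upper()
        if len(read2) >= self.k:
            candidates = self._kmer_genes.get(read2[: self.k])
            if not candidates:
                return UNASSIGNED
        else:
            candidates = set(self._seqs)
        hits = [g for g in candidates if read2 in self._seqs[g]]
        return hits[0] if len(hits) == 1 else UNASSIGNED


def gene_assignments_from_sam(sam_path: str | Path) -> dict[str, str]:
    """Gene per read name from a text SAM of read-2 alignments.

    Primary mapped records vote with their reference name; a read whose
    mapped records (including secondaries) span more than one reference is
    ambiguous and reported as unassigned.  Reference names are taken as gene
    ids (transcript-per-gene references).
    """
    refs_by_read: dict[str, set[str]] = {}
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_supplementary:
                continue
            refs_by_read.setdefault(rec.query_name, set()).add(rec.reference_name)
    return {
        name: (next(iter(refs)) if len(refs) == 1 else UNASSIGNED)
        for name, refs in refs_by_read.items()
    }


# ---------------------------------------------------------------------------
# counting / QC / normalization
# ---------------------------------------------------------------------------


def count_matrix(assignments: Iterable[tuple[str, str]],
                 sample_label: str = "") -> DigitalExpressionMatrix:
    """Tally (barcode, gene) pairs into a dense integer matrix.

    Barcodes and genes are emitted in sorted order so identical inputs give
    byte-identical outputs.
    """
    tally: Counter[tuple[str, str]] = Counter(assignments)
    barcodes = sorted({b for b, _ in tally})
    genes = sorted({g for _, g in tally})
    mat = np.zeros((len(barcodes), len(genes)), dtype=np.int64)
    b_idx = {b: i for i, b in enumerate(barcodes)}
    g_idx = {g: i for i, g in enumerate(genes)}
    for (b, g), n in tally.items():
        mat[b_idx[b], g_idx[g]] = n
    df = pd.DataFrame(mat, index=pd.Index(barcodes, name="barcode"), columns=genes)
    return DigitalExpressionMatrix(df, sample_label=sample_label)


def call_cells(matrix: DigitalExpressionMatrix,
               thresholds: QcThresholds = QcThresholds()) -> DigitalExpressionMatrix:
    """Keep barcodes with > min_reads total reads AND > min_genes detected genes."""
    if matrix.normalized_total is not None:
        raise NormalizedMatrixError("call_cells requires a raw (unnormalized) matrix")
    reads = matrix.reads_per_cell()
    genes = matrix.genes_per_cell()
    keep = matrix.data.index[(reads > thresholds.min_reads) & (genes > thresholds.min_genes)]
    return DigitalExpressionMatrix(matrix.data.loc[keep].copy(),
                                   sample_label=matrix.sample_label)


def select_top_barcodes(matrix: DigitalExpressionMatrix, n: int) -> DigitalExpressionMatrix:
    """Whitelist-free cell selection: keep the n barcodes with most reads.

    Ties at the boundary are broken lexicographically for determinism.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    order = matrix.reads_per_cell().sort_values(
        ascending=False, kind="mergesort"
    )
    keep = sorted(order.index[:n])
    return matrix.subset_barcodes(keep)


def knee_threshold(matrix: DigitalExpressionMatrix) -> int:
    """Read-count threshold at the knee of the barcode-rank curve.

    The knee is the rank with the steepest drop in log10 reads over the
    rank-sorted barcodes; barcodes at or above the returned read count pass.
    """
    reads = np.sort(matrix.reads_per_cell().to_numpy())[::-1]
    reads = reads[reads > 0]
    if reads.size < 2:
        return int(reads[0]) if reads.size else 0
    drops = np.diff(np.log10(reads.astype(float)))
    knee = int(np.argmin(drops))  # most negative step
    return int(reads[knee])


def normalize_tags(matrix: DigitalExpressionMatrix,
                   total: float = 300_000) -> DigitalExpressionMatrix:
    """Scale every cell's counts so the row sums to ``total`` tags (fractional)."""
    if total <= 0:
        raise ValueError("total must be > 0")
    sums = matrix.data.sum(axis=1)
    zero = sums.index[sums == 0]
    if len(zero):
        raise ValueError(f"cannot normalize zero-total barcode(s): {list(zero)}")
    scaled = matrix.data.astype(float).mul(total / sums, axis=0)
    return DigitalExpressionMatrix(scaled, sample_label=matrix.sample_label,
                                   normalized_total=float(total))


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------


def _fastq_pairs(read1_path: str | Path, read2_path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (read name, read1 sequence, read2 sequence); mates must be in step."""

    def _open(path):
        path = str(path)
        return gzip.open(path, "rt") if path.endswith(".gz") else open(path)

    with _open(read1_path) as f1, _open(read2_path) as f2:
        while True:
            h1 = f1.readline()
            if not h1:
                break
            s1 = f1.readline().strip()
            f1.readline(); f1.readline()
            h2 = f2.readline()
            s2 = f2.readline().strip()
            f2.readline(); f2.readline()
            n1 = h1.strip().split()[0].lstrip("@")
            n2 = h2.strip().split()[0].lstrip("@")
            if n1 != n2:
                raise ValueError(f"unpaired FASTQ records: {n1!r} vs {n2!r}")
            yield n1, s1, s2


def demultiplex(
    read1_path: str | Path,
    read2_path: str | Path,
    reference: ToyTranscriptome | TranscriptIndex | None = None,
    sam_path: str | Path | None = None,
    whitelist: Iterable[str] | None = None,
    barcode_len: int = 12,
    max_mismatch: int = 0,
) -> tuple[list[tuple[str, str]], dict]:
    """Pair read-1 barcodes with read-2 gene assignments.

    Returns the accepted (barcode, gene) assignment list plus a read
    conservation report: assigned + unassigned + rejected = total pairs.
    """
    if (reference is None) == (sam_path is None):
        raise ValueError("provide exactly one of reference / sam_path")
    index = None
    if reference is not None:
        index = reference if isinstance(reference, TranscriptIndex) else TranscriptIndex(reference)
    sam_genes = gene_assignments_from_sam(sam_path) if sam_path is not None else None
    wl = frozenset(whitelist) if whitelist is not None else None

    assignments: list[tuple[str, str]] = []
    rejected: Counter[str] = Counter()
    n_total = n_unassigned = 0
    for name, r1, r2 in _fastq_pairs(read1_path, read2_path):
        n_total += 1
        bc, reason = extract_barcode(r1, barcode_len, wl, max_mismatch)
        if bc is None:
            rejected[reason] += 1
            continue
        gene = index.assign(r2) if index is not None else sam_genes.get(name, UNASSIGNED)
        if gene == UNASSIGNED:
            n_unassigned += 1
            continue
        assignments.append((bc, gene))
    report = {
        "total_pairs": n_total,
        "assigned": len(assignments),
        "unassigned": n_unassigned,
        "rejected": dict(sorted(rejected.items())),
        "rejected_total": sum(rejected.values()),
    }
    return assignments, report


def run_pipeline(
    read1_path: str | Path,
    read2_path: str | Path,
    reference: ToyTranscriptome | TranscriptIndex | None = None,
    sam_path: str | Path | None = None,
    whitelist: Iterable[str] | None = None,
    barcode_len: int = 12,
    max_mismatch: int = 0,
    thresholds: QcThresholds | None = None,
    top_cells: int | None = None,
    normalize_total: float | None = None,
    sample_label: str = "",
) -> tuple[DigitalExpressionMatrix, dict]:
    """FASTQ pair -> demultiplex -> count -> (QC) -> (top-N) -> (normalize)."""
    assignments, report = demultiplex(
        read1_path, read2_path, reference=reference, sam_path=sam_path,
        whitelist=whitelist, barcode_len=barcode_len, max_mismatch=max_mismatch,
    )
    matrix = count_matrix(assignments, sample_label=sample_label)
    report["barcodes_before_qc"] = matrix.n_cells
    if thresholds is not None:
        matrix = call_cells(matrix, thresholds)
    if top_cells is not None:
        matrix = select_top_barcodes(matrix, top_cells)
    report["barcodes_after_qc"] = matrix.n_cells
    report["order"] = "demux -> count -> qc -> normalize"
    if normalize_total is not None:
        matrix = normalize_tags(matrix, normalize_total)
        report["normalized_total"] = float(normalize_total)
    return matrix, report
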