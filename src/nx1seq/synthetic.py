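"""Synthetic data with known ground truth: toy transcriptomes, cell
populations and paired FASTQ in the bead-barcode read layout.

Read 1 carries the 12-nt cell barcode at offset 0 followed by a fixed
downstream primer sequence; read 2 is a fragment of the captured mRNA with a
3' positional bias (oligo-dT capture).  Counts are fragments, not UMIs.

The generators are first-class package code: every pipeline, barnyard and
classification test measures recovery of the ground truth they emit.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from nx1seq.beads import DEFAULT_ANCHOR_3P

_BASES = np.array(list("ACGT"))

#: Read-1 content after the barcode (the primer region of the capture oligo).
DEFAULT_READ1_ANCHOR = DEFAULT_ANCHOR_3P[:31]


# ---------------------------------------------------------------------------
# toy transcriptome
# ---------------------------------------------------------------------------


@dataclass
class ToyTranscriptome:
    """A small reference of (gene id, transcript sequence) records.

    Gene ids carry a species prefix (``human_...``, ``mouse_...``) mirroring a
    combined two-species reference used for species-mixing runs.
    """

    records: list[tuple[str, str]]
    species_of_gene: dict[str, str]

    def __post_init__(self) -> None:
        ids = [g for g, _ in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate gene ids in transcriptome")
        for g, seq in self.records:
            if not seq or not set(seq) <= set("ACGT"):
                raise ValueError(f"transcript {g} empty or non-ACGT")

    @property
    def genes(self) -> list[str]:
        return [g for g, _ in self.records]

    @property
    def sequences(self) -> dict[str, str]:
        return dict(self.records)

    def write_fasta(self, path: str | Path) -> None:
        recs = [SeqRecord(Seq(seq), id=g, description="") for g, seq in self.records]
        SeqIO.write(recs, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path: str | Path,
                   species_of_gene: dict[str, str] | None = None) -> "ToyTranscriptome":
        records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
        if species_of_gene is None:
            species_of_gene = {g: g.split("_", 1)[0] for g, _ in records}
        return cls(records, species_of_gene)


def _shares_kmer(seq: str, kmers: set[str], k: int) -> bool:
    return any(seq[i:i + k] in kmers for i in range(len(seq) - k + 1))


def make_toy_transcriptome(
    n_genes_per_species: int,
    length_range: tuple[int, int] = (400, 600),
    species: tuple[str, ...] = ("human", "mouse"),
    seed: int | None = 0,
    gene_names: dict[str, list[str]] | None = None,
    min_unique_kmer: int = 25,
) -> ToyTranscriptome:
    """Random transcripts with no 25-mer shared between any two genes.

    The uniqueness guarantee makes exact-substring read assignment collision
    free for reads of >= ``min_unique_kmer`` nt; offending sequences are
    simply re-drawn.
    """
    if n_genes_per_species < 1:
        raise ValueError("n_genes_per_species must be >= 1")
    lo, hi = length_range
    if lo < min_unique_kmer or hi < lo:
        raise ValueError("invalid length_range")
    rng = np.random.default_rng(seed)
    records: list[tuple[str, str]] = []
    species_of: dict[str, str] = {}
    seen_kmers: set[str] = set()
    for sp in species:
        names = (gene_names or {}).get(sp) or [f"g{i:04d}" for i in range(n_genes_per_species)]
        if len(names) != n_genes_per_species:
            raise ValueError(f"gene_names[{sp!r}] must have {n_genes_per_species} entries")
        for name in names:
            gene = f"{sp}_{name}"
            while True:
                length = int(rng.integers(lo, hi + 1))
                seq = "".join(_BASES[rng.integers(0, 4, size=length)])
                if not _shares_kmer(seq, seen_kmers, min_unique_kmer):
                    break
            seen_kmers.update(
                seq[i:i + min_unique_kmer] for i in range(len(seq) - min_unique_kmer + 1)
            )
            records.append((gene, seq))
            species_of[gene] = sp
    return ToyTranscriptome(records, species_of)


# ---------------------------------------------------------------------------
# ground-truth cell populations
# ---------------------------------------------------------------------------


@dataclass
class ClassProfile:
    """Expression program of one cell class.

    ``marker_fractions`` maps marker genes to the probability that a cell of
    this class is positive for the gene; positive cells receive
    1 + Poisson(marker_mean - 1) fragments, negative cells exactly 0 — so the
    simulated positive fraction equals the specified one.  All other genes of
    the class's species receive Poisson(background_mean) background fragments.
    """

    name: str
    marker_fractions: dict[str, float] = field(default_factory=dict)
    marker_mean: float = 20.0
    background_mean: float = 2.0
    species: str = "human"

    def __post_init__(self) -> None:
        for g, f in self.marker_fractions.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"marker fraction for {g} outside [0,1]")
        if self.marker_mean < 1:
            raise ValueError("marker_mean must be >= 1")
        if self.background_mean < 0:
            raise ValueError("background_mean must be >= 0")


@dataclass
class SidePopulationSpec:
    """Cell-class composition of one tissue side / sample."""

    name: str
    n_cells: int
    class_weights: dict[str, float]

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.n_cells and (not self.class_weights or
                             any(w < 0 for w in self.class_weights.values()) or
                             sum(self.class_weights.values()) <= 0):
            raise ValueError("class_weights must be non-negative with positive sum")


@dataclass
class TruthSpec:
    """Full generative description of a synthetic cell population."""

    genes: list[str]
    classes: dict[str, ClassProfile]
    sides: list[SidePopulationSpec]
    doublet_rate: float = 0.0
    species_of_gene: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in spec")
        gene_set = set(self.genes)
        for prof in self.classes.values():
            missing = set(prof.marker_fractions) - gene_set
            if missing:
                raise ValueError(f"class {prof.name}: marker genes not in gene list: {sorted(missing)}")
        for side in self.sides:
            unknown = set(side.class_weights) - set(self.classes)
            if unknown:
                raise ValueError(f"side {side.name}: unknown classes {sorted(unknown)}")
        if not 0.0 <= self.doublet_rate <= 1.0:
            raise ValueError("doublet_rate must be in [0,1]")

    def gene_species(self, gene: str) -> str:
        if self.species_of_gene is not None:
            return self.species_of_gene[gene]
        return gene.split("_", 1)[0] if "_" in gene else "human"


@dataclass
class GroundTruth:
    """Per-cell truth table plus the fragment-count matrix."""

    cells: pd.DataFrame   # index barcode; columns side, cell_class, species, is_doublet
    counts: pd.DataFrame  # barcode x gene, integer fragments

    def __post_init__(self) -> None:
        if self.cells.index.has_duplicates:
            raise ValueError("duplicate barcodes in ground truth")
        if not self.cells.index.equals(self.counts.index):
            raise ValueError("cells and counts indexed by different barcodes")
        if self.counts.size and (self.counts.to_numpy() < 0).any():
            raise ValueError("negative fragment counts")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def write_dir(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.cells.to_csv(outdir / "truth_cells.tsv", sep="\t", index_label="barcode")
        self.counts.to_csv(outdir / "truth_counts.tsv", sep="\t", index_label="barcode")

    @classmethod
    def read_dir(cls, indir: str | Path) -> "GroundTruth":
        indir = Path(indir)
        cells = pd.read_csv(indir / "truth_cells.tsv", sep="\t", index_col="barcode")
        counts = pd.read_csv(indir / "truth_counts.tsv", sep="\t", index_col="barcode")
        return cls(cells, counts)


def _unique_barcodes(n: int, barcode_len: int, rng: np.random.Generator) -> list[str]:
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        idx = rng.integers(0, 4, size=(n - len(out), barcode_len))
        for row in _BASES[idx]:
            bc = "".join(row)
            if bc not in seen:
                seen.add(bc)
                out.append(bc)
    return out


def simulate_cells(spec: TruthSpec, seed: int | None = None, barcode_len: int = 12) -> GroundTruth:
    """Draw a cell population (classes, sides, species, fragment counts)."""
    rng = np.random.default_rng(seed)
    total = sum(s.n_cells for s in spec.sides)
    barcodes = _unique_barcodes(total, barcode_len, rng)
    genes = list(spec.genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    gene_species = np.array([spec.gene_species(g) for g in genes])

    rows = np.zeros((total, len(genes)), dtype=np.int64)
    meta: list[dict] = []

    def _draw_profile(prof: ClassProfile, row: np.ndarray) -> None:
        sp_mask = gene_species == prof.species
        marker_idx = [gene_pos[g] for g in prof.marker_fractions]
        bg_mask = sp_mask.copy()
        bg_mask[marker_idx] = False
        row[bg_mask] += rng.poisson(prof.background_mean, size=int(bg_mask.sum()))
        for g, f in prof.marker_fractions.items():
            if rng.random() < f:
                row[gene_pos[g]] += 1 + rng.poisson(prof.marker_mean - 1)

    i = 0
    for side in spec.sides:
        classes = list(side.class_weights)
        weights = np.array([side.class_weights[c] for c in classes], dtype=float)
        weights = weights / weights.sum() if side.n_cells else weights
        for _ in range(side.n_cells):
            cls_name = classes[rng.choice(len(classes), p=weights)]
            prof = spec.classes[cls_name]
            _draw_profile(prof, rows[i])
            species = prof.species
            is_doublet = False
            if spec.doublet_rate and rng.random() < spec.doublet_rate:
                other_name = classes[rng.choice(len(classes), p=weights)]
                other = spec.classes[other_name]
                _draw_profile(other, rows[i])
                is_doublet = True
                if other.species != species:
                    species = "mixed"
            meta.append(
                {"barcode": barcodes[i], "side": side.name, "cell_class": cls_name,
                 "species": species, "is_doublet": is_doublet}
            )
            i += 1

    cells = pd.DataFrame(meta).set_index("barcode") if meta else pd.DataFrame(
        columns=["side", "cell_class", "species", "is_doublet"],
        index=pd.Index([], name="barcode"),
    )
    counts = pd.DataFrame(rows, index=cells.index, columns=genes)
    return GroundTruth(cells, counts)


# ---------------------------------------------------------------------------
# FASTQ emission
# ---------------------------------------------------------------------------


def _mutate(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < error_rate)[0]
    if hit.size:
        lut = {65: b"CGT", 67: b"AGT", 71: b"ACT", 84: b"ACG"}
        for i in hit:
            arr[i] = lut[arr[i]][rng.integers(0, 3)]
    return arr.tobytes().decode()


def emit_fastq_pairs(
    truth: GroundTruth,
    transcriptome: ToyTranscriptome,
    read1_path: str | Path,
    read2_path: str | Path,
    read_len: int = 75,
    tail_window: int = 300,
    error_rate: float = 0.0,
    seed: int | None = None,
    anchor: str = DEFAULT_READ1_ANCHOR,
) -> int:
    """Write paired FASTQ for every ground-truth fragment; returns pair count.

    Fragment starts are uniform over the final ``tail_window`` nt of the
    transcript (3' bias of oligo-dT capture); substitution errors at
    ``error_rate`` per base on both mates; Phred+33 qualities.
    """
    seqs = transcriptome.sequences
    expressed = truth.counts.columns[(truth.counts.sum(axis=0) > 0).to_numpy()]
    missing = [g for g in expressed if g not in seqs]
    if missing:
        raise KeyError(f"genes absent from transcriptome: {missing}")
    rng = np.random.default_rng(seed)

    def _open(path):
        path = str(path)
        return gzip.open(path, "wt") if path.endswith(".gz") else open(path, "w")

    serial = 0
    with _open(read1_path) as f1, _open(read2_path) as f2:
        for barcode, row in truth.counts.iterrows():
            for gene in truth.counts.columns[row.to_numpy() > 0]:
                tseq = seqs[gene]
                L = len(tseq)
                for _ in range(int(row[gene])):
                    if L <= read_len:
                        frag = tseq
                    else:
                        lo = max(0, L - tail_window)
                        start = int(rng.integers(lo, L - read_len + 1))
                        frag = tseq[start:start + read_len]
                    r1 = _mutate(barcode + anchor, error_rate, rng)
                    r2 = _mutate(frag, error_rate, rng)
                    name = f"r{serial:09d}"
                    f1.write(f"@{name}\n{r1}\n+\n{'I' * len(r1)}\n")
                    f2.write(f"@{name}\n{r2}\n+\n{'I' * len(r2)}\n")
                    serial += 1
    return serial


# ---------------------------------------------------------------------------
# study-condition factories
# ---------------------------------------------------------------------------

#: Epithelial/mesenchymal marker partition used throughout (assignment of the
#: eight EMT-screen markers; CD44 and THY1 are the contested ones, see docs).
EPITHELIAL_GENES = ("EPCAM", "CDH1")
MESENCHYMAL_GENES = ("ACTA2", "VIM", "FN1", "ZEB1", "THY1", "CD44")


def default_tumor_spec(n_cells_per_side: int = 1000) -> tuple[TruthSpec, dict[str, str]]:
    """Two-side tumor population (endometrial E-side vs myometrial M-side).

    Cancer cells carry the EMT marker panel plus a spheroid-signature gene
    (FADS2, positive in 48% of E-side vs 31% of M-side cancer cells, the
    side-table template row); T cells are CD3D+, macrophages CD68+, and both
    immune classes express the chemokines CCL4/CCL20 at side-dependent rates.
    Returns the spec and the marker->class map used to build rule sets.
    """
    markers = ["EPCAM", "CDH1", "ACTA2", "VIM", "FN1", "ZEB1", "THY1", "CD44",
               "CD3D", "CD68", "FADS2", "SOX2", "CCL4", "CCL20"]
    genes = [f"human_{m}" for m in markers] + [f"human_g{i:04d}" for i in range(200)]

    def h(d: dict[str, float]) -> dict[str, float]:
        return {f"human_{k}": v for k, v in d.items()}

    cancer_common = {"EPCAM": 0.85, "CDH1": 0.6, "VIM": 0.25, "ACTA2": 0.1,
                     "FN1": 0.1, "ZEB1": 0.05, "THY1": 0.1, "CD44": 0.3,
                     "CCL4": 0.05, "CCL20": 0.1}
    classes = {
        "cancer_E": ClassProfile("cancer_E", h({**cancer_common, "FADS2": 0.48, "SOX2": 0.17})),
        "cancer_M": ClassProfile("cancer_M", h({**cancer_common, "FADS2": 0.31, "SOX2": 0.06})),
        "T": ClassProfile("T", h({"CD3D": 0.95, "CCL4": 0.30, "CCL20": 0.10})),
        "macrophage": ClassProfile("macrophage", h({"CD68": 0.95, "CCL4": 0.40, "CCL20": 0.25})),
    }
    sides = [
        SidePopulationSpec("E", n_cells_per_side, {"cancer_E": 0.70, "T": 0.15, "macrophage": 0.15}),
        SidePopulationSpec("M", n_cells_per_side, {"cancer_M": 0.55, "T": 0.30, "macrophage": 0.15}),
    ]
    marker_classes = {"cancer": ["EPCAM", "CDH1"], "T": ["CD3D"], "macrophage": ["CD68"]}
    return TruthSpec(genes=genes, classes=classes, sides=sides), marker_classes


def default_barnyard_spec(n_cells: int = 500, doublet_rate: float = 0.05,
                          n_genes_per_species: int = 100) -> TruthSpec:
    """~1:1 human/mouse cell-line mixture for species-mixing validation."""
    genes = [f"human_g{i:04d}" for i in range(n_genes_per_species)] + \
            [f"mouse_g{i:04d}" for i in range(n_genes_per_species)]
    classes = {
        "human_cell": ClassProfile("human_cell", {}, background_mean=2.0, species="human"),
        "mouse_cell": ClassProfile("mouse_cell", {}, background_mean=2.0, species="mouse"),
    }
    sides = [SidePopulationSpec("mix", n_cells, {"human_cell": 0.5, "mouse_cell": 0.5})]
    return TruthSpec(genes=genes, classes=classes, sides=sides, doublet_rate=doublet_rate)
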