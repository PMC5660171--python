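"""Barcoded capture-bead library: oligo layout, barcode sampling, collisions.

Each capture bead carries clonal copies of a single oligo: a fixed 5' anchor,
a 25-nt poly-A stretch, a random 12-nt cell barcode and a fixed 3' anchor that
ends in the oligo-dT capture region after bead processing.  Because barcodes
are synthesized as random N-mers, two beads can share a barcode by chance;
``collision_fraction`` measures that empirically and
``expected_collision_fraction`` gives the closed-form expectation under
i.i.d. uniform sampling from the 4^L barcode space.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

_BASES = np.array(list("ACGT"))
_VALID = frozenset("ACGT")

#: 5' fixed flank of the capture oligo (upstream of the poly-A stretch).
DEFAULT_ANCHOR_5P = "CCATCTCATCCCTGCGTGTCTCCGACTCAGGCAGTG"
#: 3' fixed flank of the capture oligo (downstream of the barcode).
DEFAULT_ANCHOR_3P = "ACATAGGCCGTCTTCAGCCGCTGAGACTGCCAAGGCACACAGGGGATAGG"


@dataclass(frozen=True)
class OligoLayout:
    """Layout of the single-stranded capture oligo on a bead.

    The default values reproduce the 123-nt synthesis oligo used to make the
    barcoded beads: 36-nt 5' anchor, 25 poly-A, 12-nt random barcode, 50-nt
    3' anchor.
    """

    anchor_5p: str = DEFAULT_ANCHOR_5P
    polyA_len: int = 25
    barcode_len: int = 12
    anchor_3p: str = DEFAULT_ANCHOR_3P

    def __post_init__(self) -> None:
        if self.barcode_len < 1:
            raise ValueError("barcode_len must be >= 1")
        if self.polyA_len < 0:
            raise ValueError("polyA_len must be >= 0")
        for name in ("anchor_5p", "anchor_3p"):
            seq = getattr(self, name)
            if not set(seq) <= _VALID:
                raise ValueError(f"{name} contains non-ACGT characters: {seq!r}")

    @property
    def barcode_offset(self) -> int:
        """0-based offset of the barcode within the full capture sequence."""
        return len(self.anchor_5p) + self.polyA_len


@dataclass
class BarcodeLibrary:
    """A sampled bead barcode library (one barcode string per bead)."""

    barcodes: list[str]
    barcode_len: int = 12
    seed: int | None = None
    space_size: int = field(init=False)

    def __post_init__(self) -> None:
        self.space_size = 4 ** self.barcode_len
        for bc in self.barcodes:
            if len(bc) != self.barcode_len or not set(bc) <= _VALID:
                raise ValueError(f"invalid barcode {bc!r} for length {self.barcode_len}")

    def __len__(self) -> int:
        return len(self.barcodes)

    def whitelist(self) -> frozenset[str]:
        return frozenset(self.barcodes)

    def write(self, path: str | Path) -> None:
        """Write one barcode per line; metadata goes to a sidecar header file."""
        path = Path(path)
        path.write_text("".join(bc + "\n" for bc in self.barcodes))
        sidecar = path.with_suffix(path.suffix + ".meta")
        sidecar.write_text(
            f"n_beads\t{len(self.barcodes)}\n"
            f"barcode_len\t{self.barcode_len}\n"
            f"seed\t{'' if self.seed is None else self.seed}\n"
        )

    @classmethod
    def read(cls, path: str | Path) -> "BarcodeLibrary":
        path = Path(path)
        barcodes = [line.strip() for line in path.read_text().splitlines() if line.strip()]
        if not barcodes:
            raise ValueError(f"empty barcode whitelist: {path}")
        seed = None
        sidecar = path.with_suffix(path.suffix + ".meta")
        if sidecar.exists():
            meta = dict(line.split("\t") for line in sidecar.read_text().splitlines() if "\t" in line)
            if meta.get("seed"):
                seed = int(meta["seed"])
        return cls(barcodes=barcodes, barcode_len=len(barcodes[0]), seed=seed)


def sample_library(n_beads: int, barcode_len: int = 12, seed: int | None = None) -> BarcodeLibrary:
    """Draw ``n_beads`` barcodes i.i.d. uniformly from the 4^L space.

    This models random N-mer synthesis followed by clonal emulsion-PCR
    amplification: each bead ends up with one barcode, and distinct beads may
    collide by chance.
    """
    if n_beads < 1:
        raise ValueError("n_beads must be >= 1")
    if barcode_len < 1:
        raise ValueError("barcode_len must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, 4, size=(n_beads, barcode_len))
    barcodes = ["".join(row) for row in _BASES[idx]]
    return BarcodeLibrary(barcodes=barcodes, barcode_len=barcode_len, seed=seed)


def collision_fraction(library: BarcodeLibrary) -> float:
    """Fraction of beads whose barcode occurs on >= 2 beads in the library."""
    if len(library) == 0:
        raise ValueError("collision_fraction of an empty library is undefined")
    counts = Counter(library.barcodes)
    colliding = sum(c for c in counts.values() if c >= 2)
    return colliding / len(library)


def expected_collision_fraction(n_beads: int, space_size: int) -> float:
    """Expected per-bead collision probability under uniform sampling.

    A given bead collides iff at least one of the other ``n_beads - 1`` beads
    drew the same barcode: 1 - (1 - 1/space_size)^(n_beads - 1).
    """
    if n_beads < 1:
        raise ValueError("n_beads must be >= 1")
    if space_size < 1:
        raise ValueError("space_size must be >= 1")
    if space_size == 1:
        return 0.0 if n_beads == 1 else 1.0
    return -np.expm1((n_beads - 1) * np.log1p(-1.0 / space_size))


def build_capture_sequence(layout: OligoLayout, barcode: str) -> str:
    """Assemble the sense-strand capture sequence for one bead barcode."""
    if len(barcode) != layout.barcode_len:
        raise ValueError(
            f"barcode length {len(barcode)} != layout barcode_len {layout.barcode_len}"
        )
    if not set(barcode) <= _VALID:
        raise ValueError(f"barcode contains non-ACGT characters: {barcode!r}")
    return layout.anchor_5p + "A" * layout.polyA_len + barcode + layout.anchor_3p
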