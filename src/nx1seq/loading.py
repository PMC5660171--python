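"""Poisson statistics of cell deposition into microwells.

Cells settle into wells by gravity.  With ``n`` cells distributed over ``w``
wells, the per-well occupancy is binomial(n, 1/w), which at microwell scale
(w ~ 1.6e5) is effectively Poisson with mean lambda = n/w.  At the working
cell:well ratio of 1:20 (lambda = 0.05) the model predicts that ~95% of
deposited cells sit alone in their well.

The singlet fraction here is cell-centric: the probability that a *deposited
cell* shares its well with no other cell (e^-lambda in the Poisson limit),
not the fraction of occupied wells that hold exactly one cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

#: Wells per slide (1.6e5 wells in a 20 x 20 mm section).
DEFAULT_N_WELLS = 160_000


@dataclass(frozen=True)
class LoadingSpec:
    """Parameters for one cell-seeding simulation."""

    n_cells: int = 10_000
    n_wells: int = DEFAULT_N_WELLS
    seeding_efficiency: float = 0.9
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.n_wells < 1:
            raise ValueError("n_wells must be >= 1")
        if not 0.0 <= self.seeding_efficiency <= 1.0:
            raise ValueError("seeding_efficiency must be in [0, 1]")


@dataclass
class OccupancyHistogram:
    """Number of wells holding k = 0, 1, 2, ... cells."""

    counts_by_k: dict[int, int]
    n_wells: int
    n_deposited: int

    def __post_init__(self) -> None:
        if sum(self.counts_by_k.values()) != self.n_wells:
            raise ValueError("well counts do not sum to n_wells")
        if sum(k * v for k, v in self.counts_by_k.items()) != self.n_deposited:
            raise ValueError("cell counts do not sum to n_deposited")

    @property
    def singlet_fraction_of_cells(self) -> float:
        """Fraction of deposited cells alone in their well (0 if none deposited)."""
        if self.n_deposited == 0:
            return 0.0
        return self.counts_by_k.get(1, 0) / self.n_deposited

    @property
    def multiplet_fraction_of_cells(self) -> float:
        if self.n_deposited == 0:
            return 0.0
        return 1.0 - self.singlet_fraction_of_cells

    def to_frame(self):
        import pandas as pd

        ks = sorted(self.counts_by_k)
        return pd.DataFrame(
            {"cells_per_well": ks, "n_wells": [self.counts_by_k[k] for k in ks]}
        )


def occupancy_pmf(lam: float, k: int) -> float:
    """Poisson probability of a well receiving exactly ``k`` cells."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if k < 0:
        raise ValueError("k must be >= 0")
    return float(stats.poisson.pmf(k, lam))


def singlet_fraction_of_cells(ratio: float) -> float:
    """P(a deposited cell shares its well with no other cell), Poisson limit.

    Size-biasing the Poisson occupancy gives exactly e^-lambda: the well
    containing a tagged cell holds Poisson(lambda) *additional* cells.
    ``ratio`` is the mean cells-per-well loading (0.05 at 1:20).
    """
    if ratio < 0:
        raise ValueError("ratio must be >= 0")
    return float(np.exp(-ratio))


def singlet_fraction_exact(n_cells: int, n_wells: int) -> float:
    """Finite-population singlet probability (1 - 1/w)^(n - 1).

    Exact for n_cells independently and uniformly assigned to n_wells wells.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if n_wells < 1:
        raise ValueError("n_wells must be >= 1")
    return float((1.0 - 1.0 / n_wells) ** (n_cells - 1))


def simulate_loading(spec: LoadingSpec) -> OccupancyHistogram:
    """Simulate gravity seeding: Bernoulli thinning then uniform well choice."""
    rng = np.random.default_rng(spec.seed)
    n_deposited = int(rng.binomial(spec.n_cells, spec.seeding_efficiency)) if spec.n_cells else 0
    wells = rng.integers(0, spec.n_wells, size=n_deposited)
    occupancy = np.bincount(wells, minlength=spec.n_wells)
    ks, n_wells_at_k = np.unique(occupancy, return_counts=True)
    return OccupancyHistogram(
        counts_by_k={int(k): int(c) for k, c in zip(ks, n_wells_at_k)},
        n_wells=spec.n_wells,
        n_deposited=n_deposited,
    )
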