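"""Seeded generators for heterogeneous tissue inputs.

Cell-to-cell variability enters the tissue model through a per-cell field of
the recovery decay rate ``b``.  Two families are provided:

* **binary** mixtures: each cell is independently bistable (``b = b_bi``)
  with a given probability, otherwise monostable (``b = b_mono``) —
  the idealized mixture used for the mixed-medium and annulus experiments;
* **log-normal** fields ``b = exp(N(mu, sigma**2))`` — a smooth, long-tailed
  stand-in for physiological repolarization variability.  The fraction of
  intrinsically bistable cells is the analytic tail mass
  ``P(b > b_crit) = 1 - Phi((ln(b_crit) - mu)/sigma)`` with the single-cell
  bistability onset ``b_crit = 1.77``.

An annulus (a hole standing in for a vein or artery ostium) is rasterized as
a filled disk of absent cells; tissue cells on its rim lose one or two of
their four neighbors, which is exactly the neighbor-count deficit the
reduced model predicts to be pro-arrhythmic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

B_CRIT = 1.77  # single-cell bistability onset (Hopf value of b, 2 d.p.)

__all__ = [
    "BFieldSpec",
    "AnnulusSpec",
    "AnnulusGeometry",
    "binary_field",
    "nested_binary_masks",
    "lognormal_field",
    "bistable_fraction",
    "build_annulus",
    "default_annulus",
    "B_CRIT",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def binary_field(shape, fraction, b_mono=1.0, b_bi=3.0, seed=None) -> np.ndarray:
    """Per-cell i.i.d. binary b-field: bistable with probability ``fraction``."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    rng = _rng(seed)
    bistable = rng.random(shape) < fraction
    return np.where(bistable, float(b_bi), float(b_mono))


def nested_binary_masks(shape, fractions, seed=None) -> list[np.ndarray]:
    """Bistable masks for increasing fractions where each set contains the last.

    One uniform draw per cell is thresholded at each fraction, so the mask
    for a larger fraction is a superset of the mask for a smaller one.
    """
    u = _rng(seed).random(shape)
    return [u < f for f in fractions]


def lognormal_field(shape, mu, sigma, seed=None) -> np.ndarray:
    """Log-normal b-field: ``b = exp(N(mu, sigma**2))`` element-wise."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return _rng(seed).lognormal(mean=mu, sigma=sigma, size=shape)


def bistable_fraction(mu, sigma, b_crit: float = B_CRIT) -> float:
    """Analytic fraction of intrinsically bistable cells, P(b > b_crit)."""
    return float(norm.sf((np.log(b_crit) - mu) / sigma))


@dataclass(frozen=True)
class BFieldSpec:
    """Declarative description of a b-field draw (kind + parameters)."""

    kind: str = "binary"  # binary | lognormal
    fraction: float = 0.1
    b_mono: float = 1.0
    b_bi: float = 3.0
    mu: float = 1.0
    sigma: float = 1.0

    def sample(self, shape, seed=None) -> np.ndarray:
        if self.kind == "binary":
            return binary_field(shape, self.fraction, self.b_mono, self.b_bi, seed)
        if self.kind == "lognormal":
            return lognormal_field(shape, self.mu, self.sigma, seed)
        raise ValueError(f"unknown b-field kind {self.kind!r}")


# ---------------------------------------------------------------------------
# annulus geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnulusSpec:
    """A hole in the tissue, rasterized from cell-center Euclidean distance.

    ``center`` is in 0-based (row, col) grid units; cells whose center lies
    within ``inner_radius <= dist <= radius`` are absent (ties at exactly
    ``radius`` are inside).  ``inner_radius = 0`` gives a filled disk, which
    is the default appearance of the tissue boundary.
    """

    center: tuple[float, float]
    radius: float
    inner_radius: float = 0.0

    def __post_init__(self) -> None:
        if self.radius < 0 or self.inner_radius < 0 or self.inner_radius > self.radius:
            raise ValueError("require 0 <= inner_radius <= radius")


def default_annulus(shape=(40, 40), radius: float = 10.0) -> AnnulusSpec:
    """Disk of the given radius centered in the grid."""
    r, c = shape
    return AnnulusSpec(center=((r - 1) / 2.0, (c - 1) / 2.0), radius=radius)


@dataclass(frozen=True)
class AnnulusGeometry:
    """Derived annulus structure on a concrete grid.

    Attributes
    ----------
    absent : bool grid, True where tissue is missing.
    flux_mask : (4, rows, cols) bool, order (N, S, E, W); True means the cell
        *receives* flux from that neighbor.  Masking is symmetric across each
        shared edge.
    neighbor_count : int grid of unmasked tissue neighbors per cell
        (0 inside the hole).
    boundary : bool grid, tissue cells 4-adjacent to an absent cell.
    midfield : bool grid, all remaining tissue cells.
    """

    spec: AnnulusSpec
    absent: np.ndarray
    flux_mask: np.ndarray
    neighbor_count: np.ndarray
    boundary: np.ndarray
    midfield: np.ndarray

    @property
    def tissue(self) -> np.ndarray:
        return ~self.absent

    def distance(self, shape=None) -> np.ndarray:
        """Euclidean distance of each cell center from the annulus center."""
        rows, cols = self.absent.shape
        rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        cy, cx = self.spec.center
        return np.sqrt((rr - cy) ** 2 + (cc - cx) ** 2)


def _shift(arr: np.ndarray, dr: int, dc: int, bc: str) -> np.ndarray:
    """Neighbor view: out[i,j] = arr[i+dr, j+dc] with periodic wrap or edge mirror."""
    out = np.roll(arr, (-dr, -dc), axis=(0, 1))
    if bc == "neumann":
        if dr == -1:
            out[0, :] = arr[0, :]
        elif dr == 1:
            out[-1, :] = arr[-1, :]
        if dc == -1:
            out[:, 0] = arr[:, 0]
        elif dc == 1:
            out[:, -1] = arr[:, -1]
    return out


# direction order and offsets: N = row-1, S = row+1, E = col+1, W = col-1
DIRECTIONS = ("N", "S", "E", "W")
_OFFSETS = {"N": (-1, 0), "S": (1, 0), "E": (0, 1), "W": (0, -1)}


def build_annulus(shape, spec: AnnulusSpec, bc: str = "periodic") -> AnnulusGeometry:
    """Rasterize an annulus and derive flux masks and the cell partition."""
    rows, cols = shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    cy, cx = spec.center
    dist = np.sqrt((rr - cy) ** 2 + (cc - cx) ** 2)
    absent = (dist >= spec.inner_radius) & (dist <= spec.radius)
    if spec.radius == 0:
        absent = np.zeros(shape, dtype=bool)
    touches_edge = absent[0, :].any() or absent[-1, :].any() or absent[:, 0].any() or absent[:, -1].any()
    if touches_edge and bc == "periodic":
        raise ValueError("annulus touches the grid edge under periodic boundary conditions")

    flux_mask = np.ones((4, rows, cols), dtype=bool)
    for k, name in enumerate(DIRECTIONS):
        dr, dc = _OFFSETS[name]
        neighbor_absent = _shift(absent, dr, dc, bc)
        flux_mask[k] = ~(absent | neighbor_absent)

    # count of live (non-absent, in-grid) 4-neighbors
    neighbor_count = np.zeros(shape, dtype=np.int64)
    for name in DIRECTIONS:
        dr, dc = _OFFSETS[name]
        exists = np.ones(shape, dtype=bool)
        if bc == "neumann":
            if dr == -1:
                exists[0, :] = False
            elif dr == 1:
                exists[-1, :] = False
            if dc == -1:
                exists[:, 0] = False
            elif dc == 1:
                exists[:, -1] = False
        neighbor_count += (~_shift(absent, dr, dc, bc)) & exists
    neighbor_count[absent] = 0

    adjacent_to_hole = np.zeros(shape, dtype=bool)
    for name in DIRECTIONS:
        dr, dc = _OFFSETS[name]
        adjacent_to_hole |= _shift(absent, dr, dc, bc)
    boundary = ~absent & adjacent_to_hole
    midfield = ~absent & ~boundary
    return AnnulusGeometry(spec, absent, flux_mask, neighbor_count, boundary, midfield)
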