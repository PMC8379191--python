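"""Grid-based Getis-Ord local hotspot statistic for nuclear centroids.

The image field is discretised into a square grid; the count of nuclei of one
phenotype in each grid cell is the analysed value.  For cell i with binary
distance weights w_ij(d) (1 when the inter-cell centre distance is strictly
below the scale d, 0 otherwise, w_ii = 0) the self-excluded Getis-Ord ratio

    G_i(d) = sum_{j != i} w_ij x_j / sum_{j != i} x_j

is compared with its conditional-randomisation moments

    E[G_i] = W_i / (n - 1),
    Var[G_i] = W_i (n - 1 - W_i) / ((n - 1)^2 (n - 2)) * Y_i2 / Y_i1^2,

where W_i = sum_j w_ij, Y_i1 and Y_i2 are the mean and variance of the
remaining values, giving the z-score Z_i = (G_i - E) / sqrt(Var).  Cells with
zero variance (no spatial variation among the other values) are assigned
Z = 0; cells whose remaining values sum to zero are flagged undefined.  A
seeded conditional-permutation null is provided as an independent check on
the closed-form moments.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
import warnings
from typing import Optional

import numpy as np
import pandas as pd


@dataclasses.dataclass
class GridCounts:
    """Phenotype-specific nucleus counts on a regular grid."""

    counts: np.ndarray  # (rows, cols) non-negative integers
    cell_size_px: float
    origin_px: tuple = (0.0, 0.0)  # (x, y) of the grid's top-left corner
    phenotype: str = ""
    field_shape_px: Optional[tuple] = None  # (height, width), ragged cells kept

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D grid")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.counts.size

    def cell_centres_px(self) -> np.ndarray:
        """(n, 2) array of (x, y) cell centres; ragged edge cells use the
        centre of their actual (clipped) extent."""
        rows, cols = self.counts.shape
        s = self.cell_size_px
        ox, oy = self.origin_px
        if self.field_shape_px is not None:
            h, w = self.field_shape_px
            x_hi = np.minimum((np.arange(cols) + 1) * s, w - ox)
            y_hi = np.minimum((np.arange(rows) + 1) * s, h - oy)
        else:
            x_hi = (np.arange(cols) + 1) * s
            y_hi = (np.arange(rows) + 1) * s
        cx = ox + (np.arange(cols) * s + x_hi) / 2.0
        cy = oy + (np.arange(rows) * s + y_hi) / 2.0
        xx, yy = np.meshgrid(cx, cy)
        return np.stack([xx.ravel(), yy.ravel()], axis=1)


@dataclasses.dataclass
class SpatialWeights:
    """Symmetric binary distance weights between grid-cell centres."""

    w: np.ndarray  # (n, n) in {0, 1}, zero diagonal
    d_px: float

    @property
    def W(self) -> np.ndarray:
        return self.w.sum(axis=1)


@dataclasses.dataclass
class GetisOrdResult:
    """Per-cell Getis-Ord quantities on the grid."""

    g: np.ndarray
    expected: np.ndarray
    variance: np.ndarray
    z: np.ndarray
    defined: np.ndarray  # False where the remaining counts sum to zero
    grid: GridCounts
    d_px: float
    perm_p: Optional[np.ndarray] = None

    def to_frame(self) -> pd.DataFrame:
        rows, cols = self.grid.counts.shape
        rr, cc = np.unravel_index(np.arange(rows * cols), (rows, cols))
        return pd.DataFrame(
            dict(
                row=rr,
                col=cc,
                count=self.grid.counts.ravel(),
                g=self.g.ravel(),
                expected=self.expected.ravel(),
                variance=self.variance.ravel(),
                z=self.z.ravel(),
                defined=self.defined.ravel(),
            )
        )


def grid_discretise(
    centroids: pd.DataFrame,
    field_shape_px: tuple,
    cell_size_px: float,
    phenotype: Optional[str] = None,
) -> GridCounts:
    """Bin centroids into half-open grid cells [k*s, (k+1)*s).

    ``centroids`` needs columns x_px/y_px (and phenotype when filtering).
    The ragged final row/column is kept; conservation holds: the counts sum
    to the number of (phenotype) centroids inside the field.
    """
    if cell_size_px < 1:
        raise ValueError("cell_size_px must be >= 1")
    h, w = field_shape_px
    pts = centroids
    if phenotype is not None and "phenotype" in pts.columns:
        pts = pts[pts["phenotype"] == phenotype]
    x = pts["x_px"].to_numpy(dtype=float)
    y = pts["y_px"].to_numpy(dtype=float)
    inside = (x >= 0) & (x < w) & (y >= 0) & (y < h)
    x, y = x[inside], y[inside]
    rows = int(math.ceil(h / cell_size_px))
    cols = int(math.ceil(w / cell_size_px))
    counts = np.zeros((rows, cols), dtype=np.int64)
    ci = np.floor(x / cell_size_px).astype(int)
    ri = np.floor(y / cell_size_px).astype(int)
    np.add.at(counts, (ri, ci), 1)
    if counts.sum() == 0:
        warnings.warn(
            f"no centroids of phenotype {phenotype!r} fell on the grid",
            stacklevel=2,
        )
    return GridCounts(
        counts=counts,
        cell_size_px=float(cell_size_px),
        phenotype=phenotype or "",
        field_shape_px=(h, w),
    )


def distance_band_weights(grid: GridCounts, d_px: float) -> SpatialWeights:
    """w_ij = 1 iff the Euclidean centre distance d_ij < d (strict), w_ii = 0."""
    centres = grid.cell_centres_px()
    n = centres.shape[0]
    w = np.zeros((n, n), dtype=np.int8)
    chunk = max(1, int(4e6 // max(n, 1)))
    for start in range(0, n, chunk):
        block = centres[start : start + chunk]
        diff = block[:, None, :] - centres[None, :, :]
        dist = np.sqrt((diff**2).sum(-1))
        w[start : start + chunk] = dist < d_px
    np.fill_diagonal(w, 0)
    return SpatialWeights(w=w, d_px=float(d_px))


def _disc_kernel(d_cells: float) -> np.ndarray:
    """Binary kernel of cells with centre distance strictly below d (in cell
    units), centre excluded."""
    r = int(np.ceil(d_cells))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    k = (xx**2 + yy**2) < d_cells**2
    k[r, r] = False
    return k.astype(float)


# dense pairwise weights above this many grid cells are replaced by an
# equivalent convolution over the regular lattice
_MAX_DENSE_CELLS = 6000


def getis_ord(
    grid: GridCounts,
    d_px: float,
    weights: Optional[SpatialWeights] = None,
) -> GetisOrdResult:
    """Self-excluded Getis-Ord G statistic with randomisation moments."""
    x = grid.counts.ravel().astype(float)
    n = x.size
    if x.sum() <= 0:
        raise ValueError("grid contains no counts; the statistic is undefined")
    if n < 3:
        raise ValueError("need at least 3 grid cells")
    if weights is None and n > _MAX_DENSE_CELLS:
        # large regular grid: the binary distance band is a disc kernel, so
        # the weighted sums become convolutions (nominal cell centres; the
        # sub-cell centre shift of ragged edge cells is ignored here)
        from scipy.ndimage import convolve

        kernel = _disc_kernel(d_px / grid.cell_size_px)
        counts2d = grid.counts.astype(float)
        num = convolve(counts2d, kernel, mode="constant", cval=0.0).ravel()
        W = convolve(
            np.ones_like(counts2d), kernel, mode="constant", cval=0.0
        ).ravel()
        d_used = float(d_px)
    else:
        if weights is None:
            weights = distance_band_weights(grid, d_px)
        w = weights.w.astype(float)
        W = w.sum(axis=1)
        num = w @ x
        d_used = float(weights.d_px)
    total = x.sum()
    rest_sum = total - x
    rest_sq = (x**2).sum() - x**2

    defined = rest_sum > 0
    g = np.full(n, np.nan)
    g[defined] = num[defined] / rest_sum[defined]
    expected = W / (n - 1)
    y1 = rest_sum / (n - 1)
    y2 = rest_sq / (n - 1) - y1**2
    with np.errstate(divide="ignore", invalid="ignore"):
        variance = (
            W * (n - 1 - W) / ((n - 1) ** 2 * (n - 2)) * (y2 / y1**2)
        )
    variance = np.where(defined, variance, np.nan)
    z = np.zeros(n)
    pos = defined & (variance > 0)
    z[pos] = (g[pos] - expected[pos]) / np.sqrt(variance[pos])
    z[~defined] = np.nan

    shape = grid.counts.shape
    return GetisOrdResult(
        g=g.reshape(shape),
        expected=expected.reshape(shape),
        variance=variance.reshape(shape),
        z=z.reshape(shape),
        defined=defined.reshape(shape),
        grid=grid,
        d_px=d_used,
    )


def permutation_null(
    grid: GridCounts,
    weights: SpatialWeights,
    n_perm: int = 999,
    seed: int = 0,
    exhaustive: bool = False,
):
    """Conditional-permutation null of G_i: hold x_i, permute the rest.

    Returns a dict of per-cell arrays: empirical mean, var, z (observed G
    standardised by the empirical moments) and a one-sided upper p-value
    ((1 + #{G_perm >= G_obs}) / (1 + n_perm)).  With ``exhaustive=True`` all
    distinct permutations are enumerated (tiny grids only).
    """
    if not exhaustive and n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    x = grid.counts.ravel().astype(float)
    n = x.size
    obs = getis_ord(grid, weights.d_px, weights=weights)
    g_obs = obs.g.ravel()
    w = weights.w.astype(bool)
    rng = np.random.default_rng(seed)
    mean = np.full(n, np.nan)
    var = np.full(n, np.nan)
    pvals = np.full(n, np.nan)

    all_idx = np.arange(n)
    if exhaustive:
        for i in range(n):
            rest = x[all_idx != i]
            denom = rest.sum()
            if denom <= 0:
                continue
            k = int(w[i].sum())
            gs = [
                sum(perm[:k]) / denom
                for perm in itertools.permutations(rest)
            ]
            gs = np.array(gs)
            mean[i] = gs.mean()
            var[i] = gs.var()
            pvals[i] = (1 + np.sum(gs >= g_obs[i] - 1e-12)) / (1 + len(gs))
    else:
        # shared permutation index matrix over n-1 slots; each cell i maps the
        # slots onto its own "remaining" values
        perm_idx = np.argsort(rng.random((n_perm, n - 1)), axis=1)
        for i in range(n):
            rest = x[all_idx != i]
            denom = rest.sum()
            if denom <= 0:
                continue
            k = int(w[i].sum())
            if k == 0:
                mean[i] = 0.0
                var[i] = 0.0
                pvals[i] = 1.0
                continue
            sums = rest[perm_idx[:, :k]].sum(axis=1)
            gs = sums / denom
            mean[i] = gs.mean()
            var[i] = gs.var()
            pvals[i] = (1 + np.sum(gs >= g_obs[i] - 1e-12)) / (1 + n_perm)

    with np.errstate(divide="ignore", invalid="ignore"):
        z = (g_obs - mean) / np.sqrt(var)
    z = np.where(var > 0, z, 0.0)
    shape = grid.counts.shape
    return dict(
        mean=mean.reshape(shape),
        var=var.reshape(shape),
        z=z.reshape(shape),
        p=pvals.reshape(shape),
        g_obs=g_obs.reshape(shape),
    )


def hotspot_mask(result: GetisOrdResult, z_threshold: float = 1.96) -> np.ndarray:
    """Cells flagged as hotspots: Z >= threshold, one-sided high.

    Undefined cells (NaN z) are never flagged.
    """
    z = result.z
    return np.where(np.isnan(z), False, z >= z_threshold)


def polarisation_index(
    hotspots: np.ndarray, axis_u: np.ndarray
) -> float:
    """Fraction of hotspot cells lying on the leading half of the growth axis.

    ``axis_u`` maps every grid cell to its normalised axis coordinate
    (1 = leading edge); the index is the fraction of flagged cells with
    u > 0.5, so 0.5 under no polarisation.  Raises on an empty hotspot set.
    """
    hot = np.asarray(hotspots, dtype=bool).ravel()
    u = np.asarray(axis_u, dtype=float).ravel()
    if hot.shape != u.shape:
        raise ValueError("hotspot mask and axis coordinates must align")
    sel = hot & np.isfinite(u)
    if sel.sum() == 0:
        raise ValueError("no hotspot cells with a defined axis coordinate")
    return float(np.mean(u[sel] > 0.5))


def grid_axis_coordinates(grid: GridCounts, lobules) -> np.ndarray:
    """Axis coordinate u of each grid-cell centre w.r.t. its enclosing lobule.

    Cells outside every lobule get NaN.
    """
    from .synthetic import _locate

    centres = grid.cell_centres_px()
    out = np.full(grid.n_cells, np.nan)
    for k, (cx, cy) in enumerate(centres):
        _, u = _locate(cx, cy, lobules)
        out[k] = u
    return out.reshape(grid.counts.shape)
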