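"""Scalar morphometry: Ki67 ratio, macrophage periodicity, count-box immune
densities and tertiary-lymphoid-structure detection.

Conventions follow manual stereology practice: fixed 400 x 230 um sampling
frames placed blind to staining, the >50 %-inside counting rule with top/right
edge inclusion for equivocal cells, densities normalised to the relevant
stromal compartment area, and macrophage spacing measured as arc length along
the duct (parallel to the epithelium), never as chord distance.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from shapely.geometry import Point, box as shapely_box
from sklearn.cluster import DBSCAN

from .segment import MaskSet
from .synthetic import DuctTrace

BOX_WIDTH_UM = 400.0
BOX_HEIGHT_UM = 230.0


# ---------------------------------------------------------------------------
# Ki67 pixel-area ratio
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Ki67Ratio:
    ratio: Optional[float]
    pos_pixels: int
    neg_pixels: int
    defined: bool


def ki67_epithelial_ratio(masks: MaskSet) -> Ki67Ratio:
    """Pixel-area ratio of Ki67+ to Ki67- nuclei within the epithelium mask.

    Undefined (flagged) when the epithelium contains no Ki67- nuclear pixels.
    """
    if masks.epithelium is None or masks.ki67_pos is None or masks.ki67_neg is None:
        raise ValueError("MaskSet must contain epithelium and both nuclei maps")
    epi = masks.epithelium.astype(bool)
    pos = int(np.count_nonzero((masks.ki67_pos > 0) & epi))
    neg = int(np.count_nonzero((masks.ki67_neg > 0) & epi))
    if neg == 0:
        return Ki67Ratio(None, pos, neg, defined=False)
    return Ki67Ratio(pos / neg, pos, neg, defined=True)


# ---------------------------------------------------------------------------
# Macrophage periodicity along ducts
# ---------------------------------------------------------------------------

def _merge_tight_pairs(positions: np.ndarray, cluster_gap_um: float) -> np.ndarray:
    """Merge tightly clustered small groups (< 3 cells) to their centroid.

    Successive positions closer than ``cluster_gap_um`` are treated as one
    macrophage sectioned ambiguously; pairs are replaced by their midpoint
    before run detection.
    """
    positions = np.sort(np.asarray(positions, dtype=float))
    merged: List[float] = []
    i = 0
    while i < len(positions):
        j = i
        while j + 1 < len(positions) and positions[j + 1] - positions[j] < cluster_gap_um:
            j += 1
        group = positions[i : j + 1]
        if len(group) < 3:
            merged.append(float(group.mean()))
        else:
            # larger clumps are not periodic structure; keep them unmerged so
            # the CV criterion rejects the run
            merged.extend(float(g) for g in group)
        i = j + 1
    return np.asarray(merged)


@dataclasses.dataclass
class PeriodicRun:
    positions_um: np.ndarray
    gaps_um: np.ndarray
    cv: float


def detect_periodic_runs(
    trace: DuctTrace,
    cv_tol: float = 0.30,
    min_length: int = 4,
    cluster_gap_um: float = 8.0,
) -> List[PeriodicRun]:
    """Maximal runs of >= ``min_length`` evenly spaced macrophages.

    Evenness is operationalised as the coefficient of variation of successive
    gaps being at most ``cv_tol``.  Runs are grown greedily left to right and
    emitted when extension would break the CV criterion.
    """
    positions = _merge_tight_pairs(trace.arc_positions_um, cluster_gap_um)
    runs: List[PeriodicRun] = []
    if len(positions) < min_length:
        return runs
    start = 0
    while start <= len(positions) - min_length:
        end = start + 1
        best_end = None
        while end < len(positions):
            gaps = np.diff(positions[start : end + 1])
            cv = gaps.std() / gaps.mean() if gaps.mean() > 0 else np.inf
            if cv <= cv_tol:
                if end - start + 1 >= min_length:
                    best_end = end
                end += 1
            else:
                break
        if best_end is not None:
            seg = positions[start : best_end + 1]
            gaps = np.diff(seg)
            runs.append(
                PeriodicRun(seg, gaps, float(gaps.std() / gaps.mean()))
            )
            start = best_end + 1
        else:
            start += 1
    return runs


def inter_macrophage_distances(runs: Sequence[PeriodicRun]) -> np.ndarray:
    """Successive arc-length gaps (um) pooled over runs."""
    if not runs:
        return np.empty(0)
    return np.concatenate([r.gaps_um for r in runs])


# ---------------------------------------------------------------------------
# Count boxes
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CountBox:
    """A 400 x 230 um sampling frame.

    Coordinates in pixels (origin = top-left corner of the box); physical
    dimensions fixed by the morphometry protocol.
    """

    x0_px: float
    y0_px: float
    pixel_size_um: float
    width_um: float = BOX_WIDTH_UM
    height_um: float = BOX_HEIGHT_UM
    location_class: str = "n/a"
    counts: dict = dataclasses.field(default_factory=dict)
    intralobular_stroma_mm2: float = 0.0
    total_stroma_mm2: float = 0.0
    luminal_count: int = 0
    mean_luminal_area_um2: float = 0.0

    @property
    def width_px(self) -> float:
        return self.width_um / self.pixel_size_um

    @property
    def height_px(self) -> float:
        return self.height_um / self.pixel_size_um

    @property
    def bounds_px(self) -> Tuple[float, float, float, float]:
        return (
            self.x0_px,
            self.y0_px,
            self.x0_px + self.width_px,
            self.y0_px + self.height_px,
        )

    def pixel_slice(self) -> Tuple[slice, slice]:
        x0, y0, x1, y1 = self.bounds_px
        return (
            slice(int(round(y0)), int(round(y1))),
            slice(int(round(x0)), int(round(x1))),
        )


def place_count_boxes(
    structure_mask: np.ndarray,
    n_boxes: int,
    pixel_size_um: float,
    seed: int = 0,
    artefact_mask: Optional[np.ndarray] = None,
    max_tries: int = 20000,
) -> List[CountBox]:
    """Place boxes uniformly at random among valid positions.

    Valid positions are those whose box region intersects the low-resolution
    structure (parenchyma) mask — the in-silico analogue of placing frames at
    low magnification where only ductal structure is discernible.  Boxes
    overlapping the field edge or the artefact mask are rejected and
    resampled.
    """
    structure_mask = np.asarray(structure_mask, dtype=bool)
    if not structure_mask.any():
        raise ValueError("structure mask is empty; no parenchyma to sample")
    h, w = structure_mask.shape
    bw = BOX_WIDTH_UM / pixel_size_um
    bh = BOX_HEIGHT_UM / pixel_size_um
    if bw > w or bh > h:
        raise ValueError("count box does not fit inside the field")
    rng = np.random.default_rng(seed)
    boxes: List[CountBox] = []
    tries = 0
    while len(boxes) < n_boxes:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"could not place {n_boxes} boxes in {max_tries} attempts; "
                "too few valid positions"
            )
        x0 = rng.uniform(0, w - bw)
        y0 = rng.uniform(0, h - bh)
        box = CountBox(x0, y0, pixel_size_um)
        sl = box.pixel_slice()
        if not structure_mask[sl].any():
            continue
        if artefact_mask is not None and artefact_mask[sl].any():
            continue
        boxes.append(box)
    return boxes


def classify_box_location(
    box: CountBox,
    parenchyma_mask: np.ndarray,
    fat_mask: Optional[np.ndarray] = None,
    annulus_um: float = 200.0,
    fat_fraction_threshold: float = 0.20,
) -> str:
    """'peripheral' when the frame samples the parenchyma-fat boundary.

    A box is peripheral when it intersects fat directly or when at least
    ``fat_fraction_threshold`` of an ``annulus_um``-wide ring around it is
    fat pad; central when the sampled parenchyma is surrounded by more
    parenchyma; 'n/a' when the box contains no tissue at all.
    """
    parenchyma_mask = np.asarray(parenchyma_mask, dtype=bool)
    if fat_mask is None:
        fat_mask = ~parenchyma_mask
    h, w = parenchyma_mask.shape
    sl = box.pixel_slice()
    if not parenchyma_mask[sl].any():
        return "n/a"
    if fat_mask[sl].any():
        return "peripheral"
    ann = int(round(annulus_um / box.pixel_size_um))
    y0 = max(sl[0].start - ann, 0)
    y1 = min(sl[0].stop + ann, h)
    x0 = max(sl[1].start - ann, 0)
    x1 = min(sl[1].stop + ann, w)
    ring = np.ones((y1 - y0, x1 - x0), dtype=bool)
    ring[
        sl[0].start - y0 : sl[0].stop - y0, sl[1].start - x0 : sl[1].stop - x0
    ] = False
    n_ring = np.count_nonzero(ring)
    if n_ring == 0:
        return "central"
    fat_frac = np.count_nonzero(fat_mask[y0:y1, x0:x1] & ring) / n_ring
    return "peripheral" if fat_frac >= fat_fraction_threshold else "central"


def _circle_halfplane_area(c: float, lo: float, hi: float, r: float) -> float:
    """Area of a circle (centre offset c along one axis, radius r) between the
    half-planes lo <= coord <= hi, assuming the circle crosses at most these
    two parallel lines.  Helper for the exact single-edge case."""
    def left_of(x):
        t = np.clip((x - c), -r, r)
        return r * r * np.arccos(-t / r) + t * np.sqrt(max(r * r - t * t, 0.0))

    return left_of(hi) - left_of(lo)


def nucleus_inside_fraction(
    cx: float, cy: float, r: float, bounds: Tuple[float, float, float, float]
) -> float:
    """Fraction of a circular nucleus footprint inside a box.

    Single-edge crossings are computed in closed form (so exact half-in cases
    evaluate to exactly 0.5); corner cases fall back to a polygonal
    intersection.
    """
    x0, y0, x1, y1 = bounds
    if r <= 0:
        return float(x0 <= cx < x1 and y0 <= cy < y1)
    if cx - r >= x0 and cx + r <= x1 and cy - r >= y0 and cy + r <= y1:
        return 1.0
    if cx + r <= x0 or cx - r >= x1 or cy + r <= y0 or cy - r >= y1:
        return 0.0
    cuts_x = (cx - r < x0 < cx + r) + (cx - r < x1 < cx + r)
    cuts_y = (cy - r < y0 < cy + r) + (cy - r < y1 < cy + r)
    area_full = np.pi * r * r
    if cuts_y == 0 and cuts_x > 0:
        return _circle_halfplane_area(cx, x0, x1, r) / area_full
    if cuts_x == 0 and cuts_y > 0:
        return _circle_halfplane_area(cy, y0, y1, r) / area_full
    circle = Point(cx, cy).buffer(r, quad_segs=64)
    return circle.intersection(shapely_box(x0, y0, x1, y1)).area / circle.area


def count_cells_in_box(
    box: CountBox,
    cells: pd.DataFrame,
    tie_tol: float = 1e-9,
) -> pd.Series:
    """Count cells per class under the >50 %-inside stereology rule.

    A cell is counted iff more than half of its (circular) nucleus footprint
    lies inside the box; exactly-half (equivocal) cells are counted only when
    the nucleus intersects the top or right box edge.
    """
    x0, y0, x1, y1 = box.bounds_px
    counts: dict = {}
    for rec in cells.itertuples(index=False):
        r = float(np.sqrt(rec.area_px / np.pi))
        frac = nucleus_inside_fraction(rec.x_px, rec.y_px, r, box.bounds_px)
        if frac > 0.5 + tie_tol:
            counted = True
        elif abs(frac - 0.5) <= tie_tol:
            touches_top = abs(rec.y_px - y0) < r and x0 - r < rec.x_px < x1 + r
            touches_right = abs(rec.x_px - x1) < r and y0 - r < rec.y_px < y1 + r
            counted = touches_top or touches_right
        else:
            counted = False
        if counted:
            counts[rec.cell_class] = counts.get(rec.cell_class, 0) + 1
    return pd.Series(counts, dtype=int)


def filter_macrophage_objects(
    object_areas_um2: np.ndarray, mean_luminal_nucleus_area_um2: Optional[float]
) -> np.ndarray:
    """Keep marker objects at least half the mean luminal nucleus area.

    With no luminal nuclei in the box the threshold is undefined and the
    filter is skipped with a warning.
    """
    areas = np.asarray(object_areas_um2, dtype=float)
    if mean_luminal_nucleus_area_um2 is None or not np.isfinite(
        mean_luminal_nucleus_area_um2
    ):
        warnings.warn(
            "no luminal nuclei in box; macrophage size filter skipped",
            stacklevel=2,
        )
        return areas
    return areas[areas >= 0.5 * mean_luminal_nucleus_area_um2]


@dataclasses.dataclass
class DensityRecord:
    name: str
    value: Optional[float]
    units: str
    defined: bool = True


def immune_densities(box: CountBox) -> List[DensityRecord]:
    """Per-box immune densities with the protocol's normalisations.

    Stromal macrophages per mm^2 intralobular stroma; epithelial T cells per
    100 luminal nuclei; stromal T cells per mm^2 total stroma.  Records with a
    zero normalising quantity are flagged undefined.
    """
    out: List[DensityRecord] = []
    mac = int(box.counts.get("macrophage_stromal", 0))
    if box.intralobular_stroma_mm2 > 0:
        out.append(
            DensityRecord(
                "stromal_mac_per_mm2",
                mac / box.intralobular_stroma_mm2,
                "per_mm2_intralobular_stroma",
            )
        )
    else:
        out.append(DensityRecord("stromal_mac_per_mm2", None, "per_mm2", False))
    t_epi = int(box.counts.get("t_cell_epithelial", 0))
    if box.luminal_count > 0:
        out.append(
            DensityRecord(
                "t_epi_per100", 100.0 * t_epi / box.luminal_count,
                "per_100_luminal_nuclei",
            )
        )
    else:
        out.append(DensityRecord("t_epi_per100", None, "per_100", False))
    t_str = int(box.counts.get("t_cell_stromal", 0))
    if box.total_stroma_mm2 > 0:
        out.append(
            DensityRecord(
                "t_stromal_per_mm2", t_str / box.total_stroma_mm2,
                "per_mm2_total_stroma",
            )
        )
    else:
        out.append(DensityRecord("t_stromal_per_mm2", None, "per_mm2", False))
    return out


# ---------------------------------------------------------------------------
# Tertiary lymphoid structures
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TLSRecord:
    b_hull: object  # shapely polygon of the B-cell cluster
    b_count: int
    t_adjacent: int
    t_interior_fraction: float
    qualifies: bool


def detect_tls(
    b_cells: np.ndarray,
    t_cells: np.ndarray,
    tissue_area_mm2: float,
    pixel_size_um: float = 1.0,
    cluster_radius_um: float = 30.0,
    min_b_cells: int = 20,
    annulus_um: float = 50.0,
    min_adjacent_t: int = 20,
    max_interior_t_fraction: float = 0.30,
) -> Tuple[List[TLSRecord], float]:
    """Detect B-cell aggregates with a distinct adjacent T-cell zone.

    B-cell clusters are found by density clustering (DBSCAN, radius
    ``cluster_radius_um``, at least ``min_b_cells`` members).  A cluster
    qualifies as a tertiary lymphoid structure when at least
    ``min_adjacent_t`` T cells lie within ``annulus_um`` outside the cluster
    hull while the hull interior stays predominantly B
    (interior T fraction < ``max_interior_t_fraction``).  Returns the records
    and the qualifying density per mm^2 of analysed tissue.
    """
    if tissue_area_mm2 <= 0:
        raise ValueError("tissue area must be positive")
    b_cells = np.asarray(b_cells, dtype=float).reshape(-1, 2)
    t_cells = np.asarray(t_cells, dtype=float).reshape(-1, 2)
    records: List[TLSRecord] = []
    if len(b_cells) >= min_b_cells:
        eps_px = cluster_radius_um / pixel_size_um
        labels = DBSCAN(eps=eps_px, min_samples=5).fit_predict(b_cells)
        from shapely.geometry import MultiPoint

        for lab in np.unique(labels[labels >= 0]):
            members = b_cells[labels == lab]
            if len(members) < min_b_cells:
                continue
            hull = MultiPoint([tuple(p) for p in members]).convex_hull
            ann_px = annulus_um / pixel_size_um
            t_pts = [Point(p) for p in t_cells]
            inside = [p for p in t_pts if hull.contains(p)]
            adjacent = [
                p
                for p in t_pts
                if not hull.contains(p) and hull.distance(p) <= ann_px
            ]
            n_interior_cells = len(inside) + len(members)
            t_frac = len(inside) / n_interior_cells if n_interior_cells else 0.0
            qualifies = (
                len(adjacent) >= min_adjacent_t
                and t_frac < max_interior_t_fraction
            )
            records.append(
                TLSRecord(hull, len(members), len(adjacent), t_frac, qualifies)
            )
    density = sum(r.qualifies for r in records) / tissue_area_mm2
    return records, density
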