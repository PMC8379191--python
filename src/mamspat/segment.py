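"""Classical H-DAB nuclei and epithelium segmentation.

Produces the two mask products the downstream analyses consume: a three-class
nuclei segmentation (Ki67+ / Ki67- / background label maps) and a binary
epithelium mask, plus per-nucleus centroid records.  The segmenter is a
deterministic colour-deconvolution / watershed pipeline honouring the same
output contract as a semantic-segmentation network: callers only ever see the
masks and the centroid table.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.morphology import closing, disk, remove_small_holes, remove_small_objects
from skimage.segmentation import watershed

from .stain import StainModel, fit_concentrations, rgb_to_od


@dataclasses.dataclass
class SegmentationParams:
    """Tunables of the classical segmenter.

    Pixel-unit defaults are stated for the package's default quarter-scale
    synthetic fields (0.91 um/px); scale them with pixel size for other
    supports.
    """

    smooth_sigma: float = 1.0  # Gaussian smoothing of concentration maps (px)
    beta: float = 0.15  # OD magnitude defining tissue pixels
    conc_floor: float = 0.15  # absolute concentration threshold floor
    # "half_peak" thresholds each channel at half its robust (99th pct) peak,
    # cutting both chromogens at the same relative height of the blur profile
    # so pixel areas stay comparable between channels; "otsu" is available but
    # its cut height varies with the channel's class mix
    threshold_method: str = "half_peak"
    min_nucleus_area: float = 12.0  # px^2; debris rejection
    max_nucleus_area: float = 2000.0  # px^2; sheet rejection
    watershed_min_distance: int = 5  # px between watershed seeds
    kde_bandwidth: float = 6.0  # px; nuclear-density bandwidth for epithelium
    kde_threshold: float = 0.12  # density threshold (concentration-mass units)
    closing_radius: int = 4  # px
    hole_area: int = 4000  # px^2; lumina smaller than this are filled
    min_region: int = 500  # px^2; smallest epithelial component kept


@dataclasses.dataclass
class MaskSet:
    """Paired segmentation products for one field."""

    epithelium: Optional[np.ndarray]  # bool (H, W)
    ki67_pos: Optional[np.ndarray]  # int labels (H, W)
    ki67_neg: Optional[np.ndarray]  # int labels (H, W)
    field_id: str = "field"
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        shapes = {
            m.shape
            for m in (self.epithelium, self.ki67_pos, self.ki67_neg)
            if m is not None
        }
        if len(shapes) > 1:
            raise ValueError("all masks must share the field dimensions")


class SegmentationError(ValueError):
    pass


def _rgb_array(image) -> np.ndarray:
    arr = getattr(image, "rgb", image)
    arr = np.asarray(arr)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise SegmentationError("expected an RGB image (H, W, 3)")
    return arr


def _threshold(values: np.ndarray, floor: float, method: str = "half_peak") -> float:
    """Channel threshold over tissue values, never below the absolute floor."""
    values = values[values > 0]
    if values.size < 2 or np.ptp(values) < 1e-9:
        return floor
    if method == "half_peak":
        return max(0.5 * float(np.percentile(values, 99)), floor)
    if method == "otsu":
        return max(float(threshold_otsu(values)), floor)
    raise ValueError(f"unknown threshold method {method!r}")


def _label_objects(
    mask: np.ndarray, params: SegmentationParams
) -> np.ndarray:
    """Connected components split by distance-transform watershed."""
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32)
    distance = ndimage.distance_transform_edt(mask)
    peaks = peak_local_max(
        distance,
        min_distance=params.watershed_min_distance,
        labels=mask,
        exclude_border=False,
    )
    seeds = np.zeros(mask.shape, dtype=np.int32)
    for k, (r, c) in enumerate(peaks, start=1):
        seeds[r, c] = k
    if seeds.max() == 0:
        labels, _ = ndimage.label(mask)
        return labels.astype(np.int32)
    labels = watershed(-distance, seeds, mask=mask)
    return labels.astype(np.int32)


def _area_filter(labels: np.ndarray, lo: float, hi: float) -> np.ndarray:
    if labels.max() == 0:
        return labels
    areas = np.bincount(labels.ravel())
    bad = (areas < lo) | (areas > hi)
    bad[0] = False
    out = labels.copy()
    out[bad[labels]] = 0
    return _relabel(out)


def _relabel(labels: np.ndarray) -> np.ndarray:
    ids = np.unique(labels)
    ids = ids[ids > 0]
    lut = np.zeros(labels.max() + 1, dtype=np.int32)
    lut[ids] = np.arange(1, len(ids) + 1, dtype=np.int32)
    return lut[labels]


def segment_nuclei(
    image,
    stain: StainModel,
    params: Optional[SegmentationParams] = None,
) -> MaskSet:
    """Segment Ki67+ (DAB) and Ki67- (haematoxylin-only) nuclear objects.

    The normalised image is deconvolved to haematoxylin/DAB concentration
    maps, each smoothed and thresholded (Otsu within tissue with an absolute
    floor); DAB-positive objects become Ki67+ nuclei, haematoxylin-only
    objects Ki67-; touching nuclei are split by distance-transform watershed;
    objects outside the area band are discarded.  DAB wins overlaps (a Ki67+
    nucleus is counterstained too).
    """
    params = params or SegmentationParams()
    rgb = _rgb_array(image)
    od = rgb_to_od(rgb, stain.background_intensity)
    if not np.any(np.linalg.norm(od, axis=-1) > params.beta):
        raise SegmentationError("image appears empty: no tissue above OD threshold")
    conc = fit_concentrations(od.reshape(-1, 3), stain.stain_matrix)
    haem = conc[:, 0].reshape(od.shape[:2])
    dab = conc[:, 1].reshape(od.shape[:2])
    if params.smooth_sigma > 0:
        haem = ndimage.gaussian_filter(haem, params.smooth_sigma)
        dab = ndimage.gaussian_filter(dab, params.smooth_sigma)

    tissue = np.linalg.norm(od, axis=-1) > params.beta
    thr_dab = _threshold(dab[tissue], params.conc_floor, params.threshold_method)
    thr_haem = _threshold(haem[tissue], params.conc_floor, params.threshold_method)
    dab_mask = dab > thr_dab
    haem_mask = (haem > thr_haem) & ~dab_mask

    pos = _area_filter(
        _label_objects(dab_mask, params),
        params.min_nucleus_area,
        params.max_nucleus_area,
    )
    neg = _area_filter(
        _label_objects(haem_mask, params),
        params.min_nucleus_area,
        params.max_nucleus_area,
    )
    neg[pos > 0] = 0  # exclusivity: DAB dominates
    neg = _relabel(neg)
    pixel_size = getattr(image, "pixel_size_um", 1.0)
    return MaskSet(
        epithelium=None,
        ki67_pos=pos,
        ki67_neg=neg,
        field_id=getattr(image, "field_id", "field"),
        pixel_size_um=pixel_size,
    )


def segment_epithelium(
    image,
    stain: StainModel,
    params: Optional[SegmentationParams] = None,
    nuclei: Optional[MaskSet] = None,
) -> np.ndarray:
    """Binary epithelium mask from the nuclear-density field.

    A Gaussian density of all nuclei pixels is thresholded, morphologically
    closed, small holes (lumina) filled and small components removed.  The
    operators are isotropic, so the mask commutes with right-angle rotations.
    """
    params = params or SegmentationParams()
    if nuclei is None:
        nuclei = segment_nuclei(image, stain, params)
    nuc = (nuclei.ki67_pos > 0) | (nuclei.ki67_neg > 0)
    if not nuc.any():
        return np.zeros(nuc.shape, dtype=bool)
    density = ndimage.gaussian_filter(nuc.astype(float), params.kde_bandwidth)
    mask = density > params.kde_threshold
    mask = closing(mask, disk(params.closing_radius))
    mask = remove_small_holes(mask, max_size=params.hole_area)
    # max_size here is the largest object size removed, i.e. components up to
    # min_region pixels are dropped
    mask = remove_small_objects(mask, max_size=params.min_region)
    return mask


def segment_field(
    image,
    stain: StainModel,
    params: Optional[SegmentationParams] = None,
) -> MaskSet:
    """Full MaskSet: nuclei label maps plus epithelium mask."""
    params = params or SegmentationParams()
    nuclei = segment_nuclei(image, stain, params)
    epi = segment_epithelium(image, stain, params, nuclei=nuclei)
    return dataclasses.replace(nuclei, epithelium=epi)


def extract_centroids(masks: MaskSet) -> pd.DataFrame:
    """One record per nucleus label: centroid, area, phenotype, epithelial flag.

    Centroids are unweighted pixel centroids; a nucleus is epithelial when
    its centroid pixel falls inside the epithelium mask.  Nuclei touching the
    field border are kept and flagged.
    """
    rows = []
    h = w = None
    for phenotype, labels in (("ki67_pos", masks.ki67_pos), ("ki67_neg", masks.ki67_neg)):
        if labels is None:
            continue
        h, w = labels.shape
        ids = np.unique(labels)
        ids = ids[ids > 0]
        if len(ids) == 0:
            continue
        cy, cx = np.array(
            ndimage.center_of_mass(np.ones_like(labels), labels, ids)
        ).T
        areas = ndimage.sum_labels(np.ones_like(labels), labels, ids)
        slices = ndimage.find_objects(labels)
        for nid, x, y, area in zip(ids, cx, cy, areas):
            sl = slices[nid - 1]
            touches = (
                sl[0].start == 0
                or sl[1].start == 0
                or sl[0].stop == h
                or sl[1].stop == w
            )
            if masks.epithelium is not None:
                ri = min(int(round(y)), h - 1)
                ci = min(int(round(x)), w - 1)
                epithelial = bool(masks.epithelium[ri, ci])
            else:
                epithelial = False
            rows.append(
                dict(
                    field_id=masks.field_id,
                    nucleus_id=int(nid),
                    phenotype=phenotype,
                    x_px=float(x),
                    y_px=float(y),
                    area_px=float(area),
                    epithelial=epithelial,
                    touches_border=bool(touches),
                )
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "field_id",
            "nucleus_id",
            "phenotype",
            "x_px",
            "y_px",
            "area_px",
            "epithelial",
            "touches_border",
        ],
    )
    return table.sort_values(["phenotype", "nucleus_id"]).reset_index(drop=True)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two boolean masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom
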