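"""Macenko stain-matrix estimation and H-DAB colour normalisation.

Brightfield IHC colour follows the Beer-Lambert law: transmitted intensity
``I = I0 * exp(-S @ c)`` where the columns of ``S`` are the unit optical-density
(OD) vectors of the stains (haematoxylin and DAB here) and ``c`` their
per-pixel concentrations.  The Macenko procedure estimates ``S`` from an image
by projecting tissue-pixel ODs onto the plane spanned by the top two principal
axes of the OD cloud and taking extreme percentile angles within that plane.
Normalisation refits concentrations against the source matrix, rescales them by
robust maxima, and re-renders through a reference matrix.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter
from scipy.optimize import nnls

# Published H-DAB unit OD vectors (columns: haematoxylin, DAB).
DEFAULT_HDAB_MATRIX = np.array(
    [[0.65, 0.27],
     [0.70, 0.57],
     [0.29, 0.78]]
)


class StainEstimationError(ValueError):
    """Raised when too few tissue pixels survive the OD magnitude filter."""


@dataclasses.dataclass
class StainModel:
    """A fitted two-stain colour model.

    Attributes
    ----------
    stain_matrix:
        3x2 array; columns are unit OD vectors (haematoxylin first, DAB second).
    max_concentrations:
        Robust (99th percentile) concentration per stain, used for
        intensity-range matching during normalisation.
    background_intensity:
        I0, the incident (white) intensity per the 8-bit convention.
    """

    stain_matrix: np.ndarray
    max_concentrations: np.ndarray
    background_intensity: float = 255.0

    def __post_init__(self) -> None:
        self.stain_matrix = np.asarray(self.stain_matrix, dtype=float)
        self.max_concentrations = np.asarray(self.max_concentrations, dtype=float)
        if self.stain_matrix.shape != (3, 2):
            raise ValueError("stain_matrix must be 3x2 (RGB x [haem, DAB])")
        norms = np.linalg.norm(self.stain_matrix, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("stain_matrix columns must be unit-norm")

    def to_yaml(self, path) -> None:
        payload = {
            "stain_matrix": [[float(v) for v in row] for row in self.stain_matrix],
            "max_concentrations": [float(v) for v in self.max_concentrations],
            "background_intensity": float(self.background_intensity),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)

    @classmethod
    def from_yaml(cls, path) -> "StainModel":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(
            stain_matrix=np.array(payload["stain_matrix"], dtype=float),
            max_concentrations=np.array(payload["max_concentrations"], dtype=float),
            background_intensity=float(payload["background_intensity"]),
        )

    @classmethod
    def default_hdab(cls, background_intensity: float = 255.0) -> "StainModel":
        s = DEFAULT_HDAB_MATRIX / np.linalg.norm(DEFAULT_HDAB_MATRIX, axis=0)
        return cls(s, np.array([1.0, 1.0]), background_intensity)


def rgb_to_od(image: np.ndarray, background_intensity: float = 255.0) -> np.ndarray:
    """Convert intensities to optical density, OD = -log((I + 1) / I0).

    The +1 offset guards log(0) at fully absorbed pixels; it makes background
    pixels come out at -log((I0+1)/I0), a negligible ~ -0.004 OD.
    """
    if background_intensity <= 0:
        raise ValueError("background_intensity must be positive")
    img = np.asarray(image, dtype=float)
    return -np.log((img + 1.0) / background_intensity)


def od_to_rgb(od: np.ndarray, background_intensity: float = 255.0) -> np.ndarray:
    """Invert :func:`rgb_to_od` exactly, up to clamping into [0, I0]."""
    intensity = background_intensity * np.exp(-np.asarray(od, dtype=float)) - 1.0
    return np.clip(intensity, 0.0, background_intensity)


def _tissue_pixels(od_flat: np.ndarray, beta: float) -> np.ndarray:
    return od_flat[np.linalg.norm(od_flat, axis=1) > beta]


def estimate_stain_matrix(
    image: np.ndarray,
    background_intensity: float = 255.0,
    beta: float = 0.15,
    alpha: float = 1.0,
    smooth_sigma: float = 1.5,
    min_tissue_pixels: int = 100,
) -> StainModel:
    """Estimate the H-DAB stain matrix of an RGB field by the Macenko method.

    Parameters
    ----------
    beta:
        OD magnitude threshold separating tissue from background pixels.
    alpha:
        Robust percentile (in percent) for the extreme angles in the stain
        plane; the alpha-th and (100-alpha)-th percentiles are used.
    smooth_sigma:
        Light Gaussian pre-smoothing of the OD maps (pixels).  Per-pixel OD
        noise biases the extreme percentile angles outward by roughly twice
        the per-pixel angular noise; averaging over the smoothing kernel
        suppresses this without moving the interior colour statistics.
    """
    od = rgb_to_od(image, background_intensity)
    if od.ndim != 3 or od.shape[2] != 3:
        raise ValueError("expected an RGB image (H, W, 3)")
    if smooth_sigma > 0:
        od = np.stack(
            [gaussian_filter(od[..., k], smooth_sigma) for k in range(3)], axis=-1
        )
    od_flat = od.reshape(-1, 3)
    tissue = _tissue_pixels(od_flat, beta)
    if tissue.shape[0] < min_tissue_pixels:
        raise StainEstimationError(
            f"only {tissue.shape[0]} pixels exceed the OD threshold beta={beta}; "
            f"need at least {min_tissue_pixels} tissue pixels"
        )

    # Plane of the top-2 eigenvectors of the (uncentred) OD scatter.
    _, _, vt = np.linalg.svd(tissue, full_matrices=False)
    basis = vt[:2].T  # 3x2
    # orient the basis so projections have positive first coordinate
    if np.sum(tissue @ basis[:, 0]) < 0:
        basis[:, 0] *= -1
    if np.sum(np.abs(tissue @ basis[:, 1])) > 0 and basis[0, 1] < 0:
        basis[:, 1] *= -1

    proj = tissue @ basis  # N x 2
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(phi, [alpha, 100.0 - alpha])

    def back_project(angle: float) -> np.ndarray:
        v = basis @ np.array([np.cos(angle), np.sin(angle)])
        if v.sum() < 0:
            v = -v
        v = np.clip(v, 0.0, None)
        n = np.linalg.norm(v)
        if n == 0:
            raise StainEstimationError("degenerate stain vector (all-negative OD)")
        return v / n

    v1, v2 = back_project(lo), back_project(hi)

    # Haematoxylin absorbs red light strongly -> larger R-component of the
    # unit OD vector; DAB is brown with dominant blue-channel OD.
    if v1[0] >= v2[0]:
        haem, dab = v1, v2
    else:
        haem, dab = v2, v1
    matrix = np.column_stack([haem, dab])

    conc = fit_concentrations(od_flat, matrix)
    max_c = np.percentile(conc, 99.0, axis=0)
    max_c = np.maximum(max_c, 1e-6)
    return StainModel(matrix, max_c, background_intensity)


def fit_concentrations(
    od_flat: np.ndarray, stain_matrix: np.ndarray, nonnegative: bool = False
) -> np.ndarray:
    """Per-pixel stain concentrations from OD vectors.

    Default is the clipped pseudo-inverse (the original Macenko fit); exact
    non-negative least squares is available behind ``nonnegative=True``.
    """
    if np.linalg.matrix_rank(stain_matrix) < 2:
        raise ValueError("stain matrix is singular; cannot fit concentrations")
    if nonnegative:
        out = np.empty((od_flat.shape[0], 2))
        for i, row in enumerate(od_flat):
            out[i], _ = nnls(stain_matrix, np.clip(row, 0.0, None))
        return out
    conc = od_flat @ np.linalg.pinv(stain_matrix).T
    return np.clip(conc, 0.0, None)


def normalize_to_reference(
    image: np.ndarray,
    source: StainModel,
    reference: StainModel,
    nonnegative: bool = False,
) -> np.ndarray:
    """Re-render a field's stain concentrations through a reference model.

    Concentrations are fitted against the source stain matrix, rescaled
    per-stain by reference/source robust maxima, and pushed back through the
    reference matrix.  With ``source == reference`` this is the identity up to
    one intensity unit (concentration clipping and 8-bit rounding).
    """
    od = rgb_to_od(image, source.background_intensity)
    shape = od.shape
    conc = fit_concentrations(od.reshape(-1, 3), source.stain_matrix, nonnegative)
    scale = reference.max_concentrations / source.max_concentrations
    conc = conc * scale[None, :]
    od_out = conc @ reference.stain_matrix.T
    out = od_to_rgb(od_out.reshape(shape), reference.background_intensity)
    if np.issubdtype(np.asarray(image).dtype, np.integer):
        out = np.rint(out).astype(np.asarray(image).dtype)
    return out
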