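"""Synthetic H-DAB histology fields with planted ground truth.

Emulates IHC fields of the developing ruminant mammary gland: lobulated
terminal-duct units (ellipses containing ring-shaped two-layer ductules) along
a growth axis, Ki67 positivity polarised toward the leading edge, regularly
spaced intraepithelial macrophages along ducts, centrally enriched stromal
macrophages, intraepithelial/stromal T cells, and B/T aggregates organised as
tertiary lymphoid structures.  Fields are rendered through Beer-Lambert stain
mixing (haematoxylin counterstain plus DAB for the active marker) so that the
whole downstream pipeline — stain normalisation, segmentation, spatial
statistics, morphometry — can be exercised against known planted parameters.

Two spatial supports are provided, mirroring the two measurement scales of
the source assays: a render-scale preset (sub-micron pixels, single field)
for stain/segmentation/hotspot work, and a coarser slide-scale preset
(several mm across) for count-box and TLS morphometry, where 400 x 230 um
sampling frames only make sense against mm-scale lobules.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit, logit

from .core import ImageField
from .stain import DEFAULT_HDAB_MATRIX

EPITHELIAL_CLASSES = ("luminal", "basal")

# Nuclear geometry (micrometres).  Luminal epithelial nuclei are the largest;
# lymphocyte nuclei are small and dense.
NUCLEUS_RADIUS_UM = {
    "luminal": 4.1,
    "basal": 3.2,
    "macrophage_intraepithelial": 3.6,
    "macrophage_stromal": 3.6,
    "t_cell_epithelial": 2.6,
    "t_cell_stromal": 2.6,
    "b_cell": 2.6,
}

# Stain concentrations used by the renderer (OD-scale, dimensionless).
HAEM_NUCLEUS_CONC = 0.85
HAEM_CORE_CONC = 0.70  # counterstain visible in the core of DAB+ nuclei
DAB_CONC = 1.10
DAB_CORE_FRACTION = 0.5  # haematoxylin restricted to this fraction of radius


class ConfigurationError(ValueError):
    pass


@dataclasses.dataclass
class SimulationConfig:
    """Planted parameters for one synthetic field.

    Geometry is specified in micrometres and converted through
    ``pixel_size_um``; the default render-scale field is a quarter linear
    scale of a 6322 x 4581 px, 1.5 mm^2 scanner field (0.2276 um/px at full
    scale, hence 0.9104 um/px here).
    """

    seed: int = 0
    field_width_px: int = 1580
    field_height_px: int = 1145
    pixel_size_um: float = 0.9104
    n_lobules: int = 4
    lobule_axis: Tuple[float, float] = (1.0, 0.0)  # (dx, dy), unit growth axis
    lobule_semiaxes_um: Tuple[float, float] = (200.0, 146.0)
    ductule_radius_um: float = 33.0
    ki67_p0: float = 0.30
    ki67_slope: float = 4.0
    macrophage_spacing_um: float = 60.0
    macrophage_spacing_cv: float = 0.15
    stromal_mac_density_central: float = 200.0  # cells / mm^2 central stroma
    stromal_mac_density_peripheral: float = 100.0
    central_margin_um: float = 200.0  # stroma further than this from fat = central
    t_epi_per100: float = 2.0  # intraepithelial T cells per 100 luminal nuclei
    t_stromal_density: float = 150.0  # cells / mm^2 stroma
    n_tls: int = 0
    tls_b_cells: int = 60
    tls_t_cells: int = 80
    stain_matrix: np.ndarray = dataclasses.field(
        default_factory=lambda: DEFAULT_HDAB_MATRIX.copy()
    )
    background_intensity: float = 255.0
    od_noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.field_width_px <= 0 or self.field_height_px <= 0:
            raise ConfigurationError("field dimensions must be positive")
        if self.pixel_size_um <= 0:
            raise ConfigurationError("pixel_size_um must be positive")
        if not (0.0 <= self.ki67_p0 <= 1.0):
            raise ConfigurationError("ki67_p0 must lie in [0, 1]")
        for name in (
            "stromal_mac_density_central",
            "stromal_mac_density_peripheral",
            "t_stromal_density",
            "t_epi_per100",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        self.stain_matrix = np.asarray(self.stain_matrix, dtype=float)
        if self.stain_matrix.shape != (3, 2):
            raise ConfigurationError("stain_matrix must be 3x2")
        if np.any(self.stain_matrix < 0):
            raise ConfigurationError("stain_matrix entries must be non-negative")
        self.stain_matrix = self.stain_matrix / np.linalg.norm(
            self.stain_matrix, axis=0
        )
        axis = np.asarray(self.lobule_axis, dtype=float)
        self.lobule_axis = tuple(axis / np.linalg.norm(axis))

    @property
    def px_per_um(self) -> float:
        return 1.0 / self.pixel_size_um

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


# Age-group presets: young lambs show higher baseline proliferation and wider
# inter-macrophage spacing than peri-pubertal animals.
AGE_PRESETS: Dict[str, Dict[str, float]] = {
    "young": {"ki67_p0": 0.30, "macrophage_spacing_um": 60.0},
    "old": {"ki67_p0": 0.12, "macrophage_spacing_um": 20.0},
}


def slide_scale_config(seed: int = 0, **kw) -> SimulationConfig:
    """Coarse whole-slide-like support for count-box / TLS morphometry."""
    defaults = dict(
        seed=seed,
        pixel_size_um=3.6416,
        field_width_px=1580,
        field_height_px=1145,
        n_lobules=3,
        lobule_semiaxes_um=(800.0, 580.0),
        n_tls=2,
        od_noise_sd=0.02,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


@dataclasses.dataclass
class DuctTrace:
    """An ordered duct polyline with macrophage arc-length positions."""

    polyline_px: np.ndarray  # (N, 2) as (x, y)
    arc_positions_um: np.ndarray  # sorted arc-length positions of macrophages
    field_id: str = "field"
    duct_id: int = 0

    def __post_init__(self) -> None:
        self.polyline_px = np.asarray(self.polyline_px, dtype=float)
        self.arc_positions_um = np.asarray(self.arc_positions_um, dtype=float)
        if np.any(np.diff(self.arc_positions_um) < 0):
            raise ValueError("arc positions must be non-decreasing")

    def vertex_arclengths_um(self, pixel_size_um: float) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.polyline_px, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)]) * pixel_size_um

    def point_at(self, s_um: float, pixel_size_um: float) -> np.ndarray:
        cum = self.vertex_arclengths_um(pixel_size_um)
        x = np.interp(s_um, cum, self.polyline_px[:, 0])
        y = np.interp(s_um, cum, self.polyline_px[:, 1])
        return np.array([x, y])


@dataclasses.dataclass
class GroundTruth:
    """Planted cells, masks and geometry for one synthetic field."""

    cells: pd.DataFrame
    epithelium_mask: np.ndarray
    stroma_mask: np.ndarray
    central_mask: np.ndarray
    lobules: List[dict]
    ducts: List[DuctTrace]
    config: SimulationConfig
    age_group: str = "young"

    @property
    def field_shape(self) -> Tuple[int, int]:
        return self.config.field_height_px, self.config.field_width_px

    def cells_of(self, *classes: str) -> pd.DataFrame:
        return self.cells[self.cells["cell_class"].isin(classes)]


CELL_COLUMNS = [
    "cell_id",
    "cell_class",
    "x_px",
    "y_px",
    "area_px",
    "ki67",
    "basement_contact_fraction",
    "lobule_id",
    "axis_u",
]


def _empty_cells() -> pd.DataFrame:
    return pd.DataFrame(columns=CELL_COLUMNS).astype(
        {
            "cell_id": int,
            "cell_class": str,
            "x_px": float,
            "y_px": float,
            "area_px": float,
            "ki67": bool,
            "basement_contact_fraction": float,
            "lobule_id": int,
            "axis_u": float,
        }
    )


def _ellipse_mask(shape, center, semiaxes, axis) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    dx = xx - center[0]
    dy = yy - center[1]
    ax, ay = axis
    along = dx * ax + dy * ay
    across = -dx * ay + dy * ax
    a, b = semiaxes
    return (along / a) ** 2 + (across / b) ** 2 <= 1.0


def _disc_indices(shape, cx, cy, r):
    h, w = shape
    x0, x1 = int(np.floor(cx - r)), int(np.ceil(cx + r)) + 1
    y0, y1 = int(np.floor(cy - r)), int(np.ceil(cy + r)) + 1
    x0, y0 = max(x0, 0), max(y0, 0)
    x1, y1 = min(x1, w), min(y1, h)
    if x0 >= x1 or y0 >= y1:
        return None
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
    return yy[inside], xx[inside]


def _lobule_u(pos_xy: np.ndarray, lobule: dict) -> np.ndarray:
    """Normalised axis coordinate in [0, 1]; 1 = leading (distal) edge."""
    axis = np.asarray(lobule["axis"])
    rel = pos_xy - np.asarray(lobule["center"])
    along = rel @ axis
    return np.clip(along / (2.0 * lobule["semiaxes"][0]) + 0.5, 0.0, 1.0)


def generate_field(config: SimulationConfig, age_group: str = "young") -> GroundTruth:
    """Generate a synthetic field's planted geometry and cell records.

    ``age_group`` selects the preset overrides in :data:`AGE_PRESETS`
    (young = higher Ki67 baseline, wider macrophage spacing); all other
    parameters come from ``config`` unchanged.  Deterministic given
    ``(config.seed, config, age_group)``.
    """
    if age_group not in AGE_PRESETS:
        raise ConfigurationError(f"unknown age_group {age_group!r}")
    config = config.replace(**AGE_PRESETS[age_group])
    rng_geom, rng_ki67, rng_mac, rng_imm, rng_tls = (
        np.random.default_rng(s)
        for s in np.random.SeedSequence(config.seed).spawn(5)
    )
    h, w = config.field_height_px, config.field_width_px
    shape = (h, w)
    px = config.px_per_um
    axis = np.asarray(config.lobule_axis)
    a_px = config.lobule_semiaxes_um[0] * px
    b_px = config.lobule_semiaxes_um[1] * px

    # --- lobules spread along the growth axis with lateral jitter ----------
    lobules: List[dict] = []
    epithelium = np.zeros(shape, dtype=bool)
    parenchyma = np.zeros(shape, dtype=bool)
    central = np.zeros(shape, dtype=bool)
    records: List[dict] = []
    ducts: List[DuctTrace] = []
    next_id = 0

    if config.n_lobules > 0:
        # place lobule centres on a jittered line spanning the field
        margin_x = min(a_px * 1.05, w / 2 - 1)
        margin_y = min(b_px * 1.05, h / 2 - 1)
        xs = np.linspace(margin_x, w - margin_x, config.n_lobules)
        for i, cx in enumerate(xs):
            cy = h / 2 + (rng_geom.uniform(-1, 1)) * max(h / 2 - margin_y, 0) * 0.6
            lob = {
                "lobule_id": i,
                "center": (float(cx), float(cy)),
                "semiaxes": (float(a_px), float(b_px)),
                "axis": tuple(axis),
            }
            lobules.append(lob)
            ell = _ellipse_mask(shape, lob["center"], lob["semiaxes"], axis)
            parenchyma |= ell
            m_px = config.central_margin_um * px
            sa, sb = a_px - m_px, b_px - m_px
            if sa > 0 and sb > 0:
                central |= _ellipse_mask(shape, lob["center"], (sa, sb), axis)

    # --- ductules: jittered hex-ish grid of ring ductules inside each lobule
    duct_r = config.ductule_radius_um * px
    for lob in lobules:
        cx, cy = lob["center"]
        spacing = duct_r * 2.5
        nx = int(2 * a_px // spacing) + 1
        ny = int(2 * b_px // spacing) + 1
        ductule_centers = []
        for ix in range(nx):
            for iy in range(ny):
                # offsets symmetric about the lobule centre so the leading and
                # trailing halves carry the same expected ductule density
                ox = (ix - (nx - 1) / 2 + ((iy % 2) - 0.5) * 0.5) * spacing
                oy = (iy - (ny - 1) / 2) * spacing * 0.9
                ox += rng_geom.uniform(-0.12, 0.12) * spacing
                oy += rng_geom.uniform(-0.12, 0.12) * spacing
                # rotate offsets into the lobule frame
                gx = cx + ox * axis[0] - oy * axis[1]
                gy = cy + ox * axis[1] + oy * axis[0]
                fa = (ox / (a_px - duct_r * 1.1)) ** 2 + (
                    oy / (b_px - duct_r * 1.1)
                ) ** 2
                if fa <= 1.0 and 0 <= gx < w and 0 <= gy < h:
                    ductule_centers.append((gx, gy))
        for gx, gy in ductule_centers:
            idx = _disc_indices(shape, gx, gy, duct_r)
            if idx is not None:
                epithelium[idx] = True
            u_center = float(_lobule_u(np.array([[gx, gy]]), lob)[0])
            for layer, ring_frac, cls in (
                ("luminal", 0.50, "luminal"),
                ("basal", 0.82, "basal"),
            ):
                r_nuc = NUCLEUS_RADIUS_UM[cls] * px
                ring_r = duct_r * ring_frac
                n_nuc = max(int(2 * np.pi * ring_r / (3.0 * r_nuc)), 3)
                theta0 = rng_geom.uniform(0, 2 * np.pi)
                for k in range(n_nuc):
                    th = theta0 + 2 * np.pi * k / n_nuc
                    th += rng_geom.uniform(-0.12, 0.12) * 2 * np.pi / n_nuc
                    x = gx + ring_r * np.cos(th)
                    y = gy + ring_r * np.sin(th)
                    if not (0 <= x < w and 0 <= y < h):
                        continue
                    records.append(
                        dict(
                            cell_id=next_id,
                            cell_class=cls,
                            x_px=x,
                            y_px=y,
                            area_px=np.pi * r_nuc**2,
                            ki67=False,
                            basement_contact_fraction=1.0 if cls == "basal" else 0.1,
                            lobule_id=lob["lobule_id"],
                            axis_u=float(
                                _lobule_u(np.array([[x, y]]), lob)[0]
                            ),
                        )
                    )
                    next_id += 1
            del u_center

    stroma = parenchyma & ~epithelium
    central &= stroma

    # --- ducts with periodic intraepithelial macrophages -------------------
    for lob in lobules:
        cx, cy = lob["center"]
        n_pts = 64
        t = np.linspace(-0.9, 0.9, n_pts)
        lateral = 0.18 * b_px * np.sin(
            2 * np.pi * 1.5 * (t + 1) / 2 + rng_mac.uniform(0, 2 * np.pi)
        )
        px_along = t * a_px
        pts = np.stack(
            [
                cx + px_along * axis[0] - lateral * axis[1],
                cy + px_along * axis[1] + lateral * axis[0],
            ],
            axis=1,
        )
        pts[:, 0] = np.clip(pts[:, 0], 0, w - 1)
        pts[:, 1] = np.clip(pts[:, 1], 0, h - 1)
        trace = DuctTrace(pts, np.empty(0), duct_id=lob["lobule_id"])
        total_um = trace.vertex_arclengths_um(config.pixel_size_um)[-1]
        spacing = config.macrophage_spacing_um
        sd = config.macrophage_spacing_cv * spacing
        s = rng_mac.uniform(0, spacing)
        positions = []
        while s < total_um:
            positions.append(s)
            gap = rng_mac.normal(spacing, sd)
            s += max(gap, 0.2 * spacing)
        trace.arc_positions_um = np.asarray(positions)
        ducts.append(trace)
        r_nuc = NUCLEUS_RADIUS_UM["macrophage_intraepithelial"] * px
        for s_um in positions:
            x, y = trace.point_at(s_um, config.pixel_size_um)
            records.append(
                dict(
                    cell_id=next_id,
                    cell_class="macrophage_intraepithelial",
                    x_px=float(x),
                    y_px=float(y),
                    area_px=np.pi * r_nuc**2,
                    ki67=False,
                    basement_contact_fraction=float(rng_mac.uniform(0.6, 0.9)),
                    lobule_id=lob["lobule_id"],
                    axis_u=float(_lobule_u(np.array([[x, y]]), lob)[0]),
                )
            )
            next_id += 1

    # --- stromal macrophages: Poisson, centrally enriched -------------------
    pixel_area_mm2 = (config.pixel_size_um * 1e-3) ** 2
    for region, density in (
        (central, config.stromal_mac_density_central),
        (stroma & ~central, config.stromal_mac_density_peripheral),
    ):
        area_mm2 = np.count_nonzero(region) * pixel_area_mm2
        n_cells = rng_imm.poisson(density * area_mm2) if area_mm2 > 0 else 0
        if n_cells == 0:
            continue
        ys, xs_r = np.nonzero(region)
        pick = rng_imm.integers(0, len(ys), size=n_cells)
        r_nuc = NUCLEUS_RADIUS_UM["macrophage_stromal"] * px
        for j in pick:
            x = xs_r[j] + rng_imm.uniform(0, 1)
            y = ys[j] + rng_imm.uniform(0, 1)
            lob_id, u = _locate(x, y, lobules)
            records.append(
                dict(
                    cell_id=next_id,
                    cell_class="macrophage_stromal",
                    x_px=float(x),
                    y_px=float(y),
                    area_px=np.pi * r_nuc**2,
                    ki67=False,
                    basement_contact_fraction=0.0,
                    lobule_id=lob_id,
                    axis_u=u,
                )
            )
            next_id += 1

    # --- T cells -------------------------------------------------------------
    n_luminal = sum(1 for r in records if r["cell_class"] == "luminal")
    n_t_epi = int(round(config.t_epi_per100 / 100.0 * n_luminal))
    luminal = [r for r in records if r["cell_class"] == "luminal"]
    r_t = NUCLEUS_RADIUS_UM["t_cell_epithelial"] * px
    for _ in range(n_t_epi):
        host = luminal[rng_imm.integers(0, len(luminal))]
        ang = rng_imm.uniform(0, 2 * np.pi)
        x = np.clip(host["x_px"] + 2.5 * r_t * np.cos(ang), 0, w - 1)
        y = np.clip(host["y_px"] + 2.5 * r_t * np.sin(ang), 0, h - 1)
        records.append(
            dict(
                cell_id=next_id,
                cell_class="t_cell_epithelial",
                x_px=float(x),
                y_px=float(y),
                area_px=np.pi * r_t**2,
                ki67=False,
                basement_contact_fraction=float(rng_imm.uniform(0.55, 0.95)),
                lobule_id=host["lobule_id"],
                axis_u=host["axis_u"],
            )
        )
        next_id += 1
    area_stroma_mm2 = np.count_nonzero(stroma) * pixel_area_mm2
    n_t_str = rng_imm.poisson(config.t_stromal_density * area_stroma_mm2)
    if n_t_str > 0 and area_stroma_mm2 > 0:
        ys, xs_r = np.nonzero(stroma)
        pick = rng_imm.integers(0, len(ys), size=n_t_str)
        for j in pick:
            x = xs_r[j] + rng_imm.uniform(0, 1)
            y = ys[j] + rng_imm.uniform(0, 1)
            lob_id, u = _locate(x, y, lobules)
            records.append(
                dict(
                    cell_id=next_id,
                    cell_class="t_cell_stromal",
                    x_px=float(x),
                    y_px=float(y),
                    area_px=np.pi * r_t**2,
                    ki67=False,
                    basement_contact_fraction=float(rng_imm.uniform(0.0, 0.3)),
                    lobule_id=lob_id,
                    axis_u=u,
                )
            )
            next_id += 1

    # --- tertiary lymphoid structures ---------------------------------------
    if config.n_tls > 0 and np.any(stroma):
        ys, xs_r = np.nonzero(stroma)
        r_b = NUCLEUS_RADIUS_UM["b_cell"] * px
        for _ in range(config.n_tls):
            j = rng_tls.integers(0, len(ys))
            cx_t, cy_t = float(xs_r[j]), float(ys[j])
            for _ in range(config.tls_b_cells):
                x = np.clip(cx_t + rng_tls.normal(0, 18.0 * px), 0, w - 1)
                y = np.clip(cy_t + rng_tls.normal(0, 18.0 * px), 0, h - 1)
                lob_id, u = _locate(x, y, lobules)
                records.append(
                    dict(
                        cell_id=next_id,
                        cell_class="b_cell",
                        x_px=float(x),
                        y_px=float(y),
                        area_px=np.pi * r_b**2,
                        ki67=False,
                        basement_contact_fraction=0.0,
                        lobule_id=lob_id,
                        axis_u=u,
                    )
                )
                next_id += 1
            for _ in range(config.tls_t_cells):
                rad = rng_tls.uniform(42.0, 70.0) * px
                ang = rng_tls.uniform(0, 2 * np.pi)
                x = np.clip(cx_t + rad * np.cos(ang), 0, w - 1)
                y = np.clip(cy_t + rad * np.sin(ang), 0, h - 1)
                lob_id, u = _locate(x, y, lobules)
                records.append(
                    dict(
                        cell_id=next_id,
                        cell_class="t_cell_stromal",
                        x_px=float(x),
                        y_px=float(y),
                        area_px=np.pi * r_t**2,
                        ki67=False,
                        basement_contact_fraction=0.0,
                        lobule_id=lob_id,
                        axis_u=u,
                    )
                )
                next_id += 1

    cells = pd.DataFrame(records, columns=CELL_COLUMNS) if records else _empty_cells()
    gt = GroundTruth(
        cells=cells,
        epithelium_mask=epithelium,
        stroma_mask=stroma,
        central_mask=central,
        lobules=lobules,
        ducts=ducts,
        config=config,
        age_group=age_group,
    )
    return assign_ki67(gt, config.ki67_p0, config.ki67_slope, _rng=rng_ki67)


def _locate(x: float, y: float, lobules: Sequence[dict]) -> Tuple[int, float]:
    for lob in lobules:
        rel = np.array([x, y]) - np.asarray(lob["center"])
        ax = np.asarray(lob["axis"])
        along = rel @ ax
        across = -rel[0] * ax[1] + rel[1] * ax[0]
        a, b = lob["semiaxes"]
        if (along / a) ** 2 + (across / b) ** 2 <= 1.0:
            return lob["lobule_id"], float(
                np.clip(along / (2 * a) + 0.5, 0.0, 1.0)
            )
    return -1, np.nan


def assign_ki67(
    gt: GroundTruth,
    p0: float,
    slope: float,
    seed: Optional[int] = None,
    _rng: Optional[np.random.Generator] = None,
) -> GroundTruth:
    """Mark epithelial nuclei Ki67+ with a logistic gradient along the axis.

    Each epithelial nucleus with normalised axis coordinate ``u`` (1 = leading
    edge) is positive with probability ``expit(logit(p0) + slope * (u - 0.5))``;
    non-epithelial cells are untouched.
    """
    if not (0.0 < p0 < 1.0):
        raise ConfigurationError("p0 must lie strictly inside (0, 1)")
    rng = _rng if _rng is not None else np.random.default_rng(seed)
    cells = gt.cells.copy()
    epi = cells["cell_class"].isin(EPITHELIAL_CLASSES)
    if epi.any():
        u = cells.loc[epi, "axis_u"].to_numpy(dtype=float)
        p = expit(logit(p0) + slope * (u - 0.5))
        cells.loc[epi, "ki67"] = rng.random(epi.sum()) < p
    return dataclasses.replace(gt, cells=cells)


def render_field(
    gt: GroundTruth,
    config: Optional[SimulationConfig] = None,
    markers: Iterable[str] = ("ki67", "iba1"),
    quantise: bool = True,
) -> Tuple[ImageField, Dict[str, np.ndarray]]:
    """Render a GroundTruth through Beer-Lambert H-DAB stain mixing.

    All nuclei deposit haematoxylin; cells carrying an active marker in
    ``markers`` ("ki67" for Ki67+ epithelium, "iba1" for macrophages) deposit
    DAB across their whole footprint with the counterstain confined to a
    concentric core, producing the DAB-dominant rim characteristic of strongly
    chromogenic nuclei.  RGB = I0 * exp(-S @ c) plus Gaussian OD noise,
    clipped to [0, I0].  Returns the image and pixel-perfect phenotype label
    maps ("ki67_pos": DAB+ objects, "ki67_neg": all remaining nuclei).
    """
    config = config or gt.config
    markers = set(markers)
    h, w = config.field_height_px, config.field_width_px
    px = config.px_per_um
    c_haem = np.zeros((h, w))
    c_dab = np.zeros((h, w))
    pos_labels = np.zeros((h, w), dtype=np.int32)
    neg_labels = np.zeros((h, w), dtype=np.int32)

    for rec in gt.cells.itertuples(index=False):
        r = float(np.sqrt(rec.area_px / np.pi))
        dab_cell = ("ki67" in markers and bool(rec.ki67)) or (
            "iba1" in markers and rec.cell_class.startswith("macrophage")
        )
        idx = _disc_indices((h, w), rec.x_px, rec.y_px, r)
        if idx is None:
            continue
        if dab_cell:
            c_dab[idx] += DAB_CONC
            core = _disc_indices((h, w), rec.x_px, rec.y_px, r * DAB_CORE_FRACTION)
            if core is not None:
                c_haem[core] += HAEM_CORE_CONC
            neg_labels[idx] = 0
            pos_labels[idx] = rec.cell_id + 1
        else:
            c_haem[idx] += HAEM_NUCLEUS_CONC
            keep = pos_labels[idx] == 0
            neg_labels[idx[0][keep], idx[1][keep]] = rec.cell_id + 1

    od = np.tensordot(
        np.stack([c_haem, c_dab], axis=-1), config.stain_matrix.T, axes=([2], [0])
    )
    if config.od_noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(6)[5])
        od = od + rng.normal(0.0, config.od_noise_sd, size=od.shape)
    rgb = np.clip(
        config.background_intensity * np.exp(-od), 0.0, config.background_intensity
    )
    if quantise:
        rgb = np.rint(rgb).astype(np.uint8)
    field = ImageField(
        rgb=rgb,
        pixel_size_um=config.pixel_size_um,
        field_id=f"synthetic-{gt.age_group}-seed{config.seed}",
        provenance={"seed": config.seed, "age_group": gt.age_group,
                    "markers": sorted(markers)},
    )
    labels = {"ki67_pos": pos_labels, "ki67_neg": neg_labels}
    return field, labels


# ---------------------------------------------------------------------------
# Per-animal measurement tables with the statistical structure of the study's
# source data: one row per animal x measure (several rows for pooled
# inter-macrophage distances), two age groups.
# ---------------------------------------------------------------------------

AGE_GROUP_LABELS = ("lt2mo", "5to9.5mo")


@dataclasses.dataclass
class MeasureSpec:
    name: str
    young_mean: float
    old_mean: float
    between_sd: float  # animal-to-animal SD of the animal mean
    within_sd: float = 0.0  # SD of repeated values within an animal
    n_per_animal: int = 1
    lower: float = 0.0
    units: str = ""


DEFAULT_MEASURES: Tuple[MeasureSpec, ...] = (
    MeasureSpec("ki67_epithelial_ratio", 0.35, 0.12, 0.08, units="ratio"),
    MeasureSpec(
        "inter_macrophage_distance_um", 60.0, 20.0, 6.0, within_sd=9.0,
        n_per_animal=30, units="um",
    ),
    MeasureSpec("stromal_mac_density_central", 260.0, 260.0, 50.0, units="per_mm2"),
    MeasureSpec("t_epi_per100", 2.0, 2.0, 0.8, units="per_100_luminal"),
    MeasureSpec("t_stromal_per_mm2", 150.0, 150.0, 50.0, units="per_mm2"),
    MeasureSpec("tls_per_mm2", 0.03, 0.08, 0.02, units="per_mm2"),
)

# central vs peripheral macrophage density: peripheral is drawn as a
# within-animal multiple of the central value, so the paired contrast has a
# consistent direction (central > peripheral).
PERIPHERAL_RATIO_MEAN = 0.55
PERIPHERAL_RATIO_SD = 0.10


def emulate_measurement_tables(
    n_animals_per_group=(7, 6),
    seed: int = 0,
    measures: Optional[Sequence[MeasureSpec]] = None,
) -> pd.DataFrame:
    """Draw a per-animal measurement table for two age groups.

    Values follow a two-level normal model (animal means around the group
    mean, repeated values around the animal mean), truncated at each
    measure's lower bound.  Returns a long table with columns
    animal_id, age_group, age_months, measure, value, units.
    """
    if isinstance(n_animals_per_group, int):
        n_animals_per_group = (n_animals_per_group, n_animals_per_group)
    if min(n_animals_per_group) < 2:
        raise ConfigurationError(
            "need at least 2 animals per group for group statistics"
        )
    measures = tuple(measures) if measures is not None else DEFAULT_MEASURES
    rng = np.random.default_rng(seed)
    rows: List[dict] = []
    animal_counter = 0
    for group, n_animals in zip(AGE_GROUP_LABELS, n_animals_per_group):
        young = group == AGE_GROUP_LABELS[0]
        for _ in range(n_animals):
            animal_id = f"lamb{animal_counter:02d}"
            age = rng.uniform(0.5, 2.0) if young else rng.uniform(5.0, 9.5)
            animal_counter += 1
            central_value = None
            for spec in measures:
                mean = spec.young_mean if young else spec.old_mean
                animal_mean = rng.normal(mean, spec.between_sd)
                vals = (
                    rng.normal(animal_mean, spec.within_sd, size=spec.n_per_animal)
                    if spec.within_sd > 0
                    else np.array([animal_mean])
                )
                vals = np.maximum(vals, spec.lower)
                for v in vals:
                    rows.append(
                        dict(
                            animal_id=animal_id,
                            age_group=group,
                            age_months=round(age, 1),
                            measure=spec.name,
                            value=float(v),
                            units=spec.units,
                        )
                    )
                if spec.name == "stromal_mac_density_central":
                    central_value = float(vals[0])
            if central_value is not None:
                ratio = rng.normal(PERIPHERAL_RATIO_MEAN, PERIPHERAL_RATIO_SD)
                rows.append(
                    dict(
                        animal_id=animal_id,
                        age_group=group,
                        age_months=round(age, 1),
                        measure="stromal_mac_density_peripheral",
                        value=float(max(central_value * ratio, 0.0)),
                        units="per_mm2",
                    )
                )
    return pd.DataFrame(rows)
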