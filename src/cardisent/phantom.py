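"""Multi-domain cardiac short-axis phantoms with analytic ground truth.

The generator emulates the statistical structure of a multi-scanner cine-MR
study: every subject shares the same procedural anatomy (a centred LV blood
pool, a myocardial annulus around it, and an RV crescent abutting the
annulus), radii taper from base to apex and contract from end-diastole (ED)
to end-systole (ES), and two "scanner" domains differ only in non-spatial
appearance (class mean intensities, contrast, smooth bias field, noise).
Because the geometry is continuous and analytic, end-diastolic/end-systolic
volumes and ejection fraction are known exactly, so Simpson volumetry and
clinical-index recovery can be tested without any external dataset.

Label convention: 0 = background, 1 = RV, 2 = myocardium, 3 = LV blood pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

BACKGROUND, RV, MYO, LV = 0, 1, 2, 3
CLASS_NAMES = {BACKGROUND: "background", RV: "RV", MYO: "myocardium", LV: "LV"}
FRAMES = ("ED", "ES")


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class DomainStyle:
    """Non-spatial appearance of one 'scanner' domain."""

    class_mean_intensities: dict[int, float]
    contrast_gamma: float = 1.0
    bias_field_amplitude: float = 0.0
    bias_field_order: int = 2

    def __post_init__(self):
        if self.contrast_gamma <= 0:
            raise ConfigurationError("contrast_gamma must be > 0")
        means = [self.class_mean_intensities[c] for c in (BACKGROUND, RV, MYO, LV)]
        if len(set(np.round(means, 6))) != 4:
            raise ConfigurationError("class mean intensities must be pairwise distinct")


#: Two default scanner styles: a darker low-field-like domain and a brighter,
#: higher-contrast domain with a stronger bias field.
DOMAIN_A = DomainStyle(
    class_mean_intensities={BACKGROUND: 0.10, RV: 0.55, MYO: 0.35, LV: 0.75},
    contrast_gamma=1.0,
    bias_field_amplitude=0.08,
    bias_field_order=2,
)
DOMAIN_B = DomainStyle(
    class_mean_intensities={BACKGROUND: 0.30, RV: 0.78, MYO: 0.52, LV: 0.95},
    contrast_gamma=1.3,
    bias_field_amplitude=0.15,
    bias_field_order=3,
)


@dataclass(frozen=True)
class PhantomConfig:
    image_size: int = 64
    n_subjects: int = 20
    n_slices: int = 5
    pixel_spacing: float = 1.37  # mm / pixel
    slice_thickness: float = 10.0  # mm
    domains: tuple[DomainStyle, ...] = (DOMAIN_A, DOMAIN_B)
    label_fraction: float = 0.1
    noise_sigma: float = 0.03
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 32:
            raise ConfigurationError("image_size must be >= 32")
        if not 0.0 < self.label_fraction < 1.0:
            raise ConfigurationError("label_fraction must lie in (0, 1)")
        if self.n_slices < 3:
            raise ConfigurationError("n_slices must be >= 3")


@dataclass(frozen=True)
class SubjectGeometry:
    """Continuous generating geometry of one subject, radii in pixels at base."""

    center: tuple[float, float]
    lv_radius: float  # LV blood-pool radius at base, ED
    wall_thickness: float  # myocardial wall at base, ED
    rv_radius: float  # RV disk radius at base, ED
    rv_offset: float  # distance LV centre -> RV disk centre
    apex_scale: float  # radius multiplier at the last (apical) slice
    es_lv_scale: float  # ED -> ES contraction of the blood pool
    es_rv_scale: float
    n_slices: int
    rv_angle: float = 0.0  # in-plane orientation of the RV (radians)

    def slice_scale(self, slice_index: int) -> float:
        if self.n_slices == 1:
            return 1.0
        frac = slice_index / (self.n_slices - 1)
        return 1.0 + (self.apex_scale - 1.0) * frac

    def radii(self, slice_index: int, frame: str):
        """(lv_r, epi_r, rv_r, rv_offset) for one slice/frame, in pixels."""
        if slice_index >= self.n_slices:
            raise ConfigurationError("slice_index out of range")
        s = self.slice_scale(slice_index)
        lv = self.lv_radius * s
        epi = (self.lv_radius + self.wall_thickness) * s
        rv = self.rv_radius * s
        if frame == "ES":
            lv *= self.es_lv_scale
            rv *= self.es_rv_scale
            # wall thickens as the pool contracts; epicardium shrinks less
            epi *= 0.95
        return lv, epi, rv, self.rv_offset * s


def sample_geometry(cfg: PhantomConfig, rng: np.random.Generator) -> SubjectGeometry:
    """Draw one subject's anatomy.

    Hearts in short-axis stacks vary markedly across patients in size,
    in-plane position and axis orientation, so the LV radius and wall span
    a wide range, the centre wanders by several percent of the field of
    view and the RV crescent sits at a uniformly random angle.
    """
    s = cfg.image_size
    lv = s * rng.uniform(0.09, 0.14)
    wall = s * rng.uniform(0.04, 0.07)
    rv = s * rng.uniform(0.09, 0.13)
    offset = (lv + wall) + rv * rng.uniform(0.30, 0.50)
    cx = s / 2 + rng.uniform(-0.04, 0.04) * s
    cy = s / 2 + rng.uniform(-0.04, 0.04) * s
    geom = SubjectGeometry(
        center=(cy, cx),
        lv_radius=lv,
        wall_thickness=wall,
        rv_radius=rv,
        rv_offset=offset,
        apex_scale=rng.uniform(0.30, 0.55),
        es_lv_scale=rng.uniform(0.55, 0.75),
        es_rv_scale=rng.uniform(0.65, 0.85),
        n_slices=cfg.n_slices,
        rv_angle=rng.uniform(0.0, 2 * np.pi),
    )
    # the RV crescent extends furthest from the centre, in any direction
    if offset + rv + max(abs(cx - s / 2), abs(cy - s / 2)) > s / 2 - 1:
        raise ConfigurationError("generated geometry exceeds the image frame")
    return geom


def generate_anatomy(
    geometry: SubjectGeometry, slice_index: int, frame: str, image_size: int
) -> np.ndarray:
    """Rasterize one slice's label mask by pixel-centre-in-region tests."""
    lv_r, epi_r, rv_r, rv_off = geometry.radii(slice_index, frame)
    cy, cx = geometry.center
    rv_cy = cy + rv_off * np.sin(geometry.rv_angle)
    rv_cx = cx + rv_off * np.cos(geometry.rv_angle)
    extent = max(epi_r, rv_off + rv_r)
    if (min(cx, cy) - extent < -0.5
            or max(cx, cy) + extent > image_size - 0.5):
        raise ConfigurationError("geometry exceeds the image frame")
    yy, xx = np.mgrid[0:image_size, 0:image_size]
    d_lv = (yy - cy) ** 2 + (xx - cx) ** 2
    d_rv = (yy - rv_cy) ** 2 + (xx - rv_cx) ** 2
    mask = np.zeros((image_size, image_size), dtype=np.uint8)
    mask[(d_rv < rv_r**2) & (d_lv >= epi_r**2)] = RV
    mask[(d_lv < epi_r**2) & (d_lv >= lv_r**2)] = MYO
    mask[d_lv < lv_r**2] = LV
    return mask


def _bias_field(
    image_size: int, amplitude: float, order: int, rng: np.random.Generator
) -> np.ndarray:
    """Smooth multiplicative field 1 + amplitude * P(x, y), mean-centred."""
    if amplitude == 0:
        return np.ones((image_size, image_size), dtype=np.float32)
    u = np.linspace(-1, 1, image_size)
    yy, xx = np.meshgrid(u, u, indexing="ij")
    poly = np.zeros_like(yy)
    for i in range(order + 1):
        for j in range(order + 1 - i):
            if i == j == 0:
                continue
            poly += rng.normal(0, 1) * (yy**i) * (xx**j)
    span = np.abs(poly).max()
    if span > 0:
        poly = poly / span
    poly -= poly.mean()
    return (1.0 + amplitude * poly).astype(np.float32)


def render_intensity(
    mask: np.ndarray,
    style: DomainStyle,
    rng: np.random.Generator,
    noise_sigma: float = 0.03,
    distractors: np.ndarray | None = None,
) -> np.ndarray:
    """Paint a label mask: gamma-adjusted class means x bias field + noise.

    ``distractors`` is an optional float map of surrounding-structure
    intensity levels (0 where absent); it is rendered through the same
    domain contrast but only on background pixels, emulating the bright
    non-cardiac anatomy (chest wall, liver, lung vessels) that surrounds
    the heart in real short-axis images.
    """
    lut = np.zeros(4, dtype=np.float32)
    for c in (BACKGROUND, RV, MYO, LV):
        lut[c] = style.class_mean_intensities[c] ** style.contrast_gamma
    img = lut[mask]
    if distractors is not None:
        on_bg = (mask == BACKGROUND) & (distractors > 0)
        img[on_bg] = distractors[on_bg] ** style.contrast_gamma
    img = img * _bias_field(mask.shape[0], style.bias_field_amplitude,
                            style.bias_field_order, rng)
    if noise_sigma > 0:
        img = img + rng.normal(0, noise_sigma, size=img.shape)
    return np.clip(img, 0.0, 1.0).astype(np.float32)


def sample_distractors(image_size: int, rng: np.random.Generator,
                       n_range: tuple[int, int] = (2, 5)) -> np.ndarray:
    """Random mid-intensity ellipses standing in for non-cardiac anatomy.

    Returns a float level map (0 where empty). Levels span the
    myocardium/RV mean range — like chest wall or liver, surrounding
    tissue is mid-grey, not blood-pool bright — so background cannot be
    told apart from those structures by intensity alone.
    """
    s = image_size
    levels = np.zeros((s, s), dtype=np.float32)
    yy, xx = np.mgrid[0:s, 0:s]
    for _ in range(rng.integers(n_range[0], n_range[1] + 1)):
        cy, cx = rng.uniform(2, s - 2, size=2)
        ry, rx = rng.uniform(0.04, 0.09, size=2) * s
        theta = rng.uniform(0, np.pi)
        level = rng.uniform(0.30, 0.65)
        dy, dx = yy - cy, xx - cx
        u = dy * np.cos(theta) + dx * np.sin(theta)
        v = -dy * np.sin(theta) + dx * np.cos(theta)
        inside = (u / ry) ** 2 + (v / rx) ** 2 < 1.0
        levels[inside] = level
    return levels


# --------------------------------------------------------------------- study
@dataclass
class PhantomStudy:
    """A full synthetic study: images, masks, domains, split flags and truth.

    ``images``/``masks`` are (n_subjects, 2 frames, n_slices, H, W); frame 0
    is ED and frame 1 is ES.  ``truth`` holds per-subject analytic volumes in
    mm^3 (and EF in %), computed from the continuous generating geometry,
    never from the rasterized masks.
    """

    config: PhantomConfig
    images: np.ndarray
    masks: np.ndarray
    domain_id: np.ndarray
    labeled_flag: np.ndarray
    truth: pd.DataFrame
    geometries: list[SubjectGeometry] = field(repr=False, default_factory=list)

    @property
    def n_subjects(self) -> int:
        return self.images.shape[0]

    def save(self, out_dir) -> None:
        from . import pipeline

        pipeline.write_study(self, out_dir)


def _disk_area(r: float) -> float:
    return float(np.pi * r * r)


def _lens_area(d: float, r1: float, r2: float) -> float:
    """Area of intersection of two disks with centre distance d."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        return _disk_area(min(r1, r2))
    a1 = r1**2 * np.arccos((d**2 + r1**2 - r2**2) / (2 * d * r1))
    a2 = r2**2 * np.arccos((d**2 + r2**2 - r1**2) / (2 * d * r2))
    a3 = 0.5 * np.sqrt(
        (-d + r1 + r2) * (d + r1 - r2) * (d - r1 + r2) * (d + r1 + r2)
    )
    return float(a1 + a2 - a3)


def analytic_volumes(geometry: SubjectGeometry, cfg: PhantomConfig) -> dict[str, float]:
    """Exact per-frame volumes (mm^3) of LV pool, myocardium and RV crescent."""
    px_area = cfg.pixel_spacing**2
    out = {}
    for frame in FRAMES:
        lv_v = myo_v = rv_v = 0.0
        for k in range(geometry.n_slices):
            lv_r, epi_r, rv_r, rv_off = geometry.radii(k, frame)
            lv_v += _disk_area(lv_r)
            myo_v += _disk_area(epi_r) - _disk_area(lv_r)
            rv_v += _disk_area(rv_r) - _lens_area(rv_off, rv_r, epi_r)
        scale = px_area * cfg.slice_thickness
        out[f"lv_{frame.lower()}v"] = lv_v * scale
        out[f"myo_{frame.lower()}v"] = myo_v * scale
        out[f"rv_{frame.lower()}v"] = rv_v * scale
    out["edv"] = out.pop("lv_edv")
    out["esv"] = out.pop("lv_esv")
    out["sv"] = out["edv"] - out["esv"]
    out["ef"] = 100.0 * out["sv"] / out["edv"]
    out["myo_volume"] = out.pop("myo_edv")
    out["rv_ef"] = 100.0 * (out["rv_edv"] - out["rv_esv"]) / out["rv_edv"]
    del out["myo_esv"]
    return out


def generate_study(config: PhantomConfig) -> PhantomStudy:
    """Generate a reproducible multi-domain phantom study.

    The labeled subset has round(label_fraction * n_subjects) subjects and
    every labeled subject carries masks for all slices and frames (in fact
    masks are stored for all subjects; ``labeled_flag`` governs which masks
    a semi-supervised trainer may look at).
    """
    n_lab = int(round(config.label_fraction * config.n_subjects))
    if n_lab < 1:
        raise ConfigurationError(
            "label_fraction * n_subjects < 1: raise n_subjects (or the "
            "fraction) so that at least one subject is labeled"
        )
    rng = np.random.default_rng(config.seed)
    s = config.image_size
    shape = (config.n_subjects, len(FRAMES), config.n_slices, s, s)
    images = np.zeros(shape, dtype=np.float32)
    masks = np.zeros(shape, dtype=np.uint8)
    domain_id = rng.integers(0, len(config.domains), size=config.n_subjects)
    # balanced-ish domains: force at least one subject per domain
    for d in range(len(config.domains)):
        if not np.any(domain_id == d):
            domain_id[rng.integers(0, config.n_subjects)] = d
    labeled_flag = np.zeros(config.n_subjects, dtype=bool)
    labeled_flag[rng.choice(config.n_subjects, size=n_lab, replace=False)] = True

    geometries: list[SubjectGeometry] = []
    rows = []
    for i in range(config.n_subjects):
        geom = sample_geometry(config, rng)
        geometries.append(geom)
        style = config.domains[domain_id[i]]
        distract = sample_distractors(s, rng)  # persists across slices/frames
        for f, frame in enumerate(FRAMES):
            for k in range(config.n_slices):
                m = generate_anatomy(geom, k, frame, s)
                masks[i, f, k] = m
                images[i, f, k] = render_intensity(m, style, rng,
                                                   config.noise_sigma, distract)
        row = {"subject": i, "domain": int(domain_id[i]),
               "labeled": bool(labeled_flag[i])}
        row.update(analytic_volumes(geom, config))
        rows.append(row)
    truth = pd.DataFrame(rows)
    return PhantomStudy(
        config=config,
        images=images,
        masks=masks,
        domain_id=np.asarray(domain_id),
        labeled_flag=labeled_flag,
        truth=truth,
        geometries=geometries,
    )


# ---------------------------------------------------------------- augmentation
@dataclass(frozen=True)
class AugmentParams:
    """One draw of the on-the-fly augmentation policy.

    Each component is applied with independent probability 1/2: rotation up
    to 90 degrees, zoom up to 20%, shifts up to 20% of the image, horizontal
    and vertical flips, and additive Gaussian noise (image only).
    """

    angle_deg: float = 0.0
    zoom: float = 1.0
    shift: tuple[float, float] = (0.0, 0.0)
    flip_h: bool = False
    flip_v: bool = False
    noise_sigma: float = 0.0

    @classmethod
    def draw(cls, rng: np.random.Generator, image_size: int,
             noise_sigma: float = 0.02) -> "AugmentParams":
        p = {}
        p["angle_deg"] = rng.uniform(-90, 90) if rng.random() < 0.5 else 0.0
        p["zoom"] = rng.uniform(0.8, 1.2) if rng.random() < 0.5 else 1.0
        if rng.random() < 0.5:
            lim = 0.2 * image_size
            p["shift"] = (rng.uniform(-lim, lim), rng.uniform(-lim, lim))
        else:
            p["shift"] = (0.0, 0.0)
        p["flip_h"] = rng.random() < 0.5
        p["flip_v"] = rng.random() < 0.5
        p["noise_sigma"] = noise_sigma if rng.random() < 0.5 else 0.0
        return cls(**p)


def _geometric(arr: np.ndarray, params: AugmentParams, order: int) -> np.ndarray:
    out = arr.astype(np.float32)
    if params.flip_h:
        out = out[:, ::-1]
    if params.flip_v:
        out = out[::-1, :]
    if params.angle_deg != 0.0:
        out = ndimage.rotate(out, params.angle_deg, reshape=False, order=order,
                             mode="constant", cval=0.0)
    if params.zoom != 1.0:
        h, w = out.shape
        zoomed = ndimage.zoom(out, params.zoom, order=order, mode="constant",
                              cval=0.0)
        zh, zw = zoomed.shape
        if zh >= h:
            top, left = (zh - h) // 2, (zw - w) // 2
            out = zoomed[top : top + h, left : left + w]
        else:
            pad_t, pad_l = (h - zh) // 2, (w - zw) // 2
            out = np.zeros((h, w), dtype=np.float32)
            out[pad_t : pad_t + zh, pad_l : pad_l + zw] = zoomed
    if params.shift != (0.0, 0.0):
        out = ndimage.shift(out, params.shift, order=order, mode="constant",
                            cval=0.0)
    return out


def apply_augment(image: np.ndarray, mask: np.ndarray | None,
                  params: AugmentParams):
    """Apply one augmentation draw: bilinear image, nearest-neighbour mask."""
    img = _geometric(image, params, order=1)
    if params.noise_sigma > 0:
        # noise keyed off the draw so identical params give identical output
        noise_rng = np.random.default_rng(
            abs(hash((round(params.angle_deg, 6), params.zoom, params.shift))) % (2**31)
        )
        img = img + noise_rng.normal(0, params.noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 1.0).astype(np.float32)
    if mask is None:
        return img, None
    m = _geometric(mask, params, order=0)
    return img, np.round(m).astype(mask.dtype)


def augment(image: np.ndarray, mask: np.ndarray | None,
            rng: np.random.Generator, noise_sigma: float = 0.02):
    if mask is not None and image.shape != mask.shape:
        raise ValueError("image and mask must share a shape")
    params = AugmentParams.draw(rng, image.shape[0], noise_sigma)
    return apply_augment(image, mask, params)
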