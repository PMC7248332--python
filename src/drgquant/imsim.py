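"""Synthetic fluorescence images of diffraction-limited puncta.

Each mRNA transcript is a point emitter.  Emitters are binned to an integer
pixel grid (several may share a pixel), scaled so that one emitter carries
an integrated intensity of ``epsilon * pi * (omega0/px)**2`` intensity
units, and convolved with an isotropic Gaussian point-spread function

.. math:: \\mathrm{PSF}(x, y) = I_0\\, e^{-2 (x^2 + y^2) / \\omega_0^2},

where :math:`\\omega_0` is the e^-2 radius.  The kernel used for rendering
is normalized to unit sum, so ``epsilon`` is exactly the mean per-particle
count and the peak amplitude of one isolated punctum is ``2 * epsilon``
(the unit-sum normalization of the e^-2 Gaussian evaluated at the origin
is ``2 / (pi * (omega0/px)**2)``).  Detection noise is additive zero-mean
Gaussian; the signal model is linear with no saturation.

Defaults follow confocal imaging of DRG sections: 200 nm pixels,
``omega0`` = 300 nm, ``epsilon`` = 100 i.u., 25-um circular regions of
interest standing in for an average mouse DRG soma.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

__all__ = [
    "PSFModel",
    "SimulationConfig",
    "FieldImage",
    "gaussian_kernel",
    "place_emitters",
    "render_counts",
    "psf_render",
    "add_noise",
    "simulate_roi_image",
    "roi_mask",
    "disk_mask",
    "render_neuron_tile",
    "render_section",
    "write_field_image",
    "read_field_image",
]


@dataclass(frozen=True)
class PSFModel:
    """Gaussian PSF; ``omega0_nm`` is the e^-2 radius, ``I0`` metadata only."""

    omega0_nm: float = 300.0
    I0: float = 1.0

    def __post_init__(self) -> None:
        if self.omega0_nm <= 0:
            raise ValueError("omega0 must be > 0")


@dataclass(frozen=True)
class SimulationConfig:
    epsilon: float = 100.0  # mean intensity counts per particle, i.u.
    pixel_size_nm: float = 200.0
    psf: PSFModel = field(default_factory=PSFModel)
    roi_diameter_um: float = 25.0
    density: float = 1.0  # puncta per um^2
    noise_sd: float = 1.0  # i.u.
    detect_threshold: float = 6.0  # i.u.
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.roi_diameter_um <= 0:
            raise ValueError("roi_diameter must be > 0")
        if self.density < 0:
            raise ValueError("density must be >= 0")
        if self.detect_threshold <= 0:
            raise ValueError("detect_threshold must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def px_um(self) -> float:
        return self.pixel_size_nm / 1000.0

    @property
    def omega0_px(self) -> float:
        return self.psf.omega0_nm / self.pixel_size_nm

    @property
    def single_punctum_intensity(self) -> float:
        """Integrated i.u. contributed by one isolated emitter."""
        return self.epsilon * np.pi * self.omega0_px**2

    @property
    def roi_area_um2(self) -> float:
        return np.pi * (self.roi_diameter_um / 2.0) ** 2

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class FieldImage:
    """A rendered 2-D field with physical pixel size and provenance."""

    pixels: np.ndarray
    pixel_size_nm: float
    channel: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("field image contains non-finite pixels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def total_intensity(self) -> float:
        return float(self.pixels.sum())


def gaussian_kernel(cfg: SimulationConfig) -> np.ndarray:
    """Unit-sum Gaussian kernel of e^-2 radius omega0, truncated at 4*omega0."""
    w_px = cfg.omega0_px
    if w_px < 0.5:
        warnings.warn(
            f"PSF e^-2 radius {w_px:.2f} px is below half a pixel; kernel under-sampled",
            stacklevel=2,
        )
    radius = max(1, int(np.ceil(4.0 * w_px)))
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    k = np.exp(-2.0 * (xx**2 + yy**2) / w_px**2)
    return k / k.sum()


def place_emitters(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Uniform emitter positions (um) inside the circular ROI.

    The count is Poisson(density * ROI area); coordinates are relative to
    the ROI bounding box ``[0, D] x [0, D]`` with the ROI centered at
    (D/2, D/2).  Positions may coincide.  Returns an (N, 2) array of
    (x, y); empty when the Poisson draw is zero.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    r = cfg.roi_diameter_um / 2.0
    n = int(rng.poisson(cfg.density * cfg.roi_area_um2))
    if n == 0:
        return np.empty((0, 2))
    # uniform in disk via sqrt-radius transform
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    rad = r * np.sqrt(rng.uniform(0.0, 1.0, size=n))
    return np.column_stack([r + rad * np.cos(theta), r + rad * np.sin(theta)])


def render_counts(
    positions: np.ndarray, cfg: SimulationConfig, shape: tuple[int, int] | None = None
) -> np.ndarray:
    """Bin emitter positions (um) into an integer per-pixel count matrix.

    The matrix covers the ROI bounding box at the configured resolution
    unless ``shape`` is given; the matrix sum equals the emitter count.
    """
    if shape is None:
        side = int(np.ceil(cfg.roi_diameter_um / cfg.px_um))
        shape = (side, side)
    counts = np.zeros(shape, dtype=int)
    if len(positions) == 0:
        return counts
    cols = np.clip((np.asarray(positions)[:, 0] / cfg.px_um).astype(int), 0, shape[1] - 1)
    rows = np.clip((np.asarray(positions)[:, 1] / cfg.px_um).astype(int), 0, shape[0] - 1)
    np.add.at(counts, (rows, cols), 1)
    return counts


def psf_render(count_matrix: np.ndarray, cfg: SimulationConfig, channel: str = "") -> FieldImage:
    """Convolve per-pixel emitter counts with the PSF.

    Each emitter contributes ``epsilon * pi * (omega0/px)**2`` integrated
    i.u.; with defaults that is ~706.9 i.u. with a peak of ``2 * epsilon``.
    """
    counts = np.asarray(count_matrix)
    if counts.size and counts.min() < 0:
        raise ValueError("count matrix must be non-negative")
    kernel = gaussian_kernel(cfg)
    img = ndimage.convolve(
        counts.astype(float) * cfg.single_punctum_intensity, kernel, mode="constant", cval=0.0
    )
    return FieldImage(
        pixels=img,
        pixel_size_nm=cfg.pixel_size_nm,
        channel=channel,
        meta={"config_hash": cfg.config_hash(), "seed": cfg.seed},
    )


def add_noise(
    img: FieldImage, cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> FieldImage:
    """Add i.i.d. zero-mean Gaussian detection noise of sd ``noise_sd``."""
    if cfg.noise_sd == 0:
        return FieldImage(img.pixels.copy(), img.pixel_size_nm, img.channel, dict(img.meta))
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    noisy = img.pixels + rng.normal(0.0, cfg.noise_sd, size=img.pixels.shape)
    return FieldImage(noisy, img.pixel_size_nm, img.channel, dict(img.meta))


def simulate_roi_image(
    cfg: SimulationConfig, rng: np.random.Generator | None = None, channel: str = ""
) -> tuple[FieldImage, np.ndarray]:
    """Full single-ROI simulation: place, bin, render, add noise.

    Returns the noisy image and the true emitter positions (um).
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    positions = place_emitters(cfg, rng)
    img = psf_render(render_counts(positions, cfg), cfg, channel=channel)
    return add_noise(img, cfg, rng), positions


def disk_mask(shape: tuple[int, int], center_rc: tuple[float, float], radius_px: float) -> np.ndarray:
    """Rasterized filled disk: pixels whose center lies within the radius."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rr - center_rc[0]) ** 2 + (cc - center_rc[1]) ** 2 <= radius_px**2


def roi_mask(cfg: SimulationConfig, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Boolean mask of the circular ROI inside its bounding box."""
    if shape is None:
        side = int(np.ceil(cfg.roi_diameter_um / cfg.px_um))
        shape = (side, side)
    r_px = cfg.roi_diameter_um / 2.0 / cfg.px_um
    return disk_mask(shape, ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0), r_px)


def render_neuron_tile(
    true_puncta: int,
    soma_area_um2: float,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    intensity_scale: float = 1.0,
    margin_px: int | None = None,
) -> tuple[FieldImage, np.ndarray]:
    """Render one soma as a small stand-alone tile.

    ``true_puncta`` emitters are placed uniformly in a disk of the given
    area, rendered, scaled by the per-cell ``intensity_scale`` and
    degraded with noise.  Returns the tile and the boolean soma mask.
    """
    soma_r_um = float(np.sqrt(soma_area_um2 / np.pi))
    r_px = soma_r_um / cfg.px_um
    if margin_px is None:
        margin_px = max(4, int(np.ceil(4.0 * cfg.omega0_px)) + 2)
    side = int(np.ceil(2 * r_px)) + 2 * margin_px
    center = ((side - 1) / 2.0, (side - 1) / 2.0)
    theta = rng.uniform(0.0, 2.0 * np.pi, size=true_puncta)
    rad = r_px * np.sqrt(rng.uniform(0.0, 1.0, size=true_puncta))
    rows = np.round(center[0] + rad * np.sin(theta)).astype(int)
    cols = np.round(center[1] + rad * np.cos(theta)).astype(int)
    counts = np.zeros((side, side), dtype=int)
    np.add.at(counts, (np.clip(rows, 0, side - 1), np.clip(cols, 0, side - 1)), 1)
    img = psf_render(counts, cfg)
    img.pixels *= intensity_scale
    img = add_noise(img, cfg, rng)
    return img, disk_mask((side, side), center, r_px)


def render_section(
    neurons,
    cfg: SimulationConfig,
    probe: str,
    marker: str | None = None,
    field_size_um: float | None = None,
    rng: np.random.Generator | None = None,
    max_tries: int = 500,
) -> tuple[FieldImage, FieldImage, np.ndarray]:
    """Compose neurons into one field: marker channel, probe channel, labels.

    The marker channel holds filled soma disks (one per neuron of the
    requested marker class, or all neurons when ``marker`` is None); the
    probe channel holds each neuron's puncta rendered inside its soma.
    Somata are placed uniformly without overlap; if a non-overlapping
    placement cannot be found within ``max_tries`` attempts per neuron, a
    RuntimeError suggests a larger field.  Returns (marker image, probe
    image, integer label mask) where label ``i+1`` marks neuron ``i``.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    selected = [n for n in neurons if marker is None or n.marker == marker]
    radii_um = [float(np.sqrt(n.soma_area / np.pi)) for n in selected]
    if field_size_um is None:
        # ~4x total soma footprint leaves room for rejection placement
        field_size_um = max(50.0, 2.0 * np.sqrt(4.0 * sum(a.soma_area for a in selected) / np.pi))
    side = int(np.ceil(field_size_um / cfg.px_um))
    labels = np.zeros((side, side), dtype=int)
    marker_px = np.zeros((side, side), dtype=float)
    counts = np.zeros((side, side), dtype=int)
    placed: list[tuple[float, float, float]] = []  # (row, col, r_px)
    for i, (nr, r_um) in enumerate(zip(selected, radii_um)):
        r_px = r_um / cfg.px_um
        for attempt in range(max_tries):
            row = rng.uniform(r_px, side - 1 - r_px)
            col = rng.uniform(r_px, side - 1 - r_px)
            if all((row - pr) ** 2 + (col - pc) ** 2 > (r_px + prad) ** 2 for pr, pc, prad in placed):
                break
        else:
            raise RuntimeError(
                f"could not place soma {nr.id} without overlap after {max_tries} tries; "
                "use a larger field_size_um"
            )
        placed.append((row, col, r_px))
        mask = disk_mask((side, side), (row, col), r_px)
        labels[mask] = i + 1
        marker_px[mask] = 1.0
        k = nr.true_puncta.get(probe, 0)
        if k:
            theta = rng.uniform(0.0, 2.0 * np.pi, size=k)
            rad = r_px * np.sqrt(rng.uniform(0.0, 1.0, size=k))
            rr = np.clip(np.round(row + rad * np.sin(theta)).astype(int), 0, side - 1)
            cc = np.clip(np.round(col + rad * np.cos(theta)).astype(int), 0, side - 1)
            np.add.at(counts, (rr, cc), 1)
    probe_img = add_noise(psf_render(counts, cfg, channel=probe), cfg, rng)
    marker_img = FieldImage(marker_px, cfg.pixel_size_nm, channel=marker or "marker")
    return marker_img, probe_img, labels


def write_field_image(img: FieldImage, path: str | Path) -> None:
    """Write a 32-bit float TIFF plus a JSON sidecar with pixel size/meta."""
    path = Path(path)
    tifffile.imwrite(path, img.pixels.astype(np.float32))
    sidecar = {"pixel_size_nm": img.pixel_size_nm, "channel": img.channel, **img.meta}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_field_image(path: str | Path) -> FieldImage:
    path = Path(path)
    pixels = tifffile.imread(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return FieldImage(
        pixels=pixels,
        pixel_size_nm=float(meta.pop("pixel_size_nm", 0.0) or 0.0),
        channel=meta.pop("channel", ""),
        meta=meta,
    )
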