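"""Forward widefield-microscope simulator and image-analysis pipeline.

The forward model deposits a unit-amplitude 3D Gaussian point-spread
function for every nucleolar bead onto a 7-plane voxel grid (64.8 nm
pixels, 200 nm z-step, 55 x 55 crop) and takes the maximum intensity
projection (MIP) — the same footprint as the CDC14-GFP acquisitions the
analysis pipeline was designed for.

The analysis chain mirrors the experimental one: Otsu thresholding on a
256-bin histogram, min-max normalization of the surviving signal, area in
um^2 via the pixel pitch, the standard deviation of the re-normalized
signal, and cluster counting by blind Richardson-Lucy deconvolution
(5 x 5 Gaussian kernel), two rounds of threshold-and-zero background
subtraction, regional-maxima detection (8-connectivity) and connected-
component counting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve

from .polymer import Trajectory

__all__ = [
    "ImagingParams",
    "ImageStack",
    "render_microscope_stack",
    "otsu_threshold",
    "normalize_intensities",
    "nucleolar_area",
    "normalized_signal_std",
    "count_clusters",
    "synth_image_fixture",
    "save_tiff",
    "load_tiff",
    "analyze_mip",
]


@dataclass
class ImagingParams:
    """Acquisition geometry and PSF of the simulated microscope."""

    pixel_size_um: float = 0.0648
    z_planes: int = 7
    z_step_nm: float = 200.0
    crop: int = 55
    psf_sigma_lateral_nm: float = 125.0
    psf_sigma_axial_nm: float = 300.0
    timepoints: int = 22

    def __post_init__(self):
        for name in ("pixel_size_um", "z_step_nm", "psf_sigma_lateral_nm",
                     "psf_sigma_axial_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.z_planes < 1 or self.crop < 1:
            raise ValueError("z_planes and crop must be positive")

    @property
    def pixel_size_nm(self) -> float:
        return self.pixel_size_um * 1000.0


@dataclass
class ImageStack:
    """A z-stack plus its maximum intensity projection."""

    stack: np.ndarray          # (z, y, x) non-negative intensities
    params: ImagingParams
    provenance: str = "simulated"   # "simulated" | "fixture" | "imported"
    truth: object = None       # e.g. ground-truth spot list for fixtures

    def __post_init__(self):
        self.stack = np.asarray(self.stack, dtype=float)
        if self.stack.ndim != 3:
            raise ValueError("stack must be (z, y, x)")

    @property
    def mip(self) -> np.ndarray:
        return self.stack.max(axis=0)


def render_microscope_stack(trajectory: Trajectory, t: float,
                            params: ImagingParams | None = None,
                            center: np.ndarray | None = None) -> ImageStack:
    """Render the nucleolar beads of frame ``t`` as a PSF-convolved stack.

    Each bead deposits a unit-amplitude 3D Gaussian sampled on the voxel
    grid; the grid is centered on the nucleolar centroid unless ``center``
    is given.  Beads outside the field of view contribute whatever tail
    falls on the grid.  Deterministic.
    """
    if params is None:
        params = ImagingParams()
    idx = trajectory.frame_index(t)
    pos = trajectory.positions[idx][trajectory.topology.nucleolar_mask]
    if center is None:
        center = pos.mean(axis=0)
    px = params.pixel_size_nm
    c = params.crop
    half = (c - 1) / 2.0
    xs = (np.arange(c) - half) * px + center[0]
    ys = (np.arange(c) - half) * px + center[1]
    zs = (np.arange(params.z_planes) - (params.z_planes - 1) / 2.0) \
        * params.z_step_nm + center[2]
    sl2 = 2.0 * params.psf_sigma_lateral_nm ** 2
    sa2 = 2.0 * params.psf_sigma_axial_nm ** 2
    stack = np.zeros((params.z_planes, c, c))
    for bx, by, bz in pos:
        gx = np.exp(-((xs - bx) ** 2) / sl2)
        gy = np.exp(-((ys - by) ** 2) / sl2)
        gz = np.exp(-((zs - bz) ** 2) / sa2)
        stack += gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
    return ImageStack(stack, params, provenance="simulated")


# ---------------------------------------------------------------------------
# Image statistics
# ---------------------------------------------------------------------------

def otsu_threshold(image: np.ndarray, nbins: int = 256) -> tuple:
    """Otsu's threshold over an ``nbins``-bin histogram.

    Returns ``(threshold, mask)`` where the threshold maximizes the
    between-class variance over the bin-center candidates and the mask
    selects pixels ``>= threshold``.  A constant image has no separable
    classes and raises ValueError.
    """
    img = np.asarray(image, dtype=float)
    finite = img[np.isfinite(img)]
    if finite.size == 0 or finite.max() == finite.min():
        raise ValueError("constant image: no separable intensity classes")
    counts, edges = np.histogram(finite, bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    w = counts.astype(float)
    p = w / w.sum()
    omega0 = np.cumsum(p)
    mu_t = np.cumsum(p * centers)
    mu_total = mu_t[-1]
    omega1 = 1.0 - omega0
    valid = (omega0 > 0) & (omega1 > 0)
    sigma_b = np.full(nbins, -np.inf)
    mu0 = mu_t[valid] / omega0[valid]
    mu1 = (mu_total - mu_t[valid]) / omega1[valid]
    sigma_b[valid] = omega0[valid] * omega1[valid] * (mu0 - mu1) ** 2
    # candidate t separates classes {<= center_t} / {> center_t}
    t_idx = int(np.argmax(sigma_b))
    threshold = float(centers[t_idx])
    mask = img >= threshold
    return threshold, mask


def normalize_intensities(image: np.ndarray,
                          mask: np.ndarray | None = None) -> np.ndarray:
    """Min-subtract then max-divide so the considered region spans [0, 1].

    With a mask, the min/max come from the masked region and pixels
    outside it are returned as NaN (they are excluded from any downstream
    statistic).  Idempotent on already-normalized input.
    """
    img = np.asarray(image, dtype=float)
    if mask is not None:
        region = img[mask & np.isfinite(img)]
    else:
        region = img[np.isfinite(img)]
    if region.size == 0 or region.max() == region.min():
        raise ValueError("constant region cannot be normalized")
    lo, hi = region.min(), region.max()
    out = (img - lo) / (hi - lo)
    if mask is not None:
        out = np.where(mask, out, np.nan)
    return out


def nucleolar_area(mip: np.ndarray, threshold: float,
                   pixel_size_um: float = 0.0648) -> float:
    """Suprathreshold pixel count converted to um^2 by the pixel area."""
    img = np.asarray(mip, dtype=float)
    count = int(np.sum(img[np.isfinite(img)] >= threshold))
    if count == 0:
        warnings.warn("empty mask: nucleolar area is 0")
    return count * pixel_size_um ** 2


def normalized_signal_std(mip: np.ndarray, threshold: float) -> float:
    """Population standard deviation of the suprathreshold signal after
    re-normalizing the surviving pixels to [0, 1]."""
    img = np.asarray(mip, dtype=float)
    vals = img[np.isfinite(img) & (img >= threshold)]
    if vals.size < 2:
        raise ValueError("fewer than 2 suprathreshold pixels")
    if vals.max() == vals.min():
        raise ValueError("surviving signal is constant")
    vals = (vals - vals.min()) / (vals.max() - vals.min())
    return float(vals.std(ddof=0))


# ---------------------------------------------------------------------------
# Cluster counting
# ---------------------------------------------------------------------------

def _gaussian_kernel(size: int = 5, sigma: float = 1.0) -> np.ndarray:
    ax = np.arange(size) - (size - 1) / 2.0
    g = np.exp(-(ax ** 2) / (2.0 * sigma ** 2))
    k = np.outer(g, g)
    return k / k.sum()


def _blind_richardson_lucy(image: np.ndarray, psf: np.ndarray,
                           iterations: int = 10) -> np.ndarray:
    """Blind Richardson-Lucy deconvolution: alternate multiplicative
    updates of the PSF (restricted to its support) and the image."""
    eps = 1e-12
    f = np.clip(image, 0, None) + eps
    obs = np.clip(image, 0, None) + eps
    psf = psf.copy()
    kh, kw = psf.shape
    for _ in range(iterations):
        # PSF update
        est = fftconvolve(f, psf, mode="same")
        ratio = obs / (est + eps)
        corr = fftconvolve(ratio, f[::-1, ::-1], mode="full")
        cy, cx = (corr.shape[0] - kh) // 2, (corr.shape[1] - kw) // 2
        psf = psf * corr[cy : cy + kh, cx : cx + kw]
        psf = np.clip(psf, 0, None)
        if psf.sum() <= 0:
            psf = _gaussian_kernel(kh)
        psf /= psf.sum()
        # image update
        est = fftconvolve(f, psf, mode="same")
        ratio = obs / (est + eps)
        f = f * fftconvolve(ratio, psf[::-1, ::-1], mode="same")
    return f


def count_clusters(mip: np.ndarray, deconv_iterations: int = 10,
                   recompute_threshold: bool = True) -> tuple:
    """Count bright clusters in a normalized MIP.

    Pipeline: blind Richardson-Lucy deconvolution seeded with a 5 x 5
    Gaussian kernel; two rounds of {Otsu threshold, zero sub-threshold
    pixels} (the second round re-runs Otsu on the survivors unless
    ``recompute_threshold`` is False); regional maxima with
    8-connectivity; plateaus collapse to one count via connected
    components.  Returns ``(count, peak_coordinates)``.
    """
    img = np.asarray(mip, dtype=float)
    img = np.where(np.isfinite(img), img, 0.0)
    if img.max() == img.min():
        return 0, np.empty((0, 2), dtype=int)
    f = _blind_richardson_lucy(img, _gaussian_kernel(5, 1.0),
                               deconv_iterations)
    thr0 = None
    for round_idx in range(2):
        if f.max() == f.min():
            return 0, np.empty((0, 2), dtype=int)
        if round_idx == 0 or recompute_threshold:
            try:
                thr, _ = otsu_threshold(f[f > 0] if round_idx else f)
            except ValueError:
                return 0, np.empty((0, 2), dtype=int)
            thr0 = thr
        f = np.where(f >= thr0, f, 0.0)
    if f.max() <= 0:
        return 0, np.empty((0, 2), dtype=int)
    from skimage.morphology import local_maxima

    maxima = local_maxima(f, connectivity=2) & (f > 0)
    labeled, n = ndimage.label(maxima, structure=np.ones((3, 3), dtype=int))
    coords = np.array(ndimage.center_of_mass(maxima, labeled,
                                             range(1, n + 1))).reshape(-1, 2)
    return int(n), np.round(coords).astype(int)


# ---------------------------------------------------------------------------
# Synthetic fixtures and I/O
# ---------------------------------------------------------------------------

def synth_image_fixture(n_spots: int, spot_sigma: float = 2.0,
                        noise_sd: float = 0.01, seed: int = 0,
                        params: ImagingParams | None = None,
                        blob_radius_px: float = 18.0,
                        min_separation_px: float = 0.0) -> ImageStack:
    """Synthetic stand-in for an experimental nucleolar z-stack.

    Places ``n_spots`` unit-amplitude Gaussian spots (lateral sigma
    ``spot_sigma`` px) inside a disk of ``blob_radius_px`` centered in the
    crop, across the middle z-planes, plus Gaussian read noise.  The
    ground-truth spot list is stored on ``truth``.  Reproducible from
    ``seed``.
    """
    if n_spots < 0:
        raise ValueError("n_spots must be >= 0")
    if params is None:
        params = ImagingParams()
    rng = np.random.default_rng(seed)
    c = params.crop
    z = params.z_planes
    stack = np.zeros((z, c, c))
    centers = []
    tries = 0
    while len(centers) < n_spots and tries < 10000:
        tries += 1
        r = blob_radius_px * np.sqrt(rng.random())
        phi = 2 * np.pi * rng.random()
        cx = (c - 1) / 2.0 + r * np.cos(phi)
        cy = (c - 1) / 2.0 + r * np.sin(phi)
        cz = (z - 1) / 2.0 + rng.normal(0, 0.5)
        if min_separation_px > 0 and any(
                (cx - ox) ** 2 + (cy - oy) ** 2 < min_separation_px ** 2
                for ox, oy, _ in centers):
            continue
        centers.append((cx, cy, cz))
    xs = np.arange(c)
    zs = np.arange(z)
    for cx, cy, cz in centers:
        gx = np.exp(-((xs - cx) ** 2) / (2 * spot_sigma ** 2))
        gy = np.exp(-((xs - cy) ** 2) / (2 * spot_sigma ** 2))
        gz = np.exp(-((zs - cz) ** 2) / (2 * 1.0 ** 2))
        stack += gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
    if noise_sd > 0:
        stack = np.clip(stack + rng.normal(0, noise_sd, stack.shape), 0, None)
    return ImageStack(stack, params, provenance="fixture",
                      truth=np.asarray(centers).reshape(-1, 3))


def save_tiff(image_stack: ImageStack, path) -> None:
    import tifffile

    tifffile.imwrite(path, image_stack.stack.astype(np.float32))


def load_tiff(path, params: ImagingParams | None = None) -> ImageStack:
    import tifffile

    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None, :, :]
    return ImageStack(np.asarray(stack, dtype=float),
                      params or ImagingParams(), provenance="imported")


def analyze_mip(mip: np.ndarray, pixel_size_um: float = 0.0648) -> dict:
    """The per-image report: Otsu threshold, area (um^2), raw and
    normalized signal SDs, and cluster count."""
    thr, mask = otsu_threshold(mip)
    area = nucleolar_area(mip, thr, pixel_size_um)
    raw_sd = float(np.asarray(mip, dtype=float)[np.isfinite(mip)].std(ddof=0))
    try:
        norm_sd = normalized_signal_std(mip, thr)
    except ValueError:
        norm_sd = float("nan")
    norm = normalize_intensities(np.asarray(mip, dtype=float))
    n_clusters, _ = count_clusters(norm)
    return {"threshold": thr, "area_um2": area, "raw_sd": raw_sd,
            "normalized_sd": norm_sd, "n_clusters": n_clusters}
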