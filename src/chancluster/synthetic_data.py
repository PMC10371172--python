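"""Seeded synthetic inputs with known ground truth.

Every downstream stage of the package (segmentation, size-distribution
fitting, sparklet idealization, coupling estimation) is exercised against
images and traces produced here, so each generator returns both the
rendered artifact and the ground truth used to render it.

The rendering model is deliberately simple: a cluster is a uniform-intensity
disk (2D) or sphere (3D) of the drawn size, optionally convolved with a
Gaussian PSF, plus additive Gaussian noise. Super-resolution localization
renders are exported by acquisition software as thresholded, near-binary
images, so the 2D defaults are noise-free and unblurred; confocal-like
stacks default to a diffraction-scale PSF. Photophysics (blinking,
localization precision, drift) is out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "FieldSpec",
    "GroundTruthClusters",
    "gen_localization_field",
    "gen_confocal_stack",
    "gen_sparklet_traces",
    "gen_cluster_sizes",
    "write_field",
    "write_stack",
]


class PlacementError(RuntimeError):
    """Raised when non-overlapping cluster placement fails by rejection."""


@dataclass(frozen=True)
class FieldSpec:
    """Physical geometry and imaging model of a synthetic field or stack.

    Parameters
    ----------
    width_nm, height_nm : float
        Lateral extent of the field.
    depth_um : float, optional
        Axial extent; required for 3D stacks.
    pixel_nm : float
        Lateral render pitch. Default 20 nm/px, the pitch at which
        single-molecule localization data are rendered.
    voxel_z_um : float
        Axial step for stacks. Default 0.13 um/step (spinning-disk confocal
        z-sampling).
    psf_sigma_nm : float
        Gaussian PSF sigma applied after painting. 0 disables blurring
        (binary-like localization render).
    noise_sd : float
        Additive Gaussian noise, in units of the unit cluster intensity.
    seed : int
        RNG seed; identical spec + seed gives bit-identical output.
    """

    width_nm: float
    height_nm: float
    depth_um: float | None = None
    pixel_nm: float = 20.0
    voxel_z_um: float = 0.13
    psf_sigma_nm: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_nm <= 0 or self.height_nm <= 0:
            raise ValueError("field extents must be positive")
        if self.depth_um is not None and self.depth_um <= 0:
            raise ValueError("depth_um must be positive")
        if self.pixel_nm <= 0 or self.voxel_z_um <= 0:
            raise ValueError("pixel/voxel pitch must be positive")
        if self.psf_sigma_nm < 0:
            raise ValueError("psf_sigma_nm must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def shape_2d(self) -> tuple[int, int]:
        return (
            int(round(self.height_nm / self.pixel_nm)),
            int(round(self.width_nm / self.pixel_nm)),
        )

    @property
    def shape_3d(self) -> tuple[int, int, int]:
        if self.depth_um is None:
            raise ValueError("depth_um is required for a 3D stack")
        nz = int(round(self.depth_um / self.voxel_z_um))
        ny, nx = self.shape_2d
        return (nz, ny, nx)


@dataclass
class GroundTruthClusters:
    """True centroids and sizes used to render a synthetic field/stack.

    ``centroids_nm`` is (n, 2) for 2D fields ((x, y) nm) or (n, 3) for
    stacks ((x, y, z) with z in nm as well). ``sizes`` are areas in nm^2
    (2D) or volumes in um^3 (3D).
    """

    centroids_nm: np.ndarray
    sizes: np.ndarray
    size_distribution_scale: float
    units: str = "nm2"

    def __post_init__(self) -> None:
        self.centroids_nm = np.asarray(self.centroids_nm, dtype=float)
        self.sizes = np.asarray(self.sizes, dtype=float)
        if np.any(self.sizes <= 0):
            raise ValueError("ground-truth sizes must be positive")

    def __len__(self) -> int:
        return int(self.sizes.size)

    def to_frame(self) -> pd.DataFrame:
        cols = ["x_nm", "y_nm", "z_nm"][: self.centroids_nm.shape[1]] if len(self) else ["x_nm", "y_nm"]
        df = pd.DataFrame(
            self.centroids_nm.reshape(len(self), -1) if len(self) else np.empty((0, len(cols))),
            columns=cols,
        )
        df["size_" + self.units] = self.sizes
        return df


_MAX_RETRIES = 1000


def _place_disks(
    rng: np.random.Generator,
    radii_nm: np.ndarray,
    width_nm: float,
    height_nm: float,
    margin_nm: float,
) -> np.ndarray:
    """Place circle centers uniformly without overlap, by rejection."""
    n = radii_nm.size
    centers = np.empty((n, 2))
    for i in range(n):
        r = radii_nm[i]
        for attempt in range(_MAX_RETRIES):
            x = rng.uniform(0.0, width_nm)
            y = rng.uniform(0.0, height_nm)
            if i == 0:
                break
            d2 = (centers[:i, 0] - x) ** 2 + (centers[:i, 1] - y) ** 2
            min_sep = radii_nm[:i] + r + margin_nm
            if np.all(d2 > min_sep**2):
                break
        else:
            raise PlacementError(
                f"could not place cluster {i + 1}/{n} without overlap after "
                f"{_MAX_RETRIES} retries; requested density exceeds the "
                f"non-overlap limit for this field size"
            )
        centers[i] = (x, y)
    return centers


def gen_localization_field(
    spec: FieldSpec,
    n_clusters: int,
    mean_area_nm2: float,
    margin_nm: float | None = None,
    areas_nm2: np.ndarray | None = None,
) -> tuple[np.ndarray, GroundTruthClusters]:
    """Render a 2D localization-style field of exponentially sized clusters.

    Cluster areas are i.i.d. exponential with mean ``mean_area_nm2``;
    centers are uniform with pairwise non-overlap enforced by rejection.
    Each cluster is painted as a unit-intensity disk (at minimum its
    centroid pixel), then blurred by ``spec.psf_sigma_nm`` and corrupted by
    ``spec.noise_sd``.

    Returns (image, truth); image shape is ``spec.shape_2d`` (row, col).
    """
    if n_clusters < 0:
        raise ValueError("n_clusters must be >= 0")
    if mean_area_nm2 <= 0:
        raise ValueError("mean_area_nm2 must be positive")
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape_2d
    image = np.zeros(shape, dtype=float)

    if n_clusters == 0:
        truth = GroundTruthClusters(
            np.empty((0, 2)), np.empty(0) + 1.0, mean_area_nm2, units="nm2"
        )
        truth.sizes = np.empty(0)
        return _finish_render(image, spec, rng), truth

    if areas_nm2 is not None:
        areas = np.asarray(areas_nm2, dtype=float)
        if areas.size != n_clusters:
            raise ValueError("areas_nm2 must have length n_clusters")
    else:
        areas = rng.exponential(mean_area_nm2, size=n_clusters)
    radii = np.sqrt(areas / np.pi)
    if margin_nm is None:
        margin_nm = 2.0 * spec.pixel_nm
    centers = _place_disks(rng, radii, spec.width_nm, spec.height_nm, margin_nm)

    px = spec.pixel_nm
    for (x, y), r in zip(centers, radii):
        _paint_disk(image, x / px, y / px, r / px)

    truth = GroundTruthClusters(centers, areas, mean_area_nm2, units="nm2")
    return _finish_render(image, spec, rng), truth


def _paint_disk(image: np.ndarray, cx_px: float, cy_px: float, r_px: float) -> None:
    """Paint a disk as the round(pi r^2) pixels nearest the center (>= 1).

    Area-matched painting: the painted pixel count is the drawn area rounded
    to whole pixels, so rendered sizes track drawn sizes without the +-1
    pixel jitter of a center-in-disk rule.
    """
    ny, nx = image.shape
    n_px = max(1, int(round(np.pi * r_px**2)))
    # candidate window comfortably larger than the disk
    half = int(np.ceil(r_px)) + 2
    x0 = max(int(cx_px) - half, 0)
    x1 = min(int(cx_px) + half + 1, nx)
    y0 = max(int(cy_px) - half, 0)
    y1 = min(int(cy_px) + half + 1, ny)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d2 = (xx + 0.5 - cx_px) ** 2 + (yy + 0.5 - cy_px) ** 2
    flat = np.argsort(d2, axis=None)[: min(n_px, d2.size)]
    iy, ix = np.unravel_index(flat, d2.shape)
    image[yy[iy, ix], xx[iy, ix]] = 1.0


def _finish_render(image: np.ndarray, spec: FieldSpec, rng: np.random.Generator) -> np.ndarray:
    from scipy import ndimage

    if spec.psf_sigma_nm > 0:
        sigma_px = spec.psf_sigma_nm / spec.pixel_nm
        if image.ndim == 3:
            sigma = (spec.psf_sigma_nm / (spec.voxel_z_um * 1000.0), sigma_px, sigma_px)
        else:
            sigma = sigma_px
        image = ndimage.gaussian_filter(image, sigma=sigma, mode="reflect")
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    return image


def _boundary_shell_mask(shape: tuple[int, int, int], thickness_vox: tuple[float, float, float]) -> np.ndarray:
    """Voxels within the given thickness (per axis, voxels) of the volume border."""
    nz, ny, nx = shape
    tz, ty, tx = thickness_vox
    zz = np.arange(nz)[:, None, None]
    yy = np.arange(ny)[None, :, None]
    xx = np.arange(nx)[None, None, :]
    near_z = (zz < tz) | (zz >= nz - tz)
    near_y = (yy < ty) | (yy >= ny - ty)
    near_x = (xx < tx) | (xx >= nx - tx)
    return near_z | near_y | near_x


def gen_confocal_stack(
    spec: FieldSpec,
    n_clusters: int,
    mean_volume_um3: float,
    shell: str | float = "whole",
    volumes_um3: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, GroundTruthClusters]:
    """Render a confocal-like 3D stack with clusters confined to a membrane mask.

    Parameters
    ----------
    shell : "whole" or float
        "whole" places clusters anywhere (mask = all ones). A float is a
        membrane-shell thickness in um: the mask is the set of voxels within
        that distance of the volume boundary, emulating a WGA-stained
        sarcolemmal shell. Must be at least one voxel thick.

    Cluster volumes are exponential with mean ``mean_volume_um3``; each
    cluster is painted as a unit-intensity sphere whose voxels all lie
    inside the mask (falls back to centroid-inside if the sphere cannot fit
    after the retry budget). Returns (stack, mask, truth); stack axes are
    (z, y, x).
    """
    if spec.depth_um is None:
        raise ValueError("spec.depth_um is required for a stack")
    if n_clusters < 0:
        raise ValueError("n_clusters must be >= 0")
    if mean_volume_um3 <= 0:
        raise ValueError("mean_volume_um3 must be positive")
    shape = spec.shape_3d
    vx_um = spec.pixel_nm / 1000.0
    vz_um = spec.voxel_z_um

    if shell == "whole":
        mask = np.ones(shape, dtype=bool)
    else:
        t_um = float(shell)
        if t_um < min(vx_um, vz_um):
            raise ValueError(
                f"shell thickness {t_um} um is thinner than one voxel "
                f"({min(vx_um, vz_um)} um)"
            )
        mask = _boundary_shell_mask(shape, (t_um / vz_um, t_um / vx_um, t_um / vx_um))

    rng = np.random.default_rng(spec.seed)
    stack = np.zeros(shape, dtype=float)
    if n_clusters == 0:
        truth = GroundTruthClusters(np.empty((0, 3)), np.empty(0), mean_volume_um3, units="um3")
        truth.sizes = np.empty(0)
        return _finish_render(stack, spec, rng), mask, truth

    if volumes_um3 is not None:
        volumes = np.asarray(volumes_um3, dtype=float)
        if volumes.size != n_clusters:
            raise ValueError("volumes_um3 must have length n_clusters")
    else:
        volumes = rng.exponential(mean_volume_um3, size=n_clusters)
    radii_um = (3.0 * volumes / (4.0 * np.pi)) ** (1.0 / 3.0)

    nz, ny, nx = shape
    centers_vox = np.empty((n_clusters, 3))  # (z, y, x) voxel coords
    placed_r = radii_um
    for i in range(n_clusters):
        r = radii_um[i]
        ok = False
        for attempt in range(_MAX_RETRIES):
            cz = rng.uniform(0, nz)
            cy = rng.uniform(0, ny)
            cx = rng.uniform(0, nx)
            if not mask[min(int(cz), nz - 1), min(int(cy), ny - 1), min(int(cx), nx - 1)]:
                continue
            if i > 0:
                dz = (centers_vox[:i, 0] - cz) * vz_um
                dy = (centers_vox[:i, 1] - cy) * vx_um
                dx = (centers_vox[:i, 2] - cx) * vx_um
                sep = placed_r[:i] + r + 2 * vx_um
                if np.any(dz**2 + dy**2 + dx**2 <= sep**2):
                    continue
            if _sphere_fits(mask, (cz, cy, cx), r, vz_um, vx_um) or attempt >= _MAX_RETRIES // 2:
                ok = True
                break
        if not ok:
            raise PlacementError(
                f"could not place cluster {i + 1}/{n_clusters} inside the "
                f"membrane mask after {_MAX_RETRIES} retries; reduce density "
                f"or thicken the shell"
            )
        centers_vox[i] = (cz, cy, cx)

    for (cz, cy, cx), r in zip(centers_vox, radii_um):
        _paint_sphere(stack, (cz, cy, cx), r, vz_um, vx_um)

    centroids_nm = np.column_stack(
        [
            centers_vox[:, 2] * spec.pixel_nm,
            centers_vox[:, 1] * spec.pixel_nm,
            centers_vox[:, 0] * vz_um * 1000.0,
        ]
    )
    truth = GroundTruthClusters(centroids_nm, volumes, mean_volume_um3, units="um3")
    return _finish_render(stack, spec, rng), mask, truth


def _sphere_voxels(shape, center_vox, r_um, vz_um, vxy_um):
    cz, cy, cx = center_vox
    nz, ny, nx = shape
    rz = r_um / vz_um
    rxy = r_um / vxy_um
    z0, z1 = max(int(cz - rz) - 1, 0), min(int(cz + rz) + 2, nz)
    y0, y1 = max(int(cy - rxy) - 1, 0), min(int(cy + rxy) + 2, ny)
    x0, x1 = max(int(cx - rxy) - 1, 0), min(int(cx + rxy) + 2, nx)
    if z0 >= z1 or y0 >= y1 or x0 >= x1:
        return None, None
    zz, yy, xx = np.mgrid[z0:z1, y0:y1, x0:x1]
    d2 = (
        ((zz + 0.5 - cz) * vz_um) ** 2
        + ((yy + 0.5 - cy) * vxy_um) ** 2
        + ((xx + 0.5 - cx) * vxy_um) ** 2
    )
    inside = d2 <= r_um**2
    return (slice(z0, z1), slice(y0, y1), slice(x0, x1)), inside


def _sphere_fits(mask, center_vox, r_um, vz_um, vxy_um) -> bool:
    sl, inside = _sphere_voxels(mask.shape, center_vox, r_um, vz_um, vxy_um)
    if sl is None or not inside.any():
        cz, cy, cx = (min(max(int(c), 0), n - 1) for c, n in zip(center_vox, mask.shape))
        return bool(mask[cz, cy, cx])
    return bool(np.all(mask[sl][inside]))


def _paint_sphere(stack, center_vox, r_um, vz_um, vxy_um) -> None:
    """Paint a sphere as the round(V/voxel_volume) voxels nearest the center."""
    cz, cy, cx = center_vox
    nz, ny, nx = stack.shape
    vol_um3 = 4.0 / 3.0 * np.pi * r_um**3
    n_vox = max(1, int(round(vol_um3 / (vz_um * vxy_um * vxy_um))))
    hz = int(np.ceil(r_um / vz_um)) + 2
    hxy = int(np.ceil(r_um / vxy_um)) + 2
    z0, z1 = max(int(cz) - hz, 0), min(int(cz) + hz + 1, nz)
    y0, y1 = max(int(cy) - hxy, 0), min(int(cy) + hxy + 1, ny)
    x0, x1 = max(int(cx) - hxy, 0), min(int(cx) + hxy + 1, nx)
    if z0 >= z1 or y0 >= y1 or x0 >= x1:
        return
    zz, yy, xx = np.mgrid[z0:z1, y0:y1, x0:x1]
    d2 = (
        ((zz + 0.5 - cz) * vz_um) ** 2
        + ((yy + 0.5 - cy) * vxy_um) ** 2
        + ((xx + 0.5 - cx) * vxy_um) ** 2
    )
    flat = np.argsort(d2, axis=None)[: min(n_vox, d2.size)]
    iz, iy, ix = np.unravel_index(flat, d2.shape)
    stack[zz[iz, iy, ix], yy[iz, iy, ix], xx[iz, iy, ix]] = 1.0


def gen_sparklet_traces(
    params,
    quantal_dF: float,
    noise_sd: float,
    fs_hz: float = 100.0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate a sparklet fluorescence trace from N coupled two-state channels.

    The per-frame open-channel count k(t) comes from the coupled-gating
    model (see :mod:`chancluster.sparklet`); the recorded trace is
    ``k(t) * quantal_dF + N(0, noise_sd)``, sampled at ``fs_hz`` (default
    100 Hz, the sparklet acquisition rate).

    Returns (trace DataFrame with columns time_s and dF, true k series).
    """
    from .sparklet import simulate_coupled_gating

    if fs_hz <= 0:
        raise ValueError("fs_hz must be positive")
    if quantal_dF <= 0:
        raise ValueError("quantal_dF must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    k = simulate_coupled_gating(params)
    # independent noise stream, decoupled from the gating RNG
    rng = np.random.default_rng(np.random.SeedSequence([int(params.seed), 81]))
    df_values = k * quantal_dF + rng.normal(0.0, noise_sd, size=k.size)
    t = np.arange(k.size) / fs_hz
    trace = pd.DataFrame({"time_s": t, "dF": df_values})
    return trace, k


def gen_cluster_sizes(n: int, scale: float, seed: int = 0) -> np.ndarray:
    """Draw n i.i.d. exponential cluster sizes with mean ``scale``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if scale <= 0:
        raise ValueError("scale must be positive")
    rng = np.random.default_rng(seed)
    return rng.exponential(scale, size=n)


def _sidecar(spec: FieldSpec, extra: dict | None = None) -> dict:
    d = asdict(spec)
    if extra:
        d.update(extra)
    return d


def write_field(
    out_dir: str | Path,
    stem: str,
    image: np.ndarray,
    truth: GroundTruthClusters,
    spec: FieldSpec,
) -> dict[str, Path]:
    """Write a 2D render as TIFF with pixel-size metadata + CSV/JSON ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "tiff": out / f"{stem}.tif",
        "truth": out / f"{stem}_truth.csv",
        "spec": out / f"{stem}_spec.json",
    }
    res_ppum = 1000.0 / spec.pixel_nm  # pixels per micron
    tifffile.imwrite(
        paths["tiff"],
        image.astype(np.float32),
        resolution=(res_ppum, res_ppum),
        metadata={"unit": "um", "pixel_nm": spec.pixel_nm},
    )
    truth.to_frame().to_csv(paths["truth"], index=False)
    paths["spec"].write_text(json.dumps(_sidecar(spec), indent=2))
    return paths


def write_stack(
    out_dir: str | Path,
    stem: str,
    stack: np.ndarray,
    mask: np.ndarray,
    truth: GroundTruthClusters,
    spec: FieldSpec,
) -> dict[str, Path]:
    """Write a 3D stack + membrane mask as multipage TIFF with voxel metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "tiff": out / f"{stem}.tif",
        "mask": out / f"{stem}_mask.tif",
        "truth": out / f"{stem}_truth.csv",
        "spec": out / f"{stem}_spec.json",
    }
    res_ppum = 1000.0 / spec.pixel_nm
    meta = {"unit": "um", "spacing": spec.voxel_z_um, "pixel_nm": spec.pixel_nm, "axes": "ZYX"}
    tifffile.imwrite(paths["tiff"], stack.astype(np.float32), resolution=(res_ppum, res_ppum), metadata=meta)
    tifffile.imwrite(paths["mask"], mask.astype(np.uint8), resolution=(res_ppum, res_ppum), metadata=meta)
    truth.to_frame().to_csv(paths["truth"], index=False)
    paths["spec"].write_text(json.dumps(_sidecar(spec), indent=2))
    return paths
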