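"""Synthetic TIRF image formation: kymographs and fields of view.

The imaging model is deliberately simple but faithful to the acquisition
geometry of a surface (TIRF) assay recorded on a 107 nm/pixel camera:

* a filament is a line of fluorophore density (``photons_per_um`` expected
  photons per µm of labelled polymer per frame);
* per pixel, the expected signal is the geometric overlap of the polymer
  with the pixel, convolved with an isotropic Gaussian PSF;
* shot noise is Poisson on signal + flat background, plus Gaussian camera
  read noise.

Kymographs are time × position images: rows are frames, columns are
positions along the filament axis with the origin at the seed minus end
(column ``k`` covers positions ``[k·px, (k+1)·px)``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
import yaml
from scipy import ndimage

from .synthetic_data import FilamentTrajectory, _as_rng

__all__ = [
    "OpticsConfig",
    "Kymograph",
    "FieldOverflowError",
    "render_kymograph",
    "render_field",
    "make_arc_filament",
]


class FieldOverflowError(ValueError):
    """The filament grew beyond the rendered field of view."""


@dataclass(frozen=True)
class OpticsConfig:
    """Acquisition parameters of the synthetic microscope.

    Defaults: 107 nm pixels, 2 s frames, 130 nm PSF sigma (≈ λ/2NA for a
    637 nm laser and 1.46 NA objective), and a photon budget giving a tip
    signal-to-noise ratio of roughly 5.
    """

    pixel_size_nm: float = 107.0
    frame_interval_s: float = 2.0
    psf_sigma_nm: float = 130.0
    photons_per_um: float = 1000.0
    background_photons: float = 20.0
    read_noise_sd: float = 2.0
    channels: tuple[str, ...] = ("seed", "lattice")

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0 or self.frame_interval_s <= 0:
            raise ValueError("pixel size and frame interval must be positive")
        if self.photons_per_um <= 0:
            raise ValueError("photons_per_um must be positive")
        if self.psf_sigma_nm < 0:
            raise ValueError("psf_sigma_nm must be non-negative")

    @property
    def pixel_size_um(self) -> float:
        return self.pixel_size_nm / 1000.0

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_sigma_nm / self.pixel_size_nm


@dataclass
class Kymograph:
    """Per-channel time × position intensity with calibration.

    ``seed_extent`` is the half-open column range occupied by the
    stabilized seed.
    """

    channels: dict[str, np.ndarray]
    optics: OpticsConfig
    seed_extent: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        shapes = {a.shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError("all channels must share a shape")
        for a in self.channels.values():
            if np.any(a < 0):
                raise ValueError("intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def n_cols(self) -> int:
        return next(iter(self.channels.values())).shape[1]

    @property
    def frame_times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.optics.frame_interval_s

    def write(self, path: str | Path) -> None:
        """Write as multi-page TIFF (one page per channel) + YAML sidecar."""
        path = Path(path)
        stack = np.stack([self.channels[c] for c in self.optics.channels if c in self.channels])
        tifffile.imwrite(path, stack.astype(np.float32))
        meta = {
            "pixel_size_nm": self.optics.pixel_size_nm,
            "frame_interval_s": self.optics.frame_interval_s,
            "channels": [c for c in self.optics.channels if c in self.channels],
            "seed_extent": list(self.seed_extent),
        }
        path.with_suffix(path.suffix + ".yaml").write_text(yaml.safe_dump(meta))

    @classmethod
    def read(cls, path: str | Path) -> "Kymograph":
        path = Path(path)
        stack = tifffile.imread(path)
        if stack.ndim == 2:
            stack = stack[None]
        meta = yaml.safe_load(path.with_suffix(path.suffix + ".yaml").read_text())
        optics = OpticsConfig(
            pixel_size_nm=meta["pixel_size_nm"],
            frame_interval_s=meta["frame_interval_s"],
            channels=tuple(meta["channels"]),
        )
        channels = {c: stack[i] for i, c in enumerate(meta["channels"])}
        return cls(channels, optics, tuple(meta["seed_extent"]))


def _interval_coverage(n_cols: int, px_um: float, x0: float, x1: float) -> np.ndarray:
    """Per-pixel overlap length (µm) of the interval [x0, x1) with each pixel."""
    edges = np.arange(n_cols + 1) * px_um
    return np.clip(np.minimum(x1, edges[1:]) - np.maximum(x0, edges[:-1]), 0.0, None)


def _add_noise(
    expected: np.ndarray, optics: OpticsConfig, rng: np.random.Generator
) -> np.ndarray:
    img = rng.poisson(expected + optics.background_photons).astype(float)
    if optics.read_noise_sd > 0:
        img += rng.normal(0.0, optics.read_noise_sd, img.shape)
    return np.clip(img, 0.0, None)


def render_kymograph(
    trajectory: FilamentTrajectory,
    optics: OpticsConfig = OpticsConfig(),
    rng_seed: int | np.random.Generator | None = None,
    seed_length_um: float = 2.0,
    field_length_um: float | None = None,
    noise: bool = True,
) -> Kymograph:
    """Render a trajectory as a two-channel kymograph.

    The stabilized seed occupies ``[0, seed_length_um)`` in the ``seed``
    channel; the dynamic polymer occupies ``[seed_length_um,
    seed_length_um + length(t))`` in the ``lattice`` channel.  With
    ``noise=False`` the expected (photon-mean) image is returned, with no
    background.
    """
    rng = _as_rng(rng_seed)
    dt = optics.frame_interval_s
    if trajectory.duration_s < dt:
        raise ValueError("trajectory shorter than one frame")
    n_rows = int(np.ceil(trajectory.duration_s / dt))
    t = np.arange(n_rows) * dt
    lengths = trajectory.length_at(t)
    px = optics.pixel_size_um
    max_extent = seed_length_um + float(lengths.max())
    if field_length_um is None:
        field_length_um = max_extent + 2.0
    elif max_extent > field_length_um:
        raise FieldOverflowError(
            f"filament extent {max_extent:.2f} µm exceeds field {field_length_um:.2f} µm"
        )
    n_cols = int(np.ceil(field_length_um / px))

    lattice = np.zeros((n_rows, n_cols))
    for i, L in enumerate(lengths):
        if L > 0:
            cov = _interval_coverage(n_cols, px, seed_length_um, seed_length_um + L)
            lattice[i] = cov * optics.photons_per_um
    seed = np.zeros((n_rows, n_cols))
    if seed_length_um > 0:
        seed[:] = _interval_coverage(n_cols, px, 0.0, seed_length_um) * optics.photons_per_um

    if optics.psf_sigma_px > 0:
        lattice = ndimage.gaussian_filter1d(lattice, optics.psf_sigma_px, axis=1, mode="constant")
        seed = ndimage.gaussian_filter1d(seed, optics.psf_sigma_px, axis=1, mode="constant")
    if noise:
        lattice = _add_noise(lattice, optics, rng)
        seed = _add_noise(seed, optics, rng)

    seed_cols = (0, int(round(seed_length_um / px)))
    return Kymograph({"seed": seed, "lattice": lattice}, optics, seed_cols)


def render_field(
    filaments: list[np.ndarray],
    optics: OpticsConfig = OpticsConfig(),
    field_size_um: float = 110.0,
    rng_seed: int | np.random.Generator | None = None,
    noise: bool = True,
) -> np.ndarray:
    """Render point-chain filaments into a square field of view.

    Each filament is an (N, 2) array of (x, y) in µm inside the field.
    Chains are resampled at uniform arc length (quarter-pixel steps) and
    deposited as line density before PSF blur and noise.  An empty list
    yields a background-only image.
    """
    rng = _as_rng(rng_seed)
    px = optics.pixel_size_um
    n = int(np.ceil(field_size_um / px))
    expected = np.zeros((n, n))
    step = px / 4.0
    for chain in filaments:
        chain = np.asarray(chain, dtype=float)
        if chain.ndim != 2 or chain.shape[1] != 2 or len(chain) < 2:
            raise ValueError("each filament must be an (N>=2, 2) point chain")
        if np.any(chain < 0) or np.any(chain > field_size_um):
            raise FieldOverflowError("filament coordinates outside field of view")
        seglen = np.linalg.norm(np.diff(chain, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seglen)])
        total = s[-1]
        if total <= 0:
            raise ValueError("degenerate filament (zero length)")
        su = np.arange(0.0, total, step)
        xs = np.interp(su, s, chain[:, 0])
        ys = np.interp(su, s, chain[:, 1])
        cols = np.clip((xs / px).astype(int), 0, n - 1)
        rows = np.clip((ys / px).astype(int), 0, n - 1)
        np.add.at(expected, (rows, cols), optics.photons_per_um * step)
    if optics.psf_sigma_px > 0:
        expected = ndimage.gaussian_filter(expected, optics.psf_sigma_px, mode="constant")
    if noise:
        return _add_noise(expected, optics, rng)
    return expected


def make_arc_filament(
    radius_um: float,
    arc_span_rad: float,
    n_points: int = 50,
    center: tuple[float, float] = (0.0, 0.0),
    start_angle_rad: float = 0.0,
) -> np.ndarray:
    """Points on a circular arc with uniform arc-length spacing.

    A fixture generator for curvature tests: the analytic curvature of the
    returned chain is 1/radius everywhere.
    """
    if radius_um <= 0:
        raise ValueError("radius must be positive")
    if n_points < 3:
        raise ValueError("need at least 3 points")
    theta = start_angle_rad + np.linspace(0.0, arc_span_rad, n_points)
    return np.column_stack(
        [center[0] + radius_um * np.cos(theta), center[1] + radius_um * np.sin(theta)]
    )
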