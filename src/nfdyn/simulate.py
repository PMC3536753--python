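"""Two-channel synthetic time-lapse movies with exported ground truth.

Renders populations of simulated cells into the kind of data the analysis
pipeline consumes: a constitutive nuclear-marker channel (for segmentation and
tracking) and a translocation-reporter channel in which each cell's reporter
redistributes between nucleus and a surrounding cytoplasmic annulus.  The
reporter is conserved per cell — nuclear mean n(t) and cytoplasmic mean c(t)
satisfy n(t)/c(pre) = true_trace(t) and n(t)·area_nuc + c(t)·area_cyto =
constant — so the measured normalized nuclear localization of a noiseless
render reproduces the generative trace exactly up to pixel quantization.

Nuclei are hard-edged ellipses placed on a jittered grid; they move by a
reflected random walk.  Noise is Poisson shot noise at a configurable photon
scale plus Gaussian read noise.  Not modeled: photobleaching, illumination
shading, cell division, PSF blur.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .response_model import PreparationPreset, SimulatedCell, sample_population

__all__ = [
    "ImagingConfig",
    "Movie",
    "GroundTruth",
    "FormatError",
    "render_movie",
    "write_movie",
    "read_movie",
    "write_ground_truth",
    "simulate_condition",
]

CHANNELS = ("nuclear_marker", "reporter")


class FormatError(ValueError):
    """A movie file that does not match the expected two-channel layout."""


@dataclass(frozen=True)
class ImagingConfig:
    """Acquisition geometry, optics and noise of the synthetic microscope.

    Times in minutes, lengths in pixels, intensities in arbitrary units
    (``photon_scale`` photons per unit; 0 disables shot noise).
    """

    n_frames: int = 120
    dt: float = 5.0
    stim_frame: int = 3
    height: int = 512
    width: int = 512
    nucleus_semi_axes: tuple[float, float] = (7.0, 11.0)  # (min, max) pixels
    cyto_extent: float = 10.0  # annulus thickness beyond the nucleus
    background: float = 20.0
    nuclear_brightness: float = 300.0  # marker channel, above background
    cyto_pre: float = 120.0  # pre-stimulus cytoplasmic reporter level
    photon_scale: float = 1.0
    read_noise_sd: float = 2.0
    motion_sd: float = 1.0  # random-walk step, pixels/frame
    motion_reversion: float = 0.05  # pull toward the home site, per frame
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if not (1 <= self.stim_frame < self.n_frames):
            raise ValueError("stim_frame must be >= 1 and < n_frames")
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        for name in ("background", "photon_scale", "read_noise_sd", "motion_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.nucleus_semi_axes
        if not 0 < lo <= hi:
            raise ValueError("nucleus_semi_axes must satisfy 0 < min <= max")

    @property
    def time_grid(self) -> np.ndarray:
        return (np.arange(self.n_frames) - self.stim_frame) * self.dt


@dataclass
class Movie:
    """Two-channel intensity stack, (frame, channel, row, col)."""

    stack: np.ndarray
    dt: float
    stim_frame: int
    metadata: dict = field(default_factory=dict)
    channels: tuple[str, str] = CHANNELS

    @property
    def nuclear(self) -> np.ndarray:
        return self.stack[:, 0]

    @property
    def reporter(self) -> np.ndarray:
        return self.stack[:, 1]

    @property
    def n_frames(self) -> int:
        return self.stack.shape[0]


@dataclass
class GroundTruth:
    """True labels, tracks and per-cell parameters of a rendered movie."""

    labels: np.ndarray  # (T, H, W) int32; cell_id + 1
    tracks: pd.DataFrame  # cell_id, frame, row, col
    cells: list[SimulatedCell]
    overlaps: list[tuple[int, int, int]] = field(default_factory=list)  # frame, id1, id2


# ---------------------------------------------------------------------------
# Rendering


def _place_cells(
    n_cells: int, cfg: ImagingConfig, rng: np.random.Generator
) -> np.ndarray:
    """Initial centroids on a jittered grid; raises if the field is too small."""
    footprint = cfg.nucleus_semi_axes[1] + cfg.cyto_extent
    margin = footprint + 2.0
    pitch = 2 * footprint + 12.0  # slack keeps wandering neighbours apart
    if cfg.height <= 2 * margin or cfg.width <= 2 * margin:
        raise ValueError(
            f"field {cfg.height}x{cfg.width} cannot fit a nucleus with "
            f"footprint radius {footprint:.0f} px"
        )
    rows = np.arange(margin, cfg.height - margin + 1e-9, pitch)
    cols = np.arange(margin, cfg.width - margin + 1e-9, pitch)
    sites = np.array([(r, c) for r in rows for c in cols])
    if len(sites) < n_cells:
        raise ValueError(
            f"field {cfg.height}x{cfg.width} holds at most {len(sites)} cells "
            f"of footprint {footprint:.0f} px; requested {n_cells}"
        )
    chosen = sites[rng.choice(len(sites), size=n_cells, replace=False)]
    jitter = rng.uniform(-2.0, 2.0, size=chosen.shape)
    return chosen + jitter


def _random_walk(
    start: np.ndarray, cfg: ImagingConfig, rng: np.random.Generator
) -> np.ndarray:
    """Tethered random walk, reflected at the field margins.

    Adherent cells wander around their attachment site rather than diffusing
    freely; the mean-reverting pull (``motion_reversion`` per frame) bounds
    the excursion to ~``motion_sd / sqrt(2*reversion)`` pixels while keeping
    genuine ~``motion_sd`` per-frame displacements for the tracker to handle.
    """
    margin = cfg.nucleus_semi_axes[1] + cfg.cyto_extent + 1.0
    lo = np.array([margin, margin])
    hi = np.array([cfg.height - 1 - margin, cfg.width - 1 - margin])
    path = np.empty((cfg.n_frames, 2))
    home = start.astype(float).copy()
    pos = home.copy()
    for f in range(cfg.n_frames):
        if f > 0 and cfg.motion_sd > 0:
            pos = pos - cfg.motion_reversion * (pos - home)
            pos = pos + rng.normal(0.0, cfg.motion_sd, size=2)
            # reflect at the margins
            for k in range(2):
                if pos[k] < lo[k]:
                    pos[k] = 2 * lo[k] - pos[k]
                elif pos[k] > hi[k]:
                    pos[k] = 2 * hi[k] - pos[k]
        path[f] = pos
    return path


def _ellipse_masks(
    center: np.ndarray,
    semi_axes: tuple[float, float],
    orientation: float,
    extent: float,
    shape: tuple[int, int],
) -> tuple[slice, slice, np.ndarray, np.ndarray]:
    """Nucleus and cytoplasm-annulus masks on a local bounding box."""
    a, b = semi_axes
    reach = max(a, b) + extent + 1.5
    r0 = max(int(np.floor(center[0] - reach)), 0)
    r1 = min(int(np.ceil(center[0] + reach)) + 1, shape[0])
    c0 = max(int(np.floor(center[1] - reach)), 0)
    c1 = min(int(np.ceil(center[1] + reach)) + 1, shape[1])
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dr = rr - center[0]
    dc = cc - center[1]
    ct, st = np.cos(orientation), np.sin(orientation)
    u = dr * ct + dc * st
    v = -dr * st + dc * ct
    q_nuc = (u / a) ** 2 + (v / b) ** 2
    q_out = (u / (a + extent)) ** 2 + (v / (b + extent)) ** 2
    nuc = q_nuc <= 1.0
    cyto = (q_out <= 1.0) & ~nuc
    return slice(r0, r1), slice(c0, c1), nuc, cyto


def render_movie(
    cells: list[SimulatedCell],
    cfg: ImagingConfig,
    rng: np.random.Generator | None = None,
) -> tuple[Movie, GroundTruth]:
    """Render a cell population into a noisy two-channel movie.

    Cells without an assigned path/geometry are placed and given motion here
    (deterministically from ``cfg.seed`` unless ``rng`` is supplied).
    """
    if not cells:
        raise ValueError("need at least one cell")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    shape = (cfg.height, cfg.width)
    T = cfg.n_frames

    unplaced = [c for c in cells if c.path is None]
    if unplaced:
        starts = _place_cells(len(unplaced), cfg, rng)
        lo, hi = cfg.nucleus_semi_axes
        for cell, start in zip(unplaced, starts):
            axes = tuple(np.sort(rng.uniform(lo, hi, size=2))[::-1])
            cell.semi_axes = (float(axes[0]), float(axes[1]))
            cell.orientation = float(rng.uniform(0, np.pi))
            cell.path = _random_walk(start, cfg, rng)
    brightness = {
        c.cell_id: cfg.nuclear_brightness * rng.uniform(0.8, 1.2) for c in cells
    }

    clean = np.zeros((T, 2, *shape), dtype=np.float64)
    clean += cfg.background
    labels = np.zeros((T, *shape), dtype=np.int32)
    claim = np.full((T, *shape), np.inf)
    overlaps: list[tuple[int, int, int]] = []
    track_rows = []

    for cell in cells:
        b = cell.params.baseline
        trace = cell.true_trace
        for f in range(T):
            center = cell.path[f]
            rs, cs, nuc, cyto = _ellipse_masks(
                center, cell.semi_axes, cell.orientation, cfg.cyto_extent, shape
            )
            area_n = int(nuc.sum())
            area_c = int(cyto.sum())
            if area_n == 0 or area_c == 0:
                continue
            # reporter redistribution with exact per-frame conservation:
            # n*area_n + c*area_c == c_pre*(b*area_n + area_c)
            n_t = trace[f] * cfg.cyto_pre
            c_t = cfg.cyto_pre * (b * area_n + area_c - trace[f] * area_n) / area_c
            c_t = max(c_t, 0.0)
            clean[f, 0, rs, cs][nuc] += brightness[cell.cell_id]
            rep = clean[f, 1, rs, cs]
            rep[nuc] += n_t
            rep[cyto] += c_t
            clean[f, 1, rs, cs] = rep

            # ground-truth labels; contested pixels go to the nearer centroid
            rr, cc2 = np.nonzero(nuc)
            rr_g, cc_g = rr + rs.start, cc2 + cs.start
            prev = labels[f, rr_g, cc_g]
            clash = np.unique(prev[prev > 0])
            for other in clash:
                overlaps.append((f, int(other - 1), cell.cell_id))
            d = np.hypot(rr_g - center[0], cc_g - center[1])
            closer = d < claim[f, rr_g, cc_g]
            labels[f, rr_g[closer], cc_g[closer]] = cell.cell_id + 1
            claim[f, rr_g[closer], cc_g[closer]] = d[closer]
            track_rows.append(
                {
                    "cell_id": cell.cell_id,
                    "frame": f,
                    "row": float(center[0]),
                    "col": float(center[1]),
                }
            )

    noisy = clean
    if cfg.photon_scale > 0:
        noisy = rng.poisson(noisy * cfg.photon_scale) / cfg.photon_scale
    if cfg.read_noise_sd > 0:
        noisy = noisy + rng.normal(0.0, cfg.read_noise_sd, size=noisy.shape)
    noisy = np.clip(noisy, 0.0, None).astype(np.float32)

    movie = Movie(
        stack=noisy,
        dt=cfg.dt,
        stim_frame=cfg.stim_frame,
        metadata={"seed": cfg.seed, "n_cells": len(cells)},
    )
    truth = GroundTruth(
        labels=labels,
        tracks=pd.DataFrame(track_rows, columns=["cell_id", "frame", "row", "col"]),
        cells=cells,
        overlaps=overlaps,
    )
    return movie, truth


# ---------------------------------------------------------------------------
# I/O


def write_movie(movie: Movie, path: str | Path) -> None:
    """Write a movie as multi-page TIFF (page = frame*2 + channel) + JSON sidecar."""
    path = Path(path)
    T, C, H, W = movie.stack.shape
    tifffile.imwrite(path, movie.stack.reshape(T * C, H, W))
    sidecar = {
        "format": "nfdyn-movie",
        "dimension_order": "page = frame * n_channels + channel",
        "n_frames": T,
        "channels": list(movie.channels),
        "dt_min": movie.dt,
        "stim_frame": movie.stim_frame,
        "metadata": movie.metadata,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_movie(path: str | Path) -> Movie:
    """Read a movie written by :func:`write_movie` (lossless round trip)."""
    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    sidecar_path = path.with_suffix(".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        channels = sidecar.get("channels", list(CHANNELS))
        if len(channels) != 2:
            raise FormatError(
                f"{path}: two channels required, sidecar declares {len(channels)}"
            )
        T = sidecar["n_frames"]
        if pages.shape[0] != 2 * T:
            raise FormatError(
                f"{path}: expected {2 * T} pages for {T} two-channel frames, "
                f"found {pages.shape[0]}"
            )
        dt = sidecar["dt_min"]
        stim = sidecar["stim_frame"]
        metadata = sidecar.get("metadata", {})
    else:
        if pages.shape[0] % 2 != 0:
            raise FormatError(
                f"{path}: two channels required but file has {pages.shape[0]} "
                "pages (odd page count)"
            )
        channels, dt, stim, metadata = list(CHANNELS), 5.0, 3, {}
    T = pages.shape[0] // 2
    stack = pages.reshape(T, 2, *pages.shape[1:])
    return Movie(
        stack=stack, dt=dt, stim_frame=stim, metadata=metadata, channels=tuple(channels)
    )


def write_ground_truth(truth: GroundTruth, stem: str | Path) -> None:
    """Persist ground truth: label TIFF, tracks CSV, per-cell parameter JSON."""
    stem = Path(stem)
    tifffile.imwrite(stem.with_suffix(".labels.tif"), truth.labels.astype(np.uint16))
    truth.tracks.to_csv(stem.with_suffix(".tracks.csv"), index=False)
    cells = []
    for cell in truth.cells:
        rec = {
            "cell_id": cell.cell_id,
            "responder_class": cell.responder_class.value,
            "params": {
                k: (v.value if hasattr(v, "value") else v)
                for k, v in asdict(cell.params).items()
            },
            "semi_axes": cell.semi_axes,
            "orientation": cell.orientation,
            "true_trace": cell.true_trace.tolist(),
        }
        cells.append(rec)
    stem.with_suffix(".cells.json").write_text(
        json.dumps({"cells": cells, "overlaps": truth.overlaps})
    )


# ---------------------------------------------------------------------------
# Condition-level composition


def simulate_condition(
    preset: PreparationPreset,
    conc: float,
    stnfr: bool,
    n_cells: int,
    cfg: ImagingConfig,
    seed: int | None = None,
) -> tuple[Movie, GroundTruth]:
    """Sample a population and render it; fully deterministic per seed."""
    if seed is None:
        seed = cfg.seed
    ss = np.random.SeedSequence([int(seed)])
    rng_cells, rng_render = [np.random.default_rng(s) for s in ss.spawn(2)]
    cells = sample_population(
        preset, conc, stnfr, n_cells, rng_cells, time_grid=cfg.time_grid
    )
    movie, truth = render_movie(cells, cfg, rng=rng_render)
    movie.metadata.update(
        preset=preset.name, concentration=conc, stnfr=bool(stnfr), seed=int(seed)
    )
    return movie, truth
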