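"""Nuclear segmentation, cytoplasmic measurement rings, and cell tracking.

Segmentation works on the constitutive nuclear-marker channel: Gaussian
smoothing, global Otsu threshold (with a fixed-value override), hole filling,
a distance-transform watershed to split touching nuclei, and an area filter.
Regions use 8-connectivity.  The cytoplasmic measurement region is an annulus
around each nucleus; contested pixels go to the nucleus with the nearer
centroid.  Tracking links nuclei frame to frame by mutual nearest centroids,
with a displacement gate and gap closing; ties break on the smaller label id
so results are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial.distance import cdist
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops_table
from skimage.segmentation import relabel_sequential, watershed

__all__ = [
    "SegmentationConfig",
    "LabelStack",
    "Track",
    "segment_nuclei",
    "segment_stack",
    "cytoplasm_ring",
    "link_tracks",
    "tracks_to_df",
]


@dataclass(frozen=True)
class SegmentationConfig:
    smooth_sigma: float = 1.5
    threshold: float | None = None  # None = Otsu
    min_area: int = 40
    max_area: int = 2000
    min_peak_distance: int = 7  # watershed seed separation, pixels
    ring_inner: float = 2.0  # cytoplasm annulus, pixels beyond the nucleus
    ring_outer: float = 8.0
    max_displacement: float = 10.0  # tracking gate, pixels/frame
    max_gap: int = 2  # frames a track survives unmatched


@dataclass
class LabelStack:
    """Per-frame integer label images plus a region table."""

    labels: np.ndarray  # (T, H, W) int32, 0 = background
    regions: pd.DataFrame  # columns: frame, label, row, col, area

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]


@dataclass
class Track:
    """One cell's trajectory: (frame, label, row, col) for detected frames."""

    track_id: int
    rows: list[tuple[int, int, float, float]] = field(default_factory=list)

    @property
    def start_frame(self) -> int:
        return self.rows[0][0]

    @property
    def end_frame(self) -> int:
        return self.rows[-1][0]

    @property
    def n_detections(self) -> int:
        return len(self.rows)

    def label_at(self, frame: int) -> int | None:
        for f, lab, _, _ in self.rows:
            if f == frame:
                return lab
        return None


def segment_nuclei(
    frame: np.ndarray, cfg: SegmentationConfig = SegmentationConfig()
) -> tuple[np.ndarray, pd.DataFrame]:
    """Segment nuclei in one nuclear-marker image.

    Returns the label image (0 = background) and a region table with columns
    label, row, col, area.  A blank image yields zero labels.
    """
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {img.shape}")
    if np.any(img < 0):
        raise ValueError("image intensities must be nonnegative")

    smooth = gaussian(img, sigma=cfg.smooth_sigma, preserve_range=True)
    if cfg.threshold is not None:
        thr = cfg.threshold
    else:
        if smooth.max() == smooth.min():
            return np.zeros(img.shape, dtype=np.int32), _empty_regions()
        thr = threshold_otsu(smooth)
    mask = smooth > thr
    mask = ndi.binary_fill_holes(mask)
    if not mask.any():
        return np.zeros(img.shape, dtype=np.int32), _empty_regions()

    dist = ndi.distance_transform_edt(mask)
    coords = peak_local_max(
        dist, min_distance=cfg.min_peak_distance, labels=mask, exclude_border=False
    )
    markers = np.zeros(img.shape, dtype=np.int32)
    for i, (r, c) in enumerate(coords, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        markers = cc_label(mask, connectivity=2)
    labels = watershed(-dist, markers, mask=mask, connectivity=2)

    # area filter, then compact label ids
    areas = np.bincount(labels.ravel())
    bad = np.flatnonzero((areas < cfg.min_area) | (areas > cfg.max_area))
    labels[np.isin(labels, bad[bad > 0])] = 0
    labels, _, _ = relabel_sequential(labels)
    labels = labels.astype(np.int32)
    return labels, _region_table(labels)


def _empty_regions() -> pd.DataFrame:
    return pd.DataFrame(columns=["label", "row", "col", "area"])


def _region_table(labels: np.ndarray) -> pd.DataFrame:
    if labels.max() == 0:
        return _empty_regions()
    props = regionprops_table(labels, properties=("label", "centroid", "area"))
    df = pd.DataFrame(props).rename(
        columns={"centroid-0": "row", "centroid-1": "col"}
    )
    return df[["label", "row", "col", "area"]].sort_values("label").reset_index(drop=True)


def segment_stack(
    nuclear_stack: np.ndarray, cfg: SegmentationConfig = SegmentationConfig()
) -> LabelStack:
    """Segment every frame of a nuclear-marker stack."""
    labels = np.zeros(nuclear_stack.shape, dtype=np.int32)
    tables = []
    for f in range(nuclear_stack.shape[0]):
        lab, table = segment_nuclei(nuclear_stack[f], cfg)
        labels[f] = lab
        table.insert(0, "frame", f)
        tables.append(table)
    regions = pd.concat(tables, ignore_index=True) if tables else _empty_regions()
    return LabelStack(labels=labels, regions=regions)


def cytoplasm_ring(labels: np.ndarray, r_in: float, r_out: float) -> np.ndarray:
    """Cytoplasmic measurement ring for every nucleus in a label image.

    A pixel belongs to nucleus *i*'s ring if its distance to nucleus *i* lies
    in (r_in, r_out] and it is not a nuclear pixel of any cell; a pixel within
    reach of several nuclei goes to the one with the nearest centroid.
    Returns a label image carrying the same ids as ``labels``.
    """
    if not r_out > r_in or r_in < 0:
        raise ValueError(f"need r_out > r_in >= 0, got r_in={r_in}, r_out={r_out}")
    labels = np.asarray(labels)
    rings = np.zeros(labels.shape, dtype=np.int32)
    if labels.max() == 0:
        return rings
    any_nucleus = labels > 0
    pad = int(np.ceil(r_out)) + 1
    table = _region_table(labels)
    centroids = {int(r.label): (r.row, r.col) for r in table.itertuples()}

    # distance from each candidate pixel to each nearby nucleus, via per-label
    # EDT on a padded bounding box
    claim_dist = np.full(labels.shape, np.inf)
    objects = ndi.find_objects(labels)
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        rsl = slice(max(sl[0].start - pad, 0), min(sl[0].stop + pad, labels.shape[0]))
        csl = slice(max(sl[1].start - pad, 0), min(sl[1].stop + pad, labels.shape[1]))
        crop = labels[rsl, csl] == lab
        dist = ndi.distance_transform_edt(~crop)
        band = (dist > r_in) & (dist <= r_out) & ~any_nucleus[rsl, csl]
        if not band.any():
            continue
        rr, cc = np.nonzero(band)
        rr_g, cc_g = rr + rsl.start, cc + csl.start
        cy, cx = centroids[lab]
        d_cent = np.hypot(rr_g - cy, cc_g - cx)
        closer = d_cent < claim_dist[rr_g, cc_g]
        rings[rr_g[closer], cc_g[closer]] = lab
        claim_dist[rr_g[closer], cc_g[closer]] = d_cent[closer]
    return rings


def ring_stack(label_stack: LabelStack, r_in: float, r_out: float) -> np.ndarray:
    """Cytoplasm rings for every frame of a label stack."""
    return np.stack(
        [cytoplasm_ring(label_stack.labels[f], r_in, r_out) for f in range(label_stack.n_frames)]
    )


def link_tracks(
    stack: LabelStack, max_disp: float = 10.0, max_gap: int = 2
) -> list[Track]:
    """Link per-frame nuclei into tracks by mutual nearest centroids.

    At each frame, open tracks and detections are matched where each is the
    other's nearest neighbour within ``max_disp`` pixels (of the track's last
    known centroid); ties break on the smaller detection label, then the
    smaller track id.  Unmatched tracks survive ``max_gap`` frames before
    closing; unmatched detections start new tracks.
    """
    if stack.n_frames < 1:
        raise ValueError("label stack must contain at least one frame")
    tracks: list[Track] = []
    open_tracks: list[Track] = []
    next_id = 0
    regions = stack.regions

    for frame in range(stack.n_frames):
        dets = regions[regions["frame"] == frame].sort_values("label")
        det_labels = dets["label"].to_numpy(dtype=int)
        det_pos = dets[["row", "col"]].to_numpy(dtype=float)

        matched_tracks: set[int] = set()
        matched_dets: set[int] = set()
        if open_tracks and len(det_labels):
            track_pos = np.array([[t.rows[-1][2], t.rows[-1][3]] for t in open_tracks])
            dist = cdist(track_pos, det_pos)
            # iterate mutual-nearest pairs until exhausted
            while True:
                best = None
                for ti in range(len(open_tracks)):
                    if ti in matched_tracks:
                        continue
                    row = dist[ti].copy()
                    row[list(matched_dets)] = np.inf
                    if not np.isfinite(row).any():
                        continue
                    di = int(np.argmin(row))
                    if row[di] > max_disp:
                        continue
                    col = dist[:, di].copy()
                    col[list(matched_tracks)] = np.inf
                    if int(np.argmin(col)) != ti:
                        continue
                    key = (row[di], det_labels[di], open_tracks[ti].track_id)
                    if best is None or key < best[0]:
                        best = (key, ti, di)
                if best is None:
                    break
                _, ti, di = best
                open_tracks[ti].rows.append(
                    (frame, int(det_labels[di]), float(det_pos[di, 0]), float(det_pos[di, 1]))
                )
                matched_tracks.add(ti)
                matched_dets.add(di)

        # close tracks that have been unmatched for longer than max_gap
        still_open = []
        for ti, t in enumerate(open_tracks):
            if ti in matched_tracks or frame - t.end_frame <= max_gap:
                still_open.append(t)
            else:
                tracks.append(t)
        open_tracks = still_open

        for di in range(len(det_labels)):
            if di not in matched_dets:
                t = Track(track_id=next_id)
                t.rows.append(
                    (frame, int(det_labels[di]), float(det_pos[di, 0]), float(det_pos[di, 1]))
                )
                open_tracks.append(t)
                next_id += 1

    tracks.extend(open_tracks)
    tracks.sort(key=lambda t: t.track_id)
    return tracks


def tracks_to_df(tracks: list[Track]) -> pd.DataFrame:
    rows = [
        {"track_id": t.track_id, "frame": f, "label": lab, "row": r, "col": c}
        for t in tracks
        for f, lab, r, c in t.rows
    ]
    return pd.DataFrame(rows, columns=["track_id", "frame", "label", "row", "col"])
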