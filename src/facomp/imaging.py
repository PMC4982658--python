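"""Image-analysis chain for multiplexed adhesion imaging.

Registration (subpixel phase correlation), high-pass background
subtraction, watershed segmentation of the adhesion marker channel,
per-region measurement, backward tracking through the pre-fixation
time-lapse, and age / dynamics classification.

Adhesions are segmented on the (constitutively imaged) marker channel;
component densities are then measured inside those masks in the registered
channel images.  Tracking walks backward from the final (fixation) frame:
a region is matched to the previous frame by maximum area overlap, or by
the nearest centroid within 10 px when no overlap exists; regions absent
at fixation are dropped.  Ages follow from the first appearance frame at
the 3-minute frame interval (``3'``–``12'``, or ``>12'`` when present in
every frame), and ``>12'``-old adhesions are classified AS / ST / DS by the
Pearson correlation between total marker intensity and time (thresholds
±0.7).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage, stats
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import h_maxima
from skimage.registration import phase_cross_correlation
from skimage.segmentation import watershed

from .tables import AdhesionRecord, DensityTable, from_records

logger = logging.getLogger(__name__)

#: Frame interval of the pre-fixation time-lapse, minutes.
FRAME_INTERVAL_MIN = 3.0
#: Maximum centroid distance (px) for overlap-free track matching.
TRACK_MATCH_RADIUS_PX = 10.0
#: Pearson-r thresholds separating disassembling / stationary / assembling.
DYNAMICS_R_THRESHOLD = 0.7

#: Appearance k frames before the final (fixation) frame -> age category;
#: appearing at the final frame itself means "within the last interval".
AGE_BY_FRAMES_BEFORE_FINAL = {0: "3'", 1: "6'", 2: "9'", 3: "12'"}


class DegenerateInputError(ValueError):
    """Raised for inputs on which the operation is undefined (flat images)."""


# ---------------------------------------------------------------------------
# registration and background subtraction
# ---------------------------------------------------------------------------

def register_translation(reference, moving, upsample: int = 100) -> tuple[float, float]:
    """Subpixel (dy, dx) shift of ``moving`` relative to ``reference``.

    Single-step upsampled cross-correlation in the Fourier domain; accuracy
    is 1/``upsample`` px.  Applying the returned shift to ``moving``
    (e.g. ``scipy.ndimage.shift(moving, shift)``) aligns it to the reference.
    """
    reference = np.asarray(reference, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if reference.shape != moving.shape:
        raise ValueError("images must share a shape")
    if upsample < 1:
        raise ValueError("upsample must be >= 1")
    if reference.std() == 0 or moving.std() == 0:
        raise DegenerateInputError("flat image: translation undefined")
    shift, _, _ = phase_cross_correlation(
        reference, moving, upsample_factor=upsample, normalization=None
    )
    return float(shift[0]), float(shift[1])


def highpass_subtract(image, width: float):
    """Remove large-scale background: ``image − gaussian(image, width)``,
    clipped at zero.  ``width`` (px) sets the scale above which structure is
    treated as background; features much smaller than it are preserved."""
    if width <= 0:
        raise ValueError("width must be > 0")
    img = np.asarray(image, dtype=float)
    return np.clip(img - ndimage.gaussian_filter(img, sigma=width), 0.0, None)


def subtract_background(image, width: float, foreground_mask=None):
    """High-pass background subtraction, optionally foreground-aware.

    Without a mask this is :func:`highpass_subtract`.  With a mask the
    background is estimated by normalized convolution over the background
    pixels only (``gaussian(img·bg)/gaussian(bg)``), which removes the
    upward bias that bright objects leak into a plain smoothed-background
    estimate — relevant once a segmentation is available.
    """
    if foreground_mask is None:
        return highpass_subtract(image, width)
    if width <= 0:
        raise ValueError("width must be > 0")
    img = np.asarray(image, dtype=float)
    weight = (~np.asarray(foreground_mask, dtype=bool)).astype(float)
    denom = ndimage.gaussian_filter(weight, sigma=width)
    background = ndimage.gaussian_filter(img * weight, sigma=width) / np.maximum(denom, 1e-12)
    return np.clip(img - background, 0.0, None)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentationParams:
    """Watershed parameters (the named algorithm leaves these free).

    ``smooth_sigma``
        Gaussian smoothing (px) before peak finding and watershed.
    ``seed_quantile``
        Seeds must exceed this quantile of the positive pixels; ``None``
        switches to Otsu's threshold of the smoothed image (stricter, for
        high-background data).
    ``mask_quantile``
        Flood mask: pixels above this quantile of the positive pixels.
    ``min_distance``
        Minimum seed separation (px).
    ``min_area``
        Regions below this pixel count are removed.
    ``peak_merge_ratio``
        Two intensity maxima found separate seeds only if the valley between
        them falls below this fraction of the lower peak; shallower ripple
        along one adhesion is merged into a single seed.
    ``region_half_max``
        After flooding, each region is trimmed to the pixels above this
        fraction of its own peak intensity (a full-width-at-half-maximum
        style boundary), which keeps dim and bright adhesions on equal
        footing; ``0`` disables trimming.
    """

    smooth_sigma: float = 1.5
    seed_quantile: float | None = 0.5
    mask_quantile: float = 0.1
    min_distance: int = 5
    min_area: int = 5
    region_half_max: float = 0.5
    peak_merge_ratio: float = 0.8


@dataclass
class LabelMap:
    """Integer labels per pixel (0 = background) with the pixel size."""

    labels: np.ndarray
    pixel_size: float = 1.0  # micrometer per px

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label map must be 2-D")

    @property
    def n_regions(self) -> int:
        return int(self.labels.max())

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


def segment_adhesions(
    marker_image, params: SegmentationParams = SegmentationParams(), pixel_size: float = 1.0
) -> LabelMap:
    """Watershed segmentation of a background-subtracted marker image.

    The smoothed image is inverted and flooded from seeds placed at local
    maxima above an intensity threshold; the flood is confined to a
    foreground mask, and regions below ``min_area`` pixels are dropped.
    An image with no seeds yields an empty LabelMap (not an error).
    """
    img = np.asarray(marker_image, dtype=float)
    smoothed = (
        gaussian(img, sigma=params.smooth_sigma, preserve_range=True)
        if params.smooth_sigma > 0
        else img.astype(float)
    )
    positive = smoothed[smoothed > 0]
    if positive.size == 0:
        return LabelMap(np.zeros(img.shape, dtype=np.int32), pixel_size)
    seed_thr = (
        threshold_otsu(smoothed) if params.seed_quantile is None
        else np.quantile(positive, params.seed_quantile)
    )
    mask_thr = np.quantile(positive, params.mask_quantile)
    # seeds: regional maxima with a *relative* prominence — two maxima are
    # separate seeds only if the valley between them dips below
    # ``peak_merge_ratio`` of the lower peak.  Computed as h-maxima on the
    # log image, this merges the shallow intensity ripple along a single
    # elongated adhesion while still splitting touching adhesions with
    # genuinely distinct peaks, at any brightness.
    floor = max(seed_thr * 1e-3, np.finfo(float).tiny)
    log_img = np.log(np.maximum(smoothed, floor))
    persistent = h_maxima(log_img, -np.log(params.peak_merge_ratio))
    is_peak = persistent.astype(bool) & (smoothed >= seed_thr)
    markers, n_seeds = ndimage.label(is_peak, structure=np.ones((3, 3), dtype=bool))
    if n_seeds == 0:
        return LabelMap(np.zeros(img.shape, dtype=np.int32), pixel_size)
    mask = smoothed >= mask_thr
    labels = watershed(-smoothed, markers=markers, mask=mask)
    if params.region_half_max > 0 and labels.max() > 0:
        # trim each region to its half-maximum contour so that dim and
        # bright adhesions are delimited consistently
        peak_vals = ndimage.maximum(smoothed, labels, np.arange(labels.max() + 1))
        labels = np.where(smoothed >= params.region_half_max * peak_vals[labels], labels, 0)
    # drop small regions, then renumber contiguously (watershed regions are
    # connected by construction, so no reconnection pass is needed)
    counts = np.bincount(labels.ravel())
    small = np.flatnonzero(counts < params.min_area)
    labels[np.isin(labels, small[small > 0])] = 0
    survivors = np.unique(labels[labels > 0])
    remap = np.zeros(labels.max() + 1, dtype=np.int32)
    remap[survivors] = np.arange(1, len(survivors) + 1, dtype=np.int32)
    return LabelMap(remap[labels], pixel_size)


# ---------------------------------------------------------------------------
# measurement
# ---------------------------------------------------------------------------

def measure_regions(
    labels: LabelMap,
    channels: Sequence[np.ndarray] | dict[str, np.ndarray],
    components: Sequence[str] | None = None,
    pixel_size: float | None = None,
    sample_pixels: dict[int, int] | None = None,
    rng: np.random.Generator | None = None,
    dataset_id: str = "R1O1",
) -> DensityTable:
    """Measure geometry and per-channel densities of each labeled region.

    Per region: pixel count, area (pixel count · pixel_size²), ellipse
    eccentricity from second moments (inter-focal distance over major-axis
    length), and per channel the density = mean intensity over the region's
    pixels.  ``sample_pixels`` optionally restricts the density computation
    to a random pixel subset per label (equal-sampling controls); regions
    smaller than the requested sample keep all pixels.
    """
    if isinstance(channels, dict):
        names = list(channels)
        imgs = [np.asarray(channels[n], dtype=float) for n in names]
    else:
        imgs = [np.asarray(c, dtype=float) for c in channels]
        names = list(components) if components is not None else [f"ch{i}" for i in range(len(imgs))]
    if components is not None:
        names = list(components)
    if len(names) != len(imgs):
        raise ValueError("one component name per channel required")
    for img in imgs:
        if img.shape != labels.shape:
            raise ValueError("channel shape does not match label map")
    if sample_pixels is not None and rng is None:
        rng = np.random.default_rng(0)
    px = labels.pixel_size if pixel_size is None else pixel_size

    records: list[AdhesionRecord] = []
    for prop in regionprops(labels.labels):
        coords = prop.coords
        if sample_pixels is not None:
            want = sample_pixels.get(prop.label, len(coords))
            if want < len(coords):
                idx = rng.choice(len(coords), size=want, replace=False)
                coords = coords[idx]
        rows, cols = coords[:, 0], coords[:, 1]
        densities = {n: float(img[rows, cols].mean()) for n, img in zip(names, imgs)}
        records.append(
            AdhesionRecord(
                adhesion_id=int(prop.label),
                pixel_count=int(prop.num_pixels),
                area=float(prop.num_pixels) * px * px,
                eccentricity=float(prop.eccentricity),
                densities=densities,
            )
        )
    return from_records(records, components=names, dataset_id=dataset_id)


# ---------------------------------------------------------------------------
# tracking
# ---------------------------------------------------------------------------

@dataclass
class TrackedTrajectory:
    """One adhesion followed backward from the final (post-fixation) frame."""

    adhesion_id: int
    frames: list[int]
    labels: list[int]
    centroids: list[tuple[float, float]]
    areas: list[int]
    total_intensities: list[float]
    first_frame: int
    age: str = ">12'"
    dynamics: str = "NA"

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.frames, self.frames[1:])):
            raise ValueError("frames must be strictly increasing")


def _region_summaries(label_map: LabelMap, intensity: np.ndarray | None):
    out = {}
    for prop in regionprops(label_map.labels, intensity_image=intensity):
        total = float(prop.image_intensity.sum()) if intensity is not None else float(prop.num_pixels)
        out[prop.label] = (np.array(prop.centroid), int(prop.num_pixels), total, prop.coords)
    return out


def _match_backward(
    current: dict, previous: dict, shift: tuple[float, float], shape: tuple[int, int],
    prev_labels: np.ndarray,
) -> dict[int, int]:
    """Match each current-frame label to a previous-frame label (or None).

    Maximum pixel overlap wins; ties resolve by larger overlap fraction then
    nearer centroid; with no overlap, the nearest previous centroid within
    10 px (after applying the registered shift) is taken.
    """
    matches: dict[int, int] = {}
    dyx = np.asarray(shift, dtype=float)
    for cur_label, (centroid, npix, _total, coords) in current.items():
        # shift current coords into the previous frame's coordinates
        shifted = np.rint(coords + dyx).astype(int)
        ok = (
            (shifted[:, 0] >= 0) & (shifted[:, 0] < shape[0])
            & (shifted[:, 1] >= 0) & (shifted[:, 1] < shape[1])
        )
        hits = prev_labels[shifted[ok, 0], shifted[ok, 1]]
        hits = hits[hits > 0]
        best = None
        if hits.size:
            cand, cnt = np.unique(hits, return_counts=True)
            scored = []
            for c, k in zip(cand, cnt):
                prev_centroid, prev_npix, _, _ = previous[c]
                frac = k / min(npix, prev_npix)
                dist = float(np.linalg.norm(prev_centroid - (centroid + dyx)))
                scored.append((-k, -frac, dist, int(c)))
            scored.sort()
            best = scored[0][3]
        else:
            best_dist = TRACK_MATCH_RADIUS_PX
            for c, (prev_centroid, *_rest) in previous.items():
                dist = float(np.linalg.norm(prev_centroid - (centroid + dyx)))
                if dist <= best_dist:
                    best_dist, best = dist, int(c)
        if best is not None:
            matches[cur_label] = best
    return matches


def track_adhesions(
    label_sequence: Sequence[LabelMap],
    intensity_sequence: Sequence[np.ndarray] | None = None,
    shifts: Sequence[tuple[float, float]] | None = None,
) -> list[TrackedTrajectory]:
    """Track adhesions backward from the final frame of a time-lapse.

    Only regions present at the final (post-fixation) frame yield
    trajectories; earlier regions with no surviving descendant are excluded.
    ``shifts[t]`` is the (dy, dx) of frame ``t`` relative to the final
    frame's coordinates (defaults to zero).  Deterministic: identical inputs
    produce identical trajectories.
    """
    T = len(label_sequence)
    if T < 2:
        raise ValueError("tracking needs at least 2 frames")
    if intensity_sequence is not None and len(intensity_sequence) != T:
        raise ValueError("one intensity image per frame required")
    if shifts is None:
        shifts = [(0.0, 0.0)] * T
    summaries = [
        _region_summaries(lm, intensity_sequence[t] if intensity_sequence is not None else None)
        for t, lm in enumerate(label_sequence)
    ]
    trajectories: list[TrackedTrajectory] = []
    for final_label in sorted(summaries[-1]):
        frames = [T - 1]
        labels = [final_label]
        cur = final_label
        for t in range(T - 1, 0, -1):
            rel_shift = (
                shifts[t - 1][0] - shifts[t][0],
                shifts[t - 1][1] - shifts[t][1],
            )
            match = _match_backward(
                {cur: summaries[t][cur]}, summaries[t - 1], rel_shift,
                label_sequence[t - 1].shape, label_sequence[t - 1].labels,
            ).get(cur)
            if match is None:
                break
            frames.append(t - 1)
            labels.append(match)
            cur = match
        frames.reverse()
        labels.reverse()
        traj = TrackedTrajectory(
            adhesion_id=final_label,
            frames=frames,
            labels=labels,
            centroids=[tuple(summaries[t][l][0]) for t, l in zip(frames, labels)],
            areas=[summaries[t][l][1] for t, l in zip(frames, labels)],
            total_intensities=[summaries[t][l][2] for t, l in zip(frames, labels)],
            first_frame=frames[0],
        )
        traj.age, traj.dynamics = classify_dynamics(traj, n_frames=T)
        trajectories.append(traj)
    return trajectories


def age_category(first_frame: int, n_frames: int) -> str:
    """Age label from the first-appearance frame at 3-minute spacing.

    Appearing ``k`` frames before the final frame maps to ``3(k+1)``
    minutes; adhesions present in every frame (or appearing five or more
    frames before fixation) are ``>12'``."""
    if first_frame == 0:
        return ">12'"
    k = (n_frames - 1) - first_frame
    return AGE_BY_FRAMES_BEFORE_FINAL.get(k, ">12'")


def classify_dynamics(
    trajectory: TrackedTrajectory, n_frames: int | None = None
) -> tuple[str, str]:
    """Age category and (for ``>12'`` adhesions) the AS/ST/DS class.

    Dynamics follow the Pearson correlation between total marker intensity
    and time over the last four pre-fixation frames: r > 0.7 assembling
    (AS), r < −0.7 disassembling (DS), otherwise stationary (ST); a
    constant trace (undefined r) is ST.  Younger adhesions get ``NA``.
    """
    if n_frames is None:
        n_frames = trajectory.frames[-1] + 1
    age = age_category(trajectory.first_frame, n_frames)
    if age != ">12'":
        return age, "NA"
    # last four pre-fixation frames
    window = [
        (f, v) for f, v in zip(trajectory.frames, trajectory.total_intensities)
        if n_frames - 5 <= f <= n_frames - 2
    ]
    if len(window) < 2:
        return age, "ST"
    t = np.array([w[0] for w in window], dtype=float)
    v = np.array([w[1] for w in window], dtype=float)
    if v.std() == 0 or t.std() == 0:
        return age, "ST"
    r = float(stats.pearsonr(t, v).statistic)
    if r > DYNAMICS_R_THRESHOLD:
        return age, "AS"
    if r < -DYNAMICS_R_THRESHOLD:
        return age, "DS"
    return age, "ST"


# ---------------------------------------------------------------------------
# end-to-end stack analysis
# ---------------------------------------------------------------------------

def analyze_stack(
    marker_frames: np.ndarray,
    channel_stack: np.ndarray,
    components: Sequence[str],
    channel_cycles: Sequence[int] | None = None,
    params: SegmentationParams = SegmentationParams(),
    highpass_width: float = 50.0,
    pixel_size: float = 1.0,
    upsample: int = 100,
    dataset_id: str = "R1O1",
) -> tuple[DensityTable, list[TrackedTrajectory], LabelMap]:
    """Run the full imaging chain on one field of view.

    Registration of each labeling cycle to the final marker frame, high-pass
    background subtraction, watershed segmentation of the marker, density
    measurement of every channel inside the marker masks, backward tracking
    through the pre-fixation frames, and age / dynamics annotation.

    Parameters
    ----------
    marker_frames
        ``(T, H, W)`` marker time-lapse; the last frame is the fixation
        frame on which segmentation is performed.
    channel_stack
        ``(C, H, W)`` post-fixation multiplexed channels.
    channel_cycles
        Labeling-cycle index per channel; channels of one cycle share a
        registration shift.  Defaults to one cycle for all channels.
    """
    marker_frames = np.asarray(marker_frames, dtype=float)
    channel_stack = np.asarray(channel_stack, dtype=float)
    if channel_cycles is None:
        channel_cycles = [0] * len(channel_stack)
    reference = highpass_subtract(marker_frames[-1], highpass_width)
    labels = segment_adhesions(reference, params=params, pixel_size=pixel_size)
    # once adhesions are delimited, background estimates can ignore them
    foreground = ndimage.binary_dilation(labels.labels > 0, iterations=2)

    # register each cycle to the fixation marker frame and align its channels
    aligned = []
    cycle_shift: dict[int, tuple[float, float]] = {}
    for ch, cyc in zip(channel_stack, channel_cycles):
        if cyc not in cycle_shift:
            try:
                cycle_shift[cyc] = register_translation(
                    marker_frames[-1], ch, upsample=upsample
                )
            except DegenerateInputError:
                cycle_shift[cyc] = (0.0, 0.0)
        dy, dx = cycle_shift[cyc]
        moved = ndimage.shift(ch, (dy, dx), order=1, mode="nearest") if (dy, dx) != (0.0, 0.0) else ch
        aligned.append(subtract_background(moved, highpass_width, foreground_mask=foreground))
    table = measure_regions(
        labels, aligned, components=components, pixel_size=pixel_size, dataset_id=dataset_id
    )

    # segment the pre-fixation frames and track backward
    frame_maps = [
        segment_adhesions(highpass_subtract(f, highpass_width), params=params, pixel_size=pixel_size)
        for f in marker_frames[:-1]
    ] + [labels]
    trajectories = track_adhesions(frame_maps, intensity_sequence=list(marker_frames))
    ages = {t.adhesion_id: (t.age, t.dynamics) for t in trajectories}
    table.data["age"] = [ages.get(int(l), (">12'", "NA"))[0] for l in table.data["adhesion_id"]]
    table.data["dynamics"] = [ages.get(int(l), (">12'", "NA"))[1] for l in table.data["adhesion_id"]]
    return table, trajectories, labels


# ---------------------------------------------------------------------------
# label-map persistence
# ---------------------------------------------------------------------------

def write_label_map(label_map: LabelMap, path) -> None:
    """Write a LabelMap as 16-bit TIFF (labels above 65535 are rejected)."""
    import tifffile

    if label_map.labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("too many regions for a 16-bit label TIFF")
    tifffile.imwrite(path, label_map.labels.astype(np.uint16))


def read_label_map(path, pixel_size: float = 1.0) -> LabelMap:
    import tifffile

    return LabelMap(tifffile.imread(path).astype(np.int32), pixel_size)
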