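"""Bouton-dendron contact detection and synapse classification in 3D stacks.

Expansion microscopy (ExM) swells tissue ~4x so that a conventional confocal
can resolve synaptic appositions.  A presynaptic bouton (synaptophysin, often
kisspeptin co-labelled) apposed to the GFP cytoplasm of a GnRH neuron process
is scored by the length over which the two channels' normalized intensity
profiles overlap: a side-on apposition is a synapse when the overlap exceeds
0.95 um (post-expansion), a face-view (z-stack) apposition when it exceeds
1.75 um.  Anything closer than a configurable contact distance but below the
overlap criterion is a close non-synaptic contact; the rest are separate.

In plain confocal mode (``modality="confocal"``) synapses cannot be resolved;
the operational criterion is instead the absence of dark voxels between the
labelled elements ("close apposition").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from . import defaults

__all__ = [
    "ImageScene",
    "Bouton",
    "DendronSegment",
    "MorphThresholds",
    "IntensityProfile",
    "Apposition",
    "ContactStats",
    "segment_dendrons",
    "detect_boutons",
    "pair_appositions",
    "extract_profile",
    "overlap_length",
    "classify_apposition",
    "contact_census",
    "classify_contacts",
]

CHANNEL_ROLES = ("gfp", "kisspeptin", "synaptophysin")


@dataclass
class ImageScene:
    """Multichannel 3D volume (z, y, x) with voxel and expansion metadata.

    Voxel sizes are in the post-expansion (imaged) frame.  ``expansion_factor``
    converts post-expansion lengths back to pre-expansion tissue lengths;
    confocal scenes use a factor of 1.
    """

    channels: dict[str, np.ndarray]
    voxel_xy: float
    voxel_z: float
    expansion_factor: float = 1.0
    modality: str = "ExM"

    def __post_init__(self) -> None:
        shapes = {np.asarray(v).shape for v in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        if self.voxel_xy <= 0 or self.voxel_z <= 0:
            raise ValueError("voxel sizes must be positive")
        if self.expansion_factor < 1:
            raise ValueError("expansion_factor must be >= 1")
        if self.modality not in ("ExM", "confocal"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.modality == "confocal" and self.expansion_factor != 1:
            raise ValueError("confocal scenes must have expansion_factor == 1")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    def voxel_sampling(self) -> tuple[float, float, float]:
        return (self.voxel_z, self.voxel_xy, self.voxel_xy)


@dataclass
class Bouton:
    bouton_id: int
    centroid: np.ndarray            # (z, y, x) um
    equivalent_diameter: float      # um
    has_kisspeptin: bool
    has_synaptophysin: bool
    peak_intensity: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.equivalent_diameter <= 0:
            raise ValueError("equivalent_diameter must be positive")


@dataclass
class DendronSegment:
    dendron_id: int
    skeleton: np.ndarray            # ordered (n, 3) points, (z, y, x) um
    mean_radius: float              # um
    length_post: float              # um, post-expansion
    length_pre: float               # um, pre-expansion

    def __post_init__(self) -> None:
        if self.length_post < 0 or self.length_pre < 0:
            raise ValueError("lengths must be non-negative")


@dataclass
class MorphThresholds:
    """All morphological decision constants, post-expansion micrometres."""

    theta_side: float = defaults.THETA_SIDE_UM
    theta_face: float = defaults.THETA_FACE_UM
    min_bouton_diameter: float = defaults.MIN_BOUTON_DIAMETER_UM
    profile_level: float = defaults.PROFILE_LEVEL
    face_box: float = defaults.FACE_BOX_UM
    close_gap: float = defaults.CLOSE_CONTACT_GAP_UM
    cone_half_angle_deg: float = defaults.ORIENTATION_CONE_DEG
    confocal_max_gap: int = defaults.CONFOCAL_MAX_GAP_VOXELS
    min_length_pre: float = 15.0
    intensity_threshold: str | float = "otsu"

    def __post_init__(self) -> None:
        if not (0 < self.profile_level < 1):
            raise ValueError("profile_level must lie in (0, 1)")
        for name in ("theta_side", "theta_face", "min_bouton_diameter",
                     "face_box", "close_gap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class IntensityProfile:
    positions: np.ndarray                   # um along the scan, increasing
    values: dict[str, np.ndarray]           # per channel, normalized to in-scan peak
    truncated: bool = False

    def __post_init__(self) -> None:
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")


@dataclass
class Apposition:
    bouton_id: int
    dendron_id: int
    orientation: str                # "side" | "face"
    gap: float                      # um, >= 0 (0 when touching/overlapping)
    overlap: float = 0.0            # um
    label: str = "separate"         # "synapse" | "close_nonsynaptic" | "separate"
    has_kisspeptin: bool = True
    has_synaptophysin: bool = True
    confocal_close: bool | None = None
    # geometry carried for profile extraction
    bouton_centroid: np.ndarray | None = None
    bouton_diameter: float | None = None
    anchor: np.ndarray | None = None        # nearest dendron-axis point (z,y,x) um
    direction: np.ndarray | None = None     # unit vector axis->bouton (z,y,x)


@dataclass
class ContactStats:
    n_appositions: int
    n_synapses: int
    total_dendron_length_pre: float             # um
    appositions_per_100um: float                # per 100 um pre-expansion
    synapses_per_10um: float                    # per 10 um pre-expansion
    pct_synapses_with_kisspeptin: float
    pct_appositions_cochannel: float
    dendrons_per_fiber: float
    mean_bouton_dendron_distance: float         # um, non-synaptic contacts


# ---------------------------------------------------------------------------
# segmentation helpers


def _channel_threshold(channel: np.ndarray, spec: str | float) -> float:
    if isinstance(spec, (int, float)):
        return float(spec)
    if spec == "otsu":
        return float(threshold_otsu(channel))
    raise ValueError(f"unknown threshold spec {spec!r}")


def _gfp_labels(scene: ImageScene, thresholds: MorphThresholds) -> np.ndarray:
    gfp = np.asarray(scene.channels["gfp"], dtype=float)
    if gfp.max() <= 0:
        return np.zeros(gfp.shape, dtype=int)
    # light smoothing before thresholding keeps the mask surface clean so the
    # skeleton does not zigzag (which would inflate geodesic lengths)
    gfp = ndimage.gaussian_filter(gfp, sigma=(0.5, 1.0, 1.0))
    thr = _channel_threshold(gfp, thresholds.intensity_threshold)
    mask = gfp > thr
    if not mask.any():
        return np.zeros(gfp.shape, dtype=int)
    return cc_label(mask, connectivity=3)


def _centerline(coords_um: np.ndarray, bin_um: float = 1.0) -> tuple[np.ndarray, float]:
    """Ordered centreline of a tube-like voxel cloud and its arc length.

    Voxel coordinates (um) are projected onto the component's first principal
    axis, binned along it, and replaced by per-bin centroids; the ordered
    centroid polyline is lightly smoothed and its arc length extended to the
    projected extremes.  Robust for straight or gently curved processes, which
    is the geometry this analysis targets.
    """
    c0 = coords_um.mean(axis=0)
    x = coords_um - c0
    _, vecs = np.linalg.eigh(x.T @ x)
    u = vecs[:, -1]
    t = x @ u
    t0, t1 = float(t.min()), float(t.max())
    if t1 - t0 < bin_um:
        return coords_um.mean(axis=0, keepdims=True), 0.0
    edges = np.arange(t0, t1 + bin_um, bin_um)
    which = np.clip(np.digitize(t, edges) - 1, 0, len(edges) - 2)
    pts, centers = [], []
    for b in range(len(edges) - 1):
        sel = which == b
        if sel.any():
            pts.append(coords_um[sel].mean(axis=0))
            centers.append(t[sel].mean())
    pts = np.asarray(pts)
    if len(pts) > 4:
        pts = np.column_stack(
            [ndimage.uniform_filter1d(pts[:, k], 3, mode="nearest") for k in range(3)]
        )
    length = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
    length += (centers[0] - t0) + (t1 - centers[-1])  # reach the projected tips
    return pts, length


def segment_dendrons(
    scene: ImageScene,
    thresholds: MorphThresholds | None = None,
    labels: np.ndarray | None = None,
) -> list[DendronSegment]:
    """Threshold the GFP channel and reduce each component to its centreline.

    Segment length is the arc length of the binned-centroid centreline (see
    :func:`_centerline`).  Segments whose pre-expansion length falls below
    ``min_length_pre`` are discarded.
    """
    thresholds = thresholds or MorphThresholds()
    if labels is None:
        labels = _gfp_labels(scene, thresholds)
    samp = np.asarray(scene.voxel_sampling())
    voxel_vol = scene.voxel_z * scene.voxel_xy ** 2
    segments: list[DendronSegment] = []
    for lab in range(1, labels.max() + 1):
        coords = np.argwhere(labels == lab)
        n_vox = len(coords)
        if n_vox < 8:
            continue
        pts, length = _centerline(coords * samp)
        if length <= 0:
            continue
        radius = math.sqrt(n_vox * voxel_vol / (math.pi * length))
        length_pre = length / scene.expansion_factor
        if length_pre < thresholds.min_length_pre:
            continue
        segments.append(
            DendronSegment(
                dendron_id=lab,
                skeleton=pts,
                mean_radius=radius,
                length_post=length,
                length_pre=length_pre,
            )
        )
    return segments


def detect_boutons(
    scene: ImageScene,
    thresholds: MorphThresholds | None = None,
    require_cochannel: bool = False,
    channel: str = "kisspeptin",
    cochannel: str = "synaptophysin",
) -> list[Bouton]:
    """Detect bright puncta in ``channel`` and flag co-channel membership.

    Coarse connected components above the global threshold are refined to a
    per-component half-max mask so that the equivalent diameter tracks the
    full-width-half-max size of the punctum rather than the global threshold.
    """
    thresholds = thresholds or MorphThresholds()
    img = np.asarray(scene.channels[channel], dtype=float)
    if img.max() <= 0:
        return []
    smoothed = ndimage.gaussian_filter(img, sigma=1.0)
    thr = _channel_threshold(smoothed, thresholds.intensity_threshold)
    coarse = cc_label(smoothed > thr, connectivity=3)
    co_img = np.asarray(scene.channels.get(cochannel, np.zeros_like(img)), dtype=float)
    co_sm = ndimage.gaussian_filter(co_img, sigma=1.0) if co_img.max() > 0 else co_img
    if co_img.max() > 0:
        co_thr = max(_channel_threshold(co_sm, thresholds.intensity_threshold),
                     0.3 * float(co_sm.max()))
        co_mask = co_sm > co_thr
    else:
        co_mask = np.zeros(img.shape, dtype=bool)

    samp = np.asarray(scene.voxel_sampling())
    voxel_vol = scene.voxel_z * scene.voxel_xy ** 2
    boutons: list[Bouton] = []
    bid = 0
    objects = ndimage.find_objects(coarse)
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        region = coarse[sl] == lab
        local = np.where(region, smoothed[sl], 0.0)
        peak = float(local.max())
        if peak <= 0:
            continue
        refined = local >= 0.5 * peak
        # keep the component containing the peak only
        sub_lab = cc_label(refined, connectivity=3)
        peak_idx = np.unravel_index(int(np.argmax(local)), local.shape)
        refined = sub_lab == sub_lab[peak_idx]
        n_vox = int(refined.sum())
        d_raw = 2.0 * (3.0 * n_vox * voxel_vol / (4.0 * math.pi)) ** (1.0 / 3.0)
        # remove the detector's own smoothing from the measured width in
        # quadrature (widths of convolved Gaussians add quadratically)
        blur_fwhm = 2.355 * (scene.voxel_z * scene.voxel_xy ** 2) ** (1.0 / 3.0)
        d_eq = math.sqrt(max(d_raw ** 2 - blur_fwhm ** 2, (0.5 * scene.voxel_xy) ** 2))
        if d_eq <= thresholds.min_bouton_diameter:
            continue
        w = np.where(refined, local, 0.0)
        idx = np.argwhere(refined)
        offset = np.array([s.start for s in sl])
        weights = w[refined]
        centroid_vox = (idx * weights[:, None]).sum(axis=0) / weights.sum() + offset
        centroid = centroid_vox * samp
        co_frac = float(co_mask[sl][refined].mean()) if n_vox else 0.0
        has_co = co_frac >= 0.5
        if require_cochannel and not has_co:
            continue
        peaks = {channel: peak}
        if co_img.max() > 0:
            peaks[cochannel] = float(np.where(refined, co_sm[sl], 0.0).max())
        boutons.append(
            Bouton(
                bouton_id=bid,
                centroid=centroid,
                equivalent_diameter=d_eq,
                has_kisspeptin=(channel == "kisspeptin")
                or (cochannel == "kisspeptin" and has_co),
                has_synaptophysin=(channel == "synaptophysin")
                or (cochannel == "synaptophysin" and has_co),
                peak_intensity=peaks,
            )
        )
        bid += 1
    return boutons


# ---------------------------------------------------------------------------
# pairing and profiles


def pair_appositions(
    boutons: list[Bouton],
    dendrons: list[DendronSegment],
    scene: ImageScene,
    thresholds: MorphThresholds | None = None,
    labels: np.ndarray | None = None,
) -> list[Apposition]:
    """Pair each bouton with its nearest dendron and set gap and orientation.

    The gap is the Euclidean distance from the bouton surface (centroid minus
    equivalent radius) to the nearest dendron mask voxel, clipped at zero.
    Orientation is "face" when the bouton-to-surface axis lies within the
    configured cone of the optical (z) axis, else "side".  In confocal mode the
    dark-voxel rule is evaluated along the connecting line.
    """
    thresholds = thresholds or MorphThresholds()
    if not boutons or not dendrons:
        return []
    if labels is None:
        labels = _gfp_labels(scene, thresholds)
    mask = labels > 0
    samp = np.asarray(scene.voxel_sampling())
    dist, (iz, iy, ix) = ndimage.distance_transform_edt(
        ~mask, sampling=samp, return_indices=True
    )
    skel_pts = np.concatenate([d.skeleton for d in dendrons], axis=0)
    skel_ids = np.concatenate(
        [np.full(len(d.skeleton), d.dendron_id) for d in dendrons]
    )
    # local axis tangent at every skeleton point (per segment), used to strip
    # the along-axis component from bouton-to-axis direction vectors
    tangents = np.concatenate(
        [np.gradient(d.skeleton, axis=0) if len(d.skeleton) > 1
         else np.array([[0.0, 0.0, 1.0]]) for d in dendrons]
    )
    norms = np.linalg.norm(tangents, axis=1, keepdims=True)
    tangents = np.divide(tangents, norms, out=np.zeros_like(tangents), where=norms > 0)
    tree = cKDTree(skel_pts)
    cos_cone = math.cos(math.radians(thresholds.cone_half_angle_deg))

    out: list[Apposition] = []
    for b in boutons:
        vox = np.clip(np.round(b.centroid / samp).astype(int), 0,
                      np.asarray(scene.shape) - 1)
        nearest_vox = np.array([iz[tuple(vox)], iy[tuple(vox)], ix[tuple(vox)]])
        # measure from the sub-voxel centroid, not the rounded voxel centre
        d_center = (
            float(np.linalg.norm(b.centroid - nearest_vox * samp))
            if dist[tuple(vox)] > 0 else 0.0
        )
        dendron_lab = int(labels[tuple(nearest_vox)])
        _, k = tree.query(b.centroid)
        anchor = skel_pts[k]
        if d_center <= samp.max():
            # centroid inside or touching the dendron: orient from the axis,
            # with the along-axis component removed (skeleton points are
            # discrete, so the raw offset carries a spurious axial term)
            v = b.centroid - anchor
            t = tangents[k]
            direction = v - (v @ t) * t
            if dendron_lab == 0:
                dendron_lab = int(skel_ids[k])
        else:
            direction = b.centroid - nearest_vox * samp
        norm = float(np.linalg.norm(direction))
        direction = direction / norm if norm > 0 else np.array([1.0, 0.0, 0.0])
        orientation = "face" if abs(direction[0]) >= cos_cone else "side"
        gap = max(0.0, d_center - b.equivalent_diameter / 2.0)
        app = Apposition(
            bouton_id=b.bouton_id,
            dendron_id=dendron_lab if dendron_lab else int(skel_ids[k]),
            orientation=orientation,
            gap=gap,
            has_kisspeptin=b.has_kisspeptin,
            has_synaptophysin=b.has_synaptophysin,
            bouton_centroid=np.asarray(b.centroid, dtype=float),
            bouton_diameter=b.equivalent_diameter,
            anchor=np.asarray(anchor, dtype=float),
            direction=direction,
        )
        if scene.modality == "confocal":
            app.confocal_close = _no_dark_pixels(
                scene, b, nearest_vox * samp, thresholds
            )
        out.append(app)
    return out


def _no_dark_pixels(
    scene: ImageScene,
    bouton: Bouton,
    surface_pt: np.ndarray,
    thresholds: MorphThresholds,
) -> bool:
    """Confocal close-apposition rule: no dark voxel between the elements."""
    gfp = np.asarray(scene.channels["gfp"], dtype=float)
    kiss = np.asarray(scene.channels["kisspeptin"], dtype=float)
    gfp_thr = _channel_threshold(gfp, thresholds.intensity_threshold) if gfp.max() > 0 else np.inf
    kiss_thr = _channel_threshold(kiss, thresholds.intensity_threshold) if kiss.max() > 0 else np.inf
    samp = np.asarray(scene.voxel_sampling())
    start = np.asarray(bouton.centroid, dtype=float)
    end = np.asarray(surface_pt, dtype=float)
    seg = end - start
    length = float(np.linalg.norm(seg))
    if length == 0:
        return True
    n = max(2, int(math.ceil(length / scene.voxel_xy)) + 1)
    ts = np.linspace(0.0, 1.0, n)
    pts = start[None, :] + ts[:, None] * seg[None, :]
    coords = (pts / samp).T
    gv = ndimage.map_coordinates(gfp, coords, order=1)
    kv = ndimage.map_coordinates(kiss, coords, order=1)
    # samples beyond the bouton radius and outside GFP count as "between"
    radial = ts * length
    between = (radial > bouton.equivalent_diameter / 2.0) & (gv < gfp_thr)
    dark = between & (kv < kiss_thr)
    return int(dark.sum()) < thresholds.confocal_max_gap


def extract_profile(
    scene: ImageScene,
    apposition: Apposition,
    thresholds: MorphThresholds | None = None,
    channels: tuple[str, str] = ("gfp", "synaptophysin"),
    smooth_sigma: float = 1.0,
) -> IntensityProfile:
    """Extract the relative-intensity profile used for overlap scoring.

    Side view: a 1D line scan through the dendron axis point and the bouton
    centre, sampled at the xy voxel pitch.  Face view: per-z-slice mean
    intensity inside a ``face_box`` square centred on the bouton, sampled at
    the z step.  Each channel is normalized to its own in-scan peak.
    """
    thresholds = thresholds or MorphThresholds()
    samp = np.asarray(scene.voxel_sampling())
    shape = np.asarray(scene.shape)
    truncated = False
    if apposition.orientation == "side":
        anchor = apposition.anchor
        center = apposition.bouton_centroid
        d = apposition.bouton_diameter or 1.0
        u = center - anchor
        dist = float(np.linalg.norm(u))
        u = u / dist if dist > 0 else np.array([0.0, 1.0, 0.0])
        t0, t1 = -3.5, dist + d / 2.0 + 2.0
        pitch = scene.voxel_xy
        ts = np.arange(t0, t1 + pitch / 2, pitch)
        pts = anchor[None, :] + ts[:, None] * u[None, :]
        vox = pts / samp
        inside = np.all((vox >= 0) & (vox <= shape - 1), axis=1)
        if not inside.all():
            truncated = True
            ts, vox = ts[inside], vox[inside]
        values = {}
        for ch in channels:
            img = np.asarray(scene.channels[ch], dtype=float)
            v = ndimage.map_coordinates(img, vox.T, order=1)
            if smooth_sigma > 0:
                v = ndimage.gaussian_filter1d(v, smooth_sigma)
            peak = v.max()
            values[ch] = v / peak if peak > 0 else v
        positions = ts - ts[0]
    else:  # face: box-mean z profile
        half = thresholds.face_box / 2.0
        cz, cy, cx = apposition.bouton_centroid
        y0 = max(0, int(round((cy - half) / scene.voxel_xy)))
        y1 = min(shape[1], int(round((cy + half) / scene.voxel_xy)) + 1)
        x0 = max(0, int(round((cx - half) / scene.voxel_xy)))
        x1 = min(shape[2], int(round((cx + half) / scene.voxel_xy)) + 1)
        if y0 == 0 or x0 == 0 or y1 == shape[1] or x1 == shape[2]:
            truncated = True
        values = {}
        for ch in channels:
            img = np.asarray(scene.channels[ch], dtype=float)
            v = img[:, y0:y1, x0:x1].mean(axis=(1, 2))
            if smooth_sigma > 0:
                v = ndimage.gaussian_filter1d(v, smooth_sigma * scene.voxel_xy / scene.voxel_z)
            peak = v.max()
            values[ch] = v / peak if peak > 0 else v
        positions = np.arange(shape[0]) * scene.voxel_z
    return IntensityProfile(positions=positions, values=values, truncated=truncated)


def overlap_length(
    profile: IntensityProfile,
    channel_a: str,
    channel_b: str,
    level: float = defaults.PROFILE_LEVEL,
) -> float:
    """Longest contiguous span (um) where both normalized channels are >= level.

    Crossing points are refined by linear interpolation between samples, so the
    result is not quantized to the sampling pitch.
    """
    x = np.asarray(profile.positions, dtype=float)
    a = np.asarray(profile.values[channel_a], dtype=float)
    b = np.asarray(profile.values[channel_b], dtype=float)
    g = np.minimum(a, b) - level
    if len(x) == 0 or g.max() < 0:
        return 0.0
    best = 0.0
    i = 0
    n = len(x)
    while i < n:
        if g[i] < 0:
            i += 1
            continue
        j = i
        while j + 1 < n and g[j + 1] >= 0:
            j += 1
        left = x[i]
        if i > 0:  # interpolate the upward crossing
            left = x[i - 1] + (x[i] - x[i - 1]) * (-g[i - 1]) / (g[i] - g[i - 1])
        right = x[j]
        if j + 1 < n:
            right = x[j] + (x[j + 1] - x[j]) * g[j] / (g[j] - g[j + 1])
        best = max(best, right - left)
        i = j + 1
    return float(best)


def classify_apposition(
    candidate: Apposition,
    overlap: float,
    thresholds: MorphThresholds | None = None,
    modality: str = "ExM",
) -> Apposition:
    """Assign the contact class from overlap, orientation and gap.

    A synapse requires the overlap to *strictly* exceed the orientation's
    threshold (0.95 um side-on, 1.75 um face-view, post-expansion).  Otherwise
    the contact is close non-synaptic when the gap is within ``close_gap``,
    else separate.  Confocal scenes use the dark-voxel rule instead.
    """
    thresholds = thresholds or MorphThresholds()
    candidate.overlap = float(overlap)
    if modality == "confocal":
        close = bool(candidate.confocal_close)
        candidate.label = "close_nonsynaptic" if close else "separate"
        return candidate
    theta = thresholds.theta_side if candidate.orientation == "side" else thresholds.theta_face
    if overlap > theta:
        candidate.label = "synapse"
    elif candidate.gap <= thresholds.close_gap:
        candidate.label = "close_nonsynaptic"
    else:
        candidate.label = "separate"
    return candidate


def contact_census(
    appositions: list[Apposition],
    dendrons: list[DendronSegment],
    expansion_factor: float,
    fiber_ids: dict[int, int] | None = None,
) -> ContactStats:
    """Census statistics over classified appositions, per pre-expansion length."""
    total_pre = sum(d.length_pre for d in dendrons)
    if total_pre <= 0:
        raise ValueError("total dendron length is zero; densities undefined")
    contacts = [a for a in appositions if a.label != "separate"]
    synapses = [a for a in appositions if a.label == "synapse"]
    non_syn = [a for a in appositions if a.label != "synapse"]
    pct_syn_kiss = (
        100.0 * sum(a.has_kisspeptin for a in synapses) / len(synapses)
        if synapses else float("nan")
    )
    pct_cochannel = (
        100.0 * sum(a.has_synaptophysin for a in contacts) / len(contacts)
        if contacts else float("nan")
    )
    if fiber_ids:
        per_fiber: dict[int, set[int]] = {}
        for a in contacts:
            fid = fiber_ids.get(a.bouton_id)
            if fid is not None:
                per_fiber.setdefault(fid, set()).add(a.dendron_id)
        dpf = (
            float(np.mean([len(v) for v in per_fiber.values()]))
            if per_fiber else float("nan")
        )
    else:
        dpf = float("nan")
    mean_dist = float(np.mean([a.gap for a in non_syn])) if non_syn else float("nan")
    return ContactStats(
        n_appositions=len(contacts),
        n_synapses=len(synapses),
        total_dendron_length_pre=total_pre,
        appositions_per_100um=100.0 * len(contacts) / total_pre,
        synapses_per_10um=10.0 * len(synapses) / total_pre,
        pct_synapses_with_kisspeptin=pct_syn_kiss,
        pct_appositions_cochannel=pct_cochannel,
        dendrons_per_fiber=dpf,
        mean_bouton_dendron_distance=mean_dist,
    )


def classify_contacts(
    scene: ImageScene,
    thresholds: MorphThresholds | None = None,
    require_cochannel: bool = True,
) -> tuple[list[Apposition], list[DendronSegment], list[Bouton]]:
    """Full per-scene pipeline: segment, detect, pair, profile, classify."""
    thresholds = thresholds or MorphThresholds()
    labels = _gfp_labels(scene, thresholds)
    dendrons = segment_dendrons(scene, thresholds, labels=labels)
    boutons = detect_boutons(scene, thresholds, require_cochannel=require_cochannel)
    if not dendrons or not boutons:
        return [], dendrons, boutons
    candidates = pair_appositions(boutons, dendrons, scene, thresholds, labels=labels)
    overlap_channels = (
        ("gfp", "kisspeptin") if scene.modality == "confocal" else ("gfp", "synaptophysin")
    )
    out = []
    for cand in candidates:
        prof = extract_profile(scene, cand, thresholds, channels=overlap_channels)
        ov = overlap_length(prof, *overlap_channels, level=thresholds.profile_level)
        out.append(classify_apposition(cand, ov, thresholds, modality=scene.modality))
    return out, dendrons, boutons
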