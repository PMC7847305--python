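"""Ground-truthed simulators for every stage of the pipeline.

Three generators emulate the three kinds of raw data the analyses consume:

* ``simulate_exm_scene`` — 3-channel 3D stacks of tube-like GFP dendrons with
  Gaussian-profiled kisspeptin/synaptophysin boutons planted at controlled
  signed gaps (negative gap = channel overlap), blurred by an anisotropic PSF
  with Poisson shot noise.
* ``simulate_dendron_traces`` — dendron ROI fluorescence at 0.9 Hz over 500 s
  with a puff-confined movement artifact (mean 4.5%, SD 0.5% ΔF), optional
  sustained kisspeptin-like responses, linear baseline drift and noise.
* ``simulate_photometry_lh`` — scheduled-mode (5 s on / 15 s off) photometry
  with abrupt planted synchronization events, paired with an LH series that is
  either coupled (one pulse follows each event) or uncoupled (flat baseline
  with assay noise only, the Kiss1-null regime).

Every generator is bit-for-bit reproducible from its seed and returns the
ground truth it planted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import defaults
from .calcium import RoiTrace
from .contacts import Bouton, ImageScene
from .photometry import LHSeries, PhotometryTrace, process_photometry

__all__ = [
    "SceneParams",
    "TraceParams",
    "PhotometryParams",
    "PhotometryGroundTruth",
    "simulate_exm_scene",
    "simulate_dendron_traces",
    "simulate_photometry_raw",
    "simulate_photometry_lh",
    "match_boutons",
]


# ---------------------------------------------------------------------------
# ExM scenes


@dataclass
class SceneParams:
    """Geometry, optics and planting plan for a simulated ExM/confocal scene.

    Lengths are post-expansion micrometres.  ``gap_distribution`` lists planted
    bouton-dendron signed gaps as ``(gap_um, fraction)`` tuples; a negative gap
    is an overlap (interpenetration) of that depth.  Entries may optionally
    carry an orientation ("side"/"face") and a bouton diameter:
    ``(gap, fraction, orientation, diameter)``.
    """

    n_dendrons: int = 2
    dendron_radius: float = 1.75
    dendron_length: float = 70.0
    n_boutons: int = 20
    bouton_diameter_mean: float = 2.0
    bouton_diameter_sd: float = 0.15
    gap_distribution: list[tuple] = field(
        default_factory=lambda: [(-1.6, 0.4, "side"), (0.4, 0.3), (2.5, 0.3)]
    )
    cochannel_fraction: float = 1.0
    face_fraction: float = 0.0
    fiber_divergence: float = 1.0
    psf_sigma_xy: float = 0.1
    psf_sigma_z: float = 0.3
    noise_snr: float = 10.0
    voxel_xy: float = 0.1
    voxel_z: float = 0.6
    expansion_factor: float = defaults.DEFAULT_EXPANSION_FACTOR
    modality: str = "ExM"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("dendron_radius", "dendron_length", "voxel_xy", "voxel_z",
                     "bouton_diameter_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("cochannel_fraction", "face_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_boutons and max(self.voxel_xy, self.voxel_z) > self.bouton_diameter_mean:
            raise ValueError("voxel size exceeds bouton diameter: scene undersampled")
        fracs = [e[1] for e in self.gap_distribution]
        if self.gap_distribution and not math.isclose(sum(fracs), 1.0, abs_tol=1e-6):
            raise ValueError("gap_distribution fractions must sum to 1")


def _allocate_counts(fractions: list[float], total: int) -> list[int]:
    """Largest-remainder allocation of ``total`` items to fractions."""
    raw = [f * total for f in fractions]
    counts = [int(math.floor(r)) for r in raw]
    rem = total - sum(counts)
    order = np.argsort([c - r for c, r in zip(counts, raw)])
    for i in order[:rem]:
        counts[i] += 1
    return counts


def _planted_overlap(gap: float, orientation: str, r: float, d: float) -> float:
    """Half-max overlap length implied by the planted geometry.

    The GFP half-max support along a side line scan through the axis spans
    [-r, r]; along a face-view box-mean z profile it spans +/- 0.866 r (the
    height at which a cylinder chord falls to half its maximum).  The
    Gaussian-profiled bouton's half-max support spans its diameter.
    """
    gfp_half = r if orientation == "side" else math.sqrt(3.0) / 2.0 * r
    c = r + d / 2.0 + gap          # bouton-centre offset from the axis
    lo = max(-gfp_half, c - d / 2.0)
    hi = min(gfp_half, c + d / 2.0)
    return max(0.0, hi - lo)


def _intended_class(gap: float, orientation: str, r: float, d: float) -> str:
    ov = _planted_overlap(gap, orientation, r, d)
    theta = defaults.THETA_SIDE_UM if orientation == "side" else defaults.THETA_FACE_UM
    if ov > theta:
        return "synapse"
    if max(gap, 0.0) <= defaults.CLOSE_CONTACT_GAP_UM:
        return "close_nonsynaptic"
    return "separate"


def simulate_exm_scene(params: SceneParams) -> tuple[ImageScene, pd.DataFrame]:
    """Render a 3-channel scene and return it with its planting ground truth.

    Dendrons are straight cylinders along x, stacked in y; boutons are placed
    along each dendron at jittered regular spacing, displaced in +/-y (side
    plantings) or +z (face plantings) so that their surface-to-surface signed
    gap equals the planted value.  The ground truth records, per bouton, its
    centre, diameter, channel membership, host dendron, fiber, signed gap,
    orientation and the contact class its geometry implies.
    """
    rng = np.random.default_rng(params.seed)
    r = params.dendron_radius
    vxy, vz = params.voxel_xy, params.voxel_z

    # normalize the planting plan
    entries = []
    for e in params.gap_distribution:
        gap, frac = e[0], e[1]
        orient = e[2] if len(e) > 2 and e[2] is not None else None
        diam = e[3] if len(e) > 3 else None
        entries.append((gap, frac, orient, diam))
    counts = _allocate_counts([e[1] for e in entries], params.n_boutons) if entries else []

    plan = []  # (gap, orientation, diameter)
    for (gap, _, orient, diam), cnt in zip(entries, counts):
        for _ in range(cnt):
            o = orient or ("face" if rng.random() < params.face_fraction else "side")
            d = diam if diam is not None else max(
                3 * vxy, rng.normal(params.bouton_diameter_mean, params.bouton_diameter_sd)
            )
            plan.append((gap, o, d))
    rng.shuffle(plan)

    d_max = max([p[2] for p in plan], default=params.bouton_diameter_mean)
    gap_max = max([p[0] for p in plan], default=0.0)
    margin = 2.0
    radial = r + d_max + max(gap_max, 0.0) + margin

    nx = int(math.ceil((params.dendron_length + 2 * margin) / vxy))
    y_pitch = 2 * radial
    ny = int(math.ceil(params.n_dendrons * y_pitch / vxy))
    z_axis = r + 1.5
    nz = int(math.ceil((z_axis + radial + d_max / 2.0 + 1.5) / vz))
    shape = (nz, ny, nx)

    y_centers = [(i + 0.5) * y_pitch for i in range(params.n_dendrons)]
    x0, x1 = margin, margin + params.dendron_length

    zz = (np.arange(nz) * vz)[:, None]
    yy = (np.arange(ny) * vxy)[None, :]
    gfp2d = np.zeros((nz, ny))
    for yc in y_centers:
        gfp2d = np.maximum(gfp2d, ((yy - yc) ** 2 + (zz - z_axis) ** 2 <= r ** 2).astype(float))
    xmask = ((np.arange(nx) * vxy >= x0) & (np.arange(nx) * vxy <= x1)).astype(float)
    gfp = gfp2d[:, :, None] * xmask[None, None, :]

    kiss = np.zeros(shape)
    syn = np.zeros(shape)

    # fiber assignment: fibers span ~fiber_divergence distinct dendrons
    div = max(1, int(round(params.fiber_divergence)))
    div = min(div, max(1, params.n_dendrons))

    n_co = int(round(params.cochannel_fraction * len(plan)))
    co_flags = np.zeros(len(plan), dtype=bool)
    co_flags[rng.permutation(len(plan))[:n_co]] = True

    records = []
    slots_per_dendron = {i: [] for i in range(params.n_dendrons)}
    spacing = max(4.0, 1.7 * d_max)  # keep planted puncta from merging under blur
    n_slots = max(1, int(params.dendron_length // spacing))
    if params.n_boutons > params.n_dendrons * n_slots:
        raise ValueError(
            f"cannot place {params.n_boutons} boutons without collisions: "
            f"{params.n_dendrons} dendrons x {n_slots} slots at {spacing:.1f} um spacing"
        )
    for b, (gap, orient, d) in enumerate(plan):
        fiber = b // div
        dendron = (b % div + fiber) % params.n_dendrons
        slot = len(slots_per_dendron[dendron])
        slots_per_dendron[dendron].append(b)
        xc = x0 + (slot % n_slots + 0.5) * spacing + rng.uniform(-0.5, 0.5)
        xc = min(max(xc, x0 + 1.0), x1 - 1.0)
        yc = y_centers[dendron]
        offset = r + d / 2.0 + gap
        if orient == "face":
            zb, yb = z_axis + offset, yc
        else:
            side = 1 if (slot % 2 == 0) else -1
            zb, yb = z_axis, yc + side * offset
        center = np.array([zb, yb, xc])
        intensity = rng.uniform(0.85, 1.0)
        for img, active in ((kiss, True), (syn, bool(co_flags[b]))):
            if active:
                _add_blob(img, center, d, intensity, vxy, vz)
        records.append(
            dict(
                bouton_id=b,
                z=zb, y=yb, x=xc,
                diameter=d,
                has_kisspeptin=True,
                has_synaptophysin=bool(co_flags[b]),
                dendron_id=dendron,
                fiber_id=fiber,
                orientation=orient,
                signed_gap=gap,
                intended_class=_intended_class(gap, orient, r, d),
            )
        )

    sigma = (params.psf_sigma_z / vz, params.psf_sigma_xy / vxy, params.psf_sigma_xy / vxy)
    channels = {}
    for name, img in (("gfp", gfp), ("kisspeptin", kiss), ("synaptophysin", syn)):
        img = ndimage.gaussian_filter(img, sigma)
        peak = img.max()
        if peak > 0:
            img = img / peak
        if params.noise_snr > 0:
            counts_img = rng.poisson(img * params.noise_snr ** 2) / params.noise_snr ** 2
            img = counts_img + rng.normal(0.0, 0.01, size=img.shape)
        channels[name] = img.astype(np.float32)

    scene = ImageScene(
        channels=channels,
        voxel_xy=vxy,
        voxel_z=vz,
        expansion_factor=params.expansion_factor if params.modality == "ExM" else 1.0,
        modality=params.modality,
    )
    gt = pd.DataFrame.from_records(
        records,
        columns=[
            "bouton_id", "z", "y", "x", "diameter", "has_kisspeptin",
            "has_synaptophysin", "dendron_id", "fiber_id", "orientation",
            "signed_gap", "intended_class",
        ],
    )
    return scene, gt


def _add_blob(
    img: np.ndarray, center: np.ndarray, diameter: float,
    intensity: float, vxy: float, vz: float,
) -> None:
    """Add a Gaussian-profiled spheroid whose FWHM equals its diameter."""
    nz, ny, nx = img.shape
    ext = diameter * 1.5
    z0 = max(0, int((center[0] - ext) / vz)); z1 = min(nz, int((center[0] + ext) / vz) + 2)
    y0 = max(0, int((center[1] - ext) / vxy)); y1 = min(ny, int((center[1] + ext) / vxy) + 2)
    x0 = max(0, int((center[2] - ext) / vxy)); x1 = min(nx, int((center[2] + ext) / vxy) + 2)
    if z0 >= z1 or y0 >= y1 or x0 >= x1:
        return
    zg = np.arange(z0, z1) * vz - center[0]
    yg = np.arange(y0, y1) * vxy - center[1]
    xg = np.arange(x0, x1) * vxy - center[2]
    rho2 = zg[:, None, None] ** 2 + yg[None, :, None] ** 2 + xg[None, None, :] ** 2
    blob = intensity * np.exp(-4.0 * math.log(2.0) * rho2 / diameter ** 2)
    np.maximum(img[z0:z1, y0:y1, x0:x1], blob, out=img[z0:z1, y0:y1, x0:x1])


def match_boutons(
    boutons: list[Bouton], gt: pd.DataFrame, tolerance: float = 1.0
) -> dict[int, int]:
    """Map detected bouton ids to ground-truth ids by nearest planted centre."""
    if not len(gt) or not boutons:
        return {}
    centers = gt[["z", "y", "x"]].to_numpy(dtype=float)
    out = {}
    for b in boutons:
        dists = np.linalg.norm(centers - np.asarray(b.centroid)[None, :], axis=1)
        k = int(np.argmin(dists))
        if dists[k] <= tolerance:
            out[b.bouton_id] = int(gt["bouton_id"].iloc[k])
    return out


# ---------------------------------------------------------------------------
# dendron ROI traces


@dataclass
class TraceParams:
    """Conditions for the dendron calcium-trace generator.

    Defaults mirror the recording protocol (0.9 Hz frames, 500 s total, 90 s
    puff) and the measured aCSF artifact (4.5 +/- 0.5 % ΔF).  The default
    sustained response (35% peak, ~150 s decay) emulates the kisspeptin
    response; ``response_fraction`` plants responders in ~91% of ROIs.
    """

    n_rois: int = 20
    frame_rate: float = 0.9
    duration: float = 500.0
    puff_start: float = 100.0
    puff_duration: float = 90.0
    artifact_amplitude_mean: float = defaults.ACSF_ARTIFACT_MEAN_PCT
    artifact_amplitude_sd: float = defaults.ACSF_ARTIFACT_SD_PCT
    response_amplitude: float = 35.0
    response_decay_tau: float = 100.0  # peak subsides to <5% of amplitude by 500 s
    response_fraction: float = 0.91
    drift_per_recording: float = 0.0
    noise_sd: float = 1.0
    baseline_frames: int = 20
    baseline_f: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.duration < self.puff_start + self.puff_duration:
            raise ValueError("duration must cover the puff window")
        if not 0 <= self.response_fraction <= 1:
            raise ValueError("response_fraction must lie in [0, 1]")


def simulate_dendron_traces(params: TraceParams) -> tuple[list[RoiTrace], pd.DataFrame]:
    """Generate ROI traces with planted artifacts, responses and drift.

    Each trace is baseline x (1 + drift ramp + artifact + response + noise),
    all terms in % of baseline.  The movement artifact is a half-sine confined
    to the puff window; the response ramps up across the puff and decays
    exponentially after it, hence outlasting the puff by construction.
    """
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration * params.frame_rate))
    t = np.arange(n) / params.frame_rate
    t0, te = params.puff_start, params.puff_start + params.puff_duration
    in_puff = (t >= t0) & (t <= te)
    window = np.zeros(n)
    window[in_puff] = np.sin(math.pi * (t[in_puff] - t0) / (te - t0))

    n_resp = int(round(params.response_fraction * params.n_rois))
    responders = np.zeros(params.n_rois, dtype=bool)
    responders[rng.permutation(params.n_rois)[:n_resp]] = True
    if params.response_amplitude == 0:
        responders[:] = False

    traces, records = [], []
    for i in range(params.n_rois):
        a = rng.normal(params.artifact_amplitude_mean, params.artifact_amplitude_sd)
        pct = params.drift_per_recording * t / params.duration + a * window
        amp = 0.0
        if responders[i]:
            amp = params.response_amplitude * rng.normal(1.0, 0.03)
            resp = np.zeros(n)
            ramp = in_puff
            resp[ramp] = amp * (t[ramp] - t0) / (te - t0)
            after = t > te
            resp[after] = amp * np.exp(-(t[after] - te) / params.response_decay_tau)
            pct = pct + resp
        pct = pct + rng.normal(0.0, params.noise_sd, size=n)
        raw = params.baseline_f * (1.0 + pct / 100.0)
        traces.append(
            RoiTrace(
                roi_id=f"roi{i:03d}",
                times=t,
                raw_f=raw,
                frame_rate=params.frame_rate,
                puff_window=(t0, te),
                baseline_frames=params.baseline_frames,
            )
        )
        records.append(
            dict(roi_id=f"roi{i:03d}", responder=bool(responders[i]),
                 artifact_amplitude=a, response_amplitude=amp,
                 drift=params.drift_per_recording)
        )
    return traces, pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# photometry + LH


@dataclass
class PhotometryParams:
    """Conditions for the photometry/LH generator.

    Defaults emulate the coupled intact regime: ~1.5 h recordings in scheduled
    mode (5 s on / 15 s off), four synchronization events per hour, tail-tip LH
    sampling every 4 min, and an LH pulse starting 2 min after each event.
    ``coupled=False`` (the Kiss1-null regime) leaves the LH series flat at
    baseline with only multiplicative assay noise (CV 9.3%) floored at the
    assay sensitivity (0.04 ng/mL).
    """

    duration_h: float = 1.5
    se_rate: float = 4.0            # events/h
    se_amplitude: float = 10.0      # % ΔF/F
    se_rise: float = 10.0           # s
    se_decay: float = 40.0          # s
    sampling: tuple[float, float] = defaults.PHOTOMETRY_SCHEDULE_S
    lh_sampling_interval: float = 4.0   # min
    lh_baseline: float = 0.25       # ng/mL
    lh_pulse_amplitude: float = 1.2  # ng/mL
    lh_pulse_decay: float = 6.0     # min
    lh_delay_after_se: float = 2.0  # min
    coupled: bool = True
    assay_floor: float = defaults.LH_ASSAY_FLOOR_NG_ML
    assay_cv: float = defaults.LH_ASSAY_CV
    noise_sd: float = 0.002         # raw fluorescence units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.se_rate < 0:
            raise ValueError("se_rate must be non-negative")
        if self.duration_h <= 0 or self.lh_sampling_interval <= 0:
            raise ValueError("durations and intervals must be positive")


@dataclass
class PhotometryGroundTruth:
    se_times: np.ndarray     # s, planted event peak times
    pulse_times: np.ndarray  # min, planted LH pulse onsets/peaks


def _se_shape(t: np.ndarray, t0: float, rise: float, decay: float) -> np.ndarray:
    """Unit-peak double-exponential transient starting at t0."""
    dt = t - t0
    s = np.where(dt > 0, np.exp(-np.maximum(dt, 0) / decay) - np.exp(-np.maximum(dt, 0) / rise), 0.0)
    tp = rise * decay / (decay - rise) * math.log(decay / rise)
    peak = math.exp(-tp / decay) - math.exp(-tp / rise)
    return s / peak


def simulate_photometry_raw(
    params: PhotometryParams,
) -> tuple[np.ndarray, np.ndarray, PhotometryGroundTruth]:
    """Raw scheduled samples (1 Hz within on-bursts) plus planted event times."""
    rng = np.random.default_rng(params.seed)
    duration_s = params.duration_h * 3600.0
    on, off = params.sampling
    period = on + off
    t_all = np.arange(0.0, duration_s, 1.0)
    t_raw = t_all[(t_all % period) < on]

    n_se = int(round(params.se_rate * params.duration_h))
    if params.se_amplitude == 0:
        n_se = 0
    if n_se > 0:
        # leave room after the last event for its LH pulse to be sampled
        end_margin = 60.0 * (params.lh_delay_after_se + 2.0 * params.lh_sampling_interval)
        spacing = max(duration_s - end_margin, duration_s / 2.0) / n_se
        onsets = (np.arange(n_se) + 0.5) * spacing + rng.uniform(
            -0.15 * spacing, 0.15 * spacing, size=n_se
        )
    else:
        onsets = np.array([])
    tp = (
        params.se_rise * params.se_decay / (params.se_decay - params.se_rise)
        * math.log(params.se_decay / params.se_rise)
    )
    se_peaks = onsets + tp

    base = 1.0 + 0.02 * t_raw / duration_s  # gentle acquisition drift
    f = base.copy()
    for t0 in onsets:
        f = f + (params.se_amplitude / 100.0) * _se_shape(t_raw, t0, params.se_rise, params.se_decay)
    f = f + rng.normal(0.0, params.noise_sd, size=f.shape)

    pulse_times = (
        se_peaks / 60.0 + params.lh_delay_after_se
        if params.coupled and n_se > 0 else np.array([])
    )
    return t_raw, f, PhotometryGroundTruth(se_times=se_peaks, pulse_times=pulse_times)


def simulate_photometry_lh(
    params: PhotometryParams,
) -> tuple[PhotometryTrace, LHSeries, PhotometryGroundTruth]:
    """Processed photometry trace and the matching LH series.

    When coupled, one LH pulse of the stated amplitude rises instantaneously
    ``lh_delay_after_se`` minutes after each planted event and decays
    exponentially; the series is sampled on the tail-tip schedule with
    multiplicative assay noise and floored at the assay sensitivity.
    """
    rng = np.random.default_rng(params.seed + 1)
    t_raw, f_raw, gt = simulate_photometry_raw(params)
    trace = process_photometry(t_raw, f_raw, schedule=params.sampling)

    duration_min = params.duration_h * 60.0
    t_lh = np.arange(0.0, duration_min + 1e-9, params.lh_sampling_interval)
    conc = np.full_like(t_lh, params.lh_baseline)
    for pt in gt.pulse_times:
        after = t_lh >= pt
        conc[after] += params.lh_pulse_amplitude * np.exp(
            -(t_lh[after] - pt) / params.lh_pulse_decay
        )
    conc = conc * (1.0 + rng.normal(0.0, params.assay_cv, size=conc.shape))
    conc = np.maximum(conc, params.assay_floor)
    lh = LHSeries(times=t_lh, conc=conc,
                  assay_floor=params.assay_floor, assay_cv=params.assay_cv)
    return trace, lh, gt
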