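"""Self-validation experiments: parameter recovery on simulated data.

Each function regenerates synthetic data under the study conditions, runs the
corresponding analysis from scratch and reports how well it recovers what was
planted.  These are the quantitative checks behind the package's claims; the
test suite and ``scripts/acceptance.py`` both call them.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .calcium import calibrate_threshold, compute_dff, detect_response
from .contacts import IntensityProfile, classify_contacts, contact_census, overlap_length
from .photometry import (
    coincidence,
    detect_lh_pulses,
    detect_synchronization_events,
)
from .synthetic import (
    PhotometryParams,
    SceneParams,
    TraceParams,
    match_boutons,
    simulate_dendron_traces,
    simulate_exm_scene,
    simulate_photometry_lh,
)

__all__ = [
    "reference_threshold",
    "overlap_oracle_max_error",
    "exm_recovery",
    "responder_rates",
    "coincidence_recovery",
    "RECOVERY_PLAN",
]

# planting plan for recovery runs: every gap at least two sampling voxels away
# from the 0.95/1.75 um overlap thresholds and the 1 um contact cut
RECOVERY_PLAN = [
    (-1.6, 0.30, "side", 2.0),
    (0.4, 0.20, "side", 2.0),
    (2.5, 0.15, "side", 2.0),
    (-3.2, 0.15, "face", 3.5),
    (0.4, 0.10, "face", 2.0),
    (2.5, 0.10, "face", 2.0),
]


def reference_threshold() -> float:
    """Responder threshold from a control set with mean 4.5%, SD 0.5% ΔF.

    [4.0, 4.5, 5.0] has exactly those sample statistics, so the calibrated
    threshold equals mean + 2 SD = 5.5% by construction.
    """
    return calibrate_threshold([4.0, 4.5, 5.0]).threshold


def overlap_oracle_max_error(
    seed: int, n_pairs: int = 100, pitch: float = 0.1
) -> float:
    """Worst |overlap - brute force| (um) over random analytic profile pairs.

    Each pair mixes Gaussian and rectangular bumps with random centres and
    widths, sampled at the voxel pitch; the oracle evaluates the same analytic
    curves on a 1 nm grid and measures the longest joint super-level span.
    """
    rng = np.random.default_rng(seed)
    xs = np.arange(0.0, 6.0, pitch)
    xf = np.arange(0.0, 6.0, 0.001)
    worst = 0.0
    for _ in range(n_pairs):
        curves = []
        for _ in range(2):
            c = rng.uniform(1.0, 5.0)
            if rng.random() < 0.5:
                s = rng.uniform(0.15, 0.8)
                curves.append((lambda x, c=c, s=s: np.exp(-((x - c) ** 2) / (2 * s ** 2))))
            else:
                w = rng.uniform(0.3, 2.0)
                curves.append((lambda x, c=c, w=w: ((x >= c - w / 2) & (x <= c + w / 2)).astype(float)))
        fa, fb = curves
        prof = IntensityProfile(positions=xs, values={"a": fa(xs), "b": fb(xs)})
        measured = overlap_length(prof, "a", "b", level=0.5)
        joint = np.minimum(fa(xf), fb(xf)) >= 0.5
        # longest contiguous run on the fine grid
        best = run = 0
        for v in joint:
            run = run + 1 if v else 0
            best = max(best, run)
        oracle = best * 0.001
        worst = max(worst, abs(measured - oracle))
    return worst


def _recovery_scene_params(seed: int) -> SceneParams:
    return SceneParams(
        n_dendrons=3,
        dendron_length=72.0,
        n_boutons=30,
        gap_distribution=list(RECOVERY_PLAN),
        noise_snr=5.0,
        seed=seed,
    )


def exm_recovery(seed: int, n_scenes: int = 7) -> dict:
    """Classification agreement and census recovery over simulated scenes.

    Runs the full detection/classification pipeline on ``n_scenes`` rendered
    scenes (30 planted appositions each, SNR 5, margins >= 2 voxels from every
    decision boundary) and compares each apposition's class with the planted
    ground truth, and the measured apposition density with the planted one.
    """
    agree = total = 0
    measured_contacts = planted_contacts = 0
    measured_len = planted_len = 0.0
    for k in range(n_scenes):
        params = _recovery_scene_params(seed + 101 * k)
        scene, gt = simulate_exm_scene(params)
        apps, dendrons, boutons = classify_contacts(scene)
        mapping = match_boutons(boutons, gt)
        gt_by_id = gt.set_index("bouton_id")
        for a in apps:
            gid = mapping.get(a.bouton_id)
            if gid is None:
                continue
            total += 1
            agree += a.label == gt_by_id.loc[gid, "intended_class"]
        census = contact_census(apps, dendrons, scene.expansion_factor)
        measured_contacts += census.n_appositions
        measured_len += census.total_dendron_length_pre
        planted_contacts += int((gt.intended_class != "separate").sum())
        planted_len += params.n_dendrons * params.dendron_length / params.expansion_factor
    measured_density = 100.0 * measured_contacts / measured_len
    planted_density = 100.0 * planted_contacts / planted_len
    return dict(
        agreement_pct=100.0 * agree / total,
        n_appositions=total,
        measured_density_per_100um=measured_density,
        planted_density_per_100um=planted_density,
        density_error_pct=100.0 * abs(measured_density - planted_density) / planted_density,
    )


def responder_rates(seed: int, n_rois: int = 1000) -> dict:
    """Detection rate of planted 35% responses and artifact false-positive rate.

    Responder traces carry the sustained kisspeptin-like response (35% peak,
    outlasting the 90 s puff); artifact-only traces carry just the puff-confined
    aCSF movement artifact (Normal(4.5, 0.5^2) % ΔF).  Both sets are called
    against the control-calibrated 5.5% threshold.
    """
    thr = calibrate_threshold([4.0, 4.5, 5.0])
    planted = TraceParams(n_rois=n_rois, response_fraction=1.0, noise_sd=2.0, seed=seed)
    traces, _ = simulate_dendron_traces(planted)
    hits = sum(
        detect_response(compute_dff(t), thr).responder for t in traces
    )
    artifact = dataclasses.replace(planted, response_amplitude=0.0, seed=seed + 1)
    traces0, _ = simulate_dendron_traces(artifact)
    false_pos = sum(
        detect_response(compute_dff(t), thr).responder for t in traces0
    )
    return dict(
        threshold_pct=thr.threshold,
        detection_pct=100.0 * hits / n_rois,
        false_positive_pct=100.0 * false_pos / n_rois,
        n_rois=n_rois,
    )


def coincidence_recovery(
    seed: int, n_coupled: int = 20, n_uncoupled: int = 100
) -> dict:
    """Coupled vs uncoupled (Kiss1-null-like) regime dissociation.

    Coupled runs must detect every planted synchronization event and match
    every detected LH pulse to a preceding event.  Uncoupled runs use a very
    low flat LH baseline (0.1 ng/mL) and count as clean when events persist but
    no LH pulse is detected.
    """
    coupled_perfect = 0
    frac_pulse = []
    frac_se = []
    for k in range(n_coupled):
        p = PhotometryParams(seed=seed + k)
        trace, lh, gt = simulate_photometry_lh(p)
        ses = detect_synchronization_events(trace)
        pulses = detect_lh_pulses(lh)
        res = coincidence(ses, pulses)
        frac_pulse.append(res.fraction_pulses_preceded_by_se)
        frac_se.append(res.fraction_se_followed_by_pulse)
        coupled_perfect += (
            len(ses) == len(gt.se_times)
            and res.fraction_pulses_preceded_by_se == 1.0
            and res.fraction_se_followed_by_pulse == 1.0
        )
    clean_null = 0
    for k in range(n_uncoupled):
        p = PhotometryParams(coupled=False, lh_baseline=0.1, seed=seed + 1000 + k)
        trace, lh, _ = simulate_photometry_lh(p)
        n_se = len(detect_synchronization_events(trace))
        n_pulses = len(detect_lh_pulses(lh))
        clean_null += n_se > 0 and n_pulses == 0
    return dict(
        coupled_perfect_runs=coupled_perfect,
        n_coupled=n_coupled,
        mean_fraction_pulses_preceded_by_se=float(np.mean(frac_pulse)),
        mean_fraction_se_followed_by_pulse=float(np.mean(frac_se)),
        uncoupled_zero_pulse_pct=100.0 * clean_null / n_uncoupled,
        n_uncoupled=n_uncoupled,
    )
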