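"""End-to-end orchestration: simulate, analyze, summarize, write outputs."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as kio
from .calcium import (
    ResponseThreshold,
    calibrate_threshold,
    compute_dff,
    detect_response,
    summarize_group,
)
from .config import PipelineConfig, save_config
from .contacts import ContactStats, classify_contacts, contact_census
from .photometry import (
    CoincidenceResult,
    coincidence,
    detect_lh_pulses,
    detect_synchronization_events,
)
from .synthetic import (
    simulate_dendron_traces,
    simulate_exm_scene,
    simulate_photometry_lh,
)

__all__ = ["PipelineResult", "run_pipeline"]

log = logging.getLogger("kisspulse")


@dataclass
class PipelineResult:
    census: ContactStats | None = None
    appositions: pd.DataFrame | None = None
    threshold: ResponseThreshold | None = None
    calls: pd.DataFrame | None = None
    responder_fraction: float | None = None
    coincidence: CoincidenceResult | None = None


def run_pipeline(config: PipelineConfig, out_dir=None) -> PipelineResult:
    """Run the enabled stages on freshly simulated data and write outputs.

    Stages: ``exm`` (scene -> contact classification -> census), ``calcium``
    (traces -> ΔF% -> responder calls), ``photometry`` (trace + LH ->
    events, pulses, coincidence).  With a fixed seed the result files are
    byte-identical across reruns.  Unknown stage names raise immediately.
    """
    known = {"exm", "calcium", "photometry"}
    unknown = set(config.stages) - known
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    if not config.stages:
        log.warning("no stages enabled; nothing to do")
    out = PipelineResult()
    outp = Path(out_dir) if out_dir is not None else None
    if outp is not None:
        outp.mkdir(parents=True, exist_ok=True)
        save_config(config, outp / "config_used.yaml")
    log.info("seed=%d thresholds=%s", config.seed, config.thresholds)

    if "exm" in config.stages:
        try:
            scene, gt = simulate_exm_scene(config.scene)
            apps, dendrons, _ = classify_contacts(scene, config.thresholds)
            fibers = dict(zip(gt["bouton_id"], gt["fiber_id"]))
            out.census = contact_census(
                apps, dendrons, scene.expansion_factor, fiber_ids=fibers
            )
            out.appositions = kio.appositions_to_frame(apps)
            if outp is not None:
                kio.save_appositions(apps, outp / "appositions.csv")
                kio.save_census(out.census, outp / "census.json")
                gt.to_csv(outp / "scene_ground_truth.csv", index=False)
        except Exception as exc:
            raise RuntimeError(f"exm stage failed: {exc}") from exc

    if "calcium" in config.stages:
        try:
            traces, gt = simulate_dendron_traces(config.traces)
            control_rng = np.random.default_rng(config.traces.seed + 10_000)
            controls = control_rng.normal(
                config.traces.artifact_amplitude_mean,
                config.traces.artifact_amplitude_sd,
                size=30,
            )
            thr = calibrate_threshold(controls)
            out.threshold = thr
            dffs = [compute_dff(t, drift_limit=config.drift_limit) for t in traces]
            kept = [d for d in dffs if d.qc_pass]
            calls = [detect_response(d, thr) for d in kept]
            out.calls = pd.DataFrame.from_records(
                [
                    dict(roi_id=c.roi_id, peak_dff=c.peak_dff,
                         exceeds_threshold=c.exceeds_threshold,
                         outlasts_puff=c.outlasts_puff, responder=c.responder)
                    for c in calls
                ]
            )
            summary = summarize_group(kept, calls) if kept else None
            out.responder_fraction = (
                summary.responder_fraction if summary else float("nan")
            )
            if outp is not None:
                out.calls.to_csv(outp / "response_calls.csv", index=False)
                gt.to_csv(outp / "trace_ground_truth.csv", index=False)
                if summary is not None:
                    payload = dict(
                        n_rois=summary.n_rois,
                        mean_peak=summary.mean_peak,
                        sem_peak=summary.sem_peak,
                        median_peak=summary.median_peak,
                        auc=summary.auc,
                        responder_fraction=summary.responder_fraction,
                        threshold=thr.threshold,
                    )
                    (outp / "group_summary.json").write_text(
                        json.dumps(payload, indent=2)
                    )
        except Exception as exc:
            raise RuntimeError(f"calcium stage failed: {exc}") from exc

    if "photometry" in config.stages:
        try:
            trace, lh, gt = simulate_photometry_lh(config.photometry)
            ses = detect_synchronization_events(
                trace, fraction_of_max=config.se_fraction_of_max
            )
            pulses = detect_lh_pulses(lh)
            out.coincidence = coincidence(ses, pulses, window=config.coincidence_window)
            if outp is not None:
                payload = dict(
                    n_se=out.coincidence.n_se,
                    n_pulses=out.coincidence.n_pulses,
                    matched_pairs=out.coincidence.matched_pairs,
                    fraction_pulses_preceded_by_se=out.coincidence.fraction_pulses_preceded_by_se,
                    fraction_se_followed_by_pulse=out.coincidence.fraction_se_followed_by_pulse,
                    window_min=out.coincidence.window,
                    planted_se_times_s=list(np.round(gt.se_times, 3)),
                    planted_pulse_times_min=list(np.round(gt.pulse_times, 3)),
                )
                (outp / "coincidence.json").write_text(json.dumps(payload, indent=2))
                kio.save_lh_series(lh, outp / "lh_series.csv")
        except Exception as exc:
            raise RuntimeError(f"photometry stage failed: {exc}") from exc

    return out
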