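"""End-to-end pipeline: raw record → reconstruction → bands → rates/beats → scores.

``run_pipeline`` mirrors the offline analysis of a recorded session:
reconstruct displacement from the quadrature record, split it into
bands, estimate per-window respiration rates (optionally against a
reference waveform), detect beats (HSMM heart sounds or sphygmogram
template matching), and — when R-peak annotations are supplied — score
the detections.  Everything lands in an output directory together with a
machine-readable run manifest; re-running the same manifest reproduces
byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluation import match_beats, matched_ibi_pairs, subject_scores_from_match
from .filtering import BandConfig, extract_bands
from .heartbeat import BeatTimes, detect_heartbeats_hsmm, ibi_rmse, template_match_beats
from .io import read_annotations, read_signal, write_annotations, write_signal
from .reconstruction import reconstruct
from .respiration import compare_to_reference, estimate_windows
from .signals import DisplacementTrace, QuadratureRecord, WAVELENGTH_24GHZ

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything one analysis run needs, loadable from YAML."""

    input: str
    reference_rpeaks: Optional[str] = None
    reference_respiration: Optional[str] = None
    wavelength: float = WAVELENGTH_24GHZ
    window_s: float = 30.0
    respiration_enabled: bool = True
    heartbeat_enabled: bool = True
    heartbeat_method: str = "hsmm"  # or "template"
    tolerance_ms: float = 75.0
    refit_blocks: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class StageError(RuntimeError):
    """An error attributed to a named pipeline stage."""

    def __init__(self, stage: str, source: Exception):
        super().__init__(f"stage '{stage}' failed: {source}")
        self.stage = stage


def run_pipeline(cfg: PipelineConfig, out_dir: str) -> dict:
    """Execute the configured stages and write the report bundle."""
    os.makedirs(out_dir, exist_ok=True)
    report: dict = {"config_digest": cfg.digest()}

    try:
        record = read_signal(cfg.input)
    except Exception as exc:
        raise StageError("read", exc) from exc

    try:
        if isinstance(record, QuadratureRecord):
            if cfg.wavelength and cfg.wavelength != record.wavelength:
                record.wavelength = cfg.wavelength
            displacement = reconstruct(record, refit_blocks=cfg.refit_blocks)
        elif isinstance(record, DisplacementTrace):
            displacement = record
        else:  # pragma: no cover - read_signal only returns these two
            raise TypeError(type(record))
    except StageError:
        raise
    except Exception as exc:
        raise StageError("reconstruction", exc) from exc

    try:
        bands = extract_bands(displacement)
    except Exception as exc:
        raise StageError("filtering", exc) from exc

    if cfg.respiration_enabled:
        try:
            estimates = estimate_windows(bands.respiration_bp, cfg.window_s)
            rows = [
                {"window_index": e.window_index, **{f"rr_{k}": v for k, v in e.as_dict().items()}}
                for e in estimates
            ]
            resp_df = pd.DataFrame(rows)
            if cfg.reference_respiration:
                ref = read_signal(cfg.reference_respiration)
                ref_bands = extract_bands(ref) if ref.sample_rate > 2 * 80 else None
                ref_bp = ref_bands.respiration_bp if ref_bands else ref
                comparison = compare_to_reference(bands.respiration_bp, ref_bp, cfg.window_s)
                report["respiration_comparison"] = {
                    "rmse_brpm": comparison.rmse_brpm,
                    "r_max": comparison.r_max,
                    "m_max": comparison.m_max,
                    "mean_rr_reference": comparison.mean_rr_reference,
                    "mean_rr_radar": comparison.mean_rr_radar,
                }
            resp_path = os.path.join(out_dir, "respiration.csv")
            resp_df.to_csv(resp_path, index=False, float_format="%.4f")
            report["respiration_table"] = "respiration.csv"  # relative to out_dir
            report["n_windows"] = len(rows)
        except Exception as exc:
            raise StageError("respiration", exc) from exc

    if cfg.heartbeat_enabled:
        try:
            if cfg.heartbeat_method == "hsmm":
                beats = detect_heartbeats_hsmm(bands.heartsound)
            elif cfg.heartbeat_method == "template":
                beats = template_match_beats(bands.sphygmogram)
            else:
                raise ValueError(f"unknown heartbeat method {cfg.heartbeat_method!r}")
            beat_path = os.path.join(out_dir, "beats.txt")
            write_annotations(beat_path, beats.times, ["beat"] * beats.times.size)
            report["beats_file"] = "beats.txt"
            report["n_beats"] = int(beats.times.size)

            if cfg.reference_rpeaks:
                ref_times, _ = read_annotations(cfg.reference_rpeaks)
                ref = BeatTimes(times=ref_times, source="ecg_reference")
                match = match_beats(beats, ref, cfg.tolerance_ms)
                scores = subject_scores_from_match("run", match)
                pred_ibi, ref_ibi = matched_ibi_pairs(match, ref)
                report["heartbeat_scores"] = {
                    "f1": scores.f1,
                    "sensitivity": scores.sensitivity,
                    "precision": scores.precision,
                    "tp": match.tp,
                    "fp": match.fp,
                    "fn": match.fn,
                    "ibi_rmse_ms": (
                        ibi_rmse(pred_ibi, ref_ibi) if pred_ibi.intervals.size else None
                    ),
                }
        except StageError:
            raise
        except Exception as exc:
            raise StageError("heartbeat", exc) from exc

    manifest = {
        "tool": "radarvitals",
        "version": __version__,
        "config": dataclasses.asdict(cfg),
        "config_digest": cfg.digest(),
        "numpy": np.__version__,
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(os.path.join(out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
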