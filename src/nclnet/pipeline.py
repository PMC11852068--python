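"""End-to-end orchestration: simulate → preprocess → coherence → threshold →
features → stats → decode.

``run_pipeline`` executes every stage for each configured band, persists the
intermediates (HDF5 tensors) and result tables (CSV/JSON) into the output
directory, and writes a manifest listing each artifact with its sha256, the
stage timings and the configuration used.  Stage helpers are public so the
CLI can run any stage in isolation from the previous stage's artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as nio
from .coherence import (
    DEFAULT_K,
    DEFAULT_NW,
    DEFAULT_STEP,
    DEFAULT_WIN_LEN,
    CoherenceTensor,
    coherence_tensor,
    global_mean_coherence,
    plan_windows,
)
from .decoding import run_decoding_suite
from .errors import ConfigError
from .groupstats import compare_conditions, summarize
from .netfeatures import features_per_window
from .preprocess import (
    BAND_BY_NAME,
    EpochSet,
    band_decompose,
    broadband_filter,
    downsample,
    extract_epochs,
    remove_line_noise,
)
from .surprise import DEFAULT_GRID_SIZE, select_optimal_threshold
from .synthetic import CohortConfig, Recording, generate_recording

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "preprocess_recording", "subject_tensors"]

#: Analysis sampling rate after downsampling, Hz.
FS_ANALYSIS = 1000.0


@dataclass
class PipelineConfig:
    """Full run configuration; serializable to/from JSON or YAML."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    bands: tuple[str, ...] = tuple(BAND_BY_NAME)
    win_len: int = DEFAULT_WIN_LEN
    step: int = DEFAULT_STEP
    nw: float = DEFAULT_NW
    k: int = DEFAULT_K
    grid_size: int = DEFAULT_GRID_SIZE
    community_seed: int = 0
    decoding_seed: int = 0
    decode_band: str = "beta"
    granularity: str = "window"

    def __post_init__(self) -> None:
        for name in self.bands:
            if name not in BAND_BY_NAME:
                raise ConfigError(f"bands: unknown band {name!r}")
        if self.decode_band not in self.bands:
            raise ConfigError(
                f"decode_band {self.decode_band!r} is not among bands {self.bands}"
            )

    def fast(self) -> "PipelineConfig":
        """Variant generating at 1 kHz (skips the downsampling stage)."""
        return replace(self, cohort=self.cohort.fast())

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["band_coupling"] = {
            k: list(v) for k, v in d["cohort"]["band_coupling"].items()
        }
        d["bands"] = list(self.bands)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        cohort = d.pop("cohort", {})
        cohort = dict(cohort)
        if "band_coupling" in cohort:
            cohort["band_coupling"] = {
                k: tuple(v) for k, v in cohort["band_coupling"].items()
            }
        d["cohort"] = CohortConfig(**cohort)
        if "bands" in d:
            d["bands"] = tuple(d["bands"])
        return cls(**d)

    def to_file(self, path: str | Path) -> Path:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(self.to_dict()))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2))
        return path

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        return cls.from_dict(data)


def preprocess_recording(
    recording: Recording, config: PipelineConfig
) -> dict[str, EpochSet]:
    """Conditioning chain + band decomposition + epoching for one recording.

    Broadband 1-250 Hz filter, 50 Hz notch, downsample to 1 kHz when the
    recording is at a higher rate, then one epoch set per configured band.
    """
    sig = broadband_filter(recording.signal, recording.fs)
    sig = remove_line_noise(sig, recording.fs)
    fs = recording.fs
    if fs > FS_ANALYSIS:
        sig = downsample(sig, fs, FS_ANALYSIS)
        fs = FS_ANALYSIS
    bands = [BAND_BY_NAME[name] for name in config.bands]
    decomposed = band_decompose(sig, fs, bands)
    out: dict[str, EpochSet] = {}
    for band in bands:
        out[band.name] = extract_epochs(
            recording,
            decomposed[band.name],
            config.cohort.epoch_pre,
            config.cohort.epoch_post,
            fs=fs,
            band=band,
        )
    return out


def subject_tensors(
    epoch_sets: dict[str, EpochSet], config: PipelineConfig
) -> dict[str, CoherenceTensor]:
    """Coherence tensors for every band of one subject."""
    out: dict[str, CoherenceTensor] = {}
    for band_name, es in epoch_sets.items():
        plan = plan_windows(es.n_samples, config.win_len, config.step, es.event_sample)
        out[band_name] = coherence_tensor(es, plan, nw=config.nw, k=config.k)
    return out


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute every stage and persist all artifacts; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    timings: dict[str, float] = {}
    stage = "configure"
    try:
        artifacts.append(config.to_file(out / "config.json"))

        stage = "simulate+preprocess+coherence"
        t0 = time.perf_counter()
        tensors: dict[str, dict[str, CoherenceTensor]] = {}
        for i in range(config.cohort.n_subjects):
            rec = generate_recording(config.cohort, i)
            epoch_sets = preprocess_recording(rec, config)
            tensors[rec.subject_id] = subject_tensors(epoch_sets, config)
            del rec, epoch_sets
            log.info("subject %d/%d processed", i + 1, config.cohort.n_subjects)
        artifacts.append(nio.write_tensors(out / "tensors.h5", tensors))
        timings[stage] = time.perf_counter() - t0

        stage = "global_coherence"
        t0 = time.perf_counter()
        trace_rows = []
        for subject, bands in tensors.items():
            for band_name, tensor in bands.items():
                trace = global_mean_coherence(tensor)
                mids = (
                    tensor.window_plan.midpoints() - tensor.window_plan.event_sample
                ) / FS_ANALYSIS
                for w, (mid, val) in enumerate(zip(mids, trace)):
                    trace_rows.append(
                        {
                            "subject_id": subject,
                            "band": band_name,
                            "window": w,
                            "midpoint_s": mid,
                            "mean_coherence": val,
                        }
                    )
        traces = pd.DataFrame(trace_rows)
        traces.to_csv(out / "global_coherence.csv", index=False)
        artifacts.append(out / "global_coherence.csv")
        timings[stage] = time.perf_counter() - t0

        stage = "threshold"
        t0 = time.perf_counter()
        optimal: dict[str, float] = {}
        for band_name in config.bands:
            sweep = select_optimal_threshold(
                [tensors[s][band_name] for s in tensors],
                grid_size=config.grid_size,
                seed=config.community_seed,
            )
            optimal[band_name] = sweep.optimal
            artifacts.append(nio.write_sweep_csv(out / f"sweep_{band_name}.csv", sweep))
        (out / "optimal_thresholds.json").write_text(json.dumps(optimal, indent=2))
        artifacts.append(out / "optimal_thresholds.json")
        timings[stage] = time.perf_counter() - t0

        stage = "features"
        t0 = time.perf_counter()
        feature_frames = []
        for subject, bands in tensors.items():
            for band_name, tensor in bands.items():
                feature_frames.append(
                    features_per_window(
                        tensor, optimal[band_name], seed=config.community_seed
                    )
                )
        features = pd.concat(feature_frames, ignore_index=True)
        features.to_csv(out / "features.csv", index=False)
        artifacts.append(out / "features.csv")
        timings[stage] = time.perf_counter() - t0

        stage = "stats"
        t0 = time.perf_counter()
        comparisons = compare_conditions(features, granularity=config.granularity)
        comparisons.to_csv(out / "comparisons.csv", index=False)
        artifacts.append(out / "comparisons.csv")
        summary = summarize(features, granularity=config.granularity)
        summary.to_csv(out / "summary.csv", index=False)
        artifacts.append(out / "summary.csv")
        timings[stage] = time.perf_counter() - t0

        stage = "decode"
        t0 = time.perf_counter()
        results = run_decoding_suite(
            features, band=config.decode_band, seed=config.decoding_seed
        )
        decode_json = {
            f"{r.feature_set}/{r.decoder}": {
                "fold_accuracies": r.fold_accuracies.tolist(),
                "mean_accuracy": r.mean_accuracy,
                "auc": r.auc,
            }
            for r in results
        }
        (out / "decode_results.json").write_text(json.dumps(decode_json, indent=2))
        artifacts.append(out / "decode_results.json")
        acc = pd.DataFrame(
            [
                {"decoder": r.decoder, "feature_set": r.feature_set, "mean_accuracy": r.mean_accuracy}
                for r in results
            ]
        ).pivot(index="decoder", columns="feature_set", values="mean_accuracy")
        acc.to_csv(out / "accuracy_matrix.csv")
        artifacts.append(out / "accuracy_matrix.csv")
        roc_rows = []
        for r in results:
            for fpr, tpr in r.roc:
                roc_rows.append(
                    {"feature_set": r.feature_set, "decoder": r.decoder, "fpr": fpr, "tpr": tpr}
                )
        pd.DataFrame(roc_rows).to_csv(out / "roc_points.csv", index=False)
        artifacts.append(out / "roc_points.csv")
        timings[stage] = time.perf_counter() - t0
    except Exception:
        nio.write_manifest(
            out / "manifest.json",
            [a for a in artifacts if Path(a).exists()],
            {"complete": False, "failed_stage": stage, "timings_s": timings},
        )
        log.error("pipeline failed in stage %r", stage)
        raise

    manifest_extra = {
        "complete": True,
        "timings_s": timings,
        "optimal_thresholds": optimal,
        "decode_band": config.decode_band,
    }
    nio.write_manifest(out / "manifest.json", artifacts, manifest_extra)
    return json.loads((out / "manifest.json").read_text())
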