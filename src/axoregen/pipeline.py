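"""End-to-end orchestration: simulate -> measure -> statistics, with a manifest.

A YAML config lists the stages to run and their parameters; one global seed
deterministically derives a per-stage seed, so re-running an identical config
reproduces a byte-identical result bundle. Every run writes a manifest naming
the parameter set, the seed, and the SHA-256 checksum of each output file.
"""

from __future__ import annotations

import hashlib
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, axotomy, ephys, io, kymograph, polarity, synthetic, trends

__all__ = ["AnalysisConfig", "run_full_analysis", "derive_seed"]


def derive_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31, derived from the global seed."""
    return zlib.crc32(f"{master_seed}:{stage}".encode()) & 0x7FFFFFFF


@dataclass
class AnalysisConfig:
    seed: int
    out_dir: str
    stages: dict = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(seed=int(data["seed"]), out_dir=str(data["out_dir"]),
                   stages=data.get("stages", {}),
                   log_level=data.get("log_level", "INFO"))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _run_ephys(cfg: dict, seed: int, out: Path) -> list[Path]:
    n_traces = int(cfg.get("n_traces", 5))
    rng = np.random.default_rng(seed)
    traces, features = [], []
    protocols = {}
    for i in range(n_traces):
        tid = f"trace{i:03d}"
        tr, _gt = synthetic.gen_voltage_trace(
            n_spikes=int(rng.integers(0, cfg.get("n_spikes_max", 8) + 1)),
            protocol=ephys.CurrentStepProtocol.compact(),
            noise_sd=float(cfg.get("noise_sd", 0.0)),
            seed=derive_seed(seed, tid), trace_id=tid)
        traces.append(tr)
        protocols[tid] = tr.protocol
        passive = ephys.measure_passive_properties(tr)
        events, freq = ephys.measure_spike_features(tr)
        features.append({
            "trace_id": tid, "resting_mv": passive.resting_mv,
            "input_resistance_MOhm": passive.input_resistance_MOhm,
            "fires_ap": passive.fires_ap, "n_spikes": len(events),
            "spike_frequency_Hz": freq,
            "mean_amplitude_mV": (float(np.mean([e.amplitude_mV for e in events]))
                                  if events else None),
            "mean_width_ms": (float(np.mean([e.width_ms for e in events
                                             if e.width_ms is not None]))
                              if events else None)})
    io.write_traces_csv(traces, out / "traces.csv")
    io.write_protocol_csv(protocols, out / "protocol.csv")
    io.write_json(features, out / "ephys_features.json")
    return [out / "traces.csv", out / "protocol.csv", out / "ephys_features.json"]


def _run_kymograph(cfg: dict, seed: int, out: Path) -> list[Path]:
    fractions = cfg.get("fractions", {"anterograde": 0.25, "retrograde": 0.45,
                                      "bidirectional": 0.15, "stationary": 0.15})
    tracks, _gt = synthetic.gen_vesicle_tracks(
        int(cfg.get("n_tracks", 50)), fractions,
        noise_sd_um=float(cfg.get("noise_sd_um", 0.0)), seed=seed)
    io.write_tracks_csv(tracks, out / "tracks.csv")
    summary = kymograph.summarize_transport(tracks)
    io.write_json({"n_tracks": summary.n_tracks, "fractions": summary.fractions,
                   "mean_anterograde_velocity_um_s": summary.mean_anterograde_velocity_um_s,
                   "mean_retrograde_velocity_um_s": summary.mean_retrograde_velocity_um_s},
                  out / "transport_summary.json")
    return [out / "tracks.csv", out / "transport_summary.json"]


def _run_axotomy(cfg: dict, seed: int, out: Path) -> list[Path]:
    groups = cfg.get("groups", [{"name": "cohort", "n_cells": 50}])
    cohort_all, records = [], []
    params = axotomy.AxotomyParams(**cfg.get("params", {}))
    for gi, group in enumerate(groups):
        cohort, _gt = synthetic.gen_axotomy_cohort(
            int(group.get("n_cells", 50)),
            outcome_fractions=group.get("outcome_fractions"),
            div=group.get("div"), substrate=group.get("substrate"),
            seed=derive_seed(seed, group.get("name", f"group{gi}")),
            cell_prefix=f"{group.get('name', f'group{gi}')}_")
        cohort_all.extend(cohort)
        records.extend(axotomy.analyze_timecourse(tc, params) for tc in cohort)
    io.write_axotomy_csv(cohort_all, out / "frames.csv", out / "meta.csv")
    io.records_to_frame(records).to_csv(out / "regeneration_records.csv", index=False)
    summary = axotomy.summarize_cohort(records, grouping=tuple(cfg.get("grouping", ("div",))))
    summary["summary"].to_csv(out / "cohort_summary.csv", index=False)
    io.write_json(summary["tests"], out / "cohort_tests.json")
    logs = [r.log10_retraction for r in records if r.log10_retraction is not None]
    outputs = [out / "frames.csv", out / "meta.csv",
               out / "regeneration_records.csv", out / "cohort_summary.csv",
               out / "cohort_tests.json"]
    if len(logs) >= 10:
        fit = axotomy.fit_retraction_mixture(logs, seed=derive_seed(seed, "mixture"))
        io.write_json({"k": fit.k, "weights": fit.weights, "means": fit.means,
                       "sds": fit.sds, "bic": fit.bic, "boundary_um": fit.boundary_um,
                       "analysis_parameters": {"proximal_cut_um": params.proximal_cut_um}},
                      out / "retraction_mixture.json")
        outputs.append(out / "retraction_mixture.json")
    return outputs


def _run_polarity(cfg: dict, seed: int, out: Path) -> list[Path]:
    n_cells = int(cfg.get("n_cells", 10))
    profiles_all, summaries = [], []
    for i in range(n_cells):
        profiles, cell_body, _gt = synthetic.gen_intensity_profiles(
            axon_dendrite_ratio=float(cfg.get("axon_dendrite_ratio", 2.0)),
            noise_sd=float(cfg.get("noise_sd", 0.0)),
            seed=derive_seed(seed, f"cell{i}"), cell_id=f"cell{i:03d}")
        profiles_all.extend(profiles)
        s = polarity.compute_compartment_signals(
            profiles, cell_body["intensity"], cell_body["background"])
        summaries.append(polarity.compute_polarity_ratios(s))
    io.write_profiles_csv(profiles_all, out / "profiles.csv", out / "regions.csv")
    io.write_json(summaries, out / "polarity_summaries.json")
    return [out / "profiles.csv", out / "regions.csv", out / "polarity_summaries.json"]


def _run_trends(cfg: dict, seed: int, out: Path) -> list[Path]:
    matrix, _gt = synthetic.gen_expression_matrix(
        int(cfg.get("n_genes", 200)), int(cfg.get("n_increasing", 20)),
        int(cfg.get("n_decreasing", 20)), fold=float(cfg.get("fold", 5.0)),
        cv=float(cfg.get("cv", 0.1)), seed=seed)
    io.write_expression_csv(matrix, out / "fpkm.csv", out / "samples.csv")
    calls = trends.classify_gene_trends(matrix)
    io.write_json(calls, out / "trend_calls.json")
    return [out / "fpkm.csv", out / "samples.csv", out / "trend_calls.json"]


_STAGES = {
    "ephys": _run_ephys,
    "kymograph": _run_kymograph,
    "axotomy": _run_axotomy,
    "polarity": _run_polarity,
    "trends": _run_trends,
}


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Run every configured stage and write a deterministic manifest."""
    out_root = Path(config.out_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "version": __version__, "stages": {}}
    for stage, cfg in config.stages.items():
        if stage not in _STAGES:
            raise ValueError(f"unknown stage {stage!r}; known: {sorted(_STAGES)}")
        stage_dir = out_root / stage
        stage_dir.mkdir(parents=True, exist_ok=True)
        stage_seed = derive_seed(config.seed, stage)
        try:
            outputs = _STAGES[stage](cfg or {}, stage_seed, stage_dir)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = {
            "seed": stage_seed,
            "parameters": cfg or {},
            "outputs": {str(p.relative_to(out_root)): _sha256(p) for p in outputs},
        }
    io.write_json(manifest, out_root / "manifest.json")
    return manifest
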