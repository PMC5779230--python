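"""Reading and writing the pipeline's tidy table and image formats.

All tables are plain CSV with unit-bearing column names (tip_position_um,
t_ms, ...); kymographs are single-page grayscale TIFF. Loaders validate the
schema up front and collect row-level problems into one error message.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .axotomy import AxotomyTimecourse, RegenerationRecord
from .ephys import CurrentStep, CurrentStepProtocol, VoltageTrace
from .kymograph import KymographImage, VesicleTrack
from .polarity import NeuriteIntensityProfile
from .trends import ExpressionMatrix

__all__ = [
    "SchemaError",
    "read_table",
    "write_traces_csv", "read_traces_csv",
    "write_protocol_csv", "read_protocol_csv",
    "write_tracks_csv", "read_tracks_csv",
    "write_kymograph_tiff", "read_kymograph_tiff",
    "write_axotomy_csv", "read_axotomy_csv",
    "write_profiles_csv", "read_profiles_csv",
    "write_expression_csv", "read_expression_csv",
    "records_to_frame", "write_json",
]


class SchemaError(ValueError):
    pass


def read_table(path, required_columns, numeric_columns=(), unique_key=None) -> pd.DataFrame:
    """CSV loader with schema validation; problems are reported together."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: file not found")
    df = pd.read_csv(path)
    problems = []
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    for col in numeric_columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            problems.append(f"non-numeric values in {col!r} at rows {bad.tolist()[:10]}")
        df[col] = coerced
    if unique_key is not None:
        dup = df[df.duplicated(subset=list(unique_key), keep=False)]
        if len(dup):
            problems.append(
                f"duplicated {unique_key} rows: {dup[list(unique_key)].values.tolist()[:10]}")
    if problems:
        raise SchemaError(f"{path}: " + "; ".join(problems))
    return df


# -- ephys -------------------------------------------------------------------

def write_traces_csv(traces: list[VoltageTrace], path):
    frames = [pd.DataFrame({"trace_id": tr.trace_id, "t_ms": tr.t_ms,
                            "vm_mV": tr.vm_mV}) for tr in traces]
    pd.concat(frames).to_csv(path, index=False)


def read_traces_csv(path, protocols: dict | None = None,
                    sampling_khz: float | None = None) -> list[VoltageTrace]:
    df = read_table(path, ["trace_id", "t_ms", "vm_mV"], ["t_ms", "vm_mV"],
                    unique_key=("trace_id", "t_ms"))
    traces = []
    for tid, sub in df.groupby("trace_id", sort=False):
        t = sub["t_ms"].to_numpy()
        khz = sampling_khz or 1.0 / float(np.median(np.diff(t)))
        traces.append(VoltageTrace(
            t_ms=t, vm_mV=sub["vm_mV"].to_numpy(), sampling_khz=khz,
            protocol=(protocols or {}).get(tid), trace_id=str(tid)))
    return traces


def write_protocol_csv(protocols: dict, path):
    rows = [{"trace_id": tid, "onset_ms": s.onset_ms, "duration_ms": s.duration_ms,
             "amplitude_pA": s.amplitude_pA}
            for tid, proto in protocols.items() for s in proto.steps]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_protocol_csv(path) -> dict:
    df = read_table(path, ["trace_id", "onset_ms", "duration_ms", "amplitude_pA"],
                    ["onset_ms", "duration_ms", "amplitude_pA"])
    return {str(tid): CurrentStepProtocol(
        [CurrentStep(r.onset_ms, r.duration_ms, r.amplitude_pA)
         for r in sub.itertuples()])
        for tid, sub in df.groupby("trace_id", sort=False)}


# -- kymograph ---------------------------------------------------------------

def write_tracks_csv(tracks: list[VesicleTrack], path):
    frames = [pd.DataFrame({"track_id": tr.track_id, "t_s": tr.t_s,
                            "position_um": tr.positions_um,
                            "compartment": tr.compartment}) for tr in tracks]
    pd.concat(frames).to_csv(path, index=False)


def read_tracks_csv(path) -> list[VesicleTrack]:
    df = read_table(path, ["track_id", "t_s", "position_um"],
                    ["t_s", "position_um"], unique_key=("track_id", "t_s"))
    tracks = []
    for tid, sub in df.groupby("track_id", sort=False):
        comp = sub["compartment"].iloc[0] if "compartment" in sub else "axon"
        tracks.append(VesicleTrack(track_id=str(tid), t_s=sub["t_s"].to_numpy(),
                                   positions_um=sub["position_um"].to_numpy(),
                                   compartment=str(comp)))
    return tracks


def write_kymograph_tiff(image: KymographImage, path):
    tifffile.imwrite(path, image.pixels.astype(np.float32),
                     metadata={"pixel_um": image.pixel_um,
                               "frame_interval_s": image.frame_interval_s})


def read_kymograph_tiff(path, pixel_um: float,
                        frame_interval_s: float = 1.0) -> KymographImage:
    pixels = tifffile.imread(path)
    return KymographImage(pixels=np.clip(pixels, 0, None), pixel_um=pixel_um,
                          frame_interval_s=frame_interval_s)


# -- axotomy -----------------------------------------------------------------

def write_axotomy_csv(cohort: list[AxotomyTimecourse], frames_path, meta_path):
    rows, meta = [], []
    for tc in cohort:
        flag_at = {}
        for t, kind, pos in tc.flags:
            flag_at[round(float(t), 9)] = (kind, pos)
        for i, t in enumerate(tc.t_hr):
            kind, pos = flag_at.get(round(float(t), 9), ("", np.nan))
            rows.append({"cell_id": tc.cell_id, "t_hr": t,
                         "tip_position_um": tc.tip_position_um[i],
                         "tip_area_um2": (tc.tip_area_um2[i]
                                          if tc.tip_area_um2 is not None else np.nan),
                         "flag": kind, "flag_position_um": pos})
        meta.append({"cell_id": tc.cell_id, "axotomy_um": tc.axotomy_um,
                     "DIV": tc.div, "substrate": tc.substrate,
                     "branch_points": ";".join(str(float(b)) for b in tc.branch_points_um)})
    pd.DataFrame(rows).to_csv(frames_path, index=False)
    pd.DataFrame(meta).to_csv(meta_path, index=False)


def read_axotomy_csv(frames_path, meta_path) -> list[AxotomyTimecourse]:
    frames = read_table(frames_path,
                        ["cell_id", "t_hr", "tip_position_um"],
                        ["t_hr", "tip_position_um"],
                        unique_key=("cell_id", "t_hr"))
    meta = read_table(meta_path, ["cell_id", "axotomy_um"], ["axotomy_um"],
                      unique_key=("cell_id",)).set_index("cell_id")
    cohort = []
    for cid, sub in frames.groupby("cell_id", sort=False):
        sub = sub.sort_values("t_hr")
        m = meta.loc[cid]
        flags = []
        if "flag" in sub:
            for r in sub.itertuples():
                if isinstance(r.flag, str) and r.flag:
                    pos = getattr(r, "flag_position_um", np.nan)
                    flags.append((float(r.t_hr), r.flag,
                                  None if pd.isna(pos) else float(pos)))
        area = None
        if "tip_area_um2" in sub and sub["tip_area_um2"].notna().any():
            area = sub["tip_area_um2"].to_numpy()
        branch_points = []
        if "branch_points" in meta.columns:
            bp = m["branch_points"]
            if isinstance(bp, str):
                branch_points = [float(x) for x in bp.split(";") if x]
            elif not pd.isna(bp):  # single point parsed as a number
                branch_points = [float(bp)]
        div = m.get("DIV")
        cohort.append(AxotomyTimecourse(
            cell_id=str(cid), axotomy_um=float(m["axotomy_um"]),
            t_hr=sub["t_hr"].to_numpy(),
            tip_position_um=sub["tip_position_um"].to_numpy(),
            tip_area_um2=area, flags=flags,
            div=None if pd.isna(div) else int(div),
            substrate=(m.get("substrate") if isinstance(m.get("substrate"), str) else None),
            branch_points_um=branch_points))
    return cohort


# -- polarity ----------------------------------------------------------------

def write_profiles_csv(profiles: list[NeuriteIntensityProfile],
                       profiles_path, regions_path):
    rows, regions = [], []
    for p in profiles:
        for x, y in zip(p.arclength_um, p.intensity):
            rows.append({"cell_id": p.cell_id, "neurite_id": p.neurite_id,
                         "kind": p.kind, "arclength_um": x, "intensity": y})
        for region, bg in p.region_backgrounds.items():
            regions.append({"cell_id": p.cell_id, "neurite_id": p.neurite_id,
                            "region": region, "background": bg})
    pd.DataFrame(rows).to_csv(profiles_path, index=False)
    pd.DataFrame(regions).to_csv(regions_path, index=False)


def read_profiles_csv(profiles_path, regions_path) -> list[NeuriteIntensityProfile]:
    prof = read_table(profiles_path,
                      ["cell_id", "neurite_id", "kind", "arclength_um", "intensity"],
                      ["arclength_um", "intensity"],
                      unique_key=("cell_id", "neurite_id", "arclength_um"))
    regions = read_table(regions_path, ["cell_id", "neurite_id", "region", "background"],
                         ["background"])
    bg_map: dict = {}
    for r in regions.itertuples():
        bg_map.setdefault((r.cell_id, r.neurite_id), {})[r.region] = float(r.background)
    out = []
    for (cid, nid), sub in prof.groupby(["cell_id", "neurite_id"], sort=False):
        sub = sub.sort_values("arclength_um")
        out.append(NeuriteIntensityProfile(
            cell_id=str(cid), neurite_id=str(nid), kind=str(sub["kind"].iloc[0]),
            arclength_um=sub["arclength_um"].to_numpy(),
            intensity=sub["intensity"].to_numpy(),
            region_backgrounds=bg_map.get((cid, nid), {})))
    return out


# -- expression --------------------------------------------------------------

def write_expression_csv(matrix: ExpressionMatrix, fpkm_path, samples_path):
    matrix.fpkm.rename_axis("gene").to_csv(fpkm_path)
    matrix.sample_map.to_csv(samples_path, index=False)


def read_expression_csv(fpkm_path, samples_path) -> ExpressionMatrix:
    fpkm = pd.read_csv(fpkm_path, index_col=0).rename_axis(None)
    sample_map = read_table(samples_path, ["sample_id", "div", "replicate"],
                            ["div", "replicate"], unique_key=("sample_id",))
    bad = fpkm.columns[~fpkm.dtypes.apply(lambda d: np.issubdtype(d, np.number))]
    if len(bad):
        raise SchemaError(f"{fpkm_path}: non-numeric columns {bad.tolist()}")
    return ExpressionMatrix(fpkm=fpkm, sample_map=sample_map)


# -- generic -----------------------------------------------------------------

def records_to_frame(records: list[RegenerationRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        d["flags"] = ";".join(d["flags"])
        rows.append(d)
    return pd.DataFrame(rows)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, pd.DataFrame):
        return _jsonify(obj.to_dict(orient="records"))
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_json(obj, path):
    Path(path).write_text(json.dumps(_jsonify(obj), indent=2, sort_keys=True) + "\n")
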