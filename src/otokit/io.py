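"""File formats and run configuration.

Delimited-text schemas:

* ABR series: long CSV with columns ``subject, genotype, frequency_hz,
  level_db_spl, time_ms, amplitude_uv`` (plus ``sampling_rate_hz``).
* Ear-canal recordings: raw little-endian 32-bit float samples (``.f32``)
  with a JSON sidecar carrying ``sampling_rate_hz, f1_hz, f2_hz, l1_db, l2_db``.
* Cell positions: CSV with ``subject, genotype, cell_type, position_um`` plus a
  per-subject ``total_length_um``.
* Density volumes: TIFF stacks with a JSON sidecar (``voxel_um`` and a linear
  calibration ``slope``/``intercept`` to mg HA/cm³).

Run configuration round-trips through YAML.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from otokit.abr import ABRLevelSeries, ABRRecording
from otokit.cochleogram import Cytocochleogram
from otokit.dpoae import DPOAEStimulus, EarCanalRecording
from otokit.morphometry import DensityVolume

__all__ = [
    "RunConfig",
    "write_abr_series",
    "read_abr_series",
    "write_ear_canal_recording",
    "read_ear_canal_recording",
    "write_cell_positions",
    "read_cell_positions",
    "write_cytocochleogram",
    "write_volume",
    "read_volume",
]

ABR_COLUMNS = [
    "subject",
    "genotype",
    "frequency_hz",
    "level_db_spl",
    "time_ms",
    "amplitude_uv",
    "sampling_rate_hz",
]


def write_abr_series(series: Sequence[ABRLevelSeries], path: str | Path) -> None:
    frames = []
    for s in series:
        for rec in s.recordings:
            frames.append(
                pd.DataFrame(
                    {
                        "subject": rec.subject_id,
                        "genotype": rec.genotype,
                        "frequency_hz": rec.stimulus_frequency_hz,
                        "level_db_spl": rec.level_db_spl,
                        "time_ms": rec.times_ms,
                        "amplitude_uv": rec.samples,
                        "sampling_rate_hz": rec.sampling_rate_hz,
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_abr_series(path: str | Path) -> dict[tuple[str, float], ABRLevelSeries]:
    """Series keyed by (subject, frequency)."""
    df = pd.read_csv(path)
    missing = set(ABR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"ABR table missing columns: {sorted(missing)}")
    out: dict[tuple[str, float], ABRLevelSeries] = {}
    for (subject, freq), sub in df.groupby(["subject", "frequency_hz"]):
        recs = []
        for (level,), g in sub.groupby(["level_db_spl"]):
            g = g.sort_values("time_ms")
            recs.append(
                ABRRecording(
                    samples=g["amplitude_uv"].to_numpy(),
                    sampling_rate_hz=float(g["sampling_rate_hz"].iloc[0]),
                    stimulus_frequency_hz=float(freq),
                    level_db_spl=float(level),
                    subject_id=str(subject),
                    genotype=str(g["genotype"].iloc[0]),
                )
            )
        out[(str(subject), float(freq))] = ABRLevelSeries(recordings=tuple(recs))
    return out


def write_ear_canal_recording(rec: EarCanalRecording, basepath: str | Path) -> None:
    basepath = Path(basepath)
    rec.samples.astype("<f4").tofile(basepath.with_suffix(".f32"))
    sidecar = {
        "sampling_rate_hz": rec.sampling_rate_hz,
        "f1_hz": rec.stimulus.f1_hz,
        "f2_hz": rec.stimulus.f2_hz,
        "l1_db": rec.stimulus.l1_db_spl,
        "l2_db": rec.stimulus.l2_db_spl,
    }
    basepath.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_ear_canal_recording(basepath: str | Path) -> EarCanalRecording:
    basepath = Path(basepath)
    meta = json.loads(basepath.with_suffix(".json").read_text())
    samples = np.fromfile(basepath.with_suffix(".f32"), dtype="<f4").astype(float)
    stim = DPOAEStimulus(
        f1_hz=meta["f1_hz"], f2_hz=meta["f2_hz"], l1_db_spl=meta["l1_db"], l2_db_spl=meta["l2_db"]
    )
    return EarCanalRecording(samples=samples, sampling_rate_hz=meta["sampling_rate_hz"], stimulus=stim)


def write_cell_positions(
    tables: Mapping[str, Mapping[str, Sequence[float]]],
    lengths_um: Mapping[str, float],
    genotypes: Mapping[str, str],
    path: str | Path,
) -> None:
    """``tables[subject][cell_type] -> positions``; lengths/genotypes per subject."""
    rows = []
    for subject, by_type in tables.items():
        for cell_type, positions in by_type.items():
            for pos in positions:
                rows.append(
                    {
                        "subject": subject,
                        "genotype": genotypes[subject],
                        "cell_type": cell_type,
                        "position_um": pos,
                        "total_length_um": lengths_um[subject],
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_cell_positions(
    path: str | Path,
) -> tuple[dict[str, dict[str, np.ndarray]], dict[str, float], dict[str, str]]:
    df = pd.read_csv(path)
    tables: dict[str, dict[str, np.ndarray]] = {}
    lengths: dict[str, float] = {}
    genotypes: dict[str, str] = {}
    for (subject,), sub in df.groupby(["subject"]):
        subject = str(subject)
        tables[subject] = {
            str(ct): g["position_um"].to_numpy() for (ct,), g in sub.groupby(["cell_type"])
        }
        lengths[subject] = float(sub["total_length_um"].iloc[0])
        genotypes[subject] = str(sub["genotype"].iloc[0])
    return tables, lengths, genotypes


def write_cytocochleogram(c: Cytocochleogram, path: str | Path) -> None:
    pd.DataFrame(
        {
            "bin_start_um": c.bin_edges_um[:-1],
            "bin_end_um": c.bin_edges_um[1:],
            "ohc_count": c.ohc_counts,
            "ihc_count": c.ihc_counts,
        }
    ).to_csv(path, index=False)


def write_volume(v: DensityVolume, basepath: str | Path, slope: float = 1.0, intercept: float = 0.0) -> None:
    """TIFF stack plus JSON sidecar; stored values are (density - intercept)/slope."""
    basepath = Path(basepath)
    raw = ((v.voxels - intercept) / slope).astype(np.float32)
    tifffile.imwrite(basepath.with_suffix(".tiff"), raw)
    sidecar = {"voxel_um": v.voxel_size_um, "slope": slope, "intercept": intercept}
    basepath.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_volume(basepath: str | Path) -> DensityVolume:
    basepath = Path(basepath)
    meta = json.loads(basepath.with_suffix(".json").read_text())
    raw = tifffile.imread(basepath.with_suffix(".tiff")).astype(float)
    density = raw * meta.get("slope", 1.0) + meta.get("intercept", 0.0)
    return DensityVolume(voxels=density, voxel_size_um=meta["voxel_um"])


@dataclass(frozen=True)
class RunConfig:
    """Parameters of the end-to-end synthetic phenotype comparison."""

    out_dir: str = "otokit_report"
    seed: int = 0
    abr_frequencies_hz: tuple[float, ...] = (4000.0, 8000.0, 16000.0, 32000.0)
    f2_frequencies_hz: tuple[float, ...] = (8000.0, 16000.0, 32000.0, 64000.0)
    n_subjects_per_group: int = 10
    attenuation_db: float = 15.0
    abr_noise_sd_uv: float = 0.05
    criterion_uv: float = 0.1
    margin_db: float = 5.0
    sl_db: float = 30.0
    latency_frequency_hz: float = 8000.0
    dpoae_replicates: int = 20
    bin_um: float = 100.0
    extent_um: float = 5200.0
    wt_cochlea_length_um: float = 5888.0
    ds_cochlea_length_um: float = 5250.0
    n_wt_cochleae: int = 4
    n_ds_cochleae: int = 6

    def __post_init__(self) -> None:
        if self.n_subjects_per_group < 1 or self.dpoae_replicates < 1:
            raise ValueError("cohort sizes must be positive")
        if not (self.criterion_uv > 0 and self.margin_db >= 0 and self.bin_um > 0):
            raise ValueError("analysis parameters out of range")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("abr_frequencies_hz", "f2_frequencies_hz"):
            if key in raw:
                raw[key] = tuple(float(v) for v in raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["abr_frequencies_hz"] = list(d["abr_frequencies_hz"])
        d["f2_frequencies_hz"] = list(d["f2_frequencies_hz"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))
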