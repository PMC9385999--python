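"""End-to-end synthetic phenotype comparison (control vs conductive-loss group).

``run_pipeline`` chains the generators and analyses into the full comparison:
ABR wave-I thresholds and their frequency-flat shift, equal-absolute-level and
equal-sensation-level latency tables, DPOAE threshold elevations,
cytocochleogram summaries with the cochlear-length contrast, and a
mixed-design ANOVA on the wave-I amplitudes. Everything is deterministic
given the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from otokit import abr, cochleogram, dpoae, stats, synth
from otokit._common import ThresholdResult
from otokit.io import RunConfig

__all__ = [
    "AbrCohortResult",
    "run_pipeline",
    "simulate_abr_cohort",
    "analyze_abr_cohort",
    "dpoae_threshold_elevations",
]

WAVE_RANGE = (1, 2, 3, 4, 5)


@dataclass(frozen=True)
class AbrCohortResult:
    """Per-subject series, I/O functions and thresholds for one genotype."""

    series: Mapping[tuple[str, float], abr.ABRLevelSeries]  # (subject, frequency)
    io_functions: Mapping[tuple[str, float], abr.IOFunction]
    thresholds: Mapping[tuple[str, float], ThresholdResult]

    def mean_threshold(self, frequency_hz: float) -> float:
        vals = [
            t.threshold_db
            for (_, f), t in self.thresholds.items()
            if f == frequency_hz and t.reached
        ]
        if not vals:
            raise ValueError(f"no reached thresholds at {frequency_hz} Hz")
        return float(np.mean(vals))


def simulate_abr_cohort(
    genotype: str,
    frequencies_hz,
    n_subjects: int,
    attenuation_db: float,
    noise_sd_uv: float,
    seed: int,
) -> dict[tuple[str, float], abr.ABRLevelSeries]:
    """Simulated cohort: one level series per subject and frequency."""
    out = {}
    for i in range(n_subjects):
        subject = f"{genotype}{i:02d}"
        for freq in frequencies_hz:
            params = synth.default_abr_params(
                freq,
                attenuation_db=attenuation_db,
                noise_sd_uv=noise_sd_uv,
                seed=(seed * 1009 + i * 17 + (attenuation_db > 0)) % (2**31 - 1),
            )
            out[(subject, float(freq))] = synth.simulate_abr_series(
                params, subject_id=subject, genotype=genotype
            )
    return out


def analyze_abr_cohort(
    series: Mapping[tuple[str, float], abr.ABRLevelSeries],
    criterion_uv: float = abr.DEFAULT_CRITERION_UV,
    window_kind: str = "early",
) -> AbrCohortResult:
    ios = {key: abr.build_io(s, window_kind=window_kind) for key, s in series.items()}
    thresholds = {key: abr.estimate_threshold(io, criterion_uv) for key, io in ios.items()}
    return AbrCohortResult(series=dict(series), io_functions=ios, thresholds=thresholds)


def dpoae_threshold_elevations(
    f2_frequencies_hz,
    attenuation_db: float,
    replicates: int,
    seed: int,
    margin_db: float = dpoae.DEFAULT_MARGIN_DB,
) -> pd.DataFrame:
    """Mean DPOAE threshold per f2 for a control and an attenuated ear.

    Each replicate re-draws the stochastic noise floor; thresholds are averaged
    over replicates before the elevation (attenuated - control) is formed.
    """
    rows = []
    for f2 in f2_frequencies_hz:
        for label, atten in (("control", 0.0), ("attenuated", attenuation_db)):
            for rep in range(replicates):
                params = synth.DPOAESimParams(
                    f2_hz=f2,
                    attenuation_db=atten,
                    seed=(seed * 2003 + rep * 29 + (atten > 0)) % (2**31 - 1),
                )
                io = dpoae.build_dpoae_io(synth.simulate_dpoae_io(params))
                thr = dpoae.dpoae_threshold(io, margin_db=margin_db)
                rows.append(
                    {
                        "f2_hz": f2,
                        "group": label,
                        "replicate": rep,
                        "threshold_db": thr.threshold_db,
                    }
                )
    df = pd.DataFrame(rows)
    if df["threshold_db"].isna().any():
        raise RuntimeError("a DPOAE threshold was not reached in the simulation")
    return df


def _latency_tables(
    wt: AbrCohortResult,
    ds: AbrCohortResult,
    frequency_hz: float,
    sl_db: float,
    compare_level_db: float = 80.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(equal-absolute-level table, equal-sensation-level table), averaged over subjects."""
    abs_rows, sl_rows = [], []
    wt_keys = sorted(k for k in wt.series if k[1] == frequency_hz)
    ds_keys = sorted(k for k in ds.series if k[1] == frequency_hz)
    for (wk, dk) in zip(wt_keys, ds_keys):
        ws, dsr = wt.series[wk], ds.series[dk]
        for label, s in (("reference", ws), ("comparison", dsr)):
            onsets = abr._chained_onsets(s, 1.5)
            _, windows = onsets[compare_level_db]
            lats = abr.peak_latencies(s.at_level(compare_level_db), windows)
            for wave in WAVE_RANGE:
                if wave in lats.latencies_ms:
                    abs_rows.append(
                        {"pair": wk[0] + "/" + dk[0], "group": label, "wave": wave,
                         "latency_ms": lats.latencies_ms[wave]}
                    )
        cmp = abr.equal_sl_latency_compare(
            ws, wt.thresholds[wk], dsr, ds.thresholds[dk], sl_db=sl_db
        )
        t = cmp.table.assign(pair=wk[0] + "/" + dk[0])
        sl_rows.append(t[t["wave"].isin(WAVE_RANGE)])
    abs_df = pd.DataFrame(abs_rows)
    abs_table = (
        abs_df.pivot_table(index="wave", columns="group", values="latency_ms")
        .assign(difference_ms=lambda d: d["comparison"] - d["reference"])
        .reset_index()
    )
    sl_table = (
        pd.concat(sl_rows, ignore_index=True)
        .groupby("wave", as_index=False)[
            ["reference_latency_ms", "comparison_latency_ms", "difference_ms"]
        ]
        .mean()
    )
    return abs_table, sl_table


def _wave1_amplitude_table(wt: AbrCohortResult, ds: AbrCohortResult, frequency_hz: float) -> pd.DataFrame:
    rows = []
    for cohort, genotype in ((wt, "WT"), (ds, "DS")):
        for (subject, f), io in cohort.io_functions.items():
            if f != frequency_hz:
                continue
            for level, amp in io.points:
                rows.append(
                    {"subject": subject, "genotype": genotype, "level": level, "value": amp}
                )
    return pd.DataFrame(rows)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full synthetic comparison and write the report bundle.

    Writes CSV tables plus ``report.json`` into ``cfg.out_dir`` (whose parent
    must exist) and returns the report as a dict. Reruns with the same config
    are byte-identical.
    """
    out = Path(cfg.out_dir)
    if not out.parent.exists():
        raise FileNotFoundError(f"parent of output directory does not exist: {out.parent}")
    out.mkdir(exist_ok=True)

    # --- ABR ---
    wt_series = simulate_abr_cohort(
        "WT", cfg.abr_frequencies_hz, cfg.n_subjects_per_group, 0.0, cfg.abr_noise_sd_uv, cfg.seed
    )
    ds_series = simulate_abr_cohort(
        "DS", cfg.abr_frequencies_hz, cfg.n_subjects_per_group,
        cfg.attenuation_db, cfg.abr_noise_sd_uv, cfg.seed,
    )
    wt = analyze_abr_cohort(wt_series, cfg.criterion_uv)
    ds = analyze_abr_cohort(ds_series, cfg.criterion_uv)
    wt_mean = {f: ThresholdResult(wt.mean_threshold(f), cfg.criterion_uv) for f in cfg.abr_frequencies_hz}
    ds_mean = {f: ThresholdResult(ds.mean_threshold(f), cfg.criterion_uv) for f in cfg.abr_frequencies_hz}
    shift = abr.threshold_shift(wt_mean, ds_mean)

    thr_rows = [
        {"genotype": g, "subject": k[0], "frequency_hz": k[1], "threshold_db": t.threshold_db}
        for g, cohort in (("WT", wt), ("DS", ds))
        for k, t in sorted(cohort.thresholds.items())
    ]
    pd.DataFrame(thr_rows).to_csv(out / "abr_thresholds.csv", index=False)
    io_rows = [
        {"genotype": g, "subject": k[0], "frequency_hz": k[1], "level_db_spl": level,
         "rms_uv": amp, "window": io.window_kind}
        for g, cohort in (("WT", wt), ("DS", ds))
        for k, io in sorted(cohort.io_functions.items())
        for level, amp in io.points
    ]
    pd.DataFrame(io_rows).to_csv(out / "abr_io_functions.csv", index=False)

    abs_table, sl_table = _latency_tables(wt, ds, cfg.latency_frequency_hz, cfg.sl_db)
    abs_table.to_csv(out / "latencies_equal_level.csv", index=False)
    sl_table.to_csv(out / "latencies_equal_sl.csv", index=False)

    # --- DPOAE ---
    dp = dpoae_threshold_elevations(
        cfg.f2_frequencies_hz, cfg.attenuation_db, cfg.dpoae_replicates, cfg.seed, cfg.margin_db
    )
    dp.to_csv(out / "dpoae_thresholds.csv", index=False)
    dp_mean = dp.groupby(["f2_hz", "group"])["threshold_db"].mean().unstack()
    dp_elev = (dp_mean["attenuated"] - dp_mean["control"]).to_dict()

    # --- Cochleograms ---
    grams = []
    for genotype, n, length, ohc_d, ihc_d in (
        ("WT", cfg.n_wt_cochleae, cfg.wt_cochlea_length_um, 38.3, 11.9),
        ("DS", cfg.n_ds_cochleae, cfg.ds_cochlea_length_um, 37.8, 11.7),
    ):
        for i in range(n):
            sim = synth.simulate_cochleogram(
                synth.CochleogramSimParams(
                    length_um=length,
                    ohc_density_per_100um=ohc_d,
                    ihc_density_per_100um=ihc_d,
                    seed=(cfg.seed * 401 + i) % (2**31 - 1),
                ),
                subject_id=f"{genotype}c{i}",
                genotype=genotype,
            )
            grams.append(sim.cochleogram)
    wt_grams = [g for g in grams if g.genotype == "WT"]
    ds_grams = [g for g in grams if g.genotype == "DS"]
    length_cmp = cochleogram.length_difference(
        [g.total_length_um for g in wt_grams], [g.total_length_um for g in ds_grams]
    )
    density_summary = {
        f"{geno.lower()}_{ct}_per_100um": float(
            np.mean([cochleogram.mean_density(g, cfg.extent_um, ct) for g in gs])
        )
        for geno, gs in (("WT", wt_grams), ("DS", ds_grams))
        for ct in ("ohc", "ihc")
    }

    # --- Stats ---
    amp_table = _wave1_amplitude_table(wt, ds, cfg.latency_frequency_hz)
    report_anova = stats.rm_anova(amp_table, between="genotype", within="level")
    report_anova.table.to_csv(out / "wave1_amplitude_anova.csv", index=False)
    report_anova.posthoc.to_csv(out / "wave1_amplitude_posthoc.csv", index=False)

    report = {
        "config": {"seed": cfg.seed, "attenuation_db": cfg.attenuation_db,
                   "criterion_uv": cfg.criterion_uv, "margin_db": cfg.margin_db,
                   "sl_db": cfg.sl_db, "n_subjects_per_group": cfg.n_subjects_per_group},
        "abr": {
            "mean_thresholds_wt": {str(f): wt_mean[f].threshold_db for f in cfg.abr_frequencies_hz},
            "mean_thresholds_ds": {str(f): ds_mean[f].threshold_db for f in cfg.abr_frequencies_hz},
            "threshold_shift_db": {str(f): s for f, s in shift.shifts_db.items()},
            "flatness_db": shift.flatness_db,
        },
        "latencies": {
            "equal_level_mean_delay_ms": float(abs_table["difference_ms"].mean()),
            "equal_sl_max_abs_difference_ms": float(sl_table["difference_ms"].abs().max()),
        },
        "dpoae": {"threshold_elevation_db": {str(f): float(v) for f, v in dp_elev.items()}},
        "cochleogram": {
            "length_difference_um": length_cmp.mean_difference_um,
            **density_summary,
        },
        "stats": {
            "wave1_genotype_F": float(report_anova.effect("between")["F"]),
            "wave1_genotype_p": float(report_anova.effect("between")["p"]),
        },
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
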