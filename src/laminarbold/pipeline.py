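"""End-to-end orchestration: simulate, fit, and recover.

Chains the synthetic generator, preprocessing, GLM, and depth analysis into
reproducible runs driven by a single serialisable configuration and one
master seed.  Every stage is available in-memory (``simulate_session`` /
``fit_session`` / ``recover``) and as a disk-backed run
(``run_simulate`` / ``run_fit`` / ``run_recover`` / ``run_demo``).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import FunctionalSeries, LabelVolume, read_tsv, write_tsv
from .depth import (
    bin_layers,
    compute_cbv_map,
    compute_m_map,
    condition_dpetco2,
    cvr_fit,
    depth_profiles,
    sequence_ratio,
)
from .glm import build_design, fit_glm, holm_select, orthogonalize_confounds
from .physio import CalibParams
from .preprocess import (
    bpm,
    dct_basis,
    masked_gaussian_smooth,
    percent_signal_change,
    rvt,
)
from .synth import (
    GasProtocol,
    GasTraces,
    GroundTruthMaps,
    make_gas_traces,
    make_ground_truth,
    make_motion_params,
    make_physio_traces,
    make_protocol,
    make_slab,
    simulate_bold,
)

log = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig", "PreprocessConfig", "GLMConfig", "PipelineConfig",
    "SessionBundle", "simulate_session", "fit_session", "recover",
    "run_simulate", "run_fit", "run_recover", "run_demo",
]

SEQUENCES = ("GE", "SE")


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    n_subjects: int = 8
    grid: tuple = (40, 40, 22)
    sequences: tuple = SEQUENCES
    levels: tuple = ("+5", "+10")
    tsnr: float | None = 50.0
    drift_amp: float = 0.005
    jitter_sd: float = 0.05
    transition_tau_s: float = 15.0
    gas_noise_sd: float = 0.5
    s0: float = 1000.0

    @property
    def tsnr_value(self) -> float:
        return np.inf if self.tsnr is None else float(self.tsnr)


@dataclass
class PreprocessConfig:
    fwhm_mm: float = 2.35
    highpass_hz: float = 0.003
    smooth: bool = True


@dataclass
class GLMConfig:
    alpha: float = 0.05
    family: str = "omnibus"  # or "per_condition"
    m_method: str = "ratio_mean"  # or "block_mean"


@dataclass
class PipelineConfig:
    params: CalibParams = field(default_factory=CalibParams)
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    glm: GLMConfig = field(default_factory=GLMConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        d = {
            "params": self.params.to_dict(),
            "sim": dataclasses.asdict(self.sim),
            "preprocess": dataclasses.asdict(self.preprocess),
            "glm": dataclasses.asdict(self.glm),
            "seed": self.seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        sim = dict(d.get("sim", {}))
        for key in ("grid", "sequences", "levels"):
            if key in sim:
                sim[key] = tuple(sim[key])
        return cls(
            params=CalibParams.from_dict(d.get("params", {})),
            sim=SimulationConfig(**sim),
            preprocess=PreprocessConfig(**d.get("preprocess", {})),
            glm=GLMConfig(**d.get("glm", {})),
            seed=int(d.get("seed", 0)),
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), *[int(k) for k in key]])


# --------------------------------------------------------------------------
# Simulation
# --------------------------------------------------------------------------

@dataclass
class SessionBundle:
    """Everything one simulated scanning session produces."""

    subject: int
    sequence: str
    protocol: GasProtocol
    labels: LabelVolume
    truth: GroundTruthMaps
    traces: GasTraces
    series: FunctionalSeries
    physio: pd.DataFrame
    physio_rate_hz: float
    motion: pd.DataFrame


def simulate_session(config: PipelineConfig, subject: int, sequence: str,
                     labels: LabelVolume | None = None) -> SessionBundle:
    """Simulate one subject/sequence session from the configured conditions."""
    sim = config.sim
    seq_idx = SEQUENCES.index(sequence)
    labels = labels if labels is not None else make_slab(sim.grid)
    protocol = make_protocol(sim.levels)
    truth = make_ground_truth(
        labels, sequence=sequence, params=config.params,
        seed=_rng(config.seed, subject, seq_idx, 0),
        jitter_sd=sim.jitter_sd, s0=sim.s0,
    )
    traces = make_gas_traces(
        protocol, transition_tau_s=sim.transition_tau_s,
        noise_sd=sim.gas_noise_sd, seed=_rng(config.seed, subject, seq_idx, 1),
    )
    series = simulate_bold(
        truth, traces, protocol, params=config.params,
        tsnr=sim.tsnr_value, drift_amp=sim.drift_amp,
        seed=_rng(config.seed, subject, seq_idx, 2),
    )
    physio_rate = 50.0
    physio = make_physio_traces(
        protocol, seed=_rng(config.seed, subject, seq_idx, 3), sample_rate_hz=physio_rate
    )
    motion = make_motion_params(protocol, seed=_rng(config.seed, subject, seq_idx, 4))
    return SessionBundle(
        subject=subject, sequence=sequence, protocol=protocol, labels=labels,
        truth=truth, traces=traces, series=series, physio=physio,
        physio_rate_hz=physio_rate, motion=motion,
    )


def truth_bin_summary(truth: GroundTruthMaps, labels: LabelVolume) -> pd.DataFrame:
    """Ground-truth depth-bin means for the analysed voxels (bins 1-3, in ROI)."""
    bins = bin_layers(labels.depth)
    mask = (bins > 0) & (labels.roi > 0)
    rows = []
    for b in (1, 2, 3):
        sel = mask & (bins == b)
        row = {
            "depth_bin": b,
            "m_pct": float(100.0 * truth.m_true[sel].mean()),
            "cvr": float(truth.cvr_true[sel].mean()),
            "n_voxels": int(sel.sum()),
        }
        for level, cbv in truth.cbv_ratio_true.items():
            row[f"dcbv{level}_pct"] = float(100.0 * (cbv[sel] - 1.0).mean())
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Fitting
# --------------------------------------------------------------------------

def _nuisance_table(bundle: SessionBundle) -> pd.DataFrame:
    """Six motion parameters plus RVT and BPM on the volume grid."""
    t_vol = bundle.protocol.volume_times
    nuis = bundle.motion.copy()
    nuis["rvt"] = rvt(bundle.physio["respiration"].to_numpy(), bundle.physio_rate_hz, t_vol)
    nuis["bpm"] = bpm(bundle.physio["pulse"].to_numpy(), bundle.physio_rate_hz, t_vol)
    return nuis


def fit_session(bundle: SessionBundle, config: PipelineConfig):
    """Preprocess, fit the GLM, select voxels, and map CVR / M / ΔCBV.

    Returns ``(voxel_table, qc)``: one row per Holm-selected in-mask voxel
    with its depth bin, ROI, and metric estimates; and a QC dictionary
    counting excluded voxels.
    """
    protocol, labels = bundle.protocol, bundle.labels
    pre = config.preprocess
    hc_levels = [lb[2:] for lb in protocol.condition_labels if lb.startswith("hc")]
    if len(hc_levels) < 2:
        raise ValueError("CVR needs at least two hypercapnia conditions in the session")
    if not any(lb.startswith("ho") for lb in protocol.condition_labels):
        raise ValueError(
            "protocol lacks a hyperoxia block: M-value calibration (and the "
            "ΔCBV inversion that depends on it) cannot be estimated"
        )

    series = bundle.series
    if pre.smooth and pre.fwhm_mm > 0:
        series = masked_gaussian_smooth(series, labels, fwhm_mm=pre.fwhm_mm)
    psc, valid = percent_signal_change(np.asarray(series.data, float), return_valid=True)

    bins = bin_layers(labels.depth)
    mask = (bins > 0) & (labels.roi > 0) & valid
    n_mask = int(mask.sum())
    y = psc[mask].T  # (T, V)

    # Condition plateaus are estimated as raw block contrasts: nuisance and
    # DCT drift columns enter orthogonalised against the task block
    # (intercept + binary condition indicators), so they only reduce
    # residual variance and cannot shrink the one-off gas-block betas whose
    # low-frequency content they would otherwise absorb.
    design = build_design(protocol, None)
    task = design.matrix
    nuis = _nuisance_table(bundle).to_numpy(float)
    basis = dct_basis(protocol.n_volumes, protocol.tr, pre.highpass_hz)
    confounds = orthogonalize_confounds(np.hstack([nuis, basis]), task)
    design = design.with_confounds(
        confounds, [f"conf{k + 1:02d}" for k in range(confounds.shape[1])]
    )
    result = fit_glm(y, design)

    if config.glm.family == "omnibus":
        selected = holm_select(result.f_p, config.glm.alpha)
    elif config.glm.family == "per_condition":
        p_cond = np.column_stack([result.pvalue(c) for c in result.condition_names])
        flat = holm_select(p_cond.ravel(), config.glm.alpha).reshape(p_cond.shape)
        selected = flat.any(axis=1)
    else:
        raise ValueError(f"unknown selection family {config.glm.family!r}")

    # condition betas referenced to the fitted baseline level, in percent
    intercept = result.coef("intercept")
    scale = 100.0 / (100.0 + intercept)
    dbold = {c: result.coef(c) * scale for c in result.condition_names}

    ho_label = next(lb for lb in protocol.condition_labels if lb.startswith("ho"))
    dpet = condition_dpetco2(bundle.traces, protocol, hc_levels)
    dbold_hc = np.column_stack([dbold[f"hc{lv}"] for lv in hc_levels])
    cvr = cvr_fit(dpet, dbold_hc)
    m_pct = compute_m_map(
        dbold[ho_label], bundle.traces, protocol,
        params=config.params, method=config.glm.m_method,
    )
    dcbv, qc_cbv = compute_cbv_map(dbold_hc, m_pct, hc_levels, params=config.params)

    table = pd.DataFrame({
        "subject": bundle.subject,
        "sequence": bundle.sequence,
        "depth_bin": bins[mask],
        "roi": labels.roi[mask],
        "selected": selected,
        "cvr": cvr,
        "m_pct": m_pct,
    })
    for j, lv in enumerate(hc_levels):
        table[f"dbold_hc{lv}_pct"] = dbold_hc[:, j]
        table[f"dcbv{lv}_pct"] = dcbv[:, j]
    table[f"dbold_ho_pct"] = dbold[ho_label]
    qc = {
        "n_in_mask": n_mask,
        "n_selected": int(selected.sum()),
        "n_invalid_psc": int((~valid & (bins > 0) & (labels.roi > 0)).sum()),
        "dpetco2_measured_mmHg": {lv: float(d) for lv, d in zip(hc_levels, dpet)},
        **qc_cbv,
    }
    return table[table["selected"]].drop(columns="selected").reset_index(drop=True), qc


def group_profiles(tables, metrics=None) -> dict:
    """Depth profiles per sequence from concatenated per-voxel tables."""
    table = pd.concat(tables, ignore_index=True)
    out = {}
    for seq in table["sequence"].unique():
        out[seq] = depth_profiles(table[table["sequence"] == seq], metrics=metrics)
    return out


# --------------------------------------------------------------------------
# Recovery scoring
# --------------------------------------------------------------------------

def recover(profiles: dict, truth_summaries: dict, tolerance_rel: float = 0.10) -> dict:
    """Compare estimated group depth profiles against ground-truth bin means.

    ``truth_summaries[seq]`` is a list of per-subject
    :func:`truth_bin_summary` frames.  Returns a JSON-serialisable report
    with per-sequence, per-metric, per-bin relative errors and pass flags.
    """
    report = {"tolerance_rel": tolerance_rel, "sequences": {}}
    worst = 0.0
    for seq, profile in profiles.items():
        truth_group = (
            pd.concat(truth_summaries[seq])
            .groupby("depth_bin").mean().reset_index()
        )
        entries = []
        for _, row in profile.iterrows():
            metric = row["metric"]
            if metric not in truth_group.columns:
                continue
            tr_val = float(
                truth_group.loc[truth_group["depth_bin"] == row["depth_bin"], metric].iloc[0]
            )
            est = float(row["mean"])
            rel = abs(est - tr_val) / abs(tr_val) if tr_val != 0 else np.nan
            worst = max(worst, rel)
            entries.append({
                "metric": metric, "depth_bin": int(row["depth_bin"]),
                "truth": tr_val, "estimate": est,
                "rel_error": rel, "pass": bool(rel <= tolerance_rel),
            })
        report["sequences"][seq] = entries
    report["max_rel_error"] = worst
    report["pass"] = all(
        e["pass"] for entries in report["sequences"].values() for e in entries
    )
    return report


# --------------------------------------------------------------------------
# Disk-backed runs
# --------------------------------------------------------------------------

def _session_dir(root, subject: int, sequence: str) -> Path:
    return Path(root) / f"sub-{subject + 1:02d}" / sequence


def run_simulate(config: PipelineConfig, outdir) -> Path:
    """Write the full synthetic input bundle (NIfTI + TSV + truth JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    labels = make_slab(config.sim.grid)
    labels.save(outdir / "labels")
    protocol = make_protocol(config.sim.levels)
    (outdir / "protocol.json").write_text(json.dumps(protocol.to_dict(), indent=2))
    _write_run_record(config, outdir / "run_record.json", stage="simulate")
    for subject in range(config.sim.n_subjects):
        for sequence in config.sim.sequences:
            bundle = simulate_session(config, subject, sequence, labels=labels)
            sdir = _session_dir(outdir, subject, sequence)
            sdir.mkdir(parents=True, exist_ok=True)
            bundle.series.save(sdir / "bold.nii.gz")
            write_tsv(bundle.traces.to_dataframe(), sdir / "gas.tsv", sidecar={
                "sampling": "per-volume (mid-acquisition)", "tr_s": protocol.tr,
                "units": {"petco2_mmHg": "mmHg", "peto2_mmHg": "mmHg"},
            })
            write_tsv(bundle.physio, sdir / "physio.tsv", sidecar={
                "sampling_rate_hz": bundle.physio_rate_hz,
                "columns": {"respiration": "a.u.", "pulse": "a.u."},
            })
            write_tsv(bundle.motion, sdir / "motion.tsv", sidecar={
                "sampling": "per-volume",
                "units": {"trans_*": "mm", "rot_*": "deg"},
            })
            summary = truth_bin_summary(bundle.truth, labels)
            (sdir / "truth_summary.json").write_text(json.dumps({
                "subject": subject, "sequence": sequence,
                "bin_means": summary.to_dict(orient="records"),
            }, indent=2, sort_keys=True))
    return outdir


def _load_session(indir, subject: int, sequence: str, labels, protocol) -> SessionBundle:
    sdir = _session_dir(indir, subject, sequence)
    missing = [p.name for p in (
        sdir / "bold.nii.gz", sdir / "gas.tsv", sdir / "physio.tsv", sdir / "motion.tsv",
    ) if not p.exists()]
    if missing:
        raise FileNotFoundError(f"incomplete input bundle {sdir}: missing {missing}")
    physio_meta = json.loads((sdir / "physio.json").read_text())
    return SessionBundle(
        subject=subject, sequence=sequence, protocol=protocol, labels=labels,
        truth=None, traces=GasTraces.from_dataframe(read_tsv(sdir / "gas.tsv")),
        series=FunctionalSeries.load(sdir / "bold.nii.gz"),
        physio=read_tsv(sdir / "physio.tsv"),
        physio_rate_hz=float(physio_meta["sampling_rate_hz"]),
        motion=read_tsv(sdir / "motion.tsv"),
    )


def run_fit(config: PipelineConfig, indir, outdir) -> Path:
    """Fit every session in an input bundle; write maps, profiles, QC, log."""
    indir, outdir = Path(indir), Path(outdir)
    labels = LabelVolume.load(indir / "labels")
    protocol = GasProtocol.from_dict(json.loads((indir / "protocol.json").read_text()))
    outdir.mkdir(parents=True, exist_ok=True)
    _write_run_record(config, outdir / "run_record.json", stage="fit")
    tables, qc_all = [], {}
    for subject in range(config.sim.n_subjects):
        for sequence in config.sim.sequences:
            bundle = _load_session(indir, subject, sequence, labels, protocol)
            table, qc = fit_session(bundle, config)
            tables.append(table)
            qc_all[f"sub-{subject + 1:02d}/{sequence}"] = qc
            sdir = _session_dir(outdir, subject, sequence)
            sdir.mkdir(parents=True, exist_ok=True)
            write_tsv(table, sdir / "voxels.tsv")
    profiles = group_profiles(tables)
    for seq, profile in profiles.items():
        write_tsv(profile, outdir / f"profiles_{seq}.tsv")
    if {"GE", "SE"} <= set(profiles):
        write_tsv(sequence_ratio(profiles["GE"], profiles["SE"]), outdir / "ratios_GE_SE.tsv")
    (outdir / "qc.json").write_text(json.dumps(qc_all, indent=2, sort_keys=True))
    return outdir


def run_recover(config: PipelineConfig, simdir, fitdir, out_path=None,
                tolerance_rel: float = 0.10) -> dict:
    """Score fitted group profiles against the stored ground-truth summaries."""
    simdir, fitdir = Path(simdir), Path(fitdir)
    profiles, truth_summaries = {}, {}
    for sequence in config.sim.sequences:
        path = fitdir / f"profiles_{sequence}.tsv"
        if not path.exists():
            raise FileNotFoundError(f"no fitted profiles at {path}")
        profiles[sequence] = read_tsv(path)
        summaries = []
        for subject in range(config.sim.n_subjects):
            sfile = _session_dir(simdir, subject, sequence) / "truth_summary.json"
            meta = json.loads(sfile.read_text())
            summaries.append(pd.DataFrame(meta["bin_means"]))
        truth_summaries[sequence] = summaries
    report = recover(profiles, truth_summaries, tolerance_rel=tolerance_rel)
    if out_path is not None:
        Path(out_path).write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def run_demo(config: PipelineConfig, outdir) -> dict:
    """Chain simulate -> fit -> recover under one master seed."""
    outdir = Path(outdir)
    simdir = run_simulate(config, outdir / "sim")
    fitdir = run_fit(config, simdir, outdir / "fit")
    return run_recover(config, simdir, fitdir, outdir / "recovery.json")


def _write_run_record(config: PipelineConfig, path: Path, stage: str) -> None:
    """Run header: resolved configuration and every model-parameter assumption.

    The physiological constants are recorded explicitly because all derived
    M/ΔCBV estimates depend on them.
    """
    record = {
        "stage": stage,
        "laminarbold_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "model_assumptions": config.params.to_dict(),
    }
    path.write_text(json.dumps(record, indent=2, sort_keys=True))
    log.info("run record written to %s (alpha=%g, beta=%g, oef0=%g)",
             path, config.params.alpha, config.params.beta, config.params.oef0)
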