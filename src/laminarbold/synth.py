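"""Synthetic laminar gas-challenge fMRI with known per-voxel ground truth.

Generates the full input bundle of a calibrated-BOLD session — breathing
protocol, end-tidal gas traces, respiration/pulse/motion nuisance traces,
a layered cortical slab, and GE-like / SE-like 4D BOLD series — from
per-voxel ground-truth maps pushed through the forward physiological model,
so that every downstream stage can be validated by parameter recovery.

The default protocol follows the 697 s gas paradigm (200 s baseline,
120 s hypercapnia blocks at +5 and +10 mmHg PetCO2 back to back, a return
to baseline, and a 120 s hyperoxia block at +350 mmHg PetO2) sampled at
TR = 0.85 s for 820 volumes.  Ground-truth depth profiles default to the
reported group values for all-venous (GE) and micro-vascular (SE) contrast:
M rising from 9 % (deep bin) to 21 % / 16 % (superficial, GE/SE), CVR from
0.39 to 0.64 (GE) and 0.18 to 0.25 (SE) %BOLD/mmHg, and a depth-constant
CBV increase of 12.5 % (GE) / 8.5 % (SE) at +10 mmHg.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import FunctionalSeries, LabelVolume
from .physio import (
    HC_LEVELS,
    CalibParams,
    forward_bold_hypercapnia,
    hyperoxia_dhb_ratio,
    invert_cbv,
)

log = logging.getLogger(__name__)

__all__ = [
    "Block",
    "GasProtocol",
    "GasTraces",
    "GroundTruthMaps",
    "TRUTH_ANCHORS",
    "make_protocol",
    "make_gas_traces",
    "make_slab",
    "depth_fraction",
    "make_ground_truth",
    "simulate_bold",
    "make_physio_traces",
    "make_motion_params",
]


# --------------------------------------------------------------------------
# Protocol
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Block:
    """One protocol block: a label, a duration, and gas targets above baseline."""

    label: str
    duration_s: float
    dpetco2: float = 0.0
    dpeto2: float = 0.0

    @property
    def is_condition(self) -> bool:
        return self.dpetco2 != 0.0 or self.dpeto2 != 0.0


@dataclass(frozen=True)
class GasProtocol:
    """Ordered block design plus gas baselines and the sampling TR."""

    blocks: tuple
    baseline_petco2: float = 40.0
    baseline_peto2: float = 100.0
    tr: float = 0.85

    @property
    def total_duration_s(self) -> float:
        return float(sum(b.duration_s for b in self.blocks))

    @property
    def n_volumes(self) -> int:
        return int(round(self.total_duration_s / self.tr))

    @property
    def volume_times(self) -> np.ndarray:
        """Mid-acquisition timestamps of each volume."""
        return (np.arange(self.n_volumes) + 0.5) * self.tr

    @property
    def condition_labels(self) -> list:
        return [b.label for b in self.blocks if b.is_condition]

    def block_interval(self, label: str) -> tuple:
        t = 0.0
        for b in self.blocks:
            if b.label == label:
                return (t, t + b.duration_s)
            t += b.duration_s
        raise KeyError(f"no block labelled {label!r}")

    def volumes_in(self, label: str) -> np.ndarray:
        """Boolean mask of volumes acquired during the named block."""
        start, end = self.block_interval(label)
        t = self.volume_times
        return (t >= start) & (t < end)

    def block_targets(self) -> pd.DataFrame:
        """Per-volume PetCO2/PetO2 target values (step function)."""
        t = self.volume_times
        co2 = np.full_like(t, self.baseline_petco2)
        o2 = np.full_like(t, self.baseline_peto2)
        start = 0.0
        for b in self.blocks:
            sel = (t >= start) & (t < start + b.duration_s)
            co2[sel] += b.dpetco2
            o2[sel] += b.dpeto2
            start += b.duration_s
        return pd.DataFrame({"time_s": t, "petco2_mmHg": co2, "peto2_mmHg": o2})

    def to_dict(self) -> dict:
        return {
            "blocks": [
                {"label": b.label, "duration_s": b.duration_s,
                 "dpetco2": b.dpetco2, "dpeto2": b.dpeto2}
                for b in self.blocks
            ],
            "baseline_petco2": self.baseline_petco2,
            "baseline_peto2": self.baseline_peto2,
            "tr": self.tr,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GasProtocol":
        return cls(
            blocks=tuple(Block(**b) for b in d["blocks"]),
            baseline_petco2=d.get("baseline_petco2", 40.0),
            baseline_peto2=d.get("baseline_peto2", 100.0),
            tr=d.get("tr", 0.85),
        )


def make_protocol(
    levels: Sequence[str] = ("+5", "+10"),
    *,
    baseline_s: float = 200.0,
    block_s: float = 120.0,
    recovery_s: float = 137.0,
    hyperoxia_dpeto2: float = 350.0,
    tr: float = 0.85,
    baseline_petco2: float = 40.0,
    baseline_peto2: float = 100.0,
) -> GasProtocol:
    """Build the gas-challenge block design.

    The default session is a 200 s baseline, back-to-back 120 s hypercapnia
    blocks at +5 and +10 mmHg PetCO2, a 137 s return to baseline so CO2
    clears before the O2 challenge, and a final 120 s hyperoxia block at
    +350 mmHg PetO2 — 697 s and 820 volumes at TR = 0.85 s.  The
    alternative session swaps in +3/+8 mmHg hypercapnia levels with
    identical timing.
    """
    for level in levels:
        if level not in HC_LEVELS:
            raise ValueError(f"unknown hypercapnia level {level!r}; expected one of {HC_LEVELS}")
    blocks = [Block("baseline", baseline_s)]
    for level in levels:
        blocks.append(Block(f"hc{level}", block_s, dpetco2=float(level)))
    blocks.append(Block("recovery", recovery_s))
    blocks.append(Block(f"ho+{hyperoxia_dpeto2:g}", block_s, dpeto2=hyperoxia_dpeto2))
    return GasProtocol(
        blocks=tuple(blocks),
        baseline_petco2=baseline_petco2,
        baseline_peto2=baseline_peto2,
        tr=tr,
    )


# --------------------------------------------------------------------------
# Gas traces
# --------------------------------------------------------------------------

@dataclass
class GasTraces:
    """Per-volume end-tidal gas time courses in mmHg."""

    time_s: np.ndarray
    petco2: np.ndarray
    peto2: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.time_s, "petco2_mmHg": self.petco2, "peto2_mmHg": self.peto2}
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "GasTraces":
        return cls(
            time_s=df["time_s"].to_numpy(float),
            petco2=df["petco2_mmHg"].to_numpy(float),
            peto2=df["peto2_mmHg"].to_numpy(float),
        )

    def block_mean(self, protocol: GasProtocol, label: str, gas: str = "petco2") -> float:
        sel = protocol.volumes_in(label)
        trace = self.petco2 if gas == "petco2" else self.peto2
        return float(trace[sel].mean())


def _exponential_approach(targets: np.ndarray, tau: float, dt: float) -> np.ndarray:
    """First-order relaxation of a stepped target sequence (tau = 0: exact steps)."""
    if tau == 0:
        return targets.copy()
    decay = np.exp(-dt / tau)
    out = np.empty_like(targets)
    out[0] = targets[0]
    for i in range(1, len(targets)):
        out[i] = targets[i] + (out[i - 1] - targets[i]) * decay
    return out


def make_gas_traces(
    protocol: GasProtocol,
    transition_tau_s: float = 15.0,
    noise_sd: float = 0.5,
    seed=None,
) -> GasTraces:
    """Continuous PetCO2/PetO2 traces from the block targets.

    Plateau transitions follow a first-order exponential with time constant
    ``transition_tau_s`` (a smooth ramp, as produced by sequential gas
    delivery); breath-to-breath variability is additive Gaussian noise.
    """
    if transition_tau_s < 0:
        raise ValueError("transition_tau_s must be >= 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    targets = protocol.block_targets()
    co2 = _exponential_approach(targets["petco2_mmHg"].to_numpy(), transition_tau_s, protocol.tr)
    o2 = _exponential_approach(targets["peto2_mmHg"].to_numpy(), transition_tau_s, protocol.tr)
    if noise_sd > 0:
        co2 = co2 + rng.normal(0.0, noise_sd, co2.shape)
        o2 = o2 + rng.normal(0.0, noise_sd, o2.shape)
    return GasTraces(time_s=targets["time_s"].to_numpy(), petco2=co2, peto2=o2)


# --------------------------------------------------------------------------
# Cortical slab labels
# --------------------------------------------------------------------------

def make_slab(
    shape: Sequence[int] = (40, 40, 22),
    depth_axis: int = 2,
    n_rois: int = 3,
    voxel_size_mm: tuple = (1.0, 1.0, 1.0),
) -> LabelVolume:
    """Rectangular cortical slab with 20 depth layers, ROI stripes, and veins.

    Depth layer 1 (white-matter face) to 20 (pial face) run along
    ``depth_axis``; the first and last slices are outside the cortex.  ROIs
    are contiguous stripes along the first non-depth axis and partition the
    in-cortex voxels.  Vein flags are concentrated at the superficial face
    (a deterministic sparse pattern in layers 19-20).
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3:
        raise ValueError("shape must be 3D")
    if shape[depth_axis] < 22:
        raise ValueError(
            f"depth extent {shape[depth_axis]} too small: need >= 22 slices "
            "(20 cortical layers plus one out-of-cortex slice on each face)"
        )
    depth = np.zeros(shape, dtype=int)
    idx = np.arange(shape[depth_axis])
    layer = np.where((idx >= 1) & (idx <= 20), idx, 0)
    expand = [1, 1, 1]
    expand[depth_axis] = shape[depth_axis]
    depth += layer.reshape(expand)

    stripe_axis = 0 if depth_axis != 0 else 1
    roi = np.zeros(shape, dtype=int)
    bounds = np.linspace(0, shape[stripe_axis], n_rois + 1).astype(int)
    coords = np.arange(shape[stripe_axis])
    stripe = np.zeros(shape[stripe_axis], dtype=int)
    for r in range(n_rois):
        stripe[(coords >= bounds[r]) & (coords < bounds[r + 1])] = r + 1
    expand = [1, 1, 1]
    expand[stripe_axis] = shape[stripe_axis]
    roi += stripe.reshape(expand)
    roi[depth == 0] = 0

    ii, jj, kk = np.indices(shape)
    plane = [a for ax, a in enumerate((ii, jj, kk)) if ax != depth_axis]
    vein = ((depth == 20) & ((plane[0] + 2 * plane[1]) % 3 == 0)) | (
        (depth == 19) & ((plane[0] + 2 * plane[1]) % 7 == 0)
    )
    return LabelVolume(depth=depth, roi=roi, vein=vein,
                       voxel_size_mm=voxel_size_mm, depth_axis=depth_axis)


def depth_fraction(depth: np.ndarray) -> np.ndarray:
    """Normalised cortical depth: layer 2 -> 0 (deep), layer 19 -> 1 (superficial).

    Layers 1 and 20 extrapolate linearly; voxels outside cortex give NaN.
    """
    depth = np.asarray(depth, float)
    frac = (depth - 2.0) / 17.0
    return np.where(depth >= 1, frac, np.nan)


# --------------------------------------------------------------------------
# Ground truth
# --------------------------------------------------------------------------

#: Reported group depth-profile anchors per sequence: (deep bin, superficial bin).
TRUTH_ANCHORS = {
    "GE": {"m_pct": (9.0, 21.0), "cvr": (0.39, 0.64), "dcbv10_pct": 12.5},
    "SE": {"m_pct": (9.0, 16.0), "cvr": (0.18, 0.25), "dcbv10_pct": 8.5},
}

# Mean depth fraction of the deep (layers 2-7) and superficial (14-19) bins.
_D_DEEP = np.mean((np.arange(2, 8) - 2) / 17)
_D_SUP = np.mean((np.arange(14, 20) - 2) / 17)


def _bin_anchored_line(d: np.ndarray, deep_value: float, sup_value: float) -> np.ndarray:
    """Depth-linear profile whose deep/superficial *bin means* hit the anchors."""
    slope = (sup_value - deep_value) / (_D_SUP - _D_DEEP)
    return deep_value + (d - _D_DEEP) * slope


@dataclass
class GroundTruthMaps:
    """Per-voxel generative truth for one sequence (GE-like or SE-like).

    ``m_true`` is a fraction; ``cvr_true`` is %BOLD/mmHg against targeted
    ΔPetCO2; ``cbv_ratio_true`` holds the venous CBV ratio per hypercapnia
    level, mutually consistent with ``m_true`` and ``cvr_true`` through the
    forward model.  Outside the cortex m = 0, cvr = 0 and all ratios are 1.
    """

    sequence: str
    m_true: np.ndarray
    cvr_true: np.ndarray
    cbv_ratio_true: dict
    s0: np.ndarray
    drift_phase: np.ndarray
    params: CalibParams = field(default_factory=CalibParams)

    @property
    def grid_shape(self) -> tuple:
        return self.m_true.shape

    def dbold_fraction(self, level: str) -> np.ndarray:
        """Forward-model plateau BOLD change (fraction) for one hypercapnia level."""
        return forward_bold_hypercapnia(
            self.cbv_ratio_true[level], self.params.cmro2_ratio(level),
            self.m_true, self.params,
        )


def make_ground_truth(
    labels: LabelVolume,
    sequence: str = "GE",
    params: CalibParams | None = None,
    seed=None,
    jitter_sd: float = 0.05,
    anchors: Mapping | None = None,
    s0: float = 1000.0,
) -> GroundTruthMaps:
    """Per-voxel ground truth from depth-linear group profiles plus jitter.

    Truth is built so the three headline metrics are mutually consistent:
    the M profile and the +10 mmHg CBV ratio fix the +10 plateau BOLD
    change; the CVR profile places the remaining hypercapnia plateaus on a
    straight %ΔBOLD-vs-ΔPetCO2 line; inverting the forward model then yields
    ``cbv_ratio_true`` for every level.  Lognormal voxel jitter (sd
    ``jitter_sd`` in log space) acts on M, CVR and the CBV increase
    independently; CVR is clipped to keep every plateau positive so that
    all CBV ratios stay above 1.
    """
    params = params or CalibParams()
    if sequence not in TRUTH_ANCHORS:
        raise ValueError(f"sequence must be one of {sorted(TRUTH_ANCHORS)}, got {sequence!r}")
    anchors = dict(TRUTH_ANCHORS[sequence], **(anchors or {}))
    rng = np.random.default_rng(seed)
    shape = labels.grid_shape
    cortex = labels.cortex_mask
    d = depth_fraction(labels.depth)

    def jitter():
        if jitter_sd == 0:
            return np.ones(shape)
        return np.exp(rng.normal(0.0, jitter_sd, shape))

    m_deep, m_sup = (a / 100.0 for a in anchors["m_pct"])
    cvr_deep, cvr_sup = anchors["cvr"]
    cbv10 = 1.0 + anchors["dcbv10_pct"] / 100.0

    m_true = np.where(cortex, _bin_anchored_line(d, m_deep, m_sup), 0.0) * jitter()
    cbv10_v = 1.0 + np.where(cortex, cbv10 - 1.0, 0.0) * jitter()
    cvr_v = np.where(cortex, _bin_anchored_line(d, cvr_deep, cvr_sup), 0.0) * jitter()
    m_true[~cortex] = 0.0
    cvr_v[~cortex] = 0.0

    ratio10 = params.cmro2_ratio("+10")
    y10_pct = 100.0 * forward_bold_hypercapnia(cbv10_v, ratio10, m_true, params)
    # Every level's plateau must clear the metabolic floor m*(1 - CMRO2
    # ratio): below it the inverted CBV ratio would drop under 1 (CMRO2
    # suppression alone raises BOLD at constant volume).  Clip the CVR so
    # the jittered truth stays physiologically consistent at all levels.
    for level in HC_LEVELS:
        gap = 10.0 - float(level)
        if gap <= 0:
            continue
        floor_pct = 1.2 * (1.0 - params.cmro2_ratio(level)) * 100.0 * m_true
        np.minimum(cvr_v, (y10_pct - floor_pct) / gap, out=cvr_v, where=cortex)

    cbv_ratio_true = {}
    for level in HC_LEVELS:
        y_pct = y10_pct - cvr_v * (10.0 - float(level))
        cbv = np.ones(shape)
        cbv[cortex] = invert_cbv(
            y_pct[cortex] / 100.0, m_true[cortex], params.cmro2_ratio(level), params
        )
        cbv_ratio_true[level] = cbv

    return GroundTruthMaps(
        sequence=sequence,
        m_true=m_true,
        cvr_true=cvr_v,
        cbv_ratio_true=cbv_ratio_true,
        s0=np.full(shape, float(s0)),
        drift_phase=rng.uniform(0.0, 2.0 * np.pi, shape),
        params=params,
    )


# --------------------------------------------------------------------------
# BOLD simulation
# --------------------------------------------------------------------------

def simulate_bold(
    truth: GroundTruthMaps,
    traces: GasTraces,
    protocol: GasProtocol,
    params: CalibParams | None = None,
    tsnr: float = 50.0,
    drift_amp: float = 0.005,
    seed=None,
) -> FunctionalSeries:
    """Forward-simulate a 4D BOLD series from ground truth and gas traces.

    ``s(t) = s0 * (1 + f_hc(t) + f_ho(t)) + drift(t) + noise(t)`` where

    * ``f_hc`` is the Davis+Grubb plateau response, switched on as a binary
      block at each hypercapnia level's true CBV ratio and CMRO2 scaling,
    * ``f_ho = m_true * (1 - [dHb]_v/[dHb]_v0(t))`` is driven sample-by-
      sample by the PetO2 trace,
    * drift is a slow cosine (one cycle per session, random voxel phase) of
      fractional amplitude ``drift_amp``,
    * noise is white Gaussian with sd ``s0 / tsnr`` (``tsnr = inf``: none).
    """
    params = params or truth.params
    if not tsnr > 0:
        raise ValueError("tsnr must be positive (use np.inf for noiseless)")
    if len(traces.time_s) != protocol.n_volumes:
        raise ValueError("gas traces and protocol disagree on sample count")
    rng = np.random.default_rng(seed)
    shape = truth.grid_shape
    n = protocol.n_volumes
    nvox = int(np.prod(shape))

    f = np.zeros((nvox, n))
    for label in protocol.condition_labels:
        if not label.startswith("hc"):
            continue
        level = label[2:]
        plateau = truth.dbold_fraction(level).reshape(nvox)
        f[:, protocol.volumes_in(label)] += plateau[:, None]

    dhb_t = hyperoxia_dhb_ratio(
        protocol.baseline_peto2, np.clip(traces.peto2, 1.0, None), params
    )
    f += truth.m_true.reshape(nvox, 1) * (1.0 - dhb_t[None, :] ** params.beta)

    s0 = truth.s0.reshape(nvox, 1)
    t = protocol.volume_times
    drift = drift_amp * s0 * np.cos(
        2.0 * np.pi * t[None, :] / protocol.total_duration_s
        + truth.drift_phase.reshape(nvox, 1)
    ) if drift_amp else 0.0
    signal = s0 * (1.0 + f) + drift
    if np.isfinite(tsnr):
        signal = signal + rng.normal(0.0, 1.0, (nvox, n)) * (s0 / tsnr)
    return FunctionalSeries(
        data=signal.reshape(*shape, n).astype(np.float32),
        tr=protocol.tr,
        voxel_size_mm=(1.0, 1.0, 1.0),
    )


# --------------------------------------------------------------------------
# Nuisance traces
# --------------------------------------------------------------------------

def make_physio_traces(
    protocol: GasProtocol,
    seed=None,
    sample_rate_hz: float = 50.0,
    resp_freq_hz: float = 0.28,
    pulse_freq_hz: float = 1.1,
) -> pd.DataFrame:
    """Respiration-belt and pulse-unit traces with slow rate/amplitude drift.

    Quasi-periodic signals whose instantaneous frequency and amplitude wander
    slowly, so that peak-based RVT/BPM extraction sees realistic variation.
    """
    rng = np.random.default_rng(seed)
    n = int(round(protocol.total_duration_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz

    def wander(scale):
        phases = rng.uniform(0, 2 * np.pi, 3)
        periods = np.array([90.0, 150.0, 250.0])
        w = sum(np.sin(2 * np.pi * t / p + ph) for p, ph in zip(periods, phases))
        return 1.0 + scale * w / 3.0

    resp_phase = 2 * np.pi * np.cumsum(resp_freq_hz * wander(0.10)) / sample_rate_hz
    respiration = wander(0.15) * np.sin(resp_phase)
    pulse_phase = 2 * np.pi * np.cumsum(pulse_freq_hz * wander(0.05)) / sample_rate_hz
    # sharpened waveform: systolic upstroke narrower than diastole
    pulse = wander(0.10) * (0.2 + np.sin(pulse_phase)) ** 3 / 1.728
    return pd.DataFrame({"time_s": t, "respiration": respiration, "pulse": pulse})


def make_motion_params(protocol: GasProtocol, seed=None, amplitude: float = 0.05) -> pd.DataFrame:
    """Six slowly varying rigid-body motion traces (3 translations, 3 rotations)."""
    rng = np.random.default_rng(seed)
    n = protocol.n_volumes
    cols = {}
    for name in ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"):
        walk = np.cumsum(rng.normal(0.0, 1.0, n))
        walk -= walk.mean()
        walk /= max(np.abs(walk).max(), 1e-12)
        cols[name] = amplitude * walk
    return pd.DataFrame(cols)
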