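"""Depth-resolved maps and profiles: CVR, M-value, and venous CBV change.

Converts per-voxel GLM condition estimates into the three headline metrics,
aggregates them into 3-bin cortical depth profiles (deep, middle,
superficial), and forms all-venous vs micro-vascular (GE/SE) ratios.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .physio import CalibParams, hyperoxia_dhb_ratio, invert_cbv, m_value

log = logging.getLogger(__name__)

__all__ = [
    "BIN_NAMES",
    "bin_layers",
    "cvr_fit",
    "compute_m_map",
    "compute_cbv_map",
    "depth_profiles",
    "sequence_ratio",
    "plot_profiles",
]

BIN_NAMES = {1: "deep", 2: "middle", 3: "superficial"}


def bin_layers(depth_index):
    """Collapse 20 equivolumetric layers into 3 cortical depth bins.

    Layers 1 and 20 are dropped (white-matter and CSF adjacency); the
    remaining 18 are downsampled by 6: 2-7 -> deep (1), 8-13 -> middle (2),
    14-19 -> superficial (3).  0 marks excluded/out-of-cortex voxels.
    """
    depth = np.asarray(depth_index)
    scalar = depth.ndim == 0
    depth = np.atleast_1d(depth)
    if np.any((depth < 0) | (depth > 20)):
        raise ValueError("depth layer indices must lie in 0..20")
    out = np.zeros(depth.shape, dtype=int)
    out[(depth >= 2) & (depth <= 7)] = 1
    out[(depth >= 8) & (depth <= 13)] = 2
    out[(depth >= 14) & (depth <= 19)] = 3
    return int(out[0]) if scalar else out


def cvr_fit(dpetco2, dbold_hc) -> np.ndarray:
    """Cerebrovascular reactivity: slope of %ΔBOLD against measured ΔPetCO2.

    ``dpetco2`` is the per-condition measured PetCO2 increase (mmHg);
    ``dbold_hc`` is (n_voxels, n_conditions) %ΔBOLD.  An ordinary
    least-squares line *with intercept* is fitted per voxel over the
    conditions available to that voxel (NaN marks a missing condition);
    voxels with fewer than two conditions get NaN, not zero.
    """
    x = np.asarray(dpetco2, float)
    y = np.atleast_2d(np.asarray(dbold_hc, float))
    if y.shape[1] != x.size:
        raise ValueError("dbold_hc and dpetco2 disagree on condition count")
    valid = np.isfinite(y)
    counts = valid.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        xm = np.where(valid, x[None, :], 0.0).sum(axis=1) / counts
        ym = np.where(valid, y, 0.0).sum(axis=1) / counts
        dx = np.where(valid, x[None, :] - xm[:, None], 0.0)
        dy = np.where(valid, y - ym[:, None], 0.0)
        sxx = (dx**2).sum(axis=1)
        slope = (dx * dy).sum(axis=1) / sxx
    slope[(counts < 2) | (sxx <= 0)] = np.nan
    return slope


def condition_dpetco2(traces, protocol, levels) -> np.ndarray:
    """Measured ΔPetCO2 per hypercapnia condition: block mean minus baseline mean."""
    base = traces.petco2[protocol.volumes_in("baseline")].mean()
    return np.array(
        [traces.petco2[protocol.volumes_in(f"hc{lv}")].mean() - base for lv in levels]
    )


def compute_m_map(
    dbold_ho_pct,
    traces,
    protocol,
    params: CalibParams | None = None,
    method: str = "ratio_mean",
) -> np.ndarray:
    """Per-voxel M-value (percent) from the hyperoxia %ΔBOLD estimates.

    The deoxyhaemoglobin ratio is evaluated from the measured PetO2 trace,
    either as the hyperoxia-block mean of the per-sample ratio
    (``method='ratio_mean'``, the default: a binary-regressor estimate of a
    trace-driven response is exactly calibrated by the mean ratio) or at
    the block-mean PetO2 (``method='block_mean'``, the conventional
    condition-mean form).  The baseline PetO2 is the initial-baseline block
    mean.
    """
    params = params or CalibParams()
    ho_labels = [b for b in protocol.condition_labels if b.startswith("ho")]
    if not ho_labels:
        raise ValueError(
            "protocol has no hyperoxia block: the M-value (and hence ΔCBV) "
            "requires the hyperoxia calibration condition"
        )
    base_po2 = traces.peto2[protocol.volumes_in("baseline")].mean()
    ho_sel = protocol.volumes_in(ho_labels[0])
    if method == "block_mean":
        ratio = hyperoxia_dhb_ratio(base_po2, traces.peto2[ho_sel].mean(), params)
    elif method == "ratio_mean":
        ratio = float(
            np.mean(hyperoxia_dhb_ratio(base_po2, np.clip(traces.peto2[ho_sel], 1.0, None), params))
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    dbold = np.asarray(dbold_ho_pct, float)
    return 100.0 * m_value(dbold / 100.0, ratio, params)


def compute_cbv_map(
    dbold_hc_pct,
    m_pct,
    levels,
    params: CalibParams | None = None,
):
    """Per-voxel ΔCBV (percent) per hypercapnia condition.

    ``dbold_hc_pct`` is (n_voxels, n_conditions); voxels failing physiologic
    plausibility (m <= 0, or dBOLD >= M i.e. model saturation) are returned
    as NaN and counted in the QC dict.
    """
    params = params or CalibParams()
    y = np.atleast_2d(np.asarray(dbold_hc_pct, float)) / 100.0
    m = np.asarray(m_pct, float) / 100.0
    out = np.full(y.shape, np.nan)
    qc = {"n_m_nonpositive": int((~(m > 0)).sum()), "n_saturated": 0}
    for j, level in enumerate(levels):
        cmro2 = params.cmro2_ratio(level)
        valid = (m > 0) & np.isfinite(y[:, j]) & (y[:, j] < m)
        qc["n_saturated"] += int(((m > 0) & np.isfinite(y[:, j]) & (y[:, j] >= m)).sum())
        if valid.any():
            ratio = invert_cbv(y[valid, j], m[valid], cmro2, params)
            out[valid, j] = (ratio - 1.0) * 100.0
    return out, qc


def depth_profiles(table: pd.DataFrame, metrics=None) -> pd.DataFrame:
    """Across-subject depth profiles: bin means and SEM per metric.

    ``table`` holds one row per voxel with at least ``subject`` and
    ``depth_bin`` columns plus metric columns.  Subjects are averaged per
    bin first; the profile is the across-subject mean with its standard
    error (0 by convention for a single subject).  Empty bins are missing
    rows, not zeros.
    """
    if "subject" not in table or "depth_bin" not in table:
        raise ValueError("table needs 'subject' and 'depth_bin' columns")
    if metrics is None:
        metrics = [
            c for c in table.columns
            if c not in ("subject", "sequence", "depth_bin", "roi", "voxel")
            and pd.api.types.is_numeric_dtype(table[c])
        ]
    table = table[table["depth_bin"].isin(BIN_NAMES)]
    per_subject = table.groupby(["subject", "depth_bin"])[list(metrics)].mean()
    rows = []
    for metric in metrics:
        wide = per_subject[metric].unstack("depth_bin")
        for b in wide.columns:
            vals = wide[b].dropna().to_numpy()
            if vals.size == 0:
                continue
            sem = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
            rows.append({
                "metric": metric, "depth_bin": int(b), "bin_name": BIN_NAMES[int(b)],
                "mean": float(vals.mean()), "sem": sem, "n_subjects": int(vals.size),
            })
    return pd.DataFrame(rows)


def sequence_ratio(profile_ge: pd.DataFrame, profile_se: pd.DataFrame) -> pd.DataFrame:
    """Per-bin GE/SE ratio of profile means with propagated standard error."""
    merged = profile_ge.merge(
        profile_se, on=["metric", "depth_bin", "bin_name"], suffixes=("_ge", "_se")
    )
    if merged.empty:
        raise ValueError("profiles share no (metric, depth bin) rows")
    if np.any(merged["mean_se"] == 0):
        raise ZeroDivisionError("SE profile mean of zero: GE/SE ratio undefined")
    ratio = merged["mean_ge"] / merged["mean_se"]
    rel_err = np.sqrt(
        (merged["sem_ge"] / merged["mean_ge"]) ** 2
        + (merged["sem_se"] / merged["mean_se"]) ** 2
    )
    out = merged[["metric", "depth_bin", "bin_name"]].copy()
    out["ratio"] = ratio
    out["se"] = np.abs(ratio) * rel_err
    return out


def plot_profiles(profiles: pd.DataFrame, path=None, title=None):
    """Plot depth profiles (one panel per metric, shaded +/- SEM)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    metrics = profiles["metric"].unique()
    fig, axes = plt.subplots(1, len(metrics), figsize=(4 * len(metrics), 3.2), squeeze=False)
    for ax, metric in zip(axes[0], metrics):
        sub = profiles[profiles["metric"] == metric].sort_values("depth_bin")
        ax.errorbar(sub["depth_bin"], sub["mean"], yerr=sub["sem"], marker="o")
        ax.set_xticks(list(BIN_NAMES), [BIN_NAMES[b] for b in BIN_NAMES])
        ax.set_title(metric)
        ax.set_xlabel("cortical depth bin")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
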