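"""Calibrated-BOLD physiology: oxygen transport, M-value, and Davis/Grubb model.

This module is the pure, stateless core of the package.  It implements the
hyperoxia-calibrated BOLD model (Chiarelli-style) and the Davis model with
Grubb flow-volume coupling:

* the Severinghaus haemoglobin dissociation curve and arterial O2 content,
* the venous deoxyhaemoglobin ratio ``[dHb]_v/[dHb]_v0`` under hyperoxia
  assuming unchanged CBF and CMRO2,
* the M-value (theoretical maximum BOLD signal change at full dHb washout),
* the forward hypercapnia BOLD change
  ``dBOLD/BOLD0 = M * (1 - (CBV/CBV0)^(1-beta/alpha) * (CMRO2/CMRO2|0)^beta)``
  obtained by substituting Grubb's law ``CBV/CBV0 = (CBF/CBF0)^alpha`` into
  the Davis model, and its exact inversion for the venous CBV ratio.

All BOLD changes are *fractions* internally (0.02 = 2 %); user-facing layers
convert to percent.  Functions are vectorised over numpy arrays and accept
plain scalars.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "HC_LEVELS",
    "CalibParams",
    "OxygenState",
    "DegenerateOxygenStateError",
    "ModelSaturationError",
    "severinghaus_saturation",
    "arterial_o2_content",
    "oxygen_state",
    "hyperoxia_dhb_ratio",
    "bold_change",
    "forward_bold_hyperoxia",
    "m_value",
    "grubb_cbv_ratio",
    "forward_bold_hypercapnia",
    "invert_cbv",
]

#: Hypercapnia condition labels, as targeted PetCO2 increments in mmHg.
HC_LEVELS = ("+3", "+5", "+8", "+10")

_DEFAULT_CMRO2 = {"+3": 0.97, "+5": 0.95, "+8": 0.92, "+10": 0.90}


class DegenerateOxygenStateError(ValueError):
    """Baseline venous blood is fully saturated: no deoxyhaemoglobin to wash out."""


class ModelSaturationError(ValueError):
    """Measured hypercapnic BOLD change meets or exceeds M: the model saturates."""


@dataclass(frozen=True)
class CalibParams:
    """Physiological and physical constants of the calibrated-BOLD model.

    Parameters
    ----------
    alpha:
        Grubb CBF/CBV coupling exponent (venous), dimensionless.
    beta:
        Deoxyhaemoglobin transverse-relaxation exponent; ~1 at 7 T.
    oef0:
        Baseline oxygen extraction fraction.
    hb:
        Haemoglobin concentration in g/dL.
    phi:
        O2-carrying capacity of haemoglobin, mL O2 per g Hb.
    eps:
        O2 solubility in plasma, mL O2 / dL / mmHg.
    cmro2_ratio_by_condition:
        CMRO2/CMRO2|0 per hypercapnia level; hypercapnia mildly suppresses
        oxidative metabolism, scaling roughly linearly with inspired CO2.
    """

    alpha: float = 0.2
    beta: float = 1.0
    oef0: float = 0.30
    hb: float = 15.0
    phi: float = 1.34
    eps: float = 0.0031
    cmro2_ratio_by_condition: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CMRO2)
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.beta <= 0.0:
            raise ValueError(f"beta must be > 0, got {self.beta}")
        if not 0.0 < self.oef0 < 1.0:
            raise ValueError(f"oef0 must be in (0, 1), got {self.oef0}")
        if self.hb < 0 or self.phi <= 0 or self.eps < 0:
            raise ValueError("hb must be >= 0; phi > 0; eps >= 0")
        for level, ratio in self.cmro2_ratio_by_condition.items():
            if not 0.0 < ratio <= 1.0:
                raise ValueError(
                    f"CMRO2 ratio for {level} must be in (0, 1], got {ratio}"
                )

    def cmro2_ratio(self, level: str) -> float:
        """CMRO2/CMRO2|0 for a hypercapnia level label such as ``'+10'``."""
        try:
            return self.cmro2_ratio_by_condition[level]
        except KeyError:
            known = ", ".join(sorted(self.cmro2_ratio_by_condition))
            raise KeyError(
                f"unknown hypercapnia level {level!r}; known levels: {known}"
            ) from None

    # -- serialisation (flat JSON document) ---------------------------------
    def to_dict(self) -> dict:
        d = {
            "alpha": self.alpha,
            "beta": self.beta,
            "oef0": self.oef0,
            "hb": self.hb,
            "phi": self.phi,
            "eps": self.eps,
        }
        for level, ratio in self.cmro2_ratio_by_condition.items():
            d[f"cmro2_ratio_{level}"] = ratio
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "CalibParams":
        base = {k: d[k] for k in ("alpha", "beta", "oef0", "hb", "phi", "eps") if k in d}
        cmro2 = dict(_DEFAULT_CMRO2)
        for key, value in d.items():
            if key.startswith("cmro2_ratio_"):
                cmro2[key[len("cmro2_ratio_"):]] = value
        return cls(cmro2_ratio_by_condition=cmro2, **base)

    def with_overrides(self, **kwargs) -> "CalibParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class OxygenState:
    """Arterial/venous oxygenation at one arterial O2 tension.

    ``dhb_fraction`` is the venous deoxyhaemoglobin fraction ``1 - SvO2``,
    the quantity whose hyperoxia-induced drop drives the calibration signal.
    """

    po2: float
    sao2: float
    cao2: float
    svo2: float

    @property
    def dhb_fraction(self) -> float:
        return 1.0 - self.svo2


def _asarray(x):
    arr = np.asarray(x, dtype=float)
    return arr, arr.ndim == 0


def _ret(arr, scalar):
    return float(arr) if scalar else arr


def severinghaus_saturation(po2):
    """Haemoglobin O2 saturation (fraction) from PO2 in mmHg.

    Severinghaus closed form ``1 / (23400 / (PO2^3 + 150 PO2) + 1)``;
    strictly increasing, bounded in (0, 1).
    """
    arr, scalar = _asarray(po2)
    if np.any(arr <= 0):
        raise ValueError("po2 must be positive (mmHg)")
    sat = 1.0 / (23400.0 / (arr**3 + 150.0 * arr) + 1.0)
    return _ret(sat, scalar)


def arterial_o2_content(po2, params: CalibParams | None = None):
    """Arterial O2 content CaO2 in mL O2/dL: Hb-bound plus dissolved."""
    params = params or CalibParams()
    arr, scalar = _asarray(po2)
    content = params.phi * params.hb * severinghaus_saturation(arr) + params.eps * arr
    return _ret(content, scalar)


def _venous_saturation(po2, extraction, params: CalibParams):
    """Venous saturation given a fixed arterio-venous content difference.

    ``extraction`` is OEF0 * CaO2(baseline), held constant across states
    because hyperoxia leaves CBF and CMRO2 essentially unchanged.  Venous
    dissolved O2 is neglected; SvO2 is capped at 1 (and floored at 0).
    """
    cvo2 = arterial_o2_content(po2, params) - extraction
    return np.clip(cvo2 / (params.phi * params.hb), 0.0, 1.0)


def oxygen_state(po2: float, params: CalibParams | None = None,
                 po2_baseline: float | None = None) -> OxygenState:
    """Full oxygenation state at ``po2``.

    The arterio-venous O2 content difference is anchored at the baseline
    state (``po2_baseline``, defaulting to ``po2`` itself), mirroring the
    constant-CBF/CMRO2 assumption of hyperoxia calibration.
    """
    params = params or CalibParams()
    ref = po2 if po2_baseline is None else po2_baseline
    extraction = params.oef0 * arterial_o2_content(ref, params)
    return OxygenState(
        po2=float(po2),
        sao2=severinghaus_saturation(po2),
        cao2=arterial_o2_content(po2, params),
        svo2=float(_venous_saturation(po2, extraction, params)),
    )


def hyperoxia_dhb_ratio(po2_baseline, po2_hyper, params: CalibParams | None = None):
    """Venous deoxyhaemoglobin ratio ``[dHb]_v/[dHb]_v0`` under hyperoxia.

    Assumes CBF and CMRO2 are unchanged by the O2 challenge, so the
    arterio-venous content difference stays at ``OEF0 * CaO2(baseline)``.
    ``po2_hyper`` may be an array (e.g. a PetO2 trace); values at or below
    baseline give a ratio >= 1 and are permitted so that noisy traces can be
    mapped sample-by-sample.

    Raises
    ------
    DegenerateOxygenStateError
        If baseline venous blood is fully saturated (no baseline dHb).
    """
    params = params or CalibParams()
    base, _ = _asarray(po2_baseline)
    hyper, scalar = _asarray(po2_hyper)
    if np.any(base <= 0) or np.any(hyper <= 0):
        raise ValueError("partial pressures must be positive (mmHg)")
    extraction = params.oef0 * arterial_o2_content(base, params)
    svo2_base = _venous_saturation(base, extraction, params)
    if np.any(svo2_base >= 1.0):
        raise DegenerateOxygenStateError(
            "baseline venous saturation is 1: zero baseline [dHb], the "
            "hyperoxia calibration is undefined"
        )
    svo2_hyper = _venous_saturation(hyper, extraction, params)
    ratio = (1.0 - svo2_hyper) / (1.0 - svo2_base)
    return _ret(ratio, scalar)


def bold_change(m, cbv_ratio, dhb_ratio, params: CalibParams | None = None):
    """Generic calibrated-BOLD change ``M * (1 - (CBV/CBV0) * r^beta)``.

    ``r`` is the venous deoxyhaemoglobin ratio.  With ``cbv_ratio = 1`` this
    reduces exactly to the hyperoxia form; with the Davis expression for
    ``r`` it reproduces the hypercapnia forward model.
    """
    params = params or CalibParams()
    return m * (1.0 - np.asarray(cbv_ratio, float) * np.asarray(dhb_ratio, float) ** params.beta)


def forward_bold_hyperoxia(dhb_ratio, m, params: CalibParams | None = None):
    """Hyperoxia BOLD change ``M * (1 - r^beta)`` (no CBV change)."""
    params = params or CalibParams()
    return m * (1.0 - np.asarray(dhb_ratio, float) ** params.beta)


def m_value(dbold_ho, dhb_ratio, params: CalibParams | None = None):
    """M-value from the hyperoxia BOLD change and the dHb ratio.

    ``M = dBOLD_ho / (1 - r^beta)``; linear in ``dbold_ho``.

    Raises
    ------
    DegenerateOxygenStateError
        If ``r^beta`` is (numerically) 1: the hyperoxia response carries no
        information about M.
    """
    params = params or CalibParams()
    ratio, _ = _asarray(dhb_ratio)
    denom = 1.0 - ratio**params.beta
    if np.any(np.abs(denom) < 1e-12):
        raise DegenerateOxygenStateError(
            "dhb_ratio of 1 gives an uninformative hyperoxia response (M undefined)"
        )
    arr, scalar = _asarray(dbold_ho)
    out = arr / denom
    return _ret(out, scalar and np.ndim(denom) == 0)


def grubb_cbv_ratio(cbf_ratio, params: CalibParams | None = None):
    """Grubb's law: ``CBV/CBV0 = (CBF/CBF0)^alpha``."""
    params = params or CalibParams()
    arr, scalar = _asarray(cbf_ratio)
    if np.any(arr <= 0):
        raise ValueError("cbf_ratio must be positive")
    return _ret(arr**params.alpha, scalar)


def _exponent(params: CalibParams) -> float:
    expo = 1.0 - params.beta / params.alpha
    if abs(expo) < 1e-12:
        raise ValueError("beta/alpha = 1 makes the Davis+Grubb exponent vanish")
    return expo


def forward_bold_hypercapnia(cbv_ratio, cmro2_ratio, m, params: CalibParams | None = None):
    """Davis+Grubb forward model for the hypercapnic BOLD change (fraction).

    ``dBOLD/BOLD0 = M * (1 - (CBV/CBV0)^(1 - beta/alpha) * (CMRO2/CMRO2|0)^beta)``.
    """
    params = params or CalibParams()
    cbv, scalar_c = _asarray(cbv_ratio)
    if np.any(cbv <= 0):
        raise ValueError("cbv_ratio must be positive")
    out = m * (1.0 - cbv ** _exponent(params) * np.asarray(cmro2_ratio, float) ** params.beta)
    return _ret(np.asarray(out, float), scalar_c and np.ndim(out) == 0)


def invert_cbv(dbold_hc, m, cmro2_ratio, params: CalibParams | None = None):
    """Invert the hypercapnia forward model for the venous CBV ratio.

    ``CBV/CBV0 = [(1 - dBOLD/M) / (CMRO2/CMRO2|0)^beta]^(1/(1 - beta/alpha))``

    Exact inverse of :func:`forward_bold_hypercapnia`.  The CBV change is
    conventionally reported as ``(ratio - 1) * 100`` percent.

    Raises
    ------
    ModelSaturationError
        If ``dbold_hc >= m`` anywhere (model saturated).
    ValueError
        If ``m <= 0``.
    """
    params = params or CalibParams()
    m_arr, _ = _asarray(m)
    if np.any(m_arr <= 0):
        raise ValueError("m must be positive to invert the model")
    d_arr, scalar = _asarray(dbold_hc)
    if np.any(d_arr >= m_arr):
        raise ModelSaturationError(
            "dbold_hc >= m: the measured change exceeds the model ceiling"
        )
    base = (1.0 - d_arr / m_arr) / np.asarray(cmro2_ratio, float) ** params.beta
    out = base ** (1.0 / _exponent(params))
    return _ret(np.asarray(out, float), scalar and np.ndim(out) == 0)
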