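"""Closed-form signal equations for PSIR LGE and saturation-recovery sequences.

This module collects the pure signal physics used everywhere else in the
package:

* inversion-recovery (IR) phase-sensitive signal, used by conventional
  bright-blood PSIR LGE,
* the IR + T2-preparation signal of dark-blood PSIR LGE,
* the saturation-recovery (SR) signal family of the mSASHA acquisition
  (anchor / SR / SR with T2 preparation),
* gadolinium relaxivity relations linking relaxation rates to contrast
  concentration.

Conventions: relaxation times T1 and T2 are in milliseconds, relaxation
rates R1 = 1000/T1 and R2 = 1000/T2 are in Hz, and all signals are
normalised to the equilibrium magnetisation (amplitude ``a`` for the SR
family). Perfect saturation/inversion efficiency is assumed and the
single-shot readout is treated as instantaneous sampling of the prepared
magnetisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TissueRelaxation",
    "IrTiming",
    "GdRelaxivity",
    "ir_psir_signal",
    "ir_t2_psir_signal",
    "msasha_signal",
    "sr_signal",
    "gd_concentration_from_r2",
    "r1_from_t1",
    "t1_from_r1",
    "PREP_KINDS",
]

#: Preparation kinds understood by :func:`msasha_signal`.
PREP_KINDS = ("anchor", "SR", "SR+T2prep")


def _require_positive(value: float, name: str) -> None:
    if not np.all(np.asarray(value) > 0):
        raise ValueError(f"{name} must be positive, got {value!r}")


@dataclass(frozen=True)
class TissueRelaxation:
    """Longitudinal and transverse relaxation times of a tissue.

    Parameters
    ----------
    t1 : float
        Longitudinal relaxation time in ms. Must be positive.
    t2 : float
        Transverse relaxation time in ms. Must be positive.
    """

    t1: float
    t2: float

    def __post_init__(self) -> None:
        _require_positive(self.t1, "t1")
        _require_positive(self.t2, "t2")

    @property
    def r1(self) -> float:
        """Longitudinal relaxation rate in Hz (1000/T1)."""
        return 1000.0 / self.t1

    @property
    def r2(self) -> float:
        """Transverse relaxation rate in Hz (1000/T2)."""
        return 1000.0 / self.t2

    @classmethod
    def from_rates(cls, r1: float, r2: float) -> "TissueRelaxation":
        """Build from rates in Hz; exact inverse of :attr:`r1`/:attr:`r2`."""
        _require_positive(r1, "r1")
        _require_positive(r2, "r2")
        return cls(t1=1000.0 / r1, t2=1000.0 / r2)


@dataclass(frozen=True)
class IrTiming:
    """Timing of an IR or IR+T2-preparation LGE sequence.

    ``ti`` is the inversion time of a plain IR sequence. For the IR-T2
    sequence, ``td1`` and ``td2`` are the inversion delays before and after
    the T2 preparation and ``te_prep`` is the T2-preparation echo time that
    sets the degree of T2 weighting. All in ms, all non-negative.
    """

    ti: float = 0.0
    td1: float = 0.0
    td2: float = 0.0
    te_prep: float = 0.0

    def __post_init__(self) -> None:
        for name in ("ti", "td1", "td2", "te_prep"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class GdRelaxivity:
    """Gadolinium relaxivities and native relaxation rates.

    ``r1``/``r2`` are relaxivities in s^-1 mmol^-1 L; ``r1_0``/``r2_0``
    native (pre-contrast) rates in Hz. Under fast exchange the
    post-contrast rates are linear in concentration:
    ``R = R_0 + r * [Gd]``.
    """

    r1: float = 3.9
    r2: float = 5.85
    r1_0: float = 0.0
    r2_0: float = 0.0

    def __post_init__(self) -> None:
        _require_positive(self.r1, "r1")
        _require_positive(self.r2, "r2")

    def r2_post(self, concentration_mmol_l) -> np.ndarray | float:
        """Forward model: transverse rate at a given [Gd] (Hz)."""
        return self.r2_0 + self.r2 * np.asarray(concentration_mmol_l, dtype=float)

    def r1_post(self, concentration_mmol_l) -> np.ndarray | float:
        """Forward model: longitudinal rate at a given [Gd] (Hz)."""
        return self.r1_0 + self.r1 * np.asarray(concentration_mmol_l, dtype=float)


def ir_psir_signal(ti, tissue: TissueRelaxation):
    """Phase-sensitive IR signal ``1 - 2 exp(-TI/T1)``.

    The signed signal of a standard inversion-recovery LGE readout with the
    inversion time ``ti`` (ms). Crosses zero at TI = T1 ln 2, the null
    point used to suppress normal myocardium.
    """
    ti = np.asarray(ti, dtype=float)
    if np.any(ti < 0):
        raise ValueError("ti must be non-negative")
    out = 1.0 - 2.0 * np.exp(-ti / tissue.t1)
    return out.item() if out.ndim == 0 else out


def ir_t2_psir_signal(timing: IrTiming, tissue: TissueRelaxation):
    """Phase-sensitive signal of the IR + T2-preparation (dark-blood) sequence.

    ``1 - [1 - (1 - 2 exp(-TD1/T1)) exp(-TE/T2)] exp(-TD2/T1)``

    With ``te_prep = 0`` this reduces exactly to :func:`ir_psir_signal`
    evaluated at TI = TD1 + TD2.
    """
    e1a = np.exp(-timing.td1 / tissue.t1)
    e2 = np.exp(-timing.te_prep / tissue.t2)
    e1b = np.exp(-timing.td2 / tissue.t1)
    return 1.0 - (1.0 - (1.0 - 2.0 * e1a) * e2) * e1b


def sr_signal(delay_ms, tissue_t1, te_prep_ms=0.0, tissue_t2=None, amplitude=1.0):
    """Saturation-recovery signal ``A (1 - exp(-delay/T1)) exp(-TE/T2)``.

    Vectorised workhorse behind :func:`msasha_signal` and the forward
    simulation/fitting: ``delay_ms`` is the time from saturation to
    readout, ``te_prep_ms`` the echo time of an optional T2 preparation
    (0 means no preparation, in which case ``tissue_t2`` is ignored).
    All arguments broadcast.
    """
    delay = np.asarray(delay_ms, dtype=float)
    t1 = np.asarray(tissue_t1, dtype=float)
    sig = np.asarray(amplitude, dtype=float) * (1.0 - np.exp(-delay / t1))
    te = np.asarray(te_prep_ms, dtype=float)
    if np.any(te > 0):
        if tissue_t2 is None:
            raise ValueError("tissue_t2 required when te_prep_ms > 0")
        sig = sig * np.exp(-te / np.asarray(tissue_t2, dtype=float))
    out = np.asarray(sig)
    return out.item() if out.ndim == 0 else out


def msasha_signal(
    prep_kind: str,
    ts: float,
    tissue: TissueRelaxation,
    te_prep: float = 0.0,
    recovery_duration: float | None = None,
    amplitude: float = 1.0,
):
    """Signal of one mSASHA frame for a given preparation.

    Parameters
    ----------
    prep_kind : {"anchor", "SR", "SR+T2prep"}
        Preparation of the frame. ``"SR"`` is a plain saturation-recovery
        image read out ``ts`` ms after saturation; ``"SR+T2prep"``
        additionally applies a T2 preparation with echo time ``te_prep``
        immediately before readout; ``"anchor"`` is the long-recovery
        reference image, read out ``recovery_duration`` ms after
        saturation (3 RR + TS in the default protocol), approximating the
        equilibrium amplitude.
    ts : float
        Saturation-recovery delay in ms.
    tissue : TissueRelaxation
        Tissue T1/T2.
    te_prep : float
        T2-preparation echo time in ms (only used for ``"SR+T2prep"``).
    recovery_duration : float, optional
        Total recovery time for the anchor image, ms. Required for
        ``"anchor"``.
    amplitude : float
        Proton-density amplitude A (> 0).
    """
    _require_positive(amplitude, "amplitude")
    if ts < 0:
        raise ValueError("ts must be non-negative")
    if prep_kind == "SR":
        return sr_signal(ts, tissue.t1, amplitude=amplitude)
    if prep_kind == "SR+T2prep":
        if te_prep < 0:
            raise ValueError("te_prep must be non-negative")
        return sr_signal(ts, tissue.t1, te_prep, tissue.t2, amplitude=amplitude)
    if prep_kind == "anchor":
        if recovery_duration is None:
            raise ValueError("anchor frames need recovery_duration")
        return sr_signal(recovery_duration, tissue.t1, amplitude=amplitude)
    raise ValueError(f"unknown prep_kind {prep_kind!r}; expected one of {PREP_KINDS}")


def gd_concentration_from_r2(t2_native_ms: float, t2_post_ms: float, r2: float = 5.85) -> float:
    """Gadolinium concentration from the contrast-induced change in R2.

    ``[Gd] = (1000/T2_post - 1000/T2_native) / r2`` in mmol/L, with the
    relaxivity ``r2`` in s^-1 mmol^-1 L. Blood T2 shortening after a
    standard contrast dose (roughly 250 ms native to ~142 ms
    post-contrast) corresponds to about 0.52 mmol/L at r2 = 5.85.
    """
    _require_positive(t2_native_ms, "t2_native_ms")
    _require_positive(t2_post_ms, "t2_post_ms")
    _require_positive(r2, "r2")
    if t2_post_ms > t2_native_ms:
        raise ValueError(
            "t2_post_ms exceeds t2_native_ms: implied negative contrast "
            "concentration (post-contrast T2 must not exceed native T2)"
        )
    return (1000.0 / t2_post_ms - 1000.0 / t2_native_ms) / r2


def r1_from_t1(t1_ms):
    """Longitudinal rate R1 = 1000/T1 in Hz (elementwise)."""
    t1 = np.asarray(t1_ms, dtype=float)
    if np.any(t1[np.isfinite(t1)] <= 0):
        raise ValueError("t1_ms must be positive")
    out = 1000.0 / t1
    return out.item() if out.ndim == 0 else out


def t1_from_r1(r1_hz):
    """Exact inverse of :func:`r1_from_t1`."""
    r1 = np.asarray(r1_hz, dtype=float)
    if np.any(r1[np.isfinite(r1)] <= 0):
        raise ValueError("r1_hz must be positive")
    out = 1000.0 / r1
    return out.item() if out.ndim == 0 else out
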