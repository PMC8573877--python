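"""Calculated bright-blood and dark-blood PSIR LGE from relaxation-rate maps.

Instead of synthesising the exponential inversion-recovery signal, the
calculated PSIR images are formed directly in relaxation-rate units so
that the signal is linear in gadolinium concentration:

* bright blood:  ``BB = R1 - R1m``  — zero in normal myocardium
  (R1 = R1m), positive (bright) for shorter-T1 tissue such as scar;
* dark blood:    ``DB = R1 - R1m / (a_DB R2/R2m + (1 - a_DB))`` — still
  zero in normal myocardium (where R2 = R2m makes it identical to BB),
  but with the blood pool pinned to an adjustable level LGEb (Hz) through
  the analytically solved mixing weight

      a_DB = (R1m R2m / (R1b - LGEb) - R2m) / (R2b - R2m).

LGEb controls the depth of blood suppression (-0.5 Hz by default; larger
values give greyer blood) and the images can be swept over LGEb to choose
a suppression level retrospectively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .signal_models import TissueRelaxation

__all__ = [
    "TissueReference",
    "PsirImage",
    "compute_a_db",
    "calc_bb_psir",
    "calc_db_psir",
    "estimate_normal_values",
    "lgeb_sweep",
    "db_attenuation_curve",
]


@dataclass(frozen=True)
class TissueReference:
    """Nulling and suppression constants for calculated PSIR.

    Rates are in Hz: ``r1m``/``r2m`` for normal myocardium, ``r1b``/``r2b``
    for the blood pool. ``lgeb`` is the target dark-blood signal of blood
    (Hz, -0.5 by default). ``a_db`` is derived on access so it always
    reflects the current fields.
    """

    r1m: float
    r2m: float
    r1b: float
    r2b: float
    lgeb: float = -0.5

    def __post_init__(self) -> None:
        if self.r2b == self.r2m:
            raise ValueError("r2b must differ from r2m (a_DB denominator)")
        if self.r1b == self.lgeb:
            raise ValueError("lgeb must differ from r1b (a_DB inner denominator)")

    @property
    def a_db(self) -> float:
        """Dark-blood mixing weight solved from the blood operating point."""
        return (self.r1m * self.r2m / (self.r1b - self.lgeb) - self.r2m) / (
            self.r2b - self.r2m
        )

    @classmethod
    def from_times(
        cls, t1m: float, t2m: float, t1b: float, t2b: float, lgeb: float = -0.5
    ) -> "TissueReference":
        """Build from (T1, T2) in ms for myocardium and blood."""
        return cls(
            r1m=1000.0 / t1m,
            r2m=1000.0 / t2m,
            r1b=1000.0 / t1b,
            r2b=1000.0 / t2b,
            lgeb=lgeb,
        )

    @classmethod
    def from_tissues(
        cls, myocardium: TissueRelaxation, blood: TissueRelaxation, lgeb: float = -0.5
    ) -> "TissueReference":
        return cls(
            r1m=myocardium.r1, r2m=myocardium.r2, r1b=blood.r1, r2b=blood.r2, lgeb=lgeb
        )

    def with_lgeb(self, lgeb: float) -> "TissueReference":
        return replace(self, lgeb=lgeb)

    def to_dict(self) -> dict:
        return {
            "r1m": self.r1m,
            "r2m": self.r2m,
            "r1b": self.r1b,
            "r2b": self.r2b,
            "lgeb": self.lgeb,
            "a_db": self.a_db,
        }


@dataclass
class PsirImage:
    """A calculated PSIR signal map in Hz.

    ``kind`` is "BB" or "DB"; ``reference`` records the constants the
    image was calculated with; ``n_invalid`` counts pixels whose dark-
    blood denominator was non-positive (set to NaN).
    """

    values: np.ndarray
    kind: str
    reference: TissueReference
    n_invalid: int = 0

    def window_level(self, vmin: float = -1.0, vmax: float = 2.0) -> np.ndarray:
        """Rescale to 8-bit for display; NaN maps to 0."""
        scaled = (np.nan_to_num(self.values, nan=vmin) - vmin) / (vmax - vmin)
        return np.clip(scaled * 255.0, 0, 255).astype(np.uint8)


def compute_a_db(ref: TissueReference) -> float:
    """The dark-blood mixing weight a_DB (see :class:`TissueReference`)."""
    return ref.a_db


def calc_bb_psir(r1_map, ref: TissueReference) -> PsirImage:
    """Calculated bright-blood PSIR: ``R1 - R1m`` per pixel, Hz.

    NaN pixels (unconverged fits) propagate as NaN.
    """
    values = np.asarray(r1_map, dtype=float) - ref.r1m
    return PsirImage(values=values, kind="BB", reference=ref)


def calc_db_psir(r1_map, r2_map, ref: TissueReference) -> PsirImage:
    """Calculated dark-blood PSIR per pixel, Hz.

    Equals the bright-blood image wherever R2 = R2m; equals ``lgeb`` at
    the blood operating point (R1b, R2b). Pixels with a non-positive
    denominator are NaN and counted in ``n_invalid``.
    """
    r1 = np.asarray(r1_map, dtype=float)
    r2 = np.asarray(r2_map, dtype=float)
    if r1.shape != r2.shape:
        raise ValueError(f"R1 shape {r1.shape} != R2 shape {r2.shape}")
    a = ref.a_db
    denom = a * r2 / ref.r2m + (1.0 - a)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = r1 - ref.r1m / denom
    bad = (denom <= 0) & np.isfinite(r1) & np.isfinite(r2)
    n_invalid = int(bad.sum())
    if n_invalid:
        warnings.warn(
            f"dark-blood denominator non-positive at {n_invalid} pixels; set to NaN",
            stacklevel=2,
        )
        values = np.where(bad, np.nan, values)
    return PsirImage(values=values, kind="DB", reference=ref, n_invalid=n_invalid)


def estimate_normal_values(results, myocardium_mask) -> tuple[float, float]:
    """Median (T1, T2) in ms over the segmented myocardium.

    The median over the whole myocardial segment (scar included) is used
    as the normal-value estimate: it is robust to regional abnormalities
    as long as they cover less than half the segment, and PSIR nulling is
    in any case insensitive to moderate errors in the assumed normal
    value. Only converged pixels contribute.
    """
    mask = np.asarray(myocardium_mask, dtype=bool)
    if not mask.any():
        raise ValueError("myocardium mask is empty")
    use = mask & results.converged_mask
    if not use.any():
        raise ValueError("no converged pixels inside the myocardium mask")
    return float(np.median(results.t1_map[use])), float(np.median(results.t2_map[use]))


def lgeb_sweep(r1_map, r2_map, ref: TissueReference, lgeb_values) -> list[PsirImage]:
    """One dark-blood image per LGEb value.

    Decreasing LGEb deepens the blood suppression; by construction the
    blood operating point lands exactly at each LGEb.
    """
    return [calc_db_psir(r1_map, r2_map, ref.with_lgeb(float(l))) for l in lgeb_values]


def db_attenuation_curve(
    edema_t1_grid,
    edema_t2_grid,
    remote: TissueRelaxation,
    blood: TissueRelaxation,
    lgeb: float = -0.5,
) -> np.ndarray:
    """Attenuation of the dark-blood signal by T2 elevation (edema).

    For each edematous-tissue (T1, T2) pair, returns
    ``DB(T1, T2) / BB(T1)`` — the factor by which the T2 term of the
    dark-blood formulation reduces the calculated signal relative to its
    T2-neutral (bright-blood) value. Equals 1 when the edema T2 matches
    the remote T2 and decreases as T2 rises. Undefined (NaN) where the
    bright-blood signal is zero, i.e. edema T1 equal to remote T1.

    Returns an array of shape (len(edema_t1_grid), len(edema_t2_grid)).
    """
    t1g = np.asarray(edema_t1_grid, dtype=float)
    t2g = np.asarray(edema_t2_grid, dtype=float)
    if np.any(t1g <= 0) or np.any(t2g <= 0):
        raise ValueError("edema T1/T2 grids must be positive")
    ref = TissueReference.from_tissues(remote, blood, lgeb=lgeb)
    r1 = (1000.0 / t1g)[:, None] * np.ones_like(t2g)[None, :]
    r2 = np.ones_like(t1g)[:, None] * (1000.0 / t2g)[None, :]
    bb = calc_bb_psir(r1, ref).values
    db = calc_db_psir(r1, r2, ref).values
    with np.errstate(divide="ignore", invalid="ignore"):
        att = db / bb
    return np.where(bb == 0, np.nan, att)


def plot_attenuation_curve(att, edema_t1_grid, edema_t2_grid, ax=None):
    """Plot attenuation vs edema T2, one line per edema T1."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for i, t1 in enumerate(np.asarray(edema_t1_grid)):
        ax.plot(edema_t2_grid, att[i], label=f"T1 = {t1:.0f} ms")
    ax.set_xlabel("edema T2 (ms)")
    ax.set_ylabel("DB / BB signal ratio")
    ax.legend()
    return ax
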