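"""Digital phantoms and forward simulation of noisy mSASHA image series.

Two phantom geometries are provided:

* a 9-vial relaxometry plate in the style of the standardised T1MES
  quality-assurance phantom, with ground-truth (T1, T2) spanning
  myocardium- and blood-like values with and without contrast, and
* a short-axis cardiac slice: circular blood pool, myocardial annulus and
  a scar sector (subendocardial for infarction, subepicardial for
  myocarditis), with tissue values set to post-contrast group means for
  chronic infarction or for the elevated-T2 acute/myocarditis setting.

Frames are simulated pre-registered (respiratory motion and its
correction are outside the scope of this package) with additive Gaussian
noise on the magnitude images; a Rician option exists for low-SNR work.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .protocol import ProtocolSpec, PreparationEvent
from .signal_models import TissueRelaxation, sr_signal

__all__ = [
    "Region",
    "DigitalPhantom",
    "ImageSeries",
    "T1MES_REFERENCE",
    "CARDIAC_TISSUES",
    "make_t1mes_phantom",
    "make_cardiac_phantom",
    "simulate_series",
]

#: Spin-echo reference (T1, T2) in ms for the 9 vials, long-TR standard.
T1MES_REFERENCE: tuple[tuple[float, float], ...] = (
    (439.0, 40.0),
    (1111.0, 44.3),
    (464.0, 181.0),
    (572.0, 42.5),
    (1361.0, 46.6),
    (1527.0, 234.4),
    (303.0, 41.9),
    (814.0, 44.8),
    (258.0, 154.2),
)

#: Post-contrast group-mean (T1, T2) in ms per region and scenario.
CARDIAC_TISSUES: dict[str, dict[str, tuple[float, float]]] = {
    "chronic_mi": {"mi": (441.0, 43.8), "remote": (668.0, 42.4), "blood": (466.0, 142.4)},
    "acute_mi": {"mi": (392.0, 58.3), "remote": (608.0, 41.7), "blood": (396.0, 141.8)},
    "myocarditis": {"mi": (392.0, 58.3), "remote": (608.0, 41.7), "blood": (396.0, 141.8)},
}

#: Label legend for cardiac phantoms (0 is background everywhere).
CARDIAC_LABELS = {"blood": 1, "remote": 2, "mi": 3}


@dataclass(frozen=True)
class Region:
    """A phantom region: name, ground-truth relaxation, proton density."""

    name: str
    tissue: TissueRelaxation
    amplitude: float = 1.0


@dataclass
class DigitalPhantom:
    """Integer label map plus per-label ground-truth tissue properties."""

    label_map: np.ndarray
    regions: dict[int, Region]

    def __post_init__(self) -> None:
        labels = set(np.unique(self.label_map)) - {0}
        missing = labels - set(self.regions)
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from regions")
        for lab in self.regions:
            area = int(np.sum(self.label_map == lab))
            if area < 25:
                raise ValueError(
                    f"region {lab} has only {area} px; need >= 25 for ROI statistics"
                )

    @property
    def shape(self) -> tuple[int, ...]:
        return self.label_map.shape

    def mask(self, which) -> np.ndarray:
        """Boolean mask for a label id, region name, or iterable of either."""
        if isinstance(which, (int, np.integer, str)):
            which = [which]
        ids = []
        for w in which:
            if isinstance(w, str):
                matches = [lab for lab, r in self.regions.items() if r.name == w]
                if not matches:
                    raise KeyError(f"no region named {w!r}")
                ids.extend(matches)
            else:
                ids.append(int(w))
        return np.isin(self.label_map, ids)

    def _property_map(self, getter, background=np.nan) -> np.ndarray:
        out = np.full(self.label_map.shape, background, dtype=float)
        for lab, region in self.regions.items():
            out[self.label_map == lab] = getter(region)
        return out

    def t1_map(self) -> np.ndarray:
        return self._property_map(lambda r: r.tissue.t1)

    def t2_map(self) -> np.ndarray:
        return self._property_map(lambda r: r.tissue.t2)

    def amplitude_map(self) -> np.ndarray:
        return self._property_map(lambda r: r.amplitude, background=0.0)


@dataclass
class ImageSeries:
    """A stack of single-shot magnitude images with preparation metadata.

    ``frames`` has shape (n_events, ny, nx); ``events`` lists the
    preparation of each frame in acquisition order; ``rr`` is the
    heartbeat interval used when scheduling; ``noise_sd`` the additive
    noise standard deviation in amplitude units (0 for noise-free);
    ``seed`` the generator seed (None for noise-free).
    """

    frames: np.ndarray
    events: tuple[PreparationEvent, ...]
    rr: float = 1000.0
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.events = tuple(self.events)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_events, ny, nx)")
        if self.frames.shape[0] != len(self.events):
            raise ValueError(
                f"frame count {self.frames.shape[0]} != event count {len(self.events)}"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def protocol(self, name: str = "series") -> ProtocolSpec:
        return ProtocolSpec(name=name, events=self.events, rr=self.rr)


def _disk(shape, center, radius) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def make_t1mes_phantom(
    shape: tuple[int, int] = (128, 128), vial_radius: int = 10
) -> DigitalPhantom:
    """Nine circular vials on a 3x3 grid with the reference (T1, T2) values."""
    label_map = np.zeros(shape, dtype=int)
    regions: dict[int, Region] = {}
    ny, nx = shape
    centers_y = np.linspace(ny / 6, 5 * ny / 6, 3)
    centers_x = np.linspace(nx / 6, 5 * nx / 6, 3)
    lab = 0
    for cy in centers_y:
        for cx in centers_x:
            lab += 1
            t1, t2 = T1MES_REFERENCE[lab - 1]
            label_map[_disk(shape, (cy, cx), vial_radius)] = lab
            regions[lab] = Region(f"vial{lab}", TissueRelaxation(t1, t2))
    return DigitalPhantom(label_map, regions)


def make_cardiac_phantom(
    scenario: str = "chronic_mi",
    shape: tuple[int, int] = (128, 128),
    r_blood: float | None = None,
    r_epi: float | None = None,
    scar_angle_deg: float = 75.0,
    tissues: dict[str, tuple[float, float]] | None = None,
) -> DigitalPhantom:
    """Short-axis slice: blood pool, myocardial annulus, scar sector.

    Infarct scenarios place the scar in the subendocardial half of the
    annulus (adjacent to the blood pool); myocarditis places it
    subepicardially. Radii default to 40 and 28 px on the 128-grid and
    scale with the grid otherwise. ``tissues`` overrides the scenario's
    default (T1, T2) per region.
    """
    if r_epi is None:
        r_epi = 40.0 / 128.0 * min(shape)
    if r_blood is None:
        r_blood = 0.7 * r_epi
    if scenario not in CARDIAC_TISSUES:
        raise ValueError(
            f"unknown scenario {scenario!r}; expected one of {sorted(CARDIAC_TISSUES)}"
        )
    values = dict(CARDIAC_TISSUES[scenario])
    if tissues:
        values.update(tissues)

    ny, nx = shape
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    yy, xx = np.ogrid[:ny, :nx]
    r = np.hypot(yy - cy, xx - cx)
    theta = np.degrees(np.arctan2(yy - cy, xx - cx))  # (-180, 180]

    blood = r <= r_blood
    myo = (r > r_blood) & (r <= r_epi)
    r_mid = 0.5 * (r_blood + r_epi)
    half = scar_angle_deg / 2.0
    in_sector = np.abs(theta) <= half
    if scenario == "myocarditis":
        scar = myo & in_sector & (r > r_mid)  # subepicardial
    else:
        scar = myo & in_sector & (r <= r_mid)  # subendocardial

    label_map = np.zeros(shape, dtype=int)
    label_map[blood] = CARDIAC_LABELS["blood"]
    label_map[myo] = CARDIAC_LABELS["remote"]
    label_map[scar] = CARDIAC_LABELS["mi"]

    regions = {
        lab: Region(name, TissueRelaxation(*values[name]))
        for name, lab in CARDIAC_LABELS.items()
    }
    return DigitalPhantom(label_map, regions)


def forward_frames(phantom: DigitalPhantom, protocol: ProtocolSpec) -> np.ndarray:
    """Noise-free mSASHA frames for a phantom (background pixels are 0)."""
    for e in protocol.events:
        if e.kind not in ("anchor", "SR", "SR+T2prep"):
            raise ValueError(f"cannot simulate event kind {e.kind!r}")
    t1 = phantom.t1_map()
    t2 = phantom.t2_map()
    amp = phantom.amplitude_map()
    inside = phantom.label_map > 0
    delays = protocol.recovery_durations()
    tes = protocol.te_preps()
    frames = np.zeros((protocol.n_images,) + phantom.shape, dtype=float)
    for i in range(protocol.n_images):
        frames[i][inside] = sr_signal(
            delays[i], t1[inside], tes[i], t2[inside], amplitude=amp[inside]
        )
    return frames


def simulate_series(
    phantom: DigitalPhantom,
    protocol: ProtocolSpec,
    snr: float = np.inf,
    seed: int | None = None,
    noise: str = "gaussian",
) -> ImageSeries:
    """Simulate a noisy mSASHA series from a phantom.

    ``snr`` is the anchor-image SNR at unit proton density: the additive
    noise standard deviation is (amplitude scale)/snr with the amplitude
    scale taken as the maximum region proton density (1.0 by default).
    ``snr = inf`` gives the exact noise-free forward model. A fixed seed
    reproduces the series bit for bit.
    """
    if not (snr > 0):
        raise ValueError("snr must be positive (np.inf for noise-free)")
    frames = forward_frames(phantom, protocol)
    if np.isinf(snr):
        return ImageSeries(frames, protocol.events, rr=protocol.rr, noise_sd=0.0, seed=seed)

    amp_scale = max(r.amplitude for r in phantom.regions.values())
    sd = amp_scale / snr
    rng = np.random.default_rng(seed)
    if noise == "gaussian":
        frames = frames + rng.normal(0.0, sd, size=frames.shape)
    elif noise == "rician":
        re = frames + rng.normal(0.0, sd, size=frames.shape)
        im = rng.normal(0.0, sd, size=frames.shape)
        frames = np.hypot(re, im)
    else:
        raise ValueError(f"unknown noise model {noise!r}")
    return ImageSeries(frames, protocol.events, rr=protocol.rr, noise_sd=sd, seed=seed)
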