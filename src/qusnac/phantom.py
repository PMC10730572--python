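"""Synthetic tissue-mimicking phantoms for quantitative-ultrasound analysis.

Phantoms are described geometrically (regions with scatterer statistics) and
rendered to RF echo data by :mod:`qusnac.rfsim`.  Two kinds are provided:

* a uniform *reference* phantom with known attenuation and sound speed, used
  by the reference-phantom normalization method, and
* two-class *tumour* phantoms (responder / non-responder to neoadjuvant
  chemotherapy) whose core and margin scatterer statistics follow the group
  differences reported for breast tumours: non-responders show elevated
  backscatter (scatterer number density x impedance contrast squared) in both
  core and margin, smaller scatterers, and little core-vs-margin contrast,
  while responders show larger scatterers, a core distinct from its margin,
  and stronger intra-core heterogeneity.

Every phantom carries its ground truth so downstream estimators can be scored
for parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TransducerSpec",
    "Ellipse",
    "Rect",
    "Region",
    "PhantomSpec",
    "HeterogeneityField",
    "REFERENCE_ATTENUATION_DB_MHZ_CM",
    "REFERENCE_SOUND_SPEED_M_S",
    "make_reference_phantom_spec",
    "make_tumour_phantom",
    "core_mask_for_phantom",
]

#: Attenuation coefficient of the calibration reference phantom (dB/MHz/cm).
REFERENCE_ATTENUATION_DB_MHZ_CM = 0.786
#: Sound speed of the calibration reference phantom (m/s).
REFERENCE_SOUND_SPEED_M_S = 1540.0


@dataclass(frozen=True)
class TransducerSpec:
    """Linear-array acquisition geometry.

    Defaults model a clinical linear probe operating at 6.5 MHz centre
    frequency over a 3--8 MHz band, sampled at 40 MHz, storing 512 RF lines
    across a 6 cm lateral sector.
    """

    centre_frequency: float = 6.5e6
    band_low: float = 3.0e6
    band_high: float = 8.0e6
    sampling_rate: float = 40.0e6
    n_lines: int = 512
    lateral_extent: float = 0.06
    axial_extent: float = 0.05
    sound_speed: float = 1540.0
    pulse_fractional_bandwidth: float = 0.6

    def __post_init__(self) -> None:
        if not (self.band_low < self.centre_frequency < self.band_high):
            raise ValueError("band_low < centre_frequency < band_high required")
        if self.sampling_rate <= 2.0 * self.band_high:
            raise ValueError("sampling_rate must exceed twice band_high")
        if self.n_lines < 2:
            raise ValueError("n_lines must be >= 2")
        if self.pulse_fractional_bandwidth <= 0:
            raise ValueError("pulse_fractional_bandwidth must be positive")

    @property
    def wavelength(self) -> float:
        """Wavelength at the centre frequency (m)."""
        return self.sound_speed / self.centre_frequency

    @property
    def line_spacing(self) -> float:
        """Lateral spacing between adjacent RF lines (m)."""
        return self.lateral_extent / self.n_lines

    @property
    def n_samples(self) -> int:
        """Axial samples per line: round-trip travel time times sampling rate."""
        return int(round(self.axial_extent * 2.0 / self.sound_speed * self.sampling_rate))

    @property
    def axial_sample_spacing(self) -> float:
        """Depth increment per RF sample (m)."""
        return self.sound_speed / (2.0 * self.sampling_rate)


# ---------------------------------------------------------------------------
# Geometry primitives (physical coordinates: x lateral, z axial depth, metres)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Ellipse:
    cx: float
    cz: float
    rx: float
    rz: float

    def contains(self, x: np.ndarray, z: np.ndarray) -> np.ndarray:
        return ((x - self.cx) / self.rx) ** 2 + ((z - self.cz) / self.rz) ** 2 <= 1.0

    @property
    def area(self) -> float:
        return math.pi * self.rx * self.rz

    @property
    def bbox(self) -> tuple:
        return (self.cx - self.rx, self.cx + self.rx, self.cz - self.rz, self.cz + self.rz)

    def inflate(self, width: float) -> "Ellipse":
        return Ellipse(self.cx, self.cz, self.rx + width, self.rz + width)


@dataclass(frozen=True)
class Rect:
    x0: float
    x1: float
    z0: float
    z1: float

    def contains(self, x: np.ndarray, z: np.ndarray) -> np.ndarray:
        return (x >= self.x0) & (x < self.x1) & (z >= self.z0) & (z < self.z1)

    @property
    def area(self) -> float:
        return (self.x1 - self.x0) * (self.z1 - self.z0)

    @property
    def bbox(self) -> tuple:
        return (self.x0, self.x1, self.z0, self.z1)


@dataclass(frozen=True)
class HeterogeneityField:
    """Smooth random modulation of scatterer statistics within a region.

    A zero-mean field ``g(x, z)`` built from randomly placed signed Gaussian
    bumps (correlation length ``correlation_length``) modulates the local
    scatterer density by ``1 + density_amplitude * g`` (via thinning) and the
    local scatterer radius by ``1 + radius_amplitude * g``.  The realization
    is drawn from the simulation seed, so identical (spec, seed) pairs give
    identical media.
    """

    density_amplitude: float = 0.0
    radius_amplitude: float = 0.0
    correlation_length: float = 3.5e-3

    def __post_init__(self) -> None:
        if not (0.0 <= self.density_amplitude < 1.0):
            raise ValueError("density_amplitude must lie in [0, 1)")
        if not (0.0 <= self.radius_amplitude < 1.0):
            raise ValueError("radius_amplitude must lie in [0, 1)")


@dataclass(frozen=True)
class Region:
    """Scatterer population on a geometric support.

    ``density`` is the areal scatterer number density in the imaging plane
    (1/m^2, an areal proxy for the volumetric density), ``radius_mean`` /
    ``radius_sd`` the scatterer radius distribution (m) and ``contrast`` the
    relative acoustic impedance contrast (dimensionless).  ``holes`` are
    geometries carved out of the support (assumed fully inside it).
    """

    name: str
    geometry: Ellipse | Rect
    density: float
    radius_mean: float
    radius_sd: float
    contrast: float
    holes: tuple = ()
    heterogeneity: HeterogeneityField | None = None

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError("density must be positive")
        if self.radius_mean <= 0 or self.radius_sd < 0:
            raise ValueError("radius_mean > 0 and radius_sd >= 0 required")

    def contains(self, x: np.ndarray, z: np.ndarray) -> np.ndarray:
        inside = self.geometry.contains(x, z)
        for h in self.holes:
            inside &= ~h.contains(x, z)
        return inside

    @property
    def area(self) -> float:
        return max(self.geometry.area - sum(h.area for h in self.holes), 0.0)


@dataclass(frozen=True)
class PhantomSpec:
    """A complete phantom: regions plus bulk acoustic properties.

    ``attenuation`` is the one-way amplitude attenuation coefficient in
    dB/MHz/cm; ``sound_speed`` in m/s.
    """

    name: str
    regions: tuple
    attenuation: float
    sound_speed: float = 1540.0

    def __post_init__(self) -> None:
        if self.attenuation < 0:
            raise ValueError("attenuation must be non-negative")

    def region(self, name: str) -> Region:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(name)

    def truth(self) -> dict:
        """Ground-truth scatterer statistics, for estimator-recovery scoring."""
        return {
            "attenuation_db_mhz_cm": self.attenuation,
            "sound_speed_m_s": self.sound_speed,
            "regions": {
                r.name: {
                    "density_per_m2": r.density,
                    "radius_mean_m": r.radius_mean,
                    "radius_sd_m": r.radius_sd,
                    "contrast": r.contrast,
                    "backscatter_proxy": r.density * r.contrast**2,
                }
                for r in self.regions
            },
        }


# ---------------------------------------------------------------------------
# Factories
# ---------------------------------------------------------------------------

#: Reference-phantom scatterer defaults: dense sub-resolution microspheres.
_REFERENCE_DENSITY = 1.0e8
_REFERENCE_RADIUS = 25.0e-6
_REFERENCE_RADIUS_SD = 2.0e-6


def make_reference_phantom_spec(
    transducer: TransducerSpec | None = None,
) -> PhantomSpec:
    """Uniform calibration phantom: 0.786 dB/MHz/cm, 1540 m/s.

    A single homogeneous region of 25 um-radius scatterers at 1e8/m^2 areal
    density and unit impedance contrast fills the whole frame.
    """
    t = transducer or TransducerSpec()
    body = Region(
        name="reference",
        geometry=Rect(0.0, t.lateral_extent, 0.0, t.axial_extent),
        density=_REFERENCE_DENSITY,
        radius_mean=_REFERENCE_RADIUS,
        radius_sd=_REFERENCE_RADIUS_SD,
        contrast=1.0,
    )
    return PhantomSpec(
        name="reference",
        regions=(body,),
        attenuation=REFERENCE_ATTENUATION_DB_MHZ_CM,
        sound_speed=REFERENCE_SOUND_SPEED_M_S,
    )


# Class-conditional tumour defaults.  Non-responders: elevated
# density*contrast^2 in core and margin, smaller scatterers, margin
# statistically similar to core, homogeneous core.  Responders: lower
# backscatter, larger scatterers, core distinct from margin, patchy core.
# Radii keep the scatterer diameter inside the 80-182 um range seen for
# breast lobules.  Densities are areal (1/m^2); attenuation in dB/MHz/cm.
TUMOUR_CLASS_DEFAULTS: dict = {
    "NR": {
        "core": dict(density=1.5e8, radius=45e-6, radius_sd=4e-6, contrast=1.30),
        "margin": dict(density=1.4e8, radius=47e-6, radius_sd=4e-6, contrast=1.25),
        "background": dict(density=0.8e8, radius=55e-6, radius_sd=5e-6, contrast=1.00),
        "attenuation": 1.0,
        "core_heterogeneity": HeterogeneityField(0.18, 0.09, 3.5e-3),
        "margin_heterogeneity": HeterogeneityField(0.14, 0.07, 3.5e-3),
    },
    "R": {
        "core": dict(density=0.8e8, radius=65e-6, radius_sd=6e-6, contrast=0.90),
        "margin": dict(density=1.1e8, radius=55e-6, radius_sd=5e-6, contrast=1.10),
        "background": dict(density=0.8e8, radius=55e-6, radius_sd=5e-6, contrast=1.00),
        "attenuation": 1.0,
        "core_heterogeneity": HeterogeneityField(0.50, 0.25, 3.5e-3),
        "margin_heterogeneity": HeterogeneityField(0.30, 0.15, 3.5e-3),
    },
}

#: Default tumour core semi-axes (m): a roughly 2 cm elliptical lesion.
_CORE_RX = 1.1e-2
_CORE_RZ = 0.9e-2
#: Width of the margin ring carved around the core (m).
_MARGIN_WIDTH = 5.0e-3


def make_tumour_phantom(
    response_class: str,
    seed: int,
    transducer: TransducerSpec | None = None,
    overrides: dict | None = None,
) -> tuple[PhantomSpec, Ellipse]:
    """Build a two-class tumour phantom and its core ROI geometry.

    The phantom holds an elliptical core (~2 cm) centred laterally at
    mid-frame, a 5-mm surrounding ring, and background tissue.  ``seed``
    only jitters the core centre slightly (the scatterer realization is
    drawn at simulation time); the same (class, seed) always returns an
    identical spec.  ``overrides`` may replace any entry of
    :data:`TUMOUR_CLASS_DEFAULTS` for the chosen class.
    """
    if response_class not in ("R", "NR"):
        raise ValueError("response_class must be 'R' or 'NR'")
    t = transducer or TransducerSpec()
    params = dict(TUMOUR_CLASS_DEFAULTS[response_class])
    if overrides:
        params.update(overrides)

    rng = np.random.default_rng(seed)
    # Small reproducible anatomical jitter of the lesion position.
    jx = rng.uniform(-2e-3, 2e-3)
    jz = rng.uniform(-2e-3, 2e-3)
    core = Ellipse(t.lateral_extent / 2 + jx, t.axial_extent * 0.45 + jz, _CORE_RX, _CORE_RZ)
    outer = core.inflate(_MARGIN_WIDTH)

    def mk(name, geometry, holes, p, het=None):
        return Region(
            name=name,
            geometry=geometry,
            holes=holes,
            density=p["density"],
            radius_mean=p["radius"],
            radius_sd=p["radius_sd"],
            contrast=p["contrast"],
            heterogeneity=het,
        )

    regions = (
        mk("core", core, (), params["core"], params.get("core_heterogeneity")),
        mk("margin", outer, (core,), params["margin"], params.get("margin_heterogeneity")),
        mk(
            "background",
            Rect(0.0, t.lateral_extent, 0.0, t.axial_extent),
            (outer,),
            params["background"],
        ),
    )
    spec = PhantomSpec(
        name=f"tumour_{response_class}_{seed}",
        regions=regions,
        attenuation=params["attenuation"],
        sound_speed=t.sound_speed,
    )
    return spec, core


def core_mask_for_phantom(core: Ellipse, transducer: TransducerSpec) -> np.ndarray:
    """Rasterize a core ellipse onto the RF sample grid (axial x lines)."""
    t = transducer
    z = (np.arange(t.n_samples) + 0.5) * t.axial_sample_spacing
    x = (np.arange(t.n_lines) + 0.5) * t.line_spacing
    zz, xx = np.meshgrid(z, x, indexing="ij")
    return core.contains(xx, zz)
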