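"""Synthetic specimens with known elemental composition.

A :class:`Phantom` is the simulated ground truth every scan strategy is
exercised against: one non-negative 2-D concentration field per element, a
transmission field in [0, 1] (the STXM signal), and a simple detector model
that turns concentrations into an expected fluorescence rate spectrum.

The forward model is deliberately minimal.  Each element emits a single
Gaussian line; the expected count rate in channel ``ch`` at pixel ``(r, c)``
is

    rate[ch] = background_rate
             + sum_e  concentration_e(r, c) * yield_scale_e * g_e[ch]

where ``g_e`` is the element's line profile evaluated at channel-centre
energies and renormalised so that ``sum(g_e) == 1``.  The summed line
contribution over all channels therefore equals ``concentration * yield_scale``
exactly, independent of how the line width compares to the channel width.
Physical attenuation, fluorescence yields, detector solid angle and pile-up
are out of scope: transmission is an independent stored field used only as a
gating signal.

Grid coordinates are 0-based ``(row, col)``, row-major, pixel centres;
physical step size never enters the math.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

from .errors import ConfigError

__all__ = [
    "ElementSpec",
    "DetectorModel",
    "Phantom",
    "RegionSpec",
    "PhantomConfig",
    "generate_phantom",
    "expected_xrf_rate",
    "three_element_demo",
    "load_phantom_config",
]


@dataclass(frozen=True)
class ElementSpec:
    """One emission line of one element.

    Parameters
    ----------
    name:
        Element label (e.g. ``"Si"`` or a surrogate like ``"red"``).
    line_energy:
        Line centre in keV; must be positive.
    peak_sigma:
        Gaussian line width (sigma) in keV; must be positive.
    yield_scale:
        Expected counts/s emitted into the whole line per unit concentration
        at unit dwell; must be non-negative.
    """

    name: str
    line_energy: float
    peak_sigma: float
    yield_scale: float

    def __post_init__(self) -> None:
        if self.line_energy <= 0:
            raise ConfigError(f"element {self.name!r}: line_energy must be > 0")
        if self.peak_sigma <= 0:
            raise ConfigError(f"element {self.name!r}: peak_sigma must be > 0")
        if self.yield_scale < 0:
            raise ConfigError(f"element {self.name!r}: yield_scale must be >= 0")


@dataclass(frozen=True)
class DetectorModel:
    """Multi-channel analyser model: linear energy axis plus flat continuum.

    ``channel_energies()[ch] = offset + gain * ch`` (channel centres, keV);
    ``background_rate`` is a flat continuum in counts/s/channel.
    """

    n_channels: int
    gain: float
    offset: float = 0.0
    background_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ConfigError("detector: n_channels must be >= 1")
        if self.gain <= 0:
            raise ConfigError("detector: gain must be > 0 (energy axis must increase)")
        if self.background_rate < 0:
            raise ConfigError("detector: background_rate must be >= 0")

    def channel_energies(self) -> np.ndarray:
        return self.offset + self.gain * np.arange(self.n_channels)

    def line_profile(self, element: ElementSpec) -> np.ndarray:
        """Discrete unit-sum Gaussian profile of ``element``'s line.

        The Gaussian is evaluated at channel-centre energies and renormalised
        by its discrete sum, so the per-line total rate is exact regardless of
        peak width versus channel width.  A line falling entirely outside the
        recorded energy range degenerates to the nearest channel.
        """
        e = self.channel_energies()
        g = np.exp(-0.5 * ((e - element.line_energy) / element.peak_sigma) ** 2)
        s = g.sum()
        if s <= 0 or not np.isfinite(s):
            g = np.zeros(self.n_channels)
            g[int(np.argmin(np.abs(e - element.line_energy)))] = 1.0
            return g
        return g / s


@dataclass
class Phantom:
    """Simulated specimen: per-element concentration fields + transmission.

    Invariants: all concentration values >= 0, transmission in [0, 1], all
    fields share ``shape``.
    """

    elements: list[ElementSpec]
    detector: DetectorModel
    concentration: dict[str, np.ndarray]
    transmission: np.ndarray
    _profiles: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        shape = self.transmission.shape
        if len(shape) != 2:
            raise ConfigError("transmission must be a 2-D field")
        names = {e.name for e in self.elements}
        if set(self.concentration) != names:
            raise ConfigError("concentration fields must match the element list")
        for name, conc in self.concentration.items():
            if conc.shape != shape:
                raise ConfigError(f"concentration field {name!r} shape mismatch")
            if np.any(conc < 0):
                raise ConfigError(f"concentration field {name!r} has negative values")
        if np.any(self.transmission < 0) or np.any(self.transmission > 1):
            raise ConfigError("transmission values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.transmission.shape  # type: ignore[return-value]

    def element(self, name: str) -> ElementSpec:
        for e in self.elements:
            if e.name == name:
                return e
        raise KeyError(name)

    def line_profile(self, name: str) -> np.ndarray:
        """Cached discrete line profile for element ``name``."""
        if name not in self._profiles:
            self._profiles[name] = self.detector.line_profile(self.element(name))
        return self._profiles[name]


def expected_xrf_rate(phantom: Phantom, pos: tuple[int, int]) -> np.ndarray:
    """Expected fluorescence rate spectrum (counts/s per channel) at ``pos``.

    Linear in every concentration field; the summed contribution of one line
    over all channels equals ``concentration * yield_scale`` exactly.

    Raises
    ------
    IndexError
        If ``pos`` lies outside the phantom grid.
    """
    r, c = pos
    rows, cols = phantom.shape
    if not (0 <= r < rows and 0 <= c < cols):
        raise IndexError(f"position {pos} outside grid {phantom.shape}")
    rate = np.full(phantom.detector.n_channels, phantom.detector.background_rate, float)
    for e in phantom.elements:
        conc = phantom.concentration[e.name][r, c]
        if conc > 0 and e.yield_scale > 0:
            rate += conc * e.yield_scale * phantom.line_profile(e.name)
    return rate


# ---------------------------------------------------------------------------
# Configuration-driven generation


@dataclass(frozen=True)
class RegionSpec:
    """One painted region of a phantom.

    ``geometry`` is ``"rectangle"`` (``rows``/``cols`` half-open ``[start,
    stop)`` bounds) or ``"disk"`` (``center`` = (row, col), ``radius`` in
    pixels; a pixel belongs to the disk when its centre lies within
    ``radius``).  ``transmission``, if given, overrides the substrate
    transmission inside the region.
    """

    geometry: str
    element: str
    concentration: float
    transmission: float | None = None
    rows: tuple[int, int] | None = None
    cols: tuple[int, int] | None = None
    center: tuple[float, float] | None = None
    radius: float | None = None

    def pixel_mask(self, shape: tuple[int, int], label: str) -> np.ndarray:
        """Boolean membership mask; raises ConfigError if the region leaves the grid."""
        n_rows, n_cols = shape
        if self.geometry == "rectangle":
            if self.rows is None or self.cols is None:
                raise ConfigError(f"region {label}: rectangle needs rows and cols")
            r0, r1 = self.rows
            c0, c1 = self.cols
            if not (0 <= r0 < r1 <= n_rows and 0 <= c0 < c1 <= n_cols):
                raise ConfigError(f"region {label}: rectangle outside grid {shape}")
            mask = np.zeros(shape, bool)
            mask[r0:r1, c0:c1] = True
            return mask
        if self.geometry == "disk":
            if self.center is None or self.radius is None:
                raise ConfigError(f"region {label}: disk needs center and radius")
            cr, cc = self.center
            rr, cc_grid = np.meshgrid(
                np.arange(-int(np.ceil(self.radius)) + int(np.floor(cr)),
                          int(np.floor(self.radius)) + int(np.ceil(cr)) + 1),
                np.arange(-int(np.ceil(self.radius)) + int(np.floor(cc)),
                          int(np.floor(self.radius)) + int(np.ceil(cc)) + 1),
                indexing="ij",
            )
            inside = (rr - cr) ** 2 + (cc_grid - cc) ** 2 <= self.radius**2
            if np.any(inside & ((rr < 0) | (rr >= n_rows) | (cc_grid < 0) | (cc_grid >= n_cols))):
                raise ConfigError(f"region {label}: disk outside grid {shape}")
            mask = np.zeros(shape, bool)
            mask[rr[inside], cc_grid[inside]] = True
            return mask
        raise ConfigError(f"region {label}: unknown geometry {self.geometry!r}")

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ConfigError(f"region ({self.element}): concentration must be >= 0")
        if self.transmission is not None and not (0 <= self.transmission <= 1):
            raise ConfigError(f"region ({self.element}): transmission must be in [0, 1]")


@dataclass(frozen=True)
class PhantomConfig:
    """Declarative phantom description: substrate + painted regions.

    ``seed`` drives the optional multiplicative log-normal texture
    (``texture_sigma`` > 0) and nothing else; generation is deterministic
    given the full config.
    """

    shape: tuple[int, int]
    detector: DetectorModel
    elements: tuple[ElementSpec, ...]
    substrate_element: str
    substrate_concentration: float
    substrate_transmission: float = 1.0
    regions: tuple[RegionSpec, ...] = ()
    seed: int = 0
    texture_sigma: float = 0.0

    def __post_init__(self) -> None:
        names = {e.name for e in self.elements}
        if self.substrate_element not in names:
            raise ConfigError(f"substrate element {self.substrate_element!r} not in element list")
        for i, reg in enumerate(self.regions):
            if reg.element not in names:
                raise ConfigError(f"region {i} ({reg.element!r}): element not in element list")
        if self.substrate_concentration < 0:
            raise ConfigError("substrate concentration must be >= 0")
        if not (0 <= self.substrate_transmission <= 1):
            raise ConfigError("substrate transmission must be in [0, 1]")
        if self.shape[0] < 1 or self.shape[1] < 1:
            raise ConfigError("shape must be positive")


def generate_phantom(config: PhantomConfig) -> Phantom:
    """Build the :class:`Phantom` described by ``config``.

    Deterministic given the config, including its seed.  Region
    concentrations add on top of the substrate; region transmissions
    overwrite it (later regions win where regions overlap).
    """
    shape = config.shape
    conc = {e.name: np.zeros(shape) for e in config.elements}
    conc[config.substrate_element] += config.substrate_concentration
    transmission = np.full(shape, float(config.substrate_transmission))
    for i, reg in enumerate(config.regions):
        mask = reg.pixel_mask(shape, label=f"{i} ({reg.element!r})")
        conc[reg.element][mask] += reg.concentration
        if reg.transmission is not None:
            transmission[mask] = reg.transmission
    if config.texture_sigma > 0:
        rng = np.random.default_rng(config.seed)
        for name in conc:
            conc[name] *= np.exp(rng.normal(0.0, config.texture_sigma, shape))
    return Phantom(
        elements=list(config.elements),
        detector=config.detector,
        concentration=conc,
        transmission=transmission,
    )


def load_phantom_config(path) -> PhantomConfig:
    """Read a :class:`PhantomConfig` from a YAML file (schema in the README)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return phantom_config_from_dict(raw)


def phantom_config_from_dict(raw: Mapping) -> PhantomConfig:
    try:
        det = DetectorModel(**raw["detector"])
        elements = tuple(ElementSpec(**e) for e in raw["elements"])
        regions = tuple(
            RegionSpec(
                geometry=r["geometry"],
                element=r["element"],
                concentration=r["concentration"],
                transmission=r.get("transmission"),
                rows=tuple(r["rows"]) if "rows" in r else None,
                cols=tuple(r["cols"]) if "cols" in r else None,
                center=tuple(r["center"]) if "center" in r else None,
                radius=r.get("radius"),
            )
            for r in raw.get("regions", ())
        )
        sub = raw["substrate"]
        return PhantomConfig(
            shape=tuple(raw["shape"]),
            detector=det,
            elements=elements,
            substrate_element=sub["element"],
            substrate_concentration=sub["concentration"],
            substrate_transmission=sub.get("transmission", 1.0),
            regions=regions,
            seed=raw.get("seed", 0),
            texture_sigma=raw.get("texture_sigma", 0.0),
        )
    except KeyError as exc:
        raise ConfigError(f"phantom config missing key: {exc}") from exc
    except TypeError as exc:
        raise ConfigError(f"phantom config malformed: {exc}") from exc


# ---------------------------------------------------------------------------
# Built-in demo specimen


def three_element_demo() -> Phantom:
    """5x5 demo specimen with three spectrally separable surrogate elements.

    A grey substrate covers every pixel; a red rectangle (6 pixels) and a blue
    disk (5 pixels) sit on disjoint regions.  The three emission lines are
    placed so their +/-3 sigma ROI windows do not overlap, which makes
    ROI-count thresholds able to identify each region unambiguously.  Used by
    the multi-element priority-dwell scan, whose canonical settings expose the
    red region for 1.2 s, the blue for 0.6 s and bare substrate for 0.2 s.
    """
    det = DetectorModel(n_channels=64, gain=0.05, offset=0.0, background_rate=0.0)
    elements = (
        ElementSpec("grey", line_energy=1.0, peak_sigma=0.05, yield_scale=10.0),
        ElementSpec("blue", line_energy=1.7, peak_sigma=0.05, yield_scale=10.0),
        ElementSpec("red", line_energy=2.6, peak_sigma=0.05, yield_scale=10.0),
    )
    config = PhantomConfig(
        shape=(5, 5),
        detector=det,
        elements=elements,
        substrate_element="grey",
        substrate_concentration=1.0,
        substrate_transmission=0.9,
        regions=(
            RegionSpec("rectangle", "red", concentration=3.0, transmission=0.5,
                       rows=(0, 2), cols=(2, 5)),
            RegionSpec("disk", "blue", concentration=2.0, transmission=0.7,
                       center=(3.0, 1.0), radius=1.2),
        ),
    )
    return generate_phantom(config)
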