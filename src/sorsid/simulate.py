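"""Two-layer SORS forward simulator.

Emulates the measurement physics at the level needed to exercise the
analysis chain: each acquisition channel is a linear mixture of a container
profile (surface layer) and a fluid spectrum (subsurface layer), with the
offset channel enriched in the subsurface contribution,

    zero   = a_z * container + b_z * fluid + noise
    offset = a_o * container + b_o * fluid + noise,

subject to the SORS enrichment condition b_o/a_o > b_z/a_z.  Component
spectra are rendered as sums of pseudo-Voigt bands; fluids are volume-
fraction-weighted component mixtures; containers are either broad
fluorescence envelopes (glasses) or sharp Raman band sets (polymers).

Band positions in the bundled component library are plausible constants for
the named chemicals (the methanol marker at 1034 cm^-1 and the potassium
acetate marker at 926 cm^-1 are anchored to the values used throughout the
package); all downstream tests rely only on the library's internal
consistency, not on literature-grade accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    DegenerateInputError,
    SORSMeasurement,
    SampleRecord,
    Spectrum,
    WavenumberAxis,
)

__all__ = [
    "DEFAULT_AXIS",
    "PeakSpec",
    "ComponentSpectrumDef",
    "FluidRecipe",
    "ContainerDef",
    "MixingModel",
    "NoiseModel",
    "Scenario",
    "COMPONENT_LIBRARY",
    "CONTAINER_LIBRARY",
    "CALIBRATION_CLASSES",
    "EXCIPIENT_GROUPS",
    "pseudo_voigt",
    "render_component",
    "render_container",
    "mix_fluid",
    "build_recipe",
    "simulate_measurement",
    "generate_calibration_set",
    "generate_cohort",
    "default_cohort_scenarios",
]

# 600-1900 cm^-1 at 2 cm^-1 spacing: covers the 750-1800 analysis window
# with margin for baseline fitting and band tails.
DEFAULT_AXIS = WavenumberAxis(np.linspace(600.0, 1900.0, 651))


# ---------------------------------------------------------------------------
# Band and component definitions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeakSpec:
    """One pseudo-Voigt band.

    shape_mix is the Gaussian fraction (1 = pure Gaussian, 0 = Lorentzian).
    ``shifts`` marks the band as concentration-sensitive: its center moves by
    the parent component's ``shift_coefficient`` per unit co-solute fraction.
    """

    center: float
    width: float  # FWHM, cm^-1
    amplitude: float = 1.0
    shape_mix: float = 0.7
    shifts: bool = False

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("peak width must be > 0")
        if self.amplitude < 0:
            raise ValueError("peak amplitude must be >= 0")
        if not 0.0 <= self.shape_mix <= 1.0:
            raise ValueError("shape_mix must lie in [0, 1]")


@dataclass(frozen=True)
class ComponentSpectrumDef:
    """A pure component: its band set, an optional concentration-dependent
    band shift, and a relative Raman scattering strength (signal per unit
    volume fraction relative to the library average — strong scatterers
    like the formaldehyde/methylene-glycol system punch above their
    volume)."""

    name: str
    peaks: tuple[PeakSpec, ...]
    shift_coefficient: float = 0.0  # cm^-1 per unit co-solute fraction
    strength: float = 1.0

    def __post_init__(self):
        if not self.peaks:
            raise ValueError(f"component {self.name!r} needs at least one peak")
        if self.strength <= 0:
            raise ValueError(f"component {self.name!r} needs strength > 0")


@dataclass(frozen=True)
class FluidRecipe:
    """Named fluid as (component, volume fraction) pairs summing to 1."""

    label: str
    components: tuple[tuple[str, float], ...]

    def __post_init__(self):
        fracs = np.array([f for _, f in self.components], dtype=float)
        if np.any(fracs < 0) or np.any(fracs > 1):
            raise ValueError(f"{self.label}: fractions must lie in [0, 1]")
        if abs(fracs.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"{self.label}: fractions sum to {fracs.sum():.6f}, not 1"
            )


@dataclass(frozen=True)
class ContainerDef:
    material: str
    peaks: tuple[PeakSpec, ...]  # broad bands = fluorescence envelope
    intensity_scale: float = 1.0

    def __post_init__(self):
        if not self.peaks:
            raise ValueError(f"container {self.material!r} needs a profile")
        if self.intensity_scale < 0:
            raise ValueError("intensity_scale must be >= 0")


@dataclass(frozen=True)
class MixingModel:
    """Layer weights for the two channels; defaults give qualitative SORS
    contrast (surface-dominated zero, subsurface-enriched offset)."""

    zero_container_frac: float = 0.8
    zero_fluid_frac: float = 0.2
    offset_container_frac: float = 0.3
    offset_fluid_frac: float = 0.7

    def __post_init__(self):
        vals = (
            self.zero_container_frac,
            self.zero_fluid_frac,
            self.offset_container_frac,
            self.offset_fluid_frac,
        )
        if any(v < 0 for v in vals):
            raise ValueError("mixing fractions must be >= 0")
        # subsurface enrichment: b_o/a_o > b_z/a_z, written division-free
        if not (
            self.offset_fluid_frac * self.zero_container_frac
            > self.zero_fluid_frac * self.offset_container_frac
        ):
            raise ValueError(
                "offset channel must be enriched in the fluid layer "
                "(b_o/a_o > b_z/a_z)"
            )


@dataclass(frozen=True)
class NoiseModel:
    """Detector and background noise.

    shot_scale is counts per unit intensity (Poisson); read_sd is additive
    Gaussian in intensity units; a random polynomial of order drift_order
    with coefficient sd drift_sd models slow background drift; the fluid
    itself can carry a broad fluorescence envelope.

    The default counts scale puts a 1%-level fluid component a few standard
    deviations above the per-pixel shot noise, matching the demonstrated
    ability of through-container Raman to reveal low-level (1-2%)
    formaldehyde additions.
    """

    shot_scale: float = 1.0e5
    read_sd: float = 0.001
    drift_order: int = 3
    drift_sd: float = 0.01
    fluid_fluorescence_scale: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if min(self.shot_scale, self.read_sd, self.drift_sd,
               self.fluid_fluorescence_scale) < 0 or self.drift_order < 0:
            raise ValueError("noise scales must be >= 0")

    @property
    def is_null(self) -> bool:
        """True when every stochastic term is switched off."""
        return self.shot_scale == 0 and self.read_sd == 0 and self.drift_sd == 0

    def off(self) -> "NoiseModel":
        return replace(self, shot_scale=0.0, read_sd=0.0, drift_sd=0.0,
                       fluid_fluorescence_scale=0.0)


NOISE_OFF = NoiseModel().off()


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def pseudo_voigt(x: np.ndarray, center: float, fwhm: float,
                 gauss_frac: float) -> np.ndarray:
    """Unit-height pseudo-Voigt: eta*Gaussian + (1-eta)*Lorentzian."""
    d = (x - center) / fwhm
    gauss = np.exp(-4.0 * np.log(2.0) * d * d)
    lorentz = 1.0 / (1.0 + 4.0 * d * d)
    return gauss_frac * gauss + (1.0 - gauss_frac) * lorentz


def _render_peaks(peaks: Sequence[PeakSpec], axis: WavenumberAxis,
                  shift: float = 0.0) -> np.ndarray:
    x = axis.values
    y = np.zeros_like(x)
    for p in peaks:
        c = p.center + (shift if p.shifts else 0.0)
        y += p.amplitude * pseudo_voigt(x, c, p.width, p.shape_mix)
    return y


def render_component(definition: ComponentSpectrumDef, axis: WavenumberAxis,
                     shift: float = 0.0) -> Spectrum:
    """Render a component's band set, unit-normalized to max 1."""
    x = axis.values
    for p in definition.peaks:
        c = p.center + (shift if p.shifts else 0.0)
        if c - 3 * p.width < x[0] or c + 3 * p.width > x[-1]:
            warnings.warn(
                f"{definition.name}: band at {c:g} cm^-1 (FWHM {p.width:g}) "
                f"extends beyond the axis [{x[0]:g}, {x[-1]:g}]",
                stacklevel=2,
            )
    y = _render_peaks(definition.peaks, axis, shift)
    peak = y.max()
    if peak > 0:
        y = y / peak
    return Spectrum(axis, y, {"component": definition.name, "channel": "component"})


def render_container(container: ContainerDef, axis: WavenumberAxis) -> Spectrum:
    """Render a container profile scaled by its intensity_scale."""
    y = _render_peaks(container.peaks, axis)
    peak = y.max()
    if peak > 0:
        y = y / peak
    return Spectrum(
        axis,
        container.intensity_scale * y,
        {"material": container.material, "channel": "container"},
    )


def mix_fluid(recipe: FluidRecipe,
              library: Mapping[str, ComponentSpectrumDef],
              axis: WavenumberAxis) -> Spectrum:
    """Volume-fraction-weighted sum of rendered components.

    Bands flagged as concentration-sensitive are shifted by
    shift_coefficient * (co-solute fraction), i.e. by how much of the mixture
    is *not* that component — the mechanism behind e.g. the ethanol OH-band
    position tracking water content.
    """
    y = np.zeros(len(axis))
    for name, frac in recipe.components:
        if name not in library:
            raise KeyError(f"{recipe.label}: unknown component {name!r}")
        comp = library[name]
        shift = comp.shift_coefficient * (1.0 - frac)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rendered = render_component(comp, axis, shift=shift)
        y += frac * comp.strength * rendered.intensity
    return Spectrum(axis, y, {"fluid": recipe.label, "channel": "fluid"})


# ---------------------------------------------------------------------------
# Bundled component / container libraries
# ---------------------------------------------------------------------------

def _comp(name, peaks, shift_coefficient=0.0, strength=1.0):
    return ComponentSpectrumDef(
        name=name,
        peaks=tuple(PeakSpec(*p) if isinstance(p, tuple) else p for p in peaks),
        shift_coefficient=shift_coefficient,
        strength=strength,
    )


COMPONENT_LIBRARY: dict[str, ComponentSpectrumDef] = {
    d.name: d
    for d in [
        _comp("water", [(1640, 95, 1.0, 0.8)]),
        _comp(
            "ethanol",
            [
                (883, 18, 1.0, 0.6),
                (1052, 20, 0.55, 0.6),
                (1095, 20, 0.50, 0.6),
                (1275, 24, 0.35, 0.6),
                (1454, 28, 0.50, 0.6),
                PeakSpec(1620, 120, 0.25, 1.0, shifts=True),
            ],
            shift_coefficient=-40.0,
        ),
        _comp(
            "methanol",
            [(1034, 18, 1.0, 0.6), (1110, 22, 0.35, 0.6), (1452, 26, 0.30, 0.6)],
        ),
        _comp(
            "glycerol",
            [
                (850, 20, 0.90, 0.6),
                (922, 20, 0.70, 0.6),
                (1060, 24, 0.85, 0.6),
                (1112, 24, 0.60, 0.6),
                (1260, 28, 0.50, 0.6),
                (1465, 30, 1.00, 0.6),
            ],
        ),
        # strong scatterer: a 1% admixture must remain detectable against
        # percent-level ethanol concentration differences, the sensitivity
        # through-container Raman demonstrably achieves for formaldehyde
        _comp(
            "formaldehyde",
            [(907, 18, 1.0, 0.6), (1046, 20, 0.50, 0.6), (1492, 26, 0.70, 0.6)],
            strength=2.5,
        ),
        _comp(
            "phenoxetol",
            [(1000, 16, 1.0, 0.6), (1245, 24, 0.50, 0.6), (1600, 22, 0.80, 0.6)],
        ),
        _comp(
            "picric_acid",
            [
                (820, 18, 0.60, 0.6),
                (943, 18, 0.80, 0.6),
                (1337, 26, 1.00, 0.6),
                (1550, 26, 0.50, 0.6),
            ],
        ),
        _comp(
            "ethylene_glycol",
            [
                (865, 20, 1.00, 0.6),
                (1060, 24, 0.70, 0.6),
                (1090, 24, 0.60, 0.6),
                (1270, 26, 0.40, 0.6),
                (1460, 30, 0.60, 0.6),
            ],
        ),
        _comp("potassium_acetate", [(926, 16, 1.0, 0.6), (1415, 26, 0.80, 0.6)]),
        _comp(
            "acetic_acid",
            [(893, 18, 1.0, 0.6), (1282, 24, 0.60, 0.6), (1432, 28, 0.50, 0.6)],
        ),
        _comp("potassium_nitrate", [(1050, 14, 1.0, 0.6)]),
        # quaternary-ammonium preservative outside the calibration chemistry
        _comp(
            "dowicil",
            [(970, 18, 1.0, 0.6), (1180, 22, 0.60, 0.6), (1520, 26, 0.50, 0.6)],
        ),
    ]
}


def _cont(material, peaks, scale):
    return ContainerDef(
        material=material,
        peaks=tuple(PeakSpec(*p) for p in peaks),
        intensity_scale=scale,
    )


# Glasses: broad fluorescence envelopes; polymers: sharp Raman bands over a
# weak fluorescence pedestal.  Envelope shapes are chosen so the three glass
# families are separable while remaining featureless at Raman bandwidths.
CONTAINER_LIBRARY: dict[str, ContainerDef] = {
    c.material: c
    for c in [
        # the three glass families peak at clearly different emission
        # positions (below, inside and above the analysis window), the
        # premise behind fluorescence-based glass discrimination; each
        # polymer carries its own weaker fluorescence pedestal under its
        # sharp Raman bands
        _cont("borosilicate", [(1100, 450, 1.0, 1.0)], 3.0),
        _cont("soda_lime", [(1700, 600, 1.0, 1.0)], 3.5),
        _cont("lead_glass", [(780, 420, 1.0, 1.0)], 3.0),
        _cont(
            "pmma",
            [
                (812, 16, 1.0, 0.6),
                (968, 18, 0.4, 0.6),
                (1450, 26, 0.6, 0.6),
                (1728, 22, 0.9, 0.6),
                (1550, 550, 0.25, 1.0),
            ],
            1.5,
        ),
        _cont(
            "ldpe",
            [
                (1063, 14, 0.8, 0.6),
                (1130, 14, 0.7, 0.6),
                (1296, 16, 1.0, 0.6),
                (1440, 24, 0.8, 0.6),
                (900, 500, 0.2, 1.0),
            ],
            1.5,
        ),
        _cont(
            "pp",
            [
                (809, 14, 1.0, 0.6),
                (841, 14, 0.9, 0.6),
                (973, 16, 0.7, 0.6),
                (1152, 16, 0.5, 0.6),
                (1330, 18, 0.4, 0.6),
                (1458, 24, 0.6, 0.6),
                (1200, 650, 0.3, 1.0),
            ],
            1.5,
        ),
    ]
}


# Calibration classes.  Each entry lists non-water excipients with a
# (lo, hi) volume-fraction range (point values as lo == hi); water takes the
# complement.  C1-C13 follow the mock-fluid calibration table; C14-C20 are
# stand-in recipes for the named historic formulations (Steedman's,
# Kaiserling III, Bouin's variants) whose full compositions are not
# tabulated — they are artifact-defined, internally consistent stand-ins.
CALIBRATION_CLASSES: dict[str, list[tuple[str, float, float]]] = {
    "C1": [("glycerol", 0.05, 0.05)],
    "C2": [("glycerol", 0.35, 0.35)],
    "C3": [("glycerol", 0.65, 0.65)],
    "C4": [("ethanol", 0.50, 0.60)],
    "C5": [("ethanol", 0.70, 0.80)],
    "C6": [("ethanol", 0.95, 0.95), ("methanol", 0.03, 0.03)],
    "C7": [("ethanol", 0.70, 0.70), ("methanol", 0.05, 0.05)],
    "C8": [("ethanol", 0.70, 0.70), ("methanol", 0.10, 0.10)],
    "C9": [("ethanol", 0.50, 0.50), ("formaldehyde", 0.02, 0.02)],
    "C10": [("ethanol", 0.70, 0.70), ("formaldehyde", 0.01, 0.01)],
    "C11": [("formaldehyde", 0.04, 0.05)],
    "C12": [("formaldehyde", 0.04, 0.04), ("methanol", 0.015, 0.02)],
    "C13": [("formaldehyde", 0.01, 0.01)],
    # ---- stand-ins for named historic recipes ----
    "C14": [("methanol", 0.10, 0.10)],
    "C15": [("formaldehyde", 0.10, 0.10)],
    "C16": [("phenoxetol", 0.05, 0.05), ("glycerol", 0.05, 0.05)],  # Steedman's
    "C17": [("formaldehyde", 0.04, 0.04), ("potassium_nitrate", 0.03, 0.03),
            ("glycerol", 0.30, 0.30)],  # Kaiserling III
    "C18": [("formaldehyde", 0.10, 0.10), ("picric_acid", 0.012, 0.012),
            ("acetic_acid", 0.05, 0.05)],  # Bouin's, aqueous
    "C19": [("ethanol", 0.75, 0.75), ("formaldehyde", 0.05, 0.05),
            ("picric_acid", 0.01, 0.01)],  # Bouin's, alcoholic
    "C20": [("glycerol", 0.35, 0.35), ("formaldehyde", 0.02, 0.02)],
}

# Dominant excipient per class; replicate-level disagreement within one
# group is "ambiguous", not "failed".
EXCIPIENT_GROUPS: dict[str, str] = {
    "C1": "glycerol", "C2": "glycerol", "C3": "glycerol",
    "C4": "ethanol", "C5": "ethanol", "C6": "ethanol", "C7": "ethanol",
    "C8": "ethanol", "C9": "ethanol", "C10": "ethanol",
    "C11": "formaldehyde", "C12": "formaldehyde", "C13": "formaldehyde",
    "C14": "methanol", "C15": "formaldehyde", "C16": "phenoxetol",
    "C17": "glycerol", "C18": "formaldehyde", "C19": "ethanol",
    "C20": "glycerol",
}


def build_recipe(label: str,
                 spec: Sequence[tuple[str, float, float]] | None = None,
                 rng: np.random.Generator | None = None,
                 midpoint: bool = False,
                 level: float | None = None,
                 rel_jitter: float = 0.02) -> FluidRecipe:
    """Materialize a class definition into a concrete recipe.

    Each class is modeled as one prepared mock solution at its tabulated
    composition (the midpoint of a printed range): with an ``rng``, every
    excipient fraction carries a small relative preparation variability
    (uniform within ±rel_jitter); ``level`` in [0, 1] instead picks a point
    across a printed range (a deliberate concentration series); ``midpoint``
    forces the exact nominal value.  Water takes the complement.
    """
    if spec is None:
        spec = CALIBRATION_CLASSES[label]
    comps: list[tuple[str, float]] = []
    total = 0.0
    for name, lo, hi in spec:
        mid = 0.5 * (lo + hi)
        if midpoint or (rng is None and level is None):
            frac = mid
        elif level is not None:
            frac = lo + float(level) * (hi - lo)
        else:
            frac = float(np.clip(
                mid * (1.0 + rng.uniform(-rel_jitter, rel_jitter)), 0.0, 1.0
            ))
        comps.append((name, frac))
        total += frac
    if total > 1.0 + 1e-9:
        raise ValueError(f"{label}: excipients exceed 100%")
    comps.append(("water", round(1.0 - total, 12)))
    return FluidRecipe(label=label, components=tuple(comps))


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

_FLUO_CENTER, _FLUO_WIDTH = 1200.0, 800.0


def _apply_noise(clean: np.ndarray, noise: NoiseModel,
                 rng: np.random.Generator, x01: np.ndarray) -> np.ndarray:
    y = clean.copy()
    if noise.drift_sd > 0:
        coeffs = rng.normal(0.0, noise.drift_sd, noise.drift_order + 1)
        y = y + np.polynomial.polynomial.polyval(x01, coeffs)
    if noise.shot_scale > 0:
        y = rng.poisson(np.clip(y, 0.0, None) * noise.shot_scale) / noise.shot_scale
    if noise.read_sd > 0:
        y = y + rng.normal(0.0, noise.read_sd, y.size)
    return np.clip(y, 0.0, None)


def simulate_measurement(
    recipe: FluidRecipe,
    container: ContainerDef,
    mixing: MixingModel = MixingModel(),
    noise: NoiseModel = NoiseModel(),
    axis: WavenumberAxis = DEFAULT_AXIS,
    library: Mapping[str, ComponentSpectrumDef] = COMPONENT_LIBRARY,
    sample_id: str = "SIM",
    replicate_id: str = "r1",
    offset_distance: float = 5.5,
    extra_fluid: np.ndarray | None = None,
) -> SORSMeasurement:
    """Simulate one zero/offset pair.

    ``extra_fluid`` is an optional additive perturbation to the fluid layer
    (specimen interference, contaminant bands), in fluid intensity units.
    """
    fluid = mix_fluid(recipe, library, axis).intensity.copy()
    if noise.fluid_fluorescence_scale > 0:
        fluid = fluid + noise.fluid_fluorescence_scale * pseudo_voigt(
            axis.values, _FLUO_CENTER, _FLUO_WIDTH, 1.0
        )
    if extra_fluid is not None:
        fluid = fluid + np.asarray(extra_fluid, dtype=float)
    cont = render_container(container, axis).intensity
    a_z, b_z = mixing.zero_container_frac, mixing.zero_fluid_frac
    a_o, b_o = mixing.offset_container_frac, mixing.offset_fluid_frac
    zero_clean = a_z * cont + b_z * fluid
    offset_clean = a_o * cont + b_o * fluid

    rng = np.random.default_rng(noise.seed)
    x01 = (axis.values - axis.values[0]) / (axis.values[-1] - axis.values[0])
    zero_y = _apply_noise(zero_clean, noise, rng, x01)
    offset_y = _apply_noise(offset_clean, noise, rng, x01)

    truth = {
        "true_fluid": recipe.label,
        "true_container": container.material,
        "sample_id": sample_id,
        "replicate_id": replicate_id,
    }
    zero = Spectrum(axis, zero_y, {**truth, "channel": "zero"})
    offset = Spectrum(axis, offset_y, {**truth, "channel": "offset"})
    return SORSMeasurement(
        sample_id=sample_id,
        replicate_id=replicate_id,
        zero=zero,
        offset=offset,
        offset_distance=offset_distance,
    )


def generate_calibration_set(
    class_recipes: Mapping[str, Sequence[tuple[str, float, float]]] | None = None,
    n_replicates: int = 6,
    container: ContainerDef | None = None,
    mixing: MixingModel = MixingModel(),
    noise: NoiseModel = NoiseModel(),
    axis: WavenumberAxis = DEFAULT_AXIS,
    seed: int = 0,
) -> list[tuple[str, SORSMeasurement]]:
    """Labeled calibration measurements: n_replicates per class.

    Mock fluids are measured through a single reference vial (borosilicate
    by default).  Each class is one prepared solution at its tabulated
    composition; replicates model repeat measurements across days, so they
    carry independent noise and a small (±2% relative) re-preparation
    variability.  With a null noise model replicates are identical.
    """
    if class_recipes is None:
        class_recipes = CALIBRATION_CLASSES
    labels = list(class_recipes)
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate class labels")
    if len(labels) < 2:
        raise ValueError("need at least 2 classes")
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates per class")
    if container is None:
        container = CONTAINER_LIBRARY["borosilicate"]
    ss = np.random.SeedSequence(seed)
    out: list[tuple[str, SORSMeasurement]] = []
    for label in labels:
        for rep in range(n_replicates):
            child = ss.spawn(1)[0]
            recipe = build_recipe(
                label, class_recipes[label],
                rng=np.random.default_rng(child.spawn(1)[0]),
                midpoint=noise.is_null,
            )
            rep_seed = int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
            m = simulate_measurement(
                recipe,
                container,
                mixing=mixing,
                noise=replace(noise, seed=rep_seed),
                axis=axis,
                sample_id=f"CAL-{label}",
                replicate_id=f"r{rep + 1}",
            )
            out.append((label, m))
    return out


# ---------------------------------------------------------------------------
# Cohort scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Scenario:
    """One simulated historic sample.

    ``recipe`` may be a calibration class label or a bespoke FluidRecipe (the
    latter typically out-of-calibration).  ``interferents`` injects extra
    bands into the fluid layer (specimen Raman contributions, contaminants);
    ``fluorescence_boost`` adds extra broad fluid fluorescence.
    """

    sample_id: str
    recipe: str | FluidRecipe
    container: str = "soda_lime"
    n_replicates: int = 3
    in_calibration: bool = True
    nominal: bool = True  # midpoint composition; False draws range jitter
    fluorescence_boost: float = 0.0
    interferents: tuple[PeakSpec, ...] = ()
    expected_label: str = ""

    def __post_init__(self):
        if not 1 <= self.n_replicates <= 3:
            raise ValueError("replicate count must be 1-3")
        if self.container not in CONTAINER_LIBRARY:
            raise ValueError(f"undefined container {self.container!r}")


def generate_cohort(
    scenarios: Sequence[Scenario],
    seed: int = 0,
    mixing: MixingModel = MixingModel(),
    noise: NoiseModel = NoiseModel(),
    axis: WavenumberAxis = DEFAULT_AXIS,
) -> tuple[list[SampleRecord], pd.DataFrame]:
    """Simulate a cohort and its ground-truth table."""
    ids = [s.sample_id for s in scenarios]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate sample ids in scenario list")
    ss = np.random.SeedSequence(seed)
    records: list[SampleRecord] = []
    truth_rows = []
    for scen in scenarios:
        child = ss.spawn(1)[0]
        # one jar holds one fluid: composition jitter (if any) is drawn per
        # sample, replicates differ only in measurement noise; the default
        # is the nominal class midpoint — a jar sitting at the edge of a
        # concentration-range class is a deliberately ambiguous scenario,
        # not a routine one
        if isinstance(scen.recipe, FluidRecipe):
            recipe = scen.recipe
        else:
            recipe = build_recipe(
                scen.recipe,
                rng=np.random.default_rng(child.spawn(1)[0]),
                midpoint=scen.nominal or noise.is_null,
            )
        measurements = []
        for rep in range(scen.n_replicates):
            rep_ss = child.spawn(1)[0]
            extra = None
            if scen.interferents:
                extra = _render_peaks(scen.interferents, axis)
            rep_noise = replace(
                noise,
                seed=int(rep_ss.generate_state(1, dtype=np.uint32)[0] % (2**31)),
                fluid_fluorescence_scale=(
                    noise.fluid_fluorescence_scale + scen.fluorescence_boost
                ),
            )
            measurements.append(
                simulate_measurement(
                    recipe,
                    CONTAINER_LIBRARY[scen.container],
                    mixing=mixing,
                    noise=rep_noise,
                    axis=axis,
                    sample_id=scen.sample_id,
                    replicate_id=f"r{rep + 1}",
                    extra_fluid=extra,
                )
            )
        true_label = (
            (scen.recipe if isinstance(scen.recipe, str) else scen.recipe.label)
            if scen.in_calibration
            else "OUT_OF_SET"
        )
        records.append(
            SampleRecord(
                sample_id=scen.sample_id,
                expected_label=scen.expected_label or true_label,
                measurements=measurements,
            )
        )
        truth_rows.append(
            {
                "sample_id": scen.sample_id,
                "true_fluid": true_label,
                "true_container": scen.container,
                "perturbed": bool(scen.interferents) or scen.fluorescence_boost > 0,
            }
        )
    return records, pd.DataFrame(truth_rows)


def write_cohort(
    records: Sequence[SampleRecord],
    truth: pd.DataFrame | None,
    outdir,
) -> "Path":
    """Write a simulated cohort to disk: csv2col spectra, manifest CSV and
    (when given) truth CSV.  Returns the manifest path."""
    from pathlib import Path

    from .core import write_spectrum

    outdir = Path(outdir)
    spec_dir = outdir / "spectra"
    spec_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        for m in rec.measurements:
            zname = f"{m.sample_id}_{m.replicate_id}_zero.csv"
            oname = f"{m.sample_id}_{m.replicate_id}_offset.csv"
            write_spectrum(m.zero, spec_dir / zname)
            write_spectrum(m.offset, spec_dir / oname)
            rows.append(
                {
                    "sample_id": m.sample_id,
                    "replicate_id": m.replicate_id,
                    "zero_path": f"spectra/{zname}",
                    "offset_path": f"spectra/{oname}",
                    "expected_label": rec.expected_label,
                    "offset_mm": m.offset_distance,
                }
            )
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    if truth is not None:
        truth.to_csv(outdir / "truth.csv", index=False)
    return manifest


def default_cohort_scenarios(n_samples: int = 46) -> list[Scenario]:
    """A 46-sample mock cohort: 40 in-calibration fluids cycling through the
    C1-C13 classes and all six container materials, plus 6 out-of-calibration
    fluids (quaternary-ammonium preservative, ethylene-glycol mixtures,
    phenoxetol top-ups) that a sound classifier must refuse to label."""
    classes = [f"C{i}" for i in range(1, 14)]
    materials = list(CONTAINER_LIBRARY)
    n_out = max(0, min(6, n_samples - 40)) if n_samples >= 46 else max(0, n_samples - 40)
    n_in = n_samples - (6 if n_samples >= 46 else n_out)
    scenarios = [
        Scenario(
            sample_id=f"A{i + 1}",
            recipe=classes[i % len(classes)],
            container=materials[i % len(materials)],
            n_replicates=2 + (i % 2),
        )
        for i in range(n_in)
    ]
    # formulation-strength unknowns mirroring the distinct out-of-calibration
    # fluids a survey actually refuses (a quaternary-ammonium fixative
    # formulation, glycol mixtures, a phenoxetol top-up, an acetate bath)
    out_recipes = [
        FluidRecipe("dowicil_5", (("dowicil", 0.05), ("water", 0.95))),
        FluidRecipe("dowicil_10", (("dowicil", 0.10), ("water", 0.90))),
        FluidRecipe(
            "formaldehyde_eg",
            (("formaldehyde", 0.04), ("ethylene_glycol", 0.20), ("water", 0.76)),
        ),
        FluidRecipe("eg_35", (("ethylene_glycol", 0.35), ("water", 0.65))),
        FluidRecipe(
            "phenoxetol_formol",
            (("phenoxetol", 0.05), ("formaldehyde", 0.04), ("water", 0.91)),
        ),
        FluidRecipe(
            "acetate_picric",
            (("potassium_acetate", 0.10), ("picric_acid", 0.01), ("water", 0.89)),
        ),
    ]
    for j in range(n_samples - n_in):
        scenarios.append(
            Scenario(
                sample_id=f"A{n_in + j + 1}",
                recipe=out_recipes[j % len(out_recipes)],
                container=materials[(n_in + j) % len(materials)],
                n_replicates=2 + (j % 2),
                in_calibration=False,
            )
        )
    return scenarios
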