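"""Synthetic greenhouse scenes for pea and wheat stress time courses.

Every downstream stage of the pipeline (segmentation, indices, calibration)
is exercised on scenes produced here, so the generator emulates the study
design end to end: two species (pea, wheat), five treatments (control,
drought, 100/200/400 mM NaCl irrigation), measurement days {1, 3, 5, 8,
10, 12}, ten rectangular ROIs per image, a white reflectance standard in
every frame, and a co-registered stack of RGB image + 400-1000 nm
reflectance cube (204 bands) + F0/Fm fluorescence maps + ground-truth
plant mask.

Leaf optics use a deliberately simple absorption model: a smooth baseline
with a near-infrared plateau (~0.5) minus generalized-Gaussian absorption
wells — chlorophyll wells in the red (~680 nm) and blue (~430 nm), a
carotenoid well at ~470 nm — each scaled by the relative pigment content.
Pigment degradation under stress therefore raises reflectance exactly
where chlorophylls and carotenoids absorb, which is what drives the
directionality of every index the pipeline computes (g, ExG, VEG, VARI
and NDVI fall; r rises; b rises under salinity).  Fv/Fm is coupled to a
latent vitality state as ``Fv/Fm = ceiling * vitality`` with a healthy
ceiling of 0.8.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import Rect

SPECIES = ("pea", "wheat")
TREATMENTS = ("control", "drought", "nacl100", "nacl200", "nacl400")
DEFAULT_DAYS = (1, 3, 5, 8, 10, 12)

#: Duration of the stress protocol in days.
STUDY_DURATION = 12

#: Healthy (unstressed) Fv/Fm; Fv/Fm = FVFM_CEILING * vitality.
FVFM_CEILING = 0.8

#: Spectral grid of the simulated hyperspectral camera.
N_BANDS = 204
WAVELENGTH_RANGE = (400.0, 1000.0)


def default_wavelengths() -> np.ndarray:
    return np.linspace(*WAVELENGTH_RANGE, N_BANDS)


# --------------------------------------------------------------------------
# pigment state and stress trajectories


@dataclass(frozen=True)
class PigmentState:
    """Relative pigment contents and latent photosynthetic health, all in [0, 1].

    ``chl`` scales chlorophyll absorption (red + blue wells), ``car`` scales
    carotenoid absorption (blue well), and ``vitality`` drives Fv/Fm.  The
    control state is (1, 1, 1).
    """

    chl: float
    car: float
    vitality: float

    def __post_init__(self) -> None:
        for name in ("chl", "car", "vitality"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


CONTROL_STATE = PigmentState(1.0, 1.0, 1.0)


@dataclass(frozen=True)
class StressScenario:
    """One experimental arm: species, treatment and measurement days."""

    species: str
    treatment: str
    days: tuple[int, ...] = DEFAULT_DAYS

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if not self.days or any(d < 1 or d > STUDY_DURATION for d in self.days):
            raise ValueError(f"days must lie in [1, {STUDY_DURATION}]")


#: Relative severity of each treatment (drives decay rates; ordered
#: nacl100 <= nacl200 <= nacl400 <= drought).
SEVERITY = {"control": 0.0, "nacl100": 0.5, "nacl200": 0.7, "nacl400": 0.95, "drought": 1.0}

#: Maximum relative chlorophyll loss at full severity by day 12.
CHL_MAX_DROP = 0.7
#: Day on which pigment decline begins (RGB indices shift from day 3 on).
CHL_ONSET_DAY = 1
#: Day on which vitality decline begins (Fv/Fm shifts from day 8 on).
VITALITY_ONSET_DAY = 5
#: Carotenoids degrade at half the chlorophyll rate under drought but at
#: the same rate under salinity.
CAR_RATE_RATIO = {"drought": 0.5, "nacl100": 1.0, "nacl200": 1.0, "nacl400": 1.0}


def _ramp(day: float, start: float, end: float) -> float:
    return float(np.clip((day - start) / (end - start), 0.0, 1.0))


def _vitality_max_drop(species: str, treatment: str) -> float:
    # Drought drives wheat Fv/Fm lower (~0.1) than pea (~0.2).
    if species == "wheat" and treatment == "drought":
        return 0.875
    return 0.75


def stress_trajectory(scenario: StressScenario, day: int,
                      control_drift: float = 0.0) -> PigmentState:
    """Pigment/vitality state of one arm on one measurement day.

    Control stays at (1, 1, 1) up to an optional small drift; stressed
    states decay monotonically with day, ordered by treatment severity.
    """
    if day not in scenario.days:
        raise ValueError(f"day {day} not in scenario days {scenario.days}")
    s = SEVERITY[scenario.treatment]
    if s == 0.0:
        if control_drift:
            wiggle = control_drift * 0.5 * (1 - np.cos(2 * np.pi * day / STUDY_DURATION))
            v = float(np.clip(1.0 - wiggle, 0.0, 1.0))
            return PigmentState(v, v, v)
        return CONTROL_STATE
    pigment_ramp = _ramp(day, CHL_ONSET_DAY, STUDY_DURATION)
    chl = 1.0 - CHL_MAX_DROP * s * pigment_ramp
    car = 1.0 - CHL_MAX_DROP * s * CAR_RATE_RATIO[scenario.treatment] * pigment_ramp
    vit_ramp = _ramp(day, VITALITY_ONSET_DAY, STUDY_DURATION)
    vitality = 1.0 - _vitality_max_drop(scenario.species, scenario.treatment) * s * vit_ramp
    return PigmentState(chl, car, vitality)


# --------------------------------------------------------------------------
# leaf and soil optics


@dataclass(frozen=True)
class AbsorptionWell:
    """Generalized-Gaussian absorption well: depth * exp(-0.5 |(l-c)/s|^order).

    ``order = 2`` is a plain Gaussian; higher orders give the flat-topped
    wells needed for broad, nearly saturated absorption bands.

    ``saturation`` models optical thickness (Beer-Lambert saturation): the
    well responds to relative pigment content p as 1 - (1 - p)^saturation,
    so a deep, saturated well (saturation > 1) keeps absorbing until the
    pigment is nearly gone, while a shallow well (saturation = 1) releases
    reflectance linearly as the pigment degrades.
    """

    center: float
    sigma: float
    depth: float
    order: float = 2.0
    saturation: float = 1.0

    def profile(self, wavelengths: np.ndarray) -> np.ndarray:
        u = np.abs((wavelengths - self.center) / self.sigma)
        return self.depth * np.exp(-0.5 * u**self.order)

    def response(self, pigment) -> np.ndarray:
        """Fraction of the full well depth realized at pigment content p."""
        p = np.asarray(pigment, dtype=float)
        return 1.0 - (1.0 - p) ** self.saturation


@dataclass(frozen=True)
class LeafOptics:
    """Baseline-minus-wells leaf reflectance model.

    The baseline rises through a sigmoidal red edge from ``vis_base`` to an
    NIR plateau at ``nir_plateau`` and may carry pigment-independent
    structural bumps (e.g. a blue scattering shoulder); chlorophyll wells
    scale with ``chl``, the carotenoid well with ``car``.  The shallow
    chlorophyll well near 600 nm makes pigment loss raise reflectance at
    570 nm faster than at 531 nm, so PRI falls as pigments degrade.
    """

    vis_base: float = 0.5
    nir_plateau: float = 0.5
    red_edge_center: float = 715.0
    red_edge_width: float = 12.0
    bumps: tuple[AbsorptionWell, ...] = (AbsorptionWell(440.0, 45.0, 0.105),)
    chl_wells: tuple[AbsorptionWell, ...] = (
        AbsorptionWell(680.0, 25.0, 0.43),
        AbsorptionWell(600.0, 40.0, 0.06),
        AbsorptionWell(430.0, 25.0, 0.15),
    )
    car_wells: tuple[AbsorptionWell, ...] = (AbsorptionWell(470.0, 22.0, 0.25),)
    floor: float = 0.01

    def baseline(self, wavelengths: np.ndarray) -> np.ndarray:
        from scipy.special import expit

        edge = expit((wavelengths - self.red_edge_center) / self.red_edge_width)
        base = self.vis_base + (self.nir_plateau - self.vis_base) * edge
        for bump in self.bumps:
            base = base + bump.profile(wavelengths)
        return base

    def absorption(self, wavelengths: np.ndarray, chl, car) -> np.ndarray:
        """Total pigment absorption for pigment contents ``chl``/``car``.

        ``chl``/``car`` may be scalars or (H, W) arrays; the result
        broadcasts to ``chl.shape + wavelengths.shape``.
        """
        chl = np.asarray(chl, dtype=float)
        total = np.zeros(chl.shape + wavelengths.shape)
        for well in self.chl_wells:
            total += well.response(chl)[..., None] * well.profile(wavelengths)
        for well in self.car_wells:
            total += well.response(car)[..., None] * well.profile(wavelengths)
        return total


#: Default optics (pea-like): healthy NDVI ~0.78, pea mask score mid-window.
PEA_OPTICS = LeafOptics()

#: Wheat optics: a broad flat-topped red well drives red reflectance to
#: ~0.03 (deep chlorophyll absorption) so the wheat RGB mask window, whose
#: numerator 0.1*G - R requires G > 10 R, accepts healthy wheat pixels.
WHEAT_OPTICS = LeafOptics(
    vis_base=0.47,
    bumps=(),
    chl_wells=(
        AbsorptionWell(650.0, 57.0, 0.43, order=8.0, saturation=6.0),
        AbsorptionWell(600.0, 40.0, 0.08),
        AbsorptionWell(430.0, 25.0, 0.25),
    ),
    car_wells=(AbsorptionWell(470.0, 22.0, 0.25),),
)

SPECIES_OPTICS = {"pea": PEA_OPTICS, "wheat": WHEAT_OPTICS}


def leaf_reflectance(state: PigmentState, wavelengths,
                     optics: LeafOptics = PEA_OPTICS) -> np.ndarray:
    """Leaf reflectance spectrum in (0, 1] for one pigment state.

    Reflectance decreases with ``chl`` at the red chlorophyll well and with
    ``chl + car`` in the blue; pigment degradation (state -> 0) raises
    reflectance toward the baseline.
    """
    wl = np.asarray(wavelengths, dtype=float)
    lo, hi = WAVELENGTH_RANGE
    if wl.size == 0 or wl.min() < lo or wl.max() > hi:
        raise ValueError(f"wavelengths must lie within [{lo}, {hi}] nm")
    refl = optics.baseline(wl) - optics.absorption(wl, state.chl, state.car)
    return np.clip(refl, optics.floor, 1.0)


def soil_reflectance(wavelengths) -> np.ndarray:
    """Stylized damp-substrate background: flat, slightly rising spectrum."""
    from scipy.special import expit

    wl = np.asarray(wavelengths, dtype=float)
    return 0.22 + 0.05 * expit((wl - 600.0) / 60.0)


# --------------------------------------------------------------------------
# scene rendering


@dataclass(frozen=True)
class SceneLayout:
    """Geometry and noise configuration of one rendered pallet image."""

    height: int = 60
    width: int = 120
    white_patch: Rect = Rect(0, 12, 96, 120)
    plant_region: Rect = Rect(12, 60, 0, 120)
    n_rois: int = 10
    #: Fraction of each ROI covered by the plant blob (truth plant fraction
    #: of the whole frame is ~0.28, inside the 10-60 % design range).
    blob_fraction: float = 0.35
    #: Lognormal per-pixel multiplicative intensity noise (sigma of log).
    noise_sigma: float = 0.05
    #: Per-pixel jitter (s.d.) on chl/car/vitality, emulating within-canopy
    #: biological variability.
    pigment_jitter: float = 0.004
    #: Within-canopy spread of the pigment stress response: each plant pixel
    #: realizes a fraction u ~ Uniform(1 - spread, 1) of the arm's pigment
    #: loss, so part of the canopy stays greener (as real canopies do) and
    #: threshold masks keep finding plant pixels late in the time course.
    stress_spread: float = 1.0
    #: Maximal fluorescence signal level (arbitrary detector units).
    fm_level: float = 2000.0
    fvfm_ceiling: float = FVFM_CEILING

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("image dimensions must be positive")
        shape = (self.height, self.width)
        if not (self.white_patch.within(shape) and self.plant_region.within(shape)):
            raise ValueError("white patch / plant region exceed image bounds")
        if self.white_patch.overlaps(self.plant_region):
            raise ValueError("white patch overlaps the plant region")
        if not 0.0 < self.blob_fraction <= 1.0:
            raise ValueError("blob_fraction must be in (0, 1]")


DEFAULT_LAYOUT = SceneLayout()


@dataclass(frozen=True)
class SceneBundle:
    """Co-registered rasters for one pallet at one time point."""

    rgb: np.ndarray            # (H, W, 3) uint8
    cube: np.ndarray           # (H, W, B) float32 reflectance in [0, 1]
    wavelengths: np.ndarray    # (B,) strictly increasing, nm
    f0_map: np.ndarray         # (H, W) float
    fm_map: np.ndarray         # (H, W) float
    truth_mask: np.ndarray     # (H, W) bool
    white_patch: Rect
    species: str
    treatment: str
    day: int
    layout: SceneLayout = DEFAULT_LAYOUT

    def __post_init__(self) -> None:
        shape = self.truth_mask.shape
        for name in ("rgb", "cube", "f0_map", "fm_map"):
            if getattr(self, name).shape[:2] != shape:
                raise ValueError(f"{name} shape differs from truth mask {shape}")
        if self.cube.shape[2] != self.wavelengths.size:
            raise ValueError("wavelength count must equal band count")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if float(self.cube.min()) < 0 or float(self.cube.max()) > 1:
            raise ValueError("reflectance outside [0, 1]")
        plant = self.truth_mask
        if np.any(self.fm_map[plant] < self.f0_map[plant]) or np.any(self.f0_map < 0):
            raise ValueError("fluorescence maps must satisfy fm >= f0 >= 0 on plants")


def render_rgb(spectrum, wavelengths) -> np.ndarray:
    """Broad-band RGB from reflectance: boxcar means over 600-700 (R),
    500-600 (G) and 400-500 nm (B), scaled to [0, 255], rounded half-up.

    ``spectrum`` may be a vector or an (H, W, B) cube; returns uint8 with a
    trailing channel axis.  A flat reflectance of 1.0 maps to (255, 255, 255).
    """
    wl = np.asarray(wavelengths, dtype=float)
    spec = np.asarray(spectrum, dtype=float)
    if spec.shape[-1] != wl.size:
        raise ValueError("spectrum/wavelength length mismatch")
    if wl.min() > 410.0 or wl.max() < 690.0:
        raise ValueError("spectrum does not cover the 400-700 nm visible range")
    bands = [(600.0, 700.0), (500.0, 600.0), (400.0, 500.0)]  # R, G, B
    channels = []
    for lo, hi in bands:
        sel = (wl >= lo) & (wl <= hi) if hi == 700.0 else (wl >= lo) & (wl < hi)
        if not np.any(sel):
            raise ValueError(f"no spectral bands inside {lo}-{hi} nm")
        channels.append(spec[..., sel].mean(axis=-1))
    stacked = np.stack(channels, axis=-1)
    return np.clip(np.floor(stacked * 255.0 + 0.5), 0, 255).astype(np.uint8)


def _scene_rng(seed: int, scenario: StressScenario, day: int) -> np.random.Generator:
    # Counter-based fan-out: draws depend only on (seed, species, treatment,
    # day), never on the order in which bundles are generated.
    key = (SPECIES.index(scenario.species), TREATMENTS.index(scenario.treatment), day)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _truth_mask(layout: SceneLayout) -> np.ndarray:
    from .segmentation import default_rois

    mask = np.zeros((layout.height, layout.width), dtype=bool)
    rois = default_rois((layout.height, layout.width), layout.n_rois,
                        region=layout.plant_region)
    scale = np.sqrt(layout.blob_fraction)
    for _, rect in rois:
        bh = max(1, int(round(rect.height * scale)))
        bw = max(1, int(round(rect.width * scale)))
        r0 = rect.r0 + (rect.height - bh) // 2
        c0 = rect.c0 + (rect.width - bw) // 2
        mask[r0:r0 + bh, c0:c0 + bw] = True
    return mask


def render_scene(scenario: StressScenario, day: int,
                 layout: SceneLayout = DEFAULT_LAYOUT, seed: int = 0,
                 optics: LeafOptics | None = None) -> SceneBundle:
    """Render one co-registered SceneBundle; deterministic given
    (scenario, day, layout, seed)."""
    if optics is None:
        optics = SPECIES_OPTICS[scenario.species]
    rng = _scene_rng(seed, scenario, day)
    wl = default_wavelengths()
    h, w = layout.height, layout.width
    state = stress_trajectory(scenario, day)
    truth = _truth_mask(layout)

    # Per-pixel pigment state: a heterogeneous response factor u scales the
    # pigment loss (some of the canopy stays greener), plus small jitter.
    # Vitality is spatially uniform up to jitter, so the scene-mean Fv/Fm
    # tracks the arm's trajectory.
    if layout.stress_spread > 0:
        u = 1.0 - layout.stress_spread * rng.random((h, w))
    else:
        u = np.ones((h, w))

    def jittered(value: np.ndarray | float) -> np.ndarray:
        value = np.broadcast_to(np.asarray(value, dtype=float), (h, w))
        if layout.pigment_jitter == 0:
            return value.copy()
        return np.clip(value + rng.normal(0.0, layout.pigment_jitter, (h, w)), 0.0, 1.0)

    chl = jittered(1.0 - u * (1.0 - state.chl))
    car = jittered(1.0 - u * (1.0 - state.car))
    vit = jittered(state.vitality)

    leaf = optics.baseline(wl)[None, None, :] - optics.absorption(wl, chl, car)
    leaf = np.clip(leaf, optics.floor, 1.0)

    cube = np.broadcast_to(soil_reflectance(wl), (h, w, wl.size)).copy()
    cube[truth] = leaf[truth]
    if layout.noise_sigma > 0:
        eta = rng.lognormal(0.0, layout.noise_sigma, (h, w))
        cube *= eta[:, :, None]
    cube[layout.white_patch.slices] = 1.0  # calibration standard is noise-free
    cube = np.clip(cube, 0.0, 1.0).astype(np.float32)

    rgb = render_rgb(cube, wl)

    fm = np.zeros((h, w))
    f0 = np.zeros((h, w))
    eta_f = rng.lognormal(0.0, layout.noise_sigma, (h, w)) if layout.noise_sigma else 1.0
    fm_plant = layout.fm_level * (eta_f[truth] if layout.noise_sigma else 1.0)
    fm[truth] = fm_plant
    f0[truth] = fm[truth] * (1.0 - layout.fvfm_ceiling * vit[truth])

    return SceneBundle(
        rgb=rgb, cube=cube, wavelengths=wl, f0_map=f0, fm_map=fm,
        truth_mask=truth, white_patch=layout.white_patch,
        species=scenario.species, treatment=scenario.treatment, day=day,
        layout=layout,
    )


# --------------------------------------------------------------------------
# full experiment


@dataclass(frozen=True)
class ExperimentConfig:
    """Study design: which arms to simulate and with what scene layout."""

    species: tuple[str, ...] = SPECIES
    treatments: tuple[str, ...] = TREATMENTS
    days: tuple[int, ...] = DEFAULT_DAYS
    layout: SceneLayout = DEFAULT_LAYOUT

    def __post_init__(self) -> None:
        if not self.species or not self.treatments or not self.days:
            raise ValueError("species, treatments and days must be non-empty")
        for sp in self.species:
            if sp not in SPECIES:
                raise ValueError(f"unknown species {sp!r}")
        for tr in self.treatments:
            if tr not in TREATMENTS:
                raise ValueError(f"unknown treatment {tr!r}")


def generate_experiment(config: ExperimentConfig = ExperimentConfig(),
                        seed: int = 0) -> tuple[list[SceneBundle], pd.DataFrame]:
    """One SceneBundle per (species, treatment, day), plus a manifest table.

    The default design yields 2 species x 5 treatments x 6 days = 60 bundles.
    The manifest is independent of the seed; pixel noise is not.
    """
    bundles: list[SceneBundle] = []
    rows = []
    for sp in config.species:
        for tr in config.treatments:
            scenario = StressScenario(sp, tr, config.days)
            for day in config.days:
                bundle = render_scene(scenario, day, config.layout, seed)
                bundles.append(bundle)
                rows.append(
                    {
                        "scene_id": f"{sp}_{tr}_d{day:02d}",
                        "species": sp,
                        "treatment": tr,
                        "day": day,
                        "n_rois": config.layout.n_rois,
                        "plant_pixels": int(bundle.truth_mask.sum()),
                    }
                )
    manifest = pd.DataFrame(rows)
    return bundles, manifest
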