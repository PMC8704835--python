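"""Seeded generator of ground-truth Raman scenes.

The instrument data the method was designed for is not distributable, so
this module emulates its statistical structure: a measured spectrum is
built as ``x = t + b + n`` with

* ``t = S g + Kbg y_bg`` — narrow Raman peaks (widths < 350 cm^-1) from a
  reference signature library plus a background drawn from a material
  subspace,
* ``b`` — a smooth positive baseline drawn from one of several families,
  some inside the span of the broad-Gaussian basis (exact-recovery
  regime) and some outside it (polynomials, sigmoids, exponential
  decays) to exercise robustness,
* ``n`` — heteroscedastic Gaussian noise ``N(0, gamma * diag(sigma_i^2))``
  with a smooth shot-noise-like variance profile.

Default grid: 375-3500 cm^-1 with 947 channels.  The demo signature
library holds seven synthetic agents (a nerve-agent-like target with a
CH-stretch main peak at 2700-3100 cm^-1 and fingerprint subpeaks at
500-1700 cm^-1, plus six distractors); the demo background materials are
two narrow atmospheric gas lines (O2 ~1556, N2 ~2331 cm^-1) and four
broad substrate signatures (concrete, asphalt, grass, soil archetypes).
All spectra are synthetic stand-ins, not measured references.
"""
from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Mapping, Sequence

import numpy as np

from .background import build_background_basis
from .core import (
    BackgroundBasis,
    NoiseModel,
    ReferenceLibrary,
    Spectrum,
    WavenumberGrid,
    make_grid,
)
from .gaussian import build_gaussian_basis

__all__ = [
    "PeakSpec",
    "SyntheticScene",
    "StudyConfig",
    "Study",
    "default_grid",
    "simulate_reference",
    "simulate_baseline",
    "simulate_scene",
    "simulate_study",
    "default_noise_model",
    "demo_reference_library",
    "demo_background_materials",
    "BASELINE_FAMILIES",
]


def default_grid() -> WavenumberGrid:
    """375-3500 cm^-1, 947 channels (~3.3 cm^-1 per channel)."""
    return make_grid(375.0, 3500.0, 947)


@dataclass(frozen=True)
class PeakSpec:
    """One Raman peak: center (cm^-1), FWHM (cm^-1, < 350), height, shape."""

    center: float
    width_fwhm: float
    height: float = 1.0
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.width_fwhm <= 0:
            raise ValueError("width_fwhm must be positive")
        if self.height <= 0:
            raise ValueError("height must be positive")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError("shape must be 'gaussian' or 'lorentzian'")

    def profile(self, grid: WavenumberGrid) -> np.ndarray:
        if not (grid.nu_min <= self.center <= grid.nu_max):
            raise ValueError(f"peak center {self.center} lies outside the grid")
        u = (grid.nu - self.center) / self.width_fwhm
        if self.shape == "gaussian":
            return self.height * np.exp(-4.0 * np.log(2.0) * u**2)
        return self.height / (1.0 + 4.0 * u**2)


def simulate_reference(
    grid: WavenumberGrid, peaks: Sequence[PeakSpec], label: str = ""
) -> Spectrum:
    """Sum of peak profiles, normalized to unit maximum."""
    if not peaks:
        raise ValueError("at least one peak required")
    total = np.zeros(grid.p)
    for pk in peaks:
        total += pk.profile(grid)
    return Spectrum(grid, total / total.max(), label=label)


# --- deterministic demo library -------------------------------------------
# Synthetic agent signatures: (center, fwhm, height, shape).  Each has a
# main CH-stretch-region or low-wavenumber main peak and fingerprint
# subpeaks, loosely inspired by organophosphonate / mustard / aromatic /
# phosphorus-halide chemistry but not traceable to any measured spectrum.
_AGENT_PEAKS: dict[str, list[tuple[float, float, float, str]]] = {
    "agent_gf_like": [
        (2930, 120, 1.00, "gaussian"),
        (520, 55, 0.22, "lorentzian"),
        (715, 50, 0.18, "gaussian"),
        (845, 60, 0.28, "gaussian"),
        (1025, 45, 0.20, "lorentzian"),
        (1275, 70, 0.24, "gaussian"),
        (1455, 60, 0.18, "gaussian"),
    ],
    "agent_h_like": [
        (2955, 140, 1.00, "gaussian"),
        (640, 50, 0.30, "gaussian"),
        (700, 45, 0.25, "lorentzian"),
        (1040, 55, 0.20, "gaussian"),
        (1295, 65, 0.22, "gaussian"),
        (1425, 70, 0.18, "gaussian"),
    ],
    "agent_hn_like": [
        (2885, 130, 1.00, "gaussian"),
        (560, 55, 0.20, "gaussian"),
        (890, 50, 0.26, "lorentzian"),
        (1120, 60, 0.22, "gaussian"),
        (1340, 55, 0.20, "gaussian"),
    ],
    "agent_aromatic_like": [
        (3065, 90, 0.80, "gaussian"),
        (1003, 30, 1.00, "lorentzian"),
        (1210, 45, 0.25, "gaussian"),
        (1600, 45, 0.40, "lorentzian"),
        (620, 40, 0.18, "gaussian"),
    ],
    "agent_dmmp_like": [
        (2850, 100, 0.70, "gaussian"),
        (2995, 95, 0.60, "gaussian"),
        (715, 35, 1.00, "lorentzian"),
        (900, 50, 0.25, "gaussian"),
        (1420, 60, 0.18, "gaussian"),
    ],
    "agent_mes_like": [
        (2915, 110, 1.00, "gaussian"),
        (655, 45, 0.35, "lorentzian"),
        (1045, 50, 0.30, "gaussian"),
        (1190, 55, 0.20, "gaussian"),
        (1460, 65, 0.22, "gaussian"),
    ],
    "agent_pcl3_like": [
        (510, 40, 1.00, "lorentzian"),
        (580, 45, 0.45, "gaussian"),
        (860, 55, 0.20, "gaussian"),
        (1250, 80, 0.15, "gaussian"),
        (1760, 70, 0.10, "gaussian"),
    ],
}

# Synthetic background materials: narrow atmospheric gas lines plus broad
# substrate signatures (all peak widths kept under 350 cm^-1).
_MATERIAL_PEAKS: dict[str, list[tuple[float, float, float, str]]] = {
    "oxygen": [(1556, 25, 1.00, "lorentzian")],
    "nitrogen": [(2331, 25, 1.00, "lorentzian")],
    "concrete": [
        (1086, 60, 1.00, "lorentzian"),
        (480, 150, 0.55, "gaussian"),
        (710, 90, 0.30, "gaussian"),
        (3400, 250, 0.20, "gaussian"),
    ],
    "asphalt": [
        (1370, 180, 0.90, "gaussian"),
        (1600, 140, 1.00, "gaussian"),
        (2900, 220, 0.55, "gaussian"),
    ],
    "grass": [
        (2910, 240, 0.80, "gaussian"),
        (1525, 70, 1.00, "lorentzian"),
        (1155, 60, 0.60, "lorentzian"),
        (1005, 40, 0.35, "gaussian"),
    ],
    "soil": [
        (465, 140, 1.00, "gaussian"),
        (1010, 120, 0.55, "gaussian"),
        (1650, 200, 0.35, "gaussian"),
        (3200, 300, 0.25, "gaussian"),
    ],
}


def _library_from_table(
    grid: WavenumberGrid,
    table: Mapping[str, list[tuple[float, float, float, str]]],
    rng: np.random.Generator | None = None,
    center_jitter: float = 5.0,
    width_jitter: float = 0.06,
    height_jitter: float = 0.10,
) -> list[Spectrum]:
    """Evaluate a peak table; with ``rng`` given, jitter peak centers,
    widths and heights to emulate sample/instrument variability."""
    out = []
    for name, peaks in table.items():
        specs = []
        for c, w, h, s in peaks:
            if rng is not None:
                c = c + rng.uniform(-center_jitter, center_jitter)
                w = w * rng.uniform(1 - width_jitter, 1 + width_jitter)
                h = h * rng.uniform(1 - height_jitter, 1 + height_jitter)
                c = min(max(c, grid.nu_min), grid.nu_max)
            specs.append(PeakSpec(c, w, h, s))
        out.append(simulate_reference(grid, specs, label=name))
    return out


def demo_reference_library(grid: WavenumberGrid) -> ReferenceLibrary:
    """Seven synthetic agent signatures, unit-max columns (deterministic)."""
    spectra = _library_from_table(grid, _AGENT_PEAKS)
    return ReferenceLibrary(
        grid,
        np.column_stack([s.values for s in spectra]),
        tuple(_AGENT_PEAKS),
    )


def demo_background_materials(
    grid: WavenumberGrid, rng: np.random.Generator | None = None
) -> list[Spectrum]:
    """Six synthetic background material signatures.

    Deterministic archetypes by default; with ``rng`` given, peak
    positions/widths/heights are jittered to emulate the shot-to-shot
    variability of real substrate measurements.
    """
    return _library_from_table(grid, _MATERIAL_PEAKS, rng=rng)


# --- baselines -------------------------------------------------------------

BASELINE_FAMILIES = (
    "poly",
    "sigmoid",
    "broad_gauss_mix",
    "exp_decay",
    "fluor_humps",
)


def simulate_baseline(
    grid: WavenumberGrid,
    family: str,
    params: Mapping | None = None,
    rng_seed: int | np.random.Generator | None = None,
) -> Spectrum:
    """Draw a smooth positive baseline curve.

    Families: ``poly`` (random positive Bernstein polynomial), ``sigmoid``
    (broad logistic ramp), ``exp_decay`` (exponential decay) and
    ``fluor_humps`` (fluorescence-like: blue-edge exponential tail plus
    1-3 broad humps of FWHM 500-1100 cm^-1) — all outside the span of the
    broad-Gaussian basis — and ``broad_gauss_mix`` (a combination of the
    L-vector basis itself, in span by construction, for exact-recovery
    checks).  ``amplitude`` sets the curve maximum for every family.
    """
    params = dict(params or {})
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    amp = float(params.pop("amplitude", 1.0))
    if amp < 0:
        raise ValueError("amplitude must be non-negative")
    u = (grid.nu - grid.nu_min) / grid.span
    normalize = False  # randomly drawn shapes get unit maximum before scaling
    if family == "poly":
        degree = int(params.pop("degree", 4))
        weights = params.pop("weights", None)
        if weights is None:
            weights = 0.2 + rng.random(degree + 1)
            normalize = True
        weights = np.asarray(weights, dtype=float)
        if np.any(weights < 0):
            raise ValueError("Bernstein weights must be non-negative")
        from math import comb

        shape = np.zeros(grid.p)
        d = weights.size - 1
        for k, wk in enumerate(weights):
            shape += wk * comb(d, k) * u**k * (1 - u) ** (d - k)
    elif family == "sigmoid":
        center = float(params.pop("center", rng.uniform(grid.nu_min, grid.nu_max)))
        width = float(params.pop("width", rng.uniform(300.0, 700.0)))
        rising = bool(params.pop("rising", rng.random() < 0.5))
        if width <= 0:
            raise ValueError("sigmoid width must be positive")
        z = (grid.nu - center) / width
        shape = 1.0 / (1.0 + np.exp(-z if rising else z)) + 0.1
        normalize = True
    elif family == "exp_decay":
        tau = float(params.pop("tau", rng.uniform(600.0, 1500.0)))
        offset = float(params.pop("offset", 0.1))
        if tau <= 0 or offset < 0:
            raise ValueError("tau must be positive and offset non-negative")
        shape = np.exp(-(grid.nu - grid.nu_min) / tau) + offset
        normalize = True
    elif family == "fluor_humps":
        tau = float(params.pop("tau", rng.uniform(400.0, 1000.0)))
        n_humps = int(params.pop("n_humps", rng.integers(1, 4)))
        if tau <= 0 or n_humps < 0:
            raise ValueError("tau must be positive and n_humps non-negative")
        shape = 0.6 * np.exp(-(grid.nu - grid.nu_min) / tau) + 0.1
        for _ in range(n_humps):
            c = rng.uniform(grid.nu_min, grid.nu_max)
            fwhm = rng.uniform(500.0, 1100.0)
            h = rng.uniform(0.3, 1.0)
            shape += h * np.exp(-4.0 * np.log(2.0) * ((grid.nu - c) / fwhm) ** 2)
        normalize = True
    elif family == "broad_gauss_mix":
        L = int(params.pop("L", 11))
        coeffs = params.pop("coeffs", None)
        basis = build_gaussian_basis(grid, L)
        if coeffs is None:
            coeffs = 0.2 + rng.random(L)
            normalize = True
        coeffs = np.asarray(coeffs, dtype=float)
        if coeffs.size != L:
            raise ValueError("coeffs length must equal L")
        if np.any(coeffs < 0):
            raise ValueError("broad_gauss_mix coefficients must be non-negative")
        shape = basis.matrix @ coeffs
    else:
        raise ValueError(f"unknown baseline family {family!r}; choose from {BASELINE_FAMILIES}")
    if normalize:
        shape = shape / shape.max()
    values = amp * shape
    if params:
        raise ValueError(f"unknown baseline parameters: {sorted(params)}")
    return Spectrum(grid, values, label=f"baseline:{family}")


def default_noise_model(grid: WavenumberGrid, gamma: float = 1.0) -> NoiseModel:
    """Smooth heteroscedastic (shot-noise-like) profile, median std sqrt(gamma)."""
    s = 0.6 + 0.8 * np.exp(-(((grid.nu - 1100.0) / 900.0) ** 2))
    s = s / np.median(s)
    return NoiseModel(sigma_sq=s**2, gamma=gamma)


# --- scenes ----------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticScene:
    """One simulated measurement with all of its ground-truth parts:
    ``x = t + b + n`` exactly, with ``t = S g + Kbg y_bg``."""

    x: Spectrum
    t: Spectrum
    b: Spectrum
    n: Spectrum
    g: np.ndarray
    y_bg: np.ndarray
    seed: int


def simulate_scene(
    grid: WavenumberGrid,
    refs: ReferenceLibrary,
    g: np.ndarray,
    background: BackgroundBasis,
    y_bg: np.ndarray,
    baseline: Spectrum,
    noise: NoiseModel,
    rng_seed: int = 0,
) -> SyntheticScene:
    """Compose one scene; reproducible from ``rng_seed``."""
    grid.require_match(refs.grid, "reference library")
    grid.require_match(background.grid, "background basis")
    grid.require_match(baseline.grid, "baseline")
    g = np.asarray(g, dtype=float)
    y_bg = np.asarray(y_bg, dtype=float)
    if g.size != refs.n_references:
        raise ValueError("g length must equal the number of reference spectra")
    if y_bg.size != background.n_components:
        raise ValueError("y_bg length must equal the number of background components")
    if noise.sigma_sq.size != grid.p:
        raise ValueError("noise model length must equal the channel count")
    rng = np.random.default_rng(rng_seed)
    n = rng.normal(0.0, noise.std)
    t = refs.matrix @ g + background.matrix @ y_bg
    x = t + baseline.values + n
    return SyntheticScene(
        x=Spectrum(grid, x, label=f"scene[{rng_seed}]"),
        t=Spectrum(grid, t, label="raman"),
        b=baseline,
        n=Spectrum(grid, n, label="noise"),
        g=g,
        y_bg=y_bg,
        seed=int(rng_seed),
    )


@dataclass
class StudyConfig:
    """Conditions of a simulated detection study.

    Counts default to the 500 agent / 1000 background protocol; the SNR
    (target main-peak height over median noise std) defaults to 10, a
    regime where the main peak is visible but fingerprint subpeaks sit
    near the noise floor.  Baseline maxima are 0.8-2x the signal peak,
    mixing fluorescence-like and in-span broad-Gaussian curves with other
    out-of-span families.  Background materials are jittered per scene
    (and per training measurement), so the learned background basis never
    matches a scene's background exactly — the model-mismatch floor of
    real measurements.
    """

    n_h1: int = 500
    n_h0: int = 1000
    snr: float = 10.0
    signal_amplitude: float = 1000.0
    background_amplitude: tuple[float, float] = (500.0, 1500.0)
    baseline_rel_amplitude: tuple[float, float] = (0.8, 2.0)
    baseline_mix: dict = field(
        default_factory=lambda: {
            "fluor_humps": 0.35,
            "broad_gauss_mix": 0.20,
            "poly": 0.15,
            "sigmoid": 0.15,
            "exp_decay": 0.15,
        }
    )
    n_training_backgrounds: int = 40
    n_background_components: int = 6
    target_agent: int = 0
    material_jitter: bool = True
    training_corrector: str = "arpls"

    def __post_init__(self) -> None:
        if self.n_h1 < 1 or self.n_h0 < 1:
            raise ValueError("scene counts must be positive")
        if self.snr <= 0 or self.signal_amplitude <= 0:
            raise ValueError("snr and signal_amplitude must be positive")
        for fam in self.baseline_mix:
            if fam not in BASELINE_FAMILIES:
                raise ValueError(f"unknown baseline family {fam!r}")

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "StudyConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(mapping)
        for key in ("background_amplitude", "baseline_rel_amplitude"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


@dataclass
class Study:
    """A generated study: scene lists plus the model matrices they use."""

    h1: list[SyntheticScene]
    h0: list[SyntheticScene]
    references: ReferenceLibrary
    background: BackgroundBasis
    materials: list[Spectrum]
    noise: NoiseModel
    grid: WavenumberGrid
    config: StudyConfig
    seed: int


def simulate_study(
    grid: WavenumberGrid | None = None,
    config: StudyConfig | None = None,
    rng_seed: int = 0,
) -> Study:
    """Generate a full detection study.

    The background basis handed to the fitters is learned the way a field
    system would build it: a training corpus of background-only
    measurements (jittered material mixtures + baseline + noise) is
    baseline-corrected and decomposed by SVD.  Each scene's background is
    an exact positive mixture of its own jittered material draw, so the
    learned basis carries a realistic model-mismatch floor relative to
    the scenes.
    """
    grid = grid or default_grid()
    config = config or StudyConfig()
    rng = np.random.default_rng(rng_seed)

    refs = demo_reference_library(grid)
    materials = demo_background_materials(grid)

    noise_std = config.signal_amplitude / config.snr
    noise = default_noise_model(grid, gamma=noise_std**2)

    families = list(config.baseline_mix)
    probs = np.array([config.baseline_mix[f] for f in families], dtype=float)
    probs = probs / probs.sum()

    def material_matrix() -> np.ndarray:
        mats = demo_background_materials(grid, rng if config.material_jitter else None)
        return np.column_stack([m.values for m in mats])

    def draw_background() -> tuple[BackgroundBasis, np.ndarray]:
        B = material_matrix()
        w = rng.dirichlet(np.ones(B.shape[1]))
        bg_amp = rng.uniform(*config.background_amplitude)
        return BackgroundBasis(grid, B), bg_amp * w

    def draw_baseline() -> Spectrum:
        fam = families[int(rng.choice(len(families), p=probs))]
        amp = config.signal_amplitude * rng.uniform(*config.baseline_rel_amplitude)
        return simulate_baseline(grid, fam, {"amplitude": amp}, rng)

    # training corpus: background-only measurements through the real pipeline
    zero_g = np.zeros(refs.n_references)
    train_scenes = [
        simulate_scene(
            grid, refs, zero_g, *draw_background(), draw_baseline(), noise,
            int(rng.integers(0, 2**31 - 1)),
        )
        for _ in range(config.n_training_backgrounds)
    ]
    background = build_background_basis(
        [s.x for s in train_scenes],
        config.n_background_components,
        corrector=config.training_corrector,
    )

    def draw_scene(has_agent: bool) -> SyntheticScene:
        g = np.zeros(refs.n_references)
        if has_agent:
            g[config.target_agent] = config.signal_amplitude * rng.uniform(0.8, 1.2)
        scene_bg, y_bg = draw_background()
        baseline = draw_baseline()
        seed = int(rng.integers(0, 2**31 - 1))
        return simulate_scene(grid, refs, g, scene_bg, y_bg, baseline, noise, seed)

    h1 = [draw_scene(True) for _ in range(config.n_h1)]
    h0 = [draw_scene(False) for _ in range(config.n_h0)]
    return Study(
        h1=h1,
        h0=h0,
        references=refs,
        background=background,
        materials=materials,
        noise=noise,
        grid=grid,
        config=config,
        seed=int(rng_seed),
    )
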