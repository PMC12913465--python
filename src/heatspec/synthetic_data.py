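"""Synthetic canopy reflectance and physiology generator.

Emulates the paired control (CK) / heat-treatment (T) pot experiment on
a reclaimed-legume canopy: 1-nm spectra 350-1350 nm with a green peak,
red absorption valley, sigmoid red edge (inflection 715-735 nm) and NIR
plateau 0.30-0.55; seven physiological indicators (SPAD, A, gsw, Ci,
Fv'/Fm', qP, qN) coupled to the same latent plant state; three growth
stages with stress intensity increasing from branching to budding.

The generative model is deliberately phenomenological, not radiative
transfer: a latent state (chlorophyll, stress, canopy structure, all in
[0, 1]) drives both the spectrum and the indicators, so downstream band
selection and regression face a recoverable but noisy signal.

Reflectance model, per sample::

    L(l) = 1 / (1 + exp(-(l - l_re) / 10)),  l_re = 715 + 20 * chl
    V(l) = v0 + g * exp(-(l - 550)^2 / (2 * 30^2))
           v0 = 0.08 - 0.04 * chl,  g = 0.06 * (1 - 0.5 * chl)
    P    = 0.30 + 0.15 * structure + 0.08 * stress
    R(l) = V(l) * (1 - L(l)) + P * L(l)

then a smooth multiplicative perturbation (random cubic, controlling
calibration/illumination drift) and i.i.d. additive noise, clipped to
[0, 1].  Under treatment the NIR plateau rises (+0.08 * stress) and
chlorophyll falls, reproducing the observed higher-NIR / lower-pigment
contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, GridRangeError, ValidationError
from .spectra_io import INDICATORS, SampleTable, Spectrum

STAGES = ("branching", "budding", "flowering")

#: (intercept, chlorophyll slope, stress slope, noise sd) per indicator.
#: Stress slopes are negative for all indicators except the
#: non-photochemical quenching coefficient qN, matching the observed
#: direction of every treatment contrast.  Noise sds are 5% of each
#: indicator's plausible range.
DEFAULT_COUPLING: dict[str, tuple[float, float, float, float]] = {
    "SPAD": (20.0, 30.0, -6.0, 1.75),
    "A": (5.0, 18.0, -5.0, 1.0),
    "gsw": (0.05, 0.40, -0.10, 0.022),
    "Ci": (150.0, 130.0, -50.0, 7.5),
    "FvpFmp": (0.30, 0.42, -0.10, 0.022),
    "qP": (0.25, 0.50, -0.15, 0.028),
    "qN": (0.50, 0.50, 0.35, 0.055),
}

#: Stage-dependent treatment stress ranges: effects strengthen from
#: branching to budding and persist through flowering.
DEFAULT_STRESS_RANGES: dict[str, tuple[float, float]] = {
    "branching": (0.1, 0.4),
    "budding": (0.4, 0.8),
    "flowering": (0.5, 0.8),
}

#: Stage baselines for the latent levels: pigment and canopy structure
#: rise into budding, pigment relaxes at flowering while structure
#: (hence the NIR plateau) keeps increasing.
DEFAULT_CHLOROPHYLL_BASE = {"branching": 0.55, "budding": 0.75, "flowering": 0.65}
DEFAULT_STRUCTURE_BASE = {"branching": 0.35, "budding": 0.60, "flowering": 0.70}

#: Measurement dates per stage (the study design: 5 + 5 + 4).
DEFAULT_DATES = {
    "branching": ("05-22", "05-26", "06-01", "06-05", "06-10"),
    "budding": ("06-14", "06-18", "06-23", "06-26", "06-30"),
    "flowering": ("07-05", "07-09", "07-14", "07-18"),
}

_GRID_LO, _GRID_HI = 350.0, 1350.0


@dataclass
class LatentState:
    """Unobserved plant state driving spectrum and physiology."""

    chlorophyll_level: float
    stress_level: float
    stage: str
    structure_level: float

    def __post_init__(self):
        for name in ("chlorophyll_level", "stress_level", "structure_level"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}")


@dataclass
class SimulationConfig:
    """Conditions of one simulated experiment."""

    n_per_group: int = 40
    stages: Sequence[str] = STAGES
    seed: int = 0
    grid_start: float = 350.0
    grid_stop: float = 1350.0
    grid_step: float = 1.0
    noise_sd_additive: float = 0.002
    noise_sd_smooth: float = 0.01
    coupling: Mapping[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COUPLING)
    )
    stress_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_STRESS_RANGES)
    )
    chlorophyll_base: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CHLOROPHYLL_BASE)
    )
    structure_base: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STRUCTURE_BASE)
    )
    chlorophyll_stress_slope: float = 0.35
    latent_sd: float = 0.08

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ConfigError("n_per_group must be >= 2")
        if self.grid_step <= 0:
            raise ConfigError("grid_step must be positive")
        span = self.grid_stop - self.grid_start
        n_steps = span / self.grid_step
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ConfigError("grid_step must divide the grid span")
        if self.noise_sd_additive < 0 or self.noise_sd_smooth < 0:
            raise ConfigError("noise sds must be >= 0")
        for stage in self.stages:
            if stage not in STAGES:
                raise ConfigError(f"unknown stage {stage!r}")

    def grid(self) -> np.ndarray:
        n = int(round((self.grid_stop - self.grid_start) / self.grid_step)) + 1
        return self.grid_start + self.grid_step * np.arange(n)


def reflectance_model(
    grid: np.ndarray, chlorophyll: float, stress: float, structure: float
) -> np.ndarray:
    """Noiseless reflectance for one latent state (vector over grid)."""
    grid = np.asarray(grid, dtype=float)
    l_re = 715.0 + 20.0 * chlorophyll
    logistic = 1.0 / (1.0 + np.exp(-(grid - l_re) / 10.0))
    v0 = 0.08 - 0.04 * chlorophyll
    g = 0.06 * (1.0 - 0.5 * chlorophyll)
    visible = v0 + g * np.exp(-((grid - 550.0) ** 2) / (2.0 * 30.0**2))
    plateau = 0.30 + 0.15 * structure + 0.08 * stress
    return visible * (1.0 - logistic) + plateau * logistic


def red_edge_inflection(chlorophyll: float) -> float:
    """Inflection wavelength of the generating logistic, in nm."""
    return 715.0 + 20.0 * chlorophyll


def simulate_canopy_spectrum(
    latent: LatentState,
    grid: np.ndarray,
    seed,
    noise_sd_additive: float = 0.002,
    noise_sd_smooth: float = 0.01,
) -> Spectrum:
    """One noisy canopy reflectance spectrum for a latent state.

    The smooth perturbation is multiplicative, a random cubic in the
    normalised wavelength coordinate with coefficient sd
    ``noise_sd_smooth / 2`` (typical amplitude about one sd); additive
    noise is i.i.d. Gaussian.  Values are clipped to [0, 1].
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size and (grid.min() < _GRID_LO or grid.max() > _GRID_HI):
        raise GridRangeError(
            f"grid outside supported range [{_GRID_LO:g}, {_GRID_HI:g}] nm"
        )
    if grid.size and np.any(np.diff(grid) <= 0):
        raise ValidationError("grid must be ascending")
    r = reflectance_model(
        grid, latent.chlorophyll_level, latent.stress_level, latent.structure_level
    )
    rng = np.random.default_rng(seed)
    if noise_sd_smooth > 0:
        t = (grid - grid.min()) / max(grid.max() - grid.min(), 1.0) * 2.0 - 1.0
        coeffs = rng.normal(0.0, noise_sd_smooth / 2.0, size=4)
        perturb = coeffs[0] + coeffs[1] * t + coeffs[2] * t**2 + coeffs[3] * t**3
        r = r * (1.0 + perturb)
    if noise_sd_additive > 0:
        r = r + rng.normal(0.0, noise_sd_additive, size=grid.size)
    r = np.clip(r, 0.0, 1.0)
    return Spectrum(grid, r, kind="reflectance",
                    metadata={"stage": latent.stage})


def latent_to_physiology(
    latent: LatentState,
    seed,
    coupling: Mapping[str, tuple[float, float, float, float]] | None = None,
) -> dict[str, float]:
    """Map a latent state to the seven physiological indicators.

    Each indicator is ``intercept + a * chlorophyll + b * stress`` plus
    Gaussian noise, truncated to its physically admissible range
    (non-negative; Fv'/Fm' and qP within [0, 1]).
    """
    coupling = dict(DEFAULT_COUPLING) if coupling is None else coupling
    missing = [k for k in INDICATORS if k not in coupling]
    if missing:
        raise ConfigError(f"coupling missing indicators: {missing}")
    rng = np.random.default_rng(seed)
    out = {}
    for name in INDICATORS:
        intercept, chl_slope, stress_slope, noise_sd = coupling[name]
        v = (
            intercept
            + chl_slope * latent.chlorophyll_level
            + stress_slope * latent.stress_level
        )
        if noise_sd > 0:
            v += rng.normal(0.0, noise_sd)
        v = max(v, 0.0)
        if name in ("FvpFmp", "qP"):
            v = min(v, 1.0)
        out[name] = v
    return out


def _clip01(x: float) -> float:
    return float(min(max(x, 0.0), 1.0))


def draw_latent(config: SimulationConfig, stage: str, group: str,
                rng: np.random.Generator) -> LatentState:
    """Draw one latent state for a stage/group cell."""
    if group == "CK":
        stress = 0.0
    else:
        lo, hi = config.stress_ranges[stage]
        stress = float(rng.uniform(lo, hi))
    chl = _clip01(
        config.chlorophyll_base[stage]
        - config.chlorophyll_stress_slope * stress
        + rng.normal(0.0, config.latent_sd)
    )
    structure = _clip01(
        config.structure_base[stage] + rng.normal(0.0, config.latent_sd)
    )
    return LatentState(chl, stress, stage, structure)


def simulate_experiment(config: SimulationConfig | None = None) -> list[SampleTable]:
    """Simulate the full CK/T, multi-stage experiment.

    Returns one :class:`SampleTable` per configured stage with
    ``n_per_group`` CK and ``n_per_group`` T samples each, spectra and
    physiology aligned by sample id.  Fully reproducible from
    ``config.seed``.
    """
    config = SimulationConfig() if config is None else config
    grid = config.grid()
    root = np.random.SeedSequence(config.seed)
    stage_seeds = root.spawn(len(config.stages))
    tables = []
    for stage, stage_seq in zip(config.stages, stage_seeds):
        dates = DEFAULT_DATES.get(stage, ("d1",))
        rows_spec, rows_phys, rows_meta, ids = [], [], [], []
        latent_rng = np.random.default_rng(stage_seq.spawn(1)[0])
        sample_seqs = stage_seq.spawn(2 * config.n_per_group)
        k = 0
        for group in ("CK", "T"):
            for i in range(config.n_per_group):
                latent = draw_latent(config, stage, group, latent_rng)
                spec_seq, phys_seq = sample_seqs[k].spawn(2)
                k += 1
                spec = simulate_canopy_spectrum(
                    latent, grid, spec_seq,
                    noise_sd_additive=config.noise_sd_additive,
                    noise_sd_smooth=config.noise_sd_smooth,
                )
                phys = latent_to_physiology(latent, phys_seq, config.coupling)
                sid = f"{stage}-{group}-{i:03d}"
                ids.append(sid)
                rows_spec.append(spec.values)
                rows_phys.append(phys)
                rows_meta.append({
                    "group": group,
                    "stage": stage,
                    "date": dates[i % len(dates)],
                    "pot": str(i % 2 + 1),
                    "replicate": "1",
                })
        spectra = pd.DataFrame(np.vstack(rows_spec), index=ids, columns=grid)
        physiology = pd.DataFrame(rows_phys, index=ids)
        metadata = pd.DataFrame(rows_meta, index=ids)
        tables.append(SampleTable(spectra, physiology, metadata, kind="reflectance"))
    return tables


def config_to_dict(config: SimulationConfig) -> dict:
    """Serialisable view of a config (for resolved-config output)."""
    return {
        "n_per_group": config.n_per_group,
        "stages": list(config.stages),
        "seed": config.seed,
        "grid": {
            "start": config.grid_start,
            "stop": config.grid_stop,
            "step": config.grid_step,
        },
        "noise_sd_additive": config.noise_sd_additive,
        "noise_sd_smooth": config.noise_sd_smooth,
        "coupling": {k: list(v) for k, v in config.coupling.items()},
        "stress_ranges": {k: list(v) for k, v in config.stress_ranges.items()},
        "chlorophyll_base": dict(config.chlorophyll_base),
        "structure_base": dict(config.structure_base),
        "chlorophyll_stress_slope": config.chlorophyll_stress_slope,
        "latent_sd": config.latent_sd,
    }


def config_from_dict(data: Mapping) -> SimulationConfig:
    kwargs = dict(data)
    grid = kwargs.pop("grid", None)
    if grid:
        kwargs["grid_start"] = grid["start"]
        kwargs["grid_stop"] = grid["stop"]
        kwargs["grid_step"] = grid["step"]
    if "coupling" in kwargs:
        kwargs["coupling"] = {k: tuple(v) for k, v in kwargs["coupling"].items()}
    if "stress_ranges" in kwargs:
        kwargs["stress_ranges"] = {
            k: tuple(v) for k, v in kwargs["stress_ranges"].items()
        }
    return SimulationConfig(**kwargs)
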