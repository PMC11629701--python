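"""Seeded generators emulating the study's raw data streams.

Three generators, each a pure function of its spec plus a seed:

* ``generate_abundance_series`` — flow-cytometry-like virus/bacteria
  counts for triplicate bottle incubations under three filtration
  treatments, sampled at 0 h, 12 h, 24 h, 48 h, 4 d and 8 d.  The latent
  dynamics come from the food-web model; observation noise is
  multiplicative lognormal (default CV 10%), independent per
  replicate/time/target.
* ``generate_ion_stack`` — Poisson ion-count image stacks with planted
  disk/ellipse particles at prescribed 13C/15N atom fractions.  Expected
  counts per pixel, cycle and mass follow binomial isotopologue
  probabilities (C2 masses pair two carbons; CN masses carry one
  nitrogen); an optional Gaussian blur approximates the ~150 nm primary
  beam.  Exact masks and a per-particle truth table accompany each stack.
* ``generate_protist_table`` — single-cell (c_net, n_net) tables with a
  configurable enrichment mixture and positive C-N correlation, mimicking
  a population in which a subset of protists grazes intensely on
  labelled virions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from virovory.foodweb import (
    DEFAULT_OUTPUT_TIMES,
    FoodwebParameters,
    TreatmentSpec,
    simulate_treatment,
)
from virovory.isotope import (
    NATURAL_13C_ATOM_FRACTION,
    NATURAL_15N_ATOM_FRACTION,
)
from virovory.simsroi import DEFAULT_PIXEL_SIZE_NM, MASS_ORDER, IonImageStack, ROI
from virovory.removalstats import AbundanceSeries

__all__ = [
    "ExperimentSpec",
    "Particle",
    "SceneSpec",
    "generate_abundance_series",
    "generate_ion_stack",
    "generate_protist_table",
]


# ---------------------------------------------------------------------------
# abundance series


@dataclass(frozen=True)
class ExperimentSpec:
    """A simulated size-fractionation bottle experiment.

    Defaults mirror the 8-day bacterial-fraction design: three filtration
    treatments in biological triplicate, an added virus spike of
    ~3e7 ml^-1, sampling at 0, 0.5, 1, 2, 4 and 8 days, and 10% CV
    lognormal counting noise.
    """

    treatments: tuple[str, ...] = ("lt100", "lt1p2", "lt0p1")
    n_replicates: int = 3
    times: tuple[float, ...] = DEFAULT_OUTPUT_TIMES
    params: FoodwebParameters = field(default_factory=FoodwebParameters.table1_defaults)
    virus_spike: float = 3e7
    noise_cv: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.virus_spike <= 0:
            raise ValueError("virus_spike must be positive")


def _lognormal_factors(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    if cv == 0:
        return np.ones(shape)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=0.0, sigma=sigma, size=shape)


def generate_abundance_series(spec: ExperimentSpec) -> list[AbundanceSeries]:
    """Simulate observed virus and bacteria counts for every bottle.

    The latent trajectory per treatment comes from
    :func:`virovory.foodweb.simulate_treatment` with the virus compartment
    reset to ``virus_spike`` after filtration (the added labelled virions
    dominate the pool at t = 0).  Observed counts multiply the latent
    value by independent lognormal factors with the requested CV.
    """
    rng = np.random.default_rng(spec.seed)
    out: list[AbundanceSeries] = []
    for treatment in spec.treatments:
        tspec = TreatmentSpec(
            filtration=treatment,
            duration=max(spec.times),
            output_times=tuple(spec.times),
        )
        traj = simulate_treatment(tspec, spec.params)
        # rescale latent V so V(0) equals the spike while keeping the
        # model's relative removal dynamics
        latent_v = traj.V / traj.V[0] * spec.virus_spike
        latent_b = traj.B
        for rep in range(spec.n_replicates):
            for target, latent in (("virus", latent_v), ("bacteria", latent_b)):
                factors = _lognormal_factors(rng, spec.noise_cv, latent.shape)
                observed = latent * factors
                out.append(
                    AbundanceSeries(
                        treatment=treatment,
                        replicate=f"rep{rep + 1}",
                        times=np.asarray(spec.times, dtype=float),
                        counts=observed,
                        target=target,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# ion image stacks


@dataclass(frozen=True)
class Particle:
    """A planted particle: a disk or axis-aligned ellipse of biomass."""

    center: tuple[float, float]  # (row, col) pixels
    diameter_um: float  # equivalent diameter
    f13C: float = NATURAL_13C_ATOM_FRACTION
    f15N: float = NATURAL_15N_ATOM_FRACTION
    c_density: float = 1.0  # relative to scene yield scalars
    n_density: float = 1.0
    shape: str = "disk"  # disk | ellipse
    aspect: float = 1.0  # row/col semi-axis ratio for ellipses

    def __post_init__(self) -> None:
        if self.diameter_um <= 0:
            raise ValueError("diameter_um must be positive")
        for name in ("f13C", "f15N"):
            f = getattr(self, name)
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.shape not in ("disk", "ellipse"):
            raise ValueError("shape must be 'disk' or 'ellipse'")


@dataclass(frozen=True)
class SceneSpec:
    """Geometry, particles and ion yields for one synthetic acquisition.

    ``yield_c2``/``yield_cn`` are expected total two-carbon / CN ion
    counts per pixel per cycle for unit-density biomass; the background
    contributes ``background_density`` of that.
    """

    shape: tuple[int, int] = (256, 256)
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM
    particles: tuple[Particle, ...] = ()
    background_density: float = 0.01
    background_f13C: float = NATURAL_13C_ATOM_FRACTION
    background_f15N: float = NATURAL_15N_ATOM_FRACTION
    yield_c2: float = 50.0
    yield_cn: float = 200.0
    n_cycles: int = 25
    beam_fwhm_nm: float = 150.0  # 0 disables beam blur
    seed: int = 0

    def __post_init__(self) -> None:
        if self.yield_c2 <= 0 or self.yield_cn <= 0:
            raise ValueError("ion yields must be positive")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        h, w = self.shape
        for p in self.particles:
            r, c = p.center
            if not (0 <= r < h and 0 <= c < w):
                raise ValueError(f"particle center {p.center} outside {self.shape}")


def _particle_mask(p: Particle, shape: tuple[int, int], pixel_size_nm: float) -> np.ndarray:
    rr, cc = np.indices(shape)
    radius_px = (p.diameter_um * 1000.0 / pixel_size_nm) / 2.0
    a = radius_px * np.sqrt(p.aspect)  # row semi-axis
    b = radius_px / np.sqrt(p.aspect)  # col semi-axis
    if p.shape == "disk":
        a = b = radius_px
    dr = rr - p.center[0]
    dc = cc - p.center[1]
    return (dr / a) ** 2 + (dc / b) ** 2 <= 1.0


def generate_ion_stack(
    scene: SceneSpec,
) -> tuple[IonImageStack, dict[str, np.ndarray], pd.DataFrame]:
    """Draw a Poisson ion-image stack with planted ground truth.

    Per pixel, per cycle the expected count for each mass is
    density x yield x isotopologue probability — P(12C2) = (1-f13C)^2 and
    P(13C12C) = 2 f13C (1-f13C) for the carbon dimer, (1-f15N) and f15N
    for the CN masses.  Returns the stack, a dict of exact particle
    masks, and a truth table of planted values.
    """
    h, w = scene.shape
    c_density = np.full(scene.shape, scene.background_density, dtype=float)
    n_density = np.full(scene.shape, scene.background_density, dtype=float)
    f13 = np.full(scene.shape, scene.background_f13C, dtype=float)
    f15 = np.full(scene.shape, scene.background_f15N, dtype=float)
    masks: dict[str, np.ndarray] = {}
    truth_rows = []
    for i, p in enumerate(scene.particles):
        mask = _particle_mask(p, scene.shape, scene.pixel_size_nm)
        pid = f"particle_{i}"
        masks[pid] = mask
        c_density[mask] = p.c_density
        n_density[mask] = p.n_density
        f13[mask] = p.f13C
        f15[mask] = p.f15N
        truth_rows.append(
            {
                "particle_id": pid,
                "center_row": p.center[0],
                "center_col": p.center[1],
                "diameter_um": p.diameter_um,
                "f13C": p.f13C,
                "f15N": p.f15N,
                "c_density": p.c_density,
                "n_density": p.n_density,
                "n_pixels": int(mask.sum()),
            }
        )

    lam = np.empty((len(MASS_ORDER), h, w))
    lam[0] = c_density * scene.yield_c2 * (1.0 - f13) ** 2
    lam[1] = c_density * scene.yield_c2 * 2.0 * f13 * (1.0 - f13)
    lam[2] = n_density * scene.yield_cn * (1.0 - f15)
    lam[3] = n_density * scene.yield_cn * f15
    if scene.beam_fwhm_nm > 0:
        sigma_px = scene.beam_fwhm_nm / (2.354820045 * scene.pixel_size_nm)
        for k in range(lam.shape[0]):
            lam[k] = ndimage.gaussian_filter(lam[k], sigma_px)
    if np.any(lam > 1e6):
        raise ValueError("expected count per pixel-cycle exceeds 1e6; reduce yields")

    rng = np.random.default_rng(scene.seed)
    counts = rng.poisson(
        np.broadcast_to(lam[:, None], (len(MASS_ORDER), scene.n_cycles, h, w))
    ).astype(np.int64)
    stack = IonImageStack(
        counts=counts, pixel_size_nm=scene.pixel_size_nm, dwell_ms=1.0
    )
    return stack, masks, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# protist single-cell isotope tables


def generate_protist_table(
    n_cells: int,
    mixture: Sequence[tuple[float, float, float]] = (
        (0.8, 0.0, 10.0),
        (0.2, 10.0, 85.0),
    ),
    slope: float = 0.9,
    noise_sd: float = 3.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell (c_net, n_net) table with correlated C and N enrichment.

    ``mixture`` lists (weight, low, high) uniform components for n_net
    (percent); by default most cells are weakly enriched and a grazing
    subset spans up to 85%.  c_net = slope * n_net + Gaussian noise,
    clipped to [0, 100).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    weights = np.array([m[0] for m in mixture], dtype=float)
    if np.any(weights < 0) or not np.isclose(weights.sum(), 1.0):
        raise ValueError("mixture weights must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    component = rng.choice(len(weights), size=n_cells, p=weights)
    lows = np.array([m[1] for m in mixture])[component]
    highs = np.array([m[2] for m in mixture])[component]
    n_net = rng.uniform(lows, highs)
    c_net = slope * n_net + (rng.normal(0.0, noise_sd, n_cells) if noise_sd > 0 else 0.0)
    c_net = np.clip(c_net, 0.0, np.nextafter(100.0, 0.0))
    return pd.DataFrame(
        {
            "cell_id": [f"cell_{i}" for i in range(n_cells)],
            "c_net": c_net,
            "n_net": n_net,
        }
    )
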