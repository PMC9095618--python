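"""Bundled optical/geometry profiles.

``full_scale_profile`` mirrors the experimental system: 532 nm laser, a 1920x1080
phase-only SLM demagnified onto a 350 um FIGH-350S facet (~10,000 cores),
target plane 700 um beyond the distal facet.

``desk_profile`` is the default scaled-down study condition used by the
tests and examples: a 64x64 grid at 2 um pitch (128 um window).  The
scale-down preserves the full system's dimensionless ratios rather than its
absolute size: cores keep a ~33% areal fill inside the facet (the facet
diameter scales as 2 r sqrt(n / 0.33), which reproduces the real bundle's
350 um at 10,000 cores of 1 um radius), the core spacing is within ~6% of
the real 3.3 um, and the facet occupies roughly half the grid window as in
the experiment.  In addition (a) one core's diffraction cone at z = 700 um
covers the whole target window, (b) each core disk contains its nearest
pixel center (so phase sampling exactly inverts disk rendering), and
(c) the maximum grating deflection of the 2 um pitch reaches the corners of
the 48x48 content window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mcf import CoreMap, make_synthetic_core_map

__all__ = ["OpticalProfile", "desk_profile", "full_scale_profile"]


@dataclass(frozen=True)
class OpticalProfile:
    """Grid geometry, fiber geometry and propagation distance in microns."""

    shape: tuple[int, int]        # (ny, nx) grid
    pitch_x: float
    pitch_y: float
    wavelength: float
    z: float
    core_radius: float
    min_spacing: float
    n_cores: int
    work_size: tuple[int, int]    # target content window before zero-padding
    facet_diameter: float | None = None   # None: constant-fill rule
    fill_factor: float = 0.33             # areal core fill inside the facet

    def facet_for(self, n_cores: int) -> float:
        """Facet diameter holding ``n_cores`` at the profile's fill factor,
        rounded up to 5 um (matches the real bundle at full scale)."""
        if self.facet_diameter is not None:
            return self.facet_diameter
        d = 2.0 * self.core_radius * np.sqrt(n_cores / self.fill_factor)
        return float(np.ceil(d / 5.0) * 5.0)

    def make_core_map(self, n_cores: int | None = None,
                      seed: int | None = 0) -> CoreMap:
        n = n_cores if n_cores is not None else self.n_cores
        return make_synthetic_core_map(
            n, core_radius=self.core_radius, min_spacing=self.min_spacing,
            facet_diameter=self.facet_for(n), seed=seed)


def desk_profile(shape: tuple[int, int] = (64, 64), n_cores: int = 128) -> OpticalProfile:
    """Scaled-down default conditions (single-CPU friendly)."""
    return OpticalProfile(shape=shape, pitch_x=2.0, pitch_y=2.0,
                          wavelength=0.532, z=700.0,
                          core_radius=1.5, min_spacing=3.5,
                          n_cores=n_cores, work_size=(48, 48))


def full_scale_profile() -> OpticalProfile:
    """Full experimental geometry (configuration only; heavy to simulate)."""
    return OpticalProfile(shape=(1080, 1920), pitch_x=0.4, pitch_y=0.4,
                          wavelength=0.532, z=700.0,
                          core_radius=1.0, min_spacing=3.3,
                          n_cores=10_000, work_size=(512, 512),
                          facet_diameter=350.0)
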