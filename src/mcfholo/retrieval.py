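"""Iterative phase-retrieval baselines: plain GS and the core-tailored Core-GS.

Plain Gerchberg–Saxton alternates between the modulator plane (where a
phase-only constraint forces unit amplitude) and the target plane (where
the measured/target amplitude is imposed), propagating with the band-limited
angular spectrum method in between.  It assumes a continuous phase surface;
when its hologram is sampled by the sparse, randomly placed cores of a
fiber bundle, the aliasing destroys the reconstruction.

Core-GS additionally projects onto the fiber constraint at every iteration:
the facet-plane phase is read at the core centers only and re-rendered as
piston-phase disks on the binary core-map amplitude before propagating.
The returned hologram is the per-core phase vector itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fields import ComplexField, backpropagate, propagate
from .mcf import (CoreHologram, CoreMap, disk_pixel_indices, core_pixel_indices,
                  reconstruct_far_field, sample_core_phases, wrap_phase)
from .metrics import correlation_coefficient

__all__ = ["RetrievalResult", "gs_retrieve", "core_gs_retrieve"]


@dataclass
class RetrievalResult:
    """Outcome of an iterative retrieval run.

    ``hologram`` is a full-grid wrapped phase image for plain GS and a
    :class:`CoreHologram` for Core-GS.  ``cc_trace`` holds the per-iteration
    reconstruction fidelity (empty when trace computation is disabled or
    ``iters == 0``); ``amp_error_trace`` the far-field amplitude residual
    ||  |U| - sqrt(T) ||_2 per iteration.
    """

    hologram: np.ndarray | CoreHologram
    cc_trace: np.ndarray
    amp_error_trace: np.ndarray
    iterations: int


def _initial_phase(shape, seed, init) -> np.ndarray:
    if init == "zero":
        return np.zeros(shape)
    if init == "random":
        rng = np.random.default_rng(seed)
        return rng.uniform(0.0, 2.0 * np.pi, size=shape)
    raise ValueError(f"unknown init {init!r} (expected 'zero' or 'random')")


def _check_target(target) -> np.ndarray:
    target = np.asarray(target, dtype=float)
    if target.ndim != 2:
        raise ValueError("target must be a 2-D intensity image")
    if np.any(target < 0):
        raise ValueError("target intensity must be non-negative")
    return target


def gs_retrieve(target, z: float, pitch_x: float, pitch_y: float,
                wavelength: float, iters: int, seed: int | None = None,
                init: str = "zero", compute_trace: bool = True) -> RetrievalResult:
    """Classic two-plane GS on the full pixel grid.

    Source plane: unit amplitude, free phase (the phase-only hologram).
    Target plane: amplitude sqrt(target), free phase.  With ``iters == 0``
    the initial phase is returned unchanged.
    """
    target = _check_target(target)
    if iters < 0:
        raise ValueError("iters must be >= 0")
    amp_t = np.sqrt(target)
    phase = _initial_phase(target.shape, seed, init)
    cc_trace = np.empty(iters)
    err_trace = np.empty(iters)
    for it in range(iters):
        src = ComplexField(np.exp(1j * phase), pitch_x, pitch_y, wavelength)
        far = propagate(src, z)
        if compute_trace:
            inten = np.abs(far.values) ** 2
            cc_trace[it] = correlation_coefficient(inten, target)
            err_trace[it] = float(np.linalg.norm(np.abs(far.values) - amp_t))
        constrained = far.with_values(amp_t * np.exp(1j * np.angle(far.values)))
        back = backpropagate(constrained, z)
        phase = np.angle(back.values)
    if not compute_trace:
        cc_trace = cc_trace[:0]
        err_trace = err_trace[:0]
    return RetrievalResult(wrap_phase(phase), cc_trace, err_trace, iters)


def core_gs_retrieve(target, core_map: CoreMap, z: float, pitch_x: float,
                     pitch_y: float, wavelength: float, iters: int,
                     seed: int | None = None, init: str = "zero",
                     compute_trace: bool = True) -> RetrievalResult:
    """GS with the fiber-core constraint enforced every iteration.

    Facet-plane projection: sample the back-propagated phase at the core
    centers, re-render as piston-phase unit disks (zero amplitude between
    cores), then propagate forward and impose the target amplitude.
    """
    target = _check_target(target)
    if iters < 0:
        raise ValueError("iters must be >= 0")
    shape = target.shape
    amp_t = np.sqrt(target)
    # precompute the pixel mapping once; it is the expensive part
    rows, cols, ids = disk_pixel_indices(core_map, shape, pitch_x, pitch_y)
    iy, jx = core_pixel_indices(core_map, shape, pitch_x, pitch_y)

    phase0 = _initial_phase(shape, seed, init)
    core_phases = wrap_phase(phase0[iy, jx])
    cc_trace = np.empty(iters)
    err_trace = np.empty(iters)
    values = np.zeros(shape, dtype=np.complex128)
    for it in range(iters):
        values[:] = 0.0
        values[rows, cols] = np.exp(1j * core_phases[ids])
        facet = ComplexField(values, pitch_x, pitch_y, wavelength)
        far = propagate(facet, z)
        if compute_trace:
            inten = np.abs(far.values) ** 2
            cc_trace[it] = correlation_coefficient(inten, target)
            err_trace[it] = float(np.linalg.norm(np.abs(far.values) - amp_t))
        constrained = far.with_values(amp_t * np.exp(1j * np.angle(far.values)))
        back = backpropagate(constrained, z)
        core_phases = wrap_phase(np.angle(back.values)[iy, jx])
    if not compute_trace:
        cc_trace = cc_trace[:0]
        err_trace = err_trace[:0]
    return RetrievalResult(CoreHologram(core_phases), cc_trace, err_trace, iters)
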