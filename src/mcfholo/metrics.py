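"""Reconstruction-fidelity metrics and the batch evaluation harness.

Fidelity of a reconstructed intensity image X against a target Y is the 2-D
Pearson correlation coefficient

    CC = sum_i (X_i - mean X)(Y_i - mean Y)
         / sqrt( sum_i (X_i - mean X)^2 * sum_i (Y_i - mean Y)^2 ),

which is invariant to positive affine rescaling of either image (so the
max-normalization applied for display changes nothing).  Its negative is
the training loss of the phase-encoder network.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .errors import ConstantImageError
from .mcf import CoreHologram, CoreMap, reconstruct_far_field, sample_core_phases

__all__ = ["correlation_coefficient", "npcc", "FidelityReport", "evaluate_method"]


def correlation_coefficient(X: np.ndarray, Y: np.ndarray) -> float:
    """2-D Pearson correlation coefficient between two equal-shape images."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {Y.shape}")
    xc = X - X.mean()
    yc = Y - Y.mean()
    sx = np.sum(xc * xc)
    sy = np.sum(yc * yc)
    if sx == 0.0 or sy == 0.0:
        raise ConstantImageError("correlation undefined for a constant image")
    return float(np.sum(xc * yc) / np.sqrt(sx * sy))


def npcc(X: np.ndarray, Y: np.ndarray) -> float:
    """Negative Pearson correlation coefficient (the training loss)."""
    return -correlation_coefficient(X, Y)


@dataclass
class FidelityReport:
    """Per-target CC values for one method, with box-plot summaries."""

    method: str
    cc_values: np.ndarray

    def __post_init__(self):
        cc = np.asarray(self.cc_values, dtype=float).ravel()
        if cc.size < 1:
            raise ValueError("report needs at least one CC value")
        self.cc_values = cc

    @property
    def mean(self) -> float:
        return float(self.cc_values.mean())

    @property
    def median(self) -> float:
        return float(np.median(self.cc_values))

    def quartiles(self) -> tuple[float, float]:
        q1, q3 = np.percentile(self.cc_values, [25, 75])
        return float(q1), float(q3)

    def whiskers(self) -> tuple[float, float]:
        """1.5*IQR whiskers clipped to the observed range (box-plot convention)."""
        q1, q3 = self.quartiles()
        iqr = q3 - q1
        lo = self.cc_values[self.cc_values >= q1 - 1.5 * iqr].min()
        hi = self.cc_values[self.cc_values <= q3 + 1.5 * iqr].max()
        return float(lo), float(hi)

    def summary(self) -> dict:
        q1, q3 = self.quartiles()
        lo, hi = self.whiskers()
        return {"method": self.method, "n": int(self.cc_values.size),
                "mean": self.mean, "median": self.median,
                "q1": q1, "q3": q3, "whisker_low": lo, "whisker_high": hi}

    def to_csv(self, path) -> None:
        lines = ["index,cc"] + [f"{i},{float(v)!r}" for i, v in enumerate(self.cc_values)]
        Path(path).write_text("\n".join(lines) + "\n")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=1))

    def boxplot(self, ax=None):
        """Draw the fidelity box plot; returns the matplotlib Axes."""
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(3, 4))
        ax.boxplot([self.cc_values], tick_labels=[self.method], whis=1.5)
        ax.set_ylabel("correlation coefficient")
        return ax


def evaluate_method(method, targets: Sequence[np.ndarray], core_map: CoreMap,
                    z: float, pitch_x: float, pitch_y: float, wavelength: float,
                    label: str | None = None, **method_kwargs) -> FidelityReport:
    """Run one CGH method over a target list and score every reconstruction.

    ``method`` is either one of the registered names (``"gs"``,
    ``"core-gs"``) or a callable ``target -> CoreHologram``.  Whatever the
    method, the reconstruction goes through the one shared forward model
    (:func:`mcfholo.mcf.reconstruct_far_field`), so the comparison between
    methods is fair by construction.
    """
    if len(targets) == 0:
        raise ValueError("need at least one target")
    holo_fn = _resolve_method(method, core_map, z, pitch_x, pitch_y, wavelength,
                              **method_kwargs)
    shape = np.asarray(targets[0]).shape
    ccs = np.empty(len(targets))
    for i, target in enumerate(targets):
        target = np.asarray(target, dtype=float)
        if target.shape != shape:
            raise ValueError("all targets must share one shape")
        holo = holo_fn(target)
        recon = reconstruct_far_field(holo, core_map, target.shape,
                                      pitch_x, pitch_y, wavelength, z)
        ccs[i] = correlation_coefficient(recon, target)
    name = label if label is not None else (method if isinstance(method, str)
                                            else getattr(method, "__name__", "custom"))
    return FidelityReport(name, ccs)


def _resolve_method(method, core_map, z, pitch_x, pitch_y, wavelength,
                    **kwargs) -> Callable[[np.ndarray], CoreHologram]:
    if callable(method):
        return method
    if method == "gs":
        from .retrieval import gs_retrieve

        iters = kwargs.pop("iters", 100)
        seed = kwargs.pop("seed", None)

        def run_gs(target):
            res = gs_retrieve(target, z=z, pitch_x=pitch_x, pitch_y=pitch_y,
                              wavelength=wavelength, iters=iters, seed=seed,
                              compute_trace=False, **kwargs)
            return sample_core_phases(res.hologram, core_map, pitch_x, pitch_y)

        return run_gs
    if method in ("core-gs", "core_gs"):
        from .retrieval import core_gs_retrieve

        iters = kwargs.pop("iters", 100)
        seed = kwargs.pop("seed", None)

        def run_core_gs(target):
            res = core_gs_retrieve(target, core_map, z=z, pitch_x=pitch_x,
                                   pitch_y=pitch_y, wavelength=wavelength,
                                   iters=iters, seed=seed, compute_trace=False,
                                   **kwargs)
            return res.hologram

        return run_core_gs
    raise ValueError(f"unknown method {method!r} (expected 'gs', 'core-gs' or a callable)")
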