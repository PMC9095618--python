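"""CoreNet: an unsupervised phase-encoder network for fiber phased arrays.

The network maps a target intensity to the full-resolution phase hologram
that reproduces it through the fiber.  Instead of the raw image, the input
is the complex field obtained by back-propagating the target amplitude to
the fiber facet plane (feature mapping within one plane is easier than
across planes); its real and imaginary parts feed two separate
downsampling paths of a modified residual U-Net that join at the
bottleneck.  The physical forward model — sampling the output phase at the
core positions, rendering piston-phase core disks, band-limited
angular-spectrum propagation to the target plane — is embedded in the
training graph, and the loss is the negative Pearson correlation between
the reconstructed intensity and the input target.  No precomputed hologram
ever enters the loop: the target is its own label (unsupervised).
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field

import numpy as np

from .errors import ConfigError, GeometryError
from .fields import PropagationConfig, backpropagate, transfer_function
from .mcf import (CoreHologram, CoreMap, core_pixel_indices, disk_pixel_indices,
                  reconstruct_far_field, sample_core_phases, wrap_phase)
from .metrics import npcc as npcc_loss  # noqa: F401  (re-exported: Eq. on intensities)
from .nn import Adam, BatchNorm2d, Conv2d, Module, SamplingBlock, Tensor
from .nn import tensor as T

__all__ = [
    "NetworkConfig",
    "TrainingConfig",
    "CoreNet",
    "build_corenet",
    "prepare_inputs",
    "npcc_loss",
    "DifferentiablePipeline",
    "forward_pipeline",
    "train",
    "infer_hologram",
    "save_checkpoint",
    "load_checkpoint",
]

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyper-parameters.

    ``input_size`` is the grid the back-propagated field lives on;
    ``output_size`` the modulator grid (>= input, equal at desk scale, each
    axis a power-of-two multiple of the input axis).  ``depth`` counts the
    downsampling blocks per path; ``base_width`` the channel count of the
    first level, doubling per level.
    """

    input_size: tuple[int, int] = (64, 64)
    output_size: tuple[int, int] | None = None
    depth: int = 3
    base_width: int = 8
    stem: bool = False            # optional full-resolution residual stem per path
    head_width: int = 16          # hidden channels of the phase head (0 = linear)
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self):
        out = self.output_size if self.output_size is not None else self.input_size
        object.__setattr__(self, "output_size", tuple(out))
        object.__setattr__(self, "input_size", tuple(self.input_size))
        if self.depth < 1:
            raise ConfigError("depth must be >= 1")
        if self.base_width < 1:
            raise ConfigError("base_width must be >= 1")
        for n, o in zip(self.input_size, self.output_size):
            if o < n:
                raise ConfigError("output size must be >= input size")
            if n % (1 << self.depth):
                raise ConfigError(f"input size {n} not divisible by 2^depth")
            ratio = o / n
            if abs(ratio - round(ratio)) > 0 or (round(ratio) & (round(ratio) - 1)):
                raise ConfigError("output/input ratio must be a power of two")
        r0 = self.output_size[0] // self.input_size[0]
        r1 = self.output_size[1] // self.input_size[1]
        if r0 != r1:
            raise ConfigError("output/input ratio must match on both axes")

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)

    @property
    def extra_upsamples(self) -> int:
        return int(round(np.log2(self.output_size[0] // self.input_size[0])))


@dataclass(frozen=True)
class TrainingConfig:
    """Unsupervised training hyper-parameters (Adam, NPCC loss)."""

    epochs: int = 5
    batch_size: int = 6
    learning_rate: float = 3e-3
    lr_schedule: str = "cosine"   # "cosine" decay to lr/10, or "constant"
    ema_decay: float = 0.0        # optional weight averaging; 0 = off (the loss
                                  # is still descending at 5 epochs, so averaging
                                  # lags the trajectory and is disabled by default
    betas: tuple[float, float] = (0.9, 0.999)
    z: float = 700.0
    seed: int = 0
    shuffle: bool = True

    def __post_init__(self):
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ConfigError("batch size must be >= 1")
        if self.lr_schedule not in ("cosine", "constant"):
            raise ConfigError("lr_schedule must be 'cosine' or 'constant'")
        if not (0.0 <= self.ema_decay < 1.0):
            raise ConfigError("ema_decay must be in [0, 1)")


class CoreNet(Module):
    """Dual-input residual encoder–decoder producing an unwrapped phase map."""

    def __init__(self, cfg: NetworkConfig):
        self.cfg = cfg
        self.core_bias = None     # created by attach_core_bias at training time
        rng = np.random.default_rng(cfg.seed)
        dt = cfg.np_dtype
        w = cfg.base_width
        widths = [w * (1 << i) for i in range(cfg.depth)]     # per-level channels
        cin0 = 1
        if cfg.stem:
            from .nn import ResidualBlock

            self.stem_real = ResidualBlock(1, w, "same", rng=rng, dtype=dt)
            self.stem_imag = ResidualBlock(1, w, "same", rng=rng, dtype=dt)
            cin0 = w
        self.down_real = [SamplingBlock(cin0 if i == 0 else widths[i - 1],
                                        widths[i], "down", rng=rng, dtype=dt)
                          for i in range(cfg.depth)]
        self.down_imag = [SamplingBlock(cin0 if i == 0 else widths[i - 1],
                                        widths[i], "down", rng=rng, dtype=dt)
                          for i in range(cfg.depth)]
        deep = widths[-1]
        self.bottleneck = SamplingBlock(2 * deep, deep, "same", rng=rng, dtype=dt)
        # upsampling path with skips concatenated from BOTH downsampling paths
        self.up_blocks = []
        cin = deep
        for i in range(cfg.depth - 1, -1, -1):
            cout = widths[i - 1] if i > 0 else w
            self.up_blocks.append(SamplingBlock(cin, cout, "up", rng=rng, dtype=dt))
            cin = cout + (2 * widths[i - 1] if i > 0 else 0)
        for _ in range(cfg.extra_upsamples):
            self.up_blocks.append(SamplingBlock(cin, w, "up", rng=rng, dtype=dt))
            cin = w
        # physics-guided residual head: digital phase conjugation — displaying
        # the phase of the back-propagated target field — is itself a strong
        # hologram, so when the grids coincide the output is
        # head(features) + alpha * angle(backpropagated field) with a
        # learnable alpha initialized at 1; the encoder learns the correction
        self.input_skip = cfg.extra_upsamples == 0
        if self.input_skip:
            # raw input planes plus their polar form (amplitude, phase) feed
            # the head directly at full resolution
            cin += 4
            if cfg.stem:
                cin += 2 * w      # full-resolution stem features of both paths
            self.alpha = Tensor(np.ones(1, dtype=dt), requires_grad=True)
        self.head_bn = BatchNorm2d(cin, dtype=dt)
        if cfg.head_width > 0:
            self.head_conv = Conv2d(cin, cfg.head_width, k=1, padding=0,
                                    rng=rng, dtype=dt)
            self.head_bn2 = BatchNorm2d(cfg.head_width, dtype=dt)
            self.head_out = Conv2d(cfg.head_width, 1, k=1, padding=0,
                                   rng=rng, dtype=dt)
        else:
            self.head_conv = Conv2d(cin, 1, k=1, padding=0, rng=rng, dtype=dt)
            self.head_out = None

    def forward(self, x_real: Tensor, x_imag: Tensor, training: bool = True) -> Tensor:
        """(B, 1, H, W) x 2 -> unwrapped phase (B, 1, H_out, W_out)."""
        if x_real.shape != x_imag.shape:
            raise GeometryError("the two input planes must share a shape")
        if x_real.shape[2:] != self.cfg.input_size:
            raise GeometryError(f"expected input grid {self.cfg.input_size}, "
                                f"got {x_real.shape[2:]}")
        skips_r, skips_i = [], []
        hr, hi = x_real, x_imag
        if self.cfg.stem:
            hr = self.stem_real.forward(hr, training)
            hi = self.stem_imag.forward(hi, training)
            stem_r, stem_i = hr, hi
        for br, bi in zip(self.down_real, self.down_imag):
            hr = br.forward(hr, training)
            hi = bi.forward(hi, training)
            skips_r.append(hr)
            skips_i.append(hi)
        h = self.bottleneck.forward(T.concat([hr, hi], axis=1), training)
        for i, block in enumerate(self.up_blocks):
            h = block.forward(h, training)
            level = self.cfg.depth - 2 - i          # skip level after this block
            if level >= 0:
                h = T.concat([h, skips_r[level], skips_i[level]], axis=1)
        if self.input_skip:
            ang = np.arctan2(x_imag.data, x_real.data).astype(x_real.dtype)
            amp = np.hypot(x_real.data, x_imag.data).astype(x_real.dtype)
            planes = [h, x_real, x_imag, Tensor(ang), Tensor(amp)]
            if self.cfg.stem:
                planes += [stem_r, stem_i]
            h = T.concat(planes, axis=1)
        h = T.relu(self.head_bn.forward(h, training))
        out = self.head_conv.forward(h, training)
        if self.head_out is not None:
            out = self.head_out.forward(
                T.relu(self.head_bn2.forward(out, training)), training)
        if self.input_skip:
            out = T.add(out, T.scaled_const(ang, self.alpha))
        return out

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def attach_core_bias(self, n_cores: int) -> None:
        """Create the learnable per-core phase offset vector.

        The network's hologram is read at the pixel nearest each core
        center; the sub-pixel displacement causes a small systematic phase
        offset per core that this vector absorbs (a learned calibration
        layer, fitted jointly during training and added to the hologram at
        the core positions during inference)."""
        if getattr(self, "core_bias", None) is None:
            self.core_bias = Tensor(np.zeros(n_cores, dtype=self.cfg.np_dtype),
                                    requires_grad=True)


def build_corenet(cfg: NetworkConfig) -> CoreNet:
    """Construct the network; identical cfg + seed gives identical parameters."""
    return CoreNet(cfg)


def prepare_inputs(target: np.ndarray, z: float, pitch_x: float, pitch_y: float,
                   wavelength: float) -> tuple[np.ndarray, np.ndarray]:
    """Back-propagate sqrt(target) to the facet plane; split real/imag planes."""
    fld = backpropagate(np.asarray(target, dtype=float), z, pitch_x=pitch_x,
                        pitch_y=pitch_y, wavelength=wavelength)
    return fld.values.real, fld.values.imag


class DifferentiablePipeline:
    """The embedded physical forward model as autodiff graph operations.

    Precomputes the core pixel mapping and the angular-spectrum transfer
    function once; ``loss`` then runs network-output phase -> per-core
    sampling -> disk rendering -> propagation -> intensity -> mean NPCC
    entirely in differentiable primitives.
    """

    def __init__(self, core_map: CoreMap, shape: tuple[int, int], pitch_x: float,
                 pitch_y: float, wavelength: float, z: float, dtype=np.float32):
        self.shape = tuple(shape)
        self.iy, self.jx = core_pixel_indices(core_map, self.shape, pitch_x, pitch_y)
        self.rows, self.cols, self.ids = disk_pixel_indices(core_map, self.shape,
                                                            pitch_x, pitch_y)
        cfg = PropagationConfig(z=z, ny=shape[0], nx=shape[1], pitch_x=pitch_x,
                                pitch_y=pitch_y, wavelength=wavelength)
        cdtype = np.complex64 if np.dtype(dtype) == np.float32 else np.complex128
        self.H = transfer_function(cfg).astype(cdtype)

    def reconstruct(self, phase_out: Tensor, core_bias: Tensor | None = None) -> Tensor:
        """Network phase output (B, 1, H, W) -> reconstructed intensity (B, H, W)."""
        phases = T.gather_pixels(phase_out, self.iy, self.jx)
        if core_bias is not None:
            phases = T.add_row(phases, core_bias)
        facet = T.render_phasor_field(phases, self.rows, self.cols, self.ids,
                                      self.shape)
        far = T.propagate_fixed(facet, self.H)
        return T.abs2(far)

    def loss(self, phase_out: Tensor, targets: np.ndarray,
             core_bias: Tensor | None = None) -> Tensor:
        """Mean NPCC between the batch reconstructions and their targets."""
        return T.npcc_mean(self.reconstruct(phase_out, core_bias), targets)


def forward_pipeline(model: CoreNet, target: np.ndarray, core_map: CoreMap,
                     z: float, pitch_x: float, pitch_y: float, wavelength: float):
    """Full inference chain on one target.

    Returns ``(slm_phase, core_hologram, reconstruction)``: the wrapped
    full-grid phase, the sampled per-core hologram, and the max-normalized
    reconstructed intensity through the shared forward model.
    """
    slm_phase = infer_hologram(model, target, z, pitch_x, pitch_y, wavelength,
                               core_map=core_map)
    holo = sample_core_phases(slm_phase, core_map, pitch_x, pitch_y)
    recon = reconstruct_far_field(holo, core_map, np.asarray(target).shape,
                                  pitch_x, pitch_y, wavelength, z)
    return slm_phase, holo, recon


def infer_hologram(model: CoreNet, target: np.ndarray, z: float, pitch_x: float,
                   pitch_y: float, wavelength: float,
                   core_map: CoreMap | None = None) -> np.ndarray:
    """Single forward pass; returns the wrapped [0, 2*pi) phase hologram.

    When the model carries a learned per-core calibration vector and the
    core map is supplied, the calibration is painted onto the hologram at
    the core positions.
    """
    target = np.asarray(target, dtype=float)
    if target.shape != model.cfg.input_size:
        raise GeometryError(f"target shape {target.shape} does not match the "
                            f"network input grid {model.cfg.input_size}")
    re, im = prepare_inputs(target, z, pitch_x, pitch_y, wavelength)
    dt = model.cfg.np_dtype
    xr = Tensor(re[None, None].astype(dt))
    xi = Tensor(im[None, None].astype(dt))
    with T.no_grad():
        out = model.forward(xr, xi, training=False)
    phase = out.data[0, 0].astype(float)
    if model.core_bias is not None and core_map is not None:
        iy, jx = core_pixel_indices(core_map, phase.shape, pitch_x, pitch_y)
        phase[iy, jx] += model.core_bias.data.astype(float)
    return wrap_phase(phase)


@dataclass
class TrainingHistory:
    """Per-epoch mean NPCC loss plus wall-clock bookkeeping."""

    epoch_losses: list = field(default_factory=list)
    batch_losses: list = field(default_factory=list)
    seconds: float = 0.0


def train(model: CoreNet, targets, core_map: CoreMap, tcfg: TrainingConfig,
          pitch_x: float, pitch_y: float, wavelength: float,
          verbose: bool = False) -> TrainingHistory:
    """Unsupervised training: minimize mean NPCC through the physical model.

    ``targets`` is a sequence of 2-D intensity images on the network grid.
    The loop consumes only the targets themselves — no precomputed hologram
    appears anywhere.  Reproducible for fixed network/training seeds.
    """
    n = len(targets)
    if n == 0:
        raise ValueError("training dataset is empty")
    shape = model.cfg.input_size
    dt = model.cfg.np_dtype
    stack = np.stack([np.asarray(t, dtype=float) for t in targets])
    if stack.shape[1:] != shape:
        raise GeometryError(f"targets {stack.shape[1:]} do not match the "
                            f"network grid {shape}")
    if np.any(np.ptp(stack, axis=(1, 2)) == 0):
        raise ValueError("training targets must not be constant images")

    # precompute the dual-plane inputs once (pure FFT work)
    re = np.empty((n, 1, *shape), dtype=dt)
    im = np.empty((n, 1, *shape), dtype=dt)
    for i in range(n):
        r, m = prepare_inputs(stack[i], tcfg.z, pitch_x, pitch_y, wavelength)
        re[i, 0] = r
        im[i, 0] = m
    targets_f = stack.astype(dt)

    pipeline = DifferentiablePipeline(core_map, model.cfg.output_size, pitch_x,
                                      pitch_y, wavelength, tcfg.z, dtype=dt)
    model.attach_core_bias(core_map.n_cores)
    params = model.parameters()
    opt = Adam(params, lr=tcfg.learning_rate, betas=tcfg.betas)
    ema = [p.data.copy() for p in params] if tcfg.ema_decay > 0 else None
    rng = np.random.default_rng(tcfg.seed)
    history = TrainingHistory()
    n_batches = int(np.ceil(n / tcfg.batch_size))
    total_steps = max(tcfg.epochs * n_batches - 1, 1)
    step = 0
    t0 = time.perf_counter()
    for epoch in range(tcfg.epochs):
        order = rng.permutation(n) if tcfg.shuffle else np.arange(n)
        losses = []
        for start in range(0, n, tcfg.batch_size):
            if tcfg.lr_schedule == "cosine":
                opt.lr = tcfg.learning_rate * (
                    0.55 + 0.45 * np.cos(np.pi * step / total_steps))
            step += 1
            idx = order[start:start + tcfg.batch_size]
            xr = Tensor(re[idx])
            xi = Tensor(im[idx])
            out = model.forward(xr, xi, training=True)
            loss = pipeline.loss(out, targets_f[idx], core_bias=model.core_bias)
            opt.zero_grad()
            loss.backward()
            opt.step()
            if ema is not None:
                d = tcfg.ema_decay
                for e, p in zip(ema, params):
                    e += (1.0 - d) * (p.data - e)
            losses.append(float(loss.data))
        history.batch_losses.append(losses)
        history.epoch_losses.append(float(np.mean(losses)))
        if verbose:
            print(f"epoch {epoch + 1}/{tcfg.epochs}: "
                  f"mean NPCC loss {history.epoch_losses[-1]:+.4f}")
    if ema is not None:
        for e, p in zip(ema, params):
            p.data = e
    history.seconds = time.perf_counter() - t0
    return history


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(path, model: CoreNet, core_map: CoreMap | None = None,
                    tcfg: TrainingConfig | None = None) -> None:
    """HDF5 checkpoint: weights + network config (+ core map and training config)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["network_config"] = json.dumps(asdict(model.cfg))
        if tcfg is not None:
            f.attrs["training_config"] = json.dumps(asdict(tcfg))
        grp = f.create_group("weights")
        for name, arr in model.state_arrays().items():
            grp.create_dataset(name, data=arr)
        if core_map is not None:
            cm = f.create_group("core_map")
            cm.create_dataset("centers", data=core_map.centers)
            cm.attrs["core_radius"] = core_map.core_radius
            cm.attrs["facet_diameter"] = core_map.facet_diameter


def load_checkpoint(path):
    """Returns ``(model, core_map_or_None, training_config_or_None)``."""
    import h5py

    with h5py.File(path, "r") as f:
        raw = json.loads(f.attrs["network_config"])
        raw["input_size"] = tuple(raw["input_size"])
        raw["output_size"] = tuple(raw["output_size"])
        cfg = NetworkConfig(**raw)
        model = build_corenet(cfg)
        state = {name: ds[()] for name, ds in f["weights"].items()}
        if "core_bias" in state:
            model.attach_core_bias(state["core_bias"].size)
        model.load_state_arrays(state)
        core_map = None
        if "core_map" in f:
            cm = f["core_map"]
            core_map = CoreMap(cm["centers"][()], float(cm.attrs["core_radius"]),
                               float(cm.attrs["facet_diameter"]))
        tcfg = None
        if "training_config" in f.attrs:
            t = json.loads(f.attrs["training_config"])
            t["betas"] = tuple(t["betas"])
            tcfg = TrainingConfig(**t)
    return model, core_map, tcfg
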