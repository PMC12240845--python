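"""Self-supervised reconstruction network for scanning light-field data.

The model composes three stages:

1. *Depth decomposition* (fixed, parameter-free): each of the A selected
   angular views is shifted by +alpha*z*u for every z-plane, producing an
   (A, D, H, W) tensor whose channels carry angle identity.
2. *Deblurring and fusion trunk* (learned): nine 3D convolutions with
   three lateral linear-interpolation layers whose upsampling factors
   multiply to Npix/S (2 x 2 x 13/12 for the 13x13, 3x3-scan system),
   ending in a square (y = x^2) head so the estimated volume is
   non-negative.
3. *Self-supervision* (training only): the estimated volume is forward
   projected along randomly scheduled angle subsets with the angular PSFs,
   scaled to measurement sampling, and compared with the measured views
   under the mixed Poisson-Gaussian negative log-likelihood. At inference
   only stages 1-2 run.

An optional axial fine-tuning add-on appends a small residual
encoder-decoder (two symmetric lateral down/upsampling levels with a skip
connection) after the trunk, trained supervised against ground-truth
volumes with the base weights bit-frozen, to counteract the missing-cone
axial elongation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .core import SpatialAngularStack, Volume
from .noise import GaussianCalibration, nll_mpg_grad
from .psf import AngularPSFStack
from .refocus import depth_decompose
from .simulate import forward_project_all, project_to_measurement

__all__ = [
    "NetworkSpec",
    "TrainConfig",
    "SeReNet",
    "build_serenet",
    "train_serenet",
    "infer_serenet",
    "finetune_axial",
    "AngleScheduler",
]

# trunk widths of the full-scale default spec; nine 3x3x3 convolutions give
# ~198.8k trainable parameters, within 2% of the 195k design point
FULL_WIDTHS = (38, 34, 32, 32, 28, 24, 16, 8, 1)

# numerical safeguards for the self-supervised loss: a fraction-of-a-count
# floor on predicted intensities and a symmetric clip on the per-pixel NLL
# gradient (the unclipped Poisson gradient is O(1) once P is within a
# factor of a few of M)
COUNT_FLOOR = 0.25
GRAD_CLIP = 25.0
DARK_GATE = 0.05  # counts; below this a pixel receives no push-down


@dataclass
class NetworkSpec:
    """Architecture of the deblurring/fusion trunk.

    ``interp_factors`` are (num, den) rationals whose product must equal
    Npix/S; they are inserted after conv 3, 6 and 8. ``widths`` are the
    nine conv output channel counts (the last must be 1).
    """

    angles: int = 49
    depths: int = 101
    widths: tuple = FULL_WIDTHS
    kernel: int = 3
    interp_factors: tuple = ((2, 1), (2, 1), (13, 12))
    npix: int = 13
    S: int = 3
    seed: int = 0

    def __post_init__(self):
        if len(self.widths) != 9:
            raise ValueError("trunk must have nine 3D convolution layers")
        if self.widths[-1] != 1:
            raise ValueError("last conv width must be 1 (single-channel volume)")
        num = den = 1
        for n, d in self.interp_factors:
            num *= n
            den *= d
        from math import gcd

        g = gcd(num, den)
        num, den = num // g, den // g
        g2 = gcd(self.npix, self.S)
        if (num, den) != (self.npix // g2, self.S // g2):
            raise ValueError(
                f"interp factor product {num}/{den} != Npix/S = {self.npix}/{self.S}"
            )

    @property
    def lateral_factor(self) -> float:
        return self.npix / self.S

    def output_shape(self, input_shape):
        """(A, H, W) patch -> (D, H', W') volume shape.

        The lateral sides pass through the three interpolation stages in
        order (each stage requires divisibility by its denominator); the
        depth equals the z-plane count.
        """
        A, H, W = input_shape
        if A != self.angles:
            raise ValueError(f"expected {self.angles} angle channels, got {A}")
        for n, d in self.interp_factors:
            if (H * n) % d or (W * n) % d:
                raise ValueError(f"lateral side not divisible for factor {n}/{d}")
            H, W = H * n // d, W * n // d
        return (self.depths, H, W)


def mini_spec(angles: int = 25, depths: int = 21, seed: int = 0) -> NetworkSpec:
    """Desk-scale spec: 5x5 angles, S = Npix (no lateral upsampling)."""
    return NetworkSpec(
        angles=angles,
        depths=depths,
        widths=(12, 12, 12, 12, 10, 10, 8, 8, 1),
        interp_factors=((1, 1), (1, 1), (1, 1)),
        npix=int(round(np.sqrt(angles))),
        S=int(round(np.sqrt(angles))),
        seed=seed,
    )


@dataclass
class TrainConfig:
    steps: int = 200
    angles_per_step: int = 21
    lr: float = 3e-4
    lr_min_frac: float = 0.1  # cosine decay floor
    seed: int = 0

    def __post_init__(self):
        if self.angles_per_step < 1:
            raise ValueError("angles_per_step must be >= 1")


def _build_trunk(spec: NetworkSpec) -> nn.Sequential:
    rng = np.random.default_rng(spec.seed)
    layers = []
    c_in = spec.angles
    interp_after = {3: 0, 6: 1, 8: 2}
    for i, c_out in enumerate(spec.widths, start=1):
        layers.append(nn.Conv3d(c_in, c_out, spec.kernel, rng))
        if i < 9:
            layers.append(nn.LeakyReLU())
        c_in = c_out
        if i in interp_after:
            num, den = spec.interp_factors[interp_after[i]]
            if num != den:
                layers.append(nn.UpsampleLateral(num, den))
    # square head: non-negative volumes without the exponential gradient
    # freeze a softplus suffers in dark regions of sparse scenes
    layers.append(nn.Square())
    return nn.Sequential(*layers)


class SeReNet:
    """Depth-decomposition front end + learned trunk."""

    def __init__(self, spec: NetworkSpec, psfs: AngularPSFStack):
        if spec.angles != psfs.grid.n_selected:
            raise ValueError("spec angle count != PSF selected view count")
        if spec.depths != len(psfs.z_planes):
            raise ValueError("spec depth != PSF z-plane count")
        self.spec = spec
        self.psfs = psfs
        self.model = _build_trunk(spec)
        self.finetune: nn.Sequential | None = None
        # measurements arrive in camera counts; the trunk is conditioned on
        # O(1) inputs, so inputs are divided by this scale (set to the
        # photon scale at training time) and predictions are in volume
        # intensity units
        self.input_scale = 1.0

    def n_params(self) -> int:
        n = self.model.n_params()
        if self.finetune is not None:
            n += self.finetune.n_params()
        return n

    # -- forward ---------------------------------------------------------
    def decompose(self, stack: SpatialAngularStack) -> np.ndarray:
        r = depth_decompose(stack, self.psfs.z_planes, self.psfs.alpha)
        return r.data / self.input_scale  # (A, D, H, W)

    def forward(self, refocused: np.ndarray) -> np.ndarray:
        """(A, D, H, W) refocused input -> (D, H', W') volume estimate."""
        out = self.model.forward(refocused.astype(np.float32))
        if self.finetune is not None:
            out = self.finetune.forward(out)
        return out[0]

    def backward(self, grad_volume: np.ndarray) -> None:
        g = grad_volume[None].astype(np.float32)
        if self.finetune is not None:
            g = self.finetune.backward(g)
        self.model.backward(g)

    def predict(self, stack: SpatialAngularStack) -> Volume:
        vol = self.forward(self.decompose(stack))
        return Volume(vol, self.psfs.z_planes)

    # -- persistence -----------------------------------------------------
    def state_dict(self):
        state = {"trunk": self.model.state_dict(), "input_scale": self.input_scale}
        if self.finetune is not None:
            state["finetune"] = self.finetune.state_dict()
        return state

    def load_state_dict(self, state):
        self.model.load_state_dict(state["trunk"])
        self.input_scale = state.get("input_scale", 1.0)
        if self.finetune is not None and "finetune" in state:
            self.finetune.load_state_dict(state["finetune"])


def build_serenet(spec: NetworkSpec, psfs: AngularPSFStack) -> SeReNet:
    """Construct the model and log its trainable parameter count."""
    net = SeReNet(spec, psfs)
    import logging

    logging.getLogger(__name__).info(
        "SeReNet built: %d trainable parameters", net.n_params()
    )
    return net


class AngleScheduler:
    """Random angle subsets without replacement; reshuffles when exhausted.

    Guarantees every selected angle is visited within each cycle of
    ceil(A / k) steps; sampling counts are tracked so per-angle loss
    weights can be balanced inversely to visit frequency.
    """

    def __init__(self, n_angles: int, per_step: int, seed: int = 0):
        self.n = n_angles
        self.k = min(per_step, n_angles)
        self.rng = np.random.default_rng(seed)
        self.counts = np.zeros(n_angles, int)
        self._pool: list = []

    def next(self) -> np.ndarray:
        if len(self._pool) < self.k:
            fresh = list(self.rng.permutation(self.n))
            # avoid duplicating the few leftovers already in the pool
            leftovers = set(self._pool)
            self._pool += [a for a in fresh if a not in leftovers]
        subset = np.array(self._pool[: self.k])
        self._pool = self._pool[self.k :]
        self.counts[subset] += 1
        return subset

    def weights(self, subset: np.ndarray) -> np.ndarray:
        c = np.maximum(self.counts[subset], 1)
        w = 1.0 / c
        return w * (len(subset) / w.sum())


def _measurement_adjoint(grad: np.ndarray, npix: int, S: int) -> np.ndarray:
    """Adjoint of the Npix/S area-average downscale, per 2D image."""
    if npix <= S:
        return grad
    g = np.repeat(np.repeat(grad, npix, axis=-2), npix, axis=-1) / (npix * npix)
    h, w = g.shape[-2:]
    g = g.reshape(*g.shape[:-2], h // S, S, w // S, S).sum(axis=(-3, -1))
    return g.astype(np.float32)


def _backproject_grad(grad_views: np.ndarray, psfs: AngularPSFStack, angles) -> np.ndarray:
    """Adjoint of forward_project_all for the loss gradient."""
    from .simulate import backproject

    return backproject(grad_views, psfs, list(angles))


def train_serenet(
    dataset,
    net: SeReNet,
    calib: GaussianCalibration,
    config: TrainConfig,
    photon_scale: float = 1.0,
):
    """Self-supervised training against forward projections.

    ``dataset`` is a sequence of measurement stacks (already preprocessed by
    TW/preDAO when those corrections apply). Each step predicts a volume
    from one sample, forward-projects it along a scheduled angle subset,
    scales to measurement sampling and takes an NLL-MPG gradient step.
    Returns a training log dict with the per-step loss trace.
    """
    if not dataset:
        raise ValueError("dataset is empty")
    spec = net.spec
    sched = AngleScheduler(spec.angles, config.angles_per_step, config.seed)
    opt = nn.Adam(net.model, lr=config.lr)
    rng = np.random.default_rng(config.seed + 17)
    net.input_scale = photon_scale
    # depth decomposition is fixed: cache it per sample
    cache = [net.decompose(s) for s in dataset]
    losses = []
    for step in range(config.steps):
        i = int(rng.integers(len(dataset)))
        refocused = cache[i]
        views = dataset[i].views
        subset = sched.next()
        w = sched.weights(subset)
        vol = net.forward(refocused)
        proj = forward_project_all(vol, net.psfs, subset)
        pred = project_to_measurement(proj, spec.npix, spec.S) if spec.npix > spec.S else proj
        # a small count floor keeps the NLL gradient 1 - E[tau]/P bounded
        # where the prediction is still dark but the measurement is bright
        pred_counts = np.maximum(pred, 0.0) * photon_scale + COUNT_FLOOR
        M = views[subset]
        val, grad = nll_mpg_grad(pred_counts, M, calib.mu, calib.sigma)
        wv = w[:, None, None]
        loss = float((val * wv).mean())
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"NaN/inf loss at step {step}; predictions in "
                f"[{pred_counts.min()}, {pred_counts.max()}]"
            )
        losses.append(loss)
        grad = np.clip(grad, -GRAD_CLIP, GRAD_CLIP)
        gp = (grad * wv * photon_scale / val.size).astype(np.float32)
        # push-down (positive) gradients stop once a pixel is already dark:
        # without this gate the uniform dark-background pressure drives the
        # softplus head into deep saturation and sparse bright structures
        # can no longer pull the volume back up
        dark = pred * photon_scale <= DARK_GATE
        gp = np.where(dark, np.minimum(gp, 0.0), gp).astype(np.float32)
        gp = _measurement_adjoint(gp, spec.npix, spec.S) if spec.npix > spec.S else gp
        gvol = _backproject_grad(gp, net.psfs, subset)
        opt.zero_grad()
        net.backward(gvol)
        # cosine decay
        frac = step / max(config.steps - 1, 1)
        lr = config.lr * (
            config.lr_min_frac
            + (1 - config.lr_min_frac) * 0.5 * (1 + np.cos(np.pi * frac))
        )
        opt.step(lr)
    return {"loss": losses, "angle_counts": sched.counts.tolist()}


def _sigmoid_ramp(n: int, overlap: int, steepness: float, ramp_lo: bool, ramp_hi: bool):
    d = np.arange(n, dtype=float)
    w = np.ones(n)
    if ramp_lo:
        w *= 1.0 / (1.0 + np.exp(-(d - overlap / 2) / steepness))
    if ramp_hi:
        dr = n - 1 - d
        w *= 1.0 / (1.0 + np.exp(-(dr - overlap / 2) / steepness))
    return w


def infer_serenet(
    stack: SpatialAngularStack,
    net: SeReNet,
    tile: int | None = None,
    overlap: int = 32,
    steepness: float = 4.0,
    trim: int | None = None,
) -> Volume:
    """Deterministic inference with overlapping-tile sigmoid fusion.

    Tiles of side ``tile`` (input sampling) with ``overlap`` pixels are
    predicted independently; ``trim`` pixels (default overlap/4) are
    discarded from interior tile edges — the band polluted by the conv
    zero-padding halo and the refocus shifts — and the kept regions are
    blended with per-axis sigmoid ramps normalized to sum to one.
    ``tile=None`` processes the whole field in one patch.
    """
    H, W = stack.views.shape[-2:]
    if tile is None or (tile >= H and tile >= W):
        return net.predict(stack)
    if trim is None:
        trim = overlap // 4
    if tile <= overlap or overlap <= 2 * trim:
        raise ValueError("need tile > overlap > 2*trim")
    f = net.spec.lateral_factor
    out_h, out_w = int(round(H * f)), int(round(W * f))
    D = net.spec.depths
    acc = np.zeros((D, out_h, out_w), np.float64)
    wacc = np.zeros((out_h, out_w), np.float64)
    step = tile - overlap
    ys = sorted({min(y, H - tile) for y in range(0, H - tile + step, step)})
    xs = sorted({min(x, W - tile) for x in range(0, W - tile + step, step)})
    o_kept = int(round((overlap - 2 * trim) * f))
    t_out = int(round(trim * f))
    s_out = steepness * f
    for y0 in ys:
        for x0 in xs:
            sub = SpatialAngularStack(
                stack.views[:, y0 : y0 + tile, x0 : x0 + tile], stack.grid
            )
            vol = net.predict(sub).voxels
            th, tw = vol.shape[-2:]
            lo_y = t_out if y0 > 0 else 0
            hi_y = th - t_out if y0 + tile < H else th
            lo_x = t_out if x0 > 0 else 0
            hi_x = tw - t_out if x0 + tile < W else tw
            vol = vol[:, lo_y:hi_y, lo_x:hi_x]
            wy = _sigmoid_ramp(hi_y - lo_y, o_kept, s_out, y0 > 0, y0 + tile < H)
            wx = _sigmoid_ramp(hi_x - lo_x, o_kept, s_out, x0 > 0, x0 + tile < W)
            wmap = np.outer(wy, wx)
            oy = int(round(y0 * f)) + lo_y
            ox = int(round(x0 * f)) + lo_x
            acc[:, oy : oy + vol.shape[-2], ox : ox + vol.shape[-1]] += vol * wmap
            wacc[oy : oy + vol.shape[-2], ox : ox + vol.shape[-1]] += wmap
    out = acc / np.maximum(wacc, 1e-12)
    return Volume(out.astype(np.float32), net.psfs.z_planes)


def _build_finetune(c_in: int, width: int, seed: int) -> nn.Sequential:
    """Axial fine-tuning add-on in residual form.

    out = (sqrt(base + eps) + f(base))^2 where f is a small two-level
    encoder-decoder with an additive skip whose last conv is
    zero-initialized: at initialization the add-on is the identity, so
    supervised fine-tuning starts from the pretrained model's output and
    only has to learn the axial sharpening residual. Output stays
    non-negative by construction.
    """
    rng = np.random.default_rng(seed)
    return nn.Sequential(_ResidualSqrtHead(_SkipUNet(c_in, width, rng, zero_last=True)))


class _ResidualSqrtHead(nn.Layer):
    """y = (sqrt(x + eps) + f(x))^2 with f a trainable sub-module."""

    EPS = 1e-6

    def __init__(self, f: "nn.Layer"):
        super().__init__()
        self.f = f

    def forward(self, x):
        self._s = np.sqrt(np.maximum(x, 0.0) + self.EPS).astype(np.float32)
        self._u = self.f.forward(x)
        self._t = self._s + self._u
        return (self._t * self._t).astype(np.float32)

    def backward(self, grad_out):
        gt = (2.0 * self._t * grad_out).astype(np.float32)
        gx_f = self.f.backward(gt)
        gx_direct = gt * 0.5 / self._s
        return (gx_f + gx_direct).astype(np.float32)

    def n_params(self):
        return self.f.n_params()

    def zero_grad(self):
        self.f.zero_grad()

    @property
    def params(self):
        return self.f.params

    @params.setter
    def params(self, value):
        pass

    @property
    def grads(self):
        return self.f.grads

    @grads.setter
    def grads(self, value):
        pass


class _SkipUNet(nn.Layer):
    """Two-level lateral encoder-decoder with an additive skip connection."""

    def __init__(self, c_in: int, width: int, rng, zero_last: bool = False):
        super().__init__()
        self.c1 = nn.Conv3d(c_in, width, 3, rng)
        self.a1 = nn.LeakyReLU()
        self.down = nn.UpsampleLateral(1, 2)
        self.c2 = nn.Conv3d(width, width, 3, rng)
        self.a2 = nn.LeakyReLU()
        self.up = nn.UpsampleLateral(2, 1)
        self.c3 = nn.Conv3d(width, c_in, 3, rng)
        if zero_last:
            self.c3.params["w"][...] = 0.0
            self.c3.params["b"][...] = 0.0
        self._subs = [self.c1, self.a1, self.down, self.c2, self.a2, self.up, self.c3]

    def forward(self, x):
        self._in_hw = x.shape[-2:]
        y1 = self.a1.forward(self.c1.forward(x))
        y2 = self.a2.forward(self.c2.forward(self.down.forward(y1)))
        y3 = self.up.forward(y2)
        y3 = self._match(y3, y1.shape)
        self._pad_shape = y3.shape
        return self.c3.forward(y1 + y3)

    def _match(self, y, target_shape):
        # crop/pad the decoded tensor to the skip's lateral size
        th, tw = target_shape[-2:]
        h, w = y.shape[-2:]
        if h > th:
            y = y[..., :th, :]
        elif h < th:
            y = np.pad(y, [(0, 0)] * (y.ndim - 2) + [(0, th - h), (0, 0)])
        if w > tw:
            y = y[..., :tw]
        elif w < tw:
            y = np.pad(y, [(0, 0)] * (y.ndim - 1) + [(0, tw - w)])
        self._dec_hw = (h, w)
        return y

    def backward(self, grad_out):
        g = self.c3.backward(grad_out)
        g_skip = g
        # undo crop/pad
        h, w = self._dec_hw
        th, tw = self._pad_shape[-2:]
        gd = g
        if h > th:
            gd = np.pad(gd, [(0, 0)] * (gd.ndim - 2) + [(0, h - th), (0, 0)])
        elif h < th:
            gd = gd[..., :h, :]
        if w > tw:
            gd = np.pad(gd, [(0, 0)] * (gd.ndim - 1) + [(0, w - tw)])
        elif w < tw:
            gd = gd[..., :w]
        gd = self.up.backward(gd)
        gd = self.c2.backward(self.a2.backward(gd))
        gd = self.down.backward(gd)
        return self.c1.backward(self.a1.backward(g_skip + gd))

    def n_params(self):
        return sum(l.n_params() for l in self._subs)

    def zero_grad(self):
        for l in self._subs:
            l.zero_grad()

    @property
    def params(self):
        out = {}
        for i, l in enumerate(self._subs):
            for k, v in l.params.items():
                out[f"{i}.{k}"] = v
        return out

    @params.setter
    def params(self, value):
        pass  # sub-layers own their parameters

    @property
    def grads(self):
        out = {}
        for i, l in enumerate(self._subs):
            for k, v in l.grads.items():
                out[f"{i}.{k}"] = v
        return out

    @grads.setter
    def grads(self, value):
        pass


def finetune_axial(
    net: SeReNet,
    paired_volumes,
    calib: GaussianCalibration,
    steps: int = 800,
    lr: float = 3e-3,
    width: int = 12,
    photon_scale: float = 1.0,
    seed: int = 0,
    restarts: int = 3,
):
    """Supervised axial fine-tuning with the pretrained base frozen.

    ``paired_volumes`` is a sequence of (measurement stack, ground-truth
    Volume) pairs. A small encoder-decoder in residual form is appended
    after the trunk and trained with the NLL-MPG loss against the
    ground-truth volumes; every base parameter is bit-frozen (verified,
    error on violation). Because the base is frozen, its outputs are
    cached once and only the add-on runs per step. The add-on occasionally
    lands in a poor initialization basin, so ``restarts`` independent
    inits are trained and the one with the lowest final *training* loss is
    kept. Returns the winning run's training log.
    """
    for layer in net.model.layers:
        layer.trainable = False
    base_before = {k: v.copy() for k, v in net.model.state_dict().items()}
    # the base is frozen, so its output per sample is a constant of the
    # optimization: cache it and train only the add-on each step
    cache = []
    for s, gt in paired_volumes:
        base_out = net.model.forward(net.decompose(s).astype(np.float32))
        cache.append((base_out, gt))

    def _run(init_seed):
        module = _build_finetune(1, width, init_seed)
        opt = nn.Adam(module, lr=lr)
        rng = np.random.default_rng(init_seed + 3)
        losses = []
        for _ in range(steps):
            base_out, gt = cache[int(rng.integers(len(cache)))]
            pred = module.forward(base_out)[0]
            target = gt.voxels * photon_scale
            val, grad = nll_mpg_grad(
                np.maximum(pred, 0.0) * photon_scale, target, calib.mu, calib.sigma
            )
            losses.append(float(val.mean()))
            g = (grad * photon_scale / val.size).astype(np.float32)
            opt.zero_grad()
            module.backward(g[None])
            opt.step()
        return module, losses

    best = None
    for r in range(max(restarts, 1)):
        module, losses = _run(seed + 1009 * r)
        score = float(np.mean(losses[-10:]))
        if best is None or score < best[0]:
            best = (score, module, losses)
    net.finetune = best[1]
    base_after = net.model.state_dict()
    for k in base_before:
        if not np.array_equal(base_before[k], base_after[k]):
            raise RuntimeError(f"frozen base parameter {k} changed during fine-tuning")
    return {"loss": best[2]}
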