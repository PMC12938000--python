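"""The NIR-I -> NIR-IIa image-translation network.

Architecture: three convolutional encoder stages (channels 1->32->64->128,
kernel 3, stride 2, each Conv -> BatchNorm -> ReLU), a Swin Transformer
bottleneck operating on 5x5 patch tokens of the deepest feature map, and
three decoder stages (nearest-neighbour 2x upsample -> concatenate skip ->
Conv(stride 1) -> BatchNorm -> ReLU, channels 128, 64, 32) finished by a
1-channel convolution and a sigmoid.  Skip sources are the second and first
encoder features and, for the last stage, the raw input image.

Each Swin block is layer-norm -> windowed multi-head self-attention ->
residual -> layer-norm -> 2-layer MLP -> residual; odd-numbered blocks use
cyclically shifted windows (with the standard region mask) whenever the
window is smaller than the token grid.  At the default 120x120 input the
token grid is 3x3, the window covers the full grid and shifting is a no-op.

Input height and width must be divisible by 40 = 2^3 * 5 (three stride-2
convolutions followed by 5x5 patching).
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .errors import DivisibilityError, ValidationError
from .phantom import SIZE_DIVISOR, DatasetManifest


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkConfig:
    encoder_channels: tuple = (32, 64, 128)
    encoder_kernel: int = 3
    encoder_stride: int = 2
    decoder_stride: int = 1
    patch_size: int = 5
    n_swin_blocks: int = 3
    embed_dim: int = 128
    n_heads: int = 4
    mlp_ratio: int = 4
    window: int | None = None   # None: full grid when side <= 8, else auto
    shift: int | None = None    # None: window // 2

    def validate(self):
        ch = self.encoder_channels
        if len(ch) != 3 or any(a >= b for a, b in zip(ch, ch[1:])):
            raise ValidationError("encoder_channels must be 3 strictly "
                                  "increasing values")
        if self.patch_size < 1 or self.n_swin_blocks < 1:
            raise ValidationError("patch_size and n_swin_blocks must be >= 1")
        if self.embed_dim % self.n_heads:
            raise ValidationError(
                f"embed_dim {self.embed_dim} must be divisible by n_heads "
                f"{self.n_heads}")


@dataclass(frozen=True)
class TrainConfig:
    loss: str = "l1"                 # "l1" or "l2"
    learning_rate: float = 1e-3
    epochs: int = 50
    batch_size: int = 4
    seed: int = 0
    split_fractions: tuple = (0.8, 0.1, 0.1)
    normalization: str = "minmax"    # per-image min-max to [0, 1]

    def validate(self):
        if self.loss not in ("l1", "l2"):
            raise ValidationError("loss must be 'l1' or 'l2'")
        if self.learning_rate <= 0 or self.epochs < 1 or self.batch_size < 1:
            raise ValidationError("learning_rate, epochs, batch_size must "
                                  "be positive")
        if not np.isclose(sum(self.split_fractions), 1.0):
            raise ValidationError("split fractions must sum to 1")
        if self.normalization != "minmax":
            raise ValidationError("only per-image min-max normalization is "
                                  "implemented")


def _check_divisible(shape):
    h, w = shape[-2:]
    if h % SIZE_DIVISOR or w % SIZE_DIVISOR:
        raise DivisibilityError(
            f"input of shape {(h, w)} must have height and width divisible "
            f"by {SIZE_DIVISOR}; reflect-pad to the next multiple and crop "
            "the prediction back (enhance(..., pad=True) does this)")


def _auto_window(g: int) -> int:
    """Full grid when the side is small, else the largest divisor <= 8."""
    if g <= 8:
        return g
    return max(d for d in range(1, 9) if g % d == 0)


# ---------------------------------------------------------------------------
# patch tokens
# ---------------------------------------------------------------------------

@dataclass
class FeatureStack:
    """Encoder features with channel ladder C1 < C2 < C3 at spatial scales
    H/2, H/4, H/8; held channels-last as Tensors (N, h, w, C)."""
    f1: Tensor
    f2: Tensor
    f3: Tensor


def partition_patches(f3: Tensor, patch_size: int) -> Tensor:
    """(N, h, w, C) -> (N, (h/p)*(w/p), C*p*p) patch vectors, raster order
    over the patch grid.  Lossless: merge_patches inverts it exactly.
    """
    n, h, w, c = f3.shape
    p = patch_size
    if h % p or w % p:
        raise ValidationError(f"feature map {h}x{w} not divisible by patch "
                              f"size {p}")
    x = ad.reshape(f3, (n, h // p, p, w // p, p, c))
    x = ad.transpose(x, (0, 1, 3, 5, 2, 4))
    return ad.reshape(x, (n, (h // p) * (w // p), c * p * p))


def merge_patches(tokens: Tensor, grid_shape, channels: int,
                  patch_size: int) -> Tensor:
    """Inverse of partition_patches."""
    gh, gw = grid_shape
    p = patch_size
    n = tokens.shape[0]
    x = ad.reshape(tokens, (n, gh, gw, channels, p, p))
    x = ad.transpose(x, (0, 1, 4, 2, 5, 3))
    return ad.reshape(x, (n, gh * p, gw * p, channels))


def _window_partition(x: Tensor, grid, win) -> Tensor:
    """(N, gh, gw, E) -> (N * n_windows, wh*ww, E)."""
    n, e = x.shape[0], x.shape[-1]
    gh, gw = grid
    wh, ww = win
    x = ad.reshape(x, (n, gh // wh, wh, gw // ww, ww, e))
    x = ad.transpose(x, (0, 1, 3, 2, 4, 5))
    return ad.reshape(x, (n * (gh // wh) * (gw // ww), wh * ww, e))


def _window_merge(x: Tensor, grid, win, n: int) -> Tensor:
    gh, gw = grid
    wh, ww = win
    e = x.shape[-1]
    x = ad.reshape(x, (n, gh // wh, gw // ww, wh, ww, e))
    x = ad.transpose(x, (0, 1, 3, 2, 4, 5))
    return ad.reshape(x, (n, gh * gw, e))


def _shift_mask(grid, win, shift) -> np.ndarray:
    """Additive attention mask (n_windows, T, T) for cyclic window shifts:
    tokens wrapped together from different image regions must not attend."""
    gh, gw = grid
    wh, ww = win
    sh, sw = shift
    img = np.zeros((gh, gw), np.int32)
    cnt = 0
    h_sl = ((0, gh - wh), (gh - wh, gh - sh), (gh - sh, gh)) if sh else \
        ((0, gh),)
    w_sl = ((0, gw - ww), (gw - ww, gw - sw), (gw - sw, gw)) if sw else \
        ((0, gw),)
    for h0, h1 in h_sl:
        for w0, w1 in w_sl:
            img[h0:h1, w0:w1] = cnt
            cnt += 1
    wins = img.reshape(gh // wh, wh, gw // ww, ww).transpose(0, 2, 1, 3)
    wins = wins.reshape(-1, wh * ww)
    diff = wins[:, None, :] != wins[:, :, None]
    return np.where(diff, np.float32(-1e4), np.float32(0.0))


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class ConvBlock(nn.Module):
    """Conv2D -> BatchNorm -> ReLU."""

    def __init__(self, rng, c_in, c_out, k=3, stride=1):
        super().__init__()
        self.conv = nn.Conv2d(rng, c_in, c_out, k, stride)
        self.bn = nn.BatchNorm2d(c_out)

    def forward(self, x):
        return ad.relu(self.bn(self.conv(x)))

    __call__ = forward


class SwinBlock(nn.Module):
    """LN -> windowed MHSA -> residual -> LN -> MLP -> residual."""

    def __init__(self, rng, embed: int, heads: int, mlp_ratio: int,
                 shifted: bool):
        super().__init__()
        self.embed = embed
        self.heads = heads
        self.shifted = shifted
        self.norm1 = nn.LayerNorm(embed)
        self.qkv = nn.Linear(rng, embed, 3 * embed)
        self.proj = nn.Linear(rng, embed, embed)
        self.norm2 = nn.LayerNorm(embed)
        self.fc1 = nn.Linear(rng, embed, mlp_ratio * embed)
        self.fc2 = nn.Linear(rng, mlp_ratio * embed, embed)
        self._mask_cache = {}

    def _geometry(self, grid, config: NetworkConfig):
        gh, gw = grid
        if config.window is None:
            wh, ww = _auto_window(gh), _auto_window(gw)
        else:
            wh = ww = config.window
            if gh % wh or gw % ww:
                raise ValidationError(
                    f"window {config.window} does not divide grid {grid}")
        sh = sw = 0
        if self.shifted:
            sh = (config.shift if config.shift is not None else wh // 2) \
                if wh < gh else 0
            sw = (config.shift if config.shift is not None else ww // 2) \
                if ww < gw else 0
        return (wh, ww), (sh, sw)

    def attention(self, x: Tensor, grid, config: NetworkConfig,
                  collect=None) -> Tensor:
        n = x.shape[0]
        (wh, ww), (sh, sw) = self._geometry(grid, config)
        e, h = self.embed, self.heads
        d = e // h
        g = ad.reshape(x, (n, grid[0], grid[1], e))
        if sh or sw:
            g = ad.roll(g, (-sh, -sw), (1, 2))
        wtok = _window_partition(g, grid, (wh, ww))     # (M, T, E)
        m, t = wtok.shape[0], wh * ww
        qkv = self.qkv(wtok)                            # (M, T, 3E)
        qkv = ad.reshape(qkv, (m, t, 3, h, d))
        qkv = ad.transpose(qkv, (2, 0, 3, 1, 4))        # (3, M, h, T, d)
        qs = _take_first(qkv, 0)
        ks = _take_first(qkv, 1)
        vs = _take_first(qkv, 2)
        scores = ad.matmul(qs, ad.transpose(ks, (0, 1, 3, 2))) * (d ** -0.5)
        if sh or sw:
            key = (grid, (wh, ww), (sh, sw))
            if key not in self._mask_cache:
                self._mask_cache[key] = _shift_mask(grid, (wh, ww), (sh, sw))
            mask = self._mask_cache[key]                # (nw, T, T)
            nw = mask.shape[0]
            scores = ad.reshape(scores, (n, nw, h, t, t))
            scores = scores + Tensor(mask[None, :, None, :, :])
            scores = ad.reshape(scores, (m, h, t, t))
        p = ad.softmax(scores, axis=-1)                 # (M, h, T, T)
        if collect is not None:
            collect.append(p.data.copy())
        out = ad.matmul(p, vs)                          # (M, h, T, d)
        out = ad.transpose(out, (0, 2, 1, 3))
        out = ad.reshape(out, (m, t, e))
        out = self.proj(out)
        g = _window_merge(out, grid, (wh, ww), n)
        if sh or sw:
            g = ad.reshape(g, (n, grid[0], grid[1], e))
            g = ad.roll(g, (sh, sw), (1, 2))
            g = ad.reshape(g, (n, grid[0] * grid[1], e))
        return g

    def forward(self, x: Tensor, grid, config: NetworkConfig,
                collect=None) -> Tensor:
        x = x + self.attention(self.norm1(x), grid, config, collect)
        x = x + self.fc2(ad.gelu(self.fc1(self.norm2(x))))
        return x

    __call__ = forward


def _take_first(qkv: Tensor, idx: int) -> Tensor:
    """Select qkv[idx] of a (3, M, h, T, d) tensor, keeping gradients."""
    out = Tensor(qkv.data[idx], qkv.requires_grad, (qkv,))

    def _bw(g):
        full = np.zeros_like(qkv.data)
        full[idx] = g
        qkv._accumulate(full)
    out._backward = _bw
    return out


class SwinUNet(nn.Module):
    """Full encoder / Swin bottleneck / decoder network."""

    def __init__(self, config: NetworkConfig, image_size, seed: int = 0):
        super().__init__()
        config.validate()
        _check_divisible(image_size)
        self.config = config
        self.image_size = tuple(image_size)
        rng = np.random.default_rng(seed)
        c1, c2, c3 = config.encoder_channels
        k, s = config.encoder_kernel, config.encoder_stride
        self.enc1 = ConvBlock(rng, 1, c1, k, s)
        self.enc2 = ConvBlock(rng, c1, c2, k, s)
        self.enc3 = ConvBlock(rng, c2, c3, k, s)

        p = config.patch_size
        h, w = self.image_size
        self.grid = (h // 8 // p, w // 8 // p)
        token_dim = c3 * p * p
        self.embed = nn.Linear(rng, token_dim, config.embed_dim)
        self.pos = Tensor(
            (0.02 * rng.standard_normal(
                (self.grid[0] * self.grid[1], config.embed_dim))
             ).astype(np.float32), requires_grad=True)
        self.blocks = [SwinBlock(rng, config.embed_dim, config.n_heads,
                                 config.mlp_ratio, shifted=(i % 2 == 1))
                       for i in range(config.n_swin_blocks)]
        self.unembed = nn.Linear(rng, config.embed_dim, token_dim)

        kd = config.encoder_kernel
        sd = config.decoder_stride
        self.dec1 = ConvBlock(rng, c3 + c2, c3, kd, sd)
        self.dec2 = ConvBlock(rng, c3 + c1, c2, kd, sd)
        self.dec3 = ConvBlock(rng, c2 + 1, c1, kd, sd)
        self.final = nn.Conv2d(rng, c1, 1, kd, sd)

    # -- stages --------------------------------------------------------
    def encode(self, x: Tensor) -> FeatureStack:
        if not np.isfinite(x.data).all():
            raise ValidationError("input image contains non-finite pixels")
        h, w = x.shape[1:3]
        if h % 8 or w % 8:
            raise DivisibilityError(
                f"encoder input {(h, w)} must be divisible by 8 "
                "(three stride-2 convolutions)")
        f1 = self.enc1(x)
        f2 = self.enc2(f1)
        f3 = self.enc3(f2)
        return FeatureStack(f1, f2, f3)

    def _positional(self, grid) -> Tensor:
        if grid == self.grid:
            return self.pos
        # inference on a different grid: bilinear-resize the learned table
        from scipy.ndimage import zoom
        e = self.pos.shape[1]
        table = self.pos.data.reshape(*self.grid, e)
        zoomed = zoom(table, (grid[0] / self.grid[0],
                              grid[1] / self.grid[1], 1), order=1)
        return Tensor(zoomed.reshape(grid[0] * grid[1], e))

    def stm_forward(self, f3: Tensor, collect_attn=None) -> Tensor:
        n, h, w, c = f3.shape
        p = self.config.patch_size
        if h % p or w % p:
            raise ValidationError(f"bottleneck map {h}x{w} not divisible "
                                  f"by patch size {p}")
        grid = (h // p, w // p)
        tokens = partition_patches(f3, p)
        x = self.embed(tokens) + self._positional(grid)
        for blk in self.blocks:
            x = blk(x, grid, self.config, collect_attn)
        x = self.unembed(x)
        return merge_patches(x, grid, c, p)

    def decode(self, stm_out: Tensor, skips: FeatureStack,
               original: Tensor) -> Tensor:
        d = self.dec1(ad.concat([ad.upsample_nearest2(stm_out), skips.f2]))
        d = self.dec2(ad.concat([ad.upsample_nearest2(d), skips.f1]))
        d = self.dec3(ad.concat([ad.upsample_nearest2(d), original]))
        return ad.sigmoid(self.final(d))

    def forward(self, x: Tensor, collect_attn=None) -> Tensor:
        """x: (N, H, W, 1) channels-last; returns the same shape."""
        _check_divisible(x.shape[1:3])
        skips = self.encode(x)
        s = self.stm_forward(skips.f3, collect_attn)
        return self.decode(s, skips, x)

    __call__ = forward


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainResult:
    checkpoint_path: Path
    loss_log: list          # (epoch, train_loss, val_loss)
    best_val_loss: float
    best_epoch: int


def normalize_minmax(img: np.ndarray) -> np.ndarray:
    lo, hi = float(img.min()), float(img.max())
    if hi <= lo:
        return np.zeros_like(img, np.float32)
    return ((img - lo) / (hi - lo)).astype(np.float32)


def _load_split(manifest: DatasetManifest, part: str):
    from .pipeline_io import read_image

    ids = manifest.ids_for(part)
    xs, ys = [], []
    for pid in ids:
        e = manifest.entry(pid)
        x, _ = read_image(manifest.path(e.nir1))
        y, _ = read_image(manifest.path(e.nir2a))
        xs.append(normalize_minmax(x)[..., None])
        ys.append(normalize_minmax(y)[..., None])
    return np.asarray(xs, np.float32), np.asarray(ys, np.float32)


def train(manifest: DatasetManifest, net_config: NetworkConfig | None = None,
          train_config: TrainConfig | None = None,
          out_dir=None) -> TrainResult:
    """Train on the manifest's train split, checkpointing the best val loss.

    Fully deterministic given the configs and manifest: model init and batch
    shuffling derive from ``train_config.seed``.
    """
    net_config = net_config or NetworkConfig()
    train_config = train_config or TrainConfig()
    net_config.validate()
    train_config.validate()

    xtr, ytr = _load_split(manifest, "train")
    xva, yva = _load_split(manifest, "val")
    if len(xtr) == 0 or len(xva) == 0:
        raise ValidationError("manifest needs non-empty train and val splits")

    model = SwinUNet(net_config, manifest.size, seed=train_config.seed)
    opt = nn.Adam(model.parameters(), lr=train_config.learning_rate)
    loss_fn = ad.l1_loss if train_config.loss == "l1" else ad.l2_loss
    rng = np.random.default_rng(train_config.seed + 1)

    def val_loss():
        model.eval()
        tot = 0.0
        with ad.no_grad():
            for i in range(len(xva)):
                pred = model(Tensor(xva[i:i + 1]))
                tot += float(loss_fn(pred, yva[i:i + 1]).data)
        model.train()
        return tot / len(xva)

    log_rows = []
    best = (np.inf, -1, None)
    bs = train_config.batch_size
    for epoch in range(1, train_config.epochs + 1):
        model.train()
        order = rng.permutation(len(xtr))
        tot = 0.0
        for start in range(0, len(order), bs):
            idx = order[start:start + bs]
            x = Tensor(xtr[idx], requires_grad=False)
            pred = model(x)
            loss = loss_fn(pred, ytr[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            tot += float(loss.data) * len(idx)
            x = pred = loss = None  # release the step's graph promptly
        vl = val_loss()
        log_rows.append((epoch, tot / len(xtr), vl))
        if vl < best[0]:
            best = (vl, epoch, copy.deepcopy(model.state_dict()))

    out_dir = Path(out_dir) if out_dir is not None else manifest.root / "model"
    out_dir.mkdir(parents=True, exist_ok=True)
    ckpt = out_dir / "checkpoint.npz"
    save_checkpoint(ckpt, best[2], net_config, manifest.size, train_config)
    with open(out_dir / "loss_log.csv", "w") as fh:
        fh.write("epoch,train_loss,val_loss\n")
        for row in log_rows:
            fh.write(f"{row[0]},{row[1]:.8f},{row[2]:.8f}\n")
    return TrainResult(ckpt, log_rows, best[0], best[1])


def save_checkpoint(path, state: dict, net_config: NetworkConfig,
                    image_size, train_config: TrainConfig | None = None):
    meta = {"network": asdict(net_config),
            "image_size": list(image_size),
            "training": asdict(train_config) if train_config else None,
            "format_version": 1}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> SwinUNet:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    netd = meta["network"]
    for key in ("encoder_channels",):
        netd[key] = tuple(netd[key])
    model = SwinUNet(NetworkConfig(**netd), tuple(meta["image_size"]))
    model.load_state_dict(state)
    return model


def enhance(image: np.ndarray, model: SwinUNet, pad: bool = False,
            normalize: bool = True) -> np.ndarray:
    """Single-pass inference: NIR-I frame in, NIR-IIa-like frame out.

    The frame must be divisible by 40 on both axes; with ``pad=True`` it is
    reflect-padded to the next multiple and the prediction cropped back.
    """
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 2:
        raise ValidationError("enhance expects a single 2-D frame")
    h, w = image.shape
    ph = (-h) % SIZE_DIVISOR
    pw = (-w) % SIZE_DIVISOR
    if (ph or pw) and not pad:
        _check_divisible(image.shape)  # raises with the pad suggestion
    work = np.pad(image, ((0, ph), (0, pw)), mode="reflect") \
        if (ph or pw) else image
    if normalize:
        work = normalize_minmax(work)
    model.eval()
    with ad.no_grad():
        pred = model(Tensor(work[None, :, :, None]))
    out = pred.data[0, :, :, 0]
    return np.ascontiguousarray(out[:h, :w])
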