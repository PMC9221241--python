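"""FECC-Net assembly: dual-encoder U-shaped segmentation network.

Topology (depth ``d``, input at resolution S = ``input_size``):

* **Main encoder** — ``d`` levels; level ``l`` (resolution S/2^(l-1)) applies
  two 3x3 ConvBlocks and an SE block, exports its output as the skip
  ``S_l``, then 2x max-pools.
* **ASPP bottleneck** — atrous pyramid on the deepest pooled features
  (resolution S/2^d).
* **Enhanced encoder** (full variant only) — a parallel boundary-feature
  branch over the raw input: a ConvBlock stem then, per level, a stack of
  depthwise-separable blocks; each level 2x max-pools and exports a map
  ``E_l`` at resolution S/2^l.  ``E_d`` is concatenated with the ASPP output
  at the bottleneck; ``E_1 .. E_{d-1}`` feed the matching decoder stages.
* **Decoder** — ``d`` stages; stage ``l`` (deepest first) 2x bilinearly
  upsamples, concatenates the main skip ``S_l`` and (full variant, l >= 2)
  the enhanced skip ``E_{l-1}``, then applies two ConvBlocks producing
  ``channel_schedule[l-1]`` channels.
* **Head** — 1x1 convolution (with bias) to one channel + logistic
  squashing, so outputs live strictly in (0, 1).

The lite variant drops the enhanced encoder and the corresponding decoder
concat widths.  The channel widths shipped in :data:`DEFAULT_CONFIG` were
frozen by :func:`calibrate_config`, which searches width grids with the
package's own parameter counter until the full/lite budgets round to the
published 7.0M / 3.8M.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np

from ._nn import Conv2d, MaxPool2d, Sigmoid, UpsampleBilinear2x
from .blocks import ASPP, ConvBlock, DepthwiseSeparableBlock, SEBlock
from .errors import ConfigurationError, InputError


@dataclass
class NetworkConfig:
    """Structural hyper-parameters of the network (the calibration surface)."""

    input_size: int = 512
    input_channels: int = 1
    depth: int = 4
    channel_schedule: tuple[int, ...] = (32, 64, 128, 256)
    aspp_rates: tuple[int, ...] = (1, 6, 12, 18)
    aspp_channels: int = 256
    enhanced_encoder: bool = True
    enhanced_schedule: tuple[int, ...] = (32, 64, 128, 256)
    enhanced_stack: int = 2
    se_reduction: int = 8
    threshold: float = 0.5
    dtype: str = "float32"

    def __post_init__(self) -> None:
        self.channel_schedule = tuple(self.channel_schedule)
        self.aspp_rates = tuple(self.aspp_rates)
        self.enhanced_schedule = tuple(self.enhanced_schedule)
        if self.depth < 1:
            raise ConfigurationError("depth must be >= 1")
        if len(self.channel_schedule) != self.depth:
            raise ConfigurationError("channel_schedule must have one entry per level")
        if any(b <= a for a, b in zip(self.channel_schedule, self.channel_schedule[1:])):
            raise ConfigurationError("channel_schedule must be strictly increasing")
        if self.input_size % (1 << self.depth):
            raise ConfigurationError(
                f"input_size {self.input_size} must be divisible by 2^depth = {1 << self.depth}"
            )
        if self.enhanced_encoder and len(self.enhanced_schedule) != self.depth:
            raise ConfigurationError("enhanced_schedule must have one entry per level")
        if not 0.0 < self.threshold < 1.0:
            raise ConfigurationError("threshold must lie in (0, 1)")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "NetworkConfig":
        return cls(**json.loads(text))


class FECCNet:
    """The assembled network; deterministic given (config, seed)."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0) -> None:
        self.cfg = cfg
        self.seed = seed
        rng = np.random.default_rng(seed)
        dt = np.dtype(cfg.dtype).type
        d = cfg.depth
        cs = cfg.channel_schedule
        es = cfg.enhanced_schedule

        # main encoder
        self.enc = []
        in_ch = cfg.input_channels
        for l in range(d):
            block = {
                "conv1": ConvBlock(in_ch, cs[l], rng=rng, dtype=dt),
                "conv2": ConvBlock(cs[l], cs[l], rng=rng, dtype=dt),
                "se": SEBlock(cs[l], cfg.se_reduction, rng=rng, dtype=dt),
                "pool": MaxPool2d(),
            }
            self.enc.append(block)
            in_ch = cs[l]

        self.aspp = ASPP(cs[-1], cfg.aspp_channels, cfg.aspp_channels,
                         cfg.aspp_rates, rng=rng, dtype=dt)

        # enhanced encoder (parallel branch on the raw input)
        self.enh = None
        if cfg.enhanced_encoder:
            self.enh = []
            prev = es[0]
            stem = {"blocks": [ConvBlock(cfg.input_channels, es[0], rng=rng, dtype=dt)],
                    "pool": MaxPool2d()}
            self.enh.append(stem)
            for l in range(1, d):
                blocks = [DepthwiseSeparableBlock(prev, es[l], rng=rng, dtype=dt)]
                for _ in range(cfg.enhanced_stack - 1):
                    blocks.append(DepthwiseSeparableBlock(es[l], es[l], rng=rng, dtype=dt))
                self.enh.append({"blocks": blocks, "pool": MaxPool2d()})
                prev = es[l]

        # decoder, deepest stage first
        bottleneck_ch = cfg.aspp_channels + (es[-1] if cfg.enhanced_encoder else 0)
        self.dec = []
        prev = bottleneck_ch
        for l in range(d, 0, -1):
            cat_ch = prev + cs[l - 1]
            if cfg.enhanced_encoder and l >= 2:
                cat_ch += es[l - 2]
            stage = {
                "up": UpsampleBilinear2x(),
                "conv1": ConvBlock(cat_ch, cs[l - 1], rng=rng, dtype=dt),
                "conv2": ConvBlock(cs[l - 1], cs[l - 1], rng=rng, dtype=dt),
            }
            self.dec.append(stage)
            prev = cs[l - 1]

        self.head = Conv2d(cs[0], 1, kernel_size=1, bias=True, rng=rng, dtype=dt)
        self.sigmoid = Sigmoid()

    # ---- parameters -------------------------------------------------
    def modules(self):
        for block in self.enc:
            yield block["conv1"]
            yield block["conv2"]
            yield block["se"]
        yield self.aspp
        if self.enh is not None:
            for level in self.enh:
                yield from level["blocks"]
        for stage in self.dec:
            yield stage["conv1"]
            yield stage["conv2"]
        yield self.head

    def params(self):
        out = []
        for m in self.modules():
            out.extend(m.params())
        return out

    @property
    def total_parameters(self) -> int:
        return sum(p.size for p in self.params())

    # ---- forward / backward -----------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """(N, C_in, H, W) -> per-pixel foreground probabilities (N, 1, H, W)."""
        cfg = self.cfg
        n, c, h, w = x.shape
        if c != cfg.input_channels:
            raise InputError(f"expected {cfg.input_channels} channels, got {c}")
        if h % (1 << cfg.depth) or w % (1 << cfg.depth):
            raise InputError("spatial size must be divisible by 2^depth")

        skips = []
        u = x
        for block in self.enc:
            u = block["conv1"].forward(u, train)
            u = block["conv2"].forward(u, train)
            u = block["se"].forward(u, train)
            skips.append(u)
            u = block["pool"].forward(u, train)
        u = self.aspp.forward(u, train)

        enh_maps = []
        if self.enh is not None:
            e = x
            for level in self.enh:
                for b in level["blocks"]:
                    e = b.forward(e, train)
                e = level["pool"].forward(e, train)
                enh_maps.append(e)
            u = np.concatenate([u, enh_maps[-1]], axis=1)

        self._cat_specs = []
        d = cfg.depth
        for i, stage in enumerate(self.dec):
            l = d - i  # level this stage decodes to (resolution S/2^(l-1))
            u = stage["up"].forward(u, train)
            parts = [u, skips[l - 1]]
            if self.enh is not None and l >= 2:
                parts.append(enh_maps[l - 2])
            self._cat_specs.append([p.shape[1] for p in parts])
            u = np.concatenate(parts, axis=1)
            u = stage["conv1"].forward(u, train)
            u = stage["conv2"].forward(u, train)
        logits = self.head.forward(u, train)
        return self.sigmoid.forward(logits, train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        """Backpropagate a gradient w.r.t. the output probabilities."""
        cfg = self.cfg
        d = cfg.depth
        du = self.head.backward(self.sigmoid.backward(dy))

        dskips = [None] * d
        denh = [None] * d if self.enh is not None else None
        for i in range(d - 1, -1, -1):
            stage = self.dec[i]
            l = d - i
            dcat = stage["conv1"].backward(stage["conv2"].backward(du))
            widths = self._cat_specs[i]
            ofs = np.cumsum([0] + widths)
            dparts = [dcat[:, ofs[j] : ofs[j + 1]] for j in range(len(widths))]
            dskips[l - 1] = dparts[1]
            if self.enh is not None and l >= 2:
                denh[l - 2] = dparts[2]
            du = stage["up"].backward(dparts[0])

        dx_enh = None
        if self.enh is not None:
            w_aspp = self.cfg.aspp_channels
            denh[d - 1] = du[:, w_aspp:]
            du = du[:, :w_aspp]
            de = None
            for i in range(d - 1, -1, -1):
                level = self.enh[i]
                g = denh[i] if de is None else de + denh[i]
                g = level["pool"].backward(g)
                for b in reversed(level["blocks"]):
                    g = b.backward(g)
                de = g
            dx_enh = de

        du = self.aspp.backward(du)
        for i in range(d - 1, -1, -1):
            block = self.enc[i]
            g = block["pool"].backward(du)
            g = g + dskips[i]
            g = block["se"].backward(g)
            g = block["conv2"].backward(g)
            du = block["conv1"].backward(g)
        return du if dx_enh is None else du + dx_enh

    def enhanced_feature_maps(self, x: np.ndarray, train: bool = False) -> list[np.ndarray]:
        """Run only the enhanced encoder: one map per level, at S/2^l."""
        if self.enh is None:
            raise ConfigurationError("this network has no enhanced encoder")
        maps = []
        e = x
        for level in self.enh:
            for b in level["blocks"]:
                e = b.forward(e, train)
            e = level["pool"].forward(e, train)
            maps.append(e)
        return maps

    # ---- prediction --------------------------------------------------
    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Images on the [0, 255] scale, (N, H, W) or (H, W) -> probabilities."""
        arr = np.asarray(images, dtype=np.dtype(self.cfg.dtype))
        single = arr.ndim == 2
        if single:
            arr = arr[None]
        x = (arr / 255.0)[:, None]
        p = self.forward(x, train=False)[:, 0]
        return p[0] if single else p

    def predict_mask(self, image: np.ndarray) -> np.ndarray:
        """Binarise the predicted probabilities at ``cfg.threshold``."""
        image = np.asarray(image)
        s = self.cfg.input_size
        if image.shape != (s, s):
            raise InputError(f"expected a ({s}, {s}) image, got {image.shape}")
        p = self.predict_proba(image)
        return (p > self.cfg.threshold).astype(np.uint8)

    # ---- (de)serialisation -------------------------------------------
    def _state_arrays(self):
        arrays = {}
        for i, p in enumerate(self.params()):
            arrays[f"param_{i}"] = p.data
        j = 0
        for m in self.modules():
            for layer in getattr(m, "_layers", lambda: [])():
                if hasattr(layer, "running_mean"):
                    arrays[f"bn_mean_{j}"] = layer.running_mean
                    arrays[f"bn_var_{j}"] = layer.running_var
                    j += 1
        return arrays

    def save(self, path) -> None:
        """Write weights (npz) plus a JSON sidecar with the exact config."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self._state_arrays())
        path.with_suffix(".json").write_text(
            json.dumps({"config": asdict(self.cfg), "seed": self.seed}, indent=1)
        )

    @classmethod
    def load(cls, path) -> "FECCNet":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        net = cls(NetworkConfig(**meta["config"]), seed=meta["seed"])
        with np.load(path.with_suffix(".npz")) as data:
            for i, p in enumerate(net.params()):
                p.data[...] = data[f"param_{i}"]
            j = 0
            for m in net.modules():
                for layer in getattr(m, "_layers", lambda: [])():
                    if hasattr(layer, "running_mean"):
                        layer.running_mean[...] = data[f"bn_mean_{j}"]
                        layer.running_var[...] = data[f"bn_var_{j}"]
                        j += 1
        return net


def build_fecc_net(cfg: NetworkConfig | None = None, seed: int = 0) -> FECCNet:
    """Build the full network (enhanced encoder enabled)."""
    cfg = replace(cfg or DEFAULT_CONFIG, enhanced_encoder=True)
    return FECCNet(cfg, seed=seed)


def build_fecc_net_lite(cfg: NetworkConfig | None = None, seed: int = 0) -> FECCNet:
    """Build the lite variant: no enhanced encoder, narrower decoder concats."""
    cfg = replace(cfg or DEFAULT_CONFIG, enhanced_encoder=False)
    return FECCNet(cfg, seed=seed)


def count_parameters(net: FECCNet) -> int:
    """Exact number of trainable scalars (BN contributes 2C per layer)."""
    return net.total_parameters


def _count_for(cfg: NetworkConfig) -> int:
    return FECCNet(cfg, seed=0).total_parameters


def calibrate_config(
    target_full: float = 7.0e6,
    target_lite: float = 3.8e6,
    base_widths=(32, 24, 40, 16, 48),
    aspp_widths=range(16, 513, 8),
    enhanced_bases=range(8, 129),
    stacks=(1, 2, 3),
    verbose: bool = False,
) -> NetworkConfig:
    """Freeze channel widths so both parameter budgets round to target/1e6.

    Stage 1 keeps the first base width (preference order: 32 first) whose
    geometric schedule admits an ``aspp_channels`` making the lite count
    round to ``target_lite``; stage 2, with those frozen, scans the
    enhanced-encoder base width and stack depth for the full budget,
    keeping the closest hit. The parameter counter itself is the oracle.
    Pure graph construction: runs in under a minute on one CPU.
    """
    def rounds_to(n, target):
        return round(n / 1e5) == round(target / 1e5)

    schedule = a = None
    for c in base_widths:
        cand = (c, 2 * c, 4 * c, 8 * c)
        hits = []
        for width in aspp_widths:
            cfg = NetworkConfig(channel_schedule=cand, aspp_channels=width,
                                enhanced_encoder=False)
            n = _count_for(cfg)
            if rounds_to(n, target_lite):
                hits.append((abs(n - target_lite), width, n))
        if hits:
            _, a, n_lite = min(hits)
            schedule = cand
            break
    if schedule is None:
        raise ConfigurationError("no lite configuration met the target budget")
    if verbose:  # pragma: no cover
        print(f"lite: schedule={schedule} aspp={a} -> {n_lite}")

    best_full = None
    for e in enhanced_bases:
        es = (e, 2 * e, 4 * e, 8 * e)
        for s in stacks:
            cfg = NetworkConfig(channel_schedule=schedule, aspp_channels=a,
                                enhanced_encoder=True, enhanced_schedule=es,
                                enhanced_stack=s)
            n = _count_for(cfg)
            err = abs(n - target_full)
            if rounds_to(n, target_full) and (best_full is None or err < best_full[0]):
                best_full = (err, es, s, n)
    if best_full is None:
        raise ConfigurationError("no full configuration met the target budget")
    _, es, s, n_full = best_full
    if verbose:  # pragma: no cover
        print(f"full: enhanced={es} stack={s} -> {n_full}")
    return NetworkConfig(channel_schedule=schedule, aspp_channels=a,
                         enhanced_encoder=True, enhanced_schedule=es,
                         enhanced_stack=s)


#: Frozen output of :func:`calibrate_config` (see docs/methods.md):
#: full network 7,008,469 trainable scalars (7.0M), lite 3,808,909 (3.8M).
DEFAULT_CONFIG = NetworkConfig(
    channel_schedule=(32, 64, 128, 256),
    aspp_channels=56,
    enhanced_schedule=(70, 140, 280, 560),
    enhanced_stack=3,
)

#: CPU-scale profile used by the test suite and the worked examples.
TEST_SCALE_CONFIG = NetworkConfig(
    input_size=64,
    channel_schedule=(8, 16, 32, 64),
    aspp_channels=32,
    enhanced_schedule=(8, 16, 32, 64),
    enhanced_stack=1,
)
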