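"""The detection network: a 2.5D, two-branch, multi-scale convolutional
architecture with deeply supervised side outputs.

The design follows the holistically-nested (HED) idiom. Each MRI sequence
(T2w, ADC) enters its own branch of convolutional blocks so the network can
learn sequence-specific features at the larger scales; the branch features
are then concatenated and processed by shared blocks at the smaller scales.
Every scale emits a side output (1x1 projection to the three classes,
bilinearly upsampled to the input size), and a fused head combines all side
outputs with a final 1x1 projection. Inputs are 2.5D: three adjacent slices
per sequence enter as channels, and the network predicts the middle slice.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .nn import BilinearUp, Conv2d, MaxPool2, ReLU, softmax
from .volume import VolumeError

__all__ = [
    "ModelConfig",
    "ProbabilityVolume",
    "SPCNet",
    "assemble_25d_input",
    "build_model",
    "predict_case",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``n_scales`` resolution levels (downsampled 2x between levels);
    ``branch_depth`` of them are kept sequence-separate before concatenation.
    Channel width starts at ``base_width`` and doubles per scale up to
    ``width_cap``.
    """

    n_scales: int = 5
    branch_depth: int = 2
    base_width: int = 16
    width_cap: int = 128
    n_classes: int = 3
    n_context_slices: int = 3
    input_size_px: int = 224
    deep_supervision: bool = True
    kernel_size: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.branch_depth < self.n_scales):
            raise ValueError("need 1 <= branch_depth < n_scales")
        if self.n_context_slices % 2 != 1:
            raise ValueError("n_context_slices must be odd")
        if self.input_size_px % 2 ** (self.n_scales - 1) != 0:
            raise ValueError(
                f"input_size_px={self.input_size_px} not divisible by "
                f"2^(n_scales-1)={2 ** (self.n_scales - 1)}"
            )

    def width(self, scale: int) -> int:
        return min(self.base_width * 2**scale, self.width_cap)

    @property
    def n_side_outputs(self) -> int:
        return 2 * self.branch_depth + (self.n_scales - self.branch_depth)


@dataclass
class ProbabilityVolume:
    """Per-voxel 3-class softmax output stacked over slices: (3, S, H, W)."""

    probs: np.ndarray
    in_plane_spacing_mm: float
    slice_spacing_mm: float

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 4 or self.probs.shape[0] != 3:
            raise VolumeError(f"probs must be (3, S, H, W), got {self.probs.shape}")
        if not np.allclose(self.probs.sum(axis=0), 1.0, atol=1e-5):
            raise VolumeError("class probabilities must sum to 1 per voxel")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.probs.shape[1:]

    def channel(self, idx: int) -> np.ndarray:
        return self.probs[idx]

    def cancer_probability(self) -> np.ndarray:
        """Indolent + aggressive probability (any-cancer score)."""
        return self.probs[1] + self.probs[2]


class _Block:
    """Two 3x3 conv + ReLU layers at one scale."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        self.conv1, self.relu1 = Conv2d(c_in, c_out, k, rng), ReLU()
        self.conv2, self.relu2 = Conv2d(c_out, c_out, k, rng), ReLU()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        h = self.relu1.forward(self.conv1.forward(x, train), train)
        return self.relu2.forward(self.conv2.forward(h, train), train)

    def backward(self, g: np.ndarray) -> np.ndarray:
        g = self.conv2.backward(self.relu2.backward(g))
        return self.conv1.backward(self.relu1.backward(g))

    def convs(self):
        return {"conv1": self.conv1, "conv2": self.conv2}


class SPCNet:
    """Two-branch multi-scale network with side outputs and a fused head."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        k, sz = cfg.kernel_size, cfg.input_size_px
        bd, ns = cfg.branch_depth, cfg.n_scales

        self.branch_blocks: list[list[_Block]] = []
        self.branch_pools: list[list[MaxPool2]] = []
        for _seq in range(2):
            blocks, pools = [], []
            for s in range(bd):
                c_in = cfg.n_context_slices if s == 0 else cfg.width(s - 1)
                blocks.append(_Block(c_in, cfg.width(s), k, rng))
                pools.append(MaxPool2())
            self.branch_blocks.append(blocks)
            self.branch_pools.append(pools)

        self.shared_blocks: list[_Block] = []
        self.shared_pools: list[MaxPool2] = []
        for s in range(bd, ns):
            c_in = 2 * cfg.width(bd - 1) if s == bd else cfg.width(s - 1)
            self.shared_blocks.append(_Block(c_in, cfg.width(s), k, rng))
            if s < ns - 1:
                self.shared_pools.append(MaxPool2())

        # side outputs, in emission order: seq0 scales, seq1 scales, shared scales
        self.side_projs: list[Conv2d] = []
        self.side_ups: list[BilinearUp] = []
        for _seq in range(2):
            for s in range(bd):
                self.side_projs.append(Conv2d(cfg.width(s), cfg.n_classes, 1, rng))
                self.side_ups.append(BilinearUp((sz, sz)))
        for s in range(bd, ns):
            self.side_projs.append(Conv2d(cfg.width(s), cfg.n_classes, 1, rng))
            self.side_ups.append(BilinearUp((sz, sz)))

        self.fuse = Conv2d(cfg.n_side_outputs * cfg.n_classes, cfg.n_classes, 1, rng)
        self._branch_widths = None  # cached for backward concat split

    # ---- parameter plumbing -------------------------------------------------

    def _named_convs(self) -> dict[str, Conv2d]:
        out: dict[str, Conv2d] = {}
        for seq in range(2):
            for s, blk in enumerate(self.branch_blocks[seq]):
                for cname, conv in blk.convs().items():
                    out[f"seq{seq}.block{s}.{cname}"] = conv
        for s, blk in enumerate(self.shared_blocks):
            for cname, conv in blk.convs().items():
                out[f"shared.block{s}.{cname}"] = conv
        for i, proj in enumerate(self.side_projs):
            out[f"side{i}.proj"] = proj
        out["fuse"] = self.fuse
        return out

    def params(self) -> dict[str, np.ndarray]:
        return {
            f"{name}.{p}": arr
            for name, conv in self._named_convs().items()
            for p, arr in conv.params().items()
        }

    def zero_grads(self) -> None:
        for conv in self._named_convs().values():
            conv.grads = {}

    def grads(self) -> dict[str, np.ndarray]:
        out = {}
        for name, conv in self._named_convs().items():
            for p, arr in conv.params().items():
                out[f"{name}.{p}"] = conv.grads.get(p, np.zeros_like(arr))
        return out

    # ---- forward / backward -------------------------------------------------

    def forward(
        self, x_t2: np.ndarray, x_adc: np.ndarray, train: bool = True
    ) -> tuple[np.ndarray, list[np.ndarray]]:
        """Returns (fused logits, side logits), each (B, n_classes, H, W)."""
        cfg = self.cfg
        if x_t2.shape != x_adc.shape:
            raise VolumeError("T2w and ADC input stacks must share a shape")
        if x_t2.shape[2] != cfg.input_size_px or x_t2.shape[3] != cfg.input_size_px:
            raise VolumeError(
                f"expected {cfg.input_size_px}px inputs, got {x_t2.shape[2:]}"
            )
        sides: list[np.ndarray] = []
        side_i = 0
        feats = []
        for seq, x in enumerate((x_t2, x_adc)):
            h = x
            for s in range(cfg.branch_depth):
                h = self.branch_blocks[seq][s].forward(h, train)
                proj = self.side_projs[side_i].forward(h, train)
                sides.append(self.side_ups[side_i].forward(proj, train))
                side_i += 1
                h = self.branch_pools[seq][s].forward(h, train)
            feats.append(h)
        self._branch_widths = (feats[0].shape[1], feats[1].shape[1])
        h = np.concatenate(feats, axis=1)
        for j, s in enumerate(range(cfg.branch_depth, cfg.n_scales)):
            h = self.shared_blocks[j].forward(h, train)
            proj = self.side_projs[side_i].forward(h, train)
            sides.append(self.side_ups[side_i].forward(proj, train))
            side_i += 1
            if s < cfg.n_scales - 1:
                h = self.shared_pools[j].forward(h, train)
        fused = self.fuse.forward(np.concatenate(sides, axis=1), train)
        return fused, sides

    def backward(
        self, d_fused: np.ndarray, d_sides: list[np.ndarray] | None = None
    ) -> None:
        """Accumulate parameter gradients from head gradients."""
        cfg = self.cfg
        n = cfg.n_side_outputs
        if d_sides is None:
            d_sides = [np.zeros_like(d_fused) for _ in range(n)]
        d_cat = self.fuse.backward(d_fused)
        d_sides = [
            d_sides[i] + d_cat[:, i * cfg.n_classes : (i + 1) * cfg.n_classes]
            for i in range(n)
        ]

        def side_back(i: int) -> np.ndarray:
            return self.side_projs[i].backward(self.side_ups[i].backward(d_sides[i]))

        # shared trunk, deepest first
        side_i = n - 1
        dh = None
        for j in range(len(self.shared_blocks) - 1, -1, -1):
            s = cfg.branch_depth + j
            if s < cfg.n_scales - 1:
                dh = self.shared_pools[j].backward(dh)
            dh = side_back(side_i) if dh is None else dh + side_back(side_i)
            side_i -= 1
            dh = self.shared_blocks[j].backward(dh)
        # split concat back into the two branches
        w0, _ = self._branch_widths
        d_feats = [dh[:, :w0], dh[:, w0:]]
        for seq in (1, 0):
            dh = d_feats[seq]
            base = seq * cfg.branch_depth
            for s in range(cfg.branch_depth - 1, -1, -1):
                dh = self.branch_pools[seq][s].backward(dh)
                dh = dh + side_back(base + s)
                dh = self.branch_blocks[seq][s].backward(dh)

    def predict_proba(self, x_t2: np.ndarray, x_adc: np.ndarray) -> np.ndarray:
        """Fused-head softmax probabilities, (B, n_classes, H, W)."""
        fused, _ = self.forward(x_t2, x_adc, train=False)
        return softmax(fused, axis=1)


def build_model(cfg: ModelConfig) -> SPCNet:
    """Construct the network for a configuration (weights seeded by cfg.seed)."""
    return SPCNet(cfg)


def assemble_25d_input(volume: np.ndarray, slice_index: int) -> np.ndarray:
    """Three adjacent slices (i-1, i, i+1) of a (S, H, W) volume as channels;
    missing neighbours at the volume boundary are replicated from the edge."""
    n = volume.shape[0]
    if not (0 <= slice_index < n):
        raise IndexError(f"slice {slice_index} outside volume of {n} slices")
    lo = max(slice_index - 1, 0)
    hi = min(slice_index + 1, n - 1)
    return np.stack([volume[lo], volume[slice_index], volume[hi]], axis=0)


def predict_case(
    models: SPCNet | list[SPCNet],
    t2w: np.ndarray,
    adc: np.ndarray,
    in_plane_spacing_mm: float,
    slice_spacing_mm: float,
    batch_slices: int = 8,
) -> ProbabilityVolume:
    """Slice-wise ensemble prediction for a preprocessed case.

    ``t2w``/``adc`` are (S, H, W) arrays on the model's input grid. With a
    list of models, the fused softmax maps are averaged arithmetically
    (cross-validation ensembling)."""
    if isinstance(models, SPCNet):
        models = [models]
    if t2w.shape != adc.shape:
        raise VolumeError("T2w and ADC grids differ")
    cfg = models[0].cfg
    if t2w.shape[1] != cfg.input_size_px or t2w.shape[2] != cfg.input_size_px:
        raise VolumeError(
            f"case not preprocessed to the model's {cfg.input_size_px}px grid "
            f"(got {t2w.shape[1:]})"
        )
    n_slices = t2w.shape[0]
    out = np.zeros((3, n_slices) + t2w.shape[1:])
    for start in range(0, n_slices, batch_slices):
        idxs = range(start, min(start + batch_slices, n_slices))
        xb_t2 = np.stack([assemble_25d_input(t2w, i) for i in idxs])
        xb_adc = np.stack([assemble_25d_input(adc, i) for i in idxs])
        acc = np.zeros((len(xb_t2), 3) + t2w.shape[1:])
        for m in models:
            acc += m.predict_proba(xb_t2, xb_adc)
        acc /= len(models)
        out[:, list(idxs)] = acc.transpose(1, 0, 2, 3)
    return ProbabilityVolume(out, in_plane_spacing_mm, slice_spacing_mm)


def save_checkpoint(model: SPCNet, path: str | Path) -> Path:
    """Single-file checkpoint embedding the architecture config."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {k.replace(".", "/"): v for k, v in model.params().items()}
    arrays["__config__"] = np.frombuffer(
        json.dumps(asdict(model.cfg)).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)
    return path


def load_checkpoint(path: str | Path) -> SPCNet:
    with np.load(Path(path)) as data:
        cfg = ModelConfig(**json.loads(bytes(data["__config__"]).decode()))
        model = SPCNet(cfg)
        params = model.params()
        for k, arr in params.items():
            arr[...] = data[k.replace(".", "/")]
    return model
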