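"""Segmentation networks for inner-ear patches.

Two variants of the same encoder-decoder produce per-pixel five-class
scores (background + left/right cochlea + left/right vestibule) for a
square patch, fed with three consecutive MRC slices centred on the slice of
interest:

* ``3into3`` — three parallel encoder streams, one per slice; the feature
  maps after each stream's three added convolution layers are summed before
  the deconvolutional decoder;
* ``concat3into1`` — a single encoder on the channel-stacked slice triplet.

The encoder is the front of a VGG-19-style convolution stack (the first
``encoder_depth`` 3x3 convolutions, default 15, with 2x max-pools at the
standard block boundaries), followed by three added convolution layers;
the decoder is three transposed convolutions that upsample back to the
input size, with exactly two skip connections from the encoder stages whose
spatial sizes match the two intermediate decoder stages. All layer widths
scale with ``channel_scale`` so the same architecture trains at desk scale.

Boundary slices replicate the main slice, so every slice of a stack has a
triplet.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .imageops import CropSpec, Side, crop_patch, embed_patch, minmax01
from .stack import BACKGROUND, SubjectStack

# VGG-19 convolutional front: channel per conv layer, "P" = 2x max-pool.
_VGG19_PLAN: Tuple = (
    64, 64, "P",
    128, 128, "P",
    256, 256, 256, 256, "P",
    512, 512, 512, 512, "P",
    512, 512, 512, 512,
)


@dataclass(frozen=True)
class SegModelConfig:
    """Architecture and width configuration of the segmentation network."""

    variant: Literal["3into3", "concat3into1"] = "3into3"
    encoder_depth: int = 15
    extra_conv_layers: int = 3
    deconv_layers: int = 3
    skip_taps: Optional[Tuple[int, int]] = None  # encoder pool-stage indices
    channel_scale: float = 1.0
    n_classes: int = 5
    dropout: float = 0.6
    init: Literal["random"] = "random"
    share_streams: bool = False

    def __post_init__(self) -> None:
        if self.variant not in ("3into3", "concat3into1"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if not 0.0 < self.channel_scale <= 1.0:
            raise ValueError("channel_scale must be in (0, 1]")
        if not 0.0 <= self.dropout <= 1.0:
            raise ValueError("dropout must be in [0, 1]")
        if self.deconv_layers != 3:
            raise ValueError(
                "the decoder has three deconvolution stages (two skip "
                "connections); deconv_layers must be 3"
            )
        if self.extra_conv_layers < 1:
            raise ValueError("extra_conv_layers must be >= 1")
        n_convs = sum(1 for t in _VGG19_PLAN if t != "P")
        if not 1 <= self.encoder_depth <= n_convs:
            raise ValueError(f"encoder_depth must be in [1, {n_convs}]")
        if self.init != "random":
            raise ValueError(
                "only seeded random initialization is bundled; pretrained "
                "encoder weights are not shipped with the package"
            )

    def width(self, n: int) -> int:
        return max(1, int(round(n * self.channel_scale)))


@dataclass
class SliceTriplet:
    """Three consecutive patches centred on the slice of interest."""

    previous: np.ndarray
    main: np.ndarray
    next: np.ndarray

    def __post_init__(self) -> None:
        if not (self.previous.shape == self.main.shape == self.next.shape):
            raise ValueError("triplet patches must share geometry")

    def as_array(self) -> np.ndarray:
        return np.stack([self.previous, self.main, self.next], axis=0)


class _Encoder:
    """VGG-style convolution front; records pre-pool features as skip taps."""

    def __init__(self, cin: int, cfg: SegModelConfig, rng: np.random.Generator):
        self.layers: List[tuple[str, object]] = []
        self.tap_channels: List[int] = []
        convs = 0
        ch = cin
        for token in _VGG19_PLAN:
            if token == "P":
                if convs >= cfg.encoder_depth:
                    break
                self.tap_channels.append(ch)
                self.layers.append(("pool", nn.MaxPool2d()))
                continue
            if convs >= cfg.encoder_depth:
                break
            cout = cfg.width(token)
            self.layers.append(("conv", nn.Conv2d(ch, cout, rng=rng)))
            self.layers.append(("relu", nn.ReLU()))
            ch = cout
            convs += 1
        self.out_channels = ch
        self.n_pools = len(self.tap_channels)

    def parameters(self) -> List[nn.Param]:
        return [p for _, l in self.layers for p in l.parameters()]

    def share_params_from(self, other: "_Encoder") -> None:
        for (k1, l1), (k2, l2) in zip(self.layers, other.layers):
            if k1 == "conv":
                l1.W, l1.b = l2.W, l2.b

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, List[np.ndarray]]:
        taps: List[np.ndarray] = []
        for kind, layer in self.layers:
            if kind == "pool":
                taps.append(x)
            x = layer.forward(x)
        return x, taps

    def backward(self, dx: np.ndarray, dtaps: List[Optional[np.ndarray]]) -> np.ndarray:
        dtaps = list(dtaps)
        for kind, layer in reversed(self.layers):
            dx = layer.backward(dx)
            if kind == "pool":
                dtap = dtaps.pop()
                if dtap is not None:
                    dx = dx + dtap
        return dx


class _ExtraConvs:
    """The added convolution block after the encoder (with dropout)."""

    def __init__(self, ch: int, cfg: SegModelConfig, rng: np.random.Generator):
        self.blocks = [
            (nn.Conv2d(ch, ch, rng=rng), nn.ReLU(), nn.Dropout(min(cfg.dropout, 0.999)))
            for _ in range(cfg.extra_conv_layers)
        ]

    def parameters(self) -> List[nn.Param]:
        return [p for conv, _, _ in self.blocks for p in conv.parameters()]

    def share_params_from(self, other: "_ExtraConvs") -> None:
        for (c1, _, _), (c2, _, _) in zip(self.blocks, other.blocks):
            c1.W, c1.b = c2.W, c2.b

    def forward(self, x, train=False, rng=None):
        for conv, relu, drop in self.blocks:
            x = drop.forward(relu.forward(conv.forward(x)), train=train, rng=rng)
        return x

    def backward(self, dx):
        for conv, relu, drop in reversed(self.blocks):
            dx = conv.backward(relu.backward(drop.backward(dx)))
        return dx


class SegNet:
    """The built model: use :func:`build_model`; train via :mod:`hydroseg.train`."""

    def __init__(self, cfg: SegModelConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        cin_stream = 3 if cfg.variant == "concat3into1" else 1
        n_streams = 1 if cfg.variant == "concat3into1" else 3
        self.encoders = [_Encoder(cin_stream, cfg, rng) for _ in range(n_streams)]
        self.extras = [
            _ExtraConvs(self.encoders[0].out_channels, cfg, rng) for _ in range(n_streams)
        ]
        if cfg.share_streams and n_streams > 1:
            for enc, ext in zip(self.encoders[1:], self.extras[1:]):
                enc.share_params_from(self.encoders[0])
                ext.share_params_from(self.extras[0])

        P = self.encoders[0].n_pools
        if P < 2:
            raise ValueError(
                f"encoder_depth {cfg.encoder_depth} yields {P} pooling stages; "
                "at least 2 are needed for the two skip connections"
            )
        taps = cfg.skip_taps if cfg.skip_taps is not None else (P - 1, P - 2)
        if len(taps) != 2 or not all(0 <= t < P for t in taps) or taps[0] <= taps[1]:
            raise ValueError(
                f"skip_taps must be two distinct pool-stage indices in [0, {P}), "
                f"deepest first; got {taps}"
            )
        self.skip_taps = tuple(taps)
        tap_ch = self.encoders[0].tap_channels
        cbott = self.encoders[0].out_channels
        c1, c2 = cfg.width(256), cfg.width(128)
        # strides: two x2 stages to the tapped sizes, then one stage covering
        # the remaining pooling factor back to the input size
        self.dec1 = nn.ConvTranspose2d(cbott, c1, stride=2 ** (P - taps[0]), rng=rng)
        self.rel1 = nn.ReLU()
        self.dec2 = nn.ConvTranspose2d(
            c1 + tap_ch[taps[0]], c2, stride=2 ** (taps[0] - taps[1]), rng=rng
        )
        self.rel2 = nn.ReLU()
        self.dec3 = nn.ConvTranspose2d(
            c2 + tap_ch[taps[1]], cfg.n_classes, stride=2 ** taps[1], rng=rng
        )
        self._cache = None

    # -- parameters ---------------------------------------------------------

    def parameters(self) -> List[nn.Param]:
        seen: Dict[int, nn.Param] = {}
        groups: List[List[nn.Param]] = [e.parameters() for e in self.encoders]
        groups += [e.parameters() for e in self.extras]
        groups += [self.dec1.parameters(), self.dec2.parameters(), self.dec3.parameters()]
        for g in groups:
            for p in g:
                seen.setdefault(id(p), p)
        return list(seen.values())

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {f"p{i}": p.value.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(
                f"checkpoint has {len(state)} tensors, model has {len(params)}"
            )
        for i, p in enumerate(params):
            val = np.asarray(state[f"p{i}"])
            if val.shape != p.value.shape:
                raise ValueError(f"checkpoint tensor p{i} shape mismatch")
            p.value = val.astype(np.float64).copy()

    # -- forward / backward -------------------------------------------------

    def _stream_inputs(self, x: np.ndarray) -> List[np.ndarray]:
        if self.cfg.variant == "concat3into1":
            return [x]
        return [x[:, i : i + 1] for i in range(3)]

    def stream_feature(
        self, stream: int, x_slice: np.ndarray, train: bool = False, rng=None
    ) -> np.ndarray:
        """Bottleneck feature of one stream for a (N,1,H,W) input (diagnostics)."""
        f, _ = self.encoders[stream].forward(x_slice)
        return self.extras[stream].forward(f, train=train, rng=rng)

    def forward(
        self, x: np.ndarray, train: bool = False, rng: Optional[np.random.Generator] = None
    ) -> np.ndarray:
        """Per-pixel class scores (N, n_classes, H, W) for input (N, 3, H, W)."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError(f"expected input (N, 3, H, W); got {x.shape}")
        H, W = x.shape[2], x.shape[3]
        streams = self._stream_inputs(x)
        feats, taps_main = [], None
        for s, xs in enumerate(streams):
            f, taps = self.encoders[s].forward(xs)
            f = self.extras[s].forward(f, train=train, rng=rng)
            feats.append(f)
            if s == (1 if len(streams) == 3 else 0):
                taps_main = taps  # skips come from the main (centre) stream
        fused = feats[0] if len(feats) == 1 else feats[0] + feats[1] + feats[2]

        td, ts = taps_main[self.skip_taps[0]], taps_main[self.skip_taps[1]]
        d1 = self.rel1.forward(self.dec1.forward(fused, td.shape[2:]))
        c1 = np.concatenate([d1, td], axis=1)
        d2 = self.rel2.forward(self.dec2.forward(c1, ts.shape[2:]))
        c2 = np.concatenate([d2, ts], axis=1)
        scores = self.dec3.forward(c2, (H, W))
        self._cache = (len(streams), d1.shape[1], d2.shape[1])
        return scores

    def backward(self, dscores: np.ndarray) -> None:
        n_streams, c_d1, c_d2 = self._cache
        dc2 = self.dec3.backward(dscores)
        dd2, dts = dc2[:, :c_d2], dc2[:, c_d2:]
        dc1 = self.dec2.backward(self.rel2.backward(dd2))
        dd1, dtd = dc1[:, :c_d1], dc1[:, c_d1:]
        dfused = self.dec1.backward(self.rel1.backward(dd1))

        main = 1 if n_streams == 3 else 0
        P = self.encoders[0].n_pools
        for s in range(n_streams):
            dtaps: List[Optional[np.ndarray]] = [None] * P
            if s == main:
                dtaps[self.skip_taps[0]] = dtd
                dtaps[self.skip_taps[1]] = dts
            df = self.extras[s].backward(dfused)
            self.encoders[s].backward(df, dtaps)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return nn.softmax(self.forward(x, train=False), axis=1)


def build_model(cfg: SegModelConfig, seed: int = 0) -> SegNet:
    """Construct a seeded, randomly initialized segmentation network."""
    return SegNet(cfg, seed=seed)


def argmax_labels(scores: np.ndarray) -> np.ndarray:
    """Per-pixel argmax labels with ties broken toward background."""
    labels = scores.argmax(axis=1).astype(np.uint8)
    top = scores.max(axis=1)
    labels[scores[:, BACKGROUND] >= top] = BACKGROUND
    return labels


def make_triplet(
    stack_patches: Sequence[np.ndarray], slice_index: int
) -> SliceTriplet:
    """Triplet around a slice; boundary slices replicate the main slice."""
    n = len(stack_patches)
    prev = stack_patches[slice_index - 1] if slice_index > 0 else stack_patches[slice_index]
    nxt = (
        stack_patches[slice_index + 1]
        if slice_index < n - 1
        else stack_patches[slice_index]
    )
    return SliceTriplet(previous=prev, main=stack_patches[slice_index], next=nxt)


def predict_masks(
    model: SegNet, stack: SubjectStack, crop: CropSpec = CropSpec()
) -> np.ndarray:
    """Full-frame predicted label stack for a subject.

    Each side's patches are cropped from the MRC stack, min-max normalized,
    fed as slice triplets, argmax-labelled (ties to background) and
    re-embedded at their crop origins. Deterministic in eval mode.
    """
    S, H, W = stack.shape
    out = np.zeros((S, H, W), dtype=np.uint8)
    for side in ("left", "right"):
        patches = [
            minmax01(crop_patch(stack.mrc[k], side, crop, slice_index=k).data)
            for k in range(S)
        ]
        origin = crop.origin(side)
        x = np.stack([make_triplet(patches, k).as_array() for k in range(S)], axis=0)
        labels = argmax_labels(model.forward(x, train=False))
        for k in range(S):
            frame = np.zeros((H, W), dtype=np.uint8)
            embed_patch(frame, labels[k], origin)
            out[k][frame > 0] = frame[frame > 0]
    return out
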