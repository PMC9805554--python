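"""Shared-encoder, dual-decoder U-Net for multi-task bone-scan segmentation.

One encoder path (four down-sampling stages by default) feeds two symmetric
decoder branches: a lesion branch ending in a 1-channel sigmoid head, and a
skeleton branch ending in a (C+1)-channel softmax head. The skeleton head is
refined by the parameter-free channel-spatial guidance module (CSGM)

    F' = F (x) G3x3(M) + F

where M is the Gaussian-smoothed one-hot encoding of the multi-atlas result
patch, G3x3 a normalized 3x3 Gaussian filter applied per channel, and (x)
element-wise multiplication. With ``share_encoder=False`` each branch gets an
independent encoder (the patch-Net ablation).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Tensor, concat
from .filters import smooth_3x3

__all__ = ["ModelConfig", "ForwardOutput", "MultiTaskUNet", "build_model", "csgm", "forward"]


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``depth`` is the number of down-sampling operations; input patches must be
    divisible by ``2**depth`` in both axes. ``n_skeleton_classes`` counts the
    background, i.e. it equals C+1 for C anatomical regions.
    """

    in_channels: int = 1
    base_width: int = 16
    depth: int = 4
    n_skeleton_classes: int = 21
    share_encoder: bool = True
    use_csgm: bool = True
    csgm_sigma: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.depth < 1:
            raise ValueError(f"depth must be >= 1, got {self.depth}")
        if self.n_skeleton_classes < 2:
            raise ValueError("need at least background + one skeleton class")


@dataclass
class ForwardOutput:
    """Per-patch network outputs (NCHW arrays unless squeezed)."""

    lesion_prob: np.ndarray
    skeleton_prob: np.ndarray
    lesion_prob_t: Tensor = field(repr=False, default=None)
    skeleton_prob_t: Tensor = field(repr=False, default=None)
    features_lesion: np.ndarray = field(repr=False, default=None)
    features_skeleton: np.ndarray = field(repr=False, default=None)


def csgm(features: Tensor | np.ndarray, guidance: np.ndarray, sigma: float = 1.0) -> Tensor:
    """Channel-spatial guidance: F' = F (x) G3x3(M) + F.

    ``features`` and ``guidance`` must agree in shape exactly; the guidance is
    treated as a constant (no gradient flows into M). Accepts (C,H,W) or
    (N,C,H,W).
    """
    f = features if isinstance(features, Tensor) else Tensor(np.asarray(features, dtype=np.float64))
    g = np.asarray(guidance)
    if f.shape != g.shape:
        raise ValueError(f"CSGM shape mismatch: features {f.shape} vs guidance {g.shape}")
    smoothed = smooth_3x3(g, sigma=sigma).astype(f.dtype)
    return f * Tensor(smoothed) + f


class MultiTaskUNet:
    """The multi-task network, parameters held as a flat name->Tensor map."""

    def __init__(self, config: ModelConfig):
        config.validate()
        self.config = config
        self.params: dict[str, Tensor] = {}
        self._rng = np.random.default_rng(config.seed)
        widths = [config.base_width * 2**i for i in range(config.depth + 1)]
        self.widths = widths
        encoders = ["enc"] if config.share_encoder else ["enc_lesion", "enc_skel"]
        self.encoder_names = encoders
        for enc in encoders:
            cin = config.in_channels
            for lvl, w in enumerate(widths):
                self._make_block(f"{enc}.{lvl}", cin, w)
                cin = w
        for branch in ("dec_lesion", "dec_skel"):
            for lvl in range(config.depth - 1, -1, -1):
                self._make_up(f"{branch}.up{lvl}", widths[lvl + 1], widths[lvl])
                self._make_block(f"{branch}.{lvl}", 2 * widths[lvl], widths[lvl])
        self._make_conv("head_lesion", widths[0], 1, k=1)
        # With CSGM on, a positive head bias makes the multiplicative guidance
        # active from the first step (at zero logits F (x) G(M) + F vanishes
        # and the guidance could not steer the softmax at all).
        self._make_conv(
            "head_skel", widths[0], config.n_skeleton_classes, k=1,
            bias_init=1.0 if config.use_csgm else 0.0,
        )

    # ------------------------------------------------------------ param setup
    def _new(self, name: str, arr: np.ndarray) -> None:
        self.params[name] = Tensor(arr.astype(np.float32), requires_grad=True, name=name)

    def _make_conv(self, name: str, cin: int, cout: int, k: int = 3, bias_init: float = 0.0) -> None:
        std = np.sqrt(2.0 / (cin * k * k))
        self._new(f"{name}.w", self._rng.normal(0.0, std, (cout, cin, k, k)))
        self._new(f"{name}.b", np.full(cout, bias_init))

    def _make_block(self, name: str, cin: int, cout: int) -> None:
        for i, ci in enumerate((cin, cout)):
            self._make_conv(f"{name}.conv{i}", ci, cout, k=3)
            self._new(f"{name}.norm{i}.g", np.ones(cout))
            self._new(f"{name}.norm{i}.b", np.zeros(cout))

    def _make_up(self, name: str, cin: int, cout: int) -> None:
        std = np.sqrt(2.0 / (cin * 4))
        self._new(f"{name}.w", self._rng.normal(0.0, std, (cin, cout, 2, 2)))
        self._new(f"{name}.b", np.zeros(cout))

    # ---------------------------------------------------------------- forward
    def _block(self, name: str, x: Tensor) -> Tensor:
        p = self.params
        for i in range(2):
            x = x.conv2d(p[f"{name}.conv{i}.w"], p[f"{name}.conv{i}.b"])
            x = x.instance_norm(p[f"{name}.norm{i}.g"], p[f"{name}.norm{i}.b"])
            x = x.relu()
        return x

    def _encode(self, enc: str, x: Tensor) -> list[Tensor]:
        feats = []
        for lvl in range(self.config.depth + 1):
            if lvl > 0:
                x = x.maxpool2()
            x = self._block(f"{enc}.{lvl}", x)
            feats.append(x)
        return feats

    def _decode(self, branch: str, feats: list[Tensor]) -> Tensor:
        p = self.params
        x = feats[-1]
        for lvl in range(self.config.depth - 1, -1, -1):
            x = x.conv_transpose2(p[f"{branch}.up{lvl}.w"], p[f"{branch}.up{lvl}.b"])
            x = concat([feats[lvl], x], axis=1)
            x = self._block(f"{branch}.{lvl}", x)
        return x

    def forward_batch(self, images: np.ndarray, guidance: np.ndarray | None = None) -> ForwardOutput:
        """Run the network on a batch.

        images: (N, 1, H, W) normalized to [0, 1].
        guidance: (N, C+1, H, W) Gaussian guidance maps, required when the
        CSGM is enabled (pass zeros to disable guidance for a batch).
        """
        cfg = self.config
        n, c, h, w = images.shape
        d = 2**cfg.depth
        if h % d or w % d:
            raise ValueError(f"patch {h}x{w} not divisible by 2^depth = {d}")
        x = Tensor(images.astype(np.float32))
        if cfg.share_encoder:
            feats = self._encode("enc", x)
            feats_l = feats_s = feats
        else:
            feats_l = self._encode("enc_lesion", x)
            feats_s = self._encode("enc_skel", x)
        f1 = self._decode("dec_lesion", feats_l)
        f2 = self._decode("dec_skel", feats_s)
        p = self.params
        lesion = f1.conv2d(p["head_lesion.w"], p["head_lesion.b"]).sigmoid()
        logits = f2.conv2d(p["head_skel.w"], p["head_skel.b"])
        if cfg.use_csgm:
            if guidance is None:
                raise ValueError("CSGM enabled but no guidance map supplied")
            logits = csgm(logits, guidance, sigma=cfg.csgm_sigma)
        skel = logits.softmax(axis=1)
        return ForwardOutput(
            lesion_prob=lesion.data,
            skeleton_prob=skel.data,
            lesion_prob_t=lesion,
            skeleton_prob_t=skel,
            features_lesion=f1.data,
            features_skeleton=f2.data,
        )

    # ------------------------------------------------------------ bookkeeping
    def parameters(self) -> list[Tensor]:
        return [self.params[k] for k in sorted(self.params)]

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.params.values()))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, p in self.params.items():
            p.data = np.asarray(state[k], dtype=np.float32).reshape(p.shape)

    def weights_checksum(self) -> str:
        h = hashlib.sha256()
        for k in sorted(self.params):
            h.update(k.encode())
            h.update(np.ascontiguousarray(self.params[k].data).tobytes())
        return h.hexdigest()

    # ------------------------------------------------------------ persistence
    def save(self, path, schema_hash: str = "") -> None:
        """Checkpoint: weights + full config + label-schema hash."""
        meta = json.dumps({"config": asdict(self.config), "schema_hash": schema_hash})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **{k: p.data for k, p in self.params.items()})

    @classmethod
    def load(cls, path, expect_schema_hash: str | None = None) -> "MultiTaskUNet":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            model = cls(ModelConfig(**meta["config"]))
            model.load_state_dict({k: z[k] for k in z.files if k != "__meta__"})
        if expect_schema_hash is not None and meta["schema_hash"] != expect_schema_hash:
            raise ValueError(
                f"label schema mismatch: checkpoint {meta['schema_hash']!r} "
                f"vs expected {expect_schema_hash!r}"
            )
        return model


def build_model(config: ModelConfig) -> MultiTaskUNet:
    """Construct the multi-task network from its configuration."""
    return MultiTaskUNet(config)


def forward(model: MultiTaskUNet, patch_pair) -> ForwardOutput:
    """Run one PatchPair through the model (deterministic; no dropout exists).

    The guidance map is derived from ``patch_pair.mas_patch`` via the
    Gaussian-smoothed one-hot encoding the CSGM expects.
    """
    from .mas import guidance_from_labels

    img = patch_pair.image_patch[None, None].astype(np.float32)
    guidance = None
    if model.config.use_csgm:
        guidance = guidance_from_labels(
            patch_pair.mas_patch, model.config.n_skeleton_classes, sigma=model.config.csgm_sigma
        )[None]
    out = model.forward_batch(img, guidance)
    return ForwardOutput(
        lesion_prob=out.lesion_prob[0, 0],
        skeleton_prob=out.skeleton_prob[0],
        lesion_prob_t=out.lesion_prob_t,
        skeleton_prob_t=out.skeleton_prob_t,
        features_lesion=out.features_lesion[0],
        features_skeleton=out.features_skeleton[0],
    )
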