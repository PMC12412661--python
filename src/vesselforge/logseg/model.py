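"""The segmentation network: LoG stream + encoder-decoder + ASPP fusion.

The LoG stream is a bank of single-channel convolutions whose weights are
variational Gaussians initialized at the precomputed LoG kernels — the
multiscale vessel detector the rest of the network leans on.  The regular
stream is a compact 3D U-Net (two 3x3x3 convolutions + ReLU per block,
2x2x2 max pooling, skip connections).  An atrous-spatial-pyramid-pooling
head fuses both feature sets through parallel dilated convolutions into
voxelwise lumen logits.

Architecture scale (levels, channels, depth, patch size) is configurable;
the defaults here are desk-scale, far smaller than a clinical training
setup, and the tests use smaller ones still.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .. import autodiff as ad
from .bayes import VariationalGaussian
from .kernels import DEFAULT_LEVELS, build_log_kernel

__all__ = ["SegModelConfig", "LoGBNet"]


@dataclass
class SegModelConfig:
    levels: tuple = DEFAULT_LEVELS
    prior_sds: tuple | None = None  # defaults to the per-level sigma ladder
    base_channels: int = 16
    depth: int = 3
    aspp_rates: tuple = (1, 2, 4)
    aspp_channels: int = 16
    patch_size: int = 64
    init_sd: float = 0.05
    # affine mapping of LoG responses before the sigmoid: weak (noise-level)
    # responses must land below 0.5 for the gate's voxel count to measure
    # vessel-edge extent rather than noise sign flips
    feature_gain: float = 250.0
    feature_bias: float = -5.5
    seed: int = 0

    def __post_init__(self):
        self.levels = tuple((int(s), float(g)) for s, g in self.levels)
        if self.prior_sds is None:
            self.prior_sds = tuple(g for _, g in self.levels)
        self.prior_sds = tuple(float(p) for p in self.prior_sds)
        self.aspp_rates = tuple(int(r) for r in self.aspp_rates)
        if self.patch_size % (2 ** self.depth):
            raise ValueError("patch size must be divisible by 2^depth")


class LoGBNet:
    def __init__(self, config: SegModelConfig | None = None):
        self.config = config or SegModelConfig()
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)

        # ---- LoG stream: variational kernels initialized at LoG filters
        self.log_layers = [
            VariationalGaussian(build_log_kernel(size, sigma), sd=cfg.init_sd,
                                prior_mean=0.0, prior_sd=prior)
            for (size, sigma), prior in zip(cfg.levels, cfg.prior_sds)]

        # ---- regular stream (U-Net)
        def conv_param(cin, cout, k=3):
            # float32 throughout: halves memory traffic in the GEMM-heavy convs
            std = np.sqrt(2.0 / (cin * k ** 3))
            w = ad.Tensor((rng.standard_normal((cout, cin, k, k, k)) * std
                           ).astype(np.float32), requires_grad=True)
            b = ad.Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)
            return w, b

        C = cfg.base_channels
        self.enc = []
        cin = 1
        for d in range(cfg.depth):
            cout = C * 2 ** d
            self.enc.append((conv_param(cin, cout), conv_param(cout, cout)))
            cin = cout
        cb = C * 2 ** cfg.depth
        self.bottleneck = (conv_param(cin, cb), conv_param(cb, cb))
        # decoder blocks use additive skips behind a 1x1 channel projection,
        # which keeps the wide full-resolution convolutions narrow
        self.dec = []
        for d in reversed(range(cfg.depth)):
            cskip = C * 2 ** d
            cup = C * 2 ** (d + 1)
            self.dec.append((conv_param(cup, cskip, k=1),
                             conv_param(cskip, cskip),
                             conv_param(cskip, cskip)))

        # ---- ASPP fusion head: 1x1 reduce, parallel dilated 3x3x3, 1x1 out
        nlev = len(cfg.levels)
        A = cfg.aspp_channels
        self.aspp_reduce = conv_param(C + nlev, A, k=1)
        self.aspp = [conv_param(A, A) for _ in cfg.aspp_rates]
        self.head = conv_param(A, 1, k=1)

    # ------------------------------------------------------------- params
    def parameters(self):
        ps = []
        for vg in self.log_layers:
            ps.extend(vg.parameters())
        for blocks in (*self.enc, self.bottleneck, *self.dec,
                       (self.aspp_reduce,), tuple(self.aspp), (self.head,)):
            for w, b in blocks:
                ps.extend([w, b])
        return ps

    def kl_total(self) -> ad.Tensor:
        total = self.log_layers[0].kl()
        for vg in self.log_layers[1:]:
            total = total + vg.kl()
        return total

    def sample_log_weights(self, rng) -> list:
        """One concrete weight draw per LoG layer (numpy arrays)."""
        rng = np.random.default_rng(rng) if not isinstance(
            rng, np.random.Generator) else rng
        return [vg.mean.data + np.exp(vg.log_sd.data)
                * rng.standard_normal(vg.shape).astype(vg.mean.dtype)
                for vg in self.log_layers]

    # ------------------------------------------------------------ streams
    def log_stream_forward(self, x, sample: bool = False, rng=None,
                           weight_set=None) -> ad.Tensor:
        """Per-level LoG responses mapped to [0,1] by a sigmoid.

        ``weight_set`` (list of arrays) pins one posterior draw, so a whole
        volume can be segmented under a single consistent weight sample.
        """
        x = x if isinstance(x, ad.Tensor) else ad.Tensor(
            np.asarray(x, dtype=np.float32))
        feats = []
        for li, vg in enumerate(self.log_layers):
            if weight_set is not None:
                w = ad.Tensor(weight_set[li])
            elif sample:
                w = vg.sample(np.random.default_rng(rng) if not isinstance(
                    rng, np.random.Generator) else rng)
            else:
                w = vg.mean
            resp = ad.corr3d_single(x, w)
            feats.append((resp * self.config.feature_gain
                          + self.config.feature_bias).sigmoid())
        return ad.concatenate(feats, axis=1)

    def regular_stream_forward(self, x) -> ad.Tensor:
        x = x if isinstance(x, ad.Tensor) else ad.Tensor(
            np.asarray(x, dtype=np.float32))
        if any(s % (2 ** self.config.depth) for s in x.shape[2:]):
            raise ValueError(
                f"spatial size {x.shape[2:]} not divisible by "
                f"2^{self.config.depth}")
        h, skips = x, []
        for (wa, ba), (wb, bb) in self.enc:
            h = ad.conv3d(h, wa, ba).relu()
            h = ad.conv3d(h, wb, bb).relu()
            skips.append(h)
            h = ad.maxpool3d(h)
        (wa, ba), (wb, bb) = self.bottleneck
        h = ad.conv3d(h, wa, ba).relu()
        h = ad.conv3d(h, wb, bb).relu()
        for ((wp, bp), (wa, ba), (wb, bb)), skip in zip(self.dec,
                                                        reversed(skips)):
            h = ad.conv3d(ad.upsample3d(h), wp, bp) + skip
            h = ad.conv3d(h, wa, ba).relu()
            h = ad.conv3d(h, wb, bb).relu()
        return h

    def aspp_fuse(self, log_feats: ad.Tensor, regular_feats: ad.Tensor
                  ) -> ad.Tensor:
        """Multi-dilation fusion of the two streams into voxelwise logits."""
        h = ad.concatenate([regular_feats, log_feats], axis=1)
        wr, br = self.aspp_reduce
        h = ad.conv3d(h, wr, br).relu()
        acc = None
        for rate, (w, b) in zip(self.config.aspp_rates, self.aspp):
            branch = ad.conv3d(h, w, b, dilation=rate)
            acc = branch if acc is None else acc + branch
        acc = acc.relu()
        w, b = self.head
        return ad.conv3d(acc, w, b)

    def forward(self, x, sample: bool = False, rng=None, weight_set=None):
        """Full forward pass -> (logits, LoG features), shapes (N,1|L,D,H,W)."""
        x = x if isinstance(x, ad.Tensor) else ad.Tensor(
            np.asarray(x, dtype=np.float32))
        log_feats = self.log_stream_forward(x, sample=sample, rng=rng,
                                            weight_set=weight_set)
        reg_feats = self.regular_stream_forward(x)
        return self.aspp_fuse(log_feats, reg_feats), log_feats

    def predict_proba(self, x, weight_set=None) -> np.ndarray:
        """Probabilities at the posterior mean (or a pinned weight draw)."""
        with ad.no_grad():
            logits, _ = self.forward(x, weight_set=weight_set)
        return 1.0 / (1.0 + np.exp(-np.clip(logits.data, -60, 60)))

    # -------------------------------------------------------- persistence
    def save(self, path):
        arrays = {f"p{i}": p.data for i, p in enumerate(self.parameters())}
        np.savez(path, _config=json.dumps(asdict(self.config)), **arrays)

    @classmethod
    def load(cls, path) -> "LoGBNet":
        with np.load(path, allow_pickle=False) as data:
            cfg = SegModelConfig(**json.loads(str(data["_config"])))
            model = cls(cfg)
            for i, p in enumerate(model.parameters()):
                p.data = data[f"p{i}"]
        return model
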