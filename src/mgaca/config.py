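"""Architecture configuration for the MGACA localization network."""
from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass


@dataclass
class ModelConfig:
    """All architecture hyperparameters of the MGACA network.

    The defaults describe the full published configuration: a VGG19-style
    encoder tapped at the third pooling stage, an attention-augmented atrous
    spatial pyramid pooling (ASPP) head with dilation rates 6 and 18 and
    filter widths 256/1024, squeeze-and-excite (SE) recalibration with
    reduction ratio 8, a decoder that fuses a 48-channel projection of the
    feature-map layer, two 3x3 decoder convolutions (512 then 256 filters),
    a single-channel spatial attention gate, and a sigmoid localization head.
    At ``width_multiplier=1`` this graph has exactly 22,877,922 trainable
    parameters.
    """

    input_shape: tuple = (128, 128, 3)
    feature_tap: str = "block3_pool"
    lowlevel_tap: str = "block3_pool"
    # ASPP
    aspp_filters_pool: int = 256
    aspp_filters_1x1: int = 256
    aspp_filters_d6: int = 256
    aspp_filters_d18: int = 1024
    dilation_rates: tuple = (6, 18)
    # whether the raw dilated tensor (in addition to its attended version)
    # enters the ASPP concatenation, one flag per dilation rate
    aspp_include_raw: tuple = (False, True)
    aspp_out_filters: int = 256
    se_ratio: int = 8
    # decoder
    lowlevel_filters: int = 48
    decoder_filters: tuple = (512, 256)
    output_activation: str = "sigmoid"  # or "softmax2"
    dropout_rate: float = 0.0
    # component switches (the ablation surface)
    use_aspp: bool = True
    use_dilated_attention: bool = True
    attention_scales: tuple | None = None  # None = attention at every rate
    attention_gating: bool = True
    use_se: bool = True
    use_spatial_gate: bool = True
    # misc
    pretrained_encoder: bool = False
    width_multiplier: float = 1.0
    seed: int = 0

    def __post_init__(self):
        rates = tuple(self.dilation_rates)
        if any(r < 1 for r in rates) or any(a >= b for a, b in zip(rates, rates[1:])):
            raise ValueError("dilation_rates must be strictly increasing and >= 1")
        if len(self.aspp_include_raw) != len(rates):
            raise ValueError("aspp_include_raw needs one flag per dilation rate")
        if self.width_multiplier <= 0:
            raise ValueError("width_multiplier must be positive")
        if self.se_ratio < 1:
            raise ValueError("se_ratio must be a positive integer")
        if self.output_activation not in ("sigmoid", "softmax2"):
            raise ValueError("output_activation must be 'sigmoid' or 'softmax2'")
        h, w, c = self.input_shape
        if c != 3:
            raise ValueError("input images must keep exactly 3 channels")

    def scaled(self, channels: int) -> int:
        """Apply the width multiplier, keeping SE-ratio divisibility.

        Channel counts are rounded up to the nearest multiple of ``se_ratio``
        so every SE bottleneck stays well-formed on the documented width grid
        (0.125, 0.25, 0.5, 1); at multiplier 1 all published widths are
        already multiples of the ratio and pass through unchanged.
        """
        r = self.se_ratio
        return max(r, int(math.ceil(channels * self.width_multiplier / r)) * r)

    @property
    def attended_rates(self) -> tuple:
        if not self.use_dilated_attention:
            return ()
        if self.attention_scales is None:
            return tuple(self.dilation_rates)
        return tuple(r for r in self.dilation_rates if r in self.attention_scales)

    def replace(self, **kwargs) -> "ModelConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for key in ("input_shape", "dilation_rates", "aspp_include_raw",
                    "decoder_filters", "attention_scales"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "ModelConfig":
        """Load from a YAML or JSON mapping of ModelConfig keys."""
        text = open(path).read()
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            import yaml
            data = yaml.safe_load(text)
        return cls.from_dict(data)
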