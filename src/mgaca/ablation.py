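"""Ablation variants of the MGACA network.

Each variant is a single documented structural edit of the full graph,
expressed through the component switches of :class:`~mgaca.config.ModelConfig`.
The three attention mechanisms of the full model are: the guided (mixed)
attention inside the dilated ASPP branches, the channel attention of the SE
blocks, and the spatial attention gate at the final stage.
"""
from __future__ import annotations

from dataclasses import dataclass

from .config import ModelConfig
from .model import MGACANet, build_mgaca


@dataclass(frozen=True)
class AblationSpec:
    name: str
    description: str
    overrides: tuple  # ((field, value), ...)


_SPECS = [
    AblationSpec(
        "no_attention",
        "Strip all three attention mechanisms: dilated-branch guided "
        "attention, SE channel recalibration, and the spatial gate.",
        (("use_dilated_attention", False), ("use_se", False),
         ("use_spatial_gate", False))),
    AblationSpec(
        "no_aspp",
        "Replace the ASPP block with a single 1x1 convolution.",
        (("use_aspp", False),)),
    AblationSpec(
        "spatial_only",
        "Keep only the spatial attention gate.",
        (("use_dilated_attention", False), ("use_se", False))),
    AblationSpec(
        "channel_only",
        "Keep only the SE channel attention.",
        (("use_dilated_attention", False), ("use_spatial_gate", False))),
    AblationSpec(
        "mixed_only",
        "Keep only the guided attention in the dilated ASPP branches.",
        (("use_se", False), ("use_spatial_gate", False))),
    AblationSpec(
        "single_scale",
        "Apply the dilated-branch attention at one scale (dilation 6) only; "
        "the second dilated branch contributes raw context.",
        (("attention_scales", (6,)),)),
    AblationSpec(
        "no_guidance",
        "Remove the sigmoid guidance gating: attention blocks keep their "
        "convolutions but no longer weight features, and the spatial gate "
        "is dropped.",
        (("attention_gating", False), ("use_spatial_gate", False))),
]

ABLATIONS = {spec.name: spec for spec in _SPECS}
ABLATION_NAMES = tuple(ABLATIONS)


def ablation_variant(spec: AblationSpec | str,
                     config: ModelConfig | None = None) -> MGACANet:
    """Build the network with one component removed or reduced."""
    if isinstance(spec, str):
        try:
            spec = ABLATIONS[spec]
        except KeyError:
            raise ValueError(
                f"unknown ablation {spec!r}; choose from {sorted(ABLATIONS)}"
            ) from None
    config = config or ModelConfig()
    return build_mgaca(config.replace(**dict(spec.overrides)))
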