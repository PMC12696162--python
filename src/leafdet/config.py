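"""YAML run configuration: model / train / prune / finetune / eval sections.

Defaults reproduce the reference training settings (SGD, lr0 0.01,
weight decay 0.0005, 300 epochs, 640 px input); the ``desk`` profile
shrinks the input to 160 px and the schedule to 30 epochs for CPU-scale
experiments.  Configs round-trip losslessly through YAML, and unknown
keys fail fast naming the offending path.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .head import DEFAULT_ANCHORS


@dataclass
class ModelSection:
    n_classes: int = 3
    attention: str = "eca"            # eca | se | cbam | none
    head_channels: int = 64
    dyhead_blocks: int = 2
    bot_heads: int = 4
    img_size: int = 640
    anchors: list = field(default_factory=lambda:
                          [[list(a) for a in lvl] for lvl in DEFAULT_ANCHORS])
    anchor_img_size: int = 640
    shape_iou_scale: float = 0.0
    shape_iou_swap_weights: bool = False
    sppcspc_pools: list = field(default_factory=lambda: [5, 9, 13])


@dataclass
class TrainSection:
    lr0: float = 0.01
    lrf: float = 0.01
    momentum: float = 0.937
    weight_decay: float = 0.0005
    warmup_epochs: float = 3.0
    epochs: int = 300
    batch_size: int = 16
    img_size: int = 640
    box_weight: float = 0.05
    obj_weight: float = 1.0
    cls_weight: float = 0.5


@dataclass
class PruneSection:
    speed_up: float = 2.2
    grid: list = None                 # e.g. [1.0, 1.2, ..., 2.4]
    min_channels: int = 2


@dataclass
class FinetuneSection:
    lr0: float = 0.001
    lrf: float = 0.01
    momentum: float = 0.937
    weight_decay: float = 0.0005
    warmup_epochs: float = 3.0
    warmup_momentum: float = 0.8
    warmup_bias_lr: float = 0.1
    epochs: int = 200


@dataclass
class EvalSection:
    conf_thr: float = 0.001           # decoding floor for mAP sweeps
    nms_iou: float = 0.45
    map_iou: float = 0.5
    report_conf: float = 0.25         # confusion-matrix operating point


@dataclass
class RunConfig:
    model: ModelSection = field(default_factory=ModelSection)
    train: TrainSection = field(default_factory=TrainSection)
    prune: PruneSection = field(default_factory=PruneSection)
    finetune: FinetuneSection = field(default_factory=FinetuneSection)
    eval: EvalSection = field(default_factory=EvalSection)
    seed: int = 0

    def to_dict(self):
        return asdict(self)

    @staticmethod
    def from_dict(d):
        d = dict(d or {})
        kwargs = {}
        sections = {"model": ModelSection, "train": TrainSection,
                    "prune": PruneSection, "finetune": FinetuneSection,
                    "eval": EvalSection}
        for key, cls in sections.items():
            sub = dict(d.pop(key, {}) or {})
            valid = {f.name for f in fields(cls)}
            unknown = set(sub) - valid
            if unknown:
                raise ValueError(f"unknown config key(s): "
                                 + ", ".join(f"{key}.{u}" for u in sorted(unknown)))
            kwargs[key] = cls(**sub)
        seed = d.pop("seed", 0)
        if d:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(d))}")
        return RunConfig(seed=seed, **kwargs)

    def dump(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @staticmethod
    def load(path):
        with open(path) as fh:
            return RunConfig.from_dict(yaml.safe_load(fh))

    def apply_profile(self, profile):
        """"desk" shrinks image size/epochs for single-CPU experiments."""
        if profile in (None, "full"):
            return self
        if profile == "desk":
            self.model.img_size = 160
            self.train.img_size = 160
            self.train.epochs = 30
            self.train.batch_size = 16
            self.finetune.epochs = 20
            return self
        raise ValueError(f"unknown profile: {profile!r}")
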