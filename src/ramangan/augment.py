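"""Augmentation strategy dispatch: none / balanced / stratified, GAN or SMOTE.

``balanced`` adds the same number n' of synthetic samples to every class;
``stratified`` adds m times each class's own size, preserving class priors.
Either counting scheme can be served by the per-class GANs (default) or by
SMOTE (the CNN_SMOTE-style baseline).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import SpectraDataset, class_counts
from .gan import GanConfig, SpectrumGAN, augment_balanced, augment_stratified, train_gan
from .smote import SmoteParams, smote_generate

__all__ = ["AugmentationSpec", "augmentation_counts", "train_class_gans", "augment_dataset"]

STRATEGIES = ("none", "balanced", "stratified")
GENERATORS = ("gan", "smote")


@dataclass
class AugmentationSpec:
    """What to add: counting strategy, synthetic-sample generator, and counts."""

    strategy: str = "none"
    generator: str = "gan"
    n_prime: int = 0  # balanced: samples added per class
    m: int = 0        # stratified: multiplier of each class size
    gan_config: GanConfig | None = None
    smote_params: SmoteParams | None = None

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}")
        if self.generator not in GENERATORS:
            raise ValueError(f"generator must be one of {GENERATORS}")
        if self.n_prime < 0 or self.m < 0:
            raise ValueError("counts must be >= 0")


def augmentation_counts(spec: AugmentationSpec, counts: dict[str, int]) -> dict[str, int]:
    """Synthetic samples to add per class under the spec's counting scheme."""
    if spec.strategy == "none":
        return {c: 0 for c in counts}
    if spec.strategy == "balanced":
        return {c: spec.n_prime for c in counts}
    return {c: spec.m * counts[c] for c in counts}


def train_class_gans(
    data: SpectraDataset,
    cfg: GanConfig | None = None,
    seed: int | None = None,
) -> dict[str, SpectrumGAN]:
    """Train one GAN per class present in ``data`` (derived per-class seeds)."""
    cfg = cfg if cfg is not None else GanConfig()
    models: dict[str, SpectrumGAN] = {}
    base_seed = cfg.seed if seed is None else seed
    for i, label in enumerate(data.class_set):
        from dataclasses import replace

        class_cfg = replace(cfg, seed=(base_seed + 1000003 * i) % (2**31))
        models[label] = train_gan(data.class_subset(label), class_cfg)
    return models


def augment_dataset(
    data: SpectraDataset,
    spec: AugmentationSpec,
    random_state=None,
    models: dict[str, SpectrumGAN] | None = None,
) -> SpectraDataset:
    """Apply the augmentation spec to a training dataset.

    With the GAN generator, per-class models are trained on ``data`` unless
    pre-trained ``models`` are supplied (the train-once, possibly leaky mode
    of the evaluation harness).
    """
    if spec.strategy == "none":
        return data
    seed = random_state if random_state is not None else 0
    if spec.generator == "gan":
        if models is None:
            models = train_class_gans(data, spec.gan_config, seed=seed)
        if spec.strategy == "balanced":
            return augment_balanced(data, models, spec.n_prime, random_state=seed)
        return augment_stratified(data, models, spec.m, random_state=seed)

    # SMOTE path: same counting schemes, interpolation-based generator
    per_class = augmentation_counts(spec, class_counts(data))
    out = data
    ss = np.random.SeedSequence(seed)
    for label, child in zip(data.class_set, ss.spawn(len(data.class_set))):
        n_new = per_class[label]
        if n_new:
            params = spec.smote_params or SmoteParams()
            k = min(params.k_neighbors, data.class_subset(label).n - 1)
            out = out.concat(
                smote_generate(
                    data.class_subset(label),
                    n_new,
                    SmoteParams(k_neighbors=k, seed=params.seed),
                    random_state=child,
                )
            )
    return out
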