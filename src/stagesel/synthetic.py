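"""Synthetic feature tables with the statistical structure the framework
assumes: class imbalance, informative class-conditional Gaussian features,
linearly redundant features and pure noise.

Defaults mirror the ultrasound study conditions: 347 samples split
286 benign / 61 malignant, a handful of informative dimensions, a
redundant block (random linear mixes of the informative ones) that makes
PCA concentrate the signal, and class-independent noise. ``patch_count``
> 1 emulates the histopathological patch fusion: per-patch blocks are
generated independently and concatenated in raster order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pipeline import FeatureTable, fuse_patch_features

__all__ = ["SynthSpec", "generate_table"]

#: relative noise added to redundant features; keeps |corr| with the
#: generating combination around 1/sqrt(1 + 0.01) ~ 0.995
REDUNDANT_NOISE_SD = 0.1


@dataclass(frozen=True)
class SynthSpec:
    """Generator parameters.

    effect_size is the class-mean separation of each informative feature
    in units of its (unit) noise standard deviation.
    """

    n_samples: int = 347
    class_counts: tuple[int, int] = (286, 61)  # (negatives, positives)
    n_informative: int = 5
    n_redundant: int = 5
    n_noise: int = 10
    effect_size: float = 3.0
    patch_count: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.class_counts) != self.n_samples:
            raise ValueError("class counts must sum to n_samples")
        if min(self.class_counts) <= 0 or self.n_samples <= 0:
            raise ValueError("counts must be positive")
        if self.n_informative <= 0 or self.n_redundant < 0 or self.n_noise < 0:
            raise ValueError("feature-block sizes must be nonnegative (informative > 0)")
        if self.patch_count < 1:
            raise ValueError("patch_count must be >= 1")
        if self.effect_size < 0:
            raise ValueError("effect_size must be nonnegative")


def _patch_block(
    spec: SynthSpec, y: np.ndarray, rng: np.random.Generator, prefix: str
) -> tuple[np.ndarray, list[str]]:
    n = y.size
    informative = rng.standard_normal((n, spec.n_informative))
    informative[y == 1] += spec.effect_size
    ids = [f"{prefix}inf{i}" for i in range(spec.n_informative)]

    blocks = [informative]
    if spec.n_redundant:
        mixing = rng.standard_normal((spec.n_informative, spec.n_redundant))
        combo = informative @ mixing
        redundant = combo + rng.standard_normal(combo.shape) * (
            REDUNDANT_NOISE_SD * combo.std(axis=0)
        )
        blocks.append(redundant)
        ids += [f"{prefix}red{i}" for i in range(spec.n_redundant)]
    if spec.n_noise:
        blocks.append(rng.standard_normal((n, spec.n_noise)))
        ids += [f"{prefix}noise{i}" for i in range(spec.n_noise)]
    return np.hstack(blocks), ids


def generate_table(spec: SynthSpec) -> FeatureTable:
    """Deterministic synthetic table per the spec's seed.

    Exact label marginals: ``class_counts[0]`` zeros and
    ``class_counts[1]`` ones, in shuffled order.
    """
    rng = np.random.default_rng(spec.seed)
    y = np.concatenate(
        [np.zeros(spec.class_counts[0], dtype=int), np.ones(spec.class_counts[1], dtype=int)]
    )
    y = y[rng.permutation(spec.n_samples)]

    if spec.patch_count == 1:
        X, ids = _patch_block(spec, y, rng, prefix="")
        return FeatureTable(X, y, tuple(ids))

    patches = []
    ids: list[str] = []
    for p in range(spec.patch_count):
        block, block_ids = _patch_block(spec, y, rng, prefix=f"p{p}_")
        patches.append(block)
        ids += block_ids
    X = np.vstack(
        [fuse_patch_features([patch[i] for patch in patches]) for i in range(spec.n_samples)]
    )
    return FeatureTable(X, y, tuple(ids))
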