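"""Synthetic paired platform tables and repeated-segmentation stacks.

The generator emulates the statistical structure the analysis assumes:
blocks of redundant features driven by shared latent factors, a second
platform that reproduces robust features nearly exactly while corrupting the
rest (scale bias, monotone distortion, heavy noise), and repeated
measurements with a controlled population reliability.
Everything is a pure function of (config, seed): regeneration is
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from radrobust.io import FeatureTable

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "RepeatedMeasures",
    "CORRUPTION_MENU",
    "generate_platform_pair",
    "generate_repeated_measures",
]

#: each corruption degrades mainly one robustness component:
#: scale -> MFR, cube -> correlation + KS (rank-preserving), squash -> KS,
#: noise -> correlation
CORRUPTION_MENU = ("scale", "cube", "squash", "noise")

_FILTERS = ("original", "wavelet_lll", "wavelet_lhl", "wavelet_hlh",
            "wavelet_hhl", "wavelet_lhh", "wavelet_hll", "wavelet_hhh")
_FAMILIES = ("firstorder", "glcm", "glrlm", "glszm", "gldm", "ngtdm")


@dataclass
class SimulationConfig:
    n_lesions: int = 100
    n_features: int = 60
    n_blocks: int = 6
    within_block_corr: float = 0.9
    robust_per_block: int = 1
    scale_bias_range: tuple[float, float] = (2.0, 8.0)
    corruption_fraction: float = 1.0
    noise_sd: float = 0.05
    icc_true: float | np.ndarray = 0.95
    n_repetitions: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.n_lesions < 3 or self.n_features < 1 or self.n_blocks < 1:
            raise ValueError("degenerate simulation size")
        if not 0 < self.within_block_corr < 1:
            raise ValueError("within_block_corr must be in (0, 1)")
        if self.robust_per_block * self.n_blocks > self.n_features:
            raise ValueError("more planted robust features than features")
        if not 0 <= self.corruption_fraction <= 1:
            raise ValueError("corruption_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        icc = np.atleast_1d(np.asarray(self.icc_true, dtype=float))
        if np.any(icc <= 0) or np.any(icc >= 1):
            raise ValueError("icc_true must lie in (0, 1)")
        if self.n_repetitions < 2:
            raise ValueError("need >=2 repetitions")


@dataclass
class GroundTruth:
    block_of: dict[str, int]
    robust_flags: dict[str, bool]
    applied_bias: dict[str, float]
    applied_corruption: dict[str, str]  # "" for uncorrupted features
    feature_names: list[str] = field(default_factory=list)


@dataclass
class RepeatedMeasures:
    """subjects x repetitions x features stack for reliability analysis."""

    subject_ids: list[str]
    feature_names: list[str]
    data: np.ndarray  # (n_subjects, n_repetitions, n_features)
    icc_true: np.ndarray

    def per_feature(self) -> dict[str, np.ndarray]:
        return {
            f: self.data[:, :, j] for j, f in enumerate(self.feature_names)
        }


def _feature_names(n: int, block_of: np.ndarray) -> list[str]:
    names = []
    for i in range(n):
        filt = _FILTERS[i % len(_FILTERS)]
        fam = _FAMILIES[(i // len(_FILTERS)) % len(_FAMILIES)]
        names.append(f"{filt}_{fam}_sim{i:03d}")
    return names


def generate_platform_pair(
    cfg: SimulationConfig,
) -> tuple[FeatureTable, FeatureTable, GroundTruth]:
    """Simulate two platforms' feature tables with known ground truth.

    Platform A follows a latent-factor block model: features in block b are
    ``sqrt(w) * z_b + sqrt(1 - w) * noise`` (pairwise correlation w inside a
    block, ~0 across blocks), then given per-feature scale/offset to emulate
    the magnitude spread of real features.  Platform B copies robust features
    up to ``noise_sd``-level noise and corrupts a fraction of the remainder
    with one entry of :data:`CORRUPTION_MENU`; uncorrupted non-robust
    features get moderately heavier noise than robust ones.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n, p, B = cfg.n_lesions, cfg.n_features, cfg.n_blocks
    w = cfg.within_block_corr

    block_of = np.arange(p) % B  # round-robin keeps block sizes balanced
    names = _feature_names(p, block_of)
    latent = rng.standard_normal((n, B))
    eps = rng.standard_normal((n, p))
    base = np.sqrt(w) * latent[:, block_of] + np.sqrt(1 - w) * eps

    scale = 10.0 ** rng.uniform(-1.0, 2.0, size=p)
    offset = rng.uniform(-1.0, 1.0, size=p) * scale
    A = base * scale + offset

    robust = np.zeros(p, dtype=bool)
    for b in range(B):
        members = np.flatnonzero(block_of == b)
        robust[members[: cfg.robust_per_block]] = True
    non_robust = np.flatnonzero(~robust)
    n_corrupt = int(round(cfg.corruption_fraction * len(non_robust)))
    corrupt_idx = rng.choice(non_robust, size=n_corrupt, replace=False)
    corruption = {int(j): CORRUPTION_MENU[i % len(CORRUPTION_MENU)]
                  for i, j in enumerate(sorted(corrupt_idx))}

    col_sd = A.std(axis=0)
    Bv = np.empty_like(A)
    bias = np.ones(p)
    for j in range(p):
        a = A[:, j]
        noise = rng.standard_normal(n)
        kind = corruption.get(j, "")
        if robust[j]:
            Bv[:, j] = a + cfg.noise_sd * col_sd[j] * noise
        elif kind == "scale":
            s = rng.uniform(*cfg.scale_bias_range)
            bias[j] = s
            Bv[:, j] = s * a + cfg.noise_sd * s * col_sd[j] * noise
        elif kind == "cube":
            z = (a - a.mean()) / col_sd[j]
            Bv[:, j] = z**3 + cfg.noise_sd * noise
        elif kind == "squash":
            z = (a - a.mean()) / col_sd[j]
            Bv[:, j] = np.tanh(1.5 * z) + cfg.noise_sd * noise
        elif kind == "noise":
            Bv[:, j] = a + 2.0 * col_sd[j] * noise
        else:  # uncorrupted non-robust: noisier than robust, still aligned
            Bv[:, j] = a + 6.0 * cfg.noise_sd * col_sd[j] * noise

    lesions = [f"L{i:04d}" for i in range(n)]
    truth = GroundTruth(
        block_of={names[j]: int(block_of[j]) for j in range(p)},
        robust_flags={names[j]: bool(robust[j]) for j in range(p)},
        applied_bias={names[j]: float(bias[j]) for j in range(p)},
        applied_corruption={names[j]: corruption.get(j, "") for j in range(p)},
        feature_names=list(names),
    )
    table_a = FeatureTable("A", lesions, list(names), A)
    table_b = FeatureTable("B", lesions, list(names), Bv)
    return table_a, table_b, truth


def generate_repeated_measures(cfg: SimulationConfig) -> RepeatedMeasures:
    """Repeated segmentations with per-feature population reliability.

    Each feature follows ``y_ij = s_i + e_ij`` with subject variance
    ``icc_true`` and noise variance ``1 - icc_true``, so the two-way-model
    population ICC equals ``icc_true`` exactly.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 1)  # decoupled from the pair stream
    n, k, p = cfg.n_lesions, cfg.n_repetitions, cfg.n_features
    icc = np.broadcast_to(
        np.atleast_1d(np.asarray(cfg.icc_true, dtype=float)), (p,)
    ).copy()
    subj = rng.standard_normal((n, 1, p)) * np.sqrt(icc)
    noise = rng.standard_normal((n, k, p)) * np.sqrt(1.0 - icc)
    data = subj + noise
    block_of = np.arange(p) % cfg.n_blocks
    return RepeatedMeasures(
        subject_ids=[f"L{i:04d}" for i in range(n)],
        feature_names=_feature_names(p, block_of),
        data=data,
        icc_true=icc,
    )
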