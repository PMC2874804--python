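"""Synthetic tryptic-peptide datasets with a known drift-time mechanism.

The experimental data behind the drift-time predictor — tryptic digests of
20 proteins measured on a travelling-wave ion-mobility instrument — are not
publicly deposited.  This module emulates their essential statistics so the
whole pipeline (featurization, training, cross-validation, model selection)
can be exercised end-to-end against a known ground truth:

* sequences are tryptic-like — random residues ending in K or R, with no
  internal K/R — and lengths follow the per-charge means of the emulated
  datasets (7.9 / 13.2 / 18.3 residues for charges 1+ / 2+ / 3+, clipped
  to the observed range 3..34);
* drift times come from a *teacher*: either a random 4-3-1 network drawn
  from the same model class as the student regressor (the default, making
  recovery well-posed), or an affine map of the normalized features; the
  teacher output is rescaled so each charge state hits its configured mean
  drift time (7.48 / 3.07 / 2.28 ms) and multiplied by 1 + eps with
  eps ~ N(0, noise_sd), emulating run-to-run mobility variability.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, ValidationError
from .features import (
    AMINO_ACIDS,
    ModificationPolicy,
    Peptide,
    PKaTable,
    apply_normalization,
    featurize_dataset,
    fit_normalization,
)
from .ann import TrainingConfig, _forward_batch, init_network

MIN_LENGTH = 3
MAX_LENGTH = 34

#: residues eligible for non-terminal positions (trypsin cuts after K/R)
_INTERNAL_RESIDUES = [aa for aa in AMINO_ACIDS if aa not in "KR"]

#: weight scale of the random teacher network.  Real drift times span
#: several-fold within a charge state (e.g. ~3-14 ms for 1+); a teacher with
#: unit-scale weights would respond almost flatly, making mean prediction
#: trivially "accurate" under a relative threshold.  This scale spreads the
#: teacher's logistic output over most of (0, 1).
TEACHER_INIT_RANGE = 3.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the generated datasets.

    Defaults mirror the emulated experiment: per-charge mean peptide
    lengths of 7.9, 13.2 and 18.3 residues, mean drift times of 7.48, 3.07
    and 2.28 ms, and 5% relative Gaussian noise on the drift time.
    """

    n_per_charge: Mapping[int, int] = field(
        default_factory=lambda: {1: 200, 2: 200, 3: 200}
    )
    length_means: Mapping[int, float] = field(
        default_factory=lambda: {1: 7.9, 2: 13.2, 3: 18.3}
    )
    drift_time_means: Mapping[int, float] = field(
        default_factory=lambda: {1: 7.48, 2: 3.07, 3: 2.28}
    )
    noise_sd: float = 0.05
    teacher: Literal["network", "affine"] = "network"
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_per_charge.values()):
            raise ValidationError("peptide counts must be non-negative")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        if any(m < MIN_LENGTH for m in self.length_means.values()):
            raise ValidationError(f"length means must be >= {MIN_LENGTH}")
        if self.teacher not in ("network", "affine"):
            raise ConfigurationError(f"unknown teacher {self.teacher!r}")


def _sample_length(rng: np.random.Generator, mean: float) -> int:
    # right-skewed like real tryptic length distributions; clipped to the
    # emulated range so extreme draws stay physical
    sd = max(1.5, 0.35 * mean)
    n = int(round(rng.normal(mean, sd)))
    return int(np.clip(n, MIN_LENGTH, MAX_LENGTH))


def generate_peptides(config: SyntheticConfig) -> list[Peptide]:
    """Random tryptic-like peptides, charge-stratified, deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    peptides: list[Peptide] = []
    for charge in sorted(config.n_per_charge):
        n = config.n_per_charge[charge]
        mean_len = config.length_means[charge]
        for _ in range(n):
            length = _sample_length(rng, mean_len)
            body = rng.choice(list(_INTERNAL_RESIDUES), size=length - 1)
            terminus = rng.choice(["K", "R"])
            peptides.append(Peptide(sequence="".join(body) + terminus, charge=charge))
    return peptides


def _teacher_outputs(
    Xn: np.ndarray, teacher: str, rng: np.random.Generator
) -> np.ndarray:
    """Raw (unscaled) teacher response to normalized features, in (0, 1) or R."""
    if teacher == "network":
        cfg = TrainingConfig(seed=int(rng.integers(2**31)), init_range=TEACHER_INIT_RANGE)
        net = init_network(hidden_nodes=3, config=cfg)
        A2, _ = _forward_batch(net, Xn)
        return A2[0]
    # affine: a fixed positive-leaning linear blend of the four features
    coef = np.array([0.5, 0.3, 0.1, 0.1])
    return coef @ Xn + 2.0  # offset keeps the response positive on [-1,1]^4


def generate_drift_times(
    peptides: Sequence[Peptide],
    config: SyntheticConfig,
    pka: PKaTable | None = None,
    mods: ModificationPolicy = ModificationPolicy(),
) -> list[Peptide]:
    """Attach ground-truth drift times: teacher response, rescaled per charge
    to the configured mean, with multiplicative Gaussian noise.

    Non-positive draws (possible only under extreme noise) are resampled.
    Returns new Peptide objects in input order.
    """
    if len(peptides) == 0:
        return []
    pka = pka or PKaTable.default()
    rng = np.random.default_rng(config.seed + 1)
    out: list[Peptide | None] = [None] * len(peptides)
    for charge in sorted({p.charge for p in peptides}):
        idx = [i for i, p in enumerate(peptides) if p.charge == charge]
        subset = [peptides[i] for i in idx]
        M = featurize_dataset(subset, pka=pka, mods=mods)
        Xn = apply_normalization(M, fit_normalization(M)).values
        raw = _teacher_outputs(Xn, config.teacher, rng)
        mean_raw = float(np.mean(raw))
        if mean_raw <= 0:
            raise ConfigurationError("teacher produced a non-positive mean response")
        target_mean = config.drift_time_means[charge]
        clean = raw * (target_mean / mean_raw)
        noisy = np.empty_like(clean)
        for j, t in enumerate(clean):
            val = t * (1.0 + rng.normal(0.0, config.noise_sd))
            while val <= 0:
                val = t * (1.0 + rng.normal(0.0, config.noise_sd))
            noisy[j] = val
        for j, i in enumerate(idx):
            out[i] = peptides[i].with_drift_time(float(noisy[j]))
    return out  # type: ignore[return-value]


def generate_dataset(
    config: SyntheticConfig,
    pka: PKaTable | None = None,
    mods: ModificationPolicy = ModificationPolicy(),
) -> list[Peptide]:
    """Peptides with drift times in one call: generate, then measure."""
    return generate_drift_times(generate_peptides(config), config, pka=pka, mods=mods)
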