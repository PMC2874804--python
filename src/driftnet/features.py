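"""Sequence-derived peptide descriptors for drift-time prediction.

A peptide ion's drift time in an ion-mobility separation is set by its
collision cross-section and charge, both of which trace back to the amino
acid sequence.  Each peptide is therefore summarised by a four-dimensional
descriptor vector

    (mw, sl, si1, si2)

where ``mw`` is the peptide molecular weight in Daltons, ``sl`` the number
of residues, and ``(si1, si2)`` a two-component, order-sensitive *sequence
index* built from per-residue ionization constants (pKa).  A dataset of N
peptides is the 4 x N matrix whose columns are these vectors; each feature
row is min-max normalized onto [-1, 1] before entering the regressor.

The default sequence index weights each residue's pKa by its position from
the N-terminus (si1) and from the C-terminus (si2):

    si1 = (1/N) * sum_i  i         * m_i
    si2 = (1/N) * sum_i (N - i + 1) * m_i

with ``m_i`` the pKa of residue i.  This is a reconstruction of an
order-sensitive pKa index described only by reference in the source
literature; the strategy is pluggable (see ``SEQUENCE_INDEX_STRATEGIES``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from pyteomics import mass as _ptmass

from .errors import ConfigurationError, ValidationError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: monoisotopic mass of one water molecule (Da), added once per peptide
WATER_MONO = 18.01056
WATER_AVG = 18.01528

#: fixed carbamidomethyl modification of cysteine (iodoacetamide alkylation)
CARBAMIDOMETHYL_MONO = 57.02146
CARBAMIDOMETHYL_AVG = 57.0513

#: monoisotopic residue masses (Da), from the standard pyteomics table
RESIDUE_MASS_MONO: Mapping[str, float] = {aa: _ptmass.std_aa_mass[aa] for aa in AMINO_ACIDS}

#: average residue masses (Da), computed from the standard atomic compositions
RESIDUE_MASS_AVG: Mapping[str, float] = {
    aa: _ptmass.calculate_mass(composition=_ptmass.std_aa_comp[aa], average=True)
    for aa in AMINO_ACIDS
}

FEATURE_NAMES = ("mw", "sl", "si1", "si2")


def validate_sequence(sequence: str) -> str:
    """Check that *sequence* is a non-empty string of canonical residues.

    Returns the sequence unchanged; raises :class:`ValidationError` naming
    the first offending character and its 1-based position otherwise.
    """
    if not isinstance(sequence, str) or len(sequence) == 0:
        raise ValidationError("peptide sequence must be a non-empty string")
    for pos, ch in enumerate(sequence, start=1):
        if ch not in AMINO_ACIDS:
            raise ValidationError(
                f"invalid residue {ch!r} at position {pos} in sequence {sequence!r}"
            )
    return sequence


@dataclass(frozen=True)
class Peptide:
    """A peptide ion: sequence, charge state, and optional observed drift time.

    Parameters
    ----------
    sequence:
        One-letter amino acid codes (the 20 canonical residues).
    charge:
        Number of protons on the ion; 1, 2 or 3.
    drift_time_ms:
        Experimentally observed drift time in milliseconds, if available.
    """

    sequence: str
    charge: int
    drift_time_ms: float | None = None

    def __post_init__(self) -> None:
        validate_sequence(self.sequence)
        if self.charge not in (1, 2, 3):
            raise ValidationError(f"charge must be 1, 2 or 3, got {self.charge!r}")
        if self.drift_time_ms is not None:
            t = float(self.drift_time_ms)
            if not math.isfinite(t) or t <= 0:
                raise ValidationError(
                    f"drift_time_ms must be a positive finite number, got {self.drift_time_ms!r}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def with_drift_time(self, t_ms: float) -> "Peptide":
        return replace(self, drift_time_ms=t_ms)


@dataclass(frozen=True)
class PKaTable:
    """Per-residue ionization constants used by the sequence index.

    The shipped default assigns each residue the isoelectric point of the
    free amino acid (the mean of its two dominant pKa values), so that every
    residue — not only those with ionizable side chains — carries a finite,
    chemically meaningful value.
    """

    values: Mapping[str, float]
    source_label: str

    def __post_init__(self) -> None:
        missing = sorted(set(AMINO_ACIDS) - set(self.values))
        if missing:
            raise ConfigurationError(f"pKa table missing residues: {''.join(missing)}")
        extra = sorted(set(self.values) - set(AMINO_ACIDS))
        if extra:
            raise ConfigurationError(f"pKa table has unknown residues: {''.join(extra)}")
        for aa, v in self.values.items():
            if not math.isfinite(float(v)):
                raise ConfigurationError(f"non-finite pKa value for residue {aa!r}")

    def __getitem__(self, residue: str) -> float:
        try:
            return float(self.values[residue])
        except KeyError:
            raise ConfigurationError(f"no pKa entry for residue {residue!r}") from None

    @classmethod
    def default(cls) -> "PKaTable":
        """The packaged free-amino-acid isoelectric-point table."""
        text = resources.files("driftnet.data").joinpath("pka_default.tsv").read_text()
        return cls.from_text(text, source_label="free-aa-isoelectric-point")

    @classmethod
    def from_text(cls, text: str, source_label: str) -> "PKaTable":
        values: dict[str, float] = {}
        for line in text.strip().splitlines():
            parts = line.split()
            if parts[0].lower() == "residue":
                continue
            if len(parts) != 2:
                raise ConfigurationError(f"malformed pKa table line: {line!r}")
            values[parts[0]] = float(parts[1])
        return cls(values=values, source_label=source_label)

    @classmethod
    def from_file(cls, path, source_label: str | None = None) -> "PKaTable":
        with open(path) as fh:
            return cls.from_text(fh.read(), source_label=source_label or str(path))


@dataclass(frozen=True)
class ModificationPolicy:
    """Fixed-modification and mass-flavor choices for molecular weight.

    Cysteines in the emulated sample preparation are carbamidomethylated
    (iodoacetamide alkylation, +57.02146 Da monoisotopic per C), so the
    modification defaults to on.  Monoisotopic residue masses are the
    default flavor; average masses are available.
    """

    carbamidomethyl_cys: bool = True
    average_mass: bool = False


def compute_molecular_weight(sequence: str, mods: ModificationPolicy = ModificationPolicy()) -> float:
    """Peptide molecular weight: sum of residue masses plus one water.

    Monoisotopic by default; with ``mods.carbamidomethyl_cys`` every C adds
    the fixed carbamidomethyl mass.
    """
    validate_sequence(sequence)
    if mods.average_mass:
        masses, water, cam = RESIDUE_MASS_AVG, WATER_AVG, CARBAMIDOMETHYL_AVG
    else:
        masses, water, cam = RESIDUE_MASS_MONO, WATER_MONO, CARBAMIDOMETHYL_MONO
    mw = sum(masses[aa] for aa in sequence) + water
    if mods.carbamidomethyl_cys:
        mw += cam * sequence.count("C")
    return mw


def _position_weighted_index(sequence: str, pka: PKaTable) -> tuple[float, float]:
    n = len(sequence)
    m = np.array([pka[aa] for aa in sequence])
    idx = np.arange(1, n + 1)
    si1 = float(np.dot(idx, m) / n)
    si2 = float(np.dot(idx[::-1], m) / n)
    return si1, si2


#: pluggable definitions of the two-component sequence index
SEQUENCE_INDEX_STRATEGIES: dict[str, Callable[[str, PKaTable], tuple[float, float]]] = {
    "position-weighted": _position_weighted_index,
}


def compute_sequence_index(
    sequence: str, pka: PKaTable, strategy: str = "position-weighted"
) -> tuple[float, float]:
    """Two-component, order-sensitive pKa aggregate of a sequence.

    The default strategy weights residue pKa values by position counted
    from the N-terminus (si1) and from the C-terminus (si2), normalized by
    length, so reversing a sequence swaps the two components.
    """
    validate_sequence(sequence)
    try:
        fn = SEQUENCE_INDEX_STRATEGIES[strategy]
    except KeyError:
        raise ConfigurationError(
            f"unknown sequence-index strategy {strategy!r}; "
            f"available: {sorted(SEQUENCE_INDEX_STRATEGIES)}"
        ) from None
    return fn(sequence, pka)


@dataclass(frozen=True)
class FeatureVector:
    mw: float
    sl: int
    si1: float
    si2: float

    def as_array(self) -> np.ndarray:
        return np.array([self.mw, float(self.sl), self.si1, self.si2])


@dataclass(frozen=True)
class FeatureMatrix:
    """A 4 x N matrix of descriptor vectors; column i is peptide i."""

    values: np.ndarray  # shape (4, N)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != 4 or v.shape[1] < 1:
            raise ValidationError(f"feature matrix must be 4 x N with N >= 1, got shape {v.shape}")
        object.__setattr__(self, "values", v)

    @property
    def n_peptides(self) -> int:
        return self.values.shape[1]


def featurize(
    peptide: Peptide,
    pka: PKaTable | None = None,
    mods: ModificationPolicy = ModificationPolicy(),
    strategy: str = "position-weighted",
) -> FeatureVector:
    """Descriptor vector (mw, sl, si1, si2) of a single peptide."""
    pka = pka or PKaTable.default()
    si1, si2 = compute_sequence_index(peptide.sequence, pka, strategy)
    return FeatureVector(
        mw=compute_molecular_weight(peptide.sequence, mods),
        sl=len(peptide.sequence),
        si1=si1,
        si2=si2,
    )


def featurize_dataset(
    peptides: Sequence[Peptide],
    pka: PKaTable | None = None,
    mods: ModificationPolicy = ModificationPolicy(),
    strategy: str = "position-weighted",
) -> FeatureMatrix:
    """Column-wise featurization of a dataset, preserving input order."""
    if len(peptides) == 0:
        raise ValidationError("cannot featurize an empty peptide dataset")
    pka = pka or PKaTable.default()
    cols = [featurize(p, pka, mods, strategy).as_array() for p in peptides]
    return FeatureMatrix(values=np.stack(cols, axis=1))


@dataclass(frozen=True)
class NormalizationParams:
    """Per-row min/max of a training feature matrix.

    Rows whose min equals max carry no information on the training data;
    they are flagged degenerate and map to 0 under normalization.
    """

    f_min: np.ndarray
    f_max: np.ndarray

    def __post_init__(self) -> None:
        lo = np.asarray(self.f_min, dtype=float)
        hi = np.asarray(self.f_max, dtype=float)
        if lo.shape != hi.shape or lo.ndim != 1:
            raise ValidationError("f_min and f_max must be 1-D arrays of equal length")
        if np.any(lo > hi):
            raise ValidationError("f_min must not exceed f_max")
        object.__setattr__(self, "f_min", lo)
        object.__setattr__(self, "f_max", hi)

    @property
    def degenerate(self) -> np.ndarray:
        return self.f_min == self.f_max


def fit_normalization(matrix: FeatureMatrix) -> NormalizationParams:
    """Record per-feature-row minimum and maximum of a training matrix."""
    v = matrix.values
    return NormalizationParams(f_min=v.min(axis=1), f_max=v.max(axis=1))


def apply_normalization(matrix: FeatureMatrix, params: NormalizationParams) -> FeatureMatrix:
    """Affinely map each feature row onto [-1, 1] by its training min/max.

    f_normalized = 2 (f - f_min) / (f_max - f_min) - 1.  Degenerate rows map
    to 0.  Values outside the training range (unseen data) follow the same
    affine map and may fall outside [-1, 1]; they are deliberately not
    clipped, so extrapolation is visible rather than silently distorted.
    """
    v = matrix.values
    if params.f_min.shape[0] != v.shape[0]:
        raise ValidationError(
            f"normalization params have {params.f_min.shape[0]} rows, matrix has {v.shape[0]}"
        )
    span = params.f_max - params.f_min
    safe = np.where(span == 0, 1.0, span)
    out = 2.0 * (v - params.f_min[:, None]) / safe[:, None] - 1.0
    out[params.degenerate, :] = 0.0
    return FeatureMatrix(values=out)
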