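"""Prediction-variation metrics, cross-validation and model selection.

A prediction for a peptide ion counts as correct when its *prediction
variation*

    eta = |t_pred - t_exp| / t_exp

does not exceed a chosen threshold (15% is the headline operating point).
Accuracy-versus-threshold curves, the mean signed difference
(predicted - observed, in ms) and the Pearson correlation summarise a set
of predictions; a 10-fold cross-validation harness and a hidden-node
selection sweep evaluate the regressor itself.

Cross-validation discipline: feature min/max normalization and the target
scaler are fitted on the nine training folds only, never on the fold being
validated, so no information leaks from validation records into the
scaling that preprocesses them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .features import (
    FeatureMatrix,
    ModificationPolicy,
    Peptide,
    PKaTable,
    apply_normalization,
    featurize_dataset,
    fit_normalization,
)
from .ann import ANNModel, TargetScaler, TrainingConfig, init_network, predict_drift_time, train_backprop

DEFAULT_THRESHOLD = 0.15
DEFAULT_THRESHOLD_GRID = tuple(np.round(np.arange(0.0, 0.51, 0.01), 2))


def prediction_variation(t_pred: float, t_exp: float) -> float:
    """Relative deviation of a predicted drift time from the observed one."""
    if not (t_exp > 0):
        raise ValidationError(f"observed drift time must be positive, got {t_exp!r}")
    return abs(t_pred - t_exp) / t_exp


@dataclass(frozen=True)
class PredictionRecord:
    """One peptide ion's observed and predicted drift time (ms)."""

    peptide: Peptide
    t_exp: float
    t_pred: float

    def __post_init__(self) -> None:
        if not (self.t_exp > 0):
            raise ValidationError("t_exp must be positive")

    @property
    def eta(self) -> float:
        return prediction_variation(self.t_pred, self.t_exp)


def _require_records(records: Sequence[PredictionRecord]) -> None:
    if len(records) == 0:
        raise ValidationError("at least one prediction record is required")


def accuracy_at_threshold(records: Sequence[PredictionRecord], threshold: float = DEFAULT_THRESHOLD) -> float:
    """Fraction of records with eta <= threshold (boundary counts correct)."""
    _require_records(records)
    return sum(r.eta <= threshold for r in records) / len(records)


def accuracy_curve(
    records: Sequence[PredictionRecord],
    thresholds: Sequence[float] = DEFAULT_THRESHOLD_GRID,
) -> dict[float, float]:
    """Accuracy at each threshold of an ascending grid (monotone by construction)."""
    _require_records(records)
    th = list(thresholds)
    if any(b < a for a, b in zip(th, th[1:])):
        raise ValidationError("threshold grid must be sorted ascending")
    etas = np.array([r.eta for r in records])
    return {float(t): float(np.mean(etas <= t)) for t in th}


def mean_signed_difference(records: Sequence[PredictionRecord]) -> float:
    """Mean of (predicted - observed) drift time, in ms."""
    _require_records(records)
    return float(np.mean([r.t_pred - r.t_exp for r in records]))


def pearson_correlation(records: Sequence[PredictionRecord]) -> float:
    """Product-moment correlation between predicted and observed drift times."""
    _require_records(records)
    if len(records) < 2:
        raise ValidationError("correlation requires at least two records")
    t_exp = np.array([r.t_exp for r in records])
    t_pred = np.array([r.t_pred for r in records])
    if np.ptp(t_exp) == 0 or np.ptp(t_pred) == 0:
        raise ValidationError("correlation is undefined for a constant series")
    return float(np.corrcoef(t_exp, t_pred)[0, 1])


@dataclass(frozen=True)
class EvaluationReport:
    """Aggregate metrics over a set of prediction records."""

    n: int
    accuracy_at: Mapping[float, float]
    mean_signed_diff: float
    pearson_r: float | None
    records: tuple[PredictionRecord, ...] = ()
    per_charge: Mapping[int, "EvaluationReport"] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "accuracy_at": {str(k): v for k, v in self.accuracy_at.items()},
            "mean_signed_diff_ms": self.mean_signed_diff,
            "pearson_r": self.pearson_r,
            "per_charge": {str(c): r.to_dict() for c, r in self.per_charge.items()},
        }


def evaluate(
    records: Sequence[PredictionRecord],
    thresholds: Sequence[float] = DEFAULT_THRESHOLD_GRID,
    split_by_charge: bool = True,
) -> EvaluationReport:
    """Full metric summary of a record set, with a per-charge breakdown."""
    _require_records(records)
    try:
        r = pearson_correlation(records) if len(records) >= 2 else None
    except ValidationError:
        r = None
    per_charge: dict[int, EvaluationReport] = {}
    if split_by_charge:
        charges = sorted({rec.peptide.charge for rec in records})
        if len(charges) > 1:
            for c in charges:
                sub = [rec for rec in records if rec.peptide.charge == c]
                per_charge[c] = evaluate(sub, thresholds, split_by_charge=False)
    return EvaluationReport(
        n=len(records),
        accuracy_at=accuracy_curve(records, thresholds),
        mean_signed_diff=mean_signed_difference(records),
        pearson_r=r,
        records=tuple(records),
        per_charge=per_charge,
    )


@dataclass(frozen=True)
class CVPlan:
    """A k-fold partition: folds[i] holds the validation indices of fold i."""

    n: int
    folds: tuple[tuple[int, ...], ...]
    seed: int

    def __post_init__(self) -> None:
        all_idx = sorted(i for fold in self.folds for i in fold)
        if all_idx != list(range(self.n)):
            raise ValidationError("folds must partition 0..n-1 exactly")
        sizes = [len(f) for f in self.folds]
        if max(sizes) - min(sizes) > 1:
            raise ValidationError("fold sizes must differ by at most 1")

    @property
    def k(self) -> int:
        return len(self.folds)

    def training_indices(self, fold: int) -> np.ndarray:
        held = set(self.folds[fold])
        return np.array([i for i in range(self.n) if i not in held])


def make_cv_folds(n: int, k: int = 10, seed: int = 0) -> CVPlan:
    """Random near-equal partition of n records into k validation folds."""
    if n < k:
        raise ValidationError(f"cannot split {n} records into {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = tuple(tuple(int(i) for i in chunk) for chunk in np.array_split(perm, k))
    return CVPlan(n=n, folds=folds, seed=seed)


def run_cv(
    peptides: Sequence[Peptide],
    hidden_nodes: int = 3,
    config: TrainingConfig = TrainingConfig(),
    plan: CVPlan | None = None,
    pka: PKaTable | None = None,
    mods: ModificationPolicy = ModificationPolicy(),
    thresholds: Sequence[float] = DEFAULT_THRESHOLD_GRID,
) -> EvaluationReport:
    """Charge-stratified k-fold cross-validation of the drift-time regressor.

    Every peptide must carry an observed drift time and all must share one
    charge state.  For each fold a fresh network is initialized and trained
    on the other folds — with feature normalization and target scaling
    fitted on those training folds only — and the held-out fold is
    predicted, so each record is predicted exactly once.
    """
    if any(p.drift_time_ms is None for p in peptides):
        raise ValidationError("cross-validation requires observed drift times on every peptide")
    charges = {p.charge for p in peptides}
    if len(charges) != 1:
        raise ValidationError(
            f"cross-validation runs on a single charge state, got charges {sorted(charges)}"
        )
    charge = charges.pop()
    plan = plan or make_cv_folds(len(peptides), seed=config.seed)
    if plan.n != len(peptides):
        raise ValidationError(f"CV plan covers {plan.n} records but dataset has {len(peptides)}")

    pka = pka or PKaTable.default()
    M = featurize_dataset(peptides, pka=pka, mods=mods)
    t = np.array([p.drift_time_ms for p in peptides])

    records: list[PredictionRecord | None] = [None] * len(peptides)
    for fold in range(plan.k):
        tr = plan.training_indices(fold)
        va = np.array(plan.folds[fold])
        M_tr = FeatureMatrix(values=M.values[:, tr])
        params = fit_normalization(M_tr)
        scaler = TargetScaler.fit(t[tr])
        model = init_network(hidden_nodes, config)
        model.feature_params = params
        model.target_scaler = scaler
        model.metadata.update({"charge": charge, "pka_source": pka.source_label, "fold": fold})
        model, _ = train_backprop(model, apply_normalization(M_tr, params), t[tr], config)
        X_va = apply_normalization(FeatureMatrix(values=M.values[:, va]), params).values
        from .ann import _forward_batch  # local import to keep the public surface small
        A2, _ = _forward_batch(model, X_va)
        preds = scaler.unscale(A2[0])
        for i, idx in enumerate(va):
            records[idx] = PredictionRecord(
                peptide=peptides[idx], t_exp=float(t[idx]), t_pred=float(preds[i])
            )
    assert all(r is not None for r in records)
    return evaluate(records, thresholds)  # type: ignore[arg-type]


@dataclass(frozen=True)
class HiddenNodeSelection:
    """Mean +/- sd CV accuracy per hidden-node count, and the recommended H.

    The recommendation is the smallest H whose mean accuracy lies within
    one pooled standard deviation of the best mean — the smallest network
    that is statistically indistinguishable from the top performer.
    """

    accuracy_mean: Mapping[int, float]
    accuracy_sd: Mapping[int, float]
    repeats: int
    threshold: float
    recommended: int

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "repeats": self.repeats,
            "recommended_hidden_nodes": self.recommended,
            "accuracy": {
                str(h): {"mean": self.accuracy_mean[h], "sd": self.accuracy_sd[h]}
                for h in self.accuracy_mean
            },
        }


def select_hidden_nodes(
    peptides: Sequence[Peptide],
    h_grid: Iterable[int] = range(1, 6),
    repeats: int = 10,
    config: TrainingConfig = TrainingConfig(),
    seed: int = 0,
    threshold: float = DEFAULT_THRESHOLD,
    pka: PKaTable | None = None,
    mods: ModificationPolicy = ModificationPolicy(),
) -> HiddenNodeSelection:
    """Repeated 10-fold CV over a grid of hidden-layer sizes.

    Each repeat uses a fresh random partition and fresh weight
    initialization; the table reports mean and standard deviation of
    accuracy at the given eta threshold.
    """
    h_grid = list(h_grid)
    if not h_grid:
        raise ValidationError("hidden-node grid must be non-empty")
    if repeats < 1:
        raise ValidationError("repeats must be >= 1")
    if repeats == 1:
        import warnings

        warnings.warn("repeats=1: standard deviations will be reported as 0", stacklevel=2)

    means: dict[int, float] = {}
    sds: dict[int, float] = {}
    for h in h_grid:
        accs = []
        for rep in range(repeats):
            rep_seed = (seed + 1000003 * rep + 7919 * h) % (2**31)
            rep_config = TrainingConfig(
                learning_rate=config.learning_rate, momentum=config.momentum,
                max_epochs=config.max_epochs, loss_tolerance=config.loss_tolerance,
                init_range=config.init_range, seed=rep_seed, online=config.online,
            )
            plan = make_cv_folds(len(peptides), seed=rep_seed)
            report = run_cv(peptides, h, rep_config, plan, pka=pka, mods=mods,
                            thresholds=(threshold,))
            accs.append(report.accuracy_at[threshold])
        means[h] = float(np.mean(accs))
        sds[h] = float(np.std(accs, ddof=1)) if repeats > 1 else 0.0

    best = max(means.values())
    pooled_sd = float(np.sqrt(np.mean([v**2 for v in sds.values()])))
    recommended = min(h for h in h_grid if means[h] >= best - pooled_sd)
    return HiddenNodeSelection(
        accuracy_mean=means, accuracy_sd=sds, repeats=repeats,
        threshold=threshold, recommended=recommended,
    )
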