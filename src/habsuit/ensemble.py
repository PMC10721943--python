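"""AUC-PR-weighted model ensembling and fixed-sensitivity thresholding.

The ensemble is a convex combination of member predictions with weights
proportional to each member's validation AUC-PR (each AUC-PR divided by the
included models' sum). To turn continuous suitability into a suitable /
unsuitable map, the threshold is set where a fixed fraction (default 0.95)
of presences scores at or above it — for a rare species, false negatives
cost far more than false positives, so sensitivity is pinned high and
specificity follows. Classification uses score >= t (ties suitable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import GridRaster
from .metrics import auc_pr

__all__ = [
    "EnsembleWeights",
    "ThresholdResult",
    "ensemble_weights",
    "ensemble_predict",
    "fixed_sensitivity_threshold",
    "classify_and_account",
    "WeightedEnsemble",
    "EnsembleResults",
    "max_sens_plus_spec_threshold",
]

ACRES_PER_KM2 = 247.10538


@dataclass
class EnsembleWeights:
    """Per-model weight fractions, nonnegative and summing to 1."""

    weights: dict[str, float]

    def __post_init__(self) -> None:
        vals = np.array(list(self.weights.values()), dtype=float)
        if (vals < 0).any():
            raise ValueError("weights must be nonnegative")
        if abs(vals.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")

    def __getitem__(self, model_id: str) -> float:
        return self.weights[model_id]

    def items(self):
        return self.weights.items()


def ensemble_weights(auc_pr_by_model: dict[str, float],
                     include: list[str] | None = None) -> EnsembleWeights:
    """Weights proportional to AUC-PR over the included models.

    Models outside ``include`` get no weight at all (e.g. a member whose
    AUC-PR is judged too low is fitted but excluded from the ensemble).
    """
    include = list(auc_pr_by_model) if include is None else list(include)
    if not include:
        raise ValueError("include list is empty")
    vals = np.array([auc_pr_by_model[m] for m in include], dtype=float)
    if (vals <= 0).any():
        raise ValueError("included AUC-PR values must be > 0")
    w = vals / vals.sum()
    return EnsembleWeights(dict(zip(include, w)))


def ensemble_predict(predictions: dict, weights: EnsembleWeights):
    """Pointwise/cellwise convex combination of member predictions.

    ``predictions`` maps model id to either score arrays (aligned) or
    GridRasters on one grid; only models carrying weight are consumed.
    """
    items = list(weights.items())
    missing = [m for m, _ in items if m not in predictions]
    if missing:
        raise ValueError(f"predictions missing for weighted models: {missing}")
    first = predictions[items[0][0]]
    if isinstance(first, GridRaster):
        for m, _ in items:
            if not predictions[m].aligned_with(first):
                raise ValueError("member rasters are not aligned")
        combined = sum(w * predictions[m].values for m, w in items)
        return first.like(combined, "suitability_ensemble")
    arrays = [np.asarray(predictions[m], dtype=float) for m, _ in items]
    n = arrays[0].shape
    if any(a.shape != n for a in arrays):
        raise ValueError("member prediction arrays are not aligned")
    return sum(w * a for (_, w), a in zip(items, arrays))


@dataclass
class ThresholdResult:
    """A fixed-sensitivity habitat classification and its accounting."""

    threshold: float
    target_sensitivity: float
    achieved_sensitivity: float
    specificity: float | None = None
    suitable_fraction: float | None = None
    suitable_km2: float | None = None
    suitable_acres: float | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def fixed_sensitivity_threshold(presence_scores,
                                target: float = 0.95) -> ThresholdResult:
    """Largest achievable threshold keeping sensitivity at or above target.

    Candidate thresholds are the observed presence scores plus 0 and 1
    (classification is score >= t, so these are the achievable cutpoints);
    the chosen t is the largest candidate with
    (#presences scoring >= t) / n >= target.
    """
    scores = np.asarray(presence_scores, dtype=float)
    if scores.size == 0:
        raise ValueError("presence scores are empty")
    if scores.size < 20:
        import warnings
        warnings.warn("fewer than 20 presence scores; threshold is unstable",
                      stacklevel=2)
    candidates = np.unique(np.concatenate([scores, [0.0, 1.0]]))
    n = scores.size
    best = None
    for t in candidates:
        sens = (scores >= t).sum() / n
        if sens >= target and (best is None or t > best[0]):
            best = (float(t), float(sens))
    t, sens = best  # t=0 always achieves sensitivity 1, so best exists
    return ThresholdResult(threshold=t, target_sensitivity=float(target),
                           achieved_sensitivity=sens)


def max_sens_plus_spec_threshold(presence_scores, absence_scores) -> float:
    """Alternative cutpoint maximising sensitivity + specificity."""
    p = np.asarray(presence_scores, dtype=float)
    a = np.asarray(absence_scores, dtype=float)
    candidates = np.unique(np.concatenate([p, a, [0.0, 1.0]]))
    best_t, best_v = 0.0, -np.inf
    for t in candidates:
        v = (p >= t).mean() + (a < t).mean()
        if v > best_v:
            best_t, best_v = float(t), v
    return best_t


def classify_and_account(raster: GridRaster, threshold: float,
                         target_sensitivity: float = 0.95,
                         presence_scores=None, absence_scores=None):
    """Binary habitat map plus area accounting at a threshold.

    Returns (binary GridRaster, ThresholdResult). Suitable fraction is over
    valid cells; area uses the raster cell size; acres = km² x 247.10538
    (rounded to an integer when reported). If labeled point scores are
    supplied, sensitivity/specificity at the threshold are reported too.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must be in [0, 1]")
    valid = np.isfinite(raster.values)
    if not valid.any():
        raise ValueError("raster is entirely nodata")
    suitable = np.where(valid, (raster.values >= threshold).astype(float), np.nan)
    n_suit = np.nansum(suitable)
    frac = float(n_suit / valid.sum())
    km2 = float(n_suit * raster.cell_size ** 2 / 1e6)
    acres = km2 * ACRES_PER_KM2
    sens = None
    spec = None
    if presence_scores is not None and len(presence_scores) > 0:
        p = np.asarray(presence_scores, dtype=float)
        sens = float((p >= threshold).mean())
    if absence_scores is not None and len(absence_scores) > 0:
        a = np.asarray(absence_scores, dtype=float)
        spec = float((a < threshold).mean())
    result = ThresholdResult(
        threshold=float(threshold),
        target_sensitivity=float(target_sensitivity),
        achieved_sensitivity=sens if sens is not None else float("nan"),
        specificity=spec,
        suitable_fraction=frac,
        suitable_km2=km2,
        suitable_acres=acres,
    )
    binary = raster.like(suitable, "suitable_habitat")
    return binary, result


class WeightedEnsemble:
    """AUC-PR-weighted ensemble over fitted member models.

    statsmodels-style: constructed from member results plus the validation
    table used to weigh them; ``fit()`` computes the weights and returns an
    :class:`EnsembleResults` that predicts like any single model.
    """

    def __init__(self, members: dict, validation_exog, validation_labels,
                 include: list[str] | None = None):
        self.members = dict(members)
        self.validation_exog = validation_exog
        self.validation_labels = np.asarray(validation_labels, dtype=int)
        self.include = list(include) if include is not None else list(members)

    def fit(self) -> "EnsembleResults":
        aucpr = {
            name: auc_pr(res.predict(self.validation_exog),
                         self.validation_labels)
            for name, res in self.members.items()
        }
        weights = ensemble_weights(aucpr, self.include)
        return EnsembleResults(self, weights, aucpr)


class EnsembleResults:
    def __init__(self, model: WeightedEnsemble, weights: EnsembleWeights,
                 member_auc_pr: dict):
        self.model = model
        self.weights = weights
        self.member_auc_pr = member_auc_pr

    def predict(self, exog) -> np.ndarray:
        preds = {name: self.model.members[name].predict(exog)
                 for name, _ in self.weights.items()}
        return ensemble_predict(preds, self.weights)

    def predict_raster(self, stack) -> GridRaster:
        preds = {name: self.model.members[name].predict_raster(stack)
                 for name, _ in self.weights.items()}
        return ensemble_predict(preds, self.weights)

    def summary(self) -> str:
        lines = ["Weighted ensemble (weights proportional to AUC-PR)"]
        for name, w in self.weights.items():
            lines.append(f"  {name}: weight {w:.5f}"
                         f" (AUC-PR {self.member_auc_pr[name]:.3f})")
        excluded = set(self.model.members) - dict(self.weights.items()).keys()
        for name in sorted(excluded):
            lines.append(f"  {name}: excluded"
                         f" (AUC-PR {self.member_auc_pr[name]:.3f})")
        return "\n".join(lines)
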