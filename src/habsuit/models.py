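"""Presence-background suitability models behind one fit/predict contract.

Six algorithms are exposed through a single statsmodels-style surface:
``SuitabilityModel(y, X, spec).fit()`` returns a :class:`SuitabilityResults`
carrying the predictor, variable-importance ranks and a summary table. The
downstream ensemble layer never branches on the algorithm.

Algorithms
----------
rf_downsampled
    Random forest in which every tree is grown on a balanced bootstrap —
    an equal number of presence and background rows resampled per tree —
    the standard remedy for extreme class imbalance in presence-background
    designs.
rf_shallow
    Conventional random forest with every tree limited to depth 2, trading
    variance for bias.
brt
    Boosted regression trees: staged shallow trees with shrinkage and
    bagging.
maxent
    A MaxEnt-style model realised as an l1-regularized presence-background
    logistic regression over linear, quadratic and pairwise-product
    features of the standardized covariates; output is the predicted
    probability, already in [0, 1].
mars
    Multivariate adaptive regression splines: forward selection of hinge
    basis pairs (interactions up to degree 2) followed by generalized
    cross-validation backward pruning; regression on the 0/1 label with
    predictions clipped to [0, 1].
gam
    Binomial generalized additive model with penalized B-spline smooths
    (statsmodels GLMGam).

Scores are always in [0, 1] and prediction is stateless: the same input
yields the same score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as _sp_stats
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.tree import DecisionTreeClassifier

from .grid import GridRaster
from .terrain import CovariateStack

__all__ = ["ModelSpec", "SuitabilityModel", "SuitabilityResults", "ALGORITHMS"]

ALGORITHMS = ("rf_downsampled", "rf_shallow", "brt", "maxent", "mars", "gam")

DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "rf_downsampled": {"n_trees": 500, "max_features": "sqrt"},
    "rf_shallow": {"n_trees": 500, "max_depth": 2, "max_features": "sqrt"},
    "brt": {"n_trees": 1000, "learning_rate": 0.01, "max_depth": 3,
            "bag_fraction": 0.5},
    "maxent": {"c": 1.0},
    "mars": {"max_terms": 15, "max_degree": 2, "n_knots": 10, "penalty": 3.0},
    "gam": {"df": 5, "degree": 3, "alpha": 1.0},
}


@dataclass
class ModelSpec:
    algorithm: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        merged = dict(DEFAULT_HYPERPARAMETERS[self.algorithm])
        merged.update(self.hyperparameters)
        self.hyperparameters = merged



def _maxent_feature_matrix(X: np.ndarray, mu: np.ndarray,
                           sd: np.ndarray) -> np.ndarray:
    """Standardized linear + quadratic + pairwise-product feature matrix."""
    z = (X - mu) / sd
    feats = [z, z ** 2]
    for i, j in combinations(range(X.shape[1]), 2):
        feats.append((z[:, i] * z[:, j])[:, None])
    return np.hstack(feats)


def _maxent_feature_names(names: list[str]) -> list[str]:
    out = list(names) + [f"{n}^2" for n in names]
    for i, j in combinations(range(len(names)), 2):
        out.append(f"{names[i]}*{names[j]}")
    return out


class _BalancedForestPredictor:
    """Mean positive-class probability over balanced-bootstrap trees."""

    def __init__(self, trees):
        self.trees = trees

    def __call__(self, X: np.ndarray) -> np.ndarray:
        out = np.zeros(X.shape[0])
        for tree in self.trees:
            proba = tree.predict_proba(X)
            if proba.shape[1] == 2:
                out += proba[:, 1]
            else:  # degenerate single-class bootstrap
                out += float(tree.classes_[0])
        return out / len(self.trees)


class _ProbaPredictor:
    """Positive-class probability of any fitted sklearn classifier."""

    def __init__(self, estimator):
        self.estimator = estimator

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict_proba(X)[:, 1]


class _MaxentPredictor:
    def __init__(self, classifier, mu, sd):
        self.classifier = classifier
        self.mu = mu
        self.sd = sd

    def __call__(self, X: np.ndarray) -> np.ndarray:
        feats = _maxent_feature_matrix(X, self.mu, self.sd)
        return self.classifier.predict_proba(feats)[:, 1]


class _MarsPredictor:
    def __init__(self, mars):
        self.mars = mars

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return np.clip(self.mars.predict(X), 0.0, 1.0)


class _GamPredictor:
    """B-spline bases are undefined beyond the training hull, so inputs are
    clipped to it (constant extrapolation at the boundary)."""

    def __init__(self, results, lo, hi):
        self.results = results
        self.lo = lo
        self.hi = hi

    def __call__(self, X: np.ndarray) -> np.ndarray:
        ex = np.ones((X.shape[0], 1))
        p = self.results.predict(ex, exog_smooth=np.clip(X, self.lo, self.hi))
        return np.clip(np.asarray(p, dtype=float), 0.0, 1.0)


class SuitabilityModel:
    """A presence-background suitability model before fitting.

    Parameters
    ----------
    endog : array of 0/1 labels (1 = presence)
    exog : array or DataFrame of covariates, one column per covariate
    spec : ModelSpec
    covariate_names : names for exog columns when exog is a bare array
    """

    def __init__(self, endog, exog, spec: ModelSpec,
                 covariate_names: list[str] | None = None):
        if isinstance(exog, pd.DataFrame):
            covariate_names = list(exog.columns)
            exog = exog.to_numpy(dtype=float)
        exog = np.asarray(exog, dtype=float)
        endog = np.asarray(endog, dtype=float)
        if exog.ndim != 2 or endog.shape[0] != exog.shape[0]:
            raise ValueError("endog/exog shape mismatch")
        if not np.isfinite(exog).all():
            raise ValueError("non-finite covariate values")
        uniq = set(np.unique(endog))
        if not uniq <= {0.0, 1.0}:
            raise ValueError("endog must be 0/1")
        if len(uniq) < 2:
            raise ValueError("degenerate single-class training data")
        n_pos = int(endog.sum())
        if n_pos < 10 or (endog.size - n_pos) < 10:
            raise ValueError("need at least 10 presences and 10 non-presences")
        self.endog = endog.astype(int)
        self.exog = exog
        self.spec = spec
        self.covariate_names = covariate_names or [
            f"x{i}" for i in range(exog.shape[1])
        ]

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, algorithm: str,
                       covariates: list[str] | None = None,
                       label_col: str = "label", seed: int = 0,
                       **hyperparameters) -> "SuitabilityModel":
        """Build from a point table whose label column holds either 0/1 or
        the strings presence/background/absence."""
        labels = data[label_col]
        if labels.dtype == object:
            y = (labels == "presence").astype(int).to_numpy()
        else:
            y = labels.to_numpy(dtype=int)
        if covariates is None:
            covariates = [c for c in data.columns
                          if c not in {label_col, "point_id", "x", "y", "source"}]
        spec = ModelSpec(algorithm, hyperparameters, seed)
        return cls(y, data[covariates], spec, list(covariates))

    # ------------------------------------------------------------------
    def fit(self) -> "SuitabilityResults":
        fitter = getattr(self, f"_fit_{self.spec.algorithm}")
        predict_fn, importance, extras = fitter()
        return SuitabilityResults(self, predict_fn, importance, extras)

    # -- tree ensembles -------------------------------------------------
    def _fit_rf_downsampled(self):
        hp = self.spec.hyperparameters
        rng = np.random.default_rng(self.spec.seed)
        pos = np.flatnonzero(self.endog == 1)
        neg = np.flatnonzero(self.endog == 0)
        n_bal = min(pos.size, neg.size)
        trees, bootstraps = [], []
        importances = np.zeros(self.exog.shape[1])
        for _ in range(hp["n_trees"]):
            idx = np.concatenate([
                rng.choice(pos, size=n_bal, replace=True),
                rng.choice(neg, size=n_bal, replace=True),
            ])
            tree = DecisionTreeClassifier(
                max_features=hp["max_features"],
                random_state=int(rng.integers(2**31 - 1)),
            )
            tree.fit(self.exog[idx], self.endog[idx])
            trees.append(tree)
            bootstraps.append(idx)
            importances += tree.feature_importances_
        importances /= hp["n_trees"]

        importance = dict(zip(self.covariate_names, importances))
        return (_BalancedForestPredictor(trees), importance,
                {"trees": trees, "bootstraps": bootstraps})

    def _fit_rf_shallow(self):
        hp = self.spec.hyperparameters
        rf = RandomForestClassifier(
            n_estimators=hp["n_trees"], max_depth=hp["max_depth"],
            max_features=hp["max_features"], random_state=self.spec.seed,
            n_jobs=1,
        )
        rf.fit(self.exog, self.endog)

        importance = dict(zip(self.covariate_names, rf.feature_importances_))
        return _ProbaPredictor(rf), importance, {"forest": rf}

    def _fit_brt(self):
        hp = self.spec.hyperparameters
        brt = GradientBoostingClassifier(
            n_estimators=hp["n_trees"], learning_rate=hp["learning_rate"],
            max_depth=hp["max_depth"], subsample=hp["bag_fraction"],
            random_state=self.spec.seed,
        )
        brt.fit(self.exog, self.endog)

        importance = dict(zip(self.covariate_names, brt.feature_importances_))
        return _ProbaPredictor(brt), importance, {"model": brt}

    # -- maxent-style regularized logistic --------------------------------
    def _fit_maxent(self):
        hp = self.spec.hyperparameters
        mu = self.exog.mean(axis=0)
        sd = self.exog.std(axis=0)
        sd[sd == 0] = 1.0
        feats = _maxent_feature_matrix(self.exog, mu, sd)
        feat_names = _maxent_feature_names(self.covariate_names)
        clf = LogisticRegression(
            l1_ratio=1.0, C=hp["c"], solver="liblinear",
            random_state=self.spec.seed, max_iter=2000,
        )
        clf.fit(feats, self.endog)

        coefs = np.abs(clf.coef_[0])
        importance = {}
        for name in self.covariate_names:
            total = 0.0
            for fname, c in zip(feat_names, coefs):
                if name in fname.split("*") or fname == f"{name}^2":
                    total += c
            importance[name] = total
        return _MaxentPredictor(clf, mu, sd), importance, {"classifier": clf}

    # -- MARS ---------------------------------------------------------------
    def _fit_mars(self):
        hp = self.spec.hyperparameters
        mars = _Mars(max_terms=hp["max_terms"], max_degree=hp["max_degree"],
                     n_knots=hp["n_knots"], penalty=hp["penalty"])
        mars.fit(self.exog, self.endog.astype(float))

        importance = mars.variable_importance(self.covariate_names)
        return _MarsPredictor(mars), importance, {"mars": mars}

    # -- GAM ---------------------------------------------------------------
    def _fit_gam(self):
        from statsmodels.gam.api import BSplines, GLMGam
        import statsmodels.api as sm

        hp = self.spec.hyperparameters
        k = self.exog.shape[1]
        df = [hp["df"]] * k
        degree = [hp["degree"]] * k
        bs = BSplines(self.exog, df=df, degree=degree,
                      variable_names=self.covariate_names)
        ones = np.ones((self.exog.shape[0], 1))
        # separable data breaks the binomial IRLS; retry with a lightly
        # label-smoothed response, then with escalating penalties
        eps = 1e-3
        attempts = [
            (self.endog.astype(float), hp["alpha"]),
            (self.endog * (1 - 2 * eps) + eps, hp["alpha"]),
            (self.endog * (1 - 2 * eps) + eps, hp["alpha"] * 100),
            (self.endog * (1 - 2 * eps) + eps, hp["alpha"] * 10000),
        ]
        res = None
        for endog, alpha in attempts:
            gam = GLMGam(endog, exog=ones, smoother=bs,
                         alpha=[alpha] * k, family=sm.families.Binomial())
            try:
                res = gam.fit(maxiter=100)
                if np.isfinite(res.params).all():
                    break
                res = None
            except Exception:
                res = None
        if res is None:
            raise RuntimeError("GAM fit failed to converge")

        predictor = _GamPredictor(res, self.exog.min(axis=0),
                                  self.exog.max(axis=0))

        # term contribution: variance of each smooth's partial prediction
        importance = {}
        offset = 1  # intercept column
        params = res.params
        for name, smoother in zip(self.covariate_names, bs.smoothers):
            nb = smoother.basis.shape[1]
            partial = smoother.basis @ params[offset:offset + nb]
            importance[name] = float(np.var(partial))
            offset += nb
        return predictor, importance, {"results": res}


BUNDLE_FORMAT_VERSION = 1


class SuitabilityResults:
    """A fitted suitability model: predictor, importance, diagnostics."""

    def __init__(self, model: SuitabilityModel | None, predict_fn,
                 importance: dict, extras: dict,
                 spec: ModelSpec | None = None,
                 covariate_names: list[str] | None = None):
        self.model = model
        self.spec = spec if spec is not None else model.spec
        self.covariate_names = (covariate_names if covariate_names is not None
                                else list(model.covariate_names))
        self._predict = predict_fn
        self.raw_importance_ = importance
        self.extras = extras
        self.training_scores_ = (self.predict(model.exog)
                                 if model is not None else None)

    # -- persistence -------------------------------------------------------
    def save(self, directory) -> None:
        """Persist a versioned on-disk bundle.

        The bundle holds the model spec and covariate schema as JSON, the
        fitted predictor as a pickle, and the importance table as CSV.
        """
        import json
        import pathlib
        import pickle

        directory = pathlib.Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "format_version": BUNDLE_FORMAT_VERSION,
            "algorithm": self.spec.algorithm,
            "hyperparameters": self.spec.hyperparameters,
            "seed": self.spec.seed,
            "covariate_names": self.covariate_names,
        }
        with open(directory / "bundle.json", "w") as fh:
            json.dump(meta, fh, indent=2)
        with open(directory / "predictor.pkl", "wb") as fh:
            pickle.dump(self._predict, fh)
        pd.DataFrame({
            "covariate": list(self.raw_importance_),
            "importance": list(self.raw_importance_.values()),
        }).to_csv(directory / "importance.csv", index=False)

    @classmethod
    def load(cls, directory) -> "SuitabilityResults":
        """Reload a bundle written by :meth:`save`; the training data are
        not part of the bundle, so ``training_scores_`` is None."""
        import json
        import pathlib
        import pickle

        directory = pathlib.Path(directory)
        with open(directory / "bundle.json") as fh:
            meta = json.load(fh)
        if meta.get("format_version") != BUNDLE_FORMAT_VERSION:
            raise ValueError("unsupported bundle format "
                             f"{meta.get('format_version')!r}")
        with open(directory / "predictor.pkl", "rb") as fh:
            predictor = pickle.load(fh)
        imp = pd.read_csv(directory / "importance.csv")
        importance = dict(zip(imp["covariate"], imp["importance"]))
        spec = ModelSpec(meta["algorithm"], meta["hyperparameters"],
                         meta["seed"])
        return cls(None, predictor, importance, {}, spec=spec,
                   covariate_names=list(meta["covariate_names"]))

    # ------------------------------------------------------------------
    def predict(self, exog) -> np.ndarray:
        """Suitability scores in [0, 1], one per row."""
        if isinstance(exog, pd.DataFrame):
            missing = set(self.covariate_names) - set(exog.columns)
            if missing:
                raise ValueError(f"missing covariate columns: {sorted(missing)}")
            exog = exog[self.covariate_names].to_numpy(dtype=float)
        exog = np.asarray(exog, dtype=float)
        if exog.ndim != 2 or exog.shape[1] != len(self.covariate_names):
            raise ValueError("covariate schema mismatch")
        scores = np.asarray(self._predict(exog), dtype=float)
        return np.clip(scores, 0.0, 1.0)

    def predict_raster(self, stack: CovariateStack,
                       block_rows: int = 256) -> GridRaster:
        """Cellwise suitability over a covariate stack.

        Nodata in any input layer propagates to the output; evaluation is
        block-wise over raster rows so memory stays bounded.
        """
        missing = set(self.covariate_names) - set(stack.layer_names)
        if missing:
            raise ValueError(f"stack is missing layers: {sorted(missing)}")
        template = stack.template
        out = np.full(template.values.shape, np.nan)
        for r0 in range(0, template.nrows, block_rows):
            r1 = min(r0 + block_rows, template.nrows)
            block = np.stack(
                [stack[name].values[r0:r1].ravel()
                 for name in self.covariate_names], axis=1)
            valid = np.isfinite(block).all(axis=1)
            scores = np.full(block.shape[0], np.nan)
            if valid.any():
                scores[valid] = self.predict(block[valid])
            out[r0:r1] = scores.reshape(r1 - r0, template.ncols)
        return template.like(out, f"suitability_{self.spec.algorithm}")

    def variable_importance(self) -> pd.Series:
        """Dense importance ranks, 1 = most important.

        Covariates a pruned model does not use at all are unranked (NaN),
        mirroring how pruned MARS terms are conventionally reported.
        """
        s = pd.Series(self.raw_importance_, dtype=float)
        used = s.notna() & (s > 0)
        ranks = pd.Series(np.nan, index=s.index)
        if used.any():
            ranks[used] = _sp_stats.rankdata(-s[used], method="dense")
        return ranks

    def summary(self) -> str:
        hp = ", ".join(f"{k}={v}" for k, v in self.spec.hyperparameters.items())
        ranks = self.variable_importance()
        lines = [
            f"Suitability model: {self.spec.algorithm}",
            f"  seed: {self.spec.seed}",
            f"  hyperparameters: {hp}",
            (f"  n = {self.model.endog.size} "
             f"({int(self.model.endog.sum())} presences)"
             if self.model is not None else "  (loaded bundle)"),
            "  variable importance (rank 1 = most important):",
        ]
        for name in self.covariate_names:
            r = ranks[name]
            lines.append(f"    {name}: {'unranked' if np.isnan(r) else int(r)}")
        return "\n".join(lines)


# ----------------------------------------------------------------------
# Minimal MARS: forward hinge selection + GCV backward pruning.
# ----------------------------------------------------------------------

class _Mars:
    """Least-squares MARS with hinge pairs and interactions up to
    ``max_degree``; pruned by generalized cross-validation."""

    def __init__(self, max_terms: int = 15, max_degree: int = 2,
                 n_knots: int = 10, penalty: float = 3.0):
        self.max_terms = max_terms
        self.max_degree = max_degree
        self.n_knots = n_knots
        self.penalty = penalty
        self.terms: list[tuple] = [()]  # each term: tuple of (var, knot, sign)
        self.coef: np.ndarray | None = None
        self.term_gain: list[float] = [0.0]

    # term evaluation on standardized data
    def _term_column(self, z: np.ndarray, term: tuple) -> np.ndarray:
        col = np.ones(z.shape[0])
        for var, knot, sign in term:
            h = sign * (z[:, var] - knot)
            col = col * np.maximum(h, 0.0)
        return col

    def _basis(self, z: np.ndarray, terms=None) -> np.ndarray:
        terms = self.terms if terms is None else terms
        return np.column_stack([self._term_column(z, t) for t in terms])

    @staticmethod
    def _solve_rss(B: np.ndarray, y: np.ndarray):
        G = B.T @ B + 1e-9 * np.eye(B.shape[1])
        rhs = B.T @ y
        beta = np.linalg.solve(G, rhs)
        rss = float(y @ y - beta @ rhs)
        return beta, max(rss, 0.0)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_Mars":
        self.mu_ = X.mean(axis=0)
        self.sd_ = X.std(axis=0)
        self.sd_[self.sd_ == 0] = 1.0
        z = (X - self.mu_) / self.sd_
        n, k = z.shape
        qs = np.linspace(0.05, 0.95, self.n_knots)
        knots = [np.unique(np.quantile(z[:, j], qs)) for j in range(k)]

        B = self._basis(z)
        _, rss = self._solve_rss(B, y)
        tol = 1e-8 * float(y @ y)
        while len(self.terms) + 2 <= self.max_terms:
            best = None
            G = B.T @ B
            for p_idx, parent in enumerate(self.terms):
                if len(parent) >= self.max_degree:
                    continue
                used_vars = {v for v, _, _ in parent}
                parent_col = B[:, p_idx]
                for j in range(k):
                    if j in used_vars:
                        continue
                    for t in knots[j]:
                        c1 = parent_col * np.maximum(z[:, j] - t, 0.0)
                        c2 = parent_col * np.maximum(t - z[:, j], 0.0)
                        C = np.column_stack([c1, c2])
                        M = np.block([[G, B.T @ C],
                                      [C.T @ B, C.T @ C]])
                        rhs = np.concatenate([B.T @ y, C.T @ y])
                        try:
                            beta = np.linalg.solve(
                                M + 1e-9 * np.eye(M.shape[0]), rhs)
                        except np.linalg.LinAlgError:
                            continue
                        cand_rss = max(float(y @ y - beta @ rhs), 0.0)
                        if best is None or cand_rss < best[0]:
                            best = (cand_rss, parent, j, t, C)
            if best is None or (rss - best[0]) <= tol:
                break
            cand_rss, parent, j, t, C = best
            gain = rss - cand_rss
            self.terms.append(parent + ((j, float(t), 1.0),))
            self.terms.append(parent + ((j, float(t), -1.0),))
            self.term_gain += [gain / 2.0, gain / 2.0]
            B = np.hstack([B, C])
            rss = cand_rss

        # backward pruning by GCV
        def gcv(terms_idx):
            Bi = B[:, terms_idx]
            _, rss_i = self._solve_rss(Bi, y)
            m = len(terms_idx)
            c_eff = m + self.penalty * (m - 1) / 2.0
            denom = (1.0 - c_eff / n) ** 2
            return rss_i / n / denom if denom > 0 else np.inf

        current = list(range(len(self.terms)))
        best_idx = list(current)
        best_gcv = gcv(current)
        while len(current) > 1:
            trial_best = None
            for i in current[1:]:  # never remove the intercept
                trial = [t for t in current if t != i]
                g = gcv(trial)
                if trial_best is None or g < trial_best[0]:
                    trial_best = (g, trial)
            current = trial_best[1]
            if trial_best[0] < best_gcv:
                best_gcv = trial_best[0]
                best_idx = list(current)

        self.term_gain = [self.term_gain[i] for i in best_idx]
        self.terms = [self.terms[i] for i in best_idx]
        self.coef, _ = self._solve_rss(self._basis(z), y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        z = (np.asarray(X, dtype=float) - self.mu_) / self.sd_
        return self._basis(z) @ self.coef

    def variable_importance(self, names: list[str]) -> dict:
        """Forward-pass RSS-reduction attributed to each covariate over the
        retained terms; covariates in no retained term are NaN."""
        imp = {name: np.nan for name in names}
        for term, gain in zip(self.terms, self.term_gain):
            for var, _, _ in term:
                name = names[var]
                imp[name] = gain if np.isnan(imp[name]) else imp[name] + gain
        return imp
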