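"""Elastic-net epigenetic clocks.

A clock is a penalized linear model mapping a sample's CpG beta
profile to a (possibly transformed) age target:

* ``raw_age`` — chronological age in years; the single-species clock.
* ``loglinear_age`` — age through the log-linear transform (log below
  maturity, linear above); the dual-species chronological clock, where
  each species' samples are transformed with that species' maturity
  and offset.
* ``relative_age`` — age / maximum lifespan of the sample's species; a
  dimensionless ratio that aligns species with very different
  lifespans.

Fitting uses elastic-net regression with the mixing parameter fixed
at 0.5 (midway between ridge and lasso; not tuned for performance)
and the penalty strength chosen by internal 10-fold cross-validation
minimizing mean squared error (the lambda-min rule).  External
evaluation uses leave-one-out or k-fold cross-validation: every
reported prediction comes from a model that never saw that sample.

:class:`ElasticNetClock` is a scikit-learn estimator (``fit`` /
``predict`` / ``get_params``); the module-level ``train_clock``,
``predict_clock``, ``loocv`` and ``kfold_cv`` functions are thin
wrappers operating on matrix + sample-sheet pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

from .io import ClockModel, MethylationMatrix, align
from .transforms import AgeTransformSpec

__all__ = [
    "ElasticNetClock",
    "CVResult",
    "train_clock",
    "predict_clock",
    "loocv",
    "kfold_cv",
    "evaluate_predictions",
]

_TARGET_KINDS = ("raw_age", "loglinear_age", "relative_age")


class ElasticNetClock(BaseEstimator, RegressorMixin):
    """Elastic-net age clock with per-species age transforms.

    Parameters
    ----------
    target : {"raw_age", "loglinear_age", "relative_age"}
        Regression target scale (see module docstring).
    species_params : dict or None
        Mapping species name -> :class:`~clockforge.io.SpeciesParams`.
        Required for the two dual-species targets; ignored for
        ``raw_age``.
    alpha : float
        Elastic-net mixing parameter in [0, 1]; 0.5 by convention and
        deliberately not tuned.
    n_lambda : int
        Number of points on the penalty path searched by the internal
        cross-validation.
    cv : int
        Internal cross-validation fold count for penalty selection.
    tol, max_iter : float, int
        Coordinate-descent convergence controls.
    random_state : int or None
        Seeds the internal CV fold shuffle; fixing it makes refits on
        the same data bit-identical.
    floor_at_zero : bool
        Clip reported ages at zero (off by default; a clock can
        legitimately emit a small negative age for a newborn).

    Attributes
    ----------
    probe_ids_ : list of CpG ids the model was fitted on (training order)
    coef_, intercept_ : fitted coefficients on the transformed scale
    lambda_ : the selected penalty strength
    nonzero_ : indices of probes with nonzero coefficients
    """

    def __init__(self, target: str = "raw_age", species_params=None,
                 alpha: float = 0.5, n_lambda: int = 50, cv: int = 10,
                 tol: float = 3e-3, max_iter: int = 2000, random_state=None,
                 floor_at_zero: bool = False):
        self.target = target
        self.species_params = species_params
        self.alpha = alpha
        self.n_lambda = n_lambda
        self.cv = cv
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state
        self.floor_at_zero = floor_at_zero

    # -- target transform helpers -----------------------------------------
    def _transform_spec(self, species: str) -> AgeTransformSpec:
        kind = {"raw_age": "identity", "loglinear_age": "loglinear",
                "relative_age": "relative"}[self.target]
        if kind == "identity":
            return AgeTransformSpec(kind="identity")
        params = self.species_params or {}
        if species not in params:
            raise KeyError(f"no species parameters for {species!r} "
                           f"(target {self.target!r} needs them)")
        return params[species].transform_spec(kind)

    def _encode_target(self, ages, species) -> np.ndarray:
        ages = np.asarray(ages, dtype=float)
        out = np.empty_like(ages)
        for sp in np.unique(species):
            mask = np.asarray(species) == sp
            out[mask] = self._transform_spec(sp).transform(ages[mask])
        return out

    def _decode_target(self, y, species) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        out = np.empty_like(y)
        for sp in np.unique(species):
            mask = np.asarray(species) == sp
            out[mask] = self._transform_spec(sp).inverse(
                y[mask], floor_at_zero=self.floor_at_zero)
        return out

    # -- sklearn surface ---------------------------------------------------
    def fit(self, X, y, species=None, sample_weight=None):
        """Fit the clock.

        Parameters
        ----------
        X : DataFrame or ndarray, samples x probes betas.  Missing
            values are mean-imputed per probe (with a logged count).
        y : ages in years.
        species : per-sample species labels; defaults to a single
            unnamed species (valid only for ``raw_age``).
        sample_weight : optional nonnegative per-sample weights.
            Zero-weight samples are excluded from the fit entirely
            (so zeroing out one species of a dual-species panel
            reproduces the single-species clock exactly); the
            remaining weights enter the penalized least squares.
        """
        if self.target not in _TARGET_KINDS:
            raise ValueError(f"unknown target {self.target!r}")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha (elastic-net mixing) must lie in [0, 1]")
        X = pd.DataFrame(X)
        if sample_weight is not None:
            sample_weight = np.asarray(sample_weight, dtype=float)
            if (sample_weight < 0).any():
                raise ValueError("sample weights must be nonnegative")
            keep = sample_weight > 0
            X = X.iloc[keep]
            y = np.asarray(y, dtype=float)[keep]
            if species is not None:
                species = np.asarray(species)[keep]
            sample_weight = sample_weight[keep]
            if np.allclose(sample_weight, sample_weight[0]):
                sample_weight = None
        n = X.shape[0]
        if n < self.cv:
            raise ValueError(f"fewer samples ({n}) than internal CV folds ({self.cv})")
        y = np.asarray(y, dtype=float)
        if len(y) != n:
            raise ValueError("X and y length mismatch")
        if species is None:
            species = np.array(["_single"] * n)
            if self.target != "raw_age":
                raise ValueError(f"target {self.target!r} requires species labels")
        species = np.asarray(species)

        values = X.to_numpy(dtype=float)
        n_missing = int(np.isnan(values).sum())
        if n_missing:
            warnings.warn(f"mean-imputing {n_missing} missing beta value(s) at training")
            col_mean = np.nanmean(values, axis=0)
            values = np.where(np.isnan(values), col_mean[None, :], values)

        target = self._encode_target(y, species)
        if np.ptp(target) == 0:
            raise ValueError("constant age target: nothing to regress on")

        folds = KFold(n_splits=self.cv, shuffle=True,
                      random_state=self.random_state)
        enet = ElasticNetCV(
            l1_ratio=self.alpha, alphas=self.n_lambda, cv=folds,
            tol=self.tol, max_iter=self.max_iter, n_jobs=1,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            if sample_weight is not None:
                enet.fit(values, target, sample_weight=sample_weight)
            else:
                enet.fit(values, target)

        self.probe_ids_ = [str(c) for c in X.columns]
        self.coef_ = enet.coef_
        self.intercept_ = float(enet.intercept_)
        self.lambda_ = float(enet.alpha_)
        self.nonzero_ = np.flatnonzero(enet.coef_)
        self.training_species_ = sorted({str(s) for s in species})
        self.n_features_in_ = values.shape[1]
        return self

    def linear_score(self, X) -> np.ndarray:
        """Raw linear predictor (intercept + sum of coef * beta) on the
        transformed target scale, before any inverse transform."""
        check_is_fitted(self, "coef_")
        X = pd.DataFrame(X)
        cols = [str(c) for c in X.columns]
        if cols != self.probe_ids_:
            missing = [p for p in np.asarray(self.probe_ids_)[self.nonzero_]
                       if p not in set(cols)]
            if missing:
                raise KeyError(f"matrix lacks {len(missing)} model probe(s): {missing[:5]}")
            X = X.loc[:, self.probe_ids_]
        values = X.to_numpy(dtype=float)
        if np.isnan(values).any():
            warnings.warn("mean-imputing missing betas at prediction")
            col_mean = np.nanmean(values, axis=0)
            values = np.where(np.isnan(values), col_mean[None, :], values)
        return self.intercept_ + values @ self.coef_

    def predict(self, X, species=None) -> np.ndarray:
        """Predict DNAm age (years) or relative age, by inverting the
        target transform with each sample's species parameters."""
        score = self.linear_score(X)
        if species is None:
            if self.target != "raw_age":
                raise ValueError(f"target {self.target!r} requires species labels")
            species = np.array(["_single"] * len(score))
        return self._decode_target(score, np.asarray(species))

    # -- serialization bridge ----------------------------------------------
    def to_clock_model(self) -> ClockModel:
        check_is_fitted(self, "coef_")
        nz = self.nonzero_
        return ClockModel(
            probes=[self.probe_ids_[i] for i in nz],
            coefficients=self.coef_[nz],
            intercept=self.intercept_,
            alpha=self.alpha,
            penalty=self.lambda_,
            target=self.target,
            species_params=dict(self.species_params or {}),
            training_species=[s for s in self.training_species_ if s != "_single"],
        )


# ---------------------------------------------------------------------------
# matrix + sheet wrappers
# ---------------------------------------------------------------------------

def _prepare(matrix, sheet):
    if isinstance(matrix, MethylationMatrix):
        matrix, sheet = align(matrix, sheet)
        return matrix.data, sheet
    return pd.DataFrame(matrix), sheet


def train_clock(matrix, sheet: pd.DataFrame, species_params=None,
                target: str = "raw_age", alpha: float = 0.5, seed: int = 0,
                **kwargs) -> ClockModel:
    """Train a clock on a panel and return the serializable model."""
    X, sheet = _prepare(matrix, sheet)
    if X.shape[0] < 20:
        raise ValueError(f"need >= 20 samples to train a clock, got {X.shape[0]}")
    est = ElasticNetClock(target=target, species_params=species_params,
                          alpha=alpha, random_state=seed, **kwargs)
    est.fit(X, sheet["age"].to_numpy(), species=sheet["species"].to_numpy())
    return est.to_clock_model()


def predict_clock(model: ClockModel, matrix, sheet: pd.DataFrame,
                  floor_at_zero: bool = False) -> pd.Series:
    """Score a panel with a trained clock.

    The linear score is inverted through the model's target transform
    using each sample's species parameters; chronological-age clocks
    applied to a species without stored parameters fall back per
    :func:`clockforge.cross_species.transfer_evaluate`'s policy
    (training transform), which is handled there — here an unknown
    species under a species-dependent transform is an error.
    """
    X, sheet = _prepare(matrix, sheet)
    probe_pos = {p: i for i, p in enumerate(X.columns.astype(str))}
    missing = [p for p in model.probes if p not in probe_pos]
    if missing:
        raise KeyError(f"matrix lacks {len(missing)} model probe(s): {missing[:5]}")
    sub = X.loc[:, model.probes].to_numpy(dtype=float)
    if np.isnan(sub).any():
        warnings.warn("mean-imputing missing betas at prediction")
        col_mean = np.nanmean(sub, axis=0)
        sub = np.where(np.isnan(sub), col_mean[None, :], sub)
    score = model.intercept + sub @ model.coefficients
    out = np.empty_like(score)
    for sp in sheet["species"].unique():
        mask = (sheet["species"] == sp).to_numpy()
        spec = model.transform_for(sp)
        out[mask] = spec.inverse(score[mask], floor_at_zero=floor_at_zero)
    return pd.Series(out, index=X.index, name="dnam_age")


@dataclass
class CVResult:
    """Out-of-fold predictions plus summary metrics.

    ``predictions`` has one row per sample: truth and prediction on
    the clock's reporting scale (years, or a ratio for relative-age
    clocks), the fold index, and species.
    """

    predictions: pd.DataFrame
    target: str
    scheme: str

    def metrics(self) -> pd.DataFrame:
        return evaluate_predictions(
            self.predictions["predicted"], self.predictions["truth"],
            groups=self.predictions["species"])


def evaluate_predictions(pred, truth, groups=None) -> pd.DataFrame:
    """Pearson R and median absolute error, overall and per group.

    R measures rank/linear agreement and is invariant to affine
    miscalibration; MedAE is on the measurement scale and is not —
    the pair together separates rank-ordering power from calibration.
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if len(pred) != len(truth) or len(pred) < 3:
        raise ValueError("pred and truth must have equal length >= 3")
    rows = {}

    def one(name, p_, t_):
        if np.ptp(t_) == 0:
            raise ValueError(f"zero-variance truth in group {name!r}")
        rows[name] = {
            "n": len(p_),
            "R": float(np.corrcoef(p_, t_)[0, 1]),
            "medae": float(np.median(np.abs(p_ - t_))),
            "bias": float(np.mean(p_ - t_)),
        }

    one("overall", pred, truth)
    if groups is not None:
        groups = np.asarray(groups)
        for g in sorted(map(str, np.unique(groups))):
            mask = groups.astype(str) == g
            if mask.sum() >= 3:
                one(g, pred[mask], truth[mask])
    return pd.DataFrame(rows).T


def _truth_scale(model_target: str, ages, species, species_params) -> np.ndarray:
    """Truth on the clock's reporting scale: years for chronological
    clocks, the lifespan ratio for relative-age clocks."""
    if model_target != "relative_age":
        return np.asarray(ages, dtype=float)
    out = np.empty(len(ages))
    ages = np.asarray(ages, dtype=float)
    species = np.asarray(species)
    for sp in np.unique(species):
        mask = species == sp
        out[mask] = ages[mask] / species_params[sp].max_lifespan
    return out


def _run_folds(X, sheet, species_params, target, alpha, seed, fold_iter, scheme,
               **kwargs) -> CVResult:
    ages = sheet["age"].to_numpy()
    species = sheet["species"].to_numpy()
    pred = np.full(len(ages), np.nan)
    fold_id = np.full(len(ages), -1)
    for f, (train_idx, test_idx) in enumerate(fold_iter):
        est = ElasticNetClock(target=target, species_params=species_params,
                              alpha=alpha, random_state=seed, **kwargs)
        try:
            est.fit(X.iloc[train_idx], ages[train_idx], species=species[train_idx])
        except Exception as exc:
            raise RuntimeError(f"fold {f} fit failed: {exc}") from exc
        pred[test_idx] = est.predict(X.iloc[test_idx], species=species[test_idx])
        fold_id[test_idx] = f
    truth = _truth_scale(target, ages, species, species_params or {})
    frame = pd.DataFrame({
        "truth": truth, "predicted": pred, "fold": fold_id, "species": species,
    }, index=X.index)
    return CVResult(predictions=frame, target=target, scheme=scheme)


def loocv(matrix, sheet, species_params=None, target: str = "raw_age",
          alpha: float = 0.5, seed: int = 0, **kwargs) -> CVResult:
    """Leave-one-out cross-validation: n fits, each predicting the one
    held-out sample; R and MedAE computed on the assembled out-of-fold
    predictions."""
    X, sheet = _prepare(matrix, sheet)
    n = X.shape[0]
    folds = ((np.delete(np.arange(n), i), np.array([i])) for i in range(n))
    return _run_folds(X, sheet, species_params, target, alpha, seed, folds,
                      scheme="loocv", **kwargs)


def kfold_cv(matrix, sheet, species_params=None, target: str = "raw_age",
             k: int = 10, stratify_by_species: bool = True, alpha: float = 0.5,
             seed: int = 0, **kwargs) -> CVResult:
    """k-fold cross-validation, by default stratified by species so
    every training fold contains all species.  ``k == n`` reduces to
    the leave-one-out assignment exactly (seed-independent)."""
    X, sheet = _prepare(matrix, sheet)
    n = X.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds sample count {n}")
    if k == n:
        folds = ((np.delete(np.arange(n), i), np.array([i])) for i in range(n))
    else:
        rng = np.random.default_rng(seed)
        assignment = np.empty(n, dtype=int)
        if stratify_by_species:
            strata = [np.flatnonzero(sheet["species"].to_numpy() == sp)
                      for sp in sorted(sheet["species"].unique())]
        else:
            strata = [np.arange(n)]
        for idx in strata:
            perm = rng.permutation(idx)
            assignment[perm] = np.arange(len(perm)) % k
        folds = ((np.flatnonzero(assignment != f), np.flatnonzero(assignment == f))
                 for f in range(k))
    return _run_folds(X, sheet, species_params, target, alpha, seed, folds,
                      scheme=f"kfold{k}", **kwargs)
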