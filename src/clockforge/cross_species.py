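"""Applying a trained clock to species absent from training.

A clock built for one species (or species pair) often transfers its
*rank ordering* to related species — predicted and true ages correlate
highly — while remaining poorly *calibrated*: predictions carry a
systematic offset, so the median absolute error is large even when R
is excellent.  This module quantifies both sides of that decoupling
per species, and offers an explicitly post-hoc linear recalibration
(not part of the clock itself) for users who have a few labelled
samples of the new species.

Off-species policy for chronological clocks: predictions use the
training transform unchanged (a cat clock applied to lions reports
cat-scale years).  Relative-age reporting for a new species requires
that species' maximum lifespan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clock import evaluate_predictions
from .io import ClockModel, MethylationMatrix, SpeciesParams, align

__all__ = ["TransferReport", "transfer_evaluate", "recalibrate_linear",
           "apply_recalibration"]


@dataclass
class TransferReport:
    """Per-species transfer quality: n, Pearson R, MedAE, mean signed
    offset (bias), and the slope of prediction on truth."""

    table: pd.DataFrame  # index species; columns n, R, medae, bias, slope
    predictions: pd.Series
    truth: pd.Series
    target: str

    def to_dict(self) -> dict:
        return {sp: {k: (int(v) if k == "n" else float(v)) for k, v in row.items()}
                for sp, row in self.table.to_dict(orient="index").items()}


def _fallback_transform(model: ClockModel, species: str):
    """Species missing from the model's parameter table use the first
    training species' transform for chronological targets."""
    if model.target == "raw_age" or species in model.species_params:
        return model.transform_for(species)
    if model.target == "relative_age":
        raise KeyError(
            f"relative-age reporting for {species!r} needs that species' "
            f"max lifespan; none stored and none supplied")
    donor = next((s for s in model.training_species if s in model.species_params), None)
    if donor is None:
        raise KeyError(f"no transform parameters available for {species!r}")
    return model.species_params[donor].transform_spec("loglinear")


def transfer_evaluate(model: ClockModel, matrix, sheet: pd.DataFrame,
                      species_params=None) -> TransferReport:
    """Score a panel with a clock and summarize per-species transfer.

    ``species_params`` supplies lifespans for species the model has
    never seen (needed for relative-age truth/reporting); species with
    fewer than 3 samples are excluded with a warning, since R is
    undefined below that.
    """
    if isinstance(matrix, MethylationMatrix):
        matrix, sheet = align(matrix, sheet)
        X = matrix.data
    else:
        X = pd.DataFrame(matrix)
    species_params = dict(species_params or {})

    sub = X.loc[:, model.probes].to_numpy(dtype=float)
    score = model.intercept + sub @ model.coefficients

    pred = np.empty(len(score))
    truth = sheet["age"].to_numpy(dtype=float).copy()
    for sp in sheet["species"].unique():
        mask = (sheet["species"] == sp).to_numpy()
        if model.target == "relative_age" and sp not in model.species_params:
            if sp not in species_params:
                raise KeyError(f"relative-age evaluation of {sp!r} needs max lifespan")
            spec = species_params[sp].transform_spec("relative")
        else:
            spec = _fallback_transform(model, sp)
        pred[mask] = spec.inverse(score[mask])
        if model.target == "relative_age":
            L = (model.species_params.get(sp) or species_params[sp]).max_lifespan
            truth[mask] = truth[mask] / L

    rows = {}
    for sp in sorted(sheet["species"].unique()):
        mask = (sheet["species"] == sp).to_numpy()
        if mask.sum() < 3:
            warnings.warn(f"species {sp!r} has n={int(mask.sum())} < 3, excluded")
            continue
        p_, t_ = pred[mask], truth[mask]
        m = evaluate_predictions(p_, t_).loc["overall"]
        slope = float(np.polyfit(t_, p_, 1)[0]) if np.ptp(t_) > 0 else np.nan
        rows[sp] = {"n": int(mask.sum()), "R": m["R"], "medae": m["medae"],
                    "bias": m["bias"], "slope": slope}
    return TransferReport(
        table=pd.DataFrame(rows).T,
        predictions=pd.Series(pred, index=X.index, name="predicted"),
        truth=pd.Series(truth, index=X.index, name="truth"),
        target=model.target,
    )


def recalibrate_linear(predictions, truth):
    """Least-squares line mapping raw clock output to truth.

    Returns ``(intercept, slope)`` such that ``intercept + slope *
    prediction`` approximates truth; on the fitting set the corrected
    MedAE is the residual median absolute error of the line, which
    removes any systematic offset or scale miscalibration.  A
    convenience for rank-order users with a few labelled samples;
    never part of the clock proper.
    """
    p = np.asarray(predictions, dtype=float)
    t = np.asarray(truth, dtype=float)
    if len(p) != len(t) or len(p) < 3:
        raise ValueError("need equal-length predictions/truth with n >= 3")
    if np.ptp(p) == 0:
        raise ValueError("degenerate (constant) predictions cannot be recalibrated")
    slope, intercept = np.polyfit(p, t, 1)
    return float(intercept), float(slope)


def apply_recalibration(predictions, intercept: float, slope: float) -> np.ndarray:
    return intercept + slope * np.asarray(predictions, dtype=float)
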