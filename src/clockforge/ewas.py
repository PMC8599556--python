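"""Epigenome-wide association of age.

Each CpG is tested for Pearson correlation between its beta values and
chronological age.  The chain is the classic correlation screening
statistic::

    t = r * sqrt(n - 2) / sqrt(1 - r**2)        (df = n - 2)
    p = two-sided tail of Student's t
    z = sign(r) * Phi^{-1}(1 - p/2)

so ``z`` is the signed standard-normal equivalent of the two-sided
correlation test — positive for CpGs that gain methylation with age
(hypermethylation), negative for losses.  ``|z|`` is capped at
``zmax`` (default 40) where the p-value underflows.

Per-tissue results are combined with Stouffer's method,
``Z = sum(w_i z_i) / sqrt(sum(w_i^2))``; probes absent in a tissue
contribute nothing rather than a zero z.

Selection follows a fixed genome-wide threshold (default ``p < 1e-8``)
rather than an FDR procedure, then keeps up to a cap (default 500)
most extreme CpGs per direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EWASRecord",
    "TopCpGSet",
    "cor_test_z",
    "ewas_screen",
    "stouffer_combine",
    "select_top_cpgs",
    "region_summary",
    "island_association_summary",
]

ZMAX = 40.0


@dataclass(frozen=True)
class EWASRecord:
    """Correlation-test result for one probe."""

    probe: str
    n: int
    r: float
    t: float
    p: float
    z: float
    saturated: bool = False  # |z| hit the cap (p underflow)
    valid: bool = True


def _chain(r: np.ndarray, n, zmax: float = ZMAX):
    """Vectorized r -> (t, p, z) chain with saturation handling."""
    r = np.asarray(r, dtype=float)
    n = np.broadcast_to(np.asarray(n), r.shape).astype(float)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df) / np.sqrt(1.0 - r**2)
    perfect = np.isclose(np.abs(r), 1.0)
    with np.errstate(invalid="ignore"):
        t = np.where(perfect, np.sign(r) * np.inf, t)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, 0.0, 1.0)
    with np.errstate(divide="ignore"):
        z_mag = stats.norm.isf(p / 2.0)
    saturated = ~np.isfinite(z_mag) | (z_mag > zmax)
    z = np.sign(r) * np.where(saturated, zmax, z_mag)
    z = np.where(r == 0, 0.0, z)
    return t, p, z, saturated


def cor_test_z(x, y, zmax: float = ZMAX, probe: str = "") -> EWASRecord:
    """Pearson correlation test of ``y`` (betas) against ``x`` (ages).

    Pairs with a missing value on either side are dropped.  Zero
    variance on either side marks the record invalid rather than
    raising, so a screen over many probes can proceed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError(f"need n >= 3 observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return EWASRecord(probe=probe, n=n, r=np.nan, t=np.nan, p=np.nan, z=np.nan,
                          valid=False)
    r = float(np.corrcoef(x, y)[0, 1])
    t, p, z, sat = _chain(np.array([r]), n, zmax=zmax)
    return EWASRecord(probe=probe, n=n, r=r, t=float(t[0]), p=float(p[0]),
                      z=float(z[0]), saturated=bool(sat[0]))


def ewas_screen(matrix, ages, zmax: float = ZMAX) -> pd.DataFrame:
    """Run the correlation-test chain over every probe of a matrix.

    Parameters
    ----------
    matrix : MethylationMatrix or DataFrame
        Samples x probes betas; NaN allowed (pairwise complete).
    ages : array-like
        One age per sample, aligned with matrix rows.

    Returns
    -------
    DataFrame indexed by probe with columns
    ``n, r, t, p, z, saturated, valid`` — equal, probe by probe, to a
    :func:`cor_test_z` loop, but vectorized.
    """
    data = matrix.data if hasattr(matrix, "data") else pd.DataFrame(matrix)
    ages = np.asarray(ages, dtype=float)
    if len(ages) != data.shape[0]:
        raise ValueError("ages length does not match number of samples")
    Y = data.to_numpy(dtype=float)
    finite = np.isfinite(Y) & np.isfinite(ages)[:, None]
    n = finite.sum(axis=0)

    # masked pairwise-complete Pearson per probe
    X = np.where(finite, ages[:, None], 0.0)
    Ym = np.where(finite, Y, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mx = X.sum(0) / n
        my = Ym.sum(0) / n
        sxy = (X * Ym).sum(0) - n * mx * my
        sxx = (X * X).sum(0) - n * mx**2
        syy = (Ym * Ym).sum(0) - n * my**2
        r = sxy / np.sqrt(sxx * syy)
    valid = (n >= 3) & (sxx > 0) & (syy > 0)
    r = np.where(valid, np.clip(r, -1.0, 1.0), np.nan)
    t, p, z, sat = _chain(r, np.maximum(n, 3), zmax=zmax)
    out = pd.DataFrame({
        "n": n.astype(int), "r": r, "t": t, "p": p, "z": z,
        "saturated": sat & valid, "valid": valid,
    }, index=data.columns.rename("probe_id"))
    out.loc[~out["valid"], ["t", "p", "z"]] = np.nan
    return out


def stouffer_combine(z_by_tissue: pd.DataFrame, weights=None) -> pd.Series:
    """Combine per-tissue z-scores probe-wise with Stouffer's method.

    ``z_by_tissue`` is probes x tissues; NaN marks a probe absent in a
    tissue and contributes weight 0.  Default weights are 1 per
    tissue.  ``Z = sum(w_i z_i) / sqrt(sum(w_i^2))`` over present
    tissues.
    """
    Z = pd.DataFrame(z_by_tissue).astype(float)
    if weights is None:
        w = np.ones(Z.shape[1])
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (Z.shape[1],):
            raise ValueError("weights must have one entry per tissue column")
    present = Z.notna().to_numpy()
    if not present.any(axis=1).all():
        missing = Z.index[~present.any(axis=1)].tolist()
        raise ValueError(f"probe(s) with no finite z in any tissue: {missing[:10]}")
    zv = np.where(present, Z.to_numpy(), 0.0)
    num = (zv * w).sum(axis=1)
    den = np.sqrt(((present * w) ** 2).sum(axis=1))
    return pd.Series(num / den, index=Z.index, name="z_combined")


@dataclass
class TopCpGSet:
    """Significant age-associated CpGs, split by direction."""

    hyper: list  # z > 0, gain methylation with age
    hypo: list  # z < 0
    p_threshold: float
    cap: int
    records: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)

    def __post_init__(self):
        if set(self.hyper) & set(self.hypo):
            raise ValueError("hyper and hypo lists must be disjoint")
        if len(self.hyper) > self.cap or len(self.hypo) > self.cap:
            raise ValueError("direction list exceeds cap")


def select_top_cpgs(records: pd.DataFrame, p_threshold: float = 1e-8,
                    cap: int = 500) -> TopCpGSet:
    """Select significant CpGs and keep the most extreme per direction.

    Probes with ``p < p_threshold`` are split by the sign of ``z``;
    within each direction the ``cap`` largest ``|z|`` are retained.
    Ties at the boundary break deterministically toward the
    lexicographically smaller probe id, and the output is invariant to
    input row order.
    """
    valid = records["valid"] if "valid" in records.columns else True
    rec = records[valid & (records["p"] < p_threshold)]
    out = {}
    for name, sign in (("hyper", 1), ("hypo", -1)):
        sub = rec[np.sign(rec["z"]) == sign]
        order = pd.DataFrame({
            "absz": sub["z"].abs().to_numpy(),
            "probe": sub.index.astype(str),
        }).sort_values(["absz", "probe"], ascending=[False, True], kind="mergesort")
        out[name] = list(order["probe"][:cap])
    return TopCpGSet(hyper=out["hyper"], hypo=out["hypo"], p_threshold=p_threshold,
                     cap=cap, records=records)


def region_summary(topset: TopCpGSet, annotation: pd.DataFrame,
                   background=None) -> pd.DataFrame:
    """Count top CpGs per region class, by direction, and the
    proportion hypermethylated per region (hyper / (hyper + hypo)).

    ``background`` (defaults to all annotated probes) is counted
    alongside, mirroring how genomic-context plots show the array
    background next to the selected sets.
    """
    members = list(topset.hyper) + list(topset.hypo)
    missing = [pid for pid in members if pid not in annotation.index]
    if missing:
        raise ValueError(f"unannotated top probe(s): {missing[:10]}")
    if background is None:
        background = list(annotation.index)
    regions = pd.Index(sorted(annotation["region"].unique()))
    counts = pd.DataFrame(0, index=regions, columns=["hyper", "hypo", "background"])
    for col, ids in (("hyper", topset.hyper), ("hypo", topset.hypo),
                     ("background", background)):
        vc = annotation.loc[list(ids), "region"].value_counts()
        counts.loc[vc.index, col] = vc.to_numpy()
    total = counts["hyper"] + counts["hypo"]
    with np.errstate(invalid="ignore"):
        counts["prop_hyper"] = np.where(total > 0, counts["hyper"] / total, np.nan)
    return counts


def island_association_summary(records: pd.DataFrame,
                               annotation: pd.DataFrame) -> dict:
    """Compare the age-association z of CpG-island probes against the
    rest (aging CpGs in islands skew toward hypermethylation).

    Returns per-group n / mean z / median z and a two-sided Wilcoxon
    rank-sum p-value for the island-vs-other contrast.
    """
    common = records.index.intersection(annotation.index)
    z = records.loc[common, "z"]
    z = z[np.isfinite(z)]
    island = annotation.loc[z.index, "island"].astype(bool)
    groups = {"island": z[island], "other": z[~island]}
    for name, values in groups.items():
        if len(values) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 probes")
    stat, pval = stats.ranksums(groups["island"], groups["other"])
    return {
        "island": {"n": int(len(groups["island"])),
                   "mean_z": float(groups["island"].mean()),
                   "median_z": float(groups["island"].median())},
        "other": {"n": int(len(groups["other"])),
                  "mean_z": float(groups["other"].mean()),
                  "median_z": float(groups["other"].median())},
        "ranksum_stat": float(stat),
        "ranksum_p": float(pval),
        "mean_difference": float(groups["island"].mean() - groups["other"].mean()),
    }
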