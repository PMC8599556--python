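"""Synthetic multi-species methylation panels with known aging structure.

The real substrate for cross-species clocks is a mammalian array of
~36k CpGs whose flanking sequence is conserved across species, of
which a minority drift monotonically with age.  This module emulates
that substrate at configurable scale so every downstream stage —
QC, clock training, cross-validation, transfer, EWAS — can be tested
against a known ground truth.

The generative model for sample *i* of species *s* and probe *j* is::

    beta_ij = clip(b0_j(s) + slope_j * relative_age_i
                   + sex_delta_j * 1[male_i] + eps_ij,  0, 1)

with ``eps ~ Normal(0, noise_sd)`` and ``relative_age = age /
max_lifespan(s)``.  Aging trajectories are linear in *relative* age,
not raw age, so that probes marked "shared" are genuinely conserved
across species with different lifespans.  Gaussian-then-clip noise is
a deliberate simplification of beta-distributed array noise; swap in a
different noise model by subclassing if needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MethylationMatrix, SpeciesParams, validate_sample_sheet

__all__ = ["SpeciesDesign", "GeneratorConfig", "GroundTruth", "generate_panel", "sample_ages"]

PROBE_ROLES = ("age+", "age-", "sex", "species_marker", "null")


@dataclass(frozen=True)
class SpeciesDesign:
    """Sampling design for one species in a panel."""

    n_samples: int
    age_range: tuple  # (min years, max years)
    max_lifespan: float
    maturity: float = 1.0

    def __post_init__(self):
        if self.n_samples < 3:
            raise ValueError(
                f"need n_samples >= 3 per species (correlations are undefined below), "
                f"got {self.n_samples}"
            )
        lo, hi = self.age_range
        if not 0 <= lo < hi:
            raise ValueError(f"age_range must satisfy 0 <= min < max, got {self.age_range}")
        if self.max_lifespan <= 0:
            raise ValueError("max_lifespan must be positive")

    def params(self) -> SpeciesParams:
        return SpeciesParams(max_lifespan=self.max_lifespan, maturity=self.maturity)


@dataclass
class GeneratorConfig:
    """Panel design: probe budget, per-species sampling, effect sizes.

    Effect sizes are in beta units: ``age_effect_size`` is the total
    methylation change over the full relative-age range [0, 1];
    ``sex_effect_size`` the male-female difference at a sex probe;
    ``species_offset_sd`` the spread of per-species baseline offsets
    at species-marker probes; ``age_probe_offset_sd`` the same for age
    probes (0 keeps conserved age probes identically calibrated across
    species, >0 models conserved slopes sitting on species-specific
    baselines); ``noise_sd`` the measurement noise.
    ``shared_fraction`` is the fraction of age probes whose slope is
    present in every species; the remainder age in a single species
    only.
    """

    n_probes: int = 4000
    n_age_probes: int = 300
    n_sex_probes: int = 50
    n_species_marker_probes: int = 100
    species: dict = field(default_factory=lambda: {
        "cat": SpeciesDesign(n_samples=130, age_range=(0.2, 21.0), max_lifespan=30.0,
                             maturity=1.0),
    })
    age_effect_size: float = 0.3
    sex_effect_size: float = 0.15
    species_offset_sd: float = 0.1
    age_probe_offset_sd: float = 0.0
    noise_sd: float = 0.03
    shared_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for name, value in (("n_probes", self.n_probes),
                            ("n_age_probes", self.n_age_probes),
                            ("n_sex_probes", self.n_sex_probes),
                            ("n_species_marker_probes", self.n_species_marker_probes)):
            if value < 0 or (name == "n_probes" and value <= 0):
                raise ValueError(f"{name} must be positive, got {value}")
        if self.n_age_probes + self.n_sex_probes + self.n_species_marker_probes > self.n_probes:
            raise ValueError("special probe counts exceed n_probes")
        if not 0 <= self.shared_fraction <= 1:
            raise ValueError("shared_fraction must lie in [0, 1]")
        for name, value in (("age_effect_size", self.age_effect_size),
                            ("sex_effect_size", self.sex_effect_size),
                            ("species_offset_sd", self.species_offset_sd),
                            ("age_probe_offset_sd", self.age_probe_offset_sd),
                            ("noise_sd", self.noise_sd)):
            if value < 0:
                raise ValueError(f"{name} must be nonnegative, got {value}")
        if not self.species:
            raise ValueError("at least one species required")
        for sp, design in self.species.items():
            if not isinstance(design, SpeciesDesign):
                self.species[sp] = SpeciesDesign(**design)

    def species_params(self) -> dict:
        return {sp: d.params() for sp, d in self.species.items()}


@dataclass
class GroundTruth:
    """Per-probe generative parameters, for validating downstream stages.

    ``roles`` maps probe id to one of ``age+``, ``age-``, ``sex``,
    ``species_marker``, ``null``; ``slopes`` are beta units per unit
    relative age; ``slope_species`` is ``"shared"`` or the single
    species carrying a non-shared slope; ``baselines`` is species x
    probe; ``clip_fraction`` the fraction of emitted cells that hit
    the [0, 1] clip.
    """

    roles: pd.Series
    slopes: pd.Series
    slope_species: pd.Series
    sex_delta: pd.Series
    baselines: pd.DataFrame
    clip_fraction: float

    def __post_init__(self):
        null = self.roles == "null"
        if (self.slopes[null] != 0).any() or (self.sex_delta[null] != 0).any():
            raise ValueError("null probes must carry zero slope and zero sex delta")
        pos = self.slopes[self.roles == "age+"]
        neg = self.slopes[self.roles == "age-"]
        if len(pos) and pos.min() <= 0:
            raise ValueError("age+ probes must have positive slope")
        if len(neg) and neg.max() >= 0:
            raise ValueError("age- probes must have negative slope")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "role": self.roles,
            "slope": self.slopes,
            "slope_species": self.slope_species,
            "sex_delta": self.sex_delta,
        })
        for sp in self.baselines.index:
            df[f"baseline_{sp}"] = self.baselines.loc[sp]
        return df


def sample_ages(n: int, age_range, seed=None, rng=None) -> np.ndarray:
    """Draw ``n`` ages uniformly from ``age_range = (min, max)`` years."""
    if n < 1:
        raise ValueError(f"need n >= 1, got {n}")
    lo, hi = float(age_range[0]), float(age_range[1])
    if not 0 <= lo < hi:
        raise ValueError(f"age_range must satisfy 0 <= min < max, got {age_range}")
    if rng is None:
        rng = np.random.default_rng(seed)
    return rng.uniform(lo, hi, size=n)


# region-class sampling weights by probe role; age+ probes sit
# preferentially in promoters/5'UTRs and CpG islands, age- probes in
# introns — the qualitative genomic-context pattern of aging CpGs.
_REGIONS = ("promoter", "5'UTR", "exon", "intron", "3'UTR", "upstream", "downstream",
            "intergenic")
_REGION_WEIGHTS = {
    "age+": ([0.40, 0.15, 0.15, 0.10, 0.05, 0.05, 0.05, 0.05], 0.70),
    "age-": ([0.08, 0.05, 0.12, 0.45, 0.08, 0.06, 0.06, 0.10], 0.15),
    "background": ([0.12, 0.06, 0.15, 0.25, 0.07, 0.08, 0.08, 0.19], 0.30),
}


def generate_panel(config: GeneratorConfig):
    """Generate a panel under ``config``.

    Returns ``(matrix, sheet, annotation, truth)``: a
    :class:`~clockforge.io.MethylationMatrix`, a validated sample
    sheet, a probe annotation table and the :class:`GroundTruth`.
    Identical seeds give bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    p = config.n_probes
    probes = [f"cg{j:05d}" for j in range(p)]
    species_names = list(config.species)

    # --- probe roles ------------------------------------------------------
    roles = np.array(["null"] * p, dtype=object)
    n_age = config.n_age_probes
    n_pos = (n_age + 1) // 2
    roles[:n_pos] = "age+"
    roles[n_pos:n_age] = "age-"
    roles[n_age:n_age + config.n_sex_probes] = "sex"
    m0 = n_age + config.n_sex_probes
    roles[m0:m0 + config.n_species_marker_probes] = "species_marker"

    slopes = np.zeros(p)
    slopes[:n_pos] = config.age_effect_size
    slopes[n_pos:n_age] = -config.age_effect_size

    slope_species = np.array(["shared"] * p, dtype=object)
    n_shared = int(round(config.shared_fraction * n_age))
    for idx, j in enumerate(range(n_shared, n_age)):
        slope_species[j] = species_names[idx % len(species_names)]

    sex_delta = np.zeros(p)
    sex_idx = np.arange(n_age, n_age + config.n_sex_probes)
    signs = np.where(np.arange(len(sex_idx)) % 2 == 0, 1.0, -1.0)
    sex_delta[sex_idx] = signs * config.sex_effect_size

    # --- baselines --------------------------------------------------------
    b0 = rng.uniform(0.1, 0.9, size=p)  # common baseline; limits clipping
    baselines = pd.DataFrame(
        np.tile(b0, (len(species_names), 1)), index=species_names, columns=probes)
    marker_idx = np.arange(m0, m0 + config.n_species_marker_probes)
    for sp in species_names:
        if config.species_offset_sd > 0 and len(marker_idx):
            baselines.loc[sp, baselines.columns[marker_idx]] += rng.normal(
                0, config.species_offset_sd, size=len(marker_idx))
        if config.age_probe_offset_sd > 0 and n_age:
            baselines.loc[sp, baselines.columns[:n_age]] += rng.normal(
                0, config.age_probe_offset_sd, size=n_age)

    # --- samples ----------------------------------------------------------
    sheet_rows = []
    blocks = []
    n_clipped = 0
    n_cells = 0
    for sp in species_names:
        design = config.species[sp]
        n = design.n_samples
        ages = sample_ages(n, design.age_range, rng=rng)
        sexes = rng.choice(["female", "male"], size=n)
        neut_prob = np.where(ages >= 0.8, 0.85, 0.15)  # neutering confounded with age
        neutered = np.where(rng.uniform(size=n) < neut_prob, "yes", "no")
        rel_age = ages / design.max_lifespan

        eff_slopes = np.where(
            (slope_species == "shared") | (slope_species == sp), slopes, 0.0)
        male = (sexes == "male").astype(float)
        raw = (baselines.loc[sp].to_numpy()[None, :]
               + np.outer(rel_age, eff_slopes)
               + np.outer(male, sex_delta)
               + rng.normal(0, config.noise_sd, size=(n, p)))
        clipped = (raw < 0) | (raw > 1)
        n_clipped += int(clipped.sum())
        n_cells += raw.size
        blocks.append(np.clip(raw, 0.0, 1.0))

        for i in range(n):
            sheet_rows.append({
                "sample_id": f"{sp}_{i:04d}",
                "species": sp,
                "tissue": "blood",
                "age": ages[i],
                "sex": sexes[i],
                "neutered": neutered[i],
            })

    sheet = pd.DataFrame(sheet_rows).set_index("sample_id")
    sheet = validate_sample_sheet(sheet)
    matrix = MethylationMatrix(
        pd.DataFrame(np.vstack(blocks), index=sheet.index, columns=probes))

    clip_fraction = n_clipped / n_cells
    if clip_fraction >= 0.05:
        warnings.warn(f"clipping frequency {clip_fraction:.1%} exceeds 5%")

    # --- annotation -------------------------------------------------------
    region = np.empty(p, dtype=object)
    island = np.empty(p, dtype=bool)
    for j in range(p):
        weights, island_p = _REGION_WEIGHTS.get(roles[j], _REGION_WEIGHTS["background"])
        region[j] = rng.choice(_REGIONS, p=weights)
        island[j] = rng.uniform() < island_p
    annotation = pd.DataFrame({
        "gene": [f"GENE{j % max(1, p // 4):04d}" for j in range(p)],
        "region": region,
        "island": island,
        "dist_tss": rng.integers(-5000, 5000, size=p),
    }, index=pd.Index(probes, name="probe_id"))

    truth = GroundTruth(
        roles=pd.Series(roles, index=probes),
        slopes=pd.Series(slopes, index=probes),
        slope_species=pd.Series(slope_species, index=probes),
        sex_delta=pd.Series(sex_delta, index=probes),
        baselines=baselines,
        clip_fraction=clip_fraction,
    )
    return matrix, sheet, annotation, truth
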