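"""Validated in-memory containers and flat-file readers/writers.

Everything downstream operates on four tables:

* a methylation **beta matrix** (samples x CpG probes, values in [0, 1]
  or missing),
* a **sample sheet** of per-sample covariates (species, tissue, age,
  sex, neuter status),
* a **species parameter** table (maximum lifespan, age at maturity,
  log-transform offset) that drives the age transforms, and
* a **probe annotation** table (nearest gene, region class relative to
  the TSS, CpG-island flag).

Trained clocks are serialized to a two-part flat file: a metadata
header block, then one (probe, coefficient) record per line.  Floats
are written with ``repr`` so the decimal round trip is bit exact.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .transforms import AgeTransformSpec

__all__ = [
    "MethylationMatrix",
    "SpeciesParams",
    "ClockModel",
    "REGION_CLASSES",
    "read_matrix",
    "write_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "validate_sample_sheet",
    "read_species_params",
    "write_species_params",
    "read_probe_annotation",
    "write_probe_annotation",
    "validate_probe_annotation",
    "read_clock",
    "write_clock",
    "align",
]

REGION_CLASSES = (
    "promoter",
    "5'UTR",
    "exon",
    "intron",
    "3'UTR",
    "upstream",
    "downstream",
    "intergenic",
)

SEX_VALUES = ("female", "male", "unknown")
NEUTERED_VALUES = ("yes", "no", "unknown")

CLOCK_MAGIC = "#clockforge-clock v1"


class MethylationMatrix:
    """Dense samples-by-probes matrix of beta values.

    Betas live in [0, 1]; NaN marks a missing measurement.  Sample and
    probe ids must each be unique.  Internally samples are rows; files
    in either orientation are handled by :func:`read_matrix`.
    """

    def __init__(self, data: pd.DataFrame, strict: bool = True):
        if data.index.has_duplicates:
            dup = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample id(s): {dup}")
        if data.columns.has_duplicates:
            dup = data.columns[data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate probe id(s): {dup}")
        values = data.to_numpy(dtype=float, copy=False)
        out_of_range = (values < 0) | (values > 1)
        n_bad = int(np.nansum(out_of_range))
        if n_bad:
            if strict:
                i, j = np.argwhere(np.nan_to_num(out_of_range)).T
                example = (data.index[i[0]], data.columns[j[0]], values[i[0], j[0]])
                raise ValueError(
                    f"{n_bad} beta value(s) outside [0, 1]; first at "
                    f"sample {example[0]!r}, probe {example[1]!r}: {example[2]}"
                )
            warnings.warn(f"{n_bad} beta value(s) outside [0, 1] set to missing")
            data = data.where(~out_of_range)
        self.data = data.astype(float)

    # -- convenience views -------------------------------------------------
    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def probe_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self):
        return self.data.shape

    def loc_samples(self, ids) -> "MethylationMatrix":
        return MethylationMatrix(self.data.loc[list(ids)])

    def __repr__(self):
        n, p = self.data.shape
        return f"MethylationMatrix({n} samples x {p} probes)"


@dataclass(frozen=True)
class SpeciesParams:
    """Life-history parameters for one species, in years."""

    max_lifespan: float
    maturity: float
    offset: float = 0.0

    def __post_init__(self):
        if not 0 < self.maturity < self.max_lifespan:
            raise ValueError(
                f"need 0 < maturity < max_lifespan, got maturity={self.maturity}, "
                f"max_lifespan={self.max_lifespan}"
            )
        if self.offset < 0:
            raise ValueError(f"offset must be >= 0, got {self.offset}")

    def transform_spec(self, kind: str) -> AgeTransformSpec:
        return AgeTransformSpec(
            kind=kind,
            maturity=self.maturity,
            offset=self.offset,
            max_lifespan=self.max_lifespan,
        )


#: Default life-history table.  Lifespans follow the anAge records for
#: the two clock species; maturity/offset are package defaults for the
#: log-linear transform, configurable per species.
DEFAULT_SPECIES_PARAMS = {
    "cat": SpeciesParams(max_lifespan=30.0, maturity=1.0, offset=0.0),
    "human": SpeciesParams(max_lifespan=122.0, maturity=15.0, offset=0.0),
}


@dataclass
class ClockModel:
    """A trained epigenetic clock: sparse linear score plus the age
    transform needed to map the score back to years (or to a relative
    age in [0, 1])."""

    probes: list
    coefficients: np.ndarray
    intercept: float
    alpha: float  # elastic-net mixing (0 = ridge, 1 = lasso)
    penalty: float  # selected lambda
    target: str  # raw_age | loglinear_age | relative_age
    species_params: dict = field(default_factory=dict)  # species -> SpeciesParams
    training_species: list = field(default_factory=list)

    TARGET_KINDS = ("raw_age", "loglinear_age", "relative_age")
    _TARGET_TO_TRANSFORM = {
        "raw_age": "identity",
        "loglinear_age": "loglinear",
        "relative_age": "relative",
    }

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.probes) != len(self.coefficients):
            raise ValueError("probe and coefficient lists differ in length")
        if self.target not in self.TARGET_KINDS:
            raise ValueError(f"unknown target {self.target!r}")
        for sp in self.training_species:
            if self.target != "raw_age" and sp not in self.species_params:
                raise ValueError(f"missing transform parameters for training species {sp!r}")

    def transform_for(self, species: str) -> AgeTransformSpec:
        kind = self._TARGET_TO_TRANSFORM[self.target]
        if kind == "identity":
            return AgeTransformSpec(kind="identity")
        if species not in self.species_params:
            raise KeyError(f"no species parameters for {species!r}")
        return self.species_params[species].transform_spec(kind)

    @property
    def n_probes(self) -> int:
        return len(self.probes)


# ---------------------------------------------------------------------------
# beta matrix
# ---------------------------------------------------------------------------

def _read_table(path, sep=None) -> pd.DataFrame:
    """Read a delimited table with the first column as index.  When
    ``sep`` is None the delimiter is sniffed from the header line."""
    if sep is None:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if header.count("\t") >= header.count(",") else ","
    return pd.read_csv(path, sep=sep, index_col=0)


def read_matrix(path, orientation: str = "samples_by_probes", sep=None,
                strict: bool = True) -> MethylationMatrix:
    """Read a beta matrix from a delimited file.

    ``orientation`` names what the file's *rows* are: array vendors
    ship both samples-by-probes and probes-by-samples layouts, so the
    dialect is explicit.  Out-of-range values raise under
    ``strict=True`` and are set to missing (with a warning) otherwise.
    """
    if orientation not in ("samples_by_probes", "probes_by_samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_table(path, sep=sep)
    non_numeric = df.apply(lambda c: pd.to_numeric(c, errors="coerce"))
    bad = df.notna() & non_numeric.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy()).T
        raise ValueError(
            f"non-numeric cell at row {df.index[i[0]]!r}, column {df.columns[j[0]]!r}: "
            f"{df.iloc[i[0], j[0]]!r}"
        )
    df = non_numeric
    if orientation == "probes_by_samples":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return MethylationMatrix(df, strict=strict)


def write_matrix(matrix: MethylationMatrix, path, sep="\t") -> None:
    df = matrix.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep=sep, float_format=None)


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

def validate_sample_sheet(df: pd.DataFrame) -> pd.DataFrame:
    """Normalize and validate a sample sheet.

    Requires ``species`` and ``age`` columns; fills ``tissue``, ``sex``
    and ``neutered`` with ``unknown`` defaults.  Ages must be finite
    and nonnegative.
    """
    df = df.copy()
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample id(s) in sheet: {dup}")
    for col in ("species", "age"):
        if col not in df.columns:
            raise ValueError(f"sample sheet missing required column {col!r}")
    df["age"] = pd.to_numeric(df["age"], errors="raise")
    if not np.isfinite(df["age"]).all() or (df["age"] < 0).any():
        raise ValueError("ages must be finite and nonnegative")
    if "tissue" not in df.columns:
        df["tissue"] = "blood"
    for col, vocab in (("sex", SEX_VALUES), ("neutered", NEUTERED_VALUES)):
        if col not in df.columns:
            df[col] = "unknown"
        df[col] = df[col].astype(str).str.lower()
        unknown = set(df[col]) - set(vocab)
        if unknown:
            raise ValueError(f"invalid {col} value(s): {sorted(unknown)}; allowed {vocab}")
    return df[["species", "tissue", "age", "sex", "neutered"]
              + [c for c in df.columns if c not in ("species", "tissue", "age", "sex", "neutered")]]


def read_sample_sheet(path, sep=None) -> pd.DataFrame:
    return validate_sample_sheet(_read_table(path, sep=sep))


def write_sample_sheet(sheet: pd.DataFrame, path, sep="\t") -> None:
    out = sheet.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# species parameters
# ---------------------------------------------------------------------------

def read_species_params(path, sep=None) -> dict:
    df = _read_table(path, sep=sep)
    params = {}
    for species, row in df.iterrows():
        params[str(species)] = SpeciesParams(
            max_lifespan=float(row["max_lifespan"]),
            maturity=float(row["maturity"]),
            offset=float(row.get("offset", 0.0)),
        )
    return params


def write_species_params(params: dict, path, sep="\t") -> None:
    rows = [
        {"species": sp, "max_lifespan": p.max_lifespan, "maturity": p.maturity,
         "offset": p.offset}
        for sp, p in params.items()
    ]
    pd.DataFrame(rows).set_index("species").to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# probe annotation
# ---------------------------------------------------------------------------

def validate_probe_annotation(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df.index = df.index.astype(str)
    if "region" not in df.columns or "island" not in df.columns:
        raise ValueError("probe annotation needs 'region' and 'island' columns")
    bad = set(df["region"]) - set(REGION_CLASSES)
    if bad:
        raise ValueError(f"unknown region class(es): {sorted(bad)}; allowed {REGION_CLASSES}")
    if df["island"].isna().any():
        raise ValueError("island flag must be defined for every probe")
    df["island"] = df["island"].astype(bool)
    return df


def read_probe_annotation(path, sep=None) -> pd.DataFrame:
    df = _read_table(path, sep=sep)
    if df["island"].dtype == object:
        df["island"] = df["island"].astype(str).str.lower().map(
            {"true": True, "false": False, "1": True, "0": False})
    return validate_probe_annotation(df)


def write_probe_annotation(annotation: pd.DataFrame, path, sep="\t") -> None:
    out = annotation.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# clock files
# ---------------------------------------------------------------------------

def write_clock(model: ClockModel, path) -> None:
    """Serialize a clock: a ``#key: value`` metadata header then
    tab-separated (probe, coefficient) records.  ``repr`` keeps the
    decimal round trip bit exact."""
    buf = _io.StringIO()
    buf.write(CLOCK_MAGIC + "\n")
    buf.write(f"#target: {model.target}\n")
    buf.write(f"#alpha: {float(model.alpha)!r}\n")
    buf.write(f"#penalty: {float(model.penalty)!r}\n")
    buf.write(f"#intercept: {float(model.intercept)!r}\n")
    buf.write(f"#training_species: {','.join(model.training_species)}\n")
    for sp in sorted(model.species_params):
        p = model.species_params[sp]
        buf.write(
            f"#species: {sp}\tmax_lifespan={float(p.max_lifespan)!r}\t"
            f"maturity={float(p.maturity)!r}\toffset={float(p.offset)!r}\n"
        )
    buf.write("probe\tcoefficient\n")
    for probe, coef in zip(model.probes, model.coefficients):
        buf.write(f"{probe}\t{float(coef)!r}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_clock(path) -> ClockModel:
    meta = {}
    species_params = {}
    probes, coefs = [], []
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first != CLOCK_MAGIC:
            raise ValueError(f"not a clock file (bad magic line {first!r})")
        in_header = True
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if in_header and line.startswith("#"):
                key, _, value = line[1:].partition(": ")
                if key == "species":
                    name, *fields = value.split("\t")
                    kv = dict(f.split("=", 1) for f in fields)
                    species_params[name] = SpeciesParams(
                        max_lifespan=float(kv["max_lifespan"]),
                        maturity=float(kv["maturity"]),
                        offset=float(kv.get("offset", "0.0")),
                    )
                else:
                    meta[key] = value
                continue
            if in_header:
                if line != "probe\tcoefficient":
                    raise ValueError(f"malformed clock file: expected record header, got {line!r}")
                in_header = False
                continue
            probe, _, coef = line.partition("\t")
            probes.append(probe)
            coefs.append(float(coef))
    for required in ("target", "alpha", "penalty", "intercept"):
        if required not in meta:
            raise ValueError(f"clock file missing required field {required!r}")
    training = [s for s in meta.get("training_species", "").split(",") if s]
    return ClockModel(
        probes=probes,
        coefficients=np.asarray(coefs, dtype=float),
        intercept=float(meta["intercept"]),
        alpha=float(meta["alpha"]),
        penalty=float(meta["penalty"]),
        target=meta["target"],
        species_params=species_params,
        training_species=training,
    )


# ---------------------------------------------------------------------------
# joining
# ---------------------------------------------------------------------------

def align(matrix: MethylationMatrix, sheet: pd.DataFrame):
    """Inner-join a matrix and a sample sheet on sample id.

    Rows are returned in the matrix's id order restricted to the
    intersection; unmatched ids on either side are reported with a
    warning.  Disjoint id sets are an error.
    """
    sheet = validate_sample_sheet(sheet)
    matrix_ids = pd.Index(matrix.sample_ids)
    common = [sid for sid in matrix_ids if sid in sheet.index]
    if not common:
        raise ValueError("matrix and sample sheet share no sample ids")
    dropped = sorted(set(matrix_ids) ^ set(sheet.index))
    if dropped:
        warnings.warn(f"{len(dropped)} unmatched sample id(s) dropped: {dropped[:10]}")
    return matrix.loc_samples(common), sheet.loc[common]
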