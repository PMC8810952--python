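"""Core containers and tabular IO for methylation-array datasets.

The universal input of every analysis stage is a :class:`MethylationDataset`:
a CpG-by-sample matrix of beta values (methylation fractions in ``[0, 1]``),
per-sample annotations (species, stock, tissue, sex, age), and a probe
manifest locating each CpG in the genome relative to its adjacent gene.

Beta matrices travel as TSV/CSV with CpG ids in the first column and sample
ids in the header; sample sheets as CSV; manifests as TSV; gene sets as GMT.
Missing beta values are carried explicitly as NaN and are never imputed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TISSUES = ("tail", "brain", "liver", "other")
SEXES = ("F", "M")
MATING_SYSTEMS = ("monogamous", "polygamous")
ALTITUDES = ("high", "low")
REGION_CLASSES = ("promoter", "exon", "intron", "upstream", "downstream", "intergenic")

#: Maximum lifespans in years used to convert chronological age to relative
#: age (age / max lifespan).  Values for the five Peromyscus species and
#: human follow the anAge database; the interspecific hybrid is assigned the
#: polionotus parent's lifespan.  User-supplied values always override these.
DEFAULT_MAX_LIFESPANS: dict[str, float] = {
    "Peromyscus californicus": 5.5,
    "Peromyscus eremicus": 7.4,
    "Peromyscus leucopus": 7.9,
    "Peromyscus maniculatus": 8.3,
    "Peromyscus polionotus": 5.5,
    "Peromyscus polionotus x maniculatus": 5.5,
    "Homo sapiens": 122.5,
}

_BETA_TOL = 1e-9


class DataValidationError(ValueError):
    """Raised when an input file or container violates a datamodel invariant."""


@dataclass(frozen=True)
class SampleAnnotation:
    """One array sample: organism, tissue, sex, age and group labels.

    ``max_lifespan_years`` may be None for species outside the bundled
    lifespan table; relative-age analyses then refuse the sample.
    """

    sample_id: str
    species: str
    tissue: str
    sex: str
    age_years: float
    stock: str | None = None
    mating_system: str | None = None
    altitude: str | None = None
    max_lifespan_years: float | None = None

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise DataValidationError(
                f"sample {self.sample_id!r}: tissue {self.tissue!r} not one of {TISSUES}"
            )
        if self.sex not in SEXES:
            raise DataValidationError(
                f"sample {self.sample_id!r}: sex {self.sex!r} not one of {SEXES}"
            )
        if not np.isfinite(self.age_years) or self.age_years < 0:
            raise DataValidationError(
                f"sample {self.sample_id!r}: age_years must be a non-negative number, "
                f"got {self.age_years!r}"
            )
        if self.mating_system is not None and self.mating_system not in MATING_SYSTEMS:
            raise DataValidationError(
                f"sample {self.sample_id!r}: mating_system {self.mating_system!r}"
            )
        if self.altitude is not None and self.altitude not in ALTITUDES:
            raise DataValidationError(
                f"sample {self.sample_id!r}: altitude {self.altitude!r}"
            )
        if self.max_lifespan_years is not None:
            if self.max_lifespan_years <= 0:
                raise DataValidationError(
                    f"sample {self.sample_id!r}: max_lifespan_years must be positive"
                )
            if self.age_years > self.max_lifespan_years:
                raise DataValidationError(
                    f"sample {self.sample_id!r}: age {self.age_years} exceeds "
                    f"max lifespan {self.max_lifespan_years}"
                )

    @property
    def relative_age(self) -> float | None:
        if self.max_lifespan_years is None:
            return None
        return self.age_years / self.max_lifespan_years


@dataclass(frozen=True)
class ProbeRecord:
    """Manifest entry for one CpG probe (1-based genomic position)."""

    cpg_id: str
    chrom: str
    pos: int
    adjacent_gene: str
    region_class: str
    tss_distance: int = 0

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise DataValidationError(f"probe {self.cpg_id!r}: pos must be >= 1")
        if self.region_class not in REGION_CLASSES:
            raise DataValidationError(
                f"probe {self.cpg_id!r}: region_class {self.region_class!r} "
                f"not one of {REGION_CLASSES}"
            )


class BetaMatrix:
    """CpG x sample matrix of methylation beta values.

    Values are floats in ``[0, 1]``; missing entries are NaN.  Row order
    follows ``cpg_ids``, column order ``sample_ids``.
    """

    def __init__(
        self,
        values: np.ndarray,
        cpg_ids: Sequence[str],
        sample_ids: Sequence[str],
        validate: bool = True,
    ) -> None:
        values = np.asarray(values, dtype=float)
        cpg_ids = list(map(str, cpg_ids))
        sample_ids = list(map(str, sample_ids))
        if values.ndim != 2 or values.shape != (len(cpg_ids), len(sample_ids)):
            raise DataValidationError(
                f"beta matrix shape {values.shape} does not match "
                f"{len(cpg_ids)} CpGs x {len(sample_ids)} samples"
            )
        if validate:
            if len(set(cpg_ids)) != len(cpg_ids):
                raise DataValidationError("duplicate cpg_ids in beta matrix")
            if len(set(sample_ids)) != len(sample_ids):
                raise DataValidationError("duplicate sample_ids in beta matrix")
            finite = values[np.isfinite(values)]
            if np.isinf(values).any():
                raise DataValidationError("beta matrix contains infinite values")
            if finite.size and (
                finite.min() < -_BETA_TOL or finite.max() > 1 + _BETA_TOL
            ):
                raise DataValidationError(
                    "beta values outside [0, 1]: "
                    f"range ({finite.min():.6g}, {finite.max():.6g})"
                )
        self.values = values
        self.cpg_ids = cpg_ids
        self.sample_ids = sample_ids

    @property
    def n_cpg(self) -> int:
        return len(self.cpg_ids)

    @property
    def n_sample(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cpg_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, validate: bool = True) -> "BetaMatrix":
        return cls(frame.to_numpy(dtype=float), list(frame.index), list(frame.columns), validate)

    def copy(self) -> "BetaMatrix":
        return BetaMatrix(self.values.copy(), list(self.cpg_ids), list(self.sample_ids), validate=False)

    def subset(
        self, cpg_ids: Sequence[str] | None = None, sample_ids: Sequence[str] | None = None
    ) -> "BetaMatrix":
        """Return a new matrix restricted (and reordered) to the given ids."""
        frame = self.to_frame()
        if cpg_ids is not None:
            frame = frame.loc[list(cpg_ids)]
        if sample_ids is not None:
            frame = frame[list(sample_ids)]
        return BetaMatrix.from_frame(frame, validate=False)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BetaMatrix):
            return NotImplemented
        return (
            self.cpg_ids == other.cpg_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.values, other.values, equal_nan=True)
        )


@dataclass
class MethylationDataset:
    """Aligned beta matrix + sample annotations + probe manifest."""

    beta: BetaMatrix
    samples: list[SampleAnnotation]
    manifest: list[ProbeRecord] = field(default_factory=list)
    unmapped_cpgs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        ann_ids = [s.sample_id for s in self.samples]
        if ann_ids != self.beta.sample_ids:
            raise DataValidationError(
                "sample annotations do not match beta matrix columns (same ids, same order)"
            )
        manifest_ids = {p.cpg_id for p in self.manifest}
        missing = [c for c in self.beta.cpg_ids if c not in manifest_ids]
        if self.manifest and set(missing) - set(self.unmapped_cpgs):
            raise DataValidationError(
                f"{len(missing)} CpGs have no manifest entry and are not flagged unmapped"
            )

    # -- convenience accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.beta.n_sample

    @property
    def n_cpgs(self) -> int:
        return self.beta.n_cpg

    @property
    def sample_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.samples]).set_index("sample_id", drop=False)

    @property
    def manifest_frame(self) -> pd.DataFrame:
        if not self.manifest:
            return pd.DataFrame(
                columns=["cpg_id", "chrom", "pos", "adjacent_gene", "region_class", "tss_distance"]
            ).set_index("cpg_id", drop=False)
        return pd.DataFrame([vars(p) for p in self.manifest]).set_index("cpg_id", drop=False)

    @property
    def ages(self) -> np.ndarray:
        return np.array([s.age_years for s in self.samples], dtype=float)

    def sample_mask(self, **criteria: object) -> np.ndarray:
        """Boolean mask over samples matching annotation field == value pairs."""
        mask = np.ones(self.n_samples, dtype=bool)
        for key, value in criteria.items():
            col = np.array([getattr(s, key) for s in self.samples], dtype=object)
            mask &= col == value
        return mask

    def subset_samples(self, sample_ids: Sequence[str]) -> "MethylationDataset":
        ids = list(sample_ids)
        by_id = {s.sample_id: s for s in self.samples}
        unknown = [i for i in ids if i not in by_id]
        if unknown:
            raise KeyError(f"unknown sample ids: {unknown[:5]}")
        return MethylationDataset(
            beta=self.beta.subset(sample_ids=ids),
            samples=[by_id[i] for i in ids],
            manifest=list(self.manifest),
            unmapped_cpgs=self.unmapped_cpgs,
        )

    def subset_cpgs(self, cpg_ids: Sequence[str]) -> "MethylationDataset":
        keep = set(cpg_ids)
        return MethylationDataset(
            beta=self.beta.subset(cpg_ids=list(cpg_ids)),
            samples=list(self.samples),
            manifest=[p for p in self.manifest if p.cpg_id in keep],
            unmapped_cpgs=tuple(c for c in self.unmapped_cpgs if c in keep),
        )


# -- file IO -------------------------------------------------------------------

def _sep(dialect: str) -> str:
    if dialect not in ("tsv", "csv"):
        raise ValueError(f"dialect must be 'tsv' or 'csv', got {dialect!r}")
    return "\t" if dialect == "tsv" else ","


def load_beta_matrix(path: str | Path, dialect: str = "tsv") -> BetaMatrix:
    """Read a beta matrix; first column CpG ids, header row sample ids.

    Raises :class:`DataValidationError` on duplicate ids, non-numeric cells
    or values outside ``[0, 1]`` (beyond 1e-9 tolerance).  Empty cells and
    ``NA`` become NaN (explicit missingness).
    """
    sep = _sep(dialect)
    with open(path) as handle:  # pandas mangles duplicate headers, so check raw
        header = handle.readline().rstrip("\n").split(sep)[1:]
    if len(set(header)) != len(header):
        raise DataValidationError(f"duplicate sample ids in header of {path}")
    frame = pd.read_csv(path, sep=sep, index_col=0)
    try:
        frame = frame.astype(float)
    except (TypeError, ValueError) as exc:
        raise DataValidationError(f"non-numeric beta value in {path}: {exc}") from exc
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    return BetaMatrix.from_frame(frame)


def write_beta_matrix(beta: BetaMatrix, path: str | Path, dialect: str = "tsv") -> None:
    frame = beta.to_frame()
    frame.index.name = "cpg_id"
    frame.to_csv(path, sep=_sep(dialect), float_format="%.17g")


def load_sample_sheet(
    path: str | Path,
    lifespans: Mapping[str, float] | None = None,
) -> list[SampleAnnotation]:
    """Read a sample sheet CSV into typed annotations.

    Required columns: sample_id, species, tissue, sex, age_years.  Optional:
    stock, mating_system, altitude, max_lifespan_years.  When the lifespan
    column is absent or empty it is filled from the bundled table (user
    ``lifespans`` override it); species not in the table get None with a
    warning.
    """
    frame = pd.read_csv(path)
    required = ["sample_id", "species", "tissue", "sex", "age_years"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise DataValidationError(f"sample sheet {path} missing required columns: {missing}")
    table = dict(DEFAULT_MAX_LIFESPANS)
    if lifespans:
        table.update(lifespans)

    def _opt(row: pd.Series, col: str) -> str | None:
        if col not in row or pd.isna(row[col]):
            return None
        return str(row[col])

    records: list[SampleAnnotation] = []
    for _, row in frame.iterrows():
        species = str(row["species"])
        lifespan = None
        if "max_lifespan_years" in frame.columns and not pd.isna(row["max_lifespan_years"]):
            lifespan = float(row["max_lifespan_years"])
        elif species in table:
            lifespan = table[species]
        else:
            warnings.warn(
                f"species {species!r} has no known maximum lifespan; "
                "relative-age analyses will exclude this sample",
                stacklevel=2,
            )
        records.append(
            SampleAnnotation(
                sample_id=str(row["sample_id"]),
                species=species,
                tissue=str(row["tissue"]),
                sex=str(row["sex"]),
                age_years=float(row["age_years"]),
                stock=_opt(row, "stock"),
                mating_system=_opt(row, "mating_system"),
                altitude=_opt(row, "altitude"),
                max_lifespan_years=lifespan,
            )
        )
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        raise DataValidationError("duplicate sample_id in sample sheet")
    return records


def write_sample_sheet(samples: Iterable[SampleAnnotation], path: str | Path) -> None:
    pd.DataFrame([vars(s) for s in samples]).to_csv(path, index=False)


def load_manifest(path: str | Path) -> list[ProbeRecord]:
    """Read a TSV probe manifest (cpg_id, chrom, pos, adjacent_gene, region_class[, tss_distance])."""
    frame = pd.read_csv(path, sep="\t")
    required = ["cpg_id", "chrom", "pos", "adjacent_gene", "region_class"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise DataValidationError(f"manifest {path} missing columns: {missing}")
    records = [
        ProbeRecord(
            cpg_id=str(row.cpg_id),
            chrom=str(row.chrom),
            pos=int(row.pos),
            adjacent_gene=str(row.adjacent_gene),
            region_class=str(row.region_class),
            tss_distance=int(getattr(row, "tss_distance", 0) or 0),
        )
        for row in frame.itertuples(index=False)
    ]
    ids = [r.cpg_id for r in records]
    if len(set(ids)) != len(ids):
        raise DataValidationError("duplicate cpg_id in manifest")
    return records


def write_manifest(manifest: Iterable[ProbeRecord], path: str | Path) -> None:
    pd.DataFrame([vars(p) for p in manifest]).to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Parse a GMT gene-set file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, set[str]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataValidationError(
                    f"{path}:{lineno}: GMT line needs name, description and >= 1 gene"
                )
            name = parts[0]
            if name in sets:
                raise DataValidationError(f"{path}:{lineno}: duplicate gene set {name!r}")
            sets[name] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as handle:
        for name, genes in sets.items():
            genes = sorted(set(genes))
            handle.write("\t".join([name, name] + genes) + "\n")


# -- alignment -----------------------------------------------------------------

def align_dataset(
    beta: BetaMatrix,
    samples: Sequence[SampleAnnotation],
    manifest: Sequence[ProbeRecord] | None = None,
    keep_unmapped: bool = True,
) -> MethylationDataset:
    """Intersect and order-harmonize beta columns with the sample sheet.

    Samples are restricted to the id intersection; CpGs without a manifest
    entry are either flagged unmapped (``keep_unmapped=True``) or dropped.
    Rows and columns come out in sorted-id order, which makes alignment
    idempotent and invariant to the order of its inputs.  Counts of dropped
    ids are logged.  Inputs are never mutated.
    """
    ann_by_id = {s.sample_id: s for s in samples}
    if len(ann_by_id) != len(samples):
        raise DataValidationError("duplicate sample_id in annotations")
    shared = sorted(set(beta.sample_ids) & set(ann_by_id))
    if not shared:
        raise DataValidationError("no overlap between beta matrix samples and sample sheet")
    dropped_beta = len(beta.sample_ids) - len(shared)
    dropped_sheet = len(samples) - len(shared)

    manifest = list(manifest or [])
    manifest_ids = {p.cpg_id for p in manifest}
    if manifest:
        mapped = [c for c in beta.cpg_ids if c in manifest_ids]
        unmapped = tuple(sorted(set(beta.cpg_ids) - manifest_ids))
    else:
        mapped = list(beta.cpg_ids)
        unmapped = ()
    if keep_unmapped:
        keep_cpgs = sorted(beta.cpg_ids)
    else:
        keep_cpgs = sorted(mapped)
        unmapped = ()
    if not keep_cpgs:
        raise DataValidationError("no CpGs left after manifest restriction")

    logger.info(
        "align_dataset: kept %d samples (dropped %d from beta, %d from sheet); "
        "kept %d CpGs (%d unmapped%s)",
        len(shared), dropped_beta, dropped_sheet, len(keep_cpgs), len(unmapped),
        "" if keep_unmapped else " dropped",
    )
    kept = set(keep_cpgs)
    return MethylationDataset(
        beta=beta.subset(cpg_ids=keep_cpgs, sample_ids=shared),
        samples=[ann_by_id[sid] for sid in shared],
        manifest=[p for p in manifest if p.cpg_id in kept],
        unmapped_cpgs=unmapped,
    )
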