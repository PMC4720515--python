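"""Readers, writers and depth normalization for the formats the pipeline touches.

Expression matrices travel as delimited text (gene ids in the first column,
sample ids in the header) or as MatrixMarket ``.mtx`` with ``genes.txt`` /
``samples.txt`` sidecars.  Sample annotations, gene sets (GMT dialect) and
life tables are plain TSV.  All readers validate rather than coerce: a
malformed file raises :class:`DataError` with a locator (line, gene or sample
name) instead of silently producing a defective object.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class DataError(ValueError):
    """Malformed or inconsistent input data."""


AgeUnit = Literal["days", "weeks", "years"]


@dataclass
class ExpressionMatrix:
    """Gene-by-sample nonnegative expression values.

    ``unit`` distinguishes raw sequencing counts from counts-per-million;
    depth normalization (:func:`cpm_normalize`) is the only transition
    between the two.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # genes x samples
    unit: Literal["raw_count", "cpm"] = "raw_count"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if np.isnan(self.values).any():
            g, s = np.argwhere(np.isnan(self.values))[0]
            raise DataError(
                f"missing value at gene {self.gene_ids[g]!r}, sample {self.sample_ids[s]!r}"
            )
        if (self.values < 0).any():
            g, s = np.argwhere(self.values < 0)[0]
            raise DataError(
                f"negative value {self.values[g, s]} at gene "
                f"{self.gene_ids[g]!r}, sample {self.sample_ids[s]!r}"
            )
        for kind, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise DataError(f"duplicate {kind} id {i!r}")
                seen.add(i)
        if self.unit == "cpm":
            colsums = self.values.sum(axis=0)
            if not np.allclose(colsums, 1e6, rtol=1e-9):
                bad = self.sample_ids[int(np.argmax(np.abs(colsums - 1e6)))]
                raise DataError(f"cpm column {bad!r} does not sum to 1e6")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, unit: str = "raw_count") -> "ExpressionMatrix":
        return cls(
            gene_ids=[str(g) for g in df.index],
            sample_ids=[str(s) for s in df.columns],
            values=df.to_numpy(dtype=float),
            unit=unit,  # type: ignore[arg-type]
        )


@dataclass
class SampleAnnotation:
    sample_id: str
    age: float
    age_unit: AgeUnit = "days"
    treatment: str = "none"
    replicate: int = 1
    dose: float | None = None
    dose_unit: str | None = None

    def __post_init__(self) -> None:
        if self.age < 0:
            raise DataError(f"sample {self.sample_id!r}: negative age {self.age}")


@dataclass
class GeneSet:
    """A named group of genes (one GMT line)."""

    name: str
    gene_ids: list[str]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise DataError(f"gene set {self.name!r} is empty")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DataError(f"gene set {self.name!r} contains duplicate ids")

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class LifeTable:
    """Death-time records for one cohort, one entry per animal."""

    cohort_id: str
    death_days: list[float]
    censored_days: list[float] = field(default_factory=list)
    n_declared: int | None = None  # optional declared cohort size, validated

    def __post_init__(self) -> None:
        self.death_days = [float(d) for d in self.death_days]
        self.censored_days = [float(d) for d in self.censored_days]
        if any(d < 0 for d in self.death_days + self.censored_days):
            raise DataError(f"cohort {self.cohort_id!r}: negative day in life table")
        if self.n_declared is not None and self.n_declared != self.n_total:
            raise DataError(
                f"cohort {self.cohort_id!r}: declared n_total {self.n_declared} "
                f"!= {self.n_total} recorded animals"
            )

    @property
    def n_total(self) -> int:
        return len(self.death_days) + len(self.censored_days)

    def durations(self) -> np.ndarray:
        return np.asarray(self.death_days + self.censored_days, dtype=float)

    def event_observed(self) -> np.ndarray:
        return np.asarray(
            [1] * len(self.death_days) + [0] * len(self.censored_days), dtype=int
        )


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

_SEPS = {"tsv": "\t", "csv": ","}


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".mtx":
        return "mtx"
    if suffix == ".csv":
        return "csv"
    return "tsv"


def read_counts(path: str | Path, format: str | None = None) -> ExpressionMatrix:
    """Read a raw-count matrix from TSV/CSV or MatrixMarket-with-sidecars.

    The delimited dialects expect gene ids in the first column and sample ids
    in the header row.  ``.mtx`` input additionally requires ``genes.txt`` and
    ``samples.txt`` sidecar files (one id per line) next to the matrix.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    fmt = format or _infer_format(path)
    if fmt == "mtx":
        genes_file = path.with_name("genes.txt")
        samples_file = path.with_name("samples.txt")
        for side in (genes_file, samples_file):
            if not side.exists():
                raise DataError(f"mtx sidecar missing: {side}")
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        gene_ids = genes_file.read_text().split()
        sample_ids = samples_file.read_text().split()
        return ExpressionMatrix(gene_ids, sample_ids, np.asarray(mat, dtype=float))
    if fmt not in _SEPS:
        raise DataError(f"unknown counts format {fmt!r}")
    try:
        df = pd.read_csv(path, sep=_SEPS[fmt], index_col=0)
    except pd.errors.ParserError as exc:  # ragged rows: keep pandas' line number
        raise DataError(f"{path}: {exc}") from exc
    if df.isna().any().any():
        raise DataError(f"{path}: missing values in count table")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise DataError(f"{path}: non-numeric entry in count table ({exc})") from exc
    return ExpressionMatrix.from_frame(df.astype(float))


def write_counts(m: ExpressionMatrix, path: str | Path, format: str | None = None) -> None:
    """Write a matrix in the same dialects :func:`read_counts` accepts.

    Delimited output uses Python's shortest round-tripping float repr, so a
    write/read cycle reproduces values bit-identically.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "mtx":
        scipy.io.mmwrite(path, scipy.sparse.csr_matrix(m.values))
        path.with_name("genes.txt").write_text("\n".join(m.gene_ids) + "\n")
        path.with_name("samples.txt").write_text("\n".join(m.sample_ids) + "\n")
        return
    m.to_frame().to_csv(path, sep=_SEPS[fmt])


def cpm_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Normalize raw counts for sequencing depth to counts per million.

    Each value becomes ``1e6 * count / column_sum``; gene length is
    deliberately not corrected for, since drift compares the same gene
    across samples, never different genes within one sample.
    """
    if m.unit != "raw_count":
        raise DataError("cpm_normalize expects a raw_count matrix")
    colsums = m.values.sum(axis=0)
    if (colsums <= 0).any():
        bad = m.sample_ids[int(np.argmin(colsums))]
        raise DataError(f"sample {bad!r} has zero total counts; cannot normalize")
    values = m.values * (1e6 / colsums)
    return ExpressionMatrix(list(m.gene_ids), list(m.sample_ids), values, unit="cpm")


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: per line ``name<TAB>description<TAB>gene1<TAB>...``."""
    path = Path(path)
    sets: list[GeneSet] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise DataError(f"{path}:{lineno}: GMT line needs name, description and >=1 gene")
        name, source, *genes = fields
        genes = [g for g in genes if g]
        unique = list(dict.fromkeys(genes))
        if len(unique) != len(genes):
            warnings.warn(
                f"{path}:{lineno}: gene set {name!r} lists duplicate ids; deduplicated",
                stacklevel=2,
            )
        sets.append(GeneSet(name=name, gene_ids=unique, source=source))
    return sets


def write_gene_sets(sets: Sequence[GeneSet], path: str | Path) -> None:
    lines = [
        "\t".join([gs.name, gs.source or "-", *gs.gene_ids]) for gs in sets
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# sample annotations
# ---------------------------------------------------------------------------

_ANN_REQUIRED = ["sample_id", "age", "age_unit", "treatment", "replicate"]


def read_annotations(path: str | Path) -> list[SampleAnnotation]:
    """Read a sample annotation TSV.

    Required columns: sample_id, age, age_unit, treatment, replicate;
    optional: dose, dose_unit.  Age units must be uniform within one file.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _ANN_REQUIRED if c not in df.columns]
    if missing:
        raise DataError(f"{path}: annotation columns missing: {missing}")
    units = set(df["age_unit"])
    if len(units) > 1:
        raise DataError(f"{path}: mixed age units {sorted(units)} in one annotation file")
    anns = []
    for _, row in df.iterrows():
        anns.append(
            SampleAnnotation(
                sample_id=str(row["sample_id"]),
                age=float(row["age"]),
                age_unit=str(row["age_unit"]),  # type: ignore[arg-type]
                treatment=str(row["treatment"]),
                replicate=int(row["replicate"]),
                dose=float(row["dose"]) if "dose" in df.columns and pd.notna(row.get("dose")) else None,
                dose_unit=str(row["dose_unit"]) if "dose_unit" in df.columns and pd.notna(row.get("dose_unit")) else None,
            )
        )
    ids = [a.sample_id for a in anns]
    if len(set(ids)) != len(ids):
        dup = next(i for i in ids if ids.count(i) > 1)
        raise DataError(f"{path}: duplicate sample_id {dup!r}")
    return anns


def write_annotations(anns: Sequence[SampleAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [a.sample_id for a in anns],
            "age": [a.age for a in anns],
            "age_unit": [a.age_unit for a in anns],
            "treatment": [a.treatment for a in anns],
            "replicate": [a.replicate for a in anns],
            "dose": [a.dose for a in anns],
            "dose_unit": [a.dose_unit for a in anns],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# life tables
# ---------------------------------------------------------------------------


def read_life_table(
    path: str | Path, dialect: Literal["per_animal", "per_day_counts"] = "per_animal"
) -> list[LifeTable]:
    """Read life tables, one :class:`LifeTable` per cohort.

    ``per_animal``: columns cohort, day, status (dead|censored), one row per
    animal.  ``per_day_counts``: columns cohort, day, n_dead, n_censored;
    counts are expanded to per-animal records.
    """
    df = pd.read_csv(path, sep="\t")
    tables: dict[str, LifeTable] = {}
    if dialect == "per_animal":
        for col in ("cohort", "day", "status"):
            if col not in df.columns:
                raise DataError(f"{path}: per_animal life table needs column {col!r}")
        for lineno, row in enumerate(df.itertuples(index=False), start=2):
            day = float(row.day)
            if day < 0:
                raise DataError(f"{path}:{lineno}: negative day {day}")
            lt = tables.setdefault(str(row.cohort), LifeTable(str(row.cohort), []))
            if row.status == "dead":
                lt.death_days.append(day)
            elif row.status == "censored":
                lt.censored_days.append(day)
            else:
                raise DataError(f"{path}:{lineno}: unknown status {row.status!r}")
    elif dialect == "per_day_counts":
        for col in ("cohort", "day", "n_dead", "n_censored"):
            if col not in df.columns:
                raise DataError(f"{path}: per_day_counts life table needs column {col!r}")
        for lineno, row in enumerate(df.itertuples(index=False), start=2):
            day, nd, nc = float(row.day), int(row.n_dead), int(row.n_censored)
            if day < 0 or nd < 0 or nc < 0:
                raise DataError(f"{path}:{lineno}: negative day or count")
            lt = tables.setdefault(str(row.cohort), LifeTable(str(row.cohort), []))
            lt.death_days.extend([day] * nd)
            lt.censored_days.extend([day] * nc)
    else:
        raise DataError(f"unknown life-table dialect {dialect!r}")
    if "n_total" in df.columns:
        declared = {str(c): int(v) for c, v in df.groupby("cohort")["n_total"].first().items()}
        for cohort, lt in tables.items():
            lt.n_declared = declared[cohort]
            if lt.n_declared != lt.n_total:
                raise DataError(
                    f"{path}: cohort {cohort!r} declares n_total {lt.n_declared} "
                    f"but records {lt.n_total} animals"
                )
    return list(tables.values())


def write_life_table(
    tables: Sequence[LifeTable],
    path: str | Path,
    dialect: Literal["per_animal", "per_day_counts"] = "per_animal",
) -> None:
    rows: list[dict] = []
    if dialect == "per_animal":
        for lt in tables:
            rows += [{"cohort": lt.cohort_id, "day": d, "status": "dead"} for d in lt.death_days]
            rows += [{"cohort": lt.cohort_id, "day": d, "status": "censored"} for d in lt.censored_days]
    elif dialect == "per_day_counts":
        for lt in tables:
            days = sorted(set(lt.death_days) | set(lt.censored_days))
            for d in days:
                rows.append(
                    {
                        "cohort": lt.cohort_id,
                        "day": d,
                        "n_dead": lt.death_days.count(d),
                        "n_censored": lt.censored_days.count(d),
                    }
                )
    else:
        raise DataError(f"unknown life-table dialect {dialect!r}")
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
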