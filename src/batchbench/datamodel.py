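"""Core data types and tab-delimited readers/writers.

The toolkit operates on three kinds of flat files, all UTF-8, tab-delimited,
'.' decimal separator, no quoting:

* expression table — header ``protein_id\\t<sample1>\\t...``, one protein per row
  (or transposed, with ``orientation="samples"``);
* sample metadata — header ``sample_id\\tclass\\tbatch``; class labels are the
  two phenotype groups (conventionally ``D`` and ``D*``), batch labels are
  arbitrary strings;
* complex membership — ``complex_id\\tname\\tmembers\\t[truth_label]`` with a
  semicolon-joined member list, the CORUM-style dialect.

Missing values are not permitted: the simulation and evaluation workflows are
complete-data, and the reader errors on empty cells rather than imputing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("batchbench")

CLASS_D = "D"
CLASS_DSTAR = "D*"

__all__ = [
    "ExpressionMatrix",
    "SampleMetadata",
    "ProteinComplex",
    "ComplexSet",
    "GroundTruth",
    "read_expression_table",
    "write_expression_table",
    "read_metadata",
    "write_metadata",
    "read_complexes",
    "write_complexes",
    "read_truth",
    "write_truth",
    "read_dataset",
    "write_dataset",
    "CLASS_D",
    "CLASS_DSTAR",
]


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} id: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """Proteins x samples abundance table (spectral counts or intensities).

    ``values[i, j]`` is the abundance of ``protein_ids[i]`` in
    ``sample_ids[j]``. Values must be finite and non-negative.
    """

    values: np.ndarray
    protein_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.protein_ids = [str(p) for p in self.protein_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        n_prot, n_samp = self.values.shape
        if n_prot != len(self.protein_ids):
            raise ValueError(
                f"{len(self.protein_ids)} protein ids for {n_prot} rows"
            )
        if n_samp != len(self.sample_ids):
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n_samp} columns"
            )
        _check_unique(self.protein_ids, "protein")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at protein {self.protein_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative value at protein {self.protein_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(), list(self.protein_ids), list(self.sample_ids)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.protein_ids, columns=self.sample_ids
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))

    def subset_proteins(self, keep: Sequence[str]) -> "ExpressionMatrix":
        """Row-subset preserving the order of ``keep``."""
        index = {p: i for i, p in enumerate(self.protein_ids)}
        rows = [index[p] for p in keep]
        return ExpressionMatrix(
            self.values[rows, :], list(keep), list(self.sample_ids)
        )

    def subset_samples(self, keep: Sequence[str]) -> "ExpressionMatrix":
        index = {s: j for j, s in enumerate(self.sample_ids)}
        cols = [index[s] for s in keep]
        return ExpressionMatrix(
            self.values[:, cols], list(self.protein_ids), list(keep)
        )


@dataclass
class SampleMetadata:
    """Per-sample class (phenotype) and batch assignment."""

    class_labels: dict[str, str]
    batch_labels: dict[str, str]

    def __post_init__(self) -> None:
        if set(self.class_labels) != set(self.batch_labels):
            missing = set(self.class_labels) ^ set(self.batch_labels)
            raise ValueError(f"class/batch sample sets differ: {sorted(missing)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.class_labels)

    def classes(self) -> list[str]:
        return sorted(set(self.class_labels.values()))

    def batches(self) -> list[str]:
        return sorted(set(self.batch_labels.values()))

    def class_of(self, sample: str) -> str:
        return self.class_labels[sample]

    def batch_of(self, sample: str) -> str:
        return self.batch_labels[sample]

    def samples_in_class(self, cls: str) -> list[str]:
        return [s for s, c in self.class_labels.items() if c == cls]

    def samples_in_batch(self, batch: str) -> list[str]:
        return [s for s, b in self.batch_labels.items() if b == batch]

    def class_vector(self, sample_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.class_labels[s] for s in sample_ids])

    def batch_vector(self, sample_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.batch_labels[s] for s in sample_ids])

    def validate_against(self, x: ExpressionMatrix) -> None:
        """Every matrix sample must carry exactly one class and batch label."""
        for s in x.sample_ids:
            if s not in self.class_labels:
                raise ValueError(f"sample {s!r} missing from metadata")
        counts = pd.Series(
            [self.class_labels[s] for s in x.sample_ids]
        ).value_counts()
        if len(counts) < 1 or counts.min() < 1:
            raise ValueError("at least one sample per class required")


@dataclass
class ProteinComplex:
    complex_id: str
    name: str
    members: list[str]
    truth_label: str = "unknown"  # "TP" | "TN" | "unknown"

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError(
                f"complex {self.complex_id!r} has {len(self.members)} member(s); "
                "complexes need >= 2"
            )
        if self.truth_label not in ("TP", "TN", "unknown"):
            raise ValueError(f"bad truth label {self.truth_label!r}")


@dataclass
class ComplexSet:
    """A named collection of protein complexes, optionally with TP/TN labels."""

    complexes: list[ProteinComplex] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_unique([c.complex_id for c in self.complexes], "complex")

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self):
        return iter(self.complexes)

    def ids(self) -> list[str]:
        return [c.complex_id for c in self.complexes]

    def get(self, complex_id: str) -> ProteinComplex:
        for c in self.complexes:
            if c.complex_id == complex_id:
                return c
        raise KeyError(complex_id)

    def member_union(self, ids: Iterable[str] | None = None) -> set[str]:
        wanted = set(ids) if ids is not None else None
        out: set[str] = set()
        for c in self.complexes:
            if wanted is None or c.complex_id in wanted:
                out.update(c.members)
        return out

    def labelled(self, label: str) -> "ComplexSet":
        return ComplexSet([c for c in self.complexes if c.truth_label == label])


@dataclass
class GroundTruth:
    """Proteins carrying inserted class effects, with multiplicative effect sizes.

    ``effect_sizes[p]`` is the multiplier applied to class-D* values of
    protein ``p`` (e.g. a +100% effect is stored as 2.0).
    """

    effect_sizes: dict[str, float]

    def __post_init__(self) -> None:
        for p, m in self.effect_sizes.items():
            if not m > 0:
                raise ValueError(f"non-positive effect size {m} for {p!r}")

    @property
    def differential_proteins(self) -> set[str]:
        return set(self.effect_sizes)

    def __len__(self) -> int:
        return len(self.effect_sizes)

    def validate_against(self, x: ExpressionMatrix) -> None:
        extra = self.differential_proteins - set(x.protein_ids)
        if extra:
            raise ValueError(
                f"ground-truth proteins absent from matrix: {sorted(extra)[:5]}"
            )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _scan_table(path: Path) -> list[list[str]]:
    """Split a TSV into fields, rejecting ragged rows with a line number."""
    rows: list[list[str]] = []
    width: int | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if width is None:
                width = len(fields)
            elif len(fields) != width:
                raise ValueError(
                    f"{path}: ragged row at line {lineno} "
                    f"({len(fields)} fields, expected {width})"
                )
            rows.append(fields)
    if not rows:
        raise ValueError(f"{path}: empty file")
    return rows


def read_expression_table(
    path: str | Path, orientation: str = "proteins"
) -> ExpressionMatrix:
    """Read a tab-delimited expression table.

    Parameters
    ----------
    path
        TSV with a header row of sample ids and a first column of protein ids
        (``orientation="proteins"``, the proteomics convention), or the
        transpose (``orientation="samples"``).
    """
    if orientation not in ("proteins", "samples"):
        raise ValueError(f"orientation must be 'proteins' or 'samples', got {orientation!r}")
    path = Path(path)
    rows = _scan_table(path)
    header = rows[0][1:]
    row_ids = [r[0] for r in rows[1:]]
    try:
        values = np.array(
            [[_parse_cell(path, i + 2, cell) for cell in r[1:]] for i, r in enumerate(rows[1:])],
            dtype=float,
        )
    except ValueError:
        raise
    if orientation == "samples":
        values = values.T
        row_ids, header = header, row_ids
    return ExpressionMatrix(values, row_ids, header)


def _parse_cell(path: Path, lineno: int, cell: str) -> float:
    if cell.strip() == "":
        raise ValueError(f"{path}: empty cell at line {lineno}; missing values are not supported")
    try:
        return float(cell)
    except ValueError:
        raise ValueError(f"{path}: non-numeric cell {cell!r} at line {lineno}") from None


def write_expression_table(x: ExpressionMatrix, path: str | Path) -> None:
    df = x.to_frame()
    # integer counts stay integers on disk so round-trips are bitwise exact
    if np.all(df.to_numpy() == np.round(df.to_numpy())):
        df = df.astype(np.int64)
    df.to_csv(path, sep="\t", index_label="protein_id", float_format="%.17g")


def read_metadata(path: str | Path) -> SampleMetadata:
    path = Path(path)
    rows = _scan_table(path)
    if [c.lower() for c in rows[0][:3]] != ["sample_id", "class", "batch"]:
        raise ValueError(f"{path}: expected header 'sample_id\\tclass\\tbatch'")
    cls: dict[str, str] = {}
    batch: dict[str, str] = {}
    for lineno, r in enumerate(rows[1:], start=2):
        sid, c, b = r[0], r[1], r[2]
        if sid in cls:
            raise ValueError(f"{path}: duplicate sample id {sid!r} at line {lineno}")
        cls[sid] = c
        batch[sid] = b
    return SampleMetadata(cls, batch)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tclass\tbatch\n")
        for s in meta.sample_ids:
            fh.write(f"{s}\t{meta.class_labels[s]}\t{meta.batch_labels[s]}\n")


def read_complexes(path: str | Path) -> ComplexSet:
    """Read a CORUM-style complex membership TSV.

    One complex per line: id, name, semicolon-joined members and an optional
    TP/TN truth label. Singleton complexes are dropped with a warning rather
    than rejected, since real catalogues contain them.
    """
    path = Path(path)
    out: list[ProteinComplex] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line or line.startswith("complex_id\t"):
                continue
            fields = line.split("\t")
            if len(fields) not in (3, 4):
                raise ValueError(
                    f"{path}: malformed line {lineno}: expected 3 or 4 fields, got {len(fields)}"
                )
            cid, name, member_str = fields[0], fields[1], fields[2]
            truth = fields[3] if len(fields) == 4 else "unknown"
            members = [m for m in member_str.split(";") if m.strip()]
            if not members:
                raise ValueError(f"{path}: empty member list at line {lineno}")
            if len(members) == 1:
                logger.warning(
                    "dropping singleton complex %r (line %d of %s)", cid, lineno, path
                )
                continue
            out.append(ProteinComplex(cid, name, members, truth))
    return ComplexSet(out)


def write_complexes(cs: ComplexSet, path: str | Path) -> None:
    has_truth = any(c.truth_label != "unknown" for c in cs)
    with open(path, "w", encoding="utf-8") as fh:
        header = "complex_id\tname\tmembers"
        if has_truth:
            header += "\ttruth_label"
        fh.write(header + "\n")
        for c in cs:
            line = f"{c.complex_id}\t{c.name}\t{';'.join(c.members)}"
            if has_truth:
                line += f"\t{c.truth_label}"
            fh.write(line + "\n")


def read_truth(path: str | Path) -> GroundTruth:
    path = Path(path)
    rows = _scan_table(path)
    if [c.lower() for c in rows[0][:2]] != ["protein_id", "effect_size"]:
        raise ValueError(f"{path}: expected header 'protein_id\\teffect_size'")
    sizes: dict[str, float] = {}
    for lineno, r in enumerate(rows[1:], start=2):
        if r[0] in sizes:
            raise ValueError(f"{path}: duplicate protein id {r[0]!r} at line {lineno}")
        sizes[r[0]] = _parse_cell(path, lineno, r[1])
    return GroundTruth(sizes)


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein_id\teffect_size\n")
        for p, m in truth.effect_sizes.items():
            fh.write(f"{p}\t{m:.17g}\n")


def write_dataset(
    matrix: ExpressionMatrix,
    meta: SampleMetadata,
    truth: GroundTruth | None,
    directory: str | Path,
    prefix: str = "dataset",
) -> None:
    """Write expression + metadata (+ truth) as readable TSVs in ``directory``."""
    for s in matrix.sample_ids:
        if s not in meta.class_labels:
            raise ValueError(f"sample {s!r} in matrix but missing from metadata")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_expression_table(matrix, directory / f"{prefix}.expression.tsv")
    write_metadata(meta, directory / f"{prefix}.metadata.tsv")
    if truth is not None:
        truth.validate_against(matrix)
        write_truth(truth, directory / f"{prefix}.truth.tsv")


def read_dataset(
    directory: str | Path, prefix: str = "dataset"
) -> tuple[ExpressionMatrix, SampleMetadata, GroundTruth | None]:
    directory = Path(directory)
    x = read_expression_table(directory / f"{prefix}.expression.tsv")
    meta = read_metadata(directory / f"{prefix}.metadata.tsv")
    truth_path = directory / f"{prefix}.truth.tsv"
    truth = read_truth(truth_path) if truth_path.exists() else None
    return x, meta, truth
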