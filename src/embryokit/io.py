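"""Readers and writers for the external formats the pipeline touches.

Containers
----------
``CountMatrix``
    Sparse cells × genes integer counts with cell/gene identifiers
    (10x-style MatrixMarket triplet + barcodes/features text files).
``MethCallSet``
    Per-cell cytosine-level methylation (CpG) or accessibility (GpC)
    calls in the Bismark coverage dialect.
``FeatureSet``
    Named genomic intervals grouped into classes (promoters, lineage
    enhancer sets), read from BED.

Coordinate conventions are normalised exactly once, here: BED intervals
are 0-based half-open; methylation call positions are 1-based (Bismark
dialect). Downstream code receives both unchanged and the containment
rule ``start < pos <= end`` bridges them.
"""

from __future__ import annotations

import gzip
import io as _io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "MethCallSet",
    "FeatureSet",
    "FormatError",
    "read_counts",
    "write_counts",
    "read_meth_calls",
    "write_meth_calls",
    "read_bed",
    "write_bed",
    "read_annotation",
    "write_annotation",
]

GENOTYPES = ("WT", "Dnmt1KO", "Dnmt3aKO", "Dnmt3bKO", "TetTKO", "other")
PLATFORMS = ("droplet", "plate")
CONTEXTS = ("CpG", "GpC")

#: columns every cell-annotation table must carry
ANNOTATION_COLUMNS = [
    "cell_id",
    "embryo_id",
    "genotype",
    "stage_label",
    "platform",
    "cell_type",
    "host_flag",
]


class FormatError(ValueError):
    """A file violates its format contract (dimensions, coordinates, ...)."""


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


@dataclass
class CountMatrix:
    """Sparse non-negative integer count matrix, cells × genes."""

    values: sp.csr_matrix
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    gene_names: np.ndarray | None = None

    def __post_init__(self):
        self.values = sp.csr_matrix(self.values)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.gene_names is None:
            self.gene_names = self.gene_ids.copy()
        self.gene_names = np.asarray(self.gene_names, dtype=object)
        n_cells, n_genes = self.values.shape
        if len(self.cell_ids) != n_cells:
            raise FormatError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix rows"
            )
        if len(self.gene_ids) != n_genes:
            raise FormatError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix columns"
            )
        if len(self.gene_names) != n_genes:
            raise FormatError("gene_names not aligned to gene_ids")
        if len(set(self.cell_ids)) != n_cells:
            raise FormatError("duplicate cell ids")
        if len(set(self.gene_ids)) != n_genes:
            raise FormatError("duplicate gene ids")
        data = self.values.data
        if data.size:
            if np.any(data < 0):
                raise FormatError("negative count entry")
            if not np.allclose(data, np.round(data)):
                raise FormatError("non-integer count entry")
        self.values = self.values.astype(np.int64)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def total_counts(self) -> np.ndarray:
        """Per-cell total counts (UMIs or reads)."""
        return np.asarray(self.values.sum(axis=1)).ravel()

    def subset_cells(self, mask_or_ids) -> "CountMatrix":
        idx = self._cell_index(mask_or_ids)
        return CountMatrix(
            self.values[idx], self.cell_ids[idx], self.gene_ids, self.gene_names
        )

    def subset_genes(self, mask_or_ids) -> "CountMatrix":
        idx = self._gene_index(mask_or_ids)
        return CountMatrix(
            self.values[:, idx], self.cell_ids, self.gene_ids[idx], self.gene_names[idx]
        )

    def _cell_index(self, mask_or_ids):
        arr = np.asarray(mask_or_ids)
        if arr.dtype == bool:
            return np.flatnonzero(arr)
        if np.issubdtype(arr.dtype, np.integer):
            return arr
        lookup = {c: i for i, c in enumerate(self.cell_ids)}
        return np.array([lookup[c] for c in arr], dtype=int)

    def _gene_index(self, mask_or_ids):
        arr = np.asarray(mask_or_ids)
        if arr.dtype == bool:
            return np.flatnonzero(arr)
        if np.issubdtype(arr.dtype, np.integer):
            return arr
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in arr], dtype=int)


@dataclass
class MethCallSet:
    """Per-cell methylation/accessibility calls for one context.

    ``records`` has columns ``chrom, pos, meth, unmeth`` with 1-based
    positions, sorted by (chrom, pos) and unique per (chrom, pos).
    """

    context: str
    cell_id: str
    records: pd.DataFrame

    def __post_init__(self):
        if self.context not in CONTEXTS:
            raise ValueError(f"context must be one of {CONTEXTS}, got {self.context!r}")
        df = pd.DataFrame(self.records, columns=["chrom", "pos", "meth", "unmeth"])
        df["chrom"] = df["chrom"].astype(str)
        for c in ("pos", "meth", "unmeth"):
            df[c] = df[c].astype(np.int64)
        if len(df):
            if (df["meth"] < 0).any() or (df["unmeth"] < 0).any():
                raise ValueError("negative read count")
            if ((df["meth"] + df["unmeth"]) < 1).any():
                raise ValueError("record with zero total reads")
            if df.duplicated(["chrom", "pos"]).any():
                raise ValueError("duplicate positions within a cell/chrom")
        df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        self.records = df

    @property
    def n_sites(self) -> int:
        return len(self.records)

    def site_rates(self) -> np.ndarray:
        """Fractional per-site rates meth / (meth + unmeth)."""
        r = self.records
        return (r["meth"] / (r["meth"] + r["unmeth"])).to_numpy(float)

    def binary_rates(self) -> np.ndarray:
        """Per-site binarized rates: 1 when rate >= 0.5, else 0."""
        return (self.site_rates() >= 0.5).astype(float)


@dataclass
class FeatureSet:
    """Genomic intervals grouped into classes.

    ``intervals`` has columns ``chrom, start, end, name, class_label``
    with 0-based half-open coordinates.
    """

    intervals: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["chrom", "start", "end", "name", "class_label"]
        )
    )

    def __post_init__(self):
        df = pd.DataFrame(
            self.intervals, columns=["chrom", "start", "end", "name", "class_label"]
        )
        df["chrom"] = df["chrom"].astype(str)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["name"] = df["name"].astype(str)
        df["class_label"] = df["class_label"].astype(str)
        if len(df):
            bad = df["start"] >= df["end"]
            if bad.any():
                i = int(np.flatnonzero(bad.to_numpy())[0])
                raise FormatError(f"interval with start >= end at row {i}")
            if df.duplicated(["class_label", "name"]).any():
                raise FormatError("duplicate feature name within a class")
        self.intervals = df.reset_index(drop=True)

    @property
    def classes(self) -> list[str]:
        return sorted(self.intervals["class_label"].unique())

    def of_class(self, class_label: str) -> "FeatureSet":
        sub = self.intervals[self.intervals["class_label"] == class_label]
        return FeatureSet(sub.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.intervals)


# ---------------------------------------------------------------------------
# count matrices (MatrixMarket + barcodes/features)
# ---------------------------------------------------------------------------

def read_counts(matrix_path, barcodes_path, features_path) -> CountMatrix:
    """Read a 10x-style triplet count matrix.

    The MatrixMarket file stores genes × cells (10x convention); it is
    transposed on read so the container is cells × genes. Barcode and
    feature files are one entry per line; the feature file may carry a
    second tab-separated column of gene names.
    """
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except Exception as exc:  # pragma: no cover - scipy message passthrough
        raise FormatError(f"cannot parse MatrixMarket file: {exc}") from exc
    mat = sp.csr_matrix(mat).T.tocsr()  # -> cells x genes
    with _open_text(barcodes_path) as fh:
        barcodes = [line.strip().split("\t")[0] for line in fh if line.strip()]
    gene_ids, gene_names = [], []
    with _open_text(features_path) as fh:
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            gene_ids.append(parts[0])
            gene_names.append(parts[1] if len(parts) > 1 else parts[0])
    if len(barcodes) != mat.shape[0]:
        raise FormatError(
            f"barcode file has {len(barcodes)} entries but matrix header "
            f"declares {mat.shape[0]} cells"
        )
    if len(gene_ids) != mat.shape[1]:
        raise FormatError(
            f"feature file has {len(gene_ids)} entries but matrix header "
            f"declares {mat.shape[1]} genes"
        )
    return CountMatrix(mat, np.array(barcodes, dtype=object), gene_ids, gene_names)


def write_counts(cm: CountMatrix, matrix_path, barcodes_path, features_path) -> None:
    """Write the 10x-style triplet (genes × cells MTX + text lists)."""
    scipy.io.mmwrite(str(matrix_path), cm.values.T.tocoo(), field="integer")
    with open(barcodes_path, "w") as fh:
        fh.write("\n".join(map(str, cm.cell_ids)) + "\n")
    with open(features_path, "w") as fh:
        for gid, gname in zip(cm.gene_ids, cm.gene_names):
            fh.write(f"{gid}\t{gname}\n")


# ---------------------------------------------------------------------------
# methylation calls (Bismark-coverage-style TSV)
# ---------------------------------------------------------------------------

def read_meth_calls(
    path, context: str, cell_id: str | None = None, collapse_strands: bool = False
) -> MethCallSet:
    """Read per-site methylation calls for one cell.

    Expected columns: chrom, start, end, meth_reads, unmeth_reads
    (tab-separated; an optional interleaved percentage column, as in
    6-column Bismark ``.cov`` files, is detected and dropped). A header
    line is auto-detected and skipped. Positions are 1-based and taken
    from the start column.

    Duplicate positions are merged by summing counts. Rows with zero
    total reads are dropped with a warning. With ``collapse_strands``,
    calls at adjacent positions p, p+1 (the two strands of a symmetric
    CpG) are merged onto p.
    """
    if context not in CONTEXTS:
        raise ValueError(f"context must be one of {CONTEXTS}")
    if cell_id is None:
        cell_id = Path(path).name.split(".")[0]
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                parts = line.split()
            if len(parts) < 5:
                raise FormatError(f"line {lineno}: expected >=5 columns")
            try:
                start = int(parts[1])
            except ValueError:
                if lineno == 1:
                    continue  # header line
                raise FormatError(f"line {lineno}: non-integer coordinate")
            if len(parts) >= 6:
                # 6-column Bismark .cov: chrom start end pct meth unmeth
                meth, unmeth = int(parts[4]), int(parts[5])
            else:
                meth, unmeth = int(parts[3]), int(parts[4])
            if meth < 0 or unmeth < 0:
                raise FormatError(f"line {lineno}: negative read count")
            if meth + unmeth == 0:
                warnings.warn(
                    f"{path}: line {lineno} has zero total reads; dropped",
                    stacklevel=2,
                )
                continue
            rows.append((str(parts[0]), start, meth, unmeth))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "meth", "unmeth"])
    if len(df):
        df = df.groupby(["chrom", "pos"], as_index=False, sort=True)[
            ["meth", "unmeth"]
        ].sum()
        if collapse_strands:
            df = _collapse_strand_pairs(df)
    return MethCallSet(context=context, cell_id=cell_id, records=df)


def _collapse_strand_pairs(df: pd.DataFrame) -> pd.DataFrame:
    """Merge calls at adjacent positions p, p+1 onto p (symmetric CpGs)."""
    out = []
    for chrom, sub in df.groupby("chrom", sort=True):
        sub = sub.sort_values("pos").reset_index(drop=True)
        pos = sub["pos"].to_numpy()
        meth = sub["meth"].to_numpy().copy()
        unmeth = sub["unmeth"].to_numpy().copy()
        keep = np.ones(len(sub), dtype=bool)
        i = 0
        while i < len(sub) - 1:
            if pos[i + 1] == pos[i] + 1:
                meth[i] += meth[i + 1]
                unmeth[i] += unmeth[i + 1]
                keep[i + 1] = False
                i += 2
            else:
                i += 1
        sub = pd.DataFrame(
            {"chrom": chrom, "pos": pos[keep], "meth": meth[keep], "unmeth": unmeth[keep]}
        )
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def write_meth_calls(calls: MethCallSet, path) -> None:
    """Write the 5-column dialect: chrom, start, end, meth, unmeth."""
    df = calls.records
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["pos"],
            "end": df["pos"],
            "meth": df["meth"],
            "unmeth": df["unmeth"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# BED features
# ---------------------------------------------------------------------------

def read_bed(path, class_label: str | None = None) -> FeatureSet:
    """Read BED3/BED4 intervals (0-based half-open, preserved exactly).

    ``class_label`` defaults to the file stem. track/browser/# header
    lines are skipped. Unnamed intervals get ``<class>_<lineno>`` names.
    """
    if class_label is None:
        class_label = Path(path).name.split(".")[0]
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if (
                not line
                or line.startswith("#")
                or line.startswith("track")
                or line.startswith("browser")
            ):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                parts = line.split()
            if len(parts) < 3:
                raise FormatError(f"line {lineno}: expected >=3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise FormatError(f"line {lineno}: malformed coordinate")
            if start >= end:
                raise FormatError(f"line {lineno}: start >= end ({start} >= {end})")
            name = parts[3] if len(parts) > 3 else f"{class_label}_{lineno}"
            rows.append((parts[0], start, end, name, class_label))
    return FeatureSet(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "class_label"])
    )


def write_bed(features: FeatureSet, path) -> None:
    features.intervals[["chrom", "start", "end", "name"]].to_csv(
        path, sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# cell annotation tables
# ---------------------------------------------------------------------------

def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    """Check an annotation table's required columns and vocabularies."""
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise FormatError(f"annotation missing columns: {missing}")
    if ann["cell_id"].duplicated().any():
        raise FormatError("duplicate cell_id in annotation")
    bad = set(ann["genotype"].dropna()) - set(GENOTYPES)
    if bad:
        raise FormatError(f"unknown genotype values: {sorted(bad)}")
    bad = set(ann["platform"].dropna()) - set(PLATFORMS)
    if bad:
        raise FormatError(f"unknown platform values: {sorted(bad)}")
    return ann


def read_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "embryo_id": str})
    if "host_flag" in ann.columns:
        ann["host_flag"] = ann["host_flag"].astype(bool)
    return validate_annotation(ann)


def write_annotation(ann: pd.DataFrame, path) -> None:
    validate_annotation(ann).to_csv(path, sep="\t", index=False)
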