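"""Readers and writers for the plain-text and standard formats the pipeline touches.

Coordinates are 1-based inclusive throughout the public interface; conversion to
half-open intervals is internal to overlap arithmetic. Gene identifiers are opaque
strings (no alias resolution).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

READ_TSV_COLUMNS = ("cell_barcode", "umi", "ref_start", "ref_end", "sequence")


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read with cell barcode, UMI, aligned interval and sequence."""

    cell_barcode: str
    umi: str
    ref_start: int  # 1-based inclusive
    ref_end: int  # 1-based inclusive
    sequence: str

    def __post_init__(self) -> None:
        if not self.cell_barcode or not self.umi:
            raise ValueError("cell_barcode and umi must be non-empty")
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        if self.ref_start > self.ref_end:
            raise ValueError(
                f"ref_start ({self.ref_start}) > ref_end ({self.ref_end})"
            )


@dataclass
class CountMatrix:
    """Genes x cells UMI counts with per-cell metadata.

    ``values`` is a sparse CSR matrix of shape (n_genes, n_cells);
    ``cell_meta`` is indexed by ``cell_ids`` and may carry 'cluster',
    'sample' and 'timepoint' columns.
    """

    values: sp.csr_matrix
    gene_ids: list[str]
    cell_ids: list[str]
    cell_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if self.cell_meta.empty:
            self.cell_meta = pd.DataFrame(index=pd.Index(self.cell_ids, name="cell"))
        elif not self.cell_meta.index.equals(pd.Index(self.cell_ids)):
            raise ValueError("cell_meta index must equal cell_ids")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in matrix") from None


# ---------------------------------------------------------------------------
# reads


def read_reads(path: str | Path, format: str = "tsv") -> tuple[list[ReadRecord], int]:
    """Read barcoded reads; return (records in file order, n skipped).

    Reads missing a barcode or UMI are counted and skipped. ``format`` is
    'tsv' for the plain-text dialect or 'sam' for SAM/BAM with CB/UB tags.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        return _read_reads_tsv(path)
    if format in ("sam", "bam"):
        return _read_reads_sam(path)
    raise ValueError(f"unknown read format {format!r}")


def _read_reads_tsv(path: Path) -> tuple[list[ReadRecord], int]:
    records: list[ReadRecord] = []
    skipped = 0
    with open(path) as fh:
        header = fh.readline()
        if not header:
            return records, 0
        cols = header.rstrip("\n").split("\t")
        if tuple(cols) != READ_TSV_COLUMNS:
            raise ValueError(
                f"{path}:1: expected header {list(READ_TSV_COLUMNS)}, got {cols}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 fields, got {len(parts)}")
            bc, umi, start, end, seq = parts
            if not bc or not umi:
                skipped += 1
                continue
            try:
                records.append(ReadRecord(bc, umi, int(start), int(end), seq))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return records, skipped


def _read_reads_sam(path: Path) -> tuple[list[ReadRecord], int]:
    import pysam

    records: list[ReadRecord] = []
    skipped = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh.fetch(until_eof=True):
            if aln.is_unmapped or aln.query_sequence is None:
                skipped += 1
                continue
            try:
                bc = aln.get_tag("CB")
                umi = aln.get_tag("UB")
            except KeyError:
                skipped += 1
                continue
            # pysam: reference_start is 0-based, reference_end half-open
            records.append(
                ReadRecord(
                    cell_barcode=str(bc),
                    umi=str(umi),
                    ref_start=aln.reference_start + 1,
                    ref_end=aln.reference_end,
                    sequence=aln.query_sequence,
                )
            )
    return records, skipped


def write_reads_tsv(records: list[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(READ_TSV_COLUMNS) + "\n")
        for r in records:
            fh.write(f"{r.cell_barcode}\t{r.umi}\t{r.ref_start}\t{r.ref_end}\t{r.sequence}\n")


def write_reads_sam(
    records: list[ReadRecord],
    path: str | Path,
    reference_name: str = "chr5",
    reference_length: int = 181_538_259,
) -> None:
    """Write reads as a SAM file with CB/UB tags and ungapped alignments."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": reference_name, "LN": reference_length}],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for i, r in enumerate(records):
            a = pysam.AlignedSegment(fh.header)
            a.query_name = f"read{i}"
            a.query_sequence = r.sequence
            a.reference_id = 0
            a.reference_start = r.ref_start - 1
            a.mapping_quality = 255
            # the synthetic interval may differ from len(sequence) around the
            # insertion; pad with soft clips so the CIGAR is consistent
            span = r.ref_end - r.ref_start + 1
            if span <= len(r.sequence):
                cigar = [(0, span)]
                extra = len(r.sequence) - span
                if extra:
                    cigar.append((4, extra))
            else:
                cigar = [(0, len(r.sequence))]
            a.cigartuples = cigar
            a.set_tag("CB", r.cell_barcode)
            a.set_tag("UB", r.umi)
            fh.write(a)


# ---------------------------------------------------------------------------
# count matrices (MatrixMarket triplet + sidecars)


def read_mtx(directory: str | Path) -> CountMatrix:
    directory = Path(directory)
    mat = sp.csr_matrix(scipy.io.mmread(directory / "matrix.mtx"))
    genes = (directory / "features.tsv").read_text().splitlines()
    barcodes = (directory / "barcodes.tsv").read_text().splitlines()
    if mat.shape != (len(genes), len(barcodes)):
        raise ValueError(
            f"matrix header {mat.shape} does not match sidecars "
            f"({len(genes)} features, {len(barcodes)} barcodes)"
        )
    meta_path = directory / "cell_meta.tsv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t", index_col=0, dtype={0: str})
        meta.index = meta.index.astype(str)
        meta = meta.loc[barcodes]
    else:
        meta = pd.DataFrame(index=pd.Index(barcodes, name="cell"))
    mat.eliminate_zeros()
    return CountMatrix(mat, genes, barcodes, meta)


def write_mtx(matrix: CountMatrix, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    values = sp.coo_matrix(matrix.values)
    values.eliminate_zeros()
    scipy.io.mmwrite(str(directory / "matrix.mtx"), values)
    (directory / "features.tsv").write_text("\n".join(matrix.gene_ids) + "\n")
    (directory / "barcodes.tsv").write_text("\n".join(matrix.cell_ids) + "\n")
    if len(matrix.cell_meta.columns):
        matrix.cell_meta.to_csv(directory / "cell_meta.tsv", sep="\t")


# ---------------------------------------------------------------------------
# gene lists, survival and expression tables


def read_gene_list(path: str | Path) -> list[str]:
    """Ordered unique gene ids; duplicates dropped (first kept) with a warning."""
    seen: dict[str, None] = {}
    dups = 0
    for line in Path(path).read_text().splitlines():
        gene = line.strip()
        if not gene:
            continue
        if gene in seen:
            dups += 1
        else:
            seen[gene] = None
    if dups:
        warnings.warn(f"{path}: dropped {dups} duplicate gene id(s)")
    return list(seen)


def write_gene_list(genes: list[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(genes) + "\n")


def read_survival(path: str | Path) -> pd.DataFrame:
    """Survival table with columns time (>= 0) and event (0/1), indexed by patient."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in ("time", "event"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if (df["time"] < 0).any():
        raise ValueError(f"{path}: negative survival time")
    if not df["event"].isin([0, 1]).all():
        raise ValueError(f"{path}: event column must be 0/1")
    df["event"] = df["event"].astype(int)
    return df


def write_survival(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def read_expression(path: str | Path) -> pd.DataFrame:
    """Patients x genes expression table (TSV, patients as rows)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")
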