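"""Readers and writers for the tabular formats the pipeline consumes.

Supported formats:

* SEG — tab-delimited copy-number segments (sample, chromosome, start, end,
  number of probes, segment mean as log2 copy-ratio), the cBioPortal/GISTIC
  dialect with 1-based closed intervals.
* GCT v1.2 — gene x sample expression matrices.
* GMT — gene-set collections, one set per line.
* CLS — categorical phenotype label files as used by GSEA.

All parsers validate on read and raise :class:`FormatError` naming the
offending line where possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CANONICAL_CHROMOSOMES = {str(i) for i in range(1, 23)} | {"X", "Y"}


class FormatError(ValueError):
    """A file failed structural validation."""


def normalize_chromosome(raw: str) -> str:
    """Map 'chr17', '17', 'chrX' etc. onto the canonical {1..22, X, Y} names."""
    name = raw.strip()
    if name.lower().startswith("chr"):
        name = name[3:]
    name = name.upper() if name.upper() in {"X", "Y"} else name
    if name not in CANONICAL_CHROMOSOMES:
        raise FormatError(f"non-canonical chromosome {raw!r}")
    return name


@dataclass(frozen=True)
class SegmentRecord:
    """One copy-number segment; ``segment_mean`` is the log2 copy-ratio."""

    sample_id: str
    chromosome: str
    start: int
    end: int
    num_probes: int | None
    segment_mean: float

    def __post_init__(self):
        if self.end < self.start:
            raise FormatError(
                f"segment end {self.end} < start {self.start} for {self.sample_id}"
            )


@dataclass(frozen=True)
class GeneLocus:
    """1-based closed genomic interval for a gene."""

    symbol: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.end < self.start:
            raise FormatError(f"locus end < start for {self.symbol}")
        if self.strand not in {"+", "-"}:
            raise FormatError(f"strand must be + or -, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def five_prime_half(self) -> "GeneLocus":
        """The promoter-proximal half of the gene, strand-aware."""
        mid = (self.start + self.end) // 2
        if self.strand == "+":
            return GeneLocus(self.symbol, self.chromosome, self.start, mid, self.strand)
        return GeneLocus(self.symbol, self.chromosome, mid, self.end, self.strand)


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values with a processing-stage tag."""

    values: pd.DataFrame  # index = gene symbols, columns = sample ids
    stage: str = "raw"  # raw | winsorized | normalized

    def __post_init__(self):
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise FormatError(f"duplicate gene symbols: {dups[:5]}")
        if self.stage == "normalized":
            vals = self.values.to_numpy(float)
            finite = vals[np.isfinite(vals)]
            if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
                raise FormatError("normalized stage requires values in [0, 1]")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class GeneSetCollection:
    """Named gene sets with free-text descriptions."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def restrict_to_universe(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Intersect each set with ``universe``; empty intersections are dropped."""
        uni = set(universe)
        kept = {
            name: [g for g in genes if g in uni] for name, genes in self.sets.items()
        }
        kept = {name: genes for name, genes in kept.items() if genes}
        return GeneSetCollection(kept, dict(self.descriptions))


# ---------------------------------------------------------------------------
# SEG


_SEG_HEADER_TOKENS = {"sample", "id", "chrom", "chromosome", "start", "loc.start"}


def read_seg(path) -> list[SegmentRecord]:
    """Parse a SEG file into validated :class:`SegmentRecord` objects.

    A header line is tolerated (detected by non-numeric start column).
    Chromosome names are normalized so 'chr15' and '15' compare equal.
    """
    records: list[SegmentRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}: line {lineno}: expected >=6 columns, got {len(fields)}")
            if lineno == 1 and _looks_like_header(fields):
                continue
            try:
                start, end = int(float(fields[2])), int(float(fields[3]))
                probes_raw = fields[4].strip()
                num_probes = None if probes_raw in {"", "NA", "nan"} else int(float(probes_raw))
                mean = float(fields[5])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: malformed row ({exc})") from None
            if end < start:
                raise FormatError(f"{path}: line {lineno}: end {end} < start {start}")
            if num_probes is not None and num_probes < 0:
                raise FormatError(f"{path}: line {lineno}: negative probe count")
            try:
                chrom = normalize_chromosome(fields[1])
            except FormatError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from None
            records.append(
                SegmentRecord(fields[0].strip(), chrom, start, end, num_probes, mean)
            )
    return records


def _looks_like_header(fields: Sequence[str]) -> bool:
    try:
        float(fields[2])
        return False
    except ValueError:
        return True


def write_seg(records: Iterable[SegmentRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("Sample\tChromosome\tStart\tEnd\tNum_Probes\tSegment_Mean\n")
        for rec in records:
            probes = "" if rec.num_probes is None else str(rec.num_probes)
            fh.write(
                f"{rec.sample_id}\t{rec.chromosome}\t{rec.start}\t{rec.end}\t"
                f"{probes}\t{rec.segment_mean!r}\n"
            )


# ---------------------------------------------------------------------------
# GCT v1.2


def read_gct(path) -> ExpressionMatrix:
    """Read a GCT v1.2 matrix; dimension line is checked against the body."""
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise FormatError(f"{path}: expected '#1.2' header, got {version!r}")
        dims = fh.readline().split()
        if len(dims) != 2:
            raise FormatError(f"{path}: malformed dimension line")
        n_genes, n_samples = int(dims[0]), int(dims[1])
        header = fh.readline().rstrip("\n").split("\t")
        samples = header[2:]
        if len(samples) != n_samples:
            raise FormatError(
                f"{path}: declared {n_samples} samples, header has {len(samples)}"
            )
        genes, rows = [], []
        for lineno, line in enumerate(fh, start=4):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != n_samples + 2:
                raise FormatError(f"{path}: line {lineno}: wrong column count")
            genes.append(fields[0])
            try:
                rows.append([float(v) for v in fields[2:]])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from None
    if len(genes) != n_genes:
        raise FormatError(f"{path}: declared {n_genes} genes, body has {len(genes)}")
    frame = pd.DataFrame(rows, index=genes, columns=samples, dtype=float)
    return ExpressionMatrix(frame)


def write_gct(matrix: ExpressionMatrix, path, descriptions: dict[str, str] | None = None) -> None:
    frame = matrix.values
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{frame.shape[0]}\t{frame.shape[1]}\n")
        fh.write("NAME\tDescription\t" + "\t".join(map(str, frame.columns)) + "\n")
        for gene, row in frame.iterrows():
            desc = (descriptions or {}).get(gene, "na")
            vals = "\t".join(repr(float(v)) for v in row.to_numpy())
            fh.write(f"{gene}\t{desc}\t{vals}\n")


# ---------------------------------------------------------------------------
# GMT / CLS


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT gene-set file; duplicate genes within a set are deduplicated."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: a gene set needs a name, description and >=1 gene"
                )
            name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g.strip()]
            if not genes:
                raise FormatError(f"{path}: line {lineno}: empty gene set {name!r}")
            seen: dict[str, None] = {}
            for g in genes:
                seen.setdefault(g.strip(), None)
            sets[name] = list(seen)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_cls(path) -> list[str]:
    """Read a categorical CLS phenotype file, returning one label per sample."""
    with open(path) as fh:
        head = fh.readline().split()
        if len(head) != 3:
            raise FormatError(f"{path}: malformed CLS count line")
        n_samples, n_classes = int(head[0]), int(head[1])
        class_line = fh.readline().split()
        if not class_line or class_line[0] != "#":
            raise FormatError(f"{path}: second CLS line must start with '#'")
        class_names = class_line[1:]
        if len(class_names) != n_classes:
            raise FormatError(
                f"{path}: declared {n_classes} classes, named {len(class_names)}"
            )
        labels = fh.readline().split()
    if len(labels) != n_samples:
        raise FormatError(
            f"{path}: declared {n_samples} samples, found {len(labels)} labels"
        )
    # Labels may be class names or 0-based indices into the class list.
    if all(lab in class_names for lab in labels):
        return labels
    try:
        return [class_names[int(lab)] for lab in labels]
    except (ValueError, IndexError):
        raise FormatError(f"{path}: labels are neither class names nor indices") from None


def write_cls(labels: Sequence[str], path) -> None:
    classes = list(dict.fromkeys(labels))
    with open(path, "w") as fh:
        fh.write(f"{len(labels)} {len(classes)} 1\n")
        fh.write("# " + " ".join(classes) + "\n")
        fh.write(" ".join(str(classes.index(lab)) for lab in labels) + "\n")


# ---------------------------------------------------------------------------
# Plain TSV matrices (gene-level CNA, methylation, clinical tables)


def read_matrix_tsv(path, value_dtype=float) -> pd.DataFrame:
    """Gene x sample TSV with gene symbols in the first column."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return frame.astype(value_dtype)


def write_matrix_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", float_format="%.10g")


def read_clinical_tsv(path) -> pd.DataFrame:
    """Sample annotation table indexed by sample id."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.index.duplicated().any():
        raise FormatError(f"{path}: duplicate sample ids")
    return frame
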