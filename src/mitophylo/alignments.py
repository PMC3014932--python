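"""Alignment containers, partition schemes, RY recoding, region extraction and
genome windowing.

Coordinates are 1-based inclusive in every user-facing structure (NEXUS
convention) and converted to 0-based numpy indices once, at the boundary.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

NUCLEOTIDE_ALPHABET = set("ACGTRYSWKMBDHVN?-")
RY_ALPHABET = set("RY?-")

#: IUPAC nucleotide code -> set of compatible bases
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT", "?": "ACGT", "-": "ACGT",
}


class AlignmentError(ValueError):
    """Malformed alignment, partition scheme or region specification."""


@dataclass
class Alignment:
    """A taxa-by-columns character matrix over IUPAC nucleotide codes.

    ``matrix`` holds one string per taxon; ``column_labels`` optionally assigns
    each column a partition id.
    """

    taxa: list[str]
    matrix: list[str]
    column_labels: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.matrix):
            raise AlignmentError("taxa and matrix row counts differ")
        if len(set(self.taxa)) != len(self.taxa):
            raise AlignmentError("duplicate taxon labels")
        lengths = {len(row) for row in self.matrix}
        if len(lengths) > 1:
            raise AlignmentError("ragged alignment rows")
        for row in self.matrix:
            bad = set(row.upper()) - NUCLEOTIDE_ALPHABET
            if bad:
                raise AlignmentError(f"characters outside alphabet: {sorted(bad)}")
        self.matrix = [row.upper() for row in self.matrix]
        if self.column_labels is not None and len(self.column_labels) != self.ncols:
            raise AlignmentError("column_labels length != column count")

    @property
    def ntaxa(self) -> int:
        return len(self.taxa)

    @property
    def ncols(self) -> int:
        return len(self.matrix[0]) if self.matrix else 0

    def columns(self, idx: np.ndarray | list[int]) -> "Alignment":
        """Sub-alignment of the given 0-based column indices, in order."""
        idx = np.asarray(idx, dtype=int)
        rows = ["".join(row[i] for i in idx) for row in self.matrix]
        labels = None
        if self.column_labels is not None:
            labels = [self.column_labels[i] for i in idx]
        return Alignment(list(self.taxa), rows, labels)

    def to_array(self) -> np.ndarray:
        """(ntaxa, ncols) array of single-character strings."""
        return np.array([list(row) for row in self.matrix])


@dataclass
class PartitionScheme:
    """Named, disjoint sets of 1-based column indices with per-partition encoding.

    ``encodings`` maps partition name to ``"nucleotide"`` or ``"ry"``.
    """

    partitions: dict[str, list[int]]
    encodings: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for name, cols in self.partitions.items():
            cols = sorted(int(c) for c in cols)
            if cols and cols[0] < 1:
                raise AlignmentError(f"partition {name!r}: columns are 1-based")
            overlap = seen & set(cols)
            if overlap:
                raise AlignmentError(f"partition {name!r} overlaps others at {sorted(overlap)[:5]}")
            seen |= set(cols)
            self.partitions[name] = cols
        for name in self.partitions:
            self.encodings.setdefault(name, "nucleotide")

    def sizes(self) -> dict[str, int]:
        return {name: len(cols) for name, cols in self.partitions.items()}

    def zero_based(self, name: str) -> np.ndarray:
        return np.asarray(self.partitions[name], dtype=int) - 1

    def site_partition_labels(self, ncols: int) -> list[str | None]:
        labels: list[str | None] = [None] * ncols
        for name, cols in self.partitions.items():
            for c in cols:
                if c > ncols:
                    raise AlignmentError(f"partition {name!r} column {c} > {ncols}")
                labels[c - 1] = name
        return labels


@dataclass
class RegionSpec:
    """A named gene region as ordered, non-overlapping 1-based inclusive intervals."""

    name: str
    ranges: list[tuple[int, int]]

    def __post_init__(self) -> None:
        prev_end = 0
        for start, end in self.ranges:
            if start < 1 or end < start:
                raise AlignmentError(f"region {self.name!r}: bad interval {start}-{end}")
            if start <= prev_end:
                raise AlignmentError(f"region {self.name!r}: intervals overlap or unordered")
            prev_end = end

    @property
    def width(self) -> int:
        return sum(end - start + 1 for start, end in self.ranges)

    def column_indices(self) -> np.ndarray:
        """0-based column indices covered, in order."""
        idx: list[int] = []
        for start, end in self.ranges:
            idx.extend(range(start - 1, end))
        return np.asarray(idx, dtype=int)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_alignment(path: str, format: str = "nexus") -> tuple[Alignment, PartitionScheme | None]:
    """Read a FASTA or NEXUS alignment; NEXUS charset blocks become a PartitionScheme."""
    format = format.lower()
    if format == "fasta":
        taxa, rows = [], []
        with open(path) as fh:
            label, chunks = None, []
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith(">"):
                    if label is not None:
                        taxa.append(label)
                        rows.append("".join(chunks))
                    label, chunks = line[1:].split()[0], []
                else:
                    chunks.append(line)
            if label is not None:
                taxa.append(label)
                rows.append("".join(chunks))
        return Alignment(taxa, rows), None
    if format != "nexus":
        raise AlignmentError(f"unsupported format {format!r}")
    mat = dendropy.DnaCharacterMatrix.get(path=path, schema="nexus")
    taxa = [t.label for t in mat.taxon_namespace]
    rows = [str(mat[t]).replace(" ", "") for t in mat.taxon_namespace]
    aln = Alignment(taxa, rows)
    scheme = None
    subsets = {name: ss for name, ss in mat.character_subsets.items()}
    if subsets:
        parts = {
            name: sorted(i + 1 for i in ss.character_indices) for name, ss in subsets.items()
        }
        encodings = {}
        for name, cols in parts.items():
            chars = {aln.matrix[r][c - 1] for r in range(aln.ntaxa) for c in cols[:50]}
            encodings[name] = "ry" if chars <= RY_ALPHABET else "nucleotide"
        scheme = PartitionScheme(parts, encodings)
    return aln, scheme


def _ranges_from_indices(cols: list[int]) -> str:
    """Compact 1-based NEXUS range string (`a-b` runs) for sorted column indices."""
    out, i = [], 0
    while i < len(cols):
        j = i
        while j + 1 < len(cols) and cols[j + 1] == cols[j] + 1:
            j += 1
        out.append(str(cols[i]) if i == j else f"{cols[i]}-{cols[j]}")
        i = j + 1
    return " ".join(out)


def write_alignment(aln: Alignment, path: str, format: str = "nexus",
                    scheme: PartitionScheme | None = None) -> None:
    """Write FASTA or non-interleaved NEXUS (with a SETS block when a scheme is given)."""
    format = format.lower()
    buf = io.StringIO()
    if format == "fasta":
        for taxon, row in zip(aln.taxa, aln.matrix):
            buf.write(f">{taxon}\n")
            for i in range(0, len(row), 80):
                buf.write(row[i:i + 80] + "\n")
    elif format == "nexus":
        width = max(len(t) for t in aln.taxa) + 2
        buf.write("#NEXUS\n\nBEGIN DATA;\n")
        buf.write(f"DIMENSIONS NTAX={aln.ntaxa} NCHAR={aln.ncols};\n")
        buf.write("FORMAT DATATYPE=DNA MISSING=? GAP=-;\nMATRIX\n")
        for taxon, row in zip(aln.taxa, aln.matrix):
            safe = taxon if " " not in taxon else f"'{taxon}'"
            buf.write(f"{safe:<{width}}{row}\n")
        buf.write(";\nEND;\n")
        if scheme is not None and scheme.partitions:
            buf.write("\nBEGIN SETS;\n")
            for name, cols in scheme.partitions.items():
                buf.write(f"charset {name} = {_ranges_from_indices(cols)};\n")
            buf.write("END;\n")
    else:
        raise AlignmentError(f"unsupported format {format!r}")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# Partition construction and recoding
# ---------------------------------------------------------------------------

ANNOTATION_CLASSES = ("codon1", "codon2", "codon3", "stem", "loop", "other")


def build_partition_scheme(aln: Alignment, annotations: list[str],
                           merge_rna: bool = False) -> PartitionScheme:
    """Group columns into codon-position / RNA-structure partitions.

    ``annotations`` assigns each column one of ``codon1 codon2 codon3 stem loop
    other``. With ``merge_rna`` the stem and loop classes are combined into a
    single ``rna`` partition (the configuration used for clock analyses).
    """
    if len(annotations) != aln.ncols:
        raise AlignmentError("one annotation per column required")
    bad = set(annotations) - set(ANNOTATION_CLASSES)
    if bad:
        raise AlignmentError(f"unknown annotation classes: {sorted(bad)}")
    parts: dict[str, list[int]] = {}
    for col, ann in enumerate(annotations, start=1):
        if merge_rna and ann in ("stem", "loop"):
            ann = "rna"
        parts.setdefault(ann, []).append(col)
    return PartitionScheme(parts)


def ry_recode(aln: Alignment, partition_cols: list[int] | np.ndarray) -> Alignment:
    """Recode the given 1-based columns to purine/pyrimidine.

    Within the partition: A, G, R -> R; C, T, Y -> Y; every other code,
    N and gaps -> '?'. Columns outside the partition are untouched. Only
    purine/purine and pyrimidine/pyrimidine ambiguities are information-
    preserving under the two-state encoding; everything else is missing.
    """
    cols = set(int(c) - 1 for c in partition_cols)
    if cols and (min(cols) < 0 or max(cols) >= aln.ncols):
        raise AlignmentError("RY partition column out of range")
    table = {c: ("R" if c in "AGR" else "Y" if c in "CTY" else "?")
             for c in NUCLEOTIDE_ALPHABET}
    rows = []
    for row in aln.matrix:
        rows.append("".join(table[ch] if i in cols else ch for i, ch in enumerate(row)))
    return Alignment(list(aln.taxa), rows,
                     list(aln.column_labels) if aln.column_labels else None)


def extract_regions(aln: Alignment, regions: list[RegionSpec]) -> Alignment:
    """Concatenate the given regions' columns, labelling each by region name."""
    idx: list[int] = []
    labels: list[str] = []
    for region in regions:
        ridx = region.column_indices()
        if len(ridx) and ridx.max() >= aln.ncols:
            raise AlignmentError(f"region {region.name!r} exceeds alignment bounds")
        idx.extend(ridx.tolist())
        labels.extend([region.name] * len(ridx))
    if not idx:
        return Alignment(list(aln.taxa), ["" for _ in aln.taxa], [])
    out = aln.columns(idx)
    out.column_labels = labels
    return out


@dataclass
class Window:
    """One genome window: 1-based inclusive coordinates plus its alignment."""

    start: int
    end: int
    alignment: Alignment

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    @property
    def partial(self) -> bool:
        return self.width < self._nominal

    _nominal: int = 0


def window_slice(aln: Alignment, width: int) -> list[Window]:
    """Non-overlapping consecutive windows covering the alignment.

    The final partial window is retained; its true width is recorded and its
    ``partial`` flag set so downstream consumers can filter it.
    """
    if width < 1:
        raise AlignmentError("window width must be >= 1")
    windows = []
    for start0 in range(0, aln.ncols, width):
        end0 = min(start0 + width, aln.ncols)
        win = Window(start0 + 1, end0, aln.columns(np.arange(start0, end0)))
        win._nominal = width
        windows.append(win)
    return windows


def read_region_specs(path: str) -> list[RegionSpec]:
    """Region specs from TSV rows of (name, start, end); repeated names merge."""
    ordered: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, start, end = line.split("\t")[:3]
            ordered.setdefault(name, []).append((int(start), int(end)))
    return [RegionSpec(name, ranges) for name, ranges in ordered.items()]
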