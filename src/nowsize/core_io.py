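"""Alignment I/O, MAF projection, window partitioning, and analyzability rules.

Sequences are held as a compact ``(n_taxa, length)`` uint8 matrix.  Codes 0-3
are A, C, G, T; code 4 is the alignment gap ``-``; code 5 is the ambiguity
``N``.  Both gap and N are treated as missing data by the likelihood engine,
but they are kept distinct so that files round-trip faithfully.

Coordinates are 0-based half-open throughout the library; human-readable
reports use 1-based window indices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import AlignIO, SeqIO

logger = logging.getLogger(__name__)

# Character encoding.  Anything not in this table is mapped to N; '?' and '.'
# are mapped to the gap code, and U (RNA) to T.
A, C, G, T, GAP, NCODE = 0, 1, 2, 3, 4, 5
_CODE_TO_CHAR = np.frombuffer(b"ACGT-N", dtype=np.uint8)

_CHAR_TO_CODE = np.full(256, NCODE, dtype=np.uint8)
for _ch, _code in [
    ("A", A), ("C", C), ("G", G), ("T", T), ("U", T),
    ("a", A), ("c", C), ("g", G), ("t", T), ("u", T),
    ("-", GAP), ("?", GAP), (".", GAP),
]:
    _CHAR_TO_CODE[ord(_ch)] = _code


class AlignmentFormatError(ValueError):
    """Raised for malformed or inconsistent alignment input."""


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a DNA string to the internal uint8 code vector."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CHAR_TO_CODE[raw]


def decode_sequence(codes: np.ndarray) -> str:
    """Decode a uint8 code vector back to an uppercase DNA string."""
    return _CODE_TO_CHAR[codes].tobytes().decode("ascii")


@dataclass
class Alignment:
    """A multiple sequence alignment over {A,C,G,T,-,N}.

    Parameters
    ----------
    taxa:
        Ordered, unique taxon labels.
    data:
        uint8 matrix of shape ``(len(taxa), length)`` using the module's
        character codes.
    """

    taxa: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.uint8)
        if self.data.ndim != 2:
            raise AlignmentFormatError("alignment data must be a 2-D matrix")
        if len(self.taxa) != self.data.shape[0]:
            raise AlignmentFormatError(
                f"{len(self.taxa)} taxa but {self.data.shape[0]} sequence rows"
            )
        if len(set(self.taxa)) != len(self.taxa):
            raise AlignmentFormatError("taxon labels must be unique")
        if self.data.shape[1] < 1:
            raise AlignmentFormatError("alignment must contain at least one site")

    @classmethod
    def from_sequences(cls, taxa: Sequence[str], sequences: Sequence[str]) -> "Alignment":
        if len(taxa) != len(sequences):
            raise AlignmentFormatError("taxa and sequences differ in number")
        lengths = {len(s) for s in sequences}
        if len(lengths) != 1:
            raise AlignmentFormatError(f"sequences have unequal lengths: {sorted(lengths)}")
        data = np.vstack([encode_sequence(s) for s in sequences])
        return cls(list(taxa), data)

    @property
    def n_taxa(self) -> int:
        return self.data.shape[0]

    @property
    def length(self) -> int:
        return self.data.shape[1]

    @property
    def sequences(self) -> list[str]:
        return [decode_sequence(row) for row in self.data]

    def sequence(self, taxon: str) -> str:
        return decode_sequence(self.data[self.taxa.index(taxon)])

    def window(self, start: int, end: int) -> "Alignment":
        """Slice sites ``[start, end)`` (taxa unchanged)."""
        if not (0 <= start < end <= self.length):
            raise ValueError(f"invalid window [{start}, {end}) for length {self.length}")
        return Alignment(self.taxa, self.data[:, start:end])

    def subset(self, taxa: Sequence[str]) -> "Alignment":
        idx = [self.taxa.index(t) for t in taxa]
        return Alignment(list(taxa), self.data[idx])

    def taxa_with_data(self) -> np.ndarray:
        """Boolean mask: taxon has at least one non-gap, non-N character."""
        return (self.data < GAP).any(axis=1)


@dataclass
class WindowPartition:
    """Equal-size, contiguous, non-overlapping tiling of an alignment prefix.

    The trailing remainder (``length mod window_size`` sites) is not part of
    any interval.  ``analyzable`` flags start all-true and are filled in by
    :func:`is_analyzable` via :meth:`apply_analyzability`.
    """

    window_size: int
    intervals: list[tuple[int, int]]
    analyzable: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.analyzable:
            self.analyzable = [True] * len(self.intervals)
        if len(self.analyzable) != len(self.intervals):
            raise ValueError("analyzable flags must match intervals")

    @property
    def n_windows(self) -> int:
        return len(self.intervals)

    def apply_analyzability(
        self, aln: Alignment, min_taxa_with_data: int = 3, strict: bool = True
    ) -> "WindowPartition":
        self.analyzable = [
            is_analyzable(aln.window(s, e), min_taxa_with_data, strict=strict)
            for s, e in self.intervals
        ]
        return self

    def to_tsv(self, path: str | Path, chrom: str = "chr") -> None:
        """BED-like audit table: chrom, start, end, 1-based index, analyzable."""
        with open(path, "w") as fh:
            fh.write("chrom\tstart\tend\twindow_index\tanalyzable\n")
            for i, ((s, e), ok) in enumerate(zip(self.intervals, self.analyzable), start=1):
                fh.write(f"{chrom}\t{s}\t{e}\t{i}\t{int(ok)}\n")


def read_fasta(path: str | Path) -> Alignment:
    """Read an aligned FASTA file.

    Sequences are uppercased, U is mapped to T, '?' and '.' to '-', and any
    other character outside {A,C,G,T,-,N} to N.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentFormatError(f"no FASTA records in {path}")
    taxa = [r.id for r in records]
    return Alignment.from_sequences(taxa, [str(r.seq) for r in records])


def write_fasta(aln: Alignment, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for taxon, row in zip(aln.taxa, aln.data):
            fh.write(f">{taxon}\n")
            seq = decode_sequence(row)
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _maf_species(record_id: str) -> str:
    # MAF source names are "assembly.contig"; the taxon is the assembly part.
    return record_id.split(".", 1)[0]


def maf_to_reference_fasta(
    maf: str | Path, reference: str, keep: Sequence[str]
) -> Alignment:
    """Project MAF blocks onto reference coordinates and return one alignment.

    Blocks are concatenated in reference-coordinate order, restricted to the
    taxa in ``keep``; columns where the reference carries a gap are dropped,
    and taxa absent from a block are padded with '-'.  Blocks lacking the
    reference entirely are skipped with a warning.
    """
    if reference not in keep:
        raise ValueError("`keep` must include the reference taxon")
    blocks: list[tuple[int, np.ndarray]] = []
    for block in AlignIO.parse(str(maf), "maf"):
        rows: dict[str, np.ndarray] = {}
        ref_start = None
        for rec in block:
            sp = _maf_species(rec.id)
            if sp in keep and sp not in rows:
                rows[sp] = encode_sequence(str(rec.seq))
                if sp == reference:
                    ref_start = rec.annotations.get("start", 0)
        if reference not in rows:
            logger.warning("MAF block without reference %s skipped", reference)
            continue
        width = len(rows[reference])
        mat = np.full((len(keep), width), GAP, dtype=np.uint8)
        for i, taxon in enumerate(keep):
            if taxon in rows:
                mat[i] = rows[taxon]
        # Mirror of the msa_view -G 1 projection: drop reference-gap columns.
        ref_row = mat[keep.index(reference)]
        mat = mat[:, ref_row != GAP]
        blocks.append((ref_start if ref_start is not None else 0, mat))
    if not blocks:
        raise AlignmentFormatError(f"no MAF block in {maf} contains reference {reference}")
    blocks.sort(key=lambda item: item[0])
    return Alignment(list(keep), np.concatenate([m for _, m in blocks], axis=1))


def make_windows(alignment_length: int, window_size: int) -> WindowPartition:
    """Tile ``[0, alignment_length)`` with non-overlapping windows.

    ``floor(alignment_length / window_size)`` windows are produced; the
    trailing remainder is excluded from all windowed analyses.
    """
    if window_size <= 0:
        raise ValueError(f"window_size must be positive, got {window_size}")
    if window_size > alignment_length:
        raise ValueError(
            f"window_size {window_size} exceeds alignment length {alignment_length}"
        )
    n = alignment_length // window_size
    intervals = [(i * window_size, (i + 1) * window_size) for i in range(n)]
    return WindowPartition(window_size, intervals)


def is_analyzable(
    window: Alignment, min_taxa_with_data: int = 3, strict: bool = True
) -> bool:
    """Decide whether a window supports a likelihood calculation.

    In strict mode (default) every taxon must carry at least one non-missing
    character; in lenient mode it suffices that ``min_taxa_with_data`` taxa do.
    Strict is the behaviour required when comparing AIC across window sizes on
    a fixed taxon set; the >=3-taxa rule reflects the minimum for an unrooted
    topology to exist at all.
    """
    has_data = window.taxa_with_data()
    n_with_data = int(has_data.sum())
    if n_with_data < min_taxa_with_data:
        return False
    if strict and not has_data.all():
        return False
    return True
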