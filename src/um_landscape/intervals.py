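"""Genomic interval masks.

Positions are 1-based inclusive inside the package (VCF convention); BED
input/output is 0-based half-open.  Conversion happens here, at the reader
boundary, and nowhere else.
"""

from __future__ import annotations

from pathlib import Path

from intervaltree import IntervalTree


class IntervalMask:
    """Set of genomic intervals supporting point and window overlap queries."""

    def __init__(self) -> None:
        self._trees: dict[str, IntervalTree] = {}

    @classmethod
    def from_bed(cls, path: str | Path) -> "IntervalMask":
        """Load a BED file (0-based half-open) into a mask (1-based inclusive)."""
        mask = cls()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                mask.add(chrom, start + 1, end)
        return mask

    @classmethod
    def from_tuples(cls, tuples) -> "IntervalMask":
        """Build from (chrom, start, end) triples, 1-based inclusive."""
        mask = cls()
        for chrom, start, end in tuples:
            mask.add(chrom, start, end)
        return mask

    def add(self, chrom: str, start: int, end: int) -> None:
        """Add a 1-based inclusive interval."""
        if end < start:
            raise ValueError(f"interval end {end} < start {start} on {chrom}")
        self._trees.setdefault(chrom, IntervalTree()).addi(start, end + 1)

    def contains(self, chrom: str, pos: int) -> bool:
        """Is the 1-based position inside any interval?"""
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlaps_point(pos))

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """Does the 1-based inclusive window overlap any interval?"""
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlap(start, end + 1))

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self._trees):
                for iv in sorted(self._trees[chrom]):
                    fh.write(f"{chrom}\t{iv.begin - 1}\t{iv.end - 1}\n")

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())
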