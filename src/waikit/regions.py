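"""Genomic region sets (BED convention: 0-based, half-open intervals)."""

from __future__ import annotations

from dataclasses import dataclass, field

from intervaltree import IntervalTree


@dataclass
class RegionSet:
    """A labelled set of genomic intervals with fast point queries.

    Coordinates follow BED: 0-based, half-open ``[start, end)``.  Variant
    positions are 1-based (VCF); conversion between the two conventions
    happens only inside :meth:`contains_variant` / :meth:`labels_at_variant`.
    """

    intervals: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self._trees: dict[str, IntervalTree] = {}
        for chrom, start, end, label in self.intervals:
            if start < 0 or start >= end:
                raise ValueError(f"invalid interval {(chrom, start, end, label)}")
            self._trees.setdefault(chrom, IntervalTree()).addi(start, end, label)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def contains_point(self, chrom: str, pos0: int) -> bool:
        """Membership of a 0-based position."""
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree[pos0])

    def contains_variant(self, chrom: str, pos: int) -> bool:
        """Membership of a 1-based (VCF) variant anchor position."""
        return self.contains_point(chrom, pos - 1)

    def labels_at_variant(self, chrom: str, pos: int) -> list[str]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted(iv.data for iv in tree[pos - 1])

    @classmethod
    def from_bed(cls, path) -> "RegionSet":
        """Read a BED3/BED4 file (track/comment lines ignored)."""
        intervals = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                label = parts[3] if len(parts) > 3 else f"{chrom}:{start}-{end}"
                intervals.append((chrom, start, end, label))
        return cls(intervals)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, start, end, label in self.intervals:
                fh.write(f"{chrom}\t{start}\t{end}\t{label}\n")
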