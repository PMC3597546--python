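"""Genome coordinate layout: chromosomes partitioned into fixed-width bins.

All genomic coordinates in this package are BED-style 0-based, half-open.
Bin ``i`` of a chromosome covers ``[i * bin_width, (i + 1) * bin_width)``;
a trailing partial bin shorter than ``bin_width`` is dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["GenomeLayout"]


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names/lengths plus the bin grid shared by all tracks.

    Parameters
    ----------
    chrom_names
        Chromosome identifiers, in a fixed order.
    chrom_lengths
        Length in base pairs of each chromosome, aligned with *chrom_names*.
    bin_width
        Width of a genomic bin in base pairs (default 100).
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    bin_width: int = 100
    _index: dict[str, int] = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        names = tuple(self.chrom_names)
        lengths = tuple(int(x) for x in self.chrom_lengths)
        object.__setattr__(self, "chrom_names", names)
        object.__setattr__(self, "chrom_lengths", lengths)
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if len(names) != len(lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, length in zip(names, lengths):
            if length < self.bin_width:
                raise ValueError(
                    f"chromosome {name!r} ({length} bp) is shorter than one bin"
                )
        object.__setattr__(self, "_index", {n: i for i, n in enumerate(names)})

    @classmethod
    def from_chrom_sizes(cls, path: str, bin_width: int = 100) -> "GenomeLayout":
        """Build a layout from a two-column ``chrom<TAB>size`` file."""
        names: list[str] = []
        lengths: list[int] = []
        with open(path) as fh:
            for line in fh:
                fields = line.split()
                if not fields or fields[0].startswith("#"):
                    continue
                if len(fields) < 2:
                    raise ValueError(f"malformed chrom.sizes line: {line!r}")
                names.append(fields[0])
                lengths.append(int(fields[1]))
        return cls(tuple(names), tuple(lengths), bin_width)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._index

    def length(self, chrom: str) -> int:
        return self.chrom_lengths[self._index[chrom]]

    def n_bins(self, chrom: str) -> int:
        """Number of complete bins on *chrom* (partial trailing bin dropped)."""
        return self.length(chrom) // self.bin_width

    def bin_of(self, chrom: str, position: int) -> int:
        """Bin index containing a base-pair position."""
        if not 0 <= position < self.length(chrom):
            raise ValueError(f"position {position} outside {chrom}")
        return position // self.bin_width
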