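"""Genome description and chrom.sizes I/O.

A :class:`GenomeSpec` is the minimal stand-in for a reference assembly:
an ordered set of chromosome lengths, optionally with gene intervals
(0-based, half-open) used for genic annotation of origins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable


@dataclass(frozen=True)
class GenomeSpec:
    """Ordered chromosomes (name, length in bp) plus optional gene intervals."""

    chroms: tuple[tuple[str, int], ...]
    genes: tuple[tuple[str, int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        names = [n for n, _ in self.chroms]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for name, length in self.chroms:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
        lengths = dict(self.chroms)
        for chrom, start, end in self.genes:
            if chrom not in lengths:
                raise ValueError(f"gene on unknown chromosome {chrom!r}")
            if not (0 <= start < end <= lengths[chrom]):
                raise ValueError(f"gene interval ({chrom}, {start}, {end}) out of bounds")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chroms)

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chroms]

    @property
    def size_bp(self) -> int:
        """Total genome size G in bp."""
        return sum(length for _, length in self.chroms)

    @property
    def size_kb(self) -> float:
        return self.size_bp / 1000.0

    def n_bins(self, bin_size: int) -> dict[str, int]:
        """Number of bins per chromosome at ``bin_size`` (last bin may be partial)."""
        return {n: -(-length // bin_size) for n, length in self.chroms}

    def contains(self, chrom: str, pos: int) -> bool:
        length = self.lengths.get(chrom)
        return length is not None and 0 <= pos < length


def read_chrom_sizes(path: str | Path, genes: Iterable[tuple[str, int, int]] = ()) -> GenomeSpec:
    """Read a two-column ``chrom.sizes`` text file into a :class:`GenomeSpec`."""
    chroms = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, size = line.split()[:2]
        chroms.append((name, int(size)))
    return GenomeSpec(tuple(chroms), tuple(genes))


def write_chrom_sizes(genome: GenomeSpec, path: str | Path) -> None:
    Path(path).write_text("".join(f"{n}\t{s}\n" for n, s in genome.chroms))


def default_genome(chrom_length: int = 5_000_000, n_chroms: int = 3, with_genes: bool = True) -> GenomeSpec:
    """Toy embryonic genome: ``n_chroms`` chromosomes of ``chrom_length`` bp.

    Gene intervals (when requested) tile each chromosome with a 15-kb gene
    every 25 kb, giving a genic fraction of 0.6, in the range of compact
    nematode genomes.
    """
    names = [f"chr{_roman(i + 1)}" for i in range(n_chroms)]
    chroms = tuple((n, chrom_length) for n in names)
    genes: list[tuple[str, int, int]] = []
    if with_genes:
        for name in names:
            for start in range(5_000, chrom_length - 20_000, 25_000):
                genes.append((name, start, start + 15_000))
    return GenomeSpec(chroms, tuple(genes))


def _roman(i: int) -> str:
    numerals = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]
    return numerals[i - 1] if i <= len(numerals) else str(i)
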