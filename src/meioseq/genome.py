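"""Mouse chromosome complement and fixed genome-wide binning.

All coordinates are 0-based half-open (BED convention).  The default
chromosome table carries GRCm39 sequence lengths; only lengths are needed
downstream, never sequence.  Every other module works on the ordered bin
list produced by :func:`make_binning`, so the tiling here is the single
source of truth for bin indexing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "ChromosomeSpec",
    "GenomeBinning",
    "GRCM39_CHROMOSOMES",
    "AUTOSOME_NAMES",
    "CHROMOSOME_ORDER",
    "DEFAULT_WINDOW_SIZE",
    "default_chromosomes",
    "load_chromosome_table",
    "make_binning",
]

#: canonical ordering: autosomes 1..19, then X, then Y
AUTOSOME_NAMES: tuple[str, ...] = tuple(str(i) for i in range(1, 20))
CHROMOSOME_ORDER: tuple[str, ...] = AUTOSOME_NAMES + ("X", "Y")

#: GRCm39 chromosome lengths in base pairs
GRCM39_CHROMOSOMES: dict[str, int] = {
    "1": 195_154_279,
    "2": 181_755_017,
    "3": 159_745_316,
    "4": 156_860_686,
    "5": 151_758_149,
    "6": 149_588_044,
    "7": 144_995_196,
    "8": 130_127_694,
    "9": 124_359_700,
    "10": 130_530_862,
    "11": 121_973_369,
    "12": 120_092_757,
    "13": 120_883_175,
    "14": 125_139_656,
    "15": 104_073_951,
    "16": 98_008_968,
    "17": 95_294_699,
    "18": 90_720_763,
    "19": 61_420_004,
    "X": 169_476_592,
    "Y": 91_455_967,
}

DEFAULT_WINDOW_SIZE: int = 10_000_000  # 10 Mb analysis windows


@dataclass(frozen=True)
class ChromosomeSpec:
    """One chromosome: label, length in bp, and sex-chromosome flag."""

    name: str
    length: int
    is_sex: bool

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"chromosome {self.name!r}: length must be > 0")


def default_chromosomes() -> list[ChromosomeSpec]:
    """The bundled mouse complement: 19 autosomes plus X and Y."""
    return [
        ChromosomeSpec(name, GRCM39_CHROMOSOMES[name], is_sex=name in ("X", "Y"))
        for name in CHROMOSOME_ORDER
    ]


def load_chromosome_table(path: str | Path) -> list[ChromosomeSpec]:
    """Read a two-column TSV (name, length) chromosome table.

    Lines starting with ``#`` are ignored.  Names not in the canonical
    mouse ordering are appended after Y in file order.
    """
    specs: list[ChromosomeSpec] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected 'name<TAB>length'")
        name = parts[0].strip()
        if name in seen:
            raise ValueError(f"{path}:{lineno}: duplicate chromosome {name!r}")
        seen.add(name)
        specs.append(ChromosomeSpec(name, int(parts[1]), is_sex=name in ("X", "Y")))
    if not specs:
        raise ValueError(f"{path}: empty chromosome table")

    def sort_key(spec: ChromosomeSpec) -> tuple[int, int]:
        try:
            return (0, CHROMOSOME_ORDER.index(spec.name))
        except ValueError:
            return (1, 0)

    return sorted(specs, key=sort_key)


@dataclass(frozen=True)
class GenomeBinning:
    """An ordered, gap-free tiling of the genome into fixed-size windows.

    ``bins`` holds ``(chromosome, start, end)`` triples in chromosome
    order then ascending start; only a chromosome's last bin may be
    shorter than ``window_size``.
    """

    bins: tuple[tuple[str, int, int], ...]
    window_size: int
    chromosomes: tuple[ChromosomeSpec, ...]

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def chrom_of(self, index: int) -> str:
        return self.bins[index][0]

    def bin_indices(self, chrom: str) -> list[int]:
        """Indices of the bins on ``chrom``, in genomic order."""
        return [i for i, (c, _, _) in enumerate(self.bins) if c == chrom]

    def chromosome_names(self) -> tuple[str, ...]:
        return tuple(spec.name for spec in self.chromosomes)

    def autosome_mask(self) -> "list[bool]":
        """Per-bin flag: True where the bin lies on an autosome."""
        sex = {spec.name for spec in self.chromosomes if spec.is_sex}
        return [c not in sex for c, _, _ in self.bins]


def make_binning(
    chromosomes: Sequence[ChromosomeSpec] | None = None,
    window_size: int = DEFAULT_WINDOW_SIZE,
) -> GenomeBinning:
    """Tile each chromosome into ``window_size`` windows.

    The tiling is exhaustive and non-overlapping; a chromosome whose
    length is not a multiple of the window size ends with one short
    terminal bin, so per-chromosome bin widths always sum exactly to the
    chromosome length.
    """
    if chromosomes is None:
        chromosomes = default_chromosomes()
    if not chromosomes:
        raise ValueError("chromosome list is empty")
    if window_size <= 0:
        raise ValueError("window_size must be > 0")

    bins: list[tuple[str, int, int]] = []
    for spec in chromosomes:
        start = 0
        while start < spec.length:
            end = min(start + window_size, spec.length)
            bins.append((spec.name, start, end))
            start = end
    return GenomeBinning(
        bins=tuple(bins), window_size=window_size, chromosomes=tuple(chromosomes)
    )


def oocyte_chromosomes(binning: GenomeBinning) -> list[str]:
    """Chromosomes carried by oocyte-derived samples: autosomes plus X."""
    return [spec.name for spec in binning.chromosomes if spec.name != "Y"]
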