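"""Genome description shared by all modules.

A :class:`GenomeSpec` is a minimal assembly description: ordered chromosome
names with lengths, plus an optional set of chromosomes flagged as exogenous
spike-in material (reads from an admixed foreign genome used for absolute
normalization). All coordinates in the package are 0-based, half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome names/lengths plus an optional spike-in chromosome set.

    Parameters
    ----------
    chromosomes
        Mapping of chromosome name to length in bp. Order is preserved and
        used for deterministic iteration everywhere downstream.
    spikein
        Names (subset of ``chromosomes``) belonging to the spike-in genome.
        Spike-in chromosomes never receive target-sample fragments.
    """

    chromosomes: dict[str, int]
    spikein: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("GenomeSpec requires at least one chromosome")
        names = list(self.chromosomes)
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for name, length in self.chromosomes.items():
            if int(length) <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        object.__setattr__(self, "spikein", frozenset(self.spikein))
        unknown = self.spikein - set(names)
        if unknown:
            raise ValueError(f"spike-in chromosomes not in genome: {sorted(unknown)}")

    @property
    def target_chromosomes(self) -> dict[str, int]:
        """Chromosomes of the genome under study (spike-in excluded)."""
        return {c: l for c, l in self.chromosomes.items() if c not in self.spikein}

    @property
    def spikein_chromosomes(self) -> dict[str, int]:
        return {c: l for c, l in self.chromosomes.items() if c in self.spikein}

    @property
    def target_length(self) -> int:
        return sum(self.target_chromosomes.values())

    def length_of(self, chrom: str) -> int:
        try:
            return self.chromosomes[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None


# Standard S. cerevisiae (sacCer3) chromosome lengths in bp; used by the
# study-scale synthetic experiments so origin counts and inter-origin
# distances live on a realistic 12 Mb, 16-chromosome landscape.
SACCER3_LENGTHS: dict[str, int] = {
    "chrI": 230_218,
    "chrII": 813_184,
    "chrIII": 316_620,
    "chrIV": 1_531_933,
    "chrV": 576_874,
    "chrVI": 270_161,
    "chrVII": 1_090_940,
    "chrVIII": 562_643,
    "chrIX": 439_888,
    "chrX": 745_751,
    "chrXI": 666_816,
    "chrXII": 1_078_177,
    "chrXIII": 924_431,
    "chrXIV": 784_333,
    "chrXV": 1_091_291,
    "chrXVI": 948_066,
}


def saccer3_like(spikein_length: int = 2_500_000) -> GenomeSpec:
    """A sacCer3-sized target genome with one pooled spike-in chromosome.

    The spike-in chromosome stands in for the S. pombe genome admixed at
    fixed cell ratio before ChIP; only its total mappable length matters
    for normalization, so it is represented as a single contig.
    """
    chroms = dict(SACCER3_LENGTHS)
    chroms["spombe_pool"] = spikein_length
    return GenomeSpec(chromosomes=chroms, spikein=frozenset({"spombe_pool"}))


def toy_genome(
    n_chromosomes: int = 3,
    chrom_length: int = 300_000,
    spikein_length: int = 100_000,
) -> GenomeSpec:
    """Small default genome for seconds-scale tests: 3 x 300 kb + 100 kb spike-in."""
    chroms = {f"chr{i + 1}": chrom_length for i in range(n_chromosomes)}
    if spikein_length:
        chroms["spike1"] = spikein_length
        return GenomeSpec(chromosomes=chroms, spikein=frozenset({"spike1"}))
    return GenomeSpec(chromosomes=chroms)
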