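"""Core in-memory containers shared across the pipeline.

All genomic coordinates held in these containers are 0-based, half-open
``[start, end)``. Conversions to and from 1-based conventions (VCF, the
human-readable results table) happen only at the I/O boundary in
:mod:`mbddmr.formats`.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

GENE_CLASSES = ("vomeronasal", "olfactory", "microrna", "other")
FEATURES = ("promoter", "exon", "intron", "enhancer", "intergenic")
TREATMENTS = ("control", "dehp")


@dataclass
class Gene:
    """A gene model: strand, transcription start site and exon intervals.

    ``tss`` is the first transcribed base (0-based). For a minus-strand gene
    the TSS is therefore the *rightmost* transcribed base of the locus.
    """

    symbol: str
    chrom: str
    strand: str  # '+' or '-'
    tss: int
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.symbol!r}: strand must be '+' or '-', got {self.strand!r}")


@dataclass
class GenomeModel:
    """Chromosome sequences plus gene models and enhancer intervals."""

    sequences: dict[str, str]
    genes: list[Gene] = field(default_factory=list)
    enhancers: list[tuple[str, int, int]] = field(default_factory=list)

    def chrom_length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    @property
    def chroms(self) -> list[str]:
        return list(self.sequences)

    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())


@dataclass
class Variant:
    """A strain-distinguishing variant, 0-based position of the ref allele."""

    chrom: str
    pos: int
    ref: str
    alt: str
    genotype: str = "1/1"
    depth: int = 0
    cpg_creating: bool = False
    cpg_destroying: bool = False
    protein_modifying: bool = False

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def homozygous_alt(self) -> bool:
        alleles = self.genotype.replace("|", "/").split("/")
        return all(a == "1" for a in alleles)


@dataclass
class StrainVariantSet:
    """Homozygous variants distinguishing the alternate strain from the reference."""

    records: list[Variant] = field(default_factory=list)
    strain: Optional[str] = None

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_chrom(self) -> dict[str, list[Variant]]:
        out: dict[str, list[Variant]] = {}
        for v in self.records:
            out.setdefault(v.chrom, []).append(v)
        for recs in out.values():
            recs.sort(key=lambda v: v.pos)
        return out

    def snps(self) -> "StrainVariantSet":
        return StrainVariantSet([v for v in self.records if v.is_snp], self.strain)


@dataclass
class Probe:
    """A genomic interval over which read pairs are counted.

    Either a genome tile (fixed 2.2 kb grid) or a promoter window
    (2 kb upstream to 200 bp downstream of the TSS).
    """

    id: str
    chrom: str
    start: int
    end: int
    kind: str  # 'genome_tile' | 'promoter'
    gene_symbol: Optional[str] = None
    gene_class: str = "other"
    feature: Optional[str] = None  # genome tiles only
    n_cpg_ref: int = 0
    n_cpg_snp_dependent: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"probe {self.id}: invalid interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ReadPairAlignment:
    """One aligned fragment: two read intervals plus mapping metadata."""

    chrom1: str
    start1: int
    end1: int
    chrom2: str
    start2: int
    end2: int
    name: str = "."
    unique: bool = True
    sample_id: str = ""
    strand1: str = "+"
    strand2: str = "-"

    def __post_init__(self) -> None:
        if self.start1 >= self.end1 or self.start2 >= self.end2:
            raise ValueError(f"read pair {self.name}: empty read interval")

    @property
    def concordant_chrom(self) -> bool:
        return self.chrom1 == self.chrom2

    @property
    def insert(self) -> tuple[int, int]:
        """Fragment interval [leftmost start, rightmost end); same-chromosome pairs only."""
        if not self.concordant_chrom:
            raise ValueError("insert undefined for cross-chromosome pair")
        return min(self.start1, self.start2), max(self.end1, self.end2)

    @property
    def inner_gap(self) -> int:
        """Distance between the facing ends of the two reads (negative if they overlap)."""
        if not self.concordant_chrom:
            raise ValueError("inner gap undefined for cross-chromosome pair")
        if self.start1 <= self.start2:
            return self.start2 - self.end1
        return self.start1 - self.end2


@dataclass
class CpGSiteSet:
    """Sorted CpG positions (position of the C) per chromosome for one strain.

    ``provenance`` parallels ``positions``: 'reference' for sites present in
    the reference sequence, 'snp_created' for sites that exist only under the
    strain's alternate alleles.
    """

    strain: str
    positions: dict[str, np.ndarray] = field(default_factory=dict)
    provenance: dict[str, np.ndarray] = field(default_factory=dict)

    def count_in(self, chrom: str, start: int, end: int) -> int:
        pos = self.positions.get(chrom)
        if pos is None or len(pos) == 0:
            return 0
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="left")
        return int(hi - lo)

    def n_sites(self) -> int:
        return sum(len(p) for p in self.positions.values())


@dataclass
class SampleInfo:
    sample_id: str
    strain: str
    treatment: str
    path: Optional[str] = None


class SampleSheet:
    """Sample metadata: id, strain (two levels), treatment (control/dehp)."""

    def __init__(self, samples: Iterable[SampleInfo]):
        self.samples = list(samples)
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample_ids must be unique")
        for s in self.samples:
            if s.treatment not in TREATMENTS:
                raise ValueError(f"sample {s.sample_id}: treatment must be one of {TREATMENTS}")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def strains(self) -> list[str]:
        return sorted({s.strain for s in self.samples})

    def ids_for(self, strain: Optional[str] = None, treatment: Optional[str] = None) -> list[str]:
        return [
            s.sample_id
            for s in self.samples
            if (strain is None or s.strain == strain) and (treatment is None or s.treatment == treatment)
        ]

    def info(self, sample_id: str) -> SampleInfo:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def require_full_design(self) -> None:
        """For the interaction contrast: both strains x both treatments, >=2 samples per cell."""
        strains = self.strains
        if len(strains) != 2:
            raise ValueError(f"interaction analysis needs exactly 2 strains, found {strains}")
        for st in strains:
            for tr in TREATMENTS:
                n = len(self.ids_for(st, tr))
                if n == 0:
                    raise ValueError(f"design cell ({st}, {tr}) has no samples")
                if n < 2:
                    raise ValueError(f"design cell ({st}, {tr}) has {n} sample(s); >=2 required")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "strain": [s.strain for s in self.samples],
                "treatment": [s.treatment for s in self.samples],
                "path": [s.path for s in self.samples],
            }
        )


@dataclass
class CountMatrix:
    """Probe x sample integer counts with sample metadata and library sizes.

    ``values`` is a probes-by-samples DataFrame; ``library_size`` is the total
    number of kept (filtered) pairs per sample, which can exceed the column
    sum when some pairs fall outside the probe set.
    """

    values: pd.DataFrame
    samples: SampleSheet
    library_size: pd.Series

    def __post_init__(self) -> None:
        if list(self.values.columns) != self.samples.sample_ids:
            raise ValueError("count matrix columns must match sample sheet order")
        if (self.values.values < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    def subset_probes(self, probe_ids: Iterable[str]) -> "CountMatrix":
        return CountMatrix(self.values.loc[list(probe_ids)], self.samples, self.library_size)
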