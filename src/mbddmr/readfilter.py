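"""Read-pair filtration applied before counting.

A pair survives iff, in this order:

1. **concordance** — both reads on the same chromosome and the inner gap
   (distance between the facing ends of the two reads) is at most
   ``max_gap`` (600 bp by default); overlapping or dovetailing reads
   (negative gap) are concordant;
2. **uniqueness** — the pair maps to a single genomic position;
3. **CpG content** — the insert (leftmost read start to rightmost read end)
   contains at least one CpG site of the sample's strain, counting
   SNP-dependent CpGs.

Each rejected pair is attributed to the first rule it fails, so the tally
always sums to the input size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .model import CpGSiteSet, ReadPairAlignment

DEFAULT_MAX_GAP = 600


@dataclass
class FilterTally:
    n_input: int = 0
    n_kept: int = 0
    n_discordant: int = 0
    n_multimapped: int = 0
    n_no_cpg: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "input": self.n_input,
            "kept": self.n_kept,
            "discordant": self.n_discordant,
            "multimapped": self.n_multimapped,
            "no_cpg": self.n_no_cpg,
        }

    def check_conservation(self) -> bool:
        return self.n_kept + self.n_discordant + self.n_multimapped + self.n_no_cpg == self.n_input


def filter_read_pairs(
    pairs: Iterable[ReadPairAlignment],
    cpg_sites: CpGSiteSet,
    max_gap: int = DEFAULT_MAX_GAP,
) -> tuple[list[ReadPairAlignment], FilterTally]:
    """Apply the three filtration rules; returns kept pairs and a rejection tally.

    ``cpg_sites`` must be the site set of the sample's own strain so that
    SNP-created CpGs count for that strain only.
    """
    kept: list[ReadPairAlignment] = []
    tally = FilterTally()
    known = set(cpg_sites.positions)
    for p in pairs:
        tally.n_input += 1
        for chrom in (p.chrom1, p.chrom2):
            if known and chrom not in known:
                raise ValueError(f"pair {p.name}: unknown chromosome {chrom!r}")
        if not p.concordant_chrom or p.inner_gap > max_gap:
            tally.n_discordant += 1
            continue
        if not p.unique:
            tally.n_multimapped += 1
            continue
        start, end = p.insert
        if cpg_sites.count_in(p.chrom1, start, end) < 1:
            tally.n_no_cpg += 1
            continue
        kept.append(p)
        tally.n_kept += 1
    return kept, tally
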