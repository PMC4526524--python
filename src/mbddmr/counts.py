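"""Counting filtered read pairs onto probes.

The counted unit is the insert (fragment) interval of a pair, not the two
read intervals separately, since MBD capture selects whole fragments. Two
overlap rules are provided:

* ``midpoint`` (default for disjoint genome tiles) — a pair increments the
  unique tile containing its insert midpoint, giving exact conservation of
  kept pairs over a tiling partition;
* ``any_overlap`` (default for promoter probes, which may overlap each
  other) — a pair increments every probe its insert overlaps by >=1 bp.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .model import CountMatrix, Probe, ReadPairAlignment, SampleSheet

MODES = ("midpoint", "any_overlap")


def _insert_arrays(pairs: Sequence[ReadPairAlignment]):
    chroms = np.array([p.chrom1 for p in pairs], dtype=object)
    starts = np.empty(len(pairs), dtype=np.int64)
    ends = np.empty(len(pairs), dtype=np.int64)
    for i, p in enumerate(pairs):
        starts[i], ends[i] = p.insert
    return chroms, starts, ends


def count_overlaps(
    pairs_by_sample: dict[str, Sequence[ReadPairAlignment]],
    probes: Sequence[Probe],
    samples: SampleSheet,
    mode: str = "midpoint",
) -> CountMatrix:
    """Count read pairs per probe and sample.

    ``pairs_by_sample`` maps sample_id to that sample's filtered pairs.
    Library size is the total number of pairs provided per sample
    (kept pairs), whether or not they hit a probe.
    """
    if mode not in MODES:
        raise ValueError(f"unknown counting mode {mode!r}; expected one of {MODES}")
    probe_ids = [p.id for p in probes]
    values = pd.DataFrame(
        np.zeros((len(probes), len(samples.sample_ids)), dtype=np.int64),
        index=probe_ids,
        columns=samples.sample_ids,
    )
    libsize = pd.Series(0, index=samples.sample_ids, dtype=np.int64)

    if mode == "midpoint":
        by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[int]]] = {}
        for j, p in enumerate(probes):
            by_chrom.setdefault(p.chrom, ([], [], []))  # type: ignore[arg-type]
        starts_map: dict[str, list] = {}
        for j, p in enumerate(probes):
            starts_map.setdefault(p.chrom, []).append((p.start, p.end, j))
        sorted_map = {}
        for chrom, items in starts_map.items():
            items.sort()
            s = np.array([x[0] for x in items], dtype=np.int64)
            e = np.array([x[1] for x in items], dtype=np.int64)
            idx = [x[2] for x in items]
            sorted_map[chrom] = (s, e, idx)
        for sid, pairs in pairs_by_sample.items():
            libsize[sid] = len(pairs)
            if not pairs:
                continue
            chroms, starts, ends = _insert_arrays(pairs)
            mids = (starts + ends) // 2
            col = values.columns.get_loc(sid)
            for chrom in np.unique(chroms):
                entry = sorted_map.get(chrom)
                if entry is None:
                    continue
                s, e, idx = entry
                m = mids[chroms == chrom]
                k = np.searchsorted(s, m, side="right") - 1
                ok = (k >= 0) & (m < e[np.clip(k, 0, len(e) - 1)])
                hits, counts = np.unique(k[ok], return_counts=True)
                for h, c in zip(hits, counts):
                    values.iat[idx[h], col] += int(c)
    else:  # any_overlap
        trees: dict[str, IntervalTree] = {}
        for j, p in enumerate(probes):
            trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, j)
        for sid, pairs in pairs_by_sample.items():
            libsize[sid] = len(pairs)
            col = values.columns.get_loc(sid)
            for p in pairs:
                tree = trees.get(p.chrom1)
                if tree is None:
                    continue
                start, end = p.insert
                for iv in tree.overlap(start, end):
                    values.iat[iv.data, col] += 1

    return CountMatrix(values=values, samples=samples, library_size=libsize)
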