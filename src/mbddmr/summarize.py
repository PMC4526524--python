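"""Aggregation of DMR results into reporting structures.

Three summaries mirror the study's reporting: the genomic-feature
distribution of probes (pie-chart percentages), volcano-plot quadrant counts
per gene class (significant and trend-level hyper/hypo promoters), and the
gene-class trend fractions such as "55% of vomeronasal promoters trend
hyper-methylated under DEHP".

Sign convention: ``log2fc`` is control-over-DEHP throughout, so *negative*
log2fc means hyper-methylated in DEHP. Summaries report direction labels in
both vocabularies to avoid sign confusion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .model import GENE_CLASSES, Probe
from .nbstats import CallPolicy, bonferroni_threshold

_CLASS_PATTERNS = (("vmn", "vomeronasal"), ("olfr", "olfactory"), ("mir", "microrna"))


def classify_gene_symbol(symbol: str) -> str:
    """Gene class from symbol substring, case-insensitive.

    Precedence vomeronasal ("Vmn") > olfactory ("Olfr") > microRNA ("Mir");
    anything else is "other".
    """
    low = symbol.lower()
    for pat, cls in _CLASS_PATTERNS:
        if pat in low:
            return cls
    return "other"


@dataclass
class ClassSummary:
    """Volcano quadrant counts for one gene class.

    ``n_sig_*`` counts pass both the Bonferroni p threshold and the two-fold
    change; ``n_trend_*`` exceed two-fold without reaching significance.
    Direction suffix refers to the control-over-DEHP sign: ``hyper_control``
    (positive log2fc) = hypo-methylated in DEHP; ``hypo_control`` (negative
    log2fc) = hyper-methylated in DEHP.
    """

    gene_class: str
    n_total: int
    n_sig_hyper_control: int
    n_sig_hypo_control: int
    n_trend_hyper_control: int
    n_trend_hypo_control: int

    @property
    def n_sig_hyper_dehp(self) -> int:
        return self.n_sig_hypo_control

    @property
    def n_trend_hyper_dehp(self) -> int:
        return self.n_trend_hypo_control


def volcano_quadrants(results: pd.DataFrame, gene_class: str,
                      policy: CallPolicy) -> ClassSummary:
    """Quadrant counts over promoter results for one gene class.

    ``results`` needs columns gene_class, log2fc, p. Probes with
    |log2fc| <= fc_threshold fall in no quadrant.
    """
    if gene_class not in GENE_CLASSES:
        raise ValueError(f"unknown gene class {gene_class!r}")
    if policy.promoter_m is None:
        raise ValueError("volcano quadrants need promoter_m in the policy")
    p_thresh = bonferroni_threshold(policy.promoter_alpha, policy.promoter_m)
    sub = results[results["gene_class"] == gene_class]
    up = sub["log2fc"] > policy.fc_threshold
    dn = sub["log2fc"] < -policy.fc_threshold
    sig = sub["p"] < p_thresh
    return ClassSummary(
        gene_class=gene_class,
        n_total=len(sub),
        n_sig_hyper_control=int((up & sig).sum()),
        n_sig_hypo_control=int((dn & sig).sum()),
        n_trend_hyper_control=int((up & ~sig).sum()),
        n_trend_hypo_control=int((dn & ~sig).sum()),
    )


def class_trend_fraction(n_trend: int, n_sig: int, n_total: int) -> float:
    """Percentage of the class trending in one direction: 100*(trend+sig)/total.

    Display value is rounded to the nearest integer by the caller; this
    returns the raw percentage.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return 100.0 * (n_trend + n_sig) / n_total


def trend_fraction_display(n_trend: int, n_sig: int, n_total: int) -> int:
    return int(round(class_trend_fraction(n_trend, n_sig, n_total)))


@dataclass
class FeatureDistribution:
    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def percentage(self, feature: str) -> float:
        return 100.0 * self.counts.get(feature, 0) / self.total

    def display_percentages(self) -> dict[str, int]:
        return {f: int(round(self.percentage(f))) for f in self.counts}


def feature_distribution(probes: Sequence[Probe]) -> FeatureDistribution:
    """Counts and percentages of probes per genomic feature."""
    if len(probes) == 0:
        raise ValueError("empty probe subset")
    counts: dict[str, int] = {}
    for p in probes:
        feat = p.feature or "intergenic"
        counts[feat] = counts.get(feat, 0) + 1
    return FeatureDistribution(counts=counts)


def class_summary_table(results: pd.DataFrame, policy: CallPolicy) -> pd.DataFrame:
    """All-class quadrant summary with trend fractions in both directions."""
    rows = []
    for cls in GENE_CLASSES:
        s = volcano_quadrants(results, cls, policy)
        if s.n_total == 0:
            rows.append({
                "gene_class": cls, "n_total": 0,
                "n_sig_hyper_control": 0, "n_sig_hypo_control": 0,
                "n_trend_hyper_control": 0, "n_trend_hypo_control": 0,
                "pct_trend_hyper_control": np.nan, "pct_trend_hypo_control": np.nan,
            })
            continue
        rows.append({
            "gene_class": cls,
            "n_total": s.n_total,
            "n_sig_hyper_control": s.n_sig_hyper_control,
            "n_sig_hypo_control": s.n_sig_hypo_control,
            "n_trend_hyper_control": s.n_trend_hyper_control,
            "n_trend_hypo_control": s.n_trend_hypo_control,
            "pct_trend_hyper_control": class_trend_fraction(
                s.n_trend_hyper_control, s.n_sig_hyper_control, s.n_total),
            "pct_trend_hypo_control": class_trend_fraction(
                s.n_trend_hypo_control, s.n_sig_hypo_control, s.n_total),
        })
    return pd.DataFrame(rows).set_index("gene_class", drop=False)
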