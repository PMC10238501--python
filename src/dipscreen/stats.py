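"""Coverage, enrichment and hit-clustering statistics over insertion profiles.

Also houses the library-design calculators: fold coverage (clones per site),
the Poisson-sampling expectation for the fraction of sites observed, and the
union-coverage probability across independent frame-shifted libraries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mapping import InsertionProfile

__all__ = [
    "EnrichmentTable",
    "HitCluster",
    "coverage_fraction",
    "union_coverage",
    "fold_coverage",
    "expected_fraction_observed",
    "display_transform",
    "enrichment",
    "cluster_hits",
]


def coverage_fraction(profile: InsertionProfile, n_sites: int) -> float:
    """Fraction of ``n_sites`` positions observed at least once (any orientation)."""
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    covered = len(profile.positions())
    return covered / n_sites


def union_coverage(p_single: float, k: int) -> float:
    """P(site covered in >=1 of k independent libraries) = 1 - (1-p)^k."""
    if not 0.0 <= p_single <= 1.0:
        raise ValueError("p_single must be in [0, 1]")
    if k < 1:
        raise ValueError("k must be >= 1")
    return 1.0 - (1.0 - p_single) ** k


def fold_coverage(n_clones: int, n_sites: int) -> float:
    """Library depth: clones per available insertion site."""
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    return n_clones / n_sites


def expected_fraction_observed(fold: float) -> float:
    """Fraction of sites seen at least once under Poisson sampling: 1 - e^-fold."""
    if fold < 0:
        raise ValueError("fold must be >= 0")
    return 1.0 - math.exp(-fold)


def display_transform(counts) -> np.ndarray:
    """log10(count + 1), the zero-tolerant scale used for coverage plots."""
    arr = np.asarray(counts, dtype=float)
    if (arr < 0).any():
        raise ValueError("negative counts")
    return np.log10(arr + 1.0)


@dataclass
class EnrichmentTable:
    """Per-position log2 enrichment of profile b over profile a."""

    table: pd.DataFrame  # columns: p, orientation, freq_a, freq_b, log2_enrichment
    pseudocount: float
    label_a: str = ""
    label_b: str = ""

    def value_at(self, p: int, orientation: str = "forward") -> float:
        sel = self.table[
            (self.table["p"] == p) & (self.table["orientation"] == orientation)
        ]
        if sel.empty:
            raise KeyError(f"position {(p, orientation)} not in enrichment table")
        return float(sel["log2_enrichment"].iloc[0])


def enrichment(
    profile_a: InsertionProfile,
    profile_b: InsertionProfile,
    pseudocount: float = 1.0,
) -> EnrichmentTable:
    """log2((f_b + eps) / (f_a + eps)) per (position, orientation).

    ``f`` are within-profile frequencies, so libraries of different depth are
    comparable; ``eps = pseudocount / n_positions`` (positions in the union of
    the two profiles) is a pure frequency-scale constant, making the table
    antisymmetric under profile swap and invariant to rescaling either
    profile's counts.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    keys = sorted(set(profile_a.counts) | set(profile_b.counts))
    if not keys:
        return EnrichmentTable(
            table=pd.DataFrame(
                columns=["p", "orientation", "freq_a", "freq_b", "log2_enrichment"]
            ),
            pseudocount=pseudocount,
            label_a=profile_a.label,
            label_b=profile_b.label,
        )
    tot_a = sum(profile_a.counts.values()) or 1
    tot_b = sum(profile_b.counts.values()) or 1
    eps = pseudocount / len(keys)
    rows = []
    for p, orient in keys:
        fa = profile_a.counts.get((p, orient), 0) / tot_a
        fb = profile_b.counts.get((p, orient), 0) / tot_b
        rows.append(
            {
                "p": p,
                "orientation": orient,
                "freq_a": fa,
                "freq_b": fb,
                "log2_enrichment": math.log2((fb + eps) / (fa + eps)),
            }
        )
    return EnrichmentTable(
        table=pd.DataFrame(rows),
        pseudocount=pseudocount,
        label_a=profile_a.label,
        label_b=profile_b.label,
    )


@dataclass
class HitCluster:
    """A run of nearby amino-acid insertion sites."""

    sites: list[int]
    counts: dict[int, int]
    top_site: int
    total_count: int


def cluster_hits(site_counts: dict[int, int], gap: int = 5) -> list[HitCluster]:
    """1-D single-linkage clustering of amino-acid sites.

    Sites within ``gap`` residues of a neighbour join the same cluster; the
    cluster's top site is its highest-count member (ties broken by the
    smaller site).
    """
    if gap < 1:
        raise ValueError("gap must be >= 1")
    if not site_counts:
        return []
    sites = sorted(site_counts)
    clusters: list[list[int]] = [[sites[0]]]
    for s in sites[1:]:
        if s - clusters[-1][-1] <= gap:
            clusters[-1].append(s)
        else:
            clusters.append([s])
    out = []
    for members in clusters:
        counts = {s: site_counts[s] for s in members}
        top = max(members, key=lambda s: (counts[s], -s))
        out.append(
            HitCluster(
                sites=members,
                counts=counts,
                top_site=top,
                total_count=sum(counts.values()),
            )
        )
    return out
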