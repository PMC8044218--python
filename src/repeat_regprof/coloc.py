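"""Pairwise TFBS co-localisation statistics.

Two sites co-localise when they lie within a fixed genomic window (500 bp
by default) of each other.  Co-localisation proportions are asymmetric by
construction: the proportion of TF i sites near a TF j site uses TF i's
site total as denominator.  Element-derived and rest-of-genome proportions
are compared per ordered TF pair with a pooled one-tailed two-proportion
z-test under Bonferroni control at alpha / k**2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from repeat_regprof.config import AnalysisConfig
from repeat_regprof.intervals import (
    intersect_fraction_indices,
    merge_intervals,
    window_join_indices,
)

logger = logging.getLogger(__name__)

# Star annotation tiers: per-test Bonferroni level, then two fixed tiers.
STAR_TIERS = (1e-4, 1e-5)


@dataclass
class ElementPairCounts:
    """Symmetric counts of elements bound by both TFs of each pair.

    The diagonal holds the number of elements bound by each single TF.
    ``display_transform`` is the exponent applied for heat-map export
    (fourth root compresses the dynamic range).
    """

    tfs: list[str]
    matrix: np.ndarray
    display_transform: float = 0.25

    def transformed(self) -> np.ndarray:
        return np.power(self.matrix.astype(float), self.display_transform)


@dataclass
class ColocalisationMatrix:
    """Ordered-pair co-localisation counts, proportions and test results.

    Row TF's sites near column TF.  ``counts``/``totals``/``proportions``
    describe the element-derived group; ``rest_*`` the rest of the genome.
    Self-pairs are not tested: the diagonal of ``counts`` reports totals
    and the diagonal of z/p/significant is NaN/False.
    """

    tfs: list[str]
    counts: np.ndarray
    totals: np.ndarray
    proportions: np.ndarray
    rest_counts: np.ndarray
    rest_totals: np.ndarray
    rest_proportions: np.ndarray
    z: np.ndarray
    p: np.ndarray
    significant: np.ndarray
    per_test_alpha: float

    def stars(self) -> list[list[str]]:
        """Per-cell significance stars: ``*`` below the Bonferroni per-test
        level, ``**`` below 1e-4, ``***`` below 1e-5."""
        out = []
        for i in range(len(self.tfs)):
            row = []
            for j in range(len(self.tfs)):
                p = self.p[i, j]
                if i == j or not np.isfinite(p) or p >= self.per_test_alpha:
                    row.append("")
                elif p < STAR_TIERS[1]:
                    row.append("***")
                elif p < STAR_TIERS[0]:
                    row.append("**")
                else:
                    row.append("*")
            out.append(row)
        return out


def merge_tf_sites(sites_by_tf: dict[str, list]) -> dict[str, list]:
    """Merge overlapping same-TF sites to their most distal coordinates."""
    return {tf: merge_intervals(sites) for tf, sites in sites_by_tf.items()}


def split_by_elements(sites, elements, f: float = 0.5) -> tuple[list, list]:
    """Exact partition of sites into (element-derived, non-element-derived).

    A site is element-derived when at least a fraction ``f`` of it overlaps
    some element.
    """
    derived_idx = {qi for qi, _ in intersect_fraction_indices(sites, elements, f)}
    derived = [s for i, s in enumerate(sites) if i in derived_idx]
    rest = [s for i, s in enumerate(sites) if i not in derived_idx]
    return derived, rest


def element_pair_counts(elements, sites_by_tf: dict[str, list],
                        f: float = 0.5) -> ElementPairCounts:
    """Number of elements containing binding sites of both TFs of each pair."""
    tfs = list(sites_by_tf)
    bound: list[set[str]] = []
    for tf in tfs:
        pairs = intersect_fraction_indices(sites_by_tf[tf], elements, f)
        bound.append({elements[ti].element_id for _, ti in pairs})
    k = len(tfs)
    matrix = np.zeros((k, k), dtype=np.int64)
    for i in range(k):
        for j in range(k):
            matrix[i, j] = len(bound[i] & bound[j])
    return ElementPairCounts(tfs=tfs, matrix=matrix)


def pairwise_coloc_counts(sites_by_tf: dict[str, list],
                          w: int = 500) -> tuple[list[str], np.ndarray,
                                                 np.ndarray, np.ndarray]:
    """Ordered-pair co-localisation counts and proportions.

    ``counts[i, j]`` = number of TF i sites with >= 1 TF j site within the
    window; ``proportions[i, j] = counts[i, j] / totals[i]`` (NaN when TF i
    has no sites).  The diagonal reports totals (self-pairs untested).
    """
    tfs = list(sites_by_tf)
    k = len(tfs)
    counts = np.zeros((k, k), dtype=np.int64)
    totals = np.array([len(sites_by_tf[tf]) for tf in tfs], dtype=np.int64)
    for i, tf_i in enumerate(tfs):
        for j, tf_j in enumerate(tfs):
            if i == j:
                counts[i, j] = totals[i]
                continue
            counts[i, j] = len(window_join_indices(
                sites_by_tf[tf_i], sites_by_tf[tf_j], w))
    with np.errstate(divide="ignore", invalid="ignore"):
        proportions = np.where(totals[:, None] > 0,
                               counts / totals[:, None], np.nan)
    np.fill_diagonal(proportions, np.nan)
    return tfs, counts, totals, proportions


def two_proportion_ztest(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Pooled-variance two-proportion z-test, one-tailed for group-1 excess.

    z = (k1/n1 - k2/n2) / sqrt(phat (1 - phat) (1/n1 + 1/n2)) with
    phat = (k1 + k2) / (n1 + n2); p = 1 - Phi(z).  The sign of z is kept,
    so depletion of group 1 gives z < 0 and p > 0.5.  The degenerate cases
    phat in {0, 1} return (0, 0.5) and are logged.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("n1 and n2 must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("require 0 <= k <= n in both groups")
    phat = (k1 + k2) / (n1 + n2)
    if phat in (0.0, 1.0):
        logger.info("two_proportion_ztest: degenerate pooled proportion %.0f", phat)
        return 0.0, 0.5
    z = (k1 / n1 - k2 / n2) / np.sqrt(phat * (1 - phat) * (1 / n1 + 1 / n2))
    return float(z), float(norm.sf(z))


def coloc_enrichment_matrix(element_sites_by_tf: dict[str, list],
                            other_sites_by_tf: dict[str, list],
                            config: AnalysisConfig) -> ColocalisationMatrix:
    """Test, per ordered TF pair, whether co-localisation is more frequent
    among element-derived sites than in the rest of the genome.

    Significance is Bonferroni-controlled at ``alpha / k**2`` (the k**2
    denominator includes the untested self-pairs, matching the published
    arithmetic for k = 9: 0.05 / 81 ~= 6.2e-4).
    """
    tfs = list(element_sites_by_tf)
    if set(other_sites_by_tf) != set(tfs):
        raise ValueError("element and rest groups must list the same TFs")
    k = len(tfs)
    if k < 2:
        raise ValueError("need at least two TFs")
    other_sites_by_tf = {tf: other_sites_by_tf[tf] for tf in tfs}

    _, counts, totals, proportions = pairwise_coloc_counts(
        element_sites_by_tf, config.coloc_window)
    _, rcounts, rtotals, rproportions = pairwise_coloc_counts(
        other_sites_by_tf, config.coloc_window)

    per_test_alpha = config.alpha / k**2
    z = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    significant = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            if totals[i] == 0 or rtotals[i] == 0:
                continue
            z[i, j], p[i, j] = two_proportion_ztest(
                int(counts[i, j]), int(totals[i]),
                int(rcounts[i, j]), int(rtotals[i]))
            significant[i, j] = p[i, j] < per_test_alpha
    return ColocalisationMatrix(
        tfs=tfs, counts=counts, totals=totals, proportions=proportions,
        rest_counts=rcounts, rest_totals=rtotals, rest_proportions=rproportions,
        z=z, p=p, significant=significant, per_test_alpha=per_test_alpha,
    )


def pairwise_site_distances(sites_by_tf: dict[str, list],
                            w: int = 500) -> list[tuple[str, str, int]]:
    """Raw midpoint distances of co-localised ordered site pairs (export
    only; no further statistics)."""
    from repeat_regprof.formats_io import as_interval

    out = []
    tfs = list(sites_by_tf)
    for tf_i in tfs:
        for tf_j in tfs:
            if tf_i == tf_j:
                continue
            for a in sites_by_tf[tf_i]:
                aiv = as_interval(a)
                for b in sites_by_tf[tf_j]:
                    biv = as_interval(b)
                    if biv.chrom != aiv.chrom:
                        continue
                    gap_ok = biv.start < aiv.end + w and biv.end > aiv.start - w
                    if gap_ok:
                        out.append((tf_i, tf_j, abs(biv.midpoint - aiv.midpoint)))
    return out
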