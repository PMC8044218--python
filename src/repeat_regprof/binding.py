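"""Element-centred TFBS meta-profiles and consensus-coordinate projection.

A meta-profile aligns a fixed-width window (default 20 kb, 100 bp bins) on
the midpoint of every element copy, counts binding sites per bin,
normalises each element's counts to sum to one, orients minus-strand
windows 5'->3', and averages across elements that contain at least one
site.  Binding-site positions are also projected into the subfamily
consensus frame using the RepStart/RepEnd annotation of each copy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from repeat_regprof.config import AnalysisConfig
from repeat_regprof.formats_io import (
    GenomicInterval,
    RepeatAnnotation,
    as_interval,
)
from repeat_regprof.intervals import BinGrid, bin_feature_counts, intersect_fraction_indices

logger = logging.getLogger(__name__)


@dataclass
class MetaProfile:
    """Per-bin averaged signal over element-centred windows (5'->3' when
    ``oriented``)."""

    bin_width: int
    values: np.ndarray
    n_elements: int
    oriented: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.n_elements < 1:
            raise ValueError("n_elements must be >= 1")

    @property
    def n_bins(self) -> int:
        return len(self.values)


@dataclass
class BindingSummary:
    """Per-TF and per-element binding counts.

    ``per_tf_element_count`` maps TF -> number of elements with >= 1
    assigned site; ``per_element_tfs`` maps element id -> set of bound TFs
    (bound elements only); ``n_bound_elements`` counts elements with any TF.
    """

    per_tf_element_count: dict[str, int]
    per_element_tfs: dict[str, set[str]]
    n_bound_elements: int

    def pct_of_bound(self) -> dict[str, float]:
        """Percentage of bound elements carrying each TF (denominator =
        elements bound by any TF)."""
        if self.n_bound_elements == 0:
            return {tf: 0.0 for tf in self.per_tf_element_count}
        return {tf: 100.0 * n / self.n_bound_elements
                for tf, n in self.per_tf_element_count.items()}


@dataclass(frozen=True)
class ConsensusPosition:
    """A 1-based position in the subfamily consensus sequence."""

    position: int
    element_id: str
    label: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("consensus position must be >= 1")


@dataclass(frozen=True)
class ElementWindow:
    interval: GenomicInterval
    clamped: bool


def element_window(element: RepeatAnnotation, width: int,
                   chrom_sizes: dict[str, int] | None = None) -> ElementWindow:
    """A window of exactly ``width`` bp centred on the element midpoint.

    Windows running off a chromosome edge are flagged ``clamped`` (their
    coordinates are kept unclipped); callers exclude them from averages.
    """
    if width <= 0 or width % 2 != 0:
        raise ValueError("width must be positive and even")
    iv = element.interval
    if iv.length > width:
        raise ValueError(
            f"element {element.element_id} is longer ({iv.length} bp) than the "
            f"window ({width} bp)"
        )
    mid = (iv.start + iv.end) // 2
    start = mid - width // 2
    end = mid + width // 2
    clamped = start < 0
    if chrom_sizes is not None:
        size = chrom_sizes.get(iv.chrom)
        if size is not None and end > size:
            clamped = True
    window = GenomicInterval(iv.chrom, start, end, iv.strand, element.element_id)
    return ElementWindow(interval=window, clamped=clamped)


def tfbs_meta_profile(elements, sites, config: AnalysisConfig,
                      oriented: bool = True,
                      chrom_sizes: dict[str, int] | None = None) -> MetaProfile:
    """Average normalised per-bin TFBS counts over element windows.

    Each element's bin counts are divided by their sum, so every included
    per-element profile sums to 1; elements whose window holds no site are
    excluded (profiles average over elements containing at least one site),
    as are clamped windows.  Minus-strand windows are reversed so that bin 0
    is 5'-most when ``oriented``.
    """
    profiles = []
    n_skipped_clamped = 0
    for el in elements:
        win = element_window(el, config.window_width, chrom_sizes)
        if win.clamped:
            n_skipped_clamped += 1
            continue
        grid = bin_feature_counts(
            BinGrid(win.interval, config.profile_bin), sites)
        total = grid.counts.sum()
        if total == 0:
            continue
        prof = grid.counts / total
        if oriented and el.interval.strand == "-":
            prof = prof[::-1]
        profiles.append(prof)
    if n_skipped_clamped:
        logger.info("tfbs_meta_profile: excluded %d clamped windows",
                    n_skipped_clamped)
    if not profiles:
        raise ValueError("no element window contains a binding site")
    return MetaProfile(
        bin_width=config.profile_bin,
        values=np.mean(profiles, axis=0),
        n_elements=len(profiles),
        oriented=oriented,
    )


def binding_summary(elements, sites_by_tf: dict[str, list],
                    f: float = 0.5) -> BindingSummary:
    """Assign sites to elements by the fractional-overlap rule and count.

    A site belongs to an element when at least a fraction ``f`` of the site
    overlaps that element.  Each element is evaluated independently, so a
    site spanning two elements counts once per element.
    """
    per_element: dict[str, set[str]] = {}
    per_tf: dict[str, int] = {}
    for tf, sites in sites_by_tf.items():
        pairs = intersect_fraction_indices(sites, elements, f)
        bound_ids = {elements[ti].element_id for _, ti in pairs}
        per_tf[tf] = len(bound_ids)
        for eid in bound_ids:
            per_element.setdefault(eid, set()).add(tf)
    return BindingSummary(
        per_tf_element_count=per_tf,
        per_element_tfs=per_element,
        n_bound_elements=len(per_element),
    )


def project_to_consensus(site, element: RepeatAnnotation,
                         label: str = "") -> ConsensusPosition:
    """Project a site midpoint (or integer position) into consensus coords.

    The distance from the element 5' end is added to the copy's consensus
    start (RepStart), walking in the 5'->3' direction of the element.  The
    result is clipped at 1 (RepeatMasker consensus annotations occasionally
    drift slightly).
    """
    if isinstance(site, (int, np.integer)):
        m = int(site)
    else:
        iv = as_interval(site)
        m = (iv.start + iv.end) // 2
    el = element.interval
    if not el.start <= m < el.end:
        raise ValueError(
            f"site midpoint {m} lies outside element {element.element_id}"
        )
    if el.strand == "-":
        offset = el.end - 1 - m
    else:
        offset = m - el.start
    position = max(1, element.consensus_start + offset)
    return ConsensusPosition(position=position, element_id=element.element_id,
                             label=label)


def consensus_to_genomic(position: int, element: RepeatAnnotation) -> int:
    """Inverse of :func:`project_to_consensus` (genomic bp of a consensus
    position on this copy)."""
    offset = position - element.consensus_start
    el = element.interval
    if el.strand == "-":
        return el.end - 1 - offset
    return el.start + offset


def consensus_histogram(positions, bin_width: int = 5,
                        max_pos: int = 6500) -> tuple[np.ndarray, int]:
    """Histogram of consensus positions over [1, max_pos] in fixed bins.

    Returns (counts, n_dropped) where n_dropped counts positions beyond
    ``max_pos`` (also logged).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = math.ceil(max_pos / bin_width)
    counts = np.zeros(n_bins, dtype=np.int64)
    n_dropped = 0
    for pos in positions:
        p = pos.position if isinstance(pos, ConsensusPosition) else int(pos)
        if p > max_pos:
            n_dropped += 1
            continue
        counts[(p - 1) // bin_width] += 1
    if n_dropped:
        logger.info("consensus_histogram: dropped %d positions > %d",
                    n_dropped, max_pos)
    return counts, n_dropped
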