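"""Binned RPKM meta-profiles of epigenetic marks around elements.

The input is aligned read positions (not FASTQ): each read is assigned to
a single 100 bp bin by its midpoint, counts are converted to RPKM
(reads x 1e9 / (bin length x library size)), replicates are averaged,
input controls are subtracted ("normalised RPKM"), and per-element
profiles are averaged within TF-bound and unbound element groups,
orienting minus-strand elements 5'->3'.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from repeat_regprof.config import AnalysisConfig
from repeat_regprof.binding import element_window
from repeat_regprof.formats_io import as_interval

logger = logging.getLogger(__name__)


@dataclass
class CoverageTrack:
    """Per-window, per-bin read counts for one sample of one mark."""

    sample: str
    mark: str
    role: str  # "signal" or "control"
    total_mapped: int
    counts: np.ndarray  # shape (n_windows, n_bins)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.role not in ("signal", "control"):
            raise ValueError("role must be 'signal' or 'control'")
        if self.total_mapped <= 0:
            raise ValueError("total_mapped must be positive")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")


@dataclass
class RpkmProfile:
    """Averaged (normalised) RPKM values per bin for one element group."""

    mark: str
    group: str
    values: np.ndarray
    n_replicates: int
    n_elements: int


def bin_read_midpoints(reads, windows, bin_width: int) -> np.ndarray:
    """Count read midpoints per bin for each window.

    Reads are point-like at profile resolution: each read increments exactly
    one bin (the bin holding its midpoint), so no read is double-counted.
    """
    mids: dict[str, list[int]] = defaultdict(list)
    for r in reads:
        iv = as_interval(r)
        mids[iv.chrom].append(iv.midpoint)
    sorted_mids = {c: np.sort(np.array(v, dtype=np.int64))
                   for c, v in mids.items()}

    n_bins = windows[0].length // bin_width
    out = np.zeros((len(windows), n_bins), dtype=np.int64)
    for wi, win in enumerate(windows):
        if win.length != n_bins * bin_width:
            raise ValueError("all windows must share the same length")
        pos = sorted_mids.get(win.chrom)
        if pos is None:
            continue
        lo = np.searchsorted(pos, win.start, side="left")
        hi = np.searchsorted(pos, win.end, side="left")
        if hi > lo:
            bins = (pos[lo:hi] - win.start) // bin_width
            np.add.at(out[wi], bins, 1)
    return out


def rpkm_normalise(counts, bin_width: int, total_mapped: int) -> np.ndarray:
    """RPKM = count x 1e9 / (bin_width x total_mapped)."""
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    return np.asarray(counts, dtype=float) * 1e9 / (bin_width * total_mapped)


def average_replicates(profiles: list[np.ndarray]) -> np.ndarray:
    """Element-wise mean across replicate arrays of identical shape."""
    if not profiles:
        raise ValueError("need at least one replicate")
    arrays = [np.asarray(p, dtype=float) for p in profiles]
    shape = arrays[0].shape
    for a in arrays[1:]:
        if a.shape != shape:
            raise ValueError("replicate arrays must share one shape")
    return np.mean(arrays, axis=0)


def subtract_control(mark: np.ndarray, control: np.ndarray) -> np.ndarray:
    """Normalised RPKM: mark minus input control (may go negative)."""
    mark = np.asarray(mark, dtype=float)
    control = np.asarray(control, dtype=float)
    if mark.shape != control.shape:
        raise ValueError("mark and control arrays must share one shape")
    return mark - control


def group_meta_profile(per_element: np.ndarray, element_ids: list[str],
                       strands: list[str], groups: dict[str, str],
                       oriented: bool = True) -> dict[str, np.ndarray]:
    """Average per-element bin profiles within each element group.

    ``groups`` maps element id -> group label (e.g. "bound"/"unbound");
    minus-strand rows are reversed first when ``oriented``.  Empty groups
    are omitted with a logged warning.
    """
    per_element = np.asarray(per_element, dtype=float)
    if per_element.shape[0] != len(element_ids) or len(strands) != len(element_ids):
        raise ValueError("per_element rows, element_ids and strands must align")
    rows: dict[str, list[np.ndarray]] = defaultdict(list)
    for row, eid, strand in zip(per_element, element_ids, strands):
        group = groups.get(eid)
        if group is None:
            continue
        if oriented and strand == "-":
            row = row[::-1]
        rows[group].append(row)
    wanted = set(groups.values())
    out = {}
    for group in sorted(wanted):
        if not rows.get(group):
            logger.warning("group_meta_profile: group %r is empty; omitted", group)
            continue
        out[group] = np.mean(rows[group], axis=0)
    return out


def mark_meta_profiles(elements, tracks: list[CoverageTrack],
                       groups: dict[str, str], config: AnalysisConfig,
                       oriented: bool = True) -> list[RpkmProfile]:
    """Full profiling pipeline for a set of tracks sharing one window grid.

    Per mark: convert each replicate to RPKM, average signal replicates,
    average control replicates, subtract control (when present), then
    average per group.  Track ``counts`` rows must align with ``elements``.
    """
    strands = [el.interval.strand for el in elements]
    ids = [el.element_id for el in elements]

    by_mark: dict[str, dict[str, list[CoverageTrack]]] = defaultdict(
        lambda: {"signal": [], "control": []})
    for t in tracks:
        by_mark[t.mark][t.role].append(t)

    out: list[RpkmProfile] = []
    for mark in by_mark:
        signals = by_mark[mark]["signal"]
        controls = by_mark[mark]["control"]
        if not signals:
            logger.warning("mark %r has no signal tracks; skipped", mark)
            continue
        sig = average_replicates([
            rpkm_normalise(t.counts, config.profile_bin, t.total_mapped)
            for t in signals])
        if controls:
            ctl = average_replicates([
                rpkm_normalise(t.counts, config.profile_bin, t.total_mapped)
                for t in controls])
            sig = subtract_control(sig, ctl)
        grouped = group_meta_profile(sig, ids, strands, groups, oriented)
        for group, values in grouped.items():
            n_in_group = sum(1 for e in ids if groups.get(e) == group)
            out.append(RpkmProfile(mark=mark, group=group, values=values,
                                   n_replicates=len(signals),
                                   n_elements=n_in_group))
    return out


def element_windows(elements, config: AnalysisConfig,
                    chrom_sizes: dict[str, int] | None = None):
    """Unclamped element windows plus the matching element subset."""
    kept_elements, windows = [], []
    for el in elements:
        win = element_window(el, config.window_width, chrom_sizes)
        if win.clamped:
            continue
        kept_elements.append(el)
        windows.append(win.interval)
    return kept_elements, windows
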