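"""Differential-transcript TSS analysis and the rotation-permutation
enrichment test.

Transcripts are classified by strict fold-change thresholds (up: fc > 2,
down: fc < 0.5 by default), their strand-aware start positions are taken
as transcription start sites (TSS), and the overlap of TSSs with repeat
elements is tested against a rotation null: each permutation circularly
shifts the TSS positions of every chromosome by an independent uniform
offset, preserving intra-chromosomal TSS spacing while randomising their
placement relative to the fixed elements.  The mean rotated overlap count
divided by the TSS total gives the expected probability for an exact
one-sided binomial test.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom

from repeat_regprof.config import AnalysisConfig
from repeat_regprof.formats_io import (
    GenomicInterval,
    TranscriptRecord,
    as_interval,
)
from repeat_regprof.intervals import window_join_indices

logger = logging.getLogger(__name__)

CLASSES = ("up", "down", "unchanged")


@dataclass(frozen=True)
class TssRecord:
    chrom: str
    position: int  # 0-based bp
    strand: str
    transcript_id: str
    tss_class: str = "unchanged"

    def as_interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.position, self.position + 1,
                               self.strand, self.transcript_id)


@dataclass
class EnrichmentResult:
    """Observed versus rotation-expected TSS-in-element overlap."""

    observed: int
    n_tss: int
    expected_p: float
    n_permutations: int
    p_value: float
    direction: str  # "enriched" or "depleted"
    seed: int | None = None


def classify_transcripts(records, config: AnalysisConfig,
                         apply_p_filter: bool = False) -> dict[str, str]:
    """Map transcript id -> class by strict fold-change thresholds.

    up iff fc > up_fc, down iff fc < down_fc (both strict; fc exactly at a
    threshold is unchanged).  With ``apply_p_filter``, up/down additionally
    require p_value < de_p_cut.
    """
    out = {}
    for r in records:
        if r.fold_change > config.up_fc:
            cls = "up"
        elif r.fold_change < config.down_fc:
            cls = "down"
        else:
            cls = "unchanged"
        if apply_p_filter and cls != "unchanged" and not r.p_value < config.de_p_cut:
            cls = "unchanged"
        out[r.transcript_id] = cls
    return out


def transcript_tss(record: TranscriptRecord, tss_class: str = "unchanged") -> TssRecord:
    """Strand-aware TSS: interval start on +, last base (end - 1) on -."""
    iv = record.interval
    if iv.strand == "+":
        pos = iv.start
    elif iv.strand == "-":
        pos = iv.end - 1
    else:
        raise ValueError("transcript strand must be + or -")
    return TssRecord(chrom=iv.chrom, position=pos, strand=iv.strand,
                     transcript_id=record.transcript_id, tss_class=tss_class)


def tss_by_class(records, config: AnalysisConfig,
                 apply_p_filter: bool = False) -> dict[str, list[TssRecord]]:
    """Group strand-aware TSSs by differential-expression class."""
    classes = classify_transcripts(records, config, apply_p_filter)
    out: dict[str, list[TssRecord]] = {c: [] for c in CLASSES}
    for r in records:
        cls = classes[r.transcript_id]
        out[cls].append(transcript_tss(r, cls))
    return out


def tss_element_overlap(tss_list, elements) -> tuple[int, list[tuple]]:
    """TSSs falling inside elements (half-open: start <= pos < end).

    Returns (number of TSSs inside any element, list of all (tss, element)
    pairs).
    """
    boundaries = _membership_boundaries(elements)
    count = 0
    matches = []
    for tss in tss_list:
        chrom_bounds = boundaries.get(tss.chrom)
        inside = False
        if chrom_bounds is not None:
            idx = np.searchsorted(chrom_bounds, tss.position, side="right")
            inside = bool(idx % 2)
        if inside:
            count += 1
        for el in elements:
            iv = as_interval(el)
            if iv.chrom == tss.chrom and iv.start <= tss.position < iv.end:
                matches.append((tss, el))
    return count, matches


def proximity_profile(elements_by_group: dict[str, list],
                      tss_by_class_map: dict[str, list[TssRecord]],
                      config: AnalysisConfig) -> pd.DataFrame:
    """Fraction of each group's elements with a class TSS within d bp,
    for d = step, 2 step, ..., max.

    Proportions are non-decreasing in d.  Empty groups are omitted with a
    logged warning.
    """
    rows = []
    distances = range(config.proximity_step,
                      config.proximity_max + 1, config.proximity_step)
    for group, elements in elements_by_group.items():
        if not elements:
            logger.warning("proximity_profile: group %r is empty; omitted", group)
            continue
        for cls, tss_list in tss_by_class_map.items():
            tss_ivs = [t.as_interval() for t in tss_list]
            for d in distances:
                n_within = len(window_join_indices(elements, tss_ivs, d))
                rows.append({
                    "group": group,
                    "tss_class": cls,
                    "distance": d,
                    "n_elements": len(elements),
                    "n_within": n_within,
                    "proportion": n_within / len(elements),
                })
    return pd.DataFrame(rows)


def _membership_boundaries(elements) -> dict[str, np.ndarray]:
    """Flattened sorted start/end boundaries of the element base set per
    chromosome (bookended spans coalesced), for O(log n) point membership."""
    by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for el in elements:
        iv = as_interval(el)
        by_chrom[iv.chrom].append((iv.start, iv.end))
    out = {}
    for chrom, spans in by_chrom.items():
        spans.sort()
        merged = []
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append((cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append((cur_s, cur_e))
        out[chrom] = np.array([b for span in merged for b in span], dtype=np.int64)
    return out


def rotation_null_counts(tss_list, elements, chrom_lengths: dict[str, int],
                         n_perm: int, seed: int,
                         mode: str = "per-chromosome") -> np.ndarray:
    """Rotated overlap count for each permutation.

    Each permutation draws a uniform offset in [0, L) per chromosome
    (``mode="per-chromosome"``) or a single offset applied to every
    chromosome modulo its own length (``mode="single"``), shifts all TSS
    positions circularly, and counts how many land inside an element.
    Elements stay fixed.  Deterministic given ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if mode not in ("per-chromosome", "single"):
        raise ValueError(f"unknown rotation mode: {mode!r}")
    positions: dict[str, list[int]] = defaultdict(list)
    for tss in tss_list:
        if tss.chrom not in chrom_lengths:
            raise ValueError(f"chromosome {tss.chrom} missing from chrom_lengths")
        positions[tss.chrom].append(tss.position)
    boundaries = _membership_boundaries(elements)
    for chrom in boundaries:
        if chrom not in chrom_lengths:
            raise ValueError(f"chromosome {chrom} missing from chrom_lengths")

    rng = np.random.default_rng(seed)
    counts = np.zeros(n_perm, dtype=np.int64)
    if mode == "single":
        max_len = max(chrom_lengths.values())
        shared = rng.integers(0, max_len, size=n_perm)
    for chrom in sorted(positions):
        pos = np.array(positions[chrom], dtype=np.int64)
        L = chrom_lengths[chrom]
        bounds = boundaries.get(chrom)
        offsets = (shared % L) if mode == "single" else rng.integers(0, L, size=n_perm)
        if bounds is None or len(bounds) == 0:
            continue
        shifted = (pos[None, :] + offsets[:, None]) % L
        inside = np.searchsorted(bounds, shifted, side="right") % 2 == 1
        counts += inside.sum(axis=1)
    return counts


def rotation_expected_probability(tss_list, elements,
                                  chrom_lengths: dict[str, int],
                                  n_perm: int, seed: int,
                                  mode: str = "per-chromosome") -> float:
    """Expected probability of a TSS lying in an element under rotation:
    mean rotated overlap count over permutations, divided by the TSS
    total."""
    if not tss_list:
        raise ValueError("tss_list must be non-empty")
    counts = rotation_null_counts(tss_list, elements, chrom_lengths,
                                  n_perm, seed, mode)
    return float(counts.mean() / len(tss_list))


def binomial_enrichment(observed: int, n_tss: int, expected_p: float,
                        n_permutations: int = 0,
                        seed: int | None = None) -> EnrichmentResult:
    """One-sided exact binomial test in the observed direction.

    Enriched (observed > expected mean): p = P(X >= observed); depleted
    otherwise: p = P(X <= observed), X ~ Binomial(n_tss, expected_p).
    """
    if not 0 <= observed <= n_tss:
        raise ValueError("require 0 <= observed <= n_tss")
    if not 0 <= expected_p <= 1:
        raise ValueError("expected_p must be in [0, 1]")
    mean = expected_p * n_tss
    if observed > mean:
        direction = "enriched"
        p_value = float(binom.sf(observed - 1, n_tss, expected_p))
    else:
        direction = "depleted"
        p_value = float(binom.cdf(observed, n_tss, expected_p))
    if expected_p in (0.0, 1.0):
        logger.info("binomial_enrichment: degenerate expected_p=%g", expected_p)
    return EnrichmentResult(observed=observed, n_tss=n_tss,
                            expected_p=expected_p,
                            n_permutations=n_permutations,
                            p_value=p_value, direction=direction, seed=seed)


def associate_with_known(novel_transcripts, known_transcripts) -> list[tuple]:
    """Associate novel with known transcripts sharing >= 1 bp of exon
    overlap on the same chromosome and strand."""
    by_key: dict[tuple[str, str], list[tuple[GenomicInterval, TranscriptRecord]]]
    by_key = defaultdict(list)
    for known in known_transcripts:
        for exon in known.exons:
            by_key[(exon.chrom, exon.strand)].append((exon, known))
    out = []
    for novel in novel_transcripts:
        hit_ids = set()
        for exon in novel.exons:
            for kexon, known in by_key.get((exon.chrom, exon.strand), ()):
                if kexon.start < exon.end and kexon.end > exon.start:
                    if known.transcript_id not in hit_ids:
                        hit_ids.add(known.transcript_id)
                        out.append((novel, known))
    return out
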