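"""Readers and writers for every external format the pipeline touches.

All genomic coordinates are normalised to one internal convention:
0-based, half-open ``[start, end)`` (BED-native).  Consensus coordinates
of repeat copies stay 1-based inclusive, as RepeatMasker reports them.
"""

from __future__ import annotations

import gzip
import logging
import os
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

VALID_STRANDS = ("+", "-", ".")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start: got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}: got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def as_interval(obj) -> GenomicInterval:
    """Return the :class:`GenomicInterval` of a record (or the record itself)."""
    if isinstance(obj, GenomicInterval):
        return obj
    iv = getattr(obj, "interval", None)
    if isinstance(iv, GenomicInterval):
        return iv
    raise TypeError(f"cannot interpret {type(obj).__name__} as a genomic interval")


@dataclass(frozen=True)
class RepeatAnnotation:
    """One repeat copy with its mapping into the subfamily consensus.

    ``consensus_start``/``consensus_end`` are 1-based positions in the
    subfamily consensus sequence (RepeatMasker RepStart/RepEnd).
    """

    interval: GenomicInterval
    rep_name: str
    rep_class: str = ""
    rep_family: str = ""
    consensus_start: int = 1
    consensus_end: int = 1

    def __post_init__(self) -> None:
        if not (1 <= self.consensus_start <= self.consensus_end):
            raise ValueError(
                "require consensus_end >= consensus_start >= 1: "
                f"got {self.consensus_start}..{self.consensus_end}"
            )

    @property
    def element_id(self) -> str:
        iv = self.interval
        return f"{iv.chrom}:{iv.start}-{iv.end}({iv.strand})"


@dataclass(frozen=True)
class TFBSRecord:
    """One transcription-factor binding interval."""

    interval: GenomicInterval
    tf: str
    context: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if not self.tf:
            raise ValueError("tf label must be non-empty")


@dataclass(frozen=True)
class TranscriptRecord:
    """A transcript with exon structure and differential-expression stats."""

    transcript_id: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...]
    fold_change: float
    p_value: float
    q_value: float

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"transcript {self.transcript_id}: strand must be + or -")
        if self.fold_change <= 0:
            raise ValueError(f"transcript {self.transcript_id}: fold_change must be > 0")
        for val, label in ((self.p_value, "p_value"), (self.q_value, "q_value")):
            if not 0 <= val <= 1:
                raise ValueError(f"transcript {self.transcript_id}: {label} outside [0, 1]")
        for exon in self.exons:
            if exon.chrom != self.interval.chrom or exon.strand != self.interval.strand:
                raise ValueError(
                    f"transcript {self.transcript_id}: exon on different chrom/strand"
                )
            if exon.start < self.interval.start or exon.end > self.interval.end:
                raise ValueError(
                    f"transcript {self.transcript_id}: exon outside transcript span"
                )


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def _open_text(path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _parse_int(text: str, line_no: int, path, column: str) -> int:
    try:
        return int(text)
    except ValueError:
        raise ValueError(
            f"{path}: line {line_no}: column {column!r} is not an integer: {text!r}"
        ) from None


# ---------------------------------------------------------------------------
# RepeatMasker tables
# ---------------------------------------------------------------------------

_UCSC_REQUIRED = (
    "genoName", "genoStart", "genoEnd", "strand",
    "repName", "repClass", "repFamily", "repStart", "repEnd", "repLeft",
)
_SIMPLE_REQUIRED = (
    "chrom", "start", "end", "strand", "rep_name", "consensus_start", "consensus_end",
)


def read_repeatmasker(path, rep_name_filter: str | None = None,
                      dialect: str = "simple") -> list[RepeatAnnotation]:
    """Read a RepeatMasker annotation table.

    ``dialect="ucsc"`` reads a UCSC rmsk table dump (tab-separated, header
    line possibly prefixed with ``#``, optionally gzipped).  For plus-strand
    rows the consensus span is repStart..repEnd; for minus-strand rows UCSC
    stores the consensus start position in repLeft, so consensus_start is
    taken from repLeft.  ``dialect="simple"`` reads a plain TSV with
    explicit consensus_start/consensus_end columns and sidesteps the UCSC
    minus-strand convention.

    ``rep_name_filter`` keeps only rows whose subfamily name matches exactly.
    """
    if dialect not in ("ucsc", "simple"):
        raise ValueError(f"unknown RepeatMasker dialect: {dialect!r}")
    required = _UCSC_REQUIRED if dialect == "ucsc" else _SIMPLE_REQUIRED

    records: list[RepeatAnnotation] = []
    with _open_text(path) as fh:
        header: dict[str, int] | None = None
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.lstrip("#").split("\t")
            if header is None:
                header = {name: i for i, name in enumerate(fields)}
                missing = [c for c in required if c not in header]
                if missing:
                    raise ValueError(
                        f"{path}: header lacks required {dialect} columns: {missing}"
                    )
                continue
            if len(fields) < len(header):
                raise ValueError(f"{path}: line {line_no}: expected "
                                 f"{len(header)} columns, got {len(fields)}")

            def col(name: str) -> str:
                return fields[header[name]]

            try:
                if dialect == "ucsc":
                    strand = col("strand")
                    if strand == "C":  # RepeatMasker .out convention
                        strand = "-"
                    rep_name = col("repName")
                    if rep_name_filter is not None and rep_name != rep_name_filter:
                        continue
                    start = _parse_int(col("genoStart"), line_no, path, "genoStart")
                    end = _parse_int(col("genoEnd"), line_no, path, "genoEnd")
                    rep_end = _parse_int(col("repEnd"), line_no, path, "repEnd")
                    if strand == "-":
                        cons_start = _parse_int(col("repLeft"), line_no, path, "repLeft")
                    else:
                        cons_start = _parse_int(col("repStart"), line_no, path, "repStart")
                    record = RepeatAnnotation(
                        interval=GenomicInterval(col("genoName"), start, end,
                                                 strand, rep_name),
                        rep_name=rep_name,
                        rep_class=col("repClass"),
                        rep_family=col("repFamily"),
                        consensus_start=cons_start,
                        consensus_end=rep_end,
                    )
                else:
                    rep_name = col("rep_name")
                    if rep_name_filter is not None and rep_name != rep_name_filter:
                        continue
                    start = _parse_int(col("start"), line_no, path, "start")
                    end = _parse_int(col("end"), line_no, path, "end")
                    record = RepeatAnnotation(
                        interval=GenomicInterval(col("chrom"), start, end,
                                                 col("strand"), rep_name),
                        rep_name=rep_name,
                        rep_class=col("rep_class") if "rep_class" in header else "",
                        rep_family=col("rep_family") if "rep_family" in header else "",
                        consensus_start=_parse_int(col("consensus_start"), line_no,
                                                   path, "consensus_start"),
                        consensus_end=_parse_int(col("consensus_end"), line_no,
                                                 path, "consensus_end"),
                    )
            except ValueError as exc:
                raise ValueError(f"{path}: line {line_no}: {exc}") from None
            records.append(record)
    if header is None:
        raise ValueError(f"{path}: empty file (header expected)")
    return records


def write_repeat_tsv(records: Sequence[RepeatAnnotation], path) -> None:
    """Write repeat annotations in the simple TSV dialect."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tstrand\trep_name\trep_class\trep_family\t"
                 "consensus_start\tconsensus_end\n")
        for r in records:
            iv = r.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\t{r.rep_name}\t"
                     f"{r.rep_class}\t{r.rep_family}\t{r.consensus_start}\t"
                     f"{r.consensus_end}\n")


# ---------------------------------------------------------------------------
# Primary-assembly filter
# ---------------------------------------------------------------------------

_ALT_CHROM_RE = re.compile(r"(_alt|_random|_fix)$")


def is_primary_chromosome(chrom: str) -> bool:
    return not (chrom.startswith("chrUn") or _ALT_CHROM_RE.search(chrom))


def filter_primary_chromosomes(records: Iterable) -> list:
    """Drop records on alternate/patch/unplaced sequences (UCSC naming)."""
    return [r for r in records if is_primary_chromosome(as_interval(r).chrom)]


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def _iter_bed_lines(path):
    with _open_text(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            yield line_no, line.split("\t")


def read_bed(path) -> list[GenomicInterval]:
    """Read a BED3+ file into intervals (name from column 4, strand from 6)."""
    out = []
    for line_no, fields in _iter_bed_lines(path):
        if len(fields) < 3:
            raise ValueError(f"{path}: line {line_no}: fewer than 3 BED columns")
        start = _parse_int(fields[1], line_no, path, "start")
        end = _parse_int(fields[2], line_no, path, "end")
        if end <= start:
            raise ValueError(f"{path}: line {line_no}: end <= start")
        name = fields[3] if len(fields) > 3 and fields[3] else "."
        strand = fields[5] if len(fields) > 5 and fields[5] in VALID_STRANDS else "."
        out.append(GenomicInterval(fields[0], start, end, strand, name))
    return out


def read_tf_sites(path, tf_label_source: str = "column",
                  context: str = "", source: str = "") -> list[TFBSRecord]:
    """Read TF binding sites from a BED file or a directory of per-TF BEDs.

    ``tf_label_source="column"`` takes the TF label from BED column 4;
    ``"filename"`` labels every record of a file by the file's stem (the
    natural layout for per-TF meta-cluster downloads).
    """
    if tf_label_source not in ("column", "filename"):
        raise ValueError(f"unknown tf_label_source: {tf_label_source!r}")
    paths: list = []
    if os.path.isdir(path):
        paths = sorted(
            os.path.join(path, p) for p in os.listdir(path)
            if p.endswith((".bed", ".bed.gz"))
        )
        if not paths:
            raise ValueError(f"{path}: directory contains no .bed files")
    else:
        paths = [path]

    records: list[TFBSRecord] = []
    for p in paths:
        stem = re.sub(r"\.bed(\.gz)?$", "", os.path.basename(p))
        for line_no, fields in _iter_bed_lines(p):
            if len(fields) < 3:
                raise ValueError(f"{p}: line {line_no}: fewer than 3 BED columns")
            start = _parse_int(fields[1], line_no, p, "start")
            end = _parse_int(fields[2], line_no, p, "end")
            if end <= start:
                raise ValueError(f"{p}: line {line_no}: end <= start")
            if tf_label_source == "column":
                if len(fields) < 4 or not fields[3] or fields[3] == ".":
                    raise ValueError(f"{p}: line {line_no}: missing TF label in column 4")
                tf = fields[3]
            else:
                tf = stem
            strand = fields[5] if len(fields) > 5 and fields[5] in VALID_STRANDS else "."
            records.append(TFBSRecord(
                interval=GenomicInterval(fields[0], start, end, strand, tf),
                tf=tf, context=context, source=source,
            ))
    return records


def write_bed(records: Iterable, path) -> None:
    """Write records as BED6 (score column fixed at 0)."""
    with open(path, "w") as fh:
        for r in records:
            iv = as_interval(r)
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# Transcript table
# ---------------------------------------------------------------------------

_TRANSCRIPT_COLUMNS = ("id", "chrom", "start", "end", "strand",
                       "exon_starts", "exon_ends", "fc", "pval", "qval")


def _parse_int_list(text: str) -> list[int]:
    return [int(x) for x in text.strip().strip(",").split(",") if x != ""]


def read_transcript_table(path) -> list[TranscriptRecord]:
    """Read a differential-transcript TSV.

    Expected columns: id, chrom, start, end, strand, exon_starts,
    exon_ends (comma-separated), fc, pval, qval.  Rows with missing or
    non-positive fold change are dropped and the count is logged.
    """
    records: list[TranscriptRecord] = []
    n_dropped = 0
    with _open_text(path) as fh:
        header: dict[str, int] | None = None
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.lstrip("#").split("\t")
            if header is None:
                header = {name: i for i, name in enumerate(fields)}
                missing = [c for c in _TRANSCRIPT_COLUMNS if c not in header]
                if missing:
                    raise ValueError(f"{path}: header lacks columns: {missing}")
                continue

            def col(name: str) -> str:
                return fields[header[name]]

            strand = col("strand")
            if strand not in ("+", "-"):
                raise ValueError(f"{path}: line {line_no}: strand must be + or -, "
                                 f"got {strand!r}")
            fc_text = col("fc").strip()
            if fc_text in ("", "NA", "nan", "NaN"):
                n_dropped += 1
                continue
            fc = float(fc_text)
            if fc <= 0 or not np.isfinite(fc):
                n_dropped += 1
                continue
            start = _parse_int(col("start"), line_no, path, "start")
            end = _parse_int(col("end"), line_no, path, "end")
            exon_starts = _parse_int_list(col("exon_starts"))
            exon_ends = _parse_int_list(col("exon_ends"))
            if len(exon_starts) != len(exon_ends):
                raise ValueError(f"{path}: line {line_no}: exon_starts/exon_ends "
                                 "length mismatch")
            chrom = col("chrom")
            try:
                exons = tuple(
                    GenomicInterval(chrom, s, e, strand)
                    for s, e in zip(exon_starts, exon_ends)
                )
                records.append(TranscriptRecord(
                    transcript_id=col("id"),
                    interval=GenomicInterval(chrom, start, end, strand, col("id")),
                    exons=exons,
                    fold_change=fc,
                    p_value=float(col("pval")),
                    q_value=float(col("qval")),
                ))
            except ValueError as exc:
                raise ValueError(f"{path}: line {line_no}: {exc}") from None
    if n_dropped:
        logger.info("read_transcript_table: dropped %d rows with missing or "
                    "non-positive fold change", n_dropped)
    return records


def write_transcript_table(records: Sequence[TranscriptRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TRANSCRIPT_COLUMNS) + "\n")
        for r in records:
            iv = r.interval
            starts = ",".join(str(e.start) for e in r.exons)
            ends = ",".join(str(e.end) for e in r.exons)
            fh.write(f"{r.transcript_id}\t{iv.chrom}\t{iv.start}\t{iv.end}\t"
                     f"{iv.strand}\t{starts}\t{ends}\t{r.fold_change:.6g}\t"
                     f"{r.p_value:.6g}\t{r.q_value:.6g}\n")


# ---------------------------------------------------------------------------
# chrom.sizes, FASTA, JASPAR PFM
# ---------------------------------------------------------------------------

def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with _open_text(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: line {line_no}: expected two columns")
            sizes[parts[0]] = _parse_int(parts[1], line_no, path, "size")
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def read_fasta(path) -> dict[str, str]:
    """Read a (possibly wrapped) FASTA file into an upper-case dict."""
    seqs: dict[str, list[str]] = {}
    current: list[str] | None = None
    with _open_text(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                current = seqs.setdefault(name, [])
            else:
                if current is None:
                    raise ValueError(f"{path}: sequence data before first header")
                current.append(line.upper())
    return {name: "".join(parts) for name, parts in seqs.items()}


def write_fasta(seqs: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_element_sequences(genome: dict[str, str],
                              elements: Sequence[RepeatAnnotation],
                              strand_aware: bool = True) -> dict[str, str]:
    """Extract element sequences, reverse-complementing minus-strand copies.

    Strand-aware extraction means position 0 of each returned sequence is
    the 5' end of the element, so offsets map directly into consensus
    coordinates via consensus_start.
    """
    out: dict[str, str] = {}
    for el in elements:
        iv = el.interval
        if iv.chrom not in genome:
            raise KeyError(f"chromosome {iv.chrom} absent from genome")
        seq = genome[iv.chrom][iv.start:iv.end]
        if strand_aware and iv.strand == "-":
            seq = reverse_complement(seq)
        out[el.element_id] = seq
    return out


def read_jaspar_pfm(path) -> list[tuple[str, str, np.ndarray]]:
    """Read JASPAR-format PFM text into (matrix_id, name, 4xW counts) tuples.

    Rows are in A, C, G, T order.  Parsing is delegated to Bio.motifs.
    """
    from Bio import motifs

    with open(path) as fh:
        parsed = motifs.parse(fh, "jaspar")
    out = []
    for m in parsed:
        counts = np.array([list(m.counts[base]) for base in "ACGT"], dtype=float)
        out.append((getattr(m, "matrix_id", "") or "", m.name or "", counts))
    return out


def write_jaspar_pfm(matrix_id: str, name: str, counts: np.ndarray, path) -> None:
    counts = np.asarray(counts)
    with open(path, "w") as fh:
        fh.write(f">{matrix_id} {name}\n")
        for base, row in zip("ACGT", counts):
            cells = " ".join(f"{v:10.2f}" for v in row)
            fh.write(f"{base} [{cells} ]\n")
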