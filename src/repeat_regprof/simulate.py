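"""Seeded generator of toy genomes and all pipeline inputs.

The generator emulates the statistical structure the analysis assumes —
a repeat subfamily with a TFBS-rich 5' subregion, pairwise TF coupling
restricted to elements, element-derived TSSs of up-regulated transcripts,
and active epigenetic marks on bound elements — with every planted
quantity recorded in a truth dictionary so closed-loop tests can assert
recovery.  Background TF sites follow a homogeneous Poisson process per
chromosome, the simplest model under which the null-distribution tests
are analytic.  Sequences are i.i.d. uniform bases with planted motif
words; no repeat-phylogeny realism is attempted.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np

from repeat_regprof.formats_io import (
    GenomicInterval,
    RepeatAnnotation,
    TFBSRecord,
    TranscriptRecord,
    reverse_complement,
    write_bed,
    write_chrom_sizes,
    write_fasta,
    write_jaspar_pfm,
    write_repeat_tsv,
    write_transcript_table,
)

DEFAULT_TFS = ("ESR1", "SFPQ", "MYC", "FOXA1", "NR2F2",
               "CTCF", "E2F1", "KDM5B", "ZNF143")

# Planted motif: a strongly conserved 12-mer placed at a fixed consensus
# offset inside the 5' subregion of most elements.
MOTIF_WORD = "AGGTCACAGTGA"
MOTIF_CONSENSUS_OFFSET = 300  # 0-based offset from the element 5' end


def _default_chroms() -> dict[str, int]:
    return {"chr1": 1_000_000, "chr2": 1_000_000, "chr3": 1_000_000}


def _default_tss_fraction() -> dict[str, float]:
    # The planted up-TSS fraction must exceed the element coverage fraction
    # by a wide margin (the toy genome covers ~12% with elements, so 0.4 is
    # ~3.3x coverage; the published genome-scale excess is far larger still).
    return {"up": 0.4, "down": 0.0, "unchanged": 0.0}


@dataclass
class FixtureSpec:
    """Parameters of the synthetic dataset.

    Rates are per TF; ``five_prime_enrichment`` multiplies the background
    site density inside the 900 bp 5' subregion of each element (the toy
    analogue of the promoter-dense 5' UTR).  ``coupling[(a, b)] = q``
    plants, for each in-element site of TF ``a``, a TF ``b`` site within
    ``coupling_distance`` bp with probability q.
    ``tss_in_element_fraction[cls]`` is the fraction of class-``cls`` TSSs
    placed uniformly inside elements (the rest are uniform genome-wide).
    """

    chrom_lengths: dict[str, int] = field(default_factory=_default_chroms)
    n_elements: int = 60
    element_length: int = 6_000
    five_prime_len: int = 900
    tf_names: tuple[str, ...] = DEFAULT_TFS
    background_rate: float = 100.0  # sites per Mb per TF
    five_prime_enrichment: float = 2.0
    # None -> couple the first two TFs at q = 0.8 (the planted default)
    coupling: dict[tuple[str, str], float] | None = None
    coupling_distance: int = 100
    site_length: int = 200
    n_transcripts: int = 300
    class_fractions: dict[str, float] = field(
        default_factory=lambda: {"up": 0.3, "down": 0.3, "unchanged": 0.4})
    tss_in_element_fraction: dict[str, float] = field(
        default_factory=_default_tss_fraction)
    signal_reads_per_bin: float = 5.0   # in active 5' subregions
    noise_reads_per_bin: float = 0.5    # genome-wide background
    profile_bin: int = 100
    read_length: int = 50
    marks: tuple[str, ...] = ("DNase", "H3K27ac")
    n_replicates: int = 2
    motif_fraction: float = 0.8  # fraction of elements carrying the motif word
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.coupling is None:
            self.coupling = ({(self.tf_names[0], self.tf_names[1]): 0.8}
                             if len(self.tf_names) >= 2 else {})

    def validate(self) -> None:
        if self.background_rate < 0 or self.five_prime_enrichment < 0:
            raise ValueError("rates must be >= 0")
        for pair, q in self.coupling.items():
            if not 0 <= q <= 1:
                raise ValueError(f"coupling probability {pair} outside [0, 1]")
            for tf in pair:
                if tf not in self.tf_names:
                    raise ValueError(f"coupling names unknown TF {tf!r}")
        for cls, frac in self.tss_in_element_fraction.items():
            if not 0 <= frac <= 1:
                raise ValueError(f"tss_in_element_fraction[{cls}] outside [0, 1]")
        if self.element_length >= min(self.chrom_lengths.values()):
            raise ValueError("element_length must be below the shortest chromosome")
        if self.five_prime_len > self.element_length:
            raise ValueError("five_prime_len must not exceed element_length")


@dataclass
class FixtureBundle:
    """In-memory synthetic dataset plus the planted truth."""

    spec: FixtureSpec
    elements: list[RepeatAnnotation]
    sites_by_tf: dict[str, list[TFBSRecord]]
    transcripts: list[TranscriptRecord]
    reads: dict[str, list[GenomicInterval]]  # sample id -> read intervals
    manifest: list[dict]  # sample, mark, role, total_mapped
    genome: dict[str, str] | None
    pfm: tuple[str, str, np.ndarray]
    truth: dict


# ---------------------------------------------------------------------------
# Stage generators
# ---------------------------------------------------------------------------

def simulate_elements(spec: FixtureSpec, rng: np.random.Generator,
                      rep_name: str = "L1PA2") -> list[RepeatAnnotation]:
    """Place non-overlapping elements uniformly, random strand.

    A minority of copies are 5'-truncated (consensus_start > 1), mirroring
    the truncation common in real repeat annotation.
    """
    chroms = list(spec.chrom_lengths)
    weights = np.array([spec.chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    elements = []
    attempts = 0
    while len(elements) < spec.n_elements:
        attempts += 1
        if attempts > 200 * spec.n_elements:
            raise ValueError("element placement exhausted available space")
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        L = spec.chrom_lengths[chrom]
        start = int(rng.integers(0, L - spec.element_length))
        end = start + spec.element_length
        if any(s < end and e > start for s, e in occupied[chrom]):
            continue
        occupied[chrom].append((start, end))
        strand = "+" if rng.random() < 0.5 else "-"
        truncated = rng.random() < 0.3
        cons_start = int(rng.integers(2, 1500)) if truncated else 1
        elements.append(RepeatAnnotation(
            interval=GenomicInterval(chrom, start, end, strand, rep_name),
            rep_name=rep_name,
            rep_class="LINE", rep_family="L1",
            consensus_start=cons_start,
            consensus_end=cons_start + spec.element_length - 1,
        ))
    elements.sort(key=lambda e: (e.interval.chrom, e.interval.start))
    return elements


def _five_prime_region(el: RepeatAnnotation, length: int) -> tuple[int, int]:
    iv = el.interval
    if iv.strand == "-":
        return iv.end - length, iv.end
    return iv.start, iv.start + length


def simulate_tf_sites(spec: FixtureSpec, elements,
                      rng: np.random.Generator) -> dict[str, list[TFBSRecord]]:
    """Background Poisson sites per TF, 5'-subregion enrichment, and
    planted pairwise coupling inside elements."""
    sites: dict[str, list[TFBSRecord]] = {tf: [] for tf in spec.tf_names}
    per_bp = spec.background_rate / 1e6

    def add_site(tf: str, chrom: str, mid: int, L: int) -> None:
        half = spec.site_length // 2
        start = max(0, mid - half)
        end = min(L, start + spec.site_length)
        if end <= start:
            return
        sites[tf].append(TFBSRecord(
            interval=GenomicInterval(chrom, start, end, ".", tf),
            tf=tf, context="synthetic", source="simulated"))

    for tf in spec.tf_names:
        for chrom, L in spec.chrom_lengths.items():
            n = rng.poisson(per_bp * L)
            for mid in sorted(int(x) for x in rng.integers(0, L, size=n)):
                add_site(tf, chrom, mid, L)
        if spec.five_prime_enrichment > 1:
            extra_rate = per_bp * (spec.five_prime_enrichment - 1)
            for el in elements:
                s5, e5 = _five_prime_region(el, spec.five_prime_len)
                n = rng.poisson(extra_rate * (e5 - s5))
                L = spec.chrom_lengths[el.interval.chrom]
                for mid in sorted(int(x) for x in rng.integers(s5, e5, size=n)):
                    add_site(tf, el.interval.chrom, mid, L)

    # coupling: each in-element site of TF a spawns a TF b site nearby
    spans = {c: [] for c in spec.chrom_lengths}
    for el in elements:
        spans[el.interval.chrom].append((el.interval.start, el.interval.end))

    def in_element(chrom: str, mid: int) -> bool:
        return any(s <= mid < e for s, e in spans[chrom])

    for (tf_a, tf_b), q in spec.coupling.items():
        for site in list(sites[tf_a]):
            iv = site.interval
            mid = iv.midpoint
            if not in_element(iv.chrom, mid):
                continue
            if rng.random() < q:
                shift = int(rng.integers(-spec.coupling_distance,
                                         spec.coupling_distance + 1))
                add_site(tf_b, iv.chrom, mid + shift,
                         spec.chrom_lengths[iv.chrom])
    for tf in sites:
        sites[tf].sort(key=lambda r: (r.interval.chrom, r.interval.start,
                                      r.interval.end))
    return sites


def simulate_transcripts(spec: FixtureSpec, elements,
                         rng: np.random.Generator) -> list[TranscriptRecord]:
    """Transcripts with planted class fractions and element-derived TSSs.

    For each class, a fraction of TSSs is placed uniformly inside elements;
    the remainder is uniform genome-wide.  Fold changes are drawn strictly
    inside each class band; differential classes get small p-values.
    """
    chroms = list(spec.chrom_lengths)
    weights = np.array([spec.chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    classes = []
    for cls, frac in spec.class_fractions.items():
        classes += [cls] * int(round(frac * spec.n_transcripts))
    while len(classes) < spec.n_transcripts:
        classes.append("unchanged")
    classes = classes[:spec.n_transcripts]

    records = []
    for i, cls in enumerate(classes):
        in_element = rng.random() < spec.tss_in_element_fraction.get(cls, 0.0)
        strand = "+" if rng.random() < 0.5 else "-"
        if in_element and elements:
            el = elements[int(rng.integers(0, len(elements)))]
            chrom = el.interval.chrom
            tss = int(rng.integers(el.interval.start, el.interval.end))
        else:
            chrom = chroms[rng.choice(len(chroms), p=weights)]
            tss = int(rng.integers(0, spec.chrom_lengths[chrom]))
        L = spec.chrom_lengths[chrom]
        span = int(rng.integers(2_000, 10_000))
        if strand == "+":
            start = tss
            end = min(L, tss + span)
            if end - start < 200:
                start = max(0, end - 200)
            tss = start
        else:
            end = tss + 1
            start = max(0, end - span)
            if end - start < 200:
                end = min(L, start + 200)
            tss = end - 1
        n_exons = int(rng.integers(1, 4))
        cuts = np.sort(rng.integers(start, end, size=2 * n_exons))
        exons = []
        for k in range(n_exons):
            s, e = int(cuts[2 * k]), int(cuts[2 * k + 1])
            if e <= s:
                e = s + 1
            exons.append((min(s, end - 1), min(max(e, s + 1), end)))
        # anchor the first/last exon at the TSS end of the transcript
        exons[0] = (start, max(exons[0][1], start + 1))
        exons[-1] = (min(exons[-1][0], end - 1), end)
        exon_ivs = tuple(GenomicInterval(chrom, s, e, strand)
                         for s, e in exons if e > s)

        if cls == "up":
            fc = float(np.exp(rng.uniform(np.log(2.2), np.log(8.0))))
            p = float(10 ** -rng.uniform(2, 8))
        elif cls == "down":
            fc = float(rng.uniform(0.05, 0.45))
            p = float(10 ** -rng.uniform(2, 8))
        else:
            fc = float(rng.uniform(0.6, 1.8))
            p = float(rng.uniform(0.05, 1.0))
        records.append(TranscriptRecord(
            transcript_id=f"TX{i:05d}",
            interval=GenomicInterval(chrom, start, end, strand, f"TX{i:05d}"),
            exons=exon_ivs,
            fold_change=fc,
            p_value=p,
            q_value=min(1.0, p * 1.2),
        ))
    return records


def simulate_reads(spec: FixtureSpec, elements, bound_ids: set[str],
                   rng: np.random.Generator) -> tuple[dict[str, list[GenomicInterval]],
                                                      list[dict]]:
    """Read positions for each mark/replicate plus an input control.

    Background reads are uniform genome-wide at ``noise_reads_per_bin`` per
    profile bin; signal reads pile onto the 5' subregions of TF-bound
    elements.  The input control carries background only.
    """
    reads: dict[str, list[GenomicInterval]] = {}
    manifest: list[dict] = []

    def background() -> list[GenomicInterval]:
        out = []
        rate = spec.noise_reads_per_bin / spec.profile_bin
        for chrom, L in spec.chrom_lengths.items():
            n = rng.poisson(rate * L)
            for s in sorted(int(x) for x in rng.integers(0, max(1, L - spec.read_length),
                                                         size=n)):
                out.append(GenomicInterval(chrom, s, s + spec.read_length))
        return out

    def signal() -> list[GenomicInterval]:
        out = []
        rate = spec.signal_reads_per_bin / spec.profile_bin
        for el in elements:
            if el.element_id not in bound_ids:
                continue
            s5, e5 = _five_prime_region(el, spec.five_prime_len)
            n = rng.poisson(rate * (e5 - s5))
            L = spec.chrom_lengths[el.interval.chrom]
            for s in sorted(int(x) for x in rng.integers(s5, e5, size=n)):
                out.append(GenomicInterval(el.interval.chrom, s,
                                           min(L, s + spec.read_length)))
        return out

    for mark in spec.marks:
        for rep in range(1, spec.n_replicates + 1):
            sample = f"{mark}_rep{rep}"
            reads[sample] = background() + signal()
            manifest.append({"sample": sample, "mark": mark, "role": "signal",
                             "total_mapped": len(reads[sample])})
        for rep in range(1, spec.n_replicates + 1):
            sample = f"{mark}_input_rep{rep}"
            reads[sample] = background()
            manifest.append({"sample": sample, "mark": mark, "role": "control",
                             "total_mapped": len(reads[sample])})
    return reads, manifest


def simulate_genome(spec: FixtureSpec, elements,
                    rng: np.random.Generator) -> tuple[dict[str, str], list[str]]:
    """I.i.d. uniform-base genome with the motif word planted in elements.

    The word is written so that strand-aware extraction of the element
    recovers it at 5'-end offset ``MOTIF_CONSENSUS_OFFSET`` (minus-strand
    copies carry the reverse complement on the reference strand).  Returns
    (genome, ids of elements carrying the planted word).
    """
    bases = np.array(list("ACGT"))
    genome = {}
    for chrom, L in spec.chrom_lengths.items():
        genome[chrom] = "".join(bases[rng.integers(0, 4, size=L)])
    planted: list[str] = []
    w = len(MOTIF_WORD)
    for el in elements:
        if rng.random() >= spec.motif_fraction:
            continue
        iv = el.interval
        seq = genome[iv.chrom]
        if iv.strand == "-":
            # oriented offset d from the 5' end maps to reference
            # [end - d - w, end - d) carrying the reverse complement
            start = iv.end - MOTIF_CONSENSUS_OFFSET - w
            word = reverse_complement(MOTIF_WORD)
        else:
            start = iv.start + MOTIF_CONSENSUS_OFFSET
            word = MOTIF_WORD
        if start < 0 or start + w > len(seq):
            continue
        genome[iv.chrom] = seq[:start] + word + seq[start + w:]
        planted.append(el.element_id)
    return genome, planted


def motif_pfm(n_obs: int = 90, off_count: int = 2) -> tuple[str, str, np.ndarray]:
    """A count matrix strongly favouring the planted word (JASPAR-style)."""
    w = len(MOTIF_WORD)
    counts = np.full((4, w), float(off_count))
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for j, base in enumerate(MOTIF_WORD):
        counts[idx[base], j] = float(n_obs)
    return "SYN0001.1", "SYNMOTIF", counts


# ---------------------------------------------------------------------------
# Top-level bundle
# ---------------------------------------------------------------------------

def simulate_all(spec: FixtureSpec, with_genome: bool = True) -> FixtureBundle:
    """Generate the complete input bundle, deterministic given the seed."""
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    elements = simulate_elements(spec, rng)
    sites_by_tf = simulate_tf_sites(spec, elements, rng)

    # bound = any TF site with >= half its length inside the element
    from repeat_regprof.intervals import intersect_fraction_indices
    bound_ids: set[str] = set()
    for tf, sites in sites_by_tf.items():
        for _, ti in intersect_fraction_indices(sites, elements, 0.5):
            bound_ids.add(elements[ti].element_id)

    transcripts = simulate_transcripts(spec, elements, rng)
    reads, manifest = simulate_reads(spec, elements, bound_ids, rng)
    if with_genome:
        genome, motif_elements = simulate_genome(spec, elements, rng)
    else:
        genome, motif_elements = None, []

    coverage = {c: 0 for c in spec.chrom_lengths}
    for el in elements:
        coverage[el.interval.chrom] += el.interval.length
    coverage_fraction = (sum(coverage.values())
                         / sum(spec.chrom_lengths.values()))
    truth = {
        "seed": spec.rng_seed,
        "coupling_pairs": sorted([list(p) for p in spec.coupling]),
        "tss_in_element_fraction": dict(spec.tss_in_element_fraction),
        "element_coverage_fraction": coverage_fraction,
        "bound_element_ids": sorted(bound_ids),
        "motif_word": MOTIF_WORD,
        "motif_offset": MOTIF_CONSENSUS_OFFSET,
        "motif_element_ids": sorted(motif_elements),
        "five_prime_enrichment": spec.five_prime_enrichment,
    }
    return FixtureBundle(spec=spec, elements=elements, sites_by_tf=sites_by_tf,
                         transcripts=transcripts, reads=reads,
                         manifest=manifest, genome=genome,
                         pfm=motif_pfm(), truth=truth)


def write_bundle(bundle: FixtureBundle, out_dir) -> dict[str, str]:
    """Write the bundle to disk (chrom.sizes, repeat TSV, per-TF BEDs,
    read BEDs + manifest TSV, transcript TSV, genome FASTA, PFM, truth
    JSON).  Byte-identical for identical specs."""
    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, str] = {}

    def p(name: str) -> str:
        path = os.path.join(out_dir, name)
        paths[name] = path
        return path

    write_chrom_sizes(bundle.spec.chrom_lengths, p("chrom.sizes"))
    write_repeat_tsv(bundle.elements, p("repeats.tsv"))
    tf_dir = os.path.join(out_dir, "tfbs")
    os.makedirs(tf_dir, exist_ok=True)
    for tf, sites in bundle.sites_by_tf.items():
        write_bed(sites, os.path.join(tf_dir, f"{tf}.bed"))
    paths["tfbs_dir"] = tf_dir
    write_transcript_table(bundle.transcripts, p("transcripts.tsv"))

    reads_dir = os.path.join(out_dir, "reads")
    os.makedirs(reads_dir, exist_ok=True)
    for sample, reads in bundle.reads.items():
        write_bed(reads, os.path.join(reads_dir, f"{sample}.bed"))
    paths["reads_dir"] = reads_dir
    with open(p("samples.tsv"), "w") as fh:
        fh.write("sample\tmark\trole\ttotal_mapped\n")
        for row in bundle.manifest:
            fh.write(f"{row['sample']}\t{row['mark']}\t{row['role']}\t"
                     f"{row['total_mapped']}\n")

    groups_path = p("groups.tsv")
    bound = set(bundle.truth["bound_element_ids"])
    with open(groups_path, "w") as fh:
        fh.write("element_id\tgroup\n")
        for el in bundle.elements:
            group = "bound" if el.element_id in bound else "unbound"
            fh.write(f"{el.element_id}\t{group}\n")

    if bundle.genome is not None:
        write_fasta(bundle.genome, p("genome.fa"))
    matrix_id, name, counts = bundle.pfm
    write_jaspar_pfm(matrix_id, name, counts, p("motif.pfm"))
    with open(p("truth.json"), "w") as fh:
        json.dump(bundle.truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
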