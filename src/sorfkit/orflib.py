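"""Candidate short-ORF enumeration, classification, identification and naming.

Builds the searchable target+decoy peptide library: every occurrence of an
allowed start codon (default ATG/CTG/GTG/TTG) on a spliced transcript is
extended to the first in-frame stop, length-filtered (default 6-249 aa),
classified relative to the transcript's annotated CDS, and given a stable
identifier ``transcriptID_gStart_gStop_lengthNt``.

Length convention: ``length_nt`` includes the stop codon; the peptide
excludes it, so a 135-nt ORF encodes a 44-aa peptide.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio.Data import CodonTable

from .annotation import (
    GenomeSequence,
    TranscriptModel,
    cds_transcript_span,
    spliced_sequence,
    transcript_to_genomic,
)

logger = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
DEFAULT_START_CODONS = ("ATG", "CTG", "GTG", "TTG")

_CODON_TABLE = CodonTable.unambiguous_dna_by_id[1].forward_table

CATEGORIES = (
    "annotated", "uORF", "overlap_uORF", "dORF", "overlap_dORF",
    "intORF", "altORF", "novel_nc",
)

# catalogue category -> single-letter type code used in peptide names
TYPE_CODES = {
    "uORF": "u",
    "overlap_uORF": "u",
    "dORF": "d",
    "overlap_dORF": "d",
    "intORF": "alt",
    "altORF": "alt",
    "novel_nc": "nc",
}


def translate_orf(seq: str) -> str:
    """Translate an ORF nucleotide sequence, excluding its stop codon.

    Codons containing N (or otherwise untranslatable) become X; an exact
    stop codon inside the body becomes ``*`` (never produced by the
    enumerator, but kept visible rather than silently masked).
    """
    if len(seq) % 3 != 0:
        raise ValueError(f"ORF length {len(seq)} is not divisible by 3")
    out = []
    for i in range(0, len(seq) - 3, 3):
        codon = seq[i : i + 3]
        if codon in STOP_CODONS:
            out.append("*")
        else:
            out.append(_CODON_TABLE.get(codon, "X"))
    return "".join(out)


def enumerate_orfs(
    tseq: str,
    starts: Sequence[str] = DEFAULT_START_CODONS,
    max_aa: int = 249,
    min_aa: int = 6,
) -> list[tuple[int, int, str]]:
    """Enumerate ORFs on a transcript sequence.

    Every occurrence of every allowed start codon is extended to the FIRST
    in-frame stop (TAA/TAG/TGA); ORFs with no downstream in-frame stop are
    discarded. Nested ORFs sharing a stop are all kept. Returns 1-based
    inclusive ``(t_start, t_stop, start_codon)`` triples, where ``t_stop``
    is the last base of the stop codon, sorted by position.
    """
    if not (1 <= min_aa <= max_aa):
        raise ValueError(f"need 1 <= min_aa <= max_aa, got {min_aa}, {max_aa}")
    start_set = frozenset(s.upper() for s in starts)
    n = len(tseq)
    # per-frame sorted lists of stop-codon start indices (0-based)
    stops_by_frame: list[list[int]] = [[], [], []]
    for i in range(n - 2):
        if tseq[i : i + 3] in STOP_CODONS:
            stops_by_frame[i % 3].append(i)
    from bisect import bisect_left

    out: list[tuple[int, int, str]] = []
    for i in range(n - 2):
        codon = tseq[i : i + 3]
        if codon not in start_set:
            continue
        frame_stops = stops_by_frame[i % 3]
        j = bisect_left(frame_stops, i + 3)
        if j == len(frame_stops):
            continue  # runs off the 3' end without a stop
        stop = frame_stops[j]
        n_aa = (stop - i) // 3  # residues before the stop
        if min_aa <= n_aa <= max_aa:
            out.append((i + 1, stop + 3, codon))
    out.sort()
    return out


def classify_orf(
    t_start: int, t_stop: int, cds_span: tuple[int, int] | None
) -> str:
    """Classify an ORF relative to the transcript's annotated CDS.

    ``cds_span`` is the CDS as a (start, stop) transcript interval, or
    None for a transcript without annotated CDS (→ ``novel_nc``).
    Straddle checks precede frame checks, so an ORF containing the whole
    CDS is ``overlap_uORF``; a same-frame ORF strictly inside the CDS
    (an N-terminal truncation) classifies as ``altORF``.
    """
    if cds_span is None:
        return "novel_nc"
    c_start, c_stop = cds_span
    if (t_start, t_stop) == (c_start, c_stop):
        return "annotated"
    if t_stop < c_start:
        return "uORF"
    if t_start > c_stop:
        return "dORF"
    if t_start < c_start:
        return "overlap_uORF"
    if t_stop > c_stop:
        return "overlap_dORF"
    # strictly inside the CDS span
    if (t_start - c_start) % 3 != 0:
        return "intORF"
    return "altORF"


@dataclass
class CandidateORF:
    """One enumerated candidate ORF with transcript and genomic coordinates."""

    transcript_id: str
    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    t_start: int
    t_stop: int
    g_start: int  # transcript-orientation first base (larger than g_stop on -)
    g_stop: int
    g_min: int  # normalized span for BED-style export
    g_max: int
    blocks: tuple[tuple[int, int], ...]
    length_nt: int
    start_codon: str
    category: str
    peptide: str
    orf_id: str = field(default="")

    def __post_init__(self) -> None:
        if self.length_nt != self.t_stop - self.t_start + 1:
            raise ValueError("length_nt inconsistent with transcript interval")
        if self.length_nt % 3 != 0:
            raise ValueError("length_nt not divisible by 3")
        if len(self.peptide) != self.length_nt // 3 - 1:
            raise ValueError("peptide length inconsistent with length_nt")
        if "*" in self.peptide:
            raise ValueError("peptide contains an internal stop")
        if not self.orf_id:
            self.orf_id = make_orf_id(
                self.transcript_id, self.g_start, self.g_stop, self.length_nt
            )


def make_orf_id(
    transcript_id: str, g_start: int, g_stop: int, length_nt: int
) -> str:
    """Underscore-joined ORF identifier: transcript, genomic start/stop, nt length.

    The length field is the spliced ORF length (including the stop codon),
    not the genomic span, so it is intron-invariant.
    """
    return f"{transcript_id}_{g_start}_{g_stop}_{length_nt}"


@dataclass(frozen=True)
class LibraryConfig:
    """Enumeration parameters for the candidate library."""

    start_codons: tuple[str, ...] = DEFAULT_START_CODONS
    min_aa: int = 6
    max_aa: int = 249


def orfs_from_transcript(
    model: TranscriptModel, genome: GenomeSequence, config: LibraryConfig
) -> list[CandidateORF]:
    """Enumerate and annotate all candidate ORFs on one transcript."""
    if not config.start_codons:
        return []
    tseq = spliced_sequence(model, genome)
    cds_span = cds_transcript_span(model)
    out = []
    for t_start, t_stop, codon in enumerate_orfs(
        tseq, config.start_codons, config.max_aa, config.min_aa
    ):
        g_start, g_stop, blocks = transcript_to_genomic(model, t_start, t_stop)
        peptide = translate_orf(tseq[t_start - 1 : t_stop])
        if "*" in peptide:  # N never forms a stop, so this cannot happen
            continue
        out.append(
            CandidateORF(
                transcript_id=model.transcript_id,
                gene_id=model.gene_id,
                gene_name=model.gene_name or model.gene_id,
                chrom=model.chrom,
                strand=model.strand,
                t_start=t_start,
                t_stop=t_stop,
                g_start=g_start,
                g_stop=g_stop,
                g_min=min(g_start, g_stop),
                g_max=max(g_start, g_stop),
                blocks=tuple(blocks),
                length_nt=t_stop - t_start + 1,
                start_codon=codon,
                category=classify_orf(t_start, t_stop, cds_span),
                peptide=peptide,
            )
        )
    return out


def build_candidate_library(
    models: Iterable[TranscriptModel],
    genome: GenomeSequence,
    config: LibraryConfig | None = None,
) -> list[CandidateORF]:
    """Enumerate candidate ORFs across all transcripts, deterministically ordered."""
    config = config or LibraryConfig()
    models = list(models)
    if not models:
        raise ValueError("empty annotation: no transcripts to enumerate")
    orfs: list[CandidateORF] = []
    for model in models:
        orfs.extend(orfs_from_transcript(model, genome, config))
    orfs.sort(key=lambda o: (o.chrom, o.g_min, o.transcript_id, o.length_nt))
    return orfs


def catalogue_frame(orfs: Sequence[CandidateORF]) -> pd.DataFrame:
    """Flatten a candidate-ORF collection into a catalogue table."""
    cols = [
        "orf_id", "transcript_id", "gene_id", "gene_name", "chrom", "strand",
        "t_start", "t_stop", "g_start", "g_stop", "g_min", "g_max",
        "length_nt", "start_codon", "category", "peptide",
    ]
    return pd.DataFrame([{c: getattr(o, c) for c in cols} for o in orfs],
                        columns=cols)


def write_library_fasta(
    orfs: Sequence[CandidateORF], target_path: str | Path, decoy_path: str | Path
) -> None:
    """Write the target and reversed-decoy peptide FASTA files.

    Decoys are whole-entry peptide reversals with header prefix ``DECOY_``.
    A decoy whose sequence collides with any target peptide is logged and
    its header suffixed ``_COLLISION`` so it can be excluded downstream.
    """
    target_seqs = {o.peptide for o in orfs}
    with open(target_path, "w") as tfh, open(decoy_path, "w") as dfh:
        for o in orfs:
            header = (
                f">{o.orf_id} gene={o.gene_name} type={o.category} "
                f"start_codon={o.start_codon} len_nt={o.length_nt}"
            )
            tfh.write(f"{header}\n{o.peptide}\n")
            decoy = o.peptide[::-1]
            decoy_id = f"DECOY_{o.orf_id}"
            if decoy in target_seqs:
                logger.warning("decoy of %s collides with a target sequence",
                               o.orf_id)
                decoy_id += "_COLLISION"
            dfh.write(f">{decoy_id}\n{decoy}\n")


def write_bed12(orfs: Sequence[CandidateORF], path: str | Path) -> None:
    """Write ORF genomic blocks as BED12 (0-based half-open)."""
    with open(path, "w") as fh:
        for o in orfs:
            blocks = sorted(o.blocks)
            chrom_start = blocks[0][0] - 1
            chrom_end = blocks[-1][1]
            sizes = ",".join(str(b[1] - b[0] + 1) for b in blocks)
            starts = ",".join(str(b[0] - 1 - chrom_start) for b in blocks)
            fh.write(
                "\t".join(
                    map(str, [
                        o.chrom, chrom_start, chrom_end, o.orf_id, 0, o.strand,
                        chrom_start, chrom_end, "0,0,0", len(blocks), sizes,
                        starts,
                    ])
                ) + "\n"
            )


@dataclass(frozen=True)
class NamedPeptide:
    """A catalogued peptide with its standardized ``pepNo.-Type-Gene`` name."""

    name: str
    type_code: str
    host_gene: str
    peptide: str
    orf_ids: tuple[str, ...]


def assign_names(orfs: Sequence[CandidateORF]) -> list[NamedPeptide]:
    """Assign ``pepNo.-Type-Gene`` names to identified peptides.

    ORFs sharing a (gene, peptide sequence) collapse to one named peptide
    listing all supporting orf_ids. Numbering is per gene by ascending
    normalized genomic start of the representative ORF; a gene with exactly
    one identified peptide is labeled ``pep`` without a number. Category
    ``annotated`` must be filtered out upstream.
    """
    for o in orfs:
        if o.category == "annotated":
            raise ValueError(
                f"{o.orf_id}: annotated ORFs must be removed before naming"
            )
        if o.category not in TYPE_CODES:
            raise ValueError(f"{o.orf_id}: unknown category {o.category!r}")
    # collapse to (gene, peptide) keeping the coordinate-minimal representative
    groups: dict[tuple[str, str], list[CandidateORF]] = defaultdict(list)
    for o in orfs:
        gene = o.gene_name or o.gene_id
        groups[(gene, o.peptide)].append(o)
    per_gene: dict[str, list[tuple[tuple, str, list[CandidateORF]]]] = defaultdict(list)
    for (gene, peptide), members in groups.items():
        members.sort(key=lambda o: (o.g_min, o.g_max, o.orf_id))
        rep = members[0]
        sort_key = (rep.g_min, rep.g_max, peptide)
        per_gene[gene].append((sort_key, peptide, members))
    named: list[NamedPeptide] = []
    for gene in sorted(per_gene):
        entries = sorted(per_gene[gene])
        single = len(entries) == 1
        for number, (_, peptide, members) in enumerate(entries, 1):
            rep = members[0]
            code = TYPE_CODES[rep.category]
            label = "pep" if single else f"pep{number}"
            named.append(
                NamedPeptide(
                    name=f"{label}-{code}-{gene}",
                    type_code=code,
                    host_gene=gene,
                    peptide=peptide,
                    orf_ids=tuple(sorted(m.orf_id for m in members)),
                )
            )
    names = [n.name for n in named]
    if len(names) != len(set(names)):
        raise ValueError("peptide names are not unique")
    return named
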