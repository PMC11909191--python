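"""Genome and transcript annotation I/O.

Reads a genome FASTA and an Ensembl-dialect GTF, assembles spliced
transcript sequences, and converts between transcript-relative and
genomic coordinates.

Conventions
-----------
All coordinates are 1-based and inclusive on both ends (the Ensembl GTF
convention). Transcript positions count from the transcript's 5' end, so
position 1 is the first transcribed base regardless of strand. On the
minus strand the "start" genomic coordinate of an interval is therefore
numerically *larger* than its "stop"; a normalized ``(min, max)`` span is
available for BED-style export.
"""

from __future__ import annotations

import logging
import re
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
import gffutils
from Bio import SeqIO

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_NON_ACGTN = re.compile(r"[^ACGTN]")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an ACGTN nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeSequence(dict):
    """Mapping from chromosome name to an uppercase ACGTN sequence."""

    def add(self, name: str, seq: str) -> None:
        if name in self:
            raise ValueError(f"duplicate chromosome name: {name!r}")
        seq = _NON_ACGTN.sub("N", seq.upper())
        if not seq:
            raise ValueError(f"chromosome {name!r} has an empty sequence")
        self[name] = seq


def parse_genome(path: str | Path) -> GenomeSequence:
    """Load a genome FASTA into a :class:`GenomeSequence`.

    Lowercase bases are uppercased; characters outside ACGTN become N.
    Duplicate chromosome names raise ``ValueError``.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(
                        f"{path}: line {lineno}: expected a FASTA header "
                        f"starting with '>', got {line.strip()[:30]!r}"
                    )
                break
    genome = GenomeSequence()
    for record in SeqIO.parse(str(path), "fasta"):
        genome.add(record.id, str(record.seq))
    if not genome:
        raise ValueError(f"{path}: no FASTA records found")
    return genome


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based, inclusive, stranded genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid interval {self.start}-{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )


@dataclass
class TranscriptModel:
    """A spliced, stranded transcript with optional annotated CDS.

    ``exons`` are stored sorted by genomic start and must be pairwise
    non-overlapping and on a single chromosome/strand. A CDS whose total
    length is not divisible by 3, or that is not contained in the exons,
    is dropped with a logged warning.
    """

    transcript_id: str
    gene_id: str
    gene_name: str
    biotype: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    cds: tuple[GenomicInterval, ...] | None = None
    # cumulative exon lengths in transcription order, built lazily
    _offsets: tuple[int, ...] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        if not exons:
            raise ValueError(f"{self.transcript_id}: transcript has no exons")
        for ex in exons:
            if ex.chrom != self.chrom or ex.strand != self.strand:
                raise ValueError(
                    f"{self.transcript_id}: exon {ex} disagrees with the "
                    f"transcript's chromosome/strand"
                )
        for a, b in zip(exons, exons[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"{self.transcript_id}: overlapping exons {a} and {b}"
                )
        object.__setattr__(self, "exons", exons)
        if self.cds is not None:
            cds = tuple(sorted(self.cds, key=lambda c: c.start))
            contained = all(
                any(ex.start <= c.start and c.end <= ex.end for ex in exons)
                for c in cds
            )
            total = sum(len(c) for c in cds)
            if not contained or total % 3 != 0:
                logger.warning(
                    "%s: dropping CDS (contained=%s, length %d %% 3 = %d)",
                    self.transcript_id, contained, total, total % 3,
                )
                cds = None
            object.__setattr__(self, "cds", cds)
        self._offsets = None

    # -- transcript geometry -------------------------------------------------

    @property
    def length(self) -> int:
        return sum(len(ex) for ex in self.exons)

    def _exons_5to3(self) -> tuple[GenomicInterval, ...]:
        """Exons in transcription order (5' to 3')."""
        return self.exons if self.strand == "+" else tuple(reversed(self.exons))

    def _cum_offsets(self) -> tuple[int, ...]:
        if self._offsets is None:
            offs, total = [], 0
            for ex in self._exons_5to3():
                offs.append(total)
                total += len(ex)
            self._offsets = tuple(offs)
        return self._offsets

    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )


def spliced_sequence(model: TranscriptModel, genome: GenomeSequence) -> str:
    """The transcript's spliced sequence, 5'→3' in transcript orientation."""
    try:
        chrom_seq = genome[model.chrom]
    except KeyError:
        raise ValueError(f"{model.transcript_id}: chromosome {model.chrom!r} "
                         f"not in genome") from None
    if model.exons[-1].end > len(chrom_seq):
        raise ValueError(
            f"{model.transcript_id}: exon ends at {model.exons[-1].end} but "
            f"{model.chrom} has length {len(chrom_seq)}"
        )
    seq = "".join(chrom_seq[ex.start - 1 : ex.end] for ex in model.exons)
    return seq if model.strand == "+" else reverse_complement(seq)


def transcript_to_genomic(
    model: TranscriptModel, t_start: int, t_end: int
) -> tuple[int, int, list[tuple[int, int]]]:
    """Map a transcript interval to genomic coordinates.

    Returns ``(g_start, g_end, blocks)``: the genomic base of ``t_start``
    (the interval's 5' base in transcript orientation), the genomic base
    of ``t_end``, and the exon-block list as normalized ``(min, max)``
    pairs sorted by genomic start. On the minus strand ``g_start > g_end``.
    """
    length = model.length
    if not (1 <= t_start <= t_end <= length):
        raise ValueError(
            f"transcript interval ({t_start}, {t_end}) out of range "
            f"1..{length} for {model.transcript_id}"
        )
    g_start = _t2g(model, t_start)
    g_end = _t2g(model, t_end)
    blocks: list[tuple[int, int]] = []
    offset = 0
    for ex in model._exons_5to3():
        lo = max(t_start, offset + 1)
        hi = min(t_end, offset + len(ex))
        if lo <= hi:
            if model.strand == "+":
                blocks.append((ex.start + lo - 1 - offset, ex.start + hi - 1 - offset))
            else:
                blocks.append((ex.end - (hi - 1 - offset), ex.end - (lo - 1 - offset)))
        offset += len(ex)
    blocks.sort()
    return g_start, g_end, blocks


def _t2g(model: TranscriptModel, t_pos: int) -> int:
    offsets = model._cum_offsets()
    exons = model._exons_5to3()
    i = bisect_right(offsets, t_pos - 1) - 1
    ex = exons[i]
    within = t_pos - 1 - offsets[i]
    return ex.start + within if model.strand == "+" else ex.end - within


def genomic_to_transcript(model: TranscriptModel, g_pos: int) -> int:
    """Inverse of the single-position transcript→genomic mapping."""
    offset = 0
    for ex in model._exons_5to3():
        if ex.start <= g_pos <= ex.end:
            within = g_pos - ex.start if model.strand == "+" else ex.end - g_pos
            return offset + within + 1
        offset += len(ex)
    raise ValueError(
        f"genomic position {g_pos} is not exonic in {model.transcript_id}"
    )


def cds_transcript_span(model: TranscriptModel) -> tuple[int, int] | None:
    """The annotated CDS as a (start, end) transcript interval, or None."""
    if not model.cds:
        return None
    if model.strand == "+":
        first, last = model.cds[0].start, model.cds[-1].end
    else:
        first, last = model.cds[-1].end, model.cds[0].start
    return genomic_to_transcript(model, first), genomic_to_transcript(model, last)


# -- GTF parsing -----------------------------------------------------------


def parse_gtf(path: str | Path, genome: GenomeSequence) -> list[TranscriptModel]:
    """Parse an Ensembl-dialect GTF into :class:`TranscriptModel` objects.

    Only ``exon`` and ``CDS`` features are consumed. Features lacking a
    ``transcript_id`` attribute are skipped with a warning; exons outside
    chromosome bounds or transcripts spanning two chromosomes are errors.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: dict[str, list[gffutils.Feature]] = {}
    cdss: dict[str, list[gffutils.Feature]] = {}
    meta: dict[str, dict] = {}
    for ftype, store in (("exon", exons), ("CDS", cdss)):
        for feat in db.features_of_type(ftype):
            try:
                tid = feat["transcript_id"][0]
            except KeyError:
                logger.warning("skipping %s feature without transcript_id at "
                               "%s:%d", ftype, feat.seqid, feat.start)
                continue
            store.setdefault(tid, []).append(feat)
            if tid not in meta:
                attrs = feat.attributes
                meta[tid] = {
                    "gene_id": attrs.get("gene_id", [tid])[0],
                    "gene_name": attrs.get("gene_name", attrs.get("gene_id", [tid]))[0],
                    "biotype": attrs.get(
                        "transcript_biotype", attrs.get("gene_biotype", ["unknown"])
                    )[0],
                }
    models = []
    for tid, feats in exons.items():
        chroms = {f.seqid for f in feats}
        if len(chroms) > 1:
            raise ValueError(f"transcript {tid} spans chromosomes {sorted(chroms)}")
        chrom = chroms.pop()
        if chrom not in genome:
            raise ValueError(f"transcript {tid}: chromosome {chrom!r} not in genome")
        chrom_len = len(genome[chrom])
        for f in feats:
            if f.start < 1 or f.end > chrom_len:
                raise ValueError(
                    f"transcript {tid}: exon {f.start}-{f.end} outside "
                    f"{chrom} bounds 1-{chrom_len}"
                )
        strand = feats[0].strand
        exon_ivs = tuple(
            GenomicInterval(chrom, f.start, f.end, strand) for f in feats
        )
        cds_ivs = None
        if tid in cdss:
            cds_ivs = tuple(
                GenomicInterval(chrom, f.start, f.end, strand) for f in cdss[tid]
            )
        m = meta[tid]
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=m["gene_id"],
                gene_name=m["gene_name"],
                biotype=m["biotype"],
                chrom=chrom,
                strand=strand,
                exons=exon_ivs,
                cds=cds_ivs,
            )
        )
    models.sort(key=lambda t: (t.chrom, t.exons[0].start, t.transcript_id))
    return models
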