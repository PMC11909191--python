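import numpy as np
import pytest

from sorfkit.annotation import GenomeSequence, GenomicInterval, TranscriptModel
from sorfkit.orflib import CandidateORF, build_candidate_library, catalogue_frame
from sorfkit.simulate import simulate_genome_annotation


@pytest.fixture(scope="session")
def sim(tmp_path_factory):
    """One simulated genome+annotation (seed 1) shared across the session."""
    out = tmp_path_factory.mktemp("sim_seed1")
    fasta, gtf, truth = simulate_genome_annotation(seed=1, out_dir=out)
    return {"fasta": fasta, "gtf": gtf, "truth": truth, "dir": out}


@pytest.fixture(scope="session")
def sim_genome(sim):
    from sorfkit.annotation import parse_genome

    return parse_genome(sim["fasta"])


@pytest.fixture(scope="session")
def sim_models(sim, sim_genome):
    from sorfkit.annotation import parse_gtf

    return parse_gtf(sim["gtf"], sim_genome)


@pytest.fixture(scope="session")
def sim_catalogue(sim_models, sim_genome):
    return catalogue_frame(build_candidate_library(sim_models, sim_genome))


def random_genome(rng, n_chrom=2, length=3000):
    g = GenomeSequence()
    for c in range(n_chrom):
        g.add(f"chr{c + 1}", "".join(rng.choice(list("ACGT"), size=length)))
    return g


def random_transcript(rng, genome, tid="tx"):
    """A random multi-exon stranded transcript fitting inside the genome."""
    chrom = rng.choice(sorted(genome))
    chrom_len = len(genome[chrom])
    strand = rng.choice(["+", "-"])
    n_exons = int(rng.integers(1, 5))
    pos = int(rng.integers(1, max(2, chrom_len // 4)))
    exons = []
    for _ in range(n_exons):
        length = int(rng.integers(30, 200))
        if pos + length > chrom_len:
            break
        exons.append(GenomicInterval(chrom, pos, pos + length - 1, strand))
        pos += length + int(rng.integers(10, 100))
    if not exons:
        exons = [GenomicInterval(chrom, 1, min(60, chrom_len), strand)]
    return TranscriptModel(
        transcript_id=tid, gene_id=f"g_{tid}", gene_name=f"G_{tid}",
        biotype="lncRNA", chrom=chrom, strand=strand, exons=tuple(exons),
    )


def make_orf(
    orf_id="tx1_1_24_24",
    transcript_id="tx1",
    gene_name="GENE1",
    chrom="chr1",
    strand="+",
    g_min=1,
    length_nt=None,
    category="novel_nc",
    peptide="MKLVNQR",
    start_codon="ATG",
):
    """Compact CandidateORF factory for naming/filter tests."""
    if length_nt is None:
        length_nt = 3 * (len(peptide) + 1)
    g_max = g_min + length_nt - 1
    g_start, g_stop = (g_min, g_max) if strand == "+" else (g_max, g_min)
    return CandidateORF(
        transcript_id=transcript_id, gene_id=f"gid_{gene_name}",
        gene_name=gene_name, chrom=chrom, strand=strand,
        t_start=1, t_stop=length_nt, g_start=g_start, g_stop=g_stop,
        g_min=g_min, g_max=g_max, blocks=((g_min, g_max),),
        length_nt=length_nt, start_codon=start_codon, category=category,
        peptide=peptide, orf_id=orf_id,
    )
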