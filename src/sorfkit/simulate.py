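"""Synthetic-data generators with planted ground truth.

Everything the pipeline reads can be generated here with a known answer:
a random multi-exon stranded annotation (mRNAs with in-frame CDS and
planted uORFs/dORFs, ncRNAs with planted sORFs), PSM tables drawn from a
two-component score mixture with decoys and deliberately ambiguous
spectra, and negative-binomial sgRNA count screens with planted
proliferation effects confined to ORF-body guides.

Anti-circularity: this module carries its own coordinate arithmetic,
splicing, translation and a naive scan-to-first-stop ORF enumerator
(:func:`brute_force_orfs`), so the planted truth never depends on the
library code it is used to validate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

_STOPS = ("TAA", "TAG", "TGA")
_STARTS_DEFAULT = ("ATG", "CTG", "GTG", "TTG")
_CODE = CodonTable.unambiguous_dna_by_id[1].forward_table
_SENSE_CODONS = tuple(sorted(_CODE))  # 61 sense codons
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_BASES = np.array(list("ACGT"))


# --------------------------------------------------------------------------
# independent primitives (deliberately separate from sorfkit.annotation/orflib)
# --------------------------------------------------------------------------


def _rc(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _translate(seq: str) -> str:
    return "".join(
        _CODE.get(seq[i : i + 3], "X") for i in range(0, len(seq) - 3, 3)
    )


def brute_force_orfs(
    seq: str,
    starts: Sequence[str] = _STARTS_DEFAULT,
    min_aa: int = 6,
    max_aa: int = 249,
) -> list[tuple[int, int, str]]:
    """Naive ORF enumerator: scan every start, walk codons to the first stop.

    Returns 1-based inclusive (t_start, t_stop, start_codon) triples with
    t_stop the last base of the stop codon. Used as the independent
    oracle for the library's enumerator.
    """
    start_set = set(starts)
    found = []
    n = len(seq)
    for i in range(n - 2):
        codon = seq[i : i + 3]
        if codon not in start_set:
            continue
        j = i + 3
        while j + 3 <= n:
            if seq[j : j + 3] in _STOPS:
                n_aa = (j - i) // 3
                if min_aa <= n_aa <= max_aa:
                    found.append((i + 1, j + 3, codon))
                break
            j += 3
    return found


@dataclass
class _Tx:
    """Minimal transcript record for the generator's own bookkeeping."""

    transcript_id: str
    gene_id: str
    gene_name: str
    biotype: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # sorted by genomic start
    cds: list[tuple[int, int]] | None = None

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    def exons_5to3(self) -> list[tuple[int, int]]:
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    def t2g(self, t_pos: int) -> int:
        off = 0
        for s, e in self.exons_5to3():
            n = e - s + 1
            if t_pos <= off + n:
                w = t_pos - 1 - off
                return s + w if self.strand == "+" else e - w
            off += n
        raise ValueError(f"transcript position {t_pos} out of range")

    def extract(self, chrom_seq: str) -> str:
        seq = "".join(chrom_seq[s - 1 : e] for s, e in self.exons)
        return seq if self.strand == "+" else _rc(seq)

    def blocks(self, t_start: int, t_end: int) -> list[tuple[int, int]]:
        out, off = [], 0
        for s, e in self.exons_5to3():
            n = e - s + 1
            lo, hi = max(t_start, off + 1), min(t_end, off + n)
            if lo <= hi:
                if self.strand == "+":
                    out.append((s + lo - 1 - off, s + hi - 1 - off))
                else:
                    out.append((e - (hi - 1 - off), e - (lo - 1 - off)))
            off += n
        return sorted(out)


def _classify(t_start: int, t_stop: int, cds: tuple[int, int] | None) -> str:
    """Interval-logic ORF category, mirroring the documented rules."""
    if cds is None:
        return "novel_nc"
    c0, c1 = cds
    if (t_start, t_stop) == (c0, c1):
        return "annotated"
    if t_stop < c0:
        return "uORF"
    if t_start > c1:
        return "dORF"
    if t_start < c0:
        return "overlap_uORF"
    if t_stop > c1:
        return "overlap_dORF"
    return "intORF" if (t_start - c0) % 3 != 0 else "altORF"


# --------------------------------------------------------------------------
# genome + annotation simulation
# --------------------------------------------------------------------------


@dataclass
class SyntheticTruth:
    """Planted ground truth for one generator run."""

    seed: int
    params: dict
    models: list[dict] = field(default_factory=list)
    orfs: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "params": self.params,
            "models": self.models,
            "orfs": None if self.orfs is None else self.orfs.to_dict("records"),
            "extras": {
                k: sorted(v) if isinstance(v, (set, frozenset)) else v
                for k, v in self.extras.items()
            },
        }
        # insertion order is deterministic; sorting keys would scramble the
        # orfs table's column order on round-trip
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        orfs = payload["orfs"]
        return cls(
            seed=payload["seed"],
            params=payload["params"],
            models=payload["models"],
            orfs=None if orfs is None else pd.DataFrame(orfs),
            extras=payload.get("extras", {}),
        )


def write_genome_fasta(genome: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _gtf_attrs(**kv: str) -> str:
    return " ".join(f'{k} "{v}";' for k, v in kv.items())


def _write_gtf(transcripts: Sequence[_Tx], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#!genome-build synthetic\n")
        for tx in transcripts:
            attrs = dict(
                gene_id=tx.gene_id,
                transcript_id=tx.transcript_id,
                gene_name=tx.gene_name,
                gene_biotype=tx.biotype,
                transcript_biotype=tx.biotype,
            )
            span = (tx.exons[0][0], tx.exons[-1][1])
            for ftype, ivs in (
                ("gene", [span]),
                ("transcript", [span]),
                ("exon", tx.exons),
                ("CDS", tx.cds or []),
            ):
                for s, e in ivs:
                    fh.write(
                        "\t".join(
                            [tx.chrom, "sorfkit_sim", ftype, str(s), str(e),
                             ".", tx.strand, ".", _gtf_attrs(**attrs)]
                        ) + "\n"
                    )


def _plant_orf(
    chrom: list[str], tx: _Tx, t_start: int, n_codons: int, rng: np.random.Generator
) -> None:
    """Force an ORF (ATG ... stop, no internal stops) at a transcript offset.

    ``n_codons`` counts the start plus internal codons; one stop codon is
    appended, so the edit spans ``3 * (n_codons + 1)`` transcript bases.
    """

    def set_base(t_pos: int, base: str) -> None:
        g = tx.t2g(t_pos)
        chrom[g - 1] = base if tx.strand == "+" else base.translate(_COMPLEMENT)

    def set_codon(t_pos: int, codon: str) -> None:
        for k, b in enumerate(codon):
            set_base(t_pos + k, b)

    set_codon(t_start, "ATG")
    for c in range(1, n_codons):
        pos = t_start + 3 * c
        current = "".join(
            chrom[tx.t2g(pos + k) - 1] if tx.strand == "+" else
            chrom[tx.t2g(pos + k) - 1].translate(_COMPLEMENT)
            for k in range(3)
        )
        if current in _STOPS:
            set_codon(pos, _SENSE_CODONS[rng.integers(len(_SENSE_CODONS))])
    set_codon(t_start + 3 * n_codons, _STOPS[rng.integers(3)])


def simulate_genome_annotation(
    seed: int = 1,
    out_dir: str | Path = ".",
    n_chrom: int = 2,
    n_mrna: int = 6,
    n_ncrna: int = 4,
    exon_count_range: tuple[int, int] = (1, 4),
    exon_len_range: tuple[int, int] = (150, 450),
    intron_len_range: tuple[int, int] = (80, 400),
    spacer_range: tuple[int, int] = (200, 600),
    start_codons: Sequence[str] = _STARTS_DEFAULT,
    min_aa: int = 6,
    max_aa: int = 249,
) -> tuple[Path, Path, SyntheticTruth]:
    """Simulate a genome FASTA + Ensembl-dialect GTF with planted ORF truth.

    mRNAs carry an in-frame CDS (start/stop forced, internal stops
    scrubbed) plus a planted uORF/dORF where the UTRs have room; ncRNAs
    carry one planted sORF each. The truth table lists *every* ORF
    satisfying the enumeration rules on the final sequence, computed by
    :func:`brute_force_orfs`, not by the library under test.
    """
    if n_mrna + n_ncrna < 1 or n_chrom < 1:
        raise ValueError("need at least one transcript and one chromosome")
    if intron_len_range[1] <= 0 or exon_len_range[0] < 120:
        raise ValueError("infeasible geometry: exons must be >=120 bp")
    rng = np.random.default_rng(seed)
    params = {
        "n_chrom": n_chrom, "n_mrna": n_mrna, "n_ncrna": n_ncrna,
        "exon_count_range": list(exon_count_range),
        "exon_len_range": list(exon_len_range),
        "intron_len_range": list(intron_len_range),
        "spacer_range": list(spacer_range),
        "start_codons": list(start_codons),
        "min_aa": min_aa, "max_aa": max_aa,
    }
    biotypes = ["protein_coding"] * n_mrna + ["lncRNA"] * n_ncrna
    order = rng.permutation(len(biotypes))
    cursors = {f"chr{c + 1}": 0 for c in range(n_chrom)}
    transcripts: list[_Tx] = []
    for idx, which in enumerate(order):
        biotype = biotypes[which]
        chrom = f"chr{idx % n_chrom + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(exon_count_range[0], exon_count_range[1] + 1))
        pos = cursors[chrom] + int(rng.integers(*spacer_range))
        exons = []
        for e in range(n_exons):
            if e:
                pos += int(rng.integers(*intron_len_range))
            length = int(rng.integers(*exon_len_range))
            exons.append((pos + 1, pos + length))
            pos += length
        cursors[chrom] = pos
        prefix = "SYNTM" if biotype == "protein_coding" else "SYNTN"
        transcripts.append(
            _Tx(
                transcript_id=f"{prefix}{idx:04d}",
                gene_id=f"SYNG{idx:04d}",
                gene_name=f"GENE{idx:04d}",
                biotype=biotype,
                chrom=chrom,
                strand=strand,
                exons=exons,
            )
        )
    genome_arrays = {
        chrom: [str(b) for b in _BASES[rng.integers(0, 4, cursors[chrom] + 300)]]
        for chrom in cursors
    }
    # plant CDS / sORFs by editing transcript-space codons in the genome
    for tx in transcripts:
        chrom = genome_arrays[tx.chrom]
        L = tx.length
        if tx.biotype == "protein_coding":
            utr5 = int(rng.integers(20, max(21, L // 4)))
            max_codons = (L - utr5 - 15) // 3
            n_codons = int(rng.integers(25, min(90, max_codons)))
            _plant_orf(chrom, tx, utr5 + 1, n_codons, rng)
            t_cds = (utr5 + 1, utr5 + 3 * (n_codons + 1))
            tx.cds = tx.blocks(*t_cds)
            if utr5 >= 45:
                k = int(rng.integers(7, min(12, (utr5 - 9) // 3)))
                _plant_orf(chrom, tx, 2, k, rng)
            utr3 = L - t_cds[1]
            if utr3 >= 45:
                k = int(rng.integers(7, min(12, (utr3 - 9) // 3)))
                _plant_orf(chrom, tx, t_cds[1] + 2, k, rng)
        else:
            offset = int(rng.integers(1, max(2, L // 3)))
            k = int(rng.integers(8, 30))
            if offset + 3 * (k + 1) + 2 < L:
                _plant_orf(chrom, tx, offset + 1, k, rng)
    genome = {chrom: "".join(arr) for chrom, arr in genome_arrays.items()}
    # exhaustive ORF truth from the final sequence, via the naive oracle
    orf_rows = []
    for tx in transcripts:
        tseq = tx.extract(genome[tx.chrom])
        cds_span = None
        if tx.cds:
            if tx.strand == "+":
                first, last = tx.cds[0][0], tx.cds[-1][1]
            else:
                first, last = tx.cds[-1][1], tx.cds[0][0]
            cds_span = (
                _g2t(tx, first),
                _g2t(tx, last),
            )
        for t_start, t_stop, codon in brute_force_orfs(
            tseq, start_codons, min_aa, max_aa
        ):
            g_start, g_stop = tx.t2g(t_start), tx.t2g(t_stop)
            length_nt = t_stop - t_start + 1
            orf_rows.append(
                {
                    "transcript_id": tx.transcript_id,
                    "gene_id": tx.gene_id,
                    "gene_name": tx.gene_name,
                    "chrom": tx.chrom,
                    "strand": tx.strand,
                    "t_start": t_start,
                    "t_stop": t_stop,
                    "g_start": g_start,
                    "g_stop": g_stop,
                    "g_min": min(g_start, g_stop),
                    "g_max": max(g_start, g_stop),
                    "length_nt": length_nt,
                    "start_codon": codon,
                    "category": _classify(t_start, t_stop, cds_span),
                    "peptide": _translate(tseq[t_start - 1 : t_stop]),
                    "orf_id": f"{tx.transcript_id}_{g_start}_{g_stop}_{length_nt}",
                }
            )
    truth = SyntheticTruth(
        seed=seed,
        params=params,
        models=[
            {
                "transcript_id": tx.transcript_id,
                "gene_id": tx.gene_id,
                "gene_name": tx.gene_name,
                "biotype": tx.biotype,
                "chrom": tx.chrom,
                "strand": tx.strand,
                "exons": [list(e) for e in tx.exons],
                "cds": None if tx.cds is None else [list(c) for c in tx.cds],
            }
            for tx in sorted(transcripts, key=lambda t: (t.chrom, t.exons[0][0]))
        ],
        orfs=pd.DataFrame(orf_rows).sort_values(
            ["chrom", "g_min", "transcript_id", "length_nt"]
        ).reset_index(drop=True),
    )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta = out_dir / "genome.fasta"
    gtf = out_dir / "annotation.gtf"
    write_genome_fasta(genome, fasta)
    _write_gtf(transcripts, gtf)
    truth.to_json(out_dir / "truth_annotation.json")
    return fasta, gtf, truth


def _g2t(tx: _Tx, g_pos: int) -> int:
    off = 0
    for s, e in tx.exons_5to3():
        if s <= g_pos <= e:
            w = g_pos - s if tx.strand == "+" else e - g_pos
            return off + w + 1
        off += e - s + 1
    raise ValueError(f"{g_pos} not exonic in {tx.transcript_id}")


# --------------------------------------------------------------------------
# PSM table simulation
# --------------------------------------------------------------------------


def simulate_psm_table(
    library: pd.DataFrame | Iterable[tuple[str, str]],
    seed: int = 1,
    out: str | Path | None = None,
    n_present: int = 150,
    n_samples: int = 3,
    detect_prob: float = 0.8,
    mean_extra_psms: float = 1.0,
    mu1: float = 25.0,
    sd1: float = 3.0,
    mu0: float = 10.0,
    sd0: float = 3.0,
    n_false: int = 150,
    n_decoy: int = 150,
    ambiguity_rate: float = 0.05,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate a search-engine PSM table with known true/false labels.

    Truly-present peptides generate >=1 PSM per detection with scores
    ~Normal(mu1, sd1); false target matches and decoy matches draw from
    Normal(mu0, sd0). A stated fraction of target spectra is duplicated
    against a second distinct peptide to exercise the ambiguity filter.
    """
    if mu1 < mu0:
        raise ValueError("true-score mean mu1 must be >= null mean mu0")
    if isinstance(library, pd.DataFrame):
        pairs = list(zip(library["orf_id"], library["peptide"]))
    else:
        pairs = list(library)
    if not pairs:
        raise ValueError("empty peptide library")
    by_pep: dict[str, list[str]] = {}
    for orf_id, pep in pairs:
        by_pep.setdefault(pep, []).append(orf_id)
    peptides = sorted(by_pep)
    rng = np.random.default_rng(seed)
    n_present = min(n_present, len(peptides))
    present = set(
        rng.choice(peptides, size=n_present, replace=False).tolist()
    )
    rows: list[dict] = []
    spectrum = 0

    def add_row(sample: str, pep: str, score: float, decoy: bool,
                spectrum_id: str | None = None) -> str:
        nonlocal spectrum
        if spectrum_id is None:
            spectrum += 1
            spectrum_id = f"S{spectrum:06d}"
        rows.append(
            {
                "spectrum_id": spectrum_id,
                "sample_id": sample,
                "peptide": pep,
                "orf_ids": ";".join(sorted(by_pep.get(pep, []))) if not decoy else "",
                "score": round(float(score), 4),
                "is_decoy": decoy,
            }
        )
        return spectrum_id

    for s in range(1, n_samples + 1):
        sample = f"sample{s}"
        for pep in sorted(present):
            if rng.random() >= detect_prob:
                continue
            k = 1 + rng.poisson(mean_extra_psms)
            for _ in range(k):
                add_row(sample, pep, rng.normal(mu1, sd1), decoy=False)
    n_true_spectra = spectrum
    # False matches land uniformly on the WHOLE target library: a false hit
    # on a genuinely present peptide merges into a true identification and
    # is harmless at the peptide level, which is what makes peptide-level
    # decoy FDR conservative in practice (pi0 < 1). The decoy channel draws
    # the same number of matches from the same-size reversed library.
    false_peps = rng.choice(
        peptides, size=min(n_false, len(peptides)), replace=False
    )
    for pep in false_peps:
        sample = f"sample{rng.integers(1, n_samples + 1)}"
        add_row(sample, pep, rng.normal(mu0, sd0), decoy=False)
    decoy_pool = sorted({p[::-1] for p in peptides})
    decoy_peps = rng.choice(
        decoy_pool, size=min(n_decoy, len(decoy_pool)), replace=False
    )
    for pep in decoy_peps:
        sample = f"sample{rng.integers(1, n_samples + 1)}"
        add_row(sample, pep, rng.normal(mu0, sd0), decoy=True)
    # deliberately ambiguous spectra: second distinct peptide, same spectrum
    n_ambiguous = int(round(ambiguity_rate * n_true_spectra))
    target_rows = [r for r in rows if not r["is_decoy"]]
    for i in range(n_ambiguous):
        base = target_rows[int(rng.integers(len(target_rows)))]
        alternatives = [p for p in peptides if p != base["peptide"]]
        if not alternatives:
            break
        pep = alternatives[int(rng.integers(len(alternatives)))]
        add_row(
            base["sample_id"], pep, base["score"] - abs(rng.normal(0, 1)),
            decoy=False, spectrum_id=base["spectrum_id"],
        )
    df = pd.DataFrame(
        rows,
        columns=["spectrum_id", "sample_id", "peptide", "orf_ids", "score",
                 "is_decoy"],
    )
    truth = SyntheticTruth(
        seed=seed,
        params={
            "n_present": n_present, "n_samples": n_samples,
            "detect_prob": detect_prob, "mean_extra_psms": mean_extra_psms,
            "mu1": mu1, "sd1": sd1, "mu0": mu0, "sd0": sd0,
            "n_false": n_false, "n_decoy": n_decoy,
            "ambiguity_rate": ambiguity_rate,
        },
        extras={"present_peptides": present, "n_rows": len(df)},
    )
    if out is not None:
        df.to_csv(out, sep="\t", index=False)
    return df, truth


# --------------------------------------------------------------------------
# screen count simulation
# --------------------------------------------------------------------------


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """NB(mean, dispersion) with variance = mean + dispersion * mean**2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_screen_counts(
    orf_ids: Sequence[str],
    effects: Mapping[str, float] | None = None,
    seed: int = 1,
    n_body: int = 4,
    n_upstream: int = 2,
    coverage: float = 500.0,
    dispersion: float = 0.05,
    n_replicates: int = 2,
    n_scramble: int = 100,
    n_essential: int = 50,
    essential_lfc: float = -3.0,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate a pooled proliferation screen with planted ORF effects.

    Initial counts draw from NB(coverage, dispersion); final counts from
    NB(coverage * 2**lfc, dispersion), where lfc is the planted effect for
    body guides of affected ORFs, ``essential_lfc`` for essential-gene
    controls, and 0 elsewhere (upstream guides and scrambles).
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    effects = dict(effects or {})
    unknown = set(effects) - set(orf_ids)
    if unknown:
        raise ValueError(f"effects reference unknown ORFs: {sorted(unknown)[:3]}")
    rng = np.random.default_rng(seed)
    records = []
    for orf in orf_ids:
        lfc = float(effects.get(orf, 0.0))
        for j in range(1, n_body + 1):
            records.append((f"{orf}|body{j}", orf, "body", lfc))
        for j in range(1, n_upstream + 1):
            records.append((f"{orf}|up{j}", orf, "upstream", 0.0))
    for i in range(1, n_scramble + 1):
        records.append((f"scramble{i:04d}", "scramble", "scramble", 0.0))
    for i in range(1, n_essential + 1):
        records.append((f"essential{i:04d}", "essential", "essential",
                        float(essential_lfc)))
    manifest = pd.DataFrame(
        [r[:3] for r in records], columns=["sgrna_id", "target_id", "region"]
    )
    lfcs = np.array([r[3] for r in records])
    n = len(records)
    data = {}
    for r in range(1, n_replicates + 1):
        data[f"T0_r{r}"] = _nb_draw(rng, np.full(n, coverage), dispersion)
    final_mean = coverage * np.exp2(lfcs)
    for r in range(1, n_replicates + 1):
        data[f"Tf_r{r}"] = _nb_draw(rng, final_mean, dispersion)
    counts = pd.DataFrame(data, index=manifest["sgrna_id"].values)
    counts.index.name = "sgrna_id"
    truth = SyntheticTruth(
        seed=seed,
        params={
            "n_body": n_body, "n_upstream": n_upstream, "coverage": coverage,
            "dispersion": dispersion, "n_replicates": n_replicates,
            "n_scramble": n_scramble, "n_essential": n_essential,
            "essential_lfc": essential_lfc,
        },
        extras={"effects": effects},
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
        counts.to_csv(out_dir / "counts.tsv", sep="\t")
        truth.to_json(out_dir / "truth_screen.json")
    return manifest, counts, truth
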