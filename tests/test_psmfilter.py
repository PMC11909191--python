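"""PSM loading, ambiguity filtering, target-decoy FDR and catalogue rules."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from sorfkit.psmfilter import (
    FilterReport,
    discard_ambiguous_spectra,
    load_psm_table,
    peptide_level_fdr,
    remove_annotated_and_embedded,
    resolve_redundant_orfs,
    run_psm_pipeline,
    summarize_support,
)
from sorfkit.simulate import simulate_psm_table

DATA = Path(__file__).parent / "data"


def psm_frame(rows):
    """rows: (spectrum, sample, peptide, orf_ids tuple, score, is_decoy)."""
    return pd.DataFrame(
        rows,
        columns=["spectrum_id", "sample_id", "peptide", "orf_ids", "score",
                 "is_decoy"],
    )


class TestLoadPsmTable:
    def test_well_formed_table(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text(
            "spectrum_id\tsample_id\tpeptide\torf_ids\tscore\tis_decoy\n"
            "s1\ta\tPEPK\to1;o2\t10.5\tfalse\n"
            "s2\ta\tPEPR\to3\t9\tfalse\n"
            "s3\tb\tKPEP\t\t5\ttrue\n"
        )
        df = load_psm_table(p)
        assert len(df) == 3
        assert df.loc[0, "orf_ids"] == ("o1", "o2")
        assert df.loc[2, "is_decoy"] and df.loc[2, "orf_ids"] == ()

    def test_duplicate_spectrum_peptide_keeps_best_score(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text(
            "spectrum_id\tsample_id\tpeptide\torf_ids\tscore\tis_decoy\n"
            "s1\ta\tPEPK\to1\t10\tfalse\n"
            "s1\ta\tPEPK\to1\t12\tfalse\n"
        )
        df = load_psm_table(p)
        assert len(df) == 1 and df.loc[0, "score"] == 12

    def test_missing_column_named_in_error(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("spectrum_id\tpeptide\tscore\ns1\tPEPK\t1\n")
        with pytest.raises(ValueError, match="sample_id"):
            load_psm_table(p)

    def test_non_numeric_score_reports_row(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text(
            "spectrum_id\tsample_id\tpeptide\torf_ids\tscore\tis_decoy\n"
            "s1\ta\tPEPK\to1\t10\tfalse\n"
            "s2\ta\tPEPR\to1\toops\tfalse\n"
        )
        with pytest.raises(ValueError, match="row 3"):
            load_psm_table(p)

    def test_simulator_output_round_trips(self, sim_catalogue, tmp_path):
        out = tmp_path / "psms.tsv"
        df, truth = simulate_psm_table(sim_catalogue, seed=7, out=out)
        loaded = load_psm_table(out)
        assert len(loaded) == truth.extras["n_rows"] == len(df)
        assert loaded["score"].equals(df["score"].astype(float))


class TestAmbiguityFilter:
    def test_spectrum_matching_two_sequences_fully_removed(self):
        df = psm_frame(
            [("S1", "a", "ACDK", ("o1",), 9.0, False),
             ("S1", "a", "ACEK", ("o2",), 8.0, False),
             ("S3", "a", "AAAK", ("o3",), 7.0, False)]
        )
        out = discard_ambiguous_spectra(df)
        assert list(out["spectrum_id"]) == ["S3"]

    def test_shared_orfs_same_sequence_retained(self):
        df = psm_frame([("S2", "a", "ACDK", ("o1", "o2"), 9.0, False)])
        assert len(discard_ambiguous_spectra(df)) == 1

    def test_survivors_unique_and_idempotent(self):
        rng = np.random.default_rng(3)
        rows = [
            (f"S{rng.integers(30)}", "a", f"PEP{rng.integers(20)}K", ("o",),
             float(rng.normal(10)), False)
            for _ in range(300)
        ]
        df = psm_frame(rows).drop_duplicates(["spectrum_id", "peptide"])
        out = discard_ambiguous_spectra(df)
        assert (out.groupby("spectrum_id")["peptide"].nunique() == 1).all()
        assert discard_ambiguous_spectra(out).equals(out)


class TestPeptideFdr:
    def test_hand_enumerated_threshold(self):
        rows = [(f"S{i}", "a", f"T{s}", ("o",), float(s), False)
                for i, s in enumerate([10, 9, 8, 7, 3, 2])]
        rows += [("D1", "a", "DA", (), 6.0, True), ("D2", "a", "DB", (), 1.0, True)]
        retained, table = peptide_level_fdr(psm_frame(rows), alpha=0.01)
        assert sorted(retained["peptide"]) == ["T10", "T7", "T8", "T9"]
        assert (retained["q_value"] == 0).all()
        # q-values are monotone non-increasing in score
        tq = table.sort_values("best_score")["q_value"]
        assert (tq.diff().dropna() <= 1e-12).all()

    def test_no_decoy_above_targets_returns_all_targets(self):
        rows = [("S1", "a", "TA", ("o",), 10.0, False),
                ("S2", "a", "TB", ("o",), 9.0, False),
                ("D1", "a", "DA", (), 1.0, True)]
        retained, _ = peptide_level_fdr(psm_frame(rows), alpha=0.01)
        assert sorted(retained["peptide"]) == ["TA", "TB"]

    def test_zero_decoys_instructs_decoy_search(self):
        rows = [("S1", "a", "TA", ("o",), 10.0, False)]
        with pytest.raises(ValueError, match="decoy"):
            peptide_level_fdr(psm_frame(rows))

    def test_aggregates_best_score_and_psm_count(self):
        rows = [("S1", "a", "TA", ("o1",), 5.0, False),
                ("S2", "b", "TA", ("o1", "o2"), 8.0, False),
                ("D1", "a", "DA", (), 1.0, True)]
        retained, _ = peptide_level_fdr(psm_frame(rows), alpha=0.5)
        row = retained.set_index("peptide").loc["TA"]
        assert row["best_score"] == 8.0 and row["psm_count"] == 2
        assert row["samples"] == ("a", "b") and row["orf_ids"] == ("o1", "o2")

    def test_calibration_on_simulated_tables(self, sim_catalogue):
        """Mean realized FDR over seeded score-mixture tables stays within
        1.5x the nominal 1% level (binomial tolerance of the study size)."""
        fdrs = []
        for seed in range(1, 31):
            psms, truth = simulate_psm_table(sim_catalogue, seed=seed)
            psms = psms.assign(
                orf_ids=psms["orf_ids"].map(lambda v: tuple(filter(None, v.split(";"))))
            )
            retained, _ = peptide_level_fdr(discard_ambiguous_spectra(psms), 0.01)
            present = set(truth.extras["present_peptides"])
            false_pos = sum(p not in present for p in retained["peptide"])
            fdrs.append(false_pos / max(1, len(retained)))
        assert np.mean(fdrs) <= 0.015


class TestAnnotatedAndEmbeddedRemoval:
    @pytest.fixture
    def catalogue(self):
        return pd.DataFrame(
            {"orf_id": ["oa", "oi", "onc", "ou"],
             "category": ["annotated", "intORF", "novel_nc", "uORF"]}
        )

    def pepids(self, *rows):
        return pd.DataFrame(rows, columns=["peptide", "orf_ids"])

    def test_embedded_intorf_removed(self, catalogue):
        canonical = {"P1": "XXXACDEFGHIKYYY"}
        out = remove_annotated_and_embedded(
            self.pepids(("ACDEFGHIK", ("oi",))), catalogue, canonical
        )
        assert out.empty

    def test_nc_peptide_embedded_in_canonical_retained(self, catalogue):
        canonical = {"P1": "XXXACDEFGHIKYYY"}
        out = remove_annotated_and_embedded(
            self.pepids(("ACDEFGHIK", ("onc",))), catalogue, canonical
        )
        assert len(out) == 1

    def test_annotated_only_removed_mixed_retained(self, catalogue):
        out = remove_annotated_and_embedded(
            self.pepids(("AAAK", ("oa",)), ("CCCK", ("oa", "ou"))),
            catalogue, {"P": "MMMM"},
        )
        assert list(out["peptide"]) == ["CCCK"]

    def test_il_equivalence_flag(self, catalogue):
        canonical = {"P1": "XXXACDEFGHLKYYY"}  # L where the peptide has I
        pep = self.pepids(("ACDEFGHIK", ("oi",)))
        assert len(remove_annotated_and_embedded(pep, catalogue, canonical)) == 1
        assert remove_annotated_and_embedded(
            pep, catalogue, canonical, il_equivalent=True
        ).empty

    def test_idempotent(self, catalogue):
        pep = self.pepids(("CCCK", ("ou",)), ("ACDEFGHIK", ("oi",)))
        canonical = {"P1": "ACDEFGHIK"}
        once = remove_annotated_and_embedded(pep, catalogue, canonical)
        twice = remove_annotated_and_embedded(once, catalogue, canonical)
        assert once.equals(twice)


def redundancy_catalogue(entries):
    """entries: (orf_id, g_min, length_nt, peptide); all chr1 + novel_nc."""
    rows = []
    for orf_id, g_min, length_nt, peptide in entries:
        rows.append(
            {"orf_id": orf_id, "chrom": "chr1", "strand": "+",
             "g_min": g_min, "g_max": g_min + length_nt - 1,
             "length_nt": length_nt, "category": "novel_nc",
             "peptide": peptide}
        )
    return pd.DataFrame(rows)


class TestRedundancyResolution:
    def test_longer_orf_with_unique_support_evicts_shorter(self):
        cat = redundancy_catalogue(
            [("A", 100, 180, "MAAAAKWWWWKCCCCK"), ("B", 130, 90, "MWWWWKCCCCK")]
        )
        pep = pd.DataFrame(
            {"peptide": ["MAAAAK", "MWWWWK"], "orf_ids": [("A",), ("B",)]}
        )
        out = resolve_redundant_orfs(pep, cat)
        assert list(out["peptide"]) == ["MAAAAK"]

    def test_no_unique_support_both_retained_and_flagged(self):
        cat = redundancy_catalogue(
            [("A", 100, 180, "MAAAAKWWWWKCCCCK"), ("B", 130, 90, "MWWWWKCCCCK")]
        )
        pep = pd.DataFrame(
            {"peptide": ["WWWWKCCCCK", "MWWWWK"], "orf_ids": [("A",), ("B",)]}
        )
        out = resolve_redundant_orfs(pep, cat)
        assert len(out) == 2
        assert all("unresolved_redundant" in f for f in out["flags"])

    def test_non_overlapping_orfs_untouched(self):
        cat = redundancy_catalogue(
            [("A", 100, 60, "MAAAAKWWWWKCCCCK"), ("B", 5000, 30, "MWWWWKCCCCK")]
        )
        pep = pd.DataFrame(
            {"peptide": ["MAAAAK", "MWWWWK"], "orf_ids": [("A",), ("B",)]}
        )
        out = resolve_redundant_orfs(pep, cat)
        assert len(out) == 2 and all(f == () for f in out["flags"])

    def test_randomized_groups_match_pairwise_oracle(self):
        rng = np.random.default_rng(41)
        alphabet = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(40):
            n = int(rng.integers(2, 9))
            entries, peps = [], []
            for i in range(n):
                g_min = int(rng.integers(0, 3)) * 120 + int(rng.integers(0, 40))
                length = 3 * int(rng.integers(10, 60))
                full = "".join(rng.choice(alphabet, size=length // 3 - 1))
                entries.append((f"o{i}", g_min, length, full))
                k = int(rng.integers(4, 8))
                s = int(rng.integers(0, max(1, len(full) - k)))
                peps.append((full[s : s + k], (f"o{i}",)))
            cat = redundancy_catalogue(entries)
            pep = pd.DataFrame(peps, columns=["peptide", "orf_ids"])
            out = resolve_redundant_orfs(pep, cat)
            # oracle: iterate all ORFs in descending length over *all* pairs
            info = cat.set_index("orf_id")
            support = {o: {p for p, os in peps if o in os} for o in info.index}
            order = sorted(info.index,
                           key=lambda o: (-info.loc[o, "length_nt"], o))
            dead = set()
            for L in order:
                if L in dead:
                    continue
                for S in order:
                    if S in (L,) or S in dead:
                        continue
                    if info.loc[S, "length_nt"] >= info.loc[L, "length_nt"]:
                        continue
                    if (info.loc[S, "g_min"] > info.loc[L, "g_max"]
                            or info.loc[L, "g_min"] > info.loc[S, "g_max"]):
                        continue
                    if any(p not in info.loc[S, "peptide"] for p in support[L]):
                        dead.add(S)
            surviving = {o for r in out["orf_ids"] for o in r}
            assert surviving == set(info.index) - dead

    def test_idempotent(self):
        cat = redundancy_catalogue(
            [("A", 100, 180, "MAAAAKWWWWKCCCCK"), ("B", 130, 90, "MWWWWKCCCCK")]
        )
        pep = pd.DataFrame(
            {"peptide": ["MAAAAK", "MWWWWK"], "orf_ids": [("A",), ("B",)]}
        )
        once = resolve_redundant_orfs(pep, cat)
        twice = resolve_redundant_orfs(once, cat)
        assert list(once["peptide"]) == list(twice["peptide"])


class TestSupportSummary:
    def test_single_psm_fraction(self):
        pep = pd.DataFrame(
            {"peptide": ["a", "b", "c"], "psm_count": [1, 2, 5],
             "samples": [("s1",), ("s1", "s2"), ("s1",)]}
        )
        s = summarize_support(pep)
        assert s["single_psm_fraction"] == pytest.approx(1 / 3)
        assert s["multi_psm_fraction"] == pytest.approx(2 / 3)
        assert s["multi_sample_fraction"] == pytest.approx(1 / 3)

    def test_fractions_sum_to_one(self, sim_catalogue):
        psms, _ = simulate_psm_table(sim_catalogue, seed=9)
        psms = psms.assign(
            orf_ids=psms["orf_ids"].map(lambda v: tuple(filter(None, v.split(";"))))
        )
        retained, _ = peptide_level_fdr(discard_ambiguous_spectra(psms), 0.01)
        s = summarize_support(retained)
        assert s["single_psm_fraction"] + s["multi_psm_fraction"] == pytest.approx(1.0)


class TestFilterReport:
    def test_rejects_increasing_counts(self):
        r = FilterReport()
        r.add("a", "psm", 10, 8)
        with pytest.raises(ValueError):
            r.add("b", "psm", 9, 10)
        with pytest.raises(ValueError):
            r.add("c", "psm", 9, 9)  # n_in exceeds previous n_out


class TestFullCascade:
    def test_fixture_pipeline_counts(self):
        from Bio import SeqIO

        psms = load_psm_table(DATA / "psm_fixture.tsv")
        catalogue = pd.read_csv(DATA / "catalogue_fixture.tsv", sep="\t")
        canonical = {
            r.id: str(r.seq)
            for r in SeqIO.parse(str(DATA / "canonical_synthetic.fasta"), "fasta")
        }
        final, report = run_psm_pipeline(psms, catalogue, canonical, alpha=0.01)
        counts = {s["stage"]: (s["n_in"], s["n_out"]) for s in report.stages}
        assert counts["ambiguity_filter"] == (40, 36)
        assert counts["peptide_fdr"] == (12, 10)
        assert counts["annotated_embedded_removal"] == (10, 8)
        assert counts["redundancy_resolution"] == (8, 7)
        assert len(final) == 7
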