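import numpy as np
import pandas as pd
import pytest

from fishkit import seqdb, thermo
from fishkit.genome import GenomeSequence, revcomp
from fishkit import fixtures

from _oracles import brute_count_sites


def cand_frame(seqs, spacing=100, k=None):
    k = k or len(seqs[0])
    rows = [("chr1", i * spacing, i * spacing + k, s) for i, s in enumerate(seqs)]
    return pd.DataFrame(rows, columns=seqdb.CAND_COLUMNS)


class TestUniqueKmers:
    def test_shorter_than_k_gives_empty(self):
        g = GenomeSequence({"c1": "ACG"})
        assert seqdb.extract_unique_kmers(g, 4).empty

    def test_canonical_counting_merges_strands(self):
        # ACGT occurs twice; CGTA/TACG merge to one canonical key with
        # count 2; GTAC is its own reverse complement with count 1
        g = GenomeSequence({"c1": "ACGTACGT"})
        df = seqdb.extract_unique_kmers(g, 4, canonical=True)
        assert list(df.itertuples(index=False, name=None)) == [("c1", 2, 6, "GTAC")]

    def test_forward_only_counting(self):
        g = GenomeSequence({"c1": "AAAACCCC"})
        df = seqdb.extract_unique_kmers(g, 4, canonical=False)
        assert len(df) == 5
        assert list(df["sequence"]) == ["AAAA", "AAAC", "AACC", "ACCC", "CCCC"]

    def test_kmers_with_n_are_excluded(self):
        g = GenomeSequence({"c1": "ACGTNACGA"})
        df = seqdb.extract_unique_kmers(g, 4, canonical=False)
        assert not df["sequence"].str.contains("N").any()

    def test_forward_unique_kmers_occur_once_by_brute_force(self):
        g = fixtures.synth_genome({"c1": 300}, seed=3)
        df = seqdb.extract_unique_kmers(g, 8, canonical=False)
        seq = g.records["c1"]
        for s in df["sequence"].sample(10, random_state=0):
            assert seq.count(s) == 1


class TestCompositionFilter:
    def test_homopolymer_and_gc_rejection(self):
        df = cand_frame(["A" * 40, "ACGT" * 10])
        out = seqdb.filter_composition(df)
        assert list(out["sequence"]) == ["ACGT" * 10]

    def test_bounds_are_inclusive(self):
        # exactly 14/40 GC = 0.35 and a run of exactly 6 both retained
        seq = "G" * 6 + "C" * 6 + "AT" * 13 + "GC"
        assert len(seq) == 40 and (seq.count("G") + seq.count("C")) == 14
        out = seqdb.filter_composition(cand_frame([seq]))
        assert len(out) == 1
        run7 = "G" * 7 + "C" * 5 + "AT" * 13 + "GC"
        assert seqdb.filter_composition(cand_frame([run7])).empty

    def test_idempotent_and_antimonotone(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), 40)) for _ in range(50)]
        df = cand_frame(seqs)
        once = seqdb.filter_composition(df)
        twice = seqdb.filter_composition(once)
        assert once.equals(twice)
        assert set(once["sequence"]) <= set(df["sequence"])


class TestTmWindow:
    def test_identical_sequences_all_retained(self):
        df = cand_frame(["ACGTACGTACGTACGTACGT"] * 5)
        assert len(seqdb.filter_tm_window(df)) == 5

    def test_single_candidate_is_its_own_mean(self):
        df = cand_frame(["ACGTACGTACGTACGTACGT"])
        out = seqdb.filter_tm_window(df)
        assert len(out) == 1 and "tm" in out.columns

    def test_extreme_gc_outlier_removed(self):
        seqs = ["ATATATATATATATATATAT"] * 6 + ["GCGCGCGCGCGCGCGCGCGC"]
        df = cand_frame(seqs)
        tms = [thermo.melting_temperature(s) for s in seqs]
        mean = sum(tms) / len(tms)
        assert tms[-1] - mean > 10  # construction check
        out = seqdb.filter_tm_window(df, half_width=10)
        assert len(out) == 6
        assert "GCGCGCGCGCGCGCGCGCGC" not in set(out["sequence"])


class TestHomology:
    def test_unique_candidate_counts_own_locus_once(self):
        g = fixtures.synth_genome({"c1": 500}, seed=5)
        cand = g.slice("c1", 100, 140)
        assert seqdb.count_homologous_sites(cand, g) == 1

    def test_exact_duplicate_elsewhere_counts_two(self, rng):
        base = fixtures.random_dna(400, rng)
        cand = base[100:140]
        g = GenomeSequence({"c1": base + "TTTT" + cand})
        assert seqdb.count_homologous_sites(cand, g) >= 2

    def test_site_at_exactly_70_percent_identity_counts(self, rng):
        base = fixtures.random_dna(400, rng)
        cand = base[50:90]
        mutated = fixtures.mutate_sequence(cand, 12, rng)  # 28/40 matches
        g = GenomeSequence({"c1": base + "TT" + mutated})
        n = seqdb.count_homologous_sites(cand, g, min_identity=0.70)
        assert n >= 2  # threshold is inclusive ("or higher")
        # at 13 mutations (27/40 < 70%) the planted site no longer counts
        mutated13 = fixtures.mutate_sequence(cand, 13, rng)
        g13 = GenomeSequence({"c1": base + "TT" + mutated13})
        assert seqdb.count_homologous_sites(cand, g13) == brute_count_sites(
            cand, g13.records, 28
        )

    def test_batch_counts_match_plain_loop_oracle(self, rng):
        g = fixtures.synth_genome({"c1": 200, "c2": 150}, seed=9)
        cands = [g.slice("c1", i * 20, i * 20 + 12) for i in range(5)]
        got = seqdb.count_sites_batch(cands, g, 9)
        want = [brute_count_sites(c, g.records, 9) for c in cands]
        assert list(got) == want


class TestOfftargets:
    def test_unique_candidate_not_flagged(self):
        g = fixtures.synth_genome({"c1": 500}, seed=6)
        assert seqdb.flag_offtargets(g.slice("c1", 0, 40), g) is False

    def test_eleven_one_mismatch_copies_flag(self, rng):
        cand = fixtures.random_dna(40, rng)
        parts = [cand]
        for _ in range(11):
            parts.append(fixtures.random_dna(10, rng))
            parts.append(fixtures.mutate_sequence(cand, 1, rng))
        g = GenomeSequence({"c1": "".join(parts)})
        assert seqdb.flag_offtargets(cand, g) is True

    def test_ten_copies_is_not_more_than_ten(self, rng):
        cand = fixtures.random_dna(40, rng)
        parts = [cand]
        for _ in range(10):
            parts.append(fixtures.random_dna(10, rng))
            parts.append(fixtures.mutate_sequence(cand, 2, rng))
        g = GenomeSequence({"c1": "".join(parts)})
        assert seqdb.flag_offtargets(cand, g) is False


class TestNonOverlap:
    def test_greedy_trace(self):
        df = pd.DataFrame(
            [("chr1", 0, 40, "x"), ("chr1", 20, 60, "y"), ("chr1", 50, 90, "z")],
            columns=seqdb.CAND_COLUMNS,
        )
        out = seqdb.select_nonoverlapping(df)
        assert list(zip(out["start"], out["end"])) == [(0, 40), (50, 90)]

    def test_disjoint_input_unchanged_and_identical_positions_collapse(self):
        df = cand_frame(["AAAA", "CCCC", "GGGG"], spacing=10)
        assert seqdb.select_nonoverlapping(df).equals(df)
        same = pd.DataFrame(
            [("chr1", 0, 4, "AAAA")] * 3, columns=seqdb.CAND_COLUMNS
        )
        assert len(seqdb.select_nonoverlapping(same)) == 1

    def test_unsorted_input_is_a_contract_violation(self):
        df = pd.DataFrame(
            [("chr1", 50, 90, "x"), ("chr1", 0, 40, "y")], columns=seqdb.CAND_COLUMNS
        )
        with pytest.raises(ValueError):
            seqdb.select_nonoverlapping(df)

    def test_output_disjoint_subset_preserving_order(self, rng):
        starts = np.sort(rng.integers(0, 2000, 80))
        df = pd.DataFrame(
            [("chr1", int(s), int(s) + 40, "s") for s in starts],
            columns=seqdb.CAND_COLUMNS,
        )
        out = seqdb.select_nonoverlapping(df)
        assert (out["start"].to_numpy()[1:] >= out["end"].to_numpy()[:-1]).all()
        assert out["start"].is_monotonic_increasing


class TestSecondaryStructure:
    def test_polya_retained_hairpin_rejected(self):
        arm = "GCCGCCGCCG"
        hp = arm + "AACAAA" + revcomp(arm) + "ACAACAACAACAAC"
        df = cand_frame(["A" * 40, hp])
        out = seqdb.filter_secondary_structure(df, temperature=65.0)
        assert list(out["sequence"]) == ["A" * 40]
        assert (out["dg_struct"] >= 0).all()  # dG == 0 boundary retained


class TestBuildDatabase:
    def test_poly_a_genome_yields_empty_database(self):
        g = GenomeSequence({"c1": "A" * 300})
        with pytest.warns(UserWarning):
            db = seqdb.build_database(g, k=40)
        assert len(db) == 0
        assert db.warnings_

    def test_disabled_filters_reduce_to_extract_plus_select(self):
        g = fixtures.synth_genome({"c1": 2_000}, seed=8)
        params = seqdb.DbParams(
            max_run=40, gc_min=0.0, gc_max=1.0,
            homology_filter=False, structure_filter=False, tm_filter=False,
        )
        db = seqdb.build_database(g, k=40, params=params)
        manual = seqdb.select_nonoverlapping(seqdb.extract_unique_kmers(g, 40))
        assert list(db.frame["start"]) == list(manual["start"])

    def test_pipeline_equals_stage_composition(self):
        g = fixtures.synth_genome({"c1": 3_000}, seed=12)
        params = seqdb.DbParams()
        db = seqdb.build_database(g, k=40, params=params)

        c = seqdb.extract_unique_kmers(g, 40, canonical=True)
        c = seqdb.filter_composition(c, params.max_run, params.gc_min, params.gc_max)
        c = c.assign(tm=[thermo.melting_temperature(s) for s in c["sequence"]])
        ref = float(c["tm"].mean())
        c = seqdb.filter_homology(c, g, params.homology_identity)
        c = seqdb.filter_secondary_structure(c, params.structure_temperature)
        c = seqdb.filter_tm_window(c, params.tm_half_width, reference_tm=ref)
        c = seqdb.select_nonoverlapping(c)
        c = seqdb.annotate_offtargets(c, g)
        assert list(db.frame["start"]) == list(c["start"])
        assert list(db.frame["sequence"]) == list(c["sequence"])

    def test_save_load_round_trip(self, tmp_path):
        g = fixtures.synth_genome({"c1": 1_500}, seed=13)
        db = seqdb.build_database(g, k=40)
        db.save(tmp_path / "db")
        back = seqdb.OligoDatabase.load(tmp_path / "db")
        assert back.k == db.k and back.frame.equals(db.frame)
        assert back.stage_counts == db.stage_counts


class TestConvertValidate:
    def test_three_row_bed_fills_sequences_from_genome(self, tmp_path, small_genome):
        bed = tmp_path / "in.bed"
        bed.write_text("chr1\t0\t40\nchr1\t100\t140\nchr2\t50\t90\n")
        db, report = seqdb.convert_database(bed, small_genome)
        assert len(db) == 3 and not report["errors"]
        assert db.frame.loc[0, "sequence"] == small_genome.slice("chr1", 0, 40)

    def test_one_based_conversion_decrements_starts(self, small_genome):
        df = pd.DataFrame({"chrom": ["chr1"], "start": [1], "end": [40]})
        db, _ = seqdb.convert_database(df, small_genome, one_based=True)
        assert db.frame.loc[0, "start"] == 0

    def test_out_of_bounds_row_reported(self, small_genome):
        df = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [0, 0],
                           "end": [40, 10**7]})
        db, report = seqdb.convert_database(df, small_genome)
        assert len(db) == 1 and len(report["errors"]) == 1

    def test_overlaps_reported_and_optionally_resolved(self, small_genome):
        df = pd.DataFrame({"chrom": ["chr1"] * 2, "start": [0, 20], "end": [40, 60]})
        _, report = seqdb.convert_database(df, small_genome)
        assert report["overlaps"]
        db, report2 = seqdb.convert_database(df, small_genome, resolve_overlaps=True)
        assert report2.get("resolved") and len(db) == 1

    def test_validate_flags_overlap_and_sequence_disagreement(self, small_genome):
        good = seqdb.convert_database(
            pd.DataFrame({"chrom": ["chr1"] * 2, "start": [0, 50], "end": [40, 90]}),
            small_genome,
        )[0]
        assert seqdb.validate_database(good, small_genome).passed

        bad = good.frame.copy()
        bad.loc[1, "start"], bad.loc[1, "end"] = 10, 50
        rep = seqdb.validate_database(
            seqdb.OligoDatabase(k=40, genome_id="g", frame=bad), small_genome
        )
        assert not rep.checks["non_overlapping"]
        assert rep.details["overlaps"]

        wrong = good.frame.copy()
        wrong.loc[0, "sequence"] = "T" * 40
        rep2 = seqdb.validate_database(
            seqdb.OligoDatabase(k=40, genome_id="g", frame=wrong), small_genome
        )
        assert not rep2.checks["sequence_agreement"]


class TestDatabaseStats:
    def test_uniform_database_closed_form(self):
        # oligos k=40 tiled with constant gap 20 over an exact number of cycles
        k, gap, n = 40, 20, 100
        length = n * (k + gap)
        g = fixtures.synth_genome({"c1": length}, seed=14)
        db = fixtures.synth_database(g, k=k, gap=gap, seed=0)
        stats = seqdb.database_stats(db, g, window_size=length, min_count=n)
        assert stats.median_window_gap_sd == 0.0
        assert stats.genome_coverage == pytest.approx(k / (k + gap))
        assert stats.frac_windows_ge_n == 1.0  # >= is inclusive

    def test_empty_database(self, small_genome):
        db = seqdb.OligoDatabase(k=40, genome_id="g", frame=pd.DataFrame(columns=seqdb.CAND_COLUMNS))
        stats = seqdb.database_stats(db, small_genome, 1000)
        assert stats.frac_windows_ge_n == 0.0 and stats.genome_coverage == 0.0

    def test_coverage_matches_base_masking(self, small_genome, jittered_db):
        stats = seqdb.database_stats(jittered_db, small_genome, 1000, min_count=5)
        mask_total = 0
        for chrom, grp in jittered_db.frame.groupby("chrom"):
            mask = np.zeros(small_genome.lengths[chrom], dtype=bool)
            for s, e in zip(grp["start"], grp["end"]):
                mask[s:e] = True
            mask_total += int(mask.sum())
        assert stats.genome_coverage == pytest.approx(
            mask_total / sum(small_genome.lengths.values())
        )
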