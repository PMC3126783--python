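import numpy as np
import pandas as pd
import pytest

import oracles
from seednet import motifs
from seednet.motifs import PWM, MarkovModel, MotifHit
from seednet.synthetic import random_pwms


def consensus_pwm(consensus: str, pwm_id: str = "MX") -> PWM:
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    matrix = np.zeros((len(consensus), 4))
    for j, b in enumerate(consensus):
        matrix[j, idx[b]] = 1.0
    return PWM(pwm_id, "test", matrix)


def random_seq(n, seed=0, gc=0.5):
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join("ACGT"[i] for i in rng.choice(4, size=n, p=p))


class TestPwmIO:
    def test_two_matrix_fixture_round_trip(self, tmp_path):
        pwms = random_pwms(2, seed=3, width_range=(5, 9))
        path = tmp_path / "pwms.txt"
        motifs.write_pwms(pwms, path)
        back = motifs.read_pwms(path)
        assert [p.id for p in back] == ["MA1", "MA2"]
        assert [p.width for p in back] == [p.width for p in pwms]
        for a, b in zip(pwms, back):
            assert np.abs(a.matrix - b.matrix).max() < 1e-3

    def test_row_sums_renormalized_on_load(self, tmp_path):
        (tmp_path / "p.txt").write_text(">M1 tf\n0.2501\t0.2501\t0.2501\t0.2501\n" * 1)
        pwm = motifs.read_pwms(tmp_path / "p.txt")[0]
        assert pwm.matrix.sum(axis=1) == pytest.approx(1.0)

    def test_malformed_rows_rejected(self, tmp_path):
        (tmp_path / "a.txt").write_text(">M1 tf\n0.5\t0.5\t0.0\n")
        with pytest.raises(ValueError, match="4 fields"):
            motifs.read_pwms(tmp_path / "a.txt")
        (tmp_path / "b.txt").write_text(">M1 tf\n-0.1\t0.5\t0.3\t0.3\n")
        with pytest.raises(ValueError, match="negative"):
            motifs.read_pwms(tmp_path / "b.txt")
        (tmp_path / "c.txt").write_text(">M1 tf\n\n>M2 tf\n0.25\t0.25\t0.25\t0.25\n")
        with pytest.raises(ValueError, match="empty"):
            motifs.read_pwms(tmp_path / "c.txt")


class TestScanRelative:
    def test_consensus_scores_one_on_plus_strand(self):
        pwm = consensus_pwm("ACGTAC")
        hits = motifs.scan_relative("ACGTAC", pwm, threshold=0.99)
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.strand) == (1, 1)
        assert h.rel_score == pytest.approx(1.0)

    def test_reverse_complement_hits_minus_strand_same_score(self):
        pwm = consensus_pwm("ACGTAA")
        hits = motifs.scan_relative(oracles.revcomp("ACGTAA"), pwm, threshold=0.99)
        assert len(hits) == 1
        assert hits[0].strand == -1
        assert hits[0].rel_score == pytest.approx(1.0)

    def test_matches_brute_force_window_oracle(self):
        seq = random_seq(500, seed=1, gc=0.4)
        pwm = random_pwms(1, seed=2, width_range=(7, 7))[0]
        hits = motifs.scan_relative(seq, pwm, threshold=0.55)
        expected = oracles.pwm_window_hits(seq, pwm.matrix.tolist(), 0.55)
        assert [(h.start, h.strand) for h in hits] == [(s, st) for s, st, _, _ in expected]
        for h, (_, _, rel, raw) in zip(hits, expected):
            assert h.rel_score == pytest.approx(rel, abs=1e-10)
            assert h.raw_score == pytest.approx(raw, abs=1e-10)

    def test_threshold_zero_returns_every_window_both_strands(self):
        seq = random_seq(120, seed=3)
        pwm = random_pwms(1, seed=4, width_range=(8, 8))[0]
        hits = motifs.scan_relative(seq, pwm, threshold=0.0)
        assert len(hits) == 2 * (120 - 8 + 1)

    def test_strand_closure_under_reverse_complement(self):
        seq = random_seq(200, seed=5, gc=0.35)
        pwm = random_pwms(1, seed=6, width_range=(9, 9))[0]
        fwd = motifs.scan_relative(seq, pwm, threshold=0.6)
        rev = motifs.scan_relative(oracles.revcomp(seq), pwm, threshold=0.6)
        mapped = {
            (len(seq) - h.end + 1, -h.strand, round(h.raw_score, 9)) for h in rev
        }
        assert {(h.start, h.strand, round(h.raw_score, 9)) for h in fwd} == mapped

    def test_windows_containing_n_are_skipped(self):
        pwm = consensus_pwm("ACGT")
        hits = motifs.scan_relative("ACNTACGT", pwm, threshold=0.0)
        starts = {(h.start, h.strand) for h in hits}
        assert all(s not in (1, 2, 3) for s, _ in starts)

    def test_raising_threshold_is_monotone(self):
        seq = random_seq(300, seed=7)
        pwm = random_pwms(1, seed=8)[0]
        lo = {(h.start, h.strand) for h in motifs.scan_relative(seq, pwm, 0.6)}
        hi = {(h.start, h.strand) for h in motifs.scan_relative(seq, pwm, 0.8)}
        assert hi <= lo

    def test_sequence_shorter_than_width_rejected(self):
        with pytest.raises(ValueError):
            motifs.scan_relative("ACG", consensus_pwm("ACGTAC"))


class TestMarkov:
    def test_conditionals_sum_to_one(self):
        model = motifs.train_markov([random_seq(2000, seed=9)], order=2)
        for table in model.probs:
            assert np.allclose(table.sum(axis=1), 1.0, atol=1e-12)

    def test_homopolymer_training_dominates_sampling(self):
        model = motifs.train_markov(["A" * 3000], order=0)
        seq = motifs.sample_markov(model, 1000, n=1, seed=0)[0]
        assert seq.count("A") / 1000 >= 0.99

    def test_sampling_deterministic_under_seed(self):
        model = MarkovModel.from_base_composition(0.33, order=4)
        a = motifs.sample_markov(model, 500, n=3, seed=11)
        b = motifs.sample_markov(model, 500, n=3, seed=11)
        assert a == b

    def test_sampled_composition_matches_stationary(self):
        model = MarkovModel.from_base_composition(0.40, order=2)
        seqs = motifs.sample_markov(model, 10000, n=100, seed=12)
        assert abs(motifs.gc_content(seqs) - 0.40) <= 0.01

    def test_order4_sampling_preserves_5mer_spectrum(self):
        rng = np.random.default_rng(13)
        # structured training text: biased composition with repeated motifs
        parts = []
        for _ in range(50):
            parts.append(random_seq(2000, seed=int(rng.integers(2**31)), gc=0.3))
        train = [p.replace("AAAA", "ACGT") for p in parts]
        model = motifs.train_markov(train, order=4)
        sampled = motifs.sample_markov(model, 2000, n=50, seed=14)

        def spectrum(seqs):
            counts = np.zeros(4**5)
            for s in seqs:
                idx = motifs._kmer_indices(motifs.encode(s), 5)
                counts += np.bincount(idx, minlength=4**5)
            return counts / counts.sum()

        r = np.corrcoef(spectrum(train), spectrum(sampled))[0, 1]
        assert r >= 0.95

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            motifs.train_markov([])


class TestCallFdr:
    def test_no_scannable_sequence_returns_empty(self):
        pwm = consensus_pwm("ACGTACGTAC")
        model = MarkovModel.from_base_composition(0.33)
        assert motifs.call_fdr({"s1": "ACG"}, pwm, model, seed=0) == []

    def test_planted_everywhere_recovers_most_placements(self):
        model = MarkovModel.from_base_composition(0.33, order=4)
        pwm = random_pwms(1, seed=15, width_range=(11, 11),
                          dominant_prob=(0.93, 0.97))[0]
        rng = np.random.default_rng(16)
        seqs, planted = {}, []
        backgrounds = motifs.sample_markov(model, 400, n=40, seed=17)
        for i, bg in enumerate(backgrounds):
            site = "".join(
                "ACGT"[rng.choice(4, p=pwm.matrix[j])] for j in range(pwm.width)
            )
            start = int(rng.integers(0, 400 - pwm.width + 1))
            seqs[f"s{i}"] = bg[:start] + site + bg[start + pwm.width:]
            planted.append((f"s{i}", start + 1))
        hits = motifs.call_fdr(seqs, pwm, model, seed=18)
        called = {(h.seq_id, h.start) for h in hits if h.strand == 1}
        recovered = sum(1 for p in planted if p in called)
        assert recovered / len(planted) >= 0.8

    def test_background_only_calls_are_rare(self):
        model = MarkovModel.from_base_composition(0.33, order=4)
        seqs = dict(
            zip(
                (f"s{i}" for i in range(30)),
                motifs.sample_markov(model, 400, n=30, seed=19),
            )
        )
        pwms = random_pwms(20, seed=20)
        quiet = 0
        for k, pwm in enumerate(pwms):
            hits = motifs.call_fdr(seqs, pwm, model, seed=21 + k)
            if len(hits) <= 3:
                quiet += 1
        assert quiet / len(pwms) >= 0.85

    def test_lowering_fdr_bound_is_monotone(self):
        model = MarkovModel.from_base_composition(0.33, order=4)
        seqs = dict(
            zip(
                (f"s{i}" for i in range(10)),
                motifs.sample_markov(model, 300, n=10, seed=22),
            )
        )
        pwm = random_pwms(1, seed=23)[0]
        strict = {
            h.key() for h in motifs.call_fdr(seqs, pwm, model, fdr_max=0.05, seed=24)
        }
        loose = {
            h.key() for h in motifs.call_fdr(seqs, pwm, model, fdr_max=0.30, seed=24)
        }
        assert strict <= loose


class TestConsensusHits:
    def hit(self, seq_id="s1", pwm_id="MA1", start=5, strand=1):
        return MotifHit(seq_id, pwm_id, start, start + 7, strand, 0.9, 3.0)

    def test_identical_lists_pass_through(self):
        hits = [self.hit(start=s) for s in (3, 9, 20)]
        assert motifs.consensus_hits(hits, list(hits)) == hits

    def test_disjoint_coordinates_empty(self):
        a = [self.hit(start=3)]
        b = [self.hit(start=4), self.hit(start=3, strand=-1)]
        assert motifs.consensus_hits(a, b) == []

    def test_random_overlap_matches_quadratic_oracle(self):
        rng = np.random.default_rng(25)
        def rand_hits(n):
            return [
                self.hit(
                    seq_id=f"s{rng.integers(3)}",
                    pwm_id=f"MA{rng.integers(2) + 1}",
                    start=int(rng.integers(1, 30)),
                    strand=int(rng.choice([1, -1])),
                )
                for _ in range(n)
            ]
        a, b = rand_hits(40), rand_hits(40)
        assert motifs.consensus_hits(a, b) == oracles.consensus_match(a, b)


class TestEnrichment:
    def test_hand_computed_mean_sd_flags_single_high_count(self):
        pwms = random_pwms(4, seed=26)
        hits = []
        counts = {"MA1": 5, "MA2": 1, "MA3": 1, "MA4": 1}
        for pwm_id, n in counts.items():
            hits += [MotifHit("g1", pwm_id, i + 1, i + 8, 1, 0.9, 1.0) for i in range(n)]
        table = motifs.enrichment(hits, pwms, {"g1"})
        assert table.mean == 2.0 and table.sd == 2.0
        flagged = set(table.counts.loc[table.counts.overrepresented, "pwm_id"])
        assert flagged == {"MA1"}

    def test_equal_counts_flag_nothing(self):
        pwms = random_pwms(3, seed=27)
        hits = [MotifHit("g1", p.id, 1, 8, 1, 0.9, 1.0) for p in pwms]
        table = motifs.enrichment(hits, pwms, {"g1"})
        assert not table.counts.overrepresented.any()

    def test_flag_monotone_in_count(self):
        pwms = random_pwms(5, seed=28)
        def flagged_at(extra):
            hits = [MotifHit("g1", "MA1", i + 1, i + 8, 1, 0.9, 1.0) for i in range(extra)]
            hits += [MotifHit("g1", p.id, 1, 8, 1, 0.9, 1.0) for p in pwms[1:]]
            table = motifs.enrichment(hits, pwms, {"g1"})
            return bool(
                table.counts.set_index("pwm_id").loc["MA1", "overrepresented"]
            )
        results = [flagged_at(n) for n in range(0, 12)]
        assert results == sorted(results)  # once flagged, stays flagged

    def test_needs_two_pwms(self):
        with pytest.raises(ValueError):
            motifs.enrichment([], random_pwms(1, seed=29), set())


class TestAwBox:
    def test_direct_instance_on_plus_strand(self):
        assert motifs.scan_aw_box("CATAGAAAAAAAC") == [(1, 1)]

    def test_reverse_complement_instance_on_minus_strand(self):
        seq = oracles.revcomp("CATAGAAAAAAAC")
        assert motifs.scan_aw_box(seq) == [(1, -1)]

    def test_matches_brute_force_oracle_on_long_random_sequence(self):
        seq = random_seq(10000, seed=30, gc=0.35)
        assert motifs.scan_aw_box(seq) == oracles.aw_box_matches(seq)


class TestSmallStats:
    def test_gc_content_examples(self):
        assert motifs.gc_content(["GGCC"]) == 1.0
        assert motifs.gc_content(["ATAT"]) == 0.0
        assert motifs.gc_content(["ANGC"]) == pytest.approx(2 / 3)
        with pytest.raises(ValueError):
            motifs.gc_content(["NNN"])

    def test_information_content_closed_forms(self):
        certain = consensus_pwm("A")
        assert motifs.information_content(certain)[0] == pytest.approx(2.0)
        uniform = PWM("U", "u", np.full((1, 4), 0.25))
        assert motifs.information_content(uniform)[0] == pytest.approx(0.0)
        half = PWM("H", "h", np.array([[0.5, 0.5, 0.0, 0.0]]))
        assert motifs.information_content(half)[0] == pytest.approx(1.0)


class TestExtractPromoters:
    def genome(self):
        return {"chr1": random_seq(5000, seed=31)}

    def table(self, **kw):
        row = dict(gene="g1", chrom="chr1", tss=2001, strand="+", neighbor=None)
        row.update(kw)
        return pd.DataFrame([row])

    def test_plus_strand_coordinates(self):
        genome = self.genome()
        out = motifs.extract_promoters(genome, self.table())
        assert out["g1"] == genome["chr1"][1000:2200]
        assert len(out["g1"]) == 1200

    def test_truncation_at_upstream_neighbor(self):
        out = motifs.extract_promoters(
            self.genome(), self.table(neighbor=2001 - 600 - 1)
        )
        assert len(out["g1"]) == 800  # 600 upstream + 200 UTR

    def test_minus_strand_is_mirror_image(self):
        genome = self.genome()
        out = motifs.extract_promoters(genome, self.table(strand="-", tss=3000))
        expected = oracles.revcomp(genome["chr1"][3000 - 200 : 3000 + 1000])
        assert out["g1"] == expected

    def test_clipped_at_chromosome_start(self):
        out = motifs.extract_promoters(self.genome(), self.table(tss=301))
        assert len(out["g1"]) == 300 + 200

    def test_errors(self):
        with pytest.raises(ValueError, match="chromosome"):
            motifs.extract_promoters(self.genome(), self.table(chrom="chrX"))
        with pytest.raises(ValueError, match="strand"):
            motifs.extract_promoters(self.genome(), self.table(strand="fwd"))
        with pytest.raises(ValueError, match="TSS"):
            motifs.extract_promoters(self.genome(), self.table(tss=9999))


def test_fasta_round_trip(tmp_path):
    seqs = {"a": "ACGTACGT", "b": "TTTTAAAA"}
    motifs.write_fasta(seqs, tmp_path / "x.fasta")
    assert motifs.read_fasta(tmp_path / "x.fasta") == seqs


def test_hit_table_columns(tmp_path):
    pwms = random_pwms(1, seed=32)
    hits = [MotifHit("s1", "MA1", 4, 11, -1, 0.91, 2.5)]
    motifs.write_hits(hits, pwms, tmp_path / "hits.tsv")
    df = pd.read_csv(tmp_path / "hits.tsv", sep="\t")
    assert list(df.columns) == [
        "seq_id", "pwm_id", "tf_name", "start", "end", "strand",
        "rel_score", "raw_score",
    ]
    assert df.loc[0, "strand"] == -1
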