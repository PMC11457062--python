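"""Sex-linked-region detector tests: k-mer machinery, pattern scan, coverage."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pikescan import sexlink, synth
from pikescan.io import SampleSheet
from tests.test_diversity import make_sheet, make_table

K = 31


def sheet_3v3(pop="P"):
    return make_sheet({
        "m1": (pop, "male"), "m2": (pop, "male"), "m3": (pop, "male"),
        "f1": (pop, "female"), "f2": (pop, "female"), "f3": (pop, "female"),
    })


def kmer_string(i: int) -> str:
    """Distinct canonical 31-mers indexed by integer."""
    code = np.asarray([i], dtype=np.uint64)
    canon = sexlink.canonical_codes(code, K)[0]
    return sexlink.decode_kmer(int(canon), K)


class TestKmerPrimitives:
    def test_encode_decode_roundtrip(self):
        for s in ("A" * K, "ACGTACGTACGTACGTACGTACGTACGTACG"):
            assert sexlink.decode_kmer(sexlink.encode_kmer(s), K) == s

    @given(st.integers(min_value=0, max_value=4**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_revcomp_involution(self, code):
        arr = np.asarray([code], dtype=np.uint64)
        assert sexlink.revcomp_codes(sexlink.revcomp_codes(arr, K), K)[0] == arr[0]

    @given(st.integers(min_value=0, max_value=4**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_canonical_symmetry(self, code):
        arr = np.asarray([code], dtype=np.uint64)
        rc = sexlink.revcomp_codes(arr, K)
        assert sexlink.canonical_codes(arr, K)[0] == sexlink.canonical_codes(rc, K)[0]


class TestCountKmers:
    @staticmethod
    def _fastq(path, reads):
        with open(path, "w") as fh:
            for i, r in enumerate(reads):
                fh.write(f"@r{i}\n{r}\n+\nI\n")
        return path

    def test_manual_enumeration_12bp_k5(self, tmp_path):
        # oracle: hand enumeration of 5-mers of ACGTACGTACGT
        read = "ACGTACGTACGT"
        fq = self._fastq(tmp_path / "a.fastq", [read])
        counts = sexlink.count_kmers({"s": fq}, k=5)
        expected = {}
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for i in range(len(read) - 5 + 1):
            kmer = read[i:i + 5]
            rc = "".join(comp[b] for b in reversed(kmer))
            canon = min(kmer, rc)
            expected[canon] = expected.get(canon, 0) + 1
        codes, tallies = counts.per_sample["s"]
        got = {sexlink.decode_kmer(int(c), 5): int(t) for c, t in zip(codes, tallies)}
        assert got == expected

    def test_revcomp_read_same_count_set(self, tmp_path):
        read = "ACGGTAGCCATTGACGGATCAGGCAT"
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rc = "".join(comp[b] for b in reversed(read))
        fq1 = self._fastq(tmp_path / "f.fastq", [read])
        fq2 = self._fastq(tmp_path / "r.fastq", [rc])
        c1 = sexlink.count_kmers({"s": fq1}, k=7).per_sample["s"]
        c2 = sexlink.count_kmers({"s": fq2}, k=7).per_sample["s"]
        assert np.array_equal(c1[0], c2[0]) and np.array_equal(c1[1], c2[1])

    def test_n_window_excluded(self, tmp_path):
        fq = self._fastq(tmp_path / "n.fastq", ["ACGTANGTACG"])
        counts = sexlink.count_kmers({"s": fq}, k=5)
        codes, _ = counts.per_sample["s"]
        # only windows fully left or right of the N survive: ACGTA and GTACG
        assert len(codes) == 2

    def test_even_k_rejected(self, tmp_path):
        fq = self._fastq(tmp_path / "e.fastq", ["ACGTACGT"])
        with pytest.raises(ValueError, match="odd"):
            sexlink.count_kmers({"s": fq}, k=4)

    def test_empty_fastq_warns(self, tmp_path):
        path = tmp_path / "empty.fastq"
        path.write_text("")
        with pytest.warns(UserWarning, match="empty"):
            counts = sexlink.count_kmers({"s": path}, k=5)
        assert counts.per_sample["s"][0].size == 0


class TestSexSpecificKmers:
    @staticmethod
    def _counts(male_counts, female_counts, kmer="ACG" * 10 + "A"):
        per = {}
        for i, c in enumerate(male_counts, 1):
            per[f"m{i}"] = {kmer: c} if c else {}
        for i, c in enumerate(female_counts, 1):
            per[f"f{i}"] = {kmer: c} if c else {}
        return sexlink.KmerCountSet.from_counts(K, per)

    def test_published_threshold_example(self):
        counts = self._counts((3, 3, 3), (0, 1, 2))
        out = sexlink.sex_specific_kmers(counts, sheet_3v3(), "P", "male")
        assert len(out) == 1

    def test_sum_boundary_rejected(self):
        counts = self._counts((3, 3, 1), (0, 0, 0))  # sum 7 is not > 7
        out = sexlink.sex_specific_kmers(counts, sheet_3v3(), "P", "male")
        assert len(out) == 0

    def test_sum_eight_retained(self):
        counts = self._counts((3, 3, 2), (0, 0, 0))
        out = sexlink.sex_specific_kmers(counts, sheet_3v3(), "P", "male")
        assert len(out) == 1

    def test_opposite_above_max_rejected(self):
        counts = self._counts((5, 5, 5), (0, 0, 3))
        out = sexlink.sex_specific_kmers(counts, sheet_3v3(), "P", "male")
        assert len(out) == 0

    def test_fewer_than_three_per_sex_errors(self):
        sheet = make_sheet({"m1": ("P", "male"), "m2": ("P", "male"),
                            "f1": ("P", "female"), "f2": ("P", "female"),
                            "f3": ("P", "female")})
        counts = sexlink.KmerCountSet.from_counts(K, {s: {} for s in sheet.samples})
        with pytest.raises(ValueError, match="at least 3"):
            sexlink.sex_specific_kmers(counts, sheet, "P", "male")

    def test_exhaustive_grid_matches_predicate(self):
        # full {0..4}^3 x {0..4}^3 grid, one k-mer per combination
        rule = sexlink.SexKmerRule()
        combos = list(itertools.product(range(5), repeat=6))
        kmers = {}
        seen = set()
        i = 0
        while len(kmers) < len(combos):
            s = kmer_string(i)
            i += 1
            if s not in seen:
                seen.add(s)
                kmers[len(kmers)] = s
        per = {s: {} for s in ("m1", "m2", "m3", "f1", "f2", "f3")}
        for idx, combo in enumerate(combos):
            kmer = kmers[idx]
            for j in range(3):
                if combo[j]:
                    per[f"m{j + 1}"][kmer] = combo[j]
                if combo[3 + j]:
                    per[f"f{j + 1}"][kmer] = combo[3 + j]
        counts = sexlink.KmerCountSet.from_counts(K, per)
        out = sexlink.sex_specific_kmers(counts, sheet_3v3(), "P", "male", rule)
        got = {sexlink.decode_kmer(int(c), K) for c in out}
        expected = set()
        for idx, (m1, m2, m3, f1, f2, f3) in enumerate(combos):
            males, females = (m1, m2, m3), (f1, f2, f3)
            if (all(c >= rule.target_min for c in males)
                    and sum(males) > rule.target_sum_min_exclusive
                    and all(c <= rule.opposite_max for c in females)):
                expected.add(kmers[idx])
        assert got == expected

    @given(
        opp=st.integers(min_value=0, max_value=6),
        tgt=st.integers(min_value=0, max_value=4),
        seed=st.integers(min_value=0, max_value=100),
    )
    @settings(max_examples=40, deadline=None)
    def test_rule_monotonicity(self, opp, tgt, seed):
        rng = np.random.default_rng(seed)
        per = {}
        names = ["m1", "m2", "m3", "f1", "f2", "f3"]
        kmers = [kmer_string(i) for i in range(12)]
        for s in names:
            per[s] = {k: int(c) for k, c in zip(kmers, rng.integers(0, 8, size=12)) if c}
        counts = sexlink.KmerCountSet.from_counts(K, per)
        sheet = sheet_3v3()

        def retained(rule):
            return set(sexlink.sex_specific_kmers(counts, sheet, "P", "male", rule).tolist())

        base = retained(sexlink.SexKmerRule(opposite_max=opp, target_min=tgt))
        looser_opp = retained(sexlink.SexKmerRule(opposite_max=opp + 1, target_min=tgt))
        stricter_tgt = retained(sexlink.SexKmerRule(opposite_max=opp, target_min=tgt + 1))
        assert base <= looser_opp
        assert stricter_tgt <= base


class TestMapKmers:
    def test_verbatim_reference_kmer_hits(self):
        ref = synth.simulate_reference([("chr1", 5_000)], seed=2)
        seq = ref.sequences["chr1"]
        pos0 = 1234
        window = seq[pos0:pos0 + K].astype(np.uint8)
        code = 0
        for b in window:
            code = (code << 2) | int(b)
        canon = sexlink.canonical_codes(np.asarray([code], dtype=np.uint64), K)
        hits, n_unmapped = sexlink.map_kmers_to_genome(canon, ref, K)
        assert n_unmapped == 0
        assert (pos0 + 1) in hits["pos"].tolist()

    def test_insert_kmer_unmapped(self):
        ref = synth.simulate_reference([("chr1", 5_000)], seed=2)
        rng = np.random.default_rng(99)
        foreign = rng.integers(0, 4, size=100).astype(np.uint8)
        codes, _ = sexlink._rolling_codes(foreign, K)
        canon = sexlink.canonical_codes(codes[:5], K)
        hits, n_unmapped = sexlink.map_kmers_to_genome(canon, ref, K)
        assert hits.empty and n_unmapped == 5

    def test_planted_kmers_hit_planting_coordinates(self):
        ref = synth.simulate_reference([("chr1", 200_000)], seed=4)
        rng = np.random.default_rng(1)
        planted = sorted(rng.choice(200_000 - K, size=100, replace=False).tolist())
        queries = []
        for p in planted:
            codes, _ = sexlink._rolling_codes(ref.sequences["chr1"][p:p + K], K)
            queries.append(codes[0])
        canon = sexlink.canonical_codes(np.asarray(queries, dtype=np.uint64), K)
        hits, _ = sexlink.map_kmers_to_genome(canon, ref, K)
        got_pos = set(hits["pos"].tolist())
        assert {p + 1 for p in planted} <= got_pos

    def test_one_mismatch_mode_recovers_mutated_kmer(self):
        ref = synth.simulate_reference([("chr1", 10_000)], seed=5)
        window = ref.sequences["chr1"][500:500 + K].copy()
        window[15] = (window[15] + 1) % 4  # mutate mid-base
        codes, _ = sexlink._rolling_codes(window, K)
        canon = sexlink.canonical_codes(codes, K)
        hits0, unmapped0 = sexlink.map_kmers_to_genome(canon, ref, K, max_mismatches=0)
        hits1, unmapped1 = sexlink.map_kmers_to_genome(canon, ref, K, max_mismatches=1)
        assert unmapped0 == 1
        assert unmapped1 == 0 and 501 in hits1["pos"].tolist()


class TestKmerWindowDensity:
    def test_all_hits_one_window(self):
        from pikescan.windows import make_windows

        wins = make_windows([("chr1", 50_000)], width=10_000)
        hits = pd.DataFrame({"kmer_code": [1, 2, 3], "chrom": ["chr1"] * 3,
                             "pos": [15_000, 15_500, 16_000]})
        dens = sexlink.kmer_window_density(hits, wins)
        assert [d.n_variants for d in dens] == [0, 3, 0, 0, 0]

    def test_empty_hits_all_zero(self):
        from pikescan.windows import make_windows

        wins = make_windows([("chr1", 30_000)], width=10_000)
        hits = pd.DataFrame(columns=["kmer_code", "chrom", "pos"])
        dens = sexlink.kmer_window_density(hits, wins)
        assert all(d.n_variants == 0 for d in dens)


class TestPrefilter:
    def test_hom_alt_site_dropped(self):
        table = make_table([[1, 2, 0], [1, 1, 0]], ["m1", "m2", "f1"])
        keep = sexlink.prefilter_sex_sites(table, ["m1", "m2", "f1"])
        assert keep.tolist() == [False, True]

    def test_het_homref_kept(self):
        table = make_table([[1, 0, 0]], ["m1", "m2", "f1"])
        assert sexlink.prefilter_sex_sites(table, ["m1", "m2", "f1"]).tolist() == [True]

    def test_empty_group_errors(self):
        table = make_table([[0]], ["m1"])
        with pytest.raises(ValueError):
            sexlink.prefilter_sex_sites(table, [])

    def test_brute_force_30_sites(self):
        rng = np.random.default_rng(21)
        codes = rng.choice([-1, 0, 1, 2], size=(30, 6), p=[0.05, 0.5, 0.3, 0.15])
        samples = ["m1", "m2", "m3", "f1", "f2", "f3"]
        table = make_table(codes, samples)
        keep = sexlink.prefilter_sex_sites(table, samples)
        expected = [not any(c == 2 for c in row) for row in codes]
        assert keep.tolist() == expected


class TestExactPatternScan:
    def test_cht_pattern(self):
        codes = [[1] * 5 + [0] * 5]  # 5 males het, 5 females hom-ref
        samples = [f"m{i}" for i in range(5)] + [f"f{i}" for i in range(5)]
        sheet = make_sheet({s: ("P", "male" if s.startswith("m") else "female")
                            for s in samples})
        patterns, hist = sexlink.exact_pattern_scan(make_table(codes, samples), sheet)
        assert len(patterns) == 1 and patterns[0].pattern == "male_specific_het"
        assert hist == {"chr1": {0: 1}}

    def test_tolerance_boundary(self):
        codes = [[1, 1, 1, 1, 0] + [0] * 5]  # 4/5 males het
        samples = [f"m{i}" for i in range(5)] + [f"f{i}" for i in range(5)]
        sheet = make_sheet({s: ("P", "male" if s.startswith("m") else "female")
                            for s in samples})
        table = make_table(codes, samples)
        assert not sexlink.exact_pattern_scan(table, sheet, tolerance=0)[0]
        found = sexlink.exact_pattern_scan(table, sheet, tolerance=1)[0]
        assert len(found) == 1

    def test_planted_sites_recovered_exactly(self, cohort_bundle):
        table, sheet, truth = (cohort_bundle["table"], cohort_bundle["sheet"],
                               cohort_bundle["truth"])
        cht = sheet.members("CHT")
        sub = table.subset_samples(cht)
        patterns, _ = sexlink.exact_pattern_scan(sub, sheet)
        male_sites = {(p.chrom, p.pos) for p in patterns
                      if p.pattern == "male_specific_het"}
        planted = {(table.chrom[i], int(table.pos[i]))
                   for i, c in enumerate(truth.site_class) if c == "male_linked"}
        assert planted <= male_sites
        # false positives bounded below 1% of sites
        assert len(male_sites - planted) < 0.01 * table.n_sites

    def test_missing_sex_errors(self):
        table = make_table([[0]], ["m1"])
        sheet = make_sheet({"m1": ("P", "male")})
        with pytest.raises(ValueError):
            sexlink.exact_pattern_scan(table, sheet)

    def test_null_cohort_false_positive_control(self, null_cohort_bundle):
        # expected hits under HWE: per site prod_m P(het) * prod_f P(homref)
        table, sheet, truth = (null_cohort_bundle["table"],
                               null_cohort_bundle["sheet"],
                               null_cohort_bundle["truth"])
        patterns, _ = sexlink.exact_pattern_scan(table, sheet)
        male_hits = sum(p.pattern == "male_specific_het" for p in patterns)
        pops = [p for p, _, _ in null_cohort_bundle["cohort"].spec.populations]
        n_m = sum(1 for s in table.samples if sheet.sex_of(s) == "male")
        n_f = sum(1 for s in table.samples if sheet.sex_of(s) == "female")
        pop_of = {s: sheet.population_of(s) for s in table.samples}
        sex_of = {s: sheet.sex_of(s) for s in table.samples}
        expected = 0.0
        for i, freq_row in enumerate(truth.pop_freqs):
            freq = dict(zip(pops, freq_row))
            p_site = 1.0
            for s in table.samples:
                p = freq[pop_of[s]]
                if sex_of[s] == "male":
                    p_site *= 2 * p * (1 - p)
                else:
                    p_site *= (1 - p) ** 2
            expected += p_site
        assert male_hits <= max(3 * expected, 5)


class TestSexDapcScreen:
    def test_candidates_concentrate_in_planted_interval(self, cohort_bundle):
        table, sheet, truth = (cohort_bundle["table"], cohort_bundle["sheet"],
                               cohort_bundle["truth"])
        cht = sheet.members("CHT")
        sub = table.subset_samples(cht)
        sub = sub.subset_sites(sexlink.prefilter_sex_sites(sub, cht))
        candidates, _ = sexlink.sex_dapc_screen(sub, sheet, n_pc=6)
        assert candidates
        region = truth.sex_region
        inside = [c for c in candidates
                  if c.chrom == region["chrom"]
                  and region["start"] <= c.pos <= region["end"]]
        assert len(inside) >= 0.9 * len(candidates)

    def test_null_cohort_no_dense_interval(self, null_cohort_bundle):
        table, sheet = null_cohort_bundle["table"], null_cohort_bundle["sheet"]
        members = sheet.members("CHT")
        sub = table.subset_samples(members)
        sub = sub.subset_sites(sexlink.prefilter_sex_sites(sub, members))
        candidates, _ = sexlink.sex_dapc_screen(sub, sheet, n_pc=6)
        per_100kb: dict = {}
        for c in candidates:
            key = (c.chrom, c.pos // 100_000)
            per_100kb[key] = per_100kb.get(key, 0) + 1
        assert all(v < 5 for v in per_100kb.values())

    def test_permuted_sexes_collapse(self, cohort_bundle):
        table, sheet = cohort_bundle["table"], cohort_bundle["sheet"]
        cht = sheet.members("CHT")
        sub = table.subset_samples(cht)
        sub = sub.subset_sites(sexlink.prefilter_sex_sites(sub, cht))
        true_candidates, _ = sexlink.sex_dapc_screen(sub, sheet, n_pc=6)

        rng = np.random.default_rng(3)
        frame = sheet.frame.copy()
        cht_mask = frame["population"] == "CHT"
        sexes = frame.loc[cht_mask, "sex"].to_numpy()
        rng.shuffle(sexes)
        frame.loc[cht_mask, "sex"] = sexes
        permuted_sheet = SampleSheet(frame)
        perm_candidates, _ = sexlink.sex_dapc_screen(sub, permuted_sheet, n_pc=6)
        assert len(perm_candidates) < 0.1 * max(len(true_candidates), 1)


class TestCoverageRatio:
    @staticmethod
    def _depth(rows):
        return pd.DataFrame(rows, columns=["sample", "region", "mean_depth"])

    def test_hemizygous_present(self):
        depth = self._depth([("s1", "amhby", 12.0), ("s1", "chr1", 24.0)])
        calls = sexlink.coverage_ratio_genotype(depth, "amhby", "chr1")
        assert calls[0].ratio == 0.5 and calls[0].call == "present"

    def test_zero_target_absent(self):
        depth = self._depth([("s1", "amhby", 0.0), ("s1", "chr1", 20.0)])
        calls = sexlink.coverage_ratio_genotype(depth, "amhby", "chr1")
        assert calls[0].call == "absent"

    def test_zero_control_errors(self):
        depth = self._depth([("s1", "amhby", 5.0), ("s1", "chr1", 0.0)])
        with pytest.raises(ValueError, match="s1"):
            sexlink.coverage_ratio_genotype(depth, "amhby", "chr1")

    def test_rescaling_invariance(self):
        d1 = self._depth([("s1", "amhby", 8.0), ("s1", "chr1", 20.0)])
        d2 = self._depth([("s1", "amhby", 80.0), ("s1", "chr1", 200.0)])
        c1 = sexlink.coverage_ratio_genotype(d1, "amhby", "chr1")
        c2 = sexlink.coverage_ratio_genotype(d2, "amhby", "chr1")
        assert c1[0].ratio == c2[0].ratio and c1[0].call == c2[0].call

    def test_simulated_cohort_calls(self, cohort_bundle):
        cohort, truth = cohort_bundle["cohort"], cohort_bundle["truth"]
        depth = synth.simulate_depth_table(cohort, truth, coverage_x=15.0, seed=2)
        calls = sexlink.coverage_ratio_genotype(depth, "male_insert", "chr1")
        assert all(c.call != "ambiguous" for c in calls)
        for c in calls:
            assert (c.call == "present") == truth.carrier[c.sample]
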