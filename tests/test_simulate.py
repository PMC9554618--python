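"""Read-simulator, downsampler and dataset-builder tests."""

import numpy as np
import pysam
import pytest

import detext as dx
from detext.signatures import canonical_class


class TestSeedSnvs:
    def test_zero_snvs_identity(self):
        ref = dx.random_reference(500, seed=0)
        hap, truth = dx.seed_snvs(ref, 0, 0)
        assert hap == ref
        assert truth == []

    def test_truth_consistent_with_haplotype(self, cosmic_max_table):
        ref = dx.random_reference(5000, seed=1)
        hap, truth = dx.seed_snvs(ref, 80, 1, cosmic_max_table)
        assert len(truth) == 80
        assert len({(v.chrom, v.pos) for v in truth}) == 80
        for v in truth:
            assert ref[v.chrom][v.pos - 1] == v.ref
            assert hap[v.chrom][v.pos - 1] == v.alt
            assert v.ref != v.alt

    def test_same_seed_same_truth(self):
        ref = dx.random_reference(2000, seed=2)
        t1 = dx.seed_snvs(ref, 30, 9)[1]
        t2 = dx.seed_snvs(ref, 30, 9)[1]
        assert [(v.pos, v.alt) for v in t1] == [(v.pos, v.alt) for v in t2]

    def test_too_many_snvs_rejected(self):
        ref = dx.random_reference(50, seed=0)
        with pytest.raises(ValueError):
            dx.seed_snvs(ref, 500, 0)

    def test_signature_skew_enriches_hot_class(self, cosmic_max_table):
        # T[C>T]A holds 42% of the table mass; uniform seeding gives ~1%
        ref = dx.random_reference(50_000, seed=3)
        _, truth = dx.seed_snvs(ref, 500, 3, cosmic_max_table)
        hot = 0
        for v in truth:
            ctx = ref[v.chrom][v.pos - 2 : v.pos + 1]
            cls = canonical_class(ctx[0], v.ref, v.alt, ctx[2])
            hot += cls.key == "T[C>T]A"
        assert hot / len(truth) > 0.25


class TestSimulateReads:
    def test_no_errors_no_snvs_means_no_mismatches(self, tmp_path):
        ref = dx.random_reference(5000, seed=4)
        sam = tmp_path / "clean.sam"
        dx.simulate_reads(ref, None, dx.SimConfig(depth=3, error_rate=0.0, seed=4), sam)
        from detext.pipeline import iter_candidates

        assert sum(1 for _ in iter_candidates(sam, ref)) == 0

    def test_error_rate_within_binomial_tolerance(self, tmp_path):
        ref = dx.random_reference(10_000, seed=5)
        sam = tmp_path / "err.sam"
        dx.simulate_reads(ref, None, dx.SimConfig(depth=12, error_rate=0.001, seed=5), sam)
        n_mismatch = 0
        n_bases = 0
        with pysam.AlignmentFile(str(sam)) as f:
            for rec in f:
                seq = ref[rec.reference_name]
                start = rec.reference_start
                n_bases += len(rec.query_sequence)
                n_mismatch += sum(
                    b != seq[start + i] for i, b in enumerate(rec.query_sequence)
                )
        assert n_bases >= 1e5
        p = 0.001
        se = np.sqrt(p * (1 - p) / n_bases)
        assert abs(n_mismatch / n_bases - p) < 3 * se

    def test_quality_ranges_split_by_error_status(self, tmp_path):
        ref = dx.random_reference(8000, seed=6)
        sam = tmp_path / "q.sam"
        dx.simulate_reads(ref, None, dx.SimConfig(depth=10, error_rate=0.005, seed=6), sam)
        with pysam.AlignmentFile(str(sam)) as f:
            for rec in f:
                seq = ref[rec.reference_name]
                start = rec.reference_start
                for i, b in enumerate(rec.query_sequence):
                    q = rec.query_qualities[i]
                    if b == seq[start + i]:
                        assert 33 <= q <= 36
                    else:
                        assert 7 <= q <= 19

    def test_mean_depth_near_target(self, tmp_path):
        ref = dx.random_reference(10_000, seed=7)
        sam = tmp_path / "d.sam"
        target = 6
        dx.simulate_reads(ref, None, dx.SimConfig(depth=target, seed=7), sam)
        total = 0
        with pysam.AlignmentFile(str(sam)) as f:
            for rec in f:
                total += rec.query_length
        depth = total / 10_000
        assert abs(depth - target) / target < 0.10

    def test_sam_parses_sorted_with_consistent_mates(self, toy_simulation):
        with pysam.AlignmentFile(str(toy_simulation["sam"])) as f:
            assert f.header["HD"]["SO"] == "coordinate"
            last = -1
            by_name = {}
            for rec in f:
                assert last <= rec.reference_start
                last = rec.reference_start
                by_name.setdefault(rec.query_name, []).append(rec)
            for name, pair in by_name.items():
                assert len(pair) == 2, f"orphaned mate for {name}"
                r1 = next(r for r in pair if r.is_read1)
                r2 = next(r for r in pair if r.is_read2)
                assert r1.next_reference_start == r2.reference_start
                assert r2.next_reference_start == r1.reference_start


class TestDownsample:
    def _duplicated_sam(self, tmp_path, pairs_per_pos):
        """Pairs stacked at identical start positions to exercise capping."""
        ref = dx.random_reference(2000, seed=8, name="chrD")
        header = pysam.AlignmentHeader.from_dict(
            {"HD": {"VN": "1.6", "SO": "coordinate"},
             "SQ": [{"SN": "chrD", "LN": 2000}]}
        )
        sam = tmp_path / "dup.sam"
        records = []
        for start in (100, 500, 900):
            for k in range(pairs_per_pos):
                name = f"p{start}.{k}"
                for pos, flag, mpos in (
                    (start, 0x1 | 0x2 | 0x20 | 0x40, start + 150),
                    (start + 150, 0x1 | 0x2 | 0x10 | 0x80, start),
                ):
                    a = pysam.AlignedSegment(header)
                    a.query_name = name
                    a.query_sequence = ref["chrD"][pos : pos + 50]
                    a.flag = flag
                    a.reference_id = 0
                    a.reference_start = pos
                    a.mapping_quality = 60
                    a.cigarstring = "50M"
                    a.next_reference_id = 0
                    a.next_reference_start = mpos
                    records.append(a)
        records.sort(key=lambda r: r.reference_start)
        with pysam.AlignmentFile(sam, "w", header=header) as out:
            for r in records:
                out.write(r)
        return sam

    def _pairs_per_position(self, sam):
        starts = {}
        with pysam.AlignmentFile(str(sam)) as f:
            recs = list(f)
        names = {}
        for r in recs:
            cur = names.get(r.query_name)
            if cur is None or r.reference_start < cur:
                names[r.query_name] = r.reference_start
        for name, start in names.items():
            starts.setdefault(start, set()).add(name)
        return {k: len(v) for k, v in starts.items()}, recs

    def test_caps_pairs_per_position(self, tmp_path):
        sam = self._duplicated_sam(tmp_path, pairs_per_pos=5)
        out = tmp_path / "x2.sam"
        dx.downsample_depth(sam, out, 2, seed=0)
        counts, recs = self._pairs_per_position(out)
        assert set(counts.values()) == {2}
        # mates preserved together
        names = {}
        for r in recs:
            names.setdefault(r.query_name, 0)
            names[r.query_name] += 1
        assert set(names.values()) == {2}

    def test_large_n_is_identity(self, tmp_path):
        sam = self._duplicated_sam(tmp_path, pairs_per_pos=3)
        out = tmp_path / "x9.sam"
        dx.downsample_depth(sam, out, 9, seed=0)
        assert self._pairs_per_position(out)[0] == self._pairs_per_position(sam)[0]

    def test_seeded_and_idempotent(self, tmp_path):
        sam = self._duplicated_sam(tmp_path, pairs_per_pos=5)
        a, b, c = (tmp_path / n for n in ("a.sam", "b.sam", "c.sam"))
        dx.downsample_depth(sam, a, 2, seed=3)
        dx.downsample_depth(sam, b, 2, seed=3)
        assert a.read_text() == b.read_text()
        dx.downsample_depth(a, c, 2, seed=3)
        assert c.read_text() == a.read_text()

    def test_unsorted_input_rejected(self, tmp_path):
        sam = self._duplicated_sam(tmp_path, pairs_per_pos=2)
        text = sam.read_text().splitlines()
        header = [l for l in text if l.startswith("@")]
        body = [l for l in text if not l.startswith("@")]
        shuffled = tmp_path / "shuffled.sam"
        shuffled.write_text("\n".join(header + body[::-1]) + "\n")
        with pytest.raises(ValueError, match="sorted"):
            dx.downsample_depth(shuffled, tmp_path / "y.sam", 1)


class TestBuildDataset:
    def test_balanced_counts_exact(self, toy_dataset):
        assert len(toy_dataset) == 600
        assert int(toy_dataset.labels.sum()) == 300

    def test_error_free_simulation_labels_all_true(self, tmp_path, cosmic_max_table):
        ref = dx.random_reference(5000, seed=9)
        hap, truth = dx.seed_snvs(ref, 60, 9, cosmic_max_table)
        sam = tmp_path / "t.sam"
        dx.simulate_reads(ref, hap, dx.SimConfig(depth=3, error_rate=0.0,
                                                 vaf=1.0, seed=9), sam)
        tset = {(v.chrom, v.pos, v.ref, v.alt) for v in truth}
        with pytest.raises(ValueError, match="false positive"):
            dx.build_dataset(sam, ref, tset, cosmic_max_table)

    def test_labels_follow_exact_allele_match(self, toy_simulation, toy_dataset):
        tset = toy_simulation["truth_set"]
        for _, row in toy_dataset.provenance.iterrows():
            expected = int((row.chrom, row.pos, row.ref, row.alt) in tset)
            assert row.label == expected

    def test_priors_are_table_lookups(self, toy_dataset, cosmic_max_table):
        values = set(np.round(toy_dataset.priors, 6))
        table_vals = set(
            np.round(cosmic_max_table.probabilities.to_numpy().ravel(), 6)
        )
        assert values <= table_vals

    def test_save_load_round_trip(self, toy_dataset, tmp_path):
        p = tmp_path / "ds.npz"
        toy_dataset.save(p)
        again = dx.LabeledDataset.load(p)
        np.testing.assert_array_equal(again.tokens, toy_dataset.tokens)
        np.testing.assert_array_equal(again.labels, toy_dataset.labels)
        np.testing.assert_allclose(again.priors, toy_dataset.priors)
        assert len(again.provenance) == len(toy_dataset.provenance)
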