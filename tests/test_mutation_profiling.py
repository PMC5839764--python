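"""SNP masking, mutation tallies and the depth-weighted frequency formulas."""

import numpy as np
import pandas as pd
import pytest

from shm_atlas import (
    TargetRegion,
    mask_snps,
    per_base_profile,
    site_transition_frequencies,
    subtract_control,
    summarize_region,
    summarize_regions,
    tally_mutations,
)
from shm_atlas.mutation_profiling import RegionMutationSummary


class TestMaskSnps:
    def test_snp_rows_removed(self, toy_region, make_counts_factory):
        counts = make_counts_factory(toy_region)
        masked = mask_snps(counts, {"toy": [3, 7]})
        assert set(masked["pos"]) == set(range(len(toy_region))) - {3, 7}

    def test_identity_without_mask(self, toy_region, make_counts_factory):
        counts = make_counts_factory(toy_region)
        pd.testing.assert_frame_equal(mask_snps(counts, None), counts)

    def test_vaf_threshold_removes_high_fraction_sites(
        self, toy_region, make_counts_factory
    ):
        counts = make_counts_factory(toy_region, depth=1000, mutations=[(0, "G", 500)])
        masked = mask_snps(counts, None, vaf_threshold=0.2)
        assert 0 not in set(masked["pos"])
        assert len(masked) == len(counts) - 1

    def test_monotone_masking(self, toy_region, make_counts_factory):
        counts = make_counts_factory(toy_region, mutations=[(3, "T", 5), (9, "A", 2)])
        small = summarize_region(tally_mutations(mask_snps(counts, {"toy": [3]})),
                                 mask_snps(counts, {"toy": [3]}))
        large = summarize_region(tally_mutations(mask_snps(counts, {"toy": [3, 9]})),
                                 mask_snps(counts, {"toy": [3, 9]}))
        assert large.total_mutations <= small.total_mutations
        assert large.total_sequenced_length <= small.total_sequenced_length
        assert large.seq_length_cytosines <= small.seq_length_cytosines


class TestTallyMutations:
    def test_classification_examples(self, toy_region, make_counts_factory):
        # seq[3]='G'? toy: TTAGCTATGGCCAATTAGCTATCG
        counts = make_counts_factory(
            toy_region,
            mutations=[(4, "T", 4), (8, "A", 3), (10, "A", 2)],
        )  # pos4 ref C, pos8 ref G, pos10 ref C
        sites = tally_mutations(counts)
        by_pos = {(r.pos, r.alt): r for r in sites.itertuples()}
        ct = by_pos[(4, "T")]
        assert (ct.change_label, ct.change_class, ct.c_frame_strand) == (
            "C>T", "transition", "+",
        )
        ga = by_pos[(8, "A")]
        assert (ga.change_label, ga.change_class, ga.c_frame_strand) == (
            "G>A", "transition", "-",
        )
        ca = by_pos[(10, "A")]
        assert (ca.change_label, ca.change_class) == ("C>A", "transversion")

    def test_min_alt_count_threshold(self, toy_region, make_counts_factory):
        counts = make_counts_factory(toy_region, mutations=[(4, "T", 2)])
        assert len(tally_mutations(counts, min_alt_count=3)) == 0
        assert len(tally_mutations(counts, min_alt_count=2)) == 1

    def test_ref_n_rows_skipped(self):
        region = TargetRegion("n", "g", "c", 0, 3, "ANC")
        counts = pd.DataFrame(
            {
                "region_id": "n",
                "pos": [0, 1, 2],
                "ref": ["A", "N", "C"],
                "depth": [10, 10, 10],
                "A": [10, 2, 0],
                "C": [0, 2, 9],
                "G": [0, 3, 0],
                "T": [0, 3, 1],
            }
        )
        sites = tally_mutations(counts)
        assert set(sites["pos"]) == {2}


class TestSubtractControl:
    def idx(self, pairs):
        return pd.MultiIndex.from_tuples(pairs, names=["region_id", "pos"])

    def test_floored_difference(self):
        case = pd.Series([5e-3, 1e-4], index=self.idx([("r", 1), ("r", 2)]))
        ctrl = pd.Series([1e-4, 5e-3], index=self.idx([("r", 1), ("r", 2)]))
        out = subtract_control(case, ctrl)
        assert out.loc[("r", 1)] == pytest.approx(4.9e-3)
        assert out.loc[("r", 2)] == 0.0

    def test_empty_control_is_identity(self):
        case = pd.Series([1e-3], index=self.idx([("r", 1)]))
        ctrl = pd.Series([], dtype=float, index=self.idx([]))
        out = subtract_control(case, ctrl)
        assert out.loc[("r", 1)] == pytest.approx(1e-3)


def brute_force_summary(counts, annotation=None):
    """Independent per-read-call enumeration of every summary term."""
    summary = RegionMutationSummary(region_id=str(counts["region_id"].iloc[0]))
    plus_hot = set()
    minus_hot = set()
    for pos, members in (annotation or {}).items():
        for _, strand in members:
            (plus_hot if strand == "+" else minus_hot).add(pos)
    for row in counts.itertuples():
        if row.ref not in "ACGT":
            continue
        summary.total_sequenced_length += row.depth
        if row.ref == "C":
            summary.seq_length_cytosines += row.depth
            if row.pos in plus_hot:
                summary.seq_length_cytosines_hotspot += row.depth
        if row.ref == "G":
            summary.seq_length_guanines += row.depth
            if row.pos in minus_hot:
                summary.seq_length_guanines_hotspot += row.depth
        for alt in "ACGT":
            if alt == row.ref:
                continue
            n = getattr(row, alt)
            summary.total_mutations += n
            if row.ref == "C":
                summary.mutated_cytosines += n
                if row.pos in plus_hot:
                    summary.mutated_cytosines_hotspot += n
                if alt == "T":
                    summary.ct_transition_mutations += n
            if row.ref == "G":
                summary.mutated_guanines += n
                if row.pos in minus_hot:
                    summary.mutated_guanines_hotspot += n
                if alt == "A":
                    summary.ct_transition_mutations += n
    return summary


class TestSummarizeRegion:
    def test_toy_formula_arithmetic(self):
        # 600 depth at C positions, 400 at G, 3 C>T + 1 G>A -> cg_freq 4e-3
        region = TargetRegion("t", "g", "c", 0, 5, "CCCGG")
        counts = pd.DataFrame(
            {
                "region_id": "t",
                "pos": range(5),
                "ref": list("CCCGG"),
                "depth": [200, 200, 200, 200, 200],
                "A": [0, 0, 0, 1, 0],
                "C": [198, 199, 200, 0, 0],
                "G": [0, 0, 0, 199, 200],
                "T": [2, 1, 0, 0, 0],
            }
        )
        summary = summarize_region(tally_mutations(counts), counts)
        assert summary.seq_length_cytosines == 600
        assert summary.seq_length_guanines == 400
        assert summary.cg_freq == pytest.approx(4 / 1000)
        assert summary.ct_transition_mutations == 4

    def test_no_mutations_all_zero(self, toy_region, make_counts_factory):
        counts = make_counts_factory(toy_region)
        summary = summarize_region(tally_mutations(counts), counts)
        assert summary.total_freq == 0.0
        assert summary.cg_freq == 0.0
        assert summary.hotspot_freq == 0.0

    def test_hotspot_freq_exceeds_cg_freq_when_concentrated(self):
        # all 4 C>T calls inside the single hotspot C -> hotspot_freq > cg_freq
        region = TargetRegion("h", "g", "c", 0, 6, "AGCTAA")
        annotation = {2: {("WRCY", "+")}}
        counts = pd.DataFrame(
            {
                "region_id": "h",
                "pos": range(6),
                "ref": list("AGCTAA"),
                "depth": [200] * 6,
                "A": [200, 0, 0, 0, 200, 200],
                "C": [0, 0, 196, 0, 0, 0],
                "G": [0, 200, 0, 0, 0, 0],
                "T": [0, 0, 4, 200, 0, 0],
            }
        )
        summary = summarize_region(tally_mutations(counts), counts, annotation)
        assert summary.hotspot_freq == pytest.approx(4 / 200)
        assert summary.hotspot_freq > summary.cg_freq

    def test_zero_denominator_flagged(self):
        region_counts = pd.DataFrame(
            {
                "region_id": "z",
                "pos": [0],
                "ref": ["A"],
                "depth": [100],
                "A": [100],
                "C": [0],
                "G": [0],
                "T": [0],
            }
        )
        summary = summarize_region(tally_mutations(region_counts), region_counts)
        assert summary.cg_freq == 0.0
        assert "cg_freq" in summary.flags

    def test_equivalence_with_brute_force_on_random_tables(self, rng):
        bases = np.array(list("ACGTN"))
        for _ in range(20):
            n = int(rng.integers(5, 50))
            refs = rng.choice(bases, size=n, p=[0.24, 0.24, 0.24, 0.24, 0.04])
            depth = rng.integers(0, 300, size=n)
            counts = {b: np.zeros(n, dtype=int) for b in "ACGT"}
            for i, (ref, d) in enumerate(zip(refs, depth)):
                split = rng.multinomial(d, [0.94, 0.02, 0.02, 0.02])
                order = [ref] + [b for b in "ACGT" if b != ref] if ref in "ACGT" else list("ACGT")
                for b, c in zip(order, split if ref in "ACGT" else split):
                    counts[b][i] += c
            table = pd.DataFrame(
                {"region_id": "r", "pos": range(n), "ref": refs, "depth": depth, **counts}
            )
            annotation = {
                int(i): {("WRCY", rng.choice(["+", "-"]))}
                for i in rng.choice(n, size=min(5, n), replace=False)
            }
            expected = brute_force_summary(table, annotation)
            got = summarize_region(tally_mutations(table), table, annotation)
            for field in (
                "total_mutations", "total_sequenced_length", "mutated_cytosines",
                "mutated_guanines", "seq_length_cytosines", "seq_length_guanines",
                "mutated_cytosines_hotspot", "mutated_guanines_hotspot",
                "seq_length_cytosines_hotspot", "seq_length_guanines_hotspot",
                "ct_transition_mutations",
            ):
                assert getattr(got, field) == getattr(expected, field), field
            # vectorized multi-region path agrees too
            vec = summarize_regions(table, {"r": annotation})["r"]
            for field in ("total_mutations", "ct_transition_mutations",
                          "seq_length_cytosines_hotspot", "mutated_guanines_hotspot"):
                assert getattr(vec, field) == getattr(expected, field), field

    def test_frequencies_invariant_under_depth_scaling(self, toy_region, make_counts_factory):
        counts = make_counts_factory(toy_region, depth=100, mutations=[(4, "T", 2)])
        scaled = counts.copy()
        for col in ["depth", "A", "C", "G", "T"]:
            scaled[col] *= 7
        a = summarize_region(tally_mutations(counts), counts)
        b = summarize_region(tally_mutations(scaled), scaled)
        assert a.total_freq == pytest.approx(b.total_freq)
        assert a.cg_freq == pytest.approx(b.cg_freq)
        assert a.ct_freq == pytest.approx(b.ct_freq)


class TestPerBaseProfile:
    def test_identical_case_control_is_zero(self, toy_region, make_counts_factory):
        counts = make_counts_factory(toy_region, mutations=[(4, "T", 3)])
        track = per_base_profile(toy_region, counts, counts)
        assert (track["adjusted_freq"] == 0).all()

    def test_case_only_mutation_single_entry(self, toy_region, make_counts_factory):
        ctrl = make_counts_factory(toy_region)
        case = make_counts_factory(toy_region, mutations=[(4, "T", 5)])
        track = per_base_profile(toy_region, case, ctrl)
        nonzero = track[track["adjusted_freq"] > 0]
        assert list(nonzero["pos"]) == [4]
        assert nonzero["adjusted_freq"].iloc[0] == pytest.approx(5 / 1000)

    def test_zero_control_depth_flagged(self, toy_region, make_counts_factory):
        case = make_counts_factory(toy_region)
        ctrl = make_counts_factory(toy_region).copy()
        ctrl.loc[ctrl["pos"] == 2, ["depth", "A", "C", "G", "T"]] = 0
        track = per_base_profile(toy_region, case, ctrl)
        assert bool(track.loc[track["pos"] == 2, "control_zero_depth"].iloc[0])


class TestProfileConcentratesAtHotspots:
    def test_top_decile_of_adjusted_track_is_mostly_hotspot(self):
        """In a deep double-knockout simulation the control-adjusted per-base
        track peaks at annotated hotspot positions: >=70% of top-decile C/G
        sites carry a frame-matched hotspot instance."""
        from shm_atlas import SimulationConfig, simulate_dataset

        cfg = SimulationConfig(
            n_regions=20, depth_mean=3000.0, target_fraction=1.0, seed=21,
        )
        ds = simulate_dataset(cfg, ["UngMsh2_DKO", "Aicda_KO"], keep_truth=False)
        records = []
        for region in ds.regions:
            track = per_base_profile(
                region, ds.counts["UngMsh2_DKO"], ds.counts["Aicda_KO"]
            )
            ann = ds.annotations[region.region_id]
            snps = ds.snps[region.region_id]
            for row in track.itertuples():
                if row.ref not in "CG" or row.pos in snps:
                    continue
                frame = "+" if row.ref == "C" else "-"
                is_hot = any(s == frame for _, s in ann.get(row.pos, ()))
                records.append((row.adjusted_freq, is_hot))
        records.sort(reverse=True)
        top = records[: len(records) // 10]
        hot_fraction = sum(h for _, h in top) / len(top)
        assert hot_fraction >= 0.7


class TestSiteTransitionFrequencies:
    def test_frame_aware_events(self, toy_region, make_counts_factory):
        counts = make_counts_factory(
            toy_region, mutations=[(4, "T", 10), (8, "A", 5)]
        )
        freqs = site_transition_frequencies(counts)
        assert freqs.loc[("toy", 4)] == pytest.approx(10 / 1000)
        assert freqs.loc[("toy", 8)] == pytest.approx(5 / 1000)
        # non-C/G sites are absent from the index
        assert ("toy", 0) not in freqs.index
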