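import itertools
import math

import numpy as np
import pandas as pd
import pytest

from conftest import make_table
from founderscan.errors import ConfigurationError
from founderscan.genotype_model import GenotypeTable, MISSING, SegmentSet
from founderscan.haplotype_painting import (
    ALLOZYGOUS,
    AMBIGUOUS,
    DIFFERENT,
    NO_CALL,
    SAME,
    UNASSIGNED,
    PaintingConfig,
    PairwiseCall,
    assemble_founders,
    call_invariant_regions,
    call_pairwise_runs,
    classify_joint_sites,
    joint_polymorphic_mask,
    paint_genome,
    sharing_summary,
    trio_scan_multihap,
)
from founderscan.synthetic_data import SimParams, simulate_bundle


def _joint_table(pair_genotypes, positions=None, extra_selfer=None):
    """Two focal selfers + one auxiliary selfer + two outcrossers.

    Outcrossers are 0/2 at every site (common ancestral variant) and the
    auxiliary selfer alternates so every site is selfer-polymorphic.
    """
    n = len(pair_genotypes)
    g = np.zeros((n, 5), dtype=np.int8)
    for i, (a, b) in enumerate(pair_genotypes):
        g[i, 0], g[i, 1] = a, b
    if extra_selfer is None:
        # make each site selfer-polymorphic without relying on the pair
        for i in range(n):
            vals = {v for v in (g[i, 0], g[i, 1]) if v != MISSING}
            g[i, 2] = 0 if 2 in vals or not vals else 2
    else:
        g[:, 2] = extra_selfer
    g[:, 3] = 0
    g[:, 4] = 2
    return make_table(
        g, positions=positions,
        species=["selfer", "selfer", "selfer", "outcrosser", "outcrosser"],
    )


class TestClassifyJointSites:
    def test_same_different_missing_labels(self):
        table = _joint_table([(0, 0), (0, 2), (0, MISSING), (2, 2), (1, 0)])
        idx, labels = classify_joint_sites(table, ("S1", "S2"))
        assert labels.tolist() == [SAME, DIFFERENT, NO_CALL, SAME, NO_CALL]

    def test_no_joint_sites_gives_empty_labels(self):
        # selfers monomorphic: nothing is jointly polymorphic
        g = np.array([[0, 0, 0, 0, 2], [0, 0, 0, 2, 0]], dtype=np.int8)
        table = make_table(
            g, species=["selfer"] * 3 + ["outcrosser"] * 2
        )
        idx, labels = classify_joint_sites(table, ("S1", "S2"))
        assert labels.size == 0

    def test_outcrosser_minor_count_threshold(self):
        g = np.array([[0, 2, 0, 0, 1]], dtype=np.int8)  # minor count 1
        table = make_table(g, species=["selfer"] * 3 + ["outcrosser"] * 2)
        cfg1 = PaintingConfig(min_gr_count=1)
        cfg2 = PaintingConfig(min_gr_count=2)
        assert joint_polymorphic_mask(table, cfg1).sum() == 1
        assert joint_polymorphic_mask(table, cfg2).sum() == 0


class TestPairwiseRuns:
    def test_same_run_meets_both_thresholds(self):
        """Four SAME sites spanning 1600 bp become one SAME interval."""
        table = _joint_table(
            [(0, 0), (0, 0), (0, 0), (0, 0), (0, 2), (2, 0)],
            positions=[1000, 1500, 2000, 2600, 2700, 2750],
        )
        call = call_pairwise_runs(table, ("S1", "S2"))
        same = call.intervals[call.intervals.label == "SAME"]
        assert len(same) == 1
        assert same.iloc[0].start == 1000 and same.iloc[0].end == 2601
        assert same.iloc[0].n_sites == 4

    def test_same_run_below_site_count_rejected(self):
        """Three SAME sites spanning 2 kb stay unassigned."""
        table = _joint_table(
            [(0, 0), (0, 0), (0, 0), (0, 2), (2, 0)],
            positions=[1000, 2000, 3000, 3100, 3200],
        )
        call = call_pairwise_runs(table, ("S1", "S2"))
        assert (call.intervals.label != "SAME").all()

    def test_same_run_below_span_rejected(self):
        table = _joint_table(
            [(0, 0), (0, 0), (0, 0), (0, 0), (0, 2), (2, 0)],
            positions=[1000, 1100, 1200, 1300, 1400, 1500],
        )
        call = call_pairwise_runs(table, ("S1", "S2"))
        assert (call.intervals.label != "SAME").all()

    def test_alternating_singles_make_no_intervals(self):
        table = _joint_table(
            [(0, 0), (0, 2), (0, 0), (2, 0), (0, 0), (0, 2)],
            positions=[1000, 1200, 1400, 1600, 1800, 2000],
        )
        call = call_pairwise_runs(table, ("S1", "S2"))
        assert len(call.intervals) == 0

    def test_two_consecutive_differences_suffice(self):
        table = _joint_table(
            [(0, 0), (0, 2), (2, 0), (0, 0)],
            positions=[1000, 1500, 1600, 2000],
        )
        call = call_pairwise_runs(table, ("S1", "S2"))
        diff = call.intervals[call.intervals.label == "DIFFERENT"]
        assert len(diff) == 1
        assert diff.iloc[0].start == 1500 and diff.iloc[0].end == 1601

    def test_missing_sites_do_not_break_runs(self):
        table = _joint_table(
            [(0, 0), (MISSING, 0), (0, 0), (0, 0), (0, 0), (0, 2), (2, 0)],
            positions=[1000, 1300, 1600, 1900, 2600, 2700, 2800],
        )
        call = call_pairwise_runs(table, ("S1", "S2"))
        same = call.intervals[call.intervals.label == "SAME"]
        assert len(same) == 1 and same.iloc[0].n_sites == 4

    def test_no_overlap_between_same_and_different(self, painted_k10):
        table, truth, painting, calls, invariant = painted_k10
        for call in calls[:5]:
            iv = call.intervals.sort_values(["chrom", "start"])
            for _, grp in iv.groupby("chrom"):
                s = grp["start"].to_numpy()
                e = grp["end"].to_numpy()
                assert (s[1:] >= e[:-1]).all()


class TestInvariantRegions:
    def _table(self, n_snps, span_bp, discordant=0):
        pos = np.linspace(1000, 1000 + span_bp, n_snps).astype(np.int64)
        g = np.zeros((n_snps, 6), dtype=np.int8)
        g[:, 4] = 0
        g[:, 5] = 2
        for i in range(discordant):
            g[2 + i, 1] = 2  # one selfer deviates at interior sites
        return make_table(
            g, positions=pos,
            species=["selfer"] * 4 + ["outcrosser"] * 2,
        )

    def test_long_identical_stretch_called(self):
        table = self._table(12, 30_000)
        regions = call_invariant_regions(table)
        assert len(regions) == 1
        assert regions.iloc[0].n_sites == 12

    def test_discordant_selfer_blocks_call(self):
        table = self._table(12, 30_000, discordant=2)
        regions = call_invariant_regions(table)
        # interior discordance splits the run below the site threshold
        assert (regions["n_sites"] < 10).all() if len(regions) else True

    def test_short_stretch_not_called(self):
        table = self._table(12, 10_000)
        assert len(call_invariant_regions(table)) == 0


def _manual_calls(sample_ids, same_pairs, diff_pairs, start=1000, end=2000):
    calls = []
    for a, b in itertools.combinations(sample_ids, 2):
        rows = []
        if (a, b) in same_pairs or (b, a) in same_pairs:
            rows.append(("chr1", start, end, "SAME", 10))
        elif (a, b) in diff_pairs or (b, a) in diff_pairs:
            rows.append(("chr1", start, end, "DIFFERENT", 5))
        calls.append(
            PairwiseCall(
                pair=(a, b),
                intervals=pd.DataFrame(
                    rows, columns=["chrom", "start", "end", "label", "n_sites"]
                ),
            )
        )
    return calls


def _six_selfer_table():
    g = np.zeros((2, 8), dtype=np.int8)
    g[:, 6] = 0
    g[:, 7] = 2
    return make_table(
        g, positions=[1000, 1999],
        species=["selfer"] * 6 + ["outcrosser"] * 2,
    )


class TestAssembly:
    def test_two_founder_groups(self):
        """Four mutually identical samples and a distinct pair of identical
        samples partition into two founder classes."""
        ids = [f"S{i + 1}" for i in range(6)]
        grp1, grp2 = ids[:4], ids[4:]
        same = set(itertools.combinations(grp1, 2)) | set(itertools.combinations(grp2, 2))
        diff = {(a, b) for a in grp1 for b in grp2}
        calls = _manual_calls(ids, same, diff)
        painting = assemble_founders(
            _six_selfer_table(), calls, pd.DataFrame(columns=["chrom", "start", "end", "n_sites"])
        )
        lab = painting.labels[0]
        assert set(lab[:4]) == {1} and set(lab[4:]) == {2}

    def test_conflicting_triple_is_ambiguous(self):
        """A=B, B=C, A!=C marks the whole component ambiguous."""
        ids = [f"S{i + 1}" for i in range(6)]
        same = {("S1", "S2"), ("S2", "S3")}
        diff = {("S1", "S3")}
        calls = _manual_calls(ids, same, diff)
        painting = assemble_founders(
            _six_selfer_table(), calls, pd.DataFrame(columns=["chrom", "start", "end", "n_sites"])
        )
        lab = painting.labels[0]
        assert (lab[:3] == AMBIGUOUS).all()
        # the uninvolved samples have no relations at all -> ambiguous too
        assert (lab[3:] == AMBIGUOUS).all()

    def test_all_same_single_founder(self):
        ids = [f"S{i + 1}" for i in range(6)]
        same = set(itertools.combinations(ids, 2))
        calls = _manual_calls(ids, same, set())
        painting = assemble_founders(
            _six_selfer_table(), calls, pd.DataFrame(columns=["chrom", "start", "end", "n_sites"])
        )
        assert (painting.labels[0] == 1).all()

    def test_no_relations_stay_unassigned(self):
        """A window between two evidence intervals holds no relations at
        all and stays unassigned; a window with some relations marks the
        uninvolved samples ambiguous instead."""
        ids = [f"S{i + 1}" for i in range(6)]
        calls = _manual_calls(ids, set(), set())
        calls[0] = PairwiseCall(
            pair=calls[0].pair,
            intervals=pd.DataFrame(
                [("chr1", 1000, 2000, "SAME", 10), ("chr1", 5000, 6000, "SAME", 10)],
                columns=["chrom", "start", "end", "label", "n_sites"],
            ),
        )
        painting = assemble_founders(
            _six_selfer_table(), calls, pd.DataFrame(columns=["chrom", "start", "end", "n_sites"])
        )
        w = painting.windows.reset_index(drop=True)
        gap = w.index[w["start"] == 2000][0]
        first = w.index[w["start"] == 1000][0]
        assert (painting.labels[gap] == UNASSIGNED).all()
        assert (painting.labels[first][:2] == 1).all()
        assert (painting.labels[first][2:] == AMBIGUOUS).all()

    def test_allozygous_samples_excluded(self):
        ids = [f"S{i + 1}" for i in range(6)]
        same = set(itertools.combinations(ids, 2))
        calls = _manual_calls(ids, same, set())
        allo = SegmentSet.from_records([("S1", "chr1", 1000, 2000, "ALLOZYGOUS")])
        painting = assemble_founders(
            _six_selfer_table(), calls,
            pd.DataFrame(columns=["chrom", "start", "end", "n_sites"]), allo
        )
        assert painting.labels[0][0] == ALLOZYGOUS
        assert (painting.labels[0][1:] == 1).all()

    def test_partition_invariant_to_sample_order(self):
        """Painting the same genotypes with permuted sample columns yields
        the same partition of sample ids in every window."""
        params = SimParams(n_windows=80, seed=91, k_founders=10,
                           err_het=0, miss_rate=0, f_allo=0)
        table, _ = simulate_bundle(params)
        ref_partition = _canonical_partition(paint_genome(table)[0])
        rng = np.random.default_rng(5)
        for _ in range(2):
            perm = rng.permutation(table.n_samples)
            permuted = GenotypeTable(
                sites=table.sites.copy(),
                samples=[table.samples[i] for i in perm],
                genotypes=table.genotypes[:, perm],
            )
            assert _canonical_partition(paint_genome(permuted)[0]) == ref_partition


def _canonical_partition(painting):
    """Order-free painting summary: per window, founder groups as frozensets."""
    out = []
    ids = np.array(painting.sample_ids)
    order = np.argsort(ids)
    for w in range(len(painting.windows)):
        lab = painting.labels[w]
        groups = {}
        amb = []
        for i in order:
            if lab[i] > 0:
                groups.setdefault(lab[i], set()).add(ids[i])
            elif lab[i] == AMBIGUOUS:
                amb.append(ids[i])
        key = (
            painting.windows["chrom"].iat[w],
            int(painting.windows["start"].iat[w]),
            frozenset(frozenset(g) for g in groups.values()),
            frozenset(amb),
        )
        out.append(key)
    return sorted(out, key=lambda k: (k[0], k[1]))


class TestSharingAndMonotonicity:
    def test_single_founder_truth_all_same(self):
        table, _ = simulate_bundle(
            SimParams(n_windows=60, seed=15, k_founders=1,
                      err_het=0, miss_rate=0, f_allo=0)
        )
        painting, _, _ = paint_genome(table)
        summary, _ = sharing_summary(painting)
        assert (summary["diff_frac_bp"] == 0).all()
        assert (summary["same_frac_assigned"].dropna() == 1.0).all()

    def test_fractions_sum_to_one(self, painted_k10):
        _, _, painting, _, _ = painted_k10
        summary, blocks = sharing_summary(painting)
        total = summary[["same_frac_bp", "diff_frac_bp", "ambig_frac_bp"]].sum(axis=1)
        assert np.allclose(total, 1.0)
        assert (blocks["bp"] > 0).all()

    def test_same_fraction_matches_engine_pair_probability(self, painted_k10):
        from founderscan.demographic_inference import pair_same_founder_prob

        _, _, painting, _, _ = painted_k10
        summary, _ = sharing_summary(painting)
        expected = pair_same_founder_prob(10, 1.7)
        assert abs(summary["same_frac_assigned"].mean() - expected) < 0.1

    def test_stricter_thresholds_monotone(self, clean_bundle_k10):
        """Raising min_same_sites cannot increase the SAME fraction and
        cannot decrease the ambiguous fraction."""
        table, _ = clean_bundle_k10
        fracs = []
        for n_sites in (4, 8):
            cfg = PaintingConfig(min_same_sites=n_sites)
            painting, _, _ = paint_genome(table, None, cfg)
            summary, _ = sharing_summary(painting)
            fracs.append(
                (summary["same_frac_bp"].mean(), summary["ambig_frac_bp"].mean())
            )
        assert fracs[1][0] <= fracs[0][0] + 1e-12
        assert fracs[1][1] >= fracs[0][1] - 1e-12


class TestTrioScan:
    def test_requires_four_selfers(self):
        g = np.zeros((4, 5), dtype=np.int8)
        table = make_table(g, species=["selfer"] * 3 + ["outcrosser"] * 2)
        with pytest.raises(ConfigurationError):
            trio_scan_multihap(table)

    def test_single_founder_yields_no_candidates(self):
        table, _ = simulate_bundle(
            SimParams(n_windows=80, seed=16, k_founders=1,
                      err_het=0, miss_rate=0, f_allo=0)
        )
        assert len(trio_scan_multihap(table)) == 0

    def test_two_founders_yield_no_candidates(self):
        table, _ = simulate_bundle(
            SimParams(n_windows=80, seed=17, k_founders=2, t_scaled=0.0,
                      err_het=0, miss_rate=0, f_allo=0)
        )
        assert len(trio_scan_multihap(table)) == 0

    def test_many_founders_recovered_and_validated(self):
        """With many surviving founders, at least one true three-founder
        region is found, and every reported region really holds three
        distinct founders for its trio."""
        params = SimParams(n_windows=60, window_bp=20_000, seed=18,
                           k_founders=5, t_scaled=0.3,
                           err_het=0, miss_rate=0, f_allo=0)
        table, truth = simulate_bundle(params)
        result = trio_scan_multihap(table)
        assert len(result) >= 1
        wpc = math.ceil(60 / 8)
        fv = truth.founder[[f"R{i + 1}" for i in range(6)]]
        for _, row in result.iterrows():
            trio = row["trio"].split("-")
            cn = int(row["chrom"][3:]) - 1
            n_distinct = 0
            for w in range((row["start"] - 1) // 20_000,
                           min((row["end"] - 2) // 20_000, wpc - 1) + 1):
                labels = fv.iloc[cn * wpc + w][trio]
                n_distinct = max(n_distinct, labels.nunique())
            assert n_distinct >= 3
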