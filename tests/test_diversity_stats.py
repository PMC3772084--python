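import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import make_table
from founderscan import diversity_stats as ds
from founderscan.errors import FittingError
from founderscan.genotype_model import MISSING
from founderscan.haplotype_painting import Painting, paint_genome
from founderscan.synthetic_data import SimParams, simulate_bundle


def _trivial_painting(table, label=1):
    """One window covering the whole table, every selfer on one founder."""
    selfers = [s.sample_id for s in table.samples if s.species == "selfer"]
    pos = table.sites["pos"]
    windows = pd.DataFrame(
        {"chrom": [table.sites["chrom"].iloc[0]],
         "start": [int(pos.min())], "end": [int(pos.max()) + 1]}
    )
    labels = np.full((1, len(selfers)), label, dtype=np.int8)
    pair_ids = list(itertools.combinations(selfers, 2))
    pair_rel = np.full((1, len(pair_ids)), 1, dtype=np.int8)
    return Painting(windows=windows, labels=labels, sample_ids=selfers,
                    pair_ids=pair_ids, pair_rel=pair_rel)


class TestPairwisePi:
    def test_identical_sequences_zero(self):
        table = make_table(np.zeros((50, 2), dtype=np.int8))
        est = ds.pairwise_pi(table, ["S1", "S2"])
        assert est.pi == 0.0

    def test_two_differences_over_hundred_sites(self):
        g = np.zeros((100, 2), dtype=np.int8)
        g[10, 0] = 2
        g[60, 0] = 2
        table = make_table(g)
        est = ds.pairwise_pi(table, ["S1", "S2"])
        assert est.pi == pytest.approx(0.02)

    def test_het_scores_half(self):
        g = np.array([[1, 0], [1, 2], [1, 1]], dtype=np.int8)
        table = make_table(g, species=["outcrosser", "outcrosser"])
        est = ds.pairwise_pi(table, ["S1", "S2"])
        assert est.pi == pytest.approx(0.5)

    def test_no_overlap_flagged_undefined(self):
        g = np.array([[0, MISSING], [MISSING, 2]], dtype=np.int8)
        table = make_table(g)
        est = ds.pairwise_pi(table, ["S1", "S2"])
        assert est.undefined and np.isnan(est.pi)

    def test_bootstrap_interval_brackets_point(self, clean_bundle_k10):
        table, _ = clean_bundle_k10
        outs = [s.sample_id for s in table.samples if s.species == "outcrosser"]
        est = ds.pairwise_pi(table, outs, site_class="4-fold", n_boot=100)
        assert est.ci_low <= est.pi <= est.ci_high

    def test_ci_width_shrinks_with_genome_size(self):
        widths = []
        for n_windows in (100, 400):
            table, _ = simulate_bundle(
                SimParams(n_windows=n_windows, seed=23, err_het=0, miss_rate=0, f_allo=0)
            )
            outs = [s.sample_id for s in table.samples if s.species == "outcrosser"]
            est = ds.pairwise_pi(table, outs, n_boot=100, block_bp=50_000)
            widths.append(est.ci_high - est.ci_low)
        assert widths[1] < widths[0]


class TestPartitionedPi:
    def test_among_matches_ancestral_diversity(self):
        """Diversity among founding haplotypes resembles ancestral diversity
        (long-tract geometry, where evidence tracks the founder state)."""
        table, _ = simulate_bundle(
            SimParams(n_windows=300, window_bp=50_000, seed=31,
                      err_het=0, miss_rate=0, f_allo=0)
        )
        painting, _, _ = paint_genome(table)
        part = ds.partitioned_pi(table, painting, "4-fold", class_fraction=0.4,
                                 n_boot=50)
        anc = ds.pairwise_pi(
            table, [f"G{i + 1}" for i in range(5)], site_class="4-fold",
            denominator_bp=0.4 * 300 * 50_000,
        )
        among = part[(part.pair_class == "all") & (part.partition == "among")]
        within = part[(part.pair_class == "all") & (part.partition == "within")]
        assert 0.8 <= among["pi"].iloc[0] / anc.pi <= 1.2
        assert among["pi"].iloc[0] / within["pi"].iloc[0] > 5

    def test_within_matches_engine_expectation(self):
        """Within-founder diversity approximates theta_selfer times the
        expected shared-founder pair coalescence time."""
        from founderscan.demographic_inference import expected_pair_time_shared

        table, _ = simulate_bundle(
            SimParams(n_windows=300, window_bp=50_000, seed=32,
                      err_het=0, miss_rate=0, f_allo=0)
        )
        painting, _, _ = paint_genome(table)
        part = ds.partitioned_pi(table, painting, "4-fold", class_fraction=0.4,
                                 n_boot=0)
        within = part[(part.pair_class == "all") & (part.partition == "within")]
        oracle = 0.0005 * expected_pair_time_shared(100, 1.7)
        assert 0.7 <= within["pi"].iloc[0] / oracle <= 1.3

    def test_no_different_windows_flags_among_undefined(self):
        table, _ = simulate_bundle(
            SimParams(n_windows=50, seed=33, k_founders=1,
                      err_het=0, miss_rate=0, f_allo=0)
        )
        painting, _, _ = paint_genome(table)
        part = ds.partitioned_pi(table, painting, None, n_boot=0)
        among = part[(part.pair_class == "all") & (part.partition == "among")]
        assert among["undefined"].iloc[0]

    def test_partition_masks_disjoint_and_accounted(self, painted_k10):
        """Within windows, among regions and the remainder partition every
        site, so their mismatch totals sum to the genome-wide total."""
        from founderscan.haplotype_painting import SAME, PaintingConfig, pair_identity_stretches

        table, truth, painting, _, _ = painted_k10
        a, b = painting.sample_ids[:2]
        d, c = ds._pair_site_diff(table, table.sample_index(a), table.sample_index(b))
        swin = ds._site_window_index(table, painting)
        status = painting.pair_status(a, b)
        within_mask = np.zeros(table.n_sites, dtype=bool)
        ok = swin >= 0
        within_mask[ok] = (status == SAME)[swin[ok]]
        anchors = pair_identity_stretches(table, (a, b), PaintingConfig())
        regions = ds._among_regions(painting.windows, status, anchors)
        among_mask = np.zeros(table.n_sites, dtype=bool)
        pos = table.sites["pos"].to_numpy()
        chrom = table.sites["chrom"].to_numpy()
        for ch, s, e in regions:
            among_mask |= (chrom == ch) & (pos >= s) & (pos < e)
        assert not (within_mask & among_mask).any()
        total = d.sum()
        rest = d[~within_mask & ~among_mask].sum()
        assert d[within_mask].sum() + d[among_mask].sum() + rest == pytest.approx(total)


class TestSfs:
    def test_single_segregating_site_is_singleton(self):
        g = np.zeros((3, 6), dtype=np.int8)
        g[1, 0] = 2  # one selfer carries the derived allele
        g[:, 4] = 0
        g[:, 5] = 2
        table = make_table(g, species=["selfer"] * 4 + ["outcrosser"] * 2)
        painting = _trivial_painting(table)
        sfs = ds.sfs_within_founders(table, painting, ["S1", "S2", "S3", "S4"],
                                     polarization="ancestral")
        assert sfs.counts.tolist() == [1, 0, 0]

    def test_constant_size_spectrum(self):
        """Deep single-founder population: spectrum proportional to 1/i."""
        table, _ = simulate_bundle(
            SimParams(n_selfer=4, n_outcrosser=5, k_founders=1, t_scaled=30.0,
                      theta_selfer=0.002, n_windows=400,
                      err_het=0, miss_rate=0, f_allo=0, seed=41)
        )
        painting, _, _ = paint_genome(table)
        sfs = ds.sfs_within_founders(
            table, painting, ["R1", "R2", "R3", "R4"], polarization="ancestral"
        )
        assert sfs.counts.sum() > 300
        expected = np.array([6 / 11, 3 / 11, 2 / 11])
        assert np.all(np.abs(sfs.proportions - expected) < 0.05)

    def test_polarizations_agree_when_outcrosser_major_is_ancestral(self):
        """With one founder, counted variants are post-founding mutations
        absent from the outcrosser sample, so both polarizations agree."""
        table, _ = simulate_bundle(
            SimParams(n_selfer=4, n_outcrosser=5, k_founders=1, t_scaled=30.0,
                      theta_selfer=0.002, n_windows=150,
                      err_het=0, miss_rate=0, f_allo=0, seed=42)
        )
        painting, _, _ = paint_genome(table)
        ids = ["R1", "R2", "R3", "R4"]
        a = ds.sfs_within_founders(table, painting, ids, polarization="ancestral")
        b = ds.sfs_within_founders(table, painting, ids, polarization="outcrosser_major")
        assert a.counts.tolist() == b.counts.tolist()

    def test_counts_invariant_to_sample_order(self, painted_k10):
        table, _, painting, _, _ = painted_k10
        ids = ["R1", "R2", "R3", "R4"]
        a = ds.sfs_within_founders(table, painting, ids)
        b = ds.sfs_within_founders(table, painting, list(reversed(ids)))
        assert a.counts.tolist() == b.counts.tolist()


class TestSlidingWindows:
    def test_major_frequency_one_when_shared(self):
        g = np.zeros((40, 6), dtype=np.int8)
        g[::3, 0] = 2
        g[:, 4] = 0
        g[:, 5] = 2
        table = make_table(
            g, positions=np.arange(1, 41) * 300,
            species=["selfer"] * 4 + ["outcrosser"] * 2,
        )
        painting = _trivial_painting(table)
        df, _ = ds.sliding_windows(table, painting, window_bp=6000, step_bp=2000,
                                   min_sites=5, site_class=None)
        assert (df["major_freq"].dropna() == 1.0).all()

    def test_window_count_arithmetic(self):
        g = np.zeros((200, 2), dtype=np.int8)
        g[:, 0] = 2
        table = make_table(g, positions=np.arange(1, 201) * 50,
                           species=["selfer", "selfer"])
        painting = _trivial_painting(table)
        df, _ = ds.sliding_windows(table, painting, window_bp=2000, step_bp=3000,
                                   min_sites=1, site_class=None)
        length = 200 * 50
        expected = (length - 2000) // 3000 + 1
        assert len(df) == expected

    def test_negative_correlation_with_major_frequency(self, noisy_bundle_default):
        """Diversity drops where one founding haplotype dominates."""
        table, _ = noisy_bundle_default
        painting, _, _ = paint_genome(table)
        _, r = ds.sliding_windows(table, painting, min_sites=50)
        assert r < -0.3


class TestDStatistic:
    def test_count_form(self):
        assert ds.d_from_counts(6, 2) == pytest.approx(0.5)
        with pytest.raises(FittingError):
            ds.d_from_counts(0, 0)

    def test_antisymmetry(self, noisy_bundle_default):
        table, _ = noisy_bundle_default
        selfers = [f"R{i + 1}" for i in range(6)]
        outs = [f"G{i + 1}" for i in range(5)]
        r1 = ds.d_statistic(table, selfers[:3], selfers[3:], outs, block_bp=300_000)
        r2 = ds.d_statistic(table, selfers[3:], selfers[:3], outs, block_bp=300_000)
        assert r1.d == pytest.approx(-r2.d)

    def test_unpolarizable_table_rejected(self):
        g = np.zeros((5, 4), dtype=np.int8)
        table = make_table(g, ancestral="unknown",
                           species=["selfer"] * 2 + ["outcrosser"] * 2)
        with pytest.raises(FittingError):
            ds.d_statistic(table, ["S1"], ["S2"], ["S3", "S4"])


class TestNjTrees:
    def test_three_taxon_hand_solution(self):
        """d(AB)=0.2, d(AC)=0.3, d(BC)=0.4 gives branches 0.05/0.15/0.25;
        the tree reproduces the input distances additively."""
        m = np.array([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]])
        nwk = ds.nj_from_matrix(["A", "B", "C"], m)
        assert _patristic(nwk) == pytest.approx(
            {("A", "B"): 0.2, ("A", "C"): 0.3, ("B", "C"): 0.4}, abs=1e-9
        )

    def test_additive_four_taxon_recovery(self):
        """NJ reconstructs an additive matrix exactly."""
        dist = {
            ("A", "B"): 3, ("A", "C"): 7, ("A", "D"): 8,
            ("B", "C"): 6, ("B", "D"): 7, ("C", "D"): 5,
        }
        ids = ["A", "B", "C", "D"]
        m = np.zeros((4, 4))
        for (x, y), v in dist.items():
            i, j = ids.index(x), ids.index(y)
            m[i, j] = m[j, i] = v
        nwk = ds.nj_from_matrix(ids, m)
        pat = _patristic(nwk)
        for pair, v in dist.items():
            assert pat[pair] == pytest.approx(v, abs=1e-9)

    def test_zero_distances_star(self):
        m = np.zeros((4, 4))
        nwk = ds.nj_from_matrix(["A", "B", "C", "D"], m)
        assert all(v == pytest.approx(0, abs=1e-12) for v in _patristic(nwk).values())

    def test_variants_on_bundle(self, painted_k10):
        table, _, painting, _, _ = painted_k10
        trees = ds.nj_trees(table, painting)
        assert set(trees) == {"all", "within", "among"}
        for nwk in trees.values():
            assert nwk.endswith(";")


def _patristic(nwk: str) -> dict:
    from skbio import TreeNode
    from io import StringIO

    tree = TreeNode.read(StringIO(nwk))
    tips = sorted(t.name for t in tree.tips())
    out = {}
    for a, b in itertools.combinations(tips, 2):
        out[(a, b)] = tree.find(a).distance(tree.find(b))
    return out
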