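"""Clustering, volcano statistics, and paired-pY protection enrichment."""

import numpy as np
import pytest
import scipy.stats
from sklearn.metrics import adjusted_rand_score

from phosphodyn import (
    ClusterParams,
    EgfClass,
    MergedSiteTable,
    NoiseModel,
    Shp2Class,
    cluster_profiles,
    default_archetypes,
    merge_replicates,
    paired_site_enrichment,
    select_k,
    simulate_site_table,
    volcano,
)
from phosphodyn.profile_stats import MIN_P, paired_proteins

from .conftest import make_call, make_site_table


def noise_free_merged(n_per_archetype=10, archetypes=None):
    table, truth = simulate_site_table(
        n_per_archetype,
        NoiseModel(cv=0.0, replicate_shift_sd=0.0, seed=1),
        overlap_fraction=1.0,
        archetypes=archetypes,
    )
    return merge_replicates(table), truth


class TestClusterProfiles:
    def test_noise_free_recovery_is_exact(self):
        merged, truth = noise_free_merged()
        result = cluster_profiles(merged, ClusterParams(k=6))
        ari = adjusted_rand_score(
            [truth.cluster(k) for k in result.site_order],
            [result.assignment[k] for k in result.site_order],
        )
        assert ari == 1.0

    def test_k_one_puts_everything_together(self):
        merged, _ = noise_free_merged(2)
        result = cluster_profiles(merged, ClusterParams(k=1))
        assert set(result.assignment.values()) == {1}

    def test_k_larger_than_sites_rejected(self):
        merged, _ = noise_free_merged(1)  # 6 sites
        with pytest.raises(ValueError, match="exceeds"):
            cluster_profiles(merged, ClusterParams(k=7))

    def test_duplicating_sites_preserves_structure(self):
        merged, _ = noise_free_merged(4)
        doubled = MergedSiteTable(design=merged.design)
        for key, vec in merged.profiles.items():
            doubled.profiles[key] = vec
            dup = (key[0] + "_DUP", key[1])
            doubled.profiles[dup] = vec.copy()
            for m in (key, dup):
                doubled.residues[m] = "Y"
                doubled.provenance[m] = frozenset({"rep1"})
        r1 = cluster_profiles(merged, ClusterParams(k=6))
        r2 = cluster_profiles(doubled, ClusterParams(k=6))
        shared = list(merged.profiles)
        ari = adjusted_rand_score(
            [r1.assignment[k] for k in shared], [r2.assignment[k] for k in shared]
        )
        assert ari == 1.0

    def test_multiplicative_rescaling_invariance(self):
        merged, _ = noise_free_merged(3)
        scaled = MergedSiteTable(design=merged.design)
        rng = np.random.default_rng(0)
        for key, vec in merged.profiles.items():
            scaled.profiles[key] = vec * rng.uniform(0.2, 9.0)
            scaled.residues[key] = "Y"
            scaled.provenance[key] = frozenset({"rep1"})
        r1 = cluster_profiles(merged, ClusterParams(k=6))
        r2 = cluster_profiles(scaled, ClusterParams(k=6))
        keys = list(merged.profiles)
        assert adjusted_rand_score(
            [r1.assignment[k] for k in keys], [r2.assignment[k] for k in keys]
        ) == 1.0


class TestSelectK:
    def test_singleton_range(self):
        merged, _ = noise_free_merged(2)
        assert select_k(merged, [4]) == 4

    @pytest.mark.parametrize("m", [2, 3, 4, 5, 6])
    def test_recovers_archetype_count_noise_free(self, m):
        archetypes = default_archetypes()[:m]
        merged, _ = noise_free_merged(8, archetypes=archetypes)
        assert select_k(merged, range(2, 11)) == m

    def test_degenerate_identical_data_returns_smallest_k(self, caplog):
        flat = [a for a in default_archetypes() if a.name == "flat_neutral"]
        merged, _ = noise_free_merged(10, archetypes=flat)
        with caplog.at_level("WARNING"):
            assert select_k(merged, range(2, 6)) == 2
        assert "identical" in caplog.text

    def test_out_of_range_rejected(self):
        merged, _ = noise_free_merged(1)
        with pytest.raises(ValueError):
            select_k(merged, range(2, 50))


class TestVolcano:
    def test_all_null_site(self):
        ones4, ones3 = (1.0,) * 4, (1.0,) * 3
        table = make_site_table(
            [("P1", 1, r, ones4, ones4, ones3) for r in ("rep1", "rep2")]
        )
        (pt,) = volcano(table, 5)
        assert pt.mean_fc == 1.0 and pt.p_value == 1.0 and pt.neg_log10_p == 0.0
        assert not pt.low_power

    def test_constant_twofold_elevation(self):
        """All four log2 ratios equal 1 -> mean_fc 2, degenerate minimal p."""
        dmso, wo = (1.0, 1.0, 1.0, 1.0), (1.0, 1.0, 1.0)
        shp = (2.0, 2.0, 2.0, 2.0)
        table = make_site_table([("P1", 1, r, dmso, shp, wo) for r in ("rep1", "rep2")])
        (pt,) = volcano(table, 10)
        assert pt.mean_fc == pytest.approx(2.0)
        assert pt.p_value == MIN_P

    def test_p_matches_t_distribution_closed_form(self):
        """Non-degenerate case against the textbook t statistic."""
        dmso, wo = (1.0, 1.0, 1.0, 1.0), (1.0, 1.1, 1.0)
        shp1 = (1.0, 1.8, 1.0, 1.0)
        shp2v = (1.0, 2.4, 1.0, 1.0)
        table = make_site_table(
            [("P1", 1, "rep1", dmso, shp1, wo), ("P1", 1, "rep2", dmso, shp2v, wo)]
        )
        (pt,) = volcano(table, 5)
        # oracle: recompute the four log2 ratios and the t CDF directly
        ratios = []
        for shp in (shp1, shp2v):
            ratios += [shp[1] / dmso[1], shp[1] / wo[0]]
        x = np.log2(ratios)
        t_stat = x.mean() / (x.std(ddof=1) / np.sqrt(len(x)))
        p_oracle = 2 * scipy.stats.t.sf(abs(t_stat), df=len(x) - 1)
        assert pt.p_value == pytest.approx(p_oracle, rel=1e-12)
        assert pt.mean_fc == pytest.approx(np.mean(ratios))

    def test_replicate_label_swap_is_invisible(self):
        table, _ = simulate_site_table(4, NoiseModel(cv=0.1, seed=21))
        swapped = make_site_table([])
        for p in table.profiles.values():
            rep = "rep2" if p.replicate_id == "rep1" else "rep1"
            swapped.add(
                type(p)(
                    protein_id=p.protein_id,
                    position=p.position,
                    residue=p.residue,
                    replicate_id=rep,
                    abundance=p.abundance,
                )
            )
        for a, b in zip(volcano(table, 30), volcano(swapped, 30)):
            assert a.site_key == b.site_key
            assert a.mean_fc == b.mean_fc and a.p_value == b.p_value

    def test_single_replicate_site_flagged_low_power(self):
        ones4, ones3 = (1.0,) * 4, (1.0,) * 3
        table = make_site_table([("P9", 9, "rep1", ones4, (1, 2, 1, 1), ones3)])
        (pt,) = volcano(table, 5)
        assert pt.low_power and pt.n_ratios == 2


class TestPairedSiteEnrichment:
    def test_pairing_rule_on_tandem_motifs(self):
        positions = {
            "GAB1": [627, 659],  # delta 32 -> paired
            "MPZL1": [241, 263],  # delta 22 -> paired
            "SINGLE": [100],  # unpaired
            "FARAPART": [100, 400],  # delta 300 -> unpaired at d=50
        }
        paired = paired_proteins(positions, d=50)
        assert paired == {"GAB1", "MPZL1"}

    def test_perfect_separation_hits_permutation_floor(self):
        calls, positions = [], {}
        for i in range(20):  # protected sites on paired proteins
            prot = f"PAIRED{i:02d}"
            positions[prot] = [100, 130]
            calls.append(make_call(prot, 100, shp2_class=Shp2Class.POST_STIM_POSITIVE))
        for i in range(20):  # neutral sites on unpaired proteins
            prot = f"SINGLE{i:02d}"
            positions[prot] = [100]
            calls.append(make_call(prot, 100, shp2_class=Shp2Class.NEUTRAL))
        report = paired_site_enrichment(calls, positions, d=50, n_perm=999, seed=7)
        assert report.observed == 20
        assert report.p_value == pytest.approx(1 / 1000)
        np.testing.assert_array_equal(report.table, [[20, 0], [0, 20]])

    def test_margins_match_input(self):
        rng = np.random.default_rng(3)
        calls, positions = [], {}
        for i in range(60):
            prot = f"P{i:03d}"
            positions[prot] = [50, 80] if rng.random() < 0.5 else [50]
            cls = Shp2Class.PRE_STIM_POSITIVE if rng.random() < 0.3 else Shp2Class.NEUTRAL
            calls.append(make_call(prot, 50, shp2_class=cls))
        report = paired_site_enrichment(calls, positions, n_perm=99, seed=1)
        assert report.table.sum() == 60
        n_protected = sum(
            c.shp2_class in {Shp2Class.PRE_STIM_POSITIVE, Shp2Class.POST_STIM_POSITIVE}
            for c in calls
        )
        assert report.table[0].sum() == n_protected
        assert 1 / 100 <= report.p_value <= 1.0

    def test_missing_positions_rejected(self):
        with pytest.raises(KeyError):
            paired_site_enrichment([make_call("P1", 1)], {}, n_perm=9)

    def test_invalid_n_perm_rejected(self):
        with pytest.raises(ValueError):
            paired_site_enrichment([make_call("P1", 1)], {"P1": [1]}, n_perm=0)
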