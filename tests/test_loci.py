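"""Thresholds, lead pruning, clustering, replication and PheWAS profiles."""

import numpy as np
import pandas as pd
import pytest

import mtgwas as m
from mtgwas.errors import ParameterError
from mtgwas.loci import benjamini_hochberg


def assoc_frame(cm, nlp, chrom="1", maf=0.1):
    k = len(cm)
    return pd.DataFrame({
        "variant": [f"v{i}" for i in range(k)],
        "chrom": chrom, "pos": (np.asarray(cm) * 1e6).astype(int) + 1,
        "cm": cm, "maf": maf, "neglog10_p": nlp,
    })


class TestThresholds:
    def test_study_of_3144_phenotypes(self):
        t = m.thresholds(3144)
        assert t.bonferroni_factor == 3.5
        assert t.studywide == 11.0
        assert t.phewas == 4.79

    def test_23_group_multitrait_threshold(self):
        assert m.thresholds(3144, n_groups=23).multitrait_corrected == 8.86

    def test_single_phenotype_no_correction(self):
        t = m.thresholds(1)
        assert t.studywide == t.genomewide == 7.5
        assert t.phewas == 1.30

    def test_ordering_invariant(self):
        t = m.thresholds(100, n_groups=5)
        assert t.studywide > t.genomewide
        assert np.isfinite([t.genomewide, t.studywide, t.multitrait_corrected,
                            t.phewas]).all()


def oracle_prune(df, threshold, window):
    """Exhaustive re-scan pruning oracle: rescan the full list each round."""
    alive = df[(df.neglog10_p > threshold)].copy()
    leads = []
    while len(alive):
        best = alive.sort_values(["neglog10_p", "chrom", "pos"],
                                 ascending=[False, True, True],
                                 kind="stable").iloc[0]
        leads.append(best["variant"])
        drop = (alive.chrom == best.chrom) & ((alive.cm - best.cm).abs() <= window)
        alive = alive[~drop]
    return leads


class TestPruneLeads:
    def test_hand_traced_greedy_rule(self):
        df = assoc_frame([0.0, 0.1, 0.3], [12.0, 9.0, 8.0])
        leads = m.prune_leads(df)
        assert list(leads["variant"]) == ["v0", "v2"]
        assert list(leads["cm"]) == [0.0, 0.3]

    def test_nothing_above_threshold(self):
        df = assoc_frame([0.0, 0.5], [5.0, 6.0])
        assert len(m.prune_leads(df)) == 0

    def test_maf_filter_applied_first(self):
        df = assoc_frame([0.0, 0.1], [12.0, 9.0])
        df.loc[0, "maf"] = 0.0005  # strongest variant fails MAF > 0.1%
        leads = m.prune_leads(df, maf_min=0.001)
        assert list(leads["variant"]) == ["v1"]

    def test_missing_cm_named_in_error(self):
        df = assoc_frame([0.0, 0.2], [12.0, 9.0])
        df.loc[1, "cm"] = np.nan
        with pytest.raises(ParameterError, match="v1"):
            m.prune_leads(df)

    def test_leads_mutually_separated(self):
        rng = np.random.default_rng(5)
        cm = np.sort(rng.uniform(0, 5, 100))
        df = assoc_frame(cm, rng.uniform(6, 20, 100))
        leads = m.prune_leads(df)
        c = np.sort(leads["cm"].to_numpy())
        assert np.all(np.diff(c) > 0.25)

    def test_matches_exhaustive_oracle_on_random_instances(self):
        rng = np.random.default_rng(6)
        for _ in range(300):
            k = int(rng.integers(1, 200))
            df = assoc_frame(np.round(rng.uniform(0, 3, k), 4),
                             np.round(rng.uniform(5, 15, k), 3),
                             chrom=rng.choice(["1", "2"], k))
            leads = m.prune_leads(df)
            assert list(leads["variant"]) == oracle_prune(df, 7.5, 0.25)


class TestClusterLeads:
    def test_within_window_chains_into_one_cluster(self):
        leads = assoc_frame([0.0, 0.2], [10.0, 9.0])
        leads["phenotype"] = ["p1", "p2"]
        clusters = m.cluster_leads(leads)
        assert len(clusters) == 1
        assert clusters[0].phenotypes == ["p1", "p2"]
        assert clusters[0].lead_variant == "v0"

    def test_beyond_window_splits(self):
        leads = assoc_frame([0.0, 0.3], [10.0, 9.0])
        assert len(m.cluster_leads(leads)) == 2

    def test_single_lead_single_cluster(self):
        leads = assoc_frame([1.0], [9.0])
        clusters = m.cluster_leads(leads)
        assert len(clusters) == 1
        assert clusters[0].lead_variant == "v0"

    def test_cluster_count_monotone_in_window(self):
        rng = np.random.default_rng(7)
        leads = assoc_frame(np.sort(rng.uniform(0, 10, 50)),
                            rng.uniform(8, 12, 50))
        counts = [len(m.cluster_leads(leads, window_cm=w))
                  for w in (0.05, 0.1, 0.25, 0.5, 1.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_different_chromosomes_never_cluster(self):
        leads = assoc_frame([0.0, 0.1], [10.0, 9.0], chrom=["1", "2"])
        assert len(m.cluster_leads(leads)) == 2

    def test_manual_merge_and_split(self):
        leads = assoc_frame([0.0, 0.3, 0.4], [10.0, 9.0, 8.0])
        auto = m.cluster_leads(leads)
        assert len(auto) == 2
        merged = m.cluster_leads(leads, curation=[{"action": "merge",
                                                   "clusters": [0, 1]}])
        assert len(merged) == 1
        split = m.cluster_leads(leads, curation=[{"action": "split",
                                                  "cluster": 1, "at_cm": 0.35}])
        assert len(split) == 3


class TestAssessReplication:
    def test_expected_null_count_for_427_leads(self):
        rng = np.random.default_rng(8)
        rep = m.assess_replication(rng.uniform(size=427))
        assert rep.expected_null == 21

    def test_hand_computed_bh(self):
        rep = m.assess_replication(np.array([0.01, 0.04, 0.2]))
        assert rep.n_nominal == 2
        assert rep.n_fdr == 1  # only 0.01 <= 0.05 * 1/3

    def test_all_unit_pvalues(self):
        rep = m.assess_replication(np.ones(10))
        assert rep.n_nominal == 0 and rep.n_fdr == 0

    def test_out_of_range_pvalue_rejected(self):
        with pytest.raises(ParameterError):
            m.assess_replication(np.array([0.5, 1.2]))

    def test_sign_concordance_reported(self):
        rep = m.assess_replication(np.array([0.01, 0.02]),
                                   discovery_beta=np.array([1.0, -1.0]),
                                   replication_beta=np.array([0.5, 0.5]))
        assert rep.sign_concordant == 1

    def test_bh_against_direct_definition(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=50) ** 2
        mask = benjamini_hochberg(p, q=0.1)
        n = len(p)
        srt = np.sort(p)
        k = max((i + 1 for i in range(n) if srt[i] <= 0.1 * (i + 1) / n),
                default=0)
        assert mask.sum() == k
        if k:
            assert p[mask].max() <= srt[k - 1]


class TestPhewasProfile:
    @pytest.fixture(scope="class")
    @staticmethod
    def store():
        rng = np.random.default_rng(10)
        rows = []
        for v in ["rsA", "rsB"]:
            for p_idx in range(8):
                rows.append({"variant": v, "phenotype": f"p{p_idx}",
                             "neglog10_p": rng.uniform(0, 3)})
        df = pd.DataFrame(rows)
        df.loc[(df.variant == "rsA") & (df.phenotype.isin(["p1", "p3"])),
               "neglog10_p"] = 12.0
        return df

    def test_vector_length_matches_phenotype_count(self, store):
        prof = m.phewas_profile("rsA", store, threshold=4.79)
        assert len(prof) == 8

    def test_flags_match_threshold_rule(self, store):
        prof = m.phewas_profile("rsA", store, threshold=4.79)
        flagged = set(prof.loc[prof.above_threshold, "phenotype"])
        expected = set(store.loc[(store.variant == "rsA")
                                 & (store.neglog10_p > 4.79), "phenotype"])
        assert flagged == expected == {"p1", "p3"}

    def test_unknown_variant_rejected(self, store):
        with pytest.raises(KeyError):
            m.phewas_profile("rsZ", store, threshold=4.79)

    def test_planted_causal_phenotypes_flagged(self):
        """A variant causal for two phenotypes out of six is flagged exactly
        for those two at an effect size with essentially full power."""
        G = m.simulate_genotypes(800, 30, seed=11, maf_spectrum=(0.2, 0.5))
        rng = np.random.default_rng(12)
        Y = rng.standard_normal((800, 6))
        g = G.dosages[:, 4]
        Y[:, 1] += 1.0 * g
        Y[:, 3] += 1.0 * g
        table = m.PhenotypeTable(samples=G.samples, values=Y,
                                 names=[f"p{i}" for i in range(6)])
        res = m.run_mass_gwas(G, table)
        thr = m.thresholds(6).phewas
        prof = m.phewas_profile(G.variants["id"][4], res, thr)
        flagged = set(prof.loc[prof.above_threshold, "phenotype"])
        assert flagged == {"p1", "p3"}
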