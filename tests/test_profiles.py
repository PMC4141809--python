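"""Profile aggregation, copy numbers, Jensen-Shannon distances, enrichment,
pathway profiles and protocol comparison."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import annobench as ab
from annobench.pipeline import dataset_profile, perfect_oracle_run
from annobench.profiles import (
    FunctionalProfile,
    aggregate_profile,
    bottom_recall_kos,
    compare_protocols,
    copy_numbers,
    jsd_distance,
    pathway_enrichment,
    pathway_profiles,
    per_ko_recall,
)
from annobench.protocols import ConsideredHit, WeightedAssignment


def _assignment(read_id, parts):
    """parts: list of (gene_id, weight, kos, gene_length is given via catalog)."""
    a = WeightedAssignment(read_id, "annotated")
    for gene_id, weight, kos in parts:
        a.considered.append(ConsideredHit(gene_id, 1e-9, 1e-9, weight, frozenset(kos)))
        for ko in kos:
            a.ko_weights[ko] = a.ko_weights.get(ko, 0.0) + weight / len(kos)
    return a


@pytest.fixture(scope="module")
def catalog():
    genes = [
        ab.GeneRecord("gA", "gm", 1, 300, "+", frozenset({"K1"})),
        ab.GeneRecord("gB", "gm", 401, 1000, "+", frozenset({"K1"})),  # 600 bp
        ab.GeneRecord("gC", "gm", 1101, 1400, "+", frozenset({"K2"})),
    ]
    gm = ab.GenomeRecord("gm", "A" * 1500, ab.Taxon("s", "sp", "ge"), genes)
    return ab.build_catalog([gm], {"K1": {"p1"}, "K2": {"p1", "p2"}})


class TestAggregation:
    def test_unit_weight_reads_divided_by_gene_length(self, catalog):
        assigns = [_assignment(f"r{i}", [("gA", 1.0, {"K1"})]) for i in range(400)]
        prof = aggregate_profile(assigns, catalog, "aligned_gene")
        assert prof.counts["K1"] == pytest.approx(400.0)
        assert prof.norm_counts["K1"] == pytest.approx(400 / 300)

    def test_split_read_contributes_fractions(self, catalog):
        a = _assignment("r", [("gA", 0.5, {"K1"}), ("gC", 0.5, {"K2"})])
        prof = aggregate_profile([a], catalog)
        assert prof.counts == {"K1": pytest.approx(0.5), "K2": pytest.approx(0.5)}

    def test_ko_mean_normalization_uses_member_mean(self, catalog):
        # K1 members are 300 and 600 bp -> mean 450
        a = _assignment("r", [("gA", 1.0, {"K1"})])
        prof = aggregate_profile([a], catalog, "ko_mean")
        assert prof.norm_counts["K1"] == pytest.approx(1 / 450)

    def test_empty_assignments_give_empty_profile(self, catalog):
        prof = aggregate_profile([], catalog)
        assert prof.counts == {} and prof.norm_counts == {}

    def test_total_weight_is_conserved(self, catalog):
        rng = np.random.default_rng(2)
        assigns = []
        total = 0.0
        for i in range(50):
            w = rng.dirichlet([1, 1, 1])
            parts = [("gA", w[0], {"K1"}), ("gB", w[1], {"K1"}), ("gC", w[2], {"K2"})]
            assigns.append(_assignment(f"r{i}", parts))
            total += 1.0
        prof = aggregate_profile(assigns, catalog)
        assert prof.total_count == pytest.approx(total)


class TestCopyNumbers:
    def test_equal_length_fixture_recovers_two_exactly(self, f2):
        res = perfect_oracle_run(f2.community, protocols=["top_gene"], seed=1)
        result = res[(f2.community.genomes[0].genome_id, "top_gene", "none")]
        prof = dataset_profile(result, f2.community.catalog, f2.community.markers)
        assert prof.copy_nums[f2.duplicated_ko] == pytest.approx(2.0, abs=1e-12)
        for ko, c in prof.copy_nums.items():
            if ko != f2.duplicated_ko:
                assert c == pytest.approx(1.0, abs=1e-12)

    def test_marker_ko_normalized_against_itself(self):
        prof = FunctionalProfile(norm_counts={"KM": 2.0, "KX": 1.0})
        cn = copy_numbers(prof, ["KM"])
        assert cn["KM"] == pytest.approx(1.0)
        assert cn["KX"] == pytest.approx(0.5)

    def test_absent_marker_contributes_zero_to_mean(self):
        prof = FunctionalProfile(norm_counts={"KM1": 2.0, "KX": 1.0})
        cn = copy_numbers(prof, ["KM1", "KM2"])
        assert cn["KX"] == pytest.approx(1.0)  # mean marker count = 1.0

    def test_no_marker_observed_is_an_error(self):
        prof = FunctionalProfile(norm_counts={"KX": 1.0})
        with pytest.raises(ab.ValidationError):
            copy_numbers(prof, ["KM"])


class TestJSD:
    def test_identical_distributions_at_zero(self):
        assert jsd_distance({"a": 0.5, "b": 0.5}, {"a": 0.5, "b": 0.5}) == 0.0

    def test_disjoint_supports_at_one(self):
        assert jsd_distance({"a": 1.0}, {"b": 1.0}) == pytest.approx(1.0)

    def test_matches_entropy_oracle(self):
        """sqrt(H(M) − (H(P)+H(Q))/2) computed independently, base 2."""
        p, q = np.array([0.5, 0.5]), np.array([0.25, 0.75])
        m = (p + q) / 2

        def H(v):
            return -sum(x * math.log2(x) for x in v if x > 0)

        expected = math.sqrt(H(m) - (H(p) + H(q)) / 2)
        assert jsd_distance(p, q) == pytest.approx(expected, abs=1e-12)

    def test_metric_properties_on_random_triples(self):
        rng = np.random.default_rng(23)
        for _ in range(120):
            k = int(rng.integers(2, 6))
            p, q, r = (rng.dirichlet(np.ones(k)) for _ in range(3))
            dpq, dqr, dpr = jsd_distance(p, q), jsd_distance(q, r), jsd_distance(p, r)
            assert 0.0 <= dpq <= 1.0
            assert dpq == pytest.approx(jsd_distance(q, p), abs=1e-12)
            assert dpr <= dpq + dqr + 1e-12  # triangle inequality
        assert jsd_distance(p, p) == pytest.approx(0.0, abs=1e-8)

    def test_all_zero_profile_rejected(self):
        with pytest.raises(ab.ValidationError):
            jsd_distance({"a": 0.0}, {"a": 1.0})


class TestPerKoRecall:
    def _classifications(self, catalog, spec):
        """spec: list of (src_gene, correct: bool) KO-gene reads."""
        from annobench.evaluate import ReadClassification
        from annobench.reference import Origin

        out = []
        for i, (gene, correct) in enumerate(spec):
            kos = catalog.gene_to_kos[gene]
            c = ReadClassification(
                read_id=f"r{i}", origin=Origin.KO_GENE, source_kos=kos,
                ko_fraction=1.0, gene_fraction=1.0,
                correct_ko_weight=1.0 if correct else 0.0,
            )
            out.append(c)
        return out

    def test_mean_and_ci_across_datasets(self, catalog):
        ds = {
            "d1": self._classifications(catalog, [("gA", True), ("gC", True)]),
            "d2": self._classifications(catalog, [("gA", False), ("gC", True)]),
        }
        stats = per_ko_recall(ds, catalog)
        assert stats.loc["K1", "mean_recall"] == pytest.approx(0.5)
        assert stats.loc["K2", "mean_recall"] == pytest.approx(1.0)
        assert stats.loc["K2", "ci_low"] == stats.loc["K2", "ci_high"] == 1.0
        assert stats.loc["K1", "n_genes"] == 2
        assert stats.loc["K1", "mean_gene_length"] == pytest.approx(450.0)

    def test_bottom_fraction_includes_boundary_ties(self):
        stats = pd.DataFrame(
            {"mean_recall": [0.1, 0.1, 0.5, 0.9] + [1.0] * 96},
            index=[f"K{i}" for i in range(100)],
        )
        low = bottom_recall_kos(stats, 0.05)
        assert low == {"K0", "K1", "K2", "K3", "K4"} | {
            k for k in stats.index if stats.loc[k, "mean_recall"] <= stats["mean_recall"].sort_values().iloc[4]
        }


class TestEnrichment:
    def test_hand_computed_hypergeometric(self):
        universe = {f"K{i}" for i in range(10)}
        pathway = {f"K{i}" for i in range(4)}
        low = {"K0", "K1", "K2"}
        table = pathway_enrichment(low, universe, {k: {"pw"} for k in pathway})
        # P(all 3 drawn from the 4-member pathway) = C(4,3)/C(10,3)
        assert table.loc[0, "p"] == pytest.approx(math.comb(4, 3) / math.comb(10, 3))

    def test_matches_exhaustive_subset_enumeration(self):
        rng = np.random.default_rng(31)
        for _ in range(100):
            m = int(rng.integers(5, 13))
            universe = [f"K{i}" for i in range(m)]
            pw_size = int(rng.integers(1, m + 1))
            pathway = set(rng.choice(universe, size=pw_size, replace=False))
            n_low = int(rng.integers(1, m + 1))
            low = set(rng.choice(universe, size=n_low, replace=False))
            table = pathway_enrichment(low, set(universe), {k: {"pw"} for k in pathway})
            obs = len(pathway & low)
            total = hits = 0
            for subset in itertools.combinations(universe, n_low):
                total += 1
                if len(pathway & set(subset)) >= obs:
                    hits += 1
            assert table.loc[0, "p"] == pytest.approx(hits / total, abs=1e-12)

    def test_disjoint_pathway_p_is_one(self):
        universe = {"K1", "K2", "K3", "K4"}
        table = pathway_enrichment({"K1"}, universe, {"K4": {"pw"}})
        assert table.loc[0, "overlap"] == 0
        assert table.loc[0, "p"] == pytest.approx(1.0)

    def test_low_set_equals_universe_degenerate(self):
        universe = {"K1", "K2", "K3"}
        table = pathway_enrichment(set(universe), universe, {"K1": {"pw"}})
        assert table.loc[0, "overlap"] == 1
        assert table.loc[0, "p"] == pytest.approx(1.0)

    def test_low_set_outside_universe_rejected(self):
        with pytest.raises(ab.ValidationError):
            pathway_enrichment({"KX"}, {"K1"}, {})


class TestPathwayProfiles:
    def test_multi_membership_counts_twice(self, catalog):
        profs = {"s1": {"K1": 1.0, "K2": 2.0}}
        tab = pathway_profiles(profs, catalog.ko_to_pathways)
        # pre-normalization: p1 = 1 + 2 = 3, p2 = 2; total 5
        assert tab.loc["s1", "p1"] == pytest.approx(3 / 5)
        assert tab.loc["s1", "p2"] == pytest.approx(2 / 5)
        assert tab.loc["s1"].sum() == pytest.approx(1.0)

    def test_empty_profile_gives_zero_row(self, catalog):
        tab = pathway_profiles({"s1": {}}, catalog.ko_to_pathways)
        assert tab.loc["s1"].sum() == 0.0


class TestCompareProtocols:
    def _vectors(self, rng, n_samples=12, n_pathways=6, shift=None):
        base = rng.dirichlet(np.ones(n_pathways), size=n_samples)
        a = pd.DataFrame(base, index=[f"s{i}" for i in range(n_samples)],
                         columns=[f"p{i}" for i in range(n_pathways)])
        b = a.copy()
        if shift is not None:
            pw, delta = shift
            b[pw] = b[pw] + delta
            b = b.div(b.sum(axis=1), axis=0)
        return {"top_gene": a, "alt": b}

    def test_identical_vectors_zero_distance_nothing_tested(self):
        rng = np.random.default_rng(5)
        vs = self._vectors(rng)
        result = compare_protocols(vs, "top_gene", min_samples=10)
        assert (result.inter_protocol["jsd"] == 0.0).all()
        assert result.differential.empty

    def test_constant_shift_detected_as_differential(self):
        rng = np.random.default_rng(6)
        vs = self._vectors(rng, shift=("p0", 0.3))
        result = compare_protocols(vs, "top_gene", min_samples=10)
        row = result.differential.set_index("pathway").loc["p0"]
        assert row["significant"]

    def test_sparse_difference_excluded_by_min_samples(self):
        rng = np.random.default_rng(7)
        vs = self._vectors(rng, n_samples=15)
        other = vs["alt"].copy()
        other.iloc[:5, 0] += 0.1  # differences in only 5 of 15 samples
        other = other.div(other.sum(axis=1), axis=0)
        vs["alt"] = other
        result = compare_protocols(vs, "top_gene", min_samples=10)
        # p0 differs in 5 samples -> excluded; renormalization touches all
        # pathways in those same 5 samples only, so nothing reaches 10
        assert result.differential.empty

    def test_mismatched_samples_rejected(self):
        rng = np.random.default_rng(8)
        vs = self._vectors(rng)
        vs["alt"] = vs["alt"].iloc[:-1]
        with pytest.raises(ab.ValidationError):
            compare_protocols(vs)

    def test_inter_sample_distances_cover_all_pairs(self):
        rng = np.random.default_rng(9)
        vs = self._vectors(rng, n_samples=5)
        result = compare_protocols(vs, min_samples=3)
        assert len(result.inter_sample) == 2 * (5 * 4 // 2)
        assert (result.inter_sample["jsd"] >= 0).all()
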