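"""Read classification against ground truth and precision/recall summaries.

Includes an independent brute-force oracle: metrics are recomputed from raw
(read, hit) tables with plain Python/math, re-deriving considered hits and
weights directly from the protocol definitions, and compared to the
pipeline on randomized instances.
"""

import math

import numpy as np
import pytest

import annobench as ab
from annobench.alignio import AlignmentHit, sort_hits
from annobench.evaluate import (
    classify_read,
    evaluate_dataset,
    overlap_mappability,
    summarize,
)
from annobench.protocols import ProtocolConfig, annotate_read, annotate_reads
from annobench.reference import GeneRecord, GenomeRecord, Origin, Taxon, build_catalog
from annobench.simulate import ReadRecord


def _hit(read, gene, evalue):
    return AlignmentHit(
        read_id=read, gene_id=gene, pident=90.0, length=33, mismatch=0, gapopen=0,
        qstart=1, qend=101, sstart=1, send=33, evalue=evalue, bitscore=50.0,
    )


def _read(read_id, origin, gene_ids=(), fractions=None):
    return ReadRecord(
        read_id=read_id, genome_id="gm", start=1, length=101, sequence="",
        origin=origin, gene_ids=frozenset(gene_ids),
        overlap_fractions=fractions or {origin: 1.0},
    )


@pytest.fixture(scope="module")
def catalog():
    genes = [
        GeneRecord("gA", "gm", 1, 300, "+", frozenset({"K1"})),
        GeneRecord("gB", "gm", 401, 700, "+", frozenset({"K1"})),
        GeneRecord("gC", "gm", 801, 1100, "+", frozenset({"K2"})),
        GeneRecord("gN", "gm", 1201, 1500, "+", frozenset()),
    ]
    gm = GenomeRecord("gm", "A" * 2000, Taxon("s", "sp", "ge"), genes)
    return build_catalog([gm])


class TestClassifyRead:
    def _classify(self, catalog, read, hits, protocol="top_gene"):
        a = annotate_read(read.read_id, sort_hits(hits), ProtocolConfig(protocol=protocol), catalog)
        return classify_read(a, read, catalog)

    def test_own_gene_same_ko(self, catalog):
        read = _read("r", Origin.KO_GENE, {"gA"})
        c = self._classify(catalog, read, [_hit("r", "gA", 1e-30)])
        assert c.class_weights == {"correct_gene_correct_ko": pytest.approx(1.0)}

    def test_other_gene_same_ko(self, catalog):
        read = _read("r", Origin.KO_GENE, {"gA"})
        c = self._classify(catalog, read, [_hit("r", "gB", 1e-30)])
        assert c.class_weights == {"incorrect_gene_correct_ko": pytest.approx(1.0)}

    def test_intergenic_read_with_ko_hit_is_incorrect(self, catalog):
        read = _read("r", Origin.INTERGENIC)
        c = self._classify(catalog, read, [_hit("r", "gC", 1e-5)])
        assert c.class_weights == {"incorrect_gene_incorrect_ko": pytest.approx(1.0)}

    def test_non_ko_read_own_gene_is_no_result_under_top_gene(self, catalog):
        # best alignment carries no KO: the protocol yields no functional label
        read = _read("r", Origin.NON_KO_GENE, {"gN"})
        c = self._classify(catalog, read, [_hit("r", "gN", 1e-9)])
        assert c.class_weights == {"no_result": pytest.approx(1.0)}

    def test_non_ko_read_own_gene_labeled_in_mixed_considered_set(self, catalog):
        # under top20_genes the non-KO self hit stays in the considered set
        read = _read("r", Origin.NON_KO_GENE, {"gN"})
        c = self._classify(
            catalog, read, [_hit("r", "gN", 1e-9), _hit("r", "gC", 1e-9)], "top20_genes"
        )
        assert c.class_weights["correct_gene_no_ko"] == pytest.approx(0.5)
        assert c.class_weights["incorrect_gene_incorrect_ko"] == pytest.approx(0.5)

    def test_multi_read_skipped_under_exclude(self, catalog):
        read = _read("r", Origin.MULTI, {"gA"},
                     {Origin.KO_GENE: 0.5, Origin.INTERGENIC: 0.5})
        a = annotate_read("r", [_hit("r", "gA", 1e-9)], ProtocolConfig(), catalog)
        c = classify_read(a, read, catalog, policy="exclude")
        assert c.skipped

    def test_multi_read_coverage_weighted_mixture(self, catalog):
        read = _read("r", Origin.MULTI, {"gA"},
                     {Origin.KO_GENE: 0.6, Origin.INTERGENIC: 0.4})
        a = annotate_read("r", [_hit("r", "gA", 1e-9)], ProtocolConfig(), catalog)
        c = classify_read(a, read, catalog, policy="coverage_weighted")
        assert c.class_weights["correct_gene_correct_ko"] == pytest.approx(0.6)
        assert c.class_weights["incorrect_gene_incorrect_ko"] == pytest.approx(0.4)
        assert sum(c.class_weights.values()) == pytest.approx(1.0)

    def test_annotated_class_weights_sum_to_one(self, catalog):
        read = _read("r", Origin.KO_GENE, {"gA"})
        hits = [_hit("r", "gA", 1e-9), _hit("r", "gN", 1e-9), _hit("r", "gC", 1e-9)]
        for proto in ("top_gene", "top20_genes", "top20_kos"):
            c = self._classify(catalog, read, hits, proto)
            assert sum(c.class_weights.values()) == pytest.approx(1.0)


class TestSummaries:
    def test_worked_fixture_top_gene(self, f1):
        cfg = ProtocolConfig(protocol="top_gene")
        a = annotate_reads([r.read_id for r in f1.reads], f1.hits_by_read, cfg, f1.catalog)
        s, _ = evaluate_dataset(a, f1.reads, f1.catalog, dataset_id="f1", protocol="top_gene")
        assert s.recall_ko == f1.expected["top_gene_recall_ko"]
        assert s.precision_ko == f1.expected["top_gene_precision_ko"]

    def test_worked_fixture_top_ko(self, f1):
        cfg = ProtocolConfig(protocol="top_ko")
        a = annotate_reads([r.read_id for r in f1.reads], f1.hits_by_read, cfg, f1.catalog)
        s, _ = evaluate_dataset(a, f1.reads, f1.catalog, dataset_id="f1", protocol="top_ko")
        assert s.precision_ko == pytest.approx(f1.expected["top_ko_precision_ko"])
        assert s.recall_ko == 1.0

    def test_all_no_hit_gives_zero_recall_nan_precision(self, catalog):
        reads = [_read(f"r{i}", Origin.KO_GENE, {"gA"}) for i in range(3)]
        a = annotate_reads([r.read_id for r in reads], {}, ProtocolConfig(), catalog)
        s, _ = evaluate_dataset(a, reads, catalog)
        assert s.recall_ko == 0.0
        assert math.isnan(s.precision_ko)

    def test_unannotated_reads_lower_recall_not_precision(self, catalog):
        reads = [
            _read("r1", Origin.KO_GENE, {"gA"}),
            _read("r2", Origin.KO_GENE, {"gA"}),
        ]
        hits = {"r1": [_hit("r1", "gA", 1e-30)]}  # r2 has no alignment
        a = annotate_reads(["r1", "r2"], hits, ProtocolConfig(), catalog)
        s, _ = evaluate_dataset(a, reads, catalog)
        assert s.recall_ko == pytest.approx(0.5)
        assert s.precision_ko == pytest.approx(1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ab.ValidationError):
            summarize([])

    def test_perfect_annotation_scores_one_everywhere(self, catalog):
        reads = [_read(f"r{i}", Origin.KO_GENE, {g}) for i, g in enumerate(["gA", "gB", "gC"])]
        hits = {r.read_id: [_hit(r.read_id, next(iter(r.gene_ids)), 1e-30)] for r in reads}
        a = annotate_reads([r.read_id for r in reads], hits, ProtocolConfig(), catalog)
        s, _ = evaluate_dataset(a, reads, catalog)
        assert (s.recall_ko, s.precision_ko, s.recall_gene) == (1.0, 1.0, 1.0)


class TestBruteForceOracle:
    """Pipeline metrics vs an independent re-derivation on random instances."""

    @staticmethod
    def _oracle_metrics(reads, hits_by_read, gene_kos, protocol):
        """Straight-line recomputation from the protocol definitions."""
        recall_num = recall_den = prec_num = prec_den = 0.0
        for read in reads:
            src_kos = set().union(*(gene_kos[g] for g in read.gene_ids)) if read.gene_ids else set()
            hits = sorted(hits_by_read.get(read.read_id, []),
                          key=lambda h: (h.evalue, -h.bitscore, h.gene_id))
            if protocol == "top_gene":
                considered = [h for h in hits if h.evalue_str == hits[0].evalue_str] if hits else []
                if considered and not any(gene_kos[h.gene_id] for h in considered):
                    considered = []
            else:  # top_ko
                ko_hits = [h for h in hits if gene_kos[h.gene_id]]
                considered = (
                    [h for h in ko_hits if h.evalue_str == ko_hits[0].evalue_str]
                    if ko_hits else []
                )
            if read.origin is Origin.KO_GENE:
                recall_den += 1.0
            if not considered:
                continue
            raw = [math.exp(-h.evalue) for h in considered]
            total = sum(raw)
            for h, w in zip(considered, raw):
                w /= total
                kos = gene_kos[h.gene_id]
                if not kos:
                    continue
                prec_den += w
                if kos & src_kos and read.origin is Origin.KO_GENE:
                    prec_num += w
                    recall_num += w
        recall = recall_num / recall_den if recall_den else float("nan")
        precision = prec_num / prec_den if prec_den else float("nan")
        return precision, recall

    @pytest.mark.parametrize("protocol", ["top_gene", "top_ko"])
    def test_metrics_match_oracle_on_random_instances(self, protocol):
        rng = np.random.default_rng(17)
        for _ in range(60):
            n_genes = int(rng.integers(3, 8))
            kos = [f"K{i}" for i in range(int(rng.integers(1, 4)))]
            genes = []
            pos = 1
            for i in range(n_genes):
                ko = frozenset({rng.choice(kos)}) if rng.random() < 0.7 else frozenset()
                genes.append(GeneRecord(f"g{i}", "gm", pos, pos + 89, "+", ko))
                pos += 100
            gm = GenomeRecord("gm", "A" * (pos + 50), Taxon("s", "sp", "ge"), genes)
            cat = build_catalog([gm])
            gene_kos = {g.gene_id: set(g.ko_ids) for g in genes}
            reads, hits_by_read = [], {}
            for j in range(int(rng.integers(2, 10))):
                if rng.random() < 0.8:
                    src = genes[int(rng.integers(0, n_genes))]
                    origin = Origin.KO_GENE if src.ko_ids else Origin.NON_KO_GENE
                    reads.append(_read(f"r{j}", origin, {src.gene_id}))
                else:
                    reads.append(_read(f"r{j}", Origin.INTERGENIC))
                n_hits = int(rng.integers(0, 5))
                hs = [
                    _hit(f"r{j}", f"g{int(rng.integers(0, n_genes))}",
                         float(10.0 ** -rng.integers(1, 31)))
                    for _ in range(n_hits)
                ]
                if hs:
                    hits_by_read[f"r{j}"] = sort_hits(hs)
            a = annotate_reads([r.read_id for r in reads], hits_by_read,
                               ProtocolConfig(protocol=protocol), cat)
            s, _ = evaluate_dataset(a, reads, cat)
            p_exp, r_exp = self._oracle_metrics(reads, hits_by_read, gene_kos, protocol)
            assert s.recall_ko == pytest.approx(r_exp, abs=1e-12, nan_ok=True)
            assert s.precision_ko == pytest.approx(p_exp, abs=1e-12, nan_ok=True)


class TestOverlapMappability:
    def test_partial_overlap_table(self, catalog):
        reads, classifications = [], []
        for overlap in (25, 50, 75):
            read = _read(
                f"r{overlap}", Origin.MULTI, {"gA"},
                {Origin.KO_GENE: overlap / 101, Origin.INTERGENIC: 1 - overlap / 101},
            )
            reads.append(read)
            a = annotate_read(read.read_id, [_hit(read.read_id, "gA", 1e-9)],
                              ProtocolConfig(), catalog)
            classifications.append(classify_read(a, read, catalog, policy="coverage_weighted"))
        table = overlap_mappability(classifications, reads)
        assert list(table["overlap_bp"]) == [25, 50, 75]
        for _, row in table.iterrows():
            assert row["p_correct_ko"] == pytest.approx(row["overlap_bp"] / 101)
            total = row["p_correct_ko"] + row["p_incorrect"] + row["p_no_result"]
            assert total == pytest.approx(1.0)

    def test_zero_overlap_reads_excluded(self, catalog):
        read = _read("r", Origin.MULTI, {"gN"},
                     {Origin.NON_KO_GENE: 0.5, Origin.INTERGENIC: 0.5})
        a = annotate_read("r", [], ProtocolConfig(), catalog)
        c = classify_read(a, read, catalog, policy="coverage_weighted")
        assert overlap_mappability([c], [read]).empty
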