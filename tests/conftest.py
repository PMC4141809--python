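import numpy as np
import pytest

import annobench as ab


@pytest.fixture(scope="session")
def f1():
    return ab.fixture_f1()


@pytest.fixture(scope="session")
def f2():
    return ab.fixture_f2()


@pytest.fixture(scope="session")
def toy_genome():
    """1000 bp genome: one KO gene (101..400), one non-KO gene (601..800)."""
    rng = np.random.default_rng(3)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 1000)])
    genes = [
        ab.GeneRecord("g1", "toy", 101, 400, "+", frozenset({"K1"})),
        ab.GeneRecord("g2", "toy", 601, 800, "-", frozenset()),
    ]
    return ab.GenomeRecord("toy", seq, ab.Taxon("t1", "sp1", "ge1"), genes)


@pytest.fixture(scope="session")
def nested_community():
    """2 genera x 2 species x 2 strains, all genes KO-annotated, no markers.

    Every KO family spans its genus; cross-genus 'remote' hits go to a
    different KO, so exclusion at increasing ranks strips correctness in the
    canonical order.
    """
    spec = ab.CommunitySpec(
        seed=7, genes_per_genome=6, fraction_ko_genes=1.0, n_markers=0
    )
    return ab.build_community(spec)


@pytest.fixture(scope="session")
def default_community():
    return ab.build_community(ab.CommunitySpec(seed=5))
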