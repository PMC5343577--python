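"""Supermatrix construction, JC matrices and neighbor joining."""

import itertools

import dendropy
import numpy as np
import pytest

from mitocomp.diversity import Alignment
from mitocomp.phylo import (DistanceMatrix, concatenate, jc_matrix,
                            nj_tree, split_supermatrix, write_nexus,
                            write_partitions, write_phylip)


def _aln(gene, taxa, rows):
    return Alignment(gene=gene, taxa=tuple(taxa), rows=tuple(rows))


def test_concatenate_arithmetic():
    g1 = _aln("nad2", "abc", ["A" * 12, "C" * 12, "G" * 12])
    g2 = _aln("cox1", "abc", ["T" * 9, "A" * 9, "C" * 9])
    sm = concatenate([g1, g2])
    assert sm.length == 21
    assert sm.partitions == (("nad2", 1, 12), ("cox1", 13, 21))
    assert sm.rows[0] == "A" * 12 + "T" * 9


def test_concatenate_gap_fills_missing_taxon():
    g1 = _aln("nad2", "abc", ["A" * 12, "C" * 12, "G" * 12])
    g2 = _aln("cox1", "ab", ["T" * 9, "A" * 9])
    sm = concatenate([g1, g2])
    assert sm.rows[2] == "G" * 12 + "-" * 9
    with pytest.raises(ValueError, match="duplicate taxon"):
        concatenate([_aln("nad2", "aa", ["AAA", "CCC"])])
    with pytest.raises(ValueError):
        concatenate([g1], taxa=["x", "y"])


def test_round_trip_split(sim_panel):
    from mitocomp.simulate import alignments_from_panel
    alns = alignments_from_panel(sim_panel)
    sm = concatenate(alns)
    back = {a.gene: a for a in split_supermatrix(sm)}
    for a in alns:
        assert back[a.gene].rows == a.rows
        assert back[a.gene].taxa == a.taxa


def test_partition_export_dialects():
    g1 = _aln("nad2", "ab", ["A" * 12, "C" * 12])
    g2 = _aln("cox1", "ab", ["T" * 9, "A" * 9])
    sm = concatenate([g1, g2])
    raxml = write_partitions(sm, "raxml")
    assert raxml.splitlines()[0] == "DNA, nad2 = 1-12"
    assert raxml.splitlines()[1] == "DNA, cox1 = 13-21"
    nexus = write_partitions(sm, "nexus")
    assert "charset nad2 = 1-12;" in nexus
    with pytest.raises(ValueError):
        write_partitions(sm, "phylip")
    phylip = write_phylip(sm)
    assert phylip.splitlines()[0].split() == ["2", "21"]
    assert "ntax=2 nchar=21" in write_nexus(sm)


def test_partitions_tile_random_gene_sets():
    rng = np.random.default_rng(5)
    genes = ["nad2", "cox1", "cox2", "atp8", "cob"]
    for _ in range(20):
        lens = rng.integers(3, 40, size=len(genes))
        alns = [_aln(g, "ab", ["A" * int(n), "C" * int(n)])
                for g, n in zip(genes, lens)]
        sm = concatenate(alns)
        expected = 1
        for _, s, e in sm.partitions:
            assert s == expected
            expected = e + 1
        assert expected - 1 == sm.length == int(lens.sum())


def test_jc_matrix_closed_form():
    n = 10000
    row_a = "ACGT" * (n // 4)
    # mutate exactly 10% of sites
    row_b = list(row_a)
    for k in range(0, n, 10):
        row_b[k] = {"A": "C", "C": "G", "G": "T", "T": "A"}[row_b[k]]
    sm = concatenate([_aln("nad2", "abc", [row_a, "".join(row_b), row_a])])
    dm = jc_matrix(sm)
    assert dm.d[0, 1] == pytest.approx(0.107326, abs=1e-6)
    assert dm.d[0, 2] == 0.0
    assert np.allclose(dm.d, dm.d.T)
    assert np.all(np.diag(dm.d) == 0)


def test_jc_matrix_saturation_error():
    sm = concatenate([_aln("nad2", "abc",
                           ["A" * 300, "C" * 300, "A" * 300])])
    with pytest.raises(ValueError, match="saturated pair"):
        jc_matrix(sm)


def test_distance_matrix_validation():
    with pytest.raises(ValueError, match="symmetric"):
        DistanceMatrix(taxa=("a", "b"), d=np.array([[0, 1], [2, 0]]))


def test_nj_three_taxa_closed_form():
    d = np.array([[0.0, 0.3, 0.4],
                  [0.3, 0.0, 0.5],
                  [0.4, 0.5, 0.0]])
    nwk = nj_tree(DistanceMatrix(taxa=("A", "B", "C"), d=d))
    # star resolution: la=(dab+dac-dbc)/2 etc.
    assert nwk == "(A:0.100000,B:0.200000,C:0.300000);"


def _four_taxon_topologies():
    return [("A", "B", "C", "D"), ("A", "C", "B", "D"), ("A", "D", "B", "C")]


def _patristic(newick, labels):
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    tax = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = pdm.patristic_distance(tax[labels[i]],
                                                   tax[labels[j]])
    return d


def _same_topology(nwk1, nwk2):
    ns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=nwk1, schema="newick", taxon_namespace=ns)
    t2 = dendropy.Tree.get(data=nwk2, schema="newick", taxon_namespace=ns)
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(t1, t2) == 0


def test_nj_recovers_all_four_taxon_additive_trees():
    rng = np.random.default_rng(17)
    for x, y, u, v in _four_taxon_topologies():
        for _ in range(5):
            b = np.round(rng.uniform(0.05, 0.5, size=5), 4)
            true = (f"(({x}:{b[0]},{y}:{b[1]}):{b[4]},"
                    f"({u}:{b[2]},{v}:{b[3]}):0.0);")
            labels = sorted([x, y, u, v])
            d = _patristic(true, labels)
            nwk = nj_tree(DistanceMatrix(taxa=tuple(labels), d=d))
            assert _same_topology(nwk, true)
            # additive input: distances are reproduced exactly
            d2 = _patristic(nwk, labels)
            assert np.allclose(d, d2, atol=2e-6)


def test_nj_recovers_all_five_taxon_additive_trees():
    rng = np.random.default_rng(23)
    base = "((A:{0},B:{1}):{4},(C:{2},D:{3}):0.0);"
    # all 15 unrooted 5-taxon topologies: insert E on each of the 5
    # edges of each of the 3 unrooted 4-taxon topologies
    count = 0
    for x, y, u, v in _four_taxon_topologies():
        for edge in range(5):
            b = np.round(rng.uniform(0.05, 0.5, size=7), 4)
            tips = {x: b[0], y: b[1], u: b[2], v: b[3]}
            sub = {t: f"{t}:{tips[t]}" for t in tips}
            target = [x, y, u, v, "internal"][edge]
            if target == "internal":
                core = (f"(({sub[x]},{sub[y]}):{b[4]},E:{b[6]},"
                        f"({sub[u]},{sub[v]}):{b[5]});")
            else:
                sub[target] = f"({sub[target]},E:{b[6]}):{b[5]}"
                core = (f"(({sub[x]},{sub[y]}):{b[4]},"
                        f"({sub[u]},{sub[v]}):0.0);")
            labels = ["A", "B", "C", "D", "E"]
            d = _patristic(core, labels)
            nwk = nj_tree(DistanceMatrix(taxa=tuple(labels), d=d))
            assert _same_topology(nwk, core)
            assert np.allclose(d, _patristic(nwk, labels), atol=2e-6)
            count += 1
    assert count == 15


def test_nj_agrees_with_independent_implementation():
    """Topologies match scikit-bio's neighbor joining on random
    (noisy, non-additive) distance matrices."""
    from skbio import DistanceMatrix as SkDM
    from skbio.tree import nj as sk_nj

    rng = np.random.default_rng(31)
    labels = ["A", "B", "C", "D", "E", "F"]
    for _ in range(10):
        x = rng.uniform(0.05, 0.6, size=(6, 6))
        d = np.triu(x, 1) + np.triu(x, 1).T
        ours = nj_tree(DistanceMatrix(taxa=tuple(labels), d=d))
        theirs = str(sk_nj(SkDM(d, ids=labels)))
        assert _same_topology(ours, theirs)


def test_nj_split_recovery_from_simulation():
    """NJ on JC distances recovers the true AB|CD split for nearly all
    seeds of a 4-taxon simulation with a long internal branch."""
    from mitocomp.simulate import (SimulationConfig, alignments_from_panel,
                                   evolve_on_tree, simulate_genome)
    hits = 0
    n_seeds = 50
    for seed in range(n_seeds):
        cfg = SimulationConfig(
            seed=seed, tree="((A:0.05,B:0.05):0.05,(C:0.05,D:0.05):0.05);",
            per_gene_rate={}, control_region_length=1129)
        genome = simulate_genome(cfg)
        panel = evolve_on_tree(genome, cfg)
        genes = [f.name for f in genome.features]
        sm = concatenate(alignments_from_panel(panel, genes))
        nwk = nj_tree(jc_matrix(sm))
        if _same_topology(nwk, "((A:1,B:1):1,(C:1,D:1):1);"):
            hits += 1
    assert hits / n_seeds >= 0.95
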