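import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirtrios.sequence_io import EnhancerGeneLink, ExpressionTable
from mirtrios.seed_needle import DuplexHit
from mirtrios.trio_assembly import (
    TrioCandidate,
    assemble_trios,
    bh_adjust,
    bh_adjust_per_mirna,
    hits_to_candidates,
    read_trios,
    spearman,
    write_trios,
    TrioRecord,
)
from oracles import bh_oracle, spearman_oracle


def make_hit(mir="Mir1", enh="chr1:0-100", method="miranda", pi=None):
    return DuplexHit(
        mirna_mature_name=f"{mir}_mat1", mirna_family=mir, enhancer_id=enh,
        site_start=0, site_end=20, method=method, score=150.0,
        percent_identity=pi,
    )


class TestHitsToCandidates:
    def test_expansion_over_linked_genes(self):
        links = [EnhancerGeneLink("chr1:0-100", "GeneA"),
                 EnhancerGeneLink("chr1:0-100", "GeneB")]
        cands, unlinked = hits_to_candidates([make_hit()], links)
        assert {c.gene_name for c in cands} == {"GeneA", "GeneB"}
        assert unlinked == 0

    def test_unlinked_enhancer_counted(self):
        cands, unlinked = hits_to_candidates([make_hit(enh="chrX:0-5")], [])
        assert cands == [] and unlinked == 1

    def test_candidate_count_equals_sum_over_hits(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n_enh, n_genes = 6, 5
            links = [
                EnhancerGeneLink(f"e{e}", f"g{g}")
                for e in range(n_enh) for g in range(n_genes)
                if rng.random() < 0.4
            ]
            hits = [make_hit(mir=f"Mir{m}", enh=f"e{rng.integers(n_enh)}")
                    for m in range(4)]
            genes_of = {}
            for link in links:
                genes_of.setdefault(link.enhancer_id, set()).add(link.gene_name)
            expected = sum(len(genes_of.get(h.enhancer_id, ())) for h in hits)
            cands, _ = hits_to_candidates(hits, links)
            assert len(cands) == expected


class TestSpearman:
    def test_identity(self):
        x = np.arange(1.0, 9.0)
        rho, p = spearman(x, x)
        assert rho == pytest.approx(1.0)
        assert 0 < p <= np.finfo(float).tiny

    def test_antitone(self):
        x = np.arange(1.0, 9.0)
        rho, _ = spearman(x, x[::-1])
        assert rho == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        x = np.arange(1.0, 9.0)
        y = np.array([2, 1, 4, 3, 6, 5, 8, 7], dtype=float)
        rho, _ = spearman(x, y)
        assert rho == pytest.approx(304 / 336, abs=1e-10)
        assert round(rho, 4) == 0.9048

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="variance"):
            spearman(np.ones(8), np.arange(8.0))

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 2**32 - 1), st.integers(8, 12), st.booleans())
    def test_matches_rank_pearson_oracle(self, seed, n, with_ties):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        if with_ties:
            x = np.round(x)  # induce ties
            y = np.round(y)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        rho, p = spearman(x, y)
        rho_o, p_o = spearman_oracle(x, y)
        assert rho == pytest.approx(rho_o, abs=1e-10)
        if abs(rho_o) < 1:
            assert p == pytest.approx(p_o, rel=1e-8)


class TestSpearmanPermutationOracle:
    def test_t_approximation_close_to_exact_permutation_p(self):
        """The two-sided t-approximation tracks the exact permutation null.

        For n=8 the exact distribution is enumerable (8! permutations).
        Documented tolerance: the t-approximation deviates from the exact
        two-sided permutation p-value by < 0.03 absolute over random
        untied vectors (observed max ~0.024); it is an approximation, not
        an exact method.
        """
        import itertools

        n = 8
        perms = np.array(list(itertools.permutations(range(n))))
        d2 = ((perms - np.arange(n)) ** 2).sum(axis=1)
        rho_null = 1 - 6 * d2 / (n * (n * n - 1))
        rng = np.random.default_rng(0)
        for _ in range(100):
            x, y = rng.normal(size=n), rng.normal(size=n)
            rho, p = spearman(x, y)
            p_exact = float(np.mean(np.abs(rho_null) >= abs(rho) - 1e-12))
            assert abs(p - p_exact) < 0.03


class TestBH:
    def test_single_candidate(self):
        np.testing.assert_allclose(bh_adjust([0.03]), [0.03])

    def test_hand_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_matches_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 15))
            np.testing.assert_allclose(bh_adjust(p), bh_oracle(list(p)),
                                       atol=1e-12)

    def test_adjusted_not_below_raw(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=30)
        assert np.all(bh_adjust(p) >= p - 1e-15)

    def test_grouped_by_family(self):
        fams = ["a", "b", "a", "b", "a"]
        p = [0.01, 0.5, 0.02, 0.01, 0.03]
        adj = bh_adjust_per_mirna(fams, p)
        a_idx = [0, 2, 4]
        np.testing.assert_allclose(adj[a_idx],
                                   bh_oracle([p[i] for i in a_idx]))
        b_idx = [1, 3]
        np.testing.assert_allclose(adj[b_idx],
                                   bh_oracle([p[i] for i in b_idx]))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        fams = [f"f{rng.integers(3)}" for _ in range(20)]
        p = list(rng.uniform(size=20))
        adj = bh_adjust_per_mirna(fams, p)
        perm = rng.permutation(20)
        adj_perm = bh_adjust_per_mirna([fams[i] for i in perm],
                                       [p[i] for i in perm])
        np.testing.assert_allclose(adj_perm, adj[perm])


def expr_table(features, values):
    values = np.asarray(values, dtype=float)
    samples = [f"s{i}" for i in range(values.shape[1])]
    return ExpressionTable(list(features), samples, values)


class TestAssembleTrios:
    def _tables(self, n=12, seed=0):
        rng = np.random.default_rng(seed)
        latent = np.exp(rng.normal(size=n))
        mirna = expr_table(["Mir1"], latent[None, :])
        genes = expr_table(
            ["GenePlanted", "GeneNoise"],
            np.vstack([latent * 3 + 1, np.exp(rng.normal(size=n))]),
        )
        return mirna, genes

    def _candidates(self):
        return [
            TrioCandidate("Mir1_mat1", "Mir1", "GenePlanted", "chr1:0-100",
                          "miranda"),
            TrioCandidate("Mir1_mat1", "Mir1", "GeneNoise", "chr1:0-100",
                          "miranda"),
        ]

    def test_planted_signal_retained(self):
        mirna, genes = self._tables()
        records = assemble_trios(self._candidates(), mirna, genes)
        assert [r.gene_name for r in records] == ["GenePlanted"]
        assert records[0].scc == pytest.approx(1.0)
        assert records[0].p_adj >= records[0].p_raw

    def test_noise_gene_rarely_passes(self):
        passed = 0
        for seed in range(40):
            mirna, genes = self._tables(seed=seed)
            records = assemble_trios(self._candidates(), mirna, genes)
            passed += sum(r.gene_name == "GeneNoise" for r in records)
        assert passed <= 4  # BH at 0.05 across 40 independent tries

    def test_empty_candidates(self):
        mirna, genes = self._tables()
        assert assemble_trios([], mirna, genes) == []

    def test_fdr_boundaries(self):
        mirna, genes = self._tables()
        none = assemble_trios(self._candidates(), mirna, genes, fdr=0.0)
        assert none == []
        everything = assemble_trios(self._candidates(), mirna, genes, fdr=1.0,
                                    positive_only=False)
        assert len(everything) == 2

    def test_positive_only_filters_negative_scc(self):
        rng = np.random.default_rng(0)
        latent = np.exp(rng.normal(size=12))
        mirna = expr_table(["Mir1"], latent[None, :])
        genes = expr_table(["GeneAnti"], (1 / latent)[None, :])
        cands = [TrioCandidate("Mir1_mat1", "Mir1", "GeneAnti", "e", "miranda")]
        assert assemble_trios(cands, mirna, genes) == []
        kept = assemble_trios(cands, mirna, genes, positive_only=False)
        assert len(kept) == 1 and kept[0].scc == pytest.approx(-1.0)

    def test_missing_features_dropped(self):
        mirna, genes = self._tables()
        cands = self._candidates() + [
            TrioCandidate("MirX_mat1", "MirX", "GenePlanted", "e", "miranda"),
            TrioCandidate("Mir1_mat1", "Mir1", "GeneGone", "e", "miranda"),
        ]
        records = assemble_trios(cands, mirna, genes)
        assert {r.mature_mirna for r in records} == {"Mir1_mat1"}


class TestWriteTrios:
    def _records(self, method="miranda", pi=None):
        return [TrioRecord("Mir1_mat1", "GeneA", "chr1:0-100", 0.9,
                           0.001, 0.002, method, pi=pi)]

    def test_header_only_when_empty(self, tmp_path):
        path = tmp_path / "t.tsv"
        write_trios([], path, with_pi=False)
        assert path.read_text() == \
            "mature_mirna\tGene.Name\tenhancer\tcorr (miRNA, gene)\tp.value adj\n"

    def test_seed_needle_has_pi_column(self, tmp_path):
        path = tmp_path / "t.tsv"
        write_trios(self._records("seed_needle", pi=87.5), path)
        header = path.read_text().splitlines()[0].split("\t")
        assert header == ["mature_mirna", "Gene.Name", "enhancer",
                          "corr (miRNA, gene)", "p.value adj", "PI"]

    def test_other_methods_have_five_columns(self, tmp_path):
        path = tmp_path / "t.tsv"
        write_trios(self._records("miranda"), path)
        header = path.read_text().splitlines()[0].split("\t")
        assert len(header) == 5

    def test_round_trip(self, tmp_path):
        path = tmp_path / "t.tsv"
        records = self._records("seed_needle", pi=87.5)
        write_trios(records, path)
        back = read_trios(path, method="seed_needle")
        assert len(back) == 1
        r = back[0]
        assert (r.mature_mirna, r.gene_name, r.enhancer_id) == \
               ("Mir1_mat1", "GeneA", "chr1:0-100")
        assert r.scc == pytest.approx(0.9)
        assert r.pi == pytest.approx(87.5)
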