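"""Codon translation, GTR+Gamma site classification, and DS-series bookkeeping."""

import numpy as np
import pytest

from odontree.satred import (
    Gene,
    GtrGammaParams,
    PartitionedAlignment,
    assign_site_categories,
    build_ds_series,
    fit_gtr_gamma,
    remove_categories,
    translate_cds,
)
from odontree.synth import (
    simulate_chronogram,
    simulate_multigene_alignment,
    simulate_sites,
)

JC = dict(exchangeabilities=np.ones(6), base_freqs=np.full(4, 0.25))


@pytest.fixture(scope="module")
def small_tree():
    return simulate_chronogram(12, 146.7, seed=17)


class TestTranslateCds:
    def test_standard_code(self):
        assert translate_cds({"a": "ATGAAA"})["a"] == "MK"

    def test_unresolvable_codon_is_x(self):
        assert translate_cds({"a": "ATGNNN"})["a"] == "MX"

    def test_resolvable_ambiguity_translates(self):
        # GGN is glycine whatever N is
        assert translate_cds({"a": "GGN"})["a"] == "G"

    def test_gap_codon_is_gap(self):
        assert translate_cds({"a": "ATG---"})["a"] == "M-"

    def test_partial_gap_codon_is_x(self):
        assert translate_cds({"a": "ATGA--"})["a"] == "MX"

    def test_internal_stop_names_taxon_and_index(self):
        with pytest.raises(ValueError, match="'tax1' at codon index 1"):
            translate_cds({"tax1": "ATGTAAAAA"})

    def test_length_not_multiple_of_three(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            translate_cds({"a": "ATGA"})


class TestPartitionedAlignment:
    def test_unequal_rows_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            PartitionedAlignment({"a": "ACGT", "b": "ACG"}, [Gene("g", "rrna", 0, 4)])

    def test_spans_must_partition(self):
        with pytest.raises(ValueError, match="partition"):
            PartitionedAlignment({"a": "ACGTAC"}, [Gene("g1", "rrna", 0, 4),
                                                   Gene("g2", "rrna", 3, 6)])

    def test_coding_span_must_be_codon_multiple(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            PartitionedAlignment({"a": "ACGTA"}, [Gene("g", "coding", 0, 5)])

    def test_fasta_round_trip(self, tmp_path):
        aln = PartitionedAlignment({"a": "ACGTAC", "b": "ACGTTC"},
                                   [Gene("g", "rrna", 0, 6)])
        path = tmp_path / "a.fasta"
        aln.to_fasta(str(path))
        back = PartitionedAlignment.from_fasta(str(path), aln.genes)
        assert back.sequences == aln.sequences

    def test_phylip_round_trip(self, tmp_path):
        aln = PartitionedAlignment({"tax one": "ACGTAC", "b": "ACGTTC"},
                                   [Gene("g", "rrna", 0, 6)])
        path = tmp_path / "a.phy"
        aln.to_phylip(str(path))
        back = PartitionedAlignment.from_phylip(str(path), aln.genes)
        assert back.sequences["tax_one"] == "ACGTAC"

    def test_nexus_mixed_writer(self, tmp_path, small_tree):
        sim = simulate_multigene_alignment(
            small_tree, GtrGammaParams(alpha=0.5, branch_scale=0.004, **JC),
            n_coding=1, n_rrna=1, coding_len=30, rrna_len=20, seed=1,
        )
        from odontree.satred import _translate_alignment

        ds2 = _translate_alignment(sim.alignment)
        path = tmp_path / "m.nex"
        ds2.to_nexus(str(path))
        text = path.read_text()
        assert "DATATYPE=MIXED(PROTEIN:1-10,DNA:11-30)" in text
        assert "CHARSET rrna1 = 11-30;" in text


class TestGtrGammaFit:
    def test_jukes_cantor_recovery(self, small_tree):
        params = GtrGammaParams(alpha=5.0, branch_scale=0.003, **JC)
        sim = simulate_sites(small_tree, params, 4000, seed=3)
        fit = fit_gtr_gamma(sim.alignment, small_tree, K=4)
        ex = fit.exchangeabilities
        assert ex.max() / ex.min() < 1.6  # all within ~equal under JC truth
        assert fit.branch_scale == pytest.approx(0.003, rel=0.25)

    def test_alpha_recovery(self, small_tree):
        params = GtrGammaParams(alpha=0.3, branch_scale=0.004, **JC)
        sim = simulate_sites(small_tree, params, 5000, seed=5)
        fit = fit_gtr_gamma(sim.alignment, small_tree, K=10)
        assert fit.alpha == pytest.approx(0.3, rel=0.2)

    def test_fit_at_least_as_good_as_truth(self, small_tree):
        from odontree.satred import GtrGammaSiteClassifier

        params = GtrGammaParams(alpha=0.5, branch_scale=0.004, **JC)
        sim = simulate_sites(small_tree, params, 1500, seed=7)
        clf = GtrGammaSiteClassifier(K=10)
        clf.fit(sim.alignment, small_tree)
        rows = sim.alignment.sequences
        true_params = GtrGammaParams(alpha=0.5, branch_scale=0.004, **JC)
        truth_ll = clf._loglik(
            clf.tree_index_,
            __import__("odontree.satred", fromlist=["_column_tensor"])._column_tensor(
                rows, clf.taxa_
            ),
            np.ones(sim.alignment.n_columns),
            true_params,
        )
        assert clf.log_likelihood_ >= truth_ll - 1e-6

    def test_substitution_branch_length_tree_supported(self, small_tree):
        """Classification under a supplied substitution-length tree matches
        classification under the chronogram it was derived from."""
        from odontree.satred import GtrGammaSiteClassifier, substitution_tree_index

        params = GtrGammaParams(alpha=0.4, branch_scale=0.005, **JC)
        sim = simulate_sites(small_tree, params, 200, seed=31)
        # substitution-scaled copy of the chronogram, scale folded in
        def scaled_newick(node):
            if node.is_tip:
                core = node.label
            else:
                core = "(" + ",".join(scaled_newick(c) for c in node.children) + ")"
            bl = 0.0 if node.parent is None else (node.parent.age - node.age) * 0.005
            return f"{core}:{bl:.10f}"
        sub_idx = substitution_tree_index(scaled_newick(small_tree.root) + ";")

        unit = GtrGammaParams(alpha=0.4, branch_scale=1.0, **JC)
        clf_sub = GtrGammaSiteClassifier(K=10)
        clf_sub.taxa_ = list(sub_idx.tip_rows)
        clf_sub.tree_index_ = sub_idx
        clf_sub._taxon_pos = {t: i for i, t in enumerate(clf_sub.taxa_)}
        clf_sub.params_ = unit
        post_sub = clf_sub.predict_proba(sim.alignment)

        from odontree.satred import assign_site_categories

        base = assign_site_categories(sim.alignment, small_tree, params=params, K=10)
        assert np.allclose(post_sub, base.posterior, atol=1e-8)

    def test_too_few_taxa_rejected(self, small_tree):
        rows = {t: "ACGT" for t in small_tree.tip_labels[:3]}
        with pytest.raises(ValueError, match="at least 4"):
            fit_gtr_gamma(rows, small_tree)


@pytest.fixture(scope="module")
def assigned(small_tree):
    params = GtrGammaParams(alpha=0.4, branch_scale=0.005, **JC)
    sim = simulate_sites(small_tree, params, 600, seed=9)
    assignment = assign_site_categories(
        sim.alignment, small_tree, params=params, K=10
    )
    return sim, assignment


class TestAssignment:
    def test_posteriors_sum_to_one(self, assigned):
        _, assignment = assigned
        assert np.allclose(assignment.posterior.sum(axis=1), 1.0, atol=1e-9)

    def test_assigned_is_argmax_with_low_ties(self, assigned):
        _, assignment = assigned
        assert np.array_equal(
            assignment.categories, np.argmax(assignment.posterior, axis=1) + 1
        )

    def test_invariant_columns_assigned_slowest(self, assigned):
        sim, assignment = assigned
        seqs = list(sim.alignment.sequences.values())
        for i in range(sim.alignment.n_columns):
            column = {s[i] for s in seqs}
            if len(column) == 1 and column <= set("ACGT"):
                assert assignment.categories[i] == 1

    def test_duplicating_identical_taxon_leaves_posteriors_stable(self, small_tree):
        """Attaching an identical copy of a sequence on a ~zero branch
        multiplies every site likelihood by ~1 per category and must not
        change the category posteriors."""
        from odontree.treeio import Node, Chronogram

        params = GtrGammaParams(alpha=0.4, branch_scale=0.005, **JC)
        sim = simulate_sites(small_tree, params, 150, seed=13)
        base = assign_site_categories(sim.alignment, small_tree, params=params, K=10)

        dup_tree = small_tree.copy()
        victim = dup_tree.tips()[0]
        label = victim.label
        eps = 1e-7
        victim.label = None
        victim.age = eps
        victim.add_child(Node(label, 0.0))
        victim.add_child(Node(label + "_copy", 0.0))
        dup_tree = Chronogram(dup_tree.root)
        rows = dict(sim.alignment.sequences)
        rows[label + "_copy"] = rows[label]
        dup_aln = PartitionedAlignment(rows, [Gene("rrna1", "rrna", 0, 150)])
        dup = assign_site_categories(dup_aln, dup_tree, params=params, K=10)
        assert np.allclose(dup.posterior, base.posterior, atol=1e-4)
        assert np.array_equal(dup.categories, base.categories)

    def test_rate_monotonicity_in_aggregate(self, assigned):
        sim, assignment = assigned
        means = [
            assignment.categories[sim.true_categories == c].mean()
            for c in (1, 4, 7, 10)
            if np.any(sim.true_categories == c)
        ]
        assert all(b >= a for a, b in zip(means, means[1:]))


class TestRemoveCategories:
    def make_toy(self):
        aln = PartitionedAlignment(
            {"a": "AAACCCGGG", "b": "AAACCCGGT", "c": "AAACCTGGT", "d": "ACACCTGGT"},
            [Gene("r1", "rrna", 0, 9)],
        )
        post = np.zeros((9, 10))
        cats = np.array([1, 10, 1, 2, 10, 2, 3, 10, 3])
        post[np.arange(9), cats - 1] = 1.0
        from odontree.satred import SiteRateAssignment

        assignment = SiteRateAssignment(
            posterior=post, categories=cats, columns=np.arange(9),
            genes=np.array(["r1"] * 9), K=10,
        )
        return aln, assignment

    def test_empty_drop_is_noop(self):
        aln, assignment = self.make_toy()
        reduced, frac = remove_categories(aln, assignment, set())
        assert reduced.sequences == aln.sequences
        assert frac == 0.0

    def test_exact_column_bookkeeping(self):
        aln, assignment = self.make_toy()
        reduced, frac = remove_categories(aln, assignment, {10})
        assert reduced.n_columns == 6
        assert frac == pytest.approx(3 / 9)
        assert reduced.sequences["a"] == "AACCGG"

    def test_bad_category_rejected(self):
        aln, assignment = self.make_toy()
        with pytest.raises(ValueError, match="1..10"):
            remove_categories(aln, assignment, {11})


@pytest.fixture(scope="module")
def series(small_tree):
    params = GtrGammaParams(alpha=0.4, branch_scale=0.005, **JC)
    sim = simulate_multigene_alignment(
        small_tree, params, n_coding=6, n_rrna=4,
        coding_len=60, rrna_len=50, seed=23,
    )
    return sim, build_ds_series(sim.alignment, small_tree, K=10, params=params)


class TestDsSeries:
    def test_coding_columns_reduced_three_to_one(self, series):
        sim, ds = series
        coding_nt = sum(g.length for g in sim.alignment.genes if g.kind == "coding")
        coding_aa = sum(g.length for g in ds.ds2.genes if g.kind == "aa")
        assert coding_aa == coding_nt // 3
        rrna_nt = sum(g.length for g in sim.alignment.genes if g.kind == "rrna")
        assert sum(g.length for g in ds.ds2.genes if g.kind == "rrna") == rrna_nt

    def test_nested_column_subsets(self, series):
        _, ds = series
        def rrna_cols(aln):
            out = set()
            for g in aln.genes:
                if g.kind == "rrna":
                    rows = aln.gene_rows(g)
                    for i in range(g.length):
                        out.add((g.name, "".join(r[i] for r in rows.values())))
            return out
        c2, c3, c4 = map(rrna_cols, (ds.ds2, ds.ds3, ds.ds4))
        assert c4 <= c3 <= c2

    def test_manifest_recount_matches_fractions(self, series):
        _, ds = series
        n = len(ds.manifest)
        assert ds.removal_fractions["ds3"] == pytest.approx(
            ds.manifest["dropped_in_ds3"].sum() / n
        )
        assert ds.removal_fractions["ds4"] == pytest.approx(
            ds.manifest["dropped_in_ds4"].sum() / n
        )

    def test_manifest_lossless_reconstruction(self, series):
        """DS2 rRNA columns = DS3 rRNA columns + manifest-dropped columns."""
        _, ds = series
        taxa = ds.ds2.taxa
        dropped = set(ds.manifest.loc[ds.manifest.dropped_in_ds3, "column_ds2"])
        for g2 in ds.ds2.genes:
            if g2.kind != "rrna":
                continue
            g3 = ds.ds3.gene(g2.name)
            kept_iter = iter(range(g3.length))
            for off in range(g2.length):
                col2 = g2.start + off
                col_text = "".join(ds.ds2.sequences[t][col2] for t in taxa)
                if col2 in dropped:
                    continue
                off3 = next(kept_iter)
                col3_text = "".join(
                    ds.ds3.sequences[t][g3.start + off3] for t in taxa
                )
                assert col_text == col3_text
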