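import numpy as np
import pytest

from rnasefam.family_analysis import (InsufficientDataError, OrthologSet,
                                      assign_lineage, build_ortholog_pairs,
                                      build_ortholog_set,
                                      detect_gene_sorting,
                                      detect_paralog_groups,
                                      saturation_profile, selection_summary)
from rnasefam.gene_models import GeneCall, classify_gene, translate
from rnasefam.phylo import parse_newick
from rnasefam.seq_io import SeqRecord
from rnasefam.synthetic_data import (evolve_codon_sequence,
                                     make_root_sequence)

from conftest import aligned_family, simulated_group, ungapped_alignment


def _call(gene_id, cds):
    sp, label = gene_id.split("-", 1)
    return classify_gene(SeqRecord(gene_id, sp, label, cds))


class TestAssignLineage:
    def test_reference_sequences_self_match(self):
        rng = np.random.default_rng(1)
        cds_a = make_root_sequence(rng, 130)
        cds_b = evolve_codon_sequence(cds_a, 1.2, 0.8, 2.0, 3)
        refs = {"RNase4": translate(cds_a)[:-1], "RNase5": translate(cds_b)[:-1]}
        call = _call("Bt-RNase4", cds_a)
        assert assign_lineage([call], refs)[call.record.id] == "RNase4"

    def test_unrelated_sequence_falls_to_others(self):
        refs = {"RNase4": "MKETAAAKFERQHMDSSTSAA" * 3}
        junk = _call("Oa-RNase35", "ATG" + "GGGCCCTTTAAG" * 11 + "TAA")
        with pytest.warns(UserWarning, match="Others"):
            out = assign_lineage([junk], refs, min_relative_score=0.5)
        assert out[junk.record.id] == "Others"

    def test_empty_reference_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            assign_lineage([], {})


class TestOrthologSets:
    @pytest.mark.parametrize("n,expected", [(18, 153), (13, 78), (1, 0)])
    def test_pair_counts(self, n, expected):
        members = {f"S{k}": f"S{k}-RNase1" for k in range(n)}
        oset = OrthologSet(lineage="RNase1", members=members, seed=0)
        if n < 2:
            with pytest.warns(UserWarning):
                pairs = build_ortholog_pairs(oset)
        else:
            pairs = build_ortholog_pairs(oset)
        assert len(pairs) == expected

    def test_choice_is_seeded_and_reproducible(self):
        calls = [_call(f"Ml-RNase1{c}", make_root_sequence(
            np.random.default_rng(3), 130)) for c in "ABC"]
        lineage_map = {c.record.id: "RNase1" for c in calls}
        a = build_ortholog_set(calls, lineage_map, "RNase1", seed=5)
        b = build_ortholog_set(calls, lineage_map, "RNase1", seed=5)
        assert a.members == b.members

    def test_choice_among_co_orthologs_barely_moves_the_mean_ratio(self):
        """Recent duplicates are nearly interchangeable: whichever
        co-ortholog is chosen, group mean dN/dS shifts by < 0.05."""
        rng = np.random.default_rng(8)
        anc = make_root_sequence(rng, 300)
        # two species; species X has two very recent co-orthologs
        deep_a = evolve_codon_sequence(anc, 0.10, 0.6, 2.0, 21)
        deep_b = evolve_codon_sequence(anc, 0.10, 0.6, 2.0, 22)
        co1 = evolve_codon_sequence(deep_a, 0.004, 0.6, 2.0, 23)
        co2 = evolve_codon_sequence(deep_a, 0.004, 0.6, 2.0, 24)
        ratios = []
        for chosen in (co1, co2):
            seqs = {"Xx-RNase1A": chosen, "Yy-RNase1A": deep_b}
            aln = ungapped_alignment(seqs)
            summary = selection_summary("set", list(seqs), aln,
                                        replicates=50, seed=0)
            ratios.append(summary.mean_ratio)
        assert abs(ratios[0] - ratios[1]) < 0.05


class TestParalogGroups:
    TREE = ("(((Ml-RNase1A:1,(Ml-RNase1B:1,Ml-RNase1C:1):1):1,"
            "(Bt-RNase1A:1,Bt-RNase1B:1):2):1,Hs-RNase1:3);")

    def species_of(self, tree):
        return {t: t.split("-")[0] for t in tree.tip_labels()}

    def test_species_specific_clades_found(self):
        tree = parse_newick(self.TREE)
        groups = detect_paralog_groups(tree, self.species_of(tree),
                                       lineage="RNase1", outgroup="Hs-RNase1")
        by_species = {g.species: g.n for g in groups}
        assert by_species == {"Ml": 3, "Bt": 2}
        ml = next(g for g in groups if g.species == "Ml")
        assert ml.pair_count == 3

    def test_all_singletons_give_no_groups(self):
        tree = parse_newick("((A-g:1,B-g:1):1,(C-g:1,Hs-g:2):1);")
        groups = detect_paralog_groups(tree, self.species_of(tree),
                                       outgroup="Hs-g")
        assert groups == []

    def test_pseudogenes_tolerated_inside_but_not_counted(self):
        tree = parse_newick("(((Ml-RNase5A:1,Ml-RNase5Bps:1):1,"
                            "Ml-RNase5C:2):1,Hs-RNase5:3);")
        groups = detect_paralog_groups(tree, self.species_of(tree),
                                       lineage="RNase5", outgroup="Hs-RNase5")
        assert len(groups) == 1
        assert groups[0].members == ["Ml-RNase5A", "Ml-RNase5C"]

    def test_two_member_group(self):
        tree = parse_newick("((Cp-RNase4A:0.01,Cp-RNase4B:0.01):1,Hs-RNase4:1);")
        groups = detect_paralog_groups(tree, self.species_of(tree),
                                       lineage="RNase4", outgroup="Hs-RNase4")
        assert [g.n for g in groups] == [2]


class TestGeneSorting:
    def test_interleaved_species_detected(self):
        tree = parse_newick("(((Hg-RNase6A:1,Cp-RNase6A:1):1,"
                            "(Hg-RNase6B:1,Cp-RNase6Bps:1):1):1,Hs-RNase6:3);")
        species_of = {t: t.split("-")[0] for t in tree.tip_labels()}
        sorted_, info = detect_gene_sorting(tree, ("Hg", "Cp"), species_of,
                                            outgroup="Hs-RNase6")
        assert sorted_
        assert not info["monophyletic"]["Hg"]

    def test_clean_species_clades_are_not_gene_sorting(self):
        tree = parse_newick("(((A-g1:1,A-g2:1):1,(B-g1:1,B-g2:1):1):1,Hs-g:3);")
        species_of = {t: t.split("-")[0] for t in tree.tip_labels()}
        sorted_, _ = detect_gene_sorting(tree, ("A", "B"), species_of,
                                         outgroup="Hs-g")
        assert not sorted_

    def test_species_missing_from_tree_rejected(self):
        tree = parse_newick("((A-g1:1,A-g2:1):1,Hs-g:3);")
        species_of = {t: t.split("-")[0] for t in tree.tip_labels()}
        with pytest.raises(ValueError, match=">= 2 tips"):
            detect_gene_sorting(tree, ("A", "Zz"), species_of, outgroup="Hs-g")


class TestSelectionSummary:
    def test_identical_sequences_have_undefined_ratio(self):
        cds = make_root_sequence(np.random.default_rng(2), 130)
        seqs = {f"Xx-RNase1{c}": cds for c in "ABC"}
        aln = aligned_family(seqs)
        s = selection_summary("g", list(seqs), aln, replicates=50, seed=0)
        assert s.mean_dS == s.mean_dN == 0.0
        assert s.mean_ratio is None
        assert s.pairs_gt1 == 0

    def test_two_member_group_has_no_pvalue(self):
        seqs = simulated_group(0.8, seed=31, n=2)
        aln = aligned_family(seqs)
        s = selection_summary("g", list(seqs), aln, replicates=50, seed=0)
        assert s.total_pairs == 1
        assert s.p_value is None

    def test_pair_count_and_order_invariance(self):
        seqs = simulated_group(0.8, seed=32, n=5)
        aln = aligned_family(seqs)
        ids = list(seqs)
        s1 = selection_summary("g", ids, aln, replicates=60, seed=4)
        s2 = selection_summary("g", list(reversed(ids)), aln,
                               replicates=60, seed=4)
        assert s1.total_pairs == s2.total_pairs == 10
        assert s1.mean_dS == pytest.approx(s2.mean_dS)
        assert s1.mean_ratio == pytest.approx(s2.mean_ratio)

    def test_positive_and_purifying_groups_separate(self):
        """omega = 2.0 vs 0.3 groups: mean ratios separated by more than
        three combined standard errors of the pairwise ratios."""
        hi = selection_summary("hi", *_group_aln(2.0, 41), replicates=200,
                               seed=1)
        lo = selection_summary("lo", *_group_aln(0.3, 42), replicates=200,
                               seed=2)
        assert hi.mean_ratio > 1.0 > lo.mean_ratio
        se_hi = _ratio_se(hi)
        se_lo = _ratio_se(lo)
        assert hi.mean_ratio - lo.mean_ratio > 3 * (se_hi + se_lo)
        assert hi.p_value < 0.05
        assert hi.pairs_gt1 > hi.total_pairs / 2

    def test_seeded_bootstrap_determinism(self):
        seqs = simulated_group(1.0, seed=33, n=4)
        aln = aligned_family(seqs)
        a = selection_summary("g", list(seqs), aln, replicates=80, seed=7)
        b = selection_summary("g", list(seqs), aln, replicates=80, seed=7)
        assert (a.se_dS, a.se_dN) == (b.se_dS, b.se_dN)


def _group_aln(omega, seed, n=6):
    seqs = simulated_group(omega, seed=seed, n=n)
    return list(seqs), ungapped_alignment(seqs)


def _ratio_se(summary):
    ratios = [e.ratio for e in summary.pair_estimates if e.ratio is not None]
    return float(np.std(ratios, ddof=1) / np.sqrt(len(ratios)))


class TestSaturationProfile:
    def test_constant_omega_shows_no_plateau(self):
        rng = np.random.default_rng(6)
        dS = np.sort(rng.uniform(0.02, 0.5, size=40))
        dN = 0.5 * dS + rng.normal(0, 0.01, size=40)
        prof = saturation_profile(list(zip(dS, dN)), lineage="RNase6")
        assert not prof.plateau_detected

    def test_piecewise_flat_regime_detected_near_its_breakpoint(self):
        rng = np.random.default_rng(7)
        dS = np.sort(rng.uniform(0.02, 0.5, size=60))
        dN = np.where(dS < 0.2, 0.6 * dS, 0.12) + rng.normal(0, 0.004, 60)
        prof = saturation_profile(list(zip(dS, dN)), lineage="RNase4")
        assert prof.plateau_detected
        assert prof.plateau_onset_dS == pytest.approx(0.2, abs=0.08)

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError, match=">= 10"):
            saturation_profile([(0.1, 0.05), (0.2, 0.1), (0.3, 0.12)])
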