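"""Loss-pattern rule tables, linear-vs-branched resolution, tetrasaccharide
classification and decisive-ion acquisition plans."""

import itertools

import pytest

from oligoms.fragments import sodiated_mz
from oligoms.rules import (LossPattern, LinkageHypothesis,
                           PatternInconsistentError,
                           UndeterminedTopologyError, all_hypotheses,
                           classify_tetrasaccharide, decisive_ion_plan,
                           expected_loss_set, reducing_linkage_candidates,
                           resolve_linear_vs_branched)


def keys(hyps):
    return {(h.topology, h.reducing_linkages) for h in hyps}


class TestCandidates:
    def test_dehydration_plus_60_is_the_documented_ambiguity(self):
        hyps = reducing_linkage_candidates(LossPattern(frozenset({18, 60})), 3)
        assert keys(hyps) == {("linear", (4,)), ("branched", (6, 4))}

    def test_full_ladder_means_1_6(self):
        hyps = reducing_linkage_candidates(
            LossPattern(frozenset({18, 60, 90, 120})), 3)
        assert keys(hyps) == {("linear", (6,))}

    def test_no_major_losses_means_1_2(self):
        hyps = reducing_linkage_candidates(LossPattern(frozenset()), 3)
        assert keys(hyps) == {("linear", (2,))}
        assert any("minor" in c for c in hyps[0].caveats)

    def test_inconsistent_pattern_raises(self):
        with pytest.raises(PatternInconsistentError):
            reducing_linkage_candidates(LossPattern(frozenset({120})), 3)

    def test_unsupported_residue_count(self):
        with pytest.raises(ValueError):
            reducing_linkage_candidates(LossPattern(frozenset({18})), 6)

    def test_loss_alphabet_enforced(self):
        with pytest.raises(ValueError):
            LossPattern(frozenset({42}))

    def test_table_collisions_are_exactly_the_known_ones(self):
        """The pattern table is injective apart from three collisions: the
        documented linear(1→4)/branched(1→6,1→4) pair plus the analogous
        linear(1→3)/branched(1→6,1→3) and (1→6,1→2)/(1→4,1→2) pairs."""
        by_pattern = {}
        for h in all_hypotheses():
            e = expected_loss_set(h.topology, h.reducing_linkages)
            by_pattern.setdefault(e, []).append(
                (h.topology, h.reducing_linkages))
        collisions = {frozenset(v) for v in by_pattern.values() if len(v) > 1}
        assert collisions == {
            frozenset({("linear", (4,)), ("branched", (6, 4))}),
            frozenset({("linear", (3,)), ("branched", (6, 3))}),
            frozenset({("branched", (6, 2)), ("branched", (4, 2))}),
        }


class TestResolve:
    def _cands(self):
        return [LinkageHypothesis("linear", (4,)),
                LinkageHypothesis("branched", (6, 4))]

    def test_365_in_dehydration_route_means_linear(self):
        out = resolve_linear_vs_branched(
            LossPattern(ion_flags=((365, True),)), None, 3, self._cands())
        assert len(out) == 1 and out[0].topology == "linear"
        assert out[0].status == "confirmed"

    def test_347_in_crossring_route_means_linear(self):
        out = resolve_linear_vs_branched(
            None, LossPattern(ion_flags=((347, True), (365, False))), 3,
            self._cands())
        assert len(out) == 1 and out[0].topology == "linear"

    def test_absence_everywhere_means_branched(self):
        out = resolve_linear_vs_branched(
            LossPattern(ion_flags=((365, False),)),
            LossPattern(ion_flags=((347, False), (365, False))), 3,
            self._cands())
        assert len(out) == 1 and out[0].topology == "branched"

    def test_contradiction_keeps_both_with_warning(self):
        out = resolve_linear_vs_branched(
            LossPattern(ion_flags=((365, True),)),
            LossPattern(ion_flags=((347, False), (365, False))), 3,
            self._cands())
        assert len(out) == 2
        assert all(any("contradictory" in c for c in h.caveats) for h in out)

    def test_status_transitions_guarded(self):
        h = LinkageHypothesis("linear", (4,))
        h.set_status("confirmed")
        with pytest.raises(ValueError):
            h.set_status("excluded")


class TestClassifyTetrasaccharide:
    def _ms2(self, disacch: bool):
        return LossPattern(frozenset({18, 60}),
                           ((365, disacch), (347, disacch)))

    def _loss(self, trisacch: bool):
        return {629: LossPattern(ion_flags=((527, trisacch),
                                            (509, trisacch)))}

    @pytest.mark.parametrize("disacch,trisacch,expected", [
        (True, True, "I"), (True, False, "II"),
        (False, True, "III"), (False, False, "IV"),
    ])
    def test_four_way_decision(self, disacch, trisacch, expected):
        k = classify_tetrasaccharide(self._ms2(disacch), self._loss(trisacch))
        assert k.roman == expected

    def test_missing_spectra_raise_undetermined(self):
        with pytest.raises(UndeterminedTopologyError) as exc:
            classify_tetrasaccharide(LossPattern(frozenset({18})), {})
        assert exc.value.missing

    def test_classifies_all_simulated_topologies(self, model):
        """Decision-tree walk on simulator output for one representative of
        each 1→2-free tetrasaccharide topology class."""
        from oligoms.simulate import simulate_tree
        from oligoms.spectra import bin_nominal
        from oligoms.structures import parse_structure

        reps = {
            "I": "β-Glc-(1→4)-β-Glc-(1→4)-β-Glc-(1→4)-Glc",
            "II": "α-Glc-(1→6)-α-Glc-(1→4)-[β-Glc-(1→6)]-Glc",
            "III": "α-Glc-(1→4)-[α-Glc-(1→6)]-β-Glc-(1→4)-Glc",
            "IV": "α-Glc-(1→3)-[α-Glc-(1→4)]-[α-Glc-(1→6)]-Glc",
        }
        for expected, s in reps.items():
            g = parse_structure(s)
            tree = simulate_tree(g, model=model)
            ms2 = tree.get((689,))
            pattern = LossPattern.from_spectrum(ms2, 689, (365, 347), 0.06)
            loss_patterns = {}
            for l in (18, 60, 90, 120):
                L = 689 - l
                if bin_nominal(ms2).get(L, 0.0) >= 0.01:
                    spec = tree.get((689, L))
                    if spec is not None and not spec.is_empty():
                        loss_patterns[L] = LossPattern.from_spectrum(
                            spec, L, (527, 509, 365, 347), 0.06)
            k = classify_tetrasaccharide(pattern, loss_patterns)
            assert k.roman == expected, (s, k)


class TestPlans:
    def test_trisaccharide_plan_contains_decisive_paths(self):
        plan = decisive_ion_plan(3)
        assert {(527,), (527, 509), (527, 509, 365), (527, 467),
                (527, 467, 365), (527, 365)} <= plan.paths

    def test_tetrasaccharide_plan_contains_decisive_paths(self):
        plan = decisive_ion_plan(4, 689)
        assert {(689, 629, 365), (689, 629, 467, 365)} <= plan.paths

    def test_disaccharide_plan_is_single_step(self):
        plan = decisive_ion_plan(2)
        assert plan.paths == {(365,)}

    def test_wrong_parent_mass_rejected(self):
        with pytest.raises(ValueError):
            decisive_ion_plan(3, 528)
        with pytest.raises(ValueError):
            decisive_ion_plan(6)

    def test_plan_paths_are_mass_producible(self):
        """Every m/z in every plan path lies on the sodiated ladder of some
        k-mer with an allowed loss, and each step loses mass."""
        ladder = {sodiated_mz(k, loss)[1]
                  for k in range(1, 6)
                  for loss in ("none", "H2O", "C2H4O2", "C3H6O3", "C4H8O4")
                  if k * 162 + 41 > 140}
        for n in (2, 3, 4, 5):
            plan = decisive_ion_plan(n)
            for path in plan.paths:
                assert all(mz in ladder for mz in path), path
                assert all(a > b for a, b in zip(path, path[1:])), path

    def test_exports(self, tmp_path):
        import json
        plan = decisive_ion_plan(3)
        data = json.loads(plan.to_json())
        assert data["parent_mz"] == 527
        text = plan.to_text()
        assert "527→509→365" in text
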