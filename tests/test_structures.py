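"""Structure model: parsing, canonical serialisation, topology census."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from oligoms.structures import (Anomer, GlycanParseError, GlycanStructure,
                                GlycanValidityError, Linkage, Residue,
                                disaccharide, enumerate_topologies,
                                linear_chain, parse_structure,
                                serialise_structure)


class TestParsing:
    def test_panose_string(self):
        g = parse_structure("α-Glc-(1→6)-α-Glc-(1→4)-Glc")
        assert g.size == 3 and g.is_linear
        assert g.root_anomeric == Anomer.UNSPECIFIED
        chain = g.chain()
        assert [(lk.child_anomeric, lk.position) for lk, _ in chain] == [
            (Anomer.ALPHA, 4), (Anomer.ALPHA, 6)]

    def test_monosaccharide(self):
        g = parse_structure("Glc")
        assert g.size == 1 and g.root.children == ()

    def test_isopanose_branch(self):
        g = parse_structure("α-Glc-(1→4)-[α-Glc-(1→6)]-Glc")
        assert g.size == 3 and not g.is_linear
        assert g.reducing_positions == frozenset({4, 6})
        assert all(lk.child_anomeric == Anomer.ALPHA
                   for lk, _ in g.root.children)

    @pytest.mark.parametrize("ascii_form,pretty", [
        ("a-Glc-(1-6)-a-Glc-(1-4)-Glc", "α-Glc-(1→6)-α-Glc-(1→4)-Glc"),
        ("b-Glc-(1->3)-b-Glc-(1->4)-Glc", "β-Glc-(1→3)-β-Glc-(1→4)-Glc"),
        ("alpha-Glc-(1-4)-[alpha-Glc-(1-6)]-Glc",
         "α-Glc-(1→4)-[α-Glc-(1→6)]-Glc"),
    ])
    def test_ascii_aliases_accepted_never_emitted(self, ascii_form, pretty):
        g = parse_structure(ascii_form)
        assert serialise_structure(g) == pretty

    @pytest.mark.parametrize("bad", [
        "", "Glc-(1→4)", "Glx", "α-Glc-(1→5)-Glc",
        "α-Glc-(1→4)-[α-Glc-(1→6)]", "[α-Glc-(1→6)]-",
        "α-Glc--(1→4)-Glc-junk",
    ])
    def test_malformed_strings_rejected(self, bad):
        with pytest.raises((GlycanParseError, GlycanValidityError)):
            parse_structure(bad)

    def test_duplicate_acceptor_position_rejected(self):
        with pytest.raises(GlycanValidityError, match="duplicate"):
            parse_structure("α-Glc-(1→4)-[α-Glc-(1→4)]-Glc")

    def test_1_1_linkage_representable_but_flagged(self):
        g = parse_structure("α-Glc-(1→1)-Glc")
        assert g.has_1_1_linkage()


class TestSerialisation:
    @pytest.mark.parametrize("s", [
        "Glc",
        "α-Glc-(1→6)-α-Glc-(1→4)-Glc",
        "α-Glc-(1→4)-[α-Glc-(1→6)]-Glc",
        "β-Glc-(1→4)-β-Glc-(1→4)-β-Glc-(1→4)-Glc",
    ])
    def test_canonical_examples(self, s):
        assert serialise_structure(parse_structure(s)) == s

    def test_branch_order_lowest_position_continues_chain(self):
        # same tree written branch-first must canonicalise to bracketed 1→6
        g = parse_structure("α-Glc-(1→6)-[β-Glc-(1→4)]-Glc")
        assert serialise_structure(g) == "β-Glc-(1→4)-[α-Glc-(1→6)]-Glc"


def _all_structures(max_n):
    """Exhaustive panel of rooted glucose trees with <= max_n residues."""
    anomers = (Anomer.ALPHA, Anomer.BETA, Anomer.UNSPECIFIED)

    def residues(n):
        if n == 1:
            yield Residue()
            return
        for k in (1, 2, 3):
            for sizes in _compositions(n - 1, k):
                pools = [list(residues(s)) for s in sizes]
                for kids in itertools.product(*pools):
                    for pos in itertools.permutations((2, 3, 4, 6), k):
                        for anoms in itertools.product((Anomer.ALPHA,
                                                        Anomer.BETA), repeat=k):
                            try:
                                yield Residue(children=tuple(
                                    (Linkage(a, p), c)
                                    for a, p, c in zip(anoms, pos, kids)))
                            except GlycanValidityError:
                                pass

    def _compositions(total, k):
        if k == 1:
            yield (total,)
            return
        for first in range(1, total - k + 2):
            for rest in _compositions(total - first, k - 1):
                yield (first,) + rest

    for n in range(1, max_n + 1):
        for root in residues(n):
            for ra in anomers[:1] + anomers[2:]:  # α and unspecified roots
                yield GlycanStructure(root, ra)


def test_parse_serialise_round_trip_exhaustive_small():
    count = 0
    for g in _all_structures(3):
        assert parse_structure(serialise_structure(g)) == g
        count += 1
    assert count > 100


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.data())
def test_parse_serialise_round_trip_random_4mers(data):
    def tree(n):
        if n == 1:
            return Residue()
        k = data.draw(st.integers(1, min(3, n - 1)))
        sizes = []
        left = n - 1
        for i in range(k):
            s = left - (k - 1 - i) if i == k - 1 else data.draw(
                st.integers(1, left - (k - 1 - i)))
            sizes.append(s)
            left -= s
        pos = data.draw(st.permutations([2, 3, 4, 6]))[:k]
        kids = []
        for s, p in zip(sizes, pos):
            a = data.draw(st.sampled_from([Anomer.ALPHA, Anomer.BETA]))
            kids.append((Linkage(a, p), tree(s)))
        return Residue(children=tuple(kids))

    n = data.draw(st.integers(1, 4))
    g = GlycanStructure(tree(n), data.draw(st.sampled_from(
        [Anomer.ALPHA, Anomer.BETA, Anomer.UNSPECIFIED])))
    assert parse_structure(serialise_structure(g)) == g


# --- topology census ---------------------------------------------------------

def _oracle_shapes(n):
    """Independent brute force: canonicalise all parent arrays p[i] < i."""
    def canon(children_of, node):
        return tuple(sorted(canon(children_of, c) for c in children_of[node]))

    shapes = set()
    for parents in itertools.product(*[range(i) for i in range(1, n)]):
        children = {i: [] for i in range(n)}
        for child, par in enumerate(parents, start=1):
            children[par].append(child)
        if any(len(v) > 3 for v in children.values()):
            continue
        shapes.add(canon(children, 0))
    return shapes


@pytest.mark.parametrize("n", range(1, 7))
def test_topology_census_matches_brute_force(n):
    got = {t.shape for t in enumerate_topologies(n)}
    assert got == _oracle_shapes(n)


def test_four_tetrasaccharide_types():
    classes = enumerate_topologies(4)
    assert len(classes) == 4
    kinds = [(c.kind, c.branch_depth) for c in classes]
    assert ("linear", None) in kinds
    assert ("branched", 0) in kinds          # branch at the reducing sugar
    assert ("branched", 1) in kinds          # branch on the nonreducing side
    assert sum(1 for k, _ in kinds if k == "branched") == 3


def test_trisaccharide_topologies():
    classes = enumerate_topologies(3)
    assert len(classes) == 2
    assert {c.kind for c in classes} == {"linear", "branched"}


def test_topology_range_check():
    with pytest.raises(ValueError):
        enumerate_topologies(0)
    with pytest.raises(ValueError):
        enumerate_topologies(7)


def test_builders():
    assert serialise_structure(disaccharide(Anomer.ALPHA, 4, Anomer.ALPHA)) \
        == "α-Glc-(1→4)-α-Glc"
    g = linear_chain([(Anomer.ALPHA, 4), (Anomer.ALPHA, 6)])
    assert serialise_structure(g) == "α-Glc-(1→6)-α-Glc-(1→4)-Glc"
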