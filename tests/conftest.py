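import itertools

import pytest

from oligoms.refdb import build_db, synth_fingerprints
from oligoms.simulate import ChannelModel
from oligoms.structures import (Anomer, GlycanStructure, Linkage, Residue,
                                linear_chain, serialise_structure)

AB = (Anomer.ALPHA, Anomer.BETA)


@pytest.fixture(scope="session")
def model():
    return ChannelModel()


@pytest.fixture(scope="session")
def db():
    return build_db(synth_fingerprints(seed=0))


def branched_trisaccharide(hi_pos, hi_anomer, lo_pos, lo_anomer):
    return GlycanStructure(Residue(children=(
        (Linkage(lo_anomer, lo_pos), Residue()),
        (Linkage(hi_anomer, hi_pos), Residue()),
    )))


def trisaccharide_panel():
    """Every linear trisaccharide over linkages {3,4,6} × anomers {α,β}² and
    every 1→2-free branched trisaccharide, with the set of acceptable
    elucidation outcomes (full recovery, or recovery up to the documented
    branch indeterminacy: the rarely-cleaved branch's anomer unread)."""
    panel = []
    for p1, p2 in itertools.product((3, 4, 6), repeat=2):
        for a1, a2 in itertools.product(AB, repeat=2):
            g = linear_chain([(a1, p1), (a2, p2)])
            panel.append((g, {serialise_structure(g)}))
    for hi, lo in ((6, 4), (6, 3), (4, 3)):
        for ahi, alo in itertools.product(AB, repeat=2):
            g = branched_trisaccharide(hi, ahi, lo, alo)
            partial = branched_trisaccharide(hi, ahi, lo, Anomer.UNSPECIFIED)
            panel.append((g, {serialise_structure(g),
                              serialise_structure(partial)}))
    return panel


def structure_panel(max_n=4):
    """Representative 1→2-free structures of 2..max_n residues (linear chains
    plus branched-at-root variants) for mass-balance style property tests."""
    out = []
    for n in range(2, max_n + 1):
        for combo in itertools.product((3, 4, 6), repeat=n - 1):
            anomers = [AB[i % 2] for i in range(n - 1)]
            out.append(linear_chain(list(zip(anomers, combo))))
    for hi, lo in ((6, 4), (6, 3), (4, 3)):
        out.append(branched_trisaccharide(hi, Anomer.ALPHA, lo, Anomer.BETA))
        if max_n >= 4:
            # branch at the reducing sugar, one branch extended
            out.append(GlycanStructure(Residue(children=(
                (Linkage(Anomer.ALPHA, lo), Residue()),
                (Linkage(Anomer.BETA, hi),
                 Residue(children=((Linkage(Anomer.ALPHA, 4), Residue()),))),
            ))))
    return out
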