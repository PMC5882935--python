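"""Sodiated fragment mass calculus for glucose oligosaccharides.

All ions are singly charged sodium adducts.  An intact k-mer is
``k·162.0528 + 18.0106 + 22.9892`` (hexose residues + one water + Na⁺), so the
nominal ladder runs 203, 365, 527, 689, … .  Glycosidic cleavage gives
Domon–Costello B/C ions (nonreducing side) and Y/Z ions (reducing side) at any
bond; dehydration (−18) and the retro-aldol cross-ring cleavages ⁰'²A (−60),
⁰'³A (−90) and ⁰'⁴A (−120) occur only at the reducing ring under the low-energy
sodiated CID mechanism, and only when the acceptor positions occupied on the
reducing sugar permit them (see :data:`LINEAR_LOSSES` / :data:`BRANCHED_LOSSES`).
"""

from __future__ import annotations

from dataclasses import dataclass

from .structures import Anomer, GlycanStructure, Residue

__all__ = [
    "HEXOSE_RESIDUE",
    "WATER",
    "SODIUM",
    "LOSS_MASS",
    "LOSS_NOMINAL",
    "LINEAR_LOSSES",
    "BRANCHED_LOSSES",
    "FragmentIon",
    "sodiated_mz",
    "allowed_losses",
    "enumerate_fragments",
    "complementarity_check",
]

# monoisotopic masses (u)
HEXOSE_RESIDUE = 162.0528
WATER = 18.0106
SODIUM = 22.9892  # Na minus one electron

LOSS_MASS: dict[str, float] = {
    "none": 0.0,
    "H2O": 18.0106,
    "C2H4O2": 60.0211,   # ⁰'²A retro-aldol loss
    "C3H6O3": 90.0317,   # ⁰'³A
    "C4H8O4": 120.0423,  # ⁰'⁴A
}
LOSS_NOMINAL: dict[str, int] = {
    "none": 0, "H2O": 18, "C2H4O2": 60, "C3H6O3": 90, "C4H8O4": 120,
}
_A_LABEL = {"C2H4O2": "0,2", "C3H6O3": "0,3", "C4H8O4": "0,4"}

# Loss channels opened by the linkage position(s) on the reducing sugar.
# Linear: one acceptor position occupied.
LINEAR_LOSSES: dict[int, frozenset[str]] = {
    1: frozenset(),
    2: frozenset(),  # kojibiose/sophorose: dehydration only as a minor channel
    3: frozenset({"H2O", "C3H6O3"}),
    4: frozenset({"H2O", "C2H4O2"}),
    6: frozenset({"H2O", "C2H4O2", "C3H6O3", "C4H8O4"}),
}
# Branched: two acceptor positions occupied on the reducing sugar.
BRANCHED_LOSSES: dict[frozenset[int], frozenset[str]] = {
    frozenset({4, 6}): frozenset({"H2O", "C2H4O2"}),
    frozenset({3, 6}): frozenset({"H2O", "C3H6O3"}),
    frozenset({3, 4}): frozenset({"H2O"}),
    frozenset({2, 6}): frozenset({"C2H4O2"}),
    frozenset({2, 4}): frozenset({"C2H4O2"}),
    frozenset({2, 3}): frozenset({"C3H6O3"}),
}
# channels the mechanism leaves open only weakly (kept below the spectrum
# threshold by the simulator, flagged minor here)
MINOR_LOSSES: dict[frozenset[int], frozenset[str]] = {
    frozenset({2}): frozenset({"H2O"}),
}


@dataclass(frozen=True)
class FragmentIon:
    """A Domon–Costello-labelled sodiated fragment."""

    label: str                      # e.g. "C2", "Y1", "0,2A3", "0,2X0", "[M+Na-H2O]+"
    mz_mono: float
    mz_nominal: int
    retained_residues: frozenset[int]   # residue ids, reducing sugar = 1
    neutral_loss: str                   # composition token or "complement"
    new_reducing_anomer: Anomer = Anomer.UNSPECIFIED
    minor: bool = False


def sodiated_mz(residue_count: int, loss: str = "none") -> tuple[float, int]:
    """(monoisotopic, nominal) m/z of a sodiated glucose k-mer minus a loss."""
    if residue_count < 1:
        raise ValueError(f"residue_count must be >= 1, got {residue_count}")
    if loss not in LOSS_MASS:
        raise ValueError(f"unknown neutral loss {loss!r}; "
                         f"expected one of {sorted(LOSS_MASS)}")
    mono = residue_count * HEXOSE_RESIDUE + WATER + SODIUM - LOSS_MASS[loss]
    if mono <= SODIUM:
        raise ValueError(f"loss {loss} heavier than the {residue_count}-mer ion")
    return mono, round(mono)


def allowed_losses(reducing_positions: frozenset[int]) -> frozenset[str]:
    """Major reducing-ring loss channels for the occupied acceptor positions."""
    if len(reducing_positions) == 0:
        return frozenset()
    if len(reducing_positions) == 1:
        (p,) = reducing_positions
        return LINEAR_LOSSES.get(p, frozenset())
    if len(reducing_positions) == 2:
        return BRANCHED_LOSSES.get(frozenset(reducing_positions), frozenset())
    # three substituents: intersection of the pairwise rules (conservative)
    pairs = [BRANCHED_LOSSES.get(frozenset(c), frozenset())
             for c in _pairs(reducing_positions)]
    out = pairs[0]
    for p in pairs[1:]:
        out &= p
    return out


def _pairs(s: frozenset[int]) -> list[tuple[int, int]]:
    items = sorted(s)
    return [(a, b) for i, a in enumerate(items) for b in items[i + 1:]]


def _number_residues(g: GlycanStructure) -> dict[int, Residue]:
    """Depth-first residue numbering; the reducing sugar is residue 1."""
    ids: dict[int, Residue] = {}
    counter = [0]

    def walk(res: Residue) -> int:
        counter[0] += 1
        ids[counter[0]] = res
        for _, child in res.children:
            walk(child)
        return counter[0]

    walk(g.root)
    return ids


def _subtree_ids(g: GlycanStructure) -> list[tuple[frozenset[int], "Linkage"]]:
    """Residue-id sets of every child subtree, paired with its linkage."""
    from .structures import Linkage  # local import to avoid cycle in typing

    out: list[tuple[frozenset[int], Linkage]] = []
    counter = [0]

    def walk(res: Residue) -> frozenset[int]:
        counter[0] += 1
        my = counter[0]
        ids = {my}
        for lk, child in res.children:
            sub = walk(child)
            out.append((frozenset(sub), lk))
            ids |= sub
        return frozenset(ids)

    walk(g.root)
    return out


def enumerate_fragments(g: GlycanStructure,
                        mechanism: str = "reducing-side") -> list[FragmentIon]:
    """Single-stage CID fragments of a sodiated glycan.

    ``mechanism="reducing-side"`` (default) applies the low-barrier constraint:
    dehydration and cross-ring cleavage only at the reducing ring, gated by the
    linkage rule table.  ``mechanism="all"`` opens every loss channel at every
    residue count (oracle mode for the subset property; no rule gating).
    """
    if mechanism not in ("reducing-side", "all"):
        raise ValueError(f"unknown mechanism {mechanism!r}")
    n = g.size
    all_ids = frozenset(range(1, n + 1))
    frags: list[FragmentIon] = []

    # glycosidic B/C/Y/Z at every bond
    for sub_ids, lk in _subtree_ids(g):
        i = len(sub_ids)
        j = n - i
        c_mono, c_nom = sodiated_mz(i, "none")
        y_mono, y_nom = sodiated_mz(j, "none")
        anom = lk.child_anomeric
        frags.append(FragmentIon(f"C{i}", c_mono, c_nom, sub_ids, "none", anom))
        frags.append(FragmentIon(f"B{i}", c_mono - WATER, round(c_mono - WATER),
                                 sub_ids, "H2O", anom))
        frags.append(FragmentIon(f"Y{j}", y_mono, y_nom, all_ids - sub_ids, "none",
                                 g.root_anomeric))
        frags.append(FragmentIon(f"Z{j}", y_mono - WATER, round(y_mono - WATER),
                                 all_ids - sub_ids, "H2O", g.root_anomeric))

    # reducing-ring losses
    positions = g.reducing_positions
    if mechanism == "all":
        open_losses = frozenset({"H2O", "C2H4O2", "C3H6O3", "C4H8O4"}) if n >= 1 else frozenset()
        minor = frozenset()
    else:
        open_losses = allowed_losses(positions)
        minor = MINOR_LOSSES.get(positions, frozenset())

    branched = len(positions) >= 2

    for loss in sorted(open_losses | minor):
        is_minor = loss in minor and loss not in open_losses
        if loss == "H2O":
            mono, nom = sodiated_mz(n, "H2O")
            frags.append(FragmentIon("[M+Na-H2O]+", mono, nom, all_ids, "H2O",
                                     minor=is_minor))
            continue
        # retro-aldol cross-ring ion: the lost neutral is ring atoms only
        # (60/90/120 u); every residue stays with the charged fragment
        mono, nom = sodiated_mz(n, loss)
        frags.append(FragmentIon(f"{_A_LABEL[loss]}A{n}", mono, nom,
                                 all_ids, loss, minor=is_minor))
        if branched:
            # complementary sodiated ring piece (low-mass diagnostic)
            x_mono = LOSS_MASS[loss] + SODIUM
            frags.append(FragmentIon(f"{_A_LABEL[loss]}X0", x_mono, round(x_mono),
                                     frozenset(), "complement", minor=is_minor))
    return frags


def complementarity_check(parent_mz: int, ion_a: FragmentIon,
                          ion_b: FragmentIon) -> tuple[bool, str]:
    """Nominal mass balance for a complementary glycosidic pair.

    C_i + Y_{n−i} = parent + 41 (extra water + Na) and
    B_i + Z_{n−i} = parent + 5 (Na − water).  A full-length B/C with an empty
    partner (Z0/Y0) is degenerate and passes by convention.
    """
    kinds = {ion_a.label[0], ion_b.label[0]}
    if ion_a.retained_residues & ion_b.retained_residues:
        return False, "fragments share residues"
    if kinds == {"C", "Y"}:
        expected = parent_mz + 41
    elif kinds == {"B", "Z"}:
        expected = parent_mz + 5
    else:
        return False, f"not a complementary pair: {ion_a.label}/{ion_b.label}"
    total = ion_a.mz_nominal + ion_b.mz_nominal
    if total == expected:
        return True, "balanced"
    return False, (f"{ion_a.label}+{ion_b.label} = {total}, "
                   f"expected {expected} for parent {parent_mz}")
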