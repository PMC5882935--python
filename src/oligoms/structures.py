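"""Glucose oligosaccharide structures and the structure-string dialect.

A glycan is modelled as a rooted tree of glucose (Glc) residues.  The root is
the reducing sugar (the residue with a free anomeric carbon); every other
residue is attached to its parent through a glycosidic bond described by a
:class:`Linkage` — the acceptor carbon on the parent (2, 3, 4 or 6; position 1
is representable for the trehalose-type 1→1 case but carries no rule support)
and the anomeric configuration (α/β) of the child's anomeric carbon.

Structure strings read nonreducing→reducing left to right,

    ``α-Glc-(1→6)-α-Glc-(1→4)-Glc``        (panose)
    ``α-Glc-(1→4)-[α-Glc-(1→6)]-Glc``      (isopanose, bracketed branch)

and the final (reducing) residue may omit its anomeric prefix because both
solution anomers coexist through mutarotation.  ASCII aliases (``a``/``b``,
``1-4``, ``1->4``) are accepted on input and never emitted.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator

__all__ = [
    "Anomer",
    "Linkage",
    "Residue",
    "GlycanStructure",
    "TopologyClass",
    "GlycanParseError",
    "GlycanValidityError",
    "parse_structure",
    "serialise_structure",
    "enumerate_topologies",
    "linear_chain",
    "disaccharide",
]

VALID_POSITIONS = frozenset({1, 2, 3, 4, 6})
MAX_CHILDREN = 3


class GlycanParseError(ValueError):
    """Malformed structure string; the message names the offending token."""


class GlycanValidityError(ValueError):
    """Structurally invalid glycan (e.g. duplicate acceptor position)."""


class Anomer(str, Enum):
    ALPHA = "alpha"
    BETA = "beta"
    UNSPECIFIED = "unspecified"

    @property
    def symbol(self) -> str:
        return {"alpha": "α", "beta": "β", "unspecified": ""}[self.value]


@dataclass(frozen=True, order=True)
class Linkage:
    """Glycosidic bond descriptor: child's anomeric configuration and the
    acceptor carbon on the parent residue."""

    child_anomeric: Anomer
    position: int

    def __post_init__(self) -> None:
        if self.position not in VALID_POSITIONS:
            raise GlycanValidityError(
                f"linkage position {self.position} invalid; "
                f"must be one of {sorted(VALID_POSITIONS)} (5 is a ring carbon)"
            )


@dataclass(frozen=True)
class Residue:
    """A glucose residue with its substituents, sorted by acceptor position."""

    children: tuple[tuple[Linkage, "Residue"], ...] = ()
    monosaccharide: str = "Glc"

    def __post_init__(self) -> None:
        if self.monosaccharide != "Glc":
            raise GlycanValidityError(
                f"unsupported monosaccharide {self.monosaccharide!r}; only Glc"
            )
        positions = [lk.position for lk, _ in self.children]
        if len(set(positions)) != len(positions):
            dup = sorted(p for p in positions if positions.count(p) > 1)
            raise GlycanValidityError(f"duplicate acceptor position {dup[0]}")
        if len(self.children) > MAX_CHILDREN:
            raise GlycanValidityError(
                f"{len(self.children)} substituents on one residue (max {MAX_CHILDREN})"
            )
        # canonical in-memory order: ascending acceptor position
        object.__setattr__(
            self,
            "children",
            tuple(sorted(self.children, key=lambda c: c[0].position)),
        )

    @property
    def size(self) -> int:
        return 1 + sum(r.size for _, r in self.children)


@dataclass(frozen=True)
class GlycanStructure:
    """Rooted glucose oligosaccharide; the root is the reducing sugar."""

    root: Residue
    root_anomeric: Anomer = Anomer.UNSPECIFIED

    @property
    def size(self) -> int:
        return self.root.size

    @property
    def is_linear(self) -> bool:
        res = self.root
        while res.children:
            if len(res.children) > 1:
                return False
            res = res.children[0][1]
        return True

    @property
    def reducing_positions(self) -> frozenset[int]:
        """Acceptor positions occupied on the reducing sugar."""
        return frozenset(lk.position for lk, _ in self.root.children)

    def has_1_1_linkage(self) -> bool:
        """Trehalose-type bonds are representable but not elucidable."""
        def walk(res: Residue) -> bool:
            return any(lk.position == 1 or walk(r) for lk, r in res.children)
        return walk(self.root)

    def bonds(self) -> list[tuple[tuple[int, ...], Linkage, Residue]]:
        """All glycosidic bonds as (path-to-parent, linkage, child subtree).

        The path is the sequence of child indices from the root, so bonds are
        addressable independently of residue numbering.
        """
        out: list[tuple[tuple[int, ...], Linkage, Residue]] = []

        def walk(res: Residue, path: tuple[int, ...]) -> None:
            for i, (lk, child) in enumerate(res.children):
                out.append((path, lk, child))
                walk(child, path + (i,))

        walk(self.root, ())
        return out

    def chain(self) -> list[tuple[Linkage, Residue]]:
        """For a linear glycan, bonds from the reducing end outwards."""
        if not self.is_linear:
            raise GlycanValidityError("chain() requires a linear glycan")
        out = []
        res = self.root
        while res.children:
            lk, child = res.children[0]
            out.append((lk, child))
            res = child
        return out

    def __str__(self) -> str:
        return serialise_structure(self)


# ---------------------------------------------------------------------------
# builders

def linear_chain(links: list[tuple[Anomer, int]],
                 root_anomeric: Anomer = Anomer.UNSPECIFIED) -> GlycanStructure:
    """Linear glycan from bonds listed from the reducing end outwards.

    ``links[i]`` is (anomer, acceptor position) of the bond between residue
    i+1 and residue i+2, numbering the reducing sugar 1.
    """
    node = Residue()  # nonreducing terminus
    for anomer, pos in reversed(links):
        node = Residue(children=((Linkage(anomer, pos), node),))
    return GlycanStructure(root=node, root_anomeric=root_anomeric)


def disaccharide(bond_anomeric: Anomer, position: int,
                 reducing_anomeric: Anomer = Anomer.UNSPECIFIED) -> GlycanStructure:
    """Two-residue glycan, e.g. maltose = disaccharide(ALPHA, 4, ...)."""
    return linear_chain([(bond_anomeric, position)], root_anomeric=reducing_anomeric)


# ---------------------------------------------------------------------------
# parsing

_TOKEN_RE = re.compile(
    r"""(?P<lbracket>\[)
      | (?P<rbracket>\])
      | (?P<link>\(\s*1\s*(?:→|->|-)\s*(?P<pos>\d)\s*\))
      | (?P<glc>Glc)
      | (?P<anomer>α|β|alpha|beta|\ba\b|\bb\b)
      | (?P<sep>-)
      | (?P<ws>\s+)
    """,
    re.VERBOSE,
)

_ANOMER_ALIASES = {"α": Anomer.ALPHA, "alpha": Anomer.ALPHA, "a": Anomer.ALPHA,
                   "β": Anomer.BETA, "beta": Anomer.BETA, "b": Anomer.BETA}


@dataclass
class _Tok:
    kind: str
    value: object
    pos: int


def _tokenize(text: str) -> list[_Tok]:
    toks: list[_Tok] = []
    i = 0
    while i < len(text):
        m = _TOKEN_RE.match(text, i)
        if m is None:
            raise GlycanParseError(
                f"unrecognised token at position {i}: {text[i:i + 8]!r}"
            )
        for kind in ("lbracket", "rbracket", "link", "glc", "anomer", "sep", "ws"):
            if m.group(kind):
                break
        if kind == "link":
            toks.append(_Tok("link", int(m.group("pos")), i))
        elif kind == "anomer":
            toks.append(_Tok("anomer", _ANOMER_ALIASES[m.group("anomer")], i))
        elif kind in ("glc", "lbracket", "rbracket"):
            toks.append(_Tok(kind, m.group(0), i))
        # separators/whitespace dropped
        i = m.end()
    return toks


def _parse_chain(toks: list[_Tok], i: int
                 ) -> tuple[Residue, Anomer, int, int | None]:
    """Parse a chain starting at token ``i``.

    Returns (root residue of the chain, its anomer, next index, dangling
    linkage position if the chain ended with a link token — only legal
    immediately before a closing bracket).
    """
    pending: list[tuple[Linkage, Residue]] = []
    prev: tuple[Residue, Anomer] | None = None
    prev_link: int | None = None

    while i < len(toks):
        t = toks[i]
        if t.kind == "lbracket":
            if prev is not None and prev_link is None:
                raise GlycanParseError(
                    f"residue before branch at position {t.pos} lacks a linkage")
            i += 1
            sub_root, sub_anom, i, dangling = _parse_chain(toks, i)
            if dangling is None:
                raise GlycanParseError(
                    "branch in brackets must end with a linkage like -(1→6)")
            if i >= len(toks) or toks[i].kind != "rbracket":
                raise GlycanParseError("unclosed branch bracket")
            i += 1
            pending.append((Linkage(sub_anom, dangling), sub_root))
        elif t.kind in ("anomer", "glc"):
            anom = Anomer.UNSPECIFIED
            if t.kind == "anomer":
                anom = t.value  # type: ignore[assignment]
                i += 1
                if i >= len(toks) or toks[i].kind != "glc":
                    raise GlycanParseError(
                        f"anomeric prefix at position {t.pos} not followed by Glc")
            i += 1  # consume Glc
            children = list(pending)
            pending = []
            if prev is not None:
                if prev_link is None:
                    raise GlycanParseError(
                        f"missing linkage before residue at position {t.pos}")
                children.append((Linkage(prev[1], prev_link), prev[0]))
            try:
                res = Residue(children=tuple(children))
            except GlycanValidityError:
                raise
            prev = (res, anom)
            prev_link = None
            if i < len(toks) and toks[i].kind == "link":
                prev_link = toks[i].value  # type: ignore[assignment]
                i += 1
                if i < len(toks) and toks[i].kind == "rbracket":
                    return res, anom, i, prev_link
            elif i < len(toks) and toks[i].kind == "rbracket":
                return res, anom, i, None
        else:
            raise GlycanParseError(f"unexpected token {t.value!r} at position {t.pos}")

    if prev is None:
        raise GlycanParseError("empty structure string")
    if prev_link is not None:
        raise GlycanParseError("structure string ends with a dangling linkage")
    if pending:
        raise GlycanParseError("branch not attached to an acceptor residue")
    return prev[0], prev[1], len(toks), None


def parse_structure(text: str) -> GlycanStructure:
    """Parse a structure string (nonreducing→reducing, bracketed branches)."""
    toks = _tokenize(text)
    root, anom, i, dangling = _parse_chain(toks, 0)
    if i != len(toks):
        raise GlycanParseError(
            f"trailing tokens after structure at position {toks[i].pos}")
    if dangling is not None:
        raise GlycanParseError("structure string ends with a dangling linkage")
    return GlycanStructure(root=root, root_anomeric=anom)


# ---------------------------------------------------------------------------
# serialisation

def _unit(anomer: Anomer) -> str:
    return f"{anomer.symbol}-Glc" if anomer != Anomer.UNSPECIFIED else "Glc"


def _ser(res: Residue, anomer: Anomer) -> str:
    if not res.children:
        return _unit(anomer)
    cs = list(res.children)  # already ascending by position
    main_lk, main_child = cs[0]
    branches = sorted(cs[1:], key=lambda c: -c[0].position)
    parts = [_ser(main_child, main_lk.child_anomeric), f"-(1→{main_lk.position})-"]
    for lk, child in branches:
        parts.append(f"[{_ser(child, lk.child_anomeric)}-(1→{lk.position})]-")
    parts.append(_unit(anomer))
    return "".join(parts)


def serialise_structure(g: GlycanStructure) -> str:
    """Canonical structure string: the lowest-position substituent continues
    the main chain; remaining branches are bracketed in descending position
    order. ``parse_structure(serialise_structure(g)) == g``.
    """
    return _ser(g.root, g.root_anomeric)


# ---------------------------------------------------------------------------
# topology census

Shape = tuple  # nested sorted tuples; () is a leaf


@dataclass(frozen=True)
class TopologyClass:
    """A rooted unlabeled tree shape on n residues."""

    shape: Shape
    n: int
    kind: str  # "linear" | "branched"
    branch_depth: int | None  # depth of the shallowest branch point (root = 0)


def _shapes(n: int) -> set[Shape]:
    if n == 1:
        return {()}
    out: set[Shape] = set()
    for parts in _partitions(n - 1, MAX_CHILDREN):
        child_sets = [sorted(_shapes(p)) for p in parts]
        for combo in itertools.product(*child_sets):
            out.add(tuple(sorted(combo)))
    return out


def _partitions(n: int, max_parts: int) -> Iterator[tuple[int, ...]]:
    """Partitions of n into at most max_parts positive parts (descending)."""
    def rec(n: int, maxv: int, parts: tuple[int, ...]) -> Iterator[tuple[int, ...]]:
        if n == 0:
            yield parts
            return
        if len(parts) == max_parts:
            return
        for v in range(min(n, maxv), 0, -1):
            yield from rec(n - v, v, parts + (v,))
    yield from rec(n, n, ())


def _shape_size(s: Shape) -> int:
    return 1 + sum(_shape_size(c) for c in s)


def _branch_depth(s: Shape, depth: int = 0) -> int | None:
    if len(s) > 1:
        return depth
    deeper = [_branch_depth(c, depth + 1) for c in s]
    deeper = [d for d in deeper if d is not None]
    return min(deeper) if deeper else None


def enumerate_topologies(n: int) -> list[TopologyClass]:
    """Distinct rooted unlabeled tree shapes on n residues (≤3 substituents
    per residue), tagged linear/branched with the shallowest branch depth.

    For n=4 these are the four tetrasaccharide types: linear (I), branched on
    the reducing sugar (II), branched on the nonreducing side (III), and two
    branches on the reducing sugar (IV).
    """
    if not 1 <= n <= 6:
        raise ValueError(f"residue count {n} out of range 1..6")
    classes = []
    for s in sorted(_shapes(n)):
        bd = _branch_depth(s)
        classes.append(TopologyClass(
            shape=s, n=n,
            kind="linear" if bd is None else "branched",
            branch_depth=bd,
        ))
    # linear first, then branch points from the root outwards
    classes.sort(key=lambda c: (c.kind != "linear",
                                c.branch_depth if c.branch_depth is not None else -1,
                                c.shape))
    return classes
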