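"""Anomer-resolved disaccharide CID fingerprint database.

The defining feature of the database is that the *reducing* anomeric
configuration of every entry is resolved (α or β, never unspecified): the two
solution anomers are chromatographically separable because mutarotation is
slower than the separation, so each can be fragmented on its own.  A glucose
disaccharide slot is therefore the triple

    (glycosidic-bond anomer, linkage position, reducing anomer)

giving 2 × {2,3,4,6} × 2 = 16 slots (1→1 is not covered by the scheme).

Entries may be measured spectra dropped in by a lab or synthetic fingerprints
from the channel model (:func:`synth_fingerprints`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .spectra import Spectrum, SimilarityScore, normalise, similarity
from .structures import Anomer, GlycanStructure, disaccharide, serialise_structure

__all__ = ["ReferenceEntry", "MatchResult", "MutarotatedMatch", "ReferenceDB",
           "Slot", "build_db", "synth_fingerprints", "match",
           "match_mutarotated", "bond_decision", "COMMON_NAMES", "ALL_SLOTS",
           "DEFAULT_MARGIN"]

DEFAULT_MARGIN = 0.05

Slot = tuple[Anomer, int, Anomer]   # (bond anomer, position, reducing anomer)

COMMON_NAMES: dict[tuple[Anomer, int], str] = {
    (Anomer.ALPHA, 2): "kojibiose",
    (Anomer.BETA, 2): "sophorose",
    (Anomer.ALPHA, 3): "nigerose",
    (Anomer.BETA, 3): "laminaribiose",
    (Anomer.ALPHA, 4): "maltose",
    (Anomer.BETA, 4): "cellobiose",
    (Anomer.ALPHA, 6): "isomaltose",
    (Anomer.BETA, 6): "gentiobiose",
}

ALL_SLOTS: tuple[Slot, ...] = tuple(
    (a, p, r)
    for a in (Anomer.ALPHA, Anomer.BETA)
    for p in (2, 3, 4, 6)
    for r in (Anomer.ALPHA, Anomer.BETA)
)


@dataclass
class ReferenceEntry:
    structure: GlycanStructure
    spectrum: Spectrum
    common_name: str | None = None
    provenance: str = "measured"

    def __post_init__(self) -> None:
        if self.structure.size != 2:
            raise ValueError("reference entries must be disaccharides")
        if self.structure.root_anomeric == Anomer.UNSPECIFIED:
            raise ValueError(
                "reducing anomer must be resolved (α or β) in a reference entry")
        if self.provenance not in ("measured", "synthetic"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def slot(self) -> Slot:
        lk, _ = self.structure.root.children[0]
        return (lk.child_anomeric, lk.position, self.structure.root_anomeric)

    @property
    def label(self) -> str:
        return serialise_structure(self.structure)


@dataclass
class MatchResult:
    ranked: list[tuple[ReferenceEntry, SimilarityScore]]
    decision: ReferenceEntry | None
    margin: float

    @property
    def top(self) -> tuple[ReferenceEntry, SimilarityScore] | None:
        return self.ranked[0] if self.ranked else None


@dataclass
class ReferenceDB:
    entries: dict[Slot, ReferenceEntry] = field(default_factory=dict)

    def add(self, entry: ReferenceEntry) -> None:
        if entry.slot in self.entries:
            raise ValueError(f"duplicate database slot {entry.slot}")
        self.entries[entry.slot] = entry

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries.values())

    def get(self, slot: Slot) -> ReferenceEntry | None:
        return self.entries.get(slot)


def build_db(entries) -> ReferenceDB:
    """Index reference entries by (bond anomer, position, reducing anomer)."""
    db = ReferenceDB()
    for e in entries:
        db.add(e)
    return db


def synth_fingerprints(model=None, seed: int = 0) -> list[ReferenceEntry]:
    """Synthetic fingerprints for all 16 slots from the channel model.

    Fingerprints are the zero-noise CID spectra of the corresponding
    disaccharides, so they obey the mechanism's ordinal rules by construction:
    a cis (α) reducing anomer boosts −18, the bond anomer sets the glycosidic
    share and B:C partition, the linkage position selects the loss ladder, and
    1→2 entries carry only a minor −18.  Deterministic for a given seed.
    """
    import dataclasses

    from .simulate import ChannelModel, Ion, simulate_cid

    if model is None:
        model = ChannelModel()
    model = dataclasses.replace(model, noise_sigma=0.0, seed=seed)
    entries = []
    for a, p, r in ALL_SLOTS:
        g = disaccharide(a, p, r)
        spec = simulate_cid(Ion(g), model)
        entries.append(ReferenceEntry(
            structure=g,
            spectrum=normalise(spec),
            common_name=COMMON_NAMES[(a, p)],
            provenance="synthetic",
        ))
    return entries


def match(query: Spectrum, db: ReferenceDB,
          margin: float = DEFAULT_MARGIN) -> MatchResult:
    """Rank database fingerprints against a normalised query spectrum.

    The decision is the top entry only when it beats the runner-up by at least
    ``margin`` in similarity; otherwise the decision is withheld and the
    ranking speaks for itself (the caller may still accept a linkage-level
    assignment via :func:`bond_decision`).
    """
    if len(db) == 0:
        raise ValueError("empty reference database")
    if query.is_empty():
        raise ValueError("empty query spectrum")
    ranked = sorted(((e, similarity(query, e.spectrum)) for e in db),
                    key=lambda t: -t[1].value)
    decision = None
    if len(ranked) == 1 or ranked[0][1].value - ranked[1][1].value >= margin:
        decision = ranked[0][0]
    return MatchResult(ranked=ranked, decision=decision, margin=margin)


def mixture_spectrum(entries: list[ReferenceEntry]) -> Spectrum:
    """Expected spectrum of an equimolar mixture of reference disaccharides.

    Each stored fingerprint is normalised to its own base peak, so the
    recombination weights each entry by its recorded base-peak scale
    (``raw_base`` metadata) to restore true intensity proportions; entries
    without a recorded scale contribute equally.
    """
    import numpy as np

    from .spectra import bin_nominal

    weights = [float(e.spectrum.metadata.get("raw_base", 1.0)) for e in entries]
    total = sum(weights) or 1.0
    bins: dict[int, float] = {}
    for e, w in zip(entries, weights):
        for k, v in bin_nominal(e.spectrum).items():
            bins[k] = bins.get(k, 0.0) + v * (w / total)
    keys = sorted(bins)
    return Spectrum(np.array([float(k) for k in keys]),
                    np.array([bins[k] for k in keys]))


@dataclass
class MutarotatedMatch:
    """Match of a query against mutarotation-averaged fingerprints."""

    decision: tuple[Anomer, int] | None       # (bond anomer, position)
    entries: list[ReferenceEntry]             # the pair behind the decision
    ranked: list[tuple[tuple[Anomer, int], SimilarityScore]]


def match_mutarotated(query: Spectrum, db: ReferenceDB,
                      margin: float = DEFAULT_MARGIN) -> MutarotatedMatch:
    """Match a disaccharide whose reducing anomer is genuinely unresolved.

    A Y-type disaccharide keeps the original reducing sugar, so its spectrum
    is the mutarotation mixture of both reducing anomers; comparing against
    the average of each slot pair scores the bond (anomer, position) without
    pretending to read the reducing anomer.
    """
    import numpy as np

    groups: dict[tuple[Anomer, int], list[ReferenceEntry]] = {}
    for e in db:
        a, p, _ = e.slot
        groups.setdefault((a, p), []).append(e)
    ranked = []
    for key, entries in sorted(groups.items(), key=lambda kv: (kv[0][1],
                                                               kv[0][0].value)):
        avg = mixture_spectrum(entries)
        ranked.append((key, similarity(query, avg), entries))
    ranked.sort(key=lambda t: -t[1].value)
    decision, entries = None, []
    if len(ranked) == 1 or ranked[0][1].value - ranked[1][1].value >= margin:
        decision, entries = ranked[0][0], ranked[0][2]
    return MutarotatedMatch(decision, entries,
                            [(k, s) for k, s, _ in ranked])


def bond_decision(result: MatchResult, margin: float | None = None
                  ) -> tuple[Anomer, int, Anomer | None] | None:
    """Collapse a match to a glycosidic-bond assignment.

    Returns (bond anomer, position, reducing anomer) for a clear top hit.  If
    the two top hits are the two reducing anomers of the *same* bond (the dual
    report case), the bond assignment is still accepted with reducing anomer
    None — both anomeric variants of one linkage outrank everything else.
    """
    if margin is None:
        margin = result.margin
    if not result.ranked:
        return None
    if result.decision is not None:
        a, p, r = result.decision.slot
        return (a, p, r)
    (e1, s1), (e2, s2) = result.ranked[0], result.ranked[1]
    a1, p1, _ = e1.slot
    a2, p2, _ = e2.slot
    if (a1, p1) == (a2, p2):
        third = result.ranked[2][1].value if len(result.ranked) > 2 else 0.0
        if s1.value - third >= margin:
            return (a1, p1, None)
    return None
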