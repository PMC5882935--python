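"""Decision rules mapping observed neutral-loss patterns to linkage and
topology hypotheses, plus the acquisition plans that name the structurally
decisive MSⁿ spectra.

The MS2 loss pattern of a sodiated oligosaccharide is read against the
fragmentation-pattern table (module :mod:`oligoms.fragments`): which of
−18/−60/−90/−120 appear constrains the acceptor position(s) on the reducing
sugar.  The table is not injective — a linear (1→4) glycan and one branched
(1→6, 1→4) at the reducing sugar show the same {−18, −60} pattern (likewise
linear (1→3) vs branched (1→6, 1→3), and the two 1→2-containing branched
pairs) — so the schemes descend one CID stage further: a disaccharide-region
ion (m/z 365, or 347 on a cross-ring route) in the CID of a loss ion proves a
linear chain, its absence in every such spectrum proves a branch at the
reducing sugar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .fragments import (BRANCHED_LOSSES, LINEAR_LOSSES, LOSS_NOMINAL,
                        sodiated_mz)

__all__ = [
    "LossPattern",
    "LinkageHypothesis",
    "PatternInconsistentError",
    "UndeterminedTopologyError",
    "TetrasaccharideClass",
    "PlanStep",
    "AcquisitionPlan",
    "reducing_linkage_candidates",
    "resolve_linear_vs_branched",
    "classify_tetrasaccharide",
    "decisive_ion_plan",
    "expected_loss_set",
    "all_hypotheses",
    "PRESENCE_THRESHOLD",
]

PRESENCE_THRESHOLD = 0.01   # binned intensity at/above which an ion "is present"
LOSS_ALPHABET = frozenset({18, 60, 90, 120})

# exception notes carried as caveats (decision-scheme footnotes, own wording)
NOTE_BRANCHED_WITH_DEHYDRATION = (
    "a branched reducing sugar with (1→6,1→4), (1→4,1→3) or (1→3,1→2) linkages "
    "also dehydrates; the loss pattern alone does not exclude these")
NOTE_BRANCHED_WITH_CROSSRING = (
    "branched reducing sugars with (1→6,1→3), (1→6,1→2) or (1→4,1→2) linkages, "
    "and a linear 1→1 bond, are excluded from this decision branch")
NOTE_12_OR_11_REDUCING = (
    "not applicable to 1→2 or 1→1 linkages on the reducing sugar")
NOTE_11_NOT_CONSIDERED = "1→1 (trehalose-type) linkages are not considered"
NOTE_12_MINOR_DEHYDRATION = (
    "1→2 bonds (kojibiose/sophorose class): dehydration is only a minor channel "
    "and proceeds by a different mechanism")
NOTE_TETRA_NODE_AMBIGUOUS = (
    "two scheme exceptions — 'only for (1→6,1→4) and (1→3,1→2) on the reducing "
    "sugar' and 'without (1→2) on the reducing sugar' — have an ambiguous "
    "decision-node attachment and are carried as blanket caveats")


class PatternInconsistentError(ValueError):
    """No linkage assignment is consistent with the observed loss pattern."""


class UndeterminedTopologyError(ValueError):
    def __init__(self, missing: list[tuple[int, ...]]):
        self.missing = missing
        super().__init__(
            "topology undetermined; missing decisive CID steps: "
            + ", ".join("→".join(map(str, p)) for p in missing))


@dataclass(frozen=True)
class LossPattern:
    """Observed neutral losses (nominal, relative to the precursor) plus
    presence flags for diagnostic daughter ions.

    ``ion_flags[m] is True/False`` records observed presence/absence at
    nominal m/z ``m``; a missing key means the spectrum gave no reading.
    """

    losses_observed: frozenset[int] = frozenset()
    ion_flags: tuple[tuple[int, bool], ...] = ()

    def __post_init__(self) -> None:
        bad = set(self.losses_observed) - LOSS_ALPHABET
        if bad:
            raise ValueError(f"losses {sorted(bad)} outside the alphabet "
                             f"{sorted(LOSS_ALPHABET)}")
        object.__setattr__(self, "losses_observed",
                           frozenset(self.losses_observed))
        object.__setattr__(self, "ion_flags",
                           tuple(sorted((int(k), bool(v))
                                        for k, v in dict(self.ion_flags).items())))

    def flag(self, mz: int) -> bool | None:
        return dict(self.ion_flags).get(mz)

    @classmethod
    def from_spectrum(cls, spectrum, precursor_mz: int,
                      diagnostic_ions: tuple[int, ...] = (),
                      threshold: float = PRESENCE_THRESHOLD) -> "LossPattern":
        from .spectra import bin_nominal
        bins = bin_nominal(spectrum)
        losses = frozenset(l for l in LOSS_ALPHABET
                           if bins.get(precursor_mz - l, 0.0) >= threshold)
        flags = tuple((m, bins.get(m, 0.0) >= threshold) for m in diagnostic_ions)
        return cls(losses, flags)


@dataclass
class LinkageHypothesis:
    topology: str                      # "linear" | "branched"
    reducing_linkages: tuple[int, ...]  # sorted descending, as printed
    status: str = "candidate"          # candidate | confirmed | excluded
    caveats: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.reducing_linkages = tuple(sorted(self.reducing_linkages, reverse=True))
        if self.topology == "branched" and len(self.reducing_linkages) < 2:
            raise ValueError("branched hypothesis needs >= 2 reducing linkages")
        if self.topology == "linear" and len(self.reducing_linkages) != 1:
            raise ValueError("linear hypothesis carries exactly one linkage")

    def set_status(self, new: str) -> None:
        if self.status != "candidate" and new != self.status:
            raise ValueError(f"illegal status transition {self.status}→{new}")
        self.status = new

    def key(self) -> tuple[str, tuple[int, ...]]:
        return (self.topology, self.reducing_linkages)


def expected_loss_set(topology: str, positions: tuple[int, ...]) -> frozenset[int]:
    """Major neutral losses the pattern table predicts for an assignment."""
    if topology == "linear":
        tokens = LINEAR_LOSSES[positions[0]]
    else:
        tokens = BRANCHED_LOSSES[frozenset(positions)]
    return frozenset(LOSS_NOMINAL[t] for t in tokens)


def all_hypotheses() -> list[LinkageHypothesis]:
    """Every assignment the table covers (1→1 excluded by the scheme)."""
    hyps = [LinkageHypothesis("linear", (p,)) for p in (2, 3, 4, 6)]
    hyps += [LinkageHypothesis("branched", tuple(sorted(s, reverse=True)))
             for s in BRANCHED_LOSSES]
    return hyps


def reducing_linkage_candidates(p: LossPattern, n: int) -> list[LinkageHypothesis]:
    """Linkage assignments for the reducing sugar consistent with the observed
    loss pattern: the predicted major-loss set must equal the observed set.
    """
    if n not in (3, 4, 5):
        raise ValueError(f"residue count {n} unsupported (need 3, 4 or 5)")
    out: list[LinkageHypothesis] = []
    for h in all_hypotheses():
        if expected_loss_set(h.topology, h.reducing_linkages) == p.losses_observed:
            if 2 in h.reducing_linkages:
                h.caveats.append(NOTE_12_MINOR_DEHYDRATION)
            out.append(h)
    if not out:
        raise PatternInconsistentError(
            f"no linkage assignment predicts exactly the losses "
            f"{sorted(p.losses_observed)}")
    return out


def _linear_branched_pair(cands: list[LinkageHypothesis]
                          ) -> tuple[LinkageHypothesis, LinkageHypothesis] | None:
    lin = [h for h in cands if h.topology == "linear"]
    br = [h for h in cands if h.topology == "branched"]
    if len(lin) == 1 and len(br) == 1:
        return lin[0], br[0]
    return None


def resolve_linear_vs_branched(ms3_on_dehydration: LossPattern | None,
                               ms3_on_A_ion: LossPattern | None,
                               n: int,
                               candidates: list[LinkageHypothesis] | None = None,
                               ) -> list[LinkageHypothesis]:
    """Settle a linear-vs-branched ambiguity from the CID of the loss ions.

    A disaccharide-region ion — m/z 365 in the CID of the dehydration ion, or
    m/z 347/365 in the CID of a cross-ring ion — proves the chain extends two
    residues above the reducing sugar, i.e. linear.  Absence in every supplied
    spectrum proves the branch.  Contradictory readings keep both hypotheses
    with a warning caveat.
    """
    if candidates is None:
        candidates = [LinkageHypothesis("linear", (4,)),
                      LinkageHypothesis("branched", (6, 4))]
    pair = _linear_branched_pair(candidates)
    if pair is None:
        return candidates
    linear, branched = pair

    votes: list[bool] = []
    if ms3_on_dehydration is not None:
        f = ms3_on_dehydration.flag(365)
        if f is not None:
            votes.append(f)
    if ms3_on_A_ion is not None:
        fs = [ms3_on_A_ion.flag(347), ms3_on_A_ion.flag(365)]
        fs = [f for f in fs if f is not None]
        if fs:
            votes.append(any(fs))
    if not votes:
        linear.caveats.append("no decisive loss-ion spectrum supplied")
        branched.caveats.append("no decisive loss-ion spectrum supplied")
        return [linear, branched]
    if all(votes):
        linear.set_status("confirmed")
        branched.set_status("excluded")
        return [linear]
    if not any(votes):
        branched.set_status("confirmed")
        branched.caveats.append(NOTE_BRANCHED_WITH_CROSSRING)
        linear.set_status("excluded")
        return [branched]
    linear.caveats.append("contradictory disaccharide-ion readings across routes")
    branched.caveats.append("contradictory disaccharide-ion readings across routes")
    return [linear, branched]


@dataclass(frozen=True)
class TetrasaccharideClass:
    """One of the four tetrasaccharide shapes."""

    roman: str       # I..IV
    description: str
    caveats: tuple[str, ...] = ()


_TETRA = {
    "I": "linear tetrasaccharide",
    "II": "branched at the reducing sugar",
    "III": "branched on the nonreducing side",
    "IV": "two branches on the reducing sugar",
}


def classify_tetrasaccharide(ms2: LossPattern,
                             loss_ion_patterns: dict[int, LossPattern]
                             ) -> TetrasaccharideClass:
    """Classify a tetrasaccharide (precursor m/z 689) into types I–IV.

    Reads two findings: a disaccharide-region ion (365/347) in the MS2
    spectrum, and a trisaccharide-region ion (527/509) in the CID of any
    dehydration/cross-ring ion.  Both present → linear (I); disaccharide ions
    only → branch at the reducing sugar (II); trisaccharide ions only →
    branch on the nonreducing side (III); neither → two branches (IV).
    """
    parent = sodiated_mz(4)[1]
    dehydration_ion = sodiated_mz(4, "H2O")[1]
    missing: list[tuple[int, ...]] = []
    ms2_flags = [ms2.flag(365), ms2.flag(347)]
    if all(f is None for f in ms2_flags):
        missing.append((parent,))
    tri_flags: list[bool] = []
    for loss_mz, pat in loss_ion_patterns.items():
        # on the dehydration route a Y3-type ion also sits at 509, so only
        # the C3 ion (527) is topology-decisive there; cross-ring routes can
        # use both 527 and 509
        fs = ([pat.flag(527)] if loss_mz == dehydration_ion
              else [pat.flag(527), pat.flag(509)])
        fs = [f for f in fs if f is not None]
        if fs:
            tri_flags.append(any(fs))
    if not tri_flags:
        missing.append((parent, parent - 60))
    if missing:
        raise UndeterminedTopologyError(missing)

    disacch = any(f for f in ms2_flags if f is not None)
    trisacch = any(tri_flags)
    roman = {(True, True): "I", (True, False): "II",
             (False, True): "III", (False, False): "IV"}[(disacch, trisacch)]
    caveats = [NOTE_11_NOT_CONSIDERED, NOTE_TETRA_NODE_AMBIGUOUS]
    if roman in ("I", "III"):
        caveats.append("assumes no 1→2 bond between interior residues")
    else:
        caveats.append(NOTE_BRANCHED_WITH_DEHYDRATION)
    return TetrasaccharideClass(roman, _TETRA[roman], tuple(caveats))


# ---------------------------------------------------------------------------
# acquisition plans

@dataclass(frozen=True)
class PlanStep:
    path: tuple[int, ...]   # precursor path, nominal m/z
    step: int               # procedure step the spectrum feeds
    purpose: str


@dataclass(frozen=True)
class AcquisitionPlan:
    n: int
    parent_mz: int
    steps: tuple[PlanStep, ...]

    @property
    def paths(self) -> set[tuple[int, ...]]:
        return {s.path for s in self.steps}

    def to_json(self) -> str:
        return json.dumps({
            "n": self.n,
            "parent_mz": self.parent_mz,
            "steps": [{"path": list(s.path), "step": s.step,
                       "purpose": s.purpose} for s in self.steps],
        }, indent=2)

    def to_text(self) -> str:
        lines = [f"acquisition plan: n={self.n}, parent m/z {self.parent_mz}"]
        for s in sorted(self.steps, key=lambda s: (s.step, s.path)):
            indent = "  " * len(s.path)
            lines.append(f"{indent}{'→'.join(map(str, s.path))}"
                         f"  [step {s.step}: {s.purpose}]")
        return "\n".join(lines)


def _loss_ions(parent: int) -> list[int]:
    return [parent - l for l in (18, 60, 90, 120)]


def decisive_ion_plan(n: int, parent_mz: int | None = None) -> AcquisitionPlan:
    """The ordered MSⁿ target list for an n-mer (n in 2..5).

    Every candidate loss-ion route is listed; routes whose precursor is absent
    for the actual linkage simply yield unavailable spectra and are skipped at
    elucidation time.
    """
    if n not in (2, 3, 4, 5):
        raise ValueError(f"residue count {n} unsupported (need 2..5)")
    _, expected = sodiated_mz(n)
    if parent_mz is None:
        parent_mz = expected
    if parent_mz != expected:
        raise ValueError(f"parent m/z {parent_mz} does not match a sodiated "
                         f"{n}-mer ({expected})")
    disacch = sodiated_mz(2)[1]   # 365
    steps: list[PlanStep] = []

    if n == 2:
        steps.append(PlanStep((parent_mz,), 1, "disaccharide fingerprint, DB match"))
        return AcquisitionPlan(n, parent_mz, tuple(steps))

    steps.append(PlanStep((parent_mz,), 1, "reducing-sugar linkage pattern"))
    for L in _loss_ions(parent_mz):
        steps.append(PlanStep((parent_mz, L), 2,
                              "loss-ion CID: linear/branched check, "
                              "nonreducing disaccharide generation"))
        steps.append(PlanStep((parent_mz, L, disacch), 3,
                              "nonreducing disaccharide fingerprint, DB match"))
    if n == 4:
        for L in _loss_ions(parent_mz):
            y3 = L - 162
            steps.append(PlanStep((parent_mz, L, y3), 4,
                                  "interior disaccharide generation"))
            steps.append(PlanStep((parent_mz, L, y3, disacch), 5,
                                  "interior disaccharide fingerprint, DB match"))
    if n == 5:
        y4 = sodiated_mz(4)[1]   # 689
        y3 = sodiated_mz(3)[1]   # 527
        steps.append(PlanStep((parent_mz, y4), 4, "four-mer Y-ion isolation"))
        for Lq in _loss_ions(y4):
            steps.append(PlanStep((parent_mz, y4, Lq), 4,
                                  "four-mer loss-ion CID"))
            steps.append(PlanStep((parent_mz, y4, Lq, disacch), 5,
                                  "disaccharide (residues 3,4) fingerprint"))
        steps.append(PlanStep((parent_mz, y3), 6, "three-mer Y-ion isolation"))
        for Lr in _loss_ions(y3):
            steps.append(PlanStep((parent_mz, y3, Lr), 6,
                                  "three-mer loss-ion CID"))
            steps.append(PlanStep((parent_mz, y3, Lr, disacch), 7,
                                  "disaccharide (residues 2,3) fingerprint"))
    steps.append(PlanStep((parent_mz, disacch), 8,
                          "mixed reducing/nonreducing disaccharide spectrum, "
                          "subtraction crosscheck"))
    return AcquisitionPlan(n, parent_mz, tuple(steps))
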