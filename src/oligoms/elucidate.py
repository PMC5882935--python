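"""De novo structure elucidation from an MSⁿ spectral tree.

The orchestrator walks the decisive-ion acquisition plan: the MS2 loss
pattern fixes the reducing-sugar linkage candidates; the CID of a dehydration
or cross-ring ion settles linear vs branched and generates the nonreducing
disaccharide, whose database match yields a bond anomer, a linkage position
and — because a C-type fragment inherits its reducing anomer from the cleaved
bond — the anomer of the *next* bond towards the reducing end; interior
disaccharides repeat the step; and the mixed disaccharide spectrum (the
co-isolated C₂/Y₂ populations) is deconvolved by weighted subtraction of the
already-identified fingerprint as a crosscheck.  Every bond of the reported
structure carries the provenance of each decision, agreements between
independent routes are audited, and disagreements downgrade an assignment to
unspecified rather than silently picking a side.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Protocol

from .refdb import (DEFAULT_MARGIN, MatchResult, ReferenceDB, ReferenceEntry,
                    bond_decision, match, match_mutarotated)
from .rules import (AcquisitionPlan, LinkageHypothesis, LossPattern,
                    PRESENCE_THRESHOLD, PatternInconsistentError,
                    UndeterminedTopologyError, classify_tetrasaccharide,
                    decisive_ion_plan, reducing_linkage_candidates,
                    resolve_linear_vs_branched)
from .spectra import Spectrum, bin_nominal, normalise, subtract
from .structures import (Anomer, GlycanStructure, Linkage, Residue,
                         linear_chain, serialise_structure)
from .fragments import sodiated_mz

__all__ = ["SpectrumProvider", "Evidence", "BondAssignment",
           "ElucidationReport", "SubtractionResult", "elucidate",
           "crosscheck_subtraction", "consistency_audit", "NEAR_ZERO"]

NEAR_ZERO = 0.05   # residual below this (relative) counts as "near zero"
# topology-deciding ion votes are read against the chemical-noise floor,
# not the spectrum threshold: a structural C/B fragment is never that weak
DIAGNOSTIC_SALIENCE = 0.06
# an observed loss this weak may be noise and can be dropped when the
# pattern table has no consistent row
WEAK_LOSS = 0.08

DISACCH = sodiated_mz(2)[1]   # 365


class SpectrumProvider(Protocol):
    """Contract: return the CID spectrum recorded for a precursor path, or
    None when unavailable.  Repeated requests must return the same spectrum."""

    def get(self, path: tuple[int, ...]) -> Spectrum | None: ...


@dataclass
class Evidence:
    source: str
    anomer: Anomer | None = None
    position: int | None = None


@dataclass
class BondAssignment:
    bond_id: str                      # residues numbered from the reducing end
    position: int | None = None
    anomer: Anomer | None = None
    evidence: list[Evidence] = field(default_factory=list)
    crosschecks: list[str] = field(default_factory=list)
    caveats: list[str] = field(default_factory=list)

    def add(self, source: str, anomer: Anomer | None = None,
            position: int | None = None) -> None:
        self.evidence.append(Evidence(source, anomer, position))


@dataclass
class ElucidationReport:
    n: int
    structure: GlycanStructure | None = None
    topology: str | None = None
    bonds: list[BondAssignment] = field(default_factory=list)
    caveats: list[str] = field(default_factory=list)
    undetermined: list[str] = field(default_factory=list)
    requested_paths: list[tuple[int, ...]] = field(default_factory=list)

    @property
    def structure_string(self) -> str | None:
        return serialise_structure(self.structure) if self.structure else None

    @property
    def is_partial(self) -> bool:
        if self.structure is None or self.undetermined:
            return True
        return any(b.position is None or b.anomer in (None, Anomer.UNSPECIFIED)
                   for b in self.bonds)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "structure": self.structure_string,
            "topology": self.topology,
            "partial": self.is_partial,
            "bonds": [{
                "bond": b.bond_id,
                "position": b.position,
                "anomer": b.anomer.value if b.anomer else None,
                "decided_by": [{"source": e.source,
                                "anomer": e.anomer.value if e.anomer else None,
                                "position": e.position} for e in b.evidence],
                "crosschecks": b.crosschecks,
                "caveats": b.caveats,
            } for b in self.bonds],
            "caveats": self.caveats,
            "undetermined": self.undetermined,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, ensure_ascii=False)

    def to_text(self) -> str:
        lines = [f"structure: {self.structure_string or 'undetermined'}"
                 + ("  (partial)" if self.is_partial else "")]
        if self.topology:
            lines.append(f"topology: {self.topology}")
        for b in self.bonds:
            anom = b.anomer.symbol if b.anomer and b.anomer != Anomer.UNSPECIFIED \
                else "?"
            pos = b.position if b.position is not None else "?"
            lines.append(f"  bond {b.bond_id}: {anom}(1→{pos})")
            for e in b.evidence:
                lines.append(f"    decided by: {e.source}")
            for c in b.crosschecks:
                lines.append(f"    crosscheck: {c}")
            for c in b.caveats:
                lines.append(f"    caveat: {c}")
        for c in self.caveats:
            lines.append(f"caveat: {c}")
        for u in self.undetermined:
            lines.append(f"undetermined: {u}")
        return "\n".join(lines)


@dataclass
class SubtractionResult:
    residual: Spectrum
    match: MatchResult | None
    no_second_component: bool
    weight: float


class _Fetcher:
    """Plan-gated, memoising access to a spectrum provider."""

    def __init__(self, provider: SpectrumProvider, plan: AcquisitionPlan,
                 threshold: float):
        self.provider = provider
        self.plan_paths = plan.paths
        self.threshold = threshold
        self.cache: dict[tuple[int, ...], Spectrum | None] = {}
        self.requested: list[tuple[int, ...]] = []

    def get(self, path: tuple[int, ...]) -> Spectrum | None:
        path = tuple(int(p) for p in path)
        if path not in self.plan_paths:
            raise ValueError(f"path {path} is not in the decisive-ion plan")
        if path in self.cache:
            return self.cache[path]
        self.requested.append(path)
        spec = self.provider.get(path)
        if spec is not None and not spec.is_empty():
            spec = normalise(spec, self.threshold)
        else:
            spec = None
        self.cache[path] = spec
        return spec


from .refdb import mixture_spectrum as _ref_spectrum  # noqa: E402


def crosscheck_subtraction(mixed: Spectrum,
                           identified: ReferenceEntry | list[ReferenceEntry],
                           db: ReferenceDB,
                           zero_ion: int | None = None,
                           margin: float = DEFAULT_MARGIN,
                           near_zero: float = NEAR_ZERO) -> SubtractionResult:
    """Strip an identified component's fingerprint from a mixed disaccharide
    spectrum and match what remains.

    A residual that is near zero everywhere means no second component is
    present (the branched case where essentially only one branch cleaves);
    otherwise the residual is matched against the database.
    """
    entries = identified if isinstance(identified, list) else [identified]
    if not entries:
        raise ValueError("no identified component to subtract")
    ref = _ref_spectrum(entries)
    residual = subtract(mixed, ref, zero_ion)
    weight = float(residual.metadata.get("subtraction_weight", 0.0))
    if residual.metadata.get("near_zero") or residual.is_empty(near_zero):
        return SubtractionResult(residual, None, True, weight)
    mr = match(normalise(residual), db, margin)
    return SubtractionResult(residual, mr, False, weight)


def consistency_audit(report: ElucidationReport) -> list[str]:
    """Check every multiply-decided assignment for agreement.

    Disagreeing anomer evidence downgrades the assignment to unspecified with
    a caveat; agreement and single-source assignments are recorded.  The
    report is updated in place and the audit lines returned.
    """
    audit: list[str] = []
    for b in report.bonds:
        anomers = [e.anomer for e in b.evidence if e.anomer is not None]
        positions = [e.position for e in b.evidence if e.position is not None]
        if len(set(anomers)) > 1:
            b.anomer = Anomer.UNSPECIFIED
            msg = (f"bond {b.bond_id}: anomer evidence disagrees "
                   f"({', '.join(a.value for a in anomers)}); downgraded")
            b.caveats.append(msg)
            audit.append("DISAGREE " + msg)
        elif len(anomers) >= 2:
            b.crosschecks.append(f"{len(anomers)} independent anomer readings agree")
            audit.append(f"AGREE bond {b.bond_id}: anomer "
                         f"{anomers[0].value} × {len(anomers)}")
        elif len(anomers) == 1:
            audit.append(f"SINGLE bond {b.bond_id}: anomer from one route only")
            b.crosschecks.append("no anomer crosscheck")
        if len(set(positions)) > 1:
            msg = (f"bond {b.bond_id}: position evidence disagrees "
                   f"({sorted(set(positions))})")
            b.caveats.append(msg)
            audit.append("DISAGREE " + msg)
        elif len(positions) >= 2:
            audit.append(f"AGREE bond {b.bond_id}: position "
                         f"{positions[0]} × {len(positions)}")
    return audit


# ---------------------------------------------------------------------------

def _loss_ions_by_intensity(ms2: Spectrum, parent: int) -> list[int]:
    bins = bin_nominal(ms2)
    ions = [(bins.get(parent - l, 0.0), parent - l) for l in (18, 60, 90, 120)]
    return [mz for inten, mz in sorted(ions, reverse=True)
            if inten >= PRESENCE_THRESHOLD]


def _pattern(fetcher: _Fetcher, path: tuple[int, ...],
             diagnostics: tuple[int, ...],
             threshold: float = DIAGNOSTIC_SALIENCE) -> LossPattern | None:
    spec = fetcher.get(path)
    if spec is None:
        return None
    return LossPattern.from_spectrum(spec, path[-1], diagnostics, threshold)


def _match_disaccharide(fetcher: _Fetcher, path: tuple[int, ...],
                        db: ReferenceDB, margin: float
                        ) -> tuple[MatchResult, list[ReferenceEntry]] | None:
    """Match the spectrum at ``path``; also return the entry (or dual pair)
    behind the accepted bond decision, for later subtraction."""
    spec = fetcher.get(path)
    if spec is None:
        return None
    mr = match(spec, db, margin)
    if mr.decision is not None:
        return mr, [mr.decision]
    bd = bond_decision(mr)
    if bd is not None:
        return mr, [mr.ranked[0][0], mr.ranked[1][0]]
    return mr, []


def _match_routes(fetcher: _Fetcher, paths: list[tuple[int, ...]],
                  db: ReferenceDB, margin: float
                  ) -> tuple[list[ReferenceEntry], tuple[int, ...] | None,
                             str | None]:
    """Match a definite-reducing-anomer disaccharide along several routes.

    The first route whose match clears the margin wins.  When no single route
    is decisive but every route's best hit is the same slot, that consensus is
    accepted with a caveat — independent routes agreeing is the method's own
    reliability argument.
    """
    tops: list[ReferenceEntry] = []
    for path in paths:
        got = _match_disaccharide(fetcher, path, db, margin)
        if got is None:
            continue
        mr, entries = got
        if entries:
            return entries, path, None
        tops.append(mr.ranked[0][0])
    if len(tops) >= 2 and len({e.slot for e in tops}) == 1:
        return [tops[0]], paths[0], (
            "similarity margin unmet on every route, but all routes rank the "
            "same fingerprint first")
    return [], None, None


def elucidate(provider: SpectrumProvider, n: int, db: ReferenceDB,
              threshold: float = PRESENCE_THRESHOLD,
              margin: float = DEFAULT_MARGIN,
              near_zero: float = NEAR_ZERO) -> ElucidationReport:
    """Run the full decision procedure against a spectrum provider.

    Supports trisaccharides (linear and branched), tetrasaccharides (full
    assignment for the linear class, classification with partial assignment
    for branched classes) and linear pentasaccharides.  The reducing-end
    anomer is always reported unspecified (both solution anomers coexist).
    Missing decisive spectra yield a partial report naming the paths that
    would settle the remainder.
    """
    if n not in (3, 4, 5):
        raise ValueError(f"residue count {n} unsupported (need 3, 4 or 5)")
    parent = sodiated_mz(n)[1]
    plan = decisive_ion_plan(n)
    fetcher = _Fetcher(provider, plan, threshold)
    report = ElucidationReport(n=n)

    ms2 = fetcher.get((parent,))
    if ms2 is None:
        report.undetermined.append(
            f"no MS2 spectrum; path {parent} would determine the "
            f"reducing-sugar linkage")
        report.requested_paths = fetcher.requested
        return report

    pattern, candidates = _robust_candidates(ms2, parent, n, threshold, report)
    if candidates is None:
        report.requested_paths = fetcher.requested
        return report

    loss_ions = _loss_ions_by_intensity(ms2, parent)

    if n == 4:
        _elucidate_tetra(fetcher, db, report, candidates, pattern, loss_ions,
                         parent, margin, near_zero)
    else:
        resolved = _resolve_topology(fetcher, candidates, loss_ions, parent, n)
        if len(resolved) == 1 and resolved[0].topology == "linear":
            report.topology = "linear"
            _elucidate_linear(fetcher, db, report, resolved[0], loss_ions,
                              parent, n, margin, near_zero)
        elif len(resolved) == 1 and resolved[0].topology == "branched":
            report.topology = "branched at the reducing sugar"
            _elucidate_branched_tri(fetcher, db, report, resolved[0], parent,
                                    margin, near_zero)
        else:
            for h in resolved:
                report.caveats.extend(h.caveats)
            report.undetermined.append(
                "linear vs branched unresolved; CID of the loss ions "
                + ", ".join(f"{parent}→{L}" for L in loss_ions or ["(none seen)"])
                + " would decide")
    consistency_audit(report)
    report.requested_paths = fetcher.requested
    return report


def _robust_candidates(ms2: Spectrum, parent: int, n: int, threshold: float,
                       report: ElucidationReport
                       ) -> tuple[LossPattern | None,
                                  list[LinkageHypothesis] | None]:
    """Read the MS2 loss pattern; when no table row matches, retry with the
    weakest sub-salience losses removed (a noise peak can sit on a loss bin)."""
    bins = bin_nominal(ms2)
    pattern = LossPattern.from_spectrum(ms2, parent, (DISACCH, 347), threshold)
    try:
        return pattern, reducing_linkage_candidates(pattern, n)
    except PatternInconsistentError as exc:
        weak = sorted(
            (l for l in pattern.losses_observed
             if bins.get(parent - l, 0.0) < WEAK_LOSS),
            key=lambda l: bins.get(parent - l, 0.0))
        losses = set(pattern.losses_observed)
        for l in weak:
            losses.discard(l)
            trial = LossPattern(frozenset(losses), pattern.ion_flags)
            try:
                cands = reducing_linkage_candidates(trial, n)
            except PatternInconsistentError:
                continue
            for h in cands:
                h.caveats.append(
                    f"weak −{l} signal treated as noise to fit the pattern table")
            return trial, cands
        report.undetermined.append(str(exc))
        return pattern, None


def _resolve_topology(fetcher: _Fetcher, candidates: list[LinkageHypothesis],
                      loss_ions: list[int], parent: int, n: int
                      ) -> list[LinkageHypothesis]:
    lin = [h for h in candidates if h.topology == "linear"]
    br = [h for h in candidates if h.topology == "branched"]
    if not (lin and br):
        return candidates
    deh = parent - 18
    pat18 = (_pattern(fetcher, (parent, deh), (DISACCH,))
             if deh in loss_ions else None)
    patA = None
    for L in loss_ions:
        if L != deh:
            patA = _pattern(fetcher, (parent, L), (347, DISACCH))
            if patA is not None:
                break
    return resolve_linear_vs_branched(pat18, patA, n, candidates)


def _bond(report: ElucidationReport, bond_id: str) -> BondAssignment:
    for b in report.bonds:
        if b.bond_id == bond_id:
            return b
    b = BondAssignment(bond_id)
    report.bonds.append(b)
    return b


def _apply_decision(report: ElucidationReport, bond_id: str, source: str,
                    anomer: Anomer | None, position: int | None) -> None:
    b = _bond(report, bond_id)
    b.add(source, anomer, position)
    if position is not None and b.position is None:
        b.position = position
    if anomer is not None and b.anomer in (None, Anomer.UNSPECIFIED):
        b.anomer = anomer


def _path_str(path: tuple[int, ...]) -> str:
    return "→".join(map(str, path))


def _elucidate_linear(fetcher: _Fetcher, db: ReferenceDB,
                      report: ElucidationReport, hyp: LinkageHypothesis,
                      loss_ions: list[int], parent: int, n: int,
                      margin: float, near_zero: float) -> None:
    p1 = hyp.reducing_linkages[0]
    _apply_decision(report, "1-2", "MS2 loss pattern of the precursor",
                    None, p1)
    for c in hyp.caveats:
        _bond(report, "1-2").caveats.append(c)

    # nonreducing disaccharide via the loss-ion routes
    top_entries, top_path, consensus = _match_routes(
        fetcher, [(parent, L, DISACCH) for L in loss_ions], db, margin)
    if not top_entries:
        report.undetermined.append(
            "nonreducing disaccharide unmatched; paths "
            + ", ".join(_path_str((parent, L, DISACCH)) for L in loss_ions)
            + " would decide")
        _finish_linear_structure(report, n)
        return

    a_top, p_top, r_top = _collapse_entries(top_entries)
    nb = f"{n - 1}-{n}"
    _apply_decision(report, nb, f"DB match of {_path_str(top_path)}",
                    a_top, p_top)
    if consensus:
        _bond(report, nb).caveats.append(consensus)
    if r_top is not None:
        _apply_decision(
            report, f"{n - 2}-{n - 1}",
            f"reducing anomer inherited from the {_path_str(top_path)} match",
            r_top, None)

    if n == 3:
        _step8(fetcher, db, report, top_entries, parent, "1-2", margin,
               near_zero)
    elif n == 5:
        _interior_pentasaccharide(fetcher, db, report, top_entries, parent,
                                  margin, near_zero)
        _step8(fetcher, db, report, top_entries, parent, "1-2", margin,
               near_zero)
    elif n == 4:
        pass  # handled by _elucidate_tetra
    _finish_linear_structure(report, n)


def _collapse_entries(entries: list[ReferenceEntry]
                      ) -> tuple[Anomer, int, Anomer | None]:
    a, p, r = entries[0].slot
    if len(entries) == 1:
        return a, p, r
    return a, p, None   # dual reducing-anomer report


def _step8(fetcher: _Fetcher, db: ReferenceDB, report: ElucidationReport,
           known: list[ReferenceEntry], parent: int, target_bond: str,
           margin: float, near_zero: float) -> None:
    mixed = fetcher.get((parent, DISACCH))
    if mixed is None:
        report.undetermined.append(
            f"subtraction crosscheck unavailable; path "
            f"{_path_str((parent, DISACCH))} would provide it")
        return
    # the identified C-type component has one definite reducing anomer, so
    # the best single entry is subtracted, not the pair average
    sub = crosscheck_subtraction(mixed, known[:1], db, None, margin, near_zero)
    src = (f"subtraction crosscheck on {_path_str((parent, DISACCH))} "
           f"(weight {sub.weight:.2f})")
    if sub.no_second_component:
        _bond(report, target_bond).caveats.append(
            "subtraction residual near zero: no second disaccharide "
            "population observed")
        return
    # the residual is a Y-type disaccharide: a true mutarotation mixture
    mm = match_mutarotated(normalise(sub.residual), db, margin)
    if mm.decision is None:
        _bond(report, target_bond).caveats.append(
            "subtraction residual matched no fingerprint confidently")
        return
    a, p = mm.decision
    _apply_decision(report, target_bond, src, a, p)


def _interior_pentasaccharide(fetcher: _Fetcher, db: ReferenceDB,
                              report: ElucidationReport,
                              known45: list[ReferenceEntry], parent: int,
                              margin: float, near_zero: float) -> None:
    """Interior disaccharides of a linear pentasaccharide via the Y4 and Y3
    routes; each isolation co-selects the isobaric C-side species, so the
    already-identified nonreducing fingerprint is stripped first."""
    y4 = sodiated_mz(4)[1]
    y3 = sodiated_mz(3)[1]
    for sub_parent, bond_id, inherit_bond in ((y4, "3-4", "2-3"),
                                              (y3, "2-3", "1-2")):
        spec = fetcher.get((parent, sub_parent))
        if spec is None:
            report.undetermined.append(
                f"disaccharide for bond {bond_id} unavailable; path "
                f"{_path_str((parent, sub_parent))} would provide it")
            continue
        sub_losses = _loss_ions_by_intensity(spec, sub_parent)
        done = False
        for Lq in sub_losses:
            q = fetcher.get((parent, sub_parent, Lq, DISACCH))
            if q is None:
                continue
            path = (parent, sub_parent, Lq, DISACCH)
            sub = crosscheck_subtraction(q, known45, db, None, margin,
                                         near_zero)
            if sub.no_second_component:
                # mixture is pure known fingerprint: the interior
                # disaccharide equals the nonreducing one
                a, p, r = known45[0].slot
                r = r if len(known45) == 1 else None
                _apply_decision(report, bond_id,
                                f"{_path_str(path)} identical to the "
                                f"nonreducing fingerprint after subtraction",
                                a, p)
                if r is not None:
                    _apply_decision(report, inherit_bond,
                                    f"reducing anomer inherited from "
                                    f"{_path_str(path)}", r, None)
                done = True
                break
            bd = bond_decision(sub.match)
            if bd is not None:
                a, p, r = bd
                _apply_decision(report, bond_id,
                                f"DB match of the {_path_str(path)} residual",
                                a, p)
                if r is not None:
                    _apply_decision(report, inherit_bond,
                                    f"reducing anomer inherited from the "
                                    f"{_path_str(path)} residual match",
                                    r, None)
                done = True
                break
        if not done:
            report.undetermined.append(
                f"disaccharide for bond {bond_id} unmatched along the "
                f"{_path_str((parent, sub_parent))} routes")


def _finish_linear_structure(report: ElucidationReport, n: int) -> None:
    links = []
    for i in range(1, n):
        b = _bond(report, f"{i}-{i + 1}")
        if b.position is None:
            report.undetermined.append(f"bond {i}-{i + 1} position unknown")
            return
        links.append((b.anomer or Anomer.UNSPECIFIED, b.position))
    report.structure = linear_chain(links)


def _elucidate_branched_tri(fetcher: _Fetcher, db: ReferenceDB,
                            report: ElucidationReport,
                            hyp: LinkageHypothesis, parent: int,
                            margin: float, near_zero: float) -> None:
    hi, lo = hyp.reducing_linkages   # descending
    for pos in (hi, lo):
        b = _bond(report, f"1-branch(1→{pos})")
        b.position = pos
        b.add("MS2 loss pattern + branched-topology decision", None, pos)
    for c in hyp.caveats:
        report.caveats.append(c)

    mixed = fetcher.get((parent, DISACCH))
    if mixed is None:
        report.undetermined.append(
            f"branch disaccharides unavailable; path "
            f"{_path_str((parent, DISACCH))} would provide them")
        _finish_branched_structure(report, hi, lo)
        return
    # both branch disaccharides are Y-type (mutarotation mixtures)
    mm = match_mutarotated(mixed, db, margin)
    tentative = False
    if mm.decision is not None:
        a_m, p_m = mm.decision
        entries_m = mm.entries
    else:
        # comparable branch populations: no composite dominates; take the
        # best candidate on either branch linkage and demand that the
        # subtraction residual decisively names the other branch
        cands = [k for k, _ in mm.ranked if k[1] in (hi, lo)]
        if not cands:
            report.undetermined.append(
                "mixed branch-disaccharide spectrum matched no fingerprint")
            _finish_branched_structure(report, hi, lo)
            return
        a_m, p_m = cands[0]
        entries_m = [e for e in
                     (db.get((a_m, p_m, Anomer.ALPHA)),
                      db.get((a_m, p_m, Anomer.BETA))) if e is not None]
        tentative = True
    if p_m not in (hi, lo):
        report.caveats.append(
            f"dominant disaccharide linkage (1→{p_m}) does not match either "
            f"branch; assignment withheld")
        _finish_branched_structure(report, hi, lo)
        return
    other = lo if p_m == hi else hi

    # subtract the full mutarotation pair: a Y-type disaccharide carries
    # both reducing anomers
    sub = crosscheck_subtraction(mixed, entries_m, db, None, margin, near_zero)
    ob = _bond(report, f"1-branch(1→{other})")
    if tentative:
        # accept the tentative first component only if the residual
        # decisively names the other branch
        mm2 = (match_mutarotated(normalise(sub.residual), db, margin)
               if not sub.no_second_component else None)
        if mm2 is None or mm2.decision is None or mm2.decision[1] != other:
            report.undetermined.append(
                "mixed branch-disaccharide spectrum could not be "
                "deconvolved into the two branch fingerprints")
            _finish_branched_structure(report, hi, lo)
            return
        _apply_decision(report, f"1-branch(1→{p_m})",
                        f"DB match of {_path_str((parent, DISACCH))} "
                        f"(comparable branch populations)", a_m, p_m)
        _apply_decision(report, f"1-branch(1→{other})",
                        f"DB match of the subtraction residual of "
                        f"{_path_str((parent, DISACCH))}",
                        mm2.decision[0], other)
        _finish_branched_structure(report, hi, lo)
        return

    _apply_decision(report, f"1-branch(1→{p_m})",
                    f"DB match of {_path_str((parent, DISACCH))} "
                    f"(dominant branch)", a_m, p_m)
    if sub.no_second_component:
        ob.caveats.append(
            "subtraction residual near zero: almost no disaccharide from "
            "this branch is produced, so its anomeric configuration cannot "
            "be determined")
        report.caveats.append(
            f"only the (1→{other}) linkage is known for this branch; its "
            f"anomer is unspecified")
    else:
        mm2 = match_mutarotated(normalise(sub.residual), db, margin)
        if mm2.decision is not None and mm2.decision[1] == other:
            _apply_decision(report, f"1-branch(1→{other})",
                            f"DB match of the subtraction residual of "
                            f"{_path_str((parent, DISACCH))}",
                            mm2.decision[0], other)
        else:
            ob.caveats.append("subtraction residual did not match a "
                              "fingerprint of this branch's linkage")
    _finish_branched_structure(report, hi, lo)


def _finish_branched_structure(report: ElucidationReport, hi: int,
                               lo: int) -> None:
    children = []
    for pos in (lo, hi):
        b = _bond(report, f"1-branch(1→{pos})")
        anom = b.anomer or Anomer.UNSPECIFIED
        children.append((Linkage(anom, pos), Residue()))
    report.structure = GlycanStructure(Residue(children=tuple(children)))


def _elucidate_tetra(fetcher: _Fetcher, db: ReferenceDB,
                     report: ElucidationReport,
                     candidates: list[LinkageHypothesis],
                     ms2_pattern: LossPattern, loss_ions: list[int],
                     parent: int, margin: float, near_zero: float) -> None:
    loss_patterns: dict[int, LossPattern] = {}
    for L in loss_ions:
        pat = _pattern(fetcher, (parent, L), (527, 509, DISACCH, 347))
        if pat is not None:
            loss_patterns[L] = pat
    try:
        klass = classify_tetrasaccharide(ms2_pattern, loss_patterns)
    except UndeterminedTopologyError as exc:
        report.undetermined.append(str(exc))
        return
    report.topology = f"type {klass.roman}: {klass.description}"
    report.caveats.extend(klass.caveats)

    if klass.roman != "I":
        hyps = [h for h in candidates if h.topology == "branched"] or candidates
        for h in hyps:
            report.caveats.append(
                f"reducing-sugar linkage candidates: "
                f"({', '.join(f'1→{p}' for p in h.reducing_linkages)})")
        report.undetermined.append(
            "full assignment of branched tetrasaccharides extends beyond the "
            "worked decision scheme; topology and linkage candidates reported")
        return

    lin = [h for h in candidates if h.topology == "linear"]
    if not lin:
        report.undetermined.append(
            "loss pattern admits no linear assignment yet the topology test "
            "indicates a linear chain")
        return
    hyp = lin[0]
    hyp.set_status("confirmed")
    p1 = hyp.reducing_linkages[0]
    _apply_decision(report, "1-2", "MS2 loss pattern of the precursor",
                    None, p1)

    # nonreducing disaccharide {3,4}, then interior {2,3} one level deeper
    top_entries, top_path, consensus = _match_routes(
        fetcher, [(parent, L, DISACCH) for L in loss_ions], db, margin)
    if top_entries:
        used_L = top_path[1]
        a, p, r = _collapse_entries(top_entries)
        _apply_decision(report, "3-4", f"DB match of {_path_str(top_path)}",
                        a, p)
        if consensus:
            _bond(report, "3-4").caveats.append(consensus)
        if r is not None:
            _apply_decision(report, "2-3",
                            f"reducing anomer inherited from the "
                            f"{_path_str(top_path)} match", r, None)
    if not top_entries:
        report.undetermined.append(
            "nonreducing disaccharide unmatched; paths "
            + ", ".join(_path_str((parent, L, DISACCH)) for L in loss_ions)
            + " would decide")
        _finish_linear_structure(report, 4)
        return

    ordered = [used_L] + [x for x in loss_ions if x != used_L]
    entries23, path23, consensus23 = _match_routes(
        fetcher, [(parent, L, L - 162, DISACCH) for L in ordered], db, margin)
    if entries23:
        a, p, r = _collapse_entries(entries23)
        _apply_decision(report, "2-3", f"DB match of {_path_str(path23)}",
                        a, p)
        if consensus23:
            _bond(report, "2-3").caveats.append(consensus23)
        if r is not None:
            _apply_decision(report, "1-2",
                            f"reducing anomer inherited from the "
                            f"{_path_str(path23)} match", r, None)
    else:
        report.undetermined.append(
            "interior disaccharide (residues 2,3) unmatched along the "
            "loss-ion routes")

    _step8(fetcher, db, report, top_entries, parent, "1-2", margin, near_zero)
    _finish_linear_structure(report, 4)
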