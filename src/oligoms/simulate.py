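"""Ion-trap CID emulator for sodiated glucose oligosaccharides.

Produces MSⁿ spectral trees for a known structure under the low-energy
mechanism: glycosidic B/C/Y/Z cleavage at every bond, dehydration and
retro-aldol cross-ring cleavage only at the reducing ring (gated by the
linkage rule table), channel intensities controlled by a :class:`ChannelModel`.

Two physics rules drive structure readout and are encoded here:

* dehydration is fast when O1/O2 of the reducing ring are cis (α for glucose),
  slow when trans — the −18 intensity reads the reducing anomer;
* glycosidic cleavage is the analogous process at the glycosidic oxygen, so
  the glycosidic:other-channel ratio (and the B:C partition) reads the bond
  anomer.  C/Y products regenerate a reducing end; a C-type product inherits
  its new reducing anomer from the cleaved bond.

Isolation of a nominal m/z selects *every* isobaric product population, so a
daughter spectrum is the rate-weighted mixture of their CID spectra (the
527→365 case: co-isolated C₂ and Y₂ disaccharides).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .fragments import (LOSS_MASS, SODIUM, WATER, allowed_losses, sodiated_mz)
from .rules import AcquisitionPlan
from .spectra import DEFAULT_THRESHOLD, Spectrum, normalise
from .structures import Anomer, GlycanStructure, Linkage, Residue

__all__ = ["ChannelModel", "Ion", "Channel", "SpectralTree",
           "cid_channels", "simulate_cid", "simulate_tree", "TreeProvider"]


@dataclass(frozen=True)
class ChannelModel:
    """Branching-ratio and noise settings for one simulated instrument.

    Rates are relative (the spectrum is renormalised to its base peak); the
    defaults satisfy the ordinal constraints the mechanism imposes — cis ≫
    trans dehydration, α > β glycosidic share, the 1→6 dehydration channel
    weak, 1→2 dehydration minor — while keeping all sixteen disaccharide
    fingerprints mutually distinguishable.
    """

    # glycosidic channels (per bond)
    c_ion: float = 0.8
    y_ion: float = 0.5
    b_fraction_alpha: float = 0.55   # B (and Z) share relative to C (and Y)
    b_fraction_beta: float = 0.12
    glycosidic_alpha: float = 1.0    # overall bond-cleavage factor per anomer
    glycosidic_beta: float = 0.45
    # reducing-ring losses
    dehydration_cis: float = 2.2     # α reducing anomer (O1/O2 cis)
    dehydration_trans: float = 0.25
    dehydration_16_scale: float = 0.4   # 1→6-only reducing sugar: weak channel
    minor_dehydration_cis: float = 0.65  # 1→2 class (different, slower mechanism)
    minor_dehydration_trans: float = 0.04
    cross_60: float = 0.8
    cross_90: float = 0.7
    cross_120: float = 0.5
    x0_fraction: float = 0.3         # sodium retention on the X-side piece
    # branched structures: at a branch point the lowest-position bond cleaves
    # preferentially (24:1 ≈ a 96/4 product split); 1.0 makes branches symmetric
    branch_bias: float = 24.0
    # measurement noise
    noise_sigma: float = 0.0         # lognormal sigma per peak
    chemical_noise_peaks: int = 4    # random low-level peaks when noisy
    chemical_noise_level: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("c_ion", "y_ion", "glycosidic_alpha", "glycosidic_beta",
                     "dehydration_cis", "dehydration_trans",
                     "minor_dehydration_cis", "minor_dehydration_trans",
                     "cross_60", "cross_90", "cross_120"):
            if getattr(self, name) <= 0:
                raise ValueError(f"channel rate {name} must be positive")
        for name in ("b_fraction_alpha", "b_fraction_beta", "x0_fraction",
                     "dehydration_16_scale"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"ratio parameter {name} must be in (0, 1]")
        if self.noise_sigma < 0 or self.chemical_noise_level < 0:
            raise ValueError("noise parameters must be nonnegative")
        if self.branch_bias < 1:
            raise ValueError("branch_bias must be >= 1 (favours the lower position)")

    def with_noise(self, sigma: float = 0.15, seed: int = 0) -> "ChannelModel":
        return dataclasses.replace(self, noise_sigma=sigma, seed=seed)

    def _gly(self, anomer: Anomer) -> float:
        if anomer == Anomer.ALPHA:
            return self.glycosidic_alpha
        if anomer == Anomer.BETA:
            return self.glycosidic_beta
        return 0.5 * (self.glycosidic_alpha + self.glycosidic_beta)

    def _bfrac(self, anomer: Anomer) -> float:
        if anomer == Anomer.ALPHA:
            return self.b_fraction_alpha
        if anomer == Anomer.BETA:
            return self.b_fraction_beta
        return 0.5 * (self.b_fraction_alpha + self.b_fraction_beta)

    def _dehydration(self, anomer: Anomer, positions: frozenset[int],
                     minor: bool) -> float:
        cis, trans = ((self.minor_dehydration_cis, self.minor_dehydration_trans)
                      if minor else (self.dehydration_cis, self.dehydration_trans))
        if anomer == Anomer.ALPHA:
            base = cis
        elif anomer == Anomer.BETA:
            base = trans
        else:
            base = 0.5 * (cis + trans)
        if positions == frozenset({6}):
            base *= self.dehydration_16_scale
        return base

    def _cross(self, loss: str) -> float:
        return {"C2H4O2": self.cross_60, "C3H6O3": self.cross_90,
                "C4H8O4": self.cross_120}[loss]


@dataclass(frozen=True)
class Ion:
    """A sodiated species with known provenance: an intact (sub)glycan, or the
    same after a reducing-ring loss (dehydration, cross-ring, or the water
    lost in B/Z formation, which is mass-equivalent)."""

    structure: GlycanStructure
    loss: str = "none"

    def __post_init__(self) -> None:
        if self.loss not in LOSS_MASS:
            raise ValueError(f"unknown reducing-ring state {self.loss!r}")

    @property
    def size(self) -> int:
        return self.structure.size

    @property
    def mz_mono(self) -> float:
        return sodiated_mz(self.size, self.loss)[0]

    @property
    def mz_nominal(self) -> int:
        return sodiated_mz(self.size, self.loss)[1]


@dataclass(frozen=True)
class Channel:
    label: str
    mz_mono: float
    rate: float
    product: Ion | None      # None for terminal pieces (X0)


def _detach(res: Residue, index: int) -> tuple[Linkage, Residue, Residue]:
    """Remove child ``index`` from a residue: (linkage, subtree, remainder)."""
    lk, child = res.children[index]
    rest = Residue(children=res.children[:index] + res.children[index + 1:])
    return lk, child, rest


def _detach_at(root: Residue, path: tuple[int, ...], index: int
               ) -> tuple[Linkage, Residue, Residue]:
    if not path:
        return _detach(root, index)
    i, rest_path = path[0], path[1:]
    lk, sub, new_child = _detach_at(root.children[i][1], rest_path, index)
    children = list(root.children)
    children[i] = (children[i][0], new_child)
    return lk, sub, Residue(children=tuple(children))


def _bond_bias(parent: Residue, index: int, model: ChannelModel,
               is_root: bool) -> float:
    """Cleavage bias at the reducing-sugar branch point: the lowest-position
    branch bond breaks preferentially, so the surviving Y-type disaccharide
    carries mostly the other branch."""
    if not is_root or len(parent.children) < 2:
        return 1.0
    positions = [lk.position for lk, _ in parent.children]
    return model.branch_bias if positions[index] == min(positions) else 1.0


def cid_channels(ion: Ion, model: ChannelModel) -> list[Channel]:
    """All single-cleavage dissociation channels of one trapped species."""
    g = ion.structure
    n = g.size
    channels: list[Channel] = []
    if n < 2:
        return channels

    # glycosidic cleavage at every bond
    def walk(res: Residue, path: tuple[int, ...], root_struct: Residue) -> None:
        for idx in range(len(res.children)):
            lk, subtree, remainder = _detach_at(root_struct, path, idx)
            i, j = subtree.size, n - subtree.size
            gf = model._gly(lk.child_anomeric) * _bond_bias(res, idx, model,
                                                            is_root=not path)
            bf = model._bfrac(lk.child_anomeric)
            c_struct = GlycanStructure(subtree, lk.child_anomeric)
            y_struct = GlycanStructure(remainder, g.root_anomeric)
            c_mono = sodiated_mz(i, "none")[0]
            y_mono = sodiated_mz(j, "none")[0]
            channels.append(Channel(f"C{i}", c_mono, model.c_ion * gf,
                                    Ion(c_struct, "none")))
            channels.append(Channel(f"B{i}", c_mono - WATER,
                                    model.c_ion * gf * bf, Ion(c_struct, "H2O")))
            # Y/Z keep the reducing ring and any prior loss on it
            y_loss = ion.loss
            y_mz = y_mono - LOSS_MASS[y_loss]
            suffix = "" if y_loss == "none" else "'"
            channels.append(Channel(f"Y{j}{suffix}", y_mz, model.y_ion * gf,
                                    Ion(y_struct, y_loss)))
            if y_loss == "none":
                channels.append(Channel(f"Z{j}", y_mz - WATER,
                                        model.y_ion * gf * bf, Ion(y_struct, "H2O")))
            walk(res.children[idx][1], path + (idx,), root_struct)

    walk(g.root, (), g.root)

    # reducing-ring losses (intact species only; products of a loss do not
    # lose again within one CID stage)
    if ion.loss == "none":
        positions = g.reducing_positions
        major = allowed_losses(positions)
        from .fragments import MINOR_LOSSES
        minor = MINOR_LOSSES.get(positions, frozenset())
        for loss in sorted(major | minor):
            is_minor = loss in minor and loss not in major
            if loss == "H2O":
                rate = model._dehydration(g.root_anomeric, positions, is_minor)
                mono = sodiated_mz(n, "H2O")[0]
                channels.append(Channel("[M+Na-H2O]+", mono, rate, Ion(g, "H2O")))
                continue
            rate = model._cross(loss)
            a_mono = sodiated_mz(n, loss)[0]
            a_label = {"C2H4O2": "0,2A", "C3H6O3": "0,3A", "C4H8O4": "0,4A"}[loss]
            channels.append(Channel(f"{a_label}{n}", a_mono, rate, Ion(g, loss)))
            if len(positions) >= 2:
                # complementary sodiated ring piece for branched retro-aldol
                x_mono = LOSS_MASS[loss] + SODIUM
                x_label = a_label.replace("A", "X")
                channels.append(Channel(f"{x_label}0", x_mono,
                                        rate * model.x0_fraction, None))
    return channels


Populations = list[tuple[Ion, float]]


def _mixture_channels(populations: Populations, model: ChannelModel
                      ) -> list[Channel]:
    out: list[Channel] = []
    for ion, weight in populations:
        for ch in cid_channels(ion, model):
            out.append(Channel(ch.label, ch.mz_mono, ch.rate * weight, ch.product))
    return out


def _spectrum_from_channels(channels: list[Channel],
                            precursor_path: tuple[int, ...],
                            model: ChannelModel,
                            rng: np.random.Generator | None,
                            threshold: float) -> Spectrum:
    agg: dict[float, float] = {}
    for ch in channels:
        key = round(ch.mz_mono, 4)
        agg[key] = agg.get(key, 0.0) + ch.rate
    mz = np.array(sorted(agg))
    it = np.array([agg[m] for m in sorted(agg)])
    if model.noise_sigma > 0 and rng is not None and it.size:
        it = it * rng.lognormal(0.0, model.noise_sigma, size=it.shape)
        base = float(it.max())
        k = model.chemical_noise_peaks
        if k > 0 and precursor_path:
            lo, hi = 140.0, max(float(precursor_path[-1]) - 10.0, 160.0)
            noise_mz = rng.uniform(lo, hi, size=k)
            noise_it = rng.uniform(0.0, model.chemical_noise_level * base, size=k)
            mz = np.concatenate([mz, noise_mz])
            it = np.concatenate([it, noise_it])
    # the base-peak scale is kept so mixtures of separately normalised
    # spectra can be recombined in true intensity proportions
    meta = {"raw_base": float(it.max()) if it.size else 0.0}
    spec = Spectrum(mz, it, precursor_path, meta)
    if spec.is_empty():
        return spec
    return normalise(spec, threshold)


def _rng_for(model: ChannelModel, path: tuple[int, ...]) -> np.random.Generator:
    return np.random.default_rng([int(model.seed)] + [int(p) for p in path])


def simulate_cid(species: Ion | GlycanStructure | Populations,
                 model: ChannelModel | None = None,
                 precursor_path: tuple[int, ...] = (),
                 threshold: float = DEFAULT_THRESHOLD) -> Spectrum:
    """CID spectrum of one species (or a weighted isobaric mixture)."""
    model = model or ChannelModel()
    if isinstance(species, GlycanStructure):
        species = Ion(species, "none")
    if isinstance(species, Ion):
        populations: Populations = [(species, 1.0)]
    else:
        populations = list(species)
        if not populations:
            raise ValueError("empty species population")
    if not precursor_path:
        precursor_path = (populations[0][0].mz_nominal,)
    channels = _mixture_channels(populations, model)
    rng = _rng_for(model, precursor_path)
    return _spectrum_from_channels(channels, precursor_path, model, rng, threshold)


@dataclass
class SpectralTree:
    """MSⁿ spectra keyed by precursor path (nominal m/z)."""

    root_mz: int
    spectra: dict[tuple[int, ...], Spectrum] = field(default_factory=dict)

    def get(self, path: tuple[int, ...]) -> Spectrum | None:
        return self.spectra.get(tuple(int(p) for p in path))

    def paths(self) -> list[tuple[int, ...]]:
        return sorted(self.spectra, key=lambda p: (len(p), p))

    def validate(self) -> None:
        """Every non-root path's precursor must be a peak in its parent."""
        from .spectra import bin_nominal
        for path, spec in self.spectra.items():
            if len(path) < 2 or spec.metadata.get("unreachable"):
                continue
            parent = self.spectra.get(path[:-1])
            if parent is None:
                raise ValueError(f"orphan path {path}: parent spectrum missing")
            if parent.is_empty():
                raise ValueError(f"path {path}: parent spectrum is empty")
            if bin_nominal(parent).get(path[-1], 0.0) <= 0:
                raise ValueError(
                    f"path {path}: precursor {path[-1]} absent from parent")


def simulate_tree(g: GlycanStructure,
                  plan: AcquisitionPlan | None = None,
                  model: ChannelModel | None = None,
                  threshold: float = DEFAULT_THRESHOLD) -> SpectralTree:
    """Simulate every spectrum an acquisition plan requests.

    Isolating a nominal m/z carries over all isobaric product populations with
    their channel rates as weights; unreachable plan paths yield an empty
    spectrum tagged ``unreachable``.
    """
    model = model or ChannelModel()
    root_mz = sodiated_mz(g.size)[1]
    if plan is None:
        from .rules import decisive_ion_plan
        if g.size in (2, 3, 4, 5):
            plan = decisive_ion_plan(g.size)
        else:
            plan = AcquisitionPlan(g.size, root_mz, ())
    paths = sorted(set(plan.paths) | {(root_mz,)}, key=lambda p: (len(p), p))

    tree = SpectralTree(root_mz=root_mz)
    populations: dict[tuple[int, ...], Populations] = {
        (root_mz,): [(Ion(g, "none"), 1.0)]}

    for path in paths:
        pops = populations.get(path)
        if pops is None:
            tree.spectra[path] = Spectrum(np.array([]), np.array([]), path,
                                          {"unreachable": True})
            continue
        channels = _mixture_channels(pops, model)
        rng = _rng_for(model, path)
        tree.spectra[path] = _spectrum_from_channels(channels, path, model,
                                                     rng, threshold)
        # product populations for deeper isolations
        by_nominal: dict[int, Populations] = {}
        for ch in channels:
            if ch.product is None or ch.rate <= 0:
                continue
            by_nominal.setdefault(round(ch.mz_mono), []).append(
                (ch.product, ch.rate))
        for child in paths:
            if len(child) == len(path) + 1 and child[:-1] == path:
                sel = by_nominal.get(child[-1])
                if sel:
                    total = sum(w for _, w in sel)
                    merged: dict[Ion, float] = {}
                    for ion, w in sel:
                        merged[ion] = merged.get(ion, 0.0) + w / total
                    populations[child] = list(merged.items())
    return tree


class TreeProvider:
    """Spectrum provider backed by a simulated or recorded spectral tree.

    Repeated requests for the same path return the same spectrum; unreachable
    or empty spectra are reported as unavailable (None).
    """

    def __init__(self, tree: SpectralTree):
        self._tree = tree
        self.requested: list[tuple[int, ...]] = []

    def get(self, path: tuple[int, ...]) -> Spectrum | None:
        path = tuple(int(p) for p in path)
        self.requested.append(path)
        spec = self._tree.get(path)
        if spec is None or spec.is_empty() or spec.metadata.get("unreachable"):
            return None
        return spec
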