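"""Centroided spectrum container, normalisation, binning, cosine similarity
and the weighted spectral-subtraction crosscheck.

Spectra come from a unit-resolution ion trap, so nominal (integer) m/z bins
are the matching currency throughout; monoisotopic peak positions are kept in
the container.  Matching uses cosine similarity on nominal-binned, normalised
intensities (only the ranking drives decisions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Spectrum",
    "SimilarityScore",
    "EmptySpectrumError",
    "normalise",
    "bin_nominal",
    "similarity",
    "subtract",
    "DEFAULT_THRESHOLD",
    "DEFAULT_TOLERANCE",
]

DEFAULT_THRESHOLD = 0.01   # relative-intensity floor applied after normalisation
DEFAULT_TOLERANCE = 0.5    # u; unit-resolution binning window


class EmptySpectrumError(ValueError):
    pass


@dataclass
class Spectrum:
    """Centroided peak list with its MSⁿ precursor path (nominal m/z)."""

    mz: np.ndarray
    intensity: np.ndarray
    precursor_path: tuple[int, ...] = ()
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays must have the same length")
        if np.any(self.intensity < 0):
            raise ValueError("negative peak intensity")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]
        self.precursor_path = tuple(int(p) for p in self.precursor_path)

    @classmethod
    def from_peaks(cls, peaks, precursor_path=(), **metadata) -> "Spectrum":
        peaks = list(peaks)
        mz = [p[0] for p in peaks]
        it = [p[1] for p in peaks]
        return cls(np.array(mz, dtype=float), np.array(it, dtype=float),
                   tuple(precursor_path), dict(metadata))

    @property
    def peaks(self) -> list[tuple[float, float]]:
        return list(zip(self.mz.tolist(), self.intensity.tolist()))

    def __len__(self) -> int:
        return int(self.mz.size)

    def is_empty(self, eps: float = 0.0) -> bool:
        return self.mz.size == 0 or float(self.intensity.max(initial=0.0)) <= eps


@dataclass(frozen=True)
class SimilarityScore:
    value: float
    matched_peaks: int

    def __float__(self) -> float:
        return self.value


def normalise(s: Spectrum, threshold: float = DEFAULT_THRESHOLD) -> Spectrum:
    """Base peak to 1.0, then drop peaks below the relative threshold.

    Idempotent.  Raises :class:`EmptySpectrumError` on an all-zero spectrum.
    """
    if s.is_empty():
        raise EmptySpectrumError("cannot normalise an empty or all-zero spectrum")
    base = float(s.intensity.max())
    it = s.intensity / base
    keep = it >= threshold
    return Spectrum(s.mz[keep], it[keep], s.precursor_path, dict(s.metadata))


def bin_nominal(s: Spectrum, tolerance: float = DEFAULT_TOLERANCE) -> dict[int, float]:
    """Sum intensities of peaks falling within ``tolerance`` of each integer."""
    bins: dict[int, float] = {}
    for m, i in zip(s.mz, s.intensity):
        nominal = int(round(m))
        if abs(m - nominal) <= tolerance:
            bins[nominal] = bins.get(nominal, 0.0) + float(i)
    return bins


def _vectors(a: Spectrum, b: Spectrum,
             tolerance: float) -> tuple[np.ndarray, np.ndarray, int]:
    ba, bb = bin_nominal(a, tolerance), bin_nominal(b, tolerance)
    keys = sorted(set(ba) | set(bb))
    va = np.array([ba.get(k, 0.0) for k in keys])
    vb = np.array([bb.get(k, 0.0) for k in keys])
    matched = sum(1 for k in keys if ba.get(k, 0.0) > 0 and bb.get(k, 0.0) > 0)
    return va, vb, matched


def similarity(a: Spectrum, b: Spectrum,
               tolerance: float = DEFAULT_TOLERANCE) -> SimilarityScore:
    """Cosine similarity on nominal bins; symmetric, in [0, 1]."""
    if a.is_empty() or b.is_empty():
        raise EmptySpectrumError("similarity of an empty spectrum is undefined")
    va, vb, matched = _vectors(a, b, tolerance)
    denom = float(np.linalg.norm(va) * np.linalg.norm(vb))
    value = float(np.dot(va, vb) / denom) if denom > 0 else 0.0
    return SimilarityScore(min(max(value, 0.0), 1.0), matched)


def subtract(mixed: Spectrum, ref: Spectrum, zero_ion: int | None = None,
             tolerance: float = DEFAULT_TOLERANCE,
             weight_bound: float = 2.0) -> Spectrum:
    """Weighted subtraction ``mixed − w·ref`` used to strip a known component
    from a co-isolated isobaric mixture.

    ``w`` is chosen so the designated ``zero_ion`` has zero residual intensity.
    When ``zero_ion`` is None the bin with the smallest mixed/ref intensity
    ratio is used (ties broken towards the more intense reference ion), which
    nulls at least one ion and keeps the residual nonnegative.  Negative
    residuals are clipped to zero; the result is renormalised unless it is
    near zero everywhere (tagged ``near_zero``).
    """
    bm = bin_nominal(mixed, tolerance)
    br = bin_nominal(ref, tolerance)
    if zero_ion is None:
        candidates = [(bm.get(k, 0.0) / v, -v, k) for k, v in br.items() if v > 0]
        if not candidates:
            raise EmptySpectrumError("reference spectrum has no peaks")
        _, _, zero_ion = min(candidates)
    zero_ion = int(zero_ion)
    if br.get(zero_ion, 0.0) <= 0:
        raise ValueError(f"zero ion m/z {zero_ion} absent from the reference spectrum")
    w = bm.get(zero_ion, 0.0) / br[zero_ion]
    metadata = {"subtraction_weight": w, "zero_ion": zero_ion}
    if w > weight_bound:
        metadata["warning"] = f"subtraction weight {w:.3g} exceeds sanity bound"
    keys = sorted(set(bm) | set(br))
    residual = {k: max(bm.get(k, 0.0) - w * br.get(k, 0.0), 0.0) for k in keys}
    residual[zero_ion] = 0.0
    mz = np.array([float(k) for k in keys if residual[k] > 0])
    it = np.array([residual[k] for k in keys if residual[k] > 0])
    out = Spectrum(mz, it, mixed.precursor_path, metadata)
    top = float(it.max()) if it.size else 0.0
    base = max(bm.values(), default=0.0)
    if top <= 0.05 * max(base, 1e-12):
        out.metadata["near_zero"] = True
        return out
    out.intensity = out.intensity / top
    return out
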