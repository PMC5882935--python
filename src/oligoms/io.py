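"""File formats: MGF spectra/trees, MSP-like and JSON reference databases,
YAML run configuration.

Precursor paths are encoded in the MGF TITLE as ``p527>509>365`` so trees can
be grepped.  All writers use a fixed float policy (m/z ``repr``-faithful,
intensities likewise) so read(write(x)) reproduces the in-memory values
exactly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import yaml
from pyteomics import mgf as _mgf

from .refdb import ReferenceDB, ReferenceEntry, build_db
from .spectra import Spectrum
from .structures import parse_structure, serialise_structure
from .simulate import SpectralTree

__all__ = [
    "RunConfig", "load_config", "save_config",
    "write_mgf", "read_mgf", "tree_to_json", "tree_from_json",
    "write_tree_mgf", "read_tree_mgf",
    "db_to_msp", "db_from_msp", "db_to_json", "db_from_json",
]


@dataclasses.dataclass
class RunConfig:
    """Run parameters shared by the CLI commands; YAML-serialisable."""

    threshold: float = 0.01      # relative-intensity spectrum threshold
    tolerance: float = 0.5       # u, nominal binning window
    margin: float = 0.05         # similarity margin for a match decision
    seed: int = 0
    noise_sigma: float = 0.0
    channel_model: dict = dataclasses.field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    bad = set(data) - known
    if bad:
        raise ValueError(f"unknown config keys: {sorted(bad)}")
    return RunConfig(**data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


# ---------------------------------------------------------------------------
# MGF

def _title(path: tuple[int, ...]) -> str:
    return "p" + ">".join(str(p) for p in path)


def _parse_title(title: str) -> tuple[int, ...]:
    title = title.strip()
    if not title.startswith("p"):
        raise ValueError(f"MGF TITLE {title!r} does not encode a precursor path")
    return tuple(int(x) for x in title[1:].split(">"))


def _to_mgf_dict(spec: Spectrum) -> dict:
    params = {"title": _title(spec.precursor_path)}
    if spec.precursor_path:
        params["pepmass"] = float(spec.precursor_path[-1])
    if "raw_base" in spec.metadata:
        params["raw_base"] = repr(float(spec.metadata["raw_base"]))
    if spec.metadata.get("unreachable"):
        params["unreachable"] = "1"
    return {"m/z array": np.asarray(spec.mz),
            "intensity array": np.asarray(spec.intensity),
            "params": params}


def _from_mgf_dict(entry: dict) -> Spectrum:
    params = entry.get("params", {})
    path = _parse_title(str(params.get("title", "")))
    meta = {}
    if "raw_base" in params:
        meta["raw_base"] = float(params["raw_base"])
    if params.get("unreachable"):
        meta["unreachable"] = True
    return Spectrum(np.asarray(entry["m/z array"], dtype=float),
                    np.asarray(entry["intensity array"], dtype=float),
                    path, meta)


def write_mgf(spectra: list[Spectrum], path: str | Path) -> None:
    _mgf.write((_to_mgf_dict(s) for s in spectra), output=str(path),
               file_mode="w")


def read_mgf(path: str | Path) -> list[Spectrum]:
    with _mgf.read(str(path)) as reader:
        return [_from_mgf_dict(e) for e in reader]


def write_tree_mgf(tree: SpectralTree, path: str | Path) -> None:
    write_mgf([tree.spectra[p] for p in tree.paths()], path)


def read_tree_mgf(path: str | Path) -> SpectralTree:
    spectra = read_mgf(path)
    if not spectra:
        raise ValueError(f"no spectra in {path}")
    root = min((s.precursor_path for s in spectra), key=len)[0]
    return SpectralTree(root_mz=root,
                        spectra={s.precursor_path: s for s in spectra})


# ---------------------------------------------------------------------------
# spectral tree JSON

def tree_to_json(tree: SpectralTree) -> str:
    return json.dumps({
        "root_mz": tree.root_mz,
        "spectra": [{
            "path": list(p),
            "peaks": [[m, i] for m, i in tree.spectra[p].peaks],
            "metadata": {k: v for k, v in tree.spectra[p].metadata.items()},
        } for p in tree.paths()],
    }, indent=1)


def tree_from_json(text: str) -> SpectralTree:
    data = json.loads(text)
    spectra = {}
    for block in data["spectra"]:
        path = tuple(int(x) for x in block["path"])
        peaks = block["peaks"]
        spectra[path] = Spectrum(
            np.array([p[0] for p in peaks], dtype=float),
            np.array([p[1] for p in peaks], dtype=float),
            path, dict(block.get("metadata", {})))
    return SpectralTree(root_mz=int(data["root_mz"]), spectra=spectra)


# ---------------------------------------------------------------------------
# reference DB: MSP-like flat text and JSON

def _entry_comment(e: ReferenceEntry) -> str:
    parts = [f"provenance={e.provenance}"]
    if "raw_base" in e.spectrum.metadata:
        parts.append(f"raw_base={repr(float(e.spectrum.metadata['raw_base']))}")
    return " ".join(parts)


def db_to_msp(db: ReferenceDB, path: str | Path) -> None:
    lines: list[str] = []
    for e in sorted(db, key=lambda e: (e.slot[1], e.slot[0].value,
                                       e.slot[2].value)):
        lines.append(f"Name: {e.common_name or e.label}")
        lines.append(f"Structure: {e.label}")
        lines.append(f"Comment: {_entry_comment(e)}")
        lines.append(f"Num Peaks: {len(e.spectrum)}")
        for m, i in e.spectrum.peaks:
            lines.append(f"{m!r} {i!r}")
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")


def db_from_msp(path: str | Path) -> ReferenceDB:
    entries: list[ReferenceEntry] = []
    block: dict = {}
    peaks: list[tuple[float, float]] = []

    def flush() -> None:
        if not block:
            return
        comment = dict(kv.split("=", 1) for kv in
                       block.get("comment", "").split() if "=" in kv)
        meta = {}
        if "raw_base" in comment:
            meta["raw_base"] = float(comment["raw_base"])
        spec = Spectrum(np.array([p[0] for p in peaks]),
                        np.array([p[1] for p in peaks]), (), meta)
        entries.append(ReferenceEntry(
            structure=parse_structure(block["structure"]),
            spectrum=spec,
            common_name=block.get("name"),
            provenance=comment.get("provenance", "measured")))

    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if not line:
            flush()
            block, peaks = {}, []
            continue
        if ":" in line and not line[0].isdigit():
            key, _, value = line.partition(":")
            block[key.strip().lower()] = value.strip()
        else:
            m, i = line.split()
            peaks.append((float(m), float(i)))
    flush()
    return build_db(entries)


def db_to_json(db: ReferenceDB) -> str:
    return json.dumps({
        "entries": [{
            "structure": e.label,
            "common_name": e.common_name,
            "provenance": e.provenance,
            "peaks": [[m, i] for m, i in e.spectrum.peaks],
            "metadata": dict(e.spectrum.metadata),
        } for e in sorted(db, key=lambda e: (e.slot[1], e.slot[0].value,
                                             e.slot[2].value))],
    }, indent=1, ensure_ascii=False)


def db_from_json(text: str) -> ReferenceDB:
    data = json.loads(text)
    entries = []
    for b in data["entries"]:
        peaks = b["peaks"]
        spec = Spectrum(np.array([p[0] for p in peaks]),
                        np.array([p[1] for p in peaks]), (),
                        dict(b.get("metadata", {})))
        entries.append(ReferenceEntry(
            structure=parse_structure(b["structure"]),
            spectrum=spec,
            common_name=b.get("common_name"),
            provenance=b.get("provenance", "measured")))
    return build_db(entries)


def load_db(path: str | Path) -> ReferenceDB:
    """Load a reference DB, sniffing MSP-like text vs JSON."""
    text = Path(path).read_text(encoding="utf-8")
    if text.lstrip().startswith("{"):
        return db_from_json(text)
    return db_from_msp(path)


def serialise_entry_label(e: ReferenceEntry) -> str:
    return serialise_structure(e.structure)
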