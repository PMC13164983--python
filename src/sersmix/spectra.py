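"""Spectrum container and plain-text I/O.

A spectrum is a pair of aligned 1-D arrays: a strictly increasing wavenumber
axis (cm^-1) and nonnegative-or-real intensities (arbitrary units).  Files are
two-column delimited text with a header line, ascending wavenumber.  Dataset
manifests are JSON arrays of ``{path, category, split}`` records.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

#: canonical single-component labels, in canonical order
COMPONENTS = ("A", "B", "C")

#: all seven recognisable categories (sets encoded as sorted label strings)
CATEGORIES = ("A", "B", "C", "AB", "AC", "BC", "ABC")

#: the four mixture categories used in mixture-only evaluation
MIXTURE_CATEGORIES = ("AB", "AC", "BC", "ABC")

SPLITS = ("train", "val", "test")


def category_to_set(category: str) -> frozenset[str]:
    """Map a category token like ``"AC"`` to the component set ``{A, C}``."""
    if category not in CATEGORIES:
        raise ValueError(f"unknown category token {category!r}")
    return frozenset(category)


def set_to_category(s: Sequence[str] | frozenset[str]) -> str:
    """Map a component set to its canonical sorted token, e.g. ``{C, A} -> "AC"``."""
    members = sorted(set(s))
    unknown = [m for m in members if m not in COMPONENTS]
    if unknown or not members:
        raise ValueError(f"invalid component set {s!r}")
    return "".join(members)


@dataclass
class Spectrum:
    """One spectrum: wavenumber axis (cm^-1) and intensities."""

    wavenumber: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.wavenumber = np.asarray(self.wavenumber, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavenumber.ndim != 1 or self.wavenumber.shape != self.intensity.shape:
            raise ValueError("wavenumber and intensity must be equal-length 1-D arrays")
        if self.wavenumber.size >= 2 and not np.all(np.diff(self.wavenumber) > 0):
            raise ValueError("wavenumber axis must be strictly increasing")

    def __len__(self) -> int:
        return self.wavenumber.size

    def copy(self) -> "Spectrum":
        return Spectrum(self.wavenumber.copy(), self.intensity.copy())


@dataclass
class ManifestRecord:
    path: str
    category: str
    split: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category token {self.category!r}")
        if self.split not in SPLITS:
            raise ValueError(f"unknown split token {self.split!r}")


@dataclass
class DatasetManifest:
    """Ordered collection of (path, category, split) records.

    The training split may contain only pure categories; this is validated on
    construction because mixture spectra must never reach the optimiser.
    """

    records: list[ManifestRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        for r in self.records:
            if r.split == "train" and len(r.category) > 1:
                raise ValueError(
                    f"protocol violation: mixture category {r.category!r} in train split"
                )

    def __iter__(self) -> Iterator[ManifestRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, split: str | None = None, category: str | None = None) -> "DatasetManifest":
        recs = [
            r
            for r in self.records
            if (split is None or r.split == split)
            and (category is None or r.category == category)
        ]
        return DatasetManifest(recs)


def write_spectrum(path: str | Path, s: Spectrum) -> None:
    df = pd.DataFrame({"wavenumber_cm-1": s.wavenumber, "intensity": s.intensity})
    df.to_csv(path, index=False, float_format="%.9g")


def read_spectrum(path: str | Path) -> Spectrum:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"cannot parse spectrum file {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (wavenumber, intensity)")
    wn = df.iloc[:, 0].to_numpy(dtype=float)
    it = df.iloc[:, 1].to_numpy(dtype=float)
    bad = np.flatnonzero(~(np.isfinite(wn) & np.isfinite(it)))
    if bad.size:
        # +2: one for the header line, one for 1-based numbering
        raise ValueError(f"{path}: malformed row at line {bad[0] + 2}")
    if wn.size >= 2 and not np.all(np.diff(wn) > 0):
        raise ValueError(f"{path}: wavenumber axis not strictly increasing")
    return Spectrum(wn, it)


def write_manifest(path: str | Path, manifest: DatasetManifest) -> None:
    payload = [
        {"path": r.path, "category": r.category, "split": r.split} for r in manifest
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_manifest(path: str | Path) -> DatasetManifest:
    payload = json.loads(Path(path).read_text())
    records = [ManifestRecord(d["path"], d["category"], d["split"]) for d in payload]
    return DatasetManifest(records)
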