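"""Synthetic SERS spectrum generator for a three-pesticide system.

Emulates surface-enhanced Raman spectra of paraquat (A), thiram (B) and
tricyclazole (C) and their binary/ternary mixtures.  Pure-component peak
positions follow the literature band assignments for the three compounds;
replicate-to-replicate variability, signal-enhancement disparity between
compounds, non-linear mixing with peak masking (competitive adsorption),
fluorescence/drift baselines and detector noise are modelled statistically so
that every downstream stage (preprocessing, training, two-stage inference) can
be exercised without instrument data.

Mixtures are *not* simple linear superpositions: a strongly enhancing
component suppresses the bands of a weaker co-adsorbed component, both
globally (competitive adsorption) and locally where bands overlap within one
linewidth.  ``masking_strength = 0`` recovers the exact linear-mixing limit.

All randomness is driven by named, independent streams derived from a single
seed, so a dataset is bit-reproducible from ``(config, seed)`` and a
zero-weight component never perturbs the draws of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .spectra import (
    COMPONENTS,
    CATEGORIES,
    DatasetManifest,
    ManifestRecord,
    Spectrum,
    category_to_set,
    set_to_category,
    write_manifest,
    write_spectrum,
)

# literature characteristic band positions (cm^-1) of the three compounds;
# the starred position is the reference band used for replicate-RSD checks
_PEAK_POSITIONS = {
    "A": [840, 1029, 1190, 1298, 1646, 1766],  # paraquat, ref 840
    "B": [560, 932, 1380, 1512],               # thiram, ref 1380
    "C": [596, 988, 1000, 1090, 1193, 1303, 1403, 1420, 1589],  # tricyclazole, ref 1589
}
_REFERENCE_PEAK = {"A": 840, "B": 1380, "C": 1589}

_COMP_INDEX = {c: i for i, c in enumerate(COMPONENTS)}

# stream tags for the per-purpose RNG fan-out
_STREAM_LIB, _STREAM_COMP, _STREAM_ENV, _STREAM_WEIGHT = 0, 1, 2, 3


@dataclass
class PeakLibrary:
    """Characteristic peaks of one pure compound.

    Each peak is ``(center cm^-1, relative amplitude in (0, 1], FWHM cm^-1)``;
    exactly one peak (the reference band) has relative amplitude 1.
    """

    component: str
    peaks: list[tuple[float, float, float]]

    def __post_init__(self) -> None:
        if self.component not in COMPONENTS:
            raise ValueError(f"unknown component label {self.component!r}")
        if not self.peaks:
            raise ValueError(f"peak library for {self.component} is empty")
        centers = [p[0] for p in self.peaks]
        if any(c2 <= c1 for c1, c2 in zip(centers, centers[1:])):
            raise ValueError("peak centers must be strictly increasing")
        if any(not (400.0 <= c <= 1900.0) for c in centers):
            raise ValueError("peak centers must lie within [400, 1900] cm^-1")
        amps = [p[1] for p in self.peaks]
        if any(a <= 0 for a in amps):
            raise ValueError("peak amplitudes must be positive")
        if not any(abs(a - 1.0) < 1e-12 for a in amps):
            raise ValueError("library needs a reference peak with amplitude 1")

    @property
    def centers(self) -> np.ndarray:
        return np.array([p[0] for p in self.peaks], dtype=float)


@dataclass
class BaselineConfig:
    """Additive background: order-2 polynomial drift + one broad fluorescence hump.

    Amplitudes are fractions of the noiseless signal maximum; setting them all
    to zero disables the baseline entirely.
    """

    poly_order: int = 2
    poly_coeff_range: float = 0.15
    hump_amplitude: tuple[float, float] = (0.2, 0.6)
    hump_center: tuple[float, float] = (800.0, 1400.0)
    hump_fwhm: tuple[float, float] = (300.0, 600.0)

    def is_zero(self) -> bool:
        return self.poly_coeff_range == 0 and self.hump_amplitude[1] == 0


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic dataset.

    ``amplitude_jitter_rsd`` matches the ~8% replicate RSD observed for the
    compounds' reference bands; ``enhancement`` encodes the strong
    paraquat-dominant SERS response (A : B : C = 3 : 1.5 : 1).
    """

    axis_start: float = 400.0
    axis_end: float = 1900.0
    axis_step: float = 1.0
    peak_shape: str = "lorentzian"
    amplitude_jitter_rsd: float = 0.08
    shift_jitter: float = 2.0
    baseline: BaselineConfig = field(default_factory=BaselineConfig)
    noise_sd: float = 0.01
    enhancement: dict[str, float] = field(
        default_factory=lambda: {"A": 3.0, "B": 1.5, "C": 1.0}
    )
    masking_strength: float = 0.6
    seed: int = 0
    libraries: dict[str, PeakLibrary] | None = None

    def __post_init__(self) -> None:
        if not (self.axis_start < 500.0 < 1800.0 < self.axis_end):
            raise ValueError("raw axis must strictly contain the 500-1800 cm^-1 region")
        if self.peak_shape not in ("lorentzian", "gaussian"):
            raise ValueError(f"unknown peak shape {self.peak_shape!r}")
        if self.amplitude_jitter_rsd < 0 or self.shift_jitter < 0 or self.noise_sd < 0:
            raise ValueError("jitter and noise magnitudes must be nonnegative")
        if not (0.0 <= self.masking_strength <= 1.0):
            raise ValueError("masking_strength must lie in [0, 1]")
        if self.libraries is None:
            self.libraries = default_libraries(self.seed)

    def axis(self) -> np.ndarray:
        n = int(round((self.axis_end - self.axis_start) / self.axis_step)) + 1
        return self.axis_start + self.axis_step * np.arange(n)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["libraries"] = {
            c: [list(p) for p in lib.peaks] for c, lib in self.libraries.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        d = dict(d)
        if isinstance(d.get("baseline"), Mapping):
            b = dict(d["baseline"])
            for k in ("hump_amplitude", "hump_center", "hump_fwhm"):
                if k in b:
                    b[k] = tuple(b[k])
            d["baseline"] = BaselineConfig(**b)
        if d.get("libraries") is not None:
            d["libraries"] = {
                c: PeakLibrary(c, [tuple(p) for p in peaks])
                for c, peaks in d["libraries"].items()
            }
        return cls(**d)


def default_libraries(seed: int = 0) -> dict[str, PeakLibrary]:
    """Build the three default peak libraries.

    Band positions are the literature assignments; relative amplitudes are not
    tabulated there, so they are drawn once (deterministically from ``seed``) from
    U[0.3, 1.0] with the reference band fixed at 1.0, and Lorentzian FWHMs from
    U[8, 16] cm^-1 (typical solution-phase SERS linewidths).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _STREAM_LIB]))
    libs = {}
    for comp in COMPONENTS:
        centers = _PEAK_POSITIONS[comp]
        ref = _REFERENCE_PEAK[comp]
        peaks = []
        for c in centers:
            amp = 1.0 if c == ref else float(rng.uniform(0.3, 1.0))
            fwhm = float(rng.uniform(8.0, 16.0))
            peaks.append((float(c), amp, fwhm))
        libs[comp] = PeakLibrary(comp, peaks)
    return libs


def _kernel(axis: np.ndarray, center: float, amp: float, fwhm: float, shape: str) -> np.ndarray:
    if shape == "lorentzian":
        half = fwhm / 2.0
        return amp / (1.0 + ((axis - center) / half) ** 2)
    # gaussian parameterised by FWHM
    return amp * np.exp(-4.0 * np.log(2.0) * ((axis - center) / fwhm) ** 2)


def _peak_sum(axis: np.ndarray, peaks: Sequence[tuple[float, float, float]], shape: str) -> np.ndarray:
    out = np.zeros_like(axis)
    for c, a, w in peaks:
        out += _kernel(axis, c, a, w, shape)
    return out


def component_profile(library: PeakLibrary, config: GeneratorConfig) -> Spectrum:
    """Noiseless ideal profile of one compound on the raw axis.

    The peak-kernel sum is rescaled so its maximum equals the component's
    enhancement factor.
    """
    axis = config.axis()
    for c, _, _ in library.peaks:
        if not (config.axis_start <= c <= config.axis_end):
            raise ValueError(
                f"peak at {c} cm^-1 of component {library.component} lies outside "
                f"the axis [{config.axis_start}, {config.axis_end}]"
            )
    y = _peak_sum(axis, library.peaks, config.peak_shape)
    y *= config.enhancement[library.component] / y.max()
    return Spectrum(axis, y)


def _stream(config: GeneratorConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), *map(int, key)]))


def _profile_norm(library: PeakLibrary, config: GeneratorConfig) -> float:
    """Normalisation constant of the ideal (unjittered) kernel sum."""
    return float(_peak_sum(config.axis(), library.peaks, config.peak_shape).max())


def _jittered_peaks(library: PeakLibrary, config: GeneratorConfig, index: int) -> list[tuple[float, float, float]]:
    """One replicate realisation of a component's peak list."""
    rng = _stream(config, _STREAM_COMP, _COMP_INDEX[library.component], index)
    peaks = []
    for c, a, w in library.peaks:
        amp = a * max(1e-3, 1.0 + config.amplitude_jitter_rsd * rng.standard_normal())
        center = c + rng.uniform(-config.shift_jitter, config.shift_jitter)
        peaks.append((center, amp, w))
    return peaks


def _apply_masking(
    jittered: dict[str, list[tuple[float, float, float]]],
    intensity: dict[str, float],
    masking_strength: float,
) -> dict[str, list[tuple[float, float, float]]]:
    """Attenuate bands of weaker components in a mixture.

    ``intensity`` is each component's effective signal level (weight x
    enhancement).  For every stronger/weaker pair the weaker component's bands
    are attenuated globally (competitive adsorption) and additionally where a
    band falls within one FWHM of a stronger component's band.  The dominance
    factor maps the intensity ratio r >= 1 to (r - 1)/r in [0, 1), so equal
    partners do not mask each other and the attenuation saturates as one
    component overwhelms the other.
    """
    if masking_strength == 0:
        return jittered
    out = {comp: [list(p) for p in peaks] for comp, peaks in jittered.items()}
    comps = list(jittered)
    for strong in comps:
        for weak in comps:
            if strong == weak or intensity[weak] <= 0:
                continue
            if intensity[strong] <= intensity[weak]:
                continue
            r = intensity[strong] / intensity[weak]
            dominance = (r - 1.0) / r
            global_factor = 1.0 - 0.5 * masking_strength * dominance
            local_factor = 1.0 - masking_strength * dominance
            for q in out[weak]:
                q[1] *= global_factor
                for cs, _, ws in jittered[strong]:
                    if abs(q[0] - cs) <= ws:
                        q[1] *= local_factor
                        break
    return {comp: [tuple(p) for p in peaks] for comp, peaks in out.items()}


def _baseline(config: GeneratorConfig, rng: np.random.Generator, signal_max: float) -> np.ndarray:
    axis = config.axis()
    b = config.baseline
    t = (axis - config.axis_start) / (config.axis_end - config.axis_start)
    coeffs = rng.uniform(-b.poly_coeff_range, b.poly_coeff_range, size=b.poly_order + 1)
    if b.poly_coeff_range > 0:
        coeffs[0] = abs(coeffs[0])  # keep the drift predominantly positive
    poly = signal_max * np.polynomial.polynomial.polyval(t, coeffs)
    amp = rng.uniform(*b.hump_amplitude) * signal_max
    center = rng.uniform(*b.hump_center)
    fwhm = rng.uniform(*b.hump_fwhm)
    hump = _kernel(axis, center, amp, fwhm, "gaussian")
    return np.clip(poly, 0.0, None) + hump


def _synthesize(
    members: Sequence[str],
    weights: Mapping[str, float],
    config: GeneratorConfig,
    index: int,
) -> Spectrum:
    """Shared realisation path for pure spectra and mixtures."""
    axis = config.axis()
    jittered = {c: _jittered_peaks(config.libraries[c], config, index) for c in members}
    intensity = {c: weights[c] * config.enhancement[c] for c in members}
    jittered = _apply_masking(jittered, intensity, config.masking_strength)
    y = np.zeros_like(axis)
    for c in members:
        if weights[c] == 0:
            continue
        scale = intensity[c] / _profile_norm(config.libraries[c], config)
        y += scale * _peak_sum(axis, jittered[c], config.peak_shape)
    env = _stream(config, _STREAM_ENV, index)
    signal_max = float(y.max()) if y.max() > 0 else 1.0
    if not config.baseline.is_zero():
        y = y + _baseline(config, env, signal_max)
    else:
        _baseline(config, env, signal_max)  # keep the stream position aligned
    if config.noise_sd > 0:
        y = y + config.noise_sd * signal_max * env.standard_normal(axis.size)
    return Spectrum(axis, y)


def generate_pure(component: str, n: int, config: GeneratorConfig, start_index: int = 0) -> list[Spectrum]:
    """``n`` replicate spectra of one pure compound.

    Replicates differ by per-band amplitude jitter (lognormal-like, RSD set by
    ``amplitude_jitter_rsd``), band-position jitter, a fresh baseline and
    additive noise.  Deterministic given ``(config.seed, start_index)``.
    """
    if component not in COMPONENTS:
        raise ValueError(f"unknown component label {component!r}")
    if n < 1:
        raise ValueError("n must be >= 1")
    return [
        _synthesize((component,), {component: 1.0}, config, start_index + i)
        for i in range(n)
    ]


def generate_mixture(
    S: Sequence[str] | frozenset[str],
    weights: Sequence[float],
    config: GeneratorConfig,
    index: int = 0,
) -> Spectrum:
    """One mixture spectrum over component set ``S`` with nonnegative weights."""
    members = sorted(set(S))
    if len(members) < 2:
        raise ValueError("a mixture needs at least two components")
    weights = np.asarray(list(weights), dtype=float)
    if weights.shape != (len(members),):
        raise ValueError("one weight per component required")
    if np.any(weights < 0):
        raise ValueError("mixture weights must be nonnegative")
    if not np.any(weights > 0):
        raise ValueError("mixture weights must not all be zero")
    wmap = dict(zip(members, weights))
    return _synthesize(members, wmap, config, index)


#: per-category default counts mirroring the pure/mixture split protocol:
#: mixtures appear only in validation and test
DEFAULT_TRAIN_SIZES = {"A": 157, "B": 215, "C": 220}
DEFAULT_VAL_SIZE = 50
DEFAULT_TEST_SIZE = 53


def default_sizes() -> dict[str, dict[str, int]]:
    sizes: dict[str, dict[str, int]] = {"train": dict(DEFAULT_TRAIN_SIZES)}
    sizes["val"] = {c: DEFAULT_VAL_SIZE for c in CATEGORIES}
    sizes["test"] = {c: DEFAULT_TEST_SIZE for c in CATEGORIES}
    return sizes


def _mixture_weights(members: Sequence[str], config: GeneratorConfig, index: int) -> np.ndarray:
    """Nominally equal mixing with ±20% pipetting-level variability."""
    rng = _stream(config, _STREAM_WEIGHT, index)
    w = rng.uniform(0.8, 1.2, size=len(members)) / len(members)
    return w


def iter_dataset(
    config: GeneratorConfig,
    sizes: Mapping[str, Mapping[str, int]] | None = None,
):
    """Yield ``(Spectrum, category, split, within-category index)`` records.

    Default sizes: train = 157/215/220 pure A/B/C spectra only; validation and
    test cover all seven categories with 50 and 53 spectra per category.
    Requesting a mixture category in the training split is a protocol
    violation and raises.
    """
    if sizes is None:
        sizes = default_sizes()
    for split in ("train", "val", "test"):
        for category in sizes.get(split, {}):
            if category not in CATEGORIES:
                raise ValueError(f"unknown category token {category!r}")
            if int(sizes[split][category]) < 0:
                raise ValueError("sizes must be positive")
            members = sorted(category_to_set(category))
            if split == "train" and len(members) > 1:
                raise ValueError(
                    f"protocol violation: mixture category {category} requested in train split"
                )
    index = 0  # global replicate counter -> unique RNG streams per spectrum
    for split in ("train", "val", "test"):
        for category in CATEGORIES:
            n = int(sizes.get(split, {}).get(category, 0))
            for i in range(n):
                members = sorted(category_to_set(category))
                if len(members) == 1:
                    s = _synthesize(members, {members[0]: 1.0}, config, index)
                else:
                    w = _mixture_weights(members, config, index)
                    s = _synthesize(members, dict(zip(members, w)), config, index)
                yield s, category, split, i
                index += 1


def generate_dataset(
    config: GeneratorConfig,
    out_dir: str | Path,
    sizes: Mapping[str, Mapping[str, int]] | None = None,
) -> DatasetManifest:
    """Write a full train/val/test dataset of spectrum files plus manifest."""
    out_dir = Path(out_dir)
    (out_dir / "spectra").mkdir(parents=True, exist_ok=True)
    records: list[ManifestRecord] = []
    for s, category, split, i in iter_dataset(config, sizes):
        rel = f"spectra/{split}_{category}_{i:04d}.csv"
        write_spectrum(out_dir / rel, s)
        records.append(ManifestRecord(rel, category, split))
    manifest = DatasetManifest(records)
    write_manifest(out_dir / "manifest.json", manifest)
    return manifest
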