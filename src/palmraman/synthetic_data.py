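"""Synthetic oil-palm exocarp Raman spectra with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a smooth fluorescence baseline, additive Gaussian detector noise and
Gaussian vibrational bands in the 1240-1360 cm^-1 fingerprint window whose
class-dependent amplitudes reproduce the published ripening trends — protein
(amide III), beta-carotene, carotene, lipid and guanine/cytosine intensities
rising with ripeness, chlorophyll-a absent or decreasing, tryptophan peaking
at the ripe stage.  Two component libraries are provided: ``sample_A`` (four
ripeness classes, intensities taken verbatim from the study's first cohort)
and ``sample_B`` (three classes, 13/19/15 fruits, proportional class gains
calibrated from the carotene band means 334/568/750 a.u.).  ``full_range``
additionally places chlorophyll-a bands at 744/915/986 cm^-1 for
reference-peak location tests on the raw 700-1400 cm^-1 spectrum.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .preprocess import RamanSpectrum

CLASSES_A: Tuple[str, ...] = ("unripe", "under_ripe", "ripe", "over_ripe")
CLASSES_B: Tuple[str, ...] = ("under_ripe", "ripe", "over_ripe")

#: class gains of the proportional bands, anchored on the under-ripe class
#: (carotene P8 class means 333.58 / 568.25 / 749.75 -> 1.00 / 1.70 / 2.25)
GAINS_B: Dict[str, float] = {"under_ripe": 1.00, "ripe": 1.70, "over_ripe": 2.25}

#: default Gaussian width of every band component (cm^-1);
#: FWHM ~ 11.8 cm^-1, overlapping enough that the P5/P6/P7 cluster
#: needs deconvolution at a 0.5 cm^-1 grid
DEFAULT_SIGMA: float = 5.0

DEFAULT_GRID: Tuple[float, float, float] = (700.0, 1400.0, 0.5)

_SQ2PI = float(np.sqrt(2.0 * np.pi))


@dataclass(frozen=True)
class ComponentSpec:
    """One vibrational band of the generative model.

    ``center_by_class`` / ``amplitude_by_class`` give the population mean
    position (cm^-1) and intensity (a.u.) per ripeness class; an amplitude of
    zero means the band is absent in that class.  ``center_jitter_sd`` (cm^-1)
    and ``amplitude_cv`` (dimensionless) are the between-sample variabilities.
    """

    label: str
    assignment: str
    center_by_class: Dict[str, float]
    amplitude_by_class: Dict[str, float]
    width_sigma: float = DEFAULT_SIGMA
    center_jitter_sd: float = 0.5
    amplitude_cv: float = 0.05
    width_cv: float = 0.06

    def __post_init__(self):
        if self.width_sigma <= 0:
            raise ValueError(f"{self.label}: width_sigma must be positive")
        if self.amplitude_cv < 0 or self.center_jitter_sd < 0 or self.width_cv < 0:
            raise ValueError(f"{self.label}: variabilities must be non-negative")
        if any(a < 0 for a in self.amplitude_by_class.values()):
            raise ValueError(f"{self.label}: amplitudes must be non-negative")


@dataclass(frozen=True)
class BaselineSpec:
    """Smooth additive background: a polynomial plus broad Gaussian humps.

    ``poly_coeffs`` are ascending-power coefficients in the centred variable
    ``(x - poly_center)``; ``humps`` are ``(center, amplitude, sigma)`` triples
    of very broad Gaussians mimicking fluorescence.
    """

    poly_coeffs: Tuple[float, ...] = (60.0, -0.02, 1.5e-5)
    poly_center: float = 1050.0
    humps: Tuple[Tuple[float, float, float], ...] = ((1150.0, 150.0, 300.0),)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        u = x - self.poly_center
        y = np.polynomial.polynomial.polyval(u, self.poly_coeffs)
        for c, a, s in self.humps:
            y = y + a * np.exp(-0.5 * ((x - c) / s) ** 2)
        if not np.all(np.isfinite(y)) or np.any(y < 0):
            raise ValueError("baseline must be finite and non-negative on the grid")
        return y


ZERO_BASELINE = BaselineSpec(poly_coeffs=(0.0,), humps=())
DEFAULT_BASELINE = BaselineSpec()


def _bands_b() -> List[ComponentSpec]:
    """Sample-B library: three classes, proportional gains on P1-P5, P8."""
    g = GAINS_B

    def prop(base: float) -> Dict[str, float]:
        return {c: base * g[c] for c in CLASSES_B}

    def flat(center: float) -> Dict[str, float]:
        return {c: center for c in CLASSES_B}

    return [
        ComponentSpec("P1", "proteins, amide III (beta-sheet)", flat(1244.0), prop(343.00)),
        ComponentSpec("P2", "beta carotene", flat(1263.0), prop(174.87)),
        ComponentSpec("P3", "carotene", flat(1281.0), prop(685.53)),
        # lipid band drifts upward with ripeness inside the printed 1297-1305 range
        ComponentSpec("P4", "lipid",
                      {"under_ripe": 1298.0, "ripe": 1301.0, "over_ripe": 1304.0},
                      prop(233.06), center_jitter_sd=1.0),
        ComponentSpec("P5", "guanine/cytosine", flat(1318.0), prop(283.94)),
        ComponentSpec("P6", "chlorophyll-a", flat(1325.0), {c: 0.0 for c in CLASSES_B}),
        # tryptophan: class-independent mean (grand mean 174 a.u.), high scatter,
        # so its intensity carries no ripeness signal
        ComponentSpec("P7", "tryptophan", flat(1333.0), {c: 174.07 for c in CLASSES_B},
                      amplitude_cv=0.30),
        ComponentSpec("P8", "carotene", flat(1352.0), prop(333.58)),
    ]


_TABLE_A = {
    # label: (center, assignment, amplitudes for unripe/under_ripe/ripe/over_ripe)
    "P1": (1244.0, "proteins, amide III (beta-sheet)", (172.79, 205.08, 385.40, 665.57)),
    "P2": (1258.0, "beta carotene", (118.42, 127.57, 184.36, 424.79)),
    "P3": (1281.0, "carotene", (185.73, 413.50, 778.01, 1364.08)),
    "P4": (1306.0, "lipid", (45.78, 200.61, 240.54, 391.19)),
    "P5": (1318.0, "guanine/cytosine", (0.0, 13.43, 43.44, 232.21)),
    "P6": (1325.0, "chlorophyll-a", (161.66, 35.88, 26.40, 0.0)),
    "P7": (1335.0, "tryptophan", (16.23, 0.0, 0.0, 0.0)),
    "P8": (1357.0, "carotene", (293.68, 361.46, 421.67, 597.98)),
}


def _bands_a() -> List[ComponentSpec]:
    """Sample-A library: four classes, published per-class intensities verbatim."""
    out = []
    for label, (center, assignment, amps) in _TABLE_A.items():
        out.append(ComponentSpec(
            label, assignment,
            {c: center for c in CLASSES_A},
            dict(zip(CLASSES_A, amps)),
            amplitude_cv=0.30 if label == "P7" else 0.05,
        ))
    return out


def _chlorophyll_full_range() -> List[ComponentSpec]:
    # chlorophyll-a reference bands outside the fingerprint window; intensity
    # decays with ripeness, the 915/986 bands vanishing entirely when over-ripe
    def c(label, center, amps):
        return ComponentSpec(label, "chlorophyll-a",
                             {cl: center for cl in CLASSES_B},
                             dict(zip(CLASSES_B, amps)))
    return [
        c("C744", 744.0, (90.0, 55.0, 30.0)),
        c("C915", 915.0, (30.0, 12.0, 0.0)),
        c("C986", 986.0, (45.0, 20.0, 0.0)),
    ]


def default_component_library(mode: str = "sample_B",
                              trend_demo_p7: bool = False) -> List[ComponentSpec]:
    """Return the default band library for a generator mode.

    Modes: ``sample_B`` (three-class cohort, the classifier's dataset),
    ``sample_A`` (four-class tabulated intensities), ``full_range``
    (sample-B bands plus chlorophyll-a components at 744/915/986 cm^-1).
    With ``trend_demo_p7`` the tryptophan band instead carries its published
    up-then-down class means (147.96 / 205.07 / 169.18 a.u.) as fixed effects,
    for demonstrating its non-monotone ripening trend.
    """
    if mode == "sample_A":
        lib = _bands_a()
    elif mode == "sample_B":
        lib = _bands_b()
    elif mode == "full_range":
        lib = _bands_b() + _chlorophyll_full_range()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if trend_demo_p7:
        if mode == "sample_A":
            raise ValueError("trend_demo_p7 applies to the three-class libraries")
        lib = [replace(c, amplitude_by_class=dict(
                   zip(CLASSES_B, (147.96, 205.07, 169.18))))
               if c.label == "P7" else c for c in lib]
    return lib


def default_noise_sd(mode: str = "sample_B") -> float:
    """Default additive noise: 1% of the ripe-class carotene (P3) amplitude."""
    lib = default_component_library(mode)
    p3 = next(c for c in lib if c.label == "P3")
    return 0.01 * p3.amplitude_by_class["ripe"]


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for one labelled synthetic cohort.

    Defaults reproduce the study's sample-B composition: 13 under-ripe,
    19 ripe and 15 over-ripe fruits.  ``gain_by_class`` is an extra per-class
    multiplier on top of the library amplitudes (unity by default);
    ``sample_gain_cv`` is the coefficient of variation of the multiplicative
    gain shared by all bands of one fruit (spot-to-spot coupling, focus,
    exposure); per-band scatter comes from each component's ``amplitude_cv``.
    """

    mode: str = "sample_B"
    counts: Optional[Dict[str, int]] = None
    noise_sd: Optional[float] = None
    gain_by_class: Optional[Dict[str, float]] = None
    sample_gain_cv: float = 0.05
    baseline: BaselineSpec = DEFAULT_BASELINE
    grid: Tuple[float, float, float] = DEFAULT_GRID
    trend_demo_p7: bool = False
    seed: int = 0

    def __post_init__(self):
        classes = self.classes
        counts = self.counts
        if counts is None:
            if set(classes) == set(CLASSES_B):
                counts = {"under_ripe": 13, "ripe": 19, "over_ripe": 15}
            else:
                counts = {c: 5 for c in classes}
            object.__setattr__(self, "counts", counts)
        if set(counts) - set(classes):
            raise ValueError("counts refer to classes outside the mode")
        if any(n <= 0 for n in counts.values()):
            raise ValueError("class counts must be positive")
        if self.noise_sd is None:
            object.__setattr__(self, "noise_sd", default_noise_sd(self.mode))
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.gain_by_class is None:
            object.__setattr__(self, "gain_by_class", {c: 1.0 for c in classes})

    @property
    def classes(self) -> Tuple[str, ...]:
        return CLASSES_A if self.mode == "sample_A" else CLASSES_B


@dataclass(frozen=True)
class LabeledDataset:
    """Spectra with ripeness labels plus the provenance needed to regenerate them."""

    samples: Tuple[Tuple[RamanSpectrum, str], ...]
    classes: Tuple[str, ...]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        for _, label in self.samples:
            if label not in self.classes:
                raise ValueError(f"label {label!r} outside class set {self.classes}")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def labels(self) -> List[str]:
        return [label for _, label in self.samples]

    @property
    def spectra(self) -> List[RamanSpectrum]:
        return [s for s, _ in self.samples]


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _make_grid(grid: Tuple[float, float, float]) -> np.ndarray:
    lo, hi, step = grid
    if step <= 0:
        raise ValueError("grid step must be positive")
    n = int(round((hi - lo) / step))
    return lo + step * np.arange(n + 1)


def gaussian(x: np.ndarray, amplitude: float, center: float, sigma: float) -> np.ndarray:
    """Gaussian lineshape A * exp(-(x - mu)^2 / (2 sigma^2))."""
    return amplitude * np.exp(-0.5 * ((x - center) / sigma) ** 2)


def generate_spectrum(library: Sequence[ComponentSpec], class_label: str,
                      baseline: BaselineSpec = DEFAULT_BASELINE,
                      noise_sd: float = 0.0, seed: int = 0,
                      grid: Tuple[float, float, float] = DEFAULT_GRID,
                      rng: Optional[np.random.Generator] = None) -> RamanSpectrum:
    """One spectrum at the library's population means for ``class_label``.

    intensity(x) = baseline(x) + sum_k A_k exp(-(x-mu_k)^2 / (2 sigma_k^2)) + eps(x)
    with eps i.i.d. zero-mean Gaussian of standard deviation ``noise_sd``.
    Identical ``(library, class_label, seed)`` reproduce the spectrum
    bit-for-bit.  Between-sample amplitude/position variation is applied by
    :func:`generate_cohort`, which realizes a per-sample library first.
    """
    if len(library) == 0:
        raise ValueError("component library is empty")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    x = _make_grid(grid)
    for comp in library:
        mu = comp.center_by_class[class_label]
        if not (x[0] <= mu <= x[-1]):
            raise ValueError(f"{comp.label}: center {mu} outside grid {grid[:2]}")
    y = baseline(x).astype(float)
    truth = {}
    for comp in library:
        a = comp.amplitude_by_class[class_label]
        mu = comp.center_by_class[class_label]
        y += gaussian(x, a, mu, comp.width_sigma)
        truth[comp.label] = (a, mu, comp.width_sigma)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=x.size)
    meta = {"class": class_label, "seed": seed, "noise_sd": noise_sd,
            "true_components": truth}
    return RamanSpectrum(x, y, meta)


def realize_library(library: Sequence[ComponentSpec], class_label: str,
                    rng: np.random.Generator, class_gain: float = 1.0
                    ) -> List[ComponentSpec]:
    """Draw one fruit's realized band parameters from the population model.

    Every band amplitude is ``A = mean * class_gain * (1 + eta_s) * (1 + eta_k)``
    with a shared sample gain ``eta_s`` and independent per-band relative noise
    ``eta_k`` of scale ``amplitude_cv``; centers get independent Gaussian
    jitter of scale ``center_jitter_sd`` and widths independent relative
    jitter of scale ``width_cv`` (bandwidths of real tissue spectra vary from
    fruit to fruit with composition and microstructure).  Draw order is fixed
    so a given rng state maps to exactly one realization.
    """
    # the shared (1 + eta_s) factor is folded into class_gain by the caller
    out = []
    for comp in library:
        eta_k = rng.normal(0.0, comp.amplitude_cv) if comp.amplitude_cv > 0 else 0.0
        jit = rng.normal(0.0, comp.center_jitter_sd) if comp.center_jitter_sd > 0 else 0.0
        eta_w = rng.normal(0.0, comp.width_cv) if comp.width_cv > 0 else 0.0
        amp = max(comp.amplitude_by_class[class_label] * class_gain * (1.0 + eta_k), 0.0)
        if comp.amplitude_by_class[class_label] == 0.0:
            amp = 0.0
        out.append(replace(
            comp,
            amplitude_by_class={class_label: amp},
            center_by_class={class_label: comp.center_by_class[class_label] + jit},
            width_sigma=comp.width_sigma * max(1.0 + eta_w, 0.2),
            amplitude_cv=0.0, center_jitter_sd=0.0, width_cv=0.0,
        ))
    return out


def generate_cohort(spec: CohortSpec) -> LabeledDataset:
    """Generate the labelled cohort described by ``spec`` (deterministic in seed)."""
    library = default_component_library(spec.mode, trend_demo_p7=spec.trend_demo_p7)
    root = np.random.SeedSequence(spec.seed)
    total = sum(spec.counts.get(c, 0) for c in spec.classes)
    # spawn all child streams up front, in class order, so each sample's
    # randomness is independent of the others' draw counts
    children = root.spawn(total)
    samples = []
    i = 0
    for class_label in spec.classes:
        for j in range(spec.counts.get(class_label, 0)):
            rng = np.random.default_rng(children[i])
            eta_s = rng.normal(0.0, spec.sample_gain_cv) if spec.sample_gain_cv > 0 else 0.0
            gain = spec.gain_by_class[class_label] * (1.0 + eta_s)
            realized = realize_library(library, class_label, rng, class_gain=max(gain, 0.0))
            spectrum = generate_spectrum(realized, class_label, baseline=spec.baseline,
                                         noise_sd=spec.noise_sd, grid=spec.grid, rng=rng)
            meta = dict(spectrum.metadata)
            meta["sample_id"] = f"{spec.mode}_{class_label}_{j:03d}"
            samples.append((RamanSpectrum(spectrum.shifts, spectrum.intensities, meta),
                            class_label))
            i += 1
    return LabeledDataset(tuple(samples), spec.classes,
                          provenance={"spec": spec, "seed": spec.seed})


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_spectrum_csv(spectrum: RamanSpectrum, path) -> None:
    """Write the two-column CSV read back by ``preprocess.read_spectrum_csv``.

    Values are printed with 12 significant digits, so a round trip preserves
    them to well beyond 9 significant digits.
    """
    if len(spectrum) == 0:
        raise ValueError("empty spectrum")
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write("raman_shift_cm-1,intensity_au\n")
        for x, y in zip(spectrum.shifts, spectrum.intensities):
            fh.write(f"{x:.12g},{y:.12g}\n")


def write_cohort(dataset: LabeledDataset, out_dir) -> Path:
    """Write one CSV per spectrum plus a ``manifest.csv`` mapping file to label."""
    out_dir = Path(out_dir)
    spectra_dir = out_dir / "spectra"
    spectra_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["file", "label"])
        for spectrum, label in dataset.samples:
            name = spectrum.metadata.get("sample_id", f"sample_{id(spectrum)}") + ".csv"
            write_spectrum_csv(spectrum, spectra_dir / name)
            writer.writerow([f"spectra/{name}", label])
    return manifest


def read_manifest(manifest_path) -> List[Tuple[Path, str]]:
    """Read a ``file,label`` cohort manifest; paths resolve relative to it."""
    manifest_path = Path(manifest_path)
    out = []
    with open(manifest_path) as fh:
        for row in csv.DictReader(fh):
            out.append((manifest_path.parent / row["file"], row["label"]))
    return out
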