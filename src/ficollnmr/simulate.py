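"""Synthetic plasma-NMR cohort generator.

Emulates the statistical structure of 1H-NMR fingerprints of plasma separated
on a Ficoll density gradient:

* ~20 named small-molecule metabolite signal groups (Lorentzian multiplets),
* a macromolecular baseline (broad lipid/glycoprotein humps),
* Ficoll contamination: a broad Gaussian envelope centered at 3.80 ppm
  (effective support 3.30-4.64 ppm) plus sharp peaks at 1.81, 1.84, 2.26,
  5.42 and 5.58 ppm,
* a residual water resonance at 4.70 ppm inside the excluded window,
* group-level multiplicative metabolite shifts (e.g. CRC vs LC),
* a paired anesthesia effect (general multiplicative concentration decrease
  in post samples) and drug peaks present only post-anesthesia,
* between-subject log-normal variability and additive Gaussian noise.

Acquisition types are emulated by component weighting: CPMG attenuates
macromolecule signals, diffusion editing attenuates small molecules, NOESY
keeps both. Contaminant and drug peaks are never attenuated — CPMG does not
filter the Ficoll polymer because its internal dynamics defeat
relaxation-based selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chemometrics import SampleAnnotation
from .spectra import FID, Spectrum, synthesize_fid, write_spectral_matrix

PEAK_SHAPES = ("lorentzian", "gaussian")
PEAK_COMPONENTS = ("small-molecule", "macromolecule", "contaminant", "drug")

#: Component weights per acquisition type. Contaminant and drug signals are
#: always weighted 1 regardless of pulse sequence.
ACQUISITION_WEIGHTS = {
    "noesy": {"small-molecule": 1.0, "macromolecule": 1.0},
    "cpmg": {"small-molecule": 1.0, "macromolecule": 0.2},
    "diffusion-edited": {"small-molecule": 0.1, "macromolecule": 1.0},
}

#: Sharp Ficoll resonances (ppm) that survive CPMG filtering.
FICOLL_SHARP_PPM = (1.81, 1.84, 2.26, 5.42, 5.58)
FICOLL_ENVELOPE_CENTER = 3.80


@dataclass(frozen=True)
class PeakSpec:
    """One resonance: position, half-width at half-maximum, amplitude, shape."""

    center: float
    width: float
    amplitude: float
    shape: str = "lorentzian"
    component: str = "small-molecule"

    def __post_init__(self):
        if not (self.width > 0):
            raise ValueError("width must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not (0.0 <= self.center <= 10.5):
            raise ValueError(f"center {self.center} outside [0, 10.5] ppm")
        if self.shape not in PEAK_SHAPES:
            raise ValueError(f"shape must be one of {PEAK_SHAPES}")
        if self.component not in PEAK_COMPONENTS:
            raise ValueError(f"component must be one of {PEAK_COMPONENTS}")


@dataclass(frozen=True)
class Metabolite:
    """A named signal group: multiplet positions with relative amplitudes.

    ``base_concentration`` sets the metabolite's typical relative level in the
    cohort; ``quant_region`` is the default integration window for univariate
    quantification (the tallest reasonably isolated multiplet).
    """

    name: str
    peaks: tuple[tuple[float, float], ...]  # (center ppm, relative amplitude)
    width: float
    base_concentration: float
    quant_region: tuple[float, float]

    def peak_specs(self, concentration: float | None = None) -> list[PeakSpec]:
        c = self.base_concentration if concentration is None else concentration
        return [PeakSpec(center=p, width=self.width, amplitude=c * a,
                         shape="lorentzian", component="small-molecule")
                for p, a in self.peaks]


# Curated plasma library: 20 metabolites at textbook 1H shifts. Multiplets are
# simplified to their dominant lines; quant regions are chosen around an
# isolated line (for glucose/glycine/threonine that line falls inside the
# 3.30-6.00 ppm exclusion window, as in real Ficoll plasma where those
# metabolites are lost to the analysis).
_LIBRARY = [
    ("isoleucine", ((0.935, 1.0), (1.010, 0.6)), 1.2, (0.92, 0.95)),
    ("leucine", ((0.960, 1.0), (1.710, 0.5)), 1.5, (0.95, 0.98)),
    ("valine", ((0.990, 1.0), (1.040, 1.0), (2.280, 0.3)), 1.4, (1.02, 1.06)),
    ("3-hydroxybutyrate", ((1.200, 1.0), (2.410, 0.5)), 0.8, (1.18, 1.22)),
    ("lactate", ((1.330, 1.0), (4.110, 0.3)), 3.0, (1.31, 1.35)),
    ("alanine", ((1.480, 1.0), (3.780, 0.2)), 1.8, (1.46, 1.50)),
    ("acetate", ((1.920, 1.0),), 0.9, (1.90, 1.94)),
    ("glutamate", ((2.050, 0.7), (2.350, 1.0)), 1.1, (2.33, 2.37)),
    ("methionine", ((2.130, 1.0), (2.640, 0.4)), 0.6, (2.11, 2.15)),
    ("glutamine", ((2.160, 0.7), (2.450, 1.0)), 1.5, (2.43, 2.47)),
    ("acetone", ((2.230, 1.0),), 0.5, (2.21, 2.25)),
    ("citrate", ((2.540, 1.0), (2.660, 1.0)), 1.0, (2.52, 2.56)),
    ("creatinine", ((3.040, 1.0), (4.060, 0.5)), 1.2, (3.02, 3.06)),
    ("carnitine", ((3.220, 1.0),), 0.7, (3.20, 3.24)),
    ("glycine", ((3.560, 1.0),), 1.3, (3.54, 3.58)),
    ("threonine", ((4.250, 1.0), (1.320, 0.8)), 1.0, (4.23, 4.27)),
    ("glucose", ((5.240, 0.5), (3.420, 1.0), (3.700, 1.0), (3.880, 0.8)), 6.0, (5.21, 5.27)),
    ("tyrosine", ((6.900, 1.0), (7.190, 1.0)), 0.7, (6.88, 6.92)),
    ("histidine", ((7.060, 1.0), (7.780, 0.8)), 0.6, (7.76, 7.80)),
    ("phenylalanine", ((7.370, 1.0), (7.420, 0.8)), 0.8, (7.35, 7.39)),
]

_DEFAULT_WIDTH = 0.0025  # HWHM in ppm (~1.5 Hz at 600 MHz)

#: Broad macromolecular humps (lipids, glycoproteins) as Gaussians.
MACROMOLECULE_PEAKS = (
    PeakSpec(0.90, 0.08, 3.0, "gaussian", "macromolecule"),
    PeakSpec(1.30, 0.10, 5.0, "gaussian", "macromolecule"),
    PeakSpec(2.02, 0.06, 2.0, "gaussian", "macromolecule"),
    PeakSpec(3.21, 0.05, 1.0, "gaussian", "macromolecule"),
    PeakSpec(5.30, 0.08, 1.5, "gaussian", "macromolecule"),
)

#: Residual water, inside the excluded window; never attenuated.
WATER_PEAK = PeakSpec(4.70, 0.05, 25.0, "gaussian", "contaminant")

#: Synthetic stand-in for an antibiotic administered during surgery
#: (cefuroxime-like): sharp lines, present only in post-anesthesia samples,
#: positioned outside the excluded window so the paired analysis can see them.
DEFAULT_DRUG_PEAKS = (
    PeakSpec(6.15, _DEFAULT_WIDTH, 1.0, "lorentzian", "drug"),
    PeakSpec(2.72, _DEFAULT_WIDTH, 0.7, "lorentzian", "drug"),
)


def default_ppm_axis(low: float = 0.0, high: float = 10.20,
                     n_points: int = 16384) -> np.ndarray:
    """Uniform ascending ppm grid; default 0-10.2 ppm, 16384 points."""
    return np.linspace(low, high, n_points)


def make_metabolite_library(n_metabolites: int = 20, seed: int = 0,
                            center_jitter: float = 0.002,
                            amplitude_jitter: float = 0.05) -> list[Metabolite]:
    """Build a reproducible metabolite library.

    The first 20 entries come from a curated plasma table; a small
    seed-dependent jitter on centers and base concentrations emulates
    cohort-level referencing and population differences while keeping the
    library deterministic for a given seed. Requests beyond 20 append
    unassigned singlet resonances at random positions.
    """
    if n_metabolites < 1:
        raise ValueError("n_metabolites must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[Metabolite] = []
    for name, peaks, conc, region in _LIBRARY[:n_metabolites]:
        jittered = tuple(
            (float(np.clip(p + rng.normal(0.0, center_jitter), 0.0, 10.5)), a)
            for p, a in peaks)
        conc_j = float(conc * np.exp(rng.normal(0.0, amplitude_jitter)))
        out.append(Metabolite(name=name, peaks=jittered, width=_DEFAULT_WIDTH,
                              base_concentration=conc_j, quant_region=region))
    for k in range(len(out), n_metabolites):
        center = float(rng.uniform(0.5, 9.5))
        out.append(Metabolite(
            name=f"unassigned-{k + 1}",
            peaks=((center, 1.0),),
            width=_DEFAULT_WIDTH,
            base_concentration=float(rng.uniform(0.3, 2.0)),
            quant_region=(center - 0.02, center + 0.02)))
    return out


def ficoll_contamination(intensity_scale: float = 1.0) -> list[PeakSpec]:
    """Ficoll contamination signals.

    One broad Gaussian envelope centered at 3.80 ppm whose effective support
    lies within 3.30-4.64 ppm, plus five sharp lines at 1.81, 1.84, 2.26,
    5.42 and 5.58 ppm. All amplitudes scale linearly with ``intensity_scale``.
    """
    if intensity_scale < 0:
        raise ValueError("intensity_scale must be >= 0")
    peaks = [PeakSpec(FICOLL_ENVELOPE_CENTER, 0.25, 8.0 * intensity_scale,
                      "gaussian", "contaminant")]
    for ppm in FICOLL_SHARP_PPM:
        peaks.append(PeakSpec(ppm, 0.004, 1.2 * intensity_scale,
                              "lorentzian", "contaminant"))
    return peaks


def _peak_profiles(peaks: Sequence[PeakSpec], axis: np.ndarray) -> np.ndarray:
    """(n_peaks, n_axis) unit-amplitude line shapes."""
    axis = np.asarray(axis, dtype=float)
    centers = np.array([p.center for p in peaks])[:, None]
    widths = np.array([p.width for p in peaks])[:, None]
    dx = axis[None, :] - centers
    lorentz = widths ** 2 / (dx ** 2 + widths ** 2)
    sigma = widths / np.sqrt(2.0 * np.log(2.0))
    gauss = np.exp(-0.5 * (dx / sigma) ** 2)
    is_gauss = np.array([p.shape == "gaussian" for p in peaks])[:, None]
    return np.where(is_gauss, gauss, lorentz)


def render_spectrum(peaks: Sequence[PeakSpec], axis: np.ndarray,
                    acquisition: str = "noesy", noise_sd: float = 0.0,
                    seed: int | None = None, sample_id: str = "") -> Spectrum:
    """Evaluate component-weighted peak shapes on a ppm grid and add noise.

    Weighting follows :data:`ACQUISITION_WEIGHTS`; contaminant and drug peaks
    always carry weight 1. Noise is i.i.d. additive Gaussian.
    """
    axis = np.asarray(axis, dtype=float)
    if axis.size == 0:
        raise ValueError("empty ppm axis")
    if axis.size >= 2:
        d = np.diff(axis)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("ppm axis must be strictly monotone")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if acquisition not in ACQUISITION_WEIGHTS:
        raise ValueError(f"unknown acquisition {acquisition!r}")
    weights = ACQUISITION_WEIGHTS[acquisition]
    intensity = np.zeros(axis.size)
    if peaks:
        profiles = _peak_profiles(peaks, axis)
        amps = np.array([p.amplitude * weights.get(p.component, 1.0) for p in peaks])
        intensity = amps @ profiles
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, noise_sd, axis.size)
    return Spectrum(ppm=axis, intensity=intensity, acquisition=acquisition,
                    sample_id=sample_id)


@dataclass
class CohortDesign:
    """Stated world for a synthetic paired two-group cohort.

    ``effect_table`` maps group label -> {metabolite name: multiplicative
    factor} relative to the library baseline. ``anesthesia_decrease`` is a
    single factor (or per-metabolite mapping) <= 1 applied to every metabolite
    in post-anesthesia samples — the general concentration decrease seen after
    anesthesia. Drug peaks are added only to post samples.
    """

    n_subjects_per_group: int = 20
    groups: tuple[str, ...] = ("CRC", "LC")
    paired: bool = True
    effect_table: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    anesthesia_decrease: float | Mapping[str, float] = 0.85
    drug_peaks: tuple[PeakSpec, ...] = DEFAULT_DRUG_PEAKS
    subject_sd: float = 0.10
    noise_sd: float = 0.05
    seed: int = 0
    n_metabolites: int = 20
    acquisition: str = "cpmg"
    ficoll_scale: float = 1.0
    ficoll_variability: float = 0.3  # lognormal sigma of per-sample Ficoll level
    anesthetics: tuple[str, ...] = ("etomidate", "propofol-2")
    axis: np.ndarray = field(default_factory=default_ppm_axis)

    def __post_init__(self):
        if self.n_subjects_per_group < 2:
            raise ValueError("n_subjects_per_group must be >= 2")
        if self.subject_sd < 0 or self.noise_sd < 0 or self.ficoll_scale < 0:
            raise ValueError("scale parameters must be >= 0")
        factors = (self.anesthesia_decrease.values()
                   if isinstance(self.anesthesia_decrease, Mapping)
                   else [self.anesthesia_decrease])
        if any(f <= 0 for f in factors):
            raise ValueError("anesthesia_decrease factors must be > 0")
        for group, table in self.effect_table.items():
            if any(f <= 0 for f in table.values()):
                raise ValueError(f"effect_table factors for {group} must be > 0")


@dataclass
class SyntheticSample:
    """One rendered spectrum with its annotation and true concentrations."""

    spectrum: Spectrum
    annotation: SampleAnnotation
    truth: dict[str, float]


def _anesthesia_factor(design: CohortDesign, metabolite: str) -> float:
    if isinstance(design.anesthesia_decrease, Mapping):
        return float(design.anesthesia_decrease.get(metabolite, 1.0))
    return float(design.anesthesia_decrease)


def _cohort_frame(design: CohortDesign, library: list[Metabolite],
                  rng: np.random.Generator) -> pd.DataFrame:
    """Per-sample annotations and true concentrations (long layout by sample)."""
    names = [m.name for m in library]
    known = set(names)
    for group, table in design.effect_table.items():
        unknown = set(table) - known
        if unknown:
            raise ValueError(f"effect_table for {group!r} references unknown "
                             f"metabolites: {sorted(unknown)}")
        if group not in design.groups:
            raise ValueError(f"effect_table group {group!r} not in design.groups")
    if isinstance(design.anesthesia_decrease, Mapping):
        unknown = set(design.anesthesia_decrease) - known
        if unknown:
            raise ValueError(f"anesthesia_decrease references unknown "
                             f"metabolites: {sorted(unknown)}")
    rows = []
    timepoints = ("pre", "post") if design.paired else ("pre",)
    for group in design.groups:
        g_eff = design.effect_table.get(group, {})
        for i in range(design.n_subjects_per_group):
            subject = f"{group}{i + 1:03d}"
            anesthetic = design.anesthetics[i % len(design.anesthetics)]
            subj_factor = {name: float(np.exp(rng.normal(0.0, design.subject_sd)))
                           for name in names}
            ficoll = float(design.ficoll_scale *
                           np.exp(rng.normal(0.0, design.ficoll_variability)))
            for tp in timepoints:
                truth = {}
                for m in library:
                    c = m.base_concentration * float(g_eff.get(m.name, 1.0))
                    c *= subj_factor[m.name]
                    if tp == "post":
                        c *= _anesthesia_factor(design, m.name)
                    truth[m.name] = c
                rows.append({
                    "sample_id": f"{subject}-{tp}",
                    "subject_id": subject,
                    "group": group,
                    "timepoint": tp,
                    "anesthetic": anesthetic,
                    "drugs": "cefuroxime" if tp == "post" else "",
                    "ficoll": ficoll,
                    **{f"truth:{k}": v for k, v in truth.items()},
                })
    return pd.DataFrame(rows)


def simulate_concentration_table(design: CohortDesign,
                                 library: list[Metabolite] | None = None,
                                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """True relative concentrations without spectral rendering.

    Returns ``(table, annotations)`` where ``table`` is samples x metabolites.
    Useful for fast statistical simulations that do not need line shapes.
    """
    if library is None:
        library = make_metabolite_library(design.n_metabolites, design.seed)
    rng = np.random.default_rng(design.seed)
    frame = _cohort_frame(design, library, rng)
    truth_cols = [c for c in frame.columns if c.startswith("truth:")]
    table = frame[truth_cols].copy()
    table.columns = [c.split(":", 1)[1] for c in truth_cols]
    table.index = frame["sample_id"]
    ann = frame[["sample_id", "subject_id", "group", "timepoint",
                 "anesthetic", "drugs"]].copy()
    return table, ann


def simulate_cohort(design: CohortDesign,
                    library: list[Metabolite] | None = None) -> list[SyntheticSample]:
    """Render a full synthetic cohort, fully determined by ``design.seed``."""
    if library is None:
        library = make_metabolite_library(design.n_metabolites, design.seed)
    rng = np.random.default_rng(design.seed)
    frame = _cohort_frame(design, library, rng)
    samples: list[SyntheticSample] = []
    noise_seeds = rng.integers(0, 2 ** 31 - 1, size=len(frame))
    for row_i, row in frame.iterrows():
        truth = {m.name: row[f"truth:{m.name}"] for m in library}
        peaks: list[PeakSpec] = []
        for m in library:
            peaks.extend(m.peak_specs(truth[m.name]))
        peaks.extend(MACROMOLECULE_PEAKS)
        peaks.append(WATER_PEAK)
        peaks.extend(ficoll_contamination(row["ficoll"]))
        if row["timepoint"] == "post":
            peaks.extend(design.drug_peaks)
        spectrum = render_spectrum(
            peaks, design.axis, acquisition=design.acquisition,
            noise_sd=design.noise_sd, seed=int(noise_seeds[row_i]),
            sample_id=row["sample_id"])
        annotation = SampleAnnotation(
            sample_id=row["sample_id"], subject_id=row["subject_id"],
            group=row["group"], timepoint=row["timepoint"],
            anesthetic=row["anesthetic"],
            drugs=tuple(d for d in row["drugs"].split(";") if d))
        samples.append(SyntheticSample(spectrum=spectrum, annotation=annotation,
                                       truth=truth))
    return samples


def cohort_fids(samples: Sequence[SyntheticSample], n_points: int | None = None,
                ) -> list[FID]:
    """Inverse-transform each rendered spectrum into a synthetic FID."""
    return [synthesize_fid(s.spectrum, n_points) for s in samples]


def write_cohort(samples: Sequence[SyntheticSample], out_dir: str | Path) -> dict[str, Path]:
    """Write spectral matrix (TSV), annotation CSV and truth CSV to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "spectra": out / "spectra.tsv",
        "annotations": out / "annotations.csv",
        "truth": out / "truth.csv",
    }
    write_spectral_matrix([s.spectrum for s in samples], paths["spectra"])
    ann = pd.DataFrame([{
        "sample_id": s.annotation.sample_id,
        "subject_id": s.annotation.subject_id,
        "group": s.annotation.group,
        "timepoint": s.annotation.timepoint,
        "anesthetic": s.annotation.anesthetic,
        "drugs": ";".join(s.annotation.drugs),
    } for s in samples])
    ann.to_csv(paths["annotations"], index=False)
    truth = pd.DataFrame([s.truth for s in samples],
                         index=[s.annotation.sample_id for s in samples])
    truth.to_csv(paths["truth"], index_label="sample_id")
    return paths
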