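"""Synthetic HR MAS spectrum cohorts with planted tumor-content effects.

Real tissue spectra from the biobank behind this kind of study are not
publicly deposited, so the package ships a generator that emulates
CPMG-style HR MAS 1H spectra over the -0.08 to 4.7 ppm region: positive
metabolite peaks whose concentrations depend on tumor cell content,
shared patient random effects (multiple biopsies per patient), smooth
baseline drift, per-metabolite chemical-shift jitter, occasional ethanol
contamination in the 3.642-3.691 ppm window, a broad residual near
4.2-4.4 ppm, and additive noise.

Planted effect directions follow the established tumor metabolite
phenotype: ascorbate, lactate, creatine, glycine, taurine and the
choline-containing metabolites (GPC, PCho, free choline) increase with
tumor content, glucose decreases (Warburg-type consumption), and
phosphocholine carries the largest positive effect.

Concentration noise is lognormal (positivity) and mean-one, so the
expected concentration is exactly ``baseline + slope * tumor_content``
scaled by the patient effect; the patient effect is a shared mean-one
lognormal multiplier across all of a patient's samples, which creates
the within-patient correlation that motivates patient-grouped
cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SpectrumSet

PPM_MAX = 4.7
PPM_MIN = -0.08
DEFAULT_PPM_STEP = 5.26e-4


class DesignError(ValueError):
    """Raised when a cohort design is internally inconsistent."""


@dataclass(frozen=True)
class MetabolitePeak:
    """A metabolite's resonance pattern: positions, weights, lineshape."""

    name: str
    positions: tuple[float, ...]
    relative_intensities: tuple[float, ...]
    linewidth: float = 0.006  # FWHM, ppm
    lineshape: str = "lorentzian"

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.relative_intensities):
            raise ValueError(f"{self.name}: positions/intensities length mismatch")
        if any(p < PPM_MIN or p > PPM_MAX for p in self.positions):
            raise ValueError(f"{self.name}: position outside {PPM_MIN}-{PPM_MAX} ppm")
        if self.linewidth <= 0:
            raise ValueError(f"{self.name}: linewidth must be > 0")
        if any(r <= 0 for r in self.relative_intensities):
            raise ValueError(f"{self.name}: relative intensities must be > 0")
        if self.lineshape not in ("lorentzian", "gaussian"):
            raise ValueError(f"{self.name}: unknown lineshape {self.lineshape!r}")

    def template(self, axis: np.ndarray, jitter: float = 0.0) -> np.ndarray:
        """Unit-concentration intensity profile on ``axis``, shifted by ``jitter`` ppm."""
        out = np.zeros_like(axis)
        for pos, rel in zip(self.positions, self.relative_intensities):
            d = axis - (pos + jitter)
            if self.lineshape == "lorentzian":
                out += rel / (1.0 + (2.0 * d / self.linewidth) ** 2)
            else:
                out += rel * np.exp(-4.0 * np.log(2.0) * (d / self.linewidth) ** 2)
        return out


def default_peak_library() -> list[MetabolitePeak]:
    """Conventional 1H chemical shifts for the nine modeled metabolites.

    Shifts are literature consensus values (TSP-referenced, pH ~7); they
    place the choline-containing metabolites inside the 3.196-3.252 ppm
    window and the glucose anomeric proton at 4.65 ppm.  Relative peak
    heights reflect proton multiplicity and line splitting: the
    N-trimethyl singlets of the cholines concentrate nine equivalent
    protons in one narrow line (which is why they dominate tissue
    spectra), whereas e.g. the lactate CH quartet spreads a single
    proton over four lines.
    """
    return [
        MetabolitePeak(
            "glucose",
            (3.23, 3.40, 3.46, 3.53, 3.71, 3.73, 3.82, 3.89, 4.65),
            (0.3, 0.8, 0.8, 0.5, 0.4, 0.6, 0.4, 0.4, 0.35),
        ),
        MetabolitePeak("ascorbate", (4.52,), (1.0,)),
        MetabolitePeak("lactate", (1.33, 4.11), (3.0, 0.5)),
        MetabolitePeak("creatine", (3.03, 3.93), (2.0, 0.8)),
        MetabolitePeak("glycine", (3.55,), (1.5,)),
        MetabolitePeak("taurine", (3.25, 3.42), (1.0, 1.0)),
        MetabolitePeak("gpc", (3.23,), (3.0,)),
        MetabolitePeak("pcho", (3.22,), (3.0,)),
        MetabolitePeak("choline", (3.20,), (3.0,)),
    ]


@dataclass(frozen=True)
class EffectModel:
    """Concentration model: baseline level and tumor-content slope per metabolite.

    Expected concentration at tumor-content fraction ``tc`` is
    ``max(baseline + slope * tc, 0)``, multiplied by a mean-one lognormal
    patient effect (sd ``patient_sd`` on the log scale, shared across a
    patient's samples) and a mean-one lognormal sample residual
    (``residual_sd``).
    """

    baseline: dict[str, float] = field(
        default_factory=lambda: {
            "glucose": 3.0,
            "ascorbate": 0.4,
            "lactate": 1.5,
            "creatine": 0.6,
            "glycine": 0.5,
            "taurine": 0.8,
            "gpc": 0.3,
            "pcho": 0.15,
            "choline": 0.15,
        }
    )
    slope: dict[str, float] = field(
        default_factory=lambda: {
            "glucose": -2.5,
            "ascorbate": 1.0,
            "lactate": 3.5,
            "creatine": 1.5,
            "glycine": 2.0,
            "taurine": 2.5,
            "gpc": 2.0,
            "pcho": 4.0,
            "choline": 1.0,
        }
    )
    patient_sd: float = 0.25
    residual_sd: float = 0.15

    def __post_init__(self) -> None:
        if self.patient_sd < 0 or self.residual_sd < 0:
            raise ValueError("effect model sds must be >= 0")

    def scaled(self, slope_factor: float) -> "EffectModel":
        """Copy with every tumor slope multiplied by ``slope_factor``."""
        return EffectModel(
            baseline=dict(self.baseline),
            slope={k: v * slope_factor for k, v in self.slope.items()},
            patient_sd=self.patient_sd,
            residual_sd=self.residual_sd,
        )


@dataclass(frozen=True)
class ArtifactModel:
    """Non-metabolite spectral components and noise.

    baseline_amplitude / baseline_smoothness: a broad Gaussian hump
    (width in ppm) at a random position per spectrum, emulating residual
    baseline drift surviving the CPMG filter.  shift_jitter_sd: per
    spectrum, per metabolite shift of that metabolite's whole multiplet
    (ppm), emulating pH/temperature-driven drift.  ethanol_prob /
    ethanol_amplitude: a CH2-quartet contaminant in 3.642-3.691 ppm.
    residual_amplitude: broad fatty-acid residual at 4.2-4.4 ppm.
    """

    baseline_amplitude: float = 0.5
    baseline_smoothness: float = 1.0
    shift_jitter_sd: float = 0.0015
    noise_sd: float = 0.02
    ethanol_prob: float = 0.10
    ethanol_amplitude: float = 1.0
    residual_amplitude: float = 0.3

    def __post_init__(self) -> None:
        for name in (
            "baseline_amplitude",
            "baseline_smoothness",
            "shift_jitter_sd",
            "noise_sd",
            "ethanol_amplitude",
            "residual_amplitude",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.ethanol_prob <= 1.0:
            raise ValueError("ethanol_prob must be in [0, 1]")

    @staticmethod
    def zero() -> "ArtifactModel":
        """Artifact-free rendering (pure metabolite sum)."""
        return ArtifactModel(0.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0)


# ethanol CH2 quartet inside the deleted pollution window; J ~ 7 Hz at 600 MHz
_ETHANOL_POSITIONS = (3.649, 3.660, 3.672, 3.684)
_ETHANOL_WEIGHTS = (1.0, 3.0, 3.0, 1.0)
_RESIDUAL_CENTER, _RESIDUAL_FWHM = 4.30, 0.15


@dataclass(frozen=True)
class Stratum:
    """One tumor-content stratum of the cohort design."""

    name: str
    n_samples: int
    n_patients: int  # as reported per stratum; informative, totals bind
    tc_low: float  # percent
    tc_high: float
    tc_dist: str = "constant"  # constant | uniform_int | skewed


@dataclass(frozen=True)
class CohortDesign:
    """Cohort structure: strata, patient multiplicity and rng seed.

    The default reproduces the study cohort layout: 328 biopsies from
    228 patients in four tumor-content strata (65 at 0%, 5 at 1-4%, 32
    at exactly 5%, 226 above 5%).  Patients may contribute samples from
    different strata, so per-stratum patient counts exceed the patient
    total; only the sample and patient totals are binding.
    """

    strata: tuple[Stratum, ...] = (
        Stratum("normal", 65, 43, 0.0, 0.0, "constant"),
        Stratum("tc_1_4", 5, 5, 1.0, 4.0, "uniform_int"),
        Stratum("tc_5", 32, 29, 5.0, 5.0, "constant"),
        Stratum("tc_gt5", 226, 182, 7.0, 95.0, "skewed"),
    )
    n_patients: int = 228
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return sum(s.n_samples for s in self.strata)

    def validate(self) -> None:
        n = self.n_samples
        n_two = n - self.n_patients  # patients contributing two samples
        if n_two < 0:
            raise DesignError(
                f"more patients ({self.n_patients}) than samples ({n})"
            )
        if 2 * n_two > n:
            raise DesignError(
                f"{self.n_patients} patients cannot cover {n} samples with "
                "at most two samples per patient"
            )


def default_axis(step: float = DEFAULT_PPM_STEP) -> np.ndarray:
    """Descending ppm axis from 4.7 down to -0.08 at the default spacing.

    The default step of 5.26e-4 ppm/point makes the region retained
    after all deletions (3.0-4.7 ppm minus the 3.642-3.691 and 4.2-4.4
    cuts) come out at 2759 variables.
    """
    n = int(np.floor((PPM_MAX - PPM_MIN) / step)) + 1
    return PPM_MAX - step * np.arange(n)


def _sample_tc(stratum: Stratum, rng: np.random.Generator) -> float:
    if stratum.tc_dist == "constant" or stratum.tc_low == stratum.tc_high:
        return float(stratum.tc_low)
    if stratum.tc_dist == "uniform_int":
        return float(rng.integers(int(stratum.tc_low), int(stratum.tc_high) + 1))
    # skewed: right-tailed beta, median near the low end of the range as
    # observed in real tumor-content distributions (median ~20% over 7-95%)
    frac = rng.beta(1.2, 5.0)
    return float(stratum.tc_low + frac * (stratum.tc_high - stratum.tc_low))


def metabolite_profile(
    tumor_content: float,
    patient_effect: np.ndarray,
    effects: EffectModel,
    rng: np.random.Generator,
    names: list[str] | None = None,
) -> np.ndarray:
    """Draw one sample's metabolite concentration vector.

    ``tumor_content`` is a fraction in [0, 1]; ``patient_effect`` is the
    per-metabolite multiplier shared by all samples of the patient.
    The lognormal residual is mean-one, so the expectation is exactly
    ``max(baseline + slope * tc, 0) * patient_effect``.
    """
    if not 0.0 <= tumor_content <= 1.0:
        raise ValueError("tumor_content must be a fraction in [0, 1]")
    names = names or list(effects.baseline)
    base = np.array([effects.baseline[n] for n in names])
    slope = np.array([effects.slope[n] for n in names])
    mean = np.maximum(base + slope * tumor_content, 0.0)
    sd = effects.residual_sd
    noise = np.exp(rng.normal(-0.5 * sd * sd, sd, size=len(names))) if sd > 0 else 1.0
    return mean * np.asarray(patient_effect) * noise


def patient_effects(
    effects: EffectModel, n_metabolites: int, rng: np.random.Generator
) -> np.ndarray:
    """Mean-one lognormal per-metabolite multipliers for one patient."""
    sd = effects.patient_sd
    if sd == 0:
        return np.ones(n_metabolites)
    return np.exp(rng.normal(-0.5 * sd * sd, sd, size=n_metabolites))


def render_spectrum(
    concentrations: np.ndarray,
    peaks: list[MetabolitePeak],
    artifacts: ArtifactModel,
    axis: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Render one spectrum: metabolite sum plus artifacts plus noise.

    With a zero ArtifactModel the output is exactly the linear
    combination sum(concentration * peak template).  The rng is consumed
    in a fixed order (baseline center, per-metabolite jitter, ethanol
    coin, noise) so identical seeds give identical spectra.
    """
    axis = np.asarray(axis, dtype=float)
    d = np.diff(axis)
    if not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError("axis must be strictly monotone")
    if len(concentrations) != len(peaks):
        raise ValueError("one concentration per metabolite peak required")

    y = np.zeros_like(axis)
    # smooth baseline hump at a random center
    center = rng.uniform(axis.min(), axis.max())
    if artifacts.baseline_amplitude > 0:
        y += artifacts.baseline_amplitude * np.exp(
            -0.5 * ((axis - center) / artifacts.baseline_smoothness) ** 2
        )
    jitters = rng.normal(0.0, artifacts.shift_jitter_sd or 0.0, size=len(peaks))
    for conc, peak, jit in zip(concentrations, peaks, jitters):
        if conc > 0:
            y += conc * peak.template(axis, jitter=float(jit))
    if rng.uniform() < artifacts.ethanol_prob:
        amp = artifacts.ethanol_amplitude * rng.uniform(0.5, 1.5)
        for pos, w in zip(_ETHANOL_POSITIONS, _ETHANOL_WEIGHTS):
            y += amp * w / 8.0 / (1.0 + (2.0 * (axis - pos) / 0.004) ** 2)
    if artifacts.residual_amplitude > 0:
        y += artifacts.residual_amplitude * np.exp(
            -4.0 * np.log(2.0) * ((axis - _RESIDUAL_CENTER) / _RESIDUAL_FWHM) ** 2
        )
    noise = rng.normal(0.0, 1.0, size=axis.size)
    if artifacts.noise_sd > 0:
        y += artifacts.noise_sd * noise
    return y


def _assign_patients(
    samples: list[tuple[str, float]], design: CohortDesign, rng: np.random.Generator
) -> list[int]:
    """Map each sample to a patient index, preferring tumor+normal pairs.

    ``n_samples - n_patients`` patients receive two samples; pairs are
    formed first between 0% and high-tumor-content samples (so grouped
    CV actually has patients spanning both classes), then among the
    remaining pool; all other patients contribute a single sample.
    """
    n = len(samples)
    n_two = n - design.n_patients
    order = np.arange(n)
    normal_idx = [i for i in order if samples[i][1] == 0.0]
    tumor_idx = [i for i in order if samples[i][0] == "tc_gt5"]
    rng.shuffle(normal_idx)
    rng.shuffle(tumor_idx)

    patient_of = [-1] * n
    pid = 0
    n_cross = min(n_two, len(normal_idx), len(tumor_idx))
    for k in range(n_cross):
        patient_of[normal_idx[k]] = pid
        patient_of[tumor_idx[k]] = pid
        pid += 1
    remaining = [i for i in order if patient_of[i] == -1]
    rng.shuffle(remaining)
    for _ in range(n_two - n_cross):
        a, b = remaining.pop(), remaining.pop()
        patient_of[a] = patient_of[b] = pid
        pid += 1
    for i in remaining:
        patient_of[i] = pid
        pid += 1
    assert pid == design.n_patients
    return patient_of


# Dirichlet weights for (fat, connective, glandular, necrotic) splitting
# the non-tumor share of the biopsy, loosely following observed medians
# (connective-dominated tissue with variable fat).
_TISSUE_WEIGHTS = {
    "normal": (2.0, 6.0, 0.5, 0.1),
    "tc_1_4": (1.0, 7.0, 0.3, 0.5),
    "tc_5": (0.8, 8.0, 0.3, 0.3),
    "tc_gt5": (1.0, 6.5, 0.3, 0.8),
}
_DEFAULT_TISSUE_WEIGHTS = (1.5, 6.0, 0.5, 0.5)


def generate_cohort(
    design: CohortDesign | None = None,
    effects: EffectModel | None = None,
    artifacts: ArtifactModel | None = None,
    axis: np.ndarray | None = None,
    peaks: list[MetabolitePeak] | None = None,
) -> tuple[SpectrumSet, pd.DataFrame]:
    """Generate a full synthetic cohort: spectra matrix plus metadata table.

    Deterministic given ``design`` (which carries the seed) and the
    model objects.  Metadata columns: sample_id, patient_id,
    tumor_content_pct, fat_pct, connective_pct, glandular_pct,
    necrotic_pct; the five composition percentages sum to 100.
    """
    design = design or CohortDesign()
    design.validate()
    effects = effects or EffectModel()
    artifacts = artifacts if artifacts is not None else ArtifactModel()
    axis = default_axis() if axis is None else np.asarray(axis, dtype=float)
    peaks = peaks or default_peak_library()
    names = [p.name for p in peaks]
    missing = [n for n in names if n not in effects.baseline or n not in effects.slope]
    if missing:
        raise DesignError(f"effect model missing metabolites: {missing}")

    rng = np.random.default_rng(design.seed)
    samples: list[tuple[str, float]] = []  # (stratum name, tumor content %)
    for stratum in design.strata:
        for _ in range(stratum.n_samples):
            samples.append((stratum.name, _sample_tc(stratum, rng)))
    patient_of = _assign_patients(samples, design, rng)

    effects_by_patient = {
        pid: patient_effects(effects, len(peaks), rng)
        for pid in range(design.n_patients)
    }

    n = len(samples)
    width = max(3, len(str(n)))
    pwidth = max(3, len(str(design.n_patients)))
    intensities = np.empty((n, axis.size))
    rows = []
    for i, (stratum_name, tc) in enumerate(samples):
        pid = patient_of[i]
        conc = metabolite_profile(
            tc / 100.0, effects_by_patient[pid], effects, rng, names=names
        )
        intensities[i] = render_spectrum(conc, peaks, artifacts, axis, rng)
        w = np.array(_TISSUE_WEIGHTS.get(stratum_name, _DEFAULT_TISSUE_WEIGHTS))
        comp = rng.dirichlet(w) * (100.0 - tc)
        rows.append(
            {
                "sample_id": f"S{i + 1:0{width}d}",
                "patient_id": f"P{pid + 1:0{pwidth}d}",
                "stratum": stratum_name,
                "tumor_content_pct": tc,
                "fat_pct": comp[0],
                "connective_pct": comp[1],
                "glandular_pct": comp[2],
                "necrotic_pct": comp[3],
            }
        )
    meta = pd.DataFrame(rows)
    spectra = SpectrumSet(intensities, axis, meta["sample_id"].tolist())
    return spectra, meta


def nominal_acquisition_time(n_complex_points: int, spectral_width: float) -> float:
    """Nominal FID acquisition time in seconds.

    Under the convention that ``n`` collected points spanning a spectral
    width SW (Hz) correspond to ``n / (2 * SW)`` seconds of sampling:
    32768 points over 10 kHz give 1.6384 s (printed as 1.64 s).
    """
    if n_complex_points <= 0 or spectral_width <= 0:
        raise ValueError("points and spectral width must be > 0")
    return n_complex_points / (2.0 * spectral_width)
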