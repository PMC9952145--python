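"""Synthetic PPG cohort generation with analytic ground truth.

Each pulse is modelled as the sum of two Gaussian-shaped components — a
systolic wave and a (possibly absent) diastolic wave — so that every landmark
used downstream (systolic peak, dicrotic notch, beat onset/end) exists by
construction and can be located analytically on the continuous waveform.
Recordings are concatenations of per-beat realisations with period and
amplitude jitter, plus sinusoidal baseline wander (respiration band) and
additive white noise.

Class-conditional morphology emulates the clinical observation that the
diastolic wave is attenuated or absent in cardiovascular disease: disease
classes get a smaller diastolic component, a longer crest time and shifted
beat periods, alongside demographics (age, smoking, blood pressure, SpO2)
drawn from class-specific priors.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .errors import ConfigurationError, ResolutionError

CLASS_LABELS = ("Healthy", "ACS", "CVA", "DVT", "HF", "AF")
CVD_LABELS = CLASS_LABELS[1:]

#: Subjects per class in the emulated study cohort. The source cohort is
#: described as 200 healthy + 160 CVD, but the per-class counts sum to 162;
#: the per-class counts are taken as authoritative.
DEFAULT_CLASS_COUNTS: dict[str, int] = {
    "Healthy": 200,
    "ACS": 63,
    "CVA": 50,
    "DVT": 23,
    "HF": 13,
    "AF": 13,
}


@dataclass(frozen=True)
class BeatMorphology:
    """Continuous-time parameters of one two-component pulse.

    Amplitudes are in arbitrary units, times in seconds. ``diastolic_amp = 0``
    produces a systolic-only pulse with no dicrotic notch.
    """

    systolic_amp: float
    systolic_center: float
    systolic_width: float
    diastolic_amp: float
    diastolic_center: float
    diastolic_width: float
    beat_period: float

    def __post_init__(self) -> None:
        if self.systolic_amp <= 0:
            raise ConfigurationError("systolic_amp must be > 0")
        if self.diastolic_amp < 0:
            raise ConfigurationError("diastolic_amp must be >= 0")
        if self.diastolic_amp > self.systolic_amp:
            raise ConfigurationError("diastolic_amp must not exceed systolic_amp")
        if not (0 < self.systolic_center < self.diastolic_center < self.beat_period):
            raise ConfigurationError(
                "need 0 < systolic_center < diastolic_center < beat_period"
            )
        if self.systolic_width <= 0 or self.diastolic_width <= 0:
            raise ConfigurationError("component widths must be > 0")

    def waveform(self, t: np.ndarray | float) -> np.ndarray | float:
        """Evaluate the continuous two-Gaussian pulse at time(s) ``t``."""
        s = self.systolic_amp * np.exp(
            -0.5 * ((t - self.systolic_center) / self.systolic_width) ** 2
        )
        d = self.diastolic_amp * np.exp(
            -0.5 * ((t - self.diastolic_center) / self.diastolic_width) ** 2
        )
        return s + d


@dataclass(frozen=True)
class BeatGroundTruth:
    """Analytic landmarks of one generated beat, in recording time (s)."""

    beat_index: int
    t_onset: float
    t_sys: float
    amp_sys: float
    t_notch: float | None
    amp_notch: float | None
    t_end: float

    @property
    def has_notch(self) -> bool:
        return self.t_notch is not None


@dataclass(frozen=True)
class PPGRecord:
    """One subject's sampled PPG waveform."""

    subject_id: str
    fs: float
    samples: np.ndarray
    t0: float = 0.0

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.samples)) / self.fs


@dataclass(frozen=True)
class SubjectProfile:
    """Demographics, health-status flags and oximeter readings for a subject."""

    subject_id: str
    age: float
    height: float          # m
    weight: float          # kg
    bmi: float             # kg/m^2
    gender: str            # "M" | "F"
    smoking: bool
    respiratory_problem: bool
    blood_pressure: bool
    physical_activity: bool
    others: bool           # diabetes / kidney failure / pregnancy
    spo2: float            # %
    pulse_rate: float      # bpm, device-reported
    label: str

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class MorphologyPrior:
    """Per-class Gaussian priors over BeatMorphology parameters."""

    mean: BeatMorphology
    sd: Mapping[str, float] = field(default_factory=dict)

    def draw(self, rng: np.random.Generator) -> BeatMorphology:
        values = dataclasses.asdict(self.mean)
        for name, sd in self.sd.items():
            values[name] = values[name] + sd * rng.standard_normal()
        # clip into the valid region rather than rejecting, so a draw always
        # yields a well-formed pulse
        values["systolic_amp"] = max(values["systolic_amp"], 0.1)
        values["diastolic_amp"] = float(
            np.clip(values["diastolic_amp"], 0.0, 0.95 * values["systolic_amp"])
        )
        values["systolic_width"] = max(values["systolic_width"], 0.04)
        values["diastolic_width"] = max(values["diastolic_width"], 0.05)
        values["systolic_center"] = max(values["systolic_center"], 0.08)
        values["diastolic_center"] = max(
            values["diastolic_center"], values["systolic_center"] + 0.12
        )
        values["beat_period"] = max(
            values["beat_period"], values["diastolic_center"] + 0.25
        )
        return BeatMorphology(**values)


@dataclass(frozen=True)
class DemographicsPrior:
    """Per-class priors over the ten background variables plus oximetry."""

    age: tuple[float, float]
    bmi: tuple[float, float]
    spo2: tuple[float, float]
    p_male: float
    p_smoking: float
    p_respiratory: float
    p_blood_pressure: float
    p_activity: float
    p_others: float

    def draw(
        self, rng: np.random.Generator, subject_id: str, label: str, pulse_rate: float
    ) -> SubjectProfile:
        gender = "M" if rng.random() < self.p_male else "F"
        height = rng.normal(1.75 if gender == "M" else 1.62, 0.06)
        height = float(np.clip(height, 1.45, 2.05))
        bmi = float(np.clip(rng.normal(*self.bmi), 16.0, 45.0))
        weight = bmi * height**2
        return SubjectProfile(
            subject_id=subject_id,
            age=float(np.clip(rng.normal(*self.age), 18.0, 95.0)),
            height=height,
            weight=weight,
            bmi=bmi,
            gender=gender,
            smoking=bool(rng.random() < self.p_smoking),
            respiratory_problem=bool(rng.random() < self.p_respiratory),
            blood_pressure=bool(rng.random() < self.p_blood_pressure),
            physical_activity=bool(rng.random() < self.p_activity),
            others=bool(rng.random() < self.p_others),
            spo2=float(np.clip(rng.normal(*self.spo2), 80.0, 100.0)),
            pulse_rate=pulse_rate,
            label=label,
        )


def _default_morphology_priors() -> dict[str, MorphologyPrior]:
    """Class-conditional pulse-shape priors.

    Healthy pulses have a clear diastolic wave and short crest time. Disease
    classes attenuate the diastolic wave (stiff arteries reflect earlier and
    weaker), lengthen the crest time and shift the heart rate; atrial
    fibrillation is fast, heart failure slow with a near-absent notch.
    """
    sd = {
        "systolic_amp": 0.05,
        "systolic_center": 0.010,
        "systolic_width": 0.004,
        "diastolic_amp": 0.030,
        "diastolic_center": 0.015,
        "diastolic_width": 0.005,
        "beat_period": 0.040,
    }

    def prior(sa, sc, sw, da, dc, dw, p) -> MorphologyPrior:
        return MorphologyPrior(
            BeatMorphology(sa, sc, sw, da, dc, dw, p), dict(sd)
        )

    return {
        "Healthy": prior(1.00, 0.18, 0.060, 0.45, 0.44, 0.090, 0.85),
        "ACS":     prior(0.90, 0.25, 0.080, 0.18, 0.55, 0.100, 0.82),
        "CVA":     prior(0.95, 0.22, 0.070, 0.20, 0.52, 0.095, 0.95),
        "DVT":     prior(1.00, 0.20, 0.065, 0.28, 0.46, 0.090, 0.75),
        "HF":      prior(0.80, 0.28, 0.100, 0.05, 0.58, 0.110, 1.05),
        "AF":      prior(1.05, 0.15, 0.050, 0.22, 0.36, 0.070, 0.62),
    }


def _default_demographics_priors() -> dict[str, DemographicsPrior]:
    return {
        "Healthy": DemographicsPrior((38, 12), (24, 3.0), (98.0, 0.6),
                                     0.5, 0.20, 0.05, 0.10, 0.60, 0.05),
        "ACS":     DemographicsPrior((62, 8), (29, 3.5), (95.0, 1.0),
                                     0.6, 0.55, 0.20, 0.65, 0.20, 0.35),
        "CVA":     DemographicsPrior((66, 8), (28, 3.5), (95.5, 1.0),
                                     0.5, 0.50, 0.20, 0.70, 0.15, 0.30),
        "DVT":     DemographicsPrior((55, 10), (30, 3.5), (96.0, 1.0),
                                     0.4, 0.35, 0.15, 0.45, 0.25, 0.30),
        "HF":      DemographicsPrior((70, 7), (28, 3.5), (93.5, 1.2),
                                     0.5, 0.45, 0.35, 0.70, 0.10, 0.45),
        "AF":      DemographicsPrior((68, 8), (27, 3.5), (95.0, 1.0),
                                     0.5, 0.40, 0.25, 0.60, 0.15, 0.30),
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-level configuration of the synthetic cohort.

    Defaults emulate the screening study's conditions: pulse-oximeter output
    at 120 Hz, at least 2 min per subject, and the per-class cohort
    composition (Healthy 200, ACS 63, CVA 50, DVT 23, HF 13, AF 13).
    """

    n_per_class: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_COUNTS)
    )
    fs: float = 120.0
    duration: float = 120.0
    class_morphology: Mapping[str, MorphologyPrior] = field(
        default_factory=_default_morphology_priors
    )
    demographics_priors: Mapping[str, DemographicsPrior] = field(
        default_factory=_default_demographics_priors
    )
    beat_jitter_sd: float = 0.02          # s, per-beat period jitter
    amplitude_jitter_frac: float = 0.03   # fractional per-beat amplitude jitter
    baseline_wander_amp: float = 0.10     # a.u.
    baseline_wander_freq: float = 0.25    # Hz, respiration band
    noise_sd: float = 0.02                # a.u., additive white noise
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_per_class:
            raise ConfigurationError("n_per_class must name at least one class")
        for label, n in self.n_per_class.items():
            if label not in CLASS_LABELS:
                raise ConfigurationError(f"unknown class label {label!r}")
            if n < 1:
                raise ConfigurationError(f"count for {label} must be >= 1")
        if self.fs <= 0 or self.duration <= 0:
            raise ConfigurationError("fs and duration must be positive")


def noise_free(config: GeneratorConfig | None = None, **kwargs) -> GeneratorConfig:
    """A copy of ``config`` with jitter, wander and noise all zeroed.

    On such recordings the sampled waveform is an exact tiling of per-subject
    beats and every analytic landmark is recoverable, which is what the
    fiducial-recovery benchmarks use.
    """
    base = config if config is not None else GeneratorConfig(**kwargs)
    return replace(
        base,
        beat_jitter_sd=0.0,
        amplitude_jitter_frac=0.0,
        baseline_wander_amp=0.0,
        noise_sd=0.0,
    )


def generate_beat(
    morph: BeatMorphology, fs: float
) -> tuple[np.ndarray, BeatGroundTruth]:
    """Sample one beat on [0, beat_period) and locate its analytic landmarks.

    The systolic peak is the global maximum of the continuous waveform; the
    dicrotic notch is the interior local minimum between the two components,
    marked absent when the diastolic component is zero or too weak to carve a
    minimum. Landmark times are refined by bounded scalar optimisation on the
    continuous model, so ground truth is independent of the sampling grid.

    Raises ``ResolutionError`` when a component width is sampled by fewer
    than 4 points.
    """
    for width, amp in (
        (morph.systolic_width, morph.systolic_amp),
        (morph.diastolic_width, morph.diastolic_amp),
    ):
        if amp > 0 and fs * width < 4:
            raise ResolutionError(
                f"width {width:.3g}s needs fs >= {4 / width:.1f} Hz, got {fs} Hz"
            )

    n = int(round(morph.beat_period * fs))
    t = np.arange(n) / fs
    samples = np.asarray(morph.waveform(t), dtype=float)

    # dense grid (50x oversampled) bracketing, then continuous refinement
    grid = np.linspace(0.0, morph.beat_period, 50 * max(n, 2), endpoint=False)
    values = np.asarray(morph.waveform(grid))
    i_max = int(np.argmax(values))
    lo = grid[max(i_max - 2, 0)]
    hi = grid[min(i_max + 2, len(grid) - 1)]
    res = minimize_scalar(
        lambda x: -float(morph.waveform(x)), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-10},
    )
    t_sys = float(res.x)
    amp_sys = float(morph.waveform(t_sys))

    t_notch = amp_notch = None
    if morph.diastolic_amp > 0:
        # search for an interior minimum between the two component centres
        mask = (grid > t_sys) & (grid < morph.diastolic_center)
        if mask.any():
            seg_t = grid[mask]
            seg_v = values[mask]
            j = int(np.argmin(seg_v))
            interior = 0 < j < len(seg_v) - 1
            if interior:
                res = minimize_scalar(
                    lambda x: float(morph.waveform(x)),
                    bounds=(seg_t[j - 1], seg_t[j + 1]),
                    method="bounded",
                    options={"xatol": 1e-10},
                )
                t_notch = float(res.x)
                amp_notch = float(morph.waveform(t_notch))

    gt = BeatGroundTruth(
        beat_index=0,
        t_onset=0.0,
        t_sys=t_sys,
        amp_sys=amp_sys,
        t_notch=t_notch,
        amp_notch=amp_notch,
        t_end=morph.beat_period,
    )
    return samples, gt


def _refine_extremum(
    fun, lo: float, hi: float, minimum: bool, n_grid: int = 400
) -> tuple[float, float]:
    """Grid-bracketed bounded refinement of a 1-D extremum of ``fun``."""
    grid = np.linspace(lo, hi, n_grid)
    vals = np.asarray(fun(grid))
    j = int(np.argmin(vals) if minimum else np.argmax(vals))
    a = grid[max(j - 1, 0)]
    b = grid[min(j + 1, n_grid - 1)]
    res = minimize_scalar(
        (lambda x: float(fun(x))) if minimum else (lambda x: -float(fun(x))),
        bounds=(a, b),
        method="bounded",
        options={"xatol": 1e-10},
    )
    x = float(res.x)
    return x, float(fun(x))


def generate_recording(
    subject_id: str,
    morph: BeatMorphology,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[PPGRecord, list[BeatGroundTruth]]:
    """Superpose jittered beats into one recording with wander and noise.

    Beats are placed at cumulative nominal periods but each beat's Gaussian
    components extend beyond its own period, so consecutive beats overlap
    smoothly: the diastolic decay runs under the next upstroke, as in real
    PPG. Ground-truth landmarks are therefore computed on the summed
    continuous model: the onset is the true local minimum (pulse foot)
    between two beats, the systolic peak / dicrotic notch account for the
    neighbouring beats' tails. Edge beats without a well-defined foot on
    both sides carry no ground-truth entry.
    """
    if config.duration < morph.beat_period:
        raise ConfigurationError("duration must cover at least one beat period")
    n_total = int(round(config.duration * config.fs))

    # draw the beat train: start times, per-beat morphologies
    starts: list[float] = []
    morphs: list[BeatMorphology] = []
    t_cursor = 0.0
    while t_cursor < config.duration:
        period = morph.beat_period
        if config.beat_jitter_sd > 0:
            period = period + config.beat_jitter_sd * rng.standard_normal()
            period = max(period, morph.diastolic_center + 0.2)
        scale = 1.0
        if config.amplitude_jitter_frac > 0:
            scale = max(
                1.0 + config.amplitude_jitter_frac * rng.standard_normal(), 0.1
            )
        for width, amp in (
            (morph.systolic_width, morph.systolic_amp),
            (morph.diastolic_width, morph.diastolic_amp),
        ):
            if amp > 0 and config.fs * width < 4:
                raise ResolutionError(
                    f"width {width:.3g}s needs fs >= {4 / width:.1f} Hz"
                )
        starts.append(t_cursor)
        morphs.append(
            replace(
                morph,
                beat_period=period,
                systolic_amp=morph.systolic_amp * scale,
                diastolic_amp=morph.diastolic_amp * scale,
            )
        )
        t_cursor += period

    # superpose each beat's components onto the global grid (tails included)
    signal = np.zeros(n_total)
    t_grid = np.arange(n_total) / config.fs
    tail = 6.0 * max(morph.systolic_width, morph.diastolic_width)
    for t0, m in zip(starts, morphs):
        i0 = max(int((t0 - tail) * config.fs), 0)
        i1 = min(int((t0 + m.beat_period + tail) * config.fs) + 1, n_total)
        signal[i0:i1] += m.waveform(t_grid[i0:i1] - t0)

    def local_model(i: int):
        """Continuous summed waveform near beat i (neighbours included)."""
        members = [
            (starts[j], morphs[j])
            for j in range(max(i - 1, 0), min(i + 2, len(starts)))
        ]

        def g(t):
            return sum(m.waveform(np.asarray(t) - t0) for t0, m in members)

        return g

    truths: list[BeatGroundTruth] = []
    for i in range(1, len(starts) - 1):
        m = morphs[i]
        g = local_model(i)
        b0 = starts[i]
        # pulse foot: local min of the summed model around the nominal start
        t_on, _ = _refine_extremum(
            g, b0 - 0.3 * morphs[i - 1].beat_period, b0 + 0.45 * m.beat_period,
            minimum=True,
        )
        b1 = starts[i + 1]
        t_end, _ = _refine_extremum(
            g, b1 - 0.3 * m.beat_period, b1 + 0.45 * morphs[i + 1].beat_period,
            minimum=True,
        )
        if not (t_on < b0 + m.systolic_center < t_end) or t_end > config.duration:
            continue
        t_sys, amp_sys = _refine_extremum(
            g, t_on, b0 + m.diastolic_center, minimum=False
        )
        t_notch = amp_notch = None
        if m.diastolic_amp > 0:
            lo, hi = t_sys + 1e-6, b0 + m.diastolic_center
            tn, an = _refine_extremum(g, lo, hi, minimum=True)
            # interior minimum only: reject hits at the bracket edges
            margin = (hi - lo) / 390.0
            if lo + margin < tn < hi - margin:
                t_notch, amp_notch = tn, an
        truths.append(
            BeatGroundTruth(
                beat_index=len(truths),
                t_onset=t_on,
                t_sys=t_sys,
                amp_sys=amp_sys,
                t_notch=t_notch,
                amp_notch=amp_notch,
                t_end=t_end,
            )
        )

    if config.baseline_wander_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        signal = signal + config.baseline_wander_amp * np.sin(
            2 * np.pi * config.baseline_wander_freq * t_grid + phase
        )
    if config.noise_sd > 0:
        signal = signal + config.noise_sd * rng.standard_normal(n_total)

    return PPGRecord(subject_id=subject_id, fs=config.fs, samples=signal), truths


@dataclass(frozen=True)
class SyntheticSubject:
    record: PPGRecord
    profile: SubjectProfile
    ground_truth: list[BeatGroundTruth]
    morphology: BeatMorphology


@dataclass(frozen=True)
class Cohort:
    subjects: list[SyntheticSubject]
    config: GeneratorConfig

    def __len__(self) -> int:
        return len(self.subjects)

    def subject_table(self) -> pd.DataFrame:
        return pd.DataFrame([s.profile.as_dict() for s in self.subjects])

    def ground_truth_table(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            for gt in s.ground_truth:
                rows.append(
                    {
                        "subject_id": s.profile.subject_id,
                        "beat_index": gt.beat_index,
                        "t_onset": gt.t_onset,
                        "t_sys": gt.t_sys,
                        "amp_sys": gt.amp_sys,
                        "t_notch": gt.t_notch,
                        "amp_notch": gt.amp_notch,
                        "t_end": gt.t_end,
                    }
                )
        return pd.DataFrame(rows)


def generate_cohort(config: GeneratorConfig | None = None) -> Cohort:
    """Generate the full synthetic cohort described by ``config``.

    Deterministic: the same (config, seed) yields an identical cohort.
    """
    config = config if config is not None else GeneratorConfig()
    master = np.random.default_rng(config.seed)
    subjects: list[SyntheticSubject] = []
    counter = 0
    for label in CLASS_LABELS:
        if label not in config.n_per_class:
            continue
        morph_prior = config.class_morphology[label]
        demo_prior = config.demographics_priors[label]
        for _ in range(config.n_per_class[label]):
            rng = np.random.default_rng(master.integers(0, 2**31 - 1))
            subject_id = f"S{counter:04d}"
            counter += 1
            morph = morph_prior.draw(rng)
            record, truths = generate_recording(subject_id, morph, config, rng)
            pulse_rate = float(
                np.clip(60.0 / morph.beat_period + rng.normal(0, 1.0), 30, 220)
            )
            profile = demo_prior.draw(rng, subject_id, label, round(pulse_rate, 1))
            subjects.append(SyntheticSubject(record, profile, truths, morph))
    return Cohort(subjects=subjects, config=config)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Write a cohort to disk as CSV recordings + JSON sidecars + tables."""
    out = Path(out_dir)
    signals = out / "signals"
    signals.mkdir(parents=True, exist_ok=True)
    for s in cohort.subjects:
        sid = s.profile.subject_id
        df = pd.DataFrame(
            {"time_s": s.record.times, "amplitude": s.record.samples}
        )
        df.to_csv(signals / f"{sid}.csv", index=False)
        sidecar = {
            "subject_id": sid,
            "fs_hz": s.record.fs,
            "label": s.profile.label,
        }
        (signals / f"{sid}.json").write_text(json.dumps(sidecar, indent=1))
    cohort.subject_table().to_csv(out / "subjects.csv", index=False)
    cohort.ground_truth_table().to_csv(out / "ground_truth.csv", index=False)


def read_recording(csv_path: str | Path) -> PPGRecord:
    """Load a two-column (time_s, amplitude) recording with its JSON sidecar."""
    csv_path = Path(csv_path)
    sidecar = json.loads(csv_path.with_suffix(".json").read_text())
    df = pd.read_csv(csv_path)
    return PPGRecord(
        subject_id=sidecar["subject_id"],
        fs=float(sidecar["fs_hz"]),
        samples=df["amplitude"].to_numpy(dtype=float),
        t0=float(df["time_s"].iloc[0]),
    )
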