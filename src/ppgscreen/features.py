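"""The 24 per-beat time-domain pulse-wave features and subject aggregation.

Timing features (s): peak-to-peak interval dT, pulse interval, crest time CT,
systolic/diastolic time, pulse transit time PTT (systolic peak -> dicrotic
notch). Amplitude features: systolic amplitude SA, notch amplitude, pulse
width PW at half height. Areas: total area under the pulse and the
diastolic/systolic area ratio IPA. Derived indices: augmentation indices of
amplitude and time, reflection index RI, stiffness index SI = height / PTT,
and the time ratios T1 = CT/dT, T2 = systolic time/dT, T3 = PTT/dT. APG
features: a, b, e wave amplitudes and the ratios b/a, e/a, (b-e)/a.

Per-beat baseline convention: the amplitude at the beat onset. Band-pass
filtering removes slow drift but each beat can retain a small offset, so all
amplitudes and areas are measured above the onset value.

Features undefined on a beat (no notch, last beat's dT, ...) are NaN; the
subject-level aggregation is feature-wise NaN-aware.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MalformedBeatError, SubjectExcludedError
from .fiducials import APGWave, FiducialSet, extract_fiducials
from .preprocess import Beat, FilterSpec, filter_record, segment_beats
from .synthgen import Cohort, PPGRecord, SubjectProfile

#: The per-beat feature catalogue, in declaration order (used downstream as
#: the tie-break order of the greedy feature search).
FEATURE_NAMES: tuple[str, ...] = (
    "SA",
    "dT",
    "pulse_interval",
    "CT",
    "PW",
    "notch_amp",
    "diastolic_time",
    "systolic_time",
    "PTT",
    "total_area",
    "IPA",
    "AI_amp",
    "RI",
    "AI_time",
    "SI",
    "T1",
    "T2",
    "T3",
    "a",
    "b",
    "e",
    "b_over_a",
    "e_over_a",
    "b_minus_e_over_a",
)

MIN_BEATS_PER_SUBJECT = 5


def timing_features(
    fid: FiducialSet, next_fid: FiducialSet | None = None
) -> dict[str, float]:
    """Interval features of one beat; notch-dependent entries NaN if absent.

    dT spans to the next accepted beat's systolic peak and is NaN for the
    last beat (or across a rejected beat).
    """
    out = {
        "pulse_interval": fid.t_end - fid.t_onset,
        "CT": fid.t_sys - fid.t_onset,
        "dT": math.nan,
        "PTT": math.nan,
        "systolic_time": math.nan,
        "diastolic_time": math.nan,
    }
    if next_fid is not None:
        out["dT"] = next_fid.t_sys - fid.t_sys
    if fid.has_notch:
        out["PTT"] = fid.t_notch - fid.t_sys
        out["systolic_time"] = fid.t_notch - fid.t_onset
        out["diastolic_time"] = fid.t_end - fid.t_notch
    return out


def amplitude_and_width(beat: Beat, fid: FiducialSet) -> dict[str, float]:
    """SA, notch amplitude and half-height pulse width, above the onset baseline."""
    baseline = float(beat.samples[0])
    sa = fid.amp_sys - baseline
    if sa <= 0:
        raise MalformedBeatError("systolic amplitude not above the onset baseline")
    notch_amp = math.nan
    if fid.has_notch and fid.amp_notch is not None:
        notch_amp = fid.amp_notch - baseline

    half = baseline + sa / 2.0
    x = beat.samples
    i_sys = int(round((fid.t_sys - fid.t_onset) * beat.fs))
    above = x >= half
    if not above[i_sys]:
        raise MalformedBeatError("systolic peak below its own half height")
    # first crossing before the peak, last crossing after it, with sub-sample
    # linear interpolation at both edges
    i = i_sys
    while i > 0 and above[i - 1]:
        i -= 1
    if i == 0:
        t_left = 0.0
    else:
        frac = (half - x[i - 1]) / (x[i] - x[i - 1])
        t_left = (i - 1 + frac) / beat.fs
    j = i_sys
    while j < len(x) - 1 and above[j + 1]:
        j += 1
    if j == len(x) - 1:
        t_right = (len(x) - 1) / beat.fs
    else:
        frac = (x[j] - half) / (x[j] - x[j + 1])
        t_right = (j + frac) / beat.fs
    return {"SA": sa, "notch_amp": notch_amp, "PW": t_right - t_left}


def areas(beat: Beat, fid: FiducialSet) -> dict[str, float]:
    """Trapezoidal areas of the baseline-subtracted pulse, split at the notch.

    IPA (and the split) require a notch; without one only the total area is
    defined.
    """
    baseline = float(beat.samples[0])
    y = beat.samples - baseline
    dx = 1.0 / beat.fs
    out = {
        "total_area": float(np.trapezoid(y, dx=dx)),
        "systolic_area": math.nan,
        "diastolic_area": math.nan,
        "IPA": math.nan,
    }
    if fid.has_notch:
        i_notch = int(round((fid.t_notch - fid.t_onset) * beat.fs))
        i_notch = min(max(i_notch, 1), len(y) - 2)
        sys_area = float(np.trapezoid(y[: i_notch + 1], dx=dx))
        dia_area = float(np.trapezoid(y[i_notch:], dx=dx))
        if sys_area <= 0:
            raise MalformedBeatError("non-positive systolic area")
        out["systolic_area"] = sys_area
        out["diastolic_area"] = dia_area
        out["IPA"] = dia_area / sys_area
        # keep the additivity identity exact: the split shares its boundary
        out["total_area"] = sys_area + dia_area
    return out


def indices(feats: dict[str, float], height_m: float) -> dict[str, float]:
    """The augmentation-index / time-ratio catalogue.

    AI_amp = (SA - notch)/SA, RI = notch/SA, AI_time = PTT/pulse interval,
    SI = height/PTT (m/s), T1 = CT/dT, T2 = systolic time/dT, T3 = PTT/dT.
    Entries whose inputs are NaN (absent notch, last-beat dT) stay NaN.
    """
    sa = feats["SA"]
    notch = feats["notch_amp"]
    ptt = feats["PTT"]
    dt = feats["dT"]
    out = {k: math.nan for k in ("AI_amp", "RI", "AI_time", "SI", "T1", "T2", "T3")}
    if not math.isnan(notch):
        out["AI_amp"] = (sa - notch) / sa
        out["RI"] = notch / sa
    if not math.isnan(ptt) and ptt > 0:
        out["AI_time"] = ptt / feats["pulse_interval"]
        out["SI"] = height_m / ptt
    if not math.isnan(dt) and dt > 0:
        out["T1"] = feats["CT"] / dt
        if not math.isnan(feats["systolic_time"]):
            out["T2"] = feats["systolic_time"] / dt
        if not math.isnan(ptt):
            out["T3"] = ptt / dt
    return out


def apg_features(
    a: APGWave, b: APGWave, e: APGWave | None
) -> dict[str, float]:
    """APG wave amplitudes and their stiffness-linked ratios."""
    if a.amp == 0:
        raise MalformedBeatError("APG a wave has zero amplitude")
    out = {
        "a": a.amp,
        "b": b.amp,
        "e": math.nan,
        "b_over_a": b.amp / a.amp,
        "e_over_a": math.nan,
        "b_minus_e_over_a": math.nan,
    }
    if e is not None:
        out["e"] = e.amp
        out["e_over_a"] = e.amp / a.amp
        out["b_minus_e_over_a"] = (b.amp - e.amp) / a.amp
    return out


def compute_beat_features(
    beat: Beat,
    fid: FiducialSet,
    height_m: float,
    next_fid: FiducialSet | None = None,
) -> dict[str, float]:
    """Assemble the full 24-feature vector for one beat (NaN where undefined)."""
    feats = timing_features(fid, next_fid)
    feats.update(amplitude_and_width(beat, fid))
    feats.update(areas(beat, fid))
    feats.update(indices(feats, height_m))
    if fid.apg_a is None or fid.apg_b is None:
        raise MalformedBeatError("APG a/b waves missing")
    feats.update(apg_features(fid.apg_a, fid.apg_b, fid.apg_e))
    return {name: feats[name] for name in FEATURE_NAMES}


@dataclass(frozen=True)
class SubjectFeatures:
    """Per-subject aggregate: mean and sample variance of each beat feature."""

    subject_id: str
    means: dict[str, float]
    variances: dict[str, float]
    n_beats_used: int
    notch_fraction: float
    pulse_rate_ppg: float     # 60 / mean(dT), derived cross-check
    profile: SubjectProfile

    def as_row(self) -> dict[str, float | str | bool]:
        row: dict[str, float | str | bool] = {"subject_id": self.subject_id}
        for name in FEATURE_NAMES:
            row[f"{name}_mean"] = self.means[name]
            row[f"{name}_var"] = self.variances[name]
        p = self.profile
        row.update(
            age=p.age, height=p.height, weight=p.weight, bmi=p.bmi,
            gender=1.0 if p.gender == "M" else 0.0,
            smoking=float(p.smoking),
            respiratory_problem=float(p.respiratory_problem),
            blood_pressure=float(p.blood_pressure),
            physical_activity=float(p.physical_activity),
            others=float(p.others),
            spo2=p.spo2, pulse_rate=p.pulse_rate,
            n_beats_used=self.n_beats_used,
            notch_fraction=self.notch_fraction,
            pulse_rate_ppg=self.pulse_rate_ppg,
            label=p.label,
        )
        return row


def aggregate_subject(
    beat_features: list[dict[str, float]], profile: SubjectProfile
) -> SubjectFeatures:
    """Feature-wise NaN-aware mean and sample variance (n-1) over beats.

    A subject needs at least 5 beats with a valid systolic amplitude;
    otherwise the subject is excluded from the study table.
    """
    valid = [bf for bf in beat_features if not math.isnan(bf["SA"])]
    if len(valid) < MIN_BEATS_PER_SUBJECT:
        raise SubjectExcludedError(
            f"{profile.subject_id}: only {len(valid)} valid beats "
            f"(need {MIN_BEATS_PER_SUBJECT})"
        )
    table = pd.DataFrame(valid, columns=list(FEATURE_NAMES))
    means = table.mean(skipna=True).to_dict()
    variances = table.var(ddof=1, skipna=True).to_dict()
    notch_fraction = float(table["PTT"].notna().mean())
    mean_dt = table["dT"].mean(skipna=True)
    pulse_rate_ppg = float(60.0 / mean_dt) if mean_dt and mean_dt > 0 else math.nan
    return SubjectFeatures(
        subject_id=profile.subject_id,
        means={k: float(v) for k, v in means.items()},
        variances={k: float(v) for k, v in variances.items()},
        n_beats_used=len(valid),
        notch_fraction=notch_fraction,
        pulse_rate_ppg=pulse_rate_ppg,
        profile=profile,
    )


def extract_subject(
    record: PPGRecord,
    profile: SubjectProfile,
    filter_spec: FilterSpec | None = None,
    min_beat_s: float = 0.33,
    max_beat_s: float = 2.0,
) -> SubjectFeatures:
    """Filter, segment and featurise one subject's recording."""
    filtered = filter_record(record, filter_spec)
    beats = segment_beats(filtered, min_beat_s=min_beat_s, max_beat_s=max_beat_s)
    fids: list[FiducialSet | None] = []
    for beat in beats:
        try:
            fids.append(extract_fiducials(beat))
        except MalformedBeatError:
            fids.append(None)

    rows: list[dict[str, float]] = []
    for k, (beat, fid) in enumerate(zip(beats, fids)):
        if fid is None:
            continue
        next_fid = None
        if k + 1 < len(beats) and fids[k + 1] is not None:
            # dT only across truly consecutive beats (shared boundary)
            if beats[k + 1].onset_index == beat.end_index:
                next_fid = fids[k + 1]
        try:
            rows.append(compute_beat_features(beat, fid, profile.height, next_fid))
        except MalformedBeatError:
            continue
    return aggregate_subject(rows, profile)


def extract_cohort(
    cohort: Cohort,
    filter_spec: FilterSpec | None = None,
) -> pd.DataFrame:
    """Per-subject wide feature table for a whole synthetic cohort.

    Columns: ``<feature>_mean`` / ``<feature>_var`` for the 24 features,
    demographics, SpO2, device pulse rate, bookkeeping columns and the class
    label. Subjects with too few valid beats are dropped.
    """
    rows = []
    for s in cohort.subjects:
        try:
            sf = extract_subject(s.record, s.profile, filter_spec)
        except SubjectExcludedError:
            continue
        rows.append(sf.as_row())
    return pd.DataFrame(rows)


def beat_features_long(
    record: PPGRecord,
    profile: SubjectProfile,
    filter_spec: FilterSpec | None = None,
) -> pd.DataFrame:
    """Long-format (subject_id, beat_index, feature, value) per-beat table."""
    filtered = filter_record(record, filter_spec)
    beats = segment_beats(filtered)
    rows = []
    fids = []
    for beat in beats:
        try:
            fids.append(extract_fiducials(beat))
        except MalformedBeatError:
            fids.append(None)
    for k, (beat, fid) in enumerate(zip(beats, fids)):
        if fid is None:
            continue
        next_fid = None
        if k + 1 < len(beats) and fids[k + 1] is not None:
            if beats[k + 1].onset_index == beat.end_index:
                next_fid = fids[k + 1]
        try:
            feats = compute_beat_features(beat, fid, profile.height, next_fid)
        except MalformedBeatError:
            continue
        for name, value in feats.items():
            rows.append(
                {
                    "subject_id": profile.subject_id,
                    "beat_index": beat.beat_index,
                    "feature": name,
                    "value": value,
                }
            )
    return pd.DataFrame(rows)
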