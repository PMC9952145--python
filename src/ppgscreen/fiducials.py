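"""Per-beat landmark detection: systolic peak, dicrotic notch, APG a/b/e waves.

The acceleration plethysmogram (APG) is the second derivative of the pulse;
its first positive peak (a), first negative peak (b) and the positive wave
near the dicrotic notch (e) index arterial stiffness. The notch itself is
found as the lowest local minimum of the pulse in a physiological window
after the systolic peak; when the diastolic wave is too weak to carve a
minimum (a "shoulder" pulse, common in stiff-artery subjects) the APG e-wave
position is used as a fallback, and when both fail the notch is reported
absent — a valid outcome, not an error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import MalformedBeatError
from .preprocess import Beat

APG_WINDOW = 11          # Savitzky-Golay window at 120 Hz; auto-shrunk
APG_POLYORDER = 3
APG_PROMINENCE_FRAC = 0.05
NOTCH_WINDOW_FRAC = 0.4  # notch searched in (t_sys, t_sys + frac * pulse interval]
MIN_E_DELAY_S = 0.05     # e wave cannot sit on the systolic apex itself


@dataclass(frozen=True)
class APGWave:
    t: float      # s, relative to beat onset
    amp: float    # a.u. / s^2


@dataclass(frozen=True)
class FiducialSet:
    """Landmarks of one beat; times in seconds relative to the recording."""

    t_onset: float
    t_sys: float
    amp_sys: float
    t_end: float
    t_notch: float | None = None
    amp_notch: float | None = None
    notch_source: str = "absent"   # derivative-minimum | apg-e-wave | absent
    apg_a: APGWave | None = None
    apg_b: APGWave | None = None
    apg_e: APGWave | None = None

    @property
    def has_notch(self) -> bool:
        return self.t_notch is not None

    def shifted(self, dt: float) -> "FiducialSet":
        return FiducialSet(
            t_onset=self.t_onset + dt,
            t_sys=self.t_sys + dt,
            amp_sys=self.amp_sys,
            t_end=self.t_end + dt,
            t_notch=None if self.t_notch is None else self.t_notch + dt,
            amp_notch=self.amp_notch,
            notch_source=self.notch_source,
            apg_a=self.apg_a,
            apg_b=self.apg_b,
            apg_e=self.apg_e,
        )


def detect_systolic_peak(beat: Beat) -> tuple[float, float]:
    """Locate the highest (and on ties, first) peak of the beat.

    Returns (time from beat onset in s, amplitude). A maximum sitting on the
    beat boundary means there is no pulse peak at all.
    """
    x = beat.samples
    i = int(np.argmax(x))  # argmax returns the first index on ties
    if i == 0 or i == len(x) - 1:
        raise MalformedBeatError("beat maximum lies on the boundary")
    return i / beat.fs, float(x[i])


def compute_apg(beat: Beat, window: int = APG_WINDOW) -> np.ndarray:
    """Smoothed second derivative (APG) of the beat, same length as the beat.

    Uses a Savitzky-Golay local-polynomial differentiator: raw second
    finite differences amplify noise by fs^2, so smoothing is not optional.
    """
    n = len(beat.samples)
    if n < APG_POLYORDER + 2:
        raise MalformedBeatError(f"beat of {n} samples too short for APG")
    if window > n:
        window = n if n % 2 == 1 else n - 1
        warnings.warn(
            f"APG window shrunk to {window} for a {n}-sample beat", stacklevel=2
        )
    if window % 2 == 0:
        window -= 1
    window = max(window, APG_POLYORDER + 2 - (APG_POLYORDER % 2))
    return sps.savgol_filter(
        beat.samples, window, APG_POLYORDER, deriv=2, delta=1.0 / beat.fs
    )


def detect_apg_waves(
    beat: Beat,
    apg: np.ndarray,
    t_sys: float,
    prominence_frac: float = APG_PROMINENCE_FRAC,
) -> tuple[APGWave, APGWave, APGWave | None]:
    """Find the a, b and e waves of the APG.

    a: first prominent maximum; b: first prominent minimum after a;
    e: first prominent maximum after the systolic peak (at least
    ``MIN_E_DELAY_S`` later, so smoothing side-lobes of the apex are never
    mistaken for it). A missing a or b wave makes the beat unusable; a
    missing e wave only disables the notch fallback and is returned as None.
    """
    rng = float(apg.max() - apg.min())
    if rng <= 0:
        raise MalformedBeatError("flat APG")
    prominence = prominence_frac * rng
    maxima, _ = sps.find_peaks(apg, prominence=prominence)
    minima, _ = sps.find_peaks(-apg, prominence=prominence)
    if len(maxima) == 0:
        raise MalformedBeatError("no APG a wave")
    i_a = int(maxima[0])
    after_a = minima[minima > i_a]
    if len(after_a) == 0:
        raise MalformedBeatError("no APG b wave")
    i_b = int(after_a[0])

    i_min_e = int(round((t_sys + MIN_E_DELAY_S) * beat.fs))
    e_candidates = maxima[(maxima > i_min_e) & (maxima > i_b)]
    e = None
    if len(e_candidates) > 0:
        i_e = int(e_candidates[0])
        e = APGWave(t=i_e / beat.fs, amp=float(apg[i_e]))

    return (
        APGWave(t=i_a / beat.fs, amp=float(apg[i_a])),
        APGWave(t=i_b / beat.fs, amp=float(apg[i_b])),
        e,
    )


def detect_dicrotic_notch(
    beat: Beat,
    t_sys: float,
    apg_e: APGWave | None = None,
    window_frac: float = NOTCH_WINDOW_FRAC,
) -> tuple[float | None, float | None, str]:
    """Locate the dicrotic notch, or report it absent.

    Primary: lowest local minimum of the beat in
    (t_sys, t_sys + window_frac * pulse interval]. Fallback: the APG e-wave
    time, which marks the notch when the pulse has only a shoulder there —
    accepted only if the first derivative actually has an interior local
    maximum after the systolic peak (the shoulder signature); a plain
    monotone decay has no such maximum, so systolic-only pulses stay
    notch-free.
    """
    x = beat.samples
    i_sys = int(round(t_sys * beat.fs))
    i_hi = min(int(round((t_sys + window_frac * beat.duration) * beat.fs)), len(x) - 1)
    if i_hi - i_sys >= 3:
        seg = x[i_sys : i_hi + 1]
        minima, _ = sps.find_peaks(-seg)
        if len(minima) > 0:
            j = int(minima[np.argmin(seg[minima])])
            i_notch = i_sys + j
            return i_notch / beat.fs, float(x[i_notch]), "derivative-minimum"
    if apg_e is not None and t_sys < apg_e.t < len(x) / beat.fs:
        if _has_shoulder(beat, i_sys):
            i_e = int(round(apg_e.t * beat.fs))
            return apg_e.t, float(x[min(i_e, len(x) - 1)]), "apg-e-wave"
    return None, None, "absent"


def _has_shoulder(beat: Beat, i_sys: int) -> bool:
    """True when the descending limb flattens locally (dicrotic shoulder)."""
    n = len(beat.samples)
    window = APG_WINDOW if APG_WINDOW <= n else (n if n % 2 == 1 else n - 1)
    vel = sps.savgol_filter(
        beat.samples, window, APG_POLYORDER, deriv=1, delta=1.0 / beat.fs
    )
    tail = vel[i_sys + 1 :]
    if len(tail) < 5:
        return False
    maxima, _ = sps.find_peaks(tail, prominence=0.02 * float(np.abs(vel).max()))
    return len(maxima) > 0


def extract_fiducials(beat: Beat, apg_window: int = APG_WINDOW) -> FiducialSet:
    """Run the full landmark chain on one segmented beat.

    Times are absolute (recording time): the beat's onset offset is added to
    every within-beat landmark, so that cross-beat intervals can be formed.
    """
    t_sys_rel, amp_sys = detect_systolic_peak(beat)
    apg = compute_apg(beat, window=apg_window)
    a, b, e = detect_apg_waves(beat, apg, t_sys_rel)
    t_notch_rel, amp_notch, source = detect_dicrotic_notch(beat, t_sys_rel, apg_e=e)
    t0 = beat.t_onset
    return FiducialSet(
        t_onset=t0,
        t_sys=t0 + t_sys_rel,
        amp_sys=amp_sys,
        t_end=t0 + beat.duration,
        t_notch=None if t_notch_rel is None else t0 + t_notch_rel,
        amp_notch=amp_notch,
        notch_source=source,
        apg_a=a,
        apg_b=b,
        apg_e=e,
    )
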