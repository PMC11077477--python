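"""Single-neuron calcium-trace preprocessing and activation metrics.

Implements every per-trace formula used on the two-photon GCaMP6s recordings:

* baseline z-scoring  z = (Fraw - mu) / sigma  with mu, sigma taken over the
  30 s (configurable) pre-presentation baseline window;
* consumption preprocessing: a second-order zero-phase Butterworth low-pass
  (normalized cut-on 0.266, as a fraction of Nyquist) followed by z-scoring
  against baseline statistics pooled over the below-median-activity traces;
* drug-session normalization Fcorr = (F - mu) / mu per 1-minute segment, mu
  being the mean of the lowest quintile of samples in that segment;
* peak detection at 3 sigma with a ~1.3 s minimum inter-peak distance
  (the GCaMP6s decay time);
* activation calling for natural-reward consumption (mean response > 3 sigma
  from 10 s after consumption start) and for drug sessions (any supra-3-sigma
  peak inside the 20-40 min post-injection window for cocaine, 30-50 min for
  morphine);
* the bounded preference-strength score
  (Peak_drug - Peak_natural) / (Peak_drug + Peak_natural).

All time windows are half-open [start, end); frames are 0-based.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy import signal

from .errors import InvalidInputError

logger = logging.getLogger(__name__)

DEFAULT_FRAME_RATE = 4.82        # Hz, two-photon acquisition rate
BUTTER_ORDER = 2
BUTTER_CUTON = 0.266             # fraction of Nyquist
PEAK_SIGMA_MULT = 3.0
PEAK_MIN_DISTANCE_S = 1.3        # GCaMP6s decay time
DRUG_WINDOWS_MIN = {"cocaine": (20.0, 40.0), "morphine": (30.0, 50.0)}
CONSUMPTION_DELAY_S = 10.0
SEGMENT_LEN_S = 60.0             # drug sessions: 1-min imaging segments


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class CalciumSession:
    """One imaging session: raw fluorescence plus behavioral annotations.

    ``F`` is neurons x frames (a.u.); ``events`` maps labels such as
    ``consumption_start``, ``injection``, ``licks`` to times in seconds
    (scalars or arrays); ``baseline_window`` is a half-open [t0, t1) span in
    seconds; ``neuron_ids`` are stable identifiers for cross-day matching.
    """

    F: np.ndarray
    frame_rate: float = DEFAULT_FRAME_RATE
    velocity: np.ndarray | None = None
    events: dict = field(default_factory=dict)
    baseline_window: tuple[float, float] = (0.0, 30.0)
    cell_type: str = "D1"
    session_id: str = "session"
    day: int = 0
    neuron_ids: np.ndarray | None = None
    frame_times: np.ndarray | None = None  # s; None means continuous from 0

    def __post_init__(self) -> None:
        self.F = np.atleast_2d(np.asarray(self.F, dtype=float))
        if self.F.size and not np.all(np.isfinite(self.F)):
            raise InvalidInputError("non-finite fluorescence")
        if self.frame_rate <= 0:
            raise InvalidInputError("frame_rate must be positive")
        if self.velocity is not None:
            self.velocity = np.asarray(self.velocity, dtype=float)
            if self.n_neurons > 0 and self.velocity.shape[0] != self.n_frames:
                raise InvalidInputError("velocity length != frame count")
        if self.neuron_ids is None:
            self.neuron_ids = np.arange(self.n_neurons)
        else:
            self.neuron_ids = np.asarray(self.neuron_ids)
        if self.frame_times is not None:
            self.frame_times = np.asarray(self.frame_times, dtype=float)
            if self.frame_times.shape[0] != self.n_frames:
                raise InvalidInputError("frame_times length != frame count")

    @property
    def n_neurons(self) -> int:
        return 0 if self.F.size == 0 else self.F.shape[0]

    @property
    def n_frames(self) -> int:
        return 0 if self.F.size == 0 else self.F.shape[1]

    def times(self) -> np.ndarray:
        """Per-frame acquisition times in seconds.

        Continuous sessions run from 0 at the frame rate; sessions recorded in
        scheduled windows (e.g. 1 min every 10 min post injection) carry
        explicit ``frame_times`` for the concatenated trace.
        """
        if self.frame_times is not None:
            return self.frame_times
        return np.arange(self.n_frames) / self.frame_rate

    def frames_in(self, t0: float, t1: float) -> np.ndarray:
        """Frame indices acquired inside the half-open span [t0, t1) s."""
        t = self.times()
        return np.flatnonzero((t >= t0) & (t < t1))

    def baseline_frames(self) -> np.ndarray:
        frames = self.frames_in(*self.baseline_window)
        if frames.size == 0:
            raise InvalidInputError("baseline_window outside recording")
        return frames

    # -- HDF5 interchange (groups /F, /velocity, /events/<label>) ------------

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("F", data=self.F)
            if self.velocity is not None:
                f.create_dataset("velocity", data=self.velocity)
            ev = f.create_group("events")
            for label, t in self.events.items():
                ev.create_dataset(label, data=np.atleast_1d(np.asarray(t, float)))
            f.create_dataset("neuron_ids", data=np.asarray(self.neuron_ids))
            if self.frame_times is not None:
                f.create_dataset("frame_times", data=self.frame_times)
            f.attrs["frame_rate"] = self.frame_rate
            f.attrs["cell_type"] = self.cell_type
            f.attrs["session_id"] = self.session_id
            f.attrs["day"] = self.day
            f.attrs["baseline_window"] = list(self.baseline_window)

    @classmethod
    def from_hdf5(cls, path) -> "CalciumSession":
        with h5py.File(path, "r") as f:
            events = {}
            for label, ds in f["events"].items():
                arr = ds[()]
                events[label] = float(arr[0]) if arr.shape == (1,) else arr
            return cls(
                F=f["F"][()],
                frame_rate=float(f.attrs["frame_rate"]),
                velocity=f["velocity"][()] if "velocity" in f else None,
                events=events,
                baseline_window=tuple(f.attrs["baseline_window"]),
                cell_type=str(f.attrs["cell_type"]),
                session_id=str(f.attrs["session_id"]),
                day=int(f.attrs["day"]),
                neuron_ids=f["neuron_ids"][()],
                frame_times=f["frame_times"][()] if "frame_times" in f else None,
            )


@dataclass
class PeakSet:
    """Detected peaks per neuron: parallel lists of frame indices / amplitudes."""

    frames: list[np.ndarray]
    amplitudes: list[np.ndarray]

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class ActivationCall:
    """Per-neuron activation flags for one stimulus."""

    stimulus: str
    activated: np.ndarray          # bool per neuron
    peak_amplitude: np.ndarray     # response statistic used for the call
    excluded: np.ndarray           # neurons with degenerate baseline (sigma=0)

    @property
    def n_activated(self) -> int:
        return int(self.activated.sum())


# ---------------------------------------------------------------------------
# trace transforms
# ---------------------------------------------------------------------------

def zscore_baseline(session: CalciumSession) -> tuple[np.ndarray, np.ndarray]:
    """Per-neuron z = (Fraw - mu)/sigma with baseline-window statistics.

    Returns (z, excluded): neurons whose baseline sigma is zero are flagged in
    ``excluded``, their rows set to 0, and they must be left out of any
    sigma-threshold call downstream.
    """
    frames = session.baseline_frames()
    if frames.size < 2:
        raise InvalidInputError("baseline window must contain >= 2 frames")
    base = session.F[:, frames]
    mu = base.mean(axis=1, keepdims=True)
    sd = base.std(axis=1, ddof=1, keepdims=True)
    excluded = sd[:, 0] == 0
    if excluded.any():
        logger.warning("%d neurons with zero baseline variance excluded",
                       int(excluded.sum()))
    sd_safe = np.where(sd == 0, 1.0, sd)
    z = (session.F - mu) / sd_safe
    z[excluded] = 0.0
    return z, excluded


def butter_lowpass(F: np.ndarray) -> np.ndarray:
    """Second-order zero-phase Butterworth low-pass, cut-on 0.266 of Nyquist."""
    b, a = signal.butter(BUTTER_ORDER, BUTTER_CUTON)
    return signal.filtfilt(b, a, np.atleast_2d(F), axis=1)


def consumption_preprocess(session: CalciumSession) -> np.ndarray:
    """Low-pass filter, then z-score against pooled below-median baselines.

    Each trace is filtered (zero phase); per-trace baseline means are ranked
    and the traces whose baseline mean falls strictly below the median form
    the reference subset.  mu and sigma are the mean and sd (ddof=1) of the
    baseline samples pooled over that subset, applied to every trace.
    """
    if session.n_neurons < 4:
        raise InvalidInputError("consumption_preprocess needs >= 4 traces")
    Ff = butter_lowpass(session.F)
    frames = session.baseline_frames()
    base = Ff[:, frames]
    means = base.mean(axis=1)
    below = means < np.median(means)
    if below.sum() < 2:
        raise InvalidInputError("fewer than 2 below-median baseline traces")
    pooled = base[below].ravel()
    mu = pooled.mean()
    sd = pooled.std(ddof=1)
    if sd == 0:
        raise InvalidInputError("pooled baseline has zero variance")
    return (Ff - mu) / sd


def segment_slices(n_frames: int, frame_rate: float,
                   segment_len_s: float = SEGMENT_LEN_S) -> list[slice]:
    """Consecutive half-open frame slices of ~segment_len_s each.

    The final partial segment is kept if it has >= 5 frames, otherwise merged
    into the previous one.
    """
    seg = int(round(segment_len_s * frame_rate))
    if seg < 5:
        raise InvalidInputError("segment shorter than 5 frames")
    edges = list(range(0, n_frames, seg))
    slices = [slice(s, min(s + seg, n_frames)) for s in edges]
    if len(slices) > 1 and (slices[-1].stop - slices[-1].start) < 5:
        last = slices.pop()
        prev = slices.pop()
        slices.append(slice(prev.start, last.stop))
    return slices


def drug_normalize(F: np.ndarray, frame_rate: float = DEFAULT_FRAME_RATE,
                   segment_len_s: float = SEGMENT_LEN_S) -> np.ndarray:
    """Fcorr = (F - mu)/mu per 1-minute segment; mu = lowest-quintile mean.

    The lowest quintile of a segment of n samples is its ceil(0.2 n) smallest
    values (never empty).  Segments are normalized independently and
    concatenated in time order.  Scale-free: multiplying F by a > 0 leaves
    Fcorr unchanged.
    """
    F = np.atleast_2d(np.asarray(F, dtype=float))
    out = np.empty_like(F)
    for sl in segment_slices(F.shape[1], frame_rate, segment_len_s):
        seg = F[:, sl]
        n = seg.shape[1]
        if n < 5:
            raise InvalidInputError("segment has fewer than 5 frames")
        q = math.ceil(0.2 * n)
        lowest = np.sort(seg, axis=1)[:, :q]
        mu = lowest.mean(axis=1, keepdims=True)
        if np.any(mu <= 0):
            raise InvalidInputError("non-positive lowest-quintile mean "
                                    "(fluorescence must be positive)")
        out[:, sl] = (seg - mu) / mu
    return out


# ---------------------------------------------------------------------------
# peaks and activation
# ---------------------------------------------------------------------------

def detect_peaks_trace(
    trace: np.ndarray,
    sigma: float,
    min_distance_s: float = PEAK_MIN_DISTANCE_S,
    frame_rate: float = DEFAULT_FRAME_RATE,
    sigma_mult: float = PEAK_SIGMA_MULT,
) -> tuple[np.ndarray, np.ndarray]:
    """Local maxima above sigma_mult*sigma, pruned to a minimum spacing.

    Candidate maxima are pruned greedily highest-first (ties: earlier frame
    wins) so that surviving peaks are >= round(min_distance_s * frame_rate)
    frames apart.
    """
    if sigma <= 0:
        raise InvalidInputError("sigma must be positive")
    if min_distance_s < 0:
        raise InvalidInputError("min_distance_s must be >= 0")
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        return np.empty(0, dtype=int), np.empty(0)
    cand, _ = signal.find_peaks(trace, height=sigma_mult * sigma)
    if cand.size == 0:
        return np.empty(0, dtype=int), np.empty(0)
    d = int(round(min_distance_s * frame_rate))
    order = sorted(range(cand.size), key=lambda i: (-trace[cand[i]], cand[i]))
    kept: list[int] = []
    for i in order:
        f = cand[i]
        if all(abs(f - g) >= d for g in kept):
            kept.append(f)
    kept.sort()
    kept_arr = np.asarray(kept, dtype=int)
    return kept_arr, trace[kept_arr]


def detect_peaks(
    traces: np.ndarray,
    sigma: np.ndarray | float,
    min_distance_s: float = PEAK_MIN_DISTANCE_S,
    frame_rate: float = DEFAULT_FRAME_RATE,
    sigma_mult: float = PEAK_SIGMA_MULT,
) -> PeakSet:
    """Per-neuron peak detection (see :func:`detect_peaks_trace`)."""
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    sigmas = np.broadcast_to(np.asarray(sigma, dtype=float), (traces.shape[0],))
    frames, amps = [], []
    for row, s in zip(traces, sigmas):
        f, a = detect_peaks_trace(row, s, min_distance_s, frame_rate, sigma_mult)
        frames.append(f)
        amps.append(a)
    return PeakSet(frames, amps)


def call_activation(
    session: CalciumSession,
    stimulus: str,
    sigma_mult: float = PEAK_SIGMA_MULT,
    response_window_end_s: float | None = None,
    drug_windows_min: dict[str, tuple[float, float]] = DRUG_WINDOWS_MIN,
    min_distance_s: float = PEAK_MIN_DISTANCE_S,
) -> ActivationCall:
    """Call activated neurons for one stimulus.

    Consumption stimuli (anything not in ``drug_windows_min``, e.g. food or
    water): traces are consumption-preprocessed and a neuron is activated iff
    its mean z over [consumption_start + 10 s, window end) exceeds
    ``sigma_mult`` (window end defaults to the end of the recording).

    Drug stimuli (cocaine / morphine): traces are Fcorr-normalized; a
    per-neuron sigma is estimated on the pre-injection baseline of Fcorr;
    a neuron is activated iff any detected supra-threshold peak falls in the
    half-open drug window (minutes post injection).
    """
    if stimulus in drug_windows_min:
        if "injection" not in session.events:
            raise InvalidInputError("missing event time: 'injection'")
        t_inj = float(np.atleast_1d(session.events["injection"])[0])
        # drug traces are low-pass filtered like consumption traces before
        # segment-wise Fcorr normalization; sigma is the sd of the *measured*
        # (unfiltered) Fcorr over the 1-min pre-injection baseline, and peak
        # heights are taken above the resting baseline mean -- the same
        # above-baseline convention as the consumption z-score criterion
        fcorr = drug_normalize(butter_lowpass(session.F), session.frame_rate)
        t = session.times()
        base_frames = np.flatnonzero(t < t_inj)
        if base_frames.size < 2:
            raise InvalidInputError("no pre-injection baseline frames")
        raw_base = drug_normalize(
            session.F, session.frame_rate)[:, base_frames]
        sd = raw_base.std(axis=1, ddof=1)
        excluded = sd == 0
        fcorr = fcorr - fcorr[:, base_frames].mean(axis=1, keepdims=True)
        lo_min, hi_min = drug_windows_min[stimulus]
        lo = t_inj + lo_min * 60.0
        hi = t_inj + hi_min * 60.0
        activated = np.zeros(session.n_neurons, dtype=bool)
        amp = np.zeros(session.n_neurons)
        for i in range(session.n_neurons):
            if excluded[i]:
                continue
            frames, amps = detect_peaks_trace(
                fcorr[i], sd[i], min_distance_s, session.frame_rate, sigma_mult
            )
            times = t[frames]
            in_win = (times >= lo) & (times < hi)
            if in_win.any():
                activated[i] = True
                amp[i] = amps[in_win].max()
        return ActivationCall(stimulus, activated, amp, excluded)

    # consumption mode
    key = f"{stimulus}_start" if f"{stimulus}_start" in session.events else \
        "consumption_start"
    if key not in session.events:
        raise InvalidInputError(f"missing event time: {key!r}")
    t0 = float(np.atleast_1d(session.events[key])[0]) + CONSUMPTION_DELAY_S
    t1 = response_window_end_s if response_window_end_s is not None else \
        float(session.times()[-1]) + 1.0 / session.frame_rate
    frames = session.frames_in(t0, t1)
    if frames.size == 0:
        raise InvalidInputError("response window outside recording")
    z = consumption_preprocess(session)
    mean_resp = z[:, frames].mean(axis=1)
    excluded = np.zeros(session.n_neurons, dtype=bool)
    return ActivationCall(stimulus, mean_resp > sigma_mult, mean_resp, excluded)


def venn_counts(calls: dict[str, ActivationCall]) -> dict[frozenset, int]:
    """Exclusive membership counts of the activation Venn diagram.

    Keys are frozensets of stimulus labels; a neuron contributes to the key
    holding exactly the stimuli that activated it (the empty frozenset counts
    neurons activated by nothing).
    """
    stimuli = list(calls)
    n = {len(c.activated) for c in calls.values()}
    if len(n) != 1:
        raise InvalidInputError("activation calls cover different neuron counts")
    counts: dict[frozenset, int] = {}
    for i in range(n.pop()):
        key = frozenset(s for s in stimuli if calls[s].activated[i])
        counts[key] = counts.get(key, 0) + 1
    return counts


def preference_strength(peak_drug, peak_nat):
    """(Peak_drug - Peak_nat) / (Peak_drug + Peak_nat), in [-1, 1].

    Antisymmetric; +1 means drug-exclusive response.  Where both peaks are 0
    the score is undefined and returned as NaN.
    """
    a = np.asarray(peak_drug, dtype=float)
    b = np.asarray(peak_nat, dtype=float)
    if np.any(a < 0) or np.any(b < 0):
        raise InvalidInputError("peak amplitudes must be >= 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(a + b > 0, (a - b) / (a + b), np.nan)
    return float(out) if out.ndim == 0 else out
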