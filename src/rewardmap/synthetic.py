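"""Synthetic inputs with planted ground truth for every pipeline stage.

Four generators emulate the real data the pipeline consumes:

* ``gen_fos_dataset`` — batch-structured Poisson FOS+ count tables with
  drug-responsive regions elevated by a chosen z-scale effect;
* ``gen_ish_atlas`` — per-gene regional expression vectors with planted
  positive / negative / null correlation to a FOS contrast;
* ``gen_calcium_session`` — GCaMP6s-like fluorescence traces (4.82 Hz frame
  rate, 1.3 s single-exponential decay kernel, Gaussian baseline noise) with
  reward-locked, movement-locked, and silent populations plus a treadmill
  velocity trace;
* ``gen_multisession_tensor`` — a trial x neuron x time tensor whose planted
  amplifying subpopulation scales geometrically across sessions.

Every generator is a pure function of (spec, seed): the same seed reproduces
byte-identical outputs.  Planted labels travel in a :class:`SimTruth`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calcium import CalciumSession, DEFAULT_FRAME_RATE
from .errors import InvalidSpecError
from .fos_mapping import RegionTable, RegionVector
from .fos_seq import IshAtlas

GCAMP6S_DECAY_S = 1.3


@dataclass
class SimTruth:
    """Planted ground-truth labels for generated objects."""

    responsive_regions: dict = field(default_factory=dict)
    gene_classes: dict = field(default_factory=dict)
    neuron_populations: np.ndarray | None = None
    motor_lags: np.ndarray | None = None
    tca_factors: list | None = None
    amplifying_neurons: np.ndarray | None = None
    seed: int | None = None


# ---------------------------------------------------------------------------
# FOS count tables
# ---------------------------------------------------------------------------

@dataclass
class FosSimSpec:
    """Conditions for the FOS count generator.

    ``effect_size`` is expressed on the z scale: a responsive region's mean is
    raised by effect_size * sqrt(lambda) counts, so after within-batch
    z-scoring the planted shift is ~effect_size standard deviations.
    ``batch_shift`` scales a per-batch log-mean perturbation.
    """

    n_regions: int = 200
    groups: tuple[str, ...] = ("saline", "cocaine", "morphine")
    n_per_group: int = 5
    n_batches: int = 2
    batch_shift: float = 0.3
    responsive_regions: dict = field(default_factory=dict)
    effect_size: float = 3.0
    base_rate: float = 200.0
    region_heterogeneity: float = 0.3   # lognormal sd of per-region base rates
    phase: str = "chronic"
    seed: int = 0

    def validate(self) -> None:
        if self.n_regions <= 0 or self.n_per_group <= 0:
            raise InvalidSpecError("n_regions and n_per_group must be positive")
        if self.n_batches <= 0 or self.base_rate <= 0:
            raise InvalidSpecError("n_batches and base_rate must be positive")
        for cond, idx in self.responsive_regions.items():
            if cond not in self.groups:
                raise InvalidSpecError(f"unknown condition {cond!r}")
            if any(i < 0 or i >= self.n_regions for i in idx):
                raise InvalidSpecError("responsive region index out of range")


def gen_fos_dataset(spec: FosSimSpec) -> tuple[RegionTable, SimTruth]:
    """Poisson FOS+ counts with log-linear batch effects and planted responders."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    regions = [f"R{i:03d}" for i in range(spec.n_regions)]
    base = spec.base_rate * rng.lognormal(0.0, spec.region_heterogeneity,
                                          spec.n_regions)
    batch_effect = np.exp(spec.batch_shift * rng.standard_normal(spec.n_batches))

    meta_rows, cols = [], []
    s = 0
    for cond in spec.groups:
        resp = np.asarray(spec.responsive_regions.get(cond, []), dtype=int)
        for j in range(spec.n_per_group):
            batch = j % spec.n_batches
            lam = base * batch_effect[batch]
            if resp.size:
                lam = lam.copy()
                lam[resp] = lam[resp] + spec.effect_size * np.sqrt(lam[resp])
            cols.append(rng.poisson(lam))
            meta_rows.append((f"{cond}_{j}", cond, batch, spec.phase))
            s += 1
    samples = pd.DataFrame(meta_rows, columns=["sample", "condition", "batch",
                                               "phase"])
    table = RegionTable(regions, samples, np.column_stack(cols), scale="counts")
    truth = SimTruth(
        responsive_regions={c: list(map(int, v))
                            for c, v in spec.responsive_regions.items()},
        seed=spec.seed,
    )
    return table, truth


# ---------------------------------------------------------------------------
# ISH atlases
# ---------------------------------------------------------------------------

@dataclass
class IshSimSpec:
    """Conditions for the ISH atlas generator.

    Positive genes are generated as r * z(contrast) + sqrt(1 - r^2) * eps on
    the standardized scale (so the pre-noise expected correlation with the
    contrast equals ``signal_r``), mapped affinely into nonnegative expression
    energies; ``noise_sd`` adds independent measurement noise on top.
    """

    n_genes: int = 1000
    frac_positive: float = 0.05
    frac_negative: float = 0.05
    signal_r: float = 0.6
    noise_sd: float = 0.1
    expression_offset: float = 5.0
    expression_scale: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise InvalidSpecError("n_genes must be positive")
        if not (0 <= self.frac_positive <= 1 and 0 <= self.frac_negative <= 1):
            raise InvalidSpecError("fractions must lie in [0, 1]")
        if self.frac_positive + self.frac_negative > 1:
            raise InvalidSpecError("frac_positive + frac_negative > 1")
        if not (0 < self.signal_r <= 1):
            raise InvalidSpecError("signal_r must lie in (0, 1]")


def gen_ish_atlas(spec: IshSimSpec,
                  contrast: RegionVector) -> tuple[IshAtlas, SimTruth]:
    """Gene x region atlas with planted correlation classes against a contrast."""
    spec.validate()
    n_regions = len(contrast.regions)
    if n_regions < 10:
        raise InvalidSpecError("contrast must cover >= 10 regions")
    if contrast.values.std() == 0:
        raise InvalidSpecError("contrast has zero variance")
    rng = np.random.default_rng(spec.seed)
    zc = (contrast.values - contrast.values.mean()) / contrast.values.std(ddof=1)

    n_pos = int(round(spec.frac_positive * spec.n_genes))
    n_neg = int(round(spec.frac_negative * spec.n_genes))
    classes = (["positive"] * n_pos + ["negative"] * n_neg
               + ["none"] * (spec.n_genes - n_pos - n_neg))
    genes = [f"G{i:04d}" for i in range(spec.n_genes)]
    r = spec.signal_r
    mix = math.sqrt(max(0.0, 1.0 - r * r))
    rows = []
    for cls in classes:
        eps = rng.standard_normal(n_regions)
        if cls == "positive":
            g = r * zc + mix * eps
        elif cls == "negative":
            g = -r * zc + mix * eps
        else:
            g = eps
        expr = (spec.expression_offset + spec.expression_scale * g
                + spec.noise_sd * rng.standard_normal(n_regions))
        rows.append(np.clip(expr, 0.0, None))
    atlas = IshAtlas(genes, list(contrast.regions), np.vstack(rows))
    truth = SimTruth(gene_classes=dict(zip(genes, classes)), seed=spec.seed)
    return atlas, truth


# ---------------------------------------------------------------------------
# calcium sessions
# ---------------------------------------------------------------------------

@dataclass
class CalciumSimSpec:
    """Conditions for the calcium-session generator.

    ``populations`` maps label in {reward, motor, silent} to (count, response
    amplitude in units of baseline sigma).  Reward neurons respond after each
    time in ``event_times``; motor neurons respond inside movement bouts with
    a per-neuron 1-10 frame lag; silent neurons carry baseline noise only.
    """

    n_neurons: int = 60
    frame_rate: float = DEFAULT_FRAME_RATE
    duration: float = 300.0
    kernel_decay: float = GCAMP6S_DECAY_S
    baseline_sd: float = 1.0
    baseline_level: float = 50.0
    populations: dict = field(default_factory=lambda: {
        "reward": (20, 5.0), "motor": (20, 5.0), "silent": (20, 0.0),
    })
    event_times: dict = field(default_factory=lambda: {
        "consumption_start": 120.0,
    })
    spontaneous_rate_hz: float = 0.05  # ongoing transients in every neuron
    spontaneous_amp: float = 2.0       # spontaneous amplitude, baseline-sd units
    reward_rate_hz: float = 1.0        # sustained response-event rate
    reward_duration_s: float | None = None   # None: until recording end
    movement_bout_rate: float = 0.05   # bouts per second
    bout_duration_s: float = 4.0
    bout_speed: float = 6.0            # cm/s during bouts
    rest_speed_sd: float = 0.3
    cell_type: str = "D1"
    session_id: str = "sim"
    day: int = 0
    record_windows: list | None = None   # [(start_s, stop_s)]; None = continuous
    seed: int = 0

    def validate(self) -> None:
        if self.frame_rate <= 0:
            raise InvalidSpecError("frame_rate must be positive")
        if self.n_neurons < 0 or self.duration <= 0:
            raise InvalidSpecError("invalid n_neurons or duration")
        if sum(c for c, _ in self.populations.values()) != self.n_neurons:
            raise InvalidSpecError("population counts must sum to n_neurons")
        for t in self.event_times.values():
            for tt in np.atleast_1d(np.asarray(t, dtype=float)):
                if tt >= self.duration:
                    raise InvalidSpecError(
                        f"event at {tt}s beyond duration {self.duration}s"
                    )
        if self.record_windows is not None:
            for t0, t1 in self.record_windows:
                if not (0 <= t0 < t1 <= self.duration):
                    raise InvalidSpecError("record window outside duration")


def drug_record_windows(t_injection: float = 60.0, every_min: float = 10.0,
                        n_recordings: int = 6,
                        window_s: float = 60.0) -> list[tuple[float, float]]:
    """The drug-session imaging schedule: a 1-min pre-injection baseline, then
    a 1-min recording every 10 min post injection (6 recordings in an hour)."""
    windows = [(t_injection - window_s, t_injection)]
    for k in range(1, n_recordings + 1):
        start = t_injection + k * every_min * 60.0
        windows.append((start, start + window_s))
    return windows


def _decay_kernel(decay_s: float, frame_rate: float) -> np.ndarray:
    t = np.arange(0, int(math.ceil(5 * decay_s * frame_rate)) + 1) / frame_rate
    return np.exp(-t / decay_s)   # peak 1, so impulse amplitude is preserved


def _simulate_velocity(n_frames: int, spec: CalciumSimSpec,
                       rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Alternating rest/bout square wave plus jitter; returns (velocity, moving)."""
    fr = spec.frame_rate
    moving = np.zeros(n_frames, dtype=bool)
    mean_rest = max(1.0 / max(spec.movement_bout_rate, 1e-9)
                    - spec.bout_duration_s, 1.0)
    t = rng.exponential(mean_rest)
    while True:
        start = int(round(t * fr))
        if start >= n_frames:
            break
        dur = spec.bout_duration_s * (0.5 + rng.random())
        stop = min(n_frames, start + max(1, int(round(dur * fr))))
        moving[start:stop] = True
        t += dur + rng.exponential(mean_rest)
    velocity = np.where(
        moving,
        np.clip(spec.bout_speed + rng.standard_normal(n_frames), 0.1, None),
        np.abs(rng.standard_normal(n_frames)) * spec.rest_speed_sd,
    )
    return velocity, moving


def gen_calcium_session(spec: CalciumSimSpec) -> tuple[CalciumSession, SimTruth]:
    """GCaMP6s-like session: baseline + kernel-convolved planted responses."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_frames = int(round(spec.duration * spec.frame_rate))
    if spec.n_neurons == 0:
        session = CalciumSession(
            F=np.zeros((0, n_frames)), frame_rate=spec.frame_rate,
            velocity=np.zeros(n_frames), events=dict(spec.event_times),
            cell_type=spec.cell_type, session_id=spec.session_id, day=spec.day,
        )
        return session, SimTruth(neuron_populations=np.array([], dtype=object),
                                 seed=spec.seed)

    velocity, moving = _simulate_velocity(n_frames, spec, rng)
    kernel = _decay_kernel(spec.kernel_decay, spec.frame_rate)

    labels: list[str] = []
    amps: list[float] = []
    for label, (count, amp) in spec.populations.items():
        labels += [label] * count
        amps += [amp] * count
    lags = rng.integers(1, 11, size=spec.n_neurons)

    event_frames = [
        int(round(tt * spec.frame_rate))
        for t in spec.event_times.values()
        for tt in np.atleast_1d(np.asarray(t, dtype=float))
    ]
    F = np.empty((spec.n_neurons, n_frames))
    p_spont = min(1.0, spec.spontaneous_rate_hz / spec.frame_rate)
    for i, (label, amp) in enumerate(zip(labels, amps)):
        impulses = np.zeros(n_frames)
        if spec.spontaneous_amp > 0 and p_spont > 0:
            spont = rng.random(n_frames) < p_spont
            impulses[spont] += spec.spontaneous_amp * spec.baseline_sd
        if label == "reward" and amp > 0:
            # sustained consumption-like response: a first impulse at the
            # event, then a Poisson impulse train while consumption lasts
            p_fire = min(1.0, spec.reward_rate_hz / spec.frame_rate)
            for f in event_frames:
                f_jit = f + int(rng.integers(0, 3))
                if f_jit < n_frames:
                    impulses[f_jit] += amp * spec.baseline_sd
                stop = n_frames if spec.reward_duration_s is None else min(
                    n_frames,
                    f + int(round(spec.reward_duration_s * spec.frame_rate)),
                )
                frames_on = np.flatnonzero(
                    rng.random(max(0, stop - f_jit - 1)) < p_fire
                ) + f_jit + 1
                impulses[frames_on] += amp * spec.baseline_sd
        elif label == "motor" and amp > 0:
            fire = moving & (rng.random(n_frames) < 0.12)
            idx = np.flatnonzero(fire) + lags[i]
            idx = idx[idx < n_frames]
            impulses[idx] += amp * spec.baseline_sd
        resp = np.convolve(impulses, kernel)[:n_frames]
        F[i] = (spec.baseline_level + resp
                + spec.baseline_sd * rng.standard_normal(n_frames))

    frame_times = None
    if spec.record_windows is not None:
        keep = np.concatenate([
            np.arange(int(round(t0 * spec.frame_rate)),
                      min(n_frames, int(round(t1 * spec.frame_rate))))
            for t0, t1 in spec.record_windows
        ])
        F = F[:, keep]
        velocity = velocity[keep]
        frame_times = keep / spec.frame_rate

    # baseline window: the 30 s before the earliest event, else the first 30 s
    if event_frames:
        t_first = min(event_frames) / spec.frame_rate
        b0 = max(0.0, t_first - 30.0)
        baseline = (b0, t_first) if t_first - b0 >= 2 / spec.frame_rate \
            else (0.0, min(30.0, spec.duration))
    else:
        baseline = (0.0, min(30.0, spec.duration))

    session = CalciumSession(
        F=F, frame_rate=spec.frame_rate, velocity=velocity,
        events=dict(spec.event_times), baseline_window=baseline,
        cell_type=spec.cell_type, session_id=spec.session_id, day=spec.day,
        frame_times=frame_times,
    )
    truth = SimTruth(
        neuron_populations=np.array(labels, dtype=object),
        motor_lags=lags, seed=spec.seed,
    )
    return session, truth


VENN_EVENTS = {"food_start": 100.0, "water_start": 400.0, "injection": 1200.0}
VENN_WINDOW_ENDS = {"food": 400.0, "water": 800.0}


def venn_reference_session(
    composition: list[tuple[tuple[str, ...], int]],
    frame_rate: float = 1.0,
    duration: float = 3800.0,
) -> tuple[CalciumSession, dict]:
    """A synthetic stand-in session realizing a prescribed activation Venn.

    ``composition`` lists (stimulus subset, neuron count) cells, e.g.
    ``[(("cocaine",), 5), (("food", "water", "cocaine"), 44), ...]``; the
    counts are taken from a printed Venn diagram and planted deterministically
    (no randomness): consumption responders carry a sustained fluorescence
    elevation in their stimulus window, drug responders carry large transients
    inside the post-injection quantification window, and every neuron carries
    a small sinusoidal baseline so no variance is degenerate.

    Returns the session plus the per-stimulus response-window ends to pass to
    :func:`rewardmap.calcium.call_activation`.
    """
    n_neurons = sum(c for _, c in composition)
    n = int(round(duration * frame_rate))
    t = np.arange(n) / frame_rate
    F = np.empty((n_neurons, n))
    memberships: list[tuple[str, ...]] = []
    for stimuli, count in composition:
        memberships += [tuple(stimuli)] * count

    def span(t0, t1):
        return (t >= t0) & (t < t1)

    food = span(VENN_EVENTS["food_start"] + 10.0, VENN_WINDOW_ENDS["food"])
    water = span(VENN_EVENTS["water_start"] + 10.0, VENN_WINDOW_ENDS["water"])
    drug_lo = VENN_EVENTS["injection"] + 20 * 60.0
    spike_times = [drug_lo + 100.0, drug_lo + 200.0, drug_lo + 300.0]

    for i, stimuli in enumerate(memberships):
        trace = 50.0 + 0.01 * i + 0.5 * np.sin(2 * np.pi * 0.05 * t + 0.37 * i)
        if "food" in stimuli:
            trace = trace + 10.0 * food
        if "water" in stimuli:
            trace = trace + 10.0 * water
        if "cocaine" in stimuli:
            for ts in spike_times:
                j = int(round(ts * frame_rate))
                trace[j:j + 3] += 60.0
        F[i] = trace

    session = CalciumSession(
        F=F, frame_rate=frame_rate, events=dict(VENN_EVENTS),
        baseline_window=(0.0, VENN_EVENTS["food_start"]),
        cell_type="D1", session_id="venn_reference",
    )
    return session, dict(VENN_WINDOW_ENDS)


# ---------------------------------------------------------------------------
# multi-session trial tensors
# ---------------------------------------------------------------------------

def gen_multisession_tensor(
    spec: CalciumSimSpec,
    gain_per_session: float = 1.5,
    n_sessions: int = 5,
    trials_per_session: int = 3,
    n_time: int = 40,
    noise_sd: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, SimTruth]:
    """Trials x neurons x time tensor with a planted amplifying component.

    Two planted components: component 0 loads on an "amplifying" subpopulation
    whose trial factor scales by ``gain_per_session`` from session to session;
    component 1 loads on a disjoint stationary subpopulation with a flat trial
    factor.  Nonnegative noise is added on top.

    Returns (tensor, session_labels, truth).
    """
    spec.validate()
    if gain_per_session <= 0:
        raise InvalidSpecError("gain_per_session must be positive")
    if n_sessions < 2:
        raise InvalidSpecError("need at least 2 sessions")
    rng = np.random.default_rng(spec.seed)
    n_neurons = spec.n_neurons
    if n_neurons < 4:
        raise InvalidSpecError("need >= 4 neurons for a planted tensor")
    n_trials = n_sessions * trials_per_session

    n_amp = n_neurons // 3
    n_stat = n_neurons // 3
    B = np.zeros((n_neurons, 2))
    B[:n_amp, 0] = 0.5 + rng.random(n_amp)
    B[n_amp:n_amp + n_stat, 1] = 0.5 + rng.random(n_stat)

    t = np.arange(n_time)
    C = np.column_stack([
        np.exp(-0.5 * ((t - n_time * 0.3) / (n_time * 0.08)) ** 2),
        np.exp(-0.5 * ((t - n_time * 0.7) / (n_time * 0.12)) ** 2),
    ])

    session_labels = np.repeat(np.arange(n_sessions), trials_per_session)
    A = np.empty((n_trials, 2))
    A[:, 0] = gain_per_session ** session_labels * (1 + 0.05 * rng.random(n_trials))
    A[:, 1] = 1.0 + 0.05 * rng.random(n_trials)

    tensor = np.einsum("ir,jr,kr->ijk", A, B, C)
    tensor += noise_sd * np.abs(rng.standard_normal(tensor.shape))
    truth = SimTruth(
        tca_factors=[A, B, C],
        amplifying_neurons=np.arange(n_amp),
        seed=spec.seed,
    )
    return tensor, session_labels, truth
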