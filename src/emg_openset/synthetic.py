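"""Seeded synthetic HD-sEMG benchmark generator.

Real high-density surface-EMG recordings of this kind are rarely shared, so the
package bundles a simulator that reproduces the statistical structure the
recognition pipeline consumes:

* 96 monopolar channels on a 12 x 8 grid sampled at 1 kHz,
* 20-500 Hz band-limited stochastic carriers (order-4 Butterworth band-pass
  applied to white noise), amplitude-modulated per channel,
* task-specific spatial activation maps built from Gaussian bumps on the grid
  (isometric tasks are time-constant; dynamic tasks switch between random
  mixtures of maps every 0.5-2 s),
* 5-s isometric repetitions with multiplicative inter-repetition gain jitter,
  ~60-s continuous recordings for dynamic tasks, and quiescent baseline
  segments whose amplitude sits well below any active task.

Seven target tasks (T1-T7), three static novel tasks (N1-N3) and three dynamic
novel tasks (N4-N6) are defined; the dynamic mixtures deliberately include
target-task maps (notably T1) so that novel activity partially overlaps the
trained patterns, which is what makes rejection hard.

One synthetic "subject" is one draw of per-task activation-centre positions
around the canonical layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .grids import GridSpec

REST_LABEL = "REST"

TARGET_TASKS = ("T1", "T2", "T3", "T4", "T5", "T6", "T7")
STATIC_NOVEL_TASKS = ("N1", "N2", "N3")
DYNAMIC_NOVEL_TASKS = ("N4", "N5", "N6")
NOVEL_TASKS = STATIC_NOVEL_TASKS + DYNAMIC_NOVEL_TASKS
ALL_TASKS = TARGET_TASKS + NOVEL_TASKS


@dataclass(frozen=True)
class ActivationCenter:
    """One Gaussian activation bump on the electrode grid."""

    row: float
    col: float
    spatial_sd: float
    gain: float

    def __post_init__(self) -> None:
        if self.gain < 0:
            raise ValueError("gain must be nonnegative")
        if self.spatial_sd < 0:
            raise ValueError("spatial_sd must be nonnegative")


@dataclass(frozen=True)
class MixtureSegment:
    """One piecewise-constant segment of a dynamic task trajectory."""

    t_start: float
    t_end: float
    weights: tuple[float, ...]  # over the task's component maps


@dataclass
class TaskSpec:
    """A motor task: its spatial activation pattern and repetition protocol.

    ``kind`` is one of ``target``, ``static_novel`` or ``dynamic_novel``.
    Target and static-novel tasks have a time-constant activation map built
    from ``activation_centers``.  Dynamic-novel tasks carry ``components``
    (candidate maps, typically including target-task maps) and a realized
    piecewise-constant ``dynamics`` schedule of mixture weights.
    """

    task_id: str
    kind: str
    activation_centers: list[ActivationCenter] = field(default_factory=list)
    components: list[list[ActivationCenter]] = field(default_factory=list)
    dynamics: list[MixtureSegment] | None = None
    reps: int = 10
    rep_duration_s: float = 5.0

    def __post_init__(self) -> None:
        if self.kind not in ("target", "static_novel", "dynamic_novel"):
            raise ValueError(f"unknown task kind {self.kind!r}")
        if self.kind != "dynamic_novel" and self.dynamics is not None:
            raise ValueError("only dynamic_novel tasks may carry a dynamics schedule")


@dataclass
class RawRecording:
    """A labelled multichannel recording: ``signal`` is channels x samples."""

    signal: np.ndarray
    fs: float
    grid: GridSpec
    task_id: str
    rep_index: int = 0
    baseline: bool = False
    subject: int = 0

    def __post_init__(self) -> None:
        if self.signal.ndim != 2 or self.signal.shape[0] != self.grid.n_channels:
            raise ValueError("signal must be (n_channels, n_samples) matching the grid")
        if self.baseline and self.task_id != REST_LABEL:
            raise ValueError(f"baseline recordings must be labelled {REST_LABEL}")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


# ---------------------------------------------------------------------------
# canonical task layout
# ---------------------------------------------------------------------------

def _c(row, col, sd=1.2, gain=1.0) -> ActivationCenter:
    return ActivationCenter(row, col, sd, gain)


# Two bumps per isometric task: one on the extensor half (rows 0-5) and one on
# the flexor half (rows 6-11) of the stacked arrays.
_CANONICAL_CENTERS: dict[str, list[ActivationCenter]] = {
    "T1": [_c(2, 2, gain=1.0), _c(8, 5, gain=0.7)],   # wrist pronation
    "T2": [_c(3, 5, gain=1.0), _c(9, 2, gain=0.7)],   # wrist supination
    "T3": [_c(1, 6, gain=1.0), _c(7, 1, gain=0.6)],   # wrist extension
    "T4": [_c(10, 5, gain=1.0), _c(4, 1, gain=0.6)],  # wrist flexion
    "T5": [_c(0, 3, gain=0.9), _c(6, 6, gain=0.9)],   # hand open
    "T6": [_c(11, 2, gain=0.9), _c(5, 6, gain=0.8)],  # hand close
    "T7": [_c(2, 0, gain=1.0), _c(9, 7, gain=0.8)],   # shooting gesture
    # static novels; N1 (pinch) deliberately sits between the wrist-flexion
    # and hand-close maps — similar to trained patterns but resolvable
    "N1": [_c(9, 4, gain=0.9), _c(4, 3, gain=0.8)],
    "N2": [_c(0, 0, gain=1.0), _c(6, 0, gain=0.7)],
    "N3": [_c(11, 7, gain=1.0), _c(4, 7, gain=0.7)],
}

# Dynamic tasks mix their own novel map with target maps (T1 in particular),
# emulating office activities that recruit the wrist-pronation pattern.  The
# task-specific components sit in grid regions quiet in every target map
# (left flexor edge and the mid-extensor gap), so they carry little energy
# along the directions a linear discriminant projection retains.
_DYNAMIC_COMPONENTS: dict[str, list[str | list[ActivationCenter]]] = {
    "N4": ["T1", "T6", [_c(10, 0, 1.0, 0.9), _c(5, 3, 1.0, 0.7)]],  # mouse
    "N5": ["T1", "T4", [_c(8, 0, 1.0, 0.9), _c(6, 3, 1.0, 0.7)]],   # writing
    "N6": ["T1", "T5", [_c(11, 0, 1.0, 0.9), _c(6, 0, 1.0, 0.7)]],  # typing
}


@dataclass
class BenchmarkConfig:
    """Study conditions for the synthetic benchmark.

    Defaults mirror the acquisition protocol the pipeline targets: 10
    repetitions of 5-s isometric contractions for T1-T7 and N1-N3, roughly
    one minute of continuous activity for each dynamic task, and a quiescent
    baseline segment per subject.
    """

    n_subjects: int = 3
    fs: float = 1000.0
    grid: GridSpec = field(default_factory=GridSpec)
    reps: int = 10
    rep_duration_s: float = 5.0
    dynamic_duration_s: float = 60.0
    baseline_duration_s: float = 20.0
    noise_floor: float = 0.02
    background_tone: float = 0.25  # peak gain of the smooth co-contraction field
    rep_gain_jitter: tuple[float, float] = (0.6, 1.4)
    center_jitter_sd: float = 0.3  # subject-level layout draw
    rep_center_jitter_sd: float = 1.0  # per-repetition activation-centre drift
    # intra-repetition nonstationarity: activation centres, gains and the
    # background field drift between knots this far apart, linearly
    # interpolated, so no two windows share an identical configuration
    knot_interval_s: float = 0.5
    knot_center_sd: float = 0.4
    knot_gain_range: tuple[float, float] = (0.85, 1.15)
    switch_interval_s: tuple[float, float] = (0.5, 2.0)
    tasks: list[TaskSpec] | None = None  # override the canonical task set


def default_tasks(config: BenchmarkConfig | None = None) -> list[TaskSpec]:
    """The canonical 13-task protocol (7 target, 3 static novel, 3 dynamic)."""
    config = config or BenchmarkConfig()
    tasks = []
    for tid in TARGET_TASKS + STATIC_NOVEL_TASKS:
        kind = "target" if tid in TARGET_TASKS else "static_novel"
        tasks.append(
            TaskSpec(
                task_id=tid,
                kind=kind,
                activation_centers=list(_CANONICAL_CENTERS[tid]),
                reps=config.reps,
                rep_duration_s=config.rep_duration_s,
            )
        )
    for tid in DYNAMIC_NOVEL_TASKS:
        comps = [
            list(_CANONICAL_CENTERS[ref]) if isinstance(ref, str) else list(ref)
            for ref in _DYNAMIC_COMPONENTS[tid]
        ]
        tasks.append(
            TaskSpec(
                task_id=tid,
                kind="dynamic_novel",
                components=comps,
                reps=1,
                rep_duration_s=config.dynamic_duration_s,
            )
        )
    return tasks


# ---------------------------------------------------------------------------
# activation maps
# ---------------------------------------------------------------------------

def _bump_map(centers: list[ActivationCenter], grid: GridSpec) -> np.ndarray:
    rows = np.arange(grid.rows, dtype=float)[:, None]
    cols = np.arange(grid.cols, dtype=float)[None, :]
    out = np.zeros((grid.rows, grid.cols))
    for c in centers:
        if not (0 <= c.row <= grid.rows - 1 and 0 <= c.col <= grid.cols - 1):
            raise ValueError(f"activation centre ({c.row}, {c.col}) outside the grid")
        if c.spatial_sd == 0:
            out[int(round(c.row)), int(round(c.col))] += c.gain
        else:
            d2 = (rows - c.row) ** 2 + (cols - c.col) ** 2
            out += c.gain * np.exp(-d2 / (2.0 * c.spatial_sd**2))
    return out


def make_activation_map(task: TaskSpec, grid: GridSpec, t: float = 0.0) -> np.ndarray:
    """Spatial activation (rows x cols, all entries >= 0) of ``task`` at time ``t``.

    Static tasks ignore ``t``; dynamic tasks evaluate their piecewise-constant
    mixture schedule at ``t``.
    """
    if task.kind != "dynamic_novel":
        return _bump_map(task.activation_centers, grid)
    if task.dynamics is None:
        raise ValueError(f"dynamic task {task.task_id} has no realized dynamics schedule")
    t_end = task.dynamics[-1].t_end
    if not (0.0 <= t <= t_end):
        raise ValueError(f"t={t} outside the dynamics schedule [0, {t_end}]")
    for seg in task.dynamics:
        if seg.t_start <= t < seg.t_end or (t == t_end and seg.t_end == t_end):
            out = np.zeros((grid.rows, grid.cols))
            for w, comp in zip(seg.weights, task.components):
                if w > 0:
                    out += w * _bump_map(comp, grid)
            return out
    raise RuntimeError("dynamics schedule does not cover t")  # pragma: no cover


def realize_dynamics(
    task: TaskSpec,
    duration_s: float,
    rng: np.random.Generator,
    switch_interval_s: tuple[float, float] = (0.5, 2.0),
) -> TaskSpec:
    """Draw a piecewise-constant mixture schedule for a dynamic task.

    Each segment is one trained pattern performed *simultaneously* with
    substantial extra untrained activity: a single target-pattern component
    at in-manifold amplitude (weight ~ U(0.6, 1.4), the inter-rep gain-jitter
    range) plus the task-specific novel component at weight ~ U(0.05, 0.75).  Because the novel components live in grid regions quiet
    in every trained task, they are nearly invisible to a discriminant
    projection — those windows fool a linear rejection cascade whenever the
    trained-pattern amplitude is in-manifold — while spatially shared
    convolution filters still propagate them into the embedding.
    """
    if task.kind != "dynamic_novel":
        raise ValueError("realize_dynamics applies to dynamic_novel tasks only")
    n_comp = len(task.components)
    if n_comp < 2:
        raise ValueError("dynamic tasks need at least two component maps")
    segments: list[MixtureSegment] = []
    t = 0.0
    lo, hi = switch_interval_s
    novel_only = n_comp - 1  # by construction the last component is task-specific
    while t < duration_s:
        seg_len = float(rng.uniform(lo, hi))
        t_end = min(duration_s, t + seg_len)
        others = [i for i in range(n_comp) if i != novel_only]
        chosen = int(rng.choice(others))
        weights = np.zeros(n_comp)
        weights[novel_only] = rng.uniform(0.05, 0.75)
        weights[chosen] = rng.uniform(0.6, 1.4)
        segments.append(MixtureSegment(t, t_end, tuple(weights)))
        t = t_end
    return replace(task, dynamics=segments)


# ---------------------------------------------------------------------------
# carriers and recordings
# ---------------------------------------------------------------------------

def _bandpass_sos(fs: float, low: float = 20.0, high: float = 500.0):
    nyq = fs / 2.0
    high = min(high, 0.99 * nyq)
    return sps.butter(4, [low / nyq, high / nyq], btype="bandpass", output="sos")


def synth_channel(
    duration_s: float,
    fs: float = 1000.0,
    gain: float = 1.0,
    rng_seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """One channel of band-limited (20-500 Hz) zero-mean stochastic activity.

    Gaussian white noise filtered by an order-4 Butterworth band-pass and
    scaled by ``gain``; reproducible for a fixed seed.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if fs < 2 * 500.0:
        raise ValueError("sampling rate must satisfy the 500 Hz band edge (fs >= 1000)")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    n = int(round(duration_s * fs))
    white = rng.standard_normal(n)
    carrier = sps.sosfilt(_bandpass_sos(fs), white)
    return gain * carrier


def _carriers(n_channels: int, n_samples: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal((n_channels, n_samples))
    return sps.sosfilt(_bandpass_sos(fs), white, axis=1).astype(np.float32)


def _background_map(grid: GridSpec, rng: np.random.Generator, max_gain: float) -> np.ndarray:
    """Smooth low-amplitude co-contraction tone: two very wide Gaussian bumps.

    Emulates the broad, spatially smooth background activity (neighbouring
    muscle co-activation, baseline tone drift) that accompanies any voluntary
    contraction and varies between repetitions.  It inflates within-class
    amplitude variance on *every* channel while staying spatially smooth, in
    contrast to the compact task-specific activation bumps.
    """
    if max_gain <= 0:
        return np.zeros((grid.rows, grid.cols))
    centers = [
        ActivationCenter(
            row=float(rng.uniform(0, grid.rows - 1)),
            col=float(rng.uniform(0, grid.cols - 1)),
            spatial_sd=float(rng.uniform(3.0, 6.0)),
            gain=float(rng.uniform(0.0, max_gain)),
        )
        for _ in range(2)
    ]
    return _bump_map(centers, grid)


def synth_recording(
    task: TaskSpec,
    config: BenchmarkConfig,
    rep_index: int,
    rng: np.random.Generator,
    subject: int = 0,
    rep_gain: float = 1.0,
) -> RawRecording:
    """Synthesize one repetition (or one continuous dynamic recording)."""
    grid = config.grid
    fs = config.fs
    n = int(round(task.rep_duration_s * fs))
    carriers = _carriers(grid.n_channels, n, fs, rng)

    def per_channel(amap: np.ndarray) -> np.ndarray:
        return np.array([amap[grid.position_of(ch)] for ch in range(grid.n_channels)])

    if task.kind == "dynamic_novel":
        comps = [
            _jitter_centers(comp, grid, rng, config.rep_center_jitter_sd)
            for comp in task.components
        ]
        task = replace(task, components=comps)
        task = realize_dynamics(task, task.rep_duration_s, rng, config.switch_interval_s)
        envelope = np.empty((grid.n_channels, n), dtype=np.float32)
        for seg in task.dynamics:
            amap = make_activation_map(task, grid, seg.t_start)
            amap = amap + _background_map(grid, rng, config.background_tone)
            i0, i1 = int(round(seg.t_start * fs)), int(round(seg.t_end * fs))
            envelope[:, i0:i1] = (config.noise_floor + rep_gain * per_channel(amap))[:, None]
        signal = carriers * envelope
    else:
        # per-repetition activation-centre drift: electrode/posture micro-shift
        rep_centers = _jitter_centers(
            task.activation_centers, grid, rng, config.rep_center_jitter_sd
        )
        # intra-repetition nonstationarity: the map wanders between knots
        n_knots = max(2, int(np.ceil(task.rep_duration_s / config.knot_interval_s)) + 1)
        knot_times = np.linspace(0.0, task.rep_duration_s, n_knots)
        glo, ghi = config.knot_gain_range
        knot_env = np.empty((n_knots, grid.n_channels))
        for k in range(n_knots):
            centers = _jitter_centers(rep_centers, grid, rng, config.knot_center_sd)
            amap = float(rng.uniform(glo, ghi)) * _bump_map(centers, grid)
            amap = amap + _background_map(grid, rng, config.background_tone)
            knot_env[k] = per_channel(amap)
        t_axis = np.arange(n) / fs
        envelope = np.empty((grid.n_channels, n), dtype=np.float32)
        for ch in range(grid.n_channels):
            envelope[ch] = np.interp(t_axis, knot_times, knot_env[:, ch])
        signal = carriers * (config.noise_floor + rep_gain * envelope)
    return RawRecording(
        signal=signal.astype(np.float32),
        fs=fs,
        grid=grid,
        task_id=task.task_id,
        rep_index=rep_index,
        subject=subject,
    )


def synth_baseline(config: BenchmarkConfig, rng: np.random.Generator, subject: int = 0) -> RawRecording:
    n = int(round(config.baseline_duration_s * config.fs))
    carriers = _carriers(config.grid.n_channels, n, config.fs, rng)
    return RawRecording(
        signal=(config.noise_floor * carriers).astype(np.float32),
        fs=config.fs,
        grid=config.grid,
        task_id=REST_LABEL,
        baseline=True,
        subject=subject,
    )


def _jitter_centers(
    centers: list[ActivationCenter], grid: GridSpec, rng: np.random.Generator, sd: float
) -> list[ActivationCenter]:
    out = []
    for c in centers:
        row = float(np.clip(c.row + rng.normal(0, sd), 0, grid.rows - 1))
        col = float(np.clip(c.col + rng.normal(0, sd), 0, grid.cols - 1))
        out.append(ActivationCenter(row, col, c.spatial_sd, c.gain))
    return out


def subject_tasks(config: BenchmarkConfig, subject_rng: np.random.Generator) -> list[TaskSpec]:
    """Per-subject task set: canonical layout with jittered centre positions."""
    tasks = config.tasks if config.tasks is not None else default_tasks(config)
    out = []
    for task in tasks:
        if task.kind == "dynamic_novel":
            comps = [
                _jitter_centers(comp, config.grid, subject_rng, config.center_jitter_sd)
                for comp in task.components
            ]
            out.append(replace(task, components=comps))
        else:
            centers = _jitter_centers(
                task.activation_centers, config.grid, subject_rng, config.center_jitter_sd
            )
            out.append(replace(task, activation_centers=centers))
    return out


def make_benchmark(
    config: BenchmarkConfig | None = None, rng_seed: int = 0
) -> list[RawRecording]:
    """Generate the full seeded benchmark: all subjects, tasks and baselines.

    Per subject: one baseline recording, ``reps`` isometric repetitions of each
    target and static-novel task (with multiplicative inter-rep gain jitter),
    and one continuous recording per dynamic-novel task.
    """
    config = config or BenchmarkConfig()
    tasks = config.tasks if config.tasks is not None else default_tasks(config)
    task_ids = {t.task_id for t in tasks}
    missing = [tid for tid in ALL_TASKS if tid not in task_ids]
    if missing:
        raise ValueError(f"missing task specs: {missing}")
    root = np.random.SeedSequence(rng_seed)
    recordings: list[RawRecording] = []
    for subject, subject_seed in enumerate(root.spawn(config.n_subjects)):
        layout_rng, signal_rng = (np.random.default_rng(s) for s in subject_seed.spawn(2))
        stasks = subject_tasks(config, layout_rng)
        recordings.append(synth_baseline(config, signal_rng, subject))
        lo, hi = config.rep_gain_jitter
        for task in stasks:
            for rep in range(task.reps):
                rep_gain = float(signal_rng.uniform(lo, hi))
                recordings.append(
                    synth_recording(task, config, rep, signal_rng, subject, rep_gain)
                )
    return recordings
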