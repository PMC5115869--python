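"""Synthetic ground-truth paths and multi-channel ZMW fluorescence traces.

The generator emulates the statistical structure the downstream analysis
assumes: 10 Hz alternating-excitation recordings of a donor-labelled ligand
binding to an immobilized acceptor-labelled receptor, single-step acceptor
photobleaching truncating the smFRET observation window, 10 % donor->acceptor
channel cross-talk, and additive Gaussian noise at a configurable
signal-to-noise ratio.

All randomness is driven by explicit integer seeds (per-molecule seeds are
spawned from a cohort master seed), so cohorts are reproducible
byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from zmwbind.models import (
    BOUND,
    KineticModel,
    build_generator,
    stationary_distribution,
)

FRAME_PERIOD = 0.1  # s; 10 Hz camera rate
DEFAULT_BLEACH_MEAN = 30.0  # s; typical recordings last ~1 min
DEFAULT_SNR = 5.0
DEFAULT_CROSSTALK = 0.10
FRET_AMPLITUDE = 1.0  # arbitrary intensity units; FRET efficiency ~1


@dataclass
class StatePath:
    """Exact continuous-time Markov chain realization.

    ``jump_times[i]`` is the entry time of sojourn ``i`` (``jump_times[0]``
    is 0); the final sojourn is truncated at ``total_duration``.
    """

    jump_times: np.ndarray
    states: list[str]
    total_duration: float
    model_id: int
    concentration: float
    seed: int | None = None

    def sojourns(self):
        """Yield (state, t_start, t_end) triples."""
        times = np.append(self.jump_times, self.total_duration)
        for i, s in enumerate(self.states):
            yield s, float(times[i]), float(times[i + 1])


@dataclass
class TraceSet:
    """Multi-channel per-molecule fluorescence time series.

    Channels follow the alternating-excitation naming convention:
    I_DD donor emission on donor excitation, I_AD acceptor emission on donor
    excitation (the smFRET reporter), I_AA acceptor emission on direct
    acceptor excitation (bleach-step reporter), I_DA donor emission on
    acceptor excitation (background only).
    """

    molecule_id: str
    concentration: float
    frame_period: float
    I_DD: np.ndarray
    I_AD: np.ndarray
    I_AA: np.ndarray
    I_DA: np.ndarray
    truth_state: np.ndarray | None = None  # per-frame bound class (0/1)
    truth_bleach_frame: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        n = len(self.I_DD)
        for name in ("I_AD", "I_AA", "I_DA"):
            if len(getattr(self, name)) != n:
                raise ValueError("all channels must have equal length")
        if self.frame_period <= 0:
            raise ValueError("frame_period must be > 0")

    @property
    def n_frames(self) -> int:
        return len(self.I_DD)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "frame": np.arange(self.n_frames),
                "I_DD": self.I_DD,
                "I_AD": self.I_AD,
                "I_AA": self.I_AA,
                "I_DA": self.I_DA,
            }
        )
        if self.truth_state is not None:
            df["truth_state"] = self.truth_state.astype(int)
            bleach = self.truth_bleach_frame
            df["truth_bleached"] = (
                np.zeros(self.n_frames, dtype=int)
                if bleach is None
                else (df["frame"] >= bleach).astype(int)
            )
        return df


# ---------------------------------------------------------------------------
# path simulation


def simulate_path(
    model: KineticModel,
    concentration: float,
    duration: float,
    seed: int | np.random.Generator,
) -> StatePath:
    """Gillespie realization started from the stationary distribution.

    A state with zero exit rate (e.g. the unbound state of a binding-only
    scheme at zero ligand) yields a single sojourn spanning the full
    duration.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gen = build_generator(model, concentration)
    Q = gen.Q
    labels = model.state_labels
    pi = stationary_distribution(Q)
    state = int(rng.choice(len(labels), p=pi))

    jump_times = [0.0]
    states = [state]
    t = 0.0
    while True:
        exit_rate = -Q[state, state]
        if exit_rate <= 0:
            break
        t += rng.exponential(1.0 / exit_rate)
        if t >= duration:
            break
        p = Q[state].copy()
        p[state] = 0.0
        p /= p.sum()
        state = int(rng.choice(len(labels), p=p))
        jump_times.append(t)
        states.append(state)

    return StatePath(
        jump_times=np.asarray(jump_times),
        states=[labels[s] for s in states],
        total_duration=float(duration),
        model_id=model.model_id,
        concentration=concentration,
        seed=None if isinstance(seed, np.random.Generator) else int(seed),
    )


def frames_from_path(
    path: StatePath, frame_period: float = FRAME_PERIOD, model: KineticModel | None = None
) -> np.ndarray:
    """Discretize a path to per-frame binary class labels (majority rule).

    A frame is labelled bound iff the bound-class occupancy fraction within
    the frame is >= 0.5; sub-frame excursions are unresolved, matching the
    camera's integration over each 100 ms frame.
    """
    if frame_period <= 0:
        raise ValueError("frame_period must be > 0")
    if model is not None:
        classes = model.state_classes
    else:
        # state labels follow the U*/B* convention of the presets
        classes = {s: (BOUND if s.startswith("B") else "unbound") for s in set(path.states)}
    n_frames = int(np.floor(path.total_duration / frame_period + 1e-9))
    bound_time = np.zeros(n_frames)
    for state, t0, t1 in path.sojourns():
        if classes[state] != BOUND or t1 <= t0:
            continue
        f0 = int(np.floor(t0 / frame_period))
        f1 = min(int(np.ceil(t1 / frame_period)), n_frames)
        for f in range(f0, f1):
            lo = f * frame_period
            hi = lo + frame_period
            bound_time[f] += max(0.0, min(t1, hi) - max(t0, lo))
    return (bound_time / frame_period >= 0.5).astype(np.int8)


# ---------------------------------------------------------------------------
# trace synthesis


def synthesize_traces(
    frames: np.ndarray,
    bleach_mean: float = DEFAULT_BLEACH_MEAN,
    snr: float = DEFAULT_SNR,
    crosstalk: float = DEFAULT_CROSSTALK,
    seed: int | np.random.Generator = 0,
    frame_period: float = FRAME_PERIOD,
    molecule_id: str = "mol0",
    concentration: float = 0.0,
    amplitude: float = FRET_AMPLITUDE,
) -> TraceSet:
    """Render a binary bound/unbound frame sequence as noisy channel traces.

    Before the acceptor bleaches, bound frames carry the FRET amplitude in
    I_AD (FRET efficiency is treated as 1, so the bound donor contributes
    nothing to I_DD); after the bleach, bound frames appear in I_DD instead.
    I_AA shows a single step to background at the bleach.  I_AD additionally
    receives ``crosstalk * I_DD``.  All channels carry additive Gaussian
    noise with sigma = amplitude / snr, so the idealization S/N of a clean
    recovery equals ``snr``.
    """
    if snr <= 0:
        raise ValueError("snr must be > 0")
    if not (0 <= crosstalk < 1):
        raise ValueError("crosstalk must be in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    frames = np.asarray(frames).astype(np.int8)
    n = len(frames)
    sigma = amplitude / snr if np.isfinite(snr) else 0.0

    bleach_time = rng.exponential(bleach_mean)
    bleach_frame = min(int(np.floor(bleach_time / frame_period)), n)
    pre = np.arange(n) < bleach_frame

    def noise():
        return rng.normal(0.0, sigma, n) if sigma > 0 else np.zeros(n)

    clean_dd = amplitude * frames * (~pre)  # donor visible only post-bleach
    clean_ad = amplitude * frames * pre
    clean_aa = amplitude * pre

    I_DD = clean_dd + noise()
    I_AD = clean_ad + crosstalk * I_DD + noise()
    I_AA = clean_aa + noise()
    I_DA = noise()

    return TraceSet(
        molecule_id=molecule_id,
        concentration=concentration,
        frame_period=frame_period,
        I_DD=I_DD,
        I_AD=I_AD,
        I_AA=I_AA,
        I_DA=I_DA,
        truth_state=frames,
        truth_bleach_frame=bleach_frame,
        seed=None if isinstance(seed, np.random.Generator) else int(seed),
    )


# ---------------------------------------------------------------------------
# cohorts

#: ligand concentrations used throughout (molar)
DEFAULT_CONCENTRATIONS = (0.1e-6, 0.3e-6, 1e-6, 3e-6, 10e-6)
#: per-concentration molecule counts comparable to the study cohort
DEFAULT_N_PER_CONC = 1000
DEFAULT_DURATION = 60.0  # s; a typical recording lasts about one minute


@dataclass
class BinaryCohort:
    """Idealization-level cohort: binary traces grouped by concentration."""

    traces: list[np.ndarray]
    concentrations: np.ndarray  # molar, one per trace
    frame_period: float = FRAME_PERIOD
    molecule_ids: list[str] = field(default_factory=list)


def simulate_binary_cohort(
    model: KineticModel,
    concentrations=DEFAULT_CONCENTRATIONS,
    n_per_conc: int = DEFAULT_N_PER_CONC,
    duration: float = DEFAULT_DURATION,
    seed: int = 0,
    frame_period: float = FRAME_PERIOD,
) -> BinaryCohort:
    """Noise-free binary cohort: per-molecule CTMC paths discretized at 10 Hz."""
    if n_per_conc < 1:
        raise ValueError("n_per_conc must be >= 1")
    traces, concs, ids = [], [], []
    for ci, c in enumerate(concentrations):
        rng = np.random.default_rng(np.random.SeedSequence([seed, ci]))
        for mi in range(n_per_conc):
            path = simulate_path(model, c, duration, rng)
            traces.append(frames_from_path(path, frame_period, model))
            concs.append(c)
            ids.append(f"c{ci}_m{mi}")
    return BinaryCohort(traces, np.asarray(concs), frame_period, ids)


def simulate_cohort(
    model: KineticModel,
    concentrations=DEFAULT_CONCENTRATIONS,
    n_per_conc: int = DEFAULT_N_PER_CONC,
    duration: float = DEFAULT_DURATION,
    seed: int = 0,
    bleach_mean: float = DEFAULT_BLEACH_MEAN,
    snr: float = DEFAULT_SNR,
    crosstalk: float = DEFAULT_CROSSTALK,
    frame_period: float = FRAME_PERIOD,
) -> list[TraceSet]:
    """Full synthetic cohort with noisy channels, bleaching and truth labels."""
    if n_per_conc < 1:
        raise ValueError("n_per_conc must be >= 1")
    out = []
    for ci, c in enumerate(concentrations):
        rng = np.random.default_rng(np.random.SeedSequence([seed, ci]))
        for mi in range(n_per_conc):
            path = simulate_path(model, c, duration, rng)
            frames = frames_from_path(path, frame_period, model)
            ts = synthesize_traces(
                frames,
                bleach_mean=bleach_mean,
                snr=snr,
                crosstalk=crosstalk,
                seed=rng,
                frame_period=frame_period,
                molecule_id=f"c{ci}_m{mi}",
                concentration=c,
            )
            out.append(ts)
    return out


def simulate_mixed_binary_cohort(
    models: list[KineticModel],
    concentration: float,
    n_per_model: int,
    duration: float = DEFAULT_DURATION,
    seed: int = 0,
    frame_period: float = FRAME_PERIOD,
) -> BinaryCohort:
    """Static-heterogeneity cohort: distinct molecular subpopulations, each
    following its own kinetic scheme (the alternative to dynamic
    heterogeneity, where every molecule interconverts among kinetic modes)."""
    traces, concs, ids = [], [], []
    for gi, model in enumerate(models):
        rng = np.random.default_rng(np.random.SeedSequence([seed, gi]))
        for mi in range(n_per_model):
            path = simulate_path(model, concentration, duration, rng)
            traces.append(frames_from_path(path, frame_period, model))
            concs.append(concentration)
            ids.append(f"g{gi}_m{mi}")
    return BinaryCohort(traces, np.asarray(concs), frame_period, ids)


def static_two_population_models() -> list[KineticModel]:
    """The static-heterogeneity alternative: two single-step subpopulations.

    Each population binds in one step with its own (tau_unbound, tau_bound)
    pair at 1 uM -- (2 s, 20 s) and (20 s, 2 s) -- i.e. a ten-fold spread in
    both classes with equal cycle times, so neither population dominates the
    pooled event statistics.  Dwell mixtures from such a cohort match a
    biexponential, but per-molecule means cluster at the two corners and
    successive same-class dwells correlate, which is how the diagnostics
    separate this scenario from dynamic heterogeneity.
    """
    from zmwbind.models import table1_preset

    base = table1_preset(1)
    slow_bind = base.with_rates({"U1->B1": 0.5e5, "B1->U1": 0.5})
    fast_bind = base.with_rates({"U1->B1": 5.0e5, "B1->U1": 0.05})
    return [slow_bind, fast_bind]


def simulate_multisite(
    model: KineticModel,
    n_sites: int,
    concentration: float,
    duration: float,
    seed: int = 0,
    frame_period: float = FRAME_PERIOD,
) -> np.ndarray:
    """Per-frame occupancy counts for ``n_sites`` independent identical sites.

    Emulates a tetrameric receptor (n_sites=4) where each protomer binds
    ligand independently; the observable is the number of occupied sites.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed]))
    total = None
    for _ in range(n_sites):
        path = simulate_path(model, concentration, duration, rng)
        frames = frames_from_path(path, frame_period, model).astype(np.int16)
        total = frames if total is None else total + frames
    return total
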