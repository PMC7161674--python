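"""Seeded synthetic GSR recordings, RR tachograms, and cohort tables.

Real recordings from the conditioning protocol are not redistributable, so
this module produces cohorts with the statistical structure the analysis
assumes, plus ground truth for recovery tests.

Three subject archetypes are shipped:

``HC``
    healthy control — robust skin-conductance responses to delivered
    noxious stimuli, a clear anticipatory (conditioned) response at the
    unreinforced noxious tone, and an irregular tachogram;
``UWS_CR``
    unresponsive patient who nevertheless acquired the conditioning —
    attenuated but present conditioned response, tachogram irregularity
    close to controls;
``UWS_NOCR``
    unresponsive patient without conditioning — responses to the delivered
    pressure stimulus only, no anticipatory wave, and a markedly more
    regular (lower Sample Entropy) tachogram.

Amplitude and rhythm parameters are plausible-range choices, not measured
values; see the package methods note.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import signal

from .protocol import Kind, ProtocolTimeline, Sequence, build_protocol, write_events

__all__ = [
    "KernelParams",
    "SubjectArchetype",
    "ScrTruth",
    "GsrRecording",
    "RrSeries",
    "DEFAULT_ARCHETYPES",
    "DEFAULT_KERNEL",
    "bateman_kernel",
    "kernel_peak_time",
    "load_archetypes",
    "simulate_gsr",
    "simulate_rr",
    "simulate_cohort",
]


@dataclass(frozen=True)
class KernelParams:
    """Two-exponential (Bateman-type) skin-conductance response shape."""

    tau_rise: float = 0.75  # s
    tau_decay: float = 2.0  # s
    fs: float = 32.0  # Hz

    def __post_init__(self) -> None:
        if not 0 < self.tau_rise < self.tau_decay:
            raise ValueError(
                f"need 0 < tau_rise < tau_decay, got {self.tau_rise}, {self.tau_decay}"
            )
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")


DEFAULT_KERNEL = KernelParams()


@dataclass(frozen=True)
class SubjectArchetype:
    """Generator parameters for one subject class.

    GSR amplitudes are phasic peak sizes in microsiemens; ``habituation``
    and ``extinction`` are per-repetition multiplicative decays; RR
    parameters shape the tachogram (mean interval, respiratory sinus
    arrhythmia sinusoid, AR(1)-filtered noise).
    """

    name: str
    us_amplitude: float  # µS, response to a delivered noxious stimulus
    cr_amplitude: float  # µS, anticipatory response at tone-only noxious trials
    music_amplitude: float  # µS
    habituation: float  # per repeated delivered stimulus, in [0, 1]
    extinction: float  # per tone-only repetition, in [0, 1]
    latency_mean: float = 1.5  # s
    latency_sd: float = 0.3  # s
    tonic_drift_sd: float = 0.05  # µS
    noise_sd: float = 0.01  # µS
    rr_mean: float = 800.0  # ms
    rr_rsa_amp: float = 20.0  # ms
    rr_rsa_freq: float = 0.25  # Hz
    rr_ar_coeff: float = 0.3
    rr_noise_sd: float = 25.0  # ms

    def __post_init__(self) -> None:
        for f in ("us_amplitude", "cr_amplitude", "music_amplitude"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be nonnegative")
        if not -1 < self.rr_ar_coeff < 1:
            raise ValueError("rr_ar_coeff must lie in (-1, 1)")


#: Default archetypes realising the qualitative group contrasts: conditioned
#: response present in HC and UWS_CR, absent in UWS_NOCR; tachogram
#: irregularity HC ≈ UWS_CR > UWS_NOCR.
DEFAULT_ARCHETYPES: dict[str, SubjectArchetype] = {
    "HC": SubjectArchetype(
        name="HC",
        us_amplitude=0.60,
        cr_amplitude=0.40,
        music_amplitude=0.15,
        habituation=0.90,
        extinction=0.65,
        rr_mean=780.0,
        rr_rsa_amp=15.0,
        rr_rsa_freq=0.25,
        rr_ar_coeff=0.30,
        rr_noise_sd=28.0,
    ),
    "UWS_CR": SubjectArchetype(
        name="UWS_CR",
        us_amplitude=0.40,
        cr_amplitude=0.25,
        music_amplitude=0.10,
        habituation=0.90,
        extinction=0.65,
        rr_mean=820.0,
        rr_rsa_amp=18.0,
        rr_rsa_freq=0.25,
        rr_ar_coeff=0.35,
        rr_noise_sd=24.0,
    ),
    "UWS_NOCR": SubjectArchetype(
        name="UWS_NOCR",
        us_amplitude=0.35,
        cr_amplitude=0.0,
        music_amplitude=0.08,
        habituation=0.90,
        extinction=0.65,
        rr_mean=850.0,
        rr_rsa_amp=45.0,
        rr_rsa_freq=0.25,
        rr_ar_coeff=0.92,
        rr_noise_sd=6.0,
    ),
}


def load_archetypes(path) -> dict[str, SubjectArchetype]:
    """Read archetype parameter blocks from a YAML mapping
    {name: {field: value, ...}}; unlisted fields keep their defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"archetype config {path}: expected a mapping")
    out = {}
    for name, params in raw.items():
        try:
            out[name] = SubjectArchetype(name=name, **(params or {}))
        except TypeError as exc:
            raise ValueError(f"archetype config {path}: block {name!r}: {exc}") from exc
    return out


@dataclass(frozen=True)
class ScrTruth:
    """Ground truth for one injected skin-conductance response."""

    label: str
    true_amplitude: float  # µS, phasic peak above the tonic level
    true_latency: float  # s from tone onset


@dataclass
class GsrRecording:
    fs: float
    samples: np.ndarray  # µS
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.samples.size == 0:
            raise ValueError("recording is empty")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.samples)) / self.fs


@dataclass
class RrSeries:
    """A tachogram with BASELINE / SEQ_A / SEQ_B index annotations
    (half-open ranges into ``intervals``)."""

    intervals: np.ndarray  # ms
    segments: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        if np.any(self.intervals <= 0):
            raise ValueError("RR intervals must be positive")
        prev_end = 0
        for name, (start, end) in self.segments.items():
            if start < prev_end or end < start:
                raise ValueError(f"segment {name}: ranges must be disjoint and ordered")
            prev_end = end


def bateman_kernel(params: KernelParams = DEFAULT_KERNEL) -> np.ndarray:
    """Impulse response h(t) = exp(-t/tau_decay) - exp(-t/tau_rise), sampled
    at ``fs`` and truncated where it falls below 1e-4 of its peak."""
    p = params
    t_max = p.tau_decay * 25.0  # generous; truncated against the peak below
    t = np.arange(0.0, t_max, 1.0 / p.fs)
    h = np.exp(-t / p.tau_decay) - np.exp(-t / p.tau_rise)
    keep = h >= 1e-4 * h.max()
    # h(0) = 0 precedes the peak; keep everything up to the last sample
    # above the truncation threshold.
    last = np.nonzero(keep)[0][-1]
    return h[: last + 1]


def kernel_peak_time(params: KernelParams = DEFAULT_KERNEL) -> float:
    """Closed-form time of the kernel maximum."""
    p = params
    return math.log(p.tau_decay / p.tau_rise) * p.tau_rise * p.tau_decay / (
        p.tau_decay - p.tau_rise
    )


def _tonic_component(n: int, fs: float, drift_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Slow tonic level: 2 µS offset plus a low-pass (< 0.05 Hz) random walk
    rescaled to ``drift_sd``."""
    base = np.full(n, 2.0)
    if drift_sd <= 0 or n < 16:
        return base
    walk = np.cumsum(rng.standard_normal(n))
    sos = signal.butter(2, 0.05, btype="low", fs=fs, output="sos")
    slow = signal.sosfiltfilt(sos, walk)
    sd = slow.std()
    if sd > 0:
        slow = slow * (drift_sd / sd)
    return base + slow


def _event_amplitudes(timeline: ProtocolTimeline, arch: SubjectArchetype) -> dict[str, float]:
    """Archetype rule for the phasic amplitude of each trial."""
    amps: dict[str, float] = {}
    n_delivered = 0
    n_tone_only_noc = 0
    for e in timeline.events:
        if e.kind is Kind.MUSIC:
            amps[e.label] = arch.music_amplitude
        elif not e.tone_only:  # delivered noxious stimulus
            n_delivered += 1
            amps[e.label] = arch.us_amplitude * arch.habituation ** (n_delivered - 1)
        else:  # tone-only noxious trial: conditioned response, extinguishing
            n_tone_only_noc += 1
            amps[e.label] = arch.cr_amplitude * arch.extinction ** (n_tone_only_noc - 1)
    return amps


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    if sd <= 0:
        return min(max(mean, lo), hi)
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return v
    return min(max(mean, lo), hi)


def simulate_gsr(
    timeline: ProtocolTimeline,
    archetype: SubjectArchetype,
    kernel: KernelParams = DEFAULT_KERNEL,
    seed: int = 0,
    tail: float = 30.0,
) -> tuple[GsrRecording, list[ScrTruth]]:
    """Generate one GSR recording: tonic drift + event-locked responses +
    white noise, with ground truth for every nonzero response.

    The response kernel is normalised to unit peak, so an event of
    amplitude ``a`` produces a phasic wave peaking at exactly ``a`` µS.
    """
    if seed < 0:
        raise ValueError("seed must be nonnegative")
    rng = np.random.default_rng(seed)
    fs = kernel.fs
    duration = timeline.events[-1].onset + tail
    n = int(round(duration * fs))
    samples = _tonic_component(n, fs, archetype.tonic_drift_sd, rng)

    k = bateman_kernel(kernel)
    k_unit_peak = k / k.max()
    amps = _event_amplitudes(timeline, archetype)
    truths: list[ScrTruth] = []
    for e in timeline.events:
        a = amps[e.label]
        latency = _truncated_normal(
            rng, archetype.latency_mean, archetype.latency_sd, 0.5, 4.0
        )
        if a <= 0:
            continue
        i0 = int(round((e.onset + latency) * fs))
        if i0 >= n:
            continue
        seg = k_unit_peak[: n - i0]
        samples[i0 : i0 + len(seg)] += a * seg
        truths.append(ScrTruth(label=e.label, true_amplitude=a, true_latency=latency))
    if archetype.noise_sd > 0:
        samples = samples + rng.normal(0.0, archetype.noise_sd, size=n)
    return GsrRecording(fs=fs, samples=samples), truths


def simulate_rr(
    timeline: ProtocolTimeline,
    archetype: SubjectArchetype,
    seed: int = 0,
) -> RrSeries:
    """Generate a beat-indexed tachogram covering baseline + both sequences.

    interval_k = rr_mean + RSA sinusoid at the beat's cumulative time +
    AR(1)-filtered noise; segment membership follows cumulative time
    crossing the timeline's boundaries.
    """
    if seed < 0:
        raise ValueError("seed must be nonnegative")
    arch = archetype
    if arch.rr_mean <= 0:
        raise ValueError("rr_mean must be positive")
    rng = np.random.default_rng(seed)
    end_time = timeline.end_time
    n_max = int(end_time / (arch.rr_mean / 1000.0) * 1.5) + 64
    # AR(1)-filtered innovations; ar=0 reduces to white noise.
    eps = rng.normal(0.0, arch.rr_noise_sd, size=n_max)
    noise = signal.lfilter([1.0], [1.0, -arch.rr_ar_coeff], eps)

    intervals: list[float] = []
    t = 0.0  # s, cumulative beat time
    boundaries = [timeline.baseline_duration, timeline.sequence_b_start, end_time]
    seg_edges = [0]
    bi = 0
    k = 0
    while t < end_time and k < n_max:
        rr = (
            arch.rr_mean
            + arch.rr_rsa_amp * math.sin(2.0 * math.pi * arch.rr_rsa_freq * t)
            + noise[k]
        )
        rr = max(rr, 0.2 * arch.rr_mean)  # physiological floor
        intervals.append(rr)
        t += rr / 1000.0
        k += 1
        while bi < len(boundaries) and t >= boundaries[bi]:
            seg_edges.append(k)
            bi += 1
    while len(seg_edges) < 4:
        seg_edges.append(k)
    segments = {
        "BASELINE": (seg_edges[0], seg_edges[1]),
        "SEQ_A": (seg_edges[1], seg_edges[2]),
        "SEQ_B": (seg_edges[2], seg_edges[3]),
    }
    return RrSeries(intervals=np.array(intervals), segments=segments)


# Cohort-table synthesis -----------------------------------------------------

_AGE_BANDS = ["16–20", "20–25", "26–30", "30–35", "36–40", "40–45",
              "46–50", "50–55", "56–60", "60–65", "66–70"]
_ETIOLOGIES = ["TBI", "HEM", "ANOX"]


def _synth_cohort_row(pid: int, arch_name: str, rng: np.random.Generator) -> dict:
    """One synthetic patient row following the cohort-table schema.

    Conditioned responders evolve to MCS within weeks 3-4 with high
    probability; non-responders stay UWS, a small fraction evolving only
    late (after the observation window)."""
    crsr = int(rng.integers(2, 7))
    ncs = int(rng.integers(1, 6))
    row = {
        "patient_id": pid,
        "entry_diagnosis": "UWS",
        "age_band": _AGE_BANDS[int(rng.integers(len(_AGE_BANDS)))],
        "etiology": _ETIOLOGIES[int(rng.integers(3))],
        "days_from_event": int(rng.integers(20, 60)),
        "cr_response": 1 if arch_name == "UWS_CR" else 0,
    }
    if arch_name == "UWS_CR":
        evolves = rng.random() < 8.0 / 9.0
        final = "MCS" if evolves else "UWS"
    else:
        evolves = False
        final = "UWS_LATE" if rng.random() < 2.0 / 21.0 else "UWS"
    for w in range(1, 5):
        if evolves and w >= 3:
            crsr = min(crsr + int(rng.integers(2, 5)), 20)
            ncs = min(ncs + int(rng.integers(0, 3)), 9)
        else:
            crsr = max(2, min(crsr + int(rng.integers(-1, 2)), 8))
            ncs = max(1, min(ncs + int(rng.integers(-1, 2)), 7))
        row[f"crsr_w{w}"] = crsr
        row[f"ncs_w{w}"] = ncs
    row["final_diagnosis"] = final
    return row


def simulate_cohort(
    n_hc: int = 13,
    n_uws_cr: int = 9,
    n_uws_nocr: int = 21,
    seed: int = 0,
    output_dir: str | Path = "cohort",
    timeline: ProtocolTimeline | None = None,
    kernel: KernelParams = DEFAULT_KERNEL,
    archetypes: dict[str, SubjectArchetype] | None = None,
) -> pd.DataFrame:
    """Write a full synthetic cohort to ``output_dir`` and return the
    subject manifest.

    Per subject: ``<id>_gsr.csv`` (time_s,eda_uS), ``<id>_rr.csv`` (rr_ms),
    ``<id>_segments.tsv``; shared ``events.tsv``; patients additionally get
    one row in ``cohort.csv`` (the cohort-table schema).  Per-subject seeds
    derive deterministically from the master seed.
    """
    if min(n_hc, n_uws_cr, n_uws_nocr) < 0:
        raise ValueError("cohort counts must be nonnegative")
    archetypes = archetypes or DEFAULT_ARCHETYPES
    timeline = timeline or build_protocol()
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_events(timeline, out / "events.tsv")

    plan = (
        [("HC", i) for i in range(n_hc)]
        + [("UWS_CR", i) for i in range(n_uws_cr)]
        + [("UWS_NOCR", i) for i in range(n_uws_nocr)]
    )
    manifest_rows = []
    cohort_rows = []
    master = np.random.default_rng(seed)
    subject_seeds = master.integers(0, 2**31 - 1, size=max(len(plan), 1) * 2)
    cohort_rng = np.random.default_rng(subject_seeds[-1] if len(plan) else seed)
    pid = 0
    for s, (arch_name, _) in enumerate(plan):
        arch = archetypes[arch_name]
        sid = f"S{s + 1:03d}"
        rec, truths = simulate_gsr(
            timeline, arch, kernel, seed=int(subject_seeds[2 * s])
        )
        rr = simulate_rr(timeline, arch, seed=int(subject_seeds[2 * s + 1]))
        pd.DataFrame({"time_s": rec.times, "eda_uS": rec.samples}).to_csv(
            out / f"{sid}_gsr.csv", index=False
        )
        pd.DataFrame({"rr_ms": rr.intervals}).to_csv(out / f"{sid}_rr.csv", index=False)
        pd.DataFrame(
            [
                {"segment": name, "start_index": a, "end_index": b}
                for name, (a, b) in rr.segments.items()
            ]
        ).to_csv(out / f"{sid}_segments.tsv", sep="\t", index=False)
        manifest_rows.append({"subject_id": sid, "archetype": arch_name})
        if arch_name != "HC":
            pid += 1
            cohort_rows.append(_synth_cohort_row(pid, arch_name, cohort_rng))
    manifest = pd.DataFrame(manifest_rows, columns=["subject_id", "archetype"])
    manifest.to_csv(out / "subjects.csv", index=False)
    cohort_cols = [
        "patient_id", "entry_diagnosis", "age_band", "etiology",
        "days_from_event", "cr_response",
        "crsr_w1", "ncs_w1", "crsr_w2", "ncs_w2",
        "crsr_w3", "ncs_w3", "crsr_w4", "ncs_w4", "final_diagnosis",
    ]
    pd.DataFrame(cohort_rows, columns=cohort_cols).to_csv(
        out / "cohort.csv", index=False
    )
    return manifest
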