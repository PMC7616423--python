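"""Synthetic paired scalp/intracranial EEG cohorts with annotated IEDs.

The simulator emulates the recording setting of simultaneous scalp EEG
(20 silver-chloride electrodes, Maudsley-style placement) and intracranial
foramen-ovale EEG (two 6-contact bundles, 12 channels) at 200 Hz, with
interictal epileptiform discharges (IEDs) — a sharp spike followed by a slow
wave — injected from deep mesial sources.

Forward model per subject:

* each IED event is a spike-plus-slow-wave template scaled by a lognormal
  amplitude and projected onto the 12 intracranial contacts through a fixed
  unit-norm, non-negative weight vector (contacts near the source dominate);
* the scalp sees the same source train attenuated by a skull scalar and
  spatially blurred through a fixed contact-to-scalp mixing matrix built from
  schematic 10-20 electrode geometry;
* only a configurable fraction of events is scalp-visible; the rest have
  their scalp gain suppressed well below the scalp noise floor.  The peak
  annotations list *every* event (intracranial ground truth), mirroring
  clinical iEEG-based annotation;
* background is 1/f^alpha colored noise (stronger on scalp), plus a 10 Hz
  posterior rhythm and intermittent eye-blink-like frontal artifacts on the
  scalp channels only.

Identical config + seed reproduces a bit-identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import MultichannelRecording, PairedRecording
from .errors import InvalidParameterError, SimulationError

__all__ = [
    "SynthesisConfig", "SubjectGroundTruth", "ied_template", "simulate_subject",
    "make_cohort", "event_window_snr", "scalp_mixing_matrix",
    "SCALP_CHANNELS_20", "FO_CHANNELS_12", "default_benchmark_config",
]

# Schematic 10-20 style scalp coordinates (x: left-negative, y: front-positive).
SCALP_COORDS: dict[str, tuple[float, float]] = {
    "Fp1": (-0.30, 0.95), "Fp2": (0.30, 0.95),
    "F7": (-0.80, 0.60), "F3": (-0.40, 0.50), "Fz": (0.0, 0.50),
    "F4": (0.40, 0.50), "F8": (0.80, 0.60),
    "T3": (-1.00, 0.00), "C3": (-0.50, 0.00), "Cz": (0.0, 0.00),
    "C4": (0.50, 0.00), "T4": (1.00, 0.00),
    "T5": (-0.80, -0.60), "P3": (-0.40, -0.50), "Pz": (0.0, -0.50),
    "P4": (0.40, -0.50), "T6": (0.80, -0.60),
    "O1": (-0.30, -0.95), "O2": (0.30, -0.95), "Oz": (0.0, -1.00),
}
SCALP_CHANNELS_20: list[str] = list(SCALP_COORDS)
FO_CHANNELS_12: list[str] = [f"FO-L{i}" for i in range(1, 7)] + [f"FO-R{i}" for i in range(1, 7)]

# Source / noise scales (µV): FO spikes are large; scalp noise exceeds iEEG noise.
SOURCE_AMPLITUDE_UV = 300.0
INVISIBLE_SUPPRESSION = 0.15   # extra scalp gain factor for scalp-invisible events
SEEG_NOISE_RATIO = 1.4         # scalp noise RMS relative to intracranial noise RMS
ALPHA_AMP_RATIO = 0.8          # 10 Hz rhythm amplitude relative to scalp noise RMS
REFRACTORY_S = 1.0             # minimum gap between consecutive IED peaks
EDGE_MARGIN_S = 2.5            # events kept clear of the recording edges


@dataclass
class SynthesisConfig:
    """Cohort-level simulation settings.

    ``n_ieds_per_subject=None`` draws each subject's event count uniformly from
    the clinically reported 50–953 range.  ``noise_scale`` multiplies every
    stochastic background component (colored noise, rhythm, artifacts); setting
    it to 0 yields the noise-free forward model with identical event structure,
    which the tests use as an analytic oracle.
    """

    n_subjects: int = 18
    duration_s: float = 1200.0
    sampling_rate: float = 200.0
    n_ieds_per_subject: int | None = None
    visibility_fraction: float = 0.15
    ieeg_snr_db: float = 26.0
    seeg_attenuation: float = 0.45
    noise_color_exponent: float = 1.0
    artifact_rate: float = 3.0      # scalp artifact events per minute
    noise_scale: float = 1.0
    seed: int = 0

    def validate(self):
        if self.n_subjects < 1:
            raise InvalidParameterError("n_subjects must be >= 1")
        if self.duration_s <= 0:
            raise InvalidParameterError("duration_s must be positive")
        if self.sampling_rate <= 90:
            raise InvalidParameterError(
                "sampling_rate must exceed twice the template bandwidth (~45 Hz)")
        if not 0 < self.visibility_fraction <= 1:
            raise InvalidParameterError("visibility_fraction must lie in (0, 1]")
        if not 0 < self.seeg_attenuation < 1:
            raise InvalidParameterError("seeg_attenuation must lie in (0, 1)")
        if self.n_ieds_per_subject is not None and self.n_ieds_per_subject < 0:
            raise InvalidParameterError("n_ieds_per_subject must be non-negative")
        if self.noise_scale < 0 or self.artifact_rate < 0:
            raise InvalidParameterError("noise_scale and artifact_rate must be non-negative")


@dataclass
class SubjectGroundTruth:
    """Noise-free internals of one simulated subject (for oracles/diagnostics)."""

    seeg_clean: np.ndarray          # (n_samples, 20) event signal only
    ieeg_clean: np.ndarray          # (n_samples, 12) event signal only
    scalp_mixing: np.ndarray        # (20, 12) contact-to-scalp mixing matrix
    visible: np.ndarray             # (n_events,) bool scalp-visibility mask
    amplitudes: np.ndarray = field(default=None)  # (n_events,) source amplitudes (µV)


def default_benchmark_config(seed: int = 0) -> SynthesisConfig:
    """The package's standard small cohort: 6 subjects, 200 IEDs each, 15% scalp-visible."""
    return SynthesisConfig(n_subjects=6, duration_s=300.0, n_ieds_per_subject=200,
                           visibility_fraction=0.15, seed=seed)


# --------------------------------------------------------------------- template
def ied_template(sampling_rate: float, spike_width_ms: float = 70.0,
                 slow_wave_width_ms: float = 350.0, amplitude: float = 100.0,
                 seed: int = 0) -> tuple[np.ndarray, int]:
    """Spike-plus-slow-wave IED waveform.

    Returns ``(waveform, peak_index)`` where the absolute peak equals
    ``amplitude`` and sits on the sharp component, which precedes the slow
    wave.  ``seed`` perturbs sharpness/asymmetry for morphological variety;
    identical arguments give identical arrays.
    """
    if sampling_rate <= 0:
        raise InvalidParameterError("sampling_rate must be positive")
    if spike_width_ms <= 0 or slow_wave_width_ms <= 0:
        raise InvalidParameterError("template widths must be positive")
    if spike_width_ms >= slow_wave_width_ms:
        raise InvalidParameterError("spike width must be smaller than slow-wave width")

    rng = np.random.default_rng(seed)
    sharpness = rng.uniform(2.5, 3.5)
    asymmetry = rng.uniform(0.85, 1.15)
    slow_ratio = rng.uniform(0.35, 0.50)

    ns_spike = max(4, round(sampling_rate * spike_width_ms / 1000.0))
    ns_slow = max(6, round(sampling_rate * slow_wave_width_ms / 1000.0))
    u = np.linspace(0.0, 1.0, ns_spike, endpoint=False) ** asymmetry
    spike = np.sin(np.pi * u) ** sharpness
    v = np.linspace(0.0, 1.0, ns_slow, endpoint=False)
    slow = slow_ratio * np.sin(np.pi * v)
    lead = ns_spike // 2
    tail = ns_spike // 2
    wf = np.concatenate([np.zeros(lead), spike, slow, np.zeros(tail)])
    peak = int(np.argmax(np.abs(wf)))
    m = np.abs(wf[peak])
    wf = wf * (amplitude / m) if amplitude != 0.0 else np.zeros_like(wf)
    return wf, peak


# ----------------------------------------------------------------------- mixing
def scalp_mixing_matrix() -> np.ndarray:
    """(20, 12) gain matrix mapping FO contacts to scalp electrodes.

    Each contact projects as a spatial bump around an anchor point that slides
    along the temporal-to-frontal axis of its hemisphere (FO bundles lie in the
    ambient cistern; their scalp correlates are fronto-temporal).  Columns are
    scaled to unit peak gain; a small floor keeps every electrode weakly coupled.
    """
    coords = np.array([SCALP_COORDS[c] for c in SCALP_CHANNELS_20])
    anchors = []
    for side in (-1.0, 1.0):
        start, stop = np.array([side * 1.0, -0.1]), np.array([side * 0.45, 0.8])
        for k in range(6):
            anchors.append(start + (stop - start) * k / 5.0)
    P = np.zeros((20, 12))
    for j, a in enumerate(anchors):
        d2 = ((coords - a[None, :]) ** 2).sum(axis=1)
        col = np.exp(-d2 / (2 * 0.45 ** 2)) + 0.02
        P[:, j] = col / col.max()
    return P


def _colored_noise(rng: np.random.Generator, n: int, c: int,
                   exponent: float, rms: float) -> np.ndarray:
    """1/f^exponent noise, per-channel RMS equal to ``rms``."""
    if rms == 0.0:
        return np.zeros((n, c))
    white = rng.standard_normal((n, c))
    f = np.fft.rfftfreq(n)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    shaped = np.fft.irfft(np.fft.rfft(white, axis=0) * scale[:, None], n=n, axis=0)
    shaped /= shaped.std(axis=0, keepdims=True)
    return shaped * rms


# --------------------------------------------------------------------- subjects
def _place_peaks(rng: np.random.Generator, n_events: int, n_samples: int,
                 fs: float) -> np.ndarray:
    margin = max(64, round(EDGE_MARGIN_S * fs))
    gap = round(REFRACTORY_S * fs)
    if n_events == 0:
        return np.empty(0, dtype=np.int64)
    slack = (n_samples - 2 * margin) - (n_events - 1) * gap
    if slack < 0:
        raise SimulationError(
            f"cannot place {n_events} events with a {REFRACTORY_S}s refractory gap "
            f"in {n_samples / fs:.0f}s of recording")
    u = np.sort(rng.uniform(0.0, slack, size=n_events))
    return (margin + u + np.arange(n_events) * gap).astype(np.int64)


def simulate_subject(cfg: SynthesisConfig, subject_index: int,
                     return_clean: bool = False):
    """Simulate one subject's paired recording (optionally with its ground truth).

    Deterministic in ``(cfg, subject_index)``: the subject's random stream is
    derived from ``SeedSequence([cfg.seed, subject_index])``, with independent
    child streams for event structure and each noise source, so the noise-free
    twin (``noise_scale=0``) has identical events.
    """
    cfg.validate()
    fs = cfg.sampling_rate
    n = round(cfg.duration_s * fs)
    ss = np.random.SeedSequence([cfg.seed, subject_index])
    structure_rng, ieeg_noise_rng, seeg_noise_rng, artifact_rng = \
        (np.random.Generator(np.random.PCG64(c)) for c in ss.spawn(4))

    n_events = (cfg.n_ieds_per_subject if cfg.n_ieds_per_subject is not None
                else int(structure_rng.integers(50, 954)))
    peaks = _place_peaks(structure_rng, n_events, n, fs)

    # subject-specific intracranial source weights: non-negative, concentrated
    g = structure_rng.standard_normal(12) ** 2
    w_contacts = g / np.linalg.norm(g)
    P = scalp_mixing_matrix()
    w_scalp_full = P @ w_contacts

    visible = structure_rng.random(n_events) < cfg.visibility_fraction
    amplitudes = SOURCE_AMPLITUDE_UV * np.exp(structure_rng.normal(0.0, 0.2, n_events))

    ieeg_clean = np.zeros((n, 12))
    seeg_clean = np.zeros((n, 20))
    for e in range(n_events):
        spike_ms = structure_rng.uniform(55.0, 85.0)
        slow_ms = structure_rng.uniform(300.0, 400.0)
        tpl_seed = int(structure_rng.integers(2 ** 31))
        wf, pk = ied_template(fs, spike_ms, slow_ms, amplitude=1.0, seed=tpl_seed)
        onset = int(peaks[e]) - pk
        stop = onset + len(wf)
        if onset < 0 or stop > n:   # edge margin guarantees this never triggers
            raise SimulationError("event template exceeds recording bounds")
        src = amplitudes[e] * wf
        ieeg_clean[onset:stop] += src[:, None] * w_contacts[None, :]
        gain = cfg.seeg_attenuation * (1.0 if visible[e] else INVISIBLE_SUPPRESSION)
        seeg_clean[onset:stop] += gain * src[:, None] * w_scalp_full[None, :]

    sigma_i = (SOURCE_AMPLITUDE_UV / np.sqrt(12)) * 10 ** (-cfg.ieeg_snr_db / 20.0) \
        * cfg.noise_scale
    sigma_s = SEEG_NOISE_RATIO * sigma_i
    ieeg = ieeg_clean + _colored_noise(ieeg_noise_rng, n, 12,
                                       cfg.noise_color_exponent, sigma_i)
    seeg = seeg_clean + _colored_noise(seeg_noise_rng, n, 20,
                                       cfg.noise_color_exponent, sigma_s)

    # 10 Hz posterior rhythm with a slow amplitude envelope (scalp only)
    if sigma_s > 0:
        t = np.arange(n) / fs
        y_coord = np.array([SCALP_COORDS[c][1] for c in SCALP_CHANNELS_20])
        alpha_w = np.where(y_coord < -0.3, 1.0, 0.2) * ALPHA_AMP_RATIO * sigma_s
        phases = seeg_noise_rng.uniform(0, 2 * np.pi, 20)
        env_phase = seeg_noise_rng.uniform(0, 2 * np.pi)
        env = 1.0 + 0.5 * np.sin(2 * np.pi * 0.08 * t + env_phase)
        seeg += alpha_w[None, :] * env[:, None] * np.sin(
            2 * np.pi * 10.0 * t[:, None] + phases[None, :])

    # eye-blink-like frontal artifacts (scalp only)
    n_art = artifact_rng.poisson(cfg.artifact_rate * cfg.duration_s / 60.0)
    if n_art > 0 and cfg.noise_scale > 0:
        y_coord = np.array([SCALP_COORDS[c][1] for c in SCALP_CHANNELS_20])
        w_art = 0.15 + 0.85 * np.clip(y_coord, 0.0, None) ** 2
        for _ in range(n_art):
            dur = round(artifact_rng.uniform(0.3, 0.5) * fs)
            start = int(artifact_rng.integers(0, n - dur))
            amp = artifact_rng.uniform(80.0, 150.0) * cfg.noise_scale
            bump = amp * np.hanning(dur)
            seeg[start:start + dur] += bump[:, None] * w_art[None, :]

    rec = PairedRecording(
        seeg=MultichannelRecording(seeg, fs, SCALP_CHANNELS_20),
        ieeg=MultichannelRecording(ieeg, fs, FO_CHANNELS_12),
        ied_peaks=peaks,
        subject_id=f"S{subject_index + 1}",
    )
    if return_clean:
        gt = SubjectGroundTruth(seeg_clean=seeg_clean, ieeg_clean=ieeg_clean,
                                scalp_mixing=P, visible=visible, amplitudes=amplitudes)
        return rec, gt
    return rec


def make_cohort(cfg: SynthesisConfig) -> list[PairedRecording]:
    """Simulate ``cfg.n_subjects`` subjects with ids S1, S2, ... (deterministic)."""
    cfg.validate()
    return [simulate_subject(cfg, i) for i in range(cfg.n_subjects)]


# ----------------------------------------------------------------------- oracle
def event_window_snr(clean: np.ndarray, noise: np.ndarray, peaks: np.ndarray,
                     half_width: int = 32) -> np.ndarray:
    """Per-event SNR: RMS of the clean event window over RMS of the noise there.

    Windows are the half-open ``[p - half_width, p + half_width)`` used by
    segmentation, aggregated over all channels.
    """
    out = np.empty(len(peaks))
    for i, p in enumerate(np.asarray(peaks, dtype=int)):
        sl = slice(p - half_width, p + half_width)
        s = np.sqrt(np.mean(clean[sl] ** 2))
        nz = np.sqrt(np.mean(noise[sl] ** 2))
        out[i] = np.inf if nz == 0 else s / nz
    return out
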