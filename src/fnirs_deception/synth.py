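"""Synthetic fNIRS subjects with known ground truth.

The generator emulates the statistical structure the analysis assumes for a
mock-theft interview cohort: each subject answers a three-stage, 30-question
interview (stage 1: ten non-induced responses, a shuffled half-and-half mix of
non-induced lies m=3 and truths m=4; stage 2: ten induced lies m=1; stage 3:
ten induced truths m=2).  Each answer evokes, on a small set of *informative*
voxels, a gamma-shaped hemodynamic response peaking ~1.6 s after the stimulus
whose blood-volume amplitude depends on the response class.  The response
loads 75% on dC_HbO2 and 25% on -dC_Hb (typical activation polarity), scaled
so the planted dB amplitude equals the configured class amplitude.

Physiological noise is added in concentration space — cardiac (~1.1 Hz) and
respiratory (~0.3 Hz) sinusoids with random per-voxel phases, a slow drift
sinusoid (~0.02 Hz) and white noise.  The cardiac/respiratory terms lie above
the analysis' 0.14 Hz low-pass cutoff, so the filter demonstrably removes
them; the drift survives the filter and exercises the baseline-relative
design.  Finally the concentration series is forward-mapped through the
Beer-Lambert model to strictly positive two-wavelength intensities,
I(k) = I_b * 10^(-dOD(k)).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .fnirs_io import RawRecording, StimulusEvent
from .preprocess import DEFAULT_EXTINCTION, ExtinctionTable

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "hrf_kernel",
    "simulate_subject",
    "simulate_cohort",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic cohort.

    Class blood-volume amplitudes (umol/L): induced lies respond strongest,
    non-induced lies slightly above non-induced truths (so the two are not
    discriminable, matching their merge into one problem class), induced
    truths weakest.  The true magnitude of deception-related dB is not
    established; a few umol/L is a realistic cortical-activation scale.
    """

    n_subjects: int = 10
    n_questions_per_stage: int = 10
    fs: float = 2.004
    n_voxels: int = 16
    informative_voxels: tuple[int, ...] = (0, 7)  # 0-based: voxels V1 and V8
    class_amplitudes: dict[int, float] = field(
        default_factory=lambda: {1: 4.0, 2: 1.0, 3: 2.1, 4: 1.9}
    )
    hrf_peak_s: float = 1.6
    hrf_duration_s: float = 12.0
    hrf_shape: float = 2.0
    noise_cardiac: float = 0.4
    cardiac_freq_hz: float = 1.1
    noise_respiratory: float = 0.3
    respiratory_freq_hz: float = 0.3
    noise_drift: float = 0.1
    drift_freq_hz: float = 0.02
    noise_white: float = 0.05
    inter_question_gap_s: float = 20.0
    baseline_duration_s: float = 30.0
    pre_first_question_s: float = 15.0
    post_last_question_s: float = 15.0
    base_intensity: float = 1000.0
    hbo2_fraction: float = 0.75
    subject_amplitude_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hrf_peak_s <= 0 or self.hrf_peak_s >= self.hrf_duration_s:
            raise ValueError("need 0 < hrf_peak_s < hrf_duration_s")
        for name in ("noise_cardiac", "noise_respiratory", "noise_drift",
                     "noise_white"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(v < 0 or v >= self.n_voxels for v in self.informative_voxels):
            raise ValueError("informative voxel index out of range")

    @property
    def n_questions(self) -> int:
        return 3 * self.n_questions_per_stage


@dataclass
class GroundTruth:
    """Planted structure of one synthetic subject."""

    subject_id: str
    class_labels: np.ndarray  # per question, in interview order
    events: list[StimulusEvent]
    informative_voxels: tuple[int, ...]
    clean_dC_Hb: np.ndarray  # [samples, voxels], noise-free
    clean_dC_HbO2: np.ndarray
    amplitude_scale: float


def hrf_kernel(
    peak_time_s: float = 1.6,
    duration_s: float = 12.0,
    fs: float = 2.004,
    shape: float = 2.0,
) -> np.ndarray:
    """Gamma-shaped hemodynamic response, 0 at t=0, unit peak near
    ``peak_time_s``, decaying toward 0 by ``duration_s``.

    h(t) = (t/tp)^a * exp(a * (1 - t/tp)); the sampled kernel is renormalized
    so its maximum (at the sample nearest the peak) is exactly 1.
    """
    if peak_time_s <= 0 or fs <= 0:
        raise ValueError("peak_time_s and fs must be positive")
    if peak_time_s >= duration_s:
        raise ValueError(
            f"peak_time_s {peak_time_s} must be < duration_s {duration_s}"
        )
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    u = t / peak_time_s
    h = u**shape * np.exp(shape * (1.0 - u))
    return h / h.max()


def _stage_labels(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Interview order: stage 1 non-induced (balanced m=3/m=4, shuffled),
    stage 2 induced lies, stage 3 induced truths."""
    npq = cfg.n_questions_per_stage
    stage1 = np.array([3, 4] * ((npq + 1) // 2))[:npq]
    rng.shuffle(stage1)
    return np.concatenate([stage1, np.full(npq, 1), np.full(npq, 2)])


def simulate_subject(
    cfg: SyntheticConfig,
    seed: int,
    subject_id: str = "S01",
    ext: ExtinctionTable = DEFAULT_EXTINCTION,
    amplitude_scale: float = 1.0,
) -> tuple[RawRecording, GroundTruth]:
    """One synthetic subject: raw recording + planted ground truth.

    Deterministic in ``(cfg, seed)``.  Raises if the configured amplitudes
    drive the forward-modelled intensity non-positive or non-finite.
    """
    rng = np.random.default_rng(seed)
    fs, V = cfg.fs, cfg.n_voxels

    labels = _stage_labels(cfg, rng)
    t0 = cfg.baseline_duration_s + cfg.pre_first_question_s
    event_times = t0 + np.arange(cfg.n_questions) * cfg.inter_question_gap_s
    events = [
        StimulusEvent(time_s=float(t), question_id=q + 1, class_label=int(m))
        for q, (t, m) in enumerate(zip(event_times, labels))
    ]
    duration = event_times[-1] + cfg.post_last_question_s
    n = int(np.ceil(duration * fs))
    times = np.arange(n) / fs

    # planted, noise-free concentration series
    kernel = hrf_kernel(cfg.hrf_peak_s, cfg.hrf_duration_s, fs, cfg.hrf_shape)
    clean_hbo2 = np.zeros((n, V))
    clean_hb = np.zeros((n, V))
    f = cfg.hbo2_fraction
    for ev in events:
        amp = cfg.class_amplitudes[ev.class_label] * amplitude_scale
        k0 = int(np.ceil(ev.time_s * fs - 1e-9))  # first sample at/after onset
        k1 = min(n, k0 + kernel.size)
        seg = kernel[: k1 - k0]
        for v in cfg.informative_voxels:
            # dB amplitude = amp: loadings 2*amp*f on HbO2, -2*amp*(1-f) on Hb
            clean_hbo2[k0:k1, v] += 2.0 * amp * f * seg
            clean_hb[k0:k1, v] -= 2.0 * amp * (1.0 - f) * seg

    # physiological noise in concentration space, per chromophore
    def noise_block() -> np.ndarray:
        out = np.zeros((n, V))
        for amp_, freq in (
            (cfg.noise_cardiac, cfg.cardiac_freq_hz),
            (cfg.noise_respiratory, cfg.respiratory_freq_hz),
            (cfg.noise_drift, cfg.drift_freq_hz),
        ):
            if amp_ > 0:
                phases = rng.uniform(0, 2 * np.pi, V)
                out += amp_ * np.sin(2 * np.pi * freq * times[:, None] + phases)
        if cfg.noise_white > 0:
            out += rng.normal(0.0, cfg.noise_white, (n, V))
        return out

    dC_hbo2 = clean_hbo2 + noise_block()
    dC_hb = clean_hb + noise_block()

    # forward Beer-Lambert: dOD[.,v,w] = a[w,0]*dC_Hb + a[w,1]*dC_HbO2
    a = ext.alpha
    dOD = np.stack(
        [a[w, 0] * dC_hb + a[w, 1] * dC_hbo2 for w in range(2)], axis=-1
    )
    # integer baseline intensities: the baseline average then reproduces I_b
    # exactly in floating point, so quiet voxels invert to exactly zero
    I_b = np.floor(cfg.base_intensity * rng.uniform(0.8, 1.2, (V, 2)))
    intensity = I_b[np.newaxis] * 10.0 ** (-dOD)
    if not (np.isfinite(intensity).all() and (intensity > 0).all()):
        raise ValueError(
            "configuration drives forward-modelled intensity non-positive; "
            "reduce class amplitudes or noise relative to base_intensity"
        )

    rec = RawRecording(
        subject_id=subject_id,
        fs=fs,
        wavelengths=ext.wavelengths,
        intensity=intensity,
        baseline_interval=(0.0, cfg.baseline_duration_s),
        events=events,
    )
    truth = GroundTruth(
        subject_id=subject_id,
        class_labels=labels,
        events=events,
        informative_voxels=cfg.informative_voxels,
        clean_dC_Hb=clean_hb,
        clean_dC_HbO2=clean_hbo2,
        amplitude_scale=amplitude_scale,
    )
    return rec, truth


def simulate_cohort(
    cfg: SyntheticConfig,
    ext: ExtinctionTable = DEFAULT_EXTINCTION,
) -> list[tuple[RawRecording, GroundTruth]]:
    """Independent subjects with per-subject seeds derived from ``cfg.seed``.

    Optional between-subject amplitude variability: each subject's response
    amplitudes are scaled by ``1 + subject_amplitude_sd * z`` (z standard
    normal, floored at 0.1).
    """
    if cfg.n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    master = np.random.default_rng(cfg.seed)
    seeds = master.integers(0, 2**31 - 1, size=cfg.n_subjects)
    scales = np.maximum(
        0.1, 1.0 + cfg.subject_amplitude_sd * master.standard_normal(cfg.n_subjects)
    )
    return [
        simulate_subject(
            cfg,
            seed=int(seeds[i]),
            subject_id=f"S{i + 1:02d}",
            ext=ext,
            amplitude_scale=float(scales[i]),
        )
        for i in range(cfg.n_subjects)
    ]
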