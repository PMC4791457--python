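"""Raw-intensity preprocessing: FIR low-pass, optical density, and the
modified Beer-Lambert inversion to chromophore concentration changes.

The measurement model at each voxel and wavelength is

    dOD(k) = log10( I_b / I(k) ) = a_Hb * dC_Hb(k) + a_HbO2 * dC_HbO2(k)

where ``I_b`` is the mean light intensity over the resting baseline, ``I(k)``
the intensity at sample ``k``, and ``a_*`` effective molar extinction
coefficients (tabulated decadic extinction folded with an effective
pathlength of 1; only relative contrasts matter downstream, and those are
invariant to this overall scale).  With two wavelengths the 2x2 linear system
is inverted per sample to recover ``dC_Hb`` and ``dC_HbO2`` in umol/L, from
which the relative changes in blood volume and oxygenation follow:

    dB(k) = dC_HbO2(k) + dC_Hb(k)
    dO(k) = dC_HbO2(k) - dC_Hb(k)

Physiological nuisance signals (cardiac ~1 Hz, respiratory ~0.3 Hz) are
removed by a Hamming-window FIR low-pass with a 0.14 Hz cutoff applied to the
raw intensities, by default zero-phase (forward-backward) so the 5-s
post-stimulus windows stay event-aligned.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .fnirs_io import RawRecording, StimulusEvent

__all__ = [
    "ExtinctionTable",
    "DEFAULT_EXTINCTION",
    "FilterConfig",
    "HemoSeries",
    "design_fir_lowpass",
    "lowpass_filter",
    "compute_baseline",
    "optical_density",
    "invert_beer_lambert",
    "derive_volume_oxygenation",
    "preprocess_recording",
]

_MAX_COND = 1e8


@dataclass(frozen=True)
class ExtinctionTable:
    """2x2 effective molar extinction matrix.

    Rows are wavelengths ``(l1, l2)``, columns chromophores ``(Hb, HbO2)``,
    in units such that ``dOD = alpha @ dC`` with ``dC`` in umol/L.
    """

    alpha: np.ndarray
    wavelengths: tuple[float, float] = (730.0, 850.0)

    def __post_init__(self) -> None:
        a = np.asarray(self.alpha, dtype=float)
        object.__setattr__(self, "alpha", a)
        if a.shape != (2, 2):
            raise ValueError(f"alpha must be 2x2, got {a.shape}")
        if (a < 0).any() or not (a.diagonal() > 0).all():
            # physical tables are strictly positive; zeros off the diagonal
            # are tolerated so unit/identity tables can be used in calibration
            raise ValueError("extinction coefficients must be non-negative "
                             "with a positive diagonal")
        cond = np.linalg.cond(a)
        if not np.isfinite(cond) or cond > _MAX_COND:
            raise ValueError(
                f"extinction matrix is singular or ill-conditioned "
                f"(cond={cond:.3g} > {_MAX_COND:.0e})"
            )

    @classmethod
    def from_csv(cls, path: str | Path) -> "ExtinctionTable":
        """Load from a 2x2 CSV with wavelength row labels.

        Expected layout: columns ``wavelength_nm, Hb, HbO2``; two rows.
        """
        tab = pd.read_csv(path)
        need = ["wavelength_nm", "Hb", "HbO2"]
        if list(tab.columns) != need or len(tab) != 2:
            raise ValueError(f"extinction CSV must have columns {need} and 2 rows")
        tab = tab.sort_values("wavelength_nm")
        return cls(
            alpha=tab[["Hb", "HbO2"]].to_numpy(dtype=float),
            wavelengths=tuple(tab["wavelength_nm"].astype(float)),
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "wavelength_nm": list(self.wavelengths),
                "Hb": self.alpha[:, 0],
                "HbO2": self.alpha[:, 1],
            }
        ).to_csv(path, index=False, float_format="%.17g")


# Decadic molar extinction of hemoglobin (cm^-1 / (mol/L), compiled optical
# tables) at 730 and 850 nm, scaled so that concentrations are in umol/L with
# an effective pathlength of 1:
#   730 nm: Hb 1102.2, HbO2 390.0
#   850 nm: Hb  691.3, HbO2 1058.0
DEFAULT_EXTINCTION = ExtinctionTable(
    alpha=np.array([[1.1022e-3, 0.3900e-3], [0.6913e-3, 1.0580e-3]])
)


@dataclass(frozen=True)
class FilterConfig:
    """Low-pass design: 0.14 Hz cutoff, Hamming window, odd tap count."""

    cutoff_hz: float = 0.14
    n_taps: int = 21
    zero_phase: bool = True


@dataclass
class HemoSeries:
    """Per-voxel hemodynamic time series in umol/L.

    ``dB = dC_HbO2 + dC_Hb`` (blood volume) and ``dO = dC_HbO2 - dC_Hb``
    (oxygenation), elementwise by construction.
    """

    subject_id: str
    fs: float
    dC_Hb: np.ndarray
    dC_HbO2: np.ndarray
    dB: np.ndarray
    dO: np.ndarray
    events: list[StimulusEvent] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.dB.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.dB.shape[1]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def design_fir_lowpass(
    fs: float, cutoff_hz: float = 0.14, n_taps: int = 21
) -> np.ndarray:
    """Hamming-windowed-sinc linear-phase low-pass taps, DC gain exactly 1."""
    if not 0 < cutoff_hz < fs / 2:
        raise ValueError(
            f"cutoff must lie in (0, Nyquist={fs / 2:.6g}), got {cutoff_hz}"
        )
    if n_taps < 5 or n_taps % 2 == 0:
        raise ValueError(f"n_taps must be an odd integer >= 5, got {n_taps}")
    taps = signal.firwin(n_taps, cutoff_hz, window="hamming", fs=fs)
    return taps / taps.sum()


def lowpass_filter(
    rec: RawRecording,
    taps: np.ndarray | None = None,
    config: FilterConfig = FilterConfig(),
) -> RawRecording:
    """Filter every voxel/wavelength channel identically; length preserved.

    Zero-phase (``filtfilt``) by default so event-locked features are not
    time-shifted; set ``config.zero_phase=False`` for a causal single pass.
    """
    if taps is None:
        taps = design_fir_lowpass(rec.fs, config.cutoff_hz, config.n_taps)
    taps = np.asarray(taps, dtype=float)
    if rec.n_samples <= 3 * taps.size:
        raise ValueError(
            f"recording too short to filter: {rec.n_samples} samples <= "
            f"3 x {taps.size} taps"
        )
    flat = rec.intensity.reshape(rec.n_samples, -1)
    if config.zero_phase:
        out = signal.filtfilt(taps, [1.0], flat, axis=0)
    else:
        out = signal.lfilter(taps, [1.0], flat, axis=0)
    filtered = dataclasses.replace(
        rec, intensity=out.reshape(rec.intensity.shape)
    )
    return filtered


def baseline_sample_indices(rec: RawRecording) -> np.ndarray:
    """Indices k with t0 <= k/fs < t1 for the recording's baseline interval."""
    t0, t1 = rec.baseline_interval
    k = np.arange(rec.n_samples)
    return k[(k / rec.fs >= t0) & (k / rec.fs < t1)]


def compute_baseline(rec: RawRecording) -> np.ndarray:
    """Arithmetic mean intensity over the baseline window, per voxel x wavelength."""
    idx = baseline_sample_indices(rec)
    if idx.size < 2:
        raise ValueError(
            f"baseline interval {rec.baseline_interval} contains "
            f"{idx.size} samples; need >= 2"
        )
    return rec.intensity[idx].mean(axis=0)


def optical_density(I: np.ndarray, I_b: np.ndarray) -> np.ndarray:
    """dOD = log10(I_b / I); dimensionless. Broadcasts over arrays."""
    I = np.asarray(I, dtype=float)
    I_b = np.asarray(I_b, dtype=float)
    if not ((I > 0).all() and (I_b > 0).all()):
        raise ValueError("optical density requires strictly positive intensities")
    return np.log10(I_b / I)


def invert_beer_lambert(
    dOD: np.ndarray, ext: ExtinctionTable = DEFAULT_EXTINCTION
) -> tuple[np.ndarray, np.ndarray]:
    """Solve the two-wavelength system for (dC_Hb, dC_HbO2) in umol/L.

    ``dOD`` carries the wavelength pair on its *last* axis; any leading shape
    is allowed.  Exact linear solve (not a pseudo-inverse), so the forward
    model ``alpha @ dC`` reproduces ``dOD`` to machine precision.
    """
    dOD = np.asarray(dOD, dtype=float)
    if dOD.shape[-1] != 2:
        raise ValueError(f"dOD last axis must be the wavelength pair, got {dOD.shape}")
    lead = dOD.shape[:-1]
    sol = np.linalg.solve(ext.alpha, dOD.reshape(-1, 2).T)  # [2, N]
    dC_Hb = sol[0].reshape(lead)
    dC_HbO2 = sol[1].reshape(lead)
    return dC_Hb, dC_HbO2


def derive_volume_oxygenation(
    dC_Hb: np.ndarray, dC_HbO2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """dB = dC_HbO2 + dC_Hb (blood volume); dO = dC_HbO2 - dC_Hb (oxygenation)."""
    dC_Hb = np.asarray(dC_Hb, dtype=float)
    dC_HbO2 = np.asarray(dC_HbO2, dtype=float)
    if dC_Hb.shape != dC_HbO2.shape:
        raise ValueError(
            f"shape mismatch: dC_Hb {dC_Hb.shape} vs dC_HbO2 {dC_HbO2.shape}"
        )
    return dC_HbO2 + dC_Hb, dC_HbO2 - dC_Hb


def preprocess_recording(
    rec: RawRecording,
    ext: ExtinctionTable = DEFAULT_EXTINCTION,
    filter_config: FilterConfig | None = FilterConfig(),
) -> HemoSeries:
    """Full preprocessing chain: filter -> baseline OD -> inversion -> dB/dO.

    The baseline reference ``I_b`` is always the mean of the *unfiltered*
    baseline intensity (it is defined as the resting-light measurement before
    any processing).  Pass ``filter_config=None`` to skip the low-pass, e.g.
    when checking the linear inversion arithmetic in isolation.
    """
    I_b = compute_baseline(rec)
    work = rec if filter_config is None else lowpass_filter(rec, config=filter_config)
    dOD = optical_density(work.intensity, I_b[np.newaxis])
    dC_Hb, dC_HbO2 = invert_beer_lambert(dOD, ext)
    dB, dO = derive_volume_oxygenation(dC_Hb, dC_HbO2)
    return HemoSeries(
        subject_id=rec.subject_id,
        fs=rec.fs,
        dC_Hb=dC_Hb,
        dC_HbO2=dC_HbO2,
        dB=dB,
        dO=dO,
        events=list(rec.events),
    )
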