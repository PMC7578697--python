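"""fNIRS preprocessing: raw intensities -> HbO2/HHb -> channel features.

The chain mirrors standard continuous-wave NIRS practice:

1. modified Beer-Lambert law (MBLL): optical-density changes relative to
   the baseline-interval mean intensity are mapped through the 2x2
   extinction system (two wavelengths x two chromophores), scaled by the
   source-detector separation and a differential pathlength factor;
2. zero-phase band-pass, 0.01-0.09 Hz third-order Butterworth applied
   forward-backward, suppressing slow drift below the band and cardiac
   pulsation above it without shifting event timing;
3. baseline standardization: per channel, subtract the mean of the 20-s
   pre-stimulus baseline (optionally also divide by its SD);
4. block features: mean HbO2 per channel over each CIT block after
   dropping the first ``onset_exclusion_s`` seconds (the hemodynamic
   response lags stimulus onset), giving one 16-channel feature vector
   per subject x CIT.

Sixteen channels, CH1-CH8 over the right and CH9-CH16 over the left
prefrontal cortex, sampled every 0.65 s.  Concentration changes are in
micromolar (uM), assuming extinction coefficients in 1/(mM cm) and the
source-detector separation in cm.  Time is seconds from recording start
and all intervals are half-open [start, end).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "N_CHANNELS",
    "CHANNELS",
    "DT_DEFAULT",
    "RawIntensitySeries",
    "MbllConfig",
    "HbSeries",
    "SessionLayout",
    "PreprocessConfig",
    "FeatureVector",
    "FeatureTable",
    "mbll_convert",
    "bandpass_zero_phase",
    "baseline_standardize",
    "block_features",
    "build_dataset",
    "preprocess_session",
]

N_CHANNELS = 16
CHANNELS = tuple(f"CH{i}" for i in range(1, N_CHANNELS + 1))
DT_DEFAULT = 0.65  # s per sample
CIT_IDS = ("CIT1", "CIT2", "CIT3")

# molar extinction coefficients, 1/(mM cm), tabulated values for whole blood
# at the two measurement wavelengths (columns: HbO2, HHb)
DEFAULT_WAVELENGTHS = (770.0, 840.0)
DEFAULT_EXTINCTION = np.array([[0.650, 1.3029], [1.058, 0.7804]])


@dataclass
class MbllConfig:
    """Extinction system for the two-wavelength MBLL inversion."""

    wavelengths_nm: tuple[float, float] = DEFAULT_WAVELENGTHS
    extinction: np.ndarray = field(default_factory=lambda: DEFAULT_EXTINCTION.copy())
    dpf: tuple[float, float] = (6.0, 6.0)
    separation_cm: float = 3.0

    def pathlength_matrix(self) -> np.ndarray:
        """2x2 system mapping (dHbO2, dHHb) in mM to optical-density change."""
        E = np.asarray(self.extinction, dtype=float)
        if E.shape != (2, 2):
            raise ValueError("extinction must be 2x2 (wavelength x chromophore)")
        M = E * (self.separation_cm * np.asarray(self.dpf)[:, None])
        if abs(np.linalg.det(M)) < 1e-12:
            raise ValueError("extinction system is singular; cannot separate chromophores")
        return M


@dataclass
class RawIntensitySeries:
    """Two-wavelength light intensities, shape (16 channels, 2, T)."""

    subject_id: str
    data: np.ndarray
    dt: float = DT_DEFAULT
    wavelengths_nm: tuple[float, float] = DEFAULT_WAVELENGTHS

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[:2] != (N_CHANNELS, 2):
            raise ValueError(f"data must be ({N_CHANNELS}, 2, T)")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt


@dataclass
class HbSeries:
    """Concentration-change series (uM), shapes (16, T) for HbO2 and HHb."""

    subject_id: str
    hbo: np.ndarray
    hhb: np.ndarray
    dt: float = DT_DEFAULT

    def __post_init__(self) -> None:
        self.hbo = np.asarray(self.hbo, dtype=float)
        self.hhb = np.asarray(self.hhb, dtype=float)
        if self.hbo.shape != self.hhb.shape or self.hbo.ndim != 2:
            raise ValueError("hbo and hhb must share a (channels, T) shape")
        if self.hbo.shape[0] != N_CHANNELS:
            raise ValueError(f"expected {N_CHANNELS} channels")
        if not (np.all(np.isfinite(self.hbo)) and np.all(np.isfinite(self.hhb))):
            raise ValueError("Hb series must be finite")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_samples(self) -> int:
        return self.hbo.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt


@dataclass(frozen=True)
class SessionLayout:
    """Block-design timing in seconds from recording start.

    ``blocks`` maps CIT id to its [start, end) interval; baseline, rests
    and the post-task interval are the no-stimulation periods.
    """

    baseline: tuple[float, float]
    blocks: dict[str, tuple[float, float]]
    rests: tuple[tuple[float, float], ...] = ()
    post: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        ivals = [self.baseline, *self.blocks.values(), *self.rests]
        if self.post is not None:
            ivals.append(self.post)
        for s, e in ivals:
            if not e > s:
                raise ValueError(f"empty interval ({s}, {e})")
        ordered = sorted(ivals)
        for (s0, e0), (s1, e1) in zip(ordered, ordered[1:]):
            if s1 < e0:
                raise ValueError("layout intervals overlap")

    @property
    def total_duration(self) -> float:
        ivals = [self.baseline, *self.blocks.values(), *self.rests]
        if self.post is not None:
            ivals.append(self.post)
        return max(e for _, e in ivals)

    @classmethod
    def default(
        cls,
        n_trials: int = 18,
        trial_s: float = 12.0,
        baseline_s: float = 20.0,
        rest_s: float = 20.0,
        post_s: float = 20.0,
    ) -> "SessionLayout":
        """Baseline, three CIT blocks separated by rests, post-task rest.

        ``trial_s`` is the per-trial budget: the 5.25-s item plus the
        response window until the next item.
        """
        block_s = n_trials * trial_s
        t = baseline_s
        blocks: dict[str, tuple[float, float]] = {}
        rests = []
        for i, cit in enumerate(CIT_IDS):
            blocks[cit] = (t, t + block_s)
            t += block_s
            if i < len(CIT_IDS) - 1:
                rests.append((t, t + rest_s))
                t += rest_s
        return cls(
            baseline=(0.0, baseline_s),
            blocks=blocks,
            rests=tuple(rests),
            post=(t, t + post_s),
        )


@dataclass(frozen=True)
class PreprocessConfig:
    f_lo: float = 0.01
    f_hi: float = 0.09
    filter_order: int = 3
    onset_exclusion_s: float = 10.0
    standardize_mode: str = "mean"  # "mean" or "z"

    def validate(self, dt: float) -> None:
        nyq = 0.5 / dt
        if not 0.0 < self.f_lo < self.f_hi < nyq:
            raise ValueError(
                f"band ({self.f_lo}, {self.f_hi}) Hz invalid for Nyquist {nyq:.3f} Hz"
            )
        if self.onset_exclusion_s < 0:
            raise ValueError("onset exclusion must be >= 0")
        if self.standardize_mode not in ("mean", "z"):
            raise ValueError("standardize_mode must be 'mean' or 'z'")


@dataclass(frozen=True)
class FeatureVector:
    """Standardized mean HbO2 per channel for one subject x CIT."""

    subject_id: str
    group: str
    cit_id: str
    x: np.ndarray
    mhe: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        if self.x.shape != (N_CHANNELS,) or not np.all(np.isfinite(self.x)):
            raise ValueError(f"feature vector must hold {N_CHANNELS} finite values")
        if self.group not in ("CL", "HC"):
            raise ValueError("group must be 'CL' or 'HC'")


def _interval_slice(t0: float, t1: float, dt: float, n: int) -> slice:
    """Sample indices with t in [t0, t1); sample i sits at i*dt."""
    i0 = int(np.ceil(t0 / dt - 1e-9))
    i1 = int(np.ceil(t1 / dt - 1e-9))
    return slice(max(i0, 0), min(i1, n))


def mbll_convert(
    raw: RawIntensitySeries,
    cfg: MbllConfig,
    baseline: tuple[float, float],
) -> HbSeries:
    """Invert the modified Beer-Lambert law channel by channel.

    Optical density change is -log10(I / I0) with I0 the mean intensity
    over the baseline interval; concentration changes come from the 2x2
    linear solve of the pathlength-scaled extinction system and are
    returned in uM.
    """
    sl = _interval_slice(*baseline, raw.dt, raw.n_samples)
    if sl.stop - sl.start < 1:
        raise ValueError("baseline interval lies outside the recording")
    bad = np.argwhere(raw.data <= 0)
    if bad.size:
        ch, wl, t = bad[0]
        raise ValueError(
            f"non-positive intensity at CH{ch + 1}, wavelength index {wl}, sample {t}"
        )
    i0 = raw.data[:, :, sl].mean(axis=2, keepdims=True)
    dod = -np.log10(raw.data / i0)  # (16, 2, T)
    Minv = np.linalg.inv(cfg.pathlength_matrix())
    conc_mM = np.einsum("cw,nwt->nct", Minv, dod)  # (16, 2, T): HbO2, HHb
    return HbSeries(
        subject_id=raw.subject_id,
        hbo=conc_mM[:, 0] * 1e3,
        hhb=conc_mM[:, 1] * 1e3,
        dt=raw.dt,
    )


def _butter_sos(cfg: PreprocessConfig, dt: float):
    return signal.butter(
        cfg.filter_order, (cfg.f_lo, cfg.f_hi), btype="bandpass", fs=1.0 / dt,
        output="sos",
    )


def bandpass_zero_phase(series: HbSeries, cfg: PreprocessConfig) -> HbSeries:
    """Forward-backward Butterworth band-pass (net phase shift zero).

    Edges are handled by reflecting roughly one impulse-response length
    (1 / f_lo seconds) of samples.  Series much shorter than that cannot
    be filtered meaningfully and raise.
    """
    cfg.validate(series.dt)
    sos = _butter_sos(cfg, series.dt)
    padlen = int(round(1.0 / (cfg.f_lo * series.dt)))
    if series.n_samples <= padlen:
        raise ValueError(
            f"series of {series.n_samples} samples is too short for the "
            f"{padlen}-sample reflection pad; record longer or pad the input"
        )
    out = replace(series)
    out.hbo = signal.sosfiltfilt(sos, series.hbo, axis=1, padtype="even", padlen=padlen)
    out.hhb = signal.sosfiltfilt(sos, series.hhb, axis=1, padtype="even", padlen=padlen)
    return out


def baseline_standardize(series: HbSeries, layout: SessionLayout,
                         mode: str = "mean") -> HbSeries:
    """Subtract each channel's pre-stimulus baseline mean (z-mode: / SD)."""
    sl = _interval_slice(*layout.baseline, series.dt, series.n_samples)
    if sl.stop - sl.start < 2:
        raise ValueError("baseline interval must contain at least 2 samples")
    out = replace(series)
    mu_o = series.hbo[:, sl].mean(axis=1, keepdims=True)
    mu_h = series.hhb[:, sl].mean(axis=1, keepdims=True)
    out.hbo = series.hbo - mu_o
    out.hhb = series.hhb - mu_h
    if mode == "z":
        sd_o = series.hbo[:, sl].std(axis=1, keepdims=True)
        sd_h = series.hhb[:, sl].std(axis=1, keepdims=True)
        if np.any(sd_o == 0) or np.any(sd_h == 0):
            raise ValueError("zero baseline SD; z-mode standardization undefined")
        out.hbo = out.hbo / sd_o
        out.hhb = out.hhb / sd_h
    elif mode != "mean":
        raise ValueError("mode must be 'mean' or 'z'")
    return out


def block_features(
    series: HbSeries,
    layout: SessionLayout,
    cfg: PreprocessConfig,
    group: str,
    mhe: bool = False,
) -> list[FeatureVector]:
    """Mean HbO2 per channel over each CIT block, onset window excluded."""
    vectors = []
    for cit, (start, end) in layout.blocks.items():
        if end - start <= cfg.onset_exclusion_s:
            raise ValueError(
                f"{cit} block ({end - start:.1f} s) is shorter than the "
                f"{cfg.onset_exclusion_s:.1f} s onset exclusion"
            )
        sl = _interval_slice(start + cfg.onset_exclusion_s, end, series.dt,
                             series.n_samples)
        x = series.hbo[:, sl].mean(axis=1)
        vectors.append(
            FeatureVector(subject_id=series.subject_id, group=group, cit_id=cit,
                          x=x, mhe=mhe)
        )
    return vectors


class FeatureTable:
    """Row-per-(subject, CIT) feature matrix with CL=+1 / HC=-1 encoding."""

    COLUMNS = ["subject_id", "group", "cit", *[c.lower() for c in CHANNELS]]

    def __init__(self, frame: pd.DataFrame):
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"feature table missing columns: {sorted(missing)}")
        dup = frame.duplicated(subset=["subject_id", "cit"])
        if dup.any():
            raise ValueError("duplicate (subject, cit) rows")
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def channels(self) -> tuple[str, ...]:
        return CHANNELS

    def X(self, subset: tuple[str, ...] | None = None) -> np.ndarray:
        cols = [c.lower() for c in (subset or CHANNELS)]
        return self.frame[cols].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return np.where(self.frame["group"].to_numpy() == "CL", 1, -1)

    @property
    def subjects(self) -> np.ndarray:
        return self.frame["subject_id"].to_numpy()

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        return cls(pd.read_csv(path))


def build_dataset(
    vectors: list[FeatureVector],
    include_cits: tuple[str, ...] = ("CIT1", "CIT2"),
) -> FeatureTable:
    """Assemble feature vectors into the classification table.

    CIT3 is excluded by default: the alternating-attention block proved
    too hard for the patient group, so its hemodynamics do not reflect a
    comparable cognitive load.  Pass all three CITs to keep every row.
    """
    if not include_cits:
        raise ValueError("include_cits must name at least one CIT")
    rows = []
    for v in vectors:
        if v.cit_id not in include_cits:
            continue
        rows.append(
            {"subject_id": v.subject_id, "group": v.group, "cit": v.cit_id,
             **{c.lower(): x for c, x in zip(CHANNELS, v.x)}}
        )
    if not rows:
        raise ValueError("no feature vectors match the requested CITs")
    frame = pd.DataFrame(rows).sort_values(["subject_id", "cit"]).reset_index(drop=True)
    return FeatureTable(frame)


def preprocess_session(
    series: HbSeries,
    layout: SessionLayout,
    cfg: PreprocessConfig,
    group: str,
    mhe: bool = False,
) -> list[FeatureVector]:
    """Filter, baseline-standardize and reduce one session to features."""
    filtered = bandpass_zero_phase(series, cfg)
    standardized = baseline_standardize(filtered, layout, mode=cfg.standardize_mode)
    return block_features(standardized, layout, cfg, group=group, mhe=mhe)
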