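"""Seeded synthetic fNIRS cohorts with planted, recoverable group structure.

The generator emulates the study conditions the analysis assumes: a
30-patient (CL, 10 of them flagged MHE) vs 25-control (HC) cohort, each
subject recorded through a 20-s baseline, three 18-trial CIT blocks with
20-s rests and a 20-s post-task window, at one sample per 0.65 s.

Each channel's signal is a block boxcar convolved with a delayed
double-gamma hemodynamic response function, plus physiological noise:
cardiac pulsation (injected on a fine time grid and decimated, so it
aliases exactly as a real recording would), ~0.1 Hz vasomotion, slow
linear drift with a random-walk component, and white noise.  The group
effect is an amplitude offset applied to the CL group on six channels --
CH6, CH7, CH10 respond more strongly, CH13, CH14, CH16 more weakly --
expressed in units of the between-subject response-amplitude SD so the
downstream effect size is interpretable.

Behavioural tables are drawn through a Gaussian copula: a per-subject
latent ability drives accuracy and digit-span scores up and reaction
time and number-connection times down, reproducing the observed
correlation sign structure, while every marginal is a moment-matched
truncated normal so the group means and SDs equal the configured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .preprocess import (
    CHANNELS,
    DT_DEFAULT,
    N_CHANNELS,
    HbSeries,
    MbllConfig,
    RawIntensitySeries,
    SessionLayout,
    _interval_slice,
)

__all__ = [
    "CohortSpec",
    "HrfSpec",
    "EffectSpec",
    "NoiseSpec",
    "BehaviorSpec",
    "SyntheticDataset",
    "hrf_kernel",
    "generate_session",
    "generate_cohort",
    "generate_behavior",
    "export_raw",
]

CIT_IDS = ("CIT1", "CIT2", "CIT3")


@dataclass(frozen=True)
class CohortSpec:
    n_cl: int = 30
    n_hc: int = 25
    n_mhe: int = 10  # informational sub-label within CL
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cl, self.n_hc, self.n_mhe) < 0:
            raise ValueError("cohort counts must be >= 0")
        if self.n_mhe > self.n_cl:
            raise ValueError("MHE subgroup cannot exceed the CL group")


@dataclass(frozen=True)
class HrfSpec:
    """Double-gamma HRF: response peak, undershoot peak, undershoot ratio.

    ``onset_delay_s`` shifts the whole kernel; patients with minimal
    hepatic encephalopathy show responses delayed by several seconds, so
    an alternative delay can be applied to MHE-flagged subjects.
    """

    peak_s: float = 6.0
    undershoot_s: float = 16.0
    ratio: float = 1.0 / 6.0
    onset_delay_s: float = 5.0
    mhe_onset_delay_s: float | None = None
    support_s: float = 32.0

    def delay_for(self, mhe: bool) -> float:
        if mhe and self.mhe_onset_delay_s is not None:
            return self.mhe_onset_delay_s
        return self.onset_delay_s


#: channels where the CL group responds more (+) or less (-) than HC
DEFAULT_EFFECT_SIGNS = {
    "CH6": +1.0, "CH7": +1.0, "CH10": +1.0,
    "CH13": -1.0, "CH14": -1.0, "CH16": -1.0,
}


@dataclass(frozen=True)
class EffectSpec:
    """CL-minus-HC response-amplitude offsets, in amplitude-SD units."""

    delta: float = 0.5
    signs: dict = field(default_factory=lambda: dict(DEFAULT_EFFECT_SIGNS))

    def __post_init__(self) -> None:
        for ch in self.signs:
            if ch not in CHANNELS:
                raise ValueError(f"unknown channel {ch!r}")
        if not np.isfinite(self.delta):
            raise ValueError("delta must be finite")

    def offsets(self) -> np.ndarray:
        out = np.zeros(N_CHANNELS)
        for ch, s in self.signs.items():
            out[CHANNELS.index(ch)] = s * self.delta
        return out


@dataclass(frozen=True)
class NoiseSpec:
    """Amplitudes and frequencies (Hz) of the signal and noise components.

    Amplitudes are in the generator's concentration units, fixed so that
    the baseline-standardized block features come out at order one --
    the scale the classifier's unit soft-margin penalty is calibrated
    to.  Relative magnitudes (noise vs. response amplitude) are what the
    preprocessing chain is exercised against.
    """

    cardiac_amp: float = 2.0
    cardiac_freq: float = 1.1
    cardiac_freq_jitter: float = 0.1
    vaso_amp: float = 1.5
    vaso_freq: float = 0.1
    vaso_freq_jitter: float = 0.02
    drift_span: float = 3.0  # max |linear drift| over the session
    walk_step: float = 0.02  # random-walk step SD per sample
    white_sd: float = 1.0
    base_amplitude: float = 5.0  # mean block-response amplitude
    subject_amp_sd: float = 2.0  # between-subject amplitude SD
    block_amp_sd: float = 1.0  # per-(block, channel) amplitude jitter
    channel_amp_sd: float = 0.5
    hhb_ratio: float = 0.35  # HHb = -ratio * HbO2 response + own noise

    def __post_init__(self) -> None:
        for name in ("cardiac_amp", "vaso_amp", "drift_span", "walk_step",
                     "white_sd", "subject_amp_sd", "block_amp_sd",
                     "channel_amp_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def amplitude_sd(self) -> float:
        """Reference within-group SD of the per-row response amplitude."""
        return float(np.hypot(self.subject_amp_sd, self.block_amp_sd))


def hrf_kernel(hrf: HrfSpec, dt: float, mhe: bool = False) -> np.ndarray:
    """Delayed double-gamma kernel, normalized to unit area.

    With unit area, convolving a long boxcar of amplitude a yields a
    plateau at a, so block amplitudes are in signal units.
    """
    delay = hrf.delay_for(mhe)
    t = np.arange(0.0, hrf.support_s + delay + dt, dt)
    ts = np.clip(t - delay, 0.0, None)
    peak = stats.gamma.pdf(ts, hrf.peak_s + 1.0, scale=1.0)
    under = stats.gamma.pdf(ts, hrf.undershoot_s + 1.0, scale=1.0)
    h = peak - hrf.ratio * under
    area = h.sum() * dt
    if area <= 0:
        raise ValueError("HRF kernel must integrate to a positive value")
    return h / area * dt  # discrete kernel: sum(h) == 1


def generate_session(
    subject_id: str,
    group: str,
    layout: SessionLayout,
    hrf: HrfSpec = HrfSpec(),
    effect: EffectSpec = EffectSpec(),
    noise: NoiseSpec = NoiseSpec(),
    seed: int | np.random.SeedSequence = 0,
    mhe: bool = False,
    dt: float = DT_DEFAULT,
) -> HbSeries:
    """Simulate one subject's 16-channel HbO2/HHb recording."""
    if group not in ("CL", "HC"):
        raise ValueError("group must be 'CL' or 'HC'")
    rng = np.random.default_rng(seed)
    n = int(round(layout.total_duration / dt))
    kernel = hrf_kernel(hrf, dt, mhe=mhe)

    offsets = effect.offsets() * noise.amplitude_sd if group == "CL" else np.zeros(N_CHANNELS)
    subj_jit = rng.normal(0.0, noise.subject_amp_sd)
    ch_jit = rng.normal(0.0, noise.channel_amp_sd, N_CHANNELS)

    stim = np.zeros((N_CHANNELS, n))
    for b, (start, end) in enumerate(layout.blocks.values()):
        if start < layout.baseline[1]:
            raise ValueError("CIT block overlaps the pre-stimulus baseline")
        sl = _interval_slice(start, end, dt, n)
        blk_jit = rng.normal(0.0, noise.block_amp_sd, N_CHANNELS)
        amp = noise.base_amplitude + offsets + subj_jit + ch_jit + blk_jit
        stim[:, sl] += amp[:, None]

    response = np.empty_like(stim)
    for c in range(N_CHANNELS):
        response[c] = np.convolve(stim[c], kernel)[:n]

    # cardiac pulsation on a fine grid, decimated without anti-aliasing so
    # it folds into the sampled band exactly as in a real recording
    fine = 8
    tf = np.arange(n * fine) * (dt / fine)
    f_card = noise.cardiac_freq + rng.uniform(-1, 1) * noise.cardiac_freq_jitter
    cardiac = (
        noise.cardiac_amp
        * np.sin(2 * np.pi * f_card * tf[None, :] + rng.uniform(0, 2 * np.pi, (N_CHANNELS, 1)))
    )[:, ::fine]

    t = np.arange(n) * dt
    f_vaso = noise.vaso_freq + rng.uniform(-1, 1, (N_CHANNELS, 1)) * noise.vaso_freq_jitter
    vaso = noise.vaso_amp * np.sin(2 * np.pi * f_vaso * t[None, :] + rng.uniform(0, 2 * np.pi, (N_CHANNELS, 1)))

    slope = rng.uniform(-1, 1, (N_CHANNELS, 1)) * noise.drift_span / max(t[-1], dt)
    drift = slope * t[None, :] + np.cumsum(rng.normal(0, noise.walk_step, (N_CHANNELS, n)), axis=1)

    white = rng.normal(0.0, noise.white_sd, (N_CHANNELS, n))

    hbo = response + cardiac + vaso + drift + white
    hhb = (
        -noise.hhb_ratio * response
        + rng.normal(0.0, 0.5 * noise.white_sd, (N_CHANNELS, n))
        - 0.3 * vaso
    )
    return HbSeries(subject_id=subject_id, hbo=hbo, hhb=hhb, dt=dt)


@dataclass
class SyntheticDataset:
    """Ground-truth-labelled cohort: sessions, layout, labels, behaviour."""

    sessions: list[HbSeries]
    layout: SessionLayout
    labels: pd.DataFrame  # subject_id, group, mhe
    behavior: pd.DataFrame
    effect: EffectSpec
    seed: int

    def session_for(self, subject_id: str) -> HbSeries:
        for s in self.sessions:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)


def generate_cohort(
    cohort: CohortSpec = CohortSpec(),
    layout: SessionLayout | None = None,
    hrf: HrfSpec = HrfSpec(),
    effect: EffectSpec = EffectSpec(),
    noise: NoiseSpec = NoiseSpec(),
    behavior: "BehaviorSpec | None" = None,
    dt: float = DT_DEFAULT,
) -> SyntheticDataset:
    """One seeded session per subject plus labels and behavioural table."""
    layout = layout or SessionLayout.default()
    behavior = behavior or BehaviorSpec()
    root = np.random.SeedSequence(cohort.seed)
    n_subj = cohort.n_cl + cohort.n_hc
    children = root.spawn(n_subj + 1)

    rows = []
    sessions = []
    idx = 0
    for g, count in (("CL", cohort.n_cl), ("HC", cohort.n_hc)):
        for i in range(count):
            sid = f"{g}{i + 1:02d}"
            mhe = g == "CL" and i < cohort.n_mhe
            sessions.append(
                generate_session(
                    sid, g, layout, hrf=hrf, effect=effect, noise=noise,
                    seed=children[idx], mhe=mhe, dt=dt,
                )
            )
            rows.append({"subject_id": sid, "group": g, "mhe": mhe})
            idx += 1
    labels = pd.DataFrame(rows)
    behav = generate_behavior(cohort, behavior, seed=children[-1])
    return SyntheticDataset(
        sessions=sessions, layout=layout, labels=labels, behavior=behav,
        effect=effect, seed=cohort.seed,
    )


# ---------------------------------------------------------------------------
# behavioural generator

#: (mean, SD) of accuracy and reaction time (ms) per group and CIT, the
#: observed group statistics used as generator defaults
ACCURACY_DEFAULTS = {
    ("CL", "CIT1"): (0.62, 0.30), ("CL", "CIT2"): (0.45, 0.23), ("CL", "CIT3"): (0.32, 0.21),
    ("HC", "CIT1"): (0.75, 0.28), ("HC", "CIT2"): (0.48, 0.25), ("HC", "CIT3"): (0.46, 0.26),
}
RT_DEFAULTS = {
    ("CL", "CIT1"): (8576.44, 816.34), ("CL", "CIT2"): (9595.72, 1154.55),
    ("CL", "CIT3"): (11139.09, 1490.87),
    ("HC", "CIT1"): (5799.34, 894.26), ("HC", "CIT2"): (6695.61, 1264.74),
    ("HC", "CIT3"): (6926.38, 1633.17),
}
#: nominal neurocognitive test levels (NCT in seconds, DST in span items);
#: the study reports only their correlations with CIT measures, so these
#: are plausible clinical values, not published statistics
TEST_DEFAULTS = {
    ("CL", "NCT-A"): (45.0, 14.0), ("HC", "NCT-A"): (32.0, 10.0),
    ("CL", "NCT-B"): (100.0, 30.0), ("HC", "NCT-B"): (75.0, 22.0),
    ("CL", "DST-Forward"): (5.5, 1.5), ("HC", "DST-Forward"): (6.5, 1.5),
    ("CL", "DST-Backward"): (3.5, 1.3), ("HC", "DST-Backward"): (4.5, 1.4),
}


@dataclass(frozen=True)
class BehaviorSpec:
    """Marginal (mean, SD) parameters plus the latent-ability coupling.

    ``coupling`` is the loading of each measure on a per-subject latent
    ability (accuracy and DST load positively, RT and NCT negatively),
    which induces the observed correlation signs.
    """

    accuracy: dict = field(default_factory=lambda: dict(ACCURACY_DEFAULTS))
    rt: dict = field(default_factory=lambda: dict(RT_DEFAULTS))
    tests: dict = field(default_factory=lambda: dict(TEST_DEFAULTS))
    coupling: float = 0.6

    def __post_init__(self) -> None:
        if not -1.0 < self.coupling < 1.0:
            raise ValueError("coupling must lie in (-1, 1)")
        for table in (self.accuracy, self.rt, self.tests):
            for m, s in table.values():
                if s <= 0:
                    raise ValueError("marginal SDs must be positive")


@lru_cache(maxsize=256)
def _matched_beta(mean: float, sd: float):
    """Beta distribution on [0, 1] with the requested mean and SD.

    Accuracy marginals are strongly skewed toward the scale edges (SDs
    approaching the Bernoulli bound), which no truncated normal on [0, 1]
    can reproduce; the Beta family covers every feasible (mean, SD).
    """
    var = sd * sd
    if not 0.0 < mean < 1.0 or var >= mean * (1.0 - mean):
        raise ValueError(f"(mean={mean}, sd={sd}) is infeasible on [0, 1]")
    nu = mean * (1.0 - mean) / var - 1.0
    return stats.beta(mean * nu, (1.0 - mean) * nu)


@lru_cache(maxsize=256)
def _matched_truncnorm(mean: float, sd: float, lo: float, hi: float):
    """Truncated-normal parameters whose truncated moments hit (mean, sd).

    Returns a frozen scipy distribution on [lo, hi] with the requested
    mean and SD (the parent normal is shifted/widened to compensate for
    the probability mass the truncation removes).
    """

    def make(mu, sigma):
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        return stats.truncnorm(a, b, loc=mu, scale=sigma)

    def residual(p):
        mu, log_sigma = p
        d = make(mu, np.exp(log_sigma))
        m, v = d.stats(moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    # no meaningful truncation: the identity parameters are exact
    if lo < mean - 8 * sd and hi > mean + 8 * sd:
        return make(mean, sd)
    sol = optimize.root(residual, x0=[mean, np.log(sd)], tol=1e-12)
    if not sol.success:
        raise RuntimeError(f"truncated-normal moment matching failed: {sol.message}")
    return make(sol.x[0], np.exp(sol.x[1]))


def _copula_draw(dist, z: np.ndarray, eps: np.ndarray, loading: float) -> np.ndarray:
    """Marginal-preserving draw correlated with the latent ability z."""
    u = loading * z + np.sqrt(1.0 - loading**2) * eps
    return dist.ppf(stats.norm.cdf(u))


def generate_behavior(
    cohort: CohortSpec,
    spec: BehaviorSpec = BehaviorSpec(),
    seed: int | np.random.SeedSequence | None = None,
) -> pd.DataFrame:
    """Behavioural table: one row per subject x CIT.

    Accuracy lies in [0, 1]; reaction times and NCT completion times are
    positive; DST spans are positive.  All marginals carry the configured
    group means/SDs; the shared latent ability yields negative
    accuracy-NCT and positive RT-NCT correlations.
    """
    rng = np.random.default_rng(cohort.seed if seed is None else seed)
    rho = spec.coupling
    rows = []
    for g, count in (("CL", cohort.n_cl), ("HC", cohort.n_hc)):
        z = rng.standard_normal(count)
        test_vals = {}
        for t in ("NCT-A", "NCT-B"):
            dist = _matched_truncnorm(*spec.tests[(g, t)], 0.0, np.inf)
            test_vals[t] = _copula_draw(dist, z, rng.standard_normal(count), -rho)
        for t in ("DST-Forward", "DST-Backward"):
            dist = _matched_truncnorm(*spec.tests[(g, t)], 0.0, np.inf)
            test_vals[t] = _copula_draw(dist, z, rng.standard_normal(count), rho)
        for cit in CIT_IDS:
            acc_dist = _matched_beta(*spec.accuracy[(g, cit)])
            rt_dist = _matched_truncnorm(*spec.rt[(g, cit)], 0.0, np.inf)
            acc = _copula_draw(acc_dist, z, rng.standard_normal(count), rho)
            rt = _copula_draw(rt_dist, z, rng.standard_normal(count), -rho)
            for i in range(count):
                rows.append(
                    {
                        "subject_id": f"{g}{i + 1:02d}", "group": g, "cit_id": cit,
                        "accuracy": acc[i], "rt_ms": rt[i],
                        **{t: test_vals[t][i] for t in test_vals},
                    }
                )
    return pd.DataFrame(rows).sort_values(["subject_id", "cit_id"]).reset_index(drop=True)


def export_raw(
    series: HbSeries,
    cfg: MbllConfig,
    baseline: tuple[float, float],
    i0: float = 1.0,
) -> RawIntensitySeries:
    """Forward Beer-Lambert model: Hb series -> two-wavelength intensities.

    Intensities are referenced to the baseline window so that
    :func:`citnirs.preprocess.mbll_convert` with the same baseline
    recovers the input exactly (up to the per-channel baseline constant
    that referencing removes).
    """
    M = cfg.pathlength_matrix()
    conc_mM = np.stack([series.hbo, series.hhb], axis=1) * 1e-3  # (16, 2, T)
    dod = np.einsum("wc,nct->nwt", M, conc_mM)
    sl = _interval_slice(*baseline, series.dt, series.n_samples)
    if sl.stop - sl.start < 1:
        raise ValueError("baseline interval lies outside the series")
    # reference so the baseline arithmetic-mean intensity is exactly i0
    ref = -np.log10(np.mean(10.0 ** (-dod[:, :, sl]), axis=2, keepdims=True))
    data = i0 * 10.0 ** (-(dod - ref))
    return RawIntensitySeries(
        subject_id=series.subject_id, data=data, dt=series.dt,
        wavelengths_nm=cfg.wavelengths_nm,
    )
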