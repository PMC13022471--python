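"""Synthetic resting-state cohorts with analytically known coherence.

The generative model is built so that band coherence has a closed form.
Each frequency band carries zero or more shared Gaussian sources, band
limited and unit variance; channel ``i`` receives source ``k`` with weight
``w_ik`` and adds independent band-limited noise whose per-band variance
follows a pink (1/f^alpha) envelope. Because source and noise are both
spectrally flat inside a band, the magnitude-squared coherence between
channels ``i`` and ``j`` is constant across the band and equals

    gamma2_ij = (sum_k w_ik w_jk)^2
                / ((sum_k w_ik^2 + nu_i) (sum_k w_jk^2 + nu_j))

with ``nu`` the in-band noise variance. This is the oracle every estimator
test checks against.

Group effects are planted as additive weight increments for high-excitability
(H-MEP) subjects on chosen (band, electrode-set) couplings. MEP-like EMG
trials are drawn per subject from group-specific log-normal amplitude
models; covariates are drawn group-matched so the cohort mimics an age-,
sex- and education-matched stratification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import Montage, Recording, default_montage, _canon
from .spectral_coherence import BandScheme, DEFAULT_BANDS

__all__ = [
    "CouplingSpec",
    "MEPModel",
    "CovariateModel",
    "SyntheticSpec",
    "GroundTruth",
    "CohortBundle",
    "generate_band_source",
    "true_coherence",
    "true_coherence_matrix",
    "weight_for_coherence",
    "generate_subject_eeg",
    "generate_mep_trials",
    "generate_cohort",
]


@dataclass(frozen=True)
class CouplingSpec:
    """One shared source: ``weight`` on every electrode in ``electrodes``
    within ``band`` (µV per unit source)."""

    band: str
    electrodes: tuple[str, ...]
    weight: float

    def __init__(self, band, electrodes, weight):
        object.__setattr__(self, "band", band)
        object.__setattr__(self, "electrodes", tuple(electrodes))
        object.__setattr__(self, "weight", float(weight))


@dataclass(frozen=True)
class MEPModel:
    """Log-normal MEP amplitude model (mV).

    Subject-level location is drawn N(mu_group, sigma_subject^2) on the log
    scale; per-trial amplitudes are log-normal around the subject location
    with sigma_trial. Defaults put the H location well above L, with the
    larger spread seen in high-excitability samples.
    """

    mu_l: float = -0.75
    mu_h: float = 0.33
    sigma_subject_l: float = 0.20
    sigma_subject_h: float = 0.30
    sigma_trial: float = 0.15
    n_trials: int = 15
    fs: float = 5000.0
    trace_len: float = 0.100        # s post-stimulus
    noise_sd: float = 0.01          # mV baseline EMG noise

    def location(self, group: str) -> tuple[float, float]:
        if group == "L-MEP":
            return self.mu_l, self.sigma_subject_l
        if group == "H-MEP":
            return self.mu_h, self.sigma_subject_h
        raise ValueError(f"unknown group {group!r}")


@dataclass(frozen=True)
class CovariateModel:
    """Group-wise covariate means/SDs; equal across groups by default except
    a small cMMSE shift (groups matched on age, sex, education; cognition
    subtly lower in the low-excitability group)."""

    age: tuple[float, float, float, float] = (68.3, 6.3, 67.4, 7.6)   # mL sL mH sH
    education: tuple[float, float, float, float] = (12.8, 3.2, 13.5, 2.8)
    cmmse: tuple[float, float, float, float] = (28.9, 1.2, 29.4, 1.0)
    grip: tuple[float, float, float, float] = (27.6, 9.7, 28.4, 8.4)
    male_prop: tuple[float, float] = (0.43, 0.49)                     # pL pH


@dataclass
class SyntheticSpec:
    """Full description of a synthetic cohort.

    Defaults mirror a realistic acquisition: 64-channel cap, 1000 Hz,
    5 minutes eyes-closed, pink background noise, a posterior alpha and a
    central beta coupling as the resting baseline, and no group effect.
    """

    n_subjects: int = 87
    montage: str | Montage = "64"
    fs_raw: float = 1000.0
    duration: float = 300.0
    scheme: BandScheme = field(default_factory=lambda: DEFAULT_BANDS)
    coupling: list[CouplingSpec] = field(default_factory=list)
    group_effect: list[CouplingSpec] = field(default_factory=list)
    noise_exponent: float = 1.0
    noise_variance: float = 100.0   # µV² per channel, integrated over spectrum
    sensor_noise_variance: float = 0.05  # µV² white floor across full bandwidth
    artifact_rate: float = 0.0      # probability a 2-s segment carries an artifact
    artifact_amplitude: float = 300.0  # µV
    mep: MEPModel = field(default_factory=MEPModel)
    covariates: CovariateModel = field(default_factory=CovariateModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.montage, str):
            self.montage = default_montage(self.montage)
        if not self.coupling:
            self.coupling = default_resting_coupling(self.montage, self)
        for c in self.coupling + self.group_effect:
            self.scheme[c.band]  # raises on unknown band
            for e in c.electrodes:
                self.montage.position(e)  # raises on unknown electrode
        if self.noise_variance <= 0:
            raise ValueError("noise variance must be positive")
        if self.duration * self.fs_raw < 2 * self.fs_raw:
            raise ValueError("duration too short for even one epoch")

    # -- noise bookkeeping ---------------------------------------------------

    def _noise_segments(self) -> list[tuple[float, float, float]]:
        """(lo, hi, variance) segments tiling ~the full spectrum with a pink
        envelope; scheme bands appear as their own segments so the in-band
        noise variance is exact."""
        edges: list[tuple[float, float]] = []
        lo0 = 0.5
        prev = lo0
        for b in self.scheme:
            if b.lo > prev:
                edges.append((prev, b.lo))
            edges.append((b.lo, b.hi))
            prev = b.hi
        # pink envelope stops at 64 Hz (or Nyquist); beyond it only the
        # broadband sensor floor remains, as in real amplifier noise
        top = min(self.fs_raw / 2, max(64.0, prev))
        if top > prev:
            edges.append((prev, top))
        a = self.noise_exponent
        if abs(a - 1.0) < 1e-12:
            weights = [np.log(hi / lo) for lo, hi in edges]
        else:
            weights = [(hi ** (1 - a) - lo ** (1 - a)) / (1 - a) for lo, hi in edges]
        total = sum(weights)
        return [(lo, hi, self.noise_variance * w / total)
                for (lo, hi), w in zip(edges, weights)]

    def inband_noise_variance(self, band: str) -> float:
        b = self.scheme[band]
        white = self.sensor_noise_variance * (b.hi - b.lo) / (self.fs_raw / 2)
        for lo, hi, v in self._noise_segments():
            if lo == b.lo and hi == b.hi:
                return v + white
        raise KeyError(f"band {band!r} not among noise segments")

    # -- effective weights ---------------------------------------------------

    def effective_coupling(self, group: str) -> list[CouplingSpec]:
        """Coupling list with the group effect folded in for H subjects."""
        if group in ("L-MEP", "unassigned"):
            return list(self.coupling)
        if group != "H-MEP":
            raise ValueError(f"unknown group {group!r}")
        out = list(self.coupling)
        for inc in self.group_effect:
            for i, c in enumerate(out):
                if c.band == inc.band and c.electrodes == inc.electrodes:
                    out[i] = CouplingSpec(c.band, c.electrodes,
                                          c.weight + inc.weight)
                    break
            else:
                out.append(inc)
        return out


def weight_for_coherence(gamma2: float, nu: float) -> float:
    """Source weight giving pair coherence ``gamma2`` between two channels
    that share one source symmetrically over in-band noise variance ``nu``.

    With equal weights w the pair coherence is (w²/(w²+nu))², so the
    required per-channel signal fraction is sqrt(gamma2).
    """
    if not 0 <= gamma2 < 1:
        raise ValueError("gamma2 must lie in [0, 1)")
    rho = np.sqrt(gamma2)
    return float(np.sqrt(nu * rho / (1.0 - rho)))


def default_resting_coupling(montage: Montage, spec: SyntheticSpec
                             ) -> list[CouplingSpec]:
    """Baseline eyes-closed pattern: posterior alpha coupling plus a weaker
    central beta coupling, at moderate coherence."""
    present = {_canon(l) for l in montage.labels}

    def pick(names):
        return tuple(n for n in names if _canon(n) in present)

    posterior = pick(montage.roi_scheme.get("Occipital", [])
                     + montage.roi_scheme.get("Parietal", []))
    central = pick(montage.roi_scheme.get("Central", []))
    out = []
    if len(posterior) >= 2:
        w1 = weight_for_coherence(0.40, spec.inband_noise_variance("Alpha 1"))
        w2 = weight_for_coherence(0.30, spec.inband_noise_variance("Alpha 2"))
        out.append(CouplingSpec("Alpha 1", posterior, w1))
        out.append(CouplingSpec("Alpha 2", posterior, w2))
    if len(central) >= 2:
        wb = weight_for_coherence(0.20, spec.inband_noise_variance("Beta 1"))
        out.append(CouplingSpec("Beta 1", central, wb))
    return out


# ---------------------------------------------------------------------------
# signal synthesis

def _band_bins(n: int, fs: float, lo: float, hi: float) -> np.ndarray:
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    sel = np.flatnonzero((freqs >= lo) & (freqs < hi) & (freqs > 0)
                         & (freqs < fs / 2))
    return sel


def _synth_from_bins(coefs: np.ndarray, bins: np.ndarray, n: int) -> np.ndarray:
    """Inverse-FFT synthesis from complex coefficients on selected rfft bins.

    ``coefs`` is (..., len(bins)) complex with unit variance per coefficient;
    the output time series has expected unit variance per unit coefficient
    scale when multiplied by n / sqrt(2 m).
    """
    shape = coefs.shape[:-1] + (n // 2 + 1,)
    X = np.zeros(shape, dtype=complex)
    X[..., bins] = coefs
    return np.fft.irfft(X, n=n, axis=-1)


def generate_band_source(duration: float, fs: float, band: tuple[float, float],
                         seed: int | np.random.Generator) -> np.ndarray:
    """Zero-mean, unit-variance signal with power confined to ``band``.

    Synthesised in the frequency domain: independent complex-Gaussian
    coefficients on the rfft bins inside [lo, hi), zero elsewhere, so the
    spectrum is exactly flat in band.
    """
    lo, hi = band
    if not 0 < lo < hi < fs / 2:
        raise ValueError(f"band ({lo}, {hi}) Hz outside (0, {fs / 2}) Nyquist")
    n = int(round(duration * fs))
    bins = _band_bins(n, fs, lo, hi)
    if bins.size == 0:
        raise ValueError("band contains no frequency bin at this duration")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = (rng.standard_normal(bins.size) + 1j * rng.standard_normal(bins.size))
    z *= 1.0 / np.sqrt(2.0)
    x = _synth_from_bins(z, bins, n)
    return x * (n / np.sqrt(2.0 * bins.size))


# ---------------------------------------------------------------------------
# analytic oracle

def _weight_matrix(spec: SyntheticSpec, band: str, group: str) -> np.ndarray:
    """Source-by-channel weight matrix for one band under one group."""
    labels = [_canon(l) for l in spec.montage.labels]
    idx = {l: i for i, l in enumerate(labels)}
    rows = []
    for c in spec.effective_coupling(group):
        if c.band != band:
            continue
        w = np.zeros(len(labels))
        for e in c.electrodes:
            w[idx[_canon(e)]] = c.weight
        rows.append(w)
    if not rows:
        return np.zeros((0, len(labels)))
    return np.vstack(rows)


def true_coherence_matrix(spec: SyntheticSpec, band: str,
                          group: str = "L-MEP") -> np.ndarray:
    """Closed-form band coherence matrix implied by the spec."""
    W = _weight_matrix(spec, band, group)
    nu = spec.inband_noise_variance(band)
    p = (W ** 2).sum(axis=0)            # per-channel source power
    c = W.T @ W                          # shared power
    denom = np.outer(p + nu, p + nu)
    gamma2 = c ** 2 / denom
    np.fill_diagonal(gamma2, 1.0)
    return gamma2


def true_coherence(spec: SyntheticSpec, pair: tuple[str, str], band: str,
                   group: str = "L-MEP") -> float:
    """Analytic band coherence for one electrode pair."""
    labels = [_canon(l) for l in spec.montage.labels]
    i = labels.index(_canon(pair[0]))
    j = labels.index(_canon(pair[1]))
    return float(true_coherence_matrix(spec, band, group)[i, j])


# ---------------------------------------------------------------------------
# subject-level generation

@dataclass
class GroundTruth:
    """Construction-time truth: per-group band coherence matrices, intended
    group labels, and the MEP model."""

    labels: list[str]
    coherence: dict[str, dict[str, np.ndarray]]   # group -> band -> matrix
    intended_group: list[str]
    subject_ids: list[str]
    mep: MEPModel

    def matrix(self, subject: str, band: str) -> np.ndarray:
        k = self.subject_ids.index(subject)
        return self.coherence[self.intended_group[k]][band]


def generate_subject_eeg(spec: SyntheticSpec, subject_index: int,
                         group: str = "L-MEP") -> Recording:
    """One subject's raw multi-channel recording (µV) at ``fs_raw``.

    Per-band shared sources mixed per the (group-effective) coupling, plus
    per-channel pink noise synthesised segment-wise so the in-band noise
    variance is exactly the value the coherence oracle assumes. Optional
    artifact segments add ±``artifact_amplitude`` µV frontal excursions on a
    2-s grid, recorded in ``meta['artifact_segments']``.
    """
    rng = np.random.default_rng([spec.seed, 11, subject_index])
    n = int(round(spec.duration * spec.fs_raw))
    labels = spec.montage.labels
    n_ch = len(labels)
    idx = {_canon(l): i for i, l in enumerate(labels)}

    # pink channel noise: complex coefficients scaled per segment, synthesised
    # only on the active bins; broadband sensor floor added in time domain
    segs = spec._noise_segments()
    active: list[np.ndarray] = []
    scales: list[np.ndarray] = []
    for lo, hi, var in segs:
        bins = _band_bins(n, spec.fs_raw, lo, hi)
        if bins.size:
            active.append(bins)
            scales.append(np.full(bins.size, n * np.sqrt(var / (2.0 * bins.size))))
    bins_all = np.concatenate(active)
    scale_all = np.concatenate(scales)
    z = (rng.standard_normal((n_ch, bins_all.size))
         + 1j * rng.standard_normal((n_ch, bins_all.size))) / np.sqrt(2.0)
    data = _synth_from_bins(z * scale_all, bins_all, n).T   # samples x channels
    if spec.sensor_noise_variance > 0:
        data += rng.normal(0.0, np.sqrt(spec.sensor_noise_variance),
                           size=data.shape)

    for c in spec.effective_coupling(group):
        b = spec.scheme[c.band]
        s = generate_band_source(spec.duration, spec.fs_raw, (b.lo, b.hi), rng)
        w = np.zeros(n_ch)
        for e in c.electrodes:
            w[idx[_canon(e)]] = c.weight
        data += np.outer(s, w)

    meta = {"synthetic": True, "group": group, "subject_index": subject_index}
    if spec.artifact_rate > 0:
        seg_len = int(round(2.0 * spec.fs_raw))
        n_seg = n // seg_len
        hit = np.flatnonzero(rng.random(n_seg) < spec.artifact_rate)
        bump_n = seg_len // 2
        bump = np.hanning(bump_n) * spec.artifact_amplitude
        n_front = max(1, n_ch // 3)
        for k in hit:
            start = k * seg_len + (seg_len - bump_n) // 2
            sign = rng.choice([-1.0, 1.0])
            data[start:start + bump_n, :n_front] += sign * bump[:, None]
        meta["artifact_segments"] = [int(k) for k in hit]
    return Recording(data=data, fs=spec.fs_raw, labels=list(labels), meta=meta)


def generate_mep_trials(group: str, mep: MEPModel,
                        seed: int | np.random.Generator
                        ) -> tuple[np.ndarray, tuple[float, float], np.ndarray]:
    """EMG-like MEP trials for one subject.

    Returns (trials x samples traces in mV, response window in s, the drawn
    per-trial peak-to-peak amplitudes). Each trace is baseline noise plus
    one biphasic deflection inside the response window whose peak-to-peak
    amplitude equals the drawn log-normal value.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mu, sigma_s = mep.location(group)
    mu_subject = rng.normal(mu, sigma_s)
    amps = np.exp(rng.normal(mu_subject, mep.sigma_trial, size=mep.n_trials))

    n = int(round(mep.trace_len * mep.fs))
    t = np.arange(n) / mep.fs
    onset, offset = 0.018, 0.042     # deflection support, inside 15-50 ms window
    shape = np.zeros(n)
    m = (t >= onset) & (t < offset)
    tau = (t[m] - onset) / (offset - onset)
    shape[m] = np.sin(2 * np.pi * tau) * np.hanning(m.sum())
    shape /= shape.max() - shape.min()

    traces = rng.normal(0.0, mep.noise_sd, size=(mep.n_trials, n))
    traces += amps[:, None] * shape[None, :]
    return traces, (0.015, 0.050), amps


@dataclass
class CohortBundle:
    """Everything one synthetic cohort provides downstream."""

    spec: SyntheticSpec
    recordings: list[Recording]
    mep_traces: list[np.ndarray]
    mep_window: tuple[float, float]
    cohort: pd.DataFrame
    ground_truth: GroundTruth


def generate_cohort(spec: SyntheticSpec) -> CohortBundle:
    """A full cohort: recordings, MEP trials, covariates and ground truth.

    Subjects are assigned intended groups (first half L-MEP, remainder
    H-MEP); realized MEP amplitudes are drawn from the group models, so a
    later median split on measured amplitude reproduces the intended labels
    except for rare borderline subjects. Covariates are drawn group-matched
    per the covariate model. The cohort table ships with group
    "unassigned" — stratification is the analysis's job, not the
    generator's.
    """
    from .preprocess import mep_amplitude

    if spec.n_subjects < 4:
        raise ValueError("need at least four subjects")
    n_l = spec.n_subjects // 2
    intended = ["L-MEP"] * n_l + ["H-MEP"] * (spec.n_subjects - n_l)
    ids = [f"S{k + 1:03d}" for k in range(spec.n_subjects)]

    recordings, traces_all, rows = [], [], []
    cov = spec.covariates
    window = (0.015, 0.050)
    for k, (sid, grp) in enumerate(zip(ids, intended)):
        recordings.append(generate_subject_eeg(spec, k, grp))
        rng = np.random.default_rng([spec.seed, 23, k])
        traces, window, _ = generate_mep_trials(grp, spec.mep, rng)
        traces_all.append(traces)
        amp, _ = mep_amplitude(traces, spec.mep.fs, window)
        g = 0 if grp == "L-MEP" else 1
        age = rng.normal(cov.age[2 * g], cov.age[2 * g + 1])
        edu = rng.normal(cov.education[2 * g], cov.education[2 * g + 1])
        cmmse = min(30.0, rng.normal(cov.cmmse[2 * g], cov.cmmse[2 * g + 1]))
        grip = max(5.0, rng.normal(cov.grip[2 * g], cov.grip[2 * g + 1]))
        sex = "M" if rng.random() < cov.male_prop[g] else "F"
        rows.append({"id": sid, "mep_amplitude": amp, "age": age, "sex": sex,
                     "education": edu, "cmmse": cmmse, "grip": grip,
                     "group": "unassigned"})
    cohort = pd.DataFrame(rows)

    coherence = {
        grp: {b.name: true_coherence_matrix(spec, b.name, grp)
              for b in spec.scheme}
        for grp in ("L-MEP", "H-MEP")
    }
    gt = GroundTruth(labels=list(spec.montage.labels), coherence=coherence,
                     intended_group=intended, subject_ids=ids, mep=spec.mep)
    return CohortBundle(spec=spec, recordings=recordings,
                        mep_traces=traces_all, mep_window=window,
                        cohort=cohort, ground_truth=gt)
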