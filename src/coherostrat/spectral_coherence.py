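"""Epoch-averaged cross-spectra and magnitude-squared coherence.

Coherence is estimated Welch-style with one 2-s epoch per segment: each
epoch is demeaned, Hann-tapered and Fourier transformed; cross- and
auto-spectra are averaged over epochs; magnitude-squared coherence is

    MSCoh_xy(f) = |G_xy(f)|^2 / (G_xx(f) G_yy(f))  in [0, 1].

Band values are unweighted means of MSCoh over the frequency bins falling
in each band, with half-open band edges [lo, hi) so adjacent bands never
share a bin (the top edge of the final band is inclusive).

With K averaged segments the estimator is biased upward for independent
signals by about 1/K, which is why a minimum of two segments is a hard
requirement and why downstream group comparisons use a common epoch count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import EpochedRecording

__all__ = [
    "Band",
    "BandScheme",
    "DEFAULT_BANDS",
    "CrossSpectra",
    "CoherenceSet",
    "cross_spectral_density",
    "mscoh",
    "band_average",
    "coherence_bands",
]


@dataclass(frozen=True)
class Band:
    name: str
    lo: float
    hi: float


@dataclass(frozen=True)
class BandScheme:
    """An ordered, non-overlapping set of frequency bands."""

    bands: tuple[Band, ...]

    def __post_init__(self) -> None:
        prev_hi = 0.0
        for b in self.bands:
            if not b.lo < b.hi:
                raise ValueError(f"band {b.name!r} has lo >= hi")
            if b.lo < prev_hi:
                raise ValueError(f"band {b.name!r} overlaps its predecessor")
            prev_hi = b.hi

    def __iter__(self):
        return iter(self.bands)

    def __len__(self) -> int:
        return len(self.bands)

    @property
    def names(self) -> list[str]:
        return [b.name for b in self.bands]

    def __getitem__(self, name: str) -> Band:
        for b in self.bands:
            if b.name == name:
                return b
        raise KeyError(f"unknown band {name!r}")

    @classmethod
    def from_tuples(cls, tuples) -> "BandScheme":
        return cls(tuple(Band(str(n), float(lo), float(hi)) for n, lo, hi in tuples))


DEFAULT_BANDS = BandScheme.from_tuples([
    ("Delta", 2, 4),
    ("Theta", 4, 8),
    ("Alpha 1", 8, 11),
    ("Alpha 2", 11, 13),
    ("Beta 1", 13, 20),
    ("Beta 2", 20, 30),
    ("Gamma", 30, 45),
])


@dataclass
class CrossSpectra:
    """Epoch-averaged cross-spectral matrices.

    ``G[k]`` is the Hermitian channels x channels cross-spectral matrix at
    ``freqs[k]``; diagonals hold the (real, non-negative) auto-spectra.
    ``K`` is the number of averaged epochs.
    """

    freqs: np.ndarray
    G: np.ndarray                   # freqs x channels x channels, complex
    K: int
    labels: list[str]
    window: str = "hann"

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("coherence undefined from a single segment")


@dataclass
class CoherenceSet:
    """Band-averaged coherence matrices for one subject.

    ``matrices[band]`` is symmetric with unit diagonal, entries in [0, 1].
    """

    matrices: dict[str, np.ndarray]
    labels: list[str]
    K: int
    scheme: BandScheme = field(default=DEFAULT_BANDS)

    def __getitem__(self, band: str) -> np.ndarray:
        return self.matrices[band]

    @property
    def bands(self) -> list[str]:
        return list(self.matrices)


def cross_spectral_density(ep: EpochedRecording,
                           fmax: float | None = None) -> CrossSpectra:
    """Welch cross-spectral estimate over the retained epochs.

    One segment per epoch (epochs are already disjoint), per-epoch
    demeaning, Hann taper, no within-epoch sub-segmentation. Frequency
    resolution is ``fs / samples_per_epoch`` — 0.5 Hz for 2-s epochs at
    512 Hz. Spectra carry the taper power normalisation so that summing
    the auto-spectrum recovers signal variance (Parseval). ``fmax``
    truncates the stored grid (band-pass-filtered data carry nothing
    meaningful above the filter edge).
    """
    K, n_ch, n_s = ep.data.shape
    if K < 2:
        raise ValueError("coherence undefined from a single segment")
    win = np.hanning(n_s)
    x = ep.data - ep.data.mean(axis=2, keepdims=True)
    X = np.fft.rfft(x * win, axis=2)            # epochs x channels x freqs
    freqs = np.fft.rfftfreq(n_s, d=1.0 / ep.fs)
    if fmax is not None:
        keep = freqs <= fmax
        freqs = freqs[keep]
        X = X[:, :, keep]
    norm = 1.0 / (np.sum(win ** 2) * ep.fs)     # PSD scaling (per-Hz density)
    Xf = np.ascontiguousarray(np.moveaxis(X, 2, 0))       # freqs x epochs x ch
    G = np.matmul(np.conj(np.swapaxes(Xf, 1, 2)), Xf) * (norm / K)
    return CrossSpectra(freqs=freqs, G=G, K=K, labels=list(ep.labels))


def mscoh(cs: CrossSpectra, guard: float = 1e-30) -> np.ndarray:
    """Frequency-resolved magnitude-squared coherence.

    Returns freqs x channels x channels real values in [0, 1] with unit
    diagonal. Frequencies where an auto-spectrum falls below ``guard``
    (µV²/Hz) raise rather than being clamped: a vanishing denominator means
    the band has no signal there and the ratio is meaningless.
    """
    auto = np.real(np.einsum("fcc->fc", cs.G))
    if np.any(auto < guard):
        f_bad = cs.freqs[np.any(auto < guard, axis=1)][0]
        raise ValueError(f"zero auto-spectrum at {f_bad:g} Hz")
    denom = auto[:, :, None] * auto[:, None, :]
    coh = np.abs(cs.G) ** 2 / denom
    # enforce exact symmetry/diagonal against rounding
    coh = 0.5 * (coh + np.swapaxes(coh, 1, 2))
    idx = np.arange(coh.shape[1])
    coh[:, idx, idx] = 1.0
    return np.clip(coh, 0.0, 1.0)


def band_average(coh: np.ndarray, freqs: np.ndarray,
                 scheme: BandScheme = DEFAULT_BANDS, labels: list[str] | None = None,
                 K: int = 2) -> CoherenceSet:
    """Average frequency-resolved coherence into band matrices.

    Bin selection is half-open ``lo <= f < hi``; the final band of the
    scheme includes its upper edge so the top frequency is not orphaned.
    """
    matrices: dict[str, np.ndarray] = {}
    last = scheme.bands[-1]
    for band in scheme:
        if band is last:
            sel = (freqs >= band.lo) & (freqs <= band.hi)
        else:
            sel = (freqs >= band.lo) & (freqs < band.hi)
        if not sel.any():
            raise ValueError(
                f"band {band.name!r} contains no frequency bin at this resolution"
            )
        matrices[band.name] = coh[sel].mean(axis=0)
    return CoherenceSet(matrices=matrices,
                        labels=list(labels) if labels else [],
                        K=K, scheme=scheme)


def coherence_bands(ep: EpochedRecording,
                    scheme: BandScheme = DEFAULT_BANDS,
                    fmax: float | None = None) -> CoherenceSet:
    """Convenience: epochs -> cross-spectra -> MSCoh -> band matrices."""
    cs = cross_spectral_density(ep, fmax=fmax)
    coh = mscoh(cs)
    return band_average(coh, cs.freqs, scheme, labels=cs.labels, K=cs.K)
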