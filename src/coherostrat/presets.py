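"""Ready-made study configurations for simulation experiments.

Two cohort families recur throughout the package's validation experiments:

* a *null* cohort — identical coupling in both groups, so any significant
  electrode pair is a false positive; and
* a *planted* cohort — the H-MEP group receives an additive coherence
  increment on the Temporal electrodes in the Alpha 2 and Beta 1 bands,
  emulating the excitability-linked connectivity differences the pipeline
  is designed to detect.

Both default to the reduced 19-channel montage and a scaled-down sampling
rate (128 Hz) that leaves the epoch count, 0.5 Hz spectral resolution, band
scheme, channel count and group sizes untouched, so repeated cohorts run in
seconds; the full-rate 64-channel configuration is the package default
elsewhere.
"""

from __future__ import annotations

from .io_formats import AnalysisConfig
from .synthetic_cohort import (CouplingSpec, SyntheticSpec,
                               weight_for_coherence)

__all__ = ["null_spec", "planted_temporal_spec", "fast_config"]


def null_spec(n_per_group: int = 40, seed: int = 0, fs: float = 128.0,
              duration: float = 200.0, montage: str = "19") -> SyntheticSpec:
    """Two groups drawn from one connectivity distribution (no effect)."""
    return SyntheticSpec(n_subjects=2 * n_per_group, montage=montage,
                         fs_raw=fs, duration=duration, seed=seed)


def planted_temporal_spec(n_per_group: int = 40, seed: int = 0,
                          base_gamma2: float = 0.2, delta_gamma2: float = 0.15,
                          fs: float = 128.0, duration: float = 200.0,
                          montage: str = "19",
                          bands: tuple[str, ...] = ("Alpha 2", "Beta 1")
                          ) -> SyntheticSpec:
    """Temporal-ROI coupling in ``bands`` at ``base_gamma2`` for L-MEP and
    ``base_gamma2 + delta_gamma2`` for H-MEP subjects."""
    spec = SyntheticSpec(n_subjects=2 * n_per_group, montage=montage,
                         fs_raw=fs, duration=duration, seed=seed)
    temporal = tuple(spec.montage.roi_scheme["Temporal"])
    for band in bands:
        nu = spec.inband_noise_variance(band)
        w0 = weight_for_coherence(base_gamma2, nu)
        w1 = weight_for_coherence(base_gamma2 + delta_gamma2, nu)
        spec.coupling.append(CouplingSpec(band, temporal, w0))
        spec.group_effect.append(CouplingSpec(band, temporal, w1 - w0))
    return spec


def fast_config(spec: SyntheticSpec, outdir: str = "results",
                seed: int | None = None) -> AnalysisConfig:
    """An AnalysisConfig whose conditioning chain matches ``spec``'s rate."""
    return AnalysisConfig(montage="19", target_fs=min(512.0, spec.fs_raw),
                          outdir=outdir,
                          seed=spec.seed if seed is None else seed)
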