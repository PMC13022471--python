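"""Total Coherence: per-electrode mean coherence and its global and
ROI-restricted averages.

For a band matrix C, the per-electrode value is the mean of that
electrode's coherence with every other electrode; Total Coherence (TotCoh)
is the mean of those per-electrode values, which by symmetry equals the
mean over all unordered electrode pairs. ROI TotCoh restricts the average
to pairs whose members both belong to the ROI; cross-ROI pairs and
electrodes outside every ROI contribute only to the global value.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_formats import Montage, _canon
from .spectral_coherence import CoherenceSet

__all__ = [
    "electrode_mean_coherence",
    "totcoh_global",
    "totcoh_roi",
    "totcoh_table",
    "ROI_SCOPES",
]

ROI_SCOPES = ["global", "Frontal", "Central", "Parietal", "Occipital", "Temporal"]


def _pair_mean(matrix: np.ndarray, idx: np.ndarray) -> float:
    sub = matrix[np.ix_(idx, idx)]
    m = len(idx)
    if m < 2:
        raise ValueError("need at least two electrodes for a pair mean")
    iu = np.triu_indices(m, k=1)
    return float(sub[iu].mean())


def electrode_mean_coherence(cs: CoherenceSet, band: str, electrode: str) -> float:
    """Mean coherence of one electrode with all other electrodes."""
    matrix = cs[band]
    canon = [_canon(l) for l in cs.labels]
    try:
        i = canon.index(_canon(electrode))
    except ValueError:
        raise KeyError(f"electrode {electrode!r} not in coherence matrix") from None
    row = np.delete(matrix[i], i)
    return float(row.mean())


def totcoh_global(cs: CoherenceSet, band: str) -> float:
    """Global TotCoh: mean per-electrode coherence, equal to the mean over
    all unordered pairs."""
    matrix = cs[band]
    n = matrix.shape[0]
    if n < 2:
        raise ValueError("TotCoh undefined for fewer than two channels")
    iu = np.triu_indices(n, k=1)
    return float(matrix[iu].mean())


def totcoh_roi(cs: CoherenceSet, band: str, roi: str, montage: Montage) -> float:
    """TotCoh over electrode pairs lying inside one ROI.

    Strict about coverage: every ROI electrode must be present in the
    coherence matrix (a silent drop would quietly change the pair set).
    """
    electrodes = montage.roi_electrodes(roi)
    canon = {_canon(l): i for i, l in enumerate(cs.labels)}
    idx = []
    for e in electrodes:
        ce = _canon(e)
        if ce not in canon:
            raise KeyError(f"ROI {roi!r} electrode {e!r} missing from coherence matrix")
        idx.append(canon[ce])
    return _pair_mean(cs[band], np.array(idx))


def totcoh_table(coherence_sets: dict[str, CoherenceSet], montage: Montage,
                 bands: list[str] | None = None) -> pd.DataFrame:
    """Long-format TotCoh table over subjects, bands and scopes.

    Columns: subject, band, scope (global or an ROI name), value, n_pairs.
    ``n_pairs`` is C(m, 2) for the m electrodes in scope, making the
    unequal ROI sizes visible downstream.
    """
    rows = []
    for subject, cs in coherence_sets.items():
        use_bands = bands if bands is not None else cs.bands
        n_all = len(cs.labels)
        for band in use_bands:
            rows.append({
                "subject": subject, "band": band, "scope": "global",
                "value": totcoh_global(cs, band),
                "n_pairs": n_all * (n_all - 1) // 2,
            })
            for roi, electrodes in montage.roi_scheme.items():
                m = len(electrodes)
                rows.append({
                    "subject": subject, "band": band, "scope": roi,
                    "value": totcoh_roi(cs, band, roi, montage),
                    "n_pairs": m * (m - 1) // 2,
                })
    return pd.DataFrame(rows, columns=["subject", "band", "scope", "value", "n_pairs"])
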