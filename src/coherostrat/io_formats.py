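"""Readers and writers for recordings, montages, cohort tables and results.

The package moves five kinds of payload across disk boundaries:

* multi-channel EEG/EMG recordings — EDF (clinical standard, read through
  :mod:`mne`) or a plain delimited text dialect,
* montages — electrode label to 2-D scalp position, plus named ROI lists,
* cohort tables — per-subject covariates and MEP amplitude,
* square coherence matrices with a label header,
* run configuration as YAML.

The delimited EEG dialect is one sidecar comment line ``# fs=<Hz>``, one
header line of channel labels, then one row per sample (tab or comma
separated), all values in microvolts.
"""

from __future__ import annotations

import hashlib
import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Recording",
    "Montage",
    "AnalysisConfig",
    "read_recording",
    "write_recording_delimited",
    "write_recording_edf",
    "read_montage",
    "write_montage",
    "default_montage",
    "read_cohort_table",
    "write_cohort_table",
    "read_matrix",
    "write_matrix",
    "write_results",
    "load_config",
    "save_config",
]

COHORT_COLUMNS = [
    "id", "mep_amplitude", "age", "sex", "education", "cmmse", "grip", "group",
]


def _canon(label: str) -> str:
    """Canonical channel-name form: stripped, case-folded.

    Vendor EDF headers drift in case and padding (``"FP1 "`` vs ``"Fp1"``);
    all label matching in the package goes through this form.
    """
    return label.strip().casefold()


@dataclass
class Recording:
    """A continuous multi-channel recording in microvolts.

    ``data`` is samples x channels; ``labels`` are the channel names in
    column order; ``meta`` carries free-form provenance (source path,
    filters applied, injected-artifact bookkeeping from the simulator).
    """

    data: np.ndarray
    fs: float
    labels: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a samples x channels matrix")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.labels) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[1]} channels"
            )
        canon = [_canon(l) for l in self.labels]
        if len(set(canon)) != len(canon):
            raise ValueError("duplicate channel labels")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite samples in recording")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def channel_index(self, label: str) -> int:
        canon = [_canon(l) for l in self.labels]
        try:
            return canon.index(_canon(label))
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None

    def copy_with(self, **kwargs) -> "Recording":
        return replace(self, **kwargs)


@dataclass
class Montage:
    """Electrode scalp-plane positions and the ROI scheme.

    ``positions`` maps label -> (x, y) in an azimuthal-equidistant scalp
    projection (vertex at the origin, nose toward +x). ``roi_scheme`` maps
    ROI name -> ordered electrode list; ROIs must be pairwise disjoint and
    reference only known labels. Electrodes outside every ROI take part in
    whole-head maps and global averages but in no ROI-restricted metric.
    """

    positions: dict[str, tuple[float, float]]
    roi_scheme: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        canon = [_canon(l) for l in self.positions]
        if len(set(canon)) != len(canon):
            raise ValueError("duplicate montage labels")
        known = set(canon)
        seen: dict[str, str] = {}
        for roi, electrodes in self.roi_scheme.items():
            for e in electrodes:
                ce = _canon(e)
                if ce not in known:
                    raise ValueError(f"ROI {roi!r} references unknown channel {e!r}")
                if ce in seen:
                    raise ValueError(
                        f"electrode {e!r} in both {seen[ce]!r} and {roi!r}"
                    )
                seen[ce] = roi

    @property
    def labels(self) -> list[str]:
        return list(self.positions)

    def roi_electrodes(self, roi: str) -> list[str]:
        try:
            return list(self.roi_scheme[roi])
        except KeyError:
            raise KeyError(f"unknown ROI {roi!r}") from None

    def position(self, label: str) -> tuple[float, float]:
        for lab, pos in self.positions.items():
            if _canon(lab) == _canon(label):
                return pos
        raise KeyError(f"channel {label!r} not in montage")


@dataclass
class AnalysisConfig:
    """Run configuration mirrored by the YAML config file."""

    montage: str = "64"                   # "64", "19", or a file path
    bands: list[tuple[str, float, float]] | None = None  # None -> default scheme
    target_fs: float = 512.0
    band_lo: float = 0.2
    band_hi: float = 47.0
    epoch_len: float = 2.0
    amp_thresh: float = 100.0             # µV
    z_thresh: float = 5.0
    min_clean: float = 180.0              # s
    fdr_q: float = 0.05
    alpha: float = 0.05
    t_variant: str = "pooled"
    posthoc_nominal_p: bool = True  # per-pair studentized-range tail probs
    seed: int = 0
    outdir: str = "results"

    def __post_init__(self) -> None:
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must lie in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


# ---------------------------------------------------------------------------
# recordings

def read_recording(path: str | Path, format: str | None = None) -> Recording:
    """Read an EEG/EMG recording from EDF or the delimited text dialect.

    ``format`` is ``"edf"`` or ``"delimited"``; when omitted it is inferred
    from the file suffix.
    """
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if format == "edf":
        return _read_edf(path)
    if format == "delimited":
        return _read_delimited(path)
    raise ValueError(f"unknown recording format {format!r}")


def _read_edf(path: Path) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data().T * 1e6  # mne uses volts internally
    return Recording(
        data=data,
        fs=float(raw.info["sfreq"]),
        labels=[str(ch) for ch in raw.ch_names],
        meta={"source": str(path), "format": "edf"},
    )


def _read_delimited(path: Path) -> Recording:
    fs = None
    header = None
    rows: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("fs="):
                    fs = float(body[3:])
                continue
            if header is None:
                header = line
            else:
                rows.append(line)
    if fs is None:
        raise ValueError(f"{path}: missing sampling rate ('# fs=<Hz>' header line)")
    if header is None:
        raise ValueError(f"{path}: no channel-label header line")
    sep = "\t" if "\t" in header else ","
    labels = [c.strip() for c in header.split(sep)]
    try:
        data = np.array(
            [[float(v) for v in row.split(sep)] for row in rows], dtype=float
        )
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric sample value ({exc})") from None
    if data.size == 0:
        data = data.reshape(0, len(labels))
    if data.shape[1] != len(labels):
        raise ValueError(f"{path}: row width does not match header")
    return Recording(data=data, fs=fs, labels=labels,
                     meta={"source": str(path), "format": "delimited"})


def write_recording_delimited(rec: Recording, path: str | Path,
                              fmt: str = "%.9g") -> Path:
    """Write a recording in the delimited text dialect (tab-separated)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs={rec.fs:g}\n")
        fh.write("\t".join(rec.labels) + "\n")
        np.savetxt(fh, rec.data, fmt=fmt, delimiter="\t")
    return path


def write_recording_edf(rec: Recording, path: str | Path) -> Path:
    """Write a recording as EDF (16-bit, per-channel physical scaling).

    A compact EDF writer covering the continuous-EEG subset of the format:
    one data record per second, all channels at the recording rate, physical
    units microvolts. Amplitudes quantize to 16 bits of the per-channel
    physical range, which is far below EEG noise floors.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_ch = rec.n_channels
    record_len = 1.0  # seconds per data record
    spr = fs          # samples per record per channel
    n_rec = rec.n_samples // spr
    if n_rec == 0:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    data = rec.data[: n_rec * spr]

    phys_min = np.floor(data.min(axis=0)) - 1.0
    phys_max = np.ceil(data.max(axis=0)) + 1.0
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((data - phys_min) * scale + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    def f(text: str, width: int) -> bytes:
        b = text.encode("ascii")
        if len(b) > width:
            raise ValueError(f"EDF header field too long: {text!r}")
        return b.ljust(width)

    header = b"".join([
        f("0", 8),
        f("X X X X", 80),                     # local patient id
        f("Startdate X coherostrat X X", 80), # local recording id
        f("01.01.00", 8), f("00.00.00", 8),
        f(str(256 + 256 * n_ch), 8),
        f("EDF", 44).replace(b"EDF", b"   ", 1),  # reserved: blank for EDF
        f(str(n_rec), 8),
        f(f"{record_len:g}", 8),
        f(str(n_ch), 4),
    ])
    header += b"".join(f(lab[:16], 16) for lab in rec.labels)
    header += b"".join(f("AgAgCl electrode", 80) for _ in range(n_ch))
    header += b"".join(f("uV", 8) for _ in range(n_ch))
    header += b"".join(f(f"{v:.8g}"[:8], 8) for v in phys_min)
    header += b"".join(f(f"{v:.8g}"[:8], 8) for v in phys_max)
    header += b"".join(f(str(dig_min), 8) for _ in range(n_ch))
    header += b"".join(f(str(dig_max), 8) for _ in range(n_ch))
    header += b"".join(f("", 80) for _ in range(n_ch))   # prefiltering
    header += b"".join(f(str(spr), 8) for _ in range(n_ch))
    header += b"".join(f("", 32) for _ in range(n_ch))   # reserved

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            block = digital[r * spr: (r + 1) * spr]   # spr x n_ch
            fh.write(block.T.tobytes())
    return path


# ---------------------------------------------------------------------------
# montages

def read_montage(path: str | Path) -> Montage:
    """Read a montage from a delimited file: label, x, y [, roi]."""
    path = Path(path)
    positions: dict[str, tuple[float, float]] = {}
    roi_scheme: dict[str, list[str]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            sep = "\t" if "\t" in line else ","
            parts = [p.strip() for p in line.split(sep)]
            if i == 0 and parts[0].casefold() == "label":
                continue
            label, x, y = parts[0], float(parts[1]), float(parts[2])
            if _canon(label) in {_canon(l) for l in positions}:
                raise ValueError(f"{path}: duplicate montage label {label!r}")
            positions[label] = (x, y)
            if len(parts) > 3 and parts[3]:
                roi_scheme.setdefault(parts[3], []).append(label)
    return Montage(positions=positions, roi_scheme=roi_scheme)


def write_montage(montage: Montage, path: str | Path) -> Path:
    path = Path(path)
    roi_of = {_canon(e): roi for roi, lst in montage.roi_scheme.items() for e in lst}
    with open(path, "w") as fh:
        fh.write("label\tx\ty\troi\n")
        for label, (x, y) in montage.positions.items():
            fh.write(f"{label}\t{x:.6f}\t{y:.6f}\t{roi_of.get(_canon(label), '')}\n")
    return path


def default_montage(name: str = "64") -> Montage:
    """Packaged montages: ``"64"`` (61 ROI electrodes + AFz/FT9/FT10
    unassigned) or ``"19"`` (reduced 10-20 set for fast end-to-end runs)."""
    if name not in {"64", "19"}:
        raise ValueError("default montages are '64' and '19'")
    res = importlib.resources.files("coherostrat.data") / f"montage{name}.tsv"
    with importlib.resources.as_file(res) as p:
        return read_montage(p)


# ---------------------------------------------------------------------------
# cohort tables

def read_cohort_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: cohort table missing columns {missing}")
    validate_cohort_table(df)
    return df


def validate_cohort_table(df: pd.DataFrame) -> None:
    if df["id"].duplicated().any():
        raise ValueError("duplicate subject ids in cohort table")
    if (df["mep_amplitude"] <= 0).any():
        raise ValueError("MEP amplitudes must be positive")
    bad = set(df["group"]) - {"L-MEP", "H-MEP", "unassigned"}
    if bad:
        raise ValueError(f"unknown group labels {sorted(bad)}")


def write_cohort_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, columns=[c for c in COHORT_COLUMNS
                                                    if c in df.columns])
    return path


# ---------------------------------------------------------------------------
# square labelled matrices

def write_matrix(matrix: np.ndarray, labels: Sequence[str],
                 path: str | Path) -> Path:
    """Write a square labelled matrix; full symmetric layout, 15 significant
    digits so round-trips are exact at double text precision."""
    matrix = np.asarray(matrix, dtype=float)
    n = len(labels)
    if matrix.shape != (n, n):
        raise ValueError("matrix shape does not match labels")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(labels) + "\n")
        for lab, row in zip(labels, matrix):
            fh.write(lab + "\t" + "\t".join(f"{v:.15g}" for v in row) + "\n")
    return path


def read_matrix(path: str | Path, atol: float = 1e-9
                ) -> tuple[np.ndarray, list[str]]:
    """Read a square labelled matrix; validates symmetry of the stored
    full-layout payload."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
        rows, row_labels = [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            row_labels.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    if row_labels != header:
        raise ValueError(f"{path}: row labels do not match column labels")
    m = np.array(rows, dtype=float)
    if not np.allclose(m, m.T, atol=atol):
        raise ValueError(f"{path}: stored matrix is not symmetric")
    return m, header


# ---------------------------------------------------------------------------
# results bundles

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_results(tables: Mapping[str, pd.DataFrame],
                  matrices: Mapping[str, tuple[np.ndarray, Sequence[str]]],
                  outdir: str | Path, overwrite: bool = False) -> pd.DataFrame:
    """Persist named tables (TSV) and labelled matrices; return the manifest.

    The manifest (also written to ``manifest.tsv``) lists every file with its
    SHA-256 content hash, so identical inputs produce identical manifests.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not outdir.is_dir():
        raise ValueError(f"output directory not writable: {outdir}")
    manifest_path = outdir / "manifest.tsv"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(
            f"manifest already present at {manifest_path}; pass overwrite=True"
        )
    entries = []
    for name, df in tables.items():
        p = outdir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False, float_format="%.12g")
        entries.append({"file": p.name, "kind": "table", "sha256": _sha256(p)})
    for name, (matrix, labels) in matrices.items():
        p = outdir / f"{name}.mat.tsv"
        write_matrix(matrix, labels, p)
        entries.append({"file": p.name, "kind": "matrix", "sha256": _sha256(p)})
    manifest = pd.DataFrame(entries, columns=["file", "kind", "sha256"])
    manifest.to_csv(manifest_path, sep="\t", index=False)
    return manifest


# ---------------------------------------------------------------------------
# config

def load_config(path: str | Path) -> AnalysisConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "bands" in raw and raw["bands"] is not None:
        raw["bands"] = [(str(n), float(lo), float(hi)) for n, lo, hi in raw["bands"]]
    return AnalysisConfig(**raw)


def save_config(config: AnalysisConfig, path: str | Path) -> Path:
    path = Path(path)
    payload = {k: (list(map(list, v)) if k == "bands" and v is not None else v)
               for k, v in vars(config).items()}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
    return path
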