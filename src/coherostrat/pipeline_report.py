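"""End-to-end orchestration and figure rendering.

``run_all`` drives the whole analysis on a synthetic cohort (or a directory
of recordings plus a cohort table): conditioning chain, band coherence,
Total Coherence, the group statistics, and the two figure types — the
four-panel topographic connectivity/significance maps and the ROI TotCoh
histograms. Every intermediate is persisted through :mod:`io_formats`, so
the results bundle is a pure function of (config, seed, input data).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.collections import LineCollection
from matplotlib.colors import LinearSegmentedColormap, Normalize, TwoSlopeNorm

from . import group_stats, network_metrics, preprocess
from .io_formats import (AnalysisConfig, Montage, Recording, default_montage,
                         read_cohort_table, read_montage, read_recording,
                         write_results, _canon)
from .spectral_coherence import (BandScheme, CoherenceSet, DEFAULT_BANDS,
                                 coherence_bands)
from .synthetic_cohort import CohortBundle, SyntheticSpec, generate_cohort

__all__ = [
    "RunManifest",
    "RunResults",
    "analyze",
    "run_all",
    "topo_connectivity_map",
    "totcoh_histograms",
    "group_mean_coherence",
]

_WHITE_RED = LinearSegmentedColormap.from_list("white_red",
                                               ["#ffffff", "#d62728"])


@dataclass
class RunManifest:
    """Provenance of one pipeline run."""

    config: dict
    seed: int
    files: pd.DataFrame          # file, kind, sha256
    stage_log: list[str]
    outdir: Path

    def save(self, path: str | Path | None = None) -> Path:
        path = Path(path) if path else self.outdir / "run_manifest.json"
        payload = {
            "config": self.config,
            "seed": self.seed,
            "files": self.files.to_dict(orient="records"),
            "stage_log": self.stage_log,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
        return path


def group_mean_coherence(sets: list[CoherenceSet], band: str) -> np.ndarray:
    """Arithmetic grand-average coherence matrix of one group."""
    return np.mean([cs[band] for cs in sets], axis=0)


def _load_cohort_dir(path: Path, montage: Montage
                     ) -> tuple[list[Recording], pd.DataFrame]:
    cohort = read_cohort_table(path / "cohort.tsv")
    recs = []
    for sid in cohort["id"]:
        for candidate in (path / f"{sid}.edf", path / f"{sid}.tsv"):
            if candidate.exists():
                recs.append(read_recording(candidate))
                break
        else:
            raise FileNotFoundError(f"no recording for subject {sid} in {path}")
    return recs, cohort


@dataclass
class RunResults:
    """In-memory products of one full analysis."""

    cohort: pd.DataFrame
    coh_sets: dict[str, CoherenceSet]
    montage: Montage
    scheme: BandScheme
    tests: "group_stats.PairwiseTestMap"
    sig_bands: list[str]
    totcoh: pd.DataFrame
    anova: pd.DataFrame
    posthoc: pd.DataFrame
    matching: pd.DataFrame
    stage_log: list[str]

    @property
    def significant_cells(self) -> set[tuple[str, str]]:
        """(ROI, band) cells with a Duncan-significant L-vs-H contrast."""
        return _significant_group_cells(self.posthoc)


def analyze(source: SyntheticSpec | CohortBundle | str | Path,
            config: AnalysisConfig | None = None) -> RunResults:
    """Run the complete analysis in memory.

    ``source`` is a :class:`SyntheticSpec` (the cohort is generated), an
    already generated :class:`CohortBundle`, or a directory holding
    ``cohort.tsv`` plus one recording per subject. Stages: preprocess ->
    coherence -> TotCoh -> stats. The ANOVA/Duncan stage runs on the bands
    with at least one FDR-significant electrode pair (the bands the pair
    maps single out); with fewer than two significant bands it is skipped
    and the post hoc table is empty.
    """
    config = config or AnalysisConfig()
    log: list[str] = []

    scheme = (BandScheme.from_tuples(config.bands) if config.bands
              else DEFAULT_BANDS)
    if isinstance(source, (str, Path)):
        montage = (default_montage(config.montage)
                   if config.montage in ("64", "19")
                   else read_montage(config.montage))
        recordings, cohort = _load_cohort_dir(Path(source), montage)
        log.append(f"loaded cohort of {len(cohort)} subjects from {source}")
    else:
        bundle = generate_cohort(source) if isinstance(source, SyntheticSpec) \
            else source
        montage = bundle.spec.montage
        recordings, cohort = bundle.recordings, bundle.cohort.copy()
        log.append(f"generated synthetic cohort of {len(cohort)} subjects "
                   f"(seed={bundle.spec.seed})")

    # --- preprocess + coherence, per subject
    coh_sets: dict[str, CoherenceSet] = {}
    for sid, rec in zip(cohort["id"], recordings):
        try:
            ep = preprocess.run_chain(
                rec, target_fs=config.target_fs, lo=config.band_lo,
                hi=config.band_hi, epoch_len=config.epoch_len,
                amp_thresh=config.amp_thresh, z_thresh=config.z_thresh,
                min_clean=config.min_clean)
        except ValueError as exc:
            raise RuntimeError(f"preprocess failed for subject {sid}: {exc}")
        log.append(f"{sid}: {ep.n_epochs} clean epochs, "
                   f"{len(ep.rejection_log)} rejected")
        coh_sets[sid] = coherence_bands(ep, scheme, fmax=config.band_hi + 5)

    # --- stratify and test
    cohort = group_stats.median_split(cohort)
    ids_l = cohort.loc[cohort["group"] == "L-MEP", "id"].tolist()
    ids_h = cohort.loc[cohort["group"] == "H-MEP", "id"].tolist()
    log.append(f"median split: {len(ids_l)} L-MEP / {len(ids_h)} H-MEP")
    coh_l = [coh_sets[s] for s in ids_l]
    coh_h = [coh_sets[s] for s in ids_h]
    tests = group_stats.pairwise_map_test(coh_l, coh_h, q=config.fdr_q,
                                          variant=config.t_variant)
    sig_bands = sorted(
        tests.table.loc[tests.table["significant"], "band"].unique(),
        key=scheme.names.index)
    n_sig = {b: int(tests.table.query("band == @b")["significant"].sum())
             for b in scheme.names}
    log.append("FDR-significant pairs per band: "
               + ", ".join(f"{b}={n_sig[b]}" for b in scheme.names))

    tot = network_metrics.totcoh_table(coh_sets, montage)

    anova_df = pd.DataFrame()
    posthoc = pd.DataFrame(columns=["cell_a", "cell_b", "span", "range",
                                    "critical_range", "significant",
                                    "p_nominal"])
    if len(sig_bands) >= 2:
        sub = tot[tot["band"].isin(sig_bands)]
        anova = group_stats.mixed_anova_totcoh(sub, cohort)
        anova_df = anova.table
        posthoc = group_stats.duncan_group_by_cell(
            sub, cohort, anova, alpha=config.alpha,
            nominal_p=config.posthoc_nominal_p)
        log.append("ANOVA bands: " + ", ".join(sig_bands))
    else:
        log.append("fewer than two FDR-significant bands; ANOVA skipped")

    demo = _matching_checks(cohort)

    return RunResults(cohort=cohort, coh_sets=coh_sets, montage=montage,
                      scheme=scheme, tests=tests, sig_bands=sig_bands,
                      totcoh=tot, anova=anova_df, posthoc=posthoc,
                      matching=demo, stage_log=log)


def run_all(source: SyntheticSpec | CohortBundle | str | Path,
            config: AnalysisConfig | None = None,
            figures: bool = True) -> RunManifest:
    """Run the complete pipeline and persist every product to
    ``config.outdir``; figures are rendered from the persisted tables."""
    config = config or AnalysisConfig()
    res = analyze(source, config)
    log = list(res.stage_log)
    tests, scheme, montage = res.tests, res.scheme, res.montage
    cohort = res.cohort
    coh_l = [res.coh_sets[s] for s in
             cohort.loc[cohort["group"] == "L-MEP", "id"]]
    coh_h = [res.coh_sets[s] for s in
             cohort.loc[cohort["group"] == "H-MEP", "id"]]
    n_sig = {b: int(tests.table.query("band == @b")["significant"].sum())
             for b in scheme.names}

    outdir = Path(config.outdir)
    matrices = {}
    for band in scheme.names:
        safe = band.replace(" ", "")
        matrices[f"coh_mean_L_{safe}"] = (
            group_mean_coherence(coh_l, band), tests.labels)
        matrices[f"coh_mean_H_{safe}"] = (
            group_mean_coherence(coh_h, band), tests.labels)
    fdr_table = pd.DataFrame(
        {"band": list(tests.p_fdr), "p_fdr": list(tests.p_fdr.values()),
         "n_significant": [n_sig[b] for b in tests.p_fdr]})
    files = write_results(
        tables={"cohort": cohort, "pair_tests": tests.table,
                "fdr_thresholds": fdr_table, "totcoh": res.totcoh,
                "anova": res.anova, "posthoc": res.posthoc,
                "matching": res.matching},
        matrices=matrices, outdir=outdir, overwrite=True)

    if figures:
        # render from the persisted tables so figure/table agreement is
        # structural, not a property of this process's memory
        from .io_formats import read_matrix
        pair_tests = pd.read_csv(outdir / "pair_tests.tsv", sep="\t")
        tot = pd.read_csv(outdir / "totcoh.tsv", sep="\t")
        posthoc = pd.read_csv(outdir / "posthoc.tsv", sep="\t") \
            if (outdir / "posthoc.tsv").stat().st_size else res.posthoc
        persisted = group_stats.PairwiseTestMap(
            table=pair_tests, p_fdr=dict(tests.p_fdr), q=config.fdr_q,
            labels=list(tests.labels))
        for band in (res.sig_bands or scheme.names[:1]):
            safe = band.replace(" ", "")
            mean_l, _ = read_matrix(outdir / f"coh_mean_L_{safe}.mat.tsv")
            mean_h, _ = read_matrix(outdir / f"coh_mean_H_{safe}.mat.tsv")
            topo_connectivity_map(mean_l, mean_h, persisted, montage, band,
                                  outdir / f"map_{safe}.png")
        cohort_persisted = pd.read_csv(outdir / "cohort.tsv", sep="\t")
        totcoh_histograms(tot, cohort_persisted, posthoc,
                          outdir / "totcoh_hist.png",
                          bands=res.sig_bands or None)
        log.append("figures rendered")

    manifest = RunManifest(config=vars(config).copy(), seed=config.seed,
                           files=files, stage_log=log, outdir=outdir)
    manifest.save()
    return manifest


def _matching_checks(cohort: pd.DataFrame) -> pd.DataFrame:
    """Between-group checks on covariates: t-tests for the continuous ones,
    chi-square for sex."""
    a = cohort[cohort["group"] == "L-MEP"]
    b = cohort[cohort["group"] == "H-MEP"]
    rows = []
    for col in ("age", "education", "mep_amplitude", "cmmse", "grip"):
        t, df, p = group_stats.t_test_two_sample(a[col], b[col])
        rows.append({"measure": col, "statistic": t, "df": df, "p": p,
                     "test": "t"})
    table = [[int((a["sex"] == "M").sum()), int((a["sex"] == "F").sum())],
             [int((b["sex"] == "M").sum()), int((b["sex"] == "F").sum())]]
    try:
        chi2, p = group_stats.chi_square_2x2(table)
        rows.append({"measure": "sex", "statistic": chi2, "df": 1, "p": p,
                     "test": "chi2"})
    except ValueError:
        pass
    return pd.DataFrame(rows, columns=["measure", "statistic", "df", "p", "test"])


# ---------------------------------------------------------------------------
# figures

def _positions(montage: Montage, labels: list[str]) -> np.ndarray:
    return np.array([montage.position(l) for l in labels])


def _head_outline(ax, pos: np.ndarray) -> None:
    r = 1.12 * np.max(np.hypot(pos[:, 0], pos[:, 1]))
    circle = plt.Circle((0, 0), r, fill=False, lw=1.2, color="black")
    ax.add_patch(circle)
    ax.plot([0.08 * r, 0, -0.08 * r], [0.98 * r, 1.12 * r, 0.98 * r],
            color="black", lw=1.2)      # nose marker
    ax.set_xlim(-1.3 * r, 1.3 * r)
    ax.set_ylim(-1.3 * r, 1.3 * r)
    ax.set_aspect("equal")
    ax.axis("off")


def _pair_segments(pos: np.ndarray) -> tuple[np.ndarray, list[tuple[int, int]]]:
    n = len(pos)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    segs = np.array([[pos[i], pos[j]] for i, j in pairs])
    return segs, pairs

def _draw_pairs(ax, pos, values, cmap, norm, alpha_by_value=True):
    segs, pairs = _pair_segments(pos)
    vals = np.asarray(values, dtype=float)
    colors = cmap(norm(vals))
    if alpha_by_value:
        v01 = np.clip(norm(vals), 0, 1)
        colors[:, 3] = 0.15 + 0.85 * v01     # keep dense montages legible
    lc = LineCollection(segs, colors=colors, linewidths=0.8)
    ax.add_collection(lc)
    ax.scatter(pos[:, 0], pos[:, 1], s=6, c="black", zorder=3)


def topo_connectivity_map(mean_l: np.ndarray, mean_h: np.ndarray,
                          tests: "group_stats.PairwiseTestMap",
                          montage: Montage, band: str,
                          path: str | Path, neutral: str = "#ffef9f"
                          ) -> Path:
    """Four-panel topographic map for one band.

    Panels, left to right: group-mean coherence of L-MEP and H-MEP (fixed
    white-to-red scale over [0, 1]); the signed difference L - H (blue
    negative, red positive, through a neutral colour at zero); and the
    FDR-corrected significance map (white to red with p = 0.05 at the scale
    midpoint; the scale spans p in [0, 0.1]).
    """
    sub = tests.table[tests.table["band"] == band]
    if sub.empty:
        raise ValueError(f"band {band!r} absent from the pairwise test map")
    labels = tests.labels
    pos = _positions(montage, labels)
    _, pairs = _pair_segments(pos)
    lab_idx = {_canon(l): i for i, l in enumerate(labels)}
    pair_row = {}
    for row in sub.itertuples():
        pair_row[(lab_idx[_canon(row.ch_i)], lab_idx[_canon(row.ch_j)])] = row
    coh_l = np.array([mean_l[i, j] for i, j in pairs])
    coh_h = np.array([mean_h[i, j] for i, j in pairs])
    diff = coh_l - coh_h
    p_raw = np.array([pair_row[p].p_raw for p in pairs])

    fig, axes = plt.subplots(1, 4, figsize=(14, 3.6))
    norm01 = Normalize(0.0, 1.0)
    for ax, vals, title in ((axes[0], coh_l, "L-MEP"),
                            (axes[1], coh_h, "H-MEP")):
        _head_outline(ax, pos)
        _draw_pairs(ax, pos, vals, _WHITE_RED, norm01)
        ax.set_title(f"{title}  {band}")
    fig.colorbar(plt.cm.ScalarMappable(norm=norm01, cmap=_WHITE_RED),
                 ax=axes[1], fraction=0.046)

    span = max(np.abs(diff).max(), 1e-12)
    diff_cmap = LinearSegmentedColormap.from_list(
        "diff", ["#1f3fbf", neutral, "#d62728"])
    diff_norm = TwoSlopeNorm(vmin=-span, vcenter=0.0, vmax=span)
    _head_outline(axes[2], pos)
    _draw_pairs(axes[2], pos, diff, diff_cmap, diff_norm, alpha_by_value=False)
    axes[2].set_title("difference L - H")
    fig.colorbar(plt.cm.ScalarMappable(norm=diff_norm, cmap=diff_cmap),
                 ax=axes[2], fraction=0.046)

    # significance: map p in [0, 0.1] onto red (strong) .. white, 0.05 centred
    sig_strength = np.clip((0.1 - p_raw) / 0.1, 0.0, 1.0)
    _head_outline(axes[3], pos)
    _draw_pairs(axes[3], pos, sig_strength, _WHITE_RED, norm01)
    thr = tests.p_fdr.get(band, 0.0)
    axes[3].set_title(f"significance (p_FDR = {thr:.4g})")
    fig.colorbar(plt.cm.ScalarMappable(norm=norm01, cmap=_WHITE_RED),
                 ax=axes[3], fraction=0.046)

    path = Path(path)
    fig.savefig(path, dpi=150, metadata=_fig_metadata(path))
    plt.close(fig)
    return path


def totcoh_histograms(tot: pd.DataFrame, groups, posthoc: pd.DataFrame,
                      path: str | Path, bands: list[str] | None = None
                      ) -> Path:
    """Grouped ROI TotCoh bars: L-MEP blue, H-MEP red, standard-error
    whiskers, an asterisk over each ROI x band cell whose L-vs-H contrast
    is significant in the Duncan table."""
    if isinstance(groups, pd.DataFrame):
        gmap = dict(zip(groups["id"], groups["group"]))
    else:
        gmap = dict(groups)
    df = tot[tot["scope"] != "global"].copy()
    df["grp"] = df["subject"].map(gmap)
    if bands is None:
        bands = list(df["band"].unique())
    rois = [r for r in network_metrics.ROI_SCOPES[1:]
            if r in set(df["scope"])]
    if len(rois) < len(set(df["scope"])):
        missing = set(df["scope"]) - set(rois)
        rois += sorted(missing)

    sig_cells = _significant_group_cells(posthoc)

    fig, axes = plt.subplots(1, max(len(bands), 1),
                             figsize=(4.2 * max(len(bands), 1), 3.4),
                             squeeze=False)
    for ax, band in zip(axes[0], bands):
        sub = df[df["band"] == band]
        x = np.arange(len(rois))
        width = 0.38
        tops = []
        for off, grp, color in ((-width / 2, "L-MEP", "#1f77b4"),
                                (width / 2, "H-MEP", "#d62728")):
            g = sub[sub["grp"] == grp].groupby("scope")["value"]
            means = g.mean().reindex(rois)
            sems = g.sem().reindex(rois)
            ax.bar(x + off, means, width, yerr=sems, color=color, capsize=2,
                   label=grp, error_kw={"lw": 0.8})
            tops.append((means + sems.fillna(0)).to_numpy())
        top = np.nanmax(tops, axis=0)
        for i, roi in enumerate(rois):
            if (roi, band) in sig_cells:
                ax.text(i, top[i] * 1.02, "*", ha="center", fontsize=14)
        ax.set_xticks(x)
        ax.set_xticklabels(rois, rotation=30, ha="right")
        ax.set_ylabel("TotCoh")
        ax.set_title(band)
    axes[0][0].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150, metadata=_fig_metadata(path))
    plt.close(fig)
    return path


def _significant_group_cells(posthoc: pd.DataFrame) -> set[tuple[str, str]]:
    """(roi, band) cells whose L-vs-H pair is Duncan-significant."""
    cells = set()
    if posthoc is None or posthoc.empty:
        return cells
    for row in posthoc.itertuples():
        try:
            ga, ra, ba = row.cell_a.split("|")
            gb, rb, bb = row.cell_b.split("|")
        except ValueError:
            continue
        if ra == rb and ba == bb and ga != gb and row.significant:
            cells.add((ra, ba))
    return cells


def _fig_metadata(path: Path) -> dict:
    """Scrub volatile metadata so identical inputs give identical bytes."""
    if path.suffix.lower() == ".png":
        return {"Software": None}
    if path.suffix.lower() == ".svg":
        return {"Date": None}
    return {}
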