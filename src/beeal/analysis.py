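"""Representation analyses: LFP, binned counts, correlations, PCA,
uniqueness index and the contrast-enhancement regression.

The population representation of an odor in one trial is the PN x time-bin
matrix of spike counts over the 500 ms stimulation window (100 ms bins for
correlation analysis, 40 ms for PCA trajectories), normalized by the
trial's grand sum.  Between-representation similarity is the Pearson
correlation of the two PN population vectors within each time bin,
averaged over bins (zero-variance bins are skipped and counted rather
than imputed); callers additionally average over trials and odor pairs.

Contrast enhancement is quantified per percept unit: the uniqueness index
UI = (act_rew - act_hab) / act_hab from naive activations, the fractional
change in activity of the rewarded-odor response after differential
conditioning, and the OLS regression of change on UI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RepresentationMatrix", "ContrastResult", "lfp", "binned_counts",
    "representation_correlation", "matrix_correlation", "pca_trajectory",
    "uniqueness_index", "change_in_activity", "contrast_regression",
    "percept_activations", "pairwise_panel_correlation",
]


@dataclass
class RepresentationMatrix:
    counts: np.ndarray  # (n_pn, n_bins), normalized
    bin_ms: float
    window: tuple  # (t0, t1) of the stimulation period
    raw_total: int  # spike count before normalization


@dataclass
class ContrastResult:
    ui: np.ndarray
    change: np.ndarray
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_units: int


def lfp(voltages: np.ndarray, n_pn: int) -> np.ndarray:
    """Local field potential: pointwise mean of PN membrane voltages."""
    v = np.asarray(voltages, dtype=float)
    if v.ndim != 2 or v.shape[1] < 1 or n_pn < 1:
        raise ValueError("need at least one PN voltage trace")
    return v[:, :n_pn].mean(axis=1)


def binned_counts(record, bin_ms: float = 100.0, window=None,
                  normalize: str = "grand_sum") -> RepresentationMatrix:
    """Per-PN, per-bin spike counts over the stimulation window.

    ``normalize="grand_sum"`` divides by the trial's total in-window count
    (rate normalization); ``"none"`` leaves raw counts.  The bin width
    must tile the window exactly.
    """
    if window is None:
        window = (0.0, record.duration_ms)
    t0, t1 = window
    span = t1 - t0
    if bin_ms > span:
        raise ValueError("bin is larger than the analysis window")
    n_bins = int(round(span / bin_ms))
    if abs(n_bins * bin_ms - span) > 1e-9:
        raise ValueError("bin width must divide the window length")
    edges = t0 + bin_ms * np.arange(n_bins + 1)
    counts = np.zeros((record.n_pn, n_bins))
    for i, s in enumerate(record.pn_spikes()):
        counts[i], _ = np.histogram(s, bins=edges)
    total = int(counts.sum())
    if normalize == "grand_sum" and total > 0:
        counts = counts / total
    elif normalize not in ("grand_sum", "none"):
        raise ValueError(f"unknown normalization {normalize!r}")
    return RepresentationMatrix(counts=counts, bin_ms=bin_ms, window=(t0, t1),
                                raw_total=total)


def matrix_correlation(a: np.ndarray, b: np.ndarray):
    """Bin-averaged Pearson correlation of two PN x bin matrices.

    Returns ``(correlation, n_skipped)`` where zero-variance bins in
    either matrix are excluded from the average.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("representation shapes differ")
    vals = []
    skipped = 0
    for k in range(a.shape[1]):
        x, y = a[:, k], b[:, k]
        if x.std() == 0.0 or y.std() == 0.0:
            skipped += 1
            continue
        vals.append(np.corrcoef(x, y)[0, 1])
    if not vals:
        return np.nan, skipped
    return float(np.mean(vals)), skipped


def representation_correlation(rec_a, rec_b, bin_ms: float = 100.0,
                               window=None, warn_skipped: bool = False) -> float:
    """Correlation between two trials' PN representations (bin-averaged)."""
    ma = binned_counts(rec_a, bin_ms, window)
    mb = binned_counts(rec_b, bin_ms, window)
    corr, skipped = matrix_correlation(ma.counts, mb.counts)
    if skipped and warn_skipped:
        warnings.warn(f"{skipped} zero-variance bins skipped", stacklevel=2)
    return corr


def pairwise_panel_correlation(panel: dict, names_a, names_b,
                               bin_ms: float = 100.0, window=None) -> float:
    """Mean correlation over all cross pairs of two odor groups.

    ``panel`` maps odor name -> list of SpikeRecords (as produced by
    ``run_test_panel``); every (trial of a, trial of b) pair contributes.
    """
    vals = []
    for na in names_a:
        for nb in names_b:
            if na == nb:
                continue
            for ra in panel[na]:
                for rb in panel[nb]:
                    c = representation_correlation(ra, rb, bin_ms, window)
                    if np.isfinite(c):
                        vals.append(c)
    return float(np.mean(vals)) if vals else np.nan


def pca_trajectory(records, bin_ms: float = 40.0, n_components: int = 2,
                   window=None):
    """PCA of pooled PN x bin population vectors across trials.

    Returns ``(trajectories, explained_variance_ratio)`` where
    trajectories is a list of (n_bins, n_components) arrays, one per
    record, in input order.
    """
    from sklearn.decomposition import PCA

    mats = [binned_counts(r, bin_ms, window, normalize="none").counts.T
            for r in records]
    pooled = np.concatenate(mats, axis=0)
    if n_components > pooled.shape[1]:
        raise ValueError("n_components exceeds the PN count")
    if pooled.shape[0] < 2:
        raise ValueError("need at least two time bins in total")
    pca = PCA(n_components=n_components)
    pca.fit(pooled)
    return [pca.transform(m) for m in mats], pca.explained_variance_ratio_


def percept_activations(records, n_percepts: int, window) -> np.ndarray:
    """Mean PN firing rate (Hz) per percept block over the window.

    ``records`` is a list of SpikeRecords of the same network; rates are
    averaged over trials and over each percept's PN block.
    """
    from .odors import tile_percepts

    t0, t1 = window
    dur_s = (t1 - t0) / 1000.0
    recs = list(records)
    n_pn = recs[0].n_pn
    percepts = tile_percepts(n_pn, n_percepts)
    rates = np.zeros(n_percepts)
    for rec in recs:
        counts = rec.counts_in_window(t0, t1)[:n_pn] / dur_s
        for p in percepts:
            rates[p.id] += counts[p.lo:p.hi].mean()
    return rates / len(recs)


def uniqueness_index(act_rew_naive, act_hab_naive) -> np.ndarray:
    """UI = (act_rew - act_hab) / act_hab per unit; NaN where undefined."""
    rew = np.asarray(act_rew_naive, dtype=float)
    hab = np.asarray(act_hab_naive, dtype=float)
    if rew.shape != hab.shape:
        raise ValueError("activation vectors must have equal length")
    with np.errstate(divide="ignore", invalid="ignore"):
        ui = (rew - hab) / hab
    ui[hab <= 0] = np.nan
    return ui


def change_in_activity(act_rew_trained, act_rew_naive) -> np.ndarray:
    """(trained - naive)/naive per unit; NaN where naive activation is 0."""
    tr = np.asarray(act_rew_trained, dtype=float)
    nv = np.asarray(act_rew_naive, dtype=float)
    if tr.shape != nv.shape:
        raise ValueError("activation vectors must have equal length")
    with np.errstate(divide="ignore", invalid="ignore"):
        ch = (tr - nv) / nv
    ch[nv <= 0] = np.nan
    return ch


def contrast_regression(ui, change) -> ContrastResult:
    """OLS of change-in-activity on uniqueness index.

    Units with undefined UI or change (NaN) are excluded; at least three
    valid units are required.  The p value is the two-sided t test on the
    slope.
    """
    from scipy import stats

    ui = np.asarray(ui, dtype=float)
    change = np.asarray(change, dtype=float)
    if ui.shape != change.shape:
        raise ValueError("UI and change vectors must have equal length")
    ok = np.isfinite(ui) & np.isfinite(change)
    if ok.sum() < 3:
        raise ValueError("need at least 3 valid units for the regression")
    res = stats.linregress(ui[ok], change[ok])
    return ContrastResult(
        ui=ui, change=change, slope=float(res.slope),
        intercept=float(res.intercept), r_squared=float(res.rvalue ** 2),
        p_value=float(res.pvalue), n_units=int(ok.sum()))
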