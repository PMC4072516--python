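"""Family-level history: clustering, age landscapes, peaks, dispersion.

Subfamily consensuses are grouped into families by complete-linkage
agglomeration at a pairwise-distance ceiling (default <3.5%), so that every
within-family pair of subfamilies respects the threshold.  Copy ages are
read from percent identity to the assigned subfamily consensus: identities
are binned at 0.5% and kernel-smoothed at 0.2% bandwidth, and the local
maxima of the smoothed curve date each family's retrotransposition bursts.
A Poisson diagnostic compares the variance of per-copy substitution counts
with their mean: copies deposited in a single instantaneous burst should be
Poisson (ratio ~1); overdispersion betrays extended or compound bursts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.signal import find_peaks
from scipy.spatial.distance import squareform
from scipy.stats import chi2, gaussian_kde

from .align import Scoring, global_identity

BIN_WIDTH = 0.5       # percent identity per histogram window
KDE_BANDWIDTH = 0.2   # percent identity


@dataclass
class FamilyPartition:
    families: dict[str, list[str]]          # family id -> subfamily ids
    distance_matrix: pd.DataFrame           # percent distances
    threshold: float

    def family_of(self, subfamily: str) -> str:
        for fam, subs in self.families.items():
            if subfamily in subs:
                return fam
        raise KeyError(subfamily)


@dataclass
class AgeLandscape:
    bins: np.ndarray                        # bin left edges, percent identity
    histogram: pd.DataFrame                 # families x bins, percent of total
    identities: dict[str, np.ndarray]       # per-family raw identities
    n_total: int
    peaks: list[tuple[float, str, float]] = field(default_factory=list)


@dataclass
class DispersionReport:
    family_id: str
    mean_divergence: float       # percent
    peak_divergence: float       # percent
    mean_minus_peak: float
    variance_mean_ratio: float
    overdispersed: bool
    p_value: float


def consensus_distance_matrix(consensuses: Sequence[tuple[str, str]],
                              scoring: Scoring = Scoring()) -> pd.DataFrame:
    """Pairwise percent distances (100 - global alignment identity)."""
    names = [n for n, _ in consensuses]
    n = len(names)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pct = global_identity(consensuses[i][1], consensuses[j][1], scoring)
            d[i, j] = d[j, i] = 100.0 - pct
    return pd.DataFrame(d, index=names, columns=names)


def cluster_families(consensuses: Sequence[tuple[str, str]],
                     threshold: float = 3.5,
                     youth: dict[str, float] | None = None,
                     distances: pd.DataFrame | None = None) -> FamilyPartition:
    """Complete-linkage agglomeration stopped strictly below ``threshold``.

    ``youth`` (higher = younger, e.g. mean member identity) orders family
    ids so family 1 is the youngest; input order breaks ties/absence.
    """
    names = [n for n, _ in consensuses]
    if distances is None:
        distances = consensus_distance_matrix(consensuses)
    if len(names) == 1:
        labels = np.array([1])
    else:
        condensed = squareform(distances.values, checks=False)
        Z = linkage(condensed, method="complete")
        labels = fcluster(Z, t=np.nextafter(threshold, 0),
                          criterion="distance")
    groups: dict[int, list[str]] = {}
    for name, lab in zip(names, labels):
        groups.setdefault(int(lab), []).append(name)

    def youngest(subs: list[str]) -> float:
        if youth:
            return -max(youth.get(s, -np.inf) for s in subs)
        return min(names.index(s) for s in subs)

    ordered = sorted(groups.values(), key=youngest)
    families = {f"family{i + 1}": subs for i, subs in enumerate(ordered)}
    part = FamilyPartition(families, distances, threshold)
    for subs in families.values():  # complete-linkage guarantee
        for a in subs:
            for b in subs:
                assert distances.loc[a, b] < threshold or a == b
    return part


def build_landscape(assignments: pd.DataFrame,
                    partition: FamilyPartition) -> AgeLandscape:
    """Bin per-copy identities at 0.5% per family, normalized so all bars
    over all families sum to 100% of detected elements."""
    if assignments.empty:
        raise ValueError("assignments must be non-empty")
    ids = assignments["identity"].to_numpy(dtype=float)
    lo = np.floor(ids.min() / BIN_WIDTH) * BIN_WIDTH
    edges = np.arange(lo, 100.0 + 2 * BIN_WIDTH, BIN_WIDTH)
    n_total = len(assignments)
    rows, identities = {}, {}
    for fam, subs in partition.families.items():
        sel = assignments["subfamily"].isin(subs)
        vals = assignments.loc[sel, "identity"].to_numpy(dtype=float)
        identities[fam] = vals
        counts, _ = np.histogram(vals, bins=edges)
        rows[fam] = 100.0 * counts / n_total
    hist = pd.DataFrame(rows, index=edges[:-1]).T
    return AgeLandscape(bins=edges[:-1], histogram=hist,
                        identities=identities, n_total=n_total)


def smoothed_curve(values: np.ndarray, n_total: int,
                   bandwidth: float = KDE_BANDWIDTH,
                   grid_step: float = 0.05
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel smoothed identity density on a fine grid.

    Heights are scaled to percent of all detected elements per 0.5% window,
    so they are comparable with the histogram bars.
    """
    grid = np.arange(values.min() - 2, values.max() + 2 + grid_step, grid_step)
    if len(np.unique(values)) == 1:
        dens = np.zeros_like(grid)
        dens[np.argmin(np.abs(grid - values[0]))] = 1.0 / BIN_WIDTH
    else:
        sd = values.std(ddof=1)
        kde = gaussian_kde(values, bw_method=bandwidth / sd)
        dens = kde(grid)
    height = dens * BIN_WIDTH * 100.0 * len(values) / n_total
    return grid, height


def call_peaks(landscape: AgeLandscape, bandwidth: float = KDE_BANDWIDTH,
               prominence: float = 0.1, min_separation: float = 1.0
               ) -> list[tuple[float, str, float]]:
    """Local maxima of each family's smoothed identity curve.

    ``prominence`` (percent-of-total-elements units) suppresses noise
    wiggles; ``min_separation`` (percent identity) greedily absorbs the
    jagged sub-maxima a narrow kernel produces on modest sample sizes into
    the dominant peak of each burst.  Peaks are stored on the landscape and
    returned sorted by height within each family.
    """
    peaks: list[tuple[float, str, float]] = []
    for fam, vals in landscape.identities.items():
        if len(vals) == 0:
            continue
        grid, height = smoothed_curve(vals, landscape.n_total, bandwidth)
        idx, _ = find_peaks(height, prominence=prominence)
        if len(idx) == 0 and len(np.unique(vals)) == 1:
            idx = np.array([int(np.argmax(height))])
        fam_peaks = [(float(grid[i]), fam, float(height[i])) for i in idx]
        fam_peaks.sort(key=lambda p: -p[2])
        kept: list[tuple[float, str, float]] = []
        for p in fam_peaks:
            if all(abs(p[0] - q[0]) >= min_separation for q in kept):
                kept.append(p)
        peaks.extend(kept)
    landscape.peaks = peaks
    return peaks


def dispersion_from_counts(counts: np.ndarray, alpha: float = 0.01
                           ) -> tuple[float, bool, float]:
    """Variance/mean ratio of substitution counts and a chi-square
    overdispersion verdict ((n-1)*ratio ~ chi2_{n-1} under Poisson)."""
    counts = np.asarray(counts, dtype=float)
    n = len(counts)
    mean = counts.mean()
    if n < 2 or mean == 0:
        return 0.0, False, 1.0
    ratio = counts.var(ddof=1) / mean
    p = chi2.sf((n - 1) * ratio, df=n - 1)
    return float(ratio), bool(p < alpha and ratio > 1.0), float(p)


def dispersion_diagnostic(assignments: pd.DataFrame,
                          landscape: AgeLandscape,
                          partition: FamilyPartition,
                          alpha: float = 0.01) -> list[DispersionReport]:
    """Per-family Poisson diagnostic over per-copy substitution counts."""
    if not landscape.peaks:
        raise ValueError("call_peaks must run before the dispersion diagnostic")
    best_peak = {}
    for pos, fam, height in landscape.peaks:
        if fam not in best_peak or height > best_peak[fam][1]:
            best_peak[fam] = (pos, height)
    out = []
    for fam, subs in partition.families.items():
        sel = assignments["subfamily"].isin(subs)
        if not sel.any() or fam not in best_peak:
            continue
        ids = assignments.loc[sel, "identity"].to_numpy(dtype=float)
        counts = assignments.loc[sel, "mismatches"].to_numpy(dtype=float)
        mean_div = float((100.0 - ids).mean())
        peak_div = 100.0 - best_peak[fam][0]
        ratio, over, p = dispersion_from_counts(counts, alpha)
        out.append(DispersionReport(
            family_id=fam, mean_divergence=mean_div,
            peak_divergence=peak_div,
            mean_minus_peak=mean_div - peak_div,
            variance_mean_ratio=ratio, overdispersed=over, p_value=p))
    return out


def calibrate_ages(landscape: AgeLandscape) -> dict[str, float]:
    """Relative family age = 100 - identity at the highest peak (percent
    divergence); strictly decreasing in peak identity."""
    if not landscape.peaks:
        raise ValueError("call_peaks must run before age calibration")
    best: dict[str, tuple[float, float]] = {}
    for pos, fam, height in landscape.peaks:
        if fam not in best or height > best[fam][1]:
            best[fam] = (pos, height)
    return {fam: 100.0 - pos for fam, (pos, _) in best.items()}


def nj_tree(distances: pd.DataFrame) -> str:
    """Neighbor-joining tree (Newick) from the subfamily distance matrix;
    for visualization only."""
    from skbio import DistanceMatrix
    from skbio.tree import nj
    if len(distances) < 3:
        names = list(distances.index)
        return "(" + ",".join(names) + ");"
    dm = DistanceMatrix(distances.values, ids=list(distances.index))
    return str(nj(dm)).strip()


def write_landscape(landscape: AgeLandscape, path: str | Path,
                    header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("family\tbin_start\theight_pct\n")
        for fam in landscape.histogram.index:
            for b, h in zip(landscape.bins, landscape.histogram.loc[fam]):
                fh.write(f"{fam}\t{b:.1f}\t{h:.4f}\n")


def write_peaks(peaks, path: str | Path,
                header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("family\tpeak_identity\theight_pct\n")
        for pos, fam, height in peaks:
            fh.write(f"{fam}\t{pos:.2f}\t{height:.4f}\n")


def plot_landscape(landscape: AgeLandscape, path: str | Path) -> None:
    """Stacked age-distribution bars plus smoothed curves (optional)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(8, 4))
    bottom = np.zeros(len(landscape.bins))
    for fam in landscape.histogram.index:
        h = landscape.histogram.loc[fam].to_numpy()
        ax.bar(landscape.bins, h, width=BIN_WIDTH, bottom=bottom,
               align="edge", label=fam)
        bottom += h
    ax.set_xlabel("percent identity to subfamily consensus")
    ax.set_ylabel("% of detected elements")
    ax.invert_xaxis()
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
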