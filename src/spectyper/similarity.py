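"""Composite correlation index (CCI) and spectral dendrograms.

CCI compares two binned spectral profiles interval-by-interval: the common
mass range (default 3,000-12,000 m/z) is split into a fixed number of
contiguous interval blocks (default 10), each interval contributes the
non-negative Pearson correlation of the two profiles within it, and the CCI
is the mean over intervals.  Identical profiles score 1, unrelated profiles
score ~0, and values above 0.9 indicate a strong correlation — the scale
used for strain-level comparisons.

Dendrograms of MSPs / spectra use Euclidean distance between binned
profiles with average linkage (UPGMA).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import pdist

from .msp import MainSpectralProfile, SpectralLibrary
from .spectra import PeakList

__all__ = [
    "BinnedProfile",
    "CCIMatrix",
    "bin_profile",
    "average_profile",
    "cci",
    "cci_matrix",
    "msp_dendrogram",
    "plot_cci_heatmap",
]

DEFAULT_MASS_LO = 3000.0
DEFAULT_MASS_HI = 12000.0
DEFAULT_BIN_WIDTH = 3.0
DEFAULT_N_INTERVALS = 10


@dataclass
class BinnedProfile:
    """Total-normalized, binned peak intensities on a fixed m/z grid."""

    bin_edges: np.ndarray
    values: np.ndarray
    params: dict = field(default_factory=dict)

    def same_grid(self, other: "BinnedProfile") -> bool:
        return (len(self.bin_edges) == len(other.bin_edges)
                and np.allclose(self.bin_edges, other.bin_edges))


@dataclass
class CCIMatrix:
    labels: list[str]
    values: np.ndarray
    params: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def save_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")


def _peak_arrays(p: PeakList | MainSpectralProfile) -> tuple[np.ndarray, np.ndarray]:
    return np.asarray(p.mz, float), np.asarray(p.intensity, float)


def bin_profile(
    p: PeakList | MainSpectralProfile,
    mass_lo: float = DEFAULT_MASS_LO,
    mass_hi: float = DEFAULT_MASS_HI,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> BinnedProfile:
    """Sum peak intensities into half-open bins [lo, hi) and total-normalize.

    Peaks outside [mass_lo, mass_hi) are dropped; a profile with no in-range
    peaks is all zero.
    """
    if mass_lo >= mass_hi:
        raise ValueError("mass_lo must be below mass_hi")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    mz, inten = _peak_arrays(p)
    nbins = int(np.ceil((mass_hi - mass_lo) / bin_width))
    keep = (mz >= mass_lo) & (mz < mass_hi)
    values, edges = np.histogram(mz[keep], bins=nbins, range=(mass_lo, mass_hi),
                                 weights=inten[keep])
    total = values.sum()
    if total > 0:
        values = values / total
    return BinnedProfile(edges, values,
                         params={"mass_lo": mass_lo, "mass_hi": mass_hi,
                                 "bin_width": bin_width})


def average_profile(profiles: Sequence[BinnedProfile]) -> BinnedProfile:
    """Arithmetic mean of normalized binned profiles (re-normalized)."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles to average")
    base = profiles[0]
    for p in profiles[1:]:
        if not base.same_grid(p):
            raise ValueError("profiles are on different bin grids")
    mean = np.mean([p.values for p in profiles], axis=0)
    total = mean.sum()
    if total > 0:
        mean = mean / total
    return BinnedProfile(base.bin_edges.copy(), mean, params=dict(base.params))


def _interval_corr(a: np.ndarray, b: np.ndarray) -> float:
    ca = a.std() < 1e-15
    cb = b.std() < 1e-15
    if ca and cb:
        return 1.0  # both flat: identical shape
    if ca or cb:
        return 0.0  # one flat, the other structured: no correlation
    return max(0.0, float(np.corrcoef(a, b)[0, 1]))


def cci(a: BinnedProfile, b: BinnedProfile,
        n_intervals: int = DEFAULT_N_INTERVALS) -> float:
    """Composite correlation index of two binned profiles in [0, 1]."""
    if not a.same_grid(b):
        raise ValueError("profiles must share one bin grid")
    nbins = len(a.values)
    if not (1 <= n_intervals <= nbins):
        raise ValueError("n_intervals must be between 1 and the number of bins")
    blocks = np.array_split(np.arange(nbins), n_intervals)
    return float(np.mean([_interval_corr(a.values[ix], b.values[ix]) for ix in blocks]))


def cci_matrix(
    strains: Mapping[str, Sequence[PeakList]] | Sequence[tuple[str, Sequence[PeakList]]],
    *,
    mass_lo: float = DEFAULT_MASS_LO,
    mass_hi: float = DEFAULT_MASS_HI,
    bin_width: float = DEFAULT_BIN_WIDTH,
    n_intervals: int = DEFAULT_N_INTERVALS,
    min_spectra: int = 2,
) -> CCIMatrix:
    """Pairwise CCI between strains, averaging replicates per strain first.

    Each strain must contribute at least two spectra to represent its mass
    spectral profile.  The result is exactly symmetric with unit diagonal.
    """
    items = list(strains.items()) if isinstance(strains, Mapping) else list(strains)
    if len(items) < 2:
        raise ValueError("at least two strains are required")
    profiles = []
    labels = []
    for sid, reps in items:
        reps = list(reps)
        if len(reps) < min_spectra:
            raise ValueError(
                f"strain {sid!r} has {len(reps)} spectra; at least {min_spectra} required"
            )
        profiles.append(average_profile(
            [bin_profile(r, mass_lo, mass_hi, bin_width) for r in reps]))
        labels.append(str(sid))
    n = len(profiles)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            v = cci(profiles[i], profiles[j], n_intervals)
            mat[i, j] = mat[j, i] = v
    return CCIMatrix(labels, mat, params={
        "n_intervals": n_intervals, "mass_lo": mass_lo,
        "mass_hi": mass_hi, "bin_width": bin_width,
    })


# ---------------------------------------------------------------------------
# Dendrograms


def _tree_to_newick(node, labels: list[str], parent_height: float) -> str:
    if node.is_leaf():
        return f"{labels[node.id]}:{parent_height - 0.0:.10g}"
    left = _tree_to_newick(node.get_left(), labels, node.dist)
    right = _tree_to_newick(node.get_right(), labels, node.dist)
    return f"({left},{right}):{parent_height - node.dist:.10g}"


def msp_dendrogram(
    entries: SpectralLibrary | Sequence[MainSpectralProfile] | Mapping[str, PeakList],
    *,
    mass_lo: float = 2000.0,
    mass_hi: float = 20000.0,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> tuple[str, pd.DataFrame]:
    """UPGMA dendrogram of binned profiles under Euclidean distance.

    Returns a newick string (merge heights as node heights, branch lengths
    the height differences) and the merge table.  Input entries are sorted
    by label before clustering so the result does not depend on input
    order.
    """
    if isinstance(entries, Mapping):
        items = [(str(k), v) for k, v in entries.items()]
    else:
        items = [(e.entry_name, e) for e in entries]
    if len(items) < 2:
        raise ValueError("at least two entries are required")
    items.sort(key=lambda kv: kv[0])
    labels = [k for k, _ in items]
    vecs = np.vstack([
        bin_profile(p, mass_lo, mass_hi, bin_width).values for _, p in items
    ])
    dists = pdist(vecs, metric="euclidean")
    merge = linkage(dists, method="average")
    root = to_tree(merge)
    newick = "(" + ",".join(
        _tree_to_newick(c, labels, root.dist) for c in (root.get_left(), root.get_right())
    ) + ");"
    # Root branch lengths of the two children are relative to the root height.
    table = pd.DataFrame(merge, columns=["left", "right", "height", "size"])
    return newick, table


def plot_cci_heatmap(matrix: CCIMatrix, path, *, annotate_threshold: float = 0.9) -> None:
    """Red-high / blue-low CCI heatmap; cells above the threshold annotated."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    n = len(matrix.labels)
    fig, ax = plt.subplots(figsize=(max(4, 0.4 * n), max(3.5, 0.4 * n)))
    im = ax.imshow(matrix.values, cmap="RdBu_r", vmin=0.0, vmax=1.0)
    ax.set_xticks(range(n), matrix.labels, rotation=90, fontsize=7)
    ax.set_yticks(range(n), matrix.labels, fontsize=7)
    for i in range(n):
        for j in range(n):
            if i != j and matrix.values[i, j] > annotate_threshold:
                ax.text(j, i, f"{matrix.values[i, j]:.2f}",
                        ha="center", va="center", fontsize=5)
    fig.colorbar(im, ax=ax, label="CCI")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
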