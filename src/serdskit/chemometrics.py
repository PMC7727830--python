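"""Marker-band intensity maps and hierarchical clustering of SERDS spectra.

Clustering follows the common spectroscopy recipe: the Pearson correlation
distance (1 - r) between spaxel spectra, agglomerated with Ward's minimum
variance criterion ("Ward.D2"-style: Lance-Williams updates on squared
distances, here via scipy's ward linkage on the precomputed distance
matrix).  Vector normalization (unit Euclidean norm) can be applied before
clustering; intensity maps average the spectrum over configurable marker
bands per spaxel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "IntensityMap",
    "ClusterModel",
    "vector_normalize",
    "marker_band_map",
    "pearson_distance",
    "ward_cluster",
    "cluster_summary",
    "cluster_cube",
]


@dataclass
class IntensityMap:
    """Per-spaxel scalar map (NaN at masked spaxels) plus its provenance."""

    values: np.ndarray
    bands: tuple[float, ...]
    window: float
    statistic: str = "mean"


@dataclass
class ClusterModel:
    """Ward linkage tree with labels for a chosen number of clusters k."""

    linkage_tree: np.ndarray
    labels: np.ndarray  # 1..k per clustered spectrum
    k: int


def vector_normalize(spectrum: np.ndarray) -> np.ndarray:
    """Scale a spectrum to unit Euclidean norm."""
    spectrum = np.asarray(spectrum, dtype=float)
    norm = np.linalg.norm(spectrum)
    if norm == 0:
        raise ValueError("cannot vector-normalize the zero spectrum")
    return spectrum / norm


def marker_band_map(cube, bands, window: float) -> IntensityMap:
    """Mean intensity over one or more marker bands, per spaxel.

    ``bands`` are positions on the cube's spectral axis (relative wavenumber
    for reconstructed SERDS cubes); each band is averaged over +/- window/2
    and the per-spaxel value is the mean over all listed bands.
    """
    bands = tuple(float(b) for b in np.atleast_1d(bands))
    if not bands:
        raise ValueError("need at least one marker band")
    ax = cube.axis.values
    per_band = []
    for b in bands:
        sel = np.abs(ax - b) <= window / 2.0
        if not sel.any():
            raise ValueError(f"marker band {b} lies outside the spectral axis")
        per_band.append(cube.data[..., sel].mean(axis=-1))
    values = np.mean(per_band, axis=0)
    values = np.where(cube.mask, values, np.nan)
    return IntensityMap(values=values, bands=bands, window=window)


def pearson_distance(spectra: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation distance d_ij = 1 - r_ij.

    Symmetric with zero diagonal; constant spectra have undefined
    correlation and raise.
    """
    spectra = np.asarray(spectra, dtype=float)
    if spectra.ndim != 2 or spectra.shape[0] < 2:
        raise ValueError("need at least two spectra")
    if np.any(spectra.std(axis=1) == 0):
        raise ValueError("constant spectrum: Pearson correlation undefined")
    r = np.corrcoef(spectra)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return 0.5 * (d + d.T)


def ward_cluster(distance: np.ndarray, k: int) -> ClusterModel:
    """Agglomerate a precomputed distance matrix with Ward's criterion.

    The condensed distances are merged with the Lance-Williams Ward update
    (operating on squared distances, the Ward.D2 convention); labels come
    from cutting the tree at k clusters.
    """
    distance = np.asarray(distance, dtype=float)
    n = distance.shape[0]
    if distance.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not 1 <= k <= n:
        raise ValueError(f"k must be between 1 and {n}")
    condensed = squareform(np.clip(distance, 0.0, None), checks=False)
    tree = linkage(condensed, method="ward")
    labels = fcluster(tree, t=k, criterion="maxclust")
    return ClusterModel(linkage_tree=tree, labels=labels, k=k)


def cluster_summary(model: ClusterModel, spectra: np.ndarray) -> dict[int, dict[str, np.ndarray]]:
    """Channel-wise mean and standard deviation per cluster.

    Empty clusters (possible after a maxclust cut) are excluded with a
    warning.
    """
    spectra = np.asarray(spectra, dtype=float)
    if spectra.shape[0] != model.labels.size:
        raise ValueError("label count does not match the number of spectra")
    out = {}
    for label in range(1, model.k + 1):
        members = spectra[model.labels == label]
        if members.shape[0] == 0:
            warnings.warn(f"cluster {label} is empty and was excluded")
            continue
        out[label] = {"mean": members.mean(axis=0), "sd": members.std(axis=0)}
    return out


def cluster_cube(cube, k: int, normalize: bool = False) -> tuple[np.ndarray, ClusterModel]:
    """Cluster the unmasked spaxels of a cube; returns (label grid, model).

    The label grid holds 0 at masked spaxels and 1..k elsewhere.  With
    ``normalize`` the spectra are vector-normalized before the Pearson
    distance is computed.
    """
    spectra = cube.spectra()
    if normalize:
        spectra = np.stack([vector_normalize(s) for s in spectra])
    model = ward_cluster(pearson_distance(spectra), k)
    grid = np.zeros(cube.grid_shape, dtype=int)
    grid[cube.mask] = model.labels
    return grid, model
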