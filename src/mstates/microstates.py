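"""GFP-peak topographic clustering and canonical map labeling.

Microstate segmentation works on the scalp maps observed at peaks of the
global field power (GFP), where topographies are most stable.  The peak
maps are clustered with the topographic atomize-and-agglomerate
hierarchical clustering (T-AAHC): starting from singleton clusters, the
cluster contributing least global explained variance (GEV) is repeatedly
dissolved and its member maps reassigned to the remaining cluster whose
centroid correlates best, ignoring polarity.  Group templates come from
re-clustering the pooled subject templates, and are put in the canonical
A-D order by exhaustive matching against reference maps.

All correlations here are spatial Pearson correlations across channels of
average-referenced maps; for zero-mean unit-norm vectors this equals the
plain dot product, which the implementation exploits throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np

from .montage import Montage
from .preprocess import EpochSet

__all__ = [
    "GFPSeries",
    "TemplateSet",
    "CANONICAL_CLASSES",
    "gfp",
    "gfp_peaks",
    "spatial_correlation",
    "normalize_maps",
    "taahc",
    "group_templates",
    "assign_canonical_labels",
]

CANONICAL_CLASSES: tuple[str, ...] = ("A", "B", "C", "D")


@dataclass(frozen=True)
class GFPSeries:
    """Per-frame global field power with the frame -> (epoch, sample) map."""

    values: np.ndarray
    epoch_index: np.ndarray  # kept-epoch ordinal of each frame
    sample_index: np.ndarray
    sfreq: float

    def __post_init__(self) -> None:
        if np.any(self.values < 0):
            raise ValueError("GFP values must be non-negative")


@dataclass(frozen=True)
class TemplateSet:
    """k unit-norm, average-referenced template maps.

    ``labels`` are cluster names ("0".."3" after clustering, "A".."D" once
    canonically assigned); ``gev`` is the global explained variance of the
    clustering that produced the maps, when applicable.
    """

    maps: np.ndarray = field(repr=False)  # (k, K)
    montage: Montage
    labels: tuple[str, ...]
    gev: float | None = None

    def __post_init__(self) -> None:
        maps = np.asarray(self.maps, dtype=float)
        object.__setattr__(self, "maps", maps)
        if maps.ndim != 2 or maps.shape[1] != self.montage.n_channels:
            raise ValueError("maps must be (k, n_channels)")
        if len(self.labels) != maps.shape[0]:
            raise ValueError("one label per map required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")
        if not np.allclose(maps.mean(axis=1), 0.0, atol=1e-8):
            raise ValueError("template maps must be average-referenced")
        if not np.allclose(np.linalg.norm(maps, axis=1), 1.0, atol=1e-8):
            raise ValueError("template maps must be unit-norm")

    @property
    def k(self) -> int:
        return self.maps.shape[0]


def gfp(ep: EpochSet) -> GFPSeries:
    """Global field power: population SD of potentials across channels.

    Requires average-referenced input (the GFP is defined on
    average-reference maps, where it equals the RMS of the potentials).
    """
    if ep.reference != "average":
        raise ValueError("gfp requires average-referenced epochs")
    data = ep.kept_data  # (n_epochs, K, T)
    values = data.std(axis=1, ddof=0)  # (n_epochs, T)
    n_ep, n_t = values.shape
    return GFPSeries(
        values=values.ravel(),
        epoch_index=np.repeat(np.arange(n_ep), n_t),
        sample_index=np.tile(np.arange(n_t), n_ep),
        sfreq=ep.sfreq,
    )


def gfp_peaks(g: GFPSeries) -> np.ndarray:
    """Frame indices of strict local GFP maxima, computed within each epoch.

    The first and last frame of an epoch are never peaks, and no peak can
    span an epoch boundary.  A flat series yields an empty result.
    """
    if g.values.size == 0:
        raise ValueError("empty GFP series")
    v = g.values
    interior = np.zeros(v.size, dtype=bool)
    interior[1:-1] = (v[1:-1] > v[:-2]) & (v[1:-1] > v[2:])
    same_epoch = np.zeros(v.size, dtype=bool)
    same_epoch[1:-1] = (g.epoch_index[1:-1] == g.epoch_index[:-2]) & (
        g.epoch_index[1:-1] == g.epoch_index[2:]
    )
    return np.nonzero(interior & same_epoch)[0]


def normalize_maps(maps: np.ndarray) -> np.ndarray:
    """Average-reference and unit-norm each row; zero-variance rows rejected."""
    maps = np.asarray(maps, dtype=float)
    maps = maps - maps.mean(axis=-1, keepdims=True)
    norms = np.linalg.norm(maps, axis=-1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero-variance map cannot be normalized")
    return maps / norms


def spatial_correlation(u: np.ndarray, v: np.ndarray, polarity_invariant: bool = True) -> float:
    """Spatial Pearson correlation of two maps across channels.

    With ``polarity_invariant`` the absolute value is returned, which is
    the similarity used everywhere in microstate analysis (a topography
    and its sign flip are the same brain state at opposite phases of the
    oscillatory carrier).
    """
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    uc = u - u.mean()
    vc = v - v.mean()
    nu = np.linalg.norm(uc)
    nv = np.linalg.norm(vc)
    if nu == 0 or nv == 0:
        raise ValueError("spatial correlation undefined for a zero-variance map")
    r = float(uc @ vc / (nu * nv))
    return abs(r) if polarity_invariant else r


def _principal_map(members: np.ndarray) -> np.ndarray:
    """First principal axis of member maps, polarity-aligned with the majority.

    Plain averaging would cancel under polarity flips; the leading right
    singular vector is the polarity-blind mean topography.
    """
    if members.shape[0] == 1:
        m = members[0]
        return m / np.linalg.norm(m)
    _, _, vt = np.linalg.svd(members, full_matrices=False)
    v = vt[0]
    if np.sum(np.sign(members @ v)) < 0:
        v = -v
    return v / np.linalg.norm(v)


def taahc(
    maps: np.ndarray,
    k_target: int,
    gfp_weights: np.ndarray | None = None,
) -> tuple[TemplateSet, np.ndarray]:
    """Topographic atomize-and-agglomerate hierarchical clustering.

    Parameters
    ----------
    maps
        ``(n, K)`` topographies (will be average-referenced and unit-normed).
    k_target
        Number of clusters to stop at.
    gfp_weights
        GFP value of each map, used in the GEV weighting; defaults to 1.

    Returns
    -------
    templates, assignment
        The ``k_target`` centroid maps (with ``gev`` filled in) and the
        per-map cluster index.

    Notes
    -----
    The "worst" cluster at each step is the one contributing least to
    GEV = sum_p (gfp_p * corr_p)^2 / sum_p gfp_p^2; its members are
    reassigned one shot to the centroid of highest polarity-invariant
    correlation (ties broken toward the lowest cluster index), and the
    receiving centroids are recomputed as polarity-aligned principal axes.
    """
    maps = normalize_maps(maps)
    n, n_ch = maps.shape
    if not (1 <= k_target <= n):
        raise ValueError(f"k_target must be in [1, {n}], got {k_target}")
    if gfp_weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(gfp_weights, float)
        if w.shape != (n,):
            raise ValueError("gfp_weights must have one value per map")
    denom = float(np.sum(w**2))

    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    centroids: dict[int, np.ndarray] = {i: maps[i] for i in range(n)}
    contrib: dict[int, float] = {i: float(w[i] ** 2) for i in range(n)}

    def refresh(c: int) -> None:
        idx = members[c]
        centroids[c] = _principal_map(maps[idx])
        corr = np.abs(maps[idx] @ centroids[c])
        contrib[c] = float(np.sum((w[idx] * corr) ** 2))

    while len(members) > k_target:
        worst = min(contrib, key=lambda c: (contrib[c], c))
        orphan_idx = members.pop(worst)
        del centroids[worst], contrib[worst]
        keys = sorted(members)
        cent = np.array([centroids[c] for c in keys])
        best = np.argmax(np.abs(maps[orphan_idx] @ cent.T), axis=1)
        touched = set()
        for i, b in zip(orphan_idx, best):
            members[keys[b]].append(i)
            touched.add(keys[b])
        for c in touched:
            refresh(c)

    keys = sorted(members)
    assignment = np.empty(n, dtype=int)
    for new, c in enumerate(keys):
        assignment[members[c]] = new
    tmaps = np.array([centroids[c] for c in keys])
    gev = sum(contrib[c] for c in keys) / denom
    ts = TemplateSet(tmaps, _montage_placeholder(n_ch), tuple(str(i) for i in range(len(keys))), gev=gev)
    return ts, assignment


def _montage_placeholder(n_ch: int) -> Montage:
    # taahc is montage-agnostic; callers re-attach the real montage.
    return Montage(tuple(f"ch{i}" for i in range(n_ch)), np.zeros((n_ch, 2)))


def with_montage(ts: TemplateSet, montage: Montage) -> TemplateSet:
    """Attach the real montage to a clustering result."""
    return TemplateSet(ts.maps, montage, ts.labels, gev=ts.gev)


def cluster_peak_maps(ep: EpochSet, k_target: int = 4) -> tuple[TemplateSet, np.ndarray]:
    """Subject-level pipeline: GFP peaks -> T-AAHC templates.

    Convenience wrapper combining :func:`gfp`, :func:`gfp_peaks` and
    :func:`taahc` with GFP weighting, returning templates on the epoch
    set's montage.
    """
    g = gfp(ep)
    peaks = gfp_peaks(g)
    if peaks.size < k_target:
        raise ValueError("not enough GFP peaks to cluster")
    data = ep.kept_data
    peak_maps = data[g.epoch_index[peaks], :, g.sample_index[peaks]]
    ts, assignment = taahc(peak_maps, k_target, gfp_weights=g.values[peaks])
    return with_montage(ts, ep.montage), assignment


def group_templates(subject_sets: list[TemplateSet], k_target: int = 4) -> TemplateSet:
    """Group-level templates: pool subject maps and re-cluster with T-AAHC."""
    if not subject_sets:
        raise ValueError("empty subject list")
    montage = subject_sets[0].montage
    for ts in subject_sets:
        if ts.montage.names != montage.names:
            raise ValueError("all subjects must share a montage")
    pooled = np.vstack([ts.maps for ts in subject_sets])
    ts, _ = taahc(pooled, k_target)
    return with_montage(ts, montage)


def assign_canonical_labels(t: TemplateSet, reference: TemplateSet) -> TemplateSet:
    """Order templates as canonical classes A-D by matching to reference maps.

    Searches all one-to-one pairings (4! = 24 for four classes) for the one
    maximizing the summed polarity-invariant correlation, then reorders the
    maps A, B, C, D and aligns each map's sign to correlate positively with
    its reference.  Ties in the total similarity are broken toward the
    lexicographically smallest permutation, deterministically.
    """
    if t.k != reference.k:
        raise ValueError("template and reference sets must have the same size")
    if t.montage.names != reference.montage.names:
        raise ValueError("template and reference sets must share a montage")
    k = t.k
    sim = np.abs(t.maps @ reference.maps.T)  # (candidate, reference-class)
    best_perm = None
    best_total = -np.inf
    for perm in permutations(range(k)):
        total = sum(sim[perm[j], j] for j in range(k))
        if total > best_total + 1e-12:
            best_total = total
            best_perm = perm
    ordered = t.maps[list(best_perm)].copy()
    signs = np.sign(np.einsum("ij,ij->i", ordered, reference.maps))
    signs[signs == 0] = 1.0
    ordered *= signs[:, None]
    labels = CANONICAL_CLASSES[:k] if k <= 4 else tuple(str(i) for i in range(k))
    return TemplateSet(ordered, t.montage, labels, gev=t.gev)
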