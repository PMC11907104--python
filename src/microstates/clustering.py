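"""Polarity-invariant topographic clustering (AAHC) and template handling.

Spontaneous EEG topographies are treated as equivalent to their sign-flipped
versions, so every similarity here is the absolute spatial (Pearson)
correlation.  The clustering is atomize-and-agglomerate hierarchical
clustering (AAHC): every map starts as its own cluster, and the cluster
contributing least global explained variance (GEV) is repeatedly dissolved,
its members reassigned to the best-matching surviving cluster, until the
target number of classes remains.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .montage import Montage
from .preprocessing import GFPSeries
from .recording import EEGRecording

__all__ = [
    "TemplateSet",
    "spatial_correlation",
    "gev",
    "aahc",
    "fit_individual_microstates",
    "grand_mean",
    "sort_templates",
]

DEFAULT_LABELS = ("A", "B", "C", "D")


def _normalize_map(v: np.ndarray) -> np.ndarray:
    """Average-reference then scale a topography to unit L2 norm."""
    v = np.asarray(v, dtype=float)
    v = v - v.mean()
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("cannot normalize a zero-variance map")
    return v / n


@dataclass
class TemplateSet:
    """K labeled microstate topographies, average-referenced and unit-norm.

    ``level`` records where the set sits in the sorting hierarchy:
    ``individual``, ``grand_mean``, ``grand_grand_mean`` or ``norms``.
    ``gev`` is the total global explained variance achieved when the set was
    fitted (None for analytic or averaged sets).
    """

    maps: np.ndarray  # (K, E)
    labels: tuple[str, ...] = DEFAULT_LABELS
    level: str = "individual"
    gev: float | None = None
    montage: Montage | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.maps = np.atleast_2d(np.asarray(self.maps, dtype=float))
        if len(self.labels) != self.maps.shape[0]:
            raise ValueError("one label per map required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")
        self.maps = np.array([_normalize_map(m) for m in self.maps])

    @property
    def k(self) -> int:
        return self.maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]


def spatial_correlation(u: np.ndarray, v: np.ndarray, polarity_invariant: bool = True) -> float:
    """Pearson correlation between two topographies.

    Both maps are mean-referenced before correlating.  With
    ``polarity_invariant`` (the default, appropriate for spontaneous EEG)
    the absolute value is returned.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("maps must have equal length")
    u = u - u.mean()
    v = v - v.mean()
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("zero-variance map")
    r = float(u @ v / (nu * nv))
    r = min(1.0, max(-1.0, r))
    return abs(r) if polarity_invariant else r


def gev(
    maps: np.ndarray,
    gfp_at_maps: np.ndarray,
    templates: TemplateSet,
    assignment: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Global explained variance of an assignment of maps to templates.

    GEV_k = sum_{t: a(t)=k} (GFP_t * corr(map_t, template_k))^2 / sum_t GFP_t^2

    Parameters
    ----------
    maps : (n, E) topographies (any scaling; re-referenced internally)
    gfp_at_maps : (n,) GFP weights
    templates : the K class templates
    assignment : (n,) integer class per map; -1 marks unassigned maps, which
        contribute to the denominator but to no class.

    Returns
    -------
    (per_class, total) : per-class GEV fractions (length K) and their sum.
    """
    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    w = np.asarray(gfp_at_maps, dtype=float)
    a = np.asarray(assignment, dtype=int)
    if maps.shape[0] != w.size or w.size != a.size:
        raise ValueError("maps, weights and assignment must align")
    denom = float(np.sum(w**2))
    if denom == 0:
        raise ValueError("all-zero GFP: GEV undefined")
    X = maps - maps.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(X, axis=1)
    ok = norms > 0
    C = np.zeros((maps.shape[0], templates.k))
    C[ok] = (X[ok] / norms[ok, None]) @ templates.maps.T
    per_class = np.zeros(templates.k)
    for k in range(templates.k):
        sel = a == k
        per_class[k] = np.sum((w[sel] * C[sel, k]) ** 2) / denom
    return per_class, float(per_class.sum())


def _dominant_component(V: np.ndarray, w: np.ndarray) -> np.ndarray:
    """First principal direction of weighted member maps, sign-aligned.

    V: (m, E) unit-norm mean-zero maps, w: (m,) GFP weights.  The returned
    template is the top eigenvector of sum w_i^2 v_i v_i^T, with its sign
    chosen so that the weighted majority of members correlates positively.
    """
    M = (V * (w**2)[:, None]).T @ V
    vals, vecs = np.linalg.eigh(M)
    t = vecs[:, -1]
    t = t - t.mean()  # eigenvector of mean-zero maps is mean-zero up to fp error
    t /= np.linalg.norm(t)
    s = float(np.sum(w * (V @ t)))
    if s < 0:
        t = -t
    elif s == 0 and t[np.argmax(np.abs(t))] < 0:
        t = -t
    return t


class _Cluster:
    __slots__ = ("members", "template", "contribution")

    def __init__(self, members: list[int], template: np.ndarray, contribution: float):
        self.members = members
        self.template = template
        self.contribution = contribution


def aahc(
    maps: np.ndarray,
    gfp_weights: np.ndarray,
    k_target: int,
    labels: tuple[str, ...] | None = None,
) -> tuple[TemplateSet, np.ndarray]:
    """Atomize-and-agglomerate hierarchical clustering of topographies.

    Starts from one cluster per map; at each step the cluster with the
    smallest GEV contribution is dissolved and each of its members is
    reassigned to the surviving cluster whose template it matches best by
    polarity-invariant correlation.  Cluster templates are the dominant
    spatial component of their members (GFP-weighted, sign-aligned).

    Ties on the minimal contribution go to the cluster with fewer members,
    then to the lower index — deterministic.

    Returns the fitted ``TemplateSet`` (with achieved total GEV) and the
    per-map class assignment.
    """
    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    w = np.asarray(gfp_weights, dtype=float)
    n = maps.shape[0]
    if not (1 <= k_target <= n):
        raise ValueError(f"k_target must be in [1, {n}], got {k_target}")
    if w.shape != (n,):
        raise ValueError("one GFP weight per map required")

    X = maps - maps.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-variance map in clustering input")
    V = X / norms[:, None]
    denom = float(np.sum(w**2))
    if denom == 0:
        raise ValueError("all GFP weights are zero")

    # Singleton initialization: template = the map itself, contribution w^2.
    clusters: dict[int, _Cluster] = {
        i: _Cluster([i], V[i].copy(), float(w[i] ** 2) / denom) for i in range(n)
    }

    while len(clusters) > k_target:
        # atomization target: least contribution; ties -> fewer members, lower id
        worst = min(
            clusters,
            key=lambda c: (clusters[c].contribution, len(clusters[c].members), c),
        )
        orphans = clusters.pop(worst).members
        ids = sorted(clusters)
        T = np.array([clusters[c].template for c in ids])
        best = np.argmax(np.abs(V[orphans] @ T.T), axis=1)
        touched = set()
        for m, b in zip(orphans, best):
            clusters[ids[b]].members.append(m)
            touched.add(ids[b])
        for c in touched:
            cl = clusters[c]
            idx = np.array(cl.members)
            cl.template = _dominant_component(V[idx], w[idx])
            cl.contribution = float(np.sum((w[idx] * (V[idx] @ cl.template)) ** 2)) / denom

    # order classes by descending contribution for a stable, meaningful order
    ids = sorted(clusters, key=lambda c: (-clusters[c].contribution, c))
    T = np.array([clusters[c].template for c in ids])
    # final assignment: every map to its best-matching final template (the
    # same rule backfitting uses), and GEV reported under that assignment
    dots = V @ T.T
    assignment = np.argmax(np.abs(dots), axis=1)
    per_class = np.zeros(k_target)
    for kk in range(k_target):
        sel = assignment == kk
        per_class[kk] = float(np.sum((w[sel] * dots[sel, kk]) ** 2)) / denom
    total = float(per_class.sum())
    if labels is None:
        labels = tuple(DEFAULT_LABELS[i] if i < 4 else f"M{i}" for i in range(k_target))
    ts = TemplateSet(maps=T, labels=labels, level="individual", gev=total)
    return ts, assignment


def fit_individual_microstates(
    rec: EEGRecording, gfp: GFPSeries, k: int = 4
) -> TemplateSet:
    """AAHC on the subject's maps at GFP peaks, weighted by peak GFP."""
    peaks = gfp.peak_indices
    if peaks.size < k:
        raise ValueError(
            f"subject {rec.subject_id}: only {peaks.size} GFP peaks, need >= {k}"
        )
    maps = rec.data[:, peaks].T
    weights = gfp.values[peaks]
    ts, _ = aahc(maps, weights, k)
    ts.level = "individual"
    ts.montage = rec.montage
    return ts


def sort_templates(tset: TemplateSet, reference: TemplateSet) -> TemplateSet:
    """Relabel and sign-align a template set against a reference.

    Searches all K! label permutations exhaustively for the one maximizing
    the summed polarity-invariant correlation to the reference classes; ties
    break to the lexicographically smallest permutation.  Each map's sign is
    flipped if its signed correlation with its matched reference is negative.
    """
    if tset.k != reference.k:
        raise ValueError("template sets must have the same number of classes")
    if tset.k > 6:
        raise ValueError("exhaustive sorting supported for K <= 6")
    C = tset.maps @ reference.maps.T  # signed correlations (unit-norm maps)
    best_perm, best_obj = None, -np.inf
    for perm in itertools.permutations(range(tset.k)):
        obj = sum(abs(C[perm[j], j]) for j in range(tset.k))
        if obj > best_obj + 1e-12:
            best_obj, best_perm = obj, perm
    new_maps = np.empty_like(tset.maps)
    for j in range(tset.k):
        m = tset.maps[best_perm[j]]
        if C[best_perm[j], j] < 0:
            m = -m
        new_maps[j] = m
    return TemplateSet(
        maps=new_maps,
        labels=reference.labels,
        level=tset.level,
        gev=tset.gev,
        montage=tset.montage or reference.montage,
    )


def grand_mean(
    sets: list[TemplateSet],
    reference: TemplateSet | None = None,
    level: str = "grand_mean",
) -> TemplateSet:
    """Average template sets class-wise after alignment.

    Classes are first aligned (order and polarity) across sets against the
    reference — or against the first set when no reference is given — then
    averaged per class with equal subject weighting and re-normalized.
    """
    if not sets:
        raise ValueError("need at least one template set")
    k = sets[0].k
    if any(s.k != k for s in sets):
        raise ValueError("all template sets must share K")
    if any(s.n_channels != sets[0].n_channels for s in sets):
        raise ValueError("all template sets must share the montage")
    ref = reference if reference is not None else sets[0]
    aligned = [sort_templates(s, ref) for s in sets]
    mean_maps = np.mean([s.maps for s in aligned], axis=0)
    return TemplateSet(
        maps=mean_maps,
        labels=ref.labels,
        level=level,
        montage=sets[0].montage or ref.montage,
    )
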