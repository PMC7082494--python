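"""Within-subject permutation inference and cluster-based permutation tests.

All hypothesis tests are permutation-based and respect the within-subject
design: labels are only ever permuted (or signs flipped) inside a subject's
own row, never across subjects. p-values are the fraction of permuted
statistics at least as extreme as the observed one (two-sided for t), with
a resolution floor of ``1 / n_perm``; 95% intervals of the null
distribution are reported alongside.

The cluster test follows the 5-step sensor-space procedure: (1) contrast
two paired condition maps, (2) a paired t test at every spatial-spectral
point, (3) z-score the t map across points, (4) group supra-threshold
(|z| > 3) neighbors of equal polarity into clusters — within one frequency
band — whose mass is the sum of member values, (5) compare each cluster's
|mass| against the permutation null of the maximum |mass| (within-subject
condition flips), controlling the family-wise error rate. Only clusters
with p below alpha and at least ``min_points`` members are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Delaunay
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PermutationResult",
    "ClusterResult",
    "perm_rm_anova",
    "perm_paired_t",
    "holm",
    "channel_adjacency",
    "edge_pairs",
    "edge_adjacency",
    "cluster_permutation",
    "neurophenomenological_contrast",
    "rank_conditions",
]

_TINY = np.finfo(float).tiny


@dataclass
class PermutationResult:
    """Observed statistic, permutation p, and the null distribution summary."""

    observed_stat: float
    p: float
    null_distribution: np.ndarray
    ci: tuple[float, float]
    n_perm: int
    seed: int
    effect: str = ""

    def __repr__(self) -> str:  # compact: null_distribution elided
        return (
            f"PermutationResult(effect={self.effect!r}, "
            f"stat={self.observed_stat:.4g}, p={self.p:.4g}, "
            f"ci=({self.ci[0]:.3g}, {self.ci[1]:.3g}), n_perm={self.n_perm})"
        )


@dataclass
class ClusterResult:
    """A spatial-spectral cluster: members, mass statistic and permutation p."""

    members: list[tuple[int, int]]  # (band index, unit index)
    mass: float
    p: float
    polarity: str
    band: int = field(default=-1)

    @property
    def size(self) -> int:
        return len(self.members)


def _finish(observed, null, n_perm, seed, effect, p):
    null = np.asarray(null, dtype=float)
    ci = (float(np.percentile(null, 2.5)), float(np.percentile(null, 97.5)))
    p = max(float(p), 1.0 / n_perm)
    return PermutationResult(
        observed_stat=float(observed), p=min(p, 1.0), null_distribution=null,
        ci=ci, n_perm=n_perm, seed=seed, effect=effect,
    )


def _one_way_f(scores: np.ndarray) -> float:
    """Repeated-measures one-way F: MS_condition / MS_(condition x subject)."""
    n, k = scores.shape
    grand = scores.mean()
    ss_cond = n * np.sum((scores.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((scores.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((scores - grand) ** 2)
    ss_err = ss_total - ss_cond - ss_subj
    ms_cond = ss_cond / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    if ms_err <= _TINY:
        return np.nan
    return ms_cond / ms_err


_FACTORIAL_CONTRASTS = {
    # columns ordered (A1B1, A1B2, A2B1, A2B2)
    "factor_a": np.array([1.0, 1.0, -1.0, -1.0]) / 2.0,
    "factor_b": np.array([1.0, -1.0, 1.0, -1.0]) / 2.0,
    "interaction": np.array([1.0, -1.0, -1.0, 1.0]) / 2.0,
}


def _factorial_f(scores: np.ndarray) -> dict[str, float]:
    """2x2 within-subject effects via the contrast t^2 identity.

    For a two-level within factor, F(1, n-1) equals the squared paired t of
    the per-subject contrast scores.
    """
    n = scores.shape[0]
    out = {}
    for effect, contrast in _FACTORIAL_CONTRASTS.items():
        c = scores @ contrast
        sd = c.std(ddof=1)
        if sd <= _TINY:
            out[effect] = np.nan
        else:
            t = c.mean() / (sd / np.sqrt(n))
            out[effect] = t * t
    return out


def perm_rm_anova(
    scores: np.ndarray,
    design: str = "one_way",
    n_perm: int = 1000,
    seed: int = 0,
    factor_names: tuple[str, str] = ("factor_a", "factor_b"),
):
    """Permutation repeated-measures ANOVA (subjects x conditions scores).

    ``design="one_way"`` returns one :class:`PermutationResult` for the
    condition effect. ``design="factorial_2x2"`` expects the four columns
    ordered (A1B1, A1B2, A2B1, A2B2) and returns a dict with both main
    effects and the interaction; one shared permutation stream (condition
    labels permuted independently within each subject row) evaluates all
    three effects per permutation.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[0] < 2:
        raise ValueError("scores must be subjects x conditions with >= 2 subjects")
    if not np.isfinite(scores).all():
        raise ValueError("scores contain missing cells")
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = np.random.default_rng(seed)

    if design == "one_way":
        observed = _one_way_f(scores)
        if np.isnan(observed):
            warnings.warn("constant scores: F undefined, reporting p = 1")
            return _finish(0.0, np.zeros(n_perm), n_perm, seed, "condition", 1.0)
        null = np.empty(n_perm)
        for i in range(n_perm):
            null[i] = _one_way_f(rng.permuted(scores, axis=1))
        null = np.nan_to_num(null)
        p = np.mean(null >= observed)
        return _finish(observed, null, n_perm, seed, "condition", p)

    if design == "factorial_2x2":
        if scores.shape[1] != 4:
            raise ValueError("factorial_2x2 needs exactly 4 condition columns")
        names = {
            "factor_a": factor_names[0],
            "factor_b": factor_names[1],
            "interaction": "interaction",
        }
        observed = _factorial_f(scores)
        if all(np.isnan(v) for v in observed.values()):
            warnings.warn("constant scores: F undefined, reporting p = 1")
            return {
                names[e]: _finish(0.0, np.zeros(n_perm), n_perm, seed, names[e], 1.0)
                for e in observed
            }
        null = {e: np.empty(n_perm) for e in observed}
        for i in range(n_perm):
            perm_f = _factorial_f(rng.permuted(scores, axis=1))
            for e in null:
                null[e][i] = perm_f[e]
        results = {}
        for e, obs in observed.items():
            nd = np.nan_to_num(null[e])
            if np.isnan(obs):
                results[names[e]] = _finish(0.0, nd, n_perm, seed, names[e], 1.0)
            else:
                results[names[e]] = _finish(obs, nd, n_perm, seed, names[e], np.mean(nd >= obs))
        return results

    raise ValueError(f"unknown design {design!r}")


def perm_paired_t(
    a: np.ndarray, b: np.ndarray, n_perm: int = 1000, seed: int = 0
) -> PermutationResult:
    """Two-sided permutation paired t test via within-pair sign flips."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("need equal-length paired vectors with n >= 3")
    d = a - b
    n = len(d)
    if np.allclose(d, 0):
        warnings.warn("zero-variance differences: reporting t = 0, p = 1")
        return _finish(0.0, np.zeros(n_perm), n_perm, seed, "paired_t", 1.0)

    def t_stat(x):
        # constant nonzero differences give an infinite t, which is correct
        with np.errstate(over="ignore"):
            sd = max(x.std(ddof=1), _TINY)
            return x.mean() / (sd / np.sqrt(n))

    observed = t_stat(d)
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    flipped = signs * d
    with np.errstate(over="ignore"):
        means = flipped.mean(axis=1)
        sds = np.maximum(flipped.std(axis=1, ddof=1), _TINY)
        null = means / (sds / np.sqrt(n))
    p = np.mean(np.abs(null) >= abs(observed))
    return _finish(observed, null, n_perm, seed, "paired_t", p)


def holm(pvals, alpha: float = 0.05):
    """Holm's sequential Bonferroni: (reject decisions, adjusted p-values)."""
    pvals = np.asarray(pvals, dtype=float)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="holm")
    return reject, p_adj


# ---------------------------------------------------------------------------
# adjacency construction


def channel_adjacency(
    positions: np.ndarray, max_distance: float | None = None
) -> np.ndarray:
    """Symmetric boolean channel adjacency from 2-D positions.

    Delaunay triangulation (every channel gets >= 1 neighbor) with optional
    pruning of edges longer than ``max_distance``.
    """
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    adj = np.zeros((n, n), dtype=bool)
    if n < 3:
        adj[~np.eye(n, dtype=bool)] = True
        return adj
    tri = Delaunay(positions)
    for simplex in tri.simplices:
        for i in range(3):
            a, b = simplex[i], simplex[(i + 1) % 3]
            adj[a, b] = adj[b, a] = True
    if max_distance is not None:
        dist = np.linalg.norm(positions[:, None] - positions[None, :], axis=-1)
        pruned = adj & (dist <= max_distance)
        # never orphan a channel: keep its shortest Delaunay edge
        for i in range(n):
            if adj[i].any() and not pruned[i].any():
                j = np.argmin(np.where(adj[i], dist[i], np.inf))
                pruned[i, j] = pruned[j, i] = True
        adj = pruned
    np.fill_diagonal(adj, False)
    return adj


def edge_pairs(n_channels: int) -> list[tuple[int, int]]:
    """Upper-triangle electrode pairs in row-major order."""
    return [(i, j) for i in range(n_channels) for j in range(i + 1, n_channels)]


def edge_adjacency(pairs: list[tuple[int, int]]) -> np.ndarray:
    """Two electrode pairs are adjacent iff they share an endpoint."""
    n = len(pairs)
    ends = np.array(pairs)
    share = (
        (ends[:, None, 0] == ends[None, :, 0])
        | (ends[:, None, 0] == ends[None, :, 1])
        | (ends[:, None, 1] == ends[None, :, 0])
        | (ends[:, None, 1] == ends[None, :, 1])
    )
    np.fill_diagonal(share, False)
    return share


# ---------------------------------------------------------------------------
# cluster-based permutation test


def _t_map(diffs: np.ndarray) -> np.ndarray:
    """Paired t at every point: subjects x points -> points."""
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = np.maximum(diffs.std(axis=0, ddof=1), _TINY)
    return mean / (sd / np.sqrt(n))


def _t_maps_permuted(diffs: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """Sign-flipped t maps for all permutations at once -> (n_perm, points)."""
    n = diffs.shape[0]
    mean = signs @ diffs / n
    meansq = (diffs**2).mean(axis=0)  # invariant under sign flips
    var = (meansq - mean**2) * (n / (n - 1))
    sd = np.sqrt(np.maximum(var, 0.0))
    return mean / np.maximum(sd / np.sqrt(n), _TINY)


def _zscore(values: np.ndarray) -> np.ndarray:
    sd = values.std()
    if sd <= _TINY:
        return np.zeros_like(values)
    return (values - values.mean()) / sd


def _clusters_of(
    values: np.ndarray, threshold: float, adjacency: csr_matrix, n_units: int
) -> list[tuple[list[int], float, str]]:
    """Connected supra-threshold components per band and polarity.

    ``values`` is flat (bands * units); adjacency connects units within one
    band only. Returns (flat member indices, mass, polarity) triples.
    """
    out = []
    n_bands = values.size // n_units
    grid = values.reshape(n_bands, n_units)
    for b in range(n_bands):
        for polarity, mask in (
            ("positive", grid[b] > threshold),
            ("negative", grid[b] < -threshold),
        ):
            idx = np.flatnonzero(mask)
            if idx.size == 0:
                continue
            sub = adjacency[np.ix_(idx, idx)]
            n_comp, labels = connected_components(csr_matrix(sub), directed=False)
            for comp in range(n_comp):
                members = idx[labels == comp]
                mass = float(grid[b, members].sum())
                out.append(([b * n_units + m for m in members], mass, polarity))
    return out


def _max_cluster_mass(
    values: np.ndarray, threshold: float, adjacency, n_units: int
) -> float:
    if not (np.abs(values) > threshold).any():
        return 0.0
    clusters = _clusters_of(values, threshold, adjacency, n_units)
    return max((abs(m) for _, m, _ in clusters), default=0.0)


def cluster_permutation(
    maps_a: np.ndarray,
    maps_b: np.ndarray | None,
    adjacency: np.ndarray,
    form_threshold: float = 3.0,
    n_perm: int = 1000,
    min_points: int = 3,
    seed: int = 0,
    alpha: float = 0.05,
    threshold_on: str = "z",
) -> list[ClusterResult]:
    """Cluster-based permutation test on paired per-subject maps.

    Parameters
    ----------
    maps_a, maps_b : ndarray, subjects x bands x units
        Paired condition maps (units are electrodes, or electrode pairs for
        connectivity maps). ``maps_b=None`` runs the one-sample variant
        (contrast maps tested against zero); both use within-subject sign
        flips of the per-subject difference, which for the two-condition
        case is exactly a condition-label exchange.
    adjacency : bool ndarray, units x units
        Spatial neighborhood (clusters never cross bands).
    threshold_on : {"z", "t"}
        Whether the |.| > ``form_threshold`` cluster-forming rule applies to
        the z-scored map (default) or the raw t map; cluster mass sums the
        thresholded values.

    Returns clusters with permutation ``p < alpha`` and at least
    ``min_points`` members, ordered by |mass|.
    """
    maps_a = np.asarray(maps_a, dtype=float)
    if maps_a.ndim != 3:
        raise ValueError("maps must be subjects x bands x units")
    if maps_b is not None:
        maps_b = np.asarray(maps_b, dtype=float)
        if maps_b.shape != maps_a.shape:
            raise ValueError("paired maps must have identical shape")
        diffs = maps_a - maps_b
    else:
        diffs = maps_a
    n_subj, n_bands, n_units = diffs.shape
    if adjacency.shape != (n_units, n_units):
        raise ValueError(
            f"adjacency must be {n_units} x {n_units} to match the maps"
        )
    if threshold_on not in ("z", "t"):
        raise ValueError("threshold_on must be 'z' or 't'")
    flat = diffs.reshape(n_subj, n_bands * n_units)
    adjacency_sp = csr_matrix(adjacency)

    def scored(t_flat: np.ndarray) -> np.ndarray:
        return _zscore(t_flat) if threshold_on == "z" else t_flat

    observed = scored(_t_map(flat))
    clusters = _clusters_of(observed, form_threshold, adjacency_sp, n_units)

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_subj))
    perm_t = _t_maps_permuted(flat, signs)
    null_max = np.array(
        [
            _max_cluster_mass(scored(perm_t[i]), form_threshold, adjacency_sp, n_units)
            for i in range(n_perm)
        ]
    )

    results = []
    for members_flat, mass, polarity in clusters:
        p = max(float(np.mean(null_max >= abs(mass))), 1.0 / n_perm)
        if p < alpha and len(members_flat) >= min_points:
            members = [(m // n_units, m % n_units) for m in members_flat]
            results.append(
                ClusterResult(
                    members=members, mass=mass, p=p, polarity=polarity,
                    band=members[0][0],
                )
            )
    results.sort(key=lambda c: -abs(c.mass))
    return results


# ---------------------------------------------------------------------------
# neurophenomenological contrast


def rank_conditions(ratings: pd.DataFrame, subject: int, scale: str) -> list[str]:
    """Experimental conditions of one subject ordered worst- to best-rated.

    Ties are broken by condition presentation order (the order conditions
    appear in the table), which is logged by the caller.
    """
    rows = ratings[(ratings["subject"] == subject) & (ratings["condition"] != "baseline")]
    score = dict(zip(rows["condition"], rows[scale]))
    order = {c: i for i, c in enumerate(rows["condition"])}
    return sorted(score, key=lambda c: (score[c], order[c]))


def neurophenomenological_contrast(
    maps_by_condition: dict[str, np.ndarray],
    ratings: pd.DataFrame,
    scale: str,
    adjacency: np.ndarray,
    **cluster_kwargs,
) -> tuple[np.ndarray, list[ClusterResult]]:
    """Top-2-rated minus bottom-2-rated condition contrast, cluster-tested.

    ``maps_by_condition`` maps each experimental condition to its
    subjects x bands x units array. Per subject the two highest-rated
    conditions' maps are averaged and the two lowest-rated subtracted; the
    per-subject contrast maps are then tested against zero with the
    one-sample cluster permutation (sign flips).

    Returns the contrast maps and the significant clusters.
    """
    if scale not in ("mental_relaxation", "absorption_depth"):
        raise ValueError(f"unknown rating scale {scale!r}")
    conditions = list(maps_by_condition)
    if len(conditions) < 4:
        raise ValueError("need maps for at least 4 rated conditions")
    n_subj = next(iter(maps_by_condition.values())).shape[0]
    contrasts = []
    for s in range(n_subj):
        ranked = [c for c in rank_conditions(ratings, s, scale) if c in maps_by_condition]
        if len(ranked) < 4:
            raise ValueError(f"subject {s} has fewer than 4 rated conditions with maps")
        low, high = ranked[:2], ranked[-2:]
        top = np.mean([maps_by_condition[c][s] for c in high], axis=0)
        bottom = np.mean([maps_by_condition[c][s] for c in low], axis=0)
        contrasts.append(top - bottom)
    contrast_maps = np.stack(contrasts)
    clusters = cluster_permutation(contrast_maps, None, adjacency, **cluster_kwargs)
    return contrast_maps, clusters
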