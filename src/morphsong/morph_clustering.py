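"""Trait-matrix assembly, Ward.D2 morph discovery, and rule classification.

Morphs are discovered by agglomerative hierarchical clustering (Ward.D2
criterion on Euclidean distances between z-scored traits) with the number
of clusters selected by the gap statistic: within-cluster dispersion of the
data is compared, on the log scale, against B reference datasets drawn
uniformly over each trait's observed range. Individuals lacking a full
trait complement (the paper-style "complete case" requirement of calling
song + courtship song + wing data) are classified afterwards by nearest
centroid on a small diagnostic trait set.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "TraitMatrix",
    "ClusteringResult",
    "GapResult",
    "MorphAssignment",
    "assemble_trait_matrix",
    "ward_cluster",
    "cut_tree",
    "gap_statistic",
    "classify_nearest_centroid",
    "to_newick",
    "DEFAULT_DIAGNOSTIC_TRAITS",
]

SONG_TRAITS = (
    "dominant_frequency",
    "amplitude_db",
    "rel_amplitude_A",
    "rel_amplitude_B",
    "rel_amplitude_C",
    "rel_amplitude_D",
    "rel_amplitude_E",
    "rel_amplitude_F",
    "frequency_evenness",
)

DEFAULT_WING_TRAITS = (
    "harp_width",
    "mirror_size",
    "scraper_present",
    "mirror_present",
    "file_gaps_present",
    "shape_pc1",
    "shape_pc2",
    "shape_pc3",
    "shape_pc4",
    "shape_pc5",
    "shape_pc6",
    "shape_pc7",
    "shape_pc8",
    "shape_pc9",
    "shape_pc10",
)

DEFAULT_DIAGNOSTIC_TRAITS = (
    "mirror_present",
    "harp_width",
    "calling_amplitude_db",
    "calling_frequency_evenness",
    "calling_dominant_frequency",
    "file_gaps_present",
)


@dataclass(frozen=True)
class TraitMatrix:
    """Scaled individuals x traits matrix with the scaling bookkeeping."""

    individuals: tuple[str, ...]
    traits: tuple[str, ...]
    values: np.ndarray  # z-scored
    means: np.ndarray
    sds: np.ndarray
    dropped: tuple[str, ...] = ()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.individuals), columns=list(self.traits)
        )


@dataclass(frozen=True)
class ClusteringResult:
    """Agglomerative merge tree in scipy linkage-matrix layout.

    Row i of ``merges`` is (a, b, height, size): clusters a and b (ids < n
    are leaves, ids >= n refer to earlier merge rows) joined at the given
    height on the distance scale.
    """

    merges: np.ndarray  # (n - 1, 4)
    labels: tuple[str, ...]
    linkage: str = "ward.D2"
    distance: str = "euclidean"

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


@dataclass(frozen=True)
class GapResult:
    k_candidates: tuple[int, ...]
    gap: np.ndarray
    s_k: np.ndarray
    log_w: np.ndarray
    log_w_ref: np.ndarray
    best_k: int
    labels_at_best_k: np.ndarray
    B: int
    seed: int
    rule: str = "firstSEmax"


@dataclass(frozen=True)
class MorphAssignment:
    individual_id: str
    morph: str
    method: str  # "clustered" | "rule_classified"
    distances: dict = field(default_factory=dict)


def assemble_trait_matrix(
    song_features: pd.DataFrame,
    wing_features: pd.DataFrame,
    require_complete: bool = True,
    wing_traits: tuple[str, ...] = DEFAULT_WING_TRAITS,
    mirror_absent_fill: float = 0.0,
) -> TraitMatrix:
    """Join song + wing features into a z-scored trait matrix.

    ``song_features`` is tidy (one row per recording, with ``song_type``);
    calling and courtship rows become ``calling_*`` / ``courtship_*``
    columns. An absent mirror contributes ``mirror_absent_fill`` (default 0)
    to the mirror-size trait so that whole morphs lacking mirrors are not
    discarded by the complete-case filter. Binary flags enter as 0/1 before
    z-scoring.
    """
    wide = song_features.pivot_table(
        index="individual_id",
        columns="song_type",
        values=list(SONG_TRAITS),
        aggfunc="first",
    )
    wide.columns = [f"{song_type}_{trait}" for trait, song_type in wide.columns]
    song_cols = [
        f"{st}_{t}" for st in ("calling", "courtship") for t in SONG_TRAITS
        if f"{st}_{t}" in wide.columns
    ]
    wing = wing_features.set_index("individual_id").copy()
    if "mirror_size" in wing.columns:
        wing["mirror_size"] = wing["mirror_size"].fillna(mirror_absent_fill)
    missing_wing = [t for t in wing_traits if t not in wing.columns]
    if missing_wing:
        raise ValueError(f"wing features missing traits {missing_wing}")

    joined = wide[song_cols].join(wing[list(wing_traits)], how="inner")
    if joined.empty:
        raise ValueError("no individuals shared between song and wing tables")
    trait_cols = song_cols + list(wing_traits)

    dropped: tuple[str, ...] = ()
    if require_complete:
        complete = joined.dropna()
        dropped = tuple(sorted(set(joined.index) - set(complete.index)))
        joined = complete
    if joined.empty:
        raise ValueError("no complete-case individuals remain")

    values = joined[trait_cols].to_numpy(dtype=float)
    means = values.mean(axis=0)
    sds = values.std(axis=0, ddof=1)
    zero_var = [trait_cols[i] for i in np.where(sds == 0)[0]]
    if zero_var:
        raise ValueError(
            f"zero-variance trait(s) {zero_var}: cannot z-score; drop or vary them"
        )
    return TraitMatrix(
        individuals=tuple(joined.index),
        traits=tuple(trait_cols),
        values=(values - means) / sds,
        means=means,
        sds=sds,
        dropped=dropped,
    )


# ---------------------------------------------------------------------------
# Ward.D2 agglomeration (Lance-Williams recurrence on squared dissimilarities)


def _ward_d2_linkage(x: np.ndarray) -> np.ndarray:
    """Merge tree under the Ward.D2 criterion.

    Operates on squared Euclidean dissimilarities via the Lance-Williams
    update; merge heights are reported on the distance scale (square root of
    the merge criterion), matching the convention of standard Ward.D2
    implementations. Ties are broken by the lexicographically lowest active
    pair index, so results are deterministic given input order.
    """
    n = x.shape[0]
    d2 = np.sum((x[:, None, :] - x[None, :, :]) ** 2, axis=-1)
    np.fill_diagonal(d2, np.inf)
    sizes = {i: 1 for i in range(n)}
    cluster_id = list(range(n))  # current cluster id occupying each matrix row
    active = list(range(n))
    merges = np.empty((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        sub = d2[np.ix_(active, active)]
        np.fill_diagonal(sub, np.inf)
        m = sub.min()
        ties = np.argwhere(np.isclose(sub, m, rtol=0.0, atol=0.0))
        ties = ties[ties[:, 0] < ties[:, 1]]
        ai, aj = min(map(tuple, ties))  # lowest (i, j) pair among exact ties
        i, j = active[ai], active[aj]
        ci, cj = cluster_id[i], cluster_id[j]
        ni, nj = sizes[ci], sizes[cj]
        a, b = sorted((ci, cj))
        merges[step] = (a, b, np.sqrt(d2[i, j]), ni + nj)
        # Lance-Williams (Ward.D2) update of squared dissimilarities, row i
        for k in active:
            if k in (i, j):
                continue
            nk = sizes[cluster_id[k]]
            d2[i, k] = d2[k, i] = (
                (ni + nk) * d2[i, k] + (nj + nk) * d2[j, k] - nk * d2[i, j]
            ) / (ni + nj + nk)
        sizes[next_id] = ni + nj
        cluster_id[i] = next_id
        next_id += 1
        active.remove(j)
    return merges


def ward_cluster(matrix: TraitMatrix | np.ndarray) -> ClusteringResult:
    """Hierarchical clustering of scaled traits under the Ward.D2 criterion."""
    if isinstance(matrix, TraitMatrix):
        values, labels = matrix.values, matrix.individuals
    else:
        values = np.asarray(matrix, dtype=float)
        labels = tuple(str(i) for i in range(values.shape[0]))
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("clustering needs at least two rows")
    merges = _ward_d2_linkage(values)
    if np.any(np.diff(merges[:, 2]) < -1e-10):
        raise RuntimeError("Ward.D2 heights are not monotone")  # pragma: no cover
    return ClusteringResult(merges=merges, labels=labels)


def cut_tree(result: ClusteringResult, k: int) -> np.ndarray:
    """Cluster labels (1..k) from cutting the merge tree at k clusters."""
    return fcluster(result.merges, t=k, criterion="maxclust")


def to_newick(result: ClusteringResult) -> str:
    """Dendrogram as a Newick string; branch lengths from merge heights."""
    n = len(result.labels)

    def node_height(idx: int) -> float:
        return 0.0 if idx < n else float(result.merges[idx - n][2])

    def node(idx: int) -> str:
        if idx < n:
            return result.labels[idx].replace(" ", "_")
        a, b, h, _ = result.merges[idx - n]
        parts = [
            f"{node(int(c))}:{h - node_height(int(c)):.10g}" for c in (a, b)
        ]
        return "(" + ",".join(parts) + ")"

    return node(2 * n - 2) + ";"


def merges_to_json(result: ClusteringResult) -> str:
    return json.dumps(
        {
            "linkage": result.linkage,
            "distance": result.distance,
            "labels": list(result.labels),
            "merges": result.merges.tolist(),
        }
    )


# ---------------------------------------------------------------------------
# Gap statistic


def _within_dispersion(
    values: np.ndarray, labels: np.ndarray, power: int = 2
) -> float:
    """Pooled within-cluster dispersion W.

    ``power=2``: sum of squared deviations from cluster means (equivalently
    pairwise squared distances / 2n). ``power=1``: pairwise Euclidean
    distances / 2n, the convention of the standard R implementation.
    """
    if power == 2:
        w = 0.0
        for lab in np.unique(labels):
            cluster = values[labels == lab]
            w += float(np.sum((cluster - cluster.mean(axis=0)) ** 2))
        return w
    if power != 1:
        raise ValueError("power must be 1 or 2")
    d = squareform(pdist(values))
    w = 0.0
    for lab in np.unique(labels):
        idx = np.where(labels == lab)[0]
        w += float(d[np.ix_(idx, idx)].sum()) / (2.0 * len(idx))
    return w


def _log_dispersions(
    values: np.ndarray, ks: tuple[int, ...], power: int
) -> np.ndarray:
    tree = ward_cluster(values)
    d = squareform(pdist(values)) if power == 1 else None
    out = np.empty(len(ks))
    for i, k in enumerate(ks):
        labels = cut_tree(tree, k)
        if power == 2:
            out[i] = np.log(_within_dispersion(values, labels, power=2))
        else:
            w = 0.0
            for lab in np.unique(labels):
                idx = np.where(labels == lab)[0]
                w += float(d[np.ix_(idx, idx)].sum()) / (2.0 * len(idx))
            out[i] = np.log(w)
    return out


def _max_se(gap: np.ndarray, s: np.ndarray, rule: str) -> int:
    """Index (0-based) of the chosen k under the given selection rule."""
    if rule == "globalmax":
        return int(np.argmax(gap))
    if rule == "firstmax":
        for i in range(len(gap) - 1):
            if gap[i] >= gap[i + 1]:
                return i
        return len(gap) - 1
    if rule == "Tibs2001SEmax":
        for i in range(len(gap) - 1):
            if gap[i] >= gap[i + 1] - s[i + 1]:
                return i
        return len(gap) - 1
    if rule in ("firstSEmax", "globalSEmax"):
        if rule == "globalSEmax":
            ref = int(np.argmax(gap))
        else:
            ref = len(gap) - 1
            for i in range(1, len(gap)):
                if gap[i] < gap[i - 1]:  # first local maximum
                    ref = i - 1
                    break
        for i in range(ref + 1):
            if gap[i] >= gap[ref] - s[ref]:
                return i
        return ref
    raise ValueError(f"unknown best-k rule {rule!r}")


def gap_statistic(
    matrix: TraitMatrix | np.ndarray,
    k_max: int = 10,
    B: int = 100,
    seed: int = 0,
    rule: str = "firstSEmax",
    reference: str = "pca",
    power: int = 1,
) -> GapResult:
    """Gap-statistic selection of the number of clusters.

    For each candidate k, the log within-cluster dispersion of the Ward.D2
    cut is compared with its expectation under B seeded reference datasets;
    gap(k) = mean(log W*_k) - log W_k and ``s_k`` carries the
    sqrt(1 + 1/B) simulation-error inflation.

    ``reference="pca"`` (default) draws references uniformly in the
    principal-component rotation of the centered data and rotates back —
    appropriate for correlated trait matrices, where an axis-aligned box
    grossly overstates the null dispersion and inflates the selected k.
    ``reference="original"`` draws uniformly over each trait's observed
    range. ``power`` selects the dispersion convention of
    :func:`_within_dispersion` (1 = pairwise distances, the R default).
    """
    values = matrix.values if isinstance(matrix, TraitMatrix) else np.asarray(matrix)
    n = values.shape[0]
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if k_max >= n:
        raise ValueError(f"k_max ({k_max}) must be below the number of rows ({n})")
    if B < 10:
        raise ValueError("B must be >= 10 for a usable reference distribution")
    if reference not in ("pca", "original"):
        raise ValueError("reference must be 'pca' or 'original'")

    ks = tuple(range(1, k_max + 1))
    log_w = _log_dispersions(values, ks, power)

    rng = np.random.default_rng(seed)
    centered = values - values.mean(axis=0)
    if reference == "pca":
        v_rot = np.linalg.svd(centered, full_matrices=False)[2].T
        rotated = centered @ v_rot
        lo, hi = rotated.min(axis=0), rotated.max(axis=0)
    else:
        v_rot = None
        lo, hi = values.min(axis=0), values.max(axis=0)
    log_w_star = np.empty((B, k_max))
    for b in range(B):
        ref = rng.uniform(lo, hi, size=(n, len(lo)))
        if v_rot is not None:
            ref = ref @ v_rot.T
        log_w_star[b] = _log_dispersions(ref, ks, power)
    log_w_ref = log_w_star.mean(axis=0)
    gap = log_w_ref - log_w
    s_k = log_w_star.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / B)
    best_idx = _max_se(gap, s_k, rule)
    best_k = ks[best_idx]
    tree = ward_cluster(values)
    return GapResult(
        k_candidates=ks,
        gap=gap,
        s_k=s_k,
        log_w=log_w,
        log_w_ref=log_w_ref,
        best_k=best_k,
        labels_at_best_k=cut_tree(tree, best_k),
        B=B,
        seed=seed,
        rule=rule,
    )


# ---------------------------------------------------------------------------
# Nearest-centroid classification of the larger, incomplete-data sample


def classify_nearest_centroid(
    candidates: pd.DataFrame,
    training: pd.DataFrame,
    training_morphs: pd.Series | dict,
    diagnostic_traits: tuple[str, ...] = DEFAULT_DIAGNOSTIC_TRAITS,
) -> list[MorphAssignment]:
    """Assign morph labels by nearest centroid on scaled diagnostic traits.

    ``training`` (indexed by individual_id) defines the per-morph centroids
    and the scaling; candidates need only the diagnostic traits, so
    individuals with a single song type can still be classified. Ties go to
    the first-listed morph with a warning.
    """
    traits = [t for t in diagnostic_traits if t in candidates.columns]
    if not traits:
        raise ValueError(
            f"no diagnostic traits available; need some of {diagnostic_traits}"
        )
    morphs = pd.Series(training_morphs)
    train = training.loc[morphs.index, traits].astype(float)
    means, sds = train.mean(), train.std(ddof=1)
    sds = sds.replace(0.0, 1.0)  # a flag constant in training still separates others
    train_z = (train - means) / sds
    centroids = train_z.groupby(morphs).mean()
    morph_order = list(dict.fromkeys(morphs))  # first-appearance order
    centroids = centroids.loc[[m for m in morph_order if m in centroids.index]]

    assignments = []
    cand = ((candidates[traits].astype(float) - means) / sds).to_numpy()
    cmat = centroids.to_numpy()
    for row_id, row in zip(candidates.index, cand):
        if np.any(np.isnan(row)):
            raise ValueError(f"{row_id}: missing diagnostic trait value")
        dists = np.sqrt(np.sum((cmat - row) ** 2, axis=1))
        best = int(np.argmin(dists))
        exact_ties = np.where(dists == dists[best])[0]
        if len(exact_ties) > 1:
            warnings.warn(
                f"{row_id}: equidistant from morphs "
                f"{[centroids.index[t] for t in exact_ties]}; taking the first",
                stacklevel=2,
            )
        assignments.append(
            MorphAssignment(
                individual_id=str(row_id),
                morph=str(centroids.index[best]),
                method="rule_classified",
                distances={
                    str(m): float(d) for m, d in zip(centroids.index, dists)
                },
            )
        )
    return assignments


def assignments_frame(assignments: list[MorphAssignment]) -> pd.DataFrame:
    rows = []
    for a in assignments:
        row = {"individual_id": a.individual_id, "morph": a.morph, "method": a.method}
        row.update({f"dist_{m}": d for m, d in a.distances.items()})
        rows.append(row)
    return pd.DataFrame(rows)
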