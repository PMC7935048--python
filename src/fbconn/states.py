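"""Connectivity-state clustering and fraction-rate profiling.

Banded connectivity observations (one P-vector of pair values per subject,
band and time point) are concatenated into a single observation matrix and
clustered with k-means++ (squared Euclidean distance, best of ``replicates``
random restarts by within-cluster distance).  Each centroid is a
connectivity state; the fraction of a subject's (band-specific) time points
assigned to a state is its fraction rate, and the profile of a state's
fraction rate across bands plays the role of its frequency response.

States are relabelled by descending overall occupancy so that state 0 is
always the most visited one; raw k-means label order is arbitrary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from .filterbank import BandedConnectivity

logger = logging.getLogger("fbconn")

__all__ = [
    "ObservationMatrix",
    "StateModel",
    "FractionRateTable",
    "vectorize_fnc",
    "devectorize_fnc",
    "assemble_observations",
    "cluster_states",
    "elbow_curve",
    "fraction_rates",
    "centroid_similarity",
    "match_states",
]


# ---------------------------------------------------------------------------
# FNC matrix <-> pair-vector plumbing
# ---------------------------------------------------------------------------

def vectorize_fnc(matrix: np.ndarray, atol: float = 1e-10) -> np.ndarray:
    """Upper triangle (i < j, row-major) of a symmetric connectivity matrix."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {matrix.shape}")
    if not np.allclose(matrix, matrix.T, atol=atol, equal_nan=True):
        raise ValueError(f"matrix is not symmetric within {atol}")
    iu, ju = np.triu_indices(matrix.shape[0], k=1)
    return matrix[iu, ju].copy()


def devectorize_fnc(vector: np.ndarray, diagonal: float | None = None) -> np.ndarray:
    """Rebuild the symmetric C x C matrix from its P = C(C-1)/2 pair vector.

    The diagonal is 0 unless ``diagonal`` is given (centroids carry no
    self-connectivity; pass 1.0 to reconstruct a correlation matrix).
    """
    vector = np.asarray(vector, dtype=float).ravel()
    p = vector.shape[0]
    c = int(round((1 + np.sqrt(1 + 8 * p)) / 2))
    if c * (c - 1) // 2 != p:
        raise ValueError(f"vector length {p} is not a valid pair count C(C-1)/2")
    out = np.zeros((c, c))
    iu, ju = np.triu_indices(c, k=1)
    out[iu, ju] = vector
    out[ju, iu] = vector
    if diagonal is not None:
        np.fill_diagonal(out, diagonal)
    return out


# ---------------------------------------------------------------------------
# Observation assembly
# ---------------------------------------------------------------------------

@dataclass
class ObservationMatrix:
    """Concatenated clustering observations with their provenance index."""

    values: np.ndarray              # (rows, P)
    subjects: np.ndarray            # (rows,) subject id per row
    bands: np.ndarray               # (rows,) 0-based band index per row
    times: np.ndarray               # (rows,) trajectory sample index per row
    n_dropped: int = 0

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def assemble_observations(banded: list[BandedConnectivity]) -> ObservationMatrix:
    """Stack per-subject banded connectivity into one observation matrix.

    Row order is deterministic: subjects in the given order, bands within
    subject, time within band.  Rows containing missing values are dropped
    with a logged count.  All subjects must share the same bank edges,
    window and pair ordering.
    """
    if not banded:
        raise ValueError("no banded connectivity provided")
    ref = banded[0]
    for b in banded[1:]:
        if b.pair_index != ref.pair_index:
            raise ValueError("subjects have mismatched pair orderings")
        if b.bank.edges != ref.bank.edges:
            raise ValueError("subjects were filtered with different banks")
        if b.window.half_width != ref.window.half_width:
            raise ValueError("subjects were computed with different windows")

    blocks, subj, band_ix, time_ix = [], [], [], []
    for b in banded:
        n_bands, n_t, n_p = b.values.shape
        blocks.append(b.values.reshape(n_bands * n_t, n_p))
        subj.append(np.repeat(b.subject_id or "subject", n_bands * n_t))
        band_ix.append(np.repeat(np.arange(n_bands), n_t))
        time_ix.append(np.tile(np.arange(n_t), n_bands))

    values = np.vstack(blocks)
    subjects = np.concatenate(subj)
    bands = np.concatenate(band_ix)
    times = np.concatenate(time_ix)

    keep = np.all(np.isfinite(values), axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("assemble_observations: dropped %d row(s) with missing values", n_dropped)
    return ObservationMatrix(
        values=values[keep],
        subjects=subjects[keep],
        bands=bands[keep],
        times=times[keep],
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

@dataclass
class StateModel:
    """k-means state model: centroids, per-observation labels, inertia."""

    k: int
    centroids: np.ndarray           # (k, P), ordered by descending occupancy
    labels: np.ndarray              # (rows,), 0-based state ids
    inertia: float
    replicates: int
    seed: int | None = None
    scaled: bool = False
    feature_means: np.ndarray | None = field(default=None, repr=False)
    feature_sds: np.ndarray | None = field(default=None, repr=False)


def _relabel_by_occupancy(centroids, labels, k):
    counts = np.bincount(labels, minlength=k)
    # stable sort: descending occupancy, ties by original label index
    order = np.lexsort((np.arange(k), -counts))
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    return centroids[order], remap[labels]


def cluster_states(
    obs: ObservationMatrix,
    k: int = 8,
    replicates: int = 30,
    seed: int | None = None,
    scale_features: bool = False,
    subsample: int | None = None,
) -> StateModel:
    """k-means++ clustering of connectivity observations into k states.

    The clustering is repeated ``replicates`` times from different random
    initial centroids and the solution with the lowest within-cluster
    squared distance is kept.  ``subsample`` (optional) fits on a random
    subset of rows and then assigns every row to its nearest centroid.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > obs.n_rows:
        raise ValueError(f"k={k} exceeds the number of observations ({obs.n_rows})")

    x = obs.values
    mu = sd = None
    if scale_features:
        mu = x.mean(axis=0)
        sd = x.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        x = (x - mu) / sd

    rng = np.random.default_rng(seed)
    km_seed = int(rng.integers(0, 2**31 - 1))
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=replicates,
        random_state=km_seed,
        algorithm="lloyd",
    )
    if subsample is not None and subsample < obs.n_rows:
        idx = rng.choice(obs.n_rows, size=subsample, replace=False)
        km.fit(x[idx])
        labels = km.predict(x)
        inertia = float(np.sum((x - km.cluster_centers_[labels]) ** 2))
    else:
        labels = km.fit_predict(x)
        inertia = float(km.inertia_)

    centroids, labels = _relabel_by_occupancy(km.cluster_centers_, labels, k)
    return StateModel(
        k=k,
        centroids=centroids,
        labels=labels,
        inertia=inertia,
        replicates=replicates,
        seed=seed,
        scaled=scale_features,
        feature_means=mu,
        feature_sds=sd,
    )


def elbow_curve(
    obs: ObservationMatrix,
    k_values: list[int],
    replicates: int = 30,
    seed: int | None = None,
) -> pd.DataFrame:
    """Within-cluster squared distance for each candidate k (elbow criterion)."""
    rows = []
    for i, k in enumerate(sorted(k_values)):
        child = None if seed is None else seed + i
        model = cluster_states(obs, k=k, replicates=replicates, seed=child)
        rows.append({"k": k, "inertia": model.inertia})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fraction rates
# ---------------------------------------------------------------------------

@dataclass
class FractionRateTable:
    """Per-band and overall state occupancy fractions per subject (tidy)."""

    per_band: pd.DataFrame          # columns: subject, band, state, fraction
    overall: pd.DataFrame           # columns: subject, state, fraction
    k: int


def _fractions(labels, group_keys, k, key_names):
    df = pd.DataFrame(dict(zip(key_names, group_keys)))
    df["state"] = labels
    counts = (
        df.groupby(list(key_names))["state"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=range(k), fill_value=0)
    )
    frac = counts.div(counts.sum(axis=1), axis=0)
    tidy = frac.stack().rename("fraction").reset_index()
    return tidy


def fraction_rates(model: StateModel, obs: ObservationMatrix) -> FractionRateTable:
    """Fraction of each subject's time points spent in each state.

    ``per_band`` conditions on (subject, band): the fraction of band-b
    observations of subject s labelled state c.  ``overall`` pools bands.
    Fractions over states sum to 1 for every subject (and subject-band).
    """
    if len(model.labels) != obs.n_rows:
        raise ValueError("model labels do not cover the observation matrix")
    per_band = _fractions(model.labels, (obs.subjects, obs.bands), model.k, ("subject", "band"))
    overall = _fractions(model.labels, (obs.subjects,), model.k, ("subject",))
    return FractionRateTable(per_band=per_band, overall=overall, k=model.k)


# ---------------------------------------------------------------------------
# Centroid comparison
# ---------------------------------------------------------------------------

def centroid_similarity(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation between every pair of vectorized centroids.

    Entry (i, j) is corr(a[i], b[j]); zero-variance centroids give NaN rows
    or columns with a warning.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError(f"feature lengths differ: {a.shape[1]} vs {b.shape[1]}")
    n_deg = int((a.std(axis=1) == 0).sum() + (b.std(axis=1) == 0).sum())
    if n_deg:
        logger.warning("centroid_similarity: %d zero-variance centroid(s)", n_deg)
    with np.errstate(divide="ignore", invalid="ignore"):
        full = np.corrcoef(np.vstack([a, b]))
    return full[: a.shape[0], a.shape[0]:]


def match_states(
    estimated: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Optimal one-to-one matching of estimated states to reference states.

    Solves the assignment maximizing total Pearson correlation (exact, via
    the Hungarian algorithm).  Exact ties — which arise, e.g., when an
    estimate set differs from the reference only by the sign of one state —
    resolve deterministically toward matching equal indices.  Returns
    ``(assignment, matched_corr)`` where ``assignment[r]`` is the estimated
    state matched to reference state ``r`` and ``matched_corr[r]`` its
    correlation.
    """
    estimated = np.atleast_2d(estimated)
    reference = np.atleast_2d(reference)
    if estimated.shape[0] != reference.shape[0]:
        raise ValueError(
            f"need equally many estimated ({estimated.shape[0]}) and reference "
            f"({reference.shape[0]}) states"
        )
    corr = centroid_similarity(reference, estimated)   # rows: reference
    cost = np.where(np.isfinite(corr), -corr, 1.0)
    cost -= 1e-9 * np.eye(cost.shape[0])               # deterministic tie-break
    rows, cols = linear_sum_assignment(cost)
    assignment = np.empty(reference.shape[0], dtype=int)
    assignment[rows] = cols
    matched = corr[np.arange(reference.shape[0]), assignment]
    return assignment, matched
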