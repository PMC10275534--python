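"""Comparing rest and background connectivity.

Three questions, all rank-based:

* **Fingerprints** — how similar is a subject's whole-matrix connectivity
  pattern (the 4950-entry upper triangle at 100 parcels) between two
  datasets?  Spearman rho per subject; group summaries use Fisher-z means
  of rho, reported back-transformed.
* **Network structure** — mean within-network vs. between-network
  connectivity, and the 7x7 network-collapsed matrix.
* **Individual differences** — for each connection (or network pair),
  the across-subject Spearman correlation of connectivity estimates
  between two datasets.

Subject identification (matching each subject to their most similar
matrix in another dataset) operationalizes the fingerprint idea, and
:func:`motion_association` checks whether similarity scores merely track
head motion.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as spstats

from .connectivity import fisher_z, inverse_fisher_z, vectorize_upper
from .types import AtlasLabels, ConnectivityMatrix

__all__ = [
    "spearman",
    "spearman_with_p",
    "fingerprint_similarity",
    "within_between",
    "within_between_mask",
    "connectionwise_stability",
    "collapse_networks",
    "identify_subjects",
    "motion_association",
    "StabilityResult",
    "mean_rho_via_z",
]

logger = logging.getLogger(__name__)


@dataclass
class StabilityResult:
    """Across-subject stability of individual differences between two
    datasets, at connection and at network resolution."""

    comparison: str  # e.g. "rest_x_fir"
    connection_rho: np.ndarray  # length p(p-1)/2, NaN where undefined
    network_rho: np.ndarray | None = None  # 7x7 symmetric
    n_undefined: int = 0


def _validate_pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).reshape(-1)
    y = np.asarray(y, dtype=float).reshape(-1)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.shape[0] < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for constant input")
    return x, y


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho: Pearson correlation of average (tie-adjusted) ranks."""
    x, y = _validate_pair(x, y)
    rho = spstats.spearmanr(x, y).statistic
    return float(rho)


def spearman_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho with its two-sided p-value."""
    x, y = _validate_pair(x, y)
    res = spstats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def fingerprint_similarity(a: ConnectivityMatrix, b: ConnectivityMatrix) -> float:
    """Spearman rho between the vectorized upper triangles of two matrices."""
    if a.parcel_ids != b.parcel_ids:
        raise ValueError("matrices must share parcel order")
    return spearman(vectorize_upper(a), vectorize_upper(b))


def mean_rho_via_z(rhos: np.ndarray) -> float:
    """Group-mean rho computed on the Fisher-z scale, back-transformed."""
    rhos = np.asarray(rhos, dtype=float)
    rhos = rhos[np.isfinite(rhos)]
    return float(inverse_fisher_z(np.mean(fisher_z(rhos))))


def within_between_mask(
    labels: AtlasLabels, parcel_ids
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks over the strict upper triangle: (within, between)."""
    nets = labels.vector_for(parcel_ids)
    iu = np.triu_indices(len(parcel_ids), k=1)
    same = nets[iu[0]] == nets[iu[1]]
    return same, ~same


def within_between(
    mat: ConnectivityMatrix, labels: AtlasLabels
) -> tuple[float, float]:
    """Mean z over unique within-network pairs and over between-network pairs.

    A single-parcel network simply contributes no within-network pairs.
    """
    vec = vectorize_upper(mat)
    within, between = within_between_mask(labels, mat.parcel_ids)
    mean_within = float(vec[within].mean()) if within.any() else math.nan
    mean_between = float(vec[between].mean()) if between.any() else math.nan
    return mean_within, mean_between


def collapse_networks(
    mat: ConnectivityMatrix,
    labels: AtlasLabels,
    network_order: tuple[str, ...] | None = None,
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Collapse the parcel matrix to a network x network matrix.

    Entry (m, n) is the mean of the unique ROI-pair z values joining
    networks m and n; the diagonal uses unique within-network pairs.
    Returns the symmetric matrix and the network order used.
    """
    nets = labels.vector_for(mat.parcel_ids)
    order = network_order or labels.networks()
    k = len(order)
    index = {name: i for i, name in enumerate(order)}
    iu = np.triu_indices(mat.n_parcels, k=1)
    vec = vectorize_upper(mat)
    sums = np.zeros((k, k))
    counts = np.zeros((k, k))
    a = np.array([index[n] for n in nets[iu[0]]])
    b = np.array([index[n] for n in nets[iu[1]]])
    lo, hi = np.minimum(a, b), np.maximum(a, b)
    np.add.at(sums, (lo, hi), vec)
    np.add.at(counts, (lo, hi), 1)
    with np.errstate(invalid="ignore"):
        out = sums / counts
    out = np.where(counts > 0, out, np.nan)
    out = np.triu(out) + np.triu(out, k=1).T
    return out, tuple(order)


def connectionwise_stability(
    cohort_a: list[ConnectivityMatrix],
    cohort_b: list[ConnectivityMatrix],
    comparison: str = "",
) -> StabilityResult:
    """Across-subject Spearman rho per connection between two datasets.

    For each of the p(p-1)/2 connections, the subjects' z values in
    dataset A are rank-correlated with the same subjects' values in B.
    Connections constant across subjects yield an undefined rho, recorded
    as NaN and counted.
    """
    if len(cohort_a) != len(cohort_b):
        raise ValueError("cohorts must contain the same subjects")
    if len(cohort_a) < 4:
        raise ValueError("need at least 4 subjects")
    for ma, mb in zip(cohort_a, cohort_b):
        if ma.parcel_ids != cohort_a[0].parcel_ids or mb.parcel_ids != ma.parcel_ids:
            raise ValueError("mismatched parcel order")
    A = np.stack([vectorize_upper(m) for m in cohort_a])  # subjects x conns
    B = np.stack([vectorize_upper(m) for m in cohort_b])
    ra = spstats.rankdata(A, axis=0)
    rb = spstats.rankdata(B, axis=0)
    ra = ra - ra.mean(axis=0)
    rb = rb - rb.mean(axis=0)
    num = (ra * rb).sum(axis=0)
    den = np.sqrt((ra**2).sum(axis=0) * (rb**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(den > 0, num / den, np.nan)
    n_undef = int(np.isnan(rho).sum())
    if n_undef:
        logger.info(
            "%d connections with undefined stability rho excluded", n_undef
        )
    return StabilityResult(
        comparison=comparison, connection_rho=rho, n_undefined=n_undef
    )


def network_stability(
    cohort_a: list[ConnectivityMatrix],
    cohort_b: list[ConnectivityMatrix],
    labels: AtlasLabels,
    comparison: str = "",
) -> StabilityResult:
    """Across-subject stability of the 7x7 network-collapsed estimates."""
    order = labels.networks()
    k = len(order)
    iu = np.triu_indices(k, k=0)  # include diagonal: within-network entries
    A = []
    B = []
    for ma, mb in zip(cohort_a, cohort_b):
        ca, _ = collapse_networks(ma, labels, order)
        cb, _ = collapse_networks(mb, labels, order)
        A.append(ca[iu])
        B.append(cb[iu])
    A = np.stack(A)
    B = np.stack(B)
    rho_flat = np.full(A.shape[1], np.nan)
    for j in range(A.shape[1]):
        a, b = A[:, j], B[:, j]
        if np.isnan(a).any() or np.isnan(b).any():
            continue
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            continue
        rho_flat[j] = spearman(a, b)
    net = np.full((k, k), np.nan)
    net[iu] = rho_flat
    net = np.where(np.isnan(net), net.T, net)
    return StabilityResult(
        comparison=comparison,
        connection_rho=rho_flat,
        network_rho=net,
        n_undefined=int(np.isnan(rho_flat).sum()),
    )


def identify_subjects(
    cohort_a: list[ConnectivityMatrix], cohort_b: list[ConnectivityMatrix]
) -> float:
    """Fingerprint identification accuracy.

    Each subject's matrix in A is matched to the most similar matrix in B
    (Spearman fingerprint similarity); accuracy is the fraction matched to
    themselves.  Ties break toward the lowest subject index, logged.
    """
    if len(cohort_a) != len(cohort_b):
        raise ValueError("cohorts must contain the same subjects")
    n = len(cohort_a)
    hits = 0
    for i, ma in enumerate(cohort_a):
        sims = np.array([fingerprint_similarity(ma, mb) for mb in cohort_b])
        best = int(np.argmax(sims))
        if (sims == sims[best]).sum() > 1:
            logger.warning("identification tie for subject %d; lowest index wins", i)
        if best == i:
            hits += 1
    return hits / n


def motion_association(
    similarity_scores: np.ndarray, qc_summaries: dict[str, np.ndarray]
) -> dict[str, tuple[float, float]]:
    """Spearman rho (with two-sided p) between per-subject similarity
    scores and each QC summary index (e.g. mean/max FD and DVARS)."""
    out: dict[str, tuple[float, float]] = {}
    for name, values in qc_summaries.items():
        out[name] = spearman_with_p(similarity_scores, values)
    return out
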