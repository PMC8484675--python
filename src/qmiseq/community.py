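"""Community structure: Bray–Curtis, non-metric MDS, and PERMANOVA.

All three operate on the quantified copy-number table (not raw reads): the
spike-in calibration is what makes copy numbers comparable across samples,
so dissimilarities are computed on copies as-is, without relative-abundance
standardisation (a Wisconsin/sqrt option exists for sensitivity checks).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import MDS

logger = logging.getLogger(__name__)


@dataclass
class DissimilarityMatrix:
    sample_ids: tuple[str, ...]
    values: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.sample_ids), len(self.sample_ids)):
            raise ValueError("matrix shape must match sample ids")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0):
            raise ValueError("matrix must be symmetric with a zero diagonal")
        if (v < 0).any() or (v > 1 + 1e-12).any():
            raise ValueError("Bray–Curtis values must lie in [0, 1]")


@dataclass
class OrdinationResult:
    sample_ids: tuple[str, ...]
    coordinates: np.ndarray  # (n, k), column-centred
    stress: float  # Kruskal stress-1
    n_starts: int
    seed: int


@dataclass
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    permuted_f_mean: float
    permuted_f_q95: float


def bray_curtis(
    table: pd.DataFrame,
    standardise: str | None = None,
) -> DissimilarityMatrix:
    """Bray–Curtis dissimilarity BC(x, y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ) between rows.

    ``standardise``: None (copy numbers as-is, the default), "sqrt", or
    "wisconsin" (double standardisation by species maxima then sample
    totals).  A pair of all-zero samples has an undefined BC and is set to 0
    with a warning.
    """
    values = table.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("abundances must be non-negative")
    if standardise == "sqrt":
        values = np.sqrt(values)
    elif standardise == "wisconsin":
        colmax = values.max(axis=0)
        values = np.divide(values, colmax, out=np.zeros_like(values),
                           where=colmax > 0)
        rowsum = values.sum(axis=1, keepdims=True)
        values = np.divide(values, rowsum, out=np.zeros_like(values),
                           where=rowsum > 0)
    elif standardise is not None:
        raise ValueError(f"unknown standardisation {standardise!r}")
    with np.errstate(invalid="ignore"):
        d = squareform(pdist(values, metric="braycurtis"))
    if np.isnan(d).any():
        logger.warning("all-zero sample pair(s): Bray–Curtis set to 0")
        d = np.nan_to_num(d, nan=0.0)
    np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix(tuple(str(i) for i in table.index), d)


def nmds(
    d: DissimilarityMatrix,
    k: int = 2,
    n_starts: int = 50,
    seed: int = 0,
    max_iter: int = 300,
) -> OrdinationResult:
    """Non-metric MDS minimising Kruskal stress-1 over random restarts.

    SMACOF with isotonic regression of configuration distances on
    dissimilarity ranks; the best of ``n_starts`` seeded random starts is
    returned with its stress-1 value and centred coordinates.
    """
    n = len(d.sample_ids)
    if n < 4:
        raise ValueError("NMDS needs at least 4 samples")
    mds = MDS(
        n_components=k,
        metric_mds=False,
        metric="precomputed",
        init="random",
        n_init=n_starts,
        max_iter=max_iter,
        random_state=seed,
        normalized_stress=True,
        eps=1e-9,
    )
    coords = mds.fit_transform(d.values)
    coords = coords - coords.mean(axis=0)
    stress = float(mds.stress_)
    if not np.isfinite(stress):
        raise RuntimeError("NMDS failed to converge in all starts")
    return OrdinationResult(d.sample_ids, coords, stress, n_starts, seed)


def _pseudo_f(d2: np.ndarray, groups: np.ndarray) -> float:
    """Anderson's pseudo-F from the among/within partition of squared d."""
    n = len(groups)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    labels = np.unique(groups)
    for g in labels:
        idx = np.flatnonzero(groups == g)
        if len(idx) < 1:
            continue
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    a = len(labels)
    ss_among = ss_total - ss_within
    return (ss_among / (a - 1)) / (ss_within / (n - a))


def permanova(
    d: DissimilarityMatrix,
    groups: Sequence[str],
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Permutation-based multivariate ANOVA on a dissimilarity matrix.

    The observed pseudo-F compares among-group to within-group sums of
    squared dissimilarities; significance comes from free permutation of the
    sample labels, with p = (#{F_perm ≥ F_obs} + 1) / (n_perm + 1).
    """
    groups = np.asarray(list(groups))
    if len(groups) != len(d.sample_ids):
        raise ValueError("one group label per sample required")
    labels = np.unique(groups)
    if len(labels) < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    counts = {g: int((groups == g).sum()) for g in labels}
    if min(counts.values()) < 1:
        raise ValueError("every group must be non-empty")

    d2 = d.values ** 2
    f_obs = _pseudo_f(d2, groups)
    rng = np.random.default_rng(seed)
    f_perm = np.empty(n_perm)
    for b in range(n_perm):
        f_perm[b] = _pseudo_f(d2, rng.permutation(groups))
    p = (np.sum(f_perm >= f_obs) + 1) / (n_perm + 1)
    return PermanovaResult(
        pseudo_f=float(f_obs),
        p_value=float(p),
        n_permutations=n_perm,
        permuted_f_mean=float(f_perm.mean()),
        permuted_f_q95=float(np.quantile(f_perm, 0.95)),
    )
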