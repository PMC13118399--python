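"""Community-level preprocessing and ordination.

Covers the standard amplicon-to-community steps between genus tables and
the network stage: removal of Glomeromycota (arbuscular mycorrhizal fungi)
from the ITS-derived fungal table, rarefaction to a common sequencing
depth, relative-abundance conversion, dominant-genus filtering, Bray-Curtis
dissimilarity, principal coordinate analysis and PERMANOVA.

Rarefaction draws without replacement (multivariate hypergeometric), so a
genus with count ``c`` in a sample of total ``T`` has expected rarefied
count ``depth * c / T``.  PCoA follows classical scaling of the
double-centered ``-d^2/2`` matrix; negative eigenvalues (Bray-Curtis is
non-Euclidean) are reported untransformed.  PERMANOVA uses the one-way
pseudo-F from among/within sums of squared distances with free permutation
of sample labels, and optionally the exhaustive permutation distribution.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

KINGDOM_PREFIXES = {"bacteria": "B_", "nonamf": "F_", "amf": "AMF_"}


@dataclass
class AbundanceTable:
    """Genus x sample abundance matrix for one marker set.

    ``data`` rows are kingdom-prefixed genus ids, columns sample ids.
    ``kingdom`` is one of ``bacteria`` / ``nonamf`` / ``amf``;
    ``is_relative`` flags proportions (columns sum to 1) vs raw counts.
    """

    data: pd.DataFrame
    kingdom: str
    is_relative: bool = False
    is_subset: bool = False   # genus subset of a full table; relative values
                              # stay on the full community's scale

    def __post_init__(self) -> None:
        if self.kingdom not in KINGDOM_PREFIXES:
            raise ValueError(f"unknown kingdom {self.kingdom!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate genus ids: {dups}")
        vals = self.data.to_numpy()
        if np.any(np.isnan(vals)):
            raise ValueError("NaN abundance")
        if (vals < 0).any():
            raise ValueError("negative abundance")
        if self.is_relative:
            sums = vals.sum(axis=0)
            tol_ok = (np.all(sums <= 1 + 1e-9) if self.is_subset
                      else np.allclose(sums[sums > 0], 1.0, atol=1e-9))
            if not tol_ok:
                raise ValueError("relative table columns must sum to 1")

    @property
    def genera(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def to_relative(self) -> "AbundanceTable":
        """Column-normalize to per-sample proportions."""
        sums = self.data.sum(axis=0)
        if (sums <= 0).any():
            bad = list(sums.index[sums <= 0])
            raise ValueError(f"samples with zero total abundance: {bad}")
        return replace(self, data=self.data / sums, is_relative=True)

    def subset_genera(self, genera) -> "AbundanceTable":
        missing = [g for g in genera if g not in self.data.index]
        if missing:
            raise KeyError(f"genera not in table: {missing}")
        return replace(self, data=self.data.loc[list(genera)], is_subset=True)


def remove_amf_from_its(table: AbundanceTable,
                        taxonomy: dict[str, str]) -> AbundanceTable:
    """Drop genera annotated Glomeromycota from an ITS-derived fungal table.

    ``taxonomy`` maps genus id -> phylum; genera without an entry are kept
    (unknowns are not AMF evidence).  The remainder is the non-AMF fungal
    community.
    """
    keep = [g for g in table.genera
            if taxonomy.get(g, "").lower() != "glomeromycota"]
    return replace(table, data=table.data.loc[keep], kingdom="nonamf")


def rarefy(table: AbundanceTable, depth: int | str = "min",
           seed: int | np.random.Generator = 0) -> AbundanceTable:
    """Subsample every column without replacement to a common depth.

    ``depth="min"`` uses the smallest column sum (the conventional
    lowest-sequencing-depth choice).  Counts must be integers.
    """
    if table.is_relative:
        raise ValueError("rarefaction requires a counts table")
    counts = table.data.to_numpy()
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("rarefaction requires integer counts")
    counts = counts.astype(np.int64)
    col_sums = counts.sum(axis=0)
    if depth == "min":
        depth = int(col_sums.min())
    depth = int(depth)
    if depth <= 0:
        raise ValueError("depth must be positive")
    if (col_sums < depth).any():
        bad = [s for s, t in zip(table.samples, col_sums) if t < depth]
        raise ValueError(f"depth {depth} exceeds totals of samples {bad}")
    rng = np.random.default_rng(seed)
    out = np.empty_like(counts)
    for j in range(counts.shape[1]):
        out[:, j] = rng.multivariate_hypergeometric(counts[:, j], depth)
    return replace(table, data=pd.DataFrame(
        out, index=table.data.index, columns=table.data.columns))


def dominant_genera(table: AbundanceTable, cutoff: float = 0.001) -> list[str]:
    """Genera whose mean relative abundance across samples strictly exceeds
    ``cutoff`` (default 0.1%)."""
    rel = table if table.is_relative else table.to_relative()
    means = rel.data.mean(axis=1)
    return list(means.index[means > cutoff])


def bray_curtis(table: AbundanceTable) -> pd.DataFrame:
    """Sample x sample Bray-Curtis dissimilarity matrix."""
    x = table.data.to_numpy().T  # samples x genera
    totals = x.sum(axis=1)
    if (totals <= 0).sum() > 1:
        raise ValueError("more than one all-zero sample: distances undefined")
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        num = np.abs(x[i] - x[i + 1:]).sum(axis=1)
        den = (x[i] + x[i + 1:]).sum(axis=1)
        d[i, i + 1:] = d[i + 1:, i] = num / den
    return pd.DataFrame(d, index=table.samples, columns=table.samples)


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame        # samples x axes
    eigenvalues: np.ndarray          # all, descending
    proportion_explained: np.ndarray  # over positive eigenvalues


def pcoa(dist: pd.DataFrame) -> OrdinationResult:
    """Classical scaling of a distance matrix.

    Eigen-decomposes the double-centered ``-d^2/2`` matrix; axes are ordered
    by descending eigenvalue and scaled by sqrt(eigenvalue).  Negative
    eigenvalues are reported as-is; variance fractions are normalized over
    the positive ones only.
    """
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")
    n = d.shape[0]
    a = -0.5 * d ** 2
    centering = np.eye(n) - np.ones((n, n)) / n
    g = centering @ a @ centering
    evals, evecs = np.linalg.eigh((g + g.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = np.clip(evals, 0, None)
    coords = evecs * np.sqrt(pos)
    pos_sum = pos.sum()
    prop = pos / pos_sum if pos_sum > 0 else pos
    axes = [f"PCo{i + 1}" for i in range(n)]
    idx = dist.index if isinstance(dist, pd.DataFrame) else pd.RangeIndex(n)
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=idx, columns=axes),
        eigenvalues=evals, proportion_explained=prop)


def _pseudo_f(d2: np.ndarray, labels: np.ndarray) -> float:
    """One-way PERMANOVA pseudo-F from a squared-distance matrix."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    groups = np.unique(labels)
    for g in groups:
        idx = np.flatnonzero(labels == g)
        if len(idx) < 2:
            continue
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    a = len(groups)
    ss_among = ss_total - ss_within
    return (ss_among / (a - 1)) / (ss_within / (n - a))


def permanova(dist: pd.DataFrame, design, n_perm: int | str = 999,
              seed: int | np.random.Generator = 0) -> tuple[float, float]:
    """Permutational multivariate ANOVA on a distance matrix.

    Returns (pseudo-F, p).  ``n_perm`` is the Monte-Carlo permutation count
    (>= 99), with ``p = (1 + #{F* >= F}) / (1 + n_perm)``, or ``"exact"``
    for the exhaustive distribution over all label permutations (small n
    only), where p is the exact tail proportion including the identity.
    """
    labels = design.treatment_of(dist.index).to_numpy()
    if len(np.unique(labels)) < 2:
        raise ValueError("PERMANOVA needs >= 2 groups")
    counts = pd.Series(labels).value_counts()
    if (counts < 2).any():
        raise ValueError("every group needs >= 2 members")
    d2 = np.asarray(dist, dtype=float) ** 2
    f_obs = _pseudo_f(d2, labels)
    n = len(labels)
    if n_perm == "exact":
        if n > 9:
            raise ValueError("exhaustive enumeration limited to n <= 9")
        total = math.factorial(n)
        hits = sum(
            _pseudo_f(d2, labels[list(perm)]) >= f_obs - 1e-12
            for perm in itertools.permutations(range(n)))
        return f_obs, hits / total
    n_perm = int(n_perm)
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _pseudo_f(d2, labels[perm]) >= f_obs - 1e-12:
            hits += 1
    return f_obs, (1 + hits) / (1 + n_perm)
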