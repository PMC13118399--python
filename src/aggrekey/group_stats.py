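"""Inferential primitives: one-way ANOVA with Duncan letters, Spearman
correlation, and Benjamini-Hochberg FDR adjustment.

Duncan's multiple range test compares every pair of group means through the
range of the contiguous span they delimit in the mean-sorted order.  A span
of ``p`` means is significant when its range exceeds

    R_p = q(alpha_p, p, df) * sqrt(MSE / n_h),

where ``q`` is the studentized-range quantile at the protected level
``alpha_p = 1 - (1 - alpha)**(p - 1)``, ``df`` the ANOVA error degrees of
freedom and ``n_h`` the harmonic mean group size.  Testing proceeds
step-down from the widest span: a non-significant span shields all spans it
contains.  The resulting non-significance relation is summarized as a
compact letter display (groups sharing a letter do not differ).

Note that, by construction, the protected levels make Duncan's procedure
control the *per-comparison* (prespecified pair) error rate near alpha
while the extreme pair under a global null is rejected at the protection
level 1-(1-alpha)**(k-1); the Monte-Carlo tests assert exactly these
classical properties.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from math import factorial

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: Sample size at and below which Spearman p-values switch to the exact
#: permutation distribution.
EXACT_SPEARMAN_MAX_N = 10


@lru_cache(maxsize=None)
def _duncan_q(alpha: float, span: int, df: int) -> float:
    """Studentized-range quantile at Duncan's protected level (cached:
    each scipy ppf evaluation costs ~0.1 s)."""
    protected = 1.0 - (1.0 - alpha) ** (span - 1)
    return float(stats.studentized_range.ppf(1.0 - protected, span, df))


@dataclass
class LetterAssignment:
    """Per-treatment mean, SD, n and compact letter display."""

    table: pd.DataFrame  # index: treatment; columns: mean, sd, n, letters
    alpha: float
    mse: float
    df_error: int
    f_stat: float
    p_value: float

    @property
    def letters(self) -> pd.Series:
        return self.table["letters"]

    def all_share_letter(self) -> bool:
        """True when some letter is common to every treatment (no
        significant difference anywhere)."""
        sets = [set(s) for s in self.table["letters"]]
        return len(set.intersection(*sets)) > 0


def _compact_letters(names: list[str], distinct: set[tuple[int, int]]) -> list[str]:
    """Insert-and-absorb compact letter display.

    ``names`` are ordered by descending mean; ``distinct`` holds index pairs
    (i, j), i < j, that are significantly different.
    """
    k = len(names)
    # columns: each a set of indices sharing one letter
    cols: list[set[int]] = [set(range(k))]
    for (i, j) in sorted(distinct):
        while True:
            hit = next((ci for ci, c in enumerate(cols)
                        if i in c and j in c), None)
            if hit is None:
                break
            col = cols.pop(hit)
            # split the letter: drop i from one copy, j from the other
            new = cols + [col - {j}, col - {i}]
            # absorb: drop columns contained in another, then deduplicate
            new = [c for c in new
                   if not any(c < d for d in new if d is not c)]
            cols = []
            for c in new:
                if c not in cols:
                    cols.append(c)
    # order letters by the highest-mean member so 'a' marks the top group
    cols.sort(key=lambda c: (min(c), -len(c)))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = ["" for _ in range(k)]
    for letter, col in zip(alphabet, cols):
        for i in col:
            out[i] += letter
    return ["".join(sorted(s)) for s in out]


def anova_duncan(values, design, alpha: float = 0.05) -> LetterAssignment:
    """One-way ANOVA across treatments plus Duncan's multiple range letters.

    ``values`` is a per-sample numeric Series indexed by sample id;
    ``design`` maps samples to treatments.  Requires >= 2 treatments with
    >= 2 replicates each.
    """
    values = pd.Series(values).astype(float)
    if values.isna().any():
        raise ValueError("NaN in values")
    trt = design.treatment_of(values.index)
    groups = {t: values[trt == t].to_numpy() for t in pd.unique(trt)}
    if len(groups) < 2:
        raise ValueError("need >= 2 treatments")
    sizes = {t: len(g) for t, g in groups.items()}
    if min(sizes.values()) < 2:
        raise ValueError("need >= 2 replicates per treatment")

    k = len(groups)
    n_tot = sum(sizes.values())
    df_err = n_tot - k
    mse = sum(((g - g.mean()) ** 2).sum() for g in groups.values()) / df_err
    if mse <= 0:
        raise ValueError("degenerate ANOVA: zero within-group variance")
    f_stat, p_value = stats.f_oneway(*groups.values())

    # deterministic order: descending mean, ties broken by treatment label
    order = sorted(groups, key=lambda t: (-groups[t].mean(), t))
    means = np.array([groups[t].mean() for t in order])
    n_h = k / sum(1.0 / sizes[t] for t in order)
    se = np.sqrt(mse / n_h)

    distinct: set[tuple[int, int]] = set()
    shielded = np.zeros((k, k), dtype=bool)
    for span in range(k, 1, -1):
        crit = _duncan_q(alpha, span, df_err) * se
        for i in range(0, k - span + 1):
            j = i + span - 1
            if shielded[i, j]:
                continue
            if means[i] - means[j] > crit:
                distinct.add((i, j))
            else:
                shielded[i:j + 1, i:j + 1] = True

    letters = _compact_letters(order, distinct)
    table = pd.DataFrame(
        {"mean": means,
         "sd": [groups[t].std(ddof=1) for t in order],
         "n": [sizes[t] for t in order],
         "letters": letters},
        index=pd.Index(order, name="treatment"))
    return LetterAssignment(table=table, alpha=alpha, mse=mse,
                            df_error=df_err, f_stat=float(f_stat),
                            p_value=float(p_value))


def _rank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with midrank ties.

    p-value: t-approximation for n > 10, exhaustive permutation
    distribution (two-sided, counting ties as extreme) for n <= 10.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    n = len(x)
    if n < 4:
        raise ValueError("need >= 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    rx, ry = _rank(x), _rank(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n > EXACT_SPEARMAN_MAX_N:
        _, p = stats.spearmanr(x, y)
        return rho, float(p)
    # exact: permute one rank vector over all n! arrangements, in chunks
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c ** 2).sum() * (ry_c ** 2).sum())
    target = abs(rho) * denom - 1e-12
    count = 0
    chunk: list[tuple[int, ...]] = []
    perms = itertools.permutations(range(n))
    while True:
        chunk = list(itertools.islice(perms, 100_000))
        if not chunk:
            break
        dots = rx_c[np.asarray(chunk)] @ ry_c
        count += int(np.count_nonzero(np.abs(dots) >= target))
    return rho, count / factorial(n)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p.ravel(), method="fdr_bh")
    return adj.reshape(p.shape)
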