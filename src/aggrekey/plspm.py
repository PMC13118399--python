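"""Partial least squares path modeling (PLS-PM) and crucial-genus PC1 scores.

PLS-PM estimates latent variables as weighted sums of their observed
indicator blocks and directed path coefficients among the latents.  This
implementation follows the classical Lohmoller alternating algorithm with a
reflective ("mode A") outer model and, by default, the *path* inner
weighting scheme:

1. standardize all indicators; initialize outer weights at 1;
2. latent scores = standardized weighted indicator sums;
3. inner proxies: each latent's neighbors are combined with weights from
   the chosen scheme (path: OLS coefficients on predecessors plus
   correlations with successors; centroid: correlation signs; factorial:
   correlations);
4. mode-A outer-weight update: covariance of each indicator with its
   block's inner proxy;
5. iterate to convergence of the outer weights, then estimate path
   coefficients by OLS of each endogenous latent on its predecessors.

Goodness of fit is GOF = sqrt(mean communality x mean R^2), communality
being the squared indicator-latent loading.  Latent sign indeterminacy is
resolved by forcing a positive correlation with each block's first
indicator.  Total effects obey (I - B)^{-1} - I on the path-coefficient
matrix B.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class PathSpec:
    """Latent blocks and the acyclic inner relation.

    ``blocks`` maps latent name -> indicator column list (each indicator in
    exactly one block); ``inner`` lists directed (source, target) paths.
    """

    blocks: dict[str, tuple[str, ...]]
    inner: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, inds in self.blocks.items():
            if not inds:
                raise ValueError(f"block {name!r} has no indicators")
            overlap = seen & set(inds)
            if overlap:
                raise ValueError(f"indicators in more than one block: {sorted(overlap)}")
            seen |= set(inds)
        for s, t in self.inner:
            if s not in self.blocks or t not in self.blocks:
                raise ValueError(f"inner path references unknown latent: {(s, t)}")
        self.topological_order()  # raises on a cycle

    def predecessors(self, latent: str) -> list[str]:
        return [s for s, t in self.inner if t == latent]

    def successors(self, latent: str) -> list[str]:
        return [t for s, t in self.inner if s == latent]

    def endogenous(self) -> list[str]:
        return [l for l in self.blocks if self.predecessors(l)]

    def topological_order(self) -> list[str]:
        order, seen = [], set()

        def visit(node: str, stack: tuple[str, ...]) -> None:
            if node in stack:
                raise ValueError(f"inner relation contains a cycle through {node!r}")
            if node in seen:
                return
            for p in self.predecessors(node):
                visit(p, stack + (node,))
            seen.add(node)
            order.append(node)

        for latent in self.blocks:
            visit(latent, ())
        return order


@dataclass
class PathModel:
    """Fitted PLS path model."""

    spec: PathSpec
    scores: pd.DataFrame                 # samples x latents (unit variance)
    outer_weights: dict[str, pd.Series]  # per block
    loadings: dict[str, pd.Series]       # indicator-latent correlations
    path_matrix: pd.DataFrame            # B[target, source]
    path_table: pd.DataFrame             # long format: source, target, coefficient
    r_squared: dict[str, float]
    communality: pd.Series               # per indicator
    gof: float
    iterations: int
    converged: bool


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant indicator column")
    return (x - x.mean(axis=0)) / sd


def fit_plspm(data: pd.DataFrame, spec: PathSpec, scheme: str = "path",
              tol: float = 1e-7, max_iter: int = 300) -> PathModel:
    """Estimate a PLS path model from a per-sample indicator matrix."""
    if scheme not in ("path", "centroid", "factorial"):
        raise ValueError(f"unknown inner scheme {scheme!r}")
    missing = [c for block in spec.blocks.values() for c in block
               if c not in data.columns]
    if missing:
        raise ValueError(f"indicators missing from data: {missing}")
    if data.isna().any().any():
        raise ValueError("NaN in indicator data")

    latents = list(spec.blocks)
    n = len(data)
    blocks_x = {l: _standardize(data[list(spec.blocks[l])].to_numpy(float))
                for l in latents}
    weights = {l: np.ones(len(spec.blocks[l])) for l in latents}

    def latent_scores(w):
        y = {}
        for l in latents:
            raw = blocks_x[l] @ w[l]
            sd = raw.std(ddof=1)
            if sd == 0:
                raise ValueError(f"degenerate latent {l!r}")
            y[l] = raw / sd
        return y

    y = latent_scores(weights)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # inner proxies
        z = {}
        for l in latents:
            proxy = np.zeros(n)
            preds, succs = spec.predecessors(l), spec.successors(l)
            if not preds and not succs:
                proxy = y[l].copy()
            else:
                if preds:
                    yp = np.column_stack([y[p] for p in preds])
                    if scheme == "path":
                        coef, *_ = np.linalg.lstsq(yp, y[l], rcond=None)
                    elif scheme == "factorial":
                        coef = np.array([np.corrcoef(y[p], y[l])[0, 1] for p in preds])
                    else:
                        coef = np.sign([np.corrcoef(y[p], y[l])[0, 1] for p in preds])
                    proxy = proxy + yp @ coef
                for s in succs:
                    c = np.corrcoef(y[s], y[l])[0, 1]
                    proxy = proxy + (np.sign(c) if scheme == "centroid" else c) * y[s]
            z[l] = proxy
        # mode-A outer update: indicator-proxy covariances
        new_w = {}
        for l in latents:
            w = blocks_x[l].T @ z[l] / (n - 1)
            # scale so the latent has unit variance (makes weights comparable)
            raw = blocks_x[l] @ w
            sd = raw.std(ddof=1)
            if sd == 0:
                raise ValueError(f"degenerate latent {l!r}")
            new_w[l] = w / sd
        delta = max(np.max(np.abs(new_w[l] - weights[l] /
                                  (blocks_x[l] @ weights[l]).std(ddof=1)))
                    for l in latents)
        weights = new_w
        y = latent_scores(weights)
        if delta < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"PLS-PM did not converge in {max_iter} iterations (last delta {delta:.3g})")

    # sign convention: positive correlation with the block's first indicator
    for l in latents:
        c = np.corrcoef(blocks_x[l][:, 0], y[l])[0, 1]
        if c < 0:
            weights[l] = -weights[l]
            y[l] = -y[l]

    scores = pd.DataFrame({l: y[l] for l in latents}, index=data.index)

    # path coefficients by OLS per endogenous latent
    b = pd.DataFrame(0.0, index=latents, columns=latents)
    r2: dict[str, float] = {}
    rows = []
    for l in spec.endogenous():
        preds = spec.predecessors(l)
        yp = np.column_stack([y[p] for p in preds])
        gram = yp.T @ yp
        if np.linalg.matrix_rank(gram) < len(preds):
            raise ValueError(f"singular OLS for latent {l!r}")
        coef = np.linalg.solve(gram, yp.T @ y[l])
        fitted = yp @ coef
        r2[l] = float(1 - ((y[l] - fitted) ** 2).sum() / (y[l] ** 2).sum())
        for p, c in zip(preds, coef):
            b.loc[l, p] = c
            rows.append({"source": p, "target": l, "coefficient": float(c)})
    path_table = pd.DataFrame(rows, columns=["source", "target", "coefficient"])

    loadings = {}
    communality = {}
    for l in latents:
        load = pd.Series(
            [np.corrcoef(blocks_x[l][:, j], y[l])[0, 1]
             for j in range(blocks_x[l].shape[1])],
            index=list(spec.blocks[l]))
        loadings[l] = load
        for ind, v in load.items():
            communality[ind] = v ** 2
    communality = pd.Series(communality)
    gof = float(np.sqrt(communality.mean() * np.mean(list(r2.values()))))

    return PathModel(spec=spec, scores=scores,
                     outer_weights={l: pd.Series(weights[l],
                                                 index=list(spec.blocks[l]))
                                    for l in latents},
                     loadings=loadings, path_matrix=b, path_table=path_table,
                     r_squared=r2, communality=communality, gof=gof,
                     iterations=it, converged=converged)


def effects(model: PathModel) -> pd.DataFrame:
    """Direct / indirect / total effect of every latent on every descendant.

    total = sum over all directed paths of coefficient products, which
    equals ``(I - B)^{-1} - I`` on the path-coefficient matrix; indirect is
    total minus the direct path coefficient.
    """
    if model.path_matrix is None:
        raise ValueError("model not fitted")
    b = model.path_matrix.to_numpy()
    latents = list(model.path_matrix.index)
    total = np.linalg.inv(np.eye(len(latents)) - b) - np.eye(len(latents))
    rows = []
    for i, target in enumerate(latents):
        for j, source in enumerate(latents):
            if i == j:
                continue
            direct = b[i, j]
            tot = total[i, j]
            if direct == 0 and abs(tot) < 1e-14:
                continue
            rows.append({"source": source, "target": target,
                         "direct": float(direct),
                         "indirect": float(tot - direct),
                         "total": float(tot)})
    return pd.DataFrame(rows, columns=["source", "target", "direct",
                                       "indirect", "total"])


def bootstrap_paths(data: pd.DataFrame, spec: PathSpec, n_boot: int = 499,
                    seed: int | np.random.Generator = 0, scheme: str = "path",
                    tol: float = 1e-7, max_iter: int = 300) -> pd.DataFrame:
    """Percentile bootstrap CIs and two-sided p-values for path coefficients.

    Resamples with replacement; a resample with a zero-variance indicator
    is redrawn (counted in the ``redraws`` attribute of the frame).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    point = fit_plspm(data, spec, scheme=scheme, tol=tol, max_iter=max_iter)
    paths = [(r["source"], r["target"]) for _, r in point.path_table.iterrows()]
    draws = np.empty((n_boot, len(paths)))
    redraws = 0
    b = 0
    while b < n_boot:
        idx = rng.integers(0, len(data), len(data))
        sample = data.iloc[idx]
        try:
            fit = fit_plspm(sample, spec, scheme=scheme, tol=tol,
                            max_iter=max_iter)
        except (ValueError, RuntimeError):
            redraws += 1
            if redraws > 100 * n_boot:
                raise RuntimeError("bootstrap cannot find valid resamples")
            continue
        draws[b] = [fit.path_matrix.loc[t, s] for s, t in paths]
        b += 1
    rows = []
    for k, (s, t) in enumerate(paths):
        est = point.path_matrix.loc[t, s]
        col = draws[:, k] * np.sign(est) if est != 0 else draws[:, k]
        lo, hi = np.percentile(draws[:, k], [2.5, 97.5])
        opposite = np.sum(col <= 0)
        p = min(1.0, 2.0 * (1 + opposite) / (1 + n_boot))
        rows.append({"source": s, "target": t, "coefficient": float(est),
                     "ci_low": float(lo), "ci_high": float(hi),
                     "p_value": float(p)})
    out = pd.DataFrame(rows)
    out.attrs["redraws"] = redraws
    return out


@dataclass
class PCScores:
    """First-principal-component summary of the crucial-genera sub-matrix."""

    scores: pd.Series             # per sample, mean 0
    variance_explained: float     # fraction in (0, 1]
    loadings: pd.Series = field(default_factory=pd.Series)


def pc1_scores(abundances: pd.DataFrame, genera) -> PCScores:
    """PC1 of the column-standardized genus sub-matrix (genus x sample input).

    Constant genus rows are dropped with a warning; sign is fixed so the
    first retained genus loads positively.
    """
    import warnings

    genera = list(genera)
    if len(genera) < 2:
        raise ValueError("need >= 2 genera")
    sub = abundances.loc[genera].T  # samples x genera
    if len(sub) < 3:
        raise ValueError("need >= 3 samples")
    sd = sub.std(ddof=1)
    constant = list(sd.index[sd == 0])
    if constant:
        warnings.warn(f"dropping constant genera: {constant}")
        sub = sub.drop(columns=constant)
    if sub.shape[1] == 0:
        raise ValueError("all genus columns are constant")
    x = (sub - sub.mean()) / sub.std(ddof=1)
    u, s, vt = np.linalg.svd(x.to_numpy(), full_matrices=False)
    scores = u[:, 0] * s[0]
    load = vt[0]
    if load[0] < 0:
        scores, load = -scores, -load
    frac = float(s[0] ** 2 / np.sum(s ** 2))
    return PCScores(scores=pd.Series(scores, index=sub.index, name="PC1"),
                    variance_explained=frac,
                    loadings=pd.Series(load, index=sub.columns))
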