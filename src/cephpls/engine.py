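"""Generic partial least squares path modeling (PLS-PM).

A PLS path model couples an *outer* (measurement) model — each latent
variable (LV) is a weighted composite of its manifest variables (MVs) —
with an *inner* (structural) model, a directed acyclic graph of linear
relations among the LV scores.  Estimation follows the classical
Lohmoeller/Wold alternating algorithm: inner proxies are built from
adjacent LV scores under a weighting scheme (centroid, factorial or
path), outer weights are refreshed against the proxy (Mode A for
reflective blocks, Mode B for formative blocks), and the loop repeats
until the weights stabilise.  Because composites are variance-scaled,
every score is sign-indeterminate; after convergence each LV is oriented
so that its dominant loading is positive, and the applied flips are
recorded so callers can match any external sign convention.

Path coefficients are ordinary least squares fits of each endogenous LV
score on its predecessor scores (standardised variables, so intercepts
vanish), and the global goodness of fit is
``sqrt(mean(communality) * mean(R^2))`` in the Tenenhaus sense.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "BlockSpec",
    "InnerSpec",
    "PLSPMResult",
    "PLSPMError",
    "SingularBlockError",
    "ZeroVarianceError",
    "NonConvergenceWarning",
    "standardize",
    "validate_data_matrix",
    "fit",
    "path_coefficients",
    "ols_from_correlation",
    "quality_indices",
    "goodness_of_fit",
    "lv_correlation_matrix",
]

SCHEMES = ("centroid", "factorial", "path")
GOF_VARIANTS = ("all_mvs", "multi_mv_blocks")


class PLSPMError(ValueError):
    """Invalid model specification or data."""


class ZeroVarianceError(PLSPMError):
    """A column has no sample variance and cannot be standardised."""


class SingularBlockError(PLSPMError):
    """A formative block's within-block covariance is singular."""


class NonConvergenceWarning(UserWarning):
    """The alternating algorithm hit max_iter before the weights settled."""


# ---------------------------------------------------------------------------
# model specification


@dataclass(frozen=True)
class BlockSpec:
    """One measurement block: an LV and the MVs that define it.

    ``mode`` is ``"reflective"`` (Mode A: the LV is thought to cause its
    indicators; weights updated by correlation with the inner proxy) or
    ``"formative"`` (Mode B: the indicators form the LV; weights updated
    by within-block regression of the proxy on the MVs).  The same data
    column may legitimately appear in several blocks; each block treats
    it as its own indicator.
    """

    lv_name: str
    mv_names: tuple[str, ...]
    mode: str = "reflective"

    def __post_init__(self) -> None:
        object.__setattr__(self, "mv_names", tuple(self.mv_names))
        if not self.mv_names:
            raise PLSPMError(f"block {self.lv_name!r}: mv_names is empty")
        if len(set(self.mv_names)) != len(self.mv_names):
            raise PLSPMError(f"block {self.lv_name!r}: duplicate MV names")
        if self.mode not in ("formative", "reflective"):
            raise PLSPMError(
                f"block {self.lv_name!r}: mode must be formative or reflective,"
                f" got {self.mode!r}"
            )


@dataclass(frozen=True)
class InnerSpec:
    """The structural model: a DAG over LV names."""

    lv_names: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "lv_names", tuple(self.lv_names))
        object.__setattr__(
            self, "edges", tuple((str(a), str(b)) for a, b in self.edges)
        )
        if len(set(self.lv_names)) != len(self.lv_names):
            raise PLSPMError("duplicate LV names in inner model")
        known = set(self.lv_names)
        for a, b in self.edges:
            if a not in known or b not in known:
                raise PLSPMError(f"inner edge ({a}, {b}) references unknown LV")
            if a == b:
                raise PLSPMError(f"self-loop on {a!r}")
        if len(set(self.edges)) != len(self.edges):
            raise PLSPMError("duplicate inner edges")
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            raise PLSPMError("inner model contains a cycle")
        if not self.endogenous():
            raise PLSPMError("inner model has no endogenous LV (no edges)")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.lv_names)
        g.add_edges_from(self.edges)
        return g

    def predecessors(self, lv: str) -> tuple[str, ...]:
        return tuple(a for a, b in self.edges if b == lv)

    def successors(self, lv: str) -> tuple[str, ...]:
        return tuple(b for a, b in self.edges if a == lv)

    def neighbors(self, lv: str) -> tuple[str, ...]:
        seen: list[str] = []
        for a, b in self.edges:
            other = b if a == lv else a if b == lv else None
            if other is not None and other not in seen:
                seen.append(other)
        return tuple(seen)

    def endogenous(self) -> tuple[str, ...]:
        return tuple(lv for lv in self.lv_names if self.predecessors(lv))

    def exogenous(self) -> tuple[str, ...]:
        return tuple(lv for lv in self.lv_names if not self.predecessors(lv))


# ---------------------------------------------------------------------------
# result container


@dataclass
class PLSPMResult:
    """Everything a fitted PLS path model reports.

    Per-MV quantities are keyed by (LV, MV) through per-block Series; the
    identities ``communality == loading**2`` and
    ``redundancy == communality * R2(own LV)`` hold to numerical
    round-off by construction.  ``orientation`` records the sign flip
    (+1/−1) applied to each LV by the canonicalisation rule (dominant
    loading positive), so scores can be flipped back to match an external
    sign convention.
    """

    blocks: tuple[BlockSpec, ...]
    inner: InnerSpec
    scheme: str
    outer_weights: dict[str, pd.Series]
    loadings: dict[str, pd.Series]
    communalities: dict[str, pd.Series]
    redundancies: dict[str, pd.Series]
    lv_scores: pd.DataFrame
    lv_correlations: pd.DataFrame
    path_coefficients: dict[str, pd.Series]
    r_squared: dict[str, float]
    gof: float
    gof_all_mvs: float
    gof_multi_mv_blocks: float
    gof_variant: str
    orientation: dict[str, int]
    iterations: int
    converged: bool

    def block(self, lv_name: str) -> BlockSpec:
        for b in self.blocks:
            if b.lv_name == lv_name:
                return b
        raise KeyError(lv_name)

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "blocks": {
                b.lv_name: {
                    "mode": b.mode,
                    "mvs": {
                        mv: {
                            "weight": float(self.outer_weights[b.lv_name][mv]),
                            "loading": float(self.loadings[b.lv_name][mv]),
                            "communality": float(self.communalities[b.lv_name][mv]),
                            "redundancy": float(self.redundancies[b.lv_name][mv]),
                        }
                        for mv in b.mv_names
                    },
                }
                for b in self.blocks
            },
            "inner": {
                lv: {
                    "paths": {
                        p: float(c) for p, c in self.path_coefficients[lv].items()
                    },
                    "r2": float(self.r_squared[lv]),
                }
                for lv in self.inner.endogenous()
            },
            "lv_correlations": {
                lv: [float(v) for v in self.lv_correlations.loc[lv]]
                for lv in self.lv_correlations.index
            },
            "global": {
                "gof": float(self.gof),
                "gof_variant": self.gof_variant,
                "gof_all_mvs": float(self.gof_all_mvs),
                "gof_multi_mv_blocks": float(self.gof_multi_mv_blocks),
                "iterations": self.iterations,
                "converged": self.converged,
                "orientation": dict(self.orientation),
            },
        }

    def to_json(self, path=None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


# ---------------------------------------------------------------------------
# basic numerics


def validate_data_matrix(X: pd.DataFrame) -> None:
    """Check the DataMatrix contract: numeric, complete, >=3 rows, unique
    column names, every column with nonzero sample variance."""
    if not isinstance(X, pd.DataFrame):
        raise PLSPMError("data matrix must be a pandas DataFrame")
    if X.shape[0] < 3:
        raise PLSPMError(f"need at least 3 rows, got {X.shape[0]}")
    if X.columns.duplicated().any():
        dupes = X.columns[X.columns.duplicated()].tolist()
        raise PLSPMError(f"duplicate column names: {dupes}")
    values = X.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise PLSPMError("data matrix contains missing or non-finite values")
    sd = values.std(axis=0, ddof=1)
    for name, s in zip(X.columns, sd):
        if s == 0.0 or not np.isfinite(s):
            raise ZeroVarianceError(f"column {name!r} has zero sample variance")


def standardize(X: pd.DataFrame) -> pd.DataFrame:
    """Column-wise (x - mean) / sd with the n-1 variance denominator."""
    values = X.to_numpy(dtype=float)
    sd = values.std(axis=0, ddof=1)
    for name, s in zip(X.columns, sd):
        if s == 0.0 or not np.isfinite(s):
            raise ZeroVarianceError(f"column {name!r} has zero sample variance")
    out = (values - values.mean(axis=0)) / sd
    return pd.DataFrame(out, index=X.index, columns=X.columns)


def _std_scores(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std(ddof=1)


# ---------------------------------------------------------------------------
# the alternating algorithm


def fit(
    X: pd.DataFrame,
    blocks: Sequence[BlockSpec],
    inner: InnerSpec,
    scheme: str = "centroid",
    tol: float = 1e-6,
    max_iter: int = 300,
    gof_variant: str = "all_mvs",
) -> PLSPMResult:
    """Estimate a PLS path model.

    Parameters
    ----------
    X : DataFrame
        Patients x manifest variables, complete and numeric.
    blocks : sequence of BlockSpec
        One per LV; MV names must be columns of ``X``.
    inner : InnerSpec
        Structural DAG over exactly the block LV names.
    scheme : {"centroid", "factorial", "path"}
        Inner weighting scheme (centroid is the classical default).
    tol, max_iter :
        Convergence is declared when the largest outer-weight change
        falls below ``tol``; otherwise the result is flagged
        ``converged=False`` with a :class:`NonConvergenceWarning`.
    gof_variant : {"all_mvs", "multi_mv_blocks"}
        Which blocks contribute communalities to the reported ``gof``
        (single-MV blocks have communality 1 by construction and can be
        excluded).  Both variants are always computed.
    """
    if scheme not in SCHEMES:
        raise PLSPMError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    if gof_variant not in GOF_VARIANTS:
        raise PLSPMError(f"unknown gof variant {gof_variant!r}")
    if tol <= 0:
        raise PLSPMError("tol must be positive")
    validate_data_matrix(X)

    blocks = tuple(blocks)
    block_lvs = [b.lv_name for b in blocks]
    if len(set(block_lvs)) != len(block_lvs):
        raise PLSPMError("duplicate LV across blocks")
    if set(block_lvs) != set(inner.lv_names):
        raise PLSPMError(
            f"block LVs {sorted(block_lvs)} do not match inner LVs"
            f" {sorted(inner.lv_names)}"
        )
    for b in blocks:
        missing = [mv for mv in b.mv_names if mv not in X.columns]
        if missing:
            raise PLSPMError(f"block {b.lv_name!r}: MVs not in data: {missing}")

    n = X.shape[0]
    largest_formative = max(
        (len(b.mv_names) for b in blocks if b.mode == "formative"), default=0
    )
    if n <= largest_formative:
        raise PLSPMError(
            f"n={n} rows is too small for a formative block of size"
            f" {largest_formative}"
        )

    order = list(inner.lv_names)
    by_name = {b.lv_name: b for b in blocks}
    blocks = tuple(by_name[lv] for lv in order)  # canonical order

    Z = standardize(X)
    Xb = {b.lv_name: Z[list(b.mv_names)].to_numpy() for b in blocks}

    # Formative blocks need an invertible within-block covariance; it is
    # constant across iterations, so check once.
    gram: dict[str, np.ndarray] = {}
    for b in blocks:
        G = Xb[b.lv_name].T @ Xb[b.lv_name] / (n - 1)
        if b.mode == "formative":
            if np.linalg.cond(G) > 1e10:
                raise SingularBlockError(
                    f"formative block {b.lv_name!r} has a singular or"
                    " near-singular within-block covariance"
                )
        gram[b.lv_name] = G

    weights = {b.lv_name: np.ones(len(b.mv_names)) for b in blocks}
    scores = {}
    for b in blocks:
        y = Xb[b.lv_name] @ weights[b.lv_name]
        s = y.std(ddof=1)
        weights[b.lv_name] = weights[b.lv_name] / s
        scores[b.lv_name] = y / s

    neighbors = {lv: inner.neighbors(lv) for lv in order}
    preds = {lv: inner.predecessors(lv) for lv in order}
    succs = {lv: inner.successors(lv) for lv in order}

    iterations = 0
    converged = False
    for iterations in range(1, max_iter + 1):
        Y = np.column_stack([scores[lv] for lv in order])
        R = np.corrcoef(Y, rowvar=False)
        if R.ndim == 0:  # single LV cannot happen (needs an edge) but be safe
            R = np.array([[1.0]])
        idx = {lv: i for i, lv in enumerate(order)}

        proxies = {}
        for lv in order:
            z = np.zeros(n)
            if scheme == "path":
                if preds[lv]:
                    P = np.column_stack([scores[p] for p in preds[lv]])
                    beta, *_ = np.linalg.lstsq(P, scores[lv], rcond=None)
                    z = z + P @ beta
                for srt in succs[lv]:
                    z = z + R[idx[lv], idx[srt]] * scores[srt]
            else:
                for other in neighbors[lv]:
                    r = R[idx[lv], idx[other]]
                    e = np.sign(r) if scheme == "centroid" else r
                    if e == 0.0:  # rare exact-zero correlation: keep the LV in
                        e = 1.0
                    z = z + e * scores[other]
            proxies[lv] = z

        max_delta = 0.0
        for b in blocks:
            lv = b.lv_name
            Xj = Xb[lv]
            z = proxies[lv]
            if b.mode == "reflective":
                w = Xj.T @ z / (n - 1)
            else:
                w = np.linalg.solve(gram[lv], Xj.T @ z / (n - 1))
            y = Xj @ w
            s = y.std(ddof=1)
            w = w / s
            y = y / s
            max_delta = max(max_delta, float(np.abs(w - weights[lv]).max()))
            weights[lv] = w
            scores[lv] = y
        if max_delta < tol:
            converged = True
            break

    if not converged:
        warnings.warn(
            f"PLS-PM did not converge in {max_iter} iterations"
            f" (last max weight change {max_delta:.3g})",
            NonConvergenceWarning,
            stacklevel=2,
        )

    # loadings, sign canonicalisation (dominant loading positive)
    loadings: dict[str, pd.Series] = {}
    orientation: dict[str, int] = {}
    for b in blocks:
        lv = b.lv_name
        lam = Xb[lv].T @ scores[lv] / (n - 1)
        flip = 1
        if lam[np.argmax(np.abs(lam))] < 0:
            flip = -1
            lam = -lam
            weights[lv] = -weights[lv]
            scores[lv] = -scores[lv]
        orientation[lv] = flip
        loadings[lv] = pd.Series(lam, index=list(b.mv_names), name=lv)

    lv_scores = pd.DataFrame(
        {lv: scores[lv] for lv in order}, index=X.index, columns=order
    )
    lv_corr = lv_correlation_matrix(lv_scores)

    paths, r2 = path_coefficients(lv_scores, inner)

    communalities = {lv: loadings[lv] ** 2 for lv in order}
    redundancies = {}
    endo = set(inner.endogenous())
    for b in blocks:
        lv = b.lv_name
        factor = r2[lv] if lv in endo else 0.0
        redundancies[lv] = communalities[lv] * factor

    comm_all = [float(c) for lv in order for c in communalities[lv]]
    comm_multi = [
        float(c)
        for b in blocks
        if len(b.mv_names) > 1
        for c in communalities[b.lv_name]
    ]
    r2_list = [r2[lv] for lv in inner.endogenous()]
    gof_all = goodness_of_fit(comm_all, r2_list)
    gof_multi = goodness_of_fit(comm_multi or comm_all, r2_list)
    gof = gof_all if gof_variant == "all_mvs" else gof_multi

    return PLSPMResult(
        blocks=blocks,
        inner=inner,
        scheme=scheme,
        outer_weights={
            b.lv_name: pd.Series(
                weights[b.lv_name], index=list(b.mv_names), name=b.lv_name
            )
            for b in blocks
        },
        loadings=loadings,
        communalities=communalities,
        redundancies=redundancies,
        lv_scores=lv_scores,
        lv_correlations=lv_corr,
        path_coefficients=paths,
        r_squared=r2,
        gof=gof,
        gof_all_mvs=gof_all,
        gof_multi_mv_blocks=gof_multi,
        gof_variant=gof_variant,
        orientation=orientation,
        iterations=iterations,
        converged=converged,
    )


def path_coefficients(
    scores: pd.DataFrame, inner: InnerSpec
) -> tuple[dict[str, pd.Series], dict[str, float]]:
    """Standardised OLS of each endogenous LV score on its predecessors.

    Scores are assumed standardised (mean 0, variance 1), so the
    intercept is structurally zero and R^2 is one minus the residual sum
    of squares over n-1.
    """
    paths: dict[str, pd.Series] = {}
    r2: dict[str, float] = {}
    n = scores.shape[0]
    for lv in inner.endogenous():
        pred = list(inner.predecessors(lv))
        P = scores[pred].to_numpy()
        y = scores[lv].to_numpy()
        G = P.T @ P
        if np.linalg.cond(G) > 1e10:
            raise PLSPMError(
                f"predecessor scores of {lv!r} are collinear: {pred}"
            )
        beta = np.linalg.solve(G, P.T @ y)
        resid = y - P @ beta
        r2[lv] = float(1.0 - (resid @ resid) / (n - 1))
        paths[lv] = pd.Series(beta, index=pred, name=lv)
    return paths, r2


def ols_from_correlation(
    corr: pd.DataFrame,
    response: str,
    predictors: Sequence[str],
) -> tuple[pd.Series, float, float]:
    """Standardised regression read off a correlation matrix.

    Solves the normal equations ``R_xx beta = r_xy`` and returns
    ``(beta, R2, cond)`` where ``R2 = r_xy' R_xx^{-1} r_xy`` and ``cond``
    is the condition number of the predictor submatrix — callers should
    treat individual coefficients with suspicion when it is large
    (rounded published correlation matrices easily produce condition
    numbers in the hundreds).
    """
    predictors = list(predictors)
    labels = [response, *predictors]
    missing = [l for l in labels if l not in corr.index or l not in corr.columns]
    if missing:
        raise PLSPMError(f"labels not in correlation matrix: {missing}")
    M = corr.loc[labels, labels].to_numpy(dtype=float)
    if not np.allclose(np.diag(corr.to_numpy(dtype=float)), 1.0, atol=1e-8):
        raise PLSPMError("correlation matrix must have a unit diagonal")
    if not np.allclose(M, M.T, atol=1e-8):
        raise PLSPMError("correlation matrix must be symmetric")
    Rxx = corr.loc[predictors, predictors].to_numpy(dtype=float)
    rxy = corr.loc[predictors, response].to_numpy(dtype=float)
    cond = float(np.linalg.cond(Rxx))
    if cond > 1e12:
        raise PLSPMError(
            f"predictor correlation submatrix is singular (cond={cond:.3g})"
        )
    beta = np.linalg.solve(Rxx, rxy)
    r2 = float(rxy @ beta)
    return pd.Series(beta, index=predictors, name=response), r2, cond


def quality_indices(
    result: PLSPMResult,
) -> tuple[dict[str, pd.Series], dict[str, pd.Series]]:
    """Recompute (communalities, redundancies) from a fitted result.

    communality(MV) = loading^2; redundancy(MV) = communality x R^2 of
    the MV's own LV when that LV is endogenous, else 0.
    """
    endo = set(result.inner.endogenous())
    comm = {lv: result.loadings[lv] ** 2 for lv in result.inner.lv_names}
    red = {
        lv: comm[lv] * (result.r_squared[lv] if lv in endo else 0.0)
        for lv in result.inner.lv_names
    }
    return comm, red


def goodness_of_fit(
    communalities: Iterable[float],
    r_squared: Iterable[float],
    variant: str | None = None,
) -> float:
    """Tenenhaus global GoF: sqrt(mean(communality) x mean(R^2)).

    ``variant`` is accepted for interface symmetry; callers that want the
    multi-MV-block restriction pass the already-filtered communality
    list (the engine computes both variants on every fit).
    """
    comm = [float(c) for c in communalities]
    r2 = [float(r) for r in r_squared]
    if not comm or not r2:
        raise PLSPMError("goodness_of_fit needs nonempty communality and R2 lists")
    for v in comm + r2:
        if not (0.0 <= v <= 1.0 + 1e-12):
            raise PLSPMError(f"GoF inputs must lie in [0, 1], got {v}")
    return float(np.sqrt(np.mean(comm) * np.mean(r2)))


def lv_correlation_matrix(scores: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations among LV score columns (unit diagonal,
    exactly symmetric)."""
    R = np.corrcoef(scores.to_numpy(), rowvar=False)
    R = np.atleast_2d(R)
    R = (R + R.T) / 2.0
    np.fill_diagonal(R, 1.0)
    return pd.DataFrame(R, index=scores.columns, columns=scores.columns)
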