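"""Pairwise mixed graphical model estimation by nodewise penalized regression.

Each node of a stratum (8 continuous subscale scores + 1 dichotomous
child-sex variable) is regressed on all others with an L1 penalty: Gaussian
(lasso) regressions for continuous nodes, penalized logistic regression for
the dichotomous node.  The penalty weight is chosen per node by 10-fold
cross-validation over a log-spaced grid, followed by a threshold of order
sqrt(log p / n) on the standardized coefficients that suppresses the small
spurious coefficients cross-validation is known to admit -- this is what
keeps the false-positive rate of the resulting network low.  Edges are then
aggregated with the conservative AND rule: an (i, j) edge exists only when
each node selects the other, its weight being the mean of the two absolute
standardized coefficients and, for continuous-continuous pairs, its sign
their shared sign.

This is the pairwise (k = 2) mixed Markov-random-field estimator of the
psychometric-network literature: a missing edge means conditional
independence of the two variables given all others.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold

from ._solvers import lasso_path_gram, logistic_l1_path
from .data_model import SEX_COLUMN, NetworkModel, Stratum


@dataclass
class MGMConfig:
    """Tuning knobs for nodewise estimation.

    folds: CV folds (default 10).  n_lambdas/lambda_min_ratio: the penalty
    grid runs over ``n_lambdas`` log-spaced values from lambda_max (smallest
    penalty zeroing every coefficient) down to ``lambda_min_ratio *
    lambda_max``.  rule: 'and' (conservative, default) or 'or' edge
    aggregation.  threshold_scale: the post-CV coefficient threshold is
    ``threshold_scale * sqrt(log(p) / n)``; 0 disables it.  min_n: smallest
    stratum size accepted.
    """

    folds: int = 10
    n_lambdas: int = 50
    lambda_min_ratio: float = 1e-3
    rule: str = "and"
    threshold_scale: float = 1.0
    min_n: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.rule not in ("and", "or"):
            raise ValueError("rule must be 'and' or 'or'")


@dataclass
class NodewiseFit:
    """One node's penalized regression on all other nodes."""

    node: str
    node_type: str  # "continuous" | "categorical"
    lambda_selected: float
    coefficients: dict[str, float]  # neighbor -> standardized coefficient
    cv_curve: dict[float, float]  # lambda -> mean held-out loss
    isolated_reason: str | None = None

    def support(self) -> set[str]:
        return {k for k, v in self.coefficients.items() if v != 0.0}


@dataclass
class PredictabilityTable:
    """Per-node predictability: R2 for continuous nodes, CC/nCC/CCmarg for
    the categorical node, all in [0, 1]."""

    table: pd.DataFrame  # index: node; columns: R2, CC, nCC, CCmarg

    def r2(self, node: str) -> float:
        return float(self.table.loc[node, "R2"])


def _lambda_grid(y: np.ndarray, X: np.ndarray, node_type: str, config: MGMConfig) -> np.ndarray:
    n = len(y)
    if node_type == "continuous":
        lam_max = np.max(np.abs(X.T @ y)) / n
    else:
        lam_max = np.max(np.abs(X.T @ (y - y.mean()))) / n
    lam_max = max(lam_max, 1e-12)
    return np.geomspace(lam_max, lam_max * config.lambda_min_ratio, config.n_lambdas)


def _gaussian_fit(y: np.ndarray, X: np.ndarray, lam: float) -> np.ndarray:
    """Lasso coefficients at penalty ``lam`` (1/(2n) squared loss scaling,
    intercept via centering); lam = 0 is the least-squares limit."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    if lam <= 0:
        coef, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
        return coef
    return lasso_path_gram(Xc, yc, np.array([lam]))[:, 0]


def _logistic_fit(y: np.ndarray, X: np.ndarray, lam: float) -> tuple[np.ndarray, float]:
    """L1 logistic (coefficients, unpenalized intercept) at penalty ``lam``."""
    coefs, b0s = logistic_l1_path(X, y, np.array([max(lam, 0.0)]))
    return coefs[:, 0], float(b0s[0])


def cross_validate_lambda(
    y: np.ndarray,
    X: np.ndarray,
    node_type: str,
    predictor_labels: Sequence[str],
    node: str = "y",
    config: MGMConfig | None = None,
) -> NodewiseFit:
    """Select the penalty by K-fold CV and refit on the full data.

    Held-out loss is mean squared error for continuous nodes and mean
    logistic deviance for the categorical node; the grid minimizer is
    selected (no one-standard-error rule), then coefficients below the
    sqrt(log p / n) threshold are zeroed.
    """
    config = config or MGMConfig()
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p_other = X.shape
    if n < config.folds:
        raise ValueError(
            f"n = {n} < folds = {config.folds}; use fewer folds for this stratum"
        )
    if node_type == "categorical" and len(np.unique(y)) < 2:
        return NodewiseFit(
            node, node_type, 0.0, {l: 0.0 for l in predictor_labels}, {},
            isolated_reason="constant categorical node",
        )
    grid = _lambda_grid(y, X, node_type, config)
    kf = KFold(n_splits=config.folds, shuffle=True, random_state=config.seed)
    losses = np.zeros(len(grid))
    for tr, te in kf.split(X):
        if node_type == "continuous":
            Xm = X[tr].mean(axis=0)
            ym = y[tr].mean()
            coefs = lasso_path_gram(X[tr] - Xm, y[tr] - ym, grid)
            pred = (X[te] - Xm) @ coefs + ym
            losses += ((pred - y[te][:, None]) ** 2).mean(axis=0)
        else:
            if len(np.unique(y[tr])) < 2:
                continue  # fold uninformative; contributes no loss
            coefs, b0s = logistic_l1_path(X[tr], y[tr], grid)
            eta = X[te] @ coefs + b0s[None, :]
            for k in range(len(grid)):
                losses[k] += _deviance(y[te], eta[:, k])
    losses /= config.folds
    k_sel = int(np.argmin(losses))
    lam_sel = float(grid[k_sel])
    if node_type == "continuous":
        coef = _gaussian_fit(y, X, lam_sel)
    else:
        coef, _ = _logistic_fit(y, X, lam_sel)
    tau = config.threshold_scale * math.sqrt(math.log(p_other + 1) / n)
    coef = np.where(np.abs(coef) < tau, 0.0, coef)
    return NodewiseFit(
        node=node,
        node_type=node_type,
        lambda_selected=lam_sel,
        coefficients={l: float(c) for l, c in zip(predictor_labels, coef)},
        cv_curve={float(l): float(v) for l, v in zip(grid, losses)},
    )


def _deviance(y: np.ndarray, eta: np.ndarray) -> float:
    """Mean logistic deviance (negative log-likelihood x 2)."""
    eta = np.clip(eta, -30, 30)
    ll = y * eta - np.log1p(np.exp(eta))
    return float(-2.0 * np.mean(ll))


def aggregate_and_rule(
    fits: Sequence[NodewiseFit],
    stratum_tag: tuple[str, str] | None = None,
    n: int = 0,
    rule: str = "and",
) -> NetworkModel:
    """Combine the nodewise fits into one undirected network.

    AND rule: edge (i, j) requires a nonzero coefficient in both directions;
    OR rule: in either.  Weight = mean of the two absolute coefficients
    (using 0 for a missing direction under OR).  Continuous-continuous edges
    take the shared sign; a sign conflict drops the edge onto the
    ``sign_conflicts`` list.  Edges at the categorical node are unsigned.
    """
    labels = [f.node for f in fits]
    types = {f.node: f.node_type for f in fits}
    idx = {l: i for i, l in enumerate(labels)}
    p = len(labels)
    coef = np.zeros((p, p))
    for f in fits:
        for nb, c in f.coefficients.items():
            coef[idx[f.node], idx[nb]] = c
    W = np.zeros((p, p))
    conflicts: list[tuple[str, str]] = []
    for i in range(p):
        for j in range(i + 1, p):
            a, b = coef[i, j], coef[j, i]
            if rule == "and":
                present = a != 0 and b != 0
            else:
                present = a != 0 or b != 0
            if not present:
                continue
            mag = (abs(a) + abs(b)) / 2.0
            if types[labels[i]] == "continuous" and types[labels[j]] == "continuous":
                sa, sb = np.sign(a), np.sign(b)
                if sa != 0 and sb != 0 and sa != sb:
                    conflicts.append((labels[i], labels[j]))
                    continue
                sign = sa if sa != 0 else sb
                W[i, j] = W[j, i] = sign * mag
            else:
                W[i, j] = W[j, i] = mag
    return NetworkModel(
        node_labels=labels,
        weights=W,
        node_types=[types[l] for l in labels],
        stratum=stratum_tag,
        n=n,
        sign_conflicts=conflicts,
    )


def _standardize(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Z-score columns; constant columns become all-zero (flagged by sd 0)."""
    mu = M.mean(axis=0)
    sd = M.std(axis=0)
    Z = np.zeros_like(M, dtype=float)
    ok = sd > 0
    Z[:, ok] = (M[:, ok] - mu[ok]) / sd[ok]
    return Z, sd


def estimate_stratum_network(
    stratum: Stratum, config: MGMConfig | None = None
) -> tuple[NetworkModel, list[NodewiseFit]]:
    """Estimate the mixed graphical model of one role x time stratum.

    Predictors are z-scored within the stratum; Gaussian regressions are run
    for the 8 subscale nodes (on z-scored responses) and a penalized
    logistic regression for the dichotomous child-sex node.  Constant
    columns yield isolated nodes with a warning.  Deterministic given
    ``config.seed`` (CV fold assignment).
    """
    config = config or MGMConfig()
    M = np.asarray(stratum.data, float)
    n = M.shape[0]
    if n < config.min_n:
        raise ValueError(f"stratum n = {n} below configured minimum {config.min_n}")
    labels = list(stratum.columns)
    types = ["categorical" if l == SEX_COLUMN else "continuous" for l in labels]
    Z, sd = _standardize(M)
    fits: list[NodewiseFit] = []
    for i, (lab, typ) in enumerate(zip(labels, types)):
        others = [j for j in range(len(labels)) if j != i]
        other_labels = [labels[j] for j in others]
        if sd[i] == 0:
            warnings.warn(f"node {lab} is constant in stratum; isolating it")
            fits.append(
                NodewiseFit(lab, typ, 0.0, {l: 0.0 for l in other_labels}, {},
                            isolated_reason="constant column")
            )
            continue
        X = Z[:, others]
        y = Z[:, i] if typ == "continuous" else M[:, i]
        node_config = MGMConfig(**{**config.__dict__, "seed": _node_seed(config.seed, i)})
        fits.append(
            cross_validate_lambda(y, X, typ, other_labels, node=lab, config=node_config)
        )
    net = aggregate_and_rule(
        fits, stratum_tag=(stratum.parent_role, stratum.time_point), n=n, rule=config.rule
    )
    return net, fits


def _node_seed(seed: int, node_index: int) -> int:
    return int(np.random.SeedSequence([seed, node_index]).generate_state(1)[0] % (2**31))


def predictability(fits: Sequence[NodewiseFit], stratum: Stratum) -> PredictabilityTable:
    """How well each node is predicted by its selected neighbors.

    Continuous nodes: in-sample R2 of an unpenalized refit on the selected
    support (clamped to [0, 1]); an isolated node scores 0.  Categorical
    node: correct classification CC of an unpenalized logistic refit,
    marginal (majority-class) accuracy CCmarg, and normalized accuracy
    nCC = (CC - CCmarg) / (1 - CCmarg), floored at 0.
    """
    M = np.asarray(stratum.data, float)
    labels = list(stratum.columns)
    idx = {l: i for i, l in enumerate(labels)}
    Z, sd = _standardize(M)
    rows = {}
    for f in fits:
        sel = sorted(f.support(), key=idx.__getitem__)
        cols = [idx[l] for l in sel]
        if f.node_type == "continuous":
            y = M[:, idx[f.node]]
            if not cols or np.var(y) == 0:
                r2 = 0.0
            else:
                X = np.column_stack([np.ones(len(y)), Z[:, cols]])
                beta, *_ = np.linalg.lstsq(X, y, rcond=None)
                resid = y - X @ beta
                r2 = 1.0 - resid.var() / y.var()
            rows[f.node] = {"R2": float(np.clip(r2, 0.0, 1.0)),
                            "CC": np.nan, "nCC": np.nan, "CCmarg": np.nan}
        else:
            y = M[:, idx[f.node]]
            counts = np.bincount(y.astype(int), minlength=2)
            ccmarg = counts.max() / len(y)
            if not cols or len(np.unique(y)) < 2:
                cc = ccmarg
            else:
                model = LogisticRegression(C=np.inf, max_iter=5_000)
                model.fit(Z[:, cols], y)
                cc = float(model.score(Z[:, cols], y))
            ncc = 0.0 if ccmarg >= 1.0 else max(0.0, (cc - ccmarg) / (1.0 - ccmarg))
            rows[f.node] = {"R2": np.nan, "CC": float(cc), "nCC": float(ncc),
                            "CCmarg": float(ccmarg)}
    table = pd.DataFrame.from_dict(rows, orient="index")[["R2", "CC", "nCC", "CCmarg"]]
    table = table.reindex([f.node for f in fits])
    return PredictabilityTable(table)
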