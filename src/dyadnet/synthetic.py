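"""Synthetic dyadic-cohort generator with planted conditional-dependence structure.

Real parental-distress questionnaire data of this kind is typically private,
so the analysis pipeline is exercised on simulated cohorts whose generative
model realizes exactly the structure the estimator assumes: per-stratum
Gaussian graphical models over the 8 continuous subscales (sparse precision
matrices = planted partial-correlation graphs), an exogenous dichotomous
child-sex variable entering designated nodes as a location shift, couple-level
(dyadic) and lag-1 temporal (AR(1)) coupling of the latent residuals, and
round-and-clamp discretization to bounded integer scores.

The default cohort emulates the study design being modelled: 23 enrolled
couples, 7 fathers lost after the first assessment (their partners excluded
by the complete-case filter), leaving 16 complete dyads at 3 time points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    CSV_HEADER,
    DEFAULT_SCALE_RANGES,
    ROLES,
    SEX_COLUMN,
    SUBSCALES,
    TIME_POINTS,
    CohortTable,
)

#: Latent values are mapped affinely from this symmetric range (in latent SD
#: units) onto [0, scale_max] before rounding; +-3 SD covers ~99.7% of draws.
LATENT_RANGE: tuple[float, float] = (-3.0, 3.0)

StratumKey = tuple[str, str]  # (parent_role, time_point)


class NotPositiveDefiniteError(ValueError):
    pass


def build_precision(
    edges: Sequence[tuple[int, int, float]],
    base_diag: float = 1.0,
    p: int = 8,
) -> np.ndarray:
    """Build an SPD precision matrix with prescribed partial correlations.

    For a Gaussian graphical model the partial correlation of nodes i, j
    given the rest is ``-omega_ij / sqrt(omega_ii * omega_jj)``; with unit
    diagonal (scaled by ``base_diag``) an off-diagonal entry of ``-r`` plants
    partial correlation ``r`` exactly.

    Raises :class:`NotPositiveDefiniteError` if the requested pattern is not
    positive definite (suggest smaller magnitudes).
    """
    omega = np.eye(p) * base_diag
    for i, j, r in edges:
        if not abs(r) < 1:
            raise ValueError(f"partial correlation must be in (-1, 1), got {r}")
        if i == j:
            raise ValueError("self edges are not allowed")
        omega[i, j] = omega[j, i] = -r * base_diag
    eigmin = float(np.linalg.eigvalsh(omega).min())
    if eigmin <= 1e-10:
        raise NotPositiveDefiniteError(
            f"requested edge pattern is not positive definite (min eigenvalue "
            f"{eigmin:.3g}); use smaller partial-correlation magnitudes"
        )
    return omega


def partial_correlations(precision: np.ndarray) -> np.ndarray:
    """Partial-correlation matrix implied by a precision matrix (unit diagonal)."""
    d = np.sqrt(np.diag(precision))
    pc = -precision / np.outer(d, d)
    np.fill_diagonal(pc, 1.0)
    return pc


def chain_precision(r: float = 0.3, p: int = 8) -> np.ndarray:
    """Chain graph 0-1-2-...-(p-1) with constant partial correlation ``r``."""
    return build_precision([(i, i + 1, r) for i in range(p - 1)], p=p)


def _default_precisions() -> dict[StratumKey, np.ndarray]:
    """Default planted structure, differing by role and time.

    Both roles share a symptom chain (Anxiety-Depression-Somatisation-
    Hostility), a well-being chain (Relaxation-Contentedness-
    PhysicalWellBeing-Friendliness) and a negative Anxiety-Relaxation
    bridge; the Anxiety-Depression coupling relaxes over time (acute
    distress settling), and mothers carry an extra Anxiety-Somatisation
    edge.  Magnitudes are free parameters of the simulation, not estimates
    of any real cohort.
    """
    out: dict[StratumKey, np.ndarray] = {}
    ad_by_time = {"t1": 0.35, "t2": 0.30, "t3": 0.25}
    for role in ROLES:
        for t in TIME_POINTS:
            edges = [
                (0, 1, ad_by_time[t]),  # Anxiety-Depression
                (1, 2, 0.25),  # Depression-Somatisation
                (2, 3, 0.25),  # Somatisation-Hostility
                (4, 5, 0.30),  # Relaxation-Contentedness
                (5, 6, 0.25),  # Contentedness-PhysicalWellBeing
                (6, 7, 0.25),  # PhysicalWellBeing-Friendliness
                (0, 4, -0.25),  # Anxiety-Relaxation bridge
            ]
            if role == "mother":
                edges.append((0, 2, 0.20))  # Anxiety-Somatisation
            out[(role, t)] = build_precision(edges)
    return out


@dataclass
class SyntheticSpec:
    """Generative parameters for one synthetic cohort.

    ``dropout`` lists dyad indices whose *father* records are removed at t2
    and t3 (never t1), reproducing the attrition pattern of a paired design
    where fathers stop attending after the first assessment.
    """

    n_dyads: int = 23
    precision_by_stratum: dict[StratumKey, np.ndarray] = field(
        default_factory=_default_precisions
    )
    sex_effect: Mapping[str, float] = field(
        default_factory=lambda: {"Somatisation": 0.6}
    )
    dyad_rho: float = 0.3
    time_rho: float = 0.5
    dropout: frozenset[int] = frozenset(range(16, 23))
    seed: int = 0
    scale_ranges: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SCALE_RANGES)
    )

    def __post_init__(self) -> None:
        self.dropout = frozenset(self.dropout)
        if self.n_dyads <= 0:
            raise ValueError("n_dyads must be positive")
        if not (0 <= self.dyad_rho < 1 and 0 <= self.time_rho < 1):
            raise ValueError("dyad_rho and time_rho must lie in [0, 1)")
        if len(self.dropout) > self.n_dyads or any(
            not (0 <= i < self.n_dyads) for i in self.dropout
        ):
            raise ValueError("dropout indices must be a subset of range(n_dyads)")
        for key, omega in self.precision_by_stratum.items():
            omega = np.asarray(omega, float)
            if not np.allclose(omega, omega.T):
                raise ValueError(f"precision for {key} is not symmetric")
            if np.linalg.eigvalsh(omega).min() <= 0:
                raise NotPositiveDefiniteError(f"precision for {key} is not SPD")
            self.precision_by_stratum[key] = omega


@dataclass
class PlantedTruth:
    """Ground truth planted by the generator, for recovery testing."""

    adjacency_by_stratum: dict[StratumKey, np.ndarray]  # signed 0/+1/-1, zero diag
    community_partition: dict[str, int]

    @staticmethod
    def from_spec(spec: SyntheticSpec, tol: float = 1e-12) -> "PlantedTruth":
        adj = {}
        union = np.zeros((len(SUBSCALES), len(SUBSCALES)), bool)
        for key, omega in spec.precision_by_stratum.items():
            pc = partial_correlations(omega)
            a = np.sign(pc) * (np.abs(pc) > tol)
            np.fill_diagonal(a, 0)
            adj[key] = a.astype(int)
            union |= a != 0
        # communities = connected components of the union support
        labels = {}
        seen: set[int] = set()
        block = 0
        for start in range(len(SUBSCALES)):
            if start in seen:
                continue
            stack, comp = [start], []
            while stack:
                v = stack.pop()
                if v in seen:
                    continue
                seen.add(v)
                comp.append(v)
                stack.extend(int(w) for w in np.flatnonzero(union[v]))
            for v in comp:
                labels[SUBSCALES[v]] = block
            block += 1
        return PlantedTruth(adjacency_by_stratum=adj, community_partition=labels)


def discretize_scores(
    latent: np.ndarray,
    scale_maxes: Sequence[int],
    latent_range: tuple[float, float] = LATENT_RANGE,
) -> np.ndarray:
    """Map latent columns affinely onto [0, scale_max], round, clamp.

    Monotone in the latent value; values at/below the range minimum map to 0
    and at/above the maximum to scale_max.
    """
    lo, hi = latent_range
    latent = np.asarray(latent, float)
    out = np.empty_like(latent, dtype=int)
    for k, smax in enumerate(scale_maxes):
        scaled = (latent[:, k] - lo) / (hi - lo) * smax
        out[:, k] = np.clip(np.round(scaled), 0, smax).astype(int)
    return out


def _coupling_matrix(dyad_rho: float, time_rho: float) -> np.ndarray:
    """6x6 correlation over strata ordered (mother t1..t3, father t1..t3).

    Kronecker product of a 2x2 exchangeable couple block and a 3x3 AR(1)
    over time.
    """
    c_role = np.array([[1.0, dyad_rho], [dyad_rho, 1.0]])
    lags = np.abs(np.subtract.outer(np.arange(3), np.arange(3)))
    c_time = time_rho ** lags
    return np.kron(c_role, c_time)


def generate_cohort(spec: SyntheticSpec) -> tuple[CohortTable, PlantedTruth]:
    """Draw one cohort from the generative model; deterministic given the seed.

    Sampling scheme: standard-normal innovations per dyad are correlated
    across the 6 strata by the Kronecker couple x AR(1) structure (applied
    independently per latent dimension), then colored per stratum by the
    Cholesky factor of that stratum's covariance (inverse planted precision).
    Child sex is Bernoulli(1/2) per dyad and enters designated nodes as a
    centered location shift before discretization; father dropout at t2/t3
    is applied to the final table.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_dyads, len(SUBSCALES)
    strata_keys = [(role, t) for role in ROLES for t in TIME_POINTS]
    C = _coupling_matrix(spec.dyad_rho, spec.time_rho)
    Lc = np.linalg.cholesky(C)
    # innovations: (n, 6 strata, p dims), coupled across strata per dim
    G = rng.standard_normal((n, len(strata_keys), p))
    U = np.einsum("st,ntp->nsp", Lc, G)
    sex = rng.integers(0, 2, size=n)  # 0 = male, 1 = female
    shift = np.zeros(p)
    for name, delta in spec.sex_effect.items():
        shift[SUBSCALES.index(name)] = delta
    scale_maxes = [spec.scale_ranges[s] for s in SUBSCALES]
    dyad_ids = np.array([f"d{d:03d}" for d in range(n)])
    sex_tokens = np.where(sex == 1, "female", "male")
    frames = []
    for s_idx, key in enumerate(strata_keys):
        sigma = np.linalg.inv(spec.precision_by_stratum[key])
        L = np.linalg.cholesky(sigma)
        X = U[:, s_idx, :] @ L.T
        X = X + np.outer(sex - 0.5, shift)
        scores = discretize_scores(X, scale_maxes)
        role, t = key
        frame = pd.DataFrame({"dyad_id": dyad_ids, "parent_role": role, "time_point": t})
        for k in range(p):
            frame[SUBSCALES[k]] = scores[:, k]
        frame[SEX_COLUMN] = sex_tokens
        frames.append(frame)
    df = pd.concat(frames, ignore_index=True)[list(CSV_HEADER)]
    drop_mask = (
        df["parent_role"].eq("father")
        & df["time_point"].isin(["t2", "t3"])
        & df["dyad_id"].isin({f"d{i:03d}" for i in spec.dropout})
    )
    df = df[~drop_mask]
    # interleave records dyad-wise for a natural long-format ordering
    df = df.sort_values(
        ["dyad_id", "parent_role", "time_point"],
        key=lambda c: c.map({v: i for i, v in enumerate(TIME_POINTS)})
        if c.name == "time_point"
        else (c.map({v: i for i, v in enumerate(ROLES)}) if c.name == "parent_role" else c),
        kind="stable",
    ).reset_index(drop=True)
    cohort = CohortTable(df, spec.scale_ranges)
    return cohort, PlantedTruth.from_spec(spec)
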