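"""Uncertainty-weighted positive matrix factorization (PMF) receptor model.

The receptor model decomposes a sample-by-compound concentration matrix X
(n x m, ng/g) into p non-negative factors,

    X = G F + E,    x_ij = sum_k g_ik f_kj + e_ij,

where G (n x p) holds per-sample source contributions, F (p x m) the source
profiles, and E the residual. The factorization minimizes the scaled residual
sum of squares

    Q = sum_ij (e_ij / u_ij)^2,

with u_ij the measurement uncertainty of x_ij. Uncertainties follow the
equation-based rule used by regulatory PMF practice:

    u_ij = (5/6) * MDL_j                                  if x_ij <= MDL_j
    u_ij = sqrt((EF_j * x_ij)^2 + MDL_j^2)                otherwise

with MDL the method detection limit and EF the per-compound error fraction.

Q is minimized by multiplicative updates for weighted non-negative
factorization (cell weights w_ij = 1/u_ij^2), which keep G and F non-negative
and never increase Q. Because the problem is non-convex, several random
initializations are run and the best kept; a single top-level seed expands
deterministically into per-start seeds.

After fitting, each profile row is rescaled to sum to one (f_ip, the fraction
of compound i in source p) with the scale folded into the matching
contribution column (S_kp, the total PAH mass of source p in sample k), so
S f = G F exactly. Factors are labelled by cosine similarity against a marker
library of candidate source profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .catalog import CompoundCatalog
from .concentrations import ConcentrationMatrix

__all__ = [
    "UncertaintyMatrix",
    "SourceModel",
    "NormalizedModel",
    "SourceLabel",
    "FactorScan",
    "equation_uncertainty",
    "build_uncertainty",
    "fit_pmf",
    "scan_factors",
    "normalize_profiles",
    "label_sources",
    "source_contribution_percent",
]

_EPS = 1e-12


def equation_uncertainty(x, mdl, error_fraction):
    """Equation-based measurement uncertainty for concentrations ``x``.

    Vectorized over x; ``mdl``/``error_fraction`` may be scalars or per-column
    arrays. Concentrations at or below the MDL get (5/6)*MDL, others
    sqrt((EF*x)^2 + MDL^2).
    """
    x = np.asarray(x, dtype=float)
    mdl = np.broadcast_to(np.asarray(mdl, dtype=float), x.shape)
    ef = np.broadcast_to(np.asarray(error_fraction, dtype=float), x.shape)
    below = x <= mdl
    return np.where(below, (5.0 / 6.0) * mdl, np.sqrt((ef * x) ** 2 + mdl**2))


@dataclass(frozen=True)
class UncertaintyMatrix:
    """Per-cell measurement uncertainties u_ij, same shape/units as X."""

    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)) or np.any(self.values <= 0):
            raise ValueError("uncertainties must be finite and strictly positive")


def build_uncertainty(matrix: ConcentrationMatrix, catalog: CompoundCatalog | None = None) -> UncertaintyMatrix:
    """Per-cell uncertainty matrix from the catalog's MDLs and error fractions."""
    catalog = catalog or matrix.catalog
    mdls = np.asarray(catalog.mdls, dtype=float)
    efs = np.asarray(catalog.error_fractions, dtype=float)
    if np.any(mdls <= 0):
        raise ValueError("all MDLs must be strictly positive")
    return UncertaintyMatrix(equation_uncertainty(matrix.values, mdls[None, :], efs[None, :]))


@dataclass
class SourceModel:
    """A fitted factorization: X ~ G F with objective Q."""

    p: int
    G: np.ndarray  # (n, p) contributions
    F: np.ndarray  # (p, m) profiles
    X: np.ndarray  # (n, m) data the model was fitted to
    U: np.ndarray  # (n, m) uncertainties
    Q: float
    r_squared: float
    converged: bool
    n_iter: int
    seed: int
    q_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    start_seeds: list[int] = field(default_factory=list)

    @property
    def residual(self) -> np.ndarray:
        return self.X - self.G @ self.F

    def recompute_q(self) -> float:
        return float((((self.X - self.G @ self.F) / self.U) ** 2).sum())


@dataclass
class NormalizedModel:
    """Factorization in apportionment form: S (mass) and f (unit-sum profiles)."""

    S: np.ndarray  # (n, p) total PAH mass per source per sample, ng/g
    f: np.ndarray  # (p, m) profile fractions, rows sum to 1
    catalog: CompoundCatalog
    labels: list["SourceLabel"] | None = None

    def reconstruction(self) -> np.ndarray:
        return self.S @ self.f

    @property
    def n_sources(self) -> int:
        return self.S.shape[1]


@dataclass(frozen=True)
class SourceLabel:
    name: str
    similarity: float
    low_confidence: bool


def _pooled_r_squared(x: np.ndarray, model: np.ndarray) -> float:
    """Squared Pearson correlation between observed and reconstructed cells."""
    xf, mf = x.ravel(), model.ravel()
    if np.ptp(xf) == 0 or np.ptp(mf) == 0:
        return 0.0
    return float(np.corrcoef(xf, mf)[0, 1] ** 2)


def _mu_fit_single(X, W, WX, p, rng, tol, max_iter):
    """One multiplicative-update run from a random start; returns (G, F, trace)."""
    n, m = X.shape
    scale = np.sqrt(max(X.mean(), _EPS) / p)
    G = rng.uniform(0.5, 1.5, size=(n, p)) * scale
    F = rng.uniform(0.5, 1.5, size=(p, m)) * scale

    trace = []
    q_prev = np.inf
    for it in range(max_iter):
        R = G @ F
        G *= (WX @ F.T) / ((W * R) @ F.T + _EPS)
        R = G @ F
        F *= (G.T @ WX) / (G.T @ (W * R) + _EPS)
        q = float((W * (X - G @ F) ** 2).sum())
        trace.append(q)
        if np.isfinite(q_prev) and q_prev - q <= tol * max(q_prev, _EPS):
            return G, F, np.asarray(trace), True, it + 1
        q_prev = q
    return G, F, np.asarray(trace), False, max_iter


def fit_pmf(
    matrix: ConcentrationMatrix | np.ndarray,
    uncertainty: UncertaintyMatrix | np.ndarray,
    p: int,
    n_starts: int = 20,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 5000,
) -> SourceModel:
    """Fit a p-factor uncertainty-weighted PMF; keep the best of ``n_starts``.

    Deterministic for a fixed seed. If no start meets the tolerance within
    ``max_iter`` iterations the best model is still returned, flagged
    unconverged via a warning.
    """
    X = matrix.values if isinstance(matrix, ConcentrationMatrix) else np.asarray(matrix, dtype=float)
    U = uncertainty.values if isinstance(uncertainty, UncertaintyMatrix) else np.asarray(uncertainty, dtype=float)
    if X.shape != U.shape:
        raise ValueError("data and uncertainty shapes differ")
    if not np.all(np.isfinite(U)) or np.any(U <= 0):
        raise ValueError("uncertainties must be finite and strictly positive")
    n, m = X.shape
    if not (1 <= p <= min(n, m)):
        raise ValueError(f"factor count p={p} must be in 1..min(n, m)={min(n, m)}")
    if not np.all(X.sum(axis=None) > 0):
        raise ValueError("degenerate input: concentration matrix is identically zero")

    W = 1.0 / U**2
    WX = W * X
    start_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n_starts)]

    best = None
    for s in start_seeds:
        rng = np.random.default_rng(s)
        G, F, trace, conv, iters = _mu_fit_single(X, W, WX, p, rng, tol, max_iter)
        q = trace[-1]
        if best is None or q < best[2][-1]:
            best = (G, F, trace, conv, iters, s)

    G, F, trace, conv, iters, best_seed = best
    if not conv:
        warnings.warn(f"PMF did not meet tolerance within {max_iter} iterations (best start seed {best_seed})")
    model = SourceModel(
        p=p,
        G=G,
        F=F,
        X=X,
        U=U,
        Q=float(trace[-1]),
        r_squared=_pooled_r_squared(X, G @ F),
        converged=bool(conv),
        n_iter=int(iters),
        seed=seed,
        q_trace=trace,
        start_seeds=start_seeds,
    )
    return model


@dataclass
class FactorScan:
    """Diagnostics from fitting a range of factor counts."""

    table: pd.DataFrame  # columns: p, Q, Q_expected, Q_over_Qexp, r_squared
    recommended_p: int
    models: dict[int, SourceModel]


def scan_factors(
    matrix: ConcentrationMatrix | np.ndarray,
    uncertainty: UncertaintyMatrix | np.ndarray,
    p_min: int = 3,
    p_max: int = 8,
    n_starts: int = 20,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 5000,
    r2_threshold: float = 0.91,
    q_improvement: float = 0.10,
) -> FactorScan:
    """Fit factor counts p_min..p_max and recommend a parsimonious p.

    The recommended p is the smallest with pooled r^2 at or above
    ``r2_threshold`` whose degrees-of-freedom-normalized objective
    Q/Q_expected, with Q_expected = nm - p(n+m), would improve by less than
    ``q_improvement`` (relative) when one more factor is added — i.e. the
    first adequate fit beyond which extra factors only absorb noise. Raw Q
    decreases mechanically with every added factor, so the improvement is
    judged on the normalized objective. Falls back to the p with the highest
    r^2 if no factor count qualifies.
    """
    X = matrix.values if isinstance(matrix, ConcentrationMatrix) else np.asarray(matrix, dtype=float)
    n, m = X.shape
    if p_max > min(n, m):
        raise ValueError(f"p_max={p_max} exceeds min(n, m)={min(n, m)}")

    models: dict[int, SourceModel] = {}
    rows = []
    for k, p in enumerate(range(p_min, p_max + 1)):
        model = fit_pmf(matrix, uncertainty, p, n_starts=n_starts, seed=seed + k, tol=tol, max_iter=max_iter)
        models[p] = model
        q_expected = n * m - p * (n + m)  # approximate degrees of freedom
        rows.append(
            {
                "p": p,
                "Q": model.Q,
                "Q_expected": q_expected,
                "Q_over_Qexp": model.Q / q_expected if q_expected > 0 else np.nan,
                "r_squared": model.r_squared,
            }
        )
    table = pd.DataFrame(rows)

    recommended = None
    norm_q = {row["p"]: (row["Q_over_Qexp"] if np.isfinite(row["Q_over_Qexp"]) else row["Q"]) for row in rows}
    for p in range(p_min, p_max + 1):
        if models[p].r_squared < r2_threshold:
            continue
        if p == p_max:
            recommended = p
            break
        rel_gain = (norm_q[p] - norm_q[p + 1]) / max(norm_q[p], _EPS)
        if rel_gain < q_improvement:
            recommended = p
            break
    if recommended is None:
        recommended = int(table.loc[table["r_squared"].idxmax(), "p"])
    return FactorScan(table=table, recommended_p=recommended, models=models)


def normalize_profiles(model: SourceModel, catalog: CompoundCatalog | None = None) -> NormalizedModel:
    """Rescale profiles to unit-sum fractions, folding the scale into S.

    All-zero factor rows are dropped with a warning. S f reproduces G F
    exactly for the retained factors.
    """
    from .catalog import default_catalog

    row_sums = model.F.sum(axis=1)
    keep = row_sums > 0
    if not np.all(keep):
        warnings.warn(f"dropping {int((~keep).sum())} all-zero factor(s)")
    F = model.F[keep]
    G = model.G[:, keep]
    s = F.sum(axis=1)
    f = F / s[:, None]
    S = G * s[None, :]
    return NormalizedModel(S=S, f=f, catalog=catalog or default_catalog())


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def label_sources(normalized: NormalizedModel, marker_library) -> list[SourceLabel]:
    """Assign each factor the marker-library source with maximal cosine similarity.

    Assignment is greedy by descending similarity and injective while
    candidates remain; similarities below 0.5 are flagged low-confidence.
    Ties are broken toward the candidate with the larger summed marker-compound
    fraction in the factor. The labels are stored on ``normalized``.
    """
    refs = marker_library.profiles
    names = list(marker_library.names)
    p = normalized.n_sources
    sims = np.array([[_cosine(normalized.f[k], refs[c]) for c in range(len(names))] for k in range(p)])

    order = []
    for k in range(p):
        for c in range(len(names)):
            # tie-break score: summed factor fraction on the candidate's top-5 marker compounds
            markers = np.argsort(refs[c])[::-1][:5]
            order.append((sims[k, c], float(normalized.f[k, markers].sum()), k, c))
    order.sort(key=lambda t: (-t[0], -t[1]))

    assigned_factor: dict[int, tuple[str, float]] = {}
    used_candidates: set[int] = set()
    for sim, _score, k, c in order:
        if k in assigned_factor:
            continue
        if p <= len(names) and c in used_candidates:
            continue
        assigned_factor[k] = (names[c], sim)
        used_candidates.add(c)

    labels = [
        SourceLabel(name=assigned_factor[k][0], similarity=assigned_factor[k][1],
                    low_confidence=assigned_factor[k][1] < 0.5)
        for k in range(p)
    ]
    normalized.labels = labels
    return labels


def source_contribution_percent(normalized: NormalizedModel) -> np.ndarray:
    """Percent of the total apportioned PAH mass attributed to each source."""
    totals = normalized.S.sum(axis=0)
    return 100.0 * totals / totals.sum()
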