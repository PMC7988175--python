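"""Demographic computations from structured population models.

A population projection model splits the annual transition matrix A into a
survival/growth component U (per-capita transition probabilities between
stages) and a fecundity component F (per-capita recruit production), with
A = U + F. The asymptotic population growth rate lambda is the dominant
eigenvalue of A; the net reproductive rate R0 is the dominant eigenvalue of
F (I - U)^{-1}; generation time is T = log(R0) / log(lambda), the standard
choice for stage-structured plant models.

Integral projection models (IPMs) are handled by midpoint-rule
discretization onto a mesh, after which they are ordinary matrix models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProjectionModel",
    "IPMSpec",
    "lambda_of",
    "discretize_ipm",
    "generation_time",
    "log_lambda_series",
]

_COLSUM_TOL = 1e-9


@dataclass
class ProjectionModel:
    """One year's projection of a population: A = U + F.

    Parameters
    ----------
    pop_id : str
        Population identifier.
    census_year : int
        Calendar year of the census starting the transition.
    U : ndarray, shape (s, s)
        Survival/growth matrix; entry (i, j) is the probability that an
        individual in stage j survives and moves to stage i. Column sums
        must not exceed 1 (an individual survives at most once).
    F : ndarray, shape (s, s)
        Fecundity matrix; entry (i, j) is the number of stage-i recruits
        produced per stage-j individual.
    """

    pop_id: str
    census_year: int
    U: np.ndarray
    F: np.ndarray

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.U.ndim != 2 or self.U.shape[0] != self.U.shape[1]:
            raise ValueError(f"U must be square, got shape {self.U.shape}")
        if self.F.shape != self.U.shape:
            raise ValueError(
                f"U and F must share dimensions, got {self.U.shape} vs {self.F.shape}"
            )
        if not (np.isfinite(self.U).all() and np.isfinite(self.F).all()):
            raise ValueError("matrix entries must be finite")
        if (self.U < 0).any() or (self.F < 0).any():
            raise ValueError("matrix entries must be nonnegative")
        colsums = self.U.sum(axis=0)
        bad = np.where(colsums > 1 + _COLSUM_TOL)[0]
        if bad.size:
            raise ValueError(
                f"survival column sum exceeds 1 for pop {self.pop_id!r}, "
                f"year {self.census_year}, stage {bad[0] + 1} "
                f"(sum = {colsums[bad[0]]:.6g})"
            )

    @property
    def A(self) -> np.ndarray:
        return self.U + self.F

    @property
    def n_stages(self) -> int:
        return self.U.shape[0]


@dataclass
class IPMSpec:
    """A size-structured integral projection kernel.

    ``survival_growth(z_next, z_now)`` and ``fecundity(z_next, z_now)`` are
    vectorized kernel densities on the size domain [lower, upper];
    discretization uses the midpoint rule with ``mesh_points`` cells.
    """

    survival_growth: Callable[[np.ndarray, np.ndarray], np.ndarray]
    fecundity: Callable[[np.ndarray, np.ndarray], np.ndarray]
    lower: float
    upper: float
    mesh_points: int = 100
    pop_id: str = "ipm"
    census_year: int = 0

    def __post_init__(self) -> None:
        if self.mesh_points < 1:
            raise ValueError("mesh_points must be >= 1")
        if not self.lower < self.upper:
            raise ValueError("size bounds must satisfy lower < upper")


def _check_matrix(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"matrix must be square, got shape {A.shape}")
    if not np.isfinite(A).all():
        raise ValueError("matrix entries must be finite")
    if (A < 0).any():
        raise ValueError("matrix entries must be nonnegative")
    return A


def _is_irreducible(A: np.ndarray) -> bool:
    # (I + A)^(s-1) strictly positive iff the life-cycle graph is strongly
    # connected; cheap for the small matrices used here.
    s = A.shape[0]
    M = np.eye(s) + (A > 0)
    P = np.linalg.matrix_power(M, s - 1) if s > 1 else M
    return bool((P > 0).all())


def lambda_of(model: ProjectionModel | np.ndarray) -> float:
    """Asymptotic population growth rate: dominant eigenvalue modulus of A.

    For an irreducible nonnegative matrix this is the Perron root (real and
    positive). Reducible matrices, common in real databases, are accepted
    with a warning.
    """
    A = model.A if isinstance(model, ProjectionModel) else _check_matrix(model)
    if not A.any():
        raise ValueError("all-zero projection matrix: lambda undefined")
    if not _is_irreducible(A):
        warnings.warn(
            "projection matrix is reducible; lambda taken as the largest "
            "eigenvalue modulus",
            stacklevel=2,
        )
    eigs = np.linalg.eigvals(A)
    return float(np.max(np.abs(eigs)))


def discretize_ipm(spec: IPMSpec) -> ProjectionModel:
    """Midpoint-rule discretization of an IPM kernel into a matrix model.

    Entry (i, j) = kernel(z_i, z_j) * h with h the mesh width and z the
    cell midpoints; U and F components are kept separate so that
    generation time remains computable.
    """
    h = (spec.upper - spec.lower) / spec.mesh_points
    z = spec.lower + (np.arange(spec.mesh_points) + 0.5) * h
    Znext, Znow = np.meshgrid(z, z, indexing="ij")
    U = np.asarray(spec.survival_growth(Znext, Znow), dtype=float) * h
    F = np.asarray(spec.fecundity(Znext, Znow), dtype=float) * h
    if (U < 0).any() or (F < 0).any():
        raise ValueError("kernel produced negative values on the mesh")
    return ProjectionModel(pop_id=spec.pop_id, census_year=spec.census_year, U=U, F=F)


def _fundamental_matrix(U: np.ndarray) -> np.ndarray:
    if np.max(np.abs(np.linalg.eigvals(U))) >= 1:
        raise ValueError(
            "spectral radius of U is >= 1 (immortal stages): generation time undefined"
        )
    return np.linalg.inv(np.eye(U.shape[0]) - U)


def net_reproductive_rate(model: ProjectionModel) -> float:
    """R0: dominant eigenvalue of F (I - U)^{-1}."""
    N = _fundamental_matrix(model.U)
    R = model.F @ N
    return float(np.max(np.abs(np.linalg.eigvals(R))))


def generation_time(model: ProjectionModel, *, lambda_tol: float = 1e-8) -> float:
    """Generation time T = log(R0) / log(lambda).

    When lambda is within ``lambda_tol`` of 1 the ratio degenerates; the
    fallback is the R0-weighted mean age of reproduction of a newborn
    cohort, obtained by summing the age-from-stage expansion analytically:

        T = 1' F (I-U)^{-2} c  /  1' F (I-U)^{-1} c

    with c the stage distribution of newborns (stable-stage-weighted
    column mix of F).
    """
    N = _fundamental_matrix(model.U)
    R = model.F @ N
    R0 = float(np.max(np.abs(np.linalg.eigvals(R))))
    if R0 <= 0:
        raise ValueError("R0 = 0 (no reproduction): generation time undefined")
    lam = lambda_of(model)
    if abs(np.log(lam)) < lambda_tol:
        A = model.A
        eigvals, eigvecs = np.linalg.eig(A)
        w = np.real(eigvecs[:, np.argmax(np.abs(eigvals))])
        w = np.abs(w) / np.abs(w).sum()
        births = model.F @ w
        total = births.sum()
        if total <= 0:
            raise ValueError("no reproduction at the stable stage distribution")
        c = births / total
        ones = np.ones(model.n_stages)
        num = ones @ model.F @ N @ N @ c
        den = ones @ model.F @ N @ c
        return float(num / den)
    return float(np.log(R0) / np.log(lam))


def mean_model(models: Sequence[ProjectionModel]) -> ProjectionModel:
    """Element-wise mean of a population's yearly matrices.

    Summarizes the average life cycle; used to attach a single generation
    time to a population observed over several years.
    """
    if not models:
        raise ValueError("no models given")
    pop_ids = {m.pop_id for m in models}
    if len(pop_ids) > 1:
        raise ValueError(f"models mix populations: {sorted(pop_ids)}")
    U = np.mean([m.U for m in models], axis=0)
    F = np.mean([m.F for m in models], axis=0)
    return ProjectionModel(
        pop_id=models[0].pop_id, census_year=models[0].census_year, U=U, F=F
    )


def log_lambda_series(models: Sequence[ProjectionModel]) -> pd.Series:
    """Ordered series census_year -> log(lambda) for one population."""
    if not models:
        raise ValueError("no models given")
    pop_ids = {m.pop_id for m in models}
    if len(pop_ids) > 1:
        raise ValueError(f"models mix populations: {sorted(pop_ids)}")
    dims = {m.n_stages for m in models}
    if len(dims) > 1:
        raise ValueError(f"models mix dimensions: {sorted(dims)}")
    years = [m.census_year for m in models]
    if len(set(years)) != len(years):
        dupes = sorted({y for y in years if years.count(y) > 1})
        raise ValueError(f"duplicate census years: {dupes}")
    ordered = sorted(models, key=lambda m: m.census_year)
    values = [np.log(lambda_of(m)) for m in ordered]
    return pd.Series(
        values,
        index=pd.Index([m.census_year for m in ordered], name="census_year"),
        name=models[0].pop_id,
    )
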