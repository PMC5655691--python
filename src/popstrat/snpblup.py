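"""Random SNP effect estimation from deregressed proofs (SNP-BLUP).

The model is

    y = X b + Z g + e,

with ``y`` the deregressed breeding values, ``X`` a column of ones (the only
fixed effect is a general mean), ``Z`` the genotype design matrix coded
-1/0/+1, ``g ~ N(0, I * sigma2_a / n_snp)`` the random SNP effects sharing
one prior variance, and ``e ~ N(0, D * sigma2_e)`` with
``D = diag(1 / EDC)``: a bull's residual variance shrinks with its effective
daughter contribution.  The estimates solve Henderson's mixed model
equations

    [ X'R-1X      X'R-1Z      ] [b]   [X'R-1y]
    [ Z'R-1X  Z'R-1Z + G^-1   ] [g] = [Z'R-1y],

iterated on data with Gauss-Seidel: one effect is updated at a time while
the residual vector ``e = y - Xb - Zg`` is maintained incrementally, so no
coefficient matrix is ever formed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panels import MISSING, GenotypePanel


@dataclass
class DeregressedProofs:
    """Per-animal pseudo-phenotypes for one trait.

    ``y`` holds the deregressed EBVs and ``edc`` the effective daughter
    contributions weighting each record (residual variance sigma2_e / edc).
    """

    animal_ids: list[str]
    trait: str
    y: np.ndarray
    edc: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.edc = np.asarray(self.edc, dtype=float)
        if len(self.animal_ids) != self.y.size or self.y.size != self.edc.size:
            raise ValueError("animal_ids, y and edc must have equal length")
        if np.any(self.edc <= 0):
            raise ValueError("every EDC must be positive")

    def aligned_to(self, animal_ids: list[str]) -> "DeregressedProofs":
        """Reorder records to the panel's animal order (all must be present)."""
        pos = {a: i for i, a in enumerate(self.animal_ids)}
        idx = np.array([pos[a] for a in animal_ids])
        return DeregressedProofs(list(animal_ids), self.trait, self.y[idx], self.edc[idx])


@dataclass
class VarianceSpec:
    """Variance components for one trait.

    The per-SNP prior variance is ``sigma2_a / n_snp``: the total additive
    variance spread evenly over the marker panel.
    """

    sigma2_a: float
    sigma2_e: float
    n_snp: int

    def __post_init__(self) -> None:
        if self.sigma2_a <= 0 or self.sigma2_e <= 0 or self.n_snp <= 0:
            raise ValueError("variances and n_snp must be positive")

    @property
    def sigma2_g(self) -> float:
        return self.sigma2_a / self.n_snp


@dataclass
class SNPEffectSet:
    """Estimated SNP effects for one population and trait."""

    population_id: str
    trait: str
    snp_ids: list[str]
    g_hat: np.ndarray
    mu_hat: float
    converged: bool
    n_iter: int
    residuals: np.ndarray | None = None

    def to_frame(self, panel: GenotypePanel | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"snp_id": self.snp_ids, "g_hat": self.g_hat})
        if panel is not None:
            df.insert(1, "chrom", panel.chrom)
            df.insert(2, "pos_bp", panel.pos_bp)
        return df


def design_matrix(panel: GenotypePanel) -> np.ndarray:
    """Genotype design matrix Z with missing calls set to the heterozygote 0."""
    z = panel.genotypes.astype(np.float64)
    z[panel.genotypes == MISSING] = 0.0
    return z


def solve_snp_blup(
    panel: GenotypePanel,
    proofs: DeregressedProofs,
    var: VarianceSpec,
    tol: float = 1e-10,
    max_iter: int = 2000,
) -> SNPEffectSet:
    """Gauss-Seidel (iteration on data) solution of the SNP-BLUP equations.

    Each full iteration updates the general mean and then every SNP effect
    in map order; after each single-effect update the residual vector is
    adjusted in place.  Convergence is declared when the relative L2 change
    of the full solution vector over one iteration drops below ``tol``.
    A SNP column with zero variance (all genotypes equal) keeps its effect
    at 0.
    """
    proofs = proofs.aligned_to(panel.animal_ids)
    Z = design_matrix(panel)
    y = proofs.y
    w = proofs.edc / var.sigma2_e  # diagonal of R^-1
    lam = 1.0 / var.sigma2_g  # G^-1 diagonal

    n, m = Z.shape
    # diagonal elements of the coefficient matrix
    diag_mu = w.sum()
    diag_g = np.einsum("ij,ij,i->j", Z, Z, w) + lam
    active = np.einsum("ij,ij,i->j", Z, Z, w) > 0.0

    mu = 0.0
    g = np.zeros(m)
    e = y.copy()  # residual for the zero start

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        delta_sq = 0.0
        # general mean
        new_mu = (w @ e + diag_mu * mu) / diag_mu
        e -= new_mu - mu
        delta_sq += (new_mu - mu) ** 2
        mu = new_mu
        # SNP effects in map order
        for j in range(m):
            if not active[j]:
                continue
            zj = Z[:, j]
            rhs = w @ (zj * e) + (diag_g[j] - lam) * g[j]
            new_gj = rhs / diag_g[j]
            step = new_gj - g[j]
            if step != 0.0:
                e -= zj * step
            delta_sq += step * step
            g[j] = new_gj
        norm_sq = mu * mu + g @ g
        if norm_sq == 0.0 or np.sqrt(delta_sq / norm_sq) < tol:
            converged = True
            break

    return SNPEffectSet(
        population_id=panel.population_id,
        trait=proofs.trait,
        snp_ids=list(panel.snp_ids),
        g_hat=g,
        mu_hat=float(mu),
        converged=converged,
        n_iter=it,
        residuals=e,
    )


def snp_additive_variance(g_hat, p) -> np.ndarray:
    """Additive variance contributed by a SNP: 2 * g_hat^2 * p * (1 - p).

    ``p`` is the SNP's allele frequency in the base population; the sign of
    the effect is irrelevant and a fixed allele (p in {0, 1}) contributes
    nothing.
    """
    g_hat = np.asarray(g_hat, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    return 2.0 * g_hat**2 * p * (1.0 - p)
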