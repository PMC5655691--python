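"""Cross-population SNP-effect (co)variances and the genetic correlation.

Stacking each shared SNP's two per-population effect estimates into a
2-vector y_j, the bivariate mixed model is

    y_j = mu + q_j + eps_j,   q_j ~ N(0, G),   eps_j ~ N(0, sigma2_eps I2),

with one mean per population, a 2x2 SNP (co)variance matrix ``G`` shared by
all SNPs (SNPs exchangeable, no between-SNP covariance) and one residual
variance common to both populations.  The derived genetic correlation is
``rho_g = G12 / sqrt(G11 G22)`` and the variance ratio ``G22 / G11``.

Parameters are estimated by EM-REML on the 2x2 scatter matrix of the
mean-centred effect pairs.  Note that the marginal covariance of y is
``V = G + sigma2_eps I2``: the data identify ``V`` (hence the covariance
G12 exactly), but the split of V's diagonal between G and sigma2_eps is a
likelihood ridge — EM converges to the ridge point determined by its
starting values (an even split of the marginal variance).  See the methods
note for the consequences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class EffectPairs:
    """Per-SNP effect estimates for the same trait in two populations."""

    snp_ids: list[str]
    ghat_a: np.ndarray
    ghat_b: np.ndarray
    pop_a: str = "PL"
    pop_b: str = "DE"
    trait: str = ""

    def __post_init__(self) -> None:
        self.ghat_a = np.asarray(self.ghat_a, dtype=float)
        self.ghat_b = np.asarray(self.ghat_b, dtype=float)
        if self.ghat_a.size != self.ghat_b.size or self.ghat_a.size != len(self.snp_ids):
            raise ValueError("snp_ids, ghat_a, ghat_b must have equal length")
        if not (np.all(np.isfinite(self.ghat_a)) and np.all(np.isfinite(self.ghat_b))):
            raise ValueError("effect estimates must be finite")

    @classmethod
    def from_effect_sets(cls, a, b, trait: str = "") -> "EffectPairs":
        """Join two SNPEffectSets on snp_id (inner join, a's order)."""
        fa = pd.DataFrame({"snp_id": a.snp_ids, "ga": a.g_hat})
        fb = pd.DataFrame({"snp_id": b.snp_ids, "gb": b.g_hat})
        m = fa.merge(fb, on="snp_id")
        return cls(m["snp_id"].tolist(), m["ga"].to_numpy(), m["gb"].to_numpy(),
                   pop_a=a.population_id, pop_b=b.population_id,
                   trait=trait or a.trait)

    @property
    def n_snp(self) -> int:
        return len(self.snp_ids)


@dataclass
class CrossPopG:
    """Estimated 2x2 SNP (co)variance matrix and derived quantities."""

    G: np.ndarray
    sigma2_eps: float
    mu: np.ndarray
    rho_g: float
    pop_a: str
    pop_b: str
    converged: bool
    n_iter: int
    loglik: float
    psd_projected: bool = False
    loglik_trace: np.ndarray | None = None

    def marginal_cov(self) -> np.ndarray:
        """Model-implied covariance of an effect pair: G + sigma2_eps * I."""
        return self.G + self.sigma2_eps * np.eye(2)


def _rho(G: np.ndarray) -> float:
    d = G[0, 0] * G[1, 1]
    if d <= 0:
        return np.nan
    return float(np.clip(G[0, 1] / np.sqrt(d), -1.0, 1.0))


def _project_psd(G: np.ndarray) -> tuple[np.ndarray, bool]:
    w, v = np.linalg.eigh(G)
    if w.min() >= 0:
        return G, False
    w = np.clip(w, 0.0, None)
    return (v * w) @ v.T, True


def fit_bivariate(
    pairs: EffectPairs, tol: float = 1e-10, max_iter: int = 10_000
) -> CrossPopG:
    """EM-REML fit of (G, sigma2_eps, mu) to the paired effect estimates.

    The REML log-likelihood (of the centred pairs given V = G + s*I) is
    monitored and is non-decreasing across EM iterations; convergence is
    declared on a relative log-likelihood change below ``tol``.  A G update
    that leaves the PSD cone is projected back (eigenvalue clipping) and
    flagged.  On non-convergence the last iterate is returned with
    ``converged=False``.
    """
    m = pairs.n_snp
    if m < 50:
        raise ValueError(f"need >= 50 SNPs for a stable fit, got {m}")
    Y = np.column_stack([pairs.ghat_a, pairs.ghat_b])
    mu = Y.mean(axis=0)
    R = Y - mu
    S = (R.T @ R) / (m - 1)  # REML scatter of the centred pairs

    G = S / 2.0
    s = float(np.trace(S)) / 4.0
    I2 = np.eye(2)
    loglik = -np.inf
    trace: list[float] = []
    converged = False
    projected = False
    it = 0
    for it in range(1, max_iter + 1):
        V = G + s * I2
        Vi = np.linalg.inv(V)
        ll = -0.5 * (m - 1) * (np.log(np.linalg.det(V)) + np.trace(Vi @ S))
        trace.append(ll)
        if it > 1 and abs(ll - loglik) <= tol * (abs(loglik) + 1e-12):
            loglik = ll
            converged = True
            break
        loglik = ll
        B = G @ Vi
        G_new = B @ S @ B.T + G - B @ G
        G_new = 0.5 * (G_new + G_new.T)
        G_new, proj = _project_psd(G_new)
        projected = projected or proj
        s_new = 0.5 * (s**2 * np.trace(Vi @ S @ Vi) + np.trace(s * I2 - s**2 * Vi))
        G, s = G_new, max(float(s_new), 0.0)

    return CrossPopG(
        G=G,
        sigma2_eps=s,
        mu=mu,
        rho_g=_rho(G),
        pop_a=pairs.pop_a,
        pop_b=pairs.pop_b,
        converged=converged,
        n_iter=it,
        loglik=float(loglik),
        psd_projected=projected,
        loglik_trace=np.array(trace),
    )


def variance_ratio(g: CrossPopG) -> float:
    """Ratio of the second population's SNP variance over the first's.

    With the (PL, DE) ordering used throughout the pipeline this is the
    DE/PL variance ratio.
    """
    if g.G[0, 0] <= 0 or g.G[1, 1] <= 0:
        raise ValueError("variance ratio undefined for a zero variance")
    return float(g.G[1, 1] / g.G[0, 0])
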