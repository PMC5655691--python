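"""Base-population allele frequencies from pedigree and gene content.

Only recent animals are genotyped, yet the quantity entering the per-SNP
additive variance is the allele frequency of the *base population* — the
non-genotyped pedigree founders.  Treating each SNP's gene content (0/1/2
copies of the counted allele) as a heritable trait, the mixed model

    gc = 1 mu + u + e,   u ~ N(0, A sigma2_u),  e ~ N(0, I sigma2_e),

with ``A`` the pedigree numerator relationship matrix, gives BLUE(mu) as
twice the base-population allele frequency: p_base = mu_hat / 2.  Gene
content is observed only for genotyped animals; the pedigree propagates the
information back to the founders.  ``lambda = sigma2_e / sigma2_u`` is close
to zero because gene content is almost perfectly heritable.

``A``-inverse is assembled directly from the pedigree with Henderson's
rules, ignoring inbreeding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import splu
from scipy.stats import pearsonr

from .panels import MISSING, GenotypePanel

UNKNOWN_PARENT = "0"


@dataclass
class Pedigree:
    """Animal/sire/dam triples, unknown parents coded "0".

    Animals are kept in an ancestors-first order (parents before offspring),
    established on construction; a parentage cycle is an error.
    """

    animal_ids: list[str]
    sire_ids: list[str]
    dam_ids: list[str]
    genotyped: np.ndarray = field(default=None)  # bool per animal

    def __post_init__(self) -> None:
        n = len(self.animal_ids)
        if len(self.sire_ids) != n or len(self.dam_ids) != n:
            raise ValueError("animal, sire and dam lists must have equal length")
        if self.genotyped is None:
            self.genotyped = np.zeros(n, dtype=bool)
        self.genotyped = np.asarray(self.genotyped, dtype=bool)
        self._sort_ancestors_first()

    def _sort_ancestors_first(self) -> None:
        """Topological (Kahn) sort; raises on a parentage cycle."""
        ids = self.animal_ids
        pos = {a: i for i, a in enumerate(ids)}
        n = len(ids)
        parents = []
        for s, d in zip(self.sire_ids, self.dam_ids):
            parents.append([pos[p] for p in (s, d) if p != UNKNOWN_PARENT and p in pos])
        children: list[list[int]] = [[] for _ in range(n)]
        indeg = np.zeros(n, dtype=int)
        for i, ps in enumerate(parents):
            indeg[i] = len(ps)
            for p in ps:
                children[p].append(i)
        order = [i for i in range(n) if indeg[i] == 0]
        head = 0
        while head < len(order):
            i = order[head]
            head += 1
            for c in children[i]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    order.append(c)
        if len(order) != n:
            raise ValueError("pedigree contains a parentage cycle")
        self.animal_ids = [ids[i] for i in order]
        self.sire_ids = [self.sire_ids[i] for i in order]
        self.dam_ids = [self.dam_ids[i] for i in order]
        self.genotyped = self.genotyped[order]

    @property
    def n(self) -> int:
        return len(self.animal_ids)

    def founders(self) -> np.ndarray:
        """Boolean mask of base-population animals (both parents unknown)."""
        return np.array(
            [s == UNKNOWN_PARENT and d == UNKNOWN_PARENT
             for s, d in zip(self.sire_ids, self.dam_ids)]
        )

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Sire/dam row indices (-1 for unknown), in the sorted order."""
        pos = {a: i for i, a in enumerate(self.animal_ids)}
        sire = np.array([pos.get(s, -1) if s != UNKNOWN_PARENT else -1
                         for s in self.sire_ids])
        dam = np.array([pos.get(d, -1) if d != UNKNOWN_PARENT else -1
                        for d in self.dam_ids])
        return sire, dam

    @classmethod
    def from_frame(cls, df: pd.DataFrame, genotyped_ids=None) -> "Pedigree":
        ids = df["animal_id"].astype(str).tolist()
        gt = None
        if genotyped_ids is not None:
            gset = set(genotyped_ids)
            gt = np.array([a in gset for a in ids])
        return cls(
            ids,
            df["sire_id"].astype(str).tolist(),
            df["dam_id"].astype(str).tolist(),
            gt,
        )


@dataclass
class BaseFreqSet:
    """Estimated base-population allele frequency per SNP, clamped to [0, 1]."""

    population_id: str
    snp_ids: list[str]
    p_base: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"snp_id": self.snp_ids, "p_base": self.p_base})


def a_inverse(ped: Pedigree) -> sparse.csr_matrix:
    """Inverse numerator relationship matrix by Henderson's rules.

    Inbreeding is ignored: the Mendelian-sampling contribution per animal is
    2, 4/3 or 1 for two, one or zero known parents.
    """
    sire, dam = ped.parent_indices()
    rows, cols, vals = [], [], []
    for i in range(ped.n):
        ps = [p for p in (sire[i], dam[i]) if p >= 0]
        delta = {2: 2.0, 1: 4.0 / 3.0, 0: 1.0}[len(ps)]
        rows.append(i); cols.append(i); vals.append(delta)
        for p in ps:
            rows += [i, p]; cols += [p, i]; vals += [-delta / 2.0] * 2
        for p in ps:
            for q in ps:
                rows.append(p); cols.append(q); vals.append(delta / 4.0)
    return sparse.coo_matrix((vals, (rows, cols)), shape=(ped.n, ped.n)).tocsr()


class GeneContentModel:
    """Factorised gene-content MME for one pedigree + genotyped set.

    The coefficient matrix

        [ n_obs    1'Z          ]
        [ Z'1      Z'Z + lam*Ainv ]

    depends only on the pedigree and which animals are genotyped, so it is
    factorised once and reused across SNPs.
    """

    def __init__(self, ped: Pedigree, lam: float = 0.01):
        if lam <= 0:
            raise ValueError("lambda must be positive")
        self.ped = ped
        self.lam = lam
        self.obs = np.flatnonzero(ped.genotyped)
        if self.obs.size == 0:
            raise ValueError("no genotyped animals in the pedigree")
        n = ped.n
        zz = np.zeros(n)
        zz[self.obs] = 1.0
        top = sparse.hstack(
            [sparse.coo_matrix([[float(self.obs.size)]]), sparse.coo_matrix(zz[None, :])]
        )
        bottom = sparse.hstack(
            [sparse.coo_matrix(zz[:, None]), sparse.diags(zz) + lam * a_inverse(ped)]
        )
        self._lu = splu(sparse.vstack([top, bottom]).tocsc())

    def solve(self, gene_content: np.ndarray) -> tuple[float, np.ndarray]:
        """Return (mu_hat, u_hat) for one SNP's 0/1/2 gene contents.

        ``gene_content`` is per pedigree animal (sorted order) with NaN for
        non-genotyped animals.
        """
        gc = np.asarray(gene_content, dtype=float)
        rhs = np.zeros(self.ped.n + 1)
        obs_gc = gc[self.obs]
        if np.any(np.isnan(obs_gc)):
            raise ValueError("genotyped animal with missing gene content")
        rhs[0] = obs_gc.sum()
        rhs[1 + self.obs] = obs_gc
        sol = self._lu.solve(rhs)
        return float(sol[0]), sol[1:]


def gene_content_blup(
    ped: Pedigree, gene_content: np.ndarray, lam: float = 0.01
) -> float:
    """Base-population allele frequency of one SNP: BLUE(mu)/2, clamped."""
    mu, _ = GeneContentModel(ped, lam).solve(gene_content)
    return float(np.clip(mu / 2.0, 0.0, 1.0))


def base_freqs_for_panel(
    ped: Pedigree, panel: GenotypePanel, lam: float = 0.01
) -> BaseFreqSet:
    """Estimate base frequencies for every SNP of a panel.

    Panel animals must appear in the pedigree and be flagged genotyped.
    A missing call contributes nothing for that animal at that SNP: the
    model is solved on the per-SNP observed subset (refactorising only when
    the missing pattern changes, which is rare at typical call rates).
    """
    pos = {a: i for i, a in enumerate(ped.animal_ids)}
    rows = np.array([pos[a] for a in panel.animal_ids])
    dose = panel.genotypes.astype(float) + 1.0
    dose[panel.genotypes == MISSING] = np.nan

    full_model = GeneContentModel(ped, lam)
    p = np.empty(panel.n_snp)
    cache: dict[bytes, GeneContentModel] = {}
    for j in range(panel.n_snp):
        gc = np.full(ped.n, np.nan)
        gc[rows] = dose[:, j]
        miss = np.isnan(gc) & ped.genotyped
        if not miss.any():
            model = full_model
        else:
            key = miss.tobytes()
            if key not in cache:
                sub = Pedigree(
                    list(ped.animal_ids), list(ped.sire_ids), list(ped.dam_ids),
                    ped.genotyped & ~miss,
                )
                cache[key] = GeneContentModel(sub, lam)
            model = cache[key]
        gc_j = np.where(miss, np.nan, gc)
        if model.ped.animal_ids != ped.animal_ids:  # sub-pedigree order may differ
            by_id = dict(zip(ped.animal_ids, gc_j))
            gc_j = np.array([by_id[a] for a in model.ped.animal_ids])
        mu, _ = model.solve(gc_j)
        p[j] = np.clip(mu / 2.0, 0.0, 1.0)
    return BaseFreqSet(panel.population_id, list(panel.snp_ids), p)


def base_freq_agreement(a: BaseFreqSet, b: BaseFreqSet) -> dict:
    """Pearson correlation and OLS regression of b's frequencies on a's.

    Returns ``{"pearson_r", "intercept", "slope", "r2", "n_snp"}`` over the
    shared SNP ids.
    """
    shared = [s for s in a.snp_ids if s in set(b.snp_ids)]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared SNPs")
    ia = {s: i for i, s in enumerate(a.snp_ids)}
    ib = {s: i for i, s in enumerate(b.snp_ids)}
    x = a.p_base[[ia[s] for s in shared]]
    y = b.p_base[[ib[s] for s in shared]]
    r = pearsonr(x, y).statistic
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    ss_res = ((y - fitted) ** 2).sum()
    ss_tot = ((y - y.mean()) ** 2).sum()
    return {
        "pearson_r": float(r),
        "intercept": float(coef[0]),
        "slope": float(coef[1]),
        "r2": float(1.0 - ss_res / ss_tot) if ss_tot > 0 else np.nan,
        "n_snp": len(shared),
    }
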