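"""Pairwise linkage disequilibrium, distance binning and decay regression.

LD between two loci is quantified by the squared allelic correlation

    r^2 = D^2 / (p1 (1 - p1) p2 (1 - p2)),

where ``D`` is the deviation of the AB haplotype frequency from the product
of the single-locus allele frequencies.  Same-chromosome pairs up to 5 Mbp
apart are grouped into nine fixed distance intervals and the per-interval
mean r^2 is regressed on the inverse square root of the interval's upper
boundary ``d`` (in Mbp):

    mean_r2_i = alpha + beta / sqrt(d_i) + e_i.

``beta`` measures how fast LD decays with distance, so the ratio of two
populations' predicted LD decreases over a common pair of distances equals
the ratio of their betas.

When no phased haplotypes are available, two-locus haplotype frequencies
are recovered from unphased genotypes with an EM iteration that splits the
double heterozygotes between the coupling and repulsion phases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panels import MISSING, GenotypePanel, HaplotypePanel

#: The nine distance intervals in Mbp.  All are half-open [lo, hi) except the
#: last, which is closed [3, 5].
LD_BINS_MBP: list[tuple[float, float]] = [
    (0.0, 0.025),
    (0.025, 0.05),
    (0.05, 0.075),
    (0.075, 0.12),
    (0.12, 0.2),
    (0.2, 0.5),
    (0.5, 1.5),
    (1.5, 3.0),
    (3.0, 5.0),
]

MAX_PAIR_DIST_BP: int = 5_000_000


def pair_r2(hap_a: np.ndarray, hap_b: np.ndarray) -> float:
    """Squared allelic correlation between two phased 0/1 allele columns.

    Returns NaN when either locus is monomorphic in the sample (r^2 is then
    undefined and the pair is excluded from binning).
    """
    a = np.asarray(hap_a, dtype=float)
    b = np.asarray(hap_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("haplotype columns differ in length")
    p1 = a.mean()
    p2 = b.mean()
    denom = p1 * (1 - p1) * p2 * (1 - p2)
    if denom == 0.0:
        return np.nan
    d = (a * b).mean() - p1 * p2
    return float(np.clip(d * d / denom, 0.0, 1.0))


def em_two_locus_freqs(
    geno_a: np.ndarray,
    geno_b: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> tuple[np.ndarray, int, bool]:
    """EM estimates of the four two-locus haplotype frequencies.

    Genotypes are coded -1/0/+1 (missing allowed at either locus; such
    animals are dropped pairwise).  Only the double heterozygotes are phase
    ambiguous: their AB/ab vs Ab/aB split is re-estimated each round from
    the current frequencies.  Returns ``(freqs, n_iter, converged)`` with
    ``freqs = (p_AB, p_Ab, p_aB, p_ab)`` summing to one.
    """
    ga = np.asarray(geno_a)
    gb = np.asarray(geno_b)
    ok = (ga != MISSING) & (gb != MISSING)
    # allele dosages 0/1/2 of the counted allele
    da = (ga[ok] + 1).astype(np.int64)
    db = (gb[ok] + 1).astype(np.int64)
    n = da.size
    if n == 0:
        raise ValueError("no animals with both loci observed")

    counts = np.zeros((3, 3), dtype=np.int64)
    np.add.at(counts, (da, db), 1)

    # Fixed haplotype contributions from the 8 unambiguous genotype classes.
    # Index order: AB, Ab, aB, ab (A = counted allele at locus 1, etc.)
    fixed = np.zeros(4)
    fixed[0] = 2 * counts[2, 2] + counts[2, 1] + counts[1, 2]
    fixed[1] = 2 * counts[2, 0] + counts[2, 1] + counts[1, 0]
    fixed[2] = 2 * counts[0, 2] + counts[0, 1] + counts[1, 2]
    fixed[3] = 2 * counts[0, 0] + counts[0, 1] + counts[1, 0]
    n_dh = counts[1, 1]  # double heterozygotes: AB/ab or Ab/aB

    freqs = np.full(4, 0.25)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        coupling = freqs[0] * freqs[3]
        repulsion = freqs[1] * freqs[2]
        tot = coupling + repulsion
        w = 0.5 if tot == 0 else coupling / tot
        new = fixed + n_dh * np.array([w, 1 - w, 1 - w, w])
        new /= 2.0 * n
        if np.max(np.abs(new - freqs)) < tol:
            freqs = new
            converged = True
            break
        freqs = new
    return freqs, it, converged


def r2_from_freqs(freqs: np.ndarray) -> float:
    """r^2 implied by four haplotype frequencies (AB, Ab, aB, ab)."""
    p1 = freqs[0] + freqs[1]
    p2 = freqs[0] + freqs[2]
    denom = p1 * (1 - p1) * p2 * (1 - p2)
    if denom == 0:
        return np.nan
    d = freqs[0] - p1 * p2
    return float(np.clip(d * d / denom, 0.0, 1.0))


def ld_records(
    panel: HaplotypePanel, max_dist_bp: int = MAX_PAIR_DIST_BP
) -> pd.DataFrame:
    """All same-chromosome LD records up to ``max_dist_bp`` apart.

    Returns a DataFrame (snp_i, snp_j, chrom, distance_bp, r2), pairs ordered
    with ``snp_i`` the left locus.  Pairs with a monomorphic member are
    dropped.  r^2 is computed as the squared Pearson correlation of the
    allele indicator columns, which equals the haplotype-frequency formula.
    """
    frames = []
    snp_ids = np.asarray(panel.snp_ids)
    H = panel.haplotypes.astype(np.float64)
    for c in pd.unique(panel.chrom):
        idx = np.flatnonzero(panel.chrom == c)
        if idx.size < 2:
            continue
        pos = panel.pos_bp[idx]
        sub = H[:, idx]
        sd = sub.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(sub, rowvar=False)
        ii, jj = np.triu_indices(idx.size, k=1)
        dist = pos[jj] - pos[ii]
        keep = (dist > 0) & (dist <= max_dist_bp) & (sd[ii] > 0) & (sd[jj] > 0)
        ii, jj, dist = ii[keep], jj[keep], dist[keep]
        r2 = np.clip(r[ii, jj] ** 2, 0.0, 1.0)
        frames.append(
            pd.DataFrame(
                {
                    "snp_i": snp_ids[idx[ii]],
                    "snp_j": snp_ids[idx[jj]],
                    "chrom": c,
                    "distance_bp": dist,
                    "r2": r2,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["snp_i", "snp_j", "chrom", "distance_bp", "r2"])
    return pd.concat(frames, ignore_index=True)


def ld_records_from_genotypes(
    panel: GenotypePanel, max_dist_bp: int = MAX_PAIR_DIST_BP
) -> pd.DataFrame:
    """LD records via the two-locus EM when only unphased genotypes exist."""
    rows = []
    snp_ids = np.asarray(panel.snp_ids)
    for c in pd.unique(panel.chrom):
        idx = np.flatnonzero(panel.chrom == c)
        pos = panel.pos_bp[idx]
        for a in range(idx.size):
            for b in range(a + 1, idx.size):
                dist = pos[b] - pos[a]
                if dist <= 0 or dist > max_dist_bp:
                    continue
                freqs, _, _ = em_two_locus_freqs(
                    panel.genotypes[:, idx[a]], panel.genotypes[:, idx[b]]
                )
                r2 = r2_from_freqs(freqs)
                if np.isnan(r2):
                    continue
                rows.append((snp_ids[idx[a]], snp_ids[idx[b]], c, dist, r2))
    return pd.DataFrame(
        rows, columns=["snp_i", "snp_j", "chrom", "distance_bp", "r2"]
    )


def assign_bin(distance_bp: np.ndarray) -> np.ndarray:
    """Index of the distance interval each pair falls in (-1 = outside all)."""
    d_mbp = np.asarray(distance_bp, dtype=float) / 1e6
    out = np.full(d_mbp.shape, -1, dtype=np.int64)
    for k, (lo, hi) in enumerate(LD_BINS_MBP):
        if k == len(LD_BINS_MBP) - 1:
            m = (d_mbp >= lo) & (d_mbp <= hi)  # last interval closed
        else:
            m = (d_mbp >= lo) & (d_mbp < hi)
        out[m] = k
    return out


def bin_ld(records: pd.DataFrame) -> pd.DataFrame:
    """Per-interval pair counts and mean r^2.

    Returns one row per interval (in order) with columns
    (interval, lo_mbp, hi_mbp, d_upper_mbp, n_pairs, mean_r2); an empty
    interval reports ``n_pairs = 0`` and NaN mean.
    """
    k = assign_bin(records["distance_bp"].to_numpy())
    rows = []
    for i, (lo, hi) in enumerate(LD_BINS_MBP):
        sel = records["r2"].to_numpy()[k == i]
        sel = sel[~np.isnan(sel)]
        rows.append(
            {
                "interval": f"[{lo}-{hi}" + ("]" if i == len(LD_BINS_MBP) - 1 else ")"),
                "lo_mbp": lo,
                "hi_mbp": hi,
                "d_upper_mbp": hi,
                "n_pairs": sel.size,
                "mean_r2": sel.mean() if sel.size else np.nan,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class DecayFit:
    """OLS fit of mean r^2 on 1/sqrt(d), d the interval's upper bound in Mbp."""

    alpha: float
    beta: float
    residuals: np.ndarray
    d_upper_mbp: np.ndarray

    def predict(self, d_mbp) -> np.ndarray:
        d = np.asarray(d_mbp, dtype=float)
        return self.alpha + self.beta / np.sqrt(d)


def fit_decay(bins: pd.DataFrame) -> DecayFit:
    """Fit the LD decay regression to the non-empty interval means.

    Requires at least three populated intervals.  ``beta`` is expected to be
    positive for decaying LD; a negative estimate is returned as-is.
    """
    ok = bins["n_pairs"].to_numpy() > 0
    d = bins["d_upper_mbp"].to_numpy(dtype=float)[ok]
    y = bins["mean_r2"].to_numpy(dtype=float)[ok]
    if d.size < 3:
        raise ValueError(f"decay fit needs >= 3 non-empty intervals, got {d.size}")
    X = np.column_stack([np.ones_like(d), 1.0 / np.sqrt(d)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return DecayFit(alpha=float(coef[0]), beta=float(coef[1]), residuals=resid,
                    d_upper_mbp=d)


def paired_interval_test(
    ld_a: pd.DataFrame, ld_b: pd.DataFrame, interval: tuple[float, float]
) -> dict:
    """Paired t-test of mean r^2 difference between populations in one interval.

    SNP pairs are matched across populations on the ordered (snp_i, snp_j)
    key; the test is a one-sample t on the per-pair differences
    ``r2_a - r2_b`` with n-1 degrees of freedom, two-sided.  With zero
    within-pair variance the statistic is degenerate: the test reports
    p = 1 for identically zero differences and p = 0 (flagged) for a
    constant non-zero difference.
    """
    lo, hi = interval
    closed = np.isclose(hi, LD_BINS_MBP[-1][1]) and np.isclose(lo, LD_BINS_MBP[-1][0])

    def in_interval(df: pd.DataFrame) -> pd.DataFrame:
        d = df["distance_bp"].to_numpy(dtype=float) / 1e6
        m = (d >= lo) & ((d <= hi) if closed else (d < hi))
        return df.loc[m]

    a = in_interval(ld_a)
    b = in_interval(ld_b)
    merged = a.merge(b, on=["snp_i", "snp_j"], suffixes=("_a", "_b"))
    diffs = (merged["r2_a"] - merged["r2_b"]).to_numpy(dtype=float)
    diffs = diffs[~np.isnan(diffs)]
    n = diffs.size
    if n < 2:
        return {"t": np.nan, "p": np.nan, "n_pairs": n, "mean_diff": np.nan,
                "degenerate": False, "valid": False}
    sd = diffs.std(ddof=1)
    mean = diffs.mean()
    if sd == 0.0:
        if mean == 0.0:
            return {"t": 0.0, "p": 1.0, "n_pairs": n, "mean_diff": 0.0,
                    "degenerate": True, "valid": True}
        return {"t": np.inf if mean > 0 else -np.inf, "p": 0.0, "n_pairs": n,
                "mean_diff": mean, "degenerate": True, "valid": True}
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return {"t": float(t), "p": float(p), "n_pairs": n, "mean_diff": float(mean),
            "degenerate": False, "valid": True}
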