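"""Window-based comparison of regional SNP effects between populations.

Each chromosome is tiled with non-overlapping windows of a fixed bp length
anchored at coordinate 0.  Within a window the per-SNP additive variances

    a_j = 2 * g_hat_j^2 * p_j * (1 - p_j)

(with ``p_j`` the base-population frequency) are averaged per population and
compared with the pooled two-sample statistic

    t = (abar_A - abar_B) / sqrt((s2_A + s2_B) / N_SNP),

where ``s2_x`` is the within-window sample variance of the a_j and ``N_SNP``
the number of shared SNPs in the window.  Two-sided p-values use a t
distribution with 2*N_SNP - 2 degrees of freedom, and significance across
windows is controlled with the Benjamini-Hochberg step-up FDR.  A switch
allows testing the raw effects ``g_hat`` instead of the additive variances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .basefreq import BaseFreqSet
from .snpblup import SNPEffectSet, snp_additive_variance

#: Window lengths examined by default: 0.3 Mbp to 1.5 Mbp in 0.1 Mbp steps.
DEFAULT_WINDOW_LENGTHS_BP: list[int] = [int(l) for l in np.arange(3, 16) * 100_000]


@dataclass
class WindowSpec:
    """Non-overlapping half-open windows [start, end) tiling each chromosome."""

    length_bp: int
    windows: pd.DataFrame  # chrom, start_bp, end_bp, n_snp


def make_windows(snp_map: pd.DataFrame, length_bp: int) -> WindowSpec:
    """Tile every chromosome with windows of ``length_bp`` from coordinate 0.

    ``snp_map`` needs columns chrom and pos_bp.  Windows extend to just past
    the last SNP of each chromosome; windows containing no SNP are dropped.
    Every SNP belongs to exactly one window (index ``pos_bp // length_bp``).
    """
    if length_bp <= 0:
        raise ValueError("window length must be positive")
    win_idx = snp_map["pos_bp"].to_numpy() // length_bp
    grouped = (
        pd.DataFrame({"chrom": snp_map["chrom"], "k": win_idx})
        .groupby(["chrom", "k"], sort=True)
        .size()
        .reset_index(name="n_snp")
    )
    grouped["start_bp"] = grouped["k"] * length_bp
    grouped["end_bp"] = (grouped["k"] + 1) * length_bp
    return WindowSpec(
        length_bp=length_bp,
        windows=grouped[["chrom", "start_bp", "end_bp", "n_snp"]],
    )


def additive_effects(eff: SNPEffectSet, base: BaseFreqSet) -> pd.DataFrame:
    """Per-SNP additive variances 2 g^2 p (1-p) joined on snp_id."""
    g = eff.to_frame()
    p = base.to_frame()
    df = g.merge(p, on="snp_id", how="inner")
    df["a"] = snp_additive_variance(df["g_hat"].to_numpy(), df["p_base"].to_numpy())
    return df


def window_t_test(
    eff_a: pd.DataFrame,
    eff_b: pd.DataFrame,
    snp_map: pd.DataFrame,
    spec: WindowSpec,
    value: str = "a",
) -> pd.DataFrame:
    """Per-window pooled t-test of mean per-SNP values between populations.

    ``eff_a`` / ``eff_b`` carry per-SNP columns snp_id and ``value`` (the
    additive variance ``"a"`` by default, or ``"g_hat"`` for raw effects);
    only SNPs present in both populations enter.  Windows with fewer than
    two shared SNPs have an undefined variance and are excluded from
    testing (``tested = False``).

    Returns one row per window: chrom, start_bp, end_bp, n_snp, mean_a,
    mean_b, var_a, var_b, t, p, tested.
    """
    merged = eff_a[["snp_id", value]].merge(
        eff_b[["snp_id", value]], on="snp_id", suffixes=("_a", "_b")
    )
    merged = merged.merge(snp_map[["snp_id", "chrom", "pos_bp"]], on="snp_id")
    merged["k"] = merged["pos_bp"].to_numpy() // spec.length_bp

    rows = []
    for (chrom, k), grp in merged.groupby(["chrom", "k"], sort=True):
        va = grp[f"{value}_a"].to_numpy(dtype=float)
        vb = grp[f"{value}_b"].to_numpy(dtype=float)
        n = va.size
        row = {
            "chrom": chrom,
            "start_bp": int(k) * spec.length_bp,
            "end_bp": (int(k) + 1) * spec.length_bp,
            "n_snp": n,
            "mean_a": va.mean(),
            "mean_b": vb.mean(),
            "var_a": va.var(ddof=1) if n > 1 else np.nan,
            "var_b": vb.var(ddof=1) if n > 1 else np.nan,
        }
        if n < 2:
            row.update({"t": np.nan, "p": np.nan, "tested": False})
        else:
            denom = np.sqrt((row["var_a"] + row["var_b"]) / n)
            if denom == 0.0:
                t = 0.0 if row["mean_a"] == row["mean_b"] else np.inf * np.sign(
                    row["mean_a"] - row["mean_b"]
                )
            else:
                t = (row["mean_a"] - row["mean_b"]) / denom
            p = 2.0 * stats.t.sf(abs(t), df=2 * n - 2) if np.isfinite(t) else 0.0
            if t == 0.0:
                p = 1.0
            row.update({"t": float(t), "p": float(p), "tested": True})
        rows.append(row)
    return pd.DataFrame(rows)


def bh_fdr(p_values, q_max: float = 0.10) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns ``(q_values, significant)`` with ``significant = q <= q_max``.
    An empty input yields empty outputs.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q, q <= q_max


def annotate_fdr(results: pd.DataFrame, q_max: float = 0.10) -> pd.DataFrame:
    """Attach BH q-values and significance flags to tested windows.

    The FDR family is the set of tested windows in ``results`` (one window
    length, one trait).  Untested windows get NaN q and False.
    """
    out = results.copy()
    out["q"] = np.nan
    out["significant"] = False
    tested = out["tested"].to_numpy(dtype=bool)
    if tested.any():
        q, sig = bh_fdr(out.loc[tested, "p"].to_numpy(), q_max)
        out.loc[tested, "q"] = q
        out.loc[tested, "significant"] = sig
    return out


def significance_by_window_length(
    eff_a: pd.DataFrame,
    eff_b: pd.DataFrame,
    snp_map: pd.DataFrame,
    lengths_bp=DEFAULT_WINDOW_LENGTHS_BP,
    q_max: float = 0.10,
    value: str = "a",
) -> pd.DataFrame:
    """Proportion of significant windows for each window length.

    Reproduces the scan over window lengths: one BH family per length.
    """
    rows = []
    for L in lengths_bp:
        spec = make_windows(snp_map, L)
        res = annotate_fdr(window_t_test(eff_a, eff_b, snp_map, spec, value), q_max)
        tested = res["tested"].sum()
        rows.append(
            {
                "length_bp": L,
                "n_windows": len(res),
                "n_tested": int(tested),
                "n_significant": int(res["significant"].sum()),
                "prop_significant": res["significant"].sum() / tested if tested else np.nan,
            }
        )
    return pd.DataFrame(rows)
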