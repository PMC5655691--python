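"""Per-population SNP quality control and marker-set intersection.

SNPs are screened on minor allele frequency (MAF, computed on non-missing
genotypes with the counted-allele frequency folded to <= 0.5) and on call
rate; both thresholds are inclusive.  The two populations are filtered
independently first and only markers surviving QC in both are carried
forward, with the counted allele harmonised between panels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panels import MISSING, GenotypePanel

logger = logging.getLogger(__name__)


@dataclass
class QCReport:
    """Outcome of :func:`filter_panel` on one population."""

    population_id: str
    n_input: int
    n_failed_maf: int
    n_failed_callrate: int
    n_retained: int
    retained_ids: list[str]
    removed: pd.DataFrame  # snp_id, maf, call_rate, reason

    def summary(self) -> str:
        return (
            f"{self.population_id}: {self.n_input} SNPs in, "
            f"{self.n_failed_maf} failed MAF, {self.n_failed_callrate} failed "
            f"call rate, {self.n_retained} retained"
        )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# {self.summary()}\n")
            self.removed.to_csv(fh, sep="\t", index=False)


def filter_panel(
    panel: GenotypePanel, maf_min: float = 0.01, callrate_min: float = 0.90
) -> QCReport:
    """Screen every SNP on MAF and call rate.

    A SNP is retained iff its MAF (non-missing genotypes only) is
    ``>= maf_min`` *and* its fraction of non-missing calls is
    ``>= callrate_min``.  A SNP with all calls missing has no defined MAF and
    fails call rate.
    """
    if not 0 <= maf_min <= 1 or not 0 <= callrate_min <= 1:
        raise ValueError("thresholds must lie in [0, 1]")
    if panel.n_snp == 0 or panel.n_animals == 0:
        raise ValueError("empty panel")

    cr = panel.call_rate()
    maf = panel.maf()
    cr_ok = cr >= callrate_min
    # all-missing SNPs have NaN MAF; they already fail call rate (cr == 0)
    maf_ok = np.where(np.isnan(maf), False, maf >= maf_min)
    keep = cr_ok & maf_ok

    reasons = []
    for i in np.flatnonzero(~keep):
        parts = []
        if not maf_ok[i]:
            parts.append("maf")
        if not cr_ok[i]:
            parts.append("callrate")
        reasons.append((panel.snp_ids[i], maf[i], cr[i], "+".join(parts)))
    removed = pd.DataFrame(reasons, columns=["snp_id", "maf", "call_rate", "reason"])

    return QCReport(
        population_id=panel.population_id,
        n_input=panel.n_snp,
        n_failed_maf=int((~maf_ok).sum()),
        n_failed_callrate=int((~cr_ok).sum()),
        n_retained=int(keep.sum()),
        retained_ids=[panel.snp_ids[i] for i in np.flatnonzero(keep)],
        removed=removed,
    )


def apply_report(panel: GenotypePanel, report: QCReport) -> GenotypePanel:
    """Subset a panel to the SNPs a :class:`QCReport` retained."""
    idx = {s: i for i, s in enumerate(panel.snp_ids)}
    return panel.subset_snps(np.array([idx[s] for s in report.retained_ids]))


def intersect_panels(
    a: GenotypePanel, b: GenotypePanel
) -> tuple[GenotypePanel, GenotypePanel]:
    """Restrict both panels to their shared markers, in identical order.

    The counted allele is harmonised using the panels' allele labels when
    both carry them: a SNP whose labels are swapped between panels has its
    genotype column in ``b`` sign-flipped; a SNP whose labels cannot be
    reconciled at all is dropped with a warning.  Without allele labels the
    coding is assumed to match.
    """
    pos_b = {s: i for i, s in enumerate(b.snp_ids)}
    keep_a: list[int] = []
    keep_b: list[int] = []
    flip_b: list[int] = []
    for ia, snp in enumerate(a.snp_ids):
        ib = pos_b.get(snp)
        if ib is None:
            continue
        if a.alleles is not None and b.alleles is not None:
            aa, ab = a.alleles[ia], b.alleles[ib]
            if tuple(aa) == tuple(ab):
                pass
            elif tuple(aa) == (ab[1], ab[0]):
                flip_b.append(len(keep_b))
            else:
                logger.warning(
                    "dropping %s: irreconcilable alleles %s vs %s", snp, aa, ab
                )
                continue
        keep_a.append(ia)
        keep_b.append(ib)

    out_a = a.subset_snps(np.array(keep_a, dtype=int))
    out_b = b.subset_snps(np.array(keep_b, dtype=int))
    if flip_b:
        g = out_b.genotypes.copy()
        cols = np.array(flip_b, dtype=int)
        obs = g[:, cols] != MISSING  # missing calls stay missing
        g[:, cols] = np.where(obs, -g[:, cols], g[:, cols])
        out_b.genotypes = g
    return out_a, out_b
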