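"""End-to-end orchestration: qc -> ld -> snpblup -> basefreq -> regions -> crosspop.

The pipeline compares two populations (by convention ordered (PL, DE) — the
first population is "a" everywhere) and writes one TSV per stage plus a
summary report.  Defaults follow the standard settings used throughout the
package: MAF >= 0.01, call rate >= 0.90, the nine LD distance intervals,
window lengths 0.3-1.5 Mbp in 0.1 Mbp steps, and a 10% FDR.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import basefreq as bf
from . import crosspop, ld, qc, regions, snpblup
from .panels import GenotypePanel, HaplotypePanel

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved settings for one full analysis run."""

    maf_min: float = 0.01
    callrate_min: float = 0.90
    window_lengths_bp: list = field(
        default_factory=lambda: list(regions.DEFAULT_WINDOW_LENGTHS_BP)
    )
    detail_window_bp: int = 600_000
    fdr_q: float = 0.10
    gene_content_lambda: float = 0.01
    blup_tol: float = 1e-10
    blup_max_iter: int = 2000
    reml_tol: float = 1e-10
    seed: int = 1


@dataclass
class StageInputs:
    """In-memory inputs for one population."""

    panel: GenotypePanel
    haplotypes: HaplotypePanel | None
    pedigree: bf.Pedigree
    proofs: dict  # trait -> DeregressedProofs
    variances: dict  # trait -> VarianceSpec (n_snp updated after intersection)


def _restrict_haps(hap: HaplotypePanel, panel: GenotypePanel) -> HaplotypePanel:
    idx = {s: i for i, s in enumerate(hap.snp_ids)}
    cols = np.array([idx[s] for s in panel.snp_ids])
    return HaplotypePanel(
        population_id=hap.population_id,
        animal_ids=list(hap.animal_ids),
        snp_ids=list(panel.snp_ids),
        chrom=panel.chrom,
        pos_bp=panel.pos_bp,
        haplotypes=hap.haplotypes[:, cols],
    )


def run_full_analysis(
    inputs_a: StageInputs,
    inputs_b: StageInputs,
    cfg: RunConfig,
    outdir=None,
) -> dict:
    """Run every stage on two populations and return the result bundle.

    When ``outdir`` is given, each stage writes its TSV there and a
    ``summary.json`` echoes the configuration alongside the headline
    numbers.
    """
    out: dict = {"config": dataclasses.asdict(cfg)}
    pa, pb = inputs_a.panel.population_id, inputs_b.panel.population_id

    # ---- qc ------------------------------------------------------------
    rep_a = qc.filter_panel(inputs_a.panel, cfg.maf_min, cfg.callrate_min)
    rep_b = qc.filter_panel(inputs_b.panel, cfg.maf_min, cfg.callrate_min)
    logger.info(rep_a.summary())
    logger.info(rep_b.summary())
    panel_a, panel_b = qc.intersect_panels(
        qc.apply_report(inputs_a.panel, rep_a), qc.apply_report(inputs_b.panel, rep_b)
    )
    logger.info("intersection: %d shared SNPs", panel_a.n_snp)
    out["qc"] = {pa: rep_a, pb: rep_b, "n_shared": panel_a.n_snp}
    snp_map = panel_a.snp_map()

    # ---- ld ------------------------------------------------------------
    ld_recs, fits = {}, {}
    for pop, ins, panel in ((pa, inputs_a, panel_a), (pb, inputs_b, panel_b)):
        if ins.haplotypes is not None:
            recs = ld.ld_records(_restrict_haps(ins.haplotypes, panel))
        else:
            recs = ld.ld_records_from_genotypes(panel)
        ld_recs[pop] = recs
        bins = ld.bin_ld(recs)
        fits[pop] = {"bins": bins, "fit": ld.fit_decay(bins)}
        logger.info("%s: %d LD pairs, beta=%.4f", pop, len(recs), fits[pop]["fit"].beta)
    paired = {
        b["interval"]: ld.paired_interval_test(ld_recs[pa], ld_recs[pb],
                                               (b["lo_mbp"], b["hi_mbp"]))
        for _, b in fits[pa]["bins"].iterrows()
    }
    out["ld"] = {
        "fits": fits,
        "paired_tests": paired,
        "beta_ratio": fits[pb]["fit"].beta / fits[pa]["fit"].beta,
    }

    # ---- basefreq ------------------------------------------------------
    base = {
        pop: bf.base_freqs_for_panel(ins.pedigree, panel, cfg.gene_content_lambda)
        for pop, ins, panel in ((pa, inputs_a, panel_a), (pb, inputs_b, panel_b))
    }
    out["basefreq"] = {
        "sets": base,
        "agreement": bf.base_freq_agreement(base[pa], base[pb]),
    }

    # ---- snpblup + regions + crosspop, per trait -----------------------
    traits = sorted(inputs_a.proofs)
    out["traits"] = {}
    for trait in traits:
        eff = {}
        for pop, ins, panel in ((pa, inputs_a, panel_a), (pb, inputs_b, panel_b)):
            var = dataclasses.replace(ins.variances[trait], n_snp=panel.n_snp)
            eff[pop] = snpblup.solve_snp_blup(
                panel, ins.proofs[trait], var,
                tol=cfg.blup_tol, max_iter=cfg.blup_max_iter,
            )
            logger.info("%s/%s: solver %s in %d iterations", pop, trait,
                        "converged" if eff[pop].converged else "NOT converged",
                        eff[pop].n_iter)
        add = {p: regions.additive_effects(eff[p], base[p]) for p in (pa, pb)}
        detail = regions.annotate_fdr(
            regions.window_t_test(
                add[pb], add[pa], snp_map,
                regions.make_windows(snp_map, cfg.detail_window_bp),
            ),
            cfg.fdr_q,
        )
        scan = regions.significance_by_window_length(
            add[pb], add[pa], snp_map, cfg.window_lengths_bp, cfg.fdr_q
        )
        pairs = crosspop.EffectPairs.from_effect_sets(eff[pa], eff[pb], trait)
        g = crosspop.fit_bivariate(pairs, tol=cfg.reml_tol)
        out["traits"][trait] = {
            "effects": eff,
            "windows_detail": detail,
            "window_scan": scan,
            "crosspop": g,
            "variance_ratio": crosspop.variance_ratio(g),
        }

    if outdir is not None:
        _write_bundle(out, Path(outdir), panel_a, panel_b, ld_recs, snp_map)
    return out


def _write_bundle(out, outdir: Path, panel_a, panel_b, ld_recs, snp_map) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    pa, pb = panel_a.population_id, panel_b.population_id
    for pop in (pa, pb):
        out["qc"][pop].to_tsv(outdir / f"qc_removed_{pop}.tsv")
        ld_recs[pop].to_csv(outdir / f"ld_records_{pop}.tsv", sep="\t", index=False)
        out["ld"]["fits"][pop]["bins"].to_csv(
            outdir / f"ld_bins_{pop}.tsv", sep="\t", index=False
        )
        out["basefreq"]["sets"][pop].to_frame().to_csv(
            outdir / f"basefreq_{pop}.tsv", sep="\t", index=False
        )
    for trait, tr in out["traits"].items():
        for pop, panel in ((pa, panel_a), (pb, panel_b)):
            tr["effects"][pop].to_frame(panel).to_csv(
                outdir / f"effects_{pop}_{trait}.tsv", sep="\t", index=False
            )
        tr["windows_detail"].to_csv(
            outdir / f"windows_{trait}.tsv", sep="\t", index=False
        )
        tr["window_scan"].to_csv(
            outdir / f"window_scan_{trait}.tsv", sep="\t", index=False
        )
    summary = {
        "config": out["config"],
        "n_shared_snps": out["qc"]["n_shared"],
        "ld": {
            pop: {"alpha": out["ld"]["fits"][pop]["fit"].alpha,
                  "beta": out["ld"]["fits"][pop]["fit"].beta}
            for pop in (pa, pb)
        },
        "ld_beta_ratio": out["ld"]["beta_ratio"],
        "paired_ld_tests": {
            k: {kk: (None if isinstance(v[kk], float) and np.isnan(v[kk]) else v[kk])
                for kk in ("t", "p", "n_pairs")}
            for k, v in out["ld"]["paired_tests"].items()
        },
        "basefreq_agreement": out["basefreq"]["agreement"],
        "traits": {
            trait: {
                "G": tr["crosspop"].G.tolist(),
                "sigma2_eps": tr["crosspop"].sigma2_eps,
                "rho_g": tr["crosspop"].rho_g,
                "variance_ratio": tr["variance_ratio"],
                "n_significant_detail": int(tr["windows_detail"]["significant"].sum()),
            }
            for trait, tr in out["traits"].items()
        },
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
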