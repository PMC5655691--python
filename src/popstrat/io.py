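"""Readers and writers for the plain-text formats used by the pipeline.

Genotypes travel as PLINK ped/map text files or VCF; haplotypes, pedigrees,
deregressed proofs and per-SNP effect tables are tab-separated files with a
header line.  All coordinates are 1-based in files and kept as-is
internally (positions only ever enter differences and window arithmetic).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .basefreq import Pedigree
from .panels import MISSING, GenotypePanel, HaplotypePanel
from .snpblup import DeregressedProofs


# ---------------------------------------------------------------- PLINK ped/map

def read_ped_map(ped_path, map_path, population_id: str) -> GenotypePanel:
    """Read a PLINK text fileset into a GenotypePanel.

    The counted (+1) allele of each SNP is the alphabetically first of the
    two alleles observed at that locus, so the coding is deterministic and
    the allele labels are stored on the panel for later harmonisation.
    ``0`` denotes a missing allele.
    """
    mp = pd.read_csv(
        map_path, sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos_bp"], dtype={"chrom": str},
    )
    n_snp = len(mp)
    animal_ids: list[str] = []
    rows: list[np.ndarray] = []
    allele_rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snp:
                raise ValueError(
                    f"ped line for {parts[1] if len(parts) > 1 else '?'} has "
                    f"{len(parts) - 6} allele fields, expected {2 * n_snp}"
                )
            animal_ids.append(parts[1])
            al = np.array(parts[6:], dtype="U2").reshape(n_snp, 2)
            allele_rows.append(al)
    alleles_all = np.stack(allele_rows)  # animals x snps x 2

    geno = np.full((len(animal_ids), n_snp), MISSING, dtype=np.int8)
    allele_labels = np.empty((n_snp, 2), dtype="U2")
    for j in range(n_snp):
        col = alleles_all[:, j, :]
        obs = col[col != "0"]
        uniq = sorted(set(obs.tolist()))
        if len(uniq) > 2:
            raise ValueError(f"SNP {mp['snp_id'][j]} has >2 alleles: {uniq}")
        counted = uniq[0] if uniq else "A"
        other = uniq[1] if len(uniq) > 1 else counted
        allele_labels[j] = (counted, other)
        ok = (col != "0").all(axis=1)
        geno[ok, j] = (col[ok] == counted).sum(axis=1) - 1
    return GenotypePanel(
        population_id=population_id,
        animal_ids=animal_ids,
        snp_ids=mp["snp_id"].tolist(),
        chrom=mp["chrom"].to_numpy(),
        pos_bp=mp["pos_bp"].to_numpy(),
        genotypes=geno,
        alleles=allele_labels,
    )


def write_ped_map(panel: GenotypePanel, prefix) -> None:
    """Write a panel as PLINK text files ``<prefix>.ped`` / ``<prefix>.map``."""
    prefix = Path(prefix)
    with open(prefix.with_suffix(".map"), "w") as fh:
        for snp, c, p in zip(panel.snp_ids, panel.chrom, panel.pos_bp):
            fh.write(f"{c}\t{snp}\t0\t{p}\n")
    if panel.alleles is not None:
        counted, other = panel.alleles[:, 0], panel.alleles[:, 1]
    else:
        counted = np.full(panel.n_snp, "A")
        other = np.full(panel.n_snp, "B")
    code = {1: lambda j: f"{counted[j]} {counted[j]}",
            0: lambda j: f"{counted[j]} {other[j]}",
            -1: lambda j: f"{other[j]} {other[j]}",
            MISSING: lambda j: "0 0"}
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, aid in enumerate(panel.animal_ids):
            fields = [f"F{i}", aid, "0", "0", "0", "-9"]
            g = panel.genotypes[i]
            fields += [code[int(g[j])](j) for j in range(panel.n_snp)]
            fh.write(" ".join(fields) + "\n")


def read_vcf(path, population_id: str) -> GenotypePanel:
    """Read biallelic sites from a VCF; the ALT allele is counted."""
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path), gts012=True)
    animal_ids = list(vcf.samples)
    chrom, pos, snp_ids, cols, alleles = [], [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        chrom.append(var.CHROM)
        pos.append(var.POS)
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        alleles.append((var.ALT[0], var.REF))
        # gt_types with gts012: 0=hom ref, 1=het, 2=hom alt, 3=missing
        gt = np.asarray(var.gt_types)
        col = np.select([gt == 0, gt == 1, gt == 2], [-1, 0, 1], default=MISSING)
        cols.append(col.astype(np.int8))
    return GenotypePanel(
        population_id=population_id,
        animal_ids=animal_ids,
        snp_ids=snp_ids,
        chrom=np.array(chrom),
        pos_bp=np.array(pos),
        genotypes=np.column_stack(cols),
        alleles=np.array(alleles, dtype="U20"),
    )


# -------------------------------------------------------------------- TSV files

def write_haplotypes(panel: HaplotypePanel, path) -> None:
    """Phased haplotypes as TSV: animal_id, hap (0/1), then one 0/1 string."""
    with open(path, "w") as fh:
        fh.write("animal_id\thap\t" + "\t".join(panel.snp_ids) + "\n")
        for i, aid in enumerate(panel.animal_ids):
            for h in (0, 1):
                row = panel.haplotypes[2 * i + h]
                fh.write(f"{aid}\t{h}\t" + "\t".join(map(str, row)) + "\n")


def read_haplotypes(path, snp_map: pd.DataFrame, population_id: str) -> HaplotypePanel:
    """Read the TSV written by :func:`write_haplotypes`.

    ``snp_map`` (snp_id, chrom, pos_bp) supplies the positions; its SNP
    order must match the file columns.
    """
    df = pd.read_csv(path, sep="\t", dtype={"animal_id": str})
    snp_ids = list(df.columns[2:])
    if snp_ids != snp_map["snp_id"].tolist():
        raise ValueError("haplotype file SNP columns do not match the map")
    animal_ids = df["animal_id"].tolist()[::2]
    return HaplotypePanel(
        population_id=population_id,
        animal_ids=animal_ids,
        snp_ids=snp_ids,
        chrom=snp_map["chrom"].to_numpy(),
        pos_bp=snp_map["pos_bp"].to_numpy(),
        haplotypes=df[snp_ids].to_numpy(dtype=np.int8),
    )


def write_proofs(proofs: DeregressedProofs, path) -> None:
    pd.DataFrame(
        {"animal_id": proofs.animal_ids, "trait": proofs.trait,
         "debv": proofs.y, "edc": proofs.edc}
    ).to_csv(path, sep="\t", index=False)


def read_proofs(path, trait: str | None = None) -> DeregressedProofs:
    df = pd.read_csv(path, sep="\t", dtype={"animal_id": str})
    if trait is not None:
        df = df[df["trait"] == trait]
        if df.empty:
            raise ValueError(f"no records for trait {trait!r}")
    traits = df["trait"].unique()
    if len(traits) != 1:
        raise ValueError(f"proofs file holds several traits {traits}; pass one")
    return DeregressedProofs(
        df["animal_id"].tolist(), str(traits[0]),
        df["debv"].to_numpy(), df["edc"].to_numpy(),
    )


def write_pedigree(ped: Pedigree, path) -> None:
    pd.DataFrame(
        {"animal_id": ped.animal_ids, "sire_id": ped.sire_ids,
         "dam_id": ped.dam_ids, "genotyped": ped.genotyped.astype(int)}
    ).to_csv(path, sep="\t", index=False)


def read_pedigree(path, genotyped_ids=None) -> Pedigree:
    df = pd.read_csv(
        path, sep="\t", dtype={"animal_id": str, "sire_id": str, "dam_id": str}
    )
    gt = None
    if "genotyped" in df.columns and genotyped_ids is None:
        gt = df["genotyped"].to_numpy(dtype=bool)
    elif genotyped_ids is not None:
        gset = set(genotyped_ids)
        gt = np.array([a in gset for a in df["animal_id"]])
    return Pedigree(
        df["animal_id"].tolist(), df["sire_id"].tolist(), df["dam_id"].tolist(), gt
    )


def write_truth(truth, path) -> None:
    """Serialise a SimTruth to JSON (lossless float round-trip via repr)."""
    payload = {
        "base_freqs": truth.base_freqs.tolist(),
        "pop_freqs": {k: v.tolist() for k, v in truth.pop_freqs.items()},
        "true_effects": {k: v.tolist() for k, v in truth.true_effects.items()},
        "true_G": truth.true_G.tolist(),
        "decay_rates": truth.decay_rates,
    }
    Path(path).write_text(json.dumps(payload))


def read_truth(path):
    from .simdata import SimTruth

    d = json.loads(Path(path).read_text())
    return SimTruth(
        base_freqs=np.array(d["base_freqs"]),
        pop_freqs={k: np.array(v) for k, v in d["pop_freqs"].items()},
        true_effects={k: np.array(v) for k, v in d["true_effects"].items()},
        true_G=np.array(d["true_G"]),
        decay_rates=d["decay_rates"],
    )
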