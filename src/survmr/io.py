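"""Readers and writers for the pipeline's on-disk exchange formats.

Everything round-trips through plain text: genotypes as a dosage TSV (samples
x variants) with a variant-metadata sidecar, or as a minimal VCF with GT:DS
genotype fields; expression as a genes x samples count TSV with a TSS sidecar
(gene_id, chrom, tss; 1-based); clinical and covariate tables as TSV.
"""

from __future__ import annotations

import pandas as pd

from survmr.containers import ClinicalTable, CovariateTable, ExpressionMatrix, GenotypeMatrix


def write_dosage_tsv(G: GenotypeMatrix, path, meta_path) -> None:
    G.dosages.to_csv(path, sep="\t")
    G.variant_meta.to_csv(meta_path, sep="\t")


def read_dosage_tsv(path, meta_path) -> GenotypeMatrix:
    d = pd.read_csv(path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return GenotypeMatrix(d, meta.loc[d.columns])


def write_expression_tsv(E: ExpressionMatrix, path, tss_path) -> None:
    E.values.to_csv(path, sep="\t")
    E.gene_meta.to_csv(tss_path, sep="\t")


def read_expression_tsv(path, tss_path, scale: str = "raw") -> ExpressionMatrix:
    v = pd.read_csv(path, sep="\t", index_col=0)
    meta = pd.read_csv(tss_path, sep="\t", index_col=0)
    return ExpressionMatrix(v, meta.loc[v.index], scale=scale)


def write_clinical_tsv(clinical: ClinicalTable, path) -> None:
    clinical.table.to_csv(path, sep="\t")


def read_clinical_tsv(path) -> ClinicalTable:
    return ClinicalTable(pd.read_csv(path, sep="\t", index_col=0))


def write_covariates_tsv(C: CovariateTable, path) -> None:
    C.table.to_csv(path, sep="\t")


def read_covariates_tsv(path, abundance_cols=None) -> CovariateTable:
    return CovariateTable(pd.read_csv(path, sep="\t", index_col=0), abundance_cols or [])


def write_vcf(G: GenotypeMatrix, path) -> None:
    """Write a minimal VCF with GT (hard call from rounded dosage) and DS."""
    import pysam

    header = pysam.VariantHeader()
    for chrom in pd.unique(G.variant_meta["chrom"].astype(str)):
        header.contigs.add(chrom)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DS", 1, "Float", "Estimated alternate allele dosage")
    for s in G.samples:
        header.add_sample(str(s))
    meta = G.variant_meta.sort_values(["chrom", "pos"])
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for vid, row in meta.iterrows():
            rec = vf.new_record(
                contig=str(row["chrom"]),
                start=int(row["pos"]) - 1,
                stop=int(row["pos"]),
                alleles=(str(row["ref"]), str(row["alt"])),
                id=str(vid),
            )
            for s in G.samples:
                ds = float(G.dosages.loc[s, vid])
                hard = int(round(ds))
                rec.samples[str(s)]["GT"] = (0, 0) if hard == 0 else ((0, 1) if hard == 1 else (1, 1))
                rec.samples[str(s)]["DS"] = ds
            vf.write(rec)


def read_vcf(path) -> GenotypeMatrix:
    """Read dosages (DS, falling back to GT allele counts) from a VCF."""
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        rows, meta = [], []
        for rec in vf:
            dos = []
            for s in samples:
                smp = rec.samples[s]
                ds = smp.get("DS")
                if ds is None:
                    ds = float(sum(1 for a in smp["GT"] if a == 1))
                dos.append(float(ds))
            rows.append(dos)
            meta.append(
                {
                    "variant_id": rec.id,
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": rec.alts[0],
                }
            )
    meta = pd.DataFrame(meta).set_index("variant_id")
    d = pd.DataFrame(rows, index=meta.index, columns=samples).T
    d.index.name = "sample_id"
    freq = d.mean(axis=0) / 2.0
    meta["maf"] = pd.concat([freq, 1 - freq], axis=1).min(axis=1)
    return GenotypeMatrix(d, meta)
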