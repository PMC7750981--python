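"""Readers and writers for the package's plain-text interchange formats.

VariantWeights: 5-column TSV (variant_id, effect_allele, other_allele,
beta, freq).  GenotypeMatrix: TSV with individuals in rows, variants in
columns, dosages in [0, 2]; optionally a minimal VCFv4.2 with a per-sample
DS FORMAT field.  CohortTable and ScoreVector: CSV with a header row,
UTF-8, '.' decimal.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

WEIGHT_COLS = ["variant_id", "effect_allele", "other_allele", "beta", "freq"]


def write_weights(weights: pd.DataFrame, path) -> None:
    weights[[c for c in WEIGHT_COLS if c in weights.columns]].to_csv(
        path, sep="\t", index=False
    )


def read_weights(path) -> pd.DataFrame:
    w = pd.read_csv(path, sep="\t")
    missing = [c for c in WEIGHT_COLS[:4] if c not in w.columns]
    if missing:
        raise ValueError(f"weights file lacks columns {missing}")
    return w


def write_dosages(genotypes: pd.DataFrame, path) -> None:
    genotypes.to_csv(path, sep="\t", index_label="individual_id")


def read_dosages(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="individual_id")


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_scores(scores: pd.DataFrame, path) -> None:
    scores.to_csv(path, index=False)


def read_scores(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_vcf(genotypes: pd.DataFrame, weights: pd.DataFrame, path) -> None:
    """Minimal VCFv4.2 with per-sample dosage (DS) for the panel variants.

    REF is the weights table's other allele, ALT the effect allele, so DS
    counts effect alleles directly.
    """
    samples = list(genotypes.index)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for pos, (_, row) in enumerate(weights.iterrows(), start=1):
            ds = genotypes[row["variant_id"]].to_numpy()
            fh.write(
                f"1\t{pos}\t{row['variant_id']}\t{row['other_allele']}\t"
                f"{row['effect_allele']}\t.\t.\t.\tDS\t"
                + "\t".join(f"{d:g}" for d in ds)
                + "\n"
            )


def read_vcf_dosages(path) -> pd.DataFrame:
    """Dosage matrix from a VCF with DS (preferred) or GT fields.

    Requires cyvcf2 (optional dependency).
    """
    from cyvcf2 import VCF  # deferred import: optional extra

    vcf = VCF(str(path))
    samples = vcf.samples
    ids, rows = [], []
    for variant in vcf:
        ids.append(variant.ID)
        try:
            ds = variant.format("DS")[:, 0]
        except (KeyError, TypeError):
            ds = variant.gt_types.astype(float)  # 0/1/2 from hard genotypes
            ds[ds == 3] = float("nan")  # unknown
        rows.append(ds)
    frame = pd.DataFrame(rows, index=ids, columns=samples).T
    frame.index.name = "individual_id"
    return frame


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
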