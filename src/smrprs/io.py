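"""Readers and writers for the pipeline's file formats.

Summary statistics travel as tab-delimited text: GWAS in the COJO ``.ma``
dialect (``SNP A1 A2 freq b se p n``) and QTL results in the SMR query
layout.  Genotypes (reference panels and cohorts) are exchanged either as
dosage TSV (individuals x variants, with a ``<name>.variants.tsv``
sidecar for variant metadata) or as uncompressed VCF with DS/GT FORMAT
fields.  Weight files follow the plink ``--score`` convention.  Ground
truth and cohort labels ride in JSON/TSV sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .prs import PrsModel, ScoreSet
from .synth import CohortData, GwasSummary, QtlDataset, ReferencePanel

__all__ = [
    "write_gwas_ma",
    "read_gwas_ma",
    "write_qtl_tsv",
    "read_qtl_tsv",
    "write_panel_tsv",
    "read_panel_tsv",
    "write_cohort_tsv",
    "read_cohort_tsv",
    "write_vcf",
    "read_genotypes_vcf",
    "panel_from_genotypes",
    "read_panel_any",
    "read_cohort_any",
    "write_weights",
    "read_weights",
    "write_scores",
    "read_scores",
]

_FLOAT_FMT = "%.10g"

_QTL_COLS = [
    "probe",
    "probe_chr",
    "probe_bp",
    "gene",
    "snp",
    "snp_chr",
    "snp_bp",
    "a1",
    "a2",
    "freq",
    "b",
    "se",
    "p",
]


def _to_tsv(df: pd.DataFrame, path: Path | str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


# -- GWAS summary (.ma) -------------------------------------------------------

def write_gwas_ma(gwas: GwasSummary, path: Path | str) -> None:
    out = gwas.table.rename(
        columns={"snp": "SNP", "a1": "A1", "a2": "A2", "n": "n"}
    )[["SNP", "A1", "A2", "freq", "b", "se", "p", "n"]]
    _to_tsv(out, path)


def read_gwas_ma(path: Path | str) -> GwasSummary:
    df = pd.read_csv(path, sep=r"\s+")
    df = df.rename(columns={c: c.lower() for c in df.columns})
    need = ["snp", "a1", "a2", "freq", "b", "se", "p", "n"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"GWAS file {path} missing columns {missing}")
    return GwasSummary(table=df[need])


# -- QTL summary --------------------------------------------------------------

def write_qtl_tsv(qtl: QtlDataset, path: Path | str) -> None:
    _to_tsv(qtl.table[_QTL_COLS], path)


def read_qtl_tsv(path: Path | str, n_study: int = 0) -> QtlDataset:
    df = pd.read_csv(path, sep="\t", dtype={"probe_chr": str, "snp_chr": str})
    missing = [c for c in _QTL_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"QTL file {path} missing columns {missing}")
    return QtlDataset(table=df[_QTL_COLS], n_study=n_study)


# -- reference panel / cohort as dosage TSV -----------------------------------

def write_panel_tsv(panel: ReferencePanel, prefix: Path | str) -> tuple[Path, Path]:
    prefix = Path(prefix)
    dos_path = prefix.with_suffix(".dosage.tsv")
    var_path = prefix.with_suffix(".variants.tsv")
    dos = pd.DataFrame(panel.dosages, columns=panel.variants["id"])
    dos.insert(0, "iid", [f"P{i:06d}" for i in range(panel.n_individuals)])
    _to_tsv(dos, dos_path)
    _to_tsv(panel.variants, var_path)
    meta = {"seed": panel.seed}
    var_path.with_suffix(".json").write_text(json.dumps(meta))
    return dos_path, var_path


def read_panel_tsv(prefix: Path | str) -> ReferencePanel:
    prefix = Path(prefix)
    dos = pd.read_csv(prefix.with_suffix(".dosage.tsv"), sep="\t")
    variants = pd.read_csv(prefix.with_suffix(".variants.tsv"), sep="\t", dtype={"chrom": str})
    meta_path = prefix.with_suffix(".variants.json")
    seed = json.loads(meta_path.read_text()).get("seed", 0) if meta_path.exists() else 0
    dosages = dos.drop(columns=["iid"]).to_numpy(dtype=float)
    return ReferencePanel(variants=variants, dosages=dosages, seed=seed)


def write_cohort_tsv(cohort: CohortData, prefix: Path | str) -> tuple[Path, Path]:
    prefix = Path(prefix)
    dos_path = prefix.with_suffix(".dosage.tsv")
    var_path = prefix.with_suffix(".variants.tsv")
    dos = pd.DataFrame(cohort.dosages, columns=cohort.variants["id"])
    dos.insert(0, "iid", cohort.iids)
    dos.insert(1, "label", cohort.labels)
    _to_tsv(dos, dos_path)
    _to_tsv(cohort.variants, var_path)
    var_path.with_suffix(".json").write_text(json.dumps({"design": cohort.design}))
    return dos_path, var_path


def read_cohort_tsv(prefix: Path | str) -> CohortData:
    prefix = Path(prefix)
    dos = pd.read_csv(prefix.with_suffix(".dosage.tsv"), sep="\t")
    variants = pd.read_csv(prefix.with_suffix(".variants.tsv"), sep="\t", dtype={"chrom": str})
    meta_path = prefix.with_suffix(".variants.json")
    design = "case_control"
    if meta_path.exists():
        design = json.loads(meta_path.read_text()).get("design", "case_control")
    iids = dos["iid"].astype(str).tolist()
    labels = dos["label"].to_numpy(dtype=int)
    dosages = dos.drop(columns=["iid", "label"]).to_numpy(dtype=float)
    return CohortData(
        dosages=dosages, labels=labels, variants=variants, design=design, iids=iids
    )


# -- VCF ----------------------------------------------------------------------

def write_vcf(
    variants: pd.DataFrame, dosages: np.ndarray, iids: list[str], path: Path | str
) -> None:
    """Write dosages as an uncompressed VCF (FORMAT DS; GT from rounding)."""
    path = Path(path)
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype (rounded dosage)">',
        '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage of ALT allele">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(iids),
    ]
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    for j, (_, v) in enumerate(variants.iterrows()):
        # effect allele (a1) is written as ALT so DS is the effect-allele dosage
        fields = [str(v["chrom"]), str(int(v["pos"])), str(v["id"]), str(v["a2"]), str(v["a1"]), ".", "PASS", "."]
        fields.append("GT:DS")
        col = dosages[:, j]
        for d in col:
            if np.isnan(d):
                fields.append("./.:.")
            else:
                fields.append(f"{gt_map[int(round(d))]}:{d:.4g}")
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n")


def read_genotypes_vcf(path: Path | str) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Read (variants, dosages, sample ids) from a VCF via cyvcf2.

    The ALT allele is taken as the effect allele (a1); DS is preferred,
    falling back to summing GT alleles.  Missing entries become NaN.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    iids = list(vcf.samples)
    rows, cols = [], []
    for rec in vcf:
        rows.append(
            {
                "chrom": str(rec.CHROM),
                "pos": int(rec.POS),
                "id": rec.ID or f"{rec.CHROM}:{rec.POS}",
                "a1": rec.ALT[0],
                "a2": rec.REF,
            }
        )
        ds = None
        try:
            ds = rec.format("DS")
        except Exception:
            ds = None
        if ds is not None:
            col = np.asarray(ds, dtype=float).ravel()
            col[col < 0] = np.nan
        else:
            gt = np.asarray(rec.genotype.array())[:, :2].astype(float)
            gt[gt < 0] = np.nan
            col = gt.sum(axis=1)
        cols.append(col)
    variants = pd.DataFrame(rows)
    dosages = np.column_stack(cols) if cols else np.empty((len(iids), 0))
    return variants, dosages, iids


def panel_from_genotypes(variants: pd.DataFrame, dosages: np.ndarray) -> ReferencePanel:
    """Wrap raw genotypes (e.g. from a VCF) as a reference panel.

    Generative metadata is filled with empirical frequencies and a
    no-LD-model placeholder: such a panel supports LD estimation (all the
    SMR/HEIDI/pruning stages need) but not resampling new individuals.
    """
    v = variants.copy()
    v["maf"] = dosages.mean(axis=0) / 2.0
    v["block"] = 0
    v["latent_rho"] = 0.0
    return ReferencePanel(variants=v, dosages=np.asarray(dosages, dtype=float), seed=0)


def read_panel_any(path: Path | str) -> ReferencePanel:
    """Read a panel from a dosage-TSV prefix or an uncompressed VCF."""
    path = Path(path)
    if path.suffix == ".vcf":
        variants, dosages, _ = read_genotypes_vcf(path)
        return panel_from_genotypes(variants, dosages)
    return read_panel_tsv(path)


def read_cohort_any(path: Path | str) -> CohortData:
    """Read a cohort from a dosage-TSV prefix or a VCF plus labels sidecar.

    For a VCF ``<name>.vcf`` the binary outcome labels are read from
    ``<name>.labels.tsv`` (columns iid, label).
    """
    path = Path(path)
    if path.suffix != ".vcf":
        return read_cohort_tsv(path)
    variants, dosages, iids = read_genotypes_vcf(path)
    lab = pd.read_csv(path.with_suffix(".labels.tsv"), sep="\t").set_index("iid")
    labels = lab.loc[iids, "label"].to_numpy(dtype=int)
    return CohortData(
        dosages=dosages, labels=labels, variants=variants, design="case_control", iids=iids
    )


# -- weight files -------------------------------------------------------------

def write_weights(model: PrsModel, path: Path | str) -> None:
    _to_tsv(model.table, path)


def read_weights(path: Path | str, label: str | None = None) -> PrsModel:
    df = pd.read_csv(path, sep=r"\s+")
    df = df.rename(columns={c: c.lower() for c in df.columns})
    if {"snp", "effect_allele", "other_allele", "weight"} <= set(df.columns):
        tab = df[["snp", "effect_allele", "other_allele", "weight"]]
    elif len(df.columns) == 3:  # plink 3-column score file: snp, allele, weight
        tab = df.copy()
        tab.columns = ["snp", "effect_allele", "weight"]
        tab["other_allele"] = "N"
        tab = tab[["snp", "effect_allele", "other_allele", "weight"]]
    else:
        raise ValueError(f"unrecognised weight file layout in {path}")
    return PrsModel(table=tab, label=label or Path(path).stem)


# -- score files --------------------------------------------------------------

def write_scores(scores: ScoreSet, path: Path | str) -> None:
    df = pd.DataFrame(
        {
            "iid": scores.iids or [f"I{i:06d}" for i in range(scores.scores.size)],
            "score": scores.scores,
            "n_variants_used": scores.n_variants_used,
            "label": scores.labels,
        }
    )
    _to_tsv(df, path)


def read_scores(path: Path | str, name: str = "prs") -> ScoreSet:
    df = pd.read_csv(path, sep="\t")
    return ScoreSet(
        scores=df["score"].to_numpy(dtype=float),
        labels=df["label"].to_numpy(dtype=int),
        label=name,
        n_variants_used=int(df["n_variants_used"].iloc[0]) if len(df) else 0,
        iids=df["iid"].astype(str).tolist(),
    )
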