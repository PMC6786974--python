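"""Readers and writers for the on-disk formats the toolkit exchanges.

Genotypes travel as VCF 4.2 with a per-sample ``DS`` (dosage) FORMAT field
and an ``INFO``/``AF`` INFO entry; genetic maps as PLINK 4-column map files
(chrom, id, cM, bp); phenotype/covariate/confound tables as TSV with a
``sample_id`` first column.  Reading of VCF goes through cyvcf2.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .containers import GenotypeSet, PhenotypeTable


# ---------------------------------------------------------------------------
# VCF dosages
# ---------------------------------------------------------------------------

def write_vcf_dosages(G: GenotypeSet, path: str | Path) -> Path:
    """Write a GenotypeSet as an uncompressed VCF with GT and DS fields."""
    path = Path(path)
    v = G.variants
    hard = G.get_hard_calls()
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=INFO,Number=1,Type=Float,Description="Imputation information score">\n')
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Alternate allele frequency">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Expected alternate allele dosage">\n')
        for chrom in pd.unique(v["chrom"]):
            max_pos = int(v.loc[v["chrom"] == chrom, "pos"].max())
            fh.write(f"##contig=<ID={chrom},length={max_pos + 1000}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(G.samples) + "\n")
        for j in range(G.n_variants):
            row = v.iloc[j]
            af = float(G.dosages[:, j].mean() / 2.0)
            fields = [
                str(row["chrom"]), str(int(row["pos"])), str(row["id"]),
                str(row["ref"]), str(row["alt"]), ".", "PASS",
                f"INFO={row['info']:.4f};AF={af:.6f}", "GT:DS",
            ]
            cells = [
                f"{gt_strings[int(hard[i, j])]}:{G.dosages[i, j]:.4f}"
                for i in range(G.n_samples)
            ]
            fh.write("\t".join(fields) + "\t" + "\t".join(cells) + "\n")
    return path


def read_vcf_dosages(path: str | Path, map_path: str | Path | None = None) -> GenotypeSet:
    """Read a VCF with DS dosages into a GenotypeSet.

    cM positions come from ``map_path`` (PLINK map) when given, else from the
    1 cM/Mb fallback.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    dosage_cols, records, hard_cols = [], [], []
    for var in vcf:
        ds = np.asarray(var.format("DS"), dtype=float).ravel()
        dosage_cols.append(ds)
        gts = np.asarray([g[0] + g[1] for g in var.genotypes], dtype=np.int8)
        hard_cols.append(gts)
        info = var.INFO.get("INFO")
        records.append({
            "id": var.ID, "chrom": var.CHROM, "pos": var.POS,
            "ref": var.REF, "alt": var.ALT[0],
            "info": float(info) if info is not None else np.nan,
        })
    variants = pd.DataFrame(records)
    dosages = np.column_stack(dosage_cols) if dosage_cols else np.empty((len(samples), 0))
    hard = np.column_stack(hard_cols) if hard_cols else None
    if map_path is not None:
        gmap = read_map(map_path)
        key = variants["chrom"].astype(str) + ":" + variants["pos"].astype(str)
        gkey = gmap["chrom"].astype(str) + ":" + gmap["pos"].astype(str)
        cm = pd.Series(gmap["cm"].values, index=gkey).reindex(key).values
        variants["cm"] = cm
    else:
        variants["cm"] = variants["pos"] / 1e6
    return GenotypeSet(samples=samples, dosages=dosages, variants=variants, hard_calls=hard)


# ---------------------------------------------------------------------------
# PLINK-style genetic map
# ---------------------------------------------------------------------------

def write_map(variants: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    out = variants[["chrom", "id", "cm", "pos"]].copy()
    out.to_csv(path, sep="\t", header=False, index=False, float_format="%.8f")
    return path


def read_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+", header=None,
                     names=["chrom", "id", "cm", "pos"], dtype={"chrom": str})
    return df


# ---------------------------------------------------------------------------
# Sample-keyed TSV tables
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a table whose first column is sample_id; NaN becomes 'NA'."""
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"sample_id": str})


def write_phenotypes(Y: PhenotypeTable, path: str | Path,
                     groups_path: str | Path | None = None) -> Path:
    p = write_table(Y.to_frame(), path)
    if groups_path is not None:
        pd.DataFrame({"phenotype": Y.names, "group": Y.groups}).to_csv(
            groups_path, sep="\t", index=False)
    return p


def read_phenotypes(path: str | Path, groups_path: str | Path | None = None) -> PhenotypeTable:
    df = read_table(path)
    samples = df["sample_id"].astype(str).tolist()
    names = [c for c in df.columns if c != "sample_id"]
    groups: list[str] = []
    if groups_path is not None:
        gdf = pd.read_csv(groups_path, sep="\t")
        lut = dict(zip(gdf["phenotype"], gdf["group"]))
        groups = [str(lut.get(n, "all")) for n in names]
    return PhenotypeTable(samples=samples, values=df[names].to_numpy(float),
                          names=names, groups=groups)


# ---------------------------------------------------------------------------
# Truth bundles (simulation ground truth)
# ---------------------------------------------------------------------------

def write_truth(truth, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "B_true": np.asarray(truth.B_true).tolist(),
        "E_true": np.asarray(truth.E_true).tolist(),
        "causal_effects": [[int(v), int(p), float(e)] for v, p, e in truth.causal_effects],
        "seed": int(truth.seed),
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_truth(path: str | Path):
    from .simdata import TruthSet  # deferred: io is imported by simdata

    d = json.loads(Path(path).read_text())
    return TruthSet(
        B_true=np.asarray(d["B_true"], dtype=float),
        E_true=np.asarray(d["E_true"], dtype=float),
        causal_effects=[(int(v), int(p), float(e)) for v, p, e in d["causal_effects"]],
        seed=int(d["seed"]),
    )
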