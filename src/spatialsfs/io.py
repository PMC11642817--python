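"""Text formats: provenance-headed TSVs and haploid cohort VCFs.

Every table written by the tool begins with ``#``-prefixed provenance
lines (``# key=value``) recording the tool version and the full
parameter set that produced it, so any output is regenerable from its
own header.  VCF is used only for cohort genotype matrices (contig
``synth1``, one record per synthetic site, haploid GT).
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import Cohort
from .sfs import SampleSFS

__all__ = [
    "write_sfs_tsv", "read_sfs_tsv",
    "write_table_tsv", "read_table_tsv",
    "write_coords_tsv", "read_coords_tsv",
    "write_genotypes_tsv", "read_genotypes_tsv",
    "write_cohort_vcf", "read_cohort_vcf",
]


def _format_provenance(meta: dict) -> str:
    lines = [f"# spatialsfs={__version__}"]
    for k, v in meta.items():
        lines.append(f"# {k}={v}")
    return "\n".join(lines) + "\n"


def _read_provenance(path) -> tuple[dict, int]:
    meta = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
    return meta, n_header


def write_table_tsv(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_format_provenance(meta or {}))
        df.to_csv(fh, sep="\t", index=False)


def read_table_tsv(path) -> tuple[pd.DataFrame, dict]:
    meta, skip = _read_provenance(path)
    try:
        df = pd.read_csv(path, sep="\t", skiprows=skip)
    except Exception as e:
        raise ValueError(f"malformed TSV {path}: {e}") from e
    return df, meta


def write_sfs_tsv(sfs: SampleSFS, path, meta: dict | None = None) -> None:
    """SFS as columns k / count / probability, with provenance header."""
    if sfs.M == 0:
        raise ValueError("refusing to write an empty SFS (M=0)")
    meta = dict(meta or {})
    meta.setdefault("n", sfs.n)
    meta.setdefault("M", sfs.M)
    write_table_tsv(sfs.to_frame(), path, meta)


def read_sfs_tsv(path) -> tuple[SampleSFS, dict]:
    df, meta = read_table_tsv(path)
    if "k" not in df or "count" not in df:
        raise ValueError(f"{path}: expected columns k and count")
    n = int(meta.get("n", df.k.max()))
    counts = {int(k): int(c) for k, c in zip(df.k, df["count"])}
    return SampleSFS(n=n, counts=counts), meta


def write_coords_tsv(cohort: Cohort, path, meta: dict | None = None) -> None:
    df = pd.DataFrame({"id": cohort.ids, "x": cohort.coords[:, 0], "y": cohort.coords[:, 1]})
    write_table_tsv(df, path, meta)


def read_coords_tsv(path) -> tuple[pd.DataFrame, dict]:
    df, meta = read_table_tsv(path)
    for c in ("id", "x", "y"):
        if c not in df:
            raise ValueError(f"{path}: expected columns id, x, y")
    return df, meta


def write_genotypes_tsv(cohort: Cohort, path, meta: dict | None = None) -> None:
    """Sites x individuals 0/1 matrix with site annotations as columns."""
    base = cohort.sites.copy() if cohort.sites is not None else pd.DataFrame(
        {"site_id": [f"site_{i}" for i in range(cohort.n_sites)]}
    )
    mat = pd.DataFrame(cohort.genotypes, columns=cohort.ids)
    write_table_tsv(pd.concat([base.reset_index(drop=True), mat], axis=1), path, meta)


def read_genotypes_tsv(path, coords: pd.DataFrame) -> Cohort:
    df, _ = read_table_tsv(path)
    ann_cols = [c for c in df.columns if c in ("site_id", "s_class", "s")]
    ids = [c for c in df.columns if c not in ann_cols]
    if list(ids) != list(coords.id.astype(str)):
        # allow subset/reorder by coords order
        missing = set(coords.id.astype(str)) - set(ids)
        if missing:
            raise ValueError(f"genotype matrix lacks individuals: {sorted(missing)[:5]} ...")
        ids = list(coords.id.astype(str))
    geno = df[ids].to_numpy(dtype=np.int8)
    return Cohort(
        ids=ids,
        coords=coords.set_index(coords.id.astype(str)).loc[ids, ["x", "y"]].to_numpy(),
        genotypes=geno,
        sites=df[ann_cols] if ann_cols else None,
    )


def write_cohort_vcf(cohort: Cohort, path) -> None:
    """Haploid VCF: contig synth1, positions 1..M, GT per individual.

    Site class annotations go to INFO (SCLASS, SSEL).
    """
    import pysam

    header = pysam.VariantHeader()
    header.add_line(f"##source=spatialsfs-{__version__}")
    header.add_line(f"##contig=<ID=synth1,length={cohort.n_sites + 1}>")
    header.add_line('##INFO=<ID=SCLASS,Number=1,Type=String,Description="Selection class">')
    header.add_line('##INFO=<ID=SSEL,Number=1,Type=Float,Description="Selection coefficient">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Haploid genotype">')
    for s in cohort.ids:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for i in range(cohort.n_sites):
            rec = vf.new_record(contig="synth1", start=i, stop=i + 1,
                                alleles=("A", "T"), id=_site_id(cohort, i))
            if cohort.sites is not None:
                if "s_class" in cohort.sites:
                    rec.info["SCLASS"] = str(cohort.sites.s_class.iloc[i])
                if "s" in cohort.sites:
                    rec.info["SSEL"] = float(cohort.sites.s.iloc[i])
            row = cohort.genotypes[i]
            for j, sample in enumerate(rec.samples.values()):
                sample["GT"] = (int(row[j]),)
            vf.write(rec)


def _site_id(cohort: Cohort, i: int) -> str:
    if cohort.sites is not None and "site_id" in cohort.sites:
        return str(cohort.sites.site_id.iloc[i])
    return f"site_{i}"


def read_cohort_vcf(path, coords: pd.DataFrame) -> Cohort:
    """Rebuild a Cohort from a haploid VCF plus a coordinates table."""
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        ids = list(vf.header.samples)
        rows = []
        geno_rows = []
        for rec in vf:
            rows.append({
                "site_id": rec.id,
                "s_class": rec.info.get("SCLASS"),
                "s": rec.info.get("SSEL"),
            })
            geno_rows.append([rec.samples[s]["GT"][0] or 0 for s in ids])
    cmap = coords.set_index(coords.id.astype(str))
    missing = [i for i in ids if i not in cmap.index]
    if missing:
        raise ValueError(f"coordinates missing for individuals: {missing[:5]} ...")
    sites = pd.DataFrame(rows)
    if sites.s_class.isna().all():
        sites = sites[["site_id"]]
    return Cohort(
        ids=ids,
        coords=cmap.loc[ids, ["x", "y"]].to_numpy(dtype=float),
        genotypes=np.asarray(geno_rows, dtype=np.int8),
        sites=sites,
    )
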