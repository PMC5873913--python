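"""Biallelic SNP genotype matrix with marker annotations.

Genotypes are additive-coded per cell: 0 (hom ref), 1 (het), 2 (hom alt),
:data:`MISSING` (-1).  Phase is ignored.  Marker metadata carries chromosome,
position, alleles and ``gene_context`` (exon / intron / downstream / upstream /
intergenic), which drives the neutral-marker selection rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .log import get_logger

log = get_logger("io.geno")

MISSING = -1

GENE_CONTEXTS = ("exon", "intron", "downstream", "upstream", "intergenic")


class GenotypeFormatError(ValueError):
    pass


@dataclass
class GenotypeMatrix:
    """Individuals x markers additive genotype codes plus marker metadata.

    ``codes`` is int8 with entries in {0, 1, 2, MISSING}; ``metadata`` is a
    DataFrame indexed by marker id with columns ``chrom, pos, alleles,
    gene_context`` (may be empty if no annotations are available).
    """

    individuals: list[str]
    markers: list[str]
    codes: np.ndarray
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.individuals), len(self.markers)):
            raise GenotypeFormatError("codes shape inconsistent with id lists")
        bad = ~np.isin(self.codes, (0, 1, 2, MISSING))
        if bad.any():
            raise GenotypeFormatError(f"invalid genotype codes: {np.unique(self.codes[bad])}")
        if len(set(self.markers)) != len(self.markers):
            raise GenotypeFormatError("duplicate marker ids")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def column(self, marker: str) -> np.ndarray:
        return self.codes[:, self.markers.index(marker)]

    def subset_individuals(self, ids: list[str]) -> "GenotypeMatrix":
        pos = {ind: i for i, ind in enumerate(self.individuals)}
        idx = [pos[i] for i in ids]
        return GenotypeMatrix(list(ids), list(self.markers), self.codes[idx], self.metadata)

    def subset_markers(self, markers: list[str]) -> "GenotypeMatrix":
        pos = {m: j for j, m in enumerate(self.markers)}
        idx = [pos[m] for m in markers]
        meta = self.metadata.loc[markers] if len(self.metadata) else self.metadata
        return GenotypeMatrix(list(self.individuals), list(markers), self.codes[:, idx], meta)


def read_genotypes(path, format: str = "vcf", metadata_path=None) -> GenotypeMatrix:
    """Read genotypes from a VCF 4.x file or a numeric CSV.

    VCF: biallelic records only; multiallelic records are skipped with a
    warning and counted.  GT 0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2, ./. ->
    missing; phasing ignored.  CSV: individuals x markers matrix with ``NA``
    for missing, plus a sidecar marker-metadata CSV
    (``marker_id,chrom,pos,alleles,gene_context``).
    """
    if format == "vcf":
        return _read_vcf(path)
    if format == "csv":
        return _read_geno_csv(path, metadata_path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    individuals = list(vcf.samples)
    markers: list[str] = []
    rows: list[np.ndarray] = []
    meta_rows: list[dict] = []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        mid = var.ID or f"{var.CHROM}:{var.POS}"
        if mid in set(markers):
            raise GenotypeFormatError(f"duplicate marker id {mid!r}")
        markers.append(mid)
        codes = var.gt_types.astype(np.int8)  # gts012: 0/1/2, 3=unknown
        codes[codes == 3] = MISSING
        rows.append(codes)
        ctx = var.INFO.get("GENE_CONTEXT")
        meta_rows.append(
            {
                "marker_id": mid,
                "chrom": var.CHROM,
                "pos": var.POS,
                "alleles": f"{var.REF}/{var.ALT[0]}",
                "gene_context": ctx if ctx is not None else "",
            }
        )
    if n_multi:
        log.warning("skipped %d multiallelic records", n_multi)
    codes = np.array(rows, dtype=np.int8).T if rows else np.empty((len(individuals), 0), np.int8)
    meta = pd.DataFrame(meta_rows).set_index("marker_id") if meta_rows else pd.DataFrame()
    return GenotypeMatrix(individuals, markers, codes, meta)


def _read_geno_csv(path, metadata_path) -> GenotypeMatrix:
    df = pd.read_csv(path, index_col=0)
    codes = df.to_numpy(dtype=float)
    codes = np.where(np.isnan(codes), MISSING, codes).astype(np.int8)
    markers = [str(m) for m in df.columns]
    meta = pd.DataFrame()
    if metadata_path is not None:
        meta = pd.read_csv(metadata_path, dtype={"marker_id": str}).set_index("marker_id")
        if meta.index.duplicated().any():
            raise GenotypeFormatError("duplicate marker id in metadata")
        meta = meta.reindex(markers)
    return GenotypeMatrix([str(i) for i in df.index], markers, codes, meta)


def write_geno_csv(G: GenotypeMatrix, path, metadata_path=None) -> None:
    df = pd.DataFrame(
        np.where(G.codes == MISSING, np.nan, G.codes), index=G.individuals, columns=G.markers
    )
    df.to_csv(path, index_label="individual_id", na_rep="NA", float_format="%.0f")
    if metadata_path is not None and len(G.metadata):
        G.metadata.to_csv(metadata_path, index_label="marker_id")


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(G: GenotypeMatrix, path) -> None:
    """Write an uncompressed VCF 4.2 with GT calls and GENE_CONTEXT INFO tags."""
    meta = G.metadata
    chroms = []
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=GENE_CONTEXT,Number=1,Type=String,Description="Gene context">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if len(meta):
            for c in pd.unique(meta["chrom"]):
                chroms.append(c)
                fh.write(f"##contig=<ID={c}>\n")
        else:
            fh.write("##contig=<ID=1>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.individuals)
            + "\n"
        )
        for j, mid in enumerate(G.markers):
            if len(meta):
                row = meta.loc[mid]
                chrom, pos = row["chrom"], int(row["pos"])
                ref, alt = str(row["alleles"]).split("/")
                info = f"GENE_CONTEXT={row['gene_context']}" if row["gene_context"] else "."
            else:
                chrom, pos, ref, alt, info = "1", j + 1, "A", "G", "."
            gts = "\t".join(_GT_STR[int(c)] for c in G.codes[:, j])
            fh.write(f"{chrom}\t{pos}\t{mid}\t{ref}\t{alt}\t.\tPASS\t{info}\tGT\t{gts}\n")
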