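"""Readers and writers for the SV-VCF dialect, sample panels, GFF3 and BED.

Internal coordinates are 1-based inclusive everywhere (VCF/GFF3 native);
BED input (0-based half-open) is converted at the boundary. Only the GT
FORMAT field is consumed; phasing is ignored and half-missing genotypes
(``./0``) are treated as missing, which is conservative for frequency
computations downstream.
"""

from __future__ import annotations

import gzip
import logging
import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import SVTYPES, GeneFeature, Genotype, SamplePanel, SVRecord

log = logging.getLogger(__name__)


def read_panel(path: str) -> SamplePanel:
    """Read a two-column sample-panel table (sample_id, group in {HL, LL})."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"],
                     dtype=str, comment="#")
    samples = df["sample"].tolist()
    return SamplePanel(samples, dict(zip(df["sample"], df["group"])))


def write_panel(panel: SamplePanel, path: str) -> None:
    with open(path, "w") as fh:
        for s in panel.samples:
            fh.write(f"{s}\t{panel.group[s]}\n")


def _decode_gt(alleles) -> Genotype:
    # cyvcf2 genotype entry: [allele1, allele2, phased]; -1 = missing.
    # Half-missing calls are treated as fully missing.
    if len(alleles) < 3:
        return Genotype.MISSING
    a1, a2 = int(alleles[0]), int(alleles[1])
    if a1 < 0 or a2 < 0:
        return Genotype.MISSING
    return Genotype(a1 + a2) if a1 + a2 <= 2 else Genotype.MISSING


def read_sv_vcf(path: str, panel: SamplePanel) -> list[SVRecord]:
    """Read biallelic SV records from a VCF, normalised to panel sample order.

    Lines without SVTYPE (e.g. SNPs) or with more than one ALT are skipped
    with a logged count. A DEL lacking INFO/END has it reconstructed as
    POS + |SVLEN| - 1; when both END and SVLEN are present but disagree by
    more than 1 bp, END wins and a warning is logged. A sample present in
    the panel but absent from the VCF is an error.
    """
    vf = VCF(str(path))
    vcf_samples = list(vf.samples)
    absent = [s for s in panel.samples if s not in vcf_samples]
    if absent:
        raise ValueError(f"panel samples absent from VCF: {absent}")
    order = np.array([vcf_samples.index(s) for s in panel.samples], dtype=int)

    records: list[SVRecord] = []
    n_skipped = 0
    for i, rec in enumerate(vf):
        svtype = rec.INFO.get("SVTYPE")
        if svtype is None or svtype not in SVTYPES:
            n_skipped += 1
            continue
        if len(rec.ALT) != 1:
            n_skipped += 1
            continue
        pos = int(rec.POS)
        svlen = rec.INFO.get("SVLEN")
        if isinstance(svlen, (tuple, list)):
            svlen = svlen[0]
        end = rec.INFO.get("END")
        if end is not None:
            end = int(end)
            if svlen is not None and abs(abs(int(svlen)) - (end - pos + 1)) > 1:
                log.warning(
                    "%s: END (%d) and SVLEN (%d) disagree; END wins",
                    rec.ID, end, int(svlen),
                )
        elif svtype == "INS":
            end = pos
        elif svlen is not None and svlen != 0:
            end = pos + abs(int(svlen)) - 1
        else:
            n_skipped += 1
            continue
        if svlen is None:
            svlen = -(end - pos + 1) if svtype == "DEL" else end - pos + 1
        gts = np.full(panel.n, Genotype.MISSING, dtype=np.int8)
        geno = rec.genotypes
        for j, k in enumerate(order):
            gts[j] = _decode_gt(geno[k])
        rid = rec.ID if rec.ID else f"sv_{i}"
        records.append(SVRecord(rid, rec.CHROM, pos, int(end), svtype,
                                int(svlen), gts))
    if n_skipped:
        log.warning("read_sv_vcf: skipped %d non-SV/multiallelic lines",
                    n_skipped)
    vf.close()
    return records


_GT_STR = {
    Genotype.HOM_REF: "0/0",
    Genotype.HET: "0/1",
    Genotype.HOM_ALT: "1/1",
    Genotype.MISSING: "./.",
}


def write_sv_vcf(
    records: Sequence[SVRecord],
    panel: SamplePanel,
    path: str,
    chrom_lengths: dict[str, int] | None = None,
) -> None:
    """Write records as a VCF 4.2 with symbolic ALT alleles and GT-only FORMAT.

    Lines are formatted directly so that INFO/END keeps the pipeline's
    1-based inclusive convention (END = POS + |SVLEN| - 1 for deletions);
    htslib-based writers re-derive END from SVLEN under the newer
    END = POS + |SVLEN| reading and would shift it by one.
    """
    chroms: dict[str, int] = dict(chrom_lengths or {})
    for r in records:
        if r.chrom not in chroms or chroms[r.chrom] < r.end + 1000:
            chroms[r.chrom] = max(chroms.get(r.chrom, 0), r.end + 1000)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##source=cnvselscan\n")
        for c in sorted(chroms):
            fh.write(f"##contig=<ID={c},length={int(chroms[c])}>\n")
        for t in SVTYPES:
            fh.write(f'##ALT=<ID={t},Description="{t}">\n')
        fh.write(
            '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">\n'
            '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Signed SV length">\n'
            '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.samples) + "\n")
        for r in sorted(records, key=lambda x: (x.chrom, x.pos, x.id)):
            info = f"SVTYPE={r.svtype};SVLEN={int(r.svlen)};END={int(r.end)}"
            gts = "\t".join(_GT_STR[Genotype(int(g))] for g in r.genotypes)
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.id}\tN\t<{r.svtype}>\t.\t.\t{info}\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# annotation

_GFF_KIND = {
    "gene": "gene",
    "exon": "exon",
    "CDS": "CDS",
    "five_prime_UTR": "five_prime_UTR",
    "three_prime_UTR": "three_prime_UTR",
    "ncRNA_gene": "ncRNA_gene",
    "ncRNA_exon": "ncRNA_exon",
}


def _open_text(path: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_gff3_genes(path: str) -> list[GeneFeature]:
    """Parse gene models from GFF3 into flat 1-based inclusive features.

    Feature types outside the recognised vocabulary (mRNA lines etc.) are
    ignored; sub-features inherit their gene id from the Parent attribute
    chain's root, falling back to their own ID.
    """
    import gffutils

    with _open_text(path) as fh:
        data = fh.read()
    if not data.strip():
        return []
    db = gffutils.create_db(
        data, dbfn=":memory:", from_string=True, force=True,
        keep_order=True, merge_strategy="create_unique",
    )
    out: list[GeneFeature] = []
    for feat in db.all_features():
        kind = _GFF_KIND.get(feat.featuretype)
        if kind is None:
            continue
        if kind in ("gene", "ncRNA_gene"):
            gid = feat.attributes.get("ID", [feat.id])[0]
        else:
            gid = feat.attributes.get("Parent", feat.attributes.get("ID", [feat.id]))[0]
        strand = feat.strand if feat.strand in ("+", "-") else "+"
        out.append(GeneFeature(feat.seqid, feat.start, feat.end, strand, gid, kind))
    return out


def read_bed_genes(path: str) -> list[GeneFeature]:
    """Read gene intervals from BED (0-based half-open -> 1-based inclusive)."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return []
    out = []
    for i, row in df.iterrows():
        chrom, start, end = str(row[0]), int(row[1]), int(row[2])
        name = str(row[3]) if df.shape[1] > 3 else f"bed_{i}"
        strand = str(row[5]) if df.shape[1] > 5 and str(row[5]) in "+-" else "+"
        out.append(GeneFeature(chrom, start + 1, end, strand, name, "gene"))
    return out


def read_annotation(path: str) -> list[GeneFeature]:
    """Dispatch on extension: .bed -> BED, otherwise GFF3."""
    base = str(path)[:-3] if str(path).endswith(".gz") else str(path)
    if base.endswith(".bed"):
        return read_bed_genes(path)
    return read_gff3_genes(path)


def write_gff3(features: Sequence[GeneFeature], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            if f.feature_kind in ("gene", "ncRNA_gene"):
                attrs = f"ID={f.gene_id}"
            else:
                attrs = f"ID={f.gene_id}:{f.feature_kind}:{f.start};Parent={f.gene_id}"
            fh.write(
                "\t".join([
                    f.chrom, "cnvselscan", f.feature_kind, str(f.start),
                    str(f.end), ".", f.strand, ".", attrs,
                ]) + "\n"
            )


def features_to_bed(features: Sequence[GeneFeature], path: str) -> None:
    """Write gene bodies as BED (the inverse coordinate conversion)."""
    with open(path, "w") as fh:
        for f in features:
            if f.feature_kind in ("gene", "ncRNA_gene"):
                fh.write(f"{f.chrom}\t{f.start - 1}\t{f.end}\t{f.gene_id}\t.\t{f.strand}\n")
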