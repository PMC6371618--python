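"""Readers and writers for the pipeline's file formats.

Gene models travel as a 1-based inclusive TSV (one row per transcript);
the population panel as VCF 4.2 with allele frequencies in INFO; feature
tracks as sorted TSV (chrom, start, end, value; 1-based closed) with a JSON
sidecar declaring name and resolution; the reference as plain FASTA.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam
from pyfaidx import Fasta

from .cohort import GenomePartition
from .features import POPULATIONS, FeatureTrack, GeneFeatureTable, PopulationPanel
from .types import (
    AnnotatedVariant,
    GeneModel,
    Transcript,
    VariantRecord,
)

logger = logging.getLogger(__name__)

GENE_TSV_COLUMNS = [
    "gene_id",
    "symbol",
    "chrom",
    "strand",
    "biotype",
    "transcript_id",
    "tx_start",
    "tx_end",
    "cds_start",
    "cds_end",
    "exon_starts",
    "exon_ends",
]


def write_fasta(reference: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(reference):
            fh.write(f">{chrom}\n")
            seq = reference[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> Dict[str, str]:
    fa = Fasta(str(path))
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_gene_tsv(genes: Sequence[GeneModel], path: str | Path) -> None:
    rows = []
    for g in genes:
        for tx in g.transcripts:
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "symbol": g.symbol,
                    "chrom": g.chrom,
                    "strand": g.strand,
                    "biotype": g.biotype,
                    "transcript_id": tx.tx_id,
                    "tx_start": tx.tx_start,
                    "tx_end": tx.tx_end,
                    "cds_start": tx.cds_start if tx.cds_start is not None else ".",
                    "cds_end": tx.cds_end if tx.cds_end is not None else ".",
                    "exon_starts": ",".join(str(s) for s, _ in tx.exons),
                    "exon_ends": ",".join(str(e) for _, e in tx.exons),
                }
            )
    pd.DataFrame(rows, columns=GENE_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_gene_tsv(path: str | Path) -> List[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    genes: List[GeneModel] = []
    for (gene_id, symbol, chrom, strand, biotype), sub in df.groupby(
        ["gene_id", "symbol", "chrom", "strand", "biotype"], sort=True
    ):
        txs = []
        for row in sub.itertuples(index=False):
            starts = [int(x) for x in row.exon_starts.split(",")]
            ends = [int(x) for x in row.exon_ends.split(",")]
            txs.append(
                Transcript(
                    tx_id=row.transcript_id,
                    tx_start=int(row.tx_start),
                    tx_end=int(row.tx_end),
                    exons=tuple(zip(starts, ends)),
                    cds_start=None if row.cds_start == "." else int(row.cds_start),
                    cds_end=None if row.cds_end == "." else int(row.cds_end),
                )
            )
        g = GeneModel(gene_id, symbol, chrom, strand, biotype, tuple(txs))
        g.validate()
        genes.append(g)
    return genes


def _vcf_header(contigs: Mapping[str, int]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom, length in sorted(contigs.items()):
        header.contigs.add(chrom, length=length)
    header.info.add("MAF", 1, "Float", "Folded global minor allele frequency")
    header.info.add("DAF", 1, "Float", "Derived allele frequency")
    header.info.add("COMMON", 0, "Flag", "Common variant flag (MAF > 0.05)")
    for p in POPULATIONS:
        if p != "global":
            header.info.add(f"MAF_{p}", 1, "Float", f"Folded MAF in population {p}")
    return header


def write_panel_vcf(
    panel: PopulationPanel, path: str | Path, contigs: Mapping[str, int]
) -> None:
    header = _vcf_header(contigs)
    pops = [p for p in POPULATIONS if p != "global"]
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for row in panel.frame.itertuples(index=False):
            rec = vcf.new_record(
                contig=row.chrom,
                start=int(row.pos) - 1,
                stop=int(row.pos),
                alleles=(row.ref, row.alt),
                id=row.id,
            )
            rec.info["MAF"] = float(row.maf)
            rec.info["DAF"] = float(row.daf)
            if bool(row.common):
                rec.info["COMMON"] = True
            for p in pops:
                col = f"maf_{p}"
                if hasattr(row, col):
                    rec.info[f"MAF_{p}"] = float(getattr(row, col))
            vcf.write(rec)


def read_panel_vcf(path: str | Path) -> PopulationPanel:
    pops = [p for p in POPULATIONS if p != "global"]
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            if len(rec.alleles) != 2 or any(len(a) != 1 for a in rec.alleles):
                continue
            row = {
                "chrom": rec.contig,
                "pos": rec.pos,
                "id": rec.id or "",
                "ref": rec.ref,
                "alt": rec.alts[0],
                "maf": float(rec.info["MAF"]) if "MAF" in rec.info else np.nan,
                "daf": float(rec.info["DAF"]) if "DAF" in rec.info else np.nan,
                "common": bool(rec.info.get("COMMON", False)),
            }
            for p in pops:
                key = f"MAF_{p}"
                row[f"maf_{p}"] = float(rec.info[key]) if key in rec.info else np.nan
            rows.append(row)
    return PopulationPanel(pd.DataFrame(rows))


def read_snv_vcf(path: str | Path) -> Tuple[List[VariantRecord], int]:
    """Read biallelic SNV records from a VCF; non-SNV records are skipped
    and counted."""
    variants: List[VariantRecord] = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if (
                rec.alts is None
                or len(rec.alts) != 1
                or len(rec.ref) != 1
                or len(rec.alts[0]) != 1
                or rec.ref not in "ACGT"
                or rec.alts[0] not in "ACGT"
            ):
                skipped += 1
                continue
            maf = float(rec.info["MAF"]) if "MAF" in rec.info else None
            variants.append(
                VariantRecord(
                    chrom=rec.contig,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    id=rec.id or "",
                    maf=maf,
                    common_flag=bool(rec.info.get("COMMON")) if "COMMON" in rec.info else None,
                )
            )
    if skipped:
        logger.info("skipped %d non-biallelic-SNV records", skipped)
    return variants, skipped


def write_track(track: FeatureTrack, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    track.to_frame().to_csv(directory / f"{track.name}.tsv", sep="\t", index=False)
    (directory / f"{track.name}.json").write_text(
        json.dumps({"name": track.name, "resolution": track.resolution})
    )


def read_track(directory: str | Path, name: str) -> FeatureTrack:
    directory = Path(directory)
    meta = json.loads((directory / f"{name}.json").read_text())
    df = pd.read_csv(directory / f"{name}.tsv", sep="\t", float_precision="round_trip")
    return FeatureTrack.from_records(
        meta["name"],
        [
            (r.chrom, int(r.start), int(r.end), float(r.value))
            for r in df.itertuples(index=False)
        ],
        resolution=meta.get("resolution"),
    )


def read_tracks_dir(directory: str | Path) -> Dict[str, FeatureTrack]:
    directory = Path(directory)
    out = {}
    for sidecar in sorted(directory.glob("*.json")):
        name = json.loads(sidecar.read_text())["name"]
        out[name] = read_track(directory, name)
    return out


def write_gene_features(table: GeneFeatureTable, path: str | Path) -> None:
    table.frame.rename_axis("gene_id").to_csv(path, sep="\t")


def read_gene_features(path: str | Path) -> GeneFeatureTable:
    return GeneFeatureTable(
        pd.read_csv(path, sep="\t", index_col="gene_id", float_precision="round_trip")
    )


def annotated_to_frame(annotated: Sequence[AnnotatedVariant]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variant_id": [a.key for a in annotated],
            "chrom": [a.variant.chrom for a in annotated],
            "pos": [a.variant.pos for a in annotated],
            "ref": [a.variant.ref for a in annotated],
            "alt": [a.variant.alt for a in annotated],
            "region": [a.region for a in annotated],
            "gene_id": [a.gene_id or "." for a in annotated],
            "distance_bp": [a.distance_bp for a in annotated],
            "maf": [a.variant.maf for a in annotated],
            "common": [a.variant.common_flag for a in annotated],
            "source": [a.variant.source for a in annotated],
        }
    )


def frame_to_annotated(df: pd.DataFrame) -> List[AnnotatedVariant]:
    out = []
    for row in df.itertuples(index=False):
        maf = None if pd.isna(row.maf) else float(row.maf)
        common = None if pd.isna(row.common) else bool(row.common)
        v = VariantRecord(
            chrom=row.chrom,
            pos=int(row.pos),
            ref=row.ref,
            alt=row.alt,
            id=row.variant_id,
            maf=maf,
            common_flag=common,
            source=getattr(row, "source", "") or "",
        )
        out.append(
            AnnotatedVariant(
                v,
                row.region,
                None if row.gene_id == "." else row.gene_id,
                int(row.distance_bp),
            )
        )
    return out


def write_partition(partition: GenomePartition, path: str | Path) -> None:
    Path(path).write_text(json.dumps(partition.to_dict(), indent=1))


def read_partition(path: str | Path) -> GenomePartition:
    return GenomePartition.from_dict(json.loads(Path(path).read_text()))
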