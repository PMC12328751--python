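"""Promoter extraction and CREF matrix assembly.

The proximal regulatory region of a protein-coding gene is the window
−1000..+499 around its TSS (1500 bp, TSS at relative position 0), in
transcript orientation.  The TSS is the start of the most upstream (5')
transcript: the minimum transcript start on the + strand, the maximum
transcript end on the − strand.  Windows are clipped to the chromosome,
never padded.

The CREF matrix has one row per retained protein-coding gene and one
column per PWM; the entry is the motif's hit count in the gene's promoter.
It is returned as a pandas DataFrame with sorted gene/motif identifiers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
from pyfaidx import Fasta

from ._util import revcomp
from .pwm import PWM, CutoffProfile, count_hits

logger = logging.getLogger(__name__)

UPSTREAM = 1000
DOWNSTREAM = 499

_TRANSCRIPT_TYPES = ("mRNA", "transcript")


@dataclass(frozen=True)
class GeneRegion:
    """A gene's promoter window.

    ``start``/``end`` are 1-based inclusive genomic coordinates; ``sequence``
    (when attached) is in transcript orientation (5'->3' of the gene).
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    start: int
    end: int
    sequence: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _is_protein_coding(feature) -> bool:
    for key in ("biotype", "gene_biotype", "gene_type"):
        if key in feature.attributes:
            return "protein_coding" in feature.attributes[key]
    return False


def extract_tss(gff3_path) -> dict[str, tuple[str, str, int]]:
    """Map protein-coding gene id -> (chromosome, strand, 1-based TSS).

    Genes without transcript children are skipped with a logged warning.
    """
    try:
        db = gffutils.create_db(
            str(gff3_path),
            ":memory:",
            keep_order=True,
            merge_strategy="create_unique",
        )
    except gffutils.exceptions.EmptyInputError:
        return {}
    out: dict[str, tuple[str, str, int]] = {}
    for gene in db.features_of_type("gene"):
        if not _is_protein_coding(gene):
            continue
        transcripts = list(db.children(gene, featuretype=_TRANSCRIPT_TYPES))
        if not transcripts:
            logger.warning("gene %s has no transcripts; skipped", gene.id)
            continue
        if gene.strand == "+":
            tss = min(t.start for t in transcripts)
        elif gene.strand == "-":
            tss = max(t.end for t in transcripts)
        else:
            logger.warning("gene %s has no strand; skipped", gene.id)
            continue
        out[gene.id] = (gene.seqid, gene.strand, tss)
    return out


def promoter_region(
    gene_id: str, chrom: str, strand: str, tss: int, chrom_length: int
) -> GeneRegion:
    """The −1000..+499 window around the TSS, clipped to the chromosome."""
    if strand == "+":
        start, end = tss - UPSTREAM, tss + DOWNSTREAM
    else:
        start, end = tss - DOWNSTREAM, tss + UPSTREAM
    start = max(1, start)
    end = min(chrom_length, end)
    return GeneRegion(gene_id, chrom, strand, tss, start, end)


def promoter_sequence(fasta: Fasta, region: GeneRegion) -> str:
    """Fetch the region's sequence in transcript orientation."""
    seq = str(fasta[region.chrom][region.start - 1 : region.end]).upper()
    return revcomp(seq) if region.strand == "-" else seq


def build_cref(
    fasta_path,
    gff3_path,
    pwms: list[PWM],
    cutoffs,
    min_region_length: int = 50,
    drop_truncated: bool = False,
    both_strands: bool = True,
) -> pd.DataFrame:
    """Assemble the CREF matrix from a genome, annotation and PWM library.

    ``cutoffs`` is either a single :class:`CutoffProfile` shared by all PWMs
    or a mapping ``pwm id -> CutoffProfile``.  Rows and columns are sorted by
    identifier, entries are nonnegative integers, and identical inputs give
    identical output.
    """
    fasta = Fasta(str(fasta_path))
    tss_map = extract_tss(gff3_path)
    if not tss_map:
        raise ValueError("zero protein-coding genes retained from annotation")
    if isinstance(cutoffs, CutoffProfile):
        cutoffs = {p.id: cutoffs for p in pwms}
    missing = [p.id for p in pwms if p.id not in cutoffs]
    if missing:
        raise ValueError(f"no cutoff profile for PWMs: {missing[:5]}")

    chrom_lengths = {name: len(fasta[name]) for name in fasta.keys()}
    pwms_sorted = sorted(pwms, key=lambda p: p.id)
    gene_ids = sorted(tss_map)
    rows = []
    kept_genes = []
    for gid in gene_ids:
        chrom, strand, tss = tss_map[gid]
        if chrom not in chrom_lengths:
            raise ValueError(f"chromosome {chrom!r} of gene {gid} not in FASTA")
        region = promoter_region(gid, chrom, strand, tss, chrom_lengths[chrom])
        if region.length < min_region_length and drop_truncated:
            logger.warning("gene %s promoter truncated to %d bp; dropped",
                           gid, region.length)
            continue
        seq = promoter_sequence(fasta, region)
        rows.append(
            [count_hits(p, seq, cutoffs[p.id], both_strands=both_strands)
             for p in pwms_sorted]
        )
        kept_genes.append(gid)
    if not kept_genes:
        raise ValueError("zero genes retained after truncation filtering")
    return pd.DataFrame(
        np.asarray(rows, dtype=np.int64),
        index=pd.Index(kept_genes, name="gene"),
        columns=[p.id for p in pwms_sorted],
    )


def write_cref(matrix: pd.DataFrame, out_path, params: dict | None = None) -> None:
    """Write the CREF matrix as TSV plus a sidecar JSON of build parameters."""
    out_path = Path(out_path)
    matrix.to_csv(out_path, sep="\t")
    if params is not None:
        sidecar = out_path.with_suffix(out_path.suffix + ".json")
        sidecar.write_text(json.dumps(params, indent=2, default=str))


def read_cref(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
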