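"""Protein-effect annotation and per-population allele frequencies.

A minimal, single-transcript effect annotator: each biallelic SNP inside the
coding sequence of a strand-aware gene model is mapped to its codon, the alt
base is substituted (reverse-complemented for minus-strand genes), both codons
are translated with the standard genetic code, and the variant is classified
as missense / synonymous / stop_gained / stop_lost with an "I359V"-style
label.  Variants outside the CDS are classified non_coding.

Allele frequencies are computed per (population x species) cohort as
alt-haplotype count over cohort haplotype count, plus a haplotype-weighted
"All" column, and filtered with a strict >threshold rule (a variant is kept
when it exceeds the threshold in at least one cohort).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .hapio import (
    DataIntegrityError,
    HaplotypeSet,
    Panel,
    Region,
    ValidationError,
    VariantSite,
)

EFFECT_CLASSES = ("missense", "synonymous", "stop_gained", "stop_lost", "non_coding")


@dataclass(frozen=True)
class GeneModel:
    """Single-transcript, strand-aware CDS description.

    ``ref_coding_sequence`` is given in transcript orientation (5'->3' of the
    mRNA); for minus-strand genes it is the reverse complement of the
    plus-strand genomic sequence over the CDS intervals.
    """

    chrom: str
    strand: str
    cds_intervals: tuple[Region, ...]
    ref_coding_sequence: str
    transcript_id: str = "TX1"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        total = sum(r.length for r in self.cds_intervals)
        if total % 3 != 0:
            raise ValidationError(f"total CDS length {total} is not divisible by 3")
        if len(self.ref_coding_sequence) != total:
            raise ValidationError(
                "ref_coding_sequence length must equal total CDS length"
            )
        protein = str(Seq(self.ref_coding_sequence).translate())
        if "*" in protein[:-1]:
            raise ValidationError("reference translation has an internal stop codon")

    @property
    def cds_length(self) -> int:
        return len(self.ref_coding_sequence)

    @property
    def n_codons(self) -> int:
        return self.cds_length // 3

    def protein(self) -> str:
        return str(Seq(self.ref_coding_sequence).translate())

    def transcript_index(self, pos: int) -> int | None:
        """0-based index into the coding sequence for a genomic position.

        Returns None when the position is outside every CDS interval.
        """
        offset = 0
        plus_index = None
        for iv in self.cds_intervals:
            if iv.contains(pos):
                plus_index = offset + (pos - iv.start)
                break
            offset += iv.length
        if plus_index is None:
            return None
        if self.strand == "+":
            return plus_index
        return self.cds_length - 1 - plus_index

    def genomic_ref(self, pos: int) -> str | None:
        """Plus-strand reference base at a genomic position inside the CDS."""
        idx = self.transcript_index(pos)
        if idx is None:
            return None
        base = self.ref_coding_sequence[idx]
        if self.strand == "-":
            base = str(Seq(base).reverse_complement())
        return base


@dataclass(frozen=True)
class VariantEffect:
    site: VariantSite
    effect_class: str
    aa_ref: str | None = None
    aa_pos: int | None = None
    aa_alt: str | None = None

    @property
    def label(self) -> str | None:
        if self.effect_class == "non_coding":
            return None
        return f"{self.aa_ref}{self.aa_pos}{self.aa_alt}"


def annotate_variant(gene: GeneModel, site: VariantSite) -> VariantEffect:
    """Classify a SNP against a gene model and build its amino-acid label."""
    if site.chrom != gene.chrom:
        raise ValidationError(
            f"variant chromosome {site.chrom} does not match gene {gene.chrom}"
        )
    tidx = gene.transcript_index(site.pos)
    if tidx is None:
        return VariantEffect(site=site, effect_class="non_coding")

    ref_t = site.ref
    alt_t = site.alt
    if gene.strand == "-":
        ref_t = str(Seq(ref_t).reverse_complement())
        alt_t = str(Seq(alt_t).reverse_complement())
    if gene.ref_coding_sequence[tidx] != ref_t:
        raise DataIntegrityError(
            f"VCF ref {site.ref} at {site.chrom}:{site.pos} conflicts with gene "
            f"model base {gene.genomic_ref(site.pos)}"
        )

    codon_idx = tidx // 3
    within = tidx % 3
    ref_codon = gene.ref_coding_sequence[3 * codon_idx : 3 * codon_idx + 3]
    alt_codon = ref_codon[:within] + alt_t + ref_codon[within + 1 :]
    aa_ref = str(Seq(ref_codon).translate())
    aa_alt = str(Seq(alt_codon).translate())

    if aa_ref == aa_alt:
        effect = "synonymous"
    elif aa_alt == "*":
        effect = "stop_gained"
    elif aa_ref == "*":
        effect = "stop_lost"
    else:
        effect = "missense"
    return VariantEffect(
        site=site, effect_class=effect, aa_ref=aa_ref, aa_pos=codon_idx + 1,
        aa_alt=aa_alt,
    )


def annotate_all(gene: GeneModel, hapset: HaplotypeSet) -> list[VariantEffect]:
    return [annotate_variant(gene, s) for s in hapset.sites]


# ---------------------------------------------------------------------------
# Frequencies
# ---------------------------------------------------------------------------

@dataclass
class FrequencyTable:
    """Alt-allele frequency per variant (rows) per cohort (columns) plus All.

    Frequencies are proportions in [0, 1].  The "All" column is
    haplotype-weighted by default: total alt-haplotype count over total
    haplotype count, not the mean of the cohort frequencies.
    """

    sites: tuple[VariantSite, ...]
    table: pd.DataFrame  # index aligned with sites; columns cohorts + "All"

    def to_percent_tsv(self, path) -> None:
        (self.table * 100).round(1).to_csv(path, sep="\t")


def population_allele_frequencies(
    hapset: HaplotypeSet, panel: Panel, all_mode: str = "haplotype"
) -> FrequencyTable:
    """Alt-allele frequency for every site, per (population x species) cohort.

    ``all_mode``: "haplotype" (default) pools all haplotypes for the "All"
    column; "cohort_mean" averages the cohort frequencies instead.
    """
    if hapset.n_haplotypes == 0 or hapset.n_sites == 0:
        raise ValidationError("cannot compute frequencies on an empty haplotype set")
    if all_mode not in ("haplotype", "cohort_mean"):
        raise ValidationError(f"unknown all_mode {all_mode!r}")
    cohorts = np.array(hapset.cohort_labels(panel))
    labels = list(dict.fromkeys(cohorts))  # first-appearance order
    data = {}
    for label in labels:
        cols = cohorts == label
        data[label] = hapset.matrix[:, cols].mean(axis=1)
    df = pd.DataFrame(data, index=[f"{s.pos}{s.ref}>{s.alt}" for s in hapset.sites])
    if all_mode == "haplotype":
        df["All"] = hapset.matrix.mean(axis=1)
    else:
        df["All"] = df[labels].mean(axis=1)
    return FrequencyTable(sites=hapset.sites, table=df)


def filter_high_frequency(
    table: FrequencyTable, threshold: float = 0.05
) -> list[VariantSite]:
    """Variants strictly exceeding ``threshold`` in at least one cohort.

    The "All" column is ignored; the comparison is strict (a variant at
    exactly the threshold everywhere is excluded).  Output sorted by position.
    """
    if not 0 <= threshold <= 1:
        raise ValidationError(f"threshold must be in [0, 1], got {threshold}")
    cohort_cols = [c for c in table.table.columns if c != "All"]
    keep_mask = (table.table[cohort_cols] > threshold).any(axis=1).to_numpy()
    kept = [s for s, k in zip(table.sites, keep_mask) if k]
    return sorted(kept, key=lambda s: (s.chrom, s.pos))


# ---------------------------------------------------------------------------
# Gene model persistence: minimal GFF3 CDS dialect + coding-sequence FASTA
# ---------------------------------------------------------------------------

GFF_COLUMNS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase",
    "attributes",
]


def write_gene_model(gene: GeneModel, gff_path, fasta_path) -> None:
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for iv in gene.cds_intervals:
            # GFF is 1-based inclusive; our Region is half-open.
            fh.write(
                f"{gene.chrom}\thapsignal\tCDS\t{iv.start}\t{iv.end - 1}\t.\t"
                f"{gene.strand}\t0\tID=cds-{gene.transcript_id};"
                f"Parent={gene.transcript_id}\n"
            )
    with open(fasta_path, "w") as fh:
        fh.write(f">{gene.transcript_id}\n")
        seq = gene.ref_coding_sequence
        for i in range(0, len(seq), 60):
            fh.write(seq[i : i + 60] + "\n")


def read_gene_model(gff_path, fasta_path) -> GeneModel:
    from Bio import SeqIO

    df = pd.read_csv(
        gff_path, sep="\t", comment="#", header=None, names=GFF_COLUMNS, dtype=str
    )
    cds = df[df["type"] == "CDS"]
    if cds.empty:
        raise ValidationError(f"no CDS features in {gff_path}")
    strands = set(cds["strand"])
    if len(strands) != 1:
        raise ValidationError("CDS features must share one strand")
    chroms = set(cds["seqid"])
    if len(chroms) != 1:
        raise ValidationError("CDS features must share one chromosome")
    intervals = tuple(
        Region(row.seqid, int(row.start), int(row.end) + 1)
        for row in cds.sort_values("start", key=lambda s: s.astype(int)).itertuples()
    )
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ValidationError(f"expected exactly one FASTA record in {fasta_path}")
    rec = records[0]
    return GeneModel(
        chrom=chroms.pop(),
        strand=strands.pop(),
        cds_intervals=intervals,
        ref_coding_sequence=str(rec.seq).upper(),
        transcript_id=rec.id,
    )


__all__ = [
    "GeneModel",
    "VariantEffect",
    "FrequencyTable",
    "EFFECT_CLASSES",
    "annotate_variant",
    "annotate_all",
    "population_allele_frequencies",
    "filter_high_frequency",
    "read_gene_model",
    "write_gene_model",
]
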