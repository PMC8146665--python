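"""Domain types, coordinate conventions and file I/O for phased haplotypes.

Coordinate convention used throughout the package: VCF positions are 1-based;
a :class:`Region` is half-open ``[start, end)`` so that ``end - start`` is its
length in base pairs.  Under this convention the Cyp6m2 core region
(3R:6928858..6930547) has the length 1689 bp used to define core haplotypes.

The universal in-memory currency is :class:`HaplotypeSet`: a binary allele
matrix (0 = reference, 1 = alternate) over an ordered list of biallelic SNP
sites, with one column per phased haplotype and exactly two haplotypes per
diploid sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("hapsignal")

NUCLEOTIDES = frozenset("ACGT")


class HapsignalError(Exception):
    """Base class for all package errors."""


class FormatError(HapsignalError):
    """A file does not follow the expected dialect."""


class ValidationError(HapsignalError):
    """Input values violate a documented precondition or invariant."""


class DataIntegrityError(HapsignalError):
    """Two inputs that must agree (e.g. VCF REF vs gene model) do not."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Region:
    """Half-open genomic interval ``[start, end)`` with 1-based coordinates."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(
                f"Region end must exceed start: got [{self.start}, {self.end})"
            )
        if self.start < 1:
            raise ValidationError("Region start must be a positive 1-based position")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        """True iff ``pos`` lies inside the half-open interval."""
        return self.start <= pos < self.end


@dataclass(frozen=True)
class VariantSite:
    """A biallelic SNP: single-nucleotide ref and alt at a 1-based position."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref not in NUCLEOTIDES or self.alt not in NUCLEOTIDES:
            raise ValidationError(
                f"ref/alt must be single nucleotides in ACGT: {self.ref}>{self.alt}"
            )
        if self.ref == self.alt:
            raise ValidationError(f"ref and alt must differ at pos {self.pos}")


@dataclass(frozen=True)
class Panel:
    """Mapping sample_id -> (population, species), in file/declaration order."""

    samples: tuple[str, ...]
    populations: dict[str, str]
    species: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            dupes = pd.Series(self.samples)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise ValidationError(f"duplicate sample ids in panel: {dupes}")

    def __len__(self) -> int:
        return len(self.samples)

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self.populations

    def cohort(self, sample_id: str) -> str:
        """Cohort label for a sample (population x species).

        Population labels in the field usually already encode species (e.g.
        "BFcol" vs "BFgam"); when a population contains a single species the
        population label itself is the cohort label, otherwise the species is
        appended to disambiguate.
        """
        pop = self.populations[sample_id]
        species_in_pop = {
            self.species[s] for s in self.samples if self.populations[s] == pop
        }
        if len(species_in_pop) == 1:
            return pop
        return f"{pop}|{self.species[sample_id]}"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": list(self.samples),
                "population": [self.populations[s] for s in self.samples],
                "species": [self.species[s] for s in self.samples],
            }
        )


@dataclass
class HaplotypeSet:
    """Phased binary haplotypes over an ordered list of biallelic SNP sites.

    ``matrix`` has shape (n_sites, n_haplotypes); entry (i, j) is 0 when
    haplotype j carries the reference allele at site i and 1 otherwise.
    ``meta`` has one row per haplotype with columns sample_id, hap (0/1 for
    the two chromosomes of a diploid), population and species.
    """

    sites: tuple[VariantSite, ...]
    matrix: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if self.matrix.ndim != 2:
            raise ValidationError("haplotype matrix must be 2-dimensional")
        if self.matrix.shape[0] != len(self.sites):
            raise ValidationError(
                f"matrix rows ({self.matrix.shape[0]}) != site count ({len(self.sites)})"
            )
        if self.matrix.shape[1] != len(self.meta):
            raise ValidationError("matrix columns must match meta rows")
        if self.matrix.size and not np.isin(self.matrix, (0, 1)).all():
            raise ValidationError("haplotype matrix entries must be 0 or 1")
        if len(self.meta) % 2 != 0:
            raise ValidationError("haplotype count must be twice the sample count")
        pos = self.positions
        if len(pos) > 1 and not (np.diff(pos) > 0).all():
            raise ValidationError("site positions must be strictly increasing")
        self.meta = self.meta.reset_index(drop=True)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_haplotypes(self) -> int:
        return self.matrix.shape[1]

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.sites], dtype=np.int64)

    @property
    def sample_ids(self) -> list[str]:
        return list(dict.fromkeys(self.meta["sample_id"]))

    def haplotype_ids(self) -> list[str]:
        return [
            f"{row.sample_id}_{row.hap}" for row in self.meta.itertuples(index=False)
        ]

    def restrict(self, region: Region) -> "HaplotypeSet":
        """Sites restricted to ``region`` (half-open; pos == end excluded)."""
        keep = [
            i
            for i, s in enumerate(self.sites)
            if s.chrom == region.chrom and region.contains(s.pos)
        ]
        return self.take_sites(keep)

    def take_sites(self, indices) -> "HaplotypeSet":
        indices = list(indices)
        return HaplotypeSet(
            sites=tuple(self.sites[i] for i in indices),
            matrix=self.matrix[indices, :] if indices else
                   np.empty((0, self.n_haplotypes), dtype=np.uint8),
            meta=self.meta.copy(),
        )

    def take_haplotypes(self, indices) -> "HaplotypeSet":
        indices = np.asarray(list(indices), dtype=int)
        return HaplotypeSet(
            sites=self.sites,
            matrix=self.matrix[:, indices],
            meta=self.meta.iloc[indices].reset_index(drop=True),
        )

    def cohort_labels(self, panel: Panel) -> list[str]:
        return [panel.cohort(s) for s in self.meta["sample_id"]]


# ---------------------------------------------------------------------------
# Coordinate arithmetic
# ---------------------------------------------------------------------------

def region_length(region: Region) -> int:
    """Length of a half-open region in base pairs (``end - start``)."""
    return region.length


def downstream_distance(anchor_end: int, gene_start: int) -> int:
    """Distance in bp from the end of an anchor interval to a downstream gene.

    ``anchor_end`` is the (exclusive) end coordinate of the anchor — either the
    focal gene itself or a larger enclosing cluster; published distances differ
    depending on which anchor is intended, so the anchor is an explicit
    argument rather than a fixed choice.
    """
    if gene_start <= anchor_end:
        raise ValidationError(
            f"gene start {gene_start} is not downstream of anchor end {anchor_end}"
        )
    return gene_start - anchor_end


# ---------------------------------------------------------------------------
# Panel I/O (TSV: sample_id <TAB> population <TAB> species, with header)
# ---------------------------------------------------------------------------

def read_panel(path) -> Panel:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse panel file {path}: {exc}") from exc
    required = {"sample_id", "population", "species"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"panel file missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dupes = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"].unique())
        raise ValidationError(f"duplicate sample ids in panel: {dupes}")
    return Panel(
        samples=tuple(df["sample_id"]),
        populations=dict(zip(df["sample_id"], df["population"])),
        species=dict(zip(df["sample_id"], df["species"])),
    )


def write_panel(panel: Panel, path) -> None:
    panel.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Phased VCF I/O
# ---------------------------------------------------------------------------

def read_phased_vcf(path, region: Region | None, panel: Panel) -> HaplotypeSet:
    """Read phased biallelic SNPs from a VCF into a :class:`HaplotypeSet`.

    Haplotype column order follows the panel's sample order: (sample A hap 1,
    sample A hap 2, sample B hap 1, ...).  Multiallelic, non-SNP and unphased
    records are skipped with a logged count; they are never split or imputed.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    vcf_samples = list(vcf.samples)
    if not vcf_samples:
        raise FormatError(f"VCF {path} has no sample genotype columns")
    absent = [s for s in vcf_samples if s not in panel]
    if absent:
        raise ValidationError(f"VCF samples absent from panel: {absent}")
    ordered = [s for s in panel.samples if s in set(vcf_samples)]
    col_of = {s: i for i, s in enumerate(vcf_samples)}
    order = [col_of[s] for s in ordered]

    sites: list[VariantSite] = []
    rows: list[np.ndarray] = []
    skipped = {"multiallelic": 0, "non_snp": 0, "unphased_or_missing": 0,
               "out_of_region": 0}
    saw_gt = False
    for rec in vcf:
        if region is not None and (
            rec.CHROM != region.chrom or not region.contains(rec.POS)
        ):
            skipped["out_of_region"] += 1
            continue
        if len(rec.ALT) != 1:
            skipped["multiallelic"] += 1
            continue
        if len(rec.REF) != 1 or len(rec.ALT[0]) != 1 or \
                rec.REF not in NUCLEOTIDES or rec.ALT[0] not in NUCLEOTIDES:
            skipped["non_snp"] += 1
            continue
        gts = rec.genotypes  # [allele0, allele1, phased] per sample
        if gts is None:
            raise FormatError(f"record at {rec.CHROM}:{rec.POS} has no GT field")
        saw_gt = True
        ok = all(
            len(g) == 3 and g[2] and g[0] in (0, 1) and g[1] in (0, 1)
            for g in gts
        )
        if not ok:
            skipped["unphased_or_missing"] += 1
            continue
        row = np.empty(2 * len(ordered), dtype=np.uint8)
        for j, col in enumerate(order):
            row[2 * j] = gts[col][0]
            row[2 * j + 1] = gts[col][1]
        sites.append(VariantSite(rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
        rows.append(row)
    if not saw_gt and not sites and all(v == 0 for v in skipped.values()):
        logger.info("VCF %s contained no records", path)
    for reason, count in skipped.items():
        if count:
            logger.info("read_phased_vcf: skipped %d %s record(s)", count, reason)

    matrix = (
        np.vstack(rows) if rows else np.empty((0, 2 * len(ordered)), dtype=np.uint8)
    )
    meta = pd.DataFrame(
        {
            "sample_id": np.repeat(ordered, 2),
            "hap": np.tile([1, 2], len(ordered)),
            "population": np.repeat([panel.populations[s] for s in ordered], 2),
            "species": np.repeat([panel.species[s] for s in ordered], 2),
        }
    )
    return HaplotypeSet(sites=tuple(sites), matrix=matrix, meta=meta)


def write_vcf(hapset: HaplotypeSet, path) -> None:
    """Write a HaplotypeSet as a plain-text VCF 4.2 with phased genotypes."""
    samples = hapset.sample_ids
    if 2 * len(samples) != hapset.n_haplotypes:
        raise ValidationError("haplotype metadata must pair two haplotypes per sample")
    chroms = sorted({s.chrom for s in hapset.sites})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in chroms:
            maxpos = max(s.pos for s in hapset.sites if s.chrom == chrom)
            fh.write(f"##contig=<ID={chrom},length={maxpos + 1000}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for i, site in enumerate(hapset.sites):
            row = hapset.matrix[i]
            gts = "\t".join(
                f"{row[2 * j]}|{row[2 * j + 1]}" for j in range(len(samples))
            )
            fh.write(
                f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{site.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


__all__ = [
    "Region",
    "VariantSite",
    "Panel",
    "HaplotypeSet",
    "HapsignalError",
    "FormatError",
    "ValidationError",
    "DataIntegrityError",
    "region_length",
    "downstream_distance",
    "read_panel",
    "write_panel",
    "read_phased_vcf",
    "write_vcf",
]
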