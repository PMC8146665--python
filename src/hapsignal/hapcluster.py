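"""Pairwise Hamming distances and hierarchical haplotype clustering.

Distances are counted in SNP units (number of differing biallelic sites in
the region, not per-bp), and the dendrogram is cut at a SNP threshold (default
seven).  Flat clusters at or above a minimum frequency are named C1..Ck in
descending size order; everything else is labelled wild type (``wt``).  With
single linkage (the default) the flat clusters at cut height h are exactly the
connected components of the graph joining haplotype pairs at distance <= h.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import pdist, squareform

from .hapio import HaplotypeSet, Panel, Region, ValidationError, VariantSite

logger = logging.getLogger("hapsignal")

LINKAGE_METHODS = ("single", "complete", "average")
WILDTYPE_LABEL = "wt"


@dataclass
class DistanceMatrix:
    """Condensed pairwise Hamming distance matrix in SNP units."""

    condensed: np.ndarray
    n: int
    n_sites: int

    def square(self) -> np.ndarray:
        return squareform(self.condensed)

    def __getitem__(self, ij: tuple[int, int]) -> int:
        i, j = ij
        if i == j:
            return 0
        return int(self.square()[i, j])


@dataclass
class ClusterAssignment:
    """Haplotype index -> cluster label (C1..Ck) or wild type."""

    labels: np.ndarray               # dtype object, one label per haplotype
    haplotype_samples: list[str]     # sample id per haplotype (meta order)
    cut_height: float
    linkage_method: str
    min_cluster_freq: float

    @property
    def n_haplotypes(self) -> int:
        return len(self.labels)

    @property
    def cluster_names(self) -> list[str]:
        names = sorted(
            {l for l in self.labels if l != WILDTYPE_LABEL},
            key=lambda l: int(l[1:]),
        )
        return names

    def members(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.labels == label)

    def to_frame(self, panel: Panel | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "haplotype": np.arange(self.n_haplotypes),
                "sample_id": self.haplotype_samples,
                "cluster": self.labels,
            }
        )
        if panel is not None:
            df["population"] = [panel.populations[s] for s in self.haplotype_samples]
        return df


def hamming_matrix(hapset: HaplotypeSet, region: Region | None = None) -> DistanceMatrix:
    """Pairwise SNP-count distances between all haplotypes over ``region``."""
    sub = hapset.restrict(region) if region is not None else hapset
    if sub.n_haplotypes < 2:
        raise ValidationError("need at least two haplotypes for pairwise distances")
    if sub.n_sites == 0:
        raise ValidationError("no sites in the requested region")
    # pdist hamming returns a fraction of differing coordinates
    condensed = np.rint(
        pdist(sub.matrix.T.astype(bool), metric="hamming") * sub.n_sites
    ).astype(np.int64)
    return DistanceMatrix(condensed=condensed, n=sub.n_haplotypes, n_sites=sub.n_sites)


def hierarchical_clusters(
    dist: DistanceMatrix,
    hapset: HaplotypeSet | None = None,
    linkage: str = "single",
    cut_height: float = 7,
    min_cluster_freq: float = 0.01,
) -> ClusterAssignment:
    """Agglomerative clustering cut at ``cut_height`` SNPs.

    Flat clusters whose frequency is at least ``min_cluster_freq`` are named
    C1..Ck by descending size (ties broken by the lowest member index);
    smaller clusters fold into the wild-type remainder.
    """
    if linkage not in LINKAGE_METHODS:
        raise ValidationError(f"linkage must be one of {LINKAGE_METHODS}")
    if cut_height < 0:
        raise ValidationError("cut_height must be non-negative")
    Z = scipy_linkage(dist.condensed.astype(float), method=linkage)
    flat = fcluster(Z, t=cut_height, criterion="distance")

    n = dist.n
    sizes = pd.Series(flat).value_counts()
    order = sorted(
        sizes.index,
        key=lambda c: (-sizes[c], int(np.flatnonzero(flat == c).min())),
    )
    labels = np.empty(n, dtype=object)
    next_id = 1
    for c in order:
        members = flat == c
        if sizes[c] / n >= min_cluster_freq:
            labels[members] = f"C{next_id}"
            next_id += 1
        else:
            labels[members] = WILDTYPE_LABEL
    samples = (
        list(hapset.meta["sample_id"]) if hapset is not None else [""] * n
    )
    return ClusterAssignment(
        labels=labels,
        haplotype_samples=samples,
        cut_height=cut_height,
        linkage_method=linkage,
        min_cluster_freq=min_cluster_freq,
    )


def cluster_population_summary(
    assignment: ClusterAssignment, panel: Panel
) -> pd.DataFrame:
    """Per population, the proportion of haplotypes in each cluster label.

    Rows are populations (only those with haplotypes), columns are cluster
    labels plus wt; each row sums to 1.
    """
    pops = [panel.populations[s] for s in assignment.haplotype_samples]
    df = pd.DataFrame({"population": pops, "cluster": assignment.labels})
    counts = df.groupby(["population", "cluster"], sort=True).size().unstack(
        fill_value=0
    )
    return counts.div(counts.sum(axis=1), axis=0)


def cluster_signature_variants(
    assignment: ClusterAssignment,
    hapset: HaplotypeSet,
    variants: list[VariantSite],
    signature_threshold: float = 0.9,
) -> pd.DataFrame:
    """Alt-carrier proportion of each high-frequency variant within each cluster.

    A variant is flagged as a cluster's signature when more than
    ``signature_threshold`` of the cluster's members carry the alt allele.
    """
    site_index = {s: i for i, s in enumerate(hapset.sites)}
    rows = []
    for v in variants:
        if v not in site_index:
            raise ValidationError(f"variant {v.chrom}:{v.pos} not among hapset sites")
    for label in assignment.cluster_names + [WILDTYPE_LABEL]:
        members = assignment.members(label)
        if members.size == 0:
            continue
        for v in variants:
            prop = float(hapset.matrix[site_index[v], members].mean())
            rows.append(
                {
                    "cluster": label,
                    "variant": f"{v.pos}{v.ref}>{v.alt}",
                    "pos": v.pos,
                    "carrier_proportion": prop,
                    "signature": prop > signature_threshold,
                }
            )
    return pd.DataFrame(rows)


__all__ = [
    "DistanceMatrix",
    "ClusterAssignment",
    "WILDTYPE_LABEL",
    "LINKAGE_METHODS",
    "hamming_matrix",
    "hierarchical_clusters",
    "cluster_population_summary",
    "cluster_signature_variants",
]
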