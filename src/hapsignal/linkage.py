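"""Signed Lewontin's D' linkage disequilibrium from phased haplotypes.

For two biallelic sites with alt-allele frequencies pA, pB and joint alt-alt
gamete frequency pAB, the raw disequilibrium is D = pAB - pA * pB and D' is D
normalised by its frequency-constrained extreme:

    D' = D / min(pA (1 - pB), (1 - pA) pB)          when D > 0
    D' = D / min(pA pB, (1 - pA) (1 - pB))          when D < 0
    D' = 0                                          when D = 0

so D' is signed and lies in [-1, 1]; |D'| = 1 exactly when at least one of
the four gametic classes is absent (+1: alleles perfectly coupled; -1: the
alt alleles are never found on the same haplotype).  A site monomorphic in
the analysed cohort makes D' undefined, and the package signals that
explicitly rather than silently reporting 0 — conflating the two corrupts
population-stratified analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hapio import HaplotypeSet, Panel, ValidationError, VariantSite


class MonomorphicSiteError(ValidationError):
    """D' is undefined because a site is monomorphic in the analysed cohort."""


@dataclass
class LDMatrix:
    """All-pairs signed D' with an explicit defined/undefined mask."""

    sites: tuple[VariantSite, ...]
    matrix: np.ndarray     # float; NaN where undefined
    freqs: np.ndarray      # per-site alt frequency in the analysed cohort
    defined: np.ndarray    # bool mask, same shape as matrix

    def to_frame(self) -> pd.DataFrame:
        names = [f"{s.pos}{s.ref}>{s.alt}" for s in self.sites]
        return pd.DataFrame(self.matrix, index=names, columns=names)


def dprime(hap_a: np.ndarray, hap_b: np.ndarray) -> float:
    """Signed Lewontin's D' between two binary haplotype vectors."""
    a = np.asarray(hap_a, dtype=float)
    b = np.asarray(hap_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("haplotype vectors must be 1-D and of equal length")
    p_a = a.mean()
    p_b = b.mean()
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise MonomorphicSiteError("D' undefined: a site is monomorphic")
    p_ab = (a * b).mean()
    d = p_ab - p_a * p_b
    if d > 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    elif d < 0:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    else:
        return 0.0
    return float(d / d_max)


def _site_indices(hapset: HaplotypeSet, variants: list[VariantSite]) -> list[int]:
    index = {s: i for i, s in enumerate(hapset.sites)}
    out = []
    for v in variants:
        if v not in index:
            raise ValidationError(f"variant {v.chrom}:{v.pos} not among hapset sites")
        out.append(index[v])
    return out


def dprime_matrix(hapset: HaplotypeSet, variants: list[VariantSite]) -> LDMatrix:
    """Signed D' over all unordered pairs of ``variants``.

    Pairs involving a monomorphic site are flagged undefined (NaN) rather
    than silently set to 0; the diagonal is 1 for polymorphic sites.
    """
    if not variants:
        raise ValidationError("variant list must not be empty")
    idx = _site_indices(hapset, variants)
    rows = hapset.matrix[idx, :]
    k = len(idx)
    freqs = rows.mean(axis=1)
    poly = (freqs > 0) & (freqs < 1)
    matrix = np.full((k, k), np.nan)
    defined = np.zeros((k, k), dtype=bool)
    for i in range(k):
        if poly[i]:
            matrix[i, i] = 1.0
            defined[i, i] = True
        for j in range(i + 1, k):
            if poly[i] and poly[j]:
                val = dprime(rows[i], rows[j])
                matrix[i, j] = matrix[j, i] = val
                defined[i, j] = defined[j, i] = True
    return LDMatrix(
        sites=tuple(variants), matrix=matrix, freqs=freqs, defined=defined
    )


def stratified_dprime(
    hapset: HaplotypeSet,
    variants: list[VariantSite],
    panel: Panel,
    population: str,
) -> LDMatrix:
    """D' restricted to one population's haplotypes.

    Sites monomorphic within the cohort yield undefined entries; pooled
    associations driven by population structure disappear (or become
    undefined) in the within-population view.
    """
    pops = list(panel.populations.values())
    if population not in pops:
        raise ValidationError(f"population {population!r} not present in panel")
    mask = [
        panel.populations[s] == population for s in hapset.meta["sample_id"]
    ]
    cohort = hapset.take_haplotypes(np.flatnonzero(mask))
    return dprime_matrix(cohort, variants)


__all__ = [
    "LDMatrix",
    "MonomorphicSiteError",
    "dprime",
    "dprime_matrix",
    "stratified_dprime",
]
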