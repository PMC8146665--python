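"""Extended haplotype homozygosity (EHH) decay around a core region.

Haplotypes identical over a designated core region form a core group of size
c.  Moving site by site away from the core edge (left of the core start, or
right of the core end), group members are partitioned by identity over all
sites from the edge through the current site; with subgroup sizes e_s the EHH
at that point is

    EHH(x) = sum_s C(e_s, 2) / C(c, 2)

i.e. the probability that two randomly drawn group members are identical over
the whole interval from the core out to x.  EHH starts at 1 at the core edge,
never increases with distance (the identity partition only refines), and is
truncated at the first zero or at ``max_distance`` (default 200 kb).  The
trapezoidal area under the curve gives a scalar summary for comparing a
putatively swept group against the wild-type background: sweeps and
bottlenecks both slow the decay, which is exactly the confound the
population-stratified analysis is designed to expose.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hapcluster import ClusterAssignment, WILDTYPE_LABEL
from .hapio import HaplotypeSet, Panel, Region, ValidationError

logger = logging.getLogger("hapsignal")

DIRECTIONS = ("left", "right")


class UndefinedEHHError(ValidationError):
    """EHH is undefined for a group with fewer than two members (C(c,2)=0)."""


@dataclass
class CoreGroup:
    """Haplotypes sharing one core haplotype (or one cluster label)."""

    core: Region
    group_id: str
    members: np.ndarray        # haplotype indices
    frequency: float

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class EHHCurve:
    """EHH values at increasing genomic distance from one core edge."""

    group_id: str
    direction: str
    positions: np.ndarray        # genomic coordinates, first entry = core edge
    distances: np.ndarray        # bp from the core edge; first entry 0
    ehh: np.ndarray              # values in [0, 1]; first entry 1
    group_size: int
    subgroup_sizes: list[tuple[int, ...]]  # e_s partition sizes per point


def core_groups(
    hapset: HaplotypeSet,
    core: Region,
    min_core_freq: float = 0.01,
    clusters: ClusterAssignment | None = None,
) -> list[CoreGroup]:
    """Core-haplotype groups at or above ``min_core_freq``.

    Without ``clusters``: one group per distinct core haplotype, ordered by
    descending size.  With ``clusters``: the named clusters C1..Ck become
    groups as-is, and each distinct core haplotype among the wild-type
    remainder at or above the frequency threshold becomes its own wt group
    (wt-1, wt-2, ... by descending size).
    """
    core_set = hapset.restrict(core)
    if core_set.n_sites == 0:
        raise ValidationError("no variant sites inside the core region")
    n = hapset.n_haplotypes
    keys = [tuple(col) for col in core_set.matrix.T]

    def distinct_groups(indices, prefix=""):
        by_key: dict[tuple, list[int]] = {}
        for i in indices:
            by_key.setdefault(keys[i], []).append(i)
        ordered = sorted(by_key.values(), key=lambda m: (-len(m), m[0]))
        out = []
        gid = 0
        for members in ordered:
            if len(members) / n >= min_core_freq:
                gid += 1
                out.append(
                    CoreGroup(
                        core=core,
                        group_id=f"{prefix}{gid}" if prefix else f"H{gid}",
                        members=np.asarray(members),
                        frequency=len(members) / n,
                    )
                )
        return out

    if clusters is None:
        return distinct_groups(range(n))
    if clusters.n_haplotypes != n:
        raise ValidationError("cluster assignment does not cover the haplotype set")
    groups = []
    for label in clusters.cluster_names:
        members = clusters.members(label)
        groups.append(
            CoreGroup(
                core=core,
                group_id=label,
                members=members,
                frequency=len(members) / n,
            )
        )
    wt_members = clusters.members(WILDTYPE_LABEL)
    groups.extend(distinct_groups(wt_members, prefix=f"{WILDTYPE_LABEL}-"))
    return groups


def _flank_sites(hapset: HaplotypeSet, core: Region, direction: str):
    pos = hapset.positions
    if direction == "left":
        idx = np.flatnonzero(pos < core.start)[::-1]          # outward order
        dist = core.start - pos[idx]
    elif direction == "right":
        idx = np.flatnonzero(pos >= core.end)
        dist = pos[idx] - core.end + 1
    else:
        raise ValidationError(f"direction must be one of {DIRECTIONS}")
    return idx, dist


def ehh_decay(
    hapset: HaplotypeSet,
    group: CoreGroup,
    direction: str,
    max_distance: int = 200_000,
) -> EHHCurve:
    """EHH of one core group moving outward from the core edge.

    Evaluated at every polymorphic site position out to ``max_distance``
    (EHH is constant between sites); truncated early when it reaches 0.
    """
    c = group.size
    if c < 2:
        raise UndefinedEHHError(
            f"group {group.group_id} has {c} member(s); EHH needs at least 2"
        )
    idx, dist = _flank_sites(hapset, core=group.core, direction=direction)
    keep = dist <= max_distance
    idx, dist = idx[keep], dist[keep]

    edge = group.core.start if direction == "left" else group.core.end
    positions = [edge]
    distances = [0]
    values = [1.0]
    partitions: list[tuple[int, ...]] = [(c,)]

    pairs_total = c * (c - 1) // 2
    ids = np.zeros(c, dtype=np.int64)
    members = group.members
    for site_i, d in zip(idx, dist):
        alleles = hapset.matrix[site_i, members].astype(np.int64)
        _, ids = np.unique(ids * 2 + alleles, return_inverse=True)
        counts = np.bincount(ids)
        ehh = float((counts * (counts - 1) // 2).sum() / pairs_total)
        positions.append(int(hapset.positions[site_i]))
        distances.append(int(d))
        values.append(ehh)
        partitions.append(tuple(sorted((int(x) for x in counts), reverse=True)))
        if ehh == 0.0:
            break
    return EHHCurve(
        group_id=group.group_id,
        direction=direction,
        positions=np.asarray(positions),
        distances=np.asarray(distances),
        ehh=np.asarray(values),
        group_size=c,
        subgroup_sizes=partitions,
    )


def ehh_by_population(
    hapset: HaplotypeSet,
    panel: Panel,
    core: Region,
    min_core_freq: float = 0.01,
    clusters: ClusterAssignment | None = None,
    max_distance: int = 200_000,
) -> dict[tuple[str, str, str], EHHCurve]:
    """EHH curves recomputed independently within each population cohort.

    Returns {(cohort, group_id, direction): curve}.  Groups with fewer than
    two members in a cohort are skipped with a log line.
    """
    cohorts = np.array(hapset.cohort_labels(panel))
    out: dict[tuple[str, str, str], EHHCurve] = {}
    for cohort in dict.fromkeys(cohorts):
        members = np.flatnonzero(cohorts == cohort)
        sub = hapset.take_haplotypes(members)
        sub_clusters = None
        if clusters is not None:
            sub_clusters = ClusterAssignment(
                labels=np.asarray(clusters.labels)[members],
                haplotype_samples=[clusters.haplotype_samples[i] for i in members],
                cut_height=clusters.cut_height,
                linkage_method=clusters.linkage_method,
                min_cluster_freq=clusters.min_cluster_freq,
            )
        for group in core_groups(sub, core, min_core_freq, sub_clusters):
            if group.size < 2:
                logger.info(
                    "cohort %s group %s has < 2 members; skipped",
                    cohort,
                    group.group_id,
                )
                continue
            for direction in DIRECTIONS:
                out[(cohort, group.group_id, direction)] = ehh_decay(
                    sub, group, direction, max_distance
                )
    return out


def ehh_area(curve) -> float:
    """Trapezoidal integral of EHH over genomic distance (bp).

    Accepts one curve or an iterable of curves (e.g. the left and right arms
    of the same group), in which case the areas are summed.
    """
    if isinstance(curve, EHHCurve):
        curves = [curve]
    else:
        curves = list(curve)
        if not curves:
            raise ValidationError("cannot integrate an empty set of curves")
    total = 0.0
    for cv in curves:
        if len(cv.ehh) == 0:
            raise ValidationError("cannot integrate an empty EHH curve")
        total += float(np.trapezoid(cv.ehh, cv.distances))
    return total


def curves_to_frame(curves: dict[tuple[str, str, str], EHHCurve]) -> pd.DataFrame:
    rows = []
    for (cohort, group_id, direction), cv in curves.items():
        for p, d, e in zip(cv.positions, cv.distances, cv.ehh):
            rows.append(
                {
                    "population": cohort,
                    "group": group_id,
                    "direction": direction,
                    "position": p,
                    "distance_bp": d,
                    "ehh": e,
                }
            )
    return pd.DataFrame(rows)


def mean_core_group_area(
    hapset: HaplotypeSet,
    core: Region,
    min_core_freq: float = 0.01,
    max_distance: int = 200_000,
) -> float:
    """Mean EHH area (left + right) over the cohort's core-haplotype groups.

    Groups below two members are skipped.  In a neutral cohort every group is
    wild type, so this is the cohort's background EHH level — the quantity a
    bottleneck inflates without any selection.
    """
    areas = []
    for group in core_groups(hapset, core, min_core_freq):
        if group.size < 2:
            continue
        areas.append(
            ehh_area(
                [ehh_decay(hapset, group, d, max_distance) for d in DIRECTIONS]
            )
        )
    if not areas:
        raise ValidationError("no core group with at least two members")
    return float(np.mean(areas))


def population_ehh_area(
    hapset: HaplotypeSet,
    core: Region,
    min_core_freq: float = 0.01,
    max_distance: int = 200_000,
) -> float:
    """Cohort-level EHH area: pair-weighted mean over core-haplotype groups.

    Each group's area is weighted by its share of all haplotype pairs, so the
    result integrates the probability that two randomly drawn cohort members
    share a core haplotype *and* remain identical out to distance x.  This is
    the population-scale decay summary: unlike the per-group mean (where a
    two-member group in a diverse cohort is usually a recent family with
    family-level flank identity), it responds to the diversity reduction that
    bottlenecks and sweeps produce.
    """
    n = hapset.n_haplotypes
    total_pairs = n * (n - 1) / 2
    if total_pairs == 0:
        raise ValidationError("need at least two haplotypes")
    acc = 0.0
    for group in core_groups(hapset, core, min_core_freq):
        if group.size < 2:
            continue
        area = ehh_area(
            [ehh_decay(hapset, group, d, max_distance) for d in DIRECTIONS]
        )
        acc += (group.size * (group.size - 1) / 2) * area
    return float(acc / total_pairs)


def carrier_contrast_areas(
    hapset: HaplotypeSet,
    carrier_flags: np.ndarray,
    core: Region,
    max_distance: int = 200_000,
) -> tuple[float, float]:
    """EHH areas (left + right) of focal-allele carriers vs non-carriers.

    The two groups are defined by carrier status of the focal allele rather
    than by core-haplotype identity, which makes the comparison exactly
    symmetric under neutrality when the allele segregates at frequency 1/2.
    """
    carrier_flags = np.asarray(carrier_flags, dtype=bool)
    if len(carrier_flags) != hapset.n_haplotypes:
        raise ValidationError("carrier flags must align with haplotypes")
    areas = []
    for flag in (True, False):
        members = np.flatnonzero(carrier_flags == flag)
        group = CoreGroup(
            core=core,
            group_id="carrier" if flag else WILDTYPE_LABEL,
            members=members,
            frequency=len(members) / hapset.n_haplotypes,
        )
        curves = [
            ehh_decay(hapset, group, direction, max_distance)
            for direction in DIRECTIONS
        ]
        areas.append(ehh_area(curves))
    return areas[0], areas[1]


__all__ = [
    "CoreGroup",
    "EHHCurve",
    "UndefinedEHHError",
    "DIRECTIONS",
    "core_groups",
    "ehh_decay",
    "ehh_by_population",
    "ehh_area",
    "curves_to_frame",
    "carrier_contrast_areas",
    "mean_core_group_area",
    "population_ehh_area",
]
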