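"""Forward-time Wright-Fisher haplotype simulator.

Simulates one panmictic deme of diploids over a fixed lattice of candidate SNP
positions with per-generation recombination, symmetric mutation, optional
positive selection on a focal allele, and an optional bottleneck epoch.  Each
offspring haplotype is a crossover mosaic of the two haplotypes of a parent
drawn fitness-weighted from the previous generation, so recombination produces
linkage-disequilibrium decay with distance and a selected allele drags its
flanking haplotype to high frequency (elevated extended homozygosity), while a
bottleneck produces the same long-haplotype signal without selection.

Default study conditions (chosen once; see docs/methods.md): 100 diploids per
deme (200 haplotypes), 400 sites at 200 bp spacing on chromosome arm 3R with
the focal site inside the canonical 1689 bp core region, founders all distinct
and at linkage equilibrium with shared ancestral frequencies, mu = 1e-6 per
site per generation, r = 2e-6 per bp per generation, 60 generations, and the
focal allele initialised at frequency 0.5 — the intermediate-frequency regime
of the high-frequency variants the analysis is designed around, and a choice
that makes carrier/non-carrier contrasts exactly symmetric under neutrality.
The canonical sweep scenario (:func:`sweep_config`) instead starts the focal
allele at 0.05 and switches selection on for the final 25 generations: a
recent sweep from rarity, which is what forces the recent common ancestry
(and hence the slow EHH decay) that the analysis is designed to detect.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .hapio import (
    HaplotypeSet,
    Panel,
    Region,
    ValidationError,
    VariantSite,
)
from .variant_effects import GeneModel

logger = logging.getLogger("hapsignal")

#: Core region used throughout the synthetic locus: 1689 bp on 3R, matching
#: the coordinates of the Cyp6m2 core haplotype region.
DEFAULT_CORE = Region("3R", 6928858, 6930547)

_STOPS = {"TAA", "TAG", "TGA"}
SENSE_CODONS = tuple(
    "".join(c) for c in itertools.product("ACGT", repeat=3) if "".join(c) not in _STOPS
)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated deme; defaults are the study conditions."""

    n_pop: int = 100                 # diploid population size
    n_founders: int = 200            # founder haplotypes (default: all distinct)
    n_sites: int = 400               # candidate SNP lattice size
    chrom: str = "3R"
    first_pos: int = 6889703         # lattice origin; focal site sits in DEFAULT_CORE
    site_spacing: int = 200          # bp between lattice sites
    mu: float = 1e-6                 # per-site per-generation flip probability
    r: float = 2e-6                  # per-bp per-generation crossover probability
    generations: int = 60
    s: float = 0.0                   # selection coefficient of the focal alt allele
    focal_site: int = 200            # lattice index of the selected site
    focal_freq0: float = 0.5         # initial focal alt frequency among founders
    sweep_start_gen: int | None = None  # default: generations - 15 when s > 0
    bottleneck: tuple[int, int, int] | None = None  # (start_gen, size, duration)
    seed: int = 0
    pop_label: str = "deme1"
    species: str = "gambiae"
    gene: GeneModel | None = None    # draw ref/alt letters consistent with a CDS

    def __post_init__(self) -> None:
        if not (0 <= self.mu <= 1 and 0 <= self.r <= 1):
            raise ValidationError("mu and r must lie in [0, 1]")
        if self.n_pop < 1 or self.n_sites < 2 or self.n_founders < 1:
            raise ValidationError("n_pop, n_founders and n_sites must be positive")
        if self.n_founders > 2 * self.n_pop:
            raise ValidationError("n_founders cannot exceed 2 * n_pop")
        if not 0 <= self.focal_site < self.n_sites:
            raise ValidationError("focal_site must index into the site lattice")
        if not 0 <= self.focal_freq0 <= 1:
            raise ValidationError("focal_freq0 must lie in [0, 1]")
        if self.generations < 0:
            raise ValidationError("generations must be non-negative")
        if self.bottleneck is not None:
            start, size, duration = self.bottleneck
            if size < 1 or duration < 1 or start < 1:
                raise ValidationError("bottleneck (start, size, duration) must be >= 1")

    def positions(self) -> np.ndarray:
        return self.first_pos + self.site_spacing * np.arange(
            self.n_sites, dtype=np.int64
        )

    @property
    def focal_pos(self) -> int:
        return int(self.first_pos + self.site_spacing * self.focal_site)

    def effective_sweep_start(self) -> int:
        if self.sweep_start_gen is not None:
            return self.sweep_start_gen
        return max(0, self.generations - 25)


@dataclass
class SimTruth:
    """Ground truth of one simulation run."""

    founder_mosaic: np.ndarray     # (n_haplotypes, n_sites) founder id; -1 = new mutation
    carrier_flags: np.ndarray      # bool per output haplotype: carries focal alt
    trajectory: np.ndarray         # focal alt frequency, generations + 1 entries
    focal_pos: int
    focal_site: int
    seed_used: int

    @property
    def focal_frequency(self) -> float:
        return float(self.trajectory[-1])


def _lattice_rng(config: SimConfig) -> np.random.Generator:
    # Shared across demes on the same lattice so that merged demes agree on
    # ref/alt letters and ancestral site frequencies.
    return np.random.default_rng(
        [0xBA5E, config.n_sites, config.first_pos, config.site_spacing]
    )


def _draw_sites(config: SimConfig) -> tuple[VariantSite, ...]:
    rng = _lattice_rng(config)
    letters = np.array(list("ACGT"))
    sites = []
    for pos in config.positions():
        ref = None
        if config.gene is not None:
            ref = config.gene.genomic_ref(int(pos))
        if ref is None:
            ref = str(rng.choice(letters))
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        else:
            # keep the rng stream aligned whether or not a gene overlaps
            rng.choice(letters)
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        sites.append(VariantSite(config.chrom, int(pos), ref, alt))
    return tuple(sites)


def _ancestral_freqs(config: SimConfig) -> np.ndarray:
    rng = _lattice_rng(config)
    rng.bit_generator.advance(10**6)  # independent of the letter draws
    return rng.uniform(0.1, 0.9, config.n_sites)


def simulate(config: SimConfig) -> tuple[HaplotypeSet, Panel, SimTruth]:
    """Run one deme forward in time; deterministic given the config (incl. seed)."""
    rng = np.random.default_rng(config.seed)
    S = config.n_sites
    pos = config.positions()
    gap_p = 1.0 - np.exp(-config.r * np.diff(pos))

    freqs = _ancestral_freqs(config)
    founders = (rng.random((config.n_founders, S)) < freqs).astype(np.uint8)
    k = int(round(config.focal_freq0 * config.n_founders))
    founders[:, config.focal_site] = 0
    carriers0 = rng.permutation(config.n_founders)[:k]
    founders[carriers0, config.focal_site] = 1

    if config.n_founders == 2 * config.n_pop:
        assign = np.arange(2 * config.n_pop)
    else:
        assign = rng.integers(0, config.n_founders, 2 * config.n_pop)
    pop = founders[assign].copy()
    fid = np.repeat(assign[:, None], S, axis=1).astype(np.int32)

    sweep_start = config.effective_sweep_start()
    traj = [pop[:, config.focal_site].mean()]
    for g in range(config.generations):
        t = g + 1  # generation being produced
        n_next = config.n_pop
        if config.bottleneck is not None:
            b_start, b_size, b_dur = config.bottleneck
            if b_start <= t < b_start + b_dur:
                n_next = b_size
        cur_n = pop.shape[0] // 2

        s_active = config.s if (config.s != 0 and g >= sweep_start) else 0.0
        if s_active != 0.0:
            counts = pop[0::2, config.focal_site].astype(float) + pop[
                1::2, config.focal_site
            ]
            w = (1.0 + s_active) ** counts
            p = w / w.sum()
        else:
            p = None
        parents = rng.choice(cur_n, size=(n_next, 2), p=p)
        pidx = parents.reshape(-1)  # one gamete per parent slot
        hap_a, hap_b = pop[2 * pidx], pop[2 * pidx + 1]
        fid_a, fid_b = fid[2 * pidx], fid[2 * pidx + 1]

        n_gam = 2 * n_next
        cross = rng.random((n_gam, S - 1)) < gap_p
        chooser = np.empty((n_gam, S), dtype=np.uint8)
        chooser[:, 0] = rng.integers(0, 2, n_gam)
        chooser[:, 1:] = (chooser[:, :1] + np.cumsum(cross, axis=1)) % 2
        pop = np.where(chooser == 0, hap_a, hap_b).astype(np.uint8)
        fid = np.where(chooser == 0, fid_a, fid_b)

        if config.mu > 0:
            flips = rng.random((n_gam, S)) < config.mu
            pop ^= flips.astype(np.uint8)
            fid[flips] = -1
        traj.append(pop[:, config.focal_site].mean())

    n_out = pop.shape[0] // 2
    sample_ids = [f"{config.pop_label}-{i:04d}" for i in range(n_out)]
    panel = Panel(
        samples=tuple(sample_ids),
        populations={s: config.pop_label for s in sample_ids},
        species={s: config.species for s in sample_ids},
    )
    meta = pd.DataFrame(
        {
            "sample_id": np.repeat(sample_ids, 2),
            "hap": np.tile([1, 2], n_out),
            "population": config.pop_label,
            "species": config.species,
        }
    )
    hapset = HaplotypeSet(sites=_draw_sites(config), matrix=pop.T, meta=meta)
    truth = SimTruth(
        founder_mosaic=fid,
        carrier_flags=pop[:, config.focal_site].astype(bool),
        trajectory=np.asarray(traj, dtype=float),
        focal_pos=config.focal_pos,
        focal_site=config.focal_site,
        seed_used=config.seed,
    )
    return hapset, panel, truth


def derive_seed(*entropy: int) -> int:
    """Deterministic sub-seed (< 2**31) from integer entropy components."""
    return int(np.random.SeedSequence(list(entropy)).generate_state(1)[0] % (2**31))


def simulate_surviving_sweep(
    config: SimConfig, max_tries: int = 200, min_class_freq: float = 0.05
) -> tuple[HaplotypeSet, Panel, SimTruth]:
    """Run a sweep replicate conditioned on an *ongoing* sweep.

    Replicates are re-run with the next derived seed until both allele
    classes segregate at ``min_class_freq`` (at least two haplotypes each):
    a lost allele leaves nothing to contrast, and a complete or near-complete
    sweep leaves only a handful of escaped wild-type haplotypes — typically a
    single family whose EHH is a family statistic, not a background level.
    """
    threshold = None
    for attempt in range(max_tries):
        cfg = replace(config, seed=derive_seed(config.seed, attempt))
        hapset, panel, truth = simulate(cfg)
        if threshold is None:
            threshold = max(2, int(np.ceil(min_class_freq * hapset.n_haplotypes)))
        n_car = int(truth.carrier_flags.sum())
        n_wt = int((~truth.carrier_flags).sum())
        if n_car >= threshold and n_wt >= threshold:
            if attempt:
                logger.info(
                    "sweep replicate rerun %d time(s): focal allele lost, "
                    "fixed or nearly fixed",
                    attempt,
                )
            return hapset, panel, truth
    raise ValidationError(
        f"no surviving sweep in {max_tries} attempts from seed {config.seed}"
    )


def _carrier_identity(
    hapset: HaplotypeSet, truth: SimTruth, window: int = 10000
) -> tuple[float, float]:
    """(identity, homozygosity) of focal-allele carriers over the flank.

    ``identity`` is the mean pairwise haplotype identity among carriers in the
    window (focal site itself excluded).  ``homozygosity`` multiplies it by
    the fraction of all haplotype pairs that are carrier pairs — the
    population-scale quantity a sweep inflates.  Raw carrier identity alone is
    biased upward in neutral runs that merely *survived* from rarity (few,
    deeply related carriers), so the frequency component is part of the
    sweep-vs-neutral contrast statistic.
    """
    pos = hapset.positions
    in_window = (np.abs(pos - truth.focal_pos) <= window) & (pos != truth.focal_pos)
    carriers = np.flatnonzero(truth.carrier_flags)
    if carriers.size < 2 or in_window.sum() == 0:
        return float("nan"), float("nan")
    sub = hapset.matrix[np.ix_(in_window, carriers)].T
    identity = float(1.0 - pdist(sub, metric="hamming").mean())
    n = hapset.n_haplotypes
    c = carriers.size
    pair_fraction = (c * (c - 1)) / (n * (n - 1))
    return identity, identity * pair_fraction


def simulate_sweep_contrast(
    config_neutral: SimConfig,
    config_sweep: SimConfig,
    n_reps: int,
    window: int = 10000,
) -> pd.DataFrame:
    """Paired sweep-vs-neutral replicates summarised per replicate.

    Returns one row per (replicate, scenario) with the realised focal-allele
    frequency and the mean pairwise carrier identity in the flanking window.
    Sweep replicates in which the focal allele is lost are re-run with the
    next derived seed.
    """
    if n_reps < 2:
        raise ValidationError("n_reps must be at least 2")
    a = replace(config_neutral, s=0.0, sweep_start_gen=None, seed=0)
    b = replace(config_sweep, s=0.0, sweep_start_gen=None, seed=0)
    if a != b:
        raise ValidationError("configs must be identical apart from s and seed")
    rows = []
    for rep in range(n_reps):
        # both arms get the same survival conditioning so the comparison is fair
        cfg_n = replace(config_neutral, seed=derive_seed(config_neutral.seed, rep))
        hap_n, _, truth_n = simulate_surviving_sweep(cfg_n)
        cfg_s = replace(config_sweep, seed=derive_seed(config_sweep.seed, rep))
        hap_s, _, truth_s = simulate_surviving_sweep(cfg_s)
        for scenario, hap, truth in (
            ("neutral", hap_n, truth_n),
            ("sweep", hap_s, truth_s),
        ):
            identity, homozygosity = _carrier_identity(hap, truth, window)
            rows.append(
                {
                    "rep": rep,
                    "scenario": scenario,
                    "focal_freq": truth.focal_frequency,
                    "carrier_identity": identity,
                    "carrier_homozygosity": homozygosity,
                }
            )
    return pd.DataFrame(rows)


def sweep_config(seed: int = 0, s: float = 0.2, **overrides) -> SimConfig:
    """The canonical recent hard-sweep scenario.

    A resistance-style allele present on two founder haplotypes (frequency
    0.01) drifts neutrally and then experiences selection ``s`` over the
    final 25 generations, rising towards high frequency from an essentially
    single origin and dragging its flanking haplotype with it.  Replicates
    that lose the allele (or finish it) are meant to be re-run via
    :func:`simulate_surviving_sweep`.
    """
    return SimConfig(s=s, focal_freq0=0.01, seed=seed, **overrides)


def plant_gene_model(region: Region, strand: str, seed: int) -> GeneModel:
    """Draw a reference coding sequence (no internal stops) over ``region``.

    The whole region is a single CDS interval; its length must be a positive
    multiple of 3 and at least two codons.
    """
    if region.length % 3 != 0:
        raise ValidationError(
            f"CDS region length {region.length} is not divisible by 3"
        )
    if region.length < 6:
        raise ValidationError("CDS region must cover at least 6 bases")
    rng = np.random.default_rng(seed)
    n_codons = region.length // 3
    codons = rng.choice(len(SENSE_CODONS), n_codons)
    seq = "".join(SENSE_CODONS[i] for i in codons)
    return GeneModel(
        chrom=region.chrom,
        strand=strand,
        cds_intervals=(region,),
        ref_coding_sequence=seq,
        transcript_id=f"SYNTX-{seed}",
    )


def merge_demes(
    results: list[tuple[HaplotypeSet, Panel, SimTruth]]
) -> tuple[HaplotypeSet, Panel, list[SimTruth]]:
    """Column-concatenate independently simulated demes sharing one lattice."""
    hapsets = [r[0] for r in results]
    first = hapsets[0]
    for h in hapsets[1:]:
        if h.sites != first.sites:
            raise ValidationError("demes must share an identical site lattice")
    matrix = np.hstack([h.matrix for h in hapsets])
    meta = pd.concat([h.meta for h in hapsets], ignore_index=True)
    samples: list[str] = []
    populations: dict[str, str] = {}
    species: dict[str, str] = {}
    for _, panel, _ in results:
        for s in panel.samples:
            if s in populations:
                raise ValidationError(f"duplicate sample id across demes: {s}")
            samples.append(s)
            populations[s] = panel.populations[s]
            species[s] = panel.species[s]
    merged_panel = Panel(tuple(samples), populations, species)
    return (
        HaplotypeSet(sites=first.sites, matrix=matrix, meta=meta),
        merged_panel,
        [r[2] for r in results],
    )


def write_truth(truth: SimTruth, path) -> None:
    """Persist per-haplotype truth labels and the frequency trajectory as TSV."""
    df = pd.DataFrame(
        {
            "haplotype": np.arange(len(truth.carrier_flags)),
            "carrier": truth.carrier_flags.astype(int),
        }
    )
    with open(path, "w") as fh:
        fh.write(f"#focal_pos={truth.focal_pos}\n")
        fh.write(f"#focal_site={truth.focal_site}\n")
        fh.write(f"#seed={truth.seed_used}\n")
        traj = ",".join(f"{x:.6g}" for x in truth.trajectory)
        fh.write(f"#trajectory={traj}\n")
        df.to_csv(fh, sep="\t", index=False)


__all__ = [
    "SimConfig",
    "SimTruth",
    "DEFAULT_CORE",
    "SENSE_CODONS",
    "simulate",
    "simulate_surviving_sweep",
    "simulate_sweep_contrast",
    "sweep_config",
    "plant_gene_model",
    "merge_demes",
    "derive_seed",
    "write_truth",
]
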