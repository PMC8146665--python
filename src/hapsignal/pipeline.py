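"""End-to-end orchestration: simulate -> annotate -> cluster -> LD -> MJN -> EHH.

A run is a pure function of its configuration (including the seed): every
stage writes a TSV/GraphML/DOT artefact into the output directory, and the
manifest lists each artefact with its SHA-256 content hash, so a rerun with
the same configuration is bit-identical.

The configuration is one flat TOML file.  All the analysis thresholds are
named keys with the canonical defaults: high-frequency filter 0.05, cluster
cut height 7 SNPs, maximum network edge distance 2 SNPs, minimum core-group
frequency 0.01, EHH distance cap 200000 bp.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import ehh as ehh_mod
from . import hapcluster, linkage, mjnetwork, synthetic_data, variant_effects
from .hapio import (
    HaplotypeSet,
    Panel,
    Region,
    ValidationError,
    read_panel,
    read_phased_vcf,
    write_panel,
    write_vcf,
)
from .synthetic_data import DEFAULT_CORE, SimConfig

logger = logging.getLogger("hapsignal")


@dataclass
class PipelineConfig:
    """Inputs, regions and thresholds of one full analysis run."""

    out_dir: str = "hapsignal_out"
    seed: int = 0
    # either existing inputs ...
    vcf: str | None = None
    panel: str | None = None
    gene_gff: str | None = None
    gene_fasta: str | None = None
    # ... or a simulation block
    simulate: bool = True
    sim_n_pop: int = 100
    sim_n_sites: int = 400
    sim_generations: int = 60
    sim_s: float = 0.0
    sim_bottleneck_deme: bool = False
    # regions (defaults: the synthetic 3R locus)
    chrom: str = "3R"
    gene_start: int = DEFAULT_CORE.start
    gene_end: int = DEFAULT_CORE.end
    core_start: int = DEFAULT_CORE.start
    core_end: int = DEFAULT_CORE.end
    cluster_start: int = 6924703
    cluster_end: int = 6934703
    gene_strand: str = "+"
    # thresholds
    frequency_threshold: float = 0.05
    cut_height: float = 7
    linkage_method: str = "single"
    min_cluster_freq: float = 0.01
    max_edge: int = 2
    epsilon: int = 0
    min_core_freq: float = 0.01
    max_distance: int = 200_000

    def __post_init__(self) -> None:
        if not 0 <= self.frequency_threshold <= 1:
            raise ValidationError("frequency_threshold must lie in [0, 1]")
        if self.cut_height < 0 or self.max_edge < 1 or self.min_core_freq < 0:
            raise ValidationError("thresholds out of documented range")
        if not self.simulate and (self.vcf is None or self.panel is None):
            raise ValidationError(
                "either enable the simulate block or provide vcf + panel paths"
            )
        if self.simulate and (self.vcf is not None or self.panel is not None):
            raise ValidationError(
                "provide either input paths or a simulate block, not both"
            )

    @property
    def gene_region(self) -> Region:
        return Region(self.chrom, self.gene_start, self.gene_end)

    @property
    def core_region(self) -> Region:
        return Region(self.chrom, self.core_start, self.core_end)

    @property
    def cluster_region(self) -> Region:
        return Region(self.chrom, self.cluster_start, self.cluster_end)

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run(config: PipelineConfig) -> dict:
    """Execute every stage; return the output manifest (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []

    def stage(name):
        logger.info("pipeline stage: %s", name)

    # -- stage 1: obtain haplotypes + gene model -----------------------------
    stage("input")
    gene = None
    if config.simulate:
        gene = synthetic_data.plant_gene_model(
            config.gene_region, config.gene_strand,
            seed=synthetic_data.derive_seed(config.seed, 101),
        )
        # centre the site lattice on the focal position inside the core region
        focal_site = config.sim_n_sites // 2
        spacing = SimConfig().site_spacing
        focal_pos = (config.core_start + config.core_end) // 2
        base = SimConfig(
            n_pop=config.sim_n_pop,
            n_founders=2 * config.sim_n_pop,
            n_sites=config.sim_n_sites,
            chrom=config.chrom,
            first_pos=focal_pos - spacing * focal_site,
            focal_site=focal_site,
            generations=config.sim_generations,
            s=config.sim_s,
            gene=gene,
        )
        demes = [
            replace(
                base,
                pop_label="demeA",
                # sweeps start from rarity; neutral runs from intermediate freq
                focal_freq0=0.01 if config.sim_s != 0 else base.focal_freq0,
                seed=synthetic_data.derive_seed(config.seed, 1),
            )
        ]
        if config.sim_bottleneck_deme:
            demes.append(
                replace(
                    base,
                    pop_label="demeB",
                    s=0.0,
                    bottleneck=(config.sim_generations // 3, 10, 15),
                    seed=synthetic_data.derive_seed(config.seed, 2),
                )
            )
        results = []
        for cfg in demes:
            if cfg.s != 0:
                results.append(synthetic_data.simulate_surviving_sweep(cfg))
            else:
                results.append(synthetic_data.simulate(cfg))
        hapset, panel, truths = synthetic_data.merge_demes(results)
        write_vcf(hapset, out / "haplotypes.vcf")
        write_panel(panel, out / "panel.tsv")
        for truth, cfg in zip(truths, demes):
            synthetic_data.write_truth(truth, out / f"truth_{cfg.pop_label}.tsv")
            outputs.append(out / f"truth_{cfg.pop_label}.tsv")
        variant_effects.write_gene_model(
            gene, out / "gene.gff3", out / "gene_cds.fasta"
        )
        outputs += [
            out / "haplotypes.vcf",
            out / "panel.tsv",
            out / "gene.gff3",
            out / "gene_cds.fasta",
        ]
    else:
        panel = read_panel(config.panel)
        hapset = read_phased_vcf(config.vcf, None, panel)
        truths = []
        if config.gene_gff and config.gene_fasta:
            gene = variant_effects.read_gene_model(config.gene_gff, config.gene_fasta)

    # -- stage 2: effect annotation + frequencies ----------------------------
    stage("annotate")
    gene_set = hapset.restrict(config.gene_region)
    if gene is not None and gene_set.n_sites:
        effects = variant_effects.annotate_all(gene, gene_set)
        eff_rows = [
            {
                "pos": e.site.pos,
                "ref": e.site.ref,
                "alt": e.site.alt,
                "effect": e.effect_class,
                "label": e.label or "",
            }
            for e in effects
        ]
        import pandas as pd

        pd.DataFrame(eff_rows).to_csv(out / "effects.tsv", sep="\t", index=False)
        outputs.append(out / "effects.tsv")
        missense = [
            e.site for e in effects if e.effect_class == "missense"
        ]
    else:
        missense = list(gene_set.sites)

    freq_source = (
        hapset.take_sites(
            [i for i, s in enumerate(hapset.sites) if s in set(missense)]
        )
        if missense
        else gene_set
    )
    hf_variants: list = []
    if freq_source.n_sites:
        freqs = variant_effects.population_allele_frequencies(freq_source, panel)
        freqs.to_percent_tsv(out / "frequencies.tsv")
        outputs.append(out / "frequencies.tsv")
        hf_variants = variant_effects.filter_high_frequency(
            freqs, config.frequency_threshold
        )

    # -- stage 3: Hamming clustering -----------------------------------------
    stage("cluster")
    dist = hapcluster.hamming_matrix(hapset, config.cluster_region)
    assignment = hapcluster.hierarchical_clusters(
        dist,
        hapset=hapset,
        linkage=config.linkage_method,
        cut_height=config.cut_height,
        min_cluster_freq=config.min_cluster_freq,
    )
    assignment.to_frame(panel).to_csv(out / "clusters.tsv", sep="\t", index=False)
    hapcluster.cluster_population_summary(assignment, panel).to_csv(
        out / "cluster_population_summary.tsv", sep="\t"
    )
    outputs += [out / "clusters.tsv", out / "cluster_population_summary.tsv"]
    hf_in_set = [v for v in hf_variants if v in set(hapset.sites)]
    if hf_in_set:
        hapcluster.cluster_signature_variants(
            assignment, hapset, hf_in_set
        ).to_csv(out / "cluster_signatures.tsv", sep="\t", index=False)
        outputs.append(out / "cluster_signatures.tsv")

    # -- stage 4: linkage disequilibrium -------------------------------------
    stage("ld")
    if len(hf_in_set) >= 2:
        ld = linkage.dprime_matrix(hapset, hf_in_set)
        ld.to_frame().to_csv(out / "dprime.tsv", sep="\t")
        outputs.append(out / "dprime.tsv")

    # -- stage 5: median-joining network -------------------------------------
    stage("mjn")
    cluster_set = hapset.restrict(config.cluster_region)
    net = mjnetwork.median_join(
        cluster_set.matrix.T,
        epsilon=config.epsilon,
        populations=hapset.cohort_labels(panel),
    )
    mjnetwork.write_graphml(net, out / "network.graphml")
    mjnetwork.write_dot(net, out / "network.dot")
    components = mjnetwork.components_by_edge_filter(net, config.max_edge)
    conc = mjnetwork.concordance(components, assignment)
    outputs += [out / "network.graphml", out / "network.dot"]

    # -- stage 6: EHH decay ---------------------------------------------------
    stage("ehh")
    curves = ehh_mod.ehh_by_population(
        hapset,
        panel,
        config.core_region,
        min_core_freq=config.min_core_freq,
        clusters=assignment,
        max_distance=config.max_distance,
    )
    ehh_mod.curves_to_frame(curves).to_csv(out / "ehh.tsv", sep="\t", index=False)
    outputs.append(out / "ehh.tsv")

    report: dict = {
        "n_haplotypes": hapset.n_haplotypes,
        "n_sites": hapset.n_sites,
        "n_high_frequency_variants": len(hf_variants),
        "clusters": {
            label: int(len(assignment.members(label)))
            for label in assignment.cluster_names
        },
        "mjn_concordance": conc,
    }
    if config.simulate and config.sim_s != 0 and truths:
        carrier, wt = ehh_mod.carrier_contrast_areas(
            hapset.take_haplotypes(
                np.flatnonzero(hapset.meta["population"] == "demeA")
            ),
            truths[0].carrier_flags,
            config.core_region,
            config.max_distance,
        )
        report["carrier_ehh_area"] = carrier
        report["wt_ehh_area"] = wt
        report["carrier_group_slowest_decay"] = bool(carrier > wt)

    manifest = {
        "config_seed": config.seed,
        "report": report,
        "outputs": {
            str(p.relative_to(out)): _sha256(p) for p in sorted(set(outputs))
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


__all__ = ["PipelineConfig", "run"]
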