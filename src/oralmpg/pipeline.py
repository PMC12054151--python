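"""End-to-end pipeline: curation -> coverage -> abundance -> classification -> enrichment.

Each stage writes one TSV into the output directory, and a run manifest
records the configuration, package version, stage list, and input
checksums, so that a re-run with identical inputs and config reproduces
byte-identical outputs.

Enrichment groups genomes by the habitat preference their clade
received from the classifier (abundance metric): the preferred-site set
is joined into a group label, mirroring how functional comparisons
follow habitat classification in practice.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd

from oralmpg import abundance as ab
from oralmpg import io as oio
from oralmpg.classify import classify_table
from oralmpg.config import PipelineConfig
from oralmpg.curation import dereplicate_by_ani, qc_filter
from oralmpg.enrichment import (
    binarize_function_table,
    enrich_by_habitat,
    module_completeness_table,
)

STAGES = ("curation", "coverage", "abundance", "classification", "enrichment")

_STAGE_INPUTS = {
    "curation": ("genomes", "ani"),
    "coverage": ("depth_dir",),
    "abundance": ("clades",),
    "classification": ("sites",),
    "enrichment": ("functions",),
}


def run_pipeline(
    config: PipelineConfig,
    inputs: Mapping[str, str],
    out_dir,
    skip: tuple[str, ...] = (),
) -> Path:
    """Run the pipeline stages and return the output directory.

    ``inputs`` maps input names to paths: ``genomes``, ``ani``,
    ``depth_dir`` (directory of per-sample depth TSVs, one file per
    sample, named <sample_id>.tsv[.gz]), optional ``lengths``,
    ``clades``, ``sites``, ``functions``, optional ``modules``,
    ``gene_functions`` (genome -> accession list for module scoring).
    Stages named in ``skip`` are omitted along with their outputs.
    """
    unknown = set(skip) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s) in skip: {sorted(unknown)}")
    active = [s for s in STAGES if s not in skip]
    for stage in active:
        missing = [k for k in _STAGE_INPUTS[stage] if k not in inputs]
        if missing:
            raise ValueError(
                f"stage {stage!r} requires input(s) {missing}; "
                "provide them or --skip the stage"
            )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    kept_ids: set[str] | None = None
    if "curation" in active:
        records = oio.read_genome_records(inputs["genomes"])
        ani = oio.read_ani_tsv(inputs["ani"])
        passed = qc_filter(records, config.min_completeness, config.max_contamination)
        kept = dereplicate_by_ani(passed, ani, config.ani_threshold)
        kept_ids = {r.genome_id for r in kept}
        with open(out_dir / "curated_genomes.txt", "w") as fh:
            for r in kept:
                fh.write(r.genome_id + "\n")

    summary = None
    if "coverage" in active:
        lengths = (
            oio.read_lengths_tsv(inputs["lengths"]) if "lengths" in inputs else None
        )
        depth_dir = Path(inputs["depth_dir"])
        profiles = []
        paths = sorted(
            p for p in depth_dir.iterdir()
            if p.name.endswith((".tsv", ".tsv.gz"))
        )
        if not paths:
            raise ValueError(f"no depth TSV files found in {depth_dir}")
        for path in paths:
            sample_id = path.name.removesuffix(".gz").removesuffix(".tsv")
            profiles.extend(oio.read_depth_tsv(path, sample_id, lengths))
        if kept_ids is not None:
            profiles = [p for p in profiles if p.genome_id in kept_ids]
        from oralmpg.coverage import summarize_profiles

        summary = summarize_profiles(profiles, config.breadth_threshold)
        oio.write_summary_tsv(summary, out_dir / "coverage_summary.tsv")

    clade_abund = clade_detect = None
    if "abundance" in active:
        if summary is None:
            raise ValueError(
                "stage 'abundance' needs the coverage stage (or its summary output)"
            )
        clades = oio.read_clade_map(inputs["clades"])
        rel = ab.relative_abundance(summary)
        species_rel = ab.species_relative_abundance(rel, clades)
        clade_abund = ab.clade_abundance(summary, clades)
        clade_detect = ab.clade_detection(summary, clades, config.breadth_threshold)
        rel.to_csv(out_dir / "relative_abundance.tsv", sep="\t", index=False)
        species_rel.to_csv(out_dir / "species_relative_abundance.tsv", sep="\t", index=False)
        clade_abund.to_csv(out_dir / "clade_abundance.tsv", sep="\t", index=False)
        clade_detect.to_csv(out_dir / "clade_detection.tsv", sep="\t", index=False)

    classes = None
    if "classification" in active:
        if clade_abund is None:
            raise ValueError(
                "stage 'classification' needs the abundance stage outputs"
            )
        sites = oio.read_site_map(inputs["sites"])
        classes = classify_table(
            clade_abund, clade_detect, sites,
            metric="both", site_universe=config.site_universe,
        )
        classes.to_csv(out_dir / "habitat_classes.tsv", sep="\t", index=False)

    if "enrichment" in active:
        functions = oio.read_function_table(inputs["functions"])
        if "groups" in inputs:
            groups = oio.read_groups_tsv(inputs["groups"])
        else:
            if classes is None:
                raise ValueError(
                    "stage 'enrichment' needs either a groups table or the "
                    "classification stage to derive habitat groups"
                )
            clades = oio.read_clade_map(inputs["clades"])
            pref = (
                classes[classes["metric"] == "abundance"]
                .set_index("clade_id")["preferred_sites"]
            )
            groups = clades.map(pref).rename("group")
            groups = groups[groups.notna() & (groups != "")]
        presence = binarize_function_table(functions)
        presence = presence.loc[presence.index.intersection(groups.index)]
        groups = groups.loc[presence.index]
        if groups.nunique() >= 2:
            enriched = enrich_by_habitat(presence, groups, config.q_threshold)
            enriched.to_csv(out_dir / "functional_enrichment.tsv", sep="\t", index=False)
        else:
            raise ValueError(
                "stage 'enrichment': fewer than 2 habitat groups among genomes"
            )
        if "modules" in inputs:
            modules = oio.read_module_definitions(inputs["modules"])
            fns_by_genome = {
                g: set(grp["accession"]) for g, grp in functions.groupby("genome_id")
                if g in groups.index
            }
            completeness = module_completeness_table(
                fns_by_genome, modules, config.module_completeness_threshold
            )
            completeness.to_csv(out_dir / "module_completeness.tsv", sep="\t")
            module_enriched = enrich_by_habitat(
                completeness, groups.loc[completeness.index], config.q_threshold
            )
            module_enriched.to_csv(
                out_dir / "module_enrichment.tsv", sep="\t", index=False
            )

    checksummable = {
        k: v for k, v in inputs.items() if k != "depth_dir" and Path(v).is_file()
    }
    oio.write_manifest(
        out_dir / "manifest.json", config.to_dict(), active, checksummable
    )
    return out_dir
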