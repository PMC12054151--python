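"""Readers and writers for the pipeline's tabular exchange formats.

Everything is headered TSV with a stable column order; gzip is handled
transparently by extension.  Per-base depth uses the samtools-depth
dialect (genome_id, 1-based position, integer depth); the sparse variant
— positions with zero depth omitted — is accepted, with genome lengths
supplied by a sidecar table or inferred as the maximum observed
position.
"""

from __future__ import annotations

import gzip
import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from oralmpg.config import validate_sites
from oralmpg.coverage import DepthProfile, GeneInterval, SUMMARY_COLUMNS
from oralmpg.curation import GenomeRecord
from oralmpg.enrichment import ModuleDefinition


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------- depth TSV

def write_depth_tsv(profiles: Iterable[DepthProfile], path) -> None:
    """Write profiles in samtools-depth dialect (dense, all positions)."""
    with _open_text(path, "wt") as fh:
        fh.write("genome_id\tpos\tdepth\n")
        for prof in profiles:
            for pos, depth in enumerate(prof.depths, start=1):
                fh.write(f"{prof.genome_id}\t{pos}\t{int(depth)}\n")


def read_depth_tsv(
    path,
    sample_id: str,
    lengths: Mapping[str, int] | None = None,
) -> list[DepthProfile]:
    """Read one sample's per-base depth table into profiles.

    Positions absent from the file are depth 0 (sparse dialect).  When
    ``lengths`` is given it fixes each genome's length (declared but
    unobserved genomes become all-zero profiles); otherwise length is
    inferred as the maximum observed position.
    """
    per_genome: dict[str, list[tuple[int, int]]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if parts[:3] == ["genome_id", "pos", "depth"]:
                continue
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated columns")
            genome, pos_s, depth_s = parts[0], parts[1], parts[2]
            try:
                pos, depth = int(pos_s), int(depth_s)
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer position or depth ({pos_s!r}, {depth_s!r})"
                ) from exc
            if pos < 1:
                raise ValueError(f"{path}:{lineno}: position must be >= 1, got {pos}")
            if depth < 0:
                raise ValueError(f"{path}:{lineno}: depth must be >= 0, got {depth}")
            per_genome.setdefault(genome, []).append((pos, depth))
    genome_ids = set(per_genome)
    if lengths is not None:
        genome_ids |= set(lengths)
    profiles = []
    for genome in sorted(genome_ids):
        entries = per_genome.get(genome, [])
        observed_max = max((pos for pos, _ in entries), default=0)
        length = int(lengths[genome]) if lengths and genome in lengths else observed_max
        if length < 1:
            raise ValueError(f"{path}: genome {genome}: cannot determine a length >= 1")
        if observed_max > length:
            raise ValueError(
                f"{path}: genome {genome}: position {observed_max} exceeds "
                f"declared length {length}"
            )
        depths = np.zeros(length, dtype=np.int64)
        for pos, depth in entries:
            depths[pos - 1] = depth
        profiles.append(DepthProfile(genome, sample_id, depths))
    return profiles


def read_lengths_tsv(path) -> dict[str, int]:
    table = pd.read_csv(path, sep="\t")
    return dict(zip(table["genome_id"], table["length"].astype(int)))


# ----------------------------------------------------------- gene intervals

def read_gene_intervals(path, dialect: str = "bed") -> list[GeneInterval]:
    """Gene intervals from BED (0-based half-open) or 1-based 3-column TSV.

    The TSV dialect has columns gene_id, genome_id, start, end (1-based
    inclusive); BED rows are chrom, start, end[, name].
    """
    genes = []
    if dialect == "bed":
        with _open_text(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                name = parts[3] if len(parts) > 3 else f"{chrom}:{start}-{end}"
                genes.append(GeneInterval(name, chrom, start + 1, end))
    elif dialect == "tsv1":
        table = pd.read_csv(path, sep="\t")
        for row in table.itertuples(index=False):
            genes.append(
                GeneInterval(str(row.gene_id), str(row.genome_id), int(row.start), int(row.end))
            )
    else:
        raise ValueError(f"unknown gene interval dialect {dialect!r} (use 'bed' or 'tsv1')")
    return genes


# ------------------------------------------------------------ simple tables

def write_summary_tsv(summary: pd.DataFrame, path) -> None:
    summary.to_csv(path, sep="\t", index=False, columns=SUMMARY_COLUMNS)


def read_summary_tsv(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    table["detected"] = table["detected"].astype(bool)
    return table


def write_map_tsv(mapping: pd.Series, path, key: str, value: str) -> None:
    frame = mapping.rename(value).rename_axis(key).reset_index()
    frame.to_csv(path, sep="\t", index=False)


def read_clade_map(path) -> pd.Series:
    table = pd.read_csv(path, sep="\t")
    return pd.Series(table.iloc[:, 1].values, index=table.iloc[:, 0], name="clade_id")


def read_site_map(path) -> pd.Series:
    table = pd.read_csv(path, sep="\t")
    sites = pd.Series(
        table.iloc[:, 1].astype(str).values, index=table.iloc[:, 0], name="site"
    )
    validate_sites(sites.unique())
    return sites


def write_truth_tsv(truth: Mapping[str, frozenset], path) -> None:
    with open(path, "w") as fh:
        fh.write("clade_id\tpreferred_sites\n")
        for clade in sorted(truth):
            fh.write(f"{clade}\t{','.join(sorted(truth[clade]))}\n")


# --------------------------------------------------------------- ANI / QC

def read_ani_tsv(path) -> pd.DataFrame:
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    matrix.index = matrix.index.astype(str)
    matrix.columns = matrix.columns.astype(str)
    return matrix


def write_ani_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t")


def read_genome_records(path) -> list[GenomeRecord]:
    table = pd.read_csv(path, sep="\t")
    records = []
    for row in table.itertuples(index=False):
        records.append(
            GenomeRecord(
                genome_id=str(row.genome_id),
                species_label=str(getattr(row, "species_label", "")),
                completeness=float(row.completeness),
                contamination=float(row.contamination),
                length=int(getattr(row, "length", 0)),
            )
        )
    return records


# ------------------------------------------------------- functions / modules

def read_function_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    table["count"] = table["count"].astype(int)
    if (table["count"] < 0).any():
        raise ValueError(f"{path}: counts must be non-negative")
    return table


def write_function_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_module_definitions(path) -> list[ModuleDefinition]:
    """Flattened module definitions: module_id, step_index, alternatives.

    ``alternatives`` is a comma-separated accession list; any one
    alternative satisfies its step.
    """
    table = pd.read_csv(path, sep="\t")
    modules = []
    for module_id, grp in table.groupby("module_id", sort=True):
        grp = grp.sort_values("step_index")
        steps = tuple(
            frozenset(str(alt).split(",")) for alt in grp["alternatives"]
        )
        modules.append(ModuleDefinition(str(module_id), steps))
    return modules


def read_groups_tsv(path) -> pd.Series:
    table = pd.read_csv(path, sep="\t")
    return pd.Series(table.iloc[:, 1].values, index=table.iloc[:, 0], name="group")


# ---------------------------------------------------------------- manifest

def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, config: dict, stages: list[str], inputs: Mapping[str, str]) -> None:
    import oralmpg

    manifest = {
        "tool": "oralmpg",
        "version": oralmpg.__version__,
        "config": config,
        "stages": stages,
        "input_checksums": {
            name: file_checksum(p) for name, p in sorted(inputs.items())
        },
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
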