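"""Relative abundance and clade-level abundance/prevalence series.

Two distinct normalizations coexist and are kept explicit:

* :func:`relative_abundance` — heatmap-style per-sample relative
  abundance: the Q2Q3 depth of every *undetected* genome is set to zero,
  then each genome's depth is divided by the per-sample total of the
  zeroed depths.  Values per sample sum to 1 when anything was detected.

* :func:`clade_abundance` — the classifier-facing metric: the raw sum of
  member Q2Q3 depths per clade and sample, with no detection zeroing
  (optional via ``zero_undetected=True``).

Clade prevalence uses the max-breadth rule: a clade is detected in a
sample when the best-covered member genome reaches the breadth
threshold.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd


def _clade_series(clades) -> pd.Series:
    if isinstance(clades, pd.Series):
        return clades
    if isinstance(clades, Mapping):
        return pd.Series(clades)
    raise TypeError("clades must be a mapping or Series of genome_id -> clade_id")


def _check_clades(summaries: pd.DataFrame, clades: pd.Series) -> None:
    missing = set(summaries["genome_id"]) - set(clades.index)
    if missing:
        raise KeyError(f"genomes without a clade label: {sorted(missing)}")


def relative_abundance(summaries: pd.DataFrame) -> pd.DataFrame:
    """Per-sample relative abundance of each genome.

    Undetected genomes contribute zero coverage; each sample's zeroed
    Q2Q3 depths are divided by their sample total.  A sample in which
    no genome is detected gets all-zero abundances rather than an
    error — empty mucosal samples are an expected outcome.

    Returns the input with an added ``relative_abundance`` column.
    """
    if (summaries["q2q3_mean_depth"] < 0).any():
        raise ValueError("q2q3_mean_depth must be non-negative")
    out = summaries.copy()
    zeroed = out["q2q3_mean_depth"].where(out["detected"], 0.0)
    totals = zeroed.groupby(out["sample_id"]).transform("sum")
    out["relative_abundance"] = (zeroed / totals.where(totals > 0, 1.0)).where(
        totals > 0, 0.0
    )
    return out


def clade_abundance(
    summaries: pd.DataFrame,
    clades,
    zero_undetected: bool = False,
) -> pd.DataFrame:
    """Summed member Q2Q3 depth per (clade, sample).

    By default raw depths are summed; ``zero_undetected=True`` zeroes
    undetected members first.  Abundance is linear in member depths, so
    per-sample clade totals conserve the per-sample genome totals.
    """
    clades = _clade_series(clades)
    _check_clades(summaries, clades)
    depth = summaries["q2q3_mean_depth"]
    if zero_undetected:
        depth = depth.where(summaries["detected"], 0.0)
    frame = pd.DataFrame(
        {
            "sample_id": summaries["sample_id"],
            "clade_id": summaries["genome_id"].map(clades),
            "abundance": depth,
        }
    )
    return (
        frame.groupby(["clade_id", "sample_id"], as_index=False)["abundance"]
        .sum()
        .sort_values(["clade_id", "sample_id"], ignore_index=True)
    )


def clade_detection(
    summaries: pd.DataFrame,
    clades,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Binary clade detection per sample via the max-breadth rule.

    A clade is detected in a sample iff the maximum breadth of coverage
    over its member genomes is at least ``threshold``.  Detection is
    monotone: adding a member can only switch a clade on, never off.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    clades = _clade_series(clades)
    _check_clades(summaries, clades)
    frame = pd.DataFrame(
        {
            "sample_id": summaries["sample_id"],
            "clade_id": summaries["genome_id"].map(clades),
            "breadth": summaries["breadth"],
        }
    )
    agg = frame.groupby(["clade_id", "sample_id"], as_index=False)["breadth"].max()
    agg["detected"] = agg["breadth"] >= threshold
    return agg.rename(columns={"breadth": "max_breadth"}).sort_values(
        ["clade_id", "sample_id"], ignore_index=True
    )


def species_relative_abundance(abundances: pd.DataFrame, clades) -> pd.DataFrame:
    """Species/clade-level relative abundance: sum of member genome values.

    Expects the output of :func:`relative_abundance`.  Per sample, the
    clade-level values sum exactly to the genome-level values, so the
    normalization is conserved by the aggregation.
    """
    clades = _clade_series(clades)
    _check_clades(abundances, clades)
    frame = pd.DataFrame(
        {
            "sample_id": abundances["sample_id"],
            "clade_id": abundances["genome_id"].map(clades),
            "relative_abundance": abundances["relative_abundance"],
        }
    )
    return (
        frame.groupby(["clade_id", "sample_id"], as_index=False)["relative_abundance"]
        .sum()
        .sort_values(["clade_id", "sample_id"], ignore_index=True)
    )


def abundance_matrix(table: pd.DataFrame, value_column: str, index: str = "clade_id") -> pd.DataFrame:
    """Pivot a long-form abundance table to rows x samples for heatmaps."""
    return table.pivot_table(
        index=index, columns="sample_id", values=value_column, fill_value=0.0
    )
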