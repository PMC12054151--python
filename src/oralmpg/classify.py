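"""Habitat-preference classification by exhaustive site bipartition.

Each species clade is associated with the set of oral sampling sites
where it is most differentially abundant or prevalent.  The algorithm
enumerates every unordered bipartition of the site universe into two
non-empty groups (2^(k-1) - 1 maps for k sites; 127 for the default
eight), scores each map, and keeps the map with the largest absolute
test statistic:

abundance metric
    Pooled-variance two-sample Student t statistic of per-sample summed
    clade Q2Q3 depths, group 1 vs group 2.

prevalence metric
    Rao score statistic for the group term in a binomial-logit model of
    per-sample binary clade detection on group membership.  For a single
    binary covariate this equals the Pearson chi-square of the 2x2
    group-by-detection table, N(ad - bc)^2 / (n1 n2 m1 m0).

The preferred sites are the winning map's group with the higher central
tendency (mean abundance, or detection proportion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from oralmpg.config import CLASSIFIER_SITES

Metric = Literal["abundance", "prevalence"]


@dataclass(frozen=True)
class HabitatMap:
    """An unordered bipartition of site codes into two non-empty groups."""

    group1: frozenset[str]
    group2: frozenset[str]

    def __post_init__(self) -> None:
        if not self.group1 or not self.group2:
            raise ValueError("both groups must be non-empty")
        if self.group1 & self.group2:
            raise ValueError("groups must be disjoint")

    @property
    def sites(self) -> frozenset[str]:
        return self.group1 | self.group2

    def __str__(self) -> str:
        return "{}|{}".format(
            ",".join(sorted(self.group1)), ",".join(sorted(self.group2))
        )


@dataclass(frozen=True)
class ClassificationResult:
    """Winning habitat map for one clade under one metric."""

    clade_id: str
    metric: Metric
    best_map: HabitatMap
    statistic: float
    preferred_sites: frozenset[str]


def enumerate_bipartitions(sites: Sequence[str]) -> list[HabitatMap]:
    """All unordered bipartitions of ``sites`` into two non-empty groups.

    The two classifier statistics are symmetric (up to sign) under group
    swap, so ordered duplicates are redundant; the count is
    2^(k-1) - 1.  Enumeration is deterministic: sites are sorted, the
    lexicographically smallest site is anchored in group 1, and the
    remaining subsets are generated in binary counting order.
    """
    sites = sorted(set(sites))
    k = len(sites)
    if k < 2:
        raise ValueError("need at least 2 sites to bipartition")
    if k > 20:
        raise ValueError("site universe too large to enumerate (max 20)")
    anchor, rest = sites[0], sites[1:]
    maps = []
    # mask over `rest`; all-ones would leave group 2 empty
    for mask in range(2 ** (k - 1) - 1):
        group1 = frozenset([anchor] + [s for i, s in enumerate(rest) if mask >> i & 1])
        group2 = frozenset(sites) - group1
        maps.append(HabitatMap(group1, group2))
    return maps


def _split_by_map(
    values: pd.Series, sites: pd.Series, hmap: HabitatMap
) -> tuple[np.ndarray, np.ndarray]:
    site_of = sites.reindex(values.index)
    if site_of.isna().any():
        missing = list(values.index[site_of.isna()])
        raise KeyError(f"samples without a site label: {missing}")
    g1 = values[site_of.isin(hmap.group1)].to_numpy(dtype=float)
    g2 = values[site_of.isin(hmap.group2)].to_numpy(dtype=float)
    return g1, g2


def t_statistic_for_map(values: pd.Series, sites, hmap: HabitatMap) -> float | None:
    """Pooled-variance Student t statistic of group 1 vs group 2.

    Positive when the group-1 mean exceeds the group-2 mean.  Returns
    ``None`` (map undefined) when either group has no sample or the
    combined degrees of freedom n1 + n2 - 2 are below 1.  A zero pooled
    variance yields 0 for equal means and signed infinity otherwise
    (perfect separation dominates every finite map).
    """
    sites = pd.Series(sites) if not isinstance(sites, pd.Series) else sites
    g1, g2 = _split_by_map(values, sites, hmap)
    n1, n2 = g1.size, g2.size
    if n1 == 0 or n2 == 0 or n1 + n2 - 2 < 1:
        return None
    d = g1.mean() - g2.mean()
    pooled = (np.sum((g1 - g1.mean()) ** 2) + np.sum((g2 - g2.mean()) ** 2)) / (
        n1 + n2 - 2
    )
    if pooled == 0:
        return 0.0 if d == 0 else math.copysign(math.inf, d)
    return float(d / math.sqrt(pooled * (1 / n1 + 1 / n2)))


def rao_statistic_for_map(detections: pd.Series, sites, hmap: HabitatMap) -> float | None:
    """Rao score statistic of detection on group membership.

    Equals the Pearson chi-square of the 2x2 (group x detected) table.
    Returns 0 when a margin is degenerate (every sample detected, or
    none), ``None`` when a group has no sample.
    """
    sites = pd.Series(sites) if not isinstance(sites, pd.Series) else sites
    g1, g2 = _split_by_map(detections.astype(float), sites, hmap)
    n1, n2 = g1.size, g2.size
    if n1 == 0 or n2 == 0:
        return None
    a = g1.sum()          # group1 detected
    b = g2.sum()          # group2 detected
    m1 = a + b            # detected margin
    n = n1 + n2
    m0 = n - m1
    if m1 == 0 or m0 == 0:
        return 0.0
    c, d = n1 - a, n2 - b
    return float(n * (a * d - b * c) ** 2 / (n1 * n2 * m1 * m0))


def _preferred_side(
    values: pd.Series, sites: pd.Series, hmap: HabitatMap
) -> frozenset[str]:
    # mean of a 0/1 detection vector is the detection proportion, so one
    # rule covers both metrics
    g1, g2 = _split_by_map(values.astype(float), sites, hmap)
    m1, m2 = g1.mean(), g2.mean()
    if m1 > m2:
        return hmap.group1
    if m2 > m1:
        return hmap.group2
    # equal central tendency: deterministic parsimony tie-break
    return min(
        (hmap.group1, hmap.group2), key=lambda g: (len(g), tuple(sorted(g)))
    )


def classify_clade(
    values: pd.Series,
    sites,
    metric: Metric,
    clade_id: str = "",
    site_universe: Iterable[str] = CLASSIFIER_SITES,
    min_stat: float = 0.0,
) -> ClassificationResult:
    """Pick the habitat map with the largest absolute test statistic.

    Parameters
    ----------
    values:
        Per-sample clade abundance (``metric="abundance"``) or binary
        detection (``metric="prevalence"``), indexed by sample id.
    sites:
        Mapping/Series sample id -> site code.  Samples whose site is
        outside ``site_universe`` are ignored (the hard palate, with its
        single sample, is excluded from the default universe).
    min_stat:
        When > 0, a winning map whose absolute statistic falls below
        this value is reported with empty ``preferred_sites`` ("no
        preference").  Disabled (0) by default.

    Ties in the absolute statistic break deterministically toward the
    map whose preferred group has fewer sites, then lexicographically
    smaller site codes.  Maps leaving one group without samples are
    skipped, not scored as zero.
    """
    if metric not in ("abundance", "prevalence"):
        raise ValueError(f"unknown metric {metric!r}")
    sites = pd.Series(sites) if not isinstance(sites, pd.Series) else sites
    universe = sorted(set(site_universe))
    site_of = sites.reindex(values.index)
    keep = site_of.isin(universe)
    values = values[keep]
    site_of = site_of[keep]
    represented = set(site_of)
    if len(represented) < 2:
        raise ValueError(
            "need samples from at least 2 universe sites to classify, "
            f"got {sorted(represented)}"
        )
    stat_fn = t_statistic_for_map if metric == "abundance" else rao_statistic_for_map
    best: tuple | None = None
    for hmap in enumerate_bipartitions(universe):
        stat = stat_fn(values, site_of, hmap)
        if stat is None:
            continue
        preferred = _preferred_side(values, site_of, hmap)
        key = (-abs(stat), len(preferred), tuple(sorted(preferred)))
        if best is None or key < best[0]:
            best = (key, hmap, stat, preferred)
    if best is None:
        raise ValueError(f"no habitat map is defined for clade {clade_id!r}")
    _, hmap, stat, preferred = best
    if min_stat > 0 and abs(stat) < min_stat:
        preferred = frozenset()
    return ClassificationResult(
        clade_id=clade_id,
        metric=metric,
        best_map=hmap,
        statistic=float(stat),
        preferred_sites=frozenset(preferred),
    )


def classify_table(
    abundances: pd.DataFrame,
    detections: pd.DataFrame,
    sites,
    metric: str = "both",
    site_universe: Iterable[str] = CLASSIFIER_SITES,
    min_stat: float = 0.0,
) -> pd.DataFrame:
    """Classify every clade in long-form abundance/detection tables.

    ``abundances`` needs columns (clade_id, sample_id, abundance);
    ``detections`` needs (clade_id, sample_id, detected).  Returns one
    row per clade and metric with the winning map and statistic.
    """
    if metric not in ("abundance", "prevalence", "both"):
        raise ValueError(f"unknown metric {metric!r}")
    wanted = ["abundance", "prevalence"] if metric == "both" else [metric]
    rows = []
    sources = {"abundance": (abundances, "abundance"), "prevalence": (detections, "detected")}
    for m in wanted:
        table, column = sources[m]
        for clade_id, grp in table.groupby("clade_id"):
            series = grp.set_index("sample_id")[column]
            res = classify_clade(
                series, sites, m, clade_id=str(clade_id),
                site_universe=site_universe, min_stat=min_stat,
            )
            rows.append(
                {
                    "clade_id": res.clade_id,
                    "metric": res.metric,
                    "group1": ",".join(sorted(res.best_map.group1)),
                    "group2": ",".join(sorted(res.best_map.group2)),
                    "statistic": res.statistic,
                    "preferred_sites": ",".join(sorted(res.preferred_sites)),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["clade_id", "metric", "group1", "group2", "statistic", "preferred_sites"],
    ).sort_values(["metric", "clade_id"], ignore_index=True)
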