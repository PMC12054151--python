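"""Module completeness and habitat-group functional enrichment.

Metabolic capability is scored per genome as *module completeness*: the
fraction of a pathway's enzymatic steps for which at least one
alternative ortholog is present.  A module is "complete" at the default
threshold of 0.75 (at least 75% of steps present, inclusive).

Enrichment between habitat-preference groups is tested per function (or
per module-completeness flag) with the Rao score statistic for the group
factor in a binomial-logit generalized linear model of presence on
group.  The score statistic for a categorical covariate equals the
Pearson chi-square of the groups-by-presence contingency table and is
referred to a chi-square distribution with (#groups - 1) degrees of
freedom.  P-values are Benjamini-Hochberg adjusted; a function is called
significantly enriched when its q-value is strictly below 0.01.

Occurrence counts are binarized (presence = count >= 1) before testing:
the binomial family models per-genome presence, not copy number.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class ModuleDefinition:
    """A metabolic module as an ordered list of steps.

    Each step is a set of alternative function accessions; any one
    alternative satisfies the step.  The full nested boolean grammar of
    KEGG module definitions (sub-complexes, AND-within-step) is expected
    to be flattened upstream into this step-list form.
    """

    module_id: str
    steps: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError(f"module {self.module_id}: needs at least one step")
        if any(not step for step in self.steps):
            raise ValueError(f"module {self.module_id}: steps must be non-empty")


def module_completeness(genome_functions: Iterable[str], module: ModuleDefinition) -> float:
    """Fraction of module steps with at least one alternative present."""
    present = set(genome_functions)
    satisfied = sum(1 for step in module.steps if step & present)
    return satisfied / len(module.steps)


def module_complete(
    genome_functions: Iterable[str],
    module: ModuleDefinition,
    threshold: float = 0.75,
) -> bool:
    """Completeness at or above ``threshold`` (inclusive) scores complete."""
    return module_completeness(genome_functions, module) >= threshold


def _group_series(groups) -> pd.Series:
    if isinstance(groups, pd.Series):
        return groups
    if isinstance(groups, Mapping):
        return pd.Series(groups)
    raise TypeError("groups must be a mapping or Series of genome_id -> group")


def enrichment_test(presence: pd.Series, groups) -> dict:
    """Score one function's association with habitat groups.

    Parameters
    ----------
    presence:
        Boolean per-genome presence, indexed by genome id.
    groups:
        Mapping genome id -> group label; at least two groups.

    Returns a dict with the enrichment score (Rao/Pearson chi-square),
    its p-value on (#groups - 1) df, the per-group presence proportions,
    and ``associated_groups`` — the groups whose proportion exceeds the
    pooled proportion.  A degenerate margin (function present in all
    genomes or none) scores 0 with p = 1.
    """
    groups = _group_series(groups)
    labels = groups.reindex(presence.index)
    if labels.isna().any():
        missing = list(presence.index[labels.isna()])
        raise KeyError(f"genomes without a group label: {missing}")
    present = presence.astype(bool)
    levels = sorted(labels.unique())
    if len(levels) < 2:
        raise ValueError("enrichment requires at least 2 groups")
    n_by_group = labels.value_counts().reindex(levels)
    k_by_group = present.groupby(labels).sum().reindex(levels).fillna(0)
    props = (k_by_group / n_by_group).astype(float)
    n = int(n_by_group.sum())
    k = int(k_by_group.sum())
    pooled = k / n
    if k == 0 or k == n:
        score, p = 0.0, 1.0
    else:
        expected_present = n_by_group.to_numpy(dtype=float) * pooled
        expected_absent = n_by_group.to_numpy(dtype=float) * (1 - pooled)
        observed_present = k_by_group.to_numpy(dtype=float)
        observed_absent = n_by_group.to_numpy(dtype=float) - observed_present
        score = float(
            np.sum((observed_present - expected_present) ** 2 / expected_present)
            + np.sum((observed_absent - expected_absent) ** 2 / expected_absent)
        )
        p = float(stats.chi2.sf(score, df=len(levels) - 1))
    return {
        "enrichment_score": score,
        "p_value": p,
        "associated_groups": frozenset(g for g in levels if props[g] > pooled),
        "proportions": {g: float(props[g]) for g in levels},
    }


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def binarize_function_table(functions: pd.DataFrame) -> pd.DataFrame:
    """Long-form (genome_id, accession, count) -> genome x function booleans."""
    if (functions["count"] < 0).any():
        raise ValueError("function counts must be non-negative")
    wide = functions.pivot_table(
        index="genome_id", columns="accession", values="count",
        aggfunc="sum", fill_value=0,
    )
    return wide >= 1


def enrich_by_habitat(
    presence_table: pd.DataFrame,
    groups,
    q_threshold: float = 0.01,
) -> pd.DataFrame:
    """Test every function/module for enrichment between habitat groups.

    ``presence_table`` is a genome x function boolean frame (see
    :func:`binarize_function_table`; module-completeness flags work the
    same way).  Returns one row per function with score, p, BH q,
    ``significant`` (strict q < ``q_threshold``), associated groups, and
    per-group presence proportions.  The full table is always returned;
    callers subset on ``significant``.
    """
    groups = _group_series(groups)
    ids = list(presence_table.columns)
    if not ids:
        return pd.DataFrame(
            columns=["id", "enrichment_score", "p_value", "q_value",
                     "significant", "associated_groups"]
        )
    results = [enrichment_test(presence_table[c], groups) for c in ids]
    levels = sorted(groups.reindex(presence_table.index).unique())
    out = pd.DataFrame(
        {
            "id": ids,
            "enrichment_score": [r["enrichment_score"] for r in results],
            "p_value": [r["p_value"] for r in results],
        }
    )
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    out["significant"] = out["q_value"] < q_threshold
    out["associated_groups"] = [
        ",".join(sorted(r["associated_groups"])) for r in results
    ]
    for g in levels:
        out[f"proportion_{g}"] = [r["proportions"][g] for r in results]
    return out.sort_values(
        ["q_value", "p_value", "id"], ignore_index=True
    )


def module_completeness_table(
    functions_by_genome: Mapping[str, Iterable[str]],
    modules: Sequence[ModuleDefinition],
    threshold: float = 0.75,
) -> pd.DataFrame:
    """Genome x module boolean completeness flags at ``threshold``."""
    data = {
        m.module_id: {
            g: module_complete(fns, m, threshold)
            for g, fns in functions_by_genome.items()
        }
        for m in modules
    }
    frame = pd.DataFrame(data)
    frame.index.name = "genome_id"
    return frame.sort_index()
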