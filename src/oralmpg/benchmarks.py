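"""Self-contained evaluation runs on synthetic data with known truth.

These routines generate communities or function tables with the
generator's study conditions, run the corresponding pipeline stage, and
score the result against the simulated ground truth.  They back both
the validation test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from oralmpg.abundance import clade_abundance, clade_detection
from oralmpg.classify import classify_clade
from oralmpg.enrichment import binarize_function_table, enrich_by_habitat
from oralmpg.simulate import (
    default_community_config,
    simulate_community,
    simulate_function_table,
    substream,
)


def habitat_recovery(
    seed: int,
    n_clades_total: int = 100,
    samples_per_site: int = 20,
    genome_length: int = 2000,
) -> dict[str, float]:
    """Fraction of simulated clades whose true habitat map is recovered.

    Replicates the three-clade community (tongue, plaque, gingiva
    specialists; 8 sites, ``samples_per_site`` samples each) with fresh
    substream seeds until ``n_clades_total`` clade classifications have
    been scored, for both the abundance (t) and prevalence (Rao)
    metrics.  Recovery means the classifier's preferred site set equals
    the simulated one.
    """
    correct = {"abundance": 0, "prevalence": 0}
    scored = 0
    replicate = 0
    while scored < n_clades_total:
        rep_seed = int(
            substream(seed, "habitat-recovery", str(replicate)).integers(2**31)
        )
        cfg = default_community_config(
            seed=rep_seed,
            samples_per_site=samples_per_site,
            genome_length=genome_length,
        )
        summary, _, site_map, clade_map, truth = simulate_community(cfg)
        abund = clade_abundance(summary, clade_map)
        detect = clade_detection(summary, clade_map)
        for clade, preferred in truth.items():
            if scored >= n_clades_total:
                break
            a_series = abund[abund.clade_id == clade].set_index("sample_id")["abundance"]
            d_series = detect[detect.clade_id == clade].set_index("sample_id")["detected"]
            res_a = classify_clade(a_series, site_map, "abundance", clade)
            res_p = classify_clade(d_series, site_map, "prevalence", clade)
            correct["abundance"] += res_a.preferred_sites == preferred
            correct["prevalence"] += res_p.preferred_sites == preferred
            scored += 1
        replicate += 1
    return {metric: correct[metric] / scored for metric in correct}


def _two_groups(n_per_group: int = 10) -> pd.Series:
    return pd.Series(
        {f"a{i}": "A" for i in range(n_per_group)}
        | {f"b{i}": "B" for i in range(n_per_group)}
    )


def null_enrichment_proportion(
    seed: int, n_functions: int = 1000, n_per_group: int = 10
) -> float:
    """Proportion of q < 0.01 calls on a pure-null function table."""
    groups = _two_groups(n_per_group)
    table = simulate_function_table(
        groups, [], background_functions=n_functions, background_prob=0.5, seed=seed
    )
    presence = binarize_function_table(table).reindex(groups.index, fill_value=False)
    out = enrich_by_habitat(presence, groups)
    return float(out["significant"].mean()) if len(out) else 0.0


def planted_enrichment_recall(
    seed: int, n_planted: int = 5, n_background: int = 500, n_per_group: int = 10
) -> float:
    """Recall of perfectly separating functions among null background."""
    groups = _two_groups(n_per_group)
    planted = [(f"PL{i}", "A", 1.0, 0.0) for i in range(n_planted)]
    table = simulate_function_table(
        groups, planted, background_functions=n_background,
        background_prob=0.5, seed=seed,
    )
    presence = binarize_function_table(table).reindex(groups.index, fill_value=False)
    out = enrich_by_habitat(presence, groups)
    flagged = set(out[out["significant"]]["id"])
    return len(flagged & {f"PL{i}" for i in range(n_planted)}) / n_planted


def q2q3_oracle_max_deviation(seed: int, n_vectors: int = 1000) -> float:
    """Max |Q2Q3 - brute-force sort-and-slice oracle| over random vectors."""
    from oralmpg.coverage import q2q3_mean_depth

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_vectors):
        n = int(rng.integers(1, 51))
        depths = rng.integers(0, 100, size=n)
        s = np.sort(depths)
        t = n // 4
        oracle = s[t : n - t].mean()
        worst = max(worst, abs(q2q3_mean_depth(depths) - oracle))
    return worst
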