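"""Reference-genome QC filtering and ANI-based dereplication.

Quality control keeps genomes with completeness >= 90% and contamination
strictly below 5% (estimates produced upstream, e.g. by CheckM2 —
consumed here as a table).  Dereplication then reduces the collection so
that no retained pair exceeds 98% average nucleotide identity, keeping
one representative per redundant cluster.

The pairwise-ANI constraint does not by itself determine which genome of
a redundant cluster survives; this module uses quality-ranked greedy
selection, the standard dereplication practice: candidates are visited
in order of decreasing completeness, increasing contamination,
decreasing length, then genome id, and a candidate is accepted iff its
ANI to every already-accepted genome is at or below the threshold.  The
result satisfies the pairwise constraint by construction and is maximal
(every rejected genome conflicts with an accepted one).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class GenomeRecord:
    """Metadata for one reference genome."""

    genome_id: str
    species_label: str = ""
    completeness: float = 100.0
    contamination: float = 0.0
    length: int = 0
    source: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.completeness <= 100:
            raise ValueError(
                f"{self.genome_id}: completeness {self.completeness} outside [0, 100]"
            )
        if not 0 <= self.contamination <= 100:
            raise ValueError(
                f"{self.genome_id}: contamination {self.contamination} outside [0, 100]"
            )


def qc_filter(
    records: Iterable[GenomeRecord],
    min_completeness: float = 90.0,
    max_contamination: float = 5.0,
) -> list[GenomeRecord]:
    """Keep genomes with completeness >= min and contamination < max.

    Boundary semantics follow the stated thresholds: completeness of
    exactly 90 is kept ("at least 90%"), contamination of exactly 5 is
    removed ("below 5%").
    """
    if not 0 <= min_completeness <= 100 or not 0 <= max_contamination <= 100:
        raise ValueError("QC bounds must be percentages in [0, 100]")
    return [
        r
        for r in records
        if r.completeness >= min_completeness and r.contamination < max_contamination
    ]


def symmetrize_ani(ani: pd.DataFrame) -> pd.DataFrame:
    """Symmetrize a pairwise ANI matrix by elementwise maximum.

    Alignment-based ANI (e.g. ANIb) is slightly asymmetric; taking the
    max of the two directions is the conservative choice for
    dereplication (more merging).  The diagonal is forced to 100.
    """
    if list(ani.index) != list(ani.columns):
        raise ValueError("ANI matrix must be square with matching row/column ids")
    values = ani.to_numpy(dtype=float)
    if np.nanmin(values) < 0 or np.nanmax(values) > 100:
        raise ValueError("ANI values must be percentages in [0, 100]")
    sym = np.maximum(values, values.T)
    np.fill_diagonal(sym, 100.0)
    return pd.DataFrame(sym, index=ani.index, columns=ani.columns)


def dereplicate_by_ani(
    records: Sequence[GenomeRecord],
    ani: pd.DataFrame,
    threshold: float = 98.0,
) -> list[GenomeRecord]:
    """Greedy quality-ranked dereplication at the given ANI threshold.

    Returns the accepted records in acceptance (quality) order.  Raises
    ``KeyError`` if a record is absent from the matrix.
    """
    if not 0 <= threshold <= 100:
        raise ValueError("threshold must be a percentage in [0, 100]")
    ani = symmetrize_ani(ani)
    missing = {r.genome_id for r in records} - set(ani.index)
    if missing:
        raise KeyError(f"genomes missing from ANI matrix: {sorted(missing)}")
    ranked = sorted(
        records,
        key=lambda r: (-r.completeness, r.contamination, -r.length, r.genome_id),
    )
    accepted: list[GenomeRecord] = []
    for cand in ranked:
        if all(
            ani.at[cand.genome_id, kept.genome_id] <= threshold for kept in accepted
        ):
            accepted.append(cand)
    return accepted
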