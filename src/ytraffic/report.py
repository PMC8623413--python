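"""Summary artifacts: segmental-duplication tables, the Y-gene catalog, and
expected-coverage arithmetic for pooled-sex sequencing.

Conventions: duplication sizes are the plain difference of kb coordinates
(size_kb = end_kb - start_kb, no +1); genes that disappeared from a
duplication are implicit (n_genes - n_functional - n_pseudogenes); a
multicopy locus annotated under several names counts once in the catalog.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

SEGDUP_COLUMNS = [
    "source_chromosome",
    "scaffold",
    "start_kb",
    "end_kb",
    "size_kb",
    "n_genes",
    "n_functional",
    "n_pseudogenes",
]


def interval_size_kb(start_kb: float, end_kb: float) -> float:
    """Size of a kb-coordinate interval as the plain difference end - start."""
    if end_kb < start_kb:
        raise ValueError(f"end_kb {end_kb} < start_kb {start_kb}")
    return end_kb - start_kb


def segdup_table(rows: Iterable[Mapping]) -> pd.DataFrame:
    """Validated duplication report with a column-wise totals row.

    Each row needs source_chromosome, scaffold, start_kb, end_kb, n_genes,
    n_functional and n_pseudogenes; size_kb is recomputed from the
    coordinates.  Totals sum size_kb and the three gene columns.
    """
    records = []
    for row in rows:
        size = interval_size_kb(row["start_kb"], row["end_kb"])
        n_genes = int(row["n_genes"])
        n_func = int(row["n_functional"])
        n_pseudo = int(row["n_pseudogenes"])
        if n_func + n_pseudo > n_genes:
            raise ValueError(
                f"{row.get('scaffold')}: functional + pseudogenes exceeds gene count"
            )
        records.append(
            {
                "source_chromosome": row["source_chromosome"],
                "scaffold": row["scaffold"],
                "start_kb": row["start_kb"],
                "end_kb": row["end_kb"],
                "size_kb": size,
                "n_genes": n_genes,
                "n_functional": n_func,
                "n_pseudogenes": n_pseudo,
            }
        )
    df = pd.DataFrame(records, columns=SEGDUP_COLUMNS)
    totals = {
        "source_chromosome": "total",
        "scaffold": "-",
        "start_kb": pd.NA,
        "end_kb": pd.NA,
        "size_kb": df["size_kb"].sum() if len(df) else 0,
        "n_genes": df["n_genes"].sum() if len(df) else 0,
        "n_functional": df["n_functional"].sum() if len(df) else 0,
        "n_pseudogenes": df["n_pseudogenes"].sum() if len(df) else 0,
    }
    return pd.concat([df, pd.DataFrame([totals])], ignore_index=True)


@dataclass(frozen=True)
class CatalogSummary:
    """Tally of the Y-linked gene catalog."""

    n_total_y_genes: int
    n_previously_known: int
    n_new: int
    n_multicopy: int
    copy_counts: dict[str, int]


def catalog(
    previously_known: Sequence[str],
    new_genes: Sequence[Sequence[str] | str],
    copy_counts: Mapping[str, int] | None = None,
) -> CatalogSummary:
    """Combine known and newly identified Y-linked genes into one catalog.

    Each entry of ``new_genes`` is one locus; a multicopy locus annotated
    under several names is given as a tuple/list of names and still counts
    once.  ``copy_counts`` optionally carries per-locus full-length copy
    numbers (the 95%-identity rule).
    """
    known = list(previously_known)
    new_entries = [
        tuple(entry) if not isinstance(entry, str) else (entry,) for entry in new_genes
    ]
    all_names = list(known) + [n for entry in new_entries for n in entry]
    if len(set(all_names)) != len(all_names):
        raise ValueError("duplicate gene ids across known and new lists")
    n_multicopy = 0
    counts = dict(copy_counts or {})
    for entry in new_entries:
        total = sum(counts.get(n, 1) for n in entry)
        if len(entry) > 1 or total > 1:
            n_multicopy += 1
    return CatalogSummary(
        n_total_y_genes=len(known) + len(new_entries),
        n_previously_known=len(known),
        n_new=len(new_entries),
        n_multicopy=n_multicopy,
        copy_counts=counts,
    )


def expected_y_depth(total_autosomal_depth: float, male_fraction: float) -> float:
    """Expected Y coverage from pooled-sex sequencing depth.

    Autosomes are diploid in everyone; the Y is a single copy carried only by
    the male fraction of the pool, hence depth x male_fraction / 2.  An 8.4x
    unsexed (50/50) library thus covers the Y at 2.1x.
    """
    if total_autosomal_depth <= 0:
        raise ValueError("depth must be positive")
    if not 0.0 <= male_fraction <= 1.0:
        raise ValueError("male_fraction must be in [0, 1]")
    return total_autosomal_depth * male_fraction / 2.0
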