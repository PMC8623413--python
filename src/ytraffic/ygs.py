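"""Y-linked scaffold classification from sexed read sets (the YGS procedure).

A scaffold that derives from the Y chromosome is present in male sequencing
reads but absent from female reads.  The classifier scores each assembly
scaffold by the percentage of its *valid single-copy* k-mers that are not
observed in female reads:

* single-copy: the canonical k-mer occurs exactly once in the whole assembly
  (this screens out repeats shared between the Y and other chromosomes);
* valid: the k-mer is additionally observed in the male read set (this screens
  out assembly artifacts that no read supports).

On real data the per-scaffold percentage is sharply bimodal: X/autosomal
scaffolds sit near 0% and Y scaffolds near 100%, so a simple cutoff (60% by
default) separates the classes.  Scaffolds with fewer than ``min_valid``
(default 20) valid single-copy k-mers are uninformative and left unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._encode import canonical_codes, encode, in_sorted, kmer_codes

CLASS_Y = "Y"
CLASS_XA = "XA"
CLASS_UNCLASSIFIED = "unclassified"

_READ_CHUNK_BP = 8_000_000


@dataclass
class KmerIndex:
    """Canonical k-mer occurrence counts for one sequence source.

    ``codes``/``counts`` are parallel arrays over the sorted unique canonical
    k-mers.  When built with ``per_sequence=True`` the index also retains, per
    input sequence, its sorted unique canonical codes, its total number of
    valid k-mer windows and its length -- which is what per-scaffold
    classification needs.
    """

    k: int
    label: str
    codes: np.ndarray
    counts: np.ndarray
    per_sequence: dict[str, np.ndarray] | None = None
    n_windows: dict[str, int] = field(default_factory=dict)
    sequence_lengths: dict[str, int] = field(default_factory=dict)

    @property
    def n_distinct(self) -> int:
        return int(self.codes.size)


def _iter_named(sequences) -> Iterable[tuple[str, str]]:
    if isinstance(sequences, Mapping):
        return sequences.items()
    return sequences


def build_kmer_index(
    sequences,
    k: int = 15,
    label: str = "assembly",
    per_sequence: bool = False,
) -> KmerIndex:
    """Index the canonical k-mers of a set of sequences.

    ``sequences`` is a mapping name -> sequence (or an iterable of pairs).
    Windows containing non-ACGT symbols are excluded.  Counts are total
    occurrences over all sequences (both strands collapsed to the canonical
    form).  Read sets are indexed the same way as assemblies; only the label
    differs.
    """
    if not 2 <= k <= 31:
        raise ValueError(f"k must be in [2, 31], got {k}")
    chunks: list[np.ndarray] = []
    per_seq: dict[str, np.ndarray] | None = {} if per_sequence else None
    n_windows: dict[str, int] = {}
    lengths: dict[str, int] = {}

    if per_sequence:
        for name, seq in _iter_named(sequences):
            arr = encode(seq)
            codes, _ = kmer_codes(arr, k)
            codes = canonical_codes(codes, k)
            chunks.append(codes)
            per_seq[name] = np.unique(codes)
            n_windows[name] = int(codes.size)
            lengths[name] = len(seq)
    else:
        # Concatenate sequences with a separator so short reads are k-merized
        # in a few large vector passes instead of one tiny pass per read.
        buf: list[np.ndarray] = []
        buf_bp = 0
        sep = np.array([255], dtype=np.uint8)
        for name, seq in _iter_named(sequences):
            arr = encode(seq)
            lengths[name] = len(seq)
            buf.append(arr)
            buf.append(sep)
            buf_bp += arr.size + 1
            if buf_bp >= _READ_CHUNK_BP:
                codes, _ = kmer_codes(np.concatenate(buf), k)
                chunks.append(canonical_codes(codes, k))
                buf, buf_bp = [], 0
        if buf:
            codes, _ = kmer_codes(np.concatenate(buf), k)
            chunks.append(canonical_codes(codes, k))

    allc = np.concatenate(chunks) if chunks else np.empty(0, dtype=np.int64)
    codes, counts = np.unique(allc, return_counts=True)
    return KmerIndex(
        k=k,
        label=label,
        codes=codes,
        counts=counts,
        per_sequence=per_seq,
        n_windows=n_windows,
        sequence_lengths=lengths,
    )


def classify_scaffolds(
    assembly: KmerIndex,
    male: KmerIndex,
    female: KmerIndex,
    min_valid: int = 20,
    cutoff: float = 60.0,
    female_min_count: int = 1,
    male_min_count: int = 1,
) -> pd.DataFrame:
    """Per-scaffold YGS classification.

    Returns a DataFrame with one row per assembly scaffold: counts of total,
    single-copy, valid and female-unmatched k-mers, the percentage unmatched,
    and the class label (``Y`` iff pct_unmatched >= cutoff, ``unclassified``
    iff fewer than ``min_valid`` valid single-copy k-mers).
    """
    if assembly.per_sequence is None:
        raise ValueError("assembly index must be built with per_sequence=True")
    if not (assembly.k == male.k == female.k):
        raise ValueError(
            f"all indexes must share k (got {assembly.k}, {male.k}, {female.k})"
        )
    single_copy = assembly.codes[assembly.counts == 1]
    male_present = male.codes[male.counts >= male_min_count]
    female_present = female.codes[female.counts >= female_min_count]

    rows = []
    for name, codes in assembly.per_sequence.items():
        sc = codes[in_sorted(codes, single_copy)]
        valid = sc[in_sorted(sc, male_present)]
        unmatched = valid[~in_sorted(valid, female_present)]
        n_valid = int(valid.size)
        if n_valid >= min_valid:
            pct = 100.0 * unmatched.size / n_valid
            cls = CLASS_Y if pct >= cutoff else CLASS_XA
        else:
            pct = 100.0 * unmatched.size / n_valid if n_valid else np.nan
            cls = CLASS_UNCLASSIFIED
        rows.append(
            {
                "scaffold_id": name,
                "length_bp": assembly.sequence_lengths[name],
                "n_kmers_total": assembly.n_windows[name],
                "n_single_copy": int(sc.size),
                "n_valid": n_valid,
                "n_unmatched_female": int(unmatched.size),
                "pct_unmatched": pct,
                "class": cls,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class YgsSummary:
    """Per-class scaffold counts and Mbp at one or more cutoffs."""

    totals: pd.DataFrame  # index (cutoff, class), columns n_scaffolds / mbp
    histogram: pd.DataFrame  # 1%-resolution bins of pct_unmatched
    cutoffs: tuple[float, ...]
    min_valid: int

    def y_mbp(self, cutoff: float) -> float:
        try:
            return float(self.totals.loc[(cutoff, CLASS_Y), "mbp"])
        except KeyError:
            return 0.0


def summarize(
    classifications: pd.DataFrame,
    cutoffs: Iterable[float] = (60.0, 80.0),
    min_valid: int = 20,
) -> YgsSummary:
    """Aggregate per-scaffold calls into per-class totals at each cutoff.

    Classes are re-derived from ``pct_unmatched`` and ``n_valid`` so a single
    classification table can be summarized at several cutoffs; Mbp(Y) is
    non-increasing in the cutoff.
    """
    if classifications.empty:
        raise ValueError("no classifications to summarize")
    cutoffs = tuple(cutoffs)
    df = classifications
    parts = []
    for c in cutoffs:
        informative = df["n_valid"] >= min_valid
        cls = np.where(
            ~informative,
            CLASS_UNCLASSIFIED,
            np.where(df["pct_unmatched"] >= c, CLASS_Y, CLASS_XA),
        )
        g = df.assign(cls=cls).groupby("cls", sort=True)
        sub = pd.DataFrame(
            {
                "n_scaffolds": g.size(),
                "mbp": g["length_bp"].sum() / 1e6,
            }
        )
        sub.index = pd.MultiIndex.from_product(
            [[c], sub.index], names=["cutoff", "class"]
        )
        parts.append(sub)
    totals = pd.concat(parts)

    info = df[df["n_valid"] >= min_valid]
    which = np.clip(np.floor(info["pct_unmatched"]).astype(int), 0, 100)
    hist = (
        info.assign(bin=which)
        .groupby("bin")
        .agg(
            n_scaffolds=("scaffold_id", "size"),
            mbp=("length_bp", lambda s: s.sum() / 1e6),
        )
        .reindex(range(101), fill_value=0)
    )
    return YgsSummary(totals=totals, histogram=hist, cutoffs=cutoffs, min_valid=min_valid)
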