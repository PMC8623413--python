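"""Straightforward reference implementations used for cross-validation.

These deliberately share no code with the production paths: the k-mer
reference works on explicit Python sets of k-mer strings (no integer packing,
no numpy), and the parsimony reference enumerates every
(gain branch x loss subset x loss subset) scenario outright.  Both are only
feasible on small inputs, which is exactly their job -- the fast
implementations are checked against them on instances where exhaustive
computation is possible.
"""

from __future__ import annotations

from collections import Counter
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd

from ._encode import revcomp_str


# ---------------------------------------------------------------------------
# k-mer / YGS reference


def kmer_counts_naive(seq: str, k: int) -> dict[str, int]:
    """Canonical k-mer counts by direct window enumeration."""
    counts: Counter[str] = Counter()
    seq = seq.upper()
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if any(c not in "ACGT" for c in w):
            continue
        counts[min(w, revcomp_str(w))] += 1
    return dict(counts)


def _forward_kmer_set(reads: Mapping[str, str], k: int) -> set[str]:
    out: set[str] = set()
    for seq in reads.values():
        seq = seq.upper()
        n = len(seq)
        add = out.add
        for i in range(n - k + 1):
            add(seq[i : i + k])
    # drop windows with ambiguous symbols lazily: they can never equal an
    # ACGT-only query k-mer, so leaving them in the set is harmless
    return out


def _present(kmer: str, forward_set: set[str]) -> bool:
    return kmer in forward_set or revcomp_str(kmer) in forward_set


def ygs_classify_naive(
    scaffolds: Mapping[str, str],
    male_reads: Mapping[str, str],
    female_reads: Mapping[str, str],
    k: int = 15,
    min_valid: int = 20,
    cutoff: float = 60.0,
) -> pd.DataFrame:
    """Set-algebra YGS classification (female presence threshold of one read).

    Assembly-wide canonical counts give the single-copy set; membership in
    the male/female read sets is tested against plain forward-orientation
    string sets in both orientations.
    """
    assembly_counts: Counter[str] = Counter()
    per_scaffold: dict[str, list] = {}
    for name, seq in scaffolds.items():
        c = kmer_counts_naive(seq, k)
        per_scaffold[name] = c
        assembly_counts.update(c)
    single_copy = {w for w, n in assembly_counts.items() if n == 1}
    male_set = _forward_kmer_set(male_reads, k)
    female_set = _forward_kmer_set(female_reads, k)

    rows = []
    for name, seq in scaffolds.items():
        counts = per_scaffold[name]
        sc = set(counts) & single_copy
        valid = {w for w in sc if _present(w, male_set)}
        unmatched = {w for w in valid if not _present(w, female_set)}
        n_valid = len(valid)
        if n_valid >= min_valid:
            pct = 100.0 * len(unmatched) / n_valid
            cls = "Y" if pct >= cutoff else "XA"
        else:
            pct = 100.0 * len(unmatched) / n_valid if n_valid else float("nan")
            cls = "unclassified"
        rows.append(
            {
                "scaffold_id": name,
                "length_bp": len(seq),
                "n_kmers_total": sum(counts.values()),
                "n_single_copy": len(sc),
                "n_valid": n_valid,
                "n_unmatched_female": len(unmatched),
                "pct_unmatched": pct,
                "class": cls,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# parsimony reference: exhaustive scenario enumeration


def parsimony_enumerate(states: Mapping[str, str], tree) -> tuple[int, set[str]]:
    """Exhaustive minimum event count and the set of optimal gain branches.

    Every scenario -- a gain branch, a subset of branches losing the Y copy
    (within the gain clade) and a subset losing the source copy -- is
    evaluated against the leaf states (unknown matches anything).  Feasible
    only for small trees; loss subsets are capped at one branch per leaf,
    which cannot exclude an optimum.
    """
    from .gainloss import edge_labels

    labels = edge_labels(tree)
    leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    leaf_bit = {lf: 1 << i for i, lf in enumerate(leaves)}
    full = (1 << len(leaves)) - 1

    edges = []
    for node in tree.preorder_node_iter():
        mask = 0
        for lf in node.leaf_iter():
            mask |= leaf_bit[lf.taxon.label]
        edges.append((labels[id(node.edge)], mask))

    y_mask = sum(leaf_bit[lf] for lf in leaves if states.get(lf) == "Y")
    xa_mask = sum(leaf_bit[lf] for lf in leaves if states.get(lf) == "XA")
    abs_mask = sum(leaf_bit[lf] for lf in leaves if states.get(lf) == "absent")
    if y_mask == 0:
        raise ValueError("need at least one Y leaf")

    max_losses = len(leaves)
    all_subsets = []
    for r in range(max_losses + 1):
        for combo in combinations(range(len(edges)), r):
            m = 0
            for ci in combo:
                m |= edges[ci][1]
            all_subsets.append((r, m, combo))

    # source-copy feasibility is independent of the gain branch; subsets are
    # enumerated in increasing size, so the first feasible one is minimal
    min_src = None
    for ns, src_lost, _ in all_subsets:
        p_src = full & ~src_lost
        if xa_mask & ~p_src or (y_mask | abs_mask) & p_src:
            continue
        min_src = ns
        break
    if min_src is None:
        raise ValueError("states admit no source-loss assignment")

    best_cost = None
    best_edges: set[str] = set()
    for gain_label, clade in edges:
        if y_mask & ~clade:
            continue
        for ny, y_lost, combo in all_subsets:
            if any(edges[ci][1] & ~clade for ci in combo):
                continue
            p_y = clade & ~y_lost
            if y_mask & ~p_y or (xa_mask | abs_mask) & p_y:
                continue
            cost = 1 + ny + min_src
            if best_cost is None or cost < best_cost:
                best_cost = cost
                best_edges = {gain_label}
            elif cost == best_cost:
                best_edges.add(gain_label)
            break  # increasing subset size: first feasible is minimal
    return best_cost, best_edges


# ---------------------------------------------------------------------------
# depth reference


def depth_naive(placements: pd.DataFrame, length: int, read_length: int) -> np.ndarray:
    """Per-base depth by per-read interval painting."""
    depth = np.zeros(length, dtype=np.int64)
    for row in placements.itertuples(index=False):
        depth[row.start : min(row.start + read_length, length)] += 1
    return depth
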