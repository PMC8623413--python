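"""End-to-end synthetic validation studies.

Each study builds a synthetic data set with known truth, runs the relevant
pipeline stage, and measures recovery.  The study conditions (genome sizes,
depths, rates, replicate counts) are fixed here as the package's reference
validation settings; the seed only moves the random draws.

Studies:

* ``ygs_synthetic_study`` -- a ~2.2 Mbp genome (20 autosomal + 10 Y
  scaffolds, shared repeats) with error-free 10x sexed reads; measures
  classification accuracy against truth and agreement of the unmatched
  percentages with the explicit string-set reference implementation.
* ``segdup_recovery_study`` -- a 10-copy, 200 kb duplication implanted into
  the Y of a 1 Mbp autosomal scaffold, 20x reads; measures boundary error
  (bins) and the copy-number estimate.
* ``gene_fate_recovery_study`` -- intact, stop-disrupted, frameshifted and
  expression-silenced gene copies; measures fate recovery.
* ``parsimony_enumeration_study`` -- every leaf-state pattern on a 4-leaf
  tree; measures agreement of the acquisition branch with exhaustive
  enumeration.
* ``gainloss_recovery_study`` -- 200 simulated gain/loss histories at true
  ratio 10; measures the median ratio estimate and 95% CI coverage.
"""

from __future__ import annotations

from itertools import product

import numpy as np

from . import covdup, genefate, reference, ygs
from .gainloss import estimate_ratio, infer_acquisition_branch
from .io import tree_from_newick
from .simdata import (
    GenomeSpec,
    ReadSimConfig,
    implant_segdup,
    pseudogenize,
    random_cds,
    simulate_event_history,
    simulate_genome,
    simulate_reads,
)


def _child_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


# ---------------------------------------------------------------------------


def ygs_synthetic_study(seed: int = 0) -> dict:
    """Scaffold classification accuracy and oracle agreement on a ~2.2 Mbp genome."""
    s_genome, s_male, s_female = _child_seeds(seed, 3)
    spec = GenomeSpec(
        n_autosomal_scaffolds=20,
        n_y_scaffolds=10,
        scaffold_length_bp=75_000,
        repeat_fraction=0.10,
        gc=0.45,
        seed=s_genome,
    )
    scaffolds, truth = simulate_genome(spec)
    male_reads, _ = simulate_reads(
        scaffolds, truth, ReadSimConfig(sex="male", depth=10, seed=s_male)
    )
    female_reads, _ = simulate_reads(
        scaffolds, truth, ReadSimConfig(sex="female", depth=10, seed=s_female)
    )

    assembly_idx = ygs.build_kmer_index(scaffolds, k=15, per_sequence=True)
    male_idx = ygs.build_kmer_index(male_reads, k=15, label="male_reads")
    female_idx = ygs.build_kmer_index(female_reads, k=15, label="female_reads")
    calls = ygs.classify_scaffolds(assembly_idx, male_idx, female_idx)

    informative = calls[calls["n_valid"] >= 20]
    correct = int(
        (
            informative["class"]
            == informative["scaffold_id"].map(truth.scaffold_class)
        ).sum()
    )
    accuracy_pct = 100.0 * correct / len(informative)

    oracle = reference.ygs_classify_naive(scaffolds, male_reads, female_reads, k=15)
    merged = calls.merge(oracle, on="scaffold_id", suffixes=("", "_oracle"))
    dev = (merged["pct_unmatched"] - merged["pct_unmatched_oracle"]).abs()
    max_dev = float(dev.max())

    true_y_mbp = sum(
        len(scaffolds[n]) for n, c in truth.scaffold_class.items() if c == "Y"
    ) / 1e6
    called_y_mbp = calls.loc[calls["class"] == "Y", "length_bp"].sum() / 1e6
    return {
        "accuracy_pct": accuracy_pct,
        "n_informative": int(len(informative)),
        "n_scaffolds": int(len(calls)),
        "max_pct_dev_from_oracle": max_dev,
        "genome_mbp": sum(len(s) for s in scaffolds.values()) / 1e6,
        "true_y_mbp": true_y_mbp,
        "called_y_mbp": float(called_y_mbp),
        "y_mbp_error_pct": float(100.0 * abs(called_y_mbp - true_y_mbp) / true_y_mbp),
    }


# ---------------------------------------------------------------------------


SEGDUP_TRUE_COPIES = 10
SEGDUP_INTERVAL = (400_000, 600_000)
SEGDUP_BIN_BP = 1000


def segdup_recovery_study(seed: int = 0) -> dict:
    """Boundary and copy-number recovery for an implanted 10-copy, 200 kb duplication."""
    s_genome, s_dup, s_male, s_female = _child_seeds(seed, 4)
    spec = GenomeSpec(
        n_autosomal_scaffolds=1,
        n_y_scaffolds=0,
        scaffold_length_bp=1_000_000,
        repeat_fraction=0.0,
        gc=0.45,
        seed=s_genome,
    )
    source, truth = simulate_genome(spec)
    src_name = next(iter(source))
    start, end = SEGDUP_INTERVAL
    genome, truth = implant_segdup(
        source, (src_name, start, end), n_copies=SEGDUP_TRUE_COPIES, seed=s_dup,
        truth=truth,
    )
    male_reads, _ = simulate_reads(
        genome, truth, ReadSimConfig(sex="male", depth=20, seed=s_male)
    )
    female_reads, _ = simulate_reads(
        genome, truth, ReadSimConfig(sex="female", depth=20, seed=s_female)
    )

    placements_m, _ = covdup.place_reads(male_reads, source)
    placements_f, _ = covdup.place_reads(female_reads, source)
    lengths = {src_name: len(source[src_name])}
    depth_m = covdup.depth_from_placements(placements_m, lengths, 100)
    depth_f = covdup.depth_from_placements(placements_f, lengths, 100)
    bins = covdup.bin_depth(depth_m, depth_f, bin_bp=SEGDUP_BIN_BP)
    mb, fb = covdup.autosomal_baseline(bins, [src_name])
    track = covdup.normalize(bins, mb, fb)
    calls = covdup.call_segdups(track)

    if len(calls) != 1:
        return {
            "n_calls": int(len(calls)),
            "boundary_error_bins": float("inf"),
            "est_copies": 0,
            "true_copies": SEGDUP_TRUE_COPIES,
        }
    call = calls.iloc[0]
    boundary_error_bins = max(
        abs(call["start"] - start), abs(call["end"] - end)
    ) / SEGDUP_BIN_BP
    return {
        "n_calls": 1,
        "boundary_error_bins": float(boundary_error_bins),
        "est_copies": int(call["est_copies"]),
        "true_copies": SEGDUP_TRUE_COPIES,
        "copy_error": abs(int(call["est_copies"]) - SEGDUP_TRUE_COPIES),
        "mean_male_norm": float(call["mean_male_norm"]),
    }


# ---------------------------------------------------------------------------


def gene_fate_recovery_study(seed: int = 0, n_genes: int = 32) -> dict:
    """Recovery of intact vs synthetically disabled gene copies.

    Each gene copy receives exactly one kind of defect (premature stop,
    frame-disrupting indel, or expression silencing) or none; a copy is truly
    a pseudogene iff it has a defect.  Recovery is the fraction of copies
    whose classified fate matches that truth.
    """
    seeds = _child_seeds(seed, n_genes * 2)
    kinds = ["intact", "stop", "frameshift", "silenced"]
    n_correct = 0
    for i in range(n_genes):
        kind = kinds[i % len(kinds)]
        n_codons = 100 + (seeds[i] % 150)
        ref = random_cds(n_codons, seed=seeds[i])
        share = 0.5
        if kind == "intact":
            cand = ref
        elif kind == "silenced":
            cand = ref
            share = 0.03
        else:
            stop_rate = 0.02 if kind == "stop" else 0.0
            fs_rate = 0.02 if kind == "frameshift" else 0.0
            attempt = 0
            while True:
                cand, events = pseudogenize(
                    ref, stop_rate=stop_rate, frameshift_rate=fs_rate,
                    seed=seeds[n_genes + i] + attempt,
                )
                if kind == "stop" and events:
                    break
                if kind == "frameshift" and events:
                    net = sum(
                        1 if e[0] == "frameshift_insertion" else -1 for e in events
                    )
                    if net % 3 != 0:
                        break
                attempt += 1
        integrity = genefate.check_cds_integrity(cand, ref)
        fate = genefate.classify_fate(f"gene_{i}", integrity, share)
        expected = genefate.FUNCTIONAL if kind == "intact" else genefate.PSEUDOGENE
        n_correct += fate.status == expected
    return {
        "recovery_pct": 100.0 * n_correct / n_genes,
        "n_genes": n_genes,
    }


# ---------------------------------------------------------------------------


PARSIMONY_TREE = "((A:1.0,B:1.0):1.0,(C:1.0,D:1.0):1.0);"


def parsimony_enumeration_study() -> dict:
    """Agreement of the parsimony mapper with exhaustive enumeration.

    Runs every assignment of {Y, XA, absent, unknown} to the four leaves of a
    balanced tree (patterns with at least one Y leaf) and checks that the
    fast mapper finds the same minimal cost and the same set of optimal
    acquisition branches as brute-force scenario enumeration.
    """
    tree = tree_from_newick(PARSIMONY_TREE)
    leaves = ["A", "B", "C", "D"]
    n_patterns = 0
    n_agree = 0
    for combo in product(["Y", "XA", "absent", "unknown"], repeat=4):
        states = dict(zip(leaves, combo))
        if "Y" not in combo:
            continue
        n_patterns += 1
        sc = infer_acquisition_branch(states, tree)
        best_cost, best_edges = reference.parsimony_enumerate(states, tree)
        impl_edges = {sc.gain_edge} | set(sc.tied_gain_edges)
        if sc.cost == best_cost and impl_edges == best_edges:
            n_agree += 1
    return {
        "agreement_pct": 100.0 * n_agree / n_patterns,
        "n_patterns": n_patterns,
    }


# ---------------------------------------------------------------------------


GAINLOSS_TREE = "((((A:5,B:5):5,C:10):5,D:15):5,E:20);"
GAINLOSS_TRUE_RATIO = 10.0
GAINLOSS_GAIN_RATE = 0.5  # gains per My of branch time
GAINLOSS_LOSS_RATE = 0.05  # losses per gene-My of Y-residency


GAINLOSS_MIN_EVENTS = 30


def gainloss_recovery_study(seed: int = 0, n_replicates: int = 200) -> dict:
    """Ratio recovery and CI coverage over simulated event histories.

    Histories are conditioned on carrying at least ``GAINLOSS_MIN_EVENTS``
    events (gains + losses) by redrawing, so every replicate is informative
    enough for the asymptotic test and interval to apply.
    """
    tree = tree_from_newick(GAINLOSS_TREE)
    seeds = _child_seeds(seed, n_replicates)
    ratios, covered, events = [], [], []
    for s in seeds:
        for attempt in range(1000):
            emap, _ = simulate_event_history(
                tree, GAINLOSS_GAIN_RATE, GAINLOSS_LOSS_RATE, seed=(s + attempt) % 2**31
            )
            G, L, _, _ = emap.totals()
            if G + L >= GAINLOSS_MIN_EVENTS:
                break
        est = estimate_ratio(emap)
        G, L, _, _ = emap.totals()
        events.append(G + L)
        ratios.append(est.ratio_hat)
        covered.append(est.ci_low <= GAINLOSS_TRUE_RATIO <= est.ci_high)
    return {
        "median_ratio_hat": float(np.median(ratios)),
        "ci_coverage": float(np.mean(covered)),
        "median_events": float(np.median(events)),
        "min_events": int(np.min(events)),
        "n_replicates": n_replicates,
        "true_ratio": GAINLOSS_TRUE_RATIO,
    }
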