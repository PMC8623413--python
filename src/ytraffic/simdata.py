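"""Synthetic genomes, sexed read sets, implanted duplications and event histories.

Every generator is a pure function of its inputs and a seed, and emits a
ground-truth record alongside its output, so that each downstream stage
(scaffold classification, duplication calling, gene-fate calling, gain-loss
estimation) can be tested for parameter recovery without any external data.

The genome generator emulates the situation the pipeline targets: an assembly
with autosomal/X scaffolds and Y scaffolds, where the Y is absent from female
reads and hemizygous (half depth) in male reads, and where a planted repeat
library is shared between the two classes so that single-copy k-mer filtering
is actually exercised.  Background sequence is i.i.d. nucleotides at the
configured GC; outside planted repeats, Y background is regenerated wherever a
canonical k-mer would collide with the autosomal scaffolds, so that with
``repeat_fraction=0`` the two classes share no k-mer at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._encode import canonical_codes, decode, encode, in_sorted, kmer_codes

STOP_CODONS = ("TAA", "TAG", "TGA")


# ---------------------------------------------------------------------------
# specs and truth containers


@dataclass(frozen=True)
class GenomeSpec:
    """Parameters of a synthetic assembly.

    ``unique_k`` is the k at which cross-class (Y vs autosomal) background
    k-mer disjointness is enforced; it should match the k used downstream.
    """

    n_autosomal_scaffolds: int
    n_y_scaffolds: int
    scaffold_length_bp: int
    repeat_fraction: float = 0.0
    gc: float = 0.5
    seed: int = 0
    unique_k: int = 15

    def __post_init__(self):
        if self.n_autosomal_scaffolds < 0 or self.n_y_scaffolds < 0:
            raise ValueError("scaffold counts must be non-negative")
        if self.n_autosomal_scaffolds + self.n_y_scaffolds == 0:
            raise ValueError("at least one scaffold must be requested")
        if self.scaffold_length_bp <= 0:
            raise ValueError("scaffold_length_bp must be positive")
        for name in ("repeat_fraction", "gc"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class ReadSimConfig:
    """Single-end read simulation for one sexed (or pooled) library.

    Autosomal scaffolds are sampled at ``depth``-fold coverage.  Y scaffolds
    are hemizygous, so their expected coverage is ``depth * male_fraction / 2``:
    0 for a female library, ``depth/2`` for a male one, and e.g. 8.4x total
    from an unsexed 50/50 pool gives the Y 2.1x.
    """

    sex: str
    depth: float
    read_length: int = 100
    error_rate: float = 0.0
    seed: int = 0
    male_fraction: float | None = None  # override for pooled-sex libraries

    def __post_init__(self):
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        if not 0.0 <= self.error_rate <= 0.1:
            raise ValueError("error_rate must be in [0, 0.1]")
        if self.male_fraction is not None and not 0.0 <= self.male_fraction <= 1.0:
            raise ValueError("male_fraction must be in [0, 1]")

    @property
    def effective_male_fraction(self) -> float:
        if self.male_fraction is not None:
            return self.male_fraction
        return 1.0 if self.sex == "male" else 0.0


@dataclass
class SegDupTruth:
    source_scaffold: str
    start: int
    end: int
    n_copies: int
    copy_scaffolds: list[str]
    events: list[list[tuple]]  # per copy: (kind, position, detail)


@dataclass
class SyntheticTruth:
    """Ground-truth sidecar for a simulated data set.

    Truth is never encoded in sequence headers that downstream stages read;
    it travels in this object (or its TSV serialization).
    """

    scaffold_class: dict[str, str] = field(default_factory=dict)
    repeat_intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    segdups: list[SegDupTruth] = field(default_factory=list)
    gene_fates: dict[str, str] = field(default_factory=dict)

    def scaffold_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"scaffold_id": list(self.scaffold_class), "true_class": list(self.scaffold_class.values())}
        )


# ---------------------------------------------------------------------------
# genome


def _random_background(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p).astype(np.uint8)


def simulate_genome(spec: GenomeSpec) -> tuple[dict[str, str], SyntheticTruth]:
    """Generate labeled scaffolds plus their truth table.

    Returns (scaffolds, truth) where scaffolds maps neutral ids
    (``scaffold_0001`` ...) to sequences and truth carries the Y/XA labels and
    planted-repeat intervals.  Same spec (same seed) gives byte-identical
    output.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_autosomal_scaffolds + spec.n_y_scaffolds
    labels = np.array(["XA"] * spec.n_autosomal_scaffolds + ["Y"] * spec.n_y_scaffolds)
    labels = labels[rng.permutation(n)]
    names = [f"scaffold_{i + 1:04d}" for i in range(n)]

    L = spec.scaffold_length_bp
    # Planted repeat library, shared between classes (lengths aimed at the
    # 0.5-5 kb range, capped for small test scaffolds).
    repeats: list[np.ndarray] = []
    if spec.repeat_fraction > 0:
        lo = min(500, max(20, L // 20))
        hi = max(lo + 1, min(5000, L // 4))
        for _ in range(6):
            rlen = int(rng.integers(lo, hi + 1))
            repeats.append(_random_background(rng, rlen, spec.gc))

    arrays: dict[str, np.ndarray] = {}
    repeat_intervals: dict[str, list[tuple[int, int]]] = {}
    for name in names:
        arr = _random_background(rng, L, spec.gc)
        ivs: list[tuple[int, int]] = []
        planted = 0
        while repeats and planted < spec.repeat_fraction * L:
            rep = repeats[int(rng.integers(len(repeats)))]
            if rep.size >= L:
                break
            pos = int(rng.integers(0, L - rep.size + 1))
            arr[pos : pos + rep.size] = rep
            ivs.append((pos, pos + rep.size))
            planted += rep.size
        arrays[name] = arr
        repeat_intervals[name] = ivs

    _enforce_cross_class_disjointness(arrays, labels, names, repeat_intervals, spec, rng)

    scaffolds = {name: decode(arrays[name]) for name in names}
    truth = SyntheticTruth(
        scaffold_class={name: str(lab) for name, lab in zip(names, labels)},
        repeat_intervals=repeat_intervals,
    )
    return scaffolds, truth


def _enforce_cross_class_disjointness(arrays, labels, names, repeat_intervals, spec, rng):
    """Re-randomize Y background bases whose k-mers collide with XA scaffolds.

    Windows overlapping a planted repeat are exempt (repeats are intentionally
    shared).  With repeat_fraction=0 this guarantees that no canonical k-mer of
    any Y scaffold occurs on any autosomal scaffold.
    """
    k = spec.unique_k
    xa_codes = []
    for name, lab in zip(names, labels):
        if lab == "XA":
            codes, _ = kmer_codes(arrays[name], k)
            xa_codes.append(canonical_codes(codes, k))
    if not xa_codes:
        return
    xa_set = np.unique(np.concatenate(xa_codes))
    for name, lab in zip(names, labels):
        if lab != "Y":
            continue
        arr = arrays[name]
        exempt = np.zeros(arr.size, dtype=bool)
        for s, e in repeat_intervals[name]:
            # any window touching a repeat base is exempt
            exempt[max(0, s - k + 1) : e] = True
        for _ in range(100):
            codes, starts = kmer_codes(arr, k)
            bad = starts[in_sorted(canonical_codes(codes, k), xa_set) & ~exempt[starts]]
            if bad.size == 0:
                break
            for s in np.unique(bad):
                old = arr[s + k - 1]
                arr[s + k - 1] = (old + rng.integers(1, 4)) % 4
        else:  # pragma: no cover - would need adversarial inputs
            raise RuntimeError("could not de-collide Y background k-mers")


# ---------------------------------------------------------------------------
# reads


def simulate_reads(
    scaffolds: Mapping[str, str],
    truth: SyntheticTruth,
    config: ReadSimConfig,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Sample single-end reads with per-class coverage and i.i.d. errors.

    Returns (reads, provenance); provenance is a DataFrame (read_id, scaffold,
    start, strand) recording where each read was sampled -- ground truth for
    depth and placement tests, never consumed by the classifiers themselves.
    """
    if not scaffolds:
        raise ValueError("empty scaffold set")
    rng = np.random.default_rng(config.seed)
    rl = config.read_length
    mf = config.effective_male_fraction

    reads: dict[str, str] = {}
    prov_rows = []
    counter = 0
    for name, seq in scaffolds.items():
        cls = truth.scaffold_class.get(name, "XA")
        cov = config.depth if cls == "XA" else config.depth * mf / 2.0
        if cov <= 0:
            continue
        if len(seq) < rl:
            raise ValueError(f"read_length {rl} exceeds scaffold {name} length {len(seq)}")
        arr = encode(seq)
        n_reads = int(rng.poisson(cov * len(seq) / rl))
        if n_reads == 0:
            continue
        starts = rng.integers(0, len(seq) - rl + 1, size=n_reads)
        mat = arr[starts[:, None] + np.arange(rl)]
        strands = rng.integers(0, 2, size=n_reads)  # 0 = +, 1 = -
        rev = strands == 1
        mat[rev] = 3 - mat[rev][:, ::-1]
        if config.error_rate > 0:
            err = rng.random(mat.shape) < config.error_rate
            shift = rng.integers(1, 4, size=mat.shape).astype(np.uint8)
            mat[err] = (mat[err] + shift[err]) % 4
        for i in range(n_reads):
            rid = f"r{counter:08d}"
            counter += 1
            reads[rid] = decode(mat[i])
            prov_rows.append((rid, name, int(starts[i]), "-" if rev[i] else "+"))
    provenance = pd.DataFrame(prov_rows, columns=["read_id", "scaffold", "start", "strand"])
    return reads, provenance


# ---------------------------------------------------------------------------
# segmental duplication implanting


def _mutate_copy(
    arr: np.ndarray,
    divergence: float,
    indel_rate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[tuple]]:
    events: list[tuple] = []
    out = arr.copy()
    if divergence > 0:
        n_sub = rng.binomial(out.size, divergence)
        pos = rng.choice(out.size, size=n_sub, replace=False)
        for p in np.sort(pos):
            old = int(out[p])
            new = (old + int(rng.integers(1, 4))) % 4
            out[p] = new
            events.append(("substitution", int(p), (old, new)))
    if indel_rate > 0:
        n_ind = rng.binomial(out.size, indel_rate)
        pos = np.sort(rng.choice(out.size, size=n_ind, replace=False))[::-1]
        segments = out
        for p in pos:
            if rng.random() < 0.5:
                segments = np.delete(segments, p)
                events.append(("deletion", int(p), 1))
            else:
                base = np.uint8(rng.integers(4))
                segments = np.insert(segments, p, base)
                events.append(("insertion", int(p), 1))
        out = segments
    return out, events


def implant_segdup(
    scaffolds: Mapping[str, str],
    source_interval: tuple[str, int, int],
    n_copies: int,
    per_copy_divergence: float = 0.0,
    indel_rate: float = 0.0,
    seed: int = 0,
    truth: SyntheticTruth | None = None,
) -> tuple[dict[str, str], SyntheticTruth]:
    """Append mutated copies of a source interval as new Y scaffolds.

    Each copy receives independent point divergence and 1-bp indels at the
    stated per-base rates; the truth record stores the copy count and the full
    mutation event lists.  With zero rates the copies are byte-identical to
    the source interval (sequence content is conserved exactly).
    """
    scaffold, start, end = source_interval
    if scaffold not in scaffolds:
        raise ValueError(f"unknown scaffold {scaffold!r}")
    seq = scaffolds[scaffold]
    if not (0 <= start < end <= len(seq)):
        raise ValueError(f"interval [{start}, {end}) outside scaffold of length {len(seq)}")
    if n_copies < 1:
        raise ValueError("n_copies must be >= 1")

    rng = np.random.default_rng(seed)
    src = encode(seq[start:end])
    out = dict(scaffolds)
    truth = truth if truth is not None else SyntheticTruth(
        scaffold_class={name: "XA" for name in scaffolds}
    )
    copy_names: list[str] = []
    all_events: list[list[tuple]] = []
    base = len(out)
    for i in range(n_copies):
        copy_arr, events = _mutate_copy(src, per_copy_divergence, indel_rate, rng)
        name = f"scaffold_{base + i + 1:04d}"
        out[name] = decode(copy_arr)
        truth.scaffold_class[name] = "Y"
        copy_names.append(name)
        all_events.append(events)
    truth.segdups.append(
        SegDupTruth(
            source_scaffold=scaffold,
            start=start,
            end=end,
            n_copies=n_copies,
            copy_scaffolds=copy_names,
            events=all_events,
        )
    )
    return out, truth


# ---------------------------------------------------------------------------
# CDS generation and pseudogenization


def random_cds(n_codons: int, seed: int = 0, gc: float = 0.5) -> str:
    """A random CDS: ATG start, no internal stops, one terminal stop codon."""
    if n_codons < 3:
        raise ValueError("need at least 3 codons (start, one internal, stop)")
    rng = np.random.default_rng(seed)
    codons = ["ATG"]
    alphabet = "ACGT"
    while len(codons) < n_codons - 1:
        c = "".join(alphabet[int(b)] for b in _random_background(rng, 3, gc))
        if c not in STOP_CODONS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def pseudogenize(
    cds: str,
    stop_rate: float = 0.0,
    frameshift_rate: float = 0.0,
    seed: int = 0,
) -> tuple[str, list[tuple]]:
    """Disable a CDS with premature stops and/or 1-bp frameshifting indels.

    Rates are per internal codon (start and terminal stop codons are exempt).
    Returns the mutated sequence and the event list; with both rates zero the
    input is returned unchanged.
    """
    if len(cds) < 6:
        raise ValueError("CDS shorter than 6 nt")
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    if not cds.upper().startswith("ATG"):
        raise ValueError("CDS must start with ATG")
    rng = np.random.default_rng(seed)
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    n = len(codons)
    events: list[tuple] = []
    for idx in range(1, n - 1):
        if rng.random() < stop_rate:
            codons[idx] = "TAA"
            events.append(("premature_stop", idx))
    indels: list[tuple[int, str]] = []
    for idx in range(1, n - 1):
        if rng.random() < frameshift_rate:
            kind = "deletion" if rng.random() < 0.5 else "insertion"
            indels.append((idx, kind))
            events.append((f"frameshift_{kind}", idx))
    seq = "".join(codons)
    for idx, kind in sorted(indels, reverse=True):
        p = 3 * idx
        if kind == "deletion":
            seq = seq[:p] + seq[p + 1 :]
        else:
            seq = seq[:p] + "ACGT"[int(rng.integers(4))] + seq[p:]
    return seq, events


# ---------------------------------------------------------------------------
# gain/loss event histories on a tree


def simulate_event_history(
    tree,
    gain_rate: float,
    loss_rate: float,
    seed: int = 0,
    ancestral_genes: Sequence[str] = (),
):
    """Simulate Y-gene gains and losses along a dated species tree.

    Gains arrive per branch as Poisson(gain_rate x branch length, in My);
    each resident gene is lost at rate ``loss_rate`` per gene-My of
    Y-residency, independently in each descendant lineage after a split.
    Returns (EventMap, truth) where the event map records per-branch events
    and exposures (branch time for gains, gene-My of residency for losses),
    and truth stores the generating rates and per-leaf presence.
    """
    from .gainloss import EventMap, edge_labels

    if gain_rate < 0 or loss_rate < 0:
        raise ValueError("rates must be non-negative")
    rng = np.random.default_rng(seed)
    labels = edge_labels(tree)
    gains: dict[str, list[str]] = {lab: [] for lab in labels.values()}
    losses: dict[str, list[str]] = {lab: [] for lab in labels.values()}
    gain_exposure: dict[str, float] = {}
    loss_exposure: dict[str, float] = {lab: 0.0 for lab in labels.values()}
    leaf_presence: dict[str, set[str]] = {
        lf.taxon.label: set() for lf in tree.leaf_node_iter()
    }

    def descend(gene: str, node, offset: float):
        """Propagate a resident gene from `offset` along the edge above `node`."""
        edge = node.edge
        lab = labels[id(edge)]
        elen = edge.length or 0.0
        remaining = elen - offset
        t_loss = rng.exponential(1.0 / loss_rate) if loss_rate > 0 else np.inf
        if t_loss < remaining:
            loss_exposure[lab] += t_loss
            losses[lab].append(gene)
            return
        loss_exposure[lab] += remaining
        if node.is_leaf():
            leaf_presence[node.taxon.label].add(gene)
        else:
            for child in node.child_nodes():
                descend(gene, child, 0.0)

    counter = 0
    for node in tree.preorder_node_iter():
        edge = node.edge
        lab = labels[id(edge)]
        elen = edge.length or 0.0
        gain_exposure[lab] = elen
        n_gains = rng.poisson(gain_rate * elen) if elen > 0 else 0
        for _ in range(n_gains):
            gene = f"g{counter:04d}"
            counter += 1
            t = float(rng.uniform(0.0, elen))
            gains[lab].append(gene)
            # residency on the gain branch starts at the gain time
            edge_remaining = elen - t
            t_loss = rng.exponential(1.0 / loss_rate) if loss_rate > 0 else np.inf
            if t_loss < edge_remaining:
                loss_exposure[lab] += t_loss
                losses[lab].append(gene)
                continue
            loss_exposure[lab] += edge_remaining
            if node.is_leaf():
                leaf_presence[node.taxon.label].add(gene)
            else:
                for child in node.child_nodes():
                    descend(gene, child, 0.0)

    for gene in ancestral_genes:
        root = tree.seed_node
        if root.is_leaf():
            leaf_presence[root.taxon.label].add(gene)
        else:
            for child in root.child_nodes():
                descend(gene, child, 0.0)

    emap = EventMap(
        tree=tree,
        gains=gains,
        losses=losses,
        gain_exposure=gain_exposure,
        loss_exposure=loss_exposure,
    )
    truth = {
        "gain_rate": gain_rate,
        "loss_rate": loss_rate,
        "ratio": gain_rate / loss_rate if loss_rate > 0 else np.inf,
        "n_gains": sum(len(v) for v in gains.values()),
        "n_losses": sum(len(v) for v in losses.values()),
        "leaf_presence": leaf_presence,
    }
    return emap, truth
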