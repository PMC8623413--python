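"""Autosome-to-Y segmental duplication detection from sexed read depth.

A region of an autosomal scaffold that has been copied (possibly many times)
into the Y chromosome shows excess *male* read depth -- every Y copy adds
reads that pile onto the single assembled source locus -- while female depth
stays at the diploid baseline.  With depths normalized to the autosomal
diploid baseline, one hemizygous Y copy adds 0.5 to the male track, so n Y
copies give a normalized male depth of about 1 + n/2.

The module bins per-base depth (1 kb bins by default), normalizes each sex to
its autosomal baseline, calls maximal elevated runs as duplications, inverts
the 1 + n/2 relation for copy number, and counts male-specific SNP sites
(alleles carried by male reads and entirely absent from female reads) that
diverged Y copies leave in the pileup.

Reads are never aligned externally: depth comes either from per-base depth
tables produced by standard tools, or from the internal exact-match placement
of error-free synthetic reads.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from ._encode import encode, kmer_codes

_PLACE_K = 31


# ---------------------------------------------------------------------------
# read placement and depth


def place_reads(
    reads: Mapping[str, str],
    reference: Mapping[str, str],
) -> tuple[pd.DataFrame, int]:
    """Exact-match placement of error-free reads on a reference.

    Each read (or its reverse complement) is located by its first 31-mer and
    verified by full comparison against the reference; when a read matches at
    several positions the first in reference order wins.  Reads must share
    one length.  Returns (placements, n_unplaced) with placement columns
    read_id / scaffold / start / strand.
    """
    names = list(reference)
    # concatenated reference with separators; separators can never match a
    # read base, so matches cannot straddle scaffold boundaries
    sep = np.array([255], dtype=np.uint8)
    parts, offsets = [], []
    off = 0
    for name in names:
        arr = encode(reference[name])
        offsets.append(off)
        parts.append(arr)
        parts.append(sep)
        off += arr.size + 1
    ref_cat = np.concatenate(parts)
    offsets = np.array(offsets + [off], dtype=np.int64)
    codes, starts = kmer_codes(ref_cat, _PLACE_K)
    order = np.argsort(codes, kind="stable")
    codes, starts = codes[order], starts[order]

    read_ids = list(reads)
    if not read_ids:
        return pd.DataFrame(columns=["read_id", "scaffold", "start", "strand"]), 0
    rl = len(reads[read_ids[0]])
    if any(len(reads[r]) != rl for r in read_ids):
        raise ValueError("place_reads expects fixed-length reads")
    mat = encode("".join(reads[r] for r in read_ids)).reshape(len(read_ids), rl)
    if rl < _PLACE_K:
        raise ValueError(f"reads shorter than the {_PLACE_K} bp seed")
    rc_mat = (np.uint8(3) - mat[:, ::-1]).astype(np.uint8)
    rc_mat[mat[:, ::-1] > 3] = 255

    def first_codes(m):
        c = np.zeros(m.shape[0], dtype=np.int64)
        for j in range(_PLACE_K):
            c |= np.where(m[:, j] < 4, m[:, j], 0).astype(np.int64) << (
                2 * (_PLACE_K - 1 - j)
            )
        return c, (m[:, :_PLACE_K] < 4).all(axis=1)

    fwd_codes, fwd_ok = first_codes(mat)
    rev_codes, rev_ok = first_codes(rc_mat)

    placed_pos = np.full(len(read_ids), -1, dtype=np.int64)
    placed_strand = np.zeros(len(read_ids), dtype=np.uint8)

    span = np.arange(rl)

    def try_place(query_mat, qcodes, qok, shift, strand_code):
        lo = np.searchsorted(codes, qcodes, side="left")
        hi = np.searchsorted(codes, qcodes, side="right")
        todo = np.nonzero(qok & (hi > lo) & (placed_pos < 0))[0]
        # fast path: unique candidate, vectorized verification
        uniq = todo[(hi[todo] - lo[todo]) == 1]
        if uniq.size:
            pos = starts[lo[uniq]] - shift
            valid = (pos >= 0) & (pos + rl <= ref_cat.size)
            uniq, pos = uniq[valid], pos[valid]
            segs = ref_cat[pos[:, None] + span]
            hitm = (segs == query_mat[uniq]).all(axis=1)
            placed_pos[uniq[hitm]] = pos[hitm]
            placed_strand[uniq[hitm]] = strand_code
        # slow path: several candidates
        multi = todo[(hi[todo] - lo[todo]) > 1]
        for i in multi:
            q = query_mat[i]
            best = -1
            for j in range(lo[i], hi[i]):
                p = starts[j] - shift
                if p < 0 or p + rl > ref_cat.size:
                    continue
                if np.array_equal(ref_cat[p : p + rl], q):
                    if best < 0 or p < best:
                        best = p
            if best >= 0:
                placed_pos[i] = best
                placed_strand[i] = strand_code

    try_place(mat, fwd_codes, fwd_ok, 0, 0)
    # a reverse-strand read r matches where revcomp(r) occurs; the first
    # 31-mer of revcomp(r) starts at that occurrence
    try_place(rc_mat, rev_codes, rev_ok, 0, 1)

    hit = placed_pos >= 0
    scaf_idx = np.searchsorted(offsets, placed_pos[hit], side="right") - 1
    local = placed_pos[hit] - offsets[scaf_idx]
    ids = np.array(read_ids, dtype=object)
    placements = pd.DataFrame(
        {
            "read_id": ids[hit],
            "scaffold": np.array(names, dtype=object)[scaf_idx],
            "start": local,
            "strand": np.where(placed_strand[hit] == 0, "+", "-"),
        }
    )
    return placements, int((~hit).sum())


def depth_from_placements(
    placements: pd.DataFrame,
    scaffold_lengths: Mapping[str, int],
    read_length: int,
) -> dict[str, np.ndarray]:
    """Per-base depth arrays from read placements (difference-array trick)."""
    out = {
        name: np.zeros(length + 1, dtype=np.int64)
        for name, length in scaffold_lengths.items()
    }
    for name, grp in placements.groupby("scaffold"):
        diff = out[name]
        s = grp["start"].to_numpy()
        e = np.minimum(s + read_length, len(diff) - 1)
        np.add.at(diff, s, 1)
        np.add.at(diff, e, -1)
    return {name: np.cumsum(diff[:-1]) for name, diff in out.items()}


# ---------------------------------------------------------------------------
# binning and normalization


def bin_depth(
    male_depth: Mapping[str, np.ndarray],
    female_depth: Mapping[str, np.ndarray],
    bin_bp: int = 1000,
) -> pd.DataFrame:
    """Mean male/female depth per fixed-width bin (last bin may be shorter).

    Every base of every scaffold lands in exactly one bin; the bin mean is the
    per-base depth sum divided by the actual bin span.
    """
    if bin_bp < 100:
        raise ValueError("bin_bp must be >= 100")
    rows = []
    scaffolds = sorted(set(male_depth) | set(female_depth))
    for name in scaffolds:
        m = np.asarray(male_depth.get(name, ()), dtype=float)
        f = np.asarray(female_depth.get(name, ()), dtype=float)
        L = max(m.size, f.size)
        if m.size < L:
            m = np.pad(m, (0, L - m.size))
        if f.size < L:
            f = np.pad(f, (0, L - f.size))
        if (m < 0).any() or (f < 0).any():
            raise ValueError(f"negative depths on scaffold {name}")
        edges = np.arange(0, L + bin_bp, bin_bp)
        edges[-1] = min(edges[-1], L)
        if edges[-1] == edges[-2]:
            edges = edges[:-1]
        csum_m = np.concatenate(([0.0], np.cumsum(m)))
        csum_f = np.concatenate(([0.0], np.cumsum(f)))
        for s, e in zip(edges[:-1], edges[1:]):
            rows.append(
                {
                    "scaffold_id": name,
                    "start": int(s),
                    "end": int(e),
                    "mean_depth_male": (csum_m[e] - csum_m[s]) / (e - s),
                    "mean_depth_female": (csum_f[e] - csum_f[s]) / (e - s),
                }
            )
    return pd.DataFrame(rows)


def autosomal_baseline(bins: pd.DataFrame, xa_scaffolds) -> tuple[float, float]:
    """Median male/female bin depth over confidently autosomal scaffolds."""
    sub = bins[bins["scaffold_id"].isin(set(xa_scaffolds))]
    if sub.empty:
        raise ValueError("no bins on the given autosomal scaffolds")
    return (
        float(sub["mean_depth_male"].median()),
        float(sub["mean_depth_female"].median()),
    )


def normalize(
    bins: pd.DataFrame,
    male_baseline: float,
    female_baseline: float,
) -> pd.DataFrame:
    """Depth ratio track: bin depths divided by the diploid autosomal baseline.

    Normalized male depth is ~1.0 on unduplicated autosomal sequence.  Bins
    with zero female depth but positive male depth are flagged ``female_zero``
    (candidate Y-only sequence).
    """
    if male_baseline <= 0 or female_baseline <= 0:
        raise ValueError("baselines must be positive")
    track = bins.copy()
    track["norm_male"] = track["mean_depth_male"] / male_baseline
    track["norm_female"] = track["mean_depth_female"] / female_baseline
    track["female_zero"] = (track["mean_depth_female"] == 0) & (
        track["mean_depth_male"] > 0
    )
    return track


# ---------------------------------------------------------------------------
# calling


def call_segdups(
    track: pd.DataFrame,
    min_male_norm: float = 1.4,
    min_len_bp: int = 10_000,
    max_gap_bins: int = 5,
    max_female_norm: float | None = None,
) -> pd.DataFrame:
    """Maximal elevated runs of bins as segmental-duplication calls.

    A bin is elevated when normalized male depth >= ``min_male_norm`` while
    normalized female depth stays below ``max_female_norm`` (defaults to the
    same threshold).  Runs may bridge up to ``max_gap_bins`` non-elevated
    bins and are emitted when they span at least ``min_len_bp``; coordinates
    are bin-aligned and calls never overlap.
    """
    if track.empty:
        raise ValueError("empty track")
    if max_female_norm is None:
        max_female_norm = min_male_norm
    calls = []
    for name, grp in track.groupby("scaffold_id", sort=True):
        grp = grp.sort_values("start").reset_index(drop=True)
        elevated = (
            (grp["norm_male"] >= min_male_norm)
            & (grp["norm_female"] < max_female_norm)
        ).to_numpy()
        idx = np.nonzero(elevated)[0]
        if idx.size == 0:
            continue
        runs = []
        run_start = idx[0]
        prev = idx[0]
        for i in idx[1:]:
            if i - prev - 1 > max_gap_bins:
                runs.append((run_start, prev))
                run_start = i
            prev = i
        runs.append((run_start, prev))
        for a, b in runs:
            start = int(grp.loc[a, "start"])
            end = int(grp.loc[b, "end"])
            if end - start < min_len_bp:
                continue
            sub = grp.iloc[a : b + 1]
            est, low_conf = estimate_copy_number_from_means(
                float(sub["norm_male"].mean()), float(sub["norm_female"].mean())
            )
            calls.append(
                {
                    "scaffold_id": name,
                    "start": start,
                    "end": end,
                    "size_kb": (end - start) / 1000.0,
                    "mean_male_norm": float(sub["norm_male"].mean()),
                    "mean_female_norm": float(sub["norm_female"].mean()),
                    "est_copies": est,
                    "low_confidence": low_conf,
                    "n_male_specific_snps": pd.NA,
                }
            )
    return pd.DataFrame(
        calls,
        columns=[
            "scaffold_id", "start", "end", "size_kb", "mean_male_norm",
            "mean_female_norm", "est_copies", "low_confidence",
            "n_male_specific_snps",
        ],
    )


def estimate_copy_number_from_means(
    mean_male_norm: float, mean_female_norm: float
) -> tuple[int, bool]:
    """Invert normalized male depth = 1 + n/2 for the intra-Y copy number n.

    With the diploid autosomal source still present, each hemizygous Y copy
    adds 0.5 to the normalized male track, so n = round(2 * (male - female)).
    A non-positive estimate is reported as 1 with a low-confidence flag.
    """
    est = int(round(2.0 * (mean_male_norm - mean_female_norm)))
    if est < 1:
        return 1, True
    return est, False


def estimate_copy_number(call, track: pd.DataFrame) -> tuple[int, bool]:
    """Copy number for one call (row or mapping with scaffold_id/start/end)."""
    sub = track[
        (track["scaffold_id"] == call["scaffold_id"])
        & (track["start"] >= call["start"])
        & (track["end"] <= call["end"])
    ]
    if sub.empty:
        raise ValueError("call does not overlap the track")
    return estimate_copy_number_from_means(
        float(sub["norm_male"].mean()), float(sub["norm_female"].mean())
    )


# ---------------------------------------------------------------------------
# male-specific SNPs


_ALLELES = ("A", "C", "G", "T")


def allele_counts(
    reads: Mapping[str, str],
    placements: pd.DataFrame,
    scaffold_lengths: Mapping[str, int],
) -> dict[str, np.ndarray]:
    """Per-base allele counts (4 x L per scaffold) from placed reads."""
    from ._encode import revcomp_str

    out = {
        name: np.zeros((4, length), dtype=np.int32)
        for name, length in scaffold_lengths.items()
    }
    for row in placements.itertuples(index=False):
        seq = reads[row.read_id]
        if row.strand == "-":
            seq = revcomp_str(seq)
        arr = encode(seq)
        counts = out[row.scaffold]
        pos = row.start + np.arange(arr.size)
        keep = (pos >= 0) & (pos < counts.shape[1]) & (arr < 4)
        np.add.at(counts, (arr[keep], pos[keep]), 1)
    return out


def pileup_sites(
    male_counts: Mapping[str, np.ndarray],
    female_counts: Mapping[str, np.ndarray],
) -> pd.DataFrame:
    """Candidate male-specific sites: some allele seen in males, absent in females."""
    rows = []
    for name in male_counts:
        m = male_counts[name]
        f = female_counts[name]
        cand = ((m > 0) & (f == 0)).any(axis=0) & (m.sum(axis=0) > 0)
        for pos in np.nonzero(cand)[0]:
            row = {"scaffold": name, "position": int(pos)}
            for ai, a in enumerate(_ALLELES):
                row[f"male_{a}"] = int(m[ai, pos])
                row[f"female_{a}"] = int(f[ai, pos])
            rows.append(row)
    cols = ["scaffold", "position"] + [f"male_{a}" for a in _ALLELES] + [
        f"female_{a}" for a in _ALLELES
    ]
    return pd.DataFrame(rows, columns=cols)


def count_male_specific_snps(
    sites: pd.DataFrame,
    region: tuple[str, int, int] | None = None,
    min_male_alt: int = 3,
    min_male_fraction: float = 0.1,
    min_female_depth: int = 5,
) -> int:
    """Count sites with a male allele entirely absent from female reads.

    A site counts when some allele has at least ``min_male_alt`` male reads,
    makes up at least ``min_male_fraction`` of the male depth, and has zero
    female reads while the female depth is at least ``min_female_depth``.
    """
    if sites.empty:
        return 0
    df = sites
    if region is not None:
        scaffold, start, end = region
        df = df[
            (df["scaffold"] == scaffold)
            & (df["position"] >= start)
            & (df["position"] < end)
        ]
    if df.empty:
        return 0
    male = df[[f"male_{a}" for a in _ALLELES]].to_numpy()
    female = df[[f"female_{a}" for a in _ALLELES]].to_numpy()
    male_depth = male.sum(axis=1, keepdims=True)
    female_depth = female.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(male_depth > 0, male / np.maximum(male_depth, 1), 0.0)
    qualifying = (
        (male >= min_male_alt)
        & (frac >= min_male_fraction)
        & (female == 0)
        & (female_depth >= min_female_depth)
    )
    return int(qualifying.any(axis=1).sum())
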