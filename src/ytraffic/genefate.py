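"""Functional vs pseudogene classification of duplicated gene copies, and
duplication-mechanism inference.

A Y-linked gene copy is called functional only if (i) its CDS is intact --
no premature stop codon and no net frameshifting indel relative to the
reference copy -- and (ii) it contributes more than 10% of the copy group's
expression (TPM share).  A copy failing either criterion is a pseudogene.
Copies at >= 96% nucleotide identity to their counterpart are flagged as
recent duplications.

The duplication mechanism is DNA-based when the gene sits inside a called
segmental duplication, or when the Y copy shares at least one CDS-relative
intron position with the outgroup ortholog.  An intron-less outgroup ortholog
leaves the mechanism undetermined: intron loss is lineage-specific, so the
absence of introns from the Y copy alone is not evidence of an RNA
intermediate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio import Align

INTACT = "intact"
PREMATURE_STOP = "premature_stop"
FRAMESHIFT = "frameshift"
TRUNCATED = "truncated"

FUNCTIONAL = "functional"
PSEUDOGENE = "pseudogene"

DNA_SEGDUP = "DNA_segdup"
DNA_INTRON_CONSERVED = "DNA_intron_conserved"
UNDETERMINED = "undetermined"

STOP_CODONS = {"TAA", "TAG", "TGA"}

EXPRESSION_SHARE_THRESHOLD = 0.10
RECENT_IDENTITY_THRESHOLD = 0.96
FULL_LENGTH_COPY_IDENTITY = 0.95  # copy counting for catalog-style reporting


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -4
    a.extend_gap_score = -1
    return a


@dataclass(frozen=True)
class CdsIntegrity:
    """Intactness verdict for one candidate CDS against its reference."""

    status: str
    defect_codon: int | None = None

    @property
    def intact(self) -> bool:
        return self.status == INTACT


@dataclass
class GeneModel:
    """Minimal gene-copy record linking coordinates, CDS and copy group."""

    gene_id: str
    scaffold: str
    strand: str
    exons: list[tuple[int, int]]
    cds: str
    copy_group_id: str
    location: str  # "Y" or "XA"

    def __post_init__(self):
        prev_end = -1
        for s, e in self.exons:
            if s >= e or s < prev_end:
                raise ValueError(f"{self.gene_id}: exons must be ordered, non-overlapping")
            prev_end = e
        if not self.cds:
            raise ValueError(f"{self.gene_id}: empty CDS")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass(frozen=True)
class GeneFate:
    gene_id: str
    integrity: CdsIntegrity
    expression_share: float
    status: str
    recent_flag: bool


@dataclass(frozen=True)
class MechanismCall:
    gene_id: str
    call: str
    reason: str = ""


# ---------------------------------------------------------------------------
# CDS integrity


def check_cds_integrity(candidate: str, reference: str) -> CdsIntegrity:
    """Classify a candidate CDS as intact / frameshift / premature_stop / truncated.

    The candidate is globally aligned to the reference (affine gaps: match 1,
    mismatch -1, open -4, extend -1).  Indels whose summed (net) length is not
    a multiple of 3 shift the reading frame; compensating indels that restore
    frame leave the CDS intact-frame.  An in-frame stop before the final
    codon is a premature stop.  An empty or drastically shortened candidate
    (under half the reference) is truncated.
    """
    reference = reference.upper()
    if len(reference) % 3 != 0:
        raise ValueError("reference CDS length must be divisible by 3")
    if reference[-3:] not in STOP_CODONS:
        raise ValueError("reference CDS must end with a stop codon")
    candidate = candidate.upper()
    if not candidate or len(candidate) < len(reference) / 2:
        return CdsIntegrity(status=TRUNCATED, defect_codon=0 if not candidate else len(candidate) // 3)

    net = len(candidate) - len(reference)
    if net % 3 != 0:
        return CdsIntegrity(status=FRAMESHIFT, defect_codon=_first_frameshift_codon(candidate, reference))

    n_codons = len(candidate) // 3
    for i in range(n_codons - 1):
        if candidate[3 * i : 3 * i + 3] in STOP_CODONS:
            return CdsIntegrity(status=PREMATURE_STOP, defect_codon=i)
    return CdsIntegrity(status=INTACT)


def _first_frameshift_codon(candidate: str, reference: str) -> int:
    """Reference codon index of the first indel that leaves the frame shifted."""
    aln = _aligner().align(reference, candidate)[0]
    blocks_ref, blocks_cand = aln.aligned
    net = 0
    prev_ref_end = 0
    prev_cand_end = 0
    for (rs, re), (cs, ce) in zip(blocks_ref, blocks_cand):
        deletion = rs - prev_ref_end
        insertion = cs - prev_cand_end
        if deletion or insertion:
            net += insertion - deletion
            if net % 3 != 0:
                return int(prev_ref_end) // 3
        prev_ref_end, prev_cand_end = re, ce
    # trailing indel
    return int(prev_ref_end) // 3


def nucleotide_identity(candidate: str, reference: str) -> float:
    """Global-alignment identity: identical columns / total alignment columns."""
    if not candidate or not reference:
        return 0.0
    aln = _aligner().align(reference.upper(), candidate.upper())[0]
    counts = aln.counts()
    total = counts.gaps + counts.identities + counts.mismatches
    return counts.identities / total if total else 0.0


# ---------------------------------------------------------------------------
# expression and fate


def expression_share(
    tpm_by_copy: Mapping[str, float], mode: str = "group"
) -> tuple[dict[str, float], bool]:
    """Per-copy share of the copy group's expression.

    ``group`` mode divides each copy's TPM by the group total (the default
    denominator for the >10% rule); ``pairwise`` only applies to two-copy
    groups and is then identical.  Returns (shares, all_zero_flag); an
    all-zero group yields zero shares and the flag set.
    """
    if mode not in ("group", "pairwise"):
        raise ValueError(f"unknown mode {mode!r}")
    if any(v < 0 for v in tpm_by_copy.values()):
        raise ValueError("TPM values must be non-negative")
    if mode == "pairwise" and len(tpm_by_copy) != 2:
        raise ValueError("pairwise mode requires exactly two copies")
    total = sum(tpm_by_copy.values())
    if total == 0:
        return {k: 0.0 for k in tpm_by_copy}, True
    return {k: v / total for k, v in tpm_by_copy.items()}, False


def classify_fate(
    gene_id: str,
    integrity: CdsIntegrity,
    expression_share: float,
    identity_to_counterpart: float | None = None,
) -> GeneFate:
    """Conjunction rule: functional iff CDS intact and expression share > 10%."""
    functional = integrity.intact and expression_share > EXPRESSION_SHARE_THRESHOLD
    recent = (
        identity_to_counterpart is not None
        and identity_to_counterpart >= RECENT_IDENTITY_THRESHOLD
    )
    return GeneFate(
        gene_id=gene_id,
        integrity=integrity,
        expression_share=expression_share,
        status=FUNCTIONAL if functional else PSEUDOGENE,
        recent_flag=recent,
    )


# ---------------------------------------------------------------------------
# mechanism


def infer_mechanism(
    gene_id: str,
    gene_interval: tuple[str, int, int] | None,
    segdup_calls,
    y_intron_positions: Sequence[int] | None,
    outgroup_intron_positions: Sequence[int] | None,
) -> MechanismCall:
    """DNA vs undetermined duplication mechanism for one Y-linked gene.

    Intron positions are CDS-relative.  Membership in a called segmental
    duplication proves a DNA duplication outright; otherwise an intron
    position shared exactly with the outgroup ortholog does.  An intron-less
    outgroup, or missing outgroup data, leaves the call undetermined -- and
    so does an outgroup intron missing from the Y copy alone, because intron
    loss is lineage-specific.
    """
    if gene_interval is not None and segdup_calls is not None and len(segdup_calls):
        scaffold, start, end = gene_interval
        hit = segdup_calls[
            (segdup_calls["scaffold_id"] == scaffold)
            & (segdup_calls["start"] <= start)
            & (segdup_calls["end"] >= end)
        ]
        if len(hit):
            return MechanismCall(gene_id, DNA_SEGDUP, "inside a segmental-duplication call")
    if outgroup_intron_positions is None:
        return MechanismCall(gene_id, UNDETERMINED, "no outgroup intron data")
    if not outgroup_intron_positions:
        return MechanismCall(gene_id, UNDETERMINED, "outgroup ortholog is intron-less")
    shared = set(y_intron_positions or ()) & set(outgroup_intron_positions)
    if shared:
        return MechanismCall(
            gene_id, DNA_INTRON_CONSERVED, f"{len(shared)} conserved intron position(s)"
        )
    return MechanismCall(
        gene_id, UNDETERMINED,
        "outgroup introns absent from Y copy; intron loss is lineage-specific",
    )


# ---------------------------------------------------------------------------
# convenience: copy counting and GFF3 input


def count_full_length_copies(
    identities: Iterable[float], min_identity: float = FULL_LENGTH_COPY_IDENTITY
) -> int:
    """Copies at or above the full-length identity rule (95% by default)."""
    return sum(1 for x in identities if x >= min_identity)


def read_gene_models(gff3_path: str, cds_by_gene: Mapping[str, str]) -> list[GeneModel]:
    """Load gene models from GFF3 plus a CDS FASTA mapping.

    Expects ``gene`` features carrying ``copy_group`` and ``location``
    attributes (defaulting to the gene id and ``XA``), with child ``exon``
    features.
    """
    import gffutils

    db = gffutils.create_db(gff3_path, ":memory:", merge_strategy="create_unique")
    models = []
    for gene in db.features_of_type("gene"):
        exons = sorted(
            (f.start - 1, f.end) for f in db.children(gene, featuretype="exon")
        )
        if not exons:
            exons = [(gene.start - 1, gene.end)]
        gid = gene.id
        models.append(
            GeneModel(
                gene_id=gid,
                scaffold=gene.seqid,
                strand=gene.strand,
                exons=exons,
                cds=cds_by_gene[gid],
                copy_group_id=gene.attributes.get("copy_group", [gid])[0],
                location=gene.attributes.get("location", ["XA"])[0],
            )
        )
    return models
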