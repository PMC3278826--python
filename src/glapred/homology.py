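"""Two-stage homology reduction of Glu-centered fragments.

Stage 1 flags pairs of proteins sharing more than 30% sequence similarity as
homologous.  Stage 2 re-aligns fragment pairs drawn from homologous protein
pairs and, whenever their similarity exceeds 50%, keeps only the
first-encountered fragment.  Positive and negative fragment sets are reduced
independently.

Similarity is defined as identities / alignment length (gap columns counted
in the length) on the best local alignment under BLOSUM62 with affine gap
cost 11 + 1 per gap residue.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .sequence_data import PAD, ProteinRecord, SiteFragment

PROTEIN_SIMILARITY_THRESHOLD = 0.30
FRAGMENT_SIMILARITY_THRESHOLD = 0.50


@dataclass(frozen=True)
class SimilarityResult:
    a_id: str
    b_id: str
    similarity: float


@dataclass(frozen=True)
class ReductionRecord:
    """Audit row: which fragment was dropped in favour of which."""

    kept: SiteFragment
    removed: SiteFragment
    similarity: float


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # NCBI convention: a gap of length L costs 11 + L.
    aligner.open_gap_score = -12
    aligner.extend_gap_score = -1
    return aligner


_ALIGNER = _make_aligner()


def pairwise_similarity(seq_a: str, seq_b: str) -> float:
    """Local-alignment similarity of two residue strings, in [0, 1].

    Terminal padding ``'-'`` is stripped before aligning.  An empty (or
    non-positive-scoring) best alignment yields 0.
    """
    a = seq_a.strip(PAD)
    b = seq_b.strip(PAD)
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    score = _ALIGNER.score(a, b)
    if score <= 0:
        return 0.0
    alignment = _ALIGNER.align(a, b)[0]
    counts = alignment.counts()
    length = counts.identities + counts.mismatches + counts.gaps
    if length == 0:
        return 0.0
    return counts.identities / length


def find_homologous_pairs(
    records: Sequence[ProteinRecord],
    threshold: float = PROTEIN_SIMILARITY_THRESHOLD,
) -> list[tuple[str, str]]:
    """All unordered protein pairs with similarity strictly above *threshold*."""
    if len(records) < 2:
        raise ValueError("need at least 2 records to search for homologous pairs")
    pairs: list[tuple[str, str]] = []
    for i, a in enumerate(records):
        for b in records[i + 1 :]:
            if pairwise_similarity(a.sequence, b.sequence) > threshold:
                pairs.append((a.id, b.id))
    return pairs


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def _reduce_one_class(
    fragments: Sequence[SiteFragment],
    homologous: set[tuple[str, str]],
    frag_threshold: float,
    report: list[ReductionRecord] | None,
) -> list[SiteFragment]:
    # Greedy left-to-right scan: each incoming fragment is compared against
    # the already-kept fragments from homologous parent proteins.
    kept: list[SiteFragment] = []
    for frag in fragments:
        duplicate_of: tuple[SiteFragment, float] | None = None
        for prev in kept:
            if frag.protein_id == prev.protein_id:
                continue
            if _pair_key(frag.protein_id, prev.protein_id) not in homologous:
                continue
            sim = pairwise_similarity(frag.window, prev.window)
            if sim > frag_threshold:
                duplicate_of = (prev, sim)
                break
        if duplicate_of is None:
            kept.append(frag)
        elif report is not None:
            report.append(ReductionRecord(duplicate_of[0], frag, duplicate_of[1]))
    return kept


def reduce_fragments(
    fragments: Sequence[SiteFragment],
    homologous_pairs: Iterable[tuple[str, str]],
    frag_threshold: float = FRAGMENT_SIMILARITY_THRESHOLD,
    report: list[ReductionRecord] | None = None,
) -> list[SiteFragment]:
    """Collapse redundant fragments between homologous proteins.

    Only fragment pairs whose parent proteins form a homologous pair are
    compared; among those with similarity above *frag_threshold* the
    first-encountered fragment (stable input order) is kept.  Positive and
    negative sets are reduced independently; the output preserves input
    order.  Pass *report* to collect (kept, removed, similarity) audit rows.
    """
    lengths = {len(f.window) for f in fragments}
    if len(lengths) > 1:
        raise ValueError(f"fragments have mixed window lengths: {sorted(lengths)}")
    homologous = {_pair_key(a, b) for a, b in homologous_pairs}
    kept_pos = _reduce_one_class(
        [f for f in fragments if f.is_positive], homologous, frag_threshold, report
    )
    kept_neg = _reduce_one_class(
        [f for f in fragments if not f.is_positive], homologous, frag_threshold, report
    )
    retained = set(id(f) for f in kept_pos) | set(id(f) for f in kept_neg)
    return [f for f in fragments if id(f) in retained]


def write_reduction_report(report: Sequence[ReductionRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("kept_fragment\tremoved_fragment\tsimilarity\n")
        for row in report:
            fh.write(
                f"{row.kept.protein_id}@{row.kept.center}\t"
                f"{row.removed.protein_id}@{row.removed.center}\t"
                f"{row.similarity:.4f}\n"
            )
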