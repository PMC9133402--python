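"""Minimal V/J assignment and CDR3 extraction from read-2 sequences.

A deliberately small seed-and-extend caller so the whole pipeline runs
end-to-end on synthetic reads without an external aligner.  It handles
substitutions only (no indels): each read is aligned ungapped against every
reference segment via shared k-mer seeds, the best V and J hits place the
conserved anchor codons (the V cysteine and the J FGxG phenylalanine), and
the CDR3 spans both anchors inclusive, following the convention of standard
callers so clone keys are comparable across sources.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional, Sequence

from Bio.Seq import Seq

from .repertoire import CloneKey, NonProductiveError, build_clone_key, normalize_gene_family

__all__ = [
    "SegmentReference",
    "SegmentHit",
    "ReadAnnotation",
    "CloneRecord",
    "align_segment",
    "call_vj",
    "extract_cdr3",
    "annotate_read",
    "call_clones_from_fastq",
]

DEFAULT_SEED_K = 12


@dataclass(frozen=True)
class SegmentReference:
    """One V or J reference segment with its conserved-anchor codon offset.

    ``anchor_offset`` is the 0-based start of the conserved residue codon:
    the 104-Cys for V segments, the FGxG Phe for J segments.
    """

    name: str
    chain: str  # "TRA" or "TRB"
    seq: str
    anchor_offset: int

    def __post_init__(self) -> None:
        if self.anchor_offset < 0 or self.anchor_offset + 3 > len(self.seq):
            raise ValueError(
                f"{self.name}: anchor codon at {self.anchor_offset} outside sequence"
            )
        normalize_gene_family(self.name)  # raises for malformed names

    @property
    def segment_type(self) -> str:
        """'V' or 'J', from the segment name."""
        return self.name[3]


class SegmentHit(NamedTuple):
    name: str
    score: int
    read_offset: int
    ref_offset: int

    @property
    def diagonal(self) -> int:
        return self.read_offset - self.ref_offset


def _best_run(read: str, ref: str, diagonal: int) -> Optional[tuple[int, int, int]]:
    """Best-scoring contiguous run (+1 match / -1 mismatch) on one diagonal.

    Returns (score, read_start, ref_start) of the maximum-scoring segment
    over the overlap of read and ref at the given offset, or None if they
    do not overlap.
    """
    read_start = max(0, diagonal)
    ref_start = read_start - diagonal
    n = min(len(read) - read_start, len(ref) - ref_start)
    if n <= 0:
        return None
    best = (0, read_start, ref_start)  # score 0 run of length 0
    running, run_start = 0, 0
    for i in range(n):
        s = 1 if read[read_start + i] == ref[ref_start + i] else -1
        if running <= 0:
            running, run_start = s, i
        else:
            running += s
        if running > best[0]:
            best = (running, read_start + run_start, ref_start + run_start)
    if best[0] <= 0:
        return None
    return best


def align_segment(
    read: str, ref: SegmentReference, k: int = DEFAULT_SEED_K
) -> Optional[SegmentHit]:
    """Ungapped seed-and-extend alignment of a read against one segment.

    Every k-mer shared between read and reference nominates a diagonal; on
    each nominated diagonal the maximum-scoring contiguous run (match +1,
    mismatch -1) is found, and the best run over all diagonals is returned.
    No seed, no hit.
    """
    if k < 8:
        raise ValueError("seed length k must be >= 8")
    if len(read) < k or len(ref.seq) < k:
        return None
    ref_kmers: dict[str, list[int]] = defaultdict(list)
    for j in range(len(ref.seq) - k + 1):
        ref_kmers[ref.seq[j : j + k]].append(j)
    diagonals: set[int] = set()
    for i in range(len(read) - k + 1):
        for j in ref_kmers.get(read[i : i + k], ()):
            diagonals.add(i - j)
    best: Optional[SegmentHit] = None
    for d in sorted(diagonals):
        run = _best_run(read, ref.seq, d)
        if run is None:
            continue
        score, read_start, ref_start = run
        hit = SegmentHit(ref.name, score, read_start, ref_start)
        if best is None or score > best.score:
            best = hit
    return best


def call_vj(
    read: str, refs: Sequence[SegmentReference], k: int = DEFAULT_SEED_K
) -> Optional[tuple[SegmentHit, SegmentHit]]:
    """Best V and best J hit for a read; ties broken by lexicographic name."""
    best_v: Optional[SegmentHit] = None
    best_j: Optional[SegmentHit] = None
    for ref in refs:
        hit = align_segment(read, ref, k=k)
        if hit is None:
            continue
        if ref.segment_type == "V":
            best_v = _better(best_v, hit)
        else:
            best_j = _better(best_j, hit)
    if best_v is None or best_j is None:
        return None
    return best_v, best_j


def _better(current: Optional[SegmentHit], hit: SegmentHit) -> SegmentHit:
    # higher score wins; ties go to the lexicographically smaller name
    if current is None or hit.score > current.score:
        return hit
    if hit.score == current.score and hit.name < current.name:
        return hit
    return current


@dataclass(frozen=True)
class ReadAnnotation:
    read_id: str
    v_name: str
    j_name: str
    v_score: int
    j_score: int
    cdr3_nt: str
    cdr3_aa: str
    productive: bool


def extract_cdr3(
    read: str,
    v_hit: SegmentHit,
    j_hit: SegmentHit,
    refs_by_name: dict[str, SegmentReference],
) -> Optional[tuple[str, str, bool]]:
    """CDR3 from the conserved V cysteine through the J phenylalanine, inclusive.

    The anchor codons are projected from the references onto the read along
    each hit's diagonal.  Returns (cdr3_nt, cdr3_aa, productive) or None if
    either anchor codon falls outside the read or the span is inverted.
    Productive means in-frame (length divisible by 3) with no stop codon.
    """
    v_ref = refs_by_name[v_hit.name]
    j_ref = refs_by_name[j_hit.name]
    v_anchor = v_ref.anchor_offset + v_hit.diagonal
    j_anchor = j_ref.anchor_offset + j_hit.diagonal
    if v_anchor < 0 or j_anchor + 3 > len(read) or j_anchor < v_anchor:
        return None
    cdr3_nt = read[v_anchor : j_anchor + 3]
    n_codons = len(cdr3_nt) // 3
    cdr3_aa = str(Seq(cdr3_nt[: n_codons * 3]).translate())
    productive = len(cdr3_nt) % 3 == 0 and "*" not in cdr3_aa
    return cdr3_nt, cdr3_aa, productive


def annotate_read(
    read_id: str,
    seq: str,
    refs: Sequence[SegmentReference],
    k: int = DEFAULT_SEED_K,
) -> Optional[ReadAnnotation]:
    """Full per-read annotation: V/J call plus CDR3, or None if uncallable."""
    hits = call_vj(seq, refs, k=k)
    if hits is None:
        return None
    v_hit, j_hit = hits
    refs_by_name = {r.name: r for r in refs}
    cdr3 = extract_cdr3(seq, v_hit, j_hit, refs_by_name)
    if cdr3 is None:
        return None
    cdr3_nt, cdr3_aa, productive = cdr3
    return ReadAnnotation(
        read_id=read_id,
        v_name=v_hit.name,
        j_name=j_hit.name,
        v_score=v_hit.score,
        j_score=j_hit.score,
        cdr3_nt=cdr3_nt,
        cdr3_aa=cdr3_aa,
        productive=productive,
    )


@dataclass(frozen=True)
class CloneRecord:
    """One called clone with representative gene-level fields."""

    clone_id: str
    key: CloneKey
    v_gene: str
    j_gene: str
    cdr3_nt: str
    cdr3_aa: str
    read_count: int


def call_clones_from_fastq(
    reads: Iterable[tuple[str, str]],
    refs: Sequence[SegmentReference],
    k: int = DEFAULT_SEED_K,
) -> tuple[list[CloneRecord], dict[str, str], Counter]:
    """Group productive read annotations into family-level clones.

    ``reads`` yields (read_id, sequence) from read 2.  Returns the clone
    table (descending read count, ties lexicographic on the key), a read
    id → clone id map compatible with the supporting-read export format,
    and a tally of dropped reads by reason.
    """
    groups: dict[CloneKey, list[ReadAnnotation]] = defaultdict(list)
    dropped: Counter = Counter()
    # identical read sequences (PCR duplicates) annotate identically, so
    # alignment is done once per distinct sequence
    cache: dict[str, tuple] = {}
    for read_id, seq in reads:
        hit = cache.get(seq)
        if hit is None:
            ann = annotate_read(read_id, seq, refs, k=k)
            if ann is None:
                hit = ("no_vj_or_anchor", None, None)
            elif not ann.productive:
                hit = ("unproductive", None, None)
            else:
                try:
                    key = build_clone_key(ann.v_name, ann.j_name, ann.cdr3_aa)
                    hit = (None, key, ann)
                except NonProductiveError:
                    hit = ("unproductive", None, None)
            cache[seq] = hit
        reason, key, ann = hit
        if reason is not None:
            dropped[reason] += 1
            continue
        groups[key].append(
            ReadAnnotation(
                read_id=read_id,
                v_name=ann.v_name,
                j_name=ann.j_name,
                v_score=ann.v_score,
                j_score=ann.j_score,
                cdr3_nt=ann.cdr3_nt,
                cdr3_aa=ann.cdr3_aa,
                productive=True,
            )
        )

    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    clones: list[CloneRecord] = []
    read_map: dict[str, str] = {}
    for i, (key, anns) in enumerate(ordered, start=1):
        clone_id = f"CL{i:05d}"
        # representative gene-level fields: the most common observed values
        v_gene = Counter(a.v_name for a in anns).most_common(1)[0][0]
        j_gene = Counter(a.j_name for a in anns).most_common(1)[0][0]
        cdr3_nt = Counter(a.cdr3_nt for a in anns).most_common(1)[0][0]
        clones.append(
            CloneRecord(
                clone_id=clone_id,
                key=key,
                v_gene=v_gene,
                j_gene=j_gene,
                cdr3_nt=cdr3_nt,
                cdr3_aa=key.cdr3_aa,
                read_count=len(anns),
            )
        )
        for ann in anns:
            read_map[ann.read_id] = clone_id
    return clones, read_map, dropped
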