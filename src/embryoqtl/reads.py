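"""Read-level operations: quality-weighted poly(A) trimming and the
ambiguous-alignment (repeat) filter.

3'-biased libraries frequently read into the mRNA poly(A) tail; the trimmer
removes the tail while tolerating sequencing error by scoring every candidate
trim position with base qualities.  The repeat filter discards reads whose
best alignment is not clearly better than alignments elsewhere in the genome.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np


@dataclass(frozen=True)
class Read:
    id: str
    bases: str
    qualities: tuple[int, ...]

    def __post_init__(self):
        if len(self.bases) != len(self.qualities):
            raise ValueError(f"read {self.id}: bases and qualities differ in length")
        if any(q < 0 for q in self.qualities):
            raise ValueError(f"read {self.id}: negative quality score")


@dataclass(frozen=True)
class AlignmentCandidate:
    """One candidate placement of a read.

    ``edit_distance`` counts 1 per mismatch and 2 per indel.
    ``genomic_position_key`` is the canonical genome coordinate after
    projecting transcriptome hits through splice gaps, so a genomic hit and a
    spliced-transcript hit at the same locus share a key.
    """

    read_id: str
    reference: str
    position: int
    strand: str
    edit_distance: int
    genomic_position_key: tuple

    def __post_init__(self):
        if self.edit_distance < 0:
            raise ValueError("edit distance must be non-negative")


def polya_trim_scores(bases: str, qualities) -> np.ndarray:
    """Score s_i for every candidate number of kept bases i = 0..len.

    s_i = sum of quality scores of A bases after position i minus three times
    the sum of quality scores of non-A bases after position i (N counts as
    non-A); s_len = 0 (trim nothing).
    """
    q = np.asarray(qualities, dtype=np.int64)
    is_a = np.frombuffer(bases.encode(), dtype=np.uint8) == ord("A")
    contrib = np.where(is_a, q, -3 * q)
    # s_i = sum of contrib[i:]; suffix sums with s_len = 0
    s = np.zeros(len(bases) + 1, dtype=np.int64)
    s[:-1] = contrib[::-1].cumsum()[::-1]
    return s


def trim_polya(read: Read, min_trim: int = 3) -> Read:
    """Trim the 3' poly(A) tail at the highest-scoring position.

    All bases after the argmax of s_i are removed iff that removes at least
    ``min_trim`` bases.  Score ties are broken toward keeping more bases.
    """
    if len(read.bases) == 0:
        raise ValueError("empty read")
    s = polya_trim_scores(read.bases, read.qualities)
    # last argmax = keep the most bases on ties
    best = len(s) - 1 - int(np.argmax(s[::-1]))
    if len(read.bases) - best >= min_trim:
        return replace(read, bases=read.bases[:best], qualities=read.qualities[:best])
    return read


def filter_ambiguous(candidates: list[AlignmentCandidate], margin: int = 3):
    """Repeat filter over one read's candidate alignments.

    Returns the single consolidated best alignment, or None when the read is
    ambiguous: the best and second-best alignments at *distinct* genomic
    positions are within ``margin`` edit distance of each other, or the best
    score is attained at more than one distinct genomic position.  Candidates
    sharing a genomic position key (e.g. a genomic hit and the splice-junction
    projection of the same locus) are consolidated into one record.
    """
    if not candidates:
        return None
    read_ids = {c.read_id for c in candidates}
    if len(read_ids) > 1:
        raise ValueError(f"candidates from multiple reads: {sorted(read_ids)}")
    best_by_key: dict[tuple, AlignmentCandidate] = {}
    for c in candidates:
        cur = best_by_key.get(c.genomic_position_key)
        if cur is None or c.edit_distance < cur.edit_distance:
            best_by_key[c.genomic_position_key] = c
    ranked = sorted(best_by_key.values(), key=lambda c: (c.edit_distance, c.genomic_position_key))
    best = ranked[0]
    if len(ranked) > 1:
        second = ranked[1]
        if second.edit_distance == best.edit_distance:
            return None  # best score at >1 genomic position
        if second.edit_distance - best.edit_distance <= margin:
            return None
    return best


def fixed_window_trim(read: Read, head: int = 0, tail: int = 0) -> Read:
    """Drop a fixed number of leading/trailing bases (read-length harmonization
    across sequencer models)."""
    n = len(read.bases)
    if head + tail >= n:
        raise ValueError("fixed trim would remove the whole read")
    stop = n - tail
    return replace(read, bases=read.bases[head:stop], qualities=read.qualities[head:stop])
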