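"""Ungapped spacer-vs-foreign-element search.

An exhaustive Hamming scan of every offset on both strands of small
user-supplied reference sequences (phage/plasmid FASTA).  For 30-40-base
spacers against desk-scale references this is exact and parameter-free;
identities are reported as matches/length fractions (e.g. 30/30).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio import SeqIO
from numpy.lib.stride_tricks import sliding_window_view

from ._seq import encode, revcomp


@dataclass
class ProtospacerHit:
    ref_id: str
    strand: str  # "+" or "-"
    offset: int  # 0-based start on the forward strand of the reference
    matches: int
    length: int  # spacer length; identity is matches/length

    @property
    def identity_label(self) -> str:
        return f"{self.matches}/{self.length}"


def search_spacer(
    spacer: str,
    references: Sequence[tuple[str, str]],
    max_mismatch: int = 3,
) -> Optional[ProtospacerHit]:
    """Best ungapped hit of a spacer in a set of reference sequences.

    Every offset on both strands of every reference is scored; the hit with
    the most matches wins, ties resolved by input reference order, forward
    strand before reverse, then the smallest offset.  Returns None when the
    best hit still has more than ``max_mismatch`` mismatches or when no
    reference can hold the spacer.
    """
    if not spacer:
        raise ValueError("empty spacer")
    L = len(spacer)
    enc_sp = encode(spacer)
    best: Optional[ProtospacerHit] = None
    for ref_id, ref_seq in references:
        for strand in ("+", "-"):
            seq = ref_seq if strand == "+" else revcomp(ref_seq)
            if len(seq) < L:
                continue
            windows = sliding_window_view(encode(seq), L)
            mism = np.count_nonzero(windows != enc_sp, axis=1)
            idx = int(np.argmin(mism))  # argmin takes the smallest offset on ties
            matches = L - int(mism[idx])
            offset = idx if strand == "+" else len(seq) - idx - L
            if best is None or matches > best.matches:
                best = ProtospacerHit(ref_id, strand, offset, matches, L)
    if best is None or best.length - best.matches > max_mismatch:
        return None
    return best


def search_all(
    spacers: Sequence[tuple[int, str]],
    references: Sequence[tuple[str, str]],
    max_mismatch: int = 3,
) -> list[tuple[int, ProtospacerHit]]:
    """Search every (spacer_id, sequence) pair; only hits are returned."""
    hits = []
    for sid, seq in spacers:
        hit = search_spacer(seq, references, max_mismatch)
        if hit is not None:
            hits.append((sid, hit))
    return hits


def load_references(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_hits(hits: Sequence[tuple[int, ProtospacerHit]], path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("spacer_id\tref_id\tstrand\toffset\tmatches\tlength\tidentity\n")
        for sid, h in hits:
            out.write(
                f"{sid}\t{h.ref_id}\t{h.strand}\t{h.offset}\t{h.matches}\t"
                f"{h.length}\t{h.identity_label}\n"
            )
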