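"""Direct-repeat detection and leader-end spacer extraction.

Amplicons have the structure ``[leader tail][repeat][spacer][repeat]...``
with the newest spacer closest to the leader.  Repeats are located by a
mismatch-tolerant Hamming scan; spacers are the inter-repeat segments.
Coordinates are 0-based half-open; ``position_from_leader`` is a 1-based
rank with 1 = the newest (leader-proximal) spacer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ._seq import encode, revcomp
from .model import PipelineConfig

STATUS_OK = "ok"
STATUS_NO_REPEATS = "no_repeats"
STATUS_NO_VALID_SPACERS = "no_valid_spacers"


@dataclass
class RepeatMatch:
    start: int
    end: int  # exclusive
    mismatches: int
    partial: bool = False


@dataclass
class SpacerSequence:
    sequence: str
    position_from_leader: int  # 1 = newest spacer
    source_amplicon: str


@dataclass
class ExtractionResult:
    amplicon_id: str
    spacers: list[SpacerSequence]
    status: str
    repeats: list[RepeatMatch] = field(default_factory=list)
    flagged_segments: list[str] = field(default_factory=list)  # out-of-bounds lengths
    reverse_complemented: bool = False


def locate_repeats(seq: str, cfg: PipelineConfig) -> list[RepeatMatch]:
    """All non-overlapping repeat matches in a sequence, sorted by start.

    Full matches allow up to ``repeat_max_mismatch`` substitutions; candidates
    are resolved greedily left to right, preferring fewer mismatches and then
    the leftmost start among mutually overlapping candidates.  At most one
    terminal partial match (a repeat prefix of at least ``min_partial_repeat``
    bases truncated by the 3' end, mismatch allowance scaled down
    proportionally) is appended.
    """
    rep = cfg.repeat_sequence
    L = len(rep)
    enc_seq = encode(seq)
    enc_rep = encode(rep)
    n = len(seq)

    candidates: list[tuple[int, int]] = []  # (start, mismatches)
    if n >= L:
        windows = sliding_window_view(enc_seq, L)
        mism = np.count_nonzero(windows != enc_rep, axis=1)
        for start in np.flatnonzero(mism <= cfg.repeat_max_mismatch):
            candidates.append((int(start), int(mism[start])))

    chosen: list[RepeatMatch] = []
    pos = 0
    i = 0
    while i < len(candidates):
        start, _ = candidates[i]
        if start < pos:
            i += 1
            continue
        # all candidates overlapping the earliest available one
        group = [c for c in candidates[i:] if c[0] < start + L]
        best_start, best_mm = min(group, key=lambda c: (c[1], c[0]))
        chosen.append(RepeatMatch(best_start, best_start + L, best_mm))
        pos = best_start + L
        while i < len(candidates) and candidates[i][0] < pos:
            i += 1

    # terminal partial repeat truncated by the 3' end, longest qualifying first
    tail_from = max(pos, n - L + 1)
    for t in range(tail_from, n - cfg.min_partial_repeat + 1):
        plen = n - t
        allowed = (cfg.repeat_max_mismatch * plen) // L
        mm = int(np.count_nonzero(enc_seq[t:] != enc_rep[:plen]))
        if mm <= allowed:
            chosen.append(RepeatMatch(t, n, mm, partial=True))
            break
    return chosen


def extract_spacers(
    amplicon_id: str, seq: str, cfg: PipelineConfig
) -> ExtractionResult:
    """Extract the ordered leader-end spacers of one amplicon.

    Spacers are the segments between consecutive repeat matches whose length
    falls within ``[spacer_min_len, spacer_max_len]``; segments outside the
    bounds are dropped and flagged.  The segment before the first repeat is
    leader sequence, never a spacer.  When no repeat is found, the reverse
    complement is tried once before declaring ``no_repeats``.
    """
    matches = locate_repeats(seq, cfg)
    used = seq
    rced = False
    if not matches:
        rc = revcomp(seq)
        rc_matches = locate_repeats(rc, cfg)
        if rc_matches:
            matches, used, rced = rc_matches, rc, True

    if len(matches) < 2:
        return ExtractionResult(
            amplicon_id, [], STATUS_NO_REPEATS, repeats=matches,
            reverse_complemented=rced,
        )

    spacers: list[SpacerSequence] = []
    flagged: list[str] = []
    for left, right in zip(matches, matches[1:]):
        segment = used[left.end : right.start]
        if cfg.spacer_min_len <= len(segment) <= cfg.spacer_max_len:
            spacers.append(
                SpacerSequence(segment, len(spacers) + 1, amplicon_id)
            )
        else:
            flagged.append(segment)

    status = STATUS_OK if spacers else STATUS_NO_VALID_SPACERS
    return ExtractionResult(
        amplicon_id, spacers, status, repeats=matches,
        flagged_segments=flagged, reverse_complemented=rced,
    )


def write_spacers(results: list[ExtractionResult], path) -> None:
    with open(path, "w") as out:
        for res in results:
            for sp in res.spacers:
                out.write(
                    f">{res.amplicon_id} position={sp.position_from_leader}\n"
                    f"{sp.sequence}\n"
                )


def write_status(results: list[ExtractionResult], path) -> None:
    with open(path, "w") as out:
        out.write("amplicon_id\tstatus\tn_spacers\tn_repeats\tn_flagged\trc_rescued\n")
        for res in results:
            out.write(
                f"{res.amplicon_id}\t{res.status}\t{len(res.spacers)}\t"
                f"{len(res.repeats)}\t{len(res.flagged_segments)}\t"
                f"{int(res.reverse_complemented)}\n"
            )
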