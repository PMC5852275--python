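"""Quality trimming, read filtering and paired-end merging.

The three stages mirror the usual short-read amplicon preprocessing:
sliding-window quality trimming, mate-specific length plus base-quality
filtering, and overlap-based pair merging.  All thresholds come from
:class:`~crispramp.model.PipelineConfig`.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._seq import decode, encode, overlap_match_counts, revcomp
from .model import MergedAmplicon, PipelineConfig, Read

_IDENTITY_EPS = 1e-9


def sliding_window_trim(read: Read, window: int, q_threshold: float) -> Read:
    """Cut a read at the first sliding window whose mean quality drops.

    Scans 5'->3' with a ``window``-wide window; at the first window whose
    mean quality is below ``q_threshold`` the read is cut at the window
    start, after retaining any leading bases inside that window whose own
    quality still meets the threshold (the behaviour of the standard
    SLIDINGWINDOW trimmer).  Reads shorter than the window are returned
    unchanged.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    q = np.asarray(read.qualities)
    n = len(q)
    if n < window:
        return read
    csum = np.concatenate(([0], np.cumsum(q, dtype=np.int64)))
    means = (csum[window:] - csum[:-window]) / window
    failing = np.flatnonzero(means < q_threshold)
    if failing.size == 0:
        return read
    cut = int(failing[0])
    while cut < n and q[cut] >= q_threshold:
        cut += 1
    return Read(read.read_id, read.sequence[:cut], q[:cut], read.mate)


def filter_reason(read: Read, cfg: PipelineConfig) -> Optional[str]:
    """Why a read fails the length/quality filters, or None if it passes."""
    min_len = cfg.min_len_r1 if read.mate == "R1" else cfg.min_len_r2
    if len(read) < min_len:
        return "too_short"
    q = np.asarray(read.qualities)
    frac_good = np.count_nonzero(q >= cfg.qual_floor) / len(q) if len(q) else 0.0
    if frac_good < cfg.qual_fraction:  # exactly qual_fraction passes
        return "low_quality"
    return None


def filter_reads(
    reads: Iterable[Read], cfg: PipelineConfig, dropped: Counter | None = None
) -> Iterator[Read]:
    """Yield reads passing the filters; tally drop reasons in ``dropped``."""
    for read in reads:
        reason = filter_reason(read, cfg)
        if reason is None:
            yield read
        elif dropped is not None:
            dropped[f"{read.mate}_{reason}"] += 1


def merge_pair(r1: Read, r2: Read, cfg: PipelineConfig) -> Optional[MergedAmplicon]:
    """Merge a read pair across its best qualifying overlap.

    R2 is reverse-complemented; every candidate overlap length within
    ``[min_overlap, max_overlap]`` is scored and the one with the lowest
    mismatch fraction wins (ties: longer overlap).  The merge succeeds iff
    that fraction is at most ``1 - merge_identity``.  At disagreeing overlap
    positions the higher-quality base is taken (tie: the R1 base); the
    overlap quality is the per-position maximum.

    Returns None on merge failure (a reported outcome, not an error).
    """
    a = encode(r1.sequence)
    b = encode(revcomp(r2.sequence))
    qa = np.asarray(r1.qualities)
    qb = np.asarray(r2.qualities)[::-1]
    n1, n2 = len(a), len(b)
    lo = cfg.min_overlap
    hi = min(cfg.max_overlap, n1, n2)
    if hi < lo or lo < 1:
        return None

    shifts, matches, overlaps = overlap_match_counts(a, b)
    # suffix(R1)/prefix(R2) placements: shift s = n1 - overlap
    base = n2 - 1  # index of shift 0
    ovs = np.arange(lo, hi + 1)
    idx = base + n1 - ovs
    mism = ovs - matches[idx]
    frac = mism / ovs
    # lowest mismatch fraction; ties -> longer overlap
    order = np.lexsort((-ovs, frac))
    best = int(order[0])
    ov = int(ovs[best])
    if (1.0 - float(frac[best])) < cfg.merge_identity - _IDENTITY_EPS:
        return None

    s = n1 - ov
    a_ov, b_ov = a[s:], b[:ov]
    qa_ov, qb_ov = qa[s:], qb[:ov]
    take_b = (a_ov != b_ov) & (qb_ov > qa_ov)
    merged_mid = np.where(take_b, b_ov, a_ov)
    qual_mid = np.maximum(qa_ov, qb_ov)
    sequence = r1.sequence[:s] + decode(merged_mid) + decode(b[ov:])
    qualities = np.concatenate([qa[:s], qual_mid, qb[ov:]])
    return MergedAmplicon(
        amplicon_id=r1.read_id,
        sequence=sequence,
        qualities=qualities,
        overlap_length=ov,
        source_pair=(r1.read_id, r2.read_id),
    )


@dataclass
class SampleReadResult:
    """Merged amplicons plus the per-stage attrition bookkeeping."""

    merged: list[MergedAmplicon]
    attrition: list[dict] = field(default_factory=list)


def process_pairs(
    pairs: Iterable[tuple[Read, Read]], cfg: PipelineConfig
) -> SampleReadResult:
    """Trim, filter and merge read pairs; a pair survives only if both mates do."""
    pairs = list(pairs)
    n_in = len(pairs)

    trimmed: list[tuple[Read, Read]] = []
    for r1, r2 in pairs:
        t1 = sliding_window_trim(r1, cfg.window_size, cfg.q_threshold_r1)
        t2 = sliding_window_trim(r2, cfg.window_size, cfg.q_threshold_r2)
        trimmed.append((t1, t2))

    dropped: Counter = Counter()
    kept: list[tuple[Read, Read]] = []
    for r1, r2 in trimmed:
        rs1 = filter_reason(r1, cfg)
        rs2 = filter_reason(r2, cfg)
        if rs1 is None and rs2 is None:
            kept.append((r1, r2))
        else:
            if rs1 is not None:
                dropped[f"R1_{rs1}"] += 1
            if rs2 is not None:
                dropped[f"R2_{rs2}"] += 1

    merged: list[MergedAmplicon] = []
    n_merge_fail = 0
    for r1, r2 in kept:
        amp = merge_pair(r1, r2, cfg)
        if amp is None:
            n_merge_fail += 1
        else:
            merged.append(amp)

    attrition = [
        {"stage": "input", "pairs_in": n_in, "pairs_out": n_in, "detail": ""},
        {"stage": "trim", "pairs_in": n_in, "pairs_out": n_in, "detail": ""},
        {
            "stage": "filter",
            "pairs_in": n_in,
            "pairs_out": len(kept),
            "detail": ";".join(f"{k}={v}" for k, v in sorted(dropped.items())),
        },
        {
            "stage": "merge",
            "pairs_in": len(kept),
            "pairs_out": len(merged),
            "detail": f"merge_failure={n_merge_fail}",
        },
    ]
    return SampleReadResult(merged=merged, attrition=attrition)


def read_fastq(path: str | Path, mate: str) -> list[Read]:
    """Read a Sanger Phred+33 FASTQ file into :class:`Read` objects."""
    reads = []
    with open(path) as handle:
        for title, seq, qual in FastqGeneralIterator(handle):
            read_id = title.split()[0]
            q = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int16) - 33
            reads.append(Read(read_id, seq.upper(), q, mate))
    return reads


def write_fastq(reads: Iterable[Read | MergedAmplicon], path: str | Path) -> None:
    with open(path, "w") as handle:
        for r in reads:
            name = r.read_id if isinstance(r, Read) else r.amplicon_id
            qual = "".join(chr(int(q) + 33) for q in np.asarray(r.qualities))
            handle.write(f"@{name}\n{r.sequence}\n+\n{qual}\n")
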