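"""Greedy incremental clustering of merged amplicons.

Sequences are processed longest-first and join the first existing cluster
whose representative is similar enough, otherwise they found a new cluster.
Similarity is judged on the best ungapped end-gap-free alignment (the error
model upstream is substitution-only, so internal gaps buy nothing): the
alignment must reach ``cluster_identity`` and must cover at least
``cluster_coverage`` of *both* sequences.  Requiring coverage of the longer
sequence as well keeps leader-anchored amplicons with nested spacer arrays
(a one-spacer amplicon is a literal prefix of its two-spacer sibling) in
separate clusters, which downstream typing depends on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._seq import best_overlap, encode
from .model import PipelineConfig

_EPS = 1e-9


@dataclass
class Cluster:
    representative_id: str
    member_ids: list[str] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.member_ids)


def pairwise_identity(a: str, b: str) -> tuple[float, float]:
    """Identity and coverage of the best end-gap-free alignment of two sequences.

    identity = matches / aligned columns; coverage = aligned columns /
    length of the shorter sequence.
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    matches, overlap, _ = best_overlap(encode(a), encode(b))
    return matches / overlap, overlap / min(len(a), len(b))


def _satisfies(
    rep_seq: str,
    rep_enc: np.ndarray,
    seq: str,
    seq_enc: np.ndarray,
    cfg: PipelineConfig,
) -> bool:
    """Membership rule: identity and dual-sided coverage on the best alignment."""
    short, long_ = sorted((len(rep_seq), len(seq)))
    # overlap can never exceed the shorter length, so this bound is exact
    if short < cfg.cluster_coverage * long_ - _EPS:
        return False
    if seq == rep_seq or seq in rep_seq or rep_seq in seq:
        return True  # containment: identity 1.0, overlap == shorter length
    matches, overlap, _ = best_overlap(rep_enc, seq_enc)
    if matches / overlap < cfg.cluster_identity - _EPS:
        return False
    return overlap >= cfg.cluster_coverage * long_ - _EPS


def cluster_greedy(
    seqs: list[tuple[str, str]], cfg: PipelineConfig
) -> list[Cluster]:
    """Greedy first-fit clustering, longest sequence first (ties: id order).

    Returns clusters in founding order; every input id lands in exactly one
    cluster and each representative is at least as long as its members.
    """
    order = sorted(seqs, key=lambda item: (-len(item[1]), item[0]))
    clusters: list[Cluster] = []
    rep_seqs: list[str] = []
    rep_encs: list[np.ndarray] = []
    decided: dict[str, int] = {}  # sequence -> cluster index (dedup fast path)

    for sid, seq in order:
        idx = decided.get(seq)
        if idx is None:
            enc = encode(seq)
            for j, rep_seq in enumerate(rep_seqs):
                if _satisfies(rep_seq, rep_encs[j], seq, enc, cfg):
                    idx = j
                    break
            if idx is None:
                idx = len(clusters)
                clusters.append(Cluster(representative_id=sid))
                rep_seqs.append(seq)
                rep_encs.append(enc)
            decided[seq] = idx
        clusters[idx].member_ids.append(sid)
    return clusters


def write_clusters(clusters: list[Cluster], path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("cluster_id\trepresentative_id\tmember_id\n")
        for i, cl in enumerate(clusters):
            for mid in cl.member_ids:
                out.write(f"{i}\t{cl.representative_id}\t{mid}\n")


def write_representatives(
    clusters: list[Cluster], seq_by_id: dict[str, str], path: str | Path
) -> None:
    with open(path, "w") as out:
        for i, cl in enumerate(clusters):
            out.write(
                f">{cl.representative_id} cluster={i} size={cl.size}\n"
                f"{seq_by_id[cl.representative_id]}\n"
            )
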