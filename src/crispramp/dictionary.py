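"""Mismatch-tolerant unification of spacer sequences into numbered identities.

Observed spacer sequences are collapsed onto canonical sequences with a
greedy, abundance-first star topology: a sequence joins the first existing
identity whose canonical has the same length and is within
``spacer_max_mismatch`` substitutions; otherwise it founds a new identity.
Indel-bearing variants therefore always found new identities.  Identity
numbers continue after the largest id of any pre-seeded reference catalog,
so catalog ids stay stable across runs.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._seq import encode
from .spacers import STATUS_OK, ExtractionResult


class ConsistencyError(RuntimeError):
    """Internal pipeline invariant violated (e.g. an unmapped spacer)."""


@dataclass
class SpacerIdentity:
    spacer_id: int
    canonical_sequence: str
    abundance: int = 0  # read-weighted occurrences seen in this run


@dataclass
class SpacerArray:
    """The ordered spacer ids of one amplicon, leader-end (newest) first."""

    amplicon_id: str
    ids: tuple[int, ...]
    weight: int = 1  # cluster size, i.e. read count represented
    sample_id: str | None = None

    def __len__(self) -> int:
        return len(self.ids)


def build_dictionary(
    spacers: Iterable[tuple[str, int]],
    max_mismatch: int,
    existing: Sequence[SpacerIdentity] = (),
) -> tuple[list[SpacerIdentity], dict[str, int]]:
    """Unify weighted spacer sequences into identities.

    Parameters
    ----------
    spacers : iterable of (sequence, weight)
        One entry per spacer occurrence; weights are read counts.
    max_mismatch : int
        Hamming tolerance for joining an existing identity (equal lengths only).
    existing : reference identities (e.g. the catalog), matched first in id order.

    Returns the full identity list (existing entries first, abundances updated
    in place on copies) and a mapping from every distinct observed sequence to
    its spacer id.  Unique sequences are processed by decreasing total weight
    (ties: lexicographic), so the canonical of each new identity is its most
    abundant — likely error-free — form.
    """
    totals: dict[str, int] = defaultdict(int)
    for seq, weight in spacers:
        totals[seq] += int(weight)

    identities = [
        SpacerIdentity(e.spacer_id, e.canonical_sequence, 0)
        for e in sorted(existing, key=lambda e: e.spacer_id)
    ]
    if len({e.spacer_id for e in identities}) != len(identities):
        raise ValueError("existing identities carry duplicate spacer ids")
    by_length: dict[int, list[SpacerIdentity]] = defaultdict(list)
    encodings: dict[int, np.ndarray] = {}
    for ident in identities:
        by_length[len(ident.canonical_sequence)].append(ident)
        encodings[ident.spacer_id] = encode(ident.canonical_sequence)

    next_id = max((e.spacer_id for e in identities), default=0) + 1
    mapping: dict[str, int] = {}
    for seq in sorted(totals, key=lambda s: (-totals[s], s)):
        enc = encode(seq)
        assigned = None
        for ident in by_length[len(seq)]:  # founding order within a length class
            if int(np.count_nonzero(encodings[ident.spacer_id] != enc)) <= max_mismatch:
                assigned = ident
                break
        if assigned is None:
            assigned = SpacerIdentity(next_id, seq, 0)
            next_id += 1
            identities.append(assigned)
            by_length[len(seq)].append(assigned)
            encodings[assigned.spacer_id] = enc
        assigned.abundance += totals[seq]
        mapping[seq] = assigned.spacer_id
    return identities, mapping


def arrays_from_amplicons(
    extractions: Iterable[ExtractionResult],
    mapping: Mapping[str, int],
    weights: Mapping[str, int] | None = None,
    samples: Mapping[str, str] | None = None,
) -> list[SpacerArray]:
    """One :class:`SpacerArray` per successfully extracted amplicon.

    Leader-first spacer order is preserved; ``weights`` carries cluster sizes
    (default 1) and ``samples`` optional sample labels, both keyed by
    amplicon id.  A spacer sequence missing from ``mapping`` is an internal
    consistency error.
    """
    arrays: list[SpacerArray] = []
    for res in extractions:
        if res.status != STATUS_OK:
            continue
        ids = []
        for sp in sorted(res.spacers, key=lambda s: s.position_from_leader):
            try:
                ids.append(mapping[sp.sequence])
            except KeyError as exc:
                raise ConsistencyError(
                    f"spacer of {res.amplicon_id} has no dictionary assignment"
                ) from exc
        arrays.append(
            SpacerArray(
                amplicon_id=res.amplicon_id,
                ids=tuple(ids),
                weight=int(weights[res.amplicon_id]) if weights else 1,
                sample_id=samples.get(res.amplicon_id) if samples else None,
            )
        )
    return arrays


def write_dictionary(identities: Sequence[SpacerIdentity], path) -> None:
    with open(path, "w") as out:
        for ident in identities:
            out.write(
                f">{ident.spacer_id} abundance={ident.abundance}\n"
                f"{ident.canonical_sequence}\n"
            )


def write_arrays(arrays: Sequence[SpacerArray], path) -> None:
    with open(path, "w") as out:
        out.write("amplicon_id\tsample_id\tweight\tspacer_ids\n")
        for arr in arrays:
            ids = ",".join(str(i) for i in arr.ids)
            out.write(f"{arr.amplicon_id}\t{arr.sample_id or ''}\t{arr.weight}\t{ids}\n")
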