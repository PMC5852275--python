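"""Leader-end variant classes of an assigned genotype.

Within a CT, arrays split into four exhaustive, mutually exclusive classes
relative to the origin repertoire:

* ``origin``    — a contiguous prefix of the origin repertoire;
* ``new_plus``  — one or more novel leader-end spacers followed by an origin prefix;
* ``proto``     — a contiguous origin block starting at position >= 2
  (the leader-end spacers are older than the origin's newest);
* ``others``    — everything else (deletions, internal novelties, trailing novel ids).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .dictionary import SpacerArray

ORIGIN = "origin"
NEW_PLUS = "new_plus"
PROTO = "proto"
OTHERS = "others"
VARIANT_CLASSES = (ORIGIN, NEW_PLUS, PROTO, OTHERS)


@dataclass
class VariantCall:
    amplicon_id: str
    ct_label: str
    variant: str
    leading_novel: int
    start_position_in_origin: int | None  # 1-based; None for `others`


def classify_variant(
    arr: SpacerArray, origin: Sequence[int], ct_label: str = ""
) -> VariantCall:
    """Classify one assigned array against its CT's origin repertoire.

    The array is split into a maximal leading block of novel ids (ids absent
    from the origin repertoire) and a remainder; the remainder decides the
    class.  Raises if the array shares nothing with the origin — such an
    array should never have been assigned.
    """
    origin = tuple(origin)
    origin_set = set(origin)
    ids = arr.ids
    lead = 0
    while lead < len(ids) and ids[lead] not in origin_set:
        lead += 1
    remainder = ids[lead:]
    if not remainder:
        raise ValueError(
            f"{arr.amplicon_id}: array shares no spacers with the origin repertoire"
        )

    j = origin.index(remainder[0])  # remainder[0] is in origin by construction
    contiguous = remainder == origin[j : j + len(remainder)]

    if contiguous and j == 0:
        variant = ORIGIN if lead == 0 else NEW_PLUS
        start = 1
    elif contiguous and lead == 0:  # j >= 1
        variant, start = PROTO, j + 1
    else:
        variant, start = OTHERS, None
    return VariantCall(arr.amplicon_id, ct_label, variant, lead, start)


def variant_trajectories(
    calls: Sequence[VariantCall],
    samples: Mapping[str, str],
    weights: Mapping[str, int],
) -> pd.DataFrame:
    """Weight-summed per-sample, per-CT variant fractions.

    ``samples`` and ``weights`` are keyed by amplicon id.  Each returned row
    holds the four class fractions for one (sample, CT) with nonzero total;
    absent combinations are omitted, and fractions sum to 1 per row.
    """
    sums: dict[tuple[str, str], dict[str, float]] = defaultdict(
        lambda: {v: 0.0 for v in VARIANT_CLASSES}
    )
    for call in calls:
        key = (samples[call.amplicon_id], call.ct_label)
        sums[key][call.variant] += weights[call.amplicon_id]

    rows = []
    for (sample, ct), class_weights in sorted(sums.items()):
        total = sum(class_weights.values())
        if total <= 0:
            continue
        row = {"sample_id": sample, "ct": ct, "total_weight": total}
        for v in VARIANT_CLASSES:
            row[v] = class_weights[v] / total
        rows.append(row)
    return pd.DataFrame(
        rows, columns=["sample_id", "ct", "total_weight", *VARIANT_CLASSES]
    )


def write_variant_calls(
    calls: Sequence[VariantCall], weights: Mapping[str, int], path
) -> None:
    with open(path, "w") as out:
        out.write(
            "amplicon_id\tct\tvariant\tleading_novel\tstart_position_in_origin\tweight\n"
        )
        for c in calls:
            start = "" if c.start_position_in_origin is None else c.start_position_in_origin
            out.write(
                f"{c.amplicon_id}\t{c.ct_label}\t{c.variant}\t{c.leading_novel}\t"
                f"{start}\t{weights.get(c.amplicon_id, 1)}\n"
            )
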