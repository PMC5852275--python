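"""CRISPR genotype (CT) assignment, singleton discard, and new-CT definition.

A CT is an ordered leader-end spacer repertoire; repertoires are disjoint
across CTs, so the catalog ids occurring in an array identify at most one
genotype.  Arrays whose catalog ids respect the repertoire's relative order
are assigned; arrays mixing two genotypes or scrambling the order are
reported as ambiguous, never resolved by majority.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .dictionary import SpacerArray

# Non-CT assignment labels
CANDIDATE_NEW = "candidate_new"
DISCARDED_NOVEL = "discarded_novel_1or2"
DISCARDED_SINGLETON = "discarded_singleton"
UNASSIGNED_AMBIGUOUS = "unassigned_ambiguous"
NON_CT_LABELS = frozenset(
    {CANDIDATE_NEW, DISCARDED_NOVEL, DISCARDED_SINGLETON, UNASSIGNED_AMBIGUOUS}
)

PROVENANCE_REFERENCE = "reference"
PROVENANCE_NEW = "new_this_run"


class CatalogError(ValueError):
    """Invalid CT catalog (overlapping repertoires, empty entries, ...)."""


@dataclass
class CTCatalog:
    """Mapping from CT label to its ordered origin spacer repertoire."""

    entries: dict[str, tuple[int, ...]] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)
    spacer_sequences: dict[int, str] = field(default_factory=dict)

    def validate(self) -> None:
        seen: dict[int, str] = {}
        for label, repertoire in self.entries.items():
            if not repertoire:
                raise CatalogError(f"{label}: empty spacer repertoire")
            for sid in repertoire:
                if sid in seen and seen[sid] != label:
                    raise CatalogError(
                        f"spacer {sid} occurs in both {seen[sid]} and {label}"
                    )
                seen[sid] = label

    @property
    def spacer_to_ct(self) -> dict[int, str]:
        out: dict[int, str] = {}
        for label, repertoire in self.entries.items():
            for sid in repertoire:
                out[sid] = label
        return out

    @property
    def max_spacer_id(self) -> int:
        ids = [s for rep in self.entries.values() for s in rep]
        ids += list(self.spacer_sequences)
        return max(ids, default=0)

    def next_label(self, prefix: str = "CT") -> str:
        best = 0
        for label in self.entries:
            m = re.fullmatch(rf"{re.escape(prefix)}(\d+)", label)
            if m:
                best = max(best, int(m.group(1)))
        return f"{prefix}{best + 1}"

    def copy(self) -> "CTCatalog":
        return CTCatalog(
            dict(self.entries), dict(self.provenance), dict(self.spacer_sequences)
        )


@dataclass
class CTAssignment:
    amplicon_id: str
    label: str  # a CT label or one of the NON_CT_LABELS
    novel_count: int
    matched_ids: tuple[int, ...]

    @property
    def is_assigned(self) -> bool:
        return self.label not in NON_CT_LABELS


def assign_ct(
    arr: SpacerArray, catalog: CTCatalog, min_novel_for_new: int = 3
) -> CTAssignment:
    """Assign one spacer array to a genotype.

    The catalog ids present in the array must all belong to one CT and occur
    in the same relative order as that CT's repertoire; otherwise the array
    is ambiguous.  Arrays with no catalog ids become new-CT candidates when
    they carry at least ``min_novel_for_new`` novel spacers and are discarded
    otherwise.  A single-spacer array whose id belongs to a CT is assigned
    to that CT.
    """
    s2c = catalog.spacer_to_ct
    matched = tuple(i for i in arr.ids if i in s2c)
    novel_count = len(arr.ids) - len(matched)

    if not matched:
        label = CANDIDATE_NEW if novel_count >= min_novel_for_new else DISCARDED_NOVEL
        return CTAssignment(arr.amplicon_id, label, novel_count, matched)

    cts = {s2c[i] for i in matched}
    if len(cts) > 1:
        return CTAssignment(arr.amplicon_id, UNASSIGNED_AMBIGUOUS, novel_count, matched)
    (ct,) = cts
    repertoire = catalog.entries[ct]
    positions = [repertoire.index(i) for i in matched]
    if all(p2 > p1 for p1, p2 in zip(positions, positions[1:])):
        return CTAssignment(arr.amplicon_id, ct, novel_count, matched)
    return CTAssignment(arr.amplicon_id, UNASSIGNED_AMBIGUOUS, novel_count, matched)


def discard_singletons(
    assignments: Sequence[CTAssignment], arrays: Sequence[SpacerArray]
) -> tuple[list[CTAssignment], dict]:
    """Relabel assignments whose distinct id-array has dataset-wide weight 1.

    Returns the updated assignment list plus a report with the singleton
    fraction of total weight.
    """
    if len(assignments) != len(arrays):
        raise ValueError("assignments and arrays must be parallel")
    weight_by_array: dict[tuple[int, ...], int] = defaultdict(int)
    for arr in arrays:
        weight_by_array[arr.ids] += arr.weight
    total = sum(arr.weight for arr in arrays)

    out: list[CTAssignment] = []
    singleton_weight = 0
    for asg, arr in zip(assignments, arrays):
        if weight_by_array[arr.ids] == 1:
            singleton_weight += arr.weight
            out.append(
                CTAssignment(
                    asg.amplicon_id, DISCARDED_SINGLETON, asg.novel_count,
                    asg.matched_ids,
                )
            )
        else:
            out.append(asg)
    report = {
        "total_weight": total,
        "singleton_weight": singleton_weight,
        "singleton_fraction": singleton_weight / total if total else 0.0,
    }
    return out, report


def define_new_cts(
    candidates: Sequence[SpacerArray],
    catalog: CTCatalog,
    next_label: str | None = None,
) -> tuple[CTCatalog, list[CTAssignment]]:
    """Group all-novel candidate arrays into new genotypes.

    Candidates sharing at least one spacer id in a consistent relative order
    are grouped (connected components of the sharing relation); each group
    becomes one CT whose origin repertoire is the group's longest array
    (ties: highest weight, then lexicographic amplicon id).  A candidate
    that alone links otherwise-disjoint groups (a cut vertex of the sharing
    graph), or whose shared ids conflict with its group origin's order,
    stays ``unassigned_ambiguous`` and modifies nothing.  Labels are
    assigned sequentially starting at ``next_label`` (default: one past the
    catalog's highest numeric label).

    Returns the updated catalog (disjointness re-validated) and one
    assignment per candidate.
    """
    s2c = catalog.spacer_to_ct
    for arr in candidates:
        if any(i in s2c for i in arr.ids):
            raise ValueError(
                f"{arr.amplicon_id}: candidate for a new CT contains catalog spacers"
            )

    n = len(candidates)
    id_sets = [set(arr.ids) for arr in candidates]
    adjacency: list[list[int]] = [[] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if id_sets[i] & id_sets[j]:
                adjacency[i].append(j)
                adjacency[j].append(i)

    def components(excluded: set[int]) -> list[set[int]]:
        seen: set[int] = set(excluded)
        out = []
        for start in range(n):
            if start in seen:
                continue
            comp = {start}
            stack = [start]
            seen.add(start)
            while stack:
                v = stack.pop()
                for w in adjacency[v]:
                    if w not in seen:
                        seen.add(w)
                        comp.add(w)
                        stack.append(w)
            out.append(comp)
        return out

    # a candidate bridging otherwise-disjoint groups is ambiguous, not a glue
    bridges: set[int] = set()
    all_nodes = set(range(n))
    for comp in components(set()):
        for v in comp:
            rest = comp - {v}
            if len(rest) >= 2 and len(components(all_nodes - rest)) > 1:
                bridges.add(v)

    sort_key = lambda i: (
        -len(candidates[i].ids),
        -candidates[i].weight,
        candidates[i].amplicon_id,
    )
    groups: list[dict] = []
    ambiguous: list[SpacerArray] = [candidates[i] for i in sorted(bridges, key=sort_key)]
    for comp in components(bridges):
        members = sorted(comp, key=sort_key)
        origin = candidates[members[0]]
        group = {"origin": origin, "members": [origin]}
        for i in members[1:]:
            arr = candidates[i]
            shared = [origin.ids.index(x) for x in arr.ids if x in set(origin.ids)]
            if all(b > a for a, b in zip(shared, shared[1:])):
                group["members"].append(arr)
            else:
                ambiguous.append(arr)
        groups.append(group)
    groups.sort(key=lambda g: (
        -len(g["origin"].ids), -g["origin"].weight, g["origin"].amplicon_id,
    ))

    updated = catalog.copy()
    if next_label is None:
        next_label = updated.next_label()
    m = re.fullmatch(r"([A-Za-z_]*)(\d+)", next_label)
    if not m:
        raise ValueError(f"next_label {next_label!r} must end in a number")
    prefix, num = m.group(1), int(m.group(2))

    assignments: list[CTAssignment] = []
    for group in groups:
        label = f"{prefix}{num}"
        num += 1
        updated.entries[label] = group["origin"].ids
        updated.provenance[label] = PROVENANCE_NEW
        for arr in group["members"]:
            assignments.append(
                CTAssignment(arr.amplicon_id, label, len(arr.ids), ())
            )
    for arr in ambiguous:
        assignments.append(
            CTAssignment(arr.amplicon_id, UNASSIGNED_AMBIGUOUS, len(arr.ids), ())
        )
    updated.validate()

    # return assignments in the original candidate order
    by_id = {a.amplicon_id: a for a in assignments}
    return updated, [by_id[arr.amplicon_id] for arr in candidates]


def load_catalog(path: str | Path) -> CTCatalog:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or "cts" not in raw:
        raise CatalogError(f"{path}: expected a mapping with a 'cts' section")
    entries: dict[str, tuple[int, ...]] = {}
    provenance: dict[str, str] = {}
    for label, rec in raw["cts"].items():
        entries[str(label)] = tuple(int(i) for i in rec["spacers"])
        provenance[str(label)] = str(rec.get("provenance", PROVENANCE_REFERENCE))
    sequences = {
        int(sid): str(seq) for sid, seq in (raw.get("spacers") or {}).items()
    }
    catalog = CTCatalog(entries, provenance, sequences)
    catalog.validate()
    return catalog


def write_catalog(catalog: CTCatalog, path: str | Path) -> None:
    raw = {
        "cts": {
            label: {
                "provenance": catalog.provenance.get(label, PROVENANCE_REFERENCE),
                "spacers": list(repertoire),
            }
            for label, repertoire in sorted(catalog.entries.items())
        },
        "spacers": {
            sid: seq for sid, seq in sorted(catalog.spacer_sequences.items())
        },
    }
    Path(path).write_text(yaml.safe_dump(raw, sort_keys=True))


def write_assignments(
    assignments: Iterable[CTAssignment],
    samples: Mapping[str, str] | None,
    path: str | Path,
) -> None:
    with open(path, "w") as out:
        out.write("amplicon_id\tsample_id\tlabel\tnovel_count\tmatched_ids\n")
        for asg in assignments:
            sample = samples.get(asg.amplicon_id, "") if samples else ""
            ids = ",".join(str(i) for i in asg.matched_ids)
            out.write(
                f"{asg.amplicon_id}\t{sample}\t{asg.label}\t{asg.novel_count}\t{ids}\n"
            )
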