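"""End-to-end orchestration of the amplicon typing pipeline.

Per sample: trim/filter/merge, cluster, extract spacers from cluster
representatives.  Pooled across samples: spacer dictionary (seeded from the
reference catalog), genotype assignment with singleton discard and new-CT
definition, variant classification, per-sample profiles, diversity
statistics and figure-ready trajectory tables.  All downstream weights are
cluster sizes, i.e. read counts.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import clustering, reads
from .clustering import Cluster
from .ct_typing import (
    CANDIDATE_NEW,
    CTAssignment,
    CTCatalog,
    NON_CT_LABELS,
    assign_ct,
    define_new_cts,
    discard_singletons,
    load_catalog,
    write_assignments,
    write_catalog,
)
from .dictionary import (
    SpacerArray,
    SpacerIdentity,
    arrays_from_amplicons,
    build_dictionary,
    write_arrays,
    write_dictionary,
)
from .diversity import DiversityStats, sample_stats
from .model import MergedAmplicon, PipelineConfig
from .spacers import ExtractionResult, extract_spacers, write_spacers, write_status
from .variants import (
    VARIANT_CLASSES,
    VariantCall,
    classify_variant,
    variant_trajectories,
    write_variant_calls,
)

UNASSIGNED_BIN = "unassigned"
RARE_BIN = "rare"


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and record."""


@dataclass
class SampleStage:
    sample_id: str
    attrition: list[dict]
    merged: list[MergedAmplicon]
    clusters: list[Cluster]
    extractions: list[ExtractionResult]
    member_to_rep: dict[str, str]  # member read id -> representative key


@dataclass
class PipelineResult:
    cfg: PipelineConfig
    catalog: CTCatalog  # updated with new CTs defined in this run
    per_sample: dict[str, SampleStage]
    identities: list[SpacerIdentity]
    spacer_mapping: dict[str, int]
    arrays: list[SpacerArray]
    assignments: list[CTAssignment]  # parallel to arrays
    variant_calls: list[VariantCall]
    weights: dict[str, int]  # amplicon key -> cluster size
    samples_of: dict[str, str]  # amplicon key -> sample id
    singleton_report: dict
    sample_profiles: pd.DataFrame = field(default_factory=pd.DataFrame)
    pooled_fractions: pd.DataFrame = field(default_factory=pd.DataFrame)
    dominant_cts: list[str] = field(default_factory=list)
    diversity: list[DiversityStats] = field(default_factory=list)
    trajectories: pd.DataFrame = field(default_factory=pd.DataFrame)

    def assignment_of(self, amplicon_key: str) -> CTAssignment | None:
        return self._assignment_index().get(amplicon_key)

    def _assignment_index(self) -> dict[str, CTAssignment]:
        if not hasattr(self, "_asg_index"):
            self._asg_index = {a.amplicon_id: a for a in self.assignments}
        return self._asg_index

    def read_level_calls(self) -> pd.DataFrame:
        """Per input read pair: final genotype label and variant class.

        Follows each surviving read through its cluster to the representative's
        assignment.  Columns: sample_id, read_pair_id, label, variant.
        """
        variant_of = {c.amplicon_id: c.variant for c in self.variant_calls}
        rows = []
        for sample_id, stage in self.per_sample.items():
            for member, rep_key in stage.member_to_rep.items():
                asg = self.assignment_of(rep_key)
                if asg is None:
                    continue
                rows.append(
                    {
                        "sample_id": sample_id,
                        "read_pair_id": member,
                        "label": asg.label,
                        "variant": variant_of.get(rep_key, ""),
                    }
                )
        return pd.DataFrame(
            rows, columns=["sample_id", "read_pair_id", "label", "variant"]
        )


def _sample_stage(
    sample_id: str, pairs: Sequence[tuple], cfg: PipelineConfig
) -> SampleStage:
    read_result = reads.process_pairs(pairs, cfg)
    seqs = [(amp.amplicon_id, amp.sequence) for amp in read_result.merged]
    clusters = clustering.cluster_greedy(seqs, cfg)
    seq_by_id = dict(seqs)
    extractions = []
    member_to_rep: dict[str, str] = {}
    for cl in clusters:
        key = f"{sample_id}|{cl.representative_id}"
        extractions.append(
            extract_spacers(key, seq_by_id[cl.representative_id], cfg)
        )
        for member in cl.member_ids:
            member_to_rep[member] = key
    return SampleStage(
        sample_id=sample_id,
        attrition=read_result.attrition,
        merged=read_result.merged,
        clusters=clusters,
        extractions=extractions,
        member_to_rep=member_to_rep,
    )


def run_pipeline_samples(
    sample_pairs: Sequence[tuple[str, Sequence[tuple]]],
    catalog: CTCatalog,
    cfg: PipelineConfig,
) -> PipelineResult:
    """Run the full pipeline on in-memory read pairs.

    ``sample_pairs`` is a list of ``(sample_id, [(r1, r2), ...])``.  The
    spacer dictionary, genotype definitions and singleton rule are pooled
    over all samples.
    """
    catalog.validate()
    per_sample: dict[str, SampleStage] = {}
    for sample_id, pairs in sample_pairs:
        try:
            per_sample[sample_id] = _sample_stage(sample_id, pairs, cfg)
        except Exception as exc:  # pragma: no cover - defensive
            raise PipelineError(f"sample stage failed for {sample_id}: {exc}") from exc

    weights: dict[str, int] = {}
    samples_of: dict[str, str] = {}
    occurrences: list[tuple[str, int]] = []
    all_extractions: list[ExtractionResult] = []
    for sample_id, stage in per_sample.items():
        for cl, res in zip(stage.clusters, stage.extractions):
            key = res.amplicon_id
            weights[key] = cl.size
            samples_of[key] = sample_id
            all_extractions.append(res)
            for sp in res.spacers:
                occurrences.append((sp.sequence, cl.size))

    existing = [
        SpacerIdentity(sid, seq) for sid, seq in sorted(catalog.spacer_sequences.items())
    ]
    identities, mapping = build_dictionary(
        occurrences, cfg.spacer_max_mismatch, existing
    )
    arrays = arrays_from_amplicons(all_extractions, mapping, weights, samples_of)

    assignments = [assign_ct(arr, catalog, cfg.new_ct_min_novel) for arr in arrays]
    assignments, singleton_report = discard_singletons(assignments, arrays)

    candidates = [
        arr
        for arr, asg in zip(arrays, assignments)
        if asg.label == CANDIDATE_NEW
    ]
    updated_catalog, cand_assignments = define_new_cts(candidates, catalog)
    cand_by_id = {a.amplicon_id: a for a in cand_assignments}
    assignments = [
        cand_by_id.get(asg.amplicon_id, asg) if asg.label == CANDIDATE_NEW else asg
        for asg in assignments
    ]
    # record canonical sequences for ids minted in this run
    seq_by_id = {i.spacer_id: i.canonical_sequence for i in identities}
    for repertoire in updated_catalog.entries.values():
        for sid in repertoire:
            updated_catalog.spacer_sequences.setdefault(sid, seq_by_id.get(sid, ""))

    variant_calls = []
    for arr, asg in zip(arrays, assignments):
        if asg.label in NON_CT_LABELS:
            continue
        variant_calls.append(
            classify_variant(arr, updated_catalog.entries[asg.label], asg.label)
        )

    result = PipelineResult(
        cfg=cfg,
        catalog=updated_catalog,
        per_sample=per_sample,
        identities=identities,
        spacer_mapping=mapping,
        arrays=arrays,
        assignments=assignments,
        variant_calls=variant_calls,
        weights=weights,
        samples_of=samples_of,
        singleton_report=singleton_report,
    )
    _summarize(result)
    return result


def _summarize(result: PipelineResult) -> None:
    cfg = result.cfg
    ct_weight: dict[tuple[str, str], int] = defaultdict(int)  # (sample, label)
    sample_total: dict[str, int] = defaultdict(int)
    for arr, asg in zip(result.arrays, result.assignments):
        sample = arr.sample_id or ""
        label = asg.label if asg.is_assigned else UNASSIGNED_BIN
        ct_weight[(sample, label)] += arr.weight
        sample_total[sample] += arr.weight
    for sample_id in result.per_sample:
        sample_total.setdefault(sample_id, 0)

    pooled: dict[str, int] = defaultdict(int)
    for (sample, label), w in ct_weight.items():
        pooled[label] += w
    pooled_total = sum(pooled.values())
    assigned_total = sum(w for lbl, w in pooled.items() if lbl != UNASSIGNED_BIN)

    pooled_rows = []
    for label, w in sorted(pooled.items(), key=lambda kv: (-kv[1], kv[0])):
        frac = w / pooled_total if pooled_total else 0.0
        pooled_rows.append(
            {
                "ct": label,
                "weight": w,
                "fraction_of_total": frac,
                "fraction_of_assigned": (
                    w / assigned_total
                    if assigned_total and label != UNASSIGNED_BIN
                    else 0.0
                ),
                "dominant": label != UNASSIGNED_BIN
                and frac > cfg.dominance_threshold,
            }
        )
    result.pooled_fractions = pd.DataFrame(
        pooled_rows,
        columns=["ct", "weight", "fraction_of_total", "fraction_of_assigned", "dominant"],
    )
    result.dominant_cts = [r["ct"] for r in pooled_rows if r["dominant"]]

    profile_rows = []
    for (sample, label), w in sorted(ct_weight.items()):
        total = sample_total[sample]
        frac = w / total if total else 0.0
        profile_rows.append(
            {
                "sample_id": sample,
                "ct": label,
                "weight": w,
                "fraction": frac,
                "dominant": label != UNASSIGNED_BIN and frac > cfg.dominance_threshold,
            }
        )
    result.sample_profiles = pd.DataFrame(
        profile_rows, columns=["sample_id", "ct", "weight", "fraction", "dominant"]
    )

    result.diversity = []
    for sample_id in result.per_sample:
        counts = {
            label: w
            for (s, label), w in ct_weight.items()
            if s == sample_id and label != UNASSIGNED_BIN
        }
        if counts:
            result.diversity.append(sample_stats(sample_id, counts))

    samples_map = {arr.amplicon_id: arr.sample_id or "" for arr in result.arrays}
    result.trajectories = variant_trajectories(
        result.variant_calls, samples_map, result.weights
    )


def report_tables(result: PipelineResult, focus_ct: str | None = None) -> dict:
    """Figure-ready tables: pooled fractions (rare CTs binned), per-sample
    dominant-CT trajectories, per-CT variant fractions, and the variant
    trajectory of ``focus_ct``."""
    pooled = result.pooled_fractions
    rare_weight = int(
        pooled.loc[~pooled["dominant"] & (pooled["ct"] != UNASSIGNED_BIN), "weight"].sum()
    )
    fig1 = pooled[pooled["dominant"]][["ct", "weight", "fraction_of_total"]].copy()
    total = pooled["weight"].sum()
    extra = [
        {
            "ct": RARE_BIN,
            "weight": rare_weight,
            "fraction_of_total": rare_weight / total if total else 0.0,
        }
    ]
    unassigned = pooled[pooled["ct"] == UNASSIGNED_BIN]
    if len(unassigned):
        extra.append(
            {
                "ct": UNASSIGNED_BIN,
                "weight": int(unassigned["weight"].iloc[0]),
                "fraction_of_total": float(unassigned["fraction_of_total"].iloc[0]),
            }
        )
    fig1 = pd.concat([fig1, pd.DataFrame(extra)], ignore_index=True)

    profiles = result.sample_profiles
    fig2 = profiles[profiles["ct"].isin(result.dominant_cts)][
        ["sample_id", "ct", "fraction"]
    ].reset_index(drop=True)

    pooled_variant: dict[str, dict[str, float]] = defaultdict(
        lambda: {v: 0.0 for v in VARIANT_CLASSES}
    )
    for call in result.variant_calls:
        pooled_variant[call.ct_label][call.variant] += result.weights[
            call.amplicon_id
        ]
    fig3_rows = []
    for ct in sorted(pooled_variant):
        class_weights = pooled_variant[ct]
        ct_total = sum(class_weights.values())
        row = {"ct": ct, "total_weight": ct_total}
        for v in VARIANT_CLASSES:
            row[v] = class_weights[v] / ct_total if ct_total else 0.0
        fig3_rows.append(row)
    fig3 = pd.DataFrame(fig3_rows, columns=["ct", "total_weight", *VARIANT_CLASSES])

    tables = {"fig1": fig1, "fig2": fig2, "fig3": fig3}
    if focus_ct is not None:
        available = sorted({c.ct_label for c in result.variant_calls})
        if focus_ct not in available:
            raise KeyError(
                f"CT {focus_ct!r} not present in this run; available: {available}"
            )
        traj = result.trajectories
        tables["fig4"] = traj[traj["ct"] == focus_ct].reset_index(drop=True)
    return tables


def write_outputs(result: PipelineResult, outdir: str | Path) -> Path:
    """Write every artifact of a run; identical runs write identical bytes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    for sample_id, stage in result.per_sample.items():
        sdir = outdir / sample_id
        sdir.mkdir(exist_ok=True)
        pd.DataFrame(stage.attrition).to_csv(
            sdir / "attrition.tsv", sep="\t", index=False
        )
        reads.write_fastq(stage.merged, sdir / "merged.fastq")
        clustering.write_clusters(stage.clusters, sdir / "clusters.tsv")
        seq_by_id = {amp.amplicon_id: amp.sequence for amp in stage.merged}
        clustering.write_representatives(
            stage.clusters, seq_by_id, sdir / "representatives.fasta"
        )
        write_spacers(stage.extractions, sdir / "spacers.fasta")
        write_status(stage.extractions, sdir / "extraction_status.tsv")

    pooled = outdir / "pooled"
    pooled.mkdir(exist_ok=True)
    write_dictionary(result.identities, pooled / "dictionary.fasta")
    write_arrays(result.arrays, pooled / "arrays.tsv")
    write_assignments(result.assignments, result.samples_of, pooled / "assignments.tsv")
    write_catalog(result.catalog, pooled / "catalog.yaml")
    write_variant_calls(
        result.variant_calls, result.weights, pooled / "variant_calls.tsv"
    )
    result.sample_profiles.to_csv(
        pooled / "sample_profiles.tsv", sep="\t", index=False, float_format="%.8g"
    )
    result.pooled_fractions.to_csv(
        pooled / "pooled_fractions.tsv", sep="\t", index=False, float_format="%.8g"
    )
    result.trajectories.to_csv(
        pooled / "variant_trajectories.tsv", sep="\t", index=False, float_format="%.8g"
    )

    with open(pooled / "diversity.tsv", "w") as out:
        out.write("sample_id\ts_obs\tf1\tf2\tchao1\tshannon_h\n")
        for d in result.diversity:
            out.write(
                f"{d.sample_id}\t{d.s_obs}\t{d.f1}\t{d.f2}\t"
                f"{d.chao1:.8g}\t{d.shannon_h:.8g}\n"
            )
    with open(pooled / "rarefaction.tsv", "w") as out:
        out.write("sample_id\tn\texpected_richness\n")
        for d in result.diversity:
            for n, e in d.rarefaction:
                out.write(f"{d.sample_id}\t{n}\t{e:.8g}\n")

    tables = report_tables(result)
    for name, table in tables.items():
        table.to_csv(
            pooled / f"{name}_table.tsv", sep="\t", index=False, float_format="%.8g"
        )

    with open(outdir / "run_log.txt", "w") as log:
        log.write("# pipeline run log\n\n[config]\n")
        for key, value in sorted(result.cfg.as_dict().items()):
            log.write(f"{key} = {value}\n")
        log.write("\n[stages]\n")
        for sample_id, stage in result.per_sample.items():
            for row in stage.attrition:
                log.write(
                    f"{sample_id}\t{row['stage']}\t{row['pairs_in']}\t"
                    f"{row['pairs_out']}\t{row['detail']}\n"
                )
        log.write("\n[pooled]\n")
        n_new = sum(
            1 for p in result.catalog.provenance.values() if p == "new_this_run"
        )
        label_counts = defaultdict(int)
        for asg, arr in zip(result.assignments, result.arrays):
            label_counts[asg.label if not asg.is_assigned else "assigned"] += arr.weight
        for label, count in sorted(label_counts.items()):
            log.write(f"weight_{label} = {count}\n")
        log.write(f"new_cts_defined = {n_new}\n")
        log.write(
            "singleton_fraction = "
            f"{result.singleton_report['singleton_fraction']:.8g}\n"
        )
        log.write(f"dominant_cts = {','.join(result.dominant_cts)}\n")
    return outdir


def run_pipeline(
    samples: Sequence[tuple[str, str | Path, str | Path]],
    catalog_path: str | Path,
    cfg: PipelineConfig,
    outdir: str | Path,
) -> PipelineResult:
    """File-based entry point: FASTQ pairs in, output directory out."""
    catalog = load_catalog(catalog_path)
    sample_pairs = []
    for sample_id, r1_path, r2_path in samples:
        r1 = reads.read_fastq(r1_path, "R1")
        r2 = reads.read_fastq(r2_path, "R2")
        if len(r1) != len(r2):
            raise PipelineError(
                f"sample {sample_id}: R1/R2 read counts differ "
                f"({len(r1)} vs {len(r2)})"
            )
        sample_pairs.append((sample_id, list(zip(r1, r2))))
    result = run_pipeline_samples(sample_pairs, catalog, cfg)
    write_outputs(result, outdir)
    return result
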