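"""Synthetic amplicon data with known genotype and variant structure.

Generates a reference CT catalog with disjoint spacer repertoires, seasonal
per-sample genotype compositions, and paired-end FASTQ read sets with a
ground-truth table, so every pipeline stage can be verified without any
deposited dataset.  Amplicons follow the leader-anchored structure
``[leader tail][repeat][spacer][repeat]...`` with one to five spacers; the
error model is substitution-only and R2 reads carry lower, faster-decaying
qualities than R1.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from numpy.lib.stride_tricks import sliding_window_view

from ._seq import BASES, decode, encode, revcomp
from .ct_typing import CTCatalog, PROVENANCE_REFERENCE, write_catalog
from .model import DEFAULT_REPEAT, Read
from .reads import write_fastq
from .variants import NEW_PLUS, ORIGIN, OTHERS, PROTO, VARIANT_CLASSES


class GenerationError(RuntimeError):
    """Spacer generation could not satisfy the distance constraint."""


@dataclass
class SimulationConfig:
    """Knobs of the synthetic data generator."""

    n_reference_cts: int = 16
    repertoire_length: int = 10
    spacer_length_range: tuple[int, int] = (32, 40)
    leader_tail_length: int = 150
    n_samples: int = 7
    timepoint_labels: list[str] | None = None
    abundance_model: str = "dirichlet"  # or "lognormal_walk"
    dirichlet_concentration: float = 200.0
    lognormal_sigma: float = 0.5
    dominant_ct_index: int | None = None  # index into the CT label list
    dominant_fraction: float | None = None
    bottleneck_after: int | None = None  # resample founders after this sample
    founder_concentration: float = 5.0
    variant_fractions: dict[str, float] = field(
        default_factory=lambda: {ORIGIN: 1.0}
    )
    ct_variant_fractions: dict[str, dict[str, float]] = field(default_factory=dict)
    proto_start_range: tuple[int, int] = (2, 4)  # 1-based, >= 2
    spacers_per_amplicon: tuple[float, ...] = (0.62, 0.27, 0.05, 0.03, 0.03)
    n_read_pairs: int = 2000  # per sample
    read_length: int = 300
    error_rate_r1: float = 0.001
    error_rate_r2: float = 0.005
    mean_q_r1: float = 36.0
    decay_r1: float = 4.0
    mean_q_r2: float = 30.0
    decay_r2: float = 8.0
    q_noise_sd: float = 3.0
    repeat_sequence: str = DEFAULT_REPEAT
    spacer_min_distance: int = 13  # pairwise Hamming floor between planted spacers
    novel_pool_size: int | None = None  # default: 2 per CT
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0.0 <= self.error_rate_r1 <= 0.2 or not 0.0 <= self.error_rate_r2 <= 0.2:
            raise ValueError("error rates must lie in [0, 0.2]")
        for fractions in (self.variant_fractions, *self.ct_variant_fractions.values()):
            bad = set(fractions) - set(VARIANT_CLASSES)
            if bad:
                raise ValueError(f"unknown variant class(es): {sorted(bad)}")
            if abs(sum(fractions.values()) - 1.0) > 1e-6:
                raise ValueError("variant fractions must sum to 1")
        if abs(sum(self.spacers_per_amplicon) - 1.0) > 1e-6:
            raise ValueError("spacers_per_amplicon must sum to 1")
        if self.proto_start_range[0] < 2:
            raise ValueError("proto variants must start at origin position >= 2")
        if self.abundance_model not in ("dirichlet", "lognormal_walk"):
            raise ValueError(f"unknown abundance model {self.abundance_model!r}")

    @property
    def sample_labels(self) -> list[str]:
        if self.timepoint_labels is not None:
            return list(self.timepoint_labels)
        return [f"T{i + 1}" for i in range(self.n_samples)]


@dataclass
class SimulationAux:
    """Generator-private truth not exposed through the catalog file."""

    leader: str
    novel_pool: dict[int, str]  # reserved novel spacers, ids above the catalog's
    new_plus_spacer: dict[str, int]  # per CT: the designated leader-end novel id
    others_spacer: dict[str, int]  # per CT: the designated internal novel id


def _random_clean_spacer(
    rng: np.random.Generator,
    length: int,
    existing_by_len: dict[int, list[np.ndarray]],
    repeat_enc: np.ndarray,
    min_distance: int,
    repeat_max_mismatch: int = 5,
    retries: int = 1000,
) -> np.ndarray:
    """Draw a spacer far from all same-length spacers and free of repeat hits."""
    for _ in range(retries):
        cand = rng.integers(0, 4, size=length).astype(np.uint8)
        if length >= len(repeat_enc):
            windows = sliding_window_view(cand, len(repeat_enc))
            if np.count_nonzero(windows != repeat_enc, axis=1).min() <= repeat_max_mismatch:
                continue
        peers = existing_by_len.get(length, [])
        if peers and min(
            int(np.count_nonzero(p != cand)) for p in peers
        ) < min_distance:
            continue
        return cand
    raise GenerationError(
        "could not generate a spacer satisfying the distance constraint; "
        "try longer spacers or fewer of them"
    )


def generate_catalog(sim: SimulationConfig) -> tuple[CTCatalog, SimulationAux]:
    """Random reference catalog with CT-disjoint, well-separated spacers.

    All planted spacers (catalog plus the reserved novel pool) of equal
    length are pairwise more than ``spacer_min_distance - 1`` substitutions
    apart, so dictionary recovery is unambiguous at the configured error
    rates.  Same seed, same catalog.
    """
    rng = np.random.default_rng(sim.rng_seed)
    repeat_enc = encode(sim.repeat_sequence)
    lo, hi = sim.spacer_length_range

    by_len: dict[int, list[np.ndarray]] = {}
    sequences: dict[int, str] = {}

    def draw(spacer_id: int) -> None:
        length = int(rng.integers(lo, hi + 1))
        arr = _random_clean_spacer(
            rng, length, by_len, repeat_enc, sim.spacer_min_distance
        )
        by_len.setdefault(length, []).append(arr)
        sequences[spacer_id] = decode(arr)

    n_catalog = sim.n_reference_cts * sim.repertoire_length
    for sid in range(1, n_catalog + 1):
        draw(sid)
    pool_size = (
        sim.novel_pool_size if sim.novel_pool_size is not None else 2 * sim.n_reference_cts
    )
    pool_ids = list(range(n_catalog + 1, n_catalog + pool_size + 1))
    for sid in pool_ids:
        draw(sid)

    # leader tail: random, but free of repeat-like windows
    leader_arr = _random_clean_spacer(
        rng, sim.leader_tail_length, {}, repeat_enc, 0
    ) if sim.leader_tail_length else np.empty(0, dtype=np.uint8)
    leader = decode(leader_arr)

    entries: dict[str, tuple[int, ...]] = {}
    provenance: dict[str, str] = {}
    labels = [f"CT{i + 1}" for i in range(sim.n_reference_cts)]
    for i, label in enumerate(labels):
        start = i * sim.repertoire_length + 1
        entries[label] = tuple(range(start, start + sim.repertoire_length))
        provenance[label] = PROVENANCE_REFERENCE
    catalog_sequences = {sid: sequences[sid] for sid in range(1, n_catalog + 1)}
    catalog = CTCatalog(entries, provenance, catalog_sequences)
    catalog.validate()

    new_plus_spacer: dict[str, int] = {}
    others_spacer: dict[str, int] = {}
    for i, label in enumerate(labels):
        if pool_size >= 2 * len(labels):
            new_plus_spacer[label] = pool_ids[2 * i]
            others_spacer[label] = pool_ids[2 * i + 1]
        elif pool_ids:
            new_plus_spacer[label] = pool_ids[i % len(pool_ids)]
            others_spacer[label] = pool_ids[(i + 1) % len(pool_ids)]
    aux = SimulationAux(
        leader=leader,
        novel_pool={sid: sequences[sid] for sid in pool_ids},
        new_plus_spacer=new_plus_spacer,
        others_spacer=others_spacer,
    )
    return catalog, aux


def simulate_composition(
    catalog: CTCatalog, sim: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Per-sample (CT, variant) proportions from the chosen abundance model.

    Columns: sample_id, ct, variant, proportion; proportions sum to 1 within
    each sample.  An optional bottleneck resamples the base composition with
    a low-concentration Dirichlet (founder effect) between two timepoints.
    """
    if rng is None:
        rng = np.random.default_rng(sim.rng_seed + 1)
    labels = list(catalog.entries)
    k = len(labels)
    if k == 0:
        return pd.DataFrame(columns=["sample_id", "ct", "variant", "proportion"])

    base = rng.dirichlet(np.ones(k))
    if sim.dominant_ct_index is not None and sim.dominant_fraction is not None:
        d = sim.dominant_ct_index
        rest = rng.dirichlet(np.ones(k - 1)) * (1.0 - sim.dominant_fraction)
        base = np.insert(rest, d, sim.dominant_fraction)

    rows = []
    log_abund = np.log(np.maximum(base, 1e-12))
    for t, sample in enumerate(sim.sample_labels):
        if sim.bottleneck_after is not None and t == sim.bottleneck_after + 1:
            base = rng.dirichlet(base * sim.founder_concentration + 1e-9)
            log_abund = np.log(np.maximum(base, 1e-12))
        if sim.abundance_model == "dirichlet":
            props = rng.dirichlet(base * sim.dirichlet_concentration + 1e-9)
        else:  # lognormal random walk
            log_abund = log_abund + rng.normal(0.0, sim.lognormal_sigma, size=k)
            props = np.exp(log_abund - log_abund.max())
            props = props / props.sum()
        for ct, p_ct in zip(labels, props):
            fractions = sim.ct_variant_fractions.get(ct, sim.variant_fractions)
            for variant in VARIANT_CLASSES:
                frac = fractions.get(variant, 0.0)
                if frac > 0:
                    rows.append(
                        {
                            "sample_id": sample,
                            "ct": ct,
                            "variant": variant,
                            "proportion": p_ct * frac,
                        }
                    )
    return pd.DataFrame(rows, columns=["sample_id", "ct", "variant", "proportion"])


def _variant_array(
    variant: str,
    repertoire: tuple[int, ...],
    k: int,
    ct: str,
    aux: SimulationAux,
    rng: np.random.Generator,
    sim: SimulationConfig,
) -> tuple[int, ...]:
    """Build a spacer-id array realizing one variant class (k spacers wanted)."""
    R = len(repertoire)
    if variant == ORIGIN:
        return repertoire[: max(1, min(k, R))]
    if variant == NEW_PLUS:
        k = min(max(k, 2), R + 1)
        return (aux.new_plus_spacer[ct],) + repertoire[: k - 1]
    if variant == PROTO:
        j_lo, j_hi = sim.proto_start_range
        j = int(rng.integers(j_lo, min(j_hi, R) + 1))
        k = max(1, min(k, R - j + 1))
        return repertoire[j - 1 : j - 1 + k]
    if variant == OTHERS:
        if rng.random() < 0.5 and R >= 3:  # deletion of the 2nd origin spacer
            k = min(max(k, 2), R - 1)
            return (repertoire[0],) + repertoire[2 : k + 1]
        k = min(max(k, 2), R + 1)  # novel spacer inserted after the newest
        return (repertoire[0], aux.others_spacer[ct]) + repertoire[1 : k - 1]
    raise ValueError(f"unknown variant {variant!r}")


@dataclass
class SimulatedSample:
    sample_id: str
    r1: list[Read]
    r2: list[Read]


@dataclass
class SimulatedDataset:
    catalog: CTCatalog
    aux: SimulationAux
    composition: pd.DataFrame
    samples: list[SimulatedSample]
    truth: pd.DataFrame  # read_pair_id, sample_id, true_ct, true_variant, ...

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_catalog(self.catalog, outdir / "catalog.yaml")
        self.composition.to_csv(
            outdir / "composition.tsv", sep="\t", index=False, float_format="%.8g"
        )
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        with open(outdir / "manifest.tsv", "w") as manifest:
            manifest.write("sample_id\tr1\tr2\n")
            for s in self.samples:
                r1_path = outdir / f"{s.sample_id}_R1.fastq"
                r2_path = outdir / f"{s.sample_id}_R2.fastq"
                write_fastq(s.r1, r1_path)
                write_fastq(s.r2, r2_path)
                manifest.write(f"{s.sample_id}\t{r1_path.name}\t{r2_path.name}\n")
        return outdir


def _read_qualities(
    n: int, mean: float, decay: float, noise_sd: float, rng: np.random.Generator
) -> np.ndarray:
    pos = np.arange(n) / max(n - 1, 1)
    q = mean - decay * pos
    if noise_sd > 0:
        q = q + rng.normal(0.0, noise_sd, size=n)
    return np.clip(np.rint(q), 2, 40).astype(np.int16)


def _apply_errors(
    arr: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    if rate <= 0:
        return arr
    hit = rng.random(len(arr)) < rate
    if not hit.any():
        return arr
    out = arr.copy()
    # shift by 1..3 mod 4 guarantees a different base
    out[hit] = (out[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
    return out


def synthesize_reads(
    catalog: CTCatalog,
    composition: pd.DataFrame,
    sim: SimulationConfig,
    aux: SimulationAux,
    rng: np.random.Generator | None = None,
) -> SimulatedDataset:
    """Paired-end FASTQ read sets plus a per-pair truth table.

    For each pair a (CT, variant) is drawn from the sample's composition, a
    spacer array is built by the variant rules, and the template
    ``leader + repeat + (spacer + repeat) * k`` is read from both ends with
    per-mate substitution errors and model-generated qualities.  Fully
    deterministic under a fixed seed.
    """
    if rng is None:
        rng = np.random.default_rng(sim.rng_seed + 2)
    spacer_seqs = dict(catalog.spacer_sequences)
    spacer_seqs.update(aux.novel_pool)
    repeat = sim.repeat_sequence
    k_values = np.arange(1, len(sim.spacers_per_amplicon) + 1)

    samples: list[SimulatedSample] = []
    truth_rows: list[dict] = []
    for sample in sim.sample_labels:
        rows = composition[composition["sample_id"] == sample]
        if len(rows) == 0:
            samples.append(SimulatedSample(sample, [], []))
            continue
        probs = rows["proportion"].to_numpy()
        probs = probs / probs.sum()
        draw_counts = rng.multinomial(sim.n_read_pairs, probs)
        r1_reads: list[Read] = []
        r2_reads: list[Read] = []
        serial = 0
        for (_, row), count in zip(rows.iterrows(), draw_counts):
            ct, variant = row["ct"], row["variant"]
            repertoire = catalog.entries[ct]
            for _ in range(int(count)):
                k = int(rng.choice(k_values, p=sim.spacers_per_amplicon))
                ids = _variant_array(variant, repertoire, k, ct, aux, rng, sim)
                template = (
                    aux.leader
                    + repeat
                    + "".join(spacer_seqs[i] + repeat for i in ids)
                )
                pair_id = f"{sample}.{serial:06d}"
                serial += 1
                t_enc = encode(template)
                r1_arr = _apply_errors(
                    t_enc[: sim.read_length].copy(), sim.error_rate_r1, rng
                )
                rc_enc = encode(revcomp(template))
                r2_arr = _apply_errors(
                    rc_enc[: sim.read_length].copy(), sim.error_rate_r2, rng
                )
                q1 = _read_qualities(
                    len(r1_arr), sim.mean_q_r1, sim.decay_r1, sim.q_noise_sd, rng
                )
                q2 = _read_qualities(
                    len(r2_arr), sim.mean_q_r2, sim.decay_r2, sim.q_noise_sd, rng
                )
                r1_reads.append(Read(pair_id, decode(r1_arr), q1, "R1"))
                r2_reads.append(Read(pair_id, decode(r2_arr), q2, "R2"))
                truth_rows.append(
                    {
                        "read_pair_id": pair_id,
                        "sample_id": sample,
                        "true_ct": ct,
                        "true_variant": variant,
                        "true_spacer_ids": ",".join(str(i) for i in ids),
                        "template_sequence": template,
                    }
                )
        samples.append(SimulatedSample(sample, r1_reads, r2_reads))

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "read_pair_id",
            "sample_id",
            "true_ct",
            "true_variant",
            "true_spacer_ids",
            "template_sequence",
        ],
    )
    return SimulatedDataset(catalog, aux, composition, samples, truth)


def simulate(sim: SimulationConfig) -> SimulatedDataset:
    """Catalog + composition + reads in one deterministic call."""
    catalog, aux = generate_catalog(sim)
    composition = simulate_composition(catalog, sim)
    return synthesize_reads(catalog, composition, sim, aux)


def load_simulation_config(path: str | Path) -> SimulationConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"unknown simulation key(s): {', '.join(unknown)}")
    for key in ("spacer_length_range", "proto_start_range"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    if "spacers_per_amplicon" in raw:
        raw["spacers_per_amplicon"] = tuple(raw["spacers_per_amplicon"])
    return SimulationConfig(**raw)
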