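"""Branch-specific sequence-evolution simulator for ortholog CDS triplets.

Each simulated gene starts from an ORF-like ancestral CDS (ATG start, no
internal stops, otherwise uniform codon usage) at the root of a 3-taxon
star: the ancestor evolves independently down a human (reference) branch,
a rabbit branch, and a mouse branch.  Per branch, every site substitutes
independently with the branch's probability to a uniformly chosen
different base (Jukes-Cantor-like, no transition/transversion bias), and
optionally one codon-aligned indel occurs.  Setting the mouse branch's
substitution probability above the rabbit's emulates the rodent-lineage
rate acceleration that makes rabbit CDSs sit closer to human ones.

Everything is driven by a single seeded RNG stream with a fixed draw
order (per gene: ancestor, then reference / rabbit / mouse branch), so a
config fully determines every output byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .records import Manifest, SequenceRecord, save_manifest, write_fasta

REFERENCE_SPECIES = "Homo sapiens"
RABBIT = "Oryctolagus cuniculus"
MOUSE = "Mus musculus"
LINEAGES = ("reference", "rabbit", "mouse")
_SPECIES_BY_LINEAGE = {"reference": REFERENCE_SPECIES, "rabbit": RABBIT, "mouse": MOUSE}

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_STOPS = {"TAA", "TAG", "TGA"}
# codons usable at non-start positions: all 64 minus the 3 stops
_SAFE_CODONS = np.array(
    sorted(
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if a + b + c not in _STOPS
    ),
    dtype="U3",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated ortholog dataset.

    Substitution probabilities are per-site per-branch; ``indel_prob`` is
    the per-gene probability of one codon-aligned indel event per lineage.
    The defaults encode the rate-acceleration scenario the pipeline is
    meant to detect: the mouse branch substitutes at twice the rabbit
    branch's probability, with CDS lengths around a typical single-gene
    coding sequence (900 nt).
    """

    n_genes: int = 500
    length_min: int = 900
    length_max: int = 900
    sub_prob_ref: float = 0.0
    sub_prob_rabbit: float = 0.08
    sub_prob_mouse: float = 0.16
    indel_prob: float = 0.0
    indel_len_max: int = 9
    decoy_isoforms: bool = False
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.length_min > self.length_max:
            raise ValueError("length_min > length_max")
        for name in ("length_min", "length_max"):
            v = getattr(self, name)
            if v < 3 or v % 3:
                raise ValueError(f"{name} must be a positive multiple of 3, got {v}")
        for name in ("sub_prob_ref", "sub_prob_rabbit", "sub_prob_mouse"):
            p = getattr(self, name)
            if not 0.0 <= p < 0.75:
                raise ValueError(f"{name} must be in [0, 0.75), got {p}")
        if not 0.0 <= self.indel_prob < 1.0:
            raise ValueError(f"indel_prob must be in [0, 1), got {self.indel_prob}")
        if self.indel_len_max < 3 or self.indel_len_max % 3:
            raise ValueError("indel_len_max must be a multiple of 3, >= 3")


@dataclass(frozen=True)
class IndelEvent:
    position: int  # codon-aligned nucleotide offset in the pre-indel sequence
    length: int
    kind: str  # "insertion" | "deletion"


@dataclass(frozen=True)
class TripletTruth:
    """Ground truth for one gene: ancestor plus realized per-lineage events."""

    gene_symbol: str
    ancestor_seq: str
    n_subs: dict[str, int] = field(default_factory=dict)
    indels: dict[str, list[IndelEvent]] = field(default_factory=dict)


def simulate_ancestor(length: int, rng: np.random.Generator) -> str:
    """ORF-like random CDS: ATG start, stop-free body, uniform codon usage."""
    if length < 3 or length % 3:
        raise ValueError(f"length must be a positive multiple of 3, got {length}")
    n_body = length // 3 - 1
    body = _SAFE_CODONS[rng.integers(0, len(_SAFE_CODONS), size=n_body)]
    return "ATG" + "".join(body)


def _substitute(arr: np.ndarray, sub_prob: float, rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """Substitute each site independently to a uniformly chosen other base."""
    hit = rng.random(arr.size) < sub_prob
    n = int(hit.sum())
    if n == 0:
        return arr, 0
    out = arr.copy()
    # draw 0..2 and skip over the current base to stay uniform on the other 3
    cur = np.searchsorted(_BASES, out[hit])
    offset = rng.integers(1, 4, size=n)
    out[hit] = _BASES[(cur + offset) % 4]
    return out, n


def evolve(
    seq: str,
    sub_prob: float,
    rng: np.random.Generator,
    indel_prob: float = 0.0,
    indel_len_max: int = 9,
) -> tuple[str, int, list[IndelEvent]]:
    """Evolve one sequence down one branch.

    Returns the descendant sequence, the realized substitution count, and
    the realized indel events (at most one, codon-aligned, never touching
    the start codon).
    """
    if not 0.0 <= sub_prob < 0.75:
        raise ValueError(f"sub_prob must be in [0, 0.75), got {sub_prob}")
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
    arr, n_subs = _substitute(arr, sub_prob, rng)
    events: list[IndelEvent] = []
    if indel_prob > 0 and rng.random() < indel_prob:
        n_codons = len(seq) // 3
        length = 3 * int(rng.integers(1, indel_len_max // 3 + 1))
        if rng.random() < 0.5 and n_codons - 1 > length // 3:
            # deletion of `length` nt at a codon boundary past the start codon
            codon_start = int(rng.integers(1, n_codons - length // 3 + 1))
            pos = 3 * codon_start
            arr = np.concatenate([arr[:pos], arr[pos + length :]])
            events.append(IndelEvent(pos, length, "deletion"))
        else:
            codon_start = int(rng.integers(1, n_codons + 1))
            pos = 3 * codon_start
            ins = _SAFE_CODONS[rng.integers(0, len(_SAFE_CODONS), size=length // 3)]
            ins_arr = np.frombuffer("".join(ins).encode("ascii"), dtype="S1")
            arr = np.concatenate([arr[:pos], ins_arr, arr[pos:]])
            events.append(IndelEvent(pos, length, "insertion"))
    return arr.tobytes().decode("ascii"), n_subs, events


def _branch_probs(config: SimulationConfig) -> dict[str, float]:
    return {
        "reference": config.sub_prob_ref,
        "rabbit": config.sub_prob_rabbit,
        "mouse": config.sub_prob_mouse,
    }


def simulate_triplets(config: SimulationConfig) -> tuple[list[SequenceRecord], list[TripletTruth]]:
    """Simulate the full dataset in memory: records plus truth table."""
    rng = np.random.default_rng(config.seed)
    probs = _branch_probs(config)
    records: list[SequenceRecord] = []
    truths: list[TripletTruth] = []
    for g in range(config.n_genes):
        gene = f"SIM{g + 1:04d}"
        length = 3 * int(rng.integers(config.length_min // 3, config.length_max // 3 + 1))
        ancestor = simulate_ancestor(length, rng)
        n_subs: dict[str, int] = {}
        indels: dict[str, list[IndelEvent]] = {}
        for lineage in LINEAGES:
            desc, n, events = evolve(
                ancestor, probs[lineage], rng, config.indel_prob, config.indel_len_max
            )
            n_subs[lineage] = n
            indels[lineage] = events
            species = _SPECIES_BY_LINEAGE[lineage]
            acc_tag = species.split()[0][:2].upper()
            records.append(
                SequenceRecord(
                    gene_symbol=gene,
                    species=species,
                    accession=f"SYN_{acc_tag}_{g + 1:04d}",
                    isoform_label="X1",
                    cds_seq=desc,
                )
            )
            if config.decoy_isoforms:
                # truncated decoy product to exercise isoform selection
                records.append(
                    SequenceRecord(
                        gene_symbol=gene,
                        species=species,
                        accession=f"SYN_{acc_tag}_{g + 1:04d}B",
                        isoform_label="X2",
                        cds_seq=desc[: max(3, (len(desc) // 6) * 3)],
                    )
                )
        truths.append(TripletTruth(gene, ancestor, n_subs, indels))
    return records, truths


def truth_table(truths: list[TripletTruth]) -> pd.DataFrame:
    rows = []
    for t in truths:
        for lineage in LINEAGES:
            rows.append(
                {
                    "gene": t.gene_symbol,
                    "lineage": lineage,
                    "n_subs": t.n_subs[lineage],
                    "indels": json.dumps([asdict(e) for e in t.indels[lineage]]),
                }
            )
    return pd.DataFrame(rows, columns=["gene", "lineage", "n_subs", "indels"])


def generate_dataset(config: SimulationConfig, directory: str | Path) -> Manifest:
    """Write a fixture directory: sequences.fasta, manifest.tsv, truth.tsv, ancestors.fasta."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    records, truths = simulate_triplets(config)
    write_fasta(records, directory / "sequences.fasta")
    manifest = Manifest.from_records(records, source="simulated")
    save_manifest(manifest, directory / "manifest.tsv")
    truth_table(truths).to_csv(directory / "truth.tsv", sep="\t", index=False)
    write_fasta(
        [(f"{t.gene_symbol}|ancestor|ANC|{''}", t.ancestor_seq) for t in truths],
        directory / "ancestors.fasta",
    )
    return manifest
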