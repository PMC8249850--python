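"""Synthetic taxonomies, reference sequences, communities, and reads.

The generator emulates the structure the classifiers assume: a seven-rank
taxonomy tree with configurable branching, reference sequences derived by
rank-specific substitution divergence from a common root, optional
byte-identical sequence sharing between sister species (the perfect
classifier's only failure mode), skewed Dirichlet community compositions,
and fixed-length prefix reads with i.i.d. substitution errors.

Evolution is substitution-only (no indels), so every sequence keeps the
fixed geometry the sentence encoder requires, and reads are prefixes of
their source sequence, mirroring the 150 nt truncation convention of short
single-end amplicon data.  All three generators are fully deterministic
under the configured seed.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from math import prod

import numpy as np

from .refdb_io import (
    Lineage,
    N_RANKS,
    RANK_PREFIXES,
    ReadSet,
    RefRecord,
    ReferenceDB,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SynthConfig:
    """Study conditions for the synthetic benchmark.

    branching
        Children per node at each of the 7 ranks; the product is the number
        of species.
    divergence
        Fraction of positions substituted when deriving a child taxon at
        each rank (decreasing toward the species rank, as in rRNA
        phylogenies).
    p_share
        Probability that a species is assigned a byte-identical copy of a
        sister (same-genus) species' sequence, creating the exact-sequence
        ambiguity that caps the perfect classifier below 1.
    concentration
        Dirichlet concentration of community compositions; small values
        (e.g. 0.1) give the skewed communities typical of real samples.
    """

    branching: tuple[int, ...] = (1, 2, 2, 2, 1, 2, 3)
    seq_length: int = 250
    divergence: tuple[float, ...] = (0.0, 0.15, 0.10, 0.07, 0.05, 0.03, 0.015)
    seqs_per_species: int = 3
    intraspecies_divergence: float = 0.005
    p_share: float = 0.0
    n_samples: int = 20
    concentration: float = 0.1
    reads_per_sample: int = 500
    read_length: int = 150
    error_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.branching) != N_RANKS or len(self.divergence) != N_RANKS:
            raise ValueError(f"branching and divergence must have {N_RANKS} entries")
        if any(b < 1 for b in self.branching):
            raise ValueError("branching factors must be >= 1")
        rates = (*self.divergence, self.p_share, self.error_rate)
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ValueError("rates must lie in [0, 1]")
        if self.read_length > self.seq_length:
            raise ValueError("read length exceeds sequence length")

    @property
    def n_species(self) -> int:
        return prod(self.branching)


#: named study conditions used by the command-line generator
PRESETS = {
    "tiny": SynthConfig(
        branching=(1, 2, 1, 1, 1, 2, 3),
        n_samples=5,
        reads_per_sample=100,
    ),
    "small": SynthConfig(
        branching=(1, 2, 2, 2, 1, 2, 3),
        n_samples=20,
        reads_per_sample=500,
    ),
}


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator, rank: str) -> np.ndarray:
    """Substitute a ``rate`` fraction of positions to a different base."""
    n_sub = int(round(rate * len(seq)))
    if rate > 0 and n_sub == 0:
        warnings.warn(
            f"divergence rate {rate} at rank {rank} yields < 1 substitution",
            stacklevel=3,
        )
    if n_sub == 0:
        return seq.copy()
    out = seq.copy()
    pos = rng.choice(len(seq), size=n_sub, replace=False)
    shift = rng.integers(1, 4, size=n_sub)
    out[pos] = _BASES[(np.searchsorted(_BASES, out[pos]) + shift) % 4]
    return out


def simulate_reference(config: SynthConfig) -> ReferenceDB:
    """Grow a 7-rank taxonomy and derive one or more sequences per species."""
    rng = np.random.default_rng(config.seed)
    root = _BASES[rng.integers(0, 4, size=config.seq_length)]

    # nodes at rank r: list of (label-path, sequence)
    nodes: list[tuple[tuple[str, ...], np.ndarray]] = [((), root)]
    for r in range(N_RANKS):
        children: list[tuple[tuple[str, ...], np.ndarray]] = []
        for path, seq in nodes:
            for i in range(config.branching[r]):
                label = f"{RANK_PREFIXES[r][0].upper()}{i}"
                child_seq = _mutate(seq, config.divergence[r], rng, RANK_PREFIXES[r])
                children.append(((*path, label), child_seq))
        nodes = children

    # optional byte-identical sharing between sister species (same genus)
    by_genus: dict[tuple[str, ...], list[int]] = {}
    for i, (path, _) in enumerate(nodes):
        by_genus.setdefault(path[:-1], []).append(i)
    nodes = [list(n) for n in nodes]  # type: ignore[assignment]
    shared_pairs = 0
    for sisters in by_genus.values():
        for j in sisters[1:]:
            if config.p_share > 0 and rng.random() < config.p_share:
                donor = sisters[int(rng.integers(len(sisters[:sisters.index(j)])))]
                nodes[j][1] = nodes[donor][1].copy()
                shared_pairs += 1

    records: dict[str, RefRecord] = {}
    for path, seq in nodes:
        lineage = Lineage(tuple(path))
        for c in range(config.seqs_per_species):
            copy = (
                seq.copy()
                if c == 0
                else _mutate(seq, config.intraspecies_divergence, rng, "strain")
            )
            rid = f"ref_{'_'.join(path)}_{c}"
            records[rid] = RefRecord(copy.tobytes().decode(), lineage)
    return ReferenceDB(records)


def simulate_communities(
    refdb: ReferenceDB, config: SynthConfig
) -> list[dict[Lineage, int]]:
    """Per-sample species counts: Dirichlet proportions, multinomial counts."""
    if config.concentration <= 0:
        raise ValueError("Dirichlet concentration must be positive")
    rng = np.random.default_rng([config.seed, 1])
    species = refdb.species_set()
    samples: list[dict[Lineage, int]] = []
    for _ in range(config.n_samples):
        props = rng.dirichlet(np.full(len(species), config.concentration))
        counts = rng.multinomial(config.reads_per_sample, props)
        samples.append({s: int(c) for s, c in zip(species, counts) if c > 0})
    return samples


def simulate_reads(
    refdb: ReferenceDB,
    communities: list[dict[Lineage, int]],
    config: SynthConfig,
) -> ReadSet:
    """Prefix reads drawn by community composition with i.i.d. substitution errors."""
    rng = np.random.default_rng([config.seed, 2])
    seq_of: dict[Lineage, list[str]] = {}
    for rec in refdb.records.values():
        seq_of.setdefault(rec.lineage, []).append(rec.sequence)
    reads: list[tuple[str, str]] = []
    truth: dict[str, Lineage] = {}
    n = 0
    for s_idx, sample in enumerate(communities):
        for lineage in sorted(sample):
            for _ in range(sample[lineage]):
                choices = seq_of[lineage]
                src = choices[int(rng.integers(len(choices)))]
                read = np.frombuffer(
                    src[: config.read_length].encode(), dtype="S1"
                ).copy()
                if config.error_rate > 0:
                    hits = np.nonzero(rng.random(len(read)) < config.error_rate)[0]
                    if hits.size:
                        shift = rng.integers(1, 4, size=hits.size)
                        read[hits] = _BASES[
                            (np.searchsorted(_BASES, read[hits]) + shift) % 4
                        ]
                rid = f"S{s_idx}_read{n}"
                n += 1
                reads.append((rid, read.tobytes().decode()))
                truth[rid] = lineage
    return ReadSet(reads, truth)


def simulate_all(
    config: SynthConfig,
) -> tuple[ReferenceDB, list[dict[Lineage, int]], ReadSet]:
    """Reference, communities, and reads in one call (shared seed)."""
    refdb = simulate_reference(config)
    communities = simulate_communities(refdb, config)
    reads = simulate_reads(refdb, communities, config)
    return refdb, communities, reads
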