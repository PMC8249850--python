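"""Taxonomic class weights: ecological priors over species-level classes.

A weight table assigns each class (a species-level, possibly truncated,
lineage in the bound reference database) the prior probability of observing
it in the environment under study.  ``uniform`` weights encode the classical
assumption that every species is equally likely; ``weighted`` tables are
assembled from previously observed per-sample taxon compositions.
"""
from __future__ import annotations

import csv
import json
import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

from .refdb_io import FormatError, Lineage, ReferenceDB, parse_lineage

_SUM_TOL = 1e-9

#: default prior floor for reference species never observed in any sample
DEFAULT_FLOOR = 1e-6


@dataclass
class ClassWeights:
    """Normalized probability distribution over species-level lineages."""

    weights: dict[Lineage, float]
    mode: str = "weighted"  # "uniform" | "weighted"

    def __post_init__(self) -> None:
        if not self.weights:
            raise ValueError("empty weight table")
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError("all class weights must be strictly positive")
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"class weights sum to {total}, not 1")
        if abs(total - 1.0) > _SUM_TOL:  # renormalize away float drift
            self.weights = {k: v / total for k, v in self.weights.items()}

    def __getitem__(self, lineage: Lineage) -> float:
        return self.weights[lineage]

    def __len__(self) -> int:
        return len(self.weights)

    def classes(self) -> list[Lineage]:
        return sorted(self.weights)

    def check_bound(self, refdb: ReferenceDB) -> None:
        """Raise unless the key set equals the reference database's class set."""
        if set(self.weights) != set(refdb.species_set()):
            raise ValueError("weight table is not bound to this reference database")


def uniform_weights(refdb: ReferenceDB) -> ClassWeights:
    """1/S for each of the S distinct species-level lineages (not per sequence)."""
    species = refdb.species_set()
    if not species:
        raise ValueError("reference database has no species")
    w = 1.0 / len(species)
    return ClassWeights({s: w for s in species}, mode="uniform")


def weights_from_compositions(
    samples: Sequence[Mapping[Lineage, float]],
    refdb: ReferenceDB,
    floor: float = DEFAULT_FLOOR,
) -> ClassWeights:
    """Assemble class weights by pooling per-sample species counts.

    Counts are summed across samples (weighting by observation volume),
    species present in the reference but absent from every sample receive the
    prior ``floor``, and the vector is renormalized.  Species observed in
    samples but missing from the reference are reported via a warning and
    dropped.
    """
    if not samples:
        raise ValueError("no composition samples given")
    ref_species = set(refdb.species_set())
    pooled: dict[Lineage, float] = {}
    foreign: set[Lineage] = set()
    for sample in samples:
        for lin, count in sample.items():
            if count < 0:
                raise ValueError(f"negative count for {lin}")
            if lin not in ref_species:
                foreign.add(lin)
                continue
            pooled[lin] = pooled.get(lin, 0.0) + count
    if foreign:
        warnings.warn(
            f"{len(foreign)} species in samples are absent from the reference and were dropped",
            stacklevel=2,
        )
    total = sum(pooled.values())
    if total <= 0:
        raise ValueError("all pooled counts are zero")
    weights = {lin: c / total for lin, c in pooled.items() if c > 0}
    for lin in ref_species - set(weights):
        if floor <= 0:
            continue
        weights[lin] = floor
    norm = sum(weights.values())
    weights = {lin: w / norm for lin, w in weights.items()}
    return ClassWeights(weights, mode="weighted")


def read_weights_tsv(path: str | Path) -> ClassWeights:
    weights: dict[Lineage, float] = {}
    mode = "weighted"
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if raw.startswith("#"):
                if "mode=" in raw:
                    mode = raw.split("mode=")[1].strip()
                continue
            if not raw.strip():
                continue
            row = raw.rstrip("\n").split("\t")
            if len(row) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            weights[parse_lineage(row[0])] = float(row[1])
    return ClassWeights(weights, mode=mode)


def write_weights_tsv(weights: ClassWeights, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# mode={weights.mode}\n")
        for lin in weights.classes():
            fh.write(f"{lin}\t{weights.weights[lin]:.12g}\n")


def read_weights_json(path: str | Path) -> ClassWeights:
    with open(path) as fh:
        doc = json.load(fh)
    return ClassWeights(
        {parse_lineage(k): v for k, v in doc["weights"].items()},
        mode=doc.get("mode", "weighted"),
    )


def write_weights_json(weights: ClassWeights, path: str | Path) -> None:
    doc = {
        "mode": weights.mode,
        "weights": {str(lin): w for lin, w in sorted(weights.weights.items())},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)


def read_compositions_tsv(path: str | Path) -> list[dict[Lineage, float]]:
    """Read (sample-id, lineage, count) rows into per-sample composition tables."""
    by_sample: dict[str, dict[Lineage, float]] = {}
    with open(path) as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("#") or row[0] == "sample_id":
                continue
            if len(row) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            sample = by_sample.setdefault(row[0], {})
            lin = parse_lineage(row[1])
            sample[lin] = sample.get(lin, 0.0) + float(row[2])
    if not by_sample:
        raise FormatError(f"no composition rows in {path}")
    return [by_sample[s] for s in sorted(by_sample)]


def write_compositions_tsv(
    samples: Sequence[Mapping[Lineage, float]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tlineage\tcount\n")
        for i, sample in enumerate(samples):
            for lin in sorted(sample):
                fh.write(f"S{i}\t{lin}\t{sample[lin]:g}\n")
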