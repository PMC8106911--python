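"""Offline synthetic fixtures: toy genomes with embedded domain markers.

The generator emulates the pipeline's real inputs without any download:

* each synthetic *domain* is a unique 45-residue amino-acid motif plus a
  keyword-bearing description, reverse-translated into a 135-nt stop-free
  coding insert (the *marker*);
* every temperate genome carries a fixed number of randomly chosen
  markers at random non-overlapping in-frame positions on random strands;
  virulent genomes carry each marker independently with probability
  ``leak_rate`` (0 by default — perfectly separable classes);
* background sequence is seeded-random A/C/G/T, and generation verifies
  that the six-frame products of each finished genome contain exactly the
  intended motifs (no accidental background collision).

The construction bookkeeping (which markers went into which genome) is
returned alongside and serves as the ground-truth oracle for the search
and classification stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id

from . import classifier
from .classifier import LifestyleModel
from .domain_search import DomainProfile, DomainSet, MotifBackend, PresenceVector
from .feature_table import (
    LabeledDataset,
    TEMPERATE,
    VIRULENT,
    assemble_dataset,
)
from .sixframe import GenomeRecord, translate_six_frames

_AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

_MOTIF_LEN = 45  # residues; marker insert = 3 * _MOTIF_LEN nt

# keyword-bearing description templates, cycled over domains so the
# keyword-selection stage keeps every synthetic domain
_DESCRIPTION_TEMPLATES = (
    "synthetic tyrosine integrase marker domain {i}",
    "synthetic excisionase marker domain {i}",
    "synthetic site-specific recombinase marker domain {i}",
    "synthetic transposase marker domain {i}",
    "synthetic lysogen maintenance marker domain {i}",
    "synthetic temperate lifestyle marker domain {i}",
    "synthetic ParA plasmid partitioning marker domain {i}",
)

_CODONS_BY_AA: dict[str, tuple[str, ...]] = {}
for codon, aa in unambiguous_dna_by_id[1].forward_table.items():
    _CODONS_BY_AA.setdefault(aa, tuple())
    _CODONS_BY_AA[aa] = _CODONS_BY_AA[aa] + (codon,)


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic dataset."""

    n_temperate: int = 20
    n_virulent: int = 20
    genome_length: int = 2000
    n_domains: int = 6
    markers_per_temperate: int = 3
    leak_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length < 3 * 40 * 3:
            raise ValueError("genome_length must be >= 360 nt so products can exist")
        if self.n_domains < 1:
            raise ValueError("n_domains must be >= 1")
        if self.markers_per_temperate < 1:
            raise ValueError("markers_per_temperate must be >= 1")
        if self.markers_per_temperate > self.n_domains:
            raise ValueError("markers_per_temperate cannot exceed n_domains")
        if not 0.0 <= self.leak_rate <= 1.0:
            raise ValueError("leak_rate must be in [0, 1]")
        if self.n_domains * 3 * _MOTIF_LEN > self.genome_length:
            raise ValueError("markers longer than genome: infeasible spec")


@dataclass(frozen=True)
class FixtureBundle:
    """One generated dataset plus its construction ground truth."""

    genomes: tuple[GenomeRecord, ...]
    labels: dict[str, str]
    domain_set: DomainSet
    motif_table: dict[str, str]  # accession -> amino-acid motif
    placements: dict[str, tuple[str, ...]]  # genome_id -> inserted accessions

    def expected_vector(self, genome_id: str) -> PresenceVector:
        values = np.zeros(len(self.domain_set), dtype=np.int8)
        for acc in self.placements[genome_id]:
            values[self.domain_set.index_of(acc)] = 1
        return PresenceVector(genome_id, values)

    def expected_dataset(self, partition: str | None = None) -> LabeledDataset:
        vectors = [self.expected_vector(g.id) for g in self.genomes]
        return assemble_dataset(vectors, self.labels, self.domain_set, partition)

    def motif_backend(self) -> MotifBackend:
        return MotifBackend(self.motif_table)


def _random_motif(rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(_AA_ALPHABET), size=_MOTIF_LEN))


def _reverse_translate(motif: str, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_CODONS_BY_AA[aa]) for aa in motif)


def _observed_accessions(genome: GenomeRecord, motif_table: Mapping[str, str]) -> set[str]:
    found = set()
    for product in translate_six_frames(genome):
        for acc, motif in motif_table.items():
            if motif in product.aa_seq:
                found.add(acc)
    return found


def _place_markers(
    gid: str,
    accessions: tuple[str, ...],
    marker_nt: Mapping[str, str],
    motif_table: Mapping[str, str],
    length: int,
    rng: np.random.Generator,
) -> GenomeRecord:
    """Build one genome: random background overwritten by the markers at
    non-overlapping positions; verified against the intended marker set."""
    mlen = 3 * _MOTIF_LEN
    for attempt in range(50):
        background = "".join(rng.choice(list("ACGT"), size=length))
        genome = list(background)
        occupied: list[tuple[int, int]] = []
        ok = True
        for acc in accessions:
            for _ in range(200):
                p = int(rng.integers(0, length - mlen + 1))
                if all(p + mlen <= s or p >= e for s, e in occupied):
                    break
            else:
                ok = False
                break
            occupied.append((p, p + mlen))
            insert = marker_nt[acc]
            if rng.random() < 0.5:  # reverse strand
                insert = insert.translate(_COMPLEMENT)[::-1]
            genome[p : p + mlen] = insert
        if not ok:
            continue
        record = GenomeRecord(gid, "".join(genome))
        if _observed_accessions(record, motif_table) == set(accessions):
            return record
    raise RuntimeError(
        f"could not build collision-free genome {gid!r} in 50 attempts"
    )


def generate(spec: FixtureSpec) -> FixtureBundle:
    """Generate a labeled synthetic dataset; deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    profiles, motif_table, marker_nt = [], {}, {}
    for i in range(spec.n_domains):
        acc = f"SYN{i:03d}"
        desc = _DESCRIPTION_TEMPLATES[i % len(_DESCRIPTION_TEMPLATES)].format(i=i)
        motif = _random_motif(rng)
        while motif in motif_table.values():  # pragma: no cover - astronomically rare
            motif = _random_motif(rng)
        profiles.append(DomainProfile(acc, desc))
        motif_table[acc] = motif
        marker_nt[acc] = _reverse_translate(motif, rng)
    domain_set = DomainSet(tuple(profiles), version_tag=f"synthetic-seed{spec.seed}")

    genomes, labels, placements = [], {}, {}
    all_accs = list(motif_table)
    for i in range(spec.n_temperate):
        gid = f"T{i:03d}"
        chosen = tuple(
            sorted(rng.choice(all_accs, size=spec.markers_per_temperate, replace=False))
        )
        genomes.append(
            _place_markers(gid, chosen, marker_nt, motif_table, spec.genome_length, rng)
        )
        labels[gid] = TEMPERATE
        placements[gid] = chosen
    for i in range(spec.n_virulent):
        gid = f"V{i:03d}"
        leaked = tuple(a for a in all_accs if rng.random() < spec.leak_rate)
        genomes.append(
            _place_markers(gid, leaked, marker_nt, motif_table, spec.genome_length, rng)
        )
        labels[gid] = VIRULENT
        placements[gid] = leaked
    return FixtureBundle(tuple(genomes), labels, domain_set, motif_table, placements)


@dataclass(frozen=True)
class GoldenCase:
    """A small fixed pipeline case with known expected outputs.

    ``genomes`` is a 10-genome evaluation set whose expected presence
    vectors and lifestyle calls are determined by construction; ``model``
    was trained on a disjoint 50-genome set generated under the same
    domain set, so running the full pipeline on the golden genomes must
    reproduce ``expected_calls`` exactly.
    """

    genomes: tuple[GenomeRecord, ...]
    labels: dict[str, str]
    domain_set: DomainSet
    motif_table: dict[str, str]
    expected_vectors: dict[str, PresenceVector]
    expected_calls: dict[str, str]
    model: LifestyleModel
    train_dataset: LabeledDataset
    bundle: FixtureBundle

    def motif_backend(self) -> MotifBackend:
        return MotifBackend(self.motif_table)

    def write_fixtures(self, directory) -> None:
        """Materialize the case as human-inspectable text files."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        with open(d / "genomes.fasta", "w") as fh:
            for g in self.genomes:
                fh.write(f">{g.id}\n")
                for i in range(0, len(g.seq), 70):
                    fh.write(g.seq[i : i + 70] + "\n")
        pd.DataFrame(
            {"genome_id": list(self.labels), "lifestyle": list(self.labels.values())}
        ).to_csv(d / "labels.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"accession": list(self.motif_table), "motif": list(self.motif_table.values())}
        ).to_csv(d / "motifs.tsv", sep="\t", index=False)
        self.domain_set.to_table(d / "domains.tsv")


_GOLDEN_SEED = 20_201_116


def golden_pipeline_case() -> GoldenCase:
    """The bundled deterministic 10-genome case (5 temperate, 5 virulent)."""
    spec = FixtureSpec(
        n_temperate=30,
        n_virulent=30,
        genome_length=2000,
        n_domains=6,
        markers_per_temperate=3,
        leak_rate=0.0,
        seed=_GOLDEN_SEED,
    )
    bundle = generate(spec)
    by_id = {g.id: g for g in bundle.genomes}
    golden_ids = [f"T{i:03d}" for i in range(25, 30)] + [
        f"V{i:03d}" for i in range(25, 30)
    ]
    train_ids = [g.id for g in bundle.genomes if g.id not in golden_ids]
    train_vectors = [bundle.expected_vector(gid) for gid in train_ids]
    train_dataset = assemble_dataset(
        train_vectors, bundle.labels, bundle.domain_set, partition="train"
    )
    model = classifier.fit(train_dataset, classifier.Hyperparameters(random_seed=0))
    genomes = tuple(by_id[gid] for gid in golden_ids)
    labels = {gid: bundle.labels[gid] for gid in golden_ids}
    return GoldenCase(
        genomes=genomes,
        labels=labels,
        domain_set=bundle.domain_set,
        motif_table=bundle.motif_table,
        expected_vectors={gid: bundle.expected_vector(gid) for gid in golden_ids},
        expected_calls=dict(labels),
        model=model,
        train_dataset=train_dataset,
        bundle=bundle,
    )
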