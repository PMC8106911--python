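"""Phylogenetically independent test subsets via k-mer containment.

A test genome is *related* to a training genome when their estimated
identity exceeds 80% over more than 80% of the (shorter) genome; a test
genome with no related training genome is phylogenetically independent
and gives a more conservative accuracy estimate.

Similarity is estimated from canonical k-mer containment rather than
alignment: coverage is the shared fraction of the smaller genome's
distinct k-mer set, and identity is recovered through the standard
k-mer survival transform ``identity = containment**(1/k)``.  A
precomputed pairwise table (e.g. from an external ANI tool) can be
substituted via :func:`load_pair_table`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .sixframe import GenomeRecord

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class PairSimilarity:
    """Symmetric pair record; coverage refers to the shorter genome."""

    id_a: str
    id_b: str
    identity: float
    coverage: float

    def key(self) -> frozenset:
        return frozenset((self.id_a, self.id_b))


def _canonical_kmers(seq: str, k: int) -> set[str]:
    # canonical form (lexicographic min of k-mer and its reverse
    # complement) makes the estimate strand-insensitive
    kmers = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        rc = kmer.translate(_COMPLEMENT)[::-1]
        kmers.add(min(kmer, rc))
    return kmers


def estimate_similarity(a: GenomeRecord, b: GenomeRecord, k: int = 16) -> PairSimilarity:
    """Containment-based similarity of two genomes.

    coverage = |A ∩ B| / min(|A|, |B|) over distinct canonical k-mers;
    identity = coverage ** (1/k).  Deterministic; both sequences must be
    at least k long.
    """
    for rec in (a, b):
        if len(rec) < k:
            raise ValueError(
                f"sequence {rec.id!r} shorter than k={k} ({len(rec)} nt)"
            )
    ka = _canonical_kmers(a.seq, k)
    kb = _canonical_kmers(b.seq, k)
    smaller = min(len(ka), len(kb))
    containment = len(ka & kb) / smaller if smaller else 0.0
    identity = containment ** (1.0 / k)
    return PairSimilarity(a.id, b.id, identity, containment)


def related(
    pair: PairSimilarity, id_threshold: float = 0.8, cov_threshold: float = 0.8
) -> bool:
    """True iff identity AND coverage strictly exceed their thresholds."""
    return pair.identity > id_threshold and pair.coverage > cov_threshold


def independent_test_subset(
    train_ids: Sequence[str],
    test_ids: Sequence[str],
    genomes: Mapping[str, GenomeRecord],
    k: int = 16,
    id_threshold: float = 0.8,
    cov_threshold: float = 0.8,
    pairs: Mapping[frozenset, PairSimilarity] | None = None,
) -> list[str]:
    """Test genomes with no related genome anywhere in the training set.

    Single-linkage: one related training genome excludes a test genome.
    Output preserves test_ids order.  ``pairs`` (from
    :func:`load_pair_table`) bypasses the internal estimator for any pair
    it covers.
    """
    overlap = set(train_ids) & set(test_ids)
    if overlap:
        raise ValueError(f"partitions not disjoint: {sorted(overlap)}")
    pairs = pairs or {}
    kept = []
    for tid in test_ids:
        excluded = False
        for rid in train_ids:
            pair = pairs.get(frozenset((tid, rid)))
            if pair is None:
                pair = estimate_similarity(genomes[tid], genomes[rid], k=k)
            if related(pair, id_threshold, cov_threshold):
                excluded = True
                break
        if not excluded:
            kept.append(tid)
    return kept


def load_pair_table(path) -> dict[frozenset, PairSimilarity]:
    """Read a precomputed pairwise table (id_a, id_b, identity, coverage;
    tab-separated with header) into a lookup keyed by unordered pair."""
    df = pd.read_csv(path, sep="\t")
    out = {}
    for _, row in df.iterrows():
        pair = PairSimilarity(
            str(row["id_a"]), str(row["id_b"]),
            float(row["identity"]), float(row["coverage"]),
        )
        out[pair.key()] = pair
    return out
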