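"""Domain selection (keyword + prevalence filters) and labeled matrices.

The candidate domain list is screened in two stages:

1. :func:`keyword_select` — keep domains whose free-text description
   matches lysogeny-associated search terms (six case-insensitive words
   plus one case-sensitive partitioning-protein pattern).
2. :func:`prevalence_filter` — on the *training* split only, drop domains
   detected in two or fewer training genomes, and domains whose
   class-conditional prevalence is strictly higher among virulent than
   among temperate genomes (a lysogeny marker should not be).

:class:`LabeledDataset` is the labeled presence/absence matrix shared by
model development and evaluation; it carries an optional partition tag so
train-only operations can refuse test data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .domain_search import DomainProfile, DomainSet, PresenceVector

TEMPERATE = "temperate"
VIRULENT = "virulent"
LABELS = (VIRULENT, TEMPERATE)


@dataclass(frozen=True)
class KeywordSpec:
    """Search terms over domain descriptions.

    Each term is ``(pattern, case_sensitive)``.  A pattern may contain
    '|'-separated alternatives; each alternative is matched as a literal
    substring (including any deliberate trailing space).
    """

    terms: tuple[tuple[str, bool], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", tuple((p, bool(c)) for p, c in self.terms))
        if not self.terms:
            raise ValueError("KeywordSpec requires at least one term")

    @staticmethod
    def matches(description: str, pattern: str, case_sensitive: bool) -> bool:
        hay = description if case_sensitive else description.lower()
        for alt in pattern.split("|"):
            needle = alt if case_sensitive else alt.lower()
            if needle and needle in hay:
                return True
        return False


def default_keyword_spec() -> KeywordSpec:
    """The lysogeny-associated search terms.

    The partitioning-protein pattern is case sensitive and each
    alternative keeps its trailing space: 'par' is a fragment of many
    ordinary words, so only the exact gene-name forms are accepted.
    """
    return KeywordSpec(
        (
            ("integrase", False),
            ("excisionase", False),
            ("recombinase", False),
            ("transposase", False),
            ("lysogen", False),
            ("temperate", False),
            ("parA |ParA |parB |ParB ", True),
        )
    )


def keyword_select(
    profiles: Sequence[DomainProfile],
    spec: KeywordSpec | None = None,
    version_tag: str = "keyword-selected",
) -> DomainSet:
    """Profiles whose description matches >= 1 term, in input order.

    A profile matching several terms is selected once.
    """
    spec = spec or default_keyword_spec()
    selected = [
        p
        for p in profiles
        if any(KeywordSpec.matches(p.description, pat, cs) for pat, cs in spec.terms)
    ]
    return DomainSet(tuple(selected), version_tag=version_tag)


def count_terms(domain_set: DomainSet, spec: KeywordSpec | None = None) -> pd.DataFrame:
    """Per-term counts of matching descriptions (overlaps allowed).

    A description containing several terms is counted once per term, so
    the column sum may exceed the number of domains.
    """
    spec = spec or default_keyword_spec()
    rows = []
    for pattern, cs in spec.terms:
        n = sum(
            1 for p in domain_set if KeywordSpec.matches(p.description, pattern, cs)
        )
        rows.append({"term": pattern, "count": n})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class LabeledDataset:
    """Genomes x domains presence/absence matrix with lifestyle labels.

    ``partition`` tags the object as a 'train' or 'test' split product
    (None for an unsplit dataset); model-development operations require
    the 'train' tag and raise on anything else.
    """

    genome_ids: tuple[str, ...]
    labels: tuple[str, ...]
    matrix: np.ndarray
    domain_set: DomainSet
    partition: str | None = None

    def __post_init__(self) -> None:
        gids = tuple(self.genome_ids)
        labels = tuple(self.labels)
        matrix = np.asarray(self.matrix, dtype=np.int8)
        if len(set(gids)) != len(gids):
            raise ValueError("duplicate genome ids in dataset")
        bad = sorted(set(labels) - set(LABELS))
        if bad:
            raise ValueError(f"unknown labels {bad}; expected one of {LABELS}")
        if matrix.ndim != 2 or matrix.shape != (len(gids), len(self.domain_set)):
            raise ValueError(
                f"matrix shape {matrix.shape} inconsistent with "
                f"{len(gids)} genomes x {len(self.domain_set)} domains"
            )
        if not np.isin(matrix, (0, 1)).all():
            raise ValueError("matrix entries must be 0/1")
        if len(labels) != len(gids):
            raise ValueError("labels and genome_ids length mismatch")
        matrix.setflags(write=False)
        object.__setattr__(self, "genome_ids", gids)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "matrix", matrix)

    @property
    def n(self) -> int:
        return len(self.genome_ids)

    def label_array(self) -> np.ndarray:
        return np.asarray(self.labels)

    def class_mask(self, label: str) -> np.ndarray:
        return self.label_array() == label

    def subset_rows(self, indices, partition: str | None = None) -> "LabeledDataset":
        idx = np.asarray(indices)
        return LabeledDataset(
            tuple(self.genome_ids[i] for i in idx),
            tuple(self.labels[i] for i in idx),
            self.matrix[idx],
            self.domain_set,
            partition=partition,
        )

    def subset_columns(self, domain_set: DomainSet) -> "LabeledDataset":
        """Project onto a (sub-)DomainSet, preserving its order."""
        cols = [self.domain_set.index_of(a) for a in domain_set.accessions]
        return LabeledDataset(
            self.genome_ids,
            self.labels,
            self.matrix[:, cols],
            domain_set,
            partition=self.partition,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.matrix, index=list(self.genome_ids), columns=list(self.domain_set.accessions)
        )
        df.insert(0, "lifestyle", list(self.labels))
        return df


def assemble_dataset(
    vectors: Sequence[PresenceVector],
    labels: Mapping[str, str],
    domain_set: DomainSet,
    partition: str | None = None,
) -> LabeledDataset:
    """Stack presence vectors (input order) into a LabeledDataset.

    Every genome must have exactly one label; a missing or duplicated
    label is an error.
    """
    gids = [v.genome_id for v in vectors]
    dupes = sorted({g for g in gids if gids.count(g) > 1})
    if dupes:
        raise ValueError(f"duplicate presence vectors for genomes: {dupes}")
    missing = [g for g in gids if g not in labels]
    if missing:
        raise ValueError(f"no label for genomes: {missing}")
    for v in vectors:
        if len(v) != len(domain_set):
            raise ValueError(
                f"vector for {v.genome_id!r} has length {len(v)}, "
                f"expected {len(domain_set)}"
            )
    matrix = (
        np.vstack([v.values for v in vectors])
        if vectors
        else np.zeros((0, len(domain_set)), dtype=np.int8)
    )
    return LabeledDataset(
        tuple(gids), tuple(labels[g] for g in gids), matrix, domain_set, partition
    )


def prevalence_filter(dataset: LabeledDataset, min_genomes: int = 3) -> DomainSet:
    """Training-set prevalence screen; returns the surviving DomainSet.

    Column j is dropped if it is present in fewer than ``min_genomes``
    training genomes (default 3, i.e. "two or fewer" are dropped, counting
    both classes), or if its prevalence *fraction* among virulent genomes
    strictly exceeds that among temperate genomes.  Equal fractions are
    retained.  Fractions, not raw counts, are compared because the class
    sizes are unequal.
    """
    temp = dataset.class_mask(TEMPERATE)
    vir = dataset.class_mask(VIRULENT)
    if temp.sum() == 0 or vir.sum() == 0:
        raise ValueError(
            "prevalence comparison undefined: dataset must contain both classes"
        )
    totals = dataset.matrix.sum(axis=0)
    frac_t = dataset.matrix[temp].mean(axis=0)
    frac_v = dataset.matrix[vir].mean(axis=0)
    keep = (totals >= min_genomes) & ~(frac_v > frac_t)
    surviving = tuple(
        p for p, k in zip(dataset.domain_set.profiles, keep) if k
    )
    return DomainSet(surviving, version_tag=f"{dataset.domain_set.version_tag}+prevalence")
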