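"""Domain detection over translation products and presence/absence vectors.

The search backend is pluggable behind a small contract (``SearchBackend``):
given translation products and a :class:`DomainSet`, return
:class:`DomainHit` records.  Two implementations ship here:

* :class:`PyhmmerBackend` — profile-HMM search with HMMER3 (in-process via
  pyhmmer); accepts an ``.hmm`` database file or in-memory profiles.
* :class:`MotifBackend` — exact amino-acid substring matching against a
  motif table; used by the offline synthetic fixtures so the whole
  pipeline is testable without profile databases.

External HMMER runs interoperate through :func:`parse_hmmer_tblout`,
which consumes the standard per-target tabular ("tblout") format.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Protocol, Sequence

import numpy as np
import pandas as pd

from .sixframe import TranslationProduct, parse_product_header, product_header


@dataclass(frozen=True)
class DomainProfile:
    """One conserved protein domain: accession plus free-text description."""

    accession: str
    description: str = ""
    source_length: int | None = None


@dataclass(frozen=True)
class DomainSet:
    """An ordered, duplicate-free collection of domain profiles.

    The ordering is a contract: presence vectors and trained models are
    aligned to it and it is serialized alongside any model.
    """

    profiles: tuple[DomainProfile, ...]
    version_tag: str = "unversioned"

    def __post_init__(self) -> None:
        object.__setattr__(self, "profiles", tuple(self.profiles))
        accs = [p.accession for p in self.profiles]
        if len(set(accs)) != len(accs):
            dupes = sorted({a for a in accs if accs.count(a) > 1})
            raise ValueError(f"duplicate accessions in DomainSet: {dupes}")

    @property
    def accessions(self) -> tuple[str, ...]:
        return tuple(p.accession for p in self.profiles)

    def index_of(self, accession: str) -> int:
        try:
            return self.accessions.index(accession)
        except ValueError:
            raise KeyError(accession) from None

    def __len__(self) -> int:
        return len(self.profiles)

    def __iter__(self):
        return iter(self.profiles)

    def __contains__(self, accession: str) -> bool:
        return accession in self.accessions

    def to_table(self, path) -> None:
        pd.DataFrame(
            {"accession": self.accessions,
             "description": [p.description for p in self.profiles]}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_table(cls, path, version_tag: str = "unversioned") -> "DomainSet":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        profiles = [
            DomainProfile(row["accession"], row.get("description", ""))
            for _, row in df.iterrows()
        ]
        return cls(tuple(profiles), version_tag=version_tag)


@dataclass(frozen=True)
class DomainHit:
    """One (translation product, domain) match reported by a backend."""

    domain_accession: str
    product_ref: tuple[str, int, int]  # (genome_id, frame, start_nt)
    evalue: float
    score: float

    def __post_init__(self) -> None:
        if not self.evalue > 0:
            raise ValueError("evalue must be > 0")


@dataclass(frozen=True)
class PresenceVector:
    """0/1 detection vector for one genome, aligned to a DomainSet."""

    genome_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.int8)
        if vals.ndim != 1 or not np.isin(vals, (0, 1)).all():
            raise ValueError("presence values must be a 1-d 0/1 vector")
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.values)


class SearchBackend(Protocol):
    """Run a domain set against translation products, return raw hits."""

    def search(
        self, products: Sequence[TranslationProduct], domain_set: DomainSet
    ) -> list[DomainHit]: ...


class MotifBackend:
    """Exact-substring motif matching; the offline fixture backend.

    ``motifs`` maps domain accession -> amino-acid motif.  A product hits
    a domain iff the motif occurs verbatim in its sequence.  Reported
    E-values/scores are nominal constants (the fixture guarantees that a
    match is unambiguous).
    """

    #: nominal values attached to exact matches
    MATCH_EVALUE = 1e-30
    MATCH_SCORE = 100.0

    def __init__(self, motifs: Mapping[str, str]):
        self.motifs = dict(motifs)

    def search(self, products, domain_set):
        hits = []
        for product in products:
            ref = (product.genome_id, product.frame, product.start_nt)
            for acc in domain_set.accessions:
                motif = self.motifs.get(acc)
                if motif and motif in product.aa_seq:
                    hits.append(DomainHit(acc, ref, self.MATCH_EVALUE, self.MATCH_SCORE))
        return hits


class PyhmmerBackend:
    """Profile-HMM search via HMMER3 (pyhmmer).

    Construct either from a profile database file (``.hmm``) or from a
    list of in-memory ``pyhmmer.plan7.HMM`` objects.  Hits are matched to
    the DomainSet by HMM accession when set, otherwise by HMM name.
    """

    def __init__(self, hmms=None, hmm_path=None):
        try:
            import pyhmmer  # noqa: F401
        except ImportError as exc:  # pragma: no cover - environment guard
            raise RuntimeError(
                "the pyhmmer backend requires the 'pyhmmer' package; "
                "install it or use a motif/tblout route instead"
            ) from exc
        if (hmms is None) == (hmm_path is None):
            raise ValueError("provide exactly one of hmms / hmm_path")
        if hmm_path is not None:
            from pyhmmer.plan7 import HMMFile

            with HMMFile(str(hmm_path)) as fh:
                hmms = list(fh)
        self.hmms = list(hmms)

    @staticmethod
    def _as_str(value) -> str:
        return value.decode() if isinstance(value, bytes) else str(value)

    def search(self, products, domain_set):
        import pyhmmer
        from pyhmmer.easel import Alphabet, TextSequence

        abc = Alphabet.amino()
        seqs = [
            TextSequence(
                name=product_header(p).encode(), sequence=p.aa_seq
            ).digitize(abc)
            for p in products
        ]
        hits: list[DomainHit] = []
        if not seqs:
            return hits
        for tophits in pyhmmer.hmmsearch(self.hmms, seqs, cpus=1):
            query = tophits.query
            acc = self._as_str(query.accession or query.name)
            for hit in tophits:
                if not hit.included:
                    continue
                ref = parse_product_header(self._as_str(hit.name))
                hits.append(DomainHit(acc, ref, float(hit.evalue), float(hit.score)))
        return hits

    def write_tblout(self, products, path) -> None:
        """Run the search and write standard per-target tabular output."""
        import pyhmmer
        from pyhmmer.easel import Alphabet, TextSequence

        abc = Alphabet.amino()
        seqs = [
            TextSequence(name=product_header(p).encode(), sequence=p.aa_seq).digitize(abc)
            for p in products
        ]
        with open(path, "wb") as fh:
            for tophits in pyhmmer.hmmsearch(self.hmms, seqs, cpus=1):
                tophits.write(fh, format="targets")


def search_products(
    products: Sequence[TranslationProduct],
    domain_set: DomainSet,
    backend: SearchBackend,
    evalue_threshold: float = 1e-5,
) -> list[DomainHit]:
    """All backend hits with full-sequence E-value <= ``evalue_threshold``.

    Hits referencing accessions absent from ``domain_set`` are dropped
    with a warning.  One record per (product, domain) pair; deterministic
    ordering by (accession, product_ref, evalue).
    """
    if len(domain_set) == 0:
        raise ValueError("domain_set must be non-empty")
    if not evalue_threshold > 0:
        raise ValueError("evalue_threshold must be > 0")
    kept = []
    known = set(domain_set.accessions)
    for hit in backend.search(products, domain_set):
        if hit.domain_accession not in known:
            warnings.warn(
                f"dropping hit for unknown accession {hit.domain_accession!r}",
                stacklevel=2,
            )
            continue
        if hit.evalue <= evalue_threshold:
            kept.append(hit)
    kept.sort(key=lambda h: (h.domain_accession, h.product_ref, h.evalue))
    return kept


# tblout columns (whitespace-delimited): target name, target accession,
# query name, query accession, full-seq E-value, full-seq score, ...
_TBLOUT_MIN_FIELDS = 6


def parse_hmmer_tblout(path) -> list[DomainHit]:
    """Parse HMMER3 per-target tabular output into DomainHit records.

    Comment lines ('#') are skipped.  The query (profile) accession is
    used as the domain accession when present, falling back to the query
    name.  Malformed data lines raise with the 1-based line number.
    """
    hits: list[DomainHit] = []
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split()
        if len(fields) < _TBLOUT_MIN_FIELDS:
            raise ValueError(
                f"{path}: line {lineno}: expected >= {_TBLOUT_MIN_FIELDS} "
                f"whitespace-delimited fields, got {len(fields)}"
            )
        target, _t_acc, q_name, q_acc = fields[:4]
        try:
            evalue = float(fields[4])
            score = float(fields[5])
        except ValueError as exc:
            raise ValueError(
                f"{path}: line {lineno}: unparseable numeric field: {exc}"
            ) from None
        accession = q_acc if q_acc not in ("-", "") else q_name
        ref = parse_product_header(target)
        hits.append(DomainHit(accession, ref, evalue, score))
    return hits


def build_presence_vector(
    genome_id: str, hits: Iterable[DomainHit], domain_set: DomainSet
) -> PresenceVector:
    """values[i] = 1 iff at least one hit for profiles[i]; idempotent under
    duplicate hits and invariant to hit order."""
    values = np.zeros(len(domain_set), dtype=np.int8)
    for hit in hits:
        values[domain_set.index_of(hit.domain_accession)] = 1
    return PresenceVector(genome_id, values)


def build_hmms_from_sequences(sequences: Mapping[str, str]):
    """Build single-sequence profile HMMs (accession -> amino-acid seq).

    Each profile's name and accession are set to the mapping key, so
    PyhmmerBackend hits align with a DomainSet using those accessions.
    """
    from pyhmmer.easel import Alphabet, TextSequence
    from pyhmmer.plan7 import Background, Builder

    abc = Alphabet.amino()
    builder = Builder(abc)
    bg = Background(abc)
    hmms = []
    for acc, seq in sequences.items():
        dig = TextSequence(name=acc.encode(), sequence=seq).digitize(abc)
        hmm, _, _ = builder.build(dig, bg)
        hmm.accession = acc
        hmms.append(hmm)
    return hmms


def presence_vectors_for_genomes(
    genomes,
    domain_set: DomainSet,
    backend: SearchBackend,
    evalue_threshold: float = 1e-5,
    min_len: int = 40,
) -> list[PresenceVector]:
    """Per-record pipeline: translate, search, vectorize each genome."""
    from .sixframe import translate_six_frames

    vectors = []
    for genome in genomes:
        products = translate_six_frames(genome, min_len)
        hits = search_products(products, domain_set, backend, evalue_threshold)
        vectors.append(build_presence_vector(genome.id, hits, domain_set))
    return vectors


def whole_file_presence_vector(
    genomes,
    genome_id: str,
    domain_set: DomainSet,
    backend: SearchBackend,
    evalue_threshold: float = 1e-5,
    min_len: int = 40,
) -> PresenceVector:
    """Treat all records as contigs of one genome: presence is the union
    of detections over the records."""
    per_record = presence_vectors_for_genomes(
        genomes, domain_set, backend, evalue_threshold, min_len
    )
    values = np.zeros(len(domain_set), dtype=np.int8)
    for v in per_record:
        values |= v.values
    return PresenceVector(genome_id, values)
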