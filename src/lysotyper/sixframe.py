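"""Six-frame translation into stop-free amino-acid products.

A *translation product* here is a maximal stop-free codon run in one of
the six reading frames (three forward, three on the reverse complement),
translated with the standard genetic code.  Products are not ORFs: no
start codon is required, because domain search only needs the amino-acid
content, not gene models.  Only products of at least ``min_len`` residues
(default 40) are kept.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# IUPAC DNA: unambiguous bases, N, and the partial-ambiguity codes.
# RNA (U) is deliberately rejected.
_VALID_NT = frozenset("ACGTNRYSWKMBDHV")

_CODON_TABLE = unambiguous_dna_by_id[1]  # standard code
_FORWARD = dict(_CODON_TABLE.forward_table)
_STOPS = frozenset(_CODON_TABLE.stop_codons)

FRAMES = (1, 2, 3, -1, -2, -3)


@dataclass(frozen=True)
class GenomeRecord:
    """One input nucleotide sequence (a putative complete phage genome).

    The sequence is normalized to uppercase; characters outside the IUPAC
    DNA alphabet raise ``ValueError`` naming the character and position.
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("GenomeRecord id must be non-empty")
        seq = self.seq.upper()
        for pos, ch in enumerate(seq):
            if ch not in _VALID_NT:
                raise ValueError(
                    f"invalid nucleotide {ch!r} at position {pos} in record {self.id!r}"
                )
        object.__setattr__(self, "seq", seq)

    def reverse_complement(self) -> "GenomeRecord":
        return GenomeRecord(self.id, str(Seq(self.seq).reverse_complement()))

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class TranslationProduct:
    """A stop-free amino-acid segment with frame/coordinate provenance.

    ``frame`` is one of +1..+3 (forward strand) or -1..-3 (reverse
    complement); ``start_nt`` is the 0-based offset of the first codon
    base *on the strand of the frame*.
    """

    genome_id: str
    frame: int
    start_nt: int
    aa_seq: str

    def __post_init__(self) -> None:
        if self.frame not in FRAMES:
            raise ValueError(f"frame must be one of {FRAMES}, got {self.frame}")
        if self.start_nt < 0:
            raise ValueError("start_nt must be >= 0")
        if "*" in self.aa_seq:
            raise ValueError("aa_seq must not contain stop symbols")


def _translate_codon(codon: str) -> str:
    """Standard-code translation; any codon with a non-ACGT base -> 'X'.

    Ambiguity codes are never resolved (even when all resolutions agree)
    and never treated as stop: an 'X' cannot create a spurious split.
    """
    if codon in _STOPS:
        return "*"
    aa = _FORWARD.get(codon)
    return aa if aa is not None else "X"


def _frame_products(
    genome_id: str, strand_seq: str, frame: int, offset: int, min_len: int
) -> Iterator[TranslationProduct]:
    run: list[str] = []
    run_start = offset
    pos = offset
    while pos + 3 <= len(strand_seq):
        aa = _translate_codon(strand_seq[pos : pos + 3])
        if aa == "*":
            if len(run) >= min_len:
                yield TranslationProduct(genome_id, frame, run_start, "".join(run))
            run = []
            run_start = pos + 3
        else:
            run.append(aa)
        pos += 3
    if len(run) >= min_len:
        yield TranslationProduct(genome_id, frame, run_start, "".join(run))


def translate_six_frames(
    genome: GenomeRecord, min_len: int = 40
) -> list[TranslationProduct]:
    """All maximal stop-free products of >= ``min_len`` residues.

    Trailing partial codons are ignored; stop codons delimit products and
    are never included.  Output order is deterministic: frames
    +1, +2, +3, -1, -2, -3, then ascending start coordinate.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    products: list[TranslationProduct] = []
    rc = str(Seq(genome.seq).reverse_complement())
    for frame in FRAMES:
        strand_seq = genome.seq if frame > 0 else rc
        offset = abs(frame) - 1
        products.extend(
            _frame_products(genome.id, strand_seq, frame, offset, min_len)
        )
    return products


# --- product FASTA interchange -------------------------------------------
#
# Header scheme (documented contract, round-trips through read_products_fasta):
#   >{genome_id}|frame={+d}|start={d}
# genome_id may itself contain '|'; the two provenance fields are parsed
# from the right.

_HEADER_RE = re.compile(r"^(?P<gid>.+)\|frame=(?P<frame>[+-]\d)\|start=(?P<start>\d+)$")


def product_header(product: TranslationProduct) -> str:
    return f"{product.genome_id}|frame={product.frame:+d}|start={product.start_nt}"


def parse_product_header(header: str) -> tuple[str, int, int]:
    m = _HEADER_RE.match(header)
    if m is None:
        raise ValueError(f"unparseable product header: {header!r}")
    return m.group("gid"), int(m.group("frame")), int(m.group("start"))


def write_products_fasta(products: Iterable[TranslationProduct], path) -> None:
    """One record per product; headers follow the provenance scheme above.

    Genome ids must be whitespace-free (they are FASTA id tokens)."""
    records = [
        SeqRecord(Seq(p.aa_seq), id=product_header(p), description="")
        for p in products
    ]
    SeqIO.write(records, str(path), "fasta")


def read_products_fasta(path) -> list[TranslationProduct]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        gid, frame, start = parse_product_header(rec.id)
        out.append(TranslationProduct(gid, frame, start, str(rec.seq)))
    return out


def read_genomes_fasta(path) -> list[GenomeRecord]:
    """Read a (possibly multi-record) nucleotide FASTA into GenomeRecords."""
    return [GenomeRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
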