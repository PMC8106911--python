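"""Backends, tblout parsing, presence-vector construction."""

import numpy as np
import pytest

from lysotyper.domain_search import (
    DomainHit,
    DomainProfile,
    DomainSet,
    MotifBackend,
    PyhmmerBackend,
    build_hmms_from_sequences,
    build_presence_vector,
    parse_hmmer_tblout,
    presence_vectors_for_genomes,
    search_products,
    whole_file_presence_vector,
)
from lysotyper.sixframe import TranslationProduct, translate_six_frames


def _domain_set(n=10):
    return DomainSet(tuple(DomainProfile(f"d{i}", f"domain {i}") for i in range(1, n + 1)))


def _product(aa, gid="g1", frame=1, start=0):
    return TranslationProduct(gid, frame, start, aa)


class TestSearchProducts:
    def test_zero_products_empty_hits(self):
        backend = MotifBackend({"d1": "MMMM"})
        assert search_products([], _domain_set(), backend) == []

    def test_embedded_motif_yields_exactly_one_hit(self):
        motif = "MKVLAWQRTNDEYFHGIPSC"
        backend = MotifBackend({"d3": motif})
        products = [_product("A" * 10 + motif + "A" * 10), _product("A" * 45, start=120)]
        hits = search_products(products, _domain_set(), backend)
        assert len(hits) == 1 and hits[0].domain_accession == "d3"

    def test_same_domain_on_two_products_keeps_both(self):
        backend = MotifBackend({"d2": "WWWW"})
        products = [_product("AWWWWA"), _product("WWWWY", start=30)]
        hits = search_products(products, _domain_set(), backend)
        assert [h.domain_accession for h in hits] == ["d2", "d2"]

    def test_unknown_accession_dropped_with_warning(self):
        class Rogue:
            def search(self, products, domain_set):
                return [DomainHit("not-a-domain", ("g1", 1, 0), 1e-10, 50.0)]

        with pytest.warns(UserWarning, match="not-a-domain"):
            hits = search_products([_product("A" * 40)], _domain_set(), Rogue())
        assert hits == []

    def test_threshold_filtering_is_monotone(self):
        class Fixed:
            def search(self, products, domain_set):
                return [
                    DomainHit("d1", ("g1", 1, 0), 1e-10, 50.0),
                    DomainHit("d2", ("g1", 1, 0), 1e-3, 10.0),
                ]

        ds = _domain_set()
        products = [_product("A" * 40)]
        strict = search_products(products, ds, Fixed(), evalue_threshold=1e-5)
        loose = search_products(products, ds, Fixed(), evalue_threshold=1e-2)
        assert {h.domain_accession for h in strict} <= {
            h.domain_accession for h in loose
        }
        assert [h.domain_accession for h in strict] == ["d1"]


class TestPresenceVector:
    def test_no_hits_gives_zero_vector_of_set_length(self):
        ds = DomainSet(tuple(DomainProfile(f"d{i}") for i in range(206)))
        vec = build_presence_vector("g", [], ds)
        assert len(vec) == 206 and vec.values.sum() == 0

    def test_duplicate_hits_and_order_do_not_matter(self):
        ds = _domain_set()
        ref = ("g", 1, 0)
        hits = [
            DomainHit("d3", ref, 1e-9, 1.0),
            DomainHit("d7", ref, 1e-9, 1.0),
            DomainHit("d3", ref, 1e-12, 2.0),
        ]
        expected = np.zeros(10, dtype=np.int8)
        expected[[2, 6]] = 1
        for ordering in (hits, hits[::-1]):
            vec = build_presence_vector("g", ordering, ds)
            assert (vec.values == expected).all()

    def test_every_domain_hit_once_gives_all_ones(self):
        ds = _domain_set(5)
        hits = [DomainHit(a, ("g", 1, 0), 1e-9, 1.0) for a in ds.accessions]
        assert build_presence_vector("g", hits, ds).values.sum() == 5


class TestTbloutParsing:
    def test_comment_only_file_is_empty(self, tmp_path):
        p = tmp_path / "t.tbl"
        p.write_text("# comment\n#\n# another\n")
        assert parse_hmmer_tblout(p) == []

    def test_two_rows_parse_with_their_evalues(self, tmp_path):
        p = tmp_path / "t.tbl"
        p.write_text(
            "# target  tacc  query  qacc  evalue  score  bias\n"
            "g1|frame=+1|start=0  -  m1  d1  1e-10  55.5  0.1\n"
            "g1|frame=-2|start=9  -  m2  d2  0.5  8.0  0.0\n"
        )
        hits = parse_hmmer_tblout(p)
        assert [(h.domain_accession, h.evalue) for h in hits] == [
            ("d1", 1e-10),
            ("d2", 0.5),
        ]
        assert hits[1].product_ref == ("g1", -2, 9)

    def test_non_numeric_evalue_names_the_line(self, tmp_path):
        p = tmp_path / "t.tbl"
        p.write_text(
            "g1|frame=+1|start=0  -  m1  d1  1e-10  55.5  0.1\n"
            "g1|frame=+1|start=0  -  m1  d1  oops  55.5  0.1\n"
        )
        with pytest.raises(ValueError, match="line 2"):
            parse_hmmer_tblout(p)

    def test_empty_file_is_empty_list(self, tmp_path):
        p = tmp_path / "t.tbl"
        p.write_text("")
        assert parse_hmmer_tblout(p) == []


class TestBackendEquivalence:
    """The motif backend, the in-process HMMER backend, and the tblout
    parse route must agree on the golden fixtures."""

    def test_three_routes_identical_vectors(self, golden, tmp_path):
        hmms = build_hmms_from_sequences(golden.motif_table)
        hmmer = PyhmmerBackend(hmms=hmms)
        motif = golden.motif_backend()
        for genome in golden.genomes:
            products = translate_six_frames(genome)
            v_motif = build_presence_vector(
                genome.id,
                search_products(products, golden.domain_set, motif),
                golden.domain_set,
            )
            v_hmmer = build_presence_vector(
                genome.id,
                search_products(products, golden.domain_set, hmmer),
                golden.domain_set,
            )
            tbl = tmp_path / f"{genome.id}.tbl"
            hmmer.write_tblout(products, tbl)
            parsed = [h for h in parse_hmmer_tblout(tbl) if h.evalue <= 1e-5]
            v_tbl = build_presence_vector(genome.id, parsed, golden.domain_set)
            expected = golden.expected_vectors[genome.id].values
            assert (v_motif.values == expected).all()
            assert (v_hmmer.values == expected).all()
            assert (v_tbl.values == expected).all()

    def test_hmm_database_file_round_trip(self, golden, tmp_path):
        hmms = build_hmms_from_sequences(golden.motif_table)
        db = tmp_path / "profiles.hmm"
        with open(db, "wb") as fh:
            for h in hmms:
                h.write(fh)
        backend = PyhmmerBackend(hmm_path=db)
        genome = golden.genomes[0]
        hits = search_products(
            translate_six_frames(genome), golden.domain_set, backend
        )
        vec = build_presence_vector(genome.id, hits, golden.domain_set)
        assert (vec.values == golden.expected_vectors[genome.id].values).all()


def test_whole_file_mode_unions_records(small_bundle):
    temp = [g for g in small_bundle.genomes if g.id.startswith("T")][:2]
    backend = small_bundle.motif_backend()
    union = whole_file_presence_vector(temp, "combined", small_bundle.domain_set, backend)
    per = presence_vectors_for_genomes(temp, small_bundle.domain_set, backend)
    assert (union.values == (per[0].values | per[1].values)).all()


def test_duplicate_accessions_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        DomainSet((DomainProfile("d1"), DomainProfile("d1")))
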