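"""Keyword selection, term counts, prevalence filter, dataset assembly."""

import numpy as np
import pytest

from lysotyper.domain_search import DomainProfile, DomainSet, PresenceVector
from lysotyper.feature_table import (
    KeywordSpec,
    LabeledDataset,
    assemble_dataset,
    count_terms,
    default_keyword_spec,
    keyword_select,
    prevalence_filter,
)


class TestKeywordSelect:
    @pytest.mark.parametrize(
        "description, selected",
        [
            ("Site-specific DNA recombinase/Integrase", True),  # two terms, once
            ("Paratose synthase", False),  # no case-sensitive 'ParA ' match
            ("chromosome partitioning protein ParB ", True),  # 'ParB ' with space
            ("Temperate lifestyle regulator", True),
            ("lysogeny maintenance factor", True),
            ("DNA polymerase", False),
            ("partition protein ParA homolog", True),  # 'ParA ' inside text
            ("terminal ParB", False),  # no trailing space at string end
        ],
    )
    def test_default_terms(self, description, selected):
        profiles = [DomainProfile("d1", description)]
        result = keyword_select(profiles, default_keyword_spec())
        assert (len(result) == 1) is selected

    def test_multi_term_match_selected_once(self):
        profiles = [DomainProfile("d1", "integrase and recombinase and transposase")]
        assert len(keyword_select(profiles)) == 1

    def test_monotone_in_terms(self):
        profiles = [
            DomainProfile("d1", "integrase"),
            DomainProfile("d2", "holin"),
            DomainProfile("d3", "excisionase"),
        ]
        small = KeywordSpec((("integrase", False),))
        large = KeywordSpec((("integrase", False), ("excisionase", False)))
        sel_small = set(keyword_select(profiles, small).accessions)
        sel_large = set(keyword_select(profiles, large).accessions)
        assert sel_small <= sel_large

    def test_input_order_preserved(self):
        profiles = [DomainProfile(a, "integrase") for a in ("z9", "a1", "m5")]
        assert keyword_select(profiles).accessions == ("z9", "a1", "m5")


class TestCountTerms:
    def test_empty_set_all_zero(self):
        counts = count_terms(DomainSet(()))
        assert (counts["count"] == 0).all()

    def test_overlapping_counts_by_construction(self):
        ds = DomainSet(
            (
                DomainProfile("d1", "phage integrase"),
                DomainProfile("d2", "integrase/recombinase bifunctional"),
                DomainProfile("d3", "tail fiber"),
            )
        )
        spec = KeywordSpec((("integrase", False), ("recombinase", False)))
        counts = dict(zip(count_terms(ds, spec)["term"], count_terms(ds, spec)["count"]))
        assert counts == {"integrase": 2, "recombinase": 1}
        # overlap means the term-count sum can exceed the selected total
        assert sum(counts.values()) >= len(keyword_select(list(ds), spec))


def _dataset(matrix, labels, partition=None):
    matrix = np.asarray(matrix)
    ds = DomainSet(tuple(DomainProfile(f"d{j}") for j in range(matrix.shape[1])))
    gids = tuple(f"g{i}" for i in range(matrix.shape[0]))
    return LabeledDataset(gids, tuple(labels), matrix, ds, partition)


class TestPrevalenceFilter:
    def test_hand_enumerated_rules(self):
        # 4 temperate + 4 virulent genomes, 5 candidate domains:
        # d0: 2 genomes only (both temperate)        -> dropped (<= 2)
        # d1: 3 temperate, 0 virulent                -> retained
        # d2: 1 temperate, 2 virulent (25% < 50%)    -> dropped (virulent-skewed)
        # d3: 2 temperate, 2 virulent (equal 50%)    -> retained (tie kept)
        # d4: absent everywhere                      -> dropped (<= 2)
        matrix = [
            [1, 1, 0, 1, 0],
            [1, 1, 0, 1, 0],
            [0, 1, 1, 0, 0],
            [0, 0, 0, 0, 0],
            [0, 0, 1, 1, 0],
            [0, 0, 1, 1, 0],
            [0, 0, 0, 0, 0],
            [0, 0, 0, 0, 0],
        ]
        labels = ["temperate"] * 4 + ["virulent"] * 4
        surviving = prevalence_filter(_dataset(matrix, labels))
        assert surviving.accessions == ("d1", "d3")

    def test_fraction_not_count_comparison(self):
        # 10% of temperate vs 20% of virulent -> dropped even though raw
        # temperate count (1) equals raw virulent count (1)
        matrix = np.zeros((15, 1), dtype=int)
        matrix[0, 0] = 1  # 1 of 10 temperate
        matrix[10, 0] = 1  # 1 of 5 virulent
        matrix[1, 0] = 1  # bump total above the <=2 rule: 2nd temperate
        labels = ["temperate"] * 10 + ["virulent"] * 5
        # fractions: temperate 2/10 = 0.2, virulent 1/5 = 0.2 -> tie, kept;
        # now make virulent strictly higher
        surviving = prevalence_filter(_dataset(matrix, labels))
        assert surviving.accessions == ("d0",)
        matrix2 = matrix.copy()
        matrix2[11, 0] = 1  # virulent fraction 2/5 = 0.4 > 0.2
        assert prevalence_filter(_dataset(matrix2, labels)).accessions == ()

    def test_single_class_is_an_error(self):
        with pytest.raises(ValueError, match="both classes"):
            prevalence_filter(_dataset([[1], [1], [1]], ["temperate"] * 3))

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        matrix = rng.integers(0, 2, size=(30, 8))
        labels = ["temperate"] * 18 + ["virulent"] * 12
        ds = _dataset(matrix, labels)
        once = prevalence_filter(ds)
        again = prevalence_filter(ds.subset_columns(once))
        assert again.accessions == once.accessions


class TestAssembleDataset:
    def _vectors(self, n, width=3):
        rng = np.random.default_rng(0)
        return [
            PresenceVector(f"g{i}", rng.integers(0, 2, size=width)) for i in range(n)
        ]

    def _ds(self, width=3):
        return DomainSet(tuple(DomainProfile(f"d{j}") for j in range(width)))

    def test_three_vectors_three_rows(self):
        vecs = self._vectors(3)
        labels = {v.genome_id: "temperate" for v in vecs}
        data = assemble_dataset(vecs, labels, self._ds())
        assert data.matrix.shape == (3, 3)
        assert data.genome_ids == ("g0", "g1", "g2")

    def test_missing_label_is_an_error(self):
        vecs = self._vectors(2)
        with pytest.raises(ValueError, match="g1"):
            assemble_dataset(vecs, {"g0": "temperate"}, self._ds())

    def test_duplicate_vector_is_an_error(self):
        vecs = self._vectors(1) * 2
        with pytest.raises(ValueError, match="duplicate"):
            assemble_dataset(vecs, {"g0": "virulent"}, self._ds())

    def test_permuting_vectors_permutes_rows(self):
        vecs = self._vectors(4)
        labels = {v.genome_id: "virulent" for v in vecs}
        fwd = assemble_dataset(vecs, labels, self._ds())
        rev = assemble_dataset(vecs[::-1], labels, self._ds())
        assert (rev.matrix == fwd.matrix[::-1]).all()
        assert rev.genome_ids == fwd.genome_ids[::-1]
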