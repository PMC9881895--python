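"""Paralog selection, family expansion, array layout and oligo assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quadscreen.design import (
    INTERNAL_DRS,
    INZOLIA_COMPOSITION,
    PROTOTYPE_COMPOSITION,
    In4merArray,
    LibraryDesignError,
    assemble_oligo,
    build_in4mer_arrays,
    compute_identity_stats,
    expand_families,
    library_size,
    parse_oligo,
    random_spacer,
    select_paralog_pairs,
    validate_spacer,
)


class TestIdentityStats:
    @pytest.mark.parametrize(
        "ab, ba, mean, delta",
        [(80, 70, 75, 10), (66, 66, 66, 0), (100, 0, 50, 100)],
    )
    def test_arithmetic(self, ab, ba, mean, delta):
        assert compute_identity_stats(ab, ba) == (mean, delta)

    def test_out_of_range_rejected(self):
        with pytest.raises(LibraryDesignError, match="outside"):
            compute_identity_stats(101, 50)


EXPR = pd.DataFrame(
    {"mean": [3.0, 4.0, 3.0, 4.0], "stdev": [1.0, 1.0, 2.0, 1.0]},
    index=["A", "B", "C", "D"],
)


def _cands(rows):
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "pct_ab", "pct_ba"])


class TestPairSelection:
    def test_clean_pair_accepted_under_both_profiles(self):
        cands = _cands([("A", "B", 77.5, 72.5)])  # mean 75, delta 5
        for profile in ("prototype", "inzolia"):
            out = select_paralog_pairs(cands, EXPR, profile=profile)
            assert bool(out["accepted"].iloc[0])

    @pytest.mark.parametrize(
        "ab, ba, reason",
        [(25, 25, "identity_out_of_range"), (99.8, 99.8, "identity_out_of_range")],
    )
    def test_identity_interval(self, ab, ba, reason):
        out = select_paralog_pairs(_cands([("A", "B", ab, ba)]), EXPR)
        assert out["reason"].iloc[0] == reason

    def test_identity_interval_endpoints_inclusive(self):
        out = select_paralog_pairs(_cands([("A", "B", 30, 30), ("A", "B", 99, 99)]), EXPR)
        assert out["accepted"].all()

    def test_delta_filter_dropped_in_relaxed_profile(self):
        cands = _cands([("A", "B", 81, 69)])  # mean 75, delta 12
        proto = select_paralog_pairs(cands, EXPR, profile="prototype")
        relaxed = select_paralog_pairs(cands, EXPR, profile="inzolia")
        assert proto["reason"].iloc[0] == "delta_identity"
        assert bool(relaxed["accepted"].iloc[0])

    def test_expression_variance_filter_profile_difference(self):
        cands = _cands([("A", "C", 75, 75)])  # C has stdev 2.0
        proto = select_paralog_pairs(cands, EXPR, profile="prototype")
        relaxed = select_paralog_pairs(cands, EXPR, profile="inzolia")
        assert proto["reason"].iloc[0] == "variable_expression"
        assert bool(relaxed["accepted"].iloc[0])

    def test_missing_expression_rejected_with_reason(self):
        out = select_paralog_pairs(_cands([("A", "ZZZ", 75, 75)]), EXPR)
        assert out["reason"].iloc[0] == "missing_expression"

    def test_relaxed_profile_is_superset(self, rng):
        rows = []
        genes = list(EXPR.index)
        for i in range(40):
            a, b = rng.choice(genes, size=2, replace=False)
            ab, ba = rng.uniform(10, 100, size=2)
            rows.append((a, b, ab, ba))
        cands = _cands(rows)
        proto = select_paralog_pairs(cands, EXPR, profile="prototype")
        relaxed = select_paralog_pairs(cands, EXPR, profile="inzolia")
        assert not (proto["accepted"] & ~relaxed["accepted"]).any()


class TestFamilies:
    def _identity(self, rows):
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "pct_ab", "pct_ba"])

    def test_small_drop_forms_triple(self):
        ident = self._identity([("A", "B", 80, 80), ("A", "C", 72, 72)])
        fams = expand_families(["A", "B", "C"], ident, drop_threshold=10)
        assert ("A", "B", "C") in fams

    def test_threshold_controls_family_growth(self):
        ident = self._identity([("A", "B", 80, 80), ("A", "C", 65, 65)])
        strict = expand_families(["A", "B", "C"], ident, drop_threshold=10)
        relaxed = expand_families(["A", "B", "C"], ident, drop_threshold=20)
        assert ("A", "B") in strict and ("A", "B", "C") not in strict
        assert ("A", "B", "C") in relaxed

    def test_family_capped_at_four(self):
        rows = [("A", g, 80 - i, 80 - i) for i, g in enumerate("BCDEF")]
        ident = self._identity(rows)
        fams = expand_families(list("ABCDEF"), ident, drop_threshold=10)
        sizes = {len(f) for f in fams}
        assert max(sizes) == 4
        # highest-identity companions retained
        fam = next(f for f in fams if "A" in f and len(f) == 4)
        assert set(fam) == {"A", "B", "C", "D"}

    def test_gene_without_paralog_excluded(self):
        ident = self._identity([("A", "B", 80, 80)])
        fams = expand_families(["A", "B", "LONER"], ident)
        assert all("LONER" not in f for f in fams)

    def test_order_invariance(self, rng):
        rows = [("A", "B", 80, 80), ("A", "C", 75, 75), ("B", "D", 78, 78),
                ("C", "D", 60, 60)]
        ident = self._identity(rows)
        genes = ["A", "B", "C", "D"]
        base = expand_families(genes, ident)
        for _ in range(5):
            perm = list(rng.permutation(genes))
            shuffled = ident.sample(frac=1, random_state=int(rng.integers(1e6)))
            assert expand_families(perm, shuffled) == base


def _guides(genes, per_gene=4, seed=1):
    rng = np.random.default_rng(seed)
    return {g: [random_spacer(rng) for _ in range(per_gene)] for g in genes}


class TestArrayLayout:
    def test_pair_layout_same_guides_different_order(self):
        guides = _guides(["A", "B"])
        a1, a2 = build_in4mer_arrays(("A", "B"), guides)
        A1, A2 = guides["A"][:2]
        B1, B2 = guides["B"][:2]
        assert a1.spacers == (A1, B1, A2, B2)
        assert a2.spacers == (B2, A2, B1, A1)
        assert set(a1.spacers) == set(a2.spacers)
        assert a1.spacers != a2.spacers

    def test_single_gene_uses_top_four_then_reverse(self):
        guides = _guides(["A"])
        a1, a2 = build_in4mer_arrays(("A",), guides)
        assert a1.spacers == tuple(guides["A"][:4])
        assert a2.spacers == tuple(reversed(guides["A"][:4]))

    def test_triple_pads_reproducibly_under_seed(self):
        guides = _guides(["A", "B", "C"])
        pads = [random_spacer(np.random.default_rng(99)) for _ in range(6)]
        first = build_in4mer_arrays(("A", "B", "C"), guides, pad_source=pads, seed=42)
        again = build_in4mer_arrays(("A", "B", "C"), guides, pad_source=pads, seed=42)
        assert first[0].spacers == again[0].spacers
        assert first[1].spacers == again[1].spacers
        assert first[0].pad == "nonessential-guide"
        assert first[0].spacers[3] in pads
        # per-gene guides: rank 1 on array 1, rank 2 on array 2
        assert first[0].spacers[:3] == tuple(guides[g][0] for g in "ABC")
        assert first[1].spacers[:3] == tuple(guides[g][1] for g in "ABC")

    def test_quad_arrays_use_disjoint_spacers(self):
        guides = _guides(["A", "B", "C", "D"])
        a1, a2 = build_in4mer_arrays(("A", "B", "C", "D"), guides)
        assert not set(a1.spacers) & set(a2.spacers)

    def test_insufficient_guides_names_gene(self):
        guides = {"A": ["ACGTACGTACGTACGTACGA"], "B": _guides(["B"])["B"]}
        with pytest.raises(LibraryDesignError, match="'A'"):
            build_in4mer_arrays(("A", "B"), guides)

    def test_triple_array_requires_pad_slot(self):
        sp = _guides(["x"], per_gene=4)["x"]
        with pytest.raises(LibraryDesignError, match="padding"):
            In4merArray(targets=("A", "B", "C"), spacers=tuple(sp), array_index=1)


class TestOligoAssembly:
    def _array(self, seed=0):
        rng = np.random.default_rng(seed)
        return In4merArray(
            targets=("A", "B"),
            spacers=tuple(random_spacer(rng) for _ in range(4)),
            array_index=1,
        )

    @pytest.mark.parametrize("dialect, length", [("inzolia", 208), ("prototype", 212)])
    def test_template_lengths(self, dialect, length):
        oligo = assemble_oligo(self._array(), dialect=dialect)
        assert oligo.length == length

    def test_internal_drs_verbatim_in_order(self):
        oligo = assemble_oligo(self._array())
        pos = [oligo.sequence.find(dr) for dr in INTERNAL_DRS]
        assert all(p >= 0 for p in pos)
        assert pos == sorted(pos)

    @pytest.mark.parametrize(
        "bad",
        ["ACGTACGTACGTACGTTTTT",   # Pol III terminator run
         "ACGTCTCACGTACGTACGTA",   # BsmBI site
         "ACGTACGTACGTACGTACG",    # 19 nt
         "ACGUACGUACGUACGUACGU"],  # RNA alphabet
    )
    def test_invalid_spacers_rejected(self, bad):
        with pytest.raises(LibraryDesignError):
            validate_spacer(bad)

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_round_trip_both_dialects(self, seed):
        rng = np.random.default_rng(seed)
        spacers = tuple(random_spacer(rng) for _ in range(4))
        array = In4merArray(targets=("A", "B"), spacers=spacers, array_index=1)
        for dialect in ("prototype", "inzolia"):
            oligo = assemble_oligo(array, dialect=dialect)
            assert parse_oligo(oligo.sequence, dialect=dialect) == spacers

    def test_parse_rejects_wrong_dialect(self):
        oligo = assemble_oligo(self._array(), dialect="inzolia")
        with pytest.raises(LibraryDesignError, match="flank"):
            parse_oligo(oligo.sequence, dialect="prototype")


class TestLibraryComposition:
    def test_prototype_total(self):
        assert library_size(PROTOTYPE_COMPOSITION) == 43972

    def test_relaxed_generation_total_near_fifty_thousand(self):
        total = library_size(INZOLIA_COMPOSITION)
        assert total == 2 * (19687 + 4435 + 376 + 100) + 20 + 500 + 50
        assert 49000 <= total <= 50000
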