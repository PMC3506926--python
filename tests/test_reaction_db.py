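"""Equation parsing, signatures, table loading, Km annotation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heteropath.reaction_db import (
    EquationParseError,
    Reaction,
    ReactionTableError,
    attach_km,
    load_reaction_table,
    parse_equation,
    reaction_signature,
    serialize_equation,
    synthetic_compound_id,
)
from helpers import signature_oracle


class TestParseEquation:
    def test_unit_coefficient_terms(self):
        subs, prods = parse_equation("C00022 + C00004 <=> C00186 + C00003")
        assert subs == [("C00022", 1.0), ("C00004", 1.0)]
        assert prods == [("C00186", 1.0), ("C00003", 1.0)]

    def test_prose_names_with_unicode_arrow(self):
        subs, prods = parse_equation(
            "Succinyl-CoA + acetyl-CoA ↔ CoA + 3-oxoadipyl-CoA"
        )
        assert len(subs) == 2 and len(prods) == 2
        assert all(coeff == 1.0 for _, coeff in subs + prods)

    def test_numeric_coefficients(self):
        subs, _ = parse_equation("2 C00001 + 0.5 C00007 = C00080")
        assert subs == [("C00001", 2.0), ("C00007", 0.5)]

    def test_missing_separator_raises(self):
        with pytest.raises(EquationParseError):
            parse_equation("C00001 + C00002 -> C00003")

    def test_name_resolution_and_synthetic_namespace(self):
        subs, _ = parse_equation(
            "Pentane-2,4-dione + oxygen <=> acetate + methylglyoxal",
            {"oxygen": "C00007", "acetate": "C00033", "methylglyoxal": "C00546"},
        )
        assert subs[0][0] == synthetic_compound_id("Pentane-2,4-dione")
        assert subs[1][0] == "C00007"

    coeffs = st.sampled_from([1.0, 2.0, 3.0, 0.5])
    cids = st.integers(1, 40).map(lambda i: f"C{i:05d}")
    term = st.tuples(cids, coeffs)
    side = st.lists(term, min_size=1, max_size=4)

    @given(subs=side, prods=side)
    @settings(max_examples=100, derandomize=True)
    def test_serialize_parse_roundtrip_is_fixed_point(self, subs, prods):
        text = serialize_equation(subs, prods)
        parsed = parse_equation(text)
        assert parsed == (subs, prods)
        assert serialize_equation(*parsed) == text


def _rand_reaction(rng, n_compounds=8):
    pool = [f"C{i:05d}" for i in range(1, n_compounds + 1)]
    k_s = int(rng.integers(1, 4))
    k_p = int(rng.integers(1, 4))
    pick = rng.choice(pool, size=min(k_s + k_p, n_compounds), replace=False)
    subs = tuple((c, float(rng.choice([1, 1, 2, 3]))) for c in pick[:k_s])
    prods = tuple((c, float(rng.choice([1, 1, 2, 3]))) for c in pick[k_s:])
    if not prods:
        prods = ((pool[-1], 1.0),)
    return Reaction("R", subs, prods)


class TestSignature:
    def test_side_swap_and_reorder_invariance(self):
        a = Reaction("a", (("A", 1.0), ("B", 1.0)), (("C", 1.0),))
        b = Reaction("b", (("C", 1.0),), (("B", 1.0), ("A", 1.0)))
        assert reaction_signature(a) == reaction_signature(b)

    def test_coefficient_change_breaks_signature(self):
        a = Reaction("a", (("A", 1.0), ("B", 1.0)), (("C", 1.0),))
        b = Reaction("b", (("A", 1.0), ("B", 2.0)), (("C", 1.0),))
        assert reaction_signature(a) != reaction_signature(b)

    def test_signature_equality_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(7)
        rxns = [_rand_reaction(rng) for _ in range(50)]
        for r1 in rxns:
            for r2 in rxns:
                same_sig = reaction_signature(r1) == reaction_signature(r2)
                same_oracle = signature_oracle(r1) == signature_oracle(r2)
                assert same_sig == same_oracle


class TestLoadReactionTable:
    def _write(self, path, rows):
        lines = ["reaction_id\tequation\tec\tgenes\torganisms"] + rows
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")

    def test_six_row_table_loads_six_reactions(self, table2_cases):
        assert len(table2_cases["adipate_semialdehyde"].db) == 6

    def test_empty_file_with_header(self, tmp_path):
        p = tmp_path / "empty.tsv"
        self._write(p, [])
        db = load_reaction_table(p)
        assert len(db) == 0 and db.skip_report == []

    def test_symbolic_coefficient_row_is_skipped_with_reason(self, tmp_path):
        p = tmp_path / "poly.tsv"
        self._write(p, ["R1\tn C00001 <=> C00002\t\t\t"])
        db = load_reaction_table(p)
        assert len(db) == 0
        assert len(db.skip_report) == 1 and db.skip_report[0][0] == "R1"

    def test_duplicate_reaction_id_raises(self, tmp_path):
        p = tmp_path / "dup.tsv"
        self._write(p, ["R1\tC00001 <=> C00002\t\t\t", "R1\tC00003 <=> C00004\t\t\t"])
        with pytest.raises(ReactionTableError):
            load_reaction_table(p)

    def test_missing_required_column_raises(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("reaction_id\tec\nR1\t1.1.1.1\n", encoding="utf-8")
        with pytest.raises(ReactionTableError):
            load_reaction_table(p)

    def test_row_count_accounting(self, tmp_path):
        p = tmp_path / "mix.tsv"
        self._write(p, [
            "R1\tC00001 <=> C00002\t\t\t",
            "R2\tC00002 <=> C00001\t\t\t",      # duplicate signature of R1
            "R3\tn C00001 <=> C00002\t\t\t",    # unusable
            "R4\tC00003 + C00001 <=> C00005\t\t\t",
        ])
        db = load_reaction_table(p)
        assert len(db) + len(db.skip_report) + len(db.merged) == 4
        assert db.merged == {"R2": "R1"}

    def test_duplicate_signatures_union_annotations(self, tmp_path):
        p = tmp_path / "ann.tsv"
        self._write(p, [
            "R1\tC00001 <=> C00002\t1.1.1.1\tgeneA\tOrgA",
            "R2\tC00002 <=> C00001\t2.2.2.2\tgeneB\tOrgB",
        ])
        db = load_reaction_table(p)
        keeper = db.reactions["R1"]
        assert set(keeper.ec_numbers) == {"1.1.1.1", "2.2.2.2"}
        assert {g for g, _ in keeper.sources} == {"geneA", "geneB"}


class TestAttachKm:
    def _db_with_ec(self, tmp_path, ec):
        p = tmp_path / "r.tsv"
        p.write_text(
            "reaction_id\tequation\tec\tgenes\torganisms\n"
            f"R1\tC00001 <=> C00002\t{ec}\t\t\n",
            encoding="utf-8",
        )
        return load_reaction_table(p)

    def test_minimum_km_wins(self, tmp_path):
        db = self._db_with_ec(tmp_path, "1.1.1.77")
        km = pd.DataFrame(
            [("1.1.1.77", "OrgA", 0.5), ("1.1.1.77", "OrgB", 0.2)],
            columns=["ec", "organism", "km_mM"],
        )
        out = attach_km(db, km)
        ann = out.reactions["R1"].km_annotation
        assert ann.km_value == 0.2 and ann.organism == "OrgB"

    def test_wildcard_ec_prefix_match(self, tmp_path):
        db = self._db_with_ec(tmp_path, "1.3.99.-")
        km = pd.DataFrame([("1.3.99.7", "OrgC", 1.0)], columns=["ec", "organism", "km_mM"])
        out = attach_km(db, km)
        assert out.reactions["R1"].km_annotation.organism == "OrgC"

    def test_no_match_stays_unannotated(self, tmp_path):
        db = self._db_with_ec(tmp_path, "9.9.9.9")
        km = pd.DataFrame([("1.1.1.1", "OrgA", 1.0)], columns=["ec", "organism", "km_mM"])
        out = attach_km(db, km)
        assert out.reactions["R1"].km_annotation is None

    def test_annotation_equals_linear_scan_min(self, tmp_path):
        rng = np.random.default_rng(11)
        ecs = [f"1.1.1.{i}" for i in range(1, 6)]
        rows = [
            (str(rng.choice(ecs)), f"Org{int(rng.integers(0, 5))}",
             float(np.round(rng.uniform(0.01, 2.0), 4)))
            for _ in range(40)
        ]
        km = pd.DataFrame(rows, columns=["ec", "organism", "km_mM"])
        for ec in ecs:
            db = self._db_with_ec(tmp_path, ec)
            out = attach_km(db, km)
            matching = [(k, o) for e, o, k in rows if e == ec]
            ann = out.reactions["R1"].km_annotation
            if not matching:
                assert ann is None
            else:
                expected = min(matching)
                assert (ann.km_value, ann.organism) == expected
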