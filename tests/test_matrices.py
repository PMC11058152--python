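"""Desire/supply matrix validation, I/O round-trips, and descriptive
summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aecpg_align import (
    AECPGCatalog,
    DEFAULT_CATALOG,
    DesireMatrix,
    SchemaError,
    ValidationError,
    cumulative_desire_counts,
    group_desire_summary,
    read_desire_matrix,
    read_desire_matrix_xlsx,
    read_supply_matrix,
    write_desire_matrix,
    write_supply_matrix,
)
from aecpg_align.case_study import DUTCH_SUPPLY

from conftest import make_record, make_supply


class TestRecordValidation:
    def test_score_outside_alphabet_rejected(self):
        with pytest.raises(ValidationError, match="alphabet"):
            make_record([0.3, 0, 0], [1, 0, 0])

    def test_weight_outside_alphabet_rejected(self):
        with pytest.raises(ValidationError, match="alphabet"):
            make_record([1, 0, 0], [3, 0, 0])

    def test_desire_without_weight_rejected(self):
        # an unmentioned good cannot carry expressed desire
        with pytest.raises(ValidationError, match="weight 0"):
            make_record([1, 0, 0], [0, 1, 0])

    def test_all_zero_weights_rejected(self):
        # the inclusion criterion: at least one good must be mentioned
        with pytest.raises(ValidationError, match="at least one"):
            make_record([0, 0, 0], [0, 0, 0])

    def test_half_score_reserved_for_citizens(self, catalog3):
        rec = make_record([0.5, 0, 0], [1, 0, 0], group="Banks")
        with pytest.raises(ValidationError, match="citizen"):
            DesireMatrix(catalog=catalog3, records=(rec,))

    def test_duplicate_ids_rejected(self, catalog3):
        recs = (
            make_record([1, 0, 0], [1, 0, 0], "x", "Citizens"),
            make_record([0, 1, 0], [0, 1, 0], "x", "Citizens"),
        )
        with pytest.raises(ValidationError, match="duplicate"):
            DesireMatrix(catalog=catalog3, records=recs)


@st.composite
def desire_matrices(draw):
    """Valid matrices over a 3-good catalog, mixing citizen and binary rows."""
    catalog = AECPGCatalog(("a", "b", "c"))
    n = draw(st.integers(1, 6))
    records = []
    for k in range(n):
        citizen = draw(st.booleans())
        pairs = [(0, 0), (0, 1), (0, 2), (1, 1), (1, 2)]
        if citizen:
            pairs += [(0.5, 1), (0.5, 2)]
        chosen = [draw(st.sampled_from(pairs)) for _ in range(3)]
        if all(w == 0 for _, w in chosen):
            chosen[draw(st.integers(0, 2))] = (1, 1)
        records.append(
            make_record(
                [float(d) for d, _ in chosen],
                [w for _, w in chosen],
                stakeholder_id=f"s{k}",
                group="Citizens" if citizen else "Org",
            )
        )
    return DesireMatrix(catalog=catalog, records=tuple(records))


class TestRoundTrip:
    @settings(max_examples=30, derandomize=True)
    @given(desire_matrices())
    def test_desire_matrix_roundtrip(self, tmp_path_factory, m):
        path = tmp_path_factory.mktemp("rt") / "m.csv"
        write_desire_matrix(m, path)
        back = read_desire_matrix(path, m.catalog)
        assert back == m

    def test_supply_matrix_roundtrip(self, tmp_path, dutch_supply):
        path = tmp_path / "supply.csv"
        write_supply_matrix(dutch_supply, path)
        assert read_supply_matrix(path) == dutch_supply

    def test_xlsx_adapter_maps_foreign_headers(self, tmp_path):
        # synthetic stand-in spreadsheet with spreadsheet-style headers
        df = pd.DataFrame(
            {
                "Stakeholder": ["s1"],
                "Stakeholder group": ["Banks"],
                **{f"{n}_score": [1] for n in DEFAULT_CATALOG},
                **{f"{n}_weight": [1] for n in DEFAULT_CATALOG},
            }
        ).rename(
            columns={
                "biodiversity_score": "Biodiversity score",
                "product_quality_weight": "Quality of products weight",
                "heritage_score": "Natural heritage score",
            }
        )
        path = tmp_path / "matrix.xlsx"
        df.to_excel(path, index=False)
        m = read_desire_matrix_xlsx(path)
        assert len(m) == 1
        assert m.records[0].group == "Banks"
        assert m.records[0].scores.sum() == 9


class TestReadErrors:
    def test_missing_column_named(self, tmp_path, catalog3):
        path = tmp_path / "bad.csv"
        path.write_text("stakeholder_id,group\na,Banks\n")
        with pytest.raises(SchemaError, match="biodiversity_score"):
            read_desire_matrix(path, catalog3)

    def test_invalid_row_names_stakeholder(self, tmp_path, catalog3):
        cols = ["stakeholder_id", "group"]
        for n in catalog3:
            cols += [f"{n}_score", f"{n}_weight"]
        path = tmp_path / "bad.csv"
        path.write_text(",".join(cols) + "\nrow7,Banks,1,0,0,0,0,0\n")
        with pytest.raises(ValidationError, match="row7"):
            read_desire_matrix(path, catalog3)

    def test_empty_supply_file(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(SchemaError):
            read_supply_matrix(path)

    def test_supply_value_outside_levels(self, tmp_path, catalog3):
        path = tmp_path / "s.csv"
        path.write_text("scenario_id," + ",".join(catalog3) + "\nx,0.7,0,1\n")
        with pytest.raises(ValidationError):
            read_supply_matrix(path, catalog3)


class TestGroupDesireSummary:
    def test_banks_style_cell(self, catalog3):
        # six binary scores, five of them 1: mean .83, se .17 (n-1 sd / sqrt n)
        recs = tuple(
            make_record([s, 0, 0], [1, 1, 0], f"b{k}", "Banks")
            for k, s in enumerate([1, 1, 1, 1, 1, 0])
        )
        m = DesireMatrix(catalog=catalog3, records=recs)
        table = group_desire_summary(m).table()
        assert table.loc["Banks", "biodiversity"] == "0.83 (0.17)"

    def test_two_point_group(self, catalog3):
        recs = (
            make_record([0, 0, 0], [1, 0, 0], "a", "G"),
            make_record([1, 0, 0], [1, 0, 0], "b", "G"),
        )
        m = DesireMatrix(catalog=catalog3, records=recs)
        row = group_desire_summary(m).data
        cell = row[(row.group == "G") & (row.aecpg == "biodiversity")].iloc[0]
        assert cell["mean"] == pytest.approx(0.5)
        assert cell["se"] == pytest.approx(0.5)  # sd .7071 / sqrt(2)

    def test_degenerate_groups(self, catalog3):
        recs = (
            make_record([1, 0, 0], [1, 0, 0], "only", "Solo"),
            make_record([1, 1, 0], [1, 1, 0], "c1", "Equal"),
            make_record([1, 1, 0], [1, 1, 0], "c2", "Equal"),
        )
        m = DesireMatrix(catalog=catalog3, records=recs)
        data = group_desire_summary(m).data
        assert (data[data.group == "Solo"]["se"] == 0).all()
        assert (data[data.group == "Equal"]["se"] == 0).all()

    def test_means_bounded_and_se_maximal_at_half(self, dutch_matrix):
        data = group_desire_summary(dutch_matrix).data
        assert data["mean"].between(0, 1).all()
        assert (data["se"] >= 0).all()

    def test_empty_matrix_errors(self, catalog3):
        with pytest.raises(ValidationError):
            group_desire_summary(
                DesireMatrix(catalog=catalog3, records=())
            )


class TestCumulativeCounts:
    def test_counting_rule_includes_half(self, catalog3):
        recs = (
            make_record([1, 0, 0], [1, 1, 0], "a", "Citizens"),
            make_record([0.5, 0, 0], [1, 1, 0], "b", "Citizens"),
            make_record([0, 1, 0], [1, 1, 0], "c", "Citizens"),
        )
        m = DesireMatrix(catalog=catalog3, records=recs)
        counts = cumulative_desire_counts(m)
        assert counts["biodiversity"] == 2  # 1 and 0.5 count, 0 does not
        assert counts["water_quality"] == 1
        assert counts["recreation"] == 0

    def test_permutation_invariance(self, toy_matrix):
        reversed_m = DesireMatrix(
            catalog=toy_matrix.catalog,
            records=tuple(reversed(toy_matrix.records)),
        )
        assert cumulative_desire_counts(toy_matrix).equals(
            cumulative_desire_counts(reversed_m)
        )

    def test_counts_bounded_by_n(self, dutch_matrix):
        counts = cumulative_desire_counts(dutch_matrix)
        assert (counts >= 0).all() and (counts <= len(dutch_matrix)).all()


def test_dutch_supply_rows_in_catalog_order(dutch_supply):
    assert [s.scenario_id for s in dutch_supply.scenarios] == list(DUTCH_SUPPLY)
    regional = dutch_supply["regional"]
    assert regional.supply.tolist() == [1, 1, 0.5, 1, 0.5, 1, 0.5, 1, 1]
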