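"""Screen deconvolution, normalization chain, hit calling and ranking."""

import math

import numpy as np
import pandas as pd
import pytest

from tilevar.models import ConditionsTable, CountMatrix, LibraryTable, SgRNA, ValidationError
from tilevar.screen import (
    call_hits,
    count_screen_reads,
    lfc_vs_pdna,
    lognorm,
    percent_rank,
    rank_and_percent_rank,
    rpm_normalize,
)


def _library(n_targeting=10, n_controls=0, seed=0):
    rng = np.random.default_rng(seed)
    members = []
    seen = set()
    while len(members) < n_targeting + n_controls:
        spacer = "".join("ACGT"[i] for i in rng.integers(0, 4, size=20))
        if spacer in seen:
            continue
        seen.add(spacer)
        if len(members) < n_targeting:
            members.append(SgRNA(spacer=spacer, pam="AGG", strand="+", cut_pos=30))
        else:
            members.append(SgRNA(spacer=spacer, is_control=True))
    return LibraryTable(members=members)


CONDITIONS = ConditionsTable(entries={"AAAAAA": "pDNA", "CCCCCC": "repA", "GGGGGG": "repB"})


class TestCounting:
    def test_constructed_read_lands_in_cell(self):
        lib = _library(3)
        spacer = lib.members[1].spacer
        read = "CCCCCC" + "CACCG" + spacer + "TTTTTTTT"
        m = count_screen_reads([read], lib, CONDITIONS)
        assert m.data.loc[lib.ids()[1], "repA"] == 1
        assert m.data.to_numpy().sum() == 1

    def test_discard_categories_and_conservation(self):
        lib = _library(3)
        spacer = lib.members[0].spacer
        reads = [
            "AAAAAA" + "CACCG" + spacer + "T" * 8,  # assigned
            "TTTTTT" + "CACCG" + spacer + "T" * 8,  # unknown barcode
            "AAAAAA" + "GGGGG" + spacer + "T" * 8,  # no CACCG anywhere
            "AAAAAA" + "CACCG" + "ACGT" * 5 + "T" * 8,  # unknown spacer
            "AAAAAA" + "CACCG" + "ACG",  # truncated spacer
        ]
        m = count_screen_reads(reads, lib, CONDITIONS)
        assert m.discards == {"no_barcode": 1, "no_prefix": 1, "no_spacer": 1, "too_short": 1}
        assert m.data.to_numpy().sum() + sum(m.discards.values()) == len(reads)

    def test_prefix_found_at_any_offset(self):
        lib = _library(2)
        spacer = lib.members[0].spacer
        read = "CCCCCC" + "TTTTTTTTTT" + "CACCG" + spacer
        m = count_screen_reads([read], lib, CONDITIONS)
        assert m.data.loc[lib.ids()[0], "repA"] == 1

    def test_synthetic_reads_match_construction_tallies(self):
        rng = np.random.default_rng(1)
        lib = _library(10)
        ids, spacers = lib.ids(), [g.spacer for g in lib.members]
        truth = pd.DataFrame(0, index=ids, columns=CONDITIONS.samples)
        reads = []
        barcode_of = {s: b for b, s in CONDITIONS.entries.items()}
        for _ in range(1000):
            k = int(rng.integers(0, 10))
            sample = CONDITIONS.samples[int(rng.integers(0, 3))]
            truth.iloc[k, truth.columns.get_loc(sample)] += 1
            reads.append(barcode_of[sample] + "CACCG" + spacers[k] + "ACGTACGT")
        m = count_screen_reads(reads, lib, CONDITIONS)
        assert m.data.equals(truth)

    def test_empty_library_rejected(self):
        with pytest.raises(ValidationError):
            count_screen_reads([], LibraryTable(members=[]), CONDITIONS)

    def test_duplicate_spacers_rejected_at_load(self):
        g = SgRNA(spacer="A" * 20, pam="AGG", strand="+", cut_pos=1)
        with pytest.raises(ValidationError):
            LibraryTable(members=[g, g])


class TestNormalizationChain:
    def test_rpm_forced_by_formula(self):
        m = CountMatrix(pd.DataFrame({"s": [1, 1, 2]}, index=list("abc")))
        rpm = rpm_normalize(m)
        assert rpm.data["s"].tolist() == [250000.0, 250000.0, 500000.0]

    def test_zero_column_stays_zero(self, caplog):
        m = CountMatrix(pd.DataFrame({"s": [0, 0, 0]}, index=list("abc")))
        with caplog.at_level("WARNING"):
            rpm = rpm_normalize(m)
        assert rpm.data["s"].tolist() == [0.0, 0.0, 0.0]
        assert any("zero" in r.message for r in caplog.records)

    def test_rpm_columns_sum_to_one_million(self):
        rng = np.random.default_rng(2)
        m = CountMatrix(
            pd.DataFrame(rng.integers(0, 500, size=(50, 3)), columns=list("xyz"))
        )
        rpm = rpm_normalize(m)
        assert np.allclose(rpm.data.sum(axis=0), 1e6, rtol=1e-9)

    @pytest.mark.parametrize("rpm_val,expected", [(0, 0.0), (1, 1.0)])
    def test_lognorm_values(self, rpm_val, expected):
        m = CountMatrix(pd.DataFrame({"s": [float(rpm_val)]}), layer="rpm")
        assert lognorm(m).data["s"].iloc[0] == pytest.approx(expected)

    def test_lognorm_single_guide_column(self):
        m = CountMatrix(pd.DataFrame({"s": [1_000_000.0]}), layer="rpm")
        assert lognorm(m).data["s"].iloc[0] == pytest.approx(math.log2(1_000_001))

    def test_lfc_identity_and_antisymmetry(self):
        ln = CountMatrix(
            pd.DataFrame({"pDNA": [1.0, 2.0], "s": [1.0, 2.0], "t": [3.0, 1.0]}),
            layer="lognorm",
        )
        lfc = lfc_vs_pdna(ln, "pDNA")
        assert "pDNA" not in lfc.data.columns
        assert lfc.data["s"].tolist() == [0.0, 0.0]
        swapped = CountMatrix(
            pd.DataFrame({"pDNA": [3.0, 1.0], "t": [1.0, 2.0]}), layer="lognorm"
        )
        assert (lfc_vs_pdna(swapped, "pDNA").data["t"] == -lfc.data["t"]).all()

    def test_lfc_direct_value(self):
        # rpm 3 in sample vs rpm 1 in pDNA -> log2(4) - log2(2) = 1
        rpm = CountMatrix(pd.DataFrame({"pDNA": [1.0], "s": [3.0]}), layer="rpm")
        lfc = lfc_vs_pdna(lognorm(rpm), "pDNA")
        assert lfc.data["s"].iloc[0] == pytest.approx(1.0)

    def test_lfc_missing_pdna_raises(self):
        ln = CountMatrix(pd.DataFrame({"s": [1.0]}), layer="lognorm")
        with pytest.raises(ValidationError):
            lfc_vs_pdna(ln, "pDNA")

    def test_lfc_invariant_to_column_scaling(self):
        rng = np.random.default_rng(3)
        raw = pd.DataFrame(
            rng.integers(1, 1000, size=(40, 2)), columns=["pDNA", "s"]
        )
        lfc1 = lfc_vs_pdna(lognorm(rpm_normalize(CountMatrix(raw))), "pDNA")
        scaled = raw.copy()
        scaled["s"] *= 7
        lfc2 = lfc_vs_pdna(lognorm(rpm_normalize(CountMatrix(scaled))), "pDNA")
        # scaling a column's raw counts cancels in RPM, so LFC is unchanged
        assert np.allclose(lfc1.data["s"], lfc2.data["s"])


class TestHitCalling:
    def _lfc(self, values: dict[str, float]) -> CountMatrix:
        return CountMatrix(
            pd.DataFrame({"repA": pd.Series(values)}), layer="lfc"
        )

    def test_zero_variance_controls(self):
        lib = _library(2, n_controls=3)
        ids = lib.ids()
        vals = {i: 0.5 for i in ids}
        vals[ids[0]] = 2.0
        hits = call_hits(self._lfc(vals), lib, ["repA"])
        by_id = hits.set_index("sgRNA_id")
        assert by_id.loc[ids[0], "is_hit"]
        assert by_id["threshold"].iloc[0] == pytest.approx(0.5)
        assert not by_id.loc[ids[1], "is_hit"]  # equal to threshold is not a hit

    def test_two_control_threshold_hand_computed(self):
        lib = _library(1, n_controls=2)
        ids = lib.ids()
        vals = {ids[0]: 4.0, ids[1]: 0.0, ids[2]: 2.0}
        hits = call_hits(self._lfc(vals), lib, ["repA"])
        # controls {0, 2}: mean 1, sample SD sqrt(2) -> threshold 1 + 2*sqrt(2)
        assert hits["threshold"].iloc[0] == pytest.approx(1 + 2 * math.sqrt(2))
        assert hits.set_index("sgRNA_id").loc[ids[0], "is_hit"]

    def test_single_control_rejected(self):
        lib = _library(1, n_controls=1)
        vals = {i: 0.0 for i in lib.ids()}
        with pytest.raises(ValidationError):
            call_hits(self._lfc(vals), lib, ["repA"])

    def test_replicate_averaging_at_lfc_level(self):
        lib = _library(1, n_controls=2)
        ids = lib.ids()
        data = pd.DataFrame(
            {"repA": [3.0, 0.1, -0.1], "repB": [1.0, -0.1, 0.1]}, index=ids
        )
        hits = call_hits(CountMatrix(data, layer="lfc"), lib, ["repA", "repB"])
        assert hits.set_index("sgRNA_id").loc[ids[0], "mean_lfc"] == pytest.approx(2.0)


class TestRanking:
    @pytest.mark.parametrize(
        "rank,pool,expected",
        [(16923, 18651, 90.74), (1, 18648, 0.01), (18648, 18648, 100.00)],
    )
    def test_percent_rank_rounding(self, rank, pool, expected):
        assert percent_rank(rank, pool) == expected

    def test_rank_one_is_most_enriched_with_min_ties(self):
        m = CountMatrix(
            pd.DataFrame({"s": [5.0, 9.0, 9.0, 1.0]}, index=list("abcd")), layer="lfc"
        )
        rr = rank_and_percent_rank(m, "s")
        assert rr["b"][0] == 1 and rr["c"][0] == 1  # tie shares the min rank
        assert rr["a"][0] == 3 and rr["d"][0] == 4
        assert rr["d"][1] == 100.0

    def test_row_permutation_permutes_output(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=30)
        idx = [f"g{i}" for i in range(30)]
        m1 = CountMatrix(pd.DataFrame({"s": vals}, index=idx), layer="lfc")
        perm = rng.permutation(30)
        m2 = CountMatrix(
            pd.DataFrame({"s": vals[perm]}, index=[idx[i] for i in perm]), layer="lfc"
        )
        r1 = rank_and_percent_rank(m1, "s")
        r2 = rank_and_percent_rank(m2, "s")
        assert r1 == r2
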