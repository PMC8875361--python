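"""Regulon rule engine, candidate gate, masking, comparison, heat-map export."""

import itertools

import numpy as np
import pandas as pd
import pytest

from sigreg import regulon
from sigreg.regulon import DOWN, MASKED, NS, UP
from sigreg.strains import MUTANT_STRAINS

STATUSES = (UP, DOWN, NS)


def oracle_assign(b, d, bce, cde):
    """Independent transliteration of the published assignment rules,
    sentence by sentence, used only as a test oracle.

    SigB: significantly down-regulated in both dsigB and dsigBCE but not in
    the other mutant strains, up-regulation in dsigCDE allowed (and the
    mirrored up case with down-regulation in dsigCDE allowed).  SigD: the
    same with dsigD/dsigCDE, the exception granted to dsigBCE.  SigC-and/or-E:
    simultaneously significantly down- or up-regulated in both triple
    mutants but not in the single mutants.
    """
    sigb_down = (b == DOWN) and (bce == DOWN) and (d == NS) and (cde != DOWN)
    sigb_up = (b == UP) and (bce == UP) and (d == NS) and (cde != UP)
    sigd_down = (d == DOWN) and (cde == DOWN) and (b == NS) and (bce != DOWN)
    sigd_up = (d == UP) and (cde == UP) and (b == NS) and (bce != UP)
    core_down = (bce == DOWN) and (cde == DOWN) and (b == NS) and (d == NS)
    core_up = (bce == UP) and (cde == UP) and (b == NS) and (d == NS)
    if sigb_down:
        return "SigB", "down"
    if sigb_up:
        return "SigB", "up"
    if sigd_down:
        return "SigD", "down"
    if sigd_up:
        return "SigD", "up"
    if core_down:
        return "SigCorE", "down"
    if core_up:
        return "SigCorE", "up"
    regulated = [s for s in (b, d, bce, cde) if s != NS]
    if len(regulated) >= 2:
        if set(regulated) == {UP}:
            return "shared", "up"
        if set(regulated) == {DOWN}:
            return "shared", "down"
        return "shared", "mixed"
    return "none", "na"


class TestAssignPattern:
    def test_matches_oracle_on_all_81_patterns(self):
        for pattern in itertools.product(STATUSES, repeat=4):
            assert regulon.assign_pattern(*pattern) == oracle_assign(*pattern), pattern

    @pytest.mark.parametrize("pattern,expected", [
        ((DOWN, NS, DOWN, NS), ("SigB", "down")),
        ((NS, DOWN, UP, DOWN), ("SigD", "down")),
        ((NS, NS, DOWN, DOWN), ("SigCorE", "down")),
        ((DOWN, DOWN, DOWN, DOWN), ("shared", "down")),
        ((NS, NS, NS, NS), ("none", "na")),
        ((UP, NS, UP, DOWN), ("SigB", "up")),
        ((NS, NS, UP, UP), ("SigCorE", "up")),
    ])
    def test_published_example_patterns(self, pattern, expected):
        assert regulon.assign_pattern(*pattern) == expected

    def test_labels_are_a_partition(self):
        for pattern in itertools.product(STATUSES, repeat=4):
            label, direction = regulon.assign_pattern(*pattern)
            assert label in regulon.LABELS
            assert (direction == "na") == (label == "none")

    def test_b_d_role_swap_symmetry(self):
        for b, d, bce, cde in itertools.product(STATUSES, repeat=4):
            label, direction = regulon.assign_pattern(b, d, bce, cde)
            s_label, s_direction = regulon.assign_pattern(d, b, cde, bce)
            swap = {"SigB": "SigD", "SigD": "SigB"}
            assert s_label == swap.get(label, label)
            assert s_direction == direction


def status_frame(**per_gene):
    """Build a status table: gene -> (status, twofold)."""
    return pd.DataFrame(
        {"status": {g: v[0] for g, v in per_gene.items()},
         "twofold": {g: v[1] for g, v in per_gene.items()}}
    )


def result_frame(rows):
    """ContrastResult-like table from {gene: (log2fc, fdr)}."""
    return pd.DataFrame(
        {"log2fc": {g: v[0] for g, v in rows.items()},
         "fdr": {g: v[1] for g, v in rows.items()}}
    )


class TestCallStatus:
    def test_significance_and_twofold_gates(self):
        res = result_frame({
            "a": (1.2, 0.01),    # significant and two-fold
            "b": (-0.6, 0.02),   # significant but sub-two-fold: still DOWN
            "c": (-1.5, 0.2),    # large but not significant
            "d": (0.0, 0.001),   # significant fdr but no direction
        })
        st = regulon.call_status(res)
        assert st.loc["a", "status"] == UP and st.loc["a", "twofold"]
        assert st.loc["b", "status"] == DOWN and not st.loc["b", "twofold"]
        assert st.loc["c", "status"] == NS and not st.loc["c", "twofold"]
        assert st.loc["d", "status"] == NS

    def test_nan_fdr_is_not_significant(self):
        st = regulon.call_status(result_frame({"a": (2.0, np.nan)}))
        assert st.loc["a", "status"] == NS

    def test_masked_gene(self):
        st = regulon.call_status(result_frame({"sll0306": (-3.0, 1e-9)}),
                                 mask_genes=["sll0306"])
        assert st.loc["sll0306", "status"] == MASKED
        assert not st.loc["sll0306", "twofold"]

    def test_sigma_mask_per_strain(self):
        assert regulon.sigma_mask_for_strain("dsigB") == frozenset({"sll0306"})
        assert regulon.sigma_mask_for_strain("dsigBCE") == frozenset(
            {"sll0306", "sll0184", "sll1689"})
        assert regulon.sigma_mask_for_strain("CS") == frozenset()


class TestCandidateGenes:
    def make(self, twofold_in):
        statuses = {}
        for strain in MUTANT_STRAINS:
            statuses[strain] = status_frame(
                g1=(DOWN, strain in twofold_in), g2=(DOWN, False)
            )
        return statuses

    def test_twofold_in_one_strain_suffices(self):
        genes = regulon.candidate_genes(self.make({"dsigBCE"}))
        assert list(genes) == ["g1"]

    def test_significant_subtwofold_everywhere_excluded(self):
        genes = regulon.candidate_genes(self.make(set()))
        assert len(genes) == 0

    def test_missing_strain_table_is_fatal(self):
        statuses = self.make({"dsigB"})
        del statuses["dsigD"]
        with pytest.raises(ValueError, match="dsigD"):
            regulon.candidate_genes(statuses)


class TestAssignRegulons:
    def test_masked_rule_position_flagged_unclassifiable(self):
        statuses = {
            "dsigB": status_frame(g=(MASKED, False)),
            "dsigD": status_frame(g=(NS, False)),
            "dsigBCE": status_frame(g=(DOWN, True)),
            "dsigCDE": status_frame(g=(NS, False)),
        }
        out = regulon.assign_regulons(statuses, "heat",
                                      genes=pd.Index(["g"]))
        assert bool(out.loc["g", "unclassifiable"])
        assert out.loc["g", "label"] == "none"

    def test_assigns_planted_pattern(self):
        statuses = {
            "dsigB": status_frame(g=(DOWN, True)),
            "dsigD": status_frame(g=(NS, False)),
            "dsigBCE": status_frame(g=(DOWN, True)),
            "dsigCDE": status_frame(g=(NS, False)),
        }
        out = regulon.assign_regulons(statuses, "heat")
        assert out.loc["g", "label"] == "SigB"
        assert out.loc["g", "direction"] == "down"


def assignment_frame(labels):
    return pd.DataFrame(
        {"label": labels, "direction": "down"},
        index=pd.Index(list(labels), name="gene_id"),
    )


class TestCompareConditions:
    def make(self, heat_genes, light_genes):
        heat = pd.DataFrame({"label": "SigB", "direction": "down"},
                            index=pd.Index(sorted(heat_genes), name="gene_id"))
        light = pd.DataFrame({"label": "SigB", "direction": "down"},
                             index=pd.Index(sorted(light_genes), name="gene_id"))
        return {"heat": heat, "highlight": light}

    def test_single_shared_gene_appears_in_intersection(self):
        # the high-light set shares exactly one member with the heat set
        light = {"glm", "ndhD2", "ssl2501", "slr1236", "sll0847", "slr0284"}
        heat = {"ssl2501", "pilA1", "glcD"}
        out = regulon.compare_conditions(self.make(heat, light))
        inter = set(out.gene_id[(out.label == "SigB")
                                & (out.set_name == "intersection")])
        assert inter == {"ssl2501"}
        only_light = set(out.gene_id[(out.label == "SigB")
                                     & (out.set_name == "only_highlight")])
        assert only_light == light - {"ssl2501"}

    def test_disjoint_sets_empty_intersection(self):
        out = regulon.compare_conditions(self.make({"a"}, {"b"}))
        assert (out.set_name == "intersection").sum() == 0

    def test_identical_sets_intersection_equals_union(self):
        out = regulon.compare_conditions(self.make({"a", "b"}, {"a", "b"}))
        inter = set(out.gene_id[out.set_name == "intersection"])
        assert inter == {"a", "b"}
        assert not out.set_name.str.startswith("only_").any() or (
            out[out.set_name.str.startswith("only_")].empty
        )

    def test_requires_two_conditions(self):
        with pytest.raises(ValueError, match="two conditions"):
            regulon.compare_conditions({"heat": assignment_frame("ab")})


class TestAnnotateCsResponse:
    def make_assignments(self):
        return pd.DataFrame({"label": ["SigB"], "direction": ["down"]},
                            index=pd.Index(["g1"], name="gene_id"))

    def test_upregulated_in_stressed_control(self):
        cs = result_frame({"g1": (1.1, 0.001)})
        out = regulon.annotate_cs_response(self.make_assignments(), cs)
        assert out.loc["g1", "cs_response"] == "up"

    def test_subtwofold_significant_still_counts(self):
        cs = result_frame({"g1": (0.4, 0.01)})
        out = regulon.annotate_cs_response(self.make_assignments(), cs)
        assert out.loc["g1", "cs_response"] == "up"

    def test_nonsignificant_is_ns(self):
        cs = result_frame({"g1": (-0.4, 0.6)})
        out = regulon.annotate_cs_response(self.make_assignments(), cs)
        assert out.loc["g1", "cs_response"] == "ns"

    def test_missing_table_fills_unknown(self, caplog):
        out = regulon.annotate_cs_response(self.make_assignments(), None)
        assert (out["cs_response"] == "unknown").all()


class TestHeatmapMatrix:
    def make_tables(self):
        return {
            s: result_frame({"g1": (fc, 0.01), "g2": (0.1, 0.9)})
            for s, fc in zip(MUTANT_STRAINS, (-1.2, 0.1, -1.4, 0.0))
        }

    def test_row_and_column_order_preserved(self):
        m = regulon.heatmap_matrix(self.make_tables(), ["g2", "g1"])
        assert list(m.index) == ["g2", "g1"]
        assert m.loc["g1"].tolist() == [-1.2, 0.1, -1.4, 0.0]

    def test_empty_subset_gives_zero_rows(self):
        m = regulon.heatmap_matrix(self.make_tables(), [])
        assert m.shape[0] == 0

    def test_masked_entry_written_as_na(self, tmp_path):
        m = regulon.heatmap_matrix(self.make_tables(), ["g1"],
                                   masked={"dsigB": ["g1"]})
        assert np.isnan(m.loc["g1", "dsigB"])
        regulon.write_heatmap(m, tmp_path / "hm.tsv")
        text = (tmp_path / "hm.tsv").read_text()
        assert "NA" in text.splitlines()[1]

    def test_unknown_gene_is_fatal(self):
        with pytest.raises(KeyError, match="gX"):
            regulon.heatmap_matrix(self.make_tables(), ["gX"])
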