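"""Replicate hit rule, ranking and deconvolution validation."""

import numpy as np
import pandas as pd
import pytest

from ldlrscreen import hits


def summaries_from(z_by_gene: dict, scorable=True) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": list(z_by_gene),
            "replicate_z": [list(v) for v in z_by_gene.values()],
            "n_replicates_used": [len(v) for v in z_by_gene.values()],
            "mean_z": [float(np.mean(v)) for v in z_by_gene.values()],
            "scorable": scorable,
        }
    )


def wellz_from(rows) -> pd.DataFrame:
    """rows: (gene, replicate, z [, role, qc_flag, sirna])."""
    recs = []
    for r in rows:
        gene, rep, z = r[:3]
        role = r[3] if len(r) > 3 else "sample"
        flag = r[4] if len(r) > 4 else "ok"
        rec = {"plate": f"r{rep}", "well": "A01", "replicate": rep,
               "gene": gene, "role": role, "z": z, "qc_flag": flag}
        if len(r) > 5:
            rec["sirna"] = r[5]
        recs.append(rec)
    return pd.DataFrame(recs)


class TestSummarize:
    def test_mean_and_counts(self):
        wz = wellz_from([("g", 1, 2.5), ("g", 2, 2.1), ("g", 3, 0.5)])
        s = hits.summarize_genes(wz)
        assert s["mean_z"].iloc[0] == pytest.approx(1.7)
        assert s["n_replicates_used"].iloc[0] == 3
        called = hits.call_primary_hits(s, t=2.0, k=2)
        assert called["n_beyond_up"].iloc[0] == 2

    def test_excluded_replicate_dropped(self):
        wz = wellz_from([("g", 1, np.nan, "sample", "excluded_low_cell_count"),
                         ("g", 2, 2.2), ("g", 3, 2.3)])
        s = hits.summarize_genes(wz)
        assert s["n_replicates_used"].iloc[0] == 2
        assert s["mean_z"].iloc[0] == pytest.approx(2.25)

    def test_all_replicates_excluded_unscorable(self):
        wz = wellz_from(
            [("g", r, np.nan, "sample", "excluded_degenerate_scale")
             for r in (1, 2, 3)]
            + [("other", 1, 0.1), ("other", 2, 0.2)]
        )
        design = pd.DataFrame(
            {"gene": ["g", "other"], "role": "sample"}
        )
        s = hits.summarize_genes(wz, design=design)
        row = s.set_index("gene").loc["g"]
        assert not row["scorable"]
        called = hits.call_primary_hits(s)
        assert called.set_index("gene").loc["g", "hit_call"] == "none"

    def test_controls_never_summarized(self):
        wz = wellz_from([("NS", 1, 5.0, "ns_control"), ("g", 1, 1.0),
                         ("g", 2, 1.0)])
        s = hits.summarize_genes(wz)
        assert set(s["gene"]) == {"g"}


class TestPrimaryRule:
    @pytest.mark.parametrize(
        "zs,expected",
        [
            ((2.5, 2.1, 0.5), "up"),
            ((2.5, -2.1, 1.9), "none"),       # one per direction
            ((-2.0, -2.0, 0.0), "down"),      # inclusive boundary
            ((2.0, 2.0, -3.0), "up"),
            ((1.99, 2.5, 1.0), "none"),       # only one beyond
            ((-2.5, -2.5, -2.5), "down"),
        ],
    )
    def test_rule_application(self, zs, expected):
        s = summaries_from({"g": zs})
        called = hits.call_primary_hits(s, t=2.0, k=2)
        assert called["hit_call"].iloc[0] == expected

    def test_mixed_direction_possible_config_yields_none(self):
        s = summaries_from({"g": (3.0, -3.0)})
        called = hits.call_primary_hits(s, t=2.0, k=1)
        assert called["hit_call"].iloc[0] == "none"

    def test_monotone_in_threshold_and_k(self):
        rng = np.random.default_rng(0)
        zmap = {f"g{i}": rng.normal(0, 2, 3) for i in range(200)}
        s = summaries_from(zmap)

        def hit_set(t, k):
            c = hits.call_primary_hits(s, t=t, k=k)
            return set(c.loc[c["hit_call"] != "none", "gene"])

        assert hit_set(2.5, 2) <= hit_set(2.0, 2)
        assert hit_set(2.0, 3) <= hit_set(2.0, 2)

    def test_direction_coherence(self):
        rng = np.random.default_rng(1)
        zmap = {f"g{i}": rng.normal(0, 2, 3) for i in range(300)}
        called = hits.call_primary_hits(summaries_from(zmap), t=2.0, k=2)
        up = called[called["hit_call"] == "up"]
        down = called[called["hit_call"] == "down"]
        assert (up["mean_z"] > 0).all()
        assert (down["mean_z"] < 0).all()


class TestRanking:
    def test_tie_break_and_order(self):
        s = summaries_from(
            {"b": (2.4, 2.4, 2.4), "a": (2.4, 2.4, 2.4),
             "top": (3.1, 3.1, 3.1), "dn": (-2.8, -2.8, -2.8),
             "dn2": (-3.5, -3.5, -3.5)}
        )
        ranked = hits.rank_hits(hits.call_primary_hits(s))
        assert list(ranked["gene"]) == ["top", "a", "b", "dn2", "dn"]

    def test_empty_and_singleton(self):
        empty = hits.rank_hits(
            hits.call_primary_hits(summaries_from({"g": (0.0, 0.0, 0.0)}))
        )
        assert len(empty) == 0
        one = hits.rank_hits(
            hits.call_primary_hits(summaries_from({"g": (2.5, 2.5, 0.0)}))
        )
        assert list(one["gene"]) == ["g"]


class TestDeconvolution:
    @pytest.mark.parametrize(
        "direction,zs,expected",
        [
            ("up", (1.7, 0.2, -0.3), True),
            ("up", (-1.8, -1.7, 0.1), False),   # wrong direction
            ("down", (-1.6, 0.0, 0.0), True),   # inclusive boundary
            ("down", (1.8, 1.9, 0.0), False),
            ("up", (1.59, 1.59, 1.59), False),
        ],
    )
    def test_validation_rule(self, direction, zs, expected):
        records = pd.DataFrame(
            {"gene": ["g"], "primary_direction": [direction],
             "sirna_z": [list(zs)]}
        )
        out = hits.validate_deconvolution(records, t=1.6, m=1)
        assert bool(out["validated"].iloc[0]) is expected

    def test_min_sirnas_two(self):
        records = pd.DataFrame(
            {"gene": ["g"], "primary_direction": ["up"],
             "sirna_z": [[1.7, 1.8, 0.0]]}
        )
        assert bool(
            hits.validate_deconvolution(records, t=1.6, m=2)["validated"].iloc[0]
        )
        assert not bool(
            hits.validate_deconvolution(records, t=1.6, m=3)["validated"].iloc[0]
        )

    def test_directionless_record_rejected(self):
        records = pd.DataFrame(
            {"gene": ["g"], "primary_direction": ["none"],
             "sirna_z": [[2.0, 2.0, 2.0]]}
        )
        with pytest.raises(ValueError, match="direction"):
            hits.validate_deconvolution(records)

    def test_summarize_aggregates_sirna_replicates(self):
        wz = wellz_from(
            [("g", 1, 2.0, "sample", "ok", 1), ("g", 2, 1.0, "sample", "ok", 1),
             ("g", 1, -0.5, "sample", "ok", 2), ("g", 2, 0.5, "sample", "ok", 2),
             ("g", 1, 0.0, "sample", "ok", 3), ("g", 2, 0.2, "sample", "ok", 3)]
        )
        calls = pd.DataFrame({"gene": ["g"], "hit_call": ["up"]})
        rec = hits.summarize_deconvolution(wz, calls)
        assert rec["sirna_z"].iloc[0] == pytest.approx([1.5, 0.0, 0.1])
        assert rec["primary_direction"].iloc[0] == "up"

    def test_summarize_requires_directional_primary(self):
        wz = wellz_from([("g", 1, 2.0, "sample", "ok", 1)])
        calls = pd.DataFrame({"gene": ["g"], "hit_call": ["none"]})
        with pytest.raises(ValueError, match="direction"):
            hits.summarize_deconvolution(wz, calls)
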