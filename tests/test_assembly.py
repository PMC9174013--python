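import itertools
import random

import pytest

from cernet.assembly import (
    CeRNANetwork,
    Triad,
    assemble,
    export_network,
    read_network,
    summarize,
)
from cernet.interactions import merge_pairs


def catalogs(cm_rows, mg_rows):
    return (
        merge_pairs([(c, m, "db") for c, m in cm_rows], "circRNA", "miRNA"),
        merge_pairs([(m, g, "db") for m, g in mg_rows], "miRNA", "mRNA"),
    )


def brute_force_assemble(cm_rows, mg_rows, circ_de, mirna_de, mrna_de):
    """Independent oracle: triple loop over all combinations."""
    triads = set()
    for c, m, g in itertools.product(circ_de, mirna_de, mrna_de):
        if (c, m) not in cm_rows or (m, g) not in mg_rows:
            continue
        dirs = (circ_de[c], mirna_de[m], mrna_de[g])
        if dirs == ("up", "down", "up"):
            triads.add((c, m, g, "up-down-up"))
        elif dirs == ("down", "up", "down"):
            triads.add((c, m, g, "down-up-down"))
    return triads


class TestAssemble:
    def test_consistent_triad_included(self):
        cm, mg = catalogs([("c1", "m1")], [("m1", "g1")])
        net = assemble(cm, mg, {"c1": "up"}, {"m1": "down"}, {"g1": "up"})
        assert net.triads == [Triad("c1", "m1", "g1", "up-down-up")]
        assert ("c1", "m1", "circRNA-miRNA") in net.edges

    def test_paradigm_violation_excluded(self):
        cm, mg = catalogs([("c1", "m1")], [("m1", "g1")])
        net = assemble(cm, mg, {"c1": "up"}, {"m1": "up"}, {"g1": "up"})
        assert net.triads == []
        assert net.nodes == {} and net.edges == set()

    def test_missing_de_direction_excludes_triad(self):
        cm, mg = catalogs([("c1", "m1")], [("m1", "g1")])
        net = assemble(cm, mg, {"c1": "up"}, {}, {"g1": "up"})
        assert net.triads == []

    def test_invalid_direction_rejected(self):
        cm, mg = catalogs([("c1", "m1")], [("m1", "g1")])
        with pytest.raises(ValueError, match="up or down"):
            assemble(cm, mg, {"c1": "ns"}, {"m1": "down"}, {"g1": "up"})

    def test_matches_bruteforce_oracle_on_random_catalogs(self):
        rng = random.Random(17)
        for _ in range(20):
            circs = [f"c{i}" for i in range(rng.randint(1, 10))]
            mirnas = [f"m{i}" for i in range(rng.randint(1, 10))]
            genes = [f"g{i}" for i in range(rng.randint(1, 30))]
            cm_rows = {(rng.choice(circs), rng.choice(mirnas)) for _ in range(rng.randint(0, 40))}
            mg_rows = {(rng.choice(mirnas), rng.choice(genes)) for _ in range(rng.randint(0, 80))}
            circ_de = {c: rng.choice(["up", "down"]) for c in circs if rng.random() < 0.7}
            mirna_de = {m: rng.choice(["up", "down"]) for m in mirnas if rng.random() < 0.7}
            mrna_de = {g: rng.choice(["up", "down"]) for g in genes if rng.random() < 0.7}
            cm, mg = catalogs(cm_rows, mg_rows)
            net = assemble(cm, mg, circ_de, mirna_de, mrna_de)
            got = {(t.circ_id, t.mirna_id, t.mrna_id, t.paradigm) for t in net.triads}
            assert got == brute_force_assemble(cm_rows, mg_rows, circ_de, mirna_de, mrna_de)

    def test_adding_a_pair_never_removes_triads(self):
        cm_rows, mg_rows = [("c1", "m1")], [("m1", "g1"), ("m1", "g2")]
        de = ({"c1": "up", "c2": "up"}, {"m1": "down", "m2": "down"}, {"g1": "up", "g2": "up"})
        cm, mg = catalogs(cm_rows, mg_rows)
        before = set(assemble(cm, mg, *de).triads)
        cm2, mg2 = catalogs(cm_rows + [("c2", "m2")], mg_rows + [("m2", "g1")])
        after = set(assemble(cm2, mg2, *de).triads)
        assert before <= after

    def test_removing_de_feature_removes_exactly_its_triads(self):
        cm, mg = catalogs([("c1", "m1"), ("c2", "m1")], [("m1", "g1"), ("m1", "g2")])
        de_circ = {"c1": "up", "c2": "up"}
        full = set(assemble(cm, mg, de_circ, {"m1": "down"}, {"g1": "up", "g2": "up"}).triads)
        without = set(
            assemble(cm, mg, {"c2": "up"}, {"m1": "down"}, {"g1": "up", "g2": "up"}).triads
        )
        assert without == {t for t in full if t.circ_id != "c1"}

    def test_planted_triads_recovered_from_truth(self, default_study, default_truth):
        """Feeding the planted directions recovers every planted triad."""
        directions = default_truth.de_features
        net = assemble(
            default_study.circ_mirna_pairs,
            default_study.mirna_mrna_pairs,
            {f: d for f, d in directions.items() if f.startswith("circ")},
            {f: d for f, d in directions.items() if f.startswith("mir")},
            {f: d for f, d in directions.items() if f.startswith("gene")},
        )
        assert set(default_truth.true_triads) <= set(net.triads)
        for t in net.triads:  # specificity by construction
            expected = ("up", "down", "up") if t.paradigm == "up-down-up" else ("down", "up", "down")
            assert (
                directions[t.circ_id], directions[t.mirna_id], directions[t.mrna_id]
            ) == expected


class TestSummarizeAndExport:
    def build(self):
        cm, mg = catalogs([("c1", "m1"), ("c2", "m2")], [("m1", "g1"), ("m2", "g2")])
        return assemble(
            cm, mg,
            {"c1": "up", "c2": "down"},
            {"m1": "down", "m2": "up"},
            {"g1": "up", "g2": "down"},
        )

    def test_summarize_counts(self):
        s = summarize(self.build())
        assert s == {
            "n_circ": 2, "n_mirna": 2, "n_mrna": 2, "n_triads": 2,
            "n_per_paradigm": {"up-down-up": 1, "down-up-down": 1},
        }

    def test_summarize_empty(self):
        s = summarize(CeRNANetwork())
        assert s["n_triads"] == 0 and s["n_circ"] == 0

    @pytest.mark.parametrize("fmt", ["graphml", "tsv"])
    def test_roundtrip(self, tmp_path, fmt):
        net = self.build()
        path = tmp_path / f"net.{fmt}"
        export_network(net, path, fmt)
        assert read_network(path, fmt) == net

    @pytest.mark.parametrize("fmt", ["graphml", "tsv"])
    def test_empty_network_exports_valid_document(self, tmp_path, fmt):
        path = tmp_path / f"empty.{fmt}"
        export_network(CeRNANetwork(), path, fmt)
        assert read_network(path, fmt) == CeRNANetwork()

    def test_tsv_line_count_is_triads_plus_header(self, tmp_path):
        net = self.build()
        path = tmp_path / "net.tsv"
        export_network(net, path, "tsv")
        assert len(path.read_text().strip().splitlines()) == len(net.triads) + 1

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="format"):
            export_network(CeRNANetwork(), tmp_path / "x", "xml")
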