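import pytest

from idrscape.ortholog_triage import (
    DomainHit,
    call_orthologs,
    dedup_identical,
    filter_significant,
    parse_hit_table,
    status_counts,
    write_hit_table,
)
from idrscape.synthetic_data import GeneratorSpec, gen_hit_table

DOMTBL = """\
# target name accession tlen query name accession qlen E-value score bias ...
#--- --- --- --- --- --- --- --- --- ---
protA - 512 protease - 180 1.2e-09 55.0 0.1 1 1 0 0 0 0 0 0 1 512 - -
protA - 512 zinc_finger - 60 3.4e-07 40.0 0.0 1 1 0 0 0 0 0 0 1 512 - -
protB - 300 protease - 180 2.0e-03 10.0 0.0 1 1 0 0 0 0 0 0 1 300 - -
"""


class TestParseHitTable:
    def test_toy_domtbl(self, tmp_path):
        p = tmp_path / "hits.domtbl"
        p.write_text(DOMTBL)
        hits = parse_hit_table(p, dialect="hmmer3-domtbl")
        assert len(hits) == 3
        assert hits[0].protein_id == "protA"
        assert hits[0].evalue == pytest.approx(1.2e-09)
        assert hits[0].length == 512

    def test_comments_only_gives_empty(self, tmp_path):
        p = tmp_path / "hits.domtbl"
        p.write_text("# nothing\n# here\n")
        assert parse_hit_table(p, dialect="hmmer3-domtbl") == []

    def test_duplicate_target_query_rows_collapsed(self, tmp_path):
        row = "protA - 512 protease - 180 1.2e-09 55.0 0.1 1 2 0 0 0 0 0 0 1 512 - -\n"
        p = tmp_path / "hits.domtbl"
        p.write_text(row + row)
        assert len(parse_hit_table(p, dialect="hmmer3-domtbl")) == 1

    def test_malformed_row_reports_line_number(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("protA\tsp\t\tg1\t100\tprotease\t1e-9\nbad row\n")
        with pytest.raises(ValueError, match=":2:"):
            parse_hit_table(p, dialect="tsv")

    def test_tsv_round_trip(self, tmp_path):
        hits, _ = gen_hit_table(GeneratorSpec(seed=1, n_proteins=10))
        p = tmp_path / "hits.tsv"
        write_hit_table(hits, p)
        again = parse_hit_table(p, dialect="tsv")
        assert len(again) == len(hits)
        assert {(h.protein_id, h.domain) for h in again} == \
               {(h.protein_id, h.domain) for h in hits}
        for a, b in zip(sorted(again, key=lambda h: (h.protein_id, h.domain)),
                        sorted(hits, key=lambda h: (h.protein_id, h.domain))):
            assert a.evalue == pytest.approx(b.evalue, rel=1e-5)


class TestFilterSignificant:
    def test_strictly_below_threshold_kept(self):
        kept = filter_significant([DomainHit("a", "protease", 1e-7)])
        assert len(kept) == 1

    def test_exactly_at_threshold_removed(self):
        assert filter_significant([DomainHit("a", "protease", 1e-5)]) == []

    def test_equals_brute_force_filter(self):
        import numpy as np
        rng = np.random.default_rng(6)
        hits = [DomainHit(f"p{i}", "protease", float(10.0 ** rng.uniform(-9, 0)))
                for i in range(100)]
        kept = filter_significant(hits, 1e-4)
        assert kept == [h for h in hits if h.evalue < 1e-4]


class TestCallOrthologs:
    def test_three_domains_is_full(self):
        calls = call_orthologs([
            DomainHit("a", "protease", 1e-7),
            DomainHit("a", "zinc_finger", 1e-9),
            DomainHit("a", "hmg_box", 1e-6),
        ])
        assert calls[0].status == "full"

    def test_protease_and_zinc_only_is_partial(self):
        calls = call_orthologs([
            DomainHit("a", "protease", 1e-7),
            DomainHit("a", "zinc_finger", 1e-6),
        ])
        assert calls[0].status == "partial"

    def test_single_domain_is_none(self):
        calls = call_orthologs([DomainHit("a", "hmg_box", 1e-7)])
        assert calls[0].status == "none"

    def test_longest_isoform_kept_per_gene(self):
        hits = [
            DomainHit("P1-1", "protease", 1e-7, gene="g", length=400),
            DomainHit("P1-2", "protease", 1e-7, gene="g", length=500),
        ]
        calls = call_orthologs(hits)
        assert [c.protein_id for c in calls] == ["P1-2"]

    def test_isoform_grouping_falls_back_to_id_root(self):
        hits = [
            DomainHit("P1-1", "protease", 1e-7, length=400),
            DomainHit("P1-2", "protease", 1e-7, length=500),
            DomainHit("Q9-1", "protease", 1e-7, length=100),
        ]
        survivors = {c.protein_id for c in call_orthologs(hits)}
        assert survivors == {"P1-2", "Q9-1"}

    def test_one_strain_kept_per_species(self):
        hits = [
            DomainHit("a", "protease", 1e-7, species="sp", strain="s1", length=300),
            DomainHit("b", "protease", 1e-7, species="sp", strain="s2", length=500),
        ]
        assert [c.protein_id for c in call_orthologs(hits)] == ["b"]

    def test_calls_partition_proteins(self):
        hits, _ = gen_hit_table(GeneratorSpec(seed=3, n_proteins=60))
        calls = call_orthologs(filter_significant(hits))
        counts = status_counts(calls)
        assert sum(counts.values()) == len({c.protein_id for c in calls})

    def test_lowering_threshold_never_increases_full_count(self):
        hits, _ = gen_hit_table(GeneratorSpec(seed=4, n_proteins=80))
        fulls = [
            status_counts(call_orthologs(filter_significant(hits, t)))["full"]
            for t in (1e-3, 1e-5, 1e-7, 1e-9)
        ]
        assert all(a >= b for a, b in zip(fulls, fulls[1:]))

    def test_idempotent_on_surviving_hits(self):
        hits, _ = gen_hit_table(GeneratorSpec(seed=5, n_proteins=50))
        sig = filter_significant(hits)
        calls1 = call_orthologs(sig)
        surviving_ids = {c.protein_id for c in calls1}
        calls2 = call_orthologs([h for h in sig if h.protein_id in surviving_ids])
        assert calls1 == calls2

    def test_recovers_generator_ground_truth(self):
        hits, truth = gen_hit_table(GeneratorSpec(seed=7, n_proteins=200))
        calls = call_orthologs(filter_significant(hits))
        got = {c.protein_id: c.status for c in calls}
        expected = dict(zip(truth["protein"], truth["status"]))
        assert got == expected
        counts = status_counts(calls)
        assert counts == truth["status"].value_counts().to_dict()


class TestDedupIdentical:
    def test_longer_member_kept(self):
        calls = call_orthologs([
            DomainHit("a", "protease", 1e-7, length=500),
            DomainHit("b", "protease", 1e-7, length=300),
        ])
        kept = dedup_identical(calls, [("a", "b")])
        assert [c.protein_id for c in kept] == ["a"]

    def test_no_pairs_is_identity(self):
        calls = call_orthologs([DomainHit("a", "protease", 1e-7),
                                DomainHit("b", "protease", 1e-7)])
        assert dedup_identical(calls, []) == sorted(calls,
                                                    key=lambda c: c.protein_id)

    def test_unknown_id_errors(self):
        calls = call_orthologs([DomainHit("a", "protease", 1e-7)])
        with pytest.raises(KeyError):
            dedup_identical(calls, [("a", "ghost")])

    def test_components_match_brute_force(self):
        import numpy as np
        rng = np.random.default_rng(9)
        ids = [f"p{i}" for i in range(30)]
        calls = call_orthologs([
            DomainHit(i, "protease", 1e-7, length=int(rng.integers(100, 900)))
            for i in ids
        ])
        pairs = [(ids[int(a)], ids[int(b)])
                 for a, b in rng.integers(0, 30, size=(15, 2)) if a != b]
        kept = {c.protein_id for c in dedup_identical(calls, pairs)}
        # brute-force union-find
        parent = {i: i for i in ids}

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        for a, b in pairs:
            parent[find(a)] = find(b)
        comps = {}
        lengths = {c.protein_id: c.length for c in calls}
        for i in ids:
            comps.setdefault(find(i), []).append(i)
        expected = {min(members, key=lambda m: (-lengths[m], m))
                    for members in comps.values()}
        assert kept == expected
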