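"""Operon mining: hit parsing, clustering, filtering, synteny, repeat census."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_gene
from fapkit.operon import (
    DomainHit,
    DomtbloutError,
    assign_fapB_fapC,
    best_hmm_annotation,
    cluster_genes,
    count_repeats,
    filter_fap_clusters,
    intergenic_distance,
    mine_operons,
    operon_census,
    parse_domtblout,
)
from fapkit.synth import SynthGenomeConfig, synth_fap_genome, write_domtblout


def _dom_row(target, query, evalue, ali_from, ali_to, score=100.0, dom=1, ndom=1):
    return dict(
        target=target, tlen=300, query=query, qlen=39, evalue=evalue,
        score=score, dom=dom, ndom=ndom, ali_from=ali_from, ali_to=ali_to,
    )


class TestParseDomtblout:
    def test_evalue_cutoff_drops_weak_hits(self, tmp_path):
        """Rows above the 1e-5 full-sequence e-value cutoff are dropped."""
        text = write_domtblout(
            [
                _dom_row("g1", "FapBC_repeat", 1e-8, 10, 48),
                _dom_row("g2", "FapBC_repeat", 1e-6, 10, 48),
                _dom_row("g3", "FapBC_repeat", 1e-3, 10, 48),
            ]
        )
        path = tmp_path / "hits.domtblout"
        path.write_text(text)
        hits = parse_domtblout(path)
        assert [h.gene_id for h in hits] == ["g1", "g2"]

    def test_comments_only_gives_empty_list(self, tmp_path):
        path = tmp_path / "empty.domtblout"
        path.write_text("# comment\n# another\n")
        assert parse_domtblout(path) == []

    def test_inverted_alignment_coords_raise_with_line_number(self, tmp_path):
        text = write_domtblout([_dom_row("g1", "FapBC_repeat", 1e-8, 48, 10)])
        path = tmp_path / "bad.domtblout"
        path.write_text(text)
        with pytest.raises(DomtbloutError, match="line 4"):
            parse_domtblout(path)

    def test_wrong_column_count_raises_with_line_number(self, tmp_path):
        path = tmp_path / "short.domtblout"
        path.write_text("g1 - 300 FapA - 100 1e-9 50.0\n")
        with pytest.raises(DomtbloutError, match="line 1"):
            parse_domtblout(path)

    def test_missing_file_is_io_error(self, tmp_path):
        with pytest.raises(OSError):
            parse_domtblout(tmp_path / "nope.domtblout")


class TestClustering:
    def test_gap_4999_joins_but_5000_splits(self):
        """The <5000 bp threshold is a strict inequality on the boundary gap."""
        ann = {"a": "FapA", "b": "FapD"}
        joined = cluster_genes(
            [make_gene("a", 1000, 2000), make_gene("b", 7000, 8000)], ann
        )
        assert [len(c) for c in joined] == [2]
        split = cluster_genes(
            [make_gene("a", 1000, 2000), make_gene("b", 7001, 8000)], ann
        )
        assert sorted(len(c) for c in split) == [1, 1]

    def test_contigs_never_chain(self):
        genes = [
            make_gene(f"g{i}", 1 + i * 400, 300 + i * 400, contig="c1")
            for i in range(6)
        ] + [make_gene("solo", 100, 400, contig="c2")]
        ann = {g.gene_id: "FapA" for g in genes}
        clusters = cluster_genes(genes, ann)
        assert sorted(len(c) for c in clusters) == [1, 6]

    def test_missing_genome_id_raises(self):
        g = make_gene("a", 1, 10, genome="")
        with pytest.raises(ValueError, match="genome_id"):
            cluster_genes([g], {"a": "FapA"})

    @staticmethod
    def _oracle_partition(genes, max_gap=5000):
        """Brute-force O(n^2) pairwise single-linkage union-find."""
        parent = list(range(len(genes)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i, gi in enumerate(genes):
            for j, gj in enumerate(genes):
                if i >= j or (gi.genome_id, gi.contig_id) != (gj.genome_id, gj.contig_id):
                    continue
                lo, hi = sorted([gi, gj], key=lambda g: g.start_bp)
                if intergenic_distance(lo, hi) < max_gap:
                    parent[find(i)] = find(j)
        groups = {}
        for i in range(len(genes)):
            groups.setdefault(find(i), set()).add(genes[i].gene_id)
        return sorted(frozenset(g) for g in groups.values())

    @given(
        data=st.lists(
            st.tuples(
                st.integers(0, 1),  # contig
                st.integers(0, 200_000),  # start
                st.integers(1, 3000),  # length
            ),
            min_size=1,
            max_size=50,
        ),
        perm_seed=st.integers(0, 1000),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_partition_matches_bruteforce_oracle_and_is_order_invariant(
        self, data, perm_seed
    ):
        genes = [
            make_gene(f"g{i}", s + 1, s + ln, contig=f"c{c}")
            for i, (c, s, ln) in enumerate(data)
        ]
        ann = {g.gene_id: "FapA" for g in genes}
        clusters = cluster_genes(genes, ann)
        key = lambda fs: sorted(fs)
        got = sorted((frozenset(g.gene_id for g in c.genes) for c in clusters), key=key)
        assert got == sorted(self._oracle_partition(genes), key=key)
        # partition property: every gene in exactly one cluster
        assert sum(len(c) for c in clusters) == len(genes)
        # order invariance
        shuffled = list(genes)
        np.random.default_rng(perm_seed).shuffle(shuffled)
        got2 = sorted(
            (frozenset(g.gene_id for g in c.genes)
             for c in cluster_genes(shuffled, ann)),
            key=key,
        )
        assert got2 == got

    def test_translation_invariance(self):
        genes = [make_gene("a", 1000, 2000), make_gene("b", 6500, 8000),
                 make_gene("c", 20000, 21000)]
        ann = {g.gene_id: "FapA" for g in genes}
        base = [
            sorted(g.gene_id for g in c.genes) for c in cluster_genes(genes, ann)
        ]
        shifted = [
            make_gene(g.gene_id, g.start_bp + 12345, g.end_bp + 12345)
            for g in genes
        ]
        moved = [
            sorted(g.gene_id for g in c.genes) for c in cluster_genes(shifted, ann)
        ]
        assert base == moved


def _cluster_from_hmms(hmms):
    genes = [
        make_gene(f"g{i}", 1 + i * 1000, 900 + i * 1000) for i in range(len(hmms))
    ]
    ann = {g.gene_id: h for g, h in zip(genes, hmms)}
    [cluster] = cluster_genes(genes, ann)
    return cluster


class TestFilterAndAssign:
    @pytest.mark.parametrize(
        "hmms,kept",
        [
            (["FapA", "FapBC_repeat", "FapBC_repeat", "FapD", "FapE", "FapF"], True),
            (["FapBC_repeat", "FapD", "FapE"], False),  # only 2 other genes
            (["FapA", "FapD", "FapE", "FapF"], False),  # no FapBC_repeat
        ],
    )
    def test_operon_filter(self, hmms, kept):
        clusters = filter_fap_clusters([_cluster_from_hmms(hmms)])
        assert bool(clusters) is kept

    def test_first_fapbc_gene_is_fapB_second_fapC(self):
        cluster = _cluster_from_hmms(
            ["FapA", "FapBC_repeat", "FapD", "FapBC_repeat", "FapE"]
        )
        op = assign_fapB_fapC(cluster)
        assert op.fapB_gene_id == "g1"
        assert op.fapC_gene_id == "g3"
        assert op.role_map["g1"] == "fapB" and op.role_map["g3"] == "fapC"
        assert not op.review_flag

    def test_single_fapbc_gene_leaves_roles_absent(self):
        cluster = _cluster_from_hmms(["FapA", "FapBC_repeat", "FapD", "FapE"])
        op = assign_fapB_fapC(cluster)
        assert op.fapB_gene_id is None and op.fapC_gene_id is None

    def test_three_fapbc_genes_assigns_first_two_and_flags(self):
        cluster = _cluster_from_hmms(
            ["FapBC_repeat", "FapBC_repeat", "FapBC_repeat", "FapD"]
        )
        op = assign_fapB_fapC(cluster)
        assert op.fapB_gene_id == "g0" and op.fapC_gene_id == "g1"
        assert op.review_flag

    def test_best_bitscore_wins_multi_hmm_gene(self):
        hits = [
            DomainHit("g1", "FapA", 1e-10, 50.0, 1, 1, 40),
            DomainHit("g1", "FapBC_repeat", 1e-12, 80.0, 1, 50, 88),
        ]
        assert best_hmm_annotation(hits) == {"g1": "FapBC_repeat"}


class TestRepeats:
    def test_nonoverlapping_domains_number_ir1_to_ir3(self):
        """Domains at the fibril-core positions come out as IR1..IR3 in order."""
        hits = [
            DomainHit("g", "FapBC_repeat", 1e-20, 50, 2, 110, 161),
            DomainHit("g", "FapBC_repeat", 1e-20, 50, 1, 45, 96),
            DomainHit("g", "FapBC_repeat", 1e-20, 50, 3, 173, 211),
        ]
        reps = count_repeats("g", hits)
        assert [(r.ir_index, r.start_aa, r.end_aa) for r in reps] == [
            (1, 45, 96), (2, 110, 161), (3, 173, 211)
        ]

    def test_no_domains_gives_empty_list(self):
        assert count_repeats("g", []) == []

    def test_majority_overlap_resolved_by_bitscore(self):
        # overlap 28-48 = 21 aa > 50% of the shorter (39 aa) domain
        hits = [
            DomainHit("g", "FapBC_repeat", 1e-20, 40.0, 1, 10, 48),
            DomainHit("g", "FapBC_repeat", 1e-20, 60.0, 2, 28, 66),
        ]
        reps = count_repeats("g", hits)
        assert [(r.start_aa, r.end_aa) for r in reps] == [(28, 66)]

    def test_minority_overlap_keeps_both_domains(self):
        # overlap 30-48 = 19 aa = 48.7% of 39 aa: below the resolution cutoff
        hits = [
            DomainHit("g", "FapBC_repeat", 1e-20, 40.0, 1, 10, 48),
            DomainHit("g", "FapBC_repeat", 1e-20, 60.0, 2, 30, 68),
        ]
        reps = count_repeats("g", hits)
        assert [(r.start_aa, r.end_aa) for r in reps] == [(10, 48), (30, 68)]

    def test_sequence_extraction(self):
        protein = "M" * 9 + "REPEATSEQ" + "K" * 10
        hits = [DomainHit("g", "FapBC_repeat", 1e-20, 50, 1, 10, 18)]
        [rep] = count_repeats("g", hits, protein_seq=protein)
        assert rep.sequence == "REPEATSEQ"


class TestCensusAndPipeline:
    def _mine(self, cfg, seed=5):
        g = synth_fap_genome(cfg, seed=seed)
        hits = _hits_from_text(g.domtblout_text)
        return g, mine_operons(g.genes, hits)

    def test_planted_repeat_mixture_recovered(self, tmp_path):
        cfg = SynthGenomeConfig(n_operons=10, repeats_fapC=[3] * 8 + [4] * 2)
        g, (operons, repeats, census) = self._mine(cfg)
        assert dict(census.repeats_per_fapC) == {3: 8, 4: 2}
        assert dict(census.repeats_per_fapB) == {3: 10}
        assert dict(census.genes_per_cluster) == {6: 10}
        # fapB/fapC identities match the manifest exactly
        planted_C = {op["genes"]["fapC"] for op in g.manifest["operons"]}
        assert {op.fapC_gene_id for op in operons} == planted_C

    def test_census_totals_conserved(self):
        cfg = SynthGenomeConfig(n_operons=7)
        _, (operons, repeats, census) = self._mine(cfg)
        assert sum(census.genes_per_cluster.values()) == len(operons)
        assert sum(census.repeats_per_fapC.values()) == len(operons)
        assert sum(census.repeat_lengths.values()) == sum(
            len(r) for r in repeats.values()
        )

    def test_empty_operon_list_gives_empty_tables(self):
        census = operon_census([], {})
        assert sum(census.genes_per_cluster.values()) == 0
        assert sum(census.repeats_per_fapC.values()) == 0


def _hits_from_text(text):
    import os
    import tempfile

    with tempfile.NamedTemporaryFile("w", suffix=".domtblout", delete=False) as fh:
        fh.write(text)
        path = fh.name
    try:
        return parse_domtblout(path)
    finally:
        os.unlink(path)
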