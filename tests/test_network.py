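"""Character encoding, median closure, and network construction."""

import random

import networkx as nx
import numpy as np
import pytest

from cyp75.network import (
    CharacterMatrix,
    NothingToNetworkError,
    TooManyCharactersError,
    build_network,
    encode_characters,
    hub_haplotype,
    median_closure,
)
from cyp75.sequences import CodingSequence

from _oracles import bitmask_median_closure


def _matrix_from_vectors(vectors):
    """Ad-hoc CharacterMatrix for topology tests (labels are synthetic)."""
    from cyp75.network import Character

    ids = [f"h{i}" for i in range(len(vectors))]
    width = len(vectors[0])
    return CharacterMatrix(
        haplotype_ids=ids,
        members={i: [i] for i in ids},
        characters=[Character(f"c{j}", position=j + 1) for j in range(width)],
        states=np.array(vectors, dtype=np.int8),
    )


class TestEncodeCharacters:
    def test_three_snps_three_characters(self, reference):
        nt = list(reference.nucleotides)
        for pos, alt in ((50, "A"), (400, "T"), (900, "A")):
            nt[pos - 1] = alt if nt[pos - 1] != alt else "G"
        other = CodingSequence("mut", "".join(nt))
        matrix = encode_characters([reference, other], reference, condense=False)
        assert matrix.n_characters == 3
        assert matrix.n_haplotypes == 2

    def test_paper_panel_has_nine_observed_vectors(self, reference, paper_panel):
        panel, _ = paper_panel
        matrix = encode_characters(panel, reference)
        assert matrix.n_haplotypes == 9
        assert len({tuple(row) for row in matrix.states}) == 9

    def test_identical_sequences_collapse_to_one_node(self, reference, paper_panel):
        panel, _ = paper_panel
        twin = CodingSequence("twin", panel[1].nucleotides)
        matrix = encode_characters(panel + [twin], reference)
        assert matrix.n_haplotypes == 9
        assert sorted(matrix.members[panel[1].id]) == sorted([panel[1].id, "twin"])

    def test_single_haplotype_refuses(self, reference):
        with pytest.raises(NothingToNetworkError):
            encode_characters([reference], reference)

    def test_condensation_sums_weights(self, reference, paper_panel):
        panel, truth = paper_panel
        condensed = encode_characters(panel, reference, condense=True)
        full = encode_characters(panel, reference, condense=False)
        assert sum(c.weight for c in condensed.characters) == full.n_characters
        # G19833's private characters share one pattern -> one weight-8 column
        assert max(c.weight for c in condensed.characters) == 8


class TestMedianClosure:
    def test_textbook_triple(self):
        closure = median_closure({(0, 0, 0), (1, 1, 0), (1, 0, 1)})
        assert closure == {(0, 0, 0), (1, 1, 0), (1, 0, 1), (1, 0, 0)}

    def test_identical_vectors_add_nothing(self):
        assert median_closure({(1, 0, 1)}) == {(1, 0, 1)}

    def test_idempotent(self, reference, paper_panel):
        panel, _ = paper_panel
        matrix = encode_characters(panel, reference)
        once = median_closure(matrix)
        assert median_closure(once) == once

    def test_matches_bitmask_oracle_on_random_matrices(self):
        for seed in range(30):
            rng = random.Random(seed)
            n_hap = rng.randint(2, 6)
            n_char = rng.randint(2, 10)
            vectors = {
                tuple(rng.randint(0, 1) for _ in range(n_char))
                for _ in range(n_hap)
            }
            assert median_closure(vectors) == bitmask_median_closure(vectors)

    def test_refuses_too_many_characters(self):
        wide = {(0,) * 26, (1,) * 26}
        with pytest.raises(TooManyCharactersError):
            median_closure(wide)

    def test_compatible_characters_add_no_extra_nodes(self, reference, paper_panel):
        # the study panel needs exactly one inferred intermediate: the
        # single-SNP ancestor the pink-flowered lineage and the recombinant
        # both pass through
        panel, _ = paper_panel
        matrix = encode_characters(panel, reference)
        closure = median_closure(matrix)
        assert len(closure) == matrix.n_haplotypes + 1


class TestBuildNetwork:
    def test_two_haplotypes_single_edge(self):
        matrix = _matrix_from_vectors([[0], [1]])
        graph = build_network(median_closure(matrix), matrix)
        assert graph.number_of_nodes() == 2
        assert graph.number_of_edges() == 1

    def test_textbook_triple_topology(self):
        matrix = _matrix_from_vectors([[0, 0, 0], [1, 1, 0], [1, 0, 1]])
        graph = build_network(median_closure(matrix), matrix)
        assert graph.number_of_nodes() == 4
        assert graph.number_of_edges() == 3
        assert graph.degree["100"] == 3

    def test_reference_is_hub_of_paper_panel(self, reference, paper_panel):
        panel, _ = paper_panel
        matrix = encode_characters(panel, reference)
        graph = build_network(median_closure(matrix), matrix)
        assert hub_haplotype(graph) == reference.id
        observed = [n for n, d in graph.nodes(data=True) if d["observed"]]
        assert len(observed) == 9

    def test_paths_to_reference_use_planted_characters(self, reference, paper_panel):
        panel, truth = paper_panel
        matrix = encode_characters(panel, reference)
        graph = build_network(median_closure(matrix), matrix)
        ref_node = "0" * matrix.n_characters
        for hap_id in matrix.haplotype_ids:
            vec = matrix.vector(hap_id)
            node = "".join(map(str, vec))
            path = nx.shortest_path(graph, ref_node, node)
            labels: set[str] = set()
            for a, b in zip(path, path[1:]):
                labels.update(graph.edges[a, b]["label"].split("; "))
            planted = {
                label
                for j in range(matrix.n_characters)
                if vec[j] == 1
                for label in matrix.characters[j].label.split("; ")
            }
            assert labels == planted, hap_id

    def test_export_round_trip(self, reference, paper_panel, tmp_path):
        from cyp75.network import write_network

        panel, _ = paper_panel
        matrix = encode_characters(panel, reference)
        graph = build_network(median_closure(matrix), matrix)
        write_network(
            graph, tmp_path / "n.gml", tmp_path / "e.tsv", tmp_path / "n.tsv"
        )
        loaded = nx.read_gml(tmp_path / "n.gml")
        assert loaded.number_of_nodes() == graph.number_of_nodes()
        assert loaded.number_of_edges() == graph.number_of_edges()
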