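"""Median haplotype networks over binary variant characters.

Each segregating substitution and each distinct indel event (whatever its
length) becomes one binary character: 0 for the reference state, 1 for
the derived state.  Multi-allelic sites split into one character per
derived allele, so every character really is binary.  The median closure
adds the coordinatewise majority of every triple of vectors until a fixed
point; in the resulting graph two vectors are joined when they differ in
exactly one (condensed) character, which yields the classic median
network with observed haplotypes plus inferred intermediates.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .sequences import CodingSequence
from .variants import INSERTION, SNP, VariantCall, call_variants

MAX_CHARACTERS = 25


class NothingToNetworkError(ValueError):
    """Fewer than two distinct haplotypes were supplied."""


class TooManyCharactersError(ValueError):
    """Median closure refused: too many characters (exponential blow-up)."""


def _variant_label(v: VariantCall) -> str:
    if v.kind == SNP:
        return f"SNP@{v.cds_position} {v.ref_allele}>{v.alt_allele}"
    if v.kind == INSERTION:
        return f"+{v.length} nt {v.alt_allele} ins@{v.cds_position}"
    return f"Δ{v.length} nt@{v.cds_position + 1}-{v.cds_position + v.length}"


@dataclass
class Character:
    """One binary column of the matrix (possibly a condensed bundle)."""

    label: str
    position: int  # reference CDS coordinate used for ordering
    weight: int = 1


@dataclass
class CharacterMatrix:
    haplotype_ids: list[str]  # one entry per distinct haplotype vector
    members: dict[str, list[str]]  # distinct id -> all input ids sharing it
    characters: list[Character]
    states: np.ndarray  # shape (n_haplotypes, n_characters), values {0, 1}

    @property
    def n_haplotypes(self) -> int:
        return self.states.shape[0]

    @property
    def n_characters(self) -> int:
        return self.states.shape[1]

    def vector(self, hap_id: str) -> tuple[int, ...]:
        return tuple(self.states[self.haplotype_ids.index(hap_id)])


def encode_characters(
    panel: list[CodingSequence],
    reference: CodingSequence,
    condense: bool = True,
) -> CharacterMatrix:
    """Binary character matrix of a haplotype panel against its reference.

    Haplotypes with identical sequence collapse onto one observed vector
    (their ids are recorded as co-members).  With ``condense=True``,
    characters with identical presence/absence patterns merge into one
    weighted column — the standard condensation step before median
    closure.
    """
    distinct: list[str] = []
    members: dict[str, list[str]] = {}
    seen: dict[str, str] = {}
    variants: dict[str, list[VariantCall]] = {}
    for hap in panel:
        if hap.nucleotides in seen:
            members[seen[hap.nucleotides]].append(hap.id)
            continue
        seen[hap.nucleotides] = hap.id
        distinct.append(hap.id)
        members[hap.id] = [hap.id]
        variants[hap.id] = (
            [] if hap.nucleotides == reference.nucleotides
            else call_variants(hap, reference)
        )
    if len(distinct) < 2:
        raise NothingToNetworkError("nothing to network: fewer than 2 distinct haplotypes")

    all_events: dict[tuple, VariantCall] = {}
    for calls in variants.values():
        for v in calls:
            all_events.setdefault(v.as_tuple(), v)
    keys = sorted(all_events, key=lambda k: (k[1], k[0], k[3], k[2]))
    states = np.zeros((len(distinct), len(keys)), dtype=np.int8)
    for i, hap_id in enumerate(distinct):
        carried = {v.as_tuple() for v in variants[hap_id]}
        for j, key in enumerate(keys):
            if key in carried:
                states[i, j] = 1
    characters = [
        Character(_variant_label(all_events[k]), position=k[1]) for k in keys
    ]
    matrix = CharacterMatrix(distinct, members, characters, states)
    return _condense(matrix) if condense else matrix


def _condense(matrix: CharacterMatrix) -> CharacterMatrix:
    pattern_to_cols: dict[bytes, list[int]] = {}
    for j in range(matrix.n_characters):
        pattern_to_cols.setdefault(matrix.states[:, j].tobytes(), []).append(j)
    order = sorted(pattern_to_cols.values(), key=lambda cols: cols[0])
    new_chars: list[Character] = []
    new_cols = []
    for cols in order:
        chars = [matrix.characters[j] for j in cols]
        new_chars.append(
            Character(
                label="; ".join(c.label for c in chars),
                position=min(c.position for c in chars),
                weight=sum(c.weight for c in chars),
            )
        )
        new_cols.append(matrix.states[:, cols[0]])
    states = np.column_stack(new_cols) if new_cols else np.zeros(
        (matrix.n_haplotypes, 0), dtype=np.int8
    )
    return CharacterMatrix(matrix.haplotype_ids, matrix.members, new_chars, states)


def median_closure(vectors) -> set[tuple[int, ...]]:
    """Smallest superset of the vectors closed under triplewise majority.

    Input may be a :class:`CharacterMatrix` or an iterable of binary
    tuples.  The result is order-independent: closure over sets, iterated
    to a fixed point.  Refuses more than :data:`MAX_CHARACTERS` characters
    (the closure can grow exponentially); prune or condense first.
    """
    if isinstance(vectors, CharacterMatrix):
        vecs = {tuple(int(x) for x in row) for row in vectors.states}
    else:
        vecs = {tuple(int(x) for x in v) for v in vectors}
    if not vecs:
        return set()
    width = len(next(iter(vecs)))
    if width > MAX_CHARACTERS:
        raise TooManyCharactersError(
            f"{width} characters exceed the {MAX_CHARACTERS}-character closure "
            "guard; prune rare characters or condense the matrix first"
        )
    closure = set(vecs)
    frontier = list(closure)
    while frontier:
        added: set[tuple[int, ...]] = set()
        current = list(closure)
        for a in current:
            for b in current:
                for c in frontier:
                    med = tuple(
                        (x + y + z >= 2) * 1 for x, y, z in zip(a, b, c)
                    )
                    if med not in closure and med not in added:
                        added.add(med)
        closure |= added
        frontier = list(added)
    return closure


def build_network(
    closure: set[tuple[int, ...]],
    matrix: CharacterMatrix,
) -> nx.Graph:
    """Median network graph: nodes are state vectors, edges single steps.

    Observed nodes carry their haplotype ids; the rest are inferred
    medians.  Edges connect vectors at condensed-Hamming distance 1 and
    are labelled with the separating character.  The closure guarantees
    connectivity; a disconnected result signals an internal error.
    """
    vec_to_hap: dict[tuple[int, ...], list[str]] = {}
    for hap_id in matrix.haplotype_ids:
        vec = matrix.vector(hap_id)
        vec_to_hap.setdefault(vec, []).extend(matrix.members[hap_id])
    graph = nx.Graph()
    for vec in sorted(closure):
        haps = vec_to_hap.get(vec, [])
        graph.add_node(
            "".join(map(str, vec)),
            observed=bool(haps),
            haplotypes=",".join(haps),
        )
    nodes = sorted(closure)
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            diff = [j for j in range(len(a)) if a[j] != b[j]]
            if len(diff) == 1:
                ch = matrix.characters[diff[0]]
                graph.add_edge(
                    "".join(map(str, a)),
                    "".join(map(str, b)),
                    label=ch.label,
                    weight=ch.weight,
                )
    if graph.number_of_nodes() and not nx.is_connected(graph):
        raise RuntimeError(
            "median network is disconnected; closure invariant violated (bug)"
        )
    return graph


def hub_haplotype(graph: nx.Graph) -> str:
    """Observed haplotype ids of the highest-degree observed node."""
    observed = [n for n, d in graph.nodes(data=True) if d["observed"]]
    best = max(observed, key=lambda n: (graph.degree[n], n))
    return graph.nodes[best]["haplotypes"]


def write_network(graph: nx.Graph, gml_path, edges_path, nodes_path) -> None:
    nx.write_gml(graph, str(gml_path))
    with open(edges_path, "w") as fh:
        fh.write("node1\tnode2\tlabel\n")
        for a, b, data in sorted(graph.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data['label']}\n")
    with open(nodes_path, "w") as fh:
        fh.write("node\tobserved\thaplotypes\n")
        for n, data in sorted(graph.nodes(data=True)):
            fh.write(f"{n}\t{int(data['observed'])}\t{data['haplotypes']}\n")
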