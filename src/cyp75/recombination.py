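"""Intragenic recombinant detection by triplet scanning.

For a candidate child haplotype and an ordered pair of candidate parents,
the *informative* sites are the characters at which the parents differ;
along the gene, the child must then match one parent or the other, and
the minimal number of parent switches explaining the child is the minimal
breakpoint count (0 = plain descent, 1 = a single crossover).  Scanning
all triplets in a panel and keeping, per child, the most parsimonious
parent pair reproduces the classic by-eye inference of a chimeric
haplotype carrying the 5' end of one lineage and the 3' end of another.

Support for a crossover is quantified by a permutation test: shuffling
the order of the informative sites destroys the positional clustering a
real crossover produces, so the observed breakpoint count is compared
with its distribution over random site orders.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

from .network import CharacterMatrix, encode_characters
from .sequences import CodingSequence


class UninformativeTripletError(ValueError):
    """The candidate parents do not differ at any character."""


@dataclass
class TripletResult:
    breakpoints: int
    informative_positions: list[int]  # reference CDS coordinates, in order
    matches: str  # 'A'/'B' per informative site, child's matched parent
    unexplained_positions: list[int]  # informative sites matching neither


@dataclass
class RecombinationReport:
    child: str
    parent_5prime: str
    parent_3prime: str
    minimal_breakpoints: int
    breakpoint_interval: tuple[int, int] | None  # CDS coords bounding the 1st crossover
    informative_sites_5prime: int
    informative_sites_3prime: int
    unexplained_sites: int  # triplet-segregating sites matching neither parent
    permutation_p: float | None = None
    is_recombinant: bool = False


def min_breakpoints(
    child,
    parent_a,
    parent_b,
    positions=None,
) -> TripletResult:
    """Minimal parent-switch count along ordered informative sites.

    States are integer vectors over shared characters ordered by
    reference coordinate.  Informative sites where the child matches
    neither parent (possible for multistate characters) are excluded with
    a warning and reported.  With no informative site the triplet is
    undefined.
    """
    child = np.asarray(child)
    parent_a = np.asarray(parent_a)
    parent_b = np.asarray(parent_b)
    if positions is None:
        positions = list(range(1, len(child) + 1))
    informative = np.nonzero(parent_a != parent_b)[0]
    if informative.size == 0:
        raise UninformativeTripletError("uninformative triplet: parents identical")
    matches: list[str] = []
    used_positions: list[int] = []
    unexplained: list[int] = []
    for idx in informative:
        if child[idx] == parent_a[idx]:
            matches.append("A")
        elif child[idx] == parent_b[idx]:
            matches.append("B")
        else:
            unexplained.append(positions[idx])
            continue
        used_positions.append(positions[idx])
    if unexplained:
        warnings.warn(
            f"{len(unexplained)} informative site(s) match neither parent; excluded",
            stacklevel=2,
        )
    if not matches:
        raise UninformativeTripletError(
            "uninformative triplet: no informative site explained by either parent"
        )
    breakpoints = sum(a != b for a, b in zip(matches, matches[1:]))
    return TripletResult(breakpoints, used_positions, "".join(matches), unexplained)


def permutation_pvalue(
    child,
    parent_a,
    parent_b,
    n_permutations: int = 999,
    seed: int = 0,
    positions=None,
) -> float:
    """Probability of as few breakpoints under random informative-site order.

    p = (1 + #{permutations with breakpoints <= observed}) / (n + 1);
    reproducible for a given seed.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    result = min_breakpoints(child, parent_a, parent_b, positions)
    labels = np.frombuffer(result.matches.encode(), dtype=np.uint8)
    if labels.size < 2:
        raise UninformativeTripletError("need >= 2 informative sites for a p-value")
    observed = result.breakpoints
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        if int(np.count_nonzero(perm[1:] != perm[:-1])) <= observed:
            hits += 1
    return (1 + hits) / (n_permutations + 1)


def _triplet_cost(
    matrix: CharacterMatrix,
    child_i: int,
    a_i: int,
    b_i: int,
) -> tuple[TripletResult, int] | None:
    """Triplet scan bookkeeping: breakpoints plus triplet-private sites.

    A triplet-private site is one segregating within the triplet at which
    the parents agree but the child differs — a mutation (or reversal)
    that descent from these parents cannot supply.  Total parsimony cost
    of the explanation is breakpoints + private sites.
    """
    states = matrix.states
    positions = [c.position for c in matrix.characters]
    child, pa, pb = states[child_i], states[a_i], states[b_i]
    try:
        result = min_breakpoints(child, pa, pb, positions)
    except UninformativeTripletError:
        return None
    private = int(np.count_nonzero((pa == pb) & (child != pa)))
    return result, private


def scan_triplets(
    panel: list[CodingSequence],
    reference: CodingSequence,
    n_permutations: int = 999,
    seed: int = 0,
) -> list[RecombinationReport]:
    """Best recombination explanation for every haplotype in a panel.

    For each child, every unordered parent pair is scored by total
    parsimony cost (breakpoints + sites the parents cannot supply); ties
    prefer fewer unexplained sites, then more informative sites, then
    lexicographic parent ids.  A child is called recombinant when its
    best explanation needs a crossover (breakpoints >= 1), explains every
    triplet-segregating site, and the child is not a candidate ancestor
    of another haplotype (its derived-allele set is not a subset of any
    other haplotype's) — candidate ancestors are better explained as
    intermediates of plain descent.
    """
    matrix = encode_characters(panel, reference, condense=False)
    if matrix.n_haplotypes < 3:
        raise ValueError("need at least 3 distinct haplotypes to scan triplets")
    ids = matrix.haplotype_ids
    states = matrix.states
    derived_sets = [frozenset(np.nonzero(states[i])[0]) for i in range(len(ids))]

    reports: list[RecombinationReport] = []
    for child_i, child_id in enumerate(ids):
        best = None
        best_key = None
        for a_i, b_i in itertools.combinations(
            (i for i in range(len(ids)) if i != child_i), 2
        ):
            scored = _triplet_cost(matrix, child_i, a_i, b_i)
            if scored is None:
                continue
            result, private = scored
            informative = len(result.matches)
            key = (
                result.breakpoints + private,
                private,
                -informative,
                tuple(sorted((ids[a_i], ids[b_i]))),
            )
            if best_key is None or key < best_key:
                best_key = key
                best = (result, private, a_i, b_i)
        if best is None:
            continue
        result, private, a_i, b_i = best
        # orient the pair: the 5' parent is whoever matches the first site
        if result.matches[0] == "A":
            p5, p3 = a_i, b_i
        else:
            p5, p3 = b_i, a_i
            result = TripletResult(
                result.breakpoints,
                result.informative_positions,
                result.matches.translate(str.maketrans("AB", "BA")),
                result.unexplained_positions,
            )
        interval = None
        if result.breakpoints >= 1:
            switch = next(
                i for i in range(1, len(result.matches))
                if result.matches[i] != result.matches[i - 1]
            )
            interval = (
                result.informative_positions[switch - 1],
                result.informative_positions[switch],
            )
        p_value = None
        if len(result.matches) >= 2:
            p_value = permutation_pvalue(
                states[child_i], states[p5], states[p3],
                n_permutations=n_permutations, seed=seed,
                positions=[c.position for c in matrix.characters],
            )
        is_candidate_ancestor = any(
            i != child_i and derived_sets[child_i] <= derived_sets[i]
            for i in range(len(ids))
        )
        reports.append(
            RecombinationReport(
                child=child_id,
                parent_5prime=ids[p5],
                parent_3prime=ids[p3],
                minimal_breakpoints=result.breakpoints,
                breakpoint_interval=interval,
                informative_sites_5prime=result.matches.count("A"),
                informative_sites_3prime=result.matches.count("B"),
                unexplained_sites=private,
                permutation_p=p_value,
                is_recombinant=(
                    result.breakpoints >= 1
                    and private == 0
                    and not is_candidate_ancestor
                ),
            )
        )
    return reports


def reports_to_tsv(reports: list[RecombinationReport], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "child\tparent_5prime\tparent_3prime\tminimal_breakpoints\t"
            "breakpoint_interval\tinformative_5prime\tinformative_3prime\t"
            "unexplained_sites\tpermutation_p\tis_recombinant\n"
        )
        for r in reports:
            interval = (
                f"{r.breakpoint_interval[0]}-{r.breakpoint_interval[1]}"
                if r.breakpoint_interval else ""
            )
            p = f"{r.permutation_p:.4f}" if r.permutation_p is not None else ""
            fh.write(
                f"{r.child}\t{r.parent_5prime}\t{r.parent_3prime}\t"
                f"{r.minimal_breakpoints}\t{interval}\t{r.informative_sites_5prime}\t"
                f"{r.informative_sites_3prime}\t{r.unexplained_sites}\t{p}\t"
                f"{int(r.is_recombinant)}\n"
            )
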