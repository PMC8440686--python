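"""Independent brute-force / enumeration oracles used by the test suite.

Everything here is written from the rule definitions directly, without
importing implementation internals, so a test comparing implementation
against oracle is a genuine dual-route check.
"""

from __future__ import annotations

import itertools


# --- segregation rule tables (affected index, diploid autosome unless noted) ---

def trio_autosomal_expected(model: str, i: int, f: int, m: int,
                            mother_affected: bool = False) -> bool:
    """Expected verdict for a trio (index, father, mother allele counts 0/1/2),
    parents unaffected unless ``mother_affected``."""
    if model == "AD-denovo":
        return i == 1 and f == 0 and m == 0
    if model == "AD-inherited":
        if mother_affected:
            return i == 1 and m >= 1 and f == 0
        return False  # no affected relative can carry the allele
    if model == "AR-hom":
        # parents must each carry a copy; an unaffected parent may not be hom
        return i == 2 and f == 1 and (m == 1 or (m == 2 and mother_affected))
    if model == "AR-comphet":
        return i == 1 and ((f >= 1) != (m >= 1))
    raise ValueError(model)


def xl_expected(index_sex: str, i: int, f: int) -> bool:
    """X-chromosome verdict: hemizygous male index (i, f in {0,1}) or diploid
    female index (i in {0,1,2}); father unaffected."""
    if f == 1:  # unaffected male relative carrying the allele
        return False
    if index_sex == "male":
        return i == 1
    return i == 2


def mt_expected(i: int) -> bool:
    return i == 1


def mosaic_expected(i: int, allelic_fraction, bound: float = 0.30) -> bool:
    return i >= 1 and allelic_fraction is not None and allelic_fraction < bound


# --- ROH brute force --------------------------------------------------------

def roh_segments_bruteforce(positions, counts, min_length_bp, min_sites, max_het):
    """Leftmost-greedy maximal homozygous runs, found by explicit O(n^2)
    scanning: from the current start, try every window end and keep the
    furthest homozygous end within the het budget."""
    n = len(positions)
    segments = []
    i = 0
    while i < n:
        if counts[i] == 1:
            i += 1
            continue
        best_j = i
        for j in range(i, n):
            hets = sum(1 for k in range(i, j + 1) if counts[k] == 1)
            if hets > max_het:
                break
            if counts[j] != 1:
                best_j = j
        n_sites = best_j - i + 1
        length = positions[best_j] - positions[i] + 1
        if n_sites >= min_sites and length >= min_length_bp:
            segments.append((positions[i], positions[best_j], n_sites))
        i = best_j + 1
    return segments


# --- interval overlap -------------------------------------------------------

def overlaps_naive(contig, pos, experiment_id, calls) -> bool:
    """calls: iterable of (experiment_id, contig, start, end, copy_state)."""
    for exp, c, start, end, state in calls:
        if exp == experiment_id and c == contig and state == "deletion-het" \
                and start <= pos <= end:
            return True
    return False


# --- comp-het counting ------------------------------------------------------

def comphet_pair_count_unphased(k: int) -> int:
    return len(list(itertools.combinations(range(k), 2)))


# --- graph closure ----------------------------------------------------------

def closure_bfs(terms, parents, root="HP:0000001"):
    """Breadth-first ancestor closure over a parent map, root excluded."""
    out = set()
    frontier = [t for t in terms if t in parents]
    while frontier:
        nxt = []
        for t in frontier:
            if t in out:
                continue
            out.add(t)
            nxt.extend(parents[t])
        frontier = nxt
    out.discard(root)
    return out
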