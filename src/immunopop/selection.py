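"""Codon-level tests of positive selection and recombination.

Four pieces:

* Nei–Gojobori (1986) proportion-based counting of synonymous and
  nonsynonymous differences between codon sequences, with multi-step codon
  differences averaged over all minimal mutational pathways (pathways through
  stop codons excluded when an alternative exists);
* a codon Z-test of positive selection on the alignment-wide means, with the
  standard error bootstrapped over codon sites (test statistic dN - dS);
* a single-breakpoint (SBP) recombination scan: at every candidate breakpoint
  a neighbor-joining tree (Jukes–Cantor distances) is fitted to each segment
  and the segment log-likelihoods (Felsenstein pruning under Jukes–Cantor)
  are scored by small-sample AICc against a single tree for the whole
  alignment;
* SLAC-style per-site counting: ancestral codons are reconstructed by
  parsimony (ties broken by minimizing nonsynonymous changes, then by codon
  order), observed per-site synonymous/nonsynonymous changes are summed over
  branches and compared to the Nei–Gojobori expectation with a one-tailed
  binomial test for excess nonsynonymous change.

Heavier phylogenetic codon models (REL, MEME) are not re-implemented; their
per-site output tables are consumed by :func:`consensus_selected_sites`,
which applies the >= 2-model consensus rule.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .model import AlleleCatalog, SiteSelectionTable

__all__ = [
    "BreakpointResult",
    "SlacSiteResult",
    "neigojobori_pair",
    "codon_z_test",
    "sbp_scan",
    "slac_sites",
    "consensus_selected_sites",
]

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

CODONS = ["".join(c) for c in itertools.product(BASES, repeat=3)]
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
AA = [_CODON_TABLE[c] for c in CODONS]


def _syn_site_count(codon: str) -> float:
    """Synonymous site count: per position, the fraction of the three
    single-nucleotide fates that preserve the amino acid (stop fates count
    as nonsynonymous)."""
    aa = _CODON_TABLE[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for base in BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if _CODON_TABLE[alt] == aa:
                syn += 1
        s += syn / 3.0
    return s


SYN_SITES = np.array([_syn_site_count(c) for c in CODONS])


@lru_cache(maxsize=None)
def _pathway_counts(a: str, b: str) -> tuple[float, float, float]:
    """(syn, nonsyn averaged over minimal pathways, min nonsyn over pathways).

    Pathways passing through a stop codon are dropped unless every pathway
    does.
    """
    diff_positions = [p for p in range(3) if a[p] != b[p]]
    if not diff_positions:
        return 0.0, 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_positions):
        current = a
        steps = []
        through_stop = False
        for pos in order:
            nxt = current[:pos] + b[pos] + current[pos + 1 :]
            if _CODON_TABLE[nxt] == "*" and nxt != b:
                through_stop = True
            steps.append(_CODON_TABLE[current] == _CODON_TABLE[nxt])
            current = nxt
        paths.append((through_stop, steps))
    usable = [steps for through, steps in paths if not through]
    if not usable:
        usable = [steps for _, steps in paths]
    syn_per_path = [sum(steps) for steps in usable]
    n_steps = len(diff_positions)
    sd = float(np.mean(syn_per_path))
    nd = n_steps - sd
    nd_min = n_steps - max(syn_per_path)
    return sd, nd, nd_min


# 64x64 lookup tables for vectorized pairwise counting
SD_TABLE = np.zeros((64, 64))
ND_TABLE = np.zeros((64, 64))
ND_MIN_TABLE = np.zeros((64, 64))
NT_DIFF_TABLE = np.zeros((64, 64), dtype=int)
for _i, _a in enumerate(CODONS):
    for _j, _b in enumerate(CODONS):
        _sd, _nd, _nd_min = _pathway_counts(_a, _b)
        SD_TABLE[_i, _j] = _sd
        ND_TABLE[_i, _j] = _nd
        ND_MIN_TABLE[_i, _j] = _nd_min
        NT_DIFF_TABLE[_i, _j] = sum(x != y for x, y in zip(_a, _b))


def _encode_codons(seq: str) -> np.ndarray:
    """Codon indices; -1 marks codons with gaps/ambiguity or stop codons."""
    if len(seq) % 3 != 0:
        raise ValueError("sequence length not divisible by 3")
    out = np.full(len(seq) // 3, -1, dtype=int)
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        idx = CODON_INDEX.get(codon, -1)
        if idx >= 0 and AA[idx] == "*":
            raise ValueError(f"internal stop codon {codon} at codon {i // 3 + 1}")
        out[i // 3] = idx
    return out


def neigojobori_pair(
    seq_a: str, seq_b: str
) -> tuple[float, float, float, float]:
    """Nei–Gojobori proportions for one sequence pair.

    Returns (pN, pS, syn_sites, nonsyn_sites); codons with gaps or ambiguity
    in either sequence are skipped, and site counts are averaged over the two
    sequences.
    """
    a = _encode_codons(seq_a)
    b = _encode_codons(seq_b)
    if a.size != b.size:
        raise ValueError("sequences must have equal codon length")
    valid = (a >= 0) & (b >= 0)
    if not np.any(valid):
        raise ValueError("no comparable codons")
    av, bv = a[valid], b[valid]
    sd = float(SD_TABLE[av, bv].sum())
    nd = float(ND_TABLE[av, bv].sum())
    s_sites = float((SYN_SITES[av] + SYN_SITES[bv]).sum() / 2.0)
    n_sites = 3.0 * av.size - s_sites
    p_s = sd / s_sites if s_sites > 0 else 0.0
    p_n = nd / n_sites if n_sites > 0 else 0.0
    return p_n, p_s, s_sites, n_sites


def codon_z_test(
    catalog_or_seqs: AlleleCatalog | Sequence[str],
    reps: int = 1000,
    seed: Optional[int] = None,
) -> tuple[float, float, float]:
    """Alignment-wide codon Z-test for positive selection.

    dN and dS are the means of the pairwise Nei–Gojobori proportions over all
    sequence pairs; the standard error of dN - dS is bootstrapped over codon
    sites.  Returns (dN - dS, Z, one-tailed p for dN > dS).
    """
    seqs = _sequences(catalog_or_seqs)
    if len(seqs) < 3:
        raise ValueError("need at least three sequences")
    enc = np.vstack([_encode_codons(s) for s in seqs])
    n_codons = enc.shape[1]
    pairs = list(itertools.combinations(range(len(seqs)), 2))

    sd_cols = np.zeros((len(pairs), n_codons))
    nd_cols = np.zeros((len(pairs), n_codons))
    ss_cols = np.zeros((len(pairs), n_codons))
    ns_cols = np.zeros((len(pairs), n_codons))
    for p_idx, (i, j) in enumerate(pairs):
        valid = (enc[i] >= 0) & (enc[j] >= 0)
        av, bv = enc[i][valid], enc[j][valid]
        sd_cols[p_idx, valid] = SD_TABLE[av, bv]
        nd_cols[p_idx, valid] = ND_TABLE[av, bv]
        ss_cols[p_idx, valid] = (SYN_SITES[av] + SYN_SITES[bv]) / 2.0
        ns_cols[p_idx, valid] = 3.0 - ss_cols[p_idx, valid]

    def mean_dn_ds(weights: np.ndarray) -> float:
        sd = sd_cols @ weights
        nd = nd_cols @ weights
        ss = ss_cols @ weights
        ns = ns_cols @ weights
        with np.errstate(invalid="ignore", divide="ignore"):
            p_s = np.where(ss > 0, sd / ss, 0.0)
            p_n = np.where(ns > 0, nd / ns, 0.0)
        return float(np.mean(p_n) - np.mean(p_s))

    observed = mean_dn_ds(np.ones(n_codons))

    rng = np.random.default_rng(seed)
    draws = rng.integers(0, n_codons, size=(reps, n_codons))
    boot = np.empty(reps)
    for r in range(reps):
        weights = np.bincount(draws[r], minlength=n_codons).astype(float)
        boot[r] = mean_dn_ds(weights)
    se = float(np.std(boot, ddof=1))
    if se == 0.0:
        return observed, math.nan, math.nan
    z = observed / se
    p = float(stats.norm.sf(z))
    return observed, z, p


def _sequences(catalog_or_seqs: AlleleCatalog | Sequence[str]) -> list[str]:
    if isinstance(catalog_or_seqs, AlleleCatalog):
        return [catalog_or_seqs.sequence(a) for a in catalog_or_seqs.ids]
    return list(catalog_or_seqs)


# ---------------------------------------------------------------------------
# Trees: Jukes–Cantor distances, neighbor joining, pruning likelihood
# ---------------------------------------------------------------------------


def _encode_nucleotides(seqs: Sequence[str]) -> np.ndarray:
    arr = np.full((len(seqs), len(seqs[0])), -1, dtype=np.int8)
    for i, seq in enumerate(seqs):
        for j, base in enumerate(seq):
            arr[i, j] = BASE_INDEX.get(base, -1)
    return arr


def _jc_distance_cap(p: float) -> float:
    if p >= 0.749:
        return 5.0
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _jc_distance_matrix(arr: np.ndarray, cols: slice) -> np.ndarray:
    sub = arr[:, cols]
    n = sub.shape[0]
    dist = np.zeros((n, n))
    valid = sub >= 0
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            total = int(both.sum())
            if total == 0:
                d = 5.0
            else:
                p = float(np.sum((sub[i] != sub[j]) & both)) / total
                d = _jc_distance_cap(p)
            dist[i, j] = dist[j, i] = d
    return dist


class _Node:
    """Minimal rooted-tree node for likelihood and parsimony traversals."""

    __slots__ = ("name", "length", "children", "parent")

    def __init__(self, name: Optional[str] = None, length: float = 0.0):
        self.name = name
        self.length = length
        self.children: list["_Node"] = []
        self.parent: Optional["_Node"] = None

    def add(self, child: "_Node") -> None:
        child.parent = self
        self.children.append(child)

    def is_tip(self) -> bool:
        return not self.children

    def postorder(self):
        for child in self.children:
            yield from child.postorder()
        yield self

    def preorder(self):
        yield self
        for child in self.children:
            yield from child.preorder()


def _nj_tree(dist: np.ndarray, ids: Sequence[str]) -> _Node:
    """Neighbor joining (Saitou & Nei), vectorized Q-matrix updates.

    Returns a rooted representation with a trifurcating root, negative
    branch-length estimates clipped to zero.
    """
    n = dist.shape[0]
    if n < 3:
        root = _Node()
        for i, name in enumerate(ids):
            root.add(_Node(name, float(dist[0, 1]) / 2.0 if n == 2 else 0.0))
        return root
    d = dist.astype(float).copy()
    nodes = [_Node(name) for name in ids]
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2.0) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_loc, j_loc = np.unravel_index(np.argmin(q), q.shape)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        gi, gj = active[i_loc], active[j_loc]
        dij = sub[i_loc, j_loc]
        li = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2.0 * (m - 2.0))
        lj = dij - li
        parent = _Node()
        ni, nj_ = nodes[gi], nodes[gj]
        ni.length = max(float(li), 0.0)
        nj_.length = max(float(lj), 0.0)
        parent.add(ni)
        parent.add(nj_)
        # distances from the new node to the remaining taxa
        rest = [a for a in active if a not in (gi, gj)]
        new_d = 0.5 * (d[gi, rest] + d[gj, rest] - dij)
        d[gi, rest] = new_d
        d[rest, gi] = new_d
        nodes[gi] = parent
        active = [a for a in active if a != gj]
    root = _Node()
    if len(active) == 3:
        a, b, c = active
        la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
        lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
        lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
        for g, l in zip((a, b, c), (la, lb, lc)):
            nodes[g].length = max(float(l), 0.0)
            root.add(nodes[g])
    else:
        a, b = active
        half = max(float(d[a, b]) / 2.0, 0.0)
        for g in (a, b):
            nodes[g].length = half
            root.add(nodes[g])
    return root


def _tree_loglik(tree, arr: np.ndarray, ids: Sequence[str], cols: slice) -> tuple[float, int]:
    """Log-likelihood of alignment columns under Jukes–Cantor on a fixed tree.

    Branch lengths are taken from the tree (clipped below at 1e-8).  Returns
    (log-likelihood, number of branches).
    """
    sub = arr[:, cols]
    n_cols = sub.shape[1]
    if n_cols == 0:
        return 0.0, _count_branches(tree)
    id_row = {name: i for i, name in enumerate(ids)}
    partials: dict[int, np.ndarray] = {}
    log_scale = 0.0
    n_branches = 0

    for node in tree.postorder():
        if node.is_tip():
            row = sub[id_row[node.name]]
            like = np.zeros((n_cols, 4))
            observed = row >= 0
            like[observed, row[observed]] = 1.0
            like[~observed] = 1.0
            partials[id(node)] = like
        else:
            like = np.ones((n_cols, 4))
            for child in node.children:
                n_branches += 1
                t = max(float(child.length or 0.0), 1e-8)
                e = math.exp(-4.0 * t / 3.0)
                p_matrix = np.full((4, 4), 0.25 * (1.0 - e))
                np.fill_diagonal(p_matrix, 0.25 + 0.75 * e)
                like *= partials.pop(id(child)) @ p_matrix.T
            scale = like.max(axis=1)
            scale[scale == 0.0] = 1.0
            like /= scale[:, None]
            log_scale += float(np.sum(np.log(scale)))
            partials[id(node)] = like
    root_like = partials[id(tree)]
    ll = log_scale + float(np.sum(np.log(0.25 * root_like.sum(axis=1))))
    return ll, n_branches


def _count_branches(tree: _Node) -> int:
    return sum(1 for node in tree.postorder()) - 1


def _aicc(loglik: float, k: int, n: int) -> float:
    if n - k - 1 <= 0:
        return math.inf
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


@dataclass(frozen=True)
class BreakpointResult:
    best_position: Optional[int]  # last nucleotide column (1-based) of left segment
    delta_aicc: float
    supported: bool
    single_aicc: float = math.nan
    two_tree_aicc: float = math.nan


def sbp_scan(
    catalog_or_seqs: AlleleCatalog | Sequence[str],
    ids: Optional[Sequence[str]] = None,
    min_flank: int = 20,
) -> BreakpointResult:
    """Single-breakpoint recombination scan scored by AICc.

    Candidate breakpoints are placed after every variable column with at
    least ``min_flank`` columns on each side; the best two-tree partition is
    compared against the single-tree model.  ``supported`` is True when the
    two-tree AICc improves on the single-tree AICc (delta_aicc > 0).
    """
    seqs = _sequences(catalog_or_seqs)
    if ids is None:
        if isinstance(catalog_or_seqs, AlleleCatalog):
            ids = catalog_or_seqs.ids
        else:
            ids = [f"s{i}" for i in range(len(seqs))]
    if len(seqs) < 4:
        raise ValueError("need at least four sequences")
    n_cols = len(seqs[0])
    if n_cols < 60:
        raise ValueError("alignment too short for a breakpoint scan")
    arr = _encode_nucleotides(seqs)

    variable = []
    for col in range(n_cols):
        states = set(arr[arr[:, col] >= 0, col].tolist())
        if len(states) >= 2:
            variable.append(col)
    candidates = [c for c in variable if min_flank <= c and n_cols - c >= min_flank]
    # collapse duplicate sequences for tree building speed is unnecessary at
    # this scale; NJ handles ties deterministically enough for fixed input.

    whole = slice(0, n_cols)
    dist_all = _jc_distance_matrix(arr, whole)
    tree_single = _nj_tree(dist_all, ids)
    ll_single, br_single = _tree_loglik(tree_single, arr, ids, whole)
    aicc_single = _aicc(ll_single, br_single + 1, n_cols)

    if len(variable) < 2 or not candidates:
        return BreakpointResult(
            best_position=None,
            delta_aicc=0.0,
            supported=False,
            single_aicc=aicc_single,
        )

    # prefix sums of pairwise mismatches/comparable columns for O(1) segment
    # p-distances
    n_seq = len(seqs)
    pair_idx = list(itertools.combinations(range(n_seq), 2))
    diff = np.zeros((len(pair_idx), n_cols), dtype=np.int32)
    comp = np.zeros((len(pair_idx), n_cols), dtype=np.int32)
    for p, (i, j) in enumerate(pair_idx):
        both = (arr[i] >= 0) & (arr[j] >= 0)
        diff[p] = ((arr[i] != arr[j]) & both).astype(np.int32)
        comp[p] = both.astype(np.int32)
    diff_cum = np.hstack([np.zeros((len(pair_idx), 1), dtype=np.int64), np.cumsum(diff, axis=1)])
    comp_cum = np.hstack([np.zeros((len(pair_idx), 1), dtype=np.int64), np.cumsum(comp, axis=1)])

    def segment_distance(lo: int, hi: int) -> np.ndarray:
        d = np.zeros((n_seq, n_seq))
        for p, (i, j) in enumerate(pair_idx):
            total = comp_cum[p, hi] - comp_cum[p, lo]
            if total == 0:
                val = 5.0
            else:
                val = _jc_distance_cap((diff_cum[p, hi] - diff_cum[p, lo]) / total)
            d[i, j] = d[j, i] = val
        return d

    best_aicc = math.inf
    best_pos = None
    for cut in candidates:
        tree_left = _nj_tree(segment_distance(0, cut), ids)
        tree_right = _nj_tree(segment_distance(cut, n_cols), ids)
        ll_left, br_left = _tree_loglik(tree_left, arr, ids, slice(0, cut))
        ll_right, br_right = _tree_loglik(tree_right, arr, ids, slice(cut, n_cols))
        aicc_two = _aicc(ll_left + ll_right, br_left + br_right + 1, n_cols)
        if aicc_two < best_aicc:
            best_aicc = aicc_two
            best_pos = cut
    if math.isinf(best_aicc):
        # two-tree model unidentifiable (more parameters than columns)
        return BreakpointResult(
            best_position=None,
            delta_aicc=0.0,
            supported=False,
            single_aicc=aicc_single,
        )
    delta = aicc_single - best_aicc
    return BreakpointResult(
        best_position=best_pos if best_pos is not None else None,
        delta_aicc=delta,
        supported=delta > 0.0,
        single_aicc=aicc_single,
        two_tree_aicc=best_aicc,
    )


# ---------------------------------------------------------------------------
# SLAC: ancestral codon reconstruction and per-site counting
# ---------------------------------------------------------------------------

_SENSE = np.array([i for i in range(64) if AA[i] != "*"])
# Sankoff cost: 1000 per nucleotide change, +1 per unavoidable nonsynonymous
# step (so minimal-change assignments are preferred, then those minimizing
# nonsynonymous changes).
_SANKOFF_COST = (1000.0 * NT_DIFF_TABLE + ND_MIN_TABLE)[np.ix_(_SENSE, _SENSE)]


@dataclass(frozen=True)
class SlacSiteResult:
    site: int  # 1-based codon position
    normalized_dn_ds: float
    p_value: float
    syn_changes: float
    nonsyn_changes: float
    syn_sites: float
    nonsyn_sites: float


def _sankoff_assign(tree, leaf_states: dict[str, int]) -> dict[int, int]:
    """Minimal-cost ancestral codon assignment over sense codons.

    ``leaf_states`` maps leaf name to a codon index (or -1 for missing).
    Returns node-id -> assigned sense-codon index (position in _SENSE).
    """
    n_states = _SENSE.size
    sense_pos = {int(c): p for p, c in enumerate(_SENSE)}
    costs: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_tip():
            state = leaf_states[node.name]
            vec = np.full(n_states, np.inf)
            if state < 0:
                vec[:] = 0.0
            else:
                vec[sense_pos[state]] = 0.0
            costs[id(node)] = vec
        else:
            vec = np.zeros(n_states)
            for child in node.children:
                # min over child state of child_cost + transition cost
                vec += np.min(costs[id(child)][None, :] + _SANKOFF_COST, axis=1)
            costs[id(node)] = vec

    assignment: dict[int, int] = {}
    for node in tree.preorder():
        vec = costs[id(node)]
        if node.parent is None:
            total = vec
        else:
            parent_state = assignment[id(node.parent)]
            total = _SANKOFF_COST[parent_state, :] + vec
        assignment[id(node)] = int(np.argmin(total))  # argmin → smallest codon on ties
    return assignment


def slac_sites(
    catalog: AlleleCatalog,
    breakpoint: Optional[BreakpointResult | int] = None,
) -> list[SlacSiteResult]:
    """Per-codon counting test for positive selection.

    When a supported ``breakpoint`` is given the alignment is split into two
    segments with independent NJ trees (so recombination does not masquerade
    as selection); ancestral codons come from parsimony and per-site
    synonymous/nonsynonymous changes are summed over all branches.
    """
    if len(catalog) < 4:
        raise ValueError("need at least four sequences")
    ids = catalog.ids
    seqs = [catalog.sequence(a) for a in ids]
    arr = _encode_nucleotides(seqs)
    n_cols = arr.shape[1]
    if n_cols % 3 != 0:
        raise ValueError("alignment length must be divisible by 3")
    n_codons = n_cols // 3
    enc = np.vstack([_encode_codons(s) for s in seqs])

    cut: Optional[int] = None
    if isinstance(breakpoint, BreakpointResult):
        if breakpoint.supported and breakpoint.best_position is not None:
            cut = breakpoint.best_position
    elif breakpoint is not None:
        cut = int(breakpoint)

    if cut is None:
        segments = [(slice(0, n_cols), range(n_codons))]
    else:
        left_codons = [c for c in range(n_codons) if 3 * (c + 1) <= cut]
        right_codons = [c for c in range(n_codons) if 3 * (c + 1) > cut]
        segments = [
            (slice(0, cut), left_codons),
            (slice(cut, n_cols), right_codons),
        ]

    results: list[Optional[SlacSiteResult]] = [None] * n_codons
    for cols, codon_range in segments:
        if not codon_range:
            continue
        dist = _jc_distance_matrix(arr, cols)
        tree = _nj_tree(dist, ids)
        for codon_i in codon_range:
            results[codon_i] = _slac_one_site(tree, enc, ids, codon_i)
    return [r for r in results if r is not None]


def _slac_one_site(tree, enc: np.ndarray, ids: Sequence[str], codon_i: int) -> SlacSiteResult:
    leaf_states = {name: int(enc[row, codon_i]) for row, name in enumerate(ids)}
    observed = [s for s in leaf_states.values() if s >= 0]
    site = codon_i + 1
    if len(set(observed)) <= 1:
        s_sites = float(np.mean(SYN_SITES[observed])) if observed else 1.5
        return SlacSiteResult(site, 0.0, 1.0, 0.0, 0.0, s_sites, 3.0 - s_sites)

    assignment = _sankoff_assign(tree, leaf_states)
    sd = nd = 0.0
    for node in tree.postorder():
        if node.parent is None:
            continue
        a = _SENSE[assignment[id(node.parent)]]
        b = _SENSE[assignment[id(node)]]
        if node.is_tip() and leaf_states[node.name] < 0:
            continue
        sd += SD_TABLE[a, b]
        nd += ND_TABLE[a, b]

    s_sites = float(np.mean(SYN_SITES[observed]))
    n_sites = 3.0 - s_sites
    total = sd + nd
    if total <= 0:
        return SlacSiteResult(site, 0.0, 1.0, sd, nd, s_sites, n_sites)
    p_nonsyn = n_sites / 3.0
    n_int = int(round(total))
    k_int = min(n_int, int(round(nd)))
    p = float(stats.binomtest(k_int, n_int, p_nonsyn, alternative="greater").pvalue)
    dn = nd / n_sites if n_sites > 0 else 0.0
    ds = sd / s_sites if s_sites > 0 else 0.0
    return SlacSiteResult(site, dn - ds, p, sd, nd, s_sites, n_sites)


def slac_to_selection_rows(results: Iterable[SlacSiteResult]):
    """Convert internal SLAC output to SiteSelectionTable rows."""
    from .model import SelectionRow

    return [
        SelectionRow(
            site=r.site,
            model="SLAC",
            statistic_name="normalized_dn_ds",
            statistic_value=r.normalized_dn_ds,
            evidence_kind="p_value",
            evidence_value=r.p_value,
        )
        for r in results
    ]


def consensus_selected_sites(
    table: SiteSelectionTable,
    slac_p: float = 0.05,
    rel_bf: float = 100.0,
    meme_p: float = 0.05,
    min_models: int = 2,
) -> set[int]:
    """Sites flagged by at least ``min_models`` of SLAC/REL/MEME.

    Per-model criteria: SLAC p < ``slac_p``; REL Bayes factor > ``rel_bf``;
    MEME p < ``meme_p``.
    """
    flagged: dict[int, set[str]] = {}
    for row in table.rows:
        hit = False
        if row.model == "SLAC" and row.evidence_kind == "p_value":
            hit = row.evidence_value < slac_p
        elif row.model == "REL" and row.evidence_kind == "bayes_factor":
            hit = row.evidence_value > rel_bf
        elif row.model == "MEME" and row.evidence_kind == "p_value":
            hit = row.evidence_value < meme_p
        if hit:
            flagged.setdefault(row.site, set()).add(row.model)
    return {site for site, models in flagged.items() if len(models) >= min_models}
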