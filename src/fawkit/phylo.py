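"""Phylogenetic strain grouping of TpiI4a200 haplotypes.

The TpiI4a200 marker separates fall armyworm host strains into two clades, so
a query haplotype can be assigned to the C-strain or R-strain group by
placing it against a labelled reference set.  The machinery is deliberately
deterministic and closed-form: center-star progressive alignment, p / JC69 /
TN93 pairwise distances with pairwise deletion (the intron has frequent
indels), canonical neighbor-joining with explicit tie-breaking, and
column-resampling bootstrap support.  The tree's role here is two-group
classification, which distance-based methods reproduce; no likelihood search
is attempted.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio import Align
from skbio import TreeNode

from .markers import ReferenceHaplotypeSet

__all__ = [
    "HaplotypeAlignment",
    "DistanceMatrix",
    "PhyloTree",
    "StrainAssignment",
    "align_haplotypes",
    "compute_distances",
    "build_nj_tree",
    "bootstrap_support",
    "assign_strain_group",
    "SATURATION_CAP",
]

#: distance assigned to saturated pairs (log argument non-positive)
SATURATION_CAP = 5.0

_VALID = frozenset("ACGT")


@dataclass
class HaplotypeAlignment:
    """Equal-length gapped rows plus optional strain annotation per label."""

    labels: list
    rows: list  # aligned IUPAC strings with '-' gaps
    strains: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.labels) != len(self.rows):
            raise ValueError("labels/rows length mismatch")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows have unequal lengths")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def resample_columns(self, rng: np.random.Generator) -> "HaplotypeAlignment":
        idx = rng.integers(0, self.n_cols, self.n_cols)
        rows = ["".join(r[i] for i in idx) for r in self.rows]
        return HaplotypeAlignment(list(self.labels), rows, dict(self.strains))


@dataclass
class DistanceMatrix:
    labels: list
    matrix: np.ndarray
    model: str
    capped_pairs: set = field(default_factory=set)

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T):
            raise ValueError("matrix must be symmetric")
        if (m < 0).any():
            raise ValueError("distances must be non-negative")
        if not np.allclose(np.diag(m), 0):
            raise ValueError("diagonal must be zero")
        self.matrix = m

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.labels.index(a), self.labels.index(b)])


@dataclass
class PhyloTree:
    """Unrooted tree (trifurcating root) with bootstrap support per bipartition.

    ``supports`` maps a canonical bipartition (frozenset of leaf labels on the
    side not containing the anchor taxon) to percent support in [0, 100].
    """

    root: TreeNode
    supports: dict = field(default_factory=dict)
    model: str = ""

    @property
    def leaf_names(self) -> set:
        return {t.name for t in self.root.tips()}

    def bipartitions(self) -> set:
        return _bipartitions(self.root)

    def to_newick(self, with_supports: bool = False) -> str:
        tree = self.root.copy()
        if with_supports and self.supports:
            taxa = {t.name for t in tree.tips()}
            anchor = min(taxa)
            for node in tree.non_tips(include_self=False):
                side = frozenset(t.name for t in node.tips())
                key = side if anchor not in side else frozenset(taxa - side)
                if key in self.supports:
                    node.name = str(int(round(self.supports[key])))
        buf = io.StringIO()
        tree.write(buf)
        return buf.getvalue().strip()


def _bipartitions(root: TreeNode) -> set:
    taxa = {t.name for t in root.tips()}
    anchor = min(taxa)
    out = set()
    for node in root.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > len(taxa) - 2:
            continue
        key = side if anchor not in side else frozenset(taxa - side)
        out.add(key)
    return out


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------


def _pairwise_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -4.0
    aligner.extend_gap_score = -1.0
    return aligner


def align_haplotypes(
    sequences: Mapping[str, str] | Sequence[tuple],
    strains: Mapping[str, str] | None = None,
) -> HaplotypeAlignment:
    """Center-star progressive multiple alignment with affine gap scores.

    The center sequence minimises the summed pairwise alignment distance
    (ties by lexicographic label); every other sequence is globally aligned
    to the center (match +1, mismatch -1, open -4, extend -1) and the
    pairwise alignments are merged under once-a-gap-always-a-gap.  The result
    is independent of input order: alignment steps follow sorted label order.
    """
    seqs = dict(sequences)
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences to align")
    labels = sorted(seqs)
    aligner = _pairwise_aligner()

    # choose the center by maximal summed pairwise score (== minimal distance)
    score_sum = {lab: 0.0 for lab in labels}
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            s = aligner.score(seqs[a], seqs[b])
            score_sum[a] += s
            score_sum[b] += s
    center = max(labels, key=lambda l: (score_sum[l], l))

    master = seqs[center]  # center row in current master coordinates
    aligned: dict[str, str] = {center: master}
    for lab in labels:
        if lab == center:
            continue
        aln = aligner.align(seqs[center], seqs[lab])[0]
        c_row, s_row = str(aln[0]), str(aln[1])
        master, aligned, new_row = _merge_into_master(
            master, aligned, c_row, s_row
        )
        aligned[lab] = new_row
    rows = [aligned[lab] for lab in labels]
    return HaplotypeAlignment(labels, rows, dict(strains or {}))


def _merge_into_master(
    master: str, aligned: dict, c_row: str, s_row: str
) -> tuple:
    """Merge a (center, seq) pairwise alignment into the running MSA.

    ``master`` is the center with all gaps accumulated so far; ``c_row`` is
    the center as aligned in this pairwise step.  Ungapped center positions
    coincide, so the two gap patterns are interleaved; existing rows receive
    gaps where this step introduces new ones and vice versa.
    """
    i = j = 0
    out_master = []
    out_existing = {k: [] for k in aligned}
    out_new = []
    while i < len(master) or j < len(c_row):
        m_gap = i < len(master) and master[i] == "-"
        c_gap = j < len(c_row) and c_row[j] == "-"
        if i < len(master) and j < len(c_row) and not m_gap and not c_gap:
            out_master.append(master[i])
            for k in aligned:
                out_existing[k].append(aligned[k][i])
            out_new.append(s_row[j])
            i += 1
            j += 1
        elif m_gap:
            out_master.append("-")
            for k in aligned:
                out_existing[k].append(aligned[k][i])
            out_new.append("-")
            i += 1
        else:  # c_gap or trailing center columns
            out_master.append("-")
            for k in aligned:
                out_existing[k].append("-")
            out_new.append(s_row[j])
            j += 1
    new_master = "".join(out_master)
    new_aligned = {k: "".join(v) for k, v in out_existing.items()}
    return new_master, new_aligned, "".join(out_new)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


def _pair_distance(a: str, b: str, model: str) -> tuple:
    """(distance, capped?) for one aligned pair under the chosen model.

    Columns where either row has a gap or ambiguity code are deleted for this
    pair only (pairwise deletion).
    """
    pairs = [
        (x, y) for x, y in zip(a, b) if x in _VALID and y in _VALID
    ]
    n = len(pairs)
    if n == 0:
        raise ValueError("pair has zero comparable sites")
    diffs = sum(1 for x, y in pairs if x != y)
    p = diffs / n
    if model == "p":
        return p, False
    if model == "JC69":
        arg = 1.0 - 4.0 * p / 3.0
        if arg <= 0:
            return SATURATION_CAP, True
        return -0.75 * math.log(arg), False
    if model == "TN93":
        return _tn93(pairs, n)
    raise ValueError(f"unknown model {model!r}")


def _tn93(pairs: list, n: int) -> tuple:
    counts = {b: 0 for b in "ACGT"}
    p1 = p2 = q = 0
    for x, y in pairs:
        counts[x] += 1
        counts[y] += 1
        if x != y:
            s = frozenset((x, y))
            if s == frozenset("AG"):
                p1 += 1
            elif s == frozenset("CT"):
                p2 += 1
            else:
                q += 1
    freqs = {b: counts[b] / (2 * n) for b in "ACGT"}
    gA, gC, gG, gT = freqs["A"], freqs["C"], freqs["G"], freqs["T"]
    gR, gY = gA + gG, gC + gT
    P1, P2, Q = p1 / n, p2 / n, q / n
    if gR == 0 or gY == 0 or gA * gG == 0 or gC * gT == 0:
        # degenerate composition: fall back to the JC69 closed form
        p = (p1 + p2 + q) / n
        arg = 1.0 - 4.0 * p / 3.0
        if arg <= 0:
            return SATURATION_CAP, True
        return -0.75 * math.log(arg), False
    a1 = 1.0 - gR * P1 / (2.0 * gA * gG) - Q / (2.0 * gR)
    a2 = 1.0 - gY * P2 / (2.0 * gC * gT) - Q / (2.0 * gY)
    b = 1.0 - Q / (2.0 * gR * gY)
    if a1 <= 0 or a2 <= 0 or b <= 0:
        return SATURATION_CAP, True
    d = (
        -2.0 * gA * gG / gR * math.log(a1)
        - 2.0 * gC * gT / gY * math.log(a2)
        - 2.0 * (gR * gY - gA * gG * gY / gR - gC * gT * gR / gY) * math.log(b)
    )
    return (d if d > 0 else 0.0), False


def compute_distances(aln: HaplotypeAlignment, model: str = "TN93") -> DistanceMatrix:
    """Pairwise evolutionary distances under p, JC69 or TN93.

    Saturated pairs (logarithm of a non-positive quantity) get the declared
    cap of 5.0 substitutions/site and are recorded in ``capped_pairs`` with a
    warning.
    """
    if len(aln.labels) < 2:
        raise ValueError("need at least 2 rows")
    k = len(aln.labels)
    m = np.zeros((k, k))
    capped = set()
    for i in range(k):
        for j in range(i + 1, k):
            d, cap = _pair_distance(aln.rows[i], aln.rows[j], model)
            m[i, j] = m[j, i] = d
            if cap:
                capped.add(frozenset((aln.labels[i], aln.labels[j])))
    if capped:
        warnings.warn(
            f"{len(capped)} saturated pair(s) set to distance cap {SATURATION_CAP}",
            stacklevel=2,
        )
    return DistanceMatrix(list(aln.labels), m, model, capped)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def build_nj_tree(D: DistanceMatrix) -> PhyloTree:
    """Canonical neighbor-joining (Q-matrix criterion).

    Ties in the Q minimum are broken by the lexicographically smallest pair
    of subtree keys (smallest leaf label per subtree), making the result
    deterministic.  Negative branch lengths are clamped to 0 with the length
    transferred to the sibling edge, preserving the pair's path length.  On
    additive matrices the generating topology and branch lengths are
    recovered exactly.  The returned root is the trifurcating unrooted form.
    """
    n = len(D.labels)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    nodes: dict[str, TreeNode] = {
        lab: TreeNode(name=lab) for lab in D.labels
    }
    key: dict[str, str] = {lab: lab for lab in D.labels}  # min leaf label
    d: dict[frozenset, float] = {}
    for i, a in enumerate(D.labels):
        for b in D.labels[i + 1 :]:
            d[frozenset((a, b))] = float(D.matrix[i, D.labels.index(b)])
    active = sorted(nodes)

    counter = 0
    while len(active) > 3:
        r = len(active)
        row_sum = {
            a: sum(d[frozenset((a, b))] for b in active if b != a) for a in active
        }
        best = None
        for ia, a in enumerate(active):
            for b in active[ia + 1 :]:
                qv = (r - 2) * d[frozenset((a, b))] - row_sum[a] - row_sum[b]
                pair_key = tuple(sorted((key[a], key[b])))
                cand = (qv, pair_key, a, b)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, a, b = best
        dab = d[frozenset((a, b))]
        la = 0.5 * dab + (row_sum[a] - row_sum[b]) / (2.0 * (r - 2))
        lb = dab - la
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        la, lb = max(la, 0.0), max(lb, 0.0)
        counter += 1
        uname = f"_nj{counter}"
        child_a, child_b = nodes.pop(a), nodes.pop(b)
        child_a.length = la
        child_b.length = lb
        u = TreeNode(children=[child_a, child_b])
        nodes[uname] = u
        key[uname] = min(key[a], key[b])
        for c in active:
            if c in (a, b):
                continue
            duc = 0.5 * (
                d[frozenset((a, c))] + d[frozenset((b, c))] - dab
            )
            d[frozenset((uname, c))] = max(duc, 0.0)
        active = sorted(
            (x for x in active if x not in (a, b)), key=lambda x: key[x]
        )
        active.append(uname)
        active.sort(key=lambda x: key[x])

    # join the final three at the unrooted trifurcation (3-point formulas)
    a, b, c = sorted(active, key=lambda x: key[x])
    dab = d[frozenset((a, b))]
    dac = d[frozenset((a, c))]
    dbc = d[frozenset((b, c))]
    la = max(0.5 * (dab + dac - dbc), 0.0)
    lb = max(0.5 * (dab + dbc - dac), 0.0)
    lc = max(0.5 * (dac + dbc - dab), 0.0)
    for name, length in ((a, la), (b, lb), (c, lc)):
        nodes[name].length = length
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    return PhyloTree(root=root, model=D.model)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def bootstrap_support(
    aln: HaplotypeAlignment,
    model: str = "TN93",
    B: int = 100,
    seed: int = 0,
) -> PhyloTree:
    """NJ tree with column-resampling bootstrap support on internal edges.

    Support of an internal bipartition of the optimal tree is the percentage
    of B column-resampled replicate trees containing it.  Internal edges of
    length ~0 are collapsed before supports are read, so an alignment of
    identical sequences yields a star tree with no resolved bipartitions
    (all supports vacuously 0).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if len(aln.labels) < 4:
        raise ValueError("bootstrap needs an alignment of >= 4 rows")
    tree = build_nj_tree(compute_distances(aln, model))
    _collapse_zero_edges(tree.root)
    target = tree.bipartitions()
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    for _ in range(B):
        rep = aln.resample_columns(rng)
        try:
            rep_tree = build_nj_tree(compute_distances(rep, model))
        except ValueError:  # a replicate lost all comparable sites for a pair
            continue
        rep_bps = rep_tree.bipartitions()
        for bp in target:
            if bp in rep_bps:
                counts[bp] += 1
    tree.supports = {bp: 100.0 * c / B for bp, c in counts.items()}
    return tree


def _collapse_zero_edges(root: TreeNode, tol: float = 1e-12) -> None:
    """Collapse internal edges of ~zero length into polytomies, in place."""
    changed = True
    while changed:
        changed = False
        for node in list(root.non_tips(include_self=False)):
            if node.parent is not None and (node.length or 0.0) <= tol:
                parent = node.parent
                for child in list(node.children):
                    node.remove(child)
                    parent.append(child)
                parent.remove(node)
                changed = True


# ---------------------------------------------------------------------------
# strain assignment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StrainAssignment:
    label: str
    strain: str  # C, R, unassigned
    nearest_C_dist: float
    nearest_R_dist: float


def assign_strain_group(
    query: str,
    reference: ReferenceHaplotypeSet,
    k: int = 1,
    model: str = "TN93",
    query_label: str = "query",
) -> StrainAssignment:
    """Assign a query haplotype to the C- or R-strain phylogenetic group.

    The query is aligned with the full reference set and voted on by its k
    nearest references under the model distance.  A split vote — or, at
    k = 1, exactly equal distance to the nearest C and nearest R reference —
    returns "unassigned"; the distances to the nearest reference of each
    strain are always reported as evidence.
    """
    strains = {lab: reference.strain_of(lab) for lab in reference.labels}
    if set(strains.values()) != {"C", "R"}:
        raise ValueError("reference needs at least one sequence per strain")
    seqs = {lab: reference.sequence_of(lab) for lab in reference.labels}
    seqs[query_label] = query
    aln = align_haplotypes(seqs, strains)
    D = compute_distances(aln, model)
    qi = D.labels.index(query_label)
    dists = {
        lab: float(D.matrix[qi, D.labels.index(lab)]) for lab in reference.labels
    }
    nearest_c = min(dists[l] for l in dists if strains[l] == "C")
    nearest_r = min(dists[l] for l in dists if strains[l] == "R")
    ranked = sorted(dists.items(), key=lambda kv: (kv[1], kv[0]))
    votes = [strains[lab] for lab, _ in ranked[:k]]
    n_c, n_r = votes.count("C"), votes.count("R")
    if n_c == n_r or (k == 1 and math.isclose(nearest_c, nearest_r)):
        strain = "unassigned"
    else:
        strain = "C" if n_c > n_r else "R"
    return StrainAssignment(query_label, strain, nearest_c, nearest_r)
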