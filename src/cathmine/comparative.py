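"""Comparative analysis of cathelin domains.

Progressive multiple alignment, per-cent identity with the half-up rounding
used for printed values, consensus/dominance profiling with the
uppercase / '+' / '-' display conventions, Kimura-corrected protein
distances, and neighbor-joining trees with column-bootstrap support.

The tree stage deliberately approximates maximum-likelihood inference with
distance-based NJ: the goal is descriptive clustering of conserved domains,
not likelihood estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from itertools import combinations

import numpy as np

from .core_io import CathmineError
from .locus_search import load_matrix

_GAP = "-"
_GAP_SCORE = -4.0  # column score of gap vs residue in profile alignment


# ---------------------------------------------------------------------------
# pairwise global alignment (affine gaps, Gotoh), deterministic


def needleman_wunsch(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> tuple[float, str, str]:
    """Optimal global alignment score and one alignment (affine gaps).

    A gap of length L costs gap_open + (L-1)*gap_extend. Tie-break prefers
    diagonal > up > left, giving a deterministic traceback.
    """
    if not a or not b:
        raise CathmineError("needleman_wunsch: empty sequence")
    alphabet, S = load_matrix(matrix)
    idx = {ch: i for i, ch in enumerate(alphabet)}
    x = idx.get("X", 0)
    ea = [idx.get(c, x) for c in a]
    eb = [idx.get(c, x) for c in b]
    n, m = len(a), len(b)
    NEG = -1e18
    M = np.full((n + 1, m + 1), NEG)
    E = np.full((n + 1, m + 1), NEG)  # gap in a (left moves)
    F = np.full((n + 1, m + 1), NEG)  # gap in b (up moves)
    M[0, 0] = 0.0
    for j in range(1, m + 1):
        E[0, j] = -(gap_open + (j - 1) * gap_extend)
    for i in range(1, n + 1):
        F[i, 0] = -(gap_open + (i - 1) * gap_extend)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = S[ea[i - 1], eb[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], E[i - 1, j - 1], F[i - 1, j - 1]) + s
            E[i, j] = max(M[i, j - 1] - gap_open, E[i, j - 1] - gap_extend,
                          F[i, j - 1] - gap_open)
            F[i, j] = max(M[i - 1, j] - gap_open, F[i - 1, j] - gap_extend,
                          E[i - 1, j] - gap_open)
    score = max(M[n, m], E[n, m], F[n, m])
    # traceback, preferring diagonal > up > left at equal score
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    if M[n, m] >= score:
        state = "M"
    elif F[n, m] >= score:
        state = "F"
    else:
        state = "E"
    while i > 0 or j > 0:
        if state == "M" and i > 0 and j > 0:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            target = M[i, j] - S[ea[i - 1], eb[j - 1]]
            i, j = i - 1, j - 1
            if abs(M[i, j] - target) < 1e-9:
                state = "M"
            elif abs(F[i, j] - target) < 1e-9:
                state = "F"
            else:
                state = "E"
        elif state == "F" and i > 0:  # up: consume a
            out_a.append(a[i - 1])
            out_b.append(_GAP)
            target_open = M[i - 1, j] - gap_open
            target_ext = F[i - 1, j] - gap_extend
            val = F[i, j]
            i -= 1
            if abs(target_open - val) < 1e-9:
                state = "M"
            elif abs(target_ext - val) < 1e-9:
                state = "F"
            else:
                state = "E"
        elif state == "E" and j > 0:  # left: consume b
            out_a.append(_GAP)
            out_b.append(b[j - 1])
            target_open = M[i, j - 1] - gap_open
            target_ext = E[i, j - 1] - gap_extend
            val = E[i, j]
            j -= 1
            if abs(target_open - val) < 1e-9:
                state = "M"
            elif abs(target_ext - val) < 1e-9:
                state = "E"
            else:
                state = "F"
        elif i > 0:
            out_a.append(a[i - 1])
            out_b.append(_GAP)
            i -= 1
        else:
            out_a.append(_GAP)
            out_b.append(b[j - 1])
            j -= 1
    return float(score), "".join(reversed(out_a)), "".join(reversed(out_b))


# ---------------------------------------------------------------------------
# multiple alignment


@dataclass
class Msa:
    rows: list[tuple[str, str]]  # (id, gapped sequence)

    def __post_init__(self) -> None:
        if not self.rows:
            raise CathmineError("empty alignment")
        n = len(self.rows[0][1])
        if any(len(s) != n for _, s in self.rows):
            raise CathmineError("alignment rows differ in length")

    @property
    def ncols(self) -> int:
        return len(self.rows[0][1])

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.rows]

    def degapped(self, i: int) -> str:
        return self.rows[i][1].replace(_GAP, "")

    def column(self, j: int) -> list[str]:
        return [s[j] for _, s in self.rows]


def _profile_of(rows: list[str]) -> list[dict[str, float]]:
    cols = []
    for j in range(len(rows[0])):
        d: dict[str, float] = {}
        for r in rows:
            d[r[j]] = d.get(r[j], 0.0) + 1.0
        n = len(rows)
        cols.append({k: v / n for k, v in d.items()})
    return cols


def _col_score(ca: dict[str, float], cb: dict[str, float], S, idx, x) -> float:
    score = 0.0
    for a, fa in ca.items():
        for b, fb in cb.items():
            if a == _GAP and b == _GAP:
                continue
            elif a == _GAP or b == _GAP:
                score += fa * fb * _GAP_SCORE
            else:
                score += fa * fb * float(S[idx.get(a, x), idx.get(b, x)])
    return score


def _align_profiles(
    ra: list[str], rb: list[str], matrix: str, gap_open: float, gap_extend: float
) -> tuple[list[str], list[str]]:
    """Global profile-profile alignment; returns the two row groups padded."""
    alphabet, S = load_matrix(matrix)
    idx = {ch: i for i, ch in enumerate(alphabet)}
    x = idx.get("X", 0)
    pa = _profile_of(ra)
    pb = _profile_of(rb)
    n, m = len(pa), len(pb)
    NEG = -1e18
    H = np.full((n + 1, m + 1), NEG)
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)  # 1 diag, 2 up, 3 left
    H[0, 0] = 0.0
    for i in range(1, n + 1):
        H[i, 0] = -(gap_open + (i - 1) * gap_extend)
        ptr[i, 0] = 2
    for j in range(1, m + 1):
        H[0, j] = -(gap_open + (j - 1) * gap_extend)
        ptr[0, j] = 3
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = H[i - 1, j - 1] + _col_score(pa[i - 1], pb[j - 1], S, idx, x)
            up = H[i - 1, j] - (gap_extend if ptr[i - 1, j] == 2 else gap_open)
            left = H[i, j - 1] - (gap_extend if ptr[i, j - 1] == 3 else gap_open)
            best, p = diag, 1
            if up > best:
                best, p = up, 2
            if left > best:
                best, p = left, 3
            H[i, j] = best
            ptr[i, j] = p
    i, j = n, m
    steps: list[int] = []
    while i > 0 or j > 0:
        p = ptr[i, j]
        steps.append(p)
        if p == 1:
            i, j = i - 1, j - 1
        elif p == 2:
            i -= 1
        else:
            j -= 1
    ia = ib = 0
    res_a = ["" for _ in ra]
    res_b = ["" for _ in rb]
    for p in reversed(steps):
        if p == 1:
            for k in range(len(ra)):
                res_a[k] += ra[k][ia]
            for k in range(len(rb)):
                res_b[k] += rb[k][ib]
            ia += 1
            ib += 1
        elif p == 2:
            for k in range(len(ra)):
                res_a[k] += ra[k][ia]
            for k in range(len(rb)):
                res_b[k] += _GAP
            ia += 1
        else:
            for k in range(len(ra)):
                res_a[k] += _GAP
            for k in range(len(rb)):
                res_b[k] += rb[k][ib]
            ib += 1
    return res_a, res_b


def align_msa(
    seqs: list[tuple[str, str]],
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> Msa:
    """Progressive multiple alignment with a UPGMA guide tree.

    Pairwise global alignments give p-distances for the guide tree; groups
    are then merged by profile-profile alignment. Deterministic throughout
    (lexicographic tie-breaks).
    """
    if len(seqs) < 2:
        raise CathmineError("align_msa needs at least 2 sequences")
    for sid, s in seqs:
        if not s:
            raise CathmineError(f"sequence {sid!r} is empty")
    if len(seqs) == 2:
        (ida, sa), (idb, sb) = seqs
        _, ga, gb = needleman_wunsch(sa, sb, matrix, gap_open, gap_extend)
        return Msa(rows=[(ida, ga), (idb, gb)])
    # guide distances
    n = len(seqs)
    D: dict[tuple[int, int], float] = {}
    for i, j in combinations(range(n), 2):
        _, ga, gb = needleman_wunsch(seqs[i][1], seqs[j][1], matrix, gap_open, gap_extend)
        comparable = [(a, b) for a, b in zip(ga, gb) if a != _GAP and b != _GAP]
        ident = sum(a == b for a, b in comparable)
        D[(i, j)] = 1.0 - ident / len(comparable) if comparable else 1.0
    # UPGMA with lexicographic tie-break on member id lists
    clusters: dict[int, dict] = {
        i: {"members": [i], "rows": [seqs[i][1]], "ids": [seqs[i][0]], "size": 1}
        for i in range(n)
    }
    dist = {frozenset(k): v for k, v in D.items()}

    def cdist(a: int, b: int) -> float:
        ca, cb = clusters[a], clusters[b]
        tot = 0.0
        for i in ca["members"]:
            for j in cb["members"]:
                tot += dist[frozenset((i, j))] if i != j else 0.0
        return tot / (ca["size"] * cb["size"])

    next_id = n
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for a, b in combinations(keys, 2):
            key = (cdist(a, b), tuple(sorted(clusters[a]["ids"] + clusters[b]["ids"])))
            if best is None or key < best[0]:
                best = (key, a, b)
        _, a, b = best
        ra, rb = clusters[a]["rows"], clusters[b]["rows"]
        res_a, res_b = _align_profiles(ra, rb, matrix, gap_open, gap_extend)
        clusters[next_id] = {
            "members": clusters[a]["members"] + clusters[b]["members"],
            "rows": res_a + res_b,
            "ids": clusters[a]["ids"] + clusters[b]["ids"],
            "size": clusters[a]["size"] + clusters[b]["size"],
        }
        del clusters[a], clusters[b]
        next_id += 1
    final = clusters.popitem()[1]
    order = {sid: k for k, (sid, _) in enumerate(seqs)}
    rows = sorted(zip(final["ids"], final["rows"]), key=lambda r: order[r[0]])
    return Msa(rows=list(rows))


# ---------------------------------------------------------------------------
# identity and consensus


def percent_identity(aligned_a: str, aligned_b: str) -> float:
    """100 x identical columns / total columns, gaps count as mismatches.

    Rounded half-up to 2 decimals, matching how such values are printed.
    """
    if len(aligned_a) != len(aligned_b):
        raise CathmineError("percent_identity: length mismatch")
    if not aligned_a:
        raise CathmineError("percent_identity: empty alignment")
    ident = sum(
        a == b and a != _GAP for a, b in zip(aligned_a, aligned_b)
    )
    pct = Decimal(100 * ident) / Decimal(len(aligned_a))
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class ConsensusProfile:
    """Per-column consensus under display conventions: uppercase = unanimous
    residue, lowercase = dominant residue, '+' = tied residue modes,
    '-' = dominant gap. Dominance is the modal-symbol fraction."""

    consensus: str
    dominance: list[float]

    @property
    def ncols(self) -> int:
        return len(self.consensus)


def consensus_profile(msa: Msa) -> ConsensusProfile:
    if len(msa.rows) < 2:
        raise CathmineError("consensus requires at least 2 rows")
    nrows = len(msa.rows)
    consensus = []
    dominance = []
    for j in range(msa.ncols):
        col = msa.column(j)
        counts: dict[str, int] = {}
        for c in col:
            counts[c] = counts.get(c, 0) + 1
        gap_n = counts.pop(_GAP, 0)
        if counts:
            top = max(counts.values())
            modes = sorted(c for c, v in counts.items() if v == top)
        else:
            top, modes = 0, []
        if gap_n > top:
            consensus.append("-")
            dominance.append(gap_n / nrows)
        elif len(modes) >= 2:
            consensus.append("+")
            dominance.append(top / nrows)
        elif top == nrows:
            consensus.append(modes[0].upper())
            dominance.append(1.0)
        else:
            consensus.append(modes[0].lower())
            dominance.append(top / nrows)
    return ConsensusProfile(consensus="".join(consensus), dominance=dominance)


def dominance_summary(profile: ConsensusProfile, threshold: float) -> int:
    """Number of columns whose dominance reaches ``threshold``."""
    if not 0 <= threshold <= 1:
        raise CathmineError("threshold must lie in [0, 1]")
    return sum(d >= threshold for d in profile.dominance)


# ---------------------------------------------------------------------------
# distances


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.ids), len(self.ids)):
            raise CathmineError("distance matrix shape mismatch")
        if not np.allclose(m, m.T) or np.any(np.diag(m) != 0) or np.any(m < 0):
            raise CathmineError("distance matrix must be symmetric, nonnegative, zero-diagonal")

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.ids.index(a), self.ids.index(b)])


def kimura_protein_distance(p: float, max_distance: float = 10.0) -> float:
    """Kimura's correction d = -ln(1 - p - 0.2 p^2) with an overflow cap."""
    arg = 1.0 - p - 0.2 * p * p
    if arg <= 0:
        return max_distance
    return min(-math.log(arg), max_distance)


def protein_distance(msa: Msa, max_distance: float = 10.0) -> DistanceMatrix:
    """Pairwise Kimura-corrected p-distances, gap columns excluded pairwise."""
    n = len(msa.rows)
    mat = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        a = msa.rows[i][1]
        b = msa.rows[j][1]
        pairs = [(x, y) for x, y in zip(a, b) if x != _GAP and y != _GAP]
        if not pairs:
            raise CathmineError(
                f"no comparable columns between {msa.rows[i][0]!r} and {msa.rows[j][0]!r}"
            )
        p = sum(x != y for x, y in pairs) / len(pairs)
        mat[i, j] = mat[j, i] = kimura_protein_distance(p, max_distance)
    return DistanceMatrix(ids=msa.ids, matrix=mat)


# ---------------------------------------------------------------------------
# neighbor joining and bootstrap


@dataclass
class TreeNode:
    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf():
            return [self.name]  # type: ignore[list-item]
        out: list[str] = []
        for c, _ in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class PhyloTree:
    root: TreeNode

    @property
    def leaf_names(self) -> list[str]:
        return sorted(self.root.leaves())

    def to_newick(self) -> str:
        def fmt(node: TreeNode, blen: float | None) -> str:
            if node.is_leaf():
                core = node.name or ""
            else:
                inner = ",".join(fmt(c, d) for c, d in node.children)
                label = "" if node.support is None else f"{node.support:g}"
                core = f"({inner}){label}"
            return core if blen is None else f"{core}:{blen:g}"

        return fmt(self.root, None) + ";"

    def bipartitions(self) -> dict[frozenset, TreeNode]:
        """Non-trivial splits, each keyed by the smaller-side leaf set."""
        all_leaves = frozenset(self.root.leaves())
        out: dict[frozenset, TreeNode] = {}

        def walk(node: TreeNode) -> None:
            for child, _ in node.children:
                below = frozenset(child.leaves())
                if 1 < len(below) < len(all_leaves) - 1:
                    other = all_leaves - below
                    key = min(below, other, key=lambda s: (len(s), sorted(s)))
                    out[key] = child
                walk(child)

        walk(self.root)
        return out

    def path_lengths(self) -> dict[frozenset, float]:
        """Leaf-to-leaf path lengths (for additivity checks)."""
        dists: dict[frozenset, float] = {}

        def walk(node: TreeNode) -> list[tuple[str, float]]:
            if node.is_leaf():
                return [(node.name, 0.0)]  # type: ignore[list-item]
            groups = []
            for child, blen in node.children:
                groups.append([(n, d + blen) for n, d in walk(child)])
            for gi, gj in combinations(groups, 2):
                for na, da in gi:
                    for nb, db in gj:
                        dists[frozenset((na, nb))] = da + db
            return [x for g in groups for x in g]

        walk(self.root)
        return dists


def nj_tree(dist: DistanceMatrix) -> PhyloTree:
    """Neighbor joining (Q criterion), lexicographic tie-breaks."""
    ids = list(dist.ids)
    if len(ids) < 3:
        raise CathmineError("nj_tree needs at least 3 taxa")
    nodes: dict[str, TreeNode] = {i: TreeNode(name=i) for i in ids}
    D: dict[frozenset, float] = {}
    for i, j in combinations(range(len(ids)), 2):
        D[frozenset((ids[i], ids[j]))] = float(dist.matrix[i, j])
    active = sorted(ids)
    pending: dict[str, float] = {}  # node key -> branch length to its parent-to-be
    counter = 0
    while len(active) > 2:
        r = len(active)
        totals = {a: sum(D[frozenset((a, b))] for b in active if b != a) for a in active}
        best = None
        for a, b in combinations(sorted(active), 2):
            q = (r - 2) * D[frozenset((a, b))] - totals[a] - totals[b]
            key = (q, a, b)
            if best is None or key < best:
                best = key
        _, a, b = best
        dab = D[frozenset((a, b))]
        la = 0.5 * dab + (totals[a] - totals[b]) / (2 * (r - 2))
        lb = dab - la
        la, lb = max(la, 0.0), max(lb, 0.0)
        new_key = f"@{counter}"
        counter += 1
        parent = TreeNode(children=[(nodes[a], la), (nodes[b], lb)])
        nodes[new_key] = parent
        for c in active:
            if c in (a, b):
                continue
            duc = 0.5 * (D[frozenset((a, c))] + D[frozenset((b, c))] - dab)
            D[frozenset((new_key, c))] = max(duc, 0.0)
        active = sorted([c for c in active if c not in (a, b)] + [new_key])
    a, b = active
    dab = D[frozenset((a, b))]
    root = TreeNode(children=[(nodes[a], 0.5 * dab), (nodes[b], 0.5 * dab)])
    # standard unrooted convention: if one side is internal, hang the other
    # from it so the root is trifurcating where possible
    if len(root.children) == 2 and not root.children[0][0].is_leaf():
        inner, _ = root.children[0]
        other, _ = root.children[1]
        inner.children.append((other, dab))
        root = inner
    elif len(root.children) == 2 and not root.children[1][0].is_leaf():
        inner, _ = root.children[1]
        other, _ = root.children[0]
        inner.children.append((other, dab))
        root = inner
    return PhyloTree(root=root)


def bootstrap(
    msa: Msa,
    n_reps: int,
    seed: int,
    max_distance: float = 10.0,
    resample: str = "bootstrap",
) -> PhyloTree:
    """NJ tree on the full alignment with column-bootstrap edge supports.

    ``resample='identity'`` replays the original columns (all supports 1),
    useful for calibration checks.
    """
    if n_reps < 1:
        raise CathmineError("n_reps must be >= 1")
    tree = nj_tree(protein_distance(msa, max_distance))
    target = tree.bipartitions()
    counts = {k: 0 for k in target}
    rng = np.random.default_rng(seed)
    ncols = msa.ncols
    for _ in range(n_reps):
        if resample == "identity":
            cols = np.arange(ncols)
        else:
            cols = rng.integers(0, ncols, size=ncols)
        rows = [(rid, "".join(s[c] for c in cols)) for rid, s in msa.rows]
        rep = nj_tree(protein_distance(Msa(rows=rows), max_distance))
        seen = rep.bipartitions()
        for k in counts:
            if k in seen:
                counts[k] += 1
    for k, node in target.items():
        node.support = counts[k] / n_reps
    return tree
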