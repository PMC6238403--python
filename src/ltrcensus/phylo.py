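"""RT/RNaseH phylogeny: domain extraction, alignment, neighbor joining,
bootstrap support and clade definition.

Clades follow the census rule: a monophyletic group is a clade when it
holds sequences from at least two distinct host species and its edge has
bootstrap support above 70 (out of 100 column-resampled replicates).
Distances are amino-acid proportions under pairwise deletion, with a
gamma rate-heterogeneity correction (shape 1.0) as the default model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .align import default_aa_scheme, sanitize_protein, search, six_frame_translate
from .families import Family, run_mafft


@dataclass(frozen=True)
class PhyloParams:
    model: str = "jtt_gamma"  # or "p_distance"
    gamma_shape: float = 1.0
    deletion: str = "pairwise"  # or "complete"
    bootstrap_reps: int = 100
    support_min: float = 70.0
    min_species: int = 2
    rng_seed: int = 0

    def __post_init__(self):
        if self.bootstrap_reps < 1:
            raise ValueError("bootstrap_reps must be >= 1")
        if not 0 < self.support_min <= 100:
            raise ValueError("support_min must lie in (0, 100]")
        if self.model not in ("p_distance", "jtt_gamma"):
            raise ValueError("model must be p_distance or jtt_gamma")
        if self.deletion not in ("pairwise", "complete"):
            raise ValueError("deletion must be pairwise or complete")


@dataclass
class DomainSeq:
    """An RT/RNaseH amino-acid sequence tied to a family and species."""

    family_id: str
    species: str
    aa_seq: str
    provenance: str = ""

    def __post_init__(self):
        if "*" in self.aa_seq:
            raise ValueError(f"{self.family_id}: internal stop in domain")


# ---------------------------------------------------------------------------
# Domain extraction


def extract_domain(family: Family, panel, max_e: float = 1e-3,
                   min_len: int = 100) -> tuple[DomainSeq | None, str]:
    """Translated RT/RNaseH envelope of the family representative.

    The envelope is the aligned query stretch of the best panel hit,
    frame-corrected. When the domain is interrupted by a frameshift,
    qualifying hits from other frames against the same panel subject are
    spliced, in query order, into one chimeric protein (overlapping
    residues trimmed from the later fragment). Families with no
    qualifying hit are excluded with a reason.
    """
    if family.domain_aa:
        return DomainSeq(family.family_id, family.species, family.domain_aa,
                         provenance="stored"), "ok"
    seq = family.representative_seq
    hits = search(seq, panel.as_database(), mode="blastx", max_e=max_e)
    if not hits:
        return None, "no panel hit"
    best = hits[0]
    subject = best.subject_id
    subject_aa = dict(panel.as_database())[subject]
    frames = {f: sanitize_protein(aa) for f, aa in six_frame_translate(seq)}
    scheme = default_aa_scheme()
    from .align import smith_waterman

    frame_hits = []
    for f, aa in frames.items():
        if not aa or (f > 0) != (best.frame > 0):
            continue  # splice only within one strand
        h = smith_waterman(aa, subject_aa, scheme)
        if h.score <= 0:
            continue
        frame_hits.append((f, h))
    # keep fragments scoring within a factor of the best, ordered by subject span
    top = max(h.score for _, h in frame_hits)
    frags = [(f, h) for f, h in frame_hits if h.score >= 0.15 * top]
    frags.sort(key=lambda fh: fh[1].subject_span[0])
    pieces: list[str] = []
    sub_end = -1
    for f, h in frags:
        ss, se = h.subject_span
        if se <= sub_end:
            continue  # contained in what we already have
        aa_frag = frames[f][h.query_span[0] : h.query_span[1]]
        overlap = max(sub_end - ss, 0)
        pieces.append(aa_frag[overlap:])
        sub_end = se
    domain = "".join(pieces)
    # isolated stop codons are decay substitutions; curation excises them
    # (like the frameshift splice) unless the domain is too corrupted
    n_stops = domain.count("*")
    if n_stops:
        if n_stops > max(2, int(0.05 * len(domain))):
            return None, f"too many internal stops ({n_stops})"
        domain = domain.replace("*", "")
    if len(domain) < min_len:
        return None, f"domain shorter than {min_len} aa"
    return DomainSeq(family.family_id, family.species, domain,
                     provenance=f"panel hit {subject}"), "ok"


def align_domains(domains: Sequence[DomainSeq]) -> dict[str, str]:
    """Multiple alignment of domain sequences (mafft). Requires >= 3."""
    if len(domains) < 3:
        raise ValueError("need at least 3 domains to align")
    seqs = {d.family_id: d.aa_seq for d in domains}
    return run_mafft(seqs, protein=True)


# ---------------------------------------------------------------------------
# Distances


def distance_matrix(msa: Mapping[str, str], params: PhyloParams = PhyloParams()
                    ) -> tuple[np.ndarray, list[str]]:
    """Pairwise amino-acid distances from an alignment.

    Gap handling follows the ``deletion`` option: pairwise deletion skips,
    per pair, only the columns where either row has a gap; complete
    deletion first removes every column with any gap. The proportion of
    differing shared columns p is returned as-is (p_distance) or
    gamma-corrected, d = a * ((1 - p)^(-1/a) - 1) with shape a, the
    standard correction for among-site rate variation (jtt_gamma).
    """
    labels = list(msa)
    rows = np.array([list(msa[l]) for l in labels])
    if params.deletion == "complete":
        keep = ~np.any(rows == "-", axis=0)
        rows = rows[:, keep]
    n = len(labels)
    D = np.zeros((n, n))
    gap = rows == "-"
    for i in range(n):
        for j in range(i + 1, n):
            shared = ~gap[i] & ~gap[j]
            m = int(shared.sum())
            if m == 0:
                raise ValueError(f"no shared columns between {labels[i]} and {labels[j]}")
            p = float(np.sum(rows[i][shared] != rows[j][shared])) / m
            D[i, j] = D[j, i] = _correct(p, params)
    return D, labels


def _correct(p: float, params: PhyloParams) -> float:
    if params.model == "p_distance":
        return p
    a = params.gamma_shape
    p = min(p, 0.95)  # saturation guard
    return a * ((1.0 - p) ** (-1.0 / a) - 1.0)


# ---------------------------------------------------------------------------
# Trees


@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]

    def newick(self, with_support: bool = True) -> str:
        return self._nwk(with_support) + ";"

    def _nwk(self, ws: bool) -> str:
        if self.is_leaf:
            return f"{self.name}:{self.length:.6g}"
        inner = ",".join(c._nwk(ws) for c in self.children)
        label = ""
        if ws and self.support is not None:
            label = f"{self.support:g}"
        return f"({inner}){label}:{self.length:.6g}"


def neighbor_joining(D: np.ndarray, labels: Sequence[str]) -> TreeNode:
    """Standard neighbor joining with deterministic tie-breaking.

    Q-criterion agglomeration; ties in Q resolve by the lexicographically
    smallest (min leaf label, max leaf label) pair of the joined subtrees.
    Negative branch lengths are clamped to zero with the length moved to
    the sibling branch. On an additive matrix the generating topology and
    branch lengths are recovered exactly.
    """
    D = np.asarray(D, dtype=float)
    n = len(labels)
    if D.shape != (n, n):
        raise ValueError("matrix/label size mismatch")
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if not np.allclose(D, D.T) or np.any(np.diag(D) != 0) or np.any(D < 0):
        raise ValueError("distance matrix must be symmetric, non-negative, zero-diagonal")

    nodes: list[TreeNode] = [TreeNode(name=l) for l in labels]
    # canonical label of a subtree: its smallest leaf name (for tie-breaks)
    canon = [l for l in labels]
    d = D.copy()
    active = list(range(n))
    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        ties = np.argwhere(np.isclose(q, qmin, rtol=0, atol=1e-12))
        best = min(
            ((i, j) for i, j in ties if i < j),
            key=lambda ij: tuple(sorted((canon[active[ij[0]]], canon[active[ij[1]]]))))
        ai, aj = best
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            li, lj = 0.0, dij
        elif lj < 0:
            li, lj = dij, 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)  # reduced distances can go negative
        ni, nj = nodes[i], nodes[j]
        ni.length, nj.length = li, lj
        new = TreeNode(children=[ni, nj])
        # distances to the new node
        new_idx = len(nodes)
        nodes.append(new)
        canon.append(min(canon[i], canon[j]))
        d = np.pad(d, ((0, 1), (0, 1)))
        for x in active:
            if x in (i, j):
                continue
            d[new_idx, x] = d[x, new_idx] = 0.5 * (d[i, x] + d[j, x] - dij)
        active = [x for x in active if x not in (i, j)] + [new_idx]
    i, j = active
    dij = d[i, j]
    # root between the last two nodes; the full edge length goes to one side
    nodes[i].length = max(dij, 0.0)
    nodes[j].length = 0.0
    root = TreeNode(children=[nodes[i], nodes[j]])
    return root


def leaf_distances(tree: TreeNode) -> dict[tuple[str, str], float]:
    """Path-length distances between all leaf pairs (oracle helper)."""
    out: dict[tuple[str, str], float] = {}

    def walk(node: TreeNode) -> dict[str, float]:
        if node.is_leaf:
            return {node.name: node.length}
        sides = [walk(c) for c in node.children]
        for a in range(len(sides)):
            for b in range(a + 1, len(sides)):
                for la, da in sides[a].items():
                    for lb, db in sides[b].items():
                        key = (min(la, lb), max(la, lb))
                        out[key] = da + db
        merged: dict[str, float] = {}
        for s in sides:
            for l, dd in s.items():
                merged[l] = dd + node.length
        return merged

    walk(tree)
    return out


def bipartitions(tree: TreeNode) -> dict[frozenset, TreeNode]:
    """Non-trivial bipartitions, keyed by the side not containing the
    lexicographically smallest leaf (canonical form); values are the
    internal nodes inducing them."""
    all_leaves = sorted(tree.leaf_names())
    ref = all_leaves[0]
    total = len(all_leaves)
    out: dict[frozenset, TreeNode] = {}

    def walk(node: TreeNode):
        for c in node.children:
            walk(c)
        if node.is_leaf:
            return
        side = frozenset(node.leaf_names())
        if ref in side:
            side = frozenset(all_leaves) - side
        if 2 <= len(side) <= total - 2:
            out[side] = node
    for c in tree.children:
        walk(c)
    return out


@dataclass
class SupportTree:
    """An NJ tree with bootstrap supports attached to internal edges."""

    tree: TreeNode
    supports: dict[frozenset, float]
    n_replicates: int

    def newick(self) -> str:
        return self.tree.newick(with_support=True)

    def leaf_names(self) -> list[str]:
        return self.tree.leaf_names()


def bootstrap_support(msa: Mapping[str, str], params: PhyloParams = PhyloParams()
                      ) -> SupportTree:
    """NJ tree of the full alignment with column-resampling bootstrap.

    Support of each internal edge is the percentage of replicates whose
    NJ tree contains the same bipartition. Seeded and deterministic.
    """
    rng = np.random.default_rng(params.rng_seed)
    labels = list(msa)
    D, _ = distance_matrix(msa, params)
    full = neighbor_joining(D, labels)
    parts = bipartitions(full)
    counts = {bp: 0 for bp in parts}
    ncol = len(next(iter(msa.values())))
    arr = {l: np.array(list(msa[l])) for l in labels}
    for _rep in range(params.bootstrap_reps):
        cols = rng.integers(0, ncol, size=ncol)
        sub = {l: "".join(arr[l][cols]) for l in labels}
        try:
            Db, _ = distance_matrix(sub, params)
        except ValueError:
            continue  # a pair lost all shared columns in this resample
        rep_tree = neighbor_joining(Db, labels)
        rep_parts = bipartitions(rep_tree)
        for bp in counts:
            if bp in rep_parts:
                counts[bp] += 1
    supports = {bp: 100.0 * c / params.bootstrap_reps for bp, c in counts.items()}
    for bp, node in parts.items():
        node.support = supports[bp]
    return SupportTree(tree=full, supports=supports, n_replicates=params.bootstrap_reps)


# ---------------------------------------------------------------------------
# Clade definition


@dataclass
class CladeCall:
    name: str
    members: list[str]  # family ids (references excluded)
    species: set[str]
    support: float
    lineage: str | None = None
    route: str = "phylogeny"


def define_clades(stree: SupportTree, species_of: Mapping[str, str],
                  params: PhyloParams = PhyloParams(),
                  reference_clades: Mapping[str, str] | None = None,
                  overrides: Mapping[str, frozenset] | None = None
                  ) -> tuple[list[CladeCall], list[str]]:
    """Call clades from supported bipartitions.

    A candidate group is a bipartition side with support above
    ``support_min`` (or named in ``overrides``, the escape hatch for
    manually accepted low-support groups) spanning at least
    ``min_species`` species. With ``reference_clades`` (labelled reference
    leaves in the tree), the clade for label c is the largest candidate
    side containing every reference of c and no reference of any other
    clade; candidate sides free of references become novel clades,
    largest-first among disjoint ones. Without references, the smaller
    side of each qualifying edge is the candidate and maximal disjoint
    groups are kept. Families in no clade are reported as "other".
    Returns (clade calls, other-family ids).
    """
    leaves = set(stree.leaf_names())
    refs = dict(reference_clades or {})
    fam_leaves = [l for l in leaves if l not in refs]
    overrides = dict(overrides or {})

    def supported(side: frozenset, support: float) -> bool:
        if support > params.support_min:
            return True
        return any(side == s for s in overrides.values())

    def n_species(side: frozenset) -> int:
        return len({species_of.get(l) for l in side if l in species_of and l not in refs})

    # enumerate candidate sides (both orientations of each bipartition)
    candidates: list[tuple[frozenset, float]] = []
    for part, support in stree.supports.items():
        comp = frozenset(leaves) - part
        for side in (part, comp):
            if supported(side, support) and n_species(side) >= params.min_species:
                candidates.append((side, support))

    calls: list[CladeCall] = []
    used: set[frozenset] = set()
    if refs:
        by_clade: dict[str, set[str]] = {}
        for leaf, clade in refs.items():
            by_clade.setdefault(clade, set()).add(leaf)
        for clade in sorted(by_clade):
            mine = by_clade[clade]
            others = set(refs) - mine
            pool = [(s, sup) for s, sup in candidates
                    if mine <= s and not (s & others)]
            if not pool:
                continue
            side, support = max(pool, key=lambda t: (len(t[0]), t[1], tuple(sorted(t[0]))))
            members = sorted(s for s in side if s not in refs)
            if not members:
                continue
            calls.append(CladeCall(name=clade, members=members,
                                   species={species_of[m] for m in members if m in species_of},
                                   support=support))
            used.add(side)
        # novel clades: reference-free candidate sides disjoint from all calls
        claimed: set[str] = set()
        for c in calls:
            claimed.update(c.members)
        novel_pool = [(s, sup) for s, sup in candidates if not (s & set(refs))]
        novel_pool.sort(key=lambda t: (-len(t[0]), tuple(sorted(t[0]))))
        n_novel = 0
        for side, support in novel_pool:
            members = sorted(side)
            if set(members) & claimed:
                continue
            n_novel += 1
            name = f"Novel-{n_novel}"
            if overrides:
                for oname, oside in overrides.items():
                    if side == oside:
                        name = oname
            calls.append(CladeCall(name=name, members=members,
                                   species={species_of[m] for m in members if m in species_of},
                                   support=support))
            claimed.update(members)
    else:
        all_leaves = frozenset(leaves)
        sized = []
        for side, support in candidates:
            pick = side if len(side) <= len(all_leaves) / 2 else all_leaves - side
            if not pick or len({species_of.get(l) for l in pick}) < params.min_species:
                continue
            sized.append((pick, support))
        sized.sort(key=lambda t: (-len(t[0]), tuple(sorted(t[0]))))
        claimed = set()
        n_grp = 0
        for side, support in sized:
            if set(side) & claimed:
                continue
            n_grp += 1
            name = f"Clade-{n_grp}"
            for oname, oside in (overrides or {}).items():
                if side == oside:
                    name = oname
            calls.append(CladeCall(name=name, members=sorted(side),
                                   species={species_of[m] for m in side if m in species_of},
                                   support=support))
            claimed.update(side)

    # lineages: a qualifying side containing >= 2 whole clade calls groups
    # them; each call records its smallest enclosing grouping
    call_sets = {c.name: set(c.members) for c in calls}
    groupings: list[list[str]] = []
    for side, _support in candidates:
        inside = [n for n, mem in call_sets.items() if mem and mem <= side]
        if len(inside) >= 2:
            groupings.append(inside)
    for c in calls:
        enclosing = [g for g in groupings if c.name in g]
        if enclosing:
            c.lineage = "+".join(sorted(min(enclosing, key=len)))

    claimed_all = set()
    for c in calls:
        claimed_all.update(c.members)
    other = sorted(l for l in fam_leaves if l not in claimed_all)
    calls.sort(key=lambda c: c.name)
    return calls, other


def clades_to_tsv(calls: Sequence[CladeCall], other: Sequence[str], path) -> None:
    with open(path, "w") as fh:
        fh.write("clade\tfamily\tspecies_count\tsupport\tlineage\troute\n")
        for c in calls:
            for m in c.members:
                fh.write(f"{c.name}\t{m}\t{len(c.species)}\t{c.support:.0f}\t"
                         f"{c.lineage or ''}\t{c.route}\n")
        for m in other:
            fh.write(f"other\t{m}\t\t\t\t\n")
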