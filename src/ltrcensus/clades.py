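"""Similarity-route clade assignment and mining of external collections.

Families that cannot be placed in a phylogeny are assigned to a known
clade by the five-best-hit rule: the five best hits against a classified
reference set must all carry the same clade label, and the best E-value
of any other clade must exceed the best same-clade E-value by more than
1e-10. External nucleotide collections (transcripts, unassembled
genome fragments) are mined by translated search with the census
thresholds — E <= 1e-70 and query cover > 80%, relaxed to 1e-40 and
> 50% for the scarcer Copia elements — and overlapping fragments of one
family can be merged into a chimeric element.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .align import (Hit, default_aa_scheme, evalue, sanitize_protein, search,
                    six_frame_translate, smith_waterman)
from .families import FamilyParams, passes_80_80_80
from .phylo import DomainSeq


@dataclass(frozen=True)
class CladeAssignParams:
    n_top_hits: int = 5
    evalue_gap_min: float = 1e-10
    # The printed gap rule ("difference between the best E-values higher
    # than 1e-10") is read as a magnitude gap by default: the best other-
    # clade E-value must be >= 10 orders of magnitude weaker. The literal
    # arithmetic difference is available as gap_mode="arithmetic", but for
    # homologous domains it degenerates to "no other clade hit under
    # 1e-10" and leaves almost everything unassigned.
    gap_mode: str = "log10"
    mining_max_e: float = 1e-70
    mining_min_cover: float = 80.0
    copia_max_e: float = 1e-40
    copia_min_cover: float = 50.0
    # significance floor for hits entering the five-hit rule; matches the
    # stringency the annotation stage uses for family assignment (1e-10)
    hit_max_e: float = 1e-10

    def __post_init__(self):
        if self.n_top_hits < 1:
            raise ValueError("n_top_hits must be >= 1")
        for t in (self.evalue_gap_min, self.mining_max_e, self.copia_max_e):
            if t <= 0:
                raise ValueError("thresholds must be positive")
        if self.gap_mode not in ("arithmetic", "log10"):
            raise ValueError("gap_mode must be arithmetic or log10")


@dataclass
class CladeAssignment:
    family_id: str
    clade: str | None
    route: str = "similarity"
    top_hits: list[tuple[str, str, float]] = field(default_factory=list)  # (subject, clade, E)
    e_gap: float | None = None
    reason: str = ""


def assign_by_similarity(domain: DomainSeq,
                         classified_db: Sequence[tuple[str, str, str]],
                         params: CladeAssignParams = CladeAssignParams()
                         ) -> CladeAssignment:
    """Five-best-hit clade assignment of one RT/RNaseH domain.

    ``classified_db`` rows are (id, aa sequence, clade). Assigned iff the
    ``n_top_hits`` best hits all carry one clade label AND the best
    E-value of any other clade exceeds the best same-clade E-value by
    more than ``evalue_gap_min`` (vacuously true when no other clade
    hits at all). The gap is the printed arithmetic difference by
    default; log10 mode (>= 10 orders of magnitude) is available and
    recorded in the result.
    """
    if not classified_db:
        raise ValueError("classified_db is empty")
    scheme = default_aa_scheme()
    q = sanitize_protein(domain.aa_seq)
    n_db = sum(len(s) for _, s, _ in classified_db)
    scored: list[tuple[str, str, float]] = []
    for sid, aa, clade in classified_db:
        h = smith_waterman(q, sanitize_protein(aa), scheme)
        if h.score <= 0:
            continue
        e = evalue(h.score, len(q), n_db, scheme)
        if e <= params.hit_max_e:
            scored.append((sid, clade, e))
    scored.sort(key=lambda t: (t[2], t[0]))
    top = scored[: params.n_top_hits]
    result = CladeAssignment(domain.family_id, None, top_hits=top)
    result.route = f"similarity/{params.gap_mode}"
    if not top:
        result.reason = "no hits"
        return result
    clades = {c for _, c, _ in top}
    if len(clades) != 1:
        result.reason = "top hits span multiple clades"
        return result
    clade = top[0][1]
    best_same = min(e for _, c, e in scored if c == clade)
    others = [e for _, c, e in scored if c != clade]
    if others:
        best_other = min(others)
        if params.gap_mode == "arithmetic":
            gap = best_other - best_same
            ok = gap > params.evalue_gap_min
        else:
            import math

            gap = math.log10(best_other) - math.log10(max(best_same, 1e-300))
            ok = gap >= 10.0
        result.e_gap = gap
        if not ok:
            result.reason = "insufficient E-value gap to other clades"
            return result
    result.clade = clade
    result.reason = "ok"
    return result


# ---------------------------------------------------------------------------
# Database mining


@dataclass
class MinedCandidate:
    candidate_id: str
    collection_id: str
    subject_span: tuple[int, int]
    frame: int
    aa_seq: str
    query_id: str
    superfamily: str


def mine_database(panel_queries: Sequence[DomainSeq | tuple[str, str, str]],
                  collection: Mapping[str, str],
                  params: CladeAssignParams = CladeAssignParams(),
                  relaxed_for_copia: bool = True,
                  fparams: FamilyParams = FamilyParams()
                  ) -> list[DomainSeq]:
    """Mine a nucleotide collection for RT/RNaseH-bearing elements.

    ``panel_queries`` are clade-representative domains, as DomainSeq (with
    superfamily in ``provenance``) or (id, aa, superfamily) tuples.
    Translated search applies (mining_max_e, mining_min_cover), relaxed
    to (copia_max_e, copia_min_cover) for Copia queries when
    ``relaxed_for_copia``. Hit envelopes are extracted as amino-acid
    sequences, clustered under the family comparator, and the largest
    sequence represents each mined family.
    """
    if not collection:
        return []
    queries: list[tuple[str, str, str]] = []
    for q in panel_queries:
        if isinstance(q, DomainSeq):
            queries.append((q.family_id, q.aa_seq, q.provenance or "unknown"))
        else:
            queries.append(tuple(q))
    candidates: list[MinedCandidate] = []
    for qid, aa, superfam in queries:
        relaxed = relaxed_for_copia and superfam == "Copia"
        max_e = params.copia_max_e if relaxed else params.mining_max_e
        min_cover = params.copia_min_cover if relaxed else params.mining_min_cover
        hits = search(aa, list(collection.items()), mode="tblastn",
                      max_e=max_e, min_coverage=min_cover, query_id=qid)
        for h in hits:
            subj_nt = collection[h.subject_id]
            frames = dict(six_frame_translate(subj_nt))
            aa_span = h.extra["aa_subject_span"]
            envelope = sanitize_protein(frames[h.frame])[aa_span[0] : aa_span[1]]
            if "*" in envelope:
                continue
            candidates.append(MinedCandidate(
                candidate_id=f"{h.subject_id}|{h.frame:+d}|{aa_span[0]}-{aa_span[1]}",
                collection_id=h.subject_id, subject_span=h.subject_span,
                frame=h.frame, aa_seq=envelope, query_id=qid, superfamily=superfam))
    if not candidates:
        return []
    # cluster envelopes (single linkage under the family comparator on aa)
    uniq: dict[str, MinedCandidate] = {}
    for c in sorted(candidates, key=lambda c: c.candidate_id):
        uniq.setdefault(c.candidate_id, c)
    items = list(uniq.values())
    n = len(items)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if items[i].superfamily != items[j].superfamily or find(i) == find(j):
                continue
            ok, *_ = passes_80_80_80(items[i].aa_seq, items[j].aa_seq, fparams)
            if ok:
                parent[find(i)] = find(j)
    groups: dict[int, list[MinedCandidate]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(items[i])
    out: list[DomainSeq] = []
    for gi, group in enumerate(sorted(groups.values(), key=lambda g: g[0].candidate_id), 1):
        rep = max(group, key=lambda c: (len(c.aa_seq), c.candidate_id))
        out.append(DomainSeq(
            family_id=f"mined-{rep.superfamily}-{gi}", species=rep.collection_id,
            aa_seq=rep.aa_seq,
            provenance=f"{rep.collection_id}:{rep.subject_span[0]}-{rep.subject_span[1]}({rep.frame:+d})"))
    return out


# ---------------------------------------------------------------------------
# Chimeric reconstruction


class ChimeraGapError(ValueError):
    """Fragments do not tile the domain; the gap is reported."""


def build_chimeric_element(fragments: Sequence[DomainSeq],
                           min_overlap: int = 20,
                           min_overlap_identity: float = 90.0) -> DomainSeq:
    """Merge overlapping domain fragments of one family into one sequence.

    Fragments must pairwise overlap by >= ``min_overlap`` aa at
    >= ``min_overlap_identity`` percent identity in the overlap; the
    merge is overlap-consistent, disagreements resolve by majority with
    ties to the earliest fragment in the input order.
    """
    if not fragments:
        raise ValueError("no fragments")
    if len(fragments) == 1:
        return fragments[0]
    scheme = default_aa_scheme()
    frags = list(fragments)
    # assembled consensus as list of per-column votes: (offset-aligned columns)
    placed: dict[int, tuple[int, str]] = {0: (0, frags[0].aa_seq)}  # idx -> (offset, seq)
    pending = list(range(1, len(frags)))
    while pending:
        progress = False
        for idx in list(pending):
            cand = frags[idx].aa_seq
            for pidx, (off, seq) in list(placed.items()):
                h = smith_waterman(sanitize_protein(cand), sanitize_protein(seq), scheme)
                if h.n_columns < min_overlap or h.identity_pct < min_overlap_identity:
                    continue
                # offset of cand relative to assembled frame
                cand_off = off + h.subject_span[0] - h.query_span[0]
                placed[idx] = (cand_off, cand)
                pending.remove(idx)
                progress = True
                break
            if progress:
                break
        if not progress:
            missing = ", ".join(frags[i].family_id or f"fragment {i}" for i in pending)
            raise ChimeraGapError(
                f"fragments do not overlap the assembly (>= {min_overlap} aa at "
                f">= {min_overlap_identity:.0f}%): {missing}")
    lo = min(off for off, _ in placed.values())
    hi = max(off + len(s) for off, s in placed.values())
    merged = []
    for col in range(lo, hi):
        votes: list[str] = []
        for idx in sorted(placed):
            off, s = placed[idx]
            if off <= col < off + len(s):
                votes.append(s[col - off])
        if not votes:
            raise ChimeraGapError(f"uncovered column at offset {col - lo} of the merged domain")
        counts: dict[str, int] = {}
        for v in votes:
            counts[v] = counts.get(v, 0) + 1
        best_n = max(counts.values())
        winner = next(v for v in votes if counts[v] == best_n)  # tie -> earliest fragment
        merged.append(winner)
    first = frags[0]
    return DomainSeq(family_id=first.family_id, species=first.species,
                     aa_seq="".join(merged), provenance="chimeric reconstruction")


def assignments_to_tsv(assignments: Sequence[CladeAssignment], path) -> None:
    with open(path, "w") as fh:
        fh.write("family\tclade\troute\ttop_hits\te_gap\treason\n")
        for a in assignments:
            tops = ",".join(f"{s}({c})" for s, c, _ in a.top_hits)
            gap = "" if a.e_gap is None else f"{a.e_gap:.3g}"
            fh.write(f"{a.family_id}\t{a.clade or 'unassigned'}\t{a.route}\t{tops}\t{gap}\t{a.reason}\n")
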