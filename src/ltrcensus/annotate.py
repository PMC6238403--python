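"""Library-based genome annotation: recover degraded copies, defragment
adjacent hits and assign copies to families.

The structural detector purposely misses truncated copies, solo LTRs and
heavily altered elements; this stage re-scans the genome with the curated
family library (seed-and-extend nucleotide search, divergence cut at 20%
by default), merges same-superfamily/same-strand fragments closer than
500 bp into single copies (incorporating the intervening sequence), and
assigns each copy to a family by best nucleotide hit at E <= 1e-10.
Copies whose only qualifying family lives in another species are flagged
for new-family definition; copies with no qualifying hit form the
discarded extra set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np

from .align import default_nt_scheme, evalue, _cigar_stats
from .families import Family, FamilyParams, TECopy, build_families, name_families, translatable_domain
from .io import revcomp
from .kmers import chain_seeds, kmer_codes, match_positions


@dataclass(frozen=True)
class ScanParams:
    """Genome-scan thresholds (divergence cut, defragmentation gap,
    assignment E-value)."""

    max_divergence: float = 20.0
    min_hit_len: int = 60
    min_hit_score: float = 40.0
    merge_gap_max: int = 500
    assign_max_e: float = 1e-10
    seed_k: int = 13
    max_band: int = 60
    chain_gap: int = 300

    def __post_init__(self):
        if not 0 < self.max_divergence < 100:
            raise ValueError("max_divergence must lie in (0, 100)")
        if self.merge_gap_max < 0:
            raise ValueError("merge_gap_max must be >= 0")


@dataclass
class RawHit:
    """One local library-vs-genome alignment fragment."""

    contig: str
    start: int
    end: int
    strand: str
    family_id: str
    superfamily: str
    species: str
    lib_span: tuple[int, int]
    score: float
    divergence: float

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AnnotatedCopy:
    """A defragmented genomic copy (possibly spanning merged fragments)."""

    contig: str
    start: int
    end: int
    strand: str
    superfamily: str
    family_id: str = "unassigned"
    species_hint: str = ""
    fragments: list[RawHit] = field(default_factory=list)
    score: float = 0.0
    status: str = "unassigned"  # assigned | cross_species_candidate | unassigned

    @property
    def length(self) -> int:
        return self.end - self.start


class LibraryIndex:
    """Sorted k-mer index over family representatives (both strands)."""

    def __init__(self, library: Sequence[Family] | Sequence[tuple[str, str, str, str]],
                 k: int = 13):
        # normalise to (family_id, superfamily, species, seq)
        self.entries: list[tuple[str, str, str, str]] = []
        for item in library:
            if isinstance(item, Family):
                self.entries.append((item.family_id, item.superfamily, item.species,
                                     item.representative_seq))
            else:
                self.entries.append(tuple(item))
        self.k = k
        codes_all: list[np.ndarray] = []
        meta_all: list[np.ndarray] = []
        pos_all: list[np.ndarray] = []
        for ei, (_fid, _sf, _sp, seq) in enumerate(self.entries):
            for si, s in enumerate((seq, revcomp(seq))):
                codes, pos = kmer_codes(s, k)
                codes_all.append(codes)
                pos_all.append(pos)
                meta_all.append(np.full(len(codes), 2 * ei + si, dtype=np.int64))
        if codes_all:
            codes = np.concatenate(codes_all)
            self._pos = np.concatenate(pos_all)
            self._meta = np.concatenate(meta_all)
            order = np.argsort(codes, kind="stable")
            self._codes_sorted = codes[order]
            self._order = order
        else:
            self._codes_sorted = np.empty(0, dtype=np.int64)
            self._order = np.empty(0, dtype=np.int64)
            self._pos = np.empty(0, dtype=np.int64)
            self._meta = np.empty(0, dtype=np.int64)

    def seeds(self, seq: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(genome positions, library positions, slot) of exact k-mer matches;
        slot encodes 2*entry + (0 fwd / 1 rev)."""
        qcodes, qpos = kmer_codes(seq, self.k)
        if len(qcodes) == 0 or len(self._codes_sorted) == 0:
            z = np.empty(0, dtype=np.int64)
            return z, z, z
        qi, ri = match_positions(qcodes, qpos, self._codes_sorted, self._order)
        return qpos[qi], self._pos[ri], self._meta[ri]


def _edlib_stats(query: str, target: str) -> tuple[float, float]:
    """(score under the +2/-3 gap 5/2 scheme, percent divergence) of the
    global alignment of two same-locus segments."""
    res = edlib.align(query, target, task="path", mode="NW")
    cols = ident = 0
    score = 0.0
    num = ""
    gapopens = 0
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        cols += n
        if ch == "=":
            ident += n
            score += 2.0 * n
        elif ch == "X":
            score -= 3.0 * n
        else:  # I or D
            score -= 5.0 + 2.0 * n
            gapopens += 1
    divergence = 100.0 * (1.0 - ident / cols) if cols else 100.0
    return score, divergence


def scan_genome(genome: Mapping[str, str], library, params: ScanParams = ScanParams()
                ) -> list[RawHit]:
    """Seed-and-extend nucleotide search of the family library against the
    genome; hits above the divergence cut are dropped."""
    index = library if isinstance(library, LibraryIndex) else LibraryIndex(library, params.seed_k)
    if not index.entries:
        return []
    hits: list[RawHit] = []
    for contig, seq in genome.items():
        gpos, lpos, meta = index.seeds(seq)
        if len(gpos) == 0:
            continue
        order = np.argsort(meta, kind="stable")
        gpos, lpos, meta = gpos[order], lpos[order], meta[order]
        boundaries = np.flatnonzero(np.concatenate(([True], meta[1:] != meta[:-1])))
        boundaries = np.append(boundaries, len(meta))
        for bi in range(len(boundaries) - 1):
            a, b = boundaries[bi], boundaries[bi + 1]
            slot = int(meta[a])
            ei, rev = divmod(slot, 2)
            fid, sf, sp, rep = index.entries[ei]
            chains = chain_seeds(gpos[a:b], lpos[a:b], index.k,
                                 max_band=params.max_band, max_gap=params.chain_gap,
                                 min_span=params.min_hit_len)
            ref_seq = revcomp(rep) if rev else rep
            for ch in chains:
                gseg = seq[ch.q_start : ch.q_end]
                lseg = ref_seq[ch.s_start : ch.s_end]
                score, div = _edlib_stats(gseg, lseg)
                if div > params.max_divergence or score < params.min_hit_score:
                    continue
                lib_span = ((len(rep) - ch.s_end, len(rep) - ch.s_start) if rev
                            else (ch.s_start, ch.s_end))
                hits.append(RawHit(contig=contig, start=ch.q_start, end=ch.q_end,
                                   strand="-" if rev else "+", family_id=fid,
                                   superfamily=sf, species=sp, lib_span=lib_span,
                                   score=score, divergence=div))
    hits.sort(key=lambda h: (h.contig, h.start, h.end, h.family_id))
    return _collapse_overlaps(hits)


def _collapse_overlaps(hits: list[RawHit], max_frac: float = 0.5) -> list[RawHit]:
    """Drop hits mostly covered by a better-scoring hit of the same
    superfamily (copies match several related library entries at once)."""
    kept: list[RawHit] = []
    for h in sorted(hits, key=lambda h: (-h.score, h.contig, h.start)):
        redundant = False
        for k in kept:
            if k.contig != h.contig or k.superfamily != h.superfamily:
                continue
            ov = min(k.end, h.end) - max(k.start, h.start)
            if ov > max_frac * h.length:
                redundant = True
                break
        if not redundant:
            kept.append(h)
    kept.sort(key=lambda h: (h.contig, h.start, h.end, h.family_id))
    return kept


def defragment(hits: Sequence[RawHit], merge_gap_max: int = 500) -> list[AnnotatedCopy]:
    """Merge same-superfamily, same-strand fragments closer than
    ``merge_gap_max`` (strictly) into single copies spanning the
    intervening sequence. Different superfamilies never merge. Idempotent
    and order-independent; per superfamily the output is non-overlapping.
    """
    groups: dict[tuple[str, str, str], list[RawHit]] = {}
    for h in hits:
        groups.setdefault((h.contig, h.superfamily, h.strand), []).append(h)
    copies: list[AnnotatedCopy] = []
    for (contig, sf, strand), group in sorted(groups.items()):
        group = sorted(group, key=lambda h: (h.start, h.end))
        current: list[RawHit] = [group[0]]
        for h in group[1:]:
            gap = h.start - max(x.end for x in current)
            if gap < merge_gap_max:
                current.append(h)
            else:
                copies.append(_make_copy(contig, sf, strand, current))
                current = [h]
        copies.append(_make_copy(contig, sf, strand, current))
    copies.sort(key=lambda c: (c.contig, c.start, c.superfamily))
    return copies


def _make_copy(contig: str, sf: str, strand: str, frags: list[RawHit]) -> AnnotatedCopy:
    best = max(frags, key=lambda h: h.score)
    return AnnotatedCopy(contig=contig, start=min(h.start for h in frags),
                         end=max(h.end for h in frags), strand=best.strand,
                         superfamily=sf, species_hint=best.species,
                         fragments=list(frags), score=sum(h.score for h in frags))


def assign_family(copy: AnnotatedCopy, genome: Mapping[str, str], library,
                  own_species: str, params: ScanParams = ScanParams()) -> AnnotatedCopy:
    """Best-nucleotide-hit family assignment at E <= ``assign_max_e``.

    A best family from another species flags the copy as a
    cross-species candidate for new-family definition; no qualifying hit
    leaves the copy unassigned (the discarded extra set).
    """
    index = library if isinstance(library, LibraryIndex) else LibraryIndex(library, params.seed_k)
    seq = genome[copy.contig][copy.start : copy.end]
    hits = scan_genome({"q": seq}, index, params)
    scheme = default_nt_scheme()
    n_db = sum(len(e[3]) for e in index.entries)
    best_fam, best_sp, best_e = None, None, np.inf
    for h in hits:
        e = evalue(h.score, len(seq), n_db, scheme)
        if e < best_e:
            best_fam, best_sp, best_e = h.family_id, h.species, e
    if best_fam is None or best_e > params.assign_max_e:
        copy.status = "unassigned"
        copy.family_id = "unassigned"
    elif best_sp != own_species:
        copy.status = "cross_species_candidate"
        copy.family_id = best_fam
    else:
        copy.status = "assigned"
        copy.family_id = best_fam
    return copy


def assign_copies(copies: Iterable[AnnotatedCopy], genome: Mapping[str, str],
                  library, own_species: str,
                  params: ScanParams = ScanParams()) -> list[AnnotatedCopy]:
    index = library if isinstance(library, LibraryIndex) else LibraryIndex(library, params.seed_k)
    return [assign_family(c, genome, index, own_species, params) for c in copies]


def promote_annotation_families(candidates: Sequence[AnnotatedCopy],
                                genome: Mapping[str, str], panel,
                                own_species: str,
                                fparams: FamilyParams = FamilyParams(),
                                start_index: dict[tuple[str, str], int] | None = None
                                ) -> list[Family]:
    """Define new families from cross-species candidates.

    Candidates must pass the translatable RT/RNaseH filter; survivors are
    clustered under the 80-80-80 rule and become families with origin
    ``annotation_derived``.
    """
    copies: list[TECopy] = []
    for i, c in enumerate(candidates):
        seq = genome[c.contig][c.start : c.end]
        if c.strand == "-":
            seq = revcomp(seq)
        domain, _hit, _reason = translatable_domain(seq, panel, fparams)
        if domain is None:
            continue
        copies.append(TECopy(f"rmcopy_{c.contig}_{c.start}", own_species,
                             c.superfamily, seq, c.strand, c.contig,
                             (c.start, c.end), provenance="genome_scan"))
    if not copies:
        return []
    from .families import cluster_copies

    clusters = cluster_copies(copies, fparams)
    return name_families(clusters, origin="annotation_derived", start_index=start_index)


def genomic_proportion(copies: Sequence[AnnotatedCopy], genome_length: int,
                       group_by: str = "superfamily",
                       clade_of: Mapping[str, str] | None = None):
    """Percent of the genome covered by each group (union of intervals).

    ``group_by`` is one of superfamily, family or clade (clade requires a
    family -> clade mapping; unmapped families count as 'other').
    Returns a pandas DataFrame (group, bp, percent).
    """
    import pandas as pd

    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    keyed: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for c in copies:
        if group_by == "superfamily":
            g = c.superfamily
        elif group_by == "family":
            g = c.family_id
        elif group_by == "clade":
            g = (clade_of or {}).get(c.family_id, "other")
        else:
            raise ValueError(f"unknown group_by: {group_by}")
        keyed.setdefault(g, {}).setdefault(c.contig, []).append((c.start, c.end))
    rows = []
    for g, by_contig in sorted(keyed.items()):
        bp = 0
        for intervals in by_contig.values():
            intervals.sort()
            cur_s, cur_e = intervals[0]
            for s, e in intervals[1:]:
                if s <= cur_e:
                    cur_e = max(cur_e, e)
                else:
                    bp += cur_e - cur_s
                    cur_s, cur_e = s, e
            bp += cur_e - cur_s
        rows.append({"group": g, "bp": bp, "percent": 100.0 * bp / genome_length})
    return pd.DataFrame(rows, columns=["group", "bp", "percent"])


def copies_to_tsv(copies: Iterable[AnnotatedCopy], path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tstart\tend\tstrand\tsuperfamily\tfamily_id\tstatus\tn_fragments\tscore\n")
        for c in copies:
            fh.write(f"{c.contig}\t{c.start}\t{c.end}\t{c.strand}\t{c.superfamily}\t"
                     f"{c.family_id}\t{c.status}\t{len(c.fragments)}\t{c.score:.1f}\n")


def copies_to_gff3(copies: Iterable[AnnotatedCopy], path) -> None:
    from .io import write_gff3

    feats = [(c.contig, "ltrcensus", "repeat_region", c.start, c.end, c.score,
              c.strand, {"superfamily": c.superfamily, "family": c.family_id,
                         "status": c.status})
             for c in copies]
    write_gff3(feats, path)
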