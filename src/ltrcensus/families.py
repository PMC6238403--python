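"""Family building: the 80-80-80 rule, cluster curation and orphan rescue.

Two copies belong to the same family when they align at >= 80% identity
over >= 80 bp covering >= 80% of each sequence's length. Families are the
single-linkage connected components of that relation; clusters whose
curated members still share >= 80% identity across clusters are merged;
copies that join no cluster are promoted to one-member families only if
they carry a translatable RT/RNaseH domain.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .align import (Hit, ReferencePanel, default_aa_scheme, global_identity,
                    infix_alignment, search)
from .io import fasta_string, read_fasta


@dataclass(frozen=True)
class FamilyParams:
    """Thresholds of the 80-80-80 comparator and the curation rule."""

    min_identity: float = 80.0
    min_overlap: int = 80
    min_length_fraction: float = 80.0
    insertion_purge_min: int = 20
    min_domain_aa: int = 100
    domain_max_e: float = 1e-5

    def __post_init__(self):
        if not (0 < self.min_identity <= 100 and 0 < self.min_length_fraction <= 100):
            raise ValueError("percent thresholds must lie in (0, 100]")
        if self.insertion_purge_min <= 0:
            raise ValueError("insertion_purge_min must be positive")


@dataclass
class TECopy:
    """A detected or annotation-derived element copy."""

    copy_id: str
    species: str
    superfamily: str
    seq: str
    strand: str = "+"
    contig: str | None = None
    span: tuple[int, int] | None = None
    provenance: str = "structural"  # structural | genome_scan | database_mining


@dataclass
class Family:
    """A named set of copies from one species; the census counting unit."""

    family_id: str
    species: str
    superfamily: str
    members: list[TECopy]
    origin: str = "cluster"  # cluster | orphan | external_reference | annotation_derived
    domain_aa: str | None = None
    consensus_seq: str | None = None  # majority consensus of the curated cluster

    def __post_init__(self):
        if not self.members:
            raise ValueError("a family needs at least one member")
        species = {m.species for m in self.members}
        superfams = {m.superfamily for m in self.members}
        if len(species) > 1 or len(superfams) > 1:
            raise ValueError("family members must share species and superfamily")

    @property
    def representative(self) -> TECopy:
        """Longest member (ties to the lexicographically first copy id)."""
        return max(self.members, key=lambda m: (len(m.seq), m.copy_id))

    @property
    def representative_seq(self) -> str:
        """Cluster consensus when available, else the longest member.

        Individual copies are frequently dead (stops, frameshifts from
        neutral decay); the majority consensus over the curated cluster
        alignment reconstructs a clean element the way manual curation
        of a family alignment would.
        """
        return self.consensus_seq or self.representative.seq


def passes_80_80_80(a: str, b: str, params: FamilyParams = FamilyParams()
                    ) -> tuple[bool, float, int, tuple[float, float]]:
    """Apply the 80-80-80 family comparator to two sequences.

    The shorter sequence is placed inside the longer by infix alignment
    (gap columns count against identity). Returns (verdict, identity %,
    aligned columns, (fraction of a, fraction of b) in percent). Symmetric
    by construction.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if len(a) <= len(b):
        short, long_, short_is_a = a, b, True
    else:
        short, long_, short_is_a = b, a, False
    identity, cols, span = infix_alignment(short, long_)
    frac_short = 100.0 * min(cols / len(short), 1.0)
    frac_long = 100.0 * (span[1] - span[0]) / len(long_)
    frac_a, frac_b = (frac_short, frac_long) if short_is_a else (frac_long, frac_short)
    ok = (identity >= params.min_identity and cols >= params.min_overlap
          and frac_a >= params.min_length_fraction and frac_b >= params.min_length_fraction)
    return ok, identity, cols, (frac_a, frac_b)


def cluster_copies(copies: Sequence[TECopy], params: FamilyParams = FamilyParams()
                   ) -> list[list[TECopy]]:
    """Single-linkage clusters under the 80-80-80 relation.

    Clusters are connected components of the pairwise-pass graph; the
    result is a partition of the input, independent of input order
    (components are canonicalised by copy id).
    """
    n = len(copies)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if (copies[i].superfamily != copies[j].superfamily
                    or copies[i].species != copies[j].species):
                continue
            if find(i) == find(j):
                continue
            ok, *_ = passes_80_80_80(copies[i].seq, copies[j].seq, params)
            if ok:
                parent[find(i)] = find(j)
    groups: dict[int, list[TECopy]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(copies[i])
    clusters = [sorted(g, key=lambda c: c.copy_id) for g in groups.values()]
    clusters.sort(key=lambda g: g[0].copy_id)
    return clusters


# ---------------------------------------------------------------------------
# Curation


def run_mafft(seqs: dict[str, str], protein: bool = False) -> dict[str, str]:
    """Align sequences with the mafft executable; returns aligned rows."""
    if len(seqs) < 2:
        return dict(seqs)
    exe = shutil.which("mafft")
    if exe is None:  # pragma: no cover - environment guard
        raise RuntimeError("mafft executable not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        inp = Path(tmp) / "in.fa"
        inp.write_text(fasta_string(seqs))
        args = [exe, "--quiet", "--auto"]
        if protein:
            args.append("--amino")
        out = subprocess.run(args + [str(inp)], capture_output=True, text=True, check=True)
        outp = Path(tmp) / "out.fa"
        outp.write_text(out.stdout)
        aligned = read_fasta(outp)
    # preserve input order; mafft keeps ids
    return {k: aligned[k].upper() for k in seqs}


def curate_cluster(seqs: dict[str, str], params: FamilyParams = FamilyParams(),
                   msa: dict[str, str] | None = None) -> dict[str, str]:
    """Excise copy-specific insertions longer than ``insertion_purge_min``.

    Columns of the cluster alignment occupied by exactly one member, in
    runs strictly longer than the threshold (20 bp by default), are
    removed from that member; shorter private insertions are kept.
    Singleton clusters are returned unchanged.
    """
    if len(seqs) < 2:
        return dict(seqs)
    if msa is None:
        msa = run_mafft(seqs)
    ids = list(msa)
    rows = [msa[i] for i in ids]
    ncol = len(rows[0])
    occupancy = [sum(1 for r in rows if r[c] != "-") for c in range(ncol)]
    curated: dict[str, str] = {}
    for ri, rid in enumerate(ids):
        row = rows[ri]
        drop = set()
        run: list[int] = []
        for c in range(ncol + 1):
            private = (c < ncol and row[c] != "-" and occupancy[c] == 1)
            if private:
                run.append(c)
            else:
                if len(run) > params.insertion_purge_min:
                    drop.update(run)
                run = []
        curated[rid] = "".join(ch for c, ch in enumerate(row) if ch != "-" and c not in drop)
    return curated


def cluster_consensus(msa: dict[str, str]) -> str:
    """Majority consensus of a cluster alignment.

    Per column, the most frequent residue wins (ties break to the first
    member in the alignment order); majority-gap columns are dropped.
    With >= 3 members this cleans most copy-private decay (random stops,
    small indels) out of the family sequence.
    """
    rows = list(msa.values())
    ncol = len(rows[0])
    out: list[str] = []
    for c in range(ncol):
        col = [r[c] for r in rows]
        counts: dict[str, int] = {}
        for ch in col:
            counts[ch] = counts.get(ch, 0) + 1
        best_n = max(counts.values())
        winner = next(ch for ch in col if counts[ch] == best_n)
        if winner != "-":
            out.append(winner)
    return "".join(out)


def curate_copy(copy_id: str, cluster_seqs: dict[str, str],
                params: FamilyParams = FamilyParams()) -> str:
    """Curated sequence of one member given its cluster context."""
    return curate_cluster(cluster_seqs, params)[copy_id]


# ---------------------------------------------------------------------------
# Merging and naming


_SPECIES_CODES: dict[str, str] = {}


def species_code(species: str) -> str:
    """Short code for family names, e.g. 'SpA' -> 'SA'."""
    if species not in _SPECIES_CODES:
        letters = [c for c in species if c.isalnum()]
        code = (letters[0] + letters[-1]).upper() if letters else "XX"
        _SPECIES_CODES[species] = code
    return _SPECIES_CODES[species]


def merge_clusters(clusters: Sequence[Sequence[TECopy]],
                   params: FamilyParams = FamilyParams(),
                   mode: str = "representative") -> list[list[TECopy]]:
    """Merge clusters whose elements share >= 80% identity; transitive.

    ``representative`` mode compares longest members; ``any_member`` mode
    merges when any cross-cluster pair passes. The merge relation is
    closed transitively (union-find), and the operation is idempotent.
    """
    reps = [max(cl, key=lambda c: (len(c.seq), c.copy_id)) for cl in clusters]
    n = len(clusters)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if reps[i].superfamily != reps[j].superfamily:
                continue
            if reps[i].species != reps[j].species:
                continue
            if find(i) == find(j):
                continue
            if mode == "representative":
                pairs = [(reps[i].seq, reps[j].seq)]
            else:
                pairs = [(a.seq, b.seq) for a in clusters[i] for b in clusters[j]]
            if any(passes_80_80_80(a, b, params)[0] for a, b in pairs):
                parent[find(i)] = find(j)
    merged: dict[int, list[TECopy]] = {}
    for i, cl in enumerate(clusters):
        merged.setdefault(find(i), []).extend(cl)
    out = [sorted(g, key=lambda c: c.copy_id) for g in merged.values()]
    out.sort(key=lambda g: g[0].copy_id)
    return out


def name_families(clusters: Sequence[Sequence[TECopy]], origin: str = "cluster",
                  start_index: dict[tuple[str, str], int] | None = None) -> list[Family]:
    """Wrap clusters into named families: <Superfamily>-<n>_<SpeciesCode>."""
    counters: dict[tuple[str, str], int] = dict(start_index or {})
    families = []
    for cl in clusters:
        sf, sp = cl[0].superfamily, cl[0].species
        counters[(sf, sp)] = counters.get((sf, sp), 0) + 1
        fid = f"{sf}-{counters[(sf, sp)]}_{species_code(sp)}"
        families.append(Family(family_id=fid, species=sp, superfamily=sf,
                               members=list(cl), origin=origin))
    return families


# ---------------------------------------------------------------------------
# Orphans


@dataclass
class DiscardRecord:
    copy_id: str
    reason: str


def translatable_domain(seq: str, panel: ReferencePanel,
                        params: FamilyParams = FamilyParams()
                        ) -> tuple[str | None, Hit | None, str]:
    """Best translated RT/RNaseH envelope of ``seq`` against the panel.

    Returns (domain amino acids, hit, reason). The domain qualifies only
    if the best panel hit's aligned query stretch is an open frame (no
    internal stop inside the hit envelope) of at least ``min_domain_aa``
    residues; otherwise (None, hit-or-None, reason).
    """
    hits = search(seq, panel.as_database(), mode="blastx", max_e=params.domain_max_e)
    if not hits:
        return None, None, "no panel hit"
    best = hits[0]
    from .align import sanitize_protein, six_frame_translate

    frames = dict(six_frame_translate(seq))
    aa_span = best.extra["aa_query_span"]
    envelope = sanitize_protein(frames[best.frame])[aa_span[0] : aa_span[1]]
    if "*" in envelope:
        return None, best, "internal stop in hit envelope"
    if len(envelope) < params.min_domain_aa:
        return None, best, f"domain shorter than {params.min_domain_aa} aa"
    return envelope, best, "ok"


def promote_orphans(singletons: Sequence[TECopy], panel: ReferencePanel,
                    params: FamilyParams = FamilyParams(),
                    start_index: dict[tuple[str, str], int] | None = None
                    ) -> tuple[list[Family], list[DiscardRecord]]:
    """Promote unclustered copies with a translatable RT/RNaseH domain to
    one-member families; list the rest as discards with reasons."""
    families: list[Family] = []
    discards: list[DiscardRecord] = []
    counters: dict[tuple[str, str], int] = dict(start_index or {})
    for copy in sorted(singletons, key=lambda c: c.copy_id):
        domain, hit, reason = translatable_domain(copy.seq, panel, params)
        if domain is None:
            discards.append(DiscardRecord(copy.copy_id, reason))
            continue
        key = (copy.superfamily, copy.species)
        counters[key] = counters.get(key, 0) + 1
        fid = f"{copy.superfamily}-{counters[key]}_{species_code(copy.species)}"
        families.append(Family(family_id=fid, species=copy.species,
                               superfamily=copy.superfamily, members=[copy],
                               origin="orphan", domain_aa=domain))
    return families, discards


def build_families(copies: Sequence[TECopy], panel: ReferencePanel,
                   params: FamilyParams = FamilyParams()
                   ) -> tuple[list[Family], list[DiscardRecord]]:
    """Full family-building stage: cluster, curate, merge, promote orphans.

    Copies are clustered per (species, superfamily); clusters of >= 2 are
    curated (copy-specific insertions > 20 bp excised) and merged; the
    remaining singletons go through the translatable-domain filter.
    """
    clusters = cluster_copies(copies, params)
    multi = [cl for cl in clusters if len(cl) >= 2]
    singletons = [cl[0] for cl in clusters if len(cl) == 1]
    curated_clusters: list[list[TECopy]] = []
    consensus_of: dict[str, str] = {}  # keyed by first copy id of the cluster
    for cl in multi:
        seqs = {c.copy_id: c.seq for c in cl}
        msa = run_mafft(seqs)
        curated = curate_cluster(seqs, params, msa=msa)
        consensus_of[cl[0].copy_id] = cluster_consensus(msa)
        curated_clusters.append([
            TECopy(c.copy_id, c.species, c.superfamily, curated[c.copy_id],
                   c.strand, c.contig, c.span, c.provenance) for c in cl])
    merged = merge_clusters(curated_clusters, params)
    families = name_families(merged, origin="cluster")
    for fam in families:
        keys = [m.copy_id for m in fam.members if m.copy_id in consensus_of]
        if keys:
            # after a merge, take the consensus of the largest pre-merge cluster
            best = max(keys, key=lambda k: (len(consensus_of[k]), k))
            fam.consensus_seq = consensus_of[best]
    counters: dict[tuple[str, str], int] = {}
    for fam in families:
        key = (fam.superfamily, fam.species)
        counters[key] = counters.get(key, 0) + 1
    orphan_fams, discards = promote_orphans(singletons, panel, params, start_index=counters)
    return families + orphan_fams, discards


def families_to_files(families: Iterable[Family], fasta_path, members_path) -> None:
    from .io import write_fasta

    fams = list(families)
    write_fasta({f.family_id: f.representative_seq for f in fams}, fasta_path)
    with open(members_path, "w") as fh:
        fh.write("family_id\tspecies\tsuperfamily\torigin\tcopy_id\tprovenance\n")
        for f in fams:
            for m in f.members:
                fh.write(f"{f.family_id}\t{f.species}\t{f.superfamily}\t{f.origin}\t"
                         f"{m.copy_id}\t{m.provenance}\n")
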