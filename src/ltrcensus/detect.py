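"""De-novo structural detection of paired-LTR retrotransposons.

Finds candidate elements as pairs of direct repeats satisfying the
canonical parameter window — LTR length in [80, 1500] bp, inter-LTR
distance in [2500, 11000] bp, LTR-LTR identity of at least 80% — by exact
k-mer seeding at in-window spacings, co-diagonal chaining, and global
alignment of the two repeat copies for the identity call.

Candidates are reported on the '+' strand; element strand is resolved
later from the frame of the best translated RT/RNaseH hit (LTRs are
direct repeats, so a reverse-complemented element still presents direct
repeats to the detector).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import global_identity
from .kmers import chain_seeds, kmer_codes


@dataclass(frozen=True)
class DetectionParams:
    """Structural search window. Defaults are the census parameters:
    LTR 80-1500 bp, inter-LTR distance 2500-11000 bp, identity >= 80%."""

    ltr_min: int = 80
    ltr_max: int = 1500
    dist_min: int = 2500
    dist_max: int = 11000
    ltr_identity_min: float = 80.0
    seed_k: int = 20
    max_band: int = 50
    distance_mode: str = "start_to_start"  # or "end_to_start"

    def __post_init__(self):
        if not (0 < self.ltr_min <= self.ltr_max):
            raise ValueError("need 0 < ltr_min <= ltr_max")
        if self.dist_min > self.dist_max:
            raise ValueError("need dist_min <= dist_max")
        if not (0 < self.ltr_identity_min <= 100):
            raise ValueError("ltr_identity_min must lie in (0, 100]")
        if self.distance_mode not in ("start_to_start", "end_to_start"):
            raise ValueError("distance_mode must be start_to_start or end_to_start")


@dataclass
class LTRCandidate:
    """A detected element: two LTR spans plus the internal region."""

    contig: str
    element_span: tuple[int, int]
    ltr5_span: tuple[int, int]
    ltr3_span: tuple[int, int]
    strand: str
    ltr_identity: float
    internal_span: tuple[int, int]
    extra: dict = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.element_span[1] - self.element_span[0]

    def sequence(self, contig_seq: str) -> str:
        return contig_seq[self.element_span[0] : self.element_span[1]]


def find_seed_matches(contig: str, k: int = 20,
                      window: tuple[int, int] = (2500, 11000)) -> list[tuple[int, int]]:
    """All exact k-mer repeats (direct orientation) at in-window spacing.

    Exhaustive: every pair of positions (p1 < p2) carrying the same k-mer
    with p2 - p1 inside ``window`` is reported exactly once, sorted.
    """
    if k < 8:
        raise ValueError("seed k must be >= 8")
    lo, hi = window
    codes, pos = kmer_codes(contig, k)
    if len(codes) == 0:
        return []
    order = np.argsort(codes, kind="stable")  # stable: positions stay ascending
    sc = codes[order]
    sp = pos[order]
    starts = np.flatnonzero(np.concatenate(([True], sc[1:] != sc[:-1])))
    ends = np.concatenate((starts[1:], [len(sc)]))
    pairs: list[tuple[int, int]] = []
    for a, b in zip(starts, ends):
        if b - a < 2:
            continue
        group = sp[a:b]
        for i in range(len(group) - 1):
            p1 = int(group[i])
            for j in range(i + 1, len(group)):
                d = int(group[j]) - p1
                if d > hi:
                    break
                if d >= lo:
                    pairs.append((p1, int(group[j])))
    pairs.sort()
    return pairs


def ltr_pair_identity(ltr5: str, ltr3: str) -> float:
    """Percent identity of the optimal global alignment of the two LTR
    copies; gap columns count as mismatch. Symmetric, in [0, 100]."""
    return global_identity(ltr5, ltr3)


def extend_and_call(contig_id: str, contig: str, seed_pairs: list[tuple[int, int]],
                    params: DetectionParams = DetectionParams()) -> list[LTRCandidate]:
    """Merge seed pairs into maximal repeat pairs and call candidates.

    Seed pairs sharing a spacing (within ``max_band``) and near-contiguous
    along the contig are chained into one repeat pair; the two repeat
    copies are globally aligned for the identity call; candidates failing
    any parameter bound are dropped; overlapping survivors are resolved by
    higher identity, then longer element, then leftmost start.
    """
    if not seed_pairs:
        return []
    q = np.array([p1 for p1, _ in seed_pairs], dtype=np.int64)
    s = np.array([p2 for _, p2 in seed_pairs], dtype=np.int64)
    chains = chain_seeds(q, s, params.seed_k, max_band=params.max_band,
                         max_gap=params.max_band)
    candidates: list[LTRCandidate] = []
    for ch in chains:
        ltr5 = (ch.q_start, ch.q_end)
        ltr3 = (ch.s_start, ch.s_end)
        if ltr5[1] > ltr3[0]:  # repeats must not overlap
            continue
        len5 = ltr5[1] - ltr5[0]
        len3 = ltr3[1] - ltr3[0]
        if not (params.ltr_min <= len5 <= params.ltr_max
                and params.ltr_min <= len3 <= params.ltr_max):
            continue
        if params.distance_mode == "start_to_start":
            dist = ltr3[0] - ltr5[0]
        else:
            dist = ltr3[0] - ltr5[1]
        if not (params.dist_min <= dist <= params.dist_max):
            continue
        ident = ltr_pair_identity(contig[ltr5[0]:ltr5[1]], contig[ltr3[0]:ltr3[1]])
        if ident < params.ltr_identity_min:
            continue
        candidates.append(LTRCandidate(
            contig=contig_id, element_span=(ltr5[0], ltr3[1]),
            ltr5_span=ltr5, ltr3_span=ltr3, strand="+",
            ltr_identity=ident, internal_span=(ltr5[1], ltr3[0])))
    return _resolve_overlaps(candidates)


def _resolve_overlaps(candidates: list[LTRCandidate]) -> list[LTRCandidate]:
    """Maximum-weight non-overlapping subset (weighted interval scheduling).

    Weight is the total matched repeat length scaled by identity, so two
    genuine adjacent elements always beat one spurious repeat pair
    bridging between them; ties resolve to higher identity, then longer
    element, then leftmost start via an epsilon on the weight ordering.
    """
    if not candidates:
        return []
    cands = sorted(candidates, key=lambda c: (c.element_span[1], c.element_span[0],
                                              -c.ltr_identity, -c.length))
    import bisect

    ends = [c.element_span[1] for c in cands]

    def weight(c: LTRCandidate) -> float:
        rep = (c.ltr5_span[1] - c.ltr5_span[0]) + (c.ltr3_span[1] - c.ltr3_span[0])
        return rep * (c.ltr_identity / 100.0)

    n = len(cands)
    best = [0.0] * (n + 1)
    take = [False] * n
    prev = [0] * n
    for i, c in enumerate(cands):
        prev[i] = bisect.bisect_right(ends, c.element_span[0], 0, i)
        with_c = best[prev[i]] + weight(c)
        if with_c > best[i]:
            best[i + 1] = with_c
            take[i] = True
        else:
            best[i + 1] = best[i]
    kept: list[LTRCandidate] = []
    i = n
    while i > 0:
        if take[i - 1]:
            kept.append(cands[i - 1])
            i = prev[i - 1]
        else:
            i -= 1
    kept.sort(key=lambda c: (c.contig, c.element_span[0]))
    return kept


def detect_contig(contig_id: str, contig: str,
                  params: DetectionParams = DetectionParams()) -> list[LTRCandidate]:
    """Full structural detection on one contig."""
    window = ((params.dist_min, params.dist_max) if params.distance_mode == "start_to_start"
              else (params.dist_min, params.dist_max + params.ltr_max))
    seeds = find_seed_matches(contig, params.seed_k, window)
    return extend_and_call(contig_id, contig, seeds, params)


def detect_genome(genome: dict[str, str],
                  params: DetectionParams = DetectionParams()) -> list[LTRCandidate]:
    out: list[LTRCandidate] = []
    for name, seq in genome.items():
        out.extend(detect_contig(name, seq, params))
    return out


def candidates_to_gff3(candidates: list[LTRCandidate], path) -> None:
    from .io import write_gff3

    feats = []
    for i, c in enumerate(candidates, 1):
        cid = f"ltr_element_{i}"
        feats.append((c.contig, "ltrcensus", "LTR_retrotransposon",
                      c.element_span[0], c.element_span[1], c.ltr_identity, c.strand,
                      {"ID": cid, "ltr_identity": f"{c.ltr_identity:.2f}"}))
        for part, span in (("five_prime", c.ltr5_span), ("three_prime", c.ltr3_span)):
            feats.append((c.contig, "ltrcensus", "long_terminal_repeat",
                          span[0], span[1], None, c.strand,
                          {"Parent": cid, "side": part}))
    write_gff3(feats, path)


def candidates_to_tsv(candidates: list[LTRCandidate], path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\telement_start\telement_end\tltr5_start\tltr5_end\t"
                 "ltr3_start\tltr3_end\tstrand\tltr_identity\n")
        for c in candidates:
            fh.write(f"{c.contig}\t{c.element_span[0]}\t{c.element_span[1]}\t"
                     f"{c.ltr5_span[0]}\t{c.ltr5_span[1]}\t{c.ltr3_span[0]}\t"
                     f"{c.ltr3_span[1]}\t{c.strand}\t{c.ltr_identity:.2f}\n")
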