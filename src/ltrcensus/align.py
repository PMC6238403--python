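"""Local-alignment search engine with analytic E-values.

Implements the alignment kernel used throughout the pipeline: affine-gap
Smith-Waterman (via Bio.Align.PairwiseAligner's C backend), six-frame
translation, Karlin-Altschul calibration of (lambda, K) for a scoring
scheme, E-value computation, ranked nucleotide/translated search with
E-value and query-coverage thresholds, superfamily classification against
a labelled RT/RNaseH reference panel, and a simple period-scan tandem
repeat masker.

E-values follow the ungapped Karlin-Altschul form E = K*m*n*exp(-lambda*S)
even for gapped scores: the pipeline uses E-values as deterministic,
monotone thresholds (1e-10, 1e-40, 1e-70 ...), not as calibrated tail
probabilities, so the analytic ungapped parameters are adequate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq
from scipy.optimize import brentq

from .io import revcomp

# Robinson & Robinson amino-acid background frequencies (order: standard 20).
_AA20 = "ARNDCQEGHILKMFPSTWYV"
_AA_FREQS = {
    "A": 0.07805, "R": 0.05129, "N": 0.04487, "D": 0.05364, "C": 0.01925,
    "Q": 0.04264, "E": 0.06295, "G": 0.07377, "H": 0.02199, "I": 0.05142,
    "L": 0.09019, "K": 0.05744, "M": 0.02243, "F": 0.03856, "P": 0.05203,
    "S": 0.07120, "T": 0.05841, "W": 0.01330, "Y": 0.03216, "V": 0.06441,
}


class ConfigurationError(ValueError):
    """Raised when a scoring scheme cannot be calibrated."""


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution scores plus affine gap penalties and KA parameters.

    ``gap_open``/``gap_extend`` are positive costs: a gap of length L costs
    gap_open + L * gap_extend (BLAST convention).
    """

    alphabet: str
    matrix: np.ndarray  # square, indexed by alphabet position
    gap_open: float
    gap_extend: float
    background: np.ndarray  # frequencies over ``calibration_alphabet``
    calibration_alphabet: str  # subset of alphabet used for lambda/K
    lambda_: float | None = None
    K: float | None = None
    name: str = ""

    def score(self, a: str, b: str) -> float:
        ia, ib = self.alphabet.index(a), self.alphabet.index(b)
        return float(self.matrix[ia, ib])

    @property
    def is_calibrated(self) -> bool:
        return self.lambda_ is not None and self.K is not None

    def _calibration_matrix(self) -> np.ndarray:
        idx = [self.alphabet.index(c) for c in self.calibration_alphabet]
        return self.matrix[np.ix_(idx, idx)]

    @property
    def expected_score(self) -> float:
        m = self._calibration_matrix()
        p = self.background
        return float(p @ m @ p)

    def make_aligner(self, mode: str = "local") -> PairwiseAligner:
        aligner = PairwiseAligner()
        aligner.mode = mode
        mat = substitution_matrices.Array(alphabet=self.alphabet, dims=2, data=self.matrix)
        aligner.substitution_matrix = mat
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend
        return aligner


def nucleotide_scheme(match: float = 2.0, mismatch: float = -3.0, gap_open: float = 5.0,
                      gap_extend: float = 2.0) -> ScoringScheme:
    """BLASTN-default-like nucleotide scheme (+2/-3, gap 5/2), uncalibrated."""
    alphabet = "ACGTN"
    mat = np.full((5, 5), mismatch)
    np.fill_diagonal(mat, match)
    mat[4, :] = mat[:, 4] = min(mismatch, -1.0)  # N never rewards
    return ScoringScheme(alphabet=alphabet, matrix=mat, gap_open=gap_open, gap_extend=gap_extend,
                         background=np.full(4, 0.25), calibration_alphabet="ACGT",
                         name=f"nt:{match:g}/{mismatch:g}")


def protein_scheme(gap_open: float = 11.0, gap_extend: float = 1.0) -> ScoringScheme:
    """BLOSUM62 with BLASTP-default gap costs, uncalibrated."""
    blosum = substitution_matrices.load("BLOSUM62")
    alphabet = str(blosum.alphabet)
    mat = np.asarray(blosum, dtype=float)
    bg = np.array([_AA_FREQS[a] for a in _AA20])
    return ScoringScheme(alphabet=alphabet, matrix=mat, gap_open=gap_open, gap_extend=gap_extend,
                         background=bg / bg.sum(), calibration_alphabet=_AA20, name="aa:BLOSUM62")


def calibrate(scheme: ScoringScheme) -> ScoringScheme:
    """Solve sum_ij p_i p_j exp(lambda * s_ij) = 1 for lambda > 0; estimate K.

    lambda is the unique positive root (it exists when the expected score is
    negative and a positive score is achievable). K uses the first-order
    approximation K = H / lambda where H is the relative entropy of the
    aligned-pair distribution — the right magnitude for threshold semantics.
    """
    m = scheme._calibration_matrix()
    p = scheme.background
    pp = np.outer(p, p)
    if scheme.expected_score >= 0:
        raise ConfigurationError("expected score under background must be negative")
    if m.max() <= 0:
        raise ConfigurationError("no positive score achievable; lambda has no positive root")

    def f(lam: float) -> float:
        return float(np.sum(pp * np.exp(lam * m))) - 1.0

    hi = 0.5
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e4:  # pragma: no cover - defensive
            raise ConfigurationError("failed to bracket lambda")
    lam = float(brentq(f, 1e-12, hi, xtol=1e-14, rtol=8.9e-16))
    # Relative entropy H = sum q_ij * lambda * s_ij with q_ij = p_i p_j e^{lam s_ij}
    q = pp * np.exp(lam * m)
    H = float(np.sum(q * lam * m))
    K = H / lam
    return replace(scheme, lambda_=lam, K=K)


def evalue(score: float, m: int, n: int, scheme: ScoringScheme) -> float:
    """Karlin-Altschul expectation E = K * m * n * exp(-lambda * score)."""
    if not scheme.is_calibrated:
        raise ConfigurationError("scheme is not calibrated")
    return scheme.K * m * n * math.exp(-scheme.lambda_ * score)


def bit_score(score: float, scheme: ScoringScheme) -> float:
    return (scheme.lambda_ * score - math.log(scheme.K)) / math.log(2)


# ---------------------------------------------------------------------------
# Alignment kernel


@dataclass
class Hit:
    """One local alignment between a query and a database subject."""

    query_id: str
    subject_id: str
    score: float
    evalue: float = math.inf
    bit_score: float = 0.0
    query_span: tuple[int, int] = (0, 0)      # in the query's native coordinates
    subject_span: tuple[int, int] = (0, 0)
    frame: int = 0                             # 0 for nt; +-1..3 for translated
    identity_pct: float = 0.0
    n_columns: int = 0
    n_ident: int = 0
    n_mismatch: int = 0
    n_gapopens: int = 0
    query_coverage: float = 0.0
    extra: dict = field(default_factory=dict)


def _alignment_stats(alignment) -> tuple[int, int, int, int]:
    """(columns, identities, mismatches, gap opens) of a Bio.Align alignment."""
    counts = alignment.counts()
    aligned_cols = counts.identities + counts.mismatches
    gaps = counts.gaps
    # gap opens: count maximal gap runs from the aligned blocks
    qa, sa = alignment.aligned
    gapopens = max(len(qa) - 1, 0) * 1  # each block boundary is one gap run
    return aligned_cols + gaps, counts.identities, counts.mismatches, gapopens


def smith_waterman(a: str, b: str, scheme: ScoringScheme,
                   query_id: str = "query", subject_id: str = "subject") -> Hit:
    """Optimal affine-gap local alignment of ``a`` vs ``b`` under ``scheme``.

    Returns a Hit with raw score, spans, identity over aligned columns
    (gap columns count against identity) and query coverage. A best score
    <= 0 yields the empty alignment (score 0).
    """
    for seq, label in ((a, "a"), (b, "b")):
        if not seq:
            raise ValueError(f"sequence {label} is empty")
        bad = set(seq) - set(scheme.alphabet)
        if bad:
            raise ValueError(f"sequence {label} contains letters outside the scheme alphabet: {sorted(bad)}")
    aligner = scheme.make_aligner("local")
    score = aligner.score(a, b)
    if score <= 0:
        return Hit(query_id, subject_id, 0.0)
    aln = next(iter(aligner.align(a, b)))
    cols, ident, mism, gapopens = _alignment_stats(aln)
    qa, sa = aln.aligned
    qs, qe = int(qa[0][0]), int(qa[-1][1])
    ss, se = int(sa[0][0]), int(sa[-1][1])
    identity = 100.0 * ident / cols if cols else 0.0
    return Hit(query_id, subject_id, float(score),
               query_span=(qs, qe), subject_span=(ss, se),
               identity_pct=identity, n_columns=cols, n_ident=ident,
               n_mismatch=mism, n_gapopens=gapopens,
               query_coverage=100.0 * (qe - qs) / len(a))


def global_identity(a: str, b: str) -> float:
    """Percent identity of the optimal global (NW) alignment, gaps as mismatch.

    Computed with edlib's bit-parallel unit-cost alignment; identity is
    matching columns over total aligned columns.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    res = edlib.align(a.upper(), b.upper(), task="path", mode="NW")
    cols, ident = _cigar_stats(res["cigar"])
    return 100.0 * ident / cols if cols else 0.0


def _cigar_stats(cigar: str) -> tuple[int, int]:
    """(aligned columns, match columns) from an edlib extended cigar."""
    cols = ident = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            cols += n
            if ch == "=":
                ident += n
    return cols, ident


def infix_alignment(short: str, long: str) -> tuple[float, int, tuple[int, int]]:
    """Best placement of ``short`` inside ``long`` (edlib HW mode).

    Returns (percent identity over aligned columns, aligned columns,
    (start, end) span on ``long``).
    """
    res = edlib.align(short.upper(), long.upper(), task="path", mode="HW")
    cols, ident = _cigar_stats(res["cigar"])
    start, end = res["locations"][0]
    return (100.0 * ident / cols if cols else 0.0), cols, (start, end + 1)


# ---------------------------------------------------------------------------
# Translation

_FRAMES = (1, 2, 3, -1, -2, -3)


def six_frame_translate(nuc: str) -> list[tuple[int, str]]:
    """Translate all six frames; stops rendered as '*'.

    Reverse frames -1/-2/-3 translate the reverse complement offset by
    0/1/2. Trailing bases short of a codon are dropped.
    """
    out = []
    rc = revcomp(nuc)
    for frame in _FRAMES:
        src = nuc if frame > 0 else rc
        off = abs(frame) - 1
        sub = src[off : off + 3 * ((len(src) - off) // 3)]
        aa = str(Seq(sub).translate()) if sub else ""
        out.append((frame, aa))
    return out


def frame_aa_to_nt_span(frame: int, aa_span: tuple[int, int], nt_len: int) -> tuple[int, int]:
    """Map an amino-acid span in a translation frame back to forward-strand
    nucleotide coordinates (0-based half-open)."""
    off = abs(frame) - 1
    s = off + 3 * aa_span[0]
    e = off + 3 * aa_span[1]
    if frame > 0:
        return s, e
    return nt_len - e, nt_len - s


def sanitize_protein(aa: str) -> str:
    """Replace letters outside the BLOSUM alphabet with 'X'."""
    allowed = set("ARNDCQEGHILKMFPSTWYVBZX*")
    return "".join(c if c in allowed else "X" for c in aa.upper())


def sanitize_dna(nt: str) -> str:
    allowed = set("ACGT")
    return "".join(c if c in allowed else "N" for c in nt.upper())


# ---------------------------------------------------------------------------
# Search

_NT_CAL = None
_AA_CAL = None


def default_nt_scheme() -> ScoringScheme:
    global _NT_CAL
    if _NT_CAL is None:
        _NT_CAL = calibrate(nucleotide_scheme())
    return _NT_CAL


def default_aa_scheme() -> ScoringScheme:
    global _AA_CAL
    if _AA_CAL is None:
        _AA_CAL = calibrate(protein_scheme())
    return _AA_CAL


def search(query: str, database: Mapping[str, str] | Sequence[tuple[str, str]],
           mode: str = "nt", scheme: ScoringScheme | None = None,
           max_e: float = 10.0, min_coverage: float = 0.0,
           query_id: str = "query") -> list[Hit]:
    """Rank database subjects by local-alignment E-value against ``query``.

    Modes: ``nt`` (nucleotide vs nucleotide, both strands), ``blastx``
    (nucleotide query translated in six frames vs protein subjects;
    ``translated`` is an alias) and ``tblastn`` (protein query vs
    six-frame-translated nucleotide subjects). Translated modes report the
    best frame per subject. Hits are sorted by ascending E-value, then
    descending score, then subject id; all pass (max_e, min_coverage) with
    coverage measured on the query.
    """
    if mode == "translated":
        mode = "blastx"
    items = list(database.items()) if isinstance(database, Mapping) else list(database)
    if not items:
        return []
    hits: list[Hit] = []
    if mode == "nt":
        sch = scheme or default_nt_scheme()
        aligner = sch.make_aligner("local")
        n_db = sum(len(s) for _, s in items)
        q = sanitize_dna(query)
        qrc = revcomp(q)
        for sid, subj in items:
            subj = sanitize_dna(subj)
            scored = [(float(aligner.score(qs, subj)), strand, qs)
                      for strand, qs in ((1, q), (-1, qrc))]
            best_score, strand, qs = max(scored, key=lambda t: (t[0], t[1]))
            if best_score <= 0 or evalue(best_score, len(q), n_db, sch) > max_e:
                continue
            best = smith_waterman(qs, subj, sch, query_id, sid)
            best.frame = strand if strand < 0 else 0
            if strand < 0:
                s, e = best.query_span
                best.query_span = (len(q) - e, len(q) - s)
            best.evalue = evalue(best.score, len(q), n_db, sch)
            best.bit_score = bit_score(best.score, sch)
            hits.append(best)
    elif mode == "blastx":
        sch = scheme or default_aa_scheme()
        aligner = sch.make_aligner("local")
        n_db = sum(len(s) for _, s in items)
        frames = [(f, sanitize_protein(aa)) for f, aa in six_frame_translate(sanitize_dna(query))]
        m = max(len(query) // 3, 1)
        for sid, subj in items:
            subj = sanitize_protein(subj)
            scored = [(float(aligner.score(aa, subj)), f, aa)
                      for f, aa in frames if aa]
            if not scored:
                continue
            best_score, f, aa = max(scored, key=lambda t: (t[0], -abs(t[1]), t[1]))
            if best_score <= 0 or evalue(best_score, m, n_db, sch) > max_e:
                continue
            best = smith_waterman(aa, subj, sch, query_id, sid)
            best.frame = f
            aa_span = best.query_span
            best.extra["aa_query_span"] = aa_span
            best.query_span = frame_aa_to_nt_span(best.frame, aa_span, len(query))
            best.query_coverage = 100.0 * (best.query_span[1] - best.query_span[0]) / len(query)
            best.evalue = evalue(best.score, m, n_db, sch)
            best.bit_score = bit_score(best.score, sch)
            hits.append(best)
    elif mode == "tblastn":
        sch = scheme or default_aa_scheme()
        aligner = sch.make_aligner("local")
        n_db = max(sum(len(s) for _, s in items) // 3, 1)
        q = sanitize_protein(query)
        for sid, subj in items:
            subj_nt = sanitize_dna(subj)
            frames = [(f, sanitize_protein(aa))
                      for f, aa in six_frame_translate(subj_nt) if aa]
            scored = [(float(aligner.score(q, aa)), f, aa) for f, aa in frames]
            if not scored:
                continue
            best_score, f, aa = max(scored, key=lambda t: (t[0], -abs(t[1]), t[1]))
            if best_score <= 0 or evalue(best_score, len(q), n_db, sch) > max_e:
                continue
            best = smith_waterman(q, aa, sch, query_id, sid)
            best.frame = f
            best.extra["aa_subject_span"] = best.subject_span
            best.subject_span = frame_aa_to_nt_span(best.frame, best.subject_span, len(subj))
            best.evalue = evalue(best.score, len(q), n_db, sch)
            best.bit_score = bit_score(best.score, sch)
            hits.append(best)
    else:
        raise ValueError(f"unknown search mode: {mode!r}")

    hits = [h for h in hits if h.evalue <= max_e and h.query_coverage >= min_coverage]
    hits.sort(key=lambda h: (h.evalue, -h.score, h.subject_id))
    return hits


def hits_to_table(hits: Iterable[Hit]) -> str:
    """12-column BLAST-style tab-separated hit table."""
    rows = []
    for h in hits:
        rows.append("\t".join(str(x) for x in (
            h.query_id, h.subject_id, f"{h.identity_pct:.2f}", h.n_columns,
            h.n_mismatch, h.n_gapopens, h.query_span[0] + 1, h.query_span[1],
            h.subject_span[0] + 1, h.subject_span[1], f"{h.evalue:.3g}",
            f"{h.bit_score:.1f}")))
    return "\n".join(rows)


# ---------------------------------------------------------------------------
# Reference panel


@dataclass
class PanelEntry:
    entry_id: str
    aa_seq: str
    superfamily: str
    clade: str | None = None


@dataclass
class ReferencePanel:
    """Labelled RT/RNaseH amino-acid references for classification.

    Mirrors the published panel structure (164 Copia / 122 BEL-Pao /
    116 Gypsy references in the source census; synthetic panels are
    smaller but carry the same labels).
    """

    entries: list[PanelEntry]

    def __post_init__(self):
        seen = set()
        for e in self.entries:
            if e.entry_id in seen:
                raise ValueError(f"duplicate panel id: {e.entry_id}")
            seen.add(e.entry_id)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for e in self.entries:
            out[e.superfamily] = out.get(e.superfamily, 0) + 1
        return out

    def as_database(self) -> list[tuple[str, str]]:
        return [(e.entry_id, e.aa_seq) for e in self.entries]

    def superfamily_of(self, entry_id: str) -> str:
        return self._by_id()[entry_id].superfamily

    def clade_of(self, entry_id: str) -> str | None:
        return self._by_id()[entry_id].clade

    def _by_id(self) -> dict[str, PanelEntry]:
        return {e.entry_id: e for e in self.entries}

    def one_per_clade(self) -> "ReferencePanel":
        """Slim panel with the first entry of each (superfamily, clade);
        sufficient for superfamily classification and envelope extraction."""
        seen: set[tuple[str, str | None]] = set()
        kept = []
        for e in self.entries:
            key = (e.superfamily, e.clade)
            if key not in seen:
                seen.add(key)
                kept.append(e)
        return ReferencePanel(kept)

    @classmethod
    def from_files(cls, fasta_path, labels_path) -> "ReferencePanel":
        from .io import read_fasta

        seqs = read_fasta(fasta_path)
        entries = []
        with open(labels_path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                eid, superfam = parts[0], parts[1]
                clade = parts[2] if len(parts) > 2 and parts[2] else None
                entries.append(PanelEntry(eid, seqs[eid], superfam, clade))
        return cls(entries)

    def to_files(self, fasta_path, labels_path) -> None:
        from .io import write_fasta

        write_fasta({e.entry_id: e.aa_seq for e in self.entries}, fasta_path)
        with open(labels_path, "w") as fh:
            fh.write("#id\tsuperfamily\tclade\n")
            for e in self.entries:
                fh.write(f"{e.entry_id}\t{e.superfamily}\t{e.clade or ''}\n")


def classify_superfamily(seq: str, panel: ReferencePanel, max_e: float = 1e-5,
                         scheme: ScoringScheme | None = None) -> tuple[str, str | None, Hit | None]:
    """Superfamily of the single best translated hit against the panel.

    Returns (label, strand, best hit); no hit under ``max_e`` gives
    ("unclassified", None, None). Strand is the sign of the best frame.
    """
    hits = search(seq, panel.as_database(), mode="blastx", scheme=scheme, max_e=max_e)
    if not hits:
        return "unclassified", None, None
    best = hits[0]
    strand = "+" if best.frame > 0 else "-"
    return panel.superfamily_of(best.subject_id), strand, best


# ---------------------------------------------------------------------------
# Tandem repeat masking


def mask_tandem_repeats(seq: str, min_period: int = 1, max_period: int = 50,
                        min_copies: int = 3, min_identity: float = 80.0,
                        min_array_len: int = 24, hard: bool = True
                        ) -> tuple[str, list[tuple[int, int]]]:
    """Detect and mask tandem arrays by a period autocorrelation scan.

    For each period p the sequence is compared with itself shifted by p;
    dense runs of agreement longer than max(min_copies * p, min_array_len)
    with at least ``min_identity`` percent matches are reported as arrays
    and masked (N by default, lowercase if ``hard`` is false). A simple
    stand-in for dedicated tandem-repeat finders; exact parity with them
    is a non-goal.
    """
    n = len(seq)
    if n == 0:
        return "", []
    s = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    mask = np.zeros(n, dtype=bool)
    intervals: list[tuple[int, int]] = []
    max_gap = 2  # tolerated mismatch run inside an array
    for p in range(min_period, min(max_period, n - 1) + 1):
        eq = s[:-p] == s[p:]
        if not eq.any():
            continue
        need = max(min_copies * p, min_array_len)
        # merge True-runs separated by <= max_gap mismatches
        idx = np.flatnonzero(eq)
        if idx.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(idx) > max_gap + 1)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [idx.size - 1]))
        for a, b in zip(starts, ends):
            lo, hi = int(idx[a]), int(idx[b]) + 1  # run on the shifted comparison
            run_len = hi - lo + p  # array footprint on the sequence
            if run_len < need:
                continue
            matches = int(eq[lo:hi].sum())
            if 100.0 * matches / (hi - lo) < min_identity:
                continue
            mask[lo : hi + p] = True
    if not mask.any():
        return seq, []
    # collect masked intervals
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(n)
    intervals = [(int(a), int(b)) for a, b in zip(starts, ends)]
    chars = list(seq)
    for a, b in intervals:
        for i in range(a, b):
            chars[i] = "N" if hard else chars[i].lower()
    return "".join(chars), intervals
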